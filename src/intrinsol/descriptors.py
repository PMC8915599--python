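"""Feature-table assembly: computed 2D descriptor panel plus ingested Abraham
descriptors and melting points.

The 2D panel is computed with RDKit from SMILES; the five Abraham solvation
descriptors (A: H-bond acidity, B: H-bond basicity, Spi: dipolarity/
polarizability, E: excess molar refraction in (cm3/mol)/10, V: McGowan
volume in (cm3/mol)/100) come from an external table -- their reference
calculator is commercial software, so they are inputs here. Melting points
may be measured or predicted; predicted values carry a flag and are used
when no measurement exists, mirroring common curation practice. The panel
membership is whatever the installed toolkit exports and is recorded with
any fitted model for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ABRAHAM_NAMES = ["A", "B", "Spi", "E", "V"]

#: design matrices by model family
FEATURE_SETS = ("gse", "absolv", "absolv_qa", "rfr_full")


@dataclass
class DescriptorVector:
    abraham: dict = field(default_factory=dict)   # A, B, Spi, E, V
    tm: float | None = None
    tm_predicted: bool = False
    panel: dict = field(default_factory=dict)     # named 2D descriptors
    missing: set = field(default_factory=set)


def compute_descriptor_panel(smiles: str) -> DescriptorVector:
    """Compute the full RDKit 2D descriptor panel for one structure.

    The panel includes logP ("MolLogP", reported as "logP"), molar
    refractivity ("MolMR" -> "MR"), the LabuteASA / SlogP_VSA / SMR_VSA /
    PEOE_VSA surface-area partitions, BertzCT, Ipc, the Chi connectivity
    indices, HallKierAlpha and atom/ring counts. Deterministic for a fixed
    toolkit version.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    panel = dict(Descriptors.CalcMolDescriptors(mol))
    # field-standard aliases
    panel["logP"] = panel["MolLogP"]
    panel["MR"] = panel["MolMR"]
    missing = {k for k, v in panel.items() if v is None or (isinstance(v, float) and np.isnan(v))}
    return DescriptorVector(panel=panel, missing=missing)


def _require(df: pd.DataFrame, cols: list[str], context: str) -> None:
    absent = [c for c in cols if c not in df.columns]
    if absent:
        raise ValueError(f"{context}: missing column(s) {absent}")


def assemble_feature_matrix(
    descriptor_table: pd.DataFrame,
    feature_set: str,
    molecule_ids=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the design matrix for one model family.

    ``descriptor_table`` is indexed (or indexable) by ``molecule_id`` and
    carries Abraham columns, ``tm_C``/``tm_predicted`` and any 2D panel
    columns. Feature sets:

    * ``gse``       -> [logP, tm_C]
    * ``absolv``    -> [A, B, Spi, E, V, AB] (AB = elementwise A*B)
    * ``absolv_qa`` -> [A, B, Spi]
    * ``rfr_full``  -> every numeric descriptor column plus tm_C and the
      Abraham five.

    Rows with missing mandatory features are excluded and listed in the
    returned exclusion report -- never silently imputed. A melting point
    flagged predicted is used as-is (the flag travels with the table).

    Returns ``(X, excluded)`` where ``X`` is a molecule-id-indexed frame
    with a fixed, recorded column order.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; choose from {FEATURE_SETS}")
    df = descriptor_table.copy()
    if df.index.name != "molecule_id":
        _require(df, ["molecule_id"], "descriptor table")
        df = df.set_index("molecule_id")
    if molecule_ids is not None:
        df = df.loc[[m for m in molecule_ids if m in df.index]]

    if feature_set == "gse":
        _require(df, ["logP", "tm_C"], "gse feature set")
        X = df[["logP", "tm_C"]].astype(float)
    elif feature_set == "absolv":
        _require(df, ABRAHAM_NAMES, "absolv feature set")
        X = df[ABRAHAM_NAMES].astype(float)
        X["AB"] = X["A"] * X["B"]
    elif feature_set == "absolv_qa":
        _require(df, ["A", "B", "Spi"], "absolv_qa feature set")
        X = df[["A", "B", "Spi"]].astype(float)
    else:  # rfr_full
        meta = {"tm_predicted", "abclass", "name", "smiles"}
        num = df.drop(columns=[c for c in meta if c in df.columns])
        num = num.select_dtypes(include=[np.number]).astype(float)
        # fixed, recorded order: Abraham block, tm, then the panel sorted
        front = [c for c in (*ABRAHAM_NAMES, "tm_C") if c in num.columns]
        rest = sorted(c for c in num.columns if c not in front)
        X = num[front + rest]

    bad = X.isna().any(axis=1)
    excluded = pd.DataFrame({
        "molecule_id": X.index[bad],
        "missing": [",".join(X.columns[X.loc[i].isna()]) for i in X.index[bad]],
    })
    if len(excluded):
        logger.warning("%d row(s) excluded from %s matrix for missing features",
                       len(excluded), feature_set)
    return X[~bad], excluded
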