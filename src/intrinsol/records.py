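"""Data model, unit normalization and duplicate reconciliation for solubility records.

Literature solubility values arrive in a zoo of units (molarity, molality,
mg/mL, %w/v, "1 in 15 parts of water", ...). Everything is converted once,
at ingestion, to the canonical internal scale: log10 molar at the reported
temperature. Records that cannot be converted are never silently dropped --
each rejected row is returned with a reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# pKa sanity window for aqueous measurements
PKA_MIN, PKA_MAX = -2.0, 16.0
# database span of curated intrinsic values, log molar
LOG_S0_MIN, LOG_S0_MAX = -12.0, 2.0
# temperature assumed when a source says "room temperature" or is silent
ROOM_TEMPERATURE_C = 23.0


class ABClass(str, Enum):
    """Predominant charge state at pH 7.4."""

    ACID = "acid"            # (-)
    BASE = "base"            # (+)
    NEUTRAL = "neutral"      # (0)
    ZWITTERION = "zwitterion"  # (+/-)
    QUATERNARY = "quaternary"  # permanently charged; excluded from 4-class sets


class MeasurementKind(str, Enum):
    S0 = "S0"          # intrinsic (uncharged form)
    SW = "Sw"          # free acid/base in initially pure water
    SPH = "SpH"        # buffered, at a stated pH
    PROFILE = "profile"  # one point of a log S - pH profile


class UnitError(ValueError):
    """Raised when a reported unit cannot be converted to molarity."""


@dataclass
class PKa:
    value: float
    group: str  # "acid" | "base"

    def __post_init__(self) -> None:
        if self.group not in ("acid", "base"):
            raise ValueError(f"pKa group must be 'acid' or 'base', got {self.group!r}")
        if not (PKA_MIN <= self.value <= PKA_MAX):
            raise ValueError(f"pKa {self.value} outside [{PKA_MIN}, {PKA_MAX}]")


@dataclass
class MoleculeRecord:
    id: str
    name: str = ""
    structure: str = ""          # SMILES (synthetic placeholders allowed)
    mw: float | None = None      # g/mol
    tm: float | None = None      # melting point, degC
    tm_predicted: bool = False
    pkas: list[PKa] = field(default_factory=list)
    abclass: ABClass | None = None
    identity_key: str | None = None

    def __post_init__(self) -> None:
        if self.mw is not None and not self.mw > 0:
            raise ValueError(f"mw must be > 0, got {self.mw}")
        if isinstance(self.abclass, str):
            self.abclass = ABClass(self.abclass)
        self.pkas = [p if isinstance(p, PKa) else PKa(*p) for p in self.pkas]


@dataclass
class SolubilityMeasurement:
    molecule_id: str
    kind: MeasurementKind
    value: float                 # in the reported unit
    unit: str
    pH: float | None = None
    temperature: float = ROOM_TEMPERATURE_C
    sd_log: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            self.kind = MeasurementKind(self.kind)
        if not self.value > 0:
            raise ValueError("solubility value must be > 0 before log transform")
        if self.kind in (MeasurementKind.SPH, MeasurementKind.PROFILE) and self.pH is None:
            raise ValueError(f"{self.kind.value} measurement requires a pH")


@dataclass
class IntrinsicEntry:
    """One curated intrinsic solubility value, log molar at a stated temperature."""

    molecule_id: str
    log_s0: float
    sd_log: float | None = None
    derivation: str = "reported"   # reported | from_Sw | from_profile
    temperature: float = 25.0
    source: str = ""

    def __post_init__(self) -> None:
        if not (LOG_S0_MIN <= self.log_s0 <= LOG_S0_MAX):
            raise ValueError(
                f"log_s0 {self.log_s0} outside plausible span [{LOG_S0_MIN}, {LOG_S0_MAX}]"
            )


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

#: units convertible without a molecular weight (already amount/volume)
_MOLAR_UNITS = {"mol/L": 1.0, "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6}

#: mass-based units: factor converts the numeric value to g/L
_MASS_UNITS_G_PER_L = {
    "mg/mL": 1.0,
    "g/L": 1.0,
    "ug/mL": 1e-3,
    "µg/mL": 1e-3,
    "mg/L": 1e-3,
    "mg/100mL": 1e-2,
    "mg%": 1e-2,        # mg per 100 mL
    "%w/v": 10.0,       # g per 100 mL
}


def convert_to_molar(value: float, unit: str, mw: float | None = None) -> tuple[float, dict]:
    """Convert a reported solubility to molarity (mol/L).

    ``parts`` follows the pharmacopoeial convention "1 g of solute per
    `value` mL of water"; ``mol/kg`` (molality) is returned as a molarity
    equivalent assuming solution density 1.00 g/mL and flagged
    ``approximate_molality``.

    Returns ``(molarity, flags)``; raises :class:`UnitError` for units with
    no defined conversion (e.g. ``IU/mL``) and ``ValueError`` when a
    mass-based unit lacks a molecular weight.
    """
    if not value > 0:
        raise ValueError(f"non-positive value {value}")
    flags: dict = {}
    if unit in _MOLAR_UNITS:
        return value * _MOLAR_UNITS[unit], flags
    if unit in ("mol/kg", "m"):
        flags["approximate_molality"] = True
        return value, flags
    if unit in _MASS_UNITS_G_PER_L:
        if mw is None or not mw > 0:
            raise ValueError(f"unit {unit!r} requires a positive molecular weight")
        return value * _MASS_UNITS_G_PER_L[unit] / mw, flags
    if unit == "parts":
        # "1 in N parts of water": 1 g per N mL -> 1000/N g per L
        if mw is None or not mw > 0:
            raise ValueError("unit 'parts' requires a positive molecular weight")
        flags["parts_convention"] = "1 g per value mL"
        return (1000.0 / value) / mw, flags
    raise UnitError(f"no conversion defined for unit {unit!r}")


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = [
    "molecule_id", "name", "smiles", "kind", "value", "unit",
    "pH", "temp_C", "sd_log", "source",
]
_MANDATORY = ["molecule_id", "kind", "value", "unit"]


def read_measurements(path) -> tuple[list[SolubilityMeasurement], pd.DataFrame]:
    """Read a measurements CSV; return (measurements, rejects).

    Parsing is total: every input row ends up either in the parsed list or
    in the rejects table (columns of the input plus ``reason``). A missing
    mandatory column is a hard failure naming the column.
    """
    df = pd.read_csv(path, dtype={"molecule_id": str})
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"measurements file is missing mandatory column {col!r}")
    parsed: list[SolubilityMeasurement] = []
    reject_rows: list[dict] = []
    for _, row in df.iterrows():
        reason = None
        try:
            value = float(row["value"])
            if not value > 0:
                reason = "non-positive value"
            else:
                unit = str(row["unit"]).strip()
                kind = MeasurementKind(str(row["kind"]).strip())
                ph = row.get("pH")
                ph = None if pd.isna(ph) else float(ph)
                temp = row.get("temp_C")
                if temp is None or pd.isna(temp):
                    temp = ROOM_TEMPERATURE_C
                sd = row.get("sd_log")
                sd = None if sd is None or pd.isna(sd) else float(sd)
                # probe convertibility now so unconvertible units are rejected here
                mw_probe = row.get("mw")
                mw_probe = None if mw_probe is None or pd.isna(mw_probe) else float(mw_probe)
                if unit not in _MOLAR_UNITS and unit not in ("mol/kg", "m"):
                    if unit not in _MASS_UNITS_G_PER_L and unit != "parts":
                        raise UnitError(f"no conversion defined for unit {unit!r}")
                parsed.append(SolubilityMeasurement(
                    molecule_id=str(row["molecule_id"]), kind=kind, value=value,
                    unit=unit, pH=ph, temperature=float(temp), sd_log=sd,
                    source="" if pd.isna(row.get("source")) else str(row.get("source")),
                ))
        except (ValueError, UnitError) as exc:
            reason = reason or str(exc)
        if reason is not None:
            rec = row.to_dict()
            rec["reason"] = reason
            reject_rows.append(rec)
            logger.warning("rejected row for %s: %s", row.get("molecule_id"), reason)
    rejects = pd.DataFrame(reject_rows)
    assert len(parsed) + len(rejects) == len(df)
    return parsed, rejects


def write_intrinsic(entries: Iterable[IntrinsicEntry], path) -> None:
    pd.DataFrame(
        [
            {
                "molecule_id": e.molecule_id,
                "log_s0": e.log_s0,
                "sd_log": e.sd_log,
                "derivation": e.derivation,
                "temp_C": e.temperature,
            }
            for e in entries
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Duplicate-molecule reconciliation
# ---------------------------------------------------------------------------

def identity_key(smiles: str) -> str | None:
    """Canonical SMILES of the parent (largest organic fragment), salts stripped.

    Returns None when the structure does not parse.
    """
    from rdkit import Chem
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if "." in smiles:
        mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
    return Chem.MolToSmiles(mol)


def dedupe_molecules(records: Sequence[MoleculeRecord]) -> list[list[str]]:
    """Partition record ids into same-molecule groups.

    Two records merge iff their identity keys agree (canonical parent
    SMILES) or their Morgan-fingerprint Tanimoto similarity is exactly 1.0
    -- the fingerprint route catches differently drawn inputs that
    canonicalize apart. Unparseable structures form singleton groups with a
    warning.
    """
    from rdkit import Chem, DataStructs
    from rdkit.Chem import rdFingerprintGenerator

    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    keys: dict[str, int] = {}
    fps = [None] * n
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    for i, rec in enumerate(records):
        key = rec.identity_key or identity_key(rec.structure)
        if key is None:
            logger.warning("unparseable structure for %s; singleton group", rec.id)
            continue
        rec.identity_key = key
        if key in keys:
            union(keys[key], i)
        else:
            keys[key] = i
        mol = Chem.MolFromSmiles(key)
        fps[i] = gen.GetFingerprint(mol)
    # fingerprint pass over group representatives
    reps = sorted({find(i) for i in range(n) if fps[i] is not None})
    for a_pos, i in enumerate(reps):
        for j in reps[a_pos + 1:]:
            if find(i) != find(j) and DataStructs.TanimotoSimilarity(fps[i], fps[j]) == 1.0:
                union(i, j)
    groups: dict[int, list[str]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(find(i), []).append(rec.id)
    return sorted(groups.values(), key=lambda g: g[0])


# ---------------------------------------------------------------------------
# Rule-of-5 profiling
# ---------------------------------------------------------------------------

def rule_of_5_profile(props: pd.DataFrame) -> pd.DataFrame:
    """Druglikeness profile over a property table.

    ``props`` needs (any of) the columns ``MW``, ``logP``, ``NHD``, ``NHA``.
    Returns one row per criterion with the count evaluated, count passing
    and fraction; rows with a missing property are excluded from that
    criterion's tally (and counted in ``n_missing``).
    """
    criteria = {
        "MW<500": ("MW", lambda s: s < 500),
        "logP in [0,5]": ("logP", lambda s: (s >= 0) & (s <= 5)),
        "NHD<=5": ("NHD", lambda s: s <= 5),
        "NHA<=10": ("NHA", lambda s: s <= 10),
    }
    out = []
    for label, (col, pred) in criteria.items():
        if col not in props.columns:
            out.append({"criterion": label, "n": 0, "n_pass": 0,
                        "fraction": math.nan, "n_missing": len(props)})
            continue
        s = pd.to_numeric(props[col], errors="coerce")
        ok = s.notna()
        n = int(ok.sum())
        n_pass = int(pred(s[ok]).sum())
        out.append({
            "criterion": label, "n": n, "n_pass": n_pass,
            "fraction": (n_pass / n) if n else math.nan,
            "n_missing": int(len(props) - n),
        })
    return pd.DataFrame(out)
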