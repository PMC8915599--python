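"""Evaluation statistics, train/test protocol, interlaboratory
reproducibility, PCA chemical-space maps and the three-model benchmark.

Conventions (kept deliberately, and documented because two of them differ
from the most common textbook choices):

* r^2 = 1 - sum(obs - calc)^2 / sum(obs - <obs>)^2 -- can go negative for a
  bad model and is never clamped.
* SD uses the population (1/n) form, matching the convention of the
  interlaboratory statistic this module reproduces; the sample (1/(n-1))
  form is NOT used for per-molecule scatter.
* MPP ("measure of prediction performance") is the percentage of absolute
  residuals <= 0.5 log units, boundary inclusive.
* F = (n - p - 1)/p * sum(obs - <obs>)^2 / sum(obs - calc)^2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .descriptors import assemble_feature_matrix
from .forest import rfr_fit
from .linear import absolv_fit, gse_fit, gse_fixed_model, gse_predict

logger = logging.getLogger(__name__)

MPP_THRESHOLD = 0.5


@dataclass
class EvaluationReport:
    n: int
    r2: float
    rmse: float
    bias: float
    f_stat: float | None
    mpp: float
    class_scope: str = "all"

    def as_dict(self) -> dict:
        return {
            "n": self.n, "r2": self.r2, "rmse": self.rmse, "bias": self.bias,
            "F": self.f_stat, "mpp": self.mpp, "class_scope": self.class_scope,
        }


def metrics(y_obs, y_calc, p: int = 0, class_scope: str = "all") -> EvaluationReport:
    """Prediction-quality statistics for one model on one set of values.

    ``p`` is the number of fitted model parameters (enters only the F
    statistic, which is reported None with a warning when n <= p + 1).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    if len(y_obs) != len(y_calc):
        raise ValueError("length mismatch")
    n = len(y_obs)
    resid = y_obs - y_calc
    rss = float(np.sum(resid**2))
    dev = float(np.sum((y_obs - y_obs.mean()) ** 2))
    r2 = 1.0 - rss / dev if dev > 0 else (1.0 if rss == 0 else -math.inf)
    rmse = math.sqrt(rss / n)
    bias = float(resid.mean())
    mpp = 100.0 * float(np.sum(np.abs(resid) <= MPP_THRESHOLD)) / n
    if p > 0 and n > p + 1 and rss > 0:
        f = (n - p - 1) / p * dev / rss
    else:
        f = None
        if p > 0 and n <= p + 1:
            warnings.warn(f"F statistic undefined for n={n}, p={p}", stacklevel=2)
    return EvaluationReport(n=n, r2=r2, rmse=rmse, bias=bias, f_stat=f,
                            mpp=mpp, class_scope=class_scope)


# ---------------------------------------------------------------------------
# Train/test protocol
# ---------------------------------------------------------------------------

def split_train_test(ids, fraction: float = 0.70, seed: int = 0,
                     stratify_by=None) -> tuple[list, list]:
    """Random 70/30 (by default) split into training and internal test ids.

    With ``stratify_by`` (a class label per id) each class is split to the
    target fraction within one member; classes with a single member go to
    the training set with a warning. Deterministic for a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ids = list(ids)
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        order = rng.permutation(len(ids))
        n_train = int(round(fraction * len(ids)))
        train = [ids[i] for i in order[:n_train]]
        test = [ids[i] for i in order[n_train:]]
        return sorted(train), sorted(test)
    labels = list(stratify_by)
    if len(labels) != len(ids):
        raise ValueError("stratify_by must align with ids")
    train, test = [], []
    for lab in sorted(set(map(str, labels))):
        members = [i for i, l in zip(ids, labels) if str(l) == lab]
        if len(members) < 2:
            warnings.warn(f"class {lab!r} has <2 members; placed in train", stacklevel=2)
            train.extend(members)
            continue
        order = rng.permutation(len(members))
        n_train = int(round(fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# Interlaboratory reproducibility
# ---------------------------------------------------------------------------

def _c4(n: int) -> float:
    """Normal-theory bias factor E[sample SD]/sigma for n draws."""
    return math.sqrt(2.0 / (n - 1)) * math.exp(gammaln(n / 2) - gammaln((n - 1) / 2))


@dataclass
class InterlabReport:
    per_molecule: pd.DataFrame       # molecule_id, n, mean, sd (population form)
    sd_avg: float | None             # unweighted mean of per-molecule SDs
    sd_avg_corrected: float | None   # bias-corrected estimate of the lab noise sigma
    n_replicated: int
    trend: pd.DataFrame              # SD vs binned mean log S0


def interlab_reproducibility(entries: pd.DataFrame, n_bins: int = 6) -> InterlabReport:
    """Interlaboratory scatter of replicated intrinsic solubility values.

    ``entries`` needs columns ``molecule_id`` and ``log_s0`` (one row per
    source). Only molecules reported by at least two sources enter the
    statistic. Per-molecule SD uses the population (1/n) formula; ``sd_avg``
    is the unweighted mean of those SDs -- the convention of the printed
    0.17-log-unit figure. Because the population SD of a handful of draws
    is biased low, ``sd_avg_corrected`` divides each per-molecule SD by
    c4(n)*sqrt((n-1)/n) before averaging, giving an unbiased estimate of
    the underlying lab-to-lab sigma. The trend table bins mean log S0
    against SD (low-solubility molecules tend to scatter more).
    """
    g = entries.groupby("molecule_id")["log_s0"]
    per = pd.DataFrame({"n": g.size(), "mean": g.mean()})
    def _pop_sd(s: pd.Series) -> float:
        v = s.to_numpy(dtype=float)
        if np.all(v == v[0]):  # exact replicates: exactly zero, no float dust
            return 0.0
        return float(np.sqrt(np.mean((v - v.mean()) ** 2)))

    per["sd"] = g.apply(_pop_sd)
    rep = per[per["n"] >= 2].copy()
    if len(rep) == 0:
        logger.warning("no replicated molecules; SD_avg undefined")
        sd_avg = sd_corr = None
    else:
        sd_avg = float(rep["sd"].mean())
        corr = rep.apply(
            lambda r: r["sd"] / (_c4(int(r["n"])) * math.sqrt((r["n"] - 1) / r["n"])),
            axis=1,
        )
        sd_corr = float(corr.mean())
    if len(rep):
        bins = pd.cut(rep["mean"], bins=n_bins)
        trend = rep.groupby(bins, observed=True).agg(
            n_molecules=("sd", "size"), mean_log_s0=("mean", "mean"), sd=("sd", "mean")
        ).reset_index(names="bin")
    else:
        trend = pd.DataFrame(columns=["bin", "n_molecules", "mean_log_s0", "sd"])
    return InterlabReport(
        per_molecule=per.reset_index(), sd_avg=sd_avg, sd_avg_corrected=sd_corr,
        n_replicated=int(len(rep)), trend=trend,
    )


# ---------------------------------------------------------------------------
# PCA chemical-space map and nearest neighbors
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    loadings: np.ndarray             # p x k, orthonormal columns
    scores: np.ndarray               # n x k
    explained_variance_ratio: np.ndarray
    columns: list[str]
    dropped: list[str] = field(default_factory=list)


def pca_fit(X: pd.DataFrame | np.ndarray) -> PCAResult:
    """PCA on population-standardized columns via the covariance eigenproblem.

    Zero-variance columns are dropped with a warning. Sign convention: the
    largest-|loading| element of each component is made positive. Explained
    variance fractions sum to 1 over the returned components.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(map(str, X.columns))
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        cols = [f"x{i}" for i in range(M.shape[1])]
    if M.shape[0] <= 2:
        raise ValueError("need n > 2 rows")
    if np.isnan(M).any():
        raise ValueError("missing cells not allowed in PCA input")
    mu = M.mean(axis=0)
    sigma = M.std(axis=0)  # population
    keep = sigma > 0
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance column(s): {dropped}", stacklevel=2)
    Z = (M[:, keep] - mu[keep]) / sigma[keep]
    cov = Z.T @ Z / Z.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    evr = evals / total if total > 0 else evals
    return PCAResult(
        loadings=evecs, scores=Z @ evecs, explained_variance_ratio=evr,
        columns=[c for c, k in zip(cols, keep) if k], dropped=dropped,
    )


def nearest_neighbors(scores: np.ndarray, ids, query_id, k: int = 5,
                      ncomp: int = 3, responses=None) -> pd.DataFrame:
    """k nearest neighbors of one molecule in the first ``ncomp`` PCA scores.

    Euclidean distance; the query itself is excluded. When ``responses``
    (e.g. log S0 values) are supplied, the neighbor response spread is
    reported -- high spread marks a "missing neighbors" region where a
    local average is unreliable.
    """
    ids = list(ids)
    scores = np.asarray(scores, dtype=float)
    if ncomp > scores.shape[1]:
        raise ValueError(f"ncomp={ncomp} exceeds available components {scores.shape[1]}")
    if k >= len(ids):
        raise ValueError(f"k={k} must be smaller than the number of molecules")
    qi = ids.index(query_id)
    d = np.sqrt(((scores[:, :ncomp] - scores[qi, :ncomp]) ** 2).sum(axis=1))
    d[qi] = np.inf
    nn = np.argsort(d, kind="stable")[:k]
    out = pd.DataFrame({"molecule_id": [ids[i] for i in nn], "distance": d[nn]})
    if responses is not None:
        resp = np.asarray(responses, dtype=float)
        out["response"] = resp[nn]
        out.attrs["response_variance"] = float(np.var(resp[nn]))
        out.attrs["query_response"] = float(resp[qi])
    return out


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

def _metric_row(model, scope, split, y_obs, y_calc, p, **extra):
    rep = metrics(y_obs, y_calc, p=p, class_scope=scope)
    row = {"model": model, "scope": scope, "split": split, **rep.as_dict()}
    row.pop("class_scope")
    row.update(extra)
    return row


def run_benchmark(
    data: pd.DataFrame,
    models=("gse_fixed", "gse_trained", "absolv", "rfr"),
    fraction: float = 0.70,
    seed: int = 0,
    ntree: int = 200,
    nodesize: int = 5,
    by_class: bool = True,
) -> dict:
    """Train/test benchmark of the three predictor families on one table.

    ``data`` is molecule-level with columns ``molecule_id``, ``log_s0``,
    ``sd_log``, ``abclass``, ``logP``, ``tm_C``, the Abraham five and any
    extra descriptor columns (used by the forest). The table is split
    70/30 stratified by acid-base class; quaternary ammonium rows are
    excluded from the four-class models and routed to the quaternary
    ABSOLV form only. A model failure marks its rows failed and the run
    continues.

    Returns ``{"table": DataFrame, "models": {...}, "importances": Series,
    "split": (train_ids, test_ids)}``.
    """
    df = data.set_index("molecule_id") if "molecule_id" in data.columns else data.copy()
    qa = df["abclass"].astype(str) == "quaternary"
    main = df[~qa]
    train_ids, test_ids = split_train_test(
        main.index, fraction=fraction, seed=seed,
        stratify_by=main["abclass"].astype(str) if by_class else None,
    )
    tr, te = main.loc[train_ids], main.loc[test_ids]
    rows: list[dict] = []
    fitted: dict = {}
    importances = None

    canonical = ["acid", "base", "neutral", "zwitterion"]

    def scopes(frame):
        yield "all", frame
        if by_class:
            for c in canonical:
                yield c, frame[frame["abclass"].astype(str) == c]

    for name in models:
        try:
            if name == "gse_fixed":
                fitted[name] = gse_fixed_model()
                predict = lambda g: gse_predict(g["logP"], g["tm_C"])
                p_fit = 0
                rows.append(_metric_row(name, "all", "train", tr["log_s0"],
                                        predict(tr), p=0))
            elif name == "gse_trained":
                model = gse_fit(tr["logP"], tr["tm_C"], tr["log_s0"], tr.get("sd_log"))
                fitted[name] = model
                predict = lambda g: model.predict(g[["logP"]].assign(
                    tm25=np.maximum(g["tm_C"] - 25.0, 0.0))[["logP", "tm25"]].to_numpy())
                p_fit = 3
            elif name == "absolv":
                model = absolv_fit(tr, tr["log_s0"], tr.get("sd_log"))
                fitted[name] = model
                predict = lambda g: model.predict(
                    g.assign(AB=g["A"] * g["B"])[["A", "B", "Spi", "E", "V", "AB"]])
                p_fit = 7
            elif name == "rfr":
                X_all, _ = assemble_feature_matrix(
                    df.drop(columns=["log_s0", "sd_log"], errors="ignore").reset_index(),
                    "rfr_full")
                forest = rfr_fit(X_all.loc[train_ids], tr["log_s0"],
                                 ntree=ntree, nodesize=nodesize, seed=seed)
                fitted[name] = forest
                importances = forest.feature_importance.sort_values(ascending=False)
                predict = lambda g: forest.predict(X_all.loc[g.index])
                p_fit = 0
                rows.append(_metric_row(name, "all", "train", tr["log_s0"],
                                        forest.predict(X_all.loc[train_ids]), p=0))
                have = forest.oob_counts > 0
                rows.append(_metric_row(name, "all", "oob",
                                        tr["log_s0"].to_numpy()[have],
                                        forest.oob_predictions[have], p=0))
            else:
                raise ValueError(f"unknown model {name!r}")
            for scope, g in scopes(te):
                if len(g) == 0:
                    rows.append({"model": name, "scope": scope, "split": "test",
                                 "n": 0, "r2": None, "rmse": None, "bias": None,
                                 "F": None, "mpp": None})
                    continue
                rows.append(_metric_row(name, scope, "test", g["log_s0"],
                                        predict(g), p=p_fit))
        except Exception as exc:  # keep the run alive; mark the failure
            logger.warning("model %s failed: %s", name, exc)
            rows.append({"model": name, "scope": "all", "split": "failed",
                         "n": 0, "error": str(exc)})

    # quaternary subset: its own reduced ABSOLV form
    if qa.any() and ("absolv" in models or "absolv_qa" in models):
        sub = df[qa]
        if len(sub) >= 10:
            try:
                model = absolv_fit(sub, sub["log_s0"], sub.get("sd_log"), form="absolv_qa")
                fitted["absolv_qa"] = model
                pred = model.predict(sub[["A", "B", "Spi"]])
                rows.append(_metric_row("absolv_qa", "quaternary", "train",
                                        sub["log_s0"], pred, p=4))
            except Exception as exc:
                rows.append({"model": "absolv_qa", "scope": "quaternary",
                             "split": "failed", "n": 0, "error": str(exc)})
        else:
            rows.append({"model": "absolv_qa", "scope": "quaternary", "split": "skipped",
                         "n": int(qa.sum()), "error": "too few quaternary rows"})

    return {
        "table": pd.DataFrame(rows),
        "models": fitted,
        "importances": importances,
        "split": (train_ids, test_ids),
    }
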