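"""GSE, ABSOLV weighted MLR and the quaternary-ammonium model on a shared
weighted-least-squares core.

Model forms (response: log S0, log molar):

* ``gse_fixed``:   log S0 = 0.5 - logP - 0.01 (Tm - 25)+   (no training;
  the melting term is clamped to zero for liquids, Tm < 25 degC)
* ``gse_trained``: the same design, [1, logP, (Tm - 25)+], refit by
  weighted MLR -- so the fixed model is the exact special case
  (0.5, -1.0, -0.01)
* ``absolv``:      log S0 = c0 + c1 A + c2 B + c3 Spi + c4 E + c5 V + c6 A*B
* ``absolv_qa``:   log S0 = c0 + c1 A + c2 B + c3 Spi   (permanently
  charged quaternary ammonium salts; here "S0" is the salt solubility)

Rows are weighted by w = 1 / max(sd, sd_floor)^2 from the per-measurement
standard deviation; rows without an SD get the interlaboratory average of
0.17 log units. Coefficient standard errors come from the weighted normal
equations with the residual scale estimated on n - p degrees of freedom.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

#: floor applied to reported SDs so near-zero values cannot dominate weights
SD_FLOOR = 0.05
#: default SD for rows with no reported uncertainty (interlaboratory average)
SD_DEFAULT = 0.17
#: smallest class fitted separately in per-class analyses
MIN_CLASS_N = 25

GSE_FIXED_COEFS = {"const": 0.5, "logP": -1.0, "tm25": -0.01}

_FORMS = {
    "gse_fixed": ["const", "logP", "tm25"],
    "gse_trained": ["const", "logP", "tm25"],
    "absolv": ["const", "A", "B", "Spi", "E", "V", "AB"],
    "absolv_qa": ["const", "A", "B", "Spi"],
}


class CollinearityError(ValueError):
    pass


@dataclass
class FittedLinearModel:
    """Results of a weighted linear fit (also represents the fixed GSE)."""

    form: str
    names: list[str]
    params: np.ndarray
    bse: np.ndarray | None = None
    cov: np.ndarray | None = None
    weighting: str = ""
    training_n: int = 0
    class_scope: str = "all"
    extra: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> dict:
        return dict(zip(self.names, np.asarray(self.params, dtype=float)))

    def param_correlation(self, a: str, b: str) -> float | None:
        if self.cov is None:
            return None
        i, j = self.names.index(a), self.names.index(b)
        return float(self.cov[i, j] / np.sqrt(self.cov[i, i] * self.cov[j, j]))

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[[n for n in self.names if n != "const"]].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if "const" in self.names:
            X = np.column_stack([np.ones(len(X)), X])
        return X @ self.params

    def summary(self) -> str:
        lines = [
            f"Linear model [{self.form}]  scope={self.class_scope}  n={self.training_n}",
            f"weighting: {self.weighting or 'none (fixed coefficients)'}",
            f"{'term':>10} {'coef':>12} {'std err':>12}",
        ]
        for i, name in enumerate(self.names):
            se = f"{self.bse[i]:12.4f}" if self.bse is not None else " " * 12
            lines.append(f"{name:>10} {self.params[i]:12.4f} {se}")
        for k, v in self.extra.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "form": self.form,
            "names": self.names,
            "params": list(map(float, self.params)),
            "bse": None if self.bse is None else list(map(float, self.bse)),
            "weighting": self.weighting,
            "training_n": self.training_n,
            "class_scope": self.class_scope,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedLinearModel":
        d = json.loads(text)
        return cls(
            form=d["form"], names=d["names"], params=np.array(d["params"]),
            bse=None if d.get("bse") is None else np.array(d["bse"]),
            weighting=d.get("weighting", ""), training_n=d.get("training_n", 0),
            class_scope=d.get("class_scope", "all"),
        )


def gse_fixed_model() -> FittedLinearModel:
    return FittedLinearModel(
        form="gse_fixed",
        names=list(GSE_FIXED_COEFS),
        params=np.array(list(GSE_FIXED_COEFS.values())),
        weighting="",
        class_scope="all",
    )


def _weights(sd, n: int, sd_floor: float = SD_FLOOR, sd_default: float = SD_DEFAULT):
    if sd is None:
        sd = np.full(n, sd_default)
    sd = np.asarray(sd, dtype=float).copy()
    sd[~np.isfinite(sd)] = sd_default
    return 1.0 / np.maximum(sd, sd_floor) ** 2


def weighted_mlr_fit(
    X: np.ndarray,
    y: np.ndarray,
    sd=None,
    names: list[str] | None = None,
    form: str = "custom",
    class_scope: str = "all",
    sd_floor: float = SD_FLOOR,
    sd_default: float = SD_DEFAULT,
) -> FittedLinearModel:
    """Weighted least squares: minimize sum w_i (y_i - x_i beta)^2.

    ``X`` must already contain any intercept column. Raises
    :class:`CollinearityError` naming the offending columns when the design
    is rank-deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not (n == len(y) and n > p):
        raise ValueError(f"need rows(X)={n} == len(y)={len(y)} > cols(X)={p}")
    names = names or [f"x{i}" for i in range(p)]
    w = _weights(sd, n, sd_floor, sd_default)

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    # rank check with pivoted QR so collinear columns can be named
    _, R, piv = scipy.linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.max() > 0 else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        bad = sorted(names[j] for j in piv[rank:])
        raise CollinearityError(f"rank-deficient design; collinear column(s): {bad}")

    XtWX = Xw.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yw)
    resid = y - X @ beta
    dof = n - p
    scale = float(np.sum(w * resid**2) / dof)
    cov = scale * np.linalg.inv(XtWX)
    bse = np.sqrt(np.diag(cov))
    return FittedLinearModel(
        form=form, names=list(names), params=beta, bse=bse, cov=cov,
        weighting=f"w = 1/max(sd, {sd_floor})^2; missing sd -> {sd_default}",
        training_n=n, class_scope=class_scope,
    )


# ---------------------------------------------------------------------------
# GSE
# ---------------------------------------------------------------------------

def _tm25(tm):
    """Melting term (Tm - 25)+, clamped to 0 for liquids (Tm < 25 degC)."""
    return np.maximum(np.asarray(tm, dtype=float) - 25.0, 0.0)


def gse_predict(logp, tm) -> float | np.ndarray:
    """Classic GSE: log S0 = 0.5 - logP - 0.01 (Tm - 25)+. Vectorized."""
    out = 0.5 - np.asarray(logp, dtype=float) - 0.01 * _tm25(tm)
    return out if out.ndim else float(out)


def gse_fit(
    logp, tm, y, sd=None, class_scope: str = "all", min_n: int = 10
) -> FittedLinearModel:
    """Retrain the GSE coefficients by weighted MLR on [1, logP, (Tm-25)+].

    Records the intercept-melting-term coefficient correlation, which is
    typically strongly negative for druglike training sets.
    """
    logp = np.asarray(logp, dtype=float)
    if len(logp) < min_n:
        raise ValueError(f"need at least {min_n} rows to retrain the GSE, got {len(logp)}")
    X = np.column_stack([np.ones(len(logp)), logp, _tm25(tm)])
    model = weighted_mlr_fit(X, y, sd, names=["const", "logP", "tm25"],
                             form="gse_trained", class_scope=class_scope)
    model.extra["const_tm_correlation"] = model.param_correlation("const", "tm25")
    return model


# ---------------------------------------------------------------------------
# ABSOLV
# ---------------------------------------------------------------------------

def absolv_fit(
    X: pd.DataFrame, y, sd=None, form: str = "absolv", class_scope: str = "all"
) -> FittedLinearModel:
    """Fit the ABSOLV weighted MLR. ``X`` carries the descriptor columns
    (A, B, Spi, E, V[, AB]); the AB cross term is derived if absent."""
    cols = [c for c in _FORMS[form] if c != "const"]
    X = X.copy()
    if form == "absolv" and "AB" not in X.columns:
        X["AB"] = X["A"] * X["B"]
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"{form} fit: missing descriptor column(s) {missing}")
    mat = np.column_stack([np.ones(len(X)), X[cols].to_numpy(dtype=float)])
    return weighted_mlr_fit(mat, y, sd, names=["const"] + cols,
                            form=form, class_scope=class_scope)


def absolv_predict(desc, model: FittedLinearModel) -> float | np.ndarray:
    """Predict log S0 from Abraham descriptors with a fitted ABSOLV model."""
    if model.form not in ("absolv", "absolv_qa"):
        raise ValueError(f"model form {model.form!r} is not an ABSOLV form")
    cols = [c for c in model.names if c != "const"]
    if isinstance(desc, pd.DataFrame):
        desc = desc.copy()
        if "AB" in cols and "AB" not in desc.columns:
            desc["AB"] = desc["A"] * desc["B"]
        missing = [c for c in cols if c not in desc.columns]
        if missing:
            raise ValueError(f"missing descriptor(s) {missing}")
        return model.predict(desc)
    # single mapping-like descriptor vector
    d = dict(desc)
    if "AB" in cols and "AB" not in d:
        d["AB"] = d["A"] * d["B"]
    missing = [c for c in cols if c not in d]
    if missing:
        raise ValueError(f"missing descriptor(s) {missing}")
    x = np.array([[d[c] for c in cols]], dtype=float)
    return float(model.predict(x)[0])


# ---------------------------------------------------------------------------
# Per-class fitting
# ---------------------------------------------------------------------------

def fit_by_class(
    df: pd.DataFrame, form: str, y_col: str = "log_s0", sd_col: str = "sd_log",
    class_col: str = "abclass", min_class_n: int = MIN_CLASS_N,
) -> dict:
    """Fit one model per acid-base class plus the pooled "all" model.

    Classes with fewer than ``min_class_n`` rows are reported as skipped.
    Quaternary ammonium rows are excluded from every form except
    ``absolv_qa`` (for which they are the only eligible rows); requesting
    another form on a purely quaternary input yields an empty result with
    an advisory.
    """
    out: dict = {"models": {}, "skipped": {}}

    def _one(sub: pd.DataFrame, scope: str):
        y = sub[y_col].to_numpy(dtype=float)
        sd = sub[sd_col].to_numpy(dtype=float) if sd_col in sub.columns else None
        if form in ("gse_trained",):
            return gse_fit(sub["logP"], sub["tm_C"], y, sd, class_scope=scope)
        if form in ("absolv", "absolv_qa"):
            return absolv_fit(sub, y, sd, form=form, class_scope=scope)
        raise ValueError(f"unknown trainable form {form!r}")

    qa_mask = df[class_col].astype(str) == "quaternary"
    if form == "absolv_qa":
        pool = df[qa_mask]
    else:
        pool = df[~qa_mask]
        if qa_mask.any() and not len(pool):
            out["skipped"]["all"] = (
                "input contains only quaternary ammonium records; use form='absolv_qa'"
            )
            return out

    for scope, sub in [("all", pool)] + [
        (str(c), g) for c, g in pool.groupby(class_col, observed=True)
    ]:
        if len(sub) < max(min_class_n, 3):
            out["skipped"][scope] = f"n={len(sub)} < {min_class_n}"
            continue
        try:
            out["models"][scope] = _one(sub, scope)
        except (ValueError, CollinearityError) as exc:
            out["skipped"][scope] = str(exc)
    return out


# ---------------------------------------------------------------------------
# Model facades (construct from data, fit() -> results)
# ---------------------------------------------------------------------------

class GSEModel:
    """General Solubility Equation, built from a data frame.

    ``GSEModel.from_dataframe(df).fit()`` retrains the coefficients;
    ``GSEModel.fixed()`` returns the untrained classic model. Either way
    the result is a :class:`FittedLinearModel` with ``predict``/``summary``.
    """

    def __init__(self, logp, tm, y=None, sd=None):
        self.logp, self.tm, self.y, self.sd = logp, tm, y, sd

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, y_col: str = "log_s0",
                       sd_col: str = "sd_log") -> "GSEModel":
        return cls(df["logP"], df["tm_C"], df.get(y_col), df.get(sd_col))

    @staticmethod
    def fixed() -> FittedLinearModel:
        return gse_fixed_model()

    def fit(self) -> FittedLinearModel:
        if self.y is None:
            raise ValueError("no response column available; use GSEModel.fixed()")
        return gse_fit(self.logp, self.tm, self.y, self.sd)


class AbsolvModel:
    """Abraham-solvation weighted MLR (full or quaternary-ammonium form)."""

    def __init__(self, X: pd.DataFrame, y, sd=None, form: str = "absolv"):
        if form not in ("absolv", "absolv_qa"):
            raise ValueError(form)
        self.X, self.y, self.sd, self.form = X, y, sd, form

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, y_col: str = "log_s0",
                       sd_col: str = "sd_log", form: str = "absolv") -> "AbsolvModel":
        sd = df[sd_col] if sd_col in df.columns else None
        return cls(df, df[y_col], sd, form=form)

    def fit(self) -> FittedLinearModel:
        return absolv_fit(self.X, self.y, self.sd, form=self.form)
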