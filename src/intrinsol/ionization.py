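"""Henderson-Hasselbalch solubility-pH models and the pure-water saturation solver.

For an ionizable compound the total solubility S at a given pH exceeds the
intrinsic solubility S0 of the uncharged form:

    monoprotic base:  log S = log S0 + log10(10^(pKa - pH) + 1)
    monoprotic acid:  log S = log S0 + log10(10^(pH - pKa) + 1)
    ordinary ampholyte: log S = log S0 + log10(10^(pKa_base - pH)
                                              + 10^(pH - pKa_acid) + 1)

When the pure free acid/base is equilibrated in initially pure water, the
dissolved compound itself sets the final pH (pH_sat) through the charge
balance of the saturated solution; solving that balance links a reported
"water solubility" S_w to the underlying S0. Activity coefficients are
ignored (I = 0) and Kw is fixed at 1e-14 (25 degC); pKa values are inputs
and are never refined.

Multiprotic speciation beyond one acidic plus one basic group, salt/common-
ion products, aggregation and CO2 effects are out of scope; profiles whose
shape departs from HH (weighted RMSE > 0.3 log) are flagged, not modeled.
Permanently charged (quaternary) compounds have no S0 in the HH sense and
must bypass this module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .records import ABClass, PKa

KW_25C = 1.0e-14
#: weighted-RMSE threshold above which a profile is flagged as non-HH shaped
HH_SHAPE_RMSE_FLAG = 0.3

LOG10_2 = math.log10(2.0)


class UnsupportedIonizationModel(ValueError):
    """More than one acidic or basic pKa: beyond the ampholyte model."""


class SaturationSolverError(RuntimeError):
    pass


def _split_pkas(pkas) -> tuple[float | None, float | None]:
    """Return (acid pKa, base pKa), enforcing at most one of each."""
    acid = [p.value for p in pkas if p.group == "acid"]
    base = [p.value for p in pkas if p.group == "base"]
    if len(acid) > 1 or len(base) > 1:
        raise UnsupportedIonizationModel(
            f"at most one acidic and one basic pKa supported, got "
            f"{len(acid)} acidic / {len(base)} basic"
        )
    return (acid[0] if acid else None, base[0] if base else None)


def hh_log_s(pH, log_s0: float, pkas) -> float | np.ndarray:
    """Total log solubility at ``pH`` under the Henderson-Hasselbalch model.

    ``pkas`` is a list of :class:`~intrinsol.records.PKa` (at most one
    acidic, one basic). Vectorized over ``pH``.
    """
    pka_acid, pka_base = _split_pkas(pkas)
    pH = np.asarray(pH, dtype=float)
    term = np.ones_like(pH)
    if pka_base is not None:
        term = term + 10.0 ** (pka_base - pH)
    if pka_acid is not None:
        term = term + 10.0 ** (pH - pka_acid)
    out = log_s0 + np.log10(term)
    return out if out.ndim else float(out)


@dataclass
class HHModel:
    """A solubility-pH model: intrinsic solubility plus ionization terms."""

    log_s0: float
    pkas: list[PKa] = field(default_factory=list)
    kw: float = KW_25C

    def __post_init__(self) -> None:
        self.pkas = [p if isinstance(p, PKa) else PKa(*p) for p in self.pkas]
        _split_pkas(self.pkas)  # validate

    def log_s(self, pH):
        return hh_log_s(pH, self.log_s0, self.pkas)


def classify_acid_base(pkas, ph_ref: float = 7.4) -> ABClass:
    """Acid-base class from the predominant charge state at ``ph_ref``.

    acid(-): an acidic group already deprotonated at the reference pH
    (pKa < 7.4) with no protonated basic group; base(+): the converse;
    zwitterion(+/-): both; neutral(0): otherwise (including non-ionizable
    molecules and groups that stay uncharged at 7.4, e.g. phenols with
    pKa 10).
    """
    acidic = any(p.group == "acid" and p.value < ph_ref for p in pkas)
    basic = any(p.group == "base" and p.value > ph_ref for p in pkas)
    if acidic and basic:
        return ABClass.ZWITTERION
    if acidic:
        return ABClass.ACID
    if basic:
        return ABClass.BASE
    return ABClass.NEUTRAL


# ---------------------------------------------------------------------------
# Pure-water saturation
# ---------------------------------------------------------------------------

def _charge_imbalance(pH: float, s0: float, pka_acid, pka_base, kw: float) -> float:
    """Positive minus negative charge (M) in a saturated pure-water solution.

    At saturation the neutral-species concentration is pinned at S0, so
    [BH+] = S0 * 10^(pKa_base - pH) and [A-] = S0 * 10^(pH - pKa_acid).
    """
    h = 10.0 ** (-pH)
    f = h - kw / h
    if pka_base is not None:
        f += s0 * 10.0 ** (pka_base - pH)
    if pka_acid is not None:
        f -= s0 * 10.0 ** (pH - pka_acid)
    return f


def solve_saturation_pure_water(
    log_s0: float, pkas, kw: float = KW_25C, residual_tol: float = 1e-12
) -> tuple[float, float]:
    """Solve the saturated pure-water equilibrium: returns (pH_sat, log S_w).

    Bisection on pH in [0, 14] (the imbalance is strictly decreasing in pH)
    followed by one Newton polish; the returned point satisfies
    |charge imbalance| < ``residual_tol`` M.
    """
    pka_acid, pka_base = _split_pkas(pkas)
    if pka_acid is None and pka_base is None:
        return 7.0, float(log_s0)
    s0 = 10.0 ** log_s0

    lo, hi = 0.0, 14.0
    f_lo = _charge_imbalance(lo, s0, pka_acid, pka_base, kw)
    f_hi = _charge_imbalance(hi, s0, pka_acid, pka_base, kw)
    if not (f_lo > 0 > f_hi):
        raise SaturationSolverError(
            f"no sign change on pH (0, 14): f(0)={f_lo:.3e}, f(14)={f_hi:.3e}"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _charge_imbalance(mid, s0, pka_acid, pka_base, kw) > 0:
            lo = mid
        else:
            hi = mid
    ph = 0.5 * (lo + hi)
    # one Newton polish on the (smooth) imbalance
    f = _charge_imbalance(ph, s0, pka_acid, pka_base, kw)
    eps = 1e-9
    df = (_charge_imbalance(ph + eps, s0, pka_acid, pka_base, kw) - f) / eps
    if df != 0.0:
        ph_new = ph - f / df
        if 0.0 < ph_new < 14.0:
            ph = ph_new
    resid = _charge_imbalance(ph, s0, pka_acid, pka_base, kw)
    if abs(resid) >= residual_tol:
        raise SaturationSolverError(f"charge residual {resid:.3e} M above tolerance")
    return ph, float(hh_log_s(ph, log_s0, pkas))


def invert_saturation(
    log_sw: float, pkas, kw: float = KW_25C, tol: float = 1e-9
) -> tuple[float, float]:
    """Recover (log_s0, pH_sat) from a pure-water solubility ``log_sw``.

    The forward map log_s0 -> log S_w is strictly increasing, so a
    bracketed bisection on log_s0 in [log_sw - 14, log_sw] converges; the
    round trip reproduces log_sw to better than 1e-6 log units.
    """
    pka_acid, pka_base = _split_pkas(pkas)
    if pka_acid is None and pka_base is None:
        return float(log_sw), 7.0

    def g(ls0: float) -> float:
        return solve_saturation_pure_water(ls0, pkas, kw)[1] - log_sw

    lo, hi = log_sw - 14.0, log_sw + 1e-12
    g_lo, g_hi = g(lo), g(hi)
    if not (g_lo < 0 <= g_hi):
        raise SaturationSolverError(
            f"inversion bracket failed: g({lo:.3f})={g_lo:.3e}, g({hi:.3f})={g_hi:.3e}"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    log_s0 = 0.5 * (lo + hi)
    ph_sat, _ = solve_saturation_pure_water(log_s0, pkas, kw)
    return float(log_s0), ph_sat


# ---------------------------------------------------------------------------
# Profile fitting
# ---------------------------------------------------------------------------

@dataclass
class ProfileFit:
    log_s0: float
    sd_log: float | None
    n: int
    weighted_rmse: float
    hh_shape_ok: bool
    ill_conditioned: bool


def fit_intrinsic_from_profile(points, pkas, ion_margin: float = 3.0) -> ProfileFit:
    """Weighted least-squares estimate of log S0 from (pH, log S, weight) points.

    With the pKa set fixed, the HH model is linear in log_s0:
    log S_i = log_s0 + log10 F(pH_i), so the estimate is the weighted mean
    of (log S_i - log10 F(pH_i)). ``sd_log`` is the standard error of the
    estimate (None for a single point, where the inversion is exact).

    Flags: ``ill_conditioned`` when every point sits >= ``ion_margin`` pH
    units into the fully ionized region (S0 is then an extrapolation);
    ``hh_shape_ok`` False when the weighted RMSE exceeds 0.3 log units,
    suggesting aggregation/complexation distorting the HH shape.
    """
    pts = [(float(p[0]), float(p[1]), float(p[2]) if len(p) > 2 else 1.0) for p in points]
    if not pts:
        raise ValueError("at least one profile point required")
    pka_acid, pka_base = _split_pkas(pkas)
    ph = np.array([p[0] for p in pts])
    logs = np.array([p[1] for p in pts])
    w = np.array([p[2] for p in pts])
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    shift = hh_log_s(ph, 0.0, pkas)  # log10 F(pH)
    z = logs - shift
    est = float(np.sum(w * z) / np.sum(w))
    resid = z - est
    wrmse = float(np.sqrt(np.sum(w * resid**2) / np.sum(w)))
    n = len(pts)
    if n > 1:
        scale = float(np.sum(w * resid**2) / (n - 1))
        sd = float(np.sqrt(scale / np.sum(w)))
    else:
        sd = None

    ionized = np.zeros(n, dtype=bool)
    if pka_base is not None:
        ionized |= ph <= pka_base - ion_margin
    if pka_acid is not None:
        ionized |= ph >= pka_acid + ion_margin
    ill = bool(ionized.all()) and (pka_acid is not None or pka_base is not None)
    if ill:
        warnings.warn(
            "all profile points lie in the fully-ionized region; "
            "log_s0 is an extrapolation", stacklevel=2,
        )
    return ProfileFit(
        log_s0=est, sd_log=sd, n=n, weighted_rmse=wrmse,
        hh_shape_ok=wrmse <= HH_SHAPE_RMSE_FLAG, ill_conditioned=ill,
    )
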