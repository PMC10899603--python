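"""Reaction analytics for indican synthesis and photolytic cleavage.

Covers the small set of quantities used to characterize the process:

* linear calibration of chromatographic peak area against concentration,
* conversion (product formed over substrate supplied, stoichiometry-aware),
* total turnover number (mol product per mol enzyme),
* first-order decay fitting for photolysis progress curves, and
* a zero- vs first-order model comparison (photolysis of the glycoside is
  expected to be first order when photons are not limiting the substrate).

Times are in hours internally; signals may be concentrations (mM) or peak
areas, the latter normalized to the t = 0 area before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .errors import DegenerateDesignError, FitFailureError, InputError


@dataclass(frozen=True)
class ProgressCurve:
    """Signal versus time; ``kind`` is 'concentration' (mM) or 'peak_area'."""

    times: np.ndarray
    signal: np.ndarray
    kind: str = "concentration"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)
        if t.shape != s.shape or t.ndim != 1 or len(t) < 2:
            raise InputError("need matching time/signal arrays of length >= 2")
        if t[0] < 0 or not np.all(np.diff(t) > 0):
            raise InputError("times must be >= 0 and strictly increasing")
        if np.any(s < 0):
            raise InputError("signals must be non-negative")
        if self.kind not in ("concentration", "peak_area"):
            raise InputError(f"unknown signal kind {self.kind!r}")


@dataclass(frozen=True)
class CalibrationFit:
    slope: float       # signal units per mM
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class FirstOrderFit:
    k: float           # per hour
    amplitude: float   # signal at t = 0
    half_life: float   # hours; inf when k = 0
    r_squared: float


def linear_calibration(concentrations, areas) -> CalibrationFit:
    """Ordinary least-squares calibration line (area vs concentration)."""
    conc = np.asarray(concentrations, dtype=float)
    area = np.asarray(areas, dtype=float)
    if conc.shape != area.shape or len(conc) < 3:
        raise InputError("calibration needs >= 3 matched points")
    if len(np.unique(conc)) < 2:
        raise DegenerateDesignError("all calibration concentrations identical")
    res = stats.linregress(conc, area)
    return CalibrationFit(slope=float(res.slope),
                          intercept=float(res.intercept),
                          r_squared=float(res.rvalue ** 2))


def conversion(product_final: float, substrate_initial: float,
               stoichiometry: float = 1.0) -> float:
    """Fraction of substrate converted, given product-per-substrate stoichiometry.

    Values above 1 are reported as-is with a mass-balance warning.
    """
    if substrate_initial <= 0:
        raise InputError("substrate_initial must be > 0")
    if product_final < 0:
        raise InputError("product_final must be >= 0")
    frac = product_final / (substrate_initial * stoichiometry)
    if frac > 1.0:
        warnings.warn(f"conversion {frac:.3f} exceeds 1: mass balance "
                      "violated", stacklevel=2)
    return frac


def total_turnover_number(product_mol: float, enzyme_mol: float) -> float:
    """Moles of product formed per mole of enzyme over the whole reaction."""
    if enzyme_mol <= 0:
        raise InputError("enzyme amount must be > 0")
    if product_mol < 0:
        raise InputError("product amount must be >= 0")
    return product_mol / enzyme_mol


def _exp_decay(t, a0, k):
    return a0 * np.exp(-k * t)


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_first_order(curve: ProgressCurve) -> FirstOrderFit:
    """Nonlinear least-squares fit of ``A(t) = A0 exp(-k t)``.

    Peak-area signals are normalized to the t = 0 area before fitting.
    Log-linear regression provides the starting point only; the fit itself is
    on the untransformed signal to avoid bias from noisy near-zero tails.
    """
    if len(curve.times) < 4:
        raise InputError("first-order fit needs >= 4 points")
    s = curve.signal.astype(float)
    if s[0] <= 0:
        raise InputError("initial signal must be > 0")
    if curve.kind == "peak_area":
        s = s / s[0]
    pos = s > 0
    if pos.sum() >= 2 and np.ptp(s) > 0:
        slope = stats.linregress(curve.times[pos], np.log(s[pos])).slope
        k0 = max(-float(slope), 0.0)
    else:
        k0 = 0.0
    try:
        popt, _ = curve_fit(_exp_decay, curve.times, s, p0=[float(s[0]), k0],
                            bounds=([0.0, 0.0], [np.inf, np.inf]),
                            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"first-order fit failed: {exc}") from exc
    a0, k = float(popt[0]), float(popt[1])
    if k * curve.times[-1] < 1e-8:  # no measurable decay over the span
        k = 0.0
    half_life = np.log(2) / k if k > 0 else float("inf")
    return FirstOrderFit(k=k, amplitude=a0, half_life=float(half_life),
                         r_squared=_r_squared(s, _exp_decay(curve.times, a0, k)))


def _linear_decay(t, a0, rate):
    return np.maximum(a0 - rate * t, 0.0)


def _aicc(rss: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + residual variance
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class OrderComparison:
    preferred: str            # "first-order" | "zero-order" | "indeterminate"
    rss_first: float
    rss_zero: float
    aicc_first: float
    aicc_zero: float


def compare_orders(curve: ProgressCurve,
                   aicc_margin: float = 2.0) -> OrderComparison:
    """Zero- vs first-order decay comparison by small-sample AIC.

    Declares "indeterminate" when too few points remain for the corrected
    criterion or when the AICc difference is below ``aicc_margin``.
    """
    s = curve.signal.astype(float)
    if s[0] <= 0:
        raise InputError("initial signal must be > 0")
    if curve.kind == "peak_area":
        s = s / s[0]
    t = curve.times
    first = fit_first_order(ProgressCurve(t, s, kind="concentration"))
    rss_first = float(np.sum((s - _exp_decay(t, first.amplitude, first.k)) ** 2))
    try:
        popt, _ = curve_fit(_linear_decay, t, s,
                            p0=[float(s[0]), max((s[0] - s[-1]) / t[-1], 0.0)],
                            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"zero-order fit failed: {exc}") from exc
    rss_zero = float(np.sum((s - _linear_decay(t, *popt)) ** 2))
    n = len(t)
    if n - 4 <= 0:  # AICc denominator n - k - 1 with k = 3
        return OrderComparison("indeterminate", rss_first, rss_zero,
                               float("nan"), float("nan"))
    a_first = _aicc(rss_first, n, 2)
    a_zero = _aicc(rss_zero, n, 2)
    if abs(a_first - a_zero) < aicc_margin:
        preferred = "indeterminate"
    else:
        preferred = "first-order" if a_first < a_zero else "zero-order"
    return OrderComparison(preferred, rss_first, rss_zero, a_first, a_zero)
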