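"""Differential scanning fluorimetry (DSF) melt-curve analysis.

A DSF trace reports dye fluorescence versus temperature; unfolding exposes
hydrophobic surface, the dye binds, and fluorescence rises sigmoidally with a
midpoint at the melting temperature Tm.  Above the transition, aggregation
usually makes the signal decay again; that region is excluded before fitting
by truncating at the global fluorescence maximum, which is standard DSF
practice.

Two Tm estimators are provided: a bounded least-squares fit of the Boltzmann
sigmoid ``F(T) = base + amp / (1 + exp((tm - T)/slope))`` and a smoothed
derivative-maximum method used as a cross-check.  Replicates are aggregated to
mean +/- SEM and compared against wildtype as delta-Tm; favorable single
mutations are combined into a multi-mutant plan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitFailureError, InputError, NoTransitionError


@dataclass(frozen=True)
class MeltCurve:
    """One replicate DSF trace (temperatures in degrees C, ascending)."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    variant: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if t.shape != f.shape or t.ndim != 1:
            raise InputError("temperature and fluorescence lengths differ")
        if len(t) < 10:
            raise InputError("melt curve needs at least 10 points")
        if not np.all(np.diff(t) > 0):
            raise InputError("temperatures must be strictly increasing")
        if t[0] < 20.0 or t[-1] > 100.0:
            raise InputError("temperatures must lie within [20, 100] C")


@dataclass(frozen=True)
class TmEstimate:
    tm: float
    slope: float
    amplitude: float
    baseline: float
    residual_norm: float
    method: str  # "sigmoid" | "derivative"
    variant: str = ""


@dataclass(frozen=True)
class VariantStabilityRecord:
    variant: str
    mutations: tuple[str, ...]
    tm_mean: float
    tm_sem: float
    n_replicates: int
    delta_tm: float
    activity_retained: float | bool | None = None
    sem_flagged: bool = False  # True when n = 1 and SEM is degenerate


def boltzmann(t, base, amp, tm, slope):
    """Two-state unfolding sigmoid; ``slope`` is the transition width in C."""
    return base + amp / (1.0 + np.exp((tm - t) / slope))


def _truncate_at_max(curve: MeltCurve) -> tuple[np.ndarray, np.ndarray]:
    """Drop the post-transition aggregation decay (points after the global max)."""
    i_max = int(np.argmax(curve.fluorescence))
    return curve.temperatures[: i_max + 1], curve.fluorescence[: i_max + 1]


def _smoothed_derivative(t: np.ndarray, f: np.ndarray, window: int) -> np.ndarray:
    d = np.gradient(f, t)
    if window <= 1:
        return d
    return pd.Series(d).rolling(window, center=True, min_periods=1).mean().to_numpy()


def _check_transition(t: np.ndarray, f: np.ndarray) -> None:
    if len(t) < 5 or np.ptp(f) <= 0:
        raise NoTransitionError("no rising unfolding transition in curve")
    if np.max(_smoothed_derivative(t, f, 7)) <= 0:
        raise NoTransitionError("no positive fluorescence slope in curve")


def fit_melt_sigmoid(curve: MeltCurve) -> TmEstimate:
    """Boltzmann-sigmoid Tm fit on the pre-aggregation part of the trace.

    Initialization comes from the smoothed-derivative peak; bounded least
    squares keeps tm inside the data range and slope positive.  Raises
    ``NoTransitionError`` for flat or strictly decreasing curves and
    ``FitFailureError`` on non-convergence.
    """
    t, f = _truncate_at_max(curve)
    _check_transition(t, f)
    d = _smoothed_derivative(t, f, 7)
    tm0 = float(t[int(np.argmax(d))])
    base0, amp0 = float(f.min()), float(np.ptp(f))
    slope0 = max(amp0 / (4.0 * float(d.max())), 1e-2)
    lo = [base0 - 2 * amp0, amp0 * 1e-3, float(t[0]), 1e-3]
    hi = [base0 + 2 * amp0, amp0 * 10 + 1e-9, float(t[-1]), 50.0]
    p0 = np.clip([base0, amp0, tm0, slope0], lo, hi)
    try:
        popt, _ = curve_fit(boltzmann, t, f, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"sigmoid fit failed: {exc}") from exc
    resid = f - boltzmann(t, *popt)
    return TmEstimate(tm=float(popt[2]), slope=float(popt[3]),
                      amplitude=float(popt[1]), baseline=float(popt[0]),
                      residual_norm=float(np.linalg.norm(resid)),
                      method="sigmoid", variant=curve.variant)


def tm_by_derivative(curve: MeltCurve, smooth_window: int = 7) -> TmEstimate:
    """Tm as the temperature of the smoothed dF/dT maximum (cross-check method).

    ``smooth_window = 1`` reduces to the raw finite-difference argmax.
    """
    t, f = _truncate_at_max(curve)
    _check_transition(t, f)
    d = _smoothed_derivative(t, f, smooth_window)
    i = int(np.argmax(d))
    amp = float(np.ptp(f))
    slope = amp / (4.0 * float(d[i])) if d[i] > 0 else float("nan")
    resid = float("nan")
    return TmEstimate(tm=float(t[i]), slope=slope, amplitude=amp,
                      baseline=float(f.min()), residual_norm=resid,
                      method="derivative", variant=curve.variant)


def aggregate_variant(estimates: list[TmEstimate], wildtype_mean: float,
                      variant: str = "", mutations: tuple[str, ...] = (),
                      activity_retained=None) -> VariantStabilityRecord:
    """Mean, SEM (= sd/sqrt(n), n-1 denominator) and delta-Tm versus wildtype.

    With a single replicate the SEM is reported as 0 and flagged.
    Estimates carrying different variant ids cannot be aggregated.
    """
    if not estimates:
        raise InputError("no Tm estimates to aggregate")
    ids = {e.variant for e in estimates if e.variant}
    if len(ids) > 1:
        raise InputError(f"mixed variant ids in aggregation: {sorted(ids)}")
    if not variant and ids:
        variant = next(iter(ids))
    tms = np.array([e.tm for e in estimates], dtype=float)
    n = len(tms)
    sem = float(tms.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return VariantStabilityRecord(
        variant=variant, mutations=tuple(mutations),
        tm_mean=float(tms.mean()), tm_sem=sem, n_replicates=n,
        delta_tm=float(tms.mean() - wildtype_mean),
        activity_retained=activity_retained, sem_flagged=(n == 1))


def mutation_position(mutation: str) -> int:
    """Position of a mutation in wt-position-new notation (E75P -> 75)."""
    digits = "".join(ch for ch in mutation if ch.isdigit())
    if not digits:
        raise InputError(f"cannot parse mutation {mutation!r}")
    return int(digits)


def _activity_ok(record: VariantStabilityRecord, activity_min: float) -> bool:
    act = record.activity_retained
    if act is None or act is True:
        return True
    if act is False:
        return False
    return float(act) >= activity_min


def select_combination(records: list[VariantStabilityRecord],
                       delta_tm_min: float = 1.0,
                       activity_min: float = 0.8) -> list[str]:
    """Union of favorable single mutations for a combinatorial variant.

    Single-mutant records passing both thresholds contribute their mutation;
    conflicts at one position are resolved by the larger delta-Tm; output is
    ordered by position.  Requires a wildtype reference record (empty
    mutation list) among the inputs.
    """
    if not records:
        raise InputError("no stability records")
    if not any(len(r.mutations) == 0 for r in records):
        raise InputError("records must include a wildtype reference")
    best: dict[int, tuple[float, str]] = {}
    for r in records:
        if len(r.mutations) != 1:
            continue
        if r.delta_tm < delta_tm_min or not _activity_ok(r, activity_min):
            continue
        mut = r.mutations[0]
        pos = mutation_position(mut)
        if pos not in best or r.delta_tm > best[pos][0]:
            best[pos] = (r.delta_tm, mut)
    return [best[pos][1] for pos in sorted(best)]


# ---------------------------------------------------------------------------
# Tabular front end (CSV columns: variant, replicate, temperature_C, fluorescence)
# ---------------------------------------------------------------------------

def curves_from_frame(df: pd.DataFrame) -> list[MeltCurve]:
    curves = []
    for (variant, rep), grp in df.groupby(["variant", "replicate"], sort=True):
        grp = grp.sort_values("temperature_C")
        curves.append(MeltCurve(grp["temperature_C"].to_numpy(),
                                grp["fluorescence"].to_numpy(),
                                variant=str(variant), replicate=str(rep)))
    return curves


def analyze_melt_table(df: pd.DataFrame, wildtype: str,
                       method: str = "sigmoid") -> pd.DataFrame:
    """Fit every replicate, aggregate per variant, and report delta-Tm vs WT."""
    fit = fit_melt_sigmoid if method == "sigmoid" else tm_by_derivative
    estimates: dict[str, list[TmEstimate]] = {}
    for curve in curves_from_frame(df):
        estimates.setdefault(curve.variant, []).append(fit(curve))
    if wildtype not in estimates:
        raise InputError(f"wildtype {wildtype!r} not present in table")
    wt_mean = float(np.mean([e.tm for e in estimates[wildtype]]))
    rows = []
    for variant, ests in estimates.items():
        rec = aggregate_variant(ests, wt_mean, variant=variant)
        rows.append((variant, rec.tm_mean, rec.tm_sem, rec.n_replicates,
                     rec.delta_tm))
    return pd.DataFrame(rows, columns=["variant", "tm_mean", "tm_sem", "n",
                                       "delta_tm"]).sort_values("variant",
                                                                ignore_index=True)
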