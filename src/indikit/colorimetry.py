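"""CIELAB colorimetry from spectral reflectance.

Measured reflectance spectra are resampled to a 5 nm grid over 400-700 nm,
converted to XYZ tristimulus values under the CIE 1964 10-degree observer and
illuminant D65 (Riemann Delta-lambda summation, normalized so the perfect
reflector has Y = 100), and mapped to L*a*b* with the standard piecewise
cube-root formulas.  Repeated swatch measurements are summarized as mean +/-
SD; reference populations (e.g. commercial denim swatches) as box-plot
statistics with 1.5 x IQR whiskers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _cie_data
from .errors import CoverageError, GridMismatchError, InputError, \
    InsufficientSampleError

REFLECTANCE_CLIP = 1.05


@dataclass(frozen=True)
class Spectrum:
    """Reflectance versus wavelength (nm ascending, fractions in [0, ~1]).

    Small negative sensor values are clipped to 0 and reflectance above 1
    (fluorescent-whitening artifacts) to 1.05, each with a warning.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        val = np.asarray(self.values, dtype=float).copy()
        if wl.shape != val.shape or wl.ndim != 1 or len(wl) < 2:
            raise InputError("need matching wavelength/value arrays")
        if not np.all(np.diff(wl) > 0):
            raise InputError("wavelengths must be strictly increasing")
        if np.any(val < 0):
            warnings.warn("negative reflectance clipped to 0", stacklevel=2)
            val = np.maximum(val, 0.0)
        if np.any(val > 1.0):
            warnings.warn(f"reflectance > 1 clipped to {REFLECTANCE_CLIP}",
                          stacklevel=2)
            val = np.minimum(val, REFLECTANCE_CLIP)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class LabColor:
    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not -1e-6 <= self.L <= 100.0 + 1e-6:
            raise InputError(f"L* out of range: {self.L}")


@dataclass(frozen=True)
class SwatchSummary:
    mean: LabColor
    sd: LabColor      # per-channel sample SD (n-1 denominator); 0 for n = 1
    n: int


@dataclass(frozen=True)
class ChannelBoxStats:
    median: float
    p25: float
    p75: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class ReferencePopulationStats:
    L: ChannelBoxStats
    a: ChannelBoxStats
    b: ChannelBoxStats
    n: int


def resample_spectrum(s: Spectrum, grid=None) -> Spectrum:
    """Linear interpolation onto the working grid (400-700 nm, 5 nm steps).

    Extrapolation is forbidden: the input must cover the grid.
    """
    grid = _cie_data.default_grid() if grid is None else np.asarray(grid, float)
    if s.wavelengths[0] > grid[0] or s.wavelengths[-1] < grid[-1]:
        raise CoverageError(
            f"spectrum covers {s.wavelengths[0]:g}-{s.wavelengths[-1]:g} nm, "
            f"grid needs {grid[0]:g}-{grid[-1]:g} nm")
    return Spectrum(grid, np.interp(grid, s.wavelengths, s.values),
                    sample=s.sample)


def reflectance_to_xyz(s: Spectrum, observer: np.ndarray | None = None,
                       illuminant: np.ndarray | None = None) -> np.ndarray:
    """Tristimulus X, Y, Z under the 10-degree observer and D65.

    ``X = k sum(S R xbar dl)`` etc., with ``k = 100 / sum(S ybar dl)`` so the
    perfect reflector has Y = 100 exactly.  The spectrum must already be on
    the working grid (use :func:`resample_spectrum`).
    """
    grid = _cie_data.default_grid()
    if len(s.wavelengths) != len(grid) or not np.allclose(s.wavelengths, grid):
        raise GridMismatchError("spectrum not on the 400-700 nm 5 nm grid")
    cmf = _cie_data.cmf_1964(grid) if observer is None else observer
    spd = _cie_data.d65(grid) if illuminant is None else illuminant
    if cmf.shape != (len(grid), 3) or spd.shape != (len(grid),):
        raise GridMismatchError("observer/illuminant tables not on the grid")
    k = 100.0 / float(np.sum(spd * cmf[:, 1]))
    return k * np.array([np.sum(spd * s.values * cmf[:, i]) for i in range(3)])


def whitepoint() -> np.ndarray:
    """XYZ of the perfect reflector under the embedded observer/illuminant."""
    grid = _cie_data.default_grid()
    return reflectance_to_xyz(Spectrum(grid, np.ones_like(grid)))


def _f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta ** 3,
                    np.cbrt(t),
                    t / (3 * delta ** 2) + 4.0 / 29.0)


def xyz_to_lab(xyz, white: np.ndarray | None = None) -> LabColor:
    """Standard CIE L*a*b* from tristimulus values and a white point."""
    white = whitepoint() if white is None else np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise InputError("white point must be positive")
    fx, fy, fz = _f(np.asarray(xyz, dtype=float) / white)
    return LabColor(L=float(116.0 * fy - 16.0),
                    a=float(500.0 * (fx - fy)),
                    b=float(200.0 * (fy - fz)))


def spectrum_to_lab(s: Spectrum) -> LabColor:
    """Convenience pipeline: resample -> XYZ -> Lab."""
    return xyz_to_lab(reflectance_to_xyz(resample_spectrum(s)))


def summarize_swatch(measurements: list[LabColor]) -> SwatchSummary:
    """Per-channel mean and sample SD over repeated measurements of one swatch."""
    if not measurements:
        raise InputError("no measurements")
    arr = np.array([(m.L, m.a, m.b) for m in measurements], dtype=float)
    n = len(arr)
    sd = arr.std(axis=0, ddof=1) if n > 1 else np.zeros(3)
    mean = arr.mean(axis=0)
    return SwatchSummary(mean=LabColor(*map(float, mean)),
                         sd=LabColor(*map(float, sd)), n=n)


def _channel_box(values: np.ndarray) -> ChannelBoxStats:
    p25, p50, p75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = p75 - p25
    lo_limit, hi_limit = p25 - 1.5 * iqr, p75 + 1.5 * iqr
    inside = values[(values >= lo_limit) & (values <= hi_limit)]
    outliers = values[(values < lo_limit) | (values > hi_limit)]
    return ChannelBoxStats(
        median=float(p50), p25=float(p25), p75=float(p75), iqr=float(iqr),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)))


def reference_population_stats(samples: list[LabColor]) -> ReferencePopulationStats:
    """Box-plot statistics per channel for a reference swatch population.

    Percentiles use linear interpolation between order statistics; whiskers
    extend to the most extreme points within 1.5 x IQR of the quartiles and
    points beyond are outliers.
    """
    if len(samples) < 4:
        raise InsufficientSampleError("population statistics need n >= 4")
    arr = np.array([(m.L, m.a, m.b) for m in samples], dtype=float)
    return ReferencePopulationStats(
        L=_channel_box(arr[:, 0]), a=_channel_box(arr[:, 1]),
        b=_channel_box(arr[:, 2]), n=len(samples))


# ---------------------------------------------------------------------------
# Tabular front end (CSV long format: sample, wavelength_nm, reflectance)
# ---------------------------------------------------------------------------

def spectra_from_frame(df: pd.DataFrame) -> list[Spectrum]:
    out = []
    for sample, grp in df.groupby("sample", sort=True):
        grp = grp.sort_values("wavelength_nm")
        out.append(Spectrum(grp["wavelength_nm"].to_numpy(),
                            grp["reflectance"].to_numpy(), sample=str(sample)))
    return out


def lab_table(spectra: list[Spectrum]) -> pd.DataFrame:
    rows = []
    for s in spectra:
        lab = spectrum_to_lab(s)
        rows.append((s.sample, lab.L, lab.a, lab.b))
    return pd.DataFrame(rows, columns=["sample", "L", "a", "b"])
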