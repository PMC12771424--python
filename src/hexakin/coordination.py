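"""Ferrous heme coordination-state estimation from visible absorbance spectra.

Hexacoordinate globins reversibly bind their distal histidine at the sixth
iron coordination site, so at equilibrium the deoxy ferrous protein is a
mixture of a hexacoordinate population (bis-histidyl iron) and a
pentacoordinate population (open sixth site).  The two populations have
distinct visible spectra: pentacoordinate deoxy heme shows a single broad
band near 555 nm, while hexacoordinate deoxy heme shows split alpha/beta
bands near 530 and 560 nm.  The ratio of the absorbance at the 555 nm peak
to the 540 nm trough (A555/A540) therefore tracks the hexacoordinate
fraction ``F_H``, and an empirical calibration maps the ratio onto ``F_H``.
The coordination equilibrium constant follows from

    K_H = [hexacoordinate] / [pentacoordinate],
    F_H = K_H / (1 + K_H)        <=>        K_H = F_H / (1 - F_H).

Fully pentacoordinate oxygen transporters (leghemoglobin a) sit at ratio
~1.2 (F_H = 0) and fully hexacoordinate neuroglobin at ~3.1 (F_H = 1);
these two boundary anchors form the default calibration.  The empirical
ratio-to-fraction relationship is not exactly linear, so the calibration is
a first-class, swappable input: any monotone anchor table may be supplied,
including one derived from synthetic basis spectra
(:func:`hexakin.simulate.calibration_from_basis`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Spectrum",
    "CalibrationTable",
    "CoordinationResult",
    "UndefinedRatioError",
    "NearSaturationWarning",
    "DEFAULT_CALIBRATION",
    "PEAK_NM",
    "TROUGH_NM",
    "absorbance_at",
    "peak_trough_ratio",
    "ratio_to_fraction_hexa",
    "fraction_to_KH",
    "KH_to_fraction",
    "estimate_coordination",
    "smooth_spectrum",
    "average_spectra",
]

#: Wavelength (nm) of the pentacoordinate deoxy absorbance peak used in the
#: coordination ratio.
PEAK_NM = 555.0
#: Wavelength (nm) of the trough between the split hexacoordinate bands.
TROUGH_NM = 540.0
#: Above this fraction the inferred K_H is effectively unbounded.
SATURATION_FRACTION = 0.999


class UndefinedRatioError(ValueError):
    """The A555/A540 ratio is undefined (non-positive trough absorbance)."""


class NearSaturationWarning(UserWarning):
    """F_H is at or near 1; K_H is reported but effectively unbounded."""


@dataclass(frozen=True, eq=False)
class Spectrum:
    """A single absorbance spectrum for one sample state.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelength grid in nm.
    absorbances
        Absorbance in AU, same length as ``wavelengths``.
    state
        One of ``ferric``, ``ferrous-deoxy``, ``oxy``, ``carbonmonoxy``.
    sample_id
        Free-form sample label.
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    state: str = "ferrous-deoxy"
    sample_id: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise ValueError("wavelengths and absorbances must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(ab))):
            raise ValueError("spectrum contains non-finite values")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


@dataclass(frozen=True, eq=False)
class CalibrationTable:
    """Monotone anchor table mapping the A555/A540 ratio onto F_H.

    Anchors are interpolated piecewise-linearly; ratios below the first or
    above the last anchor clamp to its fraction.  The table must contain the
    boundary anchors (F_H = 0 and F_H = 1).
    """

    ratios: np.ndarray
    fractions: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if r.ndim != 1 or f.ndim != 1 or r.size != f.size or r.size < 2:
            raise ValueError("calibration needs matching 1-D arrays with >= 2 anchors")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(f))):
            raise ValueError("calibration contains non-finite values")
        if not np.all(np.diff(r) > 0):
            raise ValueError("calibration ratios must be strictly increasing")
        if np.any(f < 0) or np.any(f > 1) or np.any(np.diff(f) < 0):
            raise ValueError("calibration fractions must be non-decreasing within [0, 1]")
        if f[0] != 0.0 or f[-1] != 1.0:
            raise ValueError("calibration must contain the F_H = 0 and F_H = 1 boundary anchors")
        if self.interpolation != "linear":
            raise ValueError(f"unsupported interpolation mode {self.interpolation!r}")
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "fractions", f)


#: Two-anchor default calibration: leghemoglobin a (ratio 1.2, fully
#: pentacoordinate) and neuroglobin (ratio 3.1, fully hexacoordinate).
DEFAULT_CALIBRATION = CalibrationTable(np.array([1.2, 3.1]), np.array([0.0, 1.0]))


@dataclass(frozen=True)
class CoordinationResult:
    """Coordination estimate for one protein: (ratio, F_H, K_H)."""

    ratio: float
    f_h: float
    k_h: float


def absorbance_at(spectrum: Spectrum, wavelength: float) -> float:
    """Absorbance at ``wavelength`` by linear interpolation.

    Exact grid hits return the stored value; queries outside the spectrum's
    span are rejected.
    """
    lo, hi = spectrum.span
    if not (lo <= wavelength <= hi):
        raise ValueError(f"wavelength {wavelength} nm outside spectrum span [{lo}, {hi}] nm")
    return float(np.interp(wavelength, spectrum.wavelengths, spectrum.absorbances))


def peak_trough_ratio(
    spectrum: Spectrum, peak_nm: float = PEAK_NM, trough_nm: float = TROUGH_NM
) -> float:
    """The A555/A540 coordination ratio of a ferrous-deoxy spectrum."""
    if spectrum.state != "ferrous-deoxy":
        raise ValueError(
            f"coordination ratio is defined for ferrous-deoxy spectra, got {spectrum.state!r}"
        )
    trough = absorbance_at(spectrum, trough_nm)
    if trough <= 0:
        raise UndefinedRatioError(
            f"absorbance at {trough_nm} nm is {trough:g}; ratio undefined"
        )
    return absorbance_at(spectrum, peak_nm) / trough


def ratio_to_fraction_hexa(ratio: float, calibration: CalibrationTable | None = None) -> float:
    """Map an A555/A540 ratio to the fraction hexacoordinate F_H.

    Monotone piecewise-linear interpolation through the calibration anchors;
    the result is clamped to [0, 1] and out-of-range ratios clamp to the
    boundary anchors.
    """
    cal = DEFAULT_CALIBRATION if calibration is None else calibration
    if not np.isfinite(ratio):
        raise ValueError("ratio must be finite")
    f = float(np.interp(ratio, cal.ratios, cal.fractions))
    return min(1.0, max(0.0, f))


def fraction_to_KH(f_h: float) -> float:
    """Invert F_H = K_H/(1+K_H) to K_H = F_H/(1-F_H).

    F_H = 1 returns ``inf``; F_H at or above 0.999 additionally emits a
    :class:`NearSaturationWarning` because the inversion is then dominated by
    measurement error (a fully hexacoordinate protein has no finite K_H).
    """
    if not (0.0 <= f_h <= 1.0):
        raise ValueError(f"F_H must lie in [0, 1], got {f_h}")
    if f_h >= SATURATION_FRACTION:
        warnings.warn(
            f"F_H = {f_h:g} is at or near saturation; K_H is effectively unbounded",
            NearSaturationWarning,
            stacklevel=2,
        )
    if f_h == 1.0:
        return math.inf
    return f_h / (1.0 - f_h)


def KH_to_fraction(k_h: float) -> float:
    """Forward map K_H -> F_H = K_H/(1+K_H)."""
    if k_h < 0 or math.isnan(k_h):
        raise ValueError(f"K_H must be >= 0, got {k_h}")
    if math.isinf(k_h):
        return 1.0
    return k_h / (1.0 + k_h)


def estimate_coordination(
    spectrum: Spectrum, calibration: CalibrationTable | None = None
) -> CoordinationResult:
    """Full coordination pipeline: spectrum -> ratio -> F_H -> K_H."""
    ratio = peak_trough_ratio(spectrum)
    f_h = ratio_to_fraction_hexa(ratio, calibration)
    return CoordinationResult(ratio=ratio, f_h=f_h, k_h=fraction_to_KH(f_h))


def smooth_spectrum(spectrum: Spectrum, window: int = 9, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing along the wavelength axis.

    Standard light smoothing before reading band ratios from noisy scans;
    requires a uniform wavelength grid.  A quadratic filter over a window
    much narrower than the band widths leaves band shapes essentially
    unchanged while suppressing point noise.
    """
    from scipy.signal import savgol_filter

    steps = np.diff(spectrum.wavelengths)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
        raise ValueError("smoothing requires a uniform wavelength grid")
    if window > spectrum.wavelengths.size:
        raise ValueError("smoothing window larger than the spectrum")
    smoothed = savgol_filter(spectrum.absorbances, window, polyorder)
    return Spectrum(
        wavelengths=spectrum.wavelengths.copy(),
        absorbances=smoothed,
        state=spectrum.state,
        sample_id=spectrum.sample_id,
    )


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra sharing one wavelength grid."""
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise ValueError("replicate spectra must share an identical wavelength grid")
        if s.state != first.state:
            raise ValueError("replicate spectra must share the same state")
    mean = np.mean([s.absorbances for s in spectra], axis=0)
    return Spectrum(
        wavelengths=first.wavelengths.copy(),
        absorbances=mean,
        state=first.state,
        sample_id=f"mean(n={len(spectra)})",
    )
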