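"""Forward simulation of the hexacoordinate-globin kinetic scheme.

The minimal mass-action scheme in which the coordination equilibrium, the
CO-competition correction, and the affinity relation all hold couples four
heme species through the pentacoordinate intermediate::

    hexa-deoxy  <==[k_H_off / k_H_on]==>  penta-deoxy
    penta-deoxy + O2  <==[k'_O2 [O2] / k_O2_off]==>  oxy
    penta-deoxy + CO  <==[k'_CO [CO] / k_CO_off]==>  carbonmonoxy

Ligands are treated in pseudo-first-order excess (constant concentration),
so the species fractions obey a linear ODE ``df/dt = A f`` whose rate matrix
has columns summing to zero (total heme is conserved).  Trajectories are
integrated with a stiff-safe solver because transient-absorption relaxations
(~1e4 s^-1) and stopped-flow displacement (~0.3 s^-1) differ by five orders
of magnitude.

Every observable the analysis stages consume can be rendered from a
trajectory plus Gaussian-band basis spectra:

* equilibrium ferrous-deoxy spectra as penta/hexa mixtures,
* flash-photolysis delta-OD transients starting from 100 % pentacoordinate
  deoxy (instantaneous, complete photolysis),
* stopped-flow O2 -> CO displacement absorbance transients starting from
  100 % oxy,
* autoxidation spectral series decaying from oxy to ferric.

Noise is additive i.i.d. Gaussian per point; identical seeds and parameters
reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .coordination import CalibrationTable, Spectrum, PEAK_NM, TROUGH_NM
from .kinetics import KineticTrace

__all__ = [
    "SPECIES",
    "KineticScheme",
    "SpeciesTrajectory",
    "GaussianBand",
    "BasisSpectra",
    "NoiseModel",
    "DEFAULT_BASIS",
    "simulate_scheme",
    "generate_flash_photolysis_trace",
    "generate_stopped_flow_displacement_trace",
    "generate_equilibrium_spectrum",
    "generate_autoox_series",
    "calibration_from_basis",
    "auto_time_grid",
]

#: Heme species order used throughout trajectories and rate matrices.
SPECIES = ("hexa_deoxy", "penta_deoxy", "oxy", "carbonmonoxy")

FOUR_LN2 = 4.0 * math.log(2.0)

# Solver tolerances: tight enough that trajectories agree with the exact
# matrix-exponential solution of the linear system to well below 1e-8.
_RTOL = 1e-10
_ATOL = 1e-12


@dataclass(frozen=True)
class KineticScheme:
    """The six rate constants of the hexa <-> penta <-> ligand-bound scheme.

    Units: unimolecular rates s^-1, bimolecular rates uM^-1 s^-1.
    """

    k_h_on: float  # penta -> hexa (distal His binding), s^-1
    k_h_off: float  # hexa -> penta, s^-1
    k_prime_o2: float  # O2 association to penta, uM^-1 s^-1
    k_o2_off: float  # O2 dissociation, s^-1
    k_prime_co: float  # CO association to penta, uM^-1 s^-1
    k_co_off: float  # CO dissociation, s^-1

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")

    @property
    def K_H(self) -> float:
        """Coordination equilibrium constant k_H_on / k_H_off."""
        if self.k_h_off > 0:
            return self.k_h_on / self.k_h_off
        return math.inf if self.k_h_on > 0 else 0.0

    @classmethod
    def from_equilibrium(
        cls,
        K_H: float,
        k_h_off: float,
        k_prime_o2: float,
        k_o2_off: float,
        k_prime_co: float,
        k_co_off: float,
    ) -> "KineticScheme":
        """Build a scheme from K_H and the His dissociation rate."""
        return cls(K_H * k_h_off, k_h_off, k_prime_o2, k_o2_off, k_prime_co, k_co_off)

    def rate_matrix(self, o2_uM: float = 0.0, co_uM: float = 0.0) -> np.ndarray:
        """Pseudo-first-order rate matrix A with df/dt = A f.

        Columns sum to zero, which is the algebraic statement of heme
        conservation.
        """
        if o2_uM < 0 or co_uM < 0:
            raise ValueError("ligand concentrations must be >= 0")
        a_o2 = self.k_prime_o2 * o2_uM
        a_co = self.k_prime_co * co_uM
        # order: hexa_deoxy, penta_deoxy, oxy, carbonmonoxy
        return np.array(
            [
                [-self.k_h_off, self.k_h_on, 0.0, 0.0],
                [self.k_h_off, -(self.k_h_on + a_o2 + a_co), self.k_o2_off, self.k_co_off],
                [0.0, a_o2, -self.k_o2_off, 0.0],
                [0.0, a_co, 0.0, -self.k_co_off],
            ]
        )


@dataclass(frozen=True, eq=False)
class SpeciesTrajectory:
    """Per-species heme fractions over time for one simulated experiment."""

    times: np.ndarray  # s
    fractions: np.ndarray  # (n_times, 4), columns in SPECIES order
    o2_uM: float
    co_uM: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (t.size, len(SPECIES)):
            raise ValueError("fractions must have shape (n_times, n_species)")
        if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
            raise ValueError("species fractions outside [0, 1]")
        if np.max(np.abs(f.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("species fractions must sum to 1 (mass conservation)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", np.clip(f, 0.0, 1.0))

    def fraction(self, species: str) -> np.ndarray:
        return self.fractions[:, SPECIES.index(species)]


def _validate_time_grid(time_grid: Sequence[float]) -> np.ndarray:
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be a 1-D array with >= 2 points")
    if not np.all(np.isfinite(t)):
        raise ValueError("time grid contains non-finite values")
    if t[0] < 0 or not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing and start at >= 0")
    return t


def _initial_vector(initial_fractions) -> np.ndarray:
    if isinstance(initial_fractions, Mapping):
        unknown = set(initial_fractions) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species {sorted(unknown)}")
        y0 = np.array([float(initial_fractions.get(s, 0.0)) for s in SPECIES])
    else:
        y0 = np.asarray(initial_fractions, dtype=float)
        if y0.shape != (len(SPECIES),):
            raise ValueError(f"initial fractions must have {len(SPECIES)} entries")
    if np.any(y0 < 0):
        raise ValueError("initial fractions must be >= 0")
    if abs(y0.sum() - 1.0) > 1e-8:
        raise ValueError("initial fractions must sum to 1")
    return y0


def simulate_scheme(
    scheme: KineticScheme,
    initial_fractions,
    time_grid: Sequence[float],
    o2_uM: float = 0.0,
    co_uM: float = 0.0,
) -> SpeciesTrajectory:
    """Integrate the mass-action scheme under pseudo-first-order ligands.

    ``initial_fractions`` may be a length-4 sequence in :data:`SPECIES` order
    or a mapping from species name to fraction (missing species are 0).  The
    trajectory starts at ``time_grid[0]`` from the given state.
    """
    t = _validate_time_grid(time_grid)
    y0 = _initial_vector(initial_fractions)
    A = scheme.rate_matrix(o2_uM, co_uM)

    if np.all(A == 0.0):
        frac = np.tile(y0, (t.size, 1))
        return SpeciesTrajectory(t, frac, o2_uM, co_uM)

    sol = solve_ivp(
        lambda _t, y: A @ y,
        (t[0], t[-1]),
        y0,
        t_eval=t,
        method="LSODA",
        rtol=_RTOL,
        atol=_ATOL,
        jac=lambda _t, _y: A,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    frac = sol.y.T
    # remove solver round-off below the conservation tolerance
    frac = np.clip(frac, 0.0, 1.0)
    return SpeciesTrajectory(t, frac, o2_uM, co_uM)


class GaussianBand(NamedTuple):
    """One absorbance band: center (nm), full width at half maximum (nm), peak (AU)."""

    center_nm: float
    fwhm_nm: float
    amplitude: float


def _render_bands(bands: Sequence[GaussianBand], wavelengths) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    out = np.zeros_like(wl, dtype=float)
    for c, w, a in bands:
        out += a * np.exp(-FOUR_LN2 * (wl - c) ** 2 / w**2)
    return out


@dataclass(frozen=True)
class BasisSpectra:
    """Gaussian-band basis spectra, one band list per heme state.

    Defaults place the pentacoordinate deoxy band at 555 nm (broad) and the
    hexacoordinate deoxy split bands at 530/560 nm, plus Soret bands in the
    400-435 nm region so that transient traces monitored at 412/420 nm have
    signal.  Band positions are qualitative; amplitudes are chosen so the
    pure-state A555/A540 ratios sit at the empirical boundary anchors
    (~1.2 pentacoordinate, ~3.1 hexacoordinate).
    """

    bands: Mapping[str, tuple[GaussianBand, ...]]

    def __post_init__(self) -> None:
        for state, blist in self.bands.items():
            for b in blist:
                if b.fwhm_nm <= 0 or b.amplitude <= 0:
                    raise ValueError(f"band widths/amplitudes must be > 0 in state {state!r}")

    def states(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def support(self) -> tuple[float, float]:
        """Wavelength range covered by the bands (centers +- 3 FWHM)."""
        lo = min(b.center_nm - 3 * b.fwhm_nm for bl in self.bands.values() for b in bl)
        hi = max(b.center_nm + 3 * b.fwhm_nm for bl in self.bands.values() for b in bl)
        return lo, hi

    def value(self, state: str, wavelengths) -> np.ndarray | float:
        """Closed-form absorbance of one state at the given wavelength(s)."""
        if state not in self.bands:
            raise ValueError(f"unknown basis state {state!r}")
        out = _render_bands(self.bands[state], np.atleast_1d(wavelengths))
        return float(out[0]) if np.isscalar(wavelengths) else out


DEFAULT_BASIS = BasisSpectra(
    bands={
        "penta_deoxy": (GaussianBand(432.0, 14.0, 10.0), GaussianBand(555.0, 58.5, 1.0)),
        "hexa_deoxy": (
            GaussianBand(425.0, 12.0, 12.0),
            GaussianBand(530.0, 20.0, 0.42),
            GaussianBand(560.0, 20.0, 1.0),
        ),
        "oxy": (
            GaussianBand(412.0, 12.0, 12.0),
            GaussianBand(541.0, 18.0, 0.9),
            GaussianBand(577.0, 18.0, 1.0),
        ),
        "carbonmonoxy": (
            GaussianBand(420.0, 10.0, 15.0),
            GaussianBand(540.0, 18.0, 0.9),
            GaussianBand(569.0, 18.0, 1.0),
        ),
        "ferric_hexa": (
            GaussianBand(409.0, 14.0, 10.0),
            GaussianBand(530.0, 25.0, 0.8),
            GaussianBand(560.0, 25.0, 0.45),
        ),
        "ferric_penta": (
            GaussianBand(403.0, 14.0, 10.0),
            GaussianBand(495.0, 50.0, 0.85),
            GaussianBand(620.0, 25.0, 0.3),
        ),
    }
)

#: Default wavelength grid for equilibrium / autoxidation spectra (nm),
#: covering the visible alpha/beta band region.
DEFAULT_VISIBLE_GRID = np.arange(450.0, 651.0, 1.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise: sd in signal units, explicit seed."""

    sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0 or not np.isfinite(self.sd):
            raise ValueError(f"noise sd must be finite and >= 0, got {self.sd}")

    def sample(self, shape, rng: np.random.Generator | None = None) -> np.ndarray:
        if self.sd == 0.0:
            return np.zeros(shape)
        if rng is None:
            rng = np.random.default_rng(self.seed)
        return rng.normal(0.0, self.sd, size=shape)


def _check_monitor_wavelength(basis: BasisSpectra, wavelength: float) -> None:
    lo, hi = basis.support()
    if not (lo <= wavelength <= hi):
        raise ValueError(
            f"monitor wavelength {wavelength} nm outside the rendered range [{lo:g}, {hi:g}] nm"
        )


def auto_time_grid(rate: float, n_points: int = 400, n_half_lives: float = 10.0) -> np.ndarray:
    """Uniform time grid spanning ``n_half_lives`` of a relaxation ``rate``."""
    if rate <= 0 or not np.isfinite(rate):
        raise ValueError(f"rate must be finite and > 0, got {rate}")
    return np.linspace(0.0, n_half_lives * math.log(2.0) / rate, n_points)


def generate_flash_photolysis_trace(
    scheme: KineticScheme,
    ligand: str,
    conc: float,
    monitor_wavelength: float,
    time_grid: Sequence[float],
    basis: BasisSpectra = DEFAULT_BASIS,
    noise: NoiseModel = NoiseModel(),
    amplitude_scale: float = 1.0,
    replicate_id: str = "",
) -> KineticTrace:
    """Delta-OD rebinding transient after instantaneous, complete photolysis.

    The initial condition is 100 % pentacoordinate deoxy (the bound ligand is
    dissociated within the instrument response); the signal is the difference
    between the trajectory's absorbance at the monitor wavelength and that of
    the pre-flash ligand-bound state, rendered from the basis spectra.
    """
    if ligand not in ("O2", "CO"):
        raise ValueError(f"ligand must be 'O2' or 'CO', got {ligand!r}")
    if conc <= 0:
        raise ValueError(f"ligand concentration must be > 0, got {conc}")
    _check_monitor_wavelength(basis, monitor_wavelength)

    o2 = conc if ligand == "O2" else 0.0
    co = conc if ligand == "CO" else 0.0
    traj = simulate_scheme(scheme, {"penta_deoxy": 1.0}, time_grid, o2_uM=o2, co_uM=co)
    values = np.array([basis.value(s, monitor_wavelength) for s in SPECIES])
    bound_state = "oxy" if ligand == "O2" else "carbonmonoxy"
    reference = basis.value(bound_state, monitor_wavelength)
    signal = amplitude_scale * (traj.fractions @ values - reference)
    signal = signal + noise.sample(signal.shape)
    return KineticTrace(
        times=traj.times,
        signal=signal,
        monitor_wavelength_nm=float(monitor_wavelength),
        o2_uM=o2,
        co_uM=co,
        replicate_id=replicate_id,
        time_unit="s",
    )


def generate_stopped_flow_displacement_trace(
    scheme: KineticScheme,
    o2_conc: float,
    co_conc: float,
    monitor_wavelength: float,
    time_grid: Sequence[float],
    basis: BasisSpectra = DEFAULT_BASIS,
    noise: NoiseModel = NoiseModel(),
    replicate_id: str = "",
) -> KineticTrace:
    """Absorbance transient of O2 -> CO displacement after 1:1 mixing.

    Starts from 100 % oxy; when CO binding is effectively irreversible
    (k'_CO [CO] >> k_CO_off) the observed relaxation approaches
    ``k_O2_off / (1 + k'_O2 [O2] / (k'_CO [CO]))``.
    """
    if co_conc <= 0:
        raise ValueError(f"CO concentration must be > 0, got {co_conc}")
    if o2_conc < 0:
        raise ValueError(f"O2 concentration must be >= 0, got {o2_conc}")
    _check_monitor_wavelength(basis, monitor_wavelength)

    traj = simulate_scheme(scheme, {"oxy": 1.0}, time_grid, o2_uM=o2_conc, co_uM=co_conc)
    values = np.array([basis.value(s, monitor_wavelength) for s in SPECIES])
    signal = traj.fractions @ values
    signal = signal + noise.sample(signal.shape)
    return KineticTrace(
        times=traj.times,
        signal=signal,
        monitor_wavelength_nm=float(monitor_wavelength),
        o2_uM=o2_conc,
        co_uM=co_conc,
        replicate_id=replicate_id,
        time_unit="s",
    )


def generate_equilibrium_spectrum(
    f_h: float,
    state: str = "ferrous-deoxy",
    basis: BasisSpectra = DEFAULT_BASIS,
    noise: NoiseModel = NoiseModel(),
    wavelength_grid=None,
    sample_id: str = "",
) -> Spectrum:
    """Equilibrium spectrum as a hexa/penta two-component mixture.

    ``absorbance = f_h * hexa + (1 - f_h) * penta`` on the requested grid,
    using the ferrous-deoxy or ferric basis pair, plus additive noise.
    """
    if not (0.0 <= f_h <= 1.0):
        raise ValueError(f"F_H must lie in [0, 1], got {f_h}")
    pairs = {"ferrous-deoxy": ("hexa_deoxy", "penta_deoxy"), "ferric": ("ferric_hexa", "ferric_penta")}
    if state not in pairs:
        raise ValueError(f"state must be one of {sorted(pairs)}, got {state!r}")
    grid = DEFAULT_VISIBLE_GRID.copy() if wavelength_grid is None else np.asarray(wavelength_grid, dtype=float)
    hexa, penta = pairs[state]
    ab = f_h * basis.value(hexa, grid) + (1.0 - f_h) * basis.value(penta, grid)
    ab = ab + noise.sample(ab.shape)
    return Spectrum(wavelengths=grid, absorbances=ab, state=state, sample_id=sample_id)


def generate_autoox_series(
    k_ox_per_h: float,
    duration_h: float,
    n_spectra: int,
    basis: BasisSpectra = DEFAULT_BASIS,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    wavelength_grid=None,
) -> list[tuple[float, Spectrum]]:
    """Timestamped spectral series of oxy -> ferric autoxidation.

    Each spectrum is ``f(t)*oxy + (1 - f(t))*ferric`` with
    ``f(t) = exp(-k_ox t)``, times in hours spaced uniformly over
    ``duration_h``.  ``seed`` (defaulting to ``noise.seed``) seeds a single
    generator drawn from sequentially, so the whole series is reproducible.
    """
    if k_ox_per_h <= 0:
        raise ValueError(f"k_ox must be > 0, got {k_ox_per_h}")
    if duration_h <= 0:
        raise ValueError(f"duration must be > 0, got {duration_h}")
    if n_spectra < 3:
        raise ValueError(f"need at least 3 spectra, got {n_spectra}")
    grid = DEFAULT_VISIBLE_GRID.copy() if wavelength_grid is None else np.asarray(wavelength_grid, dtype=float)
    oxy = basis.value("oxy", grid)
    ferric = basis.value("ferric_hexa", grid)
    rng = np.random.default_rng(seed if seed is not None else noise.seed)
    series: list[tuple[float, Spectrum]] = []
    for t_h in np.linspace(0.0, duration_h, n_spectra):
        f = math.exp(-k_ox_per_h * t_h)
        ab = f * oxy + (1.0 - f) * ferric + noise.sample(grid.shape, rng=rng)
        series.append(
            (float(t_h), Spectrum(wavelengths=grid, absorbances=ab, state="oxy", sample_id=f"t={t_h:g}h"))
        )
    return series


def calibration_from_basis(
    basis: BasisSpectra = DEFAULT_BASIS,
    n_anchors: int = 201,
    peak_nm: float = PEAK_NM,
    trough_nm: float = TROUGH_NM,
    smooth_window: int | None = None,
    polyorder: int = 2,
    wavelength_grid=None,
) -> CalibrationTable:
    """Build a ratio -> F_H calibration consistent with a basis-spectra pair.

    Evaluates the noiseless mixture ratio on a dense F_H grid and returns the
    anchor table, so coordination estimates on synthetic mixtures are exact
    up to interpolation error.  When ``smooth_window`` is set the anchors are
    computed through the same measurement protocol as smoothed spectra
    (render on the grid, Savitzky-Golay filter, interpolate), keeping the
    calibration self-consistent with that protocol.
    """
    f = np.linspace(0.0, 1.0, n_anchors)
    if smooth_window is None:
        num = f * basis.value("hexa_deoxy", peak_nm) + (1 - f) * basis.value("penta_deoxy", peak_nm)
        den = f * basis.value("hexa_deoxy", trough_nm) + (1 - f) * basis.value("penta_deoxy", trough_nm)
    else:
        from scipy.signal import savgol_filter

        grid = DEFAULT_VISIBLE_GRID.copy() if wavelength_grid is None else np.asarray(wavelength_grid, float)
        hexa = basis.value("hexa_deoxy", grid)
        penta = basis.value("penta_deoxy", grid)
        mixtures = np.outer(f, hexa) + np.outer(1 - f, penta)  # (n_anchors, n_wl)
        mixtures = savgol_filter(mixtures, smooth_window, polyorder, axis=1)
        num = np.array([np.interp(peak_nm, grid, row) for row in mixtures])
        den = np.array([np.interp(trough_nm, grid, row) for row in mixtures])
    if np.any(den <= 0):
        raise ValueError("basis gives non-positive trough absorbance; calibration undefined")
    ratio = num / den
    if not np.all(np.diff(ratio) > 0):
        raise ValueError("basis does not give a strictly monotone ratio-F_H relationship")
    return CalibrationTable(ratios=ratio, fractions=f)
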