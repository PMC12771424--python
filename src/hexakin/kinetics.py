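"""Trace fitting and ligand-binding rate/equilibrium inference.

Observed relaxation rates come from single-exponential fits of averaged
kinetic traces, ``y(t) = offset + amplitude * exp(-k_obs * t)``.  From them:

* flash-photolysis rebinding rates at known ligand concentration give the
  bimolecular association rate to the pentacoordinate intermediate,
  ``k_obs = k' [L] + k_off`` (regression over concentrations, or single-point
  division);
* the stopped-flow O2 -> CO displacement rate is corrected for CO
  competition, ``k_O2 = k_obs * (1 + k'_O2 [O2] / (k'_CO [CO]))``;
* oxygen affinities follow as ``K_O2,pent = k'_O2,pent / k_O2`` and, after
  accounting for the histidine coordination equilibrium,
  ``K_O2 = K_O2,pent / (1 + K_H)``.

Units package-wide: time s, concentrations uM, bimolecular rates uM^-1 s^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import lmfit
import numpy as np
from scipy import stats

__all__ = [
    "KineticTrace",
    "ExponentialFit",
    "BimolecularFit",
    "BindingConstants",
    "FitFailureError",
    "average_traces",
    "fit_single_exponential",
    "bimolecular_rate",
    "correct_o2_dissociation",
    "binding_constants",
]

MIN_FIT_POINTS = 8


class FitFailureError(RuntimeError):
    """A kinetic fit failed and no rate can be reported."""


@dataclass(frozen=True, eq=False)
class KineticTrace:
    """Time course of absorbance (or delta-OD) at one monitor wavelength.

    ``times`` are strictly increasing, first point >= 0, in the unit named by
    ``time_unit`` ('s', 'min' or 'h').  Ligand concentrations are the
    post-mixing values in uM and travel with the trace as metadata.
    """

    times: np.ndarray
    signal: np.ndarray
    monitor_wavelength_nm: float | None = None
    o2_uM: float = 0.0
    co_uM: float = 0.0
    replicate_id: str = ""
    time_unit: str = "s"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if t.size < 3:
            raise ValueError("a kinetic trace needs at least 3 points")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("trace contains non-finite values")
        if t[0] < 0 or not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing and start at >= 0")
        if self.time_unit not in ("s", "min", "h"):
            raise ValueError(f"unknown time unit {self.time_unit!r}")
        if self.o2_uM < 0 or self.co_uM < 0:
            raise ValueError("ligand concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)

    def with_times_in(self, unit: str) -> "KineticTrace":
        """Return the same trace expressed in another time unit."""
        per_s = {"s": 1.0, "min": 60.0, "h": 3600.0}
        if unit not in per_s:
            raise ValueError(f"unknown time unit {unit!r}")
        factor = per_s[self.time_unit] / per_s[unit]
        return replace(self, times=self.times * factor, time_unit=unit)


@dataclass(frozen=True)
class ExponentialFit:
    """Result of a single-exponential fit ``offset + amplitude*exp(-k_obs*t)``.

    ``ok`` is False for degenerate (constant) traces, non-convergence,
    non-positive rates, or R^2 < 0.9; ``message`` says why.  ``k_obs`` is in
    the inverse of the fitted trace's time unit.
    """

    amplitude: float
    k_obs: float
    offset: float
    rss: float
    stderr_k_obs: float
    r_squared: float
    ok: bool
    message: str = ""


def _exp_model(t, amplitude, k_obs, offset):
    return offset + amplitude * np.exp(-k_obs * t)


_MODEL = lmfit.Model(_exp_model, independent_vars=["t"])


def average_traces(traces: list[KineticTrace]) -> KineticTrace:
    """Pointwise mean of replicate traces on an identical grid and metadata."""
    if not traces:
        raise ValueError("no traces to average")
    first = traces[0]
    for tr in traces[1:]:
        if not np.array_equal(tr.times, first.times):
            raise ValueError("replicate traces must share an identical time grid")
        if (
            tr.monitor_wavelength_nm != first.monitor_wavelength_nm
            or tr.o2_uM != first.o2_uM
            or tr.co_uM != first.co_uM
            or tr.time_unit != first.time_unit
        ):
            raise ValueError("replicate traces must share identical metadata")
    mean = np.mean([tr.signal for tr in traces], axis=0)
    return replace(first, signal=mean, replicate_id=f"mean(n={len(traces)})")


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Log-linear initialization on the baseline-subtracted signal."""
    n_tail = max(3, t.size // 10)
    offset0 = float(np.mean(y[-n_tail:]))
    amp0 = float(y[0] - offset0)
    span = t[-1] - t[0]
    k0 = 3.0 / span if span > 0 else 1.0
    sign = 1.0 if amp0 >= 0 else -1.0
    z = sign * (y - offset0)
    mask = z > 0.05 * abs(amp0)
    if mask.sum() >= 3 and abs(amp0) > 0:
        slope = np.polyfit(t[mask], np.log(z[mask]), 1)[0]
        if slope < 0:
            k0 = -float(slope)
    return amp0, k0, offset0


def fit_single_exponential(trace: KineticTrace, direction: str = "decay") -> ExponentialFit:
    """Least-squares single-exponential fit of a kinetic trace.

    The model is ``y(t) = offset + amplitude * exp(-k_obs * t)`` with all
    three parameters free.  Initialization comes from a log-linear regression
    on the baseline-subtracted signal.  Failures are reported via the ``ok``
    flag, never as a silent number: constant traces are flagged degenerate,
    and fits with ``k_obs <= 0`` or R^2 < 0.9 are flagged rejected.

    ``direction`` is informational ('decay' or 'recovery'); the amplitude sign
    carries the same content.
    """
    if direction not in ("decay", "recovery"):
        raise ValueError(f"direction must be 'decay' or 'recovery', got {direction!r}")
    t, y = trace.times, trace.signal
    if t.size < MIN_FIT_POINTS:
        raise ValueError(f"exponential fit needs >= {MIN_FIT_POINTS} points, got {t.size}")

    scale = max(1.0, float(np.max(np.abs(y))))
    if float(np.ptp(y)) <= 1e-12 * scale:
        return ExponentialFit(
            amplitude=0.0,
            k_obs=float("nan"),
            offset=float(np.mean(y)),
            rss=0.0,
            stderr_k_obs=float("nan"),
            r_squared=float("nan"),
            ok=False,
            message="degenerate: constant trace",
        )

    amp0, k0, offset0 = _initial_guess(t, y)
    params = _MODEL.make_params(amplitude=amp0, k_obs=k0, offset=offset0)
    result = _MODEL.fit(
        y,
        params,
        t=t,
        method="leastsq",
        max_nfev=20000,
        fit_kws={"xtol": 1e-12, "ftol": 1e-12, "gtol": 1e-12},
    )
    k = float(result.params["k_obs"].value)
    stderr = result.params["k_obs"].stderr
    rss = float(np.sum(result.residual**2))
    tss = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    message = ""
    ok = bool(result.success)
    if not ok:
        message = f"non-convergence: {result.message}"
    elif k <= 0:
        ok, message = False, f"rejected: k_obs = {k:g} <= 0"
    elif r2 < 0.9:
        ok, message = False, f"rejected: R^2 = {r2:.3f} < 0.9"
    return ExponentialFit(
        amplitude=float(result.params["amplitude"].value),
        k_obs=k,
        offset=float(result.params["offset"].value),
        rss=rss,
        stderr_k_obs=float(stderr) if stderr is not None else float("nan"),
        r_squared=r2,
        ok=ok,
        message=message,
    )


@dataclass(frozen=True)
class BimolecularFit:
    """Bimolecular association line ``k_obs = k_prime * [L] + k_off``."""

    k_prime: float  # uM^-1 s^-1
    k_off_intercept: float  # s^-1
    stderr_k_prime: float
    mode: str  # "regression" | "single-point"


def bimolecular_rate(
    points: list[tuple[float, float]], k_off: float | None = None
) -> BimolecularFit:
    """Bimolecular association rate from (concentration, k_obs) points.

    With >= 2 distinct concentrations an ordinary least-squares line
    ``k_obs = k_prime*[L] + intercept`` is fitted; a negative intercept is
    reported with a warning, not clamped.  A single point is accepted when
    ``k_off`` is supplied, giving ``k_prime = (k_obs - k_off)/[L]``.
    """
    if not points:
        raise ValueError("no (concentration, k_obs) points supplied")
    conc = np.asarray([p[0] for p in points], dtype=float)
    kobs = np.asarray([p[1] for p in points], dtype=float)
    if not (np.all(np.isfinite(conc)) and np.all(np.isfinite(kobs))):
        raise ValueError("non-finite (concentration, k_obs) point")
    if np.any(conc <= 0):
        raise ValueError("ligand concentrations must be > 0")

    if conc.size == 1:
        if k_off is None:
            raise ValueError("a single concentration point requires a supplied k_off")
        return BimolecularFit(
            k_prime=float((kobs[0] - k_off) / conc[0]),
            k_off_intercept=float(k_off),
            stderr_k_prime=float("nan"),
            mode="single-point",
        )

    if np.ptp(conc) == 0:
        raise ValueError("all concentrations identical; bimolecular slope undefined")
    fit = stats.linregress(conc, kobs)
    if fit.intercept < 0:
        warnings.warn(
            f"negative intercept {fit.intercept:g} s^-1 in bimolecular fit",
            UserWarning,
            stacklevel=2,
        )
    return BimolecularFit(
        k_prime=float(fit.slope),
        k_off_intercept=float(fit.intercept),
        stderr_k_prime=float(fit.stderr) if fit.stderr is not None else float("nan"),
        mode="regression",
    )


def correct_o2_dissociation(
    k_obs: float,
    k_prime_o2: float,
    k_prime_co: float,
    o2_conc: float,
    co_conc: float,
) -> float:
    """CO-competition correction of the stopped-flow displacement rate.

    ``k_O2 = k_obs * (1 + k'_O2 [O2] / (k'_CO [CO]))``.  The correction
    depends only on the concentration ratio and is always >= k_obs.
    """
    for name, v in (
        ("k_obs", k_obs),
        ("k_prime_o2", k_prime_o2),
        ("k_prime_co", k_prime_co),
        ("o2_conc", o2_conc),
        ("co_conc", co_conc),
    ):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    if co_conc == 0:
        raise ValueError("co_conc = 0: CO competition undefined")
    if k_prime_co == 0:
        raise ValueError("k_prime_co = 0: CO competition undefined")
    return k_obs * (1.0 + k_prime_o2 * o2_conc / (k_prime_co * co_conc))


@dataclass(frozen=True)
class BindingConstants:
    """Oxygen binding parameters for one protein (one affinity-table row).

    ``K_O2_pent`` is the affinity of the pentacoordinate intermediate and
    ``K_O2 = K_O2_pent / (1 + K_H)`` the affinity after paying the histidine
    displacement cost.  When ``K_O2_pent`` was overridden (e.g. a printed
    value), ``K_O2_pent_from_rates`` preserves the k'/k ratio for comparison.
    """

    k_prime_o2_pent: float  # uM^-1 s^-1
    k_o2: float | None  # s^-1
    k_prime_co_pent: float | None  # uM^-1 s^-1
    K_O2_pent: float  # uM^-1
    K_O2: float  # uM^-1
    K_H: float
    K_O2_pent_from_rates: float | None = None


def binding_constants(
    k_prime_o2_pent: float,
    k_o2: float | None = None,
    K_H: float = 0.0,
    k_prime_co_pent: float | None = None,
    K_O2_pent_override: float | None = None,
) -> BindingConstants:
    """Assemble oxygen affinities from rates and the coordination equilibrium.

    ``K_O2_pent = k'_O2,pent / k_O2`` unless overridden, then
    ``K_O2 = K_O2_pent / (1 + K_H)``.  ``K_H = 0`` recovers the
    pentacoordinate limit ``K_O2 = K_O2_pent``; ``K_H = inf`` gives 0.
    """
    if K_H < 0 or np.isnan(K_H):
        raise ValueError(f"K_H must be >= 0, got {K_H}")
    from_rates: float | None = None
    if K_O2_pent_override is None:
        if k_o2 is None or k_o2 <= 0:
            raise ValueError("k_o2 must be > 0 when K_O2_pent is not overridden")
        K_O2_pent = k_prime_o2_pent / k_o2
    else:
        K_O2_pent = float(K_O2_pent_override)
        if k_o2 is not None and k_o2 > 0:
            from_rates = k_prime_o2_pent / k_o2
    K_O2 = 0.0 if np.isinf(K_H) else K_O2_pent / (1.0 + K_H)
    return BindingConstants(
        k_prime_o2_pent=float(k_prime_o2_pent),
        k_o2=float(k_o2) if k_o2 is not None else None,
        k_prime_co_pent=float(k_prime_co_pent) if k_prime_co_pent is not None else None,
        K_O2_pent=float(K_O2_pent),
        K_O2=float(K_O2),
        K_H=float(K_H),
        K_O2_pent_from_rates=from_rates,
    )
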