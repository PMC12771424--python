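"""End-to-end pipeline: simulate or ingest -> coordination -> kinetics ->
autoxidation -> report.

A run is configured by a human-readable YAML file; each protein entry holds
either ``truth`` (simulation ground-truth parameters) or ``inputs``
(measured data files).  Runs are deterministic given the config and seed:
all randomness flows from one seed sequence, and reports contain no
timestamps or absolute paths.  Per-protein failures are captured in the
report rather than aborting the run.

Simulated protocol (mirroring the bench workflow):

* equilibrium ferrous-deoxy spectra, 10 replicate scans averaged, ratio ->
  F_H -> K_H via a calibration derived from the same basis spectra;
* O2 flash photolysis at one concentration (air, 262 uM default), 10
  replicate traces averaged, single-exponential fit, single-point
  bimolecular rate;
* CO flash photolysis at several concentrations, bimolecular regression;
* stopped-flow O2 -> CO displacement, CO-competition correction (k_O2),
  then affinities K_O2,pent and K_O2;
* autoxidation spectral series, 575 nm extraction, k_ox and t_1/2.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from ._version import __version__
from . import io as hio
from .autoox import AutooxResult, extract_timecourse, fit_autoox
from .coordination import (
    CalibrationTable,
    CoordinationResult,
    DEFAULT_CALIBRATION,
    Spectrum,
    average_spectra,
    estimate_coordination,
    smooth_spectrum,
)
from .kinetics import (
    BindingConstants,
    ExponentialFit,
    KineticTrace,
    average_traces,
    bimolecular_rate,
    binding_constants,
    correct_o2_dissociation,
    fit_single_exponential,
)
from .simulate import (
    BasisSpectra,
    DEFAULT_BASIS,
    KineticScheme,
    NoiseModel,
    auto_time_grid,
    calibration_from_basis,
    generate_autoox_series,
    generate_equilibrium_spectrum,
    generate_flash_photolysis_trace,
    generate_stopped_flow_displacement_trace,
)

__all__ = [
    "ConfigError",
    "InputError",
    "SimulationTruth",
    "InputPaths",
    "ProteinConfig",
    "RunConfig",
    "ProteinReport",
    "SimulatedProteinData",
    "simulate_protein_data",
    "analyze_protein",
    "run_pipeline",
    "write_report",
    "read_report",
]

#: Dissolved O2 in air-equilibrated buffer at 25 C, uM.
O2_AIR_UM = 262.0
TA_O2_WAVELENGTH_NM = 420.0
TA_CO_WAVELENGTH_NM = 412.0
SF_WAVELENGTH_NM = 412.0
#: Savitzky-Golay window (points) applied to averaged spectra before the
#: band-ratio read; the calibration is built through the same protocol.
SPECTRUM_SMOOTH_WINDOW = 9


class ConfigError(ValueError):
    """The run configuration is invalid."""


class InputError(OSError):
    """An input file is missing or unreadable."""


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters and acquisition conditions for one protein.

    Rates follow the package units convention (s, uM, uM^-1 s^-1; k_ox in
    h^-1).  ``noise_sd`` is relative: the Gaussian sd applied to each
    observable is ``noise_sd`` times that observable's characteristic
    amplitude (spectrum peak, trace amplitude).  His-exchange kinetics
    default to the slow end of the plant nsHb range so that rebinding
    transients are cleanly single-exponential, matching the analysis model.
    """

    f_h: float
    k_prime_o2: float
    k_o2_off: float
    k_prime_co: float
    k_ox_per_h: float
    k_co_off: float = 0.001
    k_h_off: float = 2.0
    noise_sd: float = 0.0
    n_replicates: int = 10
    n_spectrum_replicates: int = 10
    ta_o2_uM: float = O2_AIR_UM
    ta_co_uM: tuple[float, ...] = (250.0, 500.0, 1000.0)
    sf_o2_uM: float = O2_AIR_UM / 2.0
    sf_co_uM: float = 1000.0
    autoox_duration_h: float | None = None
    autoox_n_spectra: int = 40
    autoox_n_replicates: int = 3  # measured in triplicate

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_h < 1.0):
            raise ConfigError(f"truth f_h must lie in [0, 1), got {self.f_h}")
        for name in ("k_prime_o2", "k_o2_off", "k_prime_co", "k_ox_per_h"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"truth {name} must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_replicates < 1 or self.n_spectrum_replicates < 1:
            raise ConfigError("replicate counts must be >= 1")

    @property
    def K_H(self) -> float:
        return self.f_h / (1.0 - self.f_h)

    def scheme(self) -> KineticScheme:
        return KineticScheme.from_equilibrium(
            self.K_H, self.k_h_off, self.k_prime_o2, self.k_o2_off, self.k_prime_co, self.k_co_off
        )


@dataclass(frozen=True)
class InputPaths:
    """Measured-data file groups for one protein."""

    deoxy_spectra: tuple[Path, ...] = ()
    ta_o2: tuple[Path, ...] = ()
    ta_co: tuple[Path, ...] = ()
    stopped_flow: tuple[Path, ...] = ()
    autoox_manifests: tuple[Path, ...] = ()

    def all_paths(self) -> list[Path]:
        return [
            *self.deoxy_spectra,
            *self.ta_o2,
            *self.ta_co,
            *self.stopped_flow,
            *self.autoox_manifests,
        ]


@dataclass(frozen=True)
class ProteinConfig:
    name: str
    truth: SimulationTruth | None = None
    inputs: InputPaths | None = None

    def __post_init__(self) -> None:
        if (self.truth is None) == (self.inputs is None):
            raise ConfigError(
                f"protein {self.name!r}: exactly one of 'truth' or 'inputs' must be given"
            )


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    proteins: tuple[ProteinConfig, ...]
    seed: int = 0
    output_dir: Path | None = None
    calibration_path: Path | None = None
    report_format: str = "delimited"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        if self.report_format not in ("delimited", "human"):
            raise ConfigError(f"unknown report format {self.report_format!r}")
        names = [p.name for p in self.proteins]
        if len(set(names)) != len(names):
            raise ConfigError("protein names must be unique")

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        base = Path(base_dir) if base_dir is not None else Path.cwd()

        def resolve(p) -> Path:
            path = Path(p)
            path = path if path.is_absolute() else base / path
            if not path.exists():
                raise ConfigError(f"referenced path does not exist: {path}")
            return path

        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        proteins = []
        for entry in raw.get("proteins", []):
            if "name" not in entry:
                raise ConfigError("every protein entry needs a 'name'")
            truth = inputs = None
            if "truth" in entry:
                try:
                    truth = SimulationTruth(
                        **{
                            k: tuple(v) if isinstance(v, list) else v
                            for k, v in entry["truth"].items()
                        }
                    )
                except TypeError as exc:
                    raise ConfigError(f"protein {entry['name']!r}: bad truth block ({exc})")
            if "inputs" in entry:
                blk = entry["inputs"]

                def paths(key) -> tuple[Path, ...]:
                    val = blk.get(key, [])
                    val = [val] if isinstance(val, (str, Path)) else val
                    return tuple(resolve(p) for p in val)

                manifests = paths("autoox_manifest") + paths("autoox_manifests")
                inputs = InputPaths(
                    deoxy_spectra=paths("deoxy_spectrum"),
                    ta_o2=paths("ta_o2"),
                    ta_co=paths("ta_co"),
                    stopped_flow=paths("stopped_flow"),
                    autoox_manifests=manifests,
                )
            proteins.append(ProteinConfig(name=entry["name"], truth=truth, inputs=inputs))
        out_dir = raw.get("output_dir")
        cal = raw.get("calibration")
        return cls(
            proteins=tuple(proteins),
            seed=raw.get("seed", 0),
            output_dir=Path(out_dir) if out_dir else None,
            calibration_path=resolve(cal) if cal else None,
            report_format=raw.get("report_format", "delimited"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except OSError as exc:
            raise InputError(f"cannot read config {path}: {exc}")
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}")
        return cls.from_dict(raw or {}, base_dir=path.parent)


@dataclass(frozen=True)
class ProteinReport:
    """Per-protein results: one row each of the coordination, oxygen-binding
    and autoxidation tables, plus fit diagnostics and provenance."""

    protein: str
    coordination: CoordinationResult | None = None
    binding: BindingConstants | None = None
    autoox: AutooxResult | None = None
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    error: str | None = None


@dataclass(frozen=True)
class SimulatedProteinData:
    """All synthetic observables for one protein, with replicates."""

    name: str
    truth: SimulationTruth
    scheme: KineticScheme
    deoxy_spectra: list[Spectrum]
    ta_o2: dict[float, list[KineticTrace]]
    ta_co: dict[float, list[KineticTrace]]
    stopped_flow: list[KineticTrace]
    autoox_series: list[list[tuple[float, Spectrum]]]  # replicate series


def _seed_ints(ss: np.random.SeedSequence, n: int) -> list[int]:
    return [int(x) for x in ss.generate_state(n, dtype=np.uint32)]


def simulate_protein_data(
    name: str,
    truth: SimulationTruth,
    seed_root: np.random.SeedSequence,
    basis: BasisSpectra = DEFAULT_BASIS,
) -> SimulatedProteinData:
    """Generate the full synthetic dataset for one protein.

    Noise sd per observable is ``truth.noise_sd`` times the observable's
    noiseless amplitude; every replicate gets its own child seed.
    """
    scheme = truth.scheme()
    ss_spec, ss_tao2, ss_taco, ss_sf, ss_ox = seed_root.spawn(5)

    clean_spec = generate_equilibrium_spectrum(truth.f_h, basis=basis)
    sd_spec = truth.noise_sd * float(np.max(clean_spec.absorbances))
    deoxy = [
        generate_equilibrium_spectrum(
            truth.f_h, basis=basis, noise=NoiseModel(sd_spec, s), sample_id=f"{name}_deoxy_r{i}"
        )
        for i, s in enumerate(_seed_ints(ss_spec, truth.n_spectrum_replicates))
    ]

    def _replicated_flash(ligand, conc, wavelength, stage_ss):
        rate = (
            (scheme.k_prime_o2 if ligand == "O2" else scheme.k_prime_co) * conc
            + (scheme.k_o2_off if ligand == "O2" else scheme.k_co_off)
            + scheme.k_h_on
        )
        grid = auto_time_grid(rate)
        clean = generate_flash_photolysis_trace(scheme, ligand, conc, wavelength, grid, basis)
        sd = truth.noise_sd * float(np.ptp(clean.signal))
        return [
            generate_flash_photolysis_trace(
                scheme, ligand, conc, wavelength, grid, basis,
                noise=NoiseModel(sd, s), replicate_id=f"r{i}",
            )
            for i, s in enumerate(_seed_ints(stage_ss, truth.n_replicates))
        ]

    ta_o2 = {truth.ta_o2_uM: _replicated_flash("O2", truth.ta_o2_uM, TA_O2_WAVELENGTH_NM, ss_tao2)}
    ta_co = {
        conc: _replicated_flash("CO", conc, TA_CO_WAVELENGTH_NM, child)
        for conc, child in zip(truth.ta_co_uM, ss_taco.spawn(len(truth.ta_co_uM)))
    }

    sf_rate = truth.k_o2_off / (
        1.0 + truth.k_prime_o2 * truth.sf_o2_uM / (truth.k_prime_co * truth.sf_co_uM)
    )
    sf_grid = auto_time_grid(sf_rate)
    clean_sf = generate_stopped_flow_displacement_trace(
        scheme, truth.sf_o2_uM, truth.sf_co_uM, SF_WAVELENGTH_NM, sf_grid, basis
    )
    sd_sf = truth.noise_sd * float(np.ptp(clean_sf.signal))
    stopped_flow = [
        generate_stopped_flow_displacement_trace(
            scheme, truth.sf_o2_uM, truth.sf_co_uM, SF_WAVELENGTH_NM, sf_grid, basis,
            noise=NoiseModel(sd_sf, s), replicate_id=f"r{i}",
        )
        for i, s in enumerate(_seed_ints(ss_sf, truth.n_replicates))
    ]

    duration = truth.autoox_duration_h or 5.0 / truth.k_ox_per_h
    sd_ox = truth.noise_sd * float(basis.value("oxy", 577.0))
    autoox_series = [
        generate_autoox_series(
            truth.k_ox_per_h,
            duration,
            truth.autoox_n_spectra,
            basis=basis,
            noise=NoiseModel(sd_ox, s),
        )
        for s in _seed_ints(ss_ox, truth.autoox_n_replicates)
    ]
    return SimulatedProteinData(
        name=name,
        truth=truth,
        scheme=scheme,
        deoxy_spectra=deoxy,
        ta_o2=ta_o2,
        ta_co=ta_co,
        stopped_flow=stopped_flow,
        autoox_series=autoox_series,
    )


def _fit_diag(fit: ExponentialFit) -> dict:
    return {
        "k_obs": fit.k_obs,
        "amplitude": fit.amplitude,
        "offset": fit.offset,
        "stderr_k_obs": fit.stderr_k_obs,
        "rss": fit.rss,
        "r_squared": fit.r_squared,
        "ok": fit.ok,
        "message": fit.message,
    }


def analyze_protein(
    name: str,
    deoxy_spectra: list[Spectrum] | None = None,
    ta_o2: dict[float, list[KineticTrace]] | None = None,
    ta_co: dict[float, list[KineticTrace]] | None = None,
    stopped_flow: list[KineticTrace] | None = None,
    autoox_series: list[tuple[float, Spectrum]] | None = None,
    calibration: CalibrationTable | None = None,
    k_h: float | None = None,
    provenance: dict | None = None,
    smooth_window: int | None = SPECTRUM_SMOOTH_WINDOW,
) -> ProteinReport:
    """Run every analysis stage for which inputs are present.

    ``k_h`` overrides the spectral estimate when no deoxy spectra are given
    (e.g. the kinetics-only workflow).  Raises on fit failures; catching them
    per protein is the orchestrator's job.
    """
    diagnostics: dict[str, Any] = {}
    coordination = None
    if deoxy_spectra:
        mean_spec = average_spectra(deoxy_spectra)
        if smooth_window:
            steps = np.diff(mean_spec.wavelengths)
            if np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
                mean_spec = smooth_spectrum(mean_spec, smooth_window)
        coordination = estimate_coordination(mean_spec, calibration)
        k_h = coordination.k_h

    binding = None
    if ta_o2 or ta_co or stopped_flow:
        if k_h is None:
            raise ConfigError(f"protein {name!r}: kinetics need K_H (spectra or explicit value)")

        def _points(groups, label) -> list[tuple[float, float]]:
            pts = []
            diagnostics[label] = []
            for conc in sorted(groups):
                fit = fit_single_exponential(average_traces(groups[conc]))
                if not fit.ok:
                    raise RuntimeError(f"{name} {label} fit at {conc} uM failed: {fit.message}")
                diagnostics[label].append({"conc_uM": conc, **_fit_diag(fit)})
                pts.append((conc, fit.k_obs))
            return pts

        k_prime_o2 = k_prime_co = None
        if ta_o2:
            pts = _points(ta_o2, "ta_o2")
            fit = bimolecular_rate(pts, k_off=0.0) if len(pts) == 1 else bimolecular_rate(pts)
            diagnostics["bimolecular_o2"] = asdict(fit)
            k_prime_o2 = fit.k_prime
        if ta_co:
            pts = _points(ta_co, "ta_co")
            fit = bimolecular_rate(pts, k_off=0.0) if len(pts) == 1 else bimolecular_rate(pts)
            diagnostics["bimolecular_co"] = asdict(fit)
            k_prime_co = fit.k_prime

        k_o2 = None
        if stopped_flow:
            if k_prime_o2 is None or k_prime_co is None:
                raise ConfigError(
                    f"protein {name!r}: the stopped-flow correction needs both association rates"
                )
            sf = average_traces(stopped_flow)
            fit = fit_single_exponential(sf)
            if not fit.ok:
                raise RuntimeError(f"{name} stopped-flow fit failed: {fit.message}")
            diagnostics["stopped_flow"] = {
                "o2_uM": sf.o2_uM, "co_uM": sf.co_uM, **_fit_diag(fit)
            }
            k_o2 = correct_o2_dissociation(fit.k_obs, k_prime_o2, k_prime_co, sf.o2_uM, sf.co_uM)

        if k_prime_o2 is not None and k_o2 is not None:
            binding = binding_constants(k_prime_o2, k_o2, K_H=k_h, k_prime_co_pent=k_prime_co)

    autoox = None
    if autoox_series:
        # accept a single (time, spectrum) series or a list of replicate series
        replicates = (
            [autoox_series]
            if isinstance(autoox_series[0], tuple)
            else list(autoox_series)
        )
        traces = [extract_timecourse(s) for s in replicates]
        autoox = fit_autoox(average_traces(traces))
        diagnostics["autoox"] = _fit_diag(autoox.fit)
        if not autoox.ok:
            raise RuntimeError(f"{name} autoxidation fit failed: {autoox.fit.message}")

    return ProteinReport(
        protein=name,
        coordination=coordination,
        binding=binding,
        autoox=autoox,
        diagnostics=diagnostics,
        provenance=provenance or {},
    )


def _load_inputs(inputs: InputPaths):
    for p in inputs.all_paths():
        if not Path(p).exists():
            raise InputError(f"input file missing: {p}")

    def group_traces(paths) -> dict[float, list[KineticTrace]]:
        groups: dict[float, list[KineticTrace]] = {}
        for p in paths:
            tr = hio.read_trace(p)
            conc = tr.o2_uM if tr.o2_uM > 0 else tr.co_uM
            groups.setdefault(conc, []).append(tr)
        return groups

    deoxy = [hio.read_spectrum(p) for p in inputs.deoxy_spectra]
    ta_o2 = group_traces(inputs.ta_o2)
    ta_co = group_traces(inputs.ta_co)
    sf = [hio.read_trace(p) for p in inputs.stopped_flow]
    series = [hio.read_autoox_series(p) for p in inputs.autoox_manifests] or None
    return deoxy, ta_o2, ta_co, sf, series


def run_pipeline(config: RunConfig, basis: BasisSpectra = DEFAULT_BASIS) -> list[ProteinReport]:
    """Execute the configured run and return one report per protein.

    Deterministic given config and seed.  Per-protein failures become error
    entries; an invalid config raises before any work.  When ``output_dir``
    is set, reports and the structured run log are written there.
    """
    user_cal = (
        hio.read_calibration(config.calibration_path) if config.calibration_path else None
    )
    basis_cal = calibration_from_basis(basis, smooth_window=SPECTRUM_SMOOTH_WINDOW)
    root = np.random.SeedSequence(config.seed)
    reports: list[ProteinReport] = []
    for pcfg in config.proteins:
        child = root.spawn(1)[0]
        provenance = {
            "package": "hexakin",
            "version": __version__,
            "seed": config.seed,
            "protein": pcfg.name,
            "mode": "simulated" if pcfg.truth is not None else "measured",
        }
        try:
            if pcfg.truth is not None:
                data = simulate_protein_data(pcfg.name, pcfg.truth, child, basis)
                report = analyze_protein(
                    pcfg.name,
                    deoxy_spectra=data.deoxy_spectra,
                    ta_o2=data.ta_o2,
                    ta_co=data.ta_co,
                    stopped_flow=data.stopped_flow,
                    autoox_series=data.autoox_series,
                    calibration=user_cal or basis_cal,
                    provenance=provenance,
                )
            else:
                deoxy, ta_o2, ta_co, sf, series = _load_inputs(pcfg.inputs)
                report = analyze_protein(
                    pcfg.name,
                    deoxy_spectra=deoxy or None,
                    ta_o2=ta_o2 or None,
                    ta_co=ta_co or None,
                    stopped_flow=sf or None,
                    autoox_series=series,
                    calibration=user_cal or DEFAULT_CALIBRATION,
                    provenance=provenance,
                )
        except ConfigError:
            raise
        except Exception as exc:  # per-protein isolation
            report = ProteinReport(protein=pcfg.name, provenance=provenance, error=str(exc))
        reports.append(report)
    if config.output_dir is not None:
        write_report(reports, config.output_dir, config.report_format)
    return reports


# --- report serialization -------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return {"__float__": repr(obj)}
    return obj


def _unjsonable(obj):
    if isinstance(obj, dict):
        if set(obj) == {"__float__"}:
            return float(obj["__float__"])
        return {k: _unjsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_unjsonable(v) for v in obj]
    return obj


def report_to_dict(report: ProteinReport) -> dict:
    return _jsonable(asdict(report))


def report_from_dict(raw: dict) -> ProteinReport:
    raw = _unjsonable(raw)
    coord = raw.get("coordination")
    binding = raw.get("binding")
    autoox = raw.get("autoox")
    return ProteinReport(
        protein=raw["protein"],
        coordination=CoordinationResult(**coord) if coord else None,
        binding=BindingConstants(**binding) if binding else None,
        autoox=(
            AutooxResult(
                k_ox_per_h=autoox["k_ox_per_h"],
                t_half_min=autoox["t_half_min"],
                fit=ExponentialFit(**autoox["fit"]),
                ok=autoox["ok"],
            )
            if autoox
            else None
        ),
        diagnostics=raw.get("diagnostics", {}),
        provenance=raw.get("provenance", {}),
        error=raw.get("error"),
    )


_COORD_HEADER = "protein,a555_over_a540,fraction_hexacoordinate,K_H\n"
_BINDING_HEADER = (
    "protein,k_prime_o2_pent_per_uM_per_s,k_o2_per_s,k_prime_co_pent_per_uM_per_s,"
    "K_o2_pent_per_uM,K_o2_per_uM,K_H\n"
)
_AUTOOX_HEADER = "protein,k_ox_per_h,t_half_min\n"


def _fmt(x) -> str:
    if x is None:
        return ""
    return f"{x:.12g}"


def write_report(reports: list[ProteinReport], out_dir, fmt: str = "delimited") -> list[Path]:
    """Write the three result tables plus the structured JSON run log.

    Delimited output mirrors the published table layouts (coordination:
    ratio, F_H, K_H; oxygen binding: k'_O2,pent, k_O2, K_O2,pent, K_O2;
    autoxidation: k_ox, t_1/2) with units in the headers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    log = out_dir / "report.json"
    log.write_text(
        json.dumps([report_to_dict(r) for r in reports], indent=2, sort_keys=True) + "\n"
    )
    written.append(log)

    if fmt == "delimited":
        coord_lines, bind_lines, ox_lines = [_COORD_HEADER], [_BINDING_HEADER], [_AUTOOX_HEADER]
        for r in reports:
            if r.coordination is not None:
                c = r.coordination
                coord_lines.append(f"{r.protein},{_fmt(c.ratio)},{_fmt(c.f_h)},{_fmt(c.k_h)}\n")
            if r.binding is not None:
                b = r.binding
                bind_lines.append(
                    f"{r.protein},{_fmt(b.k_prime_o2_pent)},{_fmt(b.k_o2)},"
                    f"{_fmt(b.k_prime_co_pent)},{_fmt(b.K_O2_pent)},{_fmt(b.K_O2)},{_fmt(b.K_H)}\n"
                )
            if r.autoox is not None:
                a = r.autoox
                ox_lines.append(f"{r.protein},{_fmt(a.k_ox_per_h)},{_fmt(a.t_half_min)}\n")
        for fname, lines in (
            ("coordination.csv", coord_lines),
            ("oxygen_binding.csv", bind_lines),
            ("autoxidation.csv", ox_lines),
        ):
            path = out_dir / fname
            path.write_text("".join(lines))
            written.append(path)
    elif fmt == "human":
        lines = []
        for r in reports:
            lines.append(f"== {r.protein} ==")
            if r.error:
                lines.append(f"  ERROR: {r.error}")
            if r.coordination:
                c = r.coordination
                lines.append(
                    f"  coordination: A555/A540 = {c.ratio:.3g}, F_H = {c.f_h:.3g}, K_H = {c.k_h:.3g}"
                )
            if r.binding:
                b = r.binding
                lines.append(
                    f"  oxygen binding: k'_O2,pent = {b.k_prime_o2_pent:.4g} uM^-1 s^-1, "
                    f"k_O2 = {b.k_o2:.4g} s^-1, K_O2,pent = {b.K_O2_pent:.4g} uM^-1, "
                    f"K_O2 = {b.K_O2:.4g} uM^-1"
                )
            if r.autoox:
                a = r.autoox
                lines.append(
                    f"  autoxidation: k_ox = {a.k_ox_per_h:.3g} h^-1, t_1/2 = {a.t_half_min:.3g} min"
                )
            lines.append("")
        path = out_dir / "report.txt"
        path.write_text("\n".join(lines))
        written.append(path)
    else:
        raise ConfigError(f"unknown report format {fmt!r}")
    return written


def read_report(path) -> list[ProteinReport]:
    """Parse a ``report.json`` run log back into :class:`ProteinReport`s."""
    raw = json.loads(Path(path).read_text())
    return [report_from_dict(entry) for entry in raw]
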