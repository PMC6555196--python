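"""Experiment configuration, result persistence and run manifests.

Configs are YAML with one documented schema; unknown keys are rejected with
an error naming them, and every physical quantity carries an explicit unit
suffix in its key (unit mistakes are the dominant failure mode in this
domain).  Results are persisted as HDF5 (groups ``/times``, ``/vm``,
``/vout``, ``/currents``, ``/gating/*``, JSON metadata attribute) with a CSV
fallback for small runs; both round-trip float64 arrays losslessly (CSV to
17 significant digits).  ``run_experiment`` writes a manifest so that
config + seed reproduce every numeric output bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .analysis import bundle_locking_summary
from .dynamics import MODEL_REGISTRY, StimulusSpec, SynapseSpec
from .errors import FormatError, NamingError, ValidationError
from .field import ExtracellularMedium
from .morphology import discretize, fixture_network, Network, read_swc
from .solver import (SimulationResult, SolverOptions, assemble,
                     geometry_hash, randomized_limit_cycle_init, solve)

SCHEMA_VERSION = 1

log = logging.getLogger("ephapsim")


def setup_logging(logfile: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    """Console + optional per-run file logging."""
    log.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        log.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        log.addHandler(fh)


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    fixture: str | None = None
    params: dict[str, float | int] = Field(default_factory=dict)
    swc_path: str | None = None
    swc_nseg: int = 1

    @model_validator(mode="after")
    def _one_source(self):
        if (self.fixture is None) == (self.swc_path is None):
            raise ValueError("geometry needs exactly one of fixture/swc_path")
        return self


class ModelConfig(_Strict):
    type: str = "hh"
    params: dict[str, float] = Field(default_factory=dict)


class DynamicsConfig(_Strict):
    models: dict[str, ModelConfig] = Field(
        default_factory=lambda: {"hh": ModelConfig()})


class StimulusConfig(_Strict):
    target_segment: int | None = None
    side: str = "intracellular"
    waveform: str = "dc"
    amplitude_nA: float = 0.0
    frequency_Hz: float = 0.0
    phase_rad: float = 0.0
    electrode: str = "point"
    position_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    field_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)


class SynapseConfig(_Strict):
    kind: str = "chemical"
    pre_segment: int | None = None
    post_segment: int = 0
    pre_spike_times_ms: list[float] | None = None
    pre_spike_file: str | None = None
    g_max_nS: float = 1.0
    e_syn_mV: float = 0.0
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 3.0
    threshold_mV: float = 0.0


class MediumConfig(_Strict):
    sigma_S_per_m: float | None = 0.3
    sweep_S_per_m: list[float] | None = None

    @model_validator(mode="after")
    def _nonempty(self):
        if self.sweep_S_per_m is not None and len(self.sweep_S_per_m) == 0:
            raise ValueError("sweep_S_per_m must be non-empty")
        return self

    def values(self) -> list[float]:
        return (list(self.sweep_S_per_m) if self.sweep_S_per_m is not None
                else [self.sigma_S_per_m])


class SolverConfig(_Strict):
    mode: str = "open_loop"
    formulation: str = "eliminated_ode"
    rel_tol: float = 1e-6
    abs_tol_mV: float = 1e-8
    dense_output_dt_ms: float = 0.025
    t_stop_ms: float = 30.0
    settle_ms: float = 500.0
    limit_cycle_init: bool = False


class AnalysisConfig(_Strict):
    enabled: bool = False
    window_ms: tuple[float, float] | None = None
    bin_width_ms: float = 1.0
    threshold_mV: float = 0.0
    refractory_ms: float = 2.0


class OutputConfig(_Strict):
    dir: str = "results"
    format: str = "hdf5"  # or "csv"


class ExperimentConfig(_Strict):
    """Full description of one reproducible experiment."""

    seed: int = 0
    geometry: GeometryConfig
    dynamics: DynamicsConfig = Field(default_factory=DynamicsConfig)
    stimuli: list[StimulusConfig] = Field(default_factory=list)
    synapses: list[SynapseConfig] = Field(default_factory=list)
    medium: MediumConfig = Field(default_factory=MediumConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)


def parse_config(source: str | Path | dict) -> ExperimentConfig:
    """Parse and validate a YAML config (path, text, or mapping)."""
    if isinstance(source, dict):
        data = source
    else:
        text = Path(source).read_text() if (
            isinstance(source, Path)
            or (isinstance(source, str) and "\n" not in source
                and Path(source).exists())) else str(source)
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError("config must be a mapping")
    try:
        return ExperimentConfig.model_validate(data)
    except Exception as exc:
        raise FormatError(f"invalid config: {exc}") from exc


def serialize_config(config: ExperimentConfig) -> str:
    """YAML text with all defaults recorded explicitly; round-trips through
    :func:`parse_config` unchanged."""
    return yaml.safe_dump(config.model_dump(), sort_keys=False)


# ---------------------------------------------------------------------------
# building runtime objects from a config
# ---------------------------------------------------------------------------

def build_network(config: ExperimentConfig) -> Network:
    g = config.geometry
    if g.fixture is not None:
        return fixture_network(g.fixture, **g.params)
    cell = read_swc(str(g.swc_path), nseg=g.swc_nseg)
    net = Network()
    net.add(cell)
    return discretize(net)


def build_models(config: ExperimentConfig):
    models = {}
    for tag, mc in config.dynamics.models.items():
        if mc.type not in MODEL_REGISTRY:
            raise NamingError(f"unknown model type {mc.type!r} for tag {tag!r}")
        models[tag] = MODEL_REGISTRY[mc.type](**mc.params)
    return models


def build_stimuli(config: ExperimentConfig):
    out = []
    for sc in config.stimuli:
        out.append(StimulusSpec(
            target=sc.target_segment, side=sc.side, waveform=sc.waveform,
            amplitude=sc.amplitude_nA, frequency_hz=sc.frequency_Hz,
            phase=sc.phase_rad, electrode=sc.electrode,
            position=sc.position_um, field_direction=sc.field_direction))
    return out


def build_synapses(config: ExperimentConfig, base_dir: Path | None = None):
    out = []
    for sc in config.synapses:
        pre = sc.pre_segment
        if sc.kind == "external_spikes":
            if sc.pre_spike_file is not None:
                path = Path(sc.pre_spike_file)
                if base_dir is not None and not path.is_absolute():
                    path = base_dir / path
                pre = [float(line) for line in path.read_text().split()
                       if line.strip()]
            else:
                pre = sc.pre_spike_times_ms or []
        out.append(SynapseSpec(
            kind=sc.kind, pre=pre, post=sc.post_segment, g_max=sc.g_max_nS,
            e_syn=sc.e_syn_mV, tau_rise=sc.tau_rise_ms,
            tau_decay=sc.tau_decay_ms, threshold=sc.threshold_mV))
    return out


def solver_options(config: ExperimentConfig) -> SolverOptions:
    s = config.solver
    return SolverOptions(
        rel_tol=s.rel_tol, abs_tol=s.abs_tol_mV,
        dense_output_dt=s.dense_output_dt_ms, mode=s.mode,
        formulation=s.formulation, seed=config.seed, settle_time=s.settle_ms)


# ---------------------------------------------------------------------------
# result persistence
# ---------------------------------------------------------------------------

def _meta_json(result: SimulationResult) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o).__name__)

    return json.dumps(result.metadata, default=default)


def write_result(result: SimulationResult, path: str | Path) -> Path:
    """Persist a result; format chosen by extension (.h5/.hdf5 or .csv)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["metadata"] = _meta_json(result)
            f.create_dataset("times", data=result.times)
            f.create_dataset("vm", data=result.vm)
            f.create_dataset("vout", data=result.vout)
            f.create_dataset("currents", data=result.membrane_currents)
            gg = f.create_group("gating")
            for name, arr in result.gating.items():
                d = gg.create_dataset(name, data=arr)
                d.attrs["segments"] = result.gating_segments[name]
    elif path.suffix == ".csv":
        n = result.vm.shape[0]
        cols = (["time_ms"] + [f"vm_{i}" for i in range(n)]
                + [f"vout_{i}" for i in range(n)]
                + [f"im_{i}" for i in range(n)])
        data = np.vstack([result.times, result.vm, result.vout,
                          result.membrane_currents]).T
        header = (f"# ephapsim schema {SCHEMA_VERSION}\n"
                  f"# metadata {_meta_json(result)}\n" + ",".join(cols))
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.17g")
    else:
        raise FormatError(f"unknown result format {path.suffix!r}")
    return path


def read_result(path: str | Path) -> SimulationResult:
    """Load a persisted result; schema mismatches raise :class:`FormatError`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        try:
            with h5py.File(path, "r") as f:
                version = f.attrs.get("schema_version")
                if version != SCHEMA_VERSION:
                    raise FormatError(
                        f"result schema {version!r} != expected "
                        f"{SCHEMA_VERSION}")
                meta = json.loads(f.attrs["metadata"])
                gating = {}
                gseg = {}
                for name, d in f["gating"].items():
                    gating[name] = d[...]
                    gseg[name] = np.asarray(d.attrs["segments"])
                return SimulationResult(
                    times=f["times"][...], vm=f["vm"][...],
                    vout=f["vout"][...], gating=gating, gating_segments=gseg,
                    membrane_currents=f["currents"][...], metadata=meta)
        except OSError as exc:
            raise FormatError(f"unreadable or truncated result file "
                              f"{path}: {exc}") from exc
    if path.suffix == ".csv":
        with open(path) as fh:
            head = fh.readline()
            metaline = fh.readline()
        if not head.startswith(f"# ephapsim schema {SCHEMA_VERSION}"):
            raise FormatError(f"{path}: missing/incompatible schema header")
        meta = json.loads(metaline.removeprefix("# metadata "))
        data = np.loadtxt(path, delimiter=",", skiprows=3)
        data = np.atleast_2d(data)
        n = (data.shape[1] - 1) // 3
        return SimulationResult(
            times=data[:, 0], vm=data[:, 1:1 + n].T,
            vout=data[:, 1 + n:1 + 2 * n].T, gating={}, gating_segments={},
            membrane_currents=data[:, 1 + 2 * n:1 + 3 * n].T, metadata=meta)
    raise FormatError(f"unknown result format {path.suffix!r}")


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig,
                   base_dir: str | Path = ".") -> dict:
    """Build, solve (once per sigma in the sweep), analyze, persist.

    Returns a dict of artifact paths.  Identical config + seed give
    byte-identical numeric arrays (timestamps excluded).
    """
    t_start = time.time()
    base_dir = Path(base_dir)
    out_dir = base_dir / config.output.dir
    out_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(out_dir / "run.log")
    ext = ".h5" if config.output.format == "hdf5" else ".csv"

    artifacts: dict[str, str] = {}
    manifest: dict = {"config": config.model_dump(), "seed": config.seed,
                      "version": __version__, "stages": [], "partial": False}
    stage = "build"
    try:
        network = build_network(config)
        models = build_models(config)
        stimuli = build_stimuli(config)
        synapses = build_synapses(config, base_dir)
        opts = solver_options(config)
        manifest["geometry_hash"] = geometry_hash(network)
        _validate_references(network, models, stimuli, synapses)
        manifest["stages"].append(stage)

        results = []
        sigmas = config.medium.values()
        for sigma in sigmas:
            stage = f"solve sigma={sigma}"
            log.info("solving at sigma = %g S/m (%s)", sigma,
                     config.solver.mode)
            medium = ExtracellularMedium(sigma)
            system = assemble(network, models, stimuli, synapses, medium,
                              opts)
            x0 = None
            if config.solver.limit_cycle_init:
                rng = np.random.default_rng(config.seed)
                x0 = randomized_limit_cycle_init(system, rng,
                                                 config.solver.settle_ms)
            res = solve(system, (0.0, config.solver.t_stop_ms), x0)
            log.info("solver stats: %s", res.metadata["solver_stats"])
            path = out_dir / f"result_sigma_{sigma:g}{ext}"
            write_result(res, path)
            artifacts[f"result_sigma_{sigma:g}"] = str(path)
            results.append(res)
            manifest["stages"].append(stage)

        if config.analysis.enabled:
            stage = "analysis"
            a = config.analysis
            pairs, curves = bundle_locking_summary(
                results, sigmas=sigmas,
                seeds=[config.seed] * len(results),
                window=a.window_ms, bin_width=a.bin_width_ms,
                threshold=a.threshold_mV, refractory=a.refractory_ms)
            ppath = out_dir / "locking_pairs.csv"
            cpath = out_dir / "locking_curves.csv"
            pairs.to_csv(ppath, index=False)
            curves.to_csv(cpath, index=False)
            artifacts["locking_pairs"] = str(ppath)
            artifacts["locking_curves"] = str(cpath)
            manifest["stages"].append(stage)
    except Exception:
        log.exception("experiment failed at stage %r", stage)
        manifest["partial"] = True
        manifest["failed_stage"] = stage
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["wall_time_s"] = time.time() - t_start
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(mpath)
    return artifacts


def _validate_references(network, models, stimuli, synapses) -> None:
    n = network.n_segments
    tags = {s.model_tag for s in network.segments}
    missing = tags - set(models)
    if missing:
        raise NamingError(f"no model bound for tags {sorted(missing)}")
    for st in stimuli:
        if st.side == "intracellular" and not 0 <= st.target < n:
            raise ValidationError(f"stimulus target {st.target} out of range")
    for sy in synapses:
        if not 0 <= sy.post < n:
            raise ValidationError(f"synapse post {sy.post} out of range")
        if sy.kind in ("chemical", "gap") and not 0 <= sy.pre < n:
            raise ValidationError(f"synapse pre {sy.pre} out of range")
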