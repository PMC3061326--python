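"""File formats, result export, and the end-to-end pipeline.

Canonical interchange formats are plain ASCII matrices with small JSON
sidecars: a source-space file (one point per row ``x y z [ox oy oz]`` in cm,
with a ``# spacing=<cm>`` header), a lead-field matrix (channels x DOF,
whitespace separated, with a one-kind-per-row sidecar listing ``MAG`` or
``GRAD``), and a measurements matrix (channels x samples) with timing
metadata in JSON.  Results are exported as tabular CSV plus an STC binary
(big-endian: start time ms, sample period ms, vertex count, vertex ids,
sample count, then sample-major float32 data) whose first sample holds the
superposition of all estimated dipoles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import struct
import time as _time
from pathlib import Path

import numpy as np

from .clustering import ClusterSet, cluster_dipoles, cluster_summary, refit_waveform
from .estimation import FilterResult
from .filtering import FilterConfig, run_filter
from .forward import LeadField, SensorArray, SourceSpace, neighbor_matrix
from .simulate import Measurements, NoiseModel, estimate_noise_from_prestim

__all__ = [
    "RunConfig",
    "read_source_space",
    "write_source_space",
    "read_lead_field",
    "write_lead_field",
    "read_measurements",
    "write_measurements",
    "read_inputs",
    "export_stc",
    "read_stc",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Malformed or inconsistent input files; message carries the stage."""


# ---------------------------------------------------------------------------
# ASCII formats


def write_source_space(source_space: SourceSpace, path: str | Path) -> None:
    """One point per row ``x y z [ox oy oz]`` (cm), ``# spacing=`` header."""
    path = Path(path)
    cols = source_space.points
    if source_space.orientations is not None:
        cols = np.hstack([cols, source_space.orientations])
    header = f"spacing={source_space.spacing if source_space.spacing else 0}"
    np.savetxt(path, cols, fmt="%.10g", header=header)


def read_source_space(path: str | Path) -> SourceSpace:
    path = Path(path)
    spacing = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "spacing=" in first:
        spacing = float(first.split("spacing=")[1].strip())
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] not in (3, 6):
        raise InputError(
            f"source space: expected 3 or 6 columns, got {arr.shape[1]}"
        )
    ori = arr[:, 3:6] if arr.shape[1] == 6 else None
    return SourceSpace(points=arr[:, :3], orientations=ori, spacing=spacing)


def write_lead_field(lead_field: LeadField, path: str | Path, kinds=None) -> None:
    """ASCII matrix channels x DOF; channel kinds in a ``.kinds`` sidecar."""
    path = Path(path)
    np.savetxt(path, lead_field.matrix, fmt="%.10g")
    if kinds is not None:
        Path(str(path) + ".kinds").write_text("\n".join(map(str, kinds)) + "\n")


def read_lead_field(path: str | Path, dof_per_point: int = 3) -> tuple[LeadField, list[str] | None]:
    path = Path(path)
    mat = np.loadtxt(path, ndmin=2)
    kinds = None
    sidecar = Path(str(path) + ".kinds")
    if sidecar.exists():
        kinds = sidecar.read_text().split()
        if len(kinds) != mat.shape[0]:
            raise InputError(
                f"lead field: {mat.shape[0]} rows but {len(kinds)} channel kinds"
            )
    return LeadField(matrix=mat, dof_per_point=dof_per_point), kinds


def write_measurements(measurements: Measurements, path: str | Path) -> None:
    """ASCII matrix channels x samples plus a ``.json`` timing sidecar."""
    path = Path(path)
    np.savetxt(path, measurements.data, fmt="%.17g")
    meta = {
        "t0_ms": measurements.t0,
        "sfreq_hz": measurements.sfreq,
        "prestim_ms": list(measurements.prestim),
        "channel_mask": (
            None
            if measurements.channel_mask is None
            else np.asarray(measurements.channel_mask).tolist()
        ),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_measurements(path: str | Path) -> Measurements:
    path = Path(path)
    data = np.loadtxt(path, ndmin=2)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise InputError(f"measurements: missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    mask = meta.get("channel_mask")
    return Measurements(
        data=data,
        t0=float(meta["t0_ms"]),
        sfreq=float(meta["sfreq_hz"]),
        prestim=tuple(meta["prestim_ms"]),
        channel_mask=None if mask is None else np.asarray(mask),
    )


# ---------------------------------------------------------------------------
# run configuration and input validation


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs: paths, filter and cluster settings."""

    source_space_path: str | None = None
    lead_field_path: str | None = None
    measurements_path: str | None = None
    covariance_path: str | None = None
    projection_path: str | None = None
    simulate: str | None = None  # "table1" generates the built-in benchmark
    out_dir: str = "dipoletrack_out"
    n_particles: int = 10_000
    max_dipoles: int = 5
    discrepancy: float = 1.0
    p_birth: float = 1.0 / 15.0
    p_death: float = 1.0 / 15.0
    p_move: float = 0.5
    moment_prior_std: float = 30.0
    neighbor_radius: float = 1.0
    max_clusters: int = 10
    cluster_mode: str = "location"
    constrained: bool = False
    prestim: tuple[float, float] | None = None  # overrides the sidecar window
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat ``key = value`` (or ``key: value``) config file.

        Unknown keys are rejected; values are parsed as JSON scalars where
        possible, else kept as strings.
        """
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, _, val = line.partition(sep)
                    break
            else:
                raise InputError(f"config line {line_no}: expected 'key = value'")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise InputError(f"config line {line_no}: unknown key {key!r}")
            try:
                kwargs[key] = json.loads(val)
            except json.JSONDecodeError:
                kwargs[key] = val
        if "prestim" in kwargs and kwargs["prestim"] is not None:
            kwargs["prestim"] = tuple(kwargs["prestim"])
        return cls(**kwargs)

    def validate(self) -> None:
        if self.simulate is None:
            missing = [
                n
                for n in ("source_space_path", "lead_field_path", "measurements_path")
                if getattr(self, n) is None
            ]
            if missing:
                raise InputError(f"config: mandatory inputs missing: {missing}")
        if self.discrepancy <= 0:
            raise InputError("config: discrepancy must be > 0")
        if self.neighbor_radius <= 0:
            raise InputError("config: neighbor_radius must be > 0")
        if self.max_clusters < 1:
            raise InputError("config: max_clusters must be >= 1")
        if self.n_particles < 1:
            raise InputError("config: n_particles must be >= 1")


def read_inputs(
    config: RunConfig,
) -> tuple[SourceSpace, LeadField, Measurements, NoiseModel | None, np.ndarray | None]:
    """Load and cross-validate all input files."""
    config.validate()
    ss = read_source_space(config.source_space_path)
    dof = 1 if config.constrained else 3
    if config.constrained and ss.orientations is None:
        raise InputError("source space: constrained mode requires orientations")
    lf, _kinds = read_lead_field(config.lead_field_path, dof_per_point=dof)
    expected = dof * ss.n_points
    if lf.matrix.shape[1] != expected:
        raise InputError(
            f"lead field: {lf.matrix.shape[1]} columns but source space implies "
            f"{dof} x {ss.n_points} = {expected}"
        )
    meas = read_measurements(config.measurements_path)
    if meas.n_channels != lf.n_channels:
        raise InputError(
            f"measurements: {meas.n_channels} channels but lead field has "
            f"{lf.n_channels} rows"
        )
    noise = None
    if config.covariance_path is not None:
        cov = np.loadtxt(config.covariance_path, ndmin=2)
        if cov.shape != (meas.n_channels, meas.n_channels):
            raise InputError(
                f"covariance: shape {cov.shape} does not match "
                f"{meas.n_channels} channels"
            )
        noise = NoiseModel(
            mode="covariance", covariance=cov, discrepancy=config.discrepancy
        )
    proj = None
    if config.projection_path is not None:
        proj = np.loadtxt(config.projection_path, ndmin=2)
        if proj.shape != (meas.n_channels, meas.n_channels):
            raise InputError(f"projection: shape {proj.shape} does not match channels")
        if not np.allclose(proj @ proj, proj, atol=1e-6):
            raise InputError("projection: matrix is not idempotent (P @ P != P)")
    return ss, lf, meas, noise, proj


# ---------------------------------------------------------------------------
# STC export


def export_stc(
    result: FilterResult | list,
    source_space: SourceSpace,
    path: str | Path,
    tmin_ms: float | None = None,
    tstep_ms: float | None = None,
) -> None:
    """Write the estimated-dipole sequence as an STC binary file.

    Vertices are the grid indices that ever host an estimated dipole; each
    sample's vertex value is the amplitude (nA·m) of the dipole estimated
    there at that sample.  Following the export convention for quick
    inspection, the very first sample is overwritten with the superposition
    of all estimated dipoles (per-vertex maximum amplitude over time).
    """
    if isinstance(result, FilterResult):
        dipoles_per_sample = result.dipoles_per_sample
        times = result.times
    else:
        dipoles_per_sample = result
        times = np.arange(len(result), dtype=float)
    if tmin_ms is None:
        tmin_ms = float(times[0])
    if tstep_ms is None:
        tstep_ms = float(times[1] - times[0]) if len(times) > 1 else 1.0

    vertices = sorted({d.grid_index for dips in dipoles_per_sample for d in dips})
    vmap = {v: i for i, v in enumerate(vertices)}
    n_samples = len(dipoles_per_sample)
    data = np.zeros((n_samples, len(vertices)), dtype=">f4")
    for t, dips in enumerate(dipoles_per_sample):
        for d in dips:
            data[t, vmap[d.grid_index]] = d.amplitude
    if len(vertices):
        data[0] = data.max(axis=0)  # superposition of all estimated dipoles

    with open(path, "wb") as fh:
        fh.write(struct.pack(">f", tmin_ms))
        fh.write(struct.pack(">f", tstep_ms))
        fh.write(struct.pack(">I", len(vertices)))
        fh.write(np.asarray(vertices, dtype=">u4").tobytes())
        fh.write(struct.pack(">I", n_samples))
        fh.write(data.tobytes())


def read_stc(path: str | Path) -> dict:
    """Parse an STC file back into a dict (round-trip checking)."""
    raw = Path(path).read_bytes()
    tmin, tstep = struct.unpack(">ff", raw[:8])
    (n_vert,) = struct.unpack(">I", raw[8:12])
    off = 12
    vertices = np.frombuffer(raw, dtype=">u4", count=n_vert, offset=off)
    off += 4 * n_vert
    (n_samp,) = struct.unpack(">I", raw[off : off + 4])
    off += 4
    data = np.frombuffer(raw, dtype=">f4", count=n_samp * n_vert, offset=off)
    return {
        "tmin_ms": tmin,
        "tstep_ms": tstep,
        "vertices": vertices.astype(int),
        "data": data.reshape(n_samp, n_vert).astype(float),
    }


# ---------------------------------------------------------------------------
# the pipeline


def _write_results(
    out: Path,
    result: FilterResult,
    clusters: ClusterSet,
    source_space: SourceSpace,
    sensors: SensorArray | None,
    measurements: Measurements,
) -> None:
    import pandas as pd

    result.to_frame().to_csv(out / "dipoles.csv", index=False)
    post = pd.DataFrame(
        result.order_posterior,
        columns=[f"P{k}" for k in range(result.order_posterior.shape[1])],
    )
    post.insert(0, "time_ms", result.times)
    post.insert(1, "n_hat", result.n_hat)
    post.to_csv(out / "model_order.csv", index=False)

    rows = []
    waves = []
    for cid, c in enumerate(clusters.clusters):
        _, wave = cluster_summary(c, result.times)
        if sensors is not None:
            wave = refit_waveform(c, measurements.data, sensors)
        waves.append(wave)
        rows.append(
            {
                "cluster": cid,
                "x": c.mean_location[0],
                "y": c.mean_location[1],
                "z": c.mean_location[2],
                "n_members": c.n_members,
                "first_ms": c.times.min(),
                "last_ms": c.times.max(),
            }
        )
    pd.DataFrame(rows).to_csv(out / "clusters.csv", index=False)
    np.savetxt(out / "cluster_waveforms.txt", np.asarray(waves), fmt="%.8g")
    export_stc(result, source_space, out / "dipoles.stc")


def run_pipeline(config: RunConfig) -> dict:
    """End-to-end run: inputs -> filter -> estimation -> clustering -> disk.

    Returns a summary dict (paths, timings, cluster table) and writes
    ``dipoles.csv``, ``model_order.csv``, ``clusters.csv``,
    ``cluster_waveforms.txt``, ``dipoles.stc`` and ``run_log.json`` into the
    output directory.  Fully reproducible given (inputs, config, seed).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = _time.time()

    sensors = None
    if config.simulate is not None:
        if config.simulate != "table1":
            raise InputError(f"unknown simulation scenario {config.simulate!r}")
        from . import simulate as sim

        ss, sensors, lf = sim.benchmark_geometry()
        meas, _truth = sim.simulate_benchmark(seed=config.seed)
        noise = None
        proj = None
        timings["setup_s"] = _time.time() - t0
    else:
        ss, lf, meas, noise, proj = read_inputs(config)
        timings["setup_s"] = _time.time() - t0
    if config.prestim is not None:
        meas.prestim = tuple(config.prestim)

    t1 = _time.time()
    neighbor_matrix(ss, config.neighbor_radius)
    timings["neighbors_s"] = _time.time() - t1

    if noise is None:
        noise = estimate_noise_from_prestim(meas, discrepancy=config.discrepancy)
    noise.discrepancy = config.discrepancy

    fcfg = FilterConfig(
        n_particles=config.n_particles,
        max_dipoles=config.max_dipoles,
        discrepancy=config.discrepancy,
        p_birth=config.p_birth,
        p_death=config.p_death,
        p_move=config.p_move,
        moment_prior_std=config.moment_prior_std,
        seed=config.seed,
    )
    t2 = _time.time()
    result = run_filter(meas, lf, ss, noise, fcfg, projection=proj, progress=True)
    timings["filter_s"] = _time.time() - t2

    t3 = _time.time()
    tab = result.all_dipoles()
    if tab.shape[0] == 0:
        logger.warning("no dipoles estimated; skipping clustering")
        clusters = ClusterSet(clusters=[], mode=config.cluster_mode, labels=np.array([]))
    else:
        clusters = cluster_dipoles(
            tab[:, 1:7],
            max_clusters=config.max_clusters,
            mode=config.cluster_mode,
            times=tab[:, 0],
        )
    timings["cluster_s"] = _time.time() - t3

    _write_results(out, result, clusters, ss, sensors, meas)
    log = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_samples": int(meas.n_samples),
        "n_channels": int(meas.n_channels),
        "n_grid_points": int(ss.n_points),
        "noise_sigma": noise.sigma if noise.mode == "white" else None,
        "n_clusters": clusters.n_clusters,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return log
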