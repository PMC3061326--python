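"""Synthetic six-source MEG benchmark.

Generates evoked-style measurements from a known constellation of current
dipoles in the spherical head model: Gaussian-bump source waveforms, sensor
fields computed exactly at the (off-grid) true locations, additive white
Gaussian sensor noise, and the Frobenius-norm SNR statistic.  The default
constellation is the six-source benchmark (locations in head-frame cm, peak
latencies in ms, peak planar-gradiometer amplitudes in fT/cm):

    1 (red)      (-1.37, -5.43, 7.34)   20 ms    51 fT/cm
    2 (blue)     ( 3.74,  4.54, 5.66)   40 ms    57 fT/cm
    3 (green)    (-2.04,  3.73, 9.56)   40 ms   130 fT/cm
    4 (magenta)  ( 2.96,  2.11, 9.42)  110 ms   100 fT/cm
    5 (cyan)     (-3.43, -2.71, 4.07)  110 ms   110 fT/cm
    6 (yellow)   (-1.37, -5.43, 7.34)  220 ms    51 fT/cm

Sources 1 and 6 share a location (and hence a topography), sources 4 and 5
share the identical waveform (time-correlated), and sources 2 and 3 peak
together with different durations.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .forward import SensorArray, forward_gain, fibonacci_helmet

__all__ = [
    "SimSource",
    "Measurements",
    "NoiseModel",
    "GroundTruth",
    "BENCHMARK_SOURCES",
    "BENCH_SPHERE_CENTER",
    "BENCH_CONDUCTOR_RADIUS",
    "source_waveform",
    "simulate_benchmark",
    "snr_db",
    "estimate_noise_from_prestim",
    "benchmark_helmet",
]

#: Fitted-sphere center in the head frame (cm).
BENCH_SPHERE_CENTER = np.array([0.0, 0.0, 4.0])
#: Conductor sphere radius (cm).
BENCH_CONDUCTOR_RADIUS = 9.0


@dataclasses.dataclass
class SimSource:
    """One simulated dipolar source."""

    location: np.ndarray  # cm, head frame
    peak_latency: float  # ms
    duration_fwhm: float  # ms, full width at half maximum of the activation
    peak_sensor_amp: float  # fT/cm, max planar-gradiometer reading at peak
    color_label: str = ""

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, float)
        if self.peak_sensor_amp <= 0:
            raise ValueError("peak_sensor_amp must be positive")
        if self.duration_fwhm <= 0:
            raise ValueError("duration_fwhm must be positive")


# Waveform durations (FWHM, ms): sources 2 and 3 peak together but differ in
# duration (short vs long); 4 and 5 are the identical waveform; others 30 ms.
BENCHMARK_SOURCES: list[SimSource] = [
    SimSource([-1.37, -5.43, 7.34], 20.0, 30.0, 51.0, "red"),
    SimSource([3.74, 4.54, 5.66], 40.0, 20.0, 57.0, "blue"),
    SimSource([-2.04, 3.73, 9.56], 40.0, 50.0, 130.0, "green"),
    SimSource([2.96, 2.11, 9.42], 110.0, 30.0, 100.0, "magenta"),
    SimSource([-3.43, -2.71, 4.07], 110.0, 30.0, 110.0, "cyan"),
    SimSource([-1.37, -5.43, 7.34], 220.0, 30.0, 51.0, "yellow"),
]


@dataclasses.dataclass
class Measurements:
    """Sensor data block: channels x samples plus timing metadata."""

    data: np.ndarray  # (n_channels, n_samples)
    t0: float  # ms, time of the first sample
    sfreq: float  # Hz
    prestim: tuple[float, float] = (-100.0, 0.0)  # ms
    channel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        t_last = self.t0 + (self.data.shape[1] - 1) * 1000.0 / self.sfreq
        if not (self.t0 <= self.prestim[0] <= self.prestim[1] <= t_last):
            raise ValueError("prestimulus interval must lie within the data window")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + np.arange(self.data.shape[1]) * 1000.0 / self.sfreq

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class NoiseModel:
    """Sensor-noise description used for likelihood scaling and prewhitening.

    ``white`` mode carries a single per-channel standard deviation ``sigma``;
    ``covariance`` mode carries a full SPD channel covariance whose inverse
    square root prewhitens data and lead field.  ``discrepancy`` multiplies
    the noise estimate in the filter likelihood: values < 1 demand a tighter
    fit (more sources), values > 1 a looser fit (fewer, stabler sources).
    """

    mode: str = "white"
    sigma: float = 0.0
    covariance: np.ndarray | None = None
    discrepancy: float = 1.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("white", "covariance"):
            raise ValueError("mode must be 'white' or 'covariance'")
        if self.discrepancy <= 0:
            raise ValueError("discrepancy must be positive")
        if self.mode == "covariance":
            c = np.asarray(self.covariance, float)
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError("covariance must be symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError("covariance must be positive definite")
            self.covariance = c

    def whitener(self) -> np.ndarray:
        """Inverse matrix square root of the covariance (covariance mode)."""
        if self.mode != "covariance":
            raise ValueError("whitener is defined only in covariance mode")
        w, v = np.linalg.eigh(self.covariance)
        return (v / np.sqrt(w)) @ v.T


@dataclasses.dataclass
class GroundTruth:
    """True sources behind a simulation: locations, moments, waveforms."""

    locations: np.ndarray  # (n_sources, 3) cm
    moments: np.ndarray  # (n_sources, 3) nA·m at unit waveform amplitude
    waveforms: np.ndarray  # (n_sources, n_samples), unit peak
    peak_latencies: np.ndarray  # ms
    labels: list[str]

    def signal(self, gains: np.ndarray) -> np.ndarray:
        """Noiseless sensor data given per-source gain (C, n_sources, 3)."""
        per_source = np.einsum("csa,sa->cs", gains, self.moments)
        return per_source @ self.waveforms


def source_waveform(
    peak_latency: float, duration_fwhm: float, times: np.ndarray
) -> np.ndarray:
    """Gaussian activation with unit peak at the sample nearest ``peak_latency``.

    The full width at half maximum equals ``duration_fwhm`` (ms); the peak is
    normalized to exactly 1 at the nearest sampled time so peak-amplitude
    calibration is exact on the sampling grid.
    """
    if duration_fwhm <= 0:
        raise ValueError("duration_fwhm must be positive")
    times = np.asarray(times, float)
    sigma = duration_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t_peak = times[np.argmin(np.abs(times - peak_latency))]
    return np.exp(-0.5 * ((times - t_peak) / sigma) ** 2)


def benchmark_helmet() -> SensorArray:
    """The deterministic 102-location (306-channel) benchmark helmet."""
    return fibonacci_helmet(
        sphere_center=BENCH_SPHERE_CENTER,
        conductor_radius=BENCH_CONDUCTOR_RADIUS,
    )


def benchmark_geometry(spacing: float = 0.5, shell_fraction: float = 0.81):
    """Benchmark source grid, gradiometer array, and gradiometer lead field.

    The grid is a regular lattice on the ball of radius
    ``shell_fraction * conductor_radius`` around the fitted-sphere center,
    expressed in head-frame coordinates; at the default 0.5 cm spacing it has
    ~13,000 points.  Only the 204 planar gradiometers are kept, matching the
    benchmark's channel selection.

    Returns
    -------
    (SourceSpace, SensorArray, LeadField): neighbor lists are *not* computed
    here (radius is a user choice; see :func:`~dipoletrack.forward.neighbor_matrix`).
    """
    from .forward import LeadField, assemble_lead_field, build_source_grid

    grid = build_source_grid(BENCH_CONDUCTOR_RADIUS, spacing, shell_fraction)
    grid.points = grid.points + BENCH_SPHERE_CENTER
    helmet = benchmark_helmet()
    grad = np.flatnonzero(helmet.kinds == "GRAD")
    lf_full = assemble_lead_field(grid, helmet)
    lead_field = LeadField(lf_full.matrix[grad], dof_per_point=3)
    sensors = SensorArray(
        positions=helmet.positions[grad],
        kinds=helmet.kinds[grad],
        axes=helmet.axes[grad],
        baseline=helmet.baseline,
        sphere_center=helmet.sphere_center,
        conductor_radius=helmet.conductor_radius,
    )
    return grid, sensors, lead_field


def simulate_benchmark(
    sources: list[SimSource] | None = None,
    sensors: SensorArray | None = None,
    sigma: float = 3.0,
    seed: int | None = 0,
    t0: float = -100.0,
    t_end: float = 300.0,
    sfreq: float = 1000.0,
    gradiometers_only: bool = True,
) -> tuple[Measurements, GroundTruth]:
    """Simulate the evoked benchmark and return data plus ground truth.

    Each source gets a fixed tangential moment direction (drawn reproducibly
    from ``seed``; co-located sources share a direction so they share a
    topography) and a moment magnitude calibrated so that, with all other
    sources silent, its maximum absolute planar-gradiometer reading at its
    peak latency equals ``peak_sensor_amp``.  White Gaussian noise of standard
    deviation ``sigma`` (fT/cm) is then added to every channel and sample.
    """
    if sources is None:
        sources = BENCHMARK_SOURCES
    if sensors is None:
        sensors = benchmark_helmet()
    rng = np.random.default_rng(seed)

    center = sensors.sphere_center
    locs = np.array([s.location for s in sources])
    if sensors.conductor_radius is not None:
        from .forward import GeometryError

        if np.any(
            np.linalg.norm(locs - center, axis=1) >= sensors.conductor_radius
        ):
            raise GeometryError("source location outside the conductor sphere")

    times = np.arange(t0, t_end + 1e-9, 1000.0 / sfreq)
    grad_rows = np.flatnonzero(sensors.kinds == "GRAD")
    gains = forward_gain(locs, sensors)  # (C, n_src, 3)

    # fixed tangential unit directions, one per distinct location
    directions = np.zeros((len(sources), 3))
    seen: dict[tuple, np.ndarray] = {}
    for i, s in enumerate(sources):
        key = tuple(np.round(s.location, 6))
        if key not in seen:
            radial = (s.location - center) / np.linalg.norm(s.location - center)
            v = rng.standard_normal(3)
            v -= radial * (v @ radial)
            seen[key] = v / np.linalg.norm(v)
        directions[i] = seen[key]

    moments = np.zeros((len(sources), 3))
    waveforms = np.zeros((len(sources), times.size))
    for i, s in enumerate(sources):
        waveforms[i] = source_waveform(s.peak_latency, s.duration_fwhm, times)
        pattern = gains[grad_rows, i, :] @ directions[i]  # fT/cm per nA·m
        peak_reading = np.max(np.abs(pattern))
        moments[i] = directions[i] * (s.peak_sensor_amp / peak_reading)

    truth = GroundTruth(
        locations=locs,
        moments=moments,
        waveforms=waveforms,
        peak_latencies=np.array([s.peak_latency for s in sources]),
        labels=[s.color_label for s in sources],
    )
    clean = truth.signal(gains)
    noise = rng.standard_normal(clean.shape) * sigma
    data = clean + noise

    mask = grad_rows if gradiometers_only else np.arange(sensors.n_channels)
    meas = Measurements(
        data=data[mask],
        t0=t0,
        sfreq=sfreq,
        prestim=(t0, 0.0),
        channel_mask=mask,
    )
    meas.clean = clean[mask]  # noiseless component, for SNR diagnostics
    meas.noise = noise[mask]
    return meas, truth


def snr_db(signal_matrix: np.ndarray, noise_matrix: np.ndarray) -> float:
    """Frobenius-norm SNR in dB: ``10 log10(|D|^2 / |N|^2)``.

    A zero noise matrix yields ``inf`` (documented sentinel).
    """
    d2 = float(np.sum(np.asarray(signal_matrix, float) ** 2))
    n2 = float(np.sum(np.asarray(noise_matrix, float) ** 2))
    if d2 and not n2:
        return np.inf
    return 10.0 * np.log10(d2 / n2)


def estimate_noise_from_prestim(
    measurements: Measurements, mode: str = "white", discrepancy: float = 1.0
) -> NoiseModel:
    """Estimate the sensor-noise model from the prestimulus interval.

    White mode pools the per-channel variance over prestimulus samples and
    averages across channels into a single ``sigma``; covariance mode returns
    the empirical channel covariance (for prewhitening).
    """
    times = measurements.times
    sel = (times >= measurements.prestim[0]) & (times <= measurements.prestim[1])
    if sel.sum() < 2:
        raise ValueError("prestimulus interval too short to estimate noise")
    x = measurements.data[:, sel]
    x = x - x.mean(axis=1, keepdims=True)
    if mode == "white":
        var = np.mean(np.sum(x**2, axis=1) / (x.shape[1] - 1))
        return NoiseModel(
            mode="white",
            sigma=float(np.sqrt(var)),
            discrepancy=discrepancy,
            degenerate=bool(var == 0.0),
        )
    cov = (x @ x.T) / (x.shape[1] - 1)
    return NoiseModel(mode="covariance", covariance=cov, discrepancy=discrepancy)
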