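"""Random-finite-set particle filter for dynamical dipole estimation.

The hidden state at each time sample is a *finite set* of current dipoles —
its cardinality (0..N_max) and the grid location of each dipole are both
random.  The filter approximates the Bayesian filtering posterior with N_p
weighted set-valued particles and proceeds sample by sample:

1. weight each particle by the Gaussian marginal likelihood of the data
   given its dipole locations (moments integrated out under a zero-mean
   Gaussian prior), with the noise scale multiplied by the *discrepancy*
   parameter;
2. summarize the weighted cloud (model-order posterior, dipole estimates);
3. resample systematically, keeping N_p particles;
4. evolve each particle: dipoles die, jump to neighboring grid points, or are
   born at random grid locations.

Moments are not part of the particle state: the likelihood marginalizes
them analytically (Rao-Blackwellization) under a N(0, moment_prior_std^2)
prior, and their conditional ridge estimates are re-computed per particle
per sample, which keeps particles purely positional.
"""

from __future__ import annotations

import dataclasses
import logging
import time as _time

import numpy as np
from sklearn.base import BaseEstimator

from . import estimation
from .forward import LeadField, SourceSpace
from .simulate import Measurements, NoiseModel

__all__ = [
    "Dipole",
    "Particle",
    "ParticleSet",
    "FilterConfig",
    "RFSDipoleFilter",
    "initialize_particles",
    "fit_moments",
    "likelihood_weight",
    "resample",
    "evolve",
    "run_filter",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Dipole:
    """A single current dipole on the source grid."""

    grid_index: int
    moment: np.ndarray  # (3,) nA·m, or (1,) in constrained mode


@dataclasses.dataclass
class Particle:
    """One dipole configuration: a finite set of 0..N_max dipoles plus weight."""

    dipoles: list[Dipole]
    weight: float


@dataclasses.dataclass
class ParticleSet:
    """N_p weighted dipole configurations, stored as flat arrays.

    ``locs`` is (N_p, N_max) int, padded with -1 beyond each particle's
    ``counts``; ``moments`` holds the most recent per-dipole moment fits.
    """

    locs: np.ndarray
    counts: np.ndarray
    weights: np.ndarray
    moments: np.ndarray | None = None
    time_index: int = 0

    @property
    def n_particles(self) -> int:
        return self.locs.shape[0]

    @property
    def max_dipoles(self) -> int:
        return self.locs.shape[1]

    def to_particles(self) -> list[Particle]:
        """Materialize as a list of :class:`Particle` (for inspection/tests)."""
        out = []
        for i in range(self.n_particles):
            k = int(self.counts[i])
            dips = [
                Dipole(
                    int(self.locs[i, j]),
                    None if self.moments is None else self.moments[i, j].copy(),
                )
                for j in range(k)
            ]
            out.append(Particle(dips, float(self.weights[i])))
        return out

    def validate(self) -> None:
        """Check the structural invariants (used heavily by the test suite)."""
        assert abs(self.weights.sum() - 1.0) < 1e-9, "weights must sum to 1"
        for i in range(self.n_particles):
            k = int(self.counts[i])
            row = self.locs[i, :k]
            assert len(set(row.tolist())) == k, "duplicate grid index in particle"
            assert np.all(self.locs[i, k:] == -1)


@dataclasses.dataclass
class FilterConfig:
    """Run-time parameters of the particle filter.

    ``discrepancy`` multiplies the estimated noise standard deviation in the
    likelihood: < 1 demands a tighter fit (more sources, less stable), > 1 a
    looser fit (fewer, more stable sources).  ``p_birth``/``p_death``/
    ``p_move`` govern the per-sample random-set dynamics.
    """

    n_particles: int = 10_000
    max_dipoles: int = 5
    discrepancy: float = 1.0
    p_birth: float = 1.0 / 15.0
    p_death: float = 1.0 / 15.0
    p_move: float = 0.5
    moment_prior_std: float = 30.0  # nA·m
    resample_ess_frac: float | None = None  # None: resample every sample
    seed: int | None = 0

    def __post_init__(self) -> None:
        for name in ("p_birth", "p_death", "p_move"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_birth + self.p_death > 1.0 + 1e-12:
            raise ValueError("p_birth + p_death must not exceed 1")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.discrepancy <= 0:
            raise ValueError("discrepancy must be positive")


# ---------------------------------------------------------------------------
# initialization


def initialize_particles(
    config: FilterConfig,
    source_space: SourceSpace,
    rng: np.random.Generator | None = None,
) -> ParticleSet:
    """Draw the initial particle set from the prior.

    Dipole count uniform on {0..N_max}; locations uniform over the grid
    without replacement within a particle; moments zero; weights uniform.
    """
    if source_space.n_points == 0:
        raise ValueError("source space is empty")
    if config.max_dipoles > source_space.n_points:
        raise ValueError("max_dipoles exceeds the number of grid points")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_p, n_max, n_pts = config.n_particles, config.max_dipoles, source_space.n_points

    counts = rng.integers(0, n_max + 1, size=n_p)
    locs = np.full((n_p, max(n_max, 1)), -1, dtype=np.int64)
    if n_max > 0:
        draw = rng.integers(0, n_pts, size=(n_p, n_max))
        # redraw until each particle's active slots are distinct
        for _ in range(1000):
            bad = np.zeros(n_p, dtype=bool)
            for j in range(1, n_max):
                act = counts > j
                dup = (draw[:, j][:, None] == draw[:, :j]).any(axis=1)
                bad |= act & dup
            if not bad.any():
                break
            draw[bad] = rng.integers(0, n_pts, size=(int(bad.sum()), n_max))
        valid = np.arange(n_max)[None, :] < counts[:, None]
        locs[:, :n_max][valid] = draw[valid]
    weights = np.full(n_p, 1.0 / n_p)
    return ParticleSet(locs=locs, counts=counts.astype(np.int64), weights=weights)


# ---------------------------------------------------------------------------
# weighting


def fit_moments(
    locations: np.ndarray,
    data_column: np.ndarray,
    lead_field: LeadField,
    noise: NoiseModel,
    prior_std: float = 30.0,
    discrepancy: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge least-squares dipole moments for a set of grid locations.

    Solves ``(G'G + lam I) m = G'y`` with ``lam = (sigma_eff / prior_std)^2``
    for the stacked sub-lead-field of the given locations; returns
    (moments (k, dof), residual (n_channels,)).  Zero locations yield the
    data itself as residual.
    """
    locations = np.asarray(locations, dtype=np.int64)
    y = np.asarray(data_column, float)
    if locations.size == 0:
        return np.zeros((0, lead_field.dof_per_point)), y.copy()
    if len(set(locations.tolist())) != locations.size:
        raise ValueError("locations must be distinct")
    dof = lead_field.dof_per_point
    sigma_eff = _sigma_eff(noise, discrepancy)
    lam = (sigma_eff / prior_std) ** 2
    cols = (locations[:, None] * dof + np.arange(dof)[None, :]).ravel()
    a = lead_field.matrix[:, cols]
    gram = a.T @ a + lam * np.eye(a.shape[1])
    m = np.linalg.solve(gram, a.T @ y)
    residual = y - a @ m
    return m.reshape(-1, dof), residual


def _sigma_eff(noise: NoiseModel, discrepancy: float | None = None) -> float:
    d = noise.discrepancy if discrepancy is None else discrepancy
    sigma = 1.0 if noise.mode == "covariance" else noise.sigma
    s = d * sigma
    if s <= 0:
        raise ValueError("effective noise level is zero; cannot weight particles")
    return s


def likelihood_weight(
    particle: Particle,
    data_column: np.ndarray,
    lead_field: LeadField,
    noise: NoiseModel,
    prior_std: float = 30.0,
    marginal: bool = True,
) -> float:
    """Unnormalized Gaussian likelihood weight of a single particle.

    With ``marginal=True`` (the filter's default) the dipole moments are
    integrated out under their N(0, prior_std^2) prior, giving the Gaussian
    marginal ``N(y; 0, sigma_eff^2 I + prior_std^2 A A')`` up to a constant
    shared by all particles; the log-determinant term is the Occam factor
    that keeps the model order honest.  With ``marginal=False`` the weight is
    the plain residual Gaussian ``exp(-||r||^2 / (2 sigma_eff^2))`` at the
    ridge-fitted moments.  The empty particle's residual is the data itself.
    May underflow to 0 for poor fits — the filter itself works in log space.
    """
    locs = np.array([d.grid_index for d in particle.dipoles], dtype=np.int64)
    y = np.asarray(data_column, float)
    s = _sigma_eff(noise)
    lam = (s / prior_std) ** 2
    m, residual = fit_moments(locs, y, lead_field, noise, prior_std)
    if not marginal:
        return float(np.exp(-0.5 * np.sum(residual**2) / s**2))
    if locs.size == 0:
        return float(np.exp(-0.5 * (y @ y) / s**2))
    dof = lead_field.dof_per_point
    cols = (locs[:, None] * dof + np.arange(dof)[None, :]).ravel()
    a = lead_field.matrix[:, cols]
    gram = a.T @ a + lam * np.eye(a.shape[1])
    g = a.T @ y
    mvec = m.ravel()
    quad = (y @ y - g @ mvec) / s**2
    _, logdet = np.linalg.slogdet(gram)
    occam = logdet - a.shape[1] * np.log(lam)
    return float(np.exp(-0.5 * (quad + occam)))


def _batch_log_weights(
    locs: np.ndarray,
    counts: np.ndarray,
    y: np.ndarray,
    gmat: np.ndarray,
    dof: int,
    sigma_eff: float,
    lam: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log marginal likelihoods and fitted moments for every particle, batched.

    The likelihood is the Rao-Blackwellized Gaussian marginal
    ``N(y; 0, sigma_eff^2 I + prior_std^2 A A')`` (moments integrated out),
    evaluated up to a constant shared by all particles.  Particles sharing a
    dipole configuration are deduplicated; the small ridge systems
    (dof*k x dof*k) are solved with one batched call per cardinality.  Also
    canonicalizes each particle's dipole order (sorted by grid index) and
    returns (log_lik, locs_sorted, moments).
    """
    n_p, n_max = locs.shape
    logw = np.empty(n_p)
    moments = np.zeros((n_p, n_max if n_max else 1, dof))
    locs_sorted = locs.copy()
    y2 = float(y @ y)
    inv_2s2 = 0.5 / sigma_eff**2

    logw[counts == 0] = -y2 * inv_2s2
    for k in range(1, n_max + 1):
        rows = np.flatnonzero(counts == k)
        if rows.size == 0:
            continue
        cfg = np.sort(locs[rows, :k], axis=1)
        locs_sorted[rows, :k] = cfg
        uniq, inv = np.unique(cfg, axis=0, return_inverse=True)
        m = dof * k
        cols = (uniq[:, :, None] * dof + np.arange(dof)[None, None, :]).reshape(-1)
        a = gmat[:, cols].reshape(gmat.shape[0], len(uniq), m).transpose(1, 0, 2)
        at = a.transpose(0, 2, 1)
        gram = at @ a
        gram[:, np.arange(m), np.arange(m)] += lam
        g = at @ y  # (u, m)
        mom = np.linalg.solve(gram, g[..., None])[..., 0]
        # y' Sigma^{-1} y = (y'y - g' mom) / sigma^2   (Woodbury)
        quad = (y2 - np.einsum("um,um->u", mom, g)) * 2.0 * inv_2s2
        np.maximum(quad, 0.0, out=quad)
        _, logdet = np.linalg.slogdet(gram)
        occam = logdet - m * np.log(lam)
        ll = -0.5 * (quad + occam)
        logw[rows] = ll[inv]
        moments[rows, :k, :] = mom.reshape(len(uniq), k, dof)[inv]
    return logw, locs_sorted, moments


# ---------------------------------------------------------------------------
# resampling and evolution


def resample(
    particles: ParticleSet, rng: np.random.Generator | int | None = 0
) -> ParticleSet:
    """Systematic resampling: N_p survivors with uniform weights.

    Expected copy count of particle i is ``N_p * w_i``; with uniform input
    weights every particle is copied exactly once.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = _systematic_indices(particles.weights, rng)
    return ParticleSet(
        locs=particles.locs[idx].copy(),
        counts=particles.counts[idx].copy(),
        weights=np.full(particles.n_particles, 1.0 / particles.n_particles),
        moments=None if particles.moments is None else particles.moments[idx].copy(),
        time_index=particles.time_index,
    )


def _systematic_indices(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = np.asarray(weights, float)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate weights: cannot resample")
    n = w.size
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(w / total), positions, side="right").clip(0, n - 1)


def evolve(
    particles: ParticleSet,
    source_space: SourceSpace,
    config: FilterConfig,
    rng: np.random.Generator | int | None = 0,
) -> ParticleSet:
    """Random-set dynamics: per particle, independent death / move / birth.

    Each dipole dies with probability ``p_death``; each survivor, slot by
    slot, jumps with probability ``p_move`` to a uniformly chosen entry of
    its neighbor list (self included; a jump onto another dipole of the same
    particle is canceled); finally, if the particle is below ``max_dipoles``,
    a new dipole is born with probability ``p_birth`` at a uniform grid point
    (canceled if that point is already occupied).  Weights are unchanged.
    """
    if source_space.neighbor_lists is None:
        raise ValueError("source space has no neighbor lists; call neighbor_matrix first")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nbr_flat, nbr_ptr = _flatten_neighbors(source_space)
    locs = particles.locs.copy()
    counts = particles.counts.copy()
    n_p, n_max = locs.shape
    n_pts = source_space.n_points

    # deaths (then stable compaction of survivors)
    if config.p_death > 0 and n_max > 0:
        valid = np.arange(n_max)[None, :] < counts[:, None]
        die = (rng.random((n_p, n_max)) < config.p_death) & valid
        keep = valid & ~die
        order = np.argsort(~keep, axis=1, kind="stable")
        locs = np.take_along_axis(locs, order, axis=1)
        counts = keep.sum(axis=1)
        locs[np.arange(n_max)[None, :] >= counts[:, None]] = -1

    # moves, slot by slot
    if config.p_move > 0 and n_max > 0:
        for j in range(n_max):
            act = j < counts
            mv = act & (rng.random(n_p) < config.p_move)
            rows = np.flatnonzero(mv)
            if rows.size == 0:
                continue
            cur = locs[rows, j]
            deg = nbr_ptr[cur + 1] - nbr_ptr[cur]
            pick = (rng.random(rows.size) * deg).astype(np.int64)
            tgt = nbr_flat[nbr_ptr[cur] + pick]
            other = locs[rows]
            other_mask = np.arange(n_max)[None, :] != j
            dup = ((other == tgt[:, None]) & other_mask).any(axis=1)
            locs[rows, j] = np.where(dup, cur, tgt)

    # births
    if config.p_birth > 0 and n_max > 0:
        can = counts < n_max
        b = can & (rng.random(n_p) < config.p_birth)
        rows = np.flatnonzero(b)
        if rows.size:
            cand = rng.integers(0, n_pts, size=rows.size)
            dup = (locs[rows] == cand[:, None]).any(axis=1)
            ok = ~dup
            rows, cand = rows[ok], cand[ok]
            locs[rows, counts[rows]] = cand
            counts[rows] += 1

    return ParticleSet(
        locs=locs,
        counts=counts.astype(np.int64),
        weights=particles.weights.copy(),
        time_index=particles.time_index + 1,
    )


def _flatten_neighbors(source_space: SourceSpace) -> tuple[np.ndarray, np.ndarray]:
    cache = getattr(source_space, "_nbr_csr", None)
    if cache is not None:
        return cache
    lists = source_space.neighbor_lists
    ptr = np.zeros(len(lists) + 1, dtype=np.int64)
    ptr[1:] = np.cumsum([len(l) for l in lists])
    flat = np.concatenate(lists).astype(np.int64)
    source_space._nbr_csr = (flat, ptr)
    return flat, ptr


# ---------------------------------------------------------------------------
# the estimator


class RFSDipoleFilter(BaseEstimator):
    """Random-finite-set particle filter, scikit-learn estimator interface.

    Parameters
    ----------
    source_space : SourceSpace with neighbor lists.
    lead_field : LeadField matching the source space and the data channels.
    noise : NoiseModel (white sigma or full covariance) carrying the
        discrepancy multiplier; overridden by ``discrepancy`` if that is set.
    n_particles, max_dipoles, discrepancy, p_birth, p_death, p_move,
    moment_prior_std, resample_ess_frac : see :class:`FilterConfig`.
    random_state : seed for the single generator driving all randomness.

    After ``fit(X)`` (X of shape (n_times, n_channels)):

    Attributes
    ----------
    order_posterior_ : (n_times, max_dipoles + 1) model-order posterior.
    n_hat_ : (n_times,) posterior-mode dipole count per sample.
    dipoles_ : list (per sample) of :class:`~dipoletrack.estimation.DipoleEstimate`.
    result_ : the full :class:`~dipoletrack.estimation.FilterResult`.
    """

    def __init__(
        self,
        source_space: SourceSpace | None = None,
        lead_field: LeadField | None = None,
        noise: NoiseModel | None = None,
        n_particles: int = 10_000,
        max_dipoles: int = 5,
        discrepancy: float | None = None,
        p_birth: float = 1.0 / 15.0,
        p_death: float = 1.0 / 15.0,
        p_move: float = 0.5,
        moment_prior_std: float = 30.0,
        resample_ess_frac: float | None = None,
        projection: np.ndarray | None = None,
        random_state: int | None = 0,
        progress: bool = False,
    ) -> None:
        self.source_space = source_space
        self.lead_field = lead_field
        self.noise = noise
        self.n_particles = n_particles
        self.max_dipoles = max_dipoles
        self.discrepancy = discrepancy
        self.p_birth = p_birth
        self.p_death = p_death
        self.p_move = p_move
        self.moment_prior_std = moment_prior_std
        self.resample_ess_frac = resample_ess_frac
        self.projection = projection
        self.random_state = random_state
        self.progress = progress

    def _config(self) -> FilterConfig:
        d = self.discrepancy
        if d is None:
            d = self.noise.discrepancy if self.noise is not None else 1.0
        return FilterConfig(
            n_particles=self.n_particles,
            max_dipoles=self.max_dipoles,
            discrepancy=d,
            p_birth=self.p_birth,
            p_death=self.p_death,
            p_move=self.p_move,
            moment_prior_std=self.moment_prior_std,
            resample_ess_frac=self.resample_ess_frac,
            seed=self.random_state,
        )

    def fit(self, X: np.ndarray, y: None = None, times: np.ndarray | None = None):
        """Run the filter over a (n_times, n_channels) measurement array."""
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_times, n_channels)")
        if np.isnan(X).any():
            raise ValueError("X contains NaN")
        if self.source_space is None or self.lead_field is None or self.noise is None:
            raise ValueError("source_space, lead_field and noise are required")
        data = X.T  # channels x samples internally
        gmat = self.lead_field.matrix
        if data.shape[0] != gmat.shape[0]:
            raise ValueError(
                f"channel mismatch: data has {data.shape[0]} channels, "
                f"lead field {gmat.shape[0]} rows"
            )
        if self.source_space.neighbor_lists is None:
            raise ValueError("source space needs neighbor lists (neighbor_matrix)")
        cfg = self._config()
        noise = self.noise
        if noise.mode == "covariance":
            w = noise.whitener()
            data = w @ data
            gmat = w @ gmat
        if self.projection is not None:
            p = np.asarray(self.projection, float)
            data = p @ data
            gmat = p @ gmat
        if times is None:
            times = np.arange(data.shape[1], dtype=float)

        result = _run_filter_arrays(
            data, times, gmat, self.lead_field.dof_per_point,
            self.source_space, noise, cfg, progress=self.progress,
        )
        self.result_ = result
        self.order_posterior_ = result.order_posterior
        self.n_hat_ = result.n_hat
        self.dipoles_ = result.dipoles_per_sample
        self.times_ = result.times
        return self

    def transform(self, X: np.ndarray | None = None) -> np.ndarray:
        """Return the fitted model-order posterior (n_times, max_dipoles+1)."""
        return self.order_posterior_


def _run_filter_arrays(
    data: np.ndarray,
    times: np.ndarray,
    gmat: np.ndarray,
    dof: int,
    source_space: SourceSpace,
    noise: NoiseModel,
    config: FilterConfig,
    progress: bool = False,
) -> "estimation.FilterResult":
    rng = np.random.default_rng(config.seed)
    sigma_eff = _sigma_eff(noise, config.discrepancy)
    lam = (sigma_eff / config.moment_prior_std) ** 2
    n_samples = data.shape[1]
    n_max = config.max_dipoles

    pset = initialize_particles(config, source_space, rng)
    posteriors = np.zeros((n_samples, n_max + 1))
    n_hats = np.zeros(n_samples, dtype=int)
    dipoles_per_sample: list[list] = []
    ess = np.zeros(n_samples)
    log_prev = np.zeros(config.n_particles)  # log of carried weights (uniform)
    t_start = _time.time()

    for t in range(n_samples):
        loglik, locs_sorted, moments = _batch_log_weights(
            pset.locs, pset.counts, data[:, t], gmat, dof, sigma_eff, lam
        )
        logw = log_prev + loglik
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        pset = ParticleSet(
            locs=locs_sorted, counts=pset.counts, weights=w,
            moments=moments, time_index=t,
        )
        ess[t] = 1.0 / np.sum(w**2)

        post = estimation.model_order_posterior(pset, n_max)
        n_hat = estimation.estimate_n_hat(post)
        dips = (
            estimation.conditional_dipole_estimates(pset, n_hat, source_space)
            if n_hat > 0
            else []
        )
        posteriors[t] = post
        n_hats[t] = n_hat
        dipoles_per_sample.append(dips)

        do_resample = (
            config.resample_ess_frac is None
            or ess[t] < config.resample_ess_frac * config.n_particles
        )
        if do_resample:
            pset = resample(pset, rng)
            log_prev = np.zeros(config.n_particles)
        else:
            log_prev = np.log(pset.weights * config.n_particles)
        pset = evolve(pset, source_space, config, rng)

        if progress and (t % 50 == 0 or t == n_samples - 1):
            logger.info(
                "sample %d/%d  t=%.0f ms  N_hat=%d  ESS=%.0f  (%.1f s elapsed)",
                t + 1, n_samples, times[t], n_hat, ess[t], _time.time() - t_start,
            )

    return estimation.FilterResult(
        times=np.asarray(times, float),
        order_posterior=posteriors,
        n_hat=n_hats,
        dipoles_per_sample=dipoles_per_sample,
        ess=ess,
    )


def run_filter(
    measurements: Measurements,
    lead_field: LeadField,
    source_space: SourceSpace,
    noise: NoiseModel,
    config: FilterConfig | None = None,
    projection: np.ndarray | None = None,
    progress: bool = False,
) -> "estimation.FilterResult":
    """Functional front end: run the filter over a :class:`Measurements` block."""
    if config is None:
        config = FilterConfig()
    est = RFSDipoleFilter(
        source_space=source_space,
        lead_field=lead_field,
        noise=noise,
        n_particles=config.n_particles,
        max_dipoles=config.max_dipoles,
        discrepancy=config.discrepancy,
        p_birth=config.p_birth,
        p_death=config.p_death,
        p_move=config.p_move,
        moment_prior_std=config.moment_prior_std,
        resample_ess_frac=config.resample_ess_frac,
        projection=projection,
        random_state=config.seed,
        progress=progress,
    )
    est.fit(measurements.data.T, times=measurements.times)
    return est.result_
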