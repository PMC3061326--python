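"""Particle filter: initialization, weighting, resampling, evolution, runs."""

import numpy as np
import pytest
from scipy.stats import chi2

from dipoletrack.filtering import (
    FilterConfig,
    ParticleSet,
    RFSDipoleFilter,
    _batch_log_weights,
    evolve,
    fit_moments,
    initialize_particles,
    likelihood_weight,
    resample,
    run_filter,
)
from dipoletrack.forward import LeadField, SourceSpace, neighbor_matrix
from dipoletrack.simulate import Measurements, NoiseModel

from _oracles import enumerate_transitions


@pytest.fixture
def noise():
    return NoiseModel(sigma=3.0, discrepancy=1.0)


class TestInitialization:
    def test_nmax_zero_gives_all_empty(self, small_grid):
        cfg = FilterConfig(n_particles=50, max_dipoles=0, seed=0)
        ps = initialize_particles(cfg, small_grid)
        assert np.all(ps.counts == 0)
        assert np.allclose(ps.weights, 1.0 / 50)

    def test_same_seed_is_bit_identical(self, small_grid):
        cfg = FilterConfig(n_particles=500, max_dipoles=4, seed=11)
        a = initialize_particles(cfg, small_grid)
        b = initialize_particles(cfg, small_grid)
        assert np.array_equal(a.locs, b.locs)
        assert np.array_equal(a.counts, b.counts)

    def test_count_distribution_uniform_chi_square(self, small_grid):
        """Dipole counts over 1e5 particles uniform on {0..N_max} (99% band)."""
        n_max = 4
        cfg = FilterConfig(n_particles=100_000, max_dipoles=n_max, seed=3)
        ps = initialize_particles(cfg, small_grid)
        obs = np.bincount(ps.counts, minlength=n_max + 1)
        expected = cfg.n_particles / (n_max + 1)
        stat = np.sum((obs - expected) ** 2 / expected)
        assert stat < chi2.ppf(0.99, df=n_max)

    def test_no_duplicate_locations_within_particle(self, small_grid):
        cfg = FilterConfig(n_particles=2000, max_dipoles=5, seed=1)
        initialize_particles(cfg, small_grid).validate()

    def test_nmax_exceeding_grid_rejected(self):
        ss = SourceSpace(points=[[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            initialize_particles(FilterConfig(n_particles=5, max_dipoles=3), ss)


class TestFitMoments:
    def test_exact_recovery_in_flat_prior_limit(self, small_grid, small_lead_field, noise):
        """Noiseless single-dipole data: tangential moment recovered exactly.

        The radial moment component is externally silent in the sphere model,
        so only the tangential projection is observable.
        """
        rng = np.random.default_rng(0)
        locs = np.array([40])
        m_true = rng.normal(size=3) * 10
        p = small_grid.points[40]
        rhat = p / np.linalg.norm(p)
        m_tang = m_true - rhat * (m_true @ rhat)
        y = small_lead_field.matrix[:, 120:123] @ m_true
        m, r = fit_moments(locs, y, small_lead_field, noise, prior_std=1e9)
        m_fit = m.ravel()
        m_fit_tang = m_fit - rhat * (m_fit @ rhat)
        assert np.allclose(m_fit_tang, m_tang, rtol=1e-5, atol=1e-6)
        assert np.linalg.norm(r) < 1e-6 * np.linalg.norm(y)

    def test_zero_data_gives_zero_moments(self, small_lead_field, noise):
        m, r = fit_moments(
            np.array([3, 77]), np.zeros(small_lead_field.n_channels),
            small_lead_field, noise,
        )
        assert np.allclose(m, 0.0) and np.allclose(r, 0.0)

    def test_two_dipoles_match_normal_equations_oracle(self, small_lead_field, noise):
        rng = np.random.default_rng(4)
        locs = np.array([10, 300])
        y = rng.normal(size=small_lead_field.n_channels) * 20
        prior_std = 30.0
        m, r = fit_moments(locs, y, small_lead_field, noise, prior_std=prior_std)
        cols = np.concatenate([np.arange(3 * l, 3 * l + 3) for l in locs])
        a = small_lead_field.matrix[:, cols]
        lam = (noise.discrepancy * noise.sigma / prior_std) ** 2
        oracle = np.linalg.inv(a.T @ a + lam * np.eye(6)) @ (a.T @ y)
        assert np.allclose(m.ravel(), oracle, rtol=1e-9)
        assert np.allclose(r, y - a @ oracle, rtol=1e-9)

    def test_duplicate_locations_rejected(self, small_lead_field, noise):
        with pytest.raises(ValueError):
            fit_moments(np.array([5, 5]), np.zeros(small_lead_field.n_channels),
                        small_lead_field, noise)


class TestLikelihoodWeight:
    def test_perfect_fit_residual_weight_is_one(self, small_lead_field, noise):
        from dipoletrack.filtering import Dipole, Particle

        m_true = np.array([5.0, -3.0, 8.0])
        y = small_lead_field.matrix[:, 30:33] @ m_true
        p = Particle([Dipole(10, None)], 1.0)
        w = likelihood_weight(p, y, small_lead_field, noise, prior_std=1e9,
                              marginal=False)
        assert w == pytest.approx(1.0, abs=1e-9)

    def test_larger_discrepancy_increases_residual_weight(self, small_lead_field):
        from dipoletrack.filtering import Particle

        y = np.ones(small_lead_field.n_channels)
        p_empty = Particle([], 1.0)
        w1 = likelihood_weight(p_empty, y, small_lead_field,
                               NoiseModel(sigma=3.0, discrepancy=1.0), marginal=False)
        w2 = likelihood_weight(p_empty, y, small_lead_field,
                               NoiseModel(sigma=3.0, discrepancy=2.0), marginal=False)
        assert w2 > w1

    def test_log_weight_matches_quadratic_form_oracle(self, small_lead_field, noise):
        """Marginal log-weight = -1/2 y' Sigma^-1 y - 1/2 log|Sigma| + const."""
        from dipoletrack.filtering import Dipole, Particle

        rng = np.random.default_rng(8)
        y = rng.normal(size=small_lead_field.n_channels) * 5
        locs = [20, 131]
        prior_std = 30.0
        p = Particle([Dipole(l, None) for l in locs], 1.0)
        w = likelihood_weight(p, y, small_lead_field, noise, prior_std=prior_std)

        s = noise.sigma * noise.discrepancy
        cols = np.concatenate([np.arange(3 * l, 3 * l + 3) for l in locs])
        a = small_lead_field.matrix[:, cols]
        cov = s**2 * np.eye(a.shape[0]) + prior_std**2 * (a @ a.T)
        quad = y @ np.linalg.inv(cov) @ y
        _, logdet = np.linalg.slogdet(cov)
        base = logdet - a.shape[0] * np.log(s**2)  # shared constant removed
        oracle = np.exp(-0.5 * (quad + base))
        assert np.log(w) == pytest.approx(np.log(oracle), abs=1e-8)

    def test_batch_weights_agree_with_single_particle_path(
        self, small_grid, small_lead_field, noise
    ):
        from dipoletrack.filtering import Dipole, Particle

        cfg = FilterConfig(n_particles=64, max_dipoles=3, seed=5)
        ps = initialize_particles(cfg, small_grid)
        rng = np.random.default_rng(9)
        y = rng.normal(size=small_lead_field.n_channels)  # modest scale: no underflow
        logw, locs_sorted, _ = _batch_log_weights(
            ps.locs, ps.counts, y, small_lead_field.matrix, 3, 3.0, (3.0 / 30.0) ** 2
        )
        for i in range(0, 64, 7):
            p = Particle([Dipole(int(l), None) for l in ps.locs[i, : ps.counts[i]]], 1.0)
            w = likelihood_weight(p, y, small_lead_field, noise, prior_std=30.0)
            assert logw[i] == pytest.approx(np.log(w), abs=1e-7)

    def test_zero_effective_noise_rejected(self, small_lead_field):
        from dipoletrack.filtering import Particle

        with pytest.raises(ValueError):
            likelihood_weight(Particle([], 1.0), np.zeros(small_lead_field.n_channels),
                              small_lead_field, NoiseModel(sigma=0.0))


class TestResample:
    def _pset(self, weights):
        n = len(weights)
        return ParticleSet(
            locs=np.arange(n, dtype=np.int64)[:, None],
            counts=np.ones(n, dtype=np.int64),
            weights=np.asarray(weights, float),
        )

    def test_degenerate_point_mass_copies_winner(self):
        w = np.zeros(10)
        w[4] = 1.0
        out = resample(self._pset(w), 0)
        assert np.all(out.locs[:, 0] == 4)
        assert np.allclose(out.weights, 0.1)

    def test_uniform_weights_identity_multiset(self):
        out = resample(self._pset(np.full(8, 1 / 8)), 123)
        assert sorted(out.locs[:, 0].tolist()) == list(range(8))

    def test_copy_counts_match_expectation(self):
        """Systematic resampling: E[copies of i] = N_p w_i (binomial bounds)."""
        rng = np.random.default_rng(42)
        w = np.array([0.5, 0.3, 0.15, 0.05])
        n_p, trials = 4, 10_000
        tot = np.zeros(4)
        ps = self._pset(w)
        for t in range(trials):
            out = resample(ps, np.random.default_rng(t))
            tot += np.bincount(out.locs[:, 0], minlength=4)
        mean = tot / trials
        # systematic: copies in {floor, ceil} of N_p w_i, mean = N_p w_i
        assert np.allclose(mean, n_p * w, atol=0.05)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            resample(self._pset(np.zeros(5)), 0)


class TestEvolve:
    def test_zero_probabilities_is_identity(self, small_grid):
        cfg = FilterConfig(n_particles=200, max_dipoles=3, p_birth=0, p_death=0,
                           p_move=0, seed=2)
        ps = initialize_particles(cfg, small_grid)
        out = evolve(ps, small_grid, cfg, 7)
        assert np.array_equal(out.locs, ps.locs)
        assert np.array_equal(out.counts, ps.counts)

    def test_certain_death_empties_everything(self, small_grid):
        cfg = FilterConfig(n_particles=100, max_dipoles=3, p_death=1.0, p_birth=0,
                           seed=2)
        ps = initialize_particles(cfg, small_grid)
        out = evolve(ps, small_grid, cfg, 7)
        assert np.all(out.counts == 0)
        assert np.all(out.locs == -1)

    def test_invariants_preserved(self, small_grid):
        cfg = FilterConfig(n_particles=1000, max_dipoles=5, seed=3)
        ps = initialize_particles(cfg, small_grid)
        rng = np.random.default_rng(0)
        for _ in range(10):
            ps = evolve(ps, small_grid, cfg, rng)
            ps.validate()

    def test_count_chain_matches_transition_matrix_oracle(self):
        """Empirical dipole-count chain on 3 points vs exact enumeration."""
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        ss = SourceSpace(points=pts)
        neighbor_matrix(ss, 1.0)
        cfg = FilterConfig(
            n_particles=40_000, max_dipoles=2, p_birth=0.2, p_death=0.25,
            p_move=0.5, seed=6,
        )
        ps = initialize_particles(cfg, ss)

        # exact: enumerate the ordered-state kernel, fold to the count chain
        import itertools

        states = [()]
        states += [(i,) for i in range(3)]
        states += list(itertools.permutations(range(3), 2))
        idx = {s: i for i, s in enumerate(states)}
        trans = np.zeros((len(states), len(states)))
        for s in states:
            for s2, p in enumerate_transitions(
                s, ss.neighbor_lists, 3, 2, cfg.p_birth, cfg.p_death, cfg.p_move
            ).items():
                trans[idx[s], idx[s2]] += p
        assert np.allclose(trans.sum(axis=1), 1.0, atol=1e-12)
        # exact state distribution after 5 steps from the uniform-count prior
        dist = np.zeros(len(states))
        for s in states:
            k = len(s)
            n_tuples = [1, 3, 6][k]
            dist[idx[s]] = (1 / 3) / n_tuples
        for _ in range(5):
            dist = trans.T @ dist
        exact_counts = np.zeros(3)
        for s, i in idx.items():
            exact_counts[len(s)] += dist[i]

        rng = np.random.default_rng(77)
        for _ in range(5):
            ps = evolve(ps, ss, cfg, rng)
        emp = np.bincount(ps.counts, minlength=3) / cfg.n_particles
        assert np.allclose(emp, exact_counts, atol=0.01)


class TestRunFilter:
    def test_zero_data_high_noise_selects_empty_model(self, small_grid, small_lead_field):
        data = np.zeros((small_lead_field.n_channels, 30))
        meas = Measurements(data, t0=0.0, sfreq=1000.0, prestim=(0.0, 5.0))
        cfg = FilterConfig(n_particles=300, max_dipoles=3, seed=0)
        res = run_filter(meas, small_lead_field, small_grid,
                         NoiseModel(sigma=10.0), cfg)
        assert np.all(res.n_hat == 0)
        assert np.allclose(res.order_posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_reproducible_given_seed(self, small_grid, small_lead_field):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(small_lead_field.n_channels, 12)) * 3
        meas = Measurements(data, t0=0.0, sfreq=1000.0, prestim=(0.0, 5.0))
        cfg = FilterConfig(n_particles=200, max_dipoles=2, seed=9)
        nm = NoiseModel(sigma=3.0)
        r1 = run_filter(meas, small_lead_field, small_grid, nm, cfg)
        r2 = run_filter(meas, small_lead_field, small_grid, nm, cfg)
        assert np.array_equal(r1.order_posterior, r2.order_posterior)
        assert np.array_equal(r1.all_dipoles(), r2.all_dipoles())

    def test_nan_data_rejected(self, small_grid, small_lead_field):
        est = RFSDipoleFilter(source_space=small_grid, lead_field=small_lead_field,
                              noise=NoiseModel(sigma=3.0), n_particles=10)
        x = np.zeros((5, small_lead_field.n_channels))
        x[2, 3] = np.nan
        with pytest.raises(ValueError):
            est.fit(x)

    def test_channel_mismatch_rejected(self, small_grid, small_lead_field):
        est = RFSDipoleFilter(source_space=small_grid, lead_field=small_lead_field,
                              noise=NoiseModel(sigma=3.0), n_particles=10)
        with pytest.raises(ValueError):
            est.fit(np.zeros((5, small_lead_field.n_channels + 1)))

    def test_estimator_follows_sklearn_protocol(self, small_grid, small_lead_field):
        est = RFSDipoleFilter(source_space=small_grid, lead_field=small_lead_field,
                              noise=NoiseModel(sigma=3.0), n_particles=50,
                              max_dipoles=2, random_state=0)
        params = est.get_params()
        assert params["n_particles"] == 50
        est.set_params(n_particles=80)
        assert est.n_particles == 80
        x = np.zeros((8, small_lead_field.n_channels))
        est.fit(x)
        assert est.order_posterior_.shape == (8, 3)
        assert est.transform().shape == (8, 3)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p_birth=1.2),
            dict(p_death=-0.1),
            dict(p_birth=0.6, p_death=0.6),
            dict(n_particles=0),
            dict(discrepancy=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FilterConfig(**kwargs)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(
    st.integers(0, 10_000),
    st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_systematic_copy_counts_within_one_of_expectation(seed, raw_weights):
    """Systematic resampling: every copy count is floor or ceil of N w_i."""
    w = np.asarray(raw_weights)
    w = w / w.sum()
    n = w.size
    ps = ParticleSet(
        locs=np.arange(n, dtype=np.int64)[:, None],
        counts=np.ones(n, dtype=np.int64),
        weights=w,
    )
    out = resample(ps, np.random.default_rng(seed))
    counts = np.bincount(out.locs[:, 0], minlength=n)
    assert np.all(counts >= np.floor(n * w)) and np.all(counts <= np.ceil(n * w))
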