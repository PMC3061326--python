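# Methods

This note documents the models, estimators, parameters and numerical choices
behind `dipoletrack`, and what the synthetic benchmark does and does not
establish about real data.

## State-space model

The hidden state at sample *t* is a finite set of current dipoles
X_t = {(r₁,q₁),…,(r_k,q_k)}, 0 ≤ k ≤ N_max. Locations live on a discretized
source space (grid points with a precomputed lead field); moments are
3-vectors in nA·m (or scalars along a fixed orientation in constrained
mode). Measurements are y_t = Σᵢ G(rᵢ) qᵢ + ε_t with Gaussian sensor noise.
Two noise modes exist: *white* (a single per-channel standard deviation σ̂
pooled from the prestimulus interval) and *covariance* (an empirical or
user-supplied SPD channel covariance; data and lead field are prewhitened by
its inverse matrix square root, after which the white machinery applies with
σ = 1). An optional signal-space projection matrix, validated as idempotent,
is applied to data and lead field before filtering.

### Dynamics

Between samples, each particle evolves independently:

* each dipole is deleted with probability `p_death` (default 1/15);
* each survivor, slot by slot, jumps with probability `p_move` (default 1/2)
  to a uniformly chosen entry of its neighbor list — all grid points within
  the user's neighbor radius (default 1 cm), self included; a jump onto
  another dipole of the same particle is canceled;
* if the particle holds fewer than `N_max` (default 5) dipoles, a new dipole
  is born with probability `p_birth` (default 1/15) at a uniform grid point
  (canceled if occupied).

These rates are not physical constants; they set the filter's agility. The
defaults let the dipole-count birth/death chain mix within a few tens of
samples, and all are exposed in `FilterConfig`.

### Likelihood and the discrepancy parameter

Particle weights use the Gaussian *marginal* likelihood of the dipole
locations, with moments integrated out analytically under a zero-mean
Gaussian prior of standard deviation τ = `moment_prior_std`:

    p(y | r₁..r_k) = N(y; 0, σ_eff² I + τ² A Aᵀ),   A = [G(r₁) … G(r_k)]

evaluated per particle, up to a constant shared by all particles, as
−½[(‖y‖² − gᵀm)/σ_eff² + log det(AᵀA + λI) − (3k) log λ], where
λ = (σ_eff/τ)², g = Aᵀy and m = (AᵀA + λI)⁻¹g is simultaneously the ridge
(MAP) moment estimate reported for that particle. The log-determinant term
is the Occam factor: an extra dipole must reduce the residual by more than
its evidence cost, which is what keeps the model-order posterior at zero on
pure noise. A pure residual weight exp(−‖r‖²/2σ_eff²) is retained as an
option (`likelihood_weight(..., marginal=False)`) but is not used by the
filter: it has no Occam factor, and with it the posterior mode escalates to
N_max on any data.

σ_eff = discrepancy × σ̂. Discrepancy < 1 demands a tighter fit (more
sources, less stability); > 1 a looser fit (fewer, stabler sources). Both
the likelihood scale and the ridge λ use σ_eff, so the discrepancy acts
consistently on fit and shrinkage.

`moment_prior_std` defaults to 30 nA·m. The prior must cover the moments the
data can plausibly contain; the built-in benchmark's calibrated moments span
7–97 nA·m (deep sources need large moments to reach the stated sensor
amplitudes), and 30 nA·m places that range within ~3σ. A much tighter prior
(e.g. 10 nA·m) weakens the Occam factor for deep grid points to the point
that noise is explained by deep dipoles at discrepancy < 1.

### Filtering loop

Bootstrap filter with systematic resampling every sample (an
effective-sample-size threshold `resample_ess_frac` is available, default
off). Estimation (step 2) happens on the weighted cloud *before*
resampling. All randomness flows from one `numpy` generator seeded by
`FilterConfig.seed`, with a fixed call order (initialization; then per
sample: resampling offset, death draws, per-slot move draws and neighbor
picks, birth draws and birth locations), so runs are bit-reproducible.
Particles sharing a location set are deduplicated before weighting and the
small ridge systems are solved in one batched call per cardinality; a
10,000-particle, 401-sample benchmark run takes ~20 s on one CPU.

## Per-sample estimates

* Model-order posterior: P(k) = summed weight of particles with k dipoles.
* N̂_t = posterior mode, ties toward the smaller k.
* Conditional estimates: particles with exactly N̂_t dipoles are pooled;
  their dipoles are partitioned by weighted k-means on location
  (k = N̂_t, deterministically initialized from the highest-weight
  particle). Each group reports its weighted-mean location — snapped to the
  nearest grid point, with the raw mean kept — and weighted-mean moment;
  amplitude is the moment norm. Restricting to particles with exactly N̂_t
  dipoles (rather than pooling all particles) keeps the estimator
  conditional on the selected model order.

## Clustering into stable sources

All per-sample dipole estimates, time-stamped, are partitioned by a
deterministic k-medoids scheme (greedy farthest-first seeding, Voronoi
iteration) under either the location metric (Euclidean, cm) or
location + orientation: d = ‖Δr‖ + λ_o (1 − |cos θ|), with λ_o = 1 cm per
unit and the |·| making the metric polarity-invariant (dipole polarity flips
with response phase). Starting from the user's maximum cluster count, the
count is reduced by one and the partition recomputed until every cluster
pair is *significantly different*: center distance strictly greater than
`separation_factor` (default 2) times the pooled within-cluster RMS spread.
This center-vs-spread test is the package's concrete reading of
"significantly different"; it is parameter-free per cluster and monotone in
separation. Termination is guaranteed (k strictly decreases toward 1).

Each cluster reports the unweighted mean of member locations, a
discontinuous waveform (member amplitudes at their samples; co-occurring
members sum), and a continuous waveform obtained by re-fitting a full moment
vector at the frozen mean location against the data at every sample
(`refit_waveform`), which requires the forward model.

## The forward model

Single-sphere conductor with the standard closed-form dipole solution: the
external field depends only on the sphere center; radial dipoles are
externally silent. Sensors: 102 triple-sensor locations on a Fibonacci
lattice over a spherical cap (radius 10.5 cm, cap half-angle 110°), each
with one radial magnetometer and two orthogonal planar gradiometers
(symmetric finite difference of the radial field over a 1.68 cm baseline;
fT/cm). The benchmark uses only the 204 gradiometers. The conductor sphere
(radius 9 cm) is centered at (0, 0, 4) cm in the head frame — the
conventional fitted-sphere offset — so that all benchmark sources lie 4.4 to
7.0 cm from the center; the volumetric grid is the regular lattice on the
ball of radius 0.81 × 9 cm ≈ 7.3 cm, giving 13,037 points at the default
0.5 cm spacing. The closed-form field is validated in the test suite against
an independent Biot–Savart + Geselowitz surface-integral construction.

## The synthetic benchmark

Six dipolar sources with fixed head-frame locations, peak latencies
(20/40/40/110/110/220 ms) and peak planar-gradiometer amplitudes
(51/57/130/100/110/51 fT/cm). Waveforms are unit-peak Gaussian bumps; the
two sources peaking together at 40 ms get FWHM 20 and 50 ms (short vs long),
all others 30 ms; the two 110 ms sources share the identical waveform
(fully time-correlated); the first and last source share a location (and
hence, by construction, a moment direction and topography). Moment
directions are tangential unit vectors drawn once per distinct location from
the seed; magnitudes are calibrated so each source's isolated peak
gradiometer reading equals its stated amplitude. White Gaussian noise of
σ = 3 fT/cm is added per channel and sample over −100…300 ms at 1 kHz
(401 samples). The Frobenius-norm SNR statistic 10·log₁₀(‖D‖²/‖N‖²) is
computed over the full noiseless-signal and noise matrices; the per-sample
reading is not meaningful here (at 10 dB it would require the 204-channel
norm to barely exceed the largest single channel). Because the only
unspecified ingredient is the orientation draw, the acceptance script
reports the SNR averaged over ten draws (~10.5 dB; individual draws span
roughly 9.9–11.9 dB).

What the generator emulates: evoked, trial-averaged data with focal,
transient, possibly co-located and time-correlated sources, white sensor
noise, and off-grid true locations (the sources deliberately do not lie on
the inverse grid). What it does not emulate: colored/neural background
noise, unaveraged trials, head movement, realistic (BEM/FEM) conductor
geometry, or the true proprietary sensor layout. Tests passing on this
benchmark therefore demonstrate correct and well-calibrated inference under
the stated model, not robustness to physiological noise — on real data the
discrepancy parameter typically needs to be raised above 1 to suppress
spurious activity.

## Numerical and design choices

* Ridge systems are solved by batched dense `solve`; `slogdet` on the same
  (dof·k)² matrices supplies the Occam term. λ > 0 guarantees solvability
  even for coincident-column location sets.
* The single-point lead field has rank 2 (radial silence): moment estimates
  carry an unobservable radial null component that the ridge shrinks to
  ~zero; amplitudes are effectively tangential.
* Separation test boundary: centers at exactly c × spread count as *not*
  different (strict inequality with a 1e-9 relative guard).
* Estimated locations are snapped to the nearest grid point (consistent with
  the discretized model); the unsnapped mean is stored alongside.
* STC export writes big-endian (start ms, step ms, vertex count, vertex ids,
  sample count, sample-major float32 amplitudes in nA·m); the first sample
  is overwritten with the per-vertex maximum over time as an all-time
  superposition for quick inspection.
* Degenerate inputs: zero prestimulus variance flags the noise model
  degenerate and weighting refuses a zero σ_eff; empty dipole tables skip
  clustering; all-zero particle weights raise rather than resample.

## Problem sizes used in the test suite

Unit tests run on a ~500-point 1 cm grid. The acceptance tests run the full
0.5 cm benchmark geometry with 2,000 particles across 5 seeds and 3
discrepancy values, plus a single 10,000-particle reference run; the
exhaustive-enumeration filter comparisons use 2–3 grid points where every
dipole-set state can be enumerated. These sizes keep the default suite at a
few minutes while exercising the full pipeline end to end; the
10,000-particle configuration matches the benchmark's headline setting.

## Known limitations

* Model order is bounded by N_max; simultaneous source counts beyond it are
  not representable.
* The marginal likelihood makes the filter highly sensitive: any source
  whose captured signal energy exceeds the log-determinant cost is detected,
  so the weak benchmark sources are recovered even at discrepancy 2 and
  detection onsets are early. Implementations of this method that explore
  moments by random walk instead of marginalizing them have a higher
  effective detection threshold and may miss the weakest sources.
* No backward smoothing; estimates at time t use data up to t only.
* Localization uncertainty (posterior spread per source) is computed
  nowhere; only point estimates and the model-order posterior are reported.
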