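"""Independent oracles used by the test suite.

Everything here is deliberately implemented from first principles, by routes
different from the package's own code paths: a Biot–Savart / Geselowitz
surface-integral construction of the conductor-sphere dipole field, and an
exhaustive-enumeration Bayesian (hidden-Markov) filter for tiny source
spaces.
"""

from __future__ import annotations

import itertools

import numpy as np

MU0_4PI = 1e-7


def primary_dipole_field(r0_m: np.ndarray, q_am: np.ndarray, r_m: np.ndarray) -> np.ndarray:
    """Magnetic field (T) of the primary current dipole alone (Biot–Savart)."""
    a = r_m - r0_m
    d = np.linalg.norm(a, axis=-1, keepdims=True)
    return MU0_4PI * np.cross(q_am, a) / d**3


def _legendre_pn_pn1(x: np.ndarray, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n^1(x) (without Condon-Shortley phase) for n=0..n_max."""
    x = np.asarray(x, float)
    p = np.zeros((n_max + 1,) + x.shape)
    p[0] = 1.0
    if n_max >= 1:
        p[1] = x
    for n in range(1, n_max):
        p[n + 1] = ((2 * n + 1) * x * p[n] - n * p[n - 1]) / (n + 1)
    # P_n^1 = sqrt(1-x^2) dP_n/dx ;  (1-x^2) P_n' = n (P_{n-1} - x P_n)
    s = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    p1 = np.zeros_like(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        for n in range(1, n_max + 1):
            p1[n] = np.where(s > 1e-12, n * (p[n - 1] - x * p[n]) / np.where(s > 1e-12, s, 1.0), 0.0)
    return p, p1


def surface_potential_sphere(
    r0_m: np.ndarray,
    q_am: np.ndarray,
    surf_dirs: np.ndarray,
    radius_m: float,
    sigma: float = 1.0,
    n_terms: int = 80,
) -> np.ndarray:
    """Electric potential on a homogeneous conductor sphere's surface.

    Classical Legendre expansion for a current dipole at ``r0_m`` inside a
    sphere of the given radius; ``surf_dirs`` are unit vectors to surface
    points.  Axis frame: z' along the dipole's radial position (arbitrary for
    a central dipole).
    """
    f = np.linalg.norm(r0_m)
    if f < 1e-15:
        # dipole at the center: only the n=1 (uniform) mode survives
        return 3.0 * (surf_dirs @ q_am) / (4.0 * np.pi * sigma * radius_m**2)
    zhat = r0_m / f
    q_r = float(q_am @ zhat)
    q_t_vec = q_am - q_r * zhat
    q_t = np.linalg.norm(q_t_vec)
    xhat = q_t_vec / q_t if q_t > 1e-15 * np.linalg.norm(q_am) else _any_perp(zhat)
    yhat = np.cross(zhat, xhat)

    cos_a = surf_dirs @ zhat
    sin_a_cos_b = surf_dirs @ xhat
    sin_a = np.sqrt(np.clip(1 - cos_a**2, 0.0, None))
    cos_b = np.where(sin_a > 1e-12, sin_a_cos_b / np.where(sin_a > 1e-12, sin_a, 1.0), 0.0)

    p, p1 = _legendre_pn_pn1(cos_a, n_terms)
    v = np.zeros(surf_dirs.shape[0])
    ratio = f / radius_m
    for n in range(1, n_terms + 1):
        coef = (2 * n + 1) / n * ratio ** (n - 1)
        v += coef * (n * q_r * p[n] + q_t * cos_b * p1[n])
    return v / (4.0 * np.pi * sigma * radius_m**2)


def _any_perp(u: np.ndarray) -> np.ndarray:
    v = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = v - u * (v @ u)
    return v / np.linalg.norm(v)


def sphere_dipole_field_oracle(
    location_cm: np.ndarray,
    moment_nam: np.ndarray,
    sensor_cm: np.ndarray,
    radius_cm: float = 9.0,
    n_theta: int = 200,
    n_phi: int = 400,
    n_terms: int = 80,
) -> np.ndarray:
    """Total external field (fT) of a dipole in a homogeneous conductor sphere.

    Primary Biot–Savart term plus the volume-current contribution reduced to
    a Geselowitz surface integral of the (series-expanded) surface potential.
    Entirely independent of the closed-form solution under test.
    """
    r0 = np.asarray(location_cm, float) * 1e-2
    q = np.asarray(moment_nam, float) * 1e-9
    r = np.asarray(sensor_cm, float) * 1e-2
    radius = radius_cm * 1e-2
    sigma = 1.0  # cancels against the 1/sigma in V

    # Gauss-Legendre in cos(theta), trapezoid in phi
    x_gl, w_gl = np.polynomial.legendre.leggauss(n_theta)
    phi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    ct, ph = np.meshgrid(x_gl, phi, indexing="ij")
    st = np.sqrt(1.0 - ct**2)
    dirs = np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=-1).reshape(-1, 3)
    w = (np.outer(w_gl, np.full(n_phi, 2.0 * np.pi / n_phi)) * radius**2).reshape(-1)

    v = surface_potential_sphere(r0, q, dirs, radius, sigma, n_terms)
    rp = dirs * radius
    diff = r[None, :] - rp
    d3 = np.linalg.norm(diff, axis=1, keepdims=True) ** 3
    integrand = np.cross(dirs, diff / d3)  # n_hat x grad'(1/d)
    b_surf = -MU0_4PI * sigma * np.sum((v * w)[:, None] * integrand, axis=0)
    b = primary_dipole_field(r0, q, r) + b_surf
    return b * 1e15


# ---------------------------------------------------------------------------
# exhaustive Bayesian filter on a tiny source space


def enumerate_transitions(
    state: tuple[int, ...],
    neighbor_lists: list[np.ndarray],
    n_points: int,
    n_max: int,
    p_birth: float,
    p_death: float,
    p_move: float,
) -> dict[tuple[int, ...], float]:
    """Exact transition distribution of the random-set dynamics.

    Mirrors the generative semantics: each dipole dies independently with
    ``p_death`` (survivor order preserved); then, slot by slot, each survivor
    moves with ``p_move`` to a uniform entry of its neighbor list (a move
    onto another current dipole is canceled); finally a birth is attempted
    with ``p_birth`` if below ``n_max``, at a uniform grid point (canceled if
    occupied).  States are ordered tuples of grid indices.
    """
    out: dict[tuple[int, ...], float] = {}
    k = len(state)
    for death_mask in itertools.product([False, True], repeat=k):
        p_d = 1.0
        for dies in death_mask:
            p_d *= p_death if dies else (1.0 - p_death)
        survivors = tuple(s for s, dies in zip(state, death_mask) if not dies)
        for moved, p_m in _enumerate_moves(survivors, neighbor_lists, p_move):
            for final, p_b in _enumerate_birth(moved, n_points, n_max, p_birth):
                out[final] = out.get(final, 0.0) + p_d * p_m * p_b
    return out


def _enumerate_moves(state, neighbor_lists, p_move):
    results = [(tuple(state), 1.0)]
    for j in range(len(state)):
        nxt = []
        for cur, prob in results:
            cur = list(cur)
            loc = cur[j]
            nbrs = neighbor_lists[loc]
            # no move
            nxt.append((tuple(cur), prob * (1.0 - p_move)))
            for tgt in nbrs:
                others = [c for jj, c in enumerate(cur) if jj != j]
                newloc = loc if tgt in others else int(tgt)
                c2 = list(cur)
                c2[j] = newloc
                nxt.append((tuple(c2), prob * p_move / len(nbrs)))
        # merge duplicates
        merged: dict[tuple, float] = {}
        for s, p in nxt:
            merged[s] = merged.get(s, 0.0) + p
        results = list(merged.items())
    return results


def _enumerate_birth(state, n_points, n_max, p_birth):
    out = [(tuple(state), 1.0 - p_birth if len(state) < n_max else 1.0)]
    if len(state) < n_max and p_birth > 0:
        for cand in range(n_points):
            if cand in state:
                out.append((tuple(state), p_birth / n_points))
            else:
                out.append((tuple(state) + (cand,), p_birth / n_points))
    merged: dict[tuple, float] = {}
    for s, p in out:
        merged[s] = merged.get(s, 0.0) + p
    return list(merged.items())


def exhaustive_filter(
    data: np.ndarray,
    gmat: np.ndarray,
    neighbor_lists: list[np.ndarray],
    n_points: int,
    n_max: int,
    sigma_eff: float,
    prior_std: float,
    p_birth: float,
    p_death: float,
    p_move: float,
) -> tuple[list[dict[tuple[int, ...], float]], np.ndarray]:
    """Exact forward (hidden-Markov) filter over ordered dipole-set states.

    Emission: the same Gaussian marginal likelihood the particle filter
    targets, but computed here with an explicit matrix inverse and
    determinant.  Returns per-sample posteriors over ordered states and the
    model-order posterior matrix.
    """
    states: list[tuple[int, ...]] = []
    for k in range(n_max + 1):
        states.extend(itertools.permutations(range(n_points), k))
    s_index = {s: i for i, s in enumerate(states)}
    n_states = len(states)

    # initial prior: count uniform on 0..n_max, ordered tuples uniform per count
    prior = np.zeros(n_states)
    for s in states:
        k = len(s)
        n_tuples = 1.0
        for j in range(k):
            n_tuples *= n_points - j
        prior[s_index[s]] = (1.0 / (n_max + 1)) / n_tuples

    trans = np.zeros((n_states, n_states))
    for s in states:
        for s2, p in enumerate_transitions(
            s, neighbor_lists, n_points, n_max, p_birth, p_death, p_move
        ).items():
            trans[s_index[s], s_index[s2]] += p

    lam = (sigma_eff / prior_std) ** 2
    loglik = np.zeros((n_states, data.shape[1]))
    for i, s in enumerate(states):
        if len(s) == 0:
            loglik[i] = -0.5 * np.sum(data**2, axis=0) / sigma_eff**2
            continue
        cols = np.concatenate([np.arange(3 * p_, 3 * p_ + 3) for p_ in s])
        a = gmat[:, cols]
        m = a.shape[1]
        cov = sigma_eff**2 * np.eye(a.shape[0]) + prior_std**2 * (a @ a.T)
        cov_inv = np.linalg.inv(cov)
        _, logdet = np.linalg.slogdet(cov)
        # constant offset vs the empty state: subtract C log sigma^2
        base = logdet - a.shape[0] * np.log(sigma_eff**2)
        quad = np.einsum("ct,cd,dt->t", data, cov_inv, data)
        loglik[i] = -0.5 * quad - 0.5 * base

    posteriors = []
    order_post = np.zeros((data.shape[1], n_max + 1))
    belief = prior.copy()
    for t in range(data.shape[1]):
        logw = np.log(np.maximum(belief, 1e-300)) + loglik[:, t]
        logw -= logw.max()
        post = np.exp(logw)
        post /= post.sum()
        posteriors.append({s: post[i] for i, s in enumerate(states)})
        for i, s in enumerate(states):
            order_post[t, len(s)] += post[i]
        belief = trans.T @ post
    return posteriors, order_post
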