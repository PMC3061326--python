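"""Per-sample estimates from the weighted particle cloud.

At every time sample the filter produces a weighted set of dipole
configurations.  This module turns that cloud into (1) the model-order
posterior P(k dipoles | data up to t), (2) the point estimate N̂_t = posterior
mode, and (3) conditional location/moment estimates for the N̂_t dipoles,
obtained by pooling the dipoles of all particles with exactly N̂_t dipoles and
partitioning them with weighted k-means.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .forward import SourceSpace

__all__ = [
    "DipoleEstimate",
    "FilterResult",
    "model_order_posterior",
    "estimate_n_hat",
    "conditional_dipole_estimates",
]


@dataclasses.dataclass
class DipoleEstimate:
    """One estimated dipole at one time sample."""

    grid_index: int
    location: np.ndarray  # cm, snapped to the nearest grid point
    location_raw: np.ndarray  # cm, unsnapped weighted mean
    moment: np.ndarray  # nA·m (3,) or (1,) in constrained mode
    amplitude: float  # nA·m, Euclidean norm of the moment


@dataclasses.dataclass
class FilterResult:
    """Full output of a filter run."""

    times: np.ndarray  # ms
    order_posterior: np.ndarray  # (n_samples, max_dipoles + 1)
    n_hat: np.ndarray  # (n_samples,)
    dipoles_per_sample: list[list[DipoleEstimate]]
    ess: np.ndarray | None = None  # effective sample size per sample

    def all_dipoles(self) -> "np.ndarray":
        """Stacked (time_ms, x, y, z, qx, qy, qz, amplitude) rows."""
        rows = []
        for t, dips in zip(self.times, self.dipoles_per_sample):
            for d in dips:
                q = np.zeros(3)
                q[: d.moment.size] = d.moment
                rows.append([t, *d.location, *q, d.amplitude])
        return np.asarray(rows).reshape(-1, 8)

    def to_frame(self):
        """The stacked dipole table as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            self.all_dipoles(),
            columns=["time_ms", "x", "y", "z", "qx", "qy", "qz", "amplitude"],
        )


def model_order_posterior(particles, max_dipoles: int | None = None) -> np.ndarray:
    """P(k) = total weight of particles with exactly k dipoles."""
    counts = particles.counts
    weights = particles.weights
    if max_dipoles is None:
        max_dipoles = particles.max_dipoles
    post = np.bincount(counts, weights=weights, minlength=max_dipoles + 1)
    return post / post.sum()


def estimate_n_hat(posterior: np.ndarray) -> int:
    """Mode of the model-order posterior; ties break toward the smaller count."""
    return int(np.argmax(posterior))


def _grid_tree(source_space: SourceSpace) -> cKDTree:
    tree = getattr(source_space, "_kdtree", None)
    if tree is None:
        tree = cKDTree(source_space.points)
        source_space._kdtree = tree
    return tree


def conditional_dipole_estimates(
    particles, n_hat: int, source_space: SourceSpace
) -> list[DipoleEstimate]:
    """Location/moment estimates for the N̂_t dipoles.

    Pools the dipoles of all particles holding exactly ``n_hat`` dipoles and
    partitions the pooled, weighted cloud into ``n_hat`` groups by weighted
    k-means on location, deterministically initialized from the
    highest-weight particle.  Each group yields a weighted-mean location
    (snapped to the nearest grid point) and a weighted-mean moment.
    """
    if n_hat < 1:
        raise ValueError("n_hat must be >= 1")
    rows = np.flatnonzero(particles.counts == n_hat)
    if rows.size == 0:
        raise ValueError(f"no particle holds exactly {n_hat} dipoles")
    locs_idx = particles.locs[rows, :n_hat]  # (n, n_hat)
    w = particles.weights[rows]
    if particles.moments is not None:
        moms = particles.moments[rows, :n_hat, :]
    else:
        moms = np.zeros((rows.size, n_hat, 3))

    pts = source_space.points[locs_idx.ravel()]  # (n * n_hat, 3)
    pw = np.repeat(w, n_hat)
    pm = moms.reshape(rows.size * n_hat, -1)
    pidx = locs_idx.ravel()

    if n_hat == 1:
        labels = np.zeros(pts.shape[0], dtype=int)
    else:
        init = source_space.points[locs_idx[np.argmax(w)]]
        km = KMeans(n_clusters=n_hat, init=init, n_init=1, max_iter=100, random_state=0)
        labels = km.fit_predict(pts, sample_weight=pw)

    tree = _grid_tree(source_space)
    out: list[DipoleEstimate] = []
    for g in range(n_hat):
        sel = labels == g
        if not sel.any():  # k-means dropped a cluster: fall back to init point
            sel = np.zeros_like(sel)
            sel[np.argmax(pw)] = True
        wg = pw[sel]
        wsum = wg.sum()
        loc_raw = (pts[sel] * wg[:, None]).sum(axis=0) / wsum
        mom = (pm[sel] * wg[:, None]).sum(axis=0) / wsum
        _, gi = tree.query(loc_raw)
        out.append(
            DipoleEstimate(
                grid_index=int(gi),
                location=source_space.points[int(gi)].copy(),
                location_raw=loc_raw,
                moment=mom,
                amplitude=float(np.linalg.norm(mom)),
            )
        )
    # deterministic output order: by grid index
    out.sort(key=lambda d: d.grid_index)
    return out
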