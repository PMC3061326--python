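"""Binding per-sample dipoles into stable neural sources.

The filter estimates dipoles independently at every time sample; dipoles at
different samples that represent the same neural source must be bound
together.  This module partitions the time-stamped dipole collection with a
deterministic k-medoids scheme — either on location alone or on location plus
orientation — and reduces the cluster count recursively, starting from the
user's maximum, until every pair of clusters is significantly separated
(center distance exceeding ``separation_factor`` times the pooled
within-cluster RMS spread).  Each cluster is summarized by the unweighted
mean location of its members and an amplitude waveform: the discontinuous
member-amplitude trace, or a continuous trace obtained by re-fitting the
moment at the frozen mean location against the data at every sample.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .forward import SensorArray, forward_gain

__all__ = [
    "Cluster",
    "ClusterSet",
    "DipoleClusterer",
    "cluster_dipoles",
    "clusters_significantly_different",
    "cluster_summary",
    "refit_waveform",
]


@dataclasses.dataclass
class Cluster:
    """One bound neural source."""

    member_index: np.ndarray  # indices into the input dipole table
    times: np.ndarray  # ms, one per member
    locations: np.ndarray  # (n_members, 3) cm
    moments: np.ndarray  # (n_members, 3) nA·m
    amplitudes: np.ndarray  # (n_members,) nA·m
    mean_location: np.ndarray  # (3,) cm
    mean_orientation: np.ndarray | None = None

    @property
    def n_members(self) -> int:
        return self.member_index.size


@dataclasses.dataclass
class ClusterSet:
    """Partition of all per-sample dipoles into clusters."""

    clusters: list[Cluster]
    mode: str
    labels: np.ndarray  # (n_dipoles,) cluster id per input dipole

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _orientations(moments: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(moments, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return moments / n


def _pair_dist(
    loc_a: np.ndarray,
    loc_b: np.ndarray,
    ori_a: np.ndarray | None = None,
    ori_b: np.ndarray | None = None,
    orientation_weight: float = 1.0,
) -> np.ndarray:
    """Metric between dipoles: Euclidean location distance, plus, in
    location+orientation mode, ``orientation_weight * (1 - |cos angle|)``
    (cm-equivalents; sign-invariant, as dipole polarity flips with phase)."""
    d = np.linalg.norm(loc_a[:, None, :] - loc_b[None, :, :], axis=-1)
    if ori_a is not None:
        cos = np.abs(np.einsum("ik,jk->ij", ori_a, ori_b))
        d = d + orientation_weight * (1.0 - np.clip(cos, 0.0, 1.0))
    return d


def _kmedoids(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids (Voronoi iteration) on a distance matrix.

    Seeding: first medoid minimizes total distance; the rest are added
    greedily farthest-first.  Returns integer labels.
    """
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        dmin = dist[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(dmin)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new = medoids.copy()
        for g in range(k):
            sel = np.flatnonzero(labels == g)
            if sel.size == 0:
                continue
            within = dist[np.ix_(sel, sel)].sum(axis=1)
            new[g] = sel[np.argmin(within)]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return np.argmin(dist[:, medoids], axis=1)


def clusters_significantly_different(
    cluster_a: Cluster,
    cluster_b: Cluster,
    mode: str = "location",
    separation_factor: float = 2.0,
    orientation_weight: float = 1.0,
) -> bool:
    """True iff the two cluster centers are separated by strictly more than
    ``separation_factor`` times the pooled within-cluster RMS spread (under
    the mode's metric)."""
    da = np.linalg.norm(cluster_a.mean_location - cluster_b.mean_location)
    if mode == "location_orientation":
        oa, ob = cluster_a.mean_orientation, cluster_b.mean_orientation
        if oa is not None and ob is not None:
            cos = abs(float(oa @ ob))
            da = da + orientation_weight * (1.0 - min(cos, 1.0))
    spread2 = []
    for c in (cluster_a, cluster_b):
        d = np.linalg.norm(c.locations - c.mean_location, axis=1)
        if mode == "location_orientation" and c.mean_orientation is not None:
            ori = _orientations(c.moments)
            cos = np.abs(ori @ c.mean_orientation)
            d = d + orientation_weight * (1.0 - np.clip(cos, 0.0, 1.0))
        spread2.append(d**2)
    pooled = np.sqrt(np.concatenate(spread2).mean())
    # strict inequality; the relative guard keeps the exact boundary case
    # (centers at precisely c x spread) on the "not different" side
    return bool(da > separation_factor * pooled * (1.0 + 1e-9))


def _principal_orientation(moments: np.ndarray) -> np.ndarray:
    """Sign-invariant mean orientation: leading eigenvector of sum q q'."""
    ori = _orientations(moments)
    _, v = np.linalg.eigh(ori.T @ ori)
    u = v[:, -1]
    return u / np.linalg.norm(u)


def _make_cluster(
    idx: np.ndarray,
    times: np.ndarray,
    locations: np.ndarray,
    moments: np.ndarray,
    mode: str,
) -> Cluster:
    return Cluster(
        member_index=idx,
        times=times[idx],
        locations=locations[idx],
        moments=moments[idx],
        amplitudes=np.linalg.norm(moments[idx], axis=1),
        mean_location=locations[idx].mean(axis=0),
        mean_orientation=(
            _principal_orientation(moments[idx]) if mode == "location_orientation" else None
        ),
    )


class DipoleClusterer(ClusterMixin, BaseEstimator):
    """Recursive k-medoids binding of time-stamped dipoles into sources.

    Parameters
    ----------
    max_clusters : starting (maximum) cluster count; reduced until all
        cluster pairs pass the separation test.
    mode : ``"location"`` or ``"location_orientation"``.
    separation_factor : centers must be more than this multiple of the pooled
        within-cluster RMS spread apart to count as distinct sources.
    orientation_weight : cm per unit of (1 - |cos|) in orientation mode.

    ``fit(X)`` expects X of shape (n_dipoles, 3) — locations in cm — or
    (n_dipoles, 6) with moment vectors in columns 3:6 (required for
    orientation mode).  Fitted attributes: ``labels_``, ``n_clusters_``,
    ``cluster_centers_``.
    """

    def __init__(
        self,
        max_clusters: int = 10,
        mode: str = "location",
        separation_factor: float = 2.0,
        orientation_weight: float = 1.0,
    ) -> None:
        self.max_clusters = max_clusters
        self.mode = mode
        self.separation_factor = separation_factor
        self.orientation_weight = orientation_weight

    def fit(self, X: np.ndarray, y: None = None, times: np.ndarray | None = None):
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] == 0:
            raise ValueError("cannot cluster an empty dipole list")
        if self.max_clusters < 1:
            raise ValueError("max_clusters must be >= 1")
        if self.mode not in ("location", "location_orientation"):
            raise ValueError("mode must be 'location' or 'location_orientation'")
        locations = X[:, :3]
        moments = X[:, 3:6] if X.shape[1] >= 6 else np.zeros_like(locations)
        if times is None:
            times = np.arange(X.shape[0], dtype=float)
        times = np.asarray(times, float)

        ori = _orientations(moments) if self.mode == "location_orientation" else None
        dist = _pair_dist(locations, locations, ori, ori, self.orientation_weight)

        n = X.shape[0]
        k = min(self.max_clusters, n)
        while True:
            labels = _kmedoids(dist, k) if k > 1 else np.zeros(n, dtype=int)
            # relabel to consecutive ids in order of first appearance
            _, labels = np.unique(labels, return_inverse=True)
            k_eff = labels.max() + 1
            clusters = [
                _make_cluster(np.flatnonzero(labels == g), times, locations, moments, self.mode)
                for g in range(k_eff)
            ]
            if k_eff <= 1:
                break
            ok = all(
                clusters_significantly_different(
                    clusters[a], clusters[b], self.mode,
                    self.separation_factor, self.orientation_weight,
                )
                for a in range(k_eff)
                for b in range(a + 1, k_eff)
            )
            if ok:
                break
            k = k_eff - 1

        self.labels_ = labels
        self.n_clusters_ = len(clusters)
        self.clusters_ = clusters
        self.cluster_centers_ = np.array([c.mean_location for c in clusters])
        self.cluster_set_ = ClusterSet(clusters=clusters, mode=self.mode, labels=labels)
        return self


def cluster_dipoles(
    dipole_table: np.ndarray,
    max_clusters: int,
    mode: str = "location",
    times: np.ndarray | None = None,
    separation_factor: float = 2.0,
    orientation_weight: float = 1.0,
) -> ClusterSet:
    """Functional front end over :class:`DipoleClusterer`.

    ``dipole_table`` rows are (x, y, z[, qx, qy, qz]); ``times`` (ms) aligns
    with rows.
    """
    est = DipoleClusterer(
        max_clusters=max_clusters,
        mode=mode,
        separation_factor=separation_factor,
        orientation_weight=orientation_weight,
    )
    est.fit(dipole_table, times=times)
    return est.cluster_set_


def cluster_summary(
    cluster: Cluster, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean location and member-amplitude waveform of a cluster.

    The waveform has one entry per analyzed sample: the summed amplitude of
    the cluster's members at that sample, zero where the cluster has no
    member.  (This is the discontinuous, dipole-level trace; see
    :func:`refit_waveform` for the continuous one.)
    """
    times = np.asarray(times, float)
    wave = np.zeros(times.size)
    idx = np.searchsorted(times, cluster.times)
    idx = np.clip(idx, 0, times.size - 1)
    np.add.at(wave, idx, cluster.amplitudes)
    return cluster.mean_location.copy(), wave


def refit_waveform(
    cluster: Cluster,
    data: np.ndarray,
    sensors: SensorArray,
    prior_std: float = 30.0,
    sigma_eff: float = 1.0,
    signed: bool = False,
) -> np.ndarray:
    """Continuous amplitude waveform by moment refitting at the mean location.

    At every sample the full 3-vector moment of a dipole frozen at the
    cluster's mean location is re-estimated from the data column by ridge
    least squares; the waveform is its Euclidean norm (or, with ``signed``,
    its projection on the cluster's mean orientation).
    """
    gain = forward_gain(cluster.mean_location[None, :], sensors)[:, 0, :]  # (C, 3)
    lam = (sigma_eff / prior_std) ** 2
    gram = gain.T @ gain + lam * np.eye(3)
    m = np.linalg.solve(gram, gain.T @ data)  # (3, n_samples)
    if signed:
        ref = cluster.mean_orientation
        if ref is None:
            ref = _principal_orientation(cluster.moments)
        return ref @ m
    return np.linalg.norm(m, axis=0)
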