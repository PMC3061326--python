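"""Spherical-conductor MEG forward model.

A current dipole inside a spherically symmetric conductor produces a magnetic
field outside the conductor that has a closed form (the Sarvas solution): the
volume currents contribute analytically and radial dipoles are externally
silent.  This module provides that field, magnetometer / planar-gradiometer
channel responses, regular volumetric source grids with neighbor lists, a
deterministic Vectorview-like sensor helmet, and lead-field assembly.

Units follow MEG practice: positions in cm, dipole moments in nA·m, fields in
fT, planar-gradiometer outputs in fT/cm.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SourceSpace",
    "SensorArray",
    "LeadField",
    "GeometryError",
    "dipole_field_sphere",
    "gradiometer_signal",
    "build_source_grid",
    "neighbor_matrix",
    "assemble_lead_field",
    "fibonacci_helmet",
]

# 1e-7 (mu0/4pi, SI) * 1e-2 (cm->m on the net length power) ... collapsed:
# with all lengths in metres, B[T] = 1e-7 * (...) * |Q[A·m]|; converting
# cm -> m and nA·m -> A·m and T -> fT leaves a prefactor handled inline.
_MU0_4PI = 1e-7


class GeometryError(ValueError):
    """Raised for physically invalid geometry (e.g. a sensor inside the conductor)."""


@dataclasses.dataclass
class SourceSpace:
    """Discretized source space: the finite set of allowed dipole locations.

    Attributes
    ----------
    points : (n_points, 3) float array, cm, head frame.
    orientations : optional (n_points, 3) float array of unit vectors.
    spacing : nominal grid spacing in cm.
    neighbor_lists : optional list of int arrays, one per point, listing all
        point indices (self included) within the chosen neighbor radius.
    """

    points: np.ndarray
    orientations: np.ndarray | None = None
    spacing: float | None = None
    neighbor_lists: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("source-space points must be 3-D")
        if self.orientations is not None:
            self.orientations = np.atleast_2d(np.asarray(self.orientations, float))
            if self.orientations.shape != self.points.shape:
                raise ValueError("orientations must match points in shape")
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("orientation vectors must have unit norm")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n_points


@dataclasses.dataclass
class SensorArray:
    """MEG channel geometry.

    Each channel has a position (cm); a kind, ``"MAG"`` (radial magnetometer)
    or ``"GRAD"`` (planar gradiometer); and, for gradiometers, a tangential
    unit axis along which the radial field component is differentiated with a
    symmetric finite difference of arm length ``baseline``.
    """

    positions: np.ndarray
    kinds: np.ndarray
    axes: np.ndarray
    baseline: float = 1.68
    sphere_center: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3)
    )
    conductor_radius: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.kinds = np.asarray(self.kinds)
        self.axes = np.atleast_2d(np.asarray(self.axes, float))
        self.sphere_center = np.asarray(self.sphere_center, float)
        if self.conductor_radius is not None:
            r = np.linalg.norm(self.positions - self.sphere_center, axis=1)
            if np.any(r <= self.conductor_radius):
                raise GeometryError("all channel positions must lie outside the conductor sphere")
        grad = self.kinds == "GRAD"
        if grad.any():
            ax = self.axes[grad]
            if not np.allclose(np.linalg.norm(ax, axis=1), 1.0, atol=1e-6):
                raise ValueError("gradiometer axes must be unit vectors")
            radial = self.positions[grad] - self.sphere_center
            radial /= np.linalg.norm(radial, axis=1, keepdims=True)
            if np.max(np.abs(np.sum(ax * radial, axis=1))) > 1e-6:
                raise ValueError("gradiometer axes must be tangential (orthogonal to radial)")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n_channels


@dataclasses.dataclass
class LeadField:
    """Linear map from dipole moments on the source grid to channel readings.

    ``matrix`` is (n_channels, dof_per_point * n_points); gradiometer rows are
    fT/cm per nA·m, magnetometer rows fT per nA·m.  In free-orientation mode
    (``dof_per_point == 3``) the three columns of point *p* are the responses
    to unit moments along x, y, z; in constrained mode a single column per
    point gives the response to a unit moment along the supplied orientation.
    """

    matrix: np.ndarray
    dof_per_point: int = 3

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.matrix.shape[1] // self.dof_per_point


def dipole_field_sphere(
    location: np.ndarray,
    moment: np.ndarray,
    sensor_point: np.ndarray,
    center: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
    conductor_radius: float | None = None,
) -> np.ndarray:
    """Magnetic field (fT) of a current dipole in a spherical conductor.

    Closed-form solution for a spherically symmetric conductor; the total
    field (primary plus volume currents) depends only on the sphere center,
    not on its conductivity profile.  Radial dipoles produce exactly zero
    external field.

    Parameters
    ----------
    location : (..., 3) dipole position, cm.
    moment : (..., 3) dipole moment, nA·m.
    sensor_point : (..., 3) field point, cm (outside the conductor).
    center : sphere center, cm.
    conductor_radius : if given, sensor points at radius <= this raise
        :class:`GeometryError`.

    Returns
    -------
    (..., 3) array, field in fT.  Broadcasting over leading axes is supported.
    """
    center = np.asarray(center, float)
    r0 = (np.asarray(location, float) - center) * 1e-2  # m
    r = (np.asarray(sensor_point, float) - center) * 1e-2  # m
    q = np.asarray(moment, float) * 1e-9  # A·m
    if conductor_radius is not None:
        if np.any(np.linalg.norm(np.atleast_2d(r), axis=-1) <= conductor_radius * 1e-2):
            raise GeometryError("sensor point inside or on the conductor sphere")

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1, keepdims=True)
    rn = np.linalg.norm(r, axis=-1, keepdims=True)
    r0_dot_r = np.sum(r0 * r, axis=-1, keepdims=True)
    a_dot_r = np.sum(a_vec * r, axis=-1, keepdims=True)

    F = a * (rn * a + rn**2 - r0_dot_r)
    grad_F = (a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn) * r - (
        a + 2.0 * rn + a_dot_r / a
    ) * r0
    q_x_r0 = np.cross(q, r0)
    b = _MU0_4PI * (F * q_x_r0 - np.sum(q_x_r0 * r, axis=-1, keepdims=True) * grad_F) / F**2
    return b * 1e15  # T -> fT


def gradiometer_signal(
    field_function: Callable[[np.ndarray], np.ndarray],
    position: np.ndarray,
    kind: str,
    axis: np.ndarray | None = None,
    baseline: float = 1.68,
    sphere_center: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
) -> float:
    """Channel reading for a field given as a callable ``point (cm) -> B (fT)``.

    A magnetometer reads the radial field component at its position (fT); a
    planar gradiometer reads the symmetric finite difference of the radial
    component along its tangential axis, divided by the baseline (fT/cm).
    """
    position = np.asarray(position, float)
    center = np.asarray(sphere_center, float)

    def _radial(p: np.ndarray) -> float:
        rhat = (p - center) / np.linalg.norm(p - center)
        return float(np.dot(np.asarray(field_function(p), float), rhat))

    if kind == "MAG":
        return _radial(position)
    if kind != "GRAD":
        raise ValueError(f"unknown channel kind {kind!r}")
    if axis is None:
        raise ValueError("gradiometer channel requires an axis")
    axis = np.asarray(axis, float)
    h = baseline / 2.0
    return (_radial(position + h * axis) - _radial(position - h * axis)) / baseline


def build_source_grid(
    sphere_radius: float, spacing: float, shell_fraction: float = 1.0
) -> SourceSpace:
    """Regular Cartesian grid restricted to a ball around the origin.

    Points are kept up to ``shell_fraction * sphere_radius`` and ordered
    lexicographically by (z, y, x); the origin is always a lattice point, so
    the construction is fully deterministic.
    """
    if not 0 < spacing < sphere_radius:
        raise ValueError("require 0 < spacing < sphere_radius")
    if not 0 < shell_fraction <= 1:
        raise ValueError("require 0 < shell_fraction <= 1")
    rmax = shell_fraction * sphere_radius
    if spacing >= 2 * sphere_radius:
        raise ValueError("spacing too large: grid would be empty")
    n = int(np.floor(rmax / spacing))
    coords = np.arange(-n, n + 1) * spacing
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    keep = np.linalg.norm(pts, axis=1) <= rmax + 1e-12
    return SourceSpace(points=pts[keep], spacing=spacing)


def neighbor_matrix(source_space: SourceSpace, radius: float) -> list[np.ndarray]:
    """All point indices (self included) within Euclidean ``radius`` of each point.

    The relation is symmetric by construction.  The lists are also stored on
    the source space and returned.
    """
    if radius <= 0:
        raise ValueError("neighbor radius must be positive")
    tree = cKDTree(source_space.points)
    lists = tree.query_ball_point(source_space.points, r=radius)
    out = [np.array(sorted(l), dtype=np.int64) for l in lists]
    source_space.neighbor_lists = out
    return out


def _tangential_frame(radial: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit tangential axes orthogonal to each (unit) radial vector."""
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (radial.shape[0], 1))
    near_pole = np.abs(radial[:, 2]) > 0.9
    ref[near_pole] = [1.0, 0.0, 0.0]
    e1 = np.cross(ref, radial)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(radial, e1)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    return e1, e2


def fibonacci_helmet(
    n_locations: int = 102,
    radius: float = 10.5,
    cap_half_angle_deg: float = 110.0,
    baseline: float = 1.68,
    sphere_center: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
    conductor_radius: float | None = 9.0,
) -> SensorArray:
    """Deterministic Vectorview-like helmet: 102 triple-sensor locations.

    Locations are quasi-uniform on a spherical cap (Fibonacci lattice, golden
    angle azimuth) of the given radius around ``sphere_center``; each carries
    one radial magnetometer and two orthogonal planar gradiometers, channel
    order [MAG, GRAD1, GRAD2] per location.
    """
    center = np.asarray(sphere_center, float)
    i = np.arange(n_locations)
    cos_max = np.cos(np.deg2rad(cap_half_angle_deg))
    # uniform in cos(theta) over the cap, golden-angle azimuth
    z = 1.0 - (i + 0.5) / n_locations * (1.0 - cos_max)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z**2)
    radial = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    pos = center + radius * radial
    e1, e2 = _tangential_frame(radial)

    positions = np.repeat(pos, 3, axis=0)
    kinds = np.tile(np.array(["MAG", "GRAD", "GRAD"]), n_locations)
    axes = np.zeros((3 * n_locations, 3))
    axes[1::3] = e1
    axes[2::3] = e2
    return SensorArray(
        positions=positions,
        kinds=kinds,
        axes=axes,
        baseline=baseline,
        sphere_center=center,
        conductor_radius=conductor_radius,
    )


def _channel_eval_points(sensors: SensorArray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Field-evaluation points and combination weights for every channel.

    Returns (eval_points (n_eval, 3), chan_index (n_eval,), weight (n_eval,)):
    channel c's reading = sum over its eval points of weight * radial field.
    """
    pts, idx, w = [], [], []
    h = sensors.baseline / 2.0
    for c in range(sensors.n_channels):
        p = sensors.positions[c]
        if sensors.kinds[c] == "MAG":
            pts.append(p)
            idx.append(c)
            w.append(1.0)
        else:
            ax = sensors.axes[c]
            pts.extend([p + h * ax, p - h * ax])
            idx.extend([c, c])
            w.extend([1.0 / sensors.baseline, -1.0 / sensors.baseline])
    return np.asarray(pts), np.asarray(idx), np.asarray(w)


def forward_gain(
    locations: np.ndarray,
    sensors: SensorArray,
) -> np.ndarray:
    """Free-orientation gain for arbitrary dipole locations.

    Returns (n_channels, n_locations, 3): channel response to unit moments
    (1 nA·m) along x, y, z at each location.  Vectorized over locations and
    channels; this is the kernel behind :func:`assemble_lead_field` and is
    also used to evaluate fields of off-grid (ground-truth) dipoles.
    """
    locations = np.atleast_2d(np.asarray(locations, float))
    eval_pts, chan_idx, wts = _channel_eval_points(sensors)
    center = sensors.sphere_center
    rhat = eval_pts - center
    rhat /= np.linalg.norm(rhat, axis=1, keepdims=True)

    n_loc, n_eval = locations.shape[0], eval_pts.shape[0]
    gain = np.zeros((sensors.n_channels, n_loc, 3))
    eye = np.eye(3)
    # chunk over locations to bound the (n_loc, n_eval, 3) temporaries
    chunk = max(1, int(2e6 // max(n_eval, 1)))
    for start in range(0, n_loc, chunk):
        loc = locations[start : start + chunk]  # (m, 3)
        for ax in range(3):
            b = dipole_field_sphere(
                loc[:, None, :], eye[ax], eval_pts[None, :, :], center=center
            )  # (m, n_eval, 3)
            radial_b = np.sum(b * rhat[None, :, :], axis=-1)  # (m, n_eval)
            contrib = radial_b * wts[None, :]
            acc = np.zeros((loc.shape[0], sensors.n_channels))
            np.add.at(acc, (slice(None), chan_idx), contrib)
            gain[:, start : start + loc.shape[0], ax] = acc.T
    return gain


def assemble_lead_field(
    source_space: SourceSpace,
    sensors: SensorArray,
    constrained: bool = False,
) -> LeadField:
    """Lead-field matrix for every source-grid point.

    Free mode: 3 columns per point (unit moments along x, y, z).  Constrained
    mode: one column per point, the response to a unit moment along the
    point's supplied orientation.
    """
    if constrained and source_space.orientations is None:
        raise ValueError("constrained lead field requires source-space orientations")
    gain = forward_gain(source_space.points, sensors)  # (C, P, 3)
    if constrained:
        mat = np.sum(gain * source_space.orientations[None, :, :], axis=-1)
        return LeadField(matrix=mat, dof_per_point=1)
    n_chan = gain.shape[0]
    return LeadField(matrix=gain.reshape(n_chan, -1), dof_per_point=3)
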