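"""Shared fixtures: small deterministic geometries built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from dipoletrack.forward import (
    LeadField,
    assemble_lead_field,
    build_source_grid,
    fibonacci_helmet,
    neighbor_matrix,
)


@pytest.fixture(scope="session")
def small_helmet():
    """Origin-centered helmet for unit tests (conductor radius 9 cm)."""
    return fibonacci_helmet(sphere_center=(0.0, 0.0, 0.0), conductor_radius=9.0)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid (1 cm spacing, ~500 points) with 1 cm neighbor lists."""
    grid = build_source_grid(6.0, 1.0, 5.0 / 6.0)
    neighbor_matrix(grid, 1.0)
    return grid


@pytest.fixture(scope="session")
def small_lead_field(small_grid, small_helmet):
    """Gradiometer-only lead field on the small grid."""
    lf = assemble_lead_field(small_grid, small_helmet)
    grad = np.flatnonzero(small_helmet.kinds == "GRAD")
    return LeadField(lf.matrix[grad], dof_per_point=3)


@pytest.fixture(scope="session")
def small_grad_rows(small_helmet):
    return np.flatnonzero(small_helmet.kinds == "GRAD")


def tangential_unit(point, center=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0)):
    """A unit vector tangential to the sphere at ``point`` (helper)."""
    point = np.asarray(point, float)
    center = np.asarray(center, float)
    radial = (point - center) / np.linalg.norm(point - center)
    v = np.asarray(axis, float)
    v = v - radial * (v @ radial)
    if np.linalg.norm(v) < 1e-9:
        v = np.cross(radial, [0.0, 1.0, 0.0])
    return v / np.linalg.norm(v)
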