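"""Analytic spherical-conductor forward model for MEG.

A current dipole inside a homogeneous conducting sphere produces an external
magnetic field given by the closed-form Sarvas solution, which accounts for
both the primary (dipolar) current and the secondary volume currents.  Two
classical properties of this geometry are exploited throughout the package:

* radially oriented dipoles are magnetically silent outside the sphere, so
  source orientations are restricted to the local tangential plane;
* the radial field component depends on the primary current only.

All positions are expressed in millimetres in a head-centred frame; field
units are arbitrary (the constant mu0/4pi is dropped), which is irrelevant
for beamforming and correlation analyses that are scale invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "SphereHeadModel",
    "spherical_cap_sensors",
    "leadfield",
    "tangential_basis",
    "tangentialize",
]


class GeometryError(ValueError):
    """Source/sensor geometry violates the spherical model assumptions."""


@dataclass(frozen=True)
class SphereHeadModel:
    """Homogeneous conducting sphere fitted to the head.

    Parameters
    ----------
    center : (3,) array-like, mm
        Sphere centre in the head frame.
    radius : float, mm
        Conductor radius; sources must lie strictly inside.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 90.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        if self.radius <= 0:
            raise GeometryError("sphere radius must be positive")

    def contains(self, position, margin: float = 0.0) -> bool:
        r = np.linalg.norm(np.asarray(position, float) - self.center)
        return r < self.radius - margin


def spherical_cap_sensors(
    n_channels: int,
    sensor_radius: float = 110.0,
    max_polar_deg: float = 115.0,
    center=(0.0, 0.0, 0.0),
):
    """Quasi-uniform cap of radially oriented gradiometer-like sensors.

    Sensors are laid out on a spherical cap (opening ``max_polar_deg`` from
    the vertex) with a Fibonacci spiral, emulating a whole-head MEG array at
    configurable channel count.

    Returns
    -------
    positions : (n, 3) ndarray, mm
    orientations : (n, 3) ndarray
        Unit outward radial vectors (the sensitive axis of each sensor).
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    center = np.asarray(center, float)
    i = np.arange(n_channels)
    zmin = np.cos(np.deg2rad(max_polar_deg))
    # uniform in area over the cap
    z = 1.0 - (1.0 - zmin) * (i + 0.5) / n_channels
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    ori = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    pos = center + sensor_radius * ori
    return pos, ori


def tangential_basis(model: SphereHeadModel, position) -> np.ndarray:
    """Two orthonormal vectors spanning the tangential plane at ``position``.

    Returns a (2, 3) array; radial dipoles being silent, these two directions
    span all magnetically visible source orientations.
    """
    r0 = np.asarray(position, float) - model.center
    nr = np.linalg.norm(r0)
    if nr == 0:
        raise GeometryError("source at sphere centre has no tangential plane")
    rhat = r0 / nr
    helper = np.array([0.0, 0.0, 1.0])
    if abs(rhat @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(rhat, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(rhat, e1)
    return np.vstack([e1, e2])


def tangentialize(model: SphereHeadModel, position, orientation) -> np.ndarray:
    """Project ``orientation`` onto the tangential plane and renormalize."""
    r0 = np.asarray(position, float) - model.center
    rhat = r0 / np.linalg.norm(r0)
    q = np.asarray(orientation, float)
    qt = q - (q @ rhat) * rhat
    n = np.linalg.norm(qt)
    if n < 1e-12:
        raise GeometryError("orientation is purely radial (magnetically silent)")
    return qt / n


def leadfield(
    model: SphereHeadModel,
    position,
    orientation,
    sensor_positions,
    sensor_orientations,
) -> np.ndarray:
    """Sensor-space signature of a unit current dipole (Sarvas solution).

    Parameters
    ----------
    position : (3,) mm, strictly inside the sphere.
    orientation : (3,) unit dipole moment direction.
    sensor_positions, sensor_orientations : (n, 3)
        Sensor locations (outside the sphere) and sensitive axes.

    Returns
    -------
    (n,) ndarray: projection of the magnetic field onto each sensor axis,
    linear in the dipole moment.
    """
    position = np.asarray(position, float).reshape(3)
    q = np.asarray(orientation, float).reshape(3)
    if not model.contains(position):
        raise GeometryError(
            f"dipole at {position} is not strictly inside the sphere "
            f"(radius {model.radius} mm)"
        )
    r0 = position - model.center
    r = np.atleast_2d(np.asarray(sensor_positions, float)) - model.center
    ori = np.atleast_2d(np.asarray(sensor_orientations, float))

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    R = np.linalg.norm(r, axis=1)
    if np.any(R <= model.radius):
        raise GeometryError("sensors must lie outside the conducting sphere")
    ar = np.einsum("ij,ij->i", a_vec, r)
    F = a * (R * a + R**2 - r0 @ r.T)
    gradF = (
        (a**2 / R + ar / a + 2.0 * a + 2.0 * R)[:, None] * r
        - (a + 2.0 * R + ar / a)[:, None] * r0
    )
    qxr0 = np.cross(q, r0)
    # Sarvas: B = (F * (q x r0) - ((q x r0) . r) gradF) / F^2   (mu0/4pi == 1)
    B = (F[:, None] * qxr0 - (r @ qxr0)[:, None] * gradF) / (F**2)[:, None]
    return np.einsum("ij,ij->i", B, ori)


def leadfield_tangential(
    model: SphereHeadModel, position, sensor_positions, sensor_orientations
) -> np.ndarray:
    """(n_sensors, 2) lead field for the two tangential unit orientations."""
    basis = tangential_basis(model, position)
    cols = [
        leadfield(model, position, u, sensor_positions, sensor_orientations)
        for u in basis
    ]
    return np.column_stack(cols)
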