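"""Analytic 2D deformation fields with exact Green-Lagrange strain.

A deformation field maps a reference (end-diastolic) position ``(x, y)`` in
millimetres to a displacement vector ``(u_x, u_y)`` in millimetres, and
carries the analytic Green-Lagrange strain tensor ``E = (F^T F - I) / 2`` of
the underlying map ``phi(x) = x + u(x)``.  These fields drive the phantom
generator and provide the ground truth against which decoded displacements
and mesh strains are checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = [
    "DeformationField",
    "translation",
    "rigid_rotation",
    "uniform_stretch",
    "isotropic_scaling",
    "azimuthal_scaling",
    "stretch_for_longitudinal_strain",
    "numerical_strain",
]

_ArrayMap = Callable[[np.ndarray, np.ndarray], Tuple[np.ndarray, np.ndarray]]
_StrainMap = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class DeformationField:
    """An analytic displacement map with its exact strain tensor.

    Attributes
    ----------
    descriptor : str
        Human-readable description, e.g. ``"uniform-longitudinal-stretch
        lambda=0.84"``.
    """

    descriptor: str
    _displacement: _ArrayMap
    _strain: _StrainMap

    def displacement(self, x, y) -> Tuple[np.ndarray, np.ndarray]:
        """Displacement components (mm) at reference positions (mm)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ux, uy = self._displacement(x, y)
        return np.asarray(ux, float), np.asarray(uy, float)

    def strain(self, x, y) -> np.ndarray:
        """Green-Lagrange tensor, shape ``x.shape + (2, 2)``."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.asarray(self._strain(x, y), float)

    def longitudinal_strain(self, x, y, direction) -> np.ndarray:
        """Project the strain tensor onto unit direction(s) ``l``: l^T E l."""
        e = self.strain(x, y)
        d = np.asarray(direction, float)
        return np.einsum("...i,...ij,...j->...", d, e, d)


def _zero_strain(x, y):
    return np.zeros(np.shape(x) + (2, 2))


def translation(ux: float, uy: float) -> DeformationField:
    """Rigid in-plane translation; strain is identically zero."""

    def disp(x, y):
        return np.full_like(x, float(ux)), np.full_like(y, float(uy))

    return DeformationField(f"translation u=({ux},{uy}) mm", disp, _zero_strain)


def rigid_rotation(angle_rad: float, center=(0.0, 0.0)) -> DeformationField:
    """Rigid rotation about ``center``; Green-Lagrange strain is zero."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    cx, cy = center

    def disp(x, y):
        dx, dy = x - cx, y - cy
        return c * dx - s * dy - dx, s * dx + c * dy - dy

    return DeformationField(
        f"rigid-rotation {np.degrees(angle_rad):.3g} deg about ({cx},{cy})",
        disp,
        _zero_strain,
    )


def uniform_stretch(stretch: float, axis=(1.0, 0.0), center=(0.0, 0.0)) -> DeformationField:
    """Homogeneous stretch ``lambda`` along a fixed unit axis.

    The map is ``phi(x) = c + (I + (lambda - 1) a a^T)(x - c)``; its strain is
    the constant tensor ``E = (lambda^2 - 1)/2 * a a^T``.
    """
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    lam = float(stretch)
    cx, cy = center
    e_const = 0.5 * (lam**2 - 1.0) * np.outer(a, a)

    def disp(x, y):
        proj = (x - cx) * a[0] + (y - cy) * a[1]
        return (lam - 1.0) * proj * a[0], (lam - 1.0) * proj * a[1]

    def strain(x, y):
        return np.broadcast_to(e_const, np.shape(x) + (2, 2)).copy()

    return DeformationField(
        f"uniform-stretch lambda={lam:g} axis=({a[0]:.3g},{a[1]:.3g})", disp, strain
    )


def isotropic_scaling(scale: float, center=(0.0, 0.0)) -> DeformationField:
    """Homogeneous isotropic scaling about ``center``.

    Every material direction stretches by ``lambda``, so
    ``E = (lambda^2 - 1)/2 * I``: uniform longitudinal strain on a closed
    ring (which, unlike azimuthal scaling, stays continuous all the way
    around).
    """
    lam = float(scale)
    cx, cy = center
    e_const = 0.5 * (lam**2 - 1.0) * np.eye(2)

    def disp(x, y):
        return (lam - 1.0) * (x - cx), (lam - 1.0) * (y - cy)

    def strain(x, y):
        return np.broadcast_to(e_const, np.shape(x) + (2, 2)).copy()

    return DeformationField(f"isotropic-scaling lambda={lam:g} about ({cx},{cy})", disp, strain)


def azimuthal_scaling(theta_scale: float, center=(0.0, 0.0)) -> DeformationField:
    """Azimuthal angle scaling ``(r, theta) -> (r, lambda * theta)``.

    Along the local tangential direction ``t = (-sin theta, cos theta)`` the
    stretch is ``lambda`` everywhere, so ``E = (lambda^2 - 1)/2 * t t^T``:
    a *uniform* longitudinal strain on any circumferential wall strip centred
    on ``center``.  This is the work-horse for imposing a known free-wall
    longitudinal strain on the crescent phantom.
    """
    lam = float(theta_scale)
    cx, cy = center

    def disp(x, y):
        dx, dy = x - cx, y - cy
        r = np.hypot(dx, dy)
        th = np.arctan2(dy, dx)
        return cx + r * np.cos(lam * th) - x, cy + r * np.sin(lam * th) - y

    def strain(x, y):
        dx, dy = np.broadcast_arrays(x - cx, y - cy)
        th = np.arctan2(dy, dx)
        t = np.stack([-np.sin(th), np.cos(th)], axis=-1)
        return 0.5 * (lam**2 - 1.0) * t[..., :, None] * t[..., None, :]

    return DeformationField(
        f"azimuthal-scaling lambda={lam:g} about ({cx},{cy})", disp, strain
    )


def stretch_for_longitudinal_strain(e_ll: float) -> float:
    """Stretch ratio whose Green-Lagrange strain equals ``e_ll``.

    Inverts ``E = (lambda^2 - 1)/2``; requires ``e_ll > -0.5``.
    """
    if e_ll <= -0.5:
        raise ValueError(f"longitudinal strain must exceed -0.5, got {e_ll}")
    return float(np.sqrt(1.0 + 2.0 * e_ll))


def numerical_strain(field: DeformationField, x, y, h: float = 1e-4) -> np.ndarray:
    """Green-Lagrange strain by central-difference deformation gradient.

    Independent of :meth:`DeformationField.strain`; used to validate the
    analytic tensors.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def phi(px, py):
        ux, uy = field.displacement(px, py)
        return px + ux, py + uy

    fxp = phi(x + h, y)
    fxm = phi(x - h, y)
    fyp = phi(x, y + h)
    fym = phi(x, y - h)
    f = np.empty(np.shape(x) + (2, 2))
    f[..., 0, 0] = (fxp[0] - fxm[0]) / (2 * h)
    f[..., 1, 0] = (fxp[1] - fxm[1]) / (2 * h)
    f[..., 0, 1] = (fyp[0] - fym[0]) / (2 * h)
    f[..., 1, 1] = (fyp[1] - fym[1]) / (2 * h)
    ft_f = np.einsum("...ki,...kj->...ij", f, f)
    eye = np.eye(2)
    return 0.5 * (ft_f - eye)
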