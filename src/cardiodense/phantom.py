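"""Synthetic DENSE acquisitions and volumetry fixtures with known truth.

The imaging phantom is a 2D four-chamber-like plane holding an annular LV
wall and a crescent-shaped RV free wall.  A prescribed analytic deformation
field is encoded into wrapped phase images exactly as DENSE stores it
(phase = 2 pi k_e u, wrapped into (-pi, pi], plus optional Gaussian phase
noise); background pixels carry uniform random phase.  Volumetry fixtures
slice analytic solids (nested ellipsoids / cylinders) into contour stacks
whose closed-form volumes are attached as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np

from .dense import TWO_PI, PhasePair, wrap_phase
from .fields import (
    DeformationField,
    azimuthal_scaling,
    isotropic_scaling,
    stretch_for_longitudinal_strain,
)
from .geometry import MYOCARDIAL_DENSITY_G_PER_ML, ContourStack, SliceContours
from .mesh import build_wall_mesh

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "make_phantom_pair",
    "imposed_strain_field",
    "make_cine_frames",
    "NestedEllipsoids",
    "NestedCylinders",
    "make_volumetry_phantom",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and acquisition parameters of the 2D imaging phantom.

    Coordinates are physical mm with the origin at the image centre; the
    LV annulus and RV crescent are placed by offsets from that origin.
    The defaults emulate a pediatric four-chamber DENSE acquisition:
    128 x 128 matrix, 1.6 mm in-plane spacing, k_e = 0.1 cycles/mm.
    """

    matrix: tuple = (128, 128)
    pixel_spacing_mm: float = 1.6
    k_e: float = 0.1
    lv_center_mm: tuple = (-20.0, 0.0)
    lv_radii_mm: tuple = (10.0, 18.0)  # endo, epi
    rv_center_mm: tuple = (12.0, 0.0)
    rv_radii_mm: tuple = (24.0, 30.0)  # endo, epi
    rv_arc_deg: tuple = (-60.0, 60.0)
    noise_sd_rad: float = 0.0
    seed: int = 0
    mesh_edge_mm: float = 3.0
    #: tissue-mask margin around the wall (pixels). Emulates a segmentation
    #: that keeps partial-volume boundary pixels, so every contour node has
    #: a fully valid bilinear stencil.
    mask_margin_px: float = 1.5

    def __post_init__(self):
        if self.k_e <= 0:
            raise ValueError("k_e must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.noise_sd_rad < 0:
            raise ValueError("noise SD must be non-negative")
        for name, (r_in, r_out) in (
            ("lv", self.lv_radii_mm),
            ("rv", self.rv_radii_mm),
        ):
            if not 0 < r_in < r_out:
                raise ValueError(f"{name} radii must satisfy 0 < endo < epi")
            if (r_out - r_in) < 2 * self.pixel_spacing_mm:
                raise ValueError(
                    f"{name} wall thickness {r_out - r_in} mm is below 2 pixels"
                )

    @property
    def origin_mm(self) -> tuple:
        nr, nc = self.matrix
        return (
            -0.5 * (nc - 1) * self.pixel_spacing_mm,
            -0.5 * (nr - 1) * self.pixel_spacing_mm,
        )

    def pixel_grid(self):
        """Physical (x, y) mm coordinates of pixel centres, each (nr, nc)."""
        nr, nc = self.matrix
        ox, oy = self.origin_mm
        x = ox + np.arange(nc) * self.pixel_spacing_mm
        y = oy + np.arange(nr) * self.pixel_spacing_mm
        return np.meshgrid(x, y)

    @property
    def unambiguous_range_mm(self) -> float:
        return 1.0 / (2.0 * self.k_e)


def _annulus_mask(x, y, center, radii, margin_mm=0.0):
    r = np.hypot(x - center[0], y - center[1])
    return (r >= radii[0] - margin_mm) & (r <= radii[1] + margin_mm)


def _crescent_mask(x, y, center, radii, arc_deg, margin_mm=0.0):
    dx, dy = x - center[0], y - center[1]
    r = np.hypot(dx, dy)
    th = np.degrees(np.arctan2(dy, dx))
    dth = np.degrees(margin_mm / max(radii[0], 1e-9))
    return (
        (r >= radii[0] - margin_mm)
        & (r <= radii[1] + margin_mm)
        & (th >= arc_deg[0] - dth)
        & (th <= arc_deg[1] + dth)
    )


def _arc_polyline(center, radius, arc_deg, n=181):
    th = np.radians(np.linspace(arc_deg[0], arc_deg[1], n))
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def _circle_polyline(center, radius, n=181):
    th = np.linspace(0.0, TWO_PI, n)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


@dataclass
class PhantomPair:
    """A synthetic acquisition bundled with its exact ground truth."""

    pair: PhasePair
    mask: np.ndarray
    rv_mask: np.ndarray
    lv_mask: np.ndarray
    truth_ux: np.ndarray
    truth_uy: np.ndarray
    truth_strain: np.ndarray  # (nr, nc, 2, 2) Green-Lagrange tensors
    contours_ed: dict  # name -> (N, 2) mm
    contours_es: dict
    meshes: dict  # "rv" / "lv" -> WallMesh
    field: DeformationField
    spec: PhantomSpec


def imposed_strain_field(spec: PhantomSpec, e_ll: float) -> DeformationField:
    """Deformation imposing a uniform longitudinal strain on the RV crescent.

    Azimuthal scaling about the crescent centre stretches every wall-tangent
    direction by the same ratio, so each free-wall element carries exactly
    ``e_ll`` Green-Lagrange longitudinal strain.
    """
    lam = stretch_for_longitudinal_strain(e_ll)
    return azimuthal_scaling(lam, center=spec.rv_center_mm)


def make_phantom_pair(spec: PhantomSpec, field: DeformationField) -> PhantomPair:
    """Encode a deformation field into an end-systolic DENSE phase pair.

    Tissue pixels carry ``wrap(2 pi k_e u) + N(0, noise_sd)`` (re-wrapped);
    background pixels carry uniform random phase.  If any tissue pixel's
    encoded phase magnitude exceeds pi, the pair is flagged
    ``wrapping_expected`` in its metadata (spatial unwrapping required).
    """
    x, y = spec.pixel_grid()
    margin = spec.mask_margin_px * spec.pixel_spacing_mm
    rv_mask = _crescent_mask(
        x, y, spec.rv_center_mm, spec.rv_radii_mm, spec.rv_arc_deg, margin
    )
    lv_mask = _annulus_mask(x, y, spec.lv_center_mm, spec.lv_radii_mm, margin)
    if (rv_mask & lv_mask).any():
        raise ValueError("LV annulus and RV crescent overlap; adjust the spec")
    mask = rv_mask | lv_mask

    ux, uy = field.displacement(x, y)
    if not (np.all(np.isfinite(ux[mask])) and np.all(np.isfinite(uy[mask]))):
        raise ValueError("deformation field is not finite on the phantom domain")
    truth_strain = field.strain(x, y)

    rng = np.random.default_rng(spec.seed)
    phases = []
    wrapping = False
    for u in (ux, uy):
        raw = TWO_PI * spec.k_e * u
        wrapping = wrapping or bool(np.any(np.abs(raw[mask]) > np.pi))
        ph = wrap_phase(raw)
        if spec.noise_sd_rad > 0:
            ph = wrap_phase(ph + rng.normal(0.0, spec.noise_sd_rad, ph.shape))
        background = rng.uniform(-np.pi, np.pi, ph.shape)
        background[background == -np.pi] = np.pi
        phases.append(np.where(mask, ph, background))

    pair = PhasePair(
        phase_x=phases[0],
        phase_y=phases[1],
        pixel_spacing_mm=spec.pixel_spacing_mm,
        k_e=spec.k_e,
        frame="ES",
        origin_mm=spec.origin_mm,
        meta={
            "wrapping_expected": wrapping,
            "descriptor": field.descriptor,
            "seed": spec.seed,
        },
    )

    contours_ed = {
        "rv_endo": _arc_polyline(spec.rv_center_mm, spec.rv_radii_mm[0], spec.rv_arc_deg),
        "rv_epi": _arc_polyline(spec.rv_center_mm, spec.rv_radii_mm[1], spec.rv_arc_deg),
        "lv_endo": _circle_polyline(spec.lv_center_mm, spec.lv_radii_mm[0]),
        "lv_epi": _circle_polyline(spec.lv_center_mm, spec.lv_radii_mm[1]),
    }
    contours_es = {}
    for name, poly in contours_ed.items():
        dux, duy = field.displacement(poly[:, 0], poly[:, 1])
        contours_es[name] = poly + np.column_stack([dux, duy])

    meshes = {
        "rv": build_wall_mesh(
            contours_ed["rv_endo"],
            contours_ed["rv_epi"],
            label="rv_free_wall",
            target_edge_length_mm=spec.mesh_edge_mm,
        ),
        "lv": build_wall_mesh(
            contours_ed["lv_endo"],
            contours_ed["lv_epi"],
            label="lv_wall",
            target_edge_length_mm=spec.mesh_edge_mm,
        ),
    }
    return PhantomPair(
        pair=pair,
        mask=mask,
        rv_mask=rv_mask,
        lv_mask=lv_mask,
        truth_ux=ux,
        truth_uy=uy,
        truth_strain=truth_strain,
        contours_ed=contours_ed,
        contours_es=contours_es,
        meshes=meshes,
        field=field,
        spec=spec,
    )


def make_cine_frames(
    spec: PhantomSpec,
    peak_e_ll: float,
    n_frames: int = 10,
    target: str = "lv",
) -> List[PhasePair]:
    """A linear ED->ES ramp of phase pairs for the cine tracking path.

    Frame ``i`` imposes the azimuthal stretch interpolated between 1 (ED)
    and the end-systolic value; each frame encodes displacement relative to
    end-diastole, as DENSE does.
    """
    if n_frames < 5:
        raise ValueError("need >= 5 frames")
    lam_es = stretch_for_longitudinal_strain(peak_e_ll)
    center = spec.lv_center_mm if target == "lv" else spec.rv_center_mm
    frames = []
    for i in range(n_frames):
        lam_i = 1.0 + (lam_es - 1.0) * i / (n_frames - 1)
        # isotropic contraction: stays continuous on the closed LV ring
        fld = isotropic_scaling(lam_i, center=center)
        frame_spec = replace(spec, seed=spec.seed + 1000 + i)
        frames.append(make_phantom_pair(frame_spec, fld).pair)
    return frames


# ------------------------------------------------------------- volumetry


@dataclass(frozen=True)
class NestedEllipsoids:
    """Outer (epi) and optional inner (endo) co-centred ellipsoids, mm."""

    epi_semiaxes: tuple  # (a, b, c); c along the slice axis
    endo_semiaxes: Optional[tuple] = None

    def __post_init__(self):
        a, b, c = self.epi_semiaxes
        if min(a, b, c) <= 0:
            raise ValueError("semiaxes must be positive")
        if self.endo_semiaxes is not None:
            ai, bi, ci = self.endo_semiaxes
            if min(ai, bi, ci) <= 0 or ai > a or bi > b or ci > c:
                raise ValueError("endo ellipsoid must nest inside the epi ellipsoid")

    @property
    def extent_mm(self) -> float:
        return 2.0 * self.epi_semiaxes[2]

    def analytic_volume_ml(self, surface: str) -> Optional[float]:
        axes = self.epi_semiaxes if surface == "epi" else self.endo_semiaxes
        if axes is None:
            return None
        return 4.0 / 3.0 * np.pi * axes[0] * axes[1] * axes[2] / 1000.0

    def section(self, z: float, surface: str, n_vertices: int):
        axes = self.epi_semiaxes if surface == "epi" else self.endo_semiaxes
        if axes is None:
            return None
        a, b, c = axes
        if abs(z) >= c:
            return None
        shrink = np.sqrt(1.0 - (z / c) ** 2)
        th = np.linspace(0.0, TWO_PI, n_vertices, endpoint=False)
        return np.column_stack([a * shrink * np.cos(th), b * shrink * np.sin(th)])


@dataclass(frozen=True)
class NestedCylinders:
    """Outer and optional inner co-axial circular cylinders, mm."""

    epi_radius: float
    height: float
    endo_radius: Optional[float] = None

    def __post_init__(self):
        if self.epi_radius <= 0 or self.height <= 0:
            raise ValueError("radius and height must be positive")
        if self.endo_radius is not None and not 0 < self.endo_radius <= self.epi_radius:
            raise ValueError("endo radius must nest inside the epi radius")

    @property
    def extent_mm(self) -> float:
        return self.height

    def analytic_volume_ml(self, surface: str) -> Optional[float]:
        r = self.epi_radius if surface == "epi" else self.endo_radius
        if r is None:
            return None
        return np.pi * r**2 * self.height / 1000.0

    def section(self, z: float, surface: str, n_vertices: int):
        r = self.epi_radius if surface == "epi" else self.endo_radius
        if r is None or abs(z) >= self.height / 2.0:
            return None
        th = np.linspace(0.0, TWO_PI, n_vertices, endpoint=False)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])


def make_volumetry_phantom(
    solid,
    n_slices: int,
    thickness_mm: float,
    gap_mm: float = 0.0,
    frame: str = "ED",
    ventricle: str = "RV",
    n_vertices: int = 256,
) -> ContourStack:
    """Slice an analytic solid into a contour stack with closed-form truth.

    Slice centres are placed symmetrically about the solid's equator; the
    stack must cover the solid's full extent along the slice axis.  The
    returned stack's ``meta`` holds the analytic epi/endo volumes (mL) and,
    when both surfaces exist, the shell mass at 1.05 g/mL.
    """
    if n_slices < 3:
        raise ValueError(f"need >= 3 slices, got {n_slices}")
    slab = thickness_mm + gap_mm
    coverage = n_slices * slab
    if coverage < solid.extent_mm - 1e-9:
        raise ValueError(
            f"slice stack covers {coverage} mm but the solid extends "
            f"{solid.extent_mm} mm along the slice axis"
        )
    z0 = -0.5 * (n_slices - 1) * slab
    slices = []
    for i in range(n_slices):
        z = z0 + i * slab
        slices.append(
            SliceContours(
                endo=solid.section(z, "endo", n_vertices),
                epi=solid.section(z, "epi", n_vertices),
            )
        )
    meta = {
        "analytic_epi_volume_ml": solid.analytic_volume_ml("epi"),
        "analytic_endo_volume_ml": solid.analytic_volume_ml("endo"),
    }
    if meta["analytic_endo_volume_ml"] is not None:
        shell = meta["analytic_epi_volume_ml"] - meta["analytic_endo_volume_ml"]
        meta["analytic_shell_mass_g"] = shell * MYOCARDIAL_DENSITY_G_PER_ML
    return ContourStack(
        slices=slices,
        thickness_mm=thickness_mm,
        gap_mm=gap_mm,
        frame=frame,
        ventricle=ventricle,
        meta=meta,
    )
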