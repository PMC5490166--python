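"""Ventricular volumetry and mass from short-axis contour stacks.

Simpson's rule: ventricular volume is the sum of per-slice contour areas
times the effective slab height (slice thickness + inter-slice gap).
Myocardial mass is the epi-endo shell volume times the myocardial density
of 1.05 g/mL, indexed allometrically to height^2.7 for children.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "MYOCARDIAL_DENSITY_G_PER_ML",
    "SliceContours",
    "ContourStack",
    "simpson_volume",
    "myocardial_mass",
    "index_to_height",
    "VentricleGeometry",
    "derive_geometry",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class SliceContours:
    """Endo/epi polygons (mm coordinates, open ring: no repeated vertex)."""

    endo: Optional[np.ndarray] = None
    epi: Optional[np.ndarray] = None


@dataclass
class ContourStack:
    """Per-slice endo/epi polygons with slice geometry.

    ``thickness_mm`` and ``gap_mm`` define the effective slab height per
    slice; ``frame`` is "ED" or "ES"; ``ventricle`` "LV" or "RV".
    """

    slices: List[SliceContours]
    thickness_mm: float
    gap_mm: float = 0.0
    frame: str = "ED"
    ventricle: str = "RV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")
        if self.gap_mm < 0:
            raise ValueError("slice gap must be non-negative")
        if len(self.slices) < 3:
            raise ValueError(f"need >= 3 slices, got {len(self.slices)}")
        if self.frame not in ("ED", "ES"):
            raise ValueError("frame must be 'ED' or 'ES'")
        if self.ventricle not in ("LV", "RV"):
            raise ValueError("ventricle must be 'LV' or 'RV'")

    @property
    def slab_height_mm(self) -> float:
        return self.thickness_mm + self.gap_mm


def _polygon_area(vertices: Optional[np.ndarray], where: str) -> float:
    if vertices is None:
        return 0.0
    vertices = np.asarray(vertices, float)
    if len(vertices) < 3:
        raise ValueError(f"{where}: polygon needs >= 3 vertices")
    poly = Polygon(vertices)
    if not poly.is_valid:
        raise ValueError(f"{where}: polygon is not simple")
    return float(poly.area)


def simpson_volume(stack: ContourStack, surface: str = "endo") -> float:
    """Slice-summation volume of one surface, in mL.

    Per-slice polygon area (shoelace, via shapely) times the effective slab
    height, summed over slices; slices without a contour contribute zero.
    """
    if surface not in ("endo", "epi"):
        raise ValueError("surface must be 'endo' or 'epi'")
    total_mm3 = 0.0
    for i, sl in enumerate(stack.slices):
        area = _polygon_area(getattr(sl, surface), f"slice {i} ({surface})")
        total_mm3 += area * stack.slab_height_mm
    return total_mm3 / 1000.0


def myocardial_mass(
    ed_stack: ContourStack, density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML
) -> float:
    """Myocardial mass (g) from the end-diastolic epi-endo shell.

    Requires both surfaces; a slice whose endo area exceeds its epi area, or
    a negative total shell volume, is an error.
    """
    if ed_stack.frame != "ED":
        raise ValueError("myocardial mass is computed on the end-diastolic stack")
    for i, sl in enumerate(ed_stack.slices):
        if sl.endo is not None and sl.epi is None:
            raise ValueError(f"slice {i}: epi surface required for mass")
        if sl.endo is not None:
            a_endo = _polygon_area(sl.endo, f"slice {i} (endo)")
            a_epi = _polygon_area(sl.epi, f"slice {i} (epi)")
            if a_endo > a_epi + 1e-9:
                raise ValueError(f"slice {i}: endo contour larger than epi contour")
    shell_ml = simpson_volume(ed_stack, "epi") - simpson_volume(ed_stack, "endo")
    if shell_ml < -1e-12:
        raise ValueError("negative shell volume")
    return max(shell_ml, 0.0) * density_g_per_ml


def index_to_height(mass_g: float, height_cm: float) -> float:
    """Allometric mass index: mass / height(m)^2.7, in g/m^2.7."""
    if not (100.0 < height_cm < 220.0):
        raise ValueError(f"height {height_cm} cm outside the supported (100, 220) range")
    if mass_g < 0:
        raise ValueError("mass must be non-negative")
    return mass_g / (height_cm / 100.0) ** 2.7


@dataclass
class VentricleGeometry:
    """Volumes, ejection fraction, mass and derived indices for one ventricle."""

    ventricle: str
    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    mass_g: Optional[float] = None
    mass_index: Optional[float] = None  # g/m^2.7
    mass_volume_ratio: Optional[float] = None  # g/mL, LV only (mass / EDV)


def derive_geometry(
    ed_stack: ContourStack,
    es_stack: ContourStack,
    height_cm: Optional[float] = None,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> VentricleGeometry:
    """EDV/ESV/SV/EF (and mass measures when available) from matched stacks."""
    if ed_stack.ventricle != es_stack.ventricle:
        raise ValueError("ED and ES stacks must describe the same ventricle")
    if ed_stack.frame != "ED" or es_stack.frame != "ES":
        raise ValueError("stacks must be labelled ED and ES respectively")
    edv = simpson_volume(ed_stack, "endo")
    esv = simpson_volume(es_stack, "endo")
    sv = edv - esv
    if edv <= 0:
        raise ValueError("end-diastolic volume must be positive")
    ef = 100.0 * sv / edv
    if not (0.0 <= ef <= 100.0):
        raise ValueError(f"ejection fraction {ef:.1f}% outside [0, 100]: invalid contours")

    mass = mass_index = mv_ratio = None
    has_epi = any(sl.epi is not None for sl in ed_stack.slices)
    if has_epi and all(
        sl.epi is not None for sl in ed_stack.slices if sl.endo is not None
    ):
        mass = myocardial_mass(ed_stack, density_g_per_ml)
        if height_cm is not None:
            mass_index = index_to_height(mass, height_cm)
        if ed_stack.ventricle == "LV":
            mv_ratio = mass / edv
    return VentricleGeometry(
        ventricle=ed_stack.ventricle,
        edv_ml=edv,
        esv_ml=esv,
        sv_ml=sv,
        ef_pct=ef,
        mass_g=mass,
        mass_index=mass_index,
        mass_volume_ratio=mv_ratio,
    )
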