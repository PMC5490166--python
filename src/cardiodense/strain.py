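"""Mesh-deformation strain: the end-systolic single-frame RV method and the
cine LV tracking path.

The reference (end-diastolic) wall mesh is deformed by the decoded
displacement field; for each triangle the linear map from the reference to
the deformed element gives the deformation gradient ``F``, the
Green-Lagrange tensor ``E = (F^T F - I)/2``, and the longitudinal strain
``E_LL = l^T E l`` along the element's wall-tangent direction ``l``.
Contraction is negative.  The free-wall summary is the unweighted element
mean over ``rv_free_wall`` elements (area weighting optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .dense import DisplacementField, PhasePair, anchor_component_offsets, decode_displacement, unwrap_phase
from .mesh import WallMesh

__all__ = [
    "StrainResult",
    "CineTrackingResult",
    "detect_end_systole",
    "sample_displacement",
    "deform_and_strain",
    "track_cine_lv",
]


def detect_end_systole(chamber_areas) -> int:
    """End-systolic frame index = argmin of chamber area (ties -> earliest).

    Emits a warning if the areas are all equal (returns frame 0) or strictly
    decreasing (no diastolic recovery observed; returns the last frame).
    """
    areas = np.asarray(chamber_areas, float)
    if areas.ndim != 1 or len(areas) < 3:
        raise ValueError("need at least 3 frames of chamber areas")
    if not np.all(np.isfinite(areas)):
        raise ValueError("chamber areas must be finite")
    if np.all(areas == areas[0]):
        warnings.warn("all chamber areas equal; returning the first frame")
        return 0
    idx = int(np.argmin(areas))
    if idx == len(areas) - 1 and np.all(np.diff(areas) < 0):
        warnings.warn("chamber area strictly decreasing; no diastolic recovery seen")
    return idx


def sample_displacement(field_: DisplacementField, points_mm: np.ndarray):
    """Bilinear displacement at physical points; near-mask gaps filled.

    Points must lie on the valid mask or within one pixel of it; off-mask
    pixels inside a node's bilinear stencil are filled with the
    nearest-valid value, and the number of affected nodes is returned.
    """
    pts = np.asarray(points_mm, float)
    dx = field_.pixel_spacing_mm
    ox, oy = field_.origin_mm
    cols = (pts[:, 0] - ox) / dx
    rows = (pts[:, 1] - oy) / dx

    invalid = ~field_.mask
    dist_px, idx = ndimage.distance_transform_edt(invalid, return_indices=True)
    dist_at = ndimage.map_coordinates(dist_px, [rows, cols], order=1, mode="nearest")
    if np.any(dist_at > 1.0 + 1e-6):
        n_bad = int(np.sum(dist_at > 1.0 + 1e-6))
        raise ValueError(
            f"{n_bad} mesh node(s) lie more than 1 pixel outside the displacement mask"
        )

    coverage = ndimage.map_coordinates(
        field_.mask.astype(float), [rows, cols], order=1, mode="nearest"
    )
    n_filled = int(np.sum(coverage < 1.0 - 1e-9))

    u = np.empty_like(pts)
    for k, arr in enumerate((field_.u_x, field_.u_y)):
        filled = np.where(invalid, arr[tuple(idx)], arr)
        u[:, k] = ndimage.map_coordinates(filled, [rows, cols], order=1, mode="nearest")
    return u, n_filled


@dataclass
class StrainResult:
    """Per-element Green-Lagrange strain with a free-wall summary.

    ``e_ll`` is dimensionless (multiply by 100 for %); ``engineering`` is the
    stretch-ratio strain ``lambda - 1`` along the same direction, provided as
    a secondary column for comparability with speckle-tracking conventions.
    """

    tensors: np.ndarray  # (M, 2, 2)
    e_ll: np.ndarray  # (M,)
    engineering: np.ndarray  # (M,)
    labels: np.ndarray
    excluded: np.ndarray  # inverted elements, bool (M,)
    summary_label: str
    summary_mean: float
    n_retained: int
    n_excluded: int
    n_filled_nodes: int
    meta: dict = field(default_factory=dict)

    @property
    def summary_pct(self) -> float:
        return 100.0 * self.summary_mean


def deform_and_strain(
    mesh: WallMesh,
    field_: DisplacementField,
    summary_label: str = "rv_free_wall",
    area_weighted: bool = False,
    max_inverted_fraction: float = 0.2,
) -> StrainResult:
    """Deform the mesh by the displacement field and compute element strains.

    Inverted elements (``det F <= 0``) are excluded and counted; more than
    ``max_inverted_fraction`` of them is a hard error.  The summary is the
    mean ``E_LL`` over elements carrying ``summary_label``.
    """
    u_nodes, n_filled = sample_displacement(field_, mesh.nodes)
    ref = mesh.nodes[mesh.triangles]  # (M, 3, 2)
    cur = ref + u_nodes[mesh.triangles]

    dX = np.stack([ref[:, 1] - ref[:, 0], ref[:, 2] - ref[:, 0]], axis=-1)
    dx = np.stack([cur[:, 1] - cur[:, 0], cur[:, 2] - cur[:, 0]], axis=-1)
    F = dx @ np.linalg.inv(dX)
    detF = np.linalg.det(F)
    inverted = detF <= 0.0
    frac = inverted.mean() if len(inverted) else 0.0
    if frac > max_inverted_fraction:
        raise ValueError(
            f"{inverted.sum()} of {len(inverted)} elements inverted "
            f"({100 * frac:.0f}% > {100 * max_inverted_fraction:.0f}%)"
        )

    C = np.einsum("mki,mkj->mij", F, F)
    E = 0.5 * (C - np.eye(2))
    ell = mesh.longitudinal
    e_ll = np.einsum("mi,mij,mj->m", ell, E, ell)
    stretch_sq = np.maximum(1.0 + 2.0 * e_ll, 0.0)
    engineering = np.sqrt(stretch_sq) - 1.0

    sel = (mesh.labels == summary_label) & ~inverted
    if not sel.any():
        raise ValueError(f"no retained elements labelled {summary_label!r}")
    if area_weighted:
        w = mesh.element_areas()[sel]
        summary = float(np.average(e_ll[sel], weights=w))
    else:
        summary = float(e_ll[sel].mean())

    return StrainResult(
        tensors=E,
        e_ll=e_ll,
        engineering=engineering,
        labels=mesh.labels,
        excluded=inverted,
        summary_label=summary_label,
        summary_mean=summary,
        n_retained=int(sel.sum()),
        n_excluded=int(inverted.sum()),
        n_filled_nodes=n_filled,
        meta={"area_weighted": area_weighted},
    )


@dataclass
class CineTrackingResult:
    """Per-frame mean longitudinal strain curves and their peaks.

    ``average`` is the mean of the per-view peaks when at least two views
    were supplied, else None (flagged absent).
    """

    curves: dict  # view -> (n_frames,) strain fractions
    peaks: dict  # view -> most negative value
    peak_frames: dict  # view -> frame index of the peak
    average: Optional[float]


def _decode_frame(pair: PhasePair, mask: np.ndarray) -> DisplacementField:
    unwrapped = unwrap_phase(pair, mask)
    return anchor_component_offsets(decode_displacement(unwrapped))


def track_cine_lv(
    view_frames: Mapping[str, Sequence[Optional[PhasePair]]],
    view_meshes: Mapping[str, WallMesh],
    view_masks: Mapping[str, np.ndarray],
    summary_label: str = "lv_wall",
) -> CineTrackingResult:
    """Cine tracking: per-frame strain relative to end-diastole, per view.

    Each frame's phase pair encodes displacement relative to the
    end-diastolic frame (frame 0).  No temporal smoothing is applied.  The
    peak is the most negative value of each view's curve; the two-view
    average is reported only when both views are present.
    """
    curves, peaks, peak_frames = {}, {}, {}
    for view, frames in view_frames.items():
        missing = [i for i, f in enumerate(frames) if f is None]
        if missing:
            raise ValueError(f"view {view!r} has missing frames at indices {missing}")
        if len(frames) < 5:
            raise ValueError(f"view {view!r} has {len(frames)} frames; need >= 5")
        mesh = view_meshes[view]
        mask = view_masks[view]
        curve = np.empty(len(frames))
        for i, pair in enumerate(frames):
            field_ = _decode_frame(pair, mask)
            res = deform_and_strain(mesh, field_, summary_label=summary_label)
            curve[i] = res.summary_mean
        curves[view] = curve
        idx = int(np.argmin(curve))
        peaks[view] = float(curve[idx])
        peak_frames[view] = idx
    average = float(np.mean(list(peaks.values()))) if len(peaks) >= 2 else None
    return CineTrackingResult(curves=curves, peaks=peaks, peak_frames=peak_frames, average=average)
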