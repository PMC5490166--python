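"""Displacement-encoded phase processing: masking, unwrapping, decoding.

DENSE imaging stores tissue displacement in the phase of the complex image:
a pixel that moved ``u`` mm along the encoded direction carries phase
``2 pi k_e u`` (radians), wrapped into ``(-pi, pi]``.  At the study encoding
frequency ``k_e = 0.1`` cycles/mm the unambiguous displacement range is
``+/- 1/(2 k_e) = +/- 5`` mm; larger motion must be recovered by spatial
phase unwrapping followed by a per-region choice of the additive ``2 pi``
offset (anchoring).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "TWO_PI",
    "wrap_phase",
    "PhasePair",
    "DisplacementField",
    "unwrap_phase",
    "decode_displacement",
    "anchor_component_offsets",
]

TWO_PI = 2.0 * np.pi


def wrap_phase(phi):
    """Wrap phase (radians) into the half-open interval ``(-pi, pi]``."""
    phi = np.asarray(phi, dtype=float)
    return phi - TWO_PI * np.ceil((phi - np.pi) / TWO_PI)


@dataclass
class PhasePair:
    """Horizontal/vertical displacement-encoded phase images.

    ``phase_x`` encodes horizontal (x) displacement, ``phase_y`` vertical (y)
    displacement, both in radians.  Wrapped pairs keep every value in
    ``(-pi, pi]``; after :func:`unwrap_phase` the values may exceed that
    range and ``unwrapped`` is set.
    """

    phase_x: np.ndarray
    phase_y: np.ndarray
    pixel_spacing_mm: float
    k_e: float  # encoding frequency, cycles/mm
    frame: str = "ES"
    origin_mm: tuple = (0.0, 0.0)  # physical position of pixel (0, 0) centre
    unwrapped: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.phase_x = np.asarray(self.phase_x, float)
        self.phase_y = np.asarray(self.phase_y, float)
        if self.phase_x.shape != self.phase_y.shape:
            raise ValueError("phase_x and phase_y must share shape")
        if self.phase_x.ndim != 2:
            raise ValueError("phase images must be 2D")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        if not self.unwrapped:
            for name, arr in (("phase_x", self.phase_x), ("phase_y", self.phase_y)):
                if arr.size and (arr.max() > np.pi + 1e-9 or arr.min() <= -np.pi - 1e-9):
                    raise ValueError(f"{name} has values outside (-pi, pi]")

    @property
    def shape(self):
        return self.phase_x.shape


@dataclass
class DisplacementField:
    """Per-pixel in-plane displacement (mm) with validity mask.

    ``components`` labels the connected tissue regions that were unwrapped
    independently (0 = background); each component may still carry an
    unresolved additive offset of ``1/k_e`` mm until anchored.
    """

    u_x: np.ndarray
    u_y: np.ndarray
    mask: np.ndarray
    pixel_spacing_mm: float
    origin_mm: tuple = (0.0, 0.0)
    components: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.u_x = np.asarray(self.u_x, float)
        self.u_y = np.asarray(self.u_y, float)
        self.mask = np.asarray(self.mask, bool)
        if not (self.u_x.shape == self.u_y.shape == self.mask.shape):
            raise ValueError("displacement components and mask must share shape")
        if not np.all(np.isfinite(self.u_x[self.mask])) or not np.all(
            np.isfinite(self.u_y[self.mask])
        ):
            raise ValueError("displacement must be finite on the tissue mask")

    @property
    def shape(self):
        return self.mask.shape


_NEIGHBOURS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _gradient_variance_quality(phase: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Quality map: inverse (1 + variance) of the wrapped gradients to the
    4-neighbourhood.  High quality where phase is locally smooth."""
    nr, nc = phase.shape
    sums = np.zeros_like(phase)
    sqs = np.zeros_like(phase)
    cnt = np.zeros_like(phase)
    for dr, dc in _NEIGHBOURS:
        shifted = np.full_like(phase, np.nan)
        valid = np.zeros_like(mask)
        r0, r1 = max(dr, 0), nr + min(dr, 0)
        c0, c1 = max(dc, 0), nc + min(dc, 0)
        shifted[r0:r1, c0:c1] = phase[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        valid[r0:r1, c0:c1] = mask[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        valid &= mask
        d = wrap_phase(np.where(valid, shifted - phase, 0.0))
        sums += np.where(valid, d, 0.0)
        sqs += np.where(valid, d * d, 0.0)
        cnt += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, sums / np.maximum(cnt, 1), 0.0)
        var = np.where(cnt > 0, sqs / np.maximum(cnt, 1) - mean**2, 0.0)
    return 1.0 / (1.0 + np.maximum(var, 0.0))


def _unwrap_component(phase, comp_mask, quality):
    """Quality-guided flood fill within one connected component."""
    out = np.full(phase.shape, np.nan)
    rows, cols = np.nonzero(comp_mask)
    seed_i = np.argmax(quality[rows, cols])
    sr, sc = int(rows[seed_i]), int(cols[seed_i])
    out[sr, sc] = phase[sr, sc]
    visited = np.zeros(phase.shape, bool)
    visited[sr, sc] = True
    heap = [(-quality[sr, sc], sr, sc)]
    nr, nc = phase.shape
    while heap:
        _, r, c = heapq.heappop(heap)
        base = out[r, c]
        for dr, dc in _NEIGHBOURS:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and comp_mask[r2, c2] and not visited[r2, c2]:
                d = phase[r2, c2] - phase[r, c]
                out[r2, c2] = base + (d - TWO_PI * np.ceil((d - np.pi) / TWO_PI))
                visited[r2, c2] = True
                heapq.heappush(heap, (-quality[r2, c2], r2, c2))
    return out


def unwrap_phase(pair: PhasePair, mask: np.ndarray) -> PhasePair:
    """Spatially unwrap both phase images over the tissue mask.

    Each 4-connected component of the mask is unwrapped independently by a
    quality-guided flood fill (quality = inverse local variance of wrapped
    phase gradients).  Within a component the result equals the true phase up
    to one additive multiple of ``2 pi``; off-mask pixels are NaN.

    Raises
    ------
    ValueError
        If the mask is empty or contains no connected component of at least
        10 pixels.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != pair.shape:
        raise ValueError("mask shape must match the phase images")
    if not mask.any():
        raise ValueError("tissue mask is empty")
    components, n_comp = ndimage.label(mask)
    sizes = ndimage.sum_labels(mask, components, index=np.arange(1, n_comp + 1))
    if n_comp == 0 or sizes.max() < 10:
        raise ValueError("mask has no connected component of >= 10 pixels")

    out = {}
    for name, phase in (("phase_x", pair.phase_x), ("phase_y", pair.phase_y)):
        quality = _gradient_variance_quality(phase, mask)
        unwrapped = np.full(phase.shape, np.nan)
        for label in range(1, n_comp + 1):
            comp = components == label
            unwrapped = np.where(
                comp, _unwrap_component(phase, comp, quality), unwrapped
            )
        out[name] = unwrapped

    meta = dict(pair.meta)
    meta.update(mask=mask, components=components, n_components=int(n_comp))
    return replace(
        pair, phase_x=out["phase_x"], phase_y=out["phase_y"], unwrapped=True, meta=meta
    )


def decode_displacement(pair: PhasePair, mask: Optional[np.ndarray] = None) -> DisplacementField:
    """Convert unwrapped phase to displacement: ``u = phase / (2 pi k_e)`` mm."""
    if pair.k_e <= 0:
        raise ValueError("k_e must be positive")
    if not pair.unwrapped:
        raise ValueError("phase pair must be unwrapped before decoding")
    if mask is None:
        mask = pair.meta.get("mask")
    if mask is None:
        raise ValueError("a tissue mask is required (argument or pair.meta['mask'])")
    scale = 1.0 / (TWO_PI * pair.k_e)
    mask = np.asarray(mask, bool)
    ux = np.where(mask, pair.phase_x * scale, 0.0)
    uy = np.where(mask, pair.phase_y * scale, 0.0)
    return DisplacementField(
        u_x=ux,
        u_y=uy,
        mask=mask,
        pixel_spacing_mm=pair.pixel_spacing_mm,
        origin_mm=pair.origin_mm,
        components=pair.meta.get("components"),
        provenance={"k_e": pair.k_e, "frame": pair.frame, "anchored": False},
    )


def anchor_component_offsets(
    field_: DisplacementField,
    rule: str = "median",
    anchor_px: Optional[tuple] = None,
) -> DisplacementField:
    """Resolve the per-component additive offset of ``1/k_e`` mm.

    rule="median" (default): per component and per displacement direction,
    pick the integer offset multiple that minimises the median absolute
    displacement.  rule="anchor": the component containing ``anchor_px``
    (row, col) is shifted so that pixel decodes to zero displacement;
    remaining components fall back to the median rule.
    """
    k_e = field_.provenance.get("k_e")
    if k_e is None or k_e <= 0:
        raise ValueError("field provenance lacks a positive k_e")
    step = 1.0 / k_e  # mm per 2-pi wrap
    comps = field_.components
    if comps is None:
        comps = field_.mask.astype(int)
    if rule not in ("median", "anchor"):
        raise ValueError(f"unknown anchor rule {rule!r}")
    anchor_comp = None
    if rule == "anchor":
        if anchor_px is None:
            raise ValueError("rule='anchor' requires anchor_px")
        r, c = anchor_px
        if not field_.mask[r, c]:
            raise ValueError(f"anchor pixel {anchor_px} is off the tissue mask")
        anchor_comp = comps[r, c]

    ux = field_.u_x.copy()
    uy = field_.u_y.copy()
    offsets = {}
    for label in np.unique(comps[comps > 0]):
        sel = comps == label
        shifts = []
        for arr in (ux, uy):
            if label == anchor_comp:
                n = np.round(arr[anchor_px] / step)
            else:
                n = np.round(np.median(arr[sel]) / step)
            arr[sel] -= n * step
            shifts.append(int(n))
        offsets[int(label)] = tuple(shifts)

    prov = dict(field_.provenance)
    prov.update(anchored=True, anchor_rule=rule, offsets_removed=offsets)
    return replace(field_, u_x=ux, u_y=uy, provenance=prov)
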