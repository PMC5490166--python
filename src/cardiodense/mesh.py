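"""Triangulated myocardial wall meshes in the reference configuration.

The wall between an endocardial and an epicardial contour is meshed as a
structured strip: both contours are resampled by arc length, intermediate
layers are linear blends, and each quad is split into two triangles.  Every
element carries an anatomical label and a unit longitudinal direction -- the
local wall-centreline tangent, oriented in the base-to-apex sense of the
input contour ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
from shapely.geometry import LinearRing, LineString, Polygon

__all__ = ["WallMesh", "build_wall_mesh"]

#: anatomical labels used throughout the package
LABELS = ("rv_free_wall", "septum", "lv_wall")


@dataclass
class WallMesh:
    """Reference-configuration triangle mesh of a myocardial wall.

    nodes : (N, 2) float, mm.  triangles : (M, 3) int.  labels : (M,) str.
    longitudinal : (M, 2) unit vectors, wall-tangent, base -> apex.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    labels: np.ndarray
    longitudinal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, float)
        self.triangles = np.asarray(self.triangles, int)
        self.labels = np.asarray(self.labels, object)
        self.longitudinal = np.asarray(self.longitudinal, float)
        areas = self.element_areas()
        if np.any(areas <= 0):
            raise ValueError("mesh contains degenerate (non-positive-area) triangles")
        norms = np.linalg.norm(self.longitudinal, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("longitudinal vectors must be unit length")
        if len(self.labels) != len(self.triangles):
            raise ValueError("labels must cover all elements")

    def __len__(self):
        return len(self.triangles)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def min_angles_deg(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        angles = np.empty((len(self.triangles), 3))
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles[:, i] = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        return angles.min(axis=1)


def _is_closed(curve: np.ndarray) -> bool:
    return bool(np.allclose(curve[0], curve[-1], atol=1e-9))


def _check_simple(curve: np.ndarray, closed: bool, name: str) -> None:
    geom = LinearRing(curve) if closed else LineString(curve)
    if not geom.is_simple:
        raise ValueError(f"{name} contour is self-intersecting")


def _arclength_resample(curve: np.ndarray, n: int, closed: bool) -> np.ndarray:
    pts = np.asarray(curve, float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("contour has zero length")
    # closed curves omit the duplicated endpoint
    t = np.linspace(0.0, total, n, endpoint=not closed)
    return np.column_stack([np.interp(t, s, pts[:, 0]), np.interp(t, s, pts[:, 1])])


def _signed_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def build_wall_mesh(
    endo: np.ndarray,
    epi: np.ndarray,
    label: Union[str, Callable] = "rv_free_wall",
    target_edge_length_mm: float = 3.0,
    min_angle_deg: float = 15.0,
) -> WallMesh:
    """Mesh the wall region between an endo and an epi contour.

    Contours are ``(N, 2)`` arrays of mm coordinates.  Closed contours
    (first point == last point) produce an annular mesh; open contours a
    strip.  For open contours the vertex order defines the base-to-apex
    sense of the longitudinal direction; for closed contours the tangent
    follows the (counter-clockwise) ring orientation.

    ``label`` may be a single anatomical label or a callable
    ``label(s_frac, centroid) -> str`` mapping the normalized longitudinal
    coordinate and element centroid to a label.
    """
    endo = np.asarray(endo, float)
    epi = np.asarray(epi, float)
    if endo.ndim != 2 or endo.shape[1] != 2 or len(endo) < 3:
        raise ValueError("endo contour must be (N>=3, 2)")
    if epi.ndim != 2 or epi.shape[1] != 2 or len(epi) < 3:
        raise ValueError("epi contour must be (N>=3, 2)")
    closed = _is_closed(endo)
    if closed != _is_closed(epi):
        raise ValueError("endo and epi contours must both be open or both closed")
    _check_simple(endo, closed, "endo")
    _check_simple(epi, closed, "epi")

    if closed:
        endo_ring, epi_ring = endo[:-1], epi[:-1]
        if not Polygon(epi_ring).buffer(1e-9).contains(Polygon(endo_ring)):
            raise ValueError("epi contour must enclose the endo contour")
        # orient both rings counter-clockwise
        if _signed_area(endo_ring) < 0:
            endo_ring = endo_ring[::-1]
        if _signed_area(epi_ring) < 0:
            epi_ring = epi_ring[::-1]
        endo, epi = endo_ring, epi_ring
    else:
        # align epi direction with endo (endpoint proximity)
        same = np.linalg.norm(endo[0] - epi[0]) + np.linalg.norm(endo[-1] - epi[-1])
        flipped = np.linalg.norm(endo[0] - epi[-1]) + np.linalg.norm(endo[-1] - epi[0])
        if flipped < same:
            epi = epi[::-1]

    # resolution from the centreline length and mean wall thickness
    def _length(c):
        pts = np.vstack([c, c[:1]]) if closed else c
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    length = 0.5 * (_length(endo) + _length(epi))
    n_long = max(8, int(np.ceil(length / target_edge_length_mm)) + 1)
    endo_r = _arclength_resample(endo, n_long, closed)
    epi_r = _arclength_resample(epi, n_long, closed)
    if closed:
        # start epi parameterisation at the point nearest endo_r[0]
        j0 = int(np.argmin(np.linalg.norm(epi_r - endo_r[0], axis=1)))
        epi_r = np.roll(epi_r, -j0, axis=0)
    thickness = float(np.mean(np.linalg.norm(epi_r - endo_r, axis=1)))
    n_layers = max(3, int(np.ceil(thickness / target_edge_length_mm)) + 1)

    t = np.linspace(0.0, 1.0, n_layers)[:, None, None]
    grid = (1 - t) * endo_r[None] + t * epi_r[None]  # (layers, n_long, 2)
    nodes = grid.reshape(-1, 2)

    def nid(layer, j):
        return layer * n_long + (j % n_long)

    n_cols = n_long if closed else n_long - 1
    tris, tri_param = [], []
    for layer in range(n_layers - 1):
        for j in range(n_cols):
            a, b = nid(layer, j), nid(layer, j + 1)
            c, d = nid(layer + 1, j), nid(layer + 1, j + 1)
            tris.append((a, b, d))
            tris.append((a, d, c))
            tri_param.extend([(j + 0.5) / n_cols] * 2)
    triangles = np.asarray(tris, int)
    tri_param = np.asarray(tri_param)

    # enforce consistent positive orientation
    p = nodes[triangles]
    signed = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = signed < 0
    triangles[flip] = triangles[flip][:, ::-1]

    # centreline tangents (longitudinal direction)
    centre = 0.5 * (endo_r + epi_r)
    if closed:
        tang = np.roll(centre, -1, axis=0) - np.roll(centre, 1, axis=0)
    else:
        tang = np.gradient(centre, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    j_idx = np.clip((tri_param * n_cols).astype(int), 0, n_long - 1)
    if closed:
        mid = 0.5 * (tang[j_idx] + tang[(j_idx + 1) % n_long])
    else:
        mid = 0.5 * (tang[j_idx] + tang[np.minimum(j_idx + 1, n_long - 1)])
    mid /= np.linalg.norm(mid, axis=1, keepdims=True)

    centroids = nodes[triangles].mean(axis=1)
    if callable(label):
        labels = np.array([label(s, c) for s, c in zip(tri_param, centroids)], object)
    else:
        labels = np.full(len(triangles), label, object)

    mesh = WallMesh(
        nodes=nodes,
        triangles=triangles,
        labels=labels,
        longitudinal=mid,
        meta={
            "closed": closed,
            "n_long": n_long,
            "n_layers": n_layers,
            "target_edge_length_mm": target_edge_length_mm,
        },
    )
    worst = mesh.min_angles_deg().min()
    if worst < min_angle_deg:
        raise ValueError(
            f"mesh quality below contract: min element angle {worst:.1f} deg "
            f"< {min_angle_deg} deg (check contours)"
        )
    return mesh
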