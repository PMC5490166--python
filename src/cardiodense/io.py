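"""File formats: phantom HDF5 containers, NIfTI phase pairs, contour and
cohort CSV, and the machine-readable data dictionary.

Every container that carries phase data must declare the encoding frequency
``k_e`` (cycles/mm) and the pixel spacing (mm); inputs lacking either
attribute are refused by name.  Units are fixed per column and published in
:data:`DATA_DICTIONARY`.
"""

from __future__ import annotations

import json
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .dense import PhasePair
from .geometry import ContourStack, SliceContours
from .phantom import PhantomPair

__all__ = [
    "DATA_DICTIONARY",
    "write_data_dictionary",
    "save_phantom",
    "load_phantom",
    "load_phase_pair",
    "read_phase_pair_nifti",
    "write_strain_csv",
    "write_strain_vtk",
    "write_contours_csv",
    "read_contours_csv",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: column -> (unit, description); the single source of truth for units
DATA_DICTIONARY = {
    "id": ("", "subject identifier"),
    "group": ("", "weight group: obese_overweight | healthy"),
    "sex": ("", "F | M"),
    "age": ("yr", "age at scan"),
    "height": ("cm", "standing height"),
    "weight": ("kg", "body weight"),
    "bmi": ("kg/m^2", "body mass index, weight/height^2"),
    "bmi_percentile": ("percentile", "age/sex-standardised BMI percentile"),
    "bmi_z": ("z-score", "age/sex-standardised BMI z-score"),
    "heart_rate": ("beats/min", "resting heart rate"),
    "sbp": ("mmHg", "systolic blood pressure"),
    "dbp": ("mmHg", "diastolic blood pressure"),
    "map": ("mmHg", "mean arterial pressure, (sbp + 2 dbp)/3"),
    "abdominal_circ": ("cm", "abdominal circumference"),
    "waist_circ": ("cm", "waist circumference"),
    "hip_circ": ("cm", "hip circumference"),
    "waist_hip_ratio": ("", "waist/hip circumference ratio"),
    "lvmi": ("g/m^2.7", "LV mass indexed to height^2.7"),
    "lv_edv": ("mL", "LV end-diastolic volume"),
    "lv_mv_ratio": ("g/mL", "LV mass / end-diastolic volume"),
    "lv_ef": ("%", "LV ejection fraction"),
    "rv_edv": ("mL", "RV end-diastolic volume"),
    "rv_esv": ("mL", "RV end-systolic volume"),
    "rv_sv": ("mL", "RV stroke volume, EDV - ESV"),
    "rv_ef": ("%", "RV ejection fraction, SV/EDV x 100"),
    "rv_mass": ("g", "RV myocardial mass at 1.05 g/mL"),
    "rv_mass_index": ("g/m^2.7", "RV mass indexed to height^2.7"),
    "lv_ls": ("%", "LV peak longitudinal strain (negative = contraction)"),
    "rv_fwls": ("%", "RV free-wall longitudinal strain at end-systole"),
    "remodeling_class": ("", "normal_geometry | concentric_remodeling | "
                         "eccentric_hypertrophy | concentric_hypertrophy"),
    "rv_fwls_measured": ("%", "RV free-wall strain recovered from the phantom"),
    "rv_edv_measured": ("mL", "RV EDV from slice-stack volumetry"),
    "rv_esv_measured": ("mL", "RV ESV from slice-stack volumetry"),
    "rv_ef_measured": ("%", "RV EF from slice-stack volumetry"),
    "rv_mass_measured": ("g", "RV mass from slice-stack volumetry"),
    "rv_mass_index_measured": ("g/m^2.7", "measured RV mass / height^2.7"),
}


def write_data_dictionary(path) -> None:
    payload = {
        col: {"unit": unit, "description": desc}
        for col, (unit, desc) in DATA_DICTIONARY.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------- HDF5


def _ds(group, name, data):
    # track_times=False keeps repeated writes byte-identical
    group.create_dataset(name, data=data, track_times=False)


def save_phantom(phantom: PhantomPair, path) -> None:
    """Write a phantom acquisition (phase, truth, contours) to HDF5."""
    spec = phantom.spec
    with h5py.File(path, "w") as f:
        f.attrs["k_e"] = spec.k_e
        f.attrs["pixel_spacing_mm"] = spec.pixel_spacing_mm
        f.attrs["seed"] = spec.seed
        f.attrs["origin_mm"] = phantom.pair.origin_mm
        f.attrs["descriptor"] = phantom.field.descriptor
        f.attrs["wrapping_expected"] = bool(
            phantom.pair.meta.get("wrapping_expected", False)
        )
        ph = f.create_group("phase")
        _ds(ph, "x", phantom.pair.phase_x)
        _ds(ph, "y", phantom.pair.phase_y)
        tr = f.create_group("truth")
        _ds(tr, "displacement_x", phantom.truth_ux)
        _ds(tr, "displacement_y", phantom.truth_uy)
        _ds(tr, "strain", phantom.truth_strain)
        _ds(f, "mask", phantom.mask.astype(np.uint8))
        _ds(f, "rv_mask", phantom.rv_mask.astype(np.uint8))
        _ds(f, "lv_mask", phantom.lv_mask.astype(np.uint8))
        for frame, contours in (("ed", phantom.contours_ed), ("es", phantom.contours_es)):
            g = f.create_group(f"contours/{frame}")
            for name, poly in contours.items():
                _ds(g, name, poly)


def load_phase_pair(path) -> dict:
    """Read phase images, masks and truth back from a phantom container.

    Refuses files lacking the ``k_e`` or ``pixel_spacing_mm`` attribute.
    """
    with h5py.File(path, "r") as f:
        for attr in ("k_e", "pixel_spacing_mm"):
            if attr not in f.attrs:
                raise ValueError(f"input {path} lacks required attribute {attr!r}")
        pair = PhasePair(
            phase_x=f["phase/x"][()],
            phase_y=f["phase/y"][()],
            pixel_spacing_mm=float(f.attrs["pixel_spacing_mm"]),
            k_e=float(f.attrs["k_e"]),
            origin_mm=tuple(f.attrs.get("origin_mm", (0.0, 0.0))),
            meta={"wrapping_expected": bool(f.attrs.get("wrapping_expected", False))},
        )
        out = {
            "pair": pair,
            "mask": f["mask"][()].astype(bool),
            "rv_mask": f["rv_mask"][()].astype(bool),
            "lv_mask": f["lv_mask"][()].astype(bool),
            "truth_ux": f["truth/displacement_x"][()],
            "truth_uy": f["truth/displacement_y"][()],
            "truth_strain": f["truth/strain"][()],
            "contours_ed": {k: v[()] for k, v in f["contours/ed"].items()},
            "contours_es": {k: v[()] for k, v in f["contours/es"].items()},
            "seed": int(f.attrs.get("seed", -1)),
            "descriptor": str(f.attrs.get("descriptor", "")),
        }
    return out


#: alias: the container round-trip reader
load_phantom = load_phase_pair


def read_phase_pair_nifti(path_x, path_y, k_e: Optional[float] = None) -> PhasePair:
    """Read a phase pair from two single-slice NIfTI files.

    Pixel spacing is taken from the NIfTI header; ``k_e`` has no standard
    NIfTI slot and must be supplied, otherwise the input is refused.
    """
    import nibabel as nib

    if k_e is None:
        raise ValueError("input lacks required attribute 'k_e' (pass k_e=...)")
    imgs = [nib.load(p) for p in (path_x, path_y)]
    zooms = imgs[0].header.get_zooms()
    data = [np.squeeze(np.asanyarray(img.dataobj)).astype(float) for img in imgs]
    return PhasePair(
        phase_x=data[0],
        phase_y=data[1],
        pixel_spacing_mm=float(zooms[0]),
        k_e=float(k_e),
    )


# ------------------------------------------------------------ strain export


def write_strain_csv(mesh, result, path) -> None:
    """Element table: centroid, label, E components, E_LL, engineering strain."""
    c = mesh.element_centroids()
    df = pd.DataFrame(
        {
            "centroid_x_mm": c[:, 0],
            "centroid_y_mm": c[:, 1],
            "label": mesh.labels,
            "E_xx": result.tensors[:, 0, 0],
            "E_xy": result.tensors[:, 0, 1],
            "E_yy": result.tensors[:, 1, 1],
            "E_LL": result.e_ll,
            "engineering_strain": result.engineering,
            "excluded": result.excluded,
        }
    )
    df.to_csv(path, index=False)


def write_strain_vtk(mesh, result, path) -> None:
    """Legacy ASCII VTK polydata of the mesh with E_LL as cell data."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("cardiodense wall mesh with longitudinal strain\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.nodes)} float\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.6f} {y:.6f} 0.0\n")
        m = len(mesh.triangles)
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_DATA {m}\nSCALARS E_LL float 1\nLOOKUP_TABLE default\n")
        for v in result.e_ll:
            fh.write(f"{v:.6f}\n")


# ---------------------------------------------------------------- contours


def write_contours_csv(stack: ContourStack, path) -> None:
    """Contour stack as CSV polygon lists with '#key=value' metadata lines."""
    rows = []
    for i, sl in enumerate(stack.slices):
        for surface in ("endo", "epi"):
            poly = getattr(sl, surface)
            if poly is None:
                continue
            for vx, (x, y) in enumerate(poly):
                rows.append((i, surface, vx, x, y))
    df = pd.DataFrame(rows, columns=["slice", "surface", "vertex", "x_mm", "y_mm"])
    with open(path, "w") as fh:
        fh.write(f"#thickness_mm={stack.thickness_mm}\n")
        fh.write(f"#gap_mm={stack.gap_mm}\n")
        fh.write(f"#frame={stack.frame}\n")
        fh.write(f"#ventricle={stack.ventricle}\n")
        fh.write(f"#n_slices={len(stack.slices)}\n")
        df.to_csv(fh, index=False)


def read_contours_csv(path) -> ContourStack:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    required = {"slice", "surface", "x_mm", "y_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contour CSV missing columns: {sorted(missing)}")
    n_slices = int(meta.get("n_slices", df["slice"].max() + 1))
    slices = [SliceContours() for _ in range(n_slices)]
    for (idx, surface), sub in df.groupby(["slice", "surface"], sort=True):
        poly = sub.sort_values("vertex")[["x_mm", "y_mm"]].to_numpy(float)
        setattr(slices[int(idx)], surface, poly)
    return ContourStack(
        slices=slices,
        thickness_mm=float(meta["thickness_mm"]),
        gap_mm=float(meta.get("gap_mm", 0.0)),
        frame=meta.get("frame", "ED"),
        ventricle=meta.get("ventricle", "RV"),
    )


# ---------------------------------------------------------------- cohort


REQUIRED_COHORT_COLUMNS = ("id", "group")


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    missing = set(REQUIRED_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REQUIRED_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV schema error; missing columns: {sorted(missing)}")
    return df
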