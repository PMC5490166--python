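"""LV remodeling classification from mass index and mass/volume ratio.

Four classes are defined by two cutoffs established in a healthy pediatric
cohort: LV mass index (LVMI) 27.52 g/m^2.7 and mass/volume ratio (M/V)
0.69 g/mL.  Values exactly at a cutoff classify to the lower category
(strict inequality for "above"); this boundary convention is configurable
via the cutoffs but not via the comparison operator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CUTOFFS",
    "CLASS_NAMES",
    "RemodelingClass",
    "classify_remodeling",
    "group_counts",
]

#: (LVMI g/m^2.7, M/V g/mL)
DEFAULT_CUTOFFS: Tuple[float, float] = (27.52, 0.69)

CLASS_NAMES = (
    "normal_geometry",
    "concentric_remodeling",
    "eccentric_hypertrophy",
    "concentric_hypertrophy",
)


@dataclass(frozen=True)
class RemodelingClass:
    """Classification outcome with the inputs and cutoffs that produced it."""

    name: str
    lvmi: float
    mass_volume_ratio: float
    cutoffs: Tuple[float, float]


def classify_remodeling(
    lvmi: float,
    mv_ratio: float,
    cutoffs: Tuple[float, float] = DEFAULT_CUTOFFS,
) -> RemodelingClass:
    """Assign one of the four LV remodeling classes.

    ==================  ==========  =========
    class               LVMI        M/V
    ==================  ==========  =========
    normal_geometry     <= cutoff   <= cutoff
    concentric_remod.   <= cutoff   >  cutoff
    eccentric_hyper.    >  cutoff   <= cutoff
    concentric_hyper.   >  cutoff   >  cutoff
    ==================  ==========  =========
    """
    lvmi = float(lvmi)
    mv_ratio = float(mv_ratio)
    if not (np.isfinite(lvmi) and np.isfinite(mv_ratio)):
        raise ValueError("LVMI and mass/volume ratio must be finite")
    if lvmi <= 0 or mv_ratio <= 0:
        raise ValueError("LVMI and mass/volume ratio must be positive")
    lvmi_cut, mv_cut = cutoffs
    high_mass = lvmi > lvmi_cut
    high_ratio = mv_ratio > mv_cut
    if high_mass and high_ratio:
        name = "concentric_hypertrophy"
    elif high_mass:
        name = "eccentric_hypertrophy"
    elif high_ratio:
        name = "concentric_remodeling"
    else:
        name = "normal_geometry"
    return RemodelingClass(name, lvmi, mv_ratio, tuple(cutoffs))


def group_counts(classes) -> pd.DataFrame:
    """Counts and integer percentages per remodeling class.

    ``classes`` is an iterable of class-name strings (or RemodelingClass).
    All four classes appear in the output, zero counts included; percentages
    are rounded to the nearest integer.
    """
    names = [c.name if isinstance(c, RemodelingClass) else str(c) for c in classes]
    if len(names) == 0:
        raise ValueError("empty cohort")
    unknown = set(names) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown remodeling classes: {sorted(unknown)}")
    counts = pd.Series(names).value_counts()
    out = pd.DataFrame(
        {
            "n": [int(counts.get(c, 0)) for c in CLASS_NAMES],
        },
        index=pd.Index(CLASS_NAMES, name="class"),
    )
    out["pct"] = (100.0 * out["n"] / len(names)).round().astype(int)
    return out
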