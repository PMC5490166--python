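"""Synthetic cohort tables of pediatric cardiac measures.

Each group (obese/overweight vs healthy weight) is generated as a
correlated multivariate Gaussian over the core continuous variables, with
sex as a Bernoulli draw and a handful of variables derived
deterministically so internal identities hold (BMI from weight and height,
waist/hip ratio, stroke volume and ejection fraction from the volumes, RV
mass from its height-indexed value).  The default specification carries the
group means and SDs of the study population tables, so a large draw
reproduces the published group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = ["GroupSpec", "CohortSpec", "make_cohort", "study_cohort_spec"]

#: core variables drawn as correlated Gaussians, with units
CORE_VARIABLES = {
    "age": "yr",
    "height": "cm",
    "weight": "kg",
    "bmi_percentile": "percentile",
    "bmi_z": "z-score",
    "heart_rate": "beats/min",
    "sbp": "mmHg",
    "dbp": "mmHg",
    "abdominal_circ": "cm",
    "waist_circ": "cm",
    "hip_circ": "cm",
    "lvmi": "g/m^2.7",
    "lv_edv": "mL",
    "lv_mv_ratio": "g/mL",
    "lv_ef": "%",
    "rv_edv": "mL",
    "rv_esv": "mL",
    "rv_mass_index": "g/m^2.7",
    "lv_ls": "%",
    "rv_fwls": "%",
}


@dataclass(frozen=True)
class GroupSpec:
    """Per-group sample size, female proportion, and variable means/SDs."""

    n: int
    female_prop: float
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if not 0.0 <= self.female_prop <= 1.0:
            raise ValueError("female proportion must be in [0, 1]")
        for v, s in self.sds.items():
            if s < 0:
                raise ValueError(f"SD of {v!r} must be non-negative")
        missing = set(CORE_VARIABLES) - set(self.means)
        if missing:
            raise ValueError(f"means missing for variables: {sorted(missing)}")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generator specification.

    ``correlations`` maps unordered variable pairs to within-group Pearson
    correlations of the underlying Gaussians; unspecified pairs are
    independent.  The implied correlation matrix must be positive
    semi-definite.  ``bounds`` optionally clips a variable into a physical
    range after the correlated draw (used for the BMI percentile).
    """

    groups: Mapping[str, GroupSpec]
    correlations: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    bounds: Mapping[str, Tuple[float, float]] = field(default_factory=dict)

    def correlation_matrix(self) -> np.ndarray:
        names = list(CORE_VARIABLES)
        k = len(names)
        r = np.eye(k)
        for (a, b), val in self.correlations.items():
            if a not in names or b not in names:
                raise ValueError(f"correlation names unknown variable: ({a}, {b})")
            if not -1.0 <= val <= 1.0:
                raise ValueError(f"correlation ({a}, {b}) = {val} outside [-1, 1]")
            i, j = names.index(a), names.index(b)
            r[i, j] = r[j, i] = val
        return r

    def validate(self) -> None:
        r = self.correlation_matrix()
        eigvals, eigvecs = np.linalg.eigh(r)
        if eigvals.min() < -1e-8:
            vec = np.abs(eigvecs[:, 0])
            names = np.array(list(CORE_VARIABLES))
            offenders = names[np.argsort(vec)[::-1][:4]]
            raise ValueError(
                "requested correlation matrix is not positive semi-definite; "
                f"offending block involves: {list(offenders)}"
            )


def make_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Draw a cohort table; bit-reproducible for a fixed seed.

    Core variables converge to the requested means/SDs as n grows; derived
    columns (bmi, waist_hip_ratio, rv_sv, rv_ef, rv_mass, map) follow their
    defining identities instead.
    """
    spec.validate()
    names = list(CORE_VARIABLES)
    r = spec.correlation_matrix()
    eigvals, eigvecs = np.linalg.eigh(r)
    chol = eigvecs @ np.diag(np.sqrt(np.maximum(eigvals, 0.0)))
    rng = np.random.default_rng(seed)

    rows = []
    for gi, (gname, g) in enumerate(sorted(spec.groups.items())):
        z = rng.standard_normal((g.n, len(names))) @ chol.T
        data = {}
        for j, v in enumerate(names):
            x = g.means[v] + g.sds.get(v, 0.0) * z[:, j]
            if v in spec.bounds:
                lo, hi = spec.bounds[v]
                x = np.clip(x, lo, hi)
            data[v] = x
        sex = np.where(rng.random(g.n) < g.female_prop, "F", "M")
        sub = pd.DataFrame(data)
        sub.insert(0, "group", gname)
        sub.insert(0, "id", [f"{gname[:3]}-{i:04d}" for i in range(g.n)])
        sub.insert(2, "sex", sex)
        rows.append(sub)
    df = pd.concat(rows, ignore_index=True)

    h_m = df["height"] / 100.0
    df["bmi"] = df["weight"] / h_m**2
    df["waist_hip_ratio"] = df["waist_circ"] / df["hip_circ"]
    df["map"] = (df["sbp"] + 2.0 * df["dbp"]) / 3.0
    df["rv_sv"] = df["rv_edv"] - df["rv_esv"]
    df["rv_ef"] = 100.0 * df["rv_sv"] / df["rv_edv"]
    df["rv_mass"] = df["rv_mass_index"] * h_m**2.7
    return df


def study_cohort_spec(
    n_obese: int = 34,
    n_healthy: int = 36,
) -> CohortSpec:
    """The study-population conditions: group means/SDs of the cohort tables.

    Within-group correlations encode the structure the analyses rely on:
    taller children are heavier with larger hearts; the volumes of the two
    cardiac phases track each other; RV free-wall longitudinal strain
    correlates with LV strain, systolic pressure and adiposity, and its
    magnitude declines modestly through adolescence (positive correlation
    of the signed strain with age), consistent with parallel age-strain
    regression lines in the two weight groups.
    """
    obese = GroupSpec(
        n=n_obese,
        female_prop=0.56,
        means={
            "age": 12.1, "height": 155.0, "weight": 71.0,
            "bmi_percentile": 96.0, "bmi_z": 2.0, "heart_rate": 72.0,
            "sbp": 116.0, "dbp": 73.0, "abdominal_circ": 94.0,
            "waist_circ": 85.0, "hip_circ": 101.0,
            "lvmi": 27.0, "lv_edv": 135.0, "lv_mv_ratio": 0.68, "lv_ef": 62.0,
            "rv_edv": 149.0, "rv_esv": 60.0, "rv_mass_index": 8.2,
            "lv_ls": -14.0, "rv_fwls": -16.0,
        },
        sds={
            "age": 2.9, "height": 13.0, "weight": 23.0,
            "bmi_percentile": 4.0, "bmi_z": 0.4, "heart_rate": 9.0,
            "sbp": 13.0, "dbp": 6.0, "abdominal_circ": 16.0,
            "waist_circ": 14.0, "hip_circ": 16.0,
            "lvmi": 4.0, "lv_edv": 31.0, "lv_mv_ratio": 0.10, "lv_ef": 5.0,
            "rv_edv": 38.0, "rv_esv": 17.0, "rv_mass_index": 0.9,
            "lv_ls": 2.0, "rv_fwls": 4.0,
        },
    )
    healthy = GroupSpec(
        n=n_healthy,
        female_prop=0.47,
        means={
            "age": 13.6, "height": 160.0, "weight": 50.0,
            "bmi_percentile": 48.0, "bmi_z": -0.1, "heart_rate": 70.0,
            "sbp": 109.0, "dbp": 71.0, "abdominal_circ": 72.0,
            "waist_circ": 67.0, "hip_circ": 84.0,
            "lvmi": 22.0, "lv_edv": 133.0, "lv_mv_ratio": 0.60, "lv_ef": 62.0,
            "rv_edv": 147.0, "rv_esv": 59.0, "rv_mass_index": 6.7,
            "lv_ls": -15.0, "rv_fwls": -19.0,
        },
        sds={
            "age": 2.7, "height": 17.0, "weight": 14.0,
            "bmi_percentile": 23.0, "bmi_z": 0.7, "heart_rate": 8.0,
            "sbp": 8.0, "dbp": 6.0, "abdominal_circ": 7.0,
            "waist_circ": 6.0, "hip_circ": 10.0,
            "lvmi": 3.0, "lv_edv": 41.0, "lv_mv_ratio": 0.06, "lv_ef": 4.0,
            "rv_edv": 46.0, "rv_esv": 23.0, "rv_mass_index": 1.1,
            "lv_ls": 2.0, "rv_fwls": 5.0,
        },
    )
    correlations = {
        ("height", "weight"): 0.5,
        ("waist_circ", "hip_circ"): 0.6,
        ("waist_circ", "abdominal_circ"): 0.7,
        ("sbp", "dbp"): 0.4,
        ("height", "lv_edv"): 0.5,
        ("height", "rv_edv"): 0.5,
        ("height", "rv_esv"): 0.45,
        ("lv_edv", "rv_edv"): 0.5,
        ("lv_edv", "rv_esv"): 0.4,
        ("rv_edv", "rv_esv"): 0.85,
        ("lvmi", "rv_mass_index"): 0.45,
        ("rv_mass_index", "bmi_z"): 0.40,
        ("rv_fwls", "lv_ls"): 0.34,
        ("rv_fwls", "sbp"): 0.33,
        ("rv_fwls", "hip_circ"): 0.30,
        ("rv_fwls", "age"): 0.20,
        ("lv_ls", "age"): 0.15,
    }
    return CohortSpec(
        groups={"obese_overweight": obese, "healthy": healthy},
        correlations=correlations,
        bounds={
            "bmi_percentile": (0.0, 100.0),
            "height": (110.0, 210.0),
            "weight": (15.0, 200.0),
            "lv_edv": (30.0, 400.0),
            "rv_edv": (30.0, 400.0),
            "rv_esv": (5.0, 300.0),
            "lvmi": (5.0, 80.0),
            "lv_mv_ratio": (0.2, 2.0),
            "rv_mass_index": (1.0, 30.0),
        },
    )
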