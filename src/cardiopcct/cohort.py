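"""Synthetic cohort generation with the study's group structure.

The generator emulates a 140-mouse cohort crossing APOE genotype
(APOE2/3/4), sex, exercise and the HN factor (presence of the humanized
NOS2 innate-immune component), with per-cell sample sizes and per-cell
metric means/SDs taken from the published group-summary tables embedded
below.  Metrics are drawn independently per cell from truncated normal
distributions by default (gamma optionally, to emulate the right-skewed
behaviour of EF and myocardial mass); the published tables are treated as
the population parameters, so cell means converge to them as the per-cell n
grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENOTYPES",
    "SEXES",
    "METRICS",
    "TABLE1_GROUP_SIZES",
    "TABLE2_HN_FRACTION",
    "TABLE4_GROUP_STATS",
    "CohortSpec",
    "generate_cohort",
    "summarize_cohort",
    "table4_means_table",
]

GENOTYPES = ("apoe2", "apoe3", "apoe4")
SEXES = ("male", "female")
EXERCISE = ("yes", "no")
METRICS = ("mass", "HR", "SV", "EF", "CO", "CI", "RVSV", "RVEF", "MM")

# Per-cell animal counts, (genotype, sex, exercise) -> n.
TABLE1_GROUP_SIZES = {
    ("apoe2", "female", "yes"): 20, ("apoe2", "female", "no"): 7,
    ("apoe2", "male", "yes"): 18, ("apoe2", "male", "no"): 9,
    ("apoe3", "female", "yes"): 15, ("apoe3", "female", "no"): 8,
    ("apoe3", "male", "yes"): 16, ("apoe3", "male", "no"): 6,
    ("apoe4", "female", "yes"): 12, ("apoe4", "female", "no"): 7,
    ("apoe4", "male", "yes"): 12, ("apoe4", "male", "no"): 10,
}

# Fraction of animals per genotype carrying the HN factor.
TABLE2_HN_FRACTION = {"apoe2": 0.426, "apoe3": 0.488, "apoe4": 0.488}

# Per-cell (mean, SD) of each metric, (sex, genotype, exercise) keyed.
# Units: mass g, HR beats/min, SV mL, EF %, CO mL/min, CI mL/min/g, RVSV mL,
# RVEF fraction, MM mg.
TABLE4_GROUP_STATS = {
    ("male", "apoe2", "yes"): {
        "mass": (31.467, 1.439), "HR": (468.571, 47.003), "SV": (0.033, 0.008),
        "EF": (55.104, 6.379), "CO": (15.253, 3.840), "CI": (0.484, 0.117),
        "RVSV": (0.030, 0.007), "RVEF": (0.484, 0.077), "MM": (197.4, 42.2)},
    ("male", "apoe2", "no"): {
        "mass": (31.678, 1.707), "HR": (470.857, 48.618), "SV": (0.026, 0.006),
        "EF": (47.106, 11.716), "CO": (12.176, 3.856), "CI": (0.382, 0.112),
        "RVSV": (0.025, 0.007), "RVEF": (0.416, 0.117), "MM": (203.1, 35.2)},
    ("male", "apoe3", "yes"): {
        "mass": (34.131, 1.826), "HR": (464.786, 45.435), "SV": (0.033, 0.005),
        "EF": (51.988, 5.775), "CO": (15.268, 3.175), "CI": (0.448, 0.090),
        "RVSV": (0.030, 0.005), "RVEF": (0.447, 0.089), "MM": (197.4, 22.9)},
    ("male", "apoe3", "no"): {
        "mass": (33.750, 5.381), "HR": (430.429, 15.452), "SV": (0.023, 0.002),
        "EF": (39.746, 8.566), "CO": (10.058, 1.367), "CI": (0.307, 0.072),
        "RVSV": (0.021, 0.002), "RVEF": (0.354, 0.049), "MM": (188.4, 27.3)},
    ("male", "apoe4", "yes"): {
        "mass": (30.750, 2.248), "HR": (483.286, 25.255), "SV": (0.033, 0.007),
        "EF": (52.396, 7.984), "CO": (15.666, 3.085), "CI": (0.509, 0.093),
        "RVSV": (0.029, 0.005), "RVEF": (0.499, 0.059), "MM": (202.2, 36.8)},
    ("male", "apoe4", "no"): {
        "mass": (26.640, 5.371), "HR": (448.714, 26.367), "SV": (0.020, 0.004),
        "EF": (44.511, 7.540), "CO": (8.938, 1.627), "CI": (0.348, 0.094),
        "RVSV": (0.018, 0.004), "RVEF": (0.379, 0.075), "MM": (151.8, 27.9)},
    ("female", "apoe2", "yes"): {
        "mass": (26.510, 1.981), "HR": (449.743, 48.957), "SV": (0.028, 0.005),
        "EF": (56.147, 6.017), "CO": (12.547, 2.863), "CI": (0.474, 0.105),
        "RVSV": (0.025, 0.004), "RVEF": (0.494, 0.062), "MM": (157.3, 21.2)},
    ("female", "apoe2", "no"): {
        "mass": (25.929, 4.555), "HR": (464.571, 18.582), "SV": (0.025, 0.005),
        "EF": (60.886, 6.161), "CO": (11.782, 2.314), "CI": (0.457, 0.066),
        "RVSV": (0.023, 0.005), "RVEF": (0.488, 0.022), "MM": (141.3, 16.8)},
    ("female", "apoe3", "yes"): {
        "mass": (27.887, 2.244), "HR": (470.800, 42.496), "SV": (0.024, 0.007),
        "EF": (52.783, 13.221), "CO": (11.510, 3.286), "CI": (0.412, 0.113),
        "RVSV": (0.023, 0.008), "RVEF": (0.481, 0.100), "MM": (153.8, 31.1)},
    ("female", "apoe3", "no"): {
        "mass": (29.438, 1.586), "HR": (448.821, 28.004), "SV": (0.021, 0.005),
        "EF": (45.652, 10.075), "CO": (9.291, 2.433), "CI": (0.317, 0.092),
        "RVSV": (0.018, 0.005), "RVEF": (0.406, 0.130), "MM": (156.8, 15.1)},
    ("female", "apoe4", "yes"): {
        "mass": (26.267, 5.062), "HR": (489.500, 27.180), "SV": (0.024, 0.003),
        "EF": (58.190, 5.623), "CO": (11.722, 1.642), "CI": (0.455, 0.066),
        "RVSV": (0.022, 0.003), "RVEF": (0.537, 0.060), "MM": (150.9, 16.9)},
    ("female", "apoe4", "no"): {
        "mass": (28.400, 2.772), "HR": (455.755, 51.694), "SV": (0.018, 0.006),
        "EF": (44.509, 13.259), "CO": (8.330, 3.413), "CI": (0.296, 0.128),
        "RVSV": (0.019, 0.005), "RVEF": (0.463, 0.152), "MM": (154.2, 15.0)},
}


@dataclass
class CohortSpec:
    """Cohort generator parameters; all defaults mirror the study tables."""

    group_params: dict = field(default_factory=lambda: dict(TABLE4_GROUP_STATS))
    group_sizes: dict = field(default_factory=lambda: dict(TABLE1_GROUP_SIZES))
    hn_fraction: dict = field(default_factory=lambda: dict(TABLE2_HN_FRACTION))
    metric_families: dict = field(default_factory=dict)  # metric -> "normal"|"gamma"
    seed: int | None = None

    def __post_init__(self):
        for cell, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group size for {cell} must be >= 1")
        for cell, params in self.group_params.items():
            for metric, (mean, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {metric} in cell {cell}")
        if self.seed is None:
            raise ValueError("cohort generation requires an explicit seed")


def _draw(rng: np.random.Generator, mean: float, sd: float, n: int,
          family: str) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    if family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd ** 2 / mean
        return rng.gamma(shape, scale, size=n)
    if family == "normal":
        a = (0.0 - mean) / sd  # truncate at zero
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                                   random_state=rng)
    raise ValueError(f"unknown metric family {family!r}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-animal cohort table from the per-cell distributions.

    Columns: ``animal_id``, lowercase factor columns (``genotype``, ``sex``,
    ``exercise``), integer ``hn`` (0/1) and the metric columns of
    :data:`METRICS`.  Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    counter = 0
    for genotype in GENOTYPES:
        for sex in SEXES:
            for exercise in EXERCISE:
                key_n = (genotype, sex, exercise)
                key_p = (sex, genotype, exercise)
                if key_n not in spec.group_sizes:
                    raise ValueError(f"missing group size for cell {key_n}")
                if key_p not in spec.group_params:
                    raise ValueError(f"missing distribution parameters for cell {key_p}")
                n = spec.group_sizes[key_n]
                params = spec.group_params[key_p]
                missing = [m for m in METRICS if m not in params]
                if missing:
                    raise ValueError(f"cell {key_p} lacks parameters for {missing}")
                draws = {
                    m: _draw(rng, *params[m], n,
                             spec.metric_families.get(m, "normal"))
                    for m in METRICS
                }
                hn = (rng.random(n) < spec.hn_fraction[genotype]).astype(int)
                for i in range(n):
                    rows.append({
                        "animal_id": f"M{counter + i:03d}",
                        "genotype": genotype, "sex": sex, "exercise": exercise,
                        "hn": int(hn[i]),
                        **{m: float(draws[m][i]) for m in METRICS},
                    })
                counter += n
    return pd.DataFrame(rows)


def summarize_cohort(group_sizes: dict | None = None) -> pd.DataFrame:
    """Per-genotype composition: male/female counts and percent exercised.

    Reproduces the study's composition overview from the per-cell counts
    (percentages rounded to one decimal).
    """
    sizes = dict(TABLE1_GROUP_SIZES) if group_sizes is None else group_sizes
    rows = {}
    for genotype in GENOTYPES:
        male = sum(v for (g, s, e), v in sizes.items() if g == genotype and s == "male")
        female = sum(v for (g, s, e), v in sizes.items() if g == genotype and s == "female")
        exercised = sum(v for (g, s, e), v in sizes.items()
                        if g == genotype and e == "yes")
        total = male + female
        rows[genotype] = {
            "male": male, "female": female, "total": total,
            "exercise_pct": round(100.0 * exercised / total, 1),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def table4_means_table() -> pd.DataFrame:
    """One row per (sex, genotype, exercise) cell holding the printed means.

    Feeding this to :func:`cardiopcct.metrics.percent_group_difference`
    evaluates the published percent-difference statements directly on the
    printed group means.
    """
    rows = []
    for (sex, genotype, exercise), params in TABLE4_GROUP_STATS.items():
        rows.append({"sex": sex, "genotype": genotype, "exercise": exercise,
                     **{m: mean for m, (mean, sd) in params.items()}})
    return pd.DataFrame(rows)
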