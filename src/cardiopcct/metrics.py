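"""Cardiac function metrics derived from phase-resolved segmentations.

From the chamber volume curve across the cardiac cycle:

* ``SV  = EDV - ESV``            (stroke volume, mL)
* ``EF  = 100 * SV / EDV``       (ejection fraction, percent)
* ``CO  = SV * HR``              (cardiac output, mL/min)
* ``CI  = CO / mass``            (cardiac index, mL/min/g)
* ``MM`` = mean of the diastolic and systolic myocardial volume times an
  assumed tissue density of 1.053 g/mL, reported in mg.

The same quantities computed from the right-ventricle segmentation carry an
``RV`` prefix; RVEF is stored as a *fraction* with an explicit unit flag
(group-summary tables in this field print it that way while EF is in
percent), and is never silently rescaled.

End-diastole and end-systole are selected as the phases with maximal and
minimal chamber volume; the heart rate comes from the intrinsic gating stage
(single source of truth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import STRUCTURE_IDS

__all__ = [
    "MYOCARDIUM_DENSITY_G_PER_ML",
    "ChamberVolumes",
    "CardiacMetrics",
    "chamber_volumes",
    "select_ed_es",
    "compute_metrics",
    "metrics_from_labels",
    "percent_group_difference",
    "INCONSISTENT_RESULTS_STATEMENTS",
]

MYOCARDIUM_DENSITY_G_PER_ML = 1.053

# Percent-difference statements in the source study's narrative that do not
# match its own printed group means (catalogued, not reproduced):
# stated -> value implied by the printed table.
INCONSISTENT_RESULTS_STATEMENTS = {
    ("SV", "apoe3", "male"): {"stated": 44, "table": 43},
    ("CO", "apoe3", "male"): {"stated": 51, "table": 52},
    ("CO", "apoe4", "female", "alt"): {"stated": 30, "table": 41},
    ("CI", "apoe4", "female"): {"stated": 44, "table": 54},
}


@dataclass
class ChamberVolumes:
    """Per-structure volume (mL) at every cardiac phase."""

    volumes: dict  # structure name -> (n_phases,) mL
    voxel_size: float  # mm

    def for_chamber(self, chamber: str) -> np.ndarray:
        if chamber not in self.volumes:
            raise KeyError(f"no volumes for chamber {chamber!r}")
        return self.volumes[chamber]


@dataclass
class CardiacMetrics:
    """Per-animal record of the derived function metrics."""

    SV: float  # mL
    EF: float  # percent
    CO: float  # mL/min
    CI: float  # mL/min/g
    MM: float  # mg
    HR: float  # beats/min
    mass: float  # g
    EDV: float  # mL
    ESV: float  # mL
    RVSV: float | None = None  # mL
    RVEF: float | None = None  # fraction (see rvef_unit)
    rvef_unit: str = "fraction"
    ed_phase: int | None = None
    es_phase: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.EF <= 100.0):
            raise ValueError("EF must be within [0, 100] percent")
        if self.SV > self.EDV + 1e-12:
            raise ValueError("SV cannot exceed EDV")


def chamber_volumes(labels_per_phase: np.ndarray, voxel_size: float) -> ChamberVolumes:
    """Voxel-count volumes (mL) for all 8 structures at each phase.

    ``labels_per_phase`` is (n_phases, nz, ny, nx); a voxel contributes
    ``voxel_size**3`` mm^3 = ``voxel_size**3 / 1000`` mL.
    """
    labels = np.asarray(labels_per_phase)
    if labels.ndim != 4:
        raise ValueError("labels must be (n_phases, nz, ny, nx)")
    shapes = {labels[p].shape for p in range(labels.shape[0])}
    if len(shapes) != 1:
        raise ValueError("inconsistent label shapes across phases")
    voxel_ml = (voxel_size ** 3) / 1000.0
    vols = {
        name: np.array([(labels[p] == sid).sum() for p in range(labels.shape[0])],
                       dtype=float) * voxel_ml
        for name, sid in STRUCTURE_IDS.items()
    }
    return ChamberVolumes(volumes=vols, voxel_size=voxel_size)


def select_ed_es(volumes: ChamberVolumes, chamber: str = "LV"):
    """(EDV, ESV, ed_phase, es_phase): max/min of the chamber volume curve."""
    v = volumes.for_chamber(chamber)
    if len(v) < 2:
        raise ValueError("need >= 2 phases to select ED and ES")
    ed, es = int(np.argmax(v)), int(np.argmin(v))
    if np.isclose(v[ed], v[es]):
        warnings.warn(f"{chamber} volume constant across phases; SV = 0")
    return float(v[ed]), float(v[es]), ed, es


def compute_metrics(EDV: float, ESV: float, HR: float, mass: float,
                    myo_volumes: tuple | None = None,
                    rv_EDV: float | None = None, rv_ESV: float | None = None,
                    ed_phase: int | None = None, es_phase: int | None = None) -> CardiacMetrics:
    """Assemble the per-animal metric record from volumes, HR and body mass.

    ``myo_volumes`` is the (diastolic, systolic) myocardial volume pair in
    mL; myocardial mass averages exactly these two phases.
    """
    if not (EDV >= ESV >= 0.0):
        raise ValueError("need EDV >= ESV >= 0")
    if HR <= 0 or mass <= 0:
        raise ValueError("HR and mass must be > 0")
    if EDV == 0.0:
        raise ValueError("EF undefined: EDV is zero")
    SV = EDV - ESV
    EF = 100.0 * SV / EDV
    CO = SV * HR
    CI = CO / mass
    MM = None
    if myo_volumes is not None:
        MM = float(np.mean(myo_volumes)) * MYOCARDIUM_DENSITY_G_PER_ML * 1000.0  # mg
    RVSV = RVEF = None
    if rv_EDV is not None and rv_ESV is not None:
        if not (rv_EDV >= rv_ESV >= 0) or rv_EDV == 0:
            raise ValueError("invalid right-ventricle volumes")
        RVSV = rv_EDV - rv_ESV
        RVEF = RVSV / rv_EDV  # fraction, by convention
    return CardiacMetrics(SV=SV, EF=EF, CO=CO, CI=CI, MM=MM, HR=HR, mass=mass,
                          EDV=EDV, ESV=ESV, RVSV=RVSV, RVEF=RVEF,
                          ed_phase=ed_phase, es_phase=es_phase)


def metrics_from_labels(labels_per_phase: np.ndarray, voxel_size: float,
                        HR: float, mass: float) -> CardiacMetrics:
    """Full path from phase-resolved labels to the metric record."""
    vols = chamber_volumes(labels_per_phase, voxel_size)
    EDV, ESV, ed, es = select_ed_es(vols, "LV")
    rv = vols.for_chamber("RV")
    myo = vols.for_chamber("myocardium")
    return compute_metrics(EDV, ESV, HR, mass,
                           myo_volumes=(float(myo[ed]), float(myo[es])),
                           rv_EDV=float(rv.max()), rv_ESV=float(rv.min()),
                           ed_phase=ed, es_phase=es)


def percent_group_difference(table: pd.DataFrame, metric: str,
                             cell_a: dict, cell_b: dict,
                             rounded: bool = True) -> float:
    """Percent difference of group means, 100 * (mean_a - mean_b) / mean_b.

    ``cell_a``/``cell_b`` select rows by factor values, e.g.
    ``{"sex": "male", "genotype": "apoe3", "exercise": "yes"}``.  Rounded to
    the nearest integer percent for reporting (pass ``rounded=False`` for the
    raw value).
    """
    def cell_mean(cell: dict) -> float:
        mask = pd.Series(True, index=table.index)
        for col, val in cell.items():
            mask &= table[col].astype(str).str.lower() == str(val).lower()
        sub = table.loc[mask, metric]
        if len(sub) == 0:
            raise ValueError(f"no rows match cell {cell}")
        return float(sub.mean())

    mean_a, mean_b = cell_mean(cell_a), cell_mean(cell_b)
    if mean_b == 0:
        raise ValueError("reference cell mean is zero")
    pct = 100.0 * (mean_a - mean_b) / mean_b
    return float(round(pct)) if rounded else pct
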