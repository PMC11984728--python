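"""Basis-material decomposition of multi-energy reconstructions.

With one effective energy per counting bin, the reconstructed attenuation of
a voxel is linear in the basis-material content: ``x = M c``, where column
``m`` of the sensitivity matrix ``M`` holds the attenuation per unit
concentration of material ``m`` at each bin energy.  The iodine K-edge at
33.2 keV between the first two bins is what makes iodine separable from
tissue-like bases.  Concentrations are recovered per voxel by least squares
under a non-negativity constraint, solved by an active-set scheme: the most
negative material is removed from the active set and the system re-solved in
the reduced column subspace until the optimum is reached (removed components
are reported as exactly zero).

Two basis presets are shipped: (iodine, photoelectric, Compton) and
(iodine, calcium, water).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import attenuation_coefficient
from .reconstruction import Volume5D

__all__ = [
    "SensitivityMatrix",
    "MaterialMaps",
    "calibrate_sensitivity",
    "sensitivity_from_model",
    "decompose",
    "nnls_active_set",
]


@dataclass
class SensitivityMatrix:
    """Energies x materials attenuation-per-unit-concentration matrix."""

    M: np.ndarray  # (n_energies, n_materials)
    materials: tuple
    units: tuple  # per-column concentration units
    energies_kev: np.ndarray | None = None

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[1] != len(self.materials):
            raise ValueError("M must be (n_energies, n_materials)")
        if np.linalg.matrix_rank(self.M) < self.M.shape[1]:
            raise ValueError(
                "bases not separable at these energies: sensitivity matrix is "
                f"rank deficient (materials {self.materials})")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.M))


@dataclass
class MaterialMaps:
    """Per-voxel, per-phase basis-material concentrations."""

    C: np.ndarray  # (n_materials, n_phases, nz, ny, nx)
    materials: tuple
    units: tuple
    voxel_size: float

    def map_for(self, material: str) -> np.ndarray:
        return self.C[self.materials.index(material)]


def calibrate_sensitivity(calibrations: list, materials: tuple,
                          units: tuple | None = None,
                          energies_kev: np.ndarray | None = None) -> SensitivityMatrix:
    """Build ``M`` from measurements of single-material calibration objects.

    ``calibrations`` holds one ``(attenuations, concentration, material)``
    triple per material: ``attenuations`` is the reconstructed value of the
    calibration region at each energy (any array whose first axis is energy;
    trailing axes are averaged), ``concentration`` the known content.  Column
    ``m`` is the mean attenuation divided by the concentration.
    """
    cols = {}
    for atten, conc, name in calibrations:
        if conc <= 0:
            raise ValueError(f"calibration concentration for {name!r} must be > 0")
        a = np.asarray(atten, dtype=float)
        vec = a.reshape(a.shape[0], -1).mean(axis=1)
        cols[name] = vec / conc
    missing = [m for m in materials if m not in cols]
    if missing:
        raise ValueError(f"no calibration object for material(s) {missing}")
    M = np.stack([cols[m] for m in materials], axis=1)
    if units is None:
        units = tuple("per unit concentration" for _ in materials)
    return SensitivityMatrix(M=M, materials=tuple(materials), units=tuple(units),
                             energies_kev=energies_kev)


def sensitivity_from_model(energies_kev: np.ndarray, preset: str = "iodine_ca_water",
                           voxel_size: float = 0.125) -> SensitivityMatrix:
    """Sensitivity matrix from the package's attenuation model.

    Values are attenuation per voxel length (matching reconstructed volumes)
    per unit concentration: mg/mL for iodine and calcium-like bases, volume
    fraction for water / soft tissue.  ``preset`` is ``"iodine_ca_water"``,
    ``"iodine_water"`` (two-bin acquisitions), ``"iodine_pe_cs"``
    (photoelectric ~ E^-3 and Compton ~ flat basis functions instead of
    material columns), or ``"auto"`` (basis size chosen from the bin count).
    """
    e = np.asarray(energies_kev, dtype=float)
    if preset == "auto":
        preset = "iodine_ca_water" if len(e) >= 3 else "iodine_water"
    if preset == "iodine_water":
        iodine = np.array([attenuation_coefficient("iodine", ei) for ei in e])
        water = np.array([attenuation_coefficient("water", ei) for ei in e])
        M = np.stack([iodine, water], axis=1) * voxel_size
        return SensitivityMatrix(M=M, materials=("iodine", "water"),
                                 units=("mg/mL", "fraction"), energies_kev=e)
    if preset == "iodine_ca_water":
        iodine = np.array([attenuation_coefficient("iodine", ei) for ei in e])
        water = np.array([attenuation_coefficient("water", ei) for ei in e])
        # calcium-like basis: scaled E^-3 photoelectric column (no K-edge in band)
        ca = 1.0e-3 * (30.0 / e) ** 3 + 2.0e-4
        M = np.stack([iodine, ca, water], axis=1) * voxel_size
        return SensitivityMatrix(M=M, materials=("iodine", "calcium", "water"),
                                 units=("mg/mL", "mg/mL", "fraction"),
                                 energies_kev=e)
    if preset == "iodine_pe_cs":
        iodine = np.array([attenuation_coefficient("iodine", ei) for ei in e])
        pe = (30.0 / e) ** 3
        cs = np.ones_like(e)
        M = np.stack([iodine * voxel_size, pe, cs], axis=1)
        return SensitivityMatrix(M=M, materials=("iodine", "photoelectric", "compton"),
                                 units=("mg/mL", "a.u.", "a.u."),
                                 energies_kev=e)
    raise ValueError(f"unknown preset {preset!r}")


def nnls_active_set(M: np.ndarray, b: np.ndarray, tol: float = 1.0e-12) -> np.ndarray:
    """Non-negative least squares by active-set descent with re-entry.

    Starts from the unconstrained solution; while any coefficient is
    negative, the most negative material is dropped and the reduced system
    re-solved.  Dropped materials whose optimality (KKT) multiplier turns
    positive re-enter the passive set, so the returned solution is the true
    constrained optimum, not merely a feasible point.
    """
    n = M.shape[1]
    passive = np.ones(n, dtype=bool)
    for _ in range(4 ** n):  # generous bound; typically 1-3 iterations
        c = np.zeros(n)
        if passive.any():
            sol, *_ = np.linalg.lstsq(M[:, passive], b, rcond=None)
            c[passive] = sol
        if np.any(c < -tol):
            worst = np.argmin(np.where(passive, c, np.inf))
            passive[worst] = False
            continue
        c = np.maximum(c, 0.0)
        grad = M.T @ (b - M @ c)  # KKT multipliers of the dropped materials
        blocked = ~passive & (grad > tol)
        if not blocked.any():
            return c
        passive[np.argmax(np.where(blocked, grad, -np.inf))] = True
    raise RuntimeError("active-set NNLS failed to converge")


def _nnls_batch(M: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Constrained least squares for many right-hand sides at once.

    For a small material count the non-negative optimum is found exactly by
    enumerating every passive-set candidate (all column subsets), keeping
    per voxel the feasible candidate with the smallest residual -- the same
    optimum the active-set solver reaches, fully vectorised over voxels.
    ``B`` is (n_voxels, n_energies); returns (n_voxels, n_materials).
    """
    n_mat = M.shape[1]
    n = B.shape[0]
    best = np.zeros((n, n_mat))
    best_r2 = np.einsum("ne,ne->n", B, B)  # the all-zero (empty-set) candidate
    for bits in range(1, 2 ** n_mat):
        mask = np.array([(bits >> k) & 1 for k in range(n_mat)], dtype=bool)
        cols = M[:, mask]
        C = B @ np.linalg.pinv(cols).T  # (n, k)
        resid = B - C @ cols.T
        r2 = np.einsum("ne,ne->n", resid, resid)
        feasible = np.all(C >= -1.0e-12, axis=1)
        upd = feasible & (r2 < best_r2 - 1.0e-15)
        if np.any(upd):
            best[upd] = 0.0
            best[np.ix_(upd, mask)] = C[upd]
            best_r2[upd] = r2[upd]
    return np.maximum(best, 0.0)


def decompose(x: Volume5D, M: SensitivityMatrix) -> MaterialMaps:
    """Invert the linear spectral model per voxel, per phase.

    Voxels whose unconstrained solution is already non-negative are solved
    in one vectorised least-squares pass; the remainder get the exact
    non-negative optimum from the vectorised subset solver (equivalent to
    the active-set scheme).  Output concentrations are always >= 0.
    """
    n_mat = len(M.materials)
    if x.n_energies < n_mat:
        raise ValueError(
            f"{x.n_energies} energies cannot resolve {n_mat} materials")
    vals = x.values  # (t, e, z, y, x)
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite voxel value at (t,e,z,y,x)={tuple(int(i) for i in bad)}")

    pinv = np.linalg.pinv(M.M)
    # unconstrained: (t, z, y, x, m)
    C = np.einsum("me,tezyx->tzyxm", pinv, vals)
    neg = np.any(C < -1.0e-12, axis=-1)
    if np.any(neg):
        b_all = np.moveaxis(vals, 1, -1)[neg]  # (n_bad, n_energies)
        C[neg] = _nnls_batch(M.M, b_all)
    C = np.maximum(C, 0.0)
    return MaterialMaps(C=np.moveaxis(C, -1, 0), materials=M.materials,
                        units=M.units, voxel_size=x.voxel_size)
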