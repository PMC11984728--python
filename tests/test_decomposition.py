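import numpy as np
import pytest

from cardiopcct import (Volume5D, calibrate_sensitivity, decompose,
                        nnls_active_set, sensitivity_from_model)
from cardiopcct.decomposition import SensitivityMatrix, _nnls_batch
from cardiopcct.phantom import bin_effective_energies

ENERGIES4 = bin_effective_energies(np.array([25.0, 34.0, 50.0, 60.0]), 80.0)


def brute_force_nnls(M, b):
    """Exhaustive subset enumeration: the exact non-negative optimum."""
    n = M.shape[1]
    best, best_r2 = np.zeros(n), float(b @ b)
    for bits in range(1, 2 ** n):
        mask = np.array([(bits >> k) & 1 for k in range(n)], dtype=bool)
        sol, *_ = np.linalg.lstsq(M[:, mask], b, rcond=None)
        if np.any(sol < -1e-12):
            continue
        r = b - M[:, mask] @ sol
        r2 = float(r @ r)
        if r2 < best_r2 - 1e-15:
            best = np.zeros(n)
            best[mask] = sol
            best_r2 = r2
    return np.maximum(best, 0.0)


def test_active_set_matches_exhaustive_oracle(rng):
    worst = 0.0
    for _ in range(1000):
        M = rng.normal(size=(4, 3))
        b = rng.normal(size=4)
        got = nnls_active_set(M, b)
        want = brute_force_nnls(M, b)
        worst = max(worst, float(np.abs(got - want).max()))
        assert np.all(got >= 0.0)
    assert worst < 1e-8


def test_batch_solver_matches_active_set(rng):
    M = rng.normal(size=(4, 3))
    B = rng.normal(size=(200, 4))
    batch = _nnls_batch(M, B)
    for i in range(200):
        assert np.allclose(batch[i], nnls_active_set(M, B[i]), atol=1e-9)


def test_noiseless_phantom_iodine_recovered(phantom48):
    # exact attenuation volumes at the 4 bin energies -> iodine map within 5%
    vols = np.stack([
        np.stack([phantom48.mu_volume(p, e) * phantom48.voxel_size
                  for e in ENERGIES4])
        for p in range(2)
    ])
    x = Volume5D(values=vols.astype(np.float64), voxel_size=phantom48.voxel_size)
    M = sensitivity_from_model(ENERGIES4, preset="iodine_ca_water",
                               voxel_size=phantom48.voxel_size)
    maps = decompose(x, M)
    iodine = maps.map_for("iodine")
    lv = phantom48.labels[0] == 1
    recovered = float(iodine[0][lv].mean())
    assert recovered == pytest.approx(10.0, rel=0.05)
    myo = phantom48.labels[0] == 8
    assert float(iodine[0][myo].mean()) < 0.5  # no iodine in the myocardium


def test_decompose_output_nonnegative(rng):
    vals = rng.normal(0.0, 0.01, size=(2, 4, 2, 6, 6))
    x = Volume5D(values=vals, voxel_size=0.125)
    M = sensitivity_from_model(ENERGIES4, preset="iodine_ca_water")
    maps = decompose(x, M)
    assert np.all(maps.C >= 0.0)


def test_decompose_constrained_voxels_match_oracle(rng):
    vals = rng.normal(0.0, 0.01, size=(1, 4, 1, 5, 5))
    x = Volume5D(values=vals, voxel_size=0.125)
    M = sensitivity_from_model(ENERGIES4, preset="iodine_ca_water")
    maps = decompose(x, M)
    for z in range(1):
        for y in range(5):
            for xx in range(5):
                b = vals[0, :, z, y, xx]
                want = brute_force_nnls(M.M, b)
                got = maps.C[:, 0, z, y, xx]
                assert np.allclose(got, want, atol=1e-8)


def test_rank_deficient_bases_rejected():
    with pytest.raises(ValueError, match="not separable"):
        SensitivityMatrix(M=np.array([[1.0, 2.0], [2.0, 4.0]]),
                          materials=("a", "b"), units=("u", "u"))
    with pytest.raises(ValueError, match="not separable"):
        # 3 materials cannot be resolved from 2 energies
        sensitivity_from_model(ENERGIES4[:2], preset="iodine_ca_water")


def test_auto_preset_matches_bin_count():
    two = sensitivity_from_model(ENERGIES4[:2], preset="auto")
    assert two.materials == ("iodine", "water")
    three = sensitivity_from_model(ENERGIES4, preset="auto")
    assert three.materials == ("iodine", "calcium", "water")
    with pytest.raises(ValueError, match="unknown preset"):
        sensitivity_from_model(ENERGIES4, preset="bone_water")


def test_too_few_energies_for_materials(rng):
    x = Volume5D(values=rng.random((1, 2, 1, 2, 2)), voxel_size=0.125)
    M = sensitivity_from_model(ENERGIES4, preset="iodine_ca_water")
    with pytest.raises(ValueError, match="cannot resolve"):
        decompose(x, M)


def test_nonfinite_voxel_reported_with_index(rng):
    vals = rng.random((1, 4, 1, 3, 3))
    vals[0, 2, 0, 1, 2] = np.nan
    x = Volume5D(values=vals, voxel_size=0.125)
    M = sensitivity_from_model(ENERGIES4, preset="iodine_ca_water")
    with pytest.raises(ValueError, match=r"non-finite.*\(0, 2, 0, 1, 2\)"):
        decompose(x, M)


def test_calibrate_sensitivity_from_phantom_measurements():
    # synthetic calibration objects: exact attenuation at known concentration
    M_true = sensitivity_from_model(ENERGIES4, preset="iodine_ca_water")
    cals = []
    for j, name in enumerate(M_true.materials):
        conc = 5.0
        atten = M_true.M[:, j] * conc
        cals.append((np.tile(atten[:, None], (1, 10)), conc, name))
    M_cal = calibrate_sensitivity(cals, M_true.materials)
    assert np.allclose(M_cal.M, M_true.M)
    with pytest.raises(ValueError, match="no calibration object"):
        calibrate_sensitivity(cals[:2], M_true.materials)
    with pytest.raises(ValueError, match="must be > 0"):
        calibrate_sensitivity([(cals[0][0], 0.0, "iodine")], ("iodine",))


def test_condition_number_reported():
    M = sensitivity_from_model(ENERGIES4, preset="iodine_ca_water")
    assert M.condition_number > 1.0
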