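import numpy as np
import pytest

from cardiopcct import (STRUCTURE_IDS, STRUCTURES, AcquisitionSpec,
                        ParallelProjector, PhantomSpec,
                        attenuation_coefficient, bin_effective_energies,
                        build_phantom, simulate_acquisition)
from cardiopcct.phantom import IODINE_K_EDGE_KEV


# -- attenuation model -------------------------------------------------------

# Published liquid-water mass attenuation values (NIST XCOM), cm^2/g.
WATER_REFERENCE = {20.0: 0.8096, 30.0: 0.3756, 40.0: 0.2683, 60.0: 0.2059,
                   80.0: 0.1837}


def test_water_attenuation_tracks_published_table():
    for e_kev, mu_rho in WATER_REFERENCE.items():
        mu_mm = attenuation_coefficient("water", e_kev)  # 1/mm at 1 g/mL
        assert mu_mm * 10.0 == pytest.approx(mu_rho, rel=0.05)


def test_water_attenuation_interpolates_between_table_points():
    # log-log interpolation must stay between the bracketing table values
    mu = attenuation_coefficient("water", 35.0) * 10.0
    assert WATER_REFERENCE[40.0] < mu < WATER_REFERENCE[30.0]


def test_iodine_k_edge_discontinuity():
    below = attenuation_coefficient("iodine", IODINE_K_EDGE_KEV - 0.1)
    above = attenuation_coefficient("iodine", IODINE_K_EDGE_KEV + 0.1)
    assert above / below > 3.0  # the K-edge jump


def test_soft_tissue_denser_than_water():
    for e in (20.0, 40.0, 60.0):
        assert attenuation_coefficient("soft_tissue", e) == pytest.approx(
            attenuation_coefficient("water", e) * 1.053, rel=1e-12)


def test_attenuation_errors():
    with pytest.raises(ValueError, match="unknown material"):
        attenuation_coefficient("bone", 40.0)
    with pytest.raises(ValueError, match="energy"):
        attenuation_coefficient("water", 5.0)
    with pytest.raises(ValueError, match="energy"):
        attenuation_coefficient("water", 130.0)


def test_bin_effective_energies_midpoints():
    e = bin_effective_energies(np.array([25.0, 34.0, 50.0, 60.0]), 80.0)
    assert np.allclose(e, [29.5, 42.0, 55.0, 70.0])
    # bins bracket the K-edge: first below, second above
    assert e[0] < IODINE_K_EDGE_KEV < e[1]


# -- phantom -----------------------------------------------------------------


def test_all_structures_present_every_phase(phantom48):
    for p in range(phantom48.n_phases):
        present = set(np.unique(phantom48.labels[p]))
        assert {STRUCTURE_IDS[n] for n in STRUCTURES} <= present


def test_truth_ef_matches_targets(phantom48):
    assert phantom48.truth_ef("LV") == pytest.approx(50.0, abs=1.0)
    assert phantom48.truth_ef("RV") == pytest.approx(45.0, abs=1.5)


def test_lv_volume_curve_max_at_first_phase(phantom48):
    v = phantom48.truth_volumes["LV"]
    assert int(np.argmax(v)) == 0  # frame 0 covers end-diastole
    assert v.min() < v.max()


def test_vessels_static(phantom48):
    v = phantom48.truth_volumes["aorta"]
    assert np.all(v == v[0])


def test_mu_volume_positive_in_blood(phantom48):
    mu = phantom48.mu_volume(0, 29.5)
    lv = phantom48.labels[0] == STRUCTURE_IDS["LV"]
    myo = phantom48.labels[0] == STRUCTURE_IDS["myocardium"]
    assert mu[lv].mean() > mu[myo].mean() > 0  # iodinated blood > tissue


def test_phantom_spec_validation():
    with pytest.raises(ValueError, match="n_phases"):
        PhantomSpec(n_phases=1)
    with pytest.raises(ValueError, match="EF"):
        PhantomSpec(target_EF_lv=0.0)
    with pytest.raises(ValueError, match="voxel_size"):
        PhantomSpec(voxel_size=-1.0)


def test_too_small_grid_names_structure():
    with pytest.raises(ValueError, match="too small to place structure"):
        build_phantom(PhantomSpec(grid_shape=(12, 12, 12)))


# -- acquisition -------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_stream(phantom48):
    acq = AcquisitionSpec(n_projections=50, thresholds=(25.0, 34.0),
                          noise_seed=5)
    return simulate_acquisition(phantom48, acq, ParallelProjector(48))


def test_stream_shapes_and_invariants(tiny_stream):
    assert tiny_stream.projections.shape == (50, 2, 48, 48)
    assert np.all(tiny_stream.projections >= 0)
    assert np.all(np.diff(tiny_stream.timestamps) > 0)
    assert tiny_stream.sample_rate == pytest.approx(100.0)


def test_acquisition_deterministic(phantom48):
    acq = AcquisitionSpec(n_projections=20, thresholds=(25.0,), noise_seed=7)
    proj = ParallelProjector(48)
    a = simulate_acquisition(phantom48, acq, proj)
    b = simulate_acquisition(phantom48, acq, proj)
    assert np.array_equal(a.projections, b.projections)


def test_log_transform_roundtrip_values(tiny_stream):
    log = tiny_stream.log_transform()
    assert log.log_transformed
    assert log.log_transform() is log
    back = tiny_stream.flux * np.exp(-log.projections)
    counts = np.maximum(tiny_stream.projections, 0.5)
    assert np.allclose(back, counts)


def test_noise_requires_seed():
    with pytest.raises(ValueError, match="noise_seed"):
        AcquisitionSpec(noise=True, noise_seed=None)


def test_acquisition_spec_validation():
    with pytest.raises(ValueError, match="thresholds"):
        AcquisitionSpec(thresholds=(34.0, 25.0))
    with pytest.raises(ValueError, match="180"):
        AcquisitionSpec(total_rotation=90.0)
    with pytest.raises(ValueError, match="flux"):
        AcquisitionSpec(flux=0.0)


def test_true_phase_tracks_heart_rate(tiny_stream, phantom48):
    t = tiny_stream.timestamps
    expected = np.floor(((t * phantom48.truth_HR / 60.0) % 1.0)
                        * phantom48.n_phases).astype(int)
    assert np.array_equal(tiny_stream.true_phase, expected)
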