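import numpy as np
import pytest

from cardiopcct import (ParallelProjector, ReconConfig, Sinogram5D, Volume5D,
                        bin_projections, data_fidelity, fbp_reconstruct,
                        iterative_reconstruct, regularize_joint)
from cardiopcct.reconstruction import (ProjectionSet, bilateral_smooth,
                                       temporal_svt)

N_PIX, NZ = 32, 2
ANGLES = np.arange(0.0, 180.0, 3.0)


def make_truth():
    yy, xx = np.mgrid[:N_PIX, :N_PIX]
    truth = np.zeros((2, 2, NZ, N_PIX, N_PIX))
    for t in range(2):
        r = 8 - 2 * t
        disk = ((yy - 16) ** 2 + (xx - 15) ** 2) <= r * r
        body = ((yy - 16) ** 2 + (xx - 15) ** 2) <= 144
        for e in range(2):
            truth[t, e] = 0.01 * (1 + e) * disk + 0.003 * body
    return truth


def make_sinogram(truth, noise_sd=0.0, seed=1):
    proj = ParallelProjector(N_PIX)
    rng = np.random.default_rng(seed)
    cells = {}
    for t in range(2):
        for e in range(2):
            y = np.stack([proj.project_slices(truth[t, e], a) for a in ANGLES])
            if noise_sd:
                y = y + rng.normal(0.0, noise_sd, y.shape)
            cells[(t, e)] = ProjectionSet(angles=ANGLES, y=y)
    return Sinogram5D(cells=cells, n_phases=2, n_energies=2,
                      grid_shape=(NZ, N_PIX, N_PIX), voxel_size=0.125), proj


@pytest.fixture(scope="module")
def toy():
    truth = make_truth()
    sino, proj = make_sinogram(truth)
    return truth, sino, proj


def test_fbp_recovers_interior(toy):
    truth, sino, proj = toy
    vol = fbp_reconstruct(sino.cells[(0, 0)], proj)
    interior = truth[0, 0, 0] > 0
    err = np.abs(vol[0][interior] - truth[0, 0, 0][interior])
    assert err.mean() < 0.08 * truth[0, 0].max()


def test_fbp_warns_on_limited_angle(toy):
    truth, sino, proj = toy
    limited = ProjectionSet(angles=ANGLES[:20], y=sino.cells[(0, 0)].y[:20])
    with pytest.warns(UserWarning, match="angular coverage"):
        fbp_reconstruct(limited, proj)


def test_unregularized_iterations_converge_to_truth(toy):
    truth, sino, proj = toy
    cfg = ReconConfig(lam=0.0, max_iters=10, inner_iters=10, tol=1e-8)
    vol = iterative_reconstruct(sino, cfg, projector=proj)
    rmse = np.sqrt(np.mean((vol.values - truth) ** 2)) / truth.max()
    assert rmse < 0.02
    log = np.asarray(vol.objective_log)
    assert np.all(np.diff(log) <= 1e-9 + 1e-6 * np.abs(log[:-1]))


def test_regularized_objective_monotone():
    truth = make_truth()
    sino, proj = make_sinogram(truth, noise_sd=0.01)
    cfg = ReconConfig(lam=0.2, max_iters=6, inner_iters=2, reg_blend=0.3)
    vol = iterative_reconstruct(sino, cfg, projector=proj)
    log = np.asarray(vol.objective_log)
    assert len(log) >= 2
    assert np.all(np.diff(log) <= 1e-9 + 1e-6 * np.abs(log[:-1]))


def test_divergence_raises_with_log():
    truth = make_truth()
    sino, proj = make_sinogram(truth, noise_sd=0.02)
    cfg = ReconConfig(lam=0.5, max_iters=8, inner_iters=4, reg_blend=0.3)
    with pytest.raises(RuntimeError, match="diverged"):
        iterative_reconstruct(sino, cfg, projector=proj)


def test_data_fidelity_zero_at_truth(toy):
    truth, sino, proj = toy
    vol = Volume5D(values=truth, voxel_size=0.125)
    assert data_fidelity(vol, sino, proj) == pytest.approx(0.0, abs=1e-12)
    assert data_fidelity(Volume5D(values=np.zeros_like(truth),
                                  voxel_size=0.125), sino, proj) > 1.0


def test_empty_sinogram_cell_rejected(toy):
    truth, sino, proj = toy
    cells = dict(sino.cells)
    del cells[(1, 1)]
    with pytest.raises(ValueError, match="empty"):
        Sinogram5D(cells=cells, n_phases=2, n_energies=2,
                   grid_shape=(NZ, N_PIX, N_PIX), voxel_size=0.125)


def test_bin_projections_partitions_stream(phantom48):
    from cardiopcct import (AcquisitionSpec, assign_phases,
                            extract_intrinsic_signal, simulate_acquisition)
    acq = AcquisitionSpec(n_projections=800, thresholds=(25.0, 34.0),
                          noise_seed=3)
    stream = simulate_acquisition(phantom48, acq, ParallelProjector(48))
    sig = extract_intrinsic_signal(stream)
    asn = assign_phases(sig, 5)
    sino = bin_projections(stream, asn)
    n_views = sum(sino.cells[(t, 0)].y.shape[0] for t in range(5))
    assert n_views == len(asn.kept)
    assert sino.n_energies == 2 and sino.n_phases == 5


def test_temporal_svt_clips_patch_and_reduces_noise(rng):
    base = np.ones((4, 2, 8, 8)) * np.linspace(1, 2, 4)[:, None, None, None]
    noisy = base + rng.normal(0, 0.05, base.shape)
    # patch > nz gets clipped; small threshold denoises without visible shrink
    out = temporal_svt(noisy, patch=4, svt_frac=0.01)
    assert out.shape == noisy.shape
    assert np.mean((out - base) ** 2) < np.mean((noisy - base) ** 2)
    with pytest.raises(ValueError, match="patch"):
        temporal_svt(noisy, patch=0)
    with pytest.raises(ValueError, match="larger than volume"):
        temporal_svt(noisy, patch=99)


def test_bilateral_smooth_preserves_shared_edges(rng):
    edge = np.zeros((2, 4, 16, 16))
    edge[:, :, :, 8:] = 1.0
    noisy = edge + rng.normal(0, 0.02, edge.shape)
    out = bilateral_smooth(noisy, sigma_spatial=1.0)
    # flat regions denoised ...
    assert out[:, :, :, :6].std() < noisy[:, :, :, :6].std()
    # ... while the cross-channel edge survives
    assert out[0, 0, 8, 9] - out[0, 0, 8, 6] > 0.8


def test_regularize_joint_requires_multi_energy_and_phase(toy):
    truth, _, _ = toy
    vol = Volume5D(values=truth[:, :1], voxel_size=0.125)
    with pytest.raises(ValueError, match=">= 2 energies"):
        regularize_joint(vol)


def test_recon_config_validation():
    with pytest.raises(ValueError, match="lam"):
        ReconConfig(lam=-1.0)
    with pytest.raises(ValueError, match="max_iters"):
        ReconConfig(max_iters=0)
    with pytest.raises(ValueError, match="tol"):
        ReconConfig(tol=0.0)
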