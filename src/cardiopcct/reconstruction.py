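"""5D (space x phase x energy) CT reconstruction from gated projections.

The reconstruction estimates X that minimises

    1/2 * sum_t sum_e || R X_te - Y_te ||^2  +  lambda_te * Reg(X)

where ``R`` is the (slice-stacked parallel-beam) system matrix, ``Y`` the
log-transformed projections sorted into cardiac phase bins, and ``Reg`` a
joint regulariser: a bilateral (edge-preserving) smoothing whose weight field
is computed once from all energy channels together, plus a patch-wise
singular-value soft threshold across the cardiac phases (low temporal rank).
A filtered-backprojection baseline per (phase, energy) cell initialises the
iterations and serves as an unregularised reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .gating import PhaseAssignment
from .phantom import ProjectionStream
from .projector import ParallelProjector

__all__ = [
    "ProjectionSet",
    "Sinogram5D",
    "Volume5D",
    "ReconConfig",
    "bin_projections",
    "fbp_reconstruct",
    "data_fidelity",
    "regularize_joint",
    "temporal_svt",
    "bilateral_smooth",
    "iterative_reconstruct",
]


@dataclass
class ProjectionSet:
    """Log-transformed projections of one (phase, energy) cell."""

    angles: np.ndarray  # degrees, one per view
    y: np.ndarray  # (n_views, n_det, n_slices)

    def __post_init__(self):
        if len(self.angles) != self.y.shape[0]:
            raise ValueError("angles and projections disagree in view count")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("projections must be finite")


@dataclass
class Sinogram5D:
    """Phase- and energy-binned log projections plus acquisition geometry."""

    cells: dict  # (t, e) -> ProjectionSet
    n_phases: int
    n_energies: int
    grid_shape: tuple
    voxel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for t in range(self.n_phases):
            for e in range(self.n_energies):
                if (t, e) not in self.cells or self.cells[(t, e)].y.shape[0] < 1:
                    raise ValueError(f"sinogram cell (phase={t}, energy={e}) is empty")


@dataclass
class Volume5D:
    """Reconstructed attenuation over (phase, energy, z, y, x).

    Values are attenuation per voxel length (multiply by ``1/voxel_size`` for
    1/mm).  ``values[t, e]`` is the 3D volume of phase ``t``, energy bin ``e``.
    """

    values: np.ndarray  # (n_phases, n_energies, nz, ny, nx)
    voxel_size: float  # mm

    def __post_init__(self):
        if self.values.ndim != 5:
            raise ValueError("Volume5D expects a 5D array (t, e, z, y, x)")

    @property
    def n_phases(self) -> int:
        return self.values.shape[0]

    @property
    def n_energies(self) -> int:
        return self.values.shape[1]

    @property
    def grid_shape(self) -> tuple:
        return self.values.shape[2:]


@dataclass
class ReconConfig:
    """Iterative reconstruction controls.

    ``lam`` is the global regularisation weight; the per-cell weight
    ``lambda_te`` defaults to ``lam`` scaled by each cell's share of the
    projections (cells with more views tolerate stronger smoothing).
    """

    lam: float = 0.0
    max_iters: int = 10
    tol: float = 1.0e-4  # relative objective change for convergence
    inner_iters: int = 4  # CGLS iterations per data step
    bilateral_sigma_spatial: float = 1.0  # voxels
    bilateral_sigma_int: float | None = None  # auto: 0.15 * robust range
    patch: int = 4  # temporal-SVT patch side, voxels (clipped to the grid)
    svt_frac: float = 0.05  # singular-value soft threshold, fraction of s_max
    reg_blend: float = 0.3  # proximal smoothing strength per outer iteration
    init: str = "fbp"  # or "zeros"
    nonneg: bool = False  # clamp the *final* volume at zero

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_projections(stream: ProjectionStream, assignment: PhaseAssignment) -> Sinogram5D:
    """Sort a log-transformed stream into (phase, energy) sinogram cells."""
    log_stream = stream.log_transform()
    n_bins = log_stream.projections.shape[1]
    cells = {}
    for t in range(assignment.n_phases):
        idx = assignment.exposures_in_phase(t)
        for e in range(n_bins):
            cells[(t, e)] = ProjectionSet(
                angles=log_stream.angles[idx],
                y=log_stream.projections[idx, e],
            )
    return Sinogram5D(
        cells=cells,
        n_phases=assignment.n_phases,
        n_energies=n_bins,
        grid_shape=log_stream.grid_shape,
        voxel_size=log_stream.voxel_size,
        provenance={"n_dropped": int(len(assignment.dropped)),
                    "n_exposures": int(stream.n_exposures)},
    )


# ---------------------------------------------------------------------------
# FBP baseline
# ---------------------------------------------------------------------------


def _ramp_filter(y: np.ndarray) -> np.ndarray:
    """Apply the ramp filter along the detector axis (axis 1).

    Uses the exact discrete Ram-Lak kernel (band-limited ramp), whose DC
    term avoids the cupping/offset bias of a naive |f| multiplier.
    """
    n_det = y.shape[1]
    n_pad = int(2 ** np.ceil(np.log2(max(2 * n_det, 16))))
    h = np.zeros(n_pad)
    h[0] = 0.25
    k = np.arange(1, n_pad // 2 + 1, 2)
    h[k] = -1.0 / (np.pi * k) ** 2
    h[-k] = -1.0 / (np.pi * k) ** 2
    H = np.fft.rfft(h)
    spec = np.fft.rfft(y, n=n_pad, axis=1) * H[None, :, None]
    return np.fft.irfft(spec, n=n_pad, axis=1)[:, :n_det, :]


def fbp_reconstruct(projset: ProjectionSet, projector: ParallelProjector,
                    n_slices: int | None = None) -> np.ndarray:
    """Filtered backprojection of one (phase, energy) cell -> (nz, ny, nx).

    Deterministic; warns (does not fail) when the views span less than 180
    degrees.
    """
    angles = np.asarray(projset.angles, dtype=float)
    span = _angular_span(angles)
    if span < 175.0 and len(angles) > 1:
        warnings.warn(f"angular coverage {span:.1f} deg < 180 deg; "
                      "FBP result may contain limited-angle artifacts")
    q = _ramp_filter(projset.y)
    n_views, n_det, nz = q.shape
    flat = projector.matrix(angles).T @ q.reshape(n_views * n_det, nz)
    vol = flat.reshape(projector.n_pix, projector.n_pix, nz)
    return np.ascontiguousarray(np.moveaxis(vol, 2, 0)) * (np.pi / max(n_views, 1))


def _angular_span(angles: np.ndarray) -> float:
    if len(angles) < 2:
        return 0.0
    a = np.sort(np.asarray(angles) % 180.0)
    gaps = np.diff(np.concatenate([a, [a[0] + 180.0]]))
    return 180.0 - gaps.max()


# ---------------------------------------------------------------------------
# Objective pieces
# ---------------------------------------------------------------------------


def _cell_matrix(projector: ParallelProjector, projset: ProjectionSet) -> sparse.csr_matrix:
    return projector.matrix(projset.angles)


def data_fidelity(x: Volume5D, y: Sinogram5D,
                  projector: ParallelProjector | None = None) -> float:
    """0.5 * sum over (t, e) of the squared reprojection error."""
    if x.grid_shape != tuple(y.grid_shape):
        raise ValueError("volume and sinogram grids do not match")
    if projector is None:
        projector = ParallelProjector(x.grid_shape[1])
    total = 0.0
    for (t, e), cell in y.cells.items():
        A = _cell_matrix(projector, cell)
        vol = x.values[t, e]
        nz = vol.shape[0]
        proj = (A @ vol.reshape(nz, -1).T).reshape(len(cell.angles), projector.n_det, nz)
        total += 0.5 * float(np.sum((proj - cell.y) ** 2))
    return total


def bilateral_total_variation(vol: np.ndarray) -> float:
    """Sum of absolute differences to the 26-neighbourhood (BTV surrogate)."""
    total = 0.0
    for axis in range(vol.ndim):
        total += float(np.sum(np.abs(np.diff(vol, axis=axis))))
    return total


def nuclear_norm_phases(x: np.ndarray) -> float:
    """Sum of singular values of the (voxels x phases) Casorati matrix per energy."""
    n_phases, n_energies = x.shape[:2]
    total = 0.0
    for e in range(n_energies):
        mat = x[:, e].reshape(n_phases, -1).T
        total += float(np.sum(np.linalg.svd(mat, compute_uv=False)))
    return total


# ---------------------------------------------------------------------------
# Joint regularizer
# ---------------------------------------------------------------------------


_OFFSETS = [(dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]


def bilateral_smooth(vols: np.ndarray, sigma_spatial: float = 1.0,
                     sigma_int: float | None = None) -> np.ndarray:
    """Joint bilateral smoothing of (n_energies, nz, ny, nx) channels.

    One weight field is computed from the energy-averaged guide image
    (spatial Gaussian x intensity Gaussian) and applied to every channel, so
    edges located in any channel are preserved coherently across energies.
    """
    guide = vols.mean(axis=0)
    if sigma_int is None:
        lo, hi = np.percentile(guide, [1.0, 99.0])
        sigma_int = 0.15 * max(hi - lo, 1e-12)
    out = np.zeros_like(vols)
    wsum = np.zeros_like(guide)
    for off in _OFFSETS:
        g = np.roll(guide, off, axis=(0, 1, 2))
        d2 = sum(o * o for o in off)
        w = np.exp(-d2 / (2.0 * sigma_spatial ** 2)
                   - (g - guide) ** 2 / (2.0 * sigma_int ** 2))
        wsum += w
        for e in range(vols.shape[0]):
            out[e] += w * np.roll(vols[e], off, axis=(0, 1, 2))
    return out / wsum[None]


def temporal_svt(x: np.ndarray, patch: int = 4, svt_frac: float = 0.05) -> np.ndarray:
    """Patch-wise singular-value soft thresholding across cardiac phases.

    ``x`` has shape (n_phases, nz, ny, nx).  Each non-overlapping ``patch^3``
    block is unfolded to a (voxels x phases) matrix whose singular values are
    shrunk by ``svt_frac * s_max`` (soft threshold), suppressing incoherent
    temporal fluctuations while keeping the low-rank cardiac motion.
    """
    n_phases = x.shape[0]
    grid = x.shape[1:]
    if patch < 1:
        raise ValueError("patch must be >= 1")
    if patch > max(grid):
        raise ValueError(f"patch {patch} larger than volume {grid}")
    # per-axis patch, clipped so thin axes are spanned whole
    paz, pay, pax = (min(patch, g) for g in grid)
    pads = [(0, (-g) % p) for g, p in zip(grid, (paz, pay, pax))]
    xp = np.pad(x, [(0, 0)] + pads, mode="edge")
    pz, py, px = (s // p for s, p in zip(xp.shape[1:], (paz, pay, pax)))
    blocks = xp.reshape(n_phases, pz, paz, py, pay, px, pax)
    blocks = blocks.transpose(1, 3, 5, 2, 4, 6, 0).reshape(pz, py, px, paz * pay * pax, n_phases)
    out = np.empty_like(blocks)
    for i in range(pz):
        for j in range(py):
            for k in range(px):
                u, s, vt = np.linalg.svd(blocks[i, j, k], full_matrices=False)
                thr = svt_frac * (s[0] if len(s) else 0.0)
                s = np.maximum(s - thr, 0.0)
                out[i, j, k] = (u * s) @ vt
    out = out.reshape(pz, py, px, paz, pay, pax, n_phases)
    out = out.transpose(6, 0, 3, 1, 4, 2, 5).reshape(xp.shape)
    return out[:, :grid[0], :grid[1], :grid[2]]


def regularize_joint(x: Volume5D, sigma_spatial: float = 1.0,
                     sigma_int: float | None = None, patch: int = 4,
                     svt_frac: float = 0.05, blend: float = 1.0) -> Volume5D:
    """One pass of the joint spectral/temporal regulariser.

    Spectral step: joint bilateral smoothing with a single weight field per
    phase shared by all energy channels.  Temporal step: patch-wise
    singular-value soft thresholding across phases, per energy.  ``blend``
    in (0, 1] linearly mixes the smoothed result with the input (the
    proximal-style damping used inside the iterative loop).
    """
    if x.n_energies < 2 or x.n_phases < 2:
        raise ValueError("joint regularization needs >= 2 energies and >= 2 phases")
    vals = x.values.astype(np.float64, copy=True)
    for t in range(x.n_phases):
        sm = bilateral_smooth(vals[t], sigma_spatial, sigma_int)
        vals[t] = (1.0 - blend) * vals[t] + blend * sm
    for e in range(x.n_energies):
        vals[:, e] = temporal_svt(vals[:, e], patch=patch, svt_frac=svt_frac)
    return Volume5D(values=vals, voxel_size=x.voxel_size)


# ---------------------------------------------------------------------------
# Iterative solver
# ---------------------------------------------------------------------------


def _cgls_block(A: sparse.csr_matrix, B: np.ndarray, X0: np.ndarray,
                iters: int) -> np.ndarray:
    """Conjugate-gradient least squares on a multi-column right-hand side.

    Solves ``min ||A X - B||`` column-wise (columns are volume slices) with
    independent CG scalars per column; restarting from ``X0`` keeps the
    fidelity non-increasing across restarts.
    """
    X = X0.copy()
    R = B - A @ X
    S = A.T @ R
    P = S.copy()
    gamma = np.sum(S * S, axis=0)
    for _ in range(iters):
        Q = A @ P
        denom = np.sum(Q * Q, axis=0)
        alpha = np.where(denom > 0, gamma / np.maximum(denom, 1e-300), 0.0)
        X += alpha * P
        R -= alpha * Q
        S = A.T @ R
        gamma_new = np.sum(S * S, axis=0)
        beta = np.where(gamma > 0, gamma_new / np.maximum(gamma, 1e-300), 0.0)
        P = S + beta * P
        gamma = gamma_new
    return X


def iterative_reconstruct(y: Sinogram5D, config: ReconConfig,
                          projector: ParallelProjector | None = None) -> Volume5D:
    """Minimise the joint 5D objective by alternating least-squares data steps
    with proximal regularisation.

    Each outer iteration runs ``inner_iters`` CGLS iterations on every
    (phase, energy) cell, then (when ``lam`` > 0) one pass of
    :func:`regularize_joint`.  The surrogate objective -- data fidelity plus
    the weighted BTV and temporal nuclear-norm penalties -- is recorded per
    outer iteration and must be non-increasing (to a small relative
    tolerance); if an iteration would increase it the update is damped
    towards the previous iterate, and three consecutive increases abort with
    the diagnostic log attached.
    """
    nz, ny, nx = y.grid_shape
    if projector is None:
        projector = ParallelProjector(nx)

    n_views = {te: len(cell.angles) for te, cell in y.cells.items()}
    mean_views = np.mean(list(n_views.values()))
    lambda_te = {te: config.lam * n_views[te] / mean_views for te in y.cells}

    mats = {te: _cell_matrix(projector, cell) for te, cell in y.cells.items()}

    x = np.zeros((y.n_phases, y.n_energies, nz, ny, nx))
    if config.init == "fbp":
        for (t, e), cell in y.cells.items():
            x[t, e] = fbp_reconstruct(cell, projector)

    def objective(vals: np.ndarray) -> float:
        vol = Volume5D(values=vals, voxel_size=y.voxel_size)
        obj = data_fidelity(vol, y, projector)
        if config.lam > 0:
            mean_lam = np.mean(list(lambda_te.values()))
            pen = sum(bilateral_total_variation(vals[t, e])
                      for t in range(y.n_phases) for e in range(y.n_energies))
            obj += mean_lam * (pen + nuclear_norm_phases(vals))
        return obj

    def update(vals: np.ndarray, blend: float) -> np.ndarray:
        out = vals.copy()
        for (t, e), cell in y.cells.items():
            flat = out[t, e].reshape(nz, -1).T  # (n_pix^2, nz)
            flat = _cgls_block(mats[(t, e)], cell.y.reshape(-1, nz), flat,
                               config.inner_iters)
            out[t, e] = flat.T.reshape(nz, ny, nx)
        if config.lam > 0 and blend > 0:
            vol = regularize_joint(
                Volume5D(values=out, voxel_size=y.voxel_size),
                sigma_spatial=config.bilateral_sigma_spatial,
                sigma_int=config.bilateral_sigma_int,
                patch=config.patch,
                svt_frac=config.svt_frac,
                blend=blend,
            )
            out = vol.values
        return out

    log = [objective(x)]
    n_failed = 0
    blend = config.reg_blend if config.lam > 0 else 0.0
    for _ in range(config.max_iters):
        # monotone line search: accept the first candidate (full update, then
        # geometrically damped towards the previous iterate) that does not
        # increase the surrogate objective
        x_new = update(x, blend)
        obj = objective(x_new)
        rel = (obj - log[-1]) / max(abs(log[-1]), 1e-30)
        gamma = 0.5
        while rel > 1.0e-6 and gamma > 0.05:
            x_try = x + gamma * (x_new - x)
            obj = objective(x_try)
            rel = (obj - log[-1]) / max(abs(log[-1]), 1e-30)
            if rel <= 1.0e-6:
                x_new = x_try
            gamma *= 0.5
        if rel > 1.0e-6:
            # no acceptable step: stall, soften the regularizer, try again
            n_failed += 1
            blend *= 0.5
            if n_failed >= 3:
                raise RuntimeError(
                    "iterative reconstruction diverged: objective increased "
                    f"3 consecutive outer iterations; log={log + [obj]}")
            log.append(log[-1])
            continue
        n_failed = 0
        x = x_new
        converged = abs(obj - log[-1]) / max(abs(log[-1]), 1e-30) < config.tol
        log.append(obj)
        if converged:
            break

    if config.nonneg:
        np.maximum(x, 0.0, out=x)  # applied after the logged iterates
    vol = Volume5D(values=x, voxel_size=y.voxel_size)
    vol.objective_log = log
    return vol
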