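"""Parallel-beam forward projector shared by the simulator and the reconstructor.

The system matrix ``R`` is built explicitly as a sparse matrix (Joseph-style
ray sampling with bilinear voxel weights), so the adjoint used in
reconstruction is the exact matrix transpose.  Geometry is 2D parallel-beam
applied slice-by-slice along the volume's first axis; all lengths are in
voxel units (line integrals are attenuation-per-voxel-length sums).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["ParallelProjector"]


def _angle_block(n_pix: int, n_det: int, angle_deg: float, step: float) -> sparse.csr_matrix:
    """Sparse (n_det x n_pix^2) line-integral operator for one view angle."""
    theta = np.deg2rad(angle_deg)
    c = (n_pix - 1) / 2.0
    s_det = np.arange(n_det) - (n_det - 1) / 2.0
    half = n_pix * np.sqrt(2.0) / 2.0
    t = np.arange(-half, half + step, step)
    # ray point (x, y) = s * (cos, sin) + t * (-sin, cos), image-centred
    x = s_det[:, None] * np.cos(theta) - t[None, :] * np.sin(theta) + c
    y = s_det[:, None] * np.sin(theta) + t[None, :] * np.cos(theta) + c

    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    fx = x - x0
    fy = y - y0

    rows = np.broadcast_to(np.arange(n_det)[:, None], x.shape)
    data, rr, cc = [], [], []
    for dx, dy, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xi = x0 + dx
        yi = y0 + dy
        ok = (xi >= 0) & (xi < n_pix) & (yi >= 0) & (yi < n_pix)
        data.append((w * step)[ok])
        rr.append(rows[ok])
        cc.append((xi * n_pix + yi)[ok])
    mat = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(rr), np.concatenate(cc))),
        shape=(n_det, n_pix * n_pix),
    )
    return mat.tocsr()


class ParallelProjector:
    """Slice-stacked 2D parallel-beam projector with cached per-angle blocks.

    Parameters
    ----------
    n_pix:
        In-plane grid side (square slices).
    n_det:
        Detector pixels per view (defaults to ``n_pix``), spacing one voxel.
    angle_quant_deg:
        Angles are quantised to this grid so repeated views share one cached
        sparse block (the simulator emits thousands of near-continuous
        angles).
    step:
        Ray sampling step in voxel units.
    """

    def __init__(self, n_pix: int, n_det: int | None = None,
                 angle_quant_deg: float = 0.5, step: float = 1.0):
        self.n_pix = int(n_pix)
        self.n_det = int(n_det) if n_det is not None else int(n_pix)
        self.angle_quant_deg = float(angle_quant_deg)
        self.step = float(step)
        self._blocks: dict[int, sparse.csr_matrix] = {}

    def _key(self, angle_deg: float) -> int:
        return int(round((angle_deg % 180.0) / self.angle_quant_deg))

    def block(self, angle_deg: float) -> sparse.csr_matrix:
        key = self._key(angle_deg)
        if key not in self._blocks:
            self._blocks[key] = _angle_block(
                self.n_pix, self.n_det, key * self.angle_quant_deg, self.step
            )
        return self._blocks[key]

    def matrix(self, angles_deg: np.ndarray) -> sparse.csr_matrix:
        """Stacked system matrix for a set of view angles.

        Shape ``(n_angles * n_det, n_pix**2)``; rows are ordered by angle
        then detector pixel.
        """
        return sparse.vstack([self.block(a) for a in np.atleast_1d(angles_deg)],
                             format="csr")

    # -- application helpers -------------------------------------------------

    def project_slices(self, volume: np.ndarray, angle_deg: float) -> np.ndarray:
        """Line integrals of a (nz, n_pix, n_pix) volume at one angle.

        Returns an array of shape ``(n_det, nz)``.
        """
        nz = volume.shape[0]
        flat = volume.reshape(nz, -1).T  # (n_pix^2, nz)
        return self.block(angle_deg) @ flat

    def project_slice(self, image: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
        """Sinogram (n_angles, n_det) of a single 2D slice."""
        out = self.matrix(angles_deg) @ image.ravel()
        return out.reshape(len(np.atleast_1d(angles_deg)), self.n_det)

    def backproject_slice(self, sino: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
        """Adjoint applied to a (n_angles, n_det) sinogram -> 2D image."""
        out = self.matrix(angles_deg).T @ sino.ravel()
        return out.reshape(self.n_pix, self.n_pix)
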