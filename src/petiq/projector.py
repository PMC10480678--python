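"""Sparse 2-D parallel-beam projector shared by simulation and reconstruction.

The system matrix maps an (n x n) axial slice to a sinogram of
``n_angles`` views over 180 degrees with radial bins at the voxel pitch.
Each voxel splats its value onto the two nearest radial bins with linear
interpolation, so each sinogram view sums the slice exactly:
sum_bins (A x)[view] = sum_vox x.  Line integrals (for attenuation) are
obtained by multiplying the projection by the pixel pitch.

Matrices are cached per geometry; subset row partitions (interleaved view
subsets, as used by OSEM) are cached per subset count.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import sparse


class ParallelProjector:
    def __init__(self, n_pixels: int, pixel_mm: float, n_angles: int = 96):
        if n_pixels < 2 or n_angles < 1 or pixel_mm <= 0:
            raise ValueError("invalid projector geometry")
        self.n = int(n_pixels)
        self.ds = float(pixel_mm)
        self.n_angles = int(n_angles)
        self.n_bins = self.n
        self.angles = np.pi * np.arange(self.n_angles) / self.n_angles
        self.A = self._build()
        self._subset_cache: dict[int, list] = {}
        # field-of-view support: voxels whose centre projects inside the bins
        c = (np.arange(self.n) - (self.n - 1) / 2.0) * self.ds
        X, Y = np.meshgrid(c, c, indexing="ij")
        self.support = (np.hypot(X, Y) <= (self.n_bins / 2.0 - 1.0) * self.ds).ravel()

    def _build(self) -> sparse.csr_matrix:
        n, nb = self.n, self.n_bins
        c = (np.arange(n) - (n - 1) / 2.0) * self.ds
        X, Y = np.meshgrid(c, c, indexing="ij")
        x = X.ravel()
        y = Y.ravel()
        vox = np.arange(n * n)
        rows, cols, vals = [], [], []
        centre = (nb - 1) / 2.0
        for ia, th in enumerate(self.angles):
            s = x * np.cos(th) + y * np.sin(th)
            u = s / self.ds + centre
            i0 = np.floor(u).astype(np.int64)
            f = u - i0
            for idx, w in ((i0, 1.0 - f), (i0 + 1, f)):
                ok = (idx >= 0) & (idx < nb) & (w > 1e-12)
                rows.append(ia * nb + idx[ok])
                cols.append(vox[ok])
                vals.append(w[ok])
        A = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_angles * nb, n * n),
        )
        return A.tocsr()

    def project(self, image: np.ndarray) -> np.ndarray:
        """Forward-project slices.

        ``image``: (n, n) or (n*n, nz).  Returns (n_angles*n_bins,) or
        (n_angles*n_bins, nz).  Multiply by ``self.ds`` for line integrals.
        """
        if image.ndim == 2 and image.shape == (self.n, self.n):
            return self.A @ image.reshape(-1)
        return self.A @ image

    def subsets(self, n_subsets: int) -> list[dict]:
        """Interleaved view subsets: subset k uses views k, k+S, k+2S, ..."""
        if self.n_angles % n_subsets != 0:
            raise ValueError(
                f"{n_subsets} subsets do not divide {self.n_angles} projection angles"
            )
        if n_subsets not in self._subset_cache:
            subs = []
            for k in range(n_subsets):
                views = np.arange(k, self.n_angles, n_subsets)
                rows = (views[:, None] * self.n_bins + np.arange(self.n_bins)[None, :]).ravel()
                Ak = self.A[rows]
                subs.append({"views": views, "rows": rows, "A": Ak, "AT": Ak.T.tocsr()})
            self._subset_cache[n_subsets] = subs
        return self._subset_cache[n_subsets]


@lru_cache(maxsize=8)
def get_projector(n_pixels: int, pixel_mm: float, n_angles: int = 96) -> ParallelProjector:
    """Cached projector factory (system matrices are reused across calls)."""
    return ParallelProjector(n_pixels, pixel_mm, n_angles)
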