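"""Liver tumour seeding, spherical growth, and cross-phantom transfer.

Tumours are defined by a *seed* voxel (the tumour centre) and a target
volume.  Growth takes the n voxels of liver nearest the seed centre in
physical distance (n = round(target / V_vox), ties broken lexicographically
by z, y, x index), which realises each target volume to within half a voxel
on any grid.  Seeds are reused across phantoms through their fractional
position within the liver's axis-aligned bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import structures as st
from .phantom import CodePhantom

#: The eight target tumour volumes (mL), smallest to largest.
DEFAULT_TUMOUR_VOLUMES_ML = (0.15, 0.40, 0.69, 1.68, 2.56, 3.72, 5.34, 8.09)


class TumourError(ValueError):
    pass


@dataclass
class TumourSeed:
    """A tumour centre: voxel position plus fractional liver-bbox coordinates."""

    index: int
    voxel: tuple[int, int, int]
    frac: tuple[float, float, float]


@dataclass
class TumourSet:
    """Grown tumours: seeds, targets, and realised voxel masks (index arrays)."""

    seeds: list[TumourSeed]
    target_volumes_ml: tuple[float, ...]
    masks: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    voxel_volume_ml: float
    shape: tuple[int, int, int]

    @property
    def realised_volumes_ml(self) -> list[float]:
        return [m[0].size * self.voxel_volume_ml for m in self.masks]

    def mask_array(self, index: int) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        ii, jj, kk = self.masks[index]
        out[ii, jj, kk] = True
        return out

    def combined_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for ii, jj, kk in self.masks:
            out[ii, jj, kk] = True
        return out

    def label_volume(self) -> np.ndarray:
        """Integer label image: tumour index + 1 per voxel, 0 elsewhere."""
        out = np.zeros(self.shape, dtype=np.int16)
        for i, (ii, jj, kk) in enumerate(self.masks):
            out[ii, jj, kk] = i + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seed, target, realised in zip(
            self.seeds, self.target_volumes_ml, self.realised_volumes_ml
        ):
            rows.append(
                {
                    "index": seed.index,
                    "target_mL": target,
                    "realised_mL": realised,
                    "seed_x": seed.voxel[0],
                    "seed_y": seed.voxel[1],
                    "seed_z": seed.voxel[2],
                    "frac_x": seed.frac[0],
                    "frac_y": seed.frac[1],
                    "frac_z": seed.frac[2],
                }
            )
        return pd.DataFrame(rows)


def _bbox(mask: np.ndarray):
    idx = np.nonzero(mask)
    return tuple((int(a.min()), int(a.max())) for a in idx)


def _fractional(voxel, bbox):
    return tuple(
        0.5 if hi == lo else (v - lo) / (hi - lo) for v, (lo, hi) in zip(voxel, bbox)
    )


def place_seeds(
    liver_mask: np.ndarray,
    spacing: tuple[float, float, float],
    n: int = 8,
    min_separation_mm: float = 28.0,
    margin_mm: float = 10.0,
    rng_seed: int = 0,
    exclude_mask: np.ndarray | None = None,
    restarts: int = 20,
) -> list[TumourSeed]:
    """Uniformly sample ``n`` seed voxels from the eligible liver interior.

    Eligible voxels lie at least ``margin_mm`` from the liver boundary and
    outside ``exclude_mask`` (used by the pipeline to protect the liver-VOI
    region).  Seeds are drawn greedily in random order enforcing pairwise
    separation; up to ``restarts`` reshuffles are attempted before failing
    with the best achievable count.
    """
    if not liver_mask.any():
        raise TumourError("liver mask is empty")
    dist = ndimage.distance_transform_edt(liver_mask, sampling=spacing)
    eligible = liver_mask & (dist >= margin_mm)
    if exclude_mask is not None:
        eligible &= ~exclude_mask
    cand = np.array(np.nonzero(eligible)).T
    if cand.shape[0] == 0:
        raise TumourError("no eligible seed voxels (margin too large?)")
    pos = cand * np.asarray(spacing)[None, :]
    rng = np.random.default_rng(rng_seed)
    best: list[int] = []
    for _ in range(max(restarts, 1)):
        order = rng.permutation(cand.shape[0])
        chosen: list[int] = []
        for idx in order:
            p = pos[idx]
            if all(np.linalg.norm(p - pos[j]) >= min_separation_mm for j in chosen):
                chosen.append(idx)
                if len(chosen) == n:
                    break
        if len(chosen) > len(best):
            best = chosen
        if len(best) == n:
            break
    if len(best) < n:
        raise TumourError(
            f"could only place {len(best)} of {n} seeds with separation "
            f">= {min_separation_mm} mm and margin {margin_mm} mm"
        )
    bbox = _bbox(liver_mask)
    seeds = []
    for i, idx in enumerate(best):
        voxel = tuple(int(v) for v in cand[idx])
        seeds.append(TumourSeed(index=i + 1, voxel=voxel, frac=_fractional(voxel, bbox)))
    return seeds


def grow_tumour(
    phantom: CodePhantom,
    seed: TumourSeed,
    target_volume_ml: float,
    claimed: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grow one tumour: the n nearest liver voxels to the seed centre.

    n = round(target / V_vox); physical (anisotropic) distances; ties broken
    lexicographically by (z, y, x).  Voxels in ``claimed`` are excluded; the
    mask is clipped to the liver, so the realised volume can fall short only
    when the liver region around the seed is exhausted.
    """
    vvox = phantom.voxel_volume_ml
    n = int(round(target_volume_ml / vvox))
    if n < 1:
        raise TumourError(
            f"target volume {target_volume_ml} mL is below half a voxel ({vvox / 2:.4f} mL)"
        )
    region = phantom.codes == st.LIVER
    if claimed is not None:
        region &= ~claimed
    ii, jj, kk = np.nonzero(region)
    if ii.size == 0:
        raise TumourError("no liver voxels available")
    sx, sy, sz = phantom.spacing
    cx, cy, cz = (seed.voxel[0] * sx, seed.voxel[1] * sy, seed.voxel[2] * sz)
    d2 = (ii * sx - cx) ** 2 + (jj * sy - cy) ** 2 + (kk * sz - cz) ** 2
    order = np.lexsort((ii, jj, kk, d2))
    pick = order[: min(n, order.size)]
    return ii[pick], jj[pick], kk[pick]


def grow_tumour_set(
    phantom: CodePhantom,
    seeds: list[TumourSeed],
    target_volumes_ml: tuple[float, ...] = DEFAULT_TUMOUR_VOLUMES_ML,
) -> TumourSet:
    """Grow all tumours in seed-index order; later tumours exclude voxels
    already claimed, so masks are pairwise disjoint."""
    if len(seeds) != len(target_volumes_ml):
        raise TumourError("need one target volume per seed")
    claimed = np.zeros(phantom.codes.shape, dtype=bool)
    masks = []
    for seed, target in zip(seeds, target_volumes_ml):
        ii, jj, kk = grow_tumour(phantom, seed, target, claimed=claimed)
        claimed[ii, jj, kk] = True
        masks.append((ii, jj, kk))
    return TumourSet(
        seeds=list(seeds),
        target_volumes_ml=tuple(target_volumes_ml),
        masks=masks,
        voxel_volume_ml=phantom.voxel_volume_ml,
        shape=phantom.codes.shape,
    )


def apply_tumours(phantom: CodePhantom, tumour_set: TumourSet) -> CodePhantom:
    """Overwrite liver codes with the tumour code (tumour takes precedence)."""
    codes = phantom.codes.copy()
    for ii, jj, kk in tumour_set.masks:
        codes[ii, jj, kk] = st.TUMOUR
    return phantom.with_codes(codes)


def transfer_seeds(
    seeds: list[TumourSeed],
    source_liver_mask: np.ndarray,
    target_liver_mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[TumourSeed]:
    """Map seeds between livers via fractional bounding-box coordinates,
    snapping each to the nearest target-liver voxel (physical distance)."""
    if not source_liver_mask.any() or not target_liver_mask.any():
        raise TumourError("both livers must be nonempty")
    tgt_bbox = _bbox(target_liver_mask)
    cand = np.array(np.nonzero(target_liver_mask)).T
    pos = cand * np.asarray(spacing)[None, :]
    out = []
    for seed in seeds:
        cont = np.array(
            [lo + f * (hi - lo) for f, (lo, hi) in zip(seed.frac, tgt_bbox)], dtype=float
        )
        cont_mm = cont * np.asarray(spacing)
        j = int(np.argmin(np.sum((pos - cont_mm[None, :]) ** 2, axis=1)))
        voxel = tuple(int(v) for v in cand[j])
        out.append(TumourSeed(index=seed.index, voxel=voxel, frac=_fractional(voxel, tgt_bbox)))
    return out
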