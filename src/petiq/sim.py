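"""Desk-scale PET acquisition and OSEM reconstruction.

The acquisition model keeps the two mechanisms that couple image noise to
patient habitus -- Poisson counting statistics and 511 keV attenuation --
and drops everything else (3-D system response, TOF, detector blocks,
randoms/scatter estimation).  Slices are acquired independently with a 2-D
parallel-beam geometry:

    lambda = s * t * attn .* (A a)  +  r,     counts ~ Poisson(lambda)

with ``a`` the activity map (Bq/voxel), ``attn = exp(-ds * A mu)`` the
per-line attenuation survival, ``s`` a scalar sensitivity (expected counts
per Bq * min per view), ``t`` the acquisition time per bed position, and
``r`` a uniform additive background standing in for scatter+randoms,
contributing a known fraction ``b`` of total counts.

Reconstruction is OSEM with the attenuated system model (so attenuation
and background are "corrected" in the sense that they are modelled),
followed by an anisotropic Gaussian post-filter; output is in Bq/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .activity import ActivityMap
from .phantom import CodePhantom
from .projector import ParallelProjector, get_projector
from .structures import StructureTable

#: Linear attenuation coefficient of water at 511 keV, mm^-1.
MU_WATER_511_MM = 0.0096

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def attenuation_map(
    phantom: CodePhantom,
    table: StructureTable | None = None,
    mu_water_mm: float = MU_WATER_511_MM,
) -> np.ndarray:
    """Voxelwise 511 keV linear attenuation: mu = mu_water * density / 1.0."""
    table = table or phantom.table
    if table is None:
        raise ValueError("no structure table supplied")
    table.check_covers(phantom.codes)
    dens = np.nan_to_num(table.density_lut(max_code=int(phantom.codes.max())))
    return (mu_water_mm * dens)[phantom.codes]


@dataclass
class Sinogram:
    """Measured counts, (n_angles, n_bins, nz), plus acquisition metadata."""

    counts: np.ndarray
    t_min: float
    sensitivity: float
    background_fraction: float
    background_level: float  # expected background counts per sinogram element
    n_angles: int
    pixel_mm: float
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def nz(self) -> int:
        return self.counts.shape[2]


@dataclass
class ReconImage:
    """Reconstructed activity concentration (Bq/mL), (nx, ny, nz)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)


def _as_columns(vol: np.ndarray) -> np.ndarray:
    nx, ny, nz = vol.shape
    return vol.reshape(nx * ny, nz)


def expected_sinogram(
    activity: np.ndarray,
    mu: np.ndarray,
    t_min: float,
    sensitivity: float,
    background_fraction: float,
    projector: ParallelProjector,
) -> tuple[np.ndarray, float]:
    """Noise-free expected counts and the uniform background level."""
    proj = projector.project(_as_columns(activity))
    attn = np.exp(-projector.ds * projector.project(_as_columns(mu)))
    trues = sensitivity * t_min * proj * attn
    b = background_fraction
    if not (0.0 <= b < 1.0):
        raise ValueError("background fraction must be in [0, 1)")
    r = b / (1.0 - b) * trues.sum() / trues.size if b > 0 else 0.0
    return trues, float(r)


def simulate_counts(
    activity: ActivityMap | np.ndarray,
    mu: np.ndarray,
    t_min: float = 3.0,
    sensitivity: float = 1e-4,
    background_fraction: float = 0.3,
    rng_seed=0,
    projector: ParallelProjector | None = None,
    pixel_mm: float | None = None,
    n_angles: int = 96,
) -> Sinogram:
    """Sample a Poisson sinogram of the activity map (reproducible per seed)."""
    if isinstance(activity, ActivityMap):
        if pixel_mm is None:
            pixel_mm = activity.spacing[0]
        act = activity.values
    else:
        act = activity
        if pixel_mm is None and projector is None:
            raise ValueError("pixel_mm required when passing a bare array")
    if act.shape != mu.shape:
        raise ValueError(f"activity grid {act.shape} does not match mu grid {mu.shape}")
    if t_min <= 0 or sensitivity <= 0:
        raise ValueError("acquisition time and sensitivity must be positive")
    if projector is None:
        projector = get_projector(act.shape[0], float(pixel_mm), n_angles)
    trues, r = expected_sinogram(
        act, mu, t_min, sensitivity, background_fraction, projector
    )
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    counts = rng.poisson(trues + r).astype(np.int64)
    nz = act.shape[2]
    return Sinogram(
        counts=counts.reshape(projector.n_angles, projector.n_bins, nz),
        t_min=float(t_min),
        sensitivity=float(sensitivity),
        background_fraction=float(background_fraction),
        background_level=r,
        n_angles=projector.n_angles,
        pixel_mm=projector.ds,
    )


def reconstruct(
    sino: Sinogram,
    mu: np.ndarray,
    iterations: int = 3,
    subsets: int = 16,
    fwhm_trans_mm: float = 5.5,
    fwhm_ax_mm: float = 4.0,
    spacing: tuple[float, float, float] | None = None,
    projector: ParallelProjector | None = None,
    attn: np.ndarray | None = None,
) -> ReconImage:
    """OSEM reconstruction with attenuation + background in the system model.

    All slices are updated together (the per-slice problems share the
    system matrix).  Voxel estimates (Bq/voxel) are converted to Bq/mL and
    post-filtered with the anisotropic Gaussian kernel.  Output is
    non-negative by construction.
    """
    n = mu.shape[0]
    if spacing is None:
        spacing = (sino.pixel_mm, sino.pixel_mm, sino.pixel_mm)
    if projector is None:
        projector = get_projector(n, sino.pixel_mm, sino.n_angles)
    if mu.shape[0] != n or mu.shape[1] != n or mu.shape[2] != sino.nz:
        raise ValueError("mu grid inconsistent with sinogram")
    subs = projector.subsets(subsets)  # raises if subsets do not divide angles

    nz = sino.nz
    y = sino.counts.reshape(projector.n_angles * projector.n_bins, nz).astype(np.float64)
    if attn is None:
        attn = np.exp(-projector.ds * projector.project(_as_columns(mu)))
    st = sino.sensitivity * sino.t_min
    r = sino.background_level
    support = projector.support.astype(np.float64)[:, None]

    X = np.full((n * n, nz), 1.0) * support
    eps = 1e-12
    attn_subs = [attn[sub["rows"]] for sub in subs]
    sens_subs = [sub["AT"] @ ak for sub, ak in zip(subs, attn_subs)]
    for _ in range(iterations):
        for sub, attn_k, sens in zip(subs, attn_subs, sens_subs):
            f = st * attn_k * (sub["A"] @ X) + r
            ratio = np.divide(y[sub["rows"]], f, out=np.zeros_like(f), where=f > eps)
            back = sub["AT"] @ (attn_k * ratio)
            X *= np.divide(back, sens, out=np.zeros_like(back), where=sens > eps)

    vvox_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    img = (X / vvox_ml).reshape(n, n, nz)
    sigmas = (
        fwhm_trans_mm / _FWHM_TO_SIGMA / spacing[0],
        fwhm_trans_mm / _FWHM_TO_SIGMA / spacing[1],
        fwhm_ax_mm / _FWHM_TO_SIGMA / spacing[2],
    )
    if any(s > 0 for s in sigmas):
        img = ndimage.gaussian_filter(img, sigma=sigmas)
    return ReconImage(
        values=img,
        spacing=spacing,
        meta={
            "iterations": iterations,
            "subsets": subsets,
            "fwhm_trans_mm": fwhm_trans_mm,
            "fwhm_ax_mm": fwhm_ax_mm,
            "sensitivity": sino.sensitivity,
            "t_min": sino.t_min,
        },
    )
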