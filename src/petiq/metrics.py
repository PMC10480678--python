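"""Image-quality metrics: NEMA sphere SNR/CNR, liver SNR, tumour CNR.

Conventions fixed here and used by every printed-value comparison:

* standard deviations are *population* SDs (divisor N);
* the background SD pools the voxels of all 60 background ROIs (the
  literal definition used in the source analysis, which differs from the
  NEMA NU-2 "background variability" statistic);
* the Rose-criterion threshold is inclusive: CNR >= 5 passes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage

from . import structures as st
from .phantom import CodePhantom
from .sim import ReconImage

NEMA_SPHERE_DIAMETERS_MM = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)
ROSE_THRESHOLD = 5.0


class MetricsError(ValueError):
    pass


def _values(image) -> np.ndarray:
    return image.values if isinstance(image, ReconImage) else np.asarray(image)


def _pop_sd(x: np.ndarray) -> float:
    return float(np.std(x))  # numpy default ddof=0 = population SD


# ---------------------------------------------------------------------------
# NEMA image-quality phantom
# ---------------------------------------------------------------------------


@dataclass
class NemaGeometry:
    """In-plane geometry of the synthetic NEMA-style IQ fixture."""

    body_semi_axes_mm: tuple[float, float]
    sphere_ring_radius_mm: float
    sphere_angles_deg: tuple[float, ...]
    sphere_diameters_mm: tuple[float, ...]
    centre_mm: tuple[float, float]  # physical in-plane centre of the fixture
    central_slice: int
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def sphere_centres_mm(self) -> list[tuple[float, float]]:
        out = []
        for ang in self.sphere_angles_deg:
            th = np.deg2rad(ang)
            out.append(
                (
                    self.centre_mm[0] + self.sphere_ring_radius_mm * np.cos(th),
                    self.centre_mm[1] + self.sphere_ring_radius_mm * np.sin(th),
                )
            )
        return out


@dataclass
class NemaResult:
    """Per-diameter background statistics and sphere SNR/CNR."""

    diameters_mm: tuple[float, ...]
    background_mean: dict[float, float]
    background_sd: dict[float, float]
    sphere_mean: dict[float, float]
    snr: dict[float, float] = field(default_factory=dict)
    cnr: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in self.diameters_mm:
            self.snr[d] = self.background_mean[d] / self.background_sd[d]
            self.cnr[d] = (self.sphere_mean[d] - self.background_mean[d]) / self.background_sd[d]


def _load_roi_template() -> list[tuple[float, float]]:
    with resources.files("petiq.data").joinpath("nema_roi_template.json").open() as fh:
        data = json.load(fh)
    return [tuple(p) for p in data["positions_frac"]]


def _disc_mask(shape_xy, spacing, centre_mm, radius_mm) -> np.ndarray:
    nx, ny = shape_xy
    xs = (np.arange(nx) + 0.5) * spacing[0]
    ys = (np.arange(ny) + 0.5) * spacing[1]
    return (xs[:, None] - centre_mm[0]) ** 2 + (ys[None, :] - centre_mm[1]) ** 2 <= radius_mm**2


def nema_background_rois(geom: NemaGeometry, diameter_mm: float) -> list[np.ndarray]:
    """The 60 background ROI masks for one ROI diameter.

    12 in-plane template positions (a fixed fractional layout scaled to the
    fixture's semi-axes) replicated on the central slice and the slices
    nearest +-1 cm and +-2 cm.  Every ROI must lie in the background, at
    least 15 mm from the body edge and from every sphere; violations raise.
    """
    a, b = geom.body_semi_axes_mm
    roi_r = diameter_mm / 2.0
    margin = 15.0
    positions = [(geom.centre_mm[0] + u * a, geom.centre_mm[1] + v * b) for u, v in _load_roi_template()]
    spheres = list(zip(geom.sphere_centres_mm(), geom.sphere_diameters_mm))
    for px, py in positions:
        # edge clearance: shrink the body ellipse by (margin + roi radius)
        ea, eb = a - margin - roi_r, b - margin - roi_r
        if ea <= 0 or eb <= 0 or (
            ((px - geom.centre_mm[0]) / ea) ** 2 + ((py - geom.centre_mm[1]) / eb) ** 2 > 1.0
        ):
            raise MetricsError(
                f"cannot fit 12 background ROIs of {diameter_mm} mm: "
                f"position ({px:.0f}, {py:.0f}) too close to the phantom edge"
            )
        for (sx_, sy_), sd in spheres:
            if np.hypot(px - sx_, py - sy_) < sd / 2.0 + margin + roi_r:
                raise MetricsError(
                    f"background ROI at ({px:.0f}, {py:.0f}) within 15 mm of the "
                    f"{sd:.0f} mm sphere"
                )
    nx, ny, nz = geom.shape
    sz = geom.spacing[2]
    offsets = sorted({int(round(off / sz)) for off in (-20.0, -10.0, 0.0, 10.0, 20.0)})
    if len(offsets) != 5:
        raise MetricsError("slice spacing too coarse to separate the five NEMA ROI slices")
    masks = []
    for off in offsets:
        k = geom.central_slice + off
        if not (0 <= k < nz):
            raise MetricsError("NEMA ROI slice outside the image")
        for pos in positions:
            disc = _disc_mask((nx, ny), geom.spacing, pos, roi_r)
            if not disc.any():
                raise MetricsError("empty background ROI (grid too coarse)")
            m = np.zeros((nx, ny, nz), dtype=bool)
            m[:, :, k] = disc
            masks.append(m)
    return masks


def nema_metrics(
    image,
    geom: NemaGeometry,
    diameters_mm: tuple[float, ...] = NEMA_SPHERE_DIAMETERS_MM,
) -> NemaResult:
    """SNR_i and CNR_i per sphere diameter.

    Background mean = mean of the 60 ROI means; background SD = population
    SD over the pooled voxels of the 60 ROIs; sphere mean = mean of the
    central-slice disc of the sphere's own diameter.
    """
    vals = _values(image)
    bg_mean: dict[float, float] = {}
    bg_sd: dict[float, float] = {}
    sph_mean: dict[float, float] = {}
    centres = geom.sphere_centres_mm()
    for d in diameters_mm:
        rois = nema_background_rois(geom, d)
        means = [float(vals[m].mean()) for m in rois]
        pooled = np.concatenate([vals[m] for m in rois])
        sd = _pop_sd(pooled)
        if sd == 0:
            raise MetricsError("degenerate background: zero SD over background ROIs")
        i = geom.sphere_diameters_mm.index(d)
        disc = _disc_mask(vals.shape[:2], geom.spacing, centres[i], d / 2.0)
        sph = vals[:, :, geom.central_slice][disc]
        bg_mean[d] = float(np.mean(means))
        bg_sd[d] = sd
        sph_mean[d] = float(sph.mean())
    return NemaResult(
        diameters_mm=tuple(diameters_mm),
        background_mean=bg_mean,
        background_sd=bg_sd,
        sphere_mean=sph_mean,
    )


# ---------------------------------------------------------------------------
# liver SNR / tumour CNR
# ---------------------------------------------------------------------------


def place_liver_voi(
    phantom: CodePhantom,
    tumour_mask: np.ndarray | None = None,
    diameter_mm: float = 25.0,
) -> np.ndarray:
    """Spherical VOI in the most uniform part of the liver.

    Centre = liver voxel maximising distance to the liver boundary and to
    tumour voxels (deterministic tie-break: lowest z, y, x); the full
    sphere must fit inside liver-minus-tumours.
    """
    liver = phantom.mask(st.LIVER)
    if tumour_mask is not None:
        liver = liver & ~tumour_mask
    if not liver.any():
        raise MetricsError("liver mask is empty")
    dist = ndimage.distance_transform_edt(liver, sampling=phantom.spacing)
    r = diameter_mm / 2.0
    if dist.max() < r:
        raise MetricsError(
            f"liver cannot contain a {diameter_mm} mm VOI (max inscribed "
            f"radius {dist.max():.1f} mm)"
        )
    ii, jj, kk = np.nonzero(dist == dist.max())
    order = np.lexsort((ii, jj, kk))[0]
    ci, cj, ck = int(ii[order]), int(jj[order]), int(kk[order])
    sx, sy, sz = phantom.spacing
    nx, ny, nz = phantom.codes.shape
    xs = (np.arange(nx) - ci) * sx
    ys = (np.arange(ny) - cj) * sy
    zs = (np.arange(nz) - ck) * sz
    voi = (
        xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
    ) <= r**2
    if tumour_mask is not None and (voi & tumour_mask).any():
        raise MetricsError("liver VOI overlaps a tumour")
    return voi


def liver_snr(image, voi: np.ndarray) -> float:
    """SNR_L = VOI mean / VOI voxel SD (population)."""
    vals = _values(image)[voi]
    if vals.size == 0:
        raise MetricsError("empty VOI")
    sd = _pop_sd(vals)
    if sd == 0:
        raise MetricsError("zero SD in liver VOI")
    return float(vals.mean()) / sd


def tumour_cnr(image, tumour_mask: np.ndarray, voi: np.ndarray) -> tuple[float, bool]:
    """CNR = (tumour mean - liver mean) / liver SD; Rose pass at CNR >= 5."""
    vals = _values(image)
    liver_vals = vals[voi]
    tum_vals = vals[tumour_mask]
    if liver_vals.size == 0 or tum_vals.size == 0:
        raise MetricsError("empty mask")
    sd = _pop_sd(liver_vals)
    if sd == 0:
        raise MetricsError("zero SD in liver VOI")
    cnr = (float(tum_vals.mean()) - float(liver_vals.mean())) / sd
    # inclusive threshold, robust to float round-off at the boundary
    return cnr, bool(cnr >= ROSE_THRESHOLD - 1e-9)
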