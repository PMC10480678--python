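"""Synthetic NEMA-style image-quality fixture.

A stand-in for the physical NEMA IQ phantom: an elliptical water body with
six fillable spheres (37-10 mm) on a ring in the central slice, background
filled at 10.3 kBq/mL and spheres at 41.0 kBq/mL (sphere-to-background
ratio ~4:1).  The body outline is simplified (no lung insert) and slightly
enlarged so the 12-position background-ROI template keeps 15 mm clearance
from both the edge and the spheres at every ROI diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import NEMA_SPHERE_DIAMETERS_MM, NemaGeometry
from .sim import MU_WATER_511_MM

BACKGROUND_KBQ_ML = 10.3
SPHERE_KBQ_ML = 41.0


@dataclass
class NemaFixture:
    activity_bq_per_voxel: np.ndarray
    mu: np.ndarray
    sphere_masks: dict[float, np.ndarray]
    body_mask: np.ndarray
    geometry: NemaGeometry

    @property
    def true_ratio(self) -> float:
        return SPHERE_KBQ_ML / BACKGROUND_KBQ_ML


def build_nema_fixture(
    spacing: tuple[float, float, float] = (5.46, 5.46, 5.58),
    grid_xy: tuple[int, int] = (112, 112),
    length_mm: float = 180.0,
    body_semi_axes_mm: tuple[float, float] = (165.0, 130.0),
    sphere_ring_radius_mm: float = 57.2,
    background_kbq_ml: float = BACKGROUND_KBQ_ML,
    sphere_kbq_ml: float = SPHERE_KBQ_ML,
) -> NemaFixture:
    nx, ny = grid_xy
    sx, sy, sz = spacing
    nz = max(int(round(length_mm / sz)) | 1, 9)  # odd -> well-defined centre
    central = nz // 2
    cx, cy = nx * sx / 2.0, ny * sy / 2.0
    a, b = body_semi_axes_mm
    if 2 * a > 0.95 * nx * sx or 2 * b > 0.95 * ny * sy:
        raise ValueError("fixture does not fit the grid")

    xs = (np.arange(nx) + 0.5) * sx
    ys = (np.arange(ny) + 0.5) * sy
    zs = (np.arange(nz) + 0.5) * sz
    body2d = ((xs[:, None] - cx) / a) ** 2 + ((ys[None, :] - cy) / b) ** 2 <= 1.0
    body = np.repeat(body2d[:, :, None], nz, axis=2)

    geom = NemaGeometry(
        body_semi_axes_mm=(a, b),
        sphere_ring_radius_mm=sphere_ring_radius_mm,
        sphere_angles_deg=tuple(60.0 * i for i in range(6)),
        sphere_diameters_mm=NEMA_SPHERE_DIAMETERS_MM,
        centre_mm=(cx, cy),
        central_slice=central,
        spacing=spacing,
        shape=(nx, ny, nz),
    )

    vvox_ml = sx * sy * sz / 1000.0
    conc = np.where(body, background_kbq_ml, 0.0)
    sphere_masks: dict[float, np.ndarray] = {}
    zc = zs[central]
    for (px, py), d in zip(geom.sphere_centres_mm(), geom.sphere_diameters_mm):
        r = d / 2.0
        m = (
            (xs[:, None, None] - px) ** 2
            + (ys[None, :, None] - py) ** 2
            + (zs[None, None, :] - zc) ** 2
        ) <= r**2
        if not m.any():  # sub-voxel sphere: keep at least the centre voxel
            m[int(px / sx), int(py / sy), central] = True
        sphere_masks[d] = m
        conc[m] = sphere_kbq_ml

    activity = conc * 1000.0 * vvox_ml  # kBq/mL -> Bq per voxel
    mu = np.where(body, MU_WATER_511_MM, 0.0)
    return NemaFixture(
        activity_bq_per_voxel=activity,
        mu=mu,
        sphere_masks=sphere_masks,
        body_mask=body,
        geometry=geom,
    )
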