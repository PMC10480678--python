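"""SUV-based activity painting with 68Ga physical decay.

Each voxel receives

    A_vox = A_inj * SUV(code) * V_vox / w_T        [Bq per voxel]

with A_inj the injected activity in Bq, V_vox the voxel volume in mL and
w_T the phantom weight in grams (the 1 g ~ 1 mL body-average convention).
Physical decay over the uptake period multiplies the whole map; biological
redistribution and excretion are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import CodePhantom, phantom_weight_kg
from .structures import StructureTable

#: 68Ga physical half-life in minutes.
GA68_HALF_LIFE_MIN = 67.71


def decay_factor(delta_t_min: float, half_life_min: float = GA68_HALF_LIFE_MIN) -> float:
    """exp(-ln2 * dt / T_half); dt in minutes."""
    if delta_t_min < 0:
        raise ValueError("decay interval must be non-negative")
    return float(np.exp(-np.log(2.0) * delta_t_min / half_life_min))


@dataclass
class ActivityMap:
    """Per-voxel activity (Bq/voxel) at the reference time post-injection."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    injected_mbq: float
    uptake_min: float
    decay_applied: float
    meta: dict = field(default_factory=dict)

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def total_bq(self) -> float:
        return float(self.values.sum())


def paint_activity(
    phantom: CodePhantom,
    table: StructureTable | None = None,
    a_inj_mbq: float = 100.0,
    uptake_min: float = 60.0,
    half_life_min: float = GA68_HALF_LIFE_MIN,
) -> ActivityMap:
    """Paint the voxelwise activity map for an injected activity (MBq).

    The map is linear in ``a_inj_mbq`` and zero outside the body.  Raises
    KeyError naming any phantom code absent from the table.
    """
    if a_inj_mbq < 0:
        raise ValueError("injected activity must be non-negative")
    table = table or phantom.table
    if table is None:
        raise ValueError("no structure table supplied")
    table.check_covers(phantom.codes)
    w_g = phantom_weight_kg(phantom, table) * 1000.0
    suv = np.nan_to_num(table.suv_lut(max_code=int(phantom.codes.max())))
    f = decay_factor(uptake_min, half_life_min)
    values = (
        suv[phantom.codes] * (a_inj_mbq * 1e6 * phantom.voxel_volume_ml / w_g) * f
    ).astype(np.float64)
    return ActivityMap(
        values=values,
        spacing=phantom.spacing,
        injected_mbq=a_inj_mbq,
        uptake_min=uptake_min,
        decay_applied=f,
        meta={"phantom": phantom.name, "weight_kg": w_g / 1000.0},
    )


def compute_imaged_fraction(amap: ActivityMap, phantom: CodePhantom) -> float:
    """Fraction of the *injected* activity inside the imaged axial range.

    Defined at paint time (before decay): any decay factor already applied
    to the map is divided back out.
    """
    if amap.injected_mbq == 0:
        return 0.0
    lo, hi = phantom.imaged_range
    inside = float(amap.values[:, :, lo:hi].sum())
    return inside / (amap.injected_mbq * 1e6 * amap.decay_applied)
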