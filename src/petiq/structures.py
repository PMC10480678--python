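"""Structure lookup table: voxel code -> (name, density, SUV).

The table carries the two physical attributes each anatomical structure
needs downstream: mass density (g/cm^3), which drives both phantom weight
and 511 keV attenuation, and the standardised uptake value (SUV), which
drives activity painting.  SUV here follows the body-weight convention:
SUV = concentration [Bq/mL] * body weight [g] / injected activity [Bq],
so SUV = 1 corresponds to the whole-body-average concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Canonical voxel codes used by the phantom builder.
AIR = 0
SOFT_TISSUE = 1
LUNG = 2
LIVER = 3
SPLEEN = 4
KIDNEY = 5
PANCREAS = 6
STOMACH_WALL = 7
BLADDER = 8
TUMOUR = 9

CODE_NAMES = {
    AIR: "air",
    SOFT_TISSUE: "soft_tissue",
    LUNG: "lung",
    LIVER: "liver",
    SPLEEN: "spleen",
    KIDNEY: "kidneys",
    PANCREAS: "pancreas",
    STOMACH_WALL: "stomach_wall",
    BLADDER: "bladder_contents",
    TUMOUR: "tumours",
}


@dataclass
class StructureTable:
    """Lookup table mapping integer structure codes to density and SUV.

    Stored as a small DataFrame with columns ``code, name, density_g_cm3,
    suv``.  Fast array lookups are exposed via :meth:`density_lut` /
    :meth:`suv_lut` for voxelwise painting.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"code", "name", "density_g_cm3", "suv"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"structure table missing columns: {sorted(missing)}")
        if self.df["code"].duplicated().any():
            raise ValueError("duplicate structure codes in table")
        body = self.df[self.df["code"] != AIR]
        if (body["density_g_cm3"] <= 0).any():
            raise ValueError("body structures must have density > 0")
        if (self.df["suv"] < 0).any():
            raise ValueError("SUV must be non-negative")
        self.df = self.df.sort_values("code").reset_index(drop=True)

    # -- lookups ---------------------------------------------------------
    @property
    def codes(self) -> np.ndarray:
        return self.df["code"].to_numpy()

    def has_code(self, code: int) -> bool:
        return int(code) in set(int(c) for c in self.codes)

    def density(self, code: int) -> float:
        return float(self._col(code, "density_g_cm3"))

    def suv(self, code: int) -> float:
        return float(self._col(code, "suv"))

    def name(self, code: int) -> str:
        return str(self._col(code, "name"))

    def code_of(self, name: str) -> int:
        row = self.df[self.df["name"] == name]
        if row.empty:
            raise KeyError(f"no structure named {name!r}")
        return int(row["code"].iloc[0])

    def _col(self, code: int, col: str):
        row = self.df[self.df["code"] == int(code)]
        if row.empty:
            raise KeyError(f"structure code {code} not in table")
        return row[col].iloc[0]

    def _lut(self, col: str, max_code: int | None = None) -> np.ndarray:
        top = int(self.codes.max())
        if max_code is not None:
            top = max(top, int(max_code))
        lut = np.full(top + 1, np.nan)
        lut[self.codes] = self.df[col].to_numpy()
        return lut

    def density_lut(self, max_code: int | None = None) -> np.ndarray:
        """Dense array ``lut[code] -> density``; NaN marks missing codes."""
        return self._lut("density_g_cm3", max_code)

    def suv_lut(self, max_code: int | None = None) -> np.ndarray:
        return self._lut("suv", max_code)

    def check_covers(self, codes: np.ndarray) -> None:
        """Raise KeyError naming the first voxel code absent from the table."""
        present = np.unique(codes)
        known = set(int(c) for c in self.codes)
        for c in present:
            if int(c) not in known:
                raise KeyError(f"phantom contains code {int(c)} not present in structure table")

    # -- modification ----------------------------------------------------
    def with_density(self, code: int, density: float) -> "StructureTable":
        df = self.df.copy()
        df.loc[df["code"] == int(code), "density_g_cm3"] = float(density)
        return StructureTable(df)

    def with_suv(self, code: int, suv: float) -> "StructureTable":
        df = self.df.copy()
        df.loc[df["code"] == int(code), "suv"] = float(suv)
        return StructureTable(df)

    # -- serialisation ---------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StructureTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_records(cls, records) -> "StructureTable":
        return cls(pd.DataFrame(records, columns=["code", "name", "density_g_cm3", "suv"]))


# Published density/SUV assignments for the high-uptake structures; the
# rest-of-body entries (soft tissue, lungs) are calibration constants chosen
# once so that a default cohort phantom holds ~40% of the injected activity
# within the imaged range (see docs/methods.md).
_DEFAULT_ROWS = [
    (AIR, "air", 0.0, 0.0),
    (SOFT_TISSUE, "soft_tissue", 1.00, 0.021),
    (LUNG, "lung", 0.26, 0.35),
    (LIVER, "liver", 1.06, 9.5),
    (SPLEEN, "spleen", 1.06, 23.2),
    (KIDNEY, "kidneys", 1.05, 9.7),
    (PANCREAS, "pancreas", 1.04, 5.5),
    (STOMACH_WALL, "stomach_wall", 1.05, 7.0),
    (BLADDER, "bladder_contents", 1.00, 12.0),
    (TUMOUR, "tumours", 1.05, 22.9),
]


def default_structure_table() -> StructureTable:
    """The default code -> (density, SUV) lookup used by the cohort builder."""
    return StructureTable.from_records(list(_DEFAULT_ROWS))
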