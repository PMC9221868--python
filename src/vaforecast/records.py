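"""Core domain containers: one eye-visit and one per-eye visit series.

A visit carries the 22 numerical OCT scalars read off the ETDRS macular
grid (central-point average/min/max thickness and total volume, plus
average thickness and volume for each of the nine grid zones C0, N1, N2,
S1, S2, T1, T2, I1, I2), the anti-VEGF treatment flag, the decimal
visual acuity, and an optional fundus-image reference. Thicknesses are
in millimetres, volumes in cubic millimetres, VA is decimal in [0, 1].
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

ZONES: tuple[str, ...] = ("C0", "N1", "N2", "S1", "S2", "T1", "T2", "I1", "I2")

GLOBAL_FEATURES: tuple[str, ...] = (
    "central_thickness",
    "min_central_thickness",
    "max_central_thickness",
    "total_volume",
)

#: Canonical order of the 22 OCT scalars used everywhere downstream.
FEATURE_NAMES: tuple[str, ...] = GLOBAL_FEATURES + tuple(
    f"{z}_{kind}" for z in ZONES for kind in ("avg_thickness", "volume")
)

N_FEATURES = len(FEATURE_NAMES)  # 22


class VAConversionError(ValueError):
    """Raised when a visual-acuity notation cannot be interpreted."""


class XMLParseError(ValueError):
    """Raised when an OCT metadata file contains a malformed value."""


class ConfigurationError(ValueError):
    """Raised for invalid generator or run configuration."""


@dataclass
class VisitRecord:
    """One medical examination of one eye."""

    visit_date: dt.date
    zone_avg_thickness: dict[str, float | None] = field(default_factory=dict)
    zone_volume: dict[str, float | None] = field(default_factory=dict)
    central_thickness: float | None = None
    min_central_thickness: float | None = None
    max_central_thickness: float | None = None
    total_volume: float | None = None
    treated: bool = False
    va: float | None = None
    image_path: str | None = None
    valid_pixel_percentage: dict[str, float | None] = field(default_factory=dict)

    def feature_vector(self) -> np.ndarray:
        """The 22 OCT scalars in :data:`FEATURE_NAMES` order (NaN if missing)."""
        vals = [
            self.central_thickness,
            self.min_central_thickness,
            self.max_central_thickness,
            self.total_volume,
        ]
        for z in ZONES:
            vals.append(self.zone_avg_thickness.get(z))
            vals.append(self.zone_volume.get(z))
        return np.array([np.nan if v is None else float(v) for v in vals])

    @classmethod
    def from_feature_vector(
        cls, visit_date: dt.date, values: np.ndarray, **kwargs
    ) -> "VisitRecord":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} OCT scalars, got shape {values.shape}")
        rec = cls(visit_date=visit_date, **kwargs)
        rec.central_thickness = float(values[0])
        rec.min_central_thickness = float(values[1])
        rec.max_central_thickness = float(values[2])
        rec.total_volume = float(values[3])
        for i, z in enumerate(ZONES):
            rec.zone_avg_thickness[z] = float(values[4 + 2 * i])
            rec.zone_volume[z] = float(values[5 + 2 * i])
        return rec

    def missing_zones(self) -> list[str]:
        return [
            z
            for z in ZONES
            if self.zone_avg_thickness.get(z) is None or self.zone_volume.get(z) is None
        ]


@dataclass
class EyeSeries:
    """Time-ordered irregular sequence of visits for one eye (L or R)."""

    patient_id: str
    eye: str  # "L" | "R"
    visits: list[VisitRecord] = field(default_factory=list)

    @property
    def eye_id(self) -> str:
        return f"{self.patient_id}_{self.eye}"

    def __len__(self) -> int:
        return len(self.visits)

    def sort(self) -> "EyeSeries":
        self.visits.sort(key=lambda v: v.visit_date)
        return self

    def days_since_first(self) -> np.ndarray:
        t0 = self.visits[0].visit_date
        return np.array([(v.visit_date - t0).days for v in self.visits], dtype=float)

    def va_values(self) -> np.ndarray:
        return np.array(
            [np.nan if v.va is None else v.va for v in self.visits], dtype=float
        )
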