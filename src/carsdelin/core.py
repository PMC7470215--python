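"""Shared domain types for the multispectral delineation pipeline.

Everything here is re-exported from the stage modules that own it
conceptually (:mod:`carsdelin.phantom`, :mod:`carsdelin.preprocess`); this
module only exists to keep the import graph acyclic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

WAVENUMBER_MIN = 2700.0
WAVENUMBER_MAX = 3200.0

#: anchor points of the water/fat intensity ratio (cm^-1)
WATER_ANCHOR = 3150.0
FAT_ANCHOR = 2845.0

#: the CH2 lipid band; also the reference wavenumber for SHG/TPF power scaling
FAT_PEAK = 2850.0
FAT_PEAK_WINDOW = (2840.0, 2860.0)

UNANNOTATED = 0


class TissueClass(enum.IntEnum):
    """Pathology classes of the label map (0 is reserved for unannotated)."""

    FAT = 1
    CANCER_CELLS = 2
    CANCER_CONNECTIVE = 3
    HEALTHY_CELLS = 4
    HEALTHY_CONNECTIVE = 5


ALL_CLASSES = tuple(TissueClass)
CANCER_CLASSES = (TissueClass.CANCER_CELLS, TissueClass.CANCER_CONNECTIVE)
HEALTHY_CLASSES = (TissueClass.HEALTHY_CELLS, TissueClass.HEALTHY_CONNECTIVE)

CLASS_NAMES = {
    TissueClass.FAT: "fat",
    TissueClass.CANCER_CELLS: "cancer_cells",
    TissueClass.CANCER_CONNECTIVE: "cancer_connective",
    TissueClass.HEALTHY_CELLS: "healthy_cells",
    TissueClass.HEALTHY_CONNECTIVE: "healthy_connective",
}
NAME_TO_CLASS = {v: k for k, v in CLASS_NAMES.items()}


def cars_column(wavenumber: float) -> str:
    """Canonical spectrum-table column name for a CARS wavenumber."""
    return f"cars_{wavenumber:g}"


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis restricted to 2700-3200 cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis needs at least two wavenumbers")
        if not np.all(np.diff(values) > 0):
            raise ValueError("axis must be strictly increasing")
        if values[0] < WAVENUMBER_MIN or values[-1] > WAVENUMBER_MAX:
            raise ValueError(
                f"axis must lie within [{WAVENUMBER_MIN:g}, {WAVENUMBER_MAX:g}] cm^-1"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def nearest_index(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def nearest(self, wavenumber: float) -> float:
        return float(self.values[self.nearest_index(wavenumber)])

    @property
    def cars_columns(self) -> list[str]:
        return [cars_column(v) for v in self.values]

    @property
    def channel_names(self) -> list[str]:
        """Per-channel names of a hyperstack: CARS ascending, then SHG, TPF."""
        return self.cars_columns + ["shg", "tpf"]


@dataclass
class CalibrationRecord:
    """Acquisition-time calibration: beam powers, ADC offset, detector gains."""

    pump_power: np.ndarray  # watts, one entry per axis wavenumber
    stokes_power: float
    adc_offset: float  # volts
    detector_gain: np.ndarray | None = None  # relative factor per channel

    def __post_init__(self) -> None:
        self.pump_power = np.asarray(self.pump_power, dtype=float)
        if np.any(self.pump_power <= 0) or self.stokes_power <= 0:
            raise ValueError("beam powers must be strictly positive")
        if not np.isfinite(self.adc_offset):
            raise ValueError("adc_offset must be finite")
        if self.detector_gain is not None:
            self.detector_gain = np.asarray(self.detector_gain, dtype=float)
            if np.any(self.detector_gain <= 0):
                raise ValueError("detector gains must be strictly positive")


@dataclass
class HyperStack:
    """Grid of frames, each with one image per channel, in detector volts.

    ``data`` has shape ``(grid_rows, grid_cols, n_channels, frame_h, frame_w)``
    with channels ordered as ``axis.channel_names`` (ascending CARS
    wavenumber, then SHG, then TPF). ``present`` marks acquired grid slots.
    """

    data: np.ndarray
    axis: WavenumberAxis
    present: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("stack data must be 5-D (rows, cols, channels, h, w)")
        if self.data.shape[2] != len(self.axis) + 2:
            raise ValueError(
                f"expected {len(self.axis) + 2} channels "
                f"(|axis| + SHG + TPF), got {self.data.shape[2]}"
            )
        if self.present is None:
            self.present = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)
            if self.present.shape != self.data.shape[:2]:
                raise ValueError("present mask must match the frame grid")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def channel_names(self) -> list[str]:
        return self.axis.channel_names

    @property
    def shg_index(self) -> int:
        return len(self.axis)

    @property
    def tpf_index(self) -> int:
        return len(self.axis) + 1

    def with_data(self, data: np.ndarray) -> "HyperStack":
        return HyperStack(data=data, axis=self.axis, present=self.present.copy())


def validate_label_map(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label map must be 2-D")
    if labels.min() < 0 or labels.max() > 5:
        raise ValueError("label codes must lie in {0..5}")
    return labels.astype(np.uint8)
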