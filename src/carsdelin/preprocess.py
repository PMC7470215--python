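"""Correction chain from raw frames to a block-averaged spectrum table.

Order of operations: ADC-offset subtraction, beam-power calibration,
mosaic-wide illumination correction (fourth-order 2-D polynomial fitted to
the frame-averaged intensity), stitching, and 4x4 block averaging with
majority labels.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

from .core import (
    CalibrationRecord,
    FAT_PEAK,
    HyperStack,
    UNANNOTATED,
    WavenumberAxis,
    cars_column,
    validate_label_map,
)

__all__ = [
    "CalibrationRecord",
    "IlluminationField",
    "MosaicStack",
    "SpectrumTable",
    "subtract_offset",
    "power_calibrate",
    "estimate_illumination",
    "correct_illumination",
    "stitch",
    "block_average",
]

ILLUMINATION_ORDER = 4
#: fitted polynomials can approach zero at frame corners; floor before division
ILLUMINATION_FLOOR_FRAC = 0.05


def subtract_offset(stack: HyperStack, calibration: CalibrationRecord) -> HyperStack:
    """Remove the constant ADC offset; negative results are retained."""
    return stack.with_data(stack.data - calibration.adc_offset)


def power_calibrate(
    stack: HyperStack,
    calibration: CalibrationRecord,
    ref_wavenumber: float = FAT_PEAK,
) -> HyperStack:
    """Divide out beam powers so spectra are independent of input power.

    CARS scales quadratically with pump and linearly with Stokes power, so
    channel nu is divided by pump(nu)^2 * stokes.  SHG and TPF are two-photon
    processes of the pump alone and are divided by pump(nu_ref)^2.  Detector
    gains, when present, are divided out per channel.
    """
    pump = calibration.pump_power
    if pump.size != len(stack.axis):
        raise ValueError("calibration must carry one pump power per axis wavenumber")
    scale = np.empty(stack.n_channels)
    scale[: len(stack.axis)] = pump**2 * calibration.stokes_power
    scale[stack.shg_index :] = pump[stack.axis.nearest_index(ref_wavenumber)] ** 2
    if calibration.detector_gain is not None:
        if calibration.detector_gain.size != stack.n_channels:
            raise ValueError("detector_gain must have one entry per channel")
        scale = scale * calibration.detector_gain
    return stack.with_data(stack.data / scale[None, None, :, None, None])


@dataclass
class IlluminationField:
    """Multiplicative shading over one frame, as fit coefficients + field."""

    coefficients: np.ndarray  # (order+1, order+1), term x^i y^j
    field: np.ndarray  # evaluated over one frame, unit mean

    def floored(self, floor_frac: float = ILLUMINATION_FLOOR_FRAC) -> np.ndarray:
        return np.maximum(self.field, floor_frac * self.field.max())


def _design_matrix(h: int, w: int, order: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    x = np.linspace(-1.0, 1.0, h)[:, None] * np.ones((1, w))
    y = np.ones((h, 1)) * np.linspace(-1.0, 1.0, w)[None, :]
    terms = [(i, j) for i in range(order + 1) for j in range(order + 1 - i)]
    columns = [(x**i * y**j).ravel() for i, j in terms]
    return np.column_stack(columns), terms


def estimate_illumination(
    stack: HyperStack, channels: str = "cars", order: int = ILLUMINATION_ORDER
) -> IlluminationField:
    """Fit a total-order-4 bivariate polynomial to the frame-averaged image.

    The mean image is taken over all frames and, by default, the CARS
    channels only (SHG/TPF have structurally different spatial statistics);
    ``channels`` may be "cars", "all", "shg" or "tpf".
    """
    if channels == "cars":
        data = stack.data[:, :, : len(stack.axis)]
    elif channels == "all":
        data = stack.data
    elif channels in ("shg", "tpf"):
        idx = stack.shg_index if channels == "shg" else stack.tpf_index
        data = stack.data[:, :, idx : idx + 1]
    else:
        raise ValueError(f"unknown channel subset {channels!r}")
    mean_image = data[stack.present].mean(axis=(0, 1))
    if np.allclose(mean_image, 0):
        raise ValueError("degenerate fit: frame-averaged intensity is zero everywhere")

    h, w = mean_image.shape
    design, terms = _design_matrix(h, w, order)
    beta, *_ = np.linalg.lstsq(design, mean_image.ravel(), rcond=None)
    field = (design @ beta).reshape(h, w)
    mean = field.mean()
    field = field / mean
    coefficients = np.zeros((order + 1, order + 1))
    for (i, j), b in zip(terms, beta):
        coefficients[i, j] = b / mean
    return IlluminationField(coefficients=coefficients, field=field)


def correct_illumination(
    stack: HyperStack,
    field: IlluminationField,
    floor_frac: float = ILLUMINATION_FLOOR_FRAC,
) -> HyperStack:
    """Divide every frame and channel by the (floored) shading field."""
    if field.field.shape != stack.frame_shape:
        raise ValueError(
            f"field shape {field.field.shape} does not match frame shape {stack.frame_shape}"
        )
    return stack.with_data(stack.data / field.floored(floor_frac)[None, None, None])


@dataclass
class MosaicStack:
    """Stitched mosaic: channel-major image cube over the full canvas."""

    data: np.ndarray  # (n_channels, H, W)
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.axis) + 2:
            raise ValueError("mosaic data must be (|axis|+2, H, W)")

    @property
    def channel_names(self) -> list[str]:
        return self.axis.channel_names

    @property
    def shg_index(self) -> int:
        return len(self.axis)

    @property
    def tpf_index(self) -> int:
        return len(self.axis) + 1

    def cars_image(self, wavenumber: float) -> np.ndarray:
        return self.data[self.axis.nearest_index(wavenumber)]


def stitch(stack: HyperStack) -> MosaicStack:
    """Place frames abutting on the grid — no overlap, no blending."""
    if not stack.present.all():
        gaps = [tuple(int(v) for v in rc) for rc in np.argwhere(~stack.present)]
        raise ValueError(f"missing frames at grid positions {gaps}")
    rows, cols = stack.grid_shape
    h, w = stack.frame_shape
    # (rows, cols, ch, h, w) -> (ch, rows*h, cols*w)
    mosaic = stack.data.transpose(2, 0, 3, 1, 4).reshape(stack.n_channels, rows * h, cols * w)
    return MosaicStack(data=mosaic.copy(), axis=stack.axis)


class SpectrumTable:
    """One record per retained 4x4 block: CARS vector, SHG/TPF means, label.

    Backed by a pandas DataFrame with columns ``sample_id, block_row,
    block_col, label, shg, tpf`` followed by one ``cars_<wavenumber>`` column
    per axis point.
    """

    META_COLUMNS = ["sample_id", "block_row", "block_col", "label", "shg", "tpf"]

    def __init__(self, df: pd.DataFrame, axis: WavenumberAxis):
        expected = self.META_COLUMNS + axis.cars_columns
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise ValueError(f"spectrum table is missing columns {missing}")
        labels = df["label"].to_numpy()
        if len(df) and (labels.min() < 1 or labels.max() > 5):
            raise ValueError("table labels must lie in {1..5}")
        dup = df.duplicated(subset=["sample_id", "block_row", "block_col"])
        if dup.any():
            raise ValueError("block positions must be unique per sample")
        self.df = df[expected].reset_index(drop=True)
        self.axis = axis

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy()

    @property
    def classes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.labels))

    def cars_matrix(self) -> np.ndarray:
        return self.df[self.axis.cars_columns].to_numpy(dtype=float)

    def feature_matrix(
        self,
        wavenumbers=None,
        include_shg: bool = False,
        include_tpf: bool = False,
    ) -> np.ndarray:
        """Feature columns: selected CARS wavenumbers then SHG then TPF."""
        columns = []
        if wavenumbers is None:
            columns.extend(self.axis.cars_columns)
        else:
            for wn in wavenumbers:
                name = cars_column(wn)
                if name not in self.df.columns:
                    raise ValueError(f"wavenumber {wn:g} is not a column of this table")
                columns.append(name)
        if include_shg:
            columns.append("shg")
        if include_tpf:
            columns.append("tpf")
        if not columns:
            raise ValueError("empty feature set")
        return self.df[columns].to_numpy(dtype=float)

    def subset(self, mask) -> "SpectrumTable":
        return SpectrumTable(self.df.loc[np.asarray(mask)].reset_index(drop=True), self.axis)

    @staticmethod
    def concat(tables: list["SpectrumTable"]) -> "SpectrumTable":
        if not tables:
            raise ValueError("no tables to concatenate")
        axis = tables[0].axis
        for t in tables[1:]:
            if not np.array_equal(t.axis.values, axis.values):
                raise ValueError("tables share no common wavenumber axis")
        return SpectrumTable(pd.concat([t.df for t in tables], ignore_index=True), axis)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumTable":
        df = pd.read_csv(path)
        wavenumbers = sorted(
            float(c[len("cars_") :]) for c in df.columns if c.startswith("cars_")
        )
        return cls(df, WavenumberAxis(np.asarray(wavenumbers)))


def block_average(
    mosaic: MosaicStack,
    label_map: np.ndarray,
    block_size: int = 4,
    sample_id: str = "sample",
    min_annotated_frac: float = 0.75,
    purity: float = 0.75,
) -> SpectrumTable:
    """Average ``block_size``-square pixel blocks into one record each.

    A block is retained iff at least ``min_annotated_frac`` of its pixels are
    annotated and at least ``purity`` of the annotated pixels share one
    label; the majority label is assigned.  Mixed or unannotated blocks are
    dropped.
    """
    label_map = validate_label_map(label_map)
    n_ch, h, w = mosaic.data.shape
    if label_map.shape != (h, w):
        raise ValueError("label map dimensions must match the mosaic")
    if h % block_size or w % block_size:
        raise ValueError(
            f"mosaic dimensions {h}x{w} are not divisible by block size {block_size}"
        )
    bh, bw = h // block_size, w // block_size
    npix = block_size * block_size

    blocks = mosaic.data.reshape(n_ch, bh, block_size, bw, block_size)
    means = blocks.mean(axis=(2, 4))  # (n_ch, bh, bw)

    tiles = label_map.reshape(bh, block_size, bw, block_size).transpose(0, 2, 1, 3)
    tiles = tiles.reshape(bh, bw, npix)
    counts = np.stack([(tiles == code).sum(axis=2) for code in range(6)], axis=0)
    annotated = counts[1:].sum(axis=0)
    majority_count = counts[1:].max(axis=0)
    majority_label = counts[1:].argmax(axis=0) + 1

    keep = (annotated >= np.ceil(min_annotated_frac * npix)) & (
        majority_count >= purity * np.maximum(annotated, 1)
    ) & (annotated > 0)

    rows, cols = np.nonzero(keep)
    n_wn = len(mosaic.axis)
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "block_row": rows * block_size,
            "block_col": cols * block_size,
            "label": majority_label[keep],
            "shg": means[mosaic.shg_index][keep],
            "tpf": means[mosaic.tpf_index][keep],
        }
    )
    for i, name in enumerate(mosaic.axis.cars_columns):
        df[name] = means[i][keep]
    return SpectrumTable(df, mosaic.axis)


def preprocess_stack(
    stack: HyperStack,
    labels: np.ndarray,
    calibration: CalibrationRecord,
    sample_id: str = "sample",
    block_size: int = 4,
    illumination_correction: bool = True,
    illumination_channels: str = "cars",
) -> SpectrumTable:
    """Full chain: offset, power calibration, illumination, stitch, blocks."""
    stack = subtract_offset(stack, calibration)
    stack = power_calibrate(stack, calibration)
    if illumination_correction:
        field = estimate_illumination(stack, channels=illumination_channels)
        stack = correct_illumination(stack, field)
    mosaic = stitch(stack)
    return block_average(mosaic, labels, block_size=block_size, sample_id=sample_id)


def load_and_preprocess(in_dir, sample_id: str | None = None, **kwargs) -> SpectrumTable:
    """Read a phantom directory (TIFF frames + sidecar) and preprocess it."""
    from .phantom import read_phantom

    src = pathlib.Path(in_dir)
    stack, labels, calibration = read_phantom(src)
    return preprocess_stack(
        stack, labels, calibration, sample_id=sample_id or src.name, **kwargs
    )
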