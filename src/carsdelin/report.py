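"""Metrics, spectral summaries, intensity histograms, and image rendering."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, matthews_corrcoef

from .core import (
    ALL_CLASSES,
    CANCER_CLASSES,
    CLASS_NAMES,
    FAT_ANCHOR,
    FAT_PEAK,
    HEALTHY_CLASSES,
    TissueClass,
    WATER_ANCHOR,
    WavenumberAxis,
)

__all__ = [
    "MetricsReport",
    "PALETTE",
    "compute_metrics",
    "summarize_spectra",
    "water_fat_ratio",
    "intensity_histograms",
    "render_class_map",
    "decode_class_map",
    "render_composite",
]

#: class-map palette (RGB): code 0 (unclassified) renders black
PALETTE = {
    0: (0, 0, 0),
    int(TissueClass.FAT): (255, 221, 0),  # yellow
    int(TissueClass.CANCER_CELLS): (138, 43, 226),  # violet
    int(TissueClass.CANCER_CONNECTIVE): (120, 200, 255),  # light blue
    int(TissueClass.HEALTHY_CELLS): (0, 153, 51),  # green
    int(TissueClass.HEALTHY_CONNECTIVE): (255, 140, 0),  # orange
}


@dataclass
class MetricsReport:
    """Five-class confusion plus the binary cancer-vs-healthy collapse.

    Sensitivity, specificity and ``mcc_binary`` are computed with the two
    cancer classes positive and the two healthy classes negative; records
    whose truth or prediction is fat fall in neither binary class and are
    excluded from the collapse.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    mcc_multiclass: float
    mcc_binary: float
    confusion: np.ndarray  # (5, 5) counts, truth on rows
    confusion_row_normalized: np.ndarray
    n: int
    zero_rows: list = field(default_factory=list)  # classes absent from truth

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc_multiclass": self.mcc_multiclass,
            "mcc_binary": self.mcc_binary,
            "confusion": self.confusion.tolist(),
            "confusion_row_normalized": self.confusion_row_normalized.tolist(),
            "n": self.n,
            "zero_rows": [CLASS_NAMES[TissueClass(c)] for c in self.zero_rows],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def binary_collapse(predictions: np.ndarray, truth: np.ndarray):
    """Map to cancer(1)/healthy(0); drop records touching fat either way."""
    keep = ~np.isin(truth, [TissueClass.FAT]) & ~np.isin(predictions, [TissueClass.FAT])
    pred_bin = np.isin(predictions[keep], CANCER_CLASSES).astype(int)
    true_bin = np.isin(truth[keep], CANCER_CLASSES).astype(int)
    return pred_bin, true_bin


def compute_metrics(predictions, truth) -> MetricsReport:
    predictions = np.asarray(predictions, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predictions.shape != truth.shape:
        raise ValueError("prediction and truth vectors must have equal length")
    for name, vec in (("prediction", predictions), ("truth", truth)):
        if vec.size and (vec.min() < 1 or vec.max() > 5):
            raise ValueError(f"{name} labels must lie in {{1..5}}")

    labels = [int(c) for c in ALL_CLASSES]
    confusion = confusion_matrix(truth, predictions, labels=labels)
    n = int(confusion.sum())
    accuracy = float(np.trace(confusion) / n) if n else float("nan")

    row_sums = confusion.sum(axis=1, keepdims=True)
    zero_rows = [labels[i] for i in np.flatnonzero(row_sums.ravel() == 0)]
    normalized = confusion / np.where(row_sums == 0, 1, row_sums)

    mcc_multiclass = float(matthews_corrcoef(truth, predictions))

    pred_bin, true_bin = binary_collapse(predictions, truth)
    tp = int(np.sum((pred_bin == 1) & (true_bin == 1)))
    fn = int(np.sum((pred_bin == 0) & (true_bin == 1)))
    tn = int(np.sum((pred_bin == 0) & (true_bin == 0)))
    fp = int(np.sum((pred_bin == 1) & (true_bin == 0)))
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    mcc_binary = float(matthews_corrcoef(true_bin, pred_bin)) if pred_bin.size else float("nan")

    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        mcc_multiclass=mcc_multiclass,
        mcc_binary=mcc_binary,
        confusion=confusion,
        confusion_row_normalized=normalized,
        n=n,
        zero_rows=zero_rows,
    )


@dataclass
class SpectrumSummary:
    tissue_class: TissueClass
    mean: np.ndarray
    sd: np.ndarray
    n: int
    single: bool = False  # sd undefined for one record; reported as 0


def summarize_spectra(table) -> dict[TissueClass, SpectrumSummary]:
    """Per-class mean and standard deviation spectrum over the table."""
    if len(table) == 0:
        raise ValueError("empty spectrum table")
    cars = table.cars_matrix()
    labels = table.labels
    out = {}
    for cls in np.unique(labels):
        rows = cars[labels == cls]
        single = rows.shape[0] == 1
        out[TissueClass(int(cls))] = SpectrumSummary(
            tissue_class=TissueClass(int(cls)),
            mean=rows.mean(axis=0),
            sd=np.zeros(rows.shape[1]) if single else rows.std(axis=0, ddof=1),
            n=rows.shape[0],
            single=single,
        )
    return out


def water_fat_ratio(
    spectrum,
    axis: WavenumberAxis,
    water: float = WATER_ANCHOR,
    fat: float = FAT_ANCHOR,
) -> float:
    """Intensity nearest 3150 cm^-1 over intensity nearest 2845 cm^-1.

    Returns NaN (flagged undefined) when the denominator is non-positive.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size != len(axis):
        raise ValueError("spectrum length must match the axis")
    denom = spectrum[axis.nearest_index(fat)]
    if denom <= 0:
        return float("nan")
    return float(spectrum[axis.nearest_index(water)] / denom)


@dataclass
class HistogramSet:
    """Relative-frequency SHG/TPF histograms on a shared intensity axis."""

    edges: np.ndarray
    frequencies: dict  # (TissueClass, "shg"|"tpf") -> per-bin frequency, sums to 1
    omitted: list = field(default_factory=list)  # empty (class, modality) combos


def intensity_histograms(table, bins: int = 64, upper_percentile: float = 99.5) -> HistogramSet:
    """Per-class SHG and TPF histograms; fat excluded (no SHG/TPF emission).

    Bin edges are shared across classes and both modalities so the signal
    levels can be compared on the same scale.
    """
    labels = table.labels
    keep = labels != TissueClass.FAT
    shg = table.df["shg"].to_numpy(dtype=float)[keep]
    tpf = table.df["tpf"].to_numpy(dtype=float)[keep]
    if shg.size == 0:
        raise ValueError("no non-fat records to histogram")
    pooled = np.concatenate([shg, tpf])
    lo = min(0.0, float(pooled.min()))
    hi = float(np.percentile(pooled, upper_percentile))
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)

    frequencies = {}
    omitted = []
    for cls in ALL_CLASSES:
        if cls == TissueClass.FAT:
            continue
        mask = labels == cls
        for modality, values in (("shg", "shg"), ("tpf", "tpf")):
            data = table.df[values].to_numpy(dtype=float)[mask]
            if data.size == 0:
                omitted.append((cls, modality))
                continue
            counts, _ = np.histogram(np.clip(data, lo, hi), bins=edges)
            frequencies[(cls, modality)] = counts / counts.sum()
    return HistogramSet(edges=edges, frequencies=frequencies, omitted=omitted)


def render_class_map(grid: np.ndarray) -> np.ndarray:
    """Map class codes to the fixed palette; unclassified (0) is black."""
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("empty class map")
    if grid.min() < 0 or grid.max() > 5:
        raise ValueError("class codes must lie in {0..5}")
    lut = np.zeros((6, 3), dtype=np.uint8)
    for code, rgb in PALETTE.items():
        lut[code] = rgb
    return lut[grid]


def decode_class_map(rgb: np.ndarray) -> np.ndarray:
    """Palette inverse of :func:`render_class_map` (exact round-trip)."""
    rgb = np.asarray(rgb, dtype=np.uint8)
    grid = np.full(rgb.shape[:2], -1, dtype=int)
    for code, color in PALETTE.items():
        grid[np.all(rgb == np.asarray(color, dtype=np.uint8), axis=-1)] = code
    if (grid < 0).any():
        raise ValueError("image contains colors outside the class palette")
    return grid.astype(np.uint8)


def save_class_map(grid: np.ndarray, path) -> None:
    """Write the rendered class map with an embedded legend (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.patches as mpatches
    import matplotlib.pyplot as plt

    rgb = render_class_map(grid)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    handles = [
        mpatches.Patch(color=np.asarray(PALETTE[int(cls)]) / 255.0, label=CLASS_NAMES[cls])
        for cls in ALL_CLASSES
    ]
    ax.legend(handles=handles, loc="upper right", fontsize="small", framealpha=0.9)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def _stretch(channel: np.ndarray, low: float = 1.0, high: float = 99.0) -> np.ndarray:
    lo, hi = np.percentile(channel, [low, high])
    if hi <= lo:
        return np.zeros_like(channel, dtype=float)
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0)


def render_composite(mosaic, cars_wavenumber: float = FAT_PEAK) -> np.ndarray:
    """False-color overlay: SHG red, TPF green, CARS (2850 cm^-1) blue.

    Channels are percentile-stretched (1st-99th) independently; returns a
    float RGB image in [0, 1].
    """
    rgb = np.zeros((*mosaic.data.shape[1:], 3))
    rgb[..., 0] = _stretch(mosaic.data[mosaic.shg_index])
    rgb[..., 1] = _stretch(mosaic.data[mosaic.tpf_index])
    rgb[..., 2] = _stretch(mosaic.cars_image(cars_wavenumber))
    return rgb
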