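"""Labeled synthetic multimodal mosaics (hyperspectral CARS + SHG + TPF).

The phantom emulates the statistical structure the downstream analysis
assumes: class-specific CARS band shapes (dominant lipid CH2 peak at
2850 cm^-1 for fat, protein band near 2930 cm^-1, broad water band near
3150 cm^-1, lower water/fat ratio for cancerous than healthy tissue),
class-conditional log-normal SHG/TPF intensities, per-frame polynomial
vignetting, an additive ADC offset, per-wavenumber beam-power fluctuation,
and additive detector noise on a stitched frame grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import ndimage

from .core import (
    ALL_CLASSES,
    CLASS_NAMES,
    FAT_ANCHOR,
    FAT_PEAK,
    FAT_PEAK_WINDOW,
    NAME_TO_CLASS,
    UNANNOTATED,
    WATER_ANCHOR,
    CalibrationRecord,
    HyperStack,
    TissueClass,
    WavenumberAxis,
    validate_label_map,
)

__all__ = [
    "WavenumberAxis",
    "TissueClass",
    "SpectralTemplate",
    "PhantomConfig",
    "HyperStack",
    "build_template",
    "default_band_params",
    "default_templates",
    "default_shg_tpf_params",
    "generate_phantom",
    "write_phantom",
    "read_phantom",
]

_GAUSS_K = 4.0 * np.log(2.0)  # FWHM parameterization


@dataclass(frozen=True)
class SpectralTemplate:
    """Sum of Gaussian bands plus a baseline, one per tissue class.

    Real CARS lineshapes are dispersive; only intensities are used downstream,
    so symmetric analytic bands suffice.
    """

    tissue_class: TissueClass
    band_centers: np.ndarray  # cm^-1
    band_widths: np.ndarray  # FWHM, cm^-1
    band_amplitudes: np.ndarray
    baseline: float = 0.0

    def __post_init__(self) -> None:
        for name in ("band_centers", "band_widths", "band_amplitudes"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if self.band_centers.size == 0:
            raise ValueError("template needs at least one band")
        if not (self.band_centers.size == self.band_widths.size == self.band_amplitudes.size):
            raise ValueError("band parameter arrays must have equal length")
        if np.any(self.band_amplitudes < 0):
            raise ValueError("band amplitudes must be non-negative")
        if np.any(self.band_widths <= 0):
            raise ValueError("band widths must be strictly positive")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")

    def evaluate(self, wavenumbers) -> np.ndarray:
        """Intensity at each wavenumber; accepts an axis or raw array."""
        if isinstance(wavenumbers, WavenumberAxis):
            wavenumbers = wavenumbers.values
        nu = np.atleast_1d(np.asarray(wavenumbers, dtype=float))
        d = nu[:, None] - self.band_centers[None, :]
        bands = self.band_amplitudes[None, :] * np.exp(
            -_GAUSS_K * (d / self.band_widths[None, :]) ** 2
        )
        return bands.sum(axis=1) + self.baseline

    def water_fat_ratio(self, axis: WavenumberAxis) -> float:
        values = self.evaluate(axis)
        denom = values[axis.nearest_index(FAT_ANCHOR)]
        if denom <= 0:
            return float("nan")
        return float(values[axis.nearest_index(WATER_ANCHOR)] / denom)


# Shared band structure (centers/widths fixed, amplitudes per class):
# CH2 lipid stretch at 2850, CH3/protein band at 2930, broad OH (water)
# band at 3150 cm^-1.  Cancerous tissue carries more protein and fewer
# lipids than healthy tissue, so the lipid band separates cancer from
# healthy as well as fat from everything; fat matches the cancer classes
# at the protein and water bands so its giant CH2 peak is what makes its
# profile distinct.
_BAND_CENTERS = (2850.0, 2930.0, 3150.0)
_BAND_WIDTHS = (35.0, 70.0, 170.0)
_BASELINE = 0.02

_CLASS_AMPLITUDES = {
    TissueClass.FAT: (1.00, 0.50, 0.17),
    TissueClass.CANCER_CELLS: (0.16, 0.65, 0.16),
    TissueClass.CANCER_CONNECTIVE: (0.14, 0.50, 0.18),
    TissueClass.HEALTHY_CELLS: (0.32, 0.52, 0.42),
    TissueClass.HEALTHY_CONNECTIVE: (0.30, 0.40, 0.46),
}

# Log-normal (mu, sigma) of the underlying normal, in detector volts.
# Fat emits at background level in both channels.  Connective tissue
# dominates SHG (collagen); cancer cells carry heavier high-intensity TPF
# mass than healthy cells.
_SHG_TPF_PARAMS = {
    TissueClass.FAT: {"shg": (np.log(0.004), 0.30), "tpf": (np.log(0.004), 0.30)},
    TissueClass.CANCER_CELLS: {"shg": (np.log(0.020), 0.40), "tpf": (np.log(0.200), 0.50)},
    TissueClass.CANCER_CONNECTIVE: {"shg": (np.log(0.300), 0.80), "tpf": (np.log(0.110), 0.40)},
    TissueClass.HEALTHY_CELLS: {"shg": (np.log(0.018), 0.40), "tpf": (np.log(0.050), 0.45)},
    TissueClass.HEALTHY_CONNECTIVE: {"shg": (np.log(0.250), 0.50), "tpf": (np.log(0.100), 0.40)},
}

# Per-frame multiplicative vignette: bright center, darker edges, with a
# small linear tilt (alignment asymmetry).  Coefficients index x^i y^j on
# frame coordinates normalized to [-1, 1]; total order <= 4.
_DEFAULT_SHADING = {
    (0, 0): 1.0,
    (1, 0): 0.08,
    (0, 1): 0.05,
    (2, 0): -0.30,
    (0, 2): -0.30,
    (2, 2): 0.05,
}


def default_band_params(tissue_class: TissueClass) -> dict:
    tissue_class = TissueClass(tissue_class)
    return {
        "band_centers": _BAND_CENTERS,
        "band_widths": _BAND_WIDTHS,
        "band_amplitudes": _CLASS_AMPLITUDES[tissue_class],
        "baseline": _BASELINE,
    }


def build_template(tissue_class, axis: WavenumberAxis, params: dict | None = None,
                   validate_semantics: bool = True) -> SpectralTemplate:
    """Build one class's CARS template and check its invariants on ``axis``.

    ``validate_semantics`` additionally enforces the class-level facts the
    default parameterization guarantees (fat peak location, cancer-vs-healthy
    water/fat ordering); switch it off for deliberately degenerate phantoms.
    """
    if isinstance(tissue_class, str):
        try:
            tissue_class = NAME_TO_CLASS[tissue_class]
        except KeyError:
            raise ValueError(
                f"unknown tissue class {tissue_class!r}; "
                f"expected one of {sorted(NAME_TO_CLASS)}"
            ) from None
    tissue_class = TissueClass(tissue_class)
    if params is None:
        params = default_band_params(tissue_class)
    template = SpectralTemplate(tissue_class=tissue_class, **params)

    values = template.evaluate(axis)
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("template must evaluate finite and non-negative on the axis")
    if validate_semantics and tissue_class is TissueClass.FAT:
        peak = axis.values[int(np.argmax(values))]
        if not (FAT_PEAK_WINDOW[0] <= peak <= FAT_PEAK_WINDOW[1]):
            raise ValueError(
                f"fat template peaks at {peak:g} cm^-1, outside "
                f"{FAT_PEAK_WINDOW[0]:g}-{FAT_PEAK_WINDOW[1]:g}"
            )
    return template


def default_templates(axis: WavenumberAxis) -> dict[TissueClass, SpectralTemplate]:
    """All five default templates; asserts the cancer/healthy ratio ordering."""
    templates = {cls: build_template(cls, axis) for cls in ALL_CLASSES}
    for cancer, healthy in (
        (TissueClass.CANCER_CELLS, TissueClass.HEALTHY_CELLS),
        (TissueClass.CANCER_CONNECTIVE, TissueClass.HEALTHY_CONNECTIVE),
    ):
        if not templates[cancer].water_fat_ratio(axis) < templates[healthy].water_fat_ratio(axis):
            raise ValueError(
                f"water/fat ratio of {CLASS_NAMES[cancer]} must be below "
                f"{CLASS_NAMES[healthy]}"
            )
    return templates


def default_shg_tpf_params() -> dict[TissueClass, dict[str, tuple[float, float]]]:
    return {cls: dict(_SHG_TPF_PARAMS[cls]) for cls in ALL_CLASSES}


@dataclass
class PhantomConfig:
    """Everything needed to synthesize one sample's mosaic deterministically."""

    frame_size: int = 256
    mosaic_grid: tuple[int, int] = (2, 2)
    pixel_pitch: float = 0.91  # um / pixel
    wavenumbers: tuple = tuple(np.arange(2700.0, 3201.0, 20.0))
    shading_coefficients: dict = field(default_factory=lambda: dict(_DEFAULT_SHADING))
    adc_offset: float = 0.050  # volts
    pump_power_nominal: float = 1.0  # watts
    stokes_power: float = 1.0
    power_fluctuation: float = 0.05  # relative, per wavenumber
    noise_sigma: float = 0.005  # volts, additive Gaussian
    signal_noise_frac: float = 0.0  # optional signal-dependent term
    region_smooth_sigma: float = 16.0  # px, blob smoothness on the canvas
    boundary_margin: float = 0.15  # top-two field margin below which label=0
    class_separation: float = 1.0  # 0 => all classes identical
    classes: tuple = tuple(ALL_CLASSES)
    template_params: dict | None = None  # per-class overrides
    shg_tpf_params: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_size <= 0 or self.frame_size % 4 != 0:
            raise ValueError("frame_size must be a positive multiple of 4")
        if len(self.mosaic_grid) != 2 or min(self.mosaic_grid) < 1:
            raise ValueError("mosaic_grid must be (rows, cols) with both >= 1")
        if self.noise_sigma < 0 or self.signal_noise_frac < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0 <= self.power_fluctuation < 1:
            raise ValueError("power_fluctuation must lie in [0, 1)")
        if not 0 <= self.class_separation:
            raise ValueError("class_separation must be non-negative")
        self.classes = tuple(TissueClass(c) for c in self.classes)
        if len(set(self.classes)) != len(self.classes) or not self.classes:
            raise ValueError("classes must be a non-empty set of distinct tissue classes")
        field_min = self.shading_field().min()
        if field_min <= 0:
            raise ValueError(f"shading field must be strictly positive (min {field_min:g})")

    @property
    def axis(self) -> WavenumberAxis:
        return WavenumberAxis(np.asarray(self.wavenumbers, dtype=float))

    @property
    def canvas_shape(self) -> tuple[int, int]:
        return (self.mosaic_grid[0] * self.frame_size, self.mosaic_grid[1] * self.frame_size)

    def shading_field(self, frame_size: int | None = None) -> np.ndarray:
        """Evaluate the per-frame vignette on frame pixel coordinates."""
        n = frame_size or self.frame_size
        coeffs = np.zeros((5, 5))
        for (i, j), value in self.shading_coefficients.items():
            if i + j > 4:
                raise ValueError("shading polynomial total order must be <= 4")
            coeffs[i, j] = value
        x = np.linspace(-1.0, 1.0, n)
        return npoly.polygrid2d(x, x, coeffs)  # [i_row, j_col] -> x=row, y=col


def _interpolated(values_by_class: dict, separation: float) -> dict:
    """Shrink per-class parameter vectors toward the across-class mean."""
    keys = list(values_by_class)
    stack = np.stack([np.asarray(values_by_class[k], dtype=float) for k in keys])
    mean = stack.mean(axis=0)
    return {k: mean + separation * (stack[i] - mean) for i, k in enumerate(keys)}


def _phantom_templates(config: PhantomConfig) -> dict[TissueClass, SpectralTemplate]:
    axis = config.axis
    params = {
        cls: (config.template_params or {}).get(cls) or default_band_params(cls)
        for cls in config.classes
    }
    if config.class_separation != 1.0:
        amps = _interpolated(
            {c: p["band_amplitudes"] for c, p in params.items()}, config.class_separation
        )
        params = {c: {**p, "band_amplitudes": amps[c]} for c, p in params.items()}
    semantic = config.class_separation == 1.0 and config.template_params is None
    return {
        cls: build_template(cls, axis, params[cls], validate_semantics=semantic)
        for cls in config.classes
    }


def _phantom_shg_tpf(config: PhantomConfig) -> dict[TissueClass, dict[str, tuple[float, float]]]:
    base = config.shg_tpf_params or default_shg_tpf_params()
    params = {cls: base[cls] for cls in config.classes}
    if config.class_separation == 1.0:
        return params
    flat = {c: np.array([*p["shg"], *p["tpf"]]) for c, p in params.items()}
    mixed = _interpolated(flat, config.class_separation)
    return {
        c: {"shg": (mixed[c][0], max(mixed[c][1], 1e-6)),
            "tpf": (mixed[c][2], max(mixed[c][3], 1e-6))}
        for c in params
    }


def _true_class_map(config: PhantomConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed-random-blob geometry.

    Returns ``(true_class, labels)``: the everywhere-defined generating class
    and the annotation map, masked to 0 where the top-two smoothed-field
    margin is below ``boundary_margin`` (annotation uncertainty at borders).
    """
    shape = config.canvas_shape
    fields = np.stack(
        [
            ndimage.gaussian_filter(rng.standard_normal(shape), config.region_smooth_sigma)
            for _ in config.classes
        ]
    )
    fields /= fields.reshape(len(config.classes), -1).std(axis=1)[:, None, None]
    order = np.sort(fields, axis=0)
    winner = np.argmax(fields, axis=0)
    true_class = np.asarray(config.classes, dtype=np.uint8)[winner]
    labels = true_class.copy()
    if len(config.classes) > 1:
        margin = order[-1] - order[-2]
        labels[margin < config.boundary_margin] = UNANNOTATED
    return true_class, labels


def generate_phantom(config: PhantomConfig) -> tuple[HyperStack, np.ndarray, CalibrationRecord]:
    """Synthesize ``(stack, label_map, calibration)`` deterministically.

    Raw CARS intensity at wavenumber nu:
        shading(x, y) * pump(nu)^2 * stokes * template(class, nu) + offset + noise
    SHG/TPF use pump(nu_ref)^2 (nu_ref nearest 2850 cm^-1) and per-pixel
    log-normal class-conditional draws in place of the template.
    """
    rng = np.random.default_rng(config.seed)
    axis = config.axis
    n_wn = len(axis)
    rows, cols = config.mosaic_grid
    n = config.frame_size
    canvas_h, canvas_w = config.canvas_shape

    true_class, labels = _true_class_map(config, rng)
    templates = _phantom_templates(config)
    shg_tpf = _phantom_shg_tpf(config)

    fluct = config.power_fluctuation * rng.uniform(-1.0, 1.0, size=n_wn)
    pump = config.pump_power_nominal * (1.0 + fluct)
    calibration = CalibrationRecord(
        pump_power=pump,
        stokes_power=config.stokes_power,
        adc_offset=config.adc_offset,
        detector_gain=np.ones(n_wn + 2),
    )

    class_codes = np.asarray(config.classes, dtype=np.uint8)
    spectra = np.stack([templates[c].evaluate(axis) for c in config.classes])  # (k, n_wn)
    code_to_row = np.zeros(6, dtype=np.intp)
    code_to_row[class_codes] = np.arange(len(class_codes))
    pixel_rows = code_to_row[true_class]  # (H, W)

    # Noiseless canvas, channel-major: CARS then SHG then TPF.
    canvas = np.empty((n_wn + 2, canvas_h, canvas_w))
    canvas[:n_wn] = spectra[pixel_rows].transpose(2, 0, 1)
    canvas[:n_wn] *= (pump**2 * config.stokes_power)[:, None, None]
    ref_power = pump[axis.nearest_index(FAT_PEAK)] ** 2
    for channel, offset_idx in (("shg", n_wn), ("tpf", n_wn + 1)):
        image = np.empty((canvas_h, canvas_w))
        for code, cls in zip(class_codes, config.classes):
            mu, sigma = shg_tpf[cls][channel]
            mask = true_class == code
            image[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
        canvas[offset_idx] = ref_power * image

    shading = config.shading_field()
    canvas *= np.tile(shading, config.mosaic_grid)[None]
    canvas += config.adc_offset

    # (channels, rows, h, cols, w) -> (rows, cols, channels, h, w)
    data = canvas.reshape(n_wn + 2, rows, n, cols, n).transpose(1, 3, 0, 2, 4).copy()
    if config.noise_sigma > 0 or config.signal_noise_frac > 0:
        sigma = config.noise_sigma
        if config.signal_noise_frac > 0:
            sigma = np.sqrt(
                config.noise_sigma**2
                + (config.signal_noise_frac * np.clip(data - config.adc_offset, 0, None)) ** 2
            )
        data += sigma * rng.standard_normal(data.shape)

    stack = HyperStack(data=data, axis=axis)
    return stack, validate_label_map(labels), calibration


# ---------------------------------------------------------------------------
# On-disk layout: one multi-page TIFF per frame (pages: ascending wavenumber,
# SHG, TPF), a JSON sidecar with layout/axis/calibration, an indexed TIFF for
# the label map, and the config as a plain key=value file.
# ---------------------------------------------------------------------------

def write_phantom(out_dir, stack: HyperStack, labels: np.ndarray,
                  calibration: CalibrationRecord, config: PhantomConfig | None = None) -> None:
    import pathlib

    import tifffile

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, cols = stack.grid_shape
    for r in range(rows):
        for c in range(cols):
            tifffile.imwrite(out / f"frame_r{r}_c{c}.tif", stack.data[r, c].astype(np.float32))
    tifffile.imwrite(out / "labels.tif", validate_label_map(labels))
    sidecar = {
        "grid": [rows, cols],
        "frame_shape": list(stack.frame_shape),
        "wavenumbers": stack.axis.values.tolist(),
        "channels": stack.channel_names,
        "calibration": {
            "pump_power": calibration.pump_power.tolist(),
            "stokes_power": calibration.stokes_power,
            "adc_offset": calibration.adc_offset,
            "detector_gain": None
            if calibration.detector_gain is None
            else calibration.detector_gain.tolist(),
        },
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    if config is not None:
        (out / "phantom.cfg").write_text(format_config(config))


def read_phantom(in_dir) -> tuple[HyperStack, np.ndarray, CalibrationRecord]:
    import pathlib

    import tifffile

    src = pathlib.Path(in_dir)
    sidecar = json.loads((src / "sidecar.json").read_text())
    rows, cols = sidecar["grid"]
    axis = WavenumberAxis(np.asarray(sidecar["wavenumbers"]))
    frames = np.stack(
        [
            np.stack([tifffile.imread(src / f"frame_r{r}_c{c}.tif") for c in range(cols)])
            for r in range(rows)
        ]
    ).astype(float)
    labels = validate_label_map(tifffile.imread(src / "labels.tif"))
    cal = sidecar["calibration"]
    calibration = CalibrationRecord(
        pump_power=np.asarray(cal["pump_power"]),
        stokes_power=cal["stokes_power"],
        adc_offset=cal["adc_offset"],
        detector_gain=None if cal["detector_gain"] is None else np.asarray(cal["detector_gain"]),
    )
    return HyperStack(data=frames, axis=axis), labels, calibration


_CONFIG_SCALARS = {
    "frame_size": int,
    "pixel_pitch": float,
    "adc_offset": float,
    "pump_power_nominal": float,
    "stokes_power": float,
    "power_fluctuation": float,
    "noise_sigma": float,
    "signal_noise_frac": float,
    "region_smooth_sigma": float,
    "boundary_margin": float,
    "class_separation": float,
    "seed": int,
}


def format_config(config: PhantomConfig) -> str:
    lines = []
    for name, caster in _CONFIG_SCALARS.items():
        lines.append(f"{name} = {getattr(config, name)!r}")
    lines.append(f"mosaic_grid = {config.mosaic_grid[0]}x{config.mosaic_grid[1]}")
    lines.append("wavenumbers = " + ",".join(f"{v:g}" for v in config.wavenumbers))
    lines.append("classes = " + ",".join(CLASS_NAMES[c] for c in config.classes))
    lines.append(
        "shading = "
        + ";".join(f"{i},{j}:{v!r}" for (i, j), v in sorted(config.shading_coefficients.items()))
    )
    return "\n".join(lines) + "\n"


def parse_config(text: str) -> PhantomConfig:
    kwargs: dict = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _CONFIG_SCALARS:
            kwargs[key] = _CONFIG_SCALARS[key](float(value) if _CONFIG_SCALARS[key] is int else value)
        elif key == "mosaic_grid":
            r, _, c = value.partition("x")
            kwargs["mosaic_grid"] = (int(r), int(c))
        elif key == "wavenumbers":
            kwargs["wavenumbers"] = tuple(float(v) for v in value.split(","))
        elif key == "classes":
            kwargs["classes"] = tuple(NAME_TO_CLASS[name.strip()] for name in value.split(","))
        elif key == "shading":
            coeffs = {}
            for item in value.split(";"):
                ij, _, v = item.partition(":")
                i, j = ij.split(",")
                coeffs[(int(i), int(j))] = float(v)
            kwargs["shading_coefficients"] = coeffs
        else:
            raise ValueError(f"unknown phantom config key {key!r}")
    return PhantomConfig(**kwargs)


def scaled_config(config: PhantomConfig, **overrides) -> PhantomConfig:
    """Convenience copy-with-overrides used by tests and the pipeline."""
    return replace(config, **overrides)
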