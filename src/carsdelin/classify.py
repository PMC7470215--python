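"""Pairwise SVM ensemble with majority voting and per-sample calls.

Five tissue classes give ten unordered pairs; each pair is handled by one
linear SVM trained on the selected CARS wavenumbers plus one modality
channel (SHG or TPF) fixed per pair.  A majority vote over the ten members
decides each block, and summed cancer-vs-healthy block counts decide the
sample (fat excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import (
    CANCER_CLASSES,
    CLASS_NAMES,
    HEALTHY_CLASSES,
    TissueClass,
)
from .preprocess import SpectrumTable

__all__ = [
    "PairInputSpec",
    "PairwiseEnsemble",
    "PixelClassMap",
    "DEFAULT_MODALITY",
    "default_pair_specs",
    "subsample_training",
    "train_ensemble",
    "predict_blocks",
    "call_sample",
    "cross_validate_ensemble",
]

_TPF_PAIRS = {
    frozenset({TissueClass.CANCER_CELLS, TissueClass.FAT}),
    frozenset({TissueClass.CANCER_CELLS, TissueClass.HEALTHY_CELLS}),
    frozenset({TissueClass.FAT, TissueClass.HEALTHY_CELLS}),
}

#: fixed modality assignment for every unordered class pair
DEFAULT_MODALITY = {
    frozenset({a, b}): ("tpf" if frozenset({a, b}) in _TPF_PAIRS else "shg")
    for i, a in enumerate(TissueClass)
    for b in list(TissueClass)[i + 1 :]
}


@dataclass(frozen=True)
class PairInputSpec:
    """One binary sub-problem: its two classes and its modality channel."""

    class_a: TissueClass
    class_b: TissueClass
    modality: str  # "shg" or "tpf" (always combined with the CARS features)

    def __post_init__(self) -> None:
        a, b = TissueClass(self.class_a), TissueClass(self.class_b)
        if a == b:
            raise ValueError("a pair needs two distinct classes")
        if a > b:  # canonical order: lower class code first
            a, b = b, a
        object.__setattr__(self, "class_a", a)
        object.__setattr__(self, "class_b", b)
        if self.modality not in ("shg", "tpf"):
            raise ValueError(f"modality must be 'shg' or 'tpf', got {self.modality!r}")

    @property
    def pair(self) -> frozenset:
        return frozenset({self.class_a, self.class_b})

    def __str__(self) -> str:
        return (
            f"{CLASS_NAMES[self.class_a]}|{CLASS_NAMES[self.class_b]}"
            f" ({self.modality}+CARS)"
        )


def default_pair_specs(classes=tuple(TissueClass)) -> list[PairInputSpec]:
    """All unordered pairs of ``classes`` with the fixed modality table."""
    classes = sorted(TissueClass(c) for c in classes)
    specs = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            specs.append(PairInputSpec(a, b, DEFAULT_MODALITY[frozenset({a, b})]))
    return specs


def validate_pair_specs(specs) -> None:
    pairs = [s.pair for s in specs]
    if len(set(pairs)) != len(pairs):
        raise ValueError("each unordered class pair may appear only once")


def subsample_training(
    table: SpectrumTable,
    cap: int = 30_000,
    always_full=(TissueClass.FAT, TissueClass.HEALTHY_CELLS),
    seed: int = 0,
) -> SpectrumTable:
    """Cap per-class record counts; scarce classes are kept whole.

    Classes in ``always_full`` (by default fat and healthy cells, of which
    comparatively few spectra exist) retain every record; each other class is
    uniformly subsampled without replacement to at most ``cap`` records.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    always_full = {TissueClass(c) for c in always_full}
    rng = np.random.default_rng(seed)
    labels = table.labels
    keep = np.zeros(len(table), dtype=bool)
    present = {TissueClass(c) for c in np.unique(labels)}
    for cls in sorted(always_full | present):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            warnings.warn(f"class {CLASS_NAMES[cls]} has no records; omitted")
            continue
        if cls in always_full or idx.size <= cap:
            keep[idx] = True
        else:
            keep[rng.choice(idx, size=cap, replace=False)] = True
    return table.subset(keep)


@dataclass
class PairwiseEnsemble:
    """Ten (for five classes) trained binary members plus a shared FeatureSet."""

    members: dict  # PairInputSpec -> fitted sklearn Pipeline
    feature_set: "FeatureSet"  # noqa: F821 - carsdelin.featsel.FeatureSet
    classes: list[int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.classes)
        if len(self.members) != k * (k - 1) // 2:
            raise ValueError(
                f"{k} classes require {k * (k - 1) // 2} members, got {len(self.members)}"
            )

    def member_features(self, spec: PairInputSpec) -> dict:
        fs = self.feature_set
        return {
            "wavenumbers": list(fs.wavenumbers),
            "include_shg": spec.modality == "shg" and fs.include_shg,
            "include_tpf": spec.modality == "tpf" and fs.include_tpf,
        }

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PairwiseEnsemble":
        import joblib

        return joblib.load(path)


def _make_svm(C: float, kernel: str = "linear") -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=C, decision_function_shape="ovo")),
        ]
    )


def train_ensemble(
    table: SpectrumTable,
    feature_set,
    pair_specs: list[PairInputSpec] | None = None,
    C: float = 1.0,
    seed: int = 0,
) -> PairwiseEnsemble:
    """Fit one standardized linear SVM per class pair on its modality spec."""
    labels = table.labels
    present = set(np.unique(labels).tolist())
    if pair_specs is None:
        pair_specs = default_pair_specs(sorted(present))
    validate_pair_specs(pair_specs)
    needed = {int(c) for spec in pair_specs for c in (spec.class_a, spec.class_b)}
    missing = sorted(needed - present)
    if missing:
        raise ValueError(
            "table is missing class(es): "
            + ", ".join(CLASS_NAMES[TissueClass(c)] for c in missing)
        )

    members: dict[PairInputSpec, Pipeline] = {}
    for spec in pair_specs:
        mask = (labels == spec.class_a) | (labels == spec.class_b)
        pair_table = table.subset(mask)
        X = pair_table.feature_matrix(
            wavenumbers=feature_set.wavenumbers,
            include_shg=spec.modality == "shg" and feature_set.include_shg,
            include_tpf=spec.modality == "tpf" and feature_set.include_tpf,
        )
        model = _make_svm(C)
        model.fit(X, pair_table.labels)
        members[spec] = model
    return PairwiseEnsemble(
        members=members,
        feature_set=feature_set,
        classes=sorted(needed),
        metadata={"C": C, "seed": seed, "n_train": len(table)},
    )


@dataclass
class PixelClassMap:
    """Per-block predictions over the mosaic block grid, with vote tallies."""

    block_rows: np.ndarray  # stitched-pixel origin of each block
    block_cols: np.ndarray
    predictions: np.ndarray  # class codes in {1..5}
    tallies: np.ndarray  # (n_blocks, 5), votes per class; rows sum to |members|
    sample_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.predictions)

    def to_grid(self, block_size: int = 4, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Dense block-grid image of class codes (0 where no block)."""
        rows = self.block_rows // block_size
        cols = self.block_cols // block_size
        if shape is None:
            shape = (int(rows.max()) + 1, int(cols.max()) + 1)
        grid = np.zeros(shape, dtype=np.uint8)
        grid[rows, cols] = self.predictions
        return grid


def predict_blocks(ensemble: PairwiseEnsemble, table: SpectrumTable) -> PixelClassMap:
    """Majority vote of all members; ties broken by summed decision margins."""
    n = len(table)
    tallies = np.zeros((n, 5))
    margin = np.zeros((n, 5))  # signed decision mass toward each class
    for spec, model in ensemble.members.items():
        X = table.feature_matrix(**ensemble.member_features(spec))
        votes = model.predict(X)
        decision = model.decision_function(X)  # >0 favors model classes_[1]
        lo, hi = (int(c) for c in model.named_steps["svm"].classes_)
        tallies[votes == lo, lo - 1] += 1
        tallies[votes == hi, hi - 1] += 1
        margin[:, hi - 1] += decision
        margin[:, lo - 1] -= decision

    best = tallies.max(axis=1, keepdims=True)
    tied = tallies >= best  # contenders per block
    # among vote-tied classes prefer the larger summed margin; final tie ->
    # lowest class code (argmax picks the first maximum)
    score = np.where(tied, margin, -np.inf)
    predictions = score.argmax(axis=1) + 1
    clear = (tied.sum(axis=1) == 1)
    predictions[clear] = tallies[clear].argmax(axis=1) + 1
    return PixelClassMap(
        block_rows=table.df["block_row"].to_numpy(),
        block_cols=table.df["block_col"].to_numpy(),
        predictions=predictions.astype(int),
        tallies=tallies,
        sample_ids=table.sample_ids,
    )


def call_sample(class_map) -> str:
    """Aggregate block predictions into a cancer/healthy call; fat excluded.

    Accepts a :class:`PixelClassMap` or any array of class codes.  A tie goes
    to "cancer" (the clinically costly miss); a map with only fat or
    unclassified blocks is "indeterminate".
    """
    if isinstance(class_map, PixelClassMap):
        codes = class_map.predictions
    else:
        codes = np.asarray(class_map).ravel()
    if codes.size == 0:
        raise ValueError("empty class map")
    cancer = int(np.isin(codes, CANCER_CLASSES).sum())
    healthy = int(np.isin(codes, HEALTHY_CLASSES).sum())
    if cancer == 0 and healthy == 0:
        return "indeterminate"
    return "cancer" if cancer >= healthy else "healthy"


def cross_validate_ensemble(
    table: SpectrumTable,
    feature_set,
    pair_specs: list[PairInputSpec] | None = None,
    n_splits: int = 3,
    cap: int = 30_000,
    C: float = 1.0,
    seed: int = 0,
):
    """Group-aware (sample-level) CV: blocks of one sample never span folds.

    Returns ``(metrics, predictions, truth)`` with pooled held-out
    predictions and a :class:`carsdelin.report.MetricsReport`.
    """
    from .report import compute_metrics

    groups = table.sample_ids
    n_groups = len(np.unique(groups))
    if n_groups < n_splits:
        raise ValueError(
            f"group-aware CV needs >= {n_splits} distinct samples, got {n_groups}"
        )
    predictions = np.zeros(len(table), dtype=int)
    splitter = GroupKFold(n_splits=n_splits)
    for fold, (train_idx, test_idx) in enumerate(
        splitter.split(np.zeros(len(table)), table.labels, groups)
    ):
        train = subsample_training(
            table.subset(np.isin(np.arange(len(table)), train_idx)),
            cap=cap,
            seed=seed + fold,
        )
        ensemble = train_ensemble(train, feature_set, pair_specs=pair_specs, C=C, seed=seed)
        test = table.subset(np.isin(np.arange(len(table)), test_idx))
        predictions[test_idx] = predict_blocks(ensemble, test).predictions
    metrics = compute_metrics(predictions, table.labels)
    return metrics, predictions, table.labels
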