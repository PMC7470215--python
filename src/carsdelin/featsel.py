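"""Feature selection over CARS wavenumbers.

Two schemes: recursive feature elimination driven by aggregated pairwise
linear-SVM weights (with a 40 cm^-1 minimum spectral distance applied at
read-out), and sequential forward selection by cross-validated SVM accuracy,
repeated with occurrence voting.  Plus the feature-count performance sweep.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .classify import cross_validate_ensemble, subsample_training
from .preprocess import SpectrumTable

__all__ = [
    "FeatureSet",
    "MIN_SPECTRAL_DISTANCE",
    "rfe_rank",
    "apply_distance_constraint",
    "sfs_select",
    "sweep_feature_count",
]

#: minimum spectral distance between selected wavenumbers — the width of the
#: Raman peaks in the high-wavenumber region
MIN_SPECTRAL_DISTANCE = 40.0


@dataclass
class FeatureSet:
    """Selected wavenumbers plus modality-inclusion flags.

    ``ranking`` preserves the full considered order (best first);
    ``occurrence_counts`` is populated by SFS only.
    """

    wavenumbers: list = field(default_factory=list)
    include_shg: bool = True
    include_tpf: bool = True
    ranking: list = field(default_factory=list)
    occurrence_counts: dict | None = None
    truncated: bool = False  # fewer features than requested were reachable

    def __post_init__(self) -> None:
        self.wavenumbers = [float(w) for w in self.wavenumbers]
        self.ranking = [float(w) for w in self.ranking]

    def check_distance(self, min_distance: float = MIN_SPECTRAL_DISTANCE) -> bool:
        return all(
            abs(a - b) >= min_distance
            for a, b in itertools.combinations(self.wavenumbers, 2)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "wavenumbers": self.wavenumbers,
                "include_shg": self.include_shg,
                "include_tpf": self.include_tpf,
                "ranking": self.ranking,
                "occurrence_counts": None
                if self.occurrence_counts is None
                else {f"{k:g}": int(v) for k, v in self.occurrence_counts.items()},
                "truncated": self.truncated,
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "FeatureSet":
        raw = json.loads(text)
        occ = raw.get("occurrence_counts")
        return FeatureSet(
            wavenumbers=raw["wavenumbers"],
            include_shg=raw["include_shg"],
            include_tpf=raw["include_tpf"],
            ranking=raw.get("ranking", []),
            occurrence_counts=None if occ is None else {float(k): v for k, v in occ.items()},
            truncated=raw.get("truncated", False),
        )


def _check_svm_params(kernel: str) -> None:
    if kernel != "linear":
        raise ValueError("weight-based RFE requires a linear kernel")


def pairwise_weight_scores(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Per-feature sum over all pairwise linear SVMs of squared weights.

    The binary criterion ("reject the features with the lowest weights")
    extends to the multiclass problem by aggregating the weight vectors of
    every binary sub-classification; squaring makes the sum sign-invariant.
    """
    classes = np.unique(y)
    scores = np.zeros(X.shape[1])
    for a, b in itertools.combinations(classes, 2):
        mask = (y == a) | (y == b)
        svm = SVC(kernel="linear", C=C)
        svm.fit(X[mask], y[mask])
        scores += (svm.coef_[0] ** 2)
    return scores


def rfe_rank(
    table: SpectrumTable,
    C: float = 1.0,
    kernel: str = "linear",
    cap: int | None = None,
    wavenumbers=None,
    seed: int = 0,
) -> list:
    """Rank CARS wavenumbers by recursive elimination, best first.

    Each round trains all pairwise linear SVMs on the remaining standardized
    features and eliminates the single feature with the lowest aggregate
    squared weight (ties to the lower index).  ``cap`` optionally subsamples
    each class before ranking (scarce classes kept whole); ``wavenumbers``
    restricts the considered features (default: the whole axis).
    """
    _check_svm_params(kernel)
    if len(table.classes) < 2:
        raise ValueError("RFE needs at least two classes")
    if cap is not None:
        table = subsample_training(table, cap=cap, seed=seed)
    values = (
        table.axis.values
        if wavenumbers is None
        else np.asarray([float(w) for w in wavenumbers])
    )
    X = table.feature_matrix(wavenumbers=values)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    y = table.labels

    remaining = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(remaining) > 1:
        scores = pairwise_weight_scores(X[:, remaining], y, C=C)
        worst = int(np.argmin(scores))  # ties -> lowest index, deterministic
        eliminated.append(remaining.pop(worst))
    order = remaining + eliminated[::-1]
    return [float(values[i]) for i in order]


def apply_distance_constraint(
    ranking,
    k: int,
    min_distance: float = MIN_SPECTRAL_DISTANCE,
    include_shg: bool = True,
    include_tpf: bool = True,
) -> FeatureSet:
    """Greedy top-down read-out of a ranking under the spacing constraint.

    Walks the ranking from the top, accepting a wavenumber iff it differs by
    at least ``min_distance`` from every already-accepted one, until ``k``
    are accepted or the ranking is exhausted (then ``truncated`` is set).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranking = [float(w) for w in ranking]
    accepted: list[float] = []
    for wn in ranking:
        if all(abs(wn - prev) >= min_distance for prev in accepted):
            accepted.append(wn)
            if len(accepted) == k:
                break
    if len(accepted) < k:
        warnings.warn(
            f"distance constraint of {min_distance:g} cm^-1 left only "
            f"{len(accepted)} of the {k} requested wavenumbers"
        )
    return FeatureSet(
        wavenumbers=accepted,
        include_shg=include_shg,
        include_tpf=include_tpf,
        ranking=ranking,
        truncated=len(accepted) < k,
    )


def _cv_accuracy(X: np.ndarray, y: np.ndarray, C: float, cv) -> float:
    model = Pipeline([("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=C))])
    return float(cross_val_score(model, X, y, cv=cv, scoring="accuracy").mean())


def sfs_select(
    table: SpectrumTable,
    max_features: int = 30,
    repeats: int = 20,
    C: float = 1.0,
    n_folds: int = 5,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> FeatureSet:
    """Occurrence-voted sequential forward selection over CARS wavenumbers.

    Each repeat greedily grows a feature set, adding the wavenumber that
    maximizes stratified-CV accuracy of a linear SVM, until ``max_features``.
    Repeats differ by a stratified record subsample and the fold shuffle;
    the final order is by occurrence count (ties by mean selection step,
    then by wavenumber).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    n_features = len(table.axis)
    if max_features > n_features:
        warnings.warn(
            f"max_features {max_features} exceeds the {n_features} available; capped"
        )
        max_features = n_features
    X_all = table.cars_matrix()
    y_all = table.labels
    rng = np.random.default_rng(seed)

    counts = np.zeros(n_features, dtype=int)
    step_sums = np.zeros(n_features, dtype=float)
    last_order: list[int] = []
    for _ in range(repeats):
        if repeats == 1 or subsample_frac >= 1.0:
            rows = np.arange(len(y_all))
        else:  # stratified subsample so every class survives
            rows = np.concatenate(
                [
                    rng.choice(
                        np.flatnonzero(y_all == cls),
                        size=max(2, int(round(subsample_frac * (y_all == cls).sum()))),
                        replace=False,
                    )
                    for cls in np.unique(y_all)
                ]
            )
        X, y = X_all[rows], y_all[rows]
        class_counts = np.bincount(y)
        folds = min(n_folds, int(class_counts[class_counts > 0].min()))
        cv = StratifiedKFold(
            n_splits=max(2, folds), shuffle=True, random_state=int(rng.integers(2**31))
        )
        selected: list[int] = []
        for step in range(max_features):
            candidates = [f for f in range(n_features) if f not in selected]
            accs = [
                _cv_accuracy(X[:, selected + [f]], y, C, cv) for f in candidates
            ]
            best = candidates[int(np.argmax(accs))]  # ties -> lowest index
            selected.append(best)
            counts[best] += 1
            step_sums[best] += step
        last_order = selected

    if repeats == 1:
        order = last_order
    else:
        mean_step = np.where(counts > 0, step_sums / np.maximum(counts, 1), np.inf)
        chosen = np.flatnonzero(counts > 0)
        order = sorted(chosen, key=lambda f: (-counts[f], mean_step[f], f))
    axis_values = table.axis.values
    return FeatureSet(
        wavenumbers=[float(axis_values[f]) for f in order],
        ranking=[float(axis_values[f]) for f in order],
        occurrence_counts={float(axis_values[f]): int(counts[f]) for f in np.flatnonzero(counts)},
    )


def sweep_feature_count(
    table: SpectrumTable,
    ranking,
    k_range,
    include_shg: bool = True,
    include_tpf: bool = True,
    min_distance: float = MIN_SPECTRAL_DISTANCE,
    n_splits: int = 3,
    cap: int = 30_000,
    C: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Classification performance versus number of CARS wavenumbers.

    For each ``k`` builds the top-k constrained FeatureSet from ``ranking``
    (``k=0`` runs on the modality channels alone) and evaluates the pairwise
    ensemble by group-aware CV.  Returns the curve and the k of highest
    multiclass MCC.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    records = []
    for k in k_range:
        if k == 0:
            if not (include_shg or include_tpf):
                raise ValueError("k=0 requires at least one modality channel")
            fs = FeatureSet(wavenumbers=[], include_shg=include_shg, include_tpf=include_tpf)
        else:
            fs = apply_distance_constraint(
                ranking, k, min_distance, include_shg=include_shg, include_tpf=include_tpf
            )
        metrics, _, _ = cross_validate_ensemble(
            table, fs, n_splits=n_splits, cap=cap, C=C, seed=seed
        )
        records.append(
            {
                "k": k,
                "n_features": len(fs.wavenumbers) + int(include_shg) + int(include_tpf),
                "mcc_multiclass": metrics.mcc_multiclass,
                "mcc_binary": metrics.mcc_binary,
                "accuracy": metrics.accuracy,
                "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity,
            }
        )
    curve = pd.DataFrame.from_records(records)
    best_k = int(curve.loc[curve["mcc_multiclass"].idxmax(), "k"])
    return curve, best_k
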