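import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from carsdelin import featsel
from carsdelin.core import TissueClass, WavenumberAxis
from carsdelin.featsel import (
    FeatureSet,
    apply_distance_constraint,
    rfe_rank,
    sfs_select,
    sweep_feature_count,
)
from carsdelin.preprocess import SpectrumTable

AXIS = WavenumberAxis(np.arange(2700.0, 3201.0, 25.0))


def make_table(
    class_means: dict,
    n_per_class: int = 40,
    noise: float = 0.5,
    n_samples: int = 1,
    seed: int = 0,
    shg: dict | None = None,
    tpf: dict | None = None,
    axis: WavenumberAxis = AXIS,
) -> SpectrumTable:
    """Synthetic table: per-class CARS mean vectors + Gaussian noise."""
    rng = np.random.default_rng(seed)
    records = []
    counter = itertools.count()
    for cls, mean in class_means.items():
        mean = np.asarray(mean, dtype=float)
        for i in range(n_per_class):
            idx = next(counter)
            vec = mean + noise * rng.standard_normal(len(axis))
            records.append(
                {
                    "sample_id": f"s{idx % n_samples}",
                    "block_row": 4 * (idx // 1000),
                    "block_col": 4 * (idx % 1000),
                    "label": int(cls),
                    "shg": (shg or {}).get(cls, 0.0) + 0.05 * rng.standard_normal(),
                    "tpf": (tpf or {}).get(cls, 0.0) + 0.05 * rng.standard_normal(),
                    **dict(zip(axis.cars_columns, vec)),
                }
            )
    return SpectrumTable(pd.DataFrame.from_records(records), axis)


def two_feature_table(seed=0, n=60):
    """First axis point separates the classes perfectly; rest is pure noise."""
    rng = np.random.default_rng(seed)
    means = {
        TissueClass.CANCER_CELLS: np.zeros(len(AXIS)),
        TissueClass.HEALTHY_CELLS: np.zeros(len(AXIS)),
    }
    means[TissueClass.CANCER_CELLS][0] = 10.0  # cars_2700 fully separates
    return make_table(means, n_per_class=n, noise=0.3, seed=seed)


class TestRfeRank:
    def test_noise_feature_eliminated_first(self):
        table = two_feature_table()
        ranking = rfe_rank(table, wavenumbers=[2700.0, 2725.0])
        assert ranking == [2700.0, 2725.0]

    def test_single_feature_trivial_ranking(self):
        table = two_feature_table()
        assert rfe_rank(table, wavenumbers=[2750.0]) == [2750.0]

    def test_single_class_rejected(self):
        table = two_feature_table()
        with pytest.raises(ValueError, match="two classes"):
            rfe_rank(table.subset(table.labels == TissueClass.CANCER_CELLS))

    def test_nonlinear_kernel_rejected(self):
        with pytest.raises(ValueError, match="linear"):
            rfe_rank(two_feature_table(), kernel="rbf")

    def test_first_elimination_matches_exhaustive_weight_oracle(self):
        # independent oracle: recompute aggregate squared pairwise-SVM
        # weights from scratch and compare the argmin with RFE's first drop
        rng = np.random.default_rng(3)
        for trial in range(20):
            n_feat = int(rng.integers(2, 6))
            wns = [float(AXIS.values[i]) for i in range(n_feat)]
            n_classes = int(rng.integers(2, 4))
            classes = [TissueClass(c) for c in range(2, 2 + n_classes)]
            means = {
                cls: np.concatenate(
                    [rng.normal(0, 2.0, size=n_feat), np.zeros(len(AXIS) - n_feat)]
                )
                for cls in classes
            }
            table = make_table(
                means, n_per_class=int(rng.integers(20, 67)), noise=1.0, seed=trial
            )
            ranking = rfe_rank(table, wavenumbers=wns)
            first_dropped = ranking[-1]

            X = table.feature_matrix(wavenumbers=wns)
            X = (X - X.mean(0)) / X.std(0)
            y = table.labels
            scores = np.zeros(n_feat)
            for a, b in itertools.combinations(np.unique(y), 2):
                mask = (y == a) | (y == b)
                svm = SVC(kernel="linear", C=1.0).fit(X[mask], y[mask])
                scores += svm.coef_[0] ** 2
            assert first_dropped == wns[int(np.argmin(scores))]

    def test_brute_force_cv_prefers_rfe_survivor(self):
        # keep each of the two features in turn; the survivor RFE keeps must
        # not be worse under cross-validated accuracy
        table = two_feature_table()
        ranking = rfe_rank(table, wavenumbers=[2700.0, 2725.0])
        y = table.labels
        accs = {}
        for wn in (2700.0, 2725.0):
            X = table.feature_matrix(wavenumbers=[wn])
            model = Pipeline([("s", StandardScaler()), ("m", SVC(kernel="linear"))])
            accs[wn] = cross_val_score(model, X, y, cv=5).mean()
        assert accs[ranking[0]] >= accs[ranking[1]]

    def test_fat_band_ranks_top3_on_planted_phantom(self):
        # phantom with explicitly planted discriminative bands: fat is only
        # separable at 2850; verified against the generating templates
        from carsdelin import phantom, preprocess

        planted = {
            TissueClass.FAT: dict(
                band_centers=(2850.0,), band_widths=(35.0,), band_amplitudes=(0.8,), baseline=0.1
            ),
            TissueClass.CANCER_CELLS: dict(
                band_centers=(2930.0,), band_widths=(50.0,), band_amplitudes=(0.5,), baseline=0.1
            ),
            TissueClass.CANCER_CONNECTIVE: dict(
                band_centers=(2930.0,), band_widths=(50.0,), band_amplitudes=(0.25,), baseline=0.1
            ),
            TissueClass.HEALTHY_CELLS: dict(
                band_centers=(3150.0,), band_widths=(60.0,), band_amplitudes=(0.5,), baseline=0.1
            ),
            TissueClass.HEALTHY_CONNECTIVE: dict(
                band_centers=(3150.0,), band_widths=(60.0,), band_amplitudes=(0.25,), baseline=0.1
            ),
        }
        tables = []
        for i in range(3):
            config = phantom.PhantomConfig(
                frame_size=64,
                mosaic_grid=(2, 2),
                region_smooth_sigma=8.0,
                wavenumbers=tuple(np.arange(2700.0, 3201.0, 25.0)),
                template_params=planted,
                seed=100 + i,
            )
            stack, labels, calibration = phantom.generate_phantom(config)
            tables.append(
                preprocess.preprocess_stack(stack, labels, calibration, sample_id=f"s{i}")
            )
        table = preprocess.SpectrumTable.concat(tables)
        ranking = rfe_rank(table, cap=1500, seed=0)
        assert table.axis.nearest(2850.0) in ranking[:3]

    def test_fat_band_in_default_phantom_final_set(self, cohort_table):
        # the lipid band survives into the constrained read-out; with
        # heavily correlated neighboring features the surviving point may
        # land one axis step (25 cm^-1) off the band center
        ranking = rfe_rank(cohort_table, cap=1500, seed=0)
        fs = apply_distance_constraint(ranking, k=10)
        assert any(abs(wn - 2850.0) <= 25.0 for wn in fs.wavenumbers)

    def test_fat_band_in_sfs_final_set(self, cohort_table):
        rng = np.random.default_rng(0)
        pick = rng.choice(len(cohort_table), size=600, replace=False)
        sub = cohort_table.subset(np.isin(np.arange(len(cohort_table)), pick))
        fs = sfs_select(sub, max_features=4, repeats=3, seed=0)
        assert any(abs(wn - 2850.0) <= 25.0 for wn in fs.wavenumbers)

    def test_deterministic_given_seed(self, cohort_table):
        r1 = rfe_rank(cohort_table, cap=500, seed=7)
        r2 = rfe_rank(cohort_table, cap=500, seed=7)
        assert r1 == r2


class TestDistanceConstraint:
    def test_forced_skip(self):
        fs = apply_distance_constraint([2850.0, 2860.0, 2930.0], k=2)
        assert fs.wavenumbers == [2850.0, 2930.0]
        assert not fs.truncated

    def test_zero_distance_is_vacuous(self):
        ranking = [2930.0, 2850.0, 2860.0]
        fs = apply_distance_constraint(ranking, k=3, min_distance=0.0)
        assert fs.wavenumbers == ranking

    def test_exhaustion_warns_and_flags(self):
        with pytest.warns(UserWarning, match="left only"):
            fs = apply_distance_constraint([2850.0, 2855.0, 2860.0], k=3)
        assert fs.wavenumbers == [2850.0]
        assert fs.truncated

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            apply_distance_constraint([2850.0], k=0)

    @given(
        ranking=st.lists(
            st.floats(min_value=2700.0, max_value=3200.0), min_size=1, max_size=15, unique=True
        ),
        k=st.integers(min_value=1, max_value=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_constraint_soundness_property(self, ranking, k):
        fs = apply_distance_constraint(ranking, k=k)
        for a, b in itertools.combinations(fs.wavenumbers, 2):
            assert abs(a - b) >= 40.0
        assert fs.check_distance()
        assert len(fs.wavenumbers) <= k

    def test_json_roundtrip(self):
        fs = apply_distance_constraint([2850.0, 2930.0, 2990.0], k=2)
        fs.occurrence_counts = {2850.0: 20, 2930.0: 13}
        back = FeatureSet.from_json(fs.to_json())
        assert back.wavenumbers == fs.wavenumbers
        assert back.ranking == fs.ranking
        assert back.occurrence_counts == fs.occurrence_counts
        assert back.include_shg == fs.include_shg


class TestSfsSelect:
    def test_perfect_feature_chosen_first_every_repeat(self):
        table = two_feature_table(n=30)
        repeats = 5
        fs = sfs_select(table, max_features=1, repeats=repeats, seed=0)
        assert fs.wavenumbers[0] == 2700.0
        assert fs.occurrence_counts[2700.0] == repeats

    def test_first_step_matches_exhaustive_search(self):
        # oracle: replay the same subsample/fold stream and brute-force the
        # best single feature by CV accuracy
        rng = np.random.default_rng(5)
        means = {
            TissueClass.CANCER_CELLS: rng.normal(0, 1, len(AXIS)),
            TissueClass.HEALTHY_CELLS: rng.normal(0, 1, len(AXIS)),
            TissueClass.FAT: rng.normal(0, 1, len(AXIS)),
        }
        table = make_table(means, n_per_class=30, noise=2.0, seed=5)
        fs = sfs_select(table, max_features=1, repeats=1, seed=11)

        mirror = np.random.default_rng(11)
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=int(mirror.integers(2**31)))
        y = table.labels
        accs = []
        for wn in table.axis.values:
            X = table.feature_matrix(wavenumbers=[wn])
            model = Pipeline([("s", StandardScaler()), ("m", SVC(kernel="linear", C=1.0))])
            accs.append(cross_val_score(model, X, y, cv=cv, scoring="accuracy").mean())
        expected = float(table.axis.values[int(np.argmax(accs))])
        assert fs.wavenumbers[0] == expected

    def test_repeats_1_order_is_selection_order(self):
        table = two_feature_table(n=30)
        fs = sfs_select(table, max_features=3, repeats=1, seed=2)
        assert len(fs.wavenumbers) == 3
        assert fs.ranking == fs.wavenumbers

    def test_max_features_1_returns_one_per_repeat(self):
        table = two_feature_table(n=30)
        fs = sfs_select(table, max_features=1, repeats=3, seed=0)
        assert sum(fs.occurrence_counts.values()) == 3

    def test_max_features_capped_with_warning(self):
        table = two_feature_table(n=20)
        with pytest.warns(UserWarning, match="capped"):
            fs = sfs_select(table, max_features=len(AXIS) + 5, repeats=1, seed=0)
        assert len(fs.wavenumbers) == len(AXIS)

    def test_deterministic_given_seed(self):
        table = two_feature_table(n=30)
        a = sfs_select(table, max_features=2, repeats=2, seed=4)
        b = sfs_select(table, max_features=2, repeats=2, seed=4)
        assert a.wavenumbers == b.wavenumbers
        assert a.occurrence_counts == b.occurrence_counts


@pytest.fixture(scope="module")
def planted_table():
    # exactly 4 informative CARS bands; everything else is noise
    rng = np.random.default_rng(8)
    informative = [0, 5, 10, 15]  # well-spread axis indices
    means = {}
    for j, cls in enumerate(TissueClass):
        mean = np.zeros(len(AXIS))
        for k, idx in enumerate(informative):
            mean[idx] = 3.0 * np.sin(1.0 + j * (k + 1))
        means[cls] = mean
    shg = {cls: float(j) for j, cls in enumerate(TissueClass)}
    tpf = {cls: float(-j) for j, cls in enumerate(TissueClass)}
    return make_table(
        means, n_per_class=60, noise=1.0, n_samples=4, seed=8, shg=shg, tpf=tpf
    )


class TestSweep:
    def test_curve_peaks_at_low_k_with_4_planted_bands(self, planted_table):
        ranking = rfe_rank(planted_table)
        curve, best_k = sweep_feature_count(
            planted_table, ranking, k_range=[1, 2, 4, 6, 10], n_splits=4, seed=0
        )
        assert best_k <= 6
        plateau = curve.set_index("k").loc[4, "mcc_multiclass"]
        tail = curve.set_index("k").loc[10, "mcc_multiclass"]
        assert tail <= plateau + 0.05  # non-increasing beyond plateau, CV noise

    def test_k0_modality_only_baseline(self, planted_table):
        curve, _ = sweep_feature_count(
            planted_table, [2700.0], k_range=[0], n_splits=4, seed=0
        )
        assert len(curve) == 1 and curve.loc[0, "n_features"] == 2
        assert np.isfinite(curve.loc[0, "accuracy"])

    def test_empty_k_range_rejected(self, planted_table):
        with pytest.raises(ValueError, match="k_range"):
            sweep_feature_count(planted_table, [2700.0], k_range=[])

    def test_duplicate_columns_never_help_beyond_cv_noise(self, planted_table):
        # duplicate an informative column into an uninformative slot
        df = planted_table.df.copy()
        df["cars_2725"] = df["cars_2700"]
        table = SpectrumTable(df, planted_table.axis)
        ranking = [2700.0, 2725.0, 2825.0, 2950.0]
        curve, _ = sweep_feature_count(
            table,
            ranking,
            k_range=[1, 2],
            min_distance=0.0,
            n_splits=4,
            seed=0,
        )
        mcc = curve.set_index("k")["mcc_multiclass"]
        assert mcc[2] <= mcc[1] + 0.05
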