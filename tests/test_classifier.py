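import numpy as np
import pandas as pd
import pytest

from lypred.classifier import (
    CVConfig,
    TrainedModel,
    cross_validated_scores,
    grid_search,
    make_cv_evaluator,
    train_final,
    tune_threshold,
)
from lypred.errors import ConfigError, SequenceTooShortError, StratificationError
from lypred.features import FeatureMatrix, PseAACParams, encode_matrix
from lypred.seqio import ProteinRecord
from lypred.synthetic import SyntheticSpec, generate_dataset


def gaussian_matrix(rng, n_per_class=20, n_features=5, shift=3.0):
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.repeat([1, 0], n_per_class)
    X[:, 0] += shift * y
    frame = pd.DataFrame(
        X, columns=[f"f{i}" for i in range(n_features)],
        index=[f"s{i}" for i in range(2 * n_per_class)],
    )
    return FeatureMatrix(X=frame, y=y)


class TestCrossValidatedScores:
    def test_jackknife_yields_one_value_per_sample(self, rng):
        m = gaussian_matrix(rng, n_per_class=8)
        dv = cross_validated_scores(m, CVConfig(jackknife=True))
        assert dv.shape == (16,)

    def test_separable_data_signs_agree_with_labels(self, rng):
        m = gaussian_matrix(rng, n_per_class=25, shift=4.0)
        dv = cross_validated_scores(m, CVConfig(n_folds=5, seed=0))
        agreement = np.mean((dv >= 0).astype(int) == m.y)
        assert agreement >= 0.95

    def test_n_folds_equal_n_without_jackknife_flag_is_config_error(self, rng):
        m = gaussian_matrix(rng, n_per_class=5)
        with pytest.raises(ConfigError):
            cross_validated_scores(m, CVConfig(n_folds=10))

    def test_tiny_class_stratification_error(self, rng):
        m = gaussian_matrix(rng, n_per_class=2)
        with pytest.raises(StratificationError):
            cross_validated_scores(m, CVConfig(n_folds=3))

    def test_deterministic_given_seed(self, rng):
        m = gaussian_matrix(rng, n_per_class=10)
        a = cross_validated_scores(m, CVConfig(seed=5))
        b = cross_validated_scores(m, CVConfig(seed=5))
        assert np.array_equal(a, b)

    def test_held_out_label_does_not_affect_its_decision_value(self, rng):
        # leave-one-out: flipping sample 0's label must not change its own score
        m = gaussian_matrix(rng, n_per_class=8)
        dv = cross_validated_scores(m, CVConfig(jackknife=True))
        flipped = FeatureMatrix(X=m.X.copy(), y=m.y.copy())
        flipped.y[0] = 1 - flipped.y[0]
        dv_flipped = cross_validated_scores(flipped, CVConfig(jackknife=True))
        assert dv[0] == pytest.approx(dv_flipped[0], abs=1e-12)


class TestTuneThreshold:
    def test_separable_values_reach_perfect_aa(self):
        result = tune_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], criterion="AA")
        assert result.report.aa == 100.0
        assert 0.2 < result.threshold < 0.8

    def test_random_labels_give_chance_level_aa(self, rng):
        n = 400
        dv = rng.normal(size=n)
        y = rng.integers(0, 2, size=n)
        result = tune_threshold(dv, y, criterion="AA")
        # max over thresholds inflates slightly above 50%
        assert result.report.aa < 62.0

    def test_degenerate_identical_values_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            result = tune_threshold([0.5, 0.5], [1, 0], criterion="AA")
        assert result.threshold == 0.5

    def test_threshold_semantics_ge(self):
        result = tune_threshold([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], criterion="OA")
        dv = np.array([1.0, 2.0, 3.0, 4.0])
        assert list((dv >= result.threshold).astype(int)) == [0, 0, 1, 1]


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(
        n_pos=25, n_neg=25, length_range=(60, 120),
        signal_type="dipeptide", planted_g=2, effect_size=0.8, seed=11,
    )
    return generate_dataset(spec)


class TestGridSearch:
    def test_cell_count_and_columns(self, planted):
        records, labels = planted
        result = grid_search(
            records, labels, g_range=[1, 2], delta_range=[1],
            cv=CVConfig(n_folds=5, seed=0), max_subset_size=10,
        )
        assert result.n_cells == 2
        assert set(result.table.columns) == {"g", "delta", "best_size", "best_OA", "best_AA"}

    def test_recovers_planted_gap(self, planted):
        records, labels = planted
        result = grid_search(
            records, labels, g_range=[0, 2], delta_range=[1],
            cv=CVConfig(n_folds=5, seed=0), max_subset_size=15,
        )
        assert result.best_cell[0] == 2

    def test_preflight_length_error_lists_offenders(self, planted):
        records, labels = planted
        short = ProteinRecord("tiny", "ACDEFGHIK")
        with pytest.raises(SequenceTooShortError, match="tiny"):
            grid_search(
                [short] + list(records), {**labels, "tiny": 1},
                g_range=[0, 9], delta_range=[1], cv=CVConfig(seed=0),
            )


@pytest.fixture(scope="module")
def trained():
    spec = SyntheticSpec(
        n_pos=20, n_neg=20, length_range=(40, 80),
        signal_type="dipeptide", planted_g=0, effect_size=0.8, seed=3,
    )
    records, labels = generate_dataset(spec)
    params = PseAACParams(g=0, delta=2)
    matrix = encode_matrix(records, labels, params)
    evaluator = make_cv_evaluator(CVConfig(n_folds=5, seed=0))
    from lypred.selection import anova_f_scores, incremental_feature_selection

    ranking = anova_f_scores(matrix)
    ifs = incremental_feature_selection(matrix, ranking, evaluator, max_size=10)
    model = train_final(
        records, labels, params, ifs.best_features, threshold=0.1,
        provenance={"seed": 3},
    )
    return model, records


class TestTrainedModel:
    def test_save_load_round_trip_identical_decisions(self, trained, tmp_path):
        model, records = trained
        before = model.predict(records)
        path = tmp_path / "model.zip"
        model.save(path)
        reloaded = TrainedModel.load(path)
        after = reloaded.predict(records)
        assert np.array_equal(
            before["decision_value"].to_numpy(float),
            after["decision_value"].to_numpy(float),
        )
        assert reloaded.threshold == model.threshold
        assert reloaded.selected_features == model.selected_features

    def test_short_record_gets_error_entry_others_unaffected(self, trained):
        model, records = trained
        mixed = [records[0], ProteinRecord("shorty", "AC"), records[1]]
        frame = model.predict(mixed)
        assert frame.loc[1, "error"] != ""
        assert np.isnan(frame.loc[1, "decision_value"])
        assert frame.loc[0, "error"] == "" and frame.loc[2, "error"] == ""

    def test_labels_follow_threshold(self, trained):
        model, records = trained
        frame = model.predict(records)
        ok = frame[frame["error"] == ""]
        expected = (ok["decision_value"].to_numpy(float) >= model.threshold).astype(int)
        assert list(ok["label"].to_numpy(int)) == list(expected)

    def test_unknown_feature_name_is_config_error(self, trained):
        model, records = trained
        spec = SyntheticSpec(n_pos=5, n_neg=5, length_range=(20, 30), seed=1,
                             signal_type="none")
        recs, labels = generate_dataset(spec)
        with pytest.raises(ConfigError):
            train_final(recs, labels, PseAACParams(g=0, delta=1), ["nonexistent:feature"])


class TestEndToEndRecovery:
    def test_planted_signal_reaches_high_cv_aa(self):
        spec = SyntheticSpec(
            n_pos=30, n_neg=30, length_range=(60, 120),
            signal_type="dipeptide", planted_g=2, effect_size=0.8, seed=5,
        )
        records, labels = generate_dataset(spec)
        matrix = encode_matrix(records, labels, PseAACParams(g=2, delta=1))
        from lypred.selection import anova_f_scores, incremental_feature_selection

        ranking = anova_f_scores(matrix)
        ifs = incremental_feature_selection(
            matrix, ranking, make_cv_evaluator(CVConfig(n_folds=5, seed=0)),
            max_size=20,
        )
        assert ifs.best_report.aa >= 90.0
        planted = {"dipeptide:KE:gap2", "dipeptide:WC:gap2", "dipeptide:PG:gap2"}
        assert len(planted & set(ranking.ranked_names[:10])) >= 2
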