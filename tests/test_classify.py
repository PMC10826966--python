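"""Bimodality model training, calibration and the complexity decision tree."""

import numpy as np
import pytest
from scipy import stats

import tetraclass as tc
from tetraclass import classify as clf
from tetraclass.features import MixtureFit
from tetraclass.simulate import TetradPanel

from conftest import make_planted_panels


def bimodal_panel(p_low=0.5, jitter=0.01, seed=0, parents=(0.0, 1.0)):
    """A hand-built bimodal panel with given lower-mode proportion."""
    rng = np.random.default_rng(seed)
    n_low = int(round(160 * p_low))
    v = np.concatenate(
        [rng.normal(0, jitter, n_low), rng.normal(1, jitter, 160 - n_low)]
    )
    rng.shuffle(v)
    return TetradPanel("x", "c", v.reshape(40, 4), np.asarray(parents, float))


class TestTraining:
    def test_default_model_has_100_trees(self, small_model):
        assert small_model.n_trees == 100
        assert small_model.feature_order == tc.FEATURE_NAMES

    def test_training_fit_quality(self):
        ts = tc.generate_training_set(250, 125, 125, rng_seed=21)
        model = clf.train_bimodality_model(ts, rng_seed=1)
        X = tc.feature_matrix([lp.panel for lp in ts])
        pred = model.forest.predict(X.to_numpy())
        true = [lp.w1 for lp in ts]
        assert stats.spearmanr(pred, true).statistic > 0.8

    def test_same_seed_same_predictions(self):
        ts = tc.generate_training_set(100, 50, 50, rng_seed=22)
        X = tc.feature_matrix([lp.panel for lp in ts])
        y = np.array([lp.w1 for lp in ts])
        m1 = clf.train_bimodality_model((X, y), rng_seed=5)
        m2 = clf.train_bimodality_model((X, y), rng_seed=5)
        probe = tc.feature_matrix(
            [lp.panel for lp in tc.generate_training_set(20, 0, 0, rng_seed=23)]
        )
        np.testing.assert_array_equal(
            m1.forest.predict(probe.to_numpy()), m2.forest.predict(probe.to_numpy())
        )

    def test_length_mismatch_rejected(self):
        ts = tc.generate_training_set(10, 0, 0, rng_seed=24)
        X = tc.feature_matrix([lp.panel for lp in ts])
        with pytest.raises(ValueError):
            clf.train_bimodality_model((X, np.zeros(5)))


class TestPrediction:
    def test_extreme_weights_ranked(self, small_model):
        strong = tc.generate_training_set(
            10, 0, 0, w1_sampler=lambda r, n: np.ones(n), rng_seed=30,
            noise_sd=0.0,
        )
        weak = tc.generate_training_set(
            10, 0, 0, w1_sampler=lambda r, n: np.zeros(n), rng_seed=31
        )
        for lp in strong:
            f = tc.extract_features(lp.panel)
            assert clf.predict_bimodality(small_model, f) > 0.8
        for lp in weak:
            f = tc.extract_features(lp.panel)
            assert clf.predict_bimodality(small_model, f) < 0.3

    def test_output_clipped_to_unit_interval(self, small_model):
        ts = tc.generate_training_set(30, 15, 15, rng_seed=32)
        for lp in ts:
            pred = clf.predict_bimodality(small_model, tc.extract_features(lp.panel))
            assert 0.0 <= pred <= 1.0

    def test_wrong_feature_count_rejected(self, small_model):
        with pytest.raises(ValueError):
            clf.predict_bimodality(small_model, np.zeros(10))


class TestCalibration:
    def test_perfect_separation(self, small_model):
        labeled = tc.generate_labeled_eval_set(100, 100, rng_seed=33)
        report = clf.calibrate_threshold(small_model, labeled, update_model=False)
        assert report.auc == pytest.approx(1.0)
        assert report.sensitivity_at_threshold == pytest.approx(1.0)
        assert report.specificity_at_threshold == pytest.approx(1.0)
        assert 0.0 <= report.threshold <= 1.0

    def test_shuffled_labels_near_half_auc(self, small_model):
        labeled = tc.generate_labeled_eval_set(1000, 1000, rng_seed=34)
        rng = np.random.default_rng(35)
        labels = np.array([lab for _, lab in labeled])
        rng.shuffle(labels)
        shuffled = [(p, bool(l)) for (p, _), l in zip(labeled, labels)]
        report = clf.calibrate_threshold(small_model, shuffled, update_model=False)
        assert report.auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self, small_model):
        labeled = tc.generate_labeled_eval_set(10, 0, rng_seed=36)
        with pytest.raises(ValueError):
            clf.calibrate_threshold(small_model, labeled)


class TestParentalModes:
    @pytest.fixture()
    def fit(self):
        return MixtureFit(mu1=0.0, mu2=1.0, sd1=0.1, sd2=0.1, pi1=0.5,
                          loglik=0.0, converged=True)

    def test_parents_at_component_means(self, fit):
        assert clf.assign_parental_modes(fit, [0.0, 1.0]) == ("low", "high")

    def test_parent_at_posterior_equality_is_intermediate(self, fit):
        assert clf.assign_parental_modes(fit, [0.5, 1.0])[0] == "intermediate"

    def test_parents_beyond_modes_assigned_to_nearest(self, fit):
        assert clf.assign_parental_modes(fit, [-2.0, -3.0]) == ("low", "low")

    def test_missing_parent(self, fit):
        assert clf.assign_parental_modes(fit, [np.nan, 1.0]) == ("missing", "high")

    def test_scalar_threshold_fallback(self):
        assert clf.assign_parental_modes(0.5, [0.1, 0.9]) == ("low", "high")
        assert clf.assign_parental_modes(0.5, [0.5, 0.9])[0] == "intermediate"


class TestDensityFallback:
    def test_separated_masses(self):
        rng = np.random.default_rng(37)
        v = np.concatenate(
            [rng.normal(0, 0.02, 40), rng.normal(1, 0.02, 120)]
        )
        thr, p_low, n_peaks = clf.density_peak_fallback(v)
        assert n_peaks == 2
        assert 0.0 < thr < 1.0
        assert p_low == pytest.approx(0.25, abs=0.02)

    def test_unimodal_sample_single_peak(self):
        rng = np.random.default_rng(38)
        hits = 0
        for _ in range(20):
            thr, p_low, n_peaks = clf.density_peak_fallback(rng.normal(size=160))
            if n_peaks == 1:
                assert thr is None
                hits += 1
        assert hits >= 15  # occasional wiggles allowed

    def test_threshold_between_peaks(self):
        rng = np.random.default_rng(39)
        v = np.concatenate([rng.normal(0, 0.05, 80), rng.normal(1, 0.05, 80)])
        thr, _, n_peaks = clf.density_peak_fallback(v)
        assert n_peaks >= 2
        assert 0.1 < thr < 0.9


class TestDecisionTree:
    def test_unimodal_panel_called_complex(self, small_model):
        rng = np.random.default_rng(40)
        v = rng.normal(0.5, 0.1, 160)
        panel = TetradPanel("x", "c", v.reshape(40, 4), np.array([0.5, 0.5]))
        call = clf.classify_complexity(panel, small_model)
        assert call.level == "complex" and not call.bimodal

    def test_planted_monogenic_called_monogenic(self, small_model):
        panels = make_planted_panels("monogenic", 20, seed=41, noise_sd=0.02)
        calls = clf.classify_panels(panels, small_model)
        frac = np.mean([c.level == "monogenic" for c in calls])
        assert frac >= 0.9

    def test_unbalanced_bimodal_called_oligogenic(self, small_model):
        panel = bimodal_panel(p_low=0.25, seed=42)
        call = clf.classify_complexity(panel, small_model)
        assert call.level == "oligogenic"
        assert call.subtype == "bimodal_unbalanced"
        assert call.p_low == pytest.approx(0.25, abs=0.05)

    def test_balanced_same_mode_parents_oligogenic(self, small_model):
        panel = bimodal_panel(p_low=0.5, seed=43, parents=(0.0, 0.0))
        call = clf.classify_complexity(panel, small_model)
        assert call.level == "oligogenic"
        assert call.subtype == "bimodal_parents_same_mode"

    def test_no_growth_panel_undetermined(self, small_model):
        v = np.abs(np.random.default_rng(44).normal(0, 0.005, 160))
        panel = TetradPanel("x", "c", v.reshape(40, 4), np.array([0.0, 1.0]))
        call = clf.classify_complexity(panel, small_model)
        assert call.level == "undetermined"

    def test_level_bimodal_consistency(self, small_model):
        ts = tc.generate_training_set(60, 30, 30, rng_seed=45)
        calls = clf.classify_panels([lp.panel for lp in ts], small_model)
        for c in calls:
            if c.level == "complex":
                assert not c.bimodal
            if c.level in ("monogenic", "oligogenic"):
                assert c.bimodal

    def test_calls_stable_under_rescaling_of_clear_panels(self, small_model):
        # scale-free features dominate away from the decision boundary;
        # panels with clearly extreme architectures keep their call when
        # all phenotypes (parents included) are doubled
        panels = make_planted_panels("monogenic", 25, seed=46) + make_planted_panels(
            "complex", 25, seed=47
        )
        calls = clf.classify_panels(panels, small_model)
        doubled = [
            TetradPanel(p.cross_id, p.condition, 2.0 * p.values,
                        2.0 * p.parent_values)
            for p in panels
        ]
        calls2 = clf.classify_panels(doubled, small_model)
        assert [c.level for c in calls] == [c.level for c in calls2]

    def test_uncalibrated_model_rejected(self):
        ts = tc.generate_training_set(30, 0, 0, rng_seed=48)
        model = clf.train_bimodality_model(ts, rng_seed=1)
        with pytest.raises(ValueError):
            clf.classify_complexity(ts[0].panel, model)


class TestPersistence:
    def test_round_trip(self, small_model, tmp_path):
        path = tmp_path / "model.joblib"
        clf.save_model(small_model, path)
        loaded = clf.load_model(path)
        assert loaded.threshold == small_model.threshold
        assert loaded.feature_order == small_model.feature_order
        probe = tc.feature_matrix(
            [lp.panel for lp in tc.generate_training_set(10, 0, 0, rng_seed=49)]
        )
        np.testing.assert_array_equal(
            loaded.forest.predict(probe.to_numpy()),
            small_model.forest.predict(probe.to_numpy()),
        )

    def test_feature_order_contract_enforced(self, small_model, tmp_path):
        import joblib, json

        path = tmp_path / "model.joblib"
        clf.save_model(small_model, path)
        blob = joblib.load(path)
        meta = json.loads(blob["meta_json"])
        meta["feature_order"] = meta["feature_order"][::-1]
        blob["meta_json"] = json.dumps(meta)
        joblib.dump(blob, path)
        with pytest.raises(ValueError):
            clf.load_model(path)

    def test_calls_file_round_trip(self, small_model, tmp_path):
        panels = [lp.panel for lp in tc.generate_training_set(10, 5, 5, rng_seed=50)]
        calls = clf.classify_panels(panels, small_model)
        path = tmp_path / "calls.tsv"
        clf.write_calls(calls, path)
        back = clf.read_calls(path)
        assert [c.level for c in back] == [c.level for c in calls]
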