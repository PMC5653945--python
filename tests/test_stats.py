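"""The predictive evaluation layer: aggregation, AUC, bootstrap, optimal
cutpoints, logistic fits, stepwise selection, Spearman correlation."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from osteofract import (
    ValidationError,
    aggregate_features,
    auc_continuous,
    bootstrap_bias_corrected,
    classification_accuracy,
    fit_logistic,
    optimal_threshold,
    spearman_correlation,
    stepwise_selection,
)


def _tidy(values_by_patient_plane):
    rows = []
    for (pid, plane), vals in values_by_patient_plane.items():
        for rep, v in enumerate(vals, 1):
            rows.append(
                {"patient_id": pid, "plane": plane, "replicate": rep, "sfr": v}
            )
    return pd.DataFrame(rows)


class TestAggregateFeatures:
    def test_plane_means_and_three_plane_average(self):
        df = _tidy(
            {
                ("P1", "coronal"): (0.90, 0.92),
                ("P1", "sagittal"): (0.93, 0.93),
                ("P1", "transversal"): (0.95, 0.95),
            }
        )
        agg = aggregate_features(df, ["sfr"]).set_index("section")
        assert agg.loc["coronal", "sfr"] == pytest.approx(0.91)
        assert agg.loc["average", "sfr"] == pytest.approx((0.91 + 0.93 + 0.95) / 3)

    def test_missing_plane_propagates_to_average_with_warning(self):
        df = _tidy({("P1", "coronal"): (0.9, 0.9)})
        with pytest.warns(UserWarning, match="average recorded as missing"):
            agg = aggregate_features(df, ["sfr"]).set_index("section")
        assert math.isnan(agg.loc["average", "sfr"])
        assert agg.loc["coronal", "sfr"] == pytest.approx(0.9)

    def test_full_cohort_matches_hand_oracle(self, rng):
        rows = []
        expected = {}
        for pid in ("P1", "P2"):
            plane_means = []
            for plane in ("coronal", "sagittal", "transversal"):
                vals = rng.normal(0.92, 0.02, 2)
                plane_means.append(vals.mean())
                for rep, v in enumerate(vals, 1):
                    rows.append(
                        {"patient_id": pid, "plane": plane, "replicate": rep, "sfr": v}
                    )
            expected[pid] = np.mean(plane_means)
        agg = aggregate_features(pd.DataFrame(rows), ["sfr"])
        for pid, want in expected.items():
            got = agg[(agg.patient_id == pid) & (agg.section == "average")]["sfr"]
            assert float(got.iloc[0]) == pytest.approx(want, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_features(pd.DataFrame(), ["sfr"])


class TestAucContinuous:
    def test_perfect_separation_and_all_ties(self):
        labels = ["good", "good", "poor", "poor"]
        assert auc_continuous([1, 2, 3, 4], labels) == pytest.approx(1.0)
        assert auc_continuous([5, 5, 5, 5], labels) == pytest.approx(0.5)

    def test_four_point_pair_enumeration(self):
        assert auc_continuous([1, 2, 3, 4], ["good", "good", "poor", "poor"]) == 1.0
        # poor values {1,3} vs good {2,4}: only the (3,2) pair is a win,
        # so 1 of 4 pairs -> 0.25
        assert auc_continuous([1, 2, 3, 4], ["poor", "good", "poor", "good"]) == pytest.approx(0.25)

    def test_matches_pairwise_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 50))
            values = rng.normal(0, 1, n)
            if rng.random() < 0.3:  # inject ties
                values = np.round(values, 1)
            pos = rng.random(n) < 0.5
            if pos.all() or not pos.any():
                continue
            wins = ties = 0
            for vp in values[pos]:
                for vg in values[~pos]:
                    wins += vp > vg
                    ties += vp == vg
            oracle = (wins + 0.5 * ties) / (pos.sum() * (~pos).sum())
            assert auc_continuous(values, pos) == pytest.approx(oracle, abs=1e-12)

    def test_orientation_fixed_sub_half_reported_as_is(self):
        # feature higher in GOOD responders -> AUC below 0.5, not flipped
        values = [4.0, 3.0, 2.0, 1.0]
        labels = ["good", "good", "poor", "poor"]
        assert auc_continuous(values, labels) == pytest.approx(0.0)

    def test_complement_identity(self, rng):
        values = rng.normal(0, 1, 30)
        pos = np.arange(30) % 3 == 0
        a = auc_continuous(values, pos)
        b = auc_continuous(-values, pos)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.normal(0, 1, 25)
        pos = np.arange(25) % 2 == 0
        base = auc_continuous(values, pos)
        assert auc_continuous(np.exp(values), pos) == pytest.approx(base, abs=1e-12)
        assert auc_continuous(3 * values - 7, pos) == pytest.approx(base, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        values = np.round(rng.normal(0, 1, 40), 1)
        pos = rng.random(40) < 0.4
        pos[:2], pos[-2:] = True, False
        assert auc_continuous(values, pos) == pytest.approx(
            roc_auc_score(pos, values), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc_continuous([1, 2, 3], ["poor", "poor", "poor"])


class TestBootstrap:
    def test_deterministic_under_fixed_seed(self, rng):
        values = rng.normal(0, 1, 30)
        labels = np.arange(30) % 2 == 0
        a = bootstrap_bias_corrected(values, labels, n_boot=250, seed=7)
        b = bootstrap_bias_corrected(values, labels, n_boot=250, seed=7)
        assert a == b

    def test_perfectly_separated_groups_pin_ci_at_one(self, rng):
        values = np.concatenate([rng.normal(0, 0.1, 25), rng.normal(10, 0.1, 25)])
        labels = np.array([False] * 25 + [True] * 25)
        roc = bootstrap_bias_corrected(values, labels, n_boot=300, seed=1)
        assert roc.auc == pytest.approx(1.0)
        assert roc.ci_corrected[0] > 0.99
        assert abs(roc.bias) < 0.01

    def test_ci_width_shrinks_with_group_size(self, rng):
        def width(n, seed):
            values = np.concatenate([rng.normal(0, 1, n), rng.normal(1.2, 1, n)])
            labels = np.array([False] * n + [True] * n)
            roc = bootstrap_bias_corrected(values, labels, n_boot=400, seed=seed)
            return roc.ci_corrected[1] - roc.ci_corrected[0]

        widths_small = [width(10, s) for s in range(5)]
        widths_large = [width(40, s) for s in range(5)]
        assert np.mean(widths_large) < np.mean(widths_small)

    def test_too_few_bootstraps_rejected(self, rng):
        with pytest.raises(ValidationError):
            bootstrap_bias_corrected(
                rng.normal(0, 1, 20), np.arange(20) % 2 == 0, n_boot=50
            )


def _threshold_oracle(values, pos):
    """Exhaustive chi-square scan with scipy's contingency test."""
    from scipy.stats import chi2_contingency

    best = (-1.0, None)
    distinct = np.unique(values)
    for cut in (distinct[:-1] + distinct[1:]) / 2:
        above = values > cut
        table = np.array(
            [
                [np.sum(above & pos), np.sum(above & ~pos)],
                [np.sum(~above & pos), np.sum(~above & ~pos)],
            ]
        )
        if (table.sum(1) == 0).any() or (table.sum(0) == 0).any():
            chi2 = 0.0
        else:
            chi2 = chi2_contingency(table, correction=False)[0]
        if chi2 > best[0] + 1e-12:
            best = (chi2, cut)
    return best


class TestOptimalThreshold:
    def test_unique_separating_gap_found(self):
        rule = optimal_threshold([1, 2, 8, 9], ["good", "good", "poor", "poor"])
        assert rule.cutpoint == pytest.approx(5.0)
        assert rule.direction == "greater_is_positive"
        assert classification_accuracy(rule, [1, 2, 8, 9], ["good", "good", "poor", "poor"]) == 100.0

    def test_label_flip_symmetry_of_chi_square(self, rng):
        values = rng.normal(0, 1, 20)
        labels = rng.random(20) < 0.5
        labels[0], labels[1] = True, False
        a = optimal_threshold(values, labels)
        b = optimal_threshold(values, ~labels)
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-9)
        assert a.cutpoint == pytest.approx(b.cutpoint)

    def test_matches_exhaustive_chi_square_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 50))
            values = np.round(rng.normal(0, 1, n), 2)
            pos = rng.random(n) < 0.5
            pos[0], pos[1] = True, False
            if np.unique(values).size < 2:
                continue
            rule = optimal_threshold(values, pos)
            chi2_best, _ = _threshold_oracle(values, pos)
            assert rule.chi_square == pytest.approx(chi2_best, abs=1e-9)

    def test_rule_direction_points_at_higher_poor_rate_side(self, rng):
        # the chi-square-optimal cut maximizes association, not accuracy, so
        # the guaranteed property is directional consistency: the positive
        # side of the rule is the side with the higher poor-responder rate
        for _ in range(20):
            values = rng.normal(0, 1, 30)
            pos = rng.random(30) < 0.4
            pos[0], pos[1] = True, False
            rule = optimal_threshold(values, pos)
            above = values > rule.cutpoint
            rate_above = pos[above].mean() if above.any() else 0.0
            rate_below = pos[~above].mean() if (~above).any() else 0.0
            if rule.direction == "greater_is_positive":
                assert rate_above >= rate_below
            else:
                assert rate_below > rate_above

    def test_inverted_rule_scores_zero_on_separable_data(self):
        rule = optimal_threshold([1, 2, 8, 9], ["good", "good", "poor", "poor"])
        flipped = type(rule)(
            feature=rule.feature,
            cutpoint=rule.cutpoint,
            direction="lesser_is_positive",
            chi_square=rule.chi_square,
            p_value=rule.p_value,
        )
        assert classification_accuracy(flipped, [1, 2, 8, 9], ["good", "good", "poor", "poor"]) == 0.0

    def test_constant_values_rejected(self):
        with pytest.raises(ValidationError):
            optimal_threshold([3, 3, 3, 3], ["good", "poor", "good", "poor"])


class TestFitLogistic:
    def test_balanced_symmetric_data_gives_null_slope(self):
        # outcome is an even function of x, so the likelihood is symmetric
        # in the slope and the MLE sits at zero
        x = np.array([-2.0, -1.0, 1.0, 2.0] * 10)
        y = np.array([True, False, False, True] * 10)
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        assert abs(model.coefficients["x"]) < 1e-6
        assert model.p_values["x"] > 0.99

    def test_parameter_recovery_at_n_2000(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 2000)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = rng.random(2000) < p
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        assert model.converged
        assert abs(model.coefficients["x"] - 1.2) < 3 * model.std_errors["x"]
        assert abs(model.coefficients["const"] - 0.5) < 3 * model.std_errors["const"]

    def test_perfect_separation_is_flagged_not_silent(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
        y = x > 5
        with pytest.warns(UserWarning, match="separation"):
            model = fit_logistic(pd.DataFrame({"x": x}), y)
        assert model.separation

    def test_constant_column_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            fit_logistic(pd.DataFrame({"x": np.ones(10)}), np.arange(10) % 2 == 0)


class TestStepwiseSelection:
    @staticmethod
    def _categorized_candidates(rng, n, informative_shift):
        labels = np.arange(n) % 2 == 0
        cols = {"informative": rng.normal(0, 1, n) + informative_shift * labels}
        for k in range(5):
            cols[f"noise{k}"] = rng.normal(0, 1, n)
        cat = {}
        for name, v in cols.items():
            rule = optimal_threshold(v, labels, feature=name)
            cat[name] = rule.apply(v).astype(float)
        return pd.DataFrame(cat), labels

    def test_informative_feature_retained_across_seeds(self):
        kept = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(500 + s)
            cand, labels = self._categorized_candidates(rng, 200, 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = stepwise_selection(cand, labels)
            kept += "informative" in model.included
        assert kept >= 0.9 * n_seeds

    def test_all_noise_often_yields_empty_model(self):
        empties = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(900 + s)
            labels = np.arange(60) % 2 == 0
            cand = pd.DataFrame(
                {f"noise{k}": rng.normal(0, 1, 60) for k in range(4)}
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = stepwise_selection(cand, labels)
            empties += not model.included
        # continuous noise candidates: type-I near p_enter per test
        assert empties >= n_seeds / 2

    def test_duplicated_candidate_kept_only_once(self):
        rng = np.random.default_rng(12)
        labels = np.arange(100) % 2 == 0
        x = rng.normal(0, 1, 100) + 1.5 * labels
        rule = optimal_threshold(x, labels)
        cat = rule.apply(x).astype(float)
        cand = pd.DataFrame({"a": cat, "b": cat.copy()})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = stepwise_selection(cand, labels)
        assert len([c for c in model.included if c in ("a", "b")]) == 1

    def test_empty_candidate_frame_rejected(self):
        with pytest.raises(ValidationError):
            stepwise_selection(pd.DataFrame(), np.arange(4) % 2 == 0)


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman_correlation([1, 2, 3, 5], [2, 4, 9, 10]) == pytest.approx(1.0)
        assert spearman_correlation([1, 2, 3, 5], [10, 9, 4, 2]) == pytest.approx(-1.0)

    def test_tied_sample_matches_hand_ranked_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 5.0])
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_correlation(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_rank_variance_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(spearman_correlation([1, 1, 1], [2, 3, 4]))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            spearman_correlation([1, 2], [3, 4])
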