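import math

import numpy as np
import pytest

from vidability.corpus_io import VideoRecord
from vidability.engagement import (
    COVARIATE_NAMES,
    CausalUnit,
    balance,
    build_causal_units,
    estimate_ate,
    fit_propensity,
    match,
    naive_difference,
    units_from_frame,
    units_to_frame,
)
from vidability.synthetic import generate_causal_units


def _unit(vid, treatment, overrides=None, outcome=0.0):
    covariates = {name: 1.0 for name in COVARIATE_NAMES}
    covariates.update(overrides or {})
    outcomes = {"log_view_count": outcome, "log_like_count": outcome, "log_comment_count": outcome}
    return CausalUnit(vid, treatment, covariates, outcomes)


class TestBalance:
    def test_identical_groups_have_zero_smd(self):
        units = [_unit("t1", 1), _unit("t2", 1), _unit("c1", 0), _unit("c2", 0)]
        report = balance(units)
        assert (report.table["smd_before"] == 0).all()

    def test_hand_computed_smd(self):
        # treated {2,4}, control {1,3} on one covariate: (3-2)/sd([2,4]) = 1/sqrt(2)
        units = [
            _unit("t1", 1, {"duration_s": 2.0}),
            _unit("t2", 1, {"duration_s": 4.0}),
            _unit("c1", 0, {"duration_s": 1.0}),
            _unit("c2", 0, {"duration_s": 3.0}),
        ]
        smd = balance(units).table.loc["duration_s", "smd_before"]
        assert smd == pytest.approx(1 / math.sqrt(2))

    def test_control_shifted_by_treated_sd_gives_minus_one(self):
        sd = math.sqrt(2)
        units = [
            _unit("t1", 1, {"duration_s": 2.0}),
            _unit("t2", 1, {"duration_s": 4.0}),
            _unit("c1", 0, {"duration_s": 2.0 + sd}),
            _unit("c2", 0, {"duration_s": 4.0 + sd}),
        ]
        smd = balance(units).table.loc["duration_s", "smd_before"]
        assert smd == pytest.approx(-1.0)

    def test_zero_treated_sd_with_unequal_means_flagged_infinite(self):
        units = [
            _unit("t1", 1), _unit("t2", 1),
            _unit("c1", 0, {"duration_s": 5.0}), _unit("c2", 0, {"duration_s": 5.0}),
        ]
        with pytest.warns(UserWarning, match="infinite"):
            report = balance(units)
        assert math.isinf(report.table.loc["duration_s", "smd_before"])

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            balance([_unit("t1", 1), _unit("c1", 0)])


class TestPropensity:
    def test_constant_covariates_reduce_to_treated_fraction(self):
        units = [_unit(f"t{i}", 1) for i in range(3)] + [_unit(f"c{i}", 0) for i in range(7)]
        propensity = fit_propensity(units)
        assert all(p == pytest.approx(0.3) for p in propensity.values())

    def test_null_model_coefficients_near_zero(self):
        units = generate_causal_units(2000, tau=0.0, confounding=False, seed=11)
        _, model, names = fit_propensity(units, return_model=True)
        # coefficient 0 is the intercept; the rest are covariates
        for coef, se, name in zip(model.params[1:], model.bse[1:], names):
            assert abs(coef) < 3 * se, name

    def test_known_logistic_model_recovered(self):
        rng = np.random.default_rng(21)
        n = 5000
        beta = {"duration_s": 0.8, "log_published_days": -0.5}
        units = []
        for i in range(n):
            covariates = {name: float(rng.normal()) for name in COVARIATE_NAMES}
            covariates["content_definition_sd"] = float(rng.integers(0, 2))
            eta = sum(beta.get(name, 0.0) * covariates[name] for name in COVARIATE_NAMES)
            t = int(rng.uniform() < 1 / (1 + math.exp(-eta)))
            units.append(CausalUnit(f"u{i}", t, covariates, {"log_view_count": 0.0}))
        _, model, names = fit_propensity(units, return_model=True)
        for coef, se, name in zip(model.params[1:], model.bse[1:], names):
            assert abs(coef - beta.get(name, 0.0)) < 3 * se, name

    def test_perfect_separation_names_the_covariate(self):
        units = [
            _unit(f"t{i}", 1, {"duration_s": 10.0 + i}) for i in range(3)
        ] + [_unit(f"c{i}", 0, {"duration_s": 1.0 + i}) for i in range(3)]
        with pytest.raises(ValueError, match="duration_s"):
            fit_propensity(units)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            fit_propensity([_unit("t1", 1), _unit("t2", 1)])


class TestCEM:
    def test_identical_rows_all_retained_with_unit_weights(self):
        units = [_unit(f"t{i}", 1) for i in range(2)] + [_unit(f"c{i}", 0) for i in range(3)]
        matched = match(units, "CEM")
        assert all(w == pytest.approx(1.0) for w in matched.weights.values())

    def test_unique_stratum_is_dropped(self):
        units = [
            _unit("t1", 1), _unit("t2", 1, {"duration_s": 99.0}),
            _unit("c1", 0), _unit("c2", 0),
        ]
        matched = match(units, "CEM")
        assert matched.weights["t2"] == 0.0
        assert matched.weights["t1"] == 1.0

    def test_no_common_support_is_an_error(self):
        units = [_unit("t1", 1, {"duration_s": 99.0}), _unit("c1", 0)]
        with pytest.raises(ValueError, match="common support"):
            match(units, "CEM")

    def test_control_weights_conserve_group_totals(self):
        units = generate_causal_units(800, tau=1.0, confounding=True, seed=13)
        matched = match(units, "CEM")
        wt = sum(matched.weights[u.video_id] for u in units if u.treatment == 1)
        wc = sum(matched.weights[u.video_id] for u in units if u.treatment == 0)
        n_t = len(matched.retained(units, 1))
        n_c = len(matched.retained(units, 0))
        assert wt == pytest.approx(n_t)
        assert wc == pytest.approx(n_c)

    def test_matching_reduces_mean_absolute_smd(self):
        units = generate_causal_units(800, tau=1.0, confounding=True, seed=13)
        report = balance(units, match(units, "CEM"))
        assert report.mean_abs_smd("after") < report.mean_abs_smd("before")

    def test_within_stratum_signatures_balance_exactly(self):
        # after CEM, the weighted means of the binary covariate agree
        units = generate_causal_units(800, tau=1.0, confounding=True, seed=13)
        report = balance(units, match(units, "CEM"))
        assert abs(report.table.loc["content_definition_sd", "smd_after"]) < 1e-9


class TestPSM:
    def test_one_to_one_pairing_without_replacement(self):
        units = generate_causal_units(600, tau=1.0, confounding=True, seed=19)
        matched = match(units, "PSM")
        kept_t = matched.retained(units, 1)
        kept_c = matched.retained(units, 0)
        assert len(kept_t) == len(kept_c) == matched.params["pairs"]
        assert set(matched.weights.values()) <= {0.0, 1.0}

    def test_psm_improves_balance(self):
        units = generate_causal_units(600, tau=1.0, confounding=True, seed=19)
        report = balance(units, match(units, "PSM"))
        assert report.mean_abs_smd("after") < report.mean_abs_smd("before")


class TestATE:
    def test_constant_outcome_gives_exactly_zero(self):
        units = [_unit(f"t{i}", 1, outcome=3.5) for i in range(3)] + [
            _unit(f"c{i}", 0, outcome=3.5) for i in range(3)
        ]
        est = estimate_ate(units, match(units, "CEM"), "log_view_count")
        assert est.ate == pytest.approx(0.0, abs=1e-12)
        assert est.intercept == pytest.approx(3.5)

    def test_planted_effect_recovered_without_confounding(self):
        units = generate_causal_units(2000, tau=2.5, confounding=False, seed=17)
        est = estimate_ate(units, match(units, "CEM"), "log_view_count")
        assert abs(est.ate - 2.5) < 3 * est.se

    def test_matching_reduces_confounding_bias(self):
        units = generate_causal_units(2000, tau=2.5, confounding=True, seed=17)
        est = estimate_ate(units, match(units, "CEM"), "log_view_count")
        naive = naive_difference(units, "log_view_count")
        assert abs(est.ate - 2.5) < abs(naive - 2.5)

    def test_unknown_outcome_rejected(self):
        units = generate_causal_units(100, seed=1)
        with pytest.raises(ValueError, match="outcome"):
            estimate_ate(units, match(units, "CEM"), "views")


class TestUnitConstruction:
    def test_log_transforms_applied_as_named(self):
        record = VideoRecord(
            video_id="v", description="Three words here.",
            duration_s=60.0, published_days=9.0,
            view_count=99, like_count=0, comment_count=4,
            channel_view_count=999, channel_subscriber_count=49,
            channel_video_count=20, content_definition="SD",
        )
        (unit,) = build_causal_units([record], {"v": 1})
        assert unit.covariates["log_channel_view_count"] == pytest.approx(math.log(1000))
        assert unit.covariates["log_channel_video_count"] == pytest.approx(math.log(20))
        assert unit.covariates["log_published_days"] == pytest.approx(math.log(10))
        assert unit.covariates["content_definition_sd"] == 1.0
        assert unit.covariates["description_word_count"] == 3.0
        assert unit.outcomes["log_view_count"] == pytest.approx(math.log(100))
        assert unit.outcomes["log_like_count"] == 0.0

    def test_zero_video_channels_trigger_plus_one_fallback(self):
        records = [
            VideoRecord(video_id="a", channel_video_count=0),
            VideoRecord(video_id="b", channel_video_count=10),
        ]
        with pytest.warns(UserWarning, match="log"):
            units = build_causal_units(records, {"a": 0, "b": 1})
        assert units[0].covariates["log_channel_video_count"] == 0.0
        assert units[1].covariates["log_channel_video_count"] == pytest.approx(math.log(11))

    def test_frame_round_trip(self):
        units = generate_causal_units(25, seed=2)
        assert units_from_frame(units_to_frame(units)) == units
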