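"""Unit and property tests for the water-quality index engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wqrisk import (
    IRWQISC,
    NSFWQI,
    InputError,
    ParameterRegistry,
    RatingCurve,
    aggregate_scores,
    classify,
    irwqi,
    nsfwqi,
    rate_parameter,
    summarize_scores,
)
from wqrisk.errors import ConfigError
from wqrisk.wqi import ParameterSpec, WQIResult


# ---------------------------------------------------------------------------
# Oracles (kept deliberately naive and independent of the implementation)


def interp_oracle(value, breakpoints):
    """Segment-search linear interpolation with terminal clamping."""
    xs = [x for x, _ in breakpoints]
    qs = [q for _, q in breakpoints]
    if value <= xs[0]:
        return qs[0]
    if value >= xs[-1]:
        return qs[-1]
    for i in range(len(xs) - 1):
        if xs[i] <= value <= xs[i + 1]:
            frac = (value - xs[i]) / (xs[i + 1] - xs[i])
            return qs[i] + frac * (qs[i + 1] - qs[i])
    raise AssertionError("unreachable")


def weighted_sum_oracle(qs, ws):
    num = 0.0
    den = 0.0
    for q, w in zip(qs, ws):
        num += q * w
        den += w
    return num / den


def log_geometric_oracle(qs, ws):
    return math.exp(sum(w * math.log(q) for q, w in zip(qs, ws)) / sum(ws))


# ---------------------------------------------------------------------------
# rate_parameter


class TestRateParameter:
    def test_midpoint_of_linear_curve(self, linear_curve):
        assert rate_parameter(50.0, linear_curve) == pytest.approx(50.0)

    def test_clamped_beyond_domain(self, linear_curve):
        assert rate_parameter(250.0, linear_curve) == 0.0
        assert rate_parameter(-10.0, linear_curve) == 100.0

    def test_matches_bruteforce_interpolation_oracle(self, rng):
        xs = np.sort(rng.uniform(0, 50, size=5))
        xs += np.arange(5) * 1e-3  # ensure strictly increasing
        qs = rng.uniform(0, 100, size=5)
        curve = RatingCurve("r", tuple(zip(xs, qs)))
        for value in rng.uniform(-10, 60, size=100):
            assert rate_parameter(value, curve) == pytest.approx(
                interp_oracle(value, curve.breakpoints), abs=1e-9
            )

    def test_non_finite_value_rejected(self, linear_curve):
        with pytest.raises(InputError):
            rate_parameter(float("nan"), linear_curve)

    def test_curve_validation(self):
        with pytest.raises(ConfigError):
            RatingCurve("bad", ((0.0, 10.0),))
        with pytest.raises(ConfigError):
            RatingCurve("bad", ((0.0, 10.0), (0.0, 20.0)))
        with pytest.raises(ConfigError):
            RatingCurve("bad", ((0.0, 10.0), (1.0, 120.0)))


# ---------------------------------------------------------------------------
# nsfwqi / irwqi


class TestIndices:
    def test_nsf_identity_all_70(self, registry):
        subs = {p: 70.0 for p in registry.weights(NSFWQI)}
        assert nsfwqi(subs, registry) == pytest.approx(70.0)

    def test_nsf_single_parameter_renormalizes(self, registry):
        assert nsfwqi({"no3": 42.0}, registry) == pytest.approx(42.0)

    def test_nsf_matches_direct_summation_oracle(self, registry, rng):
        weights = registry.weights(NSFWQI)
        names = list(weights)
        qs = rng.uniform(0, 100, size=len(names))
        expected = weighted_sum_oracle(qs, [weights[n] for n in names])
        assert nsfwqi(dict(zip(names, qs)), registry) == pytest.approx(expected, abs=1e-12)

    def test_irwqi_identity_all_55(self, registry):
        subs = {p: 55.0 for p in registry.weights(IRWQISC)}
        assert irwqi(subs, registry) == pytest.approx(55.0)

    def test_irwqi_two_equal_weights_geometric_mean(self, toy_registry):
        assert irwqi({"a": 25.0, "b": 100.0}, toy_registry) == pytest.approx(50.0)

    def test_irwqi_matches_log_domain_oracle(self, registry, rng):
        weights = registry.weights(IRWQISC)
        names = list(weights)
        qs = rng.uniform(1, 100, size=len(names))
        expected = log_geometric_oracle(qs, [weights[n] for n in names])
        assert irwqi(dict(zip(names, qs)), registry) == pytest.approx(expected, abs=1e-9)

    def test_empty_and_out_of_range_errors(self, registry):
        with pytest.raises(InputError):
            nsfwqi({}, registry)
        with pytest.raises(InputError):
            irwqi({}, registry)
        with pytest.raises(InputError):
            nsfwqi({"no3": 120.0}, registry)
        with pytest.raises(InputError):
            irwqi({"no3": 0.0}, registry)

    def test_registry_weight_sums(self, registry):
        assert sum(registry.weights(NSFWQI).values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(registry.weights(IRWQISC).values()) == pytest.approx(1.0, abs=1e-9)
        assert len(registry.weights(NSFWQI)) == 9
        assert len(registry.weights(IRWQISC)) == 11


# ---------------------------------------------------------------------------
# Hypothesis properties

positive_weights = st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8)


def _registry_from_weights(ws):
    return ParameterRegistry(
        parameters={
            f"p{i}": ParameterSpec(f"p{i}", nsf_weight=min(w, 1.0), irwqi_weight=min(w, 1.0))
            for i, w in enumerate(ws)
        }
    )


@settings(max_examples=50, deadline=None)
@given(ws=positive_weights, q=st.floats(1.0, 100.0))
def test_identity_property(ws, q):
    reg = _registry_from_weights(ws)
    subs = {f"p{i}": q for i in range(len(ws))}
    assert nsfwqi(subs, reg) == pytest.approx(q, abs=1e-9)
    assert irwqi(subs, reg) == pytest.approx(q, abs=1e-9)


@settings(max_examples=50, deadline=None)
@given(
    ws=positive_weights,
    data=st.data(),
)
def test_am_gm_and_range_property(ws, data):
    reg = _registry_from_weights(ws)
    qs = data.draw(st.lists(st.floats(1.0, 100.0), min_size=len(ws), max_size=len(ws)))
    subs = {f"p{i}": q for i, q in enumerate(qs)}
    a = nsfwqi(subs, reg)
    g = irwqi(subs, reg)
    assert g <= a + 1e-9
    assert min(qs) - 1e-9 <= g <= max(qs) + 1e-9
    assert min(qs) - 1e-9 <= a <= max(qs) + 1e-9


@settings(max_examples=50, deadline=None)
@given(ws=positive_weights, data=st.data(), bump=st.floats(0.1, 20.0))
def test_monotonicity_property(ws, data, bump):
    reg = _registry_from_weights(ws)
    qs = data.draw(st.lists(st.floats(1.0, 79.0), min_size=len(ws), max_size=len(ws)))
    idx = data.draw(st.integers(0, len(ws) - 1))
    subs = {f"p{i}": q for i, q in enumerate(qs)}
    bumped = dict(subs)
    bumped[f"p{idx}"] = min(qs[idx] + bump, 100.0)
    assert nsfwqi(bumped, reg) >= nsfwqi(subs, reg) - 1e-9
    assert irwqi(bumped, reg) >= irwqi(subs, reg) - 1e-9


# ---------------------------------------------------------------------------
# classify


class TestClassify:
    @pytest.mark.parametrize(
        "score,scheme,label",
        [
            (49.32, NSFWQI, "Bad"),
            (19.27, IRWQISC, "Bad"),
            (70.0, NSFWQI, "Medium"),
            (70.05, NSFWQI, "Good"),
            (25.0, NSFWQI, "Very bad"),
            (25.01, NSFWQI, "Bad"),
            (90.0, NSFWQI, "Good"),
            (100.0, NSFWQI, "Excellent"),
            (0.0, NSFWQI, "Very bad"),
            (14.99, IRWQISC, "Very bad"),
            (15.0, IRWQISC, "Bad"),
            (29.99, IRWQISC, "Bad"),
            (30.0, IRWQISC, "Relatively bad"),
            (44.99, IRWQISC, "Relatively bad"),
            (45.0, IRWQISC, "Medium"),
            (55.05, IRWQISC, "Medium"),
            (55.1, IRWQISC, "Relatively good"),
            (70.0, IRWQISC, "Relatively good"),
            (85.0, IRWQISC, "Good"),
            (85.01, IRWQISC, "Very good"),
            (100.0, IRWQISC, "Very good"),
        ],
    )
    def test_bands(self, score, scheme, label):
        assert classify(score, scheme) == label

    def test_out_of_range(self):
        for bad in (-0.1, 100.1, float("nan")):
            with pytest.raises(InputError):
                classify(bad, NSFWQI)

    def test_total_over_uniform_scores(self, rng):
        nsf_labels = {"Very bad", "Bad", "Medium", "Good", "Excellent"}
        ir_labels = {"Very bad", "Bad", "Relatively bad", "Medium",
                     "Relatively good", "Good", "Very good"}
        for score in rng.uniform(0, 100, size=10_000):
            assert classify(score, NSFWQI) in nsf_labels
            assert classify(score, IRWQISC) in ir_labels

    def test_scheme_aliases(self):
        assert classify(60.0, "nsf") == classify(60.0, "NSFWQI")
        assert classify(60.0, "irwqi") == classify(60.0, "IRWQISC")
        with pytest.raises(ConfigError):
            classify(60.0, "wqi9000")


# ---------------------------------------------------------------------------
# aggregate_scores


def _results(scheme, station_scores):
    out = []
    for station, scores in station_scores.items():
        for i, s in enumerate(scores):
            out.append(
                WQIResult(scheme=scheme, station_id=station, period=f"p{i}",
                          score=s, label=classify(s, scheme), subindices={},
                          used_weight_sum=1.0)
            )
    return out


class TestAggregate:
    def test_station1_nsf_annual_mean(self):
        # mean of printed seasonal scores: 166.15/4 = 41.5375 -> 41.5
        res = _results(NSFWQI, {"1": [49.32, 43.05, 29.4, 44.38]})
        table = aggregate_scores(res, by="station")
        assert table.loc[0, "mean_score"] == 41.5
        assert table.loc[0, "label"] == "Bad"

    def test_station4_irwqi_annual_mean(self):
        # 82.62/4 = 20.655 -> half-away-from-zero -> 20.7
        res = _results(IRWQISC, {"4": [21.92, 19.27, 20.9, 20.53]})
        table = aggregate_scores(res, by="station")
        assert table.loc[0, "mean_score"] == 20.7
        assert table.loc[0, "label"] == "Bad"

    def test_single_result_identity(self):
        res = _results(NSFWQI, {"1": [33.3]})
        table = aggregate_scores(res, by="station")
        assert table.loc[0, "mean_score"] == 33.3

    def test_label_from_unrounded_mean(self):
        # mean 25.025 rounds to 25.0 but the unrounded mean is already "Bad"
        res = _results(NSFWQI, {"1": [25.0, 25.05]})
        table = aggregate_scores(res, by="station")
        assert table.loc[0, "mean_score"] == 25.0
        assert table.loc[0, "label"] == "Bad"

    def test_mixed_schemes_rejected(self):
        res = _results(NSFWQI, {"1": [40.0]}) + _results(IRWQISC, {"1": [40.0]})
        with pytest.raises(InputError):
            aggregate_scores(res, by="station")

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            aggregate_scores([], by="station")
        with pytest.raises(InputError):
            summarize_scores([], NSFWQI)

    def test_by_period(self):
        res = _results(NSFWQI, {"1": [40.0, 50.0], "2": [60.0, 70.0]})
        table = aggregate_scores(res, by="period")
        # periods p0: (40, 60) -> 50.0; p1: (50, 70) -> 60.0
        assert list(table["mean_score"]) == [50.0, 60.0]
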