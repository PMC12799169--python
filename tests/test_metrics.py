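"""Convergence measures and decision-strategy classification."""

import numpy as np
import pandas as pd
import pytest

from netcoord import (
    STRATEGY_LABELS,
    TOY_STRATEGY_LABELS,
    classify_decision,
    convergence_series,
    coordination_rate_by_response,
    dominant_proportion,
    partner_context_entropy,
    response_entropy,
    strategy_time_series,
)
from netcoord.metrics import metrics_table, modal_response

from oracles import (
    naive_classify,
    naive_coordination_rates,
    naive_dominant_proportion,
    naive_entropy,
    naive_partner_entropy,
)


def _mini_transcript(responses_by_trial, pairs=((0, 1), (2, 3))):
    """Tidy transcript from {trial: {agent: response}} with fixed pairs."""
    rows = []
    partner = {}
    for i, j in pairs:
        partner[i], partner[j] = j, i
    points = dict.fromkeys(partner, 0)
    for trial in sorted(responses_by_trial):
        resp = responses_by_trial[trial]
        for agent in sorted(resp):
            j = partner[agent]
            matched = resp[agent].casefold() == resp[j].casefold()
            points[agent] += matched
            rows.append({
                "run_id": "mini", "trial": trial, "agent": agent, "partner": j,
                "response": resp[agent], "partner_response": resp[j],
                "matched": matched, "points": points[agent],
            })
    return pd.DataFrame(rows)


class TestDominantProportion:
    def test_examples(self):
        df = _mini_transcript({1: {0: "A", 1: "A", 2: "B", 3: "C"}})
        assert dominant_proportion(df, 1) == pytest.approx(0.5)
        df2 = _mini_transcript({1: {0: "A", 1: "A", 2: "B", 3: "B"}})
        assert dominant_proportion(df2, 1) == pytest.approx(0.5)  # tie case
        df3 = _mini_transcript({1: {0: "X", 1: "X", 2: "X", 3: "X"}})
        assert dominant_proportion(df3, 1) == 1.0

    def test_mode_merging_is_nondecreasing(self):
        # merging two response classes cannot lower the modal share
        df = _mini_transcript({1: {0: "A", 1: "B", 2: "B", 3: "C"}})
        merged = df.replace({"response": {"A": "B"}, "partner_response": {"A": "B"}})
        assert dominant_proportion(merged, 1) >= dominant_proportion(df, 1)

    def test_modal_response_tie_breaks_lexicographically(self):
        df = _mini_transcript({1: {0: "b", 1: "b", 2: "a", 3: "a"}})
        assert modal_response(df, 1) == "a"

    def test_unknown_trial_raises(self, toy_transcript):
        with pytest.raises(KeyError):
            dominant_proportion(toy_transcript, 99)


class TestResponseEntropy:
    def test_degenerate_and_maximal(self):
        same = _mini_transcript({1: {0: "A", 1: "A", 2: "A", 3: "A"}})
        assert response_entropy(same, 1) == 0.0
        distinct = _mini_transcript({1: {0: "A", 1: "B", 2: "C", 3: "D"}})
        assert response_entropy(distinct, 1, normalized=True) == pytest.approx(1.0)

    def test_two_two_split_is_one_bit(self):
        df = _mini_transcript({1: {0: "A", 1: "A", 2: "B", 3: "B"}})
        assert response_entropy(df, 1) == pytest.approx(1.0)

    def test_canonicalization_merges_variants(self):
        df = _mini_transcript({1: {0: "#Fire", 1: "fire", 2: "FIRE", 3: "#fire"}})
        assert response_entropy(df, 1) == 0.0


class TestClassifyDecision:
    def test_toy_transcript_matches_hand_labels(self, toy_transcript):
        for (agent, trial), expected in TOY_STRATEGY_LABELS.items():
            assert classify_decision(toy_transcript, agent, trial) == expected, (
                f"agent {agent}, trial {trial}"
            )

    def test_agreement_tie_codes_repeat_self(self):
        df = _mini_transcript({
            1: {0: "A", 1: "A", 2: "x", 3: "y"},
            2: {0: "A", 1: "A", 2: "x", 3: "y"},
        })
        assert classify_decision(df, 0, 2) == "repeat_self"

    def test_earlier_context_from_received_response(self):
        # own [X, Y], received [Z, Y]; "Z" at t=3 came from trial-1 context
        df = _mini_transcript({
            1: {0: "X", 1: "Z", 2: "p", 3: "q"},
            2: {0: "Y", 1: "Y", 2: "p", 3: "q"},
            3: {0: "Z", 1: "w", 2: "p", 3: "q"},
        })
        assert classify_decision(df, 0, 3) == "earlier_context"

    def test_unseen_token_is_new(self, toy_transcript):
        assert classify_decision(toy_transcript, 0, 5) == "new"

    def test_missing_history_raises(self, toy_transcript):
        truncated = toy_transcript.records[toy_transcript.records["trial"] != 2]
        with pytest.raises(ValueError):
            classify_decision(truncated, 0, 4)


class TestStrategyTimeSeries:
    def test_trial_one_is_all_new(self, small_name_game_transcript):
        series = strategy_time_series(small_name_game_transcript)
        assert series.loc[1, "new"] == 1.0

    def test_proportions_partition_every_trial(self, small_caa_transcript):
        series = strategy_time_series(small_caa_transcript)
        np.testing.assert_allclose(series.sum(axis=1).to_numpy(), 1.0, atol=1e-12)
        assert list(series.columns) == list(STRATEGY_LABELS)

    def test_matches_per_row_classifier(self, toy_transcript):
        series = strategy_time_series(toy_transcript)
        for trial in range(1, 7):
            counts = dict.fromkeys(STRATEGY_LABELS, 0)
            for agent in range(4):
                counts[classify_decision(toy_transcript, agent, trial)] += 1
            for label in STRATEGY_LABELS:
                assert series.loc[trial, label] == pytest.approx(counts[label] / 4)


class TestCoordinationRates:
    def test_rate_arithmetic(self):
        df = _mini_transcript({
            1: {0: "A", 1: "A", 2: "A", 3: "B"},
            2: {0: "A", 1: "B", 2: "B", 3: "B"},
        })
        rates = coordination_rate_by_response(df)
        # token "a": produced 4 times (3 at t1, 1 at t2), matched twice at t1
        assert rates.loc["a", "count"] == 4
        assert rates.loc["a", "rate"] == pytest.approx(0.5)

    def test_never_matched_token_has_zero_rate(self, toy_transcript):
        rates = coordination_rate_by_response(toy_transcript)
        assert rates.loc["e", "rate"] == 0.0


class TestPartnerContextEntropy:
    def test_constant_context_is_zero(self):
        df = _mini_transcript({
            1: {0: "x", 1: "S", 2: "p", 3: "q"},
            2: {0: "y", 1: "S", 2: "p", 3: "q"},
        })
        assert partner_context_entropy(df, 0) == 0.0

    def test_balanced_context_is_one_bit(self):
        df = _mini_transcript({
            1: {0: "x", 1: "A", 2: "p", 3: "q"},
            2: {0: "y", 1: "B", 2: "p", 3: "q"},
        })
        assert partner_context_entropy(df, 0) == pytest.approx(1.0)

    def test_invariant_to_trial_order(self, small_caa_transcript):
        df = small_caa_transcript.records
        shuffled = df.sample(frac=1, random_state=0)
        assert partner_context_entropy(df, 3) == pytest.approx(
            partner_context_entropy(shuffled, 3)
        )


class TestOracleEquivalence:
    """All metrics agree exactly with naive row-wise recomputation."""

    @pytest.mark.parametrize("fixture", ["toy_transcript",
                                         "small_name_game_transcript",
                                         "small_caa_transcript"])
    def test_all_metrics_match_naive_scans(self, fixture, request):
        transcript = request.getfixturevalue(fixture)
        df = transcript.records
        assert len(df) <= 200
        trials = sorted(df["trial"].unique())
        agents = sorted(df["agent"].unique())
        for trial in trials:
            assert dominant_proportion(df, trial) == pytest.approx(
                naive_dominant_proportion(df, trial), abs=1e-12
            )
            for norm in (False, True):
                assert response_entropy(df, trial, norm) == pytest.approx(
                    naive_entropy(df, trial, norm), abs=1e-12
                )
            for agent in agents:
                assert classify_decision(df, agent, trial) == naive_classify(
                    df, agent, trial
                )
        rates = coordination_rate_by_response(df)
        expected = naive_coordination_rates(df)
        assert set(rates.index) == set(expected)
        for token, (rate, count) in expected.items():
            assert rates.loc[token, "rate"] == pytest.approx(rate, abs=1e-12)
            assert rates.loc[token, "count"] == count
        for agent in agents:
            assert partner_context_entropy(df, agent) == pytest.approx(
                naive_partner_entropy(df, agent), abs=1e-12
            )


class TestExports:
    def test_convergence_series_shape_and_bounds(self, small_caa_transcript):
        conv = convergence_series(small_caa_transcript)
        assert list(conv.index) == list(range(1, 26))
        assert ((conv["normalized_entropy"] >= 0)
                & (conv["normalized_entropy"] <= 1)).all()
        assert (conv["dominant_proportion"] >= 1 / 8).all()

    def test_metrics_table_is_tidy_long(self, toy_transcript):
        table = metrics_table(toy_transcript)
        assert set(table.columns) == {"run_id", "trial", "measure", "value"}
        assert set(STRATEGY_LABELS) <= set(table["measure"])
        assert (table["run_id"] == "toy").all()
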