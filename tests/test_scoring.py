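"""Instrument scoring, screening, exclusion flow and transition rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clpnet import (
    PanelDataset,
    apply_exclusions,
    cape_weighted_score,
    classify_ples,
    cronbach_alpha,
    default_instrument_specs,
    score_factors,
    transition_rates,
)
from clpnet import nodes as nd


def cape_frame(values):
    return pd.DataFrame([values], columns=nd.CAPE_ITEMS)


class TestCapeWeightedScore:
    @pytest.mark.parametrize(
        "items,expected",
        [
            ([1] * 15, 1.0),
            ([4] * 15, 4.0),
            ([2] * 14 + [np.nan], 2.0),  # 14 valid items summing 28
        ],
    )
    def test_weighted_score_is_mean_of_valid_items(self, items, expected):
        got = cape_weighted_score(cape_frame(items))
        assert got.iloc[0] == pytest.approx(expected)

    def test_all_missing_yields_missing_score(self):
        got = cape_weighted_score(cape_frame([np.nan] * 15))
        assert np.isnan(got.iloc[0])

    def test_series_input(self):
        s = pd.Series([1, 2, 3], index=nd.CAPE_ITEMS[:3])
        assert cape_weighted_score(s) == pytest.approx(2.0)


class TestClassifyPles:
    @pytest.mark.parametrize(
        "score,expected",
        [(1.57, True), (1.00, False), (4.00, True)],
    )
    def test_cutoff_boundary_inclusive(self, score, expected):
        assert classify_ples(score) is expected

    def test_exclusive_mode_flips_boundary(self):
        assert classify_ples(1.57, inclusive=False) is False

    def test_missing_score_is_missing_class(self):
        assert classify_ples(float("nan")) is None
        out = classify_ples(pd.Series([1.0, np.nan, 2.0]))
        assert out.isna().tolist() == [False, True, False]

    @given(
        lo=st.floats(1.0, 4.0), hi=st.floats(1.0, 4.0)
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_score(self, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        assert classify_ples(lo) <= classify_ples(hi)


class TestScoreFactors:
    def test_factor_means(self):
        spec = default_instrument_specs()["aslec"]
        row = {c: 1.0 for c in nd.ASLEC_ITEMS}
        for c, v in zip(nd.ASLEC_FACTORS["A2"], (2, 2, 2)):
            row[c] = v
        for c, v in zip(nd.ASLEC_FACTORS["A4"], (1, 2, 3, 4, 5)):
            row[c] = v
        out = score_factors(pd.DataFrame([row]), spec)
        assert out.loc[0, "A2"] == pytest.approx(2.0)
        assert out.loc[0, "A4"] == pytest.approx(3.0)

    def test_mean_over_valid_items_when_one_missing(self):
        spec = default_instrument_specs()["cape"]
        row = {c: 4.0 for c in nd.CAPE_ITEMS}
        row[nd.CAPE_FACTORS["BEs"][0]] = np.nan  # 6 of 7 valid (>= 80%)
        out = score_factors(pd.DataFrame([row]), spec)
        assert out.loc[0, "BEs"] == pytest.approx(4.0)

    def test_below_completeness_is_missing(self):
        spec = default_instrument_specs()["cape"]
        row = {c: 2.0 for c in nd.CAPE_ITEMS}
        for c in nd.CAPE_FACTORS["PAs"][:2]:  # 1 of 3 valid (< 80%)
            row[c] = np.nan
        out = score_factors(pd.DataFrame([row]), spec)
        assert np.isnan(out.loc[0, "PAs"])

    def test_unknown_items_rejected(self):
        spec = default_instrument_specs()["cape"]
        with pytest.raises(ValueError, match="absent"):
            score_factors(pd.DataFrame({"cape_01": [1.0]}), spec)

    def test_permutation_invariant_over_items(self):
        spec = default_instrument_specs()["aslec"]
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.integers(1, 6, size=(20, 27)), columns=nd.ASLEC_ITEMS
        ).astype(float)
        shuffled = df[list(rng.permutation(df.columns))]
        pd.testing.assert_frame_equal(
            score_factors(df, spec), score_factors(shuffled, spec)
        )


class TestCronbachAlpha:
    def test_parallel_duplicates_give_one(self):
        x = pd.Series([1.0, 2, 3, 4, 2, 3])
        items = pd.DataFrame({f"i{k}": x for k in range(4)})
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(0)
        items = pd.DataFrame(rng.standard_normal((10000, 5)))
        assert abs(cronbach_alpha(items)) < 0.05

    def test_matches_spreadsheet_style_oracle(self):
        data = np.array(
            [[1, 2, 3], [2, 3, 3], [3, 4, 4], [4, 4, 5]], dtype=float
        )
        # independent brute-force computation from variance definitions
        k = data.shape[1]
        item_vars = sum(np.var(data[:, j], ddof=1) for j in range(k))
        total_var = np.var(data.sum(axis=1), ddof=1)
        expected = k / (k - 1) * (1 - item_vars / total_var)
        assert cronbach_alpha(pd.DataFrame(data)) == pytest.approx(expected)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 items"):
            cronbach_alpha(pd.DataFrame({"a": [1.0, 2, 3]}))
        const = pd.DataFrame({"a": [1.0, 1, 1], "b": [2.0, 2, 2]})
        with pytest.raises(ValueError, match="zero variance"):
            cronbach_alpha(const)


def _toy_records(n=6):
    base = pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(n)] * 2,
            "wave": [1] * n + [2] * n,
            "timestamp": pd.date_range("2021-10-01", periods=2 * n, freq="min"),
            "response_time_seconds": 900.0,
            "psychotic_history": 0,
            "refused_interview": 0,
        }
    )
    return base


class TestApplyExclusions:
    def test_clean_dataset_unchanged(self):
        data = PanelDataset(_toy_records())
        out, flow = apply_exclusions(data)
        assert out.n_records == data.n_records
        assert flow.duplicates_removed == 0
        assert flow.speeders_removed == 0
        assert flow.psychotic_history_removed == 0
        assert flow.refusals_removed == 0
        assert flow.valid_baseline == flow.analyzed == 6

    def test_duplicate_keeps_earliest_record(self):
        rec = _toy_records()
        dup = rec.iloc[[0]].copy()
        dup["timestamp"] = dup["timestamp"] + pd.Timedelta(days=2)
        dup["response_time_seconds"] = 111.0  # marker on the later copy
        data = PanelDataset(pd.concat([rec, dup], ignore_index=True))
        out, flow = apply_exclusions(data)
        assert flow.duplicates_removed == 1
        kept = out.records.query("id == 'P0' and wave == 1")
        assert kept["response_time_seconds"].iloc[0] == 900.0

    def test_cascade_counts_and_conservation(self):
        rec = _toy_records(8)
        rec.loc[0, "response_time_seconds"] = 120.0  # baseline speeder
        rec.loc[rec["id"] == "P1", "psychotic_history"] = 1
        rec.loc[rec["id"] == "P2", "refused_interview"] = 1
        out, flow = apply_exclusions(PanelDataset(rec))
        assert flow.baseline_collected == 8
        assert (flow.speeders_removed, flow.psychotic_history_removed,
                flow.refusals_removed) == (1, 1, 1)
        assert flow.valid_baseline == 8 - 3
        steps = (flow.duplicates_removed + flow.speeders_removed
                 + flow.psychotic_history_removed + flow.refusals_removed)
        assert flow.baseline_collected - steps == flow.valid_baseline

    def test_idempotent(self):
        rec = _toy_records(8)
        rec.loc[0, "response_time_seconds"] = 120.0
        once, _ = apply_exclusions(PanelDataset(rec))
        twice, flow2 = apply_exclusions(once)
        pd.testing.assert_frame_equal(
            once.records.reset_index(drop=True),
            twice.records.reset_index(drop=True),
        )
        assert flow2.speeders_removed == 0

    def test_missing_metadata_column_named(self):
        rec = _toy_records().drop(columns=["response_time_seconds"])
        with pytest.raises(ValueError, match="response_time_seconds"):
            apply_exclusions(PanelDataset(rec))

    def test_matches_injected_artifact_ledger(self, small_cohort):
        from clpnet import SimulationConfig, generate_cohort

        cfg = SimulationConfig(
            n_participants=500, seed=21, duplicate_rate=0.02,
            speeder_rate=0.01, psychotic_history_rate=0.01, refusal_rate=0.01,
        )
        data, _ = generate_cohort(cfg)
        _, flow = apply_exclusions(data)
        led = data.artifact_ledger
        assert flow.duplicates_removed == led["duplicates"]
        assert flow.speeders_removed == led["speeders"]
        assert flow.psychotic_history_removed == led["psychotic_history"]
        assert flow.refusals_removed == led["refusals"]


class TestTransitionRates:
    def test_printed_cohort_arithmetic(self):
        base = pd.Series([True] * 455 + [False] * 2903)
        w2 = pd.Series(
            [True] * 104 + [False] * (455 - 104)
            + [True] * 137 + [False] * (2903 - 137)
        )
        tr = transition_rates(base, w2)
        assert round(100 * tr.persistence, 1) == 22.9
        assert round(100 * tr.incidence, 1) == 4.7

    def test_all_negative_cohort(self):
        base = pd.Series([False] * 10)
        w2 = pd.Series([False] * 10)
        tr = transition_rates(base, w2)
        assert np.isnan(tr.persistence)
        assert tr.incidence == 0.0

    def test_missing_classifications_dropped(self):
        base = pd.Series([True, None, False], dtype="boolean")
        w2 = pd.Series([True, True, False], dtype="boolean")
        tr = transition_rates(base, w2)
        assert tr.baseline_positive == 1 and tr.baseline_negative == 1
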