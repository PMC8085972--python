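"""Orchestration layer: fixture tables, strata, group comparisons, full runs."""

import numpy as np
import pandas as pd
import pytest

from ihcrisk import (
    EmptyStudyError,
    SimParams,
    StudyConfig,
    compare_expression_groups,
    correlate_markers,
    descriptive_table,
    is_aggressive,
    load_table1_fixture,
    run_full_analysis,
)
from ihcrisk.analysis_pipeline import (
    SAMPLE_FLOW,
    ConfoundingError,
    case_stratum,
    control_quartile_cuts,
    fit_model_table,
    output_checksum,
    polynomial_model_search,
    stratified_models,
)
from ihcrisk.study_design import MatchedPair


class TestTable1Fixture:
    def test_loads_and_validates(self):
        fx = load_table1_fixture()
        assert fx.n_pairs == 503
        assert fx.gleason_missing == 21

    def test_descriptive_percentages(self):
        table = descriptive_table(load_table1_fixture())
        stage2 = table[(table.variable == "tumor_stage") & (table.response == "2")]
        assert stage2.percent.iloc[0] == pytest.approx(23.5)
        stage1 = table[(table.variable == "tumor_stage") & (table.response == "1")]
        assert stage1.percent.iloc[0] == pytest.approx(74.4)  # 100*374/503 half-up
        none_controls = table[
            (table.variable == "inflammation")
            & (table.response == "none")
            & (table.arm == "controls")
        ]
        assert none_controls.percent.iloc[0] == pytest.approx(39.2)

    def test_sample_flow_consistency(self):
        flow = SAMPLE_FLOW
        assert flow["potentially_eligible_cases"] - flow["matched_pairs"] == 52
        assert sum(flow["unmatched_reasons"].values()) == flow["unmatched_cases"]
        assert flow["stained_pairs"] - flow["removed_incomplete"] == flow["analytic_pairs"]


class TestStrata:
    def test_aggressive_rule(self, member_factory):
        by_gleason = member_factory(is_case=True, gleason_group=3.0, psa=5.0, tumor_stage=1.0)
        by_psa = member_factory(is_case=True, gleason_group=1.0, psa=20.0, tumor_stage=1.0)
        by_stage = member_factory(is_case=True, gleason_group=1.0, psa=5.0, tumor_stage=3.0)
        mild = member_factory(is_case=True, gleason_group=2.0, psa=5.0, tumor_stage=2.0)
        missing = member_factory(is_case=True, psa=5.0, tumor_stage=1.0)
        assert is_aggressive(by_gleason) and is_aggressive(by_psa) and is_aggressive(by_stage)
        assert not is_aggressive(mild)
        assert not is_aggressive(missing)

    def test_age_and_time_boundaries(self, member_factory):
        case65 = member_factory(is_case=True, age_at_entry=65.0, event_time=5.0)
        control = member_factory(id=9)
        pair = MatchedPair(case=case65, control=control, index_time=3.7)
        assert case_stratum(pair, "age") == "old"
        assert case_stratum(pair, "time") == "late"
        young = member_factory(is_case=True, age_at_entry=64.9, event_time=3.69)
        pair2 = MatchedPair(case=young, control=control, index_time=3.69)
        assert case_stratum(pair2, "age") == "young"
        assert case_stratum(pair2, "time") == "early"

    def test_strata_partition_pairs(self, matched_sample):
        # no pair lost or double-counted across strata
        pairs, _ = matched_sample
        for rule in ("aggressive", "age", "time"):
            labels = [case_stratum(p, rule) for p in pairs]
            assert len(labels) == len(pairs)
            assert sum(labels.count(s) for s in set(labels)) == len(pairs)
            assert len(set(labels)) == 2

    def test_small_stratum_skipped(self, matched_sample):
        pairs, _ = matched_sample
        cuts = control_quartile_cuts(pairs)
        tables = stratified_models(pairs, "age", cuts, min_pairs=10**6)
        assert tables == {}


class TestModelBattery:
    def test_tables_have_expected_rows(self, matched_sample):
        pairs, _ = matched_sample
        cuts = control_quartile_cuts(pairs)
        for adjusted in (False, True):
            table = fit_model_table(pairs, cuts, adjusted=adjusted)
            # continuous + 3 quartile rows + trend, per marker
            assert len(table) == 10
            assert set(table.model).issuperset({"nfkb_continuous", "gdf15_trend"})
            assert np.all(table.lo <= table["or"]) and np.all(table["or"] <= table.hi)

    def test_polynomial_search_loglik_monotone(self, matched_sample):
        pairs, _ = matched_sample
        cuts = control_quartile_cuts(pairs)
        table = polynomial_model_search(pairs, "gdf15", cuts, alpha=1.1)  # force full path
        assert len(table) == 3
        assert table.loglik.is_monotonic_increasing
        assert table.selected.sum() == 1


class TestGroupComparison:
    def frame(self, rng, shift=0.0, n=400):
        group = np.repeat(["AA", "White"], n // 2)
        batch = np.tile(np.arange(4), n // 4)
        platform = rng.integers(0, 2, n)
        batch_effect = 0.3 * (batch == 2)
        y = rng.normal(0, 1, n) + shift * (group == "White") + batch_effect
        return pd.DataFrame(
            {"race": group, "batch": batch, "platform": platform, "expr": y}
        )

    def test_injected_shift_recovered(self, rng):
        df = self.frame(rng, shift=0.42)
        cmp = compare_expression_groups(df, "expr", "race")
        assert abs(cmp.difference - 0.42) < 3 * cmp.se
        assert cmp.adjusted_means["White"] - cmp.adjusted_means["AA"] == pytest.approx(
            cmp.difference
        )

    def test_balanced_batches_match_raw_difference(self, rng):
        # with batch and platform composition exactly balanced across
        # groups, adjustment is orthogonal to the group contrast
        n = 400
        idx = np.arange(n)
        df = pd.DataFrame(
            {
                "race": np.repeat(["AA", "White"], n // 2),
                "batch": idx % 4,
                "platform": (idx // 4) % 2,
                "expr": rng.normal(0, 1, n) + 0.5 * (idx >= n // 2),
            }
        )
        cmp = compare_expression_groups(df, "expr", "race")
        raw = df.loc[df.race == "White", "expr"].mean() - df.loc[df.race == "AA", "expr"].mean()
        assert cmp.difference == pytest.approx(raw, abs=1e-6)

    def test_perfect_confounding_rejected(self, rng):
        df = self.frame(rng)
        df["batch"] = (df.race == "White").astype(int)  # batch == group
        with pytest.raises(ConfoundingError):
            compare_expression_groups(df, "expr", "race")


class TestCorrelateMarkers:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate_markers(x, x)[0] == pytest.approx(1.0)
        assert correlate_markers(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed(self):
        r, _ = correlate_markers([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            correlate_markers([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlate_markers([1.0, 2.0], [1.0, 2.0])


class TestRunFullAnalysis:
    def config(self, tmp_path, name, n=4000):
        return StudyConfig(
            sim_params=SimParams(n=n, seed=17),
            match_seed=18,
            phantom_subjects=2,
            out_dir=str(tmp_path / name),
        )

    def test_rerun_byte_identical(self, tmp_path):
        res1 = run_full_analysis(self.config(tmp_path, "run1"))
        res2 = run_full_analysis(self.config(tmp_path, "run2"))
        assert len(res1.pairs) == len(res2.pairs)
        assert output_checksum(tmp_path / "run1") == output_checksum(tmp_path / "run2")

    def test_outputs_written(self, tmp_path):
        run_full_analysis(self.config(tmp_path, "out"))
        out = tmp_path / "out"
        for f in ("pairs.csv", "descriptive.csv", "report.json", "models/adjusted.csv"):
            assert (out / f).exists()

    def test_zero_cases_raises_structured_error(self, tmp_path):
        cfg = StudyConfig(
            sim_params=SimParams(n=50, baseline_hazard=1e-9, seed=3), match_seed=4
        )
        with pytest.raises(EmptyStudyError):
            run_full_analysis(cfg)

    def test_phantom_roundtrip_close(self, tmp_path):
        res = run_full_analysis(self.config(tmp_path, "ph"))
        df = res.phantom_roundtrip
        assert np.allclose(df.nfkb_true, df.nfkb_quantified, atol=0.05)
        assert np.allclose(df.gdf15_true, df.gdf15_quantified, atol=0.08)
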