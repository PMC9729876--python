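"""Readout, winner-take-all calls, cohort metrics and trait binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirdsd import (
    BiomarkerPanel,
    NodeBinning,
    bin_lymph_nodes,
    call_sample,
    classify_cohort,
    classify_trait_cohort,
    compile_diagnostic_circuit,
    read_out,
    simulate_ode,
    summarize_calls,
)
from mirdsd.cohort import inv_log2p1


def _cohort_from_fpkm(matrix, groups, gene_ids, lymph=None, indicator=None):
    cols = [f"s{i}" for i in range(matrix.shape[1])]
    expr = pd.DataFrame(matrix, index=gene_ids, columns=cols)
    expr.index.name = "gene_id"
    clin = pd.DataFrame(
        {"sample_id": cols, "group": groups,
         "lymph_node_count": lymph if lymph is not None else 0,
         "tissue_indicator": indicator if indicator is not None else 0}
    )
    return expr, clin


PANEL = BiomarkerPanel(
    positive=(("T1", 2.0), ("T2", 2.0)), negative=(("H1", -2.0), ("H2", -2.0))
)


class TestReadOut:
    def test_zero_input_circuit_reads_zero(self):
        spec = compile_diagnostic_circuit(PANEL, dict.fromkeys(["T1", "T2", "H1", "H2"], 0.0))
        traj = simulate_ode(spec)
        assert read_out(traj, spec) == (0.0, 0.0)

    def test_readout_at_time_zero_is_initial_signal(self, four_input_panel, sample_fpkm):
        spec = compile_diagnostic_circuit(four_input_panel, sample_fpkm)
        traj = simulate_ode(spec)
        assert read_out(traj, spec, readout_time=0.0) == (0.0, 0.0)

    def test_off_grid_time_rejected(self, four_input_panel, sample_fpkm):
        spec = compile_diagnostic_circuit(four_input_panel, sample_fpkm)
        traj = simulate_ode(spec)
        with pytest.raises(ValueError, match="not on the sampling grid"):
            read_out(traj, spec, readout_time=5.0)

    def test_dominant_tumor_total_wins_fam(self):
        fpkm = {"T1": 15.0, "T2": 15.0, "H1": 5.0, "H2": 5.0}
        spec = compile_diagnostic_circuit(PANEL, fpkm, gate3_nM=17.0)
        fam, rox = read_out(simulate_ode(spec), spec)
        assert fam > rox


class TestCallSample:
    @pytest.mark.parametrize(
        "fam,rox,expected",
        [
            (0.0, 0.0, "indeterminate"),
            (5.0, 5.0, "indeterminate"),
            (8.0, 2.0, "positive"),
            (2.0, 8.0, "negative"),
            (0.4, 0.3, "indeterminate"),  # both below the detection floor
        ],
    )
    def test_decision_rule(self, fam, rox, expected):
        assert call_sample(fam, rox) == expected

    def test_negative_signals_rejected(self):
        with pytest.raises(ValueError):
            call_sample(-0.1, 1.0)

    @given(
        st.floats(0, 50, allow_nan=False), st.floats(0, 50, allow_nan=False)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rule_consistency(self, fam, rox):
        call = call_sample(fam, rox)
        if call == "positive":
            assert fam > rox and fam >= 0.5
        elif call == "negative":
            assert rox > fam and rox >= 0.5
        else:
            assert max(fam, rox) < 0.5 or abs(fam - rox) <= 1e-3


class TestClassifyCohort:
    def test_separable_cohort_perfectly_classified(self):
        tumor = np.array([[40.0], [40.0], [2.0], [2.0]])
        normal = np.array([[2.0], [2.0], [40.0], [40.0]])
        matrix = np.hstack([np.tile(tumor, 5), np.tile(normal, 5)])
        expr, clin = _cohort_from_fpkm(
            matrix, ["tumor"] * 5 + ["normal"] * 5, ["T1", "T2", "H1", "H2"]
        )
        results, summary = classify_cohort(expr, clin, PANEL)
        assert summary.overall_accuracy == 1.0

    def test_all_zero_cohort_all_indeterminate(self):
        matrix = np.zeros((4, 6))
        expr, clin = _cohort_from_fpkm(
            matrix, ["tumor"] * 3 + ["normal"] * 3, ["T1", "T2", "H1", "H2"]
        )
        results, summary = classify_cohort(expr, clin, PANEL)
        assert (results["call"] == "indeterminate").all()
        assert summary.overall_accuracy == 0.0

    def test_channel_symmetry_swaps_calls(self):
        fpkm_t = {"T1": 20.0, "T2": 18.0, "H1": 4.0, "H2": 2.0}
        swapped = {"T1": fpkm_t["H1"], "T2": fpkm_t["H2"], "H1": fpkm_t["T1"], "H2": fpkm_t["T2"]}
        s1 = compile_diagnostic_circuit(PANEL, fpkm_t, gate3_nM=17.0)
        s2 = compile_diagnostic_circuit(PANEL, swapped, gate3_nM=17.0)
        f1, r1 = read_out(simulate_ode(s1), s1)
        f2, r2 = read_out(simulate_ode(s2), s2)
        assert f1 == pytest.approx(r2, rel=1e-6)
        assert r1 == pytest.approx(f2, rel=1e-6)
        assert call_sample(f1, r1) == "positive" and call_sample(f2, r2) == "negative"


class TestConfusionBookkeeping:
    def _results(self):
        return pd.DataFrame(
            {"sample_id": list("abcdef"),
             "true_class": ["tumor"] * 3 + ["normal"] * 3,
             "call": ["positive", "negative", "indeterminate", "negative", "negative", "positive"]}
        )

    def test_counts_sum_to_cohort_size(self):
        s = summarize_calls(self._results())
        assert int(s.table.values.sum()) == 6 == s.n

    def test_permutation_invariance(self):
        r = self._results()
        s1 = summarize_calls(r)
        s2 = summarize_calls(r.sample(frac=1, random_state=3).reset_index(drop=True))
        pd.testing.assert_frame_equal(s1.table, s2.table)
        assert s1.overall_accuracy == s2.overall_accuracy

    def test_accuracies(self):
        s = summarize_calls(self._results())
        assert s.per_class_accuracy["tumor"] == pytest.approx(1 / 3)
        assert s.per_class_accuracy["normal"] == pytest.approx(2 / 3)
        assert s.overall_accuracy == pytest.approx(3 / 6)
        assert s.binary_accuracy == pytest.approx(3 / 5)


class TestNodeBinning:
    @pytest.mark.parametrize(
        "count,part",
        [(10, "part1"), (15, "part1"), (16, "part2"), (20, "part2"),
         (28, "part2"), (29, "part3"), (50, "part3"), (105, "part3")],
    )
    def test_stated_bin_edges(self, count, part):
        assert bin_lymph_nodes(count) == part

    def test_exhaustive_scan_matches_piecewise_oracle(self):
        for c in range(121):
            expected = "part1" if c <= 15 else ("part2" if c <= 28 else "part3")
            assert bin_lymph_nodes(c) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            bin_lymph_nodes(-1)

    def test_non_increasing_boundaries_rejected(self):
        with pytest.raises(ValueError):
            NodeBinning(boundaries=(28, 15))


class TestClassifyTraitCohort:
    def test_perfectly_coupled_trait_scores_one(self):
        # hub ratio deterministically encodes the part
        fpkm_cols, lymph = [], []
        for part, (hp, hn, count) in enumerate(
            [(30.0, 5.0, 10), (30.0, 5.0, 20), (5.0, 30.0, 60)]
        ):
            for _ in range(4):
                fpkm_cols.append([hp, hn])
                lymph.append(count)
        matrix = np.array(fpkm_cols).T
        expr, clin = _cohort_from_fpkm(matrix, ["tumor"] * 12, ["hubP", "hubN"], lymph=lymph)
        table = classify_trait_cohort(expr, clin, "hubP", "hubN", "lymph_node_count")
        assert (table["accuracy"] == 1.0).all()

    def test_empty_part_reports_nan_not_zero(self):
        matrix = np.array([[30.0, 30.0], [5.0, 5.0]])
        expr, clin = _cohort_from_fpkm(matrix, ["tumor"] * 2, ["hubP", "hubN"], lymph=[5, 10])
        table = classify_trait_cohort(expr, clin, "hubP", "hubN", "lymph_node_count")
        p3 = table.loc[table["part"] == "part3"].iloc[0]
        assert p3["n"] == 0 and np.isnan(p3["accuracy"])

    def test_independent_hubs_score_near_half(self):
        # 200 samples, hub expression independent of the trait: accuracy in the
        # binomial 99% band around 0.5
        rng = np.random.default_rng(21)
        n = 200
        matrix = inv_log2p1(rng.normal(4.0, 0.8, size=(2, n)))
        lymph = rng.integers(0, 106, n)
        expr, clin = _cohort_from_fpkm(matrix, ["tumor"] * n, ["hubP", "hubN"], lymph=lymph)
        table = classify_trait_cohort(expr, clin, "hubP", "hubN", "lymph_node_count")
        correct = table["n_correct"].sum()
        decided = table["n"].sum() - table["n_indeterminate"].sum()
        band = 2.576 * np.sqrt(0.25 / decided)
        assert abs(correct / decided - 0.5) < band

    def test_indicator_trait_levels(self):
        matrix = np.array([[30.0, 5.0], [5.0, 30.0]]).T
        expr, clin = _cohort_from_fpkm(
            matrix, ["tumor"] * 2, ["hubP", "hubN"], indicator=[1, 0]
        )
        table = classify_trait_cohort(expr, clin, "hubP", "hubN", "tissue_indicator")
        assert (table["accuracy"] == 1.0).all()
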