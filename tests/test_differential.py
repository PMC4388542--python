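import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from raftdiff.datamodel import ReferenceStats
from raftdiff.differential import (
    ConfigurationError,
    DifferentialAbundanceModel,
    InsufficientReplicationError,
    call_candidates,
    combine_experiments,
    reference_ttest,
    select_reference,
    ttest_from_ratios,
)

HSP7C = ReferenceStats("Hspa8", 1.01, 0.064, 3)


def quant_frame(entries):
    """entries: list of (experiment_id, gene, gm_ratio)."""
    return pd.DataFrame(entries, columns=["experiment_id", "gene", "gm_ratio"])


class TestCombineExperiments:
    def test_mean_and_sample_sd(self):
        frame = quant_frame([(f"exp{i}", "Ly6h", r)
                             for i, r in enumerate([0.80, 0.75, 0.73], 1)])
        combined, identified = combine_experiments(frame, 3)
        row = combined.iloc[0]
        assert row["mean_ratio"] == pytest.approx(0.76)
        assert row["sd_ratio"] == pytest.approx(0.036056, abs=1e-5)
        assert identified == {"Ly6h"}

    def test_partial_presence_identified_only(self):
        frame = quant_frame([("exp1", "Bsn", 1.1), ("exp2", "Bsn", 1.2),
                             ("exp1", "Plp1", 1.5), ("exp2", "Plp1", 1.6),
                             ("exp3", "Plp1", 1.4)])
        combined, identified = combine_experiments(frame, 3)
        assert set(combined["gene"]) == {"Plp1"}
        assert identified == {"Bsn", "Plp1"}

    def test_single_experiment_sd_missing(self):
        combined, _ = combine_experiments(quant_frame([("exp1", "Bsn", 1.1)]), 1)
        assert math.isnan(combined.iloc[0]["sd_ratio"])

    def test_empty_input(self):
        combined, identified = combine_experiments(quant_frame([]), None)
        assert combined.empty and identified == set()


class TestSelectReference:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=[
            "gene", "mean_ratio", "sd_ratio", "n_experiments_present"])

    def test_named_gene(self):
        combined = self.frame([("Hspa8", 1.01, 0.064, 3), ("Flot1", 0.80, 0.1, 3)])
        ref = select_reference(combined, "Hspa8")
        assert (ref.gene, ref.mean, ref.sd) == ("Hspa8", 1.01, 0.064)

    def test_named_gene_absent(self):
        with pytest.raises(ConfigurationError, match="Hspa8"):
            select_reference(self.frame([("Flot1", 0.8, 0.1, 3)]), "Hspa8")

    def test_auto_closest_to_one_wins_before_sd(self):
        combined = self.frame([("A", 1.00, 0.2, 3), ("B", 1.02, 0.01, 3)])
        assert select_reference(combined, "AUTO").gene == "A"

    def test_auto_sd_then_lexicographic_tiebreaks(self):
        combined = self.frame([("A", 1.00, 0.05, 3), ("B", 1.00, 0.01, 3)])
        assert select_reference(combined, "AUTO").gene == "B"
        combined = self.frame([("B", 1.00, 0.05, 3), ("A", 1.00, 0.05, 3)])
        assert select_reference(combined, "AUTO").gene == "A"


class TestReferenceTTest:
    @pytest.mark.parametrize("gene, mean, sd, p_published, direction, sig", [
        ("Ly6h", 0.76, 0.020, 0.003, "decreased", True),
        ("Plp1", 1.55, 0.176, 0.008, "increased", True),
        ("Flot1", 0.80, 0.146, 0.084, "decreased", False),
    ])
    def test_published_rows(self, gene, mean, sd, p_published, direction, sig):
        res = reference_ttest(gene, mean, sd, 3, HSP7C)
        assert res.p_value == pytest.approx(p_published, abs=0.003)
        assert res.degrees_of_freedom == 4
        assert res.direction == direction and res.significant is sig

    def test_matches_scipy_from_stats(self):
        res = reference_ttest("Thy1", 0.66, 0.132, 3, HSP7C)
        t, p = sps.ttest_ind_from_stats(0.66, 0.132, 3, 1.01, 0.064, 3)
        assert res.t_statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_self_comparison_is_null(self):
        res = reference_ttest("Hspa8", 1.01, 0.064, 3, HSP7C)
        assert res.t_statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_summary_and_vector_paths_identical(self):
        x = [0.80, 0.75, 0.73]
        ref = [1.05, 0.95, 1.03]
        from_vec = ttest_from_ratios("Ly6h", x, ref)
        xm, xs = np.mean(x), np.std(x, ddof=1)
        rm, rs = np.mean(ref), np.std(ref, ddof=1)
        from_sum = reference_ttest("Ly6h", xm, xs, 3,
                                   ReferenceStats("R", rm, rs, 3))
        assert from_vec.t_statistic == pytest.approx(from_sum.t_statistic,
                                                     rel=1e-12)
        assert from_vec.p_value == pytest.approx(from_sum.p_value, rel=1e-12)

    def test_symmetric_in_protein_and_reference(self):
        a = reference_ttest("X", 0.8, 0.1, 3, ReferenceStats("Y", 1.2, 0.2, 3))
        b = reference_ttest("Y", 1.2, 0.2, 3, ReferenceStats("X", 0.8, 0.1, 3))
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.t_statistic == pytest.approx(-b.t_statistic, rel=1e-12)

    def test_p_decreases_with_effect_size(self):
        ps = [reference_ttest("X", m, 0.1, 3, HSP7C).p_value
              for m in (1.1, 1.3, 1.5, 1.9)]
        assert ps == sorted(ps, reverse=True)

    def test_zero_variance_cases(self):
        same = reference_ttest("X", 1.0, 0.0, 3, ReferenceStats("Y", 1.0, 0.0, 3))
        assert same.p_value == 1.0
        apart = reference_ttest("X", 1.2, 0.0, 3, ReferenceStats("Y", 1.0, 0.0, 3))
        assert apart.p_value == 0.0

    def test_insufficient_replication(self):
        with pytest.raises(InsufficientReplicationError):
            reference_ttest("X", 1.0, 0.1, 1, HSP7C)

    def test_welch_differs_with_unequal_variances(self):
        student = reference_ttest("X", 1.2, 0.3, 3, HSP7C)
        welch = reference_ttest("X", 1.2, 0.3, 3, HSP7C, welch=True)
        assert welch.degrees_of_freedom < student.degrees_of_freedom
        t, p = sps.ttest_ind_from_stats(1.2, 0.3, 3, 1.01, 0.064, 3,
                                        equal_var=False)
        assert welch.p_value == pytest.approx(p, rel=1e-9)


class TestModelSurface:
    def combined(self):
        rows = [
            ("Ly6h", (0.80, 0.75, 0.73)),
            ("Hspa8", (1.05, 0.95, 1.03)),
            ("Plp1", (1.40, 1.75, 1.50)),
        ]
        return pd.DataFrame({
            "gene": [g for g, _ in rows],
            "per_experiment_ratios": [r for _, r in rows],
            "n_experiments_present": [3] * 3,
            "mean_ratio": [np.mean(r) for _, r in rows],
            "sd_ratio": [np.std(r, ddof=1) for _, r in rows],
        })

    def test_ratio_and_summary_constructions_agree(self):
        combined = self.combined()
        res_vec = DifferentialAbundanceModel.from_ratios(
            combined, reference="Hspa8").fit()
        res_sum = DifferentialAbundanceModel.from_summary(
            combined[["gene", "mean_ratio", "sd_ratio"]], n=3,
            reference="Hspa8").fit()
        pd.testing.assert_series_equal(res_vec.table["p_value"],
                                       res_sum.table["p_value"])

    def test_bh_column_bounds_raw_p(self):
        res = DifferentialAbundanceModel.from_ratios(
            self.combined(), reference="Hspa8").fit()
        assert (res.table["p_bh"] >= res.table["p_value"] - 1e-15).all()
        assert (res.table["p_bh"] <= 1.0).all()

    def test_summary_text(self):
        res = DifferentialAbundanceModel.from_ratios(
            self.combined(), reference="Hspa8").fit()
        text = res.summary()
        assert "Internal reference: Hspa8" in text
        assert "pooled-variance Student" in text

    def test_log_scale_needs_vectors(self):
        with pytest.raises(ConfigurationError):
            DifferentialAbundanceModel.from_summary(
                self.combined()[["gene", "mean_ratio", "sd_ratio"]], n=3,
                on_log_scale=True)

    def test_log_scale_swap_invariance(self):
        combined = self.combined()
        swapped = combined.copy()
        swapped["per_experiment_ratios"] = [
            tuple(1.0 / np.asarray(r)) for r in combined["per_experiment_ratios"]
        ]
        a = DifferentialAbundanceModel.from_ratios(
            combined, reference="Hspa8", on_log_scale=True).fit()
        b = DifferentialAbundanceModel.from_ratios(
            swapped, reference="Hspa8", on_log_scale=True).fit()
        assert np.allclose(a.table["p_value"], b.table["p_value"], rtol=1e-9)
        assert np.allclose(a.table["mean_ratio"] * b.table["mean_ratio"], 1.0,
                           rtol=1e-9)


class TestCallCandidates:
    def test_counts_and_partition(self):
        results = [
            reference_ttest("Ly6h", 0.76, 0.020, 3, HSP7C),
            reference_ttest("Plp1", 1.55, 0.176, 3, HSP7C),
            reference_ttest("Flot1", 0.80, 0.146, 3, HSP7C),
        ]
        sig, counts = call_candidates(results)
        assert sig == {"Ly6h", "Plp1"}
        assert counts["n_increased"] == 1 and counts["n_decreased"] == 1
        assert counts["percent_significant"] == pytest.approx(200 / 3)

    def test_empty(self):
        sig, counts = call_candidates([])
        assert sig == set() and counts["n_significant"] == 0
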