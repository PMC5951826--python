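"""Moderated differential expression, BH adjustment and concordance."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from modseeker import datasets, dea
from modseeker.dea import DeaConfig


class TestBhAdjust:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.1], [0.01, 0.1]),
        ],
    )
    def test_step_up_hand_computations(self, pvals, expected):
        assert dea.bh_adjust(pvals) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dea.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_permutation_equivariance_and_monotonicity(self, pvals):
        p = np.array(pvals)
        q = dea.bh_adjust(p)
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = dea.bh_adjust(p[perm])
        assert q_perm == pytest.approx(q[perm])
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestModeratedTest:
    def test_identical_groups_give_zero_fc_and_p_one(self, two_group_expression):
        expr, groups = two_group_expression
        expr = expr.copy()
        expr.loc["g000"] = [5.0, 6.0, 5.0, 6.0]  # identical values per group
        table = dea.moderated_test(expr, groups)
        assert table.loc["g000", "log2fc"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["g000", "pvalue"] == pytest.approx(1.0)

    def test_group_below_two_samples_rejected(self, two_group_expression):
        expr, groups = two_group_expression
        with pytest.raises(ValueError, match=">= 2 samples"):
            dea.moderated_test(expr[["c1", "t1", "t2"]], groups)

    def test_prior_df_zero_equals_pooled_t_test(self, rng):
        genes = 100
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(genes, 8)),
            index=[f"g{i}" for i in range(genes)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(["control"] * 4 + ["treated"] * 4, index=expr.columns)
        table = dea.moderated_test(expr, groups, DeaConfig(prior_df=0))
        t_ref, p_ref = sps.ttest_ind(
            expr.iloc[:, 4:], expr.iloc[:, :4], axis=1, equal_var=True
        )
        assert table["tstat"].to_numpy() == pytest.approx(t_ref, rel=1e-9)
        assert table["pvalue"].to_numpy() == pytest.approx(p_ref, rel=1e-9)

    def test_type_i_error_control_under_the_null(self):
        rng = np.random.default_rng(21)
        rates = []
        for _ in range(50):
            expr = pd.DataFrame(
                rng.normal(0, 1, size=(500, 4)) * rng.uniform(0.2, 1.0, size=(500, 1)),
                columns=["c1", "c2", "t1", "t2"],
            )
            groups = pd.Series(["control", "control", "treated", "treated"], index=expr.columns)
            table = dea.moderated_test(expr, groups)
            rates.append(float((table["pvalue"] < 0.05).mean()))
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_planted_effect_recovery(self):
        from modseeker import synthio

        config = synthio.SynthConfig(
            n_genes=300,
            planted_module_size=40,
            effect_size_log2=2.0,
            noise_sd=0.25,
            n_replicates_per_group=5,
            edge_param=0.02,
            seed=3,
        )
        network = synthio.generate_network(config)
        planted = synthio.plant_module(network, 40, seed=3)
        expr, groups = synthio.generate_expression(config, planted)
        table = dea.moderated_test(expr, groups)
        est = table.loc[sorted(planted), "log2fc"].median()
        assert abs(est - 2.0) < 0.15

    def test_agrees_with_limma_oracle(self, two_group_expression, tmp_path):
        """Independent cross-check against the reference empirical-Bayes fit."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        expr, groups = two_group_expression
        expr.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages(library(limma))
                x <- as.matrix(read.delim("expr.tsv", row.names = 1))
                design <- cbind(Intercept = 1, Treated = c(0, 0, 1, 1))
                fit <- eBayes(lmFit(x, design))
                out <- data.frame(gene = rownames(x),
                                  logFC = fit$coefficients[, "Treated"],
                                  p = fit$p.value[, "Treated"])
                write.table(out, "limma_out.tsv", sep = "\t", row.names = FALSE, quote = FALSE)
                """
            )
        )
        subprocess.run(
            ["Rscript", "limma.R"], cwd=tmp_path, check=True, capture_output=True, timeout=300
        )
        ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t", index_col="gene")
        table = dea.moderated_test(expr, groups)
        assert table["log2fc"].to_numpy() == pytest.approx(ref["logFC"].to_numpy(), abs=1e-8)
        assert np.log(table["pvalue"].to_numpy()) == pytest.approx(
            np.log(ref["p"].to_numpy()), rel=0.02
        )


class TestSignificanceRule:
    def test_published_rows_pass_the_rule(self, shared_table):
        sw = datasets.cell_line_stats(shared_table, "sw480")
        caco = datasets.cell_line_stats(shared_table, "caco2")
        assert ("AURKA", "down") in dea.call_significant(sw)
        assert ("REEP5", "down") in dea.call_significant(caco)

    def test_fold_change_filter_excludes_weak_effects(self):
        table = pd.DataFrame(
            {"log2fc": [0.30, 0.60], "pvalue": [1e-4, 1e-4], "qvalue": [0.04, 0.04]},
            index=["weak", "strong"],
        )
        sig = dea.call_significant(table)
        assert sig == {("strong", "up")}

    def test_monotone_in_thresholds(self, shared_table):
        sw = datasets.cell_line_stats(shared_table, "sw480")
        tight = dea.call_significant(sw, DeaConfig(q_threshold=0.02, fc_threshold_linear=1.8))
        loose = dea.call_significant(sw, DeaConfig(q_threshold=0.05, fc_threshold_linear=1.5))
        assert tight <= loose

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            dea.call_significant(pd.DataFrame(columns=["log2fc", "pvalue", "qvalue"]))


class TestConcordance:
    def test_published_54_gene_breakdown(self, shared_table):
        summary = dea.cross_concordance(
            datasets.cell_line_stats(shared_table, "sw480"),
            datasets.cell_line_stats(shared_table, "caco2"),
        )
        assert summary.shared_significant == 54
        assert summary.up_in_both == 28
        assert summary.down_in_both == 25
        assert summary.discordant == 1
        assert summary.discordant_genes == ["SLC12A2"]

    def test_self_comparison_has_no_discordance(self, shared_table):
        sw = datasets.cell_line_stats(shared_table, "sw480")
        summary = dea.cross_concordance(sw, sw)
        assert summary.discordant == 0
        assert summary.shared_significant == len(dea.call_significant(sw))


class TestFdrControlOnNull:
    def test_expected_q_discovery_rate_bounded(self):
        rng = np.random.default_rng(8)
        frac = []
        for _ in range(200):
            p = rng.uniform(size=1000)
            q = dea.bh_adjust(p)
            frac.append(float((q < 0.05).mean()))
        assert np.mean(frac) <= 0.05
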