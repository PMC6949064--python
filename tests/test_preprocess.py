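import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mrnet
from mrnet.preprocess import _fit_variance_prior


def two_class_labels(expr, n_pt):
    return pd.Series(
        ["PT"] * n_pt + ["NT"] * (expr.shape[1] - n_pt), index=expr.columns
    )


class TestCollapseDuplicates:
    def _dup(self):
        return pd.DataFrame(
            [[5.0, 5.0], [7.0, 7.0], [1.0, 1.0]],
            index=["G", "G", "H"],
            columns=["s1", "s2"],
        )

    def test_no_duplicates_identity(self, tiny_expr):
        assert mrnet.collapse_duplicates(tiny_expr) is tiny_expr

    def test_max_mean_row_selected(self):
        out = mrnet.collapse_duplicates(self._dup())
        assert out.loc["G"].tolist() == [7.0, 7.0]
        assert list(out.index) == ["G", "H"]

    def test_three_duplicates_highest_kept(self):
        expr = pd.DataFrame(
            [[1.0, 2.0], [9.0, 8.0], [3.0, 3.0]],
            index=["G", "G", "G"], columns=["s1", "s2"],
        )
        out = mrnet.collapse_duplicates(expr)
        assert out.loc["G"].tolist() == [9.0, 8.0]

    def test_mean_method_averages(self):
        out = mrnet.collapse_duplicates(self._dup(), method="mean")
        assert out.loc["G"].tolist() == [6.0, 6.0]


class TestBatchAdjust:
    def test_single_batch_identity(self, tiny_expr):
        batches = pd.Series("B1", index=tiny_expr.columns)
        out = mrnet.batch_adjust(tiny_expr, batches)
        assert np.allclose(out, tiny_expr, atol=1e-10)

    def test_planted_constant_shift_removed_exactly(self):
        # zero-interaction design: identical within-batch data, +3 offset
        rng = np.random.default_rng(2)
        base = rng.normal(7, 1, 100)[:, None] + rng.standard_normal(30)[None, :]
        x = pd.DataFrame(
            np.hstack([base, base + 3.0]),
            index=[f"g{i}" for i in range(100)],
            columns=[f"s{j}" for j in range(60)],
        )
        batches = pd.Series(["B1"] * 30 + ["B2"] * 30, index=x.columns)
        adj = mrnet.batch_adjust(x, batches)
        m1 = adj.iloc[:, :30].mean(axis=1)
        m2 = adj.iloc[:, 30:].mean(axis=1)
        assert np.abs(m1 - m2).max() < 1e-6

    def test_null_batches_barely_changed(self):
        # two statistically identical batches: mean |change| well below the
        # sampling SE of a batch mean
        rng = np.random.default_rng(3)
        x = pd.DataFrame(
            rng.normal(7, 1, (400, 200)),
            index=[f"g{i}" for i in range(400)],
            columns=[f"s{j}" for j in range(200)],
        )
        batches = pd.Series(["A"] * 100 + ["B"] * 100, index=x.columns)
        adj = mrnet.batch_adjust(x, batches)
        se_batch_mean = 1.0 / np.sqrt(100)
        assert np.abs(adj - x).to_numpy().mean() < 5 * se_batch_mean

    def test_shape_order_and_grand_mean_preserved(self, tiny_expr):
        batches = pd.Series(
            ["B1"] * 10 + ["B2"] * 10, index=tiny_expr.columns
        )
        adj = mrnet.batch_adjust(tiny_expr, batches)
        assert list(adj.index) == list(tiny_expr.index)
        assert list(adj.columns) == list(tiny_expr.columns)
        assert np.abs(adj.mean(axis=1) - tiny_expr.mean(axis=1)).max() < 1e-8

    def test_zero_variance_batch_rejected(self):
        x = pd.DataFrame(
            [[1.0, 1.0, 2.0, 3.0], [2.0, 2.0, 5.0, 4.0]],
            index=["g1", "g2"], columns=["a", "b", "c", "d"],
        )
        batches = pd.Series(["B1", "B1", "B2", "B2"], index=x.columns)
        with pytest.raises(ValueError, match="zero variance"):
            mrnet.batch_adjust(x, batches)

    def test_agrees_with_scanpy_combat(self):
        # independent route: the established parametric empirical-Bayes
        # batch-correction implementation on the same data
        anndata = pytest.importorskip("anndata")
        scanpy = pytest.importorskip("scanpy")
        rng = np.random.default_rng(4)
        x = rng.normal(7, 1, (80, 60))
        x[:, 30:] += rng.normal(1.0, 0.3, 80)[:, None]
        expr = pd.DataFrame(
            x, index=[f"g{i}" for i in range(80)], columns=[f"s{j}" for j in range(60)]
        )
        batches = pd.Series(["B1"] * 30 + ["B2"] * 30, index=expr.columns)
        ours = mrnet.batch_adjust(expr, batches)
        ad = anndata.AnnData(
            X=x.T.copy(), obs=pd.DataFrame({"batch": batches.to_numpy()},
                                           index=expr.columns),
        )
        scanpy.pp.combat(ad, key="batch")
        theirs = ad.X.T
        # re-center both to the same per-gene mean before comparing: the two
        # implementations restore slightly different location conventions
        ours_c = ours.to_numpy() - ours.to_numpy().mean(axis=1, keepdims=True)
        theirs_c = theirs - theirs.mean(axis=1, keepdims=True)
        assert np.abs(ours_c - theirs_c).max() < 0.05


class TestModeratedT:
    def test_d0_zero_equals_classical_pooled_t(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.standard_normal((200, 16)))
        classes = two_class_labels(expr, 8)
        de = mrnet.moderated_ttest(expr, classes, d0_override=0)
        ref = stats.ttest_ind(
            expr.iloc[:, :8], expr.iloc[:, 8:], axis=1, equal_var=True
        )
        assert np.abs(de.table["t"].to_numpy() - ref.statistic).max() < 1e-12
        assert np.abs(de.table["p"].to_numpy() - ref.pvalue).max() < 1e-12

    def test_d0_infinite_full_shrinkage(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.standard_normal((100, 12)))
        de = mrnet.moderated_ttest(expr, two_class_labels(expr, 6), d0_override=np.inf)
        assert de.table["var_shrunk"].nunique() == 1
        assert de.table["var_shrunk"].iloc[0] == pytest.approx(de.var_prior)

    def test_shrunk_variance_between_residual_and_prior(self):
        rng = np.random.default_rng(7)
        # heterogeneous true variances so the prior fit gives finite d0
        scales = rng.uniform(0.3, 3.0, 300)
        expr = pd.DataFrame(rng.standard_normal((300, 14)) * scales[:, None])
        de = mrnet.moderated_ttest(expr, two_class_labels(expr, 7))
        assert np.isfinite(de.df_prior) and de.df_prior > 0
        de.validate()

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.standard_normal((10000, 20)))
        de = mrnet.moderated_ttest(expr, two_class_labels(expr, 10))
        frac = (de.table["p"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_prior_moment_fit_recovers_planted_d0(self):
        # residual variances drawn from the scaled inverse-chi-square model
        rng = np.random.default_rng(9)
        d0_true, s0_true, df = 8.0, 1.5, 10
        s2 = d0_true * s0_true / stats.chi2.rvs(d0_true, size=20000,
                                                random_state=rng)
        s2 = s2 * stats.chi2.rvs(df, size=20000, random_state=rng) / df
        d0, s0 = _fit_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.1)

    def test_agrees_with_limma_ebayes(self, tmp_path):
        # cross-language oracle: R limma on the same matrix
        rng = np.random.default_rng(10)
        scales = rng.uniform(0.5, 2.0, 150)
        x = rng.standard_normal((150, 12)) * scales[:, None]
        x[:30, :6] += 1.0
        expr = pd.DataFrame(
            x, index=[f"g{i}" for i in range(150)],
            columns=[f"s{j}" for j in range(12)],
        )
        expr.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("expr.tsv", row.names = 1))
            design <- cbind(NT = 1, PTvsNT = rep(c(1, 0), each = 6))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t = fit$t[, "PTvsNT"], p = fit$p.value[, "PTvsNT"],
                              d0 = fit$df.prior, s0 = fit$s2.prior)
            write.table(out, "limma.tsv", sep = "\t", quote = FALSE)
            """
        )
        (tmp_path / "run.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", "run.R"], cwd=tmp_path, capture_output=True, text=True
        )
        if proc.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {proc.stderr[:200]}")
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        de = mrnet.moderated_ttest(expr, two_class_labels(expr, 6))
        assert de.df_prior == pytest.approx(ref["d0"].iloc[0], rel=0.05)
        assert de.var_prior == pytest.approx(ref["s0"].iloc[0], rel=0.05)
        assert np.abs(de.table["t"].to_numpy() - ref["t"].to_numpy()).max() < 1e-6


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert mrnet.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_unchanged(self):
        out = mrnet.bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_step_up_hand_oracle(self):
        out = mrnet.bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mrnet.bh_adjust([0.5, 1.2])

    def test_matches_direct_step_up_on_random_vectors(self):
        # independent oracle: literal step-up computation
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank_ix in range(n - 1, -1, -1):
                running = min(running, p[order[rank_ix]] * n / (rank_ix + 1))
                adj[order[rank_ix]] = running
            assert np.allclose(mrnet.bh_adjust(p), adj, atol=1e-12)


class TestBuildSignature:
    def _de(self, log2fc, p):
        tab = pd.DataFrame(
            {
                "mean_pt": 0.0, "mean_nt": 0.0, "log2fc": log2fc,
                "var_residual": 1.0, "var_shrunk": 1.0,
                "t": log2fc, "p": p,
            },
            index=[f"g{i}" for i in range(len(p))],
        )
        return mrnet.DEResult(table=tab, df_residual=10, df_prior=0,
                              var_prior=float("nan"))

    def test_linear_fc_thresholds(self):
        # FC 1.6 & fdr .01 in (up); FC 1.2 & tiny fdr out; FC 1/1.8 in (down)
        de = self._de(
            log2fc=[np.log2(1.6), np.log2(1.2), -np.log2(1.8)],
            p=[0.001, 0.0001, 0.004],
        )
        sig = mrnet.build_signature(de, fdr_cut=0.05, fc_cut=1.5)
        assert list(sig.index) == ["g0", "g2"]
        assert sig.loc["g0", "direction"] == "up"
        assert sig.loc["g2", "direction"] == "down"

    def test_empty_signature_allowed(self):
        de = self._de(log2fc=[0.1, -0.1], p=[0.9, 0.8])
        assert len(mrnet.build_signature(de)) == 0

    def test_monotone_in_cutoffs_and_order_invariant(self):
        rng = np.random.default_rng(12)
        de = self._de(log2fc=rng.normal(0, 1, 200), p=rng.random(200) ** 2)
        base = mrnet.build_signature(de, fdr_cut=0.1, fc_cut=1.3)
        tighter_fc = mrnet.build_signature(de, fdr_cut=0.1, fc_cut=1.6)
        tighter_fdr = mrnet.build_signature(de, fdr_cut=0.02, fc_cut=1.3)
        assert set(tighter_fc.index) <= set(base.index)
        assert set(tighter_fdr.index) <= set(base.index)
        # permuting gene order does not change the selected set
        perm = rng.permutation(200)
        de_perm = mrnet.DEResult(
            table=de.table.iloc[perm], df_residual=10, df_prior=0,
            var_prior=float("nan"),
        )
        sig_perm = mrnet.build_signature(de_perm, fdr_cut=0.1, fc_cut=1.3)
        assert set(sig_perm.index) == set(base.index)

    def test_signature_recall_on_default_cohort(self, default_cohort, default_discovery):
        # planted PT-shifted genes: active TFs and their targets
        truth = default_cohort.truth
        shifted = set()
        for tf in truth.active_tfs:
            shifted.add(tf)
            shifted.update(t.target for t in truth.regulons[tf])
        sig = set(default_discovery.signature.index)
        null_genes = set(default_cohort.expression.index) - shifted
        recall = len(sig & shifted) / len(shifted)
        fpr = len(sig & null_genes) / len(null_genes)
        assert recall >= 0.9
        assert fpr <= 0.01
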