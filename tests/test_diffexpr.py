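"""Differential-expression stage: normalization, moderation, FDR, filter."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

import netprox as npx
from netprox.diffexpr import PriorEstimate


def _matrix(cols: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    df.index = [f"g{i}" for i in range(len(df))]
    return df


class TestQuantileNormalize:
    def test_hand_example_two_columns(self):
        m = _matrix({"s1": [1.0, 3.0], "s2": [2.0, 4.0]})
        out = npx.quantile_normalize(m)
        np.testing.assert_allclose(out["s1"], [1.5, 3.5])
        np.testing.assert_allclose(out["s2"], [1.5, 3.5])

    def test_identical_columns_are_fixed_point(self):
        m = _matrix({"s1": [5.0, 1.0, 3.0], "s2": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(npx.quantile_normalize(m), m)

    def test_column_means_equalized(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(50, 4)) + [0, 1, 2, 3])
        out = npx.quantile_normalize(m)
        means = out.mean(axis=0).to_numpy()
        np.testing.assert_allclose(means, means[0])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            npx.quantile_normalize(_matrix({"s1": [1.0, 2.0]}))


class TestFitGroups:
    def _groups(self, n=2):
        idx = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        return pd.Series(["A"] * n + ["B"] * n, index=idx)

    def test_noiseless_shift(self):
        m = pd.DataFrame([[0.0, 0.0, 1.0, 1.0]], index=["g"],
                         columns=self._groups().index)
        fit = npx.fit_groups(m, self._groups())
        assert fit.loc["g", "logfc"] == 1.0
        assert fit.loc["g", "s2"] == 0.0
        assert fit.loc["g", "df"] == 2.0
        assert bool(fit.loc["g", "zero_variance"])

    def test_pooled_variance_by_hand(self):
        m = pd.DataFrame([[0.0, 2.0, 1.0, 3.0]], index=["g"],
                         columns=self._groups().index)
        fit = npx.fit_groups(m, self._groups())
        assert fit.loc["g", "logfc"] == 1.0
        assert fit.loc["g", "s2"] == pytest.approx(2.0)

    def test_identical_groups_zero_logfc(self):
        m = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["g"],
                         columns=self._groups().index)
        assert npx.fit_groups(m, self._groups()).loc["g", "logfc"] == 0.0

    def test_requires_two_groups(self):
        g = pd.Series(["A"] * 4, index=self._groups().index)
        m = pd.DataFrame(np.zeros((1, 4)), columns=g.index)
        with pytest.raises(ValueError):
            npx.fit_groups(m, g)


class TestEstimatePrior:
    def test_identical_variances_flag_infinite_d0(self):
        prior = npx.estimate_prior(np.full(100, 0.3), 6.0)
        assert prior.is_infinite

    def test_two_distinct_values_give_finite_d0_matching_grid_oracle(self):
        s2 = np.array([0.05, 0.2] * 200)
        df = 6.0
        prior = npx.estimate_prior(s2, df)
        assert np.isfinite(prior.d0) and prior.d0 > 0
        # grid oracle for the trigamma moment equation
        e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
        excess = e.var(ddof=1) - special.polygamma(1, df / 2)
        grid = np.linspace(0.05, 50, 20000)
        oracle = grid[np.argmin(np.abs(special.polygamma(1, grid / 2) - excess))]
        assert prior.d0 == pytest.approx(oracle, rel=1e-3)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            npx.estimate_prior(np.zeros(100), 4.0)

    def test_recovery_from_planted_prior(self):
        t = npx.gen_expression(20000, 4, 0.0, 0.0, d0_true=4.0,
                               s0sq_true=0.05, seed=11)
        fits = npx.fit_groups(t.matrix, t.groups)
        prior = npx.estimate_prior(fits["s2"].to_numpy(), fits["df"].to_numpy())
        assert prior.d0 == pytest.approx(4.0, rel=0.15)
        assert prior.s0sq == pytest.approx(0.05, rel=0.10)


class TestModeratedT:
    def test_closed_form_hand_example(self):
        t, p = npx.moderated_t(
            np.array([1.0]), np.array([1.0]), 2.0,
            PriorEstimate(d0=2.0, s0sq=1.0), n_a=2, n_b=2,
        )
        assert t[0] == pytest.approx(1.0)
        assert p[0] == pytest.approx(2 * stats.t.sf(1.0, 4))

    def test_zero_prior_df_recovers_pooled_t(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(1000, 8)),
                         columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=m.columns)
        fit = npx.fit_groups(m, groups)
        t, p = npx.moderated_t(fit["logfc"].to_numpy(), fit["s2"].to_numpy(),
                               fit["df"].to_numpy(), PriorEstimate(0.0, 1.0), 4, 4)
        ref = stats.ttest_ind(m.iloc[:, 4:], m.iloc[:, :4], axis=1)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-10)

    def test_infinite_prior_df_uses_prior_variance_and_normal(self):
        t, p = npx.moderated_t(
            np.array([1.0, 2.0]), np.array([5.0, 0.1]), 6.0,
            PriorEstimate(d0=np.inf, s0sq=1.0), n_a=2, n_b=2,
        )
        np.testing.assert_allclose(t, [1.0, 2.0])
        np.testing.assert_allclose(p, 2 * stats.norm.sf([1.0, 2.0]))

    def test_zero_posterior_variance_flagged(self):
        t, p = npx.moderated_t(np.array([1.0]), np.array([0.0]), 2.0,
                               PriorEstimate(d0=0.0, s0sq=1.0), 2, 2)
        assert np.isinf(t[0]) and p[0] == 0.0

    def test_agrees_with_limma_reference(self):
        """Full moderated pipeline vs the R reference implementation."""
        truth = npx.gen_expression(200, 4, 0.1, 1.5, seed=3)
        res, _, prior = npx.run_diffexpr(truth.matrix, truth.groups, normalize=False)
        res = res.set_index("gene")
        design = ",".join("1" if g == "mi" else "0" for g in truth.groups)
        script = (
            "suppressMessages(library(limma));"
            "m <- as.matrix(read.delim('stdin', row.names=1));"
            f"design <- model.matrix(~g, data.frame(g=c({design})));"
            "fit <- eBayes(lmFit(m, design));"
            "write.table(data.frame(d0=fit$df.prior, s0sq=fit$s2.prior,"
            " t=fit$t[,2], p=fit$p.value[,2]), sep='\\t', quote=FALSE)"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], input=truth.matrix.to_csv(sep="\t"),
            capture_output=True, text=True, check=True,
        )
        ref = pd.read_csv(pd.io.common.StringIO(proc.stdout), sep="\t")
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-5)
        assert prior.s0sq == pytest.approx(ref["s0sq"].iloc[0], rel=1e-5)
        np.testing.assert_allclose(res["t_mod"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(res["p_raw"], ref["p"], rtol=1e-8)


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(npx.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(npx.bh_adjust([0.4]), [0.4])

    def test_ties_all_equal(self):
        np.testing.assert_allclose(npx.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            npx.bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_step_up_oracle(self, p):
        # independent oracle: literal sort / scale / cumulative-min / unsort
        p = np.asarray(p)
        order = np.argsort(p, kind="mergesort")
        m = len(p)
        q = p[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(q[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q, 1.0)
        np.testing.assert_allclose(npx.bh_adjust(p), expected, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=50))
    def test_sorted_adjusted_values_monotone_in_rank(self, p):
        p = np.asarray(p)
        adj = npx.bh_adjust(p)
        by_rank = adj[np.argsort(p, kind="mergesort")]
        assert (np.diff(by_rank) >= -1e-12).all()


class TestFilterSignature:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["gene", "logfc", "p_adj"])

    def test_strict_inequalities(self):
        res = self._results([
            ("in_both", 0.3, 0.009),
            ("p_on_boundary", 1.0, 0.01),
            ("lfc_on_boundary", 0.25, 0.001),
            ("negative_lfc_in", -0.3, 0.005),
        ])
        assert npx.filter_signature(res) == ["negative_lfc_in", "in_both"]

    def test_order_by_p_then_gene(self):
        res = self._results([
            ("b", 1.0, 0.001), ("a", 1.0, 0.001), ("c", 1.0, 0.0001),
        ])
        assert npx.filter_signature(res) == ["c", "a", "b"]


class TestModeratedTTestEstimator:
    def test_fit_exposes_sklearn_style_attributes(self):
        truth = npx.gen_expression(300, 4, 0.1, 2.0, seed=5)
        est = npx.ModeratedTTest().fit(truth.matrix.T, truth.groups)
        assert set(est.results_.columns) >= {"gene", "logfc", "t_mod", "p_raw",
                                             "p_adj", "passes"}
        assert est.prior_.s0sq > 0
        assert est.get_params()["p_adj_max"] == 0.01
        recovered = set(est.signature_) & truth.de_genes
        assert len(recovered) > 0

    def test_planted_genes_recovered_at_informative_settings(self):
        """Sensitivity of the signature filter on clearly-powered planted genes."""
        sens = []
        for seed in range(20):
            t = npx.gen_expression(1000, 5, 0.05, 1.5, seed=seed)
            _, sig, _ = npx.run_diffexpr(t.matrix, t.groups)
            sens.append(len(set(sig) & t.de_genes) / len(t.de_genes))
        assert np.mean(sens) >= 0.8
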