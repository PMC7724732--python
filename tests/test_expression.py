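"""Abundance screens, the external-effects variance model and the
trait-correlation screen."""

import numpy as np
import pandas as pd
import pytest

from spermnet.datatypes import AbundanceMatrix
from spermnet.expression import (
    correlate_traits,
    expr_variance_components,
    filter_abundances,
    significant_trait_counts,
    top_trait,
)


def _mat(values, kind="mRNA", ids=None, log2=False):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"f{i}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(pd.DataFrame(values, index=ids, columns=cols), kind=kind, log2=log2)


class TestFilterAbundances:
    def test_fpkm_exactly_10_kept(self):
        m = _mat([[10.0, 10.0], [5.0, 5.0]])
        out = filter_abundances(m)
        assert out.feature_ids == ["f0"]
        assert out.log2

    def test_cpm_exactly_1_dropped(self):
        m = _mat([[1.0, 1.0], [5.0, 5.0]], kind="miRNA")
        out = filter_abundances(m)
        assert out.feature_ids == ["f1"]

    def test_all_zero_dropped_by_either(self):
        mrna = _mat([[0.0, 0.0], [20.0, 20.0]])
        mirna = _mat([[0.0, 0.0], [20.0, 20.0]], kind="miRNA")
        assert filter_abundances(mrna).feature_ids == ["f1"]
        assert filter_abundances(mirna).feature_ids == ["f1"]

    def test_log2_with_pseudocount(self):
        m = _mat([[15.0, 31.0]])
        out = filter_abundances(m, pseudocount=1.0)
        assert np.allclose(out.values.to_numpy(), [[4.0, 5.0]])

    def test_strict_per_sample_mirna(self):
        m = _mat([[0.5, 100.0], [2.0, 2.0]], kind="miRNA")
        assert filter_abundances(m, strict_per_sample=True).feature_ids == ["f1"]

    def test_empty_result_errors(self):
        with pytest.raises(ValueError):
            filter_abundances(_mat([[1.0, 1.0]]))


class TestExprVarianceComponents:
    def _covariates(self, n_lib, seed=0, runs=4):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "farm": rng.integers(0, 3, n_lib).astype(str),
                "season_year": rng.integers(0, 6, n_lib).astype(str),
                "age": rng.integers(0, 3, n_lib).astype(str),
                "run": rng.integers(0, runs, n_lib).astype(str),
            },
            index=[f"L{i}" for i in range(n_lib)],
        )

    def test_gene_share_recovered(self):
        rng = np.random.default_rng(1)
        n_lib, n_gene = 30, 50
        cov = self._covariates(n_lib, seed=2)
        gene_eff = rng.normal(0, np.sqrt(0.8), n_gene)
        Y = gene_eff[:, None] + rng.normal(0, np.sqrt(0.2), (n_gene, n_lib))
        m = AbundanceMatrix(
            pd.DataFrame(Y, index=[f"g{j}" for j in range(n_gene)],
                         columns=cov.index),
            log2=True,
        )
        res = expr_variance_components(m, cov)
        # compare against the realized (finite-sample) gene-effect share
        realized = gene_eff.var(ddof=1) / (gene_eff.var(ddof=1) + 0.2)
        assert res.shares["gene"] == pytest.approx(realized, abs=0.05)
        assert res.explained == pytest.approx(realized, abs=0.07)

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(3)
        cov = self._covariates(20, seed=4)
        Y = rng.normal(0, 1, (30, 20))
        m = AbundanceMatrix(
            pd.DataFrame(Y, index=[f"g{j}" for j in range(30)], columns=cov.index),
            log2=True,
        )
        res = expr_variance_components(m, cov)
        assert sum(res.shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_null_interactions_near_boundary(self):
        rng = np.random.default_rng(5)
        n_lib, n_gene = 24, 40
        cov = self._covariates(n_lib, seed=6)
        gene_eff = rng.normal(0, 1.0, n_gene)
        Y = gene_eff[:, None] + rng.normal(0, 0.5, (n_gene, n_lib))
        m = AbundanceMatrix(
            pd.DataFrame(Y, index=[f"g{j}" for j in range(n_gene)], columns=cov.index),
            log2=True,
        )
        res = expr_variance_components(m, cov)
        for comp in ("gene_farm", "gene_year_season", "gene_age", "gene_run"):
            assert res.shares[comp] < 0.05

    def test_single_level_factor_dropped(self):
        rng = np.random.default_rng(7)
        cov = self._covariates(15, seed=8)
        cov["run"] = "r1"
        Y = rng.normal(0, 1, (20, 15))
        m = AbundanceMatrix(
            pd.DataFrame(Y, index=[f"g{j}" for j in range(20)], columns=cov.index),
            log2=True,
        )
        with pytest.warns(UserWarning, match="run"):
            res = expr_variance_components(m, cov)
        assert "gene_run" not in res.shares

    def test_constant_response_errors(self):
        cov = self._covariates(10, seed=9)
        m = AbundanceMatrix(
            pd.DataFrame(np.full((5, 10), 3.0), index=[f"g{j}" for j in range(5)],
                         columns=cov.index),
            log2=True,
        )
        with pytest.raises(ValueError):
            expr_variance_components(m, cov)


class TestCorrelateTraits:
    def _traits(self, arrs, n):
        return pd.DataFrame(arrs, index=[f"s{j}" for j in range(n)])

    def test_feature_equal_to_trait(self):
        vals = np.linspace(1, 5, 10)
        m = _mat([vals], log2=True)
        traits = self._traits({"MT_5": vals}, 10)
        out = correlate_traits(m, traits)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-10

    def test_textbook_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        # hand-oracle: r = cov / (sd_x sd_y)
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        m = _mat([x], log2=True)
        out = correlate_traits(m, self._traits({"T": y}, 5))
        assert out["r"].iloc[0] == pytest.approx(r_hand, abs=1e-12)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        traits = self._traits({"T": y}, 30)
        r_pos = correlate_traits(_mat([x], log2=True), traits)
        r_neg = correlate_traits(_mat([-x], log2=True), traits)
        assert r_neg["r"].iloc[0] == pytest.approx(-r_pos["r"].iloc[0])
        assert r_neg["p"].iloc[0] == pytest.approx(r_pos["p"].iloc[0])

    def test_null_pairs_flagged_at_nominal_rate(self):
        rng = np.random.default_rng(11)
        n, n_feat = 100, 400
        X = rng.normal(0, 1, (n_feat, n))
        traits = self._traits({"A": rng.normal(0, 1, n), "B": rng.normal(0, 1, n)}, n)
        m = _mat(X, log2=True)
        out = correlate_traits(m, traits)
        rate = out["significant"].mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_zero_variance_feature_skipped(self):
        m = _mat([[1.0] * 10, list(range(10))], log2=True)
        traits = self._traits({"T": np.arange(10) + 0.5}, 10)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = correlate_traits(m, traits)
        assert set(out["feature_id"]) == {"f1"}

    def test_counts_and_top_trait(self):
        rng = np.random.default_rng(12)
        n = 50
        t1 = rng.normal(0, 1, n)
        t2 = rng.normal(0, 1, n)
        feat = 0.9 * t1 + 0.3 * t2 + 0.1 * rng.normal(0, 1, n)
        m = _mat([feat], log2=True)
        traits = self._traits({"T1": t1, "T2": t2}, n)
        out = correlate_traits(m, traits)
        counts = significant_trait_counts(out)
        assert counts["f0"] >= 1
        assert top_trait(out)["f0"] == "T1"
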