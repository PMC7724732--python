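"""Phenotype adjustment, MLM association, BH-FDR and interval clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spermnet.datatypes import GenotypeMatrix
from spermnet.gwas import (
    adjust_phenotypes,
    bh_fdr,
    cluster_intervals,
    mlm_assoc,
)
from spermnet.relatedness import GRM, compute_grm

from conftest import make_genotypes


class TestAdjustPhenotypes:
    def _table(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "MT_5": rng.normal(70, 10, n),
                "MT_90": rng.normal(60, 12, n),
                "farm": rng.choice(["f1", "f2", "f3"], n),
                "season_year": rng.choice([f"sy{i}" for i in range(9)], n),
                "age": rng.choice(["a1", "a2", "a3"], n),
            },
            index=[f"b{i}" for i in range(n)],
        )

    def test_residuals_orthogonal_to_covariates(self):
        t = self._table()
        adj = adjust_phenotypes(t)
        for col in ("farm", "season_year", "age"):
            for level in t[col].unique():
                ind = (t[col] == level).astype(float)
                assert abs(np.dot(adj["MT_5"], ind)) < 1e-8

    def test_ratio_computed_before_adjustment(self):
        t = self._table()
        t["VIAB_90"] = 80.0
        t["VIAB_5"] = 80.0
        raw_ratio = (t["VIAB_90"] / t["VIAB_5"]).iloc[0]
        assert raw_ratio == pytest.approx(1.0)
        adj = adjust_phenotypes(t)
        assert "R_VIAB" in adj.columns

    def test_single_level_covariates_center_only(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(
            {
                "MT_5": rng.normal(70, 10, 20),
                "farm": ["f1"] * 20,
                "season_year": ["s1"] * 20,
                "age": ["a1"] * 20,
            }
        )
        adj = adjust_phenotypes(t)
        expected = t["MT_5"] - t["MT_5"].mean()
        assert np.allclose(adj["MT_5"], expected)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=8)
    )
    def test_matches_bruteforce_definition(self, pvals):
        """q_i = min over j with p_j >= p_i of m * p_j / rank_j."""
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        rank = np.empty(m, dtype=int)
        rank[order] = np.arange(1, m + 1)
        brute = np.array(
            [min(min(m * p[j] / rank[j] for j in range(m) if p[j] >= p[i]), 1.0) for i in range(m)]
        )
        assert np.allclose(bh_fdr(p), brute, atol=1e-12)

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, 200)
        q_sm = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), q_sm, atol=1e-12)


class TestMlmAssoc:
    def _dataset(self, n=200, m=100, seed=3):
        geno = make_genotypes(n, m, seed=seed)
        rng = np.random.default_rng(seed + 1)
        cov = pd.DataFrame(
            {"farm": rng.choice(["f1", "f2"], n)}, index=geno.sample_ids
        )
        return geno, cov, rng

    def test_boundary_variance_equals_ols(self):
        geno, cov, _ = self._dataset()
        # family-structured GRM + pure-noise trait: the null REML fit lands
        # on the sigma_u2 = 0 boundary, so the scan must reduce to OLS
        rng = np.random.default_rng(1)
        y = pd.Series(rng.standard_normal(200), index=geno.sample_ids)
        fam = np.kron(np.eye(50), np.ones((4, 4)))
        grm = GRM(pd.DataFrame(fam, index=geno.sample_ids, columns=geno.sample_ids), 100)
        with pytest.warns(UserWarning, match="OLS"):
            scan = mlm_assoc(geno, y, cov, grm)
        # closed-form OLS for one SNP
        j = 0
        x = geno.dosages.iloc[:, j].to_numpy() - 1.0
        X = np.column_stack([np.ones(200), pd.get_dummies(cov["farm"], drop_first=True).to_numpy(dtype=float), x])
        beta_hat, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        resid = y.to_numpy() - X @ beta_hat
        s2 = resid @ resid / (200 - X.shape[1])
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[-1, -1])
        t = beta_hat[-1] / se
        p = 2 * stats.t.sf(abs(t), 200 - X.shape[1])
        assert scan["beta"].iloc[j] == pytest.approx(beta_hat[-1], rel=1e-8)
        assert scan["p"].iloc[j] == pytest.approx(p, rel=1e-6)

    def test_beta_invariant_to_trait_shift(self):
        geno, cov, rng = self._dataset(seed=4)
        grm = compute_grm(geno)
        base = rng.standard_normal(200)
        y1 = pd.Series(base, index=geno.sample_ids)
        y2 = pd.Series(base + 100.0, index=geno.sample_ids)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = mlm_assoc(geno, y1, cov, grm)
            s2 = mlm_assoc(geno, y2, cov, grm)
        assert np.allclose(s1["beta"], s2["beta"], atol=1e-8)

    def test_planted_effect_recovered(self):
        geno, cov, rng = self._dataset(n=300, m=300, seed=5)
        grm = compute_grm(geno)
        x = geno.dosages.iloc[:, 10].to_numpy()
        xs = (x - x.mean()) / x.std()
        y = pd.Series(0.5 * xs + rng.standard_normal(300), index=geno.sample_ids)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = mlm_assoc(geno, y, cov, grm)
        truth = 0.5 / x.std()  # per-allele effect
        row = scan.iloc[10]
        assert row["beta"] == pytest.approx(truth, abs=2 * row["se"])


class TestClusterIntervals:
    def _hits(self, positions, trait="HABN", chrom="1"):
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(positions))],
                "chrom": [chrom] * len(positions),
                "bp": positions,
                "p": np.linspace(1e-8, 1e-6, len(positions)),
                "trait": [trait] * len(positions),
            }
        )

    def test_two_intervals_with_singleton(self):
        ivs = cluster_intervals(self._hits([1_000_000, 3_000_000, 10_000_000]))
        assert len(ivs) == 2
        assert ivs[0].snp_ids == ["s0", "s1"]
        assert ivs[1].singleton

    def test_gap_exactly_5mbp_splits(self):
        ivs = cluster_intervals(self._hits([1_000_000, 6_000_000]))
        assert len(ivs) == 2

    def test_gap_just_under_5mbp_merges(self):
        ivs = cluster_intervals(self._hits([1_000_000, 5_999_999]))
        assert len(ivs) == 1

    def test_empty(self):
        assert cluster_intervals(pd.DataFrame(columns=["snp_id", "chrom", "bp", "p", "trait"])) == []

    def test_lead_has_min_p(self):
        rng = np.random.default_rng(6)
        hits = self._hits(list(rng.choice(np.arange(1, 60) * 1_000_000, 20, replace=False)))
        hits["p"] = rng.uniform(1e-10, 1e-4, 20)
        for iv in cluster_intervals(hits):
            member_p = hits.set_index("snp_id").loc[iv.snp_ids, "p"]
            assert hits.set_index("snp_id").loc[iv.lead_snp, "p"] == member_p.min()

    def test_unplaced_scaffolds_excluded(self):
        hits = self._hits([1_000_000, 2_000_000])
        hits.loc[1, "chrom"] = "scaffold_17"
        ivs = cluster_intervals(hits)
        assert len(ivs) == 1
        assert ivs[0].snp_ids == ["s0"]

    def test_matches_single_pass_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pos = sorted(rng.choice(np.arange(1, 200) * 500_000, size=rng.integers(2, 15), replace=False))
            ivs = cluster_intervals(self._hits(pos))
            # oracle: split sorted positions at gaps >= 5 Mbp
            groups, cur = [], [pos[0]]
            for a, b in zip(pos, pos[1:]):
                if b - a >= 5_000_000:
                    groups.append(cur)
                    cur = []
                cur.append(b)
            groups.append(cur)
            assert [len(iv.snp_ids) for iv in ivs] == [len(g) for g in groups]
            assert [(iv.start_bp, iv.end_bp) for iv in ivs] == [(g[0], g[-1]) for g in groups]
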