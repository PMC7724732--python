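"""RNA regression model (all-subsets, common-gene selection, stepwise)
and the SNP panel variance-explained estimator."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from spermnet.datatypes import AbundanceMatrix, Network
from spermnet.gwas import QtlInterval
from spermnet.prediction import (
    all_subsets_r2,
    build_snp_panel,
    candidate_gene_pool,
    panel_variance_explained,
    select_common_genes,
    stepwise_fit,
)
from spermnet.relatedness import compute_grm

from conftest import make_genotypes


def _pool(n_genes=4, n=50, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(1, 100, (n_genes, n))
    return pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n)])


class TestAllSubsets:
    def test_three_genes_seven_subsets(self):
        pool = _pool(3)
        y = pd.Series(np.random.default_rng(1).normal(0, 1, 50), index=pool.columns)
        table = all_subsets_r2(pool, y)
        assert len(table) == 7

    def test_single_gene_r2_is_squared_pearson(self):
        pool = _pool(2)
        rng = np.random.default_rng(2)
        y = pd.Series(0.5 * pool.loc["g0"] + rng.normal(0, 20, 50), index=pool.columns)
        table = all_subsets_r2(pool, y)
        single = table[table["subset"] == ("g0",)]["r2"].iloc[0]
        r = np.corrcoef(pool.loc["g0"], y)[0, 1]
        assert single == pytest.approx(r * r, abs=1e-10)

    def test_monotone_in_subset_inclusion(self):
        pool = _pool(4, seed=3)
        y = pd.Series(np.random.default_rng(4).normal(0, 1, 50), index=pool.columns)
        table = all_subsets_r2(pool, y).set_index("subset")
        for sub in table.index:
            for sup in table.index:
                if set(sub) < set(sup):
                    assert table.loc[[sup], "r2"].iloc[0] >= table.loc[[sub], "r2"].iloc[0] - 1e-10

    def test_best_subsets_match_bruteforce(self):
        pool = _pool(4, seed=5)
        rng = np.random.default_rng(6)
        y = pd.Series(
            2.0 * pool.loc["g1"] - 1.0 * pool.loc["g3"] + rng.normal(0, 30, 50),
            index=pool.columns,
        )
        table = all_subsets_r2(pool, y)

        # independent brute-force oracle
        def ols_r2(cols):
            X = np.column_stack([np.ones(50)] + [pool.loc[c] for c in cols])
            b, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
            res = y.to_numpy() - X @ b
            return 1 - (res @ res) / (((y - y.mean()) ** 2).sum())

        for size in (1, 2, 3, 4):
            best_row = table[table["size"] == size].sort_values("r2").iloc[-1]
            brute_best = max(
                itertools.combinations(pool.index, size), key=lambda c: ols_r2(c)
            )
            assert set(best_row["subset"]) == set(brute_best)

    def test_refuses_oversized_pool(self):
        pool = _pool(21)
        y = pd.Series(np.zeros(50), index=pool.columns)
        with pytest.raises(ValueError, match="20-gene"):
            all_subsets_r2(pool, y)


class TestSelectCommonGenes:
    def test_ubiquitous_gene_ranks_first(self):
        tables = {}
        for t in ("A", "B", "C"):
            tables[t] = pd.DataFrame(
                {
                    "subset": [("g0",), ("g1",), ("g0", "g1"), ("g0", "g2"), ("g0", "g1", "g2")],
                    "size": [1, 1, 2, 2, 3],
                    "r2": [0.5, 0.1, 0.7, 0.6, 0.8],
                }
            )
        out = select_common_genes(tables, k=1)
        assert out == ["g0"]

    def test_k_larger_than_pool_warns(self):
        tables = {"A": pd.DataFrame({"subset": [("g0",), ("g1",)], "size": [1, 1], "r2": [0.5, 0.2]})}
        with pytest.warns(UserWarning, match="pool"):
            out = select_common_genes(tables, k=5)
        assert out == ["g0", "g1"]

    def test_tally_matches_hand_count(self):
        t1 = pd.DataFrame(
            {"subset": [("a",), ("b",), ("a", "b"), ("b", "c")],
             "size": [1, 1, 2, 2], "r2": [0.6, 0.3, 0.5, 0.9]}
        )
        t2 = pd.DataFrame(
            {"subset": [("c",), ("a",), ("a", "c")],
             "size": [1, 1, 2], "r2": [0.7, 0.2, 0.9]}
        )
        # winners: t1 size1 -> (a), size2 -> (b,c); t2 size1 -> (c), size2 -> (a,c)
        # tally: a=2, b=1, c=3
        out = select_common_genes({"T1": t1, "T2": t2}, k=2)
        assert out == ["c", "a"]


class TestStepwise:
    def test_planted_single_predictor_recovered(self):
        pool = _pool(10, n=300, seed=7)
        rng = np.random.default_rng(8)
        y = pd.Series(2.0 * pool.loc["g4"] + rng.normal(0, 5, 300), index=pool.columns)
        model = stepwise_fit(pool, y, "T")
        assert "g4" in model.coefficients
        assert model.r2 > 0.95
        assert model.coefficients["g4"] == pytest.approx(2.0, rel=0.05)

    def test_pure_noise_low_entry(self):
        rng = np.random.default_rng(9)
        pool = _pool(10, n=300, seed=10)
        n_entered = 0
        n_reps = 40
        for rep in range(n_reps):
            y = pd.Series(rng.normal(0, 1, 300), index=pool.columns)
            model = stepwise_fit(pool, y, "T")
            n_entered += len(model.coefficients)
        # forward selection on the best of 10 null predictors admits the
        # extreme-order statistic, so the per-model entry count stays small
        assert n_entered / n_reps < 3.0

    def test_intercept_only_when_nothing_enters(self):
        pool = _pool(3, n=40, seed=11)
        y = pd.Series(np.zeros(40) + 5.0, index=pool.columns)
        model = stepwise_fit(pool, y, "T")
        assert model.coefficients == {}
        assert model.r2 == 0.0

    def test_matches_best_subset_with_strong_predictor(self):
        pool = _pool(4, n=100, seed=12)
        rng = np.random.default_rng(13)
        y = pd.Series(3.0 * pool.loc["g2"] + rng.normal(0, 2, 100), index=pool.columns)
        model = stepwise_fit(pool, y, "T")
        table = all_subsets_r2(pool, y)
        best = max(
            (row for _, row in table.iterrows()),
            key=lambda row: row["r2"] - 1e-6 * row["size"],
        )
        assert set(model.coefficients) <= set(best["subset"])
        assert "g2" in model.coefficients
        # stepwise R^2 cannot beat the best subset of the full pool
        assert model.r2 <= table["r2"].max() + 1e-12


class TestCandidatePool:
    def _final_net(self):
        net = Network()
        for g in ("g0", "g1", "g2", "g3"):
            net.add_node(g, "gene")
        net.add_edge("g0", "g1", 0.5, "rna")  # adjacent pair
        return net

    def _corr(self, gene_traits: dict):
        rows = []
        for g, k in gene_traits.items():
            rows += [(g, f"T{i}", 0.5, 0.01) for i in range(k)]
        df = pd.DataFrame(rows, columns=["feature_id", "trait", "r", "p"])
        df["significant"] = True
        return df

    def _abundance(self, zero_sample_for=None):
        rng = np.random.default_rng(14)
        vals = rng.uniform(1, 50, (4, 10))
        if zero_sample_for is not None:
            vals[zero_sample_for, 0] = 0.0
        return AbundanceMatrix(
            pd.DataFrame(vals, index=["g0", "g1", "g2", "g3"],
                         columns=[f"s{j}" for j in range(10)])
        )

    def test_adjacent_gene_skipped(self):
        pool = candidate_gene_pool(
            self._final_net(), self._corr({"g0": 5, "g1": 5, "g2": 4}),
            self._abundance(),
        )
        assert not ("g0" in pool and "g1" in pool)

    def test_zero_fpkm_sample_excluded(self):
        pool = candidate_gene_pool(
            self._final_net(), self._corr({"g0": 5, "g2": 4, "g3": 4}),
            self._abundance(zero_sample_for=2),
        )
        assert "g2" not in pool

    def test_three_trait_gene_excluded(self):
        pool = candidate_gene_pool(
            self._final_net(), self._corr({"g0": 5, "g2": 3, "g3": 4}),
            self._abundance(),
        )
        assert "g2" not in pool

    def test_manual_ranking_respected(self):
        pool = candidate_gene_pool(
            self._final_net(), self._corr({"g2": 4, "g3": 6}),
            self._abundance(), manual_list=["g2"], max_genes=1,
        )
        assert pool == ["g2"]

    def test_too_few_eligible_errors(self):
        with pytest.raises(ValueError):
            candidate_gene_pool(
                self._final_net(), self._corr({"g0": 5}), self._abundance()
            )


class TestSnpPanel:
    def _intervals(self):
        return [
            QtlInterval("1", 1, 2, ["sA", "sB"], "sA", "HABN", singleton=False),
            QtlInterval("2", 1, 2, ["sC", "sD"], "sC", "NABN", singleton=False),
            QtlInterval("3", 1, 1, ["sE"], "sE", "MT_5", singleton=True),
        ]

    def _scans(self, geno):
        rng = np.random.default_rng(15)
        return {
            "HABN": pd.DataFrame(
                {"snp_id": geno.snp_ids, "beta": 0.1, "se": 0.1,
                 "p": rng.uniform(0.2, 1, geno.n_snps), "q": 1.0}
            )
        }

    def test_fixture_panel_composition(self):
        geno = make_genotypes(30, 10, seed=16)
        smap = geno.snp_map.copy()
        egwas = pd.DataFrame(
            {"snp_id": ["s5"], "gene_id": ["gX"], "beta": [1.0],
             "p": [1e-8], "q": [1e-5], "cis_trans": ["trans"]}
        )
        shared = Network()
        shared.add_node("gY", "gene")
        corr = pd.DataFrame(
            [("gY", f"T{i}", 0.5, 0.01, True) for i in range(4)],
            columns=["feature_id", "trait", "r", "p", "significant"],
        )
        ann = pd.DataFrame(
            {"gene_id": ["gY"], "chrom": ["1"], "start": [6500], "end": [8500],
             "biotype": ["coding"], "tf_class": ["none"]}
        )
        # rename interval SNPs to exist in the map
        ivs = [
            QtlInterval("1", 1000, 2000, ["s0", "s1"], "s0", "HABN", False),
            QtlInterval("1", 9000, 10000, ["s8", "s9"], "s9", "NABN", False),
            QtlInterval("1", 3000, 3000, ["s2"], "s2", "MT_5", True),
        ]
        scans = self._scans(geno)
        panel = build_snp_panel(ivs, egwas, shared, corr, scans, smap, ann)
        # leads s0, s9; egwas s5; gY window covers bp 6500-8500 +- 2500
        assert "s0" in panel.snp_ids and "s9" in panel.snp_ids
        assert "s5" in panel.snp_ids
        assert "s2" not in panel.snp_ids  # singleton interval
        assert any("network_gene" in panel.sources[s] for s in panel.snp_ids)

    def test_deduplication_with_both_tags(self):
        geno = make_genotypes(30, 10, seed=17)
        ivs = [QtlInterval("1", 1000, 2000, ["s0", "s1"], "s0", "HABN", False)]
        egwas = pd.DataFrame(
            {"snp_id": ["s0"], "gene_id": ["gX"], "beta": [1.0],
             "p": [1e-8], "q": [1e-5], "cis_trans": ["trans"]}
        )
        empty_corr = pd.DataFrame(columns=["feature_id", "trait", "r", "p", "significant"])
        panel = build_snp_panel(
            ivs, egwas, Network(), empty_corr, {}, geno.snp_map,
            pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "biotype", "tf_class"]),
        )
        assert panel.snp_ids.count("s0") == 1
        assert panel.sources["s0"] == {"gwas_lead", "egwas_lead"}

    def test_empty_panel_errors(self):
        geno = make_genotypes(10, 3, seed=18)
        empty_corr = pd.DataFrame(columns=["feature_id", "trait", "r", "p", "significant"])
        with pytest.raises(ValueError):
            build_snp_panel(
                [], pd.DataFrame(columns=["snp_id", "gene_id", "p", "q"]),
                Network(), empty_corr, {}, geno.snp_map,
                pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "biotype", "tf_class"]),
            )


class TestPanelVariance:
    def test_causal_snp_variance_recovered(self):
        geno = make_genotypes(500, 300, seed=19)
        rng = np.random.default_rng(20)
        x = geno.dosages.iloc[:, 7].to_numpy()
        xs = (x - x.mean()) / x.std()
        # QTL explains 0.3 of the phenotypic variance
        y = np.sqrt(0.3) * xs + np.sqrt(0.7) * rng.standard_normal(500)
        traits = pd.DataFrame({"T": y}, index=geno.sample_ids)
        from spermnet.prediction import SnpPanel

        panel = SnpPanel(snp_ids=["s7"], sources={"s7": {"gwas_lead"}})
        out = panel_variance_explained(panel, geno, traits)
        est, se = out["var_explained"].iloc[0], out["se"].iloc[0]
        assert est == pytest.approx(0.3, abs=max(2 * se, 0.1))

    def test_null_panel_near_zero(self):
        geno = make_genotypes(400, 100, seed=21)
        rng = np.random.default_rng(22)
        traits = pd.DataFrame({"T": rng.standard_normal(400)}, index=geno.sample_ids)
        from spermnet.prediction import SnpPanel

        panel = SnpPanel(snp_ids=["s0", "s1", "s2"],
                         sources={s: {"gwas_lead"} for s in ("s0", "s1", "s2")})
        out = panel_variance_explained(panel, geno, traits)
        assert out["var_explained"].iloc[0] < 0.1

    def test_fractions_in_unit_interval(self, pipeline_result):
        pv = pipeline_result.panel_variance
        assert ((pv["var_explained"] >= 0) & (pv["var_explained"] <= 1)).all()
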