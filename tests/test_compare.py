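"""Comparative analytics: rank tests, trees, divergence, DM genes."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from bsmethpipe import compare, metrics
from bsmethpipe.simulate import SAMPLES, Genome

PLANTED_SPLIT = frozenset(
    [frozenset({"cult1", "cult2"}), frozenset({"wild1", "wild2"})]
)


def wilcoxon_enumeration_oracle(x, y) -> float:
    """Independent oracle: enumerate group assignments, U by direct pair counts."""
    pooled = list(x) + list(y)
    m = len(x)

    def ustat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    center = m * len(y) / 2.0
    obs = abs(ustat(list(x), list(y)) - center)
    hits = total = 0
    for idx in combinations(range(len(pooled)), m):
        sel = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in sel]
        total += 1
        if abs(ustat(xs, ys) - center) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_textbook_separated_samples(self):
        assert compare.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_give_one(self):
        assert compare.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0
        assert compare.wilcoxon_rank_sum([2, 2], [2, 2, 2]) == 1.0

    def test_equals_enumeration_oracle_over_all_small_shapes(self):
        """Full sweep of shapes m+n <= 12, with ties, vs the enumeration oracle."""
        rng = np.random.default_rng(12)
        for m in range(1, 11):
            for n in range(1, 12 - m + 1):
                for _ in range(3):
                    x = rng.integers(0, 6, m).astype(float)
                    y = rng.integers(0, 6, n).astype(float)
                    got = compare.wilcoxon_rank_sum(x, y)
                    want = wilcoxon_enumeration_oracle(x, y)
                    assert got == pytest.approx(want), (x, y)

    def test_large_sample_path_is_sane(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 60)
        y = rng.normal(2.0, 1, 60)
        p_shift = compare.wilcoxon_rank_sum(x, y)
        p_null = compare.wilcoxon_rank_sum(x, rng.normal(0, 1, 60))
        assert p_shift < 1e-9 < 0.05 < p_null
        with pytest.raises(ValueError):
            compare.wilcoxon_rank_sum([], [1.0])


class TestGeneGrouping:
    def _planted(self, n=100, seed=14):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n)]
        levels = pd.Series(0.0, index=genes)
        meth = genes[30:]
        levels[meth] = rng.uniform(0.01, 0.8, len(meth))
        # promoter methylation suppresses expression
        log2e = 8 - 5 * levels + rng.normal(0, 0.8, n)
        expression = pd.Series(np.power(2.0, log2e), index=genes)
        return levels, expression

    def test_quantile_groups_are_balanced_and_ordered(self):
        levels, expr = self._planted()
        res = compare.group_genes_by_methylation(levels, expr)
        assert [len(g) for g in res["groups"]] == [14] * 5
        assert len(res["unmethylated"]) == 30
        flat = [g for grp in res["groups"] for g in grp]
        assert sorted(flat + res["unmethylated"]) == sorted(levels.index)
        g1 = np.median(res["group_expression"][0])
        g5 = np.median(res["group_expression"][4])
        assert g5 < g1
        assert res["unmeth_vs_meth_p"] < 0.01

    def test_hundred_methylated_genes_make_five_groups_of_twenty(self):
        levels = pd.Series(np.linspace(0.01, 1, 100), index=[f"g{i}" for i in range(100)])
        expr = pd.Series(1.0, index=levels.index)
        res = compare.group_genes_by_methylation(levels, expr)
        assert [len(g) for g in res["groups"]] == [20] * 5

    def test_too_few_methylated_genes_is_an_error(self):
        levels = pd.Series([0, 0, 0.1, 0.2], index=list("abcd"))
        with pytest.raises(ValueError):
            compare.group_genes_by_methylation(levels, pd.Series(1.0, index=levels.index))


class TestMethylationExpressionProfile:
    def _bins(self, n_genes=80, n_bins=20, seed=15):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        bins = pd.DataFrame(rng.uniform(0, 1, (n_genes, n_bins)), index=genes)
        return rng, genes, bins

    def test_null_profile_is_flat_near_zero(self):
        rng, genes, bins = self._bins()
        expr = pd.Series(rng.lognormal(3, 1, len(genes)), index=genes)
        prof = compare.methylation_expression_correlation(bins, expr)
        assert prof["rho"].abs().max() < 0.35

    def test_planted_ttr_suppression_deeper_than_promoter(self):
        rng, genes, bins = self._bins()
        expr_log = 6 - 4.0 * bins[19] - 1.5 * bins[0] + rng.normal(0, 0.5, len(genes))
        expr = pd.Series(np.power(2.0, expr_log), index=genes)
        prof = compare.methylation_expression_correlation(bins, expr).set_index("bin")
        assert prof.loc[19, "rho"] < prof.loc[0, "rho"] < 0

    def test_exclusion_set_is_honoured(self):
        rng, genes, bins = self._bins()
        expr = pd.Series(1.0 + rng.uniform(size=len(genes)), index=genes)
        excluded = set(genes[:75])
        prof = compare.methylation_expression_correlation(bins, expr, exclude=excluded)
        assert (prof["n_genes"] <= 5).all()
        assert prof["rho"].isna().all()  # below the 10-gene minimum


class TestTrees:
    def test_identical_samples_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(16)
        v = rng.uniform(size=50)
        df = pd.DataFrame({"a": v, "b": v, "c": rng.uniform(size=50),
                           "d": rng.uniform(size=50)})
        newick, z = compare.correlation_tree(df)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        split = compare.tree_bipartition(newick)
        assert frozenset({"a", "b"}) in split

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(rng.uniform(size=(40, 4)), columns=list("abcd"))
        n1, _ = compare.correlation_tree(df)
        n2, _ = compare.correlation_tree(np.exp(3 * df))
        assert n1 == n2

    def test_constant_profile_names_the_offending_sample(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3],
                           "c": [2, 1, 3], "d": [3, 2, 1]})
        with pytest.raises(ValueError, match="'a'"):
            compare.correlation_tree(df)

    def test_expression_tree_recovers_group_structure(self, dm_study):
        expr = np.log2(dm_study.truth.expression + 1.0)
        newick, _ = compare.correlation_tree(expr)
        assert compare.tree_bipartition(newick) == PLANTED_SPLIT

    def test_nj_recovers_planted_topology_from_called_genotypes(self, dm_called):
        _, genotypes = dm_called
        newick = compare.nj_tree(genotypes)
        assert compare.tree_bipartition(newick) == PLANTED_SPLIT

    def test_identical_genotypes_give_star_tree(self):
        calls = pd.DataFrame({"contig": "c", "pos": range(10), "ref": "A",
                              "sample_base": "A", "status": "call"})
        dm = compare.p_distance_matrix({s: calls.copy() for s in SAMPLES})
        assert np.allclose(dm.data, 0.0)

    def test_nj_matches_least_squares_on_additive_distances(self):
        """4-taxon NJ equals exhaustive least-squares over the 3 topologies."""
        # additive distances on ((a,b),(c,d)) with internal branch 0.3
        ext = {"a": 0.1, "b": 0.2, "c": 0.15, "d": 0.25}
        internal = 0.3

        def dist(u, v):
            extra = internal if {u, v} not in ({"a", "b"}, {"c", "d"}) else 0.0
            return ext[u] + ext[v] + extra

        taxa = list("abcd")
        calls = {}
        n_pos = 2000
        # encode the distances as genotype tables via disagreement fractions
        rng = np.random.default_rng(18)
        seqs = {t: np.zeros(n_pos, dtype=int) for t in taxa}
        # simple additive construction: mutate independent blocks per branch
        blocks = {("a",): 0.1, ("b",): 0.2, ("c",): 0.15, ("d",): 0.25,
                  ("c", "d"): 0.3}
        start = 0
        for carriers, rate in blocks.items():
            k = int(rate * 1000)
            for t in carriers:
                seqs[t][start : start + k] = 1
            start += k
        for t in taxa:
            calls[t] = pd.DataFrame({"contig": "c", "pos": range(n_pos), "ref": "A",
                                     "sample_base": np.where(seqs[t], "G", "A"),
                                     "status": "call"})
        dmat = compare.p_distance_matrix(calls)
        # least-squares over the three resolved quartets on these distances
        def ls_cost(split):
            (p, q), (r, s) = split
            # fit via average path lengths (OLS on a quartet)
            d = dmat.between  # not used; manual below
            return (dmat[p, q] + dmat[r, s]) - 0.5 * (
                dmat[p, r] + dmat[p, s] + dmat[q, r] + dmat[q, s]
            )
        splits = [(("a", "b"), ("c", "d")), (("a", "c"), ("b", "d")),
                  (("a", "d"), ("b", "c"))]
        best = min(splits, key=ls_cost)  # four-point condition
        newick = compare.nj_tree(calls)
        got = compare.tree_bipartition(newick)
        want = frozenset([frozenset(best[0]), frozenset(best[1])])
        assert got == want == frozenset([frozenset("ab"), frozenset("cd")])


class TestDivergenceWindows:
    def _toy(self):
        """3 windows of 100 bp; hand-planted genotype differences."""
        genome = {"c": "A" * 300}
        windows = pd.DataFrame({"contig": "c", "start": [0, 100, 200],
                                "end": [100, 200, 300]})
        base = pd.DataFrame({"contig": "c", "pos": range(300), "ref": "A",
                             "sample_base": "A", "status": "call"})
        calls = {s: base.copy() for s in SAMPLES}
        # window 0: cult1 differs from everyone at 4 positions
        calls["cult1"].loc[10:13, "sample_base"] = "G"
        # window 2: wild pair shares a variant -> differs from cults only
        for s in ("wild1", "wild2"):
            calls[s].loc[250, "sample_base"] = "T"
        sites = {s: pd.DataFrame({"contig": "c", "pos": range(0), "strand": "+",
                                  "context": "CG", "n_meth": [], "n_total": [],
                                  "level": []}) for s in SAMPLES}
        return calls, sites, windows

    def test_pi_matches_per_base_pair_counting(self):
        calls, sites, windows = self._toy()
        div = compare.divergence_windows(calls, sites, windows)
        # window 0: cult1 vs 3 others x 4 positions = 12 diffs over 6 pairs x 100bp
        assert div.loc[0, "pi"] == pytest.approx(12 / 600)
        assert div.loc[1, "pi"] == 0.0
        # window 2: {w1,w2} vs {c1,c2}: 4 pairs x 1 position
        assert div.loc[2, "pi"] == pytest.approx(4 / 600)

    def test_no_snps_anywhere_gives_zero_pi(self):
        calls, sites, windows = self._toy()
        for s in SAMPLES:
            calls[s]["sample_base"] = "A"
        div = compare.divergence_windows(calls, sites, windows)
        assert (div["pi"] == 0).all()

    def test_methylation_correlation_uses_shared_deep_sites(self):
        calls, _, windows = self._toy()
        rng = np.random.default_rng(19)
        shared = rng.uniform(size=50)
        sites = {}
        for i, s in enumerate(SAMPLES):
            lv = np.clip(shared + rng.normal(0, 0.02, 50), 0, 1)
            sites[s] = pd.DataFrame({"contig": "c", "pos": np.arange(50), "strand": "+",
                                     "context": "CG", "n_meth": 5, "n_total": 10,
                                     "level": lv})
        div = compare.divergence_windows(calls, sites, windows)
        assert div.loc[0, "n_pairs"] == 6 and div.loc[0, "mean_spearman_r"] > 0.9
        assert np.isnan(div.loc[2, "mean_spearman_r"])  # no sites there

    def test_twenty_group_split_sizes_and_monotone_relation(self):
        rng = np.random.default_rng(20)
        pi = np.sort(rng.uniform(0, 0.01, 40))
        df = pd.DataFrame({"contig": "c", "start": range(40), "end": range(1, 41),
                           "pi": pi, "mean_spearman_r": 1 - 30 * pi
                           + rng.normal(0, 0.02, 40), "n_pairs": 6})
        groups = compare.divergence_vs_methylation(df)
        assert (groups["n_windows"] == 2).all() and len(groups) == 20
        assert groups["mean_pi"].is_monotonic_increasing
        assert (np.diff(groups["mean_r"]) < 0.05).all()
        with pytest.raises(ValueError):
            compare.divergence_vs_methylation(df.head(10))


class TestDmGenes:
    def test_low_coverage_region_excluded_and_label_swap_invariance(self, dm_study, dm_called):
        sites, _ = dm_called
        ann, genome = dm_study.annotation, dm_study.genome
        dm = compare.identify_dm_genes(sites, ann, genome, region_kinds=("promoter",))
        # dropping cult2's coverage of one detected gene's promoter removes it
        if len(dm):
            gid = dm.gene_id.iloc[0]
            g = ann.genes.set_index("gene_id").loc[gid]
            g = pd.Series({"contig": g.contig, "start": g.start, "end": g.end,
                           "strand": g.strand})
            contig, s, e = ann.region_span(g, "promoter")
            crippled = dict(sites)
            tab = sites["cult2"]
            inside = (tab.contig == contig) & (tab.pos >= s) & (tab.pos < e)
            keep = tab[~inside | (tab.pos < s + int(0.3 * (e - s)))]
            crippled["cult2"] = keep
            dm2 = compare.identify_dm_genes(crippled, ann, genome,
                                            region_kinds=("promoter",))
            assert gid not in set(dm2.gene_id)
        # swapping the two cultivated samples leaves the gene set unchanged
        swapped = dict(sites)
        swapped["cult1"], swapped["cult2"] = sites["cult2"], sites["cult1"]
        dm_sw = compare.identify_dm_genes(swapped, ann, genome,
                                          region_kinds=("promoter",))
        assert set(dm_sw.gene_id) == set(dm.gene_id)

    def test_overlap_degenerate_cases(self):
        pm = pd.DataFrame({s: [100.0, 200.0] for s in SAMPLES}, index=["g1", "g2"])
        empty = pd.DataFrame(columns=["gene_id", "region", "direction"])
        res = compare.dm_expression_overlap(empty, pm)
        assert res["n_overlap"] == 0 and res["n_dm_genes"] == 0
        # fold=1 counts every expressed DM gene
        dm = pd.DataFrame({"gene_id": ["g1"], "region": ["gene_body"],
                           "direction": ["up_in_cultivated"]})
        res = compare.dm_expression_overlap(dm, pm, fold=1.0)
        assert res["n_overlap"] == 1 and res["background_fraction"] == 1.0
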