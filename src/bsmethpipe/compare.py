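"""Cross-sample divergence and methylation-vs-expression analytics.

Covers: two-sample Wilcoxon rank-sum tests (exact by enumeration for small
samples, tie/continuity-corrected normal approximation otherwise), gene
grouping by region methylation with expression comparisons, per-bin
methylation-expression correlation profiles, correlation-distance
dendrograms and neighbour-joining p-distance trees over the four samples,
windowed genetic (pi) vs methylation (Spearman r) divergence, and the
differentially-methylated gene rule: significant in all four
cultivated-vs-wild comparisons with a consistent direction and
non-significant within both groups.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .simulate import GROUPS, SAMPLES

CULT_PAIRS = [("cult1", "wild1"), ("cult1", "wild2"), ("cult2", "wild1"), ("cult2", "wild2")]
WITHIN_PAIRS = [("cult1", "cult2"), ("wild1", "wild2")]
ALL_PAIRS = WITHIN_PAIRS + CULT_PAIRS


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def wilcoxon_rank_sum(x, y, exact_max_n: int = 20) -> float:
    """Two-sided two-sample Wilcoxon rank-sum p-value.

    Exact permutation enumeration of the U statistic when m + n <=
    ``exact_max_n`` (handles ties by enumerating over the tied ranks);
    otherwise the normal approximation with tie and continuity
    corrections.  Returns p in (0, 1]; completely tied data give 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if m + n <= exact_max_n:
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:m].sum() - m * (m + 1) / 2.0
        center = m * n / 2.0
        dev = abs(u_obs - center) - 1e-9
        hits = total = 0
        for idx in combinations(range(m + n), m):
            u = ranks[list(idx)].sum() - m * (m + 1) / 2.0
            total += 1
            if abs(u - center) >= dev:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))


# ---------------------------------------------------------------------------
# methylation vs expression


def group_genes_by_methylation(
    region_levels: pd.Series,
    expression: pd.Series,
    n_groups: int = 5,
    measure_name: str = "absolute_level",
) -> dict:
    """Split genes into unmethylated vs five methylation quantile groups.

    ``region_levels``: per-gene methylation level of one region kind.
    Methylated genes (level > 0) are ranked by level (ties broken by gene
    identifier) and cut into ``n_groups`` near-equal groups, group 1 lowest.
    Expression (log2(x+1) of per-million values) is compared between the
    unmethylated and methylated sets with the rank-sum test.
    """
    levels = region_levels.dropna()
    unmeth = sorted(levels.index[levels == 0])
    meth = levels[levels > 0]
    if len(meth) < n_groups:
        raise ValueError(f"need >= {n_groups} methylated genes, got {len(meth)}")
    order = sorted(meth.index, key=lambda g: (meth[g], g))
    groups = [list(chunk) for chunk in np.array_split(np.array(order, dtype=object), n_groups)]
    result = {
        "unmethylated": unmeth,
        "groups": groups,
        "measure": measure_name,
    }
    expr = np.log2(expression + 1.0)
    shared_u = [g for g in unmeth if g in expr.index]
    shared_m = [g for g in order if g in expr.index]
    if shared_u and shared_m:
        result["unmeth_vs_meth_p"] = wilcoxon_rank_sum(
            expr[shared_u].to_numpy(), expr[shared_m].to_numpy()
        )
    result["group_expression"] = [
        expr[[g for g in grp if g in expr.index]].to_numpy() for grp in groups
    ]
    return result


def methylation_expression_correlation(
    bin_levels: pd.DataFrame,
    expression: pd.Series,
    exclude: set[str] | None = None,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Per-bin Spearman rho between gene methylation and expression.

    ``bin_levels``: genes x bins matrix (one column per metagene bin).
    Genes in ``exclude`` contribute to no bin; bins with fewer than
    ``min_genes`` pairwise-complete genes give NaN.
    """
    genes = [g for g in bin_levels.index if g in expression.index]
    if exclude:
        genes = [g for g in genes if g not in exclude]
    sub = bin_levels.loc[genes]
    expr = np.log2(expression.loc[genes] + 1.0)
    rows = []
    for col in sub.columns:
        v = sub[col]
        ok = v.notna() & expr.notna()
        if ok.sum() >= min_genes and v[ok].nunique() > 1 and expr[ok].nunique() > 1:
            rho, p = stats.spearmanr(v[ok], expr[ok])
        else:
            rho, p = np.nan, np.nan
        rows.append((col, float(rho), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["bin", "rho", "p", "n_genes"])


# ---------------------------------------------------------------------------
# trees


def _spearman_distance_matrix(vectors: pd.DataFrame) -> np.ndarray:
    """1 - pairwise Spearman r over the sample columns."""
    samples = list(vectors.columns)
    for s in samples:
        col = vectors[s].dropna()
        if col.nunique() <= 1:
            raise ValueError(f"sample {s!r} has a constant profile; correlation undefined")
    k = len(samples)
    dm = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        sub = vectors[[samples[i], samples[j]]].dropna()
        rho, _ = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
        dm[i, j] = dm[j, i] = 1.0 - rho
    return dm


def correlation_tree(vectors: pd.DataFrame, method: str = "complete") -> tuple[str, np.ndarray]:
    """Agglomerative dendrogram on 1 - Spearman r distances; Newick output.

    ``vectors``: shared units (windows, sites, genes) x samples.
    """
    samples = list(vectors.columns)
    dm = _spearman_distance_matrix(vectors)
    condensed = dm[np.triu_indices(len(samples), k=1)]
    z = linkage(np.maximum(condensed, 0.0), method=method)
    tree = TreeNode.from_linkage_matrix(z, samples)
    return str(tree).strip(), z


def p_distance_matrix(genotypes: dict[str, pd.DataFrame]) -> DistanceMatrix:
    """Pairwise p-distance: differing genotypes / co-called positions."""
    samples = list(genotypes)
    indexed = {}
    for s, df in genotypes.items():
        calls = df[df["status"] == "call"] if "status" in df else df
        indexed[s] = calls.set_index(["contig", "pos"])["sample_base"]
    dm = np.zeros((len(samples), len(samples)))
    for i, j in combinations(range(len(samples)), 2):
        a, b = indexed[samples[i]], indexed[samples[j]]
        shared = a.index.intersection(b.index)
        if len(shared) == 0:
            raise ValueError(
                f"samples {samples[i]!r} and {samples[j]!r} share no called positions"
            )
        d = float((a.loc[shared].to_numpy() != b.loc[shared].to_numpy()).mean())
        dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=samples)


def nj_tree(genotypes: dict[str, pd.DataFrame]) -> str:
    """Unrooted neighbour-joining Newick from genotype p-distances."""
    dm = p_distance_matrix(genotypes)
    return str(nj(dm)).strip()


def tree_bipartition(newick: str, taxa=SAMPLES) -> frozenset[frozenset[str]]:
    """The non-trivial split of a 4-taxon tree, for topology checks."""
    tree = TreeNode.read([newick])
    names = {t.name for t in tree.tips()}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(names) - 2:
            return frozenset([side, frozenset(names - side)])
    # fall back: root partition for rooted dendrograms
    children = tree.children
    if len(children) == 2:
        side = frozenset(t.name for t in children[0].tips())
        return frozenset([side, frozenset(names - side)])
    raise ValueError("tree has no non-trivial split")


# ---------------------------------------------------------------------------
# windowed divergence


def divergence_windows(
    genotypes: dict[str, pd.DataFrame],
    site_tables: dict[str, pd.DataFrame],
    windows: pd.DataFrame,
    min_depth: int = 5,
    min_shared_sites: int = 10,
) -> pd.DataFrame:
    """Per-window pi and mean pairwise methylation Spearman r.

    pi = summed differing co-called positions over the 6 sample pairs,
    divided by 6 x window length (positions not co-called count as
    non-differing).  r averages the per-pair Spearman correlation of
    per-cytosine levels with >= ``min_depth`` coverage in both samples;
    pairs with fewer than ``min_shared_sites`` shared sites are omitted.
    """
    pairs = list(combinations(list(genotypes), 2))
    geno = {}
    for s, df in genotypes.items():
        calls = df[df["status"] == "call"] if "status" in df else df
        geno[s] = calls.set_index(["contig", "pos"])["sample_base"]
    diff_positions = {}
    for a, b in pairs:
        shared = geno[a].index.intersection(geno[b].index)
        diffs = shared[geno[a].loc[shared].to_numpy() != geno[b].loc[shared].to_numpy()]
        diff_positions[(a, b)] = {
            contig: np.sort(np.array([p for c, p in diffs if c == contig]))
            for contig in {c for c, _ in diffs}
        }
    lev = {}
    for s, df in site_tables.items():
        deep = df[df["n_total"] >= min_depth]
        lev[s] = deep.set_index(["contig", "pos", "strand"])["level"]

    rows = []
    for w in windows.itertuples():
        length = w.end - w.start
        total_diffs = 0
        for pr in pairs:
            arr = diff_positions[pr].get(w.contig)
            if arr is not None and arr.size:
                total_diffs += int(
                    np.searchsorted(arr, w.end) - np.searchsorted(arr, w.start)
                )
        pi = total_diffs / (len(pairs) * length)
        rs = []
        for a, b in pairs:
            la, lb = lev[a], lev[b]
            shared = la.index.intersection(lb.index)
            if len(shared) == 0:
                continue
            sel = [
                k for k in shared if k[0] == w.contig and w.start <= k[1] < w.end
            ]
            if len(sel) < min_shared_sites:
                continue
            va, vb = la.loc[sel].to_numpy(), lb.loc[sel].to_numpy()
            if np.unique(va).size > 1 and np.unique(vb).size > 1:
                rho, _ = stats.spearmanr(va, vb)
                rs.append(rho)
        rows.append(
            (w.contig, w.start, w.end, pi, float(np.mean(rs)) if rs else np.nan, len(rs))
        )
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "pi", "mean_spearman_r", "n_pairs"]
    )


def divergence_vs_methylation(windows: pd.DataFrame, n_groups: int = 20) -> pd.DataFrame:
    """Windows sorted by pi and split into equal-count groups.

    Remainder windows are spread over the first groups so group sizes
    differ by at most one; per-group mean pi and mean r are reported.
    """
    if len(windows) < n_groups:
        raise ValueError(f"need >= {n_groups} windows, got {len(windows)}")
    ordered = windows.sort_values(["pi", "contig", "start"], kind="mergesort")
    chunks = np.array_split(np.arange(len(ordered)), n_groups)
    rows = []
    for g, idx in enumerate(chunks, start=1):
        sub = ordered.iloc[idx]
        rows.append(
            (g, len(sub), float(sub["pi"].mean()), float(sub["mean_spearman_r"].mean()))
        )
    return pd.DataFrame(rows, columns=["group", "n_windows", "mean_pi", "mean_r"])


# ---------------------------------------------------------------------------
# differentially methylated genes


def _region_site_levels(
    sites: pd.DataFrame, contig: str, start: int, end: int, context: str | None = None
) -> np.ndarray:
    sub = sites[(sites["contig"] == contig) & (sites["pos"] >= start) & (sites["pos"] < end)]
    if context is not None:
        sub = sub[sub["context"] == context]
    return sub["level"].to_numpy()


def identify_dm_genes(
    site_tables: dict[str, pd.DataFrame],
    annotation,
    genome,
    region_kinds: tuple[str, ...] = ("promoter", "gene_body", "TTR"),
    alpha: float = 0.05,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Differentially methylated genes between cultivated and wild pairs.

    Per gene and region: every sample must cover more than ``min_coverage``
    of the region's cytosine sites; the per-cytosine level vectors of the
    covered sites feed all six pairwise rank-sum tests.  A gene is DM when
    all four cultivated-vs-wild tests are significant with one direction
    (sign of the mean-level difference) and both within-group tests are
    not.  Returns one row per (gene, region) hit plus the de-duplicated
    union flag.
    """
    from .metrics import SiteArrays

    arrays = {s: SiteArrays(df, genome) for s, df in site_tables.items()}
    samples = list(site_tables)
    rows = []
    for _, g in annotation.genes.iterrows():
        for kind in region_kinds:
            contig, start, end = annotation.region_span(g, kind)
            covs = {}
            for s in samples:
                _, n_c, n_cov = arrays[s].region_sums(contig, start, end)
                covs[s] = n_cov / n_c if n_c else 0.0
            if any(c <= min_coverage for c in covs.values()):
                continue
            vecs = {
                s: _region_site_levels(site_tables[s], contig, start, end) for s in samples
            }
            if any(len(v) == 0 for v in vecs.values()):
                continue
            pvals = {
                pr: wilcoxon_rank_sum(vecs[pr[0]], vecs[pr[1]]) for pr in ALL_PAIRS
            }
            cross_sig = all(pvals[pr] < alpha for pr in CULT_PAIRS)
            within_ns = all(pvals[pr] >= alpha for pr in WITHIN_PAIRS)
            signs = [np.mean(vecs[a]) - np.mean(vecs[b]) for a, b in CULT_PAIRS]
            consistent = all(s > 0 for s in signs) or all(s < 0 for s in signs)
            if cross_sig and within_ns and consistent:
                direction = "up_in_cultivated" if signs[0] > 0 else "down_in_cultivated"
                rows.append(
                    (g.gene_id, kind, direction, *[pvals[pr] for pr in ALL_PAIRS],
                     *[covs[s] for s in samples])
                )
    cols = (
        ["gene_id", "region", "direction"]
        + [f"p_{a}_{b}" for a, b in ALL_PAIRS]
        + [f"coverage_{s}" for s in samples]
    )
    return pd.DataFrame(rows, columns=cols)


def dm_expression_overlap(
    dm_genes: pd.DataFrame,
    per_million: pd.DataFrame,
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> dict:
    """Fraction of DM genes with a methylation-consistent expression change.

    Promoter/TTR methylation up in cultivated is expected to lower
    cultivated expression (and vice versa); gene-body DM counts with a
    >= ``fold`` change in either direction.  Also reports the background
    fraction of all quantified genes changing >= ``fold``.
    """
    cult = [s for s in per_million.columns if GROUPS.get(s) == "cult"]
    wild = [s for s in per_million.columns if GROUPS.get(s) == "wild"]
    mean_c = per_million[cult].mean(axis=1) + pseudocount
    mean_w = per_million[wild].mean(axis=1) + pseudocount
    ratio = mean_c / mean_w
    background = float(((ratio >= fold) | (ratio <= 1 / fold)).mean()) if len(ratio) else 0.0
    hits = []
    for row in dm_genes.itertuples():
        if row.gene_id not in ratio.index:
            continue
        r = ratio[row.gene_id]
        if row.region in ("promoter", "TTR"):
            expected_down = row.direction == "up_in_cultivated"
            ok = r <= 1 / fold if expected_down else r >= fold
        else:
            ok = r >= fold or r <= 1 / fold
        if ok:
            hits.append(row.gene_id)
    n_dm = int(dm_genes["gene_id"].nunique()) if len(dm_genes) else 0
    return {
        "n_dm_genes": n_dm,
        "n_overlap": len(set(hits)),
        "overlap_fraction": len(set(hits)) / n_dm if n_dm else 0.0,
        "background_fraction": background,
    }
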