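"""Region- and window-level methylation quantities.

Two region summaries are used throughout: the *absolute* methylation level
(sum of mC site levels divided by region length in bp) and the *relative*
level (the same sum divided by the number of cytosine sites in the
region), so ``absolute = relative * n_c_sites / length`` holds exactly for
every region.  On top of these: genome sliding windows (50 kb / 25 kb by
default), metagene and TE percent-coordinate profiles (overlapping 5%
windows at 2.5% steps -> 39 body bins), TE/smRNA base density, level vs
length rank correlations, and the cross-sample coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seq import CONTEXTS, context_codes, cytosine_strands
from .simulate import Annotation, Genome

N_BODY_BINS = 39  # floor((100 - 5) / 2.5) + 1 for the 5% / 2.5% scheme


@dataclass
class RegionMethylation:
    region_id: str
    kind: str
    contig: str
    start: int
    end: int
    strand: str
    absolute_level: float
    relative_level: float
    n_c_sites: int
    n_covered_c_sites: int
    length: int

    @property
    def coverage_fraction(self) -> float:
        return self.n_covered_c_sites / self.n_c_sites if self.n_c_sites else 0.0


class SiteArrays:
    """Per-contig prefix-sum caches over a called site table.

    Collapses both strands onto plus coordinates: per position, the summed
    level of called mCs, the number of cytosine sites, and the number of
    covered cytosine sites — each split by context for filtering.  Region
    sums then cost O(1).
    """

    def __init__(self, sites: pd.DataFrame, genome: Genome | dict[str, str]):
        seqs = genome.seqs if isinstance(genome, Genome) else genome
        self._cum = {}
        for contig, seq in seqs.items():
            n = len(seq)
            mask_p, mask_m = cytosine_strands(seq)
            ctx_p, ctx_m = context_codes(seq)
            c_sites = np.zeros((4, n), dtype=np.int32)
            for mask, ctx in ((mask_p, ctx_p), (mask_m, ctx_m)):
                pos = np.flatnonzero(mask)
                np.add.at(c_sites, (ctx[pos], pos), 1)
            covered = np.zeros((4, n), dtype=np.int32)
            levels = np.zeros((4, n), dtype=float)
            sub = sites[sites["contig"] == contig]
            if len(sub):
                ctx_codes = pd.Categorical(sub["context"], categories=CONTEXTS).codes
                pos = sub["pos"].to_numpy()
                np.add.at(covered, (ctx_codes, pos), 1)
                if "is_mC" in sub:
                    mc = sub["is_mC"].to_numpy().astype(bool)
                    np.add.at(levels, (ctx_codes[mc], pos[mc]), sub["level"].to_numpy()[mc])
            self._cum[contig] = tuple(
                np.concatenate([np.zeros((4, 1), a.dtype), np.cumsum(a, axis=1)], axis=1)
                for a in (levels, c_sites, covered)
            )

    def region_sums(self, contig: str, start: int, end: int, context: str | None = None):
        """(sum of mC levels, n_c_sites, n_covered) within [start, end)."""
        levels, c_sites, covered = self._cum[contig]
        start = max(start, 0)
        end = min(end, levels.shape[1] - 1)
        if end <= start:
            return 0.0, 0, 0
        if context is None:
            rows = slice(0, 4)
            agg = lambda a: float(a[rows, end].sum() - a[rows, start].sum())
        else:
            row = CONTEXTS.index(context)
            agg = lambda a: float(a[row, end] - a[row, start])
        return agg(levels), int(agg(c_sites)), int(agg(covered))


def region_levels(
    arrays: SiteArrays,
    region_id: str,
    kind: str,
    contig: str,
    start: int,
    end: int,
    strand: str = "+",
    context: str | None = None,
) -> RegionMethylation:
    """Absolute and relative methylation of one region (both DNA strands)."""
    if end <= start:
        raise ValueError(f"zero-length region {region_id}")
    total, n_c, n_cov = arrays.region_sums(contig, start, end, context)
    length = end - start
    return RegionMethylation(
        region_id=region_id,
        kind=kind,
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        absolute_level=total / length,
        relative_level=total / n_c if n_c else 0.0,
        n_c_sites=n_c,
        n_covered_c_sites=n_cov,
        length=length,
    )


def gene_region_table(
    arrays: SiteArrays,
    annotation: Annotation,
    kinds: tuple[str, ...] = ("promoter", "gene_body", "TTR"),
    context: str | None = None,
) -> pd.DataFrame:
    """Region methylation for every gene x region kind, as one DataFrame."""
    rows = []
    for _, g in annotation.genes.iterrows():
        for kind in kinds:
            contig, s, e = annotation.region_span(g, kind)
            rm = region_levels(arrays, g.gene_id, kind, contig, s, e, g.strand, context)
            rows.append(
                (g.gene_id, kind, contig, s, e, g.strand, rm.absolute_level,
                 rm.relative_level, rm.n_c_sites, rm.n_covered_c_sites, rm.length,
                 rm.coverage_fraction)
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "kind", "contig", "start", "end", "strand", "absolute_level",
                 "relative_level", "n_c_sites", "n_covered_c_sites", "length",
                 "coverage_fraction"],
    )


def sliding_windows(
    contig_lengths: dict[str, int], window: int = 50_000, step: int = 25_000
) -> pd.DataFrame:
    """Half-open window spans tiling each contig.

    Starts run at multiples of ``step``; emission stops after the first
    window that reaches the contig end, so a contig shorter than the window
    yields a single whole-contig span and no emitted window is a subset of
    its predecessor.
    """
    rows = []
    for contig, length in contig_lengths.items():
        start = 0
        while start < length:
            end = min(start + window, length)
            rows.append((contig, start, end))
            if end >= length:
                break
            start += step
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def window_levels(
    arrays: SiteArrays, windows: pd.DataFrame, context: str | None = None
) -> pd.DataFrame:
    out = windows.copy()
    vals = [
        arrays.region_sums(w.contig, w.start, w.end, context) for w in windows.itertuples()
    ]
    out["absolute_level"] = [v[0] / (w.end - w.start) for v, w in zip(vals, windows.itertuples())]
    out["relative_level"] = [v[0] / v[1] if v[1] else 0.0 for v in vals]
    out["n_c_sites"] = [v[1] for v in vals]
    out["n_covered_c_sites"] = [v[2] for v in vals]
    return out


@dataclass
class MetageneProfile:
    """Pooled percent-coordinate profile: flank / body / flank bins."""

    bins: pd.DataFrame  # segment, bin, absolute_level, relative_level, ...
    n_regions: int


def _bin_edges(length: int, pct_width: float = 5.0, pct_step: float = 2.5) -> list[tuple[int, int]]:
    n_bins = int((100.0 - pct_width) / pct_step) + 1
    edges = []
    for i in range(n_bins):
        lo = int(np.floor(length * (i * pct_step) / 100.0))
        hi = int(np.ceil(length * (i * pct_step + pct_width) / 100.0))
        edges.append((lo, max(hi, lo + 1)))
    return edges


def metagene_profile(
    arrays: SiteArrays,
    regions: pd.DataFrame,
    flank: int = 2000,
    context: str | None = None,
    min_length: int = 40,
) -> MetageneProfile:
    """Pooled metagene/TE profile over upstream flank, body and downstream flank.

    Each region is rescaled to percent coordinates and binned with the
    overlapping 5%-window / 2.5%-step scheme (39 bins per segment); flanks
    use the same scheme over their own length.  Minus-strand regions are
    flipped so bins run 5'->3'.  Regions shorter than ``min_length`` are
    skipped (degenerate bins).
    """
    segs = ("upstream", "body", "downstream")
    sums = {s: np.zeros((3, N_BODY_BINS)) for s in segs}  # levels, c_sites, bp
    n_used = 0
    for r in regions.itertuples():
        length = r.end - r.start
        if length < min_length:
            continue
        n_used += 1
        strand = getattr(r, "strand", "+")
        spans = {
            "upstream": (r.start - flank, r.start) if strand == "+" else (r.end, r.end + flank),
            "body": (r.start, r.end),
            "downstream": (r.end, r.end + flank) if strand == "+" else (r.start - flank, r.start),
        }
        for seg in segs:
            s0, e0 = spans[seg]
            seg_len = e0 - s0
            for b, (lo, hi) in enumerate(_bin_edges(seg_len)):
                if strand == "+":
                    bs, be = s0 + lo, s0 + hi
                else:
                    bs, be = e0 - hi, e0 - lo
                lv, nc, _ = arrays.region_sums(r.contig, bs, be, context)
                sums[seg][0, b] += lv
                sums[seg][1, b] += nc
                sums[seg][2, b] += be - bs
    rows = []
    for seg in segs:
        for b in range(N_BODY_BINS):
            lv, nc, bp = sums[seg][:, b]
            rows.append(
                (seg, b, lv / bp if bp else 0.0, lv / nc if nc else 0.0, int(nc), int(bp))
            )
    bins = pd.DataFrame(
        rows, columns=["segment", "bin", "absolute_level", "relative_level", "n_c_sites", "bp"]
    )
    return MetageneProfile(bins=bins, n_regions=n_used)


def feature_density(
    features: pd.DataFrame, spans: pd.DataFrame, contig_lengths: dict[str, int]
) -> np.ndarray:
    """Per-span fraction of bases covered by the feature intervals."""
    masks = {c: np.zeros(n + 1, dtype=np.int32) for c, n in contig_lengths.items()}
    for f in features.itertuples():
        masks[f.contig][max(f.start, 0)] += 1
        masks[f.contig][min(f.end, contig_lengths[f.contig])] -= 1
    cum = {
        c: np.concatenate([[0], np.cumsum(np.cumsum(m[:-1]) > 0)]) for c, m in masks.items()
    }
    out = np.zeros(len(spans))
    for i, s in enumerate(spans.itertuples()):
        lo, hi = max(s.start, 0), min(s.end, contig_lengths[s.contig])
        out[i] = (cum[s.contig][hi] - cum[s.contig][lo]) / (s.end - s.start)
    return out


def length_methylation_correlation(regions: pd.DataFrame) -> dict[str, float]:
    """Spearman rho of region length vs absolute and vs relative level."""
    if len(regions) < 3:
        raise ValueError("need at least 3 regions for a rank correlation")
    out = {}
    for measure in ("absolute_level", "relative_level"):
        rho, p = stats.spearmanr(regions["length"], regions[measure])
        out[measure] = float(rho)
        out[measure + "_p"] = float(p)
    return out


def cv_stats(levels: pd.DataFrame) -> pd.DataFrame:
    """Cross-sample mean, sd (n-1 denominator) and CV per unit.

    ``levels``: units x samples.  Units with mean 0 have undefined CV and
    are dropped.
    """
    mean = levels.mean(axis=1)
    sd = levels.std(axis=1, ddof=1)
    out = pd.DataFrame({"mean": mean, "sd": sd})
    out = out[out["mean"] > 0]
    out["cv"] = out["sd"] / out["mean"]
    return out


def level_cv_correlation(cv_table: pd.DataFrame) -> tuple[float, float]:
    """Spearman rho of log2 mean level vs log2 CV over positive pairs."""
    ok = (cv_table["mean"] > 0) & (cv_table["cv"] > 0)
    sub = cv_table[ok]
    if len(sub) < 3:
        raise ValueError("need at least 3 positive (level, CV) pairs")
    rho, p = stats.spearmanr(np.log2(sub["mean"]), np.log2(sub["cv"]))
    return float(rho), float(p)
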