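"""SAGE-style DGE tag quantification.

A reference tag database holds every CATG + 17 nt tag derivable from the
full-length cDNA set; sequenced 21-nt tags are counted per gene by exact,
unique matches only, and gene expression is the total count of a gene's
unique tags, normalised to tags per million.  A rank diagnostic reports
how many tags map to the 3'-most CATG site versus internal sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .simulate import tag_sites

TAG_LENGTH = 21
AMBIGUOUS = "__AMBIGUOUS__"


@dataclass
class TagDatabase:
    """Exact 21-mer tag -> gene map with per-gene 3'-rank bookkeeping."""

    tags: dict[str, str]  # tag -> gene_id or AMBIGUOUS
    # gene -> list of (cdna position, rank from 3' end starting at 1)
    sites: dict[str, list[tuple[int, int]]]
    has_catg: dict[str, bool]
    # (gene, tag) -> rank of the site the tag came from (unique tags only)
    tag_rank: dict[str, int] = field(default_factory=dict)


def build_tag_database(cdnas: dict[str, str]) -> TagDatabase:
    """All possible CATG + 17 nt tags from the cDNA set.

    A tag occurring in more than one gene is flagged ambiguous; a tag
    occurring at several sites of the same gene keeps its 3'-most rank.
    """
    tags: dict[str, str] = {}
    sites: dict[str, list[tuple[int, int]]] = {}
    has_catg: dict[str, bool] = {}
    rank_of: dict[str, int] = {}
    for gene, seq in cdnas.items():
        positions = tag_sites(seq)
        has_catg[gene] = bool(positions)
        ranked = [(pos, len(positions) - i) for i, pos in enumerate(positions)]
        sites[gene] = ranked
        for pos, rank in ranked:
            tag = seq[pos : pos + TAG_LENGTH]
            if tag in tags and tags[tag] != gene:
                tags[tag] = AMBIGUOUS
                rank_of.pop(tag, None)
            elif tags.get(tag) == gene:
                rank_of[tag] = min(rank_of[tag], rank)
            else:
                tags[tag] = gene
                rank_of[tag] = rank
    return TagDatabase(tags=tags, sites=sites, has_catg=has_catg, tag_rank=rank_of)


@dataclass
class ExpressionProfile:
    counts: pd.Series  # gene -> raw unique-tag count
    per_million: pd.Series
    library_size: int  # total counted (uniquely mapped) tags
    stats: dict


def map_tags(reads: Iterable[str], db: TagDatabase) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Exact-match tag counting.

    ``reads`` are raw tag sequences (>= 21 nt; only the first 21 are
    looked up).  Returns per-gene counts, a per-(gene, rank) tag tally, and
    conservation stats: mapped + ambiguous + absent + too_short = input.
    """
    counts: dict[str, int] = {}
    rank_counts: dict[tuple[str, int], int] = {}
    stats = {"input": 0, "mapped": 0, "ambiguous": 0, "absent": 0, "too_short": 0}
    for read in reads:
        stats["input"] += 1
        if len(read) < TAG_LENGTH:
            stats["too_short"] += 1
            continue
        tag = read[:TAG_LENGTH]
        gene = db.tags.get(tag)
        if gene is None:
            stats["absent"] += 1
        elif gene == AMBIGUOUS:
            stats["ambiguous"] += 1
        else:
            stats["mapped"] += 1
            counts[gene] = counts.get(gene, 0) + 1
            rank = db.tag_rank.get(tag, 0)
            rank_counts[(gene, rank)] = rank_counts.get((gene, rank), 0) + 1
    count_series = pd.Series(counts, dtype=int).sort_index()
    ranks = pd.DataFrame(
        [(g, r, n) for (g, r), n in sorted(rank_counts.items())],
        columns=["gene_id", "rank", "count"],
    )
    return count_series, ranks, stats


def normalize_per_million(counts: pd.Series) -> pd.Series:
    """Tags-per-million values; scale-invariant in the library size."""
    total = int(counts.sum())
    if total == 0:
        raise ValueError("cannot normalise an empty tag library")
    return counts * 1e6 / total


def expression_profile(reads: Iterable[str], db: TagDatabase) -> ExpressionProfile:
    counts, _, stats = map_tags(reads, db)
    total = int(counts.sum())
    pm = normalize_per_million(counts) if total else counts.astype(float)
    return ExpressionProfile(counts=counts, per_million=pm, library_size=total, stats=stats)


def tag_position_distribution(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Histogram of tag counts and supported-gene counts per 3'-site rank."""
    if not len(rank_table):
        return pd.DataFrame(columns=["rank", "tag_count", "gene_count"])
    grouped = rank_table.groupby("rank").agg(
        tag_count=("count", "sum"), gene_count=("gene_id", "nunique")
    )
    return grouped.reset_index()
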