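"""Homozygous genotype calling from bisulfite reads.

Bisulfite conversion destroys half of the base information per strand
(C->T on the read's own strand), but reads mapped to the T-genome carry
the plus strand's sequence and reads mapped to the A-genome carry the
minus strand's, so every homozygous genotype is still resolvable from one
of the two strands: sample alleles A and G are trusted only from the plus
strand (where conversion cannot create them) and alleles C and T only from
the minus strand (where, expressed in plus sense, conversion cannot create
them).  Consensus bases in the conversion-ambiguous set for a stratum are
never used as deciding evidence.

All coordinates and bases here are plus-strand sense; minus-origin read
bases have already been projected by the aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .seq import BASES, qual_to_phred_array, seq_to_array
from .simulate import Genome

PLUS_RESOLVABLE = frozenset("AG")
MINUS_RESOLVABLE = frozenset("CT")

GENOTYPE_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "sample_base",
    "strand_used",
    "depth_used",
    "status",
    "is_snp",
]


@dataclass
class GenotypeCall:
    contig: str
    pos: int
    ref_base: str
    sample_base: str
    strand_used: Literal["+", "-"]
    depth_used: int

    @property
    def is_snp(self) -> bool:
        return self.sample_base != self.ref_base


def strand_pileups(
    records: Iterable[AlignmentRecord],
    genome: Genome | dict[str, str],
    q_min: int = 30,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-contig (plus_counts, minus_counts) arrays of shape (4, length).

    Rows index A,C,G,T (plus-strand sense); the two strata are the disjoint
    sets of plus-origin and minus-origin reads.  Only bases with quality >=
    ``q_min`` are counted; overlapping mates count once.
    """
    seqs = genome.seqs if isinstance(genome, Genome) else genome
    piles = {
        c: (np.zeros((4, len(s)), dtype=np.int32), np.zeros((4, len(s)), dtype=np.int32))
        for c, s in seqs.items()
    }
    codes = {ord(b): i for i, b in enumerate(BASES)}
    for rec in records:
        stratum = 0 if rec.origin_strand == "+" else 1
        target = piles[rec.contig][stratum]
        for start, bases, quals in rec.segments():
            if not bases:
                continue
            arr = seq_to_array(bases)
            q = qual_to_phred_array(quals)
            for base_ord, row in codes.items():
                sel = (arr == base_ord) & (q >= q_min)
                if sel.any():
                    np.add.at(target[row], np.flatnonzero(sel) + start, 1)
    return piles


def strand_consensus(
    counts: dict[str, int] | np.ndarray, min_depth: int = 5, min_fraction: float = 0.9
) -> str | None:
    """Majority base of one stratum, or None when depth/purity is short."""
    if isinstance(counts, dict):
        vec = np.array([counts.get(b, 0) for b in BASES], dtype=float)
    else:
        vec = np.asarray(counts, dtype=float)
    depth = vec.sum()
    if depth < min_depth:
        return None
    top = int(vec.argmax())
    if vec[top] / depth < min_fraction:
        return None
    return BASES[top]


def resolve_genotype(
    plus_consensus: str | None,
    minus_consensus: str | None,
    ref_base: str,
) -> tuple[str, Literal["+", "-"]] | Literal["no-call", "conflict"]:
    """The strand-resolution rule.

    Plus-strand consensus decides when it is A or G; otherwise the
    minus-strand consensus decides when it is C or T (plus sense).  A
    confident A/G from plus together with a confident C/T from minus is a
    contradiction (both cannot be the homozygous allele) and is flagged.
    """
    plus_ok = plus_consensus in PLUS_RESOLVABLE
    minus_ok = minus_consensus in MINUS_RESOLVABLE
    if plus_ok and minus_ok:
        return "conflict"
    if plus_ok:
        return plus_consensus, "+"
    if minus_ok:
        return minus_consensus, "-"
    return "no-call"


def call_genotypes(
    records: Iterable[AlignmentRecord] | dict,
    genome: Genome | dict[str, str],
    q_min: int = 30,
    min_depth: int = 5,
    min_fraction: float = 0.9,
) -> pd.DataFrame:
    """Genotype every resolvable covered position; vectorised.

    ``records`` may also be a precomputed :func:`strand_pileups` result.
    Returns one row per resolved position (plus conflicts, flagged and
    excluded from the SNP set).
    """
    seqs = genome.seqs if isinstance(genome, Genome) else genome
    piles = records if isinstance(records, dict) else strand_pileups(records, genome, q_min)
    frames = []
    base_arr = np.frombuffer("".join(BASES).encode(), dtype=np.uint8)
    for contig, (plus, minus) in piles.items():
        ref = seq_to_array(seqs[contig])
        cons = []
        for counts in (plus, minus):
            depth = counts.sum(axis=0)
            top = counts.argmax(axis=0)
            topn = counts.max(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(depth > 0, topn / np.maximum(depth, 1), 0.0)
            ok = (depth >= min_depth) & (frac >= min_fraction)
            cons.append((np.where(ok, top, -1), depth))
        (cons_p, depth_p), (cons_m, depth_m) = cons
        plus_ok = (cons_p == 0) | (cons_p == 2)  # A or G
        minus_ok = (cons_m == 1) | (cons_m == 3)  # C or T
        conflict = plus_ok & minus_ok
        use_p = plus_ok & ~conflict
        use_m = minus_ok & ~conflict
        any_row = use_p | use_m | conflict
        pos = np.flatnonzero(any_row)
        if pos.size == 0:
            continue
        sample = np.where(use_p, cons_p, np.where(use_m, cons_m, 0))
        strand = np.where(use_p, "+", "-")
        depth_used = np.where(use_p, depth_p, depth_m)
        df = pd.DataFrame(
            {
                "contig": contig,
                "pos": pos,
                "ref": ref[pos].view("S1").astype(str),
                "sample_base": base_arr[sample[pos]].view("S1").astype(str)[: pos.size],
                "strand_used": strand[pos],
                "depth_used": depth_used[pos].astype(int),
                "status": np.where(conflict[pos], "conflict", "call"),
            }
        )
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=GENOTYPE_COLUMNS)
    calls = pd.concat(frames, ignore_index=True)
    calls["is_snp"] = (calls["status"] == "call") & (calls["sample_base"] != calls["ref"])
    return calls.sort_values(["contig", "pos"], ignore_index=True)


def call_snps(
    genome: Genome | dict[str, str],
    records: Iterable[AlignmentRecord],
    q_min: int = 30,
    min_depth: int = 5,
    min_fraction: float = 0.9,
) -> tuple[pd.DataFrame, int]:
    """Full genotype table plus the count of non-reference calls."""
    calls = call_genotypes(records, genome, q_min, min_depth, min_fraction)
    return calls, int(calls["is_snp"].sum()) if len(calls) else 0
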