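"""Three-letter bisulfite alignment.

The reference is converted twice: every C->T gives the *T-genome* (the
mapping target for reads that originate from the plus strand) and every
G->A gives the *A-genome* (minus-strand target).  Read pairs are converted
in silico the same way (mate 1 C->T, mate 2 G->A), placed ungapped with a
per-mate mismatch cap (2 for 44 nt reads, 4 for 75 nt), and kept only when
the best-scoring paired placement is strictly unique across both converted
genomes.  Clonal duplicates (identical start positions of both mates on the
same origin strand) are collapsed to a single representative, and aligned
reads are finally restored to their original base space for methylation and
genotype calling.

Placement search is exact: pigeonhole seeding (one of ``cap+1`` disjoint
k-mers must match exactly in any placement with <= cap mismatches) followed
by full Hamming verification, so results equal an exhaustive scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .seq import qual_to_phred_array, revcomp
from .simulate import Genome, ReadPair

DEFAULT_MISMATCH_CAPS = {44: 2, 75: 4}


def mismatch_cap(read_length: int, caps: dict[int, int] | None = None) -> int:
    caps = caps or DEFAULT_MISMATCH_CAPS
    if read_length in caps:
        return caps[read_length]
    return 2 if read_length <= 50 else 4


@dataclass
class ConvertedReference:
    """C->T and G->A converted genomes alongside the original."""

    original: dict[str, str]
    t_genome: dict[str, str]
    a_genome: dict[str, str]


def build_converted_references(genome: Genome | dict[str, str]) -> ConvertedReference:
    seqs = genome.seqs if isinstance(genome, Genome) else dict(genome)
    if not seqs or any(len(s) == 0 for s in seqs.values()):
        raise ValueError("genome must be non-empty")
    return ConvertedReference(
        original=dict(seqs),
        t_genome={c: s.replace("C", "T") for c, s in seqs.items()},
        a_genome={c: s.replace("G", "A") for c, s in seqs.items()},
    )


def convert_read_pair(pair: ReadPair) -> tuple[str, str]:
    """Mate 1 C->T, mate 2 G->A; originals live on in the ReadPair."""
    return pair.seq1.replace("C", "T"), pair.seq2.replace("G", "A")


@dataclass
class AlignmentRecord:
    """A uniquely mapped pair restored to original bases.

    ``start1``/``start2`` are the 0-based plus-strand starts of the mate 1
    and mate 2 footprints; for a minus-origin pair mate 2 is leftmost.
    ``plus_seq1``/``plus_seq2`` hold the original read bases expressed in
    plus-strand sense over those footprints (qualities co-reversed).
    """

    read_id: str
    contig: str
    start1: int
    start2: int
    origin_strand: Literal["+", "-"]
    mismatches: int
    plus_seq1: str
    plus_qual1: str
    plus_seq2: str
    plus_qual2: str
    is_clonal_duplicate: bool = False

    @property
    def start(self) -> int:
        """Leftmost reference offset of the pair."""
        return min(self.start1, self.start2)

    def segments(self, count_overlap_once: bool = True):
        """Yield (start, bases, quals) plus-sense segments of the pair.

        With ``count_overlap_once`` the part of mate 2's footprint that is
        already covered by mate 1 is trimmed, so overlapping mates never
        contribute the same genomic position twice.
        """
        yield self.start1, self.plus_seq1, self.plus_qual1
        s2, e2 = self.start2, self.start2 + len(self.plus_seq2)
        if count_overlap_once:
            s1, e1 = self.start1, self.start1 + len(self.plus_seq1)
            lo, hi = max(s1, s2), min(e1, e2)
            if lo < hi:  # overlap: keep only mate 2 bases outside mate 1
                if s2 < s1:
                    yield s2, self.plus_seq2[: s1 - s2], self.plus_qual2[: s1 - s2]
                if e2 > e1:
                    off = e1 - s2
                    yield e1, self.plus_seq2[off:], self.plus_qual2[off:]
                return
        yield s2, self.plus_seq2, self.plus_qual2


class BisulfiteAligner:
    """Exact ungapped paired-end aligner over the two converted genomes."""

    def __init__(
        self,
        genome: Genome | dict[str, str],
        max_insert: int = 600,
        mismatch_caps: dict[int, int] | None = None,
    ):
        self.refs = build_converted_references(genome)
        self.max_insert = max_insert
        self.mismatch_caps = mismatch_caps or DEFAULT_MISMATCH_CAPS
        self._indexes: dict[tuple[str, int], dict[str, list[tuple[str, int]]]] = {}

    # -- seeding -----------------------------------------------------------
    def _index(self, which: str, k: int) -> dict[str, list[tuple[str, int]]]:
        key = (which, k)
        if key not in self._indexes:
            idx: dict[str, list[tuple[str, int]]] = {}
            seqs = self.refs.t_genome if which == "T" else self.refs.a_genome
            for contig, seq in seqs.items():
                for i in range(len(seq) - k + 1):
                    idx.setdefault(seq[i : i + k], []).append((contig, i))
            self._indexes[key] = idx
        return self._indexes[key]

    def _find(self, query: str, which: str, cap: int) -> list[tuple[str, int, int]]:
        """All placements of ``query`` with <= cap mismatches: (contig, pos, mm)."""
        L = len(query)
        k = L // (cap + 1)
        index = self._index(which, k)
        seqs = self.refs.t_genome if which == "T" else self.refs.a_genome
        seen: set[tuple[str, int]] = set()
        out = []
        for i in range(cap + 1):
            seed = query[i * k : (i + 1) * k]
            for contig, pos in index.get(seed, ()):  # pigeonhole candidates
                start = pos - i * k
                if start < 0 or start + L > len(seqs[contig]) or (contig, start) in seen:
                    continue
                seen.add((contig, start))
                ref = seqs[contig][start : start + L]
                mm = 0
                for a, b in zip(query, ref):
                    if a != b:
                        mm += 1
                        if mm > cap:
                            break
                if mm <= cap:
                    out.append((contig, start, mm))
        return out

    # -- pairing -----------------------------------------------------------
    def align_read_pair(
        self, pair: ReadPair, max_mismatches: int | None = None
    ) -> AlignmentRecord | Literal["ambiguous", "unmapped"]:
        """Best strictly-unique paired placement, else 'ambiguous'/'unmapped'."""
        L1, L2 = len(pair.seq1), len(pair.seq2)
        cap1 = max_mismatches if max_mismatches is not None else mismatch_cap(L1, self.mismatch_caps)
        cap2 = max_mismatches if max_mismatches is not None else mismatch_cap(L2, self.mismatch_caps)
        m1c = pair.seq1.replace("C", "T")
        m2c = pair.seq2.replace("G", "A")

        candidates: list[tuple[int, str, str, int, int]] = []  # (mm, origin, contig, p1, p2)
        # plus origin: both footprints match the T-genome in plus orientation
        hits1 = self._find(m1c, "T", cap1)
        hits2 = self._find(revcomp(m2c), "T", cap2) if hits1 else []
        for c1, p1, mma in hits1:
            for c2, p2, mmb in hits2:
                if c1 == c2 and p1 <= p2 and p2 + L2 - p1 <= self.max_insert:
                    candidates.append((mma + mmb, "+", c1, p1, p2))
        # minus origin: mate 2 leads on the A-genome
        hits2m = self._find(m2c, "A", cap2)
        hits1m = self._find(revcomp(m1c), "A", cap1) if hits2m else []
        for c2, p2, mmb in hits2m:
            for c1, p1, mma in hits1m:
                if c1 == c2 and p2 <= p1 and p1 + L1 - p2 <= self.max_insert:
                    candidates.append((mma + mmb, "-", c1, p1, p2))

        if not candidates:
            return "unmapped"
        best = min(c[0] for c in candidates)
        top = [c for c in candidates if c[0] == best]
        if len(top) > 1:
            return "ambiguous"
        mm, origin, contig, p1, p2 = top[0]
        if origin == "+":
            seq1, q1 = pair.seq1, pair.qual1
            seq2, q2 = revcomp(pair.seq2), pair.qual2[::-1]
        else:
            seq1, q1 = revcomp(pair.seq1), pair.qual1[::-1]
            seq2, q2 = pair.seq2, pair.qual2
        return AlignmentRecord(
            read_id=pair.read_id,
            contig=contig,
            start1=p1,
            start2=p2,
            origin_strand=origin,
            mismatches=mm,
            plus_seq1=seq1,
            plus_qual1=q1,
            plus_seq2=seq2,
            plus_qual2=q2,
        )

    def align_pairs(self, pairs: Iterable[ReadPair]) -> tuple[list[AlignmentRecord], dict]:
        """Align many pairs; returns unique records and outcome tallies."""
        records, stats = [], {"unique": 0, "ambiguous": 0, "unmapped": 0}
        for pair in pairs:
            res = self.align_read_pair(pair)
            if isinstance(res, AlignmentRecord):
                records.append(res)
                stats["unique"] += 1
            else:
                stats[res] += 1
        return records, stats


def dedupe_clonal(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Collapse clonal duplicates: same (contig, both mate starts, origin).

    The survivor is the record with the highest mean base quality, ties
    broken in favour of the first-encountered read_id.  Idempotent.
    """
    best: dict[tuple, tuple[float, int]] = {}
    for i, rec in enumerate(records):
        key = (rec.contig, rec.start1, rec.start2, rec.origin_strand)
        quals = np.concatenate(
            [qual_to_phred_array(rec.plus_qual1), qual_to_phred_array(rec.plus_qual2)]
        )
        score = float(quals.mean()) if quals.size else 0.0
        if key not in best or score > best[key][0]:
            best[key] = (score, i)
    keep = sorted(i for _, i in best.values())
    out = []
    for i in keep:
        rec = records[i]
        rec.is_clonal_duplicate = False
        out.append(rec)
    return out


def restore_alignment(
    record: AlignmentRecord, genome: Genome | dict[str, str]
) -> list[tuple[int, str, str, int, bool]]:
    """Columnwise pairing of original read bases against the original reference.

    Returns ``(pos, read_base, ref_base, phred, bisulfite_consistent)`` per
    covered position (plus-strand sense; overlap between mates counted
    once).  A read T over a reference C is bisulfite-consistent for a
    plus-origin pair, as is read A over reference G for minus origin.
    """
    seqs = genome.seqs if isinstance(genome, Genome) else genome
    ref = seqs[record.contig]
    out = []
    for start, bases, quals in record.segments():
        if start < 0 or start + len(bases) > len(ref):
            raise RuntimeError("alignment outside contig bounds")
        for j, (b, q) in enumerate(zip(bases, quals)):
            pos = start + j
            r = ref[pos]
            if record.origin_strand == "+":
                consistent = r == "C" and b == "T"
            else:
                consistent = r == "G" and b == "A"
            out.append((pos, b, r, ord(q) - 33, consistent))
    return out
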