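"""Synthetic four-sample bisulfite-sequencing study generator.

Emulates a miniature comparative methylome experiment: a small reference
genome (nuclear contigs plus one unmethylated chloroplast), non-overlapping
gene / transposable-element / small-RNA annotations, phylogenetically
structured homozygous SNPs on the fixed 4-taxon topology
``((cult1,cult2),(wild1,wild2))``, compartment- and context-structured
methylation truth with a planted cultivated-vs-wild shift in a fraction of
genes, directional paired-end bisulfite reads with configurable
non-conversion and sequencing-error rates plus exact clonal duplicates, and
NlaIII-anchored DGE tag libraries with group-structured expression.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq import (
    context_codes,
    cytosine_strands,
    phred_to_qual,
    revcomp,
    seq_to_array,
)

SAMPLES = ("cult1", "cult2", "wild1", "wild2")
GROUPS = {"cult1": "cult", "cult2": "cult", "wild1": "wild", "wild2": "wild"}

COMPARTMENTS = ("intergenic", "TE", "gene_body", "promoter", "TTR")
_COMP_CODE = {name: i for i, name in enumerate(COMPARTMENTS)}

# default mean methylation probability per context x compartment, shaped
# like a plant methylome: TE >> gene body > flanks, CG > CHG > CHH
DEFAULT_METHYLATION_LEVELS = {
    "CG": {"TE": 0.85, "gene_body": 0.45, "promoter": 0.15, "TTR": 0.15, "intergenic": 0.30},
    "CHG": {"TE": 0.60, "gene_body": 0.12, "promoter": 0.08, "TTR": 0.08, "intergenic": 0.20},
    "CHH": {"TE": 0.12, "gene_body": 0.03, "promoter": 0.03, "TTR": 0.03, "intergenic": 0.05},
}

# branch order for the fixed 4-taxon tree; "internal" separates the
# cultivated pair from the wild pair and is applied on the wild side
BRANCHES = ("cult1", "cult2", "wild1", "wild2", "internal")
DEFAULT_BRANCH_RATES = {
    "cult1": 5e-4,
    "cult2": 5e-4,
    "wild1": 1e-3,
    "wild2": 1e-3,
    "internal": 2e-3,
}


class CapacityError(ValueError):
    """Requested annotation does not fit on the configured contigs."""


@dataclass
class SimConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    contigs: list[tuple[str, int, bool]] = field(
        default_factory=lambda: [("chr1", 80_000, False), ("chrC", 8_000, True)]
    )
    gene_count: int = 30
    te_count: int = 20
    smrna_count: int = 12
    methylation_levels: dict = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_METHYLATION_LEVELS.items()}
    )
    site_jitter_sd: float = 0.12
    group_divergence_sd: float = 0.04
    sample_noise_sd: float = 0.015
    dm_fraction: float = 0.1
    dm_shift: float = 0.4
    dm_region: str = "promoter"
    snp_branch_rates: dict = field(default_factory=lambda: dict(DEFAULT_BRANCH_RATES))
    read_length: int = 44
    depth: float = 6.0
    insert_range: tuple[int, int] = (150, 250)
    non_conversion_rate: float = 0.0112
    seq_error_rate: float = 0.001
    clonal_fraction: float = 0.1
    placement: str = "random"  # or "tiled": evenly spaced abutting-mate fragments
    base_quality: int = 40
    low_quality_fraction: float = 0.0
    low_quality_phred: int = 15
    promoter_bp: int = 200
    ttr_bp: int = 200
    # expression model (log2 scale) and DGE library
    expr_mean_log2: float = 5.0
    expr_sd_log2: float = 1.5
    expr_group_sd_log2: float = 0.6
    expr_sample_sd_log2: float = 0.15
    dm_expression_coupling: float = 0.5
    dm_expression_log2fc: float = 2.0
    tag_count: int = 50_000
    internal_site_prob: float = 0.1
    tag_seq_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "dm_fraction",
            "non_conversion_rate",
            "seq_error_rate",
            "clonal_fraction",
            "internal_site_prob",
            "low_quality_fraction",
            "tag_seq_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.read_length not in (44, 75):
            raise ValueError("read_length must be 44 or 75")
        if any(length < 1000 for _, length, _ in self.contigs):
            raise ValueError("contig lengths must be >= 1000 bp")
        if sum(is_cp for _, _, is_cp in self.contigs) != 1:
            raise ValueError("exactly one contig must be flagged as chloroplast")
        for ctx, comps in self.methylation_levels.items():
            for comp, p in comps.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"methylation_levels[{ctx}][{comp}] outside [0,1]")
        for br, r in self.snp_branch_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"snp_branch_rates[{br}] outside [0,1]")
        if self.placement not in ("random", "tiled"):
            raise ValueError("placement must be 'random' or 'tiled'")
        if self.dm_region not in ("promoter", "gene_body", "TTR"):
            raise ValueError("dm_region must be promoter, gene_body or TTR")

    def spawn_rng(self, *tokens) -> np.random.Generator:
        """Deterministic child generator for a named simulation stream."""
        key = [self.seed] + [
            zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tokens
        ]
        return np.random.default_rng(np.random.SeedSequence(key))


@dataclass
class Genome:
    seqs: dict[str, str]
    chloroplast: str

    @property
    def contigs(self) -> list[str]:
        return list(self.seqs)

    @property
    def nuclear(self) -> list[str]:
        return [c for c in self.seqs if c != self.chloroplast]

    def length(self, contig: str) -> int:
        return len(self.seqs[contig])


@dataclass
class Annotation:
    """Gene models plus TE and smRNA intervals; 0-based half-open spans."""

    genes: pd.DataFrame  # gene_id, contig, start, end, strand
    tes: pd.DataFrame  # te_id, contig, start, end
    smrnas: pd.DataFrame  # smrna_id, contig, start, end
    promoter_bp: int = 200
    ttr_bp: int = 200

    def promoter_span(self, gene: pd.Series) -> tuple[str, int, int]:
        if gene.strand == "+":
            return gene.contig, gene.start - self.promoter_bp, gene.start
        return gene.contig, gene.end, gene.end + self.promoter_bp

    def ttr_span(self, gene: pd.Series) -> tuple[str, int, int]:
        if gene.strand == "+":
            return gene.contig, gene.end, gene.end + self.ttr_bp
        return gene.contig, gene.start - self.ttr_bp, gene.start

    def region_span(self, gene: pd.Series, kind: str) -> tuple[str, int, int]:
        if kind == "promoter":
            return self.promoter_span(gene)
        if kind == "TTR":
            return self.ttr_span(gene)
        if kind == "gene_body":
            return gene.contig, gene.start, gene.end
        raise ValueError(f"unknown region kind {kind!r}")

    def compartment_codes(self, genome: Genome) -> dict[str, np.ndarray]:
        """Per-contig per-position compartment code arrays."""
        comp = {c: np.zeros(genome.length(c), dtype=np.int8) for c in genome.contigs}
        for _, te in self.tes.iterrows():
            comp[te.contig][te.start : te.end] = _COMP_CODE["TE"]
        for _, g in self.genes.iterrows():
            comp[g.contig][g.start : g.end] = _COMP_CODE["gene_body"]
            _, ps, pe = self.promoter_span(g)
            comp[g.contig][max(ps, 0) : pe] = _COMP_CODE["promoter"]
            _, ts, te_ = self.ttr_span(g)
            comp[g.contig][max(ts, 0) : te_] = _COMP_CODE["TTR"]
        return comp


@dataclass
class TruthSet:
    """Ground truth of the simulated study."""

    sample_genomes: dict[str, dict[str, str]]
    # methylation[sample][contig] = (prob_plus, prob_minus); NaN off-cytosine
    methylation: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    snps: pd.DataFrame  # contig, pos, ref, alt, branch, samples (comma list)
    dm_genes: pd.DataFrame  # gene_id, region, direction
    expression: pd.DataFrame | None = None  # gene_id x sample true abundance


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


# ---------------------------------------------------------------------------
# genome + annotation


def _place_intervals(
    rng: np.random.Generator,
    occupied: np.ndarray,
    n: int,
    length_range: tuple[int, int],
    margin: int = 0,
    max_tries_per_feature: int = 400,
) -> list[tuple[int, int]]:
    """Place ``n`` disjoint intervals on an occupancy mask (with margin)."""
    spans = []
    contig_len = len(occupied)
    tries = 0
    while len(spans) < n:
        if tries > max_tries_per_feature * n:
            raise CapacityError(
                f"could not place {n} features of size {length_range} on a "
                f"{contig_len} bp contig (placed {len(spans)})"
            )
        tries += 1
        flen = int(rng.integers(length_range[0], length_range[1] + 1))
        lo, hi = margin, contig_len - flen - margin
        if hi <= lo:
            raise CapacityError("feature larger than contig")
        s = int(rng.integers(lo, hi))
        if occupied[s - margin : s + flen + margin].any():
            continue
        occupied[s : s + flen] = True
        spans.append((s, s + flen))
    return spans


def generate_genome(config: SimConfig) -> tuple[Genome, Annotation]:
    """Random seeded genome and non-overlapping annotation.

    Genes (with their promoter/TTR flanks), TEs and smRNA loci are mutually
    disjoint and restricted to nuclear contigs; the chloroplast contig is
    feature-free.
    """
    rng = config.spawn_rng("genome")
    seqs = {}
    chloroplast = None
    for name, length, is_cp in config.contigs:
        seqs[name] = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        if is_cp:
            chloroplast = name
    genome = Genome(seqs=seqs, chloroplast=chloroplast)

    nuclear = genome.nuclear
    weights = np.array([genome.length(c) for c in nuclear], dtype=float)
    weights /= weights.sum()

    def split(total: int) -> list[int]:
        counts = np.floor(total * weights).astype(int)
        for i in range(total - counts.sum()):
            counts[i % len(counts)] += 1
        return list(counts)

    occupied = {c: np.zeros(genome.length(c), dtype=bool) for c in nuclear}
    flank = max(config.promoter_bp, config.ttr_bp)

    genes, tes, smrnas = [], [], []
    for contig, n_g in zip(nuclear, split(config.gene_count)):
        # a 2x flank margin keeps the (promoter, body, TTR) triples of
        # neighbouring genes disjoint; the flank footprint is then marked
        # occupied so TEs and smRNA loci cannot intrude either
        for s, e in _place_intervals(rng, occupied[contig], n_g, (500, 1500), margin=2 * flank):
            occupied[contig][max(s - flank, 0) : e + flank] = True
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((f"g{len(genes) + 1:04d}", contig, s, e, strand))
    for contig, n_t in zip(nuclear, split(config.te_count)):
        for s, e in _place_intervals(rng, occupied[contig], n_t, (300, 1500)):
            tes.append((f"te{len(tes) + 1:03d}", contig, s, e))
    for contig, n_s in zip(nuclear, split(config.smrna_count)):
        for s, e in _place_intervals(rng, occupied[contig], n_s, (50, 200)):
            smrnas.append((f"sr{len(smrnas) + 1:03d}", contig, s, e))

    ann = Annotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "contig", "start", "end", "strand"]),
        tes=pd.DataFrame(tes, columns=["te_id", "contig", "start", "end"]),
        smrnas=pd.DataFrame(smrnas, columns=["smrna_id", "contig", "start", "end"]),
        promoter_bp=config.promoter_bp,
        ttr_bp=config.ttr_bp,
    )
    return genome, ann


# ---------------------------------------------------------------------------
# SNP truth


def plant_snps(genome: Genome, config: SimConfig) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Plant homozygous substitutions per branch of ((cult1,cult2),(wild1,wild2)).

    Each branch draws substitutions independently at its configured rate on
    nuclear contigs (the chloroplast stays identical across samples); the
    internal branch is applied to both wild samples.  Returns per-sample
    genome sequences and the SNP truth table.
    """
    rng = config.spawn_rng("snps")
    carriers = {
        "cult1": ("cult1",),
        "cult2": ("cult2",),
        "wild1": ("wild1",),
        "wild2": ("wild2",),
        "internal": ("wild1", "wild2"),
    }
    arrays = {s: {c: seq_to_array(genome.seqs[c]) for c in genome.contigs} for s in SAMPLES}
    records = []
    taken: dict[str, set[int]] = {c: set() for c in genome.contigs}
    bases = np.array([ord(b) for b in "ACGT"], dtype=np.uint8)
    for branch in BRANCHES:
        rate = config.snp_branch_rates.get(branch, 0.0)
        if rate <= 0:
            continue
        for contig in genome.nuclear:
            n = len(genome.seqs[contig])
            hits = np.flatnonzero(rng.random(n) < rate)
            for pos in hits:
                pos = int(pos)
                if pos in taken[contig]:
                    continue  # one substitution per site across all branches
                taken[contig].add(pos)
                ref = genome.seqs[contig][pos]
                alt = ref
                while alt == ref:
                    alt = chr(bases[rng.integers(0, 4)])
                for s in carriers[branch]:
                    arrays[s][contig][pos] = ord(alt)
                records.append((contig, pos, ref, alt, branch, ",".join(carriers[branch])))
    sample_genomes = {
        s: {c: arrays[s][c].tobytes().decode("ascii") for c in genome.contigs} for s in SAMPLES
    }
    snps = pd.DataFrame(records, columns=["contig", "pos", "ref", "alt", "branch", "samples"])
    snps = snps.sort_values(["contig", "pos"], ignore_index=True)
    return sample_genomes, snps


# ---------------------------------------------------------------------------
# methylation truth


def _level_table(config: SimConfig) -> np.ndarray:
    """(compartment, context-code) lookup of mean methylation probability."""
    tbl = np.zeros((len(COMPARTMENTS), 4))
    for ctx_code, ctx in enumerate(("CG", "CHG", "CHH")):
        for comp, code in _COMP_CODE.items():
            tbl[code, ctx_code] = config.methylation_levels[ctx][comp]
    tbl[:, 3] = tbl[:, 2]  # edge sites with unknown context fall back to CHH level
    return tbl


def select_dm_genes(annotation: Annotation, config: SimConfig) -> pd.DataFrame:
    rng = config.spawn_rng("dm")
    n_dm = int(round(config.dm_fraction * len(annotation.genes)))
    if n_dm == 0:
        return pd.DataFrame(columns=["gene_id", "region", "direction"])
    chosen = rng.choice(annotation.genes["gene_id"].to_numpy(), size=n_dm, replace=False)
    directions = np.where(rng.random(n_dm) < 0.5, "up_in_cultivated", "down_in_cultivated")
    return pd.DataFrame(
        {"gene_id": sorted(chosen), "region": config.dm_region, "direction": directions}
    )


def assign_methylation_truth(
    genome: Genome,
    annotation: Annotation,
    config: SimConfig,
    sample_genomes: dict[str, dict[str, str]] | None = None,
    dm_genes: pd.DataFrame | None = None,
) -> tuple[dict[str, dict[str, tuple[np.ndarray, np.ndarray]]], pd.DataFrame]:
    """Per-sample, per-cytosine truth probabilities that a read shows C.

    prob = compartment-x-context mean + shared per-site jitter + per-group
    per-site divergence + per-sample per-site noise, clipped to [0,1];
    chloroplast sites are exactly 0.  A ``dm_fraction`` of genes receives a
    +/- ``dm_shift`` to the cultivated group over the configured region.
    Positions that are not cytosines in a sample's own genome are NaN.
    """
    if sample_genomes is None:
        sample_genomes = {s: dict(genome.seqs) for s in SAMPLES}
    if dm_genes is None:
        dm_genes = select_dm_genes(annotation, config)

    rng = config.spawn_rng("methylation")
    tbl = _level_table(config)
    comp = annotation.compartment_codes(genome)
    gene_by_id = annotation.genes.set_index("gene_id")

    # shared random fields drawn once on reference coordinates
    jitter, group_eff, sample_eff = {}, {}, {}
    for c in genome.contigs:
        n = genome.length(c)
        jitter[c] = rng.normal(0.0, config.site_jitter_sd, size=(2, n))
        group_eff[c] = {
            g: rng.normal(0.0, config.group_divergence_sd, size=(2, n)) for g in ("cult", "wild")
        }
        sample_eff[c] = {
            s: rng.normal(0.0, config.sample_noise_sd, size=(2, n)) for s in SAMPLES
        }

    # planted cultivated-vs-wild shifts, indexed by contig -> position mask
    dm_shift = {c: np.zeros(genome.length(c)) for c in genome.contigs}
    for _, row in dm_genes.iterrows():
        gene = gene_by_id.loc[row.gene_id]
        gene = pd.Series({"contig": gene.contig, "start": gene.start, "end": gene.end,
                          "strand": gene.strand})
        contig, s, e = annotation.region_span(gene, row.region)
        sign = 1.0 if row.direction == "up_in_cultivated" else -1.0
        dm_shift[contig][max(s, 0) : e] = sign * config.dm_shift

    methylation: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for s in SAMPLES:
        methylation[s] = {}
        for c in genome.contigs:
            seq = sample_genomes[s][c]
            ctx_p, ctx_m = context_codes(seq)
            mask_p, mask_m = cytosine_strands(seq)
            base_p = tbl[comp[c], ctx_p]
            base_m = tbl[comp[c], ctx_m]
            shift = dm_shift[c] if GROUPS[s] == "cult" else 0.0
            prob_p = base_p + jitter[c][0] + group_eff[c][GROUPS[s]][0] + sample_eff[c][s][0]
            prob_m = base_m + jitter[c][1] + group_eff[c][GROUPS[s]][1] + sample_eff[c][s][1]
            prob_p = np.clip(prob_p + shift, 0.0, 1.0)
            prob_m = np.clip(prob_m + shift, 0.0, 1.0)
            if c == genome.chloroplast:
                prob_p[:] = 0.0
                prob_m[:] = 0.0
            prob_p[~mask_p] = np.nan
            prob_m[~mask_m] = np.nan
            methylation[s][c] = (prob_p, prob_m)
    return methylation, dm_genes


# ---------------------------------------------------------------------------
# bisulfite reads


def _apply_seq_errors(arr: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size == 0:
        return
    code = {ord("A"): 0, ord("C"): 1, ord("G"): 2, ord("T"): 3}
    bases = np.array([ord(b) for b in "ACGT"], dtype=np.uint8)
    for i in hits:
        orig = code.get(int(arr[i]), 0)
        arr[i] = bases[(orig + 1 + rng.integers(0, 3)) % 4]


def _qual_string(n: int, config: SimConfig, rng: np.random.Generator) -> str:
    if config.low_quality_fraction <= 0:
        return phred_to_qual(config.base_quality) * n
    low = rng.random(n) < config.low_quality_fraction
    chars = np.where(low, phred_to_qual(config.low_quality_phred), phred_to_qual(config.base_quality))
    return "".join(chars)


def simulate_bs_reads(
    sample_seqs: dict[str, str],
    methylation: dict[str, tuple[np.ndarray, np.ndarray]],
    config: SimConfig,
    sample: str,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Directional paired-end bisulfite reads for one sample.

    Fragments are drawn from both original strands; on the originating
    strand each cytosine is emitted as C with probability
    ``p_meth + (1 - p_meth) * non_conversion_rate`` and as T otherwise.
    Mate 1 is the fragment's 5' read (C->T affected); mate 2 is the
    reverse-complement 3' end (appearing G->A affected).  Sequencing errors
    are independent per base; a ``clonal_fraction`` of fragments is
    duplicated exactly.
    """
    rng = config.spawn_rng("reads", sample)
    L = config.read_length
    pairs: list[ReadPair] = []
    frag_rows = []
    for contig, seq in sample_seqs.items():
        n = len(seq)
        prob_p, prob_m = methylation[contig]
        nc = config.non_conversion_rate
        with np.errstate(invalid="ignore"):
            ret_p = np.nan_to_num(prob_p + (1.0 - prob_p) * nc)
            ret_m = np.nan_to_num(prob_m + (1.0 - prob_m) * nc)
        arr = seq_to_array(seq)
        is_c = arr == ord("C")
        is_g = arr == ord("G")

        if config.placement == "tiled":
            flen = 2 * L
            n_frags = max(0, int(round(n * config.depth / (2 * L))))
            if n_frags == 0 or n < flen:
                continue
            step = (n - flen) / max(n_frags - 1, 1)
            strand_layouts = {
                "+": np.round(np.arange(n_frags) * step).astype(int),
                "-": np.round(np.arange(n_frags) * step).astype(int),
            }
            flens = {st: np.full(n_frags, flen) for st in "+-"}
        else:
            n_frags = max(0, int(round(n * config.depth / (2 * L))))
            lo = max(config.insert_range[0], L)
            hi = max(config.insert_range[1], lo)
            strand_layouts, flens = {}, {}
            for st in "+-":
                fl = rng.integers(lo, hi + 1, size=n_frags)
                fl = np.minimum(fl, n)
                strand_layouts[st] = np.array(
                    [int(rng.integers(0, n - f + 1)) for f in fl], dtype=int
                )
                flens[st] = fl

        for strand in "+-":
            starts, fls = strand_layouts[strand], flens[strand]
            for i in range(len(starts)):
                s, flen = int(starts[i]), int(fls[i])
                if flen < L:
                    continue
                idx1 = np.arange(s, s + L)  # leftmost footprint (plus coords)
                idx2 = np.arange(s + flen - L, s + flen)  # rightmost footprint
                if strand == "+":
                    seg1 = arr[idx1].copy()
                    seg2 = arr[idx2].copy()
                    for seg, idx in ((seg1, idx1), (seg2, idx2)):
                        cpos = np.flatnonzero(is_c[idx])
                        if cpos.size:
                            keep = rng.random(cpos.size) < ret_p[idx[cpos]]
                            seg[cpos[~keep]] = ord("T")
                    read1 = seg1.tobytes().decode("ascii")
                    read2 = revcomp(seg2.tobytes().decode("ascii"))
                else:
                    # minus-strand fragment: its cytosines sit at plus-G positions
                    seg1 = arr[idx2].copy()  # mate1 covers the right footprint
                    seg2 = arr[idx1].copy()
                    for seg, idx in ((seg1, idx2), (seg2, idx1)):
                        gpos = np.flatnonzero(is_g[idx])
                        if gpos.size:
                            keep = rng.random(gpos.size) < ret_m[idx[gpos]]
                            seg[gpos[~keep]] = ord("A")
                    read1 = revcomp(seg1.tobytes().decode("ascii"))
                    read2 = seg2.tobytes().decode("ascii")

                a1 = seq_to_array(read1)
                a2 = seq_to_array(read2)
                _apply_seq_errors(a1, config.seq_error_rate, rng)
                _apply_seq_errors(a2, config.seq_error_rate, rng)
                read1 = a1.tobytes().decode("ascii")
                read2 = a2.tobytes().decode("ascii")
                rid = f"{sample}:{contig}:{strand}:{i}"
                q1 = _qual_string(L, config, rng)
                q2 = _qual_string(L, config, rng)
                pairs.append(ReadPair(rid, read1, q1, read2, q2))
                frag_rows.append((rid, contig, s, flen, strand, False))
                if config.clonal_fraction > 0 and rng.random() < config.clonal_fraction:
                    cid = rid + ".c"
                    pairs.append(ReadPair(cid, read1, q1, read2, q2))
                    frag_rows.append((cid, contig, s, flen, strand, True))
    fragments = pd.DataFrame(
        frag_rows, columns=["read_id", "contig", "start", "frag_len", "strand", "is_clone"]
    )
    return pairs, fragments


# ---------------------------------------------------------------------------
# expression + DGE tags


def make_cdnas(genome: Genome, annotation: Annotation) -> dict[str, str]:
    """Transcript (cDNA) sequences: the gene-body sequence, 5'->3'."""
    cdnas = {}
    for _, g in annotation.genes.iterrows():
        seq = genome.seqs[g.contig][g.start : g.end]
        cdnas[g.gene_id] = seq if g.strand == "+" else revcomp(seq)
    return cdnas


def simulate_expression_truth(
    annotation: Annotation, config: SimConfig, dm_genes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """True transcript abundances (linear scale), genes x samples.

    Abundance is log-normal with a shared per-gene baseline, a per-group
    per-gene effect and small per-sample noise; a ``dm_expression_coupling``
    fraction of planted DM genes additionally gets an expression change
    opposing their cultivated methylation shift (promoter/TTR logic).
    """
    rng = config.spawn_rng("expression")
    genes = annotation.genes["gene_id"].to_numpy()
    base = rng.normal(config.expr_mean_log2, config.expr_sd_log2, size=len(genes))
    geff = {
        g: rng.normal(0.0, config.expr_group_sd_log2, size=len(genes)) for g in ("cult", "wild")
    }
    log2 = {}
    for s in SAMPLES:
        log2[s] = base + geff[GROUPS[s]] + rng.normal(
            0.0, config.expr_sample_sd_log2, size=len(genes)
        )
    df = pd.DataFrame(log2, index=genes)
    if dm_genes is not None and len(dm_genes) and config.dm_expression_coupling > 0:
        coupled = dm_genes.iloc[: int(round(config.dm_expression_coupling * len(dm_genes)))]
        for _, row in coupled.iterrows():
            # methylation up in cultivated -> expression down in cultivated
            sign = -1.0 if row.direction == "up_in_cultivated" else 1.0
            for s in SAMPLES:
                if GROUPS[s] == "cult":
                    df.loc[row.gene_id, s] += sign * config.dm_expression_log2fc
    return np.power(2.0, df)


def tag_sites(cdna: str) -> list[int]:
    """Start positions of CATG anchors with >=17 nt following, 5'->3' order."""
    sites = []
    i = cdna.find("CATG")
    while i != -1:
        if len(cdna) - (i + 4) >= 17:
            sites.append(i)
        i = cdna.find("CATG", i + 1)
    return sites


def simulate_dge_library(
    cdnas: dict[str, str],
    expression: pd.Series,
    config: SimConfig,
    sample: str,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """NlaIII DGE tag reads (id, 21-nt seq, qual) sampled by abundance.

    Each tag is CATG plus the 17 nt following the 3'-most anchor of its
    transcript; with probability ``internal_site_prob`` an internal anchor
    is emitted instead.  Transcripts without an eligible CATG emit nothing.
    """
    rng = config.spawn_rng("tags", sample)
    genes = [g for g in cdnas if expression.get(g, 0.0) > 0 and tag_sites(cdnas[g])]
    if not genes or config.tag_count == 0:
        return [], pd.DataFrame(columns=["gene_id", "count"])
    weights = np.array([expression[g] for g in genes], dtype=float)
    counts = rng.multinomial(config.tag_count, weights / weights.sum())
    reads: list[tuple[str, str, str]] = []
    qual = phred_to_qual(config.base_quality) * 21
    rows = []
    k = 0
    for g, n in zip(genes, counts):
        if n == 0:
            continue
        sites = tag_sites(cdnas[g])
        n_internal = (
            rng.binomial(n, config.internal_site_prob) if len(sites) > 1 else 0
        )
        choices = [sites[-1]] * (n - n_internal) + [
            sites[int(rng.integers(0, len(sites) - 1))] for _ in range(n_internal)
        ]
        for pos in choices:
            tag = cdnas[g][pos : pos + 21]
            if config.tag_seq_error_rate > 0:
                arr = seq_to_array(tag)
                _apply_seq_errors(arr, config.tag_seq_error_rate, rng)
                tag = arr.tobytes().decode("ascii")
            reads.append((f"{sample}:tag:{k}", tag, qual))
            k += 1
        rows.append((g, int(n)))
    truth = pd.DataFrame(rows, columns=["gene_id", "count"])
    return reads, truth


# ---------------------------------------------------------------------------
# whole-study orchestration


@dataclass
class StudyData:
    config: SimConfig
    genome: Genome
    annotation: Annotation
    truth: TruthSet
    cdnas: dict[str, str]
    reads: dict[str, tuple[list[ReadPair], pd.DataFrame]] = field(default_factory=dict)
    tags: dict[str, tuple[list[tuple[str, str, str]], pd.DataFrame]] = field(default_factory=dict)


def simulate_study(
    config: SimConfig, with_reads: bool = True, with_tags: bool = True
) -> StudyData:
    """Generate the full four-sample study deterministically from the seed."""
    genome, annotation = generate_genome(config)
    sample_genomes, snps = plant_snps(genome, config)
    dm_genes = select_dm_genes(annotation, config)
    methylation, dm_genes = assign_methylation_truth(
        genome, annotation, config, sample_genomes, dm_genes
    )
    expression = simulate_expression_truth(annotation, config, dm_genes)
    truth = TruthSet(
        sample_genomes=sample_genomes,
        methylation=methylation,
        snps=snps,
        dm_genes=dm_genes,
        expression=expression,
    )
    study = StudyData(config, genome, annotation, truth, make_cdnas(genome, annotation))
    if with_reads:
        for s in SAMPLES:
            study.reads[s] = simulate_bs_reads(sample_genomes[s], methylation[s], config, s)
    if with_tags:
        for s in SAMPLES:
            study.tags[s] = simulate_dge_library(study.cdnas, expression[s], config, s)
    return study
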