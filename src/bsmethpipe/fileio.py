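"""Text-format readers and writers.

FASTA/FASTQ go through Biopython; annotations are emitted as GFF3 (genes)
and BED6 (TEs, smRNA loci); site, genotype and alignment tables are plain
tab-delimited files.  Internal coordinates are 0-based half-open; all
text outputs use 1-based positions (BED keeps its native 0-based starts).
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentRecord
from .simulate import Annotation, Genome, ReadPair


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_genome(path: str, chloroplast: str) -> Genome:
    seqs = read_fasta(path)
    if chloroplast not in seqs:
        raise ValueError(f"chloroplast contig {chloroplast!r} not in {path}")
    return Genome(seqs=seqs, chloroplast=chloroplast)


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fastq_pairs(path1: str, path2: str) -> list[ReadPair]:
    out = []
    for r1, r2 in zip(SeqIO.parse(path1, "fastq"), SeqIO.parse(path2, "fastq")):
        q1 = "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"])
        rid = r1.id.rsplit("/", 1)[0]
        out.append(ReadPair(rid, str(r1.seq), q1, str(r2.seq), q2))
    return out


def write_tags_fastq(reads: Iterable[tuple[str, str, str]], path: str) -> None:
    with open(path, "w") as f:
        for rid, seq, qual in reads:
            f.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_tags_fastq(path: str) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(path, "fastq")]


def write_annotation(ann: Annotation, genes_path: str, te_path: str, smrna_path: str) -> None:
    with open(genes_path, "w") as f:
        f.write("##gff-version 3\n")
        for g in ann.genes.itertuples():
            f.write(
                f"{g.contig}\tbsmethpipe\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
    for df, path, name_col in ((ann.tes, te_path, "te_id"), (ann.smrnas, smrna_path, "smrna_id")):
        with open(path, "w") as f:
            for row in df.itertuples():
                f.write(
                    f"{row.contig}\t{row.start}\t{row.end}\t{getattr(row, name_col)}\t0\t+\n"
                )


def read_annotation(
    genes_path: str, te_path: str, smrna_path: str, promoter_bp: int = 200, ttr_bp: int = 200
) -> Annotation:
    genes = []
    with open(genes_path) as f:
        for line in f:
            if line.startswith("#") or not line.strip():
                continue
            contig, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            if ftype != "gene":
                continue
            gid = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)["ID"]
            genes.append((gid, contig, int(start) - 1, int(end), strand))
    beds = []
    for path, name_col in ((te_path, "te_id"), (smrna_path, "smrna_id")):
        rows = []
        with open(path) as f:
            for line in f:
                if line.strip():
                    c, s, e, name = line.split("\t")[:4]
                    rows.append((name, c, int(s), int(e)))
        beds.append(pd.DataFrame(rows, columns=[name_col, "contig", "start", "end"]))
    return Annotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "contig", "start", "end", "strand"]),
        tes=beds[0],
        smrnas=beds[1],
        promoter_bp=promoter_bp,
        ttr_bp=ttr_bp,
    )


def write_alignments(records: Iterable[AlignmentRecord], path: str) -> None:
    cols = [
        "read_id", "contig", "start1", "start2", "origin_strand", "mismatches",
        "plus_seq1", "plus_qual1", "plus_seq2", "plus_qual2",
    ]
    with open(path, "w") as f:
        f.write("\t".join(cols) + "\n")
        for r in records:
            f.write(
                f"{r.read_id}\t{r.contig}\t{r.start1 + 1}\t{r.start2 + 1}\t"
                f"{r.origin_strand}\t{r.mismatches}\t{r.plus_seq1}\t{r.plus_qual1}\t"
                f"{r.plus_seq2}\t{r.plus_qual2}\n"
            )


def read_alignments(path: str) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        AlignmentRecord(
            read_id=r.read_id,
            contig=r.contig,
            start1=int(r.start1) - 1,
            start2=int(r.start2) - 1,
            origin_strand=r.origin_strand,
            mismatches=int(r.mismatches),
            plus_seq1=r.plus_seq1,
            plus_qual1=r.plus_qual1,
            plus_seq2=r.plus_seq2,
            plus_qual2=r.plus_qual2,
        )
        for r in df.itertuples()
    ]


def write_sites(sites: pd.DataFrame, path: str) -> None:
    """CX-report-like dialect: 1-based positions, one row per covered C."""
    out = sites.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_sites(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return df


def write_genotypes(calls: pd.DataFrame, path: str) -> None:
    out = calls.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return df


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
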