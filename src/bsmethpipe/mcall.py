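"""Per-cytosine pileup, chloroplast error-rate calibration and binomial
methylcytosine calling.

Every reference cytosine (both strands) covered by at least one
quality-passing read gets a site record with its CG/CHG/CHH context, read
counts and methylation level (the fraction of reads showing the methylated
base).  The combined non-conversion + T-to-C sequencing error rate is
estimated from the unmethylated chloroplast contig, and a one-sided
binomial test against that null (per-site false-positive bound alpha)
decides which sites are methylcytosines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentRecord
from .seq import CONTEXTS, context_codes, cytosine_strands, qual_to_phred_array, seq_to_array
from .simulate import Genome

SITE_COLUMNS = [
    "contig",
    "pos",
    "strand",
    "context",
    "n_meth",
    "n_total",
    "level",
    "p_value",
    "is_mC",
]


@dataclass
class ErrorRateEstimate:
    """Pooled chloroplast estimate of the combined null C-retention rate."""

    p_err: float
    n_observations: int


def pileup_cytosines(
    records: Iterable[AlignmentRecord],
    genome: Genome | dict[str, str],
    q_min: int = 20,
    exclude: set[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Site table over all covered reference cytosines on both strands.

    Plus-strand cytosines collect evidence from plus-origin reads (read C =
    methylated, anything else unmethylated support); minus-strand cytosines
    (reference G) from minus-origin reads (read G in plus sense =
    methylated).  Bases below ``q_min`` are excluded from both counts, and
    overlapping mate bases are counted once.  ``exclude`` drops (contig,
    pos) positions, e.g. sites genotyped as non-reference by the SNP caller
    (a C->T substitution is indistinguishable from an unmethylated C).
    """
    seqs = genome.seqs if isinstance(genome, Genome) else genome
    tot = {c: np.zeros((2, len(s)), dtype=np.int32) for c, s in seqs.items()}
    met = {c: np.zeros((2, len(s)), dtype=np.int32) for c, s in seqs.items()}
    for rec in records:
        stratum = 0 if rec.origin_strand == "+" else 1
        meth_base = ord("C") if stratum == 0 else ord("G")
        for start, bases, quals in rec.segments():
            if not bases:
                continue
            arr = seq_to_array(bases)
            q = qual_to_phred_array(quals)
            ok = q >= q_min
            pos = np.arange(start, start + len(bases))[ok]
            np.add.at(tot[rec.contig][stratum], pos, 1)
            np.add.at(met[rec.contig][stratum], pos[arr[ok] == meth_base], 1)

    frames = []
    for contig, seq in seqs.items():
        mask_p, mask_m = cytosine_strands(seq)
        ctx_p, ctx_m = context_codes(seq)
        for stratum, (mask, ctx, strand) in enumerate(
            [(mask_p, ctx_p, "+"), (mask_m, ctx_m, "-")]
        ):
            covered = mask & (tot[contig][stratum] > 0)
            pos = np.flatnonzero(covered)
            if pos.size == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": pos,
                        "strand": strand,
                        "context": np.array(CONTEXTS)[ctx[pos]],
                        "n_meth": met[contig][stratum][pos],
                        "n_total": tot[contig][stratum][pos],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=SITE_COLUMNS[:7])
    sites = pd.concat(frames, ignore_index=True)
    if exclude:
        mi = pd.MultiIndex.from_frame(sites[["contig", "pos"]])
        sites = sites[~mi.isin(list(exclude))].reset_index(drop=True)
    sites["level"] = sites["n_meth"] / sites["n_total"]
    return sites.sort_values(["contig", "pos", "strand"], ignore_index=True)


def estimate_error_rate(sites: pd.DataFrame, chloroplast: str) -> ErrorRateEstimate:
    """Pooled Σ n_meth / Σ n_total over all chloroplast cytosines."""
    cp = sites[sites["contig"] == chloroplast]
    n = int(cp["n_total"].sum())
    if n == 0:
        raise ValueError(
            "no covered chloroplast cytosines: cannot calibrate the mC caller"
        )
    return ErrorRateEstimate(p_err=float(cp["n_meth"].sum()) / n, n_observations=n)


def binomial_call(n_meth: int, n_total: int, p_err: float, alpha: float = 0.05):
    """One-sided binomial tail test of a single site.

    p = P(X >= n_meth | X ~ Binomial(n_total, p_err)); the site is a mC
    when at least one read shows C and p < alpha.
    """
    if not 0.0 <= p_err <= 1.0:
        raise ValueError(f"p_err must be in [0,1], got {p_err}")
    if n_total < 1 or not 0 <= n_meth <= n_total:
        raise ValueError("need 0 <= n_meth <= n_total and n_total >= 1")
    p_value = float(stats.binom.sf(n_meth - 1, n_total, p_err))
    return (n_meth >= 1 and p_value < alpha), p_value


def call_sites(sites: pd.DataFrame, p_err: float, alpha: float = 0.05) -> pd.DataFrame:
    """Vectorised binomial calling over a site table (adds p_value, is_mC)."""
    if not 0.0 <= p_err <= 1.0:
        raise ValueError(f"p_err must be in [0,1], got {p_err}")
    out = sites.copy()
    if len(out) == 0:
        out["p_value"] = pd.Series(dtype=float)
        out["is_mC"] = pd.Series(dtype=bool)
        return out
    out["p_value"] = stats.binom.sf(out["n_meth"].to_numpy() - 1, out["n_total"].to_numpy(), p_err)
    out["is_mC"] = (out["n_meth"] >= 1) & (out["p_value"] < alpha)
    return out


def summarize_methylome(sites: pd.DataFrame, min_depth_for_level: int = 5) -> dict:
    """Per-context mC counts, densities, mean levels and a 10%-bin histogram.

    density = called mCs / covered cytosines in that context; the histogram
    uses only mCs covered by at least ``min_depth_for_level`` reads and its
    fractions sum to 1 whenever any qualifying mC exists.
    """
    summary: dict = {"contexts": {}, "histograms": {}}
    for ctx in ("CG", "CHG", "CHH"):
        sub = sites[sites["context"] == ctx]
        mc = sub[sub.get("is_mC", pd.Series(False, index=sub.index)).astype(bool)]
        covered = len(sub)
        summary["contexts"][ctx] = {
            "mc_count": int(len(mc)),
            "covered_c": covered,
            "density": len(mc) / covered if covered else 0.0,
            "mean_level_mc": float(mc["level"].mean()) if len(mc) else 0.0,
            "mean_level_all": float(sub["level"].mean()) if covered else 0.0,
        }
        deep = mc[mc["n_total"] >= min_depth_for_level]
        if len(deep):
            hist, _ = np.histogram(deep["level"], bins=np.linspace(0, 1, 11))
            summary["histograms"][ctx] = (hist / hist.sum()).tolist()
        else:
            summary["histograms"][ctx] = []
    all_mc = sites.get("is_mC", pd.Series(dtype=bool)).astype(bool)
    summary["total"] = {
        "mc_count": int(all_mc.sum()),
        "covered_c": int(len(sites)),
        "density": float(all_mc.sum() / len(sites)) if len(sites) else 0.0,
    }
    return summary
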