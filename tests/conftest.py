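"""Shared fixtures: small simulated studies, aligned and called once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bsmethpipe import mcall, snp
from bsmethpipe.align import BisulfiteAligner, dedupe_clonal
from bsmethpipe.simulate import (
    SAMPLES,
    SimConfig,
    simulate_bs_reads,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        contigs=[("chr1", 25_000, False), ("chrC", 4_000, True)],
        gene_count=10,
        te_count=8,
        smrna_count=4,
        depth=8,
        tag_count=30_000,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_aligned(small_study):
    """Deduplicated unique alignments of sample cult1 of the small study."""
    aligner = BisulfiteAligner(small_study.genome)
    records, stats = aligner.align_pairs(small_study.reads["cult1"][0])
    return dedupe_clonal(records), stats


@pytest.fixture(scope="session")
def small_sites(small_study, small_aligned):
    """Called site table for cult1 (chloroplast-calibrated)."""
    records, _ = small_aligned
    sites = mcall.pileup_cytosines(records, small_study.genome)
    est = mcall.estimate_error_rate(sites, small_study.genome.chloroplast)
    return mcall.call_sites(sites, est.p_err), est


@pytest.fixture(scope="session")
def snp_recovery_run():
    """~500 planted SNPs (~1/300 bp) on sample cult1 at 10x/strand, error-free.

    Tiled (even-coverage) fragment placement: the recovery claim is about
    the caller's resolution logic, so coverage is held at its nominal depth
    rather than Poisson-fluctuating.
    """
    cfg = SimConfig(
        seed=13,
        contigs=[("chr1", 150_000, False), ("chrC", 4_000, True)],
        gene_count=8,
        te_count=6,
        smrna_count=3,
        depth=10,
        placement="tiled",
        seq_error_rate=0.0,
        clonal_fraction=0.0,
        snp_branch_rates={"cult1": 1 / 300},
    )
    study = simulate_study(cfg, with_reads=False, with_tags=False)
    pairs, _ = simulate_bs_reads(
        study.truth.sample_genomes["cult1"], study.truth.methylation["cult1"], cfg, "cult1"
    )
    aligner = BisulfiteAligner(study.genome)
    records = dedupe_clonal(aligner.align_pairs(pairs)[0])
    calls, n_snp = snp.call_snps(study.genome, records)
    return study, calls, n_snp


@pytest.fixture(scope="session")
def dm_config() -> SimConfig:
    """Four-sample study with planted promoter DM genes at 15x depth."""
    return SimConfig(
        seed=7,
        contigs=[("chr1", 80_000, False), ("chrC", 5_000, True)],
        gene_count=30,
        te_count=15,
        smrna_count=8,
        depth=15,
        read_length=75,
        dm_fraction=1 / 3,
        dm_shift=0.4,
        dm_region="promoter",
        tag_count=40_000,
    )


@pytest.fixture(scope="session")
def dm_study(dm_config):
    return simulate_study(dm_config)


@pytest.fixture(scope="session")
def dm_called(dm_study):
    """Per-sample called sites and genotypes for the DM study."""
    aligner = BisulfiteAligner(dm_study.genome)
    sites, genotypes = {}, {}
    for s in SAMPLES:
        records = dedupe_clonal(aligner.align_pairs(dm_study.reads[s][0])[0])
        calls, _ = snp.call_snps(dm_study.genome, records)
        genotypes[s] = calls
        hits = calls[calls["is_snp"]]
        exclude = set(zip(hits["contig"], hits["pos"]))
        tab = mcall.pileup_cytosines(records, dm_study.genome, exclude=exclude)
        est = mcall.estimate_error_rate(tab, dm_study.genome.chloroplast)
        sites[s] = mcall.call_sites(tab, est.p_err)
    return sites, genotypes
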