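# Methods

## The analysis model

The pipeline targets directional paired-end bisulfite libraries from
inbred (effectively homozygous) plant lines mapped against a single
reference genome.  Its statistical core is:

- **Methylation evidence** at a cytosine is the pair (m, n): reads showing
  the methylated base (C on a plus-strand cytosine, G in plus-strand sense
  on a minus-strand cytosine) out of all quality-passing reads covering
  the site from the matching strand stratum.  The *methylation level* is
  m/n.
- **Null model**: an unmethylated cytosine still reads C with probability
  p = (non-conversion rate) + (T→C sequencing error), pooled into one
  scalar per sample because only their sum is identifiable.  p is
  estimated as Σm/Σn over every covered chloroplast cytosine — the
  chloroplast is constitutively unmethylated, so it is an in-library
  negative control.  A site is a methylcytosine when
  P(X ≥ m | X ~ Binomial(n, p)) < α with α = 0.05 and m ≥ 1.  The bound
  is per-site (no genome-wide correction): the realized false-positive
  rate on nulls is therefore ≤ α at every depth, and in practice far
  below it (≈2% averaged over depths 1–30 at p = 1.12%), because the
  discrete test is conservative.
- **Genotypes from bisulfite reads**: conversion makes C/T unreliable on
  a read's own strand, but each DNA strand is sequenced separately (reads
  mapping to the C→T-converted "T-genome" carry the plus strand, reads
  mapping to the G→A-converted "A-genome" the minus strand).  Writing
  everything in plus-strand sense: alleles A and G can only be trusted
  from the plus stratum, alleles C and T only from the minus stratum.
  The caller takes a per-stratum consensus (depth ≥ 5 at Q ≥ 30, majority
  fraction ≥ 0.9) and applies that resolution table; positions where both
  strata give confident calls in their deciding sets are contradictions
  (impossible for a clean homozygote) and are flagged and excluded.  This
  construction is *conversion-immune*: with no sequencing errors, no
  methylation state at any depth can produce a non-reference call.

## Tunable parameters (defaults)

| parameter | default | role |
| --- | --- | --- |
| base-quality cutoff, mC calling | Q20 | ≥ 99% per-base accuracy |
| base-quality cutoff, SNP calling | Q30 | ≥ 99.9% accuracy |
| SNP minimum stratum depth / majority fraction | 5 / 0.9 | homozygous consensus |
| mC test α | 0.05 | per-site false-positive bound |
| mismatch caps | 2 (44 nt), 4 (75 nt) | ungapped placement |
| genome windows | 50 kb, step 25 kb | trees, divergence |
| metagene bins | 5% window, 2.5% step → 39 body bins | profiles |
| promoter / TTR | 200 bp up of TSS / down of TTS | strand-aware |
| DM region coverage | > 80% of cytosine sites per sample | testability gate |
| expression change fold | 2 | DM–expression overlap |

Region summaries come in two exact variants: *absolute* level = Σ(mC site
levels)/region length, *relative* level = Σ(mC site levels)/number of
cytosine sites; `absolute = relative × n_C/length` holds identically.

## The synthetic study

The generator emulates a four-sample design on the fixed topology
`((cult1, cult2), (wild1, wild2))`:

- **Genome/annotation**: seeded random contigs (one flagged chloroplast)
  with mutually disjoint gene models (including 200 bp promoter/TTR
  flanks), TEs and smRNA loci on nuclear contigs only.
- **SNP truth**: homozygous substitutions drawn independently per branch
  (terminal rates ~5×10⁻⁴–10⁻³, internal 2×10⁻³ by default), applied to
  each sample's personal genome; never on the chloroplast.
- **Methylation truth**: per-site probability that a read shows C =
  compartment×context mean (TE ≫ gene body > flanks; CG > CHG > CHH)
  plus a per-site jitter shared by all samples (sd 0.12), a per-group
  per-site divergence (sd 0.04), and a small per-sample noise (sd 0.015),
  clipped to [0,1]; chloroplast ≡ 0.  A `dm_fraction` of genes gets a
  ±0.4 shift of the cultivated group over one region (promoter by
  default), planted with recorded direction.  Group and sample effects
  are independent *per site*, so within-group comparisons of a region are
  genuinely null — this is what makes the DM consistency rule's
  within-group non-significance requirement meaningful.
- **Reads**: fragments from both original strands (directional
  protocol); on the fragment's strand each cytosine reads C with
  probability p_meth + (1 − p_meth)·non-conversion (default 1.12%
  combined rate), generic sequencing errors at 0.1%, constant Q40
  qualities (optionally a low-quality fraction to exercise the Q20/Q30
  filters), insert 150–250 bp, 10% exact clonal duplicates, mean
  per-strand depth 6 by default (the study regime is ~4.5–13.5×).
  Fragment placement is uniform-random by default; a `tiled` mode places
  evenly spaced abutting-mate fragments for calibration experiments where
  coverage must sit at its nominal depth — at a mean of 10× the Poisson
  fluctuation of random placement alone leaves ~3% of positions below the
  SNP caller's depth-5 gate, which is a property of shotgun coverage, not
  of the caller, so recovery claims are evaluated under tiled placement.
- **Expression/DGE**: per-gene log-normal abundance with per-group
  effects (log2 sd 0.6) and sample noise; half of the planted DM genes
  are expression-coupled (4-fold, opposing the cultivated methylation
  shift).  Tags are CATG + 17 nt at the 3'-most eligible anchor, with a
  configurable probability of emitting an internal anchor to exercise the
  position diagnostic.

What the generator does **not** model: indels, heterozygosity,
PCR bias beyond exact clones, bisulfite degradation, quality-dependent
errors, context-specific conversion failure, chromatin-scale methylation
autocorrelation.  Passing tests therefore demonstrate the correctness of
the algorithms under the stated stochastic model, not robustness to every
artefact of real libraries.

## Numerical and design choices

- **Aligner**: exact ungapped k-mismatch search (pigeonhole seeding +
  full Hamming verification), equivalent by construction — and by test —
  to an exhaustive scan of both converted genomes.  "Uniquely mapped"
  is read strictly: an equal-best placement anywhere (either converted
  genome, any position) discards the pair.  Desk-scale genomes make this
  exactness affordable; an index-based mapper would only change speed,
  not results.
- **Mate overlap** within a pair is counted once (mate 1 wins) in both
  methylation and SNP pileups.
- **Clonal dedup** keeps the highest mean-quality record, ties to the
  first encountered; it is idempotent and never merges records differing
  in contig, either mate's start, or origin strand.
- **Wilcoxon rank-sum**: exact enumeration of the permutation
  distribution of U (ties included) for m + n ≤ 20, otherwise the normal
  approximation with tie and continuity corrections.  Fully tied data
  give p = 1.
- **Trees**: methylation and expression dendrograms use 1 − Spearman r
  with complete linkage (the linkage is configurable; the choice is not
  critical for 4 leaves).  The genomic tree is neighbour joining on
  p-distances over co-called positions.
- **π** uses all window bases in the denominator (positions not co-called
  in a pair count as non-differing), matching a SNP-table-based estimator.
- **Windows**: starts at multiples of the step; emission stops at the
  first window reaching the contig end, so no window is a subset of its
  predecessor and short contigs yield one whole-contig window.
- **Metagene bins**: integer-rounded percent intervals; bins overlap by
  design (5% width, 2.5% step), sites may contribute to two bins.
  Regions shorter than 40 bp are skipped.
- **mC calling near SNPs**: positions the sample's own genotype caller
  reports as non-reference are masked before methylation calling (a C→T
  substitution is indistinguishable from an unmethylated cytosine); a
  flag disables the mask.
- **Coverage** for the DM gate is the fraction of a region's cytosine
  sites with ≥ 1 read, and region Wilcoxon vectors use covered sites only
  (levels are undefined elsewhere).
- **DM–expression direction**: promoter/TTR methylation gains are
  expected to lower expression (and vice versa); gene-body DM accepts a
  fold change in either direction.
- Edge cytosines (within 2 bp of a contig end on their strand) get
  context `unknown` and are excluded from per-context summaries; in the
  simulator their truth level falls back to the CHH mean.

## Problem sizes

Tests and the demo run on 20–150 kb genomes at 2–30× per-strand depth
(seconds to a couple of minutes per stage on one core); the algorithms
are O(genome × depth) throughout, with the aligner's seed index the only
super-linear memory user.  All randomness flows from a single integer
seed through named child streams, so every artifact is bit-reproducible.

## Known limitations

Homozygous-only genotypes; no gapped or local alignment; tags mapped to
cDNAs, not the genome; no multiple-testing correction beyond the per-site
α (deliberate, matching the per-site bound); the within-group DM
non-significance requirement caps DM recall near (1 − α)² ≈ 0.90 even
with perfect data, since null within-group p-values fall below α at rate
α each.
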