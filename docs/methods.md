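# Methods

This note documents the models, rules and numerical choices behind
`haplotk`, and what the synthetic fixtures do and do not establish about
real data.

## Coordinates and data model

Internally all intervals are 0-based half-open `Region`s; VCF positions
(1-based), BED (0-based half-open) and `chrom:start-end` strings (1-based
inclusive) convert at the file boundary. Multi-allelic VCF rows are split
into one biallelic record per ALT at load time with the genotype
re-indexed, because matching and prioritization are defined per allele.
A missing deleteriousness annotation stays missing — a cutoff filter must
distinguish "unscored" from "benign" — and unscored records are excluded
from prioritization with a count. Symbolic ALTs and structural variants
beyond REF/ALT-representable indels are out of scope, as are CRAM input,
realignment, and any genome-wide data model: one targeted locus per run is
assumed.

## Quality filters

Reads: mapped, MAPQ ≥ 50 (default), and none of
secondary/supplementary/duplicate — the standard pre-filter for both
modalities' alignments; the filter is idempotent. Variant records:
FILTER ∈ {PASS, .} and allele depth ≥ 15 (default). Records whose allele
depth is missing cannot be qualified and are removed, counted separately
in the filter report: the pipeline only keeps records it can qualify.

## Context matching

Two callsets over the same locus may encode one haplotype change as
different record sets. The matcher works in three stages:

1. **Exact pass** — records identical in (chrom, pos, ref, alt) and
   zygosity match exactly. Phase orientation is not compared here
   because haplotype numbering between callers is arbitrary.
2. **Clustering** — remaining records from both sides are grouped by
   transitive overlap of their reference footprints padded by `pad`
   (default 10 bp, configurable). The padding must exceed typical
   indel left/right-shift distances; the synthetic generator caps its
   shifts at 8 bp for the same reason.
3. **Equivalence** — a cluster is *equivalent* iff some allowed haplotype
   placement makes both sides' reconstructed (hap1, hap2) sequence pairs
   equal over the cluster window, allowing the pair to be swapped
   wholesale between callsets. Phased hets sharing a phase set flip only
   as a block (their relative configuration — the cis/trans structure —
   is meaningful); each unphased het is enumerated over both placements,
   and a match that needed such enumeration is flagged phase-ambiguous.
   Hom-alt records sit on both haplotypes. Zygosity mismatches surface
   naturally as unequal strings. Placements that force two records to
   overlap on one haplotype are geometrically impossible and skipped;
   REF-vs-reference mismatches make the cluster discordant with an
   error note. Enumeration is capped at 2^12 placements per side;
   clusters beyond the cap (never observed at realistic density) are
   reported discordant-too-complex rather than guessed.

Concordance is counted per variant, not per record: an exact pair is one
concordant unit, an equivalent cluster one unit per variant class it
contains, each unique record one unit. Raw per-side record counts are
reported alongside so alternative denominator conventions can be
recomputed.

## Concordance metrics

With no gold standard, metrics are computed from both perspectives. From
perspective A: TP = A-records labeled exact or context-equivalent,
FP = unique-to-A, FN = unique-to-B. The *modified* accounting reclassifies
a unique record from FP to TP (and removes it from the other perspective's
FN) when it is credible in its own modality (QUAL ≥ 20, depth ≥ 15) and
the other modality's depth at its position is below 15 — below the
allele-depth pass threshold the other caller could not have emitted a
passing record there, so the site is a coverage gap, not a disagreement.
The rule's three thresholds are configurable and logged; records that
cannot be judged (missing annotations, no depth track) fail the rule and
are listed in an exclusion report. Reported rates round to 4 decimals,
half-even.

## Prioritization cascade

Stages are composable and monotone (each output ⊆ its input):

1. **Deleteriousness** — scaled CADD-style score ≥ 15, inclusive (15 is
   the conventional "potentially damaging" threshold).
2. **Sharing** — presence in every affected subject, matched by
   normalized (chrom, pos, ref, alt) after left-alignment so that
   representation differences cannot defeat the intersection.
3. **Trans filter** — AR disease from two variants of one gene requires
   them on opposite haplotypes. Retained: hom-alt candidates
   (self-satisfying); candidates with ≥ 1 trans partner (same phase set,
   opposite haplotypes; a hom-alt partner counts, since it occupies the
   opposite haplotype too); candidates in an ambiguous pair involving an
   *unphased* genotype (unprovable is not disprovable). Removed: phased
   hets whose every in-phase-set partner is cis, and singletons.
   Phased candidates in *different* phase sets are recorded as ambiguous
   pairs but do not by themselves rescue each other: blocks are
   independent, and if cross-block ambiguity retained candidates, no
   phased variant could ever be removed in multi-block data — the filter
   would be vacuous. This is the one place the design deliberately
   prefers the filter's purpose (excluding provable-cis and
   partner-less candidates) over maximal caution.
   Cohort mode evaluates the filter on each affected subject's haplotype
   data and requires survival in all; proband mode uses the single
   affected subject, skipping the sharing stage.

Ranking is by descending score, ties broken by ascending genomic
position.

## Enrichment and depth

Fold enrichment of a channel-split run is per-channel on-target signal of
the adaptive arm over the control arm. The default signal is bases of
on-target coverage (matching how enrichment of a locus is usually
quoted); read-count mode is provided for the read-ratio formulation.
The per-arm channel counts should come from the arm/channel map (the CLI
does this); falling back to distinct observed channels underestimates
thinly covered arms. A control arm with zero on-target signal yields an
infinite fold with a warning, not an exception. N50 is the largest read
length L such that reads of length ≥ L sum to at least half of all bases.
Depth profiles count filtered reads per base (filters first, consistent
with the pipeline ordering).

## Paired-depth KDE quantiles

A Gaussian product kernel with Scott's-rule bandwidth
(`scipy.stats.gaussian_kde`) is fitted over (depth_A, depth_B) at variant
sites. For each probability level p (defaults 0.25/0.5/0.75/0.95) the
density threshold whose super-level set encloses mass p is estimated by
Monte Carlo: 4000 seeded draws from the fitted density, threshold =
(1−p)-quantile of their densities. A point's quantile is the innermost
level whose threshold its density exceeds; points outside the largest
level get none. A degenerate (zero-variance) cloud assigns every point
the innermost quantile with a warning. KDE oversmoothing biases the
empirical inside-fraction slightly above p at moderate n (~0.52–0.54
observed at p = 0.5, n = 2000), within the ±0.05 calibration band the
tests assert. Unique-variant attribution labels each modality-unique
record `low_coverage_other` when the other modality's depth at its
position is below 15 (the same pass threshold as above).

## Synthetic generator

The generator defines the study conditions under which the toolkit is
validated; all of its outputs are deterministic for a given seed.

- **Reference**: each base repeats the previous with probability
  `homopolymer_boost` (default 0.25), else is drawn fresh at GC = 0.41
  (human-like); run lengths are geometric with continuation probability
  `boost + (1−boost)·p_base`, giving the homopolymer context that makes
  indel representation ambiguous.
- **Truth sets**: events are rejection-sampled ≥ 30 bp apart so that
  8 bp shift caps and near-pair composition can never collide. Indels are
  planted left-aligned (the canonical representation, so truth keys
  survive the composed encoding). A configurable fraction of indels get a
  companion SNV 2–3 bp downstream on the same haplotype to exercise
  composed-vs-decomposed records. Scores come from a low-score bulk plus
  heavy deleterious tail; with `causal=True` a SNV + 2-bp deletion pair is
  planted in trans with the top-2 scores while other high scorers are
  confined to one haplotype of a second phase set (cis decoys).
- **Re-encoding**: `left_aligned_composed` merges near pairs and
  left-aligns lone indels; `decomposed_shifted` keeps events atomic and
  right-shifts lone indels. Both styles must reconstruct byte-identical
  haplotype pairs — verified internally before emission; a failure is a
  generator bug and raises. This contract makes the generator a valid
  oracle for the matcher. Dropout regions then delete emitted records
  (calls missed for lack of coverage); unphased emission strips phase.
- **Reads**: lengths are log-normal; the population N50 of
  LogNormal(μ, σ) is exp(μ + σ²), so μ = ln(N50) − σ² analytically
  (σ = 0.6 long, 0.35 rejected). Both arms accumulate reads until their
  on-target base budget is met (adaptive: depth_mean × |target|; control:
  depth_mean/fold × |target|), so the realized per-channel enrichment
  concentrates near the requested fold — the generator's contract is to
  realize the requested conditions, with the residual stochasticity
  living in read lengths and placement. Rejected strands (default 4 per
  accepted read) are confined to the flanks.
- **Cascade cohorts** are constructed inversely: trans survivors occupy
  one phase set with interleaved haplotypes (top-2 scores on the causal
  pair), trans-removed candidates sit on one haplotype of a second phase
  set, non-shared high scorers are private to single samples, and
  sub-threshold decoys pad every callset, so the cascade reproduces the
  requested stage counts exactly. A single trans survivor among
  removable hets is unconstructible (it would need a hom-alt, which
  rescues every het) and is rejected with an explanation.

### What the fixtures do and do not show

The generator produces representation divergence, coverage dropouts,
phase structure and score distributions with known truth, which validates
the *logic* of matching, metrics, filtering and calibration. It does not
model base-level sequencing error, alignment artifacts, genotyping error,
structural variation, or real CADD score distributions — so 100%
round-trip concordance on fixtures demonstrates correctness of the
matcher, not an expected concordance level for real platform
comparisons, and exact cascade counts verify filter semantics, not
counts expected on any real family. Problem sizes in tests and the
acceptance script (20 kb loci with ~30–45 events, 1 Mb enrichment
references at 30× with 256+256 channels, 50–100 replicates) are chosen as
the smallest scales at which every stochastic quantity is measured with
comfortable margin.

## Known limitations

- Exact matching compares zygosity but not phase-set orientation across
  callers; within-cluster phase structure is compared, cross-cluster
  structure is not.
- The modified-metrics quality rule is a configurable stand-in for
  whatever rule a production pipeline would log; its defaults inherit the
  only printed anchors (QUAL 20, depth 15).
- Haplotype-resolved depth decomposition is limited to what phase tags in
  the read table provide; no haplotagging is performed.
- The matcher's enumeration cap makes pathologically dense clusters
  discordant rather than undecidable; at the enforced planting density
  this never triggers.
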