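"""Synthetic fixture generation with known ground truth.

Every input the toolkit consumes can be generated here: a random
reference with realistic homopolymer structure, a planted phased
diploid truth set (optionally containing a compound-heterozygous causal
pair in trans), two deliberately different VCF re-encodings of the same
haplotypes, channel-split read summaries from an adaptive-sampling run,
and paired two-modality depth tracks with dropout regions.

The defining contract of the re-encoding generator is that both styles
reconstruct byte-identical haplotype sequences — verified internally
with :func:`haplotk.context_match.apply_variants` before anything is
emitted — which makes it a valid oracle for the context-matching
module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .context_match import apply_variants
from .enrichment import depth_profile
from .genomic import (
    DepthProfile,
    HaplotkError,
    PhasedGenotype,
    ReadSummary,
    Region,
    VariantRecord,
)
from .io import DEFAULT_ARM_MAP, ArmChannelMap, CallsetTable
from .prioritize import CandidateVariant, TransPair


class GenerationError(HaplotkError):
    pass


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------


def make_reference(
    length: int,
    gc: float = 0.41,
    homopolymer_boost: float = 0.25,
    seed: int = 0,
) -> str:
    """A random DNA string with tunable GC content and homopolymer runs.

    Each base repeats the previous one with probability
    ``homopolymer_boost``; otherwise it is drawn fresh with the given GC
    fraction. Run lengths are therefore geometric with continuation
    probability ``homopolymer_boost + (1 - homopolymer_boost) * p_base``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be a fraction")
    if not (0.0 <= homopolymer_boost < 1.0):
        raise ValueError("homopolymer_boost must be in [0, 1)")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    fresh = rng.choice(4, size=length, p=probs)
    repeat = rng.random(length) < homopolymer_boost
    idx = np.empty(length, dtype=np.int64)
    idx[0] = fresh[0]
    for i in range(1, length):
        idx[i] = idx[i - 1] if repeat[i] else fresh[i]
    return "".join(bases[idx])


def homopolymer_run_lengths(sequence: str) -> List[int]:
    runs = []
    n = 1
    for a, b in zip(sequence, sequence[1:]):
        if a == b:
            n += 1
        else:
            runs.append(n)
            n = 1
    runs.append(n)
    return runs


# ---------------------------------------------------------------------------
# Truth sets
# ---------------------------------------------------------------------------


@dataclass
class TruthSet:
    """Planted ground truth backing every synthetic fixture."""

    reference: Dict[str, str]
    diploid_variants: List[VariantRecord]
    causal_pair: Optional[TransPair] = None
    dropout_regions: List[Region] = field(default_factory=list)
    planted_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.diploid_variants:
            seq = self.reference.get(v.chrom)
            if seq is None:
                raise GenerationError(f"variant on unknown sequence {v.chrom}")
            window = seq[v.pos - 1 : v.pos - 1 + len(v.ref_allele)]
            if window != v.ref_allele:
                raise GenerationError(
                    f"planted REF {v.ref_allele!r} mismatches reference {window!r} "
                    f"at {v.chrom}:{v.pos}"
                )
        if self.causal_pair is not None and self.causal_pair.phase_relation != "trans":
            raise GenerationError("causal pair must be in trans")


def _default_cadd(rng: np.random.Generator, n: int) -> np.ndarray:
    """Low-score bulk plus a heavy deleterious tail, on the scaled
    (phred-like) score axis."""
    bulk = rng.uniform(0.0, 14.5, size=n)
    tail = 15.0 + rng.exponential(scale=5.0, size=n)
    is_tail = rng.random(n) < 0.15
    return np.where(is_tail, np.minimum(tail, 45.0), bulk)


def _sample_positions(
    rng: np.random.Generator, seq_len: int, n: int, min_gap: int, margin: int = 25
) -> List[int]:
    """0-based anchor positions with pairwise distance >= min_gap."""
    positions: List[int] = []
    max_tries = 200 * max(n, 1)
    tries = 0
    while len(positions) < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place {n} variants with gap {min_gap} in {seq_len} bases"
            )
        p = int(rng.integers(margin, seq_len - margin))
        if all(abs(p - q) >= min_gap for q in positions):
            positions.append(p)
    positions.sort()
    return positions


_OTHER_BASES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def plant_diploid_variants(
    reference: Mapping[str, str],
    n_snv: int = 20,
    n_indel: int = 10,
    cadd_distribution=None,
    causal: bool = False,
    seed: int = 0,
    hom_fraction: float = 0.1,
    near_pair_fraction: float = 0.3,
    sample_id: str = "S1",
) -> TruthSet:
    """Plant a phased diploid truth set on the first reference sequence.

    Events are spaced >= 30 bp apart so that alternative encodings
    (shifts of up to ~8 bp, composition of near pairs) never collide.
    A ``near_pair_fraction`` of the indels get a companion SNV 2-3 bp
    downstream on the same haplotype, exercising composed-vs-decomposed
    representations. With ``causal=True`` the two top-scoring variants
    (one SNV, one 2-bp deletion) are placed in trans in phase set 1
    while every other high scorer is a phased het confined to one
    haplotype of phase set 2 (cis decoys).
    """
    if cadd_distribution is None:
        cadd_distribution = _default_cadd
    chrom = next(iter(reference))
    seq = reference[chrom]
    rng = np.random.default_rng(seed)
    n_pairs = int(round(near_pair_fraction * n_indel))
    n_anchors = n_snv + n_indel
    anchors = _sample_positions(rng, len(seq), n_anchors, min_gap=30)
    rng.shuffle(anchors)
    snv_anchors = sorted(anchors[:n_snv])
    indel_anchors = sorted(anchors[n_snv:])

    scores = np.asarray(cadd_distribution(rng, n_anchors), dtype=float)

    def _genotype(i: int) -> PhasedGenotype:
        if not causal and rng.random() < hom_fraction:
            return PhasedGenotype(1, 1, phased=True, phase_set=1)
        hap = int(rng.integers(1, 3))
        return PhasedGenotype(
            1 if hap == 1 else 0, 1 if hap == 2 else 0, phased=True, phase_set=1
        )

    records: List[VariantRecord] = []
    causal_records: List[VariantRecord] = []
    score_iter = iter(scores)

    def _make_snv(p0: int, genotype: PhasedGenotype, score: float) -> VariantRecord:
        ref = seq[p0]
        alt = _OTHER_BASES[ref][int(rng.integers(3))]
        return VariantRecord(
            chrom=chrom,
            pos=p0 + 1,
            ref_allele=ref,
            alt_allele=alt,
            genotype=genotype,
            filters=frozenset({"PASS"}),
            cadd_scaled=float(score),
            sample_id=sample_id,
        )

    def _make_indel(
        p0: int, genotype: PhasedGenotype, score: float, dlen=None, kind=None
    ) -> VariantRecord:
        if dlen is None:
            dlen = int(rng.integers(1, 7))
        if kind is None:
            kind = "del" if rng.random() < 0.5 else "ins"
        if kind == "del" and p0 + 1 + dlen <= len(seq):
            ref = seq[p0 : p0 + 1 + dlen]
            alt = seq[p0]
        else:
            ins = "".join(rng.choice(list("ACGT"), size=dlen))
            ref = seq[p0]
            alt = seq[p0] + ins
        rec = VariantRecord(
            chrom=chrom,
            pos=p0 + 1,
            ref_allele=ref,
            alt_allele=alt,
            genotype=genotype,
            filters=frozenset({"PASS"}),
            cadd_scaled=float(score),
            sample_id=sample_id,
        )
        # plant the canonical left-aligned representation so that the
        # truth keys survive the composed/left-aligned re-encoding
        return shift_indel(seq, rec, direction=-1, max_shift=8)

    if causal:
        # top-2 scores, one SNV + one 2-bp deletion, opposite haplotypes
        top = float(np.max(scores)) if len(scores) else 20.0
        causal_scores = (max(top, 20.0) + 2.0, max(top, 20.0) + 1.0)
        if not snv_anchors or not indel_anchors:
            raise GenerationError("causal planting needs at least one SNV and one indel")
        snv_p = snv_anchors.pop(0)
        del_p = indel_anchors.pop(0)
        g_snv = PhasedGenotype(1, 0, phased=True, phase_set=1)
        g_del = PhasedGenotype(0, 1, phased=True, phase_set=1)
        causal_snv = _make_snv(snv_p, g_snv, causal_scores[0])
        causal_del = _make_indel(del_p, g_del, causal_scores[1], dlen=2, kind="del")
        causal_records = [causal_snv, causal_del]
        records.extend(causal_records)

    pair_budget = n_pairs
    for p0 in snv_anchors:
        score = float(next(score_iter))
        if causal and score >= 15.0:
            g = PhasedGenotype(1, 0, phased=True, phase_set=2)  # cis decoy
        else:
            g = _genotype(p0)
        records.append(_make_snv(p0, g, score))
    for p0 in indel_anchors:
        score = float(next(score_iter))
        if causal and score >= 15.0:
            g = PhasedGenotype(1, 0, phased=True, phase_set=2)
        else:
            g = _genotype(p0)
        indel = _make_indel(p0, g, score)
        records.append(indel)
        if pair_budget > 0 and not causal:
            pair_budget -= 1
            gap = int(rng.integers(2, 4))
            companion_p0 = indel.pos - 1 + len(indel.ref_allele) + gap
            if companion_p0 < len(seq) - 25:
                records.append(_make_snv(companion_p0, indel.genotype, float(rng.uniform(0, 14))))

    records.sort(key=lambda r: (r.chrom, r.pos, r.ref_allele, r.alt_allele))
    causal_pair = None
    if causal:
        cands = [
            CandidateVariant(r, r.cadd_scaled, 1 if r.genotype.hap1_allele else 2)
            for r in causal_records
        ]
        causal_pair = TransPair(cands[0], cands[1], "trans")
    counts = {
        "total": len(records),
        "cadd": sum(1 for r in records if r.cadd_scaled >= 15.0),
        "snv": sum(1 for r in records if r.is_snv),
        "indel": sum(1 for r in records if r.is_indel),
    }
    return TruthSet(dict(reference), records, causal_pair, [], counts)


# ---------------------------------------------------------------------------
# Re-encoding of the same haplotypes
# ---------------------------------------------------------------------------


def _del_indices(rec: VariantRecord) -> Tuple[int, int]:
    """0-based first deleted index and deletion length."""
    return rec.pos, len(rec.ref_allele) - 1


def _shift_deletion(seq: str, rec: VariantRecord, direction: int, max_shift: int, lo: int, hi: int) -> VariantRecord:
    i, d = _del_indices(rec)  # deleting seq[i : i+d], anchor at i-1
    shifted = 0
    while shifted < max_shift:
        if direction > 0:
            if i + d >= len(seq) or i + d >= hi or seq[i] != seq[i + d]:
                break
            i += 1
        else:
            if i - 2 < 0 or i - 1 <= lo or seq[i - 1] != seq[i + d - 1]:
                break
            i -= 1
        shifted += 1
    return replace(rec, pos=i, ref_allele=seq[i - 1 : i + d], alt_allele=seq[i - 1])


def _shift_insertion(seq: str, rec: VariantRecord, direction: int, max_shift: int, lo: int, hi: int) -> VariantRecord:
    i = rec.pos  # inserting before 0-based index i, anchor at i-1
    ins = rec.alt_allele[1:]
    shifted = 0
    while shifted < max_shift:
        if direction > 0:
            if i >= len(seq) or i >= hi or ins[0] != seq[i]:
                break
            ins = ins[1:] + seq[i]
            i += 1
        else:
            if i - 2 < 0 or i - 1 <= lo or ins[-1] != seq[i - 1]:
                break
            ins = seq[i - 1] + ins[:-1]
            i -= 1
        shifted += 1
    return replace(rec, pos=i, ref_allele=seq[i - 1], alt_allele=seq[i - 1] + ins)


def shift_indel(
    chrom_seq: str,
    rec: VariantRecord,
    direction: int,
    max_shift: int = 8,
    lo: int = 0,
    hi: Optional[int] = None,
) -> VariantRecord:
    """Move an indel to a sequence-equivalent position ``direction`` (+1
    right / -1 left), at most ``max_shift`` steps, never crossing the
    [lo, hi) guard interval (footprints of neighboring records)."""
    hi = len(chrom_seq) if hi is None else hi
    if len(rec.ref_allele) > len(rec.alt_allele):
        return _shift_deletion(chrom_seq, rec, direction, max_shift, lo, hi)
    if len(rec.alt_allele) > len(rec.ref_allele):
        return _shift_insertion(chrom_seq, rec, direction, max_shift, lo, hi)
    return rec


def compose_records(chrom_seq: str, first: VariantRecord, second: VariantRecord) -> VariantRecord:
    """Merge two nearby same-genotype events into one spanning record."""
    if first.genotype != second.genotype:
        raise GenerationError("can only compose records with identical genotypes")
    a = first.pos - 1
    end = second.pos - 1 + len(second.ref_allele)
    ref = chrom_seq[a:end]
    alt = (
        first.alt_allele
        + chrom_seq[first.pos - 1 + len(first.ref_allele) : second.pos - 1]
        + second.alt_allele
    )
    return VariantRecord(
        chrom=first.chrom,
        pos=first.pos,
        ref_allele=ref,
        alt_allele=alt,
        genotype=first.genotype,
        qual=first.qual,
        filters=first.filters,
        depth=first.depth,
        allele_depth=first.allele_depth,
        cadd_scaled=max(
            (s for s in (first.cadd_scaled, second.cadd_scaled) if s is not None),
            default=None,
        ),
        sample_id=first.sample_id,
    )


REENCODE_STYLES = ("left_aligned_composed", "decomposed_shifted")


def reencode_callset(
    truth: TruthSet,
    style: str,
    drop_in_regions: Sequence[Region] = (),
    genotype_phase: str = "phased",
    seed: int = 0,
    depth_mean: float = 33.0,
    sample_id: Optional[str] = None,
) -> CallsetTable:
    """Emit the truth haplotypes under one of two representation styles.

    ``left_aligned_composed`` left-aligns indels and merges near pairs
    (same genotype, footprints <= 6 bp apart) into single composed
    records. ``decomposed_shifted`` keeps events atomic and shifts lone
    indels to their rightmost equivalent position. Before emission the
    haplotype sequences reconstructed from the emitted records are
    checked against the truth haplotypes; any disagreement is a
    generator bug and raises. ``drop_in_regions`` then removes emitted
    records whose footprint overlaps (simulating calls missed for lack
    of coverage), and ``genotype_phase="unphased"`` strips phase.
    """
    if style not in REENCODE_STYLES:
        raise GenerationError(f"unknown re-encoding style {style!r}")
    if genotype_phase not in ("phased", "unphased"):
        raise GenerationError(f"genotype_phase must be phased/unphased")
    rng = np.random.default_rng(seed)
    out: List[VariantRecord] = []
    by_chrom: Dict[str, List[VariantRecord]] = {}
    for r in truth.diploid_variants:
        by_chrom.setdefault(r.chrom, []).append(r)

    for chrom, recs in by_chrom.items():
        seq = truth.reference[chrom]
        recs = sorted(recs, key=lambda r: r.pos)
        emitted: List[VariantRecord] = []
        i = 0
        while i < len(recs):
            rec = recs[i]
            nxt = recs[i + 1] if i + 1 < len(recs) else None
            near = (
                nxt is not None
                and nxt.genotype == rec.genotype
                and (nxt.pos - 1) - (rec.pos - 1 + len(rec.ref_allele)) <= 6
            )
            prev_end = (
                recs[i - 1].pos - 1 + len(recs[i - 1].ref_allele) + 1 if i > 0 else 0
            )
            next_start = (nxt.pos - 2) if nxt is not None else len(seq)
            if style == "left_aligned_composed":
                if near:
                    emitted.append(compose_records(seq, rec, nxt))
                    i += 2
                    continue
                if rec.is_indel:
                    rec = shift_indel(seq, rec, direction=-1, lo=prev_end)
                emitted.append(rec)
            else:  # decomposed_shifted
                if rec.is_indel and not near:
                    rec = shift_indel(seq, rec, direction=+1, hi=next_start)
                emitted.append(rec)
            i += 1

        # generator contract: both encodings rebuild identical haplotypes
        window = Region(chrom, 0, len(seq))
        emitted_sorted = sorted(emitted, key=lambda r: r.pos)
        for hap in (1, 2):
            want = apply_variants(seq, window, recs, hap)
            got = apply_variants(seq, window, emitted_sorted, hap)
            if want != got:
                raise GenerationError(
                    f"re-encoding broke haplotype {hap} identity on {chrom}"
                )
        out.extend(emitted_sorted)

    kept: List[VariantRecord] = []
    for r in out:
        if any(r.ref_span().overlaps(reg) for reg in drop_in_regions):
            continue
        depth = max(16, int(rng.poisson(depth_mean)))
        allele = depth if r.genotype.is_hom_alt else max(15, depth // 2)
        genotype = r.genotype
        if genotype_phase == "unphased":
            genotype = replace(genotype, phased=False, phase_set=None)
        kept.append(
            replace(
                r,
                genotype=genotype,
                qual=float(np.round(rng.uniform(25.0, 60.0), 1)),
                depth=depth,
                allele_depth=allele,
                sample_id=sample_id or r.sample_id,
            )
        )
    label = "long_read" if style == "left_aligned_composed" else "short_read"
    sid = sample_id or (kept[0].sample_id if kept else "S1")
    return CallsetTable.from_records(kept, [sid], label)


# ---------------------------------------------------------------------------
# Reads and depth
# ---------------------------------------------------------------------------


def _lognormal_mu(n50_target: float, sigma: float) -> float:
    # population N50 of LogNormal(mu, sigma) is exp(mu + sigma^2)
    return math.log(n50_target) - sigma * sigma


def _channels_by_arm(arm_channel_map: ArmChannelMap) -> Dict[str, List[int]]:
    out: Dict[str, List[int]] = {"adaptive": [], "control": []}
    for (lo, hi), arm in arm_channel_map.items():
        out[arm].extend(range(lo, hi + 1))
    return out


def simulate_reads(
    reference: Mapping[str, str],
    target: Region,
    arm_channel_map: ArmChannelMap = DEFAULT_ARM_MAP,
    adaptive_n50: float = 9500.0,
    rejected_n50: float = 400.0,
    target_fold: float = 12.0,
    depth_mean: float = 30.0,
    dropout_regions: Sequence[Region] = (),
    rejected_per_accepted: float = 4.0,
    seed: int = 0,
) -> Tuple[List[ReadSummary], Dict[str, DepthProfile]]:
    """Simulate a channel-split adaptive-sampling run.

    Adaptive-arm on-target reads are drawn long (log-normal, population
    N50 = ``adaptive_n50``) until the requested mean on-target depth is
    reached; the strands that pore rejected appear as short off-target
    reads (N50 = ``rejected_n50``) confined to the flanks. The control
    arm sequences uniformly with the same length distribution until its
    on-target coverage is ``depth_mean / target_fold``, so the realized
    per-channel enrichment concentrates near ``target_fold``. Reads
    overlapping ``dropout_regions`` are discarded, leaving those
    intervals near depth zero.
    """
    chrom = target.chrom
    if chrom not in reference:
        raise GenerationError(f"target chromosome {chrom} not in reference")
    seq_len = len(reference[chrom])
    if target.end > seq_len:
        raise GenerationError("target extends beyond the reference")
    rng = np.random.default_rng(seed)
    channels = _channels_by_arm(arm_channel_map)
    for arm in ("adaptive", "control"):
        if not channels[arm]:
            raise GenerationError(f"arm/channel map assigns no channels to {arm!r}")
    sigma_long, sigma_rej = 0.6, 0.35
    mu_long = _lognormal_mu(adaptive_n50, sigma_long)
    mu_rej = _lognormal_mu(rejected_n50, sigma_rej)

    reads: List[ReadSummary] = []
    counter = 0

    def _read(arm: str, start: int, length: int) -> ReadSummary:
        nonlocal counter
        counter += 1
        return ReadSummary(
            read_id=f"{arm[:3]}{counter:07d}",
            length=length,
            mapped_region=Region(chrom, start, start + length),
            mapq=60,
            channel=int(rng.choice(channels[arm])),
            flags=frozenset(),
            arm=arm,
        )

    def _in_dropout(start: int, end: int) -> bool:
        return any(
            reg.chrom == chrom and start < reg.end and reg.start < end
            for reg in dropout_regions
        )

    # adaptive arm, accepted on-target reads
    goal = depth_mean * len(target)
    acc = 0.0
    guard = 0
    n_accepted = 0
    while acc < goal and guard < 2_000_000:
        guard += 1
        length = int(min(max(200, rng.lognormal(mu_long, sigma_long)), len(target)))
        start = int(rng.integers(target.start, target.end - length + 1))
        if _in_dropout(start, start + length):
            continue
        reads.append(_read("adaptive", start, length))
        n_accepted += 1
        acc += length

    # adaptive arm, rejected off-target reads in the flanks
    flanks = []
    if target.start > 0:
        flanks.append((0, target.start))
    if target.end < seq_len:
        flanks.append((target.end, seq_len))
    n_rejected = int(round(rejected_per_accepted * n_accepted)) if flanks else 0
    for _ in range(n_rejected):
        lo, hi = flanks[int(rng.integers(len(flanks)))]
        length = int(min(max(50, rng.lognormal(mu_rej, sigma_rej)), hi - lo))
        start = int(rng.integers(lo, hi - length + 1))
        if _in_dropout(start, start + length):
            continue
        reads.append(_read("adaptive", start, length))

    # control arm: uniform sequencing until its on-target budget is met
    goal_ctrl = depth_mean / target_fold * len(target) if target_fold > 0 else 0.0
    acc = 0.0
    guard = 0
    while acc < goal_ctrl and guard < 2_000_000:
        guard += 1
        length = int(min(max(200, rng.lognormal(mu_long, sigma_long)), seq_len))
        start = int(rng.integers(0, seq_len - length + 1))
        if _in_dropout(start, start + length):
            continue
        reads.append(_read("control", start, length))
        acc += max(0, min(start + length, target.end) - max(start, target.start))

    profiles = {
        arm: depth_profile([r for r in reads if r.arm == arm], target)
        for arm in ("adaptive", "control")
    }
    return reads, profiles


def simulate_depth_pair(
    region: Region,
    mean_a: float = 33.0,
    mean_b: float = 31.0,
    dropout_b: Sequence[Region] = (),
    seed: int = 0,
    noise_sd: float = 0.15,
    smooth_window: int = 301,
) -> Tuple[DepthProfile, DepthProfile]:
    """Paired two-modality depth tracks: smoothly varying Poisson depth
    around each modality's mean, with near-zero dropout intervals in
    modality B (emulating short-read dead zones)."""
    rng = np.random.default_rng(seed)
    n = len(region)

    def _track(mean: float, sub_rng) -> np.ndarray:
        if mean <= 0:
            return np.zeros(n, dtype=np.int64)
        noise = sub_rng.normal(0.0, noise_sd, size=n + smooth_window)
        kernel = np.ones(smooth_window) / smooth_window
        smooth = np.convolve(noise, kernel, mode="same")[: n] * math.sqrt(smooth_window)
        lam = mean * np.exp(smooth - smooth.var() / 2)
        return sub_rng.poisson(lam).astype(np.int64)

    depth_a = _track(mean_a, np.random.default_rng(rng.integers(2**31)))
    depth_b = _track(mean_b, np.random.default_rng(rng.integers(2**31)))
    for reg in dropout_b:
        if reg.chrom != region.chrom:
            continue
        s = max(reg.start, region.start) - region.start
        e = min(reg.end, region.end) - region.start
        if s < e:
            depth_b[s:e] = 0
    return DepthProfile(region, depth_a), DepthProfile(region, depth_b)


# ---------------------------------------------------------------------------
# Cascade cohorts with exact stage counts
# ---------------------------------------------------------------------------


def make_cascade_cohort(
    stage_counts: Mapping[str, int],
    n_samples: int = 3,
    affected: Sequence[str] = ("S1", "S2"),
    seed: int = 0,
) -> Tuple[Dict[str, CallsetTable], TruthSet]:
    """Construct per-sample callsets on which the prioritization cascade
    reproduces ``stage_counts`` exactly.

    Cohort counts carry keys ``{"cadd", "shared", "trans"}``; proband
    counts carry ``{"cadd", "trans"}``. Counts must be non-increasing.
    The trans-surviving candidates are built as opposite-haplotype sets
    inside one phase set (with the top-2 scores on the planted causal
    pair); trans-removed candidates are phased hets confined to one
    haplotype of a second phase set; sub-threshold decoys pad each
    sample.
    """
    keys = list(stage_counts)
    cohort = "shared" in stage_counts
    expected = ["cadd", "shared", "trans"] if cohort else ["cadd", "trans"]
    if keys != expected:
        raise GenerationError(f"stage_counts keys must be {expected}, got {keys}")
    values = [stage_counts[k] for k in expected]
    if any(b > a for a, b in zip(values, values[1:])) or any(v < 0 for v in values):
        raise GenerationError(f"stage counts must be non-increasing and >= 0: {values}")
    n_cadd = stage_counts["cadd"]
    n_base = stage_counts["shared"] if cohort else n_cadd
    n_trans = stage_counts["trans"]
    if n_trans == 1 and n_base > 1:
        raise GenerationError(
            "a single trans survivor among removable hets requires a hom-alt, "
            "which would rescue every other candidate; unconstructible"
        )

    samples = [f"S{i+1}" for i in range(max(n_samples, len(affected)))]
    affected = list(affected)
    for a in affected:
        if a not in samples:
            samples.append(a)
    if not cohort:
        samples = affected[:1]

    rng = np.random.default_rng(seed)
    n_low = 2 * max(n_cadd, 5)
    n_positions = n_cadd + n_low
    chrom = "chrT"
    seq_len = 40 * (n_positions + 4) + 200
    seq = make_reference(seq_len, seed=int(rng.integers(2**31)))
    reference = {chrom: seq}
    positions = _sample_positions(rng, seq_len, n_positions, min_gap=30)

    # descending distinct scores; survivors first so the causal pair tops the list
    high_scores = np.round(np.linspace(42.0, 15.5, num=max(n_cadd, 1)), 2)

    def _snv_at(p0: int, genotype, score, sample) -> VariantRecord:
        ref = seq[p0]
        alt = _OTHER_BASES[ref][0]
        return VariantRecord(
            chrom=chrom,
            pos=p0 + 1,
            ref_allele=ref,
            alt_allele=alt,
            genotype=genotype,
            qual=50.0,
            filters=frozenset({"PASS"}),
            depth=30,
            allele_depth=15,
            cadd_scaled=float(score),
            sample_id=sample,
        )

    pos_iter = iter(positions)
    shared_specs: List[Tuple[int, PhasedGenotype, float]] = []
    # trans survivors: one phase set, haplotypes interleaved so that the
    # top-2 scorers (the causal pair) land on opposite haplotypes
    for i in range(n_trans):
        if n_trans == 1:
            g = PhasedGenotype(1, 1, phased=True, phase_set=1)  # hom-alt survivor
        else:
            hap1 = 1 if i % 2 == 0 else 0
            g = PhasedGenotype(hap1, 1 - hap1, phased=True, phase_set=1)
        shared_specs.append((next(pos_iter), g, float(high_scores[i])))
    # trans-removed: second phase set, all on haplotype 1
    for i in range(n_trans, n_base):
        g = PhasedGenotype(1, 0, phased=True, phase_set=2)
        shared_specs.append((next(pos_iter), g, float(high_scores[i])))
    # non-shared high scorers: each private to exactly one sample
    private_specs: List[Tuple[int, PhasedGenotype, float, str]] = []
    for i in range(n_base, n_cadd):
        g = PhasedGenotype(1, 0, phased=True, phase_set=3)
        owner = samples[i % len(samples)]
        private_specs.append((next(pos_iter), g, float(high_scores[i]), owner))

    per_sample_records: Dict[str, List[VariantRecord]] = {s: [] for s in samples}
    for p0, g, score in shared_specs:
        carriers = affected if cohort else samples
        for s in carriers:
            per_sample_records[s].append(_snv_at(p0, g, score, s))
    for p0, g, score, owner in private_specs:
        per_sample_records[owner].append(_snv_at(p0, g, score, owner))
    for p0 in pos_iter:  # remaining positions: sub-threshold decoys
        owner = samples[int(rng.integers(len(samples)))]
        g = PhasedGenotype(1, 0, phased=True, phase_set=1)
        per_sample_records[owner].append(
            _snv_at(p0, g, float(rng.uniform(0.0, 14.9)), owner)
        )

    callsets = {
        s: CallsetTable.from_records(recs, [s], "long_read")
        for s, recs in per_sample_records.items()
    }
    causal_pair = None
    if n_trans >= 2:
        first = affected[0]
        top = sorted(
            (r for r in per_sample_records[first] if r.cadd_scaled >= 15.0),
            key=lambda r: -r.cadd_scaled,
        )[:2]
        cands = [
            CandidateVariant(r, r.cadd_scaled, 1 if r.genotype.hap1_allele else 2)
            for r in top
        ]
        causal_pair = TransPair(cands[0], cands[1], "trans")
    truth_union = []
    seen = set()
    for recs in per_sample_records.values():
        for r in recs:
            if r.key() not in seen:
                seen.add(r.key())
                truth_union.append(r)
    truth_union.sort(key=lambda r: r.pos)
    truth = TruthSet(reference, truth_union, causal_pair, [], dict(stage_counts))
    return callsets, truth
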