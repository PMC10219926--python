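"""Heuristic candidate narrowing for autosomal-recessive disease.

Three composable stages over phased, deleteriousness-annotated
callsets:

1. a scaled-deleteriousness cutoff (default >= 15, the conventional
   threshold above which a scaled CADD-style score is treated as
   potentially damaging);
2. intersection across the affected subjects of a family;
3. a trans-configuration filter: recessive disease from two different
   variants of one gene requires them on opposite haplotypes, so
   phased candidates whose every provable partner lies in cis are
   removed. Homozygous-alt candidates satisfy the recessive
   requirement alone and always pass.

The surviving candidates are ranked by descending score, ties broken
by genomic position.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .genomic import HaplotkError, VariantRecord
from .io import CallsetTable


class PrioritizeError(HaplotkError, ValueError):
    pass


@dataclass(frozen=True)
class CandidateVariant:
    """A scored candidate; unscored records are excluded upstream."""

    record: VariantRecord
    cadd_scaled: float
    haplotype: object  # 1, 2, "hom", or "unphased"
    shared_in: frozenset = frozenset()

    def key(self) -> Tuple[str, int, str, str]:
        return self.record.key()


@dataclass(frozen=True)
class TransPair:
    variant_x: CandidateVariant
    variant_y: CandidateVariant
    phase_relation: str  # "trans" | "cis" | "ambiguous"


def candidates_from_callset(
    callset: CallsetTable,
) -> Tuple[List[CandidateVariant], int]:
    """Build candidates from scored records; returns (candidates,
    number of unscored records excluded)."""
    candidates = []
    n_unscored = 0
    for r in callset.records:
        if r.cadd_scaled is None:
            n_unscored += 1
            continue
        g = r.genotype
        if g.is_hom_alt:
            hap: object = "hom"
        elif not g.phased:
            hap = "unphased"
        else:
            hap = 1 if g.hap1_allele == 1 else 2
        candidates.append(CandidateVariant(r, r.cadd_scaled, hap))
    return candidates, n_unscored


def filter_by_cadd(
    candidates: Sequence[CandidateVariant], cutoff: float = 15.0
) -> List[CandidateVariant]:
    """Keep candidates with scaled score >= cutoff (inclusive), order preserved."""
    return [c for c in candidates if c.cadd_scaled >= cutoff]


def shared_across(
    per_sample: Mapping[str, Sequence[CandidateVariant]],
    required_samples: Set[str],
) -> List[CandidateVariant]:
    """Candidates present (by chrom/pos/ref/alt) in every required
    sample; the returned objects come from the first required sample,
    with ``shared_in`` populated with every sample carrying the variant."""
    missing = set(required_samples) - set(per_sample)
    if missing:
        raise PrioritizeError(f"required samples absent from mapping: {sorted(missing)}")
    keysets = {s: {c.key() for c in cands} for s, cands in per_sample.items()}
    required = sorted(required_samples)
    shared_keys = set.intersection(*(keysets[s] for s in required)) if required else set()
    out = []
    for c in per_sample[required[0]]:
        if c.key() in shared_keys:
            carriers = frozenset(s for s, ks in keysets.items() if c.key() in ks)
            out.append(CandidateVariant(c.record, c.cadd_scaled, c.haplotype, carriers))
    return out


def _pair_relation(x: CandidateVariant, y: CandidateVariant) -> Optional[str]:
    """Phase relation between two candidates, or None when the pair is
    uninformative (both phased but in different phase sets: their
    relative orientation is unknowable and the pair neither proves
    trans nor rescues either candidate)."""
    gx, gy = x.record.genotype, y.record.genotype
    if gx.is_hom_alt or gy.is_hom_alt:
        return "trans"  # a hom-alt partner occupies the opposite haplotype too
    if not gx.phased or not gy.phased:
        return "ambiguous"
    if gx.phase_set != gy.phase_set or x.record.chrom != y.record.chrom:
        return None
    return "trans" if gx.hap1_allele != gy.hap1_allele else "cis"


def trans_filter(
    candidates: Sequence[CandidateVariant],
) -> Tuple[List[CandidateVariant], List[TransPair]]:
    """Remove candidates that cannot participate in a recessive
    configuration in this sample.

    Retained: hom-alt candidates (self-satisfying); candidates with at
    least one trans partner (same phase set, opposite haplotypes);
    candidates in at least one ambiguous pair involving an unphased
    genotype (unprovable is not disprovable). Removed: phased hets all
    of whose in-phase-set partners are cis and which have no unphased
    ambiguity — and singletons with no partner at all.
    """
    pairs: List[TransPair] = []
    retained: Set[int] = set()
    cands = list(candidates)
    for i, x in enumerate(cands):
        if x.record.genotype.is_hom_alt:
            retained.add(i)
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            rel = _pair_relation(cands[i], cands[j])
            if rel is None:
                continue
            pairs.append(TransPair(cands[i], cands[j], rel))
            if rel in ("trans", "ambiguous"):
                retained.add(i)
                retained.add(j)
    survivors = [c for i, c in enumerate(cands) if i in retained]
    return survivors, pairs


def rank_candidates(candidates: Sequence[CandidateVariant]) -> List[CandidateVariant]:
    """Descending score; ties broken by ascending (chrom, pos, ref, alt)."""
    return sorted(candidates, key=lambda c: (-c.cadd_scaled, c.key()))


@dataclass
class CascadeReport:
    mode: str
    stage_counts: "OrderedDict[str, int]"
    ranked: List[CandidateVariant]
    pairs: List[TransPair]
    n_unscored: int = 0

    def counts_tuple(self) -> Tuple[int, ...]:
        return tuple(self.stage_counts.values())


def run_cascade(
    per_sample_callsets: Mapping[str, CallsetTable],
    affected: Set[str],
    cutoff: float = 15.0,
    mode: str = "cohort",
) -> CascadeReport:
    """Run the narrowing cascade and report per-stage distinct-variant
    counts plus the final ranked list.

    ``cohort`` mode: score cutoff over the union of all samples, then
    intersection across affected samples, then the trans filter
    evaluated on each affected sample's haplotype data (a variant must
    survive in every affected sample). ``proband_only`` mode: cutoff
    and trans filter on the single affected sample, no intersection
    stage.
    """
    if mode not in ("cohort", "proband_only"):
        raise PrioritizeError(f"unknown mode {mode!r}")
    missing = set(affected) - set(per_sample_callsets)
    if missing:
        raise PrioritizeError(f"affected samples missing from callsets: {sorted(missing)}")
    if not affected:
        raise PrioritizeError("at least one affected sample is required")

    per_sample: Dict[str, List[CandidateVariant]] = {}
    n_unscored = 0
    for s, cs in per_sample_callsets.items():
        cands, n_miss = candidates_from_callset(cs)
        per_sample[s] = filter_by_cadd(cands, cutoff)
        n_unscored += n_miss

    counts: "OrderedDict[str, int]" = OrderedDict()
    affected_sorted = sorted(affected)

    if mode == "cohort":
        union_keys = {c.key() for cands in per_sample.values() for c in cands}
        counts["cadd"] = len(union_keys)
        shared = shared_across(per_sample, set(affected))
        shared_keys = {c.key() for c in shared}
        counts["shared"] = len(shared_keys)
        survivor_keys: Optional[Set[Tuple]] = None
        all_pairs: List[TransPair] = []
        for s in affected_sorted:
            sample_cands = [c for c in per_sample[s] if c.key() in shared_keys]
            survivors, pairs = trans_filter(sample_cands)
            all_pairs.extend(pairs)
            keys = {c.key() for c in survivors}
            survivor_keys = keys if survivor_keys is None else (survivor_keys & keys)
        survivor_keys = survivor_keys or set()
        counts["trans"] = len(survivor_keys)
        final = [c for c in shared if c.key() in survivor_keys]
        return CascadeReport(mode, counts, rank_candidates(final), all_pairs, n_unscored)

    proband = affected_sorted[0]
    cands = per_sample[proband]
    counts["cadd"] = len({c.key() for c in cands})
    survivors, pairs = trans_filter(cands)
    counts["trans"] = len({c.key() for c in survivors})
    return CascadeReport(mode, counts, rank_candidates(survivors), pairs, n_unscored)
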