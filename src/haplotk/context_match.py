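"""Haplotype-context matching of variant representations.

Two callsets over the same locus frequently encode the same underlying
haplotype change with different VCF records: one aligner reports a
composed indel where another reports several decomposed events, or an
indel is shifted to the other end of a homopolymer run. Record-level
comparison then under-reports concordance even though the reconstructed
haplotype sequences are identical.

This module decides, per cluster of discordant records, whether the two
encodings produce the same pair of haplotype sequences over a reference
window, and labels every record as ``exact``, ``context_equivalent``,
``unique_a`` or ``unique_b`` accordingly.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .genomic import HaplotkError, Region, VariantRecord
from .io import CallsetTable

LABELS = ("exact", "context_equivalent", "unique_a", "unique_b")

# Enumerating haplotype placements is exponential in the number of
# independently flippable units (phase-set groups + unphased hets);
# clusters are tiny in practice, so this cap only guards pathologies.
MAX_FLIP_UNITS = 12


class ContextMatchError(HaplotkError):
    pass


class ReferenceMismatchError(ContextMatchError):
    """A record's REF allele disagrees with the reference sequence."""


class OverlapError(ContextMatchError):
    """Two variants applied on the same haplotype overlap."""


class ClusterTooComplexError(ContextMatchError):
    pass


# ---------------------------------------------------------------------------
# Haplotype sequence reconstruction
# ---------------------------------------------------------------------------


def apply_variants(
    ref_seq: str,
    region: Region,
    variants: Sequence[VariantRecord],
    haplotype: int,
) -> str:
    """Rebuild one haplotype's sequence over ``region`` by substituting
    every variant whose genotype carries the ALT on the chosen haplotype.

    ``ref_seq`` is the reference sequence of ``region`` itself.
    Variants must be sorted by position; the ones applied on this
    haplotype must have pairwise non-overlapping REF footprints, and
    each REF allele is validated against the reference.
    """
    if len(ref_seq) != len(region):
        raise ValueError("ref_seq length does not match region length")
    pos_list = [v.pos for v in variants]
    if pos_list != sorted(pos_list):
        raise ValueError("variants must be sorted by position")
    applied = [v for v in variants if v.genotype.on_haplotype(haplotype)]
    return apply_edits(ref_seq, region, [(v.pos, v.ref_allele, v.alt_allele) for v in applied])


def apply_edits(
    ref_seq: str, region: Region, edits: Sequence[Tuple[int, str, str]]
) -> str:
    """Apply (1-based pos, ref, alt) substitutions right-to-left."""
    prev_end = None
    for pos, ref, _alt in edits:
        start0 = pos - 1
        end0 = start0 + len(ref)
        if start0 < region.start or end0 > region.end:
            raise ContextMatchError(
                f"variant footprint {pos}..{end0} outside window {region}"
            )
        if prev_end is not None and start0 < prev_end:
            raise OverlapError(
                f"applied variants overlap at {region.chrom}:{pos} on one haplotype"
            )
        prev_end = end0
        window_ref = ref_seq[start0 - region.start : end0 - region.start]
        if window_ref != ref:
            raise ReferenceMismatchError(
                f"REF allele {ref!r} does not match reference {window_ref!r} "
                f"at {region.chrom}:{pos}"
            )
    seq = ref_seq
    for pos, ref, alt in sorted(edits, key=lambda e: -e[0]):
        i = pos - 1 - region.start
        seq = seq[:i] + alt + seq[i + len(ref) :]
    return seq


# ---------------------------------------------------------------------------
# Clustering of discordant records
# ---------------------------------------------------------------------------


@dataclass
class VariantCluster:
    """Records from both callsets whose padded footprints overlap transitively."""

    region: Region
    members_a: List[VariantRecord] = field(default_factory=list)
    members_b: List[VariantRecord] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members_a) + len(self.members_b)


def cluster_discordant(
    records_a: Sequence[VariantRecord],
    records_b: Sequence[VariantRecord],
    pad: int = 10,
) -> List[VariantCluster]:
    """Group not-exactly-matched records into maximal clusters whose
    padded reference footprints overlap transitively. One-sided
    singleton clusters are allowed (and signal unique calls)."""
    tagged = [("a", r) for r in records_a] + [("b", r) for r in records_b]
    tagged.sort(key=lambda t: (t[1].chrom, t[1].pos, t[1].ref_allele, t[1].alt_allele, t[0]))
    clusters: List[VariantCluster] = []
    current: Optional[VariantCluster] = None
    current_end = -1
    for side, rec in tagged:
        span = rec.ref_span().padded(pad)
        if (
            current is None
            or span.chrom != current.region.chrom
            or span.start >= current_end
        ):
            current = VariantCluster(region=span)
            clusters.append(current)
            current_end = span.end
        else:
            current.region = current.region.union(span)
            current_end = max(current_end, span.end)
        (current.members_a if side == "a" else current.members_b).append(rec)
    return clusters


# ---------------------------------------------------------------------------
# Cluster equivalence
# ---------------------------------------------------------------------------


def _flip_units(records: Sequence[VariantRecord]):
    """Partition records into flippable units for haplotype enumeration.

    Phased hets sharing a phase set form one unit (their relative
    orientation is meaningful; only the whole block's labeling is
    arbitrary). Each unphased het is its own unit. Hom-alt records sit
    on both haplotypes and are fixed.
    """
    groups: Dict[object, List[VariantRecord]] = defaultdict(list)
    singles: List[VariantRecord] = []
    fixed: List[VariantRecord] = []
    for r in records:
        g = r.genotype
        if g.is_hom_alt:
            fixed.append(r)
        elif g.phased:
            groups[("ps", r.chrom, g.phase_set)].append(r)
        else:
            singles.append(r)
    units = list(groups.values()) + [[r] for r in singles]
    return units, fixed


def _haplotype_edit_sets(records: Sequence[VariantRecord]):
    """Yield (edits_hap1, edits_hap2) tuples over all allowed haplotype
    placements of ``records`` (phase-set blocks flip wholesale, unphased
    hets flip individually, hom-alts go to both haplotypes)."""
    units, fixed = _flip_units(records)
    if len(units) > MAX_FLIP_UNITS:
        raise ClusterTooComplexError(
            f"cluster has {len(units)} independently phaseable units (cap {MAX_FLIP_UNITS})"
        )
    fixed_edits = [(r.pos, r.ref_allele, r.alt_allele) for r in fixed]
    for flips in itertools.product((False, True), repeat=len(units)):
        hap1 = list(fixed_edits)
        hap2 = list(fixed_edits)
        for unit, flip in zip(units, flips):
            for r in unit:
                on_h1 = r.genotype.hap1_allele == 1
                if flip:
                    on_h1 = not on_h1
                (hap1 if on_h1 else hap2).append((r.pos, r.ref_allele, r.alt_allele))
        yield tuple(sorted(hap1)), tuple(sorted(hap2))


@dataclass
class ClusterVerdict:
    cluster: VariantCluster
    verdict: str  # "equivalent" | "discordant"
    phase_ambiguous: bool = False
    error: Optional[str] = None


def match_cluster(
    cluster: VariantCluster, reference: Mapping[str, str]
) -> ClusterVerdict:
    """Decide whether the two sides of a cluster encode the same pair of
    haplotype sequences over the cluster window.

    Haplotype labelings may be swapped wholesale per phase set (between
    and within callsets the numbering is arbitrary); unphased hets are
    enumerated over both placements and a match found that way is
    flagged phase-ambiguous. Zygosity mismatches surface naturally as
    unequal haplotype strings.
    """
    chrom = cluster.region.chrom
    if chrom not in reference:
        return ClusterVerdict(cluster, "discordant", error=f"no reference for {chrom}")
    chrom_seq = reference[chrom]
    region = Region(chrom, cluster.region.start, min(cluster.region.end, len(chrom_seq)))
    ref_seq = chrom_seq[region.start : region.end]

    if not cluster.members_a or not cluster.members_b:
        return ClusterVerdict(cluster, "discordant")

    def side_strings(members):
        out = []
        for hap1, hap2 in _haplotype_edit_sets(members):
            try:
                s1 = apply_edits(ref_seq, region, list(hap1))
                s2 = apply_edits(ref_seq, region, list(hap2))
            except OverlapError:
                continue  # this placement is geometrically impossible
            out.append((s1, s2))
        return out

    n_units_a = len(_flip_units(cluster.members_a)[0])
    n_units_b = len(_flip_units(cluster.members_b)[0])
    try:
        strings_a = side_strings(cluster.members_a)
        strings_b = set()
        pairs_b = side_strings(cluster.members_b)
        for s1, s2 in pairs_b:
            strings_b.add((s1, s2))
            strings_b.add((s2, s1))
    except (ReferenceMismatchError, ContextMatchError) as exc:
        return ClusterVerdict(cluster, "discordant", error=str(exc))
    for pair in strings_a:
        if pair in strings_b:
            # a single phased unit per side means the match needed no
            # genuinely ambiguous placement beyond arbitrary labeling
            ambiguous = n_units_a > 1 or n_units_b > 1
            return ClusterVerdict(cluster, "equivalent", phase_ambiguous=ambiguous)
    return ClusterVerdict(cluster, "discordant")


# ---------------------------------------------------------------------------
# Whole-callset classification
# ---------------------------------------------------------------------------


@dataclass
class CallsetComparison:
    """Per-record labels plus cluster provenance for two callsets."""

    records_a: List[VariantRecord]
    records_b: List[VariantRecord]
    labels_a: List[str]
    labels_b: List[str]
    clusters: List[ClusterVerdict]

    def records_with_label(self, side: str, label: str) -> List[VariantRecord]:
        records = self.records_a if side == "a" else self.records_b
        labels = self.labels_a if side == "a" else self.labels_b
        return [r for r, l in zip(records, labels) if l == label]

    def unique_records(self, side: str) -> List[VariantRecord]:
        return self.records_with_label(side, f"unique_{side}")

    def count(self, side: str, label: str, variant_class: str = "all") -> int:
        recs = self.records_with_label(side, label)
        if variant_class != "all":
            recs = [r for r in recs if r.variant_class == variant_class]
        return len(recs)

    def summary(self) -> dict:
        out = {}
        for side in ("a", "b"):
            for label in LABELS:
                for vc in ("all", "snv", "indel"):
                    out[f"{side}_{label}_{vc}"] = self.count(side, label, vc)
        out["n_clusters"] = len(self.clusters)
        out["n_equivalent_clusters"] = sum(
            1 for c in self.clusters if c.verdict == "equivalent"
        )
        return out


def _exact_key(r: VariantRecord):
    return (r.chrom, r.pos, r.ref_allele, r.alt_allele, r.genotype.zygosity)


def classify_callsets(
    callset_a: CallsetTable,
    callset_b: CallsetTable,
    reference: Mapping[str, str],
    region: Optional[Region] = None,
    pad: int = 10,
) -> CallsetComparison:
    """Label every record of both callsets.

    Records identical in (chrom, pos, ref, alt) and zygosity are
    ``exact`` (haplotype numbering between callers is arbitrary, so
    phase orientation is not compared at this step). The rest are
    clustered by padded-footprint overlap; members of clusters whose
    haplotype sequences agree are ``context_equivalent``; members of
    discordant clusters are ``unique_a``/``unique_b`` by origin.
    """
    if region is not None:
        callset_a = callset_a.restricted_to(region)
        callset_b = callset_b.restricted_to(region)
    records_a = list(callset_a.records)
    records_b = list(callset_b.records)
    labels_a: List[Optional[str]] = [None] * len(records_a)
    labels_b: List[Optional[str]] = [None] * len(records_b)

    by_key_b: Dict[object, List[int]] = defaultdict(list)
    for j, r in enumerate(records_b):
        by_key_b[_exact_key(r)].append(j)
    for i, r in enumerate(records_a):
        stack = by_key_b.get(_exact_key(r))
        if stack:
            j = stack.pop(0)
            labels_a[i] = "exact"
            labels_b[j] = "exact"

    rest_a = [(i, r) for i, r in enumerate(records_a) if labels_a[i] is None]
    rest_b = [(j, r) for j, r in enumerate(records_b) if labels_b[j] is None]
    clusters = cluster_discordant([r for _, r in rest_a], [r for _, r in rest_b], pad=pad)

    index_a = {id(r): i for i, r in rest_a}
    index_b = {id(r): j for j, r in rest_b}
    verdicts: List[ClusterVerdict] = []
    for cluster in clusters:
        verdict = match_cluster(cluster, reference)
        verdicts.append(verdict)
        if verdict.verdict == "equivalent":
            label_a = label_b = "context_equivalent"
        else:
            label_a, label_b = "unique_a", "unique_b"
        for r in cluster.members_a:
            labels_a[index_a[id(r)]] = label_a
        for r in cluster.members_b:
            labels_b[index_b[id(r)]] = label_b

    assert all(l is not None for l in labels_a + labels_b)
    return CallsetComparison(records_a, records_b, labels_a, labels_b, verdicts)


def concordance_rates(comparison: CallsetComparison) -> Dict[str, Optional[float]]:
    """Per-class concordance after context matching.

    The unit of counting is the variant, not the record: an exact pair
    counts once, an equivalent cluster counts once per variant class it
    contains, and each unique record counts once. Raw per-side record
    counts live in :meth:`CallsetComparison.summary` so alternative
    denominators can be recomputed.
    """
    rates: Dict[str, Optional[float]] = {}
    for vc in ("snv", "indel"):
        concordant = comparison.count("a", "exact", vc)
        for cv in comparison.clusters:
            if cv.verdict == "equivalent":
                members = cv.cluster.members_a + cv.cluster.members_b
                if any(m.variant_class == vc for m in members):
                    concordant += 1
        unique = comparison.count("a", "unique_a", vc) + comparison.count(
            "b", "unique_b", vc
        )
        total = concordant + unique
        rates[vc] = None if total == 0 else concordant / total
    return rates
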