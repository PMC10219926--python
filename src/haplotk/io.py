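"""Readers and writers for the standard formats the toolkit touches,
plus the read- and variant-level quality filters applied before any
downstream analysis (MAPQ >= 50 on reads; PASS + allele depth >= 15 on
variant records).

VCF traffic goes through :mod:`pysam`; FASTA through Biopython. The
read-summary table is a small TSV dialect (documented in the README)
so that the whole test surface stays text-only; importing directly from
an indexed alignment file is available behind ``allow_alignment=True``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO

from .genomic import (
    DepthProfile,
    HaplotkError,
    PhasedGenotype,
    ReadSummary,
    Region,
    VariantRecord,
)


class FormatError(HaplotkError, ValueError):
    """Malformed or unusable input file."""


SOURCE_LABELS = ("long_read", "short_read", "truth", "other")

_RECORD_SORT_KEY = lambda r: (r.chrom, r.pos, r.ref_allele, r.alt_allele)  # noqa: E731


@dataclass
class CallsetTable:
    """An ordered, de-duplicated collection of VariantRecords for one sample."""

    sample_ids: List[str]
    records: List[VariantRecord]
    source_label: str = "other"

    def __post_init__(self) -> None:
        if self.source_label not in SOURCE_LABELS:
            raise ValueError(f"source_label must be one of {SOURCE_LABELS}")
        keys = [_RECORD_SORT_KEY(r) for r in self.records]
        if keys != sorted(keys):
            raise ValueError("CallsetTable records must be sorted by (chrom,pos,ref,alt)")
        if len(set(keys)) != len(keys):
            raise ValueError("CallsetTable records contain exact duplicates")

    @classmethod
    def from_records(
        cls,
        records: Iterable[VariantRecord],
        sample_ids: Sequence[str],
        source_label: str = "other",
    ) -> "CallsetTable":
        """Sort records and drop exact duplicate sites, keeping the first."""
        seen = set()
        out = []
        for r in sorted(records, key=_RECORD_SORT_KEY):
            k = _RECORD_SORT_KEY(r)
            if k in seen:
                continue
            seen.add(k)
            out.append(r)
        return cls(list(sample_ids), out, source_label)

    def restricted_to(self, region: Region) -> "CallsetTable":
        recs = [r for r in self.records if r.ref_span().overlaps(region)]
        return CallsetTable(self.sample_ids, recs, self.source_label)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into a mapping of name -> upper-case sequence."""
    sequences: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate sequence name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence {rec.id!r} in {path}")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"no sequences found in {path}")
    return sequences


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _cadd_for_alt(value, alt_index0: int) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if alt_index0 < len(value) and value[alt_index0] is not None:
            return float(value[alt_index0])
        if len(value) == 1 and value[0] is not None:
            return float(value[0])
        return None
    return float(value)


def read_vcf(
    path,
    sample: Optional[str] = None,
    cadd_key: str = "CADD",
    region: Optional[Region] = None,
    source_label: str = "other",
) -> CallsetTable:
    """Load one sample's calls from a VCF 4.x file.

    Phased ``|`` genotypes populate the two haplotype slots directly
    (with the ``PS`` phase set when present); ``/`` genotypes are loaded
    with ``phased=False``. Multi-allelic rows are split into one record
    per ALT with the genotype re-indexed per allele. The scaled
    deleteriousness annotation is looked up first in FORMAT, then INFO,
    under ``cadd_key``.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if not samples:
            raise FormatError(f"VCF {path} carries no sample columns")
        if sample is None:
            sample = samples[0]
        if sample not in samples:
            raise FormatError(f"sample {sample!r} not in VCF {path} (has {samples})")
        records: List[VariantRecord] = []
        for rec in vf:
            if region is not None and not (
                rec.chrom == region.chrom
                and rec.start < region.end
                and region.start < rec.stop
            ):
                continue
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or all(g is None for g in gt):
                raise FormatError(
                    f"missing GT for sample {sample!r} at {rec.chrom}:{rec.pos}"
                )
            if len(gt) != 2:
                raise FormatError(
                    f"non-diploid GT {gt} at {rec.chrom}:{rec.pos} is not supported"
                )
            phased = bool(call.phased)
            ps = call.get("PS")
            dp = call.get("DP")
            ad = call.get("AD")
            fmt_cadd = call.get(cadd_key) if cadd_key in vf.header.formats else None
            info_cadd = rec.info.get(cadd_key) if cadd_key in vf.header.info else None
            filters = frozenset(rec.filter.keys())
            for k, alt in enumerate(rec.alts or (), start=1):
                if alt is None or set(alt) - set("ACGTN"):
                    continue  # symbolic / breakend ALTs are out of scope
                hap1 = 1 if gt[0] == k else 0
                hap2 = 1 if gt[1] == k else 0
                if hap1 == 0 and hap2 == 0:
                    continue  # this sample does not carry the ALT
                genotype = PhasedGenotype(
                    hap1_allele=hap1,
                    hap2_allele=hap2,
                    phased=phased,
                    phase_set=int(ps) if (phased and ps is not None) else None,
                )
                allele_depth = None
                if isinstance(ad, (tuple, list)) and len(ad) > k and ad[k] is not None:
                    allele_depth = int(ad[k])
                cadd = _cadd_for_alt(fmt_cadd, 0 if not isinstance(fmt_cadd, (tuple, list)) else k - 1)
                if cadd is None:
                    cadd = _cadd_for_alt(info_cadd, k - 1)
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref.upper(),
                        alt_allele=alt.upper(),
                        genotype=genotype,
                        qual=None if rec.qual is None else float(rec.qual),
                        filters=filters,
                        depth=None if dp is None else int(dp),
                        allele_depth=allele_depth,
                        cadd_scaled=cadd,
                        sample_id=sample,
                    )
                )
    return CallsetTable.from_records(records, [sample], source_label)


def write_vcf(
    callset: CallsetTable,
    path,
    contig_lengths: Optional[Mapping[str, int]] = None,
    cadd_key: str = "CADD",
) -> None:
    """Write a CallsetTable as an uncompressed VCF, round-trippable by
    :func:`read_vcf` (pos, alleles, genotype, phase set, qual, DP, AD
    and the deleteriousness annotation are preserved in value)."""
    keys = [_RECORD_SORT_KEY(r) for r in callset.records]
    if keys != sorted(keys):
        raise FormatError("write_vcf requires records sorted by (chrom,pos,ref,alt)")
    if len(callset.sample_ids) != 1:
        raise FormatError("write_vcf emits single-sample VCFs")
    sample = callset.sample_ids[0]

    header = pysam.VariantHeader()
    chroms: Dict[str, int] = {}
    for r in callset.records:
        end = r.pos - 1 + len(r.ref_allele)
        chroms[r.chrom] = max(chroms.get(r.chrom, 0), end)
    if contig_lengths:
        for c, ln in contig_lengths.items():
            chroms[c] = max(chroms.get(c, 0), int(ln))
    for c, ln in chroms.items():
        header.contigs.add(c, length=ln)
    for r in callset.records:
        for f in r.filters:
            if f not in ("PASS", ".") and f not in header.filters:
                header.filters.add(f, None, None, "imported filter")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set identifier")
    header.formats.add("DP", 1, "Integer", "Read depth at this position")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add(cadd_key, 1, "Float", "Scaled deleteriousness score")
    header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in callset.records:
            nr = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos - 1 + len(r.ref_allele),
                alleles=(r.ref_allele, r.alt_allele),
            )
            nr.qual = r.qual
            if r.filters:
                for f in sorted(r.filters):
                    if f != ".":
                        nr.filter.add(f)
            call = nr.samples[sample]
            call["GT"] = (r.genotype.hap1_allele, r.genotype.hap2_allele)
            call.phased = r.genotype.phased
            if r.genotype.phase_set is not None:
                call["PS"] = r.genotype.phase_set
            if r.depth is not None:
                call["DP"] = r.depth
            if r.allele_depth is not None:
                ref_ad = None
                if r.depth is not None:
                    ref_ad = max(r.depth - r.allele_depth, 0)
                call["AD"] = (ref_ad, r.allele_depth)
            if r.cadd_scaled is not None:
                call[cadd_key] = r.cadd_scaled
            out.write(nr)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

EXCLUDED_READ_FLAGS = frozenset({"secondary", "supplementary", "duplicate"})


def filter_reads(reads: Sequence[ReadSummary], min_mapq: int = 50) -> List[ReadSummary]:
    """Keep primary mapped reads with MAPQ >= ``min_mapq``; drop
    secondary, supplementary and duplicate alignments. Idempotent."""
    return [
        r
        for r in reads
        if r.is_mapped
        and r.mapq is not None
        and r.mapq >= min_mapq
        and not (r.flags & EXCLUDED_READ_FLAGS)
    ]


@dataclass
class PassingFilterResult:
    """Outcome of the passing-variant filter, with removal accounting."""

    callset: CallsetTable
    removed_nonpass: int = 0
    removed_low_allele_depth: int = 0
    removed_missing_allele_depth: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.removed_nonpass
            + self.removed_low_allele_depth
            + self.removed_missing_allele_depth
        )


def filter_passing_variants(
    callset: CallsetTable, min_allele_depth: int = 15
) -> PassingFilterResult:
    """Split a callset into passing variants: FILTER in {PASS, .} and
    allele depth >= ``min_allele_depth``. Records whose allele depth is
    missing cannot be qualified and are removed (and counted)."""
    kept: List[VariantRecord] = []
    result = PassingFilterResult(callset)
    for r in callset.records:
        if r.filters - {"PASS", "."}:
            result.removed_nonpass += 1
        elif r.allele_depth is None:
            if min_allele_depth > 0:
                result.removed_missing_allele_depth += 1
            else:
                kept.append(r)
        elif r.allele_depth < min_allele_depth:
            result.removed_low_allele_depth += 1
        else:
            kept.append(r)
    result.callset = CallsetTable(callset.sample_ids, kept, callset.source_label)
    return result


# ---------------------------------------------------------------------------
# Read-summary tables
# ---------------------------------------------------------------------------

READ_TSV_COLUMNS = [
    "read_id",
    "chrom",
    "start",
    "end",
    "mapq",
    "channel",
    "flags",
    "length",
]

ArmChannelMap = Mapping[Tuple[int, int], str]

DEFAULT_ARM_MAP: ArmChannelMap = {(1, 256): "adaptive", (257, 512): "control"}


def arm_for_channel(channel: int, arm_channel_map: ArmChannelMap) -> str:
    for (lo, hi), arm in arm_channel_map.items():
        if lo <= channel <= hi:
            return arm
    raise FormatError(f"channel {channel} not covered by the arm/channel map")


def parse_arm_map(text: str) -> ArmChannelMap:
    """Parse ``"1-256:adaptive,257-512:control"`` into an arm/channel map."""
    out: Dict[Tuple[int, int], str] = {}
    for part in text.split(","):
        rng, _, arm = part.strip().partition(":")
        lo, _, hi = rng.partition("-")
        if not (lo.isdigit() and hi.isdigit()) or arm not in ("adaptive", "control"):
            raise FormatError(f"malformed arm map entry {part!r}")
        out[(int(lo), int(hi))] = arm
    return out


def import_read_summaries(
    path,
    arm_channel_map: ArmChannelMap = DEFAULT_ARM_MAP,
    allow_alignment: bool = False,
) -> List[ReadSummary]:
    """Load per-read summaries from the TSV dialect (or, when
    ``allow_alignment`` is set and the path ends in .bam/.sam, from an
    alignment file with channel ids in the ``ch`` tag)."""
    p = str(path)
    if p.endswith((".bam", ".sam", ".cram")):
        if not allow_alignment:
            raise FormatError(
                "alignment import is disabled; pass allow_alignment=True or use the TSV dialect"
            )
        return _import_from_alignment(p, arm_channel_map)
    reads: List[ReadSummary] = []
    with open(p) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(READ_TSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"read TSV {path} is missing columns {sorted(missing)}")
        for row in reader:
            channel = int(row["channel"])
            arm = arm_for_channel(channel, arm_channel_map)
            unmapped = row["chrom"] in (".", "")
            region = None
            mapq = None
            flags = frozenset(
                f for f in row["flags"].split(",") if f and f != "."
            )
            if unmapped:
                flags = flags | {"unmapped"}
            else:
                region = Region(row["chrom"], int(row["start"]), int(row["end"]))
                mapq = int(row["mapq"])
            reads.append(
                ReadSummary(
                    read_id=row["read_id"],
                    length=int(row["length"]),
                    mapped_region=region,
                    mapq=mapq,
                    channel=channel,
                    flags=flags,
                    arm=arm,
                )
            )
    return reads


def _import_from_alignment(path: str, arm_channel_map: ArmChannelMap) -> List[ReadSummary]:
    reads: List[ReadSummary] = []
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for aln in af:
            flags = set()
            if aln.is_secondary:
                flags.add("secondary")
            if aln.is_supplementary:
                flags.add("supplementary")
            if aln.is_duplicate:
                flags.add("duplicate")
            if aln.is_unmapped:
                flags.add("unmapped")
            channel = int(aln.get_tag("ch")) if aln.has_tag("ch") else 0
            region = None
            mapq = None
            if not aln.is_unmapped:
                region = Region(aln.reference_name, aln.reference_start, aln.reference_end)
                mapq = aln.mapping_quality
            reads.append(
                ReadSummary(
                    read_id=aln.query_name,
                    length=aln.query_length or aln.infer_read_length() or 1,
                    mapped_region=region,
                    mapq=mapq,
                    channel=channel,
                    flags=frozenset(flags),
                    arm=arm_for_channel(channel, arm_channel_map),
                )
            )
    return reads


def write_read_summaries(reads: Sequence[ReadSummary], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(READ_TSV_COLUMNS)
        for r in reads:
            if r.mapped_region is None:
                chrom, start, end, mapq = ".", ".", ".", "."
            else:
                chrom = r.mapped_region.chrom
                start = r.mapped_region.start
                end = r.mapped_region.end
                mapq = r.mapq
            flags = ",".join(sorted(r.flags - {"unmapped"})) or "."
            w.writerow([r.read_id, chrom, start, end, mapq, r.channel, flags, r.length])


# ---------------------------------------------------------------------------
# Depth tracks (bedGraph-style runs) and BED regions
# ---------------------------------------------------------------------------


def write_depth_tsv(profile: DepthProfile, path) -> None:
    """Write a depth profile as run-length bedGraph-style rows."""
    depth = profile.depth
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "start", "end", "depth"])
        if len(depth) == 0:
            return
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(depth)]))
        for s, e in zip(starts, ends):
            w.writerow(
                [
                    profile.region.chrom,
                    profile.region.start + int(s),
                    profile.region.start + int(e),
                    int(depth[s]),
                ]
            )


def read_depth_tsv(path) -> DepthProfile:
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append((row["chrom"], int(row["start"]), int(row["end"]), int(row["depth"])))
    if not rows:
        raise FormatError(f"empty depth TSV {path}")
    chroms = {r[0] for r in rows}
    if len(chroms) != 1:
        raise FormatError(f"depth TSV {path} spans multiple sequences {sorted(chroms)}")
    chrom = rows[0][0]
    start = min(r[1] for r in rows)
    end = max(r[2] for r in rows)
    region = Region(chrom, start, end)
    depth = np.zeros(len(region), dtype=np.int64)
    for _, s, e, d in rows:
        depth[s - start : e - start] = d
    return DepthProfile(region, depth)


def read_bed(path) -> List[Region]:
    """Read 3-column BED (0-based half-open) into Regions."""
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line {i} in {path} has fewer than 3 columns")
            regions.append(Region(parts[0], int(parts[1]), int(parts[2])))
    return regions
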