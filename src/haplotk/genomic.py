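"""Core genomic domain types shared by every module of the toolkit.

Coordinate conventions
----------------------
Internally every interval is a :class:`Region` with 0-based, half-open
coordinates. All file-facing surfaces (VCF, BED, ``chrom:start-end``
region strings) convert at the boundary: VCF positions are 1-based, BED
is already 0-based half-open, and region strings are 1-based inclusive
(the convention used to describe an enrichment window such as
``chr1:214622891-217423448``).

A :class:`VariantRecord` keeps its 1-based VCF ``pos`` because that is
the identity under which callsets are compared; its reference footprint
is exposed as a 0-based :meth:`VariantRecord.ref_span` Region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import FrozenSet, Optional, Tuple

import numpy as np

VALID_BASES = frozenset("ACGTN")

READ_FLAGS = frozenset({"secondary", "supplementary", "duplicate", "unmapped"})


class HaplotkError(Exception):
    """Base class for all toolkit errors."""


class RegionParseError(HaplotkError, ValueError):
    """A region string could not be parsed into a Region."""


@dataclass(frozen=True, order=True)
class Region:
    """A 0-based, half-open genomic interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("Region chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"Region requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end

    def padded(self, pad: int) -> "Region":
        return Region(self.chrom, max(0, self.start - pad), self.end + pad)

    def union(self, other: "Region") -> "Region":
        if self.chrom != other.chrom:
            raise ValueError("cannot union regions on different sequences")
        return Region(self.chrom, min(self.start, other.start), max(self.end, other.end))

    def to_1based_str(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


# 1-based inclusive "chrom:start-end"; commas inside numbers and en/em
# dashes between them are tolerated, as are spaces after the colon.
_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_region(text: str) -> Region:
    """Parse a 1-based inclusive ``chrom:start-end`` string into a Region.

    ``"chr1:214622891-217423448"`` -> ``Region('chr1', 214622890, 217423448)``.
    """
    cleaned = text.strip().replace(",", "").replace(" ", "")
    for dash in ("–", "—", "−"):  # en dash, em dash, minus sign
        cleaned = cleaned.replace(dash, "-")
    m = _REGION_RE.match(cleaned)
    if not m:
        raise RegionParseError(f"malformed region string: {text!r}")
    chrom = m.group("chrom")
    start1 = int(m.group("start"))
    end1 = int(m.group("end"))
    if start1 < 1:
        raise RegionParseError(f"region start must be >= 1, got {start1!r} in {text!r}")
    if start1 > end1:
        raise RegionParseError(
            f"region start exceeds end: {start1!r} > {end1!r} in {text!r}"
        )
    return Region(chrom, start1 - 1, end1)


def format_region(region: Region) -> str:
    """Inverse of :func:`parse_region` on canonical inputs."""
    return region.to_1based_str()


@dataclass(frozen=True)
class PhasedGenotype:
    """A diploid genotype for a single ALT allele.

    ``hap1_allele``/``hap2_allele`` are 0 (reference) or 1 (the ALT of
    the owning record). When ``phased`` is False the order of the two
    haplotype slots carries no meaning. ``phase_set`` identifies the
    phasing block (VCF ``PS``) within which haplotype numbering is
    mutually consistent.
    """

    hap1_allele: int
    hap2_allele: int
    phased: bool = True
    phase_set: Optional[int] = None

    def __post_init__(self) -> None:
        for a in (self.hap1_allele, self.hap2_allele):
            if a not in (0, 1):
                raise ValueError(f"haplotype allele must be 0 or 1, got {a}")
        if self.hap1_allele == 0 and self.hap2_allele == 0:
            raise ValueError("an emitted variant must carry the ALT on >= 1 haplotype")

    @property
    def is_het(self) -> bool:
        return self.hap1_allele != self.hap2_allele

    @property
    def is_hom_alt(self) -> bool:
        return self.hap1_allele == 1 and self.hap2_allele == 1

    @property
    def zygosity(self) -> str:
        return "hom" if self.is_hom_alt else "het"

    def on_haplotype(self, haplotype: int) -> bool:
        """Whether the ALT allele sits on haplotype 1 or 2."""
        if haplotype not in (1, 2):
            raise ValueError("haplotype must be 1 or 2")
        return (self.hap1_allele if haplotype == 1 else self.hap2_allele) == 1

    def swapped(self) -> "PhasedGenotype":
        return replace(self, hap1_allele=self.hap2_allele, hap2_allele=self.hap1_allele)


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic ALT call with genotype, phase and annotations.

    ``pos`` is the 1-based VCF position of the first REF base. Indels
    are anchored VCF-style (REF and ALT share their first base).
    ``cadd_scaled`` holds the scaled deleteriousness (CADD-style)
    annotation; missing means unscored, never benign.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: PhasedGenotype
    qual: Optional[float] = None
    filters: FrozenSet[str] = frozenset()
    depth: Optional[int] = None
    allele_depth: Optional[int] = None
    cadd_scaled: Optional[float] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if not allele:
                raise ValueError(f"{name} allele must be non-empty")
            bad = set(allele) - VALID_BASES
            if bad:
                raise ValueError(f"{name} allele {allele!r} has non-DNA symbols {bad}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be non-negative")
        for name, v in (("depth", self.depth), ("allele_depth", self.allele_depth)):
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cadd_scaled is not None and self.cadd_scaled < 0:
            raise ValueError("cadd_scaled must be non-negative")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def variant_class(self) -> str:
        return "snv" if self.is_snv else "indel"

    def ref_span(self) -> Region:
        """0-based half-open footprint of the REF allele."""
        return Region(self.chrom, self.pos - 1, self.pos - 1 + len(self.ref_allele))

    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class ReadSummary:
    """Per-read alignment summary used for enrichment and N50 statistics.

    ``arm`` records which half of a channel-split adaptive-sampling run
    the read came from (``adaptive`` pores reject off-target strands,
    ``control`` pores sequence everything).
    """

    read_id: str
    length: int
    mapped_region: Optional[Region]
    mapq: Optional[int]
    channel: int
    flags: FrozenSet[str] = frozenset()
    arm: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("read length must be positive")
        bad = set(self.flags) - READ_FLAGS
        if bad:
            raise ValueError(f"unknown read flags {bad}")
        unmapped = self.mapped_region is None or "unmapped" in self.flags
        if unmapped and self.mapq is not None:
            raise ValueError("unmapped reads must have missing mapq")
        if not unmapped:
            if self.mapq is None:
                raise ValueError("mapped reads must carry a mapq")
            if not (0 <= self.mapq <= 60):
                raise ValueError(f"mapq out of range: {self.mapq}")
        if self.arm is not None and self.arm not in ("adaptive", "control"):
            raise ValueError(f"arm must be adaptive/control, got {self.arm!r}")

    @property
    def is_mapped(self) -> bool:
        return self.mapped_region is not None and "unmapped" not in self.flags


@dataclass
class DepthProfile:
    """Per-base integer depth over a Region."""

    region: Region
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1 or len(self.depth) != len(self.region):
            raise ValueError(
                f"depth vector length {len(self.depth)} does not match "
                f"region length {len(self.region)}"
            )
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")

    def depth_at(self, chrom: str, pos0: int) -> int:
        if not self.region.contains_pos(chrom, pos0):
            raise KeyError(f"position {chrom}:{pos0} outside profile {self.region}")
        return int(self.depth[pos0 - self.region.start])

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())

    def fraction_at_least(self, threshold: int) -> float:
        return float((self.depth >= threshold).mean())

    def coverage_summary(self, thresholds: Tuple[int, ...] = (1, 15, 17)) -> dict:
        return {
            "mean_depth": self.mean_depth,
            **{f"fraction_ge_{t}": self.fraction_at_least(t) for t in thresholds},
        }
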