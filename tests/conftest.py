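"""Shared fixtures: small constructed variant sets with known haplotype
outcomes, built programmatically so the test surface stays text-only."""

import pytest

from haplotk.genomic import PhasedGenotype, Region, VariantRecord


def make_record(pos, ref, alt, hap1=1, hap2=0, phased=True, ps=1, chrom="w", **kw):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        genotype=PhasedGenotype(hap1, hap2, phased=phased, phase_set=ps if phased else None),
        **kw,
    )


@pytest.fixture
def alternative_encodings_window():
    """A 14-base window over which two different edit inventories
    reconstruct the same 8-base haplotype sequence "ACCACGAT":
    {1-bp del, SNV A>C, 5-bp del} versus {7-bp del, 1-bp ins}.
    Mirrors the composed-vs-decomposed discordance seen between
    long-read and short-read aligner representations."""
    window = "AGACAGTGCCCGAT"
    set_a = [
        make_record(1, "AG", "A"),
        make_record(3, "A", "C"),
        make_record(5, "AGTGCC", "A"),
    ]
    set_b = [
        make_record(1, "AGACAGTG", "A"),
        make_record(10, "C", "CA"),
    ]
    return window, Region("w", 0, 14), set_a, set_b, "ACCACGAT"
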