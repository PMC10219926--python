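"""Haplotype-context matching: sequence application, clustering,
cluster equivalence (against a brute-force oracle), and whole-callset
classification."""

import itertools

import numpy as np
import pytest

from conftest import make_record
from haplotk.context_match import (
    OverlapError,
    ReferenceMismatchError,
    VariantCluster,
    apply_variants,
    classify_callsets,
    cluster_discordant,
    concordance_rates,
    match_cluster,
)
from haplotk.genomic import PhasedGenotype, Region, VariantRecord
from haplotk.io import CallsetTable
from haplotk.synthetic import make_reference, plant_diploid_variants, reencode_callset


class TestApplyVariants:
    def test_empty_variant_set_is_identity(self):
        assert apply_variants("ACGT", Region("w", 0, 4), [], 1) == "ACGT"

    def test_variant_on_other_haplotype_not_applied(self):
        rec = make_record(2, "A", "G", hap1=1, hap2=0, chrom="w")
        region = Region("w", 0, 4)
        assert apply_variants("AAAA", region, [rec], 2) == "AAAA"
        assert apply_variants("AAAA", region, [rec], 1) == "AGAA"

    def test_snv_deletion_insertion(self):
        region = Region("w", 0, 8)
        variants = [
            make_record(1, "A", "T", chrom="w"),
            make_record(3, "GT", "G", chrom="w"),
            make_record(6, "C", "CAA", chrom="w"),
        ]
        assert apply_variants("ACGTACGT", region, variants, 1) == "TCGACAAGT"

    def test_ref_mismatch_names_position(self):
        rec = make_record(2, "T", "G", chrom="w")
        with pytest.raises(ReferenceMismatchError, match="w:2"):
            apply_variants("AAAA", Region("w", 0, 4), [rec], 1)

    def test_overlapping_spans_rejected(self):
        variants = [
            make_record(2, "AC", "A", chrom="w"),
            make_record(3, "C", "T", chrom="w"),
        ]
        with pytest.raises(OverlapError):
            apply_variants("AACC", Region("w", 0, 4), variants, 1)

    def test_worked_example_both_inventories_identical(self, alternative_encodings_window):
        window, region, set_a, set_b, expected = alternative_encodings_window
        assert apply_variants(window, region, set_a, 1) == expected
        assert apply_variants(window, region, set_b, 1) == expected


class TestClusterDiscordant:
    def test_padded_overlap_merges(self):
        a = [make_record(100, "A", "G", chrom="c")]
        b = [make_record(105, "A", "G", chrom="c")]
        assert len(cluster_discordant(a, b, pad=10)) == 1

    def test_distant_records_split(self):
        a = [make_record(100, "A", "G", chrom="c")]
        b = [make_record(200, "A", "G", chrom="c")]
        clusters = cluster_discordant(a, b, pad=10)
        assert len(clusters) == 2

    def test_transitive_chain_single_cluster(self):
        # pairwise-overlapping chain; verified against brute-force union-find
        recs = [make_record(p, "A", "G", chrom="c") for p in (100, 115, 130)]
        clusters = cluster_discordant(recs, [], pad=10)
        assert len(clusters) == 1 and clusters[0].n_members == 3

        parents = list(range(3))

        def find(i):
            while parents[i] != i:
                i = parents[i]
            return i

        spans = [(r.pos - 11, r.pos + 10) for r in recs]
        for i, j in itertools.combinations(range(3), 2):
            if spans[i][0] < spans[j][1] and spans[j][0] < spans[i][1]:
                parents[find(i)] = find(j)
        assert len({find(i) for i in range(3)}) == 1


# --- brute-force oracle ----------------------------------------------------


def _naive_apply(seq, edits):
    """Independent haplotype builder: left-to-right walk."""
    by_pos = {pos - 1: (ref, alt) for pos, ref, alt in edits}
    out = []
    i = 0
    while i < len(seq):
        if i in by_pos:
            ref, alt = by_pos[i]
            if seq[i : i + len(ref)] != ref:
                raise AssertionError("oracle ref mismatch")
            out.append(alt)
            i += len(ref)
        else:
            out.append(seq[i])
            i += 1
    return "".join(out)


def _oracle_equivalent(seq, members_a, members_b):
    """Enumerate every per-record haplotype placement and compare the
    unordered pair of haplotype strings."""

    def placements(members):
        options = []
        for r in members:
            if r.genotype.is_hom_alt:
                options.append([(True, True)])
            else:
                options.append([(True, False), (False, True)])
        results = set()
        for combo in itertools.product(*options):
            haps = ([], [])
            for r, (h1, h2) in zip(members, combo):
                edit = (r.pos, r.ref_allele, r.alt_allele)
                if h1:
                    haps[0].append(edit)
                if h2:
                    haps[1].append(edit)
            try:
                s1 = _naive_apply(seq, haps[0])
                s2 = _naive_apply(seq, haps[1])
            except AssertionError:
                continue
            spans_ok = True
            for hap in haps:
                ends = sorted((p - 1, p - 1 + len(ref)) for p, ref, _ in hap)
                for (s0, e0), (s1_, _e1) in zip(ends, ends[1:]):
                    if s1_ < e0:
                        spans_ok = False
            if spans_ok:
                results.add(tuple(sorted((s1, s2))))
        return results

    return bool(placements(members_a) & placements(members_b))


class TestMatchCluster:
    def test_worked_example_equivalent(self, alternative_encodings_window):
        window, region, set_a, set_b, _ = alternative_encodings_window
        cluster = VariantCluster(region=region, members_a=set_a, members_b=set_b)
        assert match_cluster(cluster, {"w": window}).verdict == "equivalent"
        assert _oracle_equivalent(window, set_a, set_b)

    def test_one_sided_cluster_discordant(self):
        cluster = VariantCluster(
            region=Region("w", 0, 4), members_a=[make_record(2, "A", "C", chrom="w")]
        )
        assert match_cluster(cluster, {"w": "AAAA"}).verdict == "discordant"

    def test_homopolymer_shifted_deletion_equivalent(self):
        # one deletion at each end of a homopolymer run encodes the same change
        window = "CTAAAAAAGC"
        rec_left = make_record(2, "TA", "T", chrom="w")
        rec_right = make_record(7, "AA", "A", chrom="w")
        region = Region("w", 0, len(window))
        assert apply_variants(window, region, [rec_left], 1) == apply_variants(
            window, region, [rec_right], 1
        )
        cluster = VariantCluster(region=region, members_a=[rec_left], members_b=[rec_right])
        assert match_cluster(cluster, {"w": window}).verdict == "equivalent"

    def test_zygosity_mismatch_discordant(self):
        het = make_record(3, "A", "C", hap1=1, hap2=0, chrom="w")
        hom = make_record(3, "A", "C", hap1=1, hap2=1, chrom="w")
        cluster = VariantCluster(Region("w", 0, 6), [het], [hom])
        assert match_cluster(cluster, {"w": "GGAAGG"}).verdict == "discordant"

    def test_agrees_with_bruteforce_oracle_on_random_clusters(self):
        rng = np.random.default_rng(1234)
        checked = equivalent_seen = 0
        for _ in range(300):
            window = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 30))))
            # low-complexity windows make accidental equivalence more likely
            if rng.random() < 0.5:
                window = "".join(
                    rng.choice(list("AT"), size=int(rng.integers(15, 30)))
                )
            region = Region("w", 0, len(window))

            def random_side():
                members = []
                taken = []
                for _ in range(int(rng.integers(1, 4))):
                    for _try in range(20):
                        pos = int(rng.integers(2, len(window) - 4))
                        kind = rng.choice(["snv", "del", "ins"])
                        ref_len = 1 if kind != "del" else int(rng.integers(2, 4))
                        span = (pos - 1, pos - 1 + ref_len)
                        if any(s < span[1] and span[0] < e for s, e in taken):
                            continue
                        ref = window[span[0] : span[1]]
                        if kind == "snv":
                            alts = [b for b in "ACGT" if b != ref]
                            alt = str(rng.choice(alts))
                        elif kind == "del":
                            alt = ref[0]
                        else:
                            alt = ref + "".join(rng.choice(list("ACGT"), size=1))
                        if ref == alt:
                            continue
                        taken.append(span)
                        hom = rng.random() < 0.2
                        members.append(
                            make_record(
                                pos, ref, alt,
                                hap1=1, hap2=1 if hom else 0, phased=False, chrom="w",
                            )
                        )
                        break
                return sorted(members, key=lambda r: r.pos)

            ma = random_side()
            if rng.random() < 0.4:
                # a genuinely equivalent re-representation: indels shifted
                # through their homopolymer context
                from haplotk.synthetic import shift_indel

                mb = sorted(
                    (shift_indel(window, r, direction=+1) for r in ma),
                    key=lambda r: r.pos,
                )
            else:
                mb = random_side()
            if not ma or not mb:
                continue
            cluster = VariantCluster(region=region, members_a=ma, members_b=mb)
            got = match_cluster(cluster, {"w": window}).verdict == "equivalent"
            want = _oracle_equivalent(window, ma, mb)
            assert got == want, (window, ma, mb)
            checked += 1
            equivalent_seen += want
        assert checked > 200
        assert equivalent_seen > 0  # the oracle saw both outcomes


def _callset(records, sample="S1", label="other"):
    return CallsetTable.from_records(records, [sample], label)


class TestClassifyCallsets:
    def test_identical_callsets_all_exact(self):
        ref = {"c": "A" * 50 + "CGT" * 50}
        recs = [make_record(10, ref["c"][9], "T" if ref["c"][9] != "T" else "G", chrom="c"),
                make_record(120, ref["c"][119], "A" if ref["c"][119] != "A" else "C", chrom="c")]
        comp = classify_callsets(_callset(recs), _callset(list(recs)), ref)
        assert set(comp.labels_a) == {"exact"} and set(comp.labels_b) == {"exact"}
        assert concordance_rates(comp)["snv"] == 1.0

    def test_private_snv_labeled_unique(self):
        ref = {"c": "ACGT" * 40}
        shared = make_record(18, ref["c"][17], "A", chrom="c")
        private = make_record(98, ref["c"][97], "T", chrom="c")
        comp = classify_callsets(_callset([shared, private]), _callset([shared]), ref)
        assert comp.labels_a.count("unique_a") == 1
        assert comp.count("a", "exact") == 1

    def test_symmetry_mirrors_labels_and_rates(self):
        ref = {"chrT": make_reference(12000, seed=31)}
        truth = plant_diploid_variants(ref, n_snv=12, n_indel=6, seed=32)
        a = reencode_callset(truth, "left_aligned_composed", seed=33)
        b = reencode_callset(
            truth, "decomposed_shifted",
            drop_in_regions=[truth.diploid_variants[3].ref_span().padded(30)],
            seed=34,
        )
        fwd = classify_callsets(a, b, ref)
        rev = classify_callsets(b, a, ref)
        swap = {"unique_a": "unique_b", "unique_b": "unique_a"}
        assert fwd.labels_a == [swap.get(l, l) for l in rev.labels_b]
        assert fwd.labels_b == [swap.get(l, l) for l in rev.labels_a]
        assert concordance_rates(fwd) == concordance_rates(rev)

    def test_reencoded_truth_fully_concordant(self):
        ref = {"chrT": make_reference(20000, seed=41)}
        truth = plant_diploid_variants(ref, n_snv=20, n_indel=10, seed=42)
        a = reencode_callset(truth, "left_aligned_composed", seed=43)
        b = reencode_callset(truth, "decomposed_shifted", genotype_phase="unphased", seed=44)
        comp = classify_callsets(a, b, ref)
        assert comp.count("a", "unique_a") == 0 and comp.count("b", "unique_b") == 0
        rates = concordance_rates(comp)
        assert rates["snv"] == 1.0 and rates["indel"] == 1.0

    def test_planted_private_fraction_matches_rate(self):
        # k private SNVs among n shared: rate is (n-k)/n in exact arithmetic
        seq = "ACGTTGCA" * 60
        ref = {"c": seq}
        n, k = 10, 3
        shared = [
            make_record(30 * (i + 1), seq[30 * (i + 1) - 1],
                        "A" if seq[30 * (i + 1) - 1] != "A" else "C", chrom="c")
            for i in range(n - k)
        ]
        private = [
            make_record(30 * (i + 1) + 11, seq[30 * (i + 1) + 10],
                        "G" if seq[30 * (i + 1) + 10] != "G" else "T", chrom="c")
            for i in range(n - k, n)
        ]
        comp = classify_callsets(_callset(shared + private), _callset(list(shared)), ref)
        assert concordance_rates(comp)["snv"] == pytest.approx((n - k) / n)

    def test_empty_class_rate_missing(self):
        ref = {"c": "ACGT" * 30}
        rec = make_record(14, ref["c"][13], "A", chrom="c")
        comp = classify_callsets(_callset([rec]), _callset([rec]), ref)
        assert concordance_rates(comp)["indel"] is None
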