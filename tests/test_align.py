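"""Tag classification: exclusion precedence and hit bookkeeping."""

import numpy as np
import pytest

from mirquant.align import (
    EXCLUDED_MRNA,
    MIRNA,
    UNALIGNED,
    classify_tag,
    classify_tags,
    mirna_hit_multiplicity,
)
from mirquant.preprocess import ReadTag
from mirquant.reference import GenomicInterval, MatureMiRNA, ReferenceBundle


def tag(seq, count=1):
    return ReadTag(seq=seq, count=count)


def brute_force_classify(seq, bundle):
    """Independent oracle: exhaustive scan over every exon and mature seq."""
    for exon_seq in bundle.exon_index.sequences().values():
        if seq in exon_seq:
            return EXCLUDED_MRNA, set()
    hits = {
        m.name
        for m in bundle.mirnas.values()
        if seq in m.mature_seq or m.mature_seq in seq
    }
    return (MIRNA, hits) if hits else (UNALIGNED, set())


class TestClassifyTag:
    def test_exact_mature_match(self, toy_bundle):
        a = classify_tag(tag(toy_bundle.mirnas["toy-mir-1"].mature_seq), toy_bundle)
        assert a.status == MIRNA and a.hits == {"toy-mir-1"}

    def test_exclusion_precedence_over_mirna_match(self, toy_mirnas, toy_exons):
        """A tag matching both an exon and a mature miRNA is excluded."""
        mature = toy_mirnas["toy-mir-1"].mature_seq
        exons = dict(toy_exons, exon_decoy="GG" * 20 + mature + "CC" * 20)
        bundle = ReferenceBundle.build(toy_mirnas, exon_seqs=exons)
        a = classify_tag(tag(mature), bundle)
        assert a.status == EXCLUDED_MRNA and a.hits == frozenset()

    def test_unmatched_tag_is_unaligned(self, toy_bundle):
        a = classify_tag(tag("ACAC" * 5 + "TG"), toy_bundle)
        assert a.status == UNALIGNED

    def test_extended_tag_containing_mature_hits(self, toy_bundle):
        """Mature-in-tag direction: a 2-nt-extended isomiR still matches."""
        mature = toy_bundle.mirnas["toy-mir-3"].mature_seq
        a = classify_tag(tag("TC" + mature + "A"), toy_bundle)
        assert a.status == MIRNA and "toy-mir-3" in a.hits

    def test_mismatch_knob_recovers_one_substitution(self, toy_bundle):
        mature = toy_bundle.mirnas["toy-mir-1"].mature_seq
        mutated = mature[:10] + ("A" if mature[10] != "A" else "C") + mature[11:]
        assert classify_tag(tag(mutated), toy_bundle).status == UNALIGNED
        a = classify_tag(tag(mutated), toy_bundle, max_mismatch=1)
        assert a.status == MIRNA and "toy-mir-1" in a.hits

    def test_agrees_with_brute_force_oracle_on_random_tags(self, toy_exons):
        """500 random tags vs a 100-reference bundle: index == exhaustive scan."""
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        mirnas = {}
        for i in range(100):
            seq = "".join(rng.choice(bases, int(rng.integers(18, 25))))
            name = f"m{i}"
            mirnas[name] = MatureMiRNA(
                name, seq, [GenomicInterval("c", 100 * i, 100 * i + len(seq))]
            )
        bundle = ReferenceBundle.build(mirnas, exon_seqs=toy_exons)
        pool = list(mirnas.values())
        for j in range(500):
            kind = j % 3
            if kind == 0:
                seq = "".join(rng.choice(bases, int(rng.integers(15, 31))))
            elif kind == 1:  # mature-derived
                m = pool[int(rng.integers(len(pool)))]
                seq = m.mature_seq[int(rng.integers(0, 4)) :]
            else:  # exon-derived
                exon = toy_exons[f"exon_{int(rng.integers(1, 4))}"]
                a = int(rng.integers(0, 70))
                seq = exon[a : a + int(rng.integers(16, 30))]
            got = classify_tag(tag(seq), bundle)
            status, hits = brute_force_classify(seq, bundle)
            assert (got.status, set(got.hits)) == (status, hits)

    def test_classification_is_iteration_order_independent(self, toy_bundle):
        tags = [tag(m.mature_seq) for m in toy_bundle.mirnas.values()]
        fwd = classify_tags(tags, toy_bundle)
        rev = classify_tags(tags[::-1], toy_bundle)
        assert {(a.tag.seq, a.status, a.hits) for a in fwd} == {
            (a.tag.seq, a.status, a.hits) for a in rev
        }

    def test_adding_exon_only_moves_tags_toward_exclusion(self, toy_mirnas, toy_exons):
        """Growing the exclusion set never un-excludes a tag."""
        bundle0 = ReferenceBundle.build(toy_mirnas, exon_seqs=toy_exons)
        probe_tags = [tag(m.mature_seq) for m in toy_mirnas.values()]
        probe_tags.append(tag(toy_exons["exon_1"][10:32]))
        before = {a.tag.seq: a.status for a in classify_tags(probe_tags, bundle0)}
        grown = dict(toy_exons, extra="AA" + toy_mirnas["toy-mir-2"].mature_seq + "GG")
        bundle1 = ReferenceBundle.build(toy_mirnas, exon_seqs=grown)
        after = {a.tag.seq: a.status for a in classify_tags(probe_tags, bundle1)}
        for seq in before:
            if before[seq] == EXCLUDED_MRNA:
                assert after[seq] == EXCLUDED_MRNA
        assert after[toy_mirnas["toy-mir-2"].mature_seq] == EXCLUDED_MRNA


class TestHitMultiplicity:
    def test_single_locus_single_hit(self, toy_bundle):
        a = classify_tags([tag(toy_bundle.mirnas["toy-mir-1"].mature_seq, count=10)], toy_bundle)
        stats = mirna_hit_multiplicity(a, toy_bundle)
        assert stats["toy-mir-1"] == {"C": 10.0, "M": 1.0, "n_tags": 1}

    def test_two_locus_mirna_has_m_two(self, toy_bundle):
        """A mature sequence annotated at two loci: C counted once, M = 2."""
        a = classify_tags([tag(toy_bundle.mirnas["toy-mir-2"].mature_seq, count=10)], toy_bundle)
        stats = mirna_hit_multiplicity(a, toy_bundle)
        assert stats["toy-mir-2"] == {"C": 10.0, "M": 2.0, "n_tags": 1}

    def test_tag_hitting_two_mirnas_counts_toward_both(self):
        """Hand-enumerated 3-miRNA toy: a long tag containing two matures."""
        m1 = MatureMiRNA("m1", "ACGTACGTTAGCCGATTA", [GenomicInterval("c", 0, 18)])
        m2 = MatureMiRNA("m2", "GGCATTCAGTCGATCCTAGG", [GenomicInterval("c", 50, 70)])
        m3 = MatureMiRNA("m3", "TTGACCGGTAACGTGCATCA", [GenomicInterval("c", 90, 110)])
        bundle = ReferenceBundle.build({m.name: m for m in (m1, m2, m3)})
        # 28-nt tag = m1's mature + 10 nt of m2's prefix: contains m1 only
        t = tag(m1.mature_seq + m2.mature_seq[:10], count=6)
        a = classify_tags([t], bundle)
        assert a[0].hits == {"m1"}
        # a tag equal to m2 also present with count 4
        stats = mirna_hit_multiplicity(a + classify_tags([tag(m2.mature_seq, 4)], bundle), bundle)
        assert (stats["m1"]["C"], stats["m2"]["C"], stats["m3"]["C"]) == (6, 4, 0)
        # split mode divides a genuinely multi-hit tag between its targets
        both = classify_tags([tag(m1.mature_seq + "CC" + m3.mature_seq, 8)], bundle)
        assert both[0].hits == {"m1", "m3"}
        split = mirna_hit_multiplicity(both, bundle, split_multi_hits=True)
        assert (split["m1"]["C"], split["m3"]["C"]) == (4.0, 4.0)

    def test_every_annotated_mirna_reported_even_with_zero_reads(self, toy_bundle):
        stats = mirna_hit_multiplicity([], toy_bundle)
        assert set(stats) == set(toy_bundle.mirnas)
        assert all(v["C"] == 0 for v in stats.values())
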