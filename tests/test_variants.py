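import numpy as np
import pytest

from conftest import identity_read
from oracles import leftmost_equivalent, padded_matrix_call
from haploclone.alignment_io import GeneModel, ReadAlignment, Reference
from haploclone.simulate import CloneTruth, SimConfig, random_reference, simulate_mixture
from haploclone.variants import (
    CombinedVariant,
    Variant,
    annotate_combined,
    annotate_variant,
    call_read_variants,
    combine_variants,
    normalize_indels,
    normalize_variant,
    parse_variant_label,
    resolve_selection,
    variant_label,
)


def snv(reference, pos, alt=None):
    ref = reference.sequence[pos]
    if alt is None:
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
    return Variant(start=pos, kind="SNV", ref_allele=ref, alt_allele=alt)


class TestCallReadVariants:
    def test_identity_read(self, ref924):
        obs = call_read_variants(identity_read(ref924, 100, 200), ref924)
        assert obs.variants == frozenset()
        assert obs.masked == frozenset()
        assert obs.covered == ((100, 300),)

    def test_single_mismatch_c749(self, ref924, whole_cds_model):
        # c.749 maps to reference position 748
        pos = 748
        ref_base = ref924.sequence[pos]
        alt = "A" if ref_base != "A" else "G"
        seq = list(ref924.sequence[700:800])
        seq[pos - 700] = alt
        read = ReadAlignment("r", 0, 700, (("M", 100),), "".join(seq))
        obs = call_read_variants(read, ref924)
        (v,) = obs.variants
        assert variant_label(v, whole_cds_model) == f"c.749{ref_base}>{alt}"

    def test_n_base_masks_instead_of_variant(self, ref924):
        seq = list(ref924.sequence[0:50])
        seq[10] = "N"
        read = ReadAlignment("r", 0, 0, (("M", 50),), "".join(seq))
        obs = call_read_variants(read, ref924)
        assert obs.variants == frozenset()
        assert obs.masked == frozenset({10})

    def test_soft_clips_do_not_cover(self, ref924):
        read = ReadAlignment(
            "r", 0, 100, (("S", 5), ("M", 40), ("S", 5)),
            "AAAAA" + ref924.sequence[100:140] + "AAAAA",
        )
        obs = call_read_variants(read, ref924)
        assert obs.covered == ((100, 140),)
        assert obs.variants == frozenset()

    def test_deletion_positions_covered(self, ref924):
        read = ReadAlignment(
            "r", 0, 100, (("M", 20), ("D", 5), ("M", 20)),
            ref924.sequence[100:120] + ref924.sequence[125:145],
        )
        obs = call_read_variants(read, ref924)
        (v,) = obs.variants
        assert v.kind == "DEL" and v.start == 120 and len(v.ref_allele) == 5
        assert obs.covered == ((100, 145),)

    def test_edge_insertion_not_called(self, ref924):
        read = ReadAlignment("r", 0, 100, (("I", 3), ("M", 30)), "TTT" + ref924.sequence[100:130])
        obs = call_read_variants(read, ref924)
        assert obs.variants == frozenset()

    def test_purity(self, ref924):
        read = ReadAlignment(
            "r", 0, 10, (("M", 10), ("I", 2), ("M", 10)),
            ref924.sequence[10:20] + "GG" + ref924.sequence[20:30],
        )
        assert call_read_variants(read, ref924) == call_read_variants(read, ref924)


def test_oracle_equivalence_on_simulated_reads(ref924):
    """call_read_variants matches the padded-matrix column oracle on 500+
    noisy simulated reads (including indel errors)."""
    clones = [
        CloneTruth("a", frozenset({snv(ref924, 200), snv(ref924, 500)}), 0.4),
        CloneTruth(
            "b",
            frozenset({Variant(start=300, kind="DEL", ref_allele=ref924.sequence[300:304], alt_allele="")}),
            0.3,
        ),
        CloneTruth("wt", frozenset(), 0.3),
    ]
    config = SimConfig(
        seed=11, n_fragments=600, reference=ref924, read_length=400,
        substitution_rate=0.02, indel_rate=0.01,
    )
    result = simulate_mixture(clones, config)
    assert len(result.reads) >= 500
    for read in result.reads:
        obs = call_read_variants(read, ref924)
        covered, masked, variants = padded_matrix_call(read, ref924)
        assert {p for s, e in obs.covered for p in range(s, e)} == covered
        assert set(obs.masked) == masked
        assert set(obs.variants) == variants
        # and the normalized forms agree too
        norm = normalize_indels(obs, ref924)
        assert set(norm.variants) == {normalize_variant(v, ref924) for v in variants}


class TestNormalizeIndels:
    def test_deletion_left_aligned_in_homopolymer(self):
        ref = Reference("r", "CAAAT")
        v = Variant(start=3, kind="DEL", ref_allele="A", alt_allele="")
        nv = normalize_variant(v, ref)
        assert nv.start == 1

    def test_already_left_aligned_unchanged(self):
        ref = Reference("r", "CAAAT")
        v = Variant(start=1, kind="DEL", ref_allele="A", alt_allele="")
        assert normalize_variant(v, ref) == v

    def test_idempotent(self):
        ref = Reference("r", "GATCTCTCTAG")
        v = Variant(start=7, kind="DEL", ref_allele="CT", alt_allele="")
        once = normalize_variant(v, ref)
        assert normalize_variant(once, ref) == once

    def test_insertion_left_aligned(self):
        ref = Reference("r", "CAAAT")
        v = Variant(start=4, kind="INS", ref_allele="", alt_allele="A")
        nv = normalize_variant(v, ref)
        assert nv.start == 1 and nv.alt_allele == "A"

    @pytest.mark.parametrize("seed", range(8))
    def test_enumeration_oracle_on_random_repeats(self, seed):
        rng = np.random.default_rng(seed)
        # repeat-rich references maximize equivalent placements
        units = ["A", "AT", "CAG", "T", "GC"]
        seq = "".join(rng.choice(units) for _ in range(40))
        ref = Reference("r", seq)
        for _ in range(30):
            kind = "DEL" if rng.integers(0, 2) else "INS"
            if kind == "DEL":
                n = int(rng.integers(1, 4))
                start = int(rng.integers(1, len(seq) - n))
                v = Variant(start=start, kind="DEL", ref_allele=seq[start : start + n], alt_allele="")
            else:
                n = int(rng.integers(1, 4))
                start = int(rng.integers(1, len(seq)))
                alt = "".join(rng.choice(list("ACGT")) for _ in range(n))
                v = Variant(start=start, kind="INS", ref_allele="", alt_allele=alt)
            assert normalize_variant(v, ref) == leftmost_equivalent(v, ref)

    def test_observation_invariant_after_shift(self, ref924):
        # a shifted indel keeps its positions inside covered
        seq = "C" + "A" * 6 + "T" * 20
        ref = Reference("r", seq)
        read = ReadAlignment("r", 0, 3, (("M", 2), ("D", 1), ("M", 10)), seq[3:5] + seq[6:16])
        obs = normalize_indels(call_read_variants(read, ref), ref)
        (v,) = obs.variants
        assert v.start == 1
        for p in v.positions():
            assert any(s <= p < e for s, e in obs.covered)


class TestCombineVariants:
    def test_adjacent_snvs_combine(self, ref924, whole_cds_model):
        vs = [snv(ref924, 9), snv(ref924, 10)]  # c.10, c.11
        out = combine_variants(vs, whole_cds_model)
        assert len(out) == 1
        assert out[0].reason == "consecutive"
        assert out[0].members == tuple(sorted(vs, key=Variant.sort_key))

    def test_same_codon_non_adjacent(self, ref924, whole_cds_model):
        # c.7 and c.9 share codon 3
        vs = [snv(ref924, 6), snv(ref924, 8)]
        out = combine_variants(vs, whole_cds_model)
        assert len(out) == 1
        assert out[0].reason == "same_codon"

    def test_distant_snvs_stay_single(self, ref924, whole_cds_model):
        vs = [snv(ref924, 9), snv(ref924, 19)]
        out = combine_variants(vs, whole_cds_model)
        assert [cv.reason for cv in out] == ["single", "single"]

    def test_indels_never_combined(self, ref924, whole_cds_model):
        d = Variant(start=10, kind="DEL", ref_allele=ref924.sequence[10:12], alt_allele="")
        out = combine_variants([snv(ref924, 9), d], whole_cds_model)
        assert all(len(cv.members) == 1 for cv in out)


class TestAnnotate:
    def test_large_deletion_label(self, ref924, whole_cds_model):
        # deletion spanning c.1086..c.1270 in a longer CDS context
        ref = random_reference(1500, np.random.default_rng(5))
        model = GeneModel(((0, 1500),), "+")
        v = Variant(start=1085, kind="DEL", ref_allele=ref.sequence[1085:1270], alt_allele="")
        cds, _ = annotate_variant(v, model, ref)
        assert cds == "c.1086_1270del185"

    def test_insertion_length_label(self):
        ref = random_reference(1500, np.random.default_rng(6))
        model = GeneModel(((0, 1500),), "+")
        v = Variant(start=1423, kind="INS", ref_allele="", alt_allele="G" * 35)
        cds, _ = annotate_variant(v, model, ref)
        assert cds == "c.1423_1424ins35"

    def test_t315a_amino_acid_change(self):
        # codon 315 = c.943..945; make it ACT (T), mutate c.943 A>G -> GCT (A)
        rng = np.random.default_rng(8)
        seq = list(random_reference(1200, rng).sequence)
        seq[942:945] = "ACT"
        ref = Reference("r", "".join(seq))
        model = GeneModel(((0, 1200),), "+")
        v = Variant(start=942, kind="SNV", ref_allele="A", alt_allele="G")
        cds, aa = annotate_variant(v, model, ref)
        assert cds == "c.943A>G"
        assert aa == "T315A"

    def test_frameshift_markers(self, ref924, whole_cds_model):
        d1 = Variant(start=30, kind="DEL", ref_allele=ref924.sequence[30:31], alt_allele="")
        d3 = Variant(start=30, kind="DEL", ref_allele=ref924.sequence[30:33], alt_allele="")
        assert annotate_variant(d1, whole_cds_model, ref924)[1].endswith("fs")
        assert annotate_variant(d3, whole_cds_model, ref924)[1].endswith("del")

    def test_outside_cds_g_label(self, ref924):
        model = GeneModel(((100, 400),), "+")
        v = snv(ref924, 50)
        label, aa = annotate_variant(v, model, ref924)
        assert label.startswith("g.51")
        assert aa == ""

    def test_same_codon_combined_aa(self):
        rng = np.random.default_rng(9)
        seq = list(random_reference(60, rng).sequence)
        seq[6:9] = "ACT"  # codon 3 = T
        ref = Reference("r", "".join(seq))
        model = GeneModel(((0, 60),), "+")
        v1 = Variant(start=6, kind="SNV", ref_allele="A", alt_allele="G")
        v2 = Variant(start=8, kind="SNV", ref_allele="T", alt_allele="A")
        cv = CombinedVariant(members=(v1, v2), reason="same_codon")
        _, aa = annotate_combined(cv, model, ref)
        assert aa == "T3A"  # GCA = Ala


class TestLabels:
    @pytest.mark.parametrize("seed", range(5))
    def test_label_bijectivity_within_cds(self, ref924, whole_cds_model, seed):
        rng = np.random.default_rng(100 + seed)
        pool = []
        for _ in range(20):
            kind = ["SNV", "DEL", "INS"][int(rng.integers(0, 3))]
            pos = int(rng.integers(10, 900))
            if kind == "SNV":
                pool.append(snv(ref924, pos))
            elif kind == "DEL":
                n = int(rng.integers(1, 6))
                pool.append(Variant(start=pos, kind="DEL", ref_allele=ref924.sequence[pos : pos + n], alt_allele=""))
            else:
                alt = "".join(rng.choice(list("ACGT")) for _ in range(int(rng.integers(1, 6))))
                pool.append(Variant(start=pos, kind="INS", ref_allele="", alt_allele=alt))
        for v in pool:
            key = parse_variant_label(variant_label(v, whole_cds_model))
            matching = [u for u in pool if key.matches(u, whole_cds_model)]
            # the parsed key matches v; INS keys carry only the length, so
            # same-length insertions at the same junction are identical keys
            assert v in matching
            for u in matching:
                assert (u.kind, u.start) == (v.kind, v.start)

    def test_single_base_deletion_label_roundtrip(self, ref924, whole_cds_model):
        v = Variant(start=99, kind="DEL", ref_allele=ref924.sequence[99:100], alt_allele="")
        label = variant_label(v, whole_cds_model)
        assert label == "c.100del1"
        assert parse_variant_label(label).matches(v, whole_cds_model)

    def test_resolve_selection(self, ref924, whole_cds_model):
        v1, v2 = snv(ref924, 748), snv(ref924, 100)
        keys = [parse_variant_label(variant_label(v1, whole_cds_model))]
        assert resolve_selection(keys, [v1, v2], whole_cds_model) == [v1]
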