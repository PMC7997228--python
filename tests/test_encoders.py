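import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6apred.encoders import (
    DINUCLEOTIDES,
    TRINUCLEOTIDES,
    DinucPropertyTable,
    FeatureMatrix,
    KsnpfParams,
    PropensityModel,
    PseDncParams,
    encode_be,
    encode_enac,
    encode_ksnpf,
    encode_ncp,
    encode_psdp,
    encode_psednc,
    encode_psnp,
    encode_set,
    encode_tnc,
    fit_propensity,
    fuse,
)
from m6apred.sequence_io import LabeledSequenceSet

from conftest import random_rna

rna_seq = st.text(alphabet="ACGU", min_size=8, max_size=60)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations they check)


def oracle_kmer_freq(seq, k):
    counts = {"".join(p): 0 for p in itertools.product("ACGU", repeat=k)}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    return np.array([counts[m] / (len(seq) - k + 1) for m in sorted(counts)])


def oracle_enac(seq, window):
    blocks = []
    for start in range(len(seq) - window + 1):
        chunk = seq[start : start + window]
        blocks.extend(chunk.count(b) / window for b in "ACGU")
    return np.array(blocks)


def oracle_ksnpf(seq, k_max):
    out = []
    for k in range(k_max + 1):
        pairs = ["".join(p) for p in itertools.product("ACGU", repeat=2)]
        counts = dict.fromkeys(pairs, 0)
        for i in range(len(seq) - k - 1):
            counts[seq[i] + seq[i + k + 1]] += 1
        out.extend(counts[p] / (len(seq) - k - 1) for p in pairs)
    return np.array(out)


class TestBinaryEncoding:
    def test_worked_example(self):
        # GGAUUCGA, position-major one-hot
        expected = [0,0,1,0, 0,0,1,0, 1,0,0,0, 0,0,0,1, 0,0,0,1, 0,1,0,0, 0,0,1,0, 1,0,0,0]
        assert encode_be("GGAUUCGA").tolist() == expected

    def test_41nt_dimension(self):
        assert len(encode_be("A" * 41)) == 164

    @given(rna_seq)
    @settings(max_examples=50, deadline=None)
    def test_one_hot_property(self, seq):
        v = encode_be(seq)
        assert v.sum() == len(seq)
        assert set(v) <= {0.0, 1.0}

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            encode_be("ACGX")


class TestTnc:
    def test_homopolymer(self):
        v = encode_tnc("AAAA")
        assert v[TRINUCLEOTIDES.index("AAA")] == 1.0
        assert v.sum() == 1.0

    def test_acgu(self):
        v = encode_tnc("ACGU")
        assert v[TRINUCLEOTIDES.index("ACG")] == 0.5
        assert v[TRINUCLEOTIDES.index("CGU")] == 0.5
        assert v.sum() == 1.0

    def test_dimension(self):
        assert len(encode_tnc("A" * 41)) == 64

    def test_too_short(self):
        with pytest.raises(ValueError):
            encode_tnc("AC")

    def test_oracle_equivalence(self, rng):
        for _ in range(200):
            seq = random_rna(rng, int(rng.integers(3, 60)))
            np.testing.assert_allclose(encode_tnc(seq), oracle_kmer_freq(seq, 3))


class TestEnac:
    def test_dimension(self):
        assert len(encode_enac("A" * 41, window=5)) == 148

    def test_all_a(self):
        v = encode_enac("A" * 10, window=5).reshape(-1, 4)
        assert np.array_equal(v, np.tile([1, 0, 0, 0], (6, 1)))

    def test_single_window(self):
        np.testing.assert_allclose(encode_enac("ACGUA", window=5), [0.4, 0.2, 0.2, 0.2])

    def test_bad_window(self):
        with pytest.raises(ValueError):
            encode_enac("ACGU", window=5)
        with pytest.raises(ValueError):
            encode_enac("ACGU", window=0)

    def test_oracle_equivalence(self, rng):
        for _ in range(200):
            seq = random_rna(rng, int(rng.integers(5, 60)))
            np.testing.assert_allclose(encode_enac(seq, 5), oracle_enac(seq, 5))


class TestKsnpf:
    def test_dimension(self):
        assert len(encode_ksnpf("A" * 41, KsnpfParams(k_max=5))) == 96

    def test_aca_layers(self):
        v = encode_ksnpf("ACA", KsnpfParams(k_max=1))
        k0, k1 = v[:16], v[16:]
        assert k0[DINUCLEOTIDES.index("AC")] == 0.5
        assert k0[DINUCLEOTIDES.index("CA")] == 0.5
        assert k1[DINUCLEOTIDES.index("AA")] == 1.0
        assert k0.sum() == 1.0 and k1.sum() == 1.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            encode_ksnpf("ACG", KsnpfParams(k_max=5))

    def test_oracle_equivalence(self, rng):
        for _ in range(200):
            seq = random_rna(rng, int(rng.integers(8, 60)))
            np.testing.assert_allclose(
                encode_ksnpf(seq, KsnpfParams(k_max=5)), oracle_ksnpf(seq, 5)
            )


class TestNcp:
    def test_coordinates(self):
        assert encode_ncp("A").tolist() == [1, 1, 1]
        assert encode_ncp("CGU").tolist() == [0, 1, 0, 1, 0, 0, 0, 0, 1]

    def test_dimension(self):
        assert len(encode_ncp("A" * 41)) == 123

    def test_invalid(self):
        with pytest.raises(ValueError):
            encode_ncp("ACGT")  # T must be normalized upstream


class TestPropensity:
    def _make_set(self, pos, neg):
        return LabeledSequenceSet(
            sequences=pos + neg,
            labels=np.array([1] * len(pos) + [0] * len(neg)),
        )

    def test_full_separation_gives_unit_entry(self):
        s = self._make_set(["AC", "AG"], ["GC", "UG"])
        m = fit_propensity(s, order=1)
        assert m.Z[0, 0] == 1.0  # A at position 1: 100% pos, 0% neg

    def test_identical_sets_give_zero(self):
        seqs = ["ACGU", "GGCA"]
        s = self._make_set(seqs, list(seqs))
        for order in (1, 2):
            assert np.allclose(fit_propensity(s, order).Z, 0.0)

    def test_columns_sum_to_zero(self, small_seqset):
        for order in (1, 2):
            Z = fit_propensity(small_seqset, order).Z
            np.testing.assert_allclose(Z.sum(axis=0), 0.0, atol=1e-12)
            assert np.all(np.abs(Z) <= 1.0)

    def test_single_class_rejected(self):
        s = LabeledSequenceSet(sequences=["AC", "GU"], labels=np.array([1, 1]))
        with pytest.raises(ValueError):
            fit_propensity(s, order=1)

    def test_psnp_lookup(self):
        Z = np.zeros((4, 2))
        Z[0, 0] = 0.3   # A at position 1
        Z[1, 1] = -0.1  # C at position 2
        m = PropensityModel(order=1, Z=Z, length=2)
        np.testing.assert_allclose(encode_psnp("AC", m), [0.3, -0.1])

    def test_psdp_lookup(self):
        Z = np.zeros((16, 2))
        Z[DINUCLEOTIDES.index("AC"), 0] = 0.5
        Z[DINUCLEOTIDES.index("CG"), 1] = -0.2
        m = PropensityModel(order=2, Z=Z, length=3)
        np.testing.assert_allclose(encode_psdp("ACG", m), [0.5, -0.2])

    def test_dimensions_41nt(self, small_seqset):
        m1 = fit_propensity(small_seqset, 1)
        m2 = fit_propensity(small_seqset, 2)
        assert len(encode_psnp(small_seqset.sequences[0], m1)) == 41
        assert len(encode_psdp(small_seqset.sequences[0], m2)) == 40

    def test_zero_matrix_zero_vector(self):
        m = PropensityModel(order=1, Z=np.zeros((4, 5)), length=5)
        assert np.all(encode_psnp("ACGUA", m) == 0.0)

    def test_length_mismatch(self, small_seqset):
        m = fit_propensity(small_seqset, 1)
        with pytest.raises(ValueError):
            encode_psnp("ACGU", m)

    def test_permuted_labels_shrink_z(self, rng):
        # refitting on label-permuted data drives mean |z| toward 0 as n grows
        from m6apred.sequence_io import SyntheticConfig, generate_synthetic

        mags = []
        for n in (100, 1000):
            s = generate_synthetic(
                SyntheticConfig(n_pos=n, n_neg=n, motif_strength=0.8,
                                enriched_positions=(5, 9), seed=0)
            )
            perm = LabeledSequenceSet(
                sequences=s.sequences,
                labels=rng.permutation(s.labels),
                ids=list(s.ids),
            )
            mags.append(np.abs(fit_propensity(perm, 1).Z).mean())
        assert mags[1] < mags[0]

    def test_json_roundtrip(self, tmp_path, small_seqset):
        m = fit_propensity(small_seqset, 2)
        m.to_json(tmp_path / "m.json")
        again = PropensityModel.from_json(tmp_path / "m.json")
        assert again.order == 2 and again.length == 41
        np.testing.assert_array_equal(again.Z, m.Z)


class TestPseDnc:
    def test_dimension(self):
        v = encode_psednc("A" * 41, PseDncParams(lam=30, w=0.5))
        assert len(v) == 46

    @given(rna_seq.filter(lambda s: len(s) >= 10))
    @settings(max_examples=30, deadline=None)
    def test_sums_to_one_and_nonnegative(self, seq):
        v = encode_psednc(seq, PseDncParams(lam=5, w=0.7))
        assert abs(v.sum() - 1.0) < 1e-9
        assert np.all(v >= 0.0)

    def test_flat_table_zeroes_tiers(self):
        table = DinucPropertyTable(index_names=["flat"], values=np.full((1, 16), 3.0))
        v = encode_psednc("ACGUACGUAC", PseDncParams(lam=4, w=0.5), table)
        assert np.all(v[16:] == 0.0)
        np.testing.assert_allclose(v[:16].sum(), 1.0)

    def test_lambda_too_large(self):
        with pytest.raises(ValueError):
            encode_psednc("ACGUA", PseDncParams(lam=5, w=0.5))

    def test_default_table_standardized(self):
        t = DinucPropertyTable.default()
        assert t.standardized
        np.testing.assert_allclose(t.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(t.values.var(axis=1), 1.0, atol=1e-9)
        assert set(t.index_names) == {"Rise", "Roll", "Shift", "Slide", "Tilt", "Twist"}

    def test_overlapping_toggle(self):
        seq = "AACCGGUUAA"
        v_over = encode_psednc(seq, PseDncParams(lam=2, w=0.0))
        v_non = encode_psednc(seq, PseDncParams(lam=2, w=0.0), overlapping=False)
        assert not np.allclose(v_over, v_non)

    def test_psednc_oracle_small(self):
        # hand-computed: w=0 reduces to plain normalized dinucleotide freqs
        v = encode_psednc("AACG", PseDncParams(lam=1, w=0.0))
        f = np.zeros(16)
        f[DINUCLEOTIDES.index("AA")] = 1 / 3
        f[DINUCLEOTIDES.index("AC")] = 1 / 3
        f[DINUCLEOTIDES.index("CG")] = 1 / 3
        np.testing.assert_allclose(v[:16], f)
        assert v[16] == 0.0


class TestFuse:
    def test_canonical_dimension_contract(self, small_seqset):
        seqs = small_seqset.sequences
        psnp = fit_propensity(small_seqset, 1)
        psdp = fit_propensity(small_seqset, 2)
        mats = {
            "BE": encode_set(seqs, "BE"),
            "TNC": encode_set(seqs, "TNC"),
            "ENAC": encode_set(seqs, "ENAC"),
            "KSNPF": encode_set(seqs, "KSNPF"),
            "NCP": encode_set(seqs, "NCP"),
            "PseDNC": encode_set(seqs, "PseDNC"),
            "PSNP": encode_set(seqs, "PSNP", propensity=psnp),
            "PSDP": encode_set(seqs, "PSDP", propensity=psdp),
        }
        dims = {k: m.n_features for k, m in mats.items()}
        assert dims == {
            "BE": 164, "TNC": 64, "ENAC": 148, "KSNPF": 96,
            "NCP": 123, "PseDNC": 46, "PSNP": 41, "PSDP": 40,
        }
        fused = fuse(list(mats.values()))
        assert fused.n_features == 722
        # canonical order regardless of input order
        tags = []
        for t in fused.encoder_tags:
            if not tags or tags[-1] != t:
                tags.append(t)
        assert tags == ["BE", "KSNPF", "ENAC", "NCP", "PseDNC", "TNC", "PSNP", "PSDP"]

    def test_single_matrix_unchanged(self, small_seqset):
        fm = encode_set(small_seqset.sequences, "TNC")
        assert fuse([fm]) is fm

    def test_mismatched_rows(self, small_seqset):
        a = encode_set(small_seqset.sequences, "TNC")
        b = encode_set(small_seqset.sequences[:10], "NCP")
        with pytest.raises(ValueError):
            fuse([a, b])

    def test_empty_list(self):
        with pytest.raises(ValueError):
            fuse([])

    def test_tsv_export(self, tmp_path, small_seqset):
        fm = encode_set(small_seqset.sequences[:5], "TNC")
        fm.to_tsv(tmp_path / "f.tsv")
        lines = (tmp_path / "f.tsv").read_text().splitlines()
        assert lines[0].split("\t") == fm.feature_names
        assert len(lines) == 6


class TestDeterminism:
    def test_encoders_deterministic(self, small_seqset):
        seq = small_seqset.sequences[0]
        for fn in (encode_be, encode_tnc, encode_ncp):
            np.testing.assert_array_equal(fn(seq), fn(seq))
        np.testing.assert_array_equal(
            encode_ksnpf(seq, KsnpfParams(3)), encode_ksnpf(seq, KsnpfParams(3))
        )
        np.testing.assert_array_equal(
            encode_psednc(seq, PseDncParams(10, 0.5)),
            encode_psednc(seq, PseDncParams(10, 0.5)),
        )
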