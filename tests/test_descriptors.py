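"""Descriptor unit and property tests, with independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqfam.descriptors import (
    CLASS_PAIRS,
    DEFAULT_PROPERTIES,
    DescriptorConfig,
    PropertyGrouping,
    PropertyScale,
    aa_composition,
    ctd,
    ctd_composition,
    ctd_distribution,
    ctd_transition,
    featurize,
    load_groupings,
    load_scales,
    moreau_broto,
    pseaac,
)
from seqfam.sequence_io import CANONICAL_AA, ProteinSequence

from conftest import random_grouping, random_sequence

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive)


def oracle_composition(residues, class_of):
    counts = {1: 0, 2: 0, 3: 0}
    for c in residues:
        counts[class_of[c]] += 1
    return [counts[k] / len(residues) for k in (1, 2, 3)]


def oracle_transition(residues, class_of):
    tallies = {pair: 0 for pair in CLASS_PAIRS}
    for i in range(len(residues) - 1):
        a, b = class_of[residues[i]], class_of[residues[i + 1]]
        pair = (min(a, b), max(a, b))
        if a != b:
            tallies[pair] += 1
    return [tallies[p] / (len(residues) - 1) for p in CLASS_PAIRS]


def oracle_distribution(residues, class_of):
    L = len(residues)
    out = []
    for cls in (1, 2, 3):
        positions = [i + 1 for i, c in enumerate(residues) if class_of[c] == cls]
        n = len(positions)
        if n == 0:
            out.extend([0.0] * 5)
            continue
        ks = [1, max(1, int(np.floor(0.25 * n))), max(1, int(np.floor(0.5 * n))),
              max(1, int(np.floor(0.75 * n))), n]
        out.extend(positions[k - 1] / L for k in ks)
    return out


def oracle_moreau_broto(residues, norm_values, max_lag):
    L = len(residues)
    p = [norm_values[CANONICAL_AA.index(c)] for c in residues]
    out = []
    for d in range(1, max_lag + 1):
        total = sum(p[i] * p[i + d] for i in range(L - d))
        out.append(total / (L - d))
    return out


def oracle_pseaac(residues, norm_by_scale, lam, w):
    L = len(residues)
    f = [residues.count(a) / L for a in CANONICAL_AA]
    theta = []
    for k in range(1, lam + 1):
        vals = []
        for i in range(L - k):
            diffs = [
                (nv[CANONICAL_AA.index(residues[i])] - nv[CANONICAL_AA.index(residues[i + k])]) ** 2
                for nv in norm_by_scale
            ]
            vals.append(sum(diffs) / len(diffs))
        theta.append(sum(vals) / len(vals))
    denom = sum(f) + w * sum(theta)
    return [x / denom for x in f] + [w * t / denom for t in theta]


# ---------------------------------------------------------------------------
# amino-acid composition


class TestAAComposition:
    def test_homopolymer(self):
        comp = aa_composition(ProteinSequence("p", "AAAA"))
        assert comp[CANONICAL_AA.index("A")] == 1.0
        assert comp.sum() == pytest.approx(1.0)
        assert np.count_nonzero(comp) == 1

    def test_worked_example_fractions(self, example_seq):
        comp = aa_composition(example_seq)
        assert comp[CANONICAL_AA.index("A")] == pytest.approx(16 / 30)
        assert comp[CANONICAL_AA.index("E")] == pytest.approx(14 / 30)
        assert comp.sum() == pytest.approx(1.0)

    def test_matches_counting_oracle(self, rng):
        seq = random_sequence(rng, 200)
        comp = aa_composition(seq)
        expected = [seq.residues.count(a) / 200 for a in CANONICAL_AA]
        np.testing.assert_allclose(comp, expected)


# ---------------------------------------------------------------------------
# CTD


class TestCTDComposition:
    def test_worked_example(self, example_seq, ae_grouping):
        c = ctd_composition(example_seq, ae_grouping)
        a_cls, e_cls = ae_grouping.class_of["A"], ae_grouping.class_of["E"]
        assert round(c[a_cls - 1], 2) == 0.53
        assert round(c[e_cls - 1], 2) == 0.47

    def test_single_class_sequence(self, groupings):
        g = groupings["hydrophobicity"]
        class1 = [a for a in CANONICAL_AA if g.class_of[a] == 1]
        seq = ProteinSequence("p", "".join(class1) * 2)
        np.testing.assert_allclose(ctd_composition(seq, g), [1.0, 0.0, 0.0])

    def test_matches_oracle_random(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(2, 150)))
            g = random_grouping(rng)
            np.testing.assert_allclose(
                ctd_composition(seq, g), oracle_composition(seq.residues, g.class_of)
            )


class TestCTDTransition:
    def test_worked_example(self, example_seq, ae_grouping):
        t = ctd_transition(example_seq, ae_grouping)
        # A and E fall in classes 1 and 2 of this grouping -> pair (1,2)
        assert round(float(t.sum()), 2) == 0.52
        assert float(t.sum()) == pytest.approx(15 / 29)

    def test_homopolymer_no_transitions(self, ae_grouping):
        np.testing.assert_allclose(
            ctd_transition(ProteinSequence("p", "AAAA"), ae_grouping), [0, 0, 0]
        )

    def test_length_one_all_zero(self, ae_grouping):
        np.testing.assert_allclose(
            ctd_transition(ProteinSequence("p", "A"), ae_grouping), [0, 0, 0]
        )

    def test_matches_oracle_random(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(2, 150)))
            g = random_grouping(rng)
            np.testing.assert_allclose(
                ctd_transition(seq, g), oracle_transition(seq.residues, g.class_of)
            )


class TestCTDDistribution:
    def test_worked_example_both_classes(self, example_seq, ae_grouping):
        d = ctd_distribution(example_seq, ae_grouping)
        a_cls, e_cls = ae_grouping.class_of["A"], ae_grouping.class_of["E"]
        d_a = [round(x, 2) for x in d[5 * (a_cls - 1) : 5 * (a_cls - 1) + 5]]
        d_e = [round(x, 2) for x in d[5 * (e_cls - 1) : 5 * (e_cls - 1) + 5]]
        assert d_a == [0.03, 0.17, 0.40, 0.67, 0.97]
        assert d_e == [0.07, 0.27, 0.60, 0.77, 1.00]

    def test_homopolymer_quantile_rule(self, ae_grouping):
        d = ctd_distribution(ProteinSequence("p", "AAAA"), ae_grouping)
        a_cls = ae_grouping.class_of["A"]
        np.testing.assert_allclose(
            d[5 * (a_cls - 1) : 5 * (a_cls - 1) + 5], [0.25, 0.25, 0.50, 0.75, 1.00]
        )

    def test_absent_class_all_zero(self, ae_grouping):
        d = ctd_distribution(ProteinSequence("p", "AAAA"), ae_grouping)
        present = ae_grouping.class_of["A"]
        for cls in (1, 2, 3):
            if cls != present:
                np.testing.assert_allclose(d[5 * (cls - 1) : 5 * (cls - 1) + 5], 0.0)

    def test_matches_oracle_random(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(2, 150)))
            g = random_grouping(rng)
            np.testing.assert_allclose(
                ctd_distribution(seq, g), oracle_distribution(seq.residues, g.class_of)
            )


@given(st.text(alphabet=CANONICAL_AA, min_size=2, max_size=120), st.integers(0, 2**32 - 1))
@settings(max_examples=150, deadline=None)
def test_ctd_invariants(residues, grouping_seed):
    seq = ProteinSequence("p", residues)
    g = random_grouping(np.random.default_rng(grouping_seed))
    c = ctd_composition(seq, g)
    t = ctd_transition(seq, g)
    d = ctd_distribution(seq, g)
    assert c.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(c >= 0) and np.all(c <= 1)
    n_changes = sum(
        1
        for i in range(len(residues) - 1)
        if g.class_of[residues[i]] != g.class_of[residues[i + 1]]
    )
    assert t.sum() == pytest.approx(n_changes / (len(residues) - 1))
    assert t.sum() <= 1.0 + 1e-12
    for cls in (1, 2, 3):
        quint = d[5 * (cls - 1) : 5 * (cls - 1) + 5]
        positions = [i + 1 for i, ch in enumerate(residues) if g.class_of[ch] == cls]
        if not positions:
            assert np.all(quint == 0.0)
        else:
            assert np.all(np.diff(quint) >= -1e-12)
            assert quint[4] == pytest.approx(positions[-1] / len(residues))


# ---------------------------------------------------------------------------
# Moreau-Broto autocorrelation


class TestMoreauBroto:
    def test_constant_scale_gives_zero(self, rng):
        scale = PropertyScale("const", {a: 7.0 for a in CANONICAL_AA})
        seq = random_sequence(rng, 50)
        np.testing.assert_allclose(moreau_broto(seq, scale, 10), 0.0)

    def test_two_residue_single_term(self, scales):
        s = scales["hydrophobicity_kd"]
        p = s.normalized_values()
        seq = ProteinSequence("p", "AE")
        expected = p[CANONICAL_AA.index("A")] * p[CANONICAL_AA.index("E")]
        assert moreau_broto(seq, s, 1)[0] == pytest.approx(expected)

    def test_lag_too_large(self, scales):
        with pytest.raises(ValueError, match="max_lag"):
            moreau_broto(ProteinSequence("p", "AEAE"), scales["residue_mass"], 4)

    def test_matches_summation_oracle(self, rng, scales):
        s = scales["residue_mass"]
        seq = random_sequence(rng, 100)
        np.testing.assert_allclose(
            moreau_broto(seq, s, 30),
            oracle_moreau_broto(seq.residues, s.normalized_values(), 30),
        )

    def test_scale_normalization_contract(self, scales):
        for s in scales.values():
            nv = s.normalized_values()
            assert nv.mean() == pytest.approx(0.0, abs=1e-12)
            assert nv.std() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# pseudo-amino-acid composition


class TestPseAAC:
    def test_lam_zero_equals_composition(self, rng, scales):
        seq = random_sequence(rng, 60)
        np.testing.assert_allclose(
            pseaac(seq, list(scales.values()), lam=0, w=0.05), aa_composition(seq)
        )

    def test_weight_zero_tail_is_zero(self, rng, scales):
        seq = random_sequence(rng, 60)
        out = pseaac(seq, list(scales.values()), lam=5, w=0.0)
        np.testing.assert_allclose(out[:20], aa_composition(seq))
        np.testing.assert_allclose(out[20:], 0.0)

    def test_components_sum_to_one(self, rng, scales):
        seq = random_sequence(rng, 80)
        out = pseaac(seq, list(scales.values()), lam=10, w=0.05)
        assert out.sum() == pytest.approx(1.0)
        assert len(out) == 30

    def test_matches_summation_oracle(self, rng, scales):
        seq = random_sequence(rng, 80)
        used = [scales["hydrophobicity_kd"], scales["residue_mass"]]
        np.testing.assert_allclose(
            pseaac(seq, used, lam=5, w=0.05),
            oracle_pseaac(seq.residues, [s.normalized_values() for s in used], 5, 0.05),
        )

    def test_lam_too_large(self, scales):
        with pytest.raises(ValueError, match="lam"):
            pseaac(ProteinSequence("p", "AEAE"), list(scales.values()), lam=4)


# ---------------------------------------------------------------------------
# feature-vector assembly


class TestFeaturize:
    def test_default_dimension_272(self, example_seq):
        fv = featurize(example_seq)
        assert len(fv) == 20 + 12 * 21 == 272

    def test_every_ctd_block_is_21(self, example_seq):
        fv = featurize(example_seq)
        for prop in DEFAULT_PROPERTIES:
            assert len(fv.block(f"ctd:{prop}")) == 21

    def test_blocks_tile_exactly(self, example_seq):
        fv = featurize(example_seq)
        end = 0
        for _, start, length in fv.blocks:
            assert start == end
            end += length
        assert end == len(fv)

    def test_full_config_dimension(self, rng, groupings, scales):
        config = DescriptorConfig(
            autocorr_scales=("hydrophobicity_kd", "residue_mass"),
            max_lag=20,
            include_pseaac=True,
            lam=8,
        )
        seq = random_sequence(rng, 100)
        fv = featurize(seq, config, groupings, scales)
        assert len(fv) == config.dimension() == 272 + 2 * 20 + 28

    def test_deterministic_bitwise(self, example_seq):
        a = featurize(example_seq)
        b = featurize(example_seq)
        assert np.array_equal(a.values, b.values)
        assert a.config_digest == b.config_digest

    def test_permutation_invariance_of_composition_blocks(self, rng):
        seq = random_sequence(rng, 120)
        perm = rng.permutation(len(seq.residues))
        shuffled = ProteinSequence("perm", "".join(seq.residues[i] for i in perm))
        a, b = featurize(seq), featurize(shuffled)
        np.testing.assert_allclose(a.block("aac"), b.block("aac"))
        for prop in DEFAULT_PROPERTIES:
            np.testing.assert_allclose(
                a.block(f"ctd:{prop}")[:3], b.block(f"ctd:{prop}")[:3]
            )
        # order-dependent parts generally change
        assert not np.allclose(a.values, b.values)

    def test_too_short_for_block_names_block(self, groupings, scales):
        config = DescriptorConfig(autocorr_scales=("residue_mass",), max_lag=30)
        with pytest.raises(ValueError, match="autocorr:residue_mass"):
            featurize(ProteinSequence("p", "AEAEAEAEAE"), config, groupings, scales)

    def test_digest_tracks_table_edits(self, example_seq, groupings, scales):
        fv = featurize(example_seq, DescriptorConfig(), groupings, scales)
        edited = dict(groupings)
        swapped = dict(groupings["polarity"].class_of)
        swapped["A"], swapped["W"] = swapped["W"], swapped["A"]
        edited["polarity"] = PropertyGrouping("polarity", swapped)
        fv2 = featurize(example_seq, DescriptorConfig(), edited, scales)
        assert fv.config_digest != fv2.config_digest


class TestGroupingTables:
    def test_twelve_properties_present(self, groupings):
        assert set(DEFAULT_PROPERTIES) <= set(groupings)
        assert len(DEFAULT_PROPERTIES) == 12

    def test_groupings_cover_alphabet_with_all_classes(self, groupings):
        for g in groupings.values():
            assert set(g.class_of) == set(CANONICAL_AA)
            assert set(g.class_of.values()) == {1, 2, 3}

    def test_scales_cover_alphabet(self, scales):
        for s in scales.values():
            assert set(s.value_of) == set(CANONICAL_AA)
            assert np.all(np.isfinite(s.values()))
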