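"""PWM information content, scanning, matrix comparison and ORI statistics."""
import math

import numpy as np
import pytest

from promoarch.motifs import (PWM, deduplicate_motifs, information_content,
                              motif_distance, ori_permutation_test,
                              overrepresentation_index, scan_sequence)
from promoarch.promoters import PromoterRecord, revcomp
from promoarch.synthetic_data import generate_pwm

BASES = "ACGT"


def promoter(seq, gene="g"):
    return PromoterRecord(gene_id=gene, chrom=gene, tss=1500, strand="+", seq=seq)


def plant(word, at, background="A", length=2000):
    return background * at + word + background * (length - at - len(word))


class TestInformationContent:
    def test_uniform_position_zero_bits(self):
        pwm = PWM("u", np.full((6, 4), 0.25))
        assert information_content(pwm) == pytest.approx(0.0)

    def test_deterministic_position_two_bits(self):
        probs = np.full((6, 4), 0.25)
        probs[0] = [1, 0, 0, 0]
        assert information_content(PWM("d", probs)) == pytest.approx(2.0)

    def test_deterministic_8mer_16_bits(self):
        pwm = generate_pwm("ACGTTGCA", 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            per_col = sum(float(np.where(pwm.probs[i] > 0,
                                         pwm.probs[i] * np.log2(pwm.probs[i] / 0.25),
                                         0.0).sum())
                          for i in range(8))
        assert information_content(pwm) == pytest.approx(16.0) == pytest.approx(per_col)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            information_content(generate_pwm("ACGTAC", 1.0), [0.5, 0.5, 0, 0])


class TestScanning:
    def test_exact_plus_strand_match(self):
        pwm = generate_pwm("TTACGC", 1.0)
        occs = scan_sequence(pwm, plant("TTACGC", 300), "g", threshold_fraction=1.0)
        assert [(o.start, o.strand) for o in occs] == [(300, "+")]

    def test_reverse_complement_match(self):
        pwm = generate_pwm("TTACGC", 1.0)
        occs = scan_sequence(pwm, plant(revcomp("TTACGC"), 700), "g",
                             threshold_fraction=1.0)
        assert [(o.start, o.strand) for o in occs] == [(700, "-")]

    def test_all_N_promoter_never_matches(self):
        pwm = generate_pwm("TTACGC", 1.0)
        assert scan_sequence(pwm, "N" * 2000, "g", threshold_fraction=1.0) == []

    def test_threshold_monotonicity(self, rng):
        pwm = generate_pwm("TTACGCAA", 0.8)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, 2000))
        prev = None
        for t in (0.5, 0.7, 0.9, 1.0):
            hits = {(o.start, o.strand) for o in
                    scan_sequence(pwm, seq, "g", threshold_fraction=t)}
            if prev is not None:
                assert hits <= prev
            prev = hits

    def test_strand_mirror_symmetry(self, rng):
        pwm = generate_pwm("TTACGCAA", 0.85)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, 500))
        fwd = scan_sequence(pwm, seq, "g", threshold_fraction=0.8)
        rev = scan_sequence(pwm, revcomp(seq), "g", threshold_fraction=0.8)
        mirrored = {(len(seq) - o.end, {"+": "-", "-": "+"}[o.strand]) for o in rev}
        assert {(o.start, o.strand) for o in fwd} == mirrored

    def test_short_promoter_empty(self):
        assert scan_sequence(generate_pwm("ACGTAC", 1.0), "ACG", "g") == []


def naive_min_distance(pa, pb):
    """Brute-force oracle: all offsets, both orientations, mean column distance."""
    best = math.inf
    for q in (pb, pb[::-1, ::-1]):
        la, lb = len(pa), len(q)
        for off in range(-(lb - 1), la):
            cols = [(pa[i], q[i - off]) for i in range(max(0, off), min(la, off + lb))]
            d = np.mean([np.linalg.norm(a - b) for a, b in cols])
            best = min(best, d)
    return best


class TestMotifDistance:
    def test_identity(self):
        a = generate_pwm("ACGTTA", 0.9)
        d, p, off, orient = motif_distance(a, a, n_null=200, seed=1)
        assert d == pytest.approx(0.0) and off == 0 and orient == "same"
        assert p <= 0.001

    def test_reverse_complement_identity(self):
        a = generate_pwm("ACGTTAGG", 0.9)
        rc = PWM("rc", a.probs[::-1, ::-1])
        d, _, _, orient = motif_distance(a, rc, n_null=200, seed=1)
        assert d == pytest.approx(0.0) and orient == "reverse-complement"

    def test_matches_bruteforce_oracle(self, rng):
        for i in range(10):
            pa = rng.dirichlet(np.ones(4), size=int(rng.integers(6, 10)))
            pb = rng.dirichlet(np.ones(4), size=int(rng.integers(6, 10)))
            d, _, _, _ = motif_distance(PWM("a", pa), PWM("b", pb), n_null=100, seed=0)
            assert d == pytest.approx(naive_min_distance(pa, pb))

    def test_disjoint_deterministic_letters(self):
        # full overlap of letter-disjoint columns costs sqrt(2) per column, but the
        # minimum over partial overlaps can be lower; oracle confirms
        a = generate_pwm("AAAAAA", 1.0)
        b = generate_pwm("CCCCCC", 1.0)
        d, _, _, _ = motif_distance(a, b, n_null=100, seed=0)
        assert d == pytest.approx(naive_min_distance(a.probs, b.probs))
        assert d <= math.sqrt(2)

    def test_symmetry(self, rng):
        a = PWM("a", rng.dirichlet(np.ones(4), size=7))
        b = PWM("b", rng.dirichlet(np.ones(4), size=9))
        da, _, _, _ = motif_distance(a, b, n_null=100, seed=0)
        db, _, _, _ = motif_distance(b, a, n_null=100, seed=0)
        assert da == pytest.approx(db)


class TestDeduplication:
    def test_identical_pwms_one_retained(self):
        a = generate_pwm("ACGTTA", 0.9, name="a")
        b = generate_pwm("ACGTTA", 0.9, name="b")
        kept = deduplicate_motifs([a, b], n_null=200, seed=0)
        assert len(kept) == 1

    def test_higher_ic_retained(self):
        # same counts, different pseudocount: nearly identical matrices where
        # the smaller pseudocount gives the sharper (higher-IC) motif
        counts = np.zeros((8, 4))
        for i, b in enumerate("ACGTTAGC"):
            counts[i, BASES.index(b)] = 20
        sharp = PWM.from_counts("sharp", counts, pseudocount=0.1)
        soft = PWM.from_counts("soft", counts, pseudocount=0.2)
        kept = deduplicate_motifs([soft, sharp], n_null=1000, seed=0)
        assert [m.name for m in kept] == ["sharp"]

    def test_dissimilar_motifs_all_retained(self, rng):
        ms = [PWM(f"m{i}", rng.dirichlet(np.ones(4), size=8)) for i in range(3)]
        kept = deduplicate_motifs(ms, n_null=300, seed=0)
        assert len(kept) == 3

    def test_duplicate_names_rejected(self):
        a = generate_pwm("ACGTTA", 0.9, name="x")
        with pytest.raises(ValueError):
            deduplicate_motifs([a, a])

    def test_no_retained_similar_pair(self, rng):
        # property: after dedup no retained pair is similar at the threshold
        ms = [generate_pwm("ACGTTAGC", s, name=f"m{i}")
              for i, s in enumerate((0.95, 0.9, 0.6))]
        ms += [PWM("r1", rng.dirichlet(np.ones(4), size=8))]
        kept = deduplicate_motifs(ms, n_null=300, seed=0)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                _, p, _, _ = motif_distance(kept[i], kept[j], n_null=300, seed=0)
                assert p > 0.001


class TestOri:
    def test_absent_motif_zero(self):
        pwm = generate_pwm("TTACGCGG", 1.0)
        targets = [promoter("A" * 2000, f"t{i}") for i in range(3)]
        bg = [promoter(plant("TTACGCGG", 50), "b0")]
        assert overrepresentation_index(pwm, targets, bg, 1.0) == 0.0

    def test_equal_density_full_containment_is_one(self):
        pwm = generate_pwm("TTACGCGG", 1.0)
        targets = [promoter(plant("TTACGCGG", 100 + 13 * i), f"t{i}") for i in range(4)]
        bg = [promoter(plant("TTACGCGG", 300 + 17 * i), f"b{i}") for i in range(4)]
        assert overrepresentation_index(pwm, targets, bg, 1.0) == pytest.approx(1.0)

    def test_density_ratio_times_containment(self):
        # targets: 6 hits over 8 kb (0.75/kb) in 2 of 4 promoters; background:
        # 2 hits over 8 kb (0.25/kb) -> ORI = 3 x 0.5 = 1.5
        w = "TTACGCGG"
        pwm = generate_pwm(w, 1.0)
        t0 = plant(w, 100)[:400] + plant(w, 100)[:400] + plant(w, 100)[:1200]
        targets = [promoter(t0, "t0"), promoter(t0, "t1"),
                   promoter("A" * 2000, "t2"), promoter("A" * 2000, "t3")]
        bg = [promoter(plant(w, 500), "b0"), promoter(plant(w, 700), "b1"),
              promoter("A" * 2000, "b2"), promoter("A" * 2000, "b3")]
        assert overrepresentation_index(pwm, targets, bg, 1.0) == pytest.approx(1.5)

    def test_zero_background_infinite(self):
        pwm = generate_pwm("TTACGCGG", 1.0)
        targets = [promoter(plant("TTACGCGG", 100), "t0")]
        assert math.isinf(overrepresentation_index(pwm, targets,
                                                   [promoter("A" * 2000, "b0")], 1.0))

    def test_planted_only_in_observed_gives_p_zero(self):
        w = "TTACGCGG"
        pwm = generate_pwm(w, 1.0)
        observed = [promoter(plant(w, 100 + i), f"o{i}") for i in range(5)]
        universe = observed + [promoter("A" * 2000, f"u{i}") for i in range(20)]
        bg = [promoter(plant(w, 900), "b0")] + [promoter("A" * 2000, f"b{i}")
                                                for i in range(1, 4)]
        res = ori_permutation_test(pwm, observed, universe, bg, n_perm=300, seed=3,
                                   threshold_fraction=1.0)
        assert res.pvalue == 0.0 and res.overrepresented

    def test_determinism(self):
        w = "TTACGCGG"
        pwm = generate_pwm(w, 1.0)
        universe = [promoter(plant(w, 100 + 7 * i) if i % 2 else "A" * 2000, f"u{i}")
                    for i in range(20)]
        bg = [promoter(plant(w, 900), "b0")]
        r1 = ori_permutation_test(pwm, universe[:5], universe, bg, n_perm=1000, seed=11,
                                  threshold_fraction=1.0)
        r2 = ori_permutation_test(pwm, universe[:5], universe, bg, n_perm=1000, seed=11,
                                  threshold_fraction=1.0)
        assert r1.pvalue == r2.pvalue
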