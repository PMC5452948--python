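"""Feature enumeration, detection, matrix assembly, SU and the FCBF filter."""
import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promoarch.features import (BinaryFeatureMatrix, FeatureDescriptor,
                                build_feature_matrix, correlation_filter,
                                count_feature, detect_feature,
                                enumerate_candidate_features,
                                symmetrical_uncertainty)

MOTIFS = ["DM-1", "DM-2"]


def expected_count(m: int) -> int:
    pairs = m * (m + 1) // 2
    return (m + 2 * m + 40 * m
            + 20 * (4 * (m * (m - 1) // 2) + 3 * m)
            + 15 * pairs
            + 8 * m * m)


class TestEnumeration:
    @pytest.mark.parametrize("m", [1, 2, 4])
    def test_closed_form_count(self, m):
        names = [f"M{i}" for i in range(m)]
        assert len(enumerate_candidate_features(names)) == expected_count(m)

    def test_zero_motifs_empty(self):
        assert enumerate_candidate_features([]) == []

    def test_deterministic_canonical_order(self):
        a = enumerate_candidate_features(MOTIFS)
        b = enumerate_candidate_features(MOTIFS[::-1])
        assert [str(f) for f in a] == [str(f) for f in b]

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidate_features(["a", "a"])

    def test_descriptor_string_round_trip(self):
        for f in enumerate_candidate_features(MOTIFS):
            assert FeatureDescriptor.parse(str(f)) == f


class TestDetection:
    def test_position_bin_containment(self, occ_factory):
        # bin covering [-300, -200) = starts 1200..1299, plus strand
        f = FeatureDescriptor("POSITION_TSS", "DM-1", strand_a="+", bin=12)
        assert detect_feature(f, [occ_factory("DM-1", 1250, "+")]) == 1

    def test_position_bin_half_open_boundary(self, occ_factory):
        f = FeatureDescriptor("POSITION_TSS", "DM-1", strand_a="+", bin=12)
        assert detect_feature(f, [occ_factory("DM-1", 1300, "+")]) == 0  # -200 excluded
        assert detect_feature(f, [occ_factory("DM-1", 1200, "+")]) == 1  # -300 included

    def test_order_respects_positions(self, occ_factory):
        f = FeatureDescriptor("ORDER", "A", motif_b="B", strand_a="-", strand_b="+",
                              side="up")
        # A- at -800 (=700), B+ at -300 (=1200): A before B upstream -> 1
        assert detect_feature(f, [occ_factory("A", 700, "-"), occ_factory("B", 1200, "+")]) == 1
        # swapped positions -> 0
        assert detect_feature(f, [occ_factory("A", 1200, "-"), occ_factory("B", 700, "+")]) == 0

    def test_order_brute_force_three_occurrences(self, occ_factory):
        occs = [occ_factory("A", 200, "-"), occ_factory("B", 600, "+"),
                occ_factory("A", 900, "-")]
        for sa, sb, side in itertools.product("+-", "+-", ("up", "down")):
            f = FeatureDescriptor("ORDER", "A", motif_b="B", strand_a=sa,
                                  strand_b=sb, side=side)
            lo, hi = (0, 1500) if side == "up" else (1500, 2000)
            expect = any(a.start < b.start
                         for a in occs if a.motif == "A" and a.strand == sa
                         and lo <= a.start < hi
                         for b in occs if b.motif == "B" and b.strand == sb
                         and lo <= b.start < hi)
            assert detect_feature(f, occs) == int(expect)

    def test_pair_distance_absolute_separation(self, occ_factory):
        f = FeatureDescriptor("PAIR_DISTANCE", "A", motif_b="B", strand_a="+",
                              strand_b="-", bin=3)
        occs = [occ_factory("A", 1000, "+"), occ_factory("B", 1350, "-")]
        assert detect_feature(f, occs) == 1  # |350| in [300, 400)
        occs2 = [occ_factory("A", 1350, "+"), occ_factory("B", 1000, "-")]
        assert detect_feature(f, occs2) == 1  # order-agnostic
        assert detect_feature(f, [occ_factory("A", 1000, "+"),
                                  occ_factory("B", 1400, "-")]) == 0

    def test_pair_counts_by_occurrence_pairs(self, occ_factory):
        f = FeatureDescriptor("PAIR_DISTANCE", "A", motif_b="B", strand_a="+",
                              strand_b="+", bin=0)
        occs = [occ_factory("A", 100, "+"), occ_factory("A", 150, "+"),
                occ_factory("B", 180, "+")]
        # pairs within [0,100): (100,180)? sep 80 yes; (150,180) sep 30 yes -> 2
        assert count_feature(f, occs) == 2

    def test_monotone_in_occurrences(self, occ_factory, rng):
        feats = enumerate_candidate_features(MOTIFS)
        occs = []
        for _ in range(6):
            occs.append(occ_factory(MOTIFS[rng.integers(2)], int(rng.integers(0, 1990)),
                                    "+-"[rng.integers(2)]))
            base = [detect_feature(f, occs[:-1]) for f in feats[::37]]
            more = [detect_feature(f, occs) for f in feats[::37]]
            assert all(m >= b for b, m in zip(base, more))

    def test_presence_equals_or_of_oriented_and_positions(self, occ_factory, rng):
        feats = enumerate_candidate_features(["DM-1"])
        for _ in range(20):
            occs = [occ_factory("DM-1", int(rng.integers(0, 1992)), "+-"[rng.integers(2)])
                    for _ in range(rng.integers(0, 4))]
            pres = detect_feature(FeatureDescriptor("PRESENCE", "DM-1"), occs)
            oriented = [detect_feature(FeatureDescriptor("PRESENCE_ORIENTED", "DM-1",
                                                         strand_a=s), occs) for s in "+-"]
            positions = [detect_feature(f, occs) for f in feats
                         if f.ftype == "POSITION_TSS"]
            assert pres == max(oriented, default=0) == max(positions, default=0)


class TestMatrix:
    def test_all_empty_occurrences_zero_matrix(self):
        feats = enumerate_candidate_features(MOTIFS)
        m = build_feature_matrix(feats, {"a": [], "b": [], "c": []}, ["a", "b"], ["c"])
        assert m.values.sum() == 0
        assert m.labels.tolist() == [1, 1, 0]

    def test_row_matches_per_feature_detection(self, occ_factory):
        # one planted architecture exercising all six classes
        occs = [occ_factory("DM-1", 1250, "+"), occ_factory("DM-1", 1600, "-"),
                occ_factory("DM-2", 1350, "-"), occ_factory("DM-2", 100, "+")]
        feats = enumerate_candidate_features(MOTIFS)
        m = build_feature_matrix(feats, {"g": occs, "c": []}, ["g"], ["c"])
        row = m.values[0]
        expected = np.array([detect_feature(f, occs) for f in feats], dtype=np.uint8)
        assert (row == expected).all()
        assert expected.sum() > 10  # the fixture instantiates many features

    def test_matrix_matches_detection_on_random_fixtures(self, occ_factory, rng):
        feats = enumerate_candidate_features(MOTIFS)
        for trial in range(5):
            occs = [occ_factory(MOTIFS[rng.integers(2)], int(rng.integers(0, 1992)),
                                "+-"[rng.integers(2)]) for _ in range(rng.integers(1, 7))]
            m = build_feature_matrix(feats, {"g": occs, "c": []}, ["g"], ["c"])
            expected = np.array([detect_feature(f, occs) for f in feats])
            assert (m.values[0] == expected).all()

    def test_column_margins_invariant_to_gene_order(self, occ_factory):
        feats = enumerate_candidate_features(["DM-1"])
        idx = {"a": [occ_factory("DM-1", 100, "+")], "b": [occ_factory("DM-1", 700, "-")],
               "c": []}
        m1 = build_feature_matrix(feats, idx, ["a", "b"], ["c"])
        m2 = build_feature_matrix(feats, idx, ["b", "a"], ["c"])
        assert (m1.values.sum(axis=0) == m2.values.sum(axis=0)).all()

    def test_gene_in_both_classes_rejected(self):
        with pytest.raises(ValueError):
            build_feature_matrix([], {"a": []}, ["a"], ["a"])

    def test_tsv_round_trip(self, occ_factory, tmp_path):
        feats = enumerate_candidate_features(MOTIFS)
        idx = {"a": [occ_factory("DM-1", 100, "+")], "c": []}
        m = build_feature_matrix(feats, idx, ["a"], ["c"])
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = BinaryFeatureMatrix.from_tsv(p)
        assert back.genes == m.genes
        assert [str(f) for f in back.features] == [str(f) for f in m.features]
        assert (back.values == m.values).all() and (back.labels == m.labels).all()


def naive_su(x, y):
    """Independent contingency-table oracle for symmetrical uncertainty."""
    def H(vals):
        c = Counter(vals)
        n = len(vals)
        return -sum((v / n) * math.log2(v / n) for v in c.values())

    hx, hy = H(x), H(y)
    if hx == 0 or hy == 0:
        return 0.0
    hxy = H(list(zip(x, y)))
    return 2 * (hx + hy - hxy) / (hx + hy)


def naive_fcbf(X, labels, feature_order, delta=0.0):
    """Literal FCBF reimplementation: SU ranking then predominance removal."""
    su_c = [round(naive_su(X[:, i].tolist(), labels.tolist()), 12)
            for i in feature_order]
    ranked = sorted(range(len(feature_order)), key=lambda i: (-su_c[i], i))
    ranked = [i for i in ranked if su_c[i] >= delta]
    kept = []
    for i in ranked:
        if any(naive_su(X[:, feature_order[j]].tolist(),
                        X[:, feature_order[i]].tolist()) >= su_c[i] - 1e-12
               for j in kept):
            continue
        kept.append(i)
    return [feature_order[i] for i in kept]


class TestSymmetricalUncertainty:
    def test_identical_columns_one(self):
        x = np.array([0, 1, 0, 1, 1])
        assert symmetrical_uncertainty(x, x) == pytest.approx(1.0)

    def test_independent_columns_zero(self):
        assert symmetrical_uncertainty([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_against_entropy_oracle(self):
        x = [0, 0, 0, 0, 1, 1, 1, 1]
        y = [0, 0, 0, 0, 0, 1, 1, 1]
        assert symmetrical_uncertainty(x, y) == pytest.approx(naive_su(x, y))

    def test_constant_column_zero(self):
        assert symmetrical_uncertainty([1, 1, 1], [0, 1, 0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            symmetrical_uncertainty([0, 1], [0, 1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1,
                    max_size=60))
    def test_symmetry(self, pairs):
        x = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        assert symmetrical_uncertainty(x, y) == pytest.approx(
            symmetrical_uncertainty(y, x))


def toy_matrix(values, labels):
    n, F = values.shape
    feats = [FeatureDescriptor("PRESENCE", f"M{i:03d}") for i in range(F)]
    return BinaryFeatureMatrix([f"g{i}" for i in range(n)], feats, values, labels)


class TestCorrelationFilter:
    def test_label_copy_retained_first(self, rng):
        labels = np.array([1] * 10 + [0] * 10, dtype=np.int8)
        X = rng.integers(0, 2, size=(20, 5)).astype(np.uint8)
        X[:, 2] = labels
        kept = correlation_filter(toy_matrix(X, labels))
        assert str(kept[0]) == "PRES:M002"

    def test_duplicate_columns_collapse(self):
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
        col = np.array([1, 1, 1, 0, 0, 1], dtype=np.uint8)  # strongly class-correlated
        weak = np.array([0, 1, 0, 1, 0, 0], dtype=np.uint8)
        X = np.stack([col, col, weak], axis=1)
        kept = {str(f) for f in correlation_filter(toy_matrix(X, labels))}
        assert ("PRES:M000" in kept) != ("PRES:M001" in kept)

    def test_matches_naive_fcbf(self, rng):
        labels = (rng.random(30) < 0.5).astype(np.int8)
        labels[:3], labels[-3:] = 1, 0  # both classes present
        for _ in range(10):
            X = (rng.random((30, 10)) < rng.random(10)).astype(np.uint8)
            m = toy_matrix(X, labels)
            kept = [str(f) for f in correlation_filter(m)]
            expect = [str(m.features[i]) for i in
                      naive_fcbf(X, labels, list(range(10)))]
            assert kept == expect

    def test_single_class_rejected(self):
        X = np.ones((4, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            correlation_filter(toy_matrix(X, np.ones(4, dtype=np.int8)))

    def test_invariant_to_column_order(self, rng):
        labels = np.array([1] * 15 + [0] * 15, dtype=np.int8)
        X = (rng.random((30, 8)) < 0.4).astype(np.uint8)
        X[:, 0] |= labels.astype(np.uint8)  # one informative column
        m = toy_matrix(X, labels)
        kept1 = {str(f) for f in correlation_filter(m)}
        perm = list(range(8))[::-1]
        feats2 = [m.features[i] for i in perm]
        m2 = BinaryFeatureMatrix(m.genes, feats2, X[:, perm], labels)
        kept2 = {str(f) for f in correlation_filter(m2)}
        assert kept1 == kept2
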