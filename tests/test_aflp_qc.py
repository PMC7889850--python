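import numpy as np
import pytest

from markercompare.aflp_qc import (
    DegenerateReplicatesError,
    EllipseParams,
    greedy_replicate_filter,
    nmds_outlier_screen,
    replicate_distance_sum,
)
from markercompare.io_formats import BinaryMarkerMatrix, SampleMetadata

from .oracles import brute_greedy_filter


def _matrix_from_rows(rows: dict[str, list[int]], locus_ids=None):
    sample_ids = list(rows)
    values = np.array([rows[s] for s in sample_ids])
    locus_ids = locus_ids or [f"L{j + 1}" for j in range(values.shape[1])]
    return BinaryMarkerMatrix(sample_ids, locus_ids, values)


def _as_dicts(m: BinaryMarkerMatrix):
    return {
        s: {l: int(v) for l, v in zip(m.locus_ids, m.values[i])}
        for i, s in enumerate(m.sample_ids)
    }


class TestReplicateDistanceSum:
    def test_identical_pairs_zero(self):
        m = _matrix_from_rows({"a": [1, 0, 1], "a2": [1, 0, 1]})
        assert replicate_distance_sum(m, [("a", "a2")]) == 0.0

    def test_hand_sum(self):
        # pair 1 differs at 2 of 8 loci, pair 2 at 1 of 8: 0.25 + 0.125
        m = _matrix_from_rows(
            {
                "a": [1, 1, 1, 1, 0, 0, 0, 0],
                "a2": [0, 0, 1, 1, 0, 0, 0, 0],
                "b": [1, 0, 1, 0, 1, 0, 1, 0],
                "b2": [1, 0, 1, 0, 1, 0, 1, 1],
            }
        )
        s = replicate_distance_sum(m, [("a", "a2"), ("b", "b2")])
        assert s == pytest.approx(0.375)

    def test_empty_pairs(self):
        m = _matrix_from_rows({"a": [1, 0]})
        assert replicate_distance_sum(m, []) == 0.0

    def test_unknown_sample_error(self):
        m = _matrix_from_rows({"a": [1, 0]})
        with pytest.raises(ValueError):
            replicate_distance_sum(m, [("a", "nope")])


class TestGreedyReplicateFilter:
    def test_zero_sum_fixed_point(self):
        rng = np.random.default_rng(0)
        prof = rng.integers(0, 2, size=10)
        m = _matrix_from_rows({"a": prof.tolist(), "a2": prof.tolist()})
        out, log = greedy_replicate_filter(m, [("a", "a2")])
        assert log.removed_locus_ids == []
        assert out.n_loci == 10
        assert log.initial_sum == log.final_sum == 0.0

    def test_doubly_mismatching_locus_removed(self):
        # locus 7 mismatches in both pairs, everything else matches
        base = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
        rep1 = list(base)
        rep1[6] = 0
        rep2 = list(base)
        rep2[6] = 0
        m = _matrix_from_rows(
            {"a": base, "a2": rep1, "b": base, "b2": rep2}
        )
        out, log = greedy_replicate_filter(m, [("a", "a2"), ("b", "b2")])
        assert log.removed_locus_ids == ["L7"]
        assert log.final_sum == 0.0
        assert "L7" not in out.locus_ids

    def test_singly_mismatching_locus_kept_when_removal_raises_sum(self):
        # locus 3 mismatches in pair 1 only; pairs 2-5 each mismatch at three
        # later loci, so dropping locus 3 raises their p-distances:
        # S = (1 + 12)/10 = 1.3 < 12/9 = 1.333...
        base = [0] * 10
        rows = {"p1a": list(base), "p1b": list(base)}
        rows["p1b"][2] = 1
        for p, cols in zip(
            range(2, 6), [(3, 4, 5), (4, 5, 6), (5, 6, 7), (7, 8, 9)]
        ):
            a, b = list(base), list(base)
            for c in cols:
                b[c] = 1
            rows[f"p{p}a"], rows[f"p{p}b"] = a, b
        m = _matrix_from_rows(rows)
        pairs = [(f"p{p}a", f"p{p}b") for p in range(1, 6)]
        assert replicate_distance_sum(m, pairs) == pytest.approx(1.3)
        out, log = greedy_replicate_filter(m, pairs)
        decision_l3 = next(d for d in log.decisions if d.locus_id == "L3")
        assert decision_l3.sum_if_removed == pytest.approx(12 / 9)
        assert not decision_l3.accepted
        assert "L3" in out.locus_ids

    def test_matches_literal_reapplication_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            n_loci = int(rng.integers(2, 13))
            n_pairs = int(rng.integers(1, 5))
            rows = {}
            for p in range(n_pairs):
                a = rng.integers(0, 2, size=n_loci)
                b = a.copy()
                flip = rng.random(n_loci) < 0.3
                b[flip] = 1 - b[flip]
                rows[f"p{p}a"] = a.tolist()
                rows[f"p{p}b"] = b.tolist()
            m = _matrix_from_rows(rows)
            pairs = [(f"p{p}a", f"p{p}b") for p in range(n_pairs)]
            try:
                out, log = greedy_replicate_filter(m, pairs)
            except DegenerateReplicatesError:
                continue
            expected = brute_greedy_filter(_as_dicts(m), m.locus_ids, pairs)
            assert log.removed_locus_ids == expected
            assert log.final_sum <= log.initial_sum + 1e-12
            if not expected:
                assert log.final_sum == pytest.approx(log.initial_sum)

    def test_sum_never_increases_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_loci = int(rng.integers(5, 40))
            rows = {}
            for p in range(3):
                a = rng.integers(0, 2, size=n_loci)
                b = a.copy()
                flip = rng.random(n_loci) < 0.15
                b[flip] = 1 - b[flip]
                rows[f"p{p}a"], rows[f"p{p}b"] = a.tolist(), b.tolist()
            m = _matrix_from_rows(rows)
            pairs = [(f"p{p}a", f"p{p}b") for p in range(3)]
            _, log = greedy_replicate_filter(m, pairs)
            assert log.final_sum <= log.initial_sum + 1e-12
            sums = log.distance_sum_trajectory
            accepted_sums = [log.initial_sum] + [
                d.sum_after for d in log.decisions if d.accepted
            ]
            assert all(
                s2 <= s1 + 1e-12 for s1, s2 in zip(accepted_sums, accepted_sums[1:])
            )
            assert len(sums) == len(log.decisions)

    def test_degenerate_replicates_error(self):
        # column mismatch counts (3, 2, 1): L1 and L2 get removed, leaving
        # only L3 with a positive sum -> the evaluation of L3 must abort
        rows = {
            "p1a": [0, 0, 0], "p1b": [1, 1, 0],
            "p2a": [0, 0, 0], "p2b": [1, 1, 0],
            "p3a": [0, 0, 0], "p3b": [1, 0, 1],
        }
        m = _matrix_from_rows(rows)
        pairs = [("p1a", "p1b"), ("p2a", "p2b"), ("p3a", "p3b")]
        with pytest.raises(DegenerateReplicatesError):
            greedy_replicate_filter(m, pairs)

    def test_iterate_mode_reaches_fixed_point(self):
        rng = np.random.default_rng(42)
        n_loci = 30
        rows = {}
        for p in range(3):
            a = rng.integers(0, 2, size=n_loci)
            b = a.copy()
            flip = rng.random(n_loci) < 0.2
            b[flip] = 1 - b[flip]
            rows[f"p{p}a"], rows[f"p{p}b"] = a.tolist(), b.tolist()
        m = _matrix_from_rows(rows)
        pairs = [(f"p{p}a", f"p{p}b") for p in range(3)]
        out, log = greedy_replicate_filter(m, pairs, iterate=True)
        # one more pass must remove nothing
        out2, log2 = greedy_replicate_filter(out, pairs)
        assert log2.removed_locus_ids == []


class TestEllipse:
    def test_contains_center_and_excludes_far_point(self):
        ell = EllipseParams(np.zeros(2), np.eye(2), 0.90)
        inside = ell.contains(np.array([[0.0, 0.0], [10.0, 0.0]]))
        assert inside.tolist() == [True, False]

    def test_degenerate_covariance_contains_its_points(self):
        pts = np.zeros((4, 2))
        ell = EllipseParams(pts.mean(0), np.cov(pts, rowvar=False), 0.90)
        assert ell.contains(pts).all()


def _screen_fixture_outlier(seed=0):
    """3 regions x 10 individuals, 4 combos; X_1 mimics region Y in combos 1-3."""
    rng = np.random.default_rng(seed)
    regions = {"X": 0, "Y": 1, "Z": 2}
    samples = [f"{r}_{i}" for r in regions for i in range(10)]
    matrices = {}
    n_loci = 42
    for c in range(4):
        values = np.zeros((30, n_loci), dtype=np.int8)
        for si, s in enumerate(samples):
            r = regions[s.split("_")[0]]
            if s == "X_0" and c < 3:
                r = regions["Y"]
            block = slice(r * 14, r * 14 + 14)
            values[si, block] = 1
            flips = rng.choice(n_loci, size=2, replace=False)
            values[si, flips] = 1 - values[si, flips]
        matrices[f"c{c + 1}"] = BinaryMarkerMatrix(
            list(samples), [f"L{j}" for j in range(n_loci)], values
        )
    meta = SampleMetadata(
        list(samples), {s: s.split("_")[0] for s in samples}
    )
    return matrices, meta


class TestNmdsOutlierScreen:
    def test_coincident_individuals_no_exclusions(self):
        samples = [f"{r}_{i}" for r in ("X", "Y") for i in range(4)]
        values = np.array(
            [[1, 0, 1, 0] if s.startswith("X") else [0, 1, 0, 1] for s in samples]
        )
        m = BinaryMarkerMatrix(samples, ["L1", "L2", "L3", "L4"], values)
        meta = SampleMetadata(samples, {s: s.split("_")[0] for s in samples})
        report = nmds_outlier_screen({"c1": m, "c2": m}, meta, seed=1)
        assert report.excluded_individuals == []
        assert report.excluded_combos == []

    def test_planted_outlier_excluded(self):
        matrices, meta = _screen_fixture_outlier()
        report = nmds_outlier_screen(matrices, meta, seed=3)
        flags = [report.outside_flags[f"c{c}"]["X_0"] for c in range(1, 5)]
        assert sum(bool(f) for f in flags[:3]) == 3  # outside in the 3 planted combos
        assert report.individual_outside_fraction["X_0"] > 0.5
        assert "X_0" in report.excluded_individuals

    def test_combo_with_many_outliers_excluded(self):
        # one 15-member region; combo c1 plants 2 orthogonal outliers
        # (2/15 = 0.133 > 0.1), combo c2 is clean
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(15)]
        n_loci = 40
        clean = np.zeros((15, n_loci), dtype=np.int8)
        clean[:, :10] = 1  # coincident profiles: degenerate ellipse, all inside
        noisy = clean.copy()
        for si in range(2, 15):
            flips = rng.choice(n_loci, size=2, replace=False)
            noisy[si, flips] = 1 - noisy[si, flips]
        noisy[0] = 0
        noisy[0, 10:20] = 1
        noisy[1] = 0
        noisy[1, 20:30] = 1
        loci = [f"L{j}" for j in range(n_loci)]
        matrices = {
            "c1": BinaryMarkerMatrix(samples, loci, noisy),
            "c2": BinaryMarkerMatrix(samples, loci, clean),
        }
        meta = SampleMetadata(list(samples), {s: "R" for s in samples})
        report = nmds_outlier_screen(matrices, meta, seed=7)
        assert report.combo_outside_fraction["c1"] == pytest.approx(2 / 15)
        assert report.excluded_combos == ["c1"]
        # after dropping c1, nobody is outside often enough
        assert report.excluded_individuals == []

    def test_small_region_unassessable(self):
        samples = ["X_0", "X_1", "Y_0", "Y_1", "Y_2"]
        rng = np.random.default_rng(2)
        values = rng.integers(0, 2, size=(5, 12))
        m = BinaryMarkerMatrix(samples, [f"L{j}" for j in range(12)], values)
        meta = SampleMetadata(samples, {s: s.split("_")[0] for s in samples})
        report = nmds_outlier_screen({"c1": m}, meta, seed=0)
        assert report.outside_flags["c1"]["X_0"] is None
        assert report.outside_flags["c1"]["X_1"] is None
        assert "X_0" not in report.excluded_individuals

    def test_determinism(self):
        matrices, meta = _screen_fixture_outlier(seed=9)
        r1 = nmds_outlier_screen(matrices, meta, seed=11)
        r2 = nmds_outlier_screen(matrices, meta, seed=11)
        assert r1.to_dict() == r2.to_dict()
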