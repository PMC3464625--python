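"""Jaccard overlap machinery, permutation nulls, and relatedness PR."""

import numpy as np
import pandas as pd
import pytest

from cnvpop.errors import ValidationError
from cnvpop.evaluation import (
    GenomicInterval,
    best_overlap,
    jaccard,
    overlap_histogram,
    permutation_null,
    profile_distance,
    relatedness_pr,
)


class TestJaccard:
    def test_identical_intervals(self):
        a = GenomicInterval("1", 100, 200)
        assert jaccard(a, a) == 1.0

    def test_disjoint_intervals(self):
        assert jaccard(("1", 0, 100), ("1", 200, 300)) == 0.0

    def test_partial_overlap_base_counting(self):
        assert jaccard(("1", 0, 100), ("1", 50, 150)) == pytest.approx(1 / 3)

    def test_different_chromosomes(self):
        assert jaccard(("1", 0, 100), ("2", 0, 100)) == 0.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            s1, s2 = rng.integers(0, 1000, 2)
            a = ("1", int(s1), int(s1) + int(rng.integers(1, 500)))
            b = ("1", int(s2), int(s2) + int(rng.integers(1, 500)))
            j1, j2 = jaccard(a, b), jaccard(b, a)
            assert j1 == j2
            assert 0.0 <= j1 <= 1.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            jaccard(("1", 100, 100), ("1", 0, 50))


class TestBestOverlap:
    def test_absent_chromosome(self):
        assert best_overlap(("3", 0, 100), [("1", 0, 100)]) == 0.0

    def test_exact_match(self):
        ref = [("1", 0, 100), ("1", 500, 700)]
        assert best_overlap(("1", 500, 700), ref) == 1.0

    def test_matches_exhaustive_scan(self, rng):
        ref = [
            ("1", int(s), int(s) + int(rng.integers(50, 500)))
            for s in rng.integers(0, 100_000, 100)
        ]
        for _ in range(20):
            s = int(rng.integers(0, 100_000))
            region = ("1", s, s + int(rng.integers(50, 800)))
            expected = max(jaccard(region, r) for r in ref)
            assert best_overlap(region, ref) == pytest.approx(expected)


class TestOverlapHistogram:
    def test_empty_reference_all_zero_bin(self):
        pred = [("1", i * 1000, i * 1000 + 500) for i in range(7)]
        counts = overlap_histogram(pred, [])
        assert counts[0] == 7 and counts[1:].sum() == 0

    def test_identical_sets_top_bin(self):
        pred = [("1", i * 1000, i * 1000 + 500) for i in range(5)]
        counts = overlap_histogram(pred, pred)
        assert counts[-1] == 5

    def test_hand_built_partial_overlaps(self):
        ref = [("1", 0, 100)]
        pred = [
            ("1", 0, 100),  # jaccard 1.0 -> bin 10
            ("1", 50, 150),  # 1/3 -> bin 4
            ("1", 200, 300),  # 0 -> bin 0
        ]
        counts = overlap_histogram(pred, ref)
        assert counts[0] == 1 and counts[4] == 1 and counts[10] == 1
        assert counts.sum() == 3


class TestPermutationNull:
    GENOME = {"1": 10_000_000}

    def test_planted_predictions_enriched(self):
        rng = np.random.default_rng(0)
        ref = [
            ("1", int(s), int(s) + 2000) for s in rng.integers(0, 9_900_000, 60)
        ]
        report = permutation_null(ref[:30], ref, self.GENOME, n_perm=200, seed=1)
        assert report.observed[-1] == 30
        assert report.p_enrich[-1] <= 1 / 201 + 1e-12

    def test_empty_reference_all_zero(self):
        pred = [("1", 0, 1000), ("1", 5000, 8000)] * 10
        report = permutation_null(pred, [], self.GENOME, n_perm=100, seed=0)
        assert report.observed[0] == 20
        assert np.all(report.null_mean[1:] == 0)
        assert report.p_enrich[0] == pytest.approx(1.0)
        assert report.p_deplete[0] == pytest.approx(1.0)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        ref = [("1", int(s), int(s) + 1500) for s in rng.integers(0, 9_000_000, 40)]
        pred = [("1", int(s), int(s) + 1000) for s in rng.integers(0, 9_000_000, 25)]
        r1 = permutation_null(pred, ref, self.GENOME, n_perm=150, seed=9)
        r2 = permutation_null(pred, ref, self.GENOME, n_perm=150, seed=9)
        np.testing.assert_array_equal(r1.p_enrich, r2.p_enrich)
        np.testing.assert_array_equal(r1.null_mean, r2.null_mean)

    def test_counts_conserved_across_bins(self):
        rng = np.random.default_rng(5)
        ref = [("1", int(s), int(s) + 1500) for s in rng.integers(0, 9_000_000, 30)]
        pred = [("1", int(s), int(s) + 900) for s in rng.integers(0, 9_000_000, 17)]
        report = permutation_null(pred, ref, self.GENOME, n_perm=120, seed=2)
        assert report.observed.sum() == 17
        np.testing.assert_allclose(
            report.null_mean.sum(), 17, atol=1e-9
        )

    def test_region_longer_than_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            permutation_null(
                [("1", 0, 20_000_000)], [], self.GENOME, n_perm=100, seed=0
            )


class TestProfileDistance:
    def test_identical_profiles(self):
        assert profile_distance([2, 2, 3], [2, 2, 3]) == 0.0

    def test_unit_difference(self):
        assert profile_distance((2, 2, 3), (2, 2, 2)) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 12))
        assert profile_distance(a, b) == pytest.approx(profile_distance(b, a))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            profile_distance([1, 2], [1, 2, 3])


def _profiles(n_subjects, n_regions, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.choice([1.0, 2.0, 3.0], size=(n_subjects, n_regions), p=[0.1, 0.8, 0.1])
    return pd.DataFrame(
        values, index=[f"s{i}" for i in range(n_subjects)]
    )


class TestRelatednessPr:
    def test_perfect_separation_gives_auc_one(self):
        profiles = _profiles(60, 8)
        # force related pairs to identical profiles
        related = []
        for i in range(10):
            a, b = f"s{2 * i}", f"s{2 * i + 1}"
            profiles.loc[b] = profiles.loc[a]
            related.append((a, b))
        # force unrelated pairs to differ
        unrelated = []
        for i in range(10):
            a, b = f"s{20 + 2 * i}", f"s{21 + 2 * i}"
            profiles.loc[b] = profiles.loc[a].to_numpy() + 3.0
            unrelated.append((a, b))
        res = relatedness_pr(related, unrelated, profiles, n_replicates=5, seed=0)
        assert res.auc == pytest.approx(1.0)

    def test_missing_subject_named(self):
        profiles = _profiles(30, 5)
        related = [(f"s{i}", f"s{i + 1}") for i in range(0, 20, 2)]
        unrelated = [(f"s{i}", f"s{i + 1}") for i in range(1, 21, 2)]
        related[0] = ("ghost", "s1")
        with pytest.raises(ValidationError, match="ghost"):
            relatedness_pr(related, unrelated, profiles, n_replicates=2, seed=0)

    def test_random_labels_auc_near_prevalence(self):
        """With distances unrelated to the labels the PR-AUC concentrates
        near the related-pair prevalence (0.5 for balanced classes)."""
        profiles = _profiles(200, 30, seed=3)
        subjects = list(profiles.index)
        rng = np.random.default_rng(4)
        pairs = []
        for i in range(0, 160, 2):
            pairs.append((subjects[i], subjects[i + 1]))
        rng.shuffle(pairs)
        related, unrelated = pairs[:40], pairs[40:80]
        res = relatedness_pr(related, unrelated, profiles, n_replicates=30, seed=5)
        assert abs(res.mean_auc - 0.5) < max(3 * res.sd_auc, 0.12)

    def test_curve_matches_threshold_enumeration_oracle(self):
        """The PR points agree with brute-force enumeration over all
        distance thresholds."""
        profiles = pd.DataFrame(
            {
                0: [2.0, 2.0, 1.0, 1.0, 3.0, 2.0, 2.0, 2.0, 1.0, 3.0] * 4,
            },
            index=[f"s{i}" for i in range(40)],
        )
        rng = np.random.default_rng(7)
        profiles[1] = rng.normal(2, 0.5, 40)
        related = [(f"s{2 * i}", f"s{2 * i + 1}") for i in range(10)]
        unrelated = [(f"s{20 + 2 * i}", f"s{21 + 2 * i}") for i in range(10)]
        res = relatedness_pr(related, unrelated, profiles, n_replicates=2, seed=1)
        # oracle
        dist = lambda a, b: float(
            np.linalg.norm(profiles.loc[a].to_numpy() - profiles.loc[b].to_numpy())
        )
        scores = np.array(
            [-dist(a, b) for a, b in related] + [-dist(a, b) for a, b in unrelated]
        )
        labels = np.array([1] * 10 + [0] * 10)
        for t in np.unique(scores):
            predicted = scores >= t
            tp = int((predicted & (labels == 1)).sum())
            fp = int((predicted & (labels == 0)).sum())
            prec = tp / (tp + fp)
            rec = tp / labels.sum()
            match = np.isclose(res.recall, rec) & np.isclose(res.precision, prec)
            assert match.any(), (t, prec, rec)

    def test_auc_invariant_under_monotone_distance_transform(self):
        profiles = _profiles(80, 12, seed=9)
        related = [(f"s{2 * i}", f"s{2 * i + 1}") for i in range(12)]
        unrelated = [(f"s{30 + 2 * i}", f"s{31 + 2 * i}") for i in range(12)]
        res1 = relatedness_pr(related, unrelated, profiles, n_replicates=2, seed=0)
        res2 = relatedness_pr(related, unrelated, profiles * 10.0, n_replicates=2, seed=0)
        assert res1.auc == pytest.approx(res2.auc)
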