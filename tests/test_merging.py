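"""Simple merge, chromosome partitioning, PCA reduction, SOM clustering."""

import numpy as np
import pytest

from cnvpop.core import DosageMatrix, ProbeMap
from cnvpop.errors import ValidationError
from cnvpop.merging import (
    MergeConfig,
    partition_chromosome,
    pca_merge,
    pca_reduce,
    simple_merge,
    som_cluster,
)


def make_map(n, spacing=100_000, chrom="1", start=None):
    pos = (np.arange(n) + 1) * spacing if start is None else start
    return ProbeMap(
        np.array([f"{chrom}_p{i}" for i in range(n)], dtype=object),
        np.array([chrom] * n, dtype=object),
        np.asarray(pos),
    )


def brute_force_simple_merge(cn, positions, max_gap=500_000):
    """Oracle: group adjacent identical columns, splitting non-diploid runs
    at gaps > max_gap."""
    n = cn.shape[1]
    groups = []
    start = 0
    for i in range(1, n + 1):
        if i == n:
            groups.append((start, i - 1))
            break
        same = np.array_equal(cn[:, i], cn[:, start])
        diploid = np.all(cn[:, start] == 2)
        split = (not same) or (
            same and not diploid and positions[i] - positions[i - 1] > max_gap
        )
        if split:
            groups.append((start, i - 1))
            start = i
    return groups


class TestSimpleMerge:
    def test_identical_nondiploid_columns_one_region(self):
        pm = make_map(5)
        cn = np.tile(np.array([[3], [2], [2]]), (1, 5))
        regions = simple_merge(cn, pm, ["a", "b", "c"])
        assert len(regions) == 1
        assert regions[0].start == pm.positions[0] - 1
        assert regions[0].end == pm.positions[-1]
        assert regions[0].carriers == frozenset(["a"])

    def test_gap_splits_nondiploid_run(self):
        pos = np.array([100_000, 200_000, 800_000, 900_000])
        pm = make_map(4, start=pos)
        cn = np.tile(np.array([[1], [2]]), (1, 4))
        regions = simple_merge(cn, pm, ["a", "b"])
        assert len(regions) == 2  # 600 kb gap between probes 2 and 3

    def test_gap_does_not_split_diploid_run(self):
        pos = np.array([100_000, 200_000, 900_000, 1_000_000])
        pm = make_map(4, start=pos)
        cn = np.full((2, 4), 2)
        regions = simple_merge(cn, pm, ["a", "b"])
        assert len(regions) == 1

    def test_non_integer_matrix_rejected(self):
        pm = make_map(3)
        with pytest.raises(ValidationError):
            simple_merge(np.full((2, 3), 2.4), pm, ["a", "b"])

    def test_matches_brute_force_oracle(self):
        """Random small matrices agree with the exhaustive adjacent-equal-
        column grouping, including gap splits."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n_probes = 12
            pos = np.sort(
                rng.choice(np.arange(1, 40) * 100_000, size=n_probes, replace=False)
            )
            pm = make_map(n_probes, start=pos)
            cn = rng.choice([1, 2, 2, 2, 3], size=(6, n_probes))
            subjects = [f"s{i}" for i in range(6)]
            regions = simple_merge(cn, pm, subjects)
            expected = brute_force_simple_merge(cn, pos)
            got = [
                (r.probe_indices[0], r.probe_indices[1]) for r in regions
            ]
            assert got == expected

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        pm = make_map(30)
        cn = rng.choice([1, 2, 3], size=(4, 30))
        regions = simple_merge(cn, pm, [f"s{i}" for i in range(4)])
        covered = []
        for r in regions:
            covered.extend(range(r.probe_indices[0], r.probe_indices[1] + 1))
        assert covered == list(range(30))


class TestPartitionChromosome:
    def test_everywhere_diploid(self):
        pos = (np.arange(30) + 1) * 100_000
        dosage = np.full((5, 30), 2.0)
        blocks, bounds = partition_chromosome(dosage, pos)
        assert blocks == []
        assert bounds == [(0, 29)]

    def test_single_variant_run_one_block(self):
        """A variant run flanked by >= 1 Mb diploid stretches gives exactly
        one block containing the run (scanline oracle)."""
        pos = (np.arange(40) + 1) * 100_000
        dosage = np.full((4, 40), 2.0)
        dosage[0, 15:20] = 3.0
        blocks, bounds = partition_chromosome(dosage, pos)
        assert blocks == [(15, 19)]
        assert bounds == [(0, 14), (20, 39)]

    def test_short_stretch_does_not_split(self):
        """Two variant runs separated by a 0.5 Mb diploid stretch stay in a
        single block."""
        pos = (np.arange(60) + 1) * 100_000
        dosage = np.full((3, 60), 2.0)
        dosage[0, 20:23] = 1.0
        dosage[1, 27:30] = 3.0  # gap 23..26 spans 400 kb < 1 Mb
        blocks, _ = partition_chromosome(dosage, pos)
        assert blocks == [(20, 29)]

    def test_cover_exactly_once(self):
        rng = np.random.default_rng(5)
        pos = (np.arange(80) + 1) * 70_000
        dosage = np.full((6, 80), 2.0)
        for s in range(6):
            i = rng.integers(0, 75)
            dosage[s, i : i + 4] = rng.choice([1.0, 3.0])
        blocks, bounds = partition_chromosome(dosage, pos)
        idx = sorted(
            i for lo, hi in blocks + bounds for i in range(lo, hi + 1)
        )
        assert idx == list(range(80))


class TestPcaReduce:
    def test_rank_one_block(self):
        carriers = np.array([1.0, 0, 0, 0, 0, 0, 1.0, 0])
        block = 2.0 - np.outer(carriers, np.ones(6))
        block[:, :] += np.outer(carriers, np.zeros(6))
        eigen = pca_reduce(2.0 - np.outer(carriers, np.full(6, 1.0)))
        assert eigen is not None
        assert eigen.shape[0] == 1

    def test_two_orthogonal_signals_need_two_components(self):
        # two independent carrier groups on disjoint probe spans, equal
        # variance: each principal component explains 50%
        a = np.zeros(40)
        a[:10] = 1.0
        b = np.zeros(40)
        b[10:20] = 1.0
        block = np.full((40, 10), 2.0)
        block[:, :5] += a[:, None]
        block[:, 5:] -= b[:, None]
        eigen = pca_reduce(block, MergeConfig(clip_quantiles=(0, 100)))
        assert eigen.shape[0] == 2

    def test_zero_variance_block(self):
        assert pca_reduce(np.full((10, 5), 2.0)) is None

    def test_explained_variance_threshold_oracle(self, rng):
        """m is minimal with cumulative eigenvalue mass >= 90%."""
        for _ in range(10):
            block = rng.normal(2.0, 0.3, size=(30, 8))
            cfg = MergeConfig(clip_quantiles=(0, 100))
            eigen = pca_reduce(block, cfg)
            x = block - block.mean(axis=0)
            ev = np.sort(np.linalg.svd(x, compute_uv=False))[::-1] ** 2
            frac = np.cumsum(ev) / ev.sum()
            m = int(np.searchsorted(frac, 0.9 - 1e-12) + 1)
            assert eigen.shape[0] == m


class TestSomCluster:
    def test_identical_profiles_one_label(self):
        x = np.tile([1.5, -0.5], (20, 1))
        labels = som_cluster(x, MergeConfig(seed=1))
        assert len(set(labels)) == 1

    def test_two_separated_clouds_match_two_means(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1e-6, size=(15, 2))
        b = rng.normal(10, 1e-6, size=(15, 2))
        x = np.vstack([a, b])
        labels = som_cluster(x, MergeConfig(seed=3))
        assert len(set(labels)) == 2
        # agreement with a 2-means oracle up to relabeling
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=5, random_state=0).fit_predict(x)
        first, second = labels[:15], labels[15:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert len(set(km[:15])) == 1 and len(set(km[15:])) == 1

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=(40, 3))
        cfg = MergeConfig(seed=11)
        np.testing.assert_array_equal(som_cluster(x, cfg), som_cluster(x, cfg))

    def test_empty_input(self):
        assert len(som_cluster(np.empty((0, 2)))) == 0


class TestPcaMerge:
    def _dosage(self, values, pm):
        return DosageMatrix([f"s{i}" for i in range(values.shape[0])], values, pm)

    def test_all_diploid_one_region_per_chromosome(self):
        ids = np.array([f"p{i}" for i in range(40)], dtype=object)
        chroms = np.array(["1"] * 20 + ["2"] * 20, dtype=object)
        pos = np.concatenate([(np.arange(20) + 1) * 100_000] * 2)
        pm = ProbeMap(ids, chroms, pos)
        regions = pca_merge(self._dosage(np.full((5, 40), 2.0), pm))
        assert len(regions) == 2
        assert {r.chromosome for r in regions} == {"1", "2"}

    def test_clean_duplication_recovered_exactly(self):
        """One clean 30-probe duplication in 5% of subjects becomes one
        region spanning exactly those probes."""
        rng = np.random.default_rng(8)
        n, p = 200, 100
        pm = make_map(p)
        values = np.full((n, p), 2.0)
        carriers = rng.random(n) < 0.05
        assert 2 < carriers.sum() < 20
        values[carriers, 35:65] = 3.0
        regions = pca_merge(self._dosage(values, pm), MergeConfig(seed=0))
        variant = [r for r in regions if r.carrier_count > 0]
        assert len(variant) == 1
        assert variant[0].probe_indices == (35, 64)

    def test_partition_of_probe_set(self):
        rng = np.random.default_rng(4)
        pm = make_map(60)
        values = np.full((20, 60), 2.0)
        for s in range(20):
            if rng.random() < 0.3:
                i = rng.integers(0, 50)
                values[s, i : i + 8] = rng.choice([1.0, 3.0])
        regions = pca_merge(self._dosage(values, pm), MergeConfig(seed=2))
        covered = []
        for r in sorted(regions, key=lambda r: r.probe_indices):
            covered.extend(range(r.probe_indices[0], r.probe_indices[1] + 1))
        assert covered == list(range(60))

    def test_invariant_to_added_diploid_subjects(self):
        """Adding all-diploid subjects does not change the region
        partition."""
        rng = np.random.default_rng(6)
        pm = make_map(50)
        values = np.full((40, 50), 2.0)
        carriers = rng.random(40) < 0.2
        values[carriers, 10:30] = 1.0
        base = pca_merge(self._dosage(values, pm), MergeConfig(seed=5))
        extended = np.vstack([values, np.full((20, 50), 2.0)])
        more = pca_merge(self._dosage(extended, pm), MergeConfig(seed=5))
        assert [
            r.probe_indices for r in base
        ] == [r.probe_indices for r in more]
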