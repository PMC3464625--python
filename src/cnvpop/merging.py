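"""Collapse per-probe calls into consensus CNV regions.

Two mergers are provided. The *simple merge* joins maximal runs of adjacent
probes whose integer copy-number columns are identical across the whole
population, splitting a run wherever two consecutive probes lie more than
``max_gap`` (default 500 kb) apart — except for all-copy-neutral runs, where
a long low-density stretch is harmless. It is exact but leaves CNV edges
fragmented: a single subject whose breakpoint differs by one probe breaks
the run.

The *PCA merge* repairs that fragmentation in four steps, per chromosome:

1. partition the chromosome into blocks bounded by long (>= ``diploid_span``,
   default 1 Mb) stretches of probes at which every subject is diploid;
2. winsorize each probe's dosages across subjects (``clip_quantiles``) to
   suppress outlier cells;
3. take the principal-component decomposition of the centered block and keep
   the smallest number m of leading components explaining at least
   ``variance_target`` (default 90%) of the variance; every probe then has an
   m-dimensional eigen-profile (loadings scaled by singular values);
4. cluster the probes' eigen-profiles with a 2-D batch self-organizing map
   and merge strictly adjacent probes sharing a SOM unit into final regions.

Both mergers partition the probe set: their regions are disjoint, sorted and
exhaustive on every chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CNVRegion, DosageMatrix, ProbeMap, round_half_up
from .errors import ValidationError

__all__ = [
    "MergeConfig",
    "simple_merge",
    "partition_chromosome",
    "pca_reduce",
    "som_cluster",
    "pca_merge",
]


@dataclass(frozen=True)
class MergeConfig:
    """Parameters shared by the two merging algorithms.

    max_gap         : maximal basepair distance between adjacent probes of
                      one (non-diploid) simple-merge region.
    diploid_span    : minimal basepair span of an all-diploid probe stretch
                      for it to act as a PCA-merge block boundary.
    variance_target : cumulative explained-variance fraction retained by the
                      principal-component reduction.
    som_grid        : side length k of the k x k SOM grid, or "auto" for
                      k = ceil(n_probes_in_block^(1/4)) + 1.
    som_epochs      : batch training epochs.
    clip_quantiles  : (low, high) percentiles for winsorizing each probe's
                      dosages across subjects before the PCA.
    """

    max_gap: int = 500_000
    diploid_span: int = 1_000_000
    variance_target: float = 0.90
    som_grid: int | str = "auto"
    som_epochs: int = 200
    seed: int = 0
    clip_quantiles: tuple[float, float] = (1.0, 99.0)

    def __post_init__(self) -> None:
        if not (0 < self.variance_target <= 1):
            raise ValidationError("variance_target must be in (0, 1]")
        if self.max_gap <= 0 or self.diploid_span <= 0:
            raise ValidationError("gap/span parameters must be positive")
        lo, hi = self.clip_quantiles
        if not (0 <= lo < hi <= 100):
            raise ValidationError("clip_quantiles must satisfy 0 <= lo < hi <= 100")


def _make_region(
    chromosome: str,
    probe_lo: int,
    probe_hi: int,  # inclusive
    probe_map: ProbeMap,
    per_subject_value: np.ndarray,
    subjects,
) -> CNVRegion:
    start = int(probe_map.positions[probe_lo]) - 1
    end = int(probe_map.positions[probe_hi])
    rounded = np.clip(round_half_up(per_subject_value), 1, 4)
    carriers = frozenset(s for s, v in zip(subjects, rounded) if v != 2)
    return CNVRegion(
        chromosome=chromosome,
        start=start,
        end=end,
        probe_indices=(probe_lo, probe_hi),
        carriers=carriers,
        per_subject_value=np.asarray(per_subject_value, dtype=float),
        n_subjects=len(subjects),
    )


# ---------------------------------------------------------------------------
# simple merge


def simple_merge(
    cn_matrix: np.ndarray, probe_map: ProbeMap, subjects, config: MergeConfig | None = None
) -> list[CNVRegion]:
    """Merge maximal runs of adjacent probes with identical integer columns.

    The input must already be integer copy numbers (round dosages first).
    Runs whose shared column is non-diploid are additionally split at
    inter-probe gaps larger than ``max_gap``.
    """
    cfg = config or MergeConfig()
    cn = np.asarray(cn_matrix)
    if not np.issubdtype(cn.dtype, np.integer):
        if not np.all(cn == np.round(cn)):
            raise ValidationError("simple_merge requires an integer CN matrix")
        cn = cn.astype(int)
    if cn.shape != (len(subjects), probe_map.n_probes):
        raise ValidationError("CN matrix shape does not match subjects x probes")
    regions: list[CNVRegion] = []
    for chrom, sl in probe_map.chrom_blocks():
        block = cn[:, sl]
        pos = probe_map.positions[sl]
        n = block.shape[1]
        start = 0
        for i in range(1, n + 1):
            boundary = i == n
            if not boundary:
                same = np.array_equal(block[:, i], block[:, start])
                col_diploid = np.all(block[:, start] == 2)
                gap_split = (
                    same
                    and not col_diploid
                    and pos[i] - pos[i - 1] > cfg.max_gap
                )
                boundary = (not same) or gap_split
            if boundary:
                regions.append(
                    _make_region(
                        chrom,
                        sl.start + start,
                        sl.start + i - 1,
                        probe_map,
                        block[:, start].astype(float),
                        subjects,
                    )
                )
                start = i
    return regions


# ---------------------------------------------------------------------------
# PCA merge building blocks


def partition_chromosome(
    dosage_block: np.ndarray,
    positions: np.ndarray,
    config: MergeConfig | None = None,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split one chromosome into CNV blocks and diploid boundary stretches.

    A boundary stretch is a maximal run of probes at which every subject's
    dosage rounds to 2 and whose genomic span (region extent in basepairs)
    is at least ``diploid_span``. Returns (blocks, boundaries) as inclusive
    probe-index ranges local to the chromosome; together they cover every
    probe exactly once.
    """
    cfg = config or MergeConfig()
    n = dosage_block.shape[1]
    if n == 0:
        return [], []
    diploid_probe = np.all(np.abs(dosage_block - 2.0) < 0.5, axis=0)
    boundaries: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if diploid_probe[i]:
            j = i
            while j + 1 < n and diploid_probe[j + 1]:
                j += 1
            span = int(positions[j]) - (int(positions[i]) - 1)
            if span >= cfg.diploid_span:
                boundaries.append((i, j))
            i = j + 1
        else:
            i += 1
    blocks: list[tuple[int, int]] = []
    prev_end = -1
    for lo, hi in boundaries + [(n, n)]:
        if lo - 1 >= prev_end + 1:
            blocks.append((prev_end + 1, lo - 1))
        prev_end = hi
    return blocks, boundaries


def pca_reduce(
    block_dosage: np.ndarray, config: MergeConfig | None = None
) -> np.ndarray | None:
    """Winsorize, center and PC-decompose one block of the dosage matrix.

    Returns the m x probes matrix of probe loadings scaled by singular
    values, with m the smallest number of leading components whose
    cumulative explained variance reaches ``variance_target``. A
    zero-variance block returns None (one trivial cluster downstream).
    """
    cfg = config or MergeConfig()
    x = np.asarray(block_dosage, dtype=float)
    lo_q, hi_q = cfg.clip_quantiles
    lo = np.percentile(x, lo_q, axis=0)
    hi = np.percentile(x, hi_q, axis=0)
    x = np.clip(x, lo[None, :], hi[None, :])
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(np.abs(x) > 1e-12):
        return None
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    ratio = np.cumsum(var) / var.sum()
    m = int(np.searchsorted(ratio, cfg.variance_target - 1e-12) + 1)
    m = min(m, len(s))
    return s[:m, None] * vt[:m, :]


def _grid_side(n_probes: int, config: MergeConfig) -> int:
    # Capacity must stay well below the block's probe count: blocks are
    # bounded by all-diploid stretches, so one block typically holds a
    # single CNV event plus its fragmented shoulders, and surplus units
    # would quantize the shoulder gradient into spurious adjacent labels.
    if config.som_grid == "auto":
        return max(2, int(np.ceil(n_probes ** 0.25)) - 1)
    return int(config.som_grid)


def som_cluster(
    eigen_profiles: np.ndarray, config: MergeConfig | None = None
) -> np.ndarray:
    """Batch-train a 2-D SOM on probe eigen-profiles and return BMU labels.

    eigen_profiles is probes x m. The grid is k x k (see ``som_grid``) on a
    rectangular topology with a Gaussian neighbourhood whose radius shrinks
    linearly from k/2 to 0.5 over ``som_epochs`` batch epochs; codebook
    vectors are initialized uniformly at random within the per-dimension
    data range under the configured seed. Ties in the best-matching-unit
    search resolve to the lowest unit index, so labels are reproducible.
    """
    cfg = config or MergeConfig()
    x = np.asarray(eigen_profiles, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, m = x.shape
    if n == 0:
        return np.empty(0, dtype=int)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    scale = max(np.abs(x).max(), 1.0)
    if (hi - lo).max() <= 1e-9 * scale:
        # numerically identical profiles: one cluster, skip training
        return np.zeros(n, dtype=int)
    k = max(_grid_side(n, cfg), 1)
    n_units = k * k
    rng = np.random.default_rng(cfg.seed)
    span = np.where(hi > lo, hi - lo, 1.0)
    w = lo[None, :] + rng.random((n_units, m)) * span[None, :]
    gy, gx = np.divmod(np.arange(n_units), k)
    grid = np.stack([gx, gy], axis=1).astype(float)
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)
    sigma0 = max(k / 2.0, 0.5)
    sigma1 = 0.5
    epochs = max(cfg.som_epochs, 1)
    for epoch in range(epochs):
        t = epoch / max(epochs - 1, 1)
        sigma = sigma0 + (sigma1 - sigma0) * t
        d2 = ((x[:, None, :] - w[None, :, :]) ** 2).sum(-1)  # n x units
        bmu = np.argmin(d2, axis=1)
        h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))  # n x units
        mass = h.sum(axis=0)
        upd = h.T @ x
        nz = mass > 1e-12
        w[nz] = upd[nz] / mass[nz, None]
    d2 = ((x[:, None, :] - w[None, :, :]) ** 2).sum(-1)
    return np.argmin(d2, axis=1)


def pca_merge(
    dosage: DosageMatrix, config: MergeConfig | None = None
) -> list[CNVRegion]:
    """Run the four-step PCA+SOM merge over every chromosome.

    Boundary stretches become diploid regions directly; within each block,
    maximal runs of adjacent probes sharing a SOM label become regions. The
    output covers every probe exactly once, sorted along the genome.
    """
    cfg = config or MergeConfig()
    pm = dosage.probe_map
    subjects = dosage.subjects
    regions: list[CNVRegion] = []
    for chrom, sl in pm.chrom_blocks():
        block_dosage = dosage.values[:, sl]
        positions = pm.positions[sl]
        blocks, boundaries = partition_chromosome(block_dosage, positions, cfg)
        pieces: list[tuple[int, int]] = []
        for lo, hi in boundaries:
            pieces.append((lo, hi))
        for b_idx, (lo, hi) in enumerate(blocks):
            sub = block_dosage[:, lo : hi + 1]
            if sub.shape[1] == 1:
                pieces.append((lo, lo))
                continue
            eigen = pca_reduce(sub, cfg)
            if eigen is None:
                pieces.append((lo, hi))
                continue
            labels = som_cluster(eigen.T, cfg)
            run_start = 0
            for i in range(1, len(labels) + 1):
                if i == len(labels) or labels[i] != labels[run_start]:
                    pieces.append((lo + run_start, lo + i - 1))
                    run_start = i
        pieces.sort()
        for lo, hi in pieces:
            vals = block_dosage[:, lo : hi + 1].mean(axis=1)
            regions.append(
                _make_region(chrom, sl.start + lo, sl.start + hi, pm, vals, subjects)
            )
    return regions
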