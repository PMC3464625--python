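"""Synthetic SNP-array cohorts with planted CNVs, batch effects and relatives.

The generator emulates the statistical structure the dosage caller assumes:
each subject's log2 copy-number ratio at a probe is centered at log2(cn/2)
for the subject's true copy number there (0 for diploid, -1 for a
hemizygous deletion, +0.585 for a single gain), plus i.i.d. Gaussian noise
on the log2 scale. Spatial autocorrelation enters only through the Loess
smoothing step of the pipeline, matching the mixture model's premises.
Optional features mirror the messiness of real cohorts: per-batch additive
offsets and scale factors, per-carrier breakpoint jitter (each carrier's
CNV start/end shifted by up to ``breakpoint_jitter`` probes, which is what
fragments simple-merge regions), and related pairs who share their carrier
CNVs with a configurable probability.

What it does not emulate: genotype calls, linkage disequilibrium, allele-
specific intensity ratios (B-allele frequency), GC waves beyond white
noise, or homozygous deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CNVRegion,
    IntensityMatrix,
    ProbeMap,
    RatioMatrix,
    RelatednessPair,
)
from .errors import ValidationError

__all__ = [
    "CnvSpec",
    "SimConfig",
    "Cohort",
    "simulate_cohort",
    "simulate_related_pairs",
    "intensities_from_ratios",
]


@dataclass(frozen=True)
class CnvSpec:
    """One planted CNV: a probe span on a chromosome, its copy-number state
    and its population carrier frequency."""

    chromosome: str
    start_probe: int  # index within the chromosome, 0-based
    n_probes: int
    cn: int  # 1, 3 or 4
    frequency: float

    def __post_init__(self) -> None:
        if self.cn not in (1, 3, 4):
            raise ValidationError("planted CNV copy number must be 1, 3 or 4")
        if not (0 <= self.frequency <= 1):
            raise ValidationError("frequency must be in [0, 1]")
        if self.n_probes < 1 or self.start_probe < 0:
            raise ValidationError("CNV probe span must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults model a mid-size population sample on a dense array: 300
    subjects, two chromosomes of 130 probes spaced ~30 kb apart, and a
    probe-level noise standard deviation of 0.1 log2 units (comparable to
    post-normalization SNP-array noise).
    """

    n_subjects: int = 300
    chromosomes: tuple[tuple[str, int], ...] = (("1", 130), ("2", 130))
    probe_spacing: int = 30_000
    cnv_spec: tuple[CnvSpec, ...] = ()
    noise_sd: float = 0.1
    batch_effects: tuple[tuple[float, float], ...] = ()  # (offset, scale) per batch
    breakpoint_jitter: int = 0
    n_related_pairs: int = 0
    sharing: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0 <= self.sharing <= 1):
            raise ValidationError("sharing must be in [0, 1]")
        if self.n_related_pairs * 2 > self.n_subjects:
            raise ValidationError("n_related_pairs exceeds n_subjects / 2")
        chrom_sizes = dict(self.chromosomes)
        for cnv in self.cnv_spec:
            n = chrom_sizes.get(cnv.chromosome)
            if n is None or cnv.start_probe + cnv.n_probes > n:
                raise ValidationError(
                    f"CNV on {cnv.chromosome} exceeds the chromosome's probe span"
                )


@dataclass
class Cohort:
    """A simulated cohort plus its ground truth."""

    subjects: list
    probe_map: ProbeMap
    ratios: RatioMatrix  # raw (unsmoothed) log2 ratios
    truth_cn: np.ndarray  # subjects x probes integer copy numbers
    true_regions: list  # CNVRegion per planted CNV (unjittered span)
    carrier_sets: list  # list of per-CNV carrier boolean arrays
    batches: np.ndarray
    related_pairs: list = field(default_factory=list)

    def chromosome_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for chrom, sl in self.probe_map.chrom_blocks():
            sizes[chrom] = int(self.probe_map.positions[sl][-1]) + 1
        return sizes


def _build_probe_map(config: SimConfig) -> ProbeMap:
    ids, chroms, pos = [], [], []
    for chrom, n in sorted(config.chromosomes, key=lambda c: str(c[0])):
        for i in range(n):
            ids.append(f"probe_{chrom}_{i:04d}")
            chroms.append(str(chrom))
            pos.append((i + 1) * config.probe_spacing)
    return ProbeMap(
        np.array(ids, dtype=object),
        np.array(chroms, dtype=object),
        np.array(pos, dtype=np.int64),
    )


def _chrom_offsets(probe_map: ProbeMap) -> dict[str, int]:
    return {chrom: sl.start for chrom, sl in probe_map.chrom_blocks()}


def _truth_from_carriers(
    config: SimConfig,
    probe_map: ProbeMap,
    carrier_sets: list,
    rng: np.random.Generator,
) -> np.ndarray:
    n = config.n_subjects
    truth = np.full((n, probe_map.n_probes), 2, dtype=int)
    offsets = _chrom_offsets(probe_map)
    j = config.breakpoint_jitter
    for cnv, carriers in zip(config.cnv_spec, carrier_sets):
        base = offsets[cnv.chromosome] + cnv.start_probe
        chrom_len = dict(config.chromosomes)[cnv.chromosome]
        chrom_lo = offsets[cnv.chromosome]
        chrom_hi = chrom_lo + chrom_len  # exclusive
        for s in np.flatnonzero(carriers):
            lo = base + (rng.integers(-j, j + 1) if j else 0)
            hi = base + cnv.n_probes + (rng.integers(-j, j + 1) if j else 0)
            lo = max(lo, chrom_lo)
            hi = min(max(hi, lo + 1), chrom_hi)
            truth[s, lo:hi] = cnv.cn
    return truth


def _ratios_from_truth(
    truth: np.ndarray, config: SimConfig, batches: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    ratios = np.log2(truth / 2.0) + rng.normal(0.0, config.noise_sd, truth.shape)
    if config.batch_effects:
        params = list(config.batch_effects)
        for b, (offset, scale) in enumerate(params):
            mask = batches == b
            ratios[mask] = ratios[mask] * scale + offset
    return ratios


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a cohort: carriers per CNV by frequency, ratios with noise.

    Deterministic for a fixed config (including the seed). Truth tables
    record the planted integer CN matrix and the unjittered region list.
    """
    rng = np.random.default_rng(config.seed)
    probe_map = _build_probe_map(config)
    subjects = [f"S{i:04d}" for i in range(config.n_subjects)]
    n_batches = max(len(config.batch_effects), 1)
    batches = np.arange(config.n_subjects) % n_batches
    carrier_sets = [
        rng.random(config.n_subjects) < cnv.frequency for cnv in config.cnv_spec
    ]
    truth = _truth_from_carriers(config, probe_map, carrier_sets, rng)
    ratios = _ratios_from_truth(truth, config, batches, rng)
    offsets = _chrom_offsets(probe_map)
    true_regions = []
    for cnv, carriers in zip(config.cnv_spec, carrier_sets):
        lo = offsets[cnv.chromosome] + cnv.start_probe
        hi = lo + cnv.n_probes - 1
        true_regions.append(
            CNVRegion(
                chromosome=cnv.chromosome,
                start=int(probe_map.positions[lo]) - 1,
                end=int(probe_map.positions[hi]),
                probe_indices=(lo, hi),
                carriers=frozenset(
                    s for s, c in zip(subjects, carriers) if c
                ),
                per_subject_value=np.where(carriers, cnv.cn, 2).astype(float),
                n_subjects=config.n_subjects,
            )
        )
    return Cohort(
        subjects=subjects,
        probe_map=probe_map,
        ratios=RatioMatrix(subjects, ratios, probe_map),
        truth_cn=truth,
        true_regions=true_regions,
        carrier_sets=carrier_sets,
        batches=batches,
    )


def simulate_related_pairs(cohort: Cohort, config: SimConfig) -> Cohort:
    """Plant related pairs into an existing cohort.

    Subjects (0,1), (2,3), ... up to ``n_related_pairs`` become pairs. For
    each CNV, the second member copies the first member's carrier status
    with probability ``sharing`` and otherwise keeps an independent draw at
    the population frequency. The second member's ratios are regenerated
    from the updated truth with fresh noise. Returns a new Cohort; the
    input is unchanged.
    """
    rng = np.random.default_rng(config.seed + 1)
    carrier_sets = [c.copy() for c in cohort.carrier_sets]
    pairs = []
    for p in range(config.n_related_pairs):
        a, b = 2 * p, 2 * p + 1
        for cnv, carriers in zip(config.cnv_spec, carrier_sets):
            if rng.random() < config.sharing:
                carriers[b] = carriers[a]
            else:
                carriers[b] = rng.random() < cnv.frequency
        pairs.append(
            RelatednessPair(cohort.subjects[a], cohort.subjects[b], "related")
        )
    truth = _truth_from_carriers(config, cohort.probe_map, carrier_sets, rng)
    ratios = _ratios_from_truth(truth, config, cohort.batches, rng)
    true_regions = []
    for region, carriers, cnv in zip(
        cohort.true_regions, carrier_sets, config.cnv_spec
    ):
        true_regions.append(
            CNVRegion(
                chromosome=region.chromosome,
                start=region.start,
                end=region.end,
                probe_indices=region.probe_indices,
                carriers=frozenset(
                    s for s, c in zip(cohort.subjects, carriers) if c
                ),
                per_subject_value=np.where(carriers, cnv.cn, 2).astype(float),
                n_subjects=config.n_subjects,
            )
        )
    return Cohort(
        subjects=cohort.subjects,
        probe_map=cohort.probe_map,
        ratios=RatioMatrix(cohort.subjects, ratios, cohort.probe_map),
        truth_cn=truth,
        true_regions=true_regions,
        carrier_sets=carrier_sets,
        batches=cohort.batches,
        related_pairs=pairs,
    )


def intensities_from_ratios(
    cohort: Cohort, reference_level: float = 1000.0, allele_noise_sd: float = 0.05,
    seed: int | None = None,
) -> IntensityMatrix:
    """Expand ratio-level truth into a two-allele intensity matrix.

    The total intensity of subject s at probe p is R_total * 2^ratio, split
    symmetrically between the A and B alleles with multiplicative lognormal
    noise, so that the total-intensity CN-ratio path reproduces the input
    ratios up to the allele noise.
    """
    rng = np.random.default_rng(cohort.ratios.values.shape[0] if seed is None else seed)
    p = cohort.probe_map.n_probes
    n = len(cohort.subjects)
    R_A = np.full(p, reference_level / 2)
    R_B = np.full(p, reference_level / 2)
    total = reference_level * np.exp2(cohort.ratios.values)
    split = rng.lognormal(0.0, allele_noise_sd, (n, p))
    S_A = total * split / (split + 1.0)
    S_B = total / (split + 1.0)
    return IntensityMatrix(
        subjects=cohort.subjects,
        batch=cohort.batches,
        S_A=S_A,
        S_B=S_B,
        R_A=R_A,
        R_B=R_B,
        probe_map=cohort.probe_map,
    )
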