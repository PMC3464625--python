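"""Carrier frequencies and CNP / CNVR classification of merged regions.

A subject is a carrier of a region when its call over the region is
non-diploid: by default the subject's mean dosage over the region's probes,
rounded to the nearest integer, differs from 2 (a modal integer-CN rule is
available as an alternative). Regions seen in fewer than ``min_carriers``
subjects (default 5, roughly 0.1% of a ~5600-subject cohort) are excluded;
of the rest, regions with carrier frequency above ``cnp_freq`` (default 1%)
are copy-number polymorphisms (CNPs) and the remainder — frequencies
roughly between 0.1% and 1% — are copy-number variant regions (CNVRs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CNVRegion, ProbeMap, round_half_up
from .errors import ValidationError

__all__ = [
    "CatalogConfig",
    "region_frequency",
    "classify_regions",
    "genome_coverage",
    "catalog_summary",
]

SIZE_STRATA = [
    ("<1kb", 0, 1_000),
    ("1-10kb", 1_000, 10_000),
    ("10-100kb", 10_000, 100_000),
    ("100kb-1Mb", 100_000, 1_000_000),
    (">=1Mb", 1_000_000, np.inf),
]


@dataclass(frozen=True)
class CatalogConfig:
    min_carriers: int = 5
    cnp_freq: float = 0.01
    floor_freq: float = 0.001
    carrier_rule: str = "mean"  # "mean" (rounded mean dosage) or "modal"

    def __post_init__(self) -> None:
        if not (0 <= self.floor_freq < self.cnp_freq <= 1):
            raise ValidationError("need 0 <= floor_freq < cnp_freq <= 1")
        if self.carrier_rule not in ("mean", "modal"):
            raise ValidationError(f"unknown carrier rule {self.carrier_rule!r}")


def _carrier_mask(
    region: CNVRegion, calls: np.ndarray, config: CatalogConfig
) -> np.ndarray:
    lo, hi = region.probe_indices
    if lo < 0 or hi < lo or hi >= calls.shape[1]:
        raise ValidationError(
            f"region {region.chromosome}:{region.start}-{region.end} has an "
            "empty or out-of-range probe span"
        )
    sub = calls[:, lo : hi + 1]
    if config.carrier_rule == "mean":
        cn = np.clip(round_half_up(sub.mean(axis=1)), 1, 4)
    else:
        ints = np.clip(round_half_up(sub), 1, 4)
        # modal integer CN per subject over the region's probes
        cn = np.array(
            [np.bincount(row, minlength=5)[1:].argmax() + 1 for row in ints]
        )
    return cn != 2


def region_frequency(
    region: CNVRegion,
    calls: np.ndarray,
    n_subjects: int,
    config: CatalogConfig | None = None,
) -> tuple[int, float]:
    """Carrier count and frequency of one region against a call matrix."""
    cfg = config or CatalogConfig()
    mask = _carrier_mask(region, calls, cfg)
    count = int(mask.sum())
    return count, count / n_subjects


def classify_regions(
    regions: Sequence[CNVRegion],
    calls: np.ndarray,
    subjects: Sequence[str],
    config: CatalogConfig | None = None,
) -> list[CNVRegion]:
    """Attach carrier sets, frequencies and CNP/CNVR/excluded classes.

    carriers < min_carriers -> excluded; frequency > cnp_freq -> CNP;
    otherwise CNVR. ``min_carriers`` takes precedence over ``floor_freq``
    (five carriers "roughly correspond" to 0.1% in the reference cohort).
    """
    cfg = config or CatalogConfig()
    subjects = list(subjects)
    n = len(subjects)
    out = []
    for region in regions:
        mask = _carrier_mask(region, calls, cfg)
        carriers = frozenset(s for s, c in zip(subjects, mask) if c)
        freq = len(carriers) / n
        if len(carriers) < cfg.min_carriers:
            klass = "excluded"
        elif freq > cfg.cnp_freq:
            klass = "CNP"
        else:
            klass = "CNVR"
        out.append(
            CNVRegion(
                chromosome=region.chromosome,
                start=region.start,
                end=region.end,
                probe_indices=region.probe_indices,
                carriers=carriers,
                per_subject_value=region.per_subject_value,
                klass=klass,
                n_subjects=n,
            )
        )
    return out


def _stratum(length: int) -> str:
    for name, lo, hi in SIZE_STRATA:
        if lo <= length < hi:
            return name
    return SIZE_STRATA[-1][0]


def catalog_summary(regions: Sequence[CNVRegion]) -> pd.DataFrame:
    """Counts by class x size stratum x chromosome."""
    rows = [
        {
            "chromosome": r.chromosome,
            "klass": r.klass or "unclassified",
            "stratum": _stratum(r.length),
        }
        for r in regions
    ]
    if not rows:
        return pd.DataFrame(columns=["chromosome", "klass", "stratum", "count"])
    return (
        pd.DataFrame(rows)
        .groupby(["chromosome", "klass", "stratum"])
        .size()
        .rename("count")
        .reset_index()
    )


def genome_coverage(
    regions: Sequence[CNVRegion], genome_sizes: dict[str, int]
) -> dict[str, float]:
    """Fraction of the genome covered by regions of each class.

    ``genome_sizes`` maps chromosome label to its length in basepairs; the
    denominator is the total over all supplied chromosomes.
    """
    total = float(sum(genome_sizes.values()))
    if total <= 0:
        raise ValidationError("genome sizes must be positive")
    cover: dict[str, float] = {}
    for r in regions:
        size = genome_sizes.get(r.chromosome)
        if size is None:
            raise ValidationError(f"no genome size for chromosome {r.chromosome!r}")
        if r.end > size:
            raise ValidationError(
                f"region {r.chromosome}:{r.start}-{r.end} extends beyond "
                f"chromosome end {size}"
            )
        key = r.klass or "unclassified"
        cover[key] = cover.get(key, 0.0) + r.length
    return {k: v / total for k, v in cover.items()}
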