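"""Classify externally produced segments into integer copy-number calls.

Segmentation algorithms such as circular binary segmentation report only
per-subject segments and their mean log2 ratios. Turning those into calls
needs gain/loss thresholds; these are derived from the population of
segment means with the standard Tukey outlier rule (Q1 - 1.5*IQR,
Q3 + 1.5*IQR), which on typical SNP-array data lands near the canonical
+/-0.25 log2 cut-offs. Classification is strict: a mean above the upper
threshold is a simple gain (CN = 3), below the lower a loss (CN = 1), and
anything else — including means exactly at a threshold — is copy-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ProbeMap, Segment
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "ThresholdPair",
    "derive_outlier_thresholds",
    "classify_segments",
    "segments_to_probe_matrix",
]


@dataclass(frozen=True)
class ThresholdPair:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError("lower threshold must be <= upper")


def derive_outlier_thresholds(segment_means) -> ThresholdPair:
    """Tukey outlier thresholds from a vector of segment mean log2 ratios.

    upper = Q3 + 1.5*IQR, lower = Q1 - 1.5*IQR. Invariant under permutation
    of the input. Requires at least 4 values; constant input degenerates to
    lower == upper == the constant (every segment is then copy-neutral
    downstream because classification is strict).
    """
    means = np.asarray(segment_means, dtype=float)
    if means.size < 4:
        raise InsufficientDataError("need >= 4 segment means to derive thresholds")
    q1, q3 = np.percentile(means, [25, 75])
    iqr = q3 - q1
    return ThresholdPair(lower=float(q1 - 1.5 * iqr), upper=float(q3 + 1.5 * iqr))


def classify_segments(
    segments: Sequence[Segment], thresholds: ThresholdPair
) -> list[Segment]:
    """Assign cn_class: mean > upper -> 3 (gain); mean < lower -> 1 (loss);
    otherwise 2. Returns new Segment objects; input is not mutated."""
    out = []
    for s in segments:
        if s.mean_log2 > thresholds.upper:
            cn = 3
        elif s.mean_log2 < thresholds.lower:
            cn = 1
        else:
            cn = 2
        out.append(
            Segment(s.subject_id, s.chromosome, s.start, s.end, s.mean_log2, cn)
        )
    return out


def segments_to_probe_matrix(
    segments: Sequence[Segment], probe_map: ProbeMap, subjects: Sequence[str]
) -> np.ndarray:
    """Expand classified segments into a subjects x probes integer CN matrix.

    A probe at 1-based position x belongs to the 0-based half-open segment
    [start, end) iff start <= x-1 < end; probes covered by no segment are
    copy-neutral (CN 2). Overlapping segments for one subject/chromosome are
    a validation error naming the locus.
    """
    subjects = list(subjects)
    sub_index = {s: i for i, s in enumerate(subjects)}
    cn = np.full((len(subjects), probe_map.n_probes), 2, dtype=int)
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for s in segments:
        if s.cn_class is None:
            raise ValidationError("segments must be classified first")
        if s.subject_id not in sub_index:
            raise ValidationError(f"unknown subject {s.subject_id!r} in segments")
        by_key.setdefault((s.subject_id, s.chromosome), []).append(s)

    chrom_slices = dict(probe_map.chrom_blocks())
    for (subj, chrom), group in by_key.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments for subject {subj} on {chrom} "
                    f"at {b.start}"
                )
        sl = chrom_slices.get(chrom)
        if sl is None:
            continue
        pos0 = probe_map.positions[sl] - 1  # 0-based probe coordinates
        row = sub_index[subj]
        for s in group:
            lo = np.searchsorted(pos0, s.start, side="left")
            hi = np.searchsorted(pos0, s.end, side="left")
            cn[row, sl.start + lo : sl.start + hi] = s.cn_class
    return cn
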