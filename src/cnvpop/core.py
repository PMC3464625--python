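"""Domain types and text-format I/O shared by the whole pipeline.

Coordinate conventions
----------------------
SNP probes are 1-based point coordinates (the basepair position of the SNP).
All emitted genomic *regions* are 0-based half-open BED intervals: a region
spanning the probe range ``[i..j]`` has ``start = position(i) - 1`` and
``end = position(j)``, so a single-probe region has length 1 and BED files
round-trip bit-exactly.

Chromosome labels are opaque strings ("1" and "chr1" are distinct); probe
maps must be sorted by (chromosome, position) with strictly increasing
positions within each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ProbeMap",
    "IntensityMatrix",
    "RatioMatrix",
    "DosageMatrix",
    "MixtureModel",
    "Segment",
    "CNVRegion",
    "RelatednessPair",
    "read_probe_map",
    "read_matrix",
    "write_matrix",
    "read_segments",
    "write_segments",
    "write_regions",
    "read_regions",
    "round_half_up",
]

#: copy-number states modelled throughout the package
CN_STATES = np.array([1, 2, 3, 4])


def round_half_up(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer with halves away from the diploid tie.

    ``numpy.rint`` rounds halves to even, which would map a dosage of 2.5
    to 2 but 3.5 to 4; half-up keeps the carrier rule consistent.
    """
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic coordinates of array probes.

    The probe map is the spatial backbone of the pipeline: smoothing windows,
    merge gap rules and region boundaries are all expressed against it.
    """

    probe_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.probe_ids, dtype=object)
        chroms = np.asarray(self.chromosomes, dtype=object)
        pos = np.asarray(self.positions, dtype=np.int64)
        if not (len(ids) == len(chroms) == len(pos)):
            raise ValidationError("probe map columns have unequal lengths")
        if len(set(ids)) != len(ids):
            raise ValidationError("probe ids are not unique")
        # chromosomes must form contiguous blocks in sorted label order,
        # positions strictly increasing within each block
        order = np.lexsort((pos, chroms.astype(str)))
        if not np.array_equal(order, np.arange(len(ids))):
            raise ValidationError(
                "probe map is not sorted by (chromosome, position)"
            )
        for _, sl in _blocks(chroms):
            if np.any(np.diff(pos[sl]) <= 0):
                raise ValidationError(
                    "positions not strictly increasing within a chromosome"
                )
        object.__setattr__(self, "probe_ids", ids)
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "positions", pos)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def chrom_blocks(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, probe-index slice) pairs, in map order."""
        return _blocks(self.chromosomes)

    def subset(self, index: slice) -> "ProbeMap":
        return ProbeMap(
            self.probe_ids[index], self.chromosomes[index], self.positions[index]
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "chromosome": self.chromosomes,
                "position": self.positions,
            }
        ).to_csv(path, sep="\t", index=False)


def _blocks(labels: np.ndarray) -> list[tuple[str, slice]]:
    labels = np.asarray(labels, dtype=object)
    out: list[tuple[str, slice]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((str(labels[start]), slice(start, i)))
            start = i
    return out


def read_probe_map(path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    missing = {"probe_id", "chromosome", "position"} - set(df.columns)
    if missing:
        raise FormatError(f"probe map missing columns: {sorted(missing)}")
    return ProbeMap(
        df["probe_id"].to_numpy(dtype=object),
        df["chromosome"].to_numpy(dtype=object),
        df["position"].to_numpy(),
    )


@dataclass(frozen=True)
class IntensityMatrix:
    """Per-subject allele intensities plus reference-panel means.

    ``S_A``/``S_B`` are subjects x probes fluorescence intensities for the
    two SNP alleles; ``R_A``/``R_B`` are the per-probe reference-panel mean
    intensities. All values must be strictly positive so that log transforms
    are defined.
    """

    subjects: list
    batch: np.ndarray
    S_A: np.ndarray
    S_B: np.ndarray
    R_A: np.ndarray
    R_B: np.ndarray
    probe_map: ProbeMap

    def __post_init__(self) -> None:
        n, p = len(self.subjects), self.probe_map.n_probes
        for name in ("S_A", "S_B"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, p):
                raise ValidationError(f"{name} has shape {arr.shape}, want {(n, p)}")
            object.__setattr__(self, name, arr)
        for name in ("R_A", "R_B"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (p,):
                raise ValidationError(f"{name} has shape {arr.shape}, want {(p,)}")
            object.__setattr__(self, name, arr)
        if not all(
            np.all(np.asarray(getattr(self, f)) > 0)
            for f in ("S_A", "S_B", "R_A", "R_B")
        ):
            raise ValidationError("intensities must be strictly positive")
        if len(self.batch) != n:
            raise ValidationError("one batch label per subject required")


@dataclass(frozen=True)
class RatioMatrix:
    """Subjects x probes log2 copy-number ratios (~0 at two copies)."""

    subjects: list
    values: np.ndarray
    probe_map: ProbeMap
    smoothed: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.subjects), self.probe_map.n_probes):
            raise ValidationError(
                f"ratio matrix shape {vals.shape} does not match "
                f"{len(self.subjects)} subjects x {self.probe_map.n_probes} probes"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError("ratio matrix contains non-finite values")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class DosageMatrix:
    """Subjects x probes continuous expected copy number, bounded in [1, 4]."""

    subjects: list
    values: np.ndarray
    probe_map: ProbeMap
    posteriors: np.ndarray | None = None  # optional subjects x probes x 4

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.subjects), self.probe_map.n_probes):
            raise ValidationError("dosage matrix shape mismatch")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("dosage matrix contains non-finite values")
        if vals.size and (vals.min() < 1 - 1e-9 or vals.max() > 4 + 1e-9):
            raise ValidationError("dosages must lie in [1, 4]")
        object.__setattr__(self, "values", vals)
        if self.posteriors is not None:
            post = np.asarray(self.posteriors, dtype=float)
            if post.shape != vals.shape + (4,):
                raise ValidationError("posterior array shape mismatch")
            if not np.allclose(post.sum(axis=-1), 1.0, atol=1e-9):
                raise ValidationError("posteriors do not sum to 1")
            object.__setattr__(self, "posteriors", post)

    def rounded(self) -> np.ndarray:
        """Integer copy-number matrix (half-up rounding, clipped to [1, 4])."""
        return np.clip(round_half_up(self.values), 1, 4)


@dataclass(frozen=True)
class MixtureModel:
    """A fitted four-state constrained Gaussian mixture for one probe.

    Component means are pinned to ``c + log2(k/2)`` for copy-number states
    k in {1, 2, 3, 4}; only the global shift ``c`` is free, capturing a
    population whose mean copy number is not exactly two.
    """

    shift: float
    component_sds: np.ndarray
    weights: np.ndarray
    loglik: float
    converged: bool = True
    states: np.ndarray = field(default_factory=lambda: CN_STATES.copy())

    def __post_init__(self) -> None:
        sds = np.asarray(self.component_sds, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        k = len(self.states)
        if sds.shape != (k,) or w.shape != (k,):
            raise ValidationError("component parameter length mismatch")
        if np.any(sds <= 0):
            raise ValidationError("component sds must be positive")
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValidationError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "component_sds", sds)
        object.__setattr__(self, "weights", w)

    @property
    def component_means(self) -> np.ndarray:
        return self.shift + np.log2(np.asarray(self.states) / 2.0)


@dataclass
class Segment:
    """A per-subject chromosome segment with its mean log2 ratio.

    Coordinates are 0-based half-open; a probe at 1-based position x lies in
    the segment iff ``start <= x - 1 < end``.
    """

    subject_id: str
    chromosome: str
    start: int
    end: int
    mean_log2: float
    cn_class: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chromosome}:{self.start}-{self.end} has start >= end"
            )


@dataclass
class CNVRegion:
    """A consensus genomic interval with per-subject carrier information."""

    chromosome: str
    start: int
    end: int
    probe_indices: tuple[int, int]  # inclusive probe-index range in the map
    carriers: frozenset
    per_subject_value: np.ndarray
    klass: str | None = None  # CNP | CNVR | excluded | None (unclassified)
    n_subjects: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("region start must be < end")

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)

    @property
    def frequency(self) -> float:
        return self.carrier_count / self.n_subjects if self.n_subjects else 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RelatednessPair:
    subject_a: str
    subject_b: str
    label: str  # "related" | "unrelated"

    def __post_init__(self) -> None:
        if self.subject_a == self.subject_b:
            raise ValidationError("a relatedness pair needs two distinct subjects")
        if self.label not in ("related", "unrelated"):
            raise ValidationError(f"unknown pair label {self.label!r}")

    @property
    def key(self) -> frozenset:
        return frozenset((self.subject_a, self.subject_b))


# ---------------------------------------------------------------------------
# matrix I/O


def read_matrix(path, probe_map: ProbeMap, kind: str = "ratio"):
    """Read a subjects x probes TSV into a Ratio- or DosageMatrix.

    The first column holds subject ids; the header row must list probe ids
    in exactly the probe-map order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    header = [str(c) for c in df.columns]
    expected = [str(p) for p in probe_map.probe_ids]
    unknown = set(header) - set(expected)
    if unknown:
        raise FormatError(f"unknown probe id(s) in header: {sorted(unknown)[:5]}")
    if header != expected:
        raise FormatError("header probes do not match probe-map order")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        bad = df.map(lambda v: not _is_number(v))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at subject {df.index[r]!r}, probe {header[c]!r}"
        ) from None
    if np.any(~np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"missing/non-finite cell at subject {df.index[r]!r}, probe {header[c]!r}"
        )
    subjects = [str(s) for s in df.index]
    if kind == "ratio":
        return RatioMatrix(subjects, values, probe_map)
    if kind == "dosage":
        return DosageMatrix(subjects, values, probe_map)
    raise ValueError(f"unknown matrix kind {kind!r}")


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_matrix(matrix, path) -> None:
    pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.subjects, name="subject_id"),
        columns=matrix.probe_map.probe_ids,
    ).to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# segment I/O


def read_segments(path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "chromosome": str})
    missing = {"subject_id", "chromosome", "start", "end", "mean_log2"} - set(
        df.columns
    )
    if missing:
        raise FormatError(f"segment file missing columns: {sorted(missing)}")
    segs = [
        Segment(r.subject_id, r.chromosome, int(r.start), int(r.end), float(r.mean_log2))
        for r in df.itertuples()
    ]
    _check_segment_overlap(segs)
    return segs


def _check_segment_overlap(segments: Iterable[Segment]) -> None:
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for s in segments:
        by_key.setdefault((s.subject_id, s.chromosome), []).append(s)
    for (subj, chrom), group in by_key.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments for subject {subj} on {chrom} "
                    f"near {b.start}"
                )


def write_segments(segments: Sequence[Segment], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in segments],
            "chromosome": [s.chromosome for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "mean_log2": [s.mean_log2 for s in segments],
            "cn_class": [s.cn_class if s.cn_class is not None else "" for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# region I/O


def _validate_region_set(regions: Sequence[CNVRegion]) -> None:
    by_chrom: dict[str, list[CNVRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda r: r.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping regions on {chrom} near {b.start}"
                )


def write_regions(
    regions: Sequence[CNVRegion], bed_path, values_path=None, subjects=None
) -> None:
    """Write regions as BED plus an optional per-subject value side-car TSV.

    BED columns: chrom, start, end, name, carrier_count; coordinates are
    0-based half-open. The side-car TSV holds one row per subject and one
    column per region (mean dosage or integer CN over the region).
    """
    _validate_region_set(regions)
    ordered = sorted(regions, key=lambda r: (r.chromosome, r.start))
    with open(bed_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tcarrier_count\n")
        for i, r in enumerate(ordered):
            name = f"region_{i + 1}" + (f"_{r.klass}" if r.klass else "")
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{name}\t{r.carrier_count}\n")
    if values_path is not None:
        if subjects is None:
            raise ValidationError("subjects required to write per-subject values")
        cols = {
            f"{r.chromosome}:{r.start}-{r.end}": np.asarray(r.per_subject_value)
            for r in ordered
        }
        pd.DataFrame(cols, index=pd.Index(subjects, name="subject_id")).to_csv(
            values_path, sep="\t", float_format="%.10g"
        )


def read_regions(bed_path, values_path=None, n_subjects: int = 0) -> list[CNVRegion]:
    """Read a BED written by :func:`write_regions` back into CNVRegions.

    Carrier sets are not stored in BED; re-reading yields regions with empty
    carrier sets unless a per-subject side-car is supplied, in which case
    carriers are re-derived from rounded values != 2.
    """
    rows = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name, count = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), name, int(count)))
    values = None
    subjects: list = []
    if values_path is not None:
        vdf = pd.read_csv(values_path, sep="\t", index_col=0)
        subjects = [str(s) for s in vdf.index]
        values = vdf
    regions = []
    for chrom, start, end, _name, count in rows:
        col = f"{chrom}:{start}-{end}"
        if values is not None and col in values.columns:
            vals = values[col].to_numpy(dtype=float)
            carriers = frozenset(
                s
                for s, v in zip(subjects, np.clip(round_half_up(vals), 1, 4))
                if v != 2
            )
            region = CNVRegion(
                chrom, start, end, (-1, -1), carriers, vals,
                n_subjects=len(subjects),
            )
        else:
            region = CNVRegion(
                chrom, start, end, (-1, -1), frozenset(), np.empty(0),
                n_subjects=n_subjects,
            )
        regions.append(region)
    _validate_region_set(regions)
    return regions
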