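"""Log2 copy-number ratios from allele intensities, and genomic smoothing.

Three ratio variants are provided:

* ``cnr_total``   -- log2((S_A + S_B) / (R_A + R_B)), summing allele
  intensities before the log (robust to allelic noise);
* ``cnr_allelic`` -- log2(S_A/R_A) + log2(S_B/R_B), summing in log space
  (more sensitive to subtle allelic changes, also noisier);
* ``batch_median_ratio`` -- log2 of each subject's intensity over the median
  intensity of its processing batch, the batch-effect-aware variant used
  when no external reference panel is available.

Raw ratios are smoothed along physical position with a Loess filter over a
fixed-size probe window (default 41 probes, roughly 100 kb on a 500K array)
before mixture-model calling; the smoothing corrects short-range spatial
autocorrelation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ProbeMap, RatioMatrix
from .errors import DomainError, ValidationError

__all__ = [
    "SmoothingConfig",
    "cnr_total",
    "cnr_allelic",
    "batch_median_ratio",
    "loess_smooth",
    "ratios_from_intensities",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Loess window configuration.

    window_probes
        Total number of probes in each local window (odd, >= 3). Windows are
        selected by rank along the chromosome, not basepair distance, so the
        window always holds the same number of probes regardless of local
        probe density; at chromosome ends the window is asymmetric.
    degree
        Local polynomial degree (1 = local linear, the default).
    robust_iters
        Number of bisquare robustifying iterations (0 = plain Loess).
    """

    window_probes: int = 41
    degree: int = 1
    robust_iters: int = 0

    def __post_init__(self) -> None:
        if self.window_probes < 3 or self.window_probes % 2 == 0:
            raise ValidationError("window_probes must be odd and >= 3")
        if self.degree not in (0, 1, 2):
            raise ValidationError("degree must be 0, 1 or 2")
        if self.robust_iters < 0:
            raise ValidationError("robust_iters must be >= 0")


def _require_positive(*arrays) -> None:
    for arr in arrays:
        if np.any(np.asarray(arr, dtype=float) <= 0):
            raise DomainError("intensities must be strictly positive")


def cnr_total(S_A, S_B, R_A, R_B):
    """Total-intensity copy-number ratio: log2((S_A+S_B)/(R_A+R_B))."""
    _require_positive(S_A, S_B, R_A, R_B)
    S_A, S_B, R_A, R_B = (np.asarray(x, dtype=float) for x in (S_A, S_B, R_A, R_B))
    return np.log2((S_A + S_B) / (R_A + R_B))


def cnr_allelic(S_A, S_B, R_A, R_B):
    """Allelic copy-number ratio: log2(S_A/R_A) + log2(S_B/R_B)."""
    _require_positive(S_A, S_B, R_A, R_B)
    S_A, S_B, R_A, R_B = (np.asarray(x, dtype=float) for x in (S_A, S_B, R_A, R_B))
    return np.log2(S_A / R_A) + np.log2(S_B / R_B)


def ratios_from_intensities(intensities, mode: str = "total") -> RatioMatrix:
    """Apply one of the CN-ratio formulas to a full IntensityMatrix."""
    fn = {"total": cnr_total, "allelic": cnr_allelic}.get(mode)
    if fn is None:
        raise ValueError(f"unknown ratio mode {mode!r}")
    values = fn(
        intensities.S_A,
        intensities.S_B,
        intensities.R_A[None, :],
        intensities.R_B[None, :],
    )
    return RatioMatrix(intensities.subjects, values, intensities.probe_map)


def batch_median_ratio(
    intensity_total: np.ndarray, batch_labels, subjects, probe_map: ProbeMap
) -> RatioMatrix:
    """Per-batch median-reference log2 ratios.

    Cell (s, p) = log2(x_sp / median over subjects of batch(s) of x_.p).
    Every batch must contain at least two subjects; a singleton batch would
    make the subject its own reference and force its ratios to zero.
    """
    x = np.asarray(intensity_total, dtype=float)
    _require_positive(x)
    batch_labels = np.asarray(batch_labels, dtype=object)
    if x.shape[0] != len(batch_labels):
        raise ValidationError("one batch label per subject required")
    out = np.empty_like(x)
    for batch in dict.fromkeys(batch_labels):  # preserve first-seen order
        mask = batch_labels == batch
        if mask.sum() < 2:
            raise ValidationError(f"batch {batch!r} has fewer than 2 subjects")
        med = np.median(x[mask], axis=0)
        out[mask] = np.log2(x[mask] / med[None, :])
    return RatioMatrix(list(subjects), out, probe_map)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _smooth_chromosome(
    y: np.ndarray, x: np.ndarray, cfg: SmoothingConfig
) -> np.ndarray:
    """Loess-smooth a subjects x probes block for one chromosome.

    For each probe the window is the ``window_probes`` nearest probes by
    rank; tricube weights are computed from basepair distances within the
    window and a weighted polynomial is evaluated at the probe position.
    All subjects share the window and weight structure, so the local fit
    is solved for every subject at once.
    """
    n_sub, n = y.shape
    w_size = min(cfg.window_probes, n)
    half = w_size // 2
    out = np.empty_like(y)
    robust = np.ones_like(y)
    for _ in range(cfg.robust_iters + 1):
        for i in range(n):
            lo = min(max(i - half, 0), n - w_size)
            sl = slice(lo, lo + w_size)
            xs = x[sl].astype(float)
            d = np.abs(xs - x[i])
            dmax = d.max()
            w = _tricube(d / dmax) if dmax > 0 else np.ones_like(d)
            wrow = w[None, :] * robust[:, sl]  # n_sub x w
            ys = y[:, sl]
            if cfg.degree == 0:
                denom = wrow.sum(axis=1)
                denom[denom == 0] = 1.0
                out[:, i] = (wrow * ys).sum(axis=1) / denom
            else:
                # weighted polynomial fit centered at x_i, evaluated at 0
                xc = xs - x[i]
                cols = [np.ones_like(xc), xc] + (
                    [xc**2] if cfg.degree == 2 else []
                )
                X = np.stack(cols, axis=1)  # w x (deg+1)
                # normal equations per subject: (X' W X) b = X' W y
                XtW = X.T[None, :, :] * wrow[:, None, :]  # n_sub x (d+1) x w
                A = XtW @ X[None, :, :]
                b = (XtW @ ys[:, :, None])[:, :, 0]
                try:
                    beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
                except np.linalg.LinAlgError:
                    beta = np.linalg.lstsq(A[0], b.T, rcond=None)[0].T
                out[:, i] = beta[:, 0]
        if cfg.robust_iters:
            resid = y - out
            s = np.median(np.abs(resid), axis=1, keepdims=True)
            s[s == 0] = 1.0
            robust = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return out


def loess_smooth(
    ratios: RatioMatrix, config: SmoothingConfig | None = None
) -> RatioMatrix:
    """Smooth a ratio matrix along each chromosome independently.

    Smoothing is chromosome-local: probes on one chromosome never influence
    another. If a chromosome holds fewer probes than the window, the window
    shrinks to the chromosome size.
    """
    cfg = config or SmoothingConfig()
    pm = ratios.probe_map
    out = np.empty_like(ratios.values)
    for _, sl in pm.chrom_blocks():
        out[:, sl] = _smooth_chromosome(
            ratios.values[:, sl], pm.positions[sl], cfg
        )
    return RatioMatrix(ratios.subjects, out, pm, smoothed=True)
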