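"""Constrained four-state Gaussian mixture dosage calling.

At each probe, the smoothed log2 ratios of the whole population are modelled
as a mixture of four Gaussians, one per copy-number state (hemizygous
deletion, copy-neutral, one and two additional copies). The component means
are not free: they are pinned to the theoretical log2 spacing

    mu_k = c + log2(k / 2),   k in {1, 2, 3, 4}

with a single free shift ``c`` shared by all components, because the
population mean need not sit at exactly two copies while the *relative*
spacing of states on a log2 scale is fixed by arithmetic. Component
standard deviations and mixture weights are free (floored), and the
penalized likelihood is maximised with the derivative-free Nelder-Mead
simplex. Each subject's call is the posterior over the four states, and the
reported dosage is the probability-weighted copy number sum_k k * p_k — a
continuous value in [1, 4] that carries the calling uncertainty forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .core import CN_STATES, DosageMatrix, MixtureModel, RatioMatrix
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "GMMConfig",
    "fit_gmm",
    "posterior_probs",
    "expected_dosage",
    "call_matrix",
]

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


@dataclass(frozen=True)
class GMMConfig:
    """Tuning knobs for the per-probe mixture fit.

    weight_floor : minimum mixture weight per component.
    sd_floor     : minimum component standard deviation (log2 units); keeps
                   the likelihood bounded on degenerate (near-constant) data.
    shift_bounds : allowed range for the global mean shift c (log2 units).
    max_iter     : Nelder-Mead iteration cap.
    tol          : absolute log-likelihood convergence tolerance.
    tie_sds      : fit one shared sigma for all components instead of four.
    states       : modelled copy-number states; {1,2,3,4} by default (no
                   homozygous-deletion component, which is rare enough on
                   population data that it is left as an extension).
    """

    weight_floor: float = 1e-4
    sd_floor: float = 0.01
    shift_bounds: tuple[float, float] = (-0.5, 0.5)
    max_iter: int = 2000
    tol: float = 1e-8
    seed: int | None = None
    tie_sds: bool = False
    min_values: int = 20
    init_weights: tuple[float, ...] = (0.02, 0.94, 0.03, 0.01)
    states: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.weight_floor <= 0 or self.sd_floor <= 0:
            raise ValidationError("floors must be positive")
        lo, hi = self.shift_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValidationError("shift_bounds must be a finite (lo, hi) pair")
        if len(self.init_weights) != len(self.states):
            raise ValidationError("init_weights length must match states")


def _model_offsets(states) -> np.ndarray:
    return np.log2(np.asarray(states, dtype=float) / 2.0)


def _neg_loglik(theta, values, offsets, cfg: GMMConfig, n_sd: int):
    k = len(offsets)
    c = theta[0]
    sds = cfg.sd_floor + np.exp(np.minimum(theta[1 : 1 + n_sd], 50.0))
    if n_sd == 1:
        sds = np.broadcast_to(sds, (k,))
    logits = theta[1 + n_sd :]
    w = np.exp(logits - logits.max())
    w /= w.sum()
    w = np.maximum(w, cfg.weight_floor)
    w /= w.sum()
    means = c + offsets
    z = (values[:, None] - means) / sds
    z *= z
    comp = np.exp(-0.5 * z)
    comp *= w / sds
    dens = comp.sum(axis=1)
    # guard against underflow far in the tails
    ll = np.log(np.maximum(dens, 1e-300)).sum() - len(values) * _LOG_SQRT_2PI
    lo, hi = cfg.shift_bounds
    penalty = 0.0
    if c < lo:
        penalty = 1e6 * (lo - c) ** 2 * len(values)
    elif c > hi:
        penalty = 1e6 * (c - hi) ** 2 * len(values)
    return -ll + penalty


def _unpack(theta, cfg: GMMConfig, n_sd: int):
    k = len(cfg.states)
    c = float(np.clip(theta[0], *cfg.shift_bounds))
    sds = cfg.sd_floor + np.exp(np.minimum(theta[1 : 1 + n_sd], 50.0))
    if n_sd == 1:
        sds = np.repeat(sds, k)
    logits = theta[1 + n_sd :]
    logits = logits - logits.max()
    w = np.exp(logits)
    w /= w.sum()
    w = np.maximum(w, cfg.weight_floor)
    w /= w.sum()
    return c, sds, w


def fit_gmm(
    values,
    config: GMMConfig | None = None,
    warm_start: np.ndarray | None = None,
) -> MixtureModel:
    """Fit the constrained mixture to one probe's population of ratios.

    Parameters are (c, sigma_1..4, pi_1..4) with means pinned at
    c + log2(k/2). Weights are reparameterized through a softmax so they sum
    to one by construction; sds through ``floor + exp`` so floors hold; the
    shift is kept inside its bounds by a quadratic penalty. Optimisation is
    Nelder-Mead started from a diploid-dominant moment estimate; when a
    ``warm_start`` parameter vector is supplied (e.g. the previous probe's
    solution during a chromosome scan) the better-scoring start is used.
    """
    cfg = config or GMMConfig()
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < cfg.min_values:
        raise InsufficientDataError(
            f"need >= {cfg.min_values} finite values, got {len(values)}"
        )
    offsets = _model_offsets(cfg.states)
    n_sd = 1 if cfg.tie_sds else len(cfg.states)
    k = len(cfg.states)
    mad = np.median(np.abs(values - np.median(values))) * 1.4826
    sd0 = max(mad, cfg.sd_floor * 2)
    # moment-based start: the population is diploid-dominant, so the median
    # estimates the shift; assign values to the nearest pinned mean to seed
    # weights and per-component spreads
    c0 = float(np.clip(np.median(values), *cfg.shift_bounds))
    assign = np.argmin(np.abs(values[:, None] - (c0 + offsets)[None, :]), axis=1)
    counts = np.bincount(assign, minlength=k).astype(float)
    w0 = np.maximum(counts / counts.sum(), cfg.weight_floor)
    w0 = 0.5 * (w0 / w0.sum()) + 0.5 * np.asarray(cfg.init_weights, dtype=float)
    sds0 = np.empty(n_sd)
    if n_sd == 1:
        sds0[0] = sd0
    else:
        for j in range(k):
            grp = values[assign == j]
            sds0[j] = np.std(grp) if len(grp) >= 5 else sd0
        sds0 = np.clip(sds0, cfg.sd_floor * 1.5, None)
    theta0 = np.concatenate(
        [
            [c0],
            np.log(np.maximum(sds0 - cfg.sd_floor, 1e-6)),
            np.log(w0 / w0.sum()),
        ]
    )
    f0 = _neg_loglik(theta0, values, offsets, cfg, n_sd)
    warmed = False
    if warm_start is not None and len(warm_start) == len(theta0):
        f_warm = _neg_loglik(warm_start, values, offsets, cfg, n_sd)
        if f_warm < f0:
            theta0, f0, warmed = np.asarray(warm_start, dtype=float), f_warm, True
    options = {
        "maxiter": cfg.max_iter,
        "fatol": cfg.tol,
        "xatol": 1e-4,
        "maxfev": 10 * cfg.max_iter,
    }
    if warmed:
        # a tight simplex around a near-optimal start converges far faster
        # than scipy's default 5% vertex spread
        d = len(theta0)
        simplex = np.tile(theta0, (d + 1, 1))
        simplex[1:, :] += np.eye(d) * 0.02
        options["initial_simplex"] = simplex
    res = minimize(
        _neg_loglik,
        theta0,
        args=(values, offsets, cfg, n_sd),
        method="Nelder-Mead",
        options=options,
    )
    theta = res.x if res.fun <= f0 else theta0
    c, sds, w = _unpack(theta, cfg, n_sd)
    loglik = -_neg_loglik(theta, values, offsets, cfg, n_sd)
    model = MixtureModel(
        shift=c,
        component_sds=sds,
        weights=w,
        loglik=float(loglik),
        converged=bool(res.success),
        states=np.asarray(cfg.states),
    )
    object.__setattr__(model, "_theta", np.asarray(theta, dtype=float))
    return model


def posterior_probs(model: MixtureModel, value) -> np.ndarray:
    """Bayes posterior over copy-number states for one or more ratio values.

    Returns an array whose last axis has one probability per state and sums
    to one; finite for every finite input.
    """
    v = np.asarray(value, dtype=float)
    means = model.component_means
    sds = model.component_sds
    z = (v[..., None] - means) / sds
    log_post = np.log(model.weights) - np.log(sds) - 0.5 * z * z
    log_post = log_post - logsumexp(log_post, axis=-1, keepdims=True)
    return np.exp(log_post)


def expected_dosage(posterior, states=CN_STATES) -> float | np.ndarray:
    """Probability-weighted copy number: sum_k k * p_k over states {1..4}.

    The posterior must sum to one within 1e-6 along its last axis. A probe
    with posteriors (0.01, 0.09, 0.85, 0.05) therefore gets dosage 2.94.
    """
    p = np.asarray(posterior, dtype=float)
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValidationError("posterior probabilities must sum to 1")
    out = p @ np.asarray(states, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass
class QCReport:
    """Per-probe fitting diagnostics from :func:`call_matrix`."""

    failed_probes: list = field(default_factory=list)  # (probe_id, reason)
    unconverged_probes: list = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return len(self.failed_probes)

    def to_frame(self):
        import pandas as pd

        rows = [(p, "failed", r) for p, r in self.failed_probes] + [
            (p, "unconverged", "") for p in self.unconverged_probes
        ]
        return pd.DataFrame(rows, columns=["probe_id", "status", "detail"])


def call_matrix(
    smoothed: RatioMatrix,
    config: GMMConfig | None = None,
    keep_posteriors: bool = False,
) -> tuple[DosageMatrix, QCReport]:
    """Fit the mixture probe-by-probe and emit the continuous dosage matrix.

    Probes whose fit fails (too few values) are set to the diploid dosage 2
    for every subject and listed in the QC report rather than aborting the
    whole matrix. The computation is deterministic for a fixed input.
    """
    cfg = config or GMMConfig()
    if not smoothed.smoothed:
        raise ValidationError("call_matrix expects a smoothed ratio matrix")
    n_sub, n_probes = smoothed.values.shape
    dosages = np.full((n_sub, n_probes), 2.0)
    posts = np.zeros((n_sub, n_probes, len(cfg.states))) if keep_posteriors else None
    if posts is not None:
        posts[:, :, list(cfg.states).index(2)] = 1.0
    qc = QCReport()
    for _, sl in smoothed.probe_map.chrom_blocks():
        warm = None  # warm starts never cross a chromosome boundary
        for j in range(sl.start, sl.stop):
            probe_id = smoothed.probe_map.probe_ids[j]
            try:
                model = fit_gmm(smoothed.values[:, j], cfg, warm_start=warm)
            except InsufficientDataError as exc:
                qc.failed_probes.append((probe_id, str(exc)))
                continue
            warm = getattr(model, "_theta", None)
            if not model.converged:
                qc.unconverged_probes.append(probe_id)
            p = posterior_probs(model, smoothed.values[:, j])
            dosages[:, j] = expected_dosage(p, model.states)
            if posts is not None:
                posts[:, j, :] = p
    matrix = DosageMatrix(
        smoothed.subjects, dosages, smoothed.probe_map, posteriors=posts
    )
    return matrix, qc
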