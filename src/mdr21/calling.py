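"""Classify segments into copy-number states {loss, neutral, gain}.

Two callers are provided. The threshold caller labels a segment by comparing
its mean log2 level against fixed cutoffs (default +-0.2, conventional for
aCGH). The mixture caller fits a 3-component Gaussian mixture over all
segment means of a cohort, weighted by probe counts, with components ordered
loss < neutral < gain, and assigns by maximum posterior; on a degenerate fit
it falls back to the threshold rule. Three states suffice here because the
downstream analysis only uses loss and gain frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .segmentation import Segment

logger = logging.getLogger(__name__)

__all__ = [
    "CallingParams",
    "call_segments_threshold",
    "call_segments_mixture",
    "STATES",
]

STATES = ("loss", "neutral", "gain")


@dataclass
class CallingParams:
    method: str = "threshold"  # or "mixture"
    loss_cut: float = -0.2
    gain_cut: float = 0.2
    em_max_iter: int = 200
    em_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.loss_cut < 0 < self.gain_cut):
            raise ValueError("need loss_cut < 0 < gain_cut")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be positive")
        if self.method not in ("threshold", "mixture"):
            raise ValueError(f"unknown calling method {self.method!r}")


def _threshold_state(mean_level: float, params: CallingParams) -> str:
    # boundary convention: cuts are inclusive (mean == loss_cut -> loss)
    if mean_level <= params.loss_cut:
        return "loss"
    if mean_level >= params.gain_cut:
        return "gain"
    return "neutral"


def call_segments_threshold(
    segments: list[Segment], params: CallingParams | None = None
) -> list[Segment]:
    """Assign states in place by the fixed-cutoff rule; returns the segments."""
    params = params or CallingParams()
    for seg in segments:
        seg.state = _threshold_state(seg.mean_level, params)
    return segments


def _weighted_em(
    x: np.ndarray, w: np.ndarray, params: CallingParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float]] | None:
    """Weighted 3-component Gaussian EM on segment means.

    Returns (means, sds, mixing weights, responsibilities, log-likelihoods)
    or None on a degenerate fit (component collapse / empty component).
    The neutral component is initialized at 0; flank components at data
    quantiles pushed away from zero.
    """
    lo = min(float(np.quantile(x, 0.1)), -0.3)
    hi = max(float(np.quantile(x, 0.9)), 0.3)
    mu = np.array([lo, 0.0, hi])
    var = np.full(3, max(float(np.var(x)), 1e-4))
    pi = np.array([0.25, 0.5, 0.25])
    wsum = float(w.sum())
    lls: list[float] = []
    resp = None
    for _ in range(params.em_max_iter):
        # E step: weighted log densities
        logp = (
            np.log(pi)[None, :]
            - 0.5 * np.log(2 * math.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(np.sum(w * lse))
        resp = np.exp(logp - lse[:, None])
        # M step with per-point weights w
        rw = resp * w[:, None]
        nk = rw.sum(axis=0)
        if np.any(nk < 1e-8):
            return None
        mu_new = (rw * x[:, None]).sum(axis=0) / nk
        var_new = (rw * (x[:, None] - mu_new[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var_new < 1e-10):
            return None
        pi_new = nk / wsum
        mu, var, pi = mu_new, var_new, pi_new
        if lls and ll - lls[-1] < params.em_tol:
            lls.append(ll)
            break
        lls.append(ll)
    if not (mu[0] < mu[1] < mu[2]):
        # components must separate into loss < neutral < gain
        return None
    return mu, np.sqrt(var), pi, resp, lls


def call_segments_mixture(
    per_sample: dict[str, list[Segment]], params: CallingParams | None = None
) -> dict[str, list[Segment]]:
    """Cohort-level mixture calling over probe-weighted segment means.

    All segments of all samples are pooled; assignment is argmax posterior
    with ties going to neutral. Falls back to threshold calling (logged) when
    fewer than 3 distinct means exist or the EM fit degenerates.
    """
    params = params or CallingParams()
    segs = [s for segs in per_sample.values() for s in segs]
    x = np.array([s.mean_level for s in segs], dtype=float)
    w = np.array([s.n_probes for s in segs], dtype=float)
    fit = None
    if len(np.unique(x)) >= 3:
        fit = _weighted_em(x, w, params)
    if fit is None:
        logger.info("mixture fit degenerate; falling back to threshold calling")
        for segs_ in per_sample.values():
            call_segments_threshold(segs_, params)
        return per_sample
    _, _, _, resp, _ = fit
    # argmax posterior, ties -> neutral (component 1)
    best = resp.argmax(axis=1)
    ties = resp[np.arange(len(x)), best] == resp[:, 1]
    best[ties] = 1
    for seg, comp in zip(segs, best):
        seg.state = STATES[int(comp)]
    return per_sample


def em_loglik_trace(per_sample: dict[str, list[Segment]],
                    params: CallingParams | None = None) -> list[float]:
    """Log-likelihood per EM iteration (empty when the fit is degenerate)."""
    params = params or CallingParams()
    segs = [s for segs in per_sample.values() for s in segs]
    x = np.array([s.mean_level for s in segs], dtype=float)
    w = np.array([s.n_probes for s in segs], dtype=float)
    if len(np.unique(x)) < 3:
        return []
    fit = _weighted_em(x, w, params)
    return fit[4] if fit is not None else []
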