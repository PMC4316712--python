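"""Circular binary segmentation (CBS) of one sample's ordered log2 ratios.

The change statistic for an arc (window) ``values[i:j]`` against its
complement is the standardized mean difference

    T(i, j) = |mean(arc) - mean(complement)| / (sigma * sqrt(1/k + 1/(n-k)))

with ``k = j - i`` and ``sigma`` the whole-series sample standard deviation
(ddof=1). Because sigma is constant across arcs it does not affect the argmax,
and it is invariant under permutation, so permutation p-values are identical
whether or not the statistic is normalized. On the circularized sequence every
arc is either a linear window or the complement of one, and T is symmetric
under complementation, so maximizing over linear windows covers all arcs.

Significance is assessed by a seeded permutation test; the recursion accepts
the maximal-T split when p <= alpha and recurses into the resulting two or
three parts. Admissible arcs have min_width <= k <= n - min_width and leave
every resulting part either empty or >= min_width probes, so emitted segments
never fall below min_width unless the whole series does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentationParams",
    "Segment",
    "max_t_statistic",
    "permutation_pvalue",
    "segment_profile",
    "segments_to_frame",
]


@dataclass
class SegmentationParams:
    """Tuning knobs of the CBS recursion.

    alpha: significance level for accepting a split.
    n_permutations: permutations per split test; p = (1 + c) / (1 + P).
    min_width: minimum arc (and segment) width in probes.
    seed: root seed; per-node seeds are derived from (seed, lo, hi) so the
        permutation stream of a node does not depend on sibling decisions.
    """

    alpha: float = 0.01
    n_permutations: int = 1000
    min_width: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


@dataclass
class Segment:
    """Contiguous run of (non-missing) probes with a homogeneous mean.

    Probe indices are half-open into the retained (non-missing) series;
    bp bounds snap to the retained probes' positions: start_bp is the first
    probe's position and end_bp the last probe's position + 1 (half-open).
    """

    start_index: int
    end_index: int
    start_bp: int
    end_bp: int
    mean_level: float
    n_probes: int
    state: str | None = field(default=None, compare=False)


def _invalid_starts(n: int, k: int, min_width: int) -> np.ndarray:
    """Window starts i (length k) leaving a nonempty part < min_width probes.

    A start i is invalid when 0 < i < min_width (left part too small) or
    0 < n - k - i < min_width (right part too small).
    """
    last = n - k
    left = np.arange(1, min(min_width, last + 1))
    right = np.arange(max(last - min_width + 1, 0), last)
    right = right[right > 0]
    return np.union1d(left, right)


def _best_arc_raw(values: np.ndarray, min_width: int):
    """Max over admissible arcs of the unnormalized statistic.

    Returns (raw, i, j) where raw = |sum(arc) - k*mean_all| / sqrt(k(n-k)/n);
    dividing by sigma gives T. Ties broken by smallest i, then smallest j.
    Returns None when no admissible arc exists.
    """
    n = len(values)
    if n < 2 * min_width:
        return None
    cs = np.concatenate(([0.0], np.cumsum(values)))
    total = cs[-1]
    best_raw, best_i, best_j = -math.inf, 0, 0
    for k in range(min_width, n - min_width + 1):
        windows = cs[k:] - cs[:-k]
        raw = np.abs(windows - k * total / n) / math.sqrt(k * (n - k) / n)
        raw[_invalid_starts(n, k, min_width)] = -math.inf
        pos = int(np.argmax(raw))  # first occurrence = smallest i
        r = raw[pos]
        if r > best_raw or (r == best_raw and pos < best_i):
            best_raw, best_i, best_j = r, pos, pos + k
    if not math.isfinite(best_raw):
        return None
    return best_raw, best_i, best_j


try:  # optional compiled kernel for the permutation inner loop
    from numba import njit as _njit

    @_njit(cache=False)
    def _kernel_perm_max(perm, min_width, inv):  # pragma: no cover - compiled
        P, n = perm.shape
        out = np.empty(P)
        z = np.empty(n + 1)
        for p in range(P):
            tot = 0.0
            for t in range(n):
                tot += perm[p, t]
            mean = tot / n
            z[0] = 0.0
            acc = 0.0
            for t in range(n):
                acc += perm[p, t] - mean
                z[t + 1] = acc
            best = 0.0
            for k in range(min_width, n - min_width + 1):
                last = n - k
                m = abs(z[k] - z[0])  # i = 0
                d = abs(z[n] - z[last])  # i = last (window ends at n)
                if d > m:
                    m = d
                for i in range(min_width, last - min_width + 1):
                    d = abs(z[i + k] - z[i])
                    if d > m:
                        m = d
                v = m * inv[k]
                if v > best:
                    best = v
            out[p] = best
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _perm_max_raw(perm: np.ndarray, min_width: int) -> np.ndarray:
    """Per-row max of the unnormalized arc statistic; perm is (P, n).

    Dispatches to the compiled kernel when numba is available; the pure
    numpy path below is the reference implementation.
    """
    P, n = perm.shape
    if _HAVE_NUMBA:
        k = np.arange(n + 1, dtype=float)
        with np.errstate(divide="ignore"):
            inv = 1.0 / np.sqrt(k * (n - k) / n)
        return _kernel_perm_max(np.ascontiguousarray(perm), min_width, inv)
    return _perm_max_raw_numpy(perm, min_width)


def _perm_max_raw_numpy(perm: np.ndarray, min_width: int) -> np.ndarray:
    P, n = perm.shape
    cs = np.concatenate((np.zeros((P, 1)), np.cumsum(perm, axis=1)), axis=1)
    total = cs[:, -1:]
    best = np.full(P, -math.inf)
    for k in range(min_width, n - min_width + 1):
        windows = cs[:, k:] - cs[:, :-k]
        raw = np.abs(windows - k * total / n) / math.sqrt(k * (n - k) / n)
        inv = _invalid_starts(n, k, min_width)
        if inv.size:
            raw[:, inv] = -math.inf
        np.maximum(best, raw.max(axis=1), out=best)
    return best


def max_t_statistic(
    values: np.ndarray, min_width: int = 3
) -> tuple[float, int, int]:
    """Maximal standardized arc statistic and its window ``values[i:j]``.

    Returns (T, i, j). Constant input (sigma == 0) yields T = 0 at the
    leftmost admissible arc; input shorter than 2*min_width yields the
    no-split signal (0.0, 0, n).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D series of length >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing values must be dropped before segmentation")
    n = len(values)
    if n < 2 * min_width:
        return 0.0, 0, n
    sigma = float(np.std(values, ddof=1))
    if sigma == 0.0 or np.all(values == values[0]):
        return 0.0, 0, min_width
    raw, i, j = _best_arc_raw(values, min_width)
    return raw / sigma, i, j


def permutation_pvalue(
    values: np.ndarray, t_observed: float, params: SegmentationParams
) -> float:
    """Exact permutation p-value (1 + #{T* >= T_obs}) / (1 + n_permutations)."""
    values = np.asarray(values, dtype=float)
    sigma = float(np.std(values, ddof=1))
    rng = np.random.default_rng(params.seed)
    if sigma == 0.0:
        return 1.0
    raw_obs = t_observed * sigma
    count = 0
    done = 0
    while done < params.n_permutations:
        batch = min(200, params.n_permutations - done)
        perm = rng.permuted(np.tile(values, (batch, 1)), axis=1)
        count += int(np.sum(_perm_max_raw(perm, params.min_width) >= raw_obs))
        done += batch
    return (1 + count) / (1 + params.n_permutations)


def _split_is_significant(
    values: np.ndarray, raw_obs: float, params: SegmentationParams, seed: int
) -> bool:
    """Permutation decision p <= alpha with early rejection.

    Draws the same permutation stream as the full test but stops as soon as
    the exceedance count c proves p = (1+c)/(1+P) > alpha; the accept/reject
    decision is identical to running all P permutations.
    """
    P = params.n_permutations
    # p <= alpha  <=>  c <= alpha*(1+P) - 1
    c_max = math.floor(params.alpha * (1 + P) - 1 + 1e-9)
    if c_max < 0:
        return False
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    for batch in _batch_schedule(P):
        perm = rng.permuted(np.tile(values, (batch, 1)), axis=1)
        count += int(np.sum(_perm_max_raw(perm, params.min_width) >= raw_obs))
        done += batch
        if count > c_max:
            return False
    return count <= c_max


def _batch_schedule(total: int):
    """Permutation batch sizes: small first so null nodes stop early."""
    done = 0
    size = 25
    while done < total:
        b = min(size, total - done)
        yield b
        done += b
        size = min(2 * size, 400)


def _node_seed(seed: int, lo: int, hi: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((seed, lo, hi))


def segment_profile(
    positions: np.ndarray,
    values: np.ndarray,
    params: SegmentationParams | None = None,
) -> list[Segment]:
    """Recursively segment one sample's series into homogeneous-mean segments.

    ``positions``/``values`` must be finite and position-sorted (drop missing
    probes first; see :func:`mdr21.pipeline.segment_sample` for the NaN-aware
    wrapper). Returns sorted, contiguous segments covering every probe.
    """
    if params is None:
        params = SegmentationParams()
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    if len(positions) != len(values):
        raise ValueError("positions and values must have equal length")
    if len(values) == 0:
        return []
    if not np.all(np.isfinite(values)):
        raise ValueError("drop missing values before segmentation")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")

    boundaries: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        sub = values[lo:hi]
        n = hi - lo
        if n < 2 * params.min_width:
            boundaries.append((lo, hi))
            return
        sigma = float(np.std(sub, ddof=1))
        if sigma == 0.0 or np.all(sub == sub[0]):
            boundaries.append((lo, hi))
            return
        raw, i, j = _best_arc_raw(sub, params.min_width)
        if raw <= 0.0:
            boundaries.append((lo, hi))
            return
        seed = _node_seed(params.seed, lo, hi)
        if not _split_is_significant(sub, raw, params, seed):
            boundaries.append((lo, hi))
            return
        for a, b in ((0, i), (i, j), (j, n)):
            if b > a:
                recurse(lo + a, lo + b)

    recurse(0, len(values))
    boundaries.sort()
    return [
        Segment(
            start_index=a,
            end_index=b,
            start_bp=int(positions[a]),
            end_bp=int(positions[b - 1]) + 1,
            mean_level=float(np.mean(values[a:b])),
            n_probes=b - a,
        )
        for a, b in boundaries
    ]


def segments_to_frame(per_sample: dict[str, list[Segment]], chrom: str):
    """Flatten {sample_id: [Segment]} into a tidy table for TSV export."""
    import pandas as pd

    rows = []
    for sample_id, segs in per_sample.items():
        for s in segs:
            rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": chrom,
                    "start": s.start_bp,
                    "end": s.end_bp,
                    "start_index": s.start_index,
                    "end_index": s.end_index,
                    "n_probes": s.n_probes,
                    "mean_level": s.mean_level,
                    "state": s.state,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chrom", "start", "end", "start_index",
            "end_index", "n_probes", "mean_level", "state",
        ],
    )
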