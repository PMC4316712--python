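"""Project per-platform segment calls onto one fixed anchor grid.

Heterogeneous aCGH platforms (BAC arrays with ~100 kb probe spacing, oligo
arrays with ~30-50 kb) cannot be compared probe-by-probe. The cross-platform
device is a fixed grid of anchor positions along the chromosome (default
5000): each sample's discrete calls are projected onto the anchors, giving a
samples x anchors state matrix per cohort from which per-anchor deletion and
amplification frequencies follow.

An anchor takes the state of the segment containing it; if no segment covers
it (probe deserts, dropped probes), the nearest segment within ``max_gap`` bp
is used (ties to the left segment), otherwise the anchor is missing for that
sample. Frequencies use only informative (non-missing) samples per anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import Segment

__all__ = [
    "AnchorGrid",
    "AnchorCallMatrix",
    "FrequencyProfile",
    "LOSS", "NEUTRAL", "GAIN", "MISSING",
    "build_anchor_grid",
    "project_calls_to_anchors",
    "compute_frequencies",
    "combine_profiles_median",
    "profile_to_frame",
]

LOSS, NEUTRAL, GAIN, MISSING = -1, 0, 1, -9
_STATE_CODE = {"loss": LOSS, "neutral": NEUTRAL, "gain": GAIN}


@dataclass
class AnchorGrid:
    """Fixed anchor positions; anchor k sits at floor((k+0.5)*L/n)."""

    chrom: str
    chrom_length: int
    positions: np.ndarray

    @property
    def n_anchors(self) -> int:
        return len(self.positions)

    @property
    def spacing(self) -> float:
        return self.chrom_length / self.n_anchors


@dataclass
class AnchorCallMatrix:
    """samples x anchors int8 states in {LOSS, NEUTRAL, GAIN, MISSING}."""

    grid: AnchorGrid
    sample_ids: list[str]
    states: np.ndarray
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.sample_ids), self.grid.n_anchors):
            raise ValueError("state matrix shape must be samples x anchors")


@dataclass
class FrequencyProfile:
    """Per-anchor deletion/amplification fractions for one cohort.

    Anchors with no informative sample carry NaN frequencies.
    """

    grid: AnchorGrid
    cohort: str
    del_freq: np.ndarray
    amp_freq: np.ndarray
    n_informative: np.ndarray = field(default=None)


def build_anchor_grid(
    chrom_length: int, n_anchors: int = 5000, chrom: str = "chr21"
) -> AnchorGrid:
    """Evenly spaced midpoint grid: anchor k at floor((k+0.5)*L/n)."""
    if n_anchors < 1 or chrom_length <= n_anchors:
        raise ValueError("need n_anchors >= 1 and chrom_length > n_anchors")
    k = np.arange(n_anchors)
    positions = ((k + 0.5) * chrom_length // n_anchors).astype(np.int64)
    return AnchorGrid(chrom=chrom, chrom_length=chrom_length, positions=positions)


def _project_one(
    segments: list[Segment], anchors: np.ndarray, max_gap: float | None
) -> np.ndarray:
    """Project one sample's sorted, disjoint segments onto anchor positions."""
    out = np.full(len(anchors), MISSING, dtype=np.int8)
    if not segments:
        return out
    starts = np.array([s.start_bp for s in segments])
    ends = np.array([s.end_bp for s in segments])
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("overlapping segments violate the partition invariant")
    codes = np.array([_STATE_CODE[s.state] for s in segments], dtype=np.int8)
    # idx = number of segment starts <= anchor; candidate containing segment
    idx = np.searchsorted(starts, anchors, side="right") - 1
    inside = (idx >= 0) & (anchors < ends[np.clip(idx, 0, None)])
    out[inside] = codes[idx[inside]]
    # uncovered anchors: nearest segment within max_gap, ties to the left
    unc = ~inside
    if np.any(unc):
        a = anchors[unc]
        left = np.clip(idx[unc], 0, len(segments) - 1)
        right = np.clip(idx[unc] + 1, 0, len(segments) - 1)
        # distance to left segment's end (anchor right of it) and to right
        # segment's start; half-open ends make the last covered bp end-1
        d_left = np.where(idx[unc] >= 0, a - (ends[left] - 1), np.inf)
        d_right = np.where(idx[unc] + 1 < len(segments), starts[right] - a, np.inf)
        pick_left = d_left <= d_right  # tie -> left
        dist = np.where(pick_left, d_left, d_right)
        chosen = np.where(pick_left, left, right)
        ok = np.isfinite(dist)
        if max_gap is not None:
            ok &= dist <= max_gap
        tgt = np.flatnonzero(unc)[ok]
        out[tgt] = codes[chosen[ok]]
    return out


def project_calls_to_anchors(
    per_sample: dict[str, list[Segment]],
    grid: AnchorGrid,
    max_gap: float | None = None,
    cohort: str = "",
) -> AnchorCallMatrix:
    """Build the samples x anchors state matrix for one cohort.

    ``max_gap=None`` places no distance limit on the nearest-segment fallback.
    Segments must carry states (run a caller first).
    """
    sample_ids = list(per_sample)
    states = np.full((len(sample_ids), grid.n_anchors), MISSING, dtype=np.int8)
    for i, sid in enumerate(sample_ids):
        states[i] = _project_one(per_sample[sid], grid.positions, max_gap)
    return AnchorCallMatrix(grid=grid, sample_ids=sample_ids, states=states,
                            cohort=cohort)


def compute_frequencies(matrix: AnchorCallMatrix) -> FrequencyProfile:
    """Per-anchor deletion/amplification fractions over informative samples."""
    if not matrix.sample_ids:
        raise ValueError("need at least one sample")
    informative = matrix.states != MISSING
    n_inf = informative.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        del_freq = (matrix.states == LOSS).sum(axis=0) / n_inf
        amp_freq = (matrix.states == GAIN).sum(axis=0) / n_inf
    del_freq[n_inf == 0] = np.nan
    amp_freq[n_inf == 0] = np.nan
    return FrequencyProfile(
        grid=matrix.grid, cohort=matrix.cohort,
        del_freq=del_freq, amp_freq=amp_freq, n_informative=n_inf,
    )


def combine_profiles_median(profiles: list[FrequencyProfile]) -> FrequencyProfile:
    """Cross-cohort summary: per-anchor median of cohort frequencies.

    Cohorts with a missing (NaN) value at an anchor are excluded from that
    anchor's median.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if p.grid.n_anchors != grid.n_anchors or not np.array_equal(
            p.grid.positions, grid.positions
        ):
            raise ValueError("profiles must share one anchor grid")
    dels = np.vstack([p.del_freq for p in profiles])
    amps = np.vstack([p.amp_freq for p in profiles])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN anchors
        dmed = np.nanmedian(dels, axis=0)
        amed = np.nanmedian(amps, axis=0)
    n_inf = np.sum(~np.isnan(dels), axis=0)
    return FrequencyProfile(
        grid=grid, cohort="median", del_freq=dmed, amp_freq=amed,
        n_informative=n_inf,
    )


def profile_to_frame(profile: FrequencyProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "anchor_index": np.arange(profile.grid.n_anchors),
            "position": profile.grid.positions,
            "del_freq": profile.del_freq,
            "amp_freq": profile.amp_freq,
            "n_informative": profile.n_informative,
            "cohort": profile.cohort,
        }
    )
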