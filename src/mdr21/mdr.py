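"""Detect maximum-frequency deletion regions (MDRs) from frequency profiles.

A region is seeded per cohort as a maximal run of anchors whose deletion
frequency reaches ``f_min``, bridging interior gaps of up to
``max_gap_anchors`` consecutive sub-threshold anchors and discarding runs
with fewer than ``min_anchors`` qualifying anchors. Runs are then unioned
across cohorts and overlapping runs merged; this cross-cohort union is what
lets a region private to one small cohort (a Wilms-only deletion) coexist
with regions shared by several cohorts. Region bp bounds extend half an
anchor spacing beyond the first/last anchor.

Per-region, per-cohort frequencies are summarized at the sample level: a
sample counts as deleted in a region when at least ``sample_fraction`` of its
informative anchors inside the region are loss calls.

The detection rule, thresholds, and the sample-level summarization are
reconstruction choices (config-exposed); symmetric amplification-region
detection is available via ``direction="amp"`` but untuned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonization import LOSS, MISSING, AnchorCallMatrix, FrequencyProfile

__all__ = ["MdrParams", "MDRegion", "detect_regions",
           "summarize_region_frequencies", "regions_to_frame"]


@dataclass
class MdrParams:
    f_min: float = 0.25
    max_gap_anchors: int = 5
    min_anchors: int = 3
    sample_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.f_min <= 1:
            raise ValueError("f_min must be in (0, 1]")
        if self.max_gap_anchors < 0 or self.min_anchors < 0:
            raise ValueError("gap/min sizes must be >= 0")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


@dataclass
class MDRegion:
    """Contiguous high-deletion-frequency interval on the anchor grid."""

    chrom: str
    start_bp: int
    end_bp: int
    first_anchor: int
    last_anchor: int  # inclusive
    peak_del_freq: float
    name: str = ""
    per_cohort_freq: dict[str, float] = field(default_factory=dict)

    @property
    def n_anchors(self) -> int:
        return self.last_anchor - self.first_anchor + 1


def _runs_above(freq: np.ndarray, params: MdrParams) -> list[tuple[int, int]]:
    """Maximal [first, last] anchor-index runs with freq >= f_min.

    NaN counts as below threshold. Runs separated by <= max_gap_anchors
    sub-threshold anchors are bridged; runs with fewer than min_anchors
    qualifying anchors are dropped.
    """
    above = np.flatnonzero(np.nan_to_num(freq, nan=0.0) >= params.f_min)
    if above.size == 0:
        return []
    runs: list[tuple[int, int, int]] = []  # first, last, n_qualifying
    first = last = int(above[0])
    count = 1
    for a in above[1:]:
        a = int(a)
        if a - last - 1 <= params.max_gap_anchors:
            last = a
            count += 1
        else:
            runs.append((first, last, count))
            first = last = a
            count = 1
    runs.append((first, last, count))
    return [(f, l) for f, l, c in runs if c >= params.min_anchors]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent inclusive index intervals."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for f, l in intervals[1:]:
        if f <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], l)
        else:
            merged.append([f, l])
    return [tuple(m) for m in merged]


def detect_regions(
    profiles: list[FrequencyProfile],
    params: MdrParams | None = None,
    direction: str = "del",
) -> list[MDRegion]:
    """Union of per-cohort high-frequency runs, merged into sorted regions."""
    params = params or MdrParams()
    if not profiles:
        return []
    grid = profiles[0].grid
    for p in profiles[1:]:
        if not np.array_equal(p.grid.positions, grid.positions):
            raise ValueError("profiles must share one anchor grid")
    freqs = {
        p.cohort: (p.del_freq if direction == "del" else p.amp_freq)
        for p in profiles
    }
    runs: list[tuple[int, int]] = []
    for f in freqs.values():
        runs.extend(_runs_above(f, params))
    half = grid.spacing / 2.0
    regions = []
    for k, (first, last) in enumerate(_merge(runs)):
        block = np.vstack([f[first:last + 1] for f in freqs.values()])
        peak = float(np.nanmax(block))
        regions.append(
            MDRegion(
                chrom=grid.chrom,
                start_bp=max(int(grid.positions[first] - half), 0),
                end_bp=min(int(grid.positions[last] + half),
                           grid.chrom_length),
                first_anchor=first,
                last_anchor=last,
                peak_del_freq=peak,
                name=f"MDR{k + 1}",
            )
        )
    return regions


def summarize_region_frequencies(
    region: MDRegion,
    matrices: dict[str, AnchorCallMatrix],
    sample_fraction: float = 0.5,
) -> dict[str, float]:
    """Sample-level deletion frequency of the region per cohort.

    A sample is deleted when >= sample_fraction of its informative anchors
    inside the region are loss; the denominator counts samples with at least
    one informative anchor there. Cohorts with no informative anchor in the
    region get no entry.
    """
    out: dict[str, float] = {}
    sl = slice(region.first_anchor, region.last_anchor + 1)
    for cohort, mat in matrices.items():
        block = mat.states[:, sl]
        informative = (block != MISSING).sum(axis=1)
        loss = (block == LOSS).sum(axis=1)
        has_info = informative > 0
        if not np.any(has_info):
            continue
        deleted = np.zeros(len(informative), dtype=bool)
        deleted[has_info] = (
            loss[has_info] / informative[has_info] >= sample_fraction
        )
        out[cohort] = float(deleted.sum() / has_info.sum())
    region.per_cohort_freq = out
    return out


def regions_to_frame(regions: list[MDRegion]) -> pd.DataFrame:
    """Machine-readable region table with one column per cohort frequency."""
    cohorts = sorted({c for r in regions for c in r.per_cohort_freq})
    rows = []
    for r in regions:
        row = {
            "region": r.name,
            "chrom": r.chrom,
            "start": r.start_bp,
            "end": r.end_bp,
            "first_anchor": r.first_anchor,
            "last_anchor": r.last_anchor,
            "n_anchors": r.n_anchors,
            "peak_del_freq": r.peak_del_freq,
        }
        for c in cohorts:
            row[f"del_freq_{c}"] = r.per_cohort_freq.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
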