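"""Readers and writers for the plain-text formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; human-readable reports
convert to 1-based inclusive only at the printing boundary
(:func:`format_region_1based`). Probe matrices are tab-delimited with a fixed
dialect (no quoting, '.' decimal): columns ``probe_id, chrom, start, end``
followed by one column per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeMatrix",
    "GenomicInterval",
    "FormatError",
    "read_probe_matrix",
    "write_probe_matrix",
    "read_gene_annotation",
    "write_gene_annotation",
    "write_regions_bed",
    "read_regions_bed",
    "read_gmt",
    "format_region_1based",
]


class FormatError(ValueError):
    """Malformed input file (message carries the offending line where known)."""


@dataclass
class GenomicInterval:
    """0-based half-open genomic interval with an optional name/strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.name}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        """Half-open overlap: at least 1 bp shared."""
        return self.start < end and start < self.end


@dataclass
class ProbeMatrix:
    """Probe-level log2 ratios for one chromosome across samples.

    ``values`` has shape (n_probes, n_samples); NaN marks missing cells.
    Probes are kept sorted by start position and probe ids are unique.
    """

    chrom: str
    probe_id: np.ndarray
    start: np.ndarray
    end: np.ndarray
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.probe_id)
        if not (len(self.start) == len(self.end) == self.values.shape[0] == n):
            raise ValueError("probe arrays and value rows must have equal length")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError("value columns must match sample_ids")
        if np.any(self.start >= self.end):
            bad = int(np.argmax(self.start >= self.end))
            raise ValueError(f"probe {self.probe_id[bad]}: start >= end")
        ids, counts = np.unique(self.probe_id, return_counts=True)
        if np.any(counts > 1):
            raise FormatError(f"duplicate probe_id: {ids[counts > 1][0]}")
        order = np.argsort(self.start, kind="stable")
        self.probe_id = np.asarray(self.probe_id)[order]
        self.start = np.asarray(self.start)[order]
        self.end = np.asarray(self.end)[order]
        self.values = np.asarray(self.values, dtype=float)[order]

    @property
    def n_probes(self) -> int:
        return len(self.probe_id)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_series(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, values) for one sample; missing cells stay NaN.

        The probe start position is used as the probe's genomic location.
        """
        j = self.sample_ids.index(sample)
        return self.start.copy(), self.values[:, j].copy()


def read_probe_matrix(path: str | Path) -> ProbeMatrix:
    """Read a tab-delimited probe matrix (see module docstring for layout).

    Non-numeric sample cells become NaN; the per-file missing fraction is
    logged. Probes are sorted by position on load.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    required = ["probe_id", "chrom", "start", "end"]
    if list(frame.columns[:4]) != required:
        raise FormatError(
            f"{path}: first four columns must be {required}, got "
            f"{list(frame.columns[:4])}"
        )
    sample_ids = list(frame.columns[4:])
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns")
    chroms = frame["chrom"].unique()
    if len(chroms) != 1:
        raise FormatError(f"{path}: expected a single chromosome, got {list(chroms)}")
    values = frame[sample_ids].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info(
            "%s: %d missing value(s) (%.3f%% of cells)",
            path.name, n_missing, 100.0 * n_missing / values.size,
        )
    return ProbeMatrix(
        chrom=str(chroms[0]),
        probe_id=frame["probe_id"].to_numpy(str),
        start=frame["start"].astype(int).to_numpy(),
        end=frame["end"].astype(int).to_numpy(),
        values=values,
        sample_ids=sample_ids,
    )


def write_probe_matrix(pm: ProbeMatrix, path: str | Path) -> None:
    """Write a probe matrix in the canonical tab-delimited layout.

    Floats are printed at 6 significant digits, so write→read round-trips are
    exact only to that precision.
    """
    meta = pd.DataFrame(
        {"probe_id": pm.probe_id, "chrom": pm.chrom, "start": pm.start, "end": pm.end}
    )
    vals = pd.DataFrame(pm.values, columns=pm.sample_ids)
    frame = pd.concat([meta, vals], axis=1)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_gene_annotation(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ annotation (name in column 4, strand in column 6).

    Lines with ``start >= end`` or non-integer coordinates are rejected with
    their line number; the result is sorted by (chrom, start).
    """
    intervals: list[GenomicInterval] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                errors.append(f"line {lineno}: fewer than 3 columns")
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            if start >= end:
                errors.append(f"line {lineno}: start {start} >= end {end}")
                continue
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else None
            intervals.append(GenomicInterval(parts[0], start, end, name, strand))
    if errors:
        raise FormatError("; ".join(errors))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    return intervals


def write_gene_annotation(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name]
            if iv.strand is not None:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def write_regions_bed(regions, path: str | Path) -> None:
    """Write detected regions as BED6; score = round(1000 * peak deletion freq).

    ``regions`` is a sequence of :class:`mdr21.mdr.MDRegion`. Ordering is
    deterministic: by (chrom, start).
    """
    rows = sorted(regions, key=lambda r: (r.chrom, r.start_bp))
    with open(path, "w") as fh:
        for k, r in enumerate(rows):
            score = int(round(1000 * r.peak_del_freq))
            fh.write(
                f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{r.name or f'MDR{k + 1}'}"
                f"\t{score}\t.\n"
            )


def read_regions_bed(path: str | Path) -> list[GenomicInterval]:
    """Read back a regions BED as plain intervals (round-trip checks)."""
    return read_gene_annotation(path)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: GMT needs name, description, members")
            sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


def format_region_1based(chrom: str, start: int, end: int) -> str:
    """Render a 0-based half-open interval as a 1-based inclusive report string."""
    return f"{chrom}:{start + 1:,}–{end:,}"
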