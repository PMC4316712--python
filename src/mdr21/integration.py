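"""Candidate selection: intersect deletion regions with annotations, apply
the downregulation rule, and test gene-set over-representation.

A feature is a candidate when it lies inside a detected deletion region AND
is downregulated (negative effect, q below the cutoff) in at least
``min_datasets`` of the expression datasets of its own class — gene features
are only ever checked against gene-expression datasets and miRNA features
against miRNA datasets, never mixed.

Over-representation uses the upper-tail hypergeometric test: with a universe
of M features, a set of K and a query of N drawn features overlapping in k,
p = P(X >= k), X ~ Hypergeom(M, K, N), BH-corrected across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .de import bh_fdr
from .io import GenomicInterval
from .mdr import MDRegion

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateCall",
    "GeneSetCollection",
    "intersect_genes",
    "select_candidates",
    "hypergeometric_ora",
    "candidates_to_frame",
]


@dataclass
class CandidateCall:
    feature_id: str
    region: str
    datasets_down: list[str]
    is_candidate: bool


@dataclass
class GeneSetCollection:
    """Named feature sets over a fixed universe (e.g. pathway gene lists)."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"set {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def intersect_genes(
    regions: list[MDRegion], annotation: list[GenomicInterval]
) -> dict[str, list[str]]:
    """Map region name -> feature names overlapping it by >= 1 bp.

    Intervals are 0-based half-open on both sides; a feature may appear in
    several regions. Output lists preserve annotation (positional) order.
    """
    for iv in annotation:
        if iv.start >= iv.end:
            raise ValueError(f"negative-width interval {iv.name}")
    tree = IntervalTree()
    for iv in annotation:
        tree[iv.start:iv.end] = iv.name
    out: dict[str, list[str]] = {}
    for region in regions:
        if region.start_bp >= region.end_bp:
            raise ValueError(f"negative-width region {region.name}")
        hits = tree[region.start_bp:region.end_bp]
        out[region.name] = [h.data for h in sorted(hits)]
    return out


def select_candidates(
    region_features: dict[str, list[str]],
    de_results: dict[str, pd.DataFrame],
    min_datasets: int = 2,
    q_cut: float = 0.05,
) -> list[CandidateCall]:
    """Apply the candidate rule to every feature found in a region.

    ``de_results`` maps dataset label -> DE table (feature_id, effect, q) and
    must contain only datasets of the feature class under scrutiny (run once
    for genes, once for miRNAs). A feature absent from a dataset contributes
    neither up nor down there (logged at debug level). Output is sorted by
    region then feature id; the deterministic rule makes the result invariant
    under dataset reordering.
    """
    down_by_dataset: dict[str, set[str]] = {}
    known: dict[str, set[str]] = {}
    for label in sorted(de_results):
        table = de_results[label]
        mask = (table["effect"] < 0) & (table["q"] < q_cut)
        down_by_dataset[label] = set(table.loc[mask, "feature_id"])
        known[label] = set(table["feature_id"])
    calls: list[CandidateCall] = []
    for region in sorted(region_features):
        for feature in sorted(set(region_features[region])):
            datasets_down = [
                label for label in sorted(de_results)
                if feature in down_by_dataset[label]
            ]
            missing = [l for l in de_results if feature not in known[l]]
            if missing:
                logger.debug(
                    "feature %s absent from dataset(s) %s", feature, missing
                )
            calls.append(
                CandidateCall(
                    feature_id=feature,
                    region=region,
                    datasets_down=datasets_down,
                    is_candidate=len(datasets_down) >= min_datasets,
                )
            )
    return calls


def hypergeometric_ora(
    query: set[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per set, BH across sets."""
    if not collection.universe:
        raise ValueError("empty universe")
    extra = query - collection.universe
    if extra:
        raise ValueError(f"query members outside the universe: {sorted(extra)[:5]}")
    M = len(collection.universe)
    N = len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "expected": K * N / M,
                "p": min(p, 1.0),
            }
        )
    frame = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                        "expected", "p"])
    frame["q"] = bh_fdr(frame["p"].to_numpy()) if len(frame) else []
    return frame


def candidates_to_frame(calls: list[CandidateCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": c.feature_id,
                "region": c.region,
                "datasets_down": ";".join(c.datasets_down),
                "n_datasets_down": len(c.datasets_down),
                "is_candidate": c.is_candidate,
            }
            for c in calls
        ],
        columns=["feature_id", "region", "datasets_down",
                 "n_datasets_down", "is_candidate"],
    )
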