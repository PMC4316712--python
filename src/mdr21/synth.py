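"""Synthetic multi-platform aCGH cohorts and expression datasets with known
planted truth.

The default scenario pack emulates the study conditions of the chromosome-21
deletion survey: four tumor cohorts (breast 359, lung 78, melanoma 34, Wilms
18 samples) on four array layouts with chromosome-21-scale probe densities
(two BAC-array-like layouts of ~500 probes, a 60K-oligo-like layout of ~900
and a 105K-oligo-like layout of ~1600), and three recurrent deletion regions
planted at the per-cohort carrier frequencies the real survey reports
(0.269 / 0.117 / 0.617 for the proximal region in lung / breast / melanoma,
0.5 for the mid-arm melanoma region, 0.5 for the narrow Wilms-only region).

Planted breakpoints sit on the probe-grid boundaries of the cohorts that
carry them, the usual convention in segmentation benchmarks: a breakpoint
strictly inside an inter-probe gap is unrecoverable below half the gap width
by any method, so placing breakpoints between probes would measure probe
spacing, not algorithm error. The Wilms-only region is ~391 kb (13 probes on
the 1600-probe layout); the matching real region is far narrower but falls
below the probe spacing of every layout here.

Noise is i.i.d. Gaussian per probe (no wave/GC artifacts); tumor impurity is
expressed only through the chosen shift magnitude (-0.8 rather than the
pure-tumor -1.0 for a heterozygous loss). When planted lesions overlap, the
later lesion in list order overrides the shift on the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonization import AnchorGrid
from .io import GenomicInterval, ProbeMatrix

__all__ = [
    "CHR21_LENGTH",
    "PlatformLayout",
    "PlantedLesion",
    "CohortScenario",
    "TruthTable",
    "make_platform_layout",
    "simulate_cn_cohort",
    "simulate_expression_dataset",
    "simulate_mirna_dataset",
    "make_feature_annotation",
    "default_scenario_pack",
    "default_lesions",
    "default_expression_pack",
    "default_mirna_pack",
    "default_gene_sets",
    "expected_candidates",
    "derive_seed",
]

# hg19 chromosome-21 length; a config constant, not wired into any logic
CHR21_LENGTH = 48_129_895


def derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed < 2**31 from a root seed and arbitrary labels."""
    import hashlib

    h = hashlib.blake2b(repr((seed, *tokens)).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


@dataclass
class PlatformLayout:
    """Probe placement and noise level of one array platform."""

    name: str
    chrom_length: int
    noise_sd: float
    probe_positions: np.ndarray

    def __post_init__(self) -> None:
        self.probe_positions = np.asarray(self.probe_positions, dtype=np.int64)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if np.any(np.diff(self.probe_positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        if self.probe_positions.size and (
            self.probe_positions[0] < 0
            or self.probe_positions[-1] >= self.chrom_length
        ):
            raise ValueError("probe positions must lie in [0, chrom_length)")

    @property
    def n_probes(self) -> int:
        return len(self.probe_positions)

    @property
    def median_spacing(self) -> float:
        return float(np.median(np.diff(self.probe_positions)))


@dataclass
class PlantedLesion:
    """A recurrent lesion: 0-based half-open interval, direction, carrier
    frequency within the cohort and the log2 shift it applies."""

    start: int
    end: int
    direction: str  # 'deletion' or 'amplification'
    carrier_frequency: float
    log2_shift: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("lesion start must be < end")
        if not 0 <= self.carrier_frequency <= 1:
            raise ValueError("carrier_frequency must be in [0, 1]")
        if self.direction not in ("deletion", "amplification"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "deletion" and self.log2_shift >= 0:
            raise ValueError("deletion requires log2_shift < 0")
        if self.direction == "amplification" and self.log2_shift <= 0:
            raise ValueError("amplification requires log2_shift > 0")


@dataclass
class CohortScenario:
    cohort_name: str
    n_samples: int
    platform: PlatformLayout
    lesions: list[PlantedLesion] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for lesion in self.lesions:
            if lesion.start < 0 or lesion.end > self.platform.chrom_length:
                raise ValueError(
                    f"lesion {lesion.name or lesion.start} outside chromosome"
                )


@dataclass
class TruthTable:
    """Planted truth of one simulated cohort.

    ``carriers`` is a samples x lesions 0/1 matrix. True per-anchor deletion
    frequency honours the later-lesion-overrides rule on overlaps.
    """

    cohort_name: str
    sample_ids: list[str]
    lesions: list[PlantedLesion]
    carriers: np.ndarray

    def carrier_fraction(self, lesion_index: int) -> float:
        return float(self.carriers[:, lesion_index].mean())

    def true_del_freq(self, grid: AnchorGrid) -> np.ndarray:
        """Fraction of samples truly deleted at each anchor."""
        n = len(self.sample_ids)
        deleted = np.zeros((n, grid.n_anchors), dtype=bool)
        # apply lesions in order so later ones override earlier on overlaps
        for j, lesion in enumerate(self.lesions):
            inside = (grid.positions >= lesion.start) & (
                grid.positions < lesion.end
            )
            rows = self.carriers[:, j].astype(bool)
            deleted[np.ix_(rows, inside)] = lesion.direction == "deletion"
        return deleted.sum(axis=0) / n


def make_platform_layout(
    name: str,
    chrom_length: int,
    n_probes: int,
    noise_sd: float,
    mode: str = "uniform",
    seed: int = 0,
) -> PlatformLayout:
    """Lay out probes along the chromosome.

    uniform: probe i at floor((i + 0.5) * chrom_length / n_probes).
    jittered: uniform positions perturbed by a seeded Gaussian of a quarter
    of the spacing, then sorted, deduplicated and clipped to the chromosome.
    """
    if n_probes < 2:
        raise ValueError("n_probes must be >= 2")
    if chrom_length <= n_probes:
        raise ValueError("chrom_length must exceed n_probes")
    i = np.arange(n_probes)
    positions = (i + 0.5) * chrom_length // n_probes
    if mode == "jittered":
        rng = np.random.default_rng(seed)
        spacing = chrom_length / n_probes
        positions = positions + rng.normal(0, spacing / 4, n_probes)
        positions = np.unique(
            np.clip(np.round(positions), 0, chrom_length - 1)
        )
    elif mode != "uniform":
        raise ValueError(f"unknown layout mode {mode!r}")
    return PlatformLayout(
        name=name,
        chrom_length=chrom_length,
        noise_sd=noise_sd,
        probe_positions=positions.astype(np.int64),
    )


def simulate_cn_cohort(scenario: CohortScenario) -> tuple[ProbeMatrix, TruthTable]:
    """Simulate probe-level log2 ratios for one cohort.

    Each sample independently carries each lesion with its carrier
    frequency; a carried lesion sets the shift of probes inside [start, end)
    (later lesions override earlier on overlaps); i.i.d. Gaussian noise of
    the platform's noise_sd is added everywhere. Bit-reproducible from
    (scenario, seed).
    """
    platform = scenario.platform
    rng = np.random.default_rng(scenario.seed)
    n_s, n_p = scenario.n_samples, platform.n_probes
    carriers = (
        rng.random((n_s, len(scenario.lesions)))
        < np.array([l.carrier_frequency for l in scenario.lesions])
        if scenario.lesions
        else np.zeros((n_s, 0))
    ).astype(np.int8)
    shift = np.zeros((n_p, n_s))
    pos = platform.probe_positions
    for j, lesion in enumerate(scenario.lesions):
        inside = (pos >= lesion.start) & (pos < lesion.end)
        cols = carriers[:, j].astype(bool)
        block = np.ix_(inside, cols)
        shift[block] = lesion.log2_shift
    values = shift
    if platform.noise_sd > 0:
        values = values + rng.normal(0, platform.noise_sd, (n_p, n_s))
    sample_ids = [f"{scenario.cohort_name}_s{k:04d}" for k in range(n_s)]
    pm = ProbeMatrix(
        chrom="chr21",
        probe_id=np.array([f"{platform.name}_p{k:05d}" for k in range(n_p)]),
        start=pos.copy(),
        end=pos + 60,  # nominal probe footprint
        values=values,
        sample_ids=sample_ids,
    )
    truth = TruthTable(
        cohort_name=scenario.cohort_name,
        sample_ids=sample_ids,
        lesions=list(scenario.lesions),
        carriers=carriers,
    )
    return pm, truth


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def make_feature_annotation(
    n_features: int,
    chrom_length: int = CHR21_LENGTH,
    prefix: str = "G",
    half_width: int = 10_000,
) -> list[GenomicInterval]:
    """Deterministic feature intervals spread evenly along the chromosome.

    Feature i is centred at floor((i + 0.5) * chrom_length / n_features),
    so the same (n_features, chrom_length) always yields the same universe —
    datasets simulated separately share one annotation.
    """
    out = []
    for i in range(n_features):
        center = (2 * i + 1) * chrom_length // (2 * n_features)
        start = max(center - half_width, 0)
        end = min(center + half_width, chrom_length)
        out.append(GenomicInterval("chr21", start, end, f"{prefix}{i:04d}"))
    return out


def _simulate_two_group(
    annotation: list[GenomicInterval],
    n_tumor: int,
    n_normal: int,
    down_features: dict[str, float],
    noise_sd: float,
    seed: int,
    baseline_mean: float,
    label: str,
):
    from .de import ExpressionDataset

    if n_tumor < 2 or n_normal < 2:
        raise ValueError("need >= 2 samples per group")
    ids = [iv.name for iv in annotation]
    unknown = set(down_features) - set(ids)
    if unknown:
        raise ValueError(f"down features not in annotation: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    n_feat = len(ids)
    baseline = baseline_mean + rng.normal(0, 0.5, n_feat)
    values = np.tile(baseline[:, None], (1, n_tumor + n_normal))
    lfc = np.zeros(n_feat)
    for f, change in down_features.items():
        lfc[ids.index(f)] = change
    values[:, :n_tumor] += lfc[:, None]
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, values.shape)
    groups = np.array(["tumor"] * n_tumor + ["normal"] * n_normal)
    ann_frame = pd.DataFrame(
        {
            "feature_id": ids,
            "start": [iv.start for iv in annotation],
            "end": [iv.end for iv in annotation],
        }
    )
    ds = ExpressionDataset(
        values=values, feature_ids=ids, groups=groups, label=label,
        annotation=ann_frame,
    )
    return ds, dict(down_features)


def simulate_expression_dataset(
    n_genes: int = 200,
    n_tumor: int = 20,
    n_normal: int = 20,
    down_genes: dict[str, float] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    baseline_mean: float = 8.0,
    chrom_length: int = CHR21_LENGTH,
    label: str = "",
    annotation: list[GenomicInterval] | None = None,
):
    """Tumor/normal gene-expression matrix with planted downregulation.

    Returns (ExpressionDataset, truth) where truth maps planted gene id ->
    log-fold-change. Tumor columns of planted genes are shifted by their
    (negative) lfc; everything else is baseline + Gaussian noise.
    """
    if annotation is None:
        annotation = make_feature_annotation(n_genes, chrom_length, prefix="G")
    return _simulate_two_group(
        annotation, n_tumor, n_normal, down_genes or {}, noise_sd, seed,
        baseline_mean, label,
    )


def simulate_mirna_dataset(
    n_features: int = 300,
    n_tumor: int = 15,
    n_normal: int = 15,
    down_features: dict[str, float] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    baseline_mean: float = 6.0,
    chrom_length: int = CHR21_LENGTH,
    label: str = "",
    annotation: list[GenomicInterval] | None = None,
):
    """Same contract as the gene simulator at miRNA-scale feature counts."""
    if annotation is None:
        annotation = make_feature_annotation(
            n_features, chrom_length, prefix="M", half_width=200
        )
    return _simulate_two_group(
        annotation, n_tumor, n_normal, down_features or {}, noise_sd, seed,
        baseline_mean, label,
    )


# ---------------------------------------------------------------------------
# default scenario pack (the study conditions)
# ---------------------------------------------------------------------------

_PLATFORM_SPECS = {
    # cohort: (platform name, n_probes, noise_sd)
    "breast": ("bac33k", 500, 0.15),
    "lung": ("bac32k", 500, 0.15),
    "melanoma": ("oligo60k", 900, 0.25),
    "wilms": ("oligo105k", 1600, 0.25),
}

_COHORT_SIZES = {"breast": 359, "lung": 78, "melanoma": 34, "wilms": 18}

# Planted region coordinates (bp, 0-based half-open). MDR1/MDR2 breakpoints
# are multiples of chrom_length/100, i.e. probe-grid boundaries of both the
# 500- and the 900-probe layouts; MDR3 breakpoints are probe-grid boundaries
# of the 1600-probe layout that carries it.
REGION_COORDS = {
    "MDR1": (22 * CHR21_LENGTH // 100, 23 * CHR21_LENGTH // 100),
    "MDR2": (30 * CHR21_LENGTH // 100, 55 * CHR21_LENGTH // 100),
    "MDR3": (1189 * CHR21_LENGTH // 1600, 1202 * CHR21_LENGTH // 1600),
}

# cohort -> {region: carrier frequency}
PLANTED_FREQS = {
    "breast": {"MDR1": 0.117},
    "lung": {"MDR1": 0.269},
    "melanoma": {"MDR1": 0.617, "MDR2": 0.5},
    "wilms": {"MDR3": 0.5},
}

DELETION_SHIFT = -0.8


def default_lesions(cohort: str) -> list[PlantedLesion]:
    return [
        PlantedLesion(
            start=REGION_COORDS[region][0],
            end=REGION_COORDS[region][1],
            direction="deletion",
            carrier_frequency=freq,
            log2_shift=DELETION_SHIFT,
            name=region,
        )
        for region, freq in PLANTED_FREQS.get(cohort, {}).items()
    ]


def default_scenario_pack(
    seed: int = 0, with_lesions: bool = True
) -> dict[str, CohortScenario]:
    """The four-cohort study conditions with (optionally) planted lesions."""
    pack = {}
    for cohort, (pname, n_probes, noise_sd) in _PLATFORM_SPECS.items():
        layout = make_platform_layout(
            pname, CHR21_LENGTH, n_probes, noise_sd, mode="uniform"
        )
        pack[cohort] = CohortScenario(
            cohort_name=cohort,
            n_samples=_COHORT_SIZES[cohort],
            platform=layout,
            lesions=default_lesions(cohort) if with_lesions else [],
            seed=derive_seed(seed, "cn", cohort),
        )
    return pack


# planted downregulation (log-fold-change -1.5) per gene dataset; gene ids
# refer to the deterministic 200-gene annotation. G0044/G0045 lie in MDR1,
# G0060..G0109 in MDR2, G0149 in MDR3; G0020 and G0130 lie outside all three.
GENE_DOWN = {
    "breast": {"G0044": -1.5, "G0060": -1.5, "G0149": -1.5, "G0045": -1.5,
               "G0020": -1.5, "G0130": -1.5},
    "lung": {"G0044": -1.5, "G0149": -1.5, "G0020": -1.5, "G0130": -1.5},
    "melanoma": {"G0060": -1.5, "G0020": -1.5, "G0130": -1.5},
    "wilms": {"G0149": -1.5, "G0100": -1.5},
}

# planted downregulation per miRNA dataset; M0090..M0164 lie in MDR2,
# M0200 outside all regions. M0100 mirrors a miR-99a-like cluster member.
MIRNA_DOWN = {
    "breast": {"M0100": -1.5, "M0102": -1.5, "M0200": -1.5},
    "lung": {"M0100": -1.5, "M0200": -1.5},
    "melanoma": {"M0100": -1.5, "M0101": -1.5, "M0102": -1.5},
    "wilms": {"M0101": -1.5, "M0090": -1.5},
}

_GENE_DS_SIZES = {"breast": (30, 10), "lung": (25, 25),
                  "melanoma": (15, 10), "wilms": (8, 5)}
_MIRNA_DS_SIZES = {"breast": (15, 15), "lung": (12, 12),
                   "melanoma": (10, 10), "wilms": (8, 8)}


def default_expression_pack(seed: int = 0, with_planted: bool = True):
    """Four gene-expression datasets sharing one 200-gene annotation."""
    annotation = make_feature_annotation(200, CHR21_LENGTH, prefix="G")
    datasets, truths = {}, {}
    for cohort, (nt, nn) in _GENE_DS_SIZES.items():
        ds, truth = simulate_expression_dataset(
            n_tumor=nt, n_normal=nn,
            down_genes=GENE_DOWN[cohort] if with_planted else {},
            noise_sd=0.3, seed=derive_seed(seed, "expr", cohort),
            label=f"expr_{cohort}", annotation=annotation,
        )
        datasets[f"expr_{cohort}"] = ds
        truths[f"expr_{cohort}"] = truth
    return datasets, truths, annotation


def default_mirna_pack(seed: int = 0, with_planted: bool = True):
    """Four miRNA datasets sharing one 300-feature annotation."""
    annotation = make_feature_annotation(300, CHR21_LENGTH, prefix="M",
                                         half_width=200)
    datasets, truths = {}, {}
    for cohort, (nt, nn) in _MIRNA_DS_SIZES.items():
        ds, truth = simulate_mirna_dataset(
            n_tumor=nt, n_normal=nn,
            down_features=MIRNA_DOWN[cohort] if with_planted else {},
            noise_sd=0.3, seed=derive_seed(seed, "mirna", cohort),
            label=f"mir_{cohort}", annotation=annotation,
        )
        datasets[f"mir_{cohort}"] = ds
        truths[f"mir_{cohort}"] = truth
    return datasets, truths, annotation


def default_gene_sets(seed: int = 0):
    """Synthetic miRNA->target map and pathway collection for the ORA stage.

    Targets of the planted miRNA cluster members are concentrated in the
    'PROLIFERATION_LIKE' set so that a query built from the candidate miRNAs'
    targets comes out enriched there.
    """
    rng = np.random.default_rng(derive_seed(seed, "genesets"))
    universe = {f"G{i:04d}" for i in range(200)}
    ordered = sorted(universe)
    targets = {
        mir: {str(g) for g in rng.choice(ordered, size=15, replace=False)}
        for mir in ("M0100", "M0101", "M0102")
    }
    from .integration import GeneSetCollection

    prolif = set().union(*targets.values())
    prolif = set(sorted(prolif)[:25]) | {
        str(g) for g in rng.choice(ordered, 5, replace=False)
    }
    sets = {"PROLIFERATION_LIKE": prolif}
    for k in range(4):
        sets[f"RANDOM_SET_{k}"] = {
            str(g) for g in rng.choice(ordered, 20, replace=False)
        }
    return targets, GeneSetCollection(sets=sets, universe=universe)


def expected_candidates(
    planted_down_by_dataset: dict[str, dict[str, float]],
    annotation: list[GenomicInterval],
    regions: dict[str, tuple[int, int]] | None = None,
    min_datasets: int = 2,
) -> set[str]:
    """Ground-truth candidate set: inside a planted region AND planted down
    in >= min_datasets datasets."""
    regions = regions or REGION_COORDS
    count: dict[str, int] = {}
    for down in planted_down_by_dataset.values():
        for f in down:
            count[f] = count.get(f, 0) + 1
    by_name = {iv.name: iv for iv in annotation}
    out = set()
    for f, c in count.items():
        if c < min_datasets:
            continue
        iv = by_name[f]
        if any(iv.overlaps(s, e) for s, e in regions.values()):
            out.add(f)
    return out
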