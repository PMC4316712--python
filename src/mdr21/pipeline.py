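"""Configuration-driven orchestration of the full analysis.

Stages run in a fixed order — simulate (or ingest), segment, call,
harmonize, mdr, de, integrate — with every intermediate written as TSV/BED
into the output directory, so the stage subcommands compose through files
exactly as ``run_full_pipeline`` does (run-all itself goes through the same
files). A run manifest records the config hash, the global seed and a
checksum per output; a rerun with identical config and seed is bit-identical.

One global seed fans out to per-stage (and per-sample) sub-seeds by stable
hashing of stage names, so stochastic stages are isolated from each other.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, de, harmonization, integration, io, mdr, segmentation, synth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline", "STAGES", "segment_sample"]

STAGES = ["simulate", "segment", "call", "harmonize", "mdr", "de", "integrate"]


@dataclass
class PipelineConfig:
    """All knobs of a run; loadable from YAML (see ``from_yaml``)."""

    seed: int = 0
    out_dir: str = "mdr21_out"
    chrom_length: int = synth.CHR21_LENGTH
    n_anchors: int = 5000
    max_gap: float | None = None  # None -> 2x coarsest median probe spacing
    synthetic: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    calling: dict = field(default_factory=dict)
    mdr: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    inputs: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def seg_params(self, sub_seed: int = 0) -> segmentation.SegmentationParams:
        return segmentation.SegmentationParams(seed=sub_seed, **self.segmentation)

    def call_params(self) -> calling.CallingParams:
        return calling.CallingParams(
            seed=synth.derive_seed(self.seed, "call"), **self.calling
        )

    def mdr_params(self) -> mdr.MdrParams:
        return mdr.MdrParams(**self.mdr)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def segment_sample(
    positions: np.ndarray,
    values: np.ndarray,
    params: segmentation.SegmentationParams,
) -> list[segmentation.Segment]:
    """NaN-aware wrapper: drop missing probes, then run CBS."""
    keep = np.isfinite(values)
    return segmentation.segment_profile(positions[keep], values[keep], params)


# ---------------------------------------------------------------------------
# stages (each reads its predecessors' files from config.out_dir)
# ---------------------------------------------------------------------------

def _out(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(config: PipelineConfig) -> list[Path]:
    """Write simulated cohorts, truth, expression matrices and annotations.

    In inputs mode (``config.inputs`` set), external probe-matrix files are
    read, validated and re-written into the run directory instead.
    """
    out = _out(config)
    written: list[Path] = []
    if config.inputs is not None:
        for cohort, path in config.inputs["cohorts"].items():
            pm = io.read_probe_matrix(path)
            dest = out / f"cn_{cohort}.tsv"
            io.write_probe_matrix(pm, dest)
            written.append(dest)
        for key, fname in (
            ("gene_annotation", "annotation_genes.bed"),
            ("mirna_annotation", "annotation_mirna.bed"),
        ):
            if config.inputs.get(key):
                ivs = io.read_gene_annotation(config.inputs[key])
                io.write_gene_annotation(ivs, out / fname)
                written.append(out / fname)
        return written

    syn = config.synthetic
    with_lesions = syn.get("with_lesions", True)
    with_planted = syn.get("with_planted_de", True)
    scenarios = synth.default_scenario_pack(config.seed, with_lesions)
    for cohort, scn in scenarios.items():
        if "cohort_sizes" in syn:
            scn = dataclasses.replace(
                scn, n_samples=syn["cohort_sizes"][cohort]
            )
        if "n_probes" in syn:
            layout = synth.make_platform_layout(
                scn.platform.name, config.chrom_length,
                syn["n_probes"][cohort], scn.platform.noise_sd,
            )
            scn = dataclasses.replace(scn, platform=layout)
        pm, truth = synth.simulate_cn_cohort(scn)
        dest = out / f"cn_{cohort}.tsv"
        io.write_probe_matrix(pm, dest)
        written.append(dest)
        tframe = pd.DataFrame(
            truth.carriers,
            index=truth.sample_ids,
            columns=[l.name or f"lesion{j}" for j, l in enumerate(truth.lesions)],
        )
        tdest = out / f"truth_cn_{cohort}.tsv"
        tframe.to_csv(tdest, sep="\t", index_label="sample_id")
        written.append(tdest)

    gene_ds, gene_truth, gene_ann = synth.default_expression_pack(
        config.seed, with_planted
    )
    mir_ds, mir_truth, mir_ann = synth.default_mirna_pack(config.seed, with_planted)
    for datasets in (gene_ds, mir_ds):
        for label, ds in datasets.items():
            frame = pd.DataFrame(ds.values, index=ds.feature_ids,
                                 columns=[f"{g}_{k}" for k, g in enumerate(ds.groups)])
            dest = out / f"{label}.tsv"
            frame.to_csv(dest, sep="\t", index_label="feature_id",
                         float_format="%.6g")
            written.append(dest)
    io.write_gene_annotation(gene_ann, out / "annotation_genes.bed")
    io.write_gene_annotation(mir_ann, out / "annotation_mirna.bed")
    written += [out / "annotation_genes.bed", out / "annotation_mirna.bed"]
    truth_rows = [
        {"dataset": label, "feature_id": f, "lfc": lfc}
        for truths in (gene_truth, mir_truth)
        for label, down in truths.items()
        for f, lfc in down.items()
    ]
    pd.DataFrame(truth_rows, columns=["dataset", "feature_id", "lfc"]).to_csv(
        out / "truth_expression.tsv", sep="\t", index=False
    )
    written.append(out / "truth_expression.tsv")
    targets, collection = synth.default_gene_sets(config.seed)
    with open(out / "mirna_targets.gmt", "w") as fh:
        for mir_name in sorted(targets):
            fh.write("\t".join([mir_name, "targets"] + sorted(targets[mir_name])) + "\n")
    with open(out / "gene_sets.gmt", "w") as fh:
        for set_name in sorted(collection.sets):
            fh.write("\t".join([set_name, "synthetic"]
                               + sorted(collection.sets[set_name])) + "\n")
    written += [out / "mirna_targets.gmt", out / "gene_sets.gmt"]
    return written


def _cohort_names(config: PipelineConfig) -> list[str]:
    if config.inputs is not None:
        return list(config.inputs["cohorts"])
    return list(synth.default_scenario_pack(0, False))


def stage_segment(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    frames = []
    for cohort in _cohort_names(config):
        pm = io.read_probe_matrix(out / f"cn_{cohort}.tsv")
        per_sample = {}
        for sid in pm.sample_ids:
            positions, values = pm.sample_series(sid)
            params = config.seg_params(
                synth.derive_seed(config.seed, "segment", cohort, sid)
            )
            per_sample[sid] = segment_sample(positions, values, params)
        frame = segmentation.segments_to_frame(per_sample, pm.chrom)
        frame.insert(0, "cohort", cohort)
        frames.append(frame)
        logger.info("segment: %s -> %d segments over %d samples",
                    cohort, len(frame), pm.n_samples)
    dest = out / "segments.tsv"
    pd.concat(frames, ignore_index=True).drop(columns="state").to_csv(
        dest, sep="\t", index=False, float_format="%.6g"
    )
    return [dest]


def _frame_to_segments(frame: pd.DataFrame) -> dict[str, list[segmentation.Segment]]:
    out: dict[str, list[segmentation.Segment]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(row.sample_id, []).append(
            segmentation.Segment(
                start_index=int(row.start_index),
                end_index=int(row.end_index),
                start_bp=int(row.start),
                end_bp=int(row.end),
                mean_level=float(row.mean_level),
                n_probes=int(row.n_probes),
                state=getattr(row, "state", None),
            )
        )
    return out


def stage_call(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    seg_frame = pd.read_csv(out / "segments.tsv", sep="\t")
    params = config.call_params()
    frames = []
    for cohort, sub in seg_frame.groupby("cohort", sort=False):
        per_sample = _frame_to_segments(sub)
        if params.method == "mixture":
            calling.call_segments_mixture(per_sample, params)
        else:
            for segs in per_sample.values():
                calling.call_segments_threshold(segs, params)
        frame = segmentation.segments_to_frame(per_sample, sub["chrom"].iloc[0])
        frame.insert(0, "cohort", cohort)
        frames.append(frame)
    dest = out / "calls.tsv"
    pd.concat(frames, ignore_index=True).to_csv(
        dest, sep="\t", index=False, float_format="%.6g"
    )
    return [dest]


def _auto_max_gap(config: PipelineConfig, out: Path) -> float:
    """Default projection gap: 2x the coarsest cohort's median probe spacing."""
    if config.max_gap is not None:
        return config.max_gap
    spacings = []
    for cohort in _cohort_names(config):
        pm = io.read_probe_matrix(out / f"cn_{cohort}.tsv")
        spacings.append(float(np.median(np.diff(np.sort(pm.start)))))
    return 2.0 * max(spacings)


def stage_harmonize(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    call_frame = pd.read_csv(out / "calls.tsv", sep="\t")
    grid = harmonization.build_anchor_grid(config.chrom_length, config.n_anchors)
    max_gap = _auto_max_gap(config, out)
    written = []
    profiles = []
    for cohort, sub in call_frame.groupby("cohort", sort=False):
        per_sample = _frame_to_segments(sub)
        matrix = harmonization.project_calls_to_anchors(
            per_sample, grid, max_gap=max_gap, cohort=cohort
        )
        states = pd.DataFrame(matrix.states, index=matrix.sample_ids,
                              columns=grid.positions)
        dest = out / f"anchors_{cohort}.tsv"
        states.to_csv(dest, sep="\t", index_label="sample_id")
        written.append(dest)
        profiles.append(harmonization.compute_frequencies(matrix))
        logger.info("harmonize: %s -> %d/%d anchors informative for all samples",
                    cohort, int((matrix.states != harmonization.MISSING).all(0).sum()),
                    grid.n_anchors)
    combined = harmonization.combine_profiles_median(profiles)
    freq = pd.concat(
        [harmonization.profile_to_frame(p) for p in profiles + [combined]],
        ignore_index=True,
    )
    dest = out / "frequencies.tsv"
    freq.to_csv(dest, sep="\t", index=False, float_format="%.6g")
    written.append(dest)
    return written


def _load_anchor_matrices(config: PipelineConfig, out: Path):
    grid = harmonization.build_anchor_grid(config.chrom_length, config.n_anchors)
    matrices = {}
    for cohort in _cohort_names(config):
        frame = pd.read_csv(out / f"anchors_{cohort}.tsv", sep="\t",
                            index_col="sample_id")
        matrices[cohort] = harmonization.AnchorCallMatrix(
            grid=grid, sample_ids=list(frame.index),
            states=frame.to_numpy(np.int8), cohort=cohort,
        )
    return grid, matrices


def stage_mdr(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    grid, matrices = _load_anchor_matrices(config, out)
    params = config.mdr_params()
    profiles = [harmonization.compute_frequencies(m) for m in matrices.values()]
    regions = mdr.detect_regions(profiles, params)
    for region in regions:
        mdr.summarize_region_frequencies(
            region, matrices, sample_fraction=params.sample_fraction
        )
    io.write_regions_bed(regions, out / "regions.bed")
    mdr.regions_to_frame(regions).to_csv(
        out / "region_frequencies.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    logger.info("mdr: %d region(s): %s", len(regions),
                [io.format_region_1based(r.chrom, r.start_bp, r.end_bp)
                 for r in regions])
    return [out / "regions.bed", out / "region_frequencies.tsv"]


def _read_expression(path: Path, label: str) -> de.ExpressionDataset:
    frame = pd.read_csv(path, sep="\t", index_col="feature_id")
    groups = np.array([c.rsplit("_", 1)[0] for c in frame.columns])
    return de.ExpressionDataset(
        values=frame.to_numpy(float),
        feature_ids=[str(f) for f in frame.index],
        groups=groups,
        label=label,
    )


def stage_de(config: PipelineConfig) -> list[Path]:
    """Quantile-normalize and test every expression dataset.

    Gene datasets: Welch t with BH FDR. miRNA datasets: SAM with permutation
    FDR (config ``de.mirna_method: welch`` switches to the t test).
    """
    out = _out(config)
    opts = config.de
    n_perm = int(opts.get("n_perm", 500))
    mir_method = opts.get("mirna_method", "sam")
    written = []
    for kind, prefix in (("genes", "expr_"), ("mirna", "mir_")):
        frames = []
        for path in sorted(out.glob(f"{prefix}*.tsv")):
            label = path.stem
            ds = _read_expression(path, label)
            ds = dataclasses.replace(ds, values=de.quantile_normalize(ds.values))
            if kind == "genes" or mir_method == "welch":
                res = de.welch_t_test(ds)
            else:
                res = de.sam_permutation_fdr(
                    ds, n_perm=n_perm,
                    seed=synth.derive_seed(config.seed, "de", label),
                )
                res = res.rename(columns={"d": "t"})
                res["p"] = np.nan  # SAM reports permutation q only
            res.insert(0, "dataset", label)
            frames.append(res)
            logger.info("de: %s -> %d features, %d down at q<%.3g",
                        label, len(res),
                        int(((res["effect"] < 0)
                             & (res["q"] < opts.get("q_cut", 0.05))).sum()),
                        opts.get("q_cut", 0.05))
        if not frames:
            continue  # e.g. inputs mode without expression matrices
        dest = out / f"de_{kind}.tsv"
        pd.concat(frames, ignore_index=True).to_csv(
            dest, sep="\t", index=False, float_format="%.6g"
        )
        written.append(dest)
    return written


def stage_integrate(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    opts = config.de
    q_cut = float(opts.get("q_cut", 0.05))
    min_datasets = int(opts.get("min_datasets", 2))
    regions_bed = io.read_regions_bed(out / "regions.bed")
    regions = [
        mdr.MDRegion(chrom=iv.chrom, start_bp=iv.start, end_bp=iv.end,
                     first_anchor=0, last_anchor=0, peak_del_freq=0.0,
                     name=iv.name)
        for iv in regions_bed
    ]
    written = []
    all_calls = []
    candidate_mirnas: set[str] = set()
    for kind, ann_file in (("genes", "annotation_genes.bed"),
                           ("mirna", "annotation_mirna.bed")):
        if not (out / ann_file).exists() or not (out / f"de_{kind}.tsv").exists():
            continue
        annotation = io.read_gene_annotation(out / ann_file)
        de_frame = pd.read_csv(out / f"de_{kind}.tsv", sep="\t")
        de_tables = {
            label: sub for label, sub in de_frame.groupby("dataset", sort=False)
        }
        region_features = integration.intersect_genes(regions, annotation)
        calls = integration.select_candidates(
            region_features, de_tables, min_datasets=min_datasets, q_cut=q_cut
        )
        frame = integration.candidates_to_frame(calls)
        frame.insert(0, "feature_class", kind)
        all_calls.append(frame)
        if kind == "mirna":
            candidate_mirnas = {c.feature_id for c in calls if c.is_candidate}
    dest = out / "candidates.tsv"
    if not all_calls:
        all_calls = [integration.candidates_to_frame([])]
    pd.concat(all_calls, ignore_index=True).to_csv(dest, sep="\t", index=False)
    written.append(dest)

    # direction-aware ORA: targets of candidate (downregulated, in-region)
    # miRNAs against the provided pathway sets
    targets_path = out / "mirna_targets.gmt"
    sets_path = out / "gene_sets.gmt"
    if targets_path.exists() and sets_path.exists():
        targets = io.read_gmt(targets_path)
        sets = io.read_gmt(sets_path)
        universe = set().union(*sets.values()) | set().union(
            *targets.values()
        ) if sets else set()
        collection = integration.GeneSetCollection(sets=sets, universe=universe)
        query = set().union(
            *(targets.get(m, set()) for m in sorted(candidate_mirnas))
        ) if candidate_mirnas else set()
        enrich = integration.hypergeometric_ora(query, collection)
        edest = out / "enrichment.tsv"
        enrich.to_csv(edest, sep="\t", index=False, float_format="%.6g")
        written.append(edest)
    return written


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "call": stage_call,
    "harmonize": stage_harmonize,
    "mdr": stage_mdr,
    "de": stage_de,
    "integrate": stage_integrate,
}


def run_stage(name: str, config: PipelineConfig) -> list[Path]:
    try:
        return _STAGE_FUNCS[name](config)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and write the run manifest.

    Returns the manifest dict: config hash, seed, and per-stage output
    checksums. Rerunning with an identical config and seed reproduces every
    checksum bit for bit.
    """
    out = _out(config)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    for name in STAGES:
        outputs = run_stage(name, config)
        manifest["stages"][name] = {
            p.name: _sha256(p) for p in sorted(outputs)
        }
        logger.info("stage %s: %d output file(s)", name, len(outputs))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
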