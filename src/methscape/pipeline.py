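"""End-to-end orchestration: simulate -> landscape -> rank -> compare -> overlap.

Each stage writes plain-text outputs into its own subdirectory of the run
directory and records SHA-256 checksums in ``manifest.json``; a stage whose
outputs are already present for the same configuration is reloaded rather
than recomputed, so single stages can be re-run from cached upstream
outputs.  All randomness flows from the named seeds in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, compare, discordance, enrichment, genome_io
from .genome_io import (
    AnnotationSet,
    GenomePartition,
    ReadMatrix,
    define_promoters,
    map_regions_to_features,
    partition_genome,
)
from .landscape import (
    FitResult,
    IsingParameters,
    RegionLevels,
    fit_all_windows,
    region_level_table,
)
from .synthetic_data import (
    Cohort,
    EffectDesign,
    ToyGenomeConfig,
    cytosine_report_table,
    ground_truth_table,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "landscape", "rank", "compare", "overlap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str
    seed: int = 1
    genome: ToyGenomeConfig = field(default_factory=ToyGenomeConfig)
    effects: EffectDesign = field(default_factory=EffectDesign)
    coverage: float = 10.0
    read_span: int = 4
    mode: str = "pooled"
    min_reads: int = 5
    fdr: float = 0.05
    top_n: int = 500
    n_permutations: int = 10_000
    comparisons: list[dict] = field(
        default_factory=lambda: [
            {"id": "old_vs_young", "test": "old", "reference": "young"},
            {"id": "treated_vs_old", "test": "treated", "reference": "old"},
        ]
    )
    gene_sets: str | None = None

    def __post_init__(self):
        groups = set(self.effects.group_sizes)
        for comp in self.comparisons:
            for side in ("test", "reference"):
                if comp[side] not in groups:
                    raise ValueError(
                        f"comparison '{comp.get('id')}' references undefined group "
                        f"'{comp[side]}'"
                    )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "genome" in d and isinstance(d["genome"], dict):
            g = dict(d["genome"])
            if "lock_intervals" in g and g["lock_intervals"] is not None:
                g["lock_intervals"] = tuple(tuple(x) for x in g["lock_intervals"])
            if "gene_length_range" in g:
                g["gene_length_range"] = tuple(g["gene_length_range"])
            d["genome"] = ToyGenomeConfig(**g)
        if "effects" in d and isinstance(d["effects"], dict):
            d["effects"] = EffectDesign(**d["effects"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # a run is defined by its parameters, not its path
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: Cohort
    partition: GenomePartition
    sample_levels: dict[str, RegionLevels]
    sample_fits: dict[str, dict[int, FitResult]]
    ranked: pd.DataFrame
    per_comparison: dict[str, pd.DataFrame]
    jsd_tracks: dict[str, np.ndarray]
    compare_table: pd.DataFrame
    overlap_table: pd.DataFrame
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _record(manifest: dict, stage: str, paths: list[Path]) -> None:
    manifest.setdefault("stages", {})[stage] = {
        str(p.name): _sha256(p) for p in sorted(paths)
    }


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, outdir: Path, manifest: dict) -> Cohort:
    d = outdir / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(
        cfg.genome, cfg.effects, cfg.coverage, cfg.read_span, seed=cfg.seed
    )
    ann = cohort.annotation
    paths = []

    def save(df, name, writer=genome_io.write_results):
        p = d / name
        writer(df, p)
        paths.append(p)

    save(ann.genes, "genes.bed", genome_io.write_bed)
    for label in ("cpg_islands", "prc2_targets", "locks", "blocks"):
        save(ann.region_sets[label], f"{label}.bed", genome_io.write_bed)
    cpgs = pd.concat(
        [
            pd.DataFrame({"chrom": c, "pos": p})
            for c, p in ann.cpg_positions.items()
        ],
        ignore_index=True,
    )
    save(cpgs, "cpgs.tsv")
    save(
        pd.DataFrame(
            list(ann.chrom_sizes.items()), columns=["chrom", "size"]
        ),
        "chrom_sizes.tsv",
    )
    save(ground_truth_table(cohort.design), "ground_truth.tsv")
    for sid, mats in cohort.samples.items():
        p = d / f"{sid}.readmatrix.tsv.gz"
        genome_io.write_read_matrices(mats, p)
        paths.append(p)
        rep = cytosine_report_table(mats, cohort.partition)
        p2 = d / f"{sid}.cytosine_report.tsv.gz"
        genome_io.write_cytosine_report(rep, p2)
        paths.append(p2)
    _record(manifest, "simulate", paths)
    return cohort


def _load_cohort(cfg: RunConfig, outdir: Path) -> Cohort:
    """Rebuild the cohort deterministically (annotation and design are pure
    functions of the config; reads reload from the archived matrices)."""
    from .synthetic_data import design_landscapes, make_toy_genome

    genome_cfg = (
        cfg.genome
        if cfg.genome.seed
        else dataclasses.replace(cfg.genome, seed=cfg.seed)
    )
    annotation = make_toy_genome(genome_cfg)
    design = design_landscapes(annotation, cfg.effects, seed=cfg.seed + 1)
    groups = cfg.effects.sample_ids()
    n_cpgs = {w.index: w.n_cpgs for w in design.partition.windows}
    samples = {}
    for g, ids in groups.items():
        for sid in ids:
            p = outdir / "simulate" / f"{sid}.readmatrix.tsv.gz"
            if not p.exists():
                raise PipelineError("landscape", f"missing sample file {p}")
            samples[sid] = genome_io.read_read_matrices(p, n_cpgs)
    return Cohort(
        genome_cfg, cfg.effects, design, samples, groups, cfg.coverage,
        cfg.read_span, cfg.seed,
    )


def _fits_to_table(fits: dict[int, FitResult]) -> pd.DataFrame:
    rows = []
    for widx in sorted(fits):
        f = fits[widx]
        if f.estimated:
            rows.append(
                (widx, f.params.alpha, f.params.beta, f.params.gamma,
                 f.log_likelihood, int(f.converged), int(f.at_boundary),
                 f.n_reads, 1)
            )
        else:
            rows.append((widx, np.nan, np.nan, np.nan, np.nan, 0, 0, f.n_reads, 0))
    return pd.DataFrame(
        rows,
        columns=["window_index", "alpha", "beta", "gamma", "log_likelihood",
                 "converged", "at_boundary", "n_reads", "estimated"],
    )


def _fits_from_table(df: pd.DataFrame) -> dict[int, FitResult]:
    out = {}
    for rec in df.itertuples(index=False):
        if rec.estimated:
            out[int(rec.window_index)] = FitResult(
                IsingParameters(rec.alpha, rec.beta, rec.gamma),
                rec.log_likelihood, bool(rec.converged), bool(rec.at_boundary),
                int(rec.n_reads), True,
            )
        else:
            out[int(rec.window_index)] = FitResult.not_estimated(int(rec.n_reads))
    return out


def _region_bedgraph(partition: GenomePartition, values: np.ndarray) -> pd.DataFrame:
    tbl = partition.region_table()
    tbl["value"] = values
    return tbl


def _stage_landscape(
    cfg: RunConfig, outdir: Path, manifest: dict, cohort: Cohort
) -> tuple[dict[str, dict[int, FitResult]], dict[str, RegionLevels]]:
    d = outdir / "landscape"
    d.mkdir(parents=True, exist_ok=True)
    partition = cohort.partition
    fits: dict[str, dict[int, FitResult]] = {}
    levels: dict[str, RegionLevels] = {}
    paths = []
    for sid, mats in cohort.samples.items():
        cache = d / f"{sid}.params.tsv"
        if cache.exists():
            fits[sid] = _fits_from_table(genome_io.read_results(cache))
        else:
            fits[sid] = fit_all_windows(mats, partition, min_reads=cfg.min_reads)
            genome_io.write_results(_fits_to_table(fits[sid]), cache)
        paths.append(cache)
        levels[sid] = region_level_table(fits[sid], partition)
        for metric in ("mml", "nme"):
            p = d / f"{sid}.{metric}.bedGraph.gz"
            if not p.exists():
                genome_io.write_bedgraph(
                    _region_bedgraph(partition, getattr(levels[sid], metric)),
                    "value", p,
                )
            paths.append(p)
    _record(manifest, "landscape", paths)
    return fits, levels


def _stage_rank(
    cfg: RunConfig,
    outdir: Path,
    manifest: dict,
    cohort: Cohort,
    sample_levels: dict[str, RegionLevels],
):
    d = outdir / "rank"
    d.mkdir(parents=True, exist_ok=True)
    partition = cohort.partition
    promoters, bodies = define_promoters(cohort.annotation.genes, cohort.annotation.chrom_sizes)
    prom_regions = map_regions_to_features(partition, promoters)
    body_regions = map_regions_to_features(partition, bodies)
    feature_regions = {
        "promoter": prom_regions,
        "body": body_regions,
        "combined": discordance.combined_feature_regions(prom_regions, body_regions),
    }
    per_comparison: dict[str, pd.DataFrame] = {}
    jsd_tracks: dict[str, np.ndarray] = {}
    paths = []
    for ci, comp in enumerate(cfg.comparisons):
        cid = comp.get("id", f"{comp['test']}_vs_{comp['reference']}")
        test_ids = cohort.groups[comp["test"]]
        ref_ids = cohort.groups[comp["reference"]]
        test_mats = [cohort.samples[s] for s in test_ids]
        ref_mats = [cohort.samples[s] for s in ref_ids]
        sl = ([sample_levels[s] for s in test_ids], [sample_levels[s] for s in ref_ids])
        features, track = discordance.score_comparison(
            test_mats, ref_mats, partition, feature_regions,
            mode=cfg.mode, seed=cfg.seed * 100 + ci * 2, min_reads=cfg.min_reads,
            sample_levels=sl,
        )
        null = discordance.build_null(
            [sample_levels[s] for s in ref_ids], partition, feature_regions
        )
        per_comparison[cid] = discordance.gene_table_for_comparison(features, null, cid)
        jsd_tracks[cid] = track
        p = d / f"{cid}.jsd.bedGraph.gz"
        genome_io.write_bedgraph(_region_bedgraph(partition, track), "value", p)
        paths.append(p)
        p = d / f"{cid}.genes.tsv"
        genome_io.write_results(per_comparison[cid], p)
        paths.append(p)
    ranked = discordance.rank_genes(per_comparison, fdr=cfg.fdr)
    p = d / "ranked_genes.tsv"
    genome_io.write_results(ranked, p)
    paths.append(p)
    _record(manifest, "rank", paths)
    return ranked, per_comparison, jsd_tracks


def _stage_compare(
    cfg: RunConfig,
    outdir: Path,
    manifest: dict,
    cohort: Cohort,
    sample_levels: dict[str, RegionLevels],
) -> pd.DataFrame:
    d = outdir / "compare"
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, comp in enumerate(cfg.comparisons):
        cid = comp.get("id", f"{comp['test']}_vs_{comp['reference']}")
        for metric in ("mml", "nme"):
            tracks_t = [getattr(sample_levels[s], metric) for s in cohort.groups[comp["test"]]]
            tracks_r = [getattr(sample_levels[s], metric) for s in cohort.groups[comp["reference"]]]
            res = compare.compare_tracks(
                f"{metric}_{cid}", tracks_t, tracks_r, seed=cfg.seed * 100 + ci
            )
            rows.append(
                (cid, metric, float(np.mean(res.means_a)), float(np.mean(res.means_b)),
                 res.t_statistic, res.p_two_sided, res.p_one_sided,
                 res.wilcoxon_p, res.pseudo_median, res.n_tiles)
            )
    table = pd.DataFrame(
        rows,
        columns=["comparison", "metric", "test_mean", "reference_mean",
                 "t", "p_two_sided", "p_one_sided", "wilcoxon_p",
                 "pseudo_median_e", "n_tiles"],
    )
    p = d / "group_statistics.tsv"
    genome_io.write_results(table, p)
    _record(manifest, "compare", [p])
    return table


def _stage_overlap(
    cfg: RunConfig,
    outdir: Path,
    manifest: dict,
    cohort: Cohort,
    ranked: pd.DataFrame,
    per_comparison: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    d = outdir / "overlap"
    d.mkdir(parents=True, exist_ok=True)
    ann = cohort.annotation
    rows = []
    # embedded hypomethylated blocks vs LOCK domains
    perm = enrichment.permutation_overlap(
        ann.region_sets["blocks"], ann.region_sets["locks"], ann.chrom_sizes,
        n_perm=cfg.n_permutations, seed=cfg.seed,
    )
    rows.append(("blocks_in_locks", perm.observed, perm.perm_mean, perm.z, perm.p_value))
    # recurrence of significant genes across comparisons
    cids = list(per_comparison)
    if len(cids) >= 2:
        sig = {
            cid: set(t.loc[t["q_value"] < cfg.fdr, "gene_id"]) for cid, t in per_comparison.items()
        }
        universe = sorted(set(ranked["gene_id"]))
        ov = enrichment.fisher_overlap(sig[cids[0]], sig[cids[1]], universe)
        rows.append(
            (f"{cids[0]}&{cids[1]}_genes", ov.a, np.nan, ov.odds_ratio, ov.p_value)
        )
    table = pd.DataFrame(
        rows, columns=["analysis", "observed", "perm_mean", "z_or_OR", "p_value"]
    )
    paths = []
    p = d / "overlap_statistics.tsv"
    genome_io.write_results(table, p)
    paths.append(p)
    if cfg.gene_sets:
        collection = genome_io.read_gmt(cfg.gene_sets)
        universe = sorted(set(ranked["gene_id"]))
        top = discordance.top_genes(ranked, cfg.top_n)
        ora_tbl = enrichment.ora(top, collection, universe)
        p = d / "ora.tsv"
        genome_io.write_results(ora_tbl, p)
        paths.append(p)
    _record(manifest, "overlap", paths)
    return table


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, stages=STAGES) -> PipelineResult:
    """Run (or resume) the pipeline.  Stage outputs are cached in the run
    directory; a failing stage halts the run with the stage named."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_file = outdir / "run.log"
    handler = logging.FileHandler(log_file)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("methscape")
    root.addHandler(handler)
    manifest_path = outdir / "manifest.json"
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
    }
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == manifest["config_hash"]:
            manifest["stages"] = old.get("stages", {})
        else:
            logger.warning("configuration changed; cached stages will be rebuilt")
            import shutil

            for sub in STAGES:
                shutil.rmtree(outdir / sub, ignore_errors=True)

    fits = levels = None
    ranked = per_comparison = jsd_tracks = None
    compare_table = overlap_table = None
    try:
        stage = "simulate"
        marker = outdir / "simulate" / "ground_truth.tsv"
        if "simulate" in stages and not marker.exists():
            cohort = _stage_simulate(config, outdir, manifest)
        else:
            logger.info("simulate: reusing cached outputs")
            cohort = _load_cohort(config, outdir)

        if {"landscape", "rank", "compare", "overlap"} & set(stages):
            stage = "landscape"
            fits, levels = _stage_landscape(config, outdir, manifest, cohort)

        if "rank" in stages or "overlap" in stages:
            stage = "rank"
            ranked, per_comparison, jsd_tracks = _stage_rank(
                config, outdir, manifest, cohort, levels
            )

        if "compare" in stages:
            stage = "compare"
            compare_table = _stage_compare(config, outdir, manifest, cohort, levels)

        if "overlap" in stages:
            stage = "overlap"
            overlap_table = _stage_overlap(
                config, outdir, manifest, cohort, ranked, per_comparison
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - halt with the failing stage named
        raise PipelineError(stage, str(exc)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(
        config=config,
        cohort=cohort,
        partition=cohort.partition,
        sample_levels=levels,
        sample_fits=fits,
        ranked=ranked,
        per_comparison=per_comparison,
        jsd_tracks=jsd_tracks,
        compare_table=compare_table,
        overlap_table=overlap_table,
        manifest=manifest,
    )
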