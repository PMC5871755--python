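"""Configuration-driven end-to-end orchestration.

One global seed drives every stochastic stage through per-stage derived
substreams (``stage_seed``: the global seed mixed with a CRC32 hash of the
stage name, reduced below 2^31), so a run is reproducible from a single
number while stages remain statistically independent.

The bundled fixture scale — a 20-taxon database with 4 confusable V3-V4
pairs, two communities sequenced on both platforms (a 2x2 platform/sample
grid), 2,000 reads per library — is small enough for a laptop yet large
enough that every downstream stage has realistic structure to work on.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import _align
from .classify import (
    AlignmentParams,
    ReferenceIndex,
    classification_table,
    classify_reads,
    closed_reference_assign,
    greedy_cluster,
    read_quality_stats,
)
from .concordance import (
    BiasAuditReport,
    abundance_change_heatmap,
    bias_audit,
    cross_platform_correlation,
    merge_platform_tables,
)
from .diversity_phylo import (
    inverse_simpson,
    permanova,
    pcoa,
    rarefaction_curve,
    reference_tree,
    unifrac_matrix,
)
from .insilico_pcr import LONG_READ_PRIMERS, SHORT_READ_PRIMERS, virtual_pcr_table
from .io_formats import (
    OTUTable,
    SequenceRecord,
    TaxonomyLineage,
    write_fasta,
    write_fastq,
    write_newick,
    write_otu_table,
    write_taxonomy_map,
)
from .synthetic_community import (
    CommunityProfile,
    SyntheticTaxon,
    build_reference_db,
    db_lineages,
    db_records,
    long_read_config,
    merge_read_pairs,
    sample_community,
    short_read_config,
    simulate_long_reads,
    simulate_short_paired_reads,
)

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed, < 2^31."""
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a synthetic end-to-end run."""

    seed: int = 42
    n_taxa: int = 20
    n_confusable_groups: int = 4
    group_size: int = 2
    communities: tuple[str, ...] = ("cultureA", "cultureB")
    community_model: str = "lognormal"
    community_size: int = 12
    n_reads: int = 2000
    long_error_scale: float = 1.0
    short_error_scale: float = 1.0
    min_identity: float = 0.80
    cluster_threshold: float = 0.97
    rare_count: int = 4
    heatmap_pct: float = 0.5
    unifrac_variants: tuple[str, ...] = ("d_W", "d_0.5", "d_0", "d_U", "d_VAW")
    n_permutations: int = 999
    virtual_pcr_max_mismatch: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.cluster_threshold <= 1):
            raise ValueError("identity thresholds must be in (0, 1]")
        if self.rare_count < 0 or self.heatmap_pct < 0:
            raise ValueError("rare_count and heatmap_pct must be non-negative")
        if self.n_reads <= 0 or self.n_taxa <= 0:
            raise ValueError("n_reads and n_taxa must be positive")
        if len(self.communities) < 2:
            raise ValueError("need at least two communities")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["communities"] = list(self.communities)
        d["unifrac_variants"] = list(self.unifrac_variants)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("communities", "unifrac_variants"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


@dataclass
class FixtureBundle:
    """In-memory result of the simulation stages, shared by tests and docs."""

    config: PipelineConfig
    db: list[SyntheticTaxon]
    records: list[SequenceRecord]
    lineages: dict[str, TaxonomyLineage]
    profiles: dict[str, CommunityProfile]
    long_reads: dict[str, tuple[list[SequenceRecord], pd.DataFrame]]
    short_reads: dict[str, tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]]


def make_fixtures(seed: int = 42, config: PipelineConfig | None = None) -> FixtureBundle:
    """Generate the bundled synthetic dataset (deterministic given seed)."""
    cfg = config if config is not None else PipelineConfig(seed=seed)
    if config is not None and config.seed != seed:
        cfg = dataclasses.replace(config, seed=seed)
    db = build_reference_db(
        cfg.n_taxa,
        cfg.n_confusable_groups,
        cfg.group_size,
        seed=stage_seed(cfg.seed, "reference_db"),
    )
    records = db_records(db)
    lineages = db_lineages(db)
    profiles: dict[str, CommunityProfile] = {}
    long_reads = {}
    short_reads = {}
    for name in cfg.communities:
        profiles[name] = sample_community(
            db,
            model=cfg.community_model,
            n_taxa=min(cfg.community_size, len(db)),
            seed=stage_seed(cfg.seed, f"community:{name}"),
            sample_name=name,
        )
        long_cfg = long_read_config(
            cfg.n_reads,
            seed=stage_seed(cfg.seed, f"long_reads:{name}"),
            error_scale=cfg.long_error_scale,
        )
        long_reads[name] = simulate_long_reads(db, profiles[name], long_cfg)
        short_cfg = short_read_config(
            cfg.n_reads,
            seed=stage_seed(cfg.seed, f"short_reads:{name}"),
            error_scale=cfg.short_error_scale,
        )
        short_reads[name] = simulate_short_paired_reads(db, profiles[name], short_cfg)
    return FixtureBundle(
        config=cfg,
        db=db,
        records=records,
        lineages=lineages,
        profiles=profiles,
        long_reads=long_reads,
        short_reads=short_reads,
    )


def combine_single_sample_tables(tables: Sequence[OTUTable]) -> OTUTable:
    """Outer-join single-sample tables into one multi-sample table."""
    frames = [t.to_frame() for t in tables]
    merged = pd.concat(frames, axis=1).fillna(0).astype(np.int64).sort_index()
    lineages: dict[str, TaxonomyLineage] = {}
    for t in tables:
        lineages.update(t.lineages)
    return OTUTable(
        taxa=list(merged.index),
        samples=list(merged.columns),
        counts=merged.to_numpy(),
        lineages={t: lineages[t] for t in merged.index},
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute every stage in dependency order; returns the manifest.

    Stages: simulate -> virtual PCR -> classify (both platform paths) ->
    merge -> bias audit -> rank correlation / heatmaps -> tree + UniFrac +
    PCoA -> perMANOVA. All artefacts are plain-text files in ``outdir``;
    the manifest records the config, derived seeds, and output paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _align.warm_up()
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "stage_seeds": {},
        "outputs": {},
        "stats": {},
    }

    def register(stage: str, path: Path) -> Path:
        manifest["outputs"].setdefault(stage, []).append(str(path.relative_to(out)))
        return path

    # Stage 1: synthetic data -------------------------------------------------
    fixtures = make_fixtures(config.seed, config)
    for stage in ["reference_db"] + [f"community:{c}" for c in config.communities]:
        manifest["stage_seeds"][stage] = stage_seed(config.seed, stage)
    write_fasta(fixtures.records, register("simulate", out / "reference.fasta"))
    write_taxonomy_map(fixtures.lineages, register("simulate", out / "taxonomy.tsv"))
    params = AlignmentParams()
    index = ReferenceIndex(fixtures.records)
    for name in config.communities:
        reads, prov = fixtures.long_reads[name]
        write_fastq(reads, register("simulate", out / f"{name}_long.fastq"))
        prov.to_csv(out / f"{name}_long_provenance.tsv", sep="\t", index=False)
        r1, r2, sprov = fixtures.short_reads[name]
        write_fastq(r1, register("simulate", out / f"{name}_short_R1.fastq"))
        write_fastq(r2, register("simulate", out / f"{name}_short_R2.fastq"))
        sprov.to_csv(out / f"{name}_short_provenance.tsv", sep="\t", index=False)

    # Stage 2: virtual PCR audit ---------------------------------------------
    pcr_rows = []
    for pair_name, pair in (("full_gene", LONG_READ_PRIMERS), ("v3v4", SHORT_READ_PRIMERS)):
        t = virtual_pcr_table(fixtures.records, pair, config.virtual_pcr_max_mismatch)
        t.insert(0, "primer_pair", pair_name)
        pcr_rows.append(t)
    pcr_table = pd.concat(pcr_rows)
    pcr_table.to_csv(register("pcr", out / "virtual_pcr.tsv"), sep="\t")

    # Stage 3: classification, both paths ------------------------------------
    long_tables = []
    quality_rows = []
    long_assignments: dict[str, dict[str, str]] = {}
    for name in config.communities:
        reads, _ = fixtures.long_reads[name]
        results = classify_reads(reads, index, config.min_identity, params)
        frame = pd.DataFrame(
            {
                "read_id": [r.read_id for r in results],
                "accession": [r.assigned_accession for r in results],
                "identity": [round(r.identity, 6) for r in results],
                "tie": [r.tie for r in results],
            }
        )
        frame.to_csv(
            register("classify_long", out / f"{name}_long_classification.tsv"),
            sep="\t",
            index=False,
        )
        long_assignments[name] = {
            r.read_id: r.assigned_accession for r in results if r.classified
        }
        long_tables.append(
            classification_table(results, fixtures.lineages, sample_name=name)
        )
        qs = read_quality_stats(reads)
        quality_rows.append(
            {"sample": name, "mean_phred": qs.sample_mean, "median_phred": qs.sample_median}
        )
    long_table = combine_single_sample_tables(long_tables)
    write_otu_table(long_table, register("classify_long", out / "otu_long.tsv"))
    pd.DataFrame(quality_rows).to_csv(
        register("classify_long", out / "long_read_quality.tsv"), sep="\t", index=False
    )

    short_tables = []
    merge_stats = []
    for name in config.communities:
        r1, r2, _ = fixtures.short_reads[name]
        merged, failed = merge_read_pairs(r1, r2)
        merge_stats.append(
            {
                "sample": name,
                "n_pairs": len(r1),
                "n_merged": len(merged),
                "merge_rate": len(merged) / len(r1),
                "mean_merged_length": float(np.mean([len(m) for m in merged])),
            }
        )
        clusters = greedy_cluster(merged, config.cluster_threshold, params)
        table, dropped = closed_reference_assign(
            clusters,
            index,
            fixtures.lineages,
            sample_name=name,
            threshold=config.cluster_threshold,
            params=params,
        )
        manifest["stats"][f"{name}_short_dropped_reads"] = dropped
        manifest["stats"][f"{name}_short_clusters"] = len(clusters.clusters)
        short_tables.append(table)
    short_table = combine_single_sample_tables(short_tables)
    write_otu_table(short_table, register("cluster_short", out / "otu_short.tsv"))
    pd.DataFrame(merge_stats).to_csv(
        register("cluster_short", out / "merge_stats.tsv"), sep="\t", index=False
    )

    # Stage 4: merge platforms ------------------------------------------------
    merged_table = merge_platform_tables(
        short_table, long_table, min_count=config.rare_count
    )
    write_otu_table(merged_table, register("merge", out / "otu_merged.tsv"))

    # Stage 5: bias audit ------------------------------------------------------
    audit = bias_audit(
        index,
        [t.accession for t in fixtures.db],
        SHORT_READ_PRIMERS,
        min_identity=config.min_identity,
        cluster_threshold=config.cluster_threshold,
        params=params,
    )
    audit_rows = [
        {
            "comparison": f"ORIGINAL_vs_{path}",
            "n_total": v.n_total,
            "n_concordant": v.n_concordant,
            "n_discordant": v.n_discordant,
            "pct_discordant": round(v.pct_discordant, 2),
        }
        for path, v in audit.venn.items()
    ]
    audit_rows.append(
        {
            "comparison": "region_best_hit_vs_region_cluster",
            "n_total": audit.cross_path.n_total,
            "n_concordant": audit.cross_path.n_concordant,
            "n_discordant": audit.cross_path.n_discordant,
            "pct_discordant": round(audit.cross_path.pct_discordant, 2),
        }
    )
    pd.DataFrame(audit_rows).to_csv(
        register("bias_audit", out / "bias_audit.tsv"), sep="\t", index=False
    )
    manifest["stats"]["bias_audit_unique_after_clustering"] = audit.n_unique_after_clustering

    # Stage 6: concordance ----------------------------------------------------
    short_samples = [s for s in merged_table.samples if s.endswith("_illumina")]
    long_samples = [s for s in merged_table.samples if s.endswith("_minion")]
    rho = cross_platform_correlation(merged_table, short_samples, long_samples)
    pd.Series(rho, name="spearman_rho").to_csv(
        register("concordance", out / "rank_correlation.tsv"), sep="\t"
    )
    tables_for_heatmap = {"short_path": short_table, "long_path": long_table}
    for rank, matrix in abundance_change_heatmap(
        tables_for_heatmap, min_pct=config.heatmap_pct
    ).items():
        matrix.to_csv(
            register("concordance", out / f"heatmap_{rank}.tsv"), sep="\t"
        )

    # Stage 7: diversity -------------------------------------------------------
    tree = reference_tree([index[t] for t in merged_table.taxa], params)
    (out / "reference_tree.nwk").write_text(write_newick(tree) + "\n")
    register("diversity", out / "reference_tree.nwk")
    matrices = unifrac_matrix(merged_table, tree, config.unifrac_variants)
    permanova_results = {}
    labels = [
        next(c for c in config.communities if s.startswith(c))
        for s in merged_table.samples
    ]
    for variant, dm in matrices.items():
        dm.to_data_frame().to_csv(
            register("diversity", out / f"unifrac_{variant}.tsv"), sep="\t"
        )
        ordination = pcoa(dm)
        ordination.coordinates.to_csv(
            register("diversity", out / f"pcoa_{variant}.tsv"), sep="\t"
        )
        result = permanova(
            dm,
            labels,
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, f"permanova:{variant}"),
        )
        permanova_results[variant] = {
            "pseudo_F": result.pseudo_f,
            "p_value": result.p_value,
            "n_permutations": result.n_permutations,
        }
    (out / "permanova.json").write_text(json.dumps(permanova_results, indent=2))
    register("permanova", out / "permanova.json")

    alpha_rows = []
    for sample in merged_table.samples:
        counts = merged_table.to_frame()[sample].to_numpy()
        total = int(counts.sum())
        depths = sorted({max(1, total // 10), max(1, total // 2), total})
        curve = rarefaction_curve(
            counts,
            depths,
            n_reps=10,
            seed=stage_seed(config.seed, f"rarefaction:{sample}"),
        )
        for depth, mean, sd in zip(curve.depths, curve.mean, curve.sd):
            alpha_rows.append(
                {"sample": sample, "depth": depth, "inverse_simpson_mean": mean, "sd": sd}
            )
    pd.DataFrame(alpha_rows).to_csv(
        register("diversity", out / "rarefaction.tsv"), sep="\t", index=False
    )

    manifest["stage_seeds"].update(
        {
            f"permanova:{v}": stage_seed(config.seed, f"permanova:{v}")
            for v in config.unifrac_variants
        }
    )
    manifest["config_yaml"] = config.to_yaml()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
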