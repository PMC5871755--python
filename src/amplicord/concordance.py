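"""Cross-platform concordance: the error-free bias audit and table integration.

The central experiment re-implemented here: take the set of identified taxa,
*recreate* their exact (error-free) reference sequences, cut out the V3-V4
region that a short-read library would actually see, push those regions back
through both classification paths (direct best-hit alignment, and 97%
clustering + closed-reference picking), and count how many sequences come
back with a different accession than they started with. Any discordance is
attributable purely to the shorter region — taxa identical across V3-V4 but
distinct elsewhere collapse onto one accession.

The integration half merges per-platform OTU tables (rare-count filter),
aggregates them per taxonomic rank, and measures cross-platform agreement by
Spearman rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    AlignmentParams,
    DEFAULT_PARAMS,
    ReferenceIndex,
    align_semi_global,
    classify_read_best_hit,
    greedy_cluster,
)
from .insilico_pcr import Primer, extract_amplicon
from .io_formats import OTUTable, RANKS, SequenceRecord, TaxonomyLineage, UNASSIGNED

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VennCounts:
    """Concordant/discordant split of a set of reclassified sequences."""

    n_total: int
    n_concordant: int
    n_discordant: int

    def __post_init__(self) -> None:
        if self.n_concordant + self.n_discordant != self.n_total:
            raise ValueError("concordant + discordant != total")
        if min(self.n_total, self.n_concordant, self.n_discordant) < 0:
            raise ValueError("negative counts")

    @property
    def pct_discordant(self) -> float:
        if self.n_total == 0:
            return 0.0
        return 100.0 * self.n_discordant / self.n_total


def venn_from_assignments(
    original: Mapping[str, str], reassigned: Mapping[str, str]
) -> VennCounts:
    """Count ids whose reassigned accession differs from the original."""
    keys = list(original)
    disc = sum(1 for k in keys if reassigned.get(k) != original[k])
    return VennCounts(len(keys), len(keys) - disc, disc)


@dataclass(frozen=True)
class RankAbundanceTable:
    """Relative abundances aggregated to one taxonomic rank."""

    rank: str
    abundance: pd.DataFrame  # rows: rank labels, columns: samples, sums to 1


@dataclass
class BiasAuditReport:
    """Everything the error-free reclassification experiment produces."""

    venn: dict[str, VennCounts]  # path name -> ORIGINAL-vs-path counts
    cross_path: VennCounts  # region best-hit vs region cluster path
    assignments: dict[str, dict[str, str]]  # path name -> {id: accession}
    n_input_sequences: int
    n_unique_after_clustering: int
    excluded: list[str] = field(default_factory=list)  # ids without amplicons


def recreate_reference_reads(
    db: Sequence[SequenceRecord] | ReferenceIndex,
    taxon_ids: Iterable[str],
) -> list[SequenceRecord]:
    """Exact database sequences for a list of identified taxa (deduplicated)."""
    index = db if isinstance(db, ReferenceIndex) else ReferenceIndex(db)
    seen: set[str] = set()
    out: list[SequenceRecord] = []
    unknown: list[str] = []
    for taxon_id in taxon_ids:
        if taxon_id in seen:
            logger.info("recreate: duplicate id %s deduplicated", taxon_id)
            continue
        seen.add(taxon_id)
        if taxon_id not in index:
            unknown.append(taxon_id)
            continue
        out.append(index[taxon_id])
    if unknown:
        raise ValueError(f"unknown taxon ids: {unknown}")
    return out


def bias_audit(
    db: Sequence[SequenceRecord] | ReferenceIndex,
    taxon_ids: Iterable[str],
    region_primer_pair: tuple[Primer, Primer],
    min_identity: float = 0.80,
    cluster_threshold: float = 0.97,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> BiasAuditReport:
    """The error-free recreated-dataset experiment.

    Pipeline: recreate exact sequences -> extract the short-read target
    region -> reclassify the regions via (a) best-hit alignment and (b)
    greedy clustering + closed-reference assignment -> compare each
    sequence's new accession with its original identity. The full-length
    sequences are also reclassified as a control path; with a sane database
    it must be perfectly concordant.

    Sequences the primer pair fails to amplify are excluded and listed in
    the report.
    """
    index = db if isinstance(db, ReferenceIndex) else ReferenceIndex(db)
    recreated = recreate_reference_reads(index, taxon_ids)
    if not recreated:
        raise ValueError("empty taxon id list")

    regions: list[SequenceRecord] = []
    excluded: list[str] = []
    for rec in recreated:
        amp = extract_amplicon(rec, region_primer_pair[0], region_primer_pair[1])
        if amp is None:
            excluded.append(rec.id)
            logger.warning("bias audit: %s not amplifiable, excluded", rec.id)
            continue
        regions.append(SequenceRecord(id=rec.id, seq=amp.full))
    if not regions:
        raise ValueError("no recreated sequence is amplifiable by the region primers")

    original = {rec.id: rec.id for rec in regions}

    # Path 0 (control): full-length reclassification.
    full_assign = {
        rec.id: classify_read_best_hit(rec, index, min_identity, params).assigned_accession
        for rec in recreated
        if rec.id in original
    }

    # Path A: region best-hit alignment.
    region_assign = {
        rec.id: classify_read_best_hit(rec, index, min_identity, params).assigned_accession
        for rec in regions
    }

    # Path B: region clustering + closed-reference assignment.
    clusters = greedy_cluster(regions, threshold=cluster_threshold, params=params)
    cluster_assign: dict[str, str] = {}
    for cluster in clusters.clusters:
        rep_result = classify_read_best_hit(
            cluster.representative, index, min_identity=cluster_threshold, params=params
        )
        for member in cluster.member_ids:
            cluster_assign[member] = rep_result.assigned_accession

    venn = {
        "full_length_best_hit": venn_from_assignments(original, full_assign),
        "region_best_hit": venn_from_assignments(original, region_assign),
        "region_cluster_closed_ref": venn_from_assignments(original, cluster_assign),
    }
    cross = venn_from_assignments(region_assign, cluster_assign)
    return BiasAuditReport(
        venn=venn,
        cross_path=cross,
        assignments={
            "full_length_best_hit": full_assign,
            "region_best_hit": region_assign,
            "region_cluster_closed_ref": cluster_assign,
        },
        n_input_sequences=len(regions),
        n_unique_after_clustering=len(clusters.clusters),
        excluded=excluded,
    )


def merge_platform_tables(
    table_a: OTUTable,
    table_b: OTUTable,
    min_count: int = 4,
    suffixes: tuple[str, str] = ("_illumina", "_minion"),
    filter_mode: str = "cell",
) -> OTUTable:
    """Merge two platform tables after removing rare counts.

    ``filter_mode='cell'`` (default) zeroes any taxon-sample cell below
    ``min_count`` before merging; ``'row'`` instead drops taxa whose total
    count within a platform is below ``min_count``. All-zero rows are dropped
    from the result. Sample names get platform suffixes.
    """
    frames = []
    for table, suffix in ((table_a, suffixes[0]), (table_b, suffixes[1])):
        df = table.to_frame()
        if filter_mode == "cell":
            df = df.where(df >= min_count, 0)
        elif filter_mode == "row":
            df = df[df.sum(axis=1) >= min_count]
        else:
            raise ValueError(f"unknown filter_mode {filter_mode!r}")
        df = df.rename(columns={s: s + suffix for s in df.columns})
        frames.append(df)
    samples = list(frames[0].columns) + list(frames[1].columns)
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample names after suffixing: {samples}")
    merged = frames[0].join(frames[1], how="outer").fillna(0).astype(np.int64)
    merged = merged[merged.sum(axis=1) > 0]
    merged = merged.sort_index()
    lineages = {**table_a.lineages, **table_b.lineages}
    return OTUTable(
        taxa=list(merged.index),
        samples=list(merged.columns),
        counts=merged.to_numpy(),
        lineages={t: lineages[t] for t in merged.index},
    )


def aggregate_rank(table: OTUTable, rank: str) -> RankAbundanceTable:
    """Sum counts over taxa sharing a rank label, normalised per sample.

    The ``unassigned`` sentinel is kept as its own row so that each sample
    column still sums to one.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if not table.taxa:
        raise ValueError("empty OTU table")
    labels = [table.lineages[t].at(rank) for t in table.taxa]
    df = table.to_frame().astype(float)
    grouped = df.groupby(pd.Index(labels, name=rank)).sum()
    totals = grouped.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total count")
    return RankAbundanceTable(rank=rank, abundance=grouped / totals)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Returns NaN (a not-computable state, not an error) when either vector is
    constant.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors differ in length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return float("nan")
    return float(stats.spearmanr(xa, ya).statistic)


def cross_platform_correlation(
    merged_table: OTUTable,
    platform_a_samples: Sequence[str],
    platform_b_samples: Sequence[str],
    ranks: Sequence[str] = RANKS[2:],
) -> dict[str, float]:
    """Per-rank Spearman rho between platform mean abundances.

    At each rank the merged table is aggregated, mean relative abundance is
    taken within each platform's samples, and rho is computed across the
    union of taxa observed on either platform (absent taxa count as zero).
    Ranks with fewer than three taxa are reported as NaN.
    """
    if not platform_a_samples or not platform_b_samples:
        raise ValueError("both platform sample groups must be non-empty")
    out: dict[str, float] = {}
    for rank in ranks:
        agg = aggregate_rank(merged_table, rank).abundance
        mean_a = agg[list(platform_a_samples)].mean(axis=1)
        mean_b = agg[list(platform_b_samples)].mean(axis=1)
        if len(agg) < 3:
            out[rank] = float("nan")
            continue
        out[rank] = spearman_rho(mean_a.to_numpy(), mean_b.to_numpy())
    return out


def abundance_change_heatmap(
    tables: Mapping[str, OTUTable],
    ranks: Sequence[str] = ("order", "family", "genus", "species"),
    min_pct: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Per-rank relative-abundance percentage matrices across analysis paths.

    Rows are rank labels reaching at least ``min_pct`` percent in any of the
    input tables; columns are the table names (e.g. ORIGINAL / best-hit /
    cluster path); cells are percentages averaged over each table's samples.
    """
    out: dict[str, pd.DataFrame] = {}
    for rank in ranks:
        cols = {}
        for name, table in tables.items():
            agg = aggregate_rank(table, rank).abundance
            cols[name] = agg.mean(axis=1) * 100.0
        matrix = pd.DataFrame(cols).fillna(0.0)
        matrix = matrix[(matrix >= min_pct).any(axis=1)].sort_index()
        out[rank] = matrix
    return out


def unique_taxa_by_similarity(
    representatives: Mapping[str, SequenceRecord],
    reads: Sequence[SequenceRecord],
    read_assignments: Mapping[str, str],
    identity_threshold: float = 0.97,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[str]:
    """Taxa seen by one platform whose similar reads went elsewhere.

    ``representatives`` maps accession -> that platform's representative
    sequence. For each representative, find the other platform's reads at
    >= ``identity_threshold`` identity; a taxon is reported as *unique* when
    such near-identical reads exist but none of them was assigned to the
    taxon's accession — i.e. the other platform saw the same molecule and
    called it something else.
    """
    unique: list[str] = []
    for accession in sorted(representatives):
        rep = representatives[accession]
        matched_assignments: set[str] = set()
        found_match = False
        for read in reads:
            aln = align_semi_global(rep, read, params)
            if aln.identity >= identity_threshold:
                found_match = True
                assigned = read_assignments.get(read.id)
                if assigned is not None:
                    matched_assignments.add(assigned)
        if found_match and accession not in matched_assignments:
            unique.append(accession)
    return unique
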