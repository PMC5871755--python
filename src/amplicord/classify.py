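"""Read classification: long-read best-hit alignment and short-read clustering.

Two paths mirror the two sequencing platforms:

* **Long single reads** span the whole 16S gene and are classified by
  best-scoring semi-global alignment against the full-length reference
  database, gated at 80% identity (the error tolerance that makes nanopore
  reads usable despite their per-base error rate).
* **Short merged reads** cover only the V3-V4 region and go through greedy
  97%-identity centroid clustering followed by closed-reference assignment:
  cluster representatives that hit a database sequence at >=97% identity
  inherit its accession; clusters that hit nothing are discarded.

Identity is defined as matches / alignment columns over the aligned span,
excluding free end gaps on the reference; gap columns count against identity.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._align import MAX_ALIGN_LENGTH, semi_global_align, semi_global_score
from .io_formats import (
    OTUTable,
    PairwiseAlignmentRecord,
    SequenceRecord,
    TaxonomyLineage,
    read_fastq,
)

logger = logging.getLogger(__name__)

UNCLASSIFIED = "*"


@dataclass(frozen=True)
class AlignmentParams:
    """Pairwise scoring parameters (long-read mapper defaults)."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -1
    gap_extend: int = -1
    mode: str = "semi_global"
    max_length: int = MAX_ALIGN_LENGTH

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.gap_open != self.gap_extend:
            raise ValueError(
                "only linear gap costs are supported (gap_open == gap_extend)"
            )
        if self.mode != "semi_global":
            raise ValueError(f"unsupported alignment mode {self.mode!r}")


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class AlignmentResult(PairwiseAlignmentRecord):
    """A pairwise alignment annotated with its identity fraction."""

    identity: float = 0.0
    n_match: int = 0
    n_columns: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_columns and abs(self.identity - self.n_match / self.n_columns) > 1e-12:
            raise ValueError("identity inconsistent with n_match / n_columns")


@dataclass(frozen=True)
class ClassificationResult:
    read_id: str
    assigned_accession: str  # UNCLASSIFIED sentinel when below the gate
    identity: float
    tie: bool = False

    @property
    def classified(self) -> bool:
        return self.assigned_accession != UNCLASSIFIED


@dataclass
class Cluster:
    representative: SequenceRecord
    member_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float = 0.97

    @property
    def n_reads(self) -> int:
        return sum(c.size for c in self.clusters)


def align_semi_global(
    query: SequenceRecord | str,
    ref: SequenceRecord | str,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> AlignmentResult:
    """Dynamic-programming optimal semi-global alignment of query against ref."""
    qid, qseq = _as_pair(query, "query")
    rid, rseq = _as_pair(ref, "ref")
    score, aq, ar, qspan, rspan, n_match, n_cols = semi_global_align(
        qseq,
        rseq,
        match=params.match,
        mismatch=params.mismatch,
        gap=params.gap_extend,
        cap=params.max_length,
    )
    return AlignmentResult(
        query_id=qid,
        ref_id=rid,
        aligned_query=aq,
        aligned_ref=ar,
        score=score,
        query_span=qspan,
        ref_span=rspan,
        strand="+",
        identity=n_match / n_cols,
        n_match=n_match,
        n_columns=n_cols,
    )


def _as_pair(obj: SequenceRecord | str, fallback_id: str) -> tuple[str, str]:
    if isinstance(obj, SequenceRecord):
        return obj.id, obj.seq
    return fallback_id, obj


class ReferenceIndex:
    """A reference database with an 8-mer prefilter for best-hit search.

    Candidate references are shortlisted by shared k-mer count with the query
    (top ``shortlist_size``, ties kept); when the query shares no k-mer with
    any reference the search falls back to a full scan, so the gate semantics
    never silently change on divergent queries.
    """

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        k: int = 8,
        shortlist_size: int = 5,
    ) -> None:
        if not records:
            raise ValueError("empty reference database")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate accessions in reference database")
        self.records = sorted(records, key=lambda r: r.id)
        self.k = k
        self.shortlist_size = shortlist_size
        self._kmer_sets = [
            frozenset(r.seq[i : i + k] for i in range(len(r.seq) - k + 1))
            for r in self.records
        ]
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, accession: str) -> SequenceRecord:
        return self._by_id[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_id

    def candidates(self, seq: str) -> list[SequenceRecord]:
        qkmers = {seq[i : i + self.k] for i in range(len(seq) - self.k + 1)}
        shared = np.array([len(qkmers & s) for s in self._kmer_sets])
        if shared.max(initial=0) == 0:
            return list(self.records)  # exactness fallback: full scan
        order = np.argsort(-shared, kind="stable")
        keep = [i for i in order if shared[i] > 0]
        if len(keep) > self.shortlist_size:
            cut = shared[keep[self.shortlist_size - 1]]
            keep = [i for i in keep if shared[i] >= cut]
        return [self.records[i] for i in keep]


def classify_read_best_hit(
    read: SequenceRecord,
    db: ReferenceIndex | Sequence[SequenceRecord],
    min_identity: float = 0.80,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> ClassificationResult:
    """Assign a read to its best-scoring reference, identity-gated.

    The best hit is chosen by alignment score over all candidate references;
    the identity gate is applied *after* best-hit selection. Ties on the top
    score are broken to the lexicographically smallest accession and flagged.
    """
    index = db if isinstance(db, ReferenceIndex) else ReferenceIndex(db)
    candidates = index.candidates(read.seq)
    # Exact containment attains the maximal score match*len(read); no other
    # candidate can exceed it and only other containers can tie, so the DP
    # can be skipped entirely in that case.
    containers = [ref for ref in candidates if read.seq in ref.seq]
    if containers:
        winners = sorted(ref.id for ref in containers)
    else:
        scores = [
            semi_global_score(
                read.seq,
                ref.seq,
                match=params.match,
                mismatch=params.mismatch,
                gap=params.gap_extend,
                cap=params.max_length,
            )
            for ref in candidates
        ]
        best = max(scores)
        winners = sorted(ref.id for ref, s in zip(candidates, scores) if s == best)
    chosen = index[winners[0]]
    aln = align_semi_global(read, chosen, params)
    if aln.identity >= min_identity:
        return ClassificationResult(read.id, chosen.id, aln.identity, tie=len(winners) > 1)
    return ClassificationResult(read.id, UNCLASSIFIED, aln.identity, tie=len(winners) > 1)


def classify_reads(
    reads: Iterable[SequenceRecord],
    db: ReferenceIndex | Sequence[SequenceRecord],
    min_identity: float = 0.80,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[ClassificationResult]:
    index = db if isinstance(db, ReferenceIndex) else ReferenceIndex(db)
    return [classify_read_best_hit(r, index, min_identity, params) for r in reads]


def greedy_cluster(
    reads: Sequence[SequenceRecord],
    threshold: float = 0.97,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> ClusterSet:
    """Greedy centroid clustering at an identity threshold.

    Identical sequences are first collapsed; unique sequences are processed
    in order of decreasing duplicate count, then decreasing length, then
    lexicographic id. Each sequence joins the first existing representative
    it matches at >= threshold identity, else founds a new cluster — a
    deterministic rendition of UCLUST-style centroid clustering.
    """
    if not reads:
        raise ValueError("no reads to cluster")
    groups: dict[str, list[str]] = defaultdict(list)
    first_rec: dict[str, SequenceRecord] = {}
    for rec in reads:
        groups[rec.seq].append(rec.id)
        first_rec.setdefault(rec.seq, rec)
    ordered = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1]), -len(kv[0]), min(kv[1])),
    )
    clusters: list[Cluster] = []
    for seq, ids in ordered:
        placed = False
        for cluster in clusters:
            aln = align_semi_global(seq, cluster.representative.seq, params)
            if aln.identity >= threshold:
                cluster.member_ids.extend(ids)
                placed = True
                break
        if not placed:
            rep = first_rec[seq]
            clusters.append(Cluster(representative=rep, member_ids=list(ids)))
    return ClusterSet(clusters=clusters, threshold=threshold)


def closed_reference_assign(
    cluster_set: ClusterSet,
    db: ReferenceIndex | Sequence[SequenceRecord],
    lineages: Mapping[str, TaxonomyLineage],
    sample_name: str = "sample",
    threshold: float = 0.97,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[OTUTable, int]:
    """Closed-reference OTU picking: representatives -> database accessions.

    Each representative is assigned by best hit with identity >= threshold;
    clusters whose representative matches nothing are discarded (their reads
    drop out of the table — the defining behaviour of closed-reference
    picking). Returns the single-sample table and the number of discarded
    reads.
    """
    index = db if isinstance(db, ReferenceIndex) else ReferenceIndex(db)
    counts: Counter[str] = Counter()
    dropped = 0
    for cluster in cluster_set.clusters:
        result = classify_read_best_hit(
            cluster.representative, index, min_identity=threshold, params=params
        )
        if result.classified:
            counts[result.assigned_accession] += cluster.size
        else:
            dropped += cluster.size
            logger.info(
                "closed-reference: dropped cluster %s (%d reads, best identity %.3f)",
                cluster.representative.id,
                cluster.size,
                result.identity,
            )
    taxa = sorted(counts)
    table = OTUTable(
        taxa=taxa,
        samples=[sample_name],
        counts=np.array([[counts[t]] for t in taxa], dtype=np.int64).reshape(len(taxa), 1),
        lineages={t: lineages[t] for t in taxa},
    )
    return table, dropped


def classification_table(
    results: Sequence[ClassificationResult],
    lineages: Mapping[str, TaxonomyLineage],
    sample_name: str = "sample",
) -> OTUTable:
    """Aggregate per-read best-hit assignments into a single-sample table."""
    counts = Counter(r.assigned_accession for r in results if r.classified)
    taxa = sorted(counts)
    return OTUTable(
        taxa=taxa,
        samples=[sample_name],
        counts=np.array([[counts[t]] for t in taxa], dtype=np.int64).reshape(len(taxa), 1),
        lineages={t: lineages[t] for t in taxa},
    )


@dataclass(frozen=True)
class QualityStats:
    per_read_mean: tuple[float, ...]
    sample_mean: float
    sample_median: float


def read_quality_stats(fastq: str | Path | Sequence[SequenceRecord]) -> QualityStats:
    """Per-read mean Phred scores and their sample-level mean and median.

    The per-read statistic is the arithmetic mean of per-base Phred integers
    (not the Phred of the mean error probability).
    """
    records = read_fastq(fastq) if isinstance(fastq, (str, Path)) else list(fastq)
    if not records:
        raise ValueError("no FASTQ records")
    means = []
    for rec in records:
        if rec.quality is None:
            raise ValueError(f"record {rec.id!r} has no quality scores")
        means.append(float(np.mean(rec.quality)))
    arr = np.array(means)
    return QualityStats(
        per_read_mean=tuple(means),
        sample_mean=float(arr.mean()),
        sample_median=float(np.median(arr)),
    )
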