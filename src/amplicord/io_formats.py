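"""Readers and writers for the external formats the pipeline touches.

All coordinates handed out by this module are 0-based, half-open intervals on
the forward strand; strand-specific coordinates in input files (MAF minus-strand
blocks) are converted at parse time. Sequences are uppercased on input and must
stay within the IUPAC nucleotide alphabet.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from skbio import TreeNode

IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with an optional per-base Phred quality track."""

    id: str
    seq: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, base in enumerate(self.seq):
            if base not in IUPAC_CODES:
                raise ValueError(
                    f"record {self.id!r}: non-IUPAC character {base!r} at position {pos}"
                )
        if self.quality is not None:
            if len(self.quality) != len(self.seq):
                raise ValueError(
                    f"record {self.id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.seq)}"
                )
            if any(q < 0 for q in self.quality):
                raise ValueError(f"record {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TaxonomyLineage:
    """A SILVA-style accession with its seven-rank lineage (domain..species)."""

    accession: str
    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(
                f"{self.accession}: lineage must have {len(RANKS)} ranks, "
                f"got {len(self.ranks)}"
            )

    def at(self, rank: str) -> str:
        return self.ranks[RANKS.index(rank)]

    def __str__(self) -> str:
        return ";".join(self.ranks)


def lineage_from_string(accession: str, text: str) -> TaxonomyLineage:
    """Build a lineage from a semicolon-delimited string, padding to 7 ranks."""
    parts = [p.strip() for p in text.split(";") if p.strip()]
    if not parts:
        raise ValueError(f"{accession}: empty lineage")
    if len(parts) > len(RANKS):
        parts = parts[: len(RANKS)]
    parts += [UNASSIGNED] * (len(RANKS) - len(parts))
    return TaxonomyLineage(accession=accession, ranks=tuple(parts))


@dataclass
class OTUTable:
    """Taxa × samples count matrix with lineage annotations.

    The central exchange object of the pipeline: classification produces
    single-sample tables, the concordance stage merges and filters them, and
    the diversity stage consumes them as community profiles.
    """

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (|taxa|, |samples|), non-negative integers
    lineages: dict[str, TaxonomyLineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(
            len(self.taxa), len(self.samples)
        )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in OTU table")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names in OTU table")
        if (self.counts < 0).any():
            raise ValueError("negative counts in OTU table")
        missing = [t for t in self.taxa if t not in self.lineages]
        if missing:
            raise ValueError(f"taxa without lineage entries: {missing[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)

    def sample_counts(self, sample: str) -> dict[str, int]:
        j = self.samples.index(sample)
        return {t: int(c) for t, c in zip(self.taxa, self.counts[:, j])}

    def relative_abundance(self) -> pd.DataFrame:
        df = self.to_frame().astype(float)
        totals = df.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total count")
        return df / totals

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
            and self.lineages == other.lineages
        )


@dataclass(frozen=True)
class PairwiseAlignmentRecord:
    """One gapped pairwise alignment, forward-strand half-open coordinates."""

    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    score: float
    query_span: tuple[int, int]
    ref_span: tuple[int, int]
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("gapped rows have unequal lengths")
        for q, r in zip(self.aligned_query, self.aligned_ref):
            if q == "-" and r == "-":
                raise ValueError("alignment column with gap in both rows")
        for name, span, row in (
            ("query", self.query_span, self.aligned_query),
            ("ref", self.ref_span, self.aligned_ref),
        ):
            ungapped = len(row) - row.count("-")
            if span[1] - span[0] != ungapped:
                raise ValueError(
                    f"{name}_span length {span[1] - span[0]} inconsistent with "
                    f"ungapped row length {ungapped}"
                )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, order preserved)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read Phred+33 FASTQ; quality decoded to integer scores per base."""
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            records.append(
                SequenceRecord(
                    id=rec.id,
                    seq=str(rec.seq).upper(),
                    quality=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:  # Biopython flags truncation / length parity
        raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                raise ValueError(f"record {rec.id!r} has no quality track")
            qual = "".join(chr(q + 33) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Taxonomy map


def parse_taxonomy_map(path: str | Path) -> dict[str, TaxonomyLineage]:
    """Parse a two-column accession<TAB>semicolon-lineage file.

    Lineages shorter than seven ranks are padded with the ``unassigned``
    sentinel so that rank aggregation always has a label to group on.
    """
    lineages: dict[str, TaxonomyLineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                accession, lineage_text = line.split("\t", 1)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected accession<TAB>lineage") from exc
            accession = accession.strip()
            if accession in lineages:
                raise ValueError(f"{path}:{lineno}: duplicate accession {accession!r}")
            lineages[accession] = lineage_from_string(accession, lineage_text)
    if not lineages:
        raise ValueError(f"no taxonomy entries in {path}")
    return lineages


def write_taxonomy_map(lineages: Mapping[str, TaxonomyLineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for accession in lineages:
            fh.write(f"{accession}\t{lineages[accession]}\n")


# ---------------------------------------------------------------------------
# MAF


def parse_maf(path: str | Path) -> list[PairwiseAlignmentRecord]:
    """Parse pairwise MAF blocks (reference 's' line first, query second).

    Minus-strand query coordinates are converted to forward-strand half-open
    intervals using the source sequence length carried by the MAF 's' line.
    """
    records: list[PairwiseAlignmentRecord] = []
    scores: list[float] = []
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return records
    for line in text.splitlines():  # Bio.AlignIO drops the "a" line scores
        if line.startswith("a"):
            fields = dict(
                part.split("=", 1) for part in line.split()[1:] if "=" in part
            )
            scores.append(float(fields.get("score", 0.0)))
    for block_index, block in enumerate(AlignIO.parse(str(path), "maf")):
        if len(block) != 2:
            raise ValueError(f"MAF block with {len(block)} sequence lines (expected 2)")
        ref, query = block[0], block[1]
        spans = []
        strands = []
        for rec in (ref, query):
            start = int(rec.annotations["start"])
            size = int(rec.annotations["size"])
            strand = rec.annotations["strand"]
            strand = "+" if strand in (1, "+") else "-"
            if strand == "-":
                src_size = int(rec.annotations["srcSize"])
                spans.append((src_size - start - size, src_size - start))
            else:
                spans.append((start, start + size))
            strands.append(strand)
        score = scores[block_index] if block_index < len(scores) else 0.0
        records.append(
            PairwiseAlignmentRecord(
                query_id=query.id,
                ref_id=ref.id,
                aligned_query=str(query.seq).upper(),
                aligned_ref=str(ref.seq).upper(),
                score=score,
                query_span=spans[1],
                ref_span=spans[0],
                strand="+" if strands[0] == strands[1] else "-",
            )
        )
    return records


# ---------------------------------------------------------------------------
# OTU table TSV

_LINEAGE_COL = "lineage"
_ACCESSION_COL = "accession"


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    """TSV layout: accession, one column per sample, lineage last."""
    with open(path, "w") as fh:
        fh.write("\t".join([_ACCESSION_COL, *table.samples, _LINEAGE_COL]) + "\n")
        for i, taxon in enumerate(table.taxa):
            counts = "\t".join(str(int(c)) for c in table.counts[i])
            row = f"{taxon}\t{counts}" if table.samples else taxon
            fh.write(f"{row}\t{table.lineages[taxon]}\n")


def read_otu_table(path: str | Path) -> OTUTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != _ACCESSION_COL or header[-1] != _LINEAGE_COL:
            raise ValueError(f"{path}: malformed OTU table header {header[:3]}...")
        samples = header[1:-1]
        taxa: list[str] = []
        rows: list[list[int]] = []
        lineages: dict[str, TaxonomyLineage] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns")
            accession = fields[0]
            counts = []
            for col, cell in enumerate(fields[1:-1], start=2):
                try:
                    value = int(cell)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed count {cell!r} in column {col}"
                    ) from exc
                if value < 0:
                    raise ValueError(f"{path}:{lineno}: negative count in column {col}")
                counts.append(value)
            taxa.append(accession)
            rows.append(counts)
            lineages[accession] = lineage_from_string(accession, fields[-1])
    counts_arr = np.asarray(rows, dtype=np.int64).reshape(len(taxa), len(samples))
    return OTUTable(taxa=taxa, samples=samples, counts=counts_arr, lineages=lineages)


# ---------------------------------------------------------------------------
# Newick


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a rooted tree with branch lengths."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    names = [tip.name for tip in tree.tips()]
    if any(n is None for n in names):
        raise ValueError("Newick tree with unnamed leaf")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf names: {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at {node.name!r}")
    return tree


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
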