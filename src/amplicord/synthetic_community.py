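"""Synthetic 16S-like reference databases, communities, and platform reads.

The generator emulates the statistical structure the downstream analysis
relies on, without any real sequence download:

* full-length (~1.4 kb) reference sequences with nine variable regions
  (V1..V9) embedded in a conserved scaffold shared across the database,
  carrying exact binding sites for both the full-gene primer pair and the
  V3-V4 primer pair;
* designated *confusable groups*: sets of taxa byte-identical across the
  whole V3-V4 amplicon but divergent everywhere else — the property that
  makes short-read classification ambiguous while full-length reads remain
  resolvable;
* community abundance profiles (even / staggered / lognormal);
* nanopore-like long single reads of the full amplicon with a ~5.4%
  per-base error rate (the rate implied by a mean Phred quality of about
  12.65 via Q = -10*log10(p)), split substitution:insertion:deletion =
  10:2.5:1;
* Illumina-like paired 2x250 reads of the V3-V4 amplicon with a 0.3%
  substitution-only error model and high (mean Q35) qualities.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .insilico_pcr import (
    IUPAC_SETS,
    LONG_READ_PRIMERS,
    SHORT_READ_PRIMERS,
    Primer,
    extract_amplicon,
    reverse_complement,
)
from .io_formats import RANKS, SequenceRecord, TaxonomyLineage, write_fastq

# Sequence layout: (segment name, length). Conserved blocks ("c*") and primer
# binding sites are shared across a database; V1..V9 vary per taxon. The
# V3-V4 amplicon (short_fwd_site .. short_rev_site inclusive) is 440 bp, so
# 2x250 mates overlap by 60 bp; the full-gene amplicon is the whole 1,447 bp
# sequence.
_LAYOUT: tuple[tuple[str, int], ...] = (
    ("long_fwd_site", 20),
    ("c0", 30),
    ("V1", 100),
    ("c1", 30),
    ("V2", 100),
    ("c2", 30),
    ("short_fwd_site", 17),
    ("c3", 21),
    ("V3", 150),
    ("c4", 40),
    ("V4", 150),
    ("c5", 41),
    ("short_rev_site", 21),
    ("c6", 30),
    ("V5", 100),
    ("c7", 30),
    ("V6", 100),
    ("c8", 30),
    ("V7", 100),
    ("c9", 30),
    ("V8", 100),
    ("c10", 30),
    ("V9", 100),
    ("c11", 30),
    ("long_rev_site", 17),
)

SEQ_LENGTH = sum(length for _, length in _LAYOUT)
VARIABLE_REGIONS = tuple(f"V{i}" for i in range(1, 10))

_BASES = np.array(list("ACGT"))

# Long-read error model back-computed from the reported mean read quality:
# p = 10^(-12.65/10) ~= 5.43% total, split 10:2.5:1 sub:ins:del.
LONG_READ_MEAN_PHRED = 12.65
_P_TOTAL = 10 ** (-LONG_READ_MEAN_PHRED / 10)
LONG_SUB_RATE = _P_TOTAL * 10 / 13.5
LONG_INS_RATE = _P_TOTAL * 2.5 / 13.5
LONG_DEL_RATE = _P_TOTAL * 1 / 13.5


def _segment_coords() -> dict[str, tuple[int, int]]:
    coords = {}
    pos = 0
    for name, length in _LAYOUT:
        coords[name] = (pos, pos + length)
        pos += length
    return coords


SEGMENT_COORDS = _segment_coords()


@dataclass(frozen=True)
class SyntheticTaxon:
    """One reference taxon: lineage, full-length sequence, region annotation."""

    lineage: TaxonomyLineage
    seq: str
    region_map: tuple[tuple[str, int, int], ...]
    confusable_group: int | None = None

    @property
    def accession(self) -> str:
        return self.lineage.accession

    def region(self, name: str) -> str:
        for rname, start, end in self.region_map:
            if rname == name:
                return self.seq[start:end]
        raise KeyError(name)

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(id=self.accession, seq=self.seq)


@dataclass(frozen=True)
class CommunityProfile:
    """Relative-abundance composition of one sample."""

    composition: dict[str, float]
    sample_name: str

    def __post_init__(self) -> None:
        if not self.composition:
            raise ValueError("empty community profile")
        if any(v <= 0 for v in self.composition.values()):
            raise ValueError("all abundances must be > 0")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")


@dataclass(frozen=True)
class ReadSimConfig:
    """Platform error/quality model for read simulation."""

    platform: Literal["long_single", "short_paired"]
    n_reads: int
    sub_rate: float
    ins_rate: float = 0.0
    del_rate: float = 0.0
    read_length: int = 250
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (
            ("sub_rate", self.sub_rate),
            ("ins_rate", self.ins_rate),
            ("del_rate", self.del_rate),
        ):
            if not (0 <= rate < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 0.5:
            raise ValueError("total error rate must be < 0.5")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.platform not in ("long_single", "short_paired"):
            raise ValueError(f"unknown platform {self.platform!r}")


def long_read_config(n_reads: int, seed: int = 0, error_scale: float = 1.0) -> ReadSimConfig:
    """Nanopore-like defaults; ``error_scale`` 0 gives error-free reads."""
    return ReadSimConfig(
        platform="long_single",
        n_reads=n_reads,
        sub_rate=LONG_SUB_RATE * error_scale,
        ins_rate=LONG_INS_RATE * error_scale,
        del_rate=LONG_DEL_RATE * error_scale,
        quality_mean=LONG_READ_MEAN_PHRED,
        quality_sd=3.0,
        seed=seed,
    )


def short_read_config(n_reads: int, seed: int = 0, error_scale: float = 1.0) -> ReadSimConfig:
    """Illumina-like defaults: 2x250, substitution-only 0.3% error."""
    return ReadSimConfig(
        platform="short_paired",
        n_reads=n_reads,
        sub_rate=0.003 * error_scale,
        read_length=250,
        quality_mean=35.0,
        quality_sd=3.0,
        seed=seed,
    )


def _realize_primer(primer: Primer, rng: np.random.Generator) -> str:
    """Pick one concrete sequence from a degenerate primer."""
    return "".join(
        b if b in "ACGT" else str(rng.choice(sorted(IUPAC_SETS[b])))
        for b in primer.seq
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _lineage(i: int, group: int | None) -> TaxonomyLineage:
    accession = f"SYN{i:04d}.1.{SEQ_LENGTH}"
    genus = f"Genus_cg{group:02d}" if group is not None else f"Genus_{i:03d}"
    return TaxonomyLineage(
        accession=accession,
        ranks=(
            "Bacteria",
            f"Phylum_{i // 8:02d}",
            f"Class_{i // 4:02d}",
            f"Order_{i // 2:02d}",
            f"Family_{i // 2:02d}",
            genus,
            f"Species_{i:03d}",
        ),
    )


def build_reference_db(
    n_taxa: int,
    n_confusable_groups: int = 0,
    group_size: int = 2,
    seed: int = 0,
) -> list[SyntheticTaxon]:
    """Build a synthetic full-length reference database.

    Taxa 0 .. n_confusable_groups*group_size-1 are organised into confusable
    groups (consecutive runs of ``group_size``) whose members share a
    byte-identical V3-V4 amplicon region but independent V1/V2/V5..V9, i.e.
    they are distinguishable by full-length reads only. All primer binding
    sites are present exactly (0 mismatches) in every taxon.
    """
    if n_taxa <= 0:
        raise ValueError("n_taxa must be positive")
    if n_confusable_groups < 0 or group_size < 2:
        raise ValueError("need n_confusable_groups >= 0 and group_size >= 2")
    if n_confusable_groups * group_size > n_taxa:
        raise ValueError(
            f"{n_confusable_groups} groups of {group_size} exceed {n_taxa} taxa"
        )
    rng = np.random.default_rng(seed)
    long_fwd, long_rev = LONG_READ_PRIMERS
    short_fwd, short_rev = SHORT_READ_PRIMERS
    fixed_segments = {
        "long_fwd_site": _realize_primer(long_fwd, rng),
        "short_fwd_site": _realize_primer(short_fwd, rng),
        "short_rev_site": reverse_complement(_realize_primer(short_rev, rng)),
        "long_rev_site": reverse_complement(_realize_primer(long_rev, rng)),
    }
    for name, length in _LAYOUT:
        if name.startswith("c"):
            fixed_segments[name] = _random_seq(rng, length)

    shared_v34: dict[int, dict[str, str]] = {}
    taxa: list[SyntheticTaxon] = []
    for i in range(n_taxa):
        group: int | None = None
        if i < n_confusable_groups * group_size:
            group = i // group_size
        variable: dict[str, str] = {}
        for name, length in _LAYOUT:
            if name in VARIABLE_REGIONS:
                variable[name] = _random_seq(rng, length)
        if group is not None:
            if group in shared_v34:
                variable["V3"] = shared_v34[group]["V3"]
                variable["V4"] = shared_v34[group]["V4"]
            else:
                shared_v34[group] = {"V3": variable["V3"], "V4": variable["V4"]}
        parts = []
        region_map = []
        pos = 0
        for name, length in _LAYOUT:
            seg = variable.get(name, fixed_segments.get(name))
            parts.append(seg)
            if name in VARIABLE_REGIONS:
                region_map.append((name, pos, pos + length))
            pos += length
        taxa.append(
            SyntheticTaxon(
                lineage=_lineage(i, group),
                seq="".join(parts),
                region_map=tuple(region_map),
                confusable_group=group,
            )
        )
    return taxa


def db_records(db: Sequence[SyntheticTaxon]) -> list[SequenceRecord]:
    return [t.to_record() for t in db]


def db_lineages(db: Sequence[SyntheticTaxon]) -> dict[str, TaxonomyLineage]:
    return {t.accession: t.lineage for t in db}


def sample_community(
    db: Sequence[SyntheticTaxon],
    model: Literal["even", "staggered", "lognormal"] = "even",
    n_taxa: int | None = None,
    seed: int = 0,
    sample_name: str = "sample",
) -> CommunityProfile:
    """Draw a community composition over a subset of the database.

    ``even`` gives equal abundances; ``staggered`` spans exactly three orders
    of magnitude (geometric series, max/min = 1000); ``lognormal`` draws
    abundances from LogNormal(0, 1.5) and normalises.
    """
    rng = np.random.default_rng(seed)
    n = len(db) if n_taxa is None else n_taxa
    if n > len(db):
        raise ValueError(f"n_taxa {n} exceeds database size {len(db)}")
    if n < 1:
        raise ValueError("n_taxa must be >= 1")
    chosen = sorted(rng.choice(len(db), size=n, replace=False))
    accessions = [db[i].accession for i in chosen]
    if model == "even":
        weights = np.ones(n)
    elif model == "staggered":
        # slightly over three decades so the >= 10^3 span survives
        # floating-point normalisation
        weights = 10 ** (-3.01 * np.arange(n) / max(n - 1, 1))
    elif model == "lognormal":
        weights = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    weights = weights / weights.sum()
    # push residual rounding into the largest entry so the sum is exact
    composition = dict(zip(accessions, weights))
    top = max(composition, key=composition.get)
    composition[top] += 1.0 - sum(composition.values())
    return CommunityProfile(composition=composition, sample_name=sample_name)


def _mutate(
    seq: str, rng: np.random.Generator, sub: float, ins: float, dele: float
) -> str:
    """Per-base substitution / insertion / deletion process."""
    if sub == 0 and ins == 0 and dele == 0:
        return seq
    out: list[str] = []
    for base in seq:
        u = rng.random()
        if u < dele:
            pass  # base dropped
        elif u < dele + sub:
            out.append(str(rng.choice([b for b in "ACGT" if b != base])))
        else:
            out.append(base)
        if ins > 0 and rng.random() < ins:
            out.append(str(_BASES[rng.integers(0, 4)]))
    return "".join(out)


def _qualities(rng: np.random.Generator, n: int, mean: float, sd: float) -> tuple[int, ...]:
    q = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return tuple(np.clip(q, 1, 41))


def _taxon_amplicons(
    db: Sequence[SyntheticTaxon],
    profile: CommunityProfile,
    primers: tuple[Primer, Primer],
) -> dict[str, str]:
    by_id = {t.accession: t for t in db}
    amplicons: dict[str, str] = {}
    for accession in profile.composition:
        if accession not in by_id:
            raise ValueError(f"profile taxon {accession} not in database")
        amp = extract_amplicon(by_id[accession].to_record(), primers[0], primers[1])
        if amp is None:
            raise ValueError(f"taxon {accession} lacks primer sites for {primers[0].name}")
        amplicons[accession] = amp.full
    return amplicons


def simulate_long_reads(
    db: Sequence[SyntheticTaxon],
    profile: CommunityProfile,
    config: ReadSimConfig,
    out_fastq: str | Path | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate full-gene single reads.

    Reads are drawn multinomially from the profile; each read is the full
    amplicon between the full-gene primer pair, passed through the per-base
    error process. Returns the reads and a provenance table mapping read id
    to true source accession.
    """
    if config.platform != "long_single":
        raise ValueError("config.platform must be 'long_single'")
    rng = np.random.default_rng(config.seed)
    amplicons = _taxon_amplicons(db, profile, LONG_READ_PRIMERS)
    accessions = sorted(profile.composition)
    probs = np.array([profile.composition[a] for a in accessions])
    counts = rng.multinomial(config.n_reads, probs)
    reads: list[SequenceRecord] = []
    provenance = []
    idx = 0
    for accession, count in zip(accessions, counts):
        for _ in range(count):
            seq = _mutate(
                amplicons[accession], rng, config.sub_rate, config.ins_rate, config.del_rate
            )
            read_id = f"{profile.sample_name}_long_{idx:06d}"
            reads.append(
                SequenceRecord(
                    id=read_id,
                    seq=seq,
                    quality=_qualities(rng, len(seq), config.quality_mean, config.quality_sd),
                )
            )
            provenance.append({"read_id": read_id, "true_accession": accession})
            idx += 1
    if out_fastq is not None:
        write_fastq(reads, out_fastq)
    return reads, pd.DataFrame(provenance)


def simulate_short_paired_reads(
    db: Sequence[SyntheticTaxon],
    profile: CommunityProfile,
    config: ReadSimConfig,
    out_fastq_r1: str | Path | None = None,
    out_fastq_r2: str | Path | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Simulate paired short reads of the V3-V4 amplicon.

    R1 is the first ``read_length`` bases of the amplicon, R2 the reverse
    complement of the last ``read_length`` bases, each passed independently
    through the (substitution-dominated) error process.
    """
    if config.platform != "short_paired":
        raise ValueError("config.platform must be 'short_paired'")
    rng = np.random.default_rng(config.seed)
    amplicons = _taxon_amplicons(db, profile, SHORT_READ_PRIMERS)
    accessions = sorted(profile.composition)
    probs = np.array([profile.composition[a] for a in accessions])
    counts = rng.multinomial(config.n_reads, probs)
    r1_reads: list[SequenceRecord] = []
    r2_reads: list[SequenceRecord] = []
    provenance = []
    idx = 0
    length = config.read_length
    for accession, count in zip(accessions, counts):
        amp = amplicons[accession]
        r1_src = amp[:length]
        r2_src = reverse_complement(amp[-length:])
        for _ in range(count):
            base_id = f"{profile.sample_name}_short_{idx:06d}"
            for mate, src, bucket in (("1", r1_src, r1_reads), ("2", r2_src, r2_reads)):
                seq = _mutate(src, rng, config.sub_rate, config.ins_rate, config.del_rate)
                bucket.append(
                    SequenceRecord(
                        id=f"{base_id}/{mate}",
                        seq=seq,
                        quality=_qualities(
                            rng, len(seq), config.quality_mean, config.quality_sd
                        ),
                    )
                )
            provenance.append({"read_id": base_id, "true_accession": accession})
            idx += 1
    if out_fastq_r1 is not None:
        write_fastq(r1_reads, out_fastq_r1)
    if out_fastq_r2 is not None:
        write_fastq(r2_reads, out_fastq_r2)
    return r1_reads, r2_reads, pd.DataFrame(provenance)


def merge_paired_reads(
    r1: SequenceRecord,
    r2: SequenceRecord,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> SequenceRecord | None:
    """Merge a mate pair by overlap; ``None`` when no overlap qualifies.

    R2 is reverse-complemented, all overlap lengths >= ``min_overlap`` are
    scanned, and among overlaps with mismatch fraction <= ``max_mismatch_frac``
    the one with the most matching bases wins. Disagreeing overlap bases are
    resolved to the higher-quality base (R1 wins quality ties).
    """
    r2_seq = reverse_complement(r2.seq)
    r2_qual = tuple(reversed(r2.quality)) if r2.quality is not None else None
    best: tuple[int, int] | None = None  # (matches, overlap)
    max_olap = min(len(r1.seq), len(r2_seq))
    for olap in range(min_overlap, max_olap + 1):
        a = r1.seq[-olap:]
        b = r2_seq[:olap]
        mismatches = sum(1 for x, y in zip(a, b) if x != y)
        if mismatches / olap > max_mismatch_frac:
            continue
        matches = olap - mismatches
        if best is None or matches > best[0] or (matches == best[0] and olap > best[1]):
            best = (matches, olap)
    if best is None:
        return None
    olap = best[1]
    head = r1.seq[:-olap]
    tail = r2_seq[olap:]
    q1 = r1.quality if r1.quality is not None else (0,) * len(r1.seq)
    q2 = r2_qual if r2_qual is not None else (0,) * len(r2_seq)
    mid: list[str] = []
    mid_q: list[int] = []
    for k in range(olap):
        b1 = r1.seq[len(r1.seq) - olap + k]
        b2 = r2_seq[k]
        quality1 = q1[len(r1.seq) - olap + k]
        quality2 = q2[k]
        if b1 == b2:
            mid.append(b1)
            mid_q.append(max(quality1, quality2))
        elif quality2 > quality1:
            mid.append(b2)
            mid_q.append(quality2)
        else:
            mid.append(b1)
            mid_q.append(quality1)
    merged_id = r1.id.split("/")[0]
    quality = tuple(q1[: len(head)]) + tuple(mid_q) + tuple(q2[olap:])
    return SequenceRecord(id=merged_id, seq=head + "".join(mid) + tail, quality=quality)


def merge_read_pairs(
    r1_reads: Sequence[SequenceRecord],
    r2_reads: Sequence[SequenceRecord],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[SequenceRecord], int]:
    """Merge parallel mate lists; returns (merged reads, n_failed)."""
    if len(r1_reads) != len(r2_reads):
        raise ValueError("mate lists differ in length")
    merged: list[SequenceRecord] = []
    failed = 0
    for r1, r2 in zip(r1_reads, r2_reads):
        result = merge_paired_reads(r1, r2, min_overlap, max_mismatch_frac)
        if result is None:
            failed += 1
        else:
            merged.append(result)
    return merged, failed
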