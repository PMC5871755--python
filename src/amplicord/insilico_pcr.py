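"""Degenerate-primer matching, amplicon extraction, and the virtual-PCR audit.

Primer matching is gapless (Hamming) against every window of the template on
both strands, the standard virtual-PCR semantics. IUPAC ambiguity codes in the
primer match their full nucleotide set; ``N`` matches everything. The audit
side (``virtual_pcr_table`` + ``primer_bias_correlation``) asks whether primer
mismatches or GC content of a taxon predict its observed abundance — i.e.
whether PCR amplification itself biased the community profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SequenceRecord

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    """A named degenerate primer, written 5'→3'."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        bad = [b for b in self.seq if b not in IUPAC_SETS]
        if bad:
            raise ValueError(f"primer {self.name!r}: non-IUPAC characters {bad}")

    def __len__(self) -> int:
        return len(self.seq)


# The study's primer pairs. The short-read pair is stored with the sequencing
# overhang adapters already trimmed: only the locus-specific 3' parts bind the
# template, so only they participate in matching.
LONG_READ_PRIMERS = (
    Primer("S-D-bact-0008-c-S-20", "AGRGTTYGATYMTGGCTCAG"),
    Primer("S-D-bact-1391-a-A-17", "GACGGGCGGTGWGTRCA"),
)
SHORT_READ_PRIMERS = (
    Primer("341F", "CCTACGGGNGGCWGCAG"),
    Primer("805R", "GACTACHVGGGTATCTAATCC"),
)


class PrimerMatch(NamedTuple):
    """One primer binding site: half-open forward-strand interval."""

    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product on a template sequence.

    ``insert`` is the template strictly between the two primer 3' ends
    (what remains after primer trimming); ``full`` includes the primer
    binding sites; ``coords`` is the half-open interval of ``full``.
    """

    source_accession: str
    insert: str
    full: str
    coords: tuple[int, int]

    def __post_init__(self) -> None:
        if self.insert not in self.full:
            raise ValueError("amplicon insert is not a substring of full product")


def iupac_mismatches(primer: str, window: str) -> int:
    """Count window positions not covered by the primer base's IUPAC set."""
    if len(primer) != len(window):
        raise ValueError(f"primer length {len(primer)} != window length {len(window)}")
    return sum(
        1 for p, w in zip(primer, window) if w not in IUPAC_SETS.get(p, frozenset())
    )


def find_primer_sites(
    seq: str, primer: Primer | str, max_mismatch: int = 0
) -> list[PrimerMatch]:
    """All binding sites of a primer on both strands, sorted by position.

    Minus-strand sites are windows matching the primer's reverse complement;
    their coordinates are reported on the forward strand.
    """
    pseq = primer.seq if isinstance(primer, Primer) else primer
    k = len(pseq)
    if k > len(seq):
        return []
    rc = reverse_complement(pseq)
    hits: list[PrimerMatch] = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mm = iupac_mismatches(pseq, window)
        if mm <= max_mismatch:
            hits.append(PrimerMatch(i, i + k, "+", mm))
        mm_rc = iupac_mismatches(rc, window)
        if mm_rc <= max_mismatch:
            hits.append(PrimerMatch(i, i + k, "-", mm_rc))
    return hits


def extract_amplicon(
    record: SequenceRecord,
    fwd_primer: Primer | str,
    rev_primer: Primer | str,
    max_mismatch: int = 0,
    min_insert: int = 50,
) -> Amplicon | None:
    """Extract the virtual PCR product of a primer pair, or None.

    The forward primer must bind the plus strand and the reverse primer the
    minus strand downstream of it. Among candidate pairs, the shortest product
    whose insert is at least ``min_insert`` long wins. Returns ``None``
    (a failure state, not an error) when no qualifying pair exists.
    """
    fwd_sites = [
        m for m in find_primer_sites(record.seq, fwd_primer, max_mismatch) if m.strand == "+"
    ]
    rev_sites = [
        m for m in find_primer_sites(record.seq, rev_primer, max_mismatch) if m.strand == "-"
    ]
    best: Amplicon | None = None
    for f in fwd_sites:
        for r in rev_sites:
            if r.start < f.end:
                continue
            insert = record.seq[f.end : r.start]
            if len(insert) < min_insert:
                continue
            candidate = Amplicon(
                source_accession=record.id,
                insert=insert,
                full=record.seq[f.start : r.end],
                coords=(f.start, r.end),
            )
            if best is None or len(candidate.full) < len(best.full):
                best = candidate
    return best


def virtual_pcr_table(
    db: Sequence[SequenceRecord] | Iterable,
    primer_pair: tuple[Primer, Primer],
    max_mismatch: int = 3,
) -> pd.DataFrame:
    """Per-taxon minimal primer mismatch counts and amplifiability.

    Scans each template for the best (fewest-mismatch) site of the forward
    primer on the plus strand and the reverse primer on the minus strand,
    allowing up to ``max_mismatch`` mismatches. A taxon is amplifiable when
    both primers bind within the allowance.
    """
    fwd, rev = primer_pair
    rows = []
    records = list(db)
    if not records:
        raise ValueError("empty reference database")
    for rec in records:
        seq = rec.seq if isinstance(rec, SequenceRecord) else rec.seq
        fwd_hits = [m for m in find_primer_sites(seq, fwd, max_mismatch) if m.strand == "+"]
        rev_hits = [m for m in find_primer_sites(seq, rev, max_mismatch) if m.strand == "-"]
        fwd_mm = min((m.mismatches for m in fwd_hits), default=max_mismatch + 1)
        rev_mm = min((m.mismatches for m in rev_hits), default=max_mismatch + 1)
        rows.append(
            {
                "accession": rec.id,
                "fwd_mismatches": fwd_mm,
                "rev_mismatches": rev_mm,
                "amplifiable": fwd_mm <= max_mismatch and rev_mm <= max_mismatch,
            }
        )
    return pd.DataFrame(rows).set_index("accession")


def gc_content(seq: str) -> float:
    """G+C fraction over unambiguous bases; ambiguity codes are excluded."""
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


class CorrelationResult(NamedTuple):
    rho: float
    p_value: float
    computable: bool


def primer_bias_correlation(
    feature: Sequence[float] | pd.Series,
    abundance: Sequence[float] | pd.Series,
    n_permutations: int = 9999,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rho between a per-taxon feature and abundance, permutation p.

    The p-value is two-sided, from seeded label permutations of the abundance
    vector: p = (1 + #{|rho_perm| >= |rho|}) / (1 + n_permutations). A constant
    feature or abundance vector makes rho undefined; that is reported as a
    not-computable state rather than an error.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(abundance, dtype=float)
    if x.shape != y.shape:
        raise ValueError("feature and abundance vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 taxa for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, False)
    rho = stats.spearmanr(x, y).statistic
    rng = np.random.default_rng(seed)
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(yr)
        r = np.corrcoef(xr, perm)[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return CorrelationResult(float(rho), float(p), True)
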