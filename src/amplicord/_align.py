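"""Semi-global alignment engine (numba-compiled dynamic programming).

Default scoring follows the long-read mapping parameters used throughout the
package: match +1, mismatch -1, gap open -1 charged on the first gap base and
gap extend -1 on each subsequent one — i.e. a linear -1 per gap base. Only
linear gap costs (open == extend) are supported. The query is aligned
end-to-end; leading and trailing gaps on the reference are free
(query-global, reference-local), which is the right shape for an amplicon
read against a full-length reference.

Traceback tie-breaks are fixed: diagonal (match preferred over mismatch),
then gap-in-reference (consume query), then gap-in-query. The reference end
column is the first (leftmost) column attaining the optimal score.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; ambiguity codes become the sentinel 4, which
    never scores as a match — reads are not rewarded for ambiguous bases."""
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()
    arr[arr < 0] = 4
    return arr


@njit(cache=True)
def _sg_score(q, r, match, mismatch, gap):
    """Optimal semi-global score only (no traceback)."""
    n, m = q.shape[0], r.shape[0]
    prev = np.zeros(m + 1, dtype=np.int32)
    cur = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        cur[0] = gap * i
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == r[j - 1] and qi != 4) else mismatch
            v = prev[j - 1] + s
            if prev[j] + gap > v:
                v = prev[j] + gap
            if cur[j - 1] + gap > v:
                v = cur[j - 1] + gap
            cur[j] = v
        tmp = prev
        prev = cur
        cur = tmp
    best = prev[0]
    for j in range(1, m + 1):
        if prev[j] > best:
            best = prev[j]
    return best


@njit(cache=True)
def _sg_traceback(q, r, match, mismatch, gap):
    """Full DP with traceback.

    Returns (score, ops, ref_start, ref_end) where ops is a uint8 array over
    the aligned span, 0 = diagonal, 1 = gap in reference (consume query),
    2 = gap in query (consume reference), ordered 5'->3'.
    """
    n, m = q.shape[0], r.shape[0]
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    P = np.zeros((n + 1, m + 1), dtype=np.uint8)
    for j in range(m + 1):
        H[0, j] = 0
    for i in range(1, n + 1):
        H[i, 0] = gap * i
        P[i, 0] = 1
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == r[j - 1] and qi != 4) else mismatch
            diag = H[i - 1, j - 1] + s
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            # tie preference: diagonal > gap-in-ref (up) > gap-in-query (left)
            v = diag
            p = np.uint8(0)
            if up > v:
                v = up
                p = np.uint8(1)
            if left > v:
                v = left
                p = np.uint8(2)
            H[i, j] = v
            P[i, j] = p
    end_j = 0
    best = H[n, 0]
    for j in range(1, m + 1):
        if H[n, j] > best:
            best = H[n, j]
            end_j = j
    ops = np.empty(n + m, dtype=np.uint8)
    k = 0
    i, j = n, end_j
    while i > 0:
        p = P[i, j]
        ops[k] = p
        k += 1
        if p == 0:
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return best, ops[:k][::-1].copy(), j, end_j


MAX_ALIGN_LENGTH = 5000


def _check(query: str, ref: str, cap: int) -> None:
    if not query or not ref:
        raise ValueError("cannot align empty sequences")
    if len(query) > cap or len(ref) > cap:
        raise ValueError(
            f"sequence longer than alignment cap {cap} "
            f"(query {len(query)}, ref {len(ref)})"
        )


def semi_global_score(
    query: str,
    ref: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -1,
    cap: int = MAX_ALIGN_LENGTH,
) -> int:
    """Score-only DP; used to rank candidate references cheaply."""
    _check(query, ref, cap)
    if query in ref:  # exact containment: the optimum is a full-length match
        return match * len(query)
    return int(_sg_score(encode(query), encode(ref), match, mismatch, gap))


def semi_global_align(
    query: str,
    ref: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -1,
    cap: int = MAX_ALIGN_LENGTH,
):
    """Full alignment.

    Returns (score, aligned_query, aligned_ref, query_span, ref_span,
    n_match, n_columns). Spans are half-open; columns cover the aligned span
    only (free end gaps on the reference are excluded).
    """
    _check(query, ref, cap)
    if query in ref:
        start = ref.index(query)
        n = len(query)
        return (
            match * n,
            query,
            ref[start : start + n],
            (0, n),
            (start, start + n),
            n,
            n,
        )
    score, ops, ref_start, ref_end = _sg_traceback(
        encode(query), encode(ref), match, mismatch, gap
    )
    qi = 0
    rj = ref_start
    aq: list[str] = []
    ar: list[str] = []
    n_match = 0
    for op in ops:
        if op == 0:
            aq.append(query[qi])
            ar.append(ref[rj])
            if query[qi] == ref[rj]:
                n_match += 1
            qi += 1
            rj += 1
        elif op == 1:
            aq.append(query[qi])
            ar.append("-")
            qi += 1
        else:
            aq.append("-")
            ar.append(ref[rj])
            rj += 1
    return (
        int(score),
        "".join(aq),
        "".join(ar),
        (0, len(query)),
        (int(ref_start), int(ref_end)),
        n_match,
        len(ops),
    )


def warm_up() -> None:
    """Trigger JIT compilation once (e.g. at pipeline start)."""
    semi_global_score("ACGT", "ACTGT")
    semi_global_align("ACGT", "ACTGT")
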