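"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: boolean position masks for all
interval algebra, and a full dynamic-programming affine-gap local aligner
for identity/coverage. None of it calls the code under test.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def mask_from_spans(spans, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in spans:
        mask[s:e] = True
    return mask


def spans_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            in_run = False
            out.append((start, i))
    if in_run:
        out.append((start, len(mask)))
    return out


def fill_gaps(mask: np.ndarray, gap_max: int) -> np.ndarray:
    out = mask.copy()
    covered = np.flatnonzero(mask)
    for a, b in zip(covered[:-1], covered[1:]):
        if 1 < b - a <= gap_max + 1:
            out[a:b] = True
    return out


def exclusive_residues(refseq_spans, te_spans, length: int) -> int:
    ref = mask_from_spans(refseq_spans, length)
    te = mask_from_spans(te_spans, length)
    return int((ref & ~te).sum()) // 3


def host_gene_flag(refseq_spans, te_spans, length: int, min_residues: int = 90) -> bool:
    ref = mask_from_spans(refseq_spans, length)
    te = mask_from_spans(te_spans, length)
    if not ref.any():
        return False
    if not te.any():
        return True
    return exclusive_residues(refseq_spans, te_spans, length) >= min_residues


def three_way_counts(a_spans, b_spans, length: int) -> tuple[int, int, int]:
    """(both, only-A, only-B) position counts."""
    a = mask_from_spans(a_spans, length)
    b = mask_from_spans(b_spans, length)
    return int((a & b).sum()), int((a & ~b).sum()), int((b & ~a).sum())


# ---------------------------------------------------------------------------
# full-DP affine-gap local aligner


@njit(cache=False)
def _sw_fill(a, b, match, mismatch, gopen, gext):
    n, m = a.shape[0], b.shape[0]
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptrH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    ptrE = np.zeros((n + 1, m + 1), np.uint8)  # 1 opened from H
    ptrF = np.zeros((n + 1, m + 1), np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gopen
            e_ext = E[i, j - 1] + gext
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] + gopen
            f_ext = F[i - 1, j] + gext
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            val = 0.0
            ptr = 0
            if diag > val:
                val = diag
                ptr = 1
            if F[i, j] > val:
                val = F[i, j]
                ptr = 2
            if E[i, j] > val:
                val = E[i, j]
                ptr = 3
            H[i, j] = val
            ptrH[i, j] = ptr
            if val > best:
                best = val
                bi = i
                bj = j
    return H, ptrH, ptrE, ptrF, best, bi, bj


def sw_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gopen: float = -2.0,
    gext: float = -1.0,
) -> tuple[float, float, float]:
    """Optimal local alignment by full quadratic DP with affine gaps.

    Returns (score, identity, coverage_of_shorter). The gap model scores
    the first gap column ``gopen`` and each further column ``gext``.
    Traceback prefers diagonal moves on ties.
    """
    av = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bv = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    H, ptrH, ptrE, ptrF, best, bi, bj = _sw_fill(
        av, bv, match, mismatch, gopen, gext
    )
    if best <= 0:
        return 0.0, 0.0, 0.0
    i, j = bi, bj
    matches = columns = 0
    state = "H"
    while True:
        if state == "H":
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                matches += int(av[i - 1] == bv[j - 1])
                i -= 1
                j -= 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            columns += 1
            opened = ptrF[i, j]
            i -= 1
            state = "H" if opened else "F"
        else:
            columns += 1
            opened = ptrE[i, j]
            j -= 1
            state = "H" if opened else "E"
    span_a, span_b = bi - i, bj - j
    identity = matches / columns if columns else 0.0
    if len(av) <= len(bv):
        cov_short = span_a / len(av)
    else:
        cov_short = span_b / len(bv)
    return float(best), identity, cov_short


def sw_meets_family_rule(
    a: str, b: str, min_identity: float = 0.80, min_coverage: float = 0.80
) -> bool:
    """80-80-80 acceptance check on either strand, by full DP."""
    comp = str.maketrans("ACGTN", "TGCAN")
    for query in (b, b.upper().translate(comp)[::-1]):
        _, ident, cov = sw_align(a, query)
        if ident >= min_identity and cov >= min_coverage:
            return True
    return False


def random_spans(rng: np.random.Generator, length: int, max_n: int = 12):
    n = int(rng.integers(0, max_n + 1))
    spans = []
    for _ in range(n):
        s = int(rng.integers(0, length - 1))
        e = int(rng.integers(s + 1, min(length, s + 1 + int(rng.integers(1, 400)))))
        spans.append((s, e))
    return spans
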