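"""Global pairwise alignment and the identity measure used by every
capture and assignment decision.

The aligner is a full-matrix Needleman–Wunsch/Gotoh dynamic programme with
affine gaps (a gap of length L costs ``gap_open + L * gap_extend``) and
deterministic traceback tie-breaking (prefer diagonal, then up, then left).
Identity is ``matches / columns`` where columns exclude leading and trailing
terminal-gap runs, so a short tag nested inside a longer reference is not
penalised for length; the CD-HIT convention (matches over the shorter
sequence's length) is available via ``denominator="shorter"``.

``N`` scores and counts as a mismatch against everything, including ``N``.

The inner loops are numba-compiled; on first use in a session there is a
one-off JIT compilation cost of a few seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "Scoring",
    "DEFAULT_SCORING",
    "AlignmentResult",
    "encode",
    "global_align",
    "align_ops",
    "align_stats",
    "identity",
    "identity_matrix",
    "segment_identities",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_NEG = -1.0e30

# op codes in the traceback
_DIAG, _UP, _LEFT = 0, 1, 2


@dataclass(frozen=True)
class Scoring:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0


DEFAULT_SCORING = Scoring()


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    matches: int
    columns: int
    identity: float
    score: float


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as int8 codes (A=0..T=3, N=4)."""
    try:
        return np.frombuffer(
            bytes(_CODE[c] for c in seq), dtype=np.int8
        ).copy()
    except KeyError as exc:  # pragma: no cover - upstream types validate
        raise ValueError(f"non-DNA character {exc} in sequence") from exc


@njit(cache=True, fastmath=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Fill + traceback. Returns (score, ops[:n_ops]) with ops in 5'->3' order.

    Rolling score rows; predecessor states packed per cell into one byte
    (pM | pX<<2 | pY<<4) to keep the fill memory-light.
    """
    n = a.shape[0]
    m = b.shape[0]
    # states: M diagonal; X gap in b (consume a, "up"); Y gap in a ("left")
    prevM = np.full(m + 1, _NEG)
    prevX = np.full(m + 1, _NEG)
    prevY = np.full(m + 1, _NEG)
    curM = np.full(m + 1, _NEG)
    curX = np.full(m + 1, _NEG)
    curY = np.full(m + 1, _NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)

    prevM[0] = 0.0
    for j in range(1, m + 1):
        prevY[j] = gap_open + j * gap_extend
        if j > 1:
            ptr[0, j] = 2 << 4

    goe = gap_open + gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        curM[0] = _NEG
        curY[0] = _NEG
        curX[0] = gap_open + i * gap_extend
        ptr[i, 0] = (1 << 2) if i > 1 else 0
        mdiag = prevM[0]
        xdiag = prevX[0]
        ydiag = prevY[0]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            # M: tie preference M > X > Y
            bm = mdiag
            bp = 0
            if xdiag > bm:
                bm = xdiag
                bp = 1
            if ydiag > bm:
                bm = ydiag
                bp = 2
            mdiag = prevM[j]
            xdiag = prevX[j]
            ydiag = prevY[j]
            curM[j] = bm + s
            code = bp
            # X: open from M/Y above, extend from X above
            bm = mdiag + goe
            bp = 0
            v = xdiag + gap_extend
            if v > bm:
                bm = v
                bp = 1
            v = ydiag + goe
            if v > bm:
                bm = v
                bp = 2
            curX[j] = bm
            code |= bp << 2
            # Y: open from M/X on the left, extend from Y
            bm = curM[j - 1] + goe
            bp = 0
            v = curX[j - 1] + goe
            if v > bm:
                bm = v
                bp = 1
            v = curY[j - 1] + gap_extend
            if v > bm:
                bm = v
                bp = 2
            curY[j] = bm
            code |= bp << 4
            ptr[i, j] = code
        prevM, curM = curM, prevM
        prevX, curX = curX, prevX
        prevY, curY = curY, prevY

    # final state: prefer M, then X (up), then Y (left)
    state = 0
    score = prevM[m]
    if prevX[m] > score:
        score = prevX[m]
        state = 1
    if prevY[m] > score:
        score = prevY[m]
        state = 2

    ops = np.empty(n + m, dtype=np.uint8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        code = ptr[i, j]
        if state == 0:
            ops[k] = _DIAG
            state = code & 3
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = _UP
            state = (code >> 2) & 3
            i -= 1
        else:
            ops[k] = _LEFT
            state = (code >> 4) & 3
            j -= 1
        k += 1
    return score, ops[:k][::-1].copy()


@njit(cache=True)
def _stats_from_ops(a, b, ops):  # pragma: no cover
    """(matches, columns) with terminal-gap columns excluded."""
    k = ops.shape[0]
    first = -1
    last = -1
    for t in range(k):
        if ops[t] == 0:
            if first < 0:
                first = t
            last = t
    if first < 0:
        return 0, 0
    matches = 0
    i = 0
    j = 0
    for t in range(k):
        op = ops[t]
        if op == 0:
            if a[i] == b[j] and a[i] < 4 and first <= t <= last:
                matches += 1
            i += 1
            j += 1
        elif op == 1:
            i += 1
        else:
            j += 1
    return matches, last - first + 1


def align_ops(a: str | np.ndarray, b: str | np.ndarray, scoring: Scoring = DEFAULT_SCORING):
    """Low-level entry: returns (score, ops array) for two sequences."""
    ca = encode(a) if isinstance(a, str) else a
    cb = encode(b) if isinstance(b, str) else b
    if ca.size == 0 or cb.size == 0:
        raise ValueError("cannot align empty sequences")
    return _gotoh(
        ca, cb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )


def align_stats(
    a: str | np.ndarray,
    b: str | np.ndarray,
    scoring: Scoring = DEFAULT_SCORING,
    denominator: str = "alignment",
) -> tuple[float, int, int, float]:
    """Fast path: (score, matches, columns, identity) without building strings."""
    ca = encode(a) if isinstance(a, str) else a
    cb = encode(b) if isinstance(b, str) else b
    score, ops = align_ops(ca, cb, scoring)
    matches, columns = _stats_from_ops(ca, cb, ops)
    if denominator == "shorter":
        denom = min(ca.size, cb.size)
    elif denominator == "alignment":
        denom = columns
    else:
        raise ValueError("denominator must be 'alignment' or 'shorter'")
    ident = matches / denom if denom > 0 else 0.0
    return score, matches, columns, ident


_GAP_CHAR = "-"
_LETTER = "ACGTN"


def global_align(
    a: str, b: str, scoring: Scoring = DEFAULT_SCORING
) -> AlignmentResult:
    """Optimal global alignment of two sequences under an affine scheme."""
    ca, cb = encode(a), encode(b)
    score, ops = align_ops(ca, cb, scoring)
    matches, columns = _stats_from_ops(ca, cb, ops)
    rows_a: list[str] = []
    rows_b: list[str] = []
    i = j = 0
    for op in ops:
        if op == _DIAG:
            rows_a.append(a[i])
            rows_b.append(b[j])
            i += 1
            j += 1
        elif op == _UP:
            rows_a.append(a[i])
            rows_b.append(_GAP_CHAR)
            i += 1
        else:
            rows_a.append(_GAP_CHAR)
            rows_b.append(b[j])
            j += 1
    ident = matches / columns if columns > 0 else 0.0
    return AlignmentResult(
        aligned_a="".join(rows_a),
        aligned_b="".join(rows_b),
        matches=matches,
        columns=columns,
        identity=ident,
        score=float(score),
    )


def identity(
    a: str | np.ndarray,
    b: str | np.ndarray,
    scoring: Scoring = DEFAULT_SCORING,
    denominator: str = "alignment",
) -> float:
    """Global-alignment identity in [0, 1]; symmetric in its arguments."""
    return align_stats(a, b, scoring, denominator)[3]


def identity_matrix(
    seqs: list[str], scoring: Scoring = DEFAULT_SCORING
) -> np.ndarray:
    """Symmetric identity matrix; diagonal is exactly 1."""
    if len(seqs) < 2:
        raise ValueError("identity_matrix needs at least 2 sequences")
    codes = [encode(s) for s in seqs]
    n = len(codes)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = identity(codes[i], codes[j], scoring)
    return mat


def segment_identities(
    a: str | np.ndarray,
    b: str | np.ndarray,
    breakpoints: list[int],
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[float, list[tuple[int, int, int, int]]]:
    """Per-breakpoint 5'/3' segment match statistics of one global alignment.

    For each breakpoint k (a position in sequence ``a``), splits the alignment
    columns into those covering ``a[:k]`` and ``a[k:]`` and reports
    ``(m5, c5, m3, c3)`` match/column counts (terminal-gap columns of the full
    alignment excluded). Returns (full identity, per-breakpoint stats).
    Used by the chimera screen: one alignment per candidate parent serves all
    breakpoints.
    """
    ca = encode(a) if isinstance(a, str) else a
    cb = encode(b) if isinstance(b, str) else b
    _, ops = align_ops(ca, cb, scoring)
    diag = ops == _DIAG
    if not diag.any():
        return 0.0, [(0, 0, 0, 0) for _ in breakpoints]
    idx = np.nonzero(diag)[0]
    first, last = idx[0], idx[-1]
    inner = np.zeros(ops.shape[0], dtype=bool)
    inner[first : last + 1] = True
    # position in `a` *after* each column
    a_pos = np.cumsum(ops != _LEFT)
    i_idx = np.cumsum(ops != _LEFT) - 1
    j_idx = np.cumsum(ops != _UP) - 1
    is_match = diag & (ca[i_idx] == cb[j_idx]) & (ca[i_idx] < 4)
    m_total = int((is_match & inner).sum())
    c_total = int(inner.sum())
    out = []
    for k in breakpoints:
        five = inner & (a_pos <= k)
        m5 = int((is_match & five).sum())
        c5 = int(five.sum())
        out.append((m5, c5, m_total - m5, c_total - c5))
    ident = m_total / c_total if c_total else 0.0
    return ident, out
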