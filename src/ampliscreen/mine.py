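"""Reference-guided mining of an annotated sequence collection.

Implements the iterative retention rule used to pull family sequences out of
a large database: a database hit of query q is retained when its identity to
q is at least the *family floor* t(q) — the identity of the family reference
most dissimilar to q — and retained hits become queries for the next
generation until a fixed point (or ``max_generations``).  The floor is taken
over all family references (the alternative — restricting the minimum to the
references present among the hits — is noted but not used).  A ``doubt_check``
discards a candidate whose nearest non-self database neighbour is annotated
outside the family (ties resolve to discard, favouring precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import DEFAULT_SCORING, Scoring, encode, identity
from .core import RefSeq

__all__ = ["MineResult", "mine", "doubt_check"]


@dataclass
class MineResult:
    # (seq id, best query id, identity to that query, generation retained)
    retained: list[tuple[str, str, float, int]] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (seq id, reason)

    @property
    def retained_ids(self) -> list[str]:
        return [r[0] for r in self.retained]


def _family_floor(
    query_codes: np.ndarray,
    family_codes: list[np.ndarray],
    self_index: int | None,
    scoring: Scoring,
) -> float:
    vals = [
        identity(query_codes, fc, scoring)
        for i, fc in enumerate(family_codes)
        if i != self_index
    ]
    return min(vals)


def mine(
    database: list[RefSeq],
    family_refs: list[RefSeq],
    max_generations: int = 5,
    scoring: Scoring = DEFAULT_SCORING,
) -> MineResult:
    """Iterative family-floor retention over a local annotated database.

    Generation 1 hits are retained by the original family queries; each
    retained hit becomes a query in the next generation.  Termination is
    guaranteed: the retained set grows monotonically inside a finite database.
    Output is independent of database record order.
    """
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    if not database or not family_refs:
        raise ValueError("database and family_refs must be non-empty")
    db = sorted(database, key=lambda r: r.id)
    db_codes = {r.id: encode(r.sequence) for r in db}
    fam_codes = [encode(r.sequence) for r in family_refs]
    fam_ids = [r.id for r in family_refs]

    retained: dict[str, tuple[str, float, int]] = {}
    best_reason: dict[str, float] = {}  # best shortfall seen, for reporting
    queries: list[tuple[str, np.ndarray, int | None]] = [
        (r.id, fam_codes[i], i) for i, r in enumerate(family_refs)
    ]
    for generation in range(1, max_generations + 1):
        new_queries: list[tuple[str, np.ndarray, int | None]] = []
        for qid, qcodes, self_idx in queries:
            floor = _family_floor(qcodes, fam_codes, self_idx, scoring)
            for rec in db:
                if rec.id in retained or rec.id == qid:
                    continue
                ident = identity(db_codes[rec.id], qcodes, scoring)
                if ident >= floor:
                    retained[rec.id] = (qid, ident, generation)
                    new_queries.append((rec.id, db_codes[rec.id], None))
                else:
                    gap = floor - ident
                    if rec.id not in best_reason or gap < best_reason[rec.id]:
                        best_reason[rec.id] = gap
        if not new_queries:
            break
        queries = new_queries

    result = MineResult()
    for rid in sorted(retained):
        qid, ident, gen = retained[rid]
        result.retained.append((rid, qid, ident, gen))
    for rec in db:
        if rec.id not in retained and rec.id not in fam_ids:
            result.excluded.append((rec.id, "below family floor"))
    return result


def doubt_check(
    candidate: RefSeq,
    database: list[RefSeq],
    family_refs: list[RefSeq],
    family: str = "Leptocylindraceae",
    scoring: Scoring = DEFAULT_SCORING,
    tie_tolerance: float = 0.0,
) -> str:
    """Keep or discard a doubtful candidate by its nearest database neighbour.

    The database (plus the family references) is ranked by identity to the
    candidate; if the top non-self hit is annotated outside ``family`` the
    candidate is discarded.  Exact ties between a family and a non-family
    nearest hit resolve to "discard" (conservative).
    """
    cand_codes = encode(candidate.sequence)
    pool = [r for r in [*database, *family_refs] if r.id != candidate.id]
    if not pool:
        raise ValueError("no database records to compare against")
    idents = np.array([identity(cand_codes, encode(r.sequence), scoring) for r in pool])
    best = idents.max()
    top = [r for r, v in zip(pool, idents) if v >= best - tie_tolerance]
    if all(r.taxonomy.contains(family) for r in top):
        return "keep"
    return "discard"
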