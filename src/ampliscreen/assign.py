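"""Initial taxonomic assignment of reads against the annotated reference panel.

Two assignment modes are provided.  ``best_hit_assign`` keeps the full lineage
of the unique best hit by global-alignment identity, falling back to the last
common ancestor (LCA) of all tied best hits (identities compared after
rounding to 4 decimals, so equal-scoring alignments compare equal).
``consensus_assign`` considers every hit within ``top_window`` of the best
identity and truncates the lineage to the deepest rank on which at least a
``confidence`` fraction of those hits agree (threshold inclusive).
"""

from __future__ import annotations

import numpy as np

from .align import DEFAULT_SCORING, Scoring, encode, identity
from .core import AmpliconRead, Assignment, RefSeq, TaxonomyPath

__all__ = [
    "lca",
    "best_hit_assign",
    "consensus_assign",
    "filter_by_taxon",
    "panel_identities",
]

_TIE_DECIMALS = 4


def lca(paths: list[TaxonomyPath]) -> TaxonomyPath | None:
    """Longest common prefix of the rank lists.

    A single path is its own LCA; paths sharing no rank at all yield ``None``
    (root-level "unassigned").
    """
    if not paths:
        raise ValueError("lca of an empty path list")
    depth = 0
    for ranks in zip(*(p.ranks for p in paths)):
        if len(set(ranks)) == 1:
            depth += 1
        else:
            break
    if depth == 0:
        return None
    return paths[0].truncate(depth)


def panel_identities(
    read: AmpliconRead | str,
    panel: list[RefSeq],
    scoring: Scoring = DEFAULT_SCORING,
    panel_codes: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Identity of one read to every panel reference, in panel order."""
    if not panel:
        raise ValueError("reference panel is empty")
    seq = read if isinstance(read, str) else read.sequence
    codes = encode(seq)
    if panel_codes is None:
        panel_codes = [encode(r.sequence) for r in panel]
    return np.array([identity(codes, pc, scoring) for pc in panel_codes])


def best_hit_assign(
    read: AmpliconRead,
    panel: list[RefSeq],
    scoring: Scoring = DEFAULT_SCORING,
    identities: np.ndarray | None = None,
) -> Assignment:
    """Best-hit assignment with LCA fallback on exact ties.

    ``identities`` may carry precomputed per-reference identities (panel
    order) so bulk callers can reuse one alignment pass.
    """
    if identities is None:
        identities = panel_identities(read, panel, scoring)
    rounded = np.round(identities, _TIE_DECIMALS)
    best = rounded.max()
    tied = [panel[i] for i in np.nonzero(rounded == best)[0]]
    if len(tied) == 1:
        path = tied[0].taxonomy
    else:
        path = lca([r.taxonomy for r in tied])
    return Assignment(
        read_id=read.id,
        path=path,
        best_identity=float(identities.max()),
        method="best_hit_lca",
        n_hits_considered=len(tied),
    )


def consensus_assign(
    read: AmpliconRead,
    panel: list[RefSeq],
    top_window: float = 0.0,
    confidence: float = 0.80,
    scoring: Scoring = DEFAULT_SCORING,
    identities: np.ndarray | None = None,
) -> Assignment:
    """Consensus assignment over all hits within ``top_window`` of the best.

    The path is truncated to the deepest rank at which >= ``confidence`` of
    the considered hits agree (inclusive threshold).
    """
    if not 0.5 < confidence <= 1.0:
        raise ValueError("confidence must be in (0.5, 1]")
    if identities is None:
        identities = panel_identities(read, panel, scoring)
    rounded = np.round(identities, _TIE_DECIMALS)
    best = rounded.max()
    considered = [panel[i] for i in np.nonzero(rounded >= best - top_window)[0]]
    n = len(considered)
    depth = 0
    prefix: list[tuple[str, str]] = []
    max_depth = max(len(r.taxonomy) for r in considered)
    for d in range(max_depth):
        votes: dict[tuple[str, str], int] = {}
        for r in considered:
            if len(r.taxonomy) > d:
                key = r.taxonomy.ranks[d]
                votes[key] = votes.get(key, 0) + 1
        winner, count = max(votes.items(), key=lambda kv: kv[1])
        if count / n >= confidence:
            prefix.append(winner)
            depth += 1
        else:
            break
    path = TaxonomyPath(tuple(prefix)) if depth else None
    return Assignment(
        read_id=read.id,
        path=path,
        best_identity=float(identities.max()),
        method="consensus",
        n_hits_considered=n,
    )


def filter_by_taxon(
    assignments: list[Assignment], taxon: str
) -> list[str]:
    """Read ids whose assigned path contains ``taxon``; order-preserving."""
    return [
        a.read_id
        for a in assignments
        if a.path is not None and a.path.contains(taxon)
    ]
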