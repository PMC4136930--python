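"""The capture-and-refine clustering funnel.

Stages: greedy assignment of reads to reference-seeded clusters at >= 0.90
identity (capture), reference-free greedy reclustering of each capture
cluster at >= 0.97 into OTUs, singleton/doubleton removal, multi-level
furthest-neighbor (complete-linkage) clustering of an identity matrix, and a
reference-based two-parent chimera screen.

Greedy OTU seeding follows the CD-HIT convention: reads are processed
longest-first (ties broken by lexicographic id); a read joins the best-matching
existing seed at or above the cutoff, otherwise it founds a new OTU.  Exact
duplicate sequences are collapsed before seeding and re-expanded afterwards,
which leaves the partition invariant and saves alignments.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .align import DEFAULT_SCORING, Scoring, encode, identity, segment_identities
from .core import AmpliconRead, Cluster, RefSeq

__all__ = [
    "greedy_capture",
    "split_family_clusters",
    "recluster_otus",
    "remove_rare_otus",
    "furthest_neighbor_cluster",
    "chimera_screen",
]


def _per_sample_counts(member_ids: list[str], sample_of: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rid in member_ids:
        sid = sample_of[rid]
        counts[sid] = counts.get(sid, 0) + 1
    return counts


def greedy_capture(
    reads: list[AmpliconRead],
    panel: list[RefSeq],
    cutoff: float = 0.90,
    scoring: Scoring = DEFAULT_SCORING,
    identities: np.ndarray | None = None,
) -> tuple[dict[str, Cluster], list[AmpliconRead]]:
    """Assign each read to the reference of maximal identity if >= cutoff.

    Ties go to the lexicographically smallest reference id.  Returns
    (clusters keyed by reference id, unmatched reads).  ``identities`` may be
    a precomputed (n_reads, n_refs) matrix in input order.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    if not panel:
        raise ValueError("reference panel is empty")
    if identities is None:
        panel_codes = [encode(r.sequence) for r in panel]
        identities = np.array(
            [[identity(encode(rd.sequence), pc, scoring) for pc in panel_codes] for rd in reads]
        ).reshape(len(reads), len(panel))
    # stable winner: max identity, ties to smallest reference id
    ref_order = np.argsort([r.id for r in panel], kind="stable")
    members: dict[str, list[str]] = {}
    unmatched: list[AmpliconRead] = []
    sample_of = {rd.id: rd.sample_id for rd in reads}
    for r, rd in enumerate(reads):
        row = identities[r]
        best = row.max() if row.size else 0.0
        if best >= cutoff:
            for idx in ref_order:
                if row[idx] == best:
                    members.setdefault(panel[idx].id, []).append(rd.id)
                    break
        else:
            unmatched.append(rd)
    clusters = {
        ref_id: Cluster(ref_id, mids, cutoff, _per_sample_counts(mids, sample_of))
        for ref_id, mids in members.items()
    }
    return clusters, unmatched


def split_family_clusters(
    clusters: dict[str, Cluster], panel: list[RefSeq], family: str
) -> tuple[dict[str, Cluster], dict[str, Cluster]]:
    """Separate capture clusters seeded by family references from those seeded
    by non-family references (the latter are eliminated by the screen)."""
    fam_ids = {r.id for r in panel if r.taxonomy.contains(family)}
    fam = {k: c for k, c in clusters.items() if k in fam_ids}
    other = {k: c for k, c in clusters.items() if k not in fam_ids}
    return fam, other


def recluster_otus(
    reads: list[AmpliconRead],
    cutoff: float = 0.97,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[Cluster]:
    """Greedy incremental clustering into OTUs at >= ``cutoff``.

    Canonical processing order (longest sequence first, then lexicographic id)
    makes the result independent of input order.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    if not reads:
        raise ValueError("cannot recluster an empty read set")
    ordered = sorted(reads, key=lambda r: (-len(r.sequence), r.id))
    sample_of = {r.id: r.sample_id for r in reads}

    # collapse exact duplicates; exemplar = first in canonical order
    exemplar_of: dict[str, str] = {}
    dup_members: dict[str, list[str]] = {}
    uniques: list[AmpliconRead] = []
    for rd in ordered:
        ex = exemplar_of.get(rd.sequence)
        if ex is None:
            exemplar_of[rd.sequence] = rd.id
            dup_members[rd.id] = [rd.id]
            uniques.append(rd)
        else:
            dup_members[ex].append(rd.id)

    seeds: list[AmpliconRead] = []
    seed_codes: list[np.ndarray] = []
    otu_members: list[list[str]] = []
    for rd in uniques:
        codes = encode(rd.sequence)
        best_i = -1
        best_ident = 0.0
        for i, sc in enumerate(seed_codes):
            ident = identity(codes, sc, scoring)
            if ident >= cutoff and (best_i < 0 or ident > best_ident):
                best_ident = ident
                best_i = i
        if best_i >= 0:
            otu_members[best_i].extend(dup_members[rd.id])
        else:
            seeds.append(rd)
            seed_codes.append(codes)
            otu_members.append(list(dup_members[rd.id]))
    return [
        Cluster(seed.id, mids, cutoff, _per_sample_counts(mids, sample_of))
        for seed, mids in zip(seeds, otu_members)
    ]


def remove_rare_otus(
    otus: list[Cluster], min_size: int = 3
) -> tuple[list[Cluster], list[Cluster]]:
    """Drop OTUs below ``min_size`` members (singletons/doubletons by default).

    Read counts are conserved: kept + removed partitions the input.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [o for o in otus if o.size >= min_size]
    removed = [o for o in otus if o.size < min_size]
    return kept, removed


def furthest_neighbor_cluster(
    ident_matrix: np.ndarray,
    cutoffs: list[float],
    precision: int = 1000,
    ids: list[str] | None = None,
) -> dict[float, list[list[str]]]:
    """Complete-linkage (furthest-neighbor) clustering at several cutoffs.

    Distances are ``1 - identity`` rounded to 1/precision; a merge happens only
    when the maximum pairwise distance within the merged cluster is <=
    ``1 - cutoff``.  Partitions are nested: higher cutoffs refine lower ones.
    """
    mat = np.asarray(ident_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("identity matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("identity matrix must be symmetric")
    n = mat.shape[0]
    ids = ids or [str(i) for i in range(n)]
    dist = np.round((1.0 - mat) * precision) / precision
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    out: dict[float, list[list[str]]] = {}
    for cutoff in cutoffs:
        labels = hierarchy.fcluster(Z, t=(1.0 - cutoff) + 1e-12, criterion="distance")
        groups: dict[int, list[str]] = {}
        for i, lab in enumerate(labels):
            groups.setdefault(int(lab), []).append(ids[i])
        out[cutoff] = [sorted(g) for g in sorted(groups.values(), key=lambda g: sorted(g)[0])]
    return out


def chimera_screen(
    reads: list[AmpliconRead],
    panel: list[RefSeq],
    margin: float = 0.02,
    n_breakpoints: int = 9,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[list[AmpliconRead], list[AmpliconRead]]:
    """Reference-based two-parent chimera screen.

    Breakpoints are scanned at every 10% of read length (``n_breakpoints``
    interior points).  For each reference, one global alignment per read
    yields the 5'/3' segment match counts at every breakpoint; a read is
    flagged when the best column-weighted two-parent mosaic identity
    (5' from one parent, 3' from a different parent) exceeds its best
    full-length single-parent identity by at least ``margin``.
    """
    if len(panel) < 2:
        raise ValueError("chimera screen needs at least 2 references")
    clean: list[AmpliconRead] = []
    flagged: list[AmpliconRead] = []
    panel_codes = [encode(r.sequence) for r in panel]
    for rd in reads:
        codes = encode(rd.sequence)
        L = len(rd.sequence)
        breakpoints = sorted(
            {max(1, min(L - 1, round(L * (k + 1) / (n_breakpoints + 1))))
             for k in range(n_breakpoints)}
        )
        full = np.empty(len(panel))
        seg: list[list[tuple[int, int, int, int]]] = []
        for p, pc in enumerate(panel_codes):
            ident, stats = segment_identities(codes, pc, breakpoints, scoring)
            full[p] = ident
            seg.append(stats)
        best_full = full.max()
        is_chimera = False
        for b in range(len(breakpoints)):
            five = [(s[b][0], s[b][1]) for s in seg]
            three = [(s[b][2], s[b][3]) for s in seg]
            for pa in range(len(panel)):
                m5, c5 = five[pa]
                if c5 == 0:
                    continue
                for pb in range(len(panel)):
                    if pb == pa:
                        continue
                    m3, c3 = three[pb]
                    if c3 == 0:
                        continue
                    mosaic = (m5 + m3) / (c5 + c3)
                    if mosaic - best_full >= margin:
                        is_chimera = True
                        break
                if is_chimera:
                    break
            if is_chimera:
                break
        (flagged if is_chimera else clean).append(rd)
    return clean, flagged
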