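"""Phylogenetic validation of captured OTUs.

OTU representatives are threaded into the reference master alignment
(template threading: each query is globally aligned to its nearest reference
and projected into that reference's columns; query insertions are dropped and
counted).  A neighbor-joining tree over p- or Jukes–Cantor distances is
rooted on the designated far outgroups; the smallest clade containing all
family references defines the family; OTUs inside it are assigned to species
by sister-clade membership plus a nearest-reference identity floor, OTUs
inside the family but matching no species are reported as candidate new taxa
("family-unplaced"), and OTUs outside are false-positive candidates.

Phylogenetic signal is quantified by the g1 skewness of the Fitch parsimony
tree-length distribution over uniform random topologies: a left-skewed
distribution (g1 < 0) indicates hierarchical structure in the alignment.

Trees are dendropy objects throughout (Newick I/O, rooting and bipartitions
come from dendropy); the NJ agglomeration and Fitch counting are implemented
here because the validation contract pins their tie-breaking behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .align import DEFAULT_SCORING, Scoring, encode, identity

__all__ = [
    "G1Result",
    "template_align",
    "distance_from_alignment",
    "nj_tree",
    "root_tree",
    "family_clade",
    "assign_species_by_clade",
    "bootstrap_support",
    "fitch_length",
    "random_tree_g1",
]

GAP_CHARS = {"-", "."}


# ---------------------------------------------------------------------------
# alignment threading and distances


def template_align(
    queries: dict[str, str],
    master: dict[str, str],
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[dict[str, str], dict[str, int]]:
    """Thread query sequences into the master alignment.

    Each query is globally aligned to its highest-identity reference and its
    bases are projected into that reference's master columns; insertions
    relative to the template are dropped (their counts are returned).  Output
    rows always have exactly the master's column count.
    """
    if not master:
        raise ValueError("master alignment is empty")
    ncols = {len(row) for row in master.values()}
    if len(ncols) != 1:
        raise ValueError("master alignment rows have inconsistent column counts")
    width = ncols.pop()
    ref_ungapped = {
        rid: "".join(c for c in row if c not in GAP_CHARS)
        for rid, row in master.items()
    }
    ref_codes = {rid: encode(seq) for rid, seq in ref_ungapped.items()}
    # base index -> master column, per reference
    ref_cols = {}
    for rid, row in master.items():
        ref_cols[rid] = [i for i, c in enumerate(row) if c not in GAP_CHARS]

    from .align import align_ops

    out: dict[str, str] = {}
    dropped: dict[str, int] = {}
    for qid, qseq in queries.items():
        qc = encode(qseq)
        best_rid = max(
            ref_codes, key=lambda rid: (identity(qc, ref_codes[rid], scoring), rid)
        )
        _, ops = align_ops(qc, ref_codes[best_rid], scoring)
        row = ["-"] * width
        cols = ref_cols[best_rid]
        qi = 0
        ri = 0
        n_dropped = 0
        for op in ops:
            if op == 0:  # diagonal
                row[cols[ri]] = qseq[qi]
                qi += 1
                ri += 1
            elif op == 1:  # query insertion relative to template: dropped
                n_dropped += 1
                qi += 1
            else:  # deletion: gap stays at this reference column
                ri += 1
        out[qid] = "".join(row)
        dropped[qid] = n_dropped
    return out, dropped


def distance_from_alignment(
    rows: dict[str, str], correction: str = "p"
) -> tuple[list[str], np.ndarray]:
    """Pairwise distances over columns where both rows are ungapped.

    ``correction="p"`` gives the raw p-distance; ``"jc"`` applies the
    Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3).  ``N`` never matches.
    """
    ids = list(rows)
    if len(ids) < 3:
        raise ValueError("need at least 3 rows")
    widths = {len(rows[i]) for i in ids}
    if len(widths) != 1:
        raise ValueError("rows have unequal column counts")
    arr = np.array([list(rows[i]) for i in ids])
    ungapped = ~np.isin(arr, list(GAP_CHARS))
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ungapped[i] & ungapped[j]
            total = int(shared.sum())
            if total == 0:
                raise ValueError(
                    f"rows {ids[i]!r} and {ids[j]!r} share no ungapped columns"
                )
            ai, aj = arr[i][shared], arr[j][shared]
            diffs = int(((ai != aj) | (ai == "N") | (aj == "N")).sum())
            p = diffs / total
            if correction == "jc":
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p:.3f} between {ids[i]!r} and {ids[j]!r} "
                        "is beyond the Jukes-Cantor domain"
                    )
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            elif correction == "p":
                d = p
            else:
                raise ValueError("correction must be 'p' or 'jc'")
            D[i, j] = D[j, i] = d
    return ids, D


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(ids: list[str], dist: np.ndarray) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted) with the standard Q criterion.

    Ties in Q are broken by the smallest (i, j) index pair; negative branch
    lengths are clamped to 0 with the subtraction shifted to the sister edge.
    """
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.asarray(dist, dtype=float).copy()
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for name in ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(nd)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (i, j)
        flat = np.argmin(Q)
        bi, bj = divmod(int(flat), m)
        if bi > bj:
            bi, bj = bj, bi
        dij = sub[bi, bj]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = dendropy.Node()
        ci, cj = nodes[active[bi]], nodes[active[bj]]
        u.add_child(ci)
        u.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        # distances to the new node
        gi, gj = active[bi], active[bj]
        newd = 0.5 * (D[gi, :] + D[gj, :] - dij)
        D = np.vstack([D, newd])
        newcol = np.append(newd, 0.0)
        D = np.column_stack([D, newcol])
        nodes.append(u)
        new_idx = D.shape[0] - 1
        active = [g for g in active if g not in (gi, gj)] + [new_idx]

    # connect the last three through a central node
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    center = dendropy.Node()
    for node_idx, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[node_idx])
        nodes[node_idx].edge.length = length
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# rooting and clade logic


def _leaf_labels(node: dendropy.Node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def root_tree(tree: dendropy.Tree, outgroup_ids: list[str]) -> dendropy.Tree:
    """Root on the edge separating the outgroup from everything else.

    The outgroup must be a single leaf or monophyletic in the unrooted tree;
    otherwise an error is raised (never silently resolved).
    """
    if not outgroup_ids:
        raise ValueError("outgroup_ids is empty")
    t = tree.clone(depth=1)
    labels = {lf.taxon.label for lf in t.leaf_node_iter()}
    missing = set(outgroup_ids) - labels
    if missing:
        raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
    out_set = set(outgroup_ids)
    ingroup = labels - out_set
    if not ingroup:
        raise ValueError("outgroup covers the whole tree")
    # ensure the current root is on the ingroup side, then test monophyly
    t.is_rooted = True
    some_in = next(
        lf for lf in t.leaf_node_iter() if lf.taxon.label in ingroup
    )
    t.reroot_at_edge(some_in.edge, update_bipartitions=False)
    mrca = t.mrca(taxa=[t.taxon_namespace.get_taxon(x) for x in out_set])
    if _leaf_labels(mrca) != out_set:
        raise ValueError(
            "outgroup is not monophyletic in the unrooted tree; refusing to root"
        )
    edge = mrca.edge
    half = (edge.length or 0.0) / 2.0
    t.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=True)
    t.is_rooted = True
    return t


def family_clade(tree: dendropy.Tree, family_ref_ids: list[str]) -> dendropy.Node:
    """Most recent common ancestor of all family reference leaves."""
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(family_ref_ids) - labels
    if missing:
        raise ValueError(f"family reference leaves missing from tree: {sorted(missing)}")
    if len(family_ref_ids) == 1:
        for lf in tree.leaf_node_iter():
            if lf.taxon.label == family_ref_ids[0]:
                return lf
    return tree.mrca(
        taxa=[tree.taxon_namespace.get_taxon(x) for x in family_ref_ids]
    )


def assign_species_by_clade(
    tree: dendropy.Tree,
    otu_ids: list[str],
    species_ref_map: dict[str, list[str]],
    rep_best_identity: dict[str, tuple[str, float]] | None = None,
    identity_floor: float = 0.97,
) -> dict[str, str]:
    """Assign each OTU leaf to a species, "family-unplaced" or "outside".

    For an OTU inside the family clade, with ``rep_best_identity`` supplied
    (``otu id -> (nearest reference species, identity)``):

    1. representative identity below ``identity_floor`` -> "family-unplaced"
       (a candidate new taxon: more divergent from every reference than the
       family's own species are from each other);
    2. otherwise, if the smallest ancestral clade holding any reference holds
       references of exactly one species S -> S (topology decides);
    3. otherwise (topologically ambiguous position between species clades) ->
       the nearest reference's species (the identity fallback used for
       unresolved placements).

    Without ``rep_best_identity`` only the topology rule applies and
    ambiguous placements are "family-unplaced".  OTUs outside the family
    clade are "outside" (false-positive candidates, confirmed by the caller's
    nearest-reference check).
    """
    ref_species: dict[str, str] = {}
    for sp, refs in species_ref_map.items():
        if not refs:
            raise ValueError(f"species {sp!r} maps to no reference leaves")
        for r in refs:
            ref_species[r] = sp
    leaf_by_label = {
        lf.taxon.label: lf for lf in tree.leaf_node_iter()
    }
    missing = [o for o in otu_ids if o not in leaf_by_label]
    if missing:
        raise ValueError(f"OTU ids are not leaves of the tree: {missing}")
    fam_node = family_clade(tree, sorted(ref_species))
    fam_leaves = _leaf_labels(fam_node)

    out: dict[str, str] = {}
    for otu in otu_ids:
        if otu not in fam_leaves:
            out[otu] = "outside"
            continue
        if rep_best_identity is not None:
            best_sp, best_ident = rep_best_identity[otu]
            if best_ident < identity_floor:
                out[otu] = "family-unplaced"
                continue
        node = leaf_by_label[otu]
        label = "family-unplaced"
        while node is not None:
            refs_here = {x for x in _leaf_labels(node) if x in ref_species}
            if refs_here:
                species_here = {ref_species[x] for x in refs_here}
                if len(species_here) == 1:
                    label = species_here.pop()
                elif rep_best_identity is not None:
                    label = best_sp
                break
            node = node.parent_node
        out[otu] = label
    return out


# ---------------------------------------------------------------------------
# support and parsimony signal

_STATE_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}


def _row_masks(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Rows as 4-bit state masks; N and gaps are fully ambiguous (all states)."""
    ids = list(rows)
    mat = np.array(
        [[_STATE_MASK.get(c, 15) for c in rows[i]] for i in ids], dtype=np.uint8
    )
    return ids, mat


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of leaf labels."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(_leaf_labels(node))
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: sorted(s)))
    return out


def bootstrap_support(
    rows: dict[str, str],
    n_replicates: int = 100,
    seed: int = 0,
    correction: str = "p",
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """Column-resampling NJ bootstrap.

    Builds the NJ tree from the full alignment, then resamples columns with
    replacement ``n_replicates`` times; support of each original internal
    bipartition is the fraction of replicate trees containing it.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids, D = distance_from_alignment(rows, correction)
    tree = nj_tree(ids, D)
    original = _bipartitions(tree)
    counts = {bp: 0 for bp in original}
    rng = np.random.default_rng(seed)
    width = len(next(iter(rows.values())))
    keys = list(rows)
    for _ in range(n_replicates):
        cols = rng.integers(0, width, width)
        resampled = {k: "".join(rows[k][c] for c in cols) for k in keys}
        rids, rD = distance_from_alignment(resampled, correction)
        rtree = nj_tree(rids, rD)
        reps = _bipartitions(rtree)
        for bp in original:
            if bp in reps:
                counts[bp] += 1
    support = {bp: c / n_replicates for bp, c in counts.items()}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(_leaf_labels(node))
        all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        key = min(side, all_leaves - side, key=lambda s: sorted(s))
        if key in support:
            node.label = f"{support[key]:.2f}"
    return tree, support


def _fitch_count(children: dict[int, list[int]], root: int, masks: np.ndarray) -> int:
    """Vectorised Fitch bottom-up count over all columns at once."""
    changes = 0
    states: dict[int, np.ndarray] = {}
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        kids = children.get(node, [])
        if not kids:
            states[node] = masks[node]
            continue
        if not done:
            stack.append((node, True))
            stack.extend((k, False) for k in kids)
            continue
        acc = states.pop(kids[0])
        for k in kids[1:]:
            other = states.pop(k)
            inter = acc & other
            empty = inter == 0
            changes += int(empty.sum())
            acc = np.where(empty, acc | other, inter)
        states[node] = acc
    return changes


def fitch_length(tree: dendropy.Tree, rows: dict[str, str]) -> int:
    """Fitch parsimony length of ``tree`` on the alignment ``rows``."""
    ids, masks = _row_masks(rows)
    index = {name: i for i, name in enumerate(ids)}
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_labels != set(ids):
        raise ValueError("tree leaves do not match alignment row ids")
    children: dict[int, list[int]] = {}
    node_ids: dict[int, int] = {}
    next_id = len(ids)
    root = None
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_ids[id(node)] = index[node.taxon.label]
        else:
            node_ids[id(node)] = next_id
            next_id += 1
        if node.parent_node is None:
            root = node_ids[id(node)]
    full_masks = np.vstack([masks, np.zeros((next_id - len(ids), masks.shape[1]), np.uint8)])
    for node in tree.postorder_node_iter():
        if not node.is_leaf():
            children[node_ids[id(node)]] = [node_ids[id(c)] for c in node.child_nodes()]
    return _fitch_count(children, root, full_masks)


def _random_topology(n_leaves: int, rng: np.random.Generator):
    """Uniform random unrooted binary topology via sequential leaf addition.

    Returns (children, root) with leaves 0..n_leaves-1; the root is a
    trifurcation (the canonical unrooted representation)."""
    root = n_leaves
    children = {root: [0, 1, 2]}
    parent = {0: root, 1: root, 2: root}
    edges = [0, 1, 2]  # each edge named by its child node
    next_internal = n_leaves + 1
    for leaf in range(3, n_leaves):
        c = edges[int(rng.integers(0, len(edges)))]
        p = parent[c]
        u = next_internal
        next_internal += 1
        children[p][children[p].index(c)] = u
        children[u] = [c, leaf]
        parent[c] = u
        parent[u] = p
        parent[leaf] = u
        edges.extend([u, leaf])
    return children, root


@dataclass
class G1Result:
    """Skewness of the parsimony tree-length distribution over random trees."""

    n_trees: int
    mean: float
    sd: float
    min: int
    max: int
    g1: float
    undefined: bool = False


def random_tree_g1(rows: dict[str, str], n_trees: int = 1000, seed: int = 0) -> G1Result:
    """Fitch lengths of uniform random leaf-labelled binary topologies.

    g1 is the standardised third central moment of the length distribution;
    a strongly tree-like alignment yields g1 < 0 (long left tail: few trees
    are much shorter than the bulk).  With zero variance (e.g. identical
    rows) g1 is undefined and flagged.
    """
    if n_trees < 100:
        raise ValueError("n_trees must be >= 100")
    ids, masks = _row_masks(rows)
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 rows")
    # constant-capable columns (some state shared by all rows) cost 0 anywhere
    shared = masks[0].copy()
    for i in range(1, n):
        shared &= masks[i]
    masks = masks[:, shared == 0]
    rng = np.random.default_rng(seed)
    lengths = np.empty(n_trees, dtype=np.int64)
    pad = np.zeros((n + 2 + n, masks.shape[1]), dtype=np.uint8)  # internal slots
    for t in range(n_trees):
        children, root = _random_topology(n, rng)
        full = np.vstack([masks, pad[: (max(children) + 1 - n)]])
        lengths[t] = _fitch_count(children, root, full)
    mean = float(lengths.mean())
    sd = float(lengths.std())
    if sd == 0.0:
        return G1Result(n_trees, mean, sd, int(lengths.min()), int(lengths.max()), float("nan"), True)
    m3 = float(((lengths - mean) ** 3).mean())
    g1 = m3 / sd**3
    return G1Result(n_trees, mean, sd, int(lengths.min()), int(lengths.max()), g1, False)
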