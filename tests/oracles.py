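"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (enumeration, recursion, closures) and
shares no code with the package's optimised paths.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product


def enumerate_alignment_score(a: str, b: str, match=5.0, mismatch=-4.0,
                              gap_open=-10.0, gap_extend=-1.0) -> float:
    """Optimal global alignment score by exhaustive path enumeration.

    Recursion over every interleaving of diagonal/up/left moves, tracking the
    previous move to price affine gaps (a gap of length L costs
    gap_open + L*gap_extend). Only feasible for tiny sequences.
    """
    best = [float("-inf")]

    def step(i: int, j: int, prev: str, score: float) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N" and b[j] != "N") else mismatch
            step(i + 1, j + 1, "d", score + s)
        if i < len(a):
            cost = gap_extend if prev == "u" else gap_open + gap_extend
            step(i + 1, j, "u", score + cost)
        if j < len(b):
            cost = gap_extend if prev == "l" else gap_open + gap_extend
            step(i, j + 1, "l", score + cost)

    step(0, 0, "", 0.0)
    return best[0]


def memo_alignment_score(a: str, b: str, match=5.0, mismatch=-4.0,
                         gap_open=-10.0, gap_extend=-1.0) -> float:
    """Top-down memoised recursion on (i, j, previous-move).

    A second independent formulation (state = last emitted column, not the
    three-matrix Gotoh decomposition); usable up to a few hundred bases.
    """

    @lru_cache(maxsize=None)
    def go(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        out = float("-inf")
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N" and b[j] != "N") else mismatch
            out = max(out, s + go(i + 1, j + 1, "d"))
        if i < len(a):
            cost = gap_extend if prev == "u" else gap_open + gap_extend
            out = max(out, cost + go(i + 1, j, "u"))
        if j < len(b):
            cost = gap_extend if prev == "l" else gap_open + gap_extend
            out = max(out, cost + go(i, j + 1, "l"))
        return out

    return go(0, 0, "")


def levenshtein(a: str, b: str) -> int:
    """Plain unit-cost edit distance (independent of the package aligner)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def fitch_brute_force(children: dict, root: int, leaf_states: dict[int, set]) -> int:
    """Minimum total changes over all internal-node state assignments.

    Enumerates every assignment of {A,C,G,T} to internal nodes; exponential,
    fine for <= 5 leaves (<= 4 internal nodes).
    """
    internal = sorted(children)
    leaves = sorted(leaf_states)

    def edges():
        for p, kids in children.items():
            for k in kids:
                yield p, k

    best = float("inf")
    for combo in product("ACGT", repeat=len(internal)):
        assign = dict(zip(internal, combo))
        # leaves may be ambiguous sets: pick best compatible state per leaf
        cost = 0
        for p, k in edges():
            sp = assign[p]
            if k in assign:
                cost += assign[p] != assign[k]
            else:
                cost += 0 if sp in leaf_states[k] else 1
        best = min(best, cost)
    return int(best)


def lca_prefix(paths: list[tuple]) -> tuple:
    """Longest common prefix of rank tuples, computed by plain scanning."""
    out = []
    for items in zip(*paths):
        if all(x == items[0] for x in items):
            out.append(items[0])
        else:
            break
    return tuple(out)


def mine_closure(db: dict[str, str], fam: dict[str, str], ident_fn) -> set[str]:
    """Transitive closure of the family-floor retention rule.

    ``ident_fn(x, y)`` -> identity. Queries start as the family references
    (floor = min identity to the *other* family references); every retained
    hit becomes a query with the floor over all family references.
    """
    fam_ids = list(fam)
    retained: set[str] = set()
    queries: list[tuple[str, str, bool]] = [(q, fam[q], True) for q in fam_ids]
    while queries:
        next_q = []
        for qid, qseq, is_ref in queries:
            floors = [
                ident_fn(fam[f], qseq) for f in fam_ids if not (is_ref and f == qid)
            ]
            floor = min(floors)
            for hid, hseq in db.items():
                if hid in retained or hid == qid:
                    continue
                if ident_fn(hseq, qseq) >= floor:
                    retained.add(hid)
                    next_q.append((hid, hseq, False))
        queries = next_q
    return retained


def all_unrooted_topologies(n_leaves: int):
    """Yield every unrooted binary topology on leaves 0..n-1 as
    (children dict, root) with a trifurcating root; 3, 15, 105 trees for
    n = 4, 5, 6."""
    assert n_leaves >= 4

    def expand(children, parent, edges, next_leaf, next_internal):
        if next_leaf == n_leaves:
            yield {k: list(v) for k, v in children.items()}
            return
        for c in list(edges):
            p = parent[c]
            u = next_internal
            children[p][children[p].index(c)] = u
            children[u] = [c, next_leaf]
            parent[c] = u
            parent[u] = p
            parent[next_leaf] = u
            edges.extend([u, next_leaf])
            yield from expand(children, parent, edges, next_leaf + 1, next_internal + 1)
            edges.pop()
            edges.pop()
            children[p][children[p].index(u)] = c
            parent[c] = p
            del children[u]
            del parent[u]
            del parent[next_leaf]

    root = n_leaves
    children = {root: [0, 1, 2]}
    parent = {0: root, 1: root, 2: root}
    yield from ((c, root) for c in expand(children, parent, [0, 1, 2], 3, n_leaves + 1))


def topology_distances(children: dict, root: int, lengths: dict) -> dict:
    """Leaf-to-leaf path distances of a tree given per-child edge lengths."""
    # collect leaf descendants and depth-accumulated paths by DFS from root
    paths: dict[int, float] = {root: 0.0}
    order = [root]
    stack = [root]
    leaf_list = []
    while stack:
        node = stack.pop()
        for c in children.get(node, []):
            paths[c] = paths[node] + lengths[c]
            stack.append(c)
            order.append(c)
            if c not in children:
                leaf_list.append(c)
    # distances via lowest common ancestor: brute force over pairs
    parent = {}
    for p, kids in children.items():
        for k in kids:
            parent[k] = p

    def ancestors(x):
        out = [x]
        while x in parent:
            x = parent[x]
            out.append(x)
        return out

    D = {}
    for i in leaf_list:
        anc_i = ancestors(i)
        for j in leaf_list:
            if j <= i:
                continue
            anc_j = set(ancestors(j))
            lca = next(a for a in anc_i if a in anc_j)
            D[(i, j)] = paths[i] + paths[j] - 2 * paths[lca]
    return D


def topology_bipartitions(children: dict, root: int, n_leaves: int) -> set:
    """Non-trivial bipartitions as canonical frozensets of leaf indices."""
    all_leaves = frozenset(range(n_leaves))

    def leaves_under(node):
        if node not in children:
            return {node}
        out = set()
        for c in children[node]:
            out |= leaves_under(c)
        return out

    out = set()
    for node in children:
        for c in children[node]:
            if c in children:  # internal edge
                side = frozenset(leaves_under(c))
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    out.add(min(side, other, key=sorted))
    return out
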