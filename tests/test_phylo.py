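"""Template threading, distances, NJ, rooting, clade logic, Fitch, g1."""

import dendropy
import numpy as np
import pytest
from scipy import stats as sps

from ampliscreen.phylo import (
    assign_species_by_clade,
    bootstrap_support,
    distance_from_alignment,
    family_clade,
    fitch_length,
    nj_tree,
    random_tree_g1,
    root_tree,
    template_align,
    _bipartitions,
    _random_topology,
)

from oracles import (
    all_unrooted_topologies,
    fitch_brute_force,
    topology_bipartitions,
    topology_distances,
)


# ---------------------------------------------------------------- threading

def test_template_align_identical_query_reproduces_row():
    master = {"r1": "AC-GT-A", "r2": "ACCGTTA"}
    rows, dropped = template_align({"q": "ACGTA"}, master)
    assert rows["q"] == "AC-GT-A"
    assert dropped["q"] == 0


def test_template_align_deletion_adds_gap():
    master = {"r1": "ACGTT"}
    rows, dropped = template_align({"q": "ACTT"}, master)  # G deleted
    assert rows["q"] == "AC-TT"
    assert dropped["q"] == 0


def test_template_align_insertion_dropped_and_counted():
    master = {"r1": "ACGT"}
    rows, dropped = template_align({"q": "ACGGGT"}, master)
    assert len(rows["q"]) == 4
    assert dropped["q"] == 2


def test_template_align_column_count_invariant(small_panel):
    cfg, panel, master = small_panel
    fam = next(r for r in panel if r.id == "fam1")
    from ampliscreen.simulate import mutate_sequence

    queries = {
        f"q{i}": mutate_sequence(fam.sequence, 5, 2, seed=i) for i in range(4)
    }
    rows, _ = template_align(queries, master)
    width = len(next(iter(master.values())))
    assert all(len(v) == width for v in rows.values())
    with pytest.raises(ValueError):
        template_align({"q": "ACGT"}, {})


# ---------------------------------------------------------------- distances

def test_distance_examples():
    rows = {"a": "AAAAAAAAAA", "b": "AAAAAAAAAA", "c": "CCAAAAAAAA"}
    ids, D = distance_from_alignment(rows)
    assert D[ids.index("a"), ids.index("b")] == 0.0
    assert D[ids.index("a"), ids.index("c")] == pytest.approx(0.2)
    ids, DJ = distance_from_alignment(rows, correction="jc")
    expect = -0.75 * np.log(1 - 4 * 0.2 / 3)
    assert DJ[ids.index("a"), ids.index("c")] == pytest.approx(expect)


def test_jc_dominates_p_distance(rng):
    for _ in range(20):
        p = rng.uniform(0.01, 0.70)
        jc = -0.75 * np.log(1 - 4 * p / 3)
        assert jc >= p


def test_distance_no_shared_columns_errors():
    rows = {"a": "AA--", "b": "--CC", "c": "AACC"}
    with pytest.raises(ValueError, match="share no ungapped columns"):
        distance_from_alignment(rows)


# ----------------------------------------------------------------------- nj

def test_nj_three_taxa_three_point():
    ids = ["A", "B", "C"]
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    t = nj_tree(ids, D)
    lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_recovers_four_taxon_split():
    ids = ["A", "B", "C", "D"]
    D = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    t = nj_tree(ids, D)
    assert frozenset("AB") in _bipartitions(t) or frozenset("CD") in _bipartitions(t)


def test_nj_recovers_all_additive_topologies_up_to_six_taxa(rng):
    """Exhaustive: every unrooted topology on 4-6 leaves, additive distances."""
    for n in (4, 5, 6):
        for children, root in all_unrooted_topologies(n):
            lengths = {}
            for p, kids in children.items():
                for k in kids:
                    lengths[k] = float(rng.uniform(0.5, 2.0))
            D_pairs = topology_distances(children, root, lengths)
            D = np.zeros((n, n))
            for (i, j), d in D_pairs.items():
                D[i, j] = D[j, i] = d
            ids = [str(i) for i in range(n)]
            t = nj_tree(ids, D)
            got = set()
            all_leaves = frozenset(range(n))
            for bp in _bipartitions(t):
                side = frozenset(int(x) for x in bp)
                got.add(min(side, all_leaves - side, key=sorted))
            assert got == topology_bipartitions(children, root, n)


def test_nj_needs_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(["A", "B"], np.zeros((2, 2)))


# ------------------------------------------------------------------ rooting

def _quartet():
    ids = ["A", "B", "O1", "O2"]
    D = np.array(
        [[0, 1, 8, 8], [1, 0, 8, 8], [8, 8, 0, 1], [8, 8, 1, 0]], float
    )
    return nj_tree(ids, D)


def test_root_on_single_leaf():
    t = _quartet()
    rt = root_tree(t, ["O1"])
    kids = rt.seed_node.child_nodes()
    sides = [sorted(lf.taxon.label for lf in k.leaf_iter()) for k in kids]
    assert ["O1"] in sides


def test_root_on_two_leaf_monophyletic_outgroup():
    rt = root_tree(_quartet(), ["O1", "O2"])
    sides = [
        sorted(lf.taxon.label for lf in k.leaf_iter())
        for k in rt.seed_node.child_nodes()
    ]
    assert ["O1", "O2"] in sides and ["A", "B"] in sides


def test_root_nonmonophyletic_outgroup_rejected():
    with pytest.raises(ValueError, match="monophyletic"):
        root_tree(_quartet(), ["A", "O1"])


def test_root_unroot_round_trip_topology():
    t = _quartet()
    before = _bipartitions(t)
    rt = root_tree(t, ["O1", "O2"])
    rt.is_rooted = False
    rt.update_bipartitions(suppress_unifurcations=True)
    assert _bipartitions(rt) == before


# -------------------------------------------------------------- clade logic

def _hand_tree(newick):
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def test_family_clade_with_interloper():
    t = _hand_tree("((((F1,F2),(F3,X)),Y),OUT);")
    t.is_rooted = True
    node = family_clade(t, ["F1", "F2", "F3"])
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    assert leaves == ["F1", "F2", "F3", "X"]  # interloper inside the MRCA
    with pytest.raises(ValueError, match="missing"):
        family_clade(t, ["F1", "nope"])


def test_assign_species_sister_to_reference():
    t = _hand_tree("(((R_a,(R_a2,Q1)),(R_b,Q2),U1),OUT);")
    t.is_rooted = True
    labels = assign_species_by_clade(
        t, ["Q1", "Q2", "U1"],
        {"spA": ["R_a", "R_a2"], "spB": ["R_b"]},
    )
    assert labels["Q1"] == "spA"
    assert labels["Q2"] == "spB"
    # sister to the whole family: inside the clade but matching no species
    assert labels["U1"] == "family-unplaced"


def test_assign_species_outside_family_clade():
    t = _hand_tree("(((R_a,Q1),R_b),(Q2,OUT));")
    t.is_rooted = True
    labels = assign_species_by_clade(
        t, ["Q1", "Q2"], {"spA": ["R_a"], "spB": ["R_b"]}
    )
    assert labels["Q1"] == "spA"
    assert labels["Q2"] == "outside"


def test_assign_species_identity_floor_separates_novel():
    """A lineage sister to spA's reference but below the identity floor is a
    candidate new taxon (the restricted-clade case)."""
    t = _hand_tree("(((R_a,NOV),R_b),OUT);")
    t.is_rooted = True
    labels = assign_species_by_clade(
        t, ["NOV"], {"spA": ["R_a"], "spB": ["R_b"]},
        rep_best_identity={"NOV": ("spA", 0.905)},
        identity_floor=0.94,
    )
    assert labels["NOV"] == "family-unplaced"
    labels2 = assign_species_by_clade(
        t, ["NOV"], {"spA": ["R_a"], "spB": ["R_b"]},
        rep_best_identity={"NOV": ("spA", 0.985)},
        identity_floor=0.94,
    )
    assert labels2["NOV"] == "spA"


def test_assign_species_errors_on_missing_leaf():
    t = _hand_tree("((R_a,Q1),OUT);")
    t.is_rooted = True
    with pytest.raises(ValueError):
        assign_species_by_clade(t, ["ghost"], {"spA": ["R_a"]})


# ------------------------------------------------------- fitch & bootstrap

def test_fitch_hand_examples():
    rows = {"A": "A", "B": "A", "C": "C", "D": "C"}
    assert fitch_length(_hand_tree("((A,B),(C,D));"), rows) == 1
    assert fitch_length(_hand_tree("((A,C),(B,D));"), rows) == 2
    same = {k: "ACGT" for k in "ABCD"}
    assert fitch_length(_hand_tree("((A,B),(C,D));"), same) == 0


def test_fitch_matches_brute_force_on_random_five_leaf_cases(rng):
    mask = {"A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}}
    for rep in range(15):
        children, root = _random_topology(5, rng)
        col = [str("ACGT"[i]) for i in rng.integers(0, 4, 5)]
        rows = {str(i): col[i] for i in range(5)}
        # package tree built from the same topology
        def newick(node):
            if node not in children:
                return str(node)
            return "(" + ",".join(newick(c) for c in children[node]) + ")"
        t = _hand_tree(newick(root) + ";")
        got = fitch_length(t, rows)
        leaf_states = {i: mask[col[i]] for i in range(5)}
        assert got == fitch_brute_force(children, root, leaf_states)


def test_bootstrap_identical_cherry_fully_supported(rng):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
    from ampliscreen.simulate import mutate_sequence
    rows = {
        "t1": base,
        "t2": base,  # identical pair
        "t3": mutate_sequence(base, 20, 0, seed=1),
        "t4": mutate_sequence(base, 20, 0, seed=2),
        "t5": mutate_sequence(base, 25, 0, seed=3),
    }
    tree, support = bootstrap_support(rows, n_replicates=50, seed=9)
    key = min(frozenset({"t1", "t2"}), frozenset({"t3", "t4", "t5"}), key=sorted)
    assert support[key] == 1.0
    assert all(0.0 <= v <= 1.0 for v in support.values())


def test_bootstrap_reproducible_and_leaf_order_invariant(rng):
    from ampliscreen.simulate import mutate_sequence
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    rows = {f"x{i}": mutate_sequence(base, 3 + 2 * i, 0, seed=i) for i in range(5)}
    _, s1 = bootstrap_support(rows, n_replicates=30, seed=4)
    _, s2 = bootstrap_support(rows, n_replicates=30, seed=4)
    assert s1 == s2
    permuted = dict(reversed(list(rows.items())))
    _, s3 = bootstrap_support(permuted, n_replicates=30, seed=4)
    assert set(s3) == set(s1)


# ----------------------------------------------------------------------- g1

def test_g1_undefined_for_identical_rows():
    res = random_tree_g1({k: "ACGTACGT" for k in "abcde"}, n_trees=100, seed=0)
    assert res.undefined
    assert res.sd == 0.0


def test_g1_negative_for_treelike_alignment(rng):
    from ampliscreen.simulate import mutate_sequence
    anc = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
    left = mutate_sequence(anc, 25, 0, seed=1)
    right = mutate_sequence(anc, 25, 0, seed=2)
    rows = {}
    for i in range(4):
        rows[f"L{i}"] = mutate_sequence(left, 5, 0, seed=10 + i)
        rows[f"R{i}"] = mutate_sequence(right, 5, 0, seed=20 + i)
    res = random_tree_g1(rows, n_trees=400, seed=7)
    assert not res.undefined
    assert res.g1 < 0
    assert res.min >= 0 and res.max >= res.min


def test_g1_statistic_matches_direct_skewness(rng):
    """The g1 moment computation agrees with an independent skewness on the
    realised length distribution."""
    from ampliscreen.simulate import mutate_sequence
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
    rows = {f"t{i}": mutate_sequence(base, 6, 0, seed=i) for i in range(5)}
    res = random_tree_g1(rows, n_trees=200, seed=3)
    # recompute lengths independently through fitch_length on the same trees
    lengths = []
    gen = np.random.default_rng(3)
    masks = rows  # same rows
    for _ in range(200):
        children, root = _random_topology(5, gen)
        def newick(node):
            if node not in children:
                return f"t{node}"
            return "(" + ",".join(newick(c) for c in children[node]) + ")"
        t = _hand_tree(newick(root) + ";")
        lengths.append(fitch_length(t, rows))
    lengths = np.array(lengths)
    assert lengths.mean() == pytest.approx(res.mean)
    assert sps.skew(lengths, bias=True) == pytest.approx(res.g1, abs=1e-9)
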