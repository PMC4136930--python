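"""Capture clustering, OTU reclustering, rare removal, furthest-neighbor,
chimera screen."""

import numpy as np
import pytest

from ampliscreen.align import identity
from ampliscreen.cluster import (
    chimera_screen,
    furthest_neighbor_cluster,
    greedy_capture,
    recluster_otus,
    remove_rare_otus,
)
from ampliscreen.core import AmpliconRead, Cluster, RefSeq, TaxonomyPath
from ampliscreen.simulate import mutate_sequence


def _ref(rid, seq, family="FamA"):
    return RefSeq(rid, TaxonomyPath.from_names(["Euk", family, f"sp_{rid}"]), "V4", seq)


def _read(rid, seq, sample="s1"):
    return AmpliconRead(rid, sample, seq)


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(41)
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
    return [
        _ref("refA", base),
        _ref("refB", mutate_sequence(base, 15, 0, seed=1)),  # 10% from refA
    ]


def test_exact_copy_joins_reference_cluster(refs):
    clusters, unmatched = greedy_capture([_read("r1", refs[0].sequence)], refs)
    assert list(clusters) == ["refA"]
    assert clusters["refA"].member_ids == ["r1"]
    assert unmatched == []


def test_read_below_cutoff_unmatched(refs):
    far = mutate_sequence(refs[0].sequence, 40, 0, seed=2)  # ~0.73 to refA
    clusters, unmatched = greedy_capture([_read("r1", far)], refs)
    assert not clusters
    assert [r.id for r in unmatched] == ["r1"]


def test_capture_matches_thresholded_argmax_oracle(refs, rng):
    """30 reads at planted identities straddling 0.90 vs the brute-force rule."""
    reads = []
    for i in range(30):
        src = refs[i % 2]
        k = int(rng.integers(0, 30))  # 0..20% divergence
        reads.append(_read(f"r{i:02d}", mutate_sequence(
            src.sequence, k, 0, seed=int(rng.integers(0, 2**31)))))
    clusters, unmatched = greedy_capture(reads, refs, cutoff=0.90)
    got = {}
    for ref_id, c in clusters.items():
        for rid in c.member_ids:
            got[rid] = ref_id
    for rd in reads:
        idents = {r.id: identity(rd.sequence, r.sequence) for r in refs}
        best = max(idents.values())
        if best >= 0.90:
            winner = min(r for r, v in idents.items() if v == best)
            assert got[rd.id] == winner
        else:
            assert rd.id not in got
    # partition property
    assert sorted([*got, *(r.id for r in unmatched)]) == sorted(r.id for r in reads)


def test_capture_per_sample_counts_conserved(refs):
    reads = [
        _read("r1", refs[0].sequence, "s1"),
        _read("r2", refs[0].sequence, "s2"),
        _read("r3", refs[0].sequence, "s2"),
    ]
    clusters, _ = greedy_capture(reads, refs)
    c = clusters["refA"]
    assert c.per_sample_counts == {"s1": 1, "s2": 2}
    assert sum(c.per_sample_counts.values()) == c.size


def test_capture_cutoff_domain(refs):
    with pytest.raises(ValueError):
        greedy_capture([], refs, cutoff=1.5)


def test_recluster_identical_reads_one_otu():
    reads = [_read(f"r{i}", "ACGTACGTACGT") for i in range(5)]
    otus = recluster_otus(reads)
    assert len(otus) == 1
    assert otus[0].size == 5


def test_recluster_two_separated_groups(rng):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
    other = mutate_sequence(base, 10, 0, seed=3)  # ~0.93 identity: two OTUs
    reads = [_read(f"a{i}", base) for i in range(3)] + [
        _read(f"b{i}", other) for i in range(3)
    ]
    otus = recluster_otus(reads, cutoff=0.97)
    assert len(otus) == 2
    sizes = sorted(o.size for o in otus)
    assert sizes == [3, 3]


def test_recluster_invariant_to_input_order(rng):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
    reads = [
        _read(f"r{i}", mutate_sequence(base, int(rng.integers(0, 8)), 0,
                                       seed=int(rng.integers(0, 2**31))))
        for i in range(12)
    ]
    def signature(otus):
        return sorted((o.seed_id, tuple(sorted(o.member_ids))) for o in otus)
    forward = recluster_otus(reads)
    backward = recluster_otus(list(reversed(reads)))
    shuffled = list(reads)
    np.random.default_rng(0).shuffle(shuffled)
    assert signature(forward) == signature(backward) == signature(recluster_otus(shuffled))


def test_recluster_partition_property(small_screen):
    result, _, _ = small_screen
    all_members = [rid for o in [*result.otus, *result.rare_otus] for rid in o.member_ids]
    assert len(all_members) == len(set(all_members))


def test_remove_rare_examples():
    def cl(seed, n):
        return Cluster(seed, [f"{seed}_{i}" for i in range(n)], 0.97, {"s1": n})
    otus = [cl("a", 1), cl("b", 2), cl("c", 3)]
    kept, removed = remove_rare_otus(otus, min_size=3)
    assert [o.seed_id for o in kept] == ["c"]
    assert sorted(o.seed_id for o in removed) == ["a", "b"]
    assert sum(o.size for o in kept) + sum(o.size for o in removed) == 6
    kept1, removed1 = remove_rare_otus(otus, min_size=1)
    assert len(kept1) == 3 and not removed1
    with pytest.raises(ValueError):
        remove_rare_otus(otus, min_size=0)


def test_rare_filter_removes_planted_error_variants(small_screen):
    result, _, truth = small_screen
    planted = {rid for rid, o in truth.origins.items() if o.is_planted_rare}
    removed_ids = {rid for o in result.rare_otus for rid in o.member_ids}
    kept_ids = {rid for o in result.otus for rid in o.member_ids}
    # every planted heavy-error variant was captured and then removed as rare
    assert planted & kept_ids == set()
    assert planted <= removed_ids


def test_furthest_neighbor_hand_examples():
    # identities giving distances AB=0.01, AC=BC=0.05
    m = np.array([
        [1.00, 0.99, 0.95],
        [0.99, 1.00, 0.95],
        [0.95, 0.95, 1.00],
    ])
    parts = furthest_neighbor_cluster(m, [0.97, 0.95, 1.0], ids=["A", "B", "C"])
    assert parts[0.97] == [["A", "B"], ["C"]]
    assert parts[0.95] == [["A", "B", "C"]]
    assert parts[1.0] == [["A"], ["B"], ["C"]]


def test_furthest_neighbor_nested_partitions(rng):
    n = 12
    pts = rng.random((n, 1))
    d = np.abs(pts - pts.T)
    m = 1.0 - d
    cutoffs = [0.99, 0.97, 0.9, 0.5]
    parts = furthest_neighbor_cluster(m, cutoffs)
    # higher cutoff refines lower: every fine cluster inside one coarse cluster
    for hi, lo in zip(cutoffs, cutoffs[1:]):
        coarse = {x: i for i, g in enumerate(parts[lo]) for x in g}
        for g in parts[hi]:
            assert len({coarse[x] for x in g}) == 1
    # partition property at every level
    for c in cutoffs:
        flat = sorted(x for g in parts[c] for x in g)
        assert flat == sorted(str(i) for i in range(n))


def test_furthest_neighbor_rejects_asymmetry():
    m = np.array([[1.0, 0.9], [0.8, 1.0]])
    with pytest.raises(ValueError):
        furthest_neighbor_cluster(m, [0.97])


def test_chimera_exact_copy_clean(refs):
    clean, flagged = chimera_screen([_read("r1", refs[0].sequence)], refs)
    assert [r.id for r in clean] == ["r1"]
    assert not flagged


def test_chimera_midpoint_mosaic_flagged(refs):
    a, b = refs[0].sequence, refs[1].sequence  # 10% divergent parents
    mosaic = a[:75] + b[75:]
    clean, flagged = chimera_screen([_read("x", mosaic)], refs, margin=0.02)
    assert [r.id for r in flagged] == ["x"]
    assert not clean


def test_chimera_screen_precision_on_simulated_study(full_screen):
    """Reference-based mosaic screen keeps precision >= 0.9 at default margin."""
    result, _, truth = full_screen
    flagged = {r.id for r in result.chimeras}
    assert flagged, "screen flagged nothing on a study with planted chimeras"
    true_pos = {rid for rid in flagged if truth.origins[rid].is_chimera}
    assert len(true_pos) / len(flagged) >= 0.9


def test_chimera_needs_two_refs(refs):
    with pytest.raises(ValueError):
        chimera_screen([], refs[:1])
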