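"""Normalisation, the exact conditional tag-count test, rarefaction, Venn."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ampliscreen.core import SampleMeta
from ampliscreen.stats import (
    ac_pmf,
    ac_test,
    bh_adjust,
    normalize,
    rarefaction,
    species_site_table,
    venn_sharing,
)


def _meta(sid, total, site="Naples", layer="surface", fraction="3-20",
          template="cDNA"):
    return SampleMeta(sid, site, "2010-05-01", layer, fraction, template, total)


# -------------------------------------------------------------- normalize

def test_normalize_simple_proportion():
    counts = pd.DataFrame({"s1": [10]}, index=pd.Index(["spA"], name="species"))
    tab = normalize(counts, [_meta("s1", 1000)])
    assert tab.proportions.loc["spA", "s1"] == 0.01


def test_normalize_hand_fixture_and_group_shares():
    counts = pd.DataFrame(
        {"s1": [10, 0], "s2": [5, 15], "s3": [0, 30]},
        index=pd.Index(["spA", "spB"], name="species"),
    )
    meta = [_meta("s1", 100), _meta("s2", 100), _meta("s3", 300)]
    tab = normalize(counts, meta, groups={"g": ["s1", "s2", "s3"]})
    # hand arithmetic: spA 0.1 + 0.05 + 0 = 0.15; spB 0 + 0.15 + 0.1 = 0.25
    assert tab.proportions.loc["spA", "s2"] == 0.05
    assert tab.group_shares.loc["spA", "g"] == pytest.approx(0.15 / 0.40)
    assert tab.group_shares["g"].sum() == pytest.approx(1.0, abs=1e-9)
    # zero-count species kept as explicit zeros
    assert tab.proportions.loc["spB", "s1"] == 0.0


def test_normalize_zero_total_with_counts_errors():
    counts = pd.DataFrame({"s1": [3]}, index=["spA"])
    with pytest.raises(ValueError):
        normalize(counts, [_meta("s1", 0)])


# ----------------------------------------------------------------- ac test

def test_ac_pmf_closed_form_values():
    assert ac_pmf(0, 0, 1000, 1000) == pytest.approx(0.5)
    # N1=N2, x=3, y=3 -> C(6,3)/2^7
    assert ac_pmf(3, 3, 500, 500) == pytest.approx(0.15625)


@pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
def test_ac_pmf_normalises(ratio):
    N1 = 10_000
    total = float(np.sum(ac_pmf(np.arange(0, 201), 5, N1, N1 * ratio)))
    assert total == pytest.approx(1.0, abs=1e-9)


def test_ac_pmf_matches_negative_binomial():
    """Independent cross-check: the conditional law is NB(x+1, N1/(N1+N2))."""
    for x, n1, n2 in [(0, 100, 100), (7, 300, 150), (4, 100, 400)]:
        ys = np.arange(0, 60)
        ours = ac_pmf(ys, x, n1, n2)
        ref = sps.nbinom.pmf(ys, x + 1, n1 / (n1 + n2))
        assert np.allclose(ours, ref, atol=1e-12)


def test_ac_pmf_rejects_bad_input():
    with pytest.raises(ValueError):
        ac_pmf(-1, 0, 10, 10)
    with pytest.raises(ValueError):
        ac_pmf(0, 0, 0, 10)


def test_ac_test_x0_equal_libraries_upper_bound():
    """x=0, N1=N2: P(Y >= y) = 2^-y, so the 0.05 range tops out at y_hi = 5."""
    r = ac_test(0, 0, 5000, 5000)
    assert r.expected_range == (0, 5)
    assert not r.significant
    assert ac_test(0, 6, 5000, 5000).significant


def test_ac_test_symmetric_observation_p_is_one():
    r = ac_test(9, 9, 2000, 2000)
    assert r.p_two_sided == pytest.approx(1.0)
    assert not r.significant


def test_ac_test_swap_symmetry():
    """Swapping (x, N1) with (y, N2) leaves the significance call unchanged."""
    for x, y, n1, n2 in [
        (3, 30, 1000, 2000), (30, 3, 2000, 1000), (5, 5, 800, 800),
        (0, 4, 1000, 1000), (12, 40, 1000, 4000), (7, 2, 500, 1500),
    ]:
        a = ac_test(x, y, n1, n2)
        b = ac_test(y, x, n2, n1)
        assert a.significant == b.significant, (x, y, n1, n2)


def test_ac_test_significant_iff_outside_range():
    for x, y in [(5, 5), (5, 25), (0, 2), (2, 0), (40, 10)]:
        r = ac_test(x, y, 1500, 1500)
        lo, hi = r.expected_range
        assert r.significant == (y < lo or y > hi)


def test_ac_test_type_one_error_under_null(rng):
    """10,000 null splits of a tag between two equal libraries: the fraction
    declared significant at alpha 0.05 stays at or below 0.06."""
    n_sims = 10_000
    N = 50_000
    totals = rng.poisson(40, size=n_sims) + 1
    xs = rng.binomial(totals, 0.5)
    ys = totals - xs
    # cache by x: the expected range depends only on x
    range_of: dict[int, tuple[int, int]] = {}
    sig = 0
    for x, y in zip(xs, ys):
        if int(x) not in range_of:
            range_of[int(x)] = ac_test(int(x), 0, N, N).expected_range
        lo, hi = range_of[int(x)]
        sig += not (lo <= y <= hi)
    assert sig / n_sims <= 0.06


def test_bh_adjust_monotone():
    ps = [0.001, 0.01, 0.02, 0.8]
    adj = bh_adjust(ps)
    assert adj == sorted(adj)
    assert all(a >= p for a, p in zip(adj, ps))


# -------------------------------------------------------------- rarefaction

def test_rarefaction_hand_value():
    df = rarefaction([4, 1], [2])
    assert df["expected_otus"].iloc[0] == pytest.approx(1.4)


def test_rarefaction_endpoints_and_monotonicity():
    sizes = [50, 30, 20, 5, 1]
    N = sum(sizes)
    grid = [1, 10, 25, 50, N]
    df = rarefaction(sizes, grid)
    vals = df["expected_otus"].to_numpy()
    assert vals[0] == pytest.approx(1.0)
    assert vals[-1] == pytest.approx(len(sizes))
    assert np.all(np.diff(vals) >= -1e-12)
    with pytest.raises(ValueError):
        rarefaction(sizes, [N + 1])


def test_rarefaction_matches_monte_carlo(rng):
    """Closed form vs 10,000-rep random subsampling, within 3 standard errors."""
    sizes = [50, 30, 20, 5, 1]
    N = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    reps = 10_000
    for n in (5, 20, 60):
        seen = np.empty(reps)
        for r in range(reps):
            pick = rng.choice(N, size=n, replace=False)
            seen[r] = len(np.unique(labels[pick]))
        closed = rarefaction(sizes, [n])["expected_otus"].iloc[0]
        se = seen.std(ddof=1) / np.sqrt(reps)
        assert abs(closed - seen.mean()) <= 3 * se


# --------------------------------------------------------------------- venn

def test_venn_hand_enumeration():
    out = venn_sharing({"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3}})
    assert out[("A",)] == 1 and out[("B",)] == 1 and out[("C",)] == 0
    assert out[("A", "B")] == 1 and out[("A", "B", "C")] == 1
    assert out[("A", "C")] == 0 and out[("B", "C")] == 0


def test_venn_disjoint_and_identical():
    d = venn_sharing({"A": {1}, "B": {2}})
    assert d[("A",)] == 1 and d[("B",)] == 1 and d[("A", "B")] == 0
    i = venn_sharing({"A": {1, 2}, "B": {1, 2}})
    assert i[("A", "B")] == 2 and i[("A",)] == 0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.lists(
        st.sets(st.integers(min_value=0, max_value=30)),
        min_size=2, max_size=4,
    )
)
def test_venn_regions_sum_to_union(sets):
    named = {f"S{i}": s for i, s in enumerate(sets)}
    out = venn_sharing(named)
    assert sum(out.values()) == len(set.union(*sets)) if sets else True


def test_venn_rejects_five_sites():
    with pytest.raises(ValueError):
        venn_sharing({str(i): {i} for i in range(5)})


# ------------------------------------------------------- species site table

def test_species_site_table_single_sample_site():
    counts = pd.DataFrame(
        {"s1": [10, 0]}, index=pd.Index(["spA", "spB"], name="species")
    )
    meta = [_meta("s1", 200)]
    shares, presence = species_site_table(counts, meta)
    assert shares.loc["spA", "Naples"] == pytest.approx(0.05)
    assert shares.loc["spB", "Naples"] == 0.0
    assert bool(presence.loc["spA", "Naples"]) is True
    assert bool(presence.loc["spB", "Naples"]) is False


def test_species_site_table_means_over_fractions():
    counts = pd.DataFrame(
        {"s1": [10], "s2": [30], "s3": [0]},
        index=pd.Index(["spA"], name="species"),
    )
    meta = [
        _meta("s1", 100, fraction="0.8-3"),
        _meta("s2", 100, fraction="3-20"),
        _meta("s3", 100, fraction="20-2000"),
    ]
    shares, _ = species_site_table(counts, meta)
    assert shares.loc["spA", "Naples"] == pytest.approx((0.1 + 0.3 + 0.0) / 3)
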