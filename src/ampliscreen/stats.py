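"""Normalisation, differential tag-count testing, rarefaction and OTU sharing.

The differential test is the exact conditional comparison of a tag's counts
between two libraries of sizes N1 and N2 (Audic & Claverie): conditional on
observing x counts in library 1, the count in library 2 follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

a negative-binomial distribution with x+1 successes and success probability
N1/(N1+N2).  The expected range at level alpha is the equal-tail interval of
this conditional distribution; the two-sided p doubles the smaller tail
(capped at 1).  No multiple-testing correction is applied by default; a
Benjamini–Hochberg option is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import SampleMeta

__all__ = [
    "AbundanceTable",
    "ACResult",
    "normalize",
    "ac_pmf",
    "ac_test",
    "rarefaction",
    "venn_sharing",
    "species_site_table",
    "bh_adjust",
]


@dataclass
class AbundanceTable:
    """Species x sample counts with per-sample proportions and group shares."""

    counts: pd.DataFrame  # species rows, sample columns, ints
    proportions: pd.DataFrame  # counts / SampleMeta.total_reads
    group_shares: pd.DataFrame  # per group: species shares summing to 1


def normalize(
    counts: pd.DataFrame,
    metadata: list[SampleMeta],
    groups: dict[str, list[str]] | None = None,
) -> AbundanceTable:
    """Per-sample proportions and per-group renormalised shares.

    Each count is divided by its sample's ``total_reads``; for every named
    sample group the per-species summed proportions are renormalised to 1.
    Zero-count species are kept as explicit zeros.
    """
    meta = {m.sample_id: m for m in metadata}
    missing = [c for c in counts.columns if c not in meta]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    props = counts.astype(float).copy()
    for c in counts.columns:
        total = meta[c].total_reads
        if total == 0:
            if counts[c].sum() > 0:
                raise ValueError(f"sample {c} has reads but total_reads == 0")
            props[c] = 0.0
        else:
            props[c] = counts[c] / total
    groups = groups or {"all": list(counts.columns)}
    share_cols = {}
    for gname, samples in groups.items():
        summed = props[samples].sum(axis=1)
        tot = summed.sum()
        share_cols[gname] = summed / tot if tot > 0 else summed
    shares = pd.DataFrame(share_cols)
    return AbundanceTable(counts=counts, proportions=props, group_shares=shares)


def _log_ac_pmf(y: np.ndarray, x: int, N1: float, N2: float) -> np.ndarray:
    q = N2 / N1
    y = np.asarray(y, dtype=float)
    return (
        y * np.log(q)
        + gammaln(x + y + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y + 1.0)
        - (x + y + 1.0) * np.log1p(q)
    )


def ac_pmf(y: int | np.ndarray, x: int, N1: float, N2: float) -> float | np.ndarray:
    """Conditional probability of y counts in library 2 given x in library 1."""
    if np.any(np.asarray(y) < 0) or x < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    out = np.exp(_log_ac_pmf(np.asarray(y), x, N1, N2))
    return float(out) if np.isscalar(y) or np.asarray(y).ndim == 0 else out


@dataclass
class ACResult:
    x: int
    y: int
    N1: float
    N2: float
    p_two_sided: float
    expected_range: tuple[int, int]
    significant: bool


def _ac_cdf_table(x: int, N1: float, N2: float, upto: int) -> np.ndarray:
    ys = np.arange(upto + 1)
    pmf = np.exp(_log_ac_pmf(ys, x, N1, N2))
    return np.cumsum(pmf)


def ac_test(x: int, y: int, N1: float, N2: float, alpha: float = 0.05) -> ACResult:
    """Exact conditional two-library test with an equal-tail expected range.

    y_lo is the largest y with P(Y < y) <= alpha/2; y_hi the smallest y with
    P(Y > y) <= alpha/2; ``significant`` iff the observed y falls outside
    [y_lo, y_hi].  p_two_sided = min(1, 2 * min(P(Y <= y), P(Y >= y))).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    q = N2 / N1
    mean = (x + 1) * q
    upto = int(max(y + 10, mean + 20 * np.sqrt(mean * (1 + q)) + 50))
    cdf = _ac_cdf_table(x, N1, N2, upto)
    while cdf[-1] < 1.0 - 1e-12:
        upto *= 2
        cdf = _ac_cdf_table(x, N1, N2, upto)
    # y_lo: largest yy with P(Y < yy) <= alpha/2
    p_less = np.concatenate([[0.0], cdf[:-1]])  # P(Y < yy) for yy = 0..upto
    lo_candidates = np.nonzero(p_less <= alpha / 2.0 + 1e-15)[0]
    y_lo = int(lo_candidates.max())
    # y_hi: smallest yy with P(Y > yy) <= alpha/2
    p_greater = 1.0 - cdf
    hi_candidates = np.nonzero(p_greater <= alpha / 2.0 + 1e-15)[0]
    y_hi = int(hi_candidates.min())
    p_le = cdf[min(y, upto)] if y <= upto else 1.0
    p_ge = 1.0 - (cdf[y - 1] if 0 < y <= upto else (0.0 if y == 0 else 1.0))
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return ACResult(
        x=x, y=y, N1=N1, N2=N2,
        p_two_sided=float(p),
        expected_range=(y_lo, y_hi),
        significant=not (y_lo <= y <= y_hi),
    )


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (off by default in the pipeline)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj.tolist()


def rarefaction(otu_sizes: list[int], grid: list[int]) -> pd.DataFrame:
    """Expected OTU richness in random subsamples of n reads (no replacement).

    E[S(n)] = sum_i [1 - C(N - N_i, n) / C(N, n)], evaluated with log-gamma
    for stability.  Monotone non-decreasing in n; E[S(N)] equals the OTU count.
    """
    sizes = np.asarray(otu_sizes, dtype=np.int64)
    if np.any(sizes <= 0):
        raise ValueError("OTU sizes must be positive")
    N = int(sizes.sum())
    out = []
    for n in grid:
        if not 0 <= n <= N:
            raise ValueError(f"subsample size {n} exceeds total reads {N}")
        # log C(N - Ni, n) - log C(N, n), defined when N - Ni >= n
        ok = (N - sizes) >= n
        lognum = (
            gammaln(N - sizes[ok] + 1)
            - gammaln(n + 1)
            - gammaln(N - sizes[ok] - n + 1)
        )
        logden = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
        expected = float((1.0 - np.exp(lognum - logden)).sum() + (~ok).sum())
        out.append({"n": n, "expected_otus": expected})
    return pd.DataFrame(out)


def venn_sharing(site_otus: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Counts of every intersection region among 2-4 sites' OTU sets.

    Region (A, B) counts OTUs in A and B and in no other site; the region
    counts sum to the size of the union.
    """
    k = len(site_otus)
    if not 2 <= k <= 4:
        raise ValueError(
            "venn_sharing handles 2-4 sites; report a pairwise sharing matrix "
            "for larger designs"
        )
    sites = sorted(site_otus)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, k + 1):
        for combo in combinations(sites, r):
            inside = set.intersection(*(site_otus[s] for s in combo))
            for other in sites:
                if other not in combo:
                    inside = inside - site_otus[other]
            out[combo] = len(inside)
    return out


def species_site_table(
    species_counts: pd.DataFrame,
    metadata: list[SampleMeta],
    layer: str = "surface",
    template: str = "cDNA",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site mean relative frequency of each species (the map-figure recipe).

    For each site, per-species proportions (count / sample total) are averaged
    over the size fractions of the selected layer/template samples.  Returns
    (share matrix, boolean presence matrix), species x site.
    """
    meta = {m.sample_id: m for m in metadata}
    chosen = [
        c for c in species_counts.columns
        if meta[c].layer == layer and meta[c].template == template
    ]
    if not chosen:
        raise ValueError(f"no samples with layer={layer!r} template={template!r}")
    sites = sorted({meta[c].site for c in chosen})
    shares = pd.DataFrame(0.0, index=species_counts.index, columns=sites)
    for site in sites:
        cols = [c for c in chosen if meta[c].site == site]
        props = []
        for c in cols:
            total = meta[c].total_reads
            props.append(
                species_counts[c] / total if total > 0 else species_counts[c] * 0.0
            )
        shares[site] = pd.concat(props, axis=1).mean(axis=1)
    presence = shares > 0
    return shares, presence
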