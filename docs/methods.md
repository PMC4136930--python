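# Methods

This note documents the models, conventions and design choices behind
`ampliscreen`, in the order the pipeline applies them.

## Sequence identity

Every capture, assignment and mining decision rests on one identity measure:
the fraction of matching columns in the optimal global alignment under an
affine-gap scheme (match +5, mismatch −4, gap open −10, gap extend −1; a gap
of length L costs 10 + L). The dynamic programme is a full-matrix Gotoh
recursion with deterministic traceback tie-breaking (diagonal, then up, then
left) compiled with numba; its scores are verified against brute-force
alignment-path enumeration in the test suite. Two conventions matter and are
explicit:

- **Denominator.** Identity = matches / alignment columns, *excluding*
  leading and trailing terminal-gap runs, so a short tag nested in a longer
  reference is not penalised for length. The CD-HIT convention (matches over
  the shorter sequence's length) is available via `denominator="shorter"`.
  Whether the original screening tools counted terminal gap columns is not
  documented; this choice is the more permissive one for mixed-length data
  and is applied uniformly.
- **Ambiguity.** `N` is a mismatch against everything, including `N`.

Scoring values are standard DNA defaults; the screen's decisions depend on
identity ranks and thresholds, not on the absolute score scale. Banded or
heuristic acceleration is deliberately absent — inputs are desk-scale and
exactness keeps every threshold decision reproducible.

## Assignment and the taxon filter

Best-hit assignment keeps the full lineage of the unique highest-identity
reference; ties (identities equal after rounding to 4 decimals, so
equal-scoring alignments compare equal) fall back to the last common ancestor
of the tied lineages. The consensus variant considers every hit within
`top_window` of the best identity (default 0: exact ties only, matching the
best-hit behaviour) and truncates to the deepest rank where at least 80% of
hits agree; the threshold is inclusive (4 of 5 = 0.80 passes). Reads whose
assigned lineage contains the target phylum form the initial dataset.

## Clustering funnel

- **Capture (0.90).** Each read joins the reference of maximal identity when
  that identity reaches the cutoff; ties go to the lexicographically smallest
  reference id. Clusters seeded by non-family references are eliminated.
- **Chimera screen (margin 0.02).** For each read, one global alignment per
  family reference yields 5′/3′ segment match counts at every scanned
  breakpoint (every 10% of read length); the read is flagged when the best
  column-weighted two-parent mosaic identity exceeds the best single-parent
  identity by the margin. The screen runs before OTU formation so mosaics
  cannot seed OTUs. Geometry caps its sensitivity: a mosaic of two parents
  d apart can gain at most ~d/2, so parents less than ~4–5% divergent
  produce chimeras at or below the default margin. On synthetic studies the
  screen's precision is 1.0 (non-chimeric reads have mosaic gain ≈ 0) and its
  recall ~0.1–0.3 depending on which parent pairs recombine; survivors are
  absorbed by the species-assignment fallback below.
- **OTUs (0.97).** Greedy incremental clustering within each capture
  cluster: reads in canonical order (longest first, then lexicographic id)
  join the best-matching existing seed at or above the cutoff or found a new
  OTU. Exact duplicate sequences are collapsed before seeding and re-expanded
  after — identical sequences always co-cluster and the partition property is
  preserved. The canonical order makes results independent of input order.
- **Rare-OTU removal.** OTUs with fewer than 3 members (singletons and
  doubletons), pooled across samples, are removed as probable sequencing
  errors. Read counts are conserved between the kept and removed partitions.
- **Furthest-neighbor clustering** (for the OTU-based diversity analyses)
  rounds distances 1 − identity to 1/1000 and agglomerates by complete
  linkage (scipy); a merge requires every within-cluster distance ≤ 1 −
  cutoff, and partitions are nested across cutoffs.

## Phylogenetic validation

One representative per OTU — its seed read — enters the tree. Representatives
are *template-threaded*: globally aligned to their nearest reference and
projected into that reference's master-alignment columns; query insertions
relative to the template are dropped and counted. This trades alignment
fidelity for column stability (the master's coordinate system never changes),
which is what the clade logic needs.

Distances are p-distances over shared ungapped columns (Jukes–Cantor
correction available; the validation consumes topology, not branch lengths,
and at within-family divergences the two orderings agree). The tree is
neighbor-joining with the standard Q criterion, smallest-index tie-breaking,
and negative branch lengths clamped to zero with the subtraction shifted to
the sister edge; it is rooted on the far-outgroup (bolidophyte) references,
which must be monophyletic — a non-monophyletic outgroup is an error, never
silently resolved. Maximum-likelihood inference is intentionally out of
scope: the decision rules use only clade membership, and NJ over the same
alignment recovers it at these divergences (verified exhaustively on additive
matrices up to 6 taxa).

**Species assignment.** The family clade is the smallest clade containing all
family references. For an OTU inside it:

1. If its representative's best identity to any family reference falls below
   the *family envelope* — by default the minimum pairwise identity among the
   family references themselves — the OTU is a candidate new taxon
   ("family-unplaced"): it is farther from every reference than any two
   family species are from each other.
2. Otherwise, if the smallest ancestral clade holding any reference holds
   references of exactly one species, topology decides.
3. Otherwise (a topologically ambiguous position between species clades,
   e.g. a surviving close-parent chimera) the nearest reference's species is
   used — the same nearest-neighbour fallback the original screen applied to
   unresolved placements.

OTUs outside the family clade are false-positive candidates and are removed
from the curated dataset (their nearest-reference identities are reported).
A fixed identity floor was rejected during design: any constant high enough
to isolate a 9%-divergent novel lineage also mislabels legitimate
sequencing-error satellite OTUs (~3% from their reference) as novel, whereas
the family envelope separates the two scales cleanly and adapts to the panel.

**Phylogenetic signal.** `random_tree_g1` draws uniform random leaf-labelled
binary topologies (sequential random attachment, 2k−3 edges at step k),
computes each tree's Fitch parsimony length (bitmask set operations,
vectorised across columns; gaps and N are fully ambiguous), and reports the
g1 skewness of the length distribution — left skew (g1 < 0) indicates
hierarchical structure. Thresholds for significance are left to the caller,
as they depend on the number of informative sites and taxa. Defaults of
1,000–10,000 trees give a stable g1 sign; the statistic's scale is
insensitive to adding more trees. Bootstrap support is column-resampling NJ
(100 replicates by default), reported per original bipartition.

## Database mining

`mine` retains a database hit when its identity to the query is at least the
family floor t(q) = min over family references r≠q of identity(r, q), and
promotes retained hits to queries until a fixed point or `max_generations`
(default 5). The floor is taken over *all* family references; the variant
that restricts the minimum to references present among the returned hits
would loosen the rule and is not used. `doubt_check` discards a candidate
whose nearest non-self neighbour is annotated outside the family; exact ties
discard (conservative). Identity here is the global-alignment identity above,
not a local-alignment bit-score — one identity definition across the package.

## Count statistics

The two-library comparison is the exact conditional test: given x counts in
a library of size N1, the count in a library of size N2 follows
p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)), computed in log space
(equivalently negative binomial with x+1 successes and success probability
N1/(N1+N2), which serves as an independent cross-check in the tests). The
expected range at level α is the equal-tail interval (largest y with
P(Y<y) ≤ α/2; smallest y with P(Y>y) ≤ α/2); significance means the observed
count falls outside it. The two-sided p doubles the smaller tail, capped at
1 — the underlying statistic is one-sided, but reporting a *range* implies an
equal-tail two-sided convention, which is what is implemented. Because the
distribution is discrete the test is conservative: measured type-I error
under 10,000 null binomial splits is ~0.04 at nominal 0.05. No
multiple-testing correction is applied by default; Benjamini–Hochberg is
available behind a flag.

Rarefaction uses the exact hypergeometric expectation with log-gamma
evaluation; normalisation divides by each sample's total read count and
renormalises group sums to 1, keeping zero-count species as explicit zeros.
Per-site species tables follow the surface/cDNA mean-over-fractions recipe
by default (overridable).

## Synthetic data: what it emulates and what it does not

The generator is a pure function of (config, design, seed). It reproduces the
statistical structure the screen's thresholds care about:

- reference identity bands: family members mutually 93–99% identical
  (disjoint substitution sets from a common ancestor make pairwise
  divergences exact), outgroup diatoms 80–90% to the family with one placed
  just below the 0.90 capture boundary, two far outgroups < 80% sharing a
  long stem so they root the tree;
- a planted novel lineage, 29 substitutions + 7 indels from its nearest
  reference (edit distance 36 by construction), present at one of six sites;
- per-base substitution errors (default 1%), two-parent chimeras drawn from
  the *co-amplified* community of each sample (a chimera of templates absent
  from the sample would be unphysical), off-target reads, and planted
  singleton/doubleton heavy-error variants that the rare filter must remove;
- per-sample read depth is a single `reads_per_sample` knob (default 1,000).
  The orders-of-magnitude depth disparity between real V4 and V9 datasets is
  emulated by generating two studies at different depths and comparing them
  (as `compare_datasets` does), rather than by drawing random per-sample
  depths — fixed depths keep every fixture's expected counts exact.

Not emulated: platform-specific error profiles (454 homopolymer errors,
Illumina quality decay), PCR amplification bias, intragenomic rRNA variation
(intra-species variation defaults to 0, matching the low internal variation
reported for this family). Passing the recovery tests therefore demonstrates
the decision logic's correctness under idealised noise, not robustness to
platform artefacts.

## Problem sizes

The bundled end-to-end study runs 6 sites × 1,000 reads per sample at V4
length (390 bp) with 1% errors — about 6,000 reads, ~700k full-matrix
390×390 alignments, ≈4 minutes on one CPU. This depth is the package's
chosen desk-scale operating point: every rate, length, threshold and the
planted novel lineage are at their defaults, and detection of the rarest
community members (≥2.5% relative abundance → ≥25 expected reads) is
comfortably determined while the whole suite stays fast. The statistical
checks use 10,000 replicates (type-I error, rarefaction Monte-Carlo) and
2,000 random trees for g1.

## Known limitations

- Greedy OTU clustering at 1% error produces many singleton satellites
  (hundreds per 6,000 reads); the rare filter removes them, but OTU *counts*
  before filtering are sensitive to depth and error rate in a way species
  presence/absence is not.
- Close-parent chimeras (< ~4% parent divergence) are intrinsically below
  the mosaic screen's default margin; they are handled downstream by the
  species-assignment fallback rather than removed.
- The NJ placement of a single intermediate-divergence leaf (e.g. one
  isolated OTU ~10% from everything) can oscillate between just-inside and
  just-outside the family clade on sparse trees; the pipeline's trees carry
  all kept OTUs, which stabilises the placement, but single-sequence
  validation runs should prefer `correction="jc"` and more references.
- Branch lengths after rerooting are bookkeeping, not estimates; only
  topology feeds the decisions.
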