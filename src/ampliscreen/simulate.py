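"""Synthetic reference panels and amplicon studies with known ground truth.

The generator emulates the statistical structure the screen assumes: a small
family of target diatom species whose amplicons are mutually 93–99% identical,
outgroup diatoms at 80–90% identity to the family (including one deliberately
near the 0.90 capture boundary), two far outgroup flagellates (<80%, used for
rooting), a planted novel lineage differing from its nearest reference by a
configured number of substitutions and indels, per-sample communities, per-base
substitution errors, two-parent chimeras, off-target reads, and planted
singleton/doubleton error variants for the rare-OTU filter to catch.

All generation is a pure function of (config, design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AmpliconRead, RefSeq, SampleMeta, TaxonomyPath

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ReadOrigin",
    "make_reference_panel",
    "mutate_sequence",
    "simulate_study",
    "default_design",
    "default_communities",
    "NOVEL_LABEL",
]

_BASES = np.array(["A", "C", "G", "T"])
NOVEL_LABEL = "novel-clade"

_FAMILY_PATH = ("Eukaryota", "Stramenopiles", "Bacillariophyta", "Leptocylindraceae")
_OUT_DIATOM_PATH = ("Eukaryota", "Stramenopiles", "Bacillariophyta", "Chaetocerotaceae")
_FAR_OUT_PATH = ("Eukaryota", "Stramenopiles", "Bolidophyceae", "Bolidomonadaceae")
_RANKS = ("domain", "supergroup", "phylum", "family", "genus", "species")


@dataclass
class SimConfig:
    """Study-generator parameters.

    ``region_length`` defaults to the V4 amplicon length (390 bp; the V9 tag
    is 130 bp).  The planted novel lineage differs from its nearest family
    reference by ``novel_clade = (29, 7)`` substitutions/indels by default.
    ``communities`` maps site -> {species or NOVEL_LABEL -> relative
    abundance}; each site's abundances must sum to 1.
    """

    n_family_species: int = 6
    n_outgroup_taxa: int = 2
    region: str = "V4"
    region_length: int = 390
    reads_per_sample: int = 1000
    substitution_error_rate: float = 0.01
    chimera_rate: float = 0.02
    offtarget_fraction: float = 0.05
    novel_clade: tuple[int, int] = (29, 7)
    n_planted_singletons: int = 4
    n_planted_doubletons: int = 2
    communities: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("substitution_error_rate", self.substitution_error_rate),
            ("chimera_rate", self.chimera_rate),
            ("offtarget_fraction", self.offtarget_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.communities is not None:
            for site, comm in self.communities.items():
                tot = sum(comm.values())
                if abs(tot - 1.0) > 1e-9:
                    raise ValueError(
                        f"community for site {site!r} sums to {tot}, expected 1"
                    )


@dataclass
class ReadOrigin:
    """Ground-truth provenance of one generated read."""

    read_id: str
    sample_id: str
    origin: str  # species name, "chimera(parentA,parentB)", or "offtarget:<taxon>"
    is_chimera: bool = False
    is_offtarget: bool = False
    is_planted_rare: bool = False


@dataclass
class GroundTruth:
    """Everything the tests need to score the pipeline against."""

    origins: dict[str, ReadOrigin]
    presence: dict[str, dict[str, bool]]  # site -> species/NOVEL_LABEL -> present
    true_otu_of: dict[str, str]  # read_id -> origin group (species / novel / ...)

    def presence_matrix(self, sites: list[str], taxa: list[str]) -> np.ndarray:
        return np.array(
            [[self.presence[s].get(t, False) for t in taxa] for s in sites]
        )


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, length).astype(np.int8)


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _substitute(
    codes: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = codes.copy()
    shift = rng.integers(1, 4, positions.size).astype(np.int8)
    out[positions] = (out[positions] + shift) % 4
    return out


def mutate_sequence(seq: str, n_subs: int, n_indels: int, seed: int) -> str:
    """Apply exactly ``n_subs`` substitutions (always to a different base) and
    ``n_indels`` single-base insertions/deletions at distinct positions."""
    L = len(seq)
    if n_subs + n_indels > L:
        raise ValueError(
            f"cannot place {n_subs} substitutions + {n_indels} indels "
            f"in a sequence of length {L}"
        )
    rng = np.random.default_rng(seed)
    from .align import encode  # local import to avoid cycle at module load

    codes = encode(seq)
    positions = rng.choice(L, n_subs + n_indels, replace=False)
    sub_pos = positions[:n_subs]
    indel_pos = np.sort(positions[n_subs:])[::-1]  # right-to-left edits
    codes = _substitute(codes, sub_pos, rng)
    out = list(_to_str(codes))
    for p in indel_pos:
        if rng.random() < 0.5:  # deletion
            del out[p]
        else:  # insertion after p
            out.insert(p + 1, str(_BASES[rng.integers(0, 4)]))
    return "".join(out)


def _family_sub_counts(L: int, n: int) -> np.ndarray:
    """Per-species substitution counts from the family ancestor, chosen so
    that pairwise divergences (sums of disjoint counts) land in [0.01L, 0.07L],
    i.e. pairwise identity in [0.93, 0.99]."""
    lo = max(1, int(round(0.011 * L)))
    hi = max(lo + 1, int(round(0.033 * L)))
    return np.round(np.linspace(lo, hi, n)).astype(int)


def make_reference_panel(
    config: SimConfig,
) -> tuple[list[RefSeq], dict[str, str]]:
    """Build the annotated reference panel and its gapped master alignment.

    Returns ``(panel, master)`` where ``master`` maps reference id to its row
    in the master alignment.  References are substitution-only variants of a
    common ancestor, so the master alignment is column-for-column the
    unaligned panel (no gap columns); the planted novel lineage is *not* part
    of the panel — it exists only in the reads.
    """
    if config.n_family_species < 2:
        raise ValueError("need at least 2 family species")
    if config.n_outgroup_taxa < 2:
        raise ValueError("need at least 2 outgroup taxa")
    L = config.region_length
    rng = np.random.default_rng(config.seed)
    k = _family_sub_counts(L, config.n_family_species)
    d_boundary = int(round(0.10 * L))  # outgroup just below the 0.90 capture boundary
    d_out = np.round(
        np.linspace(0.12 * L, 0.16 * L, max(1, config.n_outgroup_taxa - 1))
    ).astype(int)
    d_shared_far = int(round(0.22 * L))
    d_far_extra = int(round(0.05 * L))
    n_family_pool = int(k.sum())
    if n_family_pool + max(d_boundary, int(d_out.max()), d_shared_far + d_far_extra) > L:
        raise ValueError(
            f"region_length {L} too short to realise the requested divergences"
        )

    ancestor = _random_seq(rng, L)
    pool = rng.permutation(L)
    fam_positions = pool[:n_family_pool]
    other_positions = pool[n_family_pool:]

    panel: list[RefSeq] = []
    genus_of = lambda i: "Tenuicylindrus" if i == config.n_family_species - 1 else "Leptocylindrus"
    start = 0
    for i in range(config.n_family_species):
        pos = fam_positions[start : start + k[i]]
        start += k[i]
        seq = _substitute(ancestor, pos, rng)
        genus = genus_of(i)
        sp = f"{genus}_sp{i + 1}"
        path = TaxonomyPath(
            tuple(zip(_RANKS, (*_FAMILY_PATH, genus, sp)))
        )
        panel.append(RefSeq(f"fam{i + 1}", path, config.region, _to_str(seq)))

    out_divs = [d_boundary, *d_out.tolist()][: config.n_outgroup_taxa]
    for j, d in enumerate(out_divs):
        pos = rng.choice(other_positions, d, replace=False)
        seq = _substitute(ancestor, pos, rng)
        sp = f"Chaetoceros_like_sp{j + 1}"
        path = TaxonomyPath(
            tuple(zip(_RANKS, (*_OUT_DIATOM_PATH, "Chaetoceros_like", sp)))
        )
        panel.append(RefSeq(f"out{j + 1}", path, config.region, _to_str(seq)))

    # two far outgroups sharing a long stem so they are monophyletic
    far_stem_pos = rng.choice(other_positions, d_shared_far, replace=False)
    far_ancestor = _substitute(ancestor, far_stem_pos, rng)
    remaining = np.setdiff1d(other_positions, far_stem_pos)
    for j in range(2):
        pos = rng.choice(remaining, d_far_extra, replace=False)
        seq = _substitute(far_ancestor, pos, rng)
        sp = f"Bolidomonas_like_sp{j + 1}"
        path = TaxonomyPath(
            tuple(zip(_RANKS, (*_FAR_OUT_PATH, "Bolidomonas_like", sp)))
        )
        panel.append(RefSeq(f"far{j + 1}", path, config.region, _to_str(seq)))

    master = {ref.id: ref.sequence for ref in panel}  # substitution-only: no gaps
    return panel, master


def default_design(sites: list[str] | None = None) -> list[SampleMeta]:
    """One surface cDNA 3–20 µm plankton sample per site (figure recipe)."""
    sites = sites or ["Naples", "Oslo", "Blanes", "Roscoff", "Gijon", "Varna"]
    return [
        SampleMeta(
            sample_id=f"{site}_srf_cDNA_3-20",
            site=site,
            date="2010-05-01",
            layer="surface",
            fraction="3-20",
            template="cDNA",
        )
        for site in sites
    ]


def default_communities(
    species: list[str], sites: list[str], novel_sites: list[str] | None = None
) -> dict[str, dict[str, float]]:
    """Deterministic per-site communities with structured absences.

    Species i is absent from site (i mod n_sites) (so the presence/absence
    matrix has known zero cells); the novel lineage occurs only at
    ``novel_sites`` (default: the second site, mirroring a rare taxon
    restricted to one locality). Present species get abundance >= 3%.
    """
    novel_sites = novel_sites if novel_sites is not None else [sites[1]]
    comms: dict[str, dict[str, float]] = {}
    for si, site in enumerate(sites):
        comm: dict[str, float] = {}
        weights = []
        present = []
        for i, sp in enumerate(species):
            if i % len(sites) == si:
                continue  # structured absence
            present.append(sp)
            weights.append(1.0 + 2.0 * ((i + si) % 3))
        if site in novel_sites:
            present.append(NOVEL_LABEL)
            weights.append(1.0)
        w = np.array(weights)
        w = 0.03 + 0.97 * w / w.sum()  # floor then renormalise
        w = w / w.sum()
        comms[site] = dict(zip(present, w.tolist()))
    return comms


def simulate_study(
    config: SimConfig,
    design: list[SampleMeta],
    panel: list[RefSeq] | None = None,
) -> tuple[list[AmpliconRead], list[SampleMeta], GroundTruth]:
    """Generate a full amplicon study: reads, completed metadata, ground truth.

    Reads are drawn per sample from the site's community, then per-base
    substitution errors are applied; a ``chimera_rate`` fraction are two-parent
    chimeras (5' of one family parent joined to the 3' of another at a uniform
    breakpoint); an ``offtarget_fraction`` are copies of outgroup references
    (outgroup diatoms and far outgroups, uniformly).  A handful of
    heavy-error singleton/doubleton variants are planted so the rare-OTU
    filter has true positives to remove.
    """
    if not design:
        raise ValueError("design must contain at least one sample")
    rng = np.random.default_rng(config.seed + 1)
    if panel is None:
        panel, _ = make_reference_panel(config)
    from .align import encode

    fam_refs = [r for r in panel if r.taxonomy.contains("Leptocylindraceae")]
    out_refs = [r for r in panel if not r.taxonomy.contains("Leptocylindraceae")]
    species = [r.species for r in fam_refs]
    seq_of = {r.species: encode(r.sequence) for r in panel}

    # planted novel lineage, derived from the family reference nearest to it
    novel_parent = fam_refs[0]
    n_subs, n_indels = config.novel_clade
    novel_seq = mutate_sequence(
        novel_parent.sequence, n_subs, n_indels, int(rng.integers(0, 2**31 - 1))
    )
    seq_of[NOVEL_LABEL] = encode(novel_seq)

    sites = sorted({s.site for s in design})
    communities = config.communities or default_communities(species, sites)
    for site in sites:
        unknown = set(communities.get(site, {})) - set(species) - {NOVEL_LABEL}
        if unknown:
            raise ValueError(f"site {site!r} community names unknown species {unknown}")
        if site not in communities:
            raise ValueError(f"no community defined for site {site!r}")

    reads: list[AmpliconRead] = []
    origins: dict[str, ReadOrigin] = {}
    true_otu: dict[str, str] = {}
    presence: dict[str, dict[str, bool]] = {
        site: {t: (t in communities[site]) for t in [*species, NOVEL_LABEL]}
        for site in sites
    }

    counter = 0
    for sample in design:
        comm = communities[sample.site]
        taxa = list(comm)
        probs = np.array([comm[t] for t in taxa])
        # chimera parents are co-amplified templates: family/novel taxa of
        # *this* community, abundance-weighted (fallback: uniform family pair)
        par_taxa = [t for t in taxa if t in {*species, NOVEL_LABEL}]
        par_probs = np.array([comm[t] for t in par_taxa])
        par_probs = par_probs / par_probs.sum() if par_taxa else par_probs
        use_comm_parents = len(par_taxa) >= 2
        n = config.reads_per_sample
        kinds = rng.random(n)
        picks = rng.choice(len(taxa), size=n, p=probs)
        for r in range(n):
            counter += 1
            rid = f"read{counter:07d}"
            if kinds[r] < config.offtarget_fraction:
                src = out_refs[int(rng.integers(0, len(out_refs)))]
                codes = seq_of[src.species]
                origin = f"offtarget:{src.species}"
                o = ReadOrigin(rid, sample.sample_id, origin, is_offtarget=True)
                group = origin
            elif kinds[r] < config.offtarget_fraction + config.chimera_rate:
                if use_comm_parents:
                    pa, pb = rng.choice(len(par_taxa), 2, replace=False, p=par_probs)
                    name_a, name_b = par_taxa[pa], par_taxa[pb]
                else:
                    pa, pb = rng.choice(len(fam_refs), 2, replace=False)
                    name_a, name_b = species[pa], species[pb]
                break_at = int(rng.integers(1, config.region_length))
                codes = np.concatenate(
                    [seq_of[name_a][:break_at], seq_of[name_b][break_at:]]
                )
                origin = f"chimera({name_a},{name_b})"
                o = ReadOrigin(rid, sample.sample_id, origin, is_chimera=True)
                group = "chimera"
            else:
                sp = taxa[picks[r]]
                codes = seq_of[sp]
                origin = sp
                o = ReadOrigin(rid, sample.sample_id, origin)
                group = sp
            # per-base substitution errors
            if config.substitution_error_rate > 0:
                nerr = rng.binomial(codes.size, config.substitution_error_rate)
                if nerr:
                    pos = rng.choice(codes.size, nerr, replace=False)
                    codes = _substitute(codes, pos, rng)
            reads.append(AmpliconRead(rid, sample.sample_id, _to_str(codes)))
            origins[rid] = o
            true_otu[rid] = group

    # planted heavy-error rare variants (true positives for the rare filter)
    n_rare = config.n_planted_singletons + config.n_planted_doubletons
    heavy = max(4, int(round(0.04 * config.region_length)))
    for v in range(n_rare):
        parent = fam_refs[v % len(fam_refs)]
        variant = mutate_sequence(
            parent.sequence, heavy, 0, int(rng.integers(0, 2**31 - 1))
        )
        copies = 1 if v < config.n_planted_singletons else 2
        for _ in range(copies):
            counter += 1
            rid = f"read{counter:07d}"
            sample = design[int(rng.integers(0, len(design)))]
            reads.append(AmpliconRead(rid, sample.sample_id, variant))
            origins[rid] = ReadOrigin(
                rid, sample.sample_id, parent.species, is_planted_rare=True
            )
            true_otu[rid] = f"planted-rare-{v}"

    # complete the metadata with realised read totals
    totals: dict[str, int] = {}
    for rd in reads:
        totals[rd.sample_id] = totals.get(rd.sample_id, 0) + 1
    out_design = []
    for s in design:
        s2 = SampleMeta(
            s.sample_id, s.site, s.date, s.layer, s.fraction, s.template,
            totals.get(s.sample_id, 0), dict(s.extra),
        )
        out_design.append(s2)

    return reads, out_design, GroundTruth(origins, presence, true_otu)
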