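"""End-to-end orchestration of the screening funnel.

``run_screen`` executes the full screen in the canonical order: best-hit
taxonomic assignment -> phylum filter -> reference capture at >= 0.90 ->
chimera screen -> OTU reclustering at >= 0.97 -> singleton/doubleton removal
-> template alignment -> NJ tree rooted on the far outgroups -> clade-based
species validation -> species tables.  Stage read counts are logged (they are
the funnel) and collected into a :class:`FunnelReport`.

The chimera screen runs before OTU formation so that error-free mosaics can
never seed OTUs; every stage's record counts are non-increasing down the
funnel.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, Scoring, encode, identity
from .assign import best_hit_assign, filter_by_taxon
from .cluster import (
    chimera_screen,
    greedy_capture,
    recluster_otus,
    remove_rare_otus,
    split_family_clusters,
)
from .core import AmpliconRead, Cluster, RefSeq, SampleMeta
from .io import validate_study, write_outputs
from .phylo import (
    assign_species_by_clade,
    distance_from_alignment,
    nj_tree,
    root_tree,
    template_align,
)
from .stats import ac_test, species_site_table

__all__ = ["ScreenConfig", "FunnelReport", "ScreenResult", "run_screen", "compare_datasets"]

logger = logging.getLogger("ampliscreen")
if not logger.handlers:  # stage banners to stderr by default
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(asctime)s] %(message)s", "%H:%M:%S"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class ScreenConfig:
    """Knobs of one screening run; every default mirrors the screen's
    standard settings and is overridable."""

    family: str = "Leptocylindraceae"
    target_phylum: str = "Bacillariophyta"
    outgroup_family: str = "Bolidomonadaceae"
    capture_cutoff: float = 0.90
    otu_cutoff: float = 0.97
    min_otu_size: int = 3
    chimera_margin: float = 0.02
    # None = auto: the minimum pairwise identity among family references
    # (an OTU farther from every reference than any two family species are
    # from each other is a candidate new taxon, not an intraspecific variant)
    species_identity_floor: float | None = None
    distance_correction: str = "p"
    scoring: Scoring = DEFAULT_SCORING
    seed: int = 0


@dataclass
class FunnelReport:
    """Read/OTU counts at every stage of the screen for one dataset."""

    dataset: str
    all_reads: int
    taxon_filtered: int
    putative_family: int  # captured at >= capture cutoff by a family reference
    after_chimera_removal: int
    after_rare_removal: int
    after_false_positive_removal: int
    otus_before_rare: int
    otus_after_rare: int
    otus_final: int
    species_reads: dict[str, int] = field(default_factory=dict)
    species_otus: dict[str, int] = field(default_factory=dict)

    def stages(self) -> list[int]:
        return [
            self.all_reads,
            self.taxon_filtered,
            self.putative_family,
            self.after_chimera_removal,
            self.after_rare_removal,
            self.after_false_positive_removal,
        ]

    def validate(self) -> None:
        s = self.stages()
        if any(a < b for a, b in zip(s, s[1:])):
            raise ValueError(f"funnel counts increase down the funnel: {s}")
        if sum(self.species_reads.values()) != self.after_false_positive_removal:
            raise ValueError("species read counts do not sum to the final stage")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("all reads", self.all_reads, ""),
            ("taxon-filtered", self.taxon_filtered, ""),
            ("putative family (capture)", self.putative_family, self.otus_before_rare),
            ("after chimera removal", self.after_chimera_removal, ""),
            ("after rare-OTU removal", self.after_rare_removal, self.otus_after_rare),
            ("after false-positive removal", self.after_false_positive_removal, self.otus_final),
        ]
        return pd.DataFrame(rows, columns=["stage", "reads", "otus"])


@dataclass
class ScreenResult:
    funnel: FunnelReport
    assignments: list
    capture_clusters: dict[str, Cluster]
    eliminated_clusters: dict[str, Cluster]
    unmatched: list[AmpliconRead]
    chimeras: list[AmpliconRead]
    otus: list[Cluster]  # kept OTUs after rare removal and FP removal
    rare_otus: list[Cluster]
    false_positive_otus: list[Cluster]
    otu_labels: dict[str, str]  # otu seed id -> species | family-unplaced | outside
    tree: object | None
    dropped_insertions: dict[str, int]
    species_sample_counts: pd.DataFrame  # label x sample
    species_site_shares: pd.DataFrame
    species_site_presence: pd.DataFrame

    def write(self, out_dir: str) -> str:
        tables = {
            "funnel": self.funnel.to_frame(),
            "species_sample_counts": self.species_sample_counts.reset_index(
                names="species"
            ),
            "species_site_shares": self.species_site_shares.reset_index(
                names="species"
            ),
            "otu_labels": pd.DataFrame(
                sorted(self.otu_labels.items()), columns=["otu_seed", "label"]
            ),
        }
        trees = {}
        if self.tree is not None:
            trees["validation_tree"] = self.tree.as_string(schema="newick")
        return str(write_outputs(tables, trees, out_dir))


def _empty_counts(metadata: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        0, index=pd.Index([], name="species"),
        columns=[m.sample_id for m in metadata], dtype=int,
    )


def run_screen(
    reads: list[AmpliconRead],
    panel: list[RefSeq],
    master: dict[str, str],
    metadata: list[SampleMeta],
    config: ScreenConfig | None = None,
    dataset: str = "dataset",
) -> ScreenResult:
    """Run the complete screen on one dataset. Deterministic under config."""
    cfg = config or ScreenConfig()
    validate_study(reads, metadata)
    fam_refs = [r for r in panel if r.taxonomy.contains(cfg.family)]
    far_out = [r for r in panel if r.taxonomy.contains(cfg.outgroup_family)]
    if not fam_refs:
        raise ValueError(f"panel contains no {cfg.family} references")
    logger.info("[%s] stage all-reads: %d reads", dataset, len(reads))

    # one alignment pass read x panel feeds assignment and capture
    panel_codes = [encode(r.sequence) for r in panel]
    ident_rows = np.array(
        [
            [identity(encode(rd.sequence), pc, cfg.scoring) for pc in panel_codes]
            for rd in reads
        ]
    ).reshape(len(reads), len(panel))

    assignments = [
        best_hit_assign(rd, panel, cfg.scoring, identities=ident_rows[i])
        for i, rd in enumerate(reads)
    ]
    keep_ids = set(filter_by_taxon(assignments, cfg.target_phylum))
    sel = [i for i, rd in enumerate(reads) if rd.id in keep_ids]
    filtered = [reads[i] for i in sel]
    logger.info("[%s] stage taxon-filter (%s): %d reads", dataset, cfg.target_phylum, len(filtered))

    clusters, unmatched = greedy_capture(
        filtered, panel, cfg.capture_cutoff, cfg.scoring, identities=ident_rows[sel]
    )
    fam_clusters, eliminated = split_family_clusters(clusters, panel, cfg.family)
    captured_ids = [rid for c in fam_clusters.values() for rid in c.member_ids]
    read_by_id = {rd.id: rd for rd in reads}
    captured = [read_by_id[r] for r in captured_ids]
    logger.info(
        "[%s] stage capture >=%.2f: %d reads in %d family clusters (%d non-family clusters eliminated, %d unmatched)",
        dataset, cfg.capture_cutoff, len(captured), len(fam_clusters), len(eliminated), len(unmatched),
    )

    clean, chimeras = (
        chimera_screen(captured, fam_refs, cfg.chimera_margin, scoring=cfg.scoring)
        if captured
        else ([], [])
    )
    logger.info("[%s] stage chimera-screen: %d clean, %d flagged", dataset, len(clean), len(chimeras))

    clean_ids = {rd.id for rd in clean}
    otus_before: list[Cluster] = []
    for ref_id in sorted(fam_clusters):
        members = [read_by_id[r] for r in fam_clusters[ref_id].member_ids if r in clean_ids]
        if members:
            otus_before.extend(recluster_otus(members, cfg.otu_cutoff, cfg.scoring))
    kept, rare = remove_rare_otus(otus_before, cfg.min_otu_size)
    n_after_rare = sum(o.size for o in kept)
    logger.info(
        "[%s] stage rare-OTU removal: %d OTUs -> %d OTUs (%d reads)",
        dataset, len(otus_before), len(kept), n_after_rare,
    )

    # phylogenetic validation of kept OTUs (one representative each)
    tree = None
    otu_labels: dict[str, str] = {}
    dropped: dict[str, int] = {}
    fp_otus: list[Cluster] = []
    species_ref_map: dict[str, list[str]] = {}
    for r in fam_refs:
        species_ref_map.setdefault(r.species, []).append(r.id)
    floor = cfg.species_identity_floor
    if floor is None:
        fam_codes = [encode(r.sequence) for r in fam_refs]
        floor = min(
            (
                identity(fam_codes[i], fam_codes[j], cfg.scoring)
                for i in range(len(fam_codes))
                for j in range(i + 1, len(fam_codes))
            ),
            default=1.0,
        )
        logger.info("[%s] species identity floor (auto): %.4f", dataset, floor)
    if kept:
        rep_seq = {o.seed_id: read_by_id[o.seed_id].sequence for o in kept}
        rows, dropped = template_align(rep_seq, master, cfg.scoring)
        all_rows = {**master, **rows}
        if len(all_rows) >= 3:
            ids, D = distance_from_alignment(all_rows, cfg.distance_correction)
            unrooted = nj_tree(ids, D)
            tree = root_tree(unrooted, [r.id for r in far_out]) if far_out else unrooted
            rep_best = {}
            for o in kept:
                codes = encode(rep_seq[o.seed_id])
                idents = [(identity(codes, encode(r.sequence), cfg.scoring), r.species) for r in fam_refs]
                bi, bs = max(idents)
                rep_best[o.seed_id] = (bs, bi)
            otu_labels = assign_species_by_clade(
                tree,
                [o.seed_id for o in kept],
                species_ref_map,
                rep_best_identity=rep_best,
                identity_floor=floor,
            )
        else:
            otu_labels = {o.seed_id: "family-unplaced" for o in kept}
    fp_otus = [o for o in kept if otu_labels.get(o.seed_id) == "outside"]
    final_otus = [o for o in kept if otu_labels.get(o.seed_id) != "outside"]
    n_final = sum(o.size for o in final_otus)
    logger.info(
        "[%s] stage false-positive removal: %d OTUs kept, %d flagged outside the family clade",
        dataset, len(final_otus), len(fp_otus),
    )

    # species x sample counts from validated OTUs
    sample_ids = [m.sample_id for m in metadata]
    labels = sorted({otu_labels[o.seed_id] for o in final_otus})
    counts = pd.DataFrame(0, index=pd.Index(labels, name="species"), columns=sample_ids, dtype=int)
    for o in final_otus:
        lab = otu_labels[o.seed_id]
        for sid, cnt in o.per_sample_counts.items():
            counts.loc[lab, sid] += cnt
    if counts.empty:
        counts = _empty_counts(metadata)

    species_reads = {lab: int(counts.loc[lab].sum()) for lab in counts.index}
    species_otus: dict[str, int] = {}
    for o in final_otus:
        lab = otu_labels[o.seed_id]
        species_otus[lab] = species_otus.get(lab, 0) + 1

    funnel = FunnelReport(
        dataset=dataset,
        all_reads=len(reads),
        taxon_filtered=len(filtered),
        putative_family=len(captured),
        after_chimera_removal=len(clean),
        after_rare_removal=n_after_rare,
        after_false_positive_removal=n_final,
        otus_before_rare=len(otus_before),
        otus_after_rare=len(kept),
        otus_final=len(final_otus),
        species_reads=species_reads,
        species_otus=species_otus,
    )
    funnel.validate()

    if not counts.empty and any(m.total_reads > 0 for m in metadata):
        shares, presence = species_site_table(counts, metadata)
    else:
        shares = pd.DataFrame(index=counts.index)
        presence = pd.DataFrame(index=counts.index, dtype=bool)

    return ScreenResult(
        funnel=funnel,
        assignments=assignments,
        capture_clusters=fam_clusters,
        eliminated_clusters=eliminated,
        unmatched=unmatched,
        chimeras=chimeras,
        otus=final_otus,
        rare_otus=rare,
        false_positive_otus=fp_otus,
        otu_labels=otu_labels,
        tree=tree,
        dropped_insertions=dropped,
        species_sample_counts=counts,
        species_site_shares=shares,
        species_site_presence=presence,
    )


def compare_datasets(
    result_a: ScreenResult,
    result_b: ScreenResult,
    metadata_a: list[SampleMeta],
    metadata_b: list[SampleMeta],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-species exact conditional count comparison between two datasets.

    Samples are matched by sample_id; unmatched samples are skipped with a
    warning.  Each row is one (species, sample) with the Audic-Claverie
    expected range and significance at ``alpha``.
    """
    tot_a = {m.sample_id: m.total_reads for m in metadata_a}
    tot_b = {m.sample_id: m.total_reads for m in metadata_b}
    ca, cb = result_a.species_sample_counts, result_b.species_sample_counts
    matched = [s for s in ca.columns if s in set(cb.columns)]
    skipped = [s for s in [*ca.columns, *cb.columns] if s not in matched]
    for s in sorted(set(skipped)):
        logger.warning("compare_datasets: sample %s present in only one dataset; skipped", s)
    species = sorted(set(ca.index) | set(cb.index))
    rows = []
    for sp in species:
        for s in matched:
            x = int(ca.loc[sp, s]) if sp in ca.index else 0
            y = int(cb.loc[sp, s]) if sp in cb.index else 0
            n1, n2 = tot_a[s], tot_b[s]
            if n1 <= 0 or n2 <= 0:
                continue
            r = ac_test(x, y, n1, n2, alpha)
            rows.append(
                {
                    "species": sp,
                    "sample": s,
                    "count_a": x,
                    "count_b": y,
                    "N1": n1,
                    "N2": n2,
                    "expected_lo": r.expected_range[0],
                    "expected_hi": r.expected_range[1],
                    "p_two_sided": r.p_two_sided,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(rows)
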