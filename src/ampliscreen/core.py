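"""Core domain types shared by every stage of the screen.

The pipeline operates on four kinds of objects: annotated reference amplicons
(:class:`RefSeq`), environmental reads bound to samples (:class:`AmpliconRead`),
sample metadata rows (:class:`SampleMeta`) and read clusters
(:class:`Cluster`).  Coordinates are 0-based half-open throughout; sequences
are single-stranded, forward orientation, uppercase A/C/G/T/N.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "TaxonomyPath",
    "RefSeq",
    "AmpliconRead",
    "SampleMeta",
    "Cluster",
    "Assignment",
    "LAYERS",
    "FRACTIONS",
    "TEMPLATES",
    "REGIONS",
]

LAYERS = ("surface", "DCM", "sediment")
FRACTIONS = ("0.8-3", "3-20", "20-2000", "none")
TEMPLATES = ("DNA", "cDNA")
REGIONS = ("V4", "V9", "SSU")

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


def _check_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("-", "").replace(".", "")
    if not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(
            f"record {record_id!r}: non-IUPAC-DNA characters {bad} "
            "(only A/C/G/T/N accepted)"
        )
    return seq


@dataclass(frozen=True)
class TaxonomyPath:
    """Ranked lineage, ordered from the most inclusive rank to species.

    ``ranks`` is a tuple of ``(rank_name, taxon_name)`` pairs, e.g.
    ``(("kingdom", "Eukaryota"), ..., ("species", "Leptocylindrus danicus"))``.
    The species level is optional; rank names must be unique.
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("TaxonomyPath must contain at least one rank")
        names = [r for r, _ in self.ranks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate rank names in {names}")

    @classmethod
    def from_names(cls, taxa: list[str] | tuple[str, ...]) -> "TaxonomyPath":
        """Build a path from bare taxon names, auto-numbering the ranks."""
        return cls(tuple((f"rank{i + 1}", t) for i, t in enumerate(taxa)))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.ranks)

    def contains(self, taxon: str) -> bool:
        return taxon in self.names

    def truncate(self, depth: int) -> "TaxonomyPath":
        if depth < 1:
            raise ValueError("truncation depth must be >= 1")
        return TaxonomyPath(self.ranks[:depth])

    def __len__(self) -> int:
        return len(self.ranks)

    def __str__(self) -> str:
        return ";".join(self.names)


@dataclass(frozen=True)
class RefSeq:
    """An annotated reference amplicon, trimmed to the target region
    (primer sequence excluded)."""

    id: str
    taxonomy: TaxonomyPath
    region: str
    sequence: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, self.id))

    @property
    def species(self) -> str:
        """Last taxon name in the path (species when annotated to species)."""
        return self.taxonomy.names[-1]


@dataclass(frozen=True)
class AmpliconRead:
    """One environmental read bound to a sample."""

    id: str
    sample_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, self.id))


@dataclass
class SampleMeta:
    """One sequencing sample: site, date, depth layer, size fraction and
    template type, plus the sample's total read count (the normalisation
    denominator for relative abundances)."""

    sample_id: str
    site: str
    date: str
    layer: str
    fraction: str
    template: str
    total_reads: int = 0
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"sample {self.sample_id}: layer must be one of {LAYERS}")
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"sample {self.sample_id}: fraction must be one of {FRACTIONS}"
            )
        if self.template not in TEMPLATES:
            raise ValueError(
                f"sample {self.sample_id}: template must be one of {TEMPLATES}"
            )
        if self.layer == "sediment" and self.fraction != "none":
            raise ValueError(
                f"sample {self.sample_id}: sediment samples are not size-fractioned "
                "(fraction must be 'none')"
            )
        if self.total_reads < 0:
            raise ValueError(f"sample {self.sample_id}: total_reads must be >= 0")


@dataclass
class Cluster:
    """A set of reads grouped around a seed sequence.

    ``seed_id`` is a reference id for capture clusters (level 0.90) and a
    representative read id for OTUs (level 0.97). ``per_sample_counts`` maps
    sample ids to member counts and always sums to ``len(member_ids)``.
    """

    seed_id: str
    member_ids: list[str]
    level: float
    per_sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def recount(self, sample_of: dict[str, str]) -> None:
        counts: dict[str, int] = {}
        for rid in self.member_ids:
            sid = sample_of[rid]
            counts[sid] = counts.get(sid, 0) + 1
        self.per_sample_counts = counts


@dataclass
class Assignment:
    """Taxonomic assignment of one read.

    ``path`` may be truncated to an inner rank (tie/consensus behaviour) or
    ``None`` for explicitly unassigned reads.
    """

    read_id: str
    path: TaxonomyPath | None
    best_identity: float
    method: str  # "best_hit_lca" | "consensus"
    n_hits_considered: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.best_identity <= 1.0:
            raise ValueError("best_identity must be in [0, 1]")
        if self.method not in ("best_hit_lca", "consensus"):
            raise ValueError(f"unknown assignment method {self.method!r}")
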