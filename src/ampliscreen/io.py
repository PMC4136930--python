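"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA (reads, references, aligned references), TSV (metadata and
result tables), Newick (trees) and a plain-text output manifest with content
checksums.  Taxonomy is encoded in reference FASTA headers as a
semicolon-delimited path after the id: ``>ref1;Bacillariophyta;...;L. danicus``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import AmpliconRead, RefSeq, SampleMeta, TaxonomyPath

__all__ = [
    "read_fasta",
    "read_reads",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "validate_study",
    "write_outputs",
]

_MANDATORY_META = ["sample_id", "site", "date", "layer", "fraction", "template"]


def _parse_fasta_records(path: str | Path, keep_gaps: bool):
    """Minimal validating FASTA scan yielding (lineno, header, seq)."""
    header = None
    seq_parts: list[str] = []
    header_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header_line, header, "".join(seq_parts)
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}: malformed FASTA header at line {lineno}")
                header_line = lineno
                seq_parts = []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}: sequence data before any '>' header at line {lineno}"
                    )
                seq_parts.append(line.strip())
        if header is not None:
            yield header_line, header, "".join(seq_parts)


def read_fasta(
    path: str | Path, region: str = "SSU", aligned: bool = False
) -> list[RefSeq]:
    """Read an annotated reference FASTA.

    Headers are ``id;rank1;rank2;...``; lowercase bases are uppercased and
    gaps stripped unless ``aligned`` is set (aligned rows keep ``-``).
    An empty file yields an empty list.
    """
    records: list[RefSeq] = []
    for lineno, header, raw in _parse_fasta_records(path, aligned):
        parts = [p.strip() for p in header.split(";")]
        if len(parts) < 2 or not all(parts):
            raise ValueError(
                f"{path}: header at line {lineno} must be 'id;rank1;...' "
                f"with a non-empty taxonomy, got {header!r}"
            )
        seq = raw.upper()
        if aligned:
            # keep gap columns; validate bases only
            bases = seq.replace("-", "").replace(".", "")
            RefSeq(parts[0], TaxonomyPath.from_names(parts[1:]), region, bases)
            rec = RefSeq.__new__(RefSeq)
            object.__setattr__(rec, "id", parts[0])
            object.__setattr__(rec, "taxonomy", TaxonomyPath.from_names(parts[1:]))
            object.__setattr__(rec, "region", region)
            object.__setattr__(rec, "sequence", seq)
            records.append(rec)
        else:
            records.append(
                RefSeq(parts[0], TaxonomyPath.from_names(parts[1:]), region, seq)
            )
    return records


def read_reads(path: str | Path, sample_delim: str = "|") -> list[AmpliconRead]:
    """Read environmental amplicon reads.

    Headers are ``read_id|sample_id`` (our convention for binding reads to the
    metadata table; the delimiter is configurable).
    """
    reads: list[AmpliconRead] = []
    seen: set[str] = set()
    for lineno, header, raw in _parse_fasta_records(path, False):
        if sample_delim not in header:
            raise ValueError(
                f"{path}: read header at line {lineno} lacks the "
                f"'id{sample_delim}sample_id' separator: {header!r}"
            )
        rid, sid = header.split(sample_delim, 1)
        rid, sid = rid.strip(), sid.strip()
        if rid in seen:
            raise ValueError(f"{path}: duplicate read id {rid!r} at line {lineno}")
        seen.add(rid)
        reads.append(AmpliconRead(rid, sid, raw.upper()))
    return reads


def write_fasta(
    records: Iterable[RefSeq | AmpliconRead],
    path: str | Path,
    sample_delim: str = "|",
) -> None:
    """Write references (taxonomy headers) or reads (sample headers)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, RefSeq):
                header = ";".join([rec.id, *rec.taxonomy.names])
            else:
                header = f"{rec.id}{sample_delim}{rec.sample_id}"
            fh.write(f">{header}\n{rec.sequence}\n")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata TSV.

    Mandatory columns: sample_id, site, date, layer, fraction, template.
    Optional: total_reads. Unknown columns are preserved in ``extra``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _MANDATORY_META if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory metadata column(s) {missing}")
    known = set(_MANDATORY_META) | {"total_reads"}
    extras = [c for c in df.columns if c not in known]
    out: list[SampleMeta] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        total = int(row["total_reads"]) if "total_reads" in df.columns and row["total_reads"] else 0
        out.append(
            SampleMeta(
                sample_id=sid,
                site=row["site"],
                date=row["date"],
                layer=row["layer"],
                fraction=row["fraction"],
                template=row["template"],
                total_reads=total,
                extra={c: row[c] for c in extras},
            )
        )
    return out


def write_metadata(samples: Iterable[SampleMeta], path: str | Path) -> None:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "site": s.site,
            "date": s.date,
            "layer": s.layer,
            "fraction": s.fraction,
            "template": s.template,
            "total_reads": s.total_reads,
        }
        row.update(s.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def validate_study(reads: list[AmpliconRead], samples: list[SampleMeta]) -> None:
    """Every read's sample_id must resolve to exactly one metadata row."""
    known = {s.sample_id for s in samples}
    orphans = sorted({r.sample_id for r in reads} - known)
    if orphans:
        raise ValueError(f"reads reference unknown sample_id(s): {orphans}")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    tables: Mapping[str, pd.DataFrame],
    trees: Mapping[str, str],
    out_dir: str | Path,
) -> Path:
    """Write result tables (TSV) and trees (Newick) plus a checksum manifest.

    Returns the manifest path; the manifest lists every data file with its
    sha256 so re-runs can be compared byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    for name, newick in trees.items():
        p = out / f"{name}.nwk"
        text = newick if newick.rstrip().endswith(";") else newick + ";"
        p.write_text(text.rstrip() + "\n")
        written.append(p)
    manifest = out / "MANIFEST.txt"
    with open(manifest, "w") as fh:
        for p in sorted(written):
            fh.write(f"{_checksum(p)}  {p.name}\n")
    return manifest
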