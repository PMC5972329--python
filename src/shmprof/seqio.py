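"""Sequence and table I/O plus the core data model shared by every stage.

Clones are plain FASTA records whose headers optionally carry metadata as
``clone_id|individual_id|tissue``.  Region maps are tab-separated files that
place framework (FR1-4), CDR and constant-region subregions (C-Ig, C-CP,
C-TM, C-CYT) on the reference, 0-based half-open.  All tabular output is
deterministic TSV; motif and mutation positions can be exported as BED.
Human-readable report columns that use 1-based inclusive coordinates carry an
explicit ``_1based`` suffix; everything in memory is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from shmprof._util import check_alphabet

REGION_NAMES = (
    "FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4",
    "C-Ig", "C-CP", "C-TM", "C-CYT",
)


class FastaParseError(ValueError):
    """Malformed or empty FASTA input."""


class RegionMapError(ValueError):
    """Invalid region-map file or region layout."""


@dataclass
class CloneRecord:
    """One cDNA clone with its metadata and derived annotations."""

    clone_id: str
    sequence: str
    individual_id: str = ""
    tissue: str = ""
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        check_alphabet(self.sequence, f"clone {self.clone_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RegionMap:
    """Ordered, non-overlapping region annotation of a reference sequence."""

    regions: list  # of (name, start, end), 0-based half-open
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frame_offset <= 2:
            raise RegionMapError(f"frame_offset must be 0-2, got {self.frame_offset}")
        self.regions = sorted(self.regions, key=lambda r: r[1])
        seen = set()
        prev_end = None
        for name, start, end in self.regions:
            if name not in REGION_NAMES:
                raise RegionMapError(f"unknown region name {name!r}")
            if name in seen:
                raise RegionMapError(f"duplicate region {name!r}")
            seen.add(name)
            if end <= start or start < 0:
                raise RegionMapError(f"region {name}: end <= start ({start},{end})")
            if prev_end is not None and start < prev_end:
                raise RegionMapError(f"region {name} overlaps previous region")
            prev_end = end

    def region_at(self, position: int) -> str:
        for name, start, end in self.regions:
            if start <= position < end:
                return name
        return ""

    @property
    def span(self):
        return (self.regions[0][1], self.regions[-1][2]) if self.regions else (0, 0)


@dataclass
class Dataset:
    """A clone set together with its reference baseline and region layout."""

    clones: list
    reference: Optional[object] = None  # GermlineReference
    region_map: Optional[RegionMap] = None

    def __post_init__(self) -> None:
        ids = [c.clone_id for c in self.clones]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate clone ids: {dup}")
        if self.reference is not None and self.region_map is not None:
            _, end = self.region_map.span
            if end > len(self.reference.sequence):
                raise ValueError("region map extends past reference length")


def read_fasta(path) -> list:
    """Read clones from FASTA; headers parsed as ``clone_id|individual|tissue``.

    Sequences are uppercased and U is converted to T.  Missing header fields
    default to the empty string.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython raises rarely here
        raise FastaParseError(f"malformed FASTA in {path}: {exc}") from exc
    if not entries:
        # distinguish a non-FASTA file from a simply empty one
        text = path.read_text()
        if text.strip() and not text.lstrip().startswith(">"):
            line = text.splitlines()[0][:50]
            raise FastaParseError(f"malformed FASTA in {path}: first line {line!r}")
        raise FastaParseError(f"{path}: no sequences (empty dataset)")
    records = []
    for entry in entries:
        fields = entry.description.split("|")
        clone_id = fields[0].split()[0] if fields[0].split() else fields[0]
        individual = fields[1].strip() if len(fields) > 1 else ""
        tissue = fields[2].strip() if len(fields) > 2 else ""
        if not str(entry.seq):
            raise FastaParseError(f"{path}: entry {clone_id!r} has empty sequence")
        records.append(
            CloneRecord(clone_id=clone_id, sequence=str(entry.seq),
                        individual_id=individual, tissue=tissue)
        )
    return records


def write_fasta(records: Iterable, path) -> None:
    """Write clones (or any objects with clone_id/sequence-like pairs) to FASTA."""
    out = []
    for rec in records:
        if isinstance(rec, CloneRecord):
            header = "|".join(x for x in (rec.clone_id, rec.individual_id, rec.tissue))
            header = header.rstrip("|")
            out.append(SeqRecord(Seq(rec.sequence), id=header, description=""))
        else:  # (id, sequence) pair
            name, seq = rec
            out.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta-2line")


def read_region_map(path) -> RegionMap:
    """Read a TSV region map: rows ``name<TAB>start<TAB>end`` plus an optional
    ``frame_offset<TAB>n`` line. Out-of-order rows are sorted; overlaps are
    rejected."""
    frame_offset = 0
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "frame_offset":
                frame_offset = int(parts[1])
                continue
            if len(parts) != 3:
                raise RegionMapError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            name, start, end = parts[0], int(parts[1]), int(parts[2])
            regions.append((name, start, end))
    return RegionMap(regions=regions, frame_offset=frame_offset)


def write_region_map(region_map: RegionMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"frame_offset\t{region_map.frame_offset}\n")
        for name, start, end in region_map.regions:
            fh.write(f"{name}\t{start}\t{end}\n")


def _records_frame(records: Sequence) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    if "motif_flags" in df.columns:
        df["motif_flags"] = df["motif_flags"].map(lambda s: ",".join(sorted(s)) if s else "")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    """Deterministic TSV: fixed column order, LF line endings, %.6g floats."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end, name[, score, strand, thickStart, thickEnd])
    rows as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_metadata(path, params: dict) -> None:
    """Plain-text run metadata (inputs, parameters, seed, version) in a stable
    key order so a bundle is reproducible from this file alone."""
    from shmprof import __version__

    with open(path, "w") as fh:
        fh.write(f"shmprof_version\t{__version__}\n")
        for key in sorted(params):
            fh.write(f"{key}\t{params[key]}\n")


def write_tables(results: dict, out_dir) -> list:
    """Write a stage-output bundle to ``out_dir``.

    ``results`` maps logical names to payloads: DataFrames go to ``<name>.tsv``,
    lists of dataclass records (mutations, motif hits, candidates) are
    converted to frames, BED payloads (key ending ``.bed``) are written as-is,
    and the required ``metadata`` dict becomes ``run_metadata.txt``. Returns
    the written paths; byte-identical across runs on identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        payload = results[name]
        if name == "metadata":
            p = out_dir / "run_metadata.txt"
            write_metadata(p, payload)
        elif name.endswith(".bed"):
            p = out_dir / name
            write_bed(payload, p)
        elif isinstance(payload, pd.DataFrame):
            p = out_dir / f"{name}.tsv"
            write_tsv(payload, p)
        else:
            p = out_dir / f"{name}.tsv"
            write_tsv(_records_frame(payload), p)
        written.append(p)
    return written
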