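"""Readers, writers and shared primitive types.

All tabular artifacts are plain TSV, alignments and reads are FASTA, and
trees are Newick.  Coordinates in annotation tables are 0-based half-open.
Readers validate on the way in and fail loudly, naming the offending record;
they never silently skip malformed input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from skbio import TreeNode

DNA_ALPHABET = set("ACGTN-")

#: Taxonomic ranks from shallow to deep, the fixed order every lineage uses.
RANKS = ("phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """Malformed external input (FASTA, TSV, Newick)."""


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence; gaps are retained for alignment files."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence record {self.id!r} contains non-DNA characters {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TaxonomyLineage:
    """Rank-ordered lineage from phylum down, possibly terminating early.

    A named rank implies all shallower ranks are named (no gaps).
    """

    names: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.names) > len(RANKS):
            raise ValueError(f"lineage deeper than {len(RANKS)} ranks: {self.names}")
        if any(not n for n in self.names):
            raise ValueError(f"lineage has an unnamed intermediate rank: {self.names}")

    @classmethod
    def from_string(cls, s: str, sep: str = ";") -> "TaxonomyLineage":
        s = s.strip()
        if not s:
            return cls(())
        return cls(tuple(part.strip() for part in s.split(sep)))

    def to_string(self, sep: str = ";") -> str:
        return sep.join(self.names)

    @property
    def depth(self) -> int:
        return len(self.names)

    @property
    def deepest_rank(self) -> str | None:
        return RANKS[self.depth - 1] if self.names else None

    @property
    def deepest_name(self) -> str | None:
        return self.names[-1] if self.names else None

    def at(self, rank: str) -> str | None:
        i = RANKS.index(rank)
        return self.names[i] if i < self.depth else None

    def truncate(self, depth: int) -> "TaxonomyLineage":
        return TaxonomyLineage(self.names[:depth])

    def is_prefix_of(self, other: "TaxonomyLineage") -> bool:
        return other.names[: self.depth] == self.names

    def common_prefix(self, other: "TaxonomyLineage") -> "TaxonomyLineage":
        out = []
        for a, b in zip(self.names, other.names):
            if a != b:
                break
            out.append(a)
        return TaxonomyLineage(tuple(out))

    def __bool__(self) -> bool:
        return bool(self.names)


@dataclass(frozen=True)
class SampleInfo:
    """One barcoded sample: treatment level and replicate plot."""

    sample_id: str
    barcode: str
    treatment: str
    plot: str


@dataclass
class SampleMap:
    """The sample sheet: barcodes must be mutually >=4 mismatches apart."""

    samples: list[SampleInfo]
    min_barcode_distance: int = 4

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample ids in sample map")
        for s in self.samples:
            if set(s.barcode) - set("ACGT"):
                raise FormatError(f"sample {s.sample_id!r}: barcode is not plain DNA")
        lengths = {len(s.barcode) for s in self.samples}
        if len(lengths) > 1:
            raise FormatError(f"barcodes of unequal length: {sorted(lengths)}")
        for i, a in enumerate(self.samples):
            for b in self.samples[i + 1 :]:
                d = hamming(a.barcode, b.barcode)
                if d < self.min_barcode_distance:
                    raise FormatError(
                        f"barcodes of samples {a.sample_id!r} and {b.sample_id!r} "
                        f"differ at only {d} positions (< {self.min_barcode_distance})"
                    )

    def __iter__(self):
        return iter(self.samples)

    def __len__(self):
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def barcode_length(self) -> int:
        return len(self.samples[0].barcode)

    def treatment_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.treatment
        raise KeyError(sample_id)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Region:
    start: int  # 0-based, inclusive
    end: int  # exclusive
    label: str  # "exon" or "intron"


@dataclass
class RegionAnnotation:
    """Per-column exon/intron labels over a reference alignment.

    ``frame`` is the codon phase of the first exon column (0, 1 or 2):
    phase 0 means the first exon column begins a codon.
    """

    regions: list[Region]
    frame: int = 0

    def __post_init__(self):
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")
        regs = sorted(self.regions, key=lambda r: r.start)
        pos = 0
        for r in regs:
            if r.label not in ("exon", "intron"):
                raise ValueError(f"unknown region label {r.label!r}")
            if r.start != pos:
                raise ValueError(
                    f"annotation gap/overlap at column {pos}: next region starts at {r.start}"
                )
            if r.end <= r.start:
                raise ValueError(f"empty region at {r.start}")
            pos = r.end
        self.regions = regs

    @property
    def length(self) -> int:
        return self.regions[-1].end

    def labels(self) -> list[str]:
        out = []
        for r in self.regions:
            out.extend([r.label] * (r.end - r.start))
        return out

    def exon_columns(self) -> list[int]:
        return [i for i, lab in enumerate(self.labels()) if lab == "exon"]

    def exon_length(self) -> int:
        return sum(r.end - r.start for r in self.regions if r.label == "exon")

    def codon_phase(self) -> dict[int, int]:
        """Codon phase for every exon column (alignment coordinates)."""
        phases = {}
        k = self.frame
        for col in self.exon_columns():
            phases[col] = k % 3
            k += 1
        return phases

    def is_frame_consistent(self) -> bool:
        """True when the exon stretch decomposes into whole codons.

        A leading partial codon of ``(3 - frame) % 3`` bases is allowed;
        the remainder must be a multiple of three.
        """
        lead = (3 - self.frame) % 3
        return (self.exon_length() - lead) % 3 == 0 and self.exon_length() >= lead


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA, uppercasing sequences and keeping gap characters.

    Duplicate ids and empty records are hard errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq).upper(), description=desc))
    if not records and Path(path).stat().st_size > 0:
        raise FormatError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read FASTQ; qualities are ignored (the pipeline filters by content)."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq).upper()))
    return records


# ---------------------------------------------------------------------------
# Sample map


def read_sample_map(path: str | Path) -> SampleMap:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "barcode", "treatment", "plot"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample map missing columns {sorted(missing)}")
    samples = [
        SampleInfo(row.sample_id, row.barcode.upper(), row.treatment, str(row.plot))
        for row in df.itertuples()
    ]
    return SampleMap(samples)


def write_sample_map(sample_map: SampleMap, path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.barcode, s.treatment, s.plot) for s in sample_map],
        columns=["sample_id", "barcode", "treatment", "plot"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy table:  id <TAB> semicolon-delimited lineage


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyLineage]:
    out: dict[str, TaxonomyLineage] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 'id<TAB>lineage'")
            sid, lineage = parts
            if sid in out:
                raise FormatError(f"{path}:{ln}: duplicate id {sid!r}")
            out[sid] = TaxonomyLineage.from_string(lineage)
    return out


def write_taxonomy(tax: dict[str, TaxonomyLineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lineage in tax.items():
            fh.write(f"{sid}\t{lineage.to_string()}\n")


# ---------------------------------------------------------------------------
# Region annotation table


def read_region_annotation(path: str | Path) -> RegionAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"start", "end", "label", "frame"}
    if required - set(df.columns):
        raise FormatError(f"{path}: annotation needs columns start,end,label,frame")
    frames = df["frame"].unique()
    if len(frames) != 1:
        raise FormatError(f"{path}: inconsistent frame values {frames}")
    regions = [Region(int(r.start), int(r.end), r.label) for r in df.itertuples()]
    return RegionAnnotation(regions, frame=int(frames[0]))


def write_region_annotation(ann: RegionAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        fh.write("start\tend\tlabel\tframe\n")
        for r in ann.regions:
            fh.write(f"{r.start}\t{r.end}\t{r.label}\t{ann.frame}\n")


# ---------------------------------------------------------------------------
# OTU table: rows = OTUs, columns = samples, plus one taxonomy column


def write_otu_table(
    counts: pd.DataFrame, path: str | Path, taxonomy: pd.Series | None = None
) -> None:
    """Write an OTU x sample count table with an optional taxonomy column."""
    if (counts.values < 0).any():
        bad = counts.index[(counts < 0).any(axis=1)][0]
        raise ValueError(f"negative count in OTU {bad!r}")
    out = counts.astype(int).copy()
    out.insert(
        len(out.columns),
        "taxonomy",
        taxonomy.reindex(out.index).fillna("") if taxonomy is not None else "",
    )
    out.to_csv(path, sep="\t", index_label="otu_id")


def read_otu_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="otu_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate OTU id {dup!r}")
    if "taxonomy" not in df.columns:
        raise FormatError(f"{path}: missing taxonomy column")
    taxonomy = df["taxonomy"].fillna("").astype(str)
    counts = df.drop(columns="taxonomy")
    if counts.isna().any().any() or (counts.values < 0).any():
        raise FormatError(f"{path}: counts must be non-negative integers")
    return counts.astype(int), taxonomy


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise FormatError(f"{path}: duplicate leaf name {dup!r}")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Abundance-annotated FASTA headers:  id;size=N;sample=S


_SIZE_RE = re.compile(r";size=(\d+)")


def annotate_abundance(seq_id: str, size: int, sample: str | None = None) -> str:
    s = f"{seq_id};size={size}"
    if sample is not None:
        s += f";sample={sample}"
    return s


def parse_abundance(header: str) -> tuple[str, int, str | None]:
    """Split 'id;size=N;sample=S' into (id, N, S)."""
    parts = header.split(";")
    seq_id = parts[0]
    size = 1
    sample = None
    for p in parts[1:]:
        if p.startswith("size="):
            size = int(p[5:])
        elif p.startswith("sample="):
            sample = p[7:]
    return seq_id, size, sample
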