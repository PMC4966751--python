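"""Readers/writers for the external formats the pipeline touches.

All genomic coordinates are normalized to 0-based, half-open (BED convention)
at parse time; GFF3 (1-based, inclusive) is converted at the boundary.
Minus-strand records keep forward-strand coordinates plus a strand flag.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "GenomicInterval",
    "BlatHit",
    "FamilyMap",
    "TripletAlignment",
    "FormatError",
    "SPECIES",
    "PRIMATE_PREFIXES",
    "species_of_mirna",
    "read_psl",
    "read_family_file",
    "read_alignment",
    "write_alignment",
    "read_bed",
    "read_gff3",
    "read_fasta",
    "write_fasta",
    "read_mfe_table",
    "read_target_table",
    "read_go_map",
    "seed_interval_from_mature",
]

SPECIES = ("human", "chimp", "orang")

#: miRBase name prefixes regarded as primates (great apes + old/new world monkeys).
PRIMATE_PREFIXES = frozenset(
    {"hsa", "ptr", "ppy", "ggo", "mml", "mne", "sla", "age", "lla", "oga", "cja", "ssy", "pbi", "ppa"}
)

_SPECIES_TAGS = {
    "human": ("human", "hsa", "homo", "hg19", "hg38"),
    "chimp": ("chimp", "ptr", "pan", "pantro"),
    "orang": ("orang", "ppy", "pongo", "ponabe"),
}


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other`` (0 if on different sequences)."""
        if self.seq_name != other.seq_name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        ov = self.overlap(other)
        return min(ov / len(self), ov / len(other)) if ov else 0.0

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between non-overlapping intervals; 0 if they overlap; None across sequences."""
        if self.seq_name != other.seq_name:
            return None
        if self.overlap(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class BlatHit:
    """One PSL alignment line, target coordinates forward-strand half-open."""

    query_id: str
    target: GenomicInterval
    matched_length: int
    identity: float
    query_length: int
    block_sizes: tuple[int, ...] = ()
    t_starts: tuple[int, ...] = ()
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.matched_length > self.query_length:
            raise ValueError("matched_length exceeds query_length")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity outside [0, 1]")

    @property
    def coverage(self) -> float:
        return self.matched_length / self.query_length


@dataclass
class FamilyMap:
    """miRNA id -> family id, and family id -> member ids.

    Orphan miRNAs (no family) are absent from the map; every mapped id
    belongs to exactly one family.
    """

    mirna_to_family: dict[str, str] = field(default_factory=dict)
    family_members: dict[str, list[str]] = field(default_factory=dict)

    def family_of(self, mirna_id: str) -> str | None:
        return self.mirna_to_family.get(mirna_id)

    def members(self, family_id: str) -> list[str]:
        return self.family_members.get(family_id, [])

    def family_size(self, mirna_id: str) -> int:
        fam = self.family_of(mirna_id)
        return len(self.family_members[fam]) if fam else 1

    def family_species(self, family_id: str) -> set[str]:
        return {species_of_mirna(m) for m in self.members(family_id)}

    def add(self, family_id: str, mirna_id: str) -> None:
        prev = self.mirna_to_family.get(mirna_id)
        if prev is not None and prev != family_id:
            raise FormatError(f"{mirna_id} assigned to two families ({prev}, {family_id})")
        if prev is None:
            self.mirna_to_family[mirna_id] = family_id
            self.family_members.setdefault(family_id, []).append(mirna_id)


def species_of_mirna(mirna_id: str) -> str:
    """Species code parsed from a miRBase-style name prefix (e.g. 'hsa-mir-17' -> 'hsa')."""
    return mirna_id.split("-", 1)[0].lower()


@dataclass
class TripletAlignment:
    """Three equal-length gapped rows in fixed species order (human, chimp, orang)."""

    human: str
    chimp: str
    orang: str
    locus_id: str = ""
    #: per-member (start, end) column spans when this is a concatenation
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.human = self.human.upper()
        self.chimp = self.chimp.upper()
        self.orang = self.orang.upper()
        if not (len(self.human) == len(self.chimp) == len(self.orang)):
            raise FormatError(
                "alignment rows have unequal lengths "
                f"({len(self.human)}, {len(self.chimp)}, {len(self.orang)})"
            )

    @property
    def width(self) -> int:
        return len(self.human)

    def rows(self) -> tuple[str, str, str]:
        return (self.human, self.chimp, self.orang)

    def row(self, species: str) -> str:
        return getattr(self, species)

    def slice_columns(self, start: int, end: int) -> "TripletAlignment":
        return TripletAlignment(
            self.human[start:end], self.chimp[start:end], self.orang[start:end],
            locus_id=self.locus_id,
        )

    def reverse_complement(self) -> "TripletAlignment":
        return TripletAlignment(
            _revcomp(self.human), _revcomp(self.chimp), _revcomp(self.orang),
            locus_id=self.locus_id,
        )


_COMP = str.maketrans("ACGTN-", "TGCAN-")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# PSL (BLAT)
# ---------------------------------------------------------------------------

_PSL_MIN_COLS = 21


def read_psl(path: str | Path) -> list[BlatHit]:
    """Parse a PSL file (with or without the 5-line psLayout header).

    identity = matches / (matches + misMatches + qBaseInsert); repeat matches
    count toward matched_length.  Target coordinates in PSL are already
    0-based half-open on the forward strand.
    """
    hits: list[BlatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            # psLayout header lines (first 5) never start with a digit; data lines do
            if not line.lstrip()[0].isdigit():
                if lineno <= 5:
                    continue
                raise FormatError(f"{path}:{lineno}: malformed PSL line")
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < _PSL_MIN_COLS:
                raise FormatError(f"{path}:{lineno}: expected >= {_PSL_MIN_COLS} PSL columns, got {len(fields)}")
            try:
                matches, mismatches, rep_matches = int(fields[0]), int(fields[1]), int(fields[2])
                q_gap_bases = int(fields[5])
                strand = fields[8]
                q_name, q_size = fields[9], int(fields[10])
                t_name = fields[13]
                t_start, t_end = int(fields[15]), int(fields[16])
                block_sizes = tuple(int(x) for x in fields[18].rstrip(",").split(",") if x)
                t_starts = tuple(int(x) for x in fields[20].rstrip(",").split(",") if x)
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed PSL line ({exc})") from exc
            denom = matches + mismatches + q_gap_bases
            identity = matches / denom if denom else 0.0
            hits.append(
                BlatHit(
                    query_id=q_name,
                    target=GenomicInterval(t_name, t_start, t_end, strand[-1] if strand else "+"),
                    matched_length=matches + mismatches + rep_matches,
                    identity=identity,
                    query_length=q_size,
                    block_sizes=block_sizes,
                    t_starts=t_starts,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# miFam.dat-style family file
# ---------------------------------------------------------------------------

def read_family_file(path: str | Path) -> FamilyMap:
    """Parse a miFam.dat-layout family file (AC/ID/MI stanzas separated by //)."""
    fam = FamilyMap()
    family_id: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("AC"):
                family_id = line.split(None, 1)[1].strip()
            elif line.startswith("ID"):
                # accession (AC) is the canonical key; ID is a display name
                if family_id is None:
                    family_id = line.split(None, 1)[1].strip()
            elif line.startswith("MI"):
                if family_id is None:
                    raise FormatError(f"{path}:{lineno}: MI line outside a family stanza")
                parts = line.split()
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: MI line needs accession and name")
                fam.add(family_id, parts[2])
            elif line.startswith("//"):
                family_id = None
    return fam


# ---------------------------------------------------------------------------
# Triplet alignments (aligned FASTA / ClustalW)
# ---------------------------------------------------------------------------

def _tag_species(name: str) -> str | None:
    low = name.lower()
    for sp, tags in _SPECIES_TAGS.items():
        if any(t in low for t in tags):
            return sp
    return None


def read_alignment(path: str | Path) -> TripletAlignment:
    """Read a three-record alignment tagged human/chimp/orang (FASTA or ClustalW)."""
    path = Path(path)
    text = path.read_text()
    fmt = "clustal" if text.lstrip().upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    rows: dict[str, str] = {}
    found = []
    for rec in aln:
        sp = _tag_species(rec.id) or _tag_species(rec.description)
        found.append(rec.id)
        if sp is not None:
            rows[sp] = str(rec.seq)
    missing = [sp for sp in SPECIES if sp not in rows]
    if missing:
        raise FormatError(
            f"{path}: could not identify species {missing}; record ids found: {found}"
        )
    locus = re.sub(r"^(human|hsa)[|_:-]*", "", found[0]) if found else path.stem
    return TripletAlignment(rows["human"], rows["chimp"], rows["orang"], locus_id=locus or path.stem)


def write_alignment(aln: TripletAlignment, path: str | Path) -> None:
    """Write a TripletAlignment as aligned FASTA (reread round-trips byte-identically)."""
    with open(path, "w") as fh:
        for sp in SPECIES:
            fh.write(f">{sp}|{aln.locus_id}\n{aln.row(sp)}\n")


# ---------------------------------------------------------------------------
# BED / GFF3 / FASTA / TSV
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> dict[str, GenomicInterval]:
    """BED6 (liftOver output): name -> interval. Nameless lines get bed_<n>."""
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = f[3] if len(f) > 3 and f[3] else f"bed_{lineno}"
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
            out[name] = GenomicInterval(f[0], int(f[1]), int(f[2]), strand)
    return out


_GFF_ATTR = re.compile(r"(\w+)=([^;]*)")


def read_gff3(path: str | Path, feature_types: Sequence[str] | None = None) -> pd.DataFrame:
    """GFF3 -> DataFrame (seq_name, source, type, start, end, strand, id, name, parent).

    1-based inclusive coordinates are converted to 0-based half-open.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(f)}")
            if feature_types and f[2] not in feature_types:
                continue
            attrs = dict(_GFF_ATTR.findall(f[8]))
            records.append(
                {
                    "seq_name": f[0],
                    "source": f[1],
                    "type": f[2],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6] if f[6] in "+-" else "+",
                    "id": attrs.get("ID", ""),
                    "name": attrs.get("Name", attrs.get("ID", "")),
                    "parent": attrs.get("Parent", ""),
                }
            )
    cols = ["seq_name", "source", "type", "start", "end", "strand", "id", "name", "parent"]
    return pd.DataFrame(records, columns=cols)


def gff_intervals(df: pd.DataFrame) -> dict[str, GenomicInterval]:
    """Name-keyed intervals from a read_gff3 frame."""
    out: dict[str, GenomicInterval] = {}
    for row in df.itertuples(index=False):
        if row.end > row.start:
            out[row.name] = GenomicInterval(row.seq_name, row.start, row.end, row.strand)
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_mfe_table(path: str | Path) -> dict[str, float]:
    """TSV of (sequence id, mfe in kcal/mol)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "mfe"], comment="#")
    return dict(zip(df["id"].astype(str), df["mfe"].astype(float)))


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Target predictions: mirna_id, gene_id, conserved (0/1), context_score."""
    df = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "gene_id", "conserved", "context_score"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: target table missing columns {sorted(missing)}")
    return df.drop_duplicates(subset=["mirna_id", "gene_id"]).reset_index(drop=True)


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Gene -> set of term ids from a two-column (gene_id, go_id) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go_id"], comment="#")
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"].astype(str), df["go_id"].astype(str)):
        out.setdefault(g, set()).add(t)
    return out


def seed_interval_from_mature(mature: GenomicInterval) -> GenomicInterval:
    """Seed region = positions 2-8 of the mature miRNA, in transcript orientation."""
    if mature.strand == "+":
        return GenomicInterval(mature.seq_name, mature.start + 1, mature.start + 8, "+")
    return GenomicInterval(mature.seq_name, mature.end - 8, mature.end - 1, "-")


def psl_target_span_bruteforce(hit: BlatHit) -> tuple[int, int]:
    """Target span re-derived from blockSizes/tStarts (cross-check for read_psl)."""
    if not hit.block_sizes:
        return (hit.target.start, hit.target.end)
    starts = hit.t_starts
    ends = [s + b for s, b in zip(starts, hit.block_sizes)]
    return (min(starts), max(ends))
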