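"""Four-axis miRNA classification and category-level utilities.

Axes: clustered/non-clustered (same-strand neighbours < 10 kb apart),
multiple/single copy (human paralogs in the same family), primate-specific
vs ConFam (family phylogenetic distribution), and genomic context
(intergenic / genic exon / intron / UTR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FamilyMap, GenomicInterval, PRIMATE_PREFIXES, TripletAlignment, species_of_mirna

__all__ = [
    "CategoryLabels",
    "CLUSTER_MAX_GAP",
    "INTERGENIC_MIN_DISTANCE",
    "assign_clusters",
    "assign_copies_and_conservation",
    "assign_context",
    "category_contingency",
    "concatenate_by_category",
]

CLUSTER_MAX_GAP = 10_000          # bp end-to-start between same-strand neighbours
INTERGENIC_MIN_DISTANCE = 50_000  # bp to the nearest protein-coding gene

_CLUSTERED = ("clustered", "non-clustered")
_COPIES = ("multiple", "single")
_CONSERVATION = ("primate-specific", "ConFam", "no-primate")
_CONTEXT = ("intergenic", "genic:exon", "genic:intron", "genic:UTR", "unassigned")


@dataclass(frozen=True)
class CategoryLabels:
    clustered: str
    copies: str
    conservation: str
    context: str

    def __post_init__(self) -> None:
        for value, allowed in (
            (self.clustered, _CLUSTERED),
            (self.copies, _COPIES),
            (self.conservation, _CONSERVATION),
            (self.context, _CONTEXT),
        ):
            if value not in allowed:
                raise ValueError(f"{value!r} not one of {allowed}")


def assign_clusters(mirnas: dict[str, GenomicInterval]) -> pd.DataFrame:
    """Single-linkage chaining of same-strand neighbours < 10 kb apart.

    Returns a frame indexed by miRNA id with columns 'clustered' and
    'cluster_id' (NA for singletons); invariant to input ordering.
    """
    items = sorted(mirnas.items(), key=lambda kv: (kv[1].seq_name, kv[1].strand, kv[1].start, kv[0]))
    labels: dict[str, tuple[str, object]] = {}
    cluster_no = 0
    chain: list[str] = []

    def flush(chain: list[str]) -> None:
        nonlocal cluster_no
        if len(chain) >= 2:
            cluster_no += 1
            for name in chain:
                labels[name] = ("clustered", cluster_no)
        elif chain:
            labels[chain[0]] = ("non-clustered", pd.NA)

    prev: GenomicInterval | None = None
    for name, iv in items:
        if (
            prev is not None
            and iv.seq_name == prev.seq_name
            and iv.strand == prev.strand
            and iv.start - prev.end < CLUSTER_MAX_GAP
        ):
            chain.append(name)
        else:
            flush(chain)
            chain = [name]
        prev = iv
    flush(chain)
    out = pd.DataFrame.from_dict(labels, orient="index", columns=["clustered", "cluster_id"])
    return out.reindex(mirnas.keys())


def assign_copies_and_conservation(ids: list[str], families: FamilyMap) -> pd.DataFrame:
    """Copy-number and phylogenetic-distribution labels from the family map.

    A miRNA is multiple-copy when its family holds two or more members from
    its own species (paralogous copies in that genome).  Conservation:
    primate-specific when every family member is a primate or the miRNA is an
    orphan; ConFam when the family reaches beyond primates.  A family with no
    primate member at all cannot contain the (human) query and is flagged.
    """
    rows = []
    for mid in ids:
        own = species_of_mirna(mid)
        fam = families.family_of(mid)
        if fam is None:
            rows.append({"mirna_id": mid, "copies": "single", "conservation": "primate-specific"})
            continue
        members = families.members(fam)
        own_copies = sum(species_of_mirna(m) == own for m in members)
        prefixes = {species_of_mirna(m) for m in members}
        if prefixes.isdisjoint(PRIMATE_PREFIXES):
            warnings.warn(f"{mid}: family {fam} has no primate member", stacklevel=2)
            conservation = "no-primate"
        elif prefixes <= PRIMATE_PREFIXES:
            conservation = "primate-specific"
        else:
            conservation = "ConFam"
        rows.append(
            {
                "mirna_id": mid,
                "copies": "multiple" if own_copies >= 2 else "single",
                "conservation": conservation,
            }
        )
    return pd.DataFrame(rows).set_index("mirna_id")


def assign_context(mirna: GenomicInterval, genes: pd.DataFrame) -> str:
    """Context against a protein-coding annotation (read_gff3 layout).

    >= 1 bp overlap with an exon wins; then UTR; then intron (inside a gene
    body); intergenic when the nearest gene is > 50 kb away; the 0-50 kb
    non-overlapping zone is explicitly 'unassigned'.
    """
    gene_rows = genes[genes["type"] == "gene"]
    best_distance = None
    inside_gene = False
    for g in gene_rows.itertuples(index=False):
        giv = GenomicInterval(g.seq_name, g.start, g.end, g.strand)
        if giv.overlap(mirna):
            inside_gene = True
            break
        d = giv.distance(mirna)
        if d is not None and (best_distance is None or d < best_distance):
            best_distance = d
    if inside_gene:
        for feat, label in (("exon", "genic:exon"), ("UTR", "genic:UTR")):
            sel = genes[genes["type"].str.contains(feat, case=False)]
            for f in sel.itertuples(index=False):
                if GenomicInterval(f.seq_name, f.start, f.end, f.strand).overlap(mirna):
                    return label
        return "genic:intron"
    if best_distance is None or best_distance > INTERGENIC_MIN_DISTANCE:
        return "intergenic"
    return "unassigned"


def category_contingency(
    labels: pd.DataFrame, axis_a: str, axis_b: str
) -> tuple[pd.DataFrame, float]:
    """2x2 cross-tabulation of two axes with a two-sided Fisher exact test.

    Degenerate margins give p = 1 with a warning.  Axes with more than two
    levels are reduced to their two most frequent levels.
    """
    a = labels[axis_a].astype(str)
    b = labels[axis_b].astype(str)
    top_a = a.value_counts().index[:2]
    top_b = b.value_counts().index[:2]
    mask = a.isin(top_a) & b.isin(top_b)
    table = pd.crosstab(a[mask], b[mask]).reindex(index=top_a, columns=top_b, fill_value=0)
    arr = table.to_numpy()
    if arr.shape != (2, 2) or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn(f"degenerate margin in {axis_a} x {axis_b}; p set to 1", stacklevel=2)
        return table, 1.0
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return table, float(p)


def concatenate_by_category(
    alignments: dict[str, TripletAlignment], labels: pd.Series
) -> dict[str, TripletAlignment]:
    """Column-wise concatenation per category, recording per-locus boundaries.

    Boundaries (``.segments`` on the result) let bootstraps resample at the
    miRNA level; counting statistics are additive over segments.
    """
    out: dict[str, TripletAlignment] = {}
    groups: dict[str, list[str]] = {}
    for mid, cat in labels.items():
        if mid in alignments:
            groups.setdefault(str(cat), []).append(mid)
    for cat, members in groups.items():
        h, c, o, segs = [], [], [], []
        pos = 0
        for mid in members:
            aln = alignments[mid]
            h.append(aln.human)
            c.append(aln.chimp)
            o.append(aln.orang)
            segs.append((pos, pos + aln.width))
            pos += aln.width
        cataln = TripletAlignment("".join(h), "".join(c), "".join(o), locus_id=cat)
        cataln.segments = segs
        out[cat] = cataln
    return out
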