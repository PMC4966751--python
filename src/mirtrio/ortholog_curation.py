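"""Ortholog-curation funnel: BLAT/liftOver reconciliation, alignment trimming
and filtering, the hairpin MFE filter, flank extraction and ancestral-repeat
curation.

Filters return typed rejections rather than raising, so the funnel report
can partition every removed locus by reason.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import BlatHit, GenomicInterval, TripletAlignment

__all__ = [
    "OrthologyCall",
    "MfeRecord",
    "Rejection",
    "ArRecord",
    "select_best_blat_hit",
    "resolve_orthology",
    "classify_evidence",
    "exclude_many_to_one",
    "trim_and_filter_alignment",
    "mfe_filter",
    "extract_flank_alignment",
    "curate_ancestral_repeats",
    "align_triplet",
]

MIN_BLAT_COVERAGE = 0.80     # BLAT matches of less than 80 % of query length are dropped
MIN_ROW_COVERAGE = 0.80      # non-human rows must cover >= 80 % of the human precursor
MAX_INTERNAL_GAP = 20        # nt; larger internal human-row gaps reject the alignment
MFE_TAIL = 0.05              # right tail of the human MFE distribution
FLANK_TARGET = 40            # bp kept on each side of the precursor
FLANK_EXTRACT = 100          # bp extracted before re-alignment
MIN_FLANK_FRACTION = 0.50    # of the targeted 2 * FLANK_TARGET bp
MANY_TO_ONE_OVERLAP = 0.50   # reciprocal-overlap threshold defining "same locus"
AR_MIN_LEN, AR_MAX_LEN = 70, 91


@dataclass(frozen=True)
class Rejection:
    """Typed filter outcome; ``reason`` is a stable code for the funnel report."""

    reason: str
    detail: str = ""


@dataclass
class OrthologyCall:
    mirna_id: str
    human: GenomicInterval | None = None
    chimp: GenomicInterval | None = None
    orang: GenomicInterval | None = None
    evidence: dict[str, str] = field(default_factory=dict)  # species -> evidence class
    many_to_one: bool = False
    ambiguous_best_hit: bool = False

    def interval(self, species: str) -> GenomicInterval | None:
        return getattr(self, species)


@dataclass(frozen=True)
class MfeRecord:
    sequence_id: str
    mfe: float  # kcal/mol

    def __post_init__(self) -> None:
        if not np.isfinite(self.mfe):
            raise ValueError(f"non-finite MFE for {self.sequence_id}")


def select_best_blat_hit(hits: Sequence[BlatHit]) -> BlatHit | None:
    """Best hit after dropping matches below 80 % query coverage.

    Survivors are ordered by matched length (desc), then identity (desc);
    ties break deterministically by (seq_name, start) and are flagged via
    the returned hit's position in a stable sort, so the result is invariant
    to input order.  Returns None when nothing survives.
    """
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits from multiple queries: {sorted(queries)}")
    survivors = [h for h in hits if h.matched_length >= MIN_BLAT_COVERAGE * h.query_length]
    if not survivors:
        return None
    ranked = sorted(
        survivors,
        key=lambda h: (-h.matched_length, -h.identity, h.target.seq_name, h.target.start),
    )
    best = ranked[0]
    if len(ranked) > 1:
        nxt = ranked[1]
        if nxt.matched_length == best.matched_length and nxt.identity == best.identity:
            best = dataclasses.replace(best, ambiguous=True)
    return best


def _merge_sources(blat: GenomicInterval, lifted: GenomicInterval) -> GenomicInterval | None:
    """Leftmost/rightmost union of two overlapping same-strand intervals."""
    if blat.seq_name != lifted.seq_name or blat.strand != lifted.strand:
        return None
    if blat.overlap(lifted) < 1:
        return None
    return GenomicInterval(
        blat.seq_name, min(blat.start, lifted.start), max(blat.end, lifted.end), blat.strand
    )


def resolve_orthology(
    mirna_id: str,
    blat: Mapping[str, BlatHit | None],
    lifted: Mapping[str, GenomicInterval | None],
) -> OrthologyCall | Rejection:
    """Reconcile per-species BLAT best hits with liftOver intervals.

    Both sources overlapping on one strand -> interval spans the leftmost
    and rightmost positions of the intersecting set (evidence blat+liftover).
    liftOver alone is accepted; BLAT alone is accepted (the asymmetric
    evidence classes); discordant sources (no overlap or strand conflict)
    drop the call.
    """
    call = OrthologyCall(mirna_id=mirna_id)
    for sp in ("chimp", "orang"):
        hit = blat.get(sp)
        lift = lifted.get(sp)
        if hit is not None and lift is not None:
            merged = _merge_sources(hit.target, lift)
            if merged is None:
                return Rejection("discordant", f"{sp}: BLAT {hit.target} vs liftOver {lift}")
            setattr(call, sp, merged)
            call.evidence[sp] = "blat+liftover"
        elif lift is not None:
            setattr(call, sp, lift)
            call.evidence[sp] = "liftover_only"
        elif hit is not None:
            setattr(call, sp, hit.target)
            call.evidence[sp] = "blat_only"
        else:
            call.evidence[sp] = "none"
    if call.chimp is None or call.orang is None:
        return Rejection("no_ortholog", f"missing interval in {'chimp' if call.chimp is None else 'orang'}")
    return call


def classify_evidence(call: OrthologyCall) -> str:
    """The four evidence classes tallied in the curation report."""
    ec, eo = call.evidence.get("chimp"), call.evidence.get("orang")
    if ec == "blat+liftover" and eo == "blat+liftover":
        return "blat+liftover"
    if ec in ("blat+liftover", "blat_only") and eo == "liftover_only":
        return "blat_chimp_lo_orang"
    if eo in ("blat+liftover", "blat_only") and ec == "liftover_only":
        return "blat_orang_lo_chimp"
    if ec == "liftover_only" and eo == "liftover_only":
        return "liftover_only"
    return "other"


def exclude_many_to_one(calls: Iterable[OrthologyCall]) -> tuple[list[OrthologyCall], list[OrthologyCall]]:
    """Remove every group of human miRNAs resolving to one chimp or orang locus.

    Two calls share a locus when their intervals in that species overlap
    reciprocally by >= 50 %.  All members of an overlap group are removed.
    Returns (kept, removed).
    """
    calls = list(calls)
    bad: set[int] = set()
    for sp in ("chimp", "orang"):
        ivs = [(i, c.interval(sp)) for i, c in enumerate(calls) if c.interval(sp) is not None]
        ivs.sort(key=lambda t: (t[1].seq_name, t[1].start))
        for k in range(len(ivs)):
            i, a = ivs[k]
            for m in range(k + 1, len(ivs)):
                j, b = ivs[m]
                if b.seq_name != a.seq_name or b.start >= a.end:
                    break
                if a.reciprocal_overlap(b) >= MANY_TO_ONE_OVERLAP:
                    bad.add(i)
                    bad.add(j)
    kept, removed = [], []
    for i, c in enumerate(calls):
        if i in bad:
            c.many_to_one = True
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def trim_and_filter_alignment(
    aln: TripletAlignment, human_span: tuple[int, int] | None = None
) -> TripletAlignment | Rejection:
    """Trim to the human precursor columns, then apply coverage and gap rules.

    ``human_span`` is the (start, end) of the precursor within the ungapped
    human row (defaults to the whole row).  Rejections: 'coverage' when a
    non-human row covers < 80 % of the human precursor length; 'gap' when
    the human row has an internal gap longer than 20 nt.
    """
    human_len = sum(ch != "-" for ch in aln.human)
    if human_span is None:
        human_span = (0, human_len)
    s, e = human_span
    if not (0 <= s < e <= human_len):
        raise ValueError(f"human span {human_span} outside sequence of length {human_len}")
    # map precursor positions to columns
    cols = [i for i, ch in enumerate(aln.human) if ch != "-"]
    trimmed = aln.slice_columns(cols[s], cols[e - 1] + 1)

    gap_run = max((len(run) for run in _gap_runs(trimmed.human)), default=0)
    if gap_run > MAX_INTERNAL_GAP:
        return Rejection("gap", f"internal human gap of {gap_run} nt")
    span = e - s
    for sp in ("chimp", "orang"):
        covered = sum(ch != "-" for ch in trimmed.row(sp))
        if covered < MIN_ROW_COVERAGE * span:
            return Rejection("coverage", f"{sp} covers {covered}/{span} of human precursor")
    return trimmed


def _gap_runs(row: str) -> list[str]:
    """Internal gap runs of a row (terminal gaps are trimming, not indels)."""
    runs, cur = [], 0
    for ch in row.strip("-"):
        if ch == "-":
            cur += 1
        elif cur:
            runs.append("-" * cur)
            cur = 0
    return runs


def mfe_filter(
    alignments: Mapping[str, TripletAlignment],
    mfes: Mapping[str, float],
    human_reference_mfes: Sequence[float],
) -> tuple[dict[str, TripletAlignment], dict[str, Rejection], float]:
    """Drop triplets whose sequences fold less stably than real human hairpins.

    The threshold is the 95th percentile (linear interpolation, least-negative
    direction) of the human reference MFE distribution; an alignment is
    rejected when ANY of its three sequences has mfe > threshold.  ``mfes``
    is keyed '<locus>|<species>'.
    """
    threshold = float(np.percentile(np.asarray(human_reference_mfes, dtype=float), 100 * (1 - MFE_TAIL)))
    kept: dict[str, TripletAlignment] = {}
    rejected: dict[str, Rejection] = {}
    for locus, aln in alignments.items():
        vals = {}
        for sp in ("human", "chimp", "orang"):
            key = f"{locus}|{sp}"
            if key not in mfes:
                raise KeyError(f"missing MFE record for {key}")
            vals[sp] = mfes[key]
        weak = [sp for sp, v in vals.items() if v > threshold]
        if weak:
            rejected[locus] = Rejection("mfe", f"{','.join(weak)} above threshold {threshold:.2f}")
        else:
            kept[locus] = aln
    return kept, rejected, threshold


# ---------------------------------------------------------------------------
# re-alignment (built-in Needleman-Wunsch for fixtures; external output pluggable)
# ---------------------------------------------------------------------------

def _pairwise(a: str, b: str) -> tuple[str, str]:
    """Global alignment, match 1 / mismatch -1 / gap -2."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def align_triplet(human: str, chimp: str, orang: str, locus_id: str = "") -> TripletAlignment:
    """Progressive triplet alignment anchored on the human row."""
    h1, c1 = _pairwise(human, chimp)
    h2, o1 = _pairwise(human, orang)
    # merge on human coordinates: walk both gapped human rows simultaneously
    out_h, out_c, out_o = [], [], []
    i = j = 0
    while i < len(h1) or j < len(h2):
        a = h1[i] if i < len(h1) else None
        b = h2[j] if j < len(h2) else None
        if a == "-" and (b != "-" or b is None):
            out_h.append("-"); out_c.append(c1[i]); out_o.append("-"); i += 1
        elif b == "-" and (a != "-" or a is None):
            out_h.append("-"); out_c.append("-"); out_o.append(o1[j]); j += 1
        else:
            out_h.append(a or "-")
            out_c.append(c1[i] if i < len(h1) else "-")
            out_o.append(o1[j] if j < len(h2) else "-")
            i += 1; j += 1
    return TripletAlignment("".join(out_h), "".join(out_c), "".join(out_o), locus_id=locus_id)


def extract_flank_alignment(
    call: OrthologyCall,
    genomes: Mapping[str, Mapping[str, str]],
    precursor_strands: Mapping[str, str] | None = None,
) -> TripletAlignment | Rejection:
    """Aligned 40 bp flanks on each side of the precursor.

    100 bp is extracted upstream and downstream of each species' resolved
    interval (transcript orientation; minus-strand loci are
    reverse-complemented), the flanks are re-aligned, and the 40 bp
    immediately adjacent to the precursor kept on each side.  Rejected when
    the aligned flank covers < 50 % of the targeted 80 bp, or on strand
    discordance with the precursor alignment.
    """
    if precursor_strands:
        strands = {precursor_strands.get(sp, "+") for sp in ("human", "chimp", "orang")}
        iv_strands = set()
        for sp in ("human", "chimp", "orang"):
            iv = call.interval(sp)
            if iv is not None:
                iv_strands.add(iv.strand)
        if len(strands) > 1 or (iv_strands and iv_strands != strands):
            return Rejection("strand_discordant", f"precursor strands {sorted(strands)} vs intervals {sorted(iv_strands)}")
    ups, downs = {}, {}
    for sp in ("human", "chimp", "orang"):
        iv = call.interval(sp)
        if iv is None:
            return Rejection("no_ortholog", f"no resolved interval in {sp}")
        chrom = genomes[sp][iv.seq_name]
        up = chrom[max(0, iv.start - FLANK_EXTRACT):iv.start]
        down = chrom[iv.end:iv.end + FLANK_EXTRACT]
        if iv.strand == "-":
            up, down = _rc(down), _rc(up)
        ups[sp], downs[sp] = up, down
    kept_parts = []
    for side, seqs in (("5p", ups), ("3p", downs)):
        aln = align_triplet(seqs["human"], seqs["chimp"], seqs["orang"])
        cols = [i for i, ch in enumerate(aln.human) if ch != "-"]
        if not cols:
            return Rejection("flank_coverage", f"{side} flank empty in human")
        if side == "5p":
            sub = aln.slice_columns(cols[max(0, len(cols) - FLANK_TARGET)], cols[-1] + 1)
        else:
            sub = aln.slice_columns(cols[0], cols[min(FLANK_TARGET, len(cols)) - 1] + 1)
        kept_parts.append(sub)
    flank = TripletAlignment(
        kept_parts[0].human + kept_parts[1].human,
        kept_parts[0].chimp + kept_parts[1].chimp,
        kept_parts[0].orang + kept_parts[1].orang,
        locus_id=call.mirna_id,
    )
    target = 2 * FLANK_TARGET
    for sp in ("human", "chimp", "orang"):
        covered = sum(ch != "-" for ch in flank.row(sp))
        if covered < MIN_FLANK_FRACTION * target:
            return Rejection("flank_coverage", f"{sp} aligned flank {covered}/{target} bp")
    return flank


_RC = str.maketrans("ACGTN", "TGCAN")


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class ArRecord:
    """Ancestral-repeat candidate with reciprocal-liftOver status per species."""

    ar_id: str
    human: GenomicInterval
    chimp: GenomicInterval | None = None
    orang: GenomicInterval | None = None
    reciprocal: bool = True  # survived reciprocal liftOver in all three assemblies


def curate_ancestral_repeats(ars: Iterable[ArRecord]) -> list[ArRecord]:
    """Keep ARs with reciprocal liftOver in all species, length within the
    human-miRNA interquartile range [70, 91] bp, and same-chromosome lifts."""
    kept = []
    for ar in ars:
        if not ar.reciprocal or ar.chimp is None or ar.orang is None:
            continue
        if not (AR_MIN_LEN <= len(ar.human) <= AR_MAX_LEN):
            continue
        if ar.chimp.seq_name != ar.human.seq_name or ar.orang.seq_name != ar.human.seq_name:
            continue
        kept.append(ar)
    return kept
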