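"""Synthetic human/chimp/orang miRNA triplet datasets with known parameters.

Each locus is an ancestor hairpin of 70-91 bp plus fixed-length flanks; the
three descendant rows are produced by sprinkling independent per-site
substitutions on each branch.  The emitted "orang" row is the ancestor plus
its own branch noise, so outgroup orientation is exercised realistically
(multiallelic columns arise naturally).  Substitutions at CpG-context sites
occur at ``cpg_multiplier`` times the base rate (the extra mass being
deamination transitions, C>T / G>A); per-branch rates are normalized so the
configured value is the mean per-site rate.  Fixed changes are drawn
weak-to-strong with probability ``ws_bias`` (GC-biased gene conversion
regime).  Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, TripletAlignment

__all__ = [
    "CategoryParams",
    "SimulationConfig",
    "SimulatedLocus",
    "SimulatedDataset",
    "simulate_triplets",
    "simulate_neutral_refs",
    "simulate_alignment",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
A, C, G, T = 0, 1, 2, 3

#: outgroup branch length relative to the ingroup human branch (HC-ancestor to
#: orang path vs human tip branch, approximate primate divergence-time ratio)
ORANG_FACTOR = 3.0


@dataclass
class CategoryParams:
    """Per-conservation-class simulation regime (rates as reported in the
    human/chimp category tables; orang branch defaults to 3x human)."""

    n: int
    rate_human: float
    rate_chimp: float
    rate_orang: float | None = None
    conservation: str = "primate-specific"
    clustered_fraction: float = 0.08
    multiple_fraction: float = 0.09
    genic_fraction: float = 0.61

    def __post_init__(self) -> None:
        if self.rate_orang is None:
            self.rate_orang = ORANG_FACTOR * self.rate_human
        if self.n < 0 or min(self.rate_human, self.rate_chimp, self.rate_orang) < 0:
            raise ValueError("n and rates must be non-negative")


def _default_categories() -> dict[str, CategoryParams]:
    # regime of the published category table: primate-specific miRNAs evolve
    # ~4x faster than families conserved beyond primates (ConFam)
    return {
        "primate-specific": CategoryParams(
            n=800, rate_human=0.0056, rate_chimp=0.0066,
            conservation="primate-specific",
            clustered_fraction=0.08, multiple_fraction=0.09, genic_fraction=0.61,
        ),
        "ConFam": CategoryParams(
            n=370, rate_human=0.0014, rate_chimp=0.0023,
            conservation="ConFam",
            clustered_fraction=0.51, multiple_fraction=0.60, genic_fraction=0.37,
        ),
    }


@dataclass
class SimulationConfig:
    categories: dict[str, CategoryParams] = field(default_factory=_default_categories)
    cpg_multiplier: float = 10.0
    ws_bias: float | None = 0.39
    mfe_mean: float = -37.9
    mfe_sd: float = 8.0
    flank_length: int = 40
    # neutral flank regime (ancestral-repeat-like rates)
    flank_rate_human: float = 0.0053
    flank_rate_chimp: float = 0.0059
    flank_rate_orang: float = ORANG_FACTOR * 0.0053
    min_len: int = 70
    max_len: int = 91
    #: fractions of loci in the four orthology-evidence classes
    #: (blat+liftOver both, blat-chimp/lo-orang, blat-orang/lo-chimp, liftOver-only)
    evidence_fractions: tuple[float, float, float, float] = (0.938, 0.053, 0.006, 0.003)
    two_seed_fraction: float = 0.52
    # optional violation injection for filter tests
    n_gap_violations: int = 0
    n_coverage_violations: int = 0
    n_mfe_violations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")
        if self.ws_bias is not None and not (0.0 <= self.ws_bias <= 1.0):
            raise ValueError("ws_bias must lie in [0, 1]")
        if abs(sum(self.evidence_fractions) - 1.0) > 1e-9:
            raise ValueError("evidence_fractions must sum to 1")


@dataclass
class SimulatedLocus:
    locus_id: str
    category: str
    conservation: str
    clustered: bool
    cluster_id: int | None
    context: str
    family_id: str | None
    copies: str
    evidence_class: str
    interval: GenomicInterval
    precursor: TripletAlignment
    flank5: TripletAlignment
    flank3: TripletAlignment
    true_counts: dict[str, int]
    true_flank_counts: dict[str, int]
    mfe: dict[str, float]
    seed_offsets: list[tuple[int, int]]
    rejection_truth: str | None = None  # injected violation, if any


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    loci: list[SimulatedLocus]

    def alignments(self) -> dict[str, TripletAlignment]:
        return {l.locus_id: l.precursor for l in self.loci}

    def flank_alignments(self) -> dict[str, TripletAlignment]:
        out = {}
        for l in self.loci:
            out[l.locus_id] = TripletAlignment(
                l.flank5.human + l.flank3.human,
                l.flank5.chimp + l.flank3.chimp,
                l.flank5.orang + l.flank3.orang,
                locus_id=l.locus_id,
            )
        return out

    def labels(self) -> pd.DataFrame:
        rows = [
            {
                "mirna_id": l.locus_id,
                "category": l.category,
                "clustered": "clustered" if l.clustered else "non-clustered",
                "copies": l.copies,
                "conservation": l.conservation,
                "context": l.context,
            }
            for l in self.loci
        ]
        return pd.DataFrame(rows).set_index("mirna_id")

    def truth(self) -> pd.DataFrame:
        rows = [
            {
                "mirna_id": l.locus_id,
                "category": l.category,
                "length": l.precursor.width,
                "true_human": l.true_counts["human"],
                "true_chimp": l.true_counts["chimp"],
                "true_orang": l.true_counts["orang"],
            }
            for l in self.loci
        ]
        return pd.DataFrame(rows).set_index("mirna_id")

    def seed_offsets(self) -> dict[str, list[tuple[int, int]]]:
        return {l.locus_id: l.seed_offsets for l in self.loci}


# ---------------------------------------------------------------------------
# mutation core
# ---------------------------------------------------------------------------

def _ws_cumulative(ws_bias: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-ancestral-base derived-base choice: alternatives and cumulative probs.

    Weak ancestors (A/T) mutate to a strong base with total probability
    ws_bias (split over C and G); strong ancestors (C/G) mutate to a weak
    base with total probability 1 - ws_bias.  ws_bias=None draws uniformly.
    """
    alts = np.array([[C, G, T], [A, T, G], [A, T, C], [A, C, G]], dtype=np.uint8)
    if ws_bias is None:
        probs = np.full((4, 3), 1.0 / 3.0)
    else:
        w = ws_bias
        probs = np.array(
            [
                [w / 2, w / 2, 1 - w],          # A -> C, G strong; T weak
                [(1 - w) / 2, (1 - w) / 2, w],  # C -> A, T weak; G strong
                [(1 - w) / 2, (1 - w) / 2, w],  # G -> A, T weak; C strong
                [1 - w, w / 2, w / 2],          # T -> A weak; C, G strong
            ]
        )
    return alts, np.cumsum(probs, axis=1)


def _cpg_context(anc: np.ndarray, starts: np.ndarray | None) -> np.ndarray:
    """True at both positions of each CpG dinucleotide; pairs never span locus
    boundaries (``starts`` are the concatenated locus start offsets)."""
    pair = np.zeros(anc.shape, dtype=bool)
    if anc.size < 2:
        return pair
    is_cg = (anc[:-1] == C) & (anc[1:] == G)
    if starts is not None and starts.size:
        boundary = np.zeros(anc.size - 1, dtype=bool)
        inner = starts[(starts > 0) & (starts <= anc.size - 1)]
        boundary[inner - 1] = True  # pair (s-1, s) would cross a boundary
        is_cg &= ~boundary
    ctx = np.zeros(anc.shape, dtype=bool)
    ctx[:-1] |= is_cg
    ctx[1:] |= is_cg
    return ctx


def _mutate_branch(
    anc: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    cpg_multiplier: float = 1.0,
    ws_bias: float | None = None,
    starts: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One branch of per-site Bernoulli substitutions on the ancestor codes.

    Returns (derived codes, event mask).  Site weights are cpg_multiplier at
    CpG-context sites and 1 elsewhere, normalized so the mean per-site event
    probability equals ``rate``; the excess mass at CpG sites is realized as
    deamination transitions (C>T on the C, G>A on the G).
    """
    n = anc.size
    derived = anc.copy()
    if rate <= 0 or n == 0:
        return derived, np.zeros(n, dtype=bool)
    ctx = _cpg_context(anc, starts)
    if cpg_multiplier > 1.0:
        w = np.where(ctx, cpg_multiplier, 1.0)
        p = rate * w / w.mean()
    else:
        p = np.full(n, rate)
    events = rng.random(n) < np.minimum(p, 1.0)
    idx = np.nonzero(events)[0]
    if idx.size == 0:
        return derived, events
    anc_e = anc[idx]
    alts, cum = _ws_cumulative(ws_bias)
    u = rng.random(idx.size)
    choice = (u[:, None] > cum[anc_e]).sum(axis=1)
    new = alts[anc_e, choice]
    if cpg_multiplier > 1.0:
        deam = ctx[idx] & (rng.random(idx.size) < (cpg_multiplier - 1.0) / cpg_multiplier)
        new = np.where(deam & (anc_e == C), T, new)
        new = np.where(deam & (anc_e == G), A, new)
    derived[idx] = new
    return derived, events


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def simulate_alignment(
    length: int,
    rate_human: float,
    rate_chimp: float,
    rate_orang: float,
    rng: np.random.Generator,
    cpg_multiplier: float = 1.0,
    ws_bias: float | None = None,
    locus_id: str = "sim",
) -> tuple[TripletAlignment, dict[str, int]]:
    """Low-level single-alignment simulator; returns alignment and true counts."""
    anc = rng.integers(0, 4, size=length, dtype=np.uint8)
    rows = {}
    counts = {}
    for sp, rate in (("human", rate_human), ("chimp", rate_chimp), ("orang", rate_orang)):
        seq, ev = _mutate_branch(anc, rate, rng, cpg_multiplier, ws_bias)
        rows[sp] = _codes_to_str(seq)
        counts[sp] = int(ev.sum())
    return TripletAlignment(rows["human"], rows["chimp"], rows["orang"], locus_id=locus_id), counts


# ---------------------------------------------------------------------------
# dataset generator
# ---------------------------------------------------------------------------

def _simulate_block(
    lengths: np.ndarray,
    rates: tuple[float, float, float],
    rng: np.random.Generator,
    cpg_multiplier: float,
    ws_bias: float | None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Simulate a batch of loci as one concatenated array.

    Returns (rows per species as code arrays, per-locus event counts per
    species, locus start offsets)."""
    total = int(lengths.sum())
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1])).astype(np.int64)
    anc = rng.integers(0, 4, size=total, dtype=np.uint8)
    rows: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for sp, rate in zip(("human", "chimp", "orang"), rates):
        seq, ev = _mutate_branch(anc, rate, rng, cpg_multiplier, ws_bias, starts=starts)
        rows[sp] = seq
        counts[sp] = (
            np.add.reduceat(ev.astype(np.int64), starts) if total else np.zeros(0, dtype=np.int64)
        )
    return rows, counts, starts


_EVIDENCE_CLASSES = ("blat+liftover", "blat_chimp_lo_orang", "blat_orang_lo_chimp", "liftover_only")


def simulate_triplets(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a full triplet dataset (alignments, flanks, labels, fixtures)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    loci: list[SimulatedLocus] = []
    counter = 0
    for cat_name, cp in config.categories.items():
        if cp.n == 0:
            continue
        lengths = rng.integers(config.min_len, config.max_len + 1, size=cp.n)
        rows, counts, starts = _simulate_block(
            lengths, (cp.rate_human, cp.rate_chimp, cp.rate_orang), rng,
            config.cpg_multiplier, config.ws_bias,
        )
        fl = 2 * config.flank_length
        flanks, fcounts, fstarts = _simulate_block(
            np.full(cp.n, fl),
            (config.flank_rate_human, config.flank_rate_chimp, config.flank_rate_orang),
            rng, config.cpg_multiplier, config.ws_bias,
        )
        n_clustered = 2 * int(round(cp.clustered_fraction * cp.n / 2))
        clustered_idx = set(range(n_clustered))
        n_multiple = 2 * int(round(cp.multiple_fraction * cp.n / 2))
        genic = rng.random(cp.n) < cp.genic_fraction
        # cluster mates share one host gene (or none): keep genic status equal
        for i in range(0, n_clustered - 1, 2):
            genic[i + 1] = genic[i]
        evid = rng.choice(4, size=cp.n, p=np.asarray(config.evidence_fractions))
        two_seed = rng.random(cp.n) < config.two_seed_fraction

        chrom_of = lambda i: f"chr{1 + (counter + i) // 40}"
        cursor = 10_000
        prev_chrom = None
        cluster_id = 0
        for i in range(cp.n):
            s, e = int(starts[i]), int(starts[i] + lengths[i])
            fs = int(fstarts[i])
            pre = TripletAlignment(
                *(_codes_to_str(rows[sp][s:e]) for sp in ("human", "chimp", "orang")),
                locus_id=f"hsa-sim-{counter + i + 1}",
            )
            f5 = TripletAlignment(
                *(_codes_to_str(flanks[sp][fs:fs + config.flank_length]) for sp in ("human", "chimp", "orang"))
            )
            f3 = TripletAlignment(
                *(_codes_to_str(flanks[sp][fs + config.flank_length:fs + fl]) for sp in ("human", "chimp", "orang"))
            )
            chrom = chrom_of(i)
            if chrom != prev_chrom:
                cursor = 10_000
                prev_chrom = chrom
            in_cluster = i in clustered_idx
            if in_cluster and i % 2 == 0:
                cluster_id += 1
            gap = 2_000 if (in_cluster and i % 2 == 1) else 60_000
            if i > 0:
                cursor += gap
            interval = GenomicInterval(chrom, cursor, cursor + int(lengths[i]), "+")
            cursor = interval.end

            # mature miRNAs -> seed offsets (positions 2-8 of each mature)
            m1 = 8
            seeds = [(m1 + 1, m1 + 8)]
            if two_seed[i]:
                m2 = int(lengths[i]) - 30
                seeds.append((m2 + 1, m2 + 8))

            mfe = {
                sp: float(rng.normal(config.mfe_mean, config.mfe_sd))
                for sp in ("human", "chimp", "orang")
            }
            loci.append(
                SimulatedLocus(
                    locus_id=pre.locus_id,
                    category=cat_name,
                    conservation=cp.conservation,
                    clustered=in_cluster,
                    cluster_id=cluster_id if in_cluster else None,
                    context="genic:intron" if genic[i] else "intergenic",
                    family_id=None,  # assigned below
                    copies="multiple" if i < n_multiple else "single",
                    evidence_class=_EVIDENCE_CLASSES[int(evid[i])],
                    interval=interval,
                    precursor=pre,
                    flank5=f5,
                    flank3=f3,
                    true_counts={sp: int(counts[sp][i]) for sp in ("human", "chimp", "orang")},
                    true_flank_counts={sp: int(fcounts[sp][i]) for sp in ("human", "chimp", "orang")},
                    mfe=mfe,
                    seed_offsets=seeds,
                )
            )
        counter += cp.n

    _assign_families(loci)
    _inject_violations(loci, config, rng)
    return SimulatedDataset(config=config, loci=loci)


def _assign_families(loci: list[SimulatedLocus]) -> None:
    """Family structure consistent with copies/conservation labels.

    Multiple-copy loci are paired into two-human-member families; ConFam
    families additionally carry a mouse member; single-copy primate-specific
    loci are either orphans or one-human families with a chimp member.
    """
    fam_no = 0
    by_cat: dict[str, list[SimulatedLocus]] = {}
    for l in loci:
        by_cat.setdefault(l.category, []).append(l)
    for cat, members in by_cat.items():
        multiples = [l for l in members if l.copies == "multiple"]
        singles = [l for l in members if l.copies == "single"]
        for a, b in zip(multiples[0::2], multiples[1::2]):
            fam_no += 1
            fid = f"MIPF-SIM-{fam_no}"
            a.family_id = b.family_id = fid
        for j, l in enumerate(singles):
            if l.conservation == "ConFam":
                fam_no += 1
                l.family_id = f"MIPF-SIM-{fam_no}"
            elif j % 2 == 0:  # half the primate-specific singles are orphans
                l.family_id = None
            else:
                fam_no += 1
                l.family_id = f"MIPF-SIM-{fam_no}"


def _inject_violations(loci: list[SimulatedLocus], config: SimulationConfig,
                       rng: np.random.Generator) -> None:
    """Rewrite the first few loci to violate the gap / coverage / MFE filters."""
    k = config.n_gap_violations + config.n_coverage_violations + config.n_mfe_violations
    if k > len(loci):
        raise ValueError("more injected violations than loci")
    pos = 0
    for _ in range(config.n_gap_violations):
        l = loci[pos]
        mid = l.precursor.width // 2
        gap = 25  # > 20 nt internal gap in the human row
        filler = _codes_to_str(rng.integers(0, 4, size=gap, dtype=np.uint8))
        filler2 = _codes_to_str(rng.integers(0, 4, size=gap, dtype=np.uint8))
        l.precursor = TripletAlignment(
            l.precursor.human[:mid] + "-" * gap + l.precursor.human[mid:],
            l.precursor.chimp[:mid] + filler + l.precursor.chimp[mid:],
            l.precursor.orang[:mid] + filler2 + l.precursor.orang[mid:],
            locus_id=l.locus_id,
        )
        l.rejection_truth = "gap"
        pos += 1
    for _ in range(config.n_coverage_violations):
        l = loci[pos]
        w = l.precursor.width
        cut = int(w * 0.25) + 1  # chimp row covers < 80 %
        l.precursor = TripletAlignment(
            l.precursor.human,
            "-" * cut + l.precursor.chimp[cut:],
            l.precursor.orang,
            locus_id=l.locus_id,
        )
        l.rejection_truth = "coverage"
        pos += 1
    for _ in range(config.n_mfe_violations):
        l = loci[pos]
        l.mfe["orang"] = -3.0  # far less stable than any real hairpin
        l.rejection_truth = "mfe"
        pos += 1


def simulate_neutral_refs(
    config: SimulationConfig | None = None,
    n: int = 100,
    rng: np.random.Generator | None = None,
) -> list[TripletAlignment]:
    """Neutral (ancestral-repeat-like) triplets, lengths in [min_len, max_len]."""
    config = config or SimulationConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    out = []
    for i in range(n):
        length = int(rng.integers(config.min_len, config.max_len + 1))
        aln, _ = simulate_alignment(
            length,
            config.flank_rate_human,
            config.flank_rate_chimp,
            config.flank_rate_orang,
            rng,
            cpg_multiplier=config.cpg_multiplier,
            ws_bias=config.ws_bias,
            locus_id=f"AR-sim-{i + 1}",
        )
        out.append(aln)
    return out


# ---------------------------------------------------------------------------
# fixture emission (PSL/BED/GFF3/family/MFE files consistent with the loci)
# ---------------------------------------------------------------------------

_CHROM_PAD = 100_000  # synthetic chromosome tail beyond the last locus


def _ungapped(seq: str) -> str:
    return seq.replace("-", "")


def gene_annotation(ds: SimulatedDataset) -> pd.DataFrame:
    """Protein-coding gene/exon records hosting every genic locus.

    Cluster mates share one gene; each gene spans its loci plus 2 kb on each
    side with terminal exons, so hosted miRNAs fall in the intron.
    """
    rows = []
    done: set[str] = set()
    gene_no = 0
    by_id = {l.locus_id: l for l in ds.loci}
    clusters: dict[int, list[SimulatedLocus]] = {}
    for l in ds.loci:
        if l.cluster_id is not None:
            clusters.setdefault(l.cluster_id, []).append(l)
    for l in ds.loci:
        if l.context == "intergenic" or l.locus_id in done:
            continue
        group = clusters.get(l.cluster_id, [l]) if l.cluster_id is not None else [l]
        for g in group:
            done.add(g.locus_id)
        gene_no += 1
        start = min(g.interval.start for g in group) - 2_000
        end = max(g.interval.end for g in group) + 2_000
        chrom = group[0].interval.seq_name
        gid = f"GENE-SIM-{gene_no}"
        rows.append({"seq_name": chrom, "source": "sim", "type": "gene",
                     "start": start, "end": end, "strand": "+", "id": gid,
                     "name": gid, "parent": ""})
        for es, ee in ((start, start + 500), (end - 500, end)):
            rows.append({"seq_name": chrom, "source": "sim", "type": "exon",
                         "start": es, "end": ee, "strand": "+",
                         "id": f"{gid}-exon", "name": f"{gid}-exon", "parent": gid})
    return pd.DataFrame(rows, columns=["seq_name", "source", "type", "start",
                                       "end", "strand", "id", "name", "parent"])


def build_genomes(ds: SimulatedDataset, rng: np.random.Generator | None = None
                  ) -> dict[str, dict[str, str]]:
    """Per-species chromosome sequences embedding flank5+precursor+flank3 at
    each locus interval (random filler elsewhere). Memory scales with the
    coordinate span, so intended for small datasets."""
    rng = rng or np.random.default_rng(ds.config.seed + 7)
    fl = ds.config.flank_length
    ends: dict[str, int] = {}
    for l in ds.loci:
        ends[l.interval.seq_name] = max(ends.get(l.interval.seq_name, 0), l.interval.end)
    genomes: dict[str, dict[str, bytearray]] = {sp: {} for sp in ("human", "chimp", "orang")}
    for chrom, last in ends.items():
        size = last + _CHROM_PAD
        for sp in genomes:
            genomes[sp][chrom] = bytearray(
                _BASE_BYTES[rng.integers(0, 4, size=size, dtype=np.uint8)].tobytes()
            )
    for l in ds.loci:
        chrom = l.interval.seq_name
        for sp in ("human", "chimp", "orang"):
            core = _ungapped(l.precursor.row(sp)).encode()
            up = _ungapped(l.flank5.row(sp)).encode()
            down = _ungapped(l.flank3.row(sp)).encode()
            s = l.interval.start
            genomes[sp][chrom][s - len(up):s] = up
            genomes[sp][chrom][s:s + len(core)] = core
            genomes[sp][chrom][s + len(core):s + len(core) + len(down)] = down
    return {sp: {c: b.decode() for c, b in chroms.items()} for sp, chroms in genomes.items()}


def _psl_line(locus: SimulatedLocus, species: str, chrom_size: int) -> str:
    seq = _ungapped(locus.precursor.row(species))
    iv = locus.interval
    n = len(seq)
    fields = [n, 0, 0, 0, 0, 0, 0, 0, "+", locus.locus_id, n, 0, n,
              iv.seq_name, chrom_size, iv.start, iv.start + n, 1, f"{n},", "0,", f"{iv.start},"]
    return "\t".join(str(x) for x in fields)


def write_fixtures(ds: SimulatedDataset, outdir, include_genomes: bool = False) -> None:
    """Write the fixture tree: aligned FASTA per locus, PSL/BED per species,
    miRNA and gene GFF3, miFam-style family file, MFE TSV, truth/label TSVs."""
    from pathlib import Path

    from .io_formats import write_alignment, write_fasta

    out = Path(outdir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    for l in ds.loci:
        write_alignment(l.precursor, out / "alignments" / f"{l.locus_id}.fa")

    chrom_size = max(l.interval.end for l in ds.loci) + _CHROM_PAD
    for sp, tag in (("chimp", "chimp"), ("orang", "orang")):
        with open(out / f"blat_{tag}.psl", "w") as fh:
            for l in ds.loci:
                if (sp == "chimp" and l.evidence_class in ("blat+liftover", "blat_chimp_lo_orang")) or \
                   (sp == "orang" and l.evidence_class in ("blat+liftover", "blat_orang_lo_chimp")):
                    fh.write(_psl_line(l, sp, chrom_size) + "\n")
        with open(out / f"liftover_{tag}.bed", "w") as fh:
            for l in ds.loci:
                if (sp == "chimp" and l.evidence_class in ("blat+liftover", "blat_orang_lo_chimp", "liftover_only")) or \
                   (sp == "orang" and l.evidence_class in ("blat+liftover", "blat_chimp_lo_orang", "liftover_only")):
                    iv = l.interval
                    fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{l.locus_id}\t0\t{iv.strand}\n")

    with open(out / "mirnas.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for l in ds.loci:
            iv = l.interval
            fh.write(f"{iv.seq_name}\tsim\tmiRNA_primary_transcript\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                     f"ID={l.locus_id};Name={l.locus_id}\n")
            for k, (s0, _e0) in enumerate(l.seed_offsets):
                ms, me = iv.start + s0 - 1, iv.start + s0 - 1 + 22
                fh.write(f"{iv.seq_name}\tsim\tmiRNA\t{ms + 1}\t{min(me, iv.end)}\t.\t{iv.strand}\t.\t"
                         f"ID={l.locus_id}-mat{k};Name={l.locus_id}-mat{k};Parent={l.locus_id}\n")

    genes = gene_annotation(ds)
    with open(out / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            attrs = f"ID={r.id};Name={r.name}" + (f";Parent={r.parent}" if r.parent else "")
            fh.write(f"{r.seq_name}\t{r.source}\t{r.type}\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n")

    fams: dict[str, list[str]] = {}
    for l in ds.loci:
        if l.family_id:
            fams.setdefault(l.family_id, []).append(l.locus_id)
    with open(out / "mifam.dat", "w") as fh:
        mi_no = 0
        for fid, members in fams.items():
            fh.write(f"AC   {fid}\nID   {fid.lower()}\n")
            cons = None
            for m in members:
                mi_no += 1
                fh.write(f"MI   MI-SIM-{mi_no:07d}  {m}\n")
                cons = next(l.conservation for l in ds.loci if l.locus_id == m)
            if cons == "ConFam":
                mi_no += 1
                fh.write(f"MI   MI-SIM-{mi_no:07d}  mmu-sim-{fid.split('-')[-1]}\n")
            elif len(members) == 1:
                mi_no += 1
                fh.write(f"MI   MI-SIM-{mi_no:07d}  ptr-sim-{fid.split('-')[-1]}\n")
            fh.write("//\n")

    with open(out / "mfe.tsv", "w") as fh:
        for l in ds.loci:
            for sp in ("human", "chimp", "orang"):
                fh.write(f"{l.locus_id}|{sp}\t{l.mfe[sp]:.2f}\n")

    ds.truth().to_csv(out / "truth.tsv", sep="\t")
    ds.labels().to_csv(out / "labels.tsv", sep="\t")

    if include_genomes:
        (out / "genomes").mkdir(exist_ok=True)
        for sp, chroms in build_genomes(ds).items():
            write_fasta(chroms, out / "genomes" / f"{sp}.fa")
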