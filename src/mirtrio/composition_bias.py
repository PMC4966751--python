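"""CpG-context and strong/weak partitioning of oriented substitutions.

Strong bases (S) are G/C, weak (W) are A/T; the W>S fraction of fixed
changes, n_WS / (n_WS + n_SW), indexes GC-biased gene conversion.  CpG
transitions are counted with the outgroup-oriented ancestral dinucleotide:
C>T with a conserved 3' G (forward reading) or G>A with a conserved 5' C
(reverse-strand reading, CpG>CpA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .evolution_rates import EXCLUDED, classify_columns, oriented_events
from .io_formats import TripletAlignment

__all__ = [
    "PartitionedCounts",
    "count_cpg_transitions",
    "ws_partition",
    "ws_bias",
    "proportion_test",
    "per_type_rates",
]

STRONG = frozenset("CG")
WEAK = frozenset("AT")

SUB_TYPES = [f"{a}>{b}" for a, b in permutations("ACGT", 2)]


def _ws_class(anc: str, der: str) -> str:
    if anc in STRONG and der in WEAK:
        return "SW"
    if anc in WEAK and der in STRONG:
        return "WS"
    return "SSWW"


@dataclass
class PartitionedCounts:
    """Oriented substitutions of one branch (or pooled) split by class."""

    branch: str
    cpg_transitions: int = 0
    non_cpg_substitutions: int = 0
    n_SW: int = 0
    n_WS: int = 0
    n_SS_plus_WW: int = 0
    per_type: dict[str, int] = field(default_factory=lambda: {t: 0 for t in SUB_TYPES})

    @property
    def total(self) -> int:
        return self.n_SW + self.n_WS + self.n_SS_plus_WW

    @property
    def ws_bias(self) -> float | None:
        denom = self.n_WS + self.n_SW
        return self.n_WS / denom if denom else None


def count_cpg_transitions(aln: TripletAlignment) -> dict[str, int]:
    """CpG-context transitions per branch (plus the non-CpG remainder).

    A branch substitution is CpG-context iff the oriented ancestral base is
    C with an ancestral G immediately 3' (change C>T) or G with an ancestral
    C immediately 5' (change G>A), and the partner base is conserved between
    human and chimp.  Edge columns without a partner count as non-CpG.
    """
    ev = oriented_events(aln)
    out = {"human": 0, "chimp": 0, "human_non_cpg": 0, "chimp_non_cpg": 0}
    h, c, o = aln.rows()
    for rec in ev.itertuples(index=False):
        col = rec.column
        is_cpg = False
        if rec.ancestral == "C" and rec.derived == "T" and col + 1 < aln.width:
            if o[col + 1] == "G" and h[col + 1] == "G" and c[col + 1] == "G":
                is_cpg = True
        elif rec.ancestral == "G" and rec.derived == "A" and col - 1 >= 0:
            if o[col - 1] == "C" and h[col - 1] == "C" and c[col - 1] == "C":
                is_cpg = True
        if is_cpg:
            out[rec.branch] += 1
        else:
            out[f"{rec.branch}_non_cpg"] += 1
    return out


def ws_partition(aln: TripletAlignment) -> dict[str, PartitionedCounts]:
    """Classify every oriented substitution by direction and S/W class.

    Returns PartitionedCounts per branch plus 'pooled'; CpG counts included.
    """
    cpg = count_cpg_transitions(aln)
    ev = oriented_events(aln)
    out = {b: PartitionedCounts(branch=b) for b in ("human", "chimp", "pooled")}
    out["human"].cpg_transitions = cpg["human"]
    out["human"].non_cpg_substitutions = cpg["human_non_cpg"]
    out["chimp"].cpg_transitions = cpg["chimp"]
    out["chimp"].non_cpg_substitutions = cpg["chimp_non_cpg"]
    out["pooled"].cpg_transitions = cpg["human"] + cpg["chimp"]
    out["pooled"].non_cpg_substitutions = cpg["human_non_cpg"] + cpg["chimp_non_cpg"]
    for rec in ev.itertuples(index=False):
        for target in (out[rec.branch], out["pooled"]):
            cls = _ws_class(rec.ancestral, rec.derived)
            if cls == "SW":
                target.n_SW += 1
            elif cls == "WS":
                target.n_WS += 1
            else:
                target.n_SS_plus_WW += 1
            target.per_type[f"{rec.ancestral}>{rec.derived}"] += 1
    return out


def ws_bias(counts: PartitionedCounts) -> float | None:
    """W>S bias = n_WS / (n_WS + n_SW); None when no directional change exists."""
    return counts.ws_bias


def proportion_test(a: PartitionedCounts, b: PartitionedCounts, contrast: str) -> float:
    """Two-sided Fisher exact test comparing class proportions of two groups.

    contrast 'cpg_vs_noncpg' compares CpG to non-CpG substitutions;
    'sw_vs_ws' compares S>W to W>S counts.  Empty margins give p = 1.
    """
    if contrast == "cpg_vs_noncpg":
        table = [[a.cpg_transitions, a.non_cpg_substitutions],
                 [b.cpg_transitions, b.non_cpg_substitutions]]
    elif contrast == "sw_vs_ws":
        table = [[a.n_SW, a.n_WS], [b.n_SW, b.n_WS]]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    arr = np.asarray(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn(f"degenerate margin in {contrast}; p set to 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def per_type_rates(aln: TripletAlignment, branch: str = "human") -> pd.DataFrame:
    """Rate of each of the 12 ordered substitution types on one branch.

    Denominator per type = gap-free columns whose oriented ancestral (orang)
    base equals the source base, so rates are per mutational opportunity;
    the denominators partition the effective length.
    """
    m = np.frombuffer((aln.human + aln.chimp + aln.orang).encode(), dtype=np.uint8).reshape(3, aln.width)
    code = classify_columns(m[0], m[1], m[2])
    valid = code != EXCLUDED
    denominators = {b: int(((m[2] == ord(b)) & valid).sum()) for b in "ACGT"}
    counts = ws_partition(aln)[branch].per_type
    rows = []
    for t in SUB_TYPES:
        src = t[0]
        denom = denominators[src]
        rate = counts[t] / denom if denom else np.nan
        rows.append({"type": t, "count": counts[t], "opportunities": denom, "rate": rate})
    df = pd.DataFrame(rows).set_index("type")
    df.attrs["effective_length"] = int(valid.sum())
    return df
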