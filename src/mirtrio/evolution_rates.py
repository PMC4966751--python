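"""Branch-specific substitution counting and rate statistics.

The orang-utan allele orients each column of a human/chimp/orang alignment
into ancestral and derived states: where human and chimp disagree and the
orang base equals exactly one of them, the other carries a branch-specific
substitution.  Columns with a gap or ambiguity code anywhere are dropped
from the effective length; columns with three distinct alleles cannot be
oriented and are skipped (multiallelic).  Rates are substitutions per
effective site; Tajima's relative rate test compares the two branch counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TripletAlignment

__all__ = [
    "SubstitutionSummary",
    "RateResult",
    "CategoryBootstrap",
    "classify_columns",
    "orient_and_count",
    "oriented_events",
    "substitution_rate",
    "round_rate",
    "tajima_rrt",
    "tajima_rrt_binomial",
    "rrt_batch",
    "bootstrap_category",
    "compare_categories",
    "seed_region_rates",
    "alignment_column_of_position",
    "rates_on_categories_regression",
]

# column classification codes
EXCLUDED, INVARIANT, HUMAN, CHIMP, ORANG, MULTI = range(6)

_BASES = b"ACGT"


@dataclass
class SubstitutionSummary:
    """Oriented per-branch substitution counts over the gap-free columns."""

    effective_length: int = 0
    m_human: int = 0
    m_chimp: int = 0
    n_multiallelic: int = 0
    #: human==chimp != orang columns (orang-branch or ancestral change); diagnostic only
    n_orang: int = 0

    def __post_init__(self) -> None:
        if min(self.effective_length, self.m_human, self.m_chimp, self.n_multiallelic, self.n_orang) < 0:
            raise ValueError("negative count")
        if self.m_human + self.m_chimp + self.n_multiallelic > self.effective_length:
            raise ValueError("counts exceed effective length")

    def __add__(self, other: "SubstitutionSummary") -> "SubstitutionSummary":
        return SubstitutionSummary(
            self.effective_length + other.effective_length,
            self.m_human + other.m_human,
            self.m_chimp + other.m_chimp,
            self.n_multiallelic + other.n_multiallelic,
            self.n_orang + other.n_orang,
        )

    def branch_count(self, branch: str) -> int:
        return {"human": self.m_human, "chimp": self.m_chimp}[branch]


@dataclass
class RateResult:
    rate_human: float
    rate_chimp: float
    rrt_chi2: float
    rrt_p: float
    sd_human: float | None = None
    sd_chimp: float | None = None
    ci_human: tuple[float, float] | None = None
    ci_chimp: tuple[float, float] | None = None


def _matrix(aln: TripletAlignment) -> np.ndarray:
    return np.frombuffer(
        (aln.human + aln.chimp + aln.orang).encode("ascii"), dtype=np.uint8
    ).reshape(3, aln.width)


def classify_columns(h: np.ndarray, c: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Classify alignment columns given uint8 base rows (vectorized).

    Returns codes: 0 excluded (gap/ambiguity), 1 invariant, 2 human-branch,
    3 chimp-branch, 4 orang/ancestral (human==chimp!=orang), 5 multiallelic.
    """
    valid = np.ones(h.shape, dtype=bool)
    for row in (h, c, o):
        ok = np.zeros(row.shape, dtype=bool)
        for b in _BASES:
            ok |= row == b
        valid &= ok
    code = np.zeros(h.shape, dtype=np.uint8)
    hc = h == c
    ho = h == o
    co = c == o
    code[valid & hc & ho] = INVARIANT
    code[valid & ~hc & co] = HUMAN
    code[valid & ~hc & ho] = CHIMP
    code[valid & hc & ~ho] = ORANG
    code[valid & ~hc & ~ho & ~co] = MULTI
    return code


def orient_and_count(aln: TripletAlignment) -> SubstitutionSummary:
    """Count branch-specific substitutions oriented by the orang-utan allele."""
    m = _matrix(aln)
    code = classify_columns(m[0], m[1], m[2])
    return SubstitutionSummary(
        effective_length=int((code != EXCLUDED).sum()),
        m_human=int((code == HUMAN).sum()),
        m_chimp=int((code == CHIMP).sum()),
        n_multiallelic=int((code == MULTI).sum()),
        n_orang=int((code == ORANG).sum()),
    )


def oriented_events(aln: TripletAlignment) -> pd.DataFrame:
    """Per-substitution records: column, branch, ancestral and derived base.

    The ancestral state of an oriented branch substitution is the allele
    shared with the outgroup; the derived state is the differing allele.
    """
    m = _matrix(aln)
    code = classify_columns(m[0], m[1], m[2])
    cols_h = np.nonzero(code == HUMAN)[0]
    cols_c = np.nonzero(code == CHIMP)[0]
    rec = []
    for cols, branch, der_row in ((cols_h, "human", 0), (cols_c, "chimp", 1)):
        for col in cols:
            rec.append(
                {
                    "column": int(col),
                    "branch": branch,
                    "ancestral": chr(m[2, col]),
                    "derived": chr(m[der_row, col]),
                }
            )
    return pd.DataFrame(rec, columns=["column", "branch", "ancestral", "derived"])


def round_rate(rate: float, ndigits: int = 4) -> float:
    """Round half-up for display (printed tables use 4 decimals)."""
    return float(Decimal(repr(rate)).quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def substitution_rate(summary: SubstitutionSummary, branch: str) -> float:
    """Branch substitutions per effective site (full precision; round_rate for display)."""
    if summary.effective_length == 0:
        raise ZeroDivisionError("effective length is zero; rate undefined")
    return summary.branch_count(branch) / summary.effective_length


def tajima_rrt(m1, m2):
    """Tajima's relative rate test, chi-square form.

    chi2 = (m1 - m2)^2 / (m1 + m2) on 1 df; (0, 0) gives chi2=0, p=1.
    Accepts scalars or numpy arrays.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    tot = m1 + m2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(tot > 0, (m1 - m2) ** 2 / np.where(tot > 0, tot, 1.0), 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(tot > 0, p, 1.0)
    if chi2.ndim == 0:
        return float(chi2), float(p)
    return chi2, p


def tajima_rrt_binomial(m1: int, m2: int) -> float:
    """Exact two-sided binomial alternative (p = 0.5 null on m1 of m1+m2)."""
    n = m1 + m2
    if n == 0:
        return 1.0
    return float(min(1.0, stats.binomtest(m1, n, 0.5).pvalue))


def rrt_batch(summaries: list[SubstitutionSummary], alpha: float = 0.05,
              ids: list[str] | None = None) -> pd.DataFrame:
    """Per-alignment RRT with nominal and Bonferroni significance flags.

    The Bonferroni threshold alpha/N is attached to the frame as
    ``.attrs['bonferroni_threshold']`` (full precision) and
    ``.attrs['bonferroni_threshold_display']`` (2 significant figures, as
    printed in the source tables).
    """
    n = len(summaries)
    if n < 1:
        raise ValueError("need at least one test")
    m1 = np.array([s.m_human for s in summaries])
    m2 = np.array([s.m_chimp for s in summaries])
    chi2, p = tajima_rrt(m1, m2)
    chi2 = np.atleast_1d(chi2)
    p = np.atleast_1d(p)
    threshold = alpha / n
    df = pd.DataFrame(
        {
            "id": ids if ids is not None else [str(i) for i in range(n)],
            "m_human": m1,
            "m_chimp": m2,
            "chi2": chi2,
            "p": p,
            "significant_nominal": p < alpha,
            "significant_bonferroni": p < threshold,
        }
    )
    df.attrs["bonferroni_threshold"] = threshold
    df.attrs["bonferroni_threshold_display"] = float(f"{threshold:.2g}")
    df.attrs["alpha"] = alpha
    return df


@dataclass
class CategoryBootstrap:
    """Observed concatenated rates plus bootstrap spread for one category."""

    rate_human: float
    rate_chimp: float
    sd_human: float
    sd_chimp: float
    ci_human: tuple[float, float]
    ci_chimp: tuple[float, float]
    boot_human: np.ndarray = field(repr=False, default=None)
    boot_chimp: np.ndarray = field(repr=False, default=None)


def bootstrap_category(members: list[SubstitutionSummary], B: int = 100,
                       seed: int | np.random.Generator = 0) -> CategoryBootstrap:
    """Bootstrap the concatenated category rate by resampling miRNAs.

    Each of B resamples draws len(members) members with replacement and
    recomputes the pooled rate sum(m)/sum(L) per branch; reports the sd and
    the 2.5/97.5 percentiles. Deterministic given the seed.
    """
    if not members:
        raise ValueError("empty category")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mh = np.array([s.m_human for s in members], dtype=float)
    mc = np.array([s.m_chimp for s in members], dtype=float)
    ll = np.array([s.effective_length for s in members], dtype=float)
    n = len(members)
    idx = rng.integers(0, n, size=(B, n))
    tot_l = ll[idx].sum(axis=1)
    tot_l[tot_l == 0] = np.nan
    bh = mh[idx].sum(axis=1) / tot_l
    bc = mc[idx].sum(axis=1) / tot_l
    obs_l = ll.sum()
    return CategoryBootstrap(
        rate_human=float(mh.sum() / obs_l),
        rate_chimp=float(mc.sum() / obs_l),
        sd_human=float(np.nanstd(bh, ddof=1)),
        sd_chimp=float(np.nanstd(bc, ddof=1)),
        ci_human=(float(np.nanpercentile(bh, 2.5)), float(np.nanpercentile(bh, 97.5))),
        ci_chimp=(float(np.nanpercentile(bc, 2.5)), float(np.nanpercentile(bc, 97.5))),
        boot_human=bh,
        boot_chimp=bc,
    )


def compare_categories(a: CategoryBootstrap, b: CategoryBootstrap,
                       branch: str = "human") -> str:
    """Reciprocal-tail comparison of two category rates.

    'different' iff a's observed rate falls outside b's bootstrap
    [2.5, 97.5] percentile interval AND b's observed falls outside a's;
    otherwise 'not distinguishable'.
    """
    obs_a = getattr(a, f"rate_{branch}")
    obs_b = getattr(b, f"rate_{branch}")
    ci_a = getattr(a, f"ci_{branch}")
    ci_b = getattr(b, f"ci_{branch}")
    a_out = obs_a < ci_b[0] or obs_a > ci_b[1]
    b_out = obs_b < ci_a[0] or obs_b > ci_a[1]
    return "different" if (a_out and b_out) else "not distinguishable"


def alignment_column_of_position(aln: TripletAlignment, pos: int) -> int:
    """Column index holding human-sequence position ``pos`` (0-based, gaps skipped)."""
    count = -1
    for col, ch in enumerate(aln.human):
        if ch != "-":
            count += 1
            if count == pos:
                return col
    raise IndexError(f"human position {pos} beyond ungapped length {count + 1}")


def seed_region_rates(
    alignments: dict[str, TripletAlignment],
    seed_coords: dict[str, list[tuple[int, int]]],
) -> dict[str, SubstitutionSummary]:
    """Count substitutions inside seed regions (per seed, keyed id:index).

    ``seed_coords`` maps locus id to up to two (start, end) offsets within the
    human precursor (0-based half-open, gap-free coordinates); offsets are
    mapped to alignment columns by walking the gapped human row.
    """
    out: dict[str, SubstitutionSummary] = {}
    for locus, seeds in seed_coords.items():
        aln = alignments[locus]
        ungapped = sum(ch != "-" for ch in aln.human)
        for i, (s, e) in enumerate(seeds):
            if not (0 <= s < e <= ungapped):
                raise ValueError(f"{locus} seed [{s},{e}) outside precursor of length {ungapped}")
            c0 = alignment_column_of_position(aln, s)
            c1 = alignment_column_of_position(aln, e - 1) + 1
            out[f"{locus}:{i}"] = orient_and_count(aln.slice_columns(c0, c1))
    return out


def rates_on_categories_regression(rates: pd.Series, labels: pd.DataFrame) -> pd.DataFrame:
    """OLS of per-miRNA rates on the four classification axes.

    ``labels`` needs columns clustered, copies, conservation, context; each
    axis enters as treatment-coded indicators.  Returns the statsmodels
    coefficient table (coef, se, t, p); collinear columns are dropped with a
    warning entry in ``.attrs['dropped']``.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(index=labels.index)
    X["clustered"] = (labels["clustered"] == "clustered").astype(float)
    X["multiple_copy"] = (labels["copies"] == "multiple").astype(float)
    X["primate_specific"] = (labels["conservation"] == "primate-specific").astype(float)
    ctx = labels["context"].astype(str)
    for level in sorted(ctx.unique()):
        if level in ("intergenic", "unassigned"):
            continue  # intergenic is the reference level; unassigned excluded
        X[f"context_{level.replace(':', '_')}"] = (ctx == level).astype(float)
    keep = ctx != "unassigned"
    X = X.loc[keep]
    y = pd.Series(rates).loc[keep]
    dropped = []
    for col in list(X.columns):
        if X[col].nunique() < 2:
            dropped.append(col)
            X = X.drop(columns=col)
    model = sm.OLS(y, sm.add_constant(X)).fit()
    table = pd.DataFrame(
        {"coef": model.params, "se": model.bse, "t": model.tvalues, "p": model.pvalues}
    )
    table.attrs["dropped"] = dropped
    table.attrs["r_squared"] = float(model.rsquared)
    return table
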