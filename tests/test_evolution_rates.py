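"""Unit and property tests for orientation, rates, the RRT and bootstraps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirtrio.evolution_rates import (
    SubstitutionSummary,
    alignment_column_of_position,
    bootstrap_category,
    compare_categories,
    orient_and_count,
    oriented_events,
    rates_on_categories_regression,
    round_rate,
    rrt_batch,
    seed_region_rates,
    substitution_rate,
    tajima_rrt,
    tajima_rrt_binomial,
)
from tests.conftest import make_aln


def brute_force_classify(h, c, o):
    """Independent per-column oracle for the orientation rule."""
    if any(ch not in "ACGT" for ch in (h, c, o)):
        return "excluded"
    if h == c == o:
        return "invariant"
    if h != c and c == o:
        return "human"
    if h != c and h == o:
        return "chimp"
    if h == c and h != o:
        return "orang"
    return "multi"


def brute_force_count(aln):
    keys = ("excluded", "invariant", "human", "chimp", "orang", "multi")
    counts = dict.fromkeys(keys, 0)
    for col in zip(aln.human, aln.chimp, aln.orang):
        counts[brute_force_classify(*col)] += 1
    return counts


class TestOrientAndCount:
    def test_exhaustive_64_triplet_columns(self):
        """Every (h, c, o) base combination classifies as the brute-force rule."""
        cols = list(itertools.product("ACGT", repeat=3))
        aln = make_aln(*("".join(col[i] for col in cols) for i in range(3)))
        s = orient_and_count(aln)
        oracle = brute_force_count(aln)
        assert s.effective_length == 64
        assert s.m_human == oracle["human"]
        assert s.m_chimp == oracle["chimp"]
        assert s.n_multiallelic == oracle["multi"]
        assert s.n_orang == oracle["orang"]
        # sanity of the oracle itself: 4 roots x 3 derived per single-branch class
        assert oracle["human"] == oracle["chimp"] == oracle["orang"] == 12
        assert oracle["invariant"] == 4 and oracle["multi"] == 24

    @pytest.mark.parametrize("col,branch", [
        (("G", "A", "A"), "human"),
        (("A", "G", "A"), "chimp"),
        (("G", "T", "A"), "multi"),
        (("G", "G", "A"), "orang"),
    ])
    def test_single_column_rules(self, col, branch):
        aln = make_aln(*col)
        s = orient_and_count(aln)
        got = {
            "human": s.m_human, "chimp": s.m_chimp,
            "multi": s.n_multiallelic, "orang": s.n_orang,
        }
        assert got.pop(branch) == 1
        assert all(v == 0 for v in got.values())

    def test_gaps_and_ambiguity_excluded(self):
        aln = make_aln("A-GN", "AAGA", "AAGA")
        s = orient_and_count(aln)
        assert s.effective_length == 2  # columns 0 and 2 only

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(*[st.sampled_from("ACGTN-")] * 3), min_size=1, max_size=60))
    def test_matches_bruteforce_on_random_alignments(self, cols):
        aln = make_aln(*("".join(c[i] for c in cols) for i in range(3)))
        s = orient_and_count(aln)
        oracle = brute_force_count(aln)
        assert s.m_human == oracle["human"] and s.m_chimp == oracle["chimp"]
        assert s.effective_length == len(cols) - oracle["excluded"]
        assert s.n_multiallelic == oracle["multi"]

    def test_events_match_counts_and_orientation(self):
        aln = make_aln("GCTA", "ACTA", "ACGA")
        ev = oriented_events(aln)
        s = orient_and_count(aln)
        assert len(ev) == s.m_human + s.m_chimp
        human = ev[ev.branch == "human"].iloc[0]
        assert (human.ancestral, human.derived) == ("A", "G")


class TestRates:
    @pytest.mark.parametrize("m,L,expected", [
        (32, 5558, 0.0058),
        (39, 5558, 0.007),
        (341, 62048, 0.0055),
        (402, 61283, 0.0066),
        (40, 16615, 0.0024),
        (4, 3214, 0.0012),
        (7, 2417, 0.0029),
        (0, 100, 0.0),
    ])
    def test_published_category_arithmetic(self, m, L, expected):
        s = SubstitutionSummary(effective_length=L, m_human=m)
        assert round_rate(substitution_rate(s, "human")) == pytest.approx(expected)

    def test_zero_length_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            substitution_rate(SubstitutionSummary(0, 0, 0), "human")

    def test_summary_additivity(self):
        a = SubstitutionSummary(80, 2, 1, 1)
        b = SubstitutionSummary(70, 0, 3, 0)
        tot = a + b
        assert (tot.effective_length, tot.m_human, tot.m_chimp) == (150, 2, 4)


class TestTajimaRrt:
    def test_zero_counts(self):
        assert tajima_rrt(0, 0) == (0.0, 1.0)

    def test_known_values_against_chi2_tail(self):
        chi2, p = tajima_rrt(14, 0)
        assert chi2 == pytest.approx(14.0)
        assert p == pytest.approx(stats.chi2.sf(14.0, 1), rel=1e-12)
        assert p == pytest.approx(1.83e-4, rel=0.01)
        chi2, p = tajima_rrt(3, 1)
        assert chi2 == pytest.approx(1.0)
        assert p == pytest.approx(0.3173, abs=2e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 200), st.integers(0, 200))
    def test_symmetry(self, m1, m2):
        assert tajima_rrt(m1, m2) == tajima_rrt(m2, m1)

    def test_monotone_in_imbalance_at_fixed_total(self):
        total = 30
        ps = [tajima_rrt(m1, total - m1)[1] for m1 in range(total // 2, total + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_binomial_variant(self):
        assert tajima_rrt_binomial(0, 0) == 1.0
        assert tajima_rrt_binomial(14, 0) == pytest.approx(2 * 0.5**14)


class TestRrtBatch:
    def test_bonferroni_threshold_published(self):
        summaries = [SubstitutionSummary(100, 1, 1) for _ in range(1214)]
        df = rrt_batch(summaries, alpha=0.05)
        assert df.attrs["bonferroni_threshold_display"] == pytest.approx(0.000041)

    def test_single_test_threshold_is_alpha(self):
        df = rrt_batch([SubstitutionSummary(100, 3, 0)], alpha=0.05)
        assert df.attrs["bonferroni_threshold"] == pytest.approx(0.05)

    def test_balanced_counts_never_flagged(self):
        summaries = [SubstitutionSummary(100, k, k) for k in range(5)]
        df = rrt_batch(summaries)
        assert not df["significant_nominal"].any()


class TestBootstrap:
    def test_identical_members_collapse(self):
        members = [SubstitutionSummary(100, 2, 1)] * 20
        boot = bootstrap_category(members, B=100, seed=0)
        assert boot.sd_human == pytest.approx(0.0, abs=1e-12)
        assert boot.ci_human == (pytest.approx(0.02), pytest.approx(0.02))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        members = [SubstitutionSummary(80, int(k), 1) for k in rng.integers(0, 4, 50)]
        b1 = bootstrap_category(members, B=100, seed=9)
        b2 = bootstrap_category(members, B=100, seed=9)
        assert b1.sd_human == b2.sd_human and b1.ci_chimp == b2.ci_chimp

    def test_sd_close_to_binomial_se(self, rng):
        """On homogeneous members the bootstrap sd matches sqrt(r(1-r)/L)."""
        L, r, n = 85, 0.02, 400
        members = [SubstitutionSummary(L, int(rng.binomial(L, r)), 0) for _ in range(n)]
        boot = bootstrap_category(members, B=2000, seed=1)
        se = np.sqrt(boot.rate_human * (1 - boot.rate_human) / (n * L))
        assert boot.sd_human == pytest.approx(se, rel=0.15)

    def test_pooled_rate_is_weighted_not_mean_of_rates(self):
        members = [SubstitutionSummary(10, 1, 0), SubstitutionSummary(990, 0, 0)]
        boot = bootstrap_category(members, B=10, seed=0)
        assert boot.rate_human == pytest.approx(1 / 1000)


class TestCompareCategories:
    def test_identical_categories_not_distinguishable(self):
        members = [SubstitutionSummary(80, 1, 1) for _ in range(30)]
        a = bootstrap_category(members, B=100, seed=1)
        b = bootstrap_category(members, B=100, seed=2)
        assert compare_categories(a, b) == "not distinguishable"

    def test_well_separated_rates_differ(self, rng):
        la = [SubstitutionSummary(85, int(rng.binomial(85, 0.002)), 0) for _ in range(200)]
        lb = [SubstitutionSummary(85, int(rng.binomial(85, 0.014)), 0) for _ in range(200)]
        a = bootstrap_category(la, B=100, seed=1)
        b = bootstrap_category(lb, B=100, seed=2)
        assert compare_categories(a, b) == "different"

    def test_one_sided_exceedance_insufficient(self):
        """The rule is reciprocal: one observed rate inside the other's interval
        blocks the 'different' verdict."""
        from mirtrio.evolution_rates import CategoryBootstrap

        a = CategoryBootstrap(0.005, 0.005, 0.001, 0.001, (0.004, 0.006), (0.004, 0.006))
        b = CategoryBootstrap(0.0055, 0.0055, 0.001, 0.001, (0.0, 0.02), (0.0, 0.02))
        assert compare_categories(a, b) == "not distinguishable"


class TestSeedRegions:
    def test_identical_triplet_zero(self):
        aln = make_aln("A" * 80, "A" * 80, "A" * 80, locus_id="m")
        out = seed_region_rates({"m": aln}, {"m": [(9, 16)]})
        assert out["m:0"].m_human == 0 and out["m:0"].effective_length == 7

    def test_substitution_inside_vs_outside_seed(self):
        h = list("A" * 80)
        h[12] = "G"  # inside a seed spanning positions 9..16
        h[40] = "C"  # outside
        aln = make_aln("".join(h), "A" * 80, "A" * 80, locus_id="m")
        out = seed_region_rates({"m": aln}, {"m": [(9, 16)]})
        assert out["m:0"].m_human == 1

    def test_gap_upstream_shifts_columns(self):
        """Columns are located by walking the gapped human row (oracle: the
        per-base coordinate map)."""
        human = "AC-" + "G" * 10  # gap at column 2; human position 2 is column 3
        aln = make_aln(human, "ACA" + "G" * 10, "ACA" + "G" * 10, locus_id="m")
        oracle = [i for i, ch in enumerate(human) if ch != "-"]
        for pos in (0, 1, 2, 5):
            assert alignment_column_of_position(aln, pos) == oracle[pos]
        out = seed_region_rates({"m": aln}, {"m": [(2, 9)]})
        assert out["m:0"].effective_length == 7

    def test_seed_outside_precursor_raises(self):
        aln = make_aln("A" * 20, "A" * 20, "A" * 20, locus_id="m")
        with pytest.raises(ValueError):
            seed_region_rates({"m": aln}, {"m": [(15, 25)]})


class TestRegression:
    @staticmethod
    def _labels(n, conservation):
        return pd.DataFrame(
            {
                "clustered": ["non-clustered"] * n,
                "copies": ["single"] * n,
                "conservation": conservation,
                "context": ["intergenic", "genic:intron"] * (n // 2),
            }
        )

    def test_noiseless_offsets_recovered_exactly(self):
        n = 40
        labels = self._labels(n, ["primate-specific"] * (n // 2) + ["ConFam"] * (n // 2))
        rates = 0.001 + 0.004 * (labels["conservation"] == "primate-specific") \
            + 0.002 * (labels["context"] == "genic:intron")
        table = rates_on_categories_regression(rates, labels)
        assert table.loc["primate_specific", "coef"] == pytest.approx(0.004, abs=1e-10)
        assert table.loc["context_genic_intron", "coef"] == pytest.approx(0.002, abs=1e-10)
        assert table.loc["const", "coef"] == pytest.approx(0.001, abs=1e-10)

    def test_constant_rates_zero_coefficients(self):
        labels = self._labels(20, ["primate-specific"] * 10 + ["ConFam"] * 10)
        table = rates_on_categories_regression(pd.Series([0.005] * 20), labels)
        nonconst = table.drop(index="const")
        assert np.allclose(nonconst["coef"], 0.0, atol=1e-12)

    def test_primate_offset_detected_under_noise(self, rng):
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 400
            cons = ["primate-specific"] * 280 + ["ConFam"] * 120
            labels = self._labels(n, cons)
            base = 0.0014 + 0.0042 * (labels["conservation"] == "primate-specific")
            rates = rng.binomial(85, base.to_numpy()) / 85
            table = rates_on_categories_regression(pd.Series(rates), labels)
            if table.loc["primate_specific", "p"] < 0.05 and \
               (table.drop(index=["const", "primate_specific"])["p"] > 0.05).all():
                hits += 1
        assert hits >= int(0.95 * reps)

    def test_collinear_axis_dropped(self):
        labels = self._labels(20, ["primate-specific"] * 20)
        table = rates_on_categories_regression(pd.Series([0.01] * 20), labels)
        assert "primate_specific" in table.attrs["dropped"]
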