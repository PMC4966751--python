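"""Curation-funnel behaviour: best-hit ranking, evidence reconciliation,
many-to-one exclusion, trimming/coverage/gap/MFE filters, flanks and ARs."""

import itertools

import numpy as np
import pytest

from mirtrio.io_formats import BlatHit, GenomicInterval
from mirtrio.ortholog_curation import (
    ArRecord,
    OrthologyCall,
    Rejection,
    align_triplet,
    curate_ancestral_repeats,
    exclude_many_to_one,
    extract_flank_alignment,
    mfe_filter,
    resolve_orthology,
    select_best_blat_hit,
    trim_and_filter_alignment,
)
from tests.conftest import make_aln


def hit(matched, identity, qlen=80, chrom="chr1", start=100, q="hsa-mir-x"):
    return BlatHit(q, GenomicInterval(chrom, start, start + matched), matched, identity, qlen)


class TestBestBlatHit:
    def test_low_coverage_dropped(self):
        best = select_best_blat_hit([hit(76, 0.95), hit(56, 1.0)])  # 0.70 coverage dropped
        assert best.matched_length == 76

    def test_order_by_length_then_identity(self):
        best = select_best_blat_hit([hit(80, 0.92), hit(80, 0.98, start=500)])
        assert best.identity == 0.98

    def test_all_below_coverage_gives_none(self):
        assert select_best_blat_hit([hit(60, 1.0), hit(50, 1.0)]) is None

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            select_best_blat_hit([hit(80, 1.0, q="a"), hit(80, 1.0, q="b")])

    def test_tie_break_invariant_to_input_order_and_flagged(self):
        tied = [hit(80, 0.95, chrom="chr7", start=10), hit(80, 0.95, chrom="chr1", start=900)]
        results = {select_best_blat_hit(list(perm)).target for perm in itertools.permutations(tied)}
        assert results == {GenomicInterval("chr1", 900, 980)}
        assert all(select_best_blat_hit(list(p)).ambiguous for p in itertools.permutations(tied))


class TestResolveOrthology:
    def test_overlapping_sources_take_leftmost_rightmost(self):
        call = resolve_orthology(
            "m",
            {"chimp": hit(80, 1.0, start=100), "orang": hit(80, 1.0, start=100)},
            {"chimp": GenomicInterval("chr1", 95, 178), "orang": GenomicInterval("chr1", 95, 178)},
        )
        assert call.chimp == GenomicInterval("chr1", 95, 180)
        assert call.evidence["chimp"] == "blat+liftover"

    def test_liftover_only(self):
        call = resolve_orthology(
            "m", {"chimp": None, "orang": None},
            {"chimp": GenomicInterval("chr1", 0, 80), "orang": GenomicInterval("chr2", 0, 80)},
        )
        assert call.evidence == {"chimp": "liftover_only", "orang": "liftover_only"}

    def test_different_chromosomes_dropped(self):
        res = resolve_orthology(
            "m",
            {"chimp": hit(80, 1.0, chrom="chr1"), "orang": hit(80, 1.0)},
            {"chimp": GenomicInterval("chr7", 100, 180), "orang": GenomicInterval("chr1", 100, 180)},
        )
        assert isinstance(res, Rejection) and res.reason == "discordant"

    def test_strand_conflict_is_discordant(self):
        res = resolve_orthology(
            "m",
            {"chimp": hit(80, 1.0), "orang": hit(80, 1.0)},
            {"chimp": GenomicInterval("chr1", 100, 180, "-"), "orang": GenomicInterval("chr1", 100, 180)},
        )
        assert isinstance(res, Rejection)

    def test_missing_species_rejected(self):
        res = resolve_orthology("m", {"chimp": hit(80, 1.0)}, {})
        assert isinstance(res, Rejection) and res.reason == "no_ortholog"


class TestManyToOne:
    @staticmethod
    def _call(name, start, species="chimp"):
        c = OrthologyCall(mirna_id=name)
        setattr(c, species, GenomicInterval("chr1", start, start + 80))
        setattr(c, "orang" if species == "chimp" else "chimp", GenomicInterval("chr9", start, start + 80))
        return c

    def test_two_on_same_locus_both_removed(self):
        kept, removed = exclude_many_to_one([self._call("a", 100), self._call("b", 110)])
        assert kept == [] and {c.mirna_id for c in removed} == {"a", "b"}

    def test_unique_assignments_unchanged(self):
        calls = [self._call("a", 100), self._call("b", 10_000)]
        kept, removed = exclude_many_to_one(calls)
        assert len(kept) == 2 and removed == []

    def test_three_way_pileup_matches_bruteforce(self):
        calls = [self._call(n, s) for n, s in (("a", 100), ("b", 120), ("c", 140), ("d", 5000))]
        kept, removed = exclude_many_to_one(calls)
        # brute-force overlap graph: any pair with >= 50 % reciprocal overlap
        bad = set()
        for x in calls:
            for y in calls:
                if x is not y and x.chimp.reciprocal_overlap(y.chimp) >= 0.5:
                    bad.add(x.mirna_id)
        assert {c.mirna_id for c in removed} == bad == {"a", "b", "c"}
        assert [c.mirna_id for c in kept] == ["d"]


class TestTrimAndFilter:
    def test_perfect_alignment_unchanged(self):
        aln = make_aln("ACGT" * 20, "ACGT" * 20, "ACGT" * 20)
        out = trim_and_filter_alignment(aln)
        assert out.rows() == aln.rows()

    def test_low_coverage_rejected(self):
        w = 80
        chimp = "-" * 33 + "A" * (w - 33)  # < 80 % of human
        res = trim_and_filter_alignment(make_aln("A" * w, chimp, "A" * w))
        assert isinstance(res, Rejection) and res.reason == "coverage"

    def test_long_internal_human_gap_rejected(self):
        human = "A" * 30 + "-" * 25 + "A" * 30
        other = "A" * 85
        res = trim_and_filter_alignment(make_aln(human, other, other))
        assert isinstance(res, Rejection) and res.reason == "gap"

    def test_boundary_gap_of_20_passes(self):
        human = "A" * 30 + "-" * 20 + "A" * 30
        other = "A" * 80
        out = trim_and_filter_alignment(make_aln(human, other, other))
        assert not isinstance(out, Rejection)

    def test_trims_to_human_span(self):
        aln = make_aln("--ACGTACGT--", "AAACGTACGTAA", "AAACGTACGTAA")
        out = trim_and_filter_alignment(aln)
        assert out.width == 8 and out.human == "ACGTACGT"


class TestMfeFilter:
    def test_threshold_is_95th_percentile(self, rng):
        ref = list(rng.normal(-37.9, 8, size=100))
        alns = {"m": make_aln("A" * 80, "A" * 80, "A" * 80)}
        mfes = {"m|human": -40.0, "m|chimp": -39.0, "m|orang": -38.0}
        kept, rejected, threshold = mfe_filter(alns, mfes, ref)
        assert threshold == pytest.approx(np.percentile(ref, 95))
        assert "m" in kept and not rejected

    def test_any_weak_sequence_rejects_triplet(self):
        alns = {"m": make_aln("A" * 80, "A" * 80, "A" * 80)}
        mfes = {"m|human": -40.0, "m|chimp": -39.0, "m|orang": -2.0}
        kept, rejected, threshold = mfe_filter(alns, mfes, [-40.0] * 99 + [-20.0])
        assert rejected["m"].reason == "mfe" and "orang" in rejected["m"].detail

    def test_missing_record_names_sequence(self):
        alns = {"m": make_aln("A" * 10, "A" * 10, "A" * 10)}
        with pytest.raises(KeyError, match="m\\|chimp"):
            mfe_filter(alns, {"m|human": -40.0, "m|orang": -40.0}, [-40.0] * 10)


class TestFlanks:
    @staticmethod
    def _genomes(rng, strand="+"):
        core = "".join(rng.choice(list("ACGT"), size=80))
        up = "".join(rng.choice(list("ACGT"), size=200))
        down = "".join(rng.choice(list("ACGT"), size=200))
        chrom = up + core + down
        return {"human": {"chr1": chrom}, "chimp": {"chr1": chrom}, "orang": {"chr1": chrom}}, 200, 280

    def test_identical_flanks_keep_80_bp(self, rng):
        genomes, s, e = self._genomes(rng)
        call = OrthologyCall("m", *[GenomicInterval("chr1", s, e)] * 3)
        flank = extract_flank_alignment(call, genomes)
        assert flank.width == 80
        assert flank.human == genomes["human"]["chr1"][s - 40:s] + genomes["human"]["chr1"][e:e + 40]

    def test_minus_strand_uses_transcript_orientation(self, rng):
        """Reverse-complement oracle: minus-strand flanks equal the
        reverse complement of the plus-strand extraction."""
        from mirtrio.ortholog_curation import _rc

        genomes, s, e = self._genomes(rng)
        plus = extract_flank_alignment(
            OrthologyCall("m", *[GenomicInterval("chr1", s, e)] * 3), genomes)
        minus = extract_flank_alignment(
            OrthologyCall("m", *[GenomicInterval("chr1", s, e, "-")] * 3), genomes)
        assert minus.human == _rc(plus.human)

    def test_contig_edge_short_extraction(self, rng):
        genomes, s, e = self._genomes(rng)
        # locus 10 bp from the contig start: 5' flank is only 10 bp
        genomes2 = {sp: {"chr1": g["chr1"][s - 10:]} for sp, g in genomes.items()}
        call = OrthologyCall("m", *[GenomicInterval("chr1", 10, 90)] * 3)
        flank = extract_flank_alignment(call, genomes2)
        assert not isinstance(flank, Rejection)  # 50 bp aligned >= 50 % of 80

    def test_short_chimp_flanks_rejected(self, rng):
        """A chimp locus at a contig edge aligns < 50 % of the targeted 80 bp."""
        genomes, s, e = self._genomes(rng)
        core = genomes["human"]["chr1"][s:e]
        genomes["chimp"]["chr1"] = "AACC" + core + "GGTT"  # 4 bp flanks only
        call = OrthologyCall(
            "m",
            GenomicInterval("chr1", s, e),
            GenomicInterval("chr1", 4, 84),
            GenomicInterval("chr1", s, e),
        )
        res = extract_flank_alignment(call, genomes)
        assert isinstance(res, Rejection) and res.reason == "flank_coverage"

    def test_strand_discordance_rejected(self, rng):
        genomes, s, e = self._genomes(rng)
        call = OrthologyCall("m", *[GenomicInterval("chr1", s, e)] * 3)
        res = extract_flank_alignment(call, genomes, precursor_strands={"human": "-", "chimp": "+", "orang": "+"})
        assert isinstance(res, Rejection) and res.reason == "strand_discordant"


class TestAncestralRepeats:
    @staticmethod
    def _ar(name, length=80, chrom="chr2", lift_chrom=None, reciprocal=True):
        lift_chrom = lift_chrom or chrom
        return ArRecord(
            name,
            GenomicInterval(chrom, 1000, 1000 + length),
            GenomicInterval(lift_chrom, 2000, 2000 + length),
            GenomicInterval(lift_chrom, 3000, 3000 + length),
            reciprocal=reciprocal,
        )

    def test_length_bounds(self):
        kept = curate_ancestral_repeats([self._ar("short", 65), self._ar("ok", 80), self._ar("long", 95)])
        assert [a.ar_id for a in kept] == ["ok"]

    def test_same_chromosome_required(self):
        kept = curate_ancestral_repeats([self._ar("moved", lift_chrom="chr9"), self._ar("ok")])
        assert [a.ar_id for a in kept] == ["ok"]

    def test_reciprocal_liftover_required(self):
        kept = curate_ancestral_repeats([self._ar("no", reciprocal=False), self._ar("ok")])
        assert [a.ar_id for a in kept] == ["ok"]


class TestFunnelOnSyntheticViolations:
    def test_injected_violations_rejected_with_matching_reasons(self):
        from mirtrio.synthetic_data import CategoryParams, SimulationConfig, simulate_triplets

        cfg = SimulationConfig(
            seed=21,
            categories={"only": CategoryParams(n=40, rate_human=0.005, rate_chimp=0.005)},
            n_gap_violations=3, n_coverage_violations=2, n_mfe_violations=4,
        )
        ds = simulate_triplets(cfg)
        trimmed = {}
        reasons = {}
        for l in ds.loci:
            res = trim_and_filter_alignment(l.precursor)
            if isinstance(res, Rejection):
                reasons[l.locus_id] = res.reason
            else:
                trimmed[l.locus_id] = res
        # a wide reference distribution isolates the injected MFE outliers
        mfes = {f"{l.locus_id}|{sp}": l.mfe[sp] for l in ds.loci for sp in ("human", "chimp", "orang")}
        kept, rejected, _ = mfe_filter(trimmed, mfes, human_reference_mfes=[-60.0, -10.0] * 50)
        reasons.update({k: r.reason for k, r in rejected.items()})
        truth = {l.locus_id: l.rejection_truth for l in ds.loci if l.rejection_truth}
        assert reasons == truth
        # funnel is monotone and reasons partition the removed set
        assert set(kept) | set(reasons) == {l.locus_id for l in ds.loci}
        assert not (set(kept) & set(reasons))

    def test_evidence_class_tally(self):
        from mirtrio.ortholog_curation import classify_evidence

        def call(ec, eo):
            c = OrthologyCall("m", None, GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 0, 10))
            c.evidence = {"chimp": ec, "orang": eo}
            return c

        assert classify_evidence(call("blat+liftover", "blat+liftover")) == "blat+liftover"
        assert classify_evidence(call("blat_only", "liftover_only")) == "blat_chimp_lo_orang"
        assert classify_evidence(call("liftover_only", "blat_only")) == "blat_orang_lo_chimp"
        assert classify_evidence(call("liftover_only", "liftover_only")) == "liftover_only"


class TestAligner:
    def test_identical_sequences_align_without_gaps(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=60))
        aln = align_triplet(s, s, s)
        assert aln.human == aln.chimp == aln.orang == s

    def test_single_deletion_recovered(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=60))
        aln = align_triplet(s, s[:30] + s[31:], s)
        assert aln.human == s and aln.chimp.count("-") == 1
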