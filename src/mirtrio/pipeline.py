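"""End-to-end orchestration: simulate -> curate -> classify -> rates ->
composition -> acceleration LRT, with a funnel report and a category rate
table in the layout of the published summary table.

Every threshold is a named config field defaulting to the published value;
identical config + seed reproduces the report byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .acceleration_lrt import fit_reference, lrt_acceleration
from .categories import (
    assign_clusters,
    assign_context,
    assign_copies_and_conservation,
    category_contingency,
)
from .composition_bias import proportion_test, ws_partition
from .evolution_rates import (
    SubstitutionSummary,
    bootstrap_category,
    compare_categories,
    orient_and_count,
    round_rate,
    rrt_batch,
    tajima_rrt,
)
from .io_formats import (
    gff_intervals,
    read_bed,
    read_family_file,
    read_gff3,
    read_psl,
)
from .ortholog_curation import (
    Rejection,
    classify_evidence,
    exclude_many_to_one,
    mfe_filter,
    resolve_orthology,
    select_best_blat_hit,
    trim_and_filter_alignment,
)
from .synthetic_data import SimulationConfig, simulate_neutral_refs, simulate_triplets, write_fixtures

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    outdir: str = "mirtrio_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    stages: tuple[str, ...] = ("simulate", "curate", "classify", "rates", "composition", "lrt")
    bootstrap_B: int = 100
    rrt_alpha: float = 0.05
    lrt_n_refs: int = 20
    lrt_restarts: int = 3
    write_fixture_tree: bool = True

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)


def _category_row(name: str, members: list[SubstitutionSummary], B: int, seed: int) -> dict:
    pooled = sum(members, SubstitutionSummary())
    boot = bootstrap_category(members, B=B, seed=seed)
    chi2, p = tajima_rrt(pooled.m_human, pooled.m_chimp)
    return {
        "category": name,
        "n_mirnas": len(members),
        "effective_length": pooled.effective_length,
        "subs_human": pooled.m_human,
        "subs_chimp": pooled.m_chimp,
        "rate_human": round_rate(boot.rate_human),
        "rate_chimp": round_rate(boot.rate_chimp),
        "sd_human": round_rate(boot.sd_human),
        "sd_chimp": round_rate(boot.sd_chimp),
        "rrt_chi2": chi2,
        "rrt_p": p,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in order and return the run report (also written
    as JSON/TSVs under ``config.outdir``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
    }

    # --- simulate -----------------------------------------------------------
    ds = simulate_triplets(config.simulation)
    report["n_simulated"] = len(ds.loci)
    if config.write_fixture_tree and "simulate" in config.stages:
        write_fixtures(ds, out / "fixtures")
    if config.stages == ("simulate",):
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report

    alignments = ds.alignments()
    funnel: dict[str, int] = {"input": len(ds.loci)}

    # --- curate -------------------------------------------------------------
    if "curate" in config.stages:
        fx = out / "fixtures"
        if not fx.exists():  # curation reads the standard formats, so emit them
            write_fixtures(ds, fx)
        blat = {sp: read_psl(fx / f"blat_{sp}.psl") for sp in ("chimp", "orang")}
        lifted = {sp: read_bed(fx / f"liftover_{sp}.bed") for sp in ("chimp", "orang")}
        by_query: dict[str, dict[str, list]] = {}
        for sp in ("chimp", "orang"):
            for h in blat[sp]:
                by_query.setdefault(h.query_id, {}).setdefault(sp, []).append(h)
        evidence_tally: dict[str, int] = {}
        calls = []
        rejections: dict[str, Rejection] = {}
        for l in ds.loci:
            best = {
                sp: select_best_blat_hit(by_query.get(l.locus_id, {}).get(sp, []))
                for sp in ("chimp", "orang")
            }
            lift = {sp: lifted[sp].get(l.locus_id) for sp in ("chimp", "orang")}
            call = resolve_orthology(l.locus_id, best, lift)
            if isinstance(call, Rejection):
                rejections[l.locus_id] = call
                continue
            call.human = l.interval
            evidence_tally[classify_evidence(call)] = evidence_tally.get(classify_evidence(call), 0) + 1
            calls.append(call)
        kept_calls, many = exclude_many_to_one(calls)
        for c in many:
            rejections[c.mirna_id] = Rejection("many_to_one")
        funnel["orthology"] = len(kept_calls)
        report["evidence_classes"] = evidence_tally

        surviving: dict = {}
        for c in kept_calls:
            res = trim_and_filter_alignment(alignments[c.mirna_id])
            if isinstance(res, Rejection):
                rejections[c.mirna_id] = res
            else:
                surviving[c.mirna_id] = res
        funnel["trim_filters"] = len(surviving)

        mfes = {f"{l.locus_id}|{sp}": l.mfe[sp] for l in ds.loci for sp in ("human", "chimp", "orang")}
        human_ref = [l.mfe["human"] for l in ds.loci]
        kept_aln, mfe_rej, threshold = mfe_filter(surviving, mfes, human_ref)
        rejections.update(mfe_rej)
        funnel["mfe"] = len(kept_aln)
        report["mfe_threshold"] = threshold
        report["funnel"] = funnel
        report["rejections"] = {k: v.reason for k, v in sorted(rejections.items())}
        alignments = kept_aln

    # --- classify -----------------------------------------------------------
    labels = ds.labels().loc[sorted(alignments.keys())]
    if "classify" in config.stages:
        fx = out / "fixtures"
        if fx.exists():
            mir_gff = read_gff3(fx / "mirnas.gff3", feature_types=("miRNA_primary_transcript",))
            intervals = gff_intervals(mir_gff)
            fam = read_family_file(fx / "mifam.dat")
            genes = read_gff3(fx / "genes.gff3")
            clu = assign_clusters({k: v for k, v in intervals.items() if k in alignments})
            cc = assign_copies_and_conservation(sorted(alignments.keys()), fam)
            ctx = pd.Series(
                {mid: assign_context(intervals[mid], genes) for mid in sorted(alignments.keys())},
                name="context",
            )
            labels = clu.join(cc).join(ctx).loc[sorted(alignments.keys())]
        labels.to_csv(out / "labels.tsv", sep="\t")
        table, p = category_contingency(labels, "copies", "clustered")
        report["copies_vs_clustered_fisher_p"] = p

    # --- rates --------------------------------------------------------------
    if "rates" in config.stages:
        summaries = {mid: orient_and_count(aln) for mid, aln in alignments.items()}
        per_mirna = rrt_batch(list(summaries.values()), alpha=config.rrt_alpha,
                              ids=list(summaries.keys()))
        per_mirna.to_csv(out / "per_mirna_rrt.tsv", sep="\t", index=False)
        report["bonferroni_threshold"] = per_mirna.attrs["bonferroni_threshold_display"]

        rows = []
        boots = {}
        for cons in sorted(labels["conservation"].unique()):
            ids = labels.index[labels["conservation"] == cons]
            sub = labels.loc[ids]
            members_all = [summaries[i] for i in ids]
            boots[cons] = bootstrap_category(members_all, B=config.bootstrap_B, seed=config.seed)
            rows.append(_category_row(cons, members_all, config.bootstrap_B, config.seed))
            for axis in ("clustered", "copies", "context"):
                for level in sorted(sub[axis].unique()):
                    members = [summaries[i] for i in ids[sub[axis] == level]]
                    if members:
                        rows.append(_category_row(f"{cons}/{axis}={level}", members,
                                                  config.bootstrap_B, config.seed))
        rate_table = pd.DataFrame(rows)
        rate_table.to_csv(out / "category_rates.tsv", sep="\t", index=False)
        report["category_rates"] = rate_table.to_dict(orient="records")
        if {"primate-specific", "ConFam"} <= set(boots):
            report["primate_vs_confam"] = compare_categories(
                boots["primate-specific"], boots["ConFam"], branch="human"
            )

    # --- composition --------------------------------------------------------
    if "composition" in config.stages:
        from .categories import concatenate_by_category

        concat = concatenate_by_category(alignments, labels["conservation"])
        comp = {}
        parts = {}
        for cons, aln in concat.items():
            parts[cons] = ws_partition(aln)
            pooled = parts[cons]["pooled"]
            comp[cons] = {
                "cpg_transitions": pooled.cpg_transitions,
                "non_cpg": pooled.non_cpg_substitutions,
                "n_WS": pooled.n_WS,
                "n_SW": pooled.n_SW,
                "ws_bias": pooled.ws_bias,
            }
        report["composition"] = comp
        if {"primate-specific", "ConFam"} <= set(parts):
            report["cpg_proportion_p"] = proportion_test(
                parts["primate-specific"]["pooled"], parts["ConFam"]["pooled"], "cpg_vs_noncpg"
            )

    # --- acceleration LRT ---------------------------------------------------
    if "lrt" in config.stages:
        from .categories import concatenate_by_category

        refs = simulate_neutral_refs(config.simulation, n=config.lrt_n_refs)
        ref_cat = refs[0]
        for r in refs[1:]:
            ref_cat = type(ref_cat)(
                ref_cat.human + r.human, ref_cat.chimp + r.chimp, ref_cat.orang + r.orang
            )
        branches = fit_reference(ref_cat)
        concat = concatenate_by_category(alignments, labels["conservation"])
        lrt_out = {}
        for cons, aln in sorted(concat.items()):
            res = lrt_acceleration(aln, branches, restarts=config.lrt_restarts, seed=config.seed)
            lrt_out[cons] = {"statistic": res.statistic, "p": res.p, "rho": res.rho}
        report["acceleration_lrt"] = lrt_out

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
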