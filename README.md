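# mirtrio

Comparative molecular-evolution analysis of human microRNAs against their
chimpanzee and orang-utan orthologs: how fast do miRNA hairpins accumulate
nucleotide substitutions on the human and chimpanzee branches, and do young,
primate-specific miRNAs evolve faster than families conserved beyond
primates?

The package is aimed at comparative genomicists who have (or want to
simulate) three-way precursor alignments and the surrounding annotation:
it reimplements, as a tested library plus CLI, the full analysis stack —
ortholog curation, category classification, outgroup-oriented substitution
counting, relative rate testing, composition-bias partitioning, an
acceleration likelihood-ratio test, and permutation-calibrated target
enrichment.

## The statistics at its core

**Outgroup-oriented substitution counting.** For each column of a
human/chimp/orang alignment the orang-utan allele orients ancestral and
derived states: if human ≠ chimp and orang equals exactly one of them, the
other species carries a branch-specific substitution. Columns containing a
gap or ambiguity code are excluded from the effective length *L*;
three-allele (multiallelic) columns cannot be oriented and are skipped. The
branch rate is *r* = *m*/*L* (substitutions per effective site).

**Tajima's relative rate test.** With branch counts *m₁*, *m₂*,

χ² = (*m₁* − *m₂*)² / (*m₁* + *m₂*),  1 df

tests rate equality on the two sister branches. Per-category confidence
intervals come from bootstrapping miRNAs within each category (B = 100,
pooled rate Σ*m*/Σ*L* per resample); two categories are called *different*
only when each observed rate falls outside the other's [2.5, 97.5]
percentile interval (reciprocal-tail rule).

**Composition bias.** Oriented changes are partitioned by CpG context
(C>T with conserved 3′ G, or G>A with conserved 5′ C) and by strong/weak
class; the GC-biased gene conversion index is
W>S bias = *n*<sub>W>S</sub> / (*n*<sub>W>S</sub> + *n*<sub>S>W</sub>).

**Acceleration LRT.** A Jukes–Cantor star-tree likelihood is fitted jointly
on a neutral reference (ancestral repeats or flanks) and a test region; the
null gives the test region one free rate scale, the alternative adds a
human-branch multiplier ρ ≥ 1. The statistic is referred to the 50:50
mixture of a point mass at zero and χ²(1) (boundary constraint).

**Permutation enrichment.** Per-term one-sided hypergeometric enrichment of
predicted-target genes, calibrated by 1,000 re-draws of random miRNA groups;
a term is significant only when its permuted p exceeds the observed p in
more than 99 % of permutations.

## Worked example

The synthetic generator produces triplet datasets with known branch rates
per conservation class, plus the PSL/BED/GFF3/family/MFE fixtures the
curation stage reads. A small end-to-end run:

```python
from mirtrio.pipeline import RunConfig, run_pipeline
from mirtrio.synthetic_data import SimulationConfig, CategoryParams

sim = SimulationConfig(seed=7, categories={
    "primate-specific": CategoryParams(n=200, rate_human=0.0056, rate_chimp=0.0066),
    "ConFam": CategoryParams(n=90, rate_human=0.0014, rate_chimp=0.0023,
                             conservation="ConFam", clustered_fraction=0.5,
                             multiple_fraction=0.6, genic_fraction=0.4),
})
report = run_pipeline(RunConfig(outdir="demo", seed=7, simulation=sim))
```

prints (via `report.json` / the category rate table):

```
funnel:   {'input': 290, 'orthology': 290, 'trim_filters': 290, 'mfe': 246}
evidence: {'blat+liftover': 273, 'blat_chimp_lo_orang': 15, 'blat_orang_lo_chimp': 2}
primate-specific  n=173  L=14025  subs 76/81   rate_human 0.0054 (0.0006)  rate_chimp 0.0058 (0.0006)  rrt_p 0.69
ConFam            n=73   L=5982   subs 11/12   rate_human 0.0018 (0.0005)  rate_chimp 0.002  (0.0007)  rrt_p 0.835
verdict: different
```

Reading: of 290 simulated loci, 246 survive the curation funnel (the MFE
filter removes the 5 % least-stable hairpins by construction). The
concatenated primate-specific human-branch rate (0.0054 ± 0.0006) recovers
the configured 0.0056 and is ~3× the ConFam rate (0.0018 ± 0.0005),
separated by the reciprocal-tail rule ("different"); within each category
the human and chimpanzee branches are statistically indistinguishable
(RRT p ≫ 0.05), as in the real data.

The same stages are available from the shell:

```bash
mirtrio simulate --seed 7 --out fixtures/
mirtrio run --seed 7 --out run/ --stages simulate,curate,classify,rates,composition,lrt
```

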