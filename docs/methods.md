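# Methods

This note documents the models, defaults and numerical choices behind
mirtrio, and what the synthetic experiments do and do not establish.

## Orientation and rate model

Substitutions are assigned to the human or chimpanzee branch by outgroup
parsimony: the orang-utan allele stands in for the human–chimp ancestor.
Columns with a gap or an ambiguity code in any row are removed from the
effective length; a column with three distinct alleles is recorded as
multiallelic and excluded from branch counts, and a column where human and
chimp agree but orang differs is an orang-branch/ancestral change, tallied
only as a diagnostic. No multiple-hit correction is applied: at the
divergences involved (≤ ~2 % per branch) the expected bias of the plain
count is second-order (≈ *r*² per site) and far below the sampling error of
any category in the data regime analysed. A consequence worth knowing: when
two branches hit the same site the column becomes multiallelic and both
events are lost, so oriented counts underestimate true branch rates by a
factor of roughly (1 − *r*₍other branches₎) — about 2 % of the rate for
primate-specific loci, well under half a bootstrap standard error at
category sizes, but visible in very large simulations.

Rates are reported rounded half-up to 4 decimals (as in the published
tables) while all arithmetic is done at full precision.

Tajima's relative rate test is used in its chi-square form,
(*m₁* − *m₂*)²/(*m₁* + *m₂*) on 1 df, with (0, 0) defined as χ² = 0, p = 1.
An exact two-sided binomial form (null: events split 1:1) is available as
`tajima_rrt_binomial` for small counts, where the chi-square approximation
is conservative.

Category uncertainty comes from resampling miRNAs within the category
(B = 100 by default) and recomputing the pooled rate Σ*m*/Σ*L* — the pooled
form, not the mean of per-miRNA rates, so long loci carry proportional
weight. Two categories are declared different only under the reciprocal
2.5/97.5-percentile rule; this is intentionally stricter than a two-sample
test and matches the published comparison procedure.

## Curation thresholds

All funnel thresholds are named constants with the published defaults:
BLAT hits below 80 % query coverage are discarded and survivors ranked by
matched length then identity (ties broken deterministically by target
coordinate and flagged ambiguous); overlapping BLAT and liftOver intervals
merge to their leftmost/rightmost span, discordant ones drop the call;
many-to-one orthology is operationalised as ≥ 50 % reciprocal overlap (the
source text gives no number; this is the standard convention); non-human
rows must cover ≥ 80 % of the human precursor; internal human-row gaps
> 20 nt reject the alignment; the MFE filter removes triplets in which any
sequence folds less stably than the 95th percentile (linear interpolation)
of the human reference distribution; flanks target 40 bp per side from a
100 bp extraction and require ≥ 50 % of the 80 bp aligned; ancestral
repeats must survive reciprocal liftOver, lift to the same chromosome, and
fall in the 70–91 bp human-miRNA interquartile length range.

The triplet re-aligner used for fixtures is a progressive
Needleman–Wunsch (match 1, mismatch −1, gap −2) anchored on the human row;
production alignments from an external aligner can be supplied instead —
the filters, not the aligner, are the analysis.

Copy-number counts human paralogs: a miRNA is multiple-copy when its family
contains two or more members from its own species. (Counting members across
species would make every beyond-primate family multiple-copy by
definition, contradicting the published category sizes.)

## Acceleration LRT

The published analysis ran an external phylogenetic likelihood package; here
the test is re-derived under the simplest calibratable model: Jukes–Cantor
on the unrooted three-taxon star tree, with the five observable column
classes (invariant; human-, chimp-, orang-differs; all distinct) as
sufficient statistics. The null scales all reference branch lengths by one
free factor for the test region; the alternative adds a human-branch
multiplier ρ ≥ 1 (acceleration only, one-sided, following the promoter-scan
design the original analysis cites). Because ρ = 1 lies on the boundary,
p-values use the 50:50 mixture of a point mass at zero and χ²(1).

Two fitting modes exist. The default for inference passes the reference
alignment into the likelihood (`ref=`), so reference branch lengths are
re-estimated under both hypotheses and their sampling noise propagates into
the statistic — simulations at L = 5,000/10,000 show this form holds its
size (≈ 5 % rejections at nominal 0.05). Conditioning instead on
point-estimated branch lengths (no `ref`) is faster but anti-conservative
(≈ 9 % at the same sizes) and is kept for exploratory ranking only.
Optimisation is L-BFGS-B with jittered restarts keeping the best
likelihood; restarts and the number of reference draws default to 100 each,
and the median p over reference draws is the reported summary.

## Synthetic data generator

The generator emulates the study's data regime; its defaults are the
conditions every calibration experiment runs under:

- **Categories**: 800 primate-specific loci (human branch 0.0056, chimp
  0.0066 substitutions/site) and 370 ConFam loci (0.0014 / 0.0023), the
  published category rates and sizes; hairpin lengths uniform on 70–91 bp
  with 40 bp flanks at ancestral-repeat-like neutral rates (0.0053 /
  0.0059).
- **Outgroup branch**: 3× the human rate, approximating the
  ancestor-to-orang path length relative to the human tip branch over
  primate divergence times. The emitted orang row is the ancestor plus its
  own branch noise, so multiallelic columns and orientation losses arise as
  they do in real data.
- **CpG hypermutability**: sites inside an ancestral CpG dinucleotide
  mutate at `cpg_multiplier` (default 10, the field-standard transition
  excess) times the base rate, the excess being deamination transitions
  (C>T / G>A). Per-branch rates are renormalised over the realised CpG
  content so the configured value is the *mean* per-site rate.
- **Fixation bias**: non-deamination changes are drawn weak-to-strong with
  probability `ws_bias` (default 0.39, the bias regime reported for the
  human branch). Note the realised pooled W>S fraction is lower whenever
  CpG deamination is active, since that mass is S>W by construction; the
  estimator-recovery experiment therefore runs with the multiplier at 1 to
  isolate the mechanism.
- **Evidence classes**: orthology-evidence fixtures follow the published
  class proportions (93.8 % BLAT+liftOver in both species, 5.3 % / 0.6 %
  asymmetric, 0.3 % liftOver-only).
- Substitutions are independent per-site Bernoulli events (no within-branch
  multiple hits) — adequate below ~2 % divergence and matched to the
  counting estimator under test.

What the generator does **not** emulate: hairpin thermodynamics (MFEs are
drawn from N(−37.9, 8²) rather than folded), indel processes (gap/coverage
violations are injected synthetically for filter tests), context
dependence beyond CpG, selection heterogeneity within a category, and
assembly artefacts. Passing tests therefore demonstrate that the
*statistics* behave as claimed under the stated generative model, not that
the biological conclusions transfer to any particular genome build.

## Calibration experiment sizes

The validation suite and `scripts/acceptance.py` use: 20 replicate datasets
for rate recovery/separation (full 800 + 370 design); 2,000 equal-rate
categories of 50 loci (branch counts ≈ 21) for the relative rate test's
type-I error; 200 replicates at test length 5,000 / reference length
10,000, neutral rates (0.005, 0.005, 0.015), for LRT size and 5×
acceleration power (3 optimizer restarts — the two-to-five-parameter
surfaces are well behaved, and more restarts do not change the best
likelihood at these sizes); ≥ 10,000 oriented changes for the W>S
estimator; and 5 null draws × 1,000 permutations × 100 terms for the
enrichment false-positive rate. These sizes keep each experiment in the
seconds-to-a-minute range on one CPU while leaving binomial noise well
inside the asserted tolerances.

## Degenerate inputs and tie-breaks

Zero effective length makes a rate undefined (explicit error; such loci are
excluded from aggregates). Contingency tables with an empty margin return
p = 1 with a warning rather than failing. Equal-score BLAT hits resolve by
(target name, start) so results are independent of input order. Bootstrap
and permutation procedures take explicit seeds and are bit-reproducible;
the pipeline report embeds its seed and version and reruns byte-identically.

## Known limitations

Orientation bias at high outgroup divergence (see above); the JC model
ignores transition/transversion asymmetry and base composition (an HKY
extension would slot into the same class-probability interface but needs
more than five pattern classes); per-type substitution rates are normalised
per ancestral-base opportunity, one of several defensible conventions; GO
term relationships are not propagated (the gene→term map is taken as
given); and the curation stage trusts externally supplied MFEs and
alignments rather than recomputing them.
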