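# Methods

`recvar` implements the variant-prioritization workflow used to find
recessive causes of a rare phenotype (the motivating case is renal
hypouricemia) in a small exome-sequenced case series with a healthy control
panel and no pedigrees. This note documents the models, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical and design decisions that were genuinely open.

## Prevalence-derived frequency threshold

Under Hardy–Weinberg equilibrium with full penetrance, an autosomal-recessive
disease of prevalence *P* implies a pathogenic allele frequency
*q* = √*P*: affected individuals are the *q*² homozygotes. The threshold
module computes *q* from an affected count over a screened cohort size and
rounds it half-even to a configurable number of decimals (default 2). With a
prevalence of 31/179,318 this gives *q* ≈ 0.0131, i.e. a 1% exclusion
threshold. Both the raw *q* and the rounded threshold are reported so the
rounding policy is auditable; no carrier correction or compound-het
inflation term is applied — the model is deliberately the simplest one a
point prevalence supports, and a single autosomal threshold is used for X
variants as well.

## Filtering funnel

Three per-variant predicates, applied in a fixed order with per-stage counts
recorded:

1. **Population frequency.** A variant is removed iff the *maximum* allele
   frequency over the consulted databases (default keys: dbSNP, 1000G,
   gnomAD) is strictly greater than the threshold. The max-over-databases
   rule is the conservative conjunctive reading of "not common in any
   reference panel". Variants absent from every consulted database pass by
   default (`missing_af_passes`): novel variants must survive. Global AFs
   are assumed; the database keys are configurable so population-specific
   columns can be supplied instead.
2. **Control exclusion.** A variant is removed iff some control carries it
   homozygous-alt, or — on X, for a male control outside any configured
   pseudoautosomal interval — carries any alt allele. Heterozygous controls
   never remove a variant: under a recessive model they are healthy
   carriers, and the expected carrier frequency at *q* ≈ 0.01 in a 46-person
   panel is ~1, so het-exclusion would throw away true candidates.
3. **Consequence selection.** Exactly the variants whose class is in the
   allowed set (default: missense, stop gained/lost, start lost, frameshift,
   in-frame indel, splice site — i.e. non-synonymous, indel or splice
   changes) are retained. Annotator terms are mapped onto this closed
   vocabulary with a strict unknown→`other` rule.

Because each stage is a pure per-variant predicate, the final surviving set
is invariant under stage permutation; the funnel (which is order-dependent
in its intermediate counts) is asserted monotone on every run, and a
post-hoc check re-verifies that no survivor is hom/hemizygous in a control.
No quality-based (DP/GQ) filtering is performed.

## Genotype conventions

Multiallelic records are decomposed into one biallelic record per alternate
allele; in a decomposed record a genotype allele equal to a *different* alt
is recoded as ref, which matches common decompose-then-filter practice and
keeps the recessive logic per-alt. Half-calls (`./1`) are normalized to
fully missing — the conservative choice for candidate calling. A male
heterozygous call on X (a coding artifact on a single-copy chromosome) is
treated as hemizygous-alt everywhere; pseudoautosomal intervals can be
configured to exempt regions from this recoding (default: none, matching
the simulator's output).

## Inheritance models

Per case sample and gene, from filter survivors only:

- male X, alt-carrying → **hemizygous** candidate;
- otherwise hom-alt → **homozygous** candidate;
- otherwise ≥ 2 hets in the gene → **putative compound heterozygote**.

Compound-het calling is phase-unaware: without parental genotypes a cis
configuration cannot be excluded, so any two hets in a gene qualify and the
call is labelled putative. A gene with a homozygous candidate does not also
contribute its hets to a compound het — the homozygous site alone satisfies
the model. One candidate is emitted per (sample, gene, model) listing all
supporting variants; a single unpartnered het yields nothing; controls are
never evaluated; female X is treated autosomally. Variants with an empty
gene label cannot be grouped and are logged and skipped. Dominant, de novo
and mitochondrial models are out of scope, as is any pathogenicity
re-scoring (predictor scores pass through to the report untouched).

## Kinship

Relatedness between cases is estimated with the heterozygote-concordance
(KING-robust-style) estimator

φ̂ = (N_het,het − 2·N_IBS0) / (N_het(i) + N_het(j)),

over autosomal, pairwise-complete sites with no MAF floor. This estimator
needs no allele-frequency estimates, which is what makes it usable on a
7-case series. Expected values: 0.5 for duplicates/MZ, 0.25 for
parent–offspring and full siblings, ≈ 0 for unrelated pairs; an estimate
near zero for two carriers of a shared candidate supports independent
observations rather than cryptic relatedness. When the denominator is zero
the estimator raises an explicit undefined-result error rather than
returning 0; the pipeline records such pairs as NaN. Kinship runs on all
read variants, not just filter survivors — relatedness wants many sites.
The audit counts (sites used, both-het, opposite-homozygote, per-sample
hets) are reported with every estimate.

## Synthetic cohorts

The simulator emulates the statistical structure the pipeline assumes, not
raw sequencing: a 7-case / 46-control cohort, background variants drawn
under HWE at each site's true AF, sex-aware X dosage (males draw a single
allele, emitted hom-coded), database annotations equal to the true AF, and
planted causal genotypes recorded in a truth ledger.

Defaults, chosen once as exome-realistic: 20,000 background variants; an
AF spectrum mixing common (Uniform(0.05, 0.5)), low (Uniform(0.001, 0.05))
and rare (Uniform(10⁻⁶, 0.001)) components with weights 0.2/0.3/0.5 — a
rare-heavy spectrum, as in real exomes; 5% of variants on X; a
missense-heavy consequence mix with ~40% synonymous sites; one gene per ~10
consecutive variants, enough density to create incidental single hets but
few incidental compound hets (incidental candidates are allowed and
measured, never forbidden). Database entries for very rare sites
(AF < 10⁻⁴) are dropped with probability 0.5 so the missing-AF-passes rule
is exercised the way a novel variant would exercise it. Sample sexes
alternate deterministically (CASE01 male, CASE02 female, …) so plants can
target males on X without consuming randomness.

The default plant set mirrors the structure of a compound-het discovery
plus a candidate-gene tail: one compound het (two rare missense hets,
AF 2.2×10⁻⁵, in one gene of the first case), eight homozygous genes spread
over the remaining six cases, and four X-hemizygous genes on the male
cases, one of which is carried by two different cases (AF 5×10⁻⁴ for
hom/hemi plants). Planted positions sit above 2.1×10⁸, past the background
range, so keys never collide.

Randomness follows a strict substream contract: one root seed, with
variants, genotypes and plants drawn from separately spawned generators, so
adding a plant leaves the background byte-identical. The same config and
seed reproduce the VCF byte for byte. Related pairs for kinship testing are
produced by gamete dropping (parent–offspring: one transmitted gamete;
siblings: one gamete from each of two simulated parents). Not modelled:
sequencing error, depth, genotyping error, linkage disequilibrium, and
population structure — so passing recovery tests demonstrate the logic of
the pipeline, not robustness to noisy real-world genotypes or stratified
panels.

## Reporting

The report bundle (funnel, candidates with pass-through scores, per-gene
summary with distinct-case counts, kinship matrix, JSON summary echoing the
config and seed) is deterministic: regenerating from the same inputs is
byte-identical. Group demographics are pooled as n-weighted means rounded
half-even (default 1 decimal); pooled standard deviations are deliberately
not computed, because reconstructing them from printed group means and SDs
requires the exact within-group sums and anything else would fabricate a
statistic. Unrounded pooling is exactly associative and is exposed via
`decimals=None`.

## Problem sizes used in the test suite

The suite exercises the full pipeline on the default 20,000-variant cohort
(seed 42, ~10 s end to end), verifies the candidate caller against a
brute-force rule enumerator on 1,000 random ≤10-sample × ≤50-variant
cohorts, checks kinship recovery on 50,000-site gamete-dropping simulations
(10 replicates per relationship), and funnel invariants on 200 random
cohorts. These sizes give Monte-Carlo tolerances of ±0.05 on first-degree
kinship and |φ̂| < 0.02 for unrelated pairs.

## Known limitations

- Compound-het calls are phase-unaware by design; a cis pair of hets is a
  false positive this pipeline cannot remove without parental data.
- The prevalence→threshold model ignores locus and allelic heterogeneity;
  with many causal alleles per gene the per-allele threshold should be
  lower than √P.
- The control-exclusion rule treats indels and SNVs identically.
- The simulator's AF annotations are noise-free (database AF = true AF), so
  filter behavior on discrepant database frequencies is not exercised.
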