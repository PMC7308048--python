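# Methods

## The discovery model

The pipeline targets the standard design for mapping genes of a dominantly
inherited binary trait in multiplex families: probands and relatives are
exome-sequenced, variants are filtered to rare, function-altering,
case-specific candidates, candidates are checked for co-segregation under
an autosomal dominant model, and genes are tested for rare-variant burden
against a reference population. The unit of inference is the gene, not the
variant: different families may carry different variants in the same gene.

All variants are treated as autosomal and biallelic (multiallelic VCF
records are split on read; a genotype whose only alternate allele belongs
to a *different* split key is recoded to missing rather than reference, so
splitting never fabricates reference calls). Coordinates are 1-based, as
in VCF.

## Filter cascade

Variant-level filters are pure predicates evaluated in a fixed canonical
order (QC → consequence → MAF → case-control), so the surviving set is
order-independent and only the audit labels depend on the order; the
gene-level multiple-family rule runs last. Defaults:

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.025 | strict `<` on the maximum MAF across databases; absent everywhere = novel, passes |
| `qc_thresholds` | `{}` | per-field minima; absent QC fields pass (upstream variant-quality recalibration is assumed) |
| `max_unaffected_controls_with_variant` | 1 | "more than 1 unaffected control" removes |
| `min_probands_per_gene` | 2 | "more than 1 proband" retains; probands, not variants, are the unit |
| `consensus_k`/`consensus_n` | 3 / 5 | deleteriousness consensus; annotate-only by default |

The consensus filter defaults to annotate-only because a variant that
looks benign in silico can still be a strong candidate on rarity and
segregation grounds; `consensus_removes` turns it into a removing filter.
"Biological relevance" filtering is an optional user-supplied gene
whitelist, disabled by default, since no computable rule exists for it.
Whether the MAF rule should apply per-database or to the maximum across
databases is not determined by the design; the default is the maximum
(`all_dbs` is accepted as an alias — for an upper threshold the two are
equivalent).

## Segregation

Strict mode requires the genotyped carrier set to coincide with the
genotyped affected set (restricted to known-status members);
`allow_nonpenetrance` tolerates unaffected carriers and is provided
because dominant traits of this kind often show incomplete penetrance.
Members with unknown phenotype or missing genotype never trigger
violations and do not count toward informativeness; a family with fewer
than two genotyped affected members is uninformative (the informativeness
threshold is a package choice). Verdicts are invariant to member order
and sample relabeling, and depend only on statuses and genotypes — never
on the pedigree topology — which is why the exhaustive truth-table tests
can enumerate flat families.

## Burden testing

The default burden unit is carriers: a gene's cohort count is the number
of probands carrying ≥ 1 qualifying variant, compared with per-gene
carrier counts in the reference population. The alleles unit uses
carrier chromosomes out of 2 × n_probands, with each proband contributing
its maximum single-variant dosage (so compound-het and multi-site carriers
are not double-counted against a per-gene denominator).

Fisher's exact test is computed from the conditional hypergeometric
distribution of the top-left cell given the margins. Point probabilities
are evaluated in log space with the log-gamma function and summed with
compensated summation after rescaling by the maximum, which keeps the tail
accurate to ~1e-13 relative error (validated against exact rational
enumeration). The two-sided p sums all tables whose point probability is
at most the observed one within relative tolerance 1e-7 (the tie slack
absorbs floating-point noise at ties); the default sidedness is one-sided
enrichment, matching the directional hypothesis. The odds ratio is
(a·d)/(b·c), infinite when only the denominator vanishes and undefined for
0/0.

Multiple testing defaults to Bonferroni over the genes that survive the
cascade; Benjamini-Hochberg and no adjustment are available. Ranking is
deterministic: adjusted p, then co-segregating family count, then gene
symbol.

Because the test is exact and the counts are small (tens of carrier
probands at most), the null distribution of p is discrete and
super-uniform: the realized type-I error at α = 0.05 is *below* 0.05
(≈ 0.02–0.03 under the default synthetic conditions). This is the correct,
conservative behaviour of an exact conditional test, not a defect; the
test suite asserts that the null rejection rate never exceeds the nominal
level.

## Assay statistics

One-phase decay fits minimize squared error in
`y(t) = plateau + (y0 − plateau)·exp(−K·t)` with K ≥ 0. The default fixes
y0 = 100 and plateau = 0, matching the percent-of-t0 normalization of a
cycloheximide chase; both parameters can be freed (whether a plateau
should be estimated from 12-hour chases is genuinely open, so both modes
exist). For fixed K the remaining parameters are linear and solved in
closed form, so the fit reduces to a deterministic one-dimensional search:
a log-spaced grid over K ∈ [1e-4, 50]/h followed by bounded refinement to
an absolute tolerance of 1e-12 — no starting-point or seed dependence, and
noiseless curves are recovered to better than 1e-6 relative error. A flat
curve yields K = 0 with an infinite half-life, flagged by the value rather
than an error.

The extra sum-of-squares F test compares the shared-K fit of two curves
(other parameters per-curve) with separate-K fits:
`F = ((RSS₀ − RSS₁)/df_num) / (RSS₁/df_den)`, df_num = 1,
df_den = n_total − p_alt. The separate-model RSS is guarded to never
exceed the shared optimum evaluated per curve, so F ≥ 0 holds exactly.
The null calibration study draws measurement noise at *every* timepoint,
including t = 0, around a true y0 of 100: with the fixed-y0 model this is
the correctly specified setting for the textbook degrees-of-freedom
convention, and the measured null rejection rate at α = 0.05 is ≈ 0.045.
(If instead the t = 0 point is normalized to exactly 100 and carries no
noise, counting it in df_den overstates the residual degrees of freedom
and inflates the rejection rate — a caveat for analyzing pre-normalized
curves with few timepoints.)

Reporter normalization divides firefly by Renilla per well and scales the
reference condition's mean ratio to 1; flow-cytometry surface expression
is the ratio of median fluorescence intensities, with a percent-of-WT
helper.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the motivating study design:

| parameter | default | rationale |
|---|---|---|
| `n_families` | 67 | probands in the discovery cohort |
| `family_size_range` / `generations` | 4–12 / 3 | multigenerational multiplex families |
| `n_causal_families` / `n_causal_variants` | 6 / 3 | causal gene present in 6 families through 3 distinct rare missense variants |
| `causal_maf_in_reference` | 1e-4 | very rare in the reference population |
| `penetrance` | 1.0 | pedigrees consistent with full penetrance |
| `background_genes` | 200 | background gene set for multiple-testing structure |
| `background_sites_per_gene` | 8–30 | typical exome site counts per gene in a small cohort |
| `common_site_fraction` | 0.25 | mixture weight of common (MAF 0.1–0.5, uniform) vs rare (MAF 1e-4–0.025, log-uniform) sites |
| `fraction_functional` | 0.3 | share of sites with function-altering consequences |
| `reference_population_n` | 3000 | reference individuals behind the per-gene count table |
| `controls_per_family` | 1 | sequenced unaffected relatives per family (the study sequenced roughly one for every two families) |

Every family segregates a fully penetrant dominant trait allele introduced
through one founder — in causal families that allele *is* a causal-gene
variant; elsewhere it is latent (its gene is not among the simulated
variants), so the simulated trait has a genetic architecture the analysis
can only partially resolve, as a real discovery cohort does. Transmission
is Mendelian (fair-coin allele sampling parents-before-children; audited
to zero violations), founders draw background genotypes at Hardy-Weinberg
from the generating MAFs, and families are ascertained to at least two
affected members, mirroring the selection of informative multiplex
families. That ascertainment conditions the affected:carrier ratio
slightly above the raw penetrance (≈ 0.83 at penetrance 0.8); the tests
compare against an independent oracle simulation of the same contract
rather than the unconditional value.

The per-gene reference table is drawn binomially over each gene's
qualifying sites (function-altering, generating MAF < 2.5% — the same
definition of "rare deleterious" the cohort analysis applies, emulating a
per-gene browser query); carrier counts use the exact per-gene carrier
frequency. An extra column records the generating carrier frequency so
tests can separate sampling noise from defects. Negative-control knobs
plant the causal variants into sequenced unaffected controls
(`planted_control_carriers`) or reduce the causal families to one, which
must eliminate the gene via the case-control and multiple-family rules
respectively.

What the generator does **not** emulate: linkage disequilibrium between
sites, population structure or relatedness across families, genotyping
error and missingness, annotation disagreement between databases, and
sequence-level realism (no reads, no reference genome). Passing tests
therefore demonstrate the correctness and calibration of the pipeline's
logic and statistics under the stated generative model, not robustness to
those real-data complications.

## Problem sizes used by the validation studies

Oracle-equivalence checks run exhaustively over all 2×2 tables with total
≤ 20 plus 2000 random tables with total ≤ 200 (tolerance 1e-10 relative);
all genotype/status assignments for families of 3–5 members in both
segregation modes; and 100 randomized filter fixtures of up to 200
variants. Decay recovery uses 25 decay constants spanning 0.01–1.0/h
noiselessly and 500 noisy replicates (σ = 5 percent-points at 5
timepoints); the F-test calibration uses 2000 null pairs; the burden
calibration uses 20 null cohorts (~4000 gene tests); end-to-end recovery
uses 100 independent seeds at the default conditions and 30 seeds per
negative control. The acceptance script reports the same quantities at
reduced replicate counts (30 recovery seeds, 1000 F-test pairs, 5 null
cohorts).
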