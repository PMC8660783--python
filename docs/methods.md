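# Methods

`panelburden` implements a population-based gene-panel analysis of breast
cancer risk as a reusable, tested pipeline: harmonised variant QC across
three sequencing platforms, rule-based pathogenicity classification,
carrier tabulation with subject-level exclusions, and per-gene adjusted
odds-ratio estimation. A synthetic-study generator provides complete
inputs with known ground truth, so every stage can be validated end to
end.

## Study design being modelled

Two sources of subjects: a population-based case-control study of women
with breast cancer (cases enriched for early onset, median age at
diagnosis ~40, plus age-matched unaffected controls), and a large cohort
of healthy elderly women (enrolment age ≥ 70, median ~74) used as
"super-controls". The elderly controls are valuable for rare-variant
frequencies but are *not* exchangeable with young controls: a woman who
carries a high-penetrance allele is less likely to reach age 74 without a
breast cancer diagnosis, so elderly cancer-free controls are depleted of
risk alleles. Crude odds ratios computed against them are biased away
from the null; age-adjusted odds ratios correct this, which is the
central statistical point the package demonstrates on synthetic data.

## Variant QC and harmonisation (`panelburden.qc`)

Calls from the three panels (Hi-Plex, HaloPlexHS, AmpliSeq) pass through a
fixed-order pipeline:

1. **Platform QC** — per-platform minimum read depth and variant allele
   fraction, both inclusive: ≥ 50× and ≥ 0.20 for Hi-Plex and AmpliSeq,
   ≥ 30× and ≥ 0.15 for HaloPlexHS. Inclusive boundaries are a design
   choice (the thresholds are quoted without an inequality direction);
   they are configurable per platform.
2. **Region restriction** — calls are kept only inside the intersection
   of the three panels' merged target regions. Coordinates are 0-based
   half-open internally; VCF positions convert at the read boundary.
3. **Caller intersection** — for cohorts genotyped by two callers, a
   subject's key set is intersected with the second caller's keys.
4. **Cohort-frequency filter** — variants carried by *more than* a set
   fraction (default 0.05%) of the scoped cohort's participants are
   treated as platform artefacts or too common to drive rare-variant
   risk. Removal is strict ("more than"), so a variant at exactly the
   threshold survives. The implied integer carrier cap is logged because
   fraction × cohort size is what actually bites.
5. **Locus call-rate filter** — variant sites where fewer than 95% of the
   scoped cohort's genotype calls passed QC are removed entirely.
   Variant calls alone cannot see QC failures in reference genotypes, so
   the pipeline accepts an optional per-locus coverage sidecar of QC pass
   fractions which overrides the call-derived rates; without it, the rate
   is the pass fraction among variant calls at the site.

Filters 4–5 apply only to a configurable cohort scope (default: the
elderly arm, which was sequenced on its own platform). Every step is a
pure subset operation and writes an attrition record `(step, n_in,
n_out)`; the tests audit these counts one-to-one against planted
artefacts.

## Pathogenicity classification (`panelburden.classify`)

Variants are first checked for rarity: reference-population minor allele
frequency ≤ 0.01 (inclusive), with variants absent from the reference
table counted as rare (unobserved ⇒ below threshold).

Consequences are called on one transcript per gene (CDS exon structure +
spliced coding sequence): SNVs and equal-length substitutions by swapping
the affected bases into the coding sequence and comparing the spanned
codons (strand-aware); indels by the length-difference mod-3 rule
(frameshift vs in-frame); intronic positions within ±2 bases of an
internal coding-exon junction are canonical splice variants, attributed
to the downstream exon in transcription order. Anything else is `other`,
never an exception. A protein-truncating variant (PTV) is a stop-gained,
frameshift or canonical-splice call.

The decision cascade (first match wins):

1. not rare → `not_rare`;
2. ClinVar Pathogenic / Likely Pathogenic → pathogenic (`clinvar_plp`),
   regardless of exon position — an expert-curated call outranks the
   positional heuristic below;
3. ClinVar Benign / Likely Benign → `clinvar_benign`, even for PTVs;
4. PTV + Conflicting leaning pathogenic → pathogenic (`conflicting_ptv`);
5. PTV absent from ClinVar, not in the last coding exon → pathogenic
   (`novel_ptv`);
6. PTV absent, last coding exon → `last_exon_ptv_excluded` (truncations
   there are assumed to escape nonsense-mediated decay);
7. otherwise `non_truncating_unclassified`.

"Leaning pathogenic" for Conflicting records is operationalised as ≥ 1
P/LP submission *and* strictly more P/LP than B/LB submissions — the
minimal rule that admits the canonical recurrent CHEK2 frameshift without
hand-curation; both constants are configurable. NMD-escape refinements
(e.g. the last 50 bp of the penultimate exon) are deliberately not
implemented.

## Carriers and exclusions (`panelburden.carriers`)

Subject-level exclusions run in a fixed order, each subject removed by
exactly one rule, all recorded in a ledger: males; elderly-cohort women
with a prior breast cancer diagnosis; subjects without panel data; women
with pathogenic variants in two or more genes (main analysis only — a
sensitivity mode re-admits them, counting each as a carrier of every gene
she carries). MUTYH is treated as recessive: carrier status requires two
or more *distinct* pathogenic MUTYH variants (a bi-allelic proxy, since
phase is unknowable from calls); mono-allelic carriers are demoted to
non-carriers but logged, and they do not count toward the multi-gene
rule.

Descriptive summaries report per-arm carrier counts and percentages
(denominator = arm size, rounded half-up to one decimal, matching the
printed style), any-gene and non-BRCA1/2 carriers, and covariate
medians/IQRs. Carrier-group comparisons use Welch's t-test for
continuous variables (with group means and 95% t-intervals) and a
chi-square test for binary ones, switching to Fisher's exact test when
any expected cell count is below 5.

## Association models (`panelburden.association`)

For each gene, an unconditional logistic regression of case status on the
carrier indicator plus an adjustment set: none, age only, or the six
study covariates (age, height, BMI, parity, education years, alcoholic
drinks/week). Age enters as a continuous linear term. Carriers of
*other* genes remain in the unexposed pool (harmless in the main analysis
because multi-gene carriers are excluded upstream). Complete-case
filtering is per model: rows are dropped only for missing covariates of
that adjustment set, and the reduced model of the likelihood-ratio test
is refit on exactly the same rows.

* OR = exp(carrier coefficient) from the ML fit (statsmodels `Logit`,
  Newton with a BFGS fallback).
* 95% CI = Wald, exp(β ± 1.96·SE). No profile or exact intervals, and no
  Firth penalisation — sparse genes produce honest, very wide Wald
  intervals rather than shrunken ones.
* p-value = two-sided likelihood-ratio test of the carrier term, 1 df.
  No multiple-testing correction (raw p against 0.05).
* Estimability: a model is fit only when at least one carrier is present
  among cases *and* among controls; otherwise the gene is reported as
  non-estimable ("–" in the output table). Perfect or quasi-separation
  (non-convergence, or |β| > 30) is flagged and reported non-estimable.

ER-subtype analyses treat ER-positive and ER-negative disease as separate
outcomes: cases are restricted to the subtype (ER-unknown cases dropped),
all controls retained. The variant-split analysis partitions one gene's
carriers into a designated variant vs all its other pathogenic variants
(carriers of both go to the designated stratum), fits both indicators
jointly, and tests coefficient equality with a 1-df LRT against the
common-coefficient model. Sensitivity modes: exclude the elderly arm
entirely, or re-admit multi-gene carriers.

## Synthetic-data generator (`panelburden.simulate`)

The generator samples from a single mechanistic disease model rather than
painting target summaries on:

* per-gene carrier states ~ Bernoulli(f_g), independent across genes;
* P(affected by age a) = logistic(α + β_age·a + Σ β_g·carrier_g), with
  α = −5.5 and β_age = 0.04/yr by default, giving a baseline cumulative
  risk of ≈ 2% at 40 and ≈ 7% at 74 — the right order for breast cancer;
* cases drawn from affected women with a soft early-onset weighting
  (full weight to age 50, exponentially decaying beyond, scale 8 yr);
  age-matched controls from unaffected women of the same age
  distribution; elderly controls from women unaffected at ages ≥ 70
  (truncated normal, median 74, IQR 5.8).

Carrier depletion among elderly controls *emerges* from this mechanism.
Default arm sizes (1464 / 862 / 6549), covariate distributions
(medians/IQRs per arm), parity missingness (4.3% in the elderly arm,
0.5% for other covariates) and per-gene carrier frequencies/true ORs
follow the study design being emulated; the defaults live in
`DEFAULT_CARRIER_FREQ` and `DEFAULT_TRUE_OR`. An optional two-disease
mode gives genes ER-subtype-specific effects.

The sequencing layer assigns each true carrier a **private** variant
(unique site drawn from per-gene pools of frameshift and missense sites,
with a matching ClinVar-style record where the category requires one),
mimicking the allelic heterogeneity of real truncating-variant spectra —
necessary so that genuinely pathogenic variants never recur often enough
to look like cohort-level artefacts. One deliberately recurrent variant
(a conflicting-classification CHEK2 frameshift) is shared, with its
elderly-arm carrier count capped below the cohort-frequency threshold.

Planted artefacts, each targeted by exactly one rule: a recurrent variant
at 0.2% cohort frequency (cohort-frequency filter), a depth-49 Hi-Plex
call (platform QC), a variant at a locus with a 94% coverage QC rate
(call-rate filter, via the coverage sidecar), off-target calls (region
restriction), primary-caller-only calls in the elderly arm (caller
intersection), last-exon and ClinVar-benign PTVs and a MAF-0.02 variant
(classifier), mono-allelic MUTYH carriers (demotion), one multi-gene
carrier (exclusion), spiked males and prior-breast-cancer elderly women
(subject rules).

Toy transcripts are 3-exon, 300-bp-CDS genes (one per synthetic
chromosome, every third gene on the minus strand) with planted codons so
all consequence classes are reachable; file emission writes per-subject
VCF 4.2, three BED3 panels whose intersection is a strict subset of each,
transcript/classification/frequency TSVs, a phenotype CSV, the coverage
sidecar and a ground-truth TSV for test harnesses. Identical seeds give
byte-identical bundles.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: haplotype/LD structure and phasing, real
variant spectra or hotspots, multi-transcript genes and splice isoforms,
population stratification, covariate–disease confounding beyond age
(covariates other than age are drawn independently of disease), caller
error modes beyond the planted artefact classes, and genotype-level
missingness.

## Validation studies and problem sizes

`or_recovery_study` simulates 100 replicates of a 1500-case / 850
age-matched / 6500 elderly-control design with true ORs 5 / 4 / 3.5 / 1
at carrier frequencies 0.002–0.006 and refits each gene unadjusted,
age-adjusted, and age-adjusted without the elderly arm. The package's
acceptance checks assert: age-adjusted 95% CI coverage ≥ 90% per gene;
significant upward bias of the crude OR for the strongest gene; CI
overlap between the no-elderly sensitivity fit and the full-cohort
adjusted fit in ≥ 90% of replicates. `type_one_error_study` runs 1000
small replicates (400/300/300, null gene at 5% carrier frequency) and
checks the LRT rejection rate at p < 0.05 against exact binomial 99%
bounds. The filter audit runs at 250/150/2500 — the smallest size at
which the 0.05% cohort threshold still implies at least one carrier.
Both studies complete in about a minute on one core.

## Numerical and representational choices

* Variant identity is suffix-then-prefix trimming with at least one base
  kept per allele (VCF-style anchor), advancing the position past trimmed
  prefix bases. Left-alignment is not attempted because keys carry no
  reference sequence; consequently repeat-context insertions (A>AA) are
  not representation-independent, which matters only if upstream callers
  emit inconsistent placements for the same repeat indel.
* Ties and boundaries: all QC thresholds inclusive; cohort-frequency
  removal strictly greater-than; call-rate survival at ≥ the threshold.
* Percentages round half away from zero to one decimal (printed style);
  Python's banker's rounding is deliberately avoided.
* The exhaustive cascade test enumerates every consequence × significance
  × exon-position × rarity × submission-count combination (>1000 cells)
  against an independently hand-written truth table; the consequence
  caller is checked against a full-CDS-rebuild-and-translate oracle on
  500+ random variants per strand.

## Known limitations

* One transcript per gene; no multi-transcript reconciliation.
* Missense variants without a ClinVar-style P/LP record are never called
  pathogenic — the rule set is deliberately blind to in-silico scores.
* The bi-allelic MUTYH proxy (≥ 2 distinct variants) cannot distinguish
  true compound heterozygotes from two variants in cis.
* Wald intervals on very sparse genes are asymptotically motivated but
  honest about their width; no small-sample correction is applied.
* The coverage sidecar is optional; without it the call-rate filter sees
  only variant calls and will under-detect badly covered loci.
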