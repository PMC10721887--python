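# Methods

This note documents the models, defaults, numerical choices, and known
limitations of `penetrax`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Qualifying-variant classification

Classification is a pure function of the annotation table. pLOF is the
closed set {stop_gained, frameshift, stop_lost, start_lost, splice_acceptor,
splice_donor} (with `essential_splice` accepted as an alias);
`splice_region` is deliberately outside it. Deleterious missense requires
REVEL strictly above 0.70 **and** unanimous "damaging" verdicts from SIFT,
PolyPhen2-HDIV, PolyPhen2-HVAR, LRT and MutationTaster; a missing REVEL
score or predictor verdict fails the test. This is conservative by design:
it cannot admit a variant on incomplete evidence, leaves M1/M2 untouched,
and keeps M3 specific. Varsome assertions enter only the Benign/Likely-
Benign veto — a Varsome P/LP never qualifies a variant, and a Varsome VUS
never vetoes one (so a ClinVar-P variant with a Varsome VUS is admitted).
The ClinVar conflict flag is an input bit; recomputing ClinVar's aggregation
semantics from submitter lists is out of scope.

Carrier calling treats a missing (masked) genotype as reference. Compound
heterozygosity is called from **unphased** genotypes as ≥ 2 distinct
heterozygous QVs in one gene (COL4A3/COL4A4 only), so an in-cis pair is a
known false positive; the simulator plants exactly one such pair per cohort
so that tests exercise the caveat. Male X calls are haploid encoded as
homozygous; a heterozygous male X call is contradictory input — it is
counted as carriage, flagged per participant, and warned about, rather than
dropped. Hemizygous male COL4A5 carriage counts as a recessive genotype.

## Variant QC

Genotype masking uses strict inequalities (retained only if GQ > 90 and
DP > 10), so a call at exactly GQ = 90 is masked; the frequency filter uses
"remove if AF > ceiling", so a variant at exactly the ceiling survives.
These two boundary readings are consistent with each other and are pinned by
boundary tests. The cohort's own allele frequency is recomputed from
post-masking genotypes (the alternative — pre-masking — would keep variants
whose only alternate calls are unreliable) and participates as one
frequency source. By default the recomputed cohort frequency is the
*overall* post-masking frequency: per-ancestry recomputation is available
(`compute_cohort_af(..., ancestry_labels=...)`) but is not the pipeline
default, because with ultra-rare ceilings a single carrier inside a small
ancestry group would fail the per-group test at any realistic cohort size
— the annotation table's per-ancestry database frequencies already carry
the "any ancestral group" semantics. Male X calls contribute one allele to
frequency denominators. FilterReport attributes each removed variant to the
first filter that removes it (masking, then synonymous, then frequency);
the synonymous and frequency filters commute, which a test verifies.

## CKD e-phenotyping

The 2009 CKD-EPI equation is
141·min(Scr/κ,1)^α·max(Scr/κ,1)^(−1.209)·0.993^age·1.018[F]·1.159[Black]
with κ = 0.7/0.9 and α = −0.329/−0.411 (female/male); the 2021 race-free
equation is 142·min(Scr/κ,1)^α·max(Scr/κ,1)^(−1.200)·0.9938^age·1.012[F]
with α = −0.241/−0.302. Both are frozen against hand evaluations to
0.1 ml/min/1.73 m². The race coefficient is driven by an explicit input
indicator column and is never inferred from genetic ancestry. When a
participant carries several creatinine values the median is used
(deterministic and outlier-robust; first/last/mean are switches). Label
order: RRT → case; no usable creatinine → excluded; eGFR < 60 → case;
eGFR > 90 without CKD billing codes → control; everything else excluded.
The CKD billing-code list is a documented, configurable default
(585*, 586*, V42.0, V45.11, V56*); the fully validated e-phenotype uses a
longer curated list that lives with its own publication.

## Ancestry, PCs, kinship

LD pruning uses variant-count windows (500 variants, step 50, r² > 0.05),
removing the later variant of an offending pair — a deterministic stand-in
for the common tool's MAF-based tie-break. PCA is fitted on the reference
panel only (genotypes centered at 2p̂ and scaled by √(2p̂(1−p̂)), SVD);
cohort samples are projected through the fixed loadings and never refit, so
cohort structure cannot rotate the reference axes. Ancestry assignment is a
500-tree random forest trained on the labeled reference PCs, with a held-out
accuracy report; assignments are invariant to PC sign because sign flips
relabel a coordinate consistently for reference and cohort. Downstream
models use the projection PCs as covariates (4 for the CKD models, 5 for
the PheWAS, both configurable).

Kinship uses the published robust between-family moment estimator
φ̂ = (N_Aa,Aa − 2N_AA,aa)/(2·min(N_Aa^i, N_Aa^j)) + 1/2 −
(N_Aa^i + N_Aa^j)/(4·min(N_Aa^i, N_Aa^j)), computed on pruned variants,
with greedy exclusion (drop the member with the most relatives; ties by
lexicographically later id). The estimator's sampling noise scales like
m^(−1/2) in the number of variants, so distinguishing unrelateds from the
0.0442 threshold needs a few thousand pruned variants; the simulated studies
carry only a few hundred common variants and unrelated participants by
construction, so the pipeline leaves the kinship stage off by default
(`kinship_max_n = 0`) and the estimator is validated on dedicated fixtures
(duplicate ≈ 0.5, parent–child ≈ 0.25, unrelateds below threshold at
m = 5000).

## Polygenic score

Scoring is the plain weighted dosage sum with "sum" missing semantics
(missing dosage contributes 0; mean imputation is a switch); unmatched
weight variants are counted and warned about, > 50% unmatched is an error.
P+T model building selects variants greedily by ascending p-value subject to
r² ≤ 0.2 with every already-selected variant inside a positional window;
weights stay the discovery betas. Ancestry calibration fits two regressions
on the reference only: raw score on PCs (mean), then log squared residual on
PCs (variance), with the +digamma(1/2)+log 2 ≈ 1.2704 offset so the
predicted SD is unbiased under normal residuals; a mean-only strategy is a
switch. APOL1 adjustment defaults to residualizing the recessive risk-
genotype indicator out of the calibrated score ("adjusted for" read as
removing the association); an additive-term variant was considered and
rejected as the default because it changes the score's meaning for
non-carriers of APOL1 risk. Tertiles are cut at the cohort-wide empirical
33.3/66.7 percentiles (midpoint interpolation at ties) and applied to
carriers and noncarriers alike — carrier-only percentiles would put the
strata on incomparable scales.

## Association statistics

All inference is Wald-type on the log-odds scale, matching the OR (95% CI)
reporting convention; a Jeffreys-prior (Firth-type) penalized fit with
step-halving is the automatic fallback when a binary predictor is separated
or the ML fit is unstable, because sparse carrier strata (a handful of
cases) make unpenalized ML estimates diverge. Covariates follow each
analysis's own convention: age, sex, diabetes, batch and 4 PCs for the
carrier/per-SD/interaction models; age, sex, batch and 4 PCs (no diabetes)
for the tertile figures; 5 PCs for the PheWAS. Per-SD scaling uses the
control-group SD of the standardized score, which is ≈ 1 by construction;
the distinction is retained for fidelity and its effect is negligible at
these scales. Fixed-effects pooling is inverse-variance on the log-OR
scale with Cochran's Q and I² reported. Performance metrics: AUROC by rank
statistic (Hanley–McNeil CI), crude AUROC of the score alone, and
incremental Nagelkerke pseudo-R² (full minus covariates-only).

One non-collapsibility subtlety is documented rather than hidden: the
carrier-only model omits the polygenic score, so its marginal carrier log-OR
is attenuated by roughly 1/√(1 + σ²_GPS·3/π²) ≈ 4–5% relative to the planted
conditional value. The joint carrier+score+interaction model's coefficients
equal the planted conditional values, and parameter-recovery checks use it
alongside the marginal model (whose bias is well inside sampling noise at
the default carrier counts).

## PheWAS

Case = ≥ 2 ICD occurrences mapping to the phecode (occurrences are code
instances; dates are not modeled); control = zero occurrences of any code in
the phecode's exclusion range; everyone else missing. Unmapped codes are
counted and logged. Phecodes with < 20 cases (configurable) or without
carrier variation are reported with a skip reason, never dropped silently;
non-convergent fits are flagged and excluded from the meta-analysis. The
phecode map is an input file; a small synthetic map ships for tests and the
standard map can be supplied unchanged.

## The synthetic generator

The generator is the package's study design, not a fixture. Defaults: two
cohorts of 200,000 (94% EUR, ages 40–69, 54% female) and 75,000 (43% EUR,
ages 18–89, 60% female — the sizes and mixes of the two real biobank
subsets this design emulates); ADPKD carrier frequency 6e-4 (≈120 expected
carriers in the large cohort, matching the sparse-carrier regime of
interest); planted effects βc = log 17, βg = log 1.7 per SD, βi = 0,
APOL1 log 1.8 with risk-genotype frequency 12% in AFR; baseline case rate
3%; covariate effects (age +0.3/decade, male +0.2, diabetes +0.7 at 10%
prevalence) chosen for testability, not epidemiological realism. Liability
is generated on the **logistic** scale so planted log-ORs are exactly the
estimands of the analysis models. Creatinine is back-computed by inverting
the 2009 equation from a target eGFR drawn consistently with status (cases
15–58, controls 92–120, an excluded tranche 61–89, 0.5 margins so rounding
cannot flip a label), which makes phenotyping decisions deterministic given
truth.

Rare variants follow a 16-class template per gene (pLOF, asserted P, LP,
deleterious missense, and eight decoy classes covering every exclusion
branch: benign veto, single submitter, conflict, VUS, synonymous,
over-frequency, all-calls-low-quality, 4-of-5 predictors). Rare genotypes
are sampled independently given ancestry (no LD among rare variants);
liability carriers are spread round-robin over the analyzed gene set's M1
variants with a per-variant cap just under each gene's frequency ceiling, so
planted carriers always survive the frequency filter. This cap is also why
the ultra-rare ADPKD ceiling requires biobank-scale cohorts: below ≈51,000
participants even a single carrier exceeds 1e-5 after masking, so
scaled-down fixtures relax `maf_thresholds` — a knob shared by the
generator's truth record and the pipeline's filter, keeping the two
consistent at any scale. Common variants get AR(1) latent LD within blocks
(ρ = 0.5, block 20) to make r²-based pruning and clumping non-trivial, with
Balding–Nichols (Fst = 0.1) per-ancestry frequencies; the reference panel
(2504 samples, 1000 Genomes-style group sizes) shares those frequencies
without LD. The planted standardized score is the within-cohort,
within-ancestry z-score of the raw weighted sum.

What the generator does **not** emulate — realistic haplotype phasing,
rare-variant LD, EHR temporal structure, read-level error, genuine
relatedness — bounds what passing tests show: they certify the pipeline's
decision logic and estimator calibration under the planted model, not its
behavior on real sequencing artifacts or cryptic relatedness.

## Problem sizes and determinism

Parameter-recovery checks run at the default 200,000 + 75,000 scale (about
one and a half minutes end to end); unit and property tests use cohorts of
a few thousand with relaxed frequency ceilings; the null-interaction
calibration uses 200 replicates of n = 2,000 with elevated carrier
frequency, which exercises the identical model code — Wald calibration does
not depend on the cohort-scale run. All randomness flows through
`numpy.random.Generator` objects spawned from the single configured seed
(cohort streams keyed by CRC32 of the cohort name), and writers use fixed
column orders and float formats, so a fixed-seed run is byte-identical —
asserted by tests on both the generator and the pipeline's output hashes.

## Known limitations

In-cis het pairs are miscalled as compound heterozygotes (unphased data);
the marginal carrier OR is non-collapsibly attenuated as described; the
kinship stage is validated but off by default at simulated scales; the
shipped billing-code and phecode tables are minimal synthetic stand-ins for
versioned external content; and recessive-model analyses at M1/M2 are
underpowered at any realistic carrier frequency (the simulator plants only
a handful of recessive genotypes), so recessive inference is exercised at
M3 and at the calling level rather than as a powered association study.
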