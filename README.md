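# penetrax

Polygenic modification of monogenic kidney-disease penetrance: a tested,
reusable reimplementation of a biobank-style analysis pipeline, exercised
end to end on a synthetic cohort generator with planted effects.

## The scientific problem

Autosomal dominant polycystic kidney disease (ADPKD; *PKD1*, *PKD2*) and
collagen-IV nephropathy (COL4A-AN; *COL4A3*, *COL4A4*, X-linked *COL4A5*)
are the most common monogenic kidney diseases, yet carriers of pathogenic
variants vary widely in whether and when they develop chronic kidney disease
(CKD). One hypothesis is that the carrier's *polygenic background* — a
genome-wide polygenic score (GPS) built from thousands of common variants —
modifies penetrance. Testing that requires a long pipeline: rare-variant QC
and qualifying-variant (QV) classification, electronic-phenotype CKD
case/control definitions, ancestry inference, ancestry-calibrated polygenic
scoring, carrier-stratified logistic models pooled across cohorts, and a
phenome-wide association scan. `penetrax` implements every step as a typed,
tested Python library, for methodologists and statistical geneticists who
want to study, extend, or stress-test this design without access-controlled
biobank data.

## The model

Qualifying variants come in three nested-in-spirit models:

* **M1** — predicted loss-of-function (pLOF: stop-gain, frameshift,
  stop-lost, start-lost, essential splice) plus variants asserted
  Pathogenic by ≥ 2 independent ClinVar submitters without conflicts;
* **M2** — M1 plus Likely Pathogenic under the same submitter rules;
* **M3** — pLOF plus deleterious missense (REVEL > 0.70 **and** all five of
  SIFT, PolyPhen2-HDIV, PolyPhen2-HVAR, LRT, MutationTaster damaging).

A Benign/Likely-Benign assertion in ClinVar or Varsome vetoes a variant from
every model. Variants must pass GQ > 90 / DP > 10 genotype masking and
per-ancestry frequency ceilings (MAF ≤ 1e-5 for *PKD1*/*PKD2*, ≤ 1e-3 for
the COL4A genes, in **every** ancestral group of every frequency source).

CKD cases have eGFR < 60 ml/min/1.73 m² (CKD-EPI 2009 by default; the 2021
race-free equation is a switch) or renal replacement therapy; controls have
eGFR > 90 and no CKD billing code; the 60–90 band is excluded. The GPS is a
weighted allele-dosage sum, calibrated against a labeled reference panel
(mean and variance regressed on projected principal components), adjusted
for the APOL1 recessive risk genotype (G1/G1, G2/G2, G1/G2), standardized,
and cut into cohort-wide tertiles. Association models are logistic
regressions with Wald inference (Firth fallback under separation):

```
logit P(CKD) = β0 + βc·carrier + covariates            (carrier model)
logit P(CKD) = β0 + βg·GPS + covariates                (per-SD model, by stratum)
logit P(CKD) = β0 + Σ βs·1[stratum s] + covariates     (6-level tertile model)
logit P(CKD) = β0 + βc·carrier + βg·GPS + βi·carrier·GPS + covariates
```

with the noncarrier middle tertile as reference, and cohort estimates pooled
by inverse-variance fixed-effects meta-analysis
(β̂ = Σwᵢβᵢ/Σwᵢ, wᵢ = 1/SEᵢ², SE = (Σwᵢ)^(-1/2)). The PheWAS maps ICD-9
multisets to phecodes (2 occurrences = case, controls lack the exclusion
range), fits one model per phecode per cohort, pools them, and applies a
Bonferroni threshold of 0.05 / #phecodes tested.

Because the real cohorts are access-controlled, the package ships a
first-class synthetic generator (`penetrax.simulate`) that emulates two
cohorts (≈94% vs ≈43% European ancestry; ages 40–69 vs 18–89), plants known
carrier, per-SD, interaction and APOL1 log-odds effects on the logistic
scale, back-computes creatinine from target eGFR by inverting the 2009
equation, and writes a truth record against which every downstream decision
is scored.

## Worked example

```python
from penetrax.pipeline import RunConfig, run_pipeline
from penetrax.simulate import CohortSpec, SimConfig

config = SimConfig(
    cohorts=[CohortSpec("cohort1", n_participants=8000),
             CohortSpec("cohort2", n_participants=6000,
                        ancestry_mixture={"EUR": 0.43, "AFR": 0.21, "EAS": 0.04,
                                          "SAS": 0.15, "AMR": 0.17},
                        age_range=(18, 89), female_fraction=0.60)],
    carrier_frequency={"adpkd": 0.02, "col4a": 0.02},
    maf_thresholds={g: 5e-3 for g in ("PKD1", "PKD2", "COL4A3", "COL4A4", "COL4A5")},
    baseline_case_rate=0.08, seed=7)
result = run_pipeline(RunConfig(sim=config))
m = result.meta
print(round(m["carrier"].or_, 1), round(m["gps_per_sd_noncarrier"].or_, 2))
```

Running `python examples/06_penetrance_statistics.py` (the same study)
prints:

```
planted carrier OR 17.0 -> meta estimate 13.0 (95% CI 9.9-17.3)
planted per-SD score OR 1.70 -> noncarrier estimate 1.65 (95% CI 1.57-1.75)
carrier-stratum per-SD OR 1.69 (wide CI: few carriers)
carrier tertile ORs vs noncarrier middle tertile: {'T1': 10.3, 'T2': 12.1, 'T3': 27.4}
score-by-carrier interaction p = 0.84 (planted null: should not be small)
cohort1 AUROC: full 0.65, crude 0.62, incremental R2 0.039
```

The marginal carrier estimate (13.0) sits below the planted 17 at this
scaled-down size — sampling noise plus the documented non-collapsibility
attenuation of a model that omits the score; the joint carrier+score model
in the full table recovers OR 14.9 with a CI covering 17. The carrier
tertile gradient is monotone because the planted per-SD effect also
operates within carriers, and the interaction test stays null, as planted. Each capability has a short narrative script
under `examples/`, and `penetrax --help` exposes the same stages as a thin
command line (`simulate | filter | qv | phenotype | ancestry | gps | assoc |
phewas | all`).

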