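# pylorimet

Newborn dried-blood-spot (DBS) metabolomics for matched case–control
studies of infantile hypertrophic pyloric stenosis (IHPS) — a reusable,
tested implementation of the full analysis pipeline: plate-structured
quality control and normalization, metabolome-wide matched-pair
mixed-model association with birth-era stratification, diagnosis-code
co-occurrence testing, and SNP–metabolite models, together with a
synthetic cohort generator that emulates the study design end-to-end.

## The scientific problem

IHPS is a hypertrophy of the pyloric sphincter muscle that obstructs the
gastric outlet in the first weeks of life. Lipid metabolism is implicated
in its etiology, and newborn screening biobanks make it possible to assay
hundreds of metabolites from stored heel-prick DBS cards of children who
later did or did not develop the disease. The analytical design is a
1:1 matched case–control study (matching on sex and exact day of birth,
matched pairs always measured on the same 96-well plate), with a targeted
panel of 408 metabolites (acylcarnitines, amino acids, biogenic amines,
glycerophospholipids, sphingolipids, hexoses, cholesterol esters,
glycerides). A screening-policy change in 2009 moved the median age at
DBS sampling from 6 days to 2 days, which turns the cohort into a natural
experiment for separating feeding-pattern effects (which build up over the
first week of life) from genetic effects on metabolite levels.

## The statistics at its core

**QC / normalization** (per metabolite *m*, plate *p*):

- limit of detection `LOD_{m,p}` = median raw signal of the triplicate
  paper blanks on plate *p*;
- a metabolite is kept only if ≤ 20 % of raw sample values are ≤ LOD in at
  least one of the two groups (cases, controls);
- plate correction `C_{m,p} = A_{m,p} / TV_m`, where `A_{m,p}` is the
  median of the five QC2 reference replicates above LOD and `TV_m` the
  metabolite's target value; normalized values are `Norm = Raw / C_{m,p}`;
- pooled QC2 coefficient of variation (40 observations for 8 plates) must
  be ≤ 25 %.

**Association.** Normalized concentrations are rank-based inverse-normal
transformed, `y = Φ⁻¹((r − ½)/n)`, then modelled per metabolite as

```
y_ij = β·case_ij + sex + year-of-birth (factor) + parity + GA + b_i + ε_ij
b_i ~ N(0, τ²) per matched pair,  ε ~ N(0, σ²)
```

fitted by exact REML for the balanced paired design (the model is
algebraically equivalent to a weighted combination of within-pair
differences and sums). Significance uses Bonferroni correction over the
metabolites actually tested, with a t reference (containment degrees of
freedom). Scans run on all pairs and stratified by birth era
(before/after 2009).

**Epidemiology & genetics.** Fisher's exact test (conditional-ML odds
ratio, exact central CI) for co-occurrence of the ICD-10 code P92.5
("neonatal difficulty in feeding at breast") with case status; OLS models
for metabolite levels against code timing (assigned on the day of birth
vs later); additive-dosage OLS models of SNPs (e.g. rs174547 in *FADS1*)
against metabolite levels and the product/precursor ratio
PC(38:4)/PC(38:3) that indexes desaturase activity.

## Worked example

Generate a synthetic study-scale cohort (267 pairs, 8 plates, 408
metabolites) and run the whole pipeline:

```bash
pylorimet simulate --out demo --pairs 267 --plates 8 --seed 1
pylorimet run --config run.yaml     # paths pointing at demo/, seed 1
```

or in Python:

```python
from pylorimet.cli import make_fixtures, RunConfig, run_pipeline
make_fixtures(seed=1, size="paper_scale", outdir="demo")
run_pipeline(RunConfig(panel="demo/panel.tsv", plates="demo/plates.csv",
                       samples="demo/samples.tsv", outdir="demo/results",
                       seed=1))
```

This takes ~10 s and prints/writes (seed 1):

```
qc funnel: kept=408
bonferroni threshold: 0.05/408 = 1.225e-04
significant metabolites (all pairs): 7
P92.5: OR 11.86 (2.87-105.09), p 2.47e-05

metabolite      beta       se            p stratum  n_pairs  significant
   AC(2:0) -0.540315 0.082444 2.929986e-10     all      267         True
  PC(38:3) -0.468583 0.079270 1.045628e-08     all      267         True
  PC(36:4) -0.486129 0.083224 1.519580e-08     all      267         True
PC-O(36:4) -0.461305 0.081860 4.477744e-08     all      267         True
 Histidine -0.458098 0.083356 9.166997e-08     all      267         True
  PC(44:1) -0.452203 0.083868 1.548369e-07     all      267         True
  PC(38:4) -0.423088 0.083934 8.619973e-07     all      267         True
```

The seven Bonferroni-significant metabolites are exactly the seven the
generator endows with a feeding-mediated effect (five
phosphatidylcholines, acetylcarnitine AC(2:0) and histidine), all lower
in cases. The stratified scan shows the age-at-sampling attenuation — e.g.
PC(38:4): beta −0.59 (p 2.9×10⁻⁵) in pre-2009 pairs sampled around day 6,
but −0.31 (p 4.6×10⁻³, not Bonferroni-significant at the stratum level)
in post-2009 pairs sampled around day 2. The SNP models reproduce the
dissociation pattern that argues against a genetic explanation:

```
       snp             trait      beta       se            p   n
  rs174547          PC(38:4)  0.038082 0.065751 5.627163e-01 534
  rs174547          PC(38:3)  0.399472 0.063160 5.540108e-10 534
  rs174547 PC(38:4)/PC(38:3) -0.582711 0.063407 9.862898e-19 534
```

rs174547 moves the precursor PC(38:3) and the product/precursor ratio but
not PC(38:4) itself, and carries no disease association — while the P92.5
feeding-difficulty code is strongly enriched in cases (the OR for this
synthetic draw is 11.9; the co-occurrence table is random per seed).

The per-stage commands `pylorimet qc`, `assoc`, `epi` and `genetics`
expose the same stages on any inputs in the documented formats
(plate CSV, sample TSV, panel TSV).

## Layout

- `src/pylorimet/panel.py` — metabolite nomenclature, panel definition, TSV IO
- `src/pylorimet/synth.py` — synthetic cohort/plate generator + ground truth
- `src/pylorimet/qcnorm.py` — LOD, detection filter, plate correction, CV filter
- `src/pylorimet/assoc.py` — transform, paired REML mixed model, scans,
  correlations
- `src/pylorimet/epi_gen.py` — Fisher exact, code-timing, SNP–trait models
- `src/pylorimet/cli.py` — subcommands and end-to-end pipeline
- `docs/methods.md` — models, assumptions, parameter choices, limitations
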