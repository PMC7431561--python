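# ihcmark

Biomarker discovery-to-prognosis toolkit for Wnt-pathway
immunohistochemistry studies. It covers three linked analyses:

1. **Cross-omics discovery** — find *Myc*-dependent Wnt-target genes in a
   four-genotype conditional-knockout design (wild-type, *Apc*-null,
   *Apc/Myc* double-null, *Myc*-null). A gene is a candidate when, on at
   least three independent probes, the *Apc*-null : WT fold exceeds 2 with
   *p* < 0.05 (Welch test on log2 values), the *Apc/Myc*-null : WT ratio
   stays inside the 0.75–1.25 band, and the *Apc/Myc*-null : *Apc*-null
   ratio falls below 0.5 with *p* < 0.05 — and a matching protein shows a
   > 1.2-fold increase after *Apc* deletion.
2. **Digital H-DAB scoring** — colour deconvolution of hematoxylin/DAB
   sections in optical-density space (Ruifrok–Johnston basis), a
   cytoplasmic **modified H-score**
   `0·%neg + 100·%low + 200·%pos + 300·%high ∈ [0, 300]` over four DAB
   intensity zones, and a **nuclear positive-percentage** ∈ [0, 100] (share
   of segmented nuclei whose mean DAB optical density exceeds a threshold).
   Samples are scored as the mean of ≥ 2 microscopy fields of ≥ 100 cells.
3. **Cutoff-based prognosis** — ROC/AUC against mortality, cutoff selection
   (sensitivity–specificity balance, Youden, or log-rank scan),
   Kaplan–Meier curves with log-rank comparison, multivariate Cox
   proportional-hazards (Efron ties) adjusted for age, sex, stage and
   grade, and early/late-stage subgroup re-analysis.

A seeded synthetic-data module generates every input — the four-genotype
expression/protein tables, stain-composed section images, and a 75-patient
cohort matching the published margins — with ground-truth labels, so the
whole pipeline is testable without any external data.

## Worked example

```python
from ihcmark import (CohortSimConfig, PrognosisModel, generate_cohort)

cohort = generate_cohort(CohortSimConfig(), seed=1)   # 75 patients
print(PrognosisModel(cohort, score_col="nuclear_pct").fit().summary())
```

prints (abridged):

```
Score: nuclear_pct    n = 74    deaths = 51
ROC AUC (mortality): 0.367
Cutoff (balanced): 45.2  [sens 0.569, spec 0.565]

  low group: n=39  median survival 37.5 mo  5-year survival 41.0%
 high group: n=35  median survival 86.9 mo  5-year survival 62.9%
Log-rank p (low vs high): 0.1193

Multivariate Cox (efron ties, converged=True)
                            hazard_ratio  ci95_low  ci95_high  p_value
score_group[high vs low]           0.596     0.336      1.057    0.077
...
```

One patient died within the first month and is excluded by the 30-day
inclusion rule (n = 74). The AUC below 0.5 reflects a protective marker:
deaths concentrate in the *low*-expression group, so the balanced cutoff is
read in the low-scores-test-positive direction. The adjusted hazard ratio
below 1 for the high-expression group mirrors the simulated protective
effect; at n = 75 it is attenuated by cutoff misclassification, and larger
simulated cohorts recover it sharply (see `tests/test_survival.py`).

The same objects drive the image chain:

```python
from ihcmark import (ImageSimConfig, deconvolve_hdab, generate_ihc_image,
                     nuclear_positive_fraction, segment_nuclei)

img, truth = generate_ihc_image(ImageSimConfig(), seed=3)
od = deconvolve_hdab(img)
labels = segment_nuclei(od)
print(nuclear_positive_fraction(labels, od.dab_od))  # 30.0 (truth: 30%)
```

## Command line

```bash
ihcmark simulate --kind cohort --seed 1 --out-dir data/
ihcmark discover --expression expr.tsv --design design.tsv \
                 --proteins prot.tsv --out-dir disc/
ihcmark score --compartment nuclear --fields f1.png --fields f2.png \
              --zones 60,120,180 --pos-od 0.15 --out sample.json
ihcmark prognose --cohort data/cohort.csv --score nuclear_pct \
                 --cutoff-method balanced --out-dir report/
```

Exit codes: 0 success, 2 input/schema error, 3 protocol violation (strict
mode).

## Layout

- `src/ihcmark/simulate.py` — seeded generators (omics, images, cohort)
- `src/ihcmark/omics.py` — genotype ratios, congruence filter, fold tests
- `src/ihcmark/ihc.py` — deconvolution, H-score, nuclear scoring
- `src/ihcmark/survival.py` — ROC/cutoff, KM, log-rank, Cox, group tests
- `src/ihcmark/prognosis.py` — `PrognosisModel` / `PrognosisResults`
- `src/ihcmark/pipeline.py`, `cli.py` — orchestration and `ihcmark` CLI
- `docs/methods.md` — models, defaults and their rationale, limitations
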