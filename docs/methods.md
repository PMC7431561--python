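# Methods

## Discovery filter

The discovery question is which genes behave as *Myc*-dependent Wnt
targets: induced when *Apc* is conditionally deleted, with the induction
abolished when *Myc* is co-deleted. Expression is handled on the log2
scale throughout; a genotype fold change is `2^(Δ mean log2)`, which makes
every fold and p-value invariant to a global rescaling of the linear
expression values (tested as a property).

Per probe, three criteria are evaluated: `fold(APC:WT) > 2` with
`p < 0.05`; `0.75 ≤ ratio(APCMYC:WT) ≤ 1.25` (a band with no significance
requirement — it expresses "no change", where a p-value would reward
noise); and `fold(APCMYC:APC) < 0.5` with `p < 0.05`. The two tested
contrasts use the two-sided Welch (unequal-variance) t-test on log2
values: the test is not dictated by the filter design, and Welch is the
safe default for 4-vs-4 replicate groups with no variance pooling
assumption; the choice is recorded in the ratio table metadata. P-values
are consumed raw — the filter is a screening rule, not an inference, and
applying multiplicity correction would change its published thresholds'
meaning. A probe with zero variance in both groups carries no evidence and
is reported as `p = 1` with a `degenerate` flag rather than an error.

A gene is a candidate when **at least three probes individually pass all
three criteria** and a protein mapped to the gene (shared `gene_id`;
unmapped proteins are counted and ignored) shows `fold > 1.2`. Reading
"confirmed by at least three probes" as probe-level passes is the stricter
interpretation; a `gene_mean` mode (geometric-mean folds,
Fisher-combined p-values, ≥ 3 probes present) is available for users who
prefer gene-level aggregation. The filter is monotone: relaxing any single
threshold can only grow the candidate set (property-tested).

The case/control fold comparison used for tumor/normal expression panels
reports `mean(case)/mean(control)` with a two-sided Mann–Whitney p-value:
exact by full enumeration of the `C(n, n₁)` relabelings when the pooled
sample has ≤ 12 values (ties handled by enumerating the tied rank-sum
distribution itself; the two-sided p is `2·min(P(U≤u), P(U≥u))` capped at
1), and the tie-corrected normal approximation otherwise.

## Image model and scoring

**Forward model.** Stain concentrations mix linearly in optical density
(Beer–Lambert): a pixel with hematoxylin concentration `c_H` and DAB
concentration `c_D` renders as `RGB = 255·10^(−(c_H·S_H + c_D·S_D))`
channel-wise, with the Ruifrok–Johnston H-DAB unit vectors
`S_H ≈ (0.650, 0.704, 0.286)`, `S_D ≈ (0.269, 0.568, 0.778)` and a
residual vector from their normalized cross product. Deconvolution
inverts this: `OD_c = −log10((I_c + 1)/256)` (the +1 avoids log 0),
concentrations = OD vector × inverse stain matrix, negatives clamped.
The 8-bit quantization of the forward model bounds round-trip error well
below the 0.02 OD tolerance asserted in tests for the OD ranges used.

**Synthetic sections.** A tissue disc (radius 0.45·min(width, height)) on
a near-white background carries non-overlapping elliptical nuclei
(semi-axes 4–7 px, random orientation, ≥ 3 px clearance so smoothing
cannot merge them; placement by bounded rejection sampling that fails
loudly when infeasible). All nuclei carry hematoxylin OD 0.70; a planted
fraction additionally carries nuclear DAB OD 0.60. Cytoplasm (disc minus
nuclei, baseline hematoxylin 0.15) is partitioned pixel-wise into the four
DAB classes at exactly the requested fractions (largest-remainder
rounding, so empirical fractions match within one pixel) with class ODs
0.02 / 0.25 / 0.45 / 0.70 — chosen to sit squarely inside the four
default intensity zones. The generator emulates composition, not realism:
no texture, scanner noise, stain variation, touching nuclei or stromal
structures. Tests passing on these images demonstrate the correctness of
the scoring arithmetic and segmentation logic, not robustness to real
histology.

**Cytoplasmic score.** DAB OD is mapped back to a 0–255 brightness axis
(`I = 255·10^(−OD)`) and binned at cutpoints 60/120/180 — the convention
of the standard pixel-classification plugin, configurable — into
high-positive `[0,60]`, positive `(60,120]`, low-positive `(120,180]`,
negative `(180,255]`. The modified H-score is the weighted sum
`0·f_neg + 100·f_low + 200·f_pos + 300·f_high`, forced into [0, 300] by
construction. Cytoplasm means tissue pixels outside segmented nuclei;
tissue is total stain OD > 0.08 (glass excluded), or a user-supplied mask
for material where non-epithelial regions were edited out manually.

**Nuclear score.** Nuclei are segmented by Otsu thresholding the
Gaussian-smoothed (σ = 1.5 px) hematoxylin map within tissue, connected
components, minimum area 15 px. Thresholding the counterstain alone —
rather than hematoxylin + DAB — keeps the histogram bimodal (cytoplasm
vs nuclei) regardless of how many nuclei are DAB-positive; on a combined
map, strongly positive nuclei form a third mode and Otsu can split at the
wrong valley, discarding the negative nuclei entirely. A
`include_dab=True` flag restores the combined map for material where
strong DAB displaces the counterstain. A nucleus is positive when its
mean DAB OD exceeds 0.15 (default, declared in output metadata; the
plugin this emulates does not publish its threshold); the score is
`100 × positive/total`. An area-based variant (DAB-positive nuclear area
over total nuclear area) is available by flag. No watershed splitting by
default — synthetic nuclei never touch; a flag enables it for real
images.

**Protocol.** A sample score is the unweighted mean of ≥ 2 field scores
(pooling all fields into one virtual field is available by flag; the
averaging default was chosen as the interpretation that weights fields
equally regardless of cell count). Fields with < 100 detected cells are
flagged; strict mode turns the flag into an error.

## Cohort simulation

Defaults reproduce the prognostic cohort's published margins: n = 75,
57.3% male, 62.7% stage III–IV, mean age 59.7 truncated to 33–84 (SD 11,
a stand-in — no dispersion is published), grade well/moderate/poor ≈
31/67/3%. Nuclear scores are a two-component Gaussian mixture (low mode
18%, SD 7, high mode 30 points above, 41/75 of patients high — the
published group split); only the separation and group weight are
published quantities, the mode locations are stand-ins placed so the
natural cutoff falls near the published 32%. Survival is exponential with
low-group hazard `ln 2 / 32` per month (median 32 months, the published
low-group median) and high-group hazard multiplied by the hazard ratio
(default 0.39, the published adjusted HR; values < 1 favour high
expression), administratively censored at 120 months. Covariates are
drawn independently of outcome, so the simulated HR is marginal — real
cohorts confound stage with survival, which the generator deliberately
does not emulate.

## Survival analysis

Follow-up is in months; 5-year survival is S(60) read off the
Kaplan–Meier curve; events precede censorings at tied times; the median is
the smallest time with S(t) ≤ 0.5 and is reported as undefined when never
reached. Patients must survive ≥ 1 month (≈ 30 days) post-surgery to
enter the analysis. Dichotomization labels `score ≥ cutoff` as "high";
published cutoffs (32% nuclear, 135 cytoplasmic) are cohort-derived and
therefore accepted as *inputs*, never hard-coded. Cutoff candidates are
midpoints between adjacent distinct scores; ties break toward the lower
cutoff; the test direction (which side counts as positive for mortality)
is inferred from the AUC and reported, since a protective marker reverses
it. The Cox model uses Efron tie handling by default (Breslow by flag,
recorded in metadata), Wald 95% CIs on the log-hazard scale, categorical
covariates expanded against stated reference levels (female / early /
well / low). Non-convergence and suspected separation (|log HR| > 15) are
flagged, never silent. Stage subgroups are analysed by filtering and
re-running, without interaction terms. No multiplicity adjustment is
applied across endpoints; the only adjusted p-values are the
Bonferroni-corrected Dunn pairwise tests after Kruskal–Wallis. Chi-square
group comparisons switch to Fisher's exact test when any expected cell
count is below 5 in a 2×2 table.

## Numerical and testing choices

All generators draw from a single `numpy` Generator per call, so equal
(config, seed) pairs are bit-identical. Statistical operations are
checked against independent oracles: hand-computed Welch and product-limit
values, full-enumeration Mann–Whitney and hypergeometric Fisher,
pair-counting AUC, exhaustive cutoff scans, per-pixel classification
tallies, and a plain-Python re-evaluation of the discovery predicate.
Simulation-based checks use deliberately modest problem sizes — 100 seeds
for discovery recovery, 100 cohorts of n = 2000 for Cox CI coverage, 1000
null cohorts for log-rank size, a nine-point positive-fraction sweep —
sized to give stable pass/fail margins at the asserted thresholds.

## Known limitations

- The image generator's geometry (ellipses on a disc) exercises the
  scoring chain but says nothing about crowded, textured real sections;
  segmentation on real slides will need the watershed flag and tuned
  minimum area.
- Cohort distributions beyond the published margins are stand-ins; the
  simulated AUC and log-rank power at n = 75 should not be read as
  re-estimates of the published ones.
- The Cox implementation delegates to maximum partial likelihood in
  statsmodels; no proportionality diagnostics are run beyond convergence
  and separation flags.
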