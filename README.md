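# tsrquant

Automated quantification of the **tumor-to-stroma ratio (TSR)** in
brightfield photomicrographs of EpCAM/H-DAB-stained tissue cores, as used
in prostate-cancer tissue-microarray studies, plus the cohort-level
statistics needed to test TSR as a prognostic factor for biochemical
recurrence.

The TSR expresses the relative amounts of tumor and intratumoral stroma in
a scored field. High stromal content has repeatedly been associated with
outcome in solid tumors, but visual scoring is laborious and
observer-dependent. `tsrquant` reproduces an automatic scoring pipeline:

1. **Color deconvolution.** An 8-bit RGB image is converted to optical
   density, `OD = −log10(I / I₀)`, and unmixed into hematoxylin, DAB and
   residual maps with the Ruifrok–Johnston method using the standard H-DAB
   absorption vectors (hematoxylin `(0.650, 0.704, 0.286)`, DAB
   `(0.269, 0.568, 0.778)`, residual = their unit cross product).
2. **Masking.** Each per-stain channel is rendered as an 8-bit
   pseudo-transmittance image, median filtered (disc radius 2 px), and
   binarized automatically: the **tumor** mask from the DAB channel with
   Tsai's moment-preserving threshold, the **stroma** mask from the
   hematoxylin channel with Otsu's threshold. Stroma overlapping the tumor
   mask is excluded.
3. **TSR and QC.** `TSR = tumor area / stroma area` per core. A core is
   informative only if tumor reaches all four sides of the field
   (north/south/east/west edge bands), is not effectively EpCAM-negative,
   and has non-empty stroma.
4. **Aggregation.** Per patient, the minimal and maximal TSR over
   informative cores are recorded and the patient is dichotomized on the
   maximum at a cut-off of 1: **low** (< 1) vs **high** (≥ 1).
5. **Cohort statistics.** Category proportions, chi-square / Fisher exact
   association tests, Kaplan–Meier curves and the Mantel–Cox log-rank test
   for time to biochemical recurrence.

Because no public image set exists for such cohorts, the package ships a
first-class **synthetic renderer**: elliptical DAB-brown glands with blank
lumina on hematoxylin-blue stroma, generated with a known tumor/stroma
ratio and pushed through the same Beer–Lambert model the deconvolution
inverts — so the whole pipeline is testable against ground truth.

## Worked example

Render six synthetic cores (three patients) at ground-truth ratio 2.0 and
score them:

```bash
tsrquant simulate --n-cores 6 --target-ratio 2.0 --seed 42 --out-dir sim
tsrquant quantify --sheet sim/sample_sheet.csv --out-dir results
```

The run summary printed by `quantify`:

```json
{
  "n_rows": 6,
  "n_skipped_not_included": 0,
  "n_failed_technical": 0,
  "n_quantified": 6,
  "n_informative": 6,
  "n_excluded_four_sides": 0,
  "n_flagged_epcam_negative": 0,
  "n_excluded_empty_stroma": 0,
  "n_patients": 3,
  "category_counts": { "high": 3 }
}
```

`results/cores.csv` holds per-core areas, ratios and QC flags:

```
core_id,patient_id,tumor_area_px,stroma_area_px,tsr,four_sides_pass,epcam_negative,empty_stroma,informative
P0000_c0,P0000,34460,17220,2.0012,True,False,False,True
P0000_c1,P0000,34570,17237,2.0056,True,False,False,True
...
```

Each measured TSR is within ~2% of the rendered ground truth
(`sim/truth.csv`, e.g. 1.9700 for `P0000_c0`). `results/patients.csv`
aggregates to patient level; all three patients are **high** TSR since
their maximal core TSR ≥ 1:

```
patient_id,n_informative_cores,tsr_min,tsr_max,category
P0000,2,2.0012,2.0056,high
P0001,2,2.0298,2.0362,high
P0002,2,2.0076,2.0443,high
```

With a follow-up table (`patient_id,time_months,event`) you can then run

```bash
tsrquant survival --patients results/patients.csv --followup followup.csv
```

to get Kaplan–Meier step coordinates per category and the log-rank
statistic and p-value as JSON.

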