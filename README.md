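# eamap — electroanatomic map analysis for AF substrate phenotyping

`eamap` is a Python library for analysing high-density electroanatomic maps
of the left atrium: from raw per-point bipolar/unipolar electrograms on a
triangulated surface to voltage maps, conduction-velocity (CV) maps,
per-patient substrate summaries, voltage/CV phenotype clusters, and
recurrence-free survival after ablation. It is aimed at cardiac
electrophysiology researchers who want a transparent, fully testable
re-implementation of this analysis chain — every stage is verifiable against
a built-in ground-truth simulator, so no patient data is required to
validate the methods.

## What it computes

**Signal processing.** Electrograms are band-pass filtered at 30–250 Hz
(zero-phase, so timing never shifts), screened for high-frequency noise, and
annotated: the local activation time (LAT) is the steepest downslope of the
bipolar electrogram, t* = argmin dV/dt. Bipolar voltage is the peak-to-peak
amplitude, max V − min V, within a window.

**Voltage maps.** Point voltages are interpolated onto the surface by
inverse-distance weighting (w ∝ 1/d², k = 8 neighbours, 10 mm unmapped
cut-off). Low-voltage area is the mapped-surface fraction with bipolar
voltage < 0.50 mV (also reported at 0.30 mV).

**CV maps.** Point triplets from a Delaunay triangulation (in local tangent
planes) are each fitted with a planar wavefront: the slowness vector **s**
solves (p₂−p₁)·**s** = t₂−t₁ and (p₃−p₁)·**s** = t₃−t₁, giving
CV = 1/‖**s**‖ and direction **s**/‖**s**‖. Four constraints screen the
triples — edge length within [1.5, 2.0] mm (a relaxed 1.5–10 mm preset is
provided for sparser samplings), maximum LAT difference > 2 ms, CV ≥ 0.2 m/s
(slower fits mark lines of block and are excluded), minimum internal angle
≥ 30°. Accepted velocities are interpolated like voltages; slow-CV area uses
0.6 and 0.4 m/s thresholds.

**Cohort analysis.** Patients are stratified by map-mean CV (slow < 0.6,
moderate 0.6–0.8, high ≥ 0.8 m/s) and voltage (low < 0.5, intermediate
0.5–0.75, normal ≥ 0.75 mV); the voltage–CV association uses Spearman's ρ;
group comparisons pass a Shapiro–Wilk gate into one-way ANOVA or
Kruskal–Wallis (Wilcoxon rank-sum for two groups); phenotypes come from
k-means (k = 3) on z-scored (mean CV, mean voltage), labelled so cluster 0
is the healthiest.

**Survival.** Recurrence is the first atrial tachyarrhythmia ≥ 30 s after
the 90-day blanking window. Kaplan–Meier curves (Greenwood variance) and
unweighted log-rank tests compare clusters and the prognostic dichotomies at
0.60 m/s (CV) and 0.82 mV (voltage).

**Simulator.** Disc or ellipsoidal atria with PV/LAA region labels; planar
or focal activation over regionally varying speed (0.05–3 m/s,
front-marching travel times on the mesh edge graph); electrograms whose
steepest downslope falls exactly at the prescribed LAT and whose pre-noise
peak-to-peak equals the prescribed amplitude; and a 52-patient cohort with
three phenotype clusters and cluster-dependent 24-month recurrence.

## Worked example

`examples/03_phenotypes_and_survival.py` generates a synthetic 52-patient
cohort, recovers its phenotypes, and compares survival:

```
Spearman rho(voltage, CV) = 0.53 (p = 5.6e-05)
cluster  n   centroid CV  centroid voltage
   0    28    0.76 m/s      1.57 mV
   1    13    0.51 m/s      1.43 mV
   2    11    0.48 m/s      0.56 mV
cluster 0: S(24 mo) = 0.66
cluster 1: S(24 mo) = 0.57
cluster 2: S(24 mo) = 0.42
3-way log-rank: chi2 = 1.54, df = 2, p = 0.464
CV dichotomy at 0.6 m/s: S(24) low = 0.48, high = 0.66, log-rank p = 0.164
```

Voltage and CV are positively correlated across patients; the three
phenotypes (normal/normal, slow CV with preserved voltage, slow CV with low
voltage) carry increasing recurrence risk, and the slow-CV arm of the
0.6 m/s dichotomy has visibly worse 24-month recurrence-free survival — at
n = 52 the log-rank comparisons are, as expected, not individually
significant. The other examples build a voltage map with low-voltage areas
(`01`), localise a 0.3 m/s slow-conduction patch inside 0.8 m/s tissue
(`02`), and run the full per-patient map pipeline end to end (`04`).

A thin CLI wraps the same functions:

```bash
eamap simulate --seed 2 --out scratch/map1     # write a synthetic map dataset
eamap process scratch/map1                     # annotate + map -> summary JSON
eamap run --seed 11 --out scratch/run          # full pipeline with reports
```

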