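"""Phenotype a synthetic AF cohort and compare recurrence-free survival.

Generates a 52-patient cohort with three voltage/CV phenotypes, recovers
them by k-means in the (mean CV, mean voltage) plane, and runs Kaplan-Meier
and log-rank comparisons, including the 0.60 m/s / 0.82 mV dichotomies.
"""

import numpy as np

import eamap
from eamap.survival import SurvivalRecord, dichotomised_analysis, kaplan_meier, logrank

cohort = eamap.generate_cohort(eamap.CohortSpec(seed=7))
labels, centroids, _ = eamap.kmeans_phenotypes(cohort, seed=7)

rho, p = eamap.spearman_corr([s.mean_bip_mV for s in cohort],
                             [s.mean_cv_m_per_s for s in cohort])
print(f"Spearman rho(voltage, CV) = {rho:.2f} (p = {p:.1e})")
print("cluster  n   centroid CV  centroid voltage")
for c in range(3):
    print(f"   {c}    {np.sum(labels == c):2d}    {centroids[c, 0]:.2f} m/s"
          f"      {centroids[c, 1]:.2f} mV")

records = [SurvivalRecord(s.patient_id, s.time_months, s.event, f"cluster_{l}")
           for s, l in zip(cohort, labels)]
for c in range(3):
    km = kaplan_meier([r for r in records if r.stratum == f"cluster_{c}"])
    print(f"cluster {c}: S(24 mo) = {km.at(24.0):.2f}")
chi2, df, p = logrank(records)
print(f"3-way log-rank: chi2 = {chi2:.2f}, df = {df}, p = {p:.3f}")

d = dichotomised_analysis(cohort)
cv = d["cv"]
print(f"CV dichotomy at {cv['cut']} m/s: S(24) low = {cv['low']['S_24']:.2f}, "
      f"high = {cv['high']['S_24']:.2f}, log-rank p = {cv['logrank_p']:.3f}")
print("Cluster 0 (normal CV & voltage) should show the best recurrence-free survival;")
print("slow-CV patients recur more even when voltage is preserved.")
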