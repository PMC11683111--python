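# Methods

This note records the models, numerical choices and limitations behind
`eamap`, in the spirit of a methods appendix. Units are fixed package-wide:
positions in mm, times in ms, voltages in mV, speeds in m/s. Because
1 mm/ms = 1 m/s, conduction-velocity thresholds apply without conversion.

## Electrogram model and annotation

Synthetic bipolar electrograms use a Gaussian-derivative wavelet
f(t) = −A·x·e^(−x²/2), x = (t − LAT)/σ: a positive lobe followed by a steep
negative lobe, the canonical biphasic far-field-free bipolar morphology. Its
first derivative attains its minimum exactly at t = LAT, and the continuous
template's peak-to-peak is exactly the prescribed amplitude (A is solved
from 2A·e^(−1/2) = amplitude). The unipolar channel is a Ricker wavelet
scaled to 1.63× the bipolar amplitude (the cohort-level unipolar/bipolar
ratio). The default width is 20 ms (σ = width/8 = 2.5 ms), sampled at
2 kHz; traces are windowed centred on the activation (t0 = LAT −
duration/2), which makes annotation of noiseless synthetic traces
grid-exact. Real recordings have no such alignment; annotation accuracy on
real data is limited by the sampling interval and noise, which the tests
probe by adding white noise and artefacts.

Annotation follows the steepest-downslope rule: LAT = time of the minimum
central-difference derivative within the analysis window (the whole trace by
default), ties broken to the earliest sample. A minimum-slope threshold
(default 0.02 mV/ms) separates true downslopes from flat noise; shallower
traces are flagged `rejected_amplitude`. The 30–250 Hz band-pass is an
order-2 Butterworth applied forward-backward (zero phase): activation timing
cannot shift, DC and baseline wander vanish. Because the derivative of the
template is symmetric about the LAT, filtering leaves the annotated LAT
unchanged to machine precision.

One measured consequence of filtering: the biphasic wavelet is broadband,
and the band-pass attenuates its peak-to-peak by ~5–6% at the default
width. Map voltages are nevertheless computed on the filtered trace — the
attenuation is uniform across points and patients, so maps, area fractions
and cohort structure are unaffected up to a scale factor, while filtering
first makes the measurement robust to baseline wander and noise. Round-trip
accuracy statements about the generator itself (peak-to-peak equals the
prescribed amplitude within 1%) refer to the pre-filter trace.

The noise screen emulates the qualitative operator-side exclusion of noisy
electrograms with a deterministic rule: a trace is `rejected_noise` when the
RMS of its out-of-band residual (raw minus band-passed) exceeds 1.0× the
in-band RMS, and `rejected_amplitude` when the filtered peak-to-peak falls
below 0.03 mV. Both thresholds are configuration values, not published
constants.

## Activation simulation

Planar mode assigns LAT(v) = ((v − p₀)·d̂)/speed exactly. Focal mode solves
a shortest-travel-time problem on the mesh edge graph (Dijkstra), with edge
cost = length × mean slowness of its endpoints; the graph is augmented with
the "crossing" links connecting the two vertices opposite each interior
edge, which reduces the metric anisotropy of lattice shortest paths to a few
percent at 1.5–2 mm resolution. The earliest vertex is shifted to LAT = 0.
Speeds are restricted to the physiological 0.05–3.0 m/s range.

Two properties of the focal solution matter for interpretation. First, the
residual metric error makes travel times slightly long, i.e. recovered
speeds slightly low (≲ 4% at 1.5 mm resolution). Second, inside a slow
inclusion the true first-arrival front near the boundary is driven by waves
that travel around the patch through fast tissue and re-enter, so the local
LAT gradient there genuinely corresponds to speeds above the patch value —
recovered "patch interior" CV is therefore assessed well inside the patch,
and still sits a few percent high. Both effects are physics/discretisation,
not estimator bias: on planar waves with exact LATs the triple fit is exact
to machine precision.

## CV estimation

Triples come from Delaunay triangulation. On curved clouds each point's
k = 12 nearest neighbours are projected onto their PCA tangent plane and
triangulated locally, and triangles incident to the centre point are pooled
and de-duplicated — this avoids the sliver artefacts of a global 3-D
tetrahedralisation. When the whole cloud fits in one neighbourhood a single
global triangulation is used (per-point unions can mix the diagonals of
co-circular quadrilaterals).

The per-triple estimator is a locally planar wavefront fit (a 2×2 linear
solve for the slowness vector in the triangle plane). No explicit curvature
term is included: curvature is handled by the density of triples rather than
by the local model. All-equal LATs give zero slowness; the CV is flagged
undefined (effectively infinite) and such triples always fail the
LAT-spread constraint.

The four acceptance constraints default to: edge lengths within
[1.5, 2.0] mm, maximum pairwise LAT difference > 2 ms, CV ≥ 0.2 m/s (fits
below the floor are labelled line-of-block and excluded from the CV field
rather than clamped), minimum internal angle ≥ 30°. The 1.5–2.0 mm band
reflects closely spaced electrode pairs of a high-density catheter; it is
narrower than typical inter-point spacing of an area-uniform synthetic
sampling, so a relaxed preset (1.5–10 mm) is provided and used by the
simulated pipeline. The LAT-spread rule is interpreted as the *maximum*
pairwise difference (the triple must genuinely span a wavefront passage);
an all-pairs variant can be configured. Constraints only gate inclusion —
they never alter fitted values — and the audit table exports every triple
with its per-constraint flags.

## Interpolation and map summaries

Inverse-distance weighting with power p = 2 over the k = 8 nearest data
points; a vertex within 0.1 mm of a data point snaps to its value exactly;
vertices farther than 10 mm from every data point are unmapped (NaN) and
excluded from all summaries. IDW is bounded by its data and scale-
equivariant; it cannot overshoot, at the cost of flattening sharp extrema —
the dominant term in the ~2–3% RMS error observed on smooth fields at
clinical point densities.

Map summaries are area-weighted over mapped triangles (triangle value =
mean of its three vertices): surface means are density-invariant, unlike
point averages, which are also exposed for sensitivity analysis since
map-level "average voltage" is reported both ways in practice. Low-value
area fractions (bipolar voltage < 0.5 / 0.3 mV; CV < 0.6 / 0.4 m/s) use the
same vertex-mean triangle rule, relative to the mapped area; the rule is
monotone in the threshold. PV ostia and the appendage are removed by label
(any triangle touching a non-body vertex), standing in for image-based
semi-automatic clipping, which is out of scope.

## Cohort statistics

Band boundaries are half-open with the boundary in the upper band (0.6 m/s
is "moderate", 0.75 mV is "normal"), fixing a convention the clinical bin
definitions leave open; the voltage "normal" band is open-ended above
1.0 mV so the bins partition the observed range. The comparison pipeline
gates on per-group Shapiro–Wilk at α = 0.05 (groups of n < 3 count as
non-normal); two-group comparisons always use the Wilcoxon rank-sum test,
k-group comparisons use ANOVA when all groups pass and Kruskal–Wallis
otherwise. Phenotyping is k-means with k = 3 fixed, k-means++ with 20
restarts, on z-scored (mean CV, mean voltage) only — the two axes that
define the phenotypes; area fractions can be added as an optional feature
set. Cluster indices are canonicalised by descending centroid voltage + CV
sum, so cluster 0 is always the healthiest phenotype and labels are
permutation-stable.

## Survival

Time runs in months from the procedure (1 month = 30.4375 days). The
blanking rule gates event *eligibility* — the first episode ≥ 30 s strictly
after day 90 defines the event — rather than shifting the clock, so S(t) is
defined from t = 0 and the rule is idempotent. Kaplan–Meier estimation and
the unweighted log-rank test are delegated to lifelines; Greenwood variance
is computed from the event table; events precede censorings at tied times.
The prognostic dichotomies (0.60 m/s, 0.82 mV) are fixed configuration
values; each factor is analysed independently with per-arm survival read
off at 12 and 24 months.

## Synthetic cohort

Three clusters of 30/12/10 patients (n = 52): cluster 0 normal CV and
voltage, cluster 1 slow CV with preserved voltage, cluster 2 slow CV and
low voltage. Per-cluster (mean, SD) defaults — voltage (1.6, 0.35),
(1.35, 0.25), (0.55, 0.12) mV; CV (0.75, 0.07), (0.52, 0.06),
(0.45, 0.06) m/s — are an *emulation* assembled from published group-level
statistics (e.g. high-CV-group voltage 1.47 ± 0.62 mV, cohort median
voltage 1.18 mV and CV 0.62 m/s) because per-cluster spreads are not
published anywhere; they are chosen so the clusters are recoverable but
overlapping, consistent with phenotypes that were themselves defined by
k-means in this plane. 24-month recurrence probabilities default to 0.25 /
0.33 / 0.60 per cluster; event times are exponential with the matching
24-month mass, so the expected event fraction equals the cluster
probability exactly. Patients event-free at 24 months are censored at
min(24, U(0, 36)) months — administrative close-out with uniform early
dropout, matching an observed follow-up of roughly 19 ± 11 months. This
couples censoring to event-free status; it was chosen over fully
independent censoring so the raw event fraction remains interpretable, and
it leaves Kaplan–Meier mildly optimistic-biased late in follow-up, equally
across arms. Substrate area fractions, comorbidity counts, atrial volume
index and AF type are drawn from smooth maps of the patient's voltage/CV
(calibrated to cohort medians) plus noise, giving realistic covariation
without claiming measured parameters.

The per-patient full-map pipeline simulates a planar wave at the patient's
drawn CV and an amplitude field (broad Gaussian heterogeneity multiplied
down inside fibrosis-like patches) rescaled to the drawn mean voltage, then
re-measures everything through the complete analysis chain.

What the simulator does **not** emulate: fibrillatory or re-entrant
activation, anisotropic fibre-direction conduction, catheter-contact
artefacts, fractionated/multi-deflection electrograms, spatially correlated
localisation error, and any coupling between map quality and outcome.
Passing tests therefore demonstrate correctness of the analysis chain under
sinus-rhythm-like activation with known truth, not clinical validity on
patient data.

## Problem sizes and tolerances

Verification uses a 40 mm disc at 2 mm edges (~1,500 vertices) with 2,000
mapping points for speed-sweep recovery (5% tolerance, driven by sampling
and interpolation), a 1.5 mm disc with 6,000 points for slow-patch recovery
(15% tolerance: boundary refraction plus graph metric error), 1,000 random
electrograms for annotation round-trips (1 sample / 1%), 50 seeds for
cluster recovery, and 1,000 simulations for test-size calibration (0.05 ±
0.02). The full 52-patient pipeline at 1,100 points per map runs in about
half a minute on one CPU; these sizes were chosen as the smallest at which
the respective errors are dominated by method properties rather than Monte
Carlo noise.
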