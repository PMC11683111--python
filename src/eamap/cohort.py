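"""Per-patient aggregation, stratification, statistics, and phenotype clustering.

Patients are stratified by map-mean conduction velocity (slow < 0.6 m/s,
moderate 0.6-0.8, high >= 0.8) and voltage (low < 0.5 mV, intermediate
0.5-0.75, normal >= 0.75); boundary values fall in the upper band.  The
voltage-CV association is tested with Spearman's rho; group comparisons use a
Shapiro-Wilk normality gate feeding one-way ANOVA (all groups normal, k > 2)
or Kruskal-Wallis, with the Wilcoxon rank-sum test for two groups.  Patient
phenotypes are found by k-means (k = 3) on the z-scored (mean CV, mean
voltage) plane, with cluster indices relabelled canonically: cluster 0 has
the healthiest centroid (highest voltage + CV), cluster 2 the most diseased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "PatientSummary",
    "StrataAssignment",
    "GroupComparison",
    "stratify",
    "spearman_corr",
    "compare_groups",
    "kmeans_phenotypes",
    "summaries_to_frame",
    "frame_to_summaries",
]

CV_BOUNDS = (0.6, 0.8)  # m/s: slow | moderate | high
VOLTAGE_BOUNDS = (0.5, 0.75)  # mV: low | intermediate | normal (open-ended above)


@dataclass
class PatientSummary:
    """One patient's map aggregates, covariates, and recurrence outcome."""

    patient_id: str
    group: str  # AF_paroxysmal | AF_persistent | control
    mean_bip_mV: float
    mean_uni_mV: float
    mean_cv_m_per_s: float
    area_bip_05_rel: float
    area_bip_03_rel: float
    area_cv_06_rel: float
    area_cv_04_rel: float
    n_points: int
    age_years: float = np.nan
    n_comorbidities: int = 0
    lavi_ml_per_m2: float = np.nan
    event: int = 0
    time_months: float = np.nan
    cluster_label: Optional[int] = None
    true_cluster: Optional[int] = None

    def __post_init__(self):
        for name in ("area_bip_05_rel", "area_bip_03_rel",
                     "area_cv_06_rel", "area_cv_04_rel"):
            a = getattr(self, name)
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"{name}={a} outside [0, 1]")
        if self.mean_cv_m_per_s <= 0:
            raise ValueError("mean CV must be positive")
        if np.isfinite(self.time_months) and self.time_months < 0:
            raise ValueError("follow-up time must be non-negative")


@dataclass(frozen=True)
class StrataAssignment:
    cv_band: str  # slow | moderate | high
    voltage_band: str  # low | intermediate | normal


def stratify(summary) -> StrataAssignment:
    """Assign CV and voltage bands; boundaries go to the upper band.

    Accepts a PatientSummary or any object with ``mean_cv_m_per_s`` and
    ``mean_bip_mV``.  Voltages above 1.0 mV remain ``normal`` (the band is
    open-ended so the partition covers the observed range).
    """
    cv = float(summary.mean_cv_m_per_s)
    v = float(summary.mean_bip_mV)
    if not (np.isfinite(cv) and np.isfinite(v)):
        raise ValueError("stratify needs finite mean CV and voltage")
    cv_band = "slow" if cv < CV_BOUNDS[0] else ("moderate" if cv < CV_BOUNDS[1] else "high")
    v_band = "low" if v < VOLTAGE_BOUNDS[0] else (
        "intermediate" if v < VOLTAGE_BOUNDS[1] else "normal"
    )
    return StrataAssignment(cv_band, v_band)


def spearman_corr(x: Sequence[float], y: Sequence[float]):
    """Spearman's rank correlation (average-rank ties) with large-sample p.

    Returns (rho, p).  Raises on fewer than 3 pairs or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman_corr needs >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman_corr: zero variance in an input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    """Outcome of the normality-gated group comparison."""

    test: str  # anova | kruskal_wallis | wilcoxon_rank_sum
    statistic: float
    p_value: float
    all_normal: bool
    shapiro_p: dict = field(default_factory=dict)


def compare_groups(groups: dict, alpha_normality: float = 0.05) -> GroupComparison:
    """Compare 2+ groups of values with the normality-gated pipeline.

    Shapiro-Wilk per group (alpha 0.05; groups of n < 3 count as non-normal
    since the test is undefined); if every group is normal and there are more
    than two, one-way ANOVA, otherwise Kruskal-Wallis; with exactly two
    groups the Wilcoxon rank-sum test is used regardless of normality.
    """
    names = list(groups)
    vals = [np.asarray(groups[g], dtype=float) for g in names]
    if len(vals) < 2 or any(len(v) < 2 for v in vals):
        raise ValueError("compare_groups needs >= 2 groups with n >= 2 each")
    if np.ptp(np.concatenate(vals)) == 0:
        raise ValueError("all observations identical; comparison undefined")
    shapiro_p = {}
    all_normal = True
    for g, v in zip(names, vals):
        if len(v) >= 3 and np.ptp(v) > 0:
            p = float(stats.shapiro(v).pvalue)
        else:
            p = np.nan
        shapiro_p[g] = p
        if not (p > alpha_normality):
            all_normal = False
    if len(vals) == 2:
        res = stats.ranksums(vals[0], vals[1])
        return GroupComparison("wilcoxon_rank_sum", float(res.statistic),
                               float(res.pvalue), all_normal, shapiro_p)
    if all_normal:
        res = stats.f_oneway(*vals)
        return GroupComparison("anova", float(res.statistic), float(res.pvalue),
                               all_normal, shapiro_p)
    res = stats.kruskal(*vals)
    return GroupComparison("kruskal_wallis", float(res.statistic),
                           float(res.pvalue), all_normal, shapiro_p)


def _canonical_relabel(labels: np.ndarray, centroids: np.ndarray):
    """Order clusters by centroid voltage+CV sum, descending.

    Cluster 0 becomes the healthiest phenotype (normal CV and voltage),
    the last cluster the most diseased, matching the clinical naming.
    ``centroids`` are in z-scored feature space; the sum is monotone in the
    raw means, so ordering there is equivalent.
    """
    order = np.argsort(-centroids.sum(axis=1))
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    return remap[labels], centroids[order]


def kmeans_phenotypes(
    summaries: Sequence[PatientSummary],
    k: int = 3,
    features: Sequence[str] = ("mean_cv_m_per_s", "mean_bip_mV"),
    seed: int = 0,
    n_init: int = 20,
):
    """K-means phenotyping in the (mean CV, mean voltage) plane.

    Features are z-scored; k-means++ with ``n_init`` restarts keeps the best
    inertia; labels are canonically reordered (0 = healthiest centroid).
    Returns (labels, centroids_raw_units, inertia).  Deterministic for a
    fixed seed.
    """
    X = np.array([[getattr(s, f) for f in features] for s in summaries], dtype=float)
    if len(X) < k:
        raise ValueError("need at least k patients")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("fewer distinct feature points than clusters")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**31))
    labels = km.fit_predict(Z)
    labels, centroids_z = _canonical_relabel(labels, km.cluster_centers_)
    centroids = centroids_z * sd + mu
    return labels, centroids, float(km.inertia_)


def summaries_to_frame(summaries: Sequence[PatientSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def frame_to_summaries(df: pd.DataFrame) -> list:
    cols = {f.name for f in PatientSummary.__dataclass_fields__.values()}
    out = []
    for _, row in df.iterrows():
        d = {k: v for k, v in row.items() if k in cols}
        for opt in ("cluster_label", "true_cluster"):
            if opt in d and pd.isna(d[opt]):
                d[opt] = None
            elif opt in d and d[opt] is not None:
                d[opt] = int(d[opt])
        out.append(PatientSummary(**d))
    return out
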