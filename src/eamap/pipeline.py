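"""End-to-end driver: simulate -> process -> cohort -> survival -> report.

``run_pipeline`` generates a synthetic cohort, optionally simulates and
processes a full electroanatomic map per patient (planar sinus-rhythm-like
activation at the patient's drawn conduction velocity, an amplitude field
with low-voltage patches scaled to the patient's drawn mean voltage), then
runs the cohort statistics, phenotype clustering, and survival comparisons,
writing deterministic report tables.  Two runs with the same configuration
and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import egm as _egm
from . import io as _io
from .cohort import (
    compare_groups,
    kmeans_phenotypes,
    spearman_corr,
    stratify,
    summaries_to_frame,
)
from .mapping import accepted_points, clip_regions, interpolate_field, map_summary
from .survival import SurvivalRecord, dichotomised_analysis, kaplan_meier, logrank
from .synthetic import (
    CohortSpec,
    EgmNoise,
    generate_cohort,
    make_amplitude_field,
    make_mesh,
    sample_mapping_points,
    simulate_activation,
)
from .velocity import CvConstraints, cv_field, fit_and_screen

log = logging.getLogger("eamap.pipeline")

__all__ = ["process_map", "run_pipeline", "simulate_patient_map"]


def _constraints(cfg: _io.PipelineConfig) -> CvConstraints:
    return CvConstraints(
        d_min_mm=cfg.cv_d_min_mm,
        d_max_mm=cfg.cv_d_max_mm,
        min_delta_t_ms=cfg.cv_min_delta_t_ms,
        min_cv_m_per_s=cfg.cv_min_cv_m_per_s,
        min_angle_deg=cfg.cv_min_angle_deg,
    )


def process_points(points, cfg: _io.PipelineConfig):
    """Filter, screen, and annotate every point's electrograms in place.

    Batch path: all traces of a map share one sampling rate and length, so
    filtering/annotation run on stacked arrays.  Returns the number of
    points rejected by the noise/amplitude screens.
    """
    with_traces = [p for p in points if p.bipolar is not None]
    if not with_traces:
        return 0
    fs = with_traces[0].bipolar.fs_hz
    raw = np.stack([p.bipolar.samples for p in with_traces])
    filt = _egm.bandpass_batch(raw, fs, cfg.bandpass_low_hz, cfg.bandpass_high_hz)
    ncfg = _egm.NoiseConfig(
        cfg.noise_max_out_of_band_ratio, cfg.min_peak_to_peak_mV,
        cfg.min_slope_mV_per_ms,
    )
    quality = _egm.synth_quality_batch(raw, filt, ncfg)
    t0 = np.array([p.bipolar.t0_ms for p in with_traces])
    lat, slope, slope_ok = _egm.annotate_batch(filt, fs, t0, cfg.min_slope_mV_per_ms)
    bip_ptp = filt.max(axis=1) - filt.min(axis=1)
    has_uni = all(p.unipolar is not None for p in with_traces)
    if has_uni:
        uraw = np.stack([p.unipolar.samples for p in with_traces])
        ufilt = _egm.bandpass_batch(uraw, fs, cfg.bandpass_low_hz, cfg.bandpass_high_hz)
        uni_ptp = ufilt.max(axis=1) - ufilt.min(axis=1)
    for i, p in enumerate(with_traces):
        p.lat_ms = float(lat[i])
        p.bip_mV = float(bip_ptp[i])
        if has_uni:
            p.uni_mV = float(uni_ptp[i])
        q = quality[i]
        if q == "accepted" and not slope_ok[i]:
            q = "rejected_amplitude"
        p.quality = str(q)
    n_rej = int(sum(p.quality != "accepted" for p in with_traces))
    log.info("processed %d points, rejected %d", len(with_traces), n_rej)
    return n_rej


def process_map(mesh, points, cfg: _io.PipelineConfig = None):
    """Process one annotated map into fields and a summary.

    Clips PV/LAA regions, interpolates bipolar (and unipolar) voltage from
    accepted points, estimates CV via screened Delaunay triples, interpolates
    the CV field, and returns ``(body_mesh, summary, triples)``.
    """
    cfg = cfg or _io.PipelineConfig()
    body = clip_regions(mesh)
    acc = accepted_points(points)
    if not acc:
        raise ValueError("process_map: no accepted points")
    idw = dict(
        power=cfg.idw_power,
        k_nearest=cfg.idw_k_nearest,
        snap_eps_mm=cfg.idw_snap_eps_mm,
        max_dist_mm=cfg.idw_max_dist_mm,
    )
    pos = np.stack([p.position for p in acc])
    body.fields["bip_voltage"] = interpolate_field(
        pos, np.array([p.bip_mV for p in acc]), body, **idw
    )
    if all(np.isfinite(p.uni_mV) for p in acc):
        body.fields["uni_voltage"] = interpolate_field(
            pos, np.array([p.uni_mV for p in acc]), body, **idw
        )
    triples = fit_and_screen(points, _constraints(cfg))
    n_acc = sum(t.accepted for t in triples)
    log.info("CV triples: %d fitted, %d accepted", len(triples), n_acc)
    body.fields["cv"] = cv_field(triples, body, **idw)
    summary = map_summary(body, points)
    log.info(
        "map summary: voltage %.3f mV, CV %.3f m/s, unmapped %.1f%%",
        summary.mean_bip_mV, summary.mean_cv_m_per_s,
        100 * summary.unmapped_area_frac,
    )
    return body, summary, triples


def simulate_patient_map(mesh, target_voltage_mV, target_cv_m_per_s,
                         cfg: _io.PipelineConfig, rng: np.random.Generator):
    """Simulate one patient's map matched to drawn phenotype values."""
    direction = rng.standard_normal(3)
    direction[2] = 0.0 if cfg.mesh_shape == "disc" else direction[2]
    truth = simulate_activation(
        mesh, "planar", float(np.clip(target_cv_m_per_s, 0.1, 2.5)),
        direction=direction if np.linalg.norm(direction) > 0 else (1, 0, 0),
    )
    truth.amplitude_mV = make_amplitude_field(
        mesh, mean_mV=target_voltage_mV, seed=int(rng.integers(2**31))
    )
    points = sample_mapping_points(
        mesh, truth, cfg.n_points_per_map, jitter_mm=cfg.jitter_mm,
        fs_hz=cfg.fs_hz, noise=EgmNoise(rms_mV=cfg.egm_noise_rms_mV),
        seed=int(rng.integers(2**31)),
    )
    return truth, points


def run_pipeline(cfg: _io.PipelineConfig, outdir) -> pd.DataFrame:
    """Run simulate -> process -> cohort -> survival and write reports.

    Writes ``cohort_summaries.csv``, ``cluster_report.csv``,
    ``km_curves.csv``, and ``analysis_report.json`` under ``outdir``, every
    file carrying the seed and config hash.  Returns the summary frame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash

    # ---- simulate: cohort-level truth
    spec = CohortSpec(seed=cfg.seed, sd_scale=cfg.cohort_sd_scale)
    summaries = generate_cohort(spec)
    log.info("simulated cohort of %d patients", len(summaries))

    # ---- per-patient maps (measured summaries replace drawn map metrics)
    if cfg.full_maps:
        mesh0 = make_mesh(cfg.mesh_shape, cfg.mesh_resolution_mm,
                          cfg.disc_radius_mm)
        measured = []
        for i, s in enumerate(summaries):
            rng = np.random.default_rng([cfg.seed, 7919, i])
            _, points = simulate_patient_map(
                mesh0, s.mean_bip_mV, s.mean_cv_m_per_s, cfg, rng
            )
            process_points(points, cfg)
            _, msum, _ = process_map(mesh0.copy(), points, cfg)
            measured.append(
                replace(
                    s,
                    mean_bip_mV=msum.mean_bip_mV,
                    mean_uni_mV=msum.mean_uni_mV,
                    mean_cv_m_per_s=msum.mean_cv_m_per_s,
                    area_bip_05_rel=msum.area_bip_05_rel,
                    area_bip_03_rel=msum.area_bip_03_rel,
                    area_cv_06_rel=msum.area_cv_06_rel,
                    area_cv_04_rel=msum.area_cv_04_rel,
                    n_points=msum.n_points,
                )
            )
        summaries = measured

    # ---- cohort statistics and phenotyping
    labels, centroids, inertia = kmeans_phenotypes(
        summaries, k=cfg.kmeans_k, seed=cfg.seed, n_init=cfg.kmeans_n_init
    )
    summaries = [replace(s, cluster_label=int(l)) for s, l in zip(summaries, labels)]
    volts = [s.mean_bip_mV for s in summaries]
    cvs = [s.mean_cv_m_per_s for s in summaries]
    rho, rho_p = spearman_corr(volts, cvs)
    by_type = {
        g: [s.mean_bip_mV for s in summaries if s.group == g]
        for g in ("AF_paroxysmal", "AF_persistent")
    }
    type_cmp = compare_groups(by_type)
    by_cluster = {
        f"cluster_{c}": [s.mean_bip_mV for s in summaries if s.cluster_label == c]
        for c in sorted({s.cluster_label for s in summaries})
    }
    cluster_cmp = compare_groups(by_cluster)
    strata = [stratify(s) for s in summaries]
    strata_counts = {
        "cv": {b: sum(a.cv_band == b for a in strata) for b in ("slow", "moderate", "high")},
        "voltage": {b: sum(a.voltage_band == b for a in strata)
                    for b in ("low", "intermediate", "normal")},
    }

    # ---- survival
    records = [
        SurvivalRecord(s.patient_id, s.time_months, s.event,
                       f"cluster_{s.cluster_label}")
        for s in summaries
    ]
    km_frames = []
    km_at = {}
    for c in sorted({r.stratum for r in records}):
        km = kaplan_meier([r for r in records if r.stratum == c])
        f = km.to_frame()
        f.insert(0, "stratum", c)
        km_frames.append(f)
        km_at[c] = {"n": km.n, "S_12": km.at(12.0), "S_24": km.at(24.0)}
    pairwise = {}
    clusters = sorted({r.stratum for r in records})
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            sub = [r for r in records if r.stratum in (clusters[i], clusters[j])]
            if sum(r.event for r in sub):
                chi2, _, p = logrank(sub)
                pairwise[f"{clusters[i]}_vs_{clusters[j]}"] = {
                    "chi2": chi2, "p": p,
                }
    dichot = dichotomised_analysis(
        summaries, cfg.cv_cut_m_per_s, cfg.voltage_cut_mV
    )

    # ---- report
    df = summaries_to_frame(summaries)
    _io.write_cohort_table(outdir / "cohort_summaries.csv", df, cfg.seed, chash)
    cdf = pd.DataFrame(
        {
            "cluster": range(len(centroids)),
            "n": [int((labels == c).sum()) for c in range(len(centroids))],
            "centroid_cv_m_per_s": centroids[:, 0],
            "centroid_voltage_mV": centroids[:, 1],
        }
    )
    _io.write_cohort_table(outdir / "cluster_report.csv", cdf, cfg.seed, chash)
    _io.write_cohort_table(
        outdir / "km_curves.csv", pd.concat(km_frames, ignore_index=True),
        cfg.seed, chash,
    )
    report = {
        "seed": cfg.seed,
        "config_hash": chash,
        "n_patients": len(summaries),
        "spearman": {"rho": rho, "p": rho_p},
        "voltage_by_af_type": asdict(type_cmp),
        "voltage_by_cluster": asdict(cluster_cmp),
        "strata_counts": strata_counts,
        "kmeans": {"inertia": inertia,
                   "sizes": {str(c): int((labels == c).sum())
                             for c in range(cfg.kmeans_k)}},
        "km_by_cluster": km_at,
        "logrank_pairwise": pairwise,
        "dichotomised": dichot,
    }
    (outdir / "analysis_report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2, allow_nan=True)
    )
    cfg.to_file(outdir / "config_used.yaml")
    log.info("pipeline complete: %d patients -> %s", len(summaries), outdir)
    return df
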