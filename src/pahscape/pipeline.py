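"""End-to-end pipeline: plates -> landscapes -> fits -> QC -> subpopulations -> clinic.

The stages mirror the assay's evaluation order.  ``process_cohort`` turns raw
replicate plates into per-genotype %WT landscapes, Gaussian fits, peak
features, the no-residual-activity (subpopulation 0) flag, and QC reports
with cohort-calibrated thresholds.  ``cluster_cohort`` consensus-clusters the
QC-passing residual-activity genotypes and names the clusters.
``run_pipeline`` drives everything from a config and writes tidy TSV/JSON
outputs (and optional figures) to a directory.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from .cluster import (
    ConsensusResult,
    FeatureMatrix,
    SubpopulationAssignment,
    SubpopulationNamingError,
    build_feature_matrix,
    consensus_cluster,
    name_subpopulations,
)
from .grids import ConcentrationGrid
from .model import PeakFeatures, artifact_filter, extract_features, fit_gaussian
from .plates import ActivityLandscape, PlateReplicate, background_subtract, landscape_to_long, median_landscape, normalize_to_wt
from .qc import DEFAULT_THRESHOLDS, QCReport, calibrate_thresholds, compute_rmse, count_peaks, qc_gate, replicate_variation
from .simulate import DEFAULT_COHORT_COMPOSITION, NoiseModel, SimulatedCohort, simulate_clinical, simulate_cohort


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    cohort_composition: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_COMPOSITION))
    plates_path: str | None = None  # read plates from file(s) instead of simulating
    clinical_path: str | None = None  # read clinical table instead of simulating
    qc_calibrate: bool = True
    qc_thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    qc_borderline_band: float = 0.10
    cluster_k_range: tuple[int, int] = (2, 8)
    cluster_n_resamples: int = 250
    cluster_subsample_fraction: float = 0.8
    cluster_n_restarts: int = 1
    knn_k: int = 5
    min_clinical_records: int = 10
    render: bool = False
    gamma: float = 0.4

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class CohortResults:
    """Per-genotype products of plate processing, fitting, and QC."""

    landscapes: dict[str, ActivityLandscape]  # %WT median landscapes
    wt_fits: dict[str, object]  # run_id -> GaussianFit of that run's WT
    fits: dict[str, object]
    features: dict[str, PeakFeatures]
    subpop0: dict[str, bool]
    qc: dict[str, QCReport]
    thresholds: tuple[float, float, float]


def process_genotype(
    sample_reps: list[PlateReplicate],
    wt_reps: list[PlateReplicate],
    no_dna_reps: list[PlateReplicate],
) -> ActivityLandscape:
    """Normalize each replicate against its batch-matched controls; take the median."""
    if not (len(sample_reps) == len(wt_reps) == len(no_dna_reps)):
        raise ValueError("sample/WT/no-DNA replicate counts differ")
    normalized = [normalize_to_wt(s, w, n) for s, w, n in zip(sample_reps, wt_reps, no_dna_reps)]
    return median_landscape(normalized, units="percent_wt")


def process_cohort(cohort: SimulatedCohort, qc_calibrate: bool = True,
                   qc_thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
                   qc_borderline_band: float = 0.10) -> CohortResults:
    """Plates to landscapes, fits, features, subpopulation-0 flags, and QC reports.

    QC thresholds are calibrated from the distributions of the three
    statistics over the residual-activity cohort (3x mean, the exponential
    rule) unless ``qc_calibrate`` is False, in which case the published
    defaults (or the supplied constants) gate directly.
    """
    wt_fits = {}
    for run_id, wt_reps in cohort.wt_replicates.items():
        wt_landscape = process_genotype(wt_reps, wt_reps, cohort.no_dna_replicates[run_id])
        wt_fits[run_id] = fit_gaussian(wt_landscape)
        if not wt_fits[run_id].converged:
            raise RuntimeError(f"stage fit: wild-type fit failed in run {run_id}")

    landscapes, fits, features, subpop0 = {}, {}, {}, {}
    stats: dict[str, tuple[float, int, float, bool]] = {}
    for gid, reps in sorted(cohort.replicates.items()):
        run_id = cohort.run_of[gid]
        landscape = process_genotype(reps, cohort.wt_replicates[run_id], cohort.no_dna_replicates[run_id])
        fit = fit_gaussian(landscape)
        feat = extract_features(fit, wt_fits[run_id], genotype_id=gid, grid=landscape.grid)
        landscapes[gid], fits[gid], features[gid] = landscape, fit, feat
        subpop0[gid] = artifact_filter(feat)
        rmse = compute_rmse(landscape, fit)
        nop = count_peaks(landscape)
        vt, vt_flag = replicate_variation(reps)
        stats[gid] = (rmse, nop, vt, vt_flag)

    thresholds = tuple(qc_thresholds)
    if qc_calibrate:
        eligible = [g for g in stats if not subpop0[g] and math.isfinite(stats[g][0])]
        if len(eligible) >= 2:
            calibrated = []
            for i, fallback in enumerate(thresholds):
                try:
                    calibrated.append(calibrate_thresholds([stats[g][i] for g in eligible]))
                except ValueError:  # degenerate (all-zero) statistic, e.g. noiseless data
                    calibrated.append(fallback)
            thresholds = tuple(calibrated)
    qc = {
        gid: qc_gate(gid, rmse, nop, vt, thresholds=thresholds,
                     borderline_band=qc_borderline_band, vt_no_eligible_wells=vt_flag)
        for gid, (rmse, nop, vt, vt_flag) in stats.items()
    }
    return CohortResults(landscapes=landscapes, wt_fits=wt_fits, fits=fits,
                         features=features, subpop0=subpop0, qc=qc, thresholds=thresholds)


def cluster_cohort(
    results: CohortResults,
    seed: int = 0,
    k_range: range | tuple[int, ...] = range(2, 9),
    n_resamples: int = 250,
    subsample_fraction: float = 0.8,
    n_restarts: int = 1,
) -> tuple[FeatureMatrix, ConsensusResult, dict[int, int] | None, dict[str, SubpopulationAssignment]]:
    """Cluster QC-passing residual-activity genotypes; name and assemble assignments.

    Subpopulation-0 genotypes are assigned directly from the artifact filter.
    Returns ``(feature_matrix, consensus, cluster_name_map, assignments)``;
    the name map is None (clusters unnamed) when k != 5 or the naming rules
    fail, in which case raw cluster ids are reported as negative labels.
    """
    clusterable = [
        results.features[g]
        for g in sorted(results.features)
        if not results.subpop0[g] and results.qc[g].status != "fail"
    ]
    fm = build_feature_matrix(clusterable)
    consensus = consensus_cluster(
        fm, k_range=k_range, n_resamples=n_resamples,
        subsample_fraction=subsample_fraction, seed=seed, n_restarts=n_restarts,
    )
    # WT reference for the left/right-shift rule: pooled cohort WT fit medians
    wt_phe = float(np.median([math.exp(f.mx_prime) for f in results.wt_fits.values()]))
    wt_ref = PeakFeatures("WT", 100.0, wt_phe, math.nan, math.nan, math.nan, math.nan, True)
    try:
        mapping = name_subpopulations(consensus, fm, wt_ref)
    except SubpopulationNamingError:
        mapping = None

    assignments: dict[str, SubpopulationAssignment] = {}
    for gid, flagged in results.subpop0.items():
        if flagged:
            assignments[gid] = SubpopulationAssignment(gid, 0, "artifact_filter")
    for gid, cluster in zip(consensus.genotype_ids, consensus.labels):
        label = mapping[int(cluster)] if mapping else -int(cluster)
        assignments[gid] = SubpopulationAssignment(gid, label, "consensus")
    return fm, consensus, mapping, assignments


# ---------------------------------------------------------------------------
# Disk-facing driver


def _features_frame(results: CohortResults) -> pd.DataFrame:
    rows = []
    for gid in sorted(results.features):
        f, fit, q = results.features[gid], results.fits[gid], results.qc[gid]
        rows.append(
            {
                "genotype_id": gid,
                "activity_max_pct_wt": f.activity_max_pct_wt,
                "phe_peak_uM": f.phe_peak_uM,
                "bh4_peak_uM": f.bh4_peak_uM,
                "wr_low_uM": f.working_range_low_uM,
                "wr_high_uM": f.working_range_high_uM,
                "wr_width_uM": f.working_range_width_uM,
                "subpop0_flag": results.subpop0[gid],
                "converged": fit.converged,
                "rmse_fit": fit.rmse_fit,
                "qc_status": q.status,
            }
        )
    return pd.DataFrame(rows)


def _qc_frame(results: CohortResults) -> pd.DataFrame:
    rows = []
    for gid in sorted(results.qc):
        q = results.qc[gid]
        rows.append(
            {
                "genotype_id": gid,
                "rmse": q.rmse,
                "nop": q.nop,
                "vt": q.vt,
                "rmse_thr": q.thresholds[0],
                "nop_thr": q.thresholds[1],
                "vt_thr": q.thresholds[2],
                "status": q.status,
                "failed_features": ";".join(q.failed_features),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write TSV/JSON outputs; returns the output directory.

    The pipeline is a pure function of (inputs, config, seed): reruns with the
    same config produce identical tables.  Any stage error is re-raised tagged
    with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: plates
    if config.plates_path:
        raise NotImplementedError(
            "stage plates: reading a pre-assembled cohort from disk is driven via "
            "plates.read_plate_table; run_pipeline currently drives the synthetic study"
        )
    cohort = simulate_cohort(config.cohort_composition, seed=config.seed)

    # --- stage: fit + qc
    results = process_cohort(
        cohort,
        qc_calibrate=config.qc_calibrate,
        qc_thresholds=config.qc_thresholds,
        qc_borderline_band=config.qc_borderline_band,
    )
    long = pd.concat([landscape_to_long(results.landscapes[g]) for g in sorted(results.landscapes)])
    long.to_csv(out / "landscapes.tsv", sep="\t", index=False)
    _features_frame(results).to_csv(out / "features.tsv", sep="\t", index=False, float_format="%.6g")
    _qc_frame(results).to_csv(out / "qc.tsv", sep="\t", index=False, float_format="%.6g")

    # --- stage: cluster
    lo, hi = config.cluster_k_range
    fm, consensus, mapping, assignments = cluster_cohort(
        results,
        seed=config.seed,
        k_range=range(lo, hi + 1),
        n_resamples=config.cluster_n_resamples,
        subsample_fraction=config.cluster_subsample_fraction,
        n_restarts=config.cluster_n_restarts,
    )
    pd.DataFrame(
        {
            "genotype_id": list(assignments),
            "label": [a.label for a in assignments.values()],
            "source": [a.source for a in assignments.values()],
        }
    ).sort_values("genotype_id").to_csv(out / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(consensus.consensus_matrix, index=consensus.genotype_ids, columns=consensus.genotype_ids).to_csv(
        out / "consensus_matrix.tsv", sep="\t", float_format="%.4f"
    )
    pd.DataFrame(
        {"k": list(consensus.stability_by_k), "pac": list(consensus.stability_by_k.values())}
    ).to_csv(out / "stability_by_k.tsv", sep="\t", index=False)

    # --- stage: clinical (optional)
    labels = {g: a.label for g, a in assignments.items()}
    if config.clinical_path:
        records = clin.read_clinical_table(config.clinical_path)
    else:
        records = simulate_clinical(labels, seed=config.seed)
    records = [r for r in records if r.genotype_id in labels]
    ph = clin.filter_records(records, config.min_clinical_records, "phenotype")
    rs = clin.filter_records(records, config.min_clinical_records, "response")
    summaries = clin.summarize_subpopulations(labels, ph)
    clin.summaries_to_frame(summaries).to_csv(out / "subpopulation_summary.tsv", sep="\t", index=False, float_format="%.6g")
    interp = {
        str(lab): {
            "interpretation": clin.INTERPRETATION_TEXT.get(lab, "unnamed cluster"),
            "n_genotypes": sum(1 for a in assignments.values() if a.label == lab),
        }
        for lab in sorted({a.label for a in assignments.values()})
    }
    (out / "interpretation.json").write_text(json.dumps(interp, indent=2))

    nonresp = clin.residual_activity_vs_response(labels, rs)
    log = {
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "n_genotypes": len(cohort.replicates),
        "k_selected": consensus.k_selected,
        "qc_thresholds": list(results.thresholds),
        "nonresponder_fraction_residual": nonresp,
        "named": mapping is not None,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    # --- stage: render (optional)
    if config.render:
        from .plotting import render_landscape

        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        for gid in sorted(results.landscapes):
            render_landscape(
                results.landscapes[gid], results.fits[gid], gamma=config.gamma,
                path=figdir / f"{gid}.png",
            )
    return out
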