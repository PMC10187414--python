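"""End-to-end pipelines: rest segmentation, task segmentation, association.

Chains the stage modules into the two analysis pipelines plus the
association step, governed by a single :class:`PipelineConfig` whose
defaults are the full-scale study parameters (50 × 833 subject-level
resampling, 100 × 1000 group-level, thresholds .50/.25, 32 ms smoothing
window with Besag factor 10, 32 ms minimum segment).  Reduced settings
for desk-scale synthetic runs are just alternative configs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .backfit import (
    Segmentation,
    backfit,
    refresh_correlations,
    reject_small_segments,
    smooth_labels,
    temporal_parameters,
)
from .clustering import (
    MicrostateSet,
    extract_gfp_peak_topographies,
    group_level_clustering,
    identify_error_microstate,
    segment_grand_average,
    subject_level_resampling,
)
from .core import EEGRecording, normalize_by_median_gfp, spatial_filter
from .ern import (
    ErpAverage,
    difference_wave,
    epoch_average,
    mean_amplitude,
    residualize_ern,
    select_ern_roi,
)
from .simulate import Cohort

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All stage parameters in one reproducible record."""

    seed: int = 0
    spatial_filter_g: int = 6
    # subject-level resampled clustering
    subject_epochs: int = 50
    subject_subsamples: int = 833
    subject_k_max: int = 12
    subject_restarts: int = 50
    # group-level two-stage clustering
    group_epochs: int = 100
    group_sets: int = 1000
    group_k_max: int = 15
    group_restarts: int = 100
    # task (ERP) segmentation
    task_k_max: int = 20
    task_restarts: int = 300
    # backfitting / smoothing
    min_corr_rest: float = 0.50
    min_corr_task: float = 0.25
    smooth_half_ms: float = 32.0
    besag_factor: float = 10.0
    min_segment_ms: float = 32.0
    # ERN quantification
    roi_size: int = 5
    baseline_ms: tuple[float, float] = (-500.0, -300.0)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "baseline_ms" in raw:
            raw["baseline_ms"] = tuple(raw["baseline_ms"])
        return cls(**raw)

    def hash(self) -> str:
        return eio.config_hash(dataclasses.asdict(self))


#: a configuration sized for synthetic desk-scale runs
def reduced_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(
        seed=seed,
        subject_epochs=10,
        subject_subsamples=200,
        subject_restarts=8,
        group_epochs=20,
        group_sets=200,
        group_restarts=20,
        task_restarts=50,
    )


@dataclass
class RestResult:
    group_maps: MicrostateSet
    stats: pd.DataFrame  # one row per (subject, microstate)
    segmentations: dict[str, Segmentation]


def run_rest_pipeline(cohort: Cohort, config: PipelineConfig) -> RestResult:
    """Resting pipeline: filter → GFP peaks → resampled clustering →
    group templates → median-GFP normalization → backfit → smooth →
    segment repair → temporal parameters."""
    ss = np.random.SeedSequence(config.seed).spawn(len(cohort.subjects) + 1)
    all_sets = []
    filtered: dict[str, EEGRecording] = {}
    for subj, s in zip(cohort.subjects, ss[:-1]):
        rec = spatial_filter(subj.rest, g=config.spatial_filter_g)
        filtered[subj.subject_id] = rec
        peaks = extract_gfp_peak_topographies(rec)
        all_sets.append(
            subject_level_resampling(
                peaks,
                n_epochs=config.subject_epochs,
                n_subsamples=config.subject_subsamples,
                k_grid=range(1, config.subject_k_max + 1),
                kmeans_restarts=config.subject_restarts,
                seed=s,
            )
        )
    group = group_level_clustering(
        all_sets,
        stage1_epochs=config.group_epochs,
        stage1_sets=config.group_sets,
        k_grid=range(1, config.group_k_max + 1),
        restarts=config.group_restarts,
        seed=ss[-1],
    )

    rows = []
    segs: dict[str, Segmentation] = {}
    for subj in cohort.subjects:
        rec = normalize_by_median_gfp(filtered[subj.subject_id])
        seg = backfit(rec, group, min_corr=config.min_corr_rest, polarity_mode="invariant")
        seg = smooth_labels(
            seg,
            rec,
            group,
            window_half_size_ms=config.smooth_half_ms,
            besag_factor=config.besag_factor,
        )
        seg = reject_small_segments(seg, min_dur_ms=config.min_segment_ms)
        seg = refresh_correlations(seg, rec, group)
        stats = temporal_parameters(seg, rec, group)
        df = stats.to_frame()
        df.insert(0, "subject_id", subj.subject_id)
        rows.append(df)
        segs[subj.subject_id] = seg
    return RestResult(group, pd.concat(rows, ignore_index=True), segs)


@dataclass
class TaskResult:
    error_window_ms: tuple[float, float]
    error_template: np.ndarray
    error_label: int
    erp_maps: MicrostateSet
    roi_channels: list[str]
    ern_table: pd.DataFrame  # subject_id, mean_go, mean_nogo, ern_resid, gev_error_ms
    grand_difference: ErpAverage


def run_task_pipeline(cohort: Cohort, config: PipelineConfig) -> TaskResult:
    """Task pipeline: response-locked averaging → grand-average difference
    wave → sequential segmentation → error-microstate identification →
    window-restricted per-subject backfit → microstate-guided ERN →
    residualization."""
    montage = cohort.montage
    diffs: dict[str, ErpAverage] = {}
    avgs: dict[str, tuple[ErpAverage, ErpAverage]] = {}
    for subj in cohort.subjects:
        avg_c = epoch_average(subj.correct)
        avg_e = epoch_average(subj.error)
        # raw averages are kept for amplitude measurement; the spatial
        # filter (a topographic outlier remover) feeds only the
        # segmentation / backfitting path
        avgs[subj.subject_id] = (avg_c, avg_e)
        fc = spatial_filter(EEGRecording(avg_c.data, avg_c.rate, montage), config.spatial_filter_g)
        fe = spatial_filter(EEGRecording(avg_e.data, avg_e.rate, montage), config.spatial_filter_g)
        filt_c = ErpAverage(fc.data, avg_c.times_ms, avg_c.rate, avg_c.condition, avg_c.n_trials)
        filt_e = ErpAverage(fe.data, avg_e.times_ms, avg_e.rate, avg_e.condition, avg_e.n_trials)
        diffs[subj.subject_id] = difference_wave(filt_e, filt_c)

    ids = [s.subject_id for s in cohort.subjects]
    grand = ErpAverage(
        np.mean([diffs[i].data for i in ids], axis=0),
        diffs[ids[0]].times_ms,
        diffs[ids[0]].rate,
        "difference",
        len(ids),
    )
    erp_seg = segment_grand_average(
        grand.data,
        grand.times_ms,
        exclude_window=config.baseline_ms,
        k_grid=range(1, config.task_k_max + 1),
        restarts=config.task_restarts,
        seed=np.random.SeedSequence(config.seed).spawn(1)[0],
    )
    (w0, w1), template, label = identify_error_microstate(erp_seg)
    roi = select_ern_roi(template, montage, n_roi=config.roi_size)

    window_mask = (grand.times_ms >= w0) & (grand.times_ms <= w1)
    rows = []
    for subj in cohort.subjects:
        diff = diffs[subj.subject_id]
        seg = backfit(
            diff.data,
            erp_seg.mset,
            min_corr=config.min_corr_task,
            polarity_mode="variant",
            rate=diff.rate,
            window_mask=window_mask,
        )
        stats = temporal_parameters(seg, diff.data, erp_seg.mset)
        avg_c, avg_e = avgs[subj.subject_id]
        rows.append(
            {
                "subject_id": subj.subject_id,
                "mean_go": mean_amplitude(avg_c, (w0, w1), roi, montage),
                "mean_nogo": mean_amplitude(avg_e, (w0, w1), roi, montage),
                "gev_error_ms": stats.gev[label],
            }
        )
    tab = pd.DataFrame(rows)
    tab["ern_resid"] = residualize_ern(tab["mean_go"].to_numpy(), tab["mean_nogo"].to_numpy())
    return TaskResult((w0, w1), template, label, erp_seg.mset, roi, tab, grand)


def build_cohort_table(
    cohort: Cohort,
    rest: RestResult,
    task: TaskResult,
    rest_map_a: int,
    rest_map_b: int | None = None,
) -> pd.DataFrame:
    """Assemble the per-subject analysis table for the association battery."""
    gev_wide = rest.stats.pivot(index="subject_id", columns="microstate", values="gev")
    gev_wide.columns = [f"gev_rest_{c}" for c in gev_wide.columns]
    tab = cohort.covariates.merge(gev_wide.reset_index(), on="subject_id").merge(
        task.ern_table, on="subject_id"
    )
    tab["gev_rest_a"] = tab[f"gev_rest_{rest_map_a}"]
    if rest_map_b is not None:
        tab["gev_rest_b"] = tab[f"gev_rest_{rest_map_b}"]
    return tab


def write_cohort_bundle(cohort: Cohort, out_dir, seed=None, config: PipelineConfig | None = None):
    """Write a cohort to disk as plain-text files plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=False)
    eio.write_sfp(cohort.montage, out / "montage.sfp")
    eio.write_microstate_set(
        cohort.maps, out / "ground_truth_maps.tsv", cohort.montage.channel_ids
    )
    cohort.covariates.to_csv(out / "covariates.csv", index=False)
    for subj in cohort.subjects:
        d = out / subj.subject_id
        d.mkdir()
        eio.write_recording(subj.rest, d / "rest.txt")
        np.savetxt(d / "rest_labels.txt", subj.rest_truth.true_labels, fmt="%d")
        if subj.correct is not None:
            eio.write_epochs(
                subj.correct.data, subj.correct.times_ms, subj.correct.rate, "correct_go",
                d / "epochs_correct.txt",
            )
            eio.write_epochs(
                subj.error.data, subj.error.times_ms, subj.error.rate, "error_nogo",
                d / "epochs_error.txt",
            )
    manifest = {
        "tool": "ernstates",
        "version": __version__,
        "seed": seed,
        "n_subjects": len(cohort.subjects),
        "spec": dataclasses.asdict(cohort.spec),
        "config_hash": config.hash() if config else None,
        "ground_truth": {
            "snr": cohort.spec.snr,
            "mean_segment_ms": cohort.spec.mean_segment_ms,
            "coupling_rho": cohort.spec.coupling_rho,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out / "manifest.json"
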