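"""Backfitting group templates to individual data and temporal parameters.

Backfitting assigns every sample of a recording (or ERP) to the group
template it correlates with best, subject to a minimum-correlation
threshold; temporal smoothing and small-segment repair then clean the
label sequence, and per-microstate temporal parameters (GEV, duration,
coverage, occurrence) summarize it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import MicrostateSet
from .core import EXCLUDED, UNASSIGNED, EEGRecording, compute_gfp


@dataclass
class Segmentation:
    """Per-sample microstate labelling of a recording or ERP.

    ``labels`` holds a template index per sample, or the sentinels
    UNASSIGNED (below the correlation threshold / zero GFP) and EXCLUDED
    (outside the analysis window).  ``corr`` is the winning spatial
    correlation per sample (NaN where not labelled).
    """

    labels: np.ndarray
    corr: np.ndarray
    rate: float
    n_states: int
    smoothing_converged: bool = True

    @property
    def segments(self) -> list[tuple[int, int, int]]:
        """Maximal runs of constant label: (label, start, stop_exclusive).

        Runs of UNASSIGNED are reported too; EXCLUDED stretches are not.
        """
        out = []
        n = len(self.labels)
        i = 0
        while i < n:
            if self.labels[i] == EXCLUDED:
                i += 1
                continue
            j = i
            while j + 1 < n and self.labels[j + 1] == self.labels[i]:
                j += 1
            out.append((int(self.labels[i]), i, j + 1))
            i = j + 1
        return out

    def to_frame(self, times_ms: np.ndarray | None = None) -> pd.DataFrame:
        t = (
            np.asarray(times_ms, dtype=float)
            if times_ms is not None
            else np.arange(len(self.labels)) / self.rate * 1000.0
        )
        return pd.DataFrame({"time_ms": t, "label": self.labels, "corr": self.corr})


@dataclass
class TemporalStats:
    """Per-microstate temporal parameters of a segmentation."""

    gev: np.ndarray  # fraction of GFP-weighted variance explained
    mean_duration_ms: np.ndarray
    coverage_pct: np.ndarray
    occurrence_per_s: np.ndarray
    never_assigned: np.ndarray  # bool flag per state

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "microstate": np.arange(len(self.gev)),
                "gev": self.gev,
                "mean_duration_ms": self.mean_duration_ms,
                "coverage_pct": self.coverage_pct,
                "occurrence_per_s": self.occurrence_per_s,
                "never_assigned": self.never_assigned,
            }
        )


def _correlation_matrix(data: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Spatial correlations of every sample (column) with every template row."""
    X = data - data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        V = np.where(norms > 0, X / norms, 0.0)
    T = templates - templates.mean(axis=1, keepdims=True)
    T = T / np.linalg.norm(T, axis=1, keepdims=True)
    return np.clip(T @ V, -1.0, 1.0).T  # (n_samples, K)


def backfit(
    data: np.ndarray | EEGRecording,
    maps: MicrostateSet,
    min_corr: float = 0.5,
    polarity_mode: str | None = None,
    rate: float | None = None,
    window_mask: np.ndarray | None = None,
) -> Segmentation:
    """Label every sample with its best-correlating template.

    In invariant mode the winner maximizes \\|corr\\| (map polarity ignored,
    resting default threshold .50); in variant mode the winner maximizes
    the signed correlation (ERP default threshold .25) and the threshold
    applies to the winner's correlation magnitude.  Samples below
    threshold, or with zero GFP, become UNASSIGNED; samples outside an
    optional restriction window become EXCLUDED.
    """
    if isinstance(data, EEGRecording):
        rate = data.rate
        arr = data.data
    else:
        arr = np.asarray(data, dtype=float)
        if rate is None:
            raise ValueError("rate required when passing a bare array")
    if polarity_mode is None:
        polarity_mode = maps.polarity_mode
    if arr.shape[0] != maps.n_channels:
        raise ValueError("data and templates have different channel counts")

    C = _correlation_matrix(arr, maps.templates)
    n = C.shape[0]
    if polarity_mode == "invariant":
        winners = np.argmax(np.abs(C), axis=1)
    else:
        winners = np.argmax(C, axis=1)
    cwin = C[np.arange(n), winners]
    mag = np.abs(cwin)

    labels = winners.astype(int)
    corr = mag if polarity_mode == "invariant" else cwin

    gfp = compute_gfp(arr)
    dead = gfp == 0
    low = mag < min_corr
    labels[low | dead] = UNASSIGNED
    corr = corr.astype(float)
    corr[low | dead] = np.nan
    n_dead = int(dead.sum())
    if n_dead:
        warnings.warn(f"{n_dead} zero-GFP samples left UNASSIGNED")
    if window_mask is not None:
        window_mask = np.asarray(window_mask, dtype=bool)
        labels[~window_mask] = EXCLUDED
        corr[~window_mask] = np.nan
    return Segmentation(labels, corr, float(rate), maps.k)


def smooth_labels(
    seg: Segmentation,
    data: np.ndarray | EEGRecording,
    maps: MicrostateSet,
    window_half_size_ms: float = 32.0,
    besag_factor: float = 10.0,
    max_sweeps: int = 20,
) -> Segmentation:
    """Temporal smoothing of a label sequence (windowed Besag-style penalty).

    Each labelled sample's label is iteratively re-chosen to maximize

        corr²(u_t, T_k) + λ · n_k(t) / (2·w)

    where n_k(t) counts currently-k-labelled samples within ±w samples
    (w from ``window_half_size_ms``) and λ = besag_factor × mean winning
    corr² / 10, so the documented Besag factor of 10 weights temporal
    agreement about as strongly as topographic fit.  Sweeps run to a fixed
    point or ``max_sweeps``; UNASSIGNED/EXCLUDED samples never change.
    A besag_factor of 0 is a no-op.
    """
    arr = data.data if isinstance(data, EEGRecording) else np.asarray(data, dtype=float)
    if besag_factor == 0:
        return Segmentation(
            seg.labels.copy(), seg.corr.copy(), seg.rate, seg.n_states, True
        )
    w = max(1, int(round(window_half_size_ms * seg.rate / 1000.0)))
    C = _correlation_matrix(arr, maps.templates)
    C2 = C**2
    labels = seg.labels.copy()
    movable = labels >= 0
    if not movable.any():
        return Segmentation(labels, seg.corr.copy(), seg.rate, seg.n_states, True)
    n = len(labels)
    lam = besag_factor * float(np.mean(C2[np.arange(n)[movable], labels[movable]])) / 10.0
    K = maps.k
    converged = False
    for _ in range(max_sweeps):
        # windowed same-label counts per state via cumulative sums
        onehot = np.zeros((n, K))
        onehot[movable, labels[movable]] = 1.0
        cs = np.cumsum(np.vstack([np.zeros(K), onehot]), axis=0)
        lo = np.maximum(np.arange(n) - w, 0)
        hi = np.minimum(np.arange(n) + w + 1, n)
        counts = cs[hi] - cs[lo] - onehot  # exclude the sample itself
        score = C2 + lam * counts / (2.0 * w)
        new = labels.copy()
        new[movable] = np.argmax(score[movable], axis=1)
        if np.array_equal(new, labels):
            converged = True
            break
        labels = new
    if not converged:
        warnings.warn("label smoothing did not reach a fixed point; returning current state")
    corr = seg.corr.copy()
    sgn = C if maps.polarity_mode == "variant" else np.abs(C)
    corr[movable] = sgn[np.arange(n), labels][movable]
    return Segmentation(labels, corr, seg.rate, seg.n_states, converged)


def reject_small_segments(
    seg: Segmentation,
    min_dur_ms: float = 32.0,
    iterate: bool = True,
) -> Segmentation:
    """Repair improbably small segments by splitting them between neighbours.

    Every maximal run shorter than ``min_dur_ms`` (strictly, in samples:
    shorter than ceil(min_dur_ms·rate/1000)) is divided in half: the first
    ⌈n/2⌉ samples take the preceding segment's label, the rest the
    following segment's.  A short run at a recording boundary merges
    entirely into its single neighbour.  By default the rule repeats until
    no short segment remains (splits can create new short runs);
    ``iterate=False`` gives single-pass behaviour.
    """
    min_samples = int(np.ceil(min_dur_ms * seg.rate / 1000.0))
    labels = seg.labels.copy()
    n = len(labels)

    # process each contiguous non-EXCLUDED stretch independently
    def _repair(stretch: np.ndarray) -> np.ndarray:
        runs: list[list[int]] = []  # [label, length]
        for lab in stretch:
            if runs and runs[-1][0] == lab:
                runs[-1][1] += 1
            else:
                runs.append([int(lab), 1])
        if len(runs) == 1:
            if runs[0][1] < min_samples:
                warnings.warn("stretch shorter than the minimum duration; left unchanged")
            return stretch
        passes = 0
        while True:
            changed = False
            i = 0
            while i < len(runs):
                lab, length = runs[i]
                if length >= min_samples:
                    i += 1
                    continue
                if i == 0:
                    runs[1][1] += length
                    del runs[0]
                elif i == len(runs) - 1:
                    runs[-2][1] += length
                    del runs[-1]
                else:
                    first = -(-length // 2)  # ceil: extra sample to the preceding run
                    runs[i - 1][1] += first
                    runs[i + 1][1] += length - first
                    del runs[i]
                # merge neighbours that became equal-labelled
                j = max(i - 1, 0)
                while j + 1 < len(runs):
                    if runs[j][0] == runs[j + 1][0]:
                        runs[j][1] += runs[j + 1][1]
                        del runs[j + 1]
                    else:
                        j += 1
                changed = True
                if len(runs) == 1:
                    break
                i = max(i - 1, 0)
            passes += 1
            if not changed or not iterate or len(runs) == 1:
                break
        return np.concatenate([np.full(length, lab) for lab, length in runs])

    i = 0
    while i < n:
        if labels[i] == EXCLUDED:
            i += 1
            continue
        j = i
        while j + 1 < n and labels[j + 1] != EXCLUDED:
            j += 1
        labels[i : j + 1] = _repair(labels[i : j + 1])
        i = j + 1
    corr = np.where(labels == seg.labels, seg.corr, np.nan)
    return Segmentation(labels, corr, seg.rate, seg.n_states, seg.smoothing_converged)


def refresh_correlations(
    seg: Segmentation, data: np.ndarray | EEGRecording, maps: MicrostateSet
) -> Segmentation:
    """Recompute per-sample correlations to the currently assigned template."""
    arr = data.data if isinstance(data, EEGRecording) else np.asarray(data, dtype=float)
    C = _correlation_matrix(arr, maps.templates)
    sgn = C if maps.polarity_mode == "variant" else np.abs(C)
    corr = np.full(len(seg.labels), np.nan)
    m = seg.labels >= 0
    corr[m] = sgn[np.arange(len(seg.labels)), np.clip(seg.labels, 0, None)][m]
    return Segmentation(seg.labels.copy(), corr, seg.rate, seg.n_states, seg.smoothing_converged)


def temporal_parameters(
    seg: Segmentation,
    data: np.ndarray | EEGRecording,
    maps: MicrostateSet,
    gev_denominator: str = "all",
) -> TemporalStats:
    """Per-microstate GEV, mean duration, coverage, and occurrence.

    GEV_k = Σ_{t: L(t)=k} (GFP(t)·corr(u_t, T_k))² / Σ_t GFP(t)², the sum
    in the denominator running over all eligible (non-EXCLUDED) samples by
    default (``gev_denominator="all"``) or over labelled samples only
    (``"labeled"``).  Coverage and occurrence are relative to eligible
    time, so coverage/100 = occurrence × mean_duration/1000 exactly.
    """
    arr = data.data if isinstance(data, EEGRecording) else np.asarray(data, dtype=float)
    eligible = seg.labels != EXCLUDED
    if not eligible.any():
        raise ValueError("no eligible samples")
    gfp = compute_gfp(arr)
    C = _correlation_matrix(arr, maps.templates)
    K = maps.k
    labels = seg.labels

    if gev_denominator == "all":
        denom = float(np.sum(gfp[eligible] ** 2))
    elif gev_denominator == "labeled":
        denom = float(np.sum(gfp[labels >= 0] ** 2))
    else:
        raise ValueError("gev_denominator must be 'all' or 'labeled'")
    if denom == 0:
        raise ValueError("zero total GFP variance")

    gev = np.zeros(K)
    for k in range(K):
        m = labels == k
        if m.any():
            gev[k] = float(np.sum((gfp[m] * C[m, k]) ** 2)) / denom

    total_s = float(eligible.sum()) / seg.rate
    counts = np.zeros(K)
    n_segs = np.zeros(K)
    for lab, i0, i1 in seg.segments:
        if lab >= 0:
            counts[lab] += i1 - i0
            n_segs[lab] += 1
    coverage = counts / eligible.sum() * 100.0
    occurrence = n_segs / total_s
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_dur = np.where(n_segs > 0, counts / np.maximum(n_segs, 1) / seg.rate * 1000.0, 0.0)
    return TemporalStats(gev, mean_dur, coverage, occurrence, n_segs == 0)
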