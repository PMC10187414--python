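"""Microstate clustering: GFP-peak extraction, polarity-aware modified
k-means, and the two-level resampling scheme producing group templates.

The modified k-means here differs from ordinary k-means in two ways that
are standard in the microstate literature:

* distances are correlation-based, not Euclidean — a topography belongs to
  the template it correlates with best, and in *polarity-invariant* mode
  the sign of the map is ignored (spontaneous EEG oscillates, so a map and
  its mirror image are the same brain state);
* the objective is global explained variance (GEV): the fraction of total
  GFP-weighted variance captured by assigning every map to its template.

In invariant mode the GEV-optimal template for a fixed assignment is the
dominant eigenvector of the assigned maps' outer-product sum; in variant
(polarity-respecting) mode, used for ERPs, it is the normalized mean map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DegenerateDataError, EEGRecording, compute_gfp


@dataclass
class MicrostateSet:
    """K template topographies, each zero-mean and unit-norm.

    ``polarity_mode`` records whether the templates were fit ignoring map
    polarity (``"invariant"``, resting data) or respecting it
    (``"variant"``, ERPs); downstream backfitting uses the same mode.
    ``fit_gev`` is the GEV achieved on the data the set was fit to.
    """

    templates: np.ndarray  # (K, n_channels)
    polarity_mode: str
    fit_gev: float = 0.0

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.templates, dtype=float))
        if self.polarity_mode not in ("invariant", "variant"):
            raise ValueError(f"unknown polarity_mode {self.polarity_mode!r}")
        norms = np.linalg.norm(t, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero template")
        t = t - t.mean(axis=1, keepdims=True)
        t = t / np.linalg.norm(t, axis=1, keepdims=True)
        self.templates = t

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


def extract_gfp_peak_topographies(rec: EEGRecording) -> np.ndarray:
    """Topographies at strict local maxima of the GFP series.

    GFP peaks are the moments of highest topographic signal-to-noise, and
    are the only samples entering resting-state clustering.  Endpoints are
    never peaks; a monotone GFP series yields an empty result.  Returns a
    (n_peaks, n_channels) array in temporal order.
    """
    if rec.n_samples < 3:
        raise ValueError("need at least 3 samples to find peaks")
    gfp = compute_gfp(rec.data)
    interior = np.arange(1, rec.n_samples - 1)
    is_peak = (gfp[interior] > gfp[interior - 1]) & (gfp[interior] > gfp[interior + 1])
    idx = interior[is_peak]
    return rec.data[:, idx].T.copy()


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _prepare(topos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average-reference maps; return (raw zero-mean, unit-norm, norm²) arrays."""
    X = np.atleast_2d(np.asarray(topos, dtype=float))
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise DegenerateDataError("constant topography cannot be clustered")
    V = X / norms[:, None]
    return X, V, norms**2


def _dominant_eigvec(S: np.ndarray, start: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Dominant eigenvector of a symmetric PSD matrix by warm-started power iteration.

    Inside the k-means loop the template changes little between sweeps, so
    starting from the current template converges in a handful of matvecs;
    falls back to a dense eigendecomposition if iteration stalls.
    """
    v = start / np.linalg.norm(start)
    for _ in range(max_iter):
        w = S @ v
        nw = np.linalg.norm(w)
        if nw == 0:  # start orthogonal to the range; restart densely
            break
        w /= nw
        if 1.0 - abs(np.dot(w, v)) < tol:
            return w
        v = w
    vals, vecs = np.linalg.eigh(S)
    return vecs[:, -1]


def _gev(corr_win: np.ndarray, w: np.ndarray) -> float:
    """GEV of an assignment: Σᵢ wᵢ·corrᵢ² / Σᵢ wᵢ, w = squared map norm (∝ GFP²)."""
    return float(np.sum(w * corr_win**2) / np.sum(w))


def modified_kmeans(
    topos: np.ndarray,
    k: int,
    polarity_mode: str = "invariant",
    restarts: int = 50,
    tol: float = 1e-6,
    max_iter: int = 100,
    seed=None,
) -> MicrostateSet:
    """Polarity-aware modified k-means maximizing global explained variance.

    Parameters
    ----------
    topos
        (n_maps, n_channels) topographies; average-referenced internally.
    k
        Number of templates; must not exceed the number of maps.
    polarity_mode
        ``"invariant"``: assignment by \\|corr\\|, eigenvector template update.
        ``"variant"``: assignment by signed corr, normalized-mean update.
    restarts
        Number of seeded random initializations (templates drawn from the
        data without replacement); the best run by GEV is returned.

    Returns the best :class:`MicrostateSet`; ``fit_gev`` holds its GEV.
    """
    X, V, w = _prepare(topos)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of topographies n={n}")
    rng = np.random.default_rng(seed)

    if k == n:
        T = V.copy()
        corr = np.ones(n)
        return MicrostateSet(T, polarity_mode, _gev(corr, w))

    best: tuple[float, np.ndarray, list[float]] | None = None
    for _ in range(max(1, restarts)):
        init = rng.choice(n, size=k, replace=False)
        T = V[init].copy()
        gev_prev = -np.inf
        history: list[float] = []
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            C = V @ T.T  # (n, k) correlations (all unit-norm zero-mean)
            if polarity_mode == "invariant":
                labels = np.argmax(np.abs(C), axis=1)
                cwin = np.abs(C[np.arange(n), labels])
            else:
                labels = np.argmax(C, axis=1)
                cwin = C[np.arange(n), labels]
            gev = _gev(cwin, w)
            # template update

            newT = np.empty_like(T)
            for j in range(k):
                members = labels == j
                if not members.any():
                    # re-seed an empty cluster from the worst-fit topography
                    worst = int(np.argmin(np.abs(cwin) if polarity_mode == "invariant" else cwin))
                    newT[j] = V[worst]
                    continue
                if polarity_mode == "invariant":
                    S = X[members].T @ X[members]
                    newT[j] = _dominant_eigvec(S, T[j])
                else:
                    m = X[members].sum(axis=0)
                    nm = np.linalg.norm(m)
                    if nm == 0:
                        newT[j] = V[int(np.argmin(cwin))]
                    else:
                        newT[j] = m / nm
            newT = newT - newT.mean(axis=1, keepdims=True)
            newT /= np.linalg.norm(newT, axis=1, keepdims=True)
            if gev < gev_prev + tol:
                break
            gev_prev = gev
            history.append(gev)
            T = newT
        # score final templates with a fresh assignment
        C = V @ T.T
        if polarity_mode == "invariant":
            cwin = np.max(np.abs(C), axis=1)
        else:
            cwin = np.max(C, axis=1)
        g_final = _gev(cwin, w)
        if best is None or g_final > best[0]:
            best = (g_final, T.copy(), history)
    assert best is not None
    out = MicrostateSet(best[1], polarity_mode, best[0])
    out.gev_history = best[2]  # per-iteration GEV of the winning restart
    return out


def assign_topographies(topos: np.ndarray, mset: MicrostateSet) -> tuple[np.ndarray, np.ndarray]:
    """Label each topography with its best template; returns (labels, winning corr)."""
    _, V, _ = _prepare(topos)
    C = V @ mset.templates.T
    if mset.polarity_mode == "invariant":
        labels = np.argmax(np.abs(C), axis=1)
        cwin = np.abs(C[np.arange(len(labels)), labels])
    else:
        labels = np.argmax(C, axis=1)
        cwin = C[np.arange(len(labels)), labels]
    return labels, cwin


def gev_of_set(topos: np.ndarray, mset: MicrostateSet) -> float:
    """GEV of a template set on a collection of topographies."""
    X, V, w = _prepare(topos)
    _, cwin = assign_topographies(topos, mset)
    return _gev(cwin, w)


def subject_level_resampling(
    topos: np.ndarray,
    n_epochs: int = 50,
    n_subsamples: int = 833,
    k_grid=range(1, 13),
    kmeans_restarts: int = 50,
    seed=None,
) -> list[MicrostateSet]:
    """Resampled subject-level clustering: one winning template set per epoch.

    Each resampling epoch draws ``n_subsamples`` GFP-peak topographies
    without replacement, fits the modified k-means for every k on the grid,
    and keeps the set the meta-criterion selects.  Repeating this dilutes
    the influence of any single noisy stretch of data.
    """
    from .criteria import criterion_scores, meta_criterion

    k_grid = list(k_grid)
    n = np.atleast_2d(topos).shape[0]
    if max(k_grid) > n_subsamples:
        raise ValueError("k_grid maximum exceeds subsample size")
    if n < n_subsamples:
        warnings.warn(
            f"only {n} topographies available; clipping subsample size from {n_subsamples}"
        )
        n_subsamples = n
    ss = _as_seedseq(seed).spawn(n_epochs)
    out = []
    for ep in range(n_epochs):
        rng = np.random.default_rng(ss[ep])
        idx = rng.choice(n, size=n_subsamples, replace=False)
        sub = np.atleast_2d(topos)[idx]
        sets = {
            k: modified_kmeans(
                sub, k, "invariant", restarts=kmeans_restarts, seed=rng.integers(2**31)
            )
            for k in k_grid
        }
        report = criterion_scores(sub, sets)
        out.append(sets[meta_criterion(report)])
    return out


def _pool_templates(sets: list[MicrostateSet]) -> np.ndarray:
    """Pool template maps from many sets in a canonical (order-independent) order."""
    maps = np.vstack([s.templates for s in sets])
    # canonical sign (first nonzero component positive) then lexicographic sort
    flip = np.sign(maps[np.arange(len(maps)), np.argmax(np.abs(maps) > 1e-12, axis=1)])
    flip[flip == 0] = 1.0
    maps = maps * flip[:, None]
    order = np.lexsort(np.round(maps, 12).T[::-1])
    return maps[order]


def group_level_clustering(
    all_subject_sets: list[list[MicrostateSet]],
    stage1_epochs: int = 100,
    stage1_sets: int = 1000,
    k_grid=range(1, 16),
    restarts: int = 100,
    seed=None,
) -> MicrostateSet:
    """Two-stage resampled group clustering of subject-level template sets.

    Stage 1: each of ``stage1_epochs`` resampling epochs pools the maps of
    ``stage1_sets`` randomly sampled subject sets and clusters them, the
    meta-criterion choosing k per epoch.  Stage 2: the final group model
    order is the consensus (lower-median) of the stage-1 winners' model
    orders, and the winners' pooled maps are clustered once at that k.
    Basing the final k on the resampled epochs' votes rather than on one
    more validity-index evaluation keeps the decision robust when the
    pooled winner maps contain a handful of recurring off-cluster
    templates, which otherwise register as spurious extra clusters.
    Pooling uses a canonical sort so the result does not depend on subject
    order.
    """
    from .criteria import criterion_scores, meta_criterion

    if len(all_subject_sets) < 2:
        raise ValueError("need sets from at least 2 subjects")
    k_grid = list(k_grid)
    flat = [s for subj in all_subject_sets for s in subj]
    if len(flat) < stage1_sets:
        warnings.warn(f"only {len(flat)} sets available; clipping stage-1 sample size")
        stage1_sets = len(flat)
    # canonical order of the pool, independent of subject ordering
    flat = sorted(flat, key=lambda s: s.templates.tobytes())
    ss = _as_seedseq(seed).spawn(stage1_epochs + 1)

    def _cluster_pool(maps: np.ndarray, rng: np.random.Generator) -> MicrostateSet:
        sets = {
            k: modified_kmeans(maps, k, "invariant", restarts=restarts, seed=rng.integers(2**31))
            for k in k_grid
            if k <= len(maps)
        }
        report = criterion_scores(maps, sets)
        return sets[meta_criterion(report)]

    winners = []
    for ep in range(stage1_epochs):
        rng = np.random.default_rng(ss[ep])
        idx = rng.choice(len(flat), size=stage1_sets, replace=False)
        maps = _pool_templates([flat[i] for i in sorted(idx)])
        winners.append(_cluster_pool(maps, rng))
    ks = sorted(w.k for w in winners)
    k_final = int(ks[(len(ks) - 1) // 2])
    consensus = [w for w in winners if w.k == k_final] or winners
    final_maps = _pool_templates(consensus)
    rng = np.random.default_rng(ss[-1])
    return modified_kmeans(
        final_maps, k_final, "invariant", restarts=restarts, seed=rng.integers(2**31)
    )


@dataclass
class ErpSegmentation:
    """Sequential microstate labelling of a grand-averaged ERP."""

    mset: MicrostateSet
    labels: np.ndarray  # per-sample template index, EXCLUDED in baseline
    times_ms: np.ndarray


def segment_grand_average(
    erp_data: np.ndarray,
    times_ms: np.ndarray,
    exclude_window=(-500.0, -300.0),
    k_grid=range(1, 21),
    restarts: int = 300,
    seed=None,
) -> ErpSegmentation:
    """Polarity-variant sequential segmentation of a grand-averaged ERP.

    All non-baseline timepoints (not only GFP peaks) are clustered with the
    polarity-respecting modified k-means; the meta-criterion picks k, and
    every non-baseline timepoint is labelled with its best template.
    Baseline samples are marked EXCLUDED.
    """
    from .core import EXCLUDED
    from .criteria import criterion_scores, meta_criterion

    erp_data = np.asarray(erp_data, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if erp_data.shape[1] != len(times_ms):
        raise ValueError("time axis mismatch")
    lo, hi = exclude_window
    keep = ~((times_ms >= lo) & (times_ms <= hi))
    topos = erp_data[:, keep].T
    rng = np.random.default_rng(seed)
    k_grid = [k for k in k_grid if k <= topos.shape[0]]
    sets = {
        k: modified_kmeans(topos, k, "variant", restarts=restarts, seed=rng.integers(2**31))
        for k in k_grid
    }
    report = criterion_scores(topos, sets, polarity_mode="variant")
    mset = sets[meta_criterion(report)]
    lab_keep, _ = assign_topographies(topos, mset)
    labels = np.full(len(times_ms), EXCLUDED, dtype=int)
    labels[keep] = lab_keep
    return ErpSegmentation(mset, labels, times_ms)


def identify_error_microstate(seg: ErpSegmentation, response_time_ms: float = 0.0):
    """Identify the error-related microstate: the segment spanning the response.

    Programmatic stand-in for visual inspection: among the maximal
    contiguous segments of the sequential labelling, selects the longest
    one whose time span contains ``response_time_ms`` (the button-press).
    Returns ``((start_ms, end_ms), template, label)``.
    """
    from .core import EXCLUDED

    t = seg.times_ms
    labels = seg.labels
    runs = []  # (label, i0, i1) inclusive
    i = 0
    while i < len(labels):
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        runs.append((labels[i], i, j))
        i = j + 1
    containing = [
        (lab, i0, i1)
        for lab, i0, i1 in runs
        if lab != EXCLUDED and t[i0] <= response_time_ms <= t[i1]
    ]
    if not containing:
        raise ValueError(f"no labelled segment spans t={response_time_ms} ms")
    lab, i0, i1 = max(containing, key=lambda r: r[2] - r[1])
    return (float(t[i0]), float(t[i1])), seg.mset.templates[lab], int(lab)
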