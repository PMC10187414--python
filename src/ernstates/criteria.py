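"""Cluster-validity criteria and the meta-criterion choosing the model order.

Choosing the number of microstates K is the classic weak point of k-means
segmentation; no single validity index is reliable across data shapes, so
the model order is chosen by an aggregate of seven independent indices,
each evaluated on the polarity-respecting correlation distance

    d(u, v) = 1 - |corr(u, v)|   (invariant mode)
    d(u, v) = 1 - corr(u, v)     (variant mode)

The seven: Krzanowski-Lai, silhouette, Davies-Bouldin, point-biserial,
Dunn, Calinski-Harabasz, and Pascual-Marqui's cross-validation criterion.
Each index votes for its own optimal k; the meta-criterion takes the
median vote (ties resolved toward smaller k, favouring parsimony).

Rank-one data (all topographies equal up to polarity and scale) defeats
every between/within index; such data is flagged unclusterable and every
criterion votes for the grid minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_score

from .clustering import MicrostateSet, _prepare, assign_topographies

_CRITERIA = (
    "krzanowski_lai",
    "silhouette",
    "davies_bouldin",
    "point_biserial",
    "dunn",
    "calinski_harabasz",
    "cross_validation",
)

#: indices where larger is better; the rest are minimized
_MAXIMIZE = {"krzanowski_lai", "silhouette", "point_biserial", "dunn", "calinski_harabasz"}


@dataclass
class CriterionReport:
    """Score curves and per-criterion votes over a grid of candidate k."""

    k_grid: list[int]
    curves: dict[str, dict[int, float]]
    votes: dict[str, int]
    degenerate: bool = False

    def to_json(self, path) -> None:
        import json

        payload = {
            "k_grid": self.k_grid,
            "curves": {c: {str(k): v for k, v in curve.items()} for c, curve in self.curves.items()},
            "votes": self.votes,
            "degenerate": self.degenerate,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _distance_matrix(V: np.ndarray, polarity_mode: str) -> np.ndarray:
    C = np.clip(V @ V.T, -1.0, 1.0)
    D = 1.0 - (np.abs(C) if polarity_mode == "invariant" else C)
    np.fill_diagonal(D, 0.0)
    return D


def criterion_scores(
    topos: np.ndarray,
    sets_by_k: dict[int, MicrostateSet],
    polarity_mode: str | None = None,
) -> CriterionReport:
    """Evaluate the seven validity indices for every fitted k.

    ``sets_by_k`` maps each candidate k to a :class:`MicrostateSet` fitted
    on the same ``topos``.  Indices undefined at a given k (e.g. silhouette
    at k=1, Krzanowski-Lai at the grid edges) simply do not score there; an
    index defined nowhere votes for the grid minimum.
    """
    k_grid = sorted(sets_by_k)
    if len(k_grid) < 3:
        raise ValueError("need a k grid of at least 3 candidates")
    if polarity_mode is None:
        polarity_mode = next(iter(sets_by_k.values())).polarity_mode
    X, V, w = _prepare(topos)
    n, n_ch = V.shape
    m = n_ch - 1  # degrees of freedom of an average-referenced map

    D = _distance_matrix(V, polarity_mode)
    if float(D.max(initial=0.0)) < 1e-9:
        votes = {c: min(k_grid) for c in _CRITERIA}
        return CriterionReport(k_grid, {c: {} for c in _CRITERIA}, votes, degenerate=True)

    # per-k assignments, winning correlations, and within-dispersion W_k
    labels_k, cwin_k, W_k = {}, {}, {}
    for k, mset in sets_by_k.items():
        lab, cw = assign_topographies(topos, mset)
        labels_k[k], cwin_k[k] = lab, cw
        d_own = 1.0 - (np.abs(cw) if polarity_mode == "invariant" else cw)
        W_k[k] = float(np.sum(d_own**2))
    # rank-one degeneracy: one template explains everything
    k0 = min(k_grid)
    if float(np.sum(w * cwin_k[k0] ** 2) / np.sum(w)) > 1.0 - 1e-9 and k0 == 1:
        votes = {c: min(k_grid) for c in _CRITERIA}
        return CriterionReport(k_grid, {c: {} for c in _CRITERIA}, votes, degenerate=True)

    if 1 in sets_by_k:
        T_global = sets_by_k[1].templates[0]
    else:
        vals, vecs = np.linalg.eigh(X.T @ X)
        T_global = vecs[:, -1]
    c_glob = np.clip(V @ T_global, -1.0, 1.0)
    d_glob = 1.0 - (np.abs(c_glob) if polarity_mode == "invariant" else c_glob)
    T_total = float(np.sum(d_glob**2))

    curves: dict[str, dict[int, float]] = {c: {} for c in _CRITERIA}
    for k in k_grid:
        lab = labels_k[k]
        n_used = len(np.unique(lab))
        mset = sets_by_k[k]

        if 2 <= n_used <= n - 1 and k >= 2:
            curves["silhouette"][k] = float(silhouette_score(D, lab, metric="precomputed"))

        if k >= 2 and n_used == k:
            # Davies-Bouldin on correlation distance, templates as centroids
            Td = _distance_matrix(mset.templates, polarity_mode)
            S = np.array(
                [
                    np.mean(
                        1.0
                        - (
                            np.abs(V[lab == j] @ mset.templates[j])
                            if polarity_mode == "invariant"
                            else V[lab == j] @ mset.templates[j]
                        )
                    )
                    for j in range(k)
                ]
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                R = (S[:, None] + S[None, :]) / Td
            np.fill_diagonal(R, -np.inf)
            db = float(np.mean(np.max(R, axis=1)))
            if np.isfinite(db):
                curves["davies_bouldin"][k] = db

            # Calinski-Harabasz analogue on squared correlation distances
            B = T_total - W_k[k]
            if W_k[k] > 0:
                curves["calinski_harabasz"][k] = float((B / (k - 1)) / (W_k[k] / (n - k)))

            # Dunn: min between-cluster distance over max within-cluster diameter
            masks = [lab == j for j in range(k)]
            diam = max(float(D[mk][:, mk].max(initial=0.0)) for mk in masks)
            inter = min(
                float(D[masks[a]][:, masks[b]].min())
                for a in range(k)
                for b in range(a + 1, k)
            )
            if diam > 0:
                curves["dunn"][k] = inter / diam

            # point-biserial: corr of pairwise distance with "different cluster"
            iu = np.triu_indices(n, 1)
            dvals = D[iu]
            diff = (lab[iu[0]] != lab[iu[1]]).astype(float)
            if 0 < diff.mean() < 1 and dvals.std() > 0:
                curves["point_biserial"][k] = float(np.corrcoef(dvals, diff)[0, 1])

        # Krzanowski-Lai needs both neighbours on the grid
        if k - 1 in W_k and k + 1 in W_k and k >= 2:
            diff_k = (k - 1) ** (2 / m) * W_k[k - 1] - k ** (2 / m) * W_k[k]
            diff_k1 = k ** (2 / m) * W_k[k] - (k + 1) ** (2 / m) * W_k[k + 1]
            if abs(diff_k1) > 1e-30:
                curves["krzanowski_lai"][k] = float(abs(diff_k) / abs(diff_k1))

        # Pascual-Marqui predictive-residual (cross-validation) criterion
        if k < m - 1:
            cw = cwin_k[k]
            sigma2 = float(np.sum(w * (1.0 - cw**2)) / (n * m))
            curves["cross_validation"][k] = sigma2 * ((m - 1) / (m - 1 - k)) ** 2

    votes = {}
    for c in _CRITERIA:
        curve = curves[c]
        if not curve:
            votes[c] = min(k_grid)
            continue
        ks = sorted(curve)
        scores = np.array([curve[k] for k in ks])
        best = int(np.argmax(scores)) if c in _MAXIMIZE else int(np.argmin(scores))
        votes[c] = ks[best]
    return CriterionReport(k_grid, curves, votes)


def meta_criterion(report: CriterionReport, boundary_guard: float = 0.8) -> int:
    """Aggregate the per-criterion votes: lower-median, snapped to the grid.

    An index whose optimum lands in the top ``1 - boundary_guard`` fraction
    of the grid span has effectively failed to find parsimonious structure
    (its curve keeps improving toward the grid ceiling, the signature of a
    dispersion measure with no noise floor); such votes are replaced by the
    grid minimum so they cannot drag the aggregate upward.  With seven
    criteria the median is always one of the votes; for an even number of
    valid votes the lower middle is taken, and a median falling between
    grid values snaps to the nearest grid value with ties resolved toward
    smaller k (parsimony).
    """
    if not report.votes:
        raise ValueError("empty criterion report")
    lo, hi = min(report.k_grid), max(report.k_grid)
    cut = lo + boundary_guard * (hi - lo)
    votes = sorted(lo if v > cut else v for v in report.votes.values())
    med = votes[(len(votes) - 1) // 2]
    if med in report.k_grid:
        return int(med)
    grid = np.asarray(report.k_grid)
    dist = np.abs(grid - med)
    return int(grid[np.argmin(dist)])  # argmin takes the first (smaller) on ties
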