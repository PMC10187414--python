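"""Reference-free topographic primitives shared by all pipeline stages.

Topographies are 1-D arrays of instantaneous scalp potentials (µV), one
value per channel of a montage.  All quantities in this module are defined
on average-referenced maps: average referencing projects out the spatially
constant component, after which global field power (GFP) is the spatial
standard deviation and the spatial correlation between two maps is the
Pearson correlation of their channel values (equivalently, the cosine of
the angle between the zero-mean vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import ElectrodeMontage

#: Sentinel labels used in segmentations.
UNASSIGNED = -1
EXCLUDED = -2


class InvalidDataError(ValueError):
    """Raised for non-finite or structurally invalid EEG input."""


class DegenerateDataError(ValueError):
    """Raised when an operation is undefined on the data (e.g. constant map)."""


@dataclass
class EEGRecording:
    """Continuous multichannel EEG: ``data`` is channels × samples in µV."""

    data: np.ndarray
    rate: float
    montage: ElectrodeMontage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidDataError("data must be channels × samples")
        if self.data.shape[0] != self.montage.n_channels:
            raise InvalidDataError("channel count does not match montage")
        if not np.all(np.isfinite(self.data)):
            raise InvalidDataError("recording contains non-finite values")
        if self.rate <= 0:
            raise InvalidDataError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


def average_reference(values: np.ndarray) -> np.ndarray:
    """Re-reference map(s) to the average: subtract the spatial mean.

    Accepts a single topography (1-D) or a channels × samples matrix; the
    mean over channels is removed at each sample.  Idempotent, and an exact
    linear projection.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidDataError("non-finite values in topography")
    if values.shape[0] < 2:
        raise InvalidDataError("need at least 2 channels")
    return values - values.mean(axis=0, keepdims=True)


def compute_gfp(values: np.ndarray) -> np.ndarray | float:
    """Global field power: spatial standard deviation of the map(s), µV.

    Uses the population (1/N) variance over channels.  For a channels ×
    samples matrix, returns one value per sample.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise InvalidDataError("need at least 2 channels")
    centered = values - values.mean(axis=0, keepdims=True)
    gfp = np.sqrt(np.mean(centered**2, axis=0))
    return float(gfp) if gfp.ndim == 0 else gfp


def spatial_correlation(u: np.ndarray, v: np.ndarray, polarity_mode: str = "variant") -> float:
    """Spatial (Pearson) correlation between two topographies.

    Both maps are re-average-referenced, after which Pearson correlation
    equals cosine similarity.  ``polarity_mode="invariant"`` returns the
    absolute value (sign of either map ignored), as used for spontaneous
    resting data; ``"variant"`` keeps the sign, as used for ERPs.
    """
    if polarity_mode not in ("invariant", "variant"):
        raise ValueError(f"unknown polarity_mode {polarity_mode!r}")
    u = average_reference(np.asarray(u, dtype=float))
    v = average_reference(np.asarray(v, dtype=float))
    if u.shape != v.shape:
        raise InvalidDataError("topographies have different channel counts")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateDataError("spatial correlation undefined for a constant map")
    c = float(np.dot(u, v) / (nu * nv))
    c = max(-1.0, min(1.0, c))
    return abs(c) if polarity_mode == "invariant" else c


def normalize_by_median_gfp(rec: EEGRecording) -> EEGRecording:
    """Divide all samples by the scalar median GFP of the recording.

    Removes between-subject scale differences (skull conductivity etc.)
    while leaving every spatial correlation — and hence every backfitting
    label — unchanged.  The output's median GFP is 1.
    """
    gfp = compute_gfp(rec.data)
    med = float(np.median(gfp))
    if med == 0:
        raise DegenerateDataError("median GFP is zero; cannot normalize")
    return EEGRecording(rec.data / med, rec.rate, rec.montage)


def spatial_filter(rec: EEGRecording, g: int = 6) -> EEGRecording:
    """Instantaneous topographic trimmed-mean filter.

    At every timepoint, each channel is replaced by the mean of
    {itself ∪ its ``g`` nearest montage neighbors} after discarding that
    set's single minimum and single maximum.  This rejects single-channel
    outliers and smooths topographies without mixing timepoints.  The
    output is re-average-referenced.
    """
    if g < 3:
        raise ValueError("spatial filter requires g >= 3")
    if g >= rec.n_channels:
        raise ValueError("g must be smaller than the channel count")
    nbr = rec.montage.neighbors(g)  # (n_ch, g)
    idx = np.concatenate([np.arange(rec.n_channels)[:, None], nbr], axis=1)  # (n_ch, g+1)
    pool = rec.data[idx]  # (n_ch, g+1, n_samp)
    total = pool.sum(axis=1)
    trimmed = (total - pool.min(axis=1) - pool.max(axis=1)) / (idx.shape[1] - 2)
    return EEGRecording(average_reference(trimmed), rec.rate, rec.montage)
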