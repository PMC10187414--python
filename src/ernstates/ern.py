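"""Response-locked averaging and microstate-guided ERN quantification.

The error-related negativity (ERN) is a fronto-central negative ERP
deflection within ~100 ms of an erroneous response.  Rather than fixing a
measurement window a priori, the window and channel region of interest
are taken from the error-related microstate: the window is the span the
microstate occupies around the button-press, and the ROI is the channels
surrounding the template's most negative site.  Because correct responses
elicit a similar but smaller fronto-central deflection, the per-subject
ERN score is residualized: erroneous no-go amplitudes are regressed on
correct go amplitudes and the unstandardized residuals carry forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .montage import ElectrodeMontage

#: condition → minimum usable trial count
TRIAL_MINIMA = {"correct_go": 21, "error_nogo": 6}


@dataclass
class EpochSet:
    """Response-locked trials: ``data`` is epochs × channels × samples (µV)."""

    data: np.ndarray
    times_ms: np.ndarray
    rate: float
    condition: str  # "correct_go" or "error_nogo"
    baseline_ms: tuple[float, float] = (-500.0, -300.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.times_ms):
            raise ValueError("data must be epochs × channels × samples matching times_ms")
        lo, hi = self.baseline_ms
        if lo < self.times_ms[0] or hi > self.times_ms[-1]:
            raise ValueError("baseline window outside the epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class ErpAverage:
    """Per-condition (or difference) channels × samples average, µV."""

    data: np.ndarray
    times_ms: np.ndarray
    rate: float
    condition: str
    n_trials: int


def epoch_average(epochs: EpochSet, enforce_minima: bool = True) -> ErpAverage:
    """Baseline-correct each epoch, then average across epochs.

    The per-channel mean over the baseline window is subtracted per epoch
    before averaging.  Conditions below their minimum trial count
    (21 correct go / 6 erroneous no-go) are rejected.
    """
    minimum = TRIAL_MINIMA.get(epochs.condition, 1)
    if enforce_minima and epochs.n_epochs < minimum:
        raise ValueError(
            f"{epochs.condition}: {epochs.n_epochs} trials is below the "
            f"minimum of {minimum} required for a usable average"
        )
    lo, hi = epochs.baseline_ms
    bmask = (epochs.times_ms >= lo) & (epochs.times_ms <= hi)
    if not bmask.any():
        raise ValueError("empty baseline window")
    baseline = epochs.data[:, :, bmask].mean(axis=2, keepdims=True)
    avg = (epochs.data - baseline).mean(axis=0)
    return ErpAverage(avg, epochs.times_ms.copy(), epochs.rate, epochs.condition, epochs.n_epochs)


def difference_wave(error: ErpAverage, correct: ErpAverage) -> ErpAverage:
    """Error-related activity: erroneous no-go average minus correct go average."""
    if error.data.shape != correct.data.shape or not np.allclose(
        error.times_ms, correct.times_ms
    ):
        raise ValueError("averages have mismatched axes")
    return ErpAverage(
        error.data - correct.data,
        error.times_ms.copy(),
        error.rate,
        "difference",
        min(error.n_trials, correct.n_trials),
    )


def select_ern_roi(
    template: np.ndarray, montage: ElectrodeMontage, n_roi: int = 5
) -> list[str]:
    """Channels surrounding the template's most negative site.

    Returns the channel holding the template minimum plus its
    ``n_roi − 1`` nearest montage neighbours — the "pool of channels"
    convention for ERN quantification.
    """
    template = np.asarray(template, dtype=float)
    if n_roi > montage.n_channels:
        raise ValueError("n_roi exceeds channel count")
    if n_roi < 1:
        raise ValueError("n_roi must be positive")
    center = montage.channel_ids[int(np.argmin(template))]
    return montage.nearest_to(center, n_roi)


def mean_amplitude(
    erp: ErpAverage, window_ms: tuple[float, float], roi: list[str], montage: ElectrodeMontage
) -> float:
    """Mean µV over the ROI channels and the window (bounds snapped to samples)."""
    lo, hi = window_ms
    i0 = int(np.argmin(np.abs(erp.times_ms - lo)))
    i1 = int(np.argmin(np.abs(erp.times_ms - hi)))
    if i1 < i0:
        raise ValueError("empty window after snapping")
    rows = [montage.index(ch) for ch in roi]
    if not rows:
        raise ValueError("empty ROI")
    return float(erp.data[np.ix_(rows, range(i0, i1 + 1))].mean())


def residualize_ern(go_amps: np.ndarray, nogo_amps: np.ndarray) -> np.ndarray:
    """Unstandardized residuals of no-go amplitudes regressed on go amplitudes.

    OLS with intercept; the residuals are exactly orthogonal to the go
    amplitudes and zero-mean, isolating error-specific variance from the
    shared response-locked activity.
    """
    go = np.asarray(go_amps, dtype=float)
    nogo = np.asarray(nogo_amps, dtype=float)
    if go.shape != nogo.shape or go.ndim != 1:
        raise ValueError("go and no-go amplitude vectors must match")
    if len(go) < 3:
        raise ValueError("need at least 3 subjects to residualize")
    if np.ptp(go) == 0:
        raise ValueError("constant go amplitudes; regression undefined")
    model = sm.OLS(nogo, sm.add_constant(go)).fit()
    return np.asarray(model.resid)
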