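"""Synthetic EEG with known microstate ground truth and a planted ERN.

The generator mirrors the generative structure microstate segmentation
assumes: scalp topographies that are piecewise-stable on the 30–150 ms
timescale, waxing and waning in global field power, corrupted by
spatially smooth noise.  The microstate sequence is a Markov chain with
no self-transitions and geometric dwell times; the GFP envelope is a
rectified sinusoid (period ~100 ms), giving unambiguous GFP peaks for
peak extraction to find.  Task epochs add a response-locked
fronto-central negativity on error trials, with correct trials receiving
the same shape scaled down — so residualization has real work to do.
Cohorts couple a subject's ERN scaling to the dwell time (hence GEV) of a
designated resting map through a shared latent factor, giving a tunable
population correlation for the association stage to recover.

All randomness descends from one integer seed through
``numpy.random.SeedSequence`` spawning, so every fixture is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import MicrostateSet, _as_seedseq
from .core import EEGRecording, average_reference, compute_gfp
from .ern import EpochSet
from .montage import ElectrodeMontage, make_montage


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery scoring."""

    true_maps: MicrostateSet
    true_labels: np.ndarray
    snr: float
    mean_segment_ms: float


@dataclass
class CohortSpec:
    """Study-design parameters for a simulated cohort.

    Defaults follow the emulated study conditions: 4–8-year-olds, 120 go /
    80 no-go trials, 157 s of resting data at 250 Hz, and a −8 µV planted
    error response peaking ~20 ms after the button-press.
    """

    n_subjects: int = 90
    n_channels: int = 30
    k_maps: int = 4
    age_range: tuple[float, float] = (4.0, 8.0)
    female_prop: float = 0.5
    coupling_rho: float = 0.5
    coupled_map: int = 0
    ern_amplitude_uv: float = -8.0
    ern_latency_ms: float = 20.0
    ern_width_ms: float = 60.0  # Gaussian sigma of the deflection, ms
    n_correct: int = 120
    n_error: int = 80
    rate: float = 250.0
    rest_duration_s: float = 157.0
    mean_segment_ms: float = 80.0
    snr: float = 5.0

    def __post_init__(self) -> None:
        if not abs(self.coupling_rho) < 1:
            raise ValueError("|coupling_rho| must be < 1")
        if self.n_correct < 21 or self.n_error < 6:
            raise ValueError(
                "trial counts below usability minima (21 correct go, 6 erroneous no-go)"
            )


def _smooth_field(montage: ElectrodeMontage, rng: np.random.Generator, ell: float = 0.6):
    """One spatially smooth zero-mean random field on the montage (GP draw)."""
    d = np.linalg.norm(
        montage.positions[:, None, :] - montage.positions[None, :, :], axis=-1
    )
    cov = np.exp(-(d**2) / (2 * ell**2)) + 1e-8 * np.eye(montage.n_channels)
    L = np.linalg.cholesky(cov)
    return average_reference(L @ rng.standard_normal(montage.n_channels))


def make_ground_truth_maps(
    k: int,
    montage: ElectrodeMontage,
    seed=None,
    corr_ceiling: float = 0.5,
    max_draws: int = 30000,
    filter_iterations: int = 6,
    filter_g: int = 6,
) -> MicrostateSet:
    """Draw k unit-norm ground-truth maps with bounded mutual correlation.

    Maps are seeded smooth Gaussian-process fields on the montage, iterated
    through the instantaneous spatial filter to near-fixed-points
    (``filter_iterations`` applications of the trimmed-mean kernel) so the
    analysis pipeline's own filtering cannot bias recovered templates away
    from the planted truth, then accepted by rejection sampling against the
    pairwise \\|spatial corr\\| ceiling.  The filter-stable smooth space is
    low-dimensional, so acceptance can take a few thousand draws for k = 5;
    the budget is ``max_draws`` in total.  A ceiling of 0 instead returns a
    symmetrically (Löwdin) orthogonalized set — exactly orthogonal, at a
    small cost in filter stability.
    """
    from .core import EEGRecording, spatial_filter

    if not 2 <= k < montage.n_channels:
        raise ValueError("need 2 <= k < channel count")
    rng = np.random.default_rng(seed)
    # scale the smoothing neighbourhood down on small montages, where the
    # full kernel would leave too few distinct smooth directions
    g = min(filter_g, max(3, montage.n_channels // 5))

    def _filter_smooth(v: np.ndarray) -> np.ndarray:
        X = np.repeat(v[:, None], 3, axis=1)  # filter API wants >=2 cols
        for _ in range(filter_iterations):
            X = spatial_filter(EEGRecording(X, 1000.0, montage), g).data
            nrm = np.linalg.norm(X[:, 0])
            if nrm < 1e-12:
                return v
            X = X / nrm
        return X[:, 0]

    def _draw() -> np.ndarray | None:
        v = _smooth_field(montage, rng)
        if filter_iterations > 0:
            v = _filter_smooth(v)
        v = average_reference(v)
        nv = np.linalg.norm(v)
        return None if nv < 1e-10 else v / nv

    if corr_ceiling <= 0:
        M = []
        while len(M) < k:
            v = _draw()
            if v is not None:
                M.append(v)
        M = np.stack(M)
        gram = M @ M.T
        vals, vecs = np.linalg.eigh(gram)
        M = vecs @ np.diag(vals**-0.5) @ vecs.T @ M  # Löwdin orthogonalization
        M = M - M.mean(axis=1, keepdims=True)
        M = M / np.linalg.norm(M, axis=1, keepdims=True)
        return MicrostateSet(M, "invariant")

    maps: list[np.ndarray] = []
    for _ in range(max_draws):
        v = _draw()
        if v is None:
            continue
        if all(abs(np.dot(v, m)) <= corr_ceiling for m in maps):
            maps.append(v)
            if len(maps) == k:
                return MicrostateSet(np.array(maps), "invariant")
    raise RuntimeError("could not satisfy the correlation ceiling; relax it")


def _markov_labels(
    n_samples: int,
    k: int,
    mean_segment_samples: float,
    rng: np.random.Generator,
    dwell_multipliers: np.ndarray | None = None,
) -> np.ndarray:
    """State sequence with geometric dwell times and no self-transitions."""
    if dwell_multipliers is None:
        dwell_multipliers = np.ones(k)
    labels = np.empty(n_samples, dtype=int)
    state = int(rng.integers(k))
    t = 0
    while t < n_samples:
        mean_dwell = max(mean_segment_samples * dwell_multipliers[state], 1.0)
        dwell = int(rng.geometric(min(1.0, 1.0 / mean_dwell)))
        end = min(t + dwell, n_samples)
        labels[t:end] = state
        t = end
        if k > 1:
            nxt = int(rng.integers(k - 1))
            state = nxt if nxt < state else nxt + 1
    return labels


def simulate_resting_recording(
    maps: MicrostateSet,
    montage: ElectrodeMontage,
    duration_s: float = 120.0,
    rate: float = 250.0,
    mean_segment_ms: float = 80.0,
    snr: float = 5.0,
    seed=None,
    env_period_ms: float = 100.0,
    amplitude_uv: float = 10.0,
    dwell_multipliers: np.ndarray | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Continuous resting EEG: Markov microstate sequence × GFP envelope + noise.

    Each sample is the active map times a rectified-sinusoid GFP envelope
    (period ``env_period_ms``, peak GFP ``amplitude_uv``) plus spatially
    smooth Gaussian noise scaled so the ratio of signal RMS-GFP to noise
    RMS-GFP equals ``snr`` (``snr=inf`` → noiseless).
    """
    if rate < 100:
        raise ValueError("rate must be >= 100 Hz")
    if duration_s < 10:
        raise ValueError("duration must be >= 10 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    labels = _markov_labels(n, maps.k, mean_segment_ms * rate / 1000.0, rng, dwell_multipliers)
    t = np.arange(n) / rate
    phase = rng.uniform(0, np.pi)
    env = np.abs(np.sin(np.pi * t * 1000.0 / env_period_ms + phase))
    # unit-norm map scaled so GFP of the signal equals amplitude·env
    scale = amplitude_uv * np.sqrt(montage.n_channels)
    signal = maps.templates[labels].T * (env * scale)
    if np.isfinite(snr):
        d = np.linalg.norm(
            montage.positions[:, None, :] - montage.positions[None, :, :], axis=-1
        )
        cov = np.exp(-(d**2) / (2 * 0.6**2)) + 1e-8 * np.eye(montage.n_channels)
        L = np.linalg.cholesky(cov)
        noise = average_reference(L @ rng.standard_normal((montage.n_channels, n)))
        sig_rms = float(np.sqrt(np.mean(compute_gfp(signal) ** 2)))
        noise_rms = float(np.sqrt(np.mean(compute_gfp(noise) ** 2)))
        noise *= sig_rms / (snr * noise_rms)
        data = signal + noise
    else:
        data = signal
    rec = EEGRecording(average_reference(data), rate, montage)
    return rec, GroundTruth(maps, labels, snr, mean_segment_ms)


def frontocentral_bump_map(
    montage: ElectrodeMontage, ell: float = 0.8, filter_iterations: int = 2
) -> np.ndarray:
    """Fixed fronto-central negativity topography, minimum at the vertex channel.

    A radial Gaussian bump centred on the vertex, smoothed to a
    near-fixed-point of the instantaneous spatial filter (so the analysis
    pipeline's filtering does not erode the planted amplitude),
    average-referenced, and scaled so the vertex value is −1: multiplying
    by \\|amplitude\\| µV plants exactly −\\|amplitude\\| µV at the vertex.
    """
    from .core import EEGRecording, spatial_filter

    try:
        cz = montage.index("Cz")
    except ValueError:
        cz = int(np.argmax(montage.positions[:, 2]))
    d = np.linalg.norm(montage.positions - montage.positions[cz], axis=1)
    raw = -np.exp(-(d**2) / (2 * ell**2))
    m = average_reference(raw)
    g = min(6, montage.n_channels - 1)
    for _ in range(filter_iterations):
        X = np.repeat(m[:, None], 3, axis=1)
        m = spatial_filter(EEGRecording(X, 1000.0, montage), g).data[:, 0]
    return m / abs(m[cz])  # value at the vertex = −1


def _lateral_component_map(
    montage: ElectrodeMontage, center_xyz: tuple[float, float, float], ell: float = 0.7
) -> np.ndarray:
    """Smooth radial component topography centred near ``center_xyz``.

    Average-referenced and scaled to +1 at its central channel; multiply by
    a signed amplitude to plant the component.
    """
    c = np.asarray(center_xyz, dtype=float)
    c /= np.linalg.norm(c)
    center = int(np.argmin(np.linalg.norm(montage.positions - c, axis=1)))
    d = np.linalg.norm(montage.positions - montage.positions[center], axis=1)
    m = average_reference(np.exp(-(d**2) / (2 * ell**2)))
    return m / abs(m[center])


def simulate_task_epochs(
    maps: MicrostateSet,
    montage: ElectrodeMontage,
    spec: CohortSpec,
    subject_effect: float = 1.0,
    seed=None,
    correct_scale: float = 0.3,
    background_uv: float = 5.0,
    flanker_scale: float = 0.6,
) -> tuple[EpochSet, EpochSet, GroundTruth]:
    """Response-locked go/no-go epochs with a planted error deflection.

    Both conditions share the background microstate dynamics; error epochs
    add a negative Gaussian bump (peak ``spec.ern_amplitude_uv ×
    subject_effect`` µV at the vertex, latency ``spec.ern_latency_ms``,
    width (Gaussian σ) ``spec.ern_width_ms``) with a fixed fronto-central topography.
    Correct epochs receive the same shape at ``correct_scale`` of the
    nominal amplitude — the *common* response-locked component, shared by
    all subjects — so residualizing error amplitudes on correct amplitudes
    removes the shared component while preserving the between-subject
    error-specific variance carried by ``subject_effect``.

    Error (no-go) epochs additionally carry the flanking components seen in
    real response-locked error data — a stimulus-related frontal
    negativity preceding the response (the no-go N2, absent on go trials
    because the stimuli differ) and a centro-parietal error positivity
    (Pe) following it — both at ``flanker_scale`` of the nominal amplitude
    and common to all subjects.  They bound the error-related microstate
    in time exactly as flanking microstates do in real sequential
    segmentations; ``flanker_scale=0`` disables them for closed-form
    oracles.
    """
    rng = np.random.default_rng(seed)
    rate = spec.rate
    times_ms = np.arange(int(round(-500 * rate / 1000)), int(round(800 * rate / 1000)) + 1) * (
        1000.0 / rate
    )
    n_t = len(times_ms)
    bump_topo = frontocentral_bump_map(montage)
    sigma = spec.ern_width_ms
    bump_t = np.exp(-((times_ms - spec.ern_latency_ms) ** 2) / (2 * sigma**2))
    base = bump_topo[:, None] * (abs(spec.ern_amplitude_uv) * bump_t)[None, :]

    flank = np.zeros_like(base)
    if flanker_scale > 0:
        amp = flanker_scale * abs(spec.ern_amplitude_uv)
        n2_topo = _lateral_component_map(montage, (0.0, 0.7, 0.7))  # frontal
        n2_t = np.exp(-((times_ms + 150.0) ** 2) / (2 * 60.0**2))
        pe_topo = _lateral_component_map(montage, (0.0, -0.7, 0.7))  # centro-parietal
        pe_t = np.exp(-((times_ms - 250.0) ** 2) / (2 * 70.0**2))
        flank = -amp * n2_topo[:, None] * n2_t[None, :] + amp * pe_topo[:, None] * pe_t[None, :]

    def _one_condition(n_epochs: int, bump: np.ndarray) -> np.ndarray:
        data = np.empty((n_epochs, montage.n_channels, n_t))
        for e in range(n_epochs):
            if background_uv > 0:
                rec, _ = simulate_resting_recording(
                    maps,
                    montage,
                    duration_s=max(10.0, n_t / rate + 1),
                    rate=rate,
                    mean_segment_ms=spec.mean_segment_ms,
                    snr=spec.snr,
                    seed=rng.integers(2**31),
                    amplitude_uv=background_uv,
                )
                data[e] = rec.data[:, :n_t] + bump
            else:
                data[e] = bump
        return data

    correct = EpochSet(
        _one_condition(spec.n_correct, correct_scale * base), times_ms, rate, "correct_go"
    )
    error = EpochSet(
        _one_condition(spec.n_error, subject_effect * base + flank),
        times_ms,
        rate,
        "error_nogo",
    )
    gt = GroundTruth(maps, np.array([]), spec.snr, spec.mean_segment_ms)
    return correct, error, gt


@dataclass
class SimulatedSubject:
    subject_id: str
    rest: EEGRecording
    rest_truth: GroundTruth
    correct: EpochSet
    error: EpochSet


@dataclass
class Cohort:
    """A simulated cohort: per-subject data plus the covariate/latent table."""

    montage: ElectrodeMontage
    maps: MicrostateSet
    subjects: list[SimulatedSubject]
    covariates: pd.DataFrame  # subject_id, age, sex, latents
    spec: CohortSpec


def draw_coupled_latents(
    n: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal latent vectors with population correlation rho.

    ``e_ern`` drives a subject's error-response scaling; ``e_gev`` drives
    the designated resting map's dwell time (hence its GEV).  Both load
    √|rho| on a shared factor, giving corr(e_ern, e_gev) = rho exactly in
    the population.
    """
    z = rng.standard_normal(n)
    a = np.sqrt(abs(rho))
    b = np.sqrt(1 - abs(rho))
    e_ern = a * z + b * rng.standard_normal(n)
    e_gev = np.sign(rho) * a * z + b * rng.standard_normal(n) if rho != 0 else rng.standard_normal(n)
    return e_ern, e_gev


def simulate_cohort(
    spec: CohortSpec,
    seed=None,
    rest_duration_s: float | None = None,
    with_task: bool = True,
) -> Cohort:
    """Simulate a whole cohort with subject-level ERN–GEV coupling.

    Per subject, a latent pair with population correlation
    ``spec.coupling_rho`` sets the ERN scaling (subject_effect) and the
    designated map's dwell-time multiplier; age is uniform over the stated
    range and sex Bernoulli at the stated proportion.  All latent values
    are returned in the covariate table for oracle checks.
    """
    ss = _as_seedseq(seed if seed is not None else 0)
    child = ss.spawn(spec.n_subjects + 2)
    rng = np.random.default_rng(child[0])
    montage = make_montage(spec.n_channels)
    maps = make_ground_truth_maps(spec.k_maps, montage, seed=child[1])
    e_ern, e_gev = draw_coupled_latents(spec.n_subjects, spec.coupling_rho, rng)
    subject_effect = np.clip(1.0 + 0.3 * e_ern, 0.1, None)
    dwell_mult = np.clip(1.0 + 0.35 * e_gev, 0.2, None)
    ages = rng.uniform(*spec.age_range, size=spec.n_subjects)
    sexes = (rng.uniform(size=spec.n_subjects) < spec.female_prop).astype(int)  # 1 = female

    dur = rest_duration_s if rest_duration_s is not None else spec.rest_duration_s
    subjects = []
    for i in range(spec.n_subjects):
        sub_ss = child[i + 2].spawn(2)
        mult = np.ones(spec.k_maps)
        mult[spec.coupled_map] = dwell_mult[i]
        rest, truth = simulate_resting_recording(
            maps,
            montage,
            duration_s=dur,
            rate=spec.rate,
            mean_segment_ms=spec.mean_segment_ms,
            snr=spec.snr,
            seed=sub_ss[0],
            dwell_multipliers=mult,
        )
        if with_task:
            correct, error, _ = simulate_task_epochs(
                maps, montage, spec, subject_effect=subject_effect[i], seed=sub_ss[1]
            )
        else:
            correct = error = None
        subjects.append(SimulatedSubject(f"sub-{i + 1:03d}", rest, truth, correct, error))

    cov = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": ages,
            "sex": sexes,
            "latent_ern": e_ern,
            "latent_gev": e_gev,
            "subject_effect": subject_effect,
            "dwell_multiplier": dwell_mult,
        }
    )
    return Cohort(montage, maps, subjects, cov, spec)


def simulate_association_table(
    n_subjects: int = 90,
    coupling_rho: float = 0.5,
    seed=None,
    age_range: tuple[float, float] = (4.0, 8.0),
    female_prop: float = 0.5,
    age_beta: float = 0.2,
    sex_beta: float = 0.2,
) -> pd.DataFrame:
    """Cohort table drawn directly from the latent statistical model.

    Emulates the measured analysis table — residualized ERN, a coupled
    resting-map GEV, an uncoupled GEV, and a behaviour score — without
    synthesizing EEG, for power / error-rate studies of the association
    battery.  The coupled GEV column has standardized association
    ``coupling_rho`` with the residualized ERN after age and sex effects.
    """
    rng = np.random.default_rng(seed)
    rho = coupling_rho
    e_ern, e_gev = draw_coupled_latents(n_subjects, rho, rng)
    age = rng.uniform(*age_range, size=n_subjects)
    sex = (rng.uniform(size=n_subjects) < female_prop).astype(int)
    z_age = (age - age.mean()) / age.std()
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n_subjects)],
            "age": age,
            "sex": sex,
            "ern_resid": e_ern,
            "gev_coupled": e_gev + age_beta * z_age + sex_beta * sex,
            "gev_uncoupled": rng.standard_normal(n_subjects),
            "behavior": rng.standard_normal(n_subjects),
        }
    )
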