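"""Synthetic covert-attention sessions: cue statistics, behavior, and EEG forward model.

Emulates a Posner-style cueing experiment in which a central random-dot
stimulus cues covert attention to a left or right peripheral target
location. Dot directions follow a Von Mises distribution whose
concentration plays the role of motion coherence; zero-coherence cues
are directionally ambiguous (mean resultant vector norm < 0.05). A
session comprises 8 blocks of 52 trials, 75% predictive / 25% ambiguous,
with left/right targets balanced within each condition.

The planted EEG model has two parieto-occipital alpha (8-14 Hz) sources
with fixed unit-norm topographies; attention to one hemifield increases
the variance of the ipsilateral source by (1+d) and suppresses the
contralateral one by 1/(1+d), on top of 1/f spatially correlated sensor
noise. Two bipolar EOG channels carry slow drift plus, on a configurable
fraction of trials, a half-cosine deflection exceeding the rejection
thresholds.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from . import channels as ch

logger = logging.getLogger(__name__)

LEFT = "left"
RIGHT = "right"
PREDICTIVE = "predictive"
AMBIGUOUS = "ambiguous"

#: Upper bound on the mean resultant vector norm of an ambiguous cue.
AMBIGUOUS_NORM_BOUND = 0.05


# --------------------------------------------------------------------------
# cue statistics


def resultant_vector(directions: np.ndarray) -> tuple[float, float]:
    """Length and angle of the mean unit vector of a sample of angles."""
    z = np.exp(1j * np.asarray(directions, dtype=float)).mean()
    return float(abs(z)), float(np.angle(z))


@dataclass(frozen=True)
class CueStimulus:
    """One random-dot cue: per-dot directions and their circular summary."""

    directions: np.ndarray
    n_dots: int
    mean_direction: float
    coherence: float
    resultant_norm: float
    resultant_angle: float
    condition: str
    target_side: str


def side_from_direction(mean_direction: float) -> str:
    """Target side implied by a cue's mean direction (0 rad points right)."""
    return RIGHT if np.cos(mean_direction) >= 0 else LEFT


def generate_cue(n_dots: int, mean_direction: float, coherence: float,
                 rng: np.random.Generator, *, target_side: str | None = None,
                 max_redraws: int = 1000) -> CueStimulus:
    """Draw one random-dot cue.

    Dot directions are i.i.d. Von Mises(mean_direction, kappa=coherence).
    At zero coherence the distribution is uniform on the circle and the
    sample is redrawn (up to ``max_redraws`` times) until its resultant
    norm falls below ``AMBIGUOUS_NORM_BOUND``, making the cue ambiguous.
    """
    if n_dots < 1:
        raise ValueError("n_dots must be >= 1")
    if coherence < 0:
        raise ValueError("coherence must be >= 0")
    condition = AMBIGUOUS if coherence == 0 else PREDICTIVE
    for _ in range(max_redraws):
        directions = rng.vonmises(mean_direction, coherence, size=n_dots)
        norm, angle = resultant_vector(directions)
        if condition == PREDICTIVE or norm < AMBIGUOUS_NORM_BOUND:
            break
    else:
        raise RuntimeError(
            f"could not draw an ambiguous cue with resultant norm < "
            f"{AMBIGUOUS_NORM_BOUND} in {max_redraws} redraws (n_dots={n_dots})")
    if target_side is None:
        target_side = side_from_direction(mean_direction)
    return CueStimulus(directions=directions, n_dots=n_dots,
                       mean_direction=float(mean_direction),
                       coherence=float(coherence), resultant_norm=norm,
                       resultant_angle=angle, condition=condition,
                       target_side=target_side)


# --------------------------------------------------------------------------
# behavior


@dataclass(frozen=True)
class ResponseModel:
    """Two-level behavioral response model.

    Reaction times are lognormal; the location parameter is shifted
    multiplicatively when the target appears at the unattended location
    and on ambiguous-cue trials, reproducing the slower / less accurate
    responses observed when attention is miscued. Target-identification
    error rates are Bernoulli at ``er_attended`` / ``er_unattended``.
    """

    median_rt_attended: float = 0.75   # s, predictive cue, attended target
    unattended_factor: float = 1.35
    ambiguous_factor: float = 1.30
    rt_sigma: float = 0.25             # lognormal shape
    max_rt: float = 3.0                # response window, s
    er_attended: float = 0.10
    er_unattended: float = 0.50


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    block: int
    condition: str
    target_side: str
    target_orientation: int          # +45 or -45 degrees
    attended_side: str               # generator ground truth
    reported_match: bool             # subjective report: target at attended side
    response_correct: bool
    rt: float                        # s
    target_onset_sample: int


def simulate_behavior(cue: CueStimulus, spatial_er_predictive: float,
                      spatial_er_ambiguous: float, rt_model: ResponseModel,
                      rng: np.random.Generator, *, trial_index: int = 0,
                      block: int = 0, target_orientation: int = 45,
                      target_onset_sample: int = 0,
                      report_noise: float = 0.0) -> TrialRecord:
    """Simulate one trial's covert attention shift, response, and report.

    The subject attends the target side with probability 1 - spatial_er
    for the cue's condition ("spatial error" otherwise) and truthfully
    reports whether the target appeared at the attended location, up to
    an optional report-noise flip probability.
    """
    for p in (spatial_er_predictive, spatial_er_ambiguous, report_noise):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    er = spatial_er_predictive if cue.condition == PREDICTIVE else spatial_er_ambiguous
    spatial_error = rng.random() < er
    attended = cue.target_side if not spatial_error else _other(cue.target_side)
    match = attended == cue.target_side
    reported = match if rng.random() >= report_noise else not match
    p_err = rt_model.er_attended if match else rt_model.er_unattended
    correct = rng.random() >= p_err
    median = rt_model.median_rt_attended
    if not match:
        median *= rt_model.unattended_factor
    if cue.condition == AMBIGUOUS:
        median *= rt_model.ambiguous_factor
    rt = float(np.exp(rng.normal(np.log(median), rt_model.rt_sigma)))
    rt = min(rt, rt_model.max_rt)
    return TrialRecord(trial_index=trial_index, block=block,
                       condition=cue.condition, target_side=cue.target_side,
                       target_orientation=target_orientation,
                       attended_side=attended, reported_match=reported,
                       response_correct=correct, rt=rt,
                       target_onset_sample=target_onset_sample)


def _other(side: str) -> str:
    return LEFT if side == RIGHT else RIGHT


# --------------------------------------------------------------------------
# EEG forward model


@dataclass
class GroundTruth:
    """Planted parameters of the synthetic EEG model."""

    mixing_left: np.ndarray        # unit-norm topography, left alpha source
    mixing_right: np.ndarray
    modulation_depth: float        # ipsilateral gain (1+d), contralateral 1/(1+d)
    noise_amplitude: float         # per-channel sensor-noise SD, uV
    alpha_amplitude: float         # source SD, uV
    amplitude_jitter: float        # lognormal sigma of per-trial source gain
    alpha_band: tuple[float, float]
    artifact_trial_indices: set[int]
    seed: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mixing_left"] = self.mixing_left.tolist()
        d["mixing_right"] = self.mixing_right.tolist()
        d["artifact_trial_indices"] = sorted(self.artifact_trial_indices)
        d["alpha_band"] = list(self.alpha_band)
        return d


def make_ground_truth(*, modulation_depth: float = 1.0,
                      noise_amplitude: float = 15.0,
                      alpha_amplitude: float = 20.0,
                      amplitude_jitter: float = 0.2,
                      alpha_band: tuple[float, float] = (8.0, 14.0),
                      seed: int = 0) -> GroundTruth:
    if modulation_depth < 0:
        raise ValueError("modulation_depth must be >= 0")
    return GroundTruth(
        mixing_left=ch.source_topography(ch.LEFT_POSTERIOR),
        mixing_right=ch.source_topography(ch.RIGHT_POSTERIOR),
        modulation_depth=modulation_depth, noise_amplitude=noise_amplitude,
        alpha_amplitude=alpha_amplitude, amplitude_jitter=amplitude_jitter,
        alpha_band=alpha_band, artifact_trial_indices=set(), seed=seed)


def _narrowband_source(n: int, band: tuple[float, float], sfreq: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance narrowband Gaussian oscillation (filtered white noise)."""
    white = rng.standard_normal(n)
    b, a = sp_signal.butter(4, band, btype="band", fs=sfreq)
    s = sp_signal.filtfilt(b, a, white)
    sd = s.std()
    return s / sd if sd > 0 else s


def _pink_noise(shape: tuple[int, int], sfreq: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-shaped noise per row, spectrum flattened below 1 Hz."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    spec /= np.sqrt(np.maximum(freqs, 1.0))
    spec[:, 0] = 0.0
    out = np.fft.irfft(spec, n=n, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _eog_drift(n: int, sfreq: float, amplitudes: tuple[float, ...],
               rng: np.random.Generator) -> np.ndarray:
    """Bounded slow drift: sum of low-frequency sinusoids plus 1 uV noise."""
    t = np.arange(n) / sfreq
    drift = np.zeros(n)
    for amp in amplitudes:
        f = rng.uniform(0.05, 0.4)
        phase = rng.uniform(0, 2 * np.pi)
        drift += amp * np.sin(2 * np.pi * f * t + phase)
    return drift + rng.standard_normal(n)


def _half_cosine_pulse(n: int, center: int, width: int,
                       amplitude: float) -> np.ndarray:
    pulse = np.zeros(n)
    start = max(center - width // 2, 0)
    stop = min(start + width, n)
    k = np.arange(stop - start)
    pulse[start:stop] = amplitude * 0.5 * (1 - np.cos(2 * np.pi * k / max(width - 1, 1)))
    return pulse


def simulate_eeg_trial(attended_side: str, duration: float, truth: GroundTruth,
                       rng: np.random.Generator, *, sfreq: float = 1024.0,
                       artifact: str | None = None,
                       artifact_center: int | None = None,
                       artifact_amplitude: float | None = None,
                       artifact_width: float = 0.25) -> np.ndarray:
    """Simulate one trial segment: (64 EEG + hEOG + vEOG) x samples, in uV.

    signal = mixing_left * s_L + mixing_right * s_R + noise, with the
    alpha source ipsilateral to ``attended_side`` scaled by sqrt(1+d) and
    the contralateral one by 1/sqrt(1+d) (variance (1+d)^{+-1}), so total
    power is balanced across classes. ``artifact`` ("veog" | "heog")
    injects a half-cosine deflection centered at ``artifact_center``.
    """
    if truth.modulation_depth < 0:
        raise ValueError("modulation_depth must be >= 0")
    if attended_side not in (LEFT, RIGHT):
        raise ValueError(f"unknown side {attended_side!r}")
    n = int(round(duration * sfreq))
    if n < 2:
        raise ValueError("duration too short")
    gain = np.sqrt(1.0 + truth.modulation_depth)
    g_left = gain if attended_side == LEFT else 1.0 / gain
    g_right = gain if attended_side == RIGHT else 1.0 / gain

    s_left = _narrowband_source(n, truth.alpha_band, sfreq, rng)
    s_right = _narrowband_source(n, truth.alpha_band, sfreq, rng)
    jitter_l = float(np.exp(rng.normal(0.0, truth.amplitude_jitter)))
    jitter_r = float(np.exp(rng.normal(0.0, truth.amplitude_jitter)))
    amp_l = truth.alpha_amplitude * g_left * jitter_l
    amp_r = truth.alpha_amplitude * g_right * jitter_r

    eeg = (np.outer(truth.mixing_left, amp_l * s_left)
           + np.outer(truth.mixing_right, amp_r * s_right))
    if truth.noise_amplitude > 0:
        pink = _pink_noise((ch.N_EEG, n), sfreq, rng)
        eeg = eeg + truth.noise_amplitude * (ch.noise_mixing() @ pink)

    heog = _eog_drift(n, sfreq, (3.0, 2.0, 1.0), rng)
    veog = _eog_drift(n, sfreq, (6.0, 4.0, 2.0), rng)
    if artifact is not None:
        if artifact not in ("veog", "heog"):
            raise ValueError(f"unknown artifact channel {artifact!r}")
        center = n // 2 if artifact_center is None else int(artifact_center)
        width = int(round(artifact_width * sfreq))
        if artifact_amplitude is None:
            artifact_amplitude = 150.0 if artifact == "veog" else 60.0
        pulse = _half_cosine_pulse(n, center, width, artifact_amplitude)
        if artifact == "veog":
            veog = veog + pulse
        else:
            heog = heog + pulse
    return np.vstack([eeg, heog[None, :], veog[None, :]])


# --------------------------------------------------------------------------
# whole sessions


@dataclass(frozen=True)
class SessionConfig:
    """Generator parameters; defaults reproduce the experiment's design."""

    n_blocks: int = 8
    trials_per_block: int = 52
    prop_predictive: float = 0.75
    sfreq: float = 1024.0
    n_dots: int = 400
    coherence_predictive: float = 1.29  # across-subject mean coherence threshold
    spatial_er_predictive: float = 0.10
    spatial_er_ambiguous: float = 0.50
    report_noise: float = 0.0
    modulation_depth: float = 1.0
    alpha_amplitude: float = 20.0
    noise_amplitude: float = 15.0
    amplitude_jitter: float = 0.2
    alpha_band: tuple[float, float] = (8.0, 14.0)
    artifact_fraction: float = 0.015
    artifact_veog: float = 150.0
    artifact_heog: float = 60.0
    cue_duration: float = 0.25
    delay_min: float = 1.5
    delay_max: float = 2.5
    post_target: float = 0.5
    rt_model: ResponseModel = field(default_factory=ResponseModel)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def validate(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("trial counts must be positive")
        for p in (self.prop_predictive, self.spatial_er_predictive,
                  self.spatial_er_ambiguous, self.report_noise,
                  self.artifact_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if self.modulation_depth < 0:
            raise ValueError("modulation_depth must be >= 0")
        if not 0 < self.delay_min <= self.delay_max:
            raise ValueError("invalid delay range")


@dataclass
class SessionData:
    """One simulated recording: continuous signal, events, and ground truth."""

    signal: np.ndarray                 # (66, samples) float32, uV
    channel_labels: tuple[str, ...]
    sfreq: float
    trials: list[TrialRecord]
    planted: GroundTruth
    config: SessionConfig
    cues: list[CueStimulus] = field(default_factory=list, repr=False)

    def trials_frame(self):
        import pandas as pd
        return pd.DataFrame([dataclasses.asdict(t) for t in self.trials])


def largest_remainder(proportions, n: int) -> np.ndarray:
    """Integer allocation of n items to proportions, largest-remainder rule."""
    quotas = np.asarray(proportions, dtype=float) * n
    base = np.floor(quotas).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    return base


def expected_spatial_error_rate(config: SessionConfig) -> float:
    """Design-expected overall unattended-target rate from the condition mix."""
    return (config.prop_predictive * config.spatial_er_predictive
            + (1.0 - config.prop_predictive) * config.spatial_er_ambiguous)


def _balanced_assignment(values: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    """Random order of two values with counts differing by at most 1."""
    counts = largest_remainder([0.5, 0.5], n)
    if n % 2 == 1 and rng.random() < 0.5:
        counts = counts[::-1]
    arr = np.array([values[0]] * counts[0] + [values[1]] * counts[1], dtype=object)
    return rng.permutation(arr)


def generate_session(config: SessionConfig, seed: int) -> SessionData:
    """Generate one full synthetic session (deterministic given seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_trials

    counts = largest_remainder([config.prop_predictive,
                                1.0 - config.prop_predictive], n)
    logger.info("condition allocation (largest remainder): %d predictive, "
                "%d ambiguous of %d trials", counts[0], counts[1], n)
    conditions = rng.permutation(
        np.array([PREDICTIVE] * counts[0] + [AMBIGUOUS] * counts[1], dtype=object))

    sides = np.empty(n, dtype=object)
    orientations = np.empty(n, dtype=int)
    for cond in (PREDICTIVE, AMBIGUOUS):
        idx = np.flatnonzero(conditions == cond)
        sides[idx] = _balanced_assignment((LEFT, RIGHT), len(idx), rng)
        for side in (LEFT, RIGHT):
            sub = idx[sides[idx] == side]
            orientations[sub] = _balanced_assignment((45, -45), len(sub), rng)

    n_artifact = int(largest_remainder(
        [config.artifact_fraction, 1.0 - config.artifact_fraction], n)[0])
    artifact_idx = set(map(int, rng.choice(n, size=n_artifact, replace=False))) \
        if n_artifact else set()
    artifact_channel = {i: ("veog" if rng.integers(2) == 0 else "heog")
                        for i in sorted(artifact_idx)}

    delays = rng.uniform(config.delay_min, config.delay_max, size=n)
    pre = np.round((config.cue_duration + delays) * config.sfreq).astype(int)
    post = int(round(config.post_target * config.sfreq))
    seg_len = pre + post
    offsets = np.concatenate([[0], np.cumsum(seg_len)[:-1]])
    total = int(seg_len.sum())

    truth = make_ground_truth(
        modulation_depth=config.modulation_depth,
        noise_amplitude=config.noise_amplitude,
        alpha_amplitude=config.alpha_amplitude,
        amplitude_jitter=config.amplitude_jitter,
        alpha_band=config.alpha_band, seed=seed)
    truth.artifact_trial_indices = artifact_idx

    epoch_len = int(round(1.5 * config.sfreq))
    signal = np.empty((ch.N_EEG + 2, total), dtype=np.float32)
    trials: list[TrialRecord] = []
    cues: list[CueStimulus] = []
    for i in range(n):
        mean_dir = 0.0 if sides[i] == RIGHT else np.pi
        coherence = config.coherence_predictive if conditions[i] == PREDICTIVE else 0.0
        cue = generate_cue(config.n_dots, mean_dir, coherence, rng,
                           target_side=sides[i])
        onset = int(offsets[i] + pre[i])
        rec = simulate_behavior(
            cue, config.spatial_er_predictive, config.spatial_er_ambiguous,
            config.rt_model, rng, trial_index=i,
            block=i // config.trials_per_block,
            target_orientation=int(orientations[i]),
            target_onset_sample=onset, report_noise=config.report_noise)
        artifact = artifact_channel.get(i)
        amp = None
        center = None
        if artifact is not None:
            amp = config.artifact_veog if artifact == "veog" else config.artifact_heog
            # center the deflection in the pre-target epoch window
            center = max(int(pre[i]) - epoch_len // 2, 0)
        seg = simulate_eeg_trial(
            rec.attended_side, seg_len[i] / config.sfreq, truth, rng,
            sfreq=config.sfreq, artifact=artifact, artifact_center=center,
            artifact_amplitude=amp)
        signal[:, offsets[i]:offsets[i] + seg_len[i]] = seg.astype(np.float32)
        trials.append(rec)
        cues.append(cue)

    return SessionData(signal=signal, channel_labels=ch.ALL_CHANNELS,
                       sfreq=config.sfreq, trials=trials, planted=truth,
                       config=config, cues=cues)
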