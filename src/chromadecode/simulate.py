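"""Seeded synthetic evoked-response generator.

Emulates the statistical structure of multi-sensor epoched recordings of
responses to the eight colored stimuli (4 hues x 2 luminance polarities):
a transient polarity signal peaking ~100 ms after stimulus onset with a
second transient at stimulus offset, and a later (~120 ms), more sustained
hue signal.  Each signal is a fixed per-subject spatial pattern over sensors
multiplied by a temporal profile, plus Gaussian (optionally AR(1)) sensor
noise.

The per-trial signal for condition ``(h, p)`` at sensor ``i`` and time ``t`` is ::

    x(i,t) = sign(p) * [ a_pol * w_shared(i)
                         + a_pol_hue * w_hue(i, h)
                         + beta_LM * sgn_LM(h) * w_LM(i)
                         + beta_S  * sgn_S(h)  * w_S(i) ] * f_pol(t)
           + sum_axis sgn_axis(h) * [ a_hue * w_ax(i, axis)
                         + a_hue_pol * w_ax_pol(i, axis, p) ] * f_hue(t)
           + noise(i, t)

where ``sgn_LM, sgn_S`` follow the DKL azimuth sign table.  The shared
spatial components carry the feature-invariant (generalizing) part of each
code; the hue-specific polarity component and the polarity-specific hue
component carry the non-generalizing part; and the cone-mechanism maps
``w_LM, w_S`` make polarity generalization between two hues degrade with the
number of cone-opponent sign axes that flip between them.

All randomness flows from ``SimulationConfig.seed`` through per-subject seed
sequences, so identical ``(config, subject_index)`` produce bit-identical
epochs regardless of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .colorimetry import AZIMUTH_BY_HUE, HUES, POLARITIES, SIGN_TABLE

__all__ = ["SimulationConfig", "EpochSet", "simulate_subject", "simulate_cohort"]

CONDITIONS = tuple(f"{p}_{h}" for h in HUES for p in POLARITIES)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Amplitudes are peak pattern amplitudes in fT per unit spatial weight;
    latencies, durations and taus in ms; ``noise_sd`` is the per-sample
    sensor noise SD in fT.
    """

    n_subjects: int = 18
    n_sensors: int = 306
    n_trials_per_condition: int = 500
    sample_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-200.0, 600.0)
    stimulus_duration: float = 116.0
    polarity_latency: float = 100.0
    hue_latency: float = 120.0
    polarity_offset_response_gain: float = 0.7
    hue_offset_gain: float = 0.3
    sustain_tau_polarity: float = 30.0
    sustain_tau_hue: float = 150.0
    sustain_gain_polarity: float = 0.25
    sustain_gain_hue: float = 0.45
    sustain_delay: float = 30.0
    transient_shape: float = 16.0
    amp_polarity_shared: float = 4.0
    amp_polarity_hue_specific: float = 1.2
    amp_hue_shared: float = 3.0
    amp_hue_polarity_specific: float = 2.0
    beta_LM: float = 0.8
    beta_S: float = 0.8
    noise_sd: float = 200.0
    noise_ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_sensors, self.n_trials_per_condition) <= 0:
            raise ValueError("counts must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lo, hi = self.epoch_window
        if not (lo <= 0.0 and hi >= self.stimulus_duration):
            raise ValueError("epoch window must contain 0 and stimulus_duration")
        if self.sustain_tau_polarity <= 0 or self.sustain_tau_hue <= 0:
            raise ValueError("sustain taus must be positive")
        if self.transient_shape <= 1:
            raise ValueError("transient_shape must exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass
class EpochSet:
    """Condition-labeled single-trial sensor epochs for one subject.

    ``data`` is trials x sensors x samples in fT; ``time`` gives each
    sample's latency in ms relative to stimulus onset.
    """

    data: np.ndarray
    condition_labels: np.ndarray
    time: np.ndarray
    subject_id: str
    sample_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.condition_labels = np.asarray(self.condition_labels)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x samples")
        if len(self.condition_labels) != self.data.shape[0]:
            raise ValueError("one condition label per trial required")
        if len(self.time) != self.data.shape[2]:
            raise ValueError("time axis length mismatch")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time must be strictly increasing and uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.condition_labels.tolist()))

    def trial_indices(self, condition: str) -> np.ndarray:
        idx = np.flatnonzero(self.condition_labels == condition)
        if idx.size == 0:
            raise ValueError(f"no trials for condition {condition!r}")
        return idx


def _transient(t: np.ndarray, latency: float, shape: float) -> np.ndarray:
    """Gamma-shaped bump with mode at ``latency`` and unit peak amplitude."""
    k = shape - 1.0
    tau = latency / k
    x = np.clip(t, 0.0, None) / tau
    # (x/k)^k * exp(k - x): unit peak at x = k, i.e. t = latency
    with np.errstate(invalid="ignore"):
        y = np.where(
            t > 0,
            np.exp(k * (np.log(np.maximum(x, 1e-300)) - np.log(k)) + (k - x)),
            0.0,
        )
    return y


def _plateau(
    t: np.ndarray,
    latency: float,
    duration: float,
    tau: float,
    delay: float = 30.0,
    rise: float = 20.0,
) -> np.ndarray:
    """Sustained component: a plateau rising ``delay`` ms after the transient
    peak (so the profile's maximum stays pinned at the latency) and decaying
    with time constant ``tau`` once the post-stimulus response ends."""
    start = latency + delay
    ramp = 1.0 - np.exp(-np.clip(t - start, 0.0, None) / rise)
    decay = np.exp(-np.clip(t - latency - duration, 0.0, None) / tau)
    return np.where(t > start, ramp * decay, 0.0)


def temporal_profiles(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(time, f_pol, f_hue)`` on the configured sample grid."""
    lo, hi = config.epoch_window
    dt = 1000.0 / config.sample_rate
    time = np.arange(lo, hi, dt)
    sh, dur = config.transient_shape, config.stimulus_duration
    f_pol = (
        _transient(time, config.polarity_latency, sh)
        + config.polarity_offset_response_gain * _transient(time - dur, config.polarity_latency, sh)
        + config.sustain_gain_polarity
        * _plateau(
            time, config.polarity_latency, dur, config.sustain_tau_polarity,
            delay=config.sustain_delay,
        )
    )
    f_hue = (
        _transient(time, config.hue_latency, sh)
        + config.hue_offset_gain * _transient(time - dur, config.hue_latency, sh)
        + config.sustain_gain_hue
        * _plateau(
            time, config.hue_latency, dur, config.sustain_tau_hue,
            delay=config.sustain_delay,
        )
    )
    return time, f_pol, f_hue


def _condition_patterns(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Draw this subject's spatial maps and compose per-condition patterns."""
    s = config.n_sensors
    w_shared = rng.standard_normal(s)
    w_hue_specific = {h: rng.standard_normal(s) for h in HUES}
    w_lm = rng.standard_normal(s)
    w_s = rng.standard_normal(s)
    w_axis = {ax: rng.standard_normal(s) for ax in ("LM", "S")}
    w_axis_pol = {(ax, p): rng.standard_normal(s) for ax in ("LM", "S") for p in POLARITIES}

    patterns = {}
    for cond in CONDITIONS:
        p, _, h = cond.partition("_")
        p_sign = +1.0 if p == "light" else -1.0
        sgn_lm, sgn_s = SIGN_TABLE[AZIMUTH_BY_HUE[h]]
        pol_pattern = p_sign * (
            config.amp_polarity_shared * w_shared
            + config.amp_polarity_hue_specific * w_hue_specific[h]
            + config.beta_LM * sgn_lm * w_lm
            + config.beta_S * sgn_s * w_s
        )
        hue_pattern = np.zeros(s)
        for ax, sgn in (("LM", sgn_lm), ("S", sgn_s)):
            hue_pattern += sgn * (
                config.amp_hue_shared * w_axis[ax]
                + config.amp_hue_polarity_specific * w_axis_pol[(ax, p)]
            )
        patterns[cond] = (pol_pattern, hue_pattern)
    return patterns


def simulate_subject(config: SimulationConfig, subject_index: int) -> EpochSet:
    """Generate one subject's epochs, bit-reproducible from (config, index)."""
    if not 0 <= subject_index:
        raise ValueError("subject_index must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), subject_index]))
    time, f_pol, f_hue = temporal_profiles(config)
    patterns = _condition_patterns(config, rng)

    n = config.n_trials_per_condition
    n_samples = len(time)
    data = np.empty((n * len(CONDITIONS), config.n_sensors, n_samples), dtype=np.float32)
    labels = np.empty(n * len(CONDITIONS), dtype=object)
    for ci, cond in enumerate(CONDITIONS):
        pol_pattern, hue_pattern = patterns[cond]
        signal = np.outer(pol_pattern, f_pol) + np.outer(hue_pattern, f_hue)
        block = slice(ci * n, (ci + 1) * n)
        if config.noise_sd > 0:
            eps = rng.standard_normal((n, config.n_sensors, n_samples), dtype=np.float32)
            if config.noise_ar1 > 0:
                eps *= np.float32(config.noise_sd * np.sqrt(1.0 - config.noise_ar1**2))
                eps = lfilter([1.0], [1.0, -config.noise_ar1], eps, axis=-1)
            else:
                eps *= np.float32(config.noise_sd)
            data[block] = signal.astype(np.float32)[None] + eps
        else:
            data[block] = np.broadcast_to(signal[None], (n,) + signal.shape).astype(np.float32)
        labels[block] = cond
    return EpochSet(
        data=data,
        condition_labels=labels,
        time=time,
        subject_id=f"sub-{subject_index:02d}",
        sample_rate=config.sample_rate,
    )


def simulate_cohort(config: SimulationConfig) -> list[EpochSet]:
    """Generate one :class:`EpochSet` per subject with independent seeds."""
    return [simulate_subject(config, i) for i in range(config.n_subjects)]
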