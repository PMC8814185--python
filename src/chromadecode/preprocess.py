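"""Trial screening, subsampling, baseline removal and temporal binning.

The decoding engine consumes :class:`BinnedEpochs`: equal trial counts per
condition, baseline-corrected, averaged into non-overlapping 5 ms bins
(160 bins for the default -200..600 ms epoch, with stimulus onset at the
first sample of bin 40).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import EpochSet

__all__ = [
    "BinnedEpochs",
    "reject_artifacts",
    "subsample_trials",
    "baseline_correct",
    "bin_epochs",
    "preprocess_pipeline",
]


class InsufficientTrialsError(ValueError):
    """Raised when a condition no longer has enough trials."""


@dataclass
class BinnedEpochs:
    """Trials x sensors x time-bin array with a uniform bin timeline."""

    data: np.ndarray
    condition_labels: np.ndarray
    bin_start_times: np.ndarray
    bin_width: float
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.condition_labels = np.asarray(self.condition_labels)
        self.bin_start_times = np.asarray(self.bin_start_times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x bins")
        if len(self.condition_labels) != self.data.shape[0]:
            raise ValueError("one condition label per trial required")
        if len(self.bin_start_times) != self.data.shape[2]:
            raise ValueError("bin timeline length mismatch")
        starts = self.bin_start_times
        if len(starts) > 1 and not np.allclose(np.diff(starts), self.bin_width):
            raise ValueError("bins must be uniform and non-overlapping")

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

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

    def bin_index(self, time_ms: float) -> int:
        """Index of the bin whose half-open window [start, start+w) covers ``time_ms``."""
        starts = self.bin_start_times
        if not starts[0] <= time_ms < starts[-1] + self.bin_width:
            raise ValueError(f"{time_ms} ms outside the binned epoch")
        return int(np.searchsorted(starts, time_ms, side="right") - 1)


def reject_artifacts(epochs: EpochSet, lo: float = 0.1, hi: float = 8000.0) -> EpochSet:
    """Drop trials with out-of-range activity on any sensor at any sample.

    A trial survives only if every sample's absolute value lies within
    ``[lo, hi]`` fT on every sensor; survivor order is preserved.  Raises
    :class:`InsufficientTrialsError` if a condition loses all its trials.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    absd = np.abs(epochs.data)
    bad = ((absd < lo) | (absd > hi)).any(axis=(1, 2))
    keep = ~bad
    survivors = epochs.condition_labels[keep]
    for cond in epochs.conditions:
        if not np.any(survivors == cond):
            raise InsufficientTrialsError(
                f"artifact rejection removed every trial of condition {cond!r}"
            )
    return EpochSet(
        data=epochs.data[keep],
        condition_labels=survivors,
        time=epochs.time,
        subject_id=epochs.subject_id,
        sample_rate=epochs.sample_rate,
    )


def subsample_trials(
    epochs: EpochSet, n_per_condition: int = 375, seed: int | None = 0
) -> EpochSet:
    """Randomly subsample (without replacement) to equal trial counts.

    Selected trials keep their original relative order.
    """
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    for cond in epochs.conditions:
        idx = epochs.trial_indices(cond)
        if idx.size < n_per_condition:
            raise InsufficientTrialsError(
                f"condition {cond!r} has {idx.size} trials, need {n_per_condition}"
            )
        chosen = rng.choice(idx, size=n_per_condition, replace=False)
        keep_idx.append(np.sort(chosen))
    keep = np.sort(np.concatenate(keep_idx))
    return EpochSet(
        data=epochs.data[keep],
        condition_labels=epochs.condition_labels[keep],
        time=epochs.time,
        subject_id=epochs.subject_id,
        sample_rate=epochs.sample_rate,
    )


def baseline_correct(
    epochs: EpochSet, baseline_window: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract each trial's per-sensor mean over the baseline window."""
    lo, hi = baseline_window
    mask = (epochs.time >= lo) & (epochs.time < hi)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        data=epochs.data - baseline,
        condition_labels=epochs.condition_labels,
        time=epochs.time,
        subject_id=epochs.subject_id,
        sample_rate=epochs.sample_rate,
    )


def bin_epochs(epochs: EpochSet, bin_width: float = 5.0) -> BinnedEpochs:
    """Average samples into non-overlapping ``bin_width`` ms bins.

    Bins are half-open [start, start + width) and labeled by start time; the
    epoch must divide evenly into whole bins (no partial bins).
    """
    samples_per_bin = bin_width * epochs.sample_rate / 1000.0
    if abs(samples_per_bin - round(samples_per_bin)) > 1e-9:
        raise ValueError("bin width must be a whole number of samples")
    spb = int(round(samples_per_bin))
    n_samples = epochs.data.shape[2]
    if n_samples % spb != 0:
        raise ValueError(
            f"{n_samples} samples do not divide into {bin_width} ms bins "
            f"({spb} samples each)"
        )
    n_bins = n_samples // spb
    n_trials, n_sensors = epochs.data.shape[:2]
    binned = epochs.data.reshape(n_trials, n_sensors, n_bins, spb).mean(axis=3)
    starts = epochs.time[::spb]
    return BinnedEpochs(
        data=binned,
        condition_labels=epochs.condition_labels,
        bin_start_times=starts,
        bin_width=bin_width,
        subject_id=epochs.subject_id,
    )


def preprocess_pipeline(
    epochs: EpochSet,
    n_per_condition: int | None = 375,
    reject_bounds: tuple[float, float] | None = None,
    baseline_window: tuple[float, float] = (-200.0, 0.0),
    bin_width: float = 5.0,
    seed: int | None = 0,
) -> BinnedEpochs:
    """reject -> subsample -> baseline -> bin, each stage optional.

    ``reject_bounds`` defaults to None (screen disabled): the amplitude
    screen targets recording artifacts and would misfire on white-noise
    synthetic data, where zero crossings fall below any positive lower bound.
    """
    if reject_bounds is not None:
        epochs = reject_artifacts(epochs, *reject_bounds)
    if n_per_condition is not None:
        epochs = subsample_trials(epochs, n_per_condition, seed=seed)
    if baseline_window is not None:
        epochs = baseline_correct(epochs, baseline_window)
    return bin_epochs(epochs, bin_width)
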