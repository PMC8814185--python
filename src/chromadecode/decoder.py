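"""Maximum-correlation-coefficient decoding engine.

The classifier is deliberately simple: it averages the training pseudo-trials
of each class into a mean population vector and assigns a test vector to the
class whose mean it correlates with best (Pearson, over the selected
sensors).  All of the machinery around it follows the pseudo-trial
cross-validation scheme used for noisy sensor epochs:

* per run, the trials of each condition are randomly partitioned into
  ``n_splits`` disjoint sets of ``trials_per_split`` trials, each averaged
  into one pseudo-trial;
* per fold, train and test data are z-scored per sensor with the mean/SD of
  the training pseudo-trials pooled over *all* time bins, and the
  ``n_selected_sensors`` sensors whose activity co-varies most with the
  training labels (one-way ANOVA F) are selected from training data only;
* accuracy at each bin is averaged over folds and over ``n_runs``
  re-randomizations of the partition.

Identity problems use standard leave-one-set-out cross-validation.
Generalization problems train on all pseudo-trial sets of the train
conditions and test on pseudo-trial sets built from the (disjoint) test
conditions, so no trial ever contributes to both sides.

``run_temporal_generalization`` applies each train-bin classifier (with its
train-bin sensor selection and training z-statistics) to test pseudo-trials
at every bin; its diagonal reproduces ``run_problem`` under shared seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .preprocess import BinnedEpochs
from .problems import ProblemSpec

__all__ = [
    "CVConfig",
    "DecodingCurve",
    "TGMatrix",
    "max_corr_classify",
    "make_pseudotrials",
    "select_sensors",
    "run_problem",
    "run_temporal_generalization",
    "subsample_to_match_peak",
    "PeakMatchError",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation scheme: ``n_splits`` sets of ``trials_per_split``
    trial averages, re-randomized ``n_runs`` times."""

    n_splits: int = 5
    trials_per_split: int = 75
    n_runs: int = 50
    n_selected_sensors: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValueError("need at least 2 cross-validation splits")
        if self.trials_per_split < 1 or self.n_runs < 1:
            raise ValueError("trials_per_split and n_runs must be positive")
        if self.n_selected_sensors < 2:
            raise ValueError("need at least 2 selected sensors")

    def with_(self, **kwargs) -> "CVConfig":
        return replace(self, **kwargs)


@dataclass
class DecodingCurve:
    """Per-bin classification accuracy for one problem and subject."""

    accuracy: np.ndarray
    bin_start_times: np.ndarray
    problem_id: str
    subject_id: str
    n_runs: int
    tie_count: int = 0
    selection_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 1):
            raise ValueError("accuracies must lie in [0, 1]")
        if len(self.accuracy) != len(self.bin_start_times):
            raise ValueError("accuracy and timeline lengths differ")


@dataclass
class TGMatrix:
    """Train-bin x test-bin accuracy matrix for one problem and subject."""

    accuracy: np.ndarray
    bin_start_times: np.ndarray
    problem_id: str
    subject_id: str
    n_runs: int
    tie_count: int = 0

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.accuracy.ndim != 2 or self.accuracy.shape[0] != self.accuracy.shape[1]:
            raise ValueError("TG matrix must be square")

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.accuracy).copy()


class ClassifierDecision(NamedTuple):
    class_index: int
    correlations: np.ndarray
    tie: bool


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; defined as 0 when either vector has zero variance."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def max_corr_classify(class_means: np.ndarray, test_vector: np.ndarray) -> ClassifierDecision:
    """Assign ``test_vector`` to the class mean it correlates with best.

    Exact ties go to the lower class index and are flagged.
    """
    class_means = np.asarray(class_means, dtype=float)
    test_vector = np.asarray(test_vector, dtype=float)
    if class_means.ndim != 2 or class_means.shape[1] < 2:
        raise ValueError("need class means over at least 2 sensors")
    corrs = np.array([_pearson(m, test_vector) for m in class_means])
    best = int(np.argmax(corrs))  # argmax returns the first (lowest) maximizer
    tie = bool(np.sum(corrs == corrs[best]) > 1)
    return ClassifierDecision(best, corrs, tie)


def make_pseudotrials(
    trials: np.ndarray,
    labels: np.ndarray,
    n_splits: int,
    trials_per_split: int,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Average disjoint random trial sets into ``n_splits`` pseudo-trials per class.

    ``trials`` is trials x sensors (one bin) or trials x sensors x bins; the
    leading axis of each returned array indexes the pseudo-trial set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = np.asarray(trials)
    labels = np.asarray(labels)
    out: dict[str, np.ndarray] = {}
    for lab in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == lab)
        need = n_splits * trials_per_split
        if idx.size < need:
            raise ValueError(
                f"class {lab!r} has {idx.size} trials, need {need} for "
                f"{n_splits} x {trials_per_split}"
            )
        perm = rng.permutation(idx.size)[:need].reshape(n_splits, trials_per_split)
        out[lab] = trials[idx[perm]].mean(axis=1)
    return out


def _anova_scores(group0: np.ndarray, group1: np.ndarray) -> np.ndarray:
    """Per-feature class-separation score: one-way ANOVA F (or |mean diff|
    when within-group degrees of freedom vanish).  Shapes (m, S[, B])."""
    m = group0.shape[0]
    mean0, mean1 = group0.mean(axis=0), group1.mean(axis=0)
    if m > 1:
        ssw = ((group0 - mean0) ** 2).sum(axis=0) + ((group1 - mean1) ** 2).sum(axis=0)
        ssb = m * (mean0 - mean1) ** 2 / 2.0
        dfw = 2 * m - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ssb / (ssw / dfw)
        f = np.where(np.isnan(f), -np.inf, f)  # 0/0: no signal and no noise
        return f
    return np.abs(mean0 - mean1)


def select_sensors(
    train_pseudotrials: np.ndarray, labels: np.ndarray, k: int = 25
) -> np.ndarray:
    """Indices of the ``k`` sensors most label-covarying in the training data.

    Ranking is by one-way ANOVA p-value (ascending); zero-variance sensors
    are excluded before ranking.  If fewer than ``k`` sensors are usable all
    usable sensors are returned.
    """
    X = np.asarray(train_pseudotrials, dtype=float)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("sensor selection expects exactly 2 classes")
    g0, g1 = X[labels == classes[0]], X[labels == classes[1]]
    scores = _anova_scores(g0, g1)
    usable = X.var(axis=0) > 0
    scores = np.where(usable, scores, -np.inf)
    order = np.argsort(-scores, kind="stable")
    n_usable = int(usable.sum())
    if n_usable < k:
        import warnings

        warnings.warn(
            f"only {n_usable} usable sensors (< k={k}); using all usable",
            stacklevel=2,
        )
        return order[:n_usable]
    return order[:k]


def _normalize_rows(x: np.ndarray, axis: int) -> np.ndarray:
    """Center and L2-normalize along ``axis``; zero-variance rows become 0."""
    x = x - x.mean(axis=axis, keepdims=True)
    norm = np.linalg.norm(x, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, x / np.where(norm == 0, 1.0, norm), 0.0)
    return out


class _FoldOutcome(NamedTuple):
    correct: np.ndarray  # (B,) or (B_train, B_test) summed correct counts
    ties: int
    selection: np.ndarray  # (k, B) selected sensor indices


def _score_fold(
    train_groups: tuple[np.ndarray, np.ndarray],
    test_vectors: np.ndarray,
    k: int,
    temporal_generalization: bool,
) -> _FoldOutcome:
    """Train per-bin classifiers on one fold and score the test vectors.

    ``train_groups``: per-class (m, S, B) pseudo-trials (raw units).
    ``test_vectors``: (2, S, B), one pseudo-trial per class.
    """
    g0, g1 = train_groups
    train_stack = np.concatenate([g0, g1], axis=0)
    # z-scoring statistics from the training data pooled over all bins
    mu = train_stack.mean(axis=(0, 2), keepdims=True)
    sd = train_stack.std(axis=(0, 2), keepdims=True)
    sd_safe = np.where(sd == 0, 1.0, sd)
    g0z, g1z = (g0 - mu) / sd_safe, (g1 - mu) / sd_safe
    test_z = (test_vectors - mu) / sd_safe

    scores = _anova_scores(g0z, g1z)  # (S, B)
    per_bin_var = np.concatenate([g0z, g1z], axis=0).var(axis=0)
    scores = np.where(per_bin_var > 0, scores, -np.inf)
    scores = np.where(sd[0, :, :] > 0, scores, -np.inf)  # broadcast (S,1)->(S,B)
    sel = np.argsort(-scores, axis=0, kind="stable")[:k]  # (k, B)

    means = np.stack([g0z.mean(axis=0), g1z.mean(axis=0)])  # (2, S, B)
    means_sel = np.take_along_axis(means, sel[None], axis=1)  # (2, k, B)
    mn = _normalize_rows(means_sel, axis=1)

    ties = 0
    if not temporal_generalization:
        test_sel = np.take_along_axis(test_z, sel[None], axis=1)
        tn = _normalize_rows(test_sel, axis=1)
        corr = np.einsum("tkb,ckb->tcb", tn, mn)  # (test, class, bin)
        pred1 = corr[:, 1, :] > corr[:, 0, :]
        ties = int(np.sum(corr[:, 1, :] == corr[:, 0, :]))
        correct = (~pred1[0]).astype(float) + pred1[1].astype(float)  # (B,)
        return _FoldOutcome(correct, ties, sel)

    n_bins = test_z.shape[2]
    correct = np.empty((n_bins, n_bins))
    for bt in range(n_bins):
        sel_bt = sel[:, bt]
        test_sel = test_z[:, sel_bt, :]  # (2, k, B_test)
        tn = _normalize_rows(test_sel, axis=1)
        corr = np.einsum("tkb,ck->tcb", tn, mn[:, :, bt])  # (test, class, B_test)
        pred1 = corr[:, 1, :] > corr[:, 0, :]
        ties += int(np.sum(corr[:, 1, :] == corr[:, 0, :]))
        correct[bt] = (~pred1[0]).astype(float) + pred1[1].astype(float)
    return _FoldOutcome(correct, ties, sel)


def _gather_condition_data(
    binned: BinnedEpochs, problem: ProblemSpec
) -> dict[str, np.ndarray]:
    data = {}
    counts = set()
    for cond in problem.conditions:
        idx = binned.trial_indices(cond)
        counts.add(idx.size)
        data[cond] = np.asarray(binned.data[idx], dtype=float)
    if len(counts) != 1:
        raise ValueError(
            "conditions have unequal trial counts; equalize with "
            "preprocess.subsample_trials first"
        )
    return data


def _run_engine(
    binned: BinnedEpochs,
    problem: ProblemSpec,
    cv: CVConfig,
    temporal_generalization: bool,
    trial_fraction: float = 1.0,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Shared engine; returns (summed-correct array, tie count, selection counts)."""
    if binned.n_sensors < 2:
        raise ValueError("need at least 2 sensors")
    cond_data = _gather_condition_data(binned, problem)
    n_avail = next(iter(cond_data.values())).shape[0]

    tps = cv.trials_per_split
    if trial_fraction != 1.0:
        if not 0 < trial_fraction <= 1.0:
            raise ValueError("trial_fraction must lie in (0, 1]")
        tps = int(round(trial_fraction * n_avail)) // cv.n_splits
        if tps < 1:
            raise ValueError("trial_fraction leaves no trials per split")
    if cv.n_splits * tps > n_avail:
        raise ValueError(
            f"{cv.n_splits} x {tps} trials requested but only {n_avail} available "
            "per condition"
        )
    k = min(cv.n_selected_sensors, binned.n_sensors)

    generalization = problem.train_pair != problem.test_pair
    n_bins = binned.n_bins
    shape = (n_bins, n_bins) if temporal_generalization else (n_bins,)
    total_correct = np.zeros(shape)
    ties = 0
    selection_counts = np.zeros(binned.n_sensors, dtype=np.int64)
    n_tests = 0

    for run in range(cv.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([int(cv.seed), run]))
        pseudos = {}
        for cond in problem.conditions:  # fixed order: train pair then test pair
            X = cond_data[cond]
            perm = rng.permutation(n_avail)[: cv.n_splits * tps]
            pseudos[cond] = X[perm.reshape(cv.n_splits, tps)].mean(axis=1)

        tr0, tr1 = problem.train_pair
        te0, te1 = problem.test_pair
        for fold in range(cv.n_splits):
            if generalization:
                g0, g1 = pseudos[tr0], pseudos[tr1]
            else:
                keep = np.arange(cv.n_splits) != fold
                g0, g1 = pseudos[tr0][keep], pseudos[tr1][keep]
            test = np.stack([pseudos[te0][fold], pseudos[te1][fold]])
            outcome = _score_fold((g0, g1), test, k, temporal_generalization)
            total_correct += outcome.correct
            ties += outcome.ties
            np.add.at(selection_counts, outcome.selection.ravel(), 1)
            n_tests += 2

    return total_correct / n_tests, ties, selection_counts


def run_problem(
    binned: BinnedEpochs,
    problem: ProblemSpec,
    cv: CVConfig,
    trial_fraction: float = 1.0,
) -> DecodingCurve:
    """Cross-validated decoding accuracy per time bin for one problem."""
    acc, ties, sel_counts = _run_engine(binned, problem, cv, False, trial_fraction)
    return DecodingCurve(
        accuracy=acc,
        bin_start_times=binned.bin_start_times,
        problem_id=problem.id,
        subject_id=binned.subject_id,
        n_runs=cv.n_runs,
        tie_count=ties,
        selection_counts=sel_counts,
    )


def run_temporal_generalization(
    binned: BinnedEpochs, problem: ProblemSpec, cv: CVConfig, trial_fraction: float = 1.0
) -> TGMatrix:
    """Train at every bin, test at every bin (train bins index rows)."""
    acc, ties, _ = _run_engine(binned, problem, cv, True, trial_fraction)
    return TGMatrix(
        accuracy=acc,
        bin_start_times=binned.bin_start_times,
        problem_id=problem.id,
        subject_id=binned.subject_id,
        n_runs=cv.n_runs,
        tie_count=ties,
    )


class PeakMatchError(RuntimeError):
    """Bisection could not reach the target peak accuracy."""

    def __init__(self, message: str, bracket: tuple[float, float], peaks: tuple[float, float]):
        super().__init__(message)
        self.bracket = bracket
        self.peaks = peaks


def _window_peak(curve: DecodingCurve, window: tuple[float, float]) -> float:
    t = curve.bin_start_times
    mask = (t >= window[0]) & (t < window[1])
    if not mask.any():
        raise ValueError("peak window contains no bins")
    return float(curve.accuracy[mask].max())


def subsample_to_match_peak(
    binned: BinnedEpochs,
    problem: ProblemSpec,
    cv: CVConfig,
    target_peak_accuracy: float,
    tolerance: float = 0.005,
    peak_window: tuple[float, float] = (0.0, 250.0),
    max_iter: int = 25,
) -> tuple[float, DecodingCurve]:
    """Bisect the per-condition trial fraction until the peak matches a target.

    Used to compare decoding time courses between problems whose full-data
    peaks differ: the stronger problem's trials are thinned (pseudo-trial
    counts rescaled proportionally) until its peak accuracy inside
    ``peak_window`` matches the target within ``tolerance``.
    """
    full_curve = run_problem(binned, problem, cv)
    full_peak = _window_peak(full_curve, peak_window)
    if not 0.5 < target_peak_accuracy <= full_peak + tolerance:
        raise ValueError(
            f"target {target_peak_accuracy:.3f} outside (0.5, full peak "
            f"{full_peak:.3f}]"
        )
    if abs(full_peak - target_peak_accuracy) <= tolerance:
        return 1.0, full_curve

    n_avail = binned.trial_indices(problem.train_pair[0]).size
    f_lo = cv.n_splits / n_avail  # one trial per split
    f_hi, peak_hi = 1.0, full_peak
    curve_lo = run_problem(binned, problem, cv, trial_fraction=f_lo)
    peak_lo = _window_peak(curve_lo, peak_window)
    if abs(peak_lo - target_peak_accuracy) <= tolerance:
        return f_lo, curve_lo
    if peak_lo > target_peak_accuracy:
        raise PeakMatchError(
            "target below the reachable floor", (f_lo, f_hi), (peak_lo, peak_hi)
        )
    for _ in range(max_iter):
        f_mid = 0.5 * (f_lo + f_hi)
        curve = run_problem(binned, problem, cv, trial_fraction=f_mid)
        peak = _window_peak(curve, peak_window)
        if abs(peak - target_peak_accuracy) <= tolerance:
            return f_mid, curve
        if peak > target_peak_accuracy:
            f_hi, peak_hi = f_mid, peak
        else:
            f_lo, peak_lo = f_mid, peak
    raise PeakMatchError(
        f"no fraction reached the target within tolerance {tolerance}",
        (f_lo, f_hi),
        (peak_lo, peak_hi),
    )
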