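"""Model/Results interface over the decoding engine.

Mirrors the fit-then-inspect idiom of statistical modelling libraries: a
model object is built from data plus configuration, ``fit()`` does the work,
and the returned results object carries the estimates (accuracy curves or
matrices), their uncertainties (subject bootstrap), diagnostics
(cluster-corrected significance, onsets, tie counts) and a ``summary()``
table.

`SubjectDecoding` fits one problem for one subject.  `CohortDecoding` fits a
family of problems across a cohort and is the main entry point for
study-shaped analyses::

    cohort = simulate.simulate_cohort(sim_config)
    binned = [preprocess.preprocess_pipeline(e, n_per_condition=80) for e in cohort]
    model = CohortDecoding(binned, problems.polarity_problems(), cv)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference
from .decoder import (
    CVConfig,
    DecodingCurve,
    TGMatrix,
    run_problem,
    run_temporal_generalization,
)
from .preprocess import BinnedEpochs
from .problems import ProblemSpec

__all__ = [
    "SubjectDecoding",
    "SubjectDecodingResults",
    "CohortDecoding",
    "CohortDecodingResults",
]


class SubjectDecoding:
    """One binary decoding problem for one subject's binned epochs."""

    def __init__(self, binned: BinnedEpochs, problem: ProblemSpec, cv: CVConfig | None = None):
        self.binned = binned
        self.problem = problem
        self.cv = cv if cv is not None else CVConfig()

    def fit(self, temporal_generalization: bool = False) -> "SubjectDecodingResults":
        if temporal_generalization:
            tg = run_temporal_generalization(self.binned, self.problem, self.cv)
            return SubjectDecodingResults(model=self, curve=None, tg_matrix=tg)
        curve = run_problem(self.binned, self.problem, self.cv)
        return SubjectDecodingResults(model=self, curve=curve, tg_matrix=None)


@dataclass
class SubjectDecodingResults:
    model: SubjectDecoding
    curve: DecodingCurve | None
    tg_matrix: TGMatrix | None

    @property
    def accuracy(self) -> np.ndarray:
        obj = self.curve if self.curve is not None else self.tg_matrix
        return obj.accuracy

    def peak_time(self, window: tuple[float, float] = (0.0, 250.0)) -> float:
        if self.curve is None:
            raise ValueError("peak extraction needs a per-bin curve fit")
        return inference.peak_time(self.curve.accuracy, self.curve.bin_start_times, window)


class CohortDecoding:
    """A family of decoding problems fitted across a cohort of subjects.

    Parameters
    ----------
    cohort
        One :class:`BinnedEpochs` per subject (equal bin timelines).
    problems
        The problems to fit (e.g. ``problems.polarity_problems()``).
    cv
        Cross-validation configuration shared by all fits.
    n_boot, n_perm, cdt, alpha, peak_window, seed
        Inference settings used by the results object's bootstrap and
        sign-permutation methods.
    """

    def __init__(
        self,
        cohort: list[BinnedEpochs],
        problems: list[ProblemSpec],
        cv: CVConfig | None = None,
        n_boot: int = 1000,
        n_perm: int = 1000,
        cdt: float = 0.01,
        alpha: float = 0.05,
        peak_window: tuple[float, float] = (0.0, 250.0),
        seed: int = 0,
    ):
        if not cohort:
            raise ValueError("cohort is empty")
        times = cohort[0].bin_start_times
        for b in cohort[1:]:
            if not np.array_equal(b.bin_start_times, times):
                raise ValueError("all subjects must share one bin timeline")
        self.cohort = cohort
        self.problems = {p.id: p for p in problems}
        self.cv = cv if cv is not None else CVConfig()
        self.n_boot = n_boot
        self.n_perm = n_perm
        self.cdt = cdt
        self.alpha = alpha
        self.peak_window = peak_window
        self.seed = seed

    @property
    def bin_start_times(self) -> np.ndarray:
        return self.cohort[0].bin_start_times

    def fit(self, temporal_generalization: bool = False) -> "CohortDecodingResults":
        """Fit every problem for every subject."""
        curves: dict[str, np.ndarray] = {}
        ties: dict[str, int] = {}
        selection: dict[str, np.ndarray] = {}
        for pid, problem in self.problems.items():
            per_subject = []
            tie_total = 0
            sel_total = np.zeros(self.cohort[0].n_sensors, dtype=np.int64)
            for binned in self.cohort:
                if temporal_generalization:
                    fitted = run_temporal_generalization(binned, problem, self.cv)
                else:
                    fitted = run_problem(binned, problem, self.cv)
                    if fitted.selection_counts is not None:
                        sel_total += fitted.selection_counts
                per_subject.append(fitted.accuracy)
                tie_total += fitted.tie_count
            curves[pid] = np.stack(per_subject)
            ties[pid] = tie_total
            selection[pid] = sel_total
        return CohortDecodingResults(
            model=self,
            curves=curves,
            tie_counts=ties,
            selection_counts=selection,
            temporal_generalization=temporal_generalization,
        )


@dataclass
class CohortDecodingResults:
    """Per-subject accuracy arrays plus bootstrap/permutation inference."""

    model: CohortDecoding
    curves: dict[str, np.ndarray]  # problem id -> (subjects, bins[, bins])
    tie_counts: dict[str, int]
    selection_counts: dict[str, np.ndarray]
    temporal_generalization: bool = False
    _boot_cache: dict = field(default_factory=dict, repr=False)

    @property
    def bin_start_times(self) -> np.ndarray:
        return self.model.bin_start_times

    def problem_ids(self, feature: str | None = None, mode: str | None = None) -> list[str]:
        out = []
        for pid, p in self.model.problems.items():
            if feature is not None and p.feature != feature:
                continue
            if mode is not None and p.mode != mode:
                continue
            out.append(pid)
        return out

    def family_curves(self, feature: str, mode: str) -> np.ndarray:
        """Per-subject curves averaged over all problems of one family."""
        ids = self.problem_ids(feature, mode)
        if not ids:
            raise ValueError(f"no fitted problems with feature={feature!r}, mode={mode!r}")
        return np.mean([self.curves[pid] for pid in ids], axis=0)

    def bootstrap(self, curves_or_id: str | np.ndarray) -> inference.BootstrapSummary:
        """Subject bootstrap of one problem's curves (or any (N, B) array)."""
        if isinstance(curves_or_id, str):
            key = curves_or_id
            A = self.curves[curves_or_id]
        else:
            key = None
            A = np.asarray(curves_or_id)
        if key is not None and key in self._boot_cache:
            return self._boot_cache[key]
        m = self.model
        out = inference.bootstrap_curves(
            A, self.bin_start_times, n_boot=m.n_boot, seed=m.seed, peak_window=m.peak_window
        )
        if key is not None:
            self._boot_cache[key] = out
        return out

    def significance(self, curves_or_id: str | np.ndarray) -> inference.SignificanceMask:
        """Sign-permutation cluster test of one problem (or array) vs chance."""
        A = self.curves[curves_or_id] if isinstance(curves_or_id, str) else np.asarray(curves_or_id)
        m = self.model
        return inference.signperm_cluster_test(
            A,
            chance=0.5,
            n_perm=m.n_perm,
            cdt=m.cdt,
            alpha=m.alpha,
            seed=m.seed,
            bin_start_times=self.bin_start_times,
        )

    def peak_comparison(self, id_a: str | np.ndarray, id_b: str | np.ndarray) -> inference.PeakComparison:
        """One-sided bootstrap test that problem A peaks later than problem B."""
        return inference.compare_peak_times(self.bootstrap(id_a), self.bootstrap(id_b))

    def summary(self) -> pd.DataFrame:
        """Per-problem table: peak accuracy and CI, peak time and CI, onset,
        number of significant bins."""
        if self.temporal_generalization:
            raise ValueError("summary() is defined for per-bin curve fits")
        rows = []
        for pid, problem in self.model.problems.items():
            A = self.curves[pid]
            boot = self.bootstrap(pid)
            mask = self.significance(pid)
            t = self.bin_start_times
            window = self.model.peak_window
            wmask = (t >= window[0]) & (t < window[1])
            mean_curve = A.mean(axis=0)
            peak_acc = float(mean_curve[wmask].max())
            peak_boot = [bm[wmask].max() for bm in _bootstrap_means(A, self.model)]
            onset = inference.onset_time(mask)
            rows.append(
                {
                    "problem": pid,
                    "feature": problem.feature,
                    "mode": problem.mode,
                    "peak_accuracy": peak_acc,
                    "peak_accuracy_ci_low": float(np.percentile(peak_boot, 2.5)),
                    "peak_accuracy_ci_high": float(np.percentile(peak_boot, 97.5)),
                    "peak_time_ms": inference.peak_time(mean_curve, t, window),
                    "peak_time_ci_low": boot.peak_time_ci[0],
                    "peak_time_ci_high": boot.peak_time_ci[1],
                    "onset_ms": onset,
                    "n_significant_bins": inference.significant_bin_count(mask),
                    "ties": self.tie_counts[pid],
                }
            )
        return pd.DataFrame(rows)

    def matrix_grid(self, hues: tuple[str, ...]) -> pd.DataFrame:
        """Train-hue x test-hue summary grid for polarity-matrix fits:
        per cell, peak accuracy, its time, and the significant-bin count."""
        rows = []
        summary = self.summary().set_index("problem")
        for pid, problem in self.model.problems.items():
            train_hue = problem.train_pair[0].partition("_")[2]
            test_hue = problem.test_pair[0].partition("_")[2]
            s = summary.loc[pid]
            rows.append(
                {
                    "train_hue": train_hue,
                    "test_hue": test_hue,
                    "peak_accuracy": s["peak_accuracy"],
                    "peak_time_ms": s["peak_time_ms"],
                    "n_significant_bins": s["n_significant_bins"],
                }
            )
        df = pd.DataFrame(rows)
        order = list(hues)
        df["train_hue"] = pd.Categorical(df["train_hue"], order)
        df["test_hue"] = pd.Categorical(df["test_hue"], order)
        return df.sort_values(["train_hue", "test_hue"]).reset_index(drop=True)


def _bootstrap_means(A: np.ndarray, model: CohortDecoding) -> np.ndarray:
    rng = np.random.default_rng(model.seed)
    draws = rng.integers(0, A.shape[0], size=(model.n_boot, A.shape[0]))
    return A[draws].mean(axis=1)
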