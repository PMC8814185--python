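"""Resampling inference for decoding time courses and matrices.

Everything here operates on arrays of per-subject decoding accuracies
(subjects x bins, or subjects x train-bins x test-bins):

* subject bootstrap of mean curves, confidence bands and peak latencies;
* sign-permutation cluster-corrected significance against chance (1D curves
  and 2D temporal-generalization matrices, one-sided above chance);
* within-subject label-shuffle nulls with Benjamini-Hochberg FDR;
* onset/peak extraction, test-retest reliability, counterphase
  (derivative-Spearman) and between-subject temporal-consistency
  correlations.

Permutation and null p-values use the add-one convention (they are never
exactly zero) except when all sign assignments are enumerated, in which case
the test is exact.  Bootstrap-proportion p-values of zero are reported as
``p < 1/B``, the resolution of the bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .decoder import CVConfig, run_problem
from .preprocess import BinnedEpochs
from .problems import ProblemSpec

__all__ = [
    "BootstrapSummary",
    "Cluster",
    "SignificanceMask",
    "PeakComparison",
    "bootstrap_curves",
    "peak_time",
    "compare_peak_times",
    "signperm_cluster_test",
    "onset_time",
    "within_subject_null_test",
    "test_retest",
    "derivative_spearman",
    "subject_consistency",
    "significant_bin_count",
]


# ---------------------------------------------------------------------------
# peaks and bootstrap

def peak_time(
    curve: np.ndarray,
    bin_start_times: np.ndarray,
    window: tuple[float, float] = (0.0, 250.0),
) -> float:
    """Start time (ms) of the most accurate bin inside ``window``; ties earliest."""
    curve = np.asarray(curve, dtype=float)
    t = np.asarray(bin_start_times, dtype=float)
    mask = (t >= window[0]) & (t < window[1])
    if not mask.any():
        raise ValueError("peak window contains no bins")
    idx = np.flatnonzero(mask)
    return float(t[idx[np.argmax(curve[idx])]])


@dataclass
class BootstrapSummary:
    """Subject-bootstrap summary of a set of decoding curves."""

    mean_curve: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    peak_time_samples: np.ndarray
    bin_start_times: np.ndarray
    n_boot: int

    @property
    def peak_time_ci(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.peak_time_samples, 2.5)),
            float(np.percentile(self.peak_time_samples, 97.5)),
        )

    @property
    def peak_time_mean(self) -> float:
        return float(self.peak_time_samples.mean())


def bootstrap_curves(
    subject_curves: np.ndarray,
    bin_start_times: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    peak_window: tuple[float, float] = (0.0, 250.0),
) -> BootstrapSummary:
    """Resample subjects with replacement ``n_boot`` times and average.

    Returns the grand-mean curve, a per-bin 95% percentile band over the
    resampled means, and the peak latency of every resampled mean within
    ``peak_window``.
    """
    A = np.atleast_2d(np.asarray(subject_curves, dtype=float))
    n = A.shape[0]
    if n < 2:
        warnings.warn("bootstrap over a single curve is degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=(n_boot, n))
    boot_means = A[draws].mean(axis=1)  # (n_boot, bins)
    peaks = np.array([peak_time(bm, bin_start_times, peak_window) for bm in boot_means])
    return BootstrapSummary(
        mean_curve=boot_means.mean(axis=0),
        ci_low=np.percentile(boot_means, 2.5, axis=0),
        ci_high=np.percentile(boot_means, 97.5, axis=0),
        peak_time_samples=peaks,
        bin_start_times=np.asarray(bin_start_times, dtype=float),
        n_boot=n_boot,
    )


@dataclass
class PeakComparison:
    """One-sided bootstrap comparison of two peak-latency distributions."""

    pvalue: float
    mean_difference: float
    n_boot: int

    @property
    def pvalue_text(self) -> str:
        if self.pvalue == 0.0:
            return f"p < {1.0 / self.n_boot:g}"
        return f"p = {self.pvalue:g}"


def compare_peak_times(boot_a: BootstrapSummary, boot_b: BootstrapSummary) -> PeakComparison:
    """Test whether A peaks later than B: p = proportion of (A - B) <= 0.

    This is a paired comparison: build both summaries with the same seed and
    resample count so resample ``j`` of A and of B average the same subjects.
    """
    if boot_a.n_boot != boot_b.n_boot:
        raise ValueError("bootstrap summaries have different numbers of resamples")
    d = boot_a.peak_time_samples - boot_b.peak_time_samples
    return PeakComparison(
        pvalue=float(np.mean(d <= 0)),
        mean_difference=float(d.mean()),
        n_boot=boot_a.n_boot,
    )


# ---------------------------------------------------------------------------
# sign-permutation cluster test

@dataclass
class Cluster:
    cells: np.ndarray  # flat indices into the statistic array
    mass: float
    pvalue: float

    @property
    def extent(self) -> int:
        return int(self.cells.size)


@dataclass
class SignificanceMask:
    """Cluster-corrected significance of a group-mean effect."""

    significant: np.ndarray  # bool, per bin (1D) or per cell (2D)
    clusters: list[Cluster]
    alpha: float
    cluster_defining_p: float
    bin_start_times: np.ndarray
    pointwise_p: np.ndarray = field(repr=False, default=None)
    exact: bool = False


def _connected_clusters(mask: np.ndarray) -> list[np.ndarray]:
    """Maximal runs (1D) or 4-connected components (2D) of True cells."""
    if mask.ndim == 1:
        labeled, n = ndimage.label(mask)
    else:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        labeled, n = ndimage.label(mask, structure=structure)
    flat = labeled.ravel()
    return [np.flatnonzero(flat == i) for i in range(1, n + 1)]


def signperm_cluster_test(
    subject_curves: np.ndarray,
    chance: float = 0.5,
    n_perm: int = 1000,
    cdt: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
    bin_start_times: np.ndarray | None = None,
) -> SignificanceMask:
    """Across-subject sign-permutation test with cluster correction.

    The statistic is the mean over subjects of (accuracy - chance).  The null
    flips each subject's sign independently; pointwise one-sided p-values are
    thresholded at ``cdt`` to form clusters (runs in 1D, 4-connected
    components in 2D), the cluster statistic is the summed mean effect
    ("mass"), and each cluster's p-value is the proportion of permutations
    whose maximum cluster mass reaches it.  When ``2**n_subjects <= n_perm``
    every sign assignment is enumerated and the test is exact.
    """
    A = np.asarray(subject_curves, dtype=float)
    if A.ndim < 2:
        raise ValueError("need subjects x bins (or subjects x bins x bins)")
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", stacklevel=2)

    E = A - chance
    obs = E.mean(axis=0)
    Ef = E.reshape(n, -1)

    exact = 2**n <= n_perm
    if exact:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    P = signs.shape[0]
    perm = (signs @ Ef) / n  # (P, cells)

    obs_flat = obs.ravel()
    count_obs = (perm >= obs_flat[None, :]).sum(axis=0)
    denom = P if exact else P + 1
    p_obs = (count_obs if exact else count_obs + 1) / denom

    # per-permutation pointwise p-values against the same null distribution
    ranks = sps.rankdata(perm, method="min", axis=0)
    count_ge = P - ranks + 1
    p_perm = count_ge / denom

    obs_sig = (p_obs < cdt).reshape(obs.shape)
    obs_clusters = _connected_clusters(obs_sig)

    max_mass = np.zeros(P)
    for j in range(P):
        mask_j = (p_perm[j] < cdt).reshape(obs.shape)
        if mask_j.any():
            pj = perm[j]
            masses = [pj[c].sum() for c in _connected_clusters(mask_j)]
            max_mass[j] = max(masses)

    clusters = []
    significant = np.zeros(obs.shape, dtype=bool)
    for cells in obs_clusters:
        mass = float(obs_flat[cells].sum())
        count = int((max_mass >= mass).sum())
        p_c = (count if exact else count + 1) / denom
        clusters.append(Cluster(cells=cells, mass=mass, pvalue=p_c))
        if p_c < alpha:
            significant.ravel()[cells] = True

    if bin_start_times is None:
        bin_start_times = np.arange(obs.shape[-1], dtype=float)
    return SignificanceMask(
        significant=significant,
        clusters=clusters,
        alpha=alpha,
        cluster_defining_p=cdt,
        bin_start_times=np.asarray(bin_start_times, dtype=float),
        pointwise_p=p_obs.reshape(obs.shape),
        exact=exact,
    )


def _runs_of_true(mask: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask keeping only cells inside runs of >= k consecutive True."""
    out = np.zeros_like(mask)
    for cells in _connected_clusters(mask):
        if cells.size >= k:
            out[cells] = True
    return out


def onset_time(mask: SignificanceMask, k: int = 4) -> float | None:
    """Start time of the first run of >= k consecutive significant bins at or
    after stimulus onset (time 0); None if no such run exists."""
    sig = mask.significant
    if sig.ndim != 1:
        raise ValueError("onset extraction requires a 1D mask")
    t = mask.bin_start_times
    for i in range(len(sig) - k + 1):
        if t[i] >= 0 and sig[i : i + k].all():
            return float(t[i])
    return None


def significant_bin_count(mask: SignificanceMask) -> int:
    """Number of significant 5 ms bins in a 1D mask."""
    if mask.significant.ndim != 1:
        raise ValueError("bin counting requires a 1D mask")
    return int(mask.significant.sum())


# ---------------------------------------------------------------------------
# within-subject shuffle null

@dataclass
class NullTestResult:
    observed: np.ndarray
    pvalues: np.ndarray
    fdr_significant: np.ndarray
    reported: np.ndarray  # FDR-significant AND in a run of >= min_consecutive
    bin_start_times: np.ndarray
    n_null: int


def within_subject_null_test(
    binned: BinnedEpochs,
    problem: ProblemSpec,
    cv: CVConfig,
    n_null: int = 1000,
    q: float = 0.05,
    seed: int = 0,
    min_consecutive: int = 4,
) -> NullTestResult:
    """Label-shuffle null distribution for one subject's decoding curve.

    Each null run shuffles the condition labels of the trials entering the
    problem and re-runs the decoder once; per-bin p-values are the add-one
    proportion of null accuracies reaching the observed accuracy, corrected
    with Benjamini-Hochberg at level ``q``.  The reported mask additionally
    requires ``min_consecutive`` consecutive significant bins.
    """
    observed = run_problem(binned, problem, cv).accuracy
    involved = np.concatenate([binned.trial_indices(c) for c in problem.conditions])
    rng = np.random.default_rng(seed)
    null_acc = np.empty((n_null, len(observed)))
    labels = binned.condition_labels
    for j in range(n_null):
        shuffled = labels.copy()
        shuffled[involved] = shuffled[involved[rng.permutation(involved.size)]]
        null_binned = BinnedEpochs(
            data=binned.data,
            condition_labels=shuffled,
            bin_start_times=binned.bin_start_times,
            bin_width=binned.bin_width,
            subject_id=binned.subject_id,
        )
        # the null replicates the observed estimator (same CV scheme and run
        # count) so the two distributions are directly comparable
        cv_null = cv.with_(seed=int(rng.integers(2**31)))
        null_acc[j] = run_problem(null_binned, problem, cv_null).accuracy
    pvals = (1 + (null_acc >= observed[None, :]).sum(axis=0)) / (1 + n_null)
    fdr_sig = multipletests(pvals, alpha=q, method="fdr_bh")[0]
    reported = _runs_of_true(fdr_sig, min_consecutive)
    return NullTestResult(
        observed=observed,
        pvalues=pvals,
        fdr_significant=fdr_sig,
        reported=reported,
        bin_start_times=binned.bin_start_times,
        n_null=n_null,
    )


# ---------------------------------------------------------------------------
# reliability and correlation analyses

def test_retest(
    binned: BinnedEpochs,
    problem: ProblemSpec,
    cv: CVConfig,
    fractions: tuple[float, ...] = (0.10, 0.25, 0.40, 0.50),
    n_rep: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Split-half reliability of the decoding curve at several trial fractions.

    For each fraction, two disjoint per-condition trial samples are drawn,
    decoded independently (pseudo-trial counts rescaled to the sample size),
    and the Pearson correlation between the two curves recorded; repeated
    ``n_rep`` times.  Returns a tidy table with per-fraction mean and SD.
    """
    if 2 * max(fractions) > 1.0:
        raise ValueError("fractions must allow two disjoint samples (2*max <= 1)")
    n_avail = binned.trial_indices(problem.conditions[0]).size
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        n_sel = int(round(frac * n_avail))
        tps = n_sel // cv.n_splits
        if tps < 1:
            raise ValueError(f"fraction {frac} leaves no trials per split")
        for rep in range(n_rep):
            halves: tuple[list[np.ndarray], list[np.ndarray]] = ([], [])
            for cond in binned.conditions:
                idx = binned.trial_indices(cond)
                perm = rng.permutation(idx.size)
                halves[0].append(idx[perm[:n_sel]])
                halves[1].append(idx[perm[n_sel : 2 * n_sel]])
            curves = []
            for half in halves:
                keep = np.sort(np.concatenate(half))
                sub = BinnedEpochs(
                    data=binned.data[keep],
                    condition_labels=binned.condition_labels[keep],
                    bin_start_times=binned.bin_start_times,
                    bin_width=binned.bin_width,
                    subject_id=binned.subject_id,
                )
                cv_half = cv.with_(
                    trials_per_split=tps, seed=int(rng.integers(2**31))
                )
                curves.append(run_problem(sub, problem, cv_half).accuracy)
            r = float(np.corrcoef(curves[0], curves[1])[0, 1])
            rows.append({"fraction": frac, "rep": rep, "correlation": r})
    df = pd.DataFrame(rows)
    summary = df.groupby("fraction")["correlation"].agg(["mean", "std"]).reset_index()
    return df.merge(summary, on="fraction", suffixes=("", "_frac"))


def derivative_spearman(
    curve_a: np.ndarray,
    curve_b: np.ndarray,
    bin_start_times: np.ndarray,
    start: float,
    duration: float = 116.0,
) -> tuple[float, float]:
    """Spearman correlation of the first-differenced curves over a window.

    Quantifies counterphase dynamics: two curves whose rises and dips
    alternate have strongly negative rho.
    """
    t = np.asarray(bin_start_times, dtype=float)
    mask = (t >= start) & (t < start + duration)
    if mask.sum() < 3:
        raise ValueError("window must span at least 3 bins")
    da = np.diff(np.asarray(curve_a, dtype=float)[mask])
    db = np.diff(np.asarray(curve_b, dtype=float)[mask])
    rho, p = sps.spearmanr(da, db)
    return float(rho), float(p)


def subject_consistency(
    subject_curves: np.ndarray,
    bin_start_times: np.ndarray,
    n_boot: int = 1000,
    window: tuple[float, float] = (0.0, 600.0),
    seed: int = 0,
) -> np.ndarray:
    """Temporal consistency of each subject's curve with the others.

    For each subject, Spearman-correlate their post-onset curve against the
    mean of ``n-1`` other subjects drawn with replacement, ``n_boot`` times;
    return each subject's mean correlation.
    """
    A = np.asarray(subject_curves, dtype=float)
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    t = np.asarray(bin_start_times, dtype=float)
    mask = (t >= window[0]) & (t < window[1])
    Aw = A[:, mask]
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        draws = rng.choice(others, size=(n_boot, n - 1), replace=True)
        boot_means = Aw[draws].mean(axis=1)  # (n_boot, bins)
        r_self = sps.rankdata(Aw[i])
        r_boot = sps.rankdata(boot_means, axis=1)
        rs = r_self - r_self.mean()
        rb = r_boot - r_boot.mean(axis=1, keepdims=True)
        num = rb @ rs
        den = np.linalg.norm(rs) * np.linalg.norm(rb, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(den > 0, num / den, 0.0)
        out[i] = rho.mean()
    return out
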