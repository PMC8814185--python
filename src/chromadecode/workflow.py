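"""Run-level orchestration: configuration, logging and data packaging.

Drives the full study-shaped experiment — simulate a cohort, preprocess,
decode the problem families, run the resampling statistics and assemble a
report — from a single :class:`RunConfig` that can be loaded from a YAML or
JSON file.  Every output table carries a JSON sidecar with the seeds and a
hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .decoder import CVConfig, run_problem, run_temporal_generalization
from .preprocess import BinnedEpochs, preprocess_pipeline
from .problems import ProblemSpec, hue_problems, polarity_matrix_problems, polarity_problems
from .simulate import SimulationConfig, simulate_subject

__all__ = [
    "StatsConfig",
    "PreprocessConfig",
    "RunConfig",
    "cmd_simulate",
    "cmd_decode",
    "cmd_stats",
    "cmd_report",
]

logger = logging.getLogger("chromadecode")

FAMILIES = ("polarity", "hue", "matrix", "tempgen")


@dataclass(frozen=True)
class StatsConfig:
    n_boot: int = 1000
    n_perm: int = 1000
    cdt: float = 0.01
    alpha: float = 0.05
    q: float = 0.05
    peak_window: tuple[float, float] = (0.0, 250.0)


@dataclass(frozen=True)
class PreprocessConfig:
    n_per_condition: int = 375
    bin_width: float = 5.0
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    reject_bounds: tuple[float, float] | None = None


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full run.

    The global ``seed`` deterministically re-seeds the sections: simulation
    uses ``seed``, cross-validation ``seed + 1``, statistics ``seed + 2``.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    out_dir: str = "results"
    seed: int = 0

    def reseeded(self, seed: int | None) -> "RunConfig":
        if seed is None:
            seed = self.seed
        return dataclasses.replace(
            self,
            seed=seed,
            simulation=dataclasses.replace(self.simulation, seed=seed),
            cv=dataclasses.replace(self.cv, seed=seed + 1),
        )

    @property
    def stats_seed(self) -> int:
        return self.seed + 2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, section):
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            section = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            return klass(**section)

        cfg = cls(
            simulation=build(SimulationConfig, raw.get("simulation", {})),
            cv=build(CVConfig, raw.get("cv", {})),
            stats=build(StatsConfig, raw.get("stats", {})),
            preprocess=build(PreprocessConfig, raw.get("preprocess", {})),
            out_dir=raw.get("out_dir", "results"),
            seed=int(raw.get("seed", 0)),
        )
        return cfg.reseeded(cfg.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)


def _epoch_path(out_dir: Path, subject_index: int) -> Path:
    return out_dir / f"epochs_sub-{subject_index:02d}.h5"


def cmd_simulate(config: RunConfig, out_dir: str | Path | None = None) -> list[Path]:
    """Simulate the cohort and write one epoch container per subject."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(config.simulation.n_subjects):
        epochs = simulate_subject(config.simulation, i)
        path = cio.write_epochs(epochs, _epoch_path(out, i))
        logger.info("wrote %s (%d trials)", path, epochs.n_trials)
        paths.append(path)
    return paths


def _problems_for_family(family: str) -> list[ProblemSpec]:
    if family == "polarity":
        return polarity_problems()
    if family == "hue":
        return hue_problems()
    if family == "matrix":
        return list(polarity_matrix_problems().values())
    if family == "tempgen":
        return [p for p in polarity_problems() + hue_problems() if p.mode == "generalization"]
    raise ValueError(f"unknown problem family {family!r}; choose from {FAMILIES}")


def _load_cohort(config: RunConfig, out: Path) -> list[BinnedEpochs]:
    missing = [
        str(_epoch_path(out, i))
        for i in range(config.simulation.n_subjects)
        if not _epoch_path(out, i).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing epoch containers: {missing}; run simulate first")
    pp = config.preprocess
    cohort = []
    for i in range(config.simulation.n_subjects):
        epochs = cio.read_epochs(_epoch_path(out, i))
        cohort.append(
            preprocess_pipeline(
                epochs,
                n_per_condition=pp.n_per_condition,
                reject_bounds=pp.reject_bounds,
                baseline_window=pp.baseline_window,
                bin_width=pp.bin_width,
                seed=config.seed + 100 + i,
            )
        )
    return cohort


def cmd_decode(
    config: RunConfig, family: str, out_dir: str | Path | None = None
) -> list[Path]:
    """Decode one problem family for every subject; write curve/matrix tables."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    cohort = _load_cohort(config, out)
    problems = _problems_for_family(family)
    meta_common = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "cv_seed": config.cv.seed,
        "family": family,
    }
    paths = []
    tie_counts: dict[str, int] = {}
    selection_totals = np.zeros(cohort[0].n_sensors, dtype=np.int64)
    for problem in problems:
        if family == "tempgen":
            per_subject = [
                run_temporal_generalization(b, problem, config.cv) for b in cohort
            ]
            mean_mat = np.mean([m.accuracy for m in per_subject], axis=0)
            df = pd.DataFrame(
                mean_mat,
                index=cohort[0].bin_start_times,
                columns=cohort[0].bin_start_times,
            )
            path = cio.write_table(
                df.reset_index(names="train_bin_ms"),
                out / f"tempgen_{problem.id}.tsv",
                {**meta_common, "problem": problem.id, "subjects": len(cohort)},
            )
            tie_counts[problem.id] = sum(m.tie_count for m in per_subject)
        else:
            curves = [run_problem(b, problem, config.cv) for b in cohort]
            data = {"time_ms": cohort[0].bin_start_times}
            for c in curves:
                data[c.subject_id] = c.accuracy
            df = pd.DataFrame(data)
            df["mean"] = df.drop(columns="time_ms").mean(axis=1)
            path = cio.write_table(
                df,
                out / f"curve_{problem.id}.tsv",
                {**meta_common, "problem": problem.id, "subjects": len(cohort)},
            )
            tie_counts[problem.id] = sum(c.tie_count for c in curves)
            selection_totals += np.sum([c.selection_counts for c in curves], axis=0)
        logger.info("decoded %s -> %s", problem.id, path)
        paths.append(path)
    log = {
        **meta_common,
        "tie_counts": tie_counts,
        "sensor_selection_frequency": (
            selection_totals / max(selection_totals.sum(), 1)
        ).tolist(),
    }
    (out / f"decode_{family}_log.json").write_text(json.dumps(log, indent=2))
    return paths


def _curve_files(out: Path, family: str) -> dict[str, Path]:
    prefix = {"polarity": "curve_pol_", "hue": "curve_hue_", "matrix": "curve_pol_"}[family]
    return {p.stem.removeprefix("curve_"): p for p in sorted(out.glob(prefix + "*.tsv"))}


def cmd_stats(config: RunConfig, family: str, out_dir: str | Path | None = None) -> Path:
    """Bootstrap, cluster-significance and peak/onset tables for a decoded family."""
    from . import inference

    out = Path(out_dir if out_dir is not None else config.out_dir)
    files = _curve_files(out, family)
    if not files:
        raise FileNotFoundError(f"no decoded curves for family {family!r} in {out}")
    st = config.stats
    rows = []
    for pid, path in files.items():
        df, _ = cio.read_table(path)
        times = df["time_ms"].to_numpy()
        curves = df.drop(columns=["time_ms", "mean"]).to_numpy().T  # (subjects, bins)
        boot = inference.bootstrap_curves(
            curves, times, n_boot=st.n_boot, seed=config.stats_seed, peak_window=st.peak_window
        )
        mask = inference.signperm_cluster_test(
            curves,
            n_perm=st.n_perm,
            cdt=st.cdt,
            alpha=st.alpha,
            seed=config.stats_seed,
            bin_start_times=times,
        )
        onset = inference.onset_time(mask)
        wmask = (times >= st.peak_window[0]) & (times < st.peak_window[1])
        mean_curve = curves.mean(axis=0)
        rows.append(
            {
                "problem": pid,
                "peak_accuracy": float(mean_curve[wmask].max()),
                "peak_time_ms": inference.peak_time(mean_curve, times, st.peak_window),
                "peak_time_ci_low": boot.peak_time_ci[0],
                "peak_time_ci_high": boot.peak_time_ci[1],
                "onset_ms": onset,
                "n_significant_bins": inference.significant_bin_count(mask),
            }
        )
    table = pd.DataFrame(rows)
    path = cio.write_table(
        table,
        out / f"stats_{family}.tsv",
        {"config_hash": config.config_hash, "seed": config.stats_seed, "family": family},
    )
    logger.info("stats for %s -> %s", family, path)
    return path


def cmd_report(config: RunConfig, out_dir: str | Path | None = None, figures: bool = False) -> Path:
    """Concatenate available stats tables into one report; optional figures."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    parts = []
    for family in FAMILIES:
        path = out / f"stats_{family}.tsv"
        if path.exists():
            df, _ = cio.read_table(path)
            df.insert(0, "family", family)
            parts.append(df)
    if not parts:
        raise FileNotFoundError(f"no stats tables found in {out}; run stats first")
    report = pd.concat(parts, ignore_index=True)
    path = cio.write_table(
        report, out / "report.tsv", {"config_hash": config.config_hash, "seed": config.seed}
    )
    if figures:
        _plot_family_curves(out)
    return path


def _plot_family_curves(out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for path in sorted(out.glob("curve_*.tsv")):
        df, _ = cio.read_table(path)
        ax.plot(df["time_ms"], df["mean"], lw=0.8, label=path.stem.removeprefix("curve_"))
    ax.axhline(0.5, color="gray", lw=0.5)
    ax.set_xlabel("time from stimulus onset (ms)")
    ax.set_ylabel("decoding accuracy")
    if len(ax.lines) <= 12:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "curves.png", dpi=150)
    plt.close(fig)
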