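"""End-to-end orchestration: simulate -> screen -> score -> hrv -> analyze.

Every stage writes a plain-text artifact (CSV or JSON) into the output
directory, and a manifest records the seed, a hash of the configuration and
per-stage record counts so a rerun can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, PipelineError, UndefinedAUCError
from .group_stats import (
    bonferroni_pairwise,
    filter_rts,
    oneway_anova_eta2,
    ordered_labels,
    regress_auc_on_cortisol,
)
from .hrv import HRVSeries, group_cluster_test, windowed_sd
from .metacognition import calibration_metrics, type2_roc
from .screening import assign_reactivity_groups
from .staircase import StaircaseConfig
from .synthetic import CohortTables, simulate_cohort
from .types import CohortSpec, CortisolProfile, HeartRateTrace

log = logging.getLogger("stressmeta")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    k_bins: int = 5
    bin_mode: str = "equal_width"
    rt_lo_ms: float = 200.0
    rt_hi_ms: float = 2000.0
    high_pct: float = 75.0
    low_pct: float = 25.0
    mid_band: tuple[float, float] = (40.0, 60.0)
    responder_threshold: float = 1.1
    hrv_window_s: int = 60
    hrv_span: float = 0.3
    hrv_n_boot: int = 5000
    hrv_alpha: float = 0.05

    def __post_init__(self):
        if self.cohort.seed != self.seed:
            object.__setattr__(
                self, "cohort", dataclasses.replace(self.cohort, seed=self.seed)
            )
        object.__setattr__(self, "mid_band", tuple(self.mid_band))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["hr_elevated_windows"] = [
            list(w) for w in d["cohort"]["hr_elevated_windows"]
        ]
        d["cohort"]["group_cortisol_peaks"] = list(d["cohort"]["group_cortisol_peaks"])
        d["staircase"]["start_levels"] = list(d["staircase"]["start_levels"])
        d["mid_band"] = list(d["mid_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        try:
            if "cohort" in d:
                cohort = dict(d["cohort"])
                if "hr_elevated_windows" in cohort:
                    cohort["hr_elevated_windows"] = tuple(
                        tuple(w) for w in cohort["hr_elevated_windows"]
                    )
                if "group_cortisol_peaks" in cohort:
                    cohort["group_cortisol_peaks"] = tuple(cohort["group_cortisol_peaks"])
                d["cohort"] = CohortSpec(**cohort)
            if "staircase" in d:
                sc = dict(d["staircase"])
                if "start_levels" in sc:
                    sc["start_levels"] = tuple(sc["start_levels"])
                d["staircase"] = StaircaseConfig(**sc)
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"invalid pipeline config: {exc}") from exc

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def cortisol_frame_to_profiles(cortisol: pd.DataFrame) -> list[CortisolProfile]:
    """Rows (participant_id, c0..c6) -> CortisolProfile objects."""
    cols = [f"c{i}" for i in range(7)]
    missing = [c for c in cols if c not in cortisol.columns]
    if missing:
        raise PipelineError(f"cortisol table lacks columns {missing}", stage="screen")
    return [
        CortisolProfile(
            participant_id=str(row["participant_id"]),
            samples=tuple(float(row[c]) for c in cols),
        )
        for _, row in cortisol.iterrows()
    ]


def heart_rate_frame_to_traces(hr: pd.DataFrame) -> list[HeartRateTrace]:
    return [
        HeartRateTrace(
            participant_id=str(pid),
            times_s=sub["time_s"].to_numpy(dtype=float),
            bpm=sub["bpm"].to_numpy(dtype=float),
        )
        for pid, sub in hr.groupby("participant_id", sort=True)
    ]


def score_trials(
    trials: pd.DataFrame,
    k: int = 5,
    mode: str = "equal_width",
    rt_lo_ms: float = 200.0,
    rt_hi_ms: float = 2000.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-participant metrics after RT filtering.

    Returns the summary frame and the ids of participants whose AUC was
    undefined (no errors or no corrects); those rows carry NaN AUC.
    """
    kept, excluded = filter_rts(trials, rt_lo_ms, rt_hi_ms)
    log.info("RT filter excluded %.2f%% of trials", 100 * excluded)
    rows, undefined = [], []
    for pid, sub in kept.groupby("participant_id", sort=True):
        correct = sub["correct"].to_numpy(dtype=bool)
        conf = sub["confidence"].to_numpy(dtype=float)
        mean_conf, accuracy, gap = calibration_metrics(correct, conf)
        try:
            auc = type2_roc(correct, conf, k=k, mode=mode, participant_id=pid).auc
        except UndefinedAUCError:
            undefined.append(str(pid))
            auc = float("nan")
        rows.append(
            {
                "participant_id": pid,
                "n_trials": int(sub.shape[0]),
                "accuracy": accuracy,
                "mean_confidence": mean_conf,
                "calibration_gap": gap,
                "auc": auc,
                "mean_rt_ms": float(sub["rt_ms"].mean()),
                "contrast": float(sub["contrast"].iloc[0]),
                "k": k,
                "bin_mode": mode,
            }
        )
    summary = pd.DataFrame(rows)
    summary.attrs["excluded_fraction"] = excluded
    return summary, undefined


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage, writing artifacts under ``out_dir``.

    Returns the results bundle (also written to ``results.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    warnings_log: list[str] = []
    stage_counts: dict[str, int] = {}

    def _stage(name):
        log.info("stage %s starting (t=%.1fs)", name, time.time() - t0)

    try:
        _stage("simulate")
        tables: CohortTables = simulate_cohort(config.cohort, config.staircase)
        tables.trials.to_csv(out / "trials.csv", index=False)
        tables.cortisol.to_csv(out / "cortisol.csv", index=False)
        tables.heart_rate.to_csv(out / "heart_rate.csv", index=False)
        tables.participants.to_csv(out / "participants.csv", index=False)
        stage_counts["simulate"] = len(tables.trials)

        _stage("screen")
        profiles = cortisol_frame_to_profiles(tables.cortisol)
        assignments = assign_reactivity_groups(
            profiles,
            high_pct=config.high_pct,
            low_pct=config.low_pct,
            mid_band=config.mid_band,
            responder_threshold=config.responder_threshold,
        )
        assign_df = pd.DataFrame([dataclasses.asdict(a) for a in assignments])
        assign_df.to_csv(out / "assignments.csv", index=False)
        stage_counts["screen"] = len(assign_df)

        _stage("score")
        summary, undefined = score_trials(
            tables.trials,
            k=config.k_bins,
            mode=config.bin_mode,
            rt_lo_ms=config.rt_lo_ms,
            rt_hi_ms=config.rt_hi_ms,
        )
        for pid in undefined:
            warnings_log.append(f"undefined type-2 AUC for participant {pid}")
        summary.to_csv(out / "summary.csv", index=False)
        stage_counts["score"] = len(summary)

        _stage("hrv")
        traces = heart_rate_frame_to_traces(tables.heart_rate)
        truth = tables.participants.set_index("participant_id")["group"]
        high = [
            windowed_sd(t, config.hrv_window_s)
            for t in traces
            if truth[t.participant_id] == "high"
        ]
        rest = [
            windowed_sd(t, config.hrv_window_s)
            for t in traces
            if truth[t.participant_id] in ("low", "medium")
        ]
        hrv_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7201]))
        cluster = group_cluster_test(
            (rest, high),
            n_boot=config.hrv_n_boot,
            alpha=config.hrv_alpha,
            rng=hrv_rng,
            span=config.hrv_span,
        )
        pd.DataFrame(
            {
                "window": np.arange(cluster.per_window_p.size),
                "p": cluster.per_window_p,
                "diff_mean": cluster.observed_diff,
                "diff_band_low": cluster.diff_band_low,
                "diff_band_high": cluster.diff_band_high,
                "rest_band_low": cluster.band_low[0],
                "rest_band_high": cluster.band_high[0],
                "high_band_low": cluster.band_low[1],
                "high_band_high": cluster.band_high[1],
            }
        ).to_csv(out / "hrv_windows.csv", index=False)
        cluster_summary = {
            "clusters": [list(c) for c in cluster.clusters],
            "alpha": cluster.alpha,
            "n_boot": cluster.n_boot,
        }
        (out / "hrv_clusters.json").write_text(json.dumps(cluster_summary, indent=2))
        stage_counts["hrv"] = int(cluster.per_window_p.size)

        _stage("analyze")
        merged = summary.merge(
            tables.participants[["participant_id", "group", "c2_nmol_l"]],
            on="participant_id",
        ).dropna(subset=["auc"])
        anova = oneway_anova_eta2(merged["auc"], merged["group"])
        posthoc = bonferroni_pairwise(merged["auc"], merged["group"])
        regression = regress_auc_on_cortisol(merged)
        group_means = {
            g: float(merged.loc[merged["group"] == g, "auc"].mean())
            for g in ordered_labels(merged["group"])
        }
        results = {
            "anova_auc": dataclasses.asdict(anova),
            "posthoc": posthoc.to_dict(orient="records"),
            "regression_auc_c2": dataclasses.asdict(regression),
            "group_mean_auc": group_means,
            "excluded_rt_fraction": summary.attrs["excluded_fraction"],
            "hrv_clusters": cluster_summary,
        }
        stage_counts["analyze"] = len(merged)
    except PipelineError:
        raise
    except Exception as exc:  # annotate with stage context
        raise PipelineError(f"pipeline failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stage_counts": stage_counts,
        "warnings": warnings_log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "results.json").write_text(json.dumps(results, indent=2))
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return results
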