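"""Synthetic cohorts: 2IFC trials with confidence, cortisol panels, HR traces.

The observer is a signal-detection model.  On each trial first-order evidence
``e ~ Normal(d, 1)`` with ``d = sensitivity_scale * contrast`` drives the
interval choice (correct iff ``e > 0``; a lapse responds at random).
Confidence reads out ``|e + m|`` with late Gaussian noise
``m ~ Normal(0, metacog_noise)`` through a logistic squashed onto [0.5, 1].
Late noise degrades the confidence-correctness link without touching
accuracy, which is the dissociation the analysis stage must recover.

Random draws follow a fixed order (target interval, evidence, lapse, late
noise, RT) so that observers differing only in ``metacog_noise`` produce
bit-identical first-order outcomes under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DomainError
from .observer import draw_trial
from .staircase import StaircaseConfig, run_calibration
from .types import (
    DEFAULT_SAMPLE_TIMES_MIN,
    GROUP_NAMES,
    CohortSpec,
    ObserverParams,
    TrialRecord,
)

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "block",
    "target_interval",
    "response_interval",
    "correct",
    "rt_ms",
    "confidence",
    "contrast",
]


def simulate_trials(
    params: ObserverParams,
    contrast: float,
    n: int,
    rng: np.random.Generator,
    *,
    participant_id: str = "obs",
    n_blocks: int = 1,
    start_index: int = 1,
) -> pd.DataFrame:
    """Simulate ``n`` trials at a fixed contrast; vectorized.

    Returns a DataFrame with :data:`TRIAL_COLUMNS`.
    """
    if not contrast > 0:
        raise DomainError("contrast must be positive")
    if n < 1:
        raise DomainError("n must be >= 1")
    d = params.sensitivity_scale * contrast
    target = rng.integers(1, 3, size=n)
    evidence = rng.normal(d, 1.0, size=n)
    lapse_u = rng.random(n)
    lapse_resp = rng.integers(1, 3, size=n)
    late = rng.normal(0.0, 1.0, size=n) * params.metacog_noise
    log_rt = rng.normal(np.log(params.rt_location_ms), params.rt_scale_ms, size=n)

    other = 3 - target
    response = np.where(evidence > 0, target, other)
    lapsed = lapse_u < params.lapse_rate
    response = np.where(lapsed, lapse_resp, response)
    correct = response == target

    confidence = expit(params.confidence_slope * np.abs(evidence + late))
    rt_ms = np.exp(log_rt)

    block_len = n // n_blocks if n % n_blocks == 0 else None
    idx = np.arange(start_index, start_index + n)
    if block_len:
        block = (np.arange(n) // block_len) + 1
    else:
        block = np.ones(n, dtype=int)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_index": idx,
            "block": block,
            "target_interval": target,
            "response_interval": response,
            "correct": correct,
            "rt_ms": rt_ms,
            "confidence": confidence,
            "contrast": contrast,
        }
    )[TRIAL_COLUMNS]


def simulate_trial(
    params: ObserverParams,
    contrast: float,
    rng: np.random.Generator,
    *,
    participant_id: str = "obs",
    trial_index: int = 1,
    block: int = 1,
) -> TrialRecord:
    """Simulate a single 2IFC trial with confidence and RT."""
    target, response, correct, rt_ms, confidence = draw_trial(params, contrast, rng)
    return TrialRecord(
        participant_id=participant_id,
        trial_index=trial_index,
        block=block,
        target_interval=target,
        response_interval=response,
        correct=correct,
        rt_ms=rt_ms,
        confidence=confidence,
        contrast=float(contrast),
    )


@dataclass(frozen=True)
class CohortTables:
    """Bundle returned by :func:`simulate_cohort`."""

    trials: pd.DataFrame
    cortisol: pd.DataFrame
    heart_rate: pd.DataFrame
    participants: pd.DataFrame  # generative ground truth per participant

    def __iter__(self):
        return iter((self.trials, self.cortisol, self.heart_rate))


def _cortisol_panel(
    rng: np.random.Generator, spec: CohortSpec, peak: float
) -> np.ndarray:
    """Seven samples: common baseline, rise to the C2 peak, smooth decay."""
    c0 = max(0.5, rng.normal(spec.c0_baseline_nmol_l, spec.c0_sd_nmol_l))
    c2 = max(c0 * 0.25, rng.normal(peak, spec.c2_sd_nmol_l))
    c1 = c0 + 0.6 * (c2 - c0) + rng.normal(0.0, 0.2)
    # exponential-ish return toward baseline over the four recovery samples
    decay = np.exp(-0.6 * np.arange(1, 5))
    tail = c0 + (c2 - c0) * decay + rng.normal(0.0, 0.2, size=4)
    samples = np.concatenate([[c0, c1, c2], tail])
    return np.maximum(samples, 0.1)


def _heart_rate_trace(
    rng: np.random.Generator, spec: CohortSpec, elevated: bool
) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(spec.hr_duration_s * spec.hr_fs_hz))
    per_window = int(round(60.0 * spec.hr_fs_hz))
    times = np.arange(n) / spec.hr_fs_hz
    mean_bpm = rng.normal(spec.hr_mean_bpm, 3.0)
    sd = np.full(n, spec.hr_sd_bpm)
    if elevated:
        win_idx = np.arange(n) // per_window
        for lo, hi in spec.hr_elevated_windows:
            sd[(win_idx >= lo) & (win_idx <= hi)] += spec.hr_sd_boost_bpm
    bpm = mean_bpm + rng.normal(0.0, 1.0, size=n) * sd
    return times, np.maximum(bpm, 30.0)


def simulate_cohort(
    spec: CohortSpec, staircase_cfg: StaircaseConfig | None = None
) -> CohortTables:
    """Generate a full three-group cohort under one master seed.

    Each participant receives a cortisol panel whose peak sample is drawn
    around their group's target, a metacognitive-noise parameter set
    deterministically from that peak via ``cortisol_auc_slope``, a staircase
    calibration, ``n_trials_main`` main-task trials at the calibrated
    contrast, and a heart-rate trace (variance elevated for the high group
    in the configured windows).  Per-participant seed streams are spawned
    from the master seed, so results do not change when the cohort grows.
    """
    cfg = staircase_cfg or StaircaseConfig()
    master = np.random.SeedSequence(spec.seed)
    streams = master.spawn(3 * spec.n_per_group)

    trial_frames: list[pd.DataFrame] = []
    cortisol_rows: list[dict] = []
    hr_frames: list[pd.DataFrame] = []
    participant_rows: list[dict] = []

    c2_ref = spec.c2_reference
    pidx = 0
    for g, group in enumerate(GROUP_NAMES):
        peak = spec.group_cortisol_peaks[g]
        for _ in range(spec.n_per_group):
            pid = f"p{pidx + 1:03d}"
            rng = np.random.default_rng(streams[pidx])
            pidx += 1

            samples = _cortisol_panel(rng, spec, peak)
            c2 = samples[2]
            noise = max(0.0, spec.metacog_noise_base - spec.cortisol_auc_slope * (c2 - c2_ref))
            sensitivity = max(1.0, rng.normal(spec.sensitivity_mean, spec.sensitivity_sd))
            params = ObserverParams(
                sensitivity_scale=sensitivity,
                metacog_noise=noise,
                lapse_rate=spec.lapse_rate,
                confidence_slope=spec.confidence_slope,
                rt_location_ms=spec.rt_location_ms,
                rt_scale_ms=spec.rt_scale_ms,
            )
            threshold, _ = run_calibration(params, cfg, rng)
            trials = simulate_trials(
                params,
                threshold,
                spec.n_trials_main,
                rng,
                participant_id=pid,
                n_blocks=spec.n_blocks,
            )
            trial_frames.append(trials)

            row = {"participant_id": pid}
            row.update({f"c{i}": samples[i] for i in range(7)})
            cortisol_rows.append(row)

            times, bpm = _heart_rate_trace(rng, spec, elevated=(group == "high"))
            hr_frames.append(
                pd.DataFrame({"participant_id": pid, "time_s": times, "bpm": bpm})
            )

            participant_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "c2_nmol_l": c2,
                    "metacog_noise": noise,
                    "sensitivity_scale": sensitivity,
                    "contrast": threshold,
                }
            )

    return CohortTables(
        trials=pd.concat(trial_frames, ignore_index=True),
        cortisol=pd.DataFrame(cortisol_rows),
        heart_rate=pd.concat(hr_frames, ignore_index=True),
        participants=pd.DataFrame(participant_rows),
    )


def cohort_sample_times_min() -> tuple:
    """Saliva sampling schedule used by the generator (minutes)."""
    return DEFAULT_SAMPLE_TIMES_MIN
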