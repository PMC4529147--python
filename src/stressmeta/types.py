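"""Domain types shared across the simulation and analysis stages.

All types are plain frozen dataclasses with eager validation so that invalid
objects cannot circulate through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError

N_CORTISOL_SAMPLES = 7

#: Default saliva sampling schedule, minutes from session start.  The peak
#: sample (index 2) sits ten minutes after the stress induction ends.
DEFAULT_SAMPLE_TIMES_MIN = (0.0, 20.0, 30.0, 45.0, 60.0, 75.0, 90.0)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated 2IFC observer.

    Parameters
    ----------
    sensitivity_scale
        Positive gain mapping stimulus contrast to first-order
        discriminability ``d = sensitivity_scale * contrast``.
    metacog_noise
        Standard deviation of Gaussian noise added to the decision variable
        before the confidence readout.  Zero means confidence has full access
        to the first-order evidence; large values decouple confidence from
        correctness without touching accuracy.
    lapse_rate
        Probability of a uniformly random response, in [0, 0.1].
    confidence_slope
        Positive slope of the logistic evidence-to-confidence mapping.
    rt_location_ms
        Median of the log-normal response-time distribution, milliseconds.
    rt_scale_ms
        Standard deviation of log response time (dimensionless spread of the
        log-normal model).
    """

    sensitivity_scale: float
    metacog_noise: float = 0.0
    lapse_rate: float = 0.0
    confidence_slope: float = 1.5
    rt_location_ms: float = 700.0
    rt_scale_ms: float = 0.55

    def __post_init__(self):
        if not self.sensitivity_scale > 0:
            raise DomainError("sensitivity_scale must be > 0")
        if self.metacog_noise < 0:
            raise DomainError("metacog_noise must be >= 0")
        if not 0 <= self.lapse_rate <= 0.1:
            raise DomainError("lapse_rate must be in [0, 0.1]")
        if not self.confidence_slope > 0:
            raise DomainError("confidence_slope must be > 0")
        if not (self.rt_location_ms > 0 and self.rt_scale_ms > 0):
            raise DomainError("rt_location_ms and rt_scale_ms must be > 0")


@dataclass(frozen=True)
class TrialRecord:
    """One 2IFC trial with correctness, response time and confidence."""

    participant_id: str
    trial_index: int
    block: int
    target_interval: int
    response_interval: int
    correct: bool
    rt_ms: float
    confidence: float
    contrast: float

    def __post_init__(self):
        if self.trial_index < 1:
            raise DomainError("trial_index must be >= 1")
        if self.target_interval not in (1, 2) or self.response_interval not in (1, 2):
            raise DomainError("intervals must be 1 or 2")
        if self.correct != (self.target_interval == self.response_interval):
            raise DomainError("correct flag inconsistent with intervals")
        if not self.rt_ms > 0:
            raise DomainError("rt_ms must be positive")
        if not 0.5 <= self.confidence <= 1.0:
            raise DomainError("confidence must lie in [0.5, 1]")
        if not self.contrast > 0:
            raise DomainError("contrast must be positive")


@dataclass(frozen=True)
class CortisolProfile:
    """Seven timed salivary cortisol concentrations for one participant."""

    participant_id: str
    samples: tuple  # nmol/l, C0..C6
    sample_times_min: tuple = DEFAULT_SAMPLE_TIMES_MIN

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(float(s) for s in self.samples))
        object.__setattr__(
            self, "sample_times_min", tuple(float(t) for t in self.sample_times_min)
        )
        if len(self.samples) != N_CORTISOL_SAMPLES:
            raise DomainError(
                f"expected {N_CORTISOL_SAMPLES} samples, got {len(self.samples)}"
            )
        if len(self.sample_times_min) != N_CORTISOL_SAMPLES:
            raise DomainError("sample_times_min must have 7 entries")
        if any(s <= 0 for s in self.samples):
            raise DomainError("all cortisol concentrations must be > 0")
        if any(
            t1 >= t2
            for t1, t2 in zip(self.sample_times_min, self.sample_times_min[1:])
        ):
            raise DomainError("sample times must be strictly increasing")

    @property
    def c0(self) -> float:
        return self.samples[0]

    @property
    def c2(self) -> float:
        return self.samples[2]

    @property
    def increase(self) -> float:
        """Stress-induced increase, peak sample minus baseline (nmol/l)."""
        return self.c2 - self.c0


@dataclass(frozen=True)
class HeartRateTrace:
    """Uniformly sampled heart-rate series for one participant."""

    participant_id: str
    times_s: np.ndarray
    bpm: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times_s, dtype=float)
        bpm = np.asarray(self.bpm, dtype=float)
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "bpm", bpm)
        if times.ndim != 1 or times.size != bpm.size:
            raise DomainError("times_s and bpm must be 1-d arrays of equal length")
        if times.size < 2:
            raise DomainError("trace needs at least two samples")
        steps = np.diff(times)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise DomainError("sampling must be uniform")
        if steps[0] <= 0:
            raise DomainError("times must be strictly increasing")
        if np.any(bpm <= 0):
            raise DomainError("bpm must be positive everywhere")
        if times[-1] - times[0] + steps[0] < 120.0:
            raise DomainError("trace must cover at least two one-minute windows")

    @property
    def dt_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


@dataclass(frozen=True)
class CohortSpec:
    """Generative design of a simulated three-group cohort.

    ``cortisol_auc_slope`` is the signed link between the peak cortisol
    sample and metacognitive sensitivity: negative values make high-cortisol
    participants noisier metacognitively (lower type-2 AUC), zero removes any
    systematic group difference.  Internally the metacognitive noise of
    participant *i* is ``max(0, metacog_noise_base - cortisol_auc_slope *
    (C2_i - mean(group_cortisol_peaks)))``.
    """

    n_per_group: int = 9
    group_cortisol_peaks: tuple = (4.5, 7.3, 10.7)
    cortisol_auc_slope: float = -0.2
    seed: int = 0

    # generative nuisance parameters, defaulted to sensible values
    metacog_noise_base: float = 0.8
    c0_baseline_nmol_l: float = 4.3
    c0_sd_nmol_l: float = 0.4
    c2_sd_nmol_l: float = 0.8
    sensitivity_mean: float = 10.0
    sensitivity_sd: float = 1.5
    lapse_rate: float = 0.0
    confidence_slope: float = 1.5
    rt_location_ms: float = 700.0
    rt_scale_ms: float = 0.55
    n_trials_main: int = 320
    n_blocks: int = 8
    hr_duration_s: float = 1260.0
    hr_fs_hz: float = 1.0
    hr_mean_bpm: float = 72.0
    hr_sd_bpm: float = 4.0
    hr_sd_boost_bpm: float = 3.0
    hr_elevated_windows: tuple = ((0, 7),)

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigError(
                "n_per_group must be >= 2 (group statistics undefined otherwise)"
            )
        peaks = tuple(float(p) for p in self.group_cortisol_peaks)
        object.__setattr__(self, "group_cortisol_peaks", peaks)
        if len(peaks) != 3:
            raise ConfigError("group_cortisol_peaks must give (low, medium, high)")
        if not (0 < peaks[0] < peaks[1] < peaks[2]):
            raise ConfigError("group_cortisol_peaks must be positive and increasing")
        if self.n_trials_main % self.n_blocks != 0:
            raise ConfigError("n_trials_main must divide evenly into n_blocks")
        object.__setattr__(
            self,
            "hr_elevated_windows",
            tuple((int(a), int(b)) for a, b in self.hr_elevated_windows),
        )

    @property
    def c2_reference(self) -> float:
        return float(np.mean(self.group_cortisol_peaks))


GROUP_NAMES = ("low", "medium", "high")
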