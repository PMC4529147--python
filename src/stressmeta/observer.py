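"""Scalar trial core for the signal-detection observer.

Kept free of pandas so the sequential staircase loop stays cheap.  Draw
order (target, evidence, lapse, late noise, RT) matches the vectorized
generator in :mod:`stressmeta.synthetic` field-for-field, and every trial
consumes the same number of draws regardless of parameters, so observers
differing only in metacognitive noise share first-order outcomes under the
same seed.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DomainError
from .types import ObserverParams


def draw_trial(
    params: ObserverParams, contrast: float, rng: np.random.Generator
) -> tuple[int, int, bool, float, float]:
    """Simulate one 2IFC trial; returns (target, response, correct, rt_ms, confidence)."""
    if not contrast > 0:
        raise DomainError("contrast must be positive")
    d = params.sensitivity_scale * contrast
    target = int(rng.integers(1, 3))
    evidence = rng.normal(d, 1.0)
    lapse_u = rng.random()
    lapse_resp = int(rng.integers(1, 3))
    late = rng.normal(0.0, 1.0) * params.metacog_noise
    log_rt = rng.normal(math.log(params.rt_location_ms), params.rt_scale_ms)

    response = target if evidence > 0 else 3 - target
    if lapse_u < params.lapse_rate:
        response = lapse_resp
    confidence = 1.0 / (1.0 + math.exp(-params.confidence_slope * abs(evidence + late)))
    return target, response, response == target, math.exp(log_rt), confidence
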