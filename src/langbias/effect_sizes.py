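"""Standardized mean differences from arm-level trial data.

The effect measure throughout is the standardized mean difference (SMD):
the between-arm mean difference divided by the pooled standard deviation.
By default the small-sample bias correction is applied (Hedges' g); with
``correct=False`` the uncorrected Cohen's d is returned for sensitivity
analyses.  Sign convention: arm 1 minus arm 2 — callers are responsible for
a consistent arm ordering within each meta-analysis.
"""

from __future__ import annotations

import math

from .data_model_io import EffectEstimate, TrialRecord, ValidationError

__all__ = ["hedges_g", "to_effect"]


def hedges_g(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
             correct: bool = True) -> EffectEstimate:
    """Bias-corrected standardized mean difference for two arms.

    g = J * (m1 - m2) / s_pooled, with pooled SD
    s_pooled = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)) and correction
    factor J = 1 - 3/(4(n1+n2-2) - 1).  The sampling variance is
    v = (n1+n2)/(n1*n2) + g^2/(2(n1+n2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"hedges_g: arm sizes must be >= 2, got ({n1}, {n2})")
    if s1 < 0 or s2 < 0:
        raise ValidationError("hedges_g: arm SDs must be nonnegative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / df
    if sp2 <= 0:
        raise ValidationError("hedges_g: degenerate pooled SD (both arm SDs zero)")
    d = (m1 - m2) / math.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0) if correct else 1.0
    g = j * d
    n = n1 + n2
    v = n / (n1 * n2) + g * g / (2.0 * n)
    return EffectEstimate(y=g, v=v)


def to_effect(trial: TrialRecord, correct: bool = True) -> EffectEstimate:
    """Map one trial record to an effect estimate on the SMD scale.

    Arm-level rows go through :func:`hedges_g`; contrast-level rows pass
    through as reported, with v = se^2.
    """
    if trial.data_level == "arm":
        return hedges_g(trial.arm1_mean, trial.arm1_sd, trial.arm1_n,
                        trial.arm2_mean, trial.arm2_sd, trial.arm2_n,
                        correct=correct)
    return EffectEstimate(y=trial.smd, v=trial.smd_se ** 2)
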