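"""Published Peru EQ-5D-5L coefficient tables, usable as worked-example inputs.

These are the printed estimates from the Peru valuation study's ordinal-
response analysis: the pooled conditional-logit (CL) and heteroskedastic-logit
(HCL) value sets, and the three taste classes of the selected two-scale-class
three-taste-class SALC model. They let the value-function and reporting code
be exercised against real published numbers without the (request-only) study
data. Coefficients are on the QALY-decrement scale, ordered as
:func:`salcval.health_value.dummy_names`.
"""

from __future__ import annotations

import numpy as np

from .health_value import TasteClassParams

__all__ = [
    "conditional_logit_params",
    "heteroskedastic_logit_params",
    "taste_class_params",
    "TASTE_CLASS_SHARES",
    "SCALE_CLASS_SHARES",
    "QALY_TO_LOG_ODDS",
]

# CL column: 20 incremental coefficients (MO, SC, UA, PD, AD x transitions) + power
_CL_BETA = np.array([
    0.029, 0.013, 0.171, 0.250,
    -0.021, 0.051, 0.113, 0.127,
    0.010, 0.005, 0.159, 0.202,
    0.022, 0.032, 0.154, 0.196,
    -0.036, 0.099, 0.097, 0.150,
])
_CL_SE = np.array([
    0.013, 0.014, 0.014, 0.015,
    0.014, 0.014, 0.014, 0.015,
    0.014, 0.014, 0.014, 0.014,
    0.014, 0.014, 0.014, 0.014,
    0.014, 0.014, 0.014, 0.015,
])
_CL_ALPHA, _CL_ALPHA_SE = 0.251, 0.012

_HCL_BETA = np.array([
    0.075, 0.021, 0.143, 0.201,
    0.030, 0.023, 0.104, 0.100,
    0.042, 0.010, 0.115, 0.175,
    0.052, 0.027, 0.126, 0.144,
    0.006, 0.066, 0.088, 0.116,
])
_HCL_SE = np.array([
    0.010, 0.011, 0.011, 0.012,
    0.011, 0.011, 0.011, 0.011,
    0.011, 0.011, 0.011, 0.011,
    0.011, 0.011, 0.011, 0.011,
    0.011, 0.011, 0.011, 0.011,
])
_HCL_ALPHA, _HCL_ALPHA_SE = 0.396, 0.016

# Selected SALC model (2 scale x 3 taste classes), taste-class columns.
_SALC_BETA = {
    1: np.array([
        0.163, 0.046, 0.214, 0.244,
        0.160, 0.050, 0.123, 0.124,
        0.161, 0.049, 0.159, 0.267,
        0.134, 0.100, 0.207, 0.285,
        0.166, 0.101, 0.126, 0.236,
    ]),
    2: np.array([
        0.056, 0.010, 0.124, 0.187,
        0.019, 0.006, 0.096, 0.109,
        0.026, 0.008, 0.109, 0.167,
        0.035, 0.023, 0.116, 0.109,
        -0.022, 0.046, 0.073, 0.086,
    ]),
    3: np.array([
        0.004, 0.018, 0.050, 0.112,
        -0.004, 0.023, 0.042, 0.047,
        -0.004, 0.000, 0.041, 0.088,
        0.008, 0.010, 0.041, 0.072,
        -0.009, 0.028, 0.033, 0.045,
    ]),
}
_SALC_ALPHA = {1: 0.070, 2: 0.237, 3: 0.494}
_SALC_LABEL = {
    1: "quality-of-life oriented",
    2: "middle",
    3: "quantity-of-life oriented",
}

#: Reported taste-class shares (percent of respondents).
TASTE_CLASS_SHARES = {1: 33.35, 2: 39.71, 3: 26.72}

#: Reported scale-class shares (percent of respondents), approximate.
SCALE_CLASS_SHARES = {1: 34.0, 2: 66.0}

#: HCL scale-function intercept: the estimated conversion factor from the
#: QALY scale to log odds for the reference task (latent pair, 15-29 s).
QALY_TO_LOG_ODDS = 4.020


def conditional_logit_params() -> TasteClassParams:
    """Pooled conditional-logit value set (constant scale)."""
    return TasteClassParams(
        beta=_CL_BETA.copy(), alpha=_CL_ALPHA, label="conditional logit",
        beta_se=_CL_SE.copy(), alpha_se=_CL_ALPHA_SE,
    )


def heteroskedastic_logit_params() -> TasteClassParams:
    """Pooled heteroskedastic-logit value set (task-varying scale)."""
    return TasteClassParams(
        beta=_HCL_BETA.copy(), alpha=_HCL_ALPHA, label="heteroskedastic logit",
        beta_se=_HCL_SE.copy(), alpha_se=_HCL_ALPHA_SE,
    )


def taste_class_params(k: int) -> TasteClassParams:
    """Taste class ``k`` (1, 2 or 3) of the selected SALC model."""
    if k not in _SALC_BETA:
        raise ValueError(f"taste class must be 1, 2 or 3, got {k}")
    return TasteClassParams(
        beta=_SALC_BETA[k].copy(), alpha=_SALC_ALPHA[k], label=_SALC_LABEL[k]
    )
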