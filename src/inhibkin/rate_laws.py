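"""Closed-form rate laws: the general two-site equation and the six
traditional single-site mechanisms, in double-reciprocal coefficient form.

Every law here is written as 1/v0 = slope * (1/S) + intercept with

    slope(I)     = (Ks/Vmax) * f_slope(I)
    intercept(I) = (1/Vmax)  * f_int(I)

so the mechanism lives entirely in the dimensionless factors f_slope, f_int.
For the general two-site model,

    f_slope = (1 + I/(gamma*Ki) + I/Ki) / (1 + beta*I/Ki)
    f_int   = (1 + I/Ki) / (1 + beta*I/Ki).
"""

from __future__ import annotations

import numpy as np

from .params import GeneralParams, MechanismClass, TraditionalParams

__all__ = [
    "reciprocal_coeffs",
    "rate_general",
    "traditional_coeffs",
    "traditional_rate",
]


def _check_inhibitor(I) -> np.ndarray:
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)) or np.any(I < 0):
        raise ValueError("inhibitor concentration must be finite and >= 0")
    return I


def _check_substrate(S) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)) or np.any(S <= 0):
        raise ValueError("substrate concentration must be finite and > 0")
    return S


def reciprocal_coeffs(params: GeneralParams, I):
    """Double-reciprocal slope and intercept of the general two-site law.

    Parameters
    ----------
    params : GeneralParams
    I : float or array_like
        Inhibitor concentration(s), mM, >= 0.

    Returns
    -------
    slope, intercept : float or ndarray
        slope = (Ks/Vmax)(1 + I/(gamma Ki) + I/Ki)/(1 + beta I/Ki),
        intercept = (1/Vmax)(1 + I/Ki)/(1 + beta I/Ki).
        At I=0 this is plain Michaelis-Menten (Ks/Vmax, 1/Vmax).
    """
    I = _check_inhibitor(I)
    denom = 1.0 + params.beta * I / params.Ki
    slope = (params.Ks / params.Vmax) * (1.0 + I / params.gamma_Ki + I / params.Ki) / denom
    intercept = (1.0 / params.Vmax) * (1.0 + I / params.Ki) / denom
    if slope.ndim == 0:
        return float(slope), float(intercept)
    return slope, intercept


def rate_general(params: GeneralParams, S, I):
    """Initial rate v0 under the general two-site model.

    The forward form of the reciprocal law: v0 = 1 / (slope/S + intercept),
    strictly positive for S > 0.
    """
    S = _check_substrate(S)
    slope, intercept = reciprocal_coeffs(params, I)
    v0 = 1.0 / (np.asarray(slope) / S + np.asarray(intercept))
    if v0.ndim == 0:
        return float(v0)
    return v0


def _traditional_factors(params: TraditionalParams, I: np.ndarray):
    """Dimensionless slope/intercept factors for each traditional mechanism."""
    ki = params.Ki_t
    mech = params.mechanism
    one = np.ones_like(I)
    if mech is MechanismClass.LINEAR_COMPETITIVE:
        return 1.0 + I / ki, one
    if mech is MechanismClass.LINEAR_NONCOMPETITIVE:
        shared = 1.0 + I / ki
        return shared, shared.copy()
    if mech is MechanismClass.LINEAR_MIXED:
        aki = params.alpha * ki
        return 1.0 + I / ki, 1.0 + I / aki
    if mech is MechanismClass.PARTIAL_COMPETITIVE:
        aki = params.alpha * ki
        return (1.0 + I / ki) / (1.0 + I / aki), one
    if mech is MechanismClass.PARTIAL_NONCOMPETITIVE:
        shared = (1.0 + I / ki) / (1.0 + params.beta * I / ki)
        return shared, shared.copy()
    if mech is MechanismClass.PARTIAL_MIXED:
        aki = params.alpha * ki
        denom = 1.0 + params.beta * I / aki
        return (1.0 + I / ki) / denom, (1.0 + I / aki) / denom
    raise ValueError(f"no rate law for mechanism {mech}")


def traditional_coeffs(params: TraditionalParams, I):
    """Double-reciprocal slope and intercept of a traditional mechanism."""
    I = _check_inhibitor(I)
    f_slope, f_int = _traditional_factors(params, I)
    slope = (params.Ks / params.Vmax) * f_slope
    intercept = (1.0 / params.Vmax) * f_int
    if slope.ndim == 0:
        return float(slope), float(intercept)
    return slope, intercept


def traditional_rate(params: TraditionalParams, S, I):
    """Initial rate v0 under a traditional single-site mechanism."""
    S = _check_substrate(S)
    slope, intercept = traditional_coeffs(params, I)
    v0 = 1.0 / (np.asarray(slope) / S + np.asarray(intercept))
    if v0.ndim == 0:
        return float(v0)
    return v0
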