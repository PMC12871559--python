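"""Parameter containers for the two-site general inhibition model and the
traditional single-site mechanisms, plus the exact mappings between them.

The general model describes an enzyme with one active site and two inhibitor
binding sites: one inside the active site (dissociation constant ``gamma*Ki``,
substrate binding blocked) and one beyond it (dissociation constant ``Ki``,
substrate binding unaffected; the ternary ESI complex turns over at ``beta*k3``).
The traditional description uses a single inhibition constant ``Ki_t``, an
apparent mutual-hindrance factor ``alpha`` and the same reactivity factor
``beta``.  The two parameterizations give identical double-reciprocal
coefficients under

    Ki = alpha * Ki_t,     gamma = 1 / (alpha - 1),     beta unchanged,

equivalently ``alpha = 1/gamma + 1`` and ``gamma*Ki = alpha*Ki_t/(alpha-1)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class MechanismClass(enum.Enum):
    """The six intersecting single-site inhibition mechanisms, plus flags.

    ``uncompetitive_out_of_family`` marks the parallel-line phenotype, which
    lies outside the intersecting family; ``inconclusive`` marks data whose
    secondary-plot forms conflict (never silently guessed).
    """

    LINEAR_COMPETITIVE = "linear_competitive"
    LINEAR_NONCOMPETITIVE = "linear_noncompetitive"
    LINEAR_MIXED = "linear_mixed"
    PARTIAL_COMPETITIVE = "partial_competitive"
    PARTIAL_NONCOMPETITIVE = "partial_noncompetitive"
    PARTIAL_MIXED = "partial_mixed"
    UNCOMPETITIVE_OUT_OF_FAMILY = "uncompetitive_out_of_family"
    INCONCLUSIVE = "inconclusive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Mechanisms whose secondary plots saturate (hyperbolic/partial family).
PARTIAL_MECHANISMS = frozenset(
    {
        MechanismClass.PARTIAL_COMPETITIVE,
        MechanismClass.PARTIAL_NONCOMPETITIVE,
        MechanismClass.PARTIAL_MIXED,
    }
)

#: Mechanisms with strictly linear secondary plots.
LINEAR_MECHANISMS = frozenset(
    {
        MechanismClass.LINEAR_COMPETITIVE,
        MechanismClass.LINEAR_NONCOMPETITIVE,
        MechanismClass.LINEAR_MIXED,
    }
)

#: Mechanisms for which the alpha factor is meaningful (Lineweaver-Burk lines
#: crossing off the axes).  Competitive mechanisms have no alpha.
ALPHA_MECHANISMS = frozenset(
    {
        MechanismClass.LINEAR_MIXED,
        MechanismClass.PARTIAL_COMPETITIVE,
        MechanismClass.PARTIAL_MIXED,
    }
)


def _require_positive_finite(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class GeneralParams:
    """Parameters of the unified two-binding-site rate law.

    Parameters
    ----------
    Ks : float
        Substrate dissociation constant of the ES complex, mM.
    Vmax : float
        Maximal rate, arbitrary rate units (``Vmax = k3 * [E]_total``; the
        microscopic k3 is not separately identifiable from initial rates).
    Ki : float
        Dissociation constant of the inhibitor at the site beyond the active
        site (EI and ESI complexes), mM.
    gamma : float
        Relative-affinity factor: the active-site dissociation constant is
        ``gamma * Ki``.  ``gamma < 1`` means the inhibitor prefers the active
        site.
    beta : float
        Reactivity of the ESI complex relative to ES, in [0, 1]: 1 innocuous,
        0 dead-end, in between partially productive.
    """

    Ks: float
    Vmax: float
    Ki: float
    gamma: float
    beta: float

    def __post_init__(self) -> None:
        _require_positive_finite("Ks", self.Ks)
        _require_positive_finite("Vmax", self.Vmax)
        _require_positive_finite("Ki", self.Ki)
        _require_positive_finite("gamma", self.gamma)
        if not math.isfinite(self.beta) or not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta!r}")

    @property
    def gamma_Ki(self) -> float:
        """Active-site dissociation constant gamma*Ki, mM."""
        return self.gamma * self.Ki

    @property
    def alpha(self) -> float:
        """Traditional apparent-hindrance factor implied by gamma."""
        return alpha_from_gamma(self.gamma)


@dataclass(frozen=True)
class TraditionalParams:
    """Textbook single-site inhibition parameters for one mechanism.

    ``alpha`` applies only to mixed/partial mechanisms (lines crossing off the
    y-axis); it is None for competitive mechanisms.  ``beta`` applies only to
    the hyperbolic (partial) family; None marks the linear family where the
    ESI complex is either absent or dead-end by construction of the scheme.
    """

    Ks: float
    Vmax: float
    Ki_t: float
    mechanism: MechanismClass
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        _require_positive_finite("Ks", self.Ks)
        _require_positive_finite("Vmax", self.Vmax)
        _require_positive_finite("Ki_t", self.Ki_t)
        if self.mechanism not in LINEAR_MECHANISMS | PARTIAL_MECHANISMS:
            raise ValueError(
                f"mechanism must be one of the six intersecting classes, got {self.mechanism}"
            )
        needs_alpha = self.mechanism in ALPHA_MECHANISMS
        if needs_alpha:
            if self.alpha is None:
                raise ValueError(f"{self.mechanism} requires an alpha factor")
            if not math.isfinite(self.alpha) or self.alpha <= 1.0:
                raise ValueError(f"alpha must be finite and > 1, got {self.alpha!r}")
        elif self.alpha is not None:
            raise ValueError(f"alpha does not apply to {self.mechanism}")
        needs_beta = self.mechanism in PARTIAL_MECHANISMS
        if needs_beta:
            if self.beta is None:
                raise ValueError(f"{self.mechanism} requires a beta factor")
            if not math.isfinite(self.beta) or not 0.0 <= self.beta <= 1.0:
                raise ValueError(f"beta must lie in [0, 1], got {self.beta!r}")
            if self.mechanism is MechanismClass.PARTIAL_COMPETITIVE and self.beta != 1.0:
                raise ValueError("partial competitive requires beta = 1 (innocuous ESI)")
        elif self.beta not in (None, 0.0):
            raise ValueError(f"beta does not apply to {self.mechanism}")

    @property
    def alpha_Ki_t(self) -> float | None:
        """ESI dissociation constant alpha*Ki_t, mM (None for competitive)."""
        return None if self.alpha is None else self.alpha * self.Ki_t


def alpha_from_gamma(gamma: float) -> float:
    """Traditional hindrance factor from the relative-affinity factor.

    alpha = 1/gamma + 1; strictly decreasing in gamma, tending to 1 as the
    outer site dominates (gamma >> 1).
    """
    if not math.isfinite(gamma) or gamma <= 0:
        raise ValueError(f"gamma must be positive and finite, got {gamma!r}")
    return 1.0 / gamma + 1.0


def gamma_from_alpha(alpha: float) -> float:
    """Inverse of :func:`alpha_from_gamma`: gamma = 1/(alpha - 1).

    Raises for alpha <= 1, which has no finite gamma (no apparent hindrance).
    """
    if not math.isfinite(alpha) or alpha <= 1.0:
        raise ValueError(f"alpha must be finite and > 1, got {alpha!r}")
    return 1.0 / (alpha - 1.0)


def traditional_to_general(params: TraditionalParams) -> GeneralParams:
    """Map traditional (Ki_t, alpha, beta) onto the two-site (Ki, gamma, beta).

    The mapping ``Ki = alpha*Ki_t``, ``gamma = 1/(alpha-1)`` makes the general
    double-reciprocal coefficients coincide with the traditional ones for all
    inhibitor concentrations, for every mechanism that carries an alpha.  For
    partial competitive beta = 1, for linear mixed beta = 0, for partial mixed
    beta carries over.

    Competitive mechanisms correspond to the gamma << 1 regime in which the
    outer-site Ki drops out of the observable coefficients; they cannot be
    mapped to a finite (Ki, gamma) pair and raise ``ValueError``.
    """
    if params.alpha is None:
        raise ValueError(
            f"{params.mechanism} has no alpha factor: it maps to the gamma << 1 "
            "regime with an unidentifiable outer-site Ki"
        )
    gamma = gamma_from_alpha(params.alpha)
    ki_general = params.alpha * params.Ki_t
    if params.mechanism is MechanismClass.PARTIAL_COMPETITIVE:
        beta = 1.0
    elif params.mechanism is MechanismClass.LINEAR_MIXED:
        beta = 0.0
    else:
        beta = float(params.beta)  # partial mixed
    return GeneralParams(Ks=params.Ks, Vmax=params.Vmax, Ki=ki_general, gamma=gamma, beta=beta)


def general_to_traditional(params: GeneralParams) -> TraditionalParams:
    """Inverse mapping, by matching double-reciprocal coefficients.

    Returns the traditional parameter set whose rate law is identical:
    Ki_t = Ki/alpha = gamma*Ki/(1+gamma), alpha = 1/gamma + 1, beta carried.
    The mechanism tag follows beta: 1 -> partial competitive, 0 -> linear
    mixed, in between -> partial mixed.
    """
    alpha = alpha_from_gamma(params.gamma)
    ki_t = params.Ki / alpha
    if params.beta == 1.0:
        mech = MechanismClass.PARTIAL_COMPETITIVE
        beta: float | None = 1.0
    elif params.beta == 0.0:
        mech = MechanismClass.LINEAR_MIXED
        beta = None
    else:
        mech = MechanismClass.PARTIAL_MIXED
        beta = params.beta
    return TraditionalParams(
        Ks=params.Ks, Vmax=params.Vmax, Ki_t=ki_t, mechanism=mech, alpha=alpha, beta=beta
    )


@dataclass(frozen=True)
class RegimeThresholds:
    """Cutoffs deciding when gamma/beta are treated as limiting values.

    The qualitative regimes "gamma << 1" and "gamma >> 1" are operationalised
    as gamma <= ``gamma_small`` and gamma >= ``gamma_large``; beta within
    ``beta_tol`` of 0 or 1 is snapped to the boundary (mechanism tables report
    beta to one significant figure).
    """

    gamma_small: float = 0.01
    gamma_large: float = 100.0
    beta_one: float = 0.95
    beta_zero: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.gamma_small < self.gamma_large:
            raise ValueError("need 0 < gamma_small < gamma_large")
        if not 0 <= self.beta_zero < self.beta_one <= 1:
            raise ValueError("need 0 <= beta_zero < beta_one <= 1")


def limiting_form(
    params: GeneralParams, thresholds: RegimeThresholds | None = None
) -> MechanismClass:
    """Mechanism phenotype of the general rate law in the stated regime.

    The six classical intersecting mechanisms all arise as limits of the
    two-site law:

    ========================  ==========================
    regime                    phenotype
    ========================  ==========================
    beta = 1, gamma finite    partial competitive
    beta = 1, gamma << 1      linear competitive
    beta = 0, gamma finite    linear mixed
    beta = 0, gamma >> 1      linear non-competitive
    0 < beta < 1, gamma >> 1  partial non-competitive
    0 < beta < 1, finite      partial mixed
    ========================  ==========================

    gamma << 1 yields linear competitive irrespective of beta (outer-site
    binding is negligible below Ki, so the ESI complex never accumulates).
    beta = 1 with gamma >> 1 leaves no observable inhibition at all and is
    reported inconclusive.
    """
    t = thresholds or RegimeThresholds()
    beta, gamma = params.beta, params.gamma
    if gamma <= t.gamma_small:
        return MechanismClass.LINEAR_COMPETITIVE
    if beta >= t.beta_one:
        if gamma >= t.gamma_large:
            return MechanismClass.INCONCLUSIVE  # innocuous inhibitor, no signal
        return MechanismClass.PARTIAL_COMPETITIVE
    if beta <= t.beta_zero:
        if gamma >= t.gamma_large:
            return MechanismClass.LINEAR_NONCOMPETITIVE
        return MechanismClass.LINEAR_MIXED
    if gamma >= t.gamma_large:
        return MechanismClass.PARTIAL_NONCOMPETITIVE
    return MechanismClass.PARTIAL_MIXED
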