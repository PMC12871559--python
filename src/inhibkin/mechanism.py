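"""Mechanism classification and parameter estimation from secondary profiles.

Classification follows the classical decision tree on the shapes of the
slope(I) and intercept(I) secondary plots:

* slope constant, intercept rising -> uncompetitive phenotype (parallel
  lines; outside the intersecting family this package models);
* intercept constant -> competitive family, split linear/partial by the
  slope form;
* both rising -> non-competitive if the slope/intercept ratio is constant
  across levels (lines cross on the 1/[S] axis), otherwise mixed (crossing
  in the second quadrant); split linear/partial by the shared form.

Conflicting shape evidence (e.g. hyperbolic slope with linear intercept)
is reported as inconclusive, never silently resolved.

Estimation of the traditional constants uses the textbook machinery:
linear mechanisms from the slope/intercept-versus-[I] regressions,
hyperbolic mechanisms from the 1/Delta-versus-1/[I] replots (plateau
increments), with beta from the intercept plateau (equal to 1/beta) and
alpha from the slope plateau or the alpha*Ki/Ki ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lineweaver import SecondaryProfile, delta_replot
from .params import (
    ALPHA_MECHANISMS,
    GeneralParams,
    MechanismClass,
    TraditionalParams,
    gamma_from_alpha,
)

__all__ = [
    "MechanismCall",
    "GeneralInference",
    "classify_mechanism",
    "estimate_traditional",
    "infer_general",
]


@dataclass(frozen=True)
class MechanismCall:
    """Classification outcome with the evidence that produced it."""

    mechanism: MechanismClass
    slope_form: str
    intercept_form: str
    ratio_cv: float
    crossing: str
    notes: tuple[str, ...] = ()


def classify_mechanism(
    profile: SecondaryProfile, ratio_tol: float = 0.01
) -> MechanismCall:
    """Assign one of the six intersecting mechanisms (or a flag) to a profile."""
    sf = profile.slope_model.form
    itf = profile.intercept_model.form
    notes: list[str] = []

    def call(mech: MechanismClass) -> MechanismCall:
        return MechanismCall(
            mechanism=mech,
            slope_form=sf,
            intercept_form=itf,
            ratio_cv=profile.ratio_cv,
            crossing=profile.crossing,
            notes=tuple(notes),
        )

    if sf == "constant" and itf == "constant":
        notes.append("no inhibition signal in either secondary plot")
        return call(MechanismClass.INCONCLUSIVE)
    if sf == "constant":
        notes.append("parallel Lineweaver-Burk lines: outside the intersecting family")
        return call(MechanismClass.UNCOMPETITIVE_OUT_OF_FAMILY)
    if itf == "constant":
        if sf == "linear":
            return call(MechanismClass.LINEAR_COMPETITIVE)
        return call(MechanismClass.PARTIAL_COMPETITIVE)

    # both secondary plots rise with [I]
    if sf != itf:
        notes.append(f"conflicting secondary forms: slope {sf}, intercept {itf}")
        return call(MechanismClass.INCONCLUSIVE)
    noncompetitive = profile.ratio_cv < ratio_tol
    if sf == "linear":
        return call(
            MechanismClass.LINEAR_NONCOMPETITIVE
            if noncompetitive
            else MechanismClass.LINEAR_MIXED
        )
    return call(
        MechanismClass.PARTIAL_NONCOMPETITIVE
        if noncompetitive
        else MechanismClass.PARTIAL_MIXED
    )


def _linear_ki(model) -> float:
    """Inhibition constant from a linear secondary model a(1 + I/Ki) = a + bI."""
    if model.form != "linear" or model.b is None or model.b <= 0:
        raise ValueError("secondary model is not an increasing linear form")
    return model.a / model.b


def estimate_traditional(
    profile: SecondaryProfile, mechanism: MechanismClass
) -> TraditionalParams:
    """Traditional (Ks, Vmax, Ki_t, alpha, beta) for a classified profile.

    Ks and Vmax come from the uninhibited reference line (slope0 = Ks/Vmax,
    intercept0 = 1/Vmax).  Linear mechanisms use the secondary regressions;
    hyperbolic mechanisms use the 1/Delta replots.
    """
    vmax = 1.0 / profile.intercept0
    ks = profile.slope0 / profile.intercept0
    m = MechanismClass

    if mechanism is m.LINEAR_COMPETITIVE:
        ki = _linear_ki(profile.slope_model)
        return TraditionalParams(Ks=ks, Vmax=vmax, Ki_t=ki, mechanism=mechanism)

    if mechanism is m.LINEAR_NONCOMPETITIVE:
        # both secondary plots share the same (1 + I/Ki) factor; the slope
        # regression is the canonical read-out
        ki = _linear_ki(profile.slope_model)
        return TraditionalParams(Ks=ks, Vmax=vmax, Ki_t=ki, mechanism=mechanism)

    if mechanism is m.LINEAR_MIXED:
        ki = _linear_ki(profile.slope_model)
        alpha_ki = _linear_ki(profile.intercept_model)
        return TraditionalParams(
            Ks=ks, Vmax=vmax, Ki_t=ki, mechanism=mechanism, alpha=alpha_ki / ki
        )

    if mechanism is m.PARTIAL_COMPETITIVE:
        rep = delta_replot(list(profile.lines), which="slope")
        alpha = rep.plateau_ratio  # slope saturates at alpha * slope0
        # replot slope = alpha*Ki_t / (slope0 * (alpha - 1))
        ki = rep.replot_slope * profile.slope0 * (alpha - 1.0) / alpha
        return TraditionalParams(
            Ks=ks, Vmax=vmax, Ki_t=ki, mechanism=mechanism, alpha=alpha, beta=1.0
        )

    if mechanism is m.PARTIAL_NONCOMPETITIVE:
        rep = delta_replot(list(profile.lines), which="intercept")
        beta = 1.0 / rep.plateau_ratio  # intercept saturates at intercept0 / beta
        # replot slope = Ki_t / (intercept0 * (1 - beta))
        ki = rep.replot_slope * profile.intercept0 * (1.0 - beta)
        return TraditionalParams(
            Ks=ks, Vmax=vmax, Ki_t=ki, mechanism=mechanism, beta=beta
        )

    if mechanism is m.PARTIAL_MIXED:
        rep_i = delta_replot(list(profile.lines), which="intercept")
        rep_s = delta_replot(list(profile.lines), which="slope")
        beta = 1.0 / rep_i.plateau_ratio
        # intercept factor (1 + I/(aKi))/(1 + beta I/(aKi)):
        #   replot slope = alpha*Ki_t / (intercept0 * (1 - beta))
        alpha_ki = rep_i.replot_slope * profile.intercept0 * (1.0 - beta)
        # slope factor (1 + I/Ki)/(1 + beta I/(aKi)):
        #   replot slope = 1 / (slope0 * (1/Ki - beta/(aKi)))
        inv_ki = 1.0 / (profile.slope0 * rep_s.replot_slope) + beta / alpha_ki
        ki = 1.0 / inv_ki
        return TraditionalParams(
            Ks=ks, Vmax=vmax, Ki_t=ki, mechanism=mechanism, alpha=alpha_ki / ki, beta=beta
        )

    raise ValueError(f"no estimation procedure for mechanism {mechanism}")


@dataclass(frozen=True)
class GeneralInference:
    """Two-site reparameterization of a traditional fit.

    For mixed/partial mechanisms carrying an alpha factor, gamma = 1/(alpha-1),
    Ki = alpha * Ki_t and gamma*Ki follow exactly.  For competitive mechanisms
    the data only constrain the active-site constant (gamma*Ki ~ Ki_t); the
    outer-site Ki is unidentifiable and gamma is reported as the bound
    gamma << 1 rather than a number.
    """

    beta: float
    gamma: float | None
    Ki: float | None
    gamma_Ki: float | None
    gamma_is_bound: bool
    params: GeneralParams | None
    note: str = ""


def infer_general(traditional: TraditionalParams) -> GeneralInference:
    """Reparameterize traditional constants into the two-site description."""
    mech = traditional.mechanism
    if mech in ALPHA_MECHANISMS:
        alpha = traditional.alpha
        gamma = gamma_from_alpha(alpha)
        ki = alpha * traditional.Ki_t
        if mech is MechanismClass.PARTIAL_COMPETITIVE:
            beta = 1.0
        elif mech is MechanismClass.LINEAR_MIXED:
            beta = 0.0
        else:
            beta = float(traditional.beta)
        params = GeneralParams(
            Ks=traditional.Ks, Vmax=traditional.Vmax, Ki=ki, gamma=gamma, beta=beta
        )
        return GeneralInference(
            beta=beta,
            gamma=gamma,
            Ki=ki,
            gamma_Ki=gamma * ki,
            gamma_is_bound=False,
            params=params,
        )
    if mech in (
        MechanismClass.LINEAR_NONCOMPETITIVE,
        MechanismClass.PARTIAL_NONCOMPETITIVE,
    ):
        # outer-site binding dominant: both coefficients share (1 + I/Ki)
        beta = 0.0 if mech is MechanismClass.LINEAR_NONCOMPETITIVE else float(traditional.beta)
        return GeneralInference(
            beta=beta,
            gamma=None,
            Ki=traditional.Ki_t,
            gamma_Ki=None,
            gamma_is_bound=True,
            params=None,
            note=(
                "non-competitive phenotype: gamma >> 1 (bound); the active-site "
                "constant gamma*Ki is unidentifiable and the outer-site Ki is "
                "read from Ki_t"
            ),
        )
    # competitive family: active-site binding dominant, outer site silent
    return GeneralInference(
        beta=1.0,
        gamma=None,
        Ki=None,
        gamma_Ki=traditional.Ki_t,
        gamma_is_bound=True,
        params=None,
        note=(
            "competitive phenotype: gamma << 1 (bound); the outer-site Ki is "
            "unidentifiable and gamma*Ki is read from Ki_t"
        ),
    )
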