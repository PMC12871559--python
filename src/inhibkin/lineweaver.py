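"""Lineweaver-Burk (double-reciprocal) primary fits and secondary analysis.

The classical route: per inhibitor concentration, ordinary least squares of
1/v0 against 1/[S] gives an apparent slope (Ks/Vmax-scaled) and intercept
(1/Vmax-scaled).  Plotting those against [I] and fitting nested forms --
constant, linear ``a + b I``, saturating hyperbola ``a(1+pI)/(1+qI)`` --
identifies the mechanism family: constant growth marks competitive-type
behaviour in the intercept, linear growth marks the linear mechanisms,
hyperbolic saturation marks the partial (hyperbolic) mechanisms.  The
1/Delta-versus-1/[I] replot linearises the hyperbolic case and exposes the
plateau parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import RateDataset

__all__ = [
    "LBLine",
    "SecondaryModelFit",
    "SecondaryProfile",
    "DeltaReplot",
    "fit_lb_lines",
    "fit_secondary",
    "delta_replot",
]

#: Primary fits below this R^2 are flagged rejected and excluded downstream.
R2_ACCEPT = 0.9


@dataclass(frozen=True)
class LBLine:
    """One double-reciprocal line at a fixed inhibitor concentration.

    ``accepted`` records whether the fit cleared the R^2 acceptance
    threshold applied when the line was fitted.
    """

    I: float
    slope: float
    intercept: float
    r2: float
    n_points: int
    accepted: bool = True

    def x_intersect(self) -> float:
        """1/[S]-axis crossing, -intercept/slope (diagnostic only)."""
        return -self.intercept / self.slope


def fit_lb_lines(
    data: RateDataset, weights: str = "none", r2_accept: float = R2_ACCEPT
) -> list[LBLine]:
    """Fit one double-reciprocal line per inhibitor level.

    1/v0 is computed from the replicate-mean rate per (S, I) condition and
    regressed on 1/S by unweighted OLS (``weights="none"``, the classical
    analysis); ``weights="variance"`` uses inverse-variance weights propagated
    from replicate scatter.  Lines are returned sorted by I; those with
    R^2 <= ``r2_accept`` carry ``accepted=False``.
    """
    if weights not in ("none", "variance"):
        raise ValueError(f"weights must be 'none' or 'variance', got {weights!r}")
    grouped = data.data.groupby(["I_mM", "S_mM"])["v0"]
    means = grouped.mean()
    variances = grouped.var(ddof=1)
    lines: list[LBLine] = []
    for I in np.sort(data.data["I_mM"].unique()):
        sub = means.loc[I]
        S = sub.index.to_numpy(dtype=float)
        if S.size < 3:
            raise ValueError(
                f"need >= 3 distinct substrate levels per inhibitor level, got {S.size} at I={I}"
            )
        v_mean = sub.to_numpy(dtype=float)
        x, y = 1.0 / S, 1.0 / v_mean
        if weights == "variance":
            v_var = variances.loc[I].to_numpy(dtype=float)
            # var(1/v) ~ var(v)/v^4 by the delta method; fall back to OLS when
            # replicate variance is unavailable or degenerate
            var_y = v_var / v_mean**4
            if np.all(np.isfinite(var_y)) and np.all(var_y > 0):
                w = 1.0 / var_y
                coeffs = np.polyfit(x, y, 1, w=np.sqrt(w))
            else:
                coeffs = np.polyfit(x, y, 1)
        else:
            coeffs = np.polyfit(x, y, 1)
        slope, intercept = float(coeffs[0]), float(coeffs[1])
        resid = y - (slope * x + intercept)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
        lines.append(
            LBLine(
                I=float(I),
                slope=slope,
                intercept=intercept,
                r2=r2,
                n_points=S.size,
                accepted=r2 > r2_accept,
            )
        )
    return lines


@dataclass(frozen=True)
class SecondaryModelFit:
    """Selected functional form for slope(I) or intercept(I).

    form is one of "constant", "linear", "hyperbolic":
      constant:   f(I) = a
      linear:     f(I) = a + b*I
      hyperbolic: f(I) = a*(1 + p*I)/(1 + q*I), p, q >= 0
    ``plateau`` is the I -> infinity limit a*p/q for the hyperbolic form
    (None otherwise, infinite growth for linear).
    """

    form: str
    a: float
    b: float | None = None
    p: float | None = None
    q: float | None = None
    sse: float = 0.0

    @property
    def plateau(self) -> float | None:
        if self.form == "hyperbolic" and self.q and self.q > 0:
            return self.a * self.p / self.q
        return None

    def __call__(self, I) -> np.ndarray:
        I = np.asarray(I, dtype=float)
        if self.form == "constant":
            return np.full_like(I, self.a)
        if self.form == "linear":
            return self.a + self.b * I
        return self.a * (1.0 + self.p * I) / (1.0 + self.q * I)


def _fit_constant(I: np.ndarray, y: np.ndarray) -> SecondaryModelFit:
    a = float(np.mean(y))
    return SecondaryModelFit(form="constant", a=a, sse=float(np.sum((y - a) ** 2)))


def _fit_linear(I: np.ndarray, y: np.ndarray) -> SecondaryModelFit:
    b, a = np.polyfit(I, y, 1)
    sse = float(np.sum((y - (a + b * I)) ** 2))
    return SecondaryModelFit(form="linear", a=float(a), b=float(b), sse=sse)


def _fit_hyperbolic(I: np.ndarray, y: np.ndarray) -> SecondaryModelFit:
    # y(1+qI) = a(1+pI) is linear in (a, a*p, q): exact on noiseless data and
    # a robust starting point otherwise; refine by bounded least squares.
    X = np.column_stack([np.ones_like(I), I, -I * y])
    sol, *_ = np.linalg.lstsq(X, y, rcond=None)
    a0, ap0, q0 = sol
    p0 = ap0 / a0 if a0 != 0 else 1.0
    a0 = max(a0, 1e-12)
    p0, q0 = max(p0, 1e-9), max(q0, 1e-12)

    from scipy.optimize import least_squares

    def resid(theta):
        a, p, q = theta
        return a * (1.0 + p * I) / (1.0 + q * I) - y

    fit = least_squares(
        resid, x0=[a0, p0, q0], bounds=([1e-12, 0.0, 0.0], [np.inf] * 3), method="trf"
    )
    a, p, q = (float(t) for t in fit.x)
    return SecondaryModelFit(form="hyperbolic", a=a, p=p, q=q, sse=float(np.sum(fit.fun**2)))


#: Relative SSE floor: a simpler form fitting to this fraction of sum(y^2) is
#: treated as exact and never rejected for a more complex one.
SSE_FLOOR_REL = 1e-12


def _extra_ss_ftest(simple: SecondaryModelFit, complex_: SecondaryModelFit, n: int,
                    k_simple: int, k_complex: int, alpha: float) -> bool:
    """True if the extra parameters of ``complex_`` are statistically justified."""
    df_c = n - k_complex
    if df_c <= 0:
        return False
    if complex_.sse <= 0:
        return simple.sse > 0
    f_stat = ((simple.sse - complex_.sse) / (k_complex - k_simple)) / (complex_.sse / df_c)
    if f_stat <= 0:
        return False
    p = stats.f.sf(f_stat, k_complex - k_simple, df_c)
    return p < alpha


def _select_form(I: np.ndarray, y: np.ndarray, alpha: float,
                 allow_hyperbolic: bool = True) -> SecondaryModelFit:
    n = I.size
    scale = float(np.sum(y**2))
    floor = SSE_FLOOR_REL * scale
    const = _fit_constant(I, y)
    if const.sse <= floor:
        return const
    linear = _fit_linear(I, y)
    if not _extra_ss_ftest(const, linear, n, 1, 2, alpha):
        return const
    if not allow_hyperbolic or linear.sse <= floor or n < 4:
        return linear
    hyper = _fit_hyperbolic(I, y)
    if _extra_ss_ftest(linear, hyper, n, 2, 3, alpha):
        return hyper
    return linear


@dataclass(frozen=True)
class SecondaryProfile:
    """Per-[I] lines plus the selected slope(I) and intercept(I) models.

    ``crossing`` summarises where the double-reciprocal lines intersect:
    "y_axis" (competitive family), "x_axis" (non-competitive: constant
    slope/intercept ratio), "second_quadrant" (mixed), "parallel"
    (uncompetitive phenotype), or "none" (no inhibition signal).
    """

    lines: tuple[LBLine, ...]
    rejected: tuple[LBLine, ...]
    slope_model: SecondaryModelFit
    intercept_model: SecondaryModelFit
    crossing: str
    ratio_cv: float

    @property
    def slope0(self) -> float:
        return self.lines[0].slope

    @property
    def intercept0(self) -> float:
        return self.lines[0].intercept


def fit_secondary(
    lines: list[LBLine],
    alpha: float = 0.05,
    ratio_tol: float = 0.01,
) -> SecondaryProfile:
    """Fit nested secondary models to slope(I) and intercept(I).

    Requires >= 4 inhibitor levels including the uninhibited reference.
    Form selection is by extra-sum-of-squares F-test at level ``alpha`` with
    an absolute floor so that noiseless data never over-select.  The
    crossing diagnostic uses the selected forms plus the coefficient of
    variation of slope/intercept across levels (``ratio_tol``).
    """
    accepted = tuple(sorted((ln for ln in lines if ln.accepted), key=lambda ln: ln.I))
    rejected = tuple(ln for ln in lines if not ln.accepted)
    I = np.array([ln.I for ln in accepted])
    if I.size < 4:
        raise ValueError(f"need >= 4 accepted inhibitor levels, got {I.size}")
    if 0.0 not in I:
        raise ValueError("the uninhibited reference line (I = 0) is required")
    if np.unique(I).size != I.size:
        raise ValueError("duplicate inhibitor levels in secondary fit")

    slopes = np.array([ln.slope for ln in accepted])
    intercepts = np.array([ln.intercept for ln in accepted])
    slope_model = _select_form(I, slopes, alpha)
    intercept_model = _select_form(I, intercepts, alpha)

    ratio = slopes / intercepts
    ratio_cv = float(np.std(ratio) / np.mean(ratio))
    crossing = _crossing_diagnostic(slope_model, intercept_model, ratio_cv, ratio_tol)
    return SecondaryProfile(
        lines=accepted,
        rejected=rejected,
        slope_model=slope_model,
        intercept_model=intercept_model,
        crossing=crossing,
        ratio_cv=ratio_cv,
    )


def _crossing_diagnostic(
    slope_model: SecondaryModelFit,
    intercept_model: SecondaryModelFit,
    ratio_cv: float,
    ratio_tol: float,
) -> str:
    slope_const = slope_model.form == "constant"
    int_const = intercept_model.form == "constant"
    if slope_const and int_const:
        return "none"
    if slope_const:
        return "parallel"
    if int_const:
        return "y_axis"
    if ratio_cv < ratio_tol:
        return "x_axis"
    return "second_quadrant"


@dataclass(frozen=True)
class DeltaReplot:
    """Linear replot of 1/Delta against 1/[I].

    For a hyperbolic secondary profile f(I) = a(1+pI)/(1+qI), the increment
    Delta(I) = f(I) - f(0) = a(p-q)I/(1+qI), so

        1/Delta = (1/(a(p-q))) * (1/I) + q/(a(p-q))

    is exactly linear in 1/I.  ``limiting_delta`` = 1/replot_intercept is the
    saturation increment Delta(inf); for a linear mechanism the replot
    intercept tends to 0 and the increment is unbounded.
    """

    replot_slope: float
    replot_intercept: float
    r2: float
    reference: float  # f(0), the uninhibited value

    @property
    def limiting_delta(self) -> float:
        if self.replot_intercept <= 0:
            return math.inf
        return 1.0 / self.replot_intercept

    @property
    def limiting_value(self) -> float:
        """Implied I -> infinity value of the secondary quantity."""
        return self.reference + self.limiting_delta

    @property
    def plateau_ratio(self) -> float:
        """limiting_value / reference, e.g. alpha for a slope replot or
        1/beta for an intercept replot."""
        return self.limiting_value / self.reference


def delta_replot(lines: list[LBLine], which: str = "slope") -> DeltaReplot:
    """Regress 1/(f(I) - f(0)) on 1/[I] over the nonzero inhibitor levels.

    ``which`` selects the slope or intercept of the primary lines.  Raises if
    the I = 0 reference is absent, fewer than 3 nonzero levels exist, or any
    increment is non-positive (the replot is then inapplicable: the secondary
    quantity is not increasing).
    """
    if which not in ("slope", "intercept"):
        raise ValueError(f"which must be 'slope' or 'intercept', got {which!r}")
    accepted = sorted((ln for ln in lines if ln.accepted), key=lambda ln: ln.I)
    by_I = {ln.I: ln for ln in accepted}
    if 0.0 not in by_I:
        raise ValueError("delta replot requires the I = 0 reference line")
    ref = getattr(by_I[0.0], which)
    nz = [ln for ln in accepted if ln.I > 0]
    if len(nz) < 3:
        raise ValueError(f"need >= 3 nonzero inhibitor levels, got {len(nz)}")
    deltas = np.array([getattr(ln, which) - ref for ln in nz])
    # increments at rounding-error scale mean the quantity is not increasing
    if np.any(deltas <= 1e-9 * abs(ref)):
        raise ValueError(
            f"replot inapplicable: {which} increments must all be positive "
            f"(got {deltas.tolist()})"
        )
    x = 1.0 / np.array([ln.I for ln in nz])
    y = 1.0 / deltas
    b, a = np.polyfit(x, y, 1)
    resid = y - (b * x + a)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
    return DeltaReplot(replot_slope=float(b), replot_intercept=float(a), r2=r2, reference=ref)
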