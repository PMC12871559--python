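"""Model/Results interface tying the full analysis pipeline together.

``InhibitionModel`` wraps an initial-rate dataset; ``fit()`` runs either the
classical reciprocal-space route (per-[I] double-reciprocal lines, secondary
plots, replots, mechanism classification, traditional constants, two-site
reparameterization) or a direct nonlinear least-squares fit of the general
two-site rate law in rate space, initialised from the classical estimates.

    >>> model = InhibitionModel.from_csv("rates.csv")
    >>> res = model.fit()            # classical route
    >>> print(res.summary())
    >>> res_g = model.fit(method="global")
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

from .lineweaver import LBLine, SecondaryProfile, fit_lb_lines, fit_secondary
from .mechanism import (
    GeneralInference,
    MechanismCall,
    classify_mechanism,
    estimate_traditional,
    infer_general,
)
from .params import GeneralParams, MechanismClass, TraditionalParams, general_to_traditional
from .rate_laws import rate_general
from .simulate import RateDataset

__all__ = ["InhibitionModel", "InhibitionResults", "GlobalFitResult"]


@dataclass(frozen=True)
class GlobalFitResult:
    """Direct fit of the general two-site law to all rates at once.

    Residuals are taken in rate space (not reciprocal space) so that
    constant-CV noise is not distorted; gamma and Ki vary on a log scale and
    beta is box-constrained to [0, 1].  ``stderr`` entries are None when the
    covariance is unavailable (e.g. a parameter pinned at a bound).
    """

    params: GeneralParams
    stderr: dict[str, float | None]
    sse: float
    nfev: int
    success: bool
    warnings: tuple[str, ...] = ()

    @property
    def traditional(self) -> TraditionalParams:
        return general_to_traditional(self.params)


def _global_fit(
    data: RateDataset, start: GeneralParams | None = None
) -> GlobalFitResult:
    df = data.mean_rates()
    S = df["S_mM"].to_numpy()
    I = df["I_mM"].to_numpy()
    v = df["v0"].to_numpy()

    if start is None:
        v0max = float(v.max())
        start = GeneralParams(
            Ks=float(np.median(S)), Vmax=2.0 * v0max, Ki=float(max(I.max(), 1.0)),
            gamma=1.0, beta=0.5,
        )

    p = lmfit.Parameters()
    p.add("Ks", value=start.Ks, min=1e-9)
    p.add("Vmax", value=start.Vmax, min=1e-9)
    p.add("log_Ki", value=math.log(start.Ki), min=-25, max=25)
    p.add("log_gamma", value=math.log(start.gamma), min=-25, max=25)
    p.add("beta", value=min(max(start.beta, 1e-6), 1 - 1e-6), min=0.0, max=1.0)

    def residual(pars):
        g = GeneralParams(
            Ks=pars["Ks"].value,
            Vmax=pars["Vmax"].value,
            Ki=math.exp(pars["log_Ki"].value),
            gamma=math.exp(pars["log_gamma"].value),
            beta=pars["beta"].value,
        )
        return rate_general(g, S, I) - v

    out = lmfit.minimize(residual, p, method="leastsq")
    pv = out.params
    fitted = GeneralParams(
        Ks=pv["Ks"].value,
        Vmax=pv["Vmax"].value,
        Ki=math.exp(pv["log_Ki"].value),
        gamma=math.exp(pv["log_gamma"].value),
        beta=float(np.clip(pv["beta"].value, 0.0, 1.0)),
    )
    stderr: dict[str, float | None] = {
        "Ks": pv["Ks"].stderr,
        "Vmax": pv["Vmax"].stderr,
        # delta method: se(Ki) = Ki * se(log Ki)
        "Ki": (fitted.Ki * pv["log_Ki"].stderr) if pv["log_Ki"].stderr else None,
        "gamma": (fitted.gamma * pv["log_gamma"].stderr) if pv["log_gamma"].stderr else None,
        "beta": pv["beta"].stderr,
    }
    warnings = []
    if not out.success:
        warnings.append(f"optimizer did not report success: {out.message}")
    if fitted.beta <= 1e-6 or fitted.beta >= 1 - 1e-6:
        warnings.append(f"beta pinned at boundary ({fitted.beta:.6f})")
    if fitted.beta >= 1 - 1e-6:
        warnings.append(
            "with beta = 1 the intercept carries no [I] information: only the "
            "slope constrains gamma*Ki and Ki"
        )
    return GlobalFitResult(
        params=fitted,
        stderr=stderr,
        sse=float(np.sum(np.asarray(out.residual) ** 2)),
        nfev=out.nfev,
        success=bool(out.success),
        warnings=tuple(warnings),
    )


class InhibitionModel:
    """Two-site inhibition analysis of an initial-rate dataset.

    Parameters
    ----------
    data : RateDataset or pandas.DataFrame
        Initial rates with columns ``S_mM, I_mM, replicate, v0`` (synonyms
        are accepted for DataFrames).
    r2_accept : float
        Acceptance threshold for the primary double-reciprocal lines.
    f_alpha : float
        Significance level of the extra-sum-of-squares F-test used to select
        secondary-plot forms.
    ratio_tol : float
        Relative tolerance for the constancy of slope/intercept across
        inhibitor levels (non-competitive crossing test).
    """

    def __init__(
        self,
        data: RateDataset | pd.DataFrame,
        r2_accept: float = 0.9,
        f_alpha: float = 0.05,
        ratio_tol: float = 0.01,
    ) -> None:
        if isinstance(data, pd.DataFrame):
            from .simulate import _canonicalise_columns

            data = RateDataset(data=_canonicalise_columns(data.copy()))
        self.data = data
        self.r2_accept = r2_accept
        self.f_alpha = f_alpha
        self.ratio_tol = ratio_tol

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "InhibitionModel":
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "InhibitionModel":
        return cls(RateDataset.from_csv(path), **kwargs)

    def fit(self, method: str = "classical") -> "InhibitionResults":
        """Run the analysis pipeline.

        method="classical" : Lineweaver-Burk lines -> secondary plots ->
        classification -> traditional constants -> two-site inference.
        method="global" : the same classical pass (for classification and
        starting values) followed by a direct nonlinear fit of the two-site
        law; the reported parameters then come from the global fit.
        """
        if method not in ("classical", "global"):
            raise ValueError(f"method must be 'classical' or 'global', got {method!r}")
        lines = fit_lb_lines(self.data, r2_accept=self.r2_accept)
        profile = fit_secondary(lines, alpha=self.f_alpha, ratio_tol=self.ratio_tol)
        call = classify_mechanism(profile, ratio_tol=self.ratio_tol)

        traditional: TraditionalParams | None = None
        general: GeneralInference | None = None
        estimation_error: str | None = None
        if call.mechanism not in (
            MechanismClass.INCONCLUSIVE,
            MechanismClass.UNCOMPETITIVE_OUT_OF_FAMILY,
        ):
            try:
                traditional = estimate_traditional(profile, call.mechanism)
                general = infer_general(traditional)
            except ValueError as exc:
                estimation_error = str(exc)

        global_fit: GlobalFitResult | None = None
        if method == "global":
            start = general.params if general is not None and general.params else None
            global_fit = _global_fit(self.data, start=start)
            traditional = global_fit.traditional
            general = infer_general(traditional)

        return InhibitionResults(
            model=self,
            method=method,
            lines=tuple(lines),
            profile=profile,
            mechanism_call=call,
            traditional=traditional,
            general=general,
            global_fit=global_fit,
            estimation_error=estimation_error,
        )


@dataclass(frozen=True)
class InhibitionResults:
    """Fitted pipeline output: mechanism call, parameters, diagnostics."""

    model: InhibitionModel
    method: str
    lines: tuple[LBLine, ...]
    profile: SecondaryProfile
    mechanism_call: MechanismCall
    traditional: TraditionalParams | None
    general: GeneralInference | None
    global_fit: GlobalFitResult | None
    estimation_error: str | None = None

    @property
    def mechanism(self) -> MechanismClass:
        return self.mechanism_call.mechanism

    @property
    def conclusive(self) -> bool:
        return self.traditional is not None and self.estimation_error is None

    def to_dict(self) -> dict:
        """JSON-serialisable report."""
        d: dict = {
            "method": self.method,
            "mechanism": self.mechanism.value,
            "evidence": {
                "slope_form": self.mechanism_call.slope_form,
                "intercept_form": self.mechanism_call.intercept_form,
                "ratio_cv": self.mechanism_call.ratio_cv,
                "crossing": self.mechanism_call.crossing,
                "notes": list(self.mechanism_call.notes),
            },
            "lines": [
                {
                    "I_mM": ln.I,
                    "slope": ln.slope,
                    "intercept": ln.intercept,
                    "r2": ln.r2,
                    "n_points": ln.n_points,
                    "accepted": ln.accepted,
                }
                for ln in self.lines
            ],
        }
        if self.traditional is not None:
            t = self.traditional
            d["traditional"] = {
                "Ks_mM": t.Ks,
                "Vmax": t.Vmax,
                "Ki_mM": t.Ki_t,
                "alpha": t.alpha,
                "beta": t.beta,
                "mechanism": t.mechanism.value,
            }
        if self.general is not None:
            g = self.general
            d["general"] = {
                "beta": g.beta,
                "gamma": g.gamma,
                "gamma_bound": g.gamma_is_bound,
                "Ki_mM": g.Ki,
                "gamma_Ki_mM": g.gamma_Ki,
                "note": g.note,
            }
        if self.global_fit is not None:
            gf = self.global_fit
            d["global_fit"] = {
                "params": {
                    "Ks_mM": gf.params.Ks,
                    "Vmax": gf.params.Vmax,
                    "Ki_mM": gf.params.Ki,
                    "gamma": gf.params.gamma,
                    "beta": gf.params.beta,
                },
                "stderr": gf.stderr,
                "sse": gf.sse,
                "success": gf.success,
                "warnings": list(gf.warnings),
            }
        if self.estimation_error:
            d["estimation_error"] = self.estimation_error
        return d

    def parameter_table(self) -> pd.DataFrame:
        """One-row table mirroring the layout of a mechanism-parameter table:
        Ki, alpha, beta, mechanism, gamma, gamma*Ki."""
        t, g = self.traditional, self.general
        return pd.DataFrame(
            [
                {
                    "Ki_mM": None if t is None else round(t.Ki_t, 4),
                    "alpha": None if t is None or t.alpha is None else float(f"{t.alpha:.2g}"),
                    "beta": None if t is None else t.beta,
                    "mechanism": self.mechanism.value,
                    "gamma": None if g is None else (
                        "<<1" if g.gamma_is_bound and g.Ki is None
                        else ">>1" if g.gamma_is_bound
                        else float(f"{g.gamma:.2g}")
                    ),
                    "gamma_Ki_mM": None if g is None or g.gamma_Ki is None else round(g.gamma_Ki, 4),
                    "general_Ki_mM": None if g is None or g.Ki is None else round(g.Ki, 4),
                }
            ]
        )

    def summary(self) -> str:
        """Human-readable report of the whole analysis."""
        w = 72
        out = ["=" * w, "Two-site inhibition analysis".center(w), "=" * w]
        out.append(f"Method:            {self.method}")
        out.append(f"Records:           {len(self.model.data)}")
        out.append(f"Inhibitor levels:  {[ln.I for ln in self.lines]}")
        out.append("-" * w)
        out.append("Primary double-reciprocal lines (1/v0 = slope/S + intercept)")
        out.append(f"{'I (mM)':>10} {'slope':>12} {'intercept':>12} {'R^2':>8}  flag")
        for ln in self.lines:
            flag = "" if ln.accepted else "REJECTED (R^2 <= 0.9)"
            out.append(
                f"{ln.I:>10.3g} {ln.slope:>12.6g} {ln.intercept:>12.6g} {ln.r2:>8.4f}  {flag}"
            )
        out.append("-" * w)
        out.append(
            f"Secondary forms:   slope(I) {self.profile.slope_model.form}, "
            f"intercept(I) {self.profile.intercept_model.form}"
        )
        out.append(f"Line crossing:     {self.profile.crossing}")
        out.append(f"Mechanism:         {self.mechanism.value}")
        for note in self.mechanism_call.notes:
            out.append(f"  note: {note}")
        if self.traditional is not None:
            t = self.traditional
            out.append("-" * w)
            out.append("Traditional parameters")
            out.append(f"  Ks   = {t.Ks:.6g} mM")
            out.append(f"  Vmax = {t.Vmax:.6g} (rate units)")
            out.append(f"  Ki   = {t.Ki_t:.6g} mM")
            if t.alpha is not None:
                out.append(f"  alpha = {t.alpha:.2f}")
            if t.beta is not None:
                out.append(f"  beta  = {t.beta:.2f}")
        if self.general is not None:
            g = self.general
            out.append("-" * w)
            out.append("General two-site parameters")
            if g.gamma_is_bound:
                if g.Ki is None:
                    out.append("  gamma    << 1 (bound; outer-site Ki unidentifiable)")
                    out.append(f"  gamma*Ki = {g.gamma_Ki:.6g} mM (active site)")
                else:
                    out.append("  gamma    >> 1 (bound; active-site constant unidentifiable)")
                    out.append(f"  Ki       = {g.Ki:.6g} mM (outer site)")
            else:
                out.append(f"  gamma    = {g.gamma:.4g}")
                out.append(f"  Ki       = {g.Ki:.6g} mM (outer site)")
                out.append(f"  gamma*Ki = {g.gamma_Ki:.6g} mM (active site)")
            out.append(f"  beta     = {g.beta:.2f}")
            if g.note:
                out.append(f"  note: {g.note}")
        if self.global_fit is not None:
            gf = self.global_fit
            out.append("-" * w)
            out.append(f"Global fit (rate-space least squares): SSE = {gf.sse:.4g}")
            for name, val in (
                ("Ks", gf.params.Ks),
                ("Vmax", gf.params.Vmax),
                ("Ki", gf.params.Ki),
                ("gamma", gf.params.gamma),
                ("beta", gf.params.beta),
            ):
                se = gf.stderr.get(name)
                se_txt = f" +/- {se:.3g}" if se else ""
                out.append(f"  {name:<6} = {val:.6g}{se_txt}")
            for wmsg in gf.warnings:
                out.append(f"  warning: {wmsg}")
        if self.estimation_error:
            out.append(f"Estimation error:  {self.estimation_error}")
        out.append("=" * w)
        return "\n".join(out)
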