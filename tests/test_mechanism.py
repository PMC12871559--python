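"""Mechanism classification, traditional-parameter estimation and the
two-site reparameterization, plus the global nonlinear fit."""

import numpy as np
import pytest

from inhibkin import (
    GeneralParams,
    InhibitionModel,
    MechanismClass,
    classify_mechanism,
    estimate_traditional,
    fit_lb_lines,
    fit_secondary,
    infer_general,
    limiting_form,
    reference_design,
    simulate_dataset,
)
from tests.conftest import make_traditional

M = MechanismClass

# one representative general-parameter set per noiseless regime
REGIMES = {
    M.PARTIAL_COMPETITIVE: GeneralParams(Ks=1.3, Vmax=1.0, Ki=45.0, gamma=0.5, beta=1.0),
    M.LINEAR_MIXED: GeneralParams(Ks=1.3, Vmax=1.0, Ki=36.0, gamma=0.5, beta=0.0),
    M.PARTIAL_MIXED: GeneralParams(Ks=1.3, Vmax=1.0, Ki=36.0, gamma=0.5, beta=0.6),
    M.LINEAR_COMPETITIVE: GeneralParams(Ks=1.3, Vmax=1.0, Ki=1e9, gamma=2e-8, beta=1.0),
    M.LINEAR_NONCOMPETITIVE: GeneralParams(Ks=1.3, Vmax=1.0, Ki=36.0, gamma=1e4, beta=0.0),
    M.PARTIAL_NONCOMPETITIVE: GeneralParams(Ks=1.3, Vmax=1.0, Ki=36.0, gamma=1e4, beta=0.6),
}


def _profile(params: GeneralParams):
    ds = simulate_dataset(params, reference_design())
    return fit_secondary(fit_lb_lines(ds))


class TestClassification:
    @pytest.mark.parametrize("expected", list(REGIMES))
    def test_confusion_matrix_is_identity(self, expected):
        """Each noiseless regime is classified as the limiting form of its
        generating parameters (independent oracle: the closed-form regime
        taxonomy, which never touches the data path)."""
        params = REGIMES[expected]
        assert limiting_form(params) is expected  # oracle consistency
        call = classify_mechanism(_profile(params))
        assert call.mechanism is expected

    def test_uncompetitive_phenotype_flagged(self, uncompetitive_data):
        profile = fit_secondary(fit_lb_lines(uncompetitive_data))
        call = classify_mechanism(profile)
        assert call.mechanism is M.UNCOMPETITIVE_OUT_OF_FAMILY
        assert profile.crossing == "parallel"

    def test_classification_scale_invariance(self):
        """Rescaling Vmax and jointly rescaling (S grid, Ks) leaves the
        mechanism call unchanged: the call depends only on dimensionless
        groups."""
        base = REGIMES[M.PARTIAL_MIXED]
        scaled = GeneralParams(
            Ks=base.Ks * 7.0, Vmax=base.Vmax * 31.0, Ki=base.Ki, gamma=base.gamma,
            beta=base.beta,
        )
        from inhibkin import AssayDesign

        design = AssayDesign(
            S_values=tuple(7.0 * s for s in reference_design().S_values)
        )
        ds = simulate_dataset(scaled, design)
        call = classify_mechanism(fit_secondary(fit_lb_lines(ds)))
        assert call.mechanism is M.PARTIAL_MIXED


class TestEstimateTraditional:
    def test_partial_competitive_constants(self, wt_imidazole_data):
        profile = fit_secondary(fit_lb_lines(wt_imidazole_data))
        trad = estimate_traditional(profile, M.PARTIAL_COMPETITIVE)
        assert trad.Ki_t == pytest.approx(15.0, rel=1e-6)
        assert trad.alpha == pytest.approx(3.0, rel=1e-6)
        assert trad.beta == 1.0

    def test_linear_mixed_constants(self, wt_tris_data):
        profile = fit_secondary(fit_lb_lines(wt_tris_data))
        trad = estimate_traditional(profile, M.LINEAR_MIXED)
        assert trad.Ki_t == pytest.approx(12.0, rel=1e-9)
        assert trad.alpha == pytest.approx(3.0, rel=1e-9)

    def test_partial_mixed_beta_from_intercept_plateau(self, f251a_imidazole_data):
        profile = fit_secondary(fit_lb_lines(f251a_imidazole_data))
        trad = estimate_traditional(profile, M.PARTIAL_MIXED)
        assert trad.beta == pytest.approx(0.6, rel=1e-6)
        assert trad.Ki_t == pytest.approx(12.0, rel=1e-6)
        assert trad.alpha == pytest.approx(3.0, rel=1e-6)

    def test_linear_competitive_round_trip(self):
        ds = simulate_dataset(
            make_traditional(M.LINEAR_COMPETITIVE, Ki_t=18.0), reference_design()
        )
        profile = fit_secondary(fit_lb_lines(ds))
        trad = estimate_traditional(profile, M.LINEAR_COMPETITIVE)
        assert trad.Ki_t == pytest.approx(18.0, rel=1e-9)
        assert trad.alpha is None

    def test_partial_noncompetitive_round_trip(self):
        ds = simulate_dataset(
            make_traditional(M.PARTIAL_NONCOMPETITIVE, Ki_t=30.0, beta=0.6),
            reference_design(),
        )
        profile = fit_secondary(fit_lb_lines(ds))
        trad = estimate_traditional(profile, M.PARTIAL_NONCOMPETITIVE)
        assert trad.Ki_t == pytest.approx(30.0, rel=1e-6)
        assert trad.beta == pytest.approx(0.6, rel=1e-6)


class TestInferGeneral:
    @pytest.mark.parametrize(
        "ki_t, alpha, mech, exp_gamma, exp_ki, exp_gki",
        [
            (15.0, 3.0, M.PARTIAL_COMPETITIVE, 0.5, 45.0, 22.5),
            (12.0, 3.0, M.LINEAR_MIXED, 0.5, 36.0, 18.0),
            (10.0, 12.0, M.LINEAR_MIXED, 1.0 / 11.0, 120.0, 120.0 / 11.0),
        ],
    )
    def test_table_reparameterizations(self, ki_t, alpha, mech, exp_gamma, exp_ki, exp_gki):
        trad = make_traditional(mech, Ki_t=ki_t, alpha=alpha)
        gen = infer_general(trad)
        assert gen.gamma == pytest.approx(exp_gamma, rel=1e-12)
        assert gen.Ki == pytest.approx(exp_ki, rel=1e-12)
        assert gen.gamma_Ki == pytest.approx(exp_gki, rel=1e-12)
        # round to the 2-significant-figure reporting convention
        assert float(f"{gen.gamma:.2g}") in (0.5, 0.091)

    def test_competitive_reports_gamma_bound(self):
        gen = infer_general(make_traditional(M.LINEAR_COMPETITIVE, Ki_t=18.0))
        assert gen.gamma is None and gen.gamma_is_bound
        assert gen.Ki is None  # outer site unidentifiable
        assert gen.gamma_Ki == pytest.approx(18.0)

    def test_noncompetitive_reports_outer_site(self):
        gen = infer_general(make_traditional(M.LINEAR_NONCOMPETITIVE, Ki_t=30.0))
        assert gen.gamma is None and gen.gamma_is_bound
        assert gen.Ki == pytest.approx(30.0)
        assert gen.gamma_Ki is None

    def test_alpha_gamma_consistency_by_construction(self):
        gen = infer_general(make_traditional(M.PARTIAL_MIXED))
        assert abs((1.0 / gen.gamma + 1.0) - 3.0) < 1e-12


class TestGlobalFit:
    def test_noiseless_recovery_grid(self):
        """Over identifiable (gamma, beta) regimes the global fit recovers the
        generating parameters to <= 1e-6 relative error."""
        for gamma in (0.09, 0.5, 1.0, 5.0):
            for beta in (0.0, 0.6, 1.0):
                truth = GeneralParams(Ks=1.3, Vmax=7.0, Ki=45.0, gamma=gamma, beta=beta)
                ds = simulate_dataset(truth, reference_design())
                res = InhibitionModel(ds).fit(method="global")
                p = res.global_fit.params
                assert p.Ks == pytest.approx(1.3, rel=1e-6)
                assert p.Vmax == pytest.approx(7.0, rel=1e-6)
                assert p.Ki == pytest.approx(45.0, rel=1e-5), (gamma, beta)
                assert p.gamma == pytest.approx(gamma, rel=1e-5)
                assert p.beta == pytest.approx(beta, abs=1e-6)

    def test_two_routes_agree_on_noiseless_data(self, wt_tris_data):
        """Classical secondary-plot estimates mapped to the two-site form and
        the direct global fit land on the same parameters (same optimum)."""
        classical = InhibitionModel(wt_tris_data).fit(method="classical")
        global_ = InhibitionModel(wt_tris_data).fit(method="global")
        g1, g2 = classical.general.params, global_.global_fit.params
        assert g2.Ki == pytest.approx(g1.Ki, rel=1e-6)
        assert g2.gamma == pytest.approx(g1.gamma, rel=1e-6)
        assert g2.beta == pytest.approx(g1.beta, abs=1e-6)
        assert global_.global_fit.sse < 1e-18

    def test_noisy_fit_brackets_generating_ki(self):
        """Across repeated noisy simulations (cv = 0.05) the global-fit Ki is
        typically within 20% of the generating 45 mM."""
        errors = []
        for seed in range(20):
            ds = simulate_dataset(
                REGIMES[M.PARTIAL_COMPETITIVE], reference_design(noise_cv=0.05, seed=seed)
            )
            res = InhibitionModel(ds).fit(method="global")
            errors.append(abs(res.global_fit.params.Ki - 45.0) / 45.0)
        assert np.median(errors) < 0.2

    def test_noisy_classical_recovery_unbiased(self):
        """200-seed Monte Carlo in the linear-mixed regime: the classical
        pipeline's Ki_t is unbiased within Monte-Carlo error."""
        truth = REGIMES[M.LINEAR_MIXED]  # Ki_t = 12, alpha = 3
        kis = []
        for seed in range(200):
            ds = simulate_dataset(truth, reference_design(noise_cv=0.05, seed=seed))
            res = InhibitionModel(ds).fit()
            if res.mechanism is M.LINEAR_MIXED:
                kis.append(res.traditional.Ki_t)
        kis = np.array(kis)
        assert len(kis) > 150  # classification holds up under noise
        mc_err = kis.std(ddof=1) / np.sqrt(len(kis))
        assert abs(kis.mean() - 12.0) < 4 * mc_err
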