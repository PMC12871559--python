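# Methods

## The model

An enzyme with a single active site offers an inhibitor two binding sites:
one inside the active site, mutually exclusive with substrate (dissociation
constant γ·K<sub>i</sub>, giving the IE complex), and one beyond it that
leaves substrate binding untouched (dissociation constant K<sub>i</sub>,
giving EI and the ternary ESI). ESI turns over at β·k₃ relative to ES at k₃.
Under rapid-equilibrium initial-rate conditions this yields the
double-reciprocal law

1/v₀ = (Kₛ/V_max)·(1 + I/(γKᵢ) + I/Kᵢ)/(1 + βI/Kᵢ)·(1/S)
     + (1/V_max)·(1 + I/Kᵢ)/(1 + βI/Kᵢ).

Assumptions: one substrate site (no cooperativity), at most two inhibitor
sites, rapid equilibrium, true initial rates (no substrate depletion or
product inhibition), no multi-inhibitor effects. V_max = k₃·[E]_total is the
stored quantity; k₃ alone is not identifiable from initial rates and is not
a parameter.

Every classical intersecting mechanism is a regime of (γ, β):

| γ regime | β = 1 | β = 0 | 0 < β < 1 |
|---|---|---|---|
| γ ≪ 1 | linear competitive | linear competitive | linear competitive |
| finite γ | partial competitive | linear mixed | partial mixed |
| γ ≫ 1 | no observable inhibition | linear non-competitive | partial non-competitive |

The traditional description (Kᵢᵗ, α, β) coincides with the two-site law for
all [I] under Kᵢ = α·Kᵢᵗ, γ = 1/(α−1) (equivalently α = 1/γ + 1); this is an
exact coefficient identity, verified algebraically in the test suite for all
three α-carrying mechanisms. β = 1 with γ ≫ 1 removes every [I]-dependent
term, so `limiting_form` reports that corner as inconclusive rather than
forcing a mechanism label onto an inhibitor with no effect.

The regime cutoffs are configurable (`RegimeThresholds`): γ ≤ 0.01 counts as
γ ≪ 1, γ ≥ 100 as γ ≫ 1, and β within 0.05 of a boundary snaps to it —
mechanism tables in this field report β to one significant figure, so finer
distinctions are not meaningful at classification time.

## Synthetic data generator

`reference_design()` emulates a standard chromogenic glycosidase inhibition
assay: ten substrate concentrations spanning 0.625–25 mM, five inhibitor
concentrations {0, 20, 40, 80, 120} mM (the 0 level is the mandatory
uninhibited reference for the Δ replots), and triplicate rate
determinations. The ten-point substrate ladder is the two-fold series
0.625–10 mM plus the 25 mM top point, completed with the midpoints
{1.875, 3.75, 7.5, 17.5} mM — a declared choice; only the range and count
are standard.

Noise is multiplicative Gaussian, v₀ = v·(1 + ε), ε ~ N(0, cv²), truncated
to positive rates by resampling. Rates span roughly 40-fold over this
design, so a constant coefficient of variation is far more realistic than
additive error for absorbance-derived rates; cv = 0.05 is typical of
triplicate chromogenic assays and is the default *when noise is requested*
(the generator itself defaults to noiseless). A seed is mandatory whenever
cv > 0. What the generator does **not** emulate: substrate depletion during
the measurement window, pipetting-correlated errors across a dilution
series, plate-position effects, day/batch effects, and deviations from
rapid equilibrium. Passing tests therefore certify the analysis machinery
under the stated error model, not robustness to every real-assay artifact.

## Classical analysis chain

1. **Primary fits.** Per inhibitor level, ordinary least squares of 1/v̄₀ on
   1/S, where v̄₀ is the replicate-mean rate (figure conventions in this
   field average replicates before the reciprocal transform). Unweighted OLS
   in reciprocal space mirrors the classical analysis; an inverse-variance
   weighted option (delta-method weights var(v)/v⁴) exists but is not the
   default. Lines with R² ≤ 0.9 are flagged rejected and excluded from the
   secondary stage. At least 3 substrate levels per line, 4 inhibitor levels
   (including 0) overall.
2. **Secondary model selection.** slope(I) and intercept(I) are fitted with
   three nested forms — constant a, linear a + bI, hyperbola a(1+pI)/(1+qI)
   (p, q ≥ 0) — and compared by extra-sum-of-squares F-tests at α = 0.05.
   A simpler form whose SSE is below 10⁻¹² of Σy² is accepted outright, so
   noiseless data can never over-select the richer form by an F-statistic
   built from rounding error. The hyperbola is first solved by the exact
   linearization y(1+qI) = a(1+pI) (a linear least-squares problem in
   (a, ap, q)) and then refined by bounded nonlinear least squares.
3. **Δ replots.** For hyperbolic profiles, 1/(f(I) − f(0)) against 1/I is
   exactly linear: slope 1/(a(p−q)), intercept q/(a(p−q)). The implied
   saturation increment 1/intercept gives the plateau, hence α (slope
   plateau ratio) and β (inverse intercept plateau ratio). Increments below
   10⁻⁹ of the reference are treated as "not increasing" and make the
   replot inapplicable — without this floor, exactly constant intercepts
   would produce rounding-scale Δ of arbitrary sign.
4. **Classification.** The decision tree in `classify_mechanism` (see module
   docstring). The non-competitive split uses the coefficient of variation
   of slope/intercept across levels (< 1% ⇒ lines cross on the 1/[S] axis);
   the geometric crossing diagnostic is recorded as evidence. Conflicting
   shape evidence yields `inconclusive`.
5. **Estimation.** Linear mechanisms: Kᵢᵗ = a/b from the slope regression,
   α·Kᵢᵗ likewise from the intercept regression. Hyperbolic mechanisms: the
   replot route above (the fitted hyperbola parameters p, q give an
   equivalent algebraic route; the replot is the canonical one here because
   it matches the classical graphical procedure). α is reported to 2
   significant figures in the report layer; full precision is kept
   internally.
6. **Reparameterization.** γ = 1/(α−1), Kᵢ = α·Kᵢᵗ, γKᵢ = their product.
   For competitive calls the outer-site Kᵢ is structurally unidentifiable
   (the data live in the I < Kᵢ regime); γ is reported as the bound "≪ 1"
   and the active-site constant γKᵢ is read from Kᵢᵗ. For non-competitive
   calls the converse holds: γ "≫ 1", outer-site Kᵢ = Kᵢᵗ.

## Global fit

`fit(method="global")` minimises residuals in **rate space** (reciprocal
space would inflate the influence of the smallest rates under constant-CV
noise) over (Kₛ, V_max, log Kᵢ, log γ, β), with β box-constrained to [0, 1]
and the log parameterization keeping the positive constants positive and
the affinity ratio scale-free. Starting values come from the classical
route when it succeeds. Standard errors for Kᵢ and γ are delta-method
transforms of the log-scale errors. β pinned at a boundary is reported
explicitly, as is the β = 1 degeneracy (the intercept then carries no [I]
information, so only the slope constrains γKᵢ and Kᵢ). On noiseless data
the global fit and the classical route land on the same optimum; both are
exercised against each other in the tests.

## Numerical choices and degenerate inputs

- Problem sizes: analysis examples and tests use the 10 × 5 × 3 reference
  design (150 records); Monte-Carlo checks use 200 simulated datasets at
  cv = 0.05, which keeps the whole suite in seconds.
- Non-positive rates, negative concentrations, missing uninhibited
  reference, fewer than 3 substrate or 4 inhibitor levels: hard errors with
  specific messages, never silent repair.
- CSV I/O is comma-separated with a mandatory header; the reader maps common
  column synonyms (S, [S], substrate_mM, rate, …) onto the canonical
  `S_mM, I_mM, replicate, v0` and round-trips values to 12 significant
  digits.
- Ties between slope-form and intercept-form evidence are not broken: the
  call is `inconclusive` with the conflict recorded in the notes.

## Known limitations

- The uncompetitive (parallel-line) phenotype is detected and flagged but
  not parameterized — it lies outside the two-site scheme modelled here.
- Mechanisms with more than two inhibitor sites, substrate inhibition,
  cooperative kinetics and progress-curve analysis are out of scope.
- Classification power at cv = 0.05 is regime-dependent: hyperbolic-versus-
  linear discrimination of a slope profile with γ = 0.5 and β = 1 fails in
  a minority of simulated replicates (the F-test then conservatively keeps
  the linear form); the linear-mixed regime classifies essentially always.
- The γ ≫ 1 and γ ≪ 1 calls are regime statements, not point estimates; a
  finite γ generates small deviations from the limiting law (e.g. a
  slope-based Kᵢ biased by the factor 1/(1 + 1/γ)) that are invisible below
  the noise floor but present in principle.
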