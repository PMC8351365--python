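# Methods

## Model and assumptions

The package implements a static, two-stage game of complete information
between a monopolist selling an error-free point-of-care diagnostic and a
population of `N` primary-care physicians.

Patients form a unit-mass panel per physician, indexed by a symptom score
`s` uniform on [0, 1]. Antibiotics are truly needed exactly when `s`
exceeds an unknown threshold `A` with known mean `ā ∈ (0, 1)`. A
physician of uncertainty level `b` holds the belief
`A ~ U(ā − b/2, ā + b/2)`; `b` is simultaneously the width of the belief
interval and the fraction of patients whose treatment is uncertain, and is
bounded by `b_max = 2 min(ā, 1 − ā)` so the belief interval stays inside
[0, 1]. Payoffs per patient are `B − p` if treated (cured, treatment paid,
whether or not needed), `B` if untreated and cured, `−l` if untreated and
sick, where `p = p_a + r` is the drug price plus the internalized
resistance externality. All treatment is one unit of antibiotics;
physicians are perfect agents maximizing expected net benefit. The test
is perfect (sensitivity = specificity = 1); imperfect tests, heterogeneous
`B`, and dynamic or endogenous resistance costs are out of scope.

Maintained parameter assumptions, enforced at construction and named in
the error message: `B > p`, `B − p ≥ l`, `B + l > 2p`, `p_a > 0`,
`r ≥ 0`, `l ≥ 0`, `0 < ā < 1`. The boundary `B + l = 2p` (where the
empiric cutoff stops responding to uncertainty) is rejected rather than
special-cased. The per-test fee must satisfy `t ≤ p(B+l−p)/(B+l)`; the
boundary value is accepted as a degenerate but well-defined tariff (zero
tests, zero adoption value), anything above is rejected.

Currency units are abstract; there is no time dimension and no
discounting. All patient quantities are fractions of the unit-mass panel;
aggregate quantities multiply by `N`.

## Closed forms and their oracles

Every closed-form quantity in `poctecon.model` is validated by an
independent route in `poctecon.simulate`:

- `brute_force_threshold` maximizes the exact expected benefit
  `B − p(1−s) − (B+l)·E[(s−A)⁺]` over a cutoff grid (the conditional
  expectation is analytic for uniform `A`; no sampling), recovering
  `s*(b)` to one grid step.
- `brute_force_testing_set` compares, symptom by symptom, the expected
  benefit of testing (`B − pF(s) − t`) with the empiric default,
  recovering the testing band to one grid step. These two searches return
  the caller's grid resolution without refinement, since their contract
  is agreement to one grid step.
- `simulate_physician` draws the threshold `A` once per replicate and a
  fresh symptom panel per replicate, applies only the primitive decision
  rules (cutoff, testing band, test outcome), and averages realized
  benefits. Identical seeds give bit-identical summaries. A
  conditional-exact mode (`*_panel_given_a`) integrates the panel
  analytically given the realized threshold, for low-variance checks of
  the scenario-conditional benefit components.
- `brute_force_tariff` scans a (C, t) grid, computes every physician
  type's best response from the welfare comparison, and integrates the
  firm's exact profit with the distribution's functionals; one 10× finer
  local rescan follows the coarse scan.

Agreement with simulation is judged at 3 Monte-Carlo standard errors per
comparison. Across many comparisons the false-exceedance rate of a 3-SE
band is ≈ 0.27% under correctness, so batch checks allow up to 1%
exceedances; because the per-replicate welfare distribution is strongly
left-skewed (rare untreated-sick tails), individual z-scores are
heavy-tailed and only a gross-bias cap (8 SE) is imposed on the maximum.
Algebraic identities (scenario-weighted benefit sum, net-welfare
accounting, probability normalization, `Q_Ae = 1 − s*`) are checked to
1e-12 relative.

Default validation sample sizes are 4 000 patients × 250 threshold draws
per physician for batch checks over 200 random economies, and
20 000 × 400 for single-point checks; these sizes make the 3-SE bands a
few parts in 10⁴ of the quantities checked while keeping the full
validation suite fast. Standard errors are computed across replicates, so
the welfare SE scales as `1/√n_draws` (the threshold layer dominates) and
rate SEs additionally shrink with panel size.

## Uncertainty distributions

The firm-side distribution `G` of uncertainty is any atomless density on
`[0, b_max]`. Built-ins: uniform, increasing-triangular, and scaled Beta,
all with closed-form CDF and partial mean `∫_{b0} x g dx`. Arbitrary
densities are accepted programmatically: the CDF is assembled from
per-segment adaptive quadrature (absolute tolerance 1e-12 per segment) on
a 513-node grid with monotone PCHIP interpolation between nodes;
densities that are negative or fail to integrate to 1 within 1e-6 are
rejected, and densities on other supports are rejected rather than
rescaled. Partial means for custom densities use adaptive quadrature with
absolute tolerance 1e-9.

## Equilibrium computation

The marginal adopter `b*` is found by maximizing the firm's reduced
objective `b(1 − G(b))` — a 10⁴-point grid scan, bounded local
minimization (xatol 1e-12), then a polish by root-finding on the
stationarity condition `1 − G(b) − b g(b) = 0` where it brackets. The
maximizer, not the stationarity root, is the object of interest: for
multimodal densities the first-order condition can have several roots.
Ties at the adoption cap resolve to adoption, so the marginal physician
adopts and `adopter_fraction = 1 − G(b*)` exactly.

Firm profit is always computed from its definition
`N ∫_{b0} [C + tT(t,x)] g(x) dx`, expanded exactly through the adopter
mass and partial mean, never from printed shortcut formulas.

### Device-price convention

Two conventions for the equilibrium device price circulate for this
model: the binding-adoption-constraint value
`C* = b* p(B+l−p)/(2(B+l))`, which follows from equating the marginal
adopter's welfare under the two strategies at `t = 0`, and a variant
without the factor 2. The binding-constraint form is the one consistent
with the adoption cap this package derives and tests, so the solver uses
it; the variant is reported as `alternate_device_price` in every
equilibrium report for comparability.

### Known limitation: the zero-fee result under uniform pricing

The textbook solution implemented by `solve_equilibrium` sets the
per-test fee to zero and earns device revenue only. That result is exact
when each adopter can be charged their own adoption cap (perfect
device-price discrimination): lowering `t` raises every cap one-for-one
with the testing surplus, so fee revenue is never worth distorting
testing. Under *strictly uniform* pricing — one `(C, t)` for all
practices, with `C` pinned to the **marginal** adopter's cap — the
derivative of profit with respect to `t` at `t = 0` is
`(N/(B+l))·[∫_{b0} x g dx − b0(1 − G(b0))] > 0`: a small fee extracts
testing surplus from infra-marginal, high-uncertainty adopters that the
uniform device price cannot reach. The honest tariff search
(`brute_force_tariff`) therefore finds an interior `t > 0` whose profit
strictly exceeds the zero-fee equilibrium (≈ 10.86 vs 9.17 at the
baseline economy), and the test suite asserts this dominance as a
property of the oracle. Users comparing the two should treat the
zero-fee solution as the discriminatory-pricing benchmark and the grid
optimum as the uniform-pricing optimum.

### Internalization accounting

The internalization term `N r/(B+l) ∫_{b0} x g dx` equals the drop in
aggregate *empiric* prescribing when the effective price rises from
`p_a` to `p_a + r` holding `B`, `l` fixed — i.e., prescriptions avoided
because prescribers price in the externality. Note the opposite-signed
composition effect: because internalizing raises `p`, it *shrinks* the
empiric-vs-POCT gap `N(B+l−2p)/(2(B+l))∫x g dx`; the package implements
the price-shift accounting and reports both quantities separately.

## Synthetic data

There is no external data; the simulator itself generates the synthetic
patient panels (uniform symptoms, uniform threshold beliefs) that the
model assumes, so simulation checks validate the algebra under the
model's own data-generating process. They do not test the model's realism:
real symptom severity is not uniform, tests are imperfect, panels are
finite and heterogeneous, and physicians are not perfect agents. The
continuum panel of the theory is approximated by finite sampling whose
error is quantified by the reported standard errors, not a model feature.

## Degenerate inputs and tie-breaks

`b = 0` collapses everything to the certainty benchmark (`s* = ā`, no
tests, welfare `B − p(1−ā)`). `t` at the feasibility bound gives a
degenerate testing band at `s*` and zero adoption value. Ties adopt: at
`C` equal to the cap, and equivalently at `W_e = W_POCT`. Scenario
classification of a threshold draw uses half-open intervals with the
upper scenario taking the closed end; boundary events have probability
zero, so the convention matters only in degenerate tests.
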