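# Methods

## The design

`splinetrial` implements and evaluates a Bayesian two-arm sequential trial
with two binary endpoints:

* a **primary endpoint** — an adverse event (e.g. renal scarring after a
  febrile urinary tract infection), with true rates π_T (treatment) and
  π_C (control).  The treatment effect is the absolute risk reduction
  ARR = π_T − π_C; benefit means ARR < 0.
* a **secondary endpoint** — discontinuation of the assigned treatment in
  the treatment arm, with true rate π_disc and an acceptability threshold
  m (default 0.2).  Discontinuation is a tolerability/acceptability
  measure: a treatment that works but cannot be taken is not useful.

The trial takes a single interim look after a fraction (default one half,
so `n_interim = ceil(0.5 · n_total)` per arm) of enrolment and a final look
at full enrolment.  Interim data are a nested subset of the final data:
subject-level Bernoulli outcomes are drawn once per trial and the interim
counts are cumulative counts, as in a real accruing trial.  Discontinuation
is drawn independently of the primary event process; no dependence
structure between the endpoints is modelled.

### Stopping rules

Both rule families apply the same flowchart; all boundary comparisons are
strict, with ties resolving to the non-stopping action (a measure-zero
event for continuous posteriors).

**Classical (posterior-probability) rules.**  At the interim the trial

* stops for **efficacy** iff `P(ARR < 0) > Φ(c₁)` AND `P(π_disc < m) > Φ(c₁)`,
  with c₁ = 2.74, an O'Brien–Fleming-like conservative first-look bound
  (Φ(2.74) ≈ 0.997);
* stops for **futility** iff `P(ARR < 0) < 0.5` AND `P(π_disc < m) < 0.5`;
* otherwise continues.

Both endpoints must agree for either stop — a split verdict continues the
trial.  At the final look efficacy is declared on the primary endpoint
alone when `P(ARR < 0)` exceeds the final threshold, stored directly as the
probability 0.976 (the standard two-look O'Brien–Fleming final bound).  We
deliberately store the probability rather than a z-value: the z-scale
constant 2.75 sometimes quoted alongside 0.976 is mutually inconsistent
with it (Φ(2.75) ≈ 0.997), and keeping the probability in the config means
a rounding of the z constant can never change behaviour.  The thresholds in
force are logged on every CLI run.

**HDI rules.**  The same decisions phrased through highest-posterior-density
intervals: interim efficacy needs the ARR HDI at coverage
1 − 2·(1 − Φ(2.74)) = 0.994 entirely below 0 and the discontinuation HDI at
the same coverage entirely below m; interim futility needs 0 strictly
inside the 0.5-coverage ARR HDI and m strictly inside the 0.5-coverage
discontinuation HDI; the final look declares efficacy when the 0.95 ARR HDI
lies below 0.  The 0.994 coverage is exactly the two-sided normal mass
mimicking the one-sided z = 2.74 boundary (`hdi_coverage_from_bound`).

The futility threshold 0.5 is a design calibration: under a no-effect
scenario with the true discontinuation rate sitting on m, each of the two
posterior probabilities falls below its median roughly half the time and
independently, so about a quarter of null trials stop for futility at the
interim.  The quarter is a continuous-limit heuristic: with finite discrete
data the two factors are not exactly 1/2.  Arm exchangeability makes
`P(P(ARR < 0) < 0.5)` exactly 1/2, but `P(P(π_disc < m) < 0.5)` is a
binomial sum over interim discontinuation counts — with a flat Beta(1, 1)
prior the posterior median of the rate exceeds m whenever the observed
count reaches m·n, and at n = 50 treated subjects that event has
probability 0.556, putting the exact calibration value at
0.5 × 0.556 ≈ 0.278.  The test suite checks the simulation against both
this exact enumeration and the nominal quarter (within Monte Carlo bands
at 2,000 replicates).

"Truth" labelling for the operating characteristics uses the scenario's
generating values: the effect is real iff π_T < π_C, and a futility stop is
scored *true* iff the effect is not real **or** π_disc > m (a trial that
stops because the treatment is intolerable stopped rightly even if the
treatment works).  This labelling is a package choice — indicator names of
this kind imply ground-truth classification without pinning it down — and
is centralised in `operating_characteristics`.

## Priors

Each of the three rates gets its own prior, in one of two families and at
three informativeness levels.

**Parametric:** Beta(α, β), parameterised by mean and effective sample size
(ESS = α + β, the pseudo-observation count).  `beta_from_summary(mean, ess)`
gives α = mean·ess, β = (1 − mean)·ess.

**Semiparametric:** a density `f(x) = Σ cᵢ Bᵢ(x)` in a clamped cubic
B-spline basis on [0, 1] with equally spaced interior knots, nonnegative
coefficients and unit mass.  Nonnegative coefficients make the density
nonnegative and the CDF monotone by construction, and — because the basis
is a partition of unity — the exactly-uniform density is the all-ones
coefficient vector.

### Fitting the spline to elicited quantiles

An expert panel supplies quantile judgements (levels, values).  The fit
minimises the squared deviation of the spline CDF from the elicited levels
at the elicited values, subject to nonnegativity and unit mass.  Two weak
secondary terms resolve the indeterminacy a handful of quantiles leaves
between the elicited points:

1. a grid term (total weight 0.5 spread over a 201-point grid): squared
   deviation from a monotone CDF interpolant of the elicited points.  The
   interpolant blends a natural cubic spline of the CDF itself (exact for
   uniform beliefs) with a natural cubic spline on the probit scale
   (near-linear, hence accurate, for bell-shaped beliefs); the blend
   weights are inversely proportional to each interpolant's leave-one-out
   squared error at the interior elicited points, so the data itself picks
   the scale.
2. a roughness tie-break `1e-9 · ∫ f''²`.

The whole objective is quadratic, so the solve is a single nonnegative
least squares problem (stacked rows, with the unit-mass constraint as a
heavily weighted row, renormalised exactly afterwards) — convex,
deterministic and fast (~10 ms).

**Basis size.**  The default is 14 basis functions (10 interior knots).
This is a resolution requirement, not a tuning knob: with nonnegative
coefficients the maximum representable peak density scales inversely with
the knot spacing, and elicited Beta-like beliefs of ESS ≈ 20–40 have peaks
of 4–5, which an 8-function basis (peak ceiling ≈ 3.3) simply cannot
express.  At 14 functions the fitted CDF recovers exact Beta(a, b)
quantile sets with a, b ∈ [1, 20] to sup-norm error < 0.03 (Beta(4, 16) at
five standard levels: < 0.01), verified by property test.

**Discounting** (`discount_prior`): *informative* leaves the fit unchanged;
*low-informative* mixes the spline equally with the uniform density
(staying inside the same basis) or rescales a Beta's ESS to 5 holding the
mean; *uninformative* is the exact uniform (Beta(1, 1) or all-ones
coefficients).  The mixture weight and low ESS are configurable; no
canonical discounting rule exists, so both defaults are package choices.

**Pooling** across experts is linear: densities averaged pointwise
(coefficient-wise, since all fits share a basis) and renormalised.

**Default prior centres.**  When simulations request informative or
low-informative priors without elicitation data (`default_priors`), the
stand-in centres are prior means 0.4 (treatment), 0.3 (control) and 0.15
(discontinuation), each worth 20 pseudo-observations.  The treatment
centre deliberately sits *above* the control one, so null and benefit
scenarios exercise prior–data conflict: the informative prior expects harm
while the data show none or benefit.  Spline versions fit the exact
quantiles of the implied Beta at the standard levels.  These are declared
stand-ins for an elicitation exercise whose exact parameters are not
public; change them via the `means`/`ess` arguments.

**Synthetic elicitation panels** (`generate_elicitation_fixture`) emulate n
experts reporting the quantiles of a common Beta belief at levels
(0.05, 0.25, 0.5, 0.75, 0.95), perturbed on the logit scale with Gaussian
noise (default SD 0.1) and re-sorted.  This captures inter-expert scatter
around a shared clinical expectation; it does *not* capture systematic
expert biases, over-confidence, or asymmetric disagreement, so passing
tests say nothing about robustness to a genuinely misleading panel beyond
the explicit prior–data-conflict scenarios.

## Posterior computation

All posteriors are one-dimensional, so no MCMC: the unnormalised log
posterior `log prior(x) + s·log x + (n−s)·log(1−x)` is evaluated on an
equally spaced grid over [0, 1] (default G = 2001; log space so n = 10⁴
does not underflow) and trapezoid-normalised.  Beta shapes below 1 place an
integrable singularity at a boundary grid point; that point is assigned
zero mass (the trapezoid rule cannot represent it), a documented
approximation irrelevant to shapes ≥ 1.

Draws come from inverse-CDF interpolation on the grid CDF.  The ARR
distribution uses independent draws from the two arms (default 20,000),
each arm on its own deterministically spawned substream; an exact discrete
grid-convolution of the two cell-mass vectors (`arr_grid_convolution`)
serves as the cross-check oracle in tests.  The one-dimensional
discontinuation quantities never need sampling: its tail probability and
HDI are read directly off the grid.

**HDI algorithms.**  From draws: the shortest window containing
`ceil(coverage·N)` sorted draws — deterministic given the draws.  From a
grid: a water-level scan admitting cells in order of decreasing density
until the requested mass is reached; if the admitted region is not one run
of cells the bounding interval of the whole region is returned with
`contiguous=False` (the decision rules are written for a single pair of
bounds, so they consume the bounding interval — conservative for efficacy,
anti-conservative for futility, and logged via the flag).

## Monte Carlo engine

Per-trial seeds are spawned from the master `SeedSequence` (counter-based
splitting, no global RNG state), so operating characteristics are exactly
reproducible for identical (scenario, config, n_sims, master_seed) and
every trial is independently seeded.  Five indicators are aggregated, each
with its binomial Monte Carlo standard error `sqrt(p(1−p)/n_sims)`:
the proportion declaring the effect (interim or final), the FDR (that same
proportion under a null scenario), true and false interim futility, and
true interim efficacy.

`sample_size_search` scans an increasing grid of per-arm sizes, smooths the
raw power curve by isotonic regression (power is nondecreasing in n for a
fixed design, so the smoothing is structurally justified, not cosmetic) and
returns the smallest size whose smoothed power reaches the target, or an
explicit not-achieved marker.

### Problem sizes

The package defaults to 2,000 replicates per scenario for its
acceptance-level checks and examples use 150–1,000; the headline study this
design family comes from used 10,000.  At 2,000 the MC standard error of a
proportion near 0.25 is ≈ 0.010 and near 0.03 is ≈ 0.004, which is tight
enough for every calibration band checked here; all stochastic assertions
carry explicit 3·SE bands.

## Known limitations

* The exact elicited prior parameters and scenario grid of the motivating
  study are not public; the shipped defaults (Beta mean/ESS fixtures,
  scenario grids spanning null/benefit × acceptable/unacceptable
  discontinuation) are declared stand-ins spanning the same qualitative
  regimes, so figure-level quantitative reproduction is out of scope while
  calibration-level quantities (threshold constants, ~25% futility
  calibration, FDR ≤ 0.035) are reproduced.
* π_disc is modelled in the treatment arm only (the endpoint is
  acceptability of the experimental treatment); pooling both arms would be
  a one-line change in `run_trial`.
* Whether the final HDI coverage 0.95 is meant to mirror the final
  probability threshold 0.976 (which would imply 0.952 two-sided) is
  ambiguous in the source material; 0.95 is used as printed.
* Arms are independent; no correlation between π_T and π_C posteriors, no
  longitudinal dropout-time modelling, no alpha-spending beyond the two
  looks.
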