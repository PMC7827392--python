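# Methods

## Model and assumptions

The model is a deterministic, non-spatial ODE system for four well-mixed
populations in the tumor microenvironment: proliferative tumor cells
(`Cp`, the aggressive 4T1-like phenotype), quiescent tumor cells (`Cq`,
the chemotherapy-derived, type-I-IFN-active MR20-like phenotype), NK cells
(`N`) and CD8+ T cells (`T`). Its structural assumptions:

- Tumor growth is Gompertzian, `a·C·ln(Cmax/C)`, i.e. self-limited with a
  fixed carrying capacity `Cmax`; the growth rate already nets out natural
  death. The term is defined as 0 at `C = 0` (its mathematical limit).
- Killing of tumor cells by effectors and inactivation of effectors by
  tumor cells are mass-action (`b·N·C`, `eta·T·C`; `p·C·N`, `u·C·T`).
- NK cells have a constant source `s` (innate immunity is always present);
  CTLs are stimulated by NK-tumor interaction (`r·N·C`). Both effectors
  are additionally recruited with saturating Michaelis-Menten kinetics in
  the squared burden, `g·C²/(h+C²)` and `j·C²/(k+C²)`.
- The quiescent phenotype is more immunogenic and slower-growing:
  `a2 < a1`, while `b2 > b1` and `eta2 >> eta1`. The proliferative-side
  NK-kill and CTL-stimulation rates are alpha-coupled to the quiescent
  ones, `b1 = alpha·b2`, `r1 = alpha·r2`, `alpha = 0.3`.
- Heterogeneous tumors: both clones share the capacity (the Gompertz
  logarithm carries `C = Cp + Cq`) and the five proliferative-side
  constants `a1, b1, eta1, r1, u1` are replaced by population-weighted
  means `x1h = (x1·Cp + x2·Cq)/(Cp + Cq)`. The printed source expressions
  omit the enclosing parentheses; they are read as weighted means, which
  is the only reading consistent with "averaging over the two populations"
  and which makes every mixed value a convex combination of its parents
  (a tested invariant). Only those five constants are mixed; the quiescent
  equation keeps `a2, b2, eta2`, the NK equation has a single shared `p`,
  and the recruitment terms use the total burden.
- Cell counts are continuous non-negative reals; integer semantics enter
  only through the extinction rule below. B cells/humoral response and
  spatial structure are outside the model's scope.

Default constants (units: day⁻¹, cell⁻¹day⁻¹, cells) are the calibrated
values for the 4T1/MR20 system, packaged in
`src/dormancy/data/default_params.yaml`: `a1 = 0.038`, `a2 = 0.0174`,
`Cmax = 1e9`, `alpha = 0.3`, `b2 = 5.2e-8`, `eta1 = 2.1e-8`,
`eta2 = 2.8e-7`, `s = 1.3e4`, `r2 = 1.2e-7`, `g = 0.025`, `h = 2.02e7`,
`f = 0.0412`, `p = 1.8e-8`, `j = 0.1`, `k = 2.02e7`, `m = 0.02`,
`u1 = 2.1e-8`, `u2 = 1.7e-12`. Standard initial conditions: a 5e4-cell
tumor inoculum (split by scenario), `N0 = 2.5e5`, `T0 = 5.2e5` (day-7
estimates from the underlying mouse experiments). The loader coerces
values through `float()` because bare scientific notation (`5.2e-8`)
parses as a string under YAML 1.1.

## Numerical scheme

- Classic explicit fixed-step RK4, default step 0.01 day, horizon 365
  days. The system is non-stiff at these scales (fastest rates ~20/day
  appear only after escape, giving lambda·h ~ 0.2). The solver order and
  step are the package's own choice; two guards substitute for an external
  reference: halving the step changes the dormancy trajectory by < 1e-4
  relative and no fate label anywhere in the test suite, and the dormancy
  solution agrees with an independent adaptive integration
  (scipy `solve_ivp`, RK45 at rtol 1e-10) within 0.1% at every output day.
- Extinction rule: after every accepted step, a tumor compartment in
  (0, 1) is set to 0 and logged. The rule applies to tumor compartments
  only - applying it to effectors would contradict the constant NK source.
  An extinct compartment stays at zero unless re-seeded by an injection.
  Immune compartments are floored at 0 (never flagged extinct).
- Injections are instantaneous state jumps at event days snapped to the
  integration grid (the model is non-spatial, so injection site is
  irrelevant). Conservation at each event is exact and tested.
- Escape threshold: 1e8 cells (`Cmax/10`). No numeric definition exists in
  the source material; trajectories that break immune control grow toward
  `Cmax = 1e9`, and any threshold in [1e7, 5e8] yields identical labels in
  the test scenarios. The value is exposed in configuration and CLI.
- Escape onset: two readings are implemented. The default is the day the
  burden first reaches the escape threshold - the moment escape is visible
  on a growth curve (day ~143 for the slowest escaping reference run,
  matching the reported "around day 130" timing). The alternative
  (`regrowth_minimum`) is the last local minimum before the final
  uninterrupted rise; it fires much earlier (day ~47 for the same run,
  when the proliferative clone bottoms out near one cell) and is reported
  alongside the default by `analysis/03_heterogeneous_fates.py`.
- The hot loop is JIT-compiled with numba (a pure-Python fallback of the
  identical code runs when numba is unavailable); the kernel's agreement
  with the pure right-hand-side functions is asserted to 1e-14 in tests.
- Fate classification: a clone is *eliminated* if it ends at zero,
  *escaped* if the total burden reached the threshold while the clone
  survived, *dormant* otherwise; the overall tumor is escaped if either
  clone escaped, eliminated if both clones are gone, dormant otherwise.

## Scenarios

- Series 1 (aggressive growth): proliferative-only runs over inocula
  {5e3, 1e4, 5e4, 1e5, 5e5} (the reference inoculum set is not specified;
  this ladder brackets the standard 5e4 and is configurable). All escape;
  escape day decreases strictly with inoculum.
- Series 2 (dormancy): quiescent-only 5e4-cell run; damped predator-prey
  oscillation settling near 2.3e3 cells, CTL peak near day 19.
- Series 3 (heterogeneity): two-clone runs at fixed 5e4 total. The fate
  map uses 25 log-spaced sizes (2e4..2e6) x 26 percentages (0..25%), fine
  enough to resolve all contiguous regions at minutes-scale cost. Region
  counting is 4-connected components of equal (quiescent, proliferative)
  fate pairs. The map yields five regions; four match the reference
  layout exactly, while the intermediate band computes as
  quiescent-eliminated / proliferative-*dormant* rather than
  both-eliminated: after the quiescent clone dies there, the
  proliferative-only subsystem has a stable equilibrium near 2.2e3 cells
  (where `j·C²/(k+C²) ≈ m`) and the damped oscillations never carry `Cp`
  below one cell at any tested step size. This is a genuine property of
  the equations at the packaged constants, not a solver artifact.
- Series 4 (vaccination): the vaccine seeds the quiescent compartment of
  the heterogeneous model; the challenge (5e4 proliferative cells) is an
  injection at day 0; pre-challenge injections start the integration at
  the earliest event with time reported relative to the challenge. On the
  dose grid {5e4, 1e5, 2e5, 4e5} at a 20-day lead the computed minimal
  protective dose is 1e5 - one grid step below the reported four-fold
  dose (2e5). The discrepancy is robust here across immune-initial-
  condition choices, a separate-site (no-mixing) variant, the whole
  [1e7, 5e8] threshold family and steps 0.1-0.005; protection in this
  implementation ends between 5e4 (escapes) and 1e5 (controls the
  challenge at the same ~2.2e3-cell equilibrium as above).

## Calibration and sensitivity

- Objective: sum of squared residuals of total tumor size at the
  observation days, simulated values linearly interpolated from the
  integration grid; integration failures return a large penalty with a
  warning so optimizers can continue.
- Optimizer: Nelder-Mead simplex over log10-transformed parameters
  (positivity plus even scaling across decades), box bounds in log space,
  multi-start with seeded uniform draws (first start at the box center).
  Because Nelder-Mead is comparison-based, the implementation minimizes
  `log1p(SSR)`, which follows the identical search path while making the
  function-tolerance criterion scale-free. Deterministic given the seed.
- Synthetic observations: generated by the model itself on a twice-weekly
  (3-4 day) observation grid, the cadence of caliper measurements in the
  underlying animal work. Noise is multiplicative log-normal by default
  (tumor sizes span decades); additive Gaussian is available. What passing
  recovery tests show is self-consistency of the pipeline - they cannot
  certify the published constants, whose raw fitting data are unavailable.
- Recovery design: a joint (b2, eta2) fit to one immunocompetent series is
  exact on noiseless data but leaves b2 practically unidentifiable at 5%
  noise, because NK killing is only ~5% of the total kill rate there. The
  recovery experiment therefore mirrors the original staged design: b2 is
  fitted to a T-cell-free ("nude-host": `T0 = 0`, `r = 0`) series, then
  eta2 to an immunocompetent series with b2 fixed. Both recover within
  10% at 5% noise across seeds (worst case ~7% for b2, ~3% for eta2).
- Sensitivity: `N0, T0, b, eta, p, u` are drawn independently per
  replicate from `Normal(mean, 0.25·mean)`, truncated at 0 (negative
  rates/counts are meaningless; truncations are counted and reported).
  Grouped names perturb the variant-relevant member (`b2, eta2, u2` for
  quiescent runs) with the alpha-coupled partner following. Default 500
  replicates (the analysis script uses 500/200; tests use 30-50, which
  already bound the fate frequencies tested). At cv = 0.25 dormancy is
  robust (>99% of replicates dormant) and proliferative escape is
  unconditional.

## Known limitations

- The volume-to-cell-count conversion of the original measurements is
  unpublished; observations here are already in cells, and a user mapping
  real volumes must supply their own conversion constant.
- The fate map's intermediate band and the protective-dose threshold
  differ from the reported outcomes as noted above; both trace to the
  stable low-burden proliferative equilibrium of the packaged constants.
- No stiff/implicit or stochastic (demographic-noise) solvers; no B-cell
  compartment; no spatial structure; vaccination schedules are evaluated
  on grids, not optimized.
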