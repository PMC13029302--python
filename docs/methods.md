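# Methods

## Coded factor space

All modelling and optimization happens on the coded cube. Four factors:
F1 drug concentration (continuous, 0.1 / 0.21 / 0.31 %), F2 lactose/Aerosil
adsorbent ratio (discrete, levels A / B / C), F3 SEDDS percentage
(continuous, 8 / 18 / 28 %), F4 blending method (discrete, manual /
continuous / interval). Coded-to-actual decoding is **piecewise linear
between adjacent anchor levels**, not a single affine map: F1's levels are
unevenly spaced, and the piecewise map is the only linear-per-segment
convention exact at all three anchors. Discrete factors are represented on
the coded scale and constrained to {−1, 0, +1}; the optimizers treat them
by exact enumeration, never by relaxation. (Contour-grid evaluation *can*
relax a discrete factor, but only when explicitly requested — it is a
visualisation device.)

One known ambiguity: the source study reports its desirability optimum as
F1 = 0.225 % at coded 0.19, whereas the piecewise-linear convention gives
0.21 + 0.19·0.10 = 0.229 %. The off-anchor decoding convention used there
is not recoverable; this package applies its piecewise rule consistently.

## Box–Behnken design

`build_bbd` emits the standard 4-factor BBD: for each of the six factor
pairs, the four (±1, ±1) combinations with the other factors at 0, plus
centre replicates — 27 runs at the default 3 centres. The run order
reproduces the canonical study layout (pair blocks (F1,F2), (F3,F4),
centre, (F1,F4), (F2,F3), centre, (F1,F3), (F2,F4), centre); no
randomization layer is added. The design's useful algebra — every linear
column orthogonal to every other column in the recovery term set — is what
makes each linear coefficient equal its simple contrast
(Σy at +1 − Σy at −1)/12, used throughout the tests as a fit oracle
independent of the linear-algebra path.

## Response surfaces

Term sets are explicit monomial lists (13 terms for angle of repose, 14
for blending efficiency, 6 for recovery) because the published models mix
quadratics with cubic cross terms such as F1²·F2; a degree bound would not
reproduce them. Fitting is ordinary least squares (statsmodels backend)
with diagnostics per term (SE, t, p from the unscaled covariance × MSE)
and overall (R², adjusted R², MSE = SSE/(n−p)). Default fitting is on the
per-run **means** (27 observations, df = n − p); replicate-level fitting
is available and changes df and MSE accordingly — published fit statistics
for this study (MSE/R²_adj, F-values) evidently derive from a fitting
basis that is not recoverable from the printed table, so they are treated
as reference, not reproduced. No stepwise selection or weighting: the
published models retain their higher-order terms, and the run SDs are
stored but not used as weights.

The printed regression equations also ship as constant "as-published"
models, distinct from refit models. Several downstream published numbers
are consistent only with the authors' internal full-precision models, so
the two sources are kept as first-class, clearly separated objects; the
CLI exposes both (`--models as-published|refit`).

## Desirability

One-sided Derringer ramps with a stringency exponent *s* applied inside
each individual desirability; the same *s* is shared across goals in a
sweep. Boundary convention: z exactly at the target gives d = 1, z at the
cut-off gives d = 0. The global score is the weighted geometric mean with
the 1/∑w root applied as written — weights are never silently
renormalized. The canonical configuration sets targets at the aspiration
levels (35°, 0.12, 90 %) and cut-offs at the anti-ideal points
(45.29, 0.4811, 23.829) with weights (0.2, 0.4, 0.4): this is the unique
simple assignment that reproduces the published five-point D(s) column
(0.860, 0.739, 0.635, 0.546, 0.469), via
D(s) = ((45.29 − 40.46)/10.29)^{0.2s}. Because s is a pure power on each
ramp, d(z; s) = d(z; 1)^s exactly — tested as an identity — and whenever
the optimum holds all goals but one at d = 1, the arg-max is invariant to
s while D decays geometrically.

## Weighted goal programming

Weights derive from priorities by the **reciprocal rule**
w_i = (1/r_i)/∑(1/r_j): it is the only reading of "normalize the
priorities" that maps the study's priorities (2, 1, 1) to its weights
(0.2, 0.4, 0.4). Deviations are derived quantities of (z, T) —
n = max(T−z, 0), p = max(z−T, 0) — rather than free optimization
variables: for fixed factors the G-minimizing feasible deviations are
exactly these, so the reduced formulation attains the same optimum as the
explicit constrained one (property-tested), and G becomes a deterministic
objective over the factor domain. The achievement function normalizes each
unwanted deviation by its aspiration level (w_i/T_i), making G invariant
to jointly rescaling a response and its aspiration; a zero aspiration is
rejected. Ideal/nadir pre-scaling from the payoff matrix is available as
an opt-in mode, in which G is the plain weighted sum of normalized
unwanted deviations (normalizing by a scaled aspiration near zero would be
ill-posed); the default follows the achievement function as written.

## Mixed-domain optimizer

Both optimizers share one deterministic global solver: enumerate all 9
discrete-level combinations; per combination evaluate a uniform seed grid
on the continuous square (default step 0.05, i.e. 41×41), then polish the
best 5 seeds with bounded Nelder–Mead (derivative-free; tolerance 1e−8);
return the overall best, ties broken to lexicographically smallest
coordinates. The objectives here are low-order polynomials (or clipped
powers of them) on a square, so the seed grid already lands near every
basin and the polish only sharpens; an exhaustive `grid_oracle`
(default lattice step 0.005) keeps the solver honest in tests — agreement
within 1e−4 over 50 seeded random surfaces. No stochastic metaheuristics:
reproducibility outranks generality for a decision pipeline.

## Design-space overlay

Overlay masks evaluate each quality constraint on a lattice over a 2-D
slice; the intersection is the multi-response design space. Discrete
factors may not serve as slice axes and must be fixed at anchor levels —
the overlay is a decision map and shows only admissible settings. The
default thresholds (z1 ≤ 40°, z2 ≤ 0.12, z3 ≥ 90 %) combine the
flowability specification of the target product profile with the two
aspiration levels; the source figure does not print its exact shading
thresholds, so these defaults are a documented assumption. Rendering is
left to the caller: the grid exports as long-format CSV.

## Quality metrics

Angle of repose α = arctan(h/(0.5·d)) in degrees; blending efficiency as
the sample CV (n−1 denominator, pharmacopoeial convention for small n);
drug recovery as a percentage, deliberately not clipped at 100 (assay and
sampling variability legitimately exceed it). Content uniformity follows
Ph.Eur. 2.9.6: AV = |M − X| + k·s with M clamping X to [98.5, 101.5] and
k = 2.4 wired for n = 10 (other n require a user-supplied k), compliance
at AV ≤ 15. Only the in-band branch of the M rule appears in the source
study; the clamp branches follow the pharmacopoeial standard.

## Synthetic studies

The generator emulates the real study's structure: a 27-run BBD with
triplicate Gaussian replicates per run, means ± SD stored alongside the
raw replicates, i.i.d. noise per replicate (heteroscedastic per-run SDs
supported, mirroring the varying SDs of real tables). Randomness uses one
master seed with per-(response, run) substreams, so adding a response or
run never perturbs existing draws. `preset_conflicting_truth` reproduces
the study's essential tension — one factor improves the maximized response
while degrading both minimized ones — with closed-form single-response
optima (40 / 0.04 / 108 at F3 = −1, −1, +1 respectively) documented for
tests; its noise scales (1.5°, 0.02 CV, 8 %) match the order of magnitude
of real triplicate scatter.

What the generator does *not* emulate: correlated errors across responses
measured on the same batch, assay nonlinearity, run-order drift, or any
model misspecification (truths are exactly polynomial). Passing recovery
and coverage tests therefore demonstrates correctness of the estimator and
optimizer machinery, not robustness to real-world error structure.

## Problem sizes and numerical choices

Simulation-based checks use 27-run studies throughout — the design the
method is built for: 200 replications for sampling-spread checks, 500 for
CI coverage, 50 seeded random surfaces for optimizer-vs-oracle agreement.
Oracle lattices use step 0.005 (~1.4 M points over the 9 discrete
combinations). Rank deficiency is detected before fitting and reported
with the offending terms; saturated fits flag their diagnostics as
undefined rather than fabricating them. Comparisons against printed
coefficients round half-away-from-zero to the printed decimals; full
precision is always reported.

## Known limitations

- Single-response term sets and the 4-factor BBD constructor are tailored
  to this study family; other design families (central composite, full
  factorial) and mixed-effects/weighted fits are out of scope.
- The desirability module implements one-sided goals only (no
  nominal-the-best).
- Goal programming is weighted-sum only — no lexicographic/preemptive or
  Chebyshev variants, and no Pareto-frontier enumeration (aspiration
  levels are the practical alternative).
- Published internal-model-dependent numbers (payoff-matrix extremes,
  optimizer-coordinate endpoints) are not reproducible from the printed
  rounded equations and are treated as reference values, never asserted.
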