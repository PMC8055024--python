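# Methods

## The agent-based model

Agents live on a continuous 2-D toroidal plane (side 200 world units; the
torus avoids edge artifacts). Each agent carries a position, a heading, a
dominance value `D > 0`, and two sex-specific constants: its initial
dominance (females 16, males 32) and its intensity of aggression `StepDom`
(females 0.1, males 1.0). All other movement and perception parameters are
shared between the sexes: field of view 120°, personal space 4, near view
24, maximum view 48, move distance 1, flee distance 2, chase distance 1,
withdraw distance 0, and the turn angles/errors listed in
`domworld.SimParams` (wiggle 0±10°, search 90±10°, won 0±0°, flee 180±10°).

**Activation.** Time advances in periods; within a period every agent is
activated exactly once in a fresh uniform random order. This discrete
random-permutation scheme replaces an explicit event clock; nothing
downstream depends on sub-period timing.

**Behaviour rule.** On activation the focal looks for the nearest other
within its field of view and maximum view (toroidal metric; ties broken by
index, a measure-zero event in continuous space):

- nearest within personal space → *mental battle*: attack only if the focal
  wins `numMentalBattles` (= 1) internal simulations, each won with
  probability `D_i/(D_i+D_j)`. On attack the real fight is won by the
  initiator with that same probability; the winner turns toward the loser
  and advances the chase distance, the loser turns away (±10° error) and
  flees. On a failed mental battle the focal turns away 180°±10° and
  withdraws 0 units (it stays in place but will wander off, since the
  opponent leaves its field of view). The stay-facing alternative was
  evaluated and changed neither fight rates nor any downstream slope
  materially.
- nearest within near view → keep going (move distance along the current
  heading, wiggle error applied): the agent is in a group.
- nearest beyond near view but within maximum view → turn toward it and
  advance (returning toward the group).
- nobody visible → search turn (90°±10°, random side) and advance.

**Winner–loser update.** After a decided fight,
`Δ = (w − D_i/(D_i+D_j))·S`; the winner gains `Δ` and the loser loses `Δ`
(zero-sum), floored at `D ≥ 0.01` so win probabilities stay defined. An
expected victory changes little; an upset changes much — the damped
self-reinforcing dynamic that differentiates the hierarchy. `S` is a single
scale per fight; because the sexes differ in `StepDom`, a convention must
pick it in mixed-sex fights. The convention is configurable
(`initiator` — the default, `winner`, `opponent`, `mean`); all four were
evaluated and `initiator` reproduces the reported slope pattern best. Note
that conditional on a fight happening `E[Δ] = 0`, so between-individual
dominance differentiation is driven by the variance of the update (a
diffusion sped up by the winner–loser feedback), not by a per-fight drift.
This is why long runs are needed before sex-ratio effects on female
dominance are measurable.

**Initialisation and run length.** Agents start uniform in a disc of radius
20 at the world centre (within view of each other) with uniform headings.
Class defaults are 300 periods with a 60-period burn-in; the
reproduction experiment uses the calibrated run length 2000 periods with
fights tallied over the final 600 (`pipeline.EXPERIMENT_N_PERIODS`,
`EXPERIMENT_BURN_IN`), chosen on a scan as the point where the dominance
distribution has differentiated enough that the cross-group slopes
stabilise. Every run is reproducible from one seed; per-run and per-group
seeds are spawned deterministically from it.

## Hierarchy statistics

From the winner×loser count matrix of a group(-period):

- **ADI**: per individual, the mean over partners actually interacted with
  of the fraction of fights won against that partner; individuals with no
  interactions have undefined ADI and are left unranked. ADI values are
  rationals; ranking compares them after rounding to 9 decimals so that
  equal rationals computed in floating point tie exactly (an exact-fraction
  variant backs the tests).
- **Ranks**: descending ADI, competition style (tied individuals share the
  best rank of their block).
- **FDI**: the mean over ranked females of the proportion of ranked males
  strictly below them. A tied male contributes `tieWeight` (default 0,
  configurable to 0.5); the default is consistent with observed co-alpha
  females in groups whose FDI is still below 1. The grouped-count view
  (successes out of `n_males × n_females`) uses the same fixed denominator
  for every female.
- **Unknown relations**: the fraction of unordered dyads with zero
  interactions, over all dyads of the group.
- **Aggression fractions**: male–male acts / all male-initiated acts and
  female-to-male acts / all female-initiated acts. Simulated data carry the
  initiator of every attack; when only a winner–loser matrix is available,
  won fights attributed to the winner stand in (configurable). The
  male–male fraction is excluded in single-male groups.

## Beta-binomial inference

Grouped proportions are modelled as beta-binomial: `k ~ BetaBin(n, μ, θ)`
with logit-linear `μ` and precision `θ > 0` (binomial as `θ → ∞`).
Estimation is maximum likelihood (not REML-like), so likelihood-ratio
comparisons and AIC are coherent across nested and non-nested models.
Gradients of the log-likelihood in the linear predictor and in `log θ` are
analytic (digamma/trigamma); optimisation is L-BFGS-B with `log θ` bounded
in [−10, 20] and three jittered restarts on failure. Convergence is judged
by the gradient at the optimum, not the optimizer's status flag. Standard
errors come from the inverse observed information (central-difference
Hessian of the analytic gradient).

**Random intercepts.** Each grouping factor contributes i.i.d.
`N(0, σ_f²)` intercepts, integrated by a Laplace approximation (one
quadrature point): the inner mode is found by damped Newton with the
analytic gradient and Hessian of the joint log-density, and the outer
optimisation runs over `(β, log θ, log σ_f)` with `log σ` bounded in
[−9, 5] — the lower bound is the numerical zero boundary, at which the
marginal equals the fixed-effects likelihood to well below 1e-6. Against
exact quadrature on a deliberately hard tiny case (two observations per
group) the Laplace marginal is accurate to 0.03 log-units; against an
independent TMB-based implementation on the 14-row empirical fit it agrees
to 1e-5 in log-likelihood and 4 decimals in coefficients.

**Boundary tests.** LRTs of parameters on the boundary of their space use
chi-bar-square mixtures: `{0: ½, 1: ½}` for one boundary parameter
(overdispersion), `{0: ¼, 1: ½, 2: ¼}` for two variance components, with
`χ²₀` a point mass at zero. Pseudo-R² is `1 − exp(−(2/n)·ΔlogLik)`
(optionally Nagelkerke-rescaled; the unrescaled variant is the default and
both are reported).

## The two analysis arms

**Simulated arm.** 40 independent runs, each simulating the 14 field group
compositions. Per run, five fixed-effects beta-binomial regressions across
groups: FDI counts on the proportion of males; male–male aggression counts
(of total male acts) on the proportion of males (single-male groups
excluded); female-to-male counts (of total female acts) on the proportion
of males; and FDI counts on each aggression fraction. Per-run fits use no
random effects — the 14 groups within a run are independent; a group
intercept is available as an option. Slopes are averaged across runs and
tested against zero by one-sample t (df = 39). Fits that fail the gradient
check or exceed |slope| > 100 (separation) are excluded and counted as
warnings. The docile-male check regresses male-to-female acts out of all
male acts on the proportion of males with a `logit(n_females/(n_adults−1))`
offset — the random-encounter expectation — so a nonzero slope means males
redirect aggression away from or toward females beyond chance; the
offset-vs-covariate choice is configurable, offset by default.

**Empirical arm.** The packaged table of 14 group-periods (three
populations, six groups) drives: the unknown-relation/group-size
correlation (the product-moment and the rank coefficient differ materially
on the printed two-decimal values — 0.68 vs 0.59 — so both are computed and
reported side by side); the count of FDI ≥ 0.5; and mixed fits with population and
group-within-population intercepts on counts reconstructed as
`round(FDI × n_males × n_females)` out of `n_males × n_females` — raw
matrices are not published, so all downstream coefficients are labelled
reconstructed and read qualitatively (sign, significance, AIC ordering).
Models use the exact `n_males/n_adults` ratio as the regressor, not the
printed rounded proportion.

## The synthetic generators

`synth.generate_interaction_matrix` draws latent strengths per individual
(normal on a logit scale, sex-specific means defaulting to `log 2` apart —
loosely mirroring the simulator's 2:1 initial-dominance ratio), a Poisson
number of fights per dyad (default rate 2, about the per-dyad interaction
density of the field data), and logistic win probabilities in the strength
difference. It emulates the *statistical* structure the metrics assume —
independent dyadic sampling around a fixed latent order. It does not
emulate winner–loser dynamics, spatial encounter structure, or
observation-effort differences between groups, so tests built on it
validate the metric and fitting chain, not the behaviour of real capuchin
data. `synth.simulate_betabin_dataset` draws grouped beta-binomial counts
with known coefficients, precision and random-intercept variances for
recovery tests.

## Numerical choices and limitations

- Angles in degrees; turn errors uniform on ±error; search side fair coin.
- Fight geometry: flee first (away direction ±error, 2 units), then the
  winner advances 1 unit along the original winner→loser bearing.
- The beta-binomial pmf is computed via log-gamma and is stable to n ≈ 1e4.
- Problem sizes in the test suite (replicate counts, group counts, run
  lengths) are chosen to exercise each property at meaningful power while
  keeping the whole suite fast; the reproduction experiment itself always
  uses the full 40 × 14 design.
- Per-group FDI success counts are small (totals 3–60), so per-run
  FDI-regression slopes are heavy-tailed across runs; their 40-run means
  carry s.e.m.s of ~0.4–0.8. The aggression-composition slopes, built on
  hundreds of acts per group, are far more stable (cross-run t ≈ 30).
- The simulator reproduces the direction and approximate magnitude of all
  reported slope patterns, but the female-to-male aggression slope
  saturates ~15% below the originally reported value at every run length
  and update convention tried; with the original simulator unavailable,
  the residual gap presumably sits in unstated movement or update details.
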