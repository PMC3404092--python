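# Methods

## The model

`cumculture` studies when a population of social learners can sustain or
accumulate a culturally transmitted skill, as a function of population size
`N`. Each individual `i` carries a continuous skill value `z_i`; a new
generation acquires its values by imitating members of the previous one
through an *inaccurate* transmission process. The change in the population
mean `z̄` across one generation follows the Price equation,

    Δz̄ = Cov(c, z) / c̄ + E(c·Δz) / c̄ ,

where `c_i` is the likelihood that individual `i` is copied and `Δz_i` the
transmission change incurred when copying `i`. Under the tractability
assumption that *every* learner copies the most skilled individual
(`c_h = 1`, all other `c_i = 0`), this reduces to the gap between the
expected population maximum and the population mean, plus the mean imitation
error.

### Skill distributions and expected maxima

Skills are i.i.d. draws from one of three location-scale families, and the
selection term is the expected largest order statistic of an `N`-sample:

| family | parameters | E[max of N] − E[z] |
|---|---|---|
| Gumbel | mode `m`, scale `β` | `β·ln N` |
| Logistic | location, scale `s` | `s·(ψ(N) + γ)` |
| Normal | mean `μ`, sd `σ` | `σ·Φ⁻¹(0.5264^(1/N))` |

Here `γ` is the Euler–Mascheroni constant and `ψ` the digamma function. The
Normal expression is the Chen–Tyler closed-form approximation of the exact
integral `N·∫ z φ(z) Φ(z)^(N−1) dz`, which the package also evaluates by
adaptive quadrature over `[μ − 10σ, μ + (10 + ln N)σ]` (absolute tolerance
1e-9; the integrand's effective support is bounded). Measured against that
integral, the approximation is accurate to better than 1% relative error for
`N` in `[5, 5000]`; it degrades sharply below that (≈1.4% at `N = 4`, ≈2.7%
at `N = 3`, ≈6.2% at `N = 2`, where the exact value is `1/√π`). Users who
need small-`N` Normal expectations should call the quadrature routine
directly.

### Transmission error and complexity

A learner copying a mentor of skill `z` realizes a draw from the error
family located at `z − α`: Gumbel(mode `z − α`, scale `β`) or
Normal(mean `z − α_N`, sd `σ`). The expected imitation error is therefore
`−α + γβ` (Gumbel) or `−α_N` (Normal). Its magnitude — the *transmission
inaccuracy* — is the package's measure of skill complexity: a complex skill
is one that is copied with a large expected shortfall. The Gumbel curves
are conventionally reported on the `α` axis (with the error spread set equal
to the skill scale, the model's standard parameterization); `ErrorSpec.mean`
exposes the `−α + γβ` conversion. The Logistic variant keeps the
Gumbel-style error of the original model, and its critical curve is solved
in transmission inaccuracy.

### Critical curves and sensitivity

Setting `Δz̄ = 0` yields the maximum sustainable complexity per `N`:

    Gumbel:    α* = β·(ln N + γ)
    Logistic:  I* = s·(ψ(N) + γ)
    Normal:    I* = σ·Φ⁻¹(0.5264^(1/N))

All three are strictly increasing in `N`; `critical_population_size` inverts
them by integer bisection. The derivative of each curve with respect to `N`
(`β/N`, `s·ψ₁(N)`, and the chain-rule derivative of the Chen–Tyler form)
measures how much sustainable complexity a population loses per head of
population decline. With variance-matched scales (`σ = βπ/√6 ≈ 1.28 β`,
so all families share the Gumbel's variance `π²β²/6`), the Normal derivative
lies below the Gumbel and Logistic derivatives at every `N ≥ 2`: Normal
populations are the least sensitive to demographic change, though the
population effect itself — e.g. a drop from `N = 5000` to `N = 2000` lowers
sustainable complexity — survives under all three families.

## The agent-based model

The simulation half replaces the copy-the-best idealization with an explicit
generational loop: *vertical transmission* (each adult produces one offspring
that copies it inaccurately), *oblique transmission* (each offspring gets
`κ` opportunities to copy a non-parent adult chosen by a mentor-selection
strategy, adopting the realized copy only if it strictly improves on its
current value), and *replacement*. Migration between subpopulations is out
of scope; runs concern single isolated populations.

Strategies: `best` (argmax, lowest index on ties), `payoff_proportional`
(candidates are adults strictly better than the learner, weighted by the
skill difference; the step is skipped when no adult qualifies), `random`
(uniform), `conformity_interval` (uniform over adults within ±2 skill scales
of the adult generation's mode — a four-scale window, a deliberately modest
conformity), and `conformity_inverse` (weight `1/(|z − mode| + δ)` with
`δ = 1e-6·scale` to keep the weight finite at the mode; the distortion is
negligible at realistic spreads).

Design choices where the design was genuinely open:

- **Mode estimator.** Conformity needs the mode of a continuous sample. The
  package uses the half-sample mode of the current adult generation,
  recomputed each generation: robust, deterministic (ties break toward the
  smaller value; the two-point base case returns the smaller value), and
  free of bandwidth choices. It is unbiased for the families used here but
  converges at the `n^(−1/3)` rate (sampling sd ≈ 0.1 at `n = 1e5`).
- **Adoption filter.** The improvement filter compares the learner's current
  value with the *realized* copy (mentor's value plus error), for every
  strategy. The alternative — unconditional adoption, arguably truer to pure
  conformity — is available via `Strategy(improvement_filter=False)`.
- **κ (oblique rounds).** Default 1; each extra round is a fresh
  select/copy/adopt opportunity against the same (static) adult generation.
- **Initial population.** Location 0 (all results are location-equivariant),
  scale equal to the configured skill scale.
- **Payoff selection at scale.** Selection probabilities are computed
  exactly on the sorted adult values with prefix sums and a vectorized
  binary search, avoiding the `N × N` weight matrix; the per-generation cost
  is `O(N log N)`.

Randomness: one master seed per run; replicate and cell substreams are
spawned deterministically (`numpy.random.SeedSequence`) and recorded in the
run manifest, so every pipeline is bit-reproducible.

## Sweep experiments

The maximum sustainable complexity for a (strategy, `N`) cell is estimated
on a fixed `α` grid: a trajectory counts as *sustained* when the
least-squares slope of `z̄` versus generation, after discarding a 10%
burn-in (transients from the arbitrary starting distribution), is ≥ 0; a
grid point is sustainable when at least half of the replicates sustain it
(an unbiased threshold at the critical point, where the slope is zero in
expectation); `α*` is the largest sustainable grid point, never
interpolated, so results are exactly reproducible. All three knobs
(burn-in, slope tolerance, required fraction) are configuration, and
lowering the slope tolerance can never lower `α*`.

Default problem sizes: `N ∈ {2, 5, 10, 25, 50, 100, 250, 500, 1000}` (the
reduced preset uses `{10, 50, 250, 1000}`), `T = 100` generations, 10
replicates, and a 40-point linear `α` grid from 0.2 to 8.0 (step 0.2) —
desk-scale settings that still resolve the payoff-bias plateau above
`N = 250`. For Normal-family sweeps the skill sd is variance-matched to the
Gumbel (`σ = 1.28` at unit `β`). Strategy `best` in a sweep runs the pure
copy-the-best mode, the bridge to the analytic model: its `α*` tracks
`β(ln N + γ)` to within one grid step.

## What the generator does and does not emulate

Synthetic populations are i.i.d. draws from the stated families, and errors
are i.i.d. given the mentor — there is no skill heritability beyond the
copied value, no age structure, no innovation process, no migration, and no
evolution of the learning strategies themselves. Passing tests therefore
show that the *models* behave as derived (critical thresholds, strategy
orderings, plateaus), not that real skill distributions are Gumbel or Normal
or that real learners use any particular strategy.

## Numerical notes and limitations

- `γ`, `ψ`, `ψ₁`, `Φ`, `Φ⁻¹` come from numpy/scipy special functions at full
  double precision.
- Degenerate inputs: zero error spread is disallowed (use a tiny spread to
  approximate deterministic copying); empty candidate pools skip the oblique
  step; an all-zero copying-likelihood vector is a degenerate-selection
  error in the Price routine.
- `α*` estimates inherit grid resolution (±1 step) and replicate noise near
  the critical point, where the sustained fraction hovers around 1/2 by
  construction.
- The Logistic family is analytic-only; the simulation half covers Gumbel
  and Normal skills.
- One-generation expectations, not stochastic equilibria: the analytic model
  makes no claim about the stationary distribution of `z̄`.
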