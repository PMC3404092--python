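# cumculture

Demography and cumulative culture: when is a population large enough to
sustain — or ratchet up — a culturally transmitted skill?

`cumculture` is for researchers in cultural evolution, evolutionary
archaeology and anthropology who want to probe the robustness of the
classic demographic models of skill transmission. It implements, side by
side:

- an **analytic skill-transmission model**: the Price-equation change in
  mean skill when learners copy the most skilled individual, under Gumbel,
  Logistic or Normal skill distributions, with critical population-size
  curves and their sensitivity to demographic change; and
- an **agent-based model** of vertical plus oblique transmission in which
  the mentor-selection rule is pluggable — copy-the-best, payoff-
  proportional, random copying, and two conformity variants — with sweep
  experiments that estimate the maximum sustainable skill complexity per
  population size.

## The model in brief

Each of `N` individuals carries a skill value `z_i`. The change in mean
skill across one generation is given by the Price equation
`Δz̄ = Cov(c, z)/c̄ + E(c·Δz)/c̄`, with `c_i` the likelihood that `i` is
copied. When everyone copies the best individual and skills follow a
Gumbel(mode `m`, scale `β`) distribution with a Gumbel(−`α`, `β`)
imitation error,

    Δz̄ = −α + β·(γ + ln N),        γ ≈ 0.5772 (Euler–Mascheroni)

so the maximum sustainable complexity is `α* = β(ln N + γ)`; analogous
forms hold for Logistic skills (`s·(ψ(N) + γ)`, digamma `ψ`) and Normal
skills (`σ·Φ⁻¹(0.5264^(1/N))`, the Chen–Tyler approximation of the largest
order statistic). The agent-based half replaces the copy-the-best
idealization with explicit vertical and oblique transmission under weaker
selection rules. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from cumculture import (
    ErrorSpec, SkillDistributionSpec, Strategy,
    critical_complexity, max_sustainable_alpha, run_henrich_mode,
)

# analytic critical complexity for N = 1000 Gumbel learners (beta = 1)
print(round(critical_complexity("gumbel", 1000), 3))
# expected imitation error of an easy skill (alpha = beta = 0.1)
print(round(ErrorSpec("gumbel", 0.1, 0.1).mean, 3))
# simulated mean one-generation skill change at N=100, alpha=3
traj = run_henrich_mode(
    100, ErrorSpec("gumbel", 3.0, 1.0),
    SkillDistributionSpec("gumbel", 0, 1), 10_000, np.random.default_rng(1),
)
print(round(float(np.diff(traj.mean_skill).mean()), 3))
# sweep-estimated sustainable complexity at N=100 under copy-the-best
print(max_sustainable_alpha(100, Strategy("best"), "gumbel", seed=1))
```

prints

```
7.485
-0.042
2.179
5.0
```

`7.485` is `ln 1000 + γ`, the largest transmission inaccuracy 1000
copy-the-best learners can sustain; `-0.042` is the mean imitation error of
a low-complexity skill; `2.179` is the simulated per-generation gain at
`N = 100, α = 3`, matching the closed form `−3 + γ + ln 100 ≈ 2.182`; and
`5.0` is the sweep's on-grid estimate of the critical complexity at
`N = 100` — within one grid step (0.2) of the analytic value `5.182`.

## Command line

```sh
cumculture analytic --family gumbel --scale 1 --n 2:5000 --sensitivity --out out/
cumculture abm --n 250 --alpha 1 --strategy payoff_proportional --seed 1 --out out/
cumculture sweep --preset reduced --seed 1 --out out/
cumculture reproduce critical-curves --out out/
```

Every output CSV is paired with a JSON manifest (full configuration,
master seed, per-cell substream seeds) from which the run can be reproduced
byte-for-byte.

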