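# Methods

## Model

An aggregate of p62 oligomers cross-linked by ubiquitinated cargo is reduced
to three counts: `i` one-hand bound cross-linkers, `j` both-hand bound
cross-linkers (the cross-links proper), and `k` oligomers of size `n ≥ 3`
(one ubiquitin-binding site per subunit).  The triplet carries no shape or
topology information; reaction rates are to be read as averages over the
aggregate geometries compatible with a triplet.  A triplet is admissible
when `k ≥ 2`, `j ≥ k − 1` (enough cross-links to be connected) and
`i + 2j ≤ nk` (binding sites are finite).

Six mass-action reactions act on the state (rates in the table in
`discrete.py`).  Two deserve comment:

- **Cross-link breaking** occurs at total rate `κ₋ j` and has two outcomes:
  with probability `α_{j,k} = (nk − 2j − n + 2)₊/((n−2)k + 4 − n)` the broken
  link was an oligomer's only connection and the oligomer detaches (with the
  whole aggregate lost when `k = 2`); otherwise the aggregate merely loosens.
  `α` interpolates linearly between 1 on a chain (`j = k − 1`) and 0 on a
  tightly connected aggregate (`nk − 2j ≤ n − 2`).
- **Detachment load**: the departing oligomer carries
  `ℓ = ⌊(n−1)i/(nk−2j)⌉` one-hand bound cross-linkers — the rounded expected
  share of `i` on the lost oligomer.  Ties (exact .5) round half-up; the
  choice is arbitrary but both tie rules keep `ℓ` within the admissibility
  bounds `(n−1−nk+i+2j)₊ ≤ ℓ ≤ min(i, n−1)`, which the test suite verifies
  by exhaustive enumeration.

Free cross-linkers and free oligomers are assumed abundant: `κ₁ = κ₁′[Ubi]`
and `κ₂ = κ₂′[p62ₙ]` are constant pseudo-first-order rates.  Scaling the
counts by a large typical size `k₀` (`p = i/k₀`, …, with `κ₃ = κ₃′k₀`)
yields the deterministic continuum system quoted in the README.  The
admissibility conditions become `s = nr − p − 2q ≥ 0` and `q ≥ r`, and both
are propagated by the flow, as are positivity and the a priori growth bounds
`p+q+r ≤ (p₀+q₀+r₀)e^{t·max(nκ₁, κ₂)}` and `r ≥ 2q/n ≥ (2q₀/n)e^{−κ₋t}`;
all are asserted along computed trajectories in the tests.

## Regimes

The parameter
`ᾱ = n/(n−2) + (κ₋₁ + κ₁ − √((κ₁+κ₋₁)² + 4κ₁κ₂(n−1)))/(κ₋(n−1))`
is the detachment probability evaluated at the candidate steady state.  The
classification — extinction for `ᾱ ≥ 1`, finite size with an explicit
steady state for `0 < ᾱ < 1`, unbounded growth for `ᾱ ≤ 0` — is a
conjecture supported here numerically (`classify_regime` reports a
*predicted* regime); the steady-state formulas, the equivalent explicit
inequalities on `κ₁κ₂`, and the quadratic-growth coefficients
(`p₁`, `q₂ = (n/2)r₂`, `s₁`) are exact closed forms.  `classify_regime`
computes the classification both from ᾱ and from the product inequalities
and raises if they ever disagree beyond the boundary tolerance (1e-9,
relative); exact-boundary parameter sets are flagged `boundary` and bucketed
with `ᾱ = 1 → extinction`, `ᾱ = 0 → growth`.

### The no-breaking limit

For `κ₋ = 0` the pair `(p, s)` closes into a planar system whose unique
positive equilibrium is the intersection of the two nullclines
`κ₁s = (κ₂+κ₋₁+κ₃s)p` and `((n−1)κ₂+κ₋₁)p = (κ₁+κ₃p)s`:

```
p∞ = (n−2)κ₁κ₂ / (κ₃(nκ₂ + 2κ₋₁)),    s∞ = (n−2)κ₂ / (2κ₃),
```

with linear growth `ṙ → κ₂p∞` and `q̇ → p∞(κ₂ + κ₃s∞)`.  (For unit rates
and `n = 5` this is `(p∞, s∞) = (3/7, 3/2)`; the package derives the
equilibrium from the nullclines rather than quoting a constant, and the
tests confirm it both algebraically and by long integration from distinct
initial states.)  Global attraction is monitored through the box Lyapunov
function `L(p, s) = a − 1`, where `a ≥ 1` is the unique scale putting
`(p, s)` on the boundary of `[p∞/a, ap∞] × [s∞/a, as∞]`; `L` is zero only
at the equilibrium and non-increasing along trajectories (tested with an
absolute slack of 1e-8 to absorb integrator noise once `a − 1` reaches the
tolerance floor).

## Numerics

- **Integration**: `scipy.integrate.solve_ivp` with LSODA, `rtol = 1e-8`,
  `atol = 1e-10` by default (both exposed).  The vector field is undefined
  at `r = 0` but extends continuously by zero on admissible states; the
  integrator stops with a `terminated_at_origin` flag once `r` falls below
  `ε = 1e-10` (extinction), avoiding the 0/0 region.
- **Constraint repair**: after integration, violations of
  `p, q, r, s, q−r ≥ 0` up to round-off (relative `1e-10`, or 100·rtol) are
  clipped onto the constraint surface; anything larger raises, since the
  constraints are propagated analytically and a real violation means the
  integrator was misused.  State construction itself validates strictly —
  only the integrator's repair path may project.
- **Quadratics** (critical breaking rate, `K_d` estimation) are solved in
  closed form with the cancellation-stable root
  `x = 2c/(b + √(b² + 4ac))`; tests cross-check against bisection on ᾱ.
- **Exponent fitting** is a least-squares slope of `log x` vs `log t` on
  the final decade of a `t = 10⁴` run (window configurable, must start at
  `t ≥ 10` to exclude the transient).  The growth-coefficient cross-check
  fits `p/t`, `q/t²`, `r/t²` at `t = 10⁴`; agreement is ~1% for breaking
  rates well inside the growth regime and degrades near the `ᾱ = 0`
  boundary, where the subleading corrections decay more slowly — the test
  sets sit at `κ₋ ∈ {0.1, 0.15, 0.2}` for unit binding rates.
- **SSA**: direct method — one exponential waiting time from the total
  propensity and one uniform draw per event — on a seeded
  `numpy.random.Generator`; ensembles spawn independent child streams from a
  single `SeedSequence`, so every run is reproducible from its seed.
  Ensemble summaries sample each path by last-event-before-t and scale by
  `k₀`.

## Discrete–continuum consistency and its one exception

The scaled ensemble mean of the SSA tracks the ODE solution with an error
that shrinks with `k₀` — with one deliberate exception.  The detachment
load `ℓ` is a *deterministically rounded* integer, while the continuum
drift uses the unrounded expectation `(n−1)p/((n−2)r)`.  The rounding
residual does not average out (all replicates round the same ratio the same
way), producing an `O(1)` drift bias in `p` — of order
`κ₋ α q · frac` per unit time, where `frac` is the rounding error of the
load ratio — that is independent of `k₀` and accumulates with the number of
detachment events.  `q` and `r` are unaffected (`ℓ` only moves `i`).
Consequently the mean-field comparison in the tests uses a short horizon
(`t ≤ 0.15`) and a growth-regime parameter set (breaking rate 0.2), where
the measured bias stays well inside three standard errors of a 500-replicate
ensemble; over long horizons the stochastic scheme equilibrates at a
slightly `p`-shifted composition by construction, and no choice of `k₀`
removes this.

## Parameters and reference values

| parameter | meaning | default / reference |
|---|---|---|
| `n` | oligomer size (binding sites per p62 oligomer) | 5 (reference experiments; ≥ 3 required) |
| `κ₁, κ₂` | Ubi / oligomer addition (per time) | 1 in the canonical sets |
| `κ₃` | compactification (continuum scale) | 1 |
| `κ₋₁` | one-hand unbinding | 1 |
| `κ₋` | cross-link breaking | 0.6 / 0.93 / 0.2 / 0 across the regimes |
| `K_d` | `κ₋₁/κ₁′` (µM) | 0.5 for the reference phase diagram |

Time is dimensionless throughout the kinetic core; only the bifurcation
module speaks µM, and there the overall time scale `κ₁′` cancels from every
regime boundary (ᾱ is 0-homogeneous in the four binding/unbinding rates),
so it is fixed to 1.  `κ₃` enters neither ᾱ nor the boundary curves.

The canonical parameter sets (all rates 1, `n = 5`, initial state
`(2, 4, 3)`, breaking rate as above) are shipped as regenerable fixtures
with their closed-form expectations: ᾱ ∈ {0.6366, 1.0021, −1.4235}, steady
state `(0.2553, 0.6683, 0.4326)`, growth coefficients
`(p₁, q₂, r₂) = (0.03704, 0.01816, 0.007264)`, and the `κ₋ = 0` limits
`(p∞, s∞) = (3/7, 3/2)`.

## What the generator and tests do and do not show

The synthetic inputs are parameter sets and admissible states spanning the
three regimes — they emulate the *conditions* of the model (abundant free
particles, a single aggregate, fixed oligomer size), not real measurement
noise, oligomer-size heterogeneity, nucleation, or coagulation of multiple
aggregates.  Passing tests therefore demonstrate internal correctness of
the scheme, its continuum limit and its closed forms, plus consistency with
the published onset-concentration estimates (`K_d` 0.44–0.73 µM /
0.20–0.31 µM); they do not validate the biological assumptions themselves.
Problem sizes used by the default suite: exhaustive state enumeration up to
`k = 6` for `n ∈ {3, 4, 5}`; ensembles of 200–500 replicates at
`k₀ ≤ 200`; 50–200 random parameter sets; integrations to `t = 10⁴`
(exponents) and adaptive horizons up to `5·10⁴` (fate checks).

## Known limitations

- The finite-size/extinction/growth trichotomy away from the closed forms
  rests on numerical corroboration of a conjecture, not proof.
- Free-particle depletion, nucleation, aggregate coagulation and
  fragmentation into multiple aggregates are out of scope; with depletion,
  unbounded growth would saturate.
- A distribution of oligomer sizes is not modelled; `n` is one number.
- The triplet description ignores aggregate geometry; all rates are
  mean-field in shape space.
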