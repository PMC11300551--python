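# Methods

## Model

The population state is the number of cooperators `i ∈ {0, …, N}` in a
well-mixed group of `N` players.  Per generation, an ordered pair
(imitator, role model) is drawn uniformly; the imitator adopts the model's
strategy with the Fermi probability `σ(β Δf) = (1 + e^{−β Δf})^{-1}`, where
`Δf` is the model-minus-imitator payoff difference and `β ≥ 0` the intensity
of selection.  Payoffs come from the Donation Game or the Public Goods Game,
whose defining property here is that the cooperator–defector gap
`δ = Π_C(i) − Π_D(i)` is independent of `i` and negative.  Within the
dilemma region (DG: `B > c > 0`; PGG: `1 < r < n ≤ N`) negativity is
automatic; parameterisations outside it are rejected unless `force=True`.

The institution pays the per-generation incentive `θ_j` of the README only
in states `1 ≤ j ≤ t`.  Inside the Fermi exponent the incentive appears as
the shift `θ_j / j` added to the cooperator–defector gap — the
per-cooperator outlay, identical to the per-capita effect `θ` for reward
with `a = 1`.  This is the `gap_convention="cost"` default.  For punishment
and mixed schemes one can argue the shift should instead be the per-capita
payoff effect `θ` (each punished defector loses `θ`); that reading is
exposed as `gap_convention="effect"`.  The default follows the transition
rule the analytical results are built on; the option exists because the two
conventions genuinely differ for non-reward schemes and users should be able
to compare them.

Without mutation the chain is absorbing at `S_0` and `S_N` and

    E(θ) = Σ_{j=1}^{N−1} w_j θ_j,   w_j = weights over fundamental-matrix rows,

with start conventions `equal` (½·(n_{1j} + n_{N−1,j})), `alldef` (n_{1j}),
and `weighted` (f_D n_{1j} + f_C n_{N−1,j}, `f_D = (1 + e^{x})^{-1}`,
`x = β(N−1)(δ+θ)`).  The weighted convention is implemented exactly in this
form; note its exponent uses `(N−1)(δ+θ)` while the thresholded fixation
ratio exponent is `(N−1)δ + tθ` — an asymmetry of the convention itself that
we reproduce rather than resolve.

### Cost under general mutation

With mutation rate `μ > 0` no state is absorbing, so "expected total cost"
needs a stopping rule.  We accumulate `θ` along the trajectory until the
first visit to a homogeneous state (`S_0` or `S_N`), strictly after leaving
the start when the start is itself homogeneous.  Operationally: make the
homogeneous states absorbing in the `μ > 0` transition matrix, take the
fundamental matrix of the transient block, and add the (free, since
`θ_0 = θ_N = 0` under the threshold gate) initial dwell for homogeneous
starts.  A literal `(I − U)^{-1}` over all `N + 1` states does not exist for
`μ > 0`; the cost-to-first-homogeneous-hit definition is the natural
generalisation consistent with the `μ → 0` limit (verified numerically: the
`μ → 0⁺` values converge to the absorbing-chain cost) and with Monte-Carlo
simulation of the same stopping rule.  The threshold gate `θ_j = 0` for
`j > t` is applied for `μ > 0` exactly as for `μ = 0`.

## Closed forms (t = 1, 2)

Because `δ` is constant, `I − U` factors as `diag{i(N−i)/N²}·W` with `W`
tridiagonal over the four logistic coefficients
`a = σ(β(δ+θ))`, `b = σ(βδ)`, `c = 1−a`, `d = 1−b`, and hence
`n_{ij} = (W^{-1})_{ij} · N²/(j(N−j))`.  (The diagonal factor must sit on
the *left* of `W`; the right-factored form is inconsistent with the
`1/(N−j)` weights and with direct inversion.)  Inverse entries of a
tridiagonal matrix satisfy second-order recurrences; the relevant sequence
is

    ŷ_0 = ŷ_1 = 1,   ŷ_j = ŷ_{j−1} − (bd) ŷ_{j−2},

with three interchangeable evaluators (recurrence; signed binomials
`(−1)^k C(j−k, k)` with exact integer coefficients; characteristic roots of
`x² − x + bd = 0`, valid for `bd ≤ 1/4` and routed back to the recurrence
within 1e-8 of the degenerate double root).  The convention `ŷ_{−1} = 0`
extends every formula down to `N = 2`.  Indexing follows `ŷ_j = y_{N−j}`,
so the `t = 1` cost uses `y₂ = ŷ_{N−2}`, `y₃ = ŷ_{N−3}`:

    E_r(θ) | equal  = N²θ/(2(N−1)) · (1 + d^{N−2}/y₂) / (1 − ad·y₃/y₂)
    E_r(θ) | alldef = N²θ/(N−1) · 1/(1 − ad·y₃/y₂)

(the `(W^{-1})_{1,1}` factor is the *reciprocal* `1/(1 − ad y₃/y₂)`), and
for `t = 2` the four entries `(W^{-1})_{1,1}, (W^{-1})_{N−1,1},
(W^{-1})_{1,2}, (W^{-1})_{N−1,2}` with the modified pivot
`y₂ = ŷ_{N−3} − ad·ŷ_{N−4}`.  Both all-defector cost formulas carry the
`N²θ_j/(j(N−j))` state weights throughout.  The closed forms require a
state-independent gap shift over `j ≤ t` (reward with any `a`; any scheme at
`t = 1`); other cases are served by the matrix path, and `t = 2` at `N = 3`
(the full-invest case, different matrix structure) is routed there with a
warning.

The θ-derivative of the `t = 1` cost,

    E_r'(θ) = N²/(2(N−1)) (y₂ + d^{N−2}) / (y₂ − ad y₃) ·
              [1 + θ d y₃ β e^{−β(δ+θ)} a² / (y₂ − ad y₃)]

(equal start; drop the `d^{N−2}` reflection and the ½ for the all-defector
start), is strictly positive — the basis for solving
`min_{θ ≥ θ₀} E(θ) = E(θ₀)` analytically at `t = 1`.  "Monotone" here means
`E_r' > 0` (increasing cost), not convexity.

### Asymptotic limits

Neutral drift (`β → 0`): with `P(N) = ŷ_{N−2}(1/4)` and
`Q(N) = ŷ_{N−3}(1/4)` evaluated in exact rational arithmetic (the
alternating binomial sums lose precision in floating point for `N ≳ 25`),

    equal:  N²θ/(N−1) · (P + 2^{−(N−2)}) · 2/(4P − Q)
    alldef: N²θ/(N−1) · 4P/(4P − Q).

Strong selection (`β → ∞`), identical for both starts: `+∞` if `δ+θ > 0`
(the incentive overturns the drift at the paid state, which is then
revisited endlessly), `2N²θ/(N−1)` on the knife edge `δ+θ = 0`, and
`N²θ/(N−1)` if `δ+θ < 0`.

## Cooperation frequency and optimisation

In the small-mutation limit the population hops between homogeneous states
via fixation events; the cooperation frequency is
`ρ_DC/(ρ_DC + ρ_CD)`.  Fixation probabilities are computed from the product
form `(1 + Σ_i Π_{k≤i} u_{k,k−1}/u_{k,k+1})^{-1}` entirely in log space
(softplus differences, logsumexp), which telescopes analytically to
`ρ_DC/ρ_CD = e^{β[(N−1)δ + tθ]}`; the implementation keeps the two routes
separate so the identity is a genuine cross-check.  Inverting the logistic
frequency gives `θ₀(ω) = (log(ω/(1−ω))/β − (N−1)δ)/t`.  Negative `θ₀`
(attainable targets below ½) is reported but clamped to 0 as a minimiser —
negative rewards are outside the model.  For thresholds other than `t = 1`
monotonicity of `E(θ)` is only conjectured below a critical threshold, so
`optimise_cost` falls back to a deterministic 2001-point grid on
`[max(θ₀,0), θ₀ + 10|δ|(N−1)/t]` with bounded local refinement.

## Numerical choices

- **Stable logistic** evaluated piecewise; no overflow or NaN up to
  `|β·gap| = 1e4` (saturates to 0/1).
- **Banded solves** (`scipy.linalg.solve_banded`) for the fundamental
  matrix; explicit inverses appear only in tests.
- **Precision auto-switch**: `1 − ad`-type denominators cancel
  catastrophically under strong selection; for `t = 2` two such denominators
  compound.  Whenever `β(|δ| + |δ+θ|) > 10`, both the closed forms and the
  matrix route recompute in mpmath with working precision
  `40 + β(|δ| + |δ+θ|)/2` digits.  This keeps the two routes within ~1e-9
  of each other over the full grid (worst observed ≈ 4e-10) and resolves
  `β = 50` costs to the strong-selection limits at 1e-6.
- **Exact integers/rationals** for the `ŷ` coefficient table and the
  neutral-drift limits (`fractions.Fraction`); floats only at the final cast.
- **Degenerate cases**: `bd = 1/4` (repeated characteristic root) routes to
  the recurrence; zero recurrence pivots in the generic tridiagonal-inverse
  raise a named error; a non-absorbing transient system raises instead of
  returning NaN.

## Monte-Carlo oracle

Trajectories are sampled from the exact one-step probabilities (so the
simulator validates the cost definitions, not the chain construction) in
fixed batches of 10 000 replicates, each batch on its own Philox stream
spawned from the run seed.  Results are bit-reproducible for a given seed,
and two runs over disjoint batch ranges (`replicate_offset`) merge exactly
into the combined statistics — the practical replicate-splitting invariance
on a single CPU.  A max-steps guard (default 1e7 sweep iterations) reports
truncated trajectories rather than hiding them.  The generator emulates the
model exactly; what it cannot tell you is anything about real behavioural
data — passing Monte-Carlo checks certifies the analytic machinery, not the
model's empirical adequacy.

Problem sizes used in the validation suite: populations `N ≤ 12` for
analytic grids, a 64-cell Monte-Carlo grid (`N ∈ {4,6}`, `t ∈ {1,2}`,
`β ∈ {0.1,1}`, reward `θ ∈ {0.5,2}`, punishment `θ ∈ {0.25,0.75}`, both
start conventions) at 200 000 replicates per cell.  The punishment θ values
are smaller because the printed gap-shift convention makes large punishment
incentives metastable at `j = 1` (expected absorption times of thousands of
generations), which is scientifically interesting but a poor Monte-Carlo
validation cell.

## Limitations

- Closed forms cover `t ∈ {1, 2}` (and, from prior art, `t = N−1`); the
  matrix path covers all thresholds numerically but offers no monotonicity
  guarantee for `2 < t < N−1`.
- The critical threshold `t*` below which the cost stays monotone for all
  `β` is explored numerically only (at `N = 4` it is `N−1`).
- Games whose payoff gap depends on the state (snowdrift, general
  prisoner's dilemma, collective-risk) are out of scope — the tridiagonal
  factorisation breaks without a constant `δ`.
- Well-mixed populations only; no structure, no simultaneous mutations.
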