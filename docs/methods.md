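# Methods

## Scope and modelling assumptions

The package treats a gene regulatory network as a set of protein
concentrations `s` (molecules/cell) obeying linear rate laws
`ds/dt = A(t)·s + B·u(t)`, obtained by linearizing Hill-function production
kinetics. The linearization is two-section and piecewise: on
`0 ≤ x* ≤ 2K` the Hill curve is replaced by the chord through the origin
and `(2K, Fmax)` (slope `Fmax/2K`); above `2K` production saturates at
`Fmax`. The approximation is exact at `x* = 0` and at the threshold, and
worst near `K`, where the chord overshoots the Hill curve by up to
`Fmax·(1/2 − 1/(1+2ⁿ)·2ⁿ/…)` depending on the Hill coefficient; the
analyses in this package all operate in the sub-threshold regime, where the
dynamics are genuinely linear. Repression mirrors activation: a descending
line from `Fmax` at zero repressor, floored at the basal rate (a negative
production rate is unphysical). Signal-dependent activation of a
transcription factor enters as a multiplicative Hill factor in `[0, 1]`
applied to the total TF concentration. The repressor-signal and
repressor-TF linear forms are reconstructed from the stated mirror symmetry
with the activator forms; they are not independently sourced.

Units are molecules/cell for concentrations and per-minute for rates
throughout — a documentation convention, not enforced by types.

Multi-input promoters are additive/subtractive: each incoming edge
contributes `±F·(source concentration)` to the target's production.
Cooperativity, AND-logic and mutual exclusion are out of scope. Linear
models can transiently go negative; trajectories are reported as-is with a
flag, never clamped, because clamping would break superposition and the
eigen-expansion checks.

## Transfer-function algebra

`RationalTF` stores real polynomial coefficients, descending degree, monic
denominator; roots come from the companion matrix (`numpy.roots`). The four
reduction rules are cascade (product), parallel (sum), feedback closure
`G/(1 ± GH)` and autoregulation collapse `1/(s + D ± H)`.

`reduce_network` reduces an arbitrary wiring by signal-flow node
elimination: each gene's first-order block is absorbed into its incoming
edge gains, self-loops are closed first (the autoregulation/feedback rule),
and intermediate genes are then removed one at a time by splicing incoming
into outgoing branches (cascade), summing parallel contributions. Every
elimination step is one of the four rules, and nested loops close
innermost-first as their interior nodes disappear. Internally the gains are
kept in *factored* form (gain, zero list, pole list): structurally shared
factors are cancelled by pairwise matching (tolerance `1e-8`, relative to
the root magnitude) instead of re-finding roots of summed coefficient
polynomials, which would be catastrophically ill-conditioned once factors
repeat. The returned transfer function is minimal for all shipped
topologies and matches the numeric resolvent `C(sI−A)⁻¹B` to machine
precision (the test suite checks 20 random points on the imaginary axis per
topology at 1e-9 relative).

Stability is classified from the poles with an axis tolerance: a pole is
"on the imaginary axis" when `|Re| < 1e-9·max(1, |Im|)` — needed because
the roots of `s² + b` carry floating-point fuzz. Simple axis poles give
`marginally_stable`; repeated axis poles or any right-half-plane pole give
`unstable`.

Steady-state errors of the two-gene loop under basal downstream production
come from the final value theorem applied to the loop error
`e(t) = F_step − F_ZY·z(t)`: a signal component `F_step/(1 + L(0))` and a
basal component `−F_ZY·F_0Z/D_Z/(1 + L(0))`, with DC loop gain
`L(0) = F_YZ F_ZY/(D_Y D_Z)`. The theorem is refused when the closed loop
is not asymptotically stable.

## Response specifications

First-order: time constant `1/D`, rise time `2.2/D`, settling time `4/D`.
The `4/D` figure is the engineering approximation; the object also reports
the exact 2%-band entry `−ln(0.02)/D = 3.912/D`, and the tests verify both
against crossing times measured on the closed form.

Second-order `gain/(s² + a·s + b)`: `ωₙ = √b`, `ζ = a/(2√b)`, damped
frequency `ω_d = ωₙ√(1−ζ²)`; peak time `π/ω_d`, percent overshoot
`100·exp(−ζπ/√(1−ζ²))` and settling time `4/(ζωₙ)` for the underdamped
class. These underdamped relations are the standard textbook second-order
results. `|a| < 1e-6·√b` counts as undamped ("close to zero" damping);
the threshold is configurable.

The two-gene oscillator (positive autoregulation `F1` on the activator
gene, cross activation `F2`, negative autoregulation `F3` on the repressor
gene, cross repression `F4`) has damping `a = D1 + D2 − F1 + F3` and
constant term `b = (D1−F1)(D2+F3) + F2·F4`. The only negative contribution
to `a` is the positive-autoregulation strength — which is why positive
autoregulation is required for an undamped oscillation — and the negative
terms of `b` (`−F1·D2`, `−F1·F3`) are the instability risks. Deleting the
negative autoregulation (`F3 = 0`) leaves `F4` only in the positive term
`F2·F4`, making the frequency monotone in `F4`. This parameter-role
assignment is the one consistent with both the deletion variant and the
sign structure of `b`; the source material's notation is internally
inconsistent on whether the damping's positive term is written `F2` or
`F3`, and the package follows the self-consistent algebra.

`step_response_numeric` converts the transfer function to
controllable-canonical state-space and steps it with an exact zero-order-
hold discretization (matrix exponential per grid interval). This
reproduces the first-order closed form to float precision and conserves
undamped oscillation amplitude exactly, which a forward-Euler integrator
cannot do at any practical step size; forward Euler remains the integrator
of `statespace.simulate`, mirroring the discretization the estimation
pipeline is built on.

Dominant poles are the pair with *greatest* real part — the slowest-
decaying, behavior-governing pair. (Descriptions of this pair as having the
"least real values" occur in the literature; the crossing behavior it is
used to track makes clear that greatest real part is meant.)

## State-space simulation

Forward Euler `s_{k+1} = s_k + h·(A s_k + B u_k)` with default `h = 0.1`
min and a warning when `h` exceeds the stability bound `2/max|Re λ|` for
constant `A`. Time-varying `A(t)` and `u(t)` are supported via callables.
The convergence tests confirm first-order accuracy by step halving, and a
two-state trajectory is checked against the eigen-mode expansion
`C₁e^{λ₁t}φ₁ + C₂e^{λ₂t}φ₂ + s_eq` with the constants fitted from the
initial condition.

## Estimation

With constant `F`, `D`, zero basal rate and `y₁ = 0`, the Euler recursion
unrolls to `y = Hx` with lower-triangular `H[k,j] = hF(1−hD)^{k−j}`
(`j ≤ k`), mapping the regulator history `x₁…x_n` to the downstream series
`y₂…y_{n+1}`; `H` is full-rank with diagonal `hF`. Batch weighted least
squares is `(HᵀΣ⁻¹H)⁻¹HᵀΣ⁻¹y`. The recursive estimator processes one row
at a time with gain `K = PHᵀ(HPHᵀ + R)⁻¹` and the Joseph-form covariance
update `(I−KH)P(I−KH)ᵀ + KRKᵀ`, which preserves symmetry and positive
semi-definiteness over long runs; it reproduces the batch solution with the
matching prior exactly (asserted at 1e-8), and approaches the
unregularized batch answer as the prior covariance is widened — exact
agreement there is limited by float64 conditioning, not by the algebra.

The Kalman filter runs on the exact joint model of the simulated scenario:
state `(x_k, y_k)`, transition `[[1, 0], [hF, 1−hD]]`, process noise only
in the x row, measurement `y_k` plus extrinsic noise. The regulator carries
a random-walk prior with per-step variance `Q = x_sd² = 100`
(molecules/cell)²; `Q` is exposed as a parameter since no canonical value
exists for it. Intrinsic regulator noise enters through `Q`, extrinsic
measurement noise through `R = y_sd²`; the two are deliberately kept in
separate covariances. Defaults follow the simulation conventions:
`D = 0.01/min`, `F = 0.05/min` (mid-range of 0.01–0.1), `h = 1` min so
that `hD = 0.01 ≪ 1`, `x̄ = 200`, `x_sd = 10`, `y_sd = 9`. The baseline
the filter is judged against is per-step inversion of the recursion,
`(y_{k+1} − (1−hD)y_k)/(hF)`, which is unbiased but amplifies noise by
`1/(hF)`.

## Synthetic data and case-study fixtures

`generate_noisy_x` draws i.i.d. Gaussian fluctuation around a constant
mean; `generate_y_from_x` propagates it through the Euler recursion and
adds extrinsic Gaussian noise from an independent stream spawned from the
same seed. These generators emulate steady-state expression with white
noise only: no transcriptional bursting, no cell-cycle dilution ramps, no
temporally correlated extrinsic fluctuations. Passing tests therefore
demonstrate correctness of the linear-Gaussian machinery, not robustness to
real measurement artifacts.

Eight case studies ship as JSON files under `grncontrol/data/`, each with
machine-checkable predicates evaluated in the test suite. Default rates
follow the simulation conventions (`D = 0.01/min`, strengths in
0.01–0.1/min, inputs in 100–1000 molecules/cell); basal rates are zero in
the fixtures whose published behaviors assume negligible basal activity.
Where a wiring is only shown graphically in the source material, the
fixture encodes a documented canonical choice:

* **irma4** — four-gene analog of the IRMA yeast benchmark
  (CBF1→GAL4→SWI5→ASH1⊣CBF1 with SWI5⊣CBF1 replaced by a repressive
  SWI5→CBF1 edge and a positive SWI5 self-loop). No parameter values are
  published for the linear analog; the fixture uses `D = 0.04/min` on all
  four genes and strengths 0.01–0.02 so that the nominal circuit is stable
  and a common scaling of (CBF1→GAL4, SWI5→SWI5, SWI5→ASH1, ASH1→CBF1) by
  ~4.4× carries the dominant pole pair monotonically across the imaginary
  axis within the 1–10× scan — the qualitative behavior the case study
  demonstrates. Both feedback cycles are negative, so the crossing pair is
  oscillatory.
* **ffl_cascade** — two stages in cascade, each an incoherent type-1 FFL
  (direct activation plus delayed repression → pulse) and a coherent
  type-1 FFL (direct plus delayed activation → delay) sharing one
  intermediate regulator per stage. Production constants are chosen inside
  the standard range so that the pulse predicate (maximum > 1.2× final
  value, threshold configurable) and the half-rise ordering C1 < C2 < C3
  hold.
* **six_node** — genes A–F with the coherent FFL A→B, A→C, B→C embedded and
  a downstream activation chain C→D→E→F; gene A is driven by an external
  input X.
* **oscillator** — the two-gene tunable oscillator with `F2 = F3 = 0.02`,
  so the undamped condition `F1 = D1 + D2 + F2` holds under either reading
  of the notation discussed above; `F1 = 0.04` satisfies it exactly.

## Problem sizes and numerical defaults

The shipped analyses use networks of 1–6 genes, simulations of up to
15 000 Euler steps (1500 min at `h = 0.1`), and estimation runs of 1000
steps replicated over 50 seeds; the acceptance script reports the
50-seed average. Root-matching tolerance in the reduction is `1e-8`
relative; exact common-factor cancellation after feedback closure uses
`1e-9`; equilibrium residuals are verified below `1e-9` relative.

## Known limitations

* The linearization is only as good as the sub-threshold assumption; no
  warning is emitted when simulated concentrations exceed `2K` because the
  network specification does not carry the Hill thresholds.
* `reduce_network` returns the transfer function between one designated
  input and one output; multi-input analyses require one reduction per
  input (superposition makes this exact).
* The Kalman filter assumes known `F`, `D`, and noise levels; estimating
  them from data is out of scope.
* Discrete-time transfer functions, Bode/Nyquist analysis and stochastic
  differential equations are not implemented.
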