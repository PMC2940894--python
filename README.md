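# grncontrol

Linear control-theory modelling of gene regulatory networks, for systems and
synthetic biologists who want quick, interpretable answers about circuit
dynamics — response speed, stability, oscillation, steady-state error — and
for anyone estimating an upstream regulator from noisy downstream expression
measurements.

## The model

A simply regulated gene obeys `dy/dt = F(t) − d(t)·y(t)`, production minus
degradation/dilution. Hill-function production kinetics

    F(x*) = F0 + Fmax · x*ⁿ / (Kⁿ + x*ⁿ)

are replaced by a two-section piecewise linearization: a line through the
origin and `(2K, Fmax)` (slope `F₂ = Fmax/2K`), clamped at `Fmax` beyond the
threshold `2K`. Below threshold each gene becomes the first-order linear
block

    G(s) = 1 / (s + D)

with a single pole at `−D`. Networks of such blocks are then:

* **reduced** by block-diagram algebra — cascade (product), parallel (sum),
  feedback `G/(1 ± GH)`, and autoregulation folding a self-loop of strength
  `H` into an effective degradation `D′ = D + H` (negative autoregulation)
  or `D″ = D − H` (positive) — to a single rational transfer function whose
  poles decide stability and whose second-order form gives the natural
  frequency `ωₙ = √b` and damping ratio `ζ = a/(2√b)`;
* **simulated** as linear state-space models `ds/dt = A·s + B·u` (forward
  Euler, time-varying coefficients allowed), with eigenvalues of `A` playing
  the role of the poles and equilibria from `A·s + B·u = 0`;
* **inverted** statistically: the Euler recursion
  `y_{k+1} = (1−hD)·y_k + hF·x_k` makes the regulator history a linear
  least-squares problem, solved in batch, recursively, or — for a
  fluctuating regulator — with the discrete-time Kalman filter.

## Worked example

Analyze the two-gene negative feedback loop (X→Y→Z, Z⊣Y; all rates in the
shipped fixture: `d_y = d_z = 0.01/min`, `f_yz = 0.04`, `f_zy = 0.01`,
drive 10 molecules/min):

```sh
grncontrol fixtures emit negative_feedback --out nets
grncontrol analyze --network nets/negative_feedback.json --out results
```

prints

```json
{"stability": "stable", "poles": [[-0.01, -0.02], [-0.01, 0.02]]}
```

— a complex pole pair at `−0.01 ± 0.02i` per minute: the loop is stable but
underdamped, so both proteins approach their steady state through damped
oscillations (`ωₙ = √(d_y d_z + f_yz f_zy) = 0.0224/min`, `ζ = 0.447`).
Simulating from 400 molecules/cell of each protein,

```sh
grncontrol simulate --network nets/negative_feedback.json --initial 400,400 --out results
# {"final": {"Y": 199.99995, "Z": 799.999854}}
```

the trajectory spirals into the unique equilibrium (200, 800), the same
point `equilibrium()` returns from the linear solve.

Estimating a fluctuating regulator (x = 200 ± 10 molecules/cell, extrinsic
measurement noise sd 9, `F = 0.05/min`, `D = 0.01/min`, 1000 one-minute
steps):

```sh
grncontrol kalman --seed 1 --out results
# {"mean_estimate": 199.4177530814024, "filter_mse": 286.3154577973803,
#  "naive_inversion_mse": 59770.98304225528}
```

The filter's time-averaged estimate sits within 0.3% of the true mean, and
its mean squared error is ~200× smaller than per-step inversion of the
recursion, which amplifies measurement noise by `1/(hF)`.

The same objects are available from Python:

```python
from grncontrol import build_negative_feedback, eigen_analysis, equilibrium

model = build_negative_feedback(d_y=0.01, d_z=0.01, f_yz=0.04, f_zy=0.01, drive=10.0)
eigen_analysis(model).verdict      # 'underdamped oscillation, stable'
equilibrium(model).as_dict()       # {'y': 200.0, 'z': 800.0}
```

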