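# Methods

This note documents the models, the clamping protocol, the parameter
choices, and the known limitations of the `criticality` package.

## The method in one paragraph

Criticality Analysis (CA) represents a tabular data sample as the stable
orbit (or steady state) that a network of chaos-controlled nonlinear
oscillators settles into when the sample's attribute values are held
("clamped") as constant perturbations at the network's inputs.  Because
the controlled system is deterministic, the same sample always selects the
same orbit, and similar samples select nearby orbits; summarising each
orbit by a few numbers (the maxima of the network's total signals, a
median frequency) yields a low-dimensional nonlinear embedding on which an
ordinary classifier can operate.  The representation itself requires no
training.

## Rate Control of Chaos

Each oscillator is stabilised by Rate Control of Chaos (RCC): selected
reaction-rate terms are multiplied by control factors

    q(v)   = v / (v + mu),               (saturating quotient, in [0, 1))
    sigma  = f_scale * exp(xi * q),      (control factor, xi < 0)

which leave the locations of equilibria untouched (sigma multiplies rate
*terms*, not states) while compressing the local rate landscape enough
that the system leaves its chaotic regime and settles into a periodic
orbit or fixed point.  Setting `xi = 0` recovers the uncontrolled system
(`BerryParams.without_control()`).

Quotients have concentration semantics: a small negative transient in a
state variable is clamped to zero *for the quotient only*; the raw state
is never clipped.  A state excursion below -1e3 (Berry) or beyond |1e12|
(both models) aborts the run with a `NumericalBlowUp` diagnostic carrying
the sample index.

## The Berry bienzymatic oscillator

Four variables: extracellular matrix `m`, soluble filaments `f`,
proteinase `p`, transglutaminase `g`.  Proteinase degrades matrix into
filaments, transglutaminase reassembles filaments into matrix, both enzyme
pools are produced under Hill kinetics in `f` (exponents 4) with RCC
control (`mu_f = 2`, `xi_p = xi_g = -3`) on the production terms, and
matrix is produced at the drive rate `rim` — the bifurcation parameter.
All kinetic constants are the published operating point (see
`BerryParams`); `ka` is stored as the printed numeric value 0.0455, since
the printed defining product of `kdeg` and `Kdeg` (0.055) contradicts the
printed number and the quotient (~0.04545) matches it.

Measured behaviour of this implementation (single oscillator, RK4,
h = 0.1, from (1, 1, 1, 1)):

* `rim` below ~0.008: stable fixed point.
* `rim` ~ 0.008–0.016: slow, large-amplitude relaxation oscillations with
  irregular peak heights; the uncontrolled (`xi = 0`) model has a small
  positive largest Lyapunov exponent here (up to ~1.2e-4 per time unit at
  `rim = 0.014`, Benettin estimate over 3e6 steps).  The controlled model
  at the same drive estimates at or below zero.
* `rim` ~ 0.02–0.03: stable limit cycles (periods ~1000–2000 time units).
* `rim` ~ 0.03–0.15: stable focus; trajectories spiral in with decay
  rates of order 1e-3 per time unit.  The focus location moves smoothly
  with `rim` — this is the input-to-state map the representation exploits.
* `rim` sustained above ~0.17: the proteinase consumption term saturates
  and `m` grows without bound (detected as blow-up).  This is the
  "too-strong input destabilises the network" boundary.

## The Wu 4-D hyperchaotic model

A four-variable Lorenz extension (`x, y, z, w`) with quadratic
cross-terms, an extra feedback loop `w`, and RCC factors on the quadratic
terms; external input enters as `rho = rho_gain * eps` (default gain
-100) in the `w` equation.  Parameters are stored exactly as published;
`r = -600` is kept as an inert configuration field because it does not
appear in the vector field as used here.

**Known limitation.**  Under these constants the controlled system has no
stable equilibria: every equilibrium reachable for `eps` in [0.5, 8] has
a real Jacobian eigenvalue of order +10^2, driven by the positive
feedback between the `e*sigma_x*y*z` term and the `sigma_z*x*y` term,
which the bounded control factors (at these `mu` scales) cannot cancel.
Long integrations at stable step sizes (h <= 1e-4) drift along a slow ray
(`y -> 0+`, `z` pinned, `x` and `w` growing linearly) instead of
converging, and at h = 0.1 the integration overflows within a few steps
(the Jacobian norm far exceeds 1/h).  The steady-state representation
this model is meant to provide is therefore not reachable with these
constants; the corresponding end-to-end test is expected to fail and the
acceptance script reports the honestly computed terminal derivative norm.
All Wu machinery (diffusive coupling, kernels, steady-state features) is
implemented and verified mechanically against the reference vector field.

## Networks and the clamping protocol

* **Berry coupling** (matrix-mediated, no self-connections):
  `rim_i = sum_{k != i} w[k, i] * m_k + eps_i`, where `w[k, i]` feeds
  oscillator `i` from source `k`.  Weights are uniform, an explicit
  matrix, or clipped-normal random draws (seeded).
* **Wu coupling** (diffusive, self term included): a single weight vector
  gives every oscillator the same `D_v = sum_k w_k * v_k` added to each
  equation.
* **Protocol**: rows are statically scaled, presented in a seeded shuffled
  order, and each row is clamped for `steps_per_sample` fixed RK4 (or
  fixed-step Fehlberg) steps of size `step_size`; the network state
  carries over between samples (no reset).  A reset-per-sample mode exists
  for experiments that need the representation to be a pure function of
  the row.
* **Cadence**: states are recorded every `record_stride` steps (default
  10); Hebbian weight updates and dynamic normalisation are re-evaluated
  on the same recorded-grid cadence, which keeps learning cost independent
  of the step size and makes runs bit-reproducible.
* **Features**: after discarding the leading `transient_fraction`
  (default 0.5) of each window, the per-sample summary is the maximum of
  the total F and total M signals (sums over the reservoir oscillators),
  the median frequency of total F (cumulative-periodogram estimator;
  a peak-interval estimator is available), per-unit maxima when readout
  units are present, and the terminal totals with a convergence flag for
  steady-state regimes.

Maxima are computed on the recorded grid, a resolution limit of
`record_stride * step_size` time units.

## Dynamic Hebbian learning and readout units

The learned weight is a closed-form function of the two filament
quotients, `w_ij = theta * exp(alpha * q_i * q_j) * sgn(q_j - q_i)` with
`sgn(0) = 0` — an assignment, not an increment — so the weight matrix is
antisymmetric at every instant and bounded by `theta * max(1, e^alpha)`.
Negative learned weights enter the coupling sums as-is.

The published typical gain `theta = 1` produces O(1) weights, three
orders of magnitude above the fixed-coupling scale of these networks;
the network survives (the antisymmetric signs largely cancel) but the
input-driven structure of the representation is destroyed.  Network-level
examples in this package therefore use `theta = 0.01`, which leaves the
learned weights in the same regime as the fixed couplings they replace;
the rule itself is tested at the published defaults.

Readout units are ordinary Berry oscillators driven by the reservoir
totals: `rim_7 = phi_7 * (sum_k w_k * F + m_8)` and symmetrically for
unit 8, with the readout connections maintained by the Hebbian rule
(`alpha = -3`, `theta = 3`, `phi = 0.00015`).  The partner's matrix value
is scaled by `phi` along with the weighted total: taken bare, the two
readouts obey `d(m7 + m8)/dt >= m7 + m8` once the reservoir is active
(the sustainable drive of a Berry unit is capped near ~0.2 by proteinase
consumption, while `m` is O(1)–O(10)) and diverge exponentially — the
scaled form is the only bounded reading.  A `per_unit` mode weights each
unit's own `f`/`m` instead of the total.

## Dynamic normalisation

The effective input is `f_eps * exp(theta_eps * q_eps * q_i) * eps` with
`q_eps = eps / (eps + mu_eps)`; `mu_eps` is frozen per attribute as the
dataset maximum at load time and recorded in the run metadata.  With
`theta_eps <= 0` the effective input never exceeds `f_eps * eps` and
shrinks both with the attribute's own saturation and with the receiving
oscillator's filament level, so attributes two orders of magnitude apart
are compressed onto comparable effective ranges and a constant input
becomes a dynamic drive.  Attributes with negative values are shifted by
their minimum before scaling (recorded in metadata).  The triple-product
exponent is implemented exactly as defined.  Normalisation is undefined
for Wu networks (no filament quotient) and rejected at configuration.

## Synthetic study conditions

The generator (`make_blobs`) emulates small positive tabular benchmarks
of the Iris type: `n_classes` Gaussian blobs with unit within-class
standard deviation whose centroids are spaced `separation` standard
deviations apart **along the positive diagonal**, so classes are ordered
by overall attribute magnitude the way Iris species are ordered by flower
size.  This is deliberate: the CA amplitude features respond to the total
drive a sample delivers, so class structure that lives only in the
*direction* of the attribute vector (equal-magnitude classes) is invisible
to them — a measured property of the method, not of the generator.
Attributes are shifted nonnegative; everything is seeded.

Defaults for the end-to-end experiments, chosen once (the input scalar is
the experimentally-tuned quantity of this method, exactly as for the
original datasets):

| quantity | value | why |
| --- | --- | --- |
| classes x per-class x attributes | 3 x 40 x 4 | Iris-sized table |
| separation | 6 sd | well-separated but overlapping tails |
| input scalar | 0.0075 | puts per-unit drives at ~0.02–0.1, inside the controlled focus/orbit domain; 0.02 reaches the runaway boundary |
| network | 4 Berry units, uniform w = 0.0005 | published small-network configuration |
| clamp | 10,000 steps of h = 0.1 | ~2–10 natural periods; keeps a 120-sample run near 10 s |
| transient fraction | 0.5 | conservative settling margin |

With these conditions the method's central claims hold in this
implementation:
repeated samples reproduce their (max_F, max_M) to well under 1% once the
network is running; 5-NN accuracy on (max_F, max_M) is ~0.95; and the
per-sample max_M of the 4-unit and 64-unit configurations (inputs to the
first four units, coupling reduced to 5e-5) rank-correlate above 0.99
when each sample's response is measured from a common reset state.  The
carry-over protocol at the published Iris scalars instead places the
network in a slow excitable charge-discharge cycle (period ~10^4 time
units, about two 50,000-step windows) whose phase dominates window
maxima; this regime is documented as a limitation of the amplitude
features rather than hidden by the defaults.

What passing these tests does **not** show about real data: the generator
has no attribute correlations, no heavy tails, no measurement noise, no
class-conditional covariance structure, and its classes are linearly
separable in the raw space; CA's value on such data must be judged on the
real datasets themselves.

## Numerical choices

* Fixed-step integration only (classical RK4 default; 5th-order solution
  of the Fehlberg 4(5) tableau as the alternative).  Determinism of the
  representation requires that the step sequence never depend on the
  trajectory.
* The production path runs numba-compiled kernels; a pure-Python
  reference path (generic integrator over the model vector fields) is
  kept and the test suite asserts bit-level (1e-12) agreement between the
  two on short runs, for both integrators and both models.
* Lyapunov exponents use the Benettin two-trajectory method
  (renormalisation every 10 steps, separation 1e-7) with long horizons
  (3e6 steps) because the exponents in the chaotic window are O(1e-4) per
  time unit and shorter estimates are noise-dominated.
* Median frequency: mean-removed cumulative periodogram; the first
  frequency bin at which cumulative power reaches half the total.
  Constant (converged) windows have no defined frequency and yield NaN
  with the `converged` flag set.
* Convergence flag: last-quartile range below 1e-6 of the mean level.
* Ties in `sgn` at exactly equal quotients give weight 0 (the only choice
  keeping the rule antisymmetric and continuous-in-measure).

## Reproducibility

Every source of randomness (connectivity draws, presentation order,
synthetic data) flows from named integer seeds recorded in the run
metadata and HDF5 output; a run is reproducible bit-for-bit from its
`RunConfig` alone on the same platform.
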