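# Methods

## Model overview

The package simulates the integration of adult-born granule cells (DGCs)
into the dentate gyrus, modelled as a competitive circuit: `N_DGC` granule
cells receive excitatory feedforward input from `N_EC` entorhinal-cortex
cells and recurrent inhibition from `N_I` interneurons.  Input patterns are
non-negative and L2-normalized (feedforward inhibition is modelled as
divisive normalization of the input).  Rates are unit-free with 1
corresponding to 10 Hz.

Two network variants are implemented:

* **Biologically plausible network** (`neurogen.network`, `protocols`):
  graded rates through a rectified-tanh transfer, explicit interneurons with
  a rectified-linear transfer and a subtractive sparsity term `p* N_DGC`.
* **Simplified network** (`neurogen.simple`): one binary (Heaviside) unit
  per cluster with implicit all-to-all inhibition `w_rec < 0`.  This variant
  admits closed-form analysis and carries all quantitative benchmarks.

Both share the plasticity rule (`neurogen.plasticity`): a rate-threshold
Hebbian pair (LTP above the postsynaptic threshold `theta`, LTD below) plus
a heterosynaptic depression term `-beta w [nu-theta]+ nu^3` that bounds the
weight norm.  Under a frozen winning set the weight row converges to
`(gamma/beta) <G1(nu) x> / <G2(nu)>` with `G1 = (nu-theta) nu`,
`G2 = (nu-theta) nu^3`; with binary rates the norm ceiling is
`gamma/beta = 1.5`.

## Parameters

Biologically plausible network (defaults of `NetworkConfig` /
`PlasticityConfig`): `N_I = 25`, `p_IE = p_EI = 0.9`, `w_IE = 1`,
`|w_EI| = 1/(p_EI N_I)`, `tau_m = 20 ms`, `tau_inh = 2 ms`, `L = 0.5`,
`p* = 0.1`, `dt = 0.1 ms`, `eta = 0.01`, `eta_b = 0.01`, `nu0 = 0.2`,
`theta = 0.15`, `alpha0 = 0.05`, `gamma0 = 10` (so `gamma = 9.85`),
`beta = 1`.

Simplified network (`SimpleNetConfig`, `PlasticityConfig.simple()`):
`w_rec = -1.2`, `b_mature = 1.2`, `b_birth = 0.9`, threshold ramp over
12 000 presentations, `dt = 1 ms`, `eta = 0.01`, `theta = 0.15`,
`alpha0 = 0.03`, `gamma0 = 1.65` (so `gamma = 1.5`), `beta = 1`.

Derived constants: `gamma = gamma0 - theta` and `alpha = alpha0 / theta^3`.
The division in the alpha relation is a deliberate reading (the relation is
typeset ambiguously in different renderings); it keeps the LTD magnitude
commensurate with LTP near `nu = theta` and an `alpha_override` field exists
for the alternative.  With `||w|| = 1.5` and `b = 1.2` the similar/distinct
boundary is `xi_thresh = sqrt(||w||/b - 1) = 0.5`, and single-winner
competition requires `w_rec < b - max_xi ||w||/(1+xi^2) ~ -0.24`.

## Synthetic data

`ClusterSpec` builds `K` equidistant unit centers in `N_EC = 2^K` dimensions
(Walsh square waves shifted along the diagonal, normalized by
`c0 = sqrt(N_EC (1+xi^2))`); every pair of centers has dot product
`1/(1+xi^2)`.  The power-of-two dimension is a structural requirement of the
Walsh construction; the standard configuration is `K = 7`, `N_EC = 128`.
Patterns are drawn from a von Mises–Fisher distribution around each center
using the standard beta-envelope rejection sampler for the radial component
(attempt budget 10^6 per sample, guarding against malformed concentrations)
and a uniformly random tangent direction, then re-normalized.  Train and
test splits consume disjoint RNG streams derived from the base seed by fixed
offsets, so the test set is invariant to `n_train`.

What the generator emulates: tightly concentrated, equidistant,
non-negative input ensembles whose pairwise similarity is a single dial
(`s = 1 - xi`) — the cleanest setting in which the similar/distinct
dichotomy can be stated and solved in closed form.  What it does not
emulate: the within-class structure of natural stimuli (multiple prototypes
per class, unequal class spacing, heavy-tailed dispersion).  Tests passing
on this data therefore validate the mechanism, not performance claims on
natural images; the external-image adapter (`normalize_external_patterns`)
exists for the latter, with block-average downsampling as a configurable
choice since no canonical reduction is prescribed.

At small concentrations samples can leave the positive quadrant; they are
kept as sampled and a warning is logged, since input rates are nominally
non-negative.  Non-negativity is only asserted for similar-cluster data at
`kappa >= 1e3`.

## Maturation protocol

Pretraining initializes feedforward rows at Uniform(0,1) normalized to unit
norm and trains all cells on the familiar classes.  Cells whose converged
rate exceeds 1 Hz (`nu > 0.1`) for at least one training pattern are
selective; they are frozen (`eta = 0`).  Unresponsive cells are replaced by
newborns: zero feedforward weights, re-sampled *depolarizing* GABAergic
input, no output to interneurons, threshold pinned at 0.  The early phase
presents one epoch (configurable) of all classes in one shuffled stream with
the novel class interspersed.  The GABA-switch then flips the sign of the
existing interneuron inputs on the same mask, samples output connections
Bernoulli(`p_IE`), and enables threshold adaptation
`db = eta_b (nu - nu0)`.  The late phase presents one more epoch (or more).

Threshold adaptation applies to late-phase newborns by default.  Applying
the same rule to mature cells during pretraining is available as an opt-in
(`adapt_mature_b=True`): for cells that never win, `db = eta_b (0 - nu0)`
decreases the threshold without bound and eventually makes them fire for
everything, which corrupts the unresponsive/selective partition, so the
opt-in is off by default.  It is useful where sharper competition between
few units is wanted (the two-unit parameter-recovery test uses it).

Controls: (1) all classes pretrained simultaneously from random weights;
(2) selective cells frozen, unresponsive cells kept plastic with weights and
wiring intact; (3) every cell kept plastic.  None of the controls uses the
GABA-switch machinery.

## Numerical choices

* **Graded-rate integration**: coupled forward Euler for DGCs and
  interneurons at `dt = 0.1 ms` (well below `tau_inh = 2 ms`); rates start
  at zero for every pattern.  Convergence is declared when the largest rate
  derivative falls below `tol = 1e-6` per ms; `T_max = 2000 tau_m` guards
  against non-convergence, which raises an error carrying the last state.
  Halving `dt` changes converged rates by < 1e-5 (tested).
* **Binary-rate relaxation**: within a constant Heaviside configuration the
  dynamics are linear, so `simple_converge` integrates them *exactly*,
  event by event, solving each threshold-crossing time in closed form
  (`e^{-t} = (b - c)/d`) and overshooting each event by `1e-9 tau_m` so a
  crossing cannot re-trigger.  A forward-Euler integrator is kept as
  `method="euler"`; the two agree to 1e-5 and both match exhaustive
  enumeration of stable binary configurations for up to four units
  (property-tested).  `H(0) = 0`, so the silent state is absorbing for
  exactly-threshold input.  An event budget of 10^4 catches genuine limit
  cycles.
* **Plasticity timing**: weights update once per pattern after rate
  convergence (synchronous), with elementwise clamping at zero applied after
  the full three-term update.
* **Fisher axes**: the two-class discriminant is computed as
  `S_W^{-1}(mu_m - mu_n)` (the leading eigenvector of the rank-one
  generalized problem); near-singular `S_W` (condition number > 1e10) is
  ridge-regularized with `eps = 1e-8 Tr(S_W)/dim` and logged.  Axis origins
  are set so the training pool's mean projection is zero.
* **Participation ratio**: `PR = Tr(C)^2 / Tr(C^2)` computed through the
  Gram matrix on the smaller side of the data matrix, avoiding a 128x128
  covariance when patterns are few (or a PxP Gram when they are many).
* **Angles** are reported in degrees throughout.
* **Trailing windows**: the toy run reports "final" and "end-of-early"
  norms/angles as means over the last 500 presentations of the respective
  phase.
* **Toy-run angle reference**: the angle `phi` is measured against the
  center of mass of the novel cluster, i.e. the normalized average of the
  novel training stimuli (not the noiseless construction center); with
  6000 patterns at `kappa = 1e4` the two differ by well under 0.1 degrees.

## Scaled test conditions

The quantitative benchmarks (geometry, thresholds, participation ratio,
mature norm, toy neurogenesis) run at the full study conditions: seven
clusters, 128 dimensions, `kappa = 1e4`, 6000 training patterns per cluster.
Protocol-level tests of the biologically plausible network run on reduced
problems (K = 3 clusters in 8 dimensions, 2–10 granule cells, tens of
patterns per cluster) so whole maturation protocols finish in seconds.  Two
quantities must be scaled alongside the problem size: the newborn threshold
ramp keeps its published *proportion* of the early epoch (two thirds) rather
than its absolute length, and learning rates/epoch counts are chosen so the
weight e-folding time remains shorter than the training schedule.

## Known limitations

* The timing prediction — a novel class introduced mid-way through the
  early phase is learned poorly compared to introduction at the start — is
  an emergent property of the full-size graded-rate network and does not
  survive desk-scale reduction: with few units the rate distribution
  saturates, weight updates re-average quickly, and the outcome becomes
  independent of introduction time.  The sequencing machinery
  (`novel_start_fraction`, `eta_maturation`) is implemented and its
  mechanics are tested, but the emergent claim itself is not asserted at
  small scale.
* Readout performance numbers on natural-image benchmarks are not asserted
  anywhere; classification and reconstruction readouts are validated on the
  synthetic ensembles only.
* Mossy cells, spiking dynamics, and within-dentate plasticity are outside
  the model: interneuron wiring is fixed apart from the birth/switch edits.
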