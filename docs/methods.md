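# Methods

## Model and scope

A LIF neuron under time-to-first-spike coding receives n weighted input
spikes at times t_1 ≤ … ≤ t_n on the encoding window [0, λ] and accumulates

    u(t) = Σ_{i : t_i ≤ t} w_i e^{−(t − t_i)/τ},

with resting potential 0; any membrane resistance and charge factors are
absorbed into the weights, which are therefore expressed directly in
potential units.  Between events the potential strictly decays, so the first
threshold crossing can only happen *at* an input time; the event scan over
k = 1…n returning the smallest k with u(t_k) ≥ θ is exhaustive (this is
verified against a dense-grid crossing search in the tests).  Each neuron
emits a single output spike; refractoriness, reset and multi-spike outputs
are out of scope, as are convolutional/recurrent topologies and training.

λ ("number of time steps") is used purely as a length scale: dividing a
sorted uniform train by λ gives uniform order statistics on [0, 1].  Times
are continuous reals.

## Desired firing time

The discrete firing rule makes the output time piecewise constant in the
perturbation.  The desired firing time removes this: assuming a uniform
potential rise between the pre-firing maximum (t_j, u_j) and the crossing
(t_m, u_m), the threshold is met at

    t_d = t_j + (θ − u_j)(t_m − t_j)/(u_m − u_j),

which satisfies t_j < t_d ≤ t_m and is continuous in the inputs.  j is the
argmax of the potential over events before m; ties are broken toward the
larger index so the interpolation interval is as local as possible.  When
the very first event crosses (m = 1) there is no predecessor; the output
time is taken to be t_1 itself, so the deviation under a perturbation is
exactly |Δt_1| (results carry a `degenerate` flag).

## Three deviation semantics

For a concrete train and perturbation the package distinguishes:

* `exact` — recompute the full firing solution on the shifted train
  t + ΔT (weight–spike association fixed at the unperturbed ordering; the
  train is not re-sorted and times may exceed λ).  This is the literal
  reading of the sensitivity definition and the default Monte-Carlo
  baseline.  It contains the direct translation of every event time: for a
  constant shift ΔT = δ·1 the deviation is exactly δ regardless of the
  potential dynamics.
* `potential` — freeze the event clock at the unperturbed times and perturb
  only the decay algebra, so the potential at event k becomes
  Σ_{i≤k} w_i e^{−(t_k − t_i − Δt_i)/τ}.  Algebraically this equals solving
  the unperturbed train with weights boosted to w_i e^{Δt_i/τ}.  This is the
  potential-mediated effect that the analytic linearization models.
* `linearized` — the first-order expression Δy = (t_m − t_j)/(u_m − u_j)·Δu_j
  with Δu_j the algebraic potential difference at t_j, i.e. the
  uniform-upward-shift picture of the interpolated crossing.

These are genuinely different quantities.  Even in `potential` mode the
small-scale ratio of exact to linearized deviation is not 1: perturbing the
inputs changes u_m and u_j by different amounts, so the interpolation slope
changes, leaving a residual of relative size
(θ − u_j)/(u_m − u_j) · (Δu̇_m/Δu̇_j − 1) (median ≈ 5% under the default
study conditions, occasionally much larger when u_j ≪ θ).  In `exact` mode
the translation terms dominate and the ratio is O(1)–O(10).  The test suite
asserts exactly what holds: differentiability of the exact deviation, and
an order-one band for the potential-mode/linearized ratio.

## Closed-form sensitivity

Normalized sorted-uniform inputs are Beta order statistics,
X_(k) ~ Beta(k, n−k+1) with raw moments μ_h(k) = Π_{r<h}(k+r)/(n+1+r).  The
closed form makes three approximations, kept deliberately separate:

1. **Independence** — the joint law of the order statistics is replaced by
   the product of their Beta marginals, and expectations of products are
   factored into products of expectations (including the ratio: the
   reciprocal denominator is approximated around its input-independent
   part).
2. **Taylor truncation** (order q) — exponential-decay expectations are
   truncated as A_i = Σ_{h=0}^{q} (λ/τ)^h μ_h(i)/h! for e^{+λX_(i)/τ} and
   B_k likewise with −λ/τ.  The mixed perturbation factor
   D_i ≈ E[(e^{Δt_i/τ}−1)e^{λX_(i)/τ}] is truncated to total degree q.
   q = None uses the exact marginal expectation 1F1(k; n+1; ±λ/τ).  The
   default is q = 3 (cubic); the displayed quadratic factors of the
   classical presentation correspond to q = 2, and at λ/τ = 1.28 the cubic
   truncation is markedly closer to the sort-based simulation (relative
   error of E[u_j] at mid-train indices ≈ 0.3% vs ≈ 4–5%).  Accuracy
   degrades toward the last indices, where λE[X_(k)]/τ → λ/τ; the algorithm
   only evaluates the expectations at the selected mid-train indices.
3. **Geometric truncation** (order p) — the reciprocal of the potential
   rise is expanded as 1/(u_m − u_j) ≈ (1/w_m)Σ_{r=0}^{p}(−G/w_m)^r with
   G = Σ_{j<i<m} w_i A_i B_m, i.e. the contributions of inputs up to j are
   assumed to cancel between u_m and u_j.  Default p = 1; p = None uses
   1/(w_m + G).

With these pieces,

    E[u_k]  = Σ_{i<k} w_i A_i B_k + w_k,
    E[Δu_m] = Σ_{i<m} w_i D_i B_m + w_m(e^{Δt_m/τ} − 1),
    s       = λ(m−j)/(n+1) · [Σ_{i<j} w_i D_i B_j + w_j(e^{Δt_j/τ} − 1)]
              · (1/w_m)Σ_{r=0}^{p}(−G/w_m)^r.

The final summand of E[Δu_m] and of the numerator of s is the boundary term
of the index at which the quantity is evaluated: its value is
input-independent (the decay interval is zero), exactly parallel to the
separated +w_k of E[u_k], so it needs no order-statistic expectation and is
kept exactly (Taylor-truncated at the same q for consistency).  The
`boundary=False` option drops it, reproducing the shorter classical
presentation of both formulas; with the boundary terms the closed forms
match sort-based Monte-Carlo estimates of E[u_j] and E[Δu_m] within a few
percent at the reference conditions, which is the package's acceptance
check for the expectation layer.

The indices are selected from the expected-potential profile: m is the
smallest k with E[u_k] ≥ θ (the event-driven rule applied to the expected
trajectory) and j the argmax of E[u_k] over k < m, ties toward the larger
index.  Selection is invariant under joint positive scaling of weights and
threshold.  If no index reaches θ in expectation, a
`NotFiredInExpectationError` is raised.

E[Δu_m] is the canonical scalar measure of perturbation magnitude and the
x-axis of all perturbation sweeps; target measures are converted to scale
factors by bracketed root-finding (the measure is strictly increasing in
the scale for a nonnegative direction).

## Known accuracy limits of the closed form

The expectation layer (E[u_k], E[Δu_m]) is accurate to a few percent.  The
sensitivity layer is not, whenever firing happens mid-train:

* The denominator approximation w_m + G ignores the decay of the potential
  accumulated up to index j between t_j and t_m.  The true rise
  u_m − u_j = w_m − u_j(1 − e^{−(t_m−t_j)/τ}) + … is typically much smaller
  than w_m when u_j ≈ θ is several times w_m, so the closed form
  underestimates.
* E[num/den] is replaced by E[num]·(approximate 1/den).  The numerator and
  the reciprocal denominator are positively correlated (both grow with the
  gap t_m − t_j), and 1/(u_m − u_j) is heavy-tailed; both effects push the
  true expectation above the factored value.
* At fixed (j, m) *without* conditioning on m being the first crossing, the
  integrand (t_m − t_j)Δu_j/(u_m − u_j) has a non-integrable singularity at
  u_m = u_j: the denominator's density is positive near zero, so the
  expectation the semi-analytic oracle estimates is divergent, and its
  Monte-Carlo mean is sample-size dependent (the exclusion of u_m ≤ u_j
  samples does not remove the den → 0+ tail).  In the true definition the
  first-crossing condition bounds the deviation by t_m − t_j, which is why
  the simulation baseline is finite and stable.  Comparisons between the
  closed form and the fixed-index oracle are therefore reported but cannot
  be expected to converge, at any truncation order.

Consequently, under the reference conditions (θ = 0.4·Σw, firing around the
9th–11th of 20 inputs) the closed form tracks the Monte-Carlo baseline in
*trend* — strictly increasing in the perturbation measure, rank-identical
curves — but underestimates its magnitude severalfold, in every deviation
mode.  The discrepancy shrinks when firing occurs early (small θ), where
w_m + G is a good estimate of the rise and the heavy tail is absent.  Users
who need magnitudes should use the Monte-Carlo route; the closed form is
for trend analysis and parameter ranking, which is also what the package's
sweep experiments validate.

## Parameter sweeps

Sensitivity is swept against the perturbation measure, τ (39–62), λ
(55–66), n (30–40, with λ = 128, τ = 80), and for networks against the
perturbation measure (structure 20-5-1) and the input dimension n⁰ (15–25,
structure n⁰-5-1).  Observed structure:

* s increases strictly with the perturbation measure, and nested
  perturbations ΔT₁ < ΔT₂ < ΔT₃ preserve their order at every setting.
* Against τ, s is piecewise nonincreasing; every upward jump coincides with
  a change of the selected (j, m).  The same jump mechanism appears in the
  dimension sweeps (n and n⁰): under the fraction-of-total-weight threshold
  rule, θ grows with the dimension, the selected indices shift as the grid
  advances, and the decreasing trend holds piecewise between index changes
  rather than globally.
* Against λ, s increases over the swept range.

## Networks

Layer l's closed-form sensitivity applies the per-neuron formula with the
synapse index treated as order-statistic index — the uniform-input
assumption is retained at hidden layers although hidden spike times are
neither uniform nor independent; this is a known model approximation, and
hidden-layer times are used as-is (no renormalization to [0, λ]).  The
Monte-Carlo baseline forward-propagates desired firing times between layers
by default (keeping the end-to-end deviation continuous); an option uses
actual firing times.  Within a layer, each sample's input spikes are sorted
once and every neuron's weight row is permuted accordingly; the perturbed
pass reuses the unperturbed permutation so the weight–spike association is
fixed.  A sample is excluded when any neuron in either pass fails to fire.

## Synthetic data

The fixture generators emulate the reference study conditions: weights
i.i.d. uniform on [0, 1]; input trains sorted uniforms on [0, λ]; one
nonnegative random perturbation direction scaled to strictly increasing
target measures, guaranteeing elementwise nesting; thresholds from the rule
θ = 0.4·Σw per neuron (placing expected firing mid-train so that j, m and
the pre-firing maximum are all nontrivial), overridable per config.  For
input-dimension sweeps, weight draws are nested across dimensions (a longer
draw extends a shorter one; network first-layer matrices are drawn at the
largest fan-in and sliced) so the sweep isolates the dimension effect from
weight-draw noise.  What the generator does **not** emulate: structured or
correlated spike codes, non-uniform input distributions (which break the
Beta marginals), trained weight configurations, and negative weights.
Passing tests therefore demonstrate correctness of the implementation and
the stated statistical properties under uniform coding, not performance on
data from trained networks.

## Numerical choices and problem sizes

* Monte-Carlo defaults: 10⁵ samples per neuron estimate (standard error
  well below the trend effects of interest; estimates at this size run in
  well under a second via the vectorized event scan), 10⁴ per sweep point
  and per network estimate.  Seeds are mandatory in all configs; every
  estimate is exactly reproducible.
* Non-firing samples are excluded from Monte-Carlo means, not counted as
  zero (the sensitivity conditions on an output existing; counting zeros
  would silently bias downward).  The excluded fraction is reported and
  more than 50% exclusion raises an error.
* The batch event scan uses the prefix recursion
  P_k = P_{k−1}e^{−(t_k−t_{k−1})/τ} + w_k, an algebraic identity valid for
  any time ordering — needed because perturbed trains are deliberately not
  re-sorted.
* Scale calibration solves E[Δu_m](c·direction) = target with brentq on a
  doubling bracket (xtol 1e-12).
* Ties in the argmax of (expected) potentials break toward the larger
  index; threshold comparisons use ≥.
* Zero perturbations short-circuit to exactly 0.0 in every route.
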