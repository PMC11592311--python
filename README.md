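# lifsens

Input-perturbation sensitivity analysis for temporal-coded spiking neural
networks (SNNs) with leaky integrate-and-fire (LIF) neurons.

## The problem

In a time-to-first-spike code, every neuron's output is the time at which
its membrane potential first reaches the firing threshold.  How much does
that output time move when the input spike times are jittered?  The
*sensitivity* of a neuron is defined as the expected absolute output-time
deviation caused by a fixed perturbation vector ΔT, taken over all inputs:

    s(ΔT) = E_T | f(T + ΔT, W) − f(T, W) |,

with the input train T treated as n i.i.d. uniform spike times on the
encoding window [0, λ], sorted.  The sensitivity of a layer is the vector of
its neurons' sensitivities, and the sensitivity of a fully connected network
is obtained iteratively: each layer's sensitivity vector becomes the next
layer's input perturbation, and the output layer's vector is the network's
sensitivity.

The package is aimed at researchers studying the noise tolerance and
parameter selection of temporal-coded SNNs: it quantifies how sensitivity
depends on the perturbation magnitude, the membrane time constant τ, the
window length λ and the input dimension n.

## The model

The membrane potential of a LIF neuron receiving weighted input spikes is
(resting potential 0, weights in potential units)

    u(t) = Σ_{i : t_i ≤ t} w_i exp(−(t − t_i)/τ),

and the neuron fires at the first input time t_m with u(t_m) ≥ θ.  Because
the potential rises only at input events, the raw output time is discrete in
the perturbation; the **desired firing time** removes this discreteness by
interpolating the potential linearly between the pre-firing maximum
(t_j, u_j) and the crossing event (t_m, u_m):

    t_d = t_j + (θ − u_j)(t_m − t_j)/(u_m − u_j).

Three routes to the sensitivity are implemented and cross-validated:

* **Monte Carlo** (`neuron_sensitivity_mc`, `network_mc_sensitivity`) —
  direct simulation over sorted-uniform trains, with three per-sample
  deviation modes (`exact`, `potential`, `linearized`; see
  `docs/methods.md`).
* **Closed form** (`neuron_sensitivity_closed_form`, `snn_sensitivity`) —
  fully analytic.  Normalized sorted-uniform times are Beta order
  statistics, X_(k) ~ Beta(k, n−k+1); treating them as independent
  marginals and Taylor-truncating the decay factors gives

      s = λ(m−j)/(n+1) · [ Σ_{i<j} w_i D_i B_j + w_j(e^{Δt_j/τ}−1) ]
          · (1/w_m) Σ_{r=0}^{p} (−G/w_m)^r,

  where A_i, B_k are the truncated expectations of e^{±λX_(k)/τ},
  D_i truncates (e^{Δt_i/τ}−1)e^{λX_(i)/τ}, G = Σ_{j<i<m} w_i A_i B_m, and
  (j, m) are selected from the expected-potential profile
  E[u_k] = Σ_{i<k} w_i A_i B_k + w_k.  The perturbation magnitude is
  measured by the expected potential difference E[Δu_m], the package's
  canonical x-axis for all sweeps.
* **Semi-analytic oracle** (`neuron_sensitivity_oracle`) — Monte Carlo of
  the pre-truncation integrand (t_m−t_j)Δu_j/(u_m−u_j) at fixed (j, m),
  under the true joint law and under the independence approximation, to
  isolate where the analytic error arises.

## Worked example

A neuron with n = 20 synapses, weights uniform on [0, 1] (seed 101),
τ = 50 ms, window λ = 64, threshold θ = 0.4·Σw, perturbed by a nonnegative
random direction scaled so that E[Δu_m] = 0.06:

```text
$ lifsens neuron --samples 100000 --measure 0.06
theta              = 4.61118
E[du_m] (measure)  = 0.06  (scale 1.02762)
expected indices   : j = 8, m = 9
s (closed form)    = 0.146676
s (MC, exact     ) = 0.874548  +- 0.0023 (excluded 0.00%)
```

The threshold is crossed in expectation at the 9th input, with the
pre-firing maximum at the 8th.  The closed form predicts an expected output
shift of ≈ 0.15 time units; the exact-recomputation Monte-Carlo baseline
measures ≈ 0.87.  The gap is the method's real approximation error at
mid-train firing: the exact deviation includes the direct translation of the
event times, and the closed form's mean-field denominator w_m + G
overestimates the typically small potential rise u_m − u_j (see
`docs/methods.md`).  Both curves increase monotonically with the
perturbation measure and rank identically, which is the level at which the
analytic formula is informative.

The same comparison for a 20-5-1 network:

```text
$ lifsens network --samples 10000 --measure 0.06
structure          = 20-5-1
S (algorithm)      = [0.023571]
S (network MC)     = [0.701626]
```

Parameter sweeps (perturbation magnitude, time constant, window length,
input dimension, and the two network variants) are run with
`lifsens sweep --experiment tau --output tau.csv` or from a YAML config
(`lifsens sweep --config my.yaml`; `--show-config` prints the resolved
settings).  Each sweep writes one CSV row per grid point and perturbation
with the closed-form and Monte-Carlo values, the selected indices (j, m),
the measure E[Δu_m] and diagnostics.

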