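# Methods

## The reduction

`neuroreduce` reduces a network of `P` populations of `N` noisy spiking
neurons with *linear* synapses to a deterministic system of `P` ordinary
differential equations (plus one memory state and one synaptic filter state
per population).

**Microscopic model.** Each neuron `i` of population `α` carries a voltage
`v_i` and auxiliary variables (adaptation or gating), and obeys an Itô SDE

    dX_i = [ f(X_i) + g(I_α(t) + ξ_i + Σ_j J_ij s_j(t)) ] dt + σ dW_i,
    ds_j/dt = (v_j − s_j) / τ_s,

where `f` is one of three excitable single-neuron models (below), the
synaptic trace `s_j` is the presynaptic voltage convolved with the unit-area
exponential kernel `η(t) = e^{−t/τ_s}/τ_s`, `ξ_i ~ N(0, λ)` is a constant
per-neuron input offset, and the weights are Gaussian with block structure

    J_ij ~ N( J̄_αβ / N_β ,  σ^J_αβ / √N_β )     (i ∈ α, j ∈ β).

This scaling makes the summed input mean independent of `N` with finite
disorder variance; both exponents are configurable.

**Macroscopic observable.** The activity of population `α` is

    ν_α(t) = ⟨ v_i(t) ⟩_{i∈α} ∗ ψ(t),

the population-averaged voltage convolved with a normalized symmetric
window `ψ` of width `T_w`.  The window must exceed the duration of a spike
(here: a few relaxation periods) and stay small relative to the input
timescale.  It is voltage-based rather than spike-count-based on purpose:
it is a linear functional of the microscopic state and therefore commutes
with population averaging.

**Closure.** In the large-`N` limit neurons of a population become
independent samples of one law (propagation of chaos), so `⟨v⟩ → E[v]`.
Writing each model's voltage drift as *linear part plus residual*,

    dv/dt = ℓ₀ v + (adaptation memory term) + g·I_input + r(state),

the only unclosed quantity in the equation for `ν_α` is `E[r]`.  Because
the adaptation equations are linear, their population means are *exact*
auxiliary ODEs driven by `ν`.  The closure assumption — synapses and inputs
slow compared with the neuronal relaxation — replaces `E[r](t)` with

    S(I_eff_α(t)),   I_eff_α = I_α + Σ_β J̄_αβ (η ∗ ν_β),

where the **effective nonlinearity** `S(I, σ)` is the long-run temporal
average of `r` for a *single* uncoupled neuron driven by constant input `I`
at noise `σ`.  The reduced system is then, per population,

    dν/dt = ℓ₀ ν + (amp/rate) m + g·I_eff + S(I_eff),
    dm/dt = rate (ν + offset − m),          # exponential-memory state
    dg_β/dt = (ν_β − g_β)/τ_s.              # synaptic filter

The memory kernel is exactly exponential, so it is realized as one extra
linear ODE rather than a history integral (exact, O(1) memory).  The
synaptic filtering of `ν` inside `I_eff` is on by default and can be
toggled (`filter_effective_input`).

## Models and their linear/nonlinear split

Time is in milliseconds, voltage in millivolts, throughout.

| model | dynamics | linear part L | residual r |
|---|---|---|---|
| `mckean` | `v' = (f(v) − w)/ε + I`; `w' = c(v − b w)`; `f` piecewise linear, N-shaped (knees `±1`, middle slope `2/3`, outer slope `−1`) | `−(1/ε)δ₀ − (c/ε) e^{−bc t}H(t)` | `(f(v) + v)/ε`, saturating at `±5/(3ε)` |
| `fhn` | `v' = v − v³/3 − w + I`; `w' = (v + a − b w)/τ_w` (a=0.7, b=0.8, τ_w=12.5) | `−k δ₀ − (1/τ_w) e^{−(b/τ_w)t}H(t)` with `k = 4c₁/3` (secant slope of the cubic's decreasing negative branch) | `v − v³/3 + k v` |
| `hh` | original squid-axon Hodgkin-Huxley, rest ≈ 0 mV (C=1, gNa=120, gK=36, gL=0.3, ENa=115, EK=−12, EL=10.613) | `−(gL/C) δ₀` (no delayed term can be split off the gating dynamics) | `(−gNa m³h(V−ENa) − gK n⁴(V−EK) + gL·EL)/C` |

The split is self-consistent: at a stationary closure the reduced `ν*`
equals the single neuron's fixed-point voltage exactly, and in the
oscillatory regime it equals the cycle-averaged voltage (this follows from
averaging the adaptation equation over one period and is verified in the
tests).

Default McKean parameters `b = 0.5, c = 0.1, ε = 0.5` give a relaxation
cycle of ≈ 19 ms; `c` was chosen so that spike period ≪ averaging window
≪ input timescale in the packaged experiments (see *Timescale hierarchy*).
Numeric parameter values for all models are standard literature values and
every one is exposed in configuration.

## The closed-form McKean nonlinearity

With the piecewise-linear nullcline the slow flow on each outer branch is
a linear ODE, so the transit times along the two slow manifolds between
the knee levels are logarithms:

    T_± = ln( (A_± − w_entry) / (A_± − w_exit) ) / ( c (b + 1/s) ),

with `A_±` the (virtual) slow-flow equilibria and `s` the outer slope.
The residual `r` is *constant* on each outer branch (`±(m+s)v_knee/ε`), so
the cycle average is the transit-time-weighted mean of the two levels:

    S(I) = [ T_− r_− + T_+ r_+ ] / (T_− + T_+)     inside the window,
    S(I) = r_∓                                      outside (fixed point).

The oscillatory window is `I ∈ (v_lo (1/b − m)/ε, v_hi (1/b − m)/ε)`.
At the thresholds one transit time diverges logarithmically: `S` is
continuous, non-decreasing, with vertical tangents — and the divergence of
the period is the class I excitability signature.  The formula is exact in
the singular limit; at finite `ε` the measured period exceeds it by the
fold-delay correction (≈ 4% at ε = 0.1, ≈ 1% at ε = 0.02 with c = 0.04).
Accuracy tests therefore use strongly separated timescales.

## Numerical estimation of S

`estimate_point` integrates one neuron (Euler–Maruyama; compiled kernels)
at constant input, discards a transient of at least ten slow timescales,
and averages `r` over ≥ 20 periods (or ≥ a configured horizon when
stationary), reporting a batch-means standard error.  Periods come from
the biased autocorrelation of the subsampled residual trace: first peak
after the first zero crossing, hill-climbing refinement on the farthest
clean multiple, subharmonic guard, parabolic sub-sample interpolation.

`build_surface` runs all (input × initial-condition) pairs of a noise
level as one vectorized batch.  Initial conditions are *anchored*: the
deterministic fixed point (slightly jittered, so an unstable equilibrium
escapes during the discarded transient instead of fabricating a spurious
branch) plus a strongly excited state plus dispersed random states.  The
per-init values are segmented by a 1-D largest-gap rule: two branches iff
the largest sorted gap exceeds `max(5 × median other gaps, 5 × pooled SE,
0.02 × surface span)`; a further well-separated split raises an error
(more than two attractors is out of scope).  A noise level is *regime II*
iff any input shows two branches.  No smoothing is applied beyond linear
interpolation; all horizons and thresholds are stored in the surface
metadata.

`deterministic_sweep` replaces numerical continuation: a forward sweep
(continuing the integration state as `I` increases) tracks the fixed-point
branch until its fold, a backward sweep tracks the cycle down to its fold;
disagreement delimits the bistable window.  Unsettled points (no
stationarity, no detected period) are flagged and excluded.  Excitability
class in `bifurcation_report` is decided by refining the cycle fold by
bisection and comparing the period very near onset with the period a tenth
of the grid span above: ≥ 30% growth ⇒ class I (arbitrarily slow orbits),
flat ⇒ class II.

## Regime II integration

When the single neuron is bistable (Hodgkin-Huxley at low noise), `S` is
two-valued over the bistable window.  The reduced integrator carries one
attractor label per population, evaluates the labeled branch of the swept
`BranchSystem`, and flips the label when `I_eff` crosses the fold at which
the branch ends (event located by bisection inside the RK4 step; `ν` is
carried continuously — the rule selects which branch of `S` is used, it
does not reset the state).  Noise-induced attractor switching in the
network is deliberately not modeled; in that regime path-wise agreement is
out of reach and only qualitative structure is recovered.

## Timescale hierarchy and the packaged experiments

The reduction requires (fast → slow): spike upstroke (≈ ε) < relaxation
period < averaging window `T_w` < synaptic/input timescales.  The default
experiments (`compare_model`) use P = 3 populations of N = 200 neurons,
τ_s = 15 ms, inputs made of logistic ramps varying over 100–300 ms, and:

* McKean: σ = 0.2, window 60 ms (≈ 3 periods), mean-coupling scale 0.5,
  disorder 0.3;
* FitzHugh-Nagumo: σ = 0.15, window 60 ms, coupling 0.3, disorder 0.05;
* Hodgkin-Huxley: σ = 3 (regime I), weak coupling 0.05, window 20 ms.

The disorder scales are set to a small fraction of each model's sigmoid
transition width: quenched weight disorder gives each neuron a static
offset in its effective input, and when that spread is comparable to the
transition width the population response is a *smeared* sigmoid that the
single-neuron `S` does not capture (with FHN disorder at 0.1 this leaves a
smooth ≈ 10% bias; at 0.05 the bias is ≈ 2–4%).  The same mechanism bounds
the useful coupling strength: beyond it, positive self-coupling entrains
the population (partial synchrony), the macroscopic activity acquires
power at the spike timescale, and the slow-closure assumption breaks —
visible as error growth in the `J` robustness sweep rather than hidden.

The comparison metric is the per-population mean absolute difference
between the windowed network activity and the reduced trajectory over the
non-transient span, also reported relative to the network trace's dynamic
range.  Transient spans (half a window at each edge) are excluded from
both series.

## What the synthetic experiments do and do not show

The input bank emulates slow, smooth, plateau-and-ramp drive; the
connectivity is dense Gaussian without Dale's law, sparseness, or
conductance-based synapses.  Passing tests demonstrate the internal
consistency and accuracy of the reduction *under its stated assumptions*
(linear synaptic integration, slow synapses and inputs, large random
populations).  They do not establish accuracy for sparse or structured
connectivity, fast synapses (the τ_s sweep shows the failure directly),
strongly synchronized regimes, or noise-driven attractor switching.

## Numerical choices

* Euler–Maruyama for all stochastic integration (dt = 0.05 ms for the
  two-variable models, 0.01 ms for Hodgkin-Huxley); gating variables are
  clipped to [0, 1] after each stochastic step.  Non-finite states abort
  with the blow-up time.
* Fixed-step RK4 for the reduced system; step-halving changes trajectories
  by < 0.5% at the default step (verified in tests).
* Named RNG streams (weights / initial conditions / dynamical noise /
  input offsets) derived from one seed, so one concern can be varied while
  the others are held fixed; every seeded operation is bit-reproducible.
* Surface lookups never extrapolate beyond the tabulated hull (an error
  names the offending input and time); branch interpolants allow a
  one-grid-cell margin past their fold so that trial integrator stages can
  evaluate during event location.
* Propagation-of-chaos diagnostics use the exact all-pairs mean
  correlation identity `(N·Var(mean of standardized traces) − 1)/(N − 1)`
  rather than sampled pairs.

## Known limitations

* The Hodgkin-Huxley linear part is instantaneous decay only; the reduction
  degrades for strong coupling (kept weak in the packaged experiment).
* Quenched disorder and input heterogeneity smear the effective sigmoid;
  the reduction ignores this (first-order effect bounded by keeping the
  spread small relative to the sigmoid transition width).
* Regime II accuracy is limited by random attractor switching in the
  network, which a deterministic reduced model cannot reproduce.
* Only stable attractors are swept; unstable branches are not continued.
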