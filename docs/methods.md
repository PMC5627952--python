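# Methods

## Model

A single postsynaptic neuron is driven through a synaptic pathway of
`N = 512` vesicle release sites partitioned equally into `M` active zones
(AZs), each AZ innervated by one presynaptic neuron. The two extremes are
the *giant* pathway (`M = 1`: one axon, 512 sites, synchronous release —
calyx-like) and the *cortical* pathway (`M = 512`: 512 independent axons
with one site each — temporal summation).

**Stimulus.** Each presynaptic neuron fires as an inhomogeneous Poisson
process with shared rate `λ_S(t) = A + B sin(2πft)` (defaults `A = 30` Hz,
`B = 20` Hz, so the rate swings between 10 and 50 Hz) and an absolute
dead time of 2 ms. Spike times are drawn by thinning a homogeneous
process at the tight bound `A + B`; a candidate inside the dead time of
the last accepted spike is deleted, otherwise it is accepted with
probability `λ_S(t)/(A+B)`. Under the deletion convention a constant-rate
train has long-run rate `λ/(1 + λ·r)`; this is what the tests assert. The
modulation starts at phase zero (`λ = A` at `t = 0`), which is continuous
and fixes the reference for all phase measurements.

**Release (short-term depression).** A site holds at most one
readily-releasable vesicle. On each presynaptic spike, every occupied
site of that AZ releases independently with probability `P_v = 0.25`; a
site that released refills after an i.i.d. exponential delay with mean
`τ_rec = 0.5` s (infinite reserve pool). The simulation is event-driven:
each release schedules the site's next availability time directly, which
is distribution-equivalent to the small-Δt automaton (refill probability
`Δt/τ_rec` per step) — the equivalence is verified by a χ² test against a
vectorised small-Δt oracle. All sites start occupied, which is why the
opening cycles of every run are discarded.

**Synapse and membrane.** The summed release count process `r(t)` drives
a dimensionless difference-of-exponentials conductance
(`dg/dt = −g/τ_d + x`, `τ_rise dx/dt = −x + r`, defaults
`τ_rise = 0.1` ms, `τ_d = 1` ms; `τ_rise = 0` is the delta-synapse limit
in which `g` jumps by the released count). The synaptic current
`ḡ·g·(v − E_syn)` (with `E_syn = 0` mV) is applied so that it
depolarises the cell — the AMPA convention; note the printed form of the
current equation, taken literally together with a `+I/a` membrane term,
would hyperpolarise, and we deliberately use the physiologically
meaningful sign. The peak conductance is `ḡ = w_M × scale` where `w_M`
(0.12 … 0.42 for M = 1 … 512) is a per-configuration calibration weight
chosen so that all configurations fire at similar low rates, and the
scale is 1.2915 nS for `τ_rise = 0.1` ms and 1 nS for `τ_rise = 0`.
1.2915 nS is exactly 1 nS divided by the peak value 0.7743 =
`(τ_rise/τ_d)^(τ_rise/(τ_d−τ_rise))` of the unit double-exponential
response, so a unitary release peaks at `w_M` nS for either rise time.

Two membranes are implemented on a 20 µm × 20 µm cylinder
(area 1.2566×10⁻⁵ cm²): a two-gate Hodgkin–Huxley variant with
`ḡ_K n²` and `ḡ_Na m² h` currents, logistic steady-state activations
centred at −40/−45/−40 mV (slope 3 mV) and fixed gate time constants
(0.05/0.5/2 ms) — class-II excitability — and a leaky integrate-and-fire
neuron (`v_thresh = −51.5` mV, `v_reset = −80` mV, refractory clamp
1.8 ms). Both use the membrane time constant `C_m/g_l = 5` ms and leak
reversal −66 mV. Integration is forward Euler (as in the original
procedure) with step 0.05 ms for `f ≤ 1` Hz and `0.05/f` ms above, so a
cycle always spans the same number of steps; HH spikes are upward
crossings of +10 mV. Initial conditions `v = −66` mV, gates at 0; the
startup transient lies inside the discarded cycles.

**Units.** Seconds everywhere in the stimulus/release layer; the
membrane kernels work in mV/ms with conductances converted to mS·cm⁻²,
so all current terms are µA·cm⁻² (`ḡ[S]·g·mV·10³/area[cm²]` for the
synaptic term). A dimensional audit is part of the unit tests (the 5 ms
relaxation, the closed-form LIF rate, and the 66 pA current example).

## Phase estimation

Output spikes pooled over all repeats of a condition are binned at
`t_b = 5` ms over the largest whole number of modulation cycles after
discarding the first 3 cycles. The complex order parameter
`r̄ e^{iφ̄} = (1/K) Σ_k r_k e^{i2πf t_b k}` (absolute bin index `k`,
right-edge convention as printed; a bin-centre mode is available and
removes a ~0.9° systematic at f = 1 Hz) gives the mean phase, and the
phase lead is `φ_l = π/2 − φ̄`, positive when the response peaks before
the input does. The estimator is validated against the un-binned first
Fourier coefficient of the spike train.

## Theory

Conditional vesicle availability obeys
`dP/dt = (1−P)/τ_rec − P_v λ_S(t) P`. With `κ = 1/(1/τ_rec + P_v A)`
(the effective depression time constant, 105.3 ms at the defaults) the
first-order steady state is
`P ≈ (κ/τ_rec)(1 + B P_v κ/√(1+ω²κ²) · cos(ωt + arctan(1/(ωκ))))`, i.e.
a phase shift `Θ = π − arctan(ωκ)` relative to `λ_S` — 146.52° at
f = 1 Hz versus 144.54° for the exact ODE solution (adaptive RK, rtol
1e-10, first 4 of 12 cycles discarded, phase from first Fourier
coefficients with `λ_S`'s coefficient divided out; this ratio convention
removes any argument-sign ambiguity and makes all theory phases
sine-phase leads relative to the drive).

The release-rate proxy `c(t) = N_M P_v P(t) ⌈τ_p M λ_S(t)⌉` aggregates
expected arrivals over a window `τ_p` (default 30 ms; 10/30/60 ms for
f = 0.1/1/5 Hz reproduce the per-frequency refinement) and quantises
them, which is what distinguishes configurations: without the ceiling,
`c` is independent of `M`. Its first-harmonic phase `Θ(M, f)` is
evaluated on a grid with step ≤ `τ_p/10`. For `M = 1` the ceiling pins
the phase to the availability phase (coincidence detection); for large
`M` it approaches the phase of `P(t)·λ_S(t)`, which equals
`arctan(ωτ_rec) − arctan(ωκ)` (38.86° at f = 1 Hz) and is maximised at
`ω* = 1/√(τ_rec κ)`, i.e. `f* ≈ 0.69` Hz — the depression resonance. The
resonance period `1/f*` scales linearly with `√τ_rec` (R² > 0.999 over
τ_rec ∈ [0.1, 2] s) and approximately with `1/√P_v` (R² ≈ 0.97 over
P_v ∈ [0.05, 1]); it does not depend on the modulation depth `B`.

## Randomness and reproducibility

One master seed feeds a `SeedSequence` tree: per-neuron spike streams are
spawned children (so a neuron's train does not depend on `M`), and
vesicle-release randomness lives on separate streams keyed by
`(seed, purpose, M, f, repeat indices)`. This makes every sweep cell
bit-reproducible in isolation, supports the protocol of re-running the
same input spike trains with fresh release randomness, and allows cells
to run concurrently. Random numbers are pre-drawn with numpy generators
and consumed by position inside the compiled kernels, so results do not
depend on compilation details.

## Scale of the shipped experiments

Default sweeps use 23 cycles per run with the first 3 discarded and 10
input-spike-train sets × 2 release repeats (20 pooled repeats) per cell;
the reference study pooled up to 100 × 100. At this scale the pooled
phase lead of a cell at f = 1 Hz is reproducible across seeds to a few
degrees (giant pathway 86–89°, cortical 39.7–40.4° over seeds 1/2/7),
which is well inside the ±10° band used by the acceptance checks. The
consistency battery runs all ten configurations at 13 cycles with 8
pooled repeats, enough to hold the 5–25 spikes/s calibration band and
the <15° HH-vs-LIF surface agreement.

## What the synthetic conditions do and do not show

All inputs are generated by the package itself under the idealised
assumptions above: Poisson spiking with a shared sinusoidal rate,
identical independent release sites, a point-neuron soma. Passing tests
demonstrate internal consistency of simulation and theory under these
assumptions — they do not speak to dendritic filtering, facilitation or
activity-dependent replenishment (explicitly out of scope), correlated
presynaptic activity beyond the shared rate, or heterogeneous release
parameters across sites.

## Numerical choices and edge cases

- Theory-side ODE work uses an adaptive high-order solver (accuracy is
  cheap there); only the membrane uses Euler, deliberately, to mirror the
  simulated system being analysed. Halving the membrane step moves
  volley-locked spike times by <0.1 ms; for stochastic drive near
  threshold, single spikes can appear/disappear under step halving
  (grazing trajectories), which is inherent to threshold systems and not
  treated as an error.
- Release events falling between membrane grid points are injected at
  the next grid point; the total injected count is conserved exactly.
  Delta-synapse impulses are scaled by `1/dt` so the conductance
  increment is step-size invariant.
- A PSTH whose counts are uniform over whole cycles has an order
  parameter at the roundoff floor; the estimator raises rather than
  returning a meaningless phase, and sweep cells with no spikes after the
  discard window are flagged instead of erroring.
- `v` beyond ±200 mV aborts a membrane run (step-size failure guard).
- Ten calibrated `w_M` values exist; other `M` require an explicit
  weight, and `M` must divide `N` exactly.
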