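# stpphase

Short-term synaptic depression does more than scale synaptic gain: when a
neuron is driven by inputs whose firing rate oscillates on the timescale
of vesicle recovery (tenths of seconds to seconds), depression shifts the
*phase* of the postsynaptic spiking response. How large that shift is
depends on how the synaptic pathway is wired: a *giant* synapse (one axon,
many release sites, e.g. a calyx) responds almost in anti-phase to the
drive, while a *cortical* pathway (many independent axons, one site each)
shows a modest phase lead with a resonance in modulation frequency.
`stpphase` simulates this system end to end and implements the matching
analytical theory, for computational neuroscientists studying short-term
plasticity, rhythmic motor/sensory pathways, or phase coding.

## Model in brief

- Presynaptic drive: `M` independent Poisson trains with shared rate
  `λ_S(t) = A + B sin(2πft)` (defaults 30 ± 20 Hz) and a 2 ms dead time.
- Depressing synapses: `N = 512` release sites split into `M` active
  zones; an occupied site releases with probability `P_v = 0.25` per
  spike and refills after an exponential delay with mean `τ_rec = 0.5` s
  (event-driven simulation of the stochastic automaton).
- Postsynaptic neuron: difference-of-exponentials AMPA conductance into
  either a two-gate Hodgkin–Huxley model (`ḡ_K n²`, `ḡ_Na m²h`) or a
  leaky integrate-and-fire model, integrated by forward Euler.
- Readout: PSTH (5 ms bins, whole cycles, first 3 cycles discarded) and
  the circular order parameter `r̄ e^{iφ̄} = (1/K) Σ_k r_k e^{i2πf t_b k}`;
  the phase lead is `φ_l = π/2 − φ̄`.
- Theory: availability ODE `dP/dt = (1−P)/τ_rec − P_v λ_S P`, its
  closed-form phase `Θ = π − arctan(ωκ)` with
  `κ = 1/(1/τ_rec + P_v A)`, the quantised release-rate phase
  `Θ(M, f)`, and the resonance `f* = 1/(2π√(τ_rec κ))`.

See `docs/methods.md` for the full account.

## Worked example

```python
from stpphase import ExperimentConfig, run_cell, TheoryParams, \
    availability_phase, resonance_frequency
import numpy as np

cfg = ExperimentConfig(model="hh", cycles=23,
                       repeats_spikes=10, repeats_release=2, seed=1)
for M in (1, 512):
    row = run_cell(cfg, M, f=1.0)
    print(f"M={M:3d}: phase lead {row['phase_lead_deg']:5.1f} deg, "
          f"rate {row['mean_rate_hz']:.1f} /s")

p = TheoryParams()
print(f"availability phase: {np.degrees(availability_phase(1.0, p)):.2f} deg")
print(f"resonance: f* = {resonance_frequency(p):.2f} Hz")
```

prints

```
M=  1: phase lead  87.2 deg, rate 9.5 /s
M=512: phase lead  39.7 deg, rate 15.7 /s
availability phase: 146.52 deg
resonance: f* = 0.69 Hz
```

The giant pathway (`M = 1`) leads the 1 Hz input modulation by almost a
quarter cycle — its release sites are most replenished, and population
EPSCs largest, well before the input rate peaks — while the cortical
pathway (`M = 512`) integrates many asynchronous EPSCs and leads by only
~40°. The availability phase of ~146° is what drives both effects, and
the theoretical phase lead of the large-`M` pathway is maximised near
0.69 Hz for these depression parameters.

There is also a CLI (`stpphase stimulus|release|simulate|phase|theory|sweep`);
try `stpphase sweep --config cfg.toml --seed 1 --out results/`.

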