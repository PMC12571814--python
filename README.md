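# neurosync

Closed-loop simulation and control of neural synchronization.

`neurosync` models "cognitive states" as synchronization regimes of a
population of coupled phase oscillators, attaches a metabolic-cost signal to
the dynamics, closes the loop with reinforcement-learning controllers, and
analyses the synthesized EEG-like and BOLD-like signals with the standard
neuroimaging toolkit (band power, phase-locking value, circular statistics,
HRF convolution, GLM, ICA, functional connectivity).  It is aimed at
computational-neuroscience work on neurofeedback and neuroadaptive control,
where a fully synthetic, fully seeded test bed is needed before touching
real EEG/fMRI recordings.

## Model

Each of N oscillators carries a phase θ_i evolving under the Kuramoto
mean-field dynamics with an external drive (all rates in Hz, scaled by 2π
internally):

    dθ_i/dt = 2π ω_i + (2π K / N) Σ_j sin(θ_j − θ_i) + 2π I_i(t)

Global synchrony is the order parameter R(t) e^{iψ(t)} = (1/N) Σ_j e^{iθ_j}.
Three cognitive conditions are preset: **focused** (K = 10, uniform +5 Hz
drive), **multitasking** (K = 5, +5 Hz to half the population and −5 Hz to
the other half), and **resting** (K = 1, no drive); natural frequencies come
from an intrinsic N(10, 2) Hz law, a clustered Gaussian law, or a uniform
5–20 Hz law.

Metabolic cost and the control reward are

    E(t) = α R + β |dR/dt| + γ P_EEG + δ S_fMRI        (α, β, γ, δ = 10.01, 5, 3, 2)
    r(t) = −(|R_target − R| + E)

where P_EEG is the normalized envelope power of the mean-field EEG signal
and S_fMRI the HRF-convolved synchrony.  A tabular Q-learning agent
(10 × 10 bins over R and E) and a DQN (two hidden ReLU layers, experience
replay, target network, Adam) act on the coupling constant once per 0.1 s
to track condition-dependent synchrony targets.

## Worked example

```python
import numpy as np
from neurosync import FrequencyModel, simulate_condition, synthesize_eeg
from neurosync import band_power, ALPHA_BAND, BETA_BAND

for cond in ("focused", "multitasking", "resting"):
    vals = [simulate_condition(FrequencyModel(), cond, n=10, dt=0.01,
                               duration=10.0, seed=s).stationary_mean_R()
            for s in range(20)]
    print(cond, round(float(np.mean(vals)), 3))

traj = simulate_condition(FrequencyModel(), "resting", n=10, duration=10.0,
                          seed=0, K=10.0)          # locked ~10 Hz rhythm
raw, _ = synthesize_eeg(traj)
print("alpha/beta power ratio:",
      round(band_power(raw, 100, ALPHA_BAND) / band_power(raw, 100, BETA_BAND)))
```

prints

```
focused 0.977
multitasking 0.407
resting 0.347
alpha/beta power ratio: 498392
```

Focused attention locks the population (R near 1), multitasking splits it
into two drifting clusters (time-mean R ≈ 0.4), and rest stays near the
finite-size incoherent floor (≈ 0.89/√N ≈ 0.3 at N = 10).  A synchronized
population with ~10 Hz natural frequencies produces an alpha-dominant
EEG-like signal.

A command-line interface exposes the experiment drivers:

```bash
neurosync simulate --out runs/suite        # 3 models × 3 conditions table
neurosync train --agent both --seed 0      # RL learning curves
neurosync glm --out runs/glm               # simulated-fMRI GLM / ICA / connectivity
neurosync fixtures --out mm.csv            # balanced multimodal CSV (900 rows)
neurosync compare --reference a.csv --simulated b.csv --delay 0.2
```

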