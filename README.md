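# sgdege

Simulations of cerebellar learning by **stochastic gradient descent with
estimated global errors** (SGDEGE), for computational neuroscientists who
want to study perturbation-based learning rules in cerebellar circuit
models.

The package implements four related models:

* **Microzone network** (`sgdege.network`) — S×L Purkinje cells (PC), L
  nuclear projection neurones (PN), L nucleo-olivary neurones (NO) and N×S
  binary mossy fibres (M), all threshold-linear rate units saturating at
  r<sub>max</sub>. Spontaneous climbing-fibre *perturbation complex spikes*
  (probability ρ per fibre per movement) raise PC firing by A Hz in one time
  bin. After each movement the olive compares the global error
  ℰ = (1/LT)·Σ|PN − R| with the inhibition ℐ = (1/LT)·Σ NO and broadcasts an
  *error complex spike* iff IO = ℰ − ℐ > 0, fixing the update sign
  c = sign(IO):

      w → w − α_w·c·Σ_t η_l(t)·M_is(t)        (M→PC, perturbation-gated)
      v → [v + α_v·c·Σ_t M_is(t)]₊            (M→NO, rectified)

  The NO pathway learns to cancel the average error so that the sign of the
  residual reports whether the perturbation helped — a biologically
  plausible stochastic gradient descent with 400 output variables (40 PN ×
  10 time bins) optimised per movement from a single scalar error.
* **Marr-Albus-Ito baseline** (`sgdege.mai`) — the classical
  climbing-fibre-as-error model: it minimises the population-average signed
  error but cannot optimise per-cell, per-bin firing profiles, and with an
  unsigned error the rates simply saturate.
* **Reduced model** (`sgdege.reduced`) — a single P-cell in the (P, 𝒥)
  phase plane, with the corridor geometry, the analytic fixed point
  (R − A(q+1)/2, qR + (1−q²)A/2) for q < 1, the sufficient convergence
  conditions, and the q ≥ 1 failure mode.
* **Analog perceptron** (`sgdege.perceptron`) — SGDEGE versus the delta
  rule on p random input→rate associations over Nm = 1000 fibres, with
  empirical storage-capacity scanning around the predicted capacity of 391
  patterns.

## Worked example

```python
from sgdege import NetworkParams, simulate_microzone
from sgdege.recipes import error_windows

params = NetworkParams()          # standard configuration, 2 patterns
traj, state, patterns, targets = simulate_microzone(params, 120_000, seed=1)
init, tail = error_windows(traj, 60_000)
print(f"initial error {init:.2f} Hz, final error {tail:.2f} Hz, "
      f"fold reduction {init / tail:.1f}")
```

prints

```
initial error 17.83 Hz, final error 1.47 Hz, fold reduction 12.1
```

i.e. learning two interleaved movements in parallel reduces the global
output error from ~18 Hz to ~1.5 Hz (an ~12-fold reduction) over 60,000
trials per pattern, with the olivary inhibition tracking the error to
within ~0.005 Hz midway through the run (`traj` columns `error_hz`,
`inhibition_hz`).

The same experiments are available from the shell:

```sh
sgdege recipe fig8 --seed 1 --out out/fig8      # full network learning
sgdege recipe fig2 --seed 1 --out out/fig2      # Marr-Albus-Ito failure modes
sgdege reduced --p0 60.4 --j0 20 --trials 10000 # (P, J) phase-plane run
sgdege perceptron --algorithm sgdege --patterns 1 --trials 4000
sgdege capacity --p-grid 300,450 --trials 20000 # capacity bracket
```

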