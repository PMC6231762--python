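# Methods

## Models

### Microzone network

Purkinje cells sit on an S×L grid (S sagittal, L lateral); the l-th column
inhibits the l-th projection neurone (PN) and the l-th nucleo-olivary
neurone (NO) of the cerebellar nuclei. N mossy fibres per sagittal row (N·S
in total) subsume granule cells and interneurons; each fibre contacts each
Purkinje cell of its row with probability 1/2 (mask σ) and exactly one PN
and one NO (the same index l(i,s)). All units are rate neurons with the
saturating threshold-linear f-I curve Φ(x) = min(max(x, 0), r_max).

A movement is T time bins of binary mossy activity: each pattern activates
exactly N·S/2 fibres, each in a single uniformly drawn bin. Targets are the
PN rates R_l(t), i.i.d. uniform on [0, 2·r̄_D]. Rates per trial:

    PC_sl(t) = Φ( Σ_i w_isl σ_isl M_is(t) + η_l(t)·A )
    PN_l(t)  = Φ( u_M→PN Σ_(i,s)→l M_is(t) + u_PC→PN Σ_s PC_sl(t) )
    NO_l(t)  = Φ( Σ_(i,s)→l v_is M_is(t) + q·u_PC→PN Σ_s PC_sl(t) )

η_l(t) marks a perturbation complex spike of climbing fibre l (probability
ρ per presentation, one uniformly drawn bin). The fixed weights
u_M→PN = 4TL·r̄_D/(NS) and u_PC→PN = −r̄_D/(r̄_PC·S) and the uniform initial
distributions of w (on [0, 8T·r̄_PC/N]) and v (on [0, (NO₀+q·r̄_D)·4TL/(NS)])
set the initial mean rates to r̄_PC, r̄_D and NO₀. NO₀ = 15 Hz puts the
initial olivary imbalance |ℰ − ℐ| at order 1 Hz.

After each movement (evaluate-then-update; updates are offline) the sign
c = sign(ℰ − ℐ) gates both plasticity rules; see the README for the update
equations. Ties (ℰ = ℐ) count as "no error complex spike", c = −1. Weight
positivity is enforced on v only; w is unconstrained (effective negative
weights can arise through interneuron pathways). Patterns are presented
cyclically (a shuffled mode would change nothing statistically for p = 2 and
is not provided).

Default parameters: S=10, L=40, T=10, N=2000, p=2, r_max=300 Hz, ρ=0.03,
A=2 Hz, α_w=0.02, α_v=2·10⁻⁴, r̄_PC=50 Hz, r̄_D=30 Hz, q=0.5, NO₀=15 Hz
(hence u_M→PN=2.4, u_PC→PN=−0.06).

**Trial counting.** One "trial" of a pattern means one presentation of that
pattern; with p interleaved patterns, per-pattern trial k spans
presentations p·k … p·k+p−1. All reported windows (initial error: first 500
per-pattern trials; tracking: 10,000–20,000; final error: 55,000–60,000)
are on the per-pattern axis. The standard run is 60,000 trials per pattern,
i.e. 120,000 presentations. At that point the error has essentially reached
its asymptote (~1.4–1.5 Hz; running twice as long changes it by a few
percent at most).

### Marr-Albus-Ito baseline

Same architecture and initial weights, no perturbations and no NO
population. The climbing fibre broadcasts the movement error itself; when
it is positive all synapses of fibres active in the pattern are depressed
by α_w, otherwise every M→PC weight drifts up by β_w = 0.002. Signed mode
uses mean(R − PN) and converges — but only in the population mean; unsigned
mode uses mean|PN − R|, which is never negative, so depression runs away,
Purkinje rates pin at zero and the error grows. Demonstration runs draw
target means away from r̄_D (the paper-style protocol varies them between
10 and 50 Hz): 50 Hz for the signed demonstration (so the mean-rate
relaxation is visible against a large initial gap) and 10 Hz for the
unsigned one (so the runaway is conspicuous).

### Reduced model

State (P, 𝒥): P the rate of a single principal cell (target R), 𝒥 the
mossy drive to its NO pathway. Perturbed trials (probability ρ): error
|P+A−R|, estimate [𝒥−q(P+A)]₊, and both variables step (P by ∓ΔP, 𝒥 by
±Δ𝒥); unperturbed trials move 𝒥 only. The estimate on unperturbed trials
is rectified, [𝒥−qP]₊, for consistency with the definition of the
inhibition; a flag (`rectify_unperturbed=False`) exposes the literal
unrectified comparison — the two differ only in the far region 𝒥 < qP.
Sign ties again count as c = −1.

The update signs flip across the lines C: 𝒥−qP−qA = |P−R+A| and D:
𝒥−qP = |P−R|. For q < 1, C⁺ and D⁻ meet at (R − A(q+1)/2, qR + (1−q²)A/2);
trajectories drift to a corridor, descend it linearly on average, and end
fluctuating around the intersection, so the long-run error is A(q+1)/2.
Sufficient conditions for corridor convergence: 0 < ρ < 1, Δ𝒥 < (1−q)·A and
ΔP + Δ𝒥/(1+q) < A, plus q < 1.

Degenerate input worth knowing about: if the start point is commensurate
with the ΔP lattice such that P exactly reaches R − A, the perturbed error
is exactly zero there and the tie rule bounces P back — a measure-zero trap
that disappears for any non-lattice initial condition. Demonstration runs
therefore use starts like P₀ = 130.4. For q ≥ 1 there is no fixed point:
at q = 1 the rate wanders without a restoring force, for q > 1 it drifts
monotonically past the target.

### Analog perceptron

One P-cell, Nm = 1000 Bernoulli(f = 0.2) binary inputs, non-negative
weights, rate P = Φ(γ(w·x − θ) + A·[perturbed]) saturating at
P_max = 100 Hz, θ = 12.85, γ = 1. SGDEGE uses the reduced-model logic with
the estimate [v·x − qP]₊; per-synapse steps are ΔP/(γ·n_active) and
Δ𝒥/n_active, so that one update moves the pattern's rate (or NO drive) by
exactly the reduced-model step while nothing clips — this is what makes the
corridor analysis and the floor A(1+q)/2 apply pattern by pattern. The
delta rule moves the rate by lr·(R − P) per presentation (lr = 0.1; the
point of the comparison is that it may take large steps for large errors).
Algorithm parameters: A=2, ΔP=0.2, Δ𝒥=0.4, ρ=0.2, q=0.5.

**Target statistics.** The storage capacity of a perceptron with
sign-constrained weights depends jointly on the threshold and on the
input-output association statistics. With binary f = 0.2 inputs the
feasibility of the association system w·x = θ + R (w ≥ 0) is governed by
the dispersion of the required currents: wide target bands (e.g. uniform on
[0, 60] Hz) are infeasible beyond ~60–100 patterns at θ = 12.85, far below
the theoretical capacity of 391 quoted for these parameters, whereas the
printed threshold is capacity-optimal for a narrow band. Defaults are
therefore targets uniform on [3, 7] Hz, for which independent non-negative
least-squares feasibility checks place the capacity transition at ~390–410
patterns, bracketing the prediction; the band is configurable
(`target_lo`, `target_hi`) and recorded with every run. Initial weights are
uniform on [0, 2θ/(f·Nm)] (mean current = θ, so initial rates are near
zero) and initial v puts the mean NO drive at 5 Hz, the order of the
initial error, so error tracking starts near balance.

Capacity scanning runs the chosen rule at each pattern count and reports
the largest p whose tail error is below a threshold (delta rule) or within
a tolerance of the perturbation floor (SGDEGE). The standard check is a
coarse bracket (p = 300 learns to zero, p = 450 does not); a fine scan over
a p-grid around 391 uses the same entry point with more grid points and
trials.

## Numerical implementation

The simulation loop exploits the sparsity of the inputs: per pattern, only
the N·S/2 active (fibre, bin) pairs matter. The loop caches, per pattern,
the mossy synaptic drive to every PC bin (S·T × L) and to every NO bin
(T × L) and updates these caches incrementally as weights change (a trial
touches ~ρ·L climbing fibres and the active fibres only). Caches are
recomputed exactly from the weight matrices every 2,000 trials, which
bounds floating-point drift; the whole loop is plain double-precision
numpy. A direct per-trial evaluation of the rate equations
(`run_simulation(..., fast=False)`) consumes identical random draws and is
used in tests to verify trajectory-for-trajectory equality; both are
checked against naive nested-loop transcriptions of the equations on small
instances at 10⁻¹⁰ relative tolerance. A full-size 60,000-trials-per-
pattern run takes ~25 s on one CPU core. The Marr-Albus-Ito runs use the
same caching plus closed-form weight reconstruction (all its updates are
spatially uniform), and the perceptron inner loops are numba-compiled.

Randomness: a single root seed spawns independent named substreams
(patterns, targets, connectivity, initial w, initial v, perturbations) via
`numpy.random.SeedSequence.spawn`, so changing the trial count or consuming
one stream never alters another. Every run is reproducible from
(parameters, seed), and run metadata embeds both.

## What the synthetic data does and does not emulate

Inputs are the idealised code of the model: exactly half the fibres active
per movement, one bin each, independent across patterns; targets i.i.d.
uniform. Real mossy-fibre/granule-cell activity is temporally extended,
correlated across fibres and movements, and not half-active; passing tests
therefore demonstrate the algorithm's behaviour under the model's stated
conditions, not robustness to realistic input statistics. Likewise the
olive is a threshold comparator (no olivary dynamics, conduction delays or
eligibility-trace kinetics), plasticity is offline after each movement, and
movement production/evaluation is abstracted into the target comparison.

## Known limitations

* The final-error level of the network run (~1.45–1.6 Hz across seeds at
  the standard window) sits a few percent above its asymptote; seeds differ
  by ~±0.1 Hz.
* The analytic in-corridor convergence *rate* of the reduced model is not
  implemented; tests assert the empirical linear-descent property instead.
* The theoretical capacity formula is not implemented; capacity is
  bracketed empirically.
* For q ≥ 1 the reduced model's P is not rectified at zero; it is an
  abstract variable and diverges (q > 1) by design.
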