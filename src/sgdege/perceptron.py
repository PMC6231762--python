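"""Analog perceptron trained by SGDEGE and by the delta rule.

A single rate unit (``P``-cell) receives ``Nm`` binary inputs with coding
level ``f`` through non-negative weights and fires at
``P = phi(gamma*(w.x - theta) + A*[perturbed])`` saturating at ``Pmax``.
``p`` random input patterns must be associated with uniformly distributed
target rates.  SGDEGE uses the same perturbation/estimated-error logic as
the reduced model; per-synapse steps are scaled by ``1/(gamma*n_active)`` so
that one update moves the pattern's rate by exactly ``dP`` (or the
nucleo-olivary drive by ``dJ``) while no weight is clipped at zero.  The
delta rule uses the full signed error, moving the rate by ``lr*(R - P)`` per
presentation, and serves as the full-information comparison: it is faster
and reaches zero error below the storage capacity, while SGDEGE's final
error is limited by the ongoing perturbations to ``A*(1+q)/2``.

The inner loops are compiled with numba; patterns are presented cyclically
and the mean unperturbed error over patterns is recorded once per sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "PerceptronParams",
    "PerceptronState",
    "PatternSet1D",
    "make_patterns_1d",
    "init_perceptron",
    "perceptron_rate",
    "sgdege_percep_trial",
    "delta_rule_trial",
    "run_perceptron",
    "capacity_scan",
]


@dataclass(frozen=True)
class PerceptronParams:
    """Analog-perceptron and SGDEGE parameters (defaults: standard configuration)."""

    Nm: int = 1000  # input fibres
    f: float = 0.2  # coding level (P(input active))
    Pmax: float = 100.0  # Hz, saturation
    theta: float = 12.85  # threshold, input-current units
    gamma: float = 1.0  # Hz per unit current
    A: float = 2.0  # Hz, perturbation amplitude
    rho: float = 0.2  # perturbation probability per trial
    dP: float = 0.2  # Hz, rate-space P step
    dJ: float = 0.4  # Hz, rate-space J step
    q: float = 0.5  # P -> NO inhibition strength
    p: int = 1  # number of patterns
    target_lo: float = 3.0  # Hz, lower edge of the uniform target band
    target_hi: float = 7.0  # Hz, upper edge of the uniform target band
    v0_mean_drive: float = 5.0  # Hz, initial mean NO drive v.x

    def __post_init__(self) -> None:
        if not (0.0 < self.f < 1.0):
            raise ValueError("f must lie in (0, 1)")
        if self.Nm < 1 or self.Pmax <= 0 or self.gamma <= 0:
            raise ValueError("Nm, Pmax and gamma must be positive")
        if not (0.0 <= self.target_lo < self.target_hi <= self.Pmax):
            raise ValueError("target band must satisfy 0 <= lo < hi <= Pmax")


@dataclass
class PerceptronState:
    """Non-negative input weights to the P-cell (w) and to the NO pathway (v)."""

    w: np.ndarray
    v: np.ndarray


@dataclass(frozen=True)
class PatternSet1D:
    """Binary input vectors x (p, Nm) with Bernoulli(f) entries and targets R (p,)."""

    x: np.ndarray
    R: np.ndarray


def make_patterns_1d(params: PerceptronParams, seed) -> PatternSet1D:
    """Draw the random input/target associations to be stored.

    Inputs are Bernoulli(f); target rates are uniform on
    ``[target_lo, target_hi]``.  The storage capacity of the perceptron
    depends on these input-output statistics jointly with the threshold: the
    default narrow band is the regime in which the default ``theta`` is
    capacity-optimal.
    """
    rng = np.random.default_rng(seed)
    x = (rng.random((params.p, params.Nm)) < params.f).astype(np.uint8)
    R = rng.uniform(params.target_lo, params.target_hi, size=params.p)
    return PatternSet1D(x=x, R=R)


def init_perceptron(params: PerceptronParams, seed) -> PerceptronState:
    """Uniform initial weights.

    ``w`` is uniform on ``[0, 2*theta/(f*Nm)]`` so the initial mean input
    current equals the threshold (initial rates of order zero); ``v`` is
    scaled analogously so the initial mean NO drive is ``v0_mean_drive``.
    """
    rng = np.random.default_rng(seed)
    w_hi = 2.0 * params.theta / (params.f * params.Nm)
    v_hi = 2.0 * params.v0_mean_drive / (params.f * params.Nm)
    w = rng.uniform(0.0, w_hi, size=params.Nm)
    v = rng.uniform(0.0, v_hi, size=params.Nm)
    return PerceptronState(w=w, v=v)


def perceptron_rate(state: PerceptronState, x_mu: np.ndarray, perturbed: bool, params: PerceptronParams) -> float:
    """P-cell rate for one input vector: phi(gamma*(w.x - theta) + A*[pert])."""
    current = float(state.w @ x_mu.astype(float)) - params.theta
    rate = params.gamma * current + (params.A if perturbed else 0.0)
    return float(min(max(rate, 0.0), params.Pmax))


def sgdege_percep_trial(state: PerceptronState, pattern: PatternSet1D, mu: int, params: PerceptronParams, rng: np.random.Generator) -> PerceptronState:
    """One SGDEGE presentation of pattern ``mu``, in place.

    Perturbation with probability ``rho``; error ``|P - R|`` with the
    (possibly perturbed) rate; estimate ``[v.x - q*P]_+``; sign
    ``c = sign(E - I)`` with ties negative.  On perturbed trials the active
    ``w`` move by ``-c*dP/(gamma*n_active)`` each; the active ``v`` always
    move by ``+c*dJ/n_active``; both rectified at zero.
    """
    x = pattern.x[mu].astype(float)
    n_act = float(x.sum())
    perturbed = bool(rng.random() < params.rho)
    P = perceptron_rate(state, pattern.x[mu], perturbed, params)
    err = abs(P - pattern.R[mu])
    est = max(float(state.v @ x) - params.q * P, 0.0)
    c = 1.0 if err - est > 0 else -1.0
    if perturbed and n_act > 0:
        state.w = np.maximum(state.w - c * params.dP / (params.gamma * n_act) * x, 0.0)
    if n_act > 0:
        state.v = np.maximum(state.v + c * params.dJ / n_act * x, 0.0)
    return state


def delta_rule_trial(state: PerceptronState, pattern: PatternSet1D, mu: int, learning_rate: float, params: PerceptronParams) -> PerceptronState:
    """One delta-rule presentation: w on active fibres moves by
    ``lr*(R - P)/(gamma*n_active)`` each (rate moves by ``lr*(R - P)``),
    rectified at zero.  No perturbation, no v."""
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    x = pattern.x[mu].astype(float)
    n_act = float(x.sum())
    P = perceptron_rate(state, pattern.x[mu], False, params)
    if n_act > 0:
        step = learning_rate * (pattern.R[mu] - P) / (params.gamma * n_act)
        state.w = np.maximum(state.w + step * x, 0.0)
    return state


@njit(cache=True)
def _sgdege_kernel(w, v, idx, ptr, n_act, R, n_sweeps, record_every,
                   A, rho, dP, dJ, q, gamma, theta, Pmax, seed):
    np.random.seed(seed)
    p = R.shape[0]
    n_rec = n_sweeps // record_every
    curve = np.zeros(n_rec)
    sweep_ix = np.zeros(n_rec, dtype=np.int64)
    r = 0
    for sweep in range(n_sweeps):
        for mu in range(p):
            cur = -theta
            vd = 0.0
            for k in range(ptr[mu], ptr[mu + 1]):
                cur += w[idx[k]]
                vd += v[idx[k]]
            perturbed = np.random.random() < rho
            rate = gamma * cur
            if perturbed:
                rate += A
            if rate < 0.0:
                rate = 0.0
            elif rate > Pmax:
                rate = Pmax
            err = abs(rate - R[mu])
            est = vd - q * rate
            if est < 0.0:
                est = 0.0
            c = 1.0 if err - est > 0.0 else -1.0
            na = n_act[mu]
            if perturbed and na > 0:
                dw = -c * dP / (gamma * na)
                for k in range(ptr[mu], ptr[mu + 1]):
                    nw = w[idx[k]] + dw
                    w[idx[k]] = nw if nw > 0.0 else 0.0
            if na > 0:
                dv = c * dJ / na
                for k in range(ptr[mu], ptr[mu + 1]):
                    nv = v[idx[k]] + dv
                    v[idx[k]] = nv if nv > 0.0 else 0.0
        if (sweep + 1) % record_every == 0:
            tot = 0.0
            for mu in range(p):
                cur = -theta
                for k in range(ptr[mu], ptr[mu + 1]):
                    cur += w[idx[k]]
                rate = gamma * cur
                if rate < 0.0:
                    rate = 0.0
                elif rate > Pmax:
                    rate = Pmax
                tot += abs(rate - R[mu])
            curve[r] = tot / p
            sweep_ix[r] = sweep
            r += 1
    return sweep_ix, curve


@njit(cache=True)
def _delta_kernel(w, idx, ptr, n_act, R, n_sweeps, record_every,
                  lr, gamma, theta, Pmax):
    p = R.shape[0]
    n_rec = n_sweeps // record_every
    curve = np.zeros(n_rec)
    sweep_ix = np.zeros(n_rec, dtype=np.int64)
    r = 0
    for sweep in range(n_sweeps):
        for mu in range(p):
            cur = -theta
            for k in range(ptr[mu], ptr[mu + 1]):
                cur += w[idx[k]]
            rate = gamma * cur
            if rate < 0.0:
                rate = 0.0
            elif rate > Pmax:
                rate = Pmax
            na = n_act[mu]
            if na > 0:
                dw = lr * (R[mu] - rate) / (gamma * na)
                for k in range(ptr[mu], ptr[mu + 1]):
                    nw = w[idx[k]] + dw
                    w[idx[k]] = nw if nw > 0.0 else 0.0
        if (sweep + 1) % record_every == 0:
            tot = 0.0
            for mu in range(p):
                cur = -theta
                for k in range(ptr[mu], ptr[mu + 1]):
                    cur += w[idx[k]]
                rate = gamma * cur
                if rate < 0.0:
                    rate = 0.0
                elif rate > Pmax:
                    rate = Pmax
                tot += abs(rate - R[mu])
            curve[r] = tot / p
            sweep_ix[r] = sweep
            r += 1
    return sweep_ix, curve


def _csr(x: np.ndarray):
    """Active-fibre indices of each pattern in compressed (idx, ptr) form."""
    idx_list = [np.nonzero(row)[0] for row in x]
    ptr = np.zeros(len(idx_list) + 1, dtype=np.int64)
    ptr[1:] = np.cumsum([a.size for a in idx_list])
    idx = np.concatenate(idx_list) if idx_list else np.zeros(0, dtype=np.int64)
    n_act = np.array([float(a.size) for a in idx_list])
    return idx.astype(np.int64), ptr, n_act


def run_perceptron(
    algorithm: str,
    params: PerceptronParams,
    n_trials_per_pattern: int,
    seed: int,
    *,
    learning_rate: float = 0.1,
    record_every: int = 1,
    state: PerceptronState | None = None,
    pattern: PatternSet1D | None = None,
):
    """Learn the stored associations; returns ``(curve, final_state, pattern)``.

    ``curve`` is a DataFrame (sweep, mean_error_hz) of the mean unperturbed
    error over patterns, sampled every ``record_every`` sweeps; patterns are
    presented cyclically.  ``seed`` spawns the pattern, initial-weight and
    perturbation streams; a zero-sweep run returns the initial error.
    """
    if algorithm not in ("sgdege", "delta"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    ss = np.random.SeedSequence(seed).spawn(3)
    if pattern is None:
        pattern = make_patterns_1d(params, ss[0])
    if state is None:
        state = init_perceptron(params, ss[1])
    idx, ptr, n_act = _csr(pattern.x)
    if n_trials_per_pattern == 0:
        rates = np.array(
            [perceptron_rate(state, pattern.x[mu], False, params) for mu in range(params.p)]
        )
        curve = pd.DataFrame({"sweep": [0], "mean_error_hz": [float(np.abs(rates - pattern.R).mean())]})
        return curve, state, pattern
    if algorithm == "sgdege":
        pert_seed = int(np.random.default_rng(ss[2]).integers(0, 2**31 - 1))
        sweep_ix, curve = _sgdege_kernel(
            state.w, state.v, idx, ptr, n_act, pattern.R,
            n_trials_per_pattern, record_every,
            params.A, params.rho, params.dP, params.dJ, params.q,
            params.gamma, params.theta, params.Pmax, pert_seed,
        )
    else:
        sweep_ix, curve = _delta_kernel(
            state.w, idx, ptr, n_act, pattern.R,
            n_trials_per_pattern, record_every,
            learning_rate, params.gamma, params.theta, params.Pmax,
        )
    return pd.DataFrame({"sweep": sweep_ix, "mean_error_hz": curve}), state, pattern


def capacity_scan(
    algorithm: str,
    params: PerceptronParams,
    p_grid,
    n_trials_per_pattern: int,
    error_threshold: float,
    seed: int,
    *,
    learning_rate: float = 0.1,
    tail_frac: float = 0.1,
):
    """Empirical storage-capacity bracketing.

    Runs learning at each pattern count in ``p_grid`` (ascending) and
    returns ``(critical_p, table)``: the largest p whose final mean error
    (tail average of the learning curve) is below ``error_threshold`` - for
    SGDEGE the threshold should sit just above the perturbation floor
    ``A*(1+q)/2``.  ``critical_p`` is None if no grid point passes.
    """
    p_grid = list(p_grid)
    if not p_grid:
        raise ValueError("p_grid must not be empty")
    if sorted(p_grid) != p_grid:
        raise ValueError("p_grid must be sorted ascending")
    rows = []
    critical = None
    for k, p in enumerate(p_grid):
        pars = PerceptronParams(**{**_asdict(params), "p": int(p)})
        rec = max(1, n_trials_per_pattern // 200)
        curve, _, _ = run_perceptron(
            algorithm, pars, n_trials_per_pattern, seed + k, learning_rate=learning_rate, record_every=rec
        )
        tail = curve.mean_error_hz.values[-max(1, int(tail_frac * len(curve))):]
        final = float(tail.mean())
        rows.append({"p": int(p), "final_error_hz": final})
        if final < error_threshold:
            critical = int(p)
    return critical, pd.DataFrame(rows)


def _asdict(params: PerceptronParams) -> dict:
    from dataclasses import asdict

    return asdict(params)
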