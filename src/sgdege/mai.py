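"""Marr-Albus-Ito baseline: climbing fibre as a direct error signal.

The comparison model shares the microzone architecture (M, PC and PN cell
types, connectivity and initial weights) but has no perturbations and no
nucleo-olivary population.  The climbing fibre broadcasts the movement error
itself and plasticity follows the classical picture: whenever the error is
positive, active mossy-fibre synapses onto Purkinje cells are depressed by
``alpha_w``; otherwise *all* M->PC weights drift upwards by ``beta_w``.

Two error definitions are compared.  The *signed* error, mean(R - PN), can
be minimised by this rule - but only the population-average rate converges;
individual firing profiles remain wrong.  The *unsigned* error, mean|PN - R|,
is never negative, so the rule depresses continuously, Purkinje rates pin at
zero and the error grows.  This failure motivates the perturbation-based
algorithm of :mod:`sgdege.network`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkParams, NetworkState, init_weights, nuclear_rates, purkinje_rates
from .patterns import build_connectivity, generate_patterns, generate_targets, substreams

__all__ = ["MAIParams", "mai_error", "mai_update", "run_mai", "MAIResult"]


@dataclass(frozen=True)
class MAIParams:
    """Plasticity parameters of the simplified model.

    ``alpha_w`` is the LTD step applied to active synapses when the error is
    positive; ``beta_w`` is the slow LTP drift applied to all synapses
    otherwise.  ``error_mode`` selects the signed (mean(R - PN)) or unsigned
    (mean|PN - R|) definition of the broadcast error.
    """

    alpha_w: float = 0.02
    beta_w: float = 0.002
    error_mode: str = "signed"

    def __post_init__(self) -> None:
        if self.alpha_w <= 0 or self.beta_w <= 0:
            raise ValueError("alpha_w and beta_w must be positive")
        if self.error_mode not in ("signed", "unsigned"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")


def mai_error(pn: np.ndarray, target: np.ndarray, mode: str) -> float:
    """Movement error broadcast by the climbing fibres.

    ``signed`` returns mean(R - PN) over (l, t) (can be negative);
    ``unsigned`` returns mean|PN - R|.
    """
    if pn.shape != target.shape:
        raise ValueError("PN and target shapes differ")
    if mode == "signed":
        return float(np.mean(target - pn))
    if mode == "unsigned":
        return float(np.abs(pn - target).mean())
    raise ValueError(f"unknown error_mode {mode!r}")


def mai_update(state: NetworkState, pattern_m: np.ndarray, error: float, params: MAIParams) -> NetworkState:
    """One plasticity step, in place.

    Positive error: every M->PC weight of a fibre active anywhere in the
    pattern is decreased by ``alpha_w`` (times its number of active bins).
    Otherwise all weights increase by ``beta_w``.  Weights are unconstrained
    in sign.
    """
    if error > 0:
        state.w -= params.alpha_w * pattern_m.sum(axis=2, dtype=float)[:, :, np.newaxis]
    else:
        state.w += params.beta_w
    return state


@dataclass
class MAIResult:
    """Trajectory and before/after snapshots of a simplified-model run."""

    trajectory: pd.DataFrame
    state: NetworkState
    pn_initial: np.ndarray  # (p, L, T)
    pn_final: np.ndarray  # (p, L, T)
    pc_final: np.ndarray  # (p, S, L, T)
    targets: np.ndarray  # (p, L, T)


def _pn_rates_all(state, patterns, params):
    """Unperturbed PN (and PC) rates for every pattern."""
    sh = params.shape
    eta0 = np.zeros((sh.L, sh.T), dtype=np.uint8)
    pns, pcs = [], []
    for mu in range(sh.p):
        pc = purkinje_rates(state, patterns.m[mu], eta0, params)
        pn, _ = nuclear_rates(state, patterns.m[mu], pc, params)
        pns.append(pn)
        pcs.append(pc)
    return np.stack(pns), np.stack(pcs)


def run_mai(
    mai_params: MAIParams,
    net_params: NetworkParams,
    n_trials: int,
    seed: int,
    *,
    target_mean: float = 10.0,
    patterns=None,
    targets=None,
) -> MAIResult:
    """Run the simplified model for ``n_trials`` cyclic presentations.

    The target distribution mean is configurable (uniform on
    ``[0, 2*target_mean]``): relaxation of the mean PN rate towards the mean
    target is only visible when the two initially differ, so means away from
    ``rbar_D`` are used for the demonstration runs.

    Because every update is spatially uniform over the active synapses, the
    simulation tracks the per-pattern synaptic drives incrementally; the
    weight matrix itself is reconstructed from the event counts at the end.
    """
    sh = net_params.shape
    N, S, L, T, p = sh.N, sh.S, sh.L, sh.T, sh.p
    NS, ST = N * S, S * T
    streams = substreams(seed)
    if patterns is None:
        patterns = generate_patterns(sh, streams["patterns"])
    if targets is None:
        targets = generate_targets(L, T, p, target_mean, streams["targets"])
    conn = build_connectivity(sh, streams["connectivity"])
    state = init_weights(net_params, conn, rng_w=streams["init_w"], rng_v=streams["init_v"])

    sig2 = conn.sigma.reshape(NS, L)
    pn_l = conn.pn_assign.reshape(NS)
    # Per-pattern caches of the mossy drive to each PC bin (S*T, L), plus the
    # precomputed uniform-step increments:
    #   ltd[mu][nu]: effect on pattern nu's PC drive of a unit decrement of
    #   all synapses of fibres active in pattern mu (sigma-weighted counts);
    #   drift[nu]: effect of a unit increment of every weight.
    act, key_pc, drive_pn, r_lt = [], [], [], []
    pc_in = []
    for mu in range(p):
        m2 = patterns.m[mu].reshape(NS, T)
        f, t = np.nonzero(m2)
        act.append(f)
        key = (f % S) * T + t
        key_pc.append(key)
        cache = np.zeros((ST, L))
        W2 = state.w.reshape(NS, L)
        np.add.at(cache, key, W2[f] * sig2[f])
        pc_in.append(cache)
        drive_pn.append(
            net_params.u_M_PN
            * np.bincount(pn_l[f] * T + t, minlength=L * T).astype(float).reshape(L, T)
        )
        r_lt.append(targets.r[mu])
    ltd = [[np.zeros((ST, L)) for _ in range(p)] for _ in range(p)]
    drift = [np.zeros((ST, L)) for _ in range(p)]
    for nu in range(p):
        np.add.at(drift[nu], key_pc[nu], sig2[act[nu]].astype(float))
        for mu in range(p):
            common = np.isin(act[nu], act[mu], assume_unique=True)
            np.add.at(ltd[mu][nu], key_pc[nu][common], sig2[act[nu][common]].astype(float))

    pn0, _ = _pn_rates_all(state, patterns, net_params)
    n_ltd = np.zeros(p, dtype=np.int64)  # LTD events while pattern mu shown
    n_ltp = 0

    errors = np.empty(n_trials)
    unsigned = np.empty(n_trials)
    rmax = net_params.rmax
    for trial in range(n_trials):
        mu = trial % p
        pc = np.clip(pc_in[mu], 0.0, rmax)
        pc_sum = pc.reshape(S, T, L).sum(axis=0).T  # (L, T)
        pn = np.clip(drive_pn[mu] + net_params.u_PC_PN * pc_sum, 0.0, rmax)
        e = mai_error(pn, r_lt[mu], mai_params.error_mode)
        errors[trial] = e
        unsigned[trial] = float(np.abs(pn - r_lt[mu]).mean())
        if e > 0:
            n_ltd[mu] += 1
            for nu in range(p):
                pc_in[nu] -= mai_params.alpha_w * ltd[mu][nu]
        else:
            n_ltp += 1
            for nu in range(p):
                pc_in[nu] += mai_params.beta_w * drift[nu]

    # Reconstruct the final weight matrix from the uniform update counts.
    state.w += mai_params.beta_w * n_ltp
    for mu in range(p):
        active_map = patterns.m[mu].sum(axis=2, dtype=float)  # (N, S)
        state.w -= mai_params.alpha_w * n_ltd[mu] * active_map[:, :, np.newaxis]

    pn1, pc1 = _pn_rates_all(state, patterns, net_params)
    traj = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "pattern": np.arange(n_trials) % p,
            "pattern_trial": np.arange(n_trials) // p,
            "error_hz": errors,
            "unsigned_error_hz": unsigned,
        }
    )
    return MAIResult(
        trajectory=traj,
        state=state,
        pn_initial=pn0,
        pn_final=pn1,
        pc_final=pc1,
        targets=targets.r.copy(),
    )
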