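"""Full microzone model learning by stochastic gradient descent with
estimated global errors (SGDEGE).

The network contains S*L Purkinje cells (PC) on a grid, L nuclear projection
neurones (PN), L nucleo-olivary neurones (NO) and N*S binary mossy fibres
(M).  All units are rate units with a saturating threshold-linear f-I curve.
Each trial presents one spatiotemporal input pattern ("movement"):

* each of the L climbing fibres independently emits a *perturbation* complex
  spike with probability ``rho``, transiently raising the firing of its S
  Purkinje cells by ``A`` Hz in one random time bin;
* the movement error ``E`` (mean absolute deviation of PN rates from their
  targets) is compared at the inferior olive with the inhibition ``I`` (mean
  NO rate); an *error* complex spike is broadcast iff ``E - I > 0``, giving
  the update sign ``c``;
* mossy-fibre synapses onto perturbed Purkinje cells are changed by
  ``-alpha_w * c`` (only where the fibre was active in the perturbed bin),
  and mossy-fibre synapses onto nucleo-olivary cells by ``+alpha_v * c``
  (rectified at zero), so that the NO pathway learns to cancel the average
  error while the PC pathway descends the error gradient signalled by the
  perturbations.

Weights are evaluated before they are updated (offline updates after each
movement).  :func:`run_simulation` exploits the sparsity of the binary input
patterns and maintains incrementally-updated synaptic drives, which makes the
full-size 60,000-trial run take well under a minute; ``fast=False`` selects a
direct per-trial evaluation of the rate equations that consumes the same
random draws and produces the same trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patterns import (
    Connectivity,
    MossyPatternSet,
    ShapeParams,
    TargetRates,
    build_connectivity,
    generate_patterns,
    generate_targets,
    substreams,
)

__all__ = [
    "NetworkParams",
    "NetworkState",
    "phi",
    "init_weights",
    "draw_perturbation",
    "perturbation_eta",
    "purkinje_rates",
    "nuclear_rates",
    "movement_error",
    "olive_inhibition",
    "ecs_sign",
    "sgdege_update",
    "run_simulation",
    "simulate_microzone",
]


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the microzone simulation.

    Defaults are the standard full-scale configuration.  The fixed synaptic
    weights are derived quantities: ``u_M_PN = 4*T*L*rbar_D/(N*S)``,
    ``u_PC_PN = -rbar_D/(rbar_PC*S)`` and ``u_PC_NO = q*u_PC_PN``, chosen so
    that initial mean rates are ``rbar_PC`` for Purkinje cells, ``rbar_D``
    for projection neurones and ``NO0`` for nucleo-olivary neurones.
    """

    shape: ShapeParams = field(default_factory=lambda: ShapeParams(S=10, L=40, T=10, N=2000, p=2))
    rmax: float = 300.0  # Hz, saturation of the f-I curve
    rho: float = 0.03  # pCS probability per climbing fibre per presentation
    A: float = 2.0  # Hz, perturbation amplitude
    alpha_w: float = 0.02  # learning rate, M->PC synapses
    alpha_v: float = 2e-4  # learning rate, M->NO synapses
    rbar_PC: float = 50.0  # Hz, mean Purkinje cell rate
    rbar_D: float = 30.0  # Hz, mean nuclear (PN and target) rate
    q: float = 0.5  # PC->NO strength relative to PC->PN
    NO0: float = 15.0  # Hz, initial mean NO rate

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.rmax <= 0 or self.q < 0:
            raise ValueError("rmax must be positive and q non-negative")

    @property
    def u_M_PN(self) -> float:
        sh = self.shape
        return 4.0 * sh.T * sh.L * self.rbar_D / (sh.N * sh.S)

    @property
    def u_PC_PN(self) -> float:
        return -self.rbar_D / (self.rbar_PC * self.shape.S)

    @property
    def u_PC_NO(self) -> float:
        return self.q * self.u_PC_PN

    @property
    def w_init_max(self) -> float:
        """Upper bound of the uniform initial M->PC weight distribution."""
        return 8.0 * self.shape.T * self.rbar_PC / self.shape.N

    @property
    def v_init_max(self) -> float:
        """Upper bound of the uniform initial M->NO weight distribution."""
        sh = self.shape
        return (self.NO0 + self.q * self.rbar_D) * 4.0 * sh.T * sh.L / (sh.N * sh.S)

    @property
    def n_output_variables(self) -> int:
        """Number of optimised outputs per movement (PN rates x time bins)."""
        return self.shape.L * self.shape.T


@dataclass
class NetworkState:
    """Plastic weights and wiring of the microzone.

    ``w`` (N, S, L) are the mossy-fibre -> Purkinje-cell weights
    (unconstrained in sign: effective negative weights can arise through
    interneurone pathways).  ``v`` (N, S) are the mossy-fibre ->
    nucleo-olivary weights (one per fibre, since each fibre contacts a single
    NO cell); they are constrained to remain non-negative.
    """

    w: np.ndarray
    v: np.ndarray
    conn: Connectivity

    def copy(self) -> "NetworkState":
        return NetworkState(w=self.w.copy(), v=self.v.copy(), conn=self.conn)


def phi(x, rmax: float):
    """Saturating threshold-linear f-I curve: 0 below 0, linear, ``rmax`` above."""
    return np.clip(x, 0.0, rmax)


def init_weights(params: NetworkParams, conn: Connectivity, seed=None, *, rng_w=None, rng_v=None) -> NetworkState:
    """Draw initial plastic weights from their uniform distributions.

    ``w`` is uniform on ``[0, 8*T*rbar_PC/N]`` and ``v`` on
    ``[0, (NO0 + q*rbar_D)*4*T*L/(N*S)]``, which set the initial mean rates.
    Either pass a single ``seed`` (two child streams are spawned from it) or
    explicit generators ``rng_w``/``rng_v``.
    """
    if rng_w is None or rng_v is None:
        ss = np.random.SeedSequence(seed).spawn(2)
        rng_w = np.random.default_rng(ss[0])
        rng_v = np.random.default_rng(ss[1])
    sh = params.shape
    w = rng_w.uniform(0.0, params.w_init_max, size=(sh.N, sh.S, sh.L))
    v = rng_v.uniform(0.0, params.v_init_max, size=(sh.N, sh.S))
    return NetworkState(w=w, v=v, conn=conn)


def draw_perturbation(rng: np.random.Generator, L: int, T: int, rho: float):
    """One perturbation draw: per-climbing-fibre Bernoulli(rho) mask and bins.

    A bin is drawn for every fibre so the stream consumption is independent
    of the outcome (this keeps fast and reference paths draw-for-draw
    identical).
    """
    mask = rng.random(L) < rho
    bins = rng.integers(0, T, size=L)
    return mask, bins


def perturbation_eta(mask: np.ndarray, bins: np.ndarray, T: int) -> np.ndarray:
    """Dense indicator eta (L, T): 1 where climbing fibre l spiked in bin t."""
    L = mask.shape[0]
    eta = np.zeros((L, T), dtype=np.uint8)
    ls = np.nonzero(mask)[0]
    eta[ls, bins[ls]] = 1
    return eta


def purkinje_rates(state: NetworkState, pattern_m: np.ndarray, eta: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Purkinje cell rates (S, L, T) for one pattern and perturbation draw.

    ``PC[s,l,t] = phi(sum_i w[i,s,l]*sigma[i,s,l]*M[i,s,t] + eta[l,t]*A)``.
    """
    sh = params.shape
    if pattern_m.shape != (sh.N, sh.S, sh.T) or eta.shape != (sh.L, sh.T):
        raise ValueError("pattern/perturbation shapes inconsistent with params")
    drive = np.einsum("isl,ist->slt", state.w * state.conn.sigma, pattern_m.astype(float))
    drive += eta[np.newaxis, :, :] * params.A
    return phi(drive, params.rmax)


def nuclear_rates(state: NetworkState, pattern_m: np.ndarray, pc: np.ndarray, params: NetworkParams):
    """Projection-neurone and nucleo-olivary rates, each (L, T).

    PN cells receive the fixed mossy drive ``u_M_PN`` from their assigned
    fibres and inhibition ``u_PC_PN`` from the S Purkinje cells of their
    column; NO cells receive the plastic drive ``v`` and the q-scaled PC
    inhibition.
    """
    sh = params.shape
    if pc.shape != (sh.S, sh.L, sh.T):
        raise ValueError("pc shape inconsistent with params")
    m2 = pattern_m.reshape(sh.N * sh.S, sh.T).astype(float)
    pn_drive = np.zeros((sh.L, sh.T))
    np.add.at(pn_drive, state.conn.pn_assign.reshape(-1), m2)
    no_drive = np.zeros((sh.L, sh.T))
    np.add.at(no_drive, state.conn.no_assign.reshape(-1), state.v.reshape(-1, 1) * m2)
    pc_sum = pc.sum(axis=0)  # (L, T)
    pn = phi(params.u_M_PN * pn_drive + params.u_PC_PN * pc_sum, params.rmax)
    no = phi(no_drive + params.u_PC_NO * pc_sum, params.rmax)
    return pn, no


def movement_error(pn: np.ndarray, target: np.ndarray) -> float:
    """Global movement error: mean over (l, t) of |PN - R|, in Hz."""
    if pn.shape != target.shape:
        raise ValueError("PN and target shapes differ")
    return float(np.abs(pn - target).mean())


def olive_inhibition(no: np.ndarray) -> float:
    """Inhibition reaching the olive: mean NO rate over (l, t), in Hz."""
    return float(np.mean(no))


def ecs_sign(error: float, inhibition: float) -> int:
    """Sign of the olivary drive IO = E - I.

    An error complex spike is emitted only when IO is strictly positive, so
    the tie IO = 0 yields c = -1 (no spike).
    """
    return 1 if error - inhibition > 0 else -1


def sgdege_update(state: NetworkState, pattern_m: np.ndarray, eta: np.ndarray, c: int, params: NetworkParams) -> NetworkState:
    """Apply both plasticity updates in place for one presentation.

    ``w[i,s,l] -= alpha_w * c * sum_t eta[l,t]*M[i,s,t]`` (only synapses of
    fibres active in the same bin as a perturbation of that column's climbing
    fibre change) and ``v[i,s] = [v[i,s] + alpha_v * c * sum_t M[i,s,t]]_+``
    (all synapses of active fibres, rectified at zero).
    """
    gate = np.einsum("lt,ist->isl", eta.astype(float), pattern_m.astype(float))
    state.w -= params.alpha_w * c * gate
    state.v = np.maximum(state.v + params.alpha_v * c * pattern_m.sum(axis=2), 0.0)
    return state


def _trajectory_frame(n_trials, p, pattern_ix, err, inh, ecs, n_pert):
    # 'trial' counts total presentations; 'pattern_trial' is the per-pattern
    # presentation counter (the trial axis used when reporting one pattern).
    trial = np.arange(n_trials)
    return pd.DataFrame(
        {
            "trial": trial,
            "pattern": pattern_ix,
            "pattern_trial": trial // p,
            "error_hz": err,
            "inhibition_hz": inh,
            "olive_drive_hz": err - inh,
            "ecs": ecs,
            "n_perturbations": n_pert,
        }
    )


def _run_reference(params, patterns, targets, state, rng, n_trials):
    """Direct per-trial evaluation of the rate equations (no caching)."""
    sh = params.shape
    pattern_ix = np.arange(n_trials) % sh.p
    err = np.empty(n_trials)
    inh = np.empty(n_trials)
    ecs = np.empty(n_trials, dtype=np.int8)
    n_pert = np.empty(n_trials, dtype=np.int32)
    for trial in range(n_trials):
        mu = trial % sh.p
        mask, bins = draw_perturbation(rng, sh.L, sh.T, params.rho)
        eta = perturbation_eta(mask, bins, sh.T)
        m_mu = patterns.m[mu]
        pc = purkinje_rates(state, m_mu, eta, params)
        pn, no = nuclear_rates(state, m_mu, pc, params)
        e = movement_error(pn, targets.r[mu])
        i = olive_inhibition(no)
        c = ecs_sign(e, i)
        sgdege_update(state, m_mu, eta, c, params)
        err[trial] = e
        inh[trial] = i
        ecs[trial] = c
        n_pert[trial] = int(mask.sum())
    return _trajectory_frame(n_trials, sh.p, pattern_ix, err, inh, ecs, n_pert), state


def _run_fast(params, patterns, targets, state, rng, n_trials, refresh_every):
    """Sparse incremental simulation loop.

    Per-pattern synaptic drives (mossy input to PC and NO populations) are
    cached and updated incrementally as the few touched weights change; they
    are recomputed exactly from the weight matrices every ``refresh_every``
    trials to keep floating-point drift negligible.
    """
    sh = params.shape
    N, S, L, T, p = sh.N, sh.S, sh.L, sh.T, sh.p
    NS = N * S
    ST, TL = S * T, T * L
    rmax, A, rho = params.rmax, params.A, params.rho
    alpha_w, alpha_v = params.alpha_w, params.alpha_v
    u_pc_pn, u_pc_no = params.u_PC_PN, params.u_PC_NO

    W2 = state.w.reshape(NS, L)
    sig2 = state.conn.sigma.reshape(NS, L)
    v = state.v.reshape(NS)
    pn_l = state.conn.pn_assign.reshape(NS)
    no_l = state.conn.no_assign.reshape(NS)

    # --- per-pattern precomputation over the sparse active sets ------------
    act, t_act, key_pc, key_no, drive_pn, r_tl = [], [], [], [], [], []
    is_act = np.zeros((p, NS), dtype=bool)
    bin_of = np.full((p, NS), -1, dtype=np.int64)
    for mu in range(p):
        m2 = patterns.m[mu].reshape(NS, T)
        f, t = np.nonzero(m2)
        act.append(f)
        t_act.append(t)
        is_act[mu, f] = True
        bin_of[mu, f] = t
        key_pc.append((f % S) * T + t)
        key_no.append(t * L + no_l[f])
        drive_pn.append(
            params.u_M_PN * np.bincount(t * L + pn_l[f], minlength=TL).astype(float).reshape(T, L)
        )
        r_tl.append(np.ascontiguousarray(targets.r[mu].T))  # (T, L)

    # Cross-pattern index maps: positions (into pattern mu's active list) of
    # fibres also active in pattern nu, and their (t, l) keys in nu.
    pos_cross = [[None] * p for _ in range(p)]
    keyno_cross = [[None] * p for _ in range(p)]
    for mu in range(p):
        for nu in range(p):
            if nu == mu:
                continue
            pos = np.nonzero(is_act[nu, act[mu]])[0]
            f_common = act[mu][pos]
            pos_cross[mu][nu] = pos
            keyno_cross[mu][nu] = bin_of[nu, f_common] * L + no_l[f_common]

    # Per (pattern, bin): fibres active in that bin and, per other pattern,
    # the subset also active there with its destination rows in the PC cache.
    fibres_at = [[act[mu][t_act[mu] == t] for t in range(T)] for mu in range(p)]
    rows_at = [[None] * T for _ in range(p)]  # rows_at[mu][t][nu] -> (f2, rows)
    for mu in range(p):
        for t in range(T):
            fb = fibres_at[mu][t]
            entry = []
            for nu in range(p):
                f2 = fb if nu == mu else fb[is_act[nu, fb]]
                rows = (f2 % S) * T + bin_of[nu, f2]
                entry.append((f2, rows))
            rows_at[mu][t] = entry

    pc_in = [np.zeros((ST, L)) for _ in range(p)]
    j_drive = [np.zeros(TL) for _ in range(p)]

    def refresh():
        for mu in range(p):
            pc_in[mu][:] = 0.0
            np.add.at(pc_in[mu], key_pc[mu], W2[act[mu]] * sig2[act[mu]])
            j_drive[mu][:] = np.bincount(key_no[mu], weights=v[act[mu]], minlength=TL)

    refresh()

    pattern_ix = np.arange(n_trials) % p
    err = np.empty(n_trials)
    inh = np.empty(n_trials)
    ecs = np.empty(n_trials, dtype=np.int8)
    n_pert = np.empty(n_trials, dtype=np.int32)
    s_rows = np.arange(S) * T

    for trial in range(n_trials):
        if trial and trial % refresh_every == 0:
            refresh()
        mu = trial % p
        mask = rng.random(L) < rho
        bins = rng.integers(0, T, size=L)
        pert_ls = np.nonzero(mask)[0]

        # --- rates (evaluate with current weights) -------------------------
        if pert_ls.size:
            pc_raw = pc_in[mu].copy()
            for l in pert_ls:
                pc_raw[s_rows + bins[l], l] += A
            pc = np.clip(pc_raw, 0.0, rmax, out=pc_raw)
        else:
            pc = np.clip(pc_in[mu], 0.0, rmax)
        pc_sum = pc.reshape(S, T, L).sum(axis=0)  # (T, L)
        pn = np.clip(drive_pn[mu] + u_pc_pn * pc_sum, 0.0, rmax)
        no = np.clip(j_drive[mu].reshape(T, L) + u_pc_no * pc_sum, 0.0, rmax)
        e = float(np.abs(pn - r_tl[mu]).mean())
        i = float(no.mean())
        c = 1.0 if e - i > 0 else -1.0

        # --- M->NO update (all active fibres, rectified) -------------------
        idx = act[mu]
        old = v[idx]
        new = np.maximum(old + alpha_v * c, 0.0)
        dv = new - old
        v[idx] = new
        j_drive[mu] += np.bincount(key_no[mu], weights=dv, minlength=TL)
        for nu in range(p):
            if nu == mu:
                continue
            j_drive[nu] += np.bincount(
                keyno_cross[mu][nu], weights=dv[pos_cross[mu][nu]], minlength=TL
            )

        # --- M->PC update (perturbation-gated) -----------------------------
        if pert_ls.size:
            dw = -alpha_w * c
            for l in pert_ls:
                t = bins[l]
                fb = fibres_at[mu][t]
                if fb.size == 0:
                    continue
                W2[fb, l] += dw
                for nu in range(p):
                    f2, rows = rows_at[mu][t][nu]
                    if f2.size:
                        pc_in[nu][:, l] += np.bincount(
                            rows, weights=dw * sig2[f2, l], minlength=ST
                        )

        err[trial] = e
        inh[trial] = i
        ecs[trial] = c
        n_pert[trial] = pert_ls.size

    return _trajectory_frame(n_trials, sh.p, pattern_ix, err, inh, ecs, n_pert), state


def run_simulation(
    params: NetworkParams,
    patterns: MossyPatternSet,
    targets: TargetRates,
    n_trials: int,
    seed: int | None = None,
    *,
    state: NetworkState | None = None,
    rng_pert: np.random.Generator | None = None,
    fast: bool = True,
    refresh_every: int = 2000,
):
    """Present the patterns cyclically for ``n_trials`` presentations.

    Each presentation evaluates the rates (with the perturbation included in
    the movement), compares error and inhibition at the olive and then
    applies both weight updates.  Returns ``(trajectory, final_state)``; the
    trajectory is a DataFrame with one row per trial (pattern index, error,
    inhibition, olivary drive, eCS sign, perturbation count).

    When ``state``/``rng_pert`` are not supplied, connectivity, initial
    weights and the perturbation stream are derived from the named
    sub-streams of ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    streams = substreams(seed) if (state is None or rng_pert is None) else None
    if state is None:
        conn = build_connectivity(params.shape, streams["connectivity"])
        state = init_weights(params, conn, rng_w=streams["init_w"], rng_v=streams["init_v"])
    if rng_pert is None:
        rng_pert = streams["perturbations"]
    runner = _run_fast if fast else _run_reference
    args = (params, patterns, targets, state, rng_pert, n_trials)
    if fast:
        return _run_fast(*args, refresh_every)
    return _run_reference(*args)


def simulate_microzone(params: NetworkParams, n_trials: int, seed: int, *, fast: bool = True, target_mean: float | None = None):
    """Generate inputs from ``seed`` and run the full learning simulation.

    Patterns, targets, connectivity, initial weights and perturbations all
    come from independent named sub-streams of the single root seed.
    Returns ``(trajectory, final_state, patterns, targets)``.
    """
    sh = params.shape
    streams = substreams(seed)
    patterns = generate_patterns(sh, streams["patterns"])
    targets = generate_targets(
        sh.L, sh.T, sh.p, params.rbar_D if target_mean is None else target_mean, streams["targets"]
    )
    conn = build_connectivity(sh, streams["connectivity"])
    state = init_weights(params, conn, rng_w=streams["init_w"], rng_v=streams["init_v"])
    traj, final = run_simulation(
        params, patterns, targets, n_trials, state=state, rng_pert=streams["perturbations"], fast=fast
    )
    return traj, final, patterns, targets
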