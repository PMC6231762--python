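"""Shared fixtures and independent nested-loop oracles.

The oracles deliberately use plain Python triple loops over the model
equations so that the vectorized implementations are checked against an
independent transcription rather than against themselves.
"""

from __future__ import annotations

import numpy as np
import pytest

from sgdege.network import NetworkParams, simulate_microzone
from sgdege.patterns import ShapeParams


def naive_purkinje(state, pattern_m, eta, params):
    """Triple-loop PC rates: phi(sum_i w*sigma*M + eta*A)."""
    sh = params.shape
    pc = np.zeros((sh.S, sh.L, sh.T))
    for s in range(sh.S):
        for l in range(sh.L):
            for t in range(sh.T):
                drive = 0.0
                for i in range(sh.N):
                    drive += state.w[i, s, l] * state.conn.sigma[i, s, l] * pattern_m[i, s, t]
                drive += eta[l, t] * params.A
                pc[s, l, t] = min(max(drive, 0.0), params.rmax)
    return pc


def naive_nuclear(state, pattern_m, pc, params):
    """Triple-loop PN and NO rates."""
    sh = params.shape
    pn = np.zeros((sh.L, sh.T))
    no = np.zeros((sh.L, sh.T))
    for l in range(sh.L):
        for t in range(sh.T):
            pn_drive = 0.0
            no_drive = 0.0
            for i in range(sh.N):
                for s in range(sh.S):
                    if pattern_m[i, s, t]:
                        if state.conn.pn_assign[i, s] == l:
                            pn_drive += params.u_M_PN
                        if state.conn.no_assign[i, s] == l:
                            no_drive += state.v[i, s]
            pc_sum = sum(pc[s, l, t] for s in range(sh.S))
            pn[l, t] = min(max(pn_drive + params.u_PC_PN * pc_sum, 0.0), params.rmax)
            no[l, t] = min(max(no_drive + params.u_PC_NO * pc_sum, 0.0), params.rmax)
    return pn, no


@pytest.fixture
def tiny_shape():
    return ShapeParams(S=2, L=3, T=4, N=4, p=2)


@pytest.fixture
def tiny_params(tiny_shape):
    return NetworkParams(shape=tiny_shape, rho=0.3)


FIG8_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def fig8_runs():
    """Three full-scale microzone learning runs (60,000 trials per pattern).

    Shared by the acceptance tests for the fold reduction, the final error
    and the error-tracking properties.
    """
    params = NetworkParams()
    n_presentations = 60_000 * params.shape.p
    runs = {}
    for seed in FIG8_SEEDS:
        traj, state, patterns, targets = simulate_microzone(params, n_presentations, seed)
        runs[seed] = traj
    return runs
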