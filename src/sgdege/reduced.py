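"""Single-cell reduction of the learning algorithm: dynamics in the (P, J) plane.

A single principal cell with rate ``P`` (target ``R``) and a scalar mossy
drive ``J`` to the nucleo-olivary pathway capture the algorithm's essence.
The error is ``E = |P - R|`` (``|P + A - R|`` on perturbed trials, which
occur with probability ``rho``); the olive's inhibition is the rectified
``I = [J - q*P]_+`` (``[J - q*(P+A)]_+`` when perturbed).  The update sign is
``c = sign(E - I)`` with ties counted as negative (no error complex spike).
``J`` moves by ``c*dJ`` every trial; ``P`` moves by ``-c*dP`` only on
perturbed trials.

The geometry of the plane is organised by two pairs of half-lines where the
update signs flip: ``C``: ``J - q*P - q*A = |P - R + A|`` and ``D``:
``J - q*P = |P - R|``.  For ``q < 1`` the lines ``C+`` and ``D-`` intersect
at ``(R - A*(q+1)/2, q*R + (1-q^2)*A/2)``; trajectories descend a
"convergence corridor" and end up fluctuating around that point, so the
final error fluctuates around ``A*(q+1)/2``.  For ``q >= 1`` there is no
intersection and the rate drifts past its target without stopping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReducedParams",
    "ReducedState",
    "HalfLine",
    "CorridorGeometry",
    "reduced_step",
    "corridor_geometry",
    "check_convergence_conditions",
    "run_reduced",
]


@dataclass(frozen=True)
class ReducedParams:
    """Parameters of the reduced model (rates in Hz, probabilities unitless)."""

    R: float = 100.0  # target rate
    A: float = 10.0  # perturbation amplitude
    rho: float = 0.2  # perturbation probability per trial
    dP: float = 1.0  # P step per perturbed trial
    dJ: float = 2.0  # J step per trial
    q: float = 0.5  # P-cell -> NO inhibition strength
    rectify_unperturbed: bool = True  # use [J - q*P]_+ (not the raw value) off-perturbation

    def __post_init__(self) -> None:
        if self.A <= 0 or self.dP <= 0 or self.dJ <= 0:
            raise ValueError("A, dP and dJ must be positive")
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie in (0, 1), got {self.rho}")

    @property
    def beta(self) -> float:
        """Step ratio dJ/dP, one of the two parameters selecting the corridor line."""
        return self.dJ / self.dP


@dataclass
class ReducedState:
    P: float
    J: float


@dataclass(frozen=True)
class HalfLine:
    """Half-line J = slope*P + intercept on the domain P >= pmin / P <= pmax."""

    slope: float
    intercept: float
    pmin: float | None = None
    pmax: float | None = None

    def j(self, p: float) -> float:
        return self.slope * p + self.intercept


@dataclass(frozen=True)
class CorridorGeometry:
    """The four sign-flip half-lines and, for q < 1, the C+/D- fixed point."""

    c_plus: HalfLine
    c_minus: HalfLine
    d_plus: HalfLine
    d_minus: HalfLine
    fixed_point: tuple[float, float] | None


def _estimate(J: float, P: float, q: float, A: float, perturbed: bool, rectify: bool) -> float:
    raw = J - q * P - (q * A if perturbed else 0.0)
    if perturbed or rectify:
        return max(raw, 0.0)
    return raw


def reduced_step(state: ReducedState, params: ReducedParams, rng: np.random.Generator):
    """One trial of the reduced dynamics.

    Returns ``(new_state, log)`` where ``log`` is a dict with the trial's
    error, estimate, perturbation flag and update sign.  The single random
    draw is the perturbation Bernoulli.
    """
    perturbed = bool(rng.random() < params.rho)
    rate = state.P + (params.A if perturbed else 0.0)
    err = abs(rate - params.R)
    est = _estimate(state.J, state.P, params.q, params.A, perturbed, params.rectify_unperturbed)
    c = 1.0 if err - est > 0 else -1.0
    new_p = state.P - c * params.dP if perturbed else state.P
    new_j = state.J + c * params.dJ
    log = {"perturbed": perturbed, "error": err, "estimate": est, "c": c}
    return ReducedState(P=new_p, J=new_j), log


def corridor_geometry(params: ReducedParams) -> CorridorGeometry:
    """Sign-flip lines and fixed point of the (P, J) plane.

    ``C`` (perturbed-trial flip): ``J = q*P + q*A + |P - R + A|`` splits into
    ``C+`` (slope 1+q, P >= R-A) and ``C-`` (slope q-1, P <= R-A); ``D``
    (unperturbed flip): ``J = q*P + |P - R|`` into ``D+`` (P >= R) and ``D-``
    (P <= R).  ``C+`` and ``D-`` intersect iff ``q < 1``, at
    ``(R - A*(q+1)/2, q*R + (1 - q^2)*A/2)``.
    """
    R, A, q = params.R, params.A, params.q
    c_plus = HalfLine(1.0 + q, q * A - R + A, pmin=R - A)
    c_minus = HalfLine(q - 1.0, q * A + R - A, pmax=R - A)
    d_plus = HalfLine(1.0 + q, -R, pmin=R)
    d_minus = HalfLine(q - 1.0, R, pmax=R)
    if q < 1.0:
        fp = (R - A * (q + 1.0) / 2.0, q * R + (1.0 - q * q) * A / 2.0)
    else:
        fp = None
    return CorridorGeometry(c_plus, c_minus, d_plus, d_minus, fp)


def check_convergence_conditions(params: ReducedParams) -> dict[str, bool]:
    """Evaluate the sufficient conditions for corridor convergence.

    Convergence to the fixed-point neighbourhood requires ``q < 1`` (the
    fixed point exists), ``0 < rho < 1`` (updates are not confined to one
    line), ``dJ < (1 - q)*A`` and ``dP + dJ/(1 + q) < A`` (steps small enough
    not to jump over the corridor).
    """
    report = {
        "q_lt_1": params.q < 1.0,
        "rho_in_0_1": 0.0 < params.rho < 1.0,
        "dJ_lt_(1-q)A": params.dJ < (1.0 - params.q) * params.A,
        "dP+dJ/(1+q)_lt_A": params.dP + params.dJ / (1.0 + params.q) < params.A,
    }
    report["all_pass"] = all(report.values())
    return report


def run_reduced(params: ReducedParams, P0: float, J0: float, n_trials: int, seed) -> pd.DataFrame:
    """Simulate ``n_trials`` steps from ``(P0, J0)``; deterministic given seed.

    Returns a DataFrame with one row per trial: P and J *before* the update,
    the perturbation flag and the update sign, plus the post-update values.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    R, A, q = params.R, params.A, params.q
    rho, dP, dJ = params.rho, params.dP, params.dJ
    rectify = params.rectify_unperturbed
    P, J = float(P0), float(J0)
    out = np.empty((n_trials, 4))
    draws = rng.random(n_trials)
    for k in range(n_trials):
        perturbed = draws[k] < rho
        if perturbed:
            err = abs(P + A - R)
            est = max(J - q * P - q * A, 0.0)
        else:
            err = abs(P - R)
            raw = J - q * P
            est = max(raw, 0.0) if rectify else raw
        c = 1.0 if err - est > 0 else -1.0
        out[k, 0] = P
        out[k, 1] = J
        out[k, 2] = perturbed
        out[k, 3] = c
        if perturbed:
            P -= c * dP
        J += c * dJ
    df = pd.DataFrame(out, columns=["P", "J", "perturbed", "c"])
    df.insert(0, "trial", np.arange(n_trials))
    df["perturbed"] = df["perturbed"].astype(bool)
    df.attrs["final"] = (P, J)
    return df
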