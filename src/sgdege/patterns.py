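"""Synthetic mossy-fibre input patterns, target rate profiles and connectivity.

The microzone model is driven entirely by synthetic inputs: binary
spatiotemporal mossy-fibre patterns (one active time bin per active fibre),
uniformly distributed target firing-rate profiles for the nuclear projection
neurones, and random fixed connectivity (the mossy-fibre -> Purkinje-cell
contact mask and the one-to-one fibre -> nuclear-cell assignments).

All generators are deterministic given a seed.  A single root seed spawns
independent named sub-streams (patterns, targets, connectivity, initial
weights, perturbations) so that, e.g., changing the trial count of a run does
not alter the input patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShapeParams",
    "MossyPatternSet",
    "TargetRates",
    "Connectivity",
    "substreams",
    "generate_patterns",
    "generate_targets",
    "build_connectivity",
]

#: Fixed order of the named RNG sub-streams spawned from a root seed.
STREAM_NAMES = (
    "patterns",
    "targets",
    "connectivity",
    "init_w",
    "init_v",
    "perturbations",
)


def substreams(seed: int) -> dict[str, np.random.Generator]:
    """Spawn the named, independent RNG streams used by a simulation.

    Parameters
    ----------
    seed : int
        Root seed.  Each named stream is an independent child of
        ``np.random.SeedSequence(seed)``; the spawn order is fixed by
        :data:`STREAM_NAMES`.
    """
    children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
    return {name: np.random.default_rng(ss) for name, ss in zip(STREAM_NAMES, children)}


@dataclass(frozen=True)
class ShapeParams:
    """Geometry of the simulated microzone.

    Attributes
    ----------
    S : int
        Sagittal extent (rows of Purkinje cells).
    L : int
        Lateral extent (columns of Purkinje cells; also the number of
        projection and nucleo-olivary neurones and of climbing fibres).
    T : int
        Time bins per movement.
    N : int
        Mossy fibres per sagittal position (N*S fibres in total).
    p : int
        Number of patterns ("movements") to learn.
    """

    S: int
    L: int
    T: int
    N: int
    p: int

    def __post_init__(self) -> None:
        for name in ("S", "L", "T", "N", "p"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a strictly positive integer, got {v!r}")
        if (self.N * self.S) % 2 != 0:
            raise ValueError(f"N*S must be even so that NS/2 is integral, got N*S={self.N * self.S}")

    @property
    def n_fibres(self) -> int:
        return self.N * self.S

    @property
    def n_active(self) -> int:
        """Active fibres per pattern (exactly half of all fibres)."""
        return self.n_fibres // 2


@dataclass(frozen=True)
class MossyPatternSet:
    """Binary mossy-fibre activity, indexed (pattern, fibre i, sagittal s, time t).

    Exactly ``N*S/2`` fibres are active in each pattern; each active fibre
    fires in exactly one time bin.
    """

    m: np.ndarray  # uint8, shape (p, N, S, T)
    shape_params: ShapeParams

    def active(self, mu: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Indices (i, s, t) of the active fibre/bin entries of pattern ``mu``."""
        return np.nonzero(self.m[mu])

    def to_frame(self):
        """Active entries as a tidy table (pattern, fibre, sagittal, time)."""
        import pandas as pd

        mus, fis, ss, ts = np.nonzero(self.m)
        return pd.DataFrame({"pattern": mus, "fibre": fis, "sagittal": ss, "time": ts})


@dataclass(frozen=True)
class TargetRates:
    """Target projection-neurone rates, indexed (pattern, neurone l, time t), in Hz."""

    r: np.ndarray  # float64, shape (p, L, T)
    mean_rate: float

    def to_frame(self):
        import pandas as pd

        p, L, T = self.r.shape
        mu, l, t = np.meshgrid(np.arange(p), np.arange(L), np.arange(T), indexing="ij")
        return pd.DataFrame(
            {"pattern": mu.ravel(), "neurone": l.ravel(), "time": t.ravel(), "rate": self.r.ravel()}
        )


@dataclass(frozen=True)
class Connectivity:
    """Fixed random wiring of the microzone.

    Attributes
    ----------
    sigma : np.ndarray
        Binary mask (N, S, L): fibre (i, s) contacts the Purkinje cell in
        column l of its row with probability 1/2.
    pn_assign : np.ndarray
        (N, S) map: the single projection neurone l(i, s) contacted by each
        fibre.
    no_assign : np.ndarray
        (N, S) map: the single nucleo-olivary neurone contacted by each fibre
        (identical to ``pn_assign`` in the default model).
    """

    sigma: np.ndarray
    pn_assign: np.ndarray
    no_assign: np.ndarray


def generate_patterns(shape: ShapeParams, seed) -> MossyPatternSet:
    """Draw ``p`` independent binary mossy-fibre patterns.

    For each pattern, exactly ``N*S/2`` of the ``N*S`` fibres are chosen
    active, uniformly without replacement; each active fibre is assigned a
    single uniformly chosen time bin.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed)
    p, N, S, T = shape.p, shape.N, shape.S, shape.T
    m = np.zeros((p, N * S, T), dtype=np.uint8)
    for mu in range(p):
        act = rng.choice(N * S, size=shape.n_active, replace=False)
        bins = rng.integers(0, T, size=shape.n_active)
        m[mu, act, bins] = 1
    return MossyPatternSet(m=m.reshape(p, N, S, T), shape_params=shape)


def generate_targets(L: int, T: int, p: int, mean_rate: float, seed) -> TargetRates:
    """Draw i.i.d. uniform target rates on ``[0, 2*mean_rate]`` Hz."""
    if mean_rate <= 0:
        raise ValueError(f"mean_rate must be positive, got {mean_rate}")
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.0, 2.0 * mean_rate, size=(p, L, T))
    return TargetRates(r=r, mean_rate=float(mean_rate))


def build_connectivity(shape: ShapeParams, seed) -> Connectivity:
    """Draw the fixed wiring: sigma mask (prob 1/2) and nuclear assignments."""
    rng = np.random.default_rng(seed)
    N, S, L = shape.N, shape.S, shape.L
    sigma = (rng.random((N, S, L)) < 0.5).astype(np.uint8)
    pn_assign = rng.integers(0, L, size=(N, S))
    # Default model: each fibre contacts the projection neurone and the
    # nucleo-olivary neurone with the same index l(i, s).
    return Connectivity(sigma=sigma, pn_assign=pn_assign, no_assign=pn_assign.copy())
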