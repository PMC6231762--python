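"""Named experiment recipes, parameter sensitivity and result writers.

Each recipe reproduces one figure-level result with the standard parameters:

``fig2``
    Marr-Albus-Ito baseline, signed and unsigned error modes.
``fig8``
    Full microzone learning of two interleaved patterns (60,000 trials per
    pattern by default).
``fig9``
    Reduced-model trajectories from several initial conditions, corridor
    geometry and convergence-condition report.
``fig10``
    Analog perceptron: single-pattern SGDEGE floor and a below-capacity
    delta-rule run.
``sensitivity``
    +-10% variations of the four key parameters (alpha_w, alpha_v, rho, A)
    around the fig8 configuration at matched seeds.

Error summaries use *per-pattern* trial windows: the initial error is the
mean over the first 500 trials of each pattern and the final error the mean
over per-pattern trials 55,000-60,000 (proportional windows - first 1/120
and last 1/12 - for other run lengths).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mai as mai_mod
from . import perceptron as perc_mod
from . import reduced as red_mod
from .network import NetworkParams, simulate_microzone
from .patterns import ShapeParams

__all__ = [
    "RunSummary",
    "run_recipe",
    "sensitivity_sweep",
    "fig8_params",
    "error_windows",
    "RECIPES",
]

SENSITIVITY_PARAMS = ("alpha_w", "alpha_v", "rho", "A")

#: Default per-pattern trial count of the full network recipe.
FIG8_TRIALS_PER_PATTERN = 60_000


@dataclass
class RunSummary:
    """Headline numbers of one recipe run (errors in Hz)."""

    recipe: str
    initial_error: float
    final_error: float
    fold_reduction: float
    n_trials: int
    seed: int
    elapsed_s: float
    params: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def fig8_params(**overrides) -> NetworkParams:
    """The standard full-network configuration, with optional field overrides."""
    shape_over = {k: overrides.pop(k) for k in ("S", "L", "T", "N", "p") if k in overrides}
    shape = ShapeParams(S=10, L=40, T=10, N=2000, p=2)
    if shape_over:
        shape = dataclasses.replace(shape, **shape_over)
    return dataclasses.replace(NetworkParams(shape=shape), **overrides)


def error_windows(traj: pd.DataFrame, n_per_pattern: int, *, init_window: int | None = None, tail_window: tuple[int, int] | None = None):
    """Initial- and tail-window mean errors on the per-pattern trial axis.

    Defaults: initial = first 500 per-pattern trials (or 1/120 of the run if
    shorter), tail = per-pattern trials 55,000-60,000 when the run has the
    standard length, otherwise the last 1/12 of the run.
    """
    pt = traj["pattern_trial"].to_numpy()
    err = traj["error_hz"].to_numpy()
    if init_window is None:
        init_window = min(500, max(1, n_per_pattern // 120))
    if tail_window is None:
        if n_per_pattern == FIG8_TRIALS_PER_PATTERN:
            tail_window = (55_000, 60_000)
        else:
            tail_window = (n_per_pattern - max(1, n_per_pattern // 12), n_per_pattern)
    init = float(err[pt < init_window].mean())
    tail = float(err[(pt >= tail_window[0]) & (pt < tail_window[1])].mean())
    return init, tail


def _summarise_network(recipe, traj, n_per_pattern, seed, elapsed, params, extra=None):
    init, tail = error_windows(traj, n_per_pattern)
    e = traj["error_hz"].to_numpy()
    i = traj["inhibition_hz"].to_numpy()
    pt = traj["pattern_trial"].to_numpy()
    mism_init = float(np.abs(e - i)[pt < 500].mean())
    sel = (pt >= 10_000) & (pt < 20_000)
    mism_mid = float(np.abs(e - i)[sel].mean()) if sel.any() else float("nan")
    # first per-pattern trial at which the tracking mismatch (500-trial
    # moving average) drops below 10% of its initial value
    k = 500
    if len(e) > 2 * k:
        ma = np.convolve(np.abs(e - i), np.ones(k) / k, mode="valid")
        below = np.nonzero(ma < 0.1 * mism_init)[0]
        tracked_at = int(pt[below[0]]) if below.size else None
    else:
        tracked_at = None
    extra = dict(extra or {})
    extra.update(
        {
            "tracking_mismatch_initial_hz": mism_init,
            "tracking_mismatch_mid_hz": mism_mid,
            "tracking_established_at_pattern_trial": tracked_at,
        }
    )
    return RunSummary(
        recipe=recipe,
        initial_error=init,
        final_error=tail,
        fold_reduction=init / tail if tail > 0 else float("inf"),
        n_trials=len(traj),
        seed=seed,
        elapsed_s=elapsed,
        params=_params_dict(params),
        extra=extra,
    )


def _params_dict(params) -> dict:
    d = dataclasses.asdict(params)
    return d


def _recipe_fig8(seed, overrides, out_dir):
    n_per = int(overrides.pop("n_trials_per_pattern", FIG8_TRIALS_PER_PATTERN))
    params = fig8_params(**overrides)
    t0 = time.perf_counter()
    traj, state, patterns, targets = simulate_microzone(params, n_per * params.shape.p, seed)
    elapsed = time.perf_counter() - t0
    summary = _summarise_network("fig8", traj, n_per, seed, elapsed, params)
    if out_dir is not None:
        traj.to_csv(out_dir / "trajectory.csv", index=False)
        np.savez_compressed(out_dir / "final_weights.npz", w=state.w, v=state.v)
    return summary, {"trajectory": traj, "state": state, "targets": targets}


def _recipe_fig2(seed, overrides, out_dir):
    # The relaxation of the mean rate (signed mode) is demonstrated with a
    # target mean far from the initial PN mean; the saturation failure
    # (unsigned mode) with a low target mean so the runaway is conspicuous.
    n_trials = int(overrides.pop("n_trials", 10_000))
    target_means = {
        "signed": float(overrides.pop("target_mean_signed", 50.0)),
        "unsigned": float(overrides.pop("target_mean_unsigned", 10.0)),
    }
    mai_over = {k: overrides.pop(k) for k in ("alpha_w", "beta_w") if k in overrides}
    params = fig8_params(**overrides)
    t0 = time.perf_counter()
    results = {}
    for mode in ("signed", "unsigned"):
        mp = mai_mod.MAIParams(error_mode=mode, **mai_over)
        results[mode] = mai_mod.run_mai(mp, params, n_trials, seed, target_mean=target_means[mode])
    elapsed = time.perf_counter() - t0
    sg = results["signed"]
    un = results["unsigned"]
    mean_gap_0 = abs(float(sg.pn_initial.mean()) - float(sg.targets.mean()))
    mean_gap_1 = abs(float(sg.pn_final.mean()) - float(sg.targets.mean()))
    uns0 = float(np.abs(sg.pn_initial - sg.targets).mean())
    uns1 = float(np.abs(sg.pn_final - sg.targets).mean())
    extra = {
        "signed_mean_rate_gap_initial_hz": mean_gap_0,
        "signed_mean_rate_gap_final_hz": mean_gap_1,
        "signed_unsigned_error_initial_hz": uns0,
        "signed_unsigned_error_final_hz": uns1,
        "unsigned_error_initial_hz": float(un.trajectory.unsigned_error_hz.iloc[0]),
        "unsigned_error_final_hz": float(un.trajectory.unsigned_error_hz.iloc[-1]),
        "unsigned_pc_zero_fraction": float((un.pc_final == 0).mean()),
    }
    summary = RunSummary(
        recipe="fig2",
        initial_error=mean_gap_0,
        final_error=mean_gap_1,
        fold_reduction=mean_gap_0 / mean_gap_1 if mean_gap_1 > 0 else float("inf"),
        n_trials=n_trials,
        seed=seed,
        elapsed_s=elapsed,
        params=_params_dict(params),
        extra=extra,
    )
    if out_dir is not None:
        for mode, res in results.items():
            res.trajectory.to_csv(out_dir / f"mai_{mode}_trajectory.csv", index=False)
            _profiles_frame(res).to_csv(out_dir / f"mai_{mode}_profiles.csv", index=False)
    return summary, results


def _profiles_frame(res) -> pd.DataFrame:
    """Per-neurone firing profiles before/after learning (first pattern)."""
    p, L, T = res.pn_initial.shape
    l, t = np.meshgrid(np.arange(L), np.arange(T), indexing="ij")
    return pd.DataFrame(
        {
            "neurone": l.ravel(),
            "time": t.ravel(),
            "rate_initial_hz": res.pn_initial[0].ravel(),
            "rate_final_hz": res.pn_final[0].ravel(),
            "target_hz": res.targets[0].ravel(),
        }
    )


def _recipe_fig9(seed, overrides, out_dir):
    n_trials = int(overrides.pop("n_trials", 10_000))
    starts = overrides.pop("starts", [(60.4, 20.0), (140.4, 100.0), (60.4, 120.0), (140.4, 10.0)])
    params = red_mod.ReducedParams(**overrides)
    geo = red_mod.corridor_geometry(params)
    cond = red_mod.check_convergence_conditions(params)
    t0 = time.perf_counter()
    trajs = []
    late_means = []
    ss = np.random.SeedSequence(seed).spawn(len(starts))
    for k, (p0, j0) in enumerate(starts):
        df = red_mod.run_reduced(params, p0, j0, n_trials, ss[k])
        df.insert(0, "start", k)
        trajs.append(df)
        late_means.append(float(df.P.iloc[-n_trials // 5 :].mean()))
    elapsed = time.perf_counter() - t0
    fp = geo.fixed_point
    final = (
        float(np.mean([abs(m - fp[0]) for m in late_means])) if fp is not None else float("nan")
    )
    extra = {
        "fixed_point": fp,
        "late_mean_P_per_start": late_means,
        "conditions": cond,
        "converged": fp is not None and all(abs(m - fp[0]) < 1.0 for m in late_means),
    }
    init = float(np.mean([abs(p0 - params.R) for p0, _ in starts]))
    summary = RunSummary(
        recipe="fig9",
        initial_error=init,
        final_error=final,
        fold_reduction=init / final if final and final > 0 else float("inf"),
        n_trials=n_trials,
        seed=seed,
        elapsed_s=elapsed,
        params=_params_dict(params),
        extra=extra,
    )
    if out_dir is not None:
        pd.concat(trajs).to_csv(out_dir / "reduced_trajectories.csv", index=False)
        (out_dir / "geometry.json").write_text(
            json.dumps(
                {
                    "fixed_point": fp,
                    "conditions": cond,
                    "lines": {
                        name: dataclasses.asdict(getattr(geo, name))
                        for name in ("c_plus", "c_minus", "d_plus", "d_minus")
                    },
                },
                indent=2,
                default=_jsonable,
            )
        )
    return summary, {"trajectories": trajs, "geometry": geo}


def _recipe_fig10(seed, overrides, out_dir):
    n_sweeps = int(overrides.pop("n_trials_per_pattern", 3000))
    p_delta = int(overrides.pop("p_delta", 50))
    params = perc_mod.PerceptronParams(**overrides)
    t0 = time.perf_counter()
    curve_s, _, pat_s = perc_mod.run_perceptron("sgdege", params, n_sweeps, seed, record_every=10)
    pars_d = dataclasses.replace(params, p=p_delta)
    curve_d, _, _ = perc_mod.run_perceptron("delta", pars_d, n_sweeps, seed, record_every=10)
    elapsed = time.perf_counter() - t0
    floor = params.A * (1 + params.q) / 2
    tail = max(1, len(curve_s) // 10)
    final_s = float(curve_s.mean_error_hz.iloc[-tail:].mean())
    extra = {
        "sgdege_final_error_hz": final_s,
        "perturbation_floor_hz": floor,
        "delta_p": p_delta,
        "delta_final_error_hz": float(curve_d.mean_error_hz.iloc[-1]),
        "sgdege_auc": float(curve_s.mean_error_hz.sum()),
        "delta_auc": float(curve_d.mean_error_hz.sum()),
    }
    init = float(curve_s.mean_error_hz.iloc[0])
    summary = RunSummary(
        recipe="fig10",
        initial_error=init,
        final_error=final_s,
        fold_reduction=init / final_s if final_s > 0 else float("inf"),
        n_trials=n_sweeps,
        seed=seed,
        elapsed_s=elapsed,
        params=_params_dict(params),
        extra=extra,
    )
    if out_dir is not None:
        curve_s.to_csv(out_dir / "sgdege_learning_curve.csv", index=False)
        curve_d.to_csv(out_dir / "delta_learning_curve.csv", index=False)
    return summary, {"sgdege": curve_s, "delta": curve_d}


def sensitivity_sweep(
    seed: int,
    *,
    n_trials_per_pattern: int = FIG8_TRIALS_PER_PATTERN,
    factors=(0.9, 1.1),
    param_names=SENSITIVITY_PARAMS,
    base_overrides: dict | None = None,
) -> pd.DataFrame:
    """Tail-window error change under +-10% variations of the key parameters.

    One baseline run plus ``len(param_names) * len(factors)`` perturbed runs,
    all at matched seeds (identical patterns, targets, connectivity, initial
    weights and perturbation stream).  Returns a table with the relative
    change of the tail-window final error for each variation.
    """
    for name in param_names:
        if name not in SENSITIVITY_PARAMS:
            raise ValueError(f"unknown sensitivity parameter {name!r}")
    base_overrides = dict(base_overrides or {})
    base = fig8_params(**base_overrides)
    rows = []

    def run_one(params):
        traj, *_ = simulate_microzone(params, n_trials_per_pattern * params.shape.p, seed)
        _, tail = error_windows(traj, n_trials_per_pattern)
        return tail

    base_final = run_one(base)
    rows.append({"param": "baseline", "multiplier": 1.0, "final_error_hz": base_final, "rel_change": 0.0})
    for name in param_names:
        for mult in factors:
            pert = dataclasses.replace(base, **{name: getattr(base, name) * mult})
            final = run_one(pert)
            rows.append(
                {
                    "param": name,
                    "multiplier": mult,
                    "final_error_hz": final,
                    "rel_change": (final - base_final) / base_final,
                }
            )
    return pd.DataFrame(rows)


def _recipe_sensitivity(seed, overrides, out_dir):
    n_per = int(overrides.pop("n_trials_per_pattern", FIG8_TRIALS_PER_PATTERN))
    t0 = time.perf_counter()
    table = sensitivity_sweep(seed, n_trials_per_pattern=n_per, base_overrides=overrides)
    elapsed = time.perf_counter() - t0
    base = float(table.final_error_hz.iloc[0])
    worst = float(table.rel_change.abs().max())
    summary = RunSummary(
        recipe="sensitivity",
        initial_error=base,
        final_error=base,
        fold_reduction=1.0,
        n_trials=n_per,
        seed=seed,
        elapsed_s=elapsed,
        params={"n_trials_per_pattern": n_per},
        extra={"max_abs_rel_change": worst, "table": table.to_dict(orient="records")},
    )
    if out_dir is not None:
        table.to_csv(out_dir / "sensitivity.csv", index=False)
    return summary, {"table": table}


RECIPES = {
    "fig2": _recipe_fig2,
    "fig8": _recipe_fig8,
    "fig9": _recipe_fig9,
    "fig10": _recipe_fig10,
    "sensitivity": _recipe_sensitivity,
}


def run_recipe(name: str, seed: int = 0, overrides: dict | None = None, out_dir=None):
    """Execute a named recipe; returns ``(RunSummary, artifacts)``.

    ``overrides`` are recipe-specific parameter replacements (validated by
    the underlying dataclasses).  When ``out_dir`` is given, trajectory
    tables and a ``summary.json`` (parameters and seed included) are written
    there.
    """
    if name not in RECIPES:
        raise KeyError(f"unknown recipe {name!r}; available: {sorted(RECIPES)}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    summary, artifacts = RECIPES[name](seed, dict(overrides or {}), out_dir)
    if not np.isfinite(summary.final_error):
        if name != "fig9":  # fig9 reports NaN when no fixed point exists
            raise ArithmeticError(f"recipe {name} produced a non-finite final error")
    if out_dir is not None:
        (out_dir / "summary.json").write_text(summary.to_json())
    return summary, artifacts
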