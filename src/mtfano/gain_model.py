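"""The multiplicative-gain model of spike-count variance, and its fits.

Conditioned on direction theta, the count variance under the model is

    var(x|theta) = f(theta)**alpha * <g**alpha> + f(theta)**2 * var(g)

with trial gain g ~ Gamma(mean 1, variance var_g).  Because <g> = 1 and
var(g) is small, <g**alpha> ~ 1 and the working approximation is

    var(x|theta) ~ f(theta)**alpha + f(theta)**2 * var(g)
    FF(theta)    ~ f(theta)**(alpha-1) + f(theta) * var(g)

For alpha < 1 and small var(g) the first term dominates and FF is
U-shaped in direction (positive FFTI); when the gain term dominates FF
follows the tuning curve (flat or negative FFTI).  A change in var(g)
alone can therefore reverse Fano-factor tuning — the model's central
mechanism.

Fitting variants: a population-level grid search minimizing the
two-sample Kolmogorov-Smirnov distance between model and observed FFTI
distributions; constrained two-state fits sharing alpha or var(g); and a
per-neuron least-squares fit of the FF-vs-direction curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .core import CountMatrix, GainModelParams, TuningCurveFit

__all__ = [
    "GainModelFit",
    "gain_moment",
    "predict_variance",
    "predict_ff",
    "predict_ffti_distribution",
    "fit_population_ks",
    "fit_constrained",
    "fit_neuron_lsq",
    "default_alpha_grid",
    "default_var_g_grid",
]


def default_alpha_grid(step: float = 0.01, hi: float = 1.5) -> np.ndarray:
    return np.round(np.arange(0.0, hi + step / 2, step), 10)


def default_var_g_grid() -> np.ndarray:
    """Hybrid log-plus-linear spacing over [0, 0.2] (fits span two decades)."""
    return np.concatenate([[0.0], np.geomspace(1e-4, 0.02, 15),
                           np.linspace(0.03, 0.2, 18)])


@dataclass
class GainModelFit:
    variant: Literal["population_ks", "shared_alpha", "shared_var_g",
                     "per_neuron_lsq", "per_neuron_var_g_common_alpha"]
    params: dict
    objective: float
    surface: pd.DataFrame | None = None
    boundary_warning: bool = False
    model_sample: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Forward predictions

def gain_moment(alpha: float, var_g: float) -> float:
    """Exact <g**alpha> for the mean-1 Gamma gain:
    var_g**alpha * Gamma(1/var_g + alpha) / Gamma(1/var_g)."""
    if var_g == 0:
        return 1.0
    k = 1.0 / var_g
    return float(np.exp(alpha * np.log(var_g) + gammaln(k + alpha) - gammaln(k)))


def predict_variance(f_value, params: GainModelParams, exact: bool = False):
    """Model count variance at expected count f_value (> 0)."""
    f = np.asarray(f_value, dtype=float)
    if np.any(f <= 0):
        raise ValueError("f_value must be positive")
    moment = gain_moment(params.alpha, params.var_g) if exact else 1.0
    return f ** params.alpha * moment + f ** 2 * params.var_g


def predict_ff(f_value, params: GainModelParams, exact: bool = False):
    """Model Fano factor: f**(alpha-1)*<g**alpha> + f*var_g."""
    return predict_variance(f_value, params, exact=exact) / np.asarray(f_value, dtype=float)


def predict_ffti_distribution(tuning_set: Sequence[TuningCurveFit],
                              params: GainModelParams, n_trials: int,
                              n_reps: int = 1, seed: int = 0,
                              direction_grid: Sequence[float] | None = None
                              ) -> np.ndarray:
    """Model FFTI sample: simulate counts per tuning curve, compute FFTI.

    Returns an array of length len(tuning_set) * n_reps.  Warns when any
    neuron yields undefined FFTI in more than half its repetitions.
    """
    from .response_stats import direction_stats, tuning_indices
    from .synthetic_data import SyntheticConfig, generate_trial_counts

    if direction_grid is None:
        direction_grid = tuple(float(d) for d in range(-90, 91, 15))
    out = []
    undef = np.zeros(len(tuning_set), dtype=int)
    for rep in range(n_reps):
        cfg = SyntheticConfig(n_neurons=len(tuning_set), n_trials=n_trials,
                              direction_grid=direction_grid, gain_params=params,
                              tuning=list(tuning_set), seed=seed + rep)
        cm = generate_trial_counts(cfg)
        for i, curve in enumerate(tuning_set):
            ds = direction_stats(
                CountMatrix(cm.counts[i:i + 1], cm.directions),
                pref=float(curve.pref_direction))[0]
            ffti = tuning_indices(ds).FFTI
            if np.isnan(ffti):
                undef[i] += 1
            else:
                out.append(ffti)
    if n_reps and np.any(undef > n_reps / 2):
        warnings.warn("some neurons yield undefined FFTI in > 50% of repetitions")
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Population KS fits

def _grid_seed(seed: int, ia: int, iv: int) -> int:
    # fixed seed per grid point keeps the objective surface smooth
    return (seed * 1_000_003 + ia * 1009 + iv) % (2 ** 31 - 1)


def fit_population_ks(observed_ffti: np.ndarray,
                      tuning_set: Sequence[TuningCurveFit],
                      grid_alpha: np.ndarray, grid_var_g: np.ndarray,
                      n_trials: int = 100, sample_factor: int = 20,
                      seed: int = 0,
                      direction_grid: Sequence[float] | None = None
                      ) -> GainModelFit:
    """Grid search of (alpha, var_g) minimizing the two-sample KS distance
    between the model FFTI distribution and the observed sample.

    The model sample at each grid point has ``sample_factor`` times the
    observed size (rounded up over repetitions of the tuning set), with a
    fixed per-grid-point seed so the objective surface is smooth.
    """
    observed = np.asarray(observed_ffti, dtype=float)
    observed = observed[~np.isnan(observed)]
    if observed.size < 10:
        raise ValueError("observed FFTI sample must have >= 10 values")
    n_reps = int(np.ceil(sample_factor * observed.size / len(tuning_set)))
    rows = []
    best = (np.inf, None, None)
    for ia, a in enumerate(np.asarray(grid_alpha, dtype=float)):
        for iv, v in enumerate(np.asarray(grid_var_g, dtype=float)):
            sample = predict_ffti_distribution(
                tuning_set, GainModelParams(a, v), n_trials, n_reps,
                seed=_grid_seed(seed, ia, iv), direction_grid=direction_grid)
            ks = stats.ks_2samp(sample, observed).statistic if sample.size else 1.0
            rows.append({"alpha": a, "var_g": v, "ks_stat": ks})
            if ks < best[0]:
                best = (ks, a, v)
    surface = pd.DataFrame(rows)
    ks, a, v = float(best[0]), float(best[1]), float(best[2])
    on_boundary = (a in (grid_alpha[0], grid_alpha[-1])
                   or v in (grid_var_g[0], grid_var_g[-1]))
    if on_boundary:
        warnings.warn("KS optimum on grid boundary; consider extending the grid")
    model_sample = predict_ffti_distribution(
        tuning_set, GainModelParams(a, v), n_trials, n_reps, seed=seed,
        direction_grid=direction_grid)
    return GainModelFit("population_ks", {"alpha": a, "var_g": v}, ks,
                        surface=surface, boundary_warning=bool(on_boundary),
                        model_sample=model_sample)


def fit_constrained(states: dict[str, tuple[np.ndarray, Sequence[TuningCurveFit]]],
                    constraint: Literal["shared_alpha", "shared_var_g"],
                    grid_alpha: np.ndarray, grid_var_g: np.ndarray,
                    n_trials: int = 100, sample_factor: int = 20, seed: int = 0,
                    direction_grid: Sequence[float] | None = None) -> GainModelFit:
    """Two-state fit with one parameter shared between states.

    The shared parameter minimizes the sum over states of squared KS
    statistics, the free parameter being optimized per state.  ``states``
    maps a label to (observed FFTI sample, tuning set).
    """
    if len(states) < 2:
        raise ValueError("need two states for a constrained fit")
    surfaces = {}
    for si, (label, (obs, tuning)) in enumerate(states.items()):
        fit = fit_population_ks(obs, tuning, grid_alpha, grid_var_g,
                                n_trials=n_trials, sample_factor=sample_factor,
                                seed=seed + 7919 * si, direction_grid=direction_grid)
        surfaces[label] = fit.surface.pivot(index="alpha", columns="var_g",
                                            values="ks_stat")
    shared_axis = 0 if constraint == "shared_alpha" else 1
    shared_grid = np.asarray(grid_alpha if constraint == "shared_alpha" else grid_var_g,
                             dtype=float)
    objective = np.zeros(shared_grid.size)
    free_idx = {}
    for label, surf in surfaces.items():
        mat = surf.to_numpy()
        if constraint == "shared_var_g":
            mat = mat.T  # rows indexed by the shared parameter
        best_free = mat.min(axis=1)
        objective += best_free ** 2
        free_idx[label] = mat.argmin(axis=1)
    k = int(np.argmin(objective))
    shared_value = float(shared_grid[k])
    free_grid = np.asarray(grid_var_g if constraint == "shared_alpha" else grid_alpha,
                           dtype=float)
    params = {"shared": shared_value,
              "per_state": {label: float(free_grid[free_idx[label][k]])
                            for label in surfaces}}
    surface_long = pd.concat(
        [s.reset_index().melt(id_vars="alpha", var_name="var_g", value_name="ks_stat")
         .assign(state=label) for label, s in surfaces.items()],
        ignore_index=True)
    return GainModelFit(constraint, params, float(objective[k]), surface=surface_long)


# ---------------------------------------------------------------------------
# Per-neuron least squares

def fit_neuron_lsq(ff_by_direction: np.ndarray, f_by_direction: np.ndarray,
                   alpha_starts: Sequence[float] = (0.2, 0.5, 0.8, 1.1),
                   var_g_starts: Sequence[float] = (1e-3, 0.02, 0.1),
                   alpha_bounds: tuple[float, float] = (0.0, 2.0)
                   ) -> tuple[float, float, float]:
    """Least-squares fit of FF(theta) = f**(alpha-1) + f*var_g per neuron.

    ``f_by_direction`` are the observed mean counts (the model's f(theta))
    and ``ff_by_direction`` the observed Fano factors at the same
    directions; NaN entries are dropped.  Returns (alpha, var_g, rss);
    raises RuntimeError when no start converges.
    """
    ff = np.asarray(ff_by_direction, dtype=float)
    f = np.asarray(f_by_direction, dtype=float)
    ok = ~(np.isnan(ff) | np.isnan(f)) & (f > 0)
    ff, f = ff[ok], f[ok]
    if ff.size < 5:
        raise ValueError("need >= 5 directions with defined FF")

    def resid(p):
        a, v = p
        return f ** (a - 1.0) + f * v - ff

    best, best_cost = None, np.inf
    for a0 in alpha_starts:
        for v0 in var_g_starts:
            try:
                sol = optimize.least_squares(
                    resid, [a0, v0],
                    bounds=([alpha_bounds[0], 0.0], [alpha_bounds[1], np.inf]))
            except Exception:  # pragma: no cover
                continue
            if sol.cost < best_cost:
                best, best_cost = sol, sol.cost
    if best is None:  # pragma: no cover
        raise RuntimeError("per-neuron least-squares fit failed to converge")
    a, v = best.x
    return float(a), float(v), float(2 * best_cost)


def fit_neurons_lsq_frame(stats: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply fit_neuron_lsq per neuron to a tidy stats frame
    (columns neuron_id, direction_deg, mean, ff)."""
    rows = []
    for nid, grp in stats.groupby("neuron_id"):
        try:
            a, v, rss = fit_neuron_lsq(grp["ff"].to_numpy(), grp["mean"].to_numpy(),
                                       **kwargs)
            rows.append({"neuron_id": nid, "alpha": a, "var_g": v, "rss": rss,
                         "converged": True})
        except (RuntimeError, ValueError):
            rows.append({"neuron_id": nid, "alpha": np.nan, "var_g": np.nan,
                         "rss": np.nan, "converged": False})
    return pd.DataFrame(rows)
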