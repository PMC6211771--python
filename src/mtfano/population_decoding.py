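"""Population Fisher-information decoding with information-limiting correlations.

A model MT population has von Mises tuning curves f_i(theta) with preferred
directions tiling the circle, an imposed Fano-factor tuning (mean FF across
directions held at exactly 1), pairwise correlations decaying with the
difference in preferred direction,

    c(d) = c_max * (exp(kappa*(cos d + 1)) - 1) / (exp(2*kappa) - 1),

and an optional rank-one information-limiting covariance component
eps * f'(theta) f'(theta)^T (eps in squared degrees).  The linear Fisher
information J = f'^T Sigma^{-1} f' (covariance-derivative terms ignored)
obeys J_eps = J0 / (1 + eps*J0), so the Cramer-Rao bound on direction
discrimination, sqrt(1/J0 + eps) degrees, saturates at sqrt(eps) no matter
how many neurons are added.

All angles are degrees; f' is computed analytically per degree so J has
units deg^-2 and the bound is in degrees directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .core import TuningCurveFit, von_mises_tuning

__all__ = [
    "CorrelationKernel",
    "FFTuningSpec",
    "PopulationModel",
    "DecodingResult",
    "corr_kernel_value",
    "kernel_hwhm",
    "build_covariance",
    "linear_fisher",
    "neurons_to_threshold",
    "time_to_threshold",
    "homogeneous_population",
    "heterogeneous_population",
    "cumulative_tuning",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationKernel:
    c_max: float = 0.1
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.c_max <= 1.0):
            raise ValueError("c_max must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    def __call__(self, d_deg) -> np.ndarray:
        d = np.deg2rad(np.asarray(d_deg, dtype=float))
        return self.c_max * np.expm1(self.kappa * (np.cos(d) + 1.0)) / np.expm1(2.0 * self.kappa)


def corr_kernel_value(d_deg, kernel: CorrelationKernel):
    """Pairwise correlation at preferred-direction difference d (degrees)."""
    return kernel(d_deg)


def kernel_hwhm(kernel: CorrelationKernel) -> float:
    """Half-width at half-maximum of the correlation kernel, by root solving
    c(d) = c_max/2 on (0, 180)."""
    from scipy.optimize import brentq
    if kernel.c_max == 0:
        raise ValueError("flat kernel has no half-maximum")
    return float(brentq(lambda d: kernel(d) - kernel.c_max / 2.0, 1e-9, 180.0 - 1e-9))


@dataclass(frozen=True)
class FFTuningSpec:
    """Imposed von Mises Fano-factor tuning with direction-averaged FF = 1.

    ``sign='positive'`` dips at the preferred direction (U-shaped, FFTI>0);
    ``'negative'`` is its mirror image about FF = 1; ``'flat'`` is FF = 1.
    """

    sign: Literal["positive", "flat", "negative"] = "flat"
    amplitude: float = 0.3
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sign not in ("positive", "flat", "negative"):
            raise ValueError(f"unknown FF tuning sign {self.sign!r}")

    def ff(self, theta_deg, pref_deg: float, grid_deg: np.ndarray) -> np.ndarray:
        """FF at theta for a neuron with preferred direction pref, normalized
        so the average over ``grid_deg`` is exactly 1."""
        if self.sign == "flat" or self.amplitude == 0:
            return np.ones_like(np.asarray(theta_deg, dtype=float))
        shape = von_mises_tuning(np.asarray(theta_deg, dtype=float), 0.0, 1.0,
                                 self.kappa, pref_deg)
        shape_mean = von_mises_tuning(np.asarray(grid_deg, dtype=float), 0.0, 1.0,
                                      self.kappa, pref_deg).mean()
        s = -1.0 if self.sign == "positive" else 1.0
        out = 1.0 + s * self.amplitude * (shape - shape_mean)
        if np.any(out <= 0):
            raise ValueError("FF tuning amplitude too large: nonpositive FF")
        return out


@dataclass
class PopulationModel:
    tuning_set: list[TuningCurveFit]
    ff_spec: FFTuningSpec = field(default_factory=FFTuningSpec)
    corr: CorrelationKernel = field(default_factory=CorrelationKernel)
    epsilon: float = 0.0            # deg^2
    direction_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 360.0, 15.0))
    kind: Literal["homogeneous", "heterogeneous"] = "homogeneous"
    eval_theta: float = 0.0
    correlate_total_variance: bool = True

    def __post_init__(self) -> None:
        if len(self.tuning_set) < 2:
            raise ValueError("population needs >= 2 neurons")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        self.direction_grid = np.asarray(self.direction_grid, dtype=float)

    @property
    def n_neurons(self) -> int:
        return len(self.tuning_set)

    @property
    def pref_directions(self) -> np.ndarray:
        return np.array([c.pref_direction for c in self.tuning_set])


def homogeneous_population(curve: TuningCurveFit, n: int, **kwargs) -> PopulationModel:
    """N copies of one tuning curve, preferred directions tiling the circle."""
    prefs = np.arange(n) * 360.0 / n - 180.0
    return PopulationModel([curve.with_pref(p) for p in prefs],
                           kind="homogeneous", **kwargs)


def heterogeneous_population(tuning_pool: Sequence[TuningCurveFit], n: int,
                             seed: int, sample_with_replacement: bool = True,
                             pref_mode: Literal["even", "uniform"] = "even",
                             **kwargs) -> PopulationModel:
    """Sample N curves from a pool and reassign preferred directions.

    With ``pref_mode='even'`` the preferred directions are spaced evenly
    over the circle; ``'uniform'`` draws them uniformly at random.
    """
    if len(tuning_pool) == 0:
        raise ValueError("tuning_pool must be nonempty")
    rng = np.random.default_rng(seed)
    if sample_with_replacement:
        idx = rng.integers(0, len(tuning_pool), size=n)
    else:
        if n > len(tuning_pool):
            raise ValueError("cannot sample more than the pool without replacement")
        idx = rng.permutation(len(tuning_pool))[:n]
    if pref_mode == "even":
        prefs = np.arange(n) * 360.0 / n - 180.0
    else:
        prefs = rng.uniform(-180.0, 180.0, size=n)
    curves = [tuning_pool[i].with_pref(p) for i, p in zip(idx, prefs)]
    return PopulationModel(curves, kind="heterogeneous", **kwargs)


# ---------------------------------------------------------------------------
# Covariance assembly

def _psd_repair(sigma: np.ndarray, clip_frac: float = 1e-10,
                max_rel_change: float = 1e-6) -> np.ndarray:
    """Clip tiny negative eigenvalues; error if the repair is not negligible."""
    sigma = 0.5 * (sigma + sigma.T)
    try:
        np.linalg.cholesky(sigma)
        return sigma            # already PD — skip the eigendecomposition
    except np.linalg.LinAlgError:
        pass
    w, v = np.linalg.eigh(sigma)
    floor = clip_frac * w.max()
    if w.min() >= floor:
        return sigma
    w_clipped = np.clip(w, floor, None)
    repaired = (v * w_clipped) @ v.T
    rel = np.linalg.norm(repaired - sigma) / np.linalg.norm(sigma)
    if rel > max_rel_change:
        raise ValueError(
            f"covariance PSD repair changed the matrix by {rel:.2e} "
            f"(> {max_rel_change:.0e}): model covariance is not valid")
    return repaired


def build_covariance(pop: PopulationModel, theta: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(Sigma_0, Sigma_eps) at stimulus direction theta.

    Diagonal: var_i = FF_i(theta) * f_i(theta).  Off-diagonal:
    c(d_ij) * sqrt(var_i var_j) from the correlation kernel on
    preferred-direction differences.  Sigma_eps adds the rank-one
    information-limiting term eps * f' f'^T (f' in counts per degree).
    """
    f = np.array([c(theta) for c in pop.tuning_set], dtype=float)
    prefs = pop.pref_directions
    ff = np.array([pop.ff_spec.ff(theta, p, pop.direction_grid) for p in prefs],
                  dtype=float).ravel()
    if pop.correlate_total_variance:
        var = ff * f
    else:
        var = f  # correlate the Poisson part only; FF applied to diagonal below
    if np.any(var <= 0):
        raise ValueError("zero or negative variance in the population model")
    d = prefs[:, None] - prefs[None, :]
    c = pop.corr(d)
    np.fill_diagonal(c, 1.0)
    sigma0 = c * np.sqrt(np.outer(var, var))
    if not pop.correlate_total_variance:
        np.fill_diagonal(sigma0, ff * f)
    sigma0 = _psd_repair(sigma0)
    fprime = np.array([c_.derivative(theta) for c_ in pop.tuning_set], dtype=float)
    sigma_eps = sigma0 + pop.epsilon * np.outer(fprime, fprime)
    return sigma0, sigma_eps


# ---------------------------------------------------------------------------
# Fisher information and thresholds

@dataclass
class DecodingResult:
    J0: float                     # deg^-2
    J_eps: float                  # deg^-2
    cr_bound_deg: float
    theta: float
    min_n: int | None = None
    min_t_ms: float | None = None


def _quadratic_form(fprime: np.ndarray, sigma: np.ndarray) -> float:
    try:
        return float(fprime @ np.linalg.solve(sigma, fprime))
    except np.linalg.LinAlgError:
        ridge = 1e-10 * np.trace(sigma) / sigma.shape[0]
        log.warning("singular covariance; retrying with ridge %.3g", ridge)
        return float(fprime @ np.linalg.solve(
            sigma + ridge * np.eye(sigma.shape[0]), fprime))


def linear_fisher(pop: PopulationModel, theta: float,
                  consistency_tol: float = 1e-6) -> DecodingResult:
    """Linear Fisher information and Cramer-Rao bound at direction theta.

    J_eps is computed both directly from Sigma_eps and through the
    rank-one-update identity J_eps = J0/(1 + eps*J0); the two must agree
    to ``consistency_tol`` relative (internal consistency check).
    """
    sigma0, sigma_eps = build_covariance(pop, theta)
    fprime = np.array([c.derivative(theta) for c in pop.tuning_set], dtype=float)
    j0 = _quadratic_form(fprime, sigma0)
    j_eps_direct = _quadratic_form(fprime, sigma_eps)
    j_eps_formula = j0 / (1.0 + pop.epsilon * j0)
    if j_eps_formula > 0:
        rel = abs(j_eps_direct - j_eps_formula) / j_eps_formula
        if rel > consistency_tol:
            raise AssertionError(
                f"rank-one-update identity violated: relative gap {rel:.2e}")
    cr = np.sqrt(1.0 / j0 + pop.epsilon) if j0 > 0 else np.inf
    return DecodingResult(j0, j_eps_formula, float(cr), theta)


def mean_cr_bound(pop: PopulationModel, theta_grid=None) -> float:
    """Cramer-Rao bound averaged over evaluation directions."""
    grid = pop.direction_grid if theta_grid is None else np.asarray(theta_grid)
    return float(np.mean([linear_fisher(pop, th).cr_bound_deg for th in grid]))


def neurons_to_threshold(pop_family: Callable[[int], PopulationModel],
                         threshold_deg: float,
                         n_grid: Sequence[int],
                         theta_grid=None) -> tuple[int | None, np.ndarray]:
    """Smallest population size whose mean Cramer-Rao bound is <= threshold.

    ``pop_family`` maps N to a PopulationModel; the search bisects over the
    (verified monotone) bound-vs-N curve.  Returns (minimal N or None, the
    full curve as an (N, bound) array).  A threshold below sqrt(eps) is
    unreachable — the information-limiting floor — and returns None.
    """
    n_grid = sorted(int(n) for n in n_grid)
    bounds = np.array([mean_cr_bound(pop_family(n), theta_grid) for n in n_grid])
    if np.any(np.diff(bounds) > 1e-9):
        raise ValueError("Cramer-Rao bound is not non-increasing in N on this grid")
    eps = pop_family(n_grid[0]).epsilon
    if threshold_deg < np.sqrt(eps):
        log.info("threshold %.3g deg below the information-limiting floor %.3g deg",
                 threshold_deg, np.sqrt(eps))
        return None, np.column_stack([n_grid, bounds])
    hit = np.flatnonzero(bounds <= threshold_deg)
    min_n = int(n_grid[hit[0]]) if hit.size else None
    return min_n, np.column_stack([n_grid, bounds])


def cumulative_tuning(rate_curve: TuningCurveFit, latency_ms: float,
                      t_ms: float) -> TuningCurveFit | None:
    """Expected cumulative-count tuning up to time T for a rate ramp with a
    hard latency onset: counts(T) = rate * max(0, T - latency) (rate in
    counts/ms given by ``rate_curve``)."""
    dt = max(0.0, t_ms - latency_ms)
    if dt == 0.0:
        return None
    return replace(rate_curve, baseline_b=rate_curve.baseline_b * dt,
                   amplitude_A=rate_curve.amplitude_A * dt, rss=None)


def time_to_threshold(pop_family: Callable[[float], PopulationModel | None],
                      threshold_deg: float, t_grid_ms: Sequence[float],
                      theta_grid=None) -> tuple[float | None, np.ndarray]:
    """Smallest accumulation time whose mean bound is <= threshold.

    ``pop_family`` maps T (ms) to a PopulationModel built from cumulative
    tuning up to T, or None before the response latency (no signal: the
    bound is infinite there).  Returns (minimal T or None, (T, bound) curve).
    """
    rows = []
    min_t = None
    for t in sorted(float(t) for t in t_grid_ms):
        pop = pop_family(t)
        b = np.inf if pop is None else mean_cr_bound(pop, theta_grid)
        rows.append((t, b))
        if min_t is None and b <= threshold_deg:
            min_t = t
    if min_t is None:
        log.info("bound never crosses %.3g deg within the analysis window",
                 threshold_deg)
    return min_t, np.asarray(rows)
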