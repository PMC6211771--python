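"""Synthetic spike-count and spike-train generators.

Every downstream analysis in this package is exercised on data from these
generators, which emulate the statistical structure of direction-tuned
cortical responses:

* direction-tuned mean counts (von Mises or Gaussian tuning curves);
* a trial-wise multiplicative gain g ~ Gamma(mean 1, variance var_g);
* count variance scaling as rate**alpha about the gain-scaled mean;
* a slow within-trial gain process with exponential autocorrelation
  (stationary AR(1), time constant tau_gain_ms);
* a hard response-latency onset; and
* population pairwise correlations that decay with the difference in
  preferred direction, plus an optional information-limiting component.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Literal, Sequence

import numpy as np

from .core import BinnedSpikeTensor, CountMatrix, GainModelParams, TuningCurveFit

__all__ = [
    "SyntheticConfig",
    "generate_trial_counts",
    "generate_temporal_trains",
    "generate_population_sample",
    "sample_gain",
    "ar1_gain_process",
]


def _default_direction_grid() -> tuple[float, ...]:
    # 13 directions spanning +/-90 deg in 15-deg steps around preferred.
    return tuple(float(d) for d in range(-90, 91, 15))


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic two-dimensional (count) or temporal run."""

    n_neurons: int = 1
    n_trials: int = 100
    direction_grid: Sequence[float] = field(default_factory=_default_direction_grid)
    gain_params: GainModelParams = field(default_factory=lambda: GainModelParams(1.0, 0.0))
    tuning: TuningCurveFit | Sequence[TuningCurveFit] | Callable[[int], TuningCurveFit] = field(
        default_factory=lambda: TuningCurveFit(10.0, 40.0, 2.0, 0.0))
    latency_ms: float = 0.0
    bin_ms: float = 2.0
    tau_gain_ms: float = 0.0
    trial_duration_ms: float = 500.0
    count_mode: Literal["continuous", "rounded"] = "continuous"
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.direction_grid, dtype=float)
        if len(np.unique(grid)) != grid.size:
            raise ValueError("direction_grid entries must be unique")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.bin_ms <= 0 or self.trial_duration_ms <= 0:
            raise ValueError("bin_ms and trial_duration_ms must be positive")
        n_bins = self.trial_duration_ms / self.bin_ms
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("bin_ms must divide trial_duration_ms")
        if self.latency_ms < 0 or self.tau_gain_ms < 0:
            raise ValueError("latency_ms and tau_gain_ms must be >= 0")

    def tuning_for(self, neuron: int) -> TuningCurveFit:
        if isinstance(self.tuning, TuningCurveFit):
            return self.tuning
        if callable(self.tuning):
            return self.tuning(neuron)
        return self.tuning[neuron]

    def manifest(self) -> dict:
        d = {
            "n_neurons": self.n_neurons,
            "n_trials": self.n_trials,
            "direction_grid": list(map(float, self.direction_grid)),
            "gain_params": asdict(self.gain_params),
            "latency_ms": self.latency_ms,
            "bin_ms": self.bin_ms,
            "tau_gain_ms": self.tau_gain_ms,
            "trial_duration_ms": self.trial_duration_ms,
            "count_mode": self.count_mode,
            "seed": self.seed,
        }
        if isinstance(self.tuning, TuningCurveFit):
            d["tuning"] = asdict(self.tuning)
        return d

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)


def sample_gain(params: GainModelParams, size, rng: np.random.Generator) -> np.ndarray:
    """Draw trial gains: Gamma(1/var_g, var_g), or exactly 1 when var_g = 0."""
    if params.var_g == 0:
        return np.ones(size)
    return rng.gamma(shape=params.gamma_shape, scale=params.gamma_scale, size=size)


def generate_trial_counts(config: SyntheticConfig) -> CountMatrix:
    """Sample spike counts from the multiplicative-gain variance model.

    Per trial the tuned mean f(theta) is scaled by a Gamma gain g, and the
    count is drawn from a normal law with mean mu = f(theta)*g and variance
    mu**alpha, clipped below at zero (continuous by default; ``rounded``
    mode rounds to integers, which biases Fano factors at low rates).
    """
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.direction_grid, dtype=float)
    p = config.gain_params
    counts = np.empty((config.n_neurons, grid.size, config.n_trials))
    for i in range(config.n_neurons):
        f = config.tuning_for(i)(grid)  # (n_dir,)
        if np.any(f <= 0):
            raise ValueError(
                f"tuning of neuron {i} is non-positive at some direction; "
                "mu**alpha is then undefined — reject configuration")
        g = sample_gain(p, (grid.size, config.n_trials), rng)
        mu = f[:, None] * g
        sd = np.sqrt(mu ** p.alpha)
        counts[i] = np.clip(rng.normal(mu, sd), 0.0, None)
    if config.count_mode == "rounded":
        counts = np.round(counts)
    return CountMatrix(counts, grid)


def ar1_gain_process(n_trials: int, n_bins: int, var_g: float, tau_ms: float,
                     bin_ms: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary mean-1 AR(1) gain with lag-k correlation exp(-k*bin/tau).

    A discrete Ornstein-Uhlenbeck process initialized from its stationary
    distribution; degenerates to constant gain 1 when var_g = 0 and to
    white gain noise when tau_ms = 0.
    """
    if var_g == 0:
        if tau_ms > 0:
            warnings.warn("tau_gain_ms > 0 with var_g = 0: gain process is constant")
        return np.ones((n_trials, n_bins))
    if tau_ms == 0:
        return 1.0 + np.sqrt(var_g) * rng.standard_normal((n_trials, n_bins))
    rho = np.exp(-bin_ms / tau_ms)
    innov_sd = np.sqrt(var_g * (1.0 - rho ** 2))
    x = np.empty((n_trials, n_bins))
    x[:, 0] = np.sqrt(var_g) * rng.standard_normal(n_trials)
    eps = innov_sd * rng.standard_normal((n_trials, n_bins - 1))
    for t in range(1, n_bins):
        x[:, t] = rho * x[:, t - 1] + eps[:, t - 1]
    return 1.0 + x


def generate_temporal_trains(config: SyntheticConfig,
                             count_window_ms: float = 250.0) -> BinnedSpikeTensor:
    """Poisson trains modulated by a slow AR(1) gain and a latency onset.

    Per-bin counts are Poisson with rate f(theta) * g_t * bin_ms/window_ms
    (f is the expected count in ``count_window_ms``), zero before
    ``latency_ms``.  The spike-count autocorrelation of the output decays
    with time constant ~ tau_gain_ms.
    """
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.direction_grid, dtype=float)
    n_bins = int(round(config.trial_duration_ms / config.bin_ms))
    p = config.gain_params
    counts = np.empty((config.n_neurons, grid.size, config.n_trials, n_bins),
                      dtype=np.int64)
    onset_bin = int(np.ceil(config.latency_ms / config.bin_ms))
    for i in range(config.n_neurons):
        f = config.tuning_for(i)(grid)
        for di in range(grid.size):
            g = ar1_gain_process(config.n_trials, n_bins, p.var_g,
                                 config.tau_gain_ms, config.bin_ms, rng)
            rate = f[di] * np.clip(g, 0.0, None) * (config.bin_ms / count_window_ms)
            if onset_bin > 0:
                rate[:, :onset_bin] = 0.0
            counts[i, di] = rng.poisson(rate)
    return BinnedSpikeTensor(counts, grid, bin_ms=config.bin_ms)


def generate_population_sample(pop, n_trials: int, seed: int):
    """Sample correlated population responses at the model's evaluation direction.

    Draws ``n_trials`` samples from a multivariate normal with the model
    mean vector and the information-limited covariance Sigma_eps, and
    returns ``(samples, Sigma_eps)`` so the generating covariance can be
    compared against empirical estimates.
    """
    from .population_decoding import build_covariance

    rng = np.random.default_rng(seed)
    theta = float(pop.eval_theta)
    mean = np.array([c(theta) for c in pop.tuning_set], dtype=float)
    _, sigma_eps = build_covariance(pop, theta)
    samples = rng.multivariate_normal(mean, sigma_eps, size=n_trials,
                                      method="eigh")
    return samples, sigma_eps
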