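"""Shared domain types for spike-count variability analysis.

The objects here are deliberately thin: counts live in pandas/numpy
containers, and the dataclasses carry the model parameters that the
generator, the statistics and the fitting code all share.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GainModelParams",
    "TuningCurveFit",
    "CountMatrix",
    "BinnedSpikeTensor",
    "tuning_value",
    "von_mises_tuning",
    "gaussian_tuning",
]


@dataclass(frozen=True)
class GainModelParams:
    """Parameters of the multiplicative-gain variance model.

    The trial gain g is Gamma-distributed with mean 1 and variance
    ``var_g`` (shape 1/var_g, scale var_g — the unique mean-1 Gamma).
    Spike-count variance scales with the underlying rate as rate**alpha.
    """

    alpha: float
    var_g: float

    ALPHA_RANGE = (0.0, 2.0)

    def __post_init__(self) -> None:
        lo, hi = self.ALPHA_RANGE
        if not np.isfinite(self.alpha) or not (lo <= self.alpha <= hi):
            raise ValueError(f"alpha must be finite and in [{lo}, {hi}], got {self.alpha}")
        if not np.isfinite(self.var_g) or self.var_g < 0:
            raise ValueError(f"var_g must be finite and >= 0, got {self.var_g}")

    @property
    def gamma_shape(self) -> float:
        if self.var_g == 0:
            raise ValueError("degenerate gain (var_g=0) has no Gamma form")
        return 1.0 / self.var_g

    @property
    def gamma_scale(self) -> float:
        if self.var_g == 0:
            raise ValueError("degenerate gain (var_g=0) has no Gamma form")
        return self.var_g


def von_mises_tuning(theta_deg: np.ndarray, b: float, A: float, kappa: float,
                     pref_deg: float) -> np.ndarray:
    """Circular tuning curve b + A*(exp(kappa*(cos(d)+1))-1)/(exp(2*kappa)-1).

    Equals b + A at the preferred direction and b at 180 degrees away;
    360-degree periodic and even about the preferred direction.
    """
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - pref_deg)
    return b + A * np.expm1(kappa * (np.cos(d) + 1.0)) / np.expm1(2.0 * kappa)


def gaussian_tuning(theta_deg: np.ndarray, b: float, A: float, sigma_deg: float,
                    pref_deg: float) -> np.ndarray:
    """Gaussian direction tuning on the circle (wrapped difference)."""
    d = np.asarray(theta_deg, dtype=float) - pref_deg
    d = (d + 180.0) % 360.0 - 180.0
    return b + A * np.exp(-0.5 * (d / sigma_deg) ** 2)


@dataclass(frozen=True)
class TuningCurveFit:
    """Parametric direction tuning curve (counts per counting window)."""

    baseline_b: float
    amplitude_A: float
    width: float          # kappa (dimensionless) for von Mises, sigma in deg for gaussian
    pref_direction: float  # degrees in [-180, 180)
    shape: Literal["von_mises", "gaussian"] = "von_mises"
    rss: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_b < 0 or self.amplitude_A < 0:
            raise ValueError("baseline and amplitude must be nonnegative")
        if self.width <= 0:
            raise ValueError("tuning width must be positive")
        if self.shape not in ("von_mises", "gaussian"):
            raise ValueError(f"unknown tuning shape {self.shape!r}")

    def __call__(self, theta_deg) -> np.ndarray:
        if self.shape == "von_mises":
            return von_mises_tuning(theta_deg, self.baseline_b, self.amplitude_A,
                                    self.width, self.pref_direction)
        return gaussian_tuning(theta_deg, self.baseline_b, self.amplitude_A,
                               self.width, self.pref_direction)

    def derivative(self, theta_deg) -> np.ndarray:
        """Analytic d f / d theta in counts per degree."""
        th = np.asarray(theta_deg, dtype=float)
        if self.shape == "von_mises":
            d = np.deg2rad(th - self.pref_direction)
            val = (-self.amplitude_A * self.width * np.sin(d)
                   * np.exp(self.width * (np.cos(d) + 1.0))
                   / np.expm1(2.0 * self.width))
            return val * np.pi / 180.0
        d = (th - self.pref_direction + 180.0) % 360.0 - 180.0
        return (-self.amplitude_A * d / self.width ** 2
                * np.exp(-0.5 * (d / self.width) ** 2))

    def with_pref(self, pref_deg: float) -> "TuningCurveFit":
        return replace(self, pref_direction=float(pref_deg))


def tuning_value(curve: TuningCurveFit, theta_deg) -> np.ndarray:
    return curve(theta_deg)


@dataclass
class CountMatrix:
    """Trial-resolved spike counts indexed by neuron x direction x trial.

    ``counts`` has shape (n_neurons, n_directions, n_trials).  Directions
    are degrees; the counting window (start, end in ms) and its alignment
    are metadata carried along for provenance.
    """

    counts: np.ndarray
    directions: np.ndarray
    window: tuple[float, float] = (0.0, 250.0)
    alignment: Literal["stimulus_onset", "response_onset"] = "stimulus_onset"
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (neuron, direction, trial)")
        if self.counts.shape[1] != self.directions.size:
            raise ValueError("direction axis mismatch")
        if len(np.unique(self.directions)) != self.directions.size:
            raise ValueError("directions must be unique")
        if self.counts.shape[2] < 2:
            raise ValueError("need >= 2 trials per direction")
        if self.window[1] <= self.window[0]:
            raise ValueError("window end must exceed start")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.counts.shape[0])

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[2]

    def to_frame(self) -> pd.DataFrame:
        n, d, t = self.counts.shape
        idx = pd.MultiIndex.from_product(
            [np.asarray(self.neuron_ids), self.directions, np.arange(t)],
            names=["neuron_id", "direction_deg", "trial"])
        return pd.DataFrame({"count": self.counts.ravel()}, index=idx).reset_index()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, window=(0.0, 250.0),
                   alignment="stimulus_onset") -> "CountMatrix":
        required = {"neuron_id", "direction_deg", "trial", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"counts table needs columns {sorted(required)}")
        pivot = df.pivot_table(index="neuron_id", columns=["direction_deg", "trial"],
                               values="count")
        neurons = pivot.index.to_numpy()
        directions = np.array(sorted(df["direction_deg"].unique()))
        trials = np.array(sorted(df["trial"].unique()))
        arr = np.full((neurons.size, directions.size, trials.size), np.nan)
        for di, dd in enumerate(directions):
            for ti, tt in enumerate(trials):
                arr[:, di, ti] = pivot[(dd, tt)].to_numpy()
        if np.isnan(arr).any():
            raise ValueError("counts table is not a complete neuron x direction x trial grid")
        return cls(arr, directions, window=window, alignment=alignment,
                   neuron_ids=neurons)

    @classmethod
    def from_csv(cls, path, window=(0.0, 250.0), alignment="stimulus_onset") -> "CountMatrix":
        return cls.from_frame(pd.read_csv(path), window=window, alignment=alignment)


@dataclass
class BinnedSpikeTensor:
    """Binned spike trains: counts (neuron, direction, trial, time-bin)."""

    counts: np.ndarray
    directions: np.ndarray
    bin_ms: float
    t0_ms: float = 0.0
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.counts.ndim != 4:
            raise ValueError("counts must be (neuron, direction, trial, bin)")
        if self.counts.shape[1] != self.directions.size:
            raise ValueError("direction axis mismatch")
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.counts.shape[0])

    @property
    def n_bins(self) -> int:
        return self.counts.shape[3]

    @property
    def bin_starts_ms(self) -> np.ndarray:
        return self.t0_ms + self.bin_ms * np.arange(self.n_bins)

    def window_counts(self, window: tuple[float, float],
                      alignment="stimulus_onset") -> CountMatrix:
        """Sum bins whose start lies in [window[0], window[1])."""
        starts = self.bin_starts_ms
        mask = (starts >= window[0]) & (starts < window[1])
        if not mask.any():
            raise ValueError("window outside the recorded span")
        summed = self.counts[..., mask].sum(axis=3)
        return CountMatrix(summed, self.directions, window=window,
                           alignment=alignment, neuron_ids=self.neuron_ids)

    def to_frame(self) -> pd.DataFrame:
        n, d, t, b = self.counts.shape
        idx = pd.MultiIndex.from_product(
            [np.asarray(self.neuron_ids), self.directions, np.arange(t),
             self.bin_starts_ms],
            names=["neuron_id", "direction_deg", "trial", "bin_start_ms"])
        return pd.DataFrame({"count": self.counts.ravel()}, index=idx).reset_index()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
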