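"""Spike-count statistics, tuning fits, tuning indices and mean matching.

The central quantities are the per-direction mean count, unbiased count
variance, and Fano factor FF = variance/mean, together with contrast
indices comparing the preferred direction against the orthogonal ones:

    DI   = (r_pref - r_orth) / (r_pref + r_orth)
    VTI  = (var_pref - var_orth) / (var_pref + var_orth)
    FFTI = (FF_orth - FF_pref) / (FF_orth + FF_pref)

Positive FFTI means U-shaped Fano-factor tuning (a dip in FF at the
preferred direction); negative FFTI means Gaussian-like FF tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core import BinnedSpikeTensor, CountMatrix, TuningCurveFit

__all__ = [
    "DirectionStats",
    "TuningIndices",
    "count_in_window",
    "direction_stats",
    "tuning_indices",
    "fit_tuning_curve",
    "estimate_latency",
    "ff_expanding_windows",
    "mean_matched_ffti",
    "MeanMatchResult",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Windowed counting

def count_in_window(data, window: tuple[float, float],
                    alignment: str = "stimulus_onset",
                    latencies_ms=None) -> CountMatrix:
    """Count events in the half-open interval [start, end).

    ``data`` is either a :class:`BinnedSpikeTensor` or a nested sequence of
    spike-time arrays indexed [neuron][direction][trial] (ms), paired with a
    ``directions`` attribute or passed as ``(spike_times, directions)``.
    With ``alignment='response_onset'`` the window is shifted by each
    neuron's latency (required).
    """
    if window[1] <= window[0]:
        raise ValueError("window end must exceed start")
    if isinstance(data, BinnedSpikeTensor):
        if alignment == "response_onset":
            if latencies_ms is None:
                raise ValueError("response_onset alignment requires per-neuron latencies")
            mats = []
            for i in range(data.counts.shape[0]):
                shifted = (window[0] + latencies_ms[i], window[1] + latencies_ms[i])
                mats.append(data.window_counts(shifted).counts[i])
            return CountMatrix(np.stack(mats), data.directions, window=window,
                               alignment="response_onset", neuron_ids=data.neuron_ids)
        return data.window_counts(window, alignment=alignment)
    spike_times, directions = data
    if len(spike_times) == 0:
        raise ValueError("empty trial set")
    lat = latencies_ms if alignment == "response_onset" else None
    if alignment == "response_onset" and lat is None:
        raise ValueError("response_onset alignment requires per-neuron latencies")
    n_neurons = len(spike_times)
    n_dir = len(directions)
    n_trials = len(spike_times[0][0])
    counts = np.empty((n_neurons, n_dir, n_trials))
    for i in range(n_neurons):
        off = lat[i] if lat is not None else 0.0
        for d in range(n_dir):
            for t in range(n_trials):
                st = np.asarray(spike_times[i][d][t], dtype=float)
                counts[i, d, t] = np.count_nonzero(
                    (st >= window[0] + off) & (st < window[1] + off))
    return CountMatrix(counts, np.asarray(directions, dtype=float),
                       window=window, alignment=alignment)


# ---------------------------------------------------------------------------
# Per-direction statistics

@dataclass
class DirectionStats:
    """Per-direction count statistics for one neuron (directions aligned
    so that the preferred direction is at ``pref_direction``)."""

    directions: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    ff: np.ndarray            # NaN where the mean is zero (FF undefined)
    pref_direction: float
    orth_mode: Literal["average", "pool"] = "average"
    pooled_orth: tuple[float, float] | None = None  # (mean, var) when pooling

    def _nearest(self, target: float) -> int:
        d = (self.directions - target + 180.0) % 360.0 - 180.0
        return int(np.argmin(np.abs(d)))

    def _orth_indices(self) -> list[int]:
        plus = self._nearest(self.pref_direction + 90.0)
        minus = self._nearest(self.pref_direction - 90.0)
        return [plus] if plus == minus else [minus, plus]

    @property
    def r_pref(self) -> float:
        return float(self.mean[self._nearest(self.pref_direction)])

    @property
    def r_orth(self) -> float:
        return float(np.mean(self.mean[self._orth_indices()]))

    @property
    def var_pref(self) -> float:
        return float(self.var[self._nearest(self.pref_direction)])

    @property
    def var_orth(self) -> float:
        return float(np.mean(self.var[self._orth_indices()]))

    @property
    def ff_pref(self) -> float:
        return float(self.ff[self._nearest(self.pref_direction)])

    @property
    def ff_orth(self) -> float:
        idx = self._orth_indices()
        if self.orth_mode == "pool" and self.pooled_orth is not None:
            m, v = self.pooled_orth
            return v / m if m > 0 else np.nan
        vals = self.ff[idx]
        if np.isnan(vals).all():
            return np.nan
        return float(np.nanmean(vals))


@dataclass(frozen=True)
class TuningIndices:
    DI: float
    VTI: float
    FFTI: float
    delta_FF: float
    excluded_reason: str | None = None


def direction_stats(cm: CountMatrix, pref: float | Literal["argmax", "fit"] = "argmax",
                    orth_mode: Literal["average", "pool"] = "average"
                    ) -> list[DirectionStats]:
    """Mean, unbiased variance and Fano factor per direction, per neuron.

    ``pref`` selects how the preferred direction is determined: a float uses
    that direction for every neuron, ``'argmax'`` the direction of maximum
    mean count, ``'fit'`` the preferred direction of a von Mises tuning fit
    (less noisy on real data).  ``orth_mode='pool'`` pools trials across the
    two orthogonal directions instead of averaging their statistics.
    """
    if cm.n_trials < 2:
        raise ValueError("variance needs >= 2 trials per direction")
    out = []
    for i in range(cm.n_neurons):
        c = cm.counts[i]
        mean = c.mean(axis=1)
        var = c.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ff = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)
        if isinstance(pref, (int, float)):
            p = float(pref)
        elif pref == "argmax":
            p = float(cm.directions[int(np.argmax(mean))])
        elif pref == "fit":
            fit = fit_tuning_curve(cm.directions, mean, shape="von_mises")
            p = float(cm.directions[
                int(np.argmin(np.abs((cm.directions - fit.pref_direction + 180) % 360 - 180)))])
        else:
            raise ValueError(f"unknown pref mode {pref!r}")
        ds = DirectionStats(cm.directions.copy(), mean, var, ff, p, orth_mode)
        if orth_mode == "pool":
            idx = ds._orth_indices()
            pooled = c[idx].ravel()
            ds.pooled_orth = (float(pooled.mean()), float(pooled.var(ddof=1)))
        out.append(ds)
    return out


def tuning_indices(ds: DirectionStats) -> TuningIndices:
    """Contrast indices of mean, variance and Fano factor (pref vs orth)."""
    def contrast(a, b):
        s = a + b
        return (a - b) / s if s > 0 else np.nan

    di = contrast(ds.r_pref, ds.r_orth)
    vti = contrast(ds.var_pref, ds.var_orth)
    ff_o, ff_p = ds.ff_orth, ds.ff_pref
    if np.isnan(ff_o):
        reason = ("did not emit any spikes to the orthogonal stimulus direction, "
                  "and thus FF_orth was not defined")
        log.info("neuron excluded from FFTI: %s", reason)
        return TuningIndices(di, vti, np.nan, np.nan, excluded_reason=reason)
    ffti = contrast(ff_o, ff_p)
    return TuningIndices(di, vti, ffti, ff_o - ff_p)


def indices_frame(cm: CountMatrix, **kwargs) -> pd.DataFrame:
    """Convenience: tuning indices for every neuron in a count matrix."""
    rows = []
    for nid, ds in zip(np.asarray(cm.neuron_ids), direction_stats(cm, **kwargs)):
        ti = tuning_indices(ds)
        rows.append({"neuron_id": nid, "DI": ti.DI, "VTI": ti.VTI, "FFTI": ti.FFTI,
                     "delta_FF": ti.delta_FF, "excluded_reason": ti.excluded_reason})
    return pd.DataFrame(rows)


def stats_frame(cm: CountMatrix, **kwargs) -> pd.DataFrame:
    rows = []
    for nid, ds in zip(np.asarray(cm.neuron_ids), direction_stats(cm, **kwargs)):
        for d, m, v, f in zip(ds.directions, ds.mean, ds.var, ds.ff):
            rows.append({"neuron_id": nid, "direction_deg": d,
                         "mean": m, "var": v, "ff": f})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tuning-curve fitting

def _vm(theta, b, A, kappa, pref):
    from .core import von_mises_tuning
    return von_mises_tuning(theta, b, A, kappa, pref)


def _gauss(theta, b, A, sigma, pref):
    from .core import gaussian_tuning
    return gaussian_tuning(theta, b, A, sigma, pref)


def fit_tuning_curve(directions, means, shape: str = "von_mises") -> TuningCurveFit:
    """Nonlinear least-squares fit of a tuning curve to mean counts.

    Multi-start over width; raises RuntimeError if no start converges.
    A flat profile is returned with amplitude ~0 and an arbitrary
    (unconstrained) preferred direction.
    """
    directions = np.asarray(directions, dtype=float)
    means = np.asarray(means, dtype=float)
    if np.unique(directions).size < 4:
        raise ValueError("need >= 4 distinct directions to fit a tuning curve")
    fn = _vm if shape == "von_mises" else _gauss
    b0 = max(float(means.min()), 1e-6)
    A0 = max(float(means.max() - means.min()), 1e-6)
    pref0 = float(directions[int(np.argmax(means))])
    widths = (0.5, 1.0, 2.0, 4.0) if shape == "von_mises" else (20.0, 40.0, 80.0)
    lo = [0.0, 0.0, 1e-3, -360.0]
    hi = [np.inf, np.inf, 50.0 if shape == "von_mises" else 360.0, 360.0]
    best, best_rss = None, np.inf
    last_err = None
    for w0 in widths:
        try:
            popt, _ = optimize.curve_fit(
                fn, directions, means, p0=[b0, A0, w0, pref0],
                bounds=(lo, hi), maxfev=20000)
        except RuntimeError as err:  # pragma: no cover - rare solver failure
            last_err = err
            continue
        rss = float(np.sum((fn(directions, *popt) - means) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
    if best is None:
        raise RuntimeError(f"tuning fit failed to converge: {last_err}")
    b, A, width, pref = best
    pref = (pref + 180.0) % 360.0 - 180.0
    return TuningCurveFit(float(b), float(A), float(width), float(pref),
                          shape=shape, rss=best_rss)


# ---------------------------------------------------------------------------
# Latency

def estimate_latency(psth_rate, bin_ms: float, onset_ms: float,
                     k: float = 3.0, m: int = 5) -> float | None:
    """First time after motion onset when the PSTH exceeds baseline.

    The baseline epoch is everything before ``onset_ms``; the criterion is
    rate > baseline mean + k * baseline SD for ``m`` consecutive bins.
    Returns the latency in ms relative to onset, or None when the
    criterion is never met.
    """
    psth_rate = np.asarray(psth_rate, dtype=float)
    onset_bin = int(round(onset_ms / bin_ms))
    if onset_bin < 1:
        raise ValueError("a pre-motion baseline epoch is required")
    base = psth_rate[:onset_bin]
    thresh = base.mean() + k * base.std(ddof=0)
    above = psth_rate[onset_bin:] > thresh
    if m > 1:
        run = np.convolve(above.astype(int), np.ones(m, dtype=int), mode="valid")
        hits = np.flatnonzero(run == m)
    else:
        hits = np.flatnonzero(above)
    if hits.size == 0:
        return None
    return float(hits[0] * bin_ms)


# ---------------------------------------------------------------------------
# Expanding-window Fano factors

def ff_expanding_windows(trains: BinnedSpikeTensor, durations_ms: Sequence[float],
                         alignment: str = "stimulus_onset",
                         latencies_ms=None) -> pd.DataFrame:
    """Fano factor of counts in windows expanding from onset.

    Windows all begin at motion onset (or at each neuron's response onset
    with ``alignment='response_onset'``).  The FF is taken at each neuron's
    preferred direction (direction of maximum mean count over the longest
    window).  Returns a tidy frame plus ``population_mean``/``population_sd``
    columns; windows with zero mean count yield NaN and are excluded from
    the population mean.
    """
    durations = np.asarray(durations_ms, dtype=float)
    if np.any(np.diff(durations) <= 0):
        raise ValueError("durations must be strictly increasing")
    full = count_in_window(trains, (0.0, durations[-1]), alignment, latencies_ms)
    pref_idx = full.counts.mean(axis=2).argmax(axis=1)
    rows = []
    for dur in durations:
        cmd = count_in_window(trains, (0.0, dur), alignment, latencies_ms)
        for i in range(cmd.n_neurons):
            c = cmd.counts[i, pref_idx[i]]
            mean = c.mean()
            ff = c.var(ddof=1) / mean if mean > 0 else np.nan
            rows.append({"neuron": i, "duration_ms": dur, "ff": ff})
    df = pd.DataFrame(rows)
    pop = df.groupby("duration_ms")["ff"].agg(
        population_mean="mean", population_sd="std",
        n_excluded=lambda s: int(s.isna().sum()))
    return df.merge(pop, on="duration_ms")


# ---------------------------------------------------------------------------
# Mean-matched FFTI

@dataclass
class MeanMatchResult:
    ffti_a: np.ndarray
    ffti_b: np.ndarray
    raw_ffti_a: float
    raw_ffti_b: float
    n_bins: int
    n_resamples: int
    matched_ff_a: pd.DataFrame | None = None  # mean matched FF vs direction
    matched_ff_b: pd.DataFrame | None = None

    @property
    def summary(self) -> dict:
        return {
            "ffti_a_mean": float(np.mean(self.ffti_a)),
            "ffti_a_sd": float(np.std(self.ffti_a)),
            "ffti_b_mean": float(np.mean(self.ffti_b)),
            "ffti_b_sd": float(np.std(self.ffti_b)),
        }


def _state_table(state: pd.DataFrame) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    req = {"direction_deg", "mean", "ff"}
    if not req.issubset(state.columns):
        raise ValueError(f"state table needs columns {sorted(req)}")
    out = {}
    for d, grp in state.groupby("direction_deg"):
        out[float(d)] = (grp["mean"].to_numpy(float), grp["ff"].to_numpy(float))
    return out


def _population_ffti(ff_by_dir: dict[float, float]) -> float:
    ff_pref = ff_by_dir[0.0]
    orth = [ff_by_dir[d] for d in (90.0, -90.0) if d in ff_by_dir]
    ff_orth = float(np.mean(orth))
    return (ff_orth - ff_pref) / (ff_orth + ff_pref)


def mean_matched_ffti(state_a: pd.DataFrame, state_b: pd.DataFrame,
                      n_bins: int = 15, n_resamples: int = 10_000,
                      directions: Sequence[float] = (-90.0, 0.0, 90.0),
                      seed: int = 0,
                      return_curves: bool = False) -> MeanMatchResult:
    """Mean-matched population FFTI between two behavioral states.

    At each direction (preferred = 0 deg and the orthogonal directions),
    neuron-level mean counts from both states are histogrammed into
    ``n_bins`` evenly spaced bins spanning the pooled range; in every bin
    the over-populated state randomly discards neurons until the bin counts
    match, removing mean-rate confounds.  The mean FF over retained neurons
    gives a per-state FF at that direction, and a population FFTI from the
    preferred vs orthogonal FFs.  Repeating ``n_resamples`` times yields
    the resampled FFTI distribution per state.

    Input tables have one row per neuron x direction with columns
    ``direction_deg`` (aligned, preferred = 0), ``mean`` and ``ff``.
    """
    rng = np.random.default_rng(seed)
    ta, tb = _state_table(state_a), _state_table(state_b)
    directions = [float(d) for d in directions]
    for d in directions:
        if d not in ta or d not in tb:
            raise ValueError(f"direction {d} missing from one of the states")

    # Precompute bin assignments once per direction; the randomness is only
    # in which points are discarded.
    bins: dict[float, tuple[list[np.ndarray], list[np.ndarray]]] = {}
    for d in directions:
        ma, _ = ta[d]
        mb, _ = tb[d]
        lo = min(ma.min(), mb.min())
        hi = max(ma.max(), mb.max())
        edges = np.linspace(lo, hi + 1e-12, n_bins + 1)
        ia = np.clip(np.digitize(ma, edges) - 1, 0, n_bins - 1)
        ib = np.clip(np.digitize(mb, edges) - 1, 0, n_bins - 1)
        groups_a = [np.flatnonzero(ia == k) for k in range(n_bins)]
        groups_b = [np.flatnonzero(ib == k) for k in range(n_bins)]
        if not any(g.size and h.size for g, h in zip(groups_a, groups_b)):
            raise ValueError(
                f"no overlapping mean-count bins at direction {d}: "
                "all points would be discarded")
        bins[d] = (groups_a, groups_b)

    ffti_a = np.empty(n_resamples)
    ffti_b = np.empty(n_resamples)
    curve_a = {d: 0.0 for d in directions}
    curve_b = {d: 0.0 for d in directions}
    for r in range(n_resamples):
        ff_a: dict[float, float] = {}
        ff_b: dict[float, float] = {}
        for d in directions:
            groups_a, groups_b = bins[d]
            _, ffs_a = ta[d]
            _, ffs_b = tb[d]
            keep_a: list[np.ndarray] = []
            keep_b: list[np.ndarray] = []
            for ga, gb in zip(groups_a, groups_b):
                n = min(ga.size, gb.size)
                if n == 0:
                    continue
                keep_a.append(ga if ga.size == n else rng.choice(ga, n, replace=False))
                keep_b.append(gb if gb.size == n else rng.choice(gb, n, replace=False))
            ff_a[d] = float(np.mean(ffs_a[np.concatenate(keep_a)]))
            ff_b[d] = float(np.mean(ffs_b[np.concatenate(keep_b)]))
        ffti_a[r] = _population_ffti(ff_a)
        ffti_b[r] = _population_ffti(ff_b)
        for d in directions:
            curve_a[d] += ff_a[d] / n_resamples
            curve_b[d] += ff_b[d] / n_resamples

    raw_a = _population_ffti({d: float(np.mean(ta[d][1])) for d in directions})
    raw_b = _population_ffti({d: float(np.mean(tb[d][1])) for d in directions})
    res = MeanMatchResult(ffti_a, ffti_b, raw_a, raw_b, n_bins, n_resamples)
    if return_curves:
        res.matched_ff_a = pd.DataFrame(
            {"direction_deg": directions, "ff": [curve_a[d] for d in directions]})
        res.matched_ff_b = pd.DataFrame(
            {"direction_deg": directions, "ff": [curve_b[d] for d in directions]})
    return res


def fit_cosine_ff(directions_deg, ff_values) -> tuple[float, float]:
    """Least-squares cosine fit FF(theta) = c0 + c1*cos(theta); returns (c0, c1)."""
    th = np.deg2rad(np.asarray(directions_deg, dtype=float))
    X = np.column_stack([np.ones_like(th), np.cos(th)])
    coef, *_ = np.linalg.lstsq(X, np.asarray(ff_values, dtype=float), rcond=None)
    return float(coef[0]), float(coef[1])
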