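"""End-to-end orchestration: presets, fixtures, and the staged pipeline.

Two presets parameterize the synthetic states the analyses are exercised
on.  The *alert-like* state has low gain variance, a short gain
correlation time and short latency; the *anesthetized-like* state has
nearly an order of magnitude more gain variance, slower gain fluctuations
and longer latency.  Gain-model parameters are the state-specific best-fit
pairs (alpha = 0.31, var_g = 0.0094 alert; alpha = 0.74, var_g = 0.0732
anesthetized); gain correlation times are 29 ms and 88 ms and latencies
56 ms and 94 ms.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GainModelParams, TuningCurveFit
from .synthetic_data import SyntheticConfig, generate_trial_counts, generate_temporal_trains

log = logging.getLogger(__name__)

__all__ = ["PRESETS", "preset_config", "make_fixtures", "run_pipeline",
           "load_config", "ALL_STAGES"]

ALL_STAGES = ("simulate", "stats", "mean_match", "autocorr", "mi", "fit_gain",
              "decode")

PRESETS: dict[str, dict] = {
    "alert_like": {
        "gain": {"alpha": 0.31, "var_g": 0.0094},
        "tuning": {"baseline_b": 3.0, "amplitude_A": 12.0, "width": 2.0,
                   "pref_direction": 0.0, "shape": "von_mises"},
        "direction_grid": [float(d) for d in range(-180, 180, 15)],
        "tau_gain_ms": 29.0,
        "latency_ms": 56.0,
        "n_neurons": 30,
        "n_trials": 100,
    },
    "anesthetized_like": {
        "gain": {"alpha": 0.74, "var_g": 0.0732},
        "tuning": {"baseline_b": 3.0, "amplitude_A": 9.0, "width": 2.0,
                   "pref_direction": 0.0, "shape": "von_mises"},
        "direction_grid": [float(d) for d in range(-90, 91, 15)],
        "tau_gain_ms": 88.0,
        "latency_ms": 94.0,
        "n_neurons": 30,
        "n_trials": 100,
    },
}


def _jitter_tuning(base: dict, rng: np.random.Generator) -> TuningCurveFit:
    # mild neuron-to-neuron heterogeneity around the preset tuning
    return TuningCurveFit(
        baseline_b=float(base["baseline_b"] * rng.uniform(0.7, 1.3)),
        amplitude_A=float(base["amplitude_A"] * rng.uniform(0.7, 1.3)),
        width=float(base["width"] * rng.uniform(0.8, 1.25)),
        pref_direction=base["pref_direction"],
        shape=base["shape"])


def preset_config(preset: str, seed: int, heterogeneous: bool = True,
                  **overrides) -> SyntheticConfig:
    """SyntheticConfig for a named preset; overrides replace preset fields."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    p = {**PRESETS[preset], **overrides}
    rng = np.random.default_rng(seed + 101)
    if heterogeneous:
        curves = [_jitter_tuning(p["tuning"], rng) for _ in range(p["n_neurons"])]
        tuning = curves
    else:
        tuning = TuningCurveFit(**p["tuning"])
    return SyntheticConfig(
        n_neurons=p["n_neurons"], n_trials=p["n_trials"],
        direction_grid=p["direction_grid"],
        gain_params=GainModelParams(**p["gain"]),
        tuning=tuning, latency_ms=p["latency_ms"],
        tau_gain_ms=p["tau_gain_ms"], seed=seed)


def make_fixtures(preset: str, out_dir, seed: int = 0,
                  temporal: bool = False) -> dict[str, Path]:
    """Write small seeded CSV datasets (plus manifest) for a preset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = preset_config(preset, seed)
    paths = {}
    cm = generate_trial_counts(cfg)
    paths["counts"] = out / f"{preset}_counts.csv"
    cm.to_csv(paths["counts"])
    if temporal:
        # single direction keeps the binned-train table small; the temporal
        # analyses work on within-trial fluctuations, not direction tuning
        tcfg = preset_config(preset, seed, n_neurons=min(cfg.n_neurons, 10),
                             n_trials=min(cfg.n_trials, 60),
                             direction_grid=[0.0])
        trains = generate_temporal_trains(tcfg)
        paths["trains"] = out / f"{preset}_trains.csv"
        trains.to_csv(paths["trains"])
    paths["manifest"] = out / f"{preset}_manifest.json"
    cfg.write_manifest(paths["manifest"])
    return paths


# ---------------------------------------------------------------------------
# Staged pipeline

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "results/pipeline",
    "stages": list(ALL_STAGES),
    "states": {"alert": {"preset": "alert_like"},
               "anesthetized": {"preset": "anesthetized_like"}},
    "temporal": {"n_neurons": 8, "n_trials": 60, "trial_duration_ms": 500.0},
    "mean_match": {"n_resamples": 2000},
    "mi": {"n_boot": 30, "max_neurons": 10},
    "fit_gain": {},
    "decode": {"n": 100, "kind": "homogeneous", "ff_amplitude": 0.3,
               "c_max": 0.1, "kappa_corr": 1.0, "epsilon": 4.0,
               "threshold_deg": 3.0,
               "n_grid": [25, 50, 100, 200, 400]},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config({**DEFAULT_CONFIG, **(cfg or {})})


def validate_config(cfg: dict) -> dict:
    cfg = {**DEFAULT_CONFIG, **cfg}
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    bad = set(cfg["stages"]) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    for label, sc in cfg["states"].items():
        if sc.get("preset") not in PRESETS:
            raise ValueError(f"state {label!r} needs a known preset")
    return cfg


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_pipeline(config: dict) -> dict:
    """Execute the requested stages in dependency order.

    Stages: simulate -> stats -> (mean_match | autocorr | mi) -> fit_gain
    -> decode.  Writes per-stage CSV/JSON outputs plus a manifest (config
    hash, seed, per-stage runtimes) under ``out_dir``.  Reruns with an
    identical config produce identical result files.
    """
    from . import gain_model, info_metrics, response_stats, temporal_stats
    from . import population_decoding as pdec
    from .core import CountMatrix

    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in cfg["stages"]]
    seed = cfg["seed"]
    runtimes = {}
    artifacts: dict[str, str] = {}
    state: dict = {}

    def record(stage, t0):
        runtimes[stage] = round(time.perf_counter() - t0, 3)

    if "simulate" in stages:
        t0 = time.perf_counter()
        state["counts"] = {}
        for li, (label, sc) in enumerate(sorted(cfg["states"].items())):
            scfg = preset_config(sc["preset"], seed + li,
                                 **{k: v for k, v in sc.items() if k != "preset"})
            cm = generate_trial_counts(scfg)
            state["counts"][label] = cm
            path = out / f"counts_{label}.csv"
            cm.to_csv(path)
            artifacts[f"counts_{label}"] = str(path)
        record("simulate", t0)

    def need_counts():
        if "counts" not in state:
            raise RuntimeError("stage requires 'simulate' output; run it first")
        return state["counts"]

    if "stats" in stages:
        t0 = time.perf_counter()
        state["stats"] = {}
        for label, cm in need_counts().items():
            sf = response_stats.stats_frame(cm, pref="argmax")
            ind = response_stats.indices_frame(cm, pref="argmax")
            sf.to_csv(out / f"stats_{label}.csv", index=False)
            ind.to_csv(out / f"indices_{label}.csv", index=False)
            state["stats"][label] = sf
            artifacts[f"stats_{label}"] = str(out / f"stats_{label}.csv")
        record("stats", t0)

    if "mean_match" in stages:
        t0 = time.perf_counter()
        if "stats" not in state:
            raise RuntimeError("mean_match requires 'stats' output; run it first")
        labels = sorted(state["stats"])
        a, b = state["stats"][labels[0]], state["stats"][labels[1]]
        common = sorted(set(a["direction_deg"]) & set(b["direction_deg"])
                        & {-90.0, 0.0, 90.0})
        res = response_stats.mean_matched_ffti(
            a, b, directions=common, seed=seed,
            n_resamples=cfg["mean_match"]["n_resamples"])
        _write_json(out / "mean_match.json",
                    {"state_a": labels[0], "state_b": labels[1], **res.summary,
                     "raw_ffti_a": res.raw_ffti_a, "raw_ffti_b": res.raw_ffti_b})
        artifacts["mean_match"] = str(out / "mean_match.json")
        record("mean_match", t0)

    if "autocorr" in stages:
        t0 = time.perf_counter()
        ac_out = {}
        for li, (label, sc) in enumerate(sorted(cfg["states"].items())):
            tcfg = preset_config(sc["preset"], seed + 31 + li,
                                 n_neurons=cfg["temporal"]["n_neurons"],
                                 n_trials=cfg["temporal"]["n_trials"],
                                 trial_duration_ms=cfg["temporal"]["trial_duration_ms"],
                                 latency_ms=0.0,
                                 direction_grid=[0.0])
            trains = generate_temporal_trains(tcfg)
            ac = temporal_stats.spike_count_autocorrelation(trains)
            fit = temporal_stats.fit_exponential_decay(ac)
            pd.DataFrame({"lag_ms": ac.lags_ms, "ac_mean": ac.population,
                          "ac_sd": ac.sd()}).to_csv(
                out / f"autocorr_{label}.csv", index=False)
            ac_out[label] = {"tau_ms": fit.tau_ms, "amplitude": fit.amplitude,
                             "lag_range_ms": list(fit.lag_range_ms),
                             "ill_defined": fit.ill_defined}
        _write_json(out / "autocorr_fits.json", ac_out)
        artifacts["autocorr"] = str(out / "autocorr_fits.json")
        record("autocorr", t0)

    if "mi" in stages:
        t0 = time.perf_counter()
        rows = []
        for label, cm in need_counts().items():
            nmax = min(cm.n_neurons, cfg["mi"]["max_neurons"])
            for i in range(nmax):
                est = info_metrics.bias_corrected_mi(
                    cm, i, n_boot=cfg["mi"]["n_boot"], seed=seed + i)
                rows.append({"state": label, "neuron_id": i,
                             "time_ms": cm.window[1],
                             "plugin_bits": est.plugin_bits,
                             "corrected_bits": est.corrected_bits})
        pd.DataFrame(rows).to_csv(out / "mi.csv", index=False)
        artifacts["mi"] = str(out / "mi.csv")
        record("mi", t0)

    if "fit_gain" in stages:
        t0 = time.perf_counter()
        fits = {}
        for label, cm in need_counts().items():
            sf = response_stats.stats_frame(cm, pref="argmax")
            per_neuron = gain_model.fit_neurons_lsq_frame(sf)
            per_neuron.to_csv(out / f"gainfit_{label}.csv", index=False)
            fits[label] = {
                "median_alpha": float(per_neuron["alpha"].median()),
                "median_var_g": float(per_neuron["var_g"].median()),
            }
        _write_json(out / "gainfit_summary.json", fits)
        artifacts["fit_gain"] = str(out / "gainfit_summary.json")
        record("fit_gain", t0)

    if "decode" in stages:
        t0 = time.perf_counter()
        dc = cfg["decode"]
        curve = TuningCurveFit(3.0, 12.0, 2.0, 0.0)
        results = {}
        for sign in ("positive", "flat", "negative"):
            def family(n, sign=sign):
                return pdec.homogeneous_population(
                    curve, n,
                    ff_spec=pdec.FFTuningSpec(sign, dc["ff_amplitude"]),
                    corr=pdec.CorrelationKernel(dc["c_max"], dc["kappa_corr"]),
                    epsilon=dc["epsilon"])
            min_n, curve_n = pdec.neurons_to_threshold(
                family, dc["threshold_deg"], dc["n_grid"])
            results[sign] = {"min_n": min_n,
                             "bound_vs_n": curve_n.tolist()}
        _write_json(out / "decode.json", results)
        artifacts["decode"] = str(out / "decode.json")
        record("decode", t0)

    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": seed,
        "stages_run": stages,
        "runtimes_s": runtimes,
        "artifacts": artifacts,
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
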