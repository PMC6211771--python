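"""Per-direction statistics, tuning indices, and mean-matched FFTI.

Finding to reproduce: the alert-like state shows sub-Poisson, U-shaped
Fano-factor tuning (positive FFTI), the anesthetized-like state supra-
Poisson, flat tuning (FFTI near or below zero) — and the contrast
survives mean matching, so it is not a firing-rate artifact.
"""

import json
from pathlib import Path

from mtfano.core import CountMatrix
from mtfano.response_stats import indices_frame, mean_matched_ffti, stats_frame

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    stats = {}
    for state in ("alert_like", "anesthetized_like"):
        cm = CountMatrix.from_csv(ROOT.parent / "scratch" / "data" / f"{state}_counts.csv")
        sf = stats_frame(cm, pref="argmax")
        idx = indices_frame(cm, pref="argmax")
        sf.to_csv(ROOT / f"stats_{state}.csv", index=False)
        idx.to_csv(ROOT / f"indices_{state}.csv", index=False)
        stats[state] = sf
        print(f"{state}: mean FF = {sf['ff'].mean():.3f}, "
              f"mean FFTI = {idx['FFTI'].mean():+.3f}, "
              f"mean DI = {idx['DI'].mean():.3f}")

    common = [-90.0, 0.0, 90.0]
    res = mean_matched_ffti(stats["alert_like"], stats["anesthetized_like"],
                            directions=common, n_resamples=10_000, seed=2)
    summary = {**res.summary, "raw_ffti_alert": res.raw_ffti_a,
               "raw_ffti_anesthetized": res.raw_ffti_b}
    with open(ROOT / "mean_match.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(f"mean-matched FFTI: alert {summary['ffti_a_mean']:+.3f} "
          f"(sd {summary['ffti_a_sd']:.3f}), anesthetized "
          f"{summary['ffti_b_mean']:+.3f} (sd {summary['ffti_b_sd']:.3f})")
    print("rate matching preserves the FFTI contrast:",
          summary["ffti_a_mean"] > summary["ffti_b_mean"])


if __name__ == "__main__":
    main()
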