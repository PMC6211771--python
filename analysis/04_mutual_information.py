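"""Single-neuron mutual information between spike count and direction.

Finding to reproduce: alert-like neurons carry more direction information
per 250 ms count than anesthetized-like neurons (higher rates, sharper
effective tuning relative to variability), and the finite-sample bias
correction pulls the plugin estimates down.
"""

from pathlib import Path

import pandas as pd

from mtfano.core import CountMatrix
from mtfano.info_metrics import bias_corrected_mi

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for state in ("alert_like", "anesthetized_like"):
        cm = CountMatrix.from_csv(ROOT.parent / "scratch" / "data" / f"{state}_counts.csv")
        for i in range(cm.n_neurons):
            est = bias_corrected_mi(cm, i, n_boot=30, seed=100 + i)
            rows.append({"state": state, "neuron_id": i,
                         "time_ms": cm.window[1],
                         "plugin_bits": est.plugin_bits,
                         "corrected_bits": est.corrected_bits})
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "mi.csv", index=False)
    by_state = df.groupby("state")[["plugin_bits", "corrected_bits"]].mean()
    print(by_state.round(3))
    a = by_state.loc["alert_like", "corrected_bits"]
    b = by_state.loc["anesthetized_like", "corrected_bits"]
    print(f"alert-like carries more information: {a:.3f} > {b:.3f} = {a > b}")


if __name__ == "__main__":
    main()
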