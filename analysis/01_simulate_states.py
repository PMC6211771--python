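"""Generate the two synthetic behavioral states used by every later stage.

The alert-like state has low gain variance (0.0094), a 29 ms gain
correlation time and 56 ms latency; the anesthetized-like state has gain
variance 0.0732 (nearly an order of magnitude more), an 88 ms correlation
time and 94 ms latency.  Raw data tables are bulky and regenerable, so
they go under scratch/data/ (excluded from version control); the later
stages read them from there and write their small summary tables under
results/.
"""

from pathlib import Path

from mtfano.pipeline import make_fixtures

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    for preset in ("alert_like", "anesthetized_like"):
        paths = make_fixtures(preset, OUT, seed=1, temporal=True)
        print(f"{preset}:")
        for kind, p in paths.items():
            print(f"  {kind}: {p}")


if __name__ == "__main__":
    main()
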