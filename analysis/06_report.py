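"""Summarize a results directory into summary.json / summary.md."""

import argparse
from pathlib import Path

from vtcwm.pipeline import report


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    report(args.results)
    print((args.results / "summary.md").read_text())


if __name__ == "__main__":
    main()
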