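"""Regenerate the Monte-Carlo null table of the dip statistic.

Simulates the dip under the uniform null for a grid of sample sizes and
freezes the empirical quantiles into ``src/scbinsim/_dip_table.py``.
Usage:  python scripts/make_dip_table.py [--reps 10000] [--seed 20240901]
"""

from __future__ import annotations

import argparse
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))
from scbinsim._dip import dip_statistic  # noqa: E402

N_GRID = [10, 15, 20, 30, 50, 80, 120, 200, 300, 500, 800, 1200, 2000]
PROBS = np.concatenate([
    np.round(np.arange(0.01, 0.95, 0.01), 2),
    [0.95, 0.96, 0.97, 0.98, 0.985, 0.99, 0.995, 0.998, 0.999],
])


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=10000)
    ap.add_argument("--seed", type=int, default=20240901)
    ap.add_argument("--out", default=str(pathlib.Path(__file__).resolve().parents[1]
                                         / "src" / "scbinsim" / "_dip_table.py"))
    args = ap.parse_args()

    rows = []
    for n in N_GRID:
        rng = np.random.default_rng([args.seed, n])
        dips = np.array([dip_statistic(rng.random(n)) for _ in range(args.reps)])
        rows.append(np.quantile(dips, PROBS))
        print(f"n={n}: median={np.median(dips):.5f} "
              f"q95={np.quantile(dips, 0.95):.5f}", flush=True)

    with open(args.out, "w") as fh:
        fh.write('"""Monte-Carlo null quantiles of the dip statistic.\n\n')
        fh.write(f"Uniform null, {args.reps} replicates per sample size, seeded\n")
        fh.write(f"({args.seed}); regenerate with scripts/make_dip_table.py.\n")
        fh.write('"""\n\n')
        fh.write(f"N_GRID = {N_GRID}\n\n")
        fh.write("PROBS = [\n    " + ",\n    ".join(
            ", ".join(f"{p:g}" for p in PROBS[i:i + 8])
            for i in range(0, len(PROBS), 8)) + ",\n]\n\n")
        fh.write("QUANTILES = [\n")
        for row in rows:
            fh.write("    [\n        " + ",\n        ".join(
                ", ".join(f"{v:.6g}" for v in row[i:i + 8])
                for i in range(0, len(row), 8)) + ",\n    ],\n")
        fh.write("]\n")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
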