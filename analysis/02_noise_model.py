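#!/usr/bin/env python
"""Estimate the background-noise model from the eight simulated germline
controls and summarize it: rate location, per-position spread, and the
sample-level jitter component that regularizes the 5-SD rule.

Reads results/sim/control*.tsv, writes results/noise_model.tsv.
"""

from pathlib import Path

import numpy as np

import alkdeep as ad
from alkdeep import noise as N
from alkdeep import pileup as P

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    controls = [
        P.read_pileup_tsv(p) for p in sorted((ROOT / "sim").glob("control*.tsv"))
    ]
    model = ad.estimate_background(controls)
    N.write_noise_tsv(model, ROOT / "noise_model.tsv")
    means = model.table["mean"]
    print(f"{len(model.table)} (position, alt) entries from {len(controls)} controls")
    print(f"median background fraction: {np.median(means):.2e}")
    print(f"95th percentile background fraction: {np.quantile(means, 0.95):.2e}")
    print(f"sample-level jitter CV: {model.rel_jitter_sd:.3f}")
    print(f"noise floor: {model.floor:g}")
    print(f"entries with zero sample SD (floored): "
          f"{int((model.table['sd'] == 0).sum())}")


if __name__ == "__main__":
    main()
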