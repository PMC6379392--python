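#!/usr/bin/env python
"""Generate the synthetic study data: error profile, eight germline
controls, spiked tumours at the cohort's observed allele fractions, and the
three hotspot dilution series.

Writes pileup TSVs under results/sim/ for the downstream steps.  The
conditions mirror the assay design: depth 5000x (10000x for the dilution
and dual-clone experiments), per-site error rates around 0.1%, sample-level
rate jitter.
"""

import json
from pathlib import Path

import alkdeep as ad
from alkdeep import pileup as P
from alkdeep import reference as R

SEED = 20190218 % 2**31  # fixed study seed for the narrative analysis
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    reference = ad.default_reference()
    profile = ad.draw_error_profile(seed=SEED)

    controls = ad.simulate_control_cohort(
        profile, n_controls=8, depth=5000, seed=SEED + 1
    )
    for i, ctrl in enumerate(controls):
        P.write_pileup_tsv(ctrl, OUT / f"control{i + 1}.tsv")

    # one tumour per cohort case with a deep-sequencing mutation entry
    table = ad.load_cohort()
    mutated = table[table["deep_seq"].str.contains(r"\d", regex=True)]
    _, pileups = ad.simulate_cohort(mutated, profile, reference, seed=SEED + 2)
    for case_id, pu in pileups.items():
        P.write_pileup_tsv(pu, OUT / f"case{case_id}.tsv")

    # three dilution series, one per hotspot amplicon
    manifest = {"controls": 8, "cases": sorted(pileups), "dilutions": {}}
    for j, name in enumerate(["F1174L", "F1245I", "R1275Q"]):
        pos, _, alt = R.mutation_site(name, reference)
        base = ad.SimulatedSample(
            f"dil_{name}", spike_ins=(ad.SpikeIn(pos, alt, 0.5),),
            depth=10_000, seed=SEED + 10 + j,
        )
        series = ad.simulate_dilution_series(base, [0, 10, 40])
        paths = []
        for s in series:
            path = OUT / f"{s.sample_id}.tsv"
            P.write_pileup_tsv(ad.simulate_pileup(s, profile), path)
            paths.append(path.name)
        manifest["dilutions"][name] = {
            "site": [pos, alt], "steps": paths,
            "expected_vafs": [0.5, 0.5 / 11, 0.5 / 41],
        }
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"wrote {len(controls)} controls, {len(pileups)} tumour pileups and "
          f"3 dilution series to {OUT}")


if __name__ == "__main__":
    main()
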