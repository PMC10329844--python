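#!/usr/bin/env python
"""Control-vs-knockout interaction-set comparison.

Simulates the knockout of the looping factor by regenerating the same peak
landscape with the planted (factor-dependent) loops removed and a weakened
background, calls interactions in both conditions, and reports the retained /
lost / gained interaction fractions and shared-anchor statistics — the
comparison used to quantify loop loss after factor depletion. Writes the
report under results/knockout/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from roninloops import io as rio
from roninloops.caller import (CallerConfig, call_interactions,
                               compare_interaction_sets)
from roninloops.pipeline import derive_seed
from roninloops.synthetic import SyntheticConfig, simulate_pets


def main(seed=1, data="results/data", loops="results/loops",
         out="results/knockout"):
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    peaks = rio.read_peaks_bed(Path(data) / "peaks.bed")
    control_calls = rio.read_interactions(Path(loops) / "interactions.tsv")
    control_sig = control_calls[control_calls["significant"]]

    # knockout: no planted loops; a few residual factor-independent loops,
    # each within one chromosome so they survive the inter filter
    rng = np.random.default_rng(derive_seed(seed, "ko-residual"))
    residual = []
    for chrom, idx in peaks.groupby("chrom").indices.items():
        i, j = np.sort(rng.choice(np.sort(idx), 2, replace=False))
        residual.append((peaks.loc[i, "peak_id"], peaks.loc[j, "peak_id"], 12))
    residual = tuple(residual)
    cfg = SyntheticConfig(n_chromosomes=2, chrom_length=20_000_000,
                          n_background_pets=20_000, planted_loops=residual,
                          seed=derive_seed(seed, "ko-pets"))
    ko_pets, _ = simulate_pets(peaks, cfg)
    ko_calls, _ = call_interactions(ko_pets, peaks, CallerConfig(
        fdr=0.01, seed=derive_seed(seed, "ko-caller")))
    ko_sig = ko_calls[ko_calls["significant"]]

    report = compare_interaction_sets(control_sig, ko_sig)
    report["anchor_pet_deltas"].to_csv(out / "anchor_pet_deltas.tsv",
                                       sep="\t", index=False)
    scalar = {k: v for k, v in report.items() if k != "anchor_pet_deltas"}
    with open(out / "comparison.json", "w") as fh:
        json.dump(scalar, fh, indent=2, default=float)

    print(f"control: {report['n_a']} interactions; knockout: "
          f"{report['n_b']} interactions")
    print(f"retained {100 * report['frac_retained']:.1f}% of control "
          f"interactions; {report['n_lost']} lost, {report['n_gained']} "
          f"gained")
    print(f"{report['n_shared_anchors']} control anchors still engaged "
          f"({100 * (report['frac_shared_anchors_of_b'] or 0):.0f}% of "
          "knockout anchors)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--loops", default="results/loops")
    ap.add_argument("--out", default="results/knockout")
    a = ap.parse_args()
    main(a.seed, a.data, a.loops, a.out)
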