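#!/usr/bin/env python
"""Call significant promoter-promoter interactions from the PET library.

Reads the synthetic dataset from 01, runs the full caller (dedup ->
self-ligation/interchromosomal filters -> peak assignment -> hypergeometric
p -> BH q -> shuffled-null FDR cutoff -> >= 3-PET rule), annotates anchors
against the gene models, and writes the interaction table plus a WashU-style
arc export under results/loops/.
"""

import argparse
import json
from pathlib import Path

from roninloops import io as rio
from roninloops.analytics import export_arcs
from roninloops.caller import CallerConfig, call_interactions, classify_anchors
from roninloops.pipeline import derive_seed


def main(seed=1, data="results/data", out="results/loops", fdr=0.01):
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    pets = rio.read_bedpe(Path(data) / "pets.bedpe")
    peaks = rio.read_peaks_bed(Path(data) / "peaks.bed")
    genes = rio.read_genes(Path(data) / "genes.tsv")

    cfg = CallerConfig(fdr=fdr, seed=derive_seed(seed, "caller"))
    calls, log = call_interactions(pets, peaks, cfg)
    calls = classify_anchors(calls, genes, promoter_window=cfg.promoter_window)

    rio.write_interactions(calls, out / "interactions.tsv", seed=seed)
    sig = calls[calls["significant"]]
    rio.write_washu(export_arcs(sig), out / "interactions.washu.txt", seed=seed)
    with open(out / "caller_log.json", "w") as fh:
        json.dump({k: (v if v == v else None) for k, v in log.items()}, fh,
                  indent=2, default=float)

    conserved = (log["n_input"] == log["n_duplicates_removed"]
                 + log["n_self_ligation"] + log["n_inter"]
                 + log["n_unassigned"] + log["n_same_peak"]
                 + log["n_assigned"])
    cats = sig["category"].value_counts(normalize=True)
    print(f"input {log['n_input']} PETs -> {log['n_assigned']} assigned "
          f"(dedup removed {log['n_duplicates_removed']}, self-ligation "
          f"{log['n_self_ligation']}, inter {log['n_inter']}); "
          f"conservation identity holds: {conserved}")
    print(f"{len(calls)} candidate pairs, {len(sig)} significant at "
          f"FDR {fdr} (cutoff p <= {log['cutoff']:.3g})")
    if len(sig):
        print("significant-call categories: "
              + ", ".join(f"{k}: {100 * v:.0f}%" for k, v in cats.items()))


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/loops")
    ap.add_argument("--fdr", type=float, default=0.01)
    a = ap.parse_args()
    main(a.seed, a.data, a.out, a.fdr)
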