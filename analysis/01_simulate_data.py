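#!/usr/bin/env python
"""Generate the synthetic study dataset.

Builds a two-chromosome toy genome with clustered housekeeping genes, places
RBMs upstream of their TSSs (-81 bp on average), derives binding peaks whose
intensity tracks RBM count, plants loops between promoter peaks, and
simulates a PET library (background + planted loops + self-ligation +
interchromosomal noise + PCR duplicates). Writes everything under
results/data/ in plain-text genomics formats.
"""

import argparse
from pathlib import Path

import numpy as np

from roninloops import io as rio
from roninloops.pipeline import derive_seed
from roninloops.synthetic import (SyntheticConfig, generate_genome,
                                  generate_peaks, generate_signal_track,
                                  place_rbms, simulate_pets)


def main(seed=1, out="results/data"):
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(n_chromosomes=2, chrom_length=20_000_000,
                          n_genes=300, cluster_count=6, cluster_span=400_000,
                          n_background_pets=20_000,
                          seed=derive_seed(seed, "synthetic"))
    genome = generate_genome(cfg)
    motifs = place_rbms(genome, cfg)
    peaks = generate_peaks(genome, motifs, cfg)

    # plant 10 loops per chromosome between well-separated promoter peaks
    rng = np.random.default_rng(derive_seed(seed, "planted"))
    planted = []
    for chrom, idx in peaks.groupby("chrom").indices.items():
        for _ in range(10):
            i, j = np.sort(rng.choice(np.sort(idx), 2, replace=False))
            if peaks.loc[j, "start"] - peaks.loc[i, "end"] > 10_000:
                planted.append((peaks.loc[i, "peak_id"],
                                peaks.loc[j, "peak_id"], 15))
    cfg = cfg.with_(planted_loops=tuple(planted))
    pets, log = simulate_pets(peaks, cfg)
    signal = generate_signal_track(genome, peaks, cfg)

    rio.write_genes(genome.genes, out / "genes.tsv", seed=cfg.seed)
    rio.write_chrom_sizes(genome.chrom_sizes, out / "chrom.sizes")
    rio.write_peaks_bed(peaks, out / "peaks.bed", seed=cfg.seed)
    motif_bed = motifs.rename(columns={"sequence": "name"}).assign(score=0)
    rio.write_bed(motif_bed[["chrom", "start", "end", "name", "score",
                             "strand"]], out / "motifs.bed", seed=cfg.seed)
    rio.write_bedpe(pets, out / "pets.bedpe", seed=cfg.seed)
    rio.write_bedgraph(signal, out / "signal.bedgraph", seed=cfg.seed)

    print(f"genome: {len(genome.genes)} genes on {len(genome.chromosomes)} "
          f"chromosomes; {len(motifs)} RBM instances; {len(peaks)} peaks")
    print(f"PET library: {log['n_emitted']} PETs "
          f"({log['n_duplicates']} duplicates, {log['n_self_ligation']} "
          f"self-ligation, {log['n_inter']} interchromosomal, "
          f"{log['n_planted']} planted); {len(planted)} planted loops")
    print(f"written to {out}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/data")
    a = ap.parse_args()
    main(a.seed, a.out)
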