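#!/usr/bin/env python
"""Annotation and descriptive analytics over the called interactions.

Computes: bound genes (peak within TSS +/- 1 kb), set enrichment of bound
genes in housekeeping/metabolic annotations, binned density correlations
(RBMs vs peak vs loop intensity), the promoter RBM-count vs loop-degree
relation, the housekeeping-gene metagene signal profile (100/300/100 bins),
and the interaction network with its incidence matrix and hub ranking.
Writes tables under results/analytics/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from roninloops import io as rio
from roninloops.analytics import (binned_density, build_network,
                                  density_correlation, gene_metaplot,
                                  loop_density_track, overlap_enrichment)
from roninloops.caller import bound_genes, loops_vs_rbm


def main(data="results/data", loops="results/loops", out="results/analytics"):
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    genes = rio.read_genes(Path(data) / "genes.tsv")
    peaks = rio.read_peaks_bed(Path(data) / "peaks.bed")
    motifs = rio.read_bed(Path(data) / "motifs.bed").rename(
        columns={"name": "sequence"})
    sizes = rio.read_chrom_sizes(Path(data) / "chrom.sizes")
    signal = rio.read_bedgraph(Path(data) / "signal.bedgraph")
    calls = rio.read_interactions(Path(loops) / "interactions.tsv")
    sig = calls[calls["significant"]]

    bound = bound_genes(peaks, genes)
    universe = set(genes["gene_id"])
    hk = set(genes.loc[genes["housekeeping"], "gene_id"])
    met = set(genes.loc[genes["metabolic"], "gene_id"])
    k_hk, p_hk = overlap_enrichment(bound, hk, universe)
    k_met, p_met = overlap_enrichment(bound, met, universe)

    bin_bp = 2e6
    tracks = {"rbm": binned_density(motifs, sizes, bin_bp),
              "peak": binned_density(peaks, sizes, bin_bp,
                                     weight_col="intensity"),
              "loop": loop_density_track(sig, sizes, bin_bp)}
    corr = density_correlation(tracks)
    corr.to_csv(out / "density_correlation.tsv", sep="\t")

    rbm_rel = loops_vs_rbm(calls, motifs, genes)
    rbm_rel["table"].to_csv(out / "rbm_vs_loop_degree.tsv", sep="\t",
                            index=False)

    profile = gene_metaplot(signal, genes[genes["housekeeping"]])
    pd.DataFrame({"bin": np.arange(500), "mean_signal": profile.values}
                 ).to_csv(out / "metagene_profile.tsv", sep="\t", index=False)

    net = build_network(sig)
    net.vertices.to_csv(out / "network_vertices.tsv", sep="\t", index=False)
    net.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    iu, ju = np.nonzero(net.incidence)
    pd.DataFrame({"vertex": iu, "edge": ju, "value": 1}
                 ).to_csv(out / "incidence_triplets.tsv", sep="\t", index=False)

    summary = {
        "n_bound_genes": len(bound),
        "bound_vs_housekeeping": {"overlap": k_hk, "p": p_hk},
        "bound_vs_metabolic": {"overlap": k_met, "p": p_met},
        "rbm_peak_corr": float(corr.loc["rbm", "peak"]),
        "rbm_loop_corr": float(corr.loc["rbm", "loop"]),
        "rbm_loop_degree_spearman": rbm_rel["spearman_rho"],
        "n_network_vertices": len(net.vertices),
        "n_network_edges": len(net.edges),
        "top_hub_degree": int(net.hubs["degree"].iloc[0]) if len(net.vertices) else 0,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)

    print(f"{len(bound)} bound genes; housekeeping enrichment p = {p_hk:.3g}, "
          f"metabolic p = {p_met:.3g}")
    print(f"density correlations: RBM-peak r = {summary['rbm_peak_corr']:.3f}, "
          f"RBM-loop r = {summary['rbm_loop_corr']:.3f}")
    print(f"promoter RBM count vs loop degree: Spearman rho = "
          f"{summary['rbm_loop_degree_spearman']}")
    print(f"network: {summary['n_network_vertices']} anchors, "
          f"{summary['n_network_edges']} loops, top hub degree "
          f"{summary['top_hub_degree']}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--loops", default="results/loops")
    ap.add_argument("--out", default="results/analytics")
    a = ap.parse_args()
    main(a.data, a.loops, a.out)
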