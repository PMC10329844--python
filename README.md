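# roninloops

Housekeeping genes mostly lack distal enhancers, yet their transcription is
finely tuned. One proposed mechanism is that the transcription factor Ronin
(Thap11), which binds an ultra-conserved promoter-proximal motif
(RBM, `CTGGGARWTGTAGTY`, centred on average 81 bp upstream of the TSS),
physically assembles multiple housekeeping-gene promoters into clusters —
promoter-promoter loops playing the role that enhancer-promoter loops play at
cell-identity genes. `roninloops` is a tested re-implementation of the
computational core of that analysis, for people who want to run, probe or
extend the statistics on their own ChIA-PET-style data or on fully synthetic
data the package generates itself:

* **`roninloops.synthetic`** — toy genomes with clustered housekeeping genes,
  RBM placements (offset ~ N(−81, σ) from the TSS), intensity-graded binding
  peaks, and PET libraries with an exactly-known null (two ends drawn
  independently ∝ peak intensity) plus planted loops, self-ligation PETs,
  interchromosomal noise and PCR duplicates.
* **`roninloops.caller`** — the ChIA-PET interaction caller: duplicate
  collapse, removal of intrachromosomal PETs < 4 kb (self-ligation) and of
  interchromosomal PETs, ≥ 1 bp end/peak assignment, and per anchor pair the
  hypergeometric upper tail

  p(A,B) = P(X ≥ k),  X ~ Hypergeom(N, n_A, n_B),

  where N counts qualifying PETs, n_A and n_B the PETs touching each anchor,
  and k the PETs linking the pair; Benjamini-Hochberg q-values; an empirical
  FDR cutoff from shuffling the PET end linkage; and the ≥ 3-PET
  high-confidence rule. Anchors are annotated promoter (TSS ± 2,500 bp,
  promoter wins ties) / enhancer / other, and call sets from two conditions
  (e.g. control vs knockout) can be compared by reciprocal anchor overlap.
* **`roninloops.polymer`** — a coarse-grained chromosome model that predicts
  looping from RBM positions alone: nodes interact through
  V(r) = ε[(r_m/r)¹² − 2(r_m/r)⁶] with well depth ε ∝ (RBM_i + RBM_j) and
  equilibrium distance r_m = c·(r_chr·e^(−r_chr/r_D) + 1) controlled by the
  dephasing distance r_D; velocity-Verlet integration in the NVT ensemble
  (Anderson thermostat), a 1/r repulsive wall on a cubic box of edge 5× the
  polymer contour length, time-averaged contact maps and PET-pair-length
  histograms, and an MSE-based parameter scan.
* **`roninloops.analytics`** — IUPAC consensus scanning on both strands,
  order-invariant binned density correlations (18.5 Mb bins by default),
  100/300/100-bin metagene profiles (500 bins per gene), hypergeometric
  set enrichment, interaction networks with incidence matrices, and
  WashU-style arc exports.

## Worked example

The `analysis/` scripts run the whole study on synthetic data:

```bash
python analysis/01_simulate_data.py --seed 1     # genome, motifs, peaks, PETs
python analysis/02_call_loops.py    --seed 1     # interaction calling
python analysis/03_annotate_and_profile.py       # annotation & correlations
python analysis/04_polymer_simulation.py --seed 1
python analysis/05_parameter_scan.py     --seed 1
python analysis/06_knockout_comparison.py --seed 1
```

With seed 1 the first two stages print:

```
genome: 300 genes on 2 chromosomes; 369 RBM instances; 134 peaks
PET library: 21306 PETs (1006 duplicates, 2000 self-ligation, 1000 interchromosomal, 300 planted); 20 planted loops
input 21306 PETs -> 8552 assigned (dedup removed 1006, self-ligation 2216, inter 9532); conservation identity holds: True
3027 candidate pairs, 20 significant at FDR 0.01 (cutoff p <= 0.000284)
significant-call categories: P-P: 100%
```

Reading: of 21,306 simulated PETs, the caller removes duplicates,
self-ligation (< 4 kb) and interchromosomal PETs, assigns 8,552 to peak
pairs, and — among 3,027 candidate pairs — recovers exactly the 20 planted
loops at FDR 0.01, every one of them promoter-promoter (all peaks sit at
promoters, so this mirrors the ~95% promoter-promoter fraction seen for a
promoter-binding factor). The record counts always satisfy the conservation
identity `input = duplicates + self + inter + unassigned + same-peak +
assigned`. Stage 03 then reports, for this run, a binned RBM-vs-peak density
correlation of 1.000 and RBM-vs-loop of 0.993, and strong enrichment of
bound genes in housekeeping (p ≈ 2e−87) and metabolic (p ≈ 1e−12)
annotations.

A single CLI wraps the same stages (`ronin-loops simulate-data | call-loops |
simulate-polymer | run-all`, each with `--seed/--out/--config`).

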