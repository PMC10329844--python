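# Methods

This note documents the models, statistics and numerical choices behind
`roninloops`, in the order the pipeline runs them.

## Synthetic study conditions

The generator (`roninloops.synthetic`) emulates the statistical structure a
ChIA-PET experiment for a promoter-binding looping factor is assumed to have;
it deliberately does *not* simulate reads, linkers or alignment (those stages
are out of scope — peaks and aligned PETs are the pipeline's inputs).

* **Genome.** `n_chromosomes` × `chrom_length` (default 2 × 10 Mb) with
  `n_genes` gene models. Housekeeping genes (default half) are dealt
  round-robin into `cluster_count` non-overlapping windows of `cluster_span`,
  reproducing the local clustering of housekeeping genes; the rest are placed
  uniformly. Gene lengths are log-uniform on 2–60 kb. A metabolic flag is
  drawn with higher probability for housekeeping genes (0.6 vs 0.2) so that
  set-enrichment analyses have structure to find.
* **RBMs.** Each housekeeping promoter draws a motif count from
  `rbm_per_promoter_dist` — default a zero-truncated Poisson(λ=2), chosen to
  produce mostly low-count promoters with occasional multi-RBM hubs; the
  source material states no distribution. Offsets from the TSS are
  N(−81, 25) bp, applied along the gene's strand (upstream = 5′ of the TSS),
  matching the motif's documented promoter-proximal preference.
* **Peaks.** One peak per RBM-bearing promoter, 2,000 bp wide (the reported
  average peak width for this factor), centred on the TSS; intensity =
  a·(RBM count) + N(0, σ) truncated at 0. Overlapping peaks merge with
  summed intensity, so peak sets are always non-overlapping.
* **PETs.** Background PETs draw both end peaks independently with
  probability ∝ intensity — exactly the product-of-marginals null the caller
  tests against — then place each end uniformly inside its peak (end width
  50 bp, a typical tag footprint). Planted loops add `extra_pet_count` PETs
  to chosen pairs. Self-ligation PETs take spans uniform on [100, 3,999] bp
  so the < 4 kb filter removes exactly this class; a span of exactly 4,000
  is retained. Interchromosomal PETs pair peaks on different chromosomes.
  Each PET is duplicated with probability `duplicate_rate`; the binomial
  draw is recorded in the generator log so duplicate accounting is testable.
  Strands are independent uniform (deduplication uses strand but no strand
  model is stated).
* **Determinism.** Every generator derives its stream from
  (`seed`, stage label) through a SHA-256 digest; identical configs produce
  byte-identical files. (Python's salted built-in `hash` must not be used
  here — it changes across processes.)

What the generator does *not* emulate: mappability and GC biases, peak-width
heterogeneity, distance-dependent background (background link probability is
independent of genomic distance), chromatin-state covariates, and replicate
structure. Passing tests therefore demonstrate correctness of the statistics
under the stated null and planted-signal conditions, not robustness to every
bias of real libraries — in particular the hypergeometric null is exactly
true here, which is the point of the design.

## Interaction caller

Pipeline: normalize end order → collapse PETs identical in coordinates and
strands at both ends → classify (interchromosomal out; intrachromosomal with
midpoint span < 4,000 bp out as self-ligation) → assign ends to peaks with
≥ 1 bp overlap → pair statistics → significance. Interchromosomal PETs are
classified and exportable but never tested.

* **Span** is the distance between end midpoints (`span_mode="inner"` gives
  the inner distance instead). The removal threshold is strict (`< 4 kb`).
* **Assignment.** An end overlapping several peaks goes to the peak with
  maximal overlap, ties to the leftmost. PETs with both ends in one peak are
  excluded from pair statistics and from the population N (a pair requires
  two distinct anchors, and the shuffle permutes exactly the assigned,
  distinct-anchor PETs).
* **Hypergeometric test.** For each pair, p = P(X ≥ k) with
  X ~ Hypergeom(N, n_A, n_B); N is genome-wide by default
  (`population="per_chromosome"` switches scope). The tail is computed in
  log space from the pmf at k with a term-ratio recursion, ascending when k
  is above the mean (the tail decays) and as 1 − lower tail otherwise;
  agreement with exact rational enumeration is 1e−12 relative for all
  N ≤ 12 and with `scipy.stats.hypergeom.sf` to 1e−9 at N up to 5·10⁴.
* **Null and cutoff.** Each of `n_shuffles` (default 100) shuffles permutes
  the end-2 anchor labels across assigned PETs, preserving N exactly and the
  marginals in expectation, and recomputes all pair p-values. The cutoff at
  target FDR f is the largest observed p-value c with
  (mean null count ≤ c) / (observed count ≤ c) ≤ f; a pooled-null quantile
  reading is available as `cutoff_mode="null_quantile"`.
* **Significance** requires all three: p ≤ cutoff, BH q ≤ f, and
  pet count ≥ 3 (high-confidence rule). The conjunction is the conservative
  reading of a procedure described as using all three devices. Defaults:
  f = 0.01 for Ronin-type runs, 0.05 for Pol II-type runs.
* **Annotation.** Promoter = [TSS − 2,500, TSS + 2,500) half-open (so a
  coordinate exactly at TSS + 2,500 is outside); enhancers are intervals
  that lose ties to promoters; bound genes = peak overlapping
  [TSS − 1,000, TSS + 1,000).
* **Audit.** Every run logs the conservation identity
  input = duplicates + self + inter + unassigned + same-peak + assigned.

Calibration behaviour worth knowing: because the shuffled null conditions on
the anchor marginals, promoters that accumulate many loops develop heavy
marginals and their individual pairs are judged *against* that — hub-driven
marginal inflation does not create significance. This is why calibration on
pure-null libraries is, in practice, conservative (the measured false-call
fraction at f = 0.05 is ~0).

## Polymer model

Nodes of `node_size_bp` (a motif at a bin boundary belongs to the right-hand
node) interact through V(r) = ε[(r_m/r)¹² − 2(r_m/r)⁶].

* **Well depth** ε = `epsilon_scale` · (rbm_i + rbm_j); adjacent nodes add a
  backbone term of 10 × `epsilon_scale` to keep the chain connected (chain
  integrity is otherwise unspecified). Zero-ε pairs keep only the repulsive
  branch (r < r_m, shifted to 0 at r_m) as excluded volume. Attractive pairs
  are cut off at 3 r_m with an energy shift to zero.
* **Equilibrium distance.** The printed formula for r_m is typographically
  garbled; the adopted reading is r_m = c·(r_chr·e^(−r_chr/r_D) + 1) with
  r_chr = |i−j| in node units, which encodes the dephasing semantics
  (correlation lost beyond r_D, maximum of r_m exactly at r_chr = r_D,
  finite large-separation limit c). It is isolated in
  `equilibrium_distance` so alternative readings can be swapped. r_chr is
  measured in nodes because the dephasing distance itself is quoted in
  nodes.
* **Units and defaults.** Reduced units (mass = k_B = 1); T = 4,000,
  dt = 0.15625 and r_D = 10 are taken verbatim as reduced-quantity labels
  (they have no physical-unit meaning). `epsilon_scale` = 4,000 and
  `r_m_scale` = 300 were chosen once so that (i) the backbone well is
  ~10 k_BT at the default T — bonds essentially never escape past the
  cutoff, keeping the chain intact — and (ii) the harmonic frequency at the
  bond minimum satisfies ω·dt ≈ 0.5, stable for velocity Verlet at the
  printed dt. One RBM in a pair then contributes ~1 k_BT of well depth, so
  contact enrichment grows smoothly with RBM sum.
* **Ensemble.** Velocity Verlet (half-kick/drift/half-kick) with an Anderson
  thermostat: each node's velocity is resampled from Maxwell-Boltzmann(T)
  with per-step probability ν (default 0.05). Without the thermostat the
  integrator conserves energy to < 1e−3 relative over 1,000 steps at small
  dt and is time-reversible to roundoff.
* **Box.** Cubic, edge = 5 × contour length (contour length = n · c),
  with wall potential ε_B·r_m,B/r_B per face (ε_B = `epsilon_scale`,
  r_m,B = `r_m_scale`); a node that drifts out is reflected back and
  counted.
* **Initialization.** Seeded self-avoiding walk with bond length equal to
  the adjacent-pair r_m, followed by capped steepest descent: a fresh walk
  inevitably leaves some non-adjacent pairs inside their repulsive range
  (r_m grows with backbone separation up to r_D), and integrating from
  there is unstable at any sensible dt. Velocities start
  Maxwell-Boltzmann(T).
* **Equilibration.** The instantaneous total energy of a thermostatted
  system fluctuates by ~√(2/(3N)) relative even at equilibrium, so a plain
  fluctuation threshold can never be met. The monitor instead splits the
  trailing `equil_window` (500) into 10 block means and declares equilibrium
  when the first-half/second-half mean difference is below
  `equil_tol`(0.02) × the energy scale *plus three standard errors* of that
  difference — i.e. when no drift is detectable beyond canonical noise.
  Hard cap 200,000 steps, then an error with diagnostics.
* **Contacts.** Contact map entry (i,j) = fraction of production frames with
  |x_i − x_j| < capture radius. The default capture radius is 5 × c: under
  the dephasing rule bonded neighbours sit at ~1.9 c and mid-range bound
  pairs at ~4–5 c, so smaller radii (including 1.5 c) register no contacts
  at all. The PET-pair-length histogram weights each (frame, pair) contact
  at span |i−j| × node_size and normalizes to 1.
* **Parameter scan.** One seeded simulation per grid point; MSE between
  normalized histograms; best = argmin, ties to the first grid point.

Problem sizes used by the test suite and acceptance script — chains of 20–24
nodes, 1,500–3,000 production steps, 3×3 grids, 10 replicates — are the
package's chosen desk-scale study conditions; the defaults
(`n_production_steps` = 10,000) match the published production length and
run comfortably for a few hundred nodes.

## Analytics

* **Motif scan.** Exact IUPAC matching (R={A,G}, W={A,T}, Y={C,T}) of
  `CTGGGARWTGTAGTY` on both strands; minus-strand hits are reported in
  plus-strand coordinates; overlapping hits all reported; N never matches.
  Position-weight-matrix scoring and de-novo discovery are out of scope.
* **Density correlations.** Features are counted (or intensity/PET-weighted)
  in fixed bins (default 18.5 Mb; the final partial bin is kept, raw
  counts); loop intensity contributes at both anchors of each interaction
  (the arc-plot vertex convention; single-anchor counting is a flag).
  Pearson r uses exactly-rounded `fsum` reductions, so the result is
  bit-identical under any permutation of the concatenated bins — the
  order-invariance the analysis asserts.
* **Metagene profile.** 2,000 bp flanks in 100 bins of 20 bp; the gene body
  in 300 equal fractional bins regardless of length, by length-weighted
  (exact integral) averaging — bodies shorter than 300 bp work and no
  length-dependent bias is introduced; minus-strand genes are flipped so
  profiles read 5′→3′; group profile = unweighted mean of per-gene profiles
  (500 bins).
* **Enrichment** shares the caller's hypergeometric tail routine, so the two
  modules cannot disagree.
* **Networks.** Vertices = deduplicated anchors carrying their summed PET
  counts; edges = significant interactions; the incidence matrix has column
  sums identically 2; hubs are vertices ranked by degree. Arc export keeps
  only interactions with both anchors fully inside the requested region.

## Known limitations

* The caller's p-values assume the genome-wide product-of-marginals null;
  distance-dependent background (real ChIA-PET has one) is neither simulated
  nor modelled, so absolute p-values on real data are optimistic even though
  the shuffle cutoff partially compensates.
* The polymer model is qualitative by construction: reduced units, no
  bending rigidity, no hydrodynamics, and an r_m rule adopted from a garbled
  printed formula. Contact maps are meant to be compared by pattern and by
  pair-length distribution, not absolute frequency.
* Replicate merging is merge-then-dedup; the alternative order is not
  implemented.
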