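"""Synthetic genomes, RBM placements, peaks, signal tracks and PET collections.

The generator emulates the statistical structure the interaction caller and the
polymer simulator assume about real ChIA-PET data for a promoter-binding factor:

* housekeeping genes grouped into local clusters along the genome;
* RBM (Ronin-binding motif) instances with a strong promoter-proximal
  positional preference, -81 bp upstream of the TSS on average;
* one binding peak per RBM-bearing promoter (~2 kb wide), intensity
  increasing with the promoter's RBM count;
* PET collections whose background links two ends independently in
  proportion to peak intensities (the hypergeometric null), plus planted
  enriched loops, self-ligation PETs (< 4 kb), interchromosomal noise and
  PCR duplicates.

All coordinates are 0-based half-open (BED convention). Every generator is a
pure function of (inputs, config.seed).
"""

from __future__ import annotations

import hashlib

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "GenomeModel",
    "ConfigError",
    "zero_truncated_poisson_pmf",
    "generate_genome",
    "place_rbms",
    "generate_peaks",
    "simulate_pets",
    "generate_signal_track",
    "realize_consensus",
]

RBM_CONSENSUS = "CTGGGARWTGTAGTY"
MOTIF_LENGTH = len(RBM_CONSENSUS)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ConfigError(ValueError):
    """Raised when a synthetic-data configuration is inconsistent."""


def zero_truncated_poisson_pmf(lam: float, max_count: int = 10) -> np.ndarray:
    """pmf over 0..max_count of a zero-truncated Poisson(lam), renormalized.

    Index 0 carries probability 0: every promoter that carries the motif at
    all carries at least one copy.
    """
    k = np.arange(max_count + 1)
    fact = np.cumprod(np.concatenate([[1.0], np.arange(1.0, max_count + 1)]))
    pmf = lam ** k * np.exp(-lam) / fact
    pmf[0] = 0.0
    return pmf / pmf.sum()


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    Defaults mirror the regime the caller is meant for: a small multi-megabase
    genome, housekeeping genes concentrated in clusters, 1-5 RBMs per bound
    promoter peaking at -81 bp from the TSS, ~2 kb peaks, and a PET library
    dominated by intensity-proportional background.
    """

    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 300
    cluster_count: int = 6
    cluster_span: int = 200_000
    housekeeping_fraction: float = 0.5
    metabolic_prob_hk: float = 0.6
    metabolic_prob_other: float = 0.2
    rbm_per_promoter_dist: tuple = tuple(zero_truncated_poisson_pmf(2.0))
    rbm_offset_mean: float = -81.0
    rbm_offset_sd: float = 25.0
    peak_width: int = 2_000
    peak_intensity_per_rbm: float = 1.0
    peak_noise_sd: float = 0.1
    pet_end_length: int = 50
    n_background_pets: int = 50_000
    planted_loops: tuple = ()        # (peak_id_a, peak_id_b, extra_pet_count)
    self_ligation_fraction: float = 0.10
    self_ligation_span: tuple = (100, 3_999)
    inter_fraction: float = 0.05
    duplicate_rate: float = 0.05
    signal_baseline: float = 1.0
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        for name in ("self_ligation_fraction", "inter_fraction", "duplicate_rate",
                     "housekeeping_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if self.self_ligation_fraction + self.inter_fraction > 1.0:
            raise ConfigError("self_ligation_fraction + inter_fraction must be <= 1")
        if self.chrom_length <= self.cluster_span:
            raise ConfigError("chrom_length must exceed cluster_span")
        if self.cluster_count * self.cluster_span > self.n_chromosomes * self.chrom_length:
            raise ConfigError("clusters do not fit in the genome")
        pmf = np.asarray(self.rbm_per_promoter_dist, dtype=float)
        if pmf.ndim != 1 or np.any(pmf < 0) or not np.isclose(pmf.sum(), 1.0):
            raise ConfigError("rbm_per_promoter_dist must be a pmf over 0..max")
        return self

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass
class GenomeModel:
    """Chromosome sizes plus gene models; the coordinate frame for all stages."""

    chromosomes: list          # [(name, length)]
    genes: pd.DataFrame        # gene_id, chrom, strand, tss, tes, housekeeping, metabolic, cluster_id

    @property
    def chrom_sizes(self) -> dict:
        return dict(self.chromosomes)


GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes",
                "housekeeping", "metabolic", "cluster_id"]


def _rng(config: SyntheticConfig, label: str) -> np.random.Generator:
    # a stable digest keys each stage's stream off (seed, label); Python's
    # built-in hash is salted per process and would break reproducibility
    key = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(config.seed), spawn_key=(key,)))


def generate_genome(config: SyntheticConfig) -> GenomeModel:
    """Place genes so each housekeeping cluster fits one cluster_span window.

    Housekeeping genes are dealt round-robin into ``cluster_count`` clusters
    whose windows are drawn without overlap; remaining genes land uniformly
    outside no particular structure. Gene lengths are log-uniform 2-60 kb.
    """
    config.validate()
    rng = _rng(config, "genome")
    chroms = [(f"chr{i + 1}", int(config.chrom_length))
              for i in range(config.n_chromosomes)]
    if config.n_genes == 0:
        return GenomeModel(chroms, pd.DataFrame(columns=GENE_COLUMNS))

    n_hk = int(round(config.n_genes * config.housekeeping_fraction))
    n_clusters = min(config.cluster_count, max(n_hk, 1))

    # non-overlapping cluster windows, spread over chromosomes round-robin
    windows = []
    per_chrom = {name: [] for name, _ in chroms}
    for ci in range(n_clusters):
        chrom = chroms[ci % len(chroms)][0]
        for _ in range(1000):
            start = int(rng.integers(0, config.chrom_length - config.cluster_span))
            if all(start + config.cluster_span <= s or start >= e
                   for s, e in per_chrom[chrom]):
                per_chrom[chrom].append((start, start + config.cluster_span))
                windows.append((chrom, start))
                break
        else:  # pragma: no cover - only reachable with pathological configs
            raise ConfigError("could not place non-overlapping cluster windows")

    rows = []
    for gi in range(config.n_genes):
        hk = gi < n_hk
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(np.exp(rng.uniform(np.log(2_000), np.log(60_000))))
        if hk:
            cluster = gi % n_clusters
            chrom, wstart = windows[cluster]
            tss = int(rng.integers(wstart, wstart + config.cluster_span - length))
            # keep the full gene body inside the window so the whole cluster
            # falls within one span, the property the caller's tests assume
            if strand == "-":
                tss = tss + length
        else:
            cluster = -1
            chrom = chroms[int(rng.integers(len(chroms)))][0]
            tss = int(rng.integers(length, config.chrom_length - length))
        tes = tss + length if strand == "+" else tss - length
        metabolic = rng.random() < (config.metabolic_prob_hk if hk
                                    else config.metabolic_prob_other)
        rows.append((f"G{gi:05d}", chrom, strand, tss, tes, hk, bool(metabolic), cluster))

    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return GenomeModel(chroms, genes)


def realize_consensus(rng: np.random.Generator, consensus: str = RBM_CONSENSUS) -> str:
    """One concrete sequence matching the IUPAC consensus."""
    return "".join(c if c in "ACGT" else _IUPAC[c][int(rng.integers(len(_IUPAC[c])))]
                   for c in consensus)


def place_rbms(genome: GenomeModel, config: SyntheticConfig) -> pd.DataFrame:
    """RBM instances per housekeeping promoter, offset ~ N(mean, sd) from TSS.

    The signed offset is measured along the gene's strand (negative =
    upstream) and locates the motif's 5'-most base relative to the TSS:
    for a + strand gene at TSS t the hit starts at t + offset; for a -
    strand gene it ends at t - offset. Hits are clipped to the chromosome.
    """
    config.validate()
    rng = _rng(config, "rbm")
    pmf = np.asarray(config.rbm_per_promoter_dist, dtype=float)
    sizes = genome.chrom_sizes
    rows = []
    hk = genome.genes[genome.genes["housekeeping"]]
    for g in hk.itertuples(index=False):
        count = int(rng.choice(len(pmf), p=pmf))
        for _ in range(count):
            offset = rng.normal(config.rbm_offset_mean, config.rbm_offset_sd)
            if g.strand == "+":
                start = int(round(g.tss + offset))
            else:
                start = int(round(g.tss - offset)) - MOTIF_LENGTH
            start = int(np.clip(start, 0, sizes[g.chrom] - MOTIF_LENGTH))
            rows.append((g.chrom, start, start + MOTIF_LENGTH, g.strand,
                         realize_consensus(rng), g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "sequence", "gene_id"])


def generate_peaks(genome: GenomeModel, motifs: pd.DataFrame,
                   config: SyntheticConfig) -> pd.DataFrame:
    """One peak per RBM-bearing promoter; intensity = a * RBM count + noise.

    Peaks are ``peak_width`` wide, centred on the TSS. Overlapping peaks are
    merged with summed intensity, so the returned set is non-overlapping.
    """
    config.validate()
    rng = _rng(config, "peaks")
    cols = ["chrom", "start", "end", "intensity", "peak_id"]
    if motifs.empty:
        return pd.DataFrame(columns=cols)
    counts = motifs.groupby("gene_id").size()
    genes = genome.genes.set_index("gene_id")
    sizes = genome.chrom_sizes
    half = config.peak_width // 2
    raw = []
    for gene_id, n_rbm in counts.items():
        g = genes.loc[gene_id]
        start = max(0, int(g.tss) - half)
        end = min(sizes[g.chrom], int(g.tss) + half)
        intensity = config.peak_intensity_per_rbm * n_rbm
        if config.peak_noise_sd > 0:
            intensity += rng.normal(0.0, config.peak_noise_sd)
        raw.append((g.chrom, start, end, max(0.0, intensity)))
    raw.sort()
    merged = []
    for chrom, start, end, inten in raw:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = [chrom, prev[1], max(prev[2], end), prev[3] + inten]
        else:
            merged.append([chrom, start, end, inten])
    df = pd.DataFrame(merged, columns=cols[:4])
    df["peak_id"] = [f"P{i:05d}" for i in range(len(df))]
    return df


PET_COLUMNS = ["chrom1", "start1", "end1", "strand1",
               "chrom2", "start2", "end2", "strand2", "name"]


def _uniform_end_in_peak(rng, peaks, idx, end_length):
    start = peaks["start"].to_numpy()[idx]
    end = peaks["end"].to_numpy()[idx]
    width = np.maximum(end - start - end_length, 1)
    s = start + (rng.random(idx.size) * width).astype(np.int64)
    return s, s + end_length


def normalize_pet_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Order each PET's ends so (chrom1, start1) <= (chrom2, start2)."""
    swap = (df["chrom1"] > df["chrom2"]) | (
        (df["chrom1"] == df["chrom2"]) & (df["start1"] > df["start2"]))
    out = df.copy()
    for a, b in (("chrom1", "chrom2"), ("start1", "start2"),
                 ("end1", "end2"), ("strand1", "strand2")):
        out.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    return out


def simulate_pets(peaks: pd.DataFrame, config: SyntheticConfig,
                  chrom_sizes: dict | None = None):
    """A PET library over the peak set; returns (pets, log).

    Background PETs pick their two end peaks independently with probability
    proportional to intensity (the hypergeometric null of the caller), then
    place each end uniformly inside its peak. Planted loops add extra PETs
    for the stated peak pairs. A ``self_ligation_fraction`` of the library
    has both ends on one chromosome closer than 4 kb; ``inter_fraction``
    spans chromosomes; ``duplicate_rate`` of PETs are emitted twice
    verbatim. Strands are independent uniform.
    """
    config.validate()
    rng = _rng(config, "pets")
    if len(peaks) < 2 and config.n_background_pets > 0:
        raise ConfigError("background generation needs at least two peaks")
    known = set(peaks["peak_id"]) if len(peaks) else set()
    for a, b, _ in config.planted_loops:
        if a not in known or b not in known:
            raise ConfigError(f"planted loop references unknown peak id ({a}, {b})")

    n_bg = config.n_background_pets
    n_self = int(round(n_bg * config.self_ligation_fraction))
    n_inter = int(round(n_bg * config.inter_fraction))
    n_loopable = n_bg - n_self - n_inter

    frames = []
    probs = None
    if len(peaks):
        inten = peaks["intensity"].to_numpy(dtype=float)
        probs = inten / inten.sum() if inten.sum() > 0 else np.full(len(peaks), 1 / len(peaks))

    if n_loopable > 0:
        i1 = rng.choice(len(peaks), size=n_loopable, p=probs)
        i2 = rng.choice(len(peaks), size=n_loopable, p=probs)
        s1, e1 = _uniform_end_in_peak(rng, peaks, i1, config.pet_end_length)
        s2, e2 = _uniform_end_in_peak(rng, peaks, i2, config.pet_end_length)
        frames.append(pd.DataFrame({
            "chrom1": peaks["chrom"].to_numpy()[i1], "start1": s1, "end1": e1,
            "strand1": np.where(rng.random(n_loopable) < 0.5, "+", "-"),
            "chrom2": peaks["chrom"].to_numpy()[i2], "start2": s2, "end2": e2,
            "strand2": np.where(rng.random(n_loopable) < 0.5, "+", "-"),
        }))

    for a, b, extra in config.planted_loops:
        ia = np.full(extra, peaks.index[peaks["peak_id"] == a][0])
        ib = np.full(extra, peaks.index[peaks["peak_id"] == b][0])
        s1, e1 = _uniform_end_in_peak(rng, peaks, ia, config.pet_end_length)
        s2, e2 = _uniform_end_in_peak(rng, peaks, ib, config.pet_end_length)
        frames.append(pd.DataFrame({
            "chrom1": peaks["chrom"].to_numpy()[ia], "start1": s1, "end1": e1,
            "strand1": np.where(rng.random(extra) < 0.5, "+", "-"),
            "chrom2": peaks["chrom"].to_numpy()[ib], "start2": s2, "end2": e2,
            "strand2": np.where(rng.random(extra) < 0.5, "+", "-"),
        }))

    if n_self > 0:
        idx = rng.choice(len(peaks), size=n_self, p=probs)
        s1, e1 = _uniform_end_in_peak(rng, peaks, idx, config.pet_end_length)
        lo, hi = config.self_ligation_span
        span = rng.integers(lo, hi + 1, size=n_self)
        s2 = s1 + span
        frames.append(pd.DataFrame({
            "chrom1": peaks["chrom"].to_numpy()[idx], "start1": s1, "end1": e1,
            "strand1": np.where(rng.random(n_self) < 0.5, "+", "-"),
            "chrom2": peaks["chrom"].to_numpy()[idx], "start2": s2,
            "end2": s2 + config.pet_end_length,
            "strand2": np.where(rng.random(n_self) < 0.5, "+", "-"),
        }))

    if n_inter > 0:
        chroms = peaks["chrom"].unique()
        if len(chroms) < 2:
            raise ConfigError("inter_fraction > 0 needs peaks on >= 2 chromosomes")
        made = 0
        parts = []
        while made < n_inter:
            i1 = rng.choice(len(peaks), size=n_inter - made, p=probs)
            i2 = rng.choice(len(peaks), size=n_inter - made, p=probs)
            keep = peaks["chrom"].to_numpy()[i1] != peaks["chrom"].to_numpy()[i2]
            i1, i2 = i1[keep], i2[keep]
            if i1.size == 0:
                continue
            s1, e1 = _uniform_end_in_peak(rng, peaks, i1, config.pet_end_length)
            s2, e2 = _uniform_end_in_peak(rng, peaks, i2, config.pet_end_length)
            parts.append(pd.DataFrame({
                "chrom1": peaks["chrom"].to_numpy()[i1], "start1": s1, "end1": e1,
                "strand1": np.where(rng.random(i1.size) < 0.5, "+", "-"),
                "chrom2": peaks["chrom"].to_numpy()[i2], "start2": s2, "end2": e2,
                "strand2": np.where(rng.random(i1.size) < 0.5, "+", "-"),
            }))
            made += i1.size
        frames.extend(parts)

    if frames:
        pets = pd.concat(frames, ignore_index=True)
    else:
        pets = pd.DataFrame(columns=PET_COLUMNS[:-1])

    n_distinct = len(pets)
    dup_mask = rng.random(n_distinct) < config.duplicate_rate
    n_duplicates = int(dup_mask.sum())
    if n_duplicates:
        pets = pd.concat([pets, pets[dup_mask]], ignore_index=True)

    pets = normalize_pet_frame(pets)
    pets["name"] = [f"PET{i:07d}" for i in range(len(pets))]
    pets = pets[PET_COLUMNS]
    log = {
        "n_emitted": len(pets),
        "n_distinct_generated": n_distinct,
        "n_duplicates": n_duplicates,
        "n_background": n_loopable,
        "n_self_ligation": n_self,
        "n_inter": n_inter,
        "n_planted": int(sum(extra for *_, extra in config.planted_loops)),
        "seed": config.seed,
    }
    return pets, log


def generate_signal_track(genome: GenomeModel, peaks: pd.DataFrame,
                          config: SyntheticConfig) -> pd.DataFrame:
    """Piecewise-constant coverage: baseline plus a bump of height intensity
    over each peak. Returned as a bedGraph-like frame (chrom, start, end,
    value) with contiguous non-overlapping intervals per chromosome."""
    config.validate()
    rows = []
    for chrom, length in genome.chromosomes:
        sub = peaks[peaks["chrom"] == chrom].sort_values("start")
        pos = 0
        for p in sub.itertuples(index=False):
            if p.start > pos:
                rows.append((chrom, pos, p.start, config.signal_baseline))
            rows.append((chrom, p.start, p.end, config.signal_baseline + p.intensity))
            pos = p.end
        if pos < length:
            rows.append((chrom, pos, length, config.signal_baseline))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
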