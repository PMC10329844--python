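"""Annotation and descriptive computations: IUPAC motif scanning, binned
density correlations, metagene profiles, set enrichment, interaction networks
and arc-ready exports."""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .stats import hypergeom_upper_tail
from .synthetic import RBM_CONSENSUS, _IUPAC

__all__ = [
    "scan_rbm",
    "binned_density",
    "density_correlation",
    "gene_metaplot",
    "overlap_enrichment",
    "build_network",
    "InteractionNetwork",
    "export_arcs",
]

_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _matches_at(seq: str, pos: int, classes) -> bool:
    for off, allowed in enumerate(classes):
        if seq[pos + off] not in allowed:
            return False
    return True


def scan_rbm(sequence: str, consensus: str = RBM_CONSENSUS,
             chrom: str = "seq") -> pd.DataFrame:
    """All exact IUPAC-consensus matches on both strands.

    R={A,G}, W={A,T}, Y={C,T} etc.; N in the sequence never matches (no
    consensus class contains N). Minus-strand hits are reported in
    plus-strand coordinates with strand='-'. Overlapping hits are all
    reported. Coordinates are 0-based half-open.
    """
    consensus = consensus.upper()
    for c in consensus:
        if c not in _IUPAC:
            raise ValueError(f"invalid IUPAC character {c!r} in consensus")
    seq = sequence.upper()
    L = len(consensus)
    fwd = [set(_IUPAC[c]) for c in consensus]
    rev = [set(_IUPAC[c]) for c in _revcomp(consensus)]
    rows = []
    for pos in range(len(seq) - L + 1):
        if _matches_at(seq, pos, fwd):
            rows.append((chrom, pos, pos + L, "+", seq[pos:pos + L]))
        if _matches_at(seq, pos, rev):
            rows.append((chrom, pos, pos + L, "-", seq[pos:pos + L]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "sequence"])


def binned_density(positions: pd.DataFrame, chrom_sizes: dict,
                   bin_bp: float = 18.5e6,
                   weight_col: str | None = None) -> pd.DataFrame:
    """Per-chromosome binned counts (or weight sums) over fixed-size bins.

    Each chromosome is evenly partitioned into bins of ``bin_bp``; the final
    partial bin is kept with raw (unnormalized) counts. Point features bin
    by their midpoint. Returns (chrom, bin, value) with contiguous bins.
    """
    bin_bp = int(bin_bp)
    rows = []
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / bin_bp))
        vals = np.zeros(n_bins)
        sub = positions[positions["chrom"] == chrom]
        if len(sub):
            if "end" in sub.columns:
                mid = ((sub["start"] + sub["end"]) // 2).to_numpy()
            else:
                mid = sub["start"].to_numpy()
            idx = np.clip(mid // bin_bp, 0, n_bins - 1).astype(int)
            w = sub[weight_col].to_numpy(dtype=float) if weight_col else np.ones(len(sub))
            np.add.at(vals, idx, w)
        for b in range(n_bins):
            rows.append((chrom, b, vals[b]))
    return pd.DataFrame(rows, columns=["chrom", "bin", "value"])


def loop_density_track(calls: pd.DataFrame, chrom_sizes: dict,
                       bin_bp: float = 18.5e6,
                       per_anchor: bool = True) -> pd.DataFrame:
    """Loop intensity per bin: PET counts of interactions whose anchor
    midpoint falls in the bin; each interaction contributes at both anchors
    (arc-plot vertex convention) unless ``per_anchor`` is False."""
    rows = []
    for r in calls.itertuples(index=False):
        rows.append((r.chrom_a, (r.start_a + r.end_a) // 2, r.pet_count))
        if per_anchor:
            rows.append((r.chrom_b, (r.start_b + r.end_b) // 2, r.pet_count))
    df = pd.DataFrame(rows, columns=["chrom", "start", "pet_count"])
    return binned_density(df, chrom_sizes, bin_bp, weight_col="pet_count")


def density_correlation(tracks: dict, chrom_sizes: dict | None = None,
                        bin_bp: float = 18.5e6) -> pd.DataFrame:
    """Pairwise Pearson r between concatenated binned densities.

    ``tracks`` maps name -> binned frame from :func:`binned_density` (or any
    frame with a ``value`` column on identical bins). Pearson r is invariant
    under any whole-bin permutation applied to all tracks, so the
    concatenation order of chromosomes does not matter.
    """
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("need at least two feature tracks")
    vectors = {}
    length = None
    for name in names:
        v = np.asarray(tracks[name]["value"], dtype=float)
        if length is None:
            length = v.size
        elif v.size != length:
            raise ValueError("tracks binned over different grids")
        vectors[name] = v
    if length < 2:
        raise ValueError("correlation undefined for fewer than two bins")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                r = _pearson_exact(vectors[a], vectors[b])
                out.loc[a, b] = out.loc[b, a] = r
    return out


def _pearson_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with exactly-rounded (fsum) reductions, so the result is
    bit-identical under any permutation applied to both vectors."""
    n = x.size
    mx = math.fsum(x) / n
    my = math.fsum(y) / n
    dx = x - mx
    dy = y - my
    cov = math.fsum(dx * dy)
    vx = math.fsum(dx * dx)
    vy = math.fsum(dy * dy)
    if vx == 0.0 or vy == 0.0:
        return np.nan
    return cov / math.sqrt(vx * vy)


class _StepSignal:
    """Integrable piecewise-constant signal per chromosome (0 off-track)."""

    def __init__(self, bedgraph: pd.DataFrame):
        self.chroms = {}
        for chrom, grp in bedgraph.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            edges = np.concatenate([grp["start"].to_numpy(dtype=float),
                                    [grp["end"].to_numpy()[-1]]])
            vals = grp["value"].to_numpy(dtype=float)
            # cumulative integral at each edge
            widths = np.diff(edges)
            cum = np.concatenate([[0.0], np.cumsum(vals * widths)])
            self.chroms[chrom] = (edges, vals, cum)

    def integral(self, chrom: str, a: float, b: float) -> float:
        """Integral of the signal over [a, b); regions off-track count 0."""
        if chrom not in self.chroms or b <= a:
            return 0.0
        edges, vals, cum = self.chroms[chrom]
        a = np.clip(a, edges[0], edges[-1])
        b = np.clip(b, edges[0], edges[-1])
        if b <= a:
            return 0.0

        def cum_at(x):
            i = np.searchsorted(edges, x, side="right") - 1
            i = min(max(i, 0), len(vals) - 1)
            return cum[i] + vals[i] * (x - edges[i])

        return cum_at(b) - cum_at(a)

    def mean(self, chrom: str, a: float, b: float) -> float:
        if b <= a:
            return 0.0
        return self.integral(chrom, a, b) / (b - a)


@dataclass
class MetaProfile:
    values: np.ndarray   # length flank_bins + body_bins + flank_bins
    n_genes: int
    flank_bins: int = 100
    body_bins: int = 300


def gene_metaplot(signal: pd.DataFrame, genes: pd.DataFrame,
                  flank_bp: int = 2_000, flank_bins: int = 100,
                  body_bins: int = 300) -> MetaProfile:
    """Average signal profile across genes on a fixed 100/300/100-bin frame.

    Per gene: the 2 kb upstream of the TSS and the 2 kb downstream of the
    TES are split into 100 bins of 20 bp; the gene body is split into 300
    equal fractional bins regardless of length (length-weighted averaging
    handles fractional bp, so bodies shorter than 300 bp still work). Minus
    strand genes are flipped so every profile reads 5' to 3'. The group
    profile is the unweighted mean of per-gene profiles (500 bins).
    """
    sig = _StepSignal(signal)
    total_bins = 2 * flank_bins + body_bins
    flank_bin_bp = flank_bp / flank_bins
    profiles = []
    for g in genes.itertuples(index=False):
        if g.tes == g.tss:
            raise ValueError(f"gene {g.gene_id} has zero-length body")
        vec = np.empty(total_bins)
        if g.strand == "+":
            five, three = g.tss, g.tes
            direction = 1.0
        else:
            five, three = g.tss, g.tes   # tss > tes on minus strand
            direction = -1.0
        # upstream flank, 5'->3'
        for b in range(flank_bins):
            a0 = five - direction * flank_bp + direction * b * flank_bin_bp
            a1 = a0 + direction * flank_bin_bp
            vec[b] = sig.mean(g.chrom, min(a0, a1), max(a0, a1))
        body_len = abs(three - five)
        for b in range(body_bins):
            a0 = five + direction * body_len * b / body_bins
            a1 = five + direction * body_len * (b + 1) / body_bins
            vec[flank_bins + b] = sig.mean(g.chrom, min(a0, a1), max(a0, a1))
        for b in range(flank_bins):
            a0 = three + direction * b * flank_bin_bp
            a1 = a0 + direction * flank_bin_bp
            vec[flank_bins + body_bins + b] = sig.mean(
                g.chrom, min(a0, a1), max(a0, a1))
        profiles.append(vec)
    if not profiles:
        raise ValueError("no genes to profile")
    return MetaProfile(values=np.mean(profiles, axis=0), n_genes=len(profiles),
                       flank_bins=flank_bins, body_bins=body_bins)


def overlap_enrichment(set_a, set_b, universe):
    """(|A & B|, hypergeometric upper-tail p) for two sets in a universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    return k, hypergeom_upper_tail(k, len(u), len(a), len(b))


@dataclass
class InteractionNetwork:
    graph: nx.Graph
    vertices: pd.DataFrame     # anchor, chrom, start, end, total_pets, degree
    edges: pd.DataFrame        # anchor_a, anchor_b, pet_count
    incidence: np.ndarray      # vertex x edge 0/1 matrix

    @property
    def hubs(self) -> pd.DataFrame:
        return self.vertices.sort_values("degree", ascending=False)


def build_network(calls: pd.DataFrame) -> InteractionNetwork:
    """Graph over anchors (vertices) and significant interactions (edges).

    Vertices are deduplicated by anchor identity; per-vertex total PET count
    sums the PETs of every incident interaction (the arc-plot dot size).
    Incidence-matrix column sums are identically 2.
    """
    g = nx.Graph()
    vertex_info = {}
    edges = []
    for r in calls.itertuples(index=False):
        va = (r.chrom_a, int(r.start_a), int(r.end_a))
        vb = (r.chrom_b, int(r.start_b), int(r.end_b))
        for v, aid in ((va, r.anchor_a), (vb, r.anchor_b)):
            info = vertex_info.setdefault(v, {"anchor": aid, "total_pets": 0})
            info["total_pets"] += int(r.pet_count)
        g.add_edge(va, vb, pet_count=int(r.pet_count))
        edges.append((r.anchor_a, r.anchor_b, int(r.pet_count)))
    vertices = sorted(vertex_info)
    vindex = {v: i for i, v in enumerate(vertices)}
    incidence = np.zeros((len(vertices), len(edges)), dtype=np.int8)
    for e, r in enumerate(calls.itertuples(index=False)):
        incidence[vindex[(r.chrom_a, int(r.start_a), int(r.end_a))], e] = 1
        incidence[vindex[(r.chrom_b, int(r.start_b), int(r.end_b))], e] = 1
    vdf = pd.DataFrame(
        [(vertex_info[v]["anchor"], v[0], v[1], v[2],
          vertex_info[v]["total_pets"], g.degree[v]) for v in vertices],
        columns=["anchor", "chrom", "start", "end", "total_pets", "degree"])
    edf = pd.DataFrame(edges, columns=["anchor_a", "anchor_b", "pet_count"])
    return InteractionNetwork(graph=g, vertices=vdf, edges=edf, incidence=incidence)


def export_arcs(calls: pd.DataFrame, region: tuple | None = None) -> pd.DataFrame:
    """WashU-style long-range records, optionally restricted to a region.

    With ``region = (chrom, start, end)``, only interactions whose anchors
    BOTH lie fully inside the region are kept. Returns a frame whose rows
    format as ``chrA,startA,endA<TAB>chrB,startB,endB<TAB>score``.
    """
    sub = calls
    if region is not None:
        try:
            chrom, start, end = region
            start, end = int(start), int(end)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed region {region!r}") from exc
        if end < start:
            raise ValueError(f"malformed region {region!r}")
        inside = ((calls["chrom_a"] == chrom) & (calls["chrom_b"] == chrom)
                  & (calls["start_a"] >= start) & (calls["end_a"] <= end)
                  & (calls["start_b"] >= start) & (calls["end_b"] <= end))
        sub = calls[inside]
    return pd.DataFrame({
        "anchor_a": [f"{r.chrom_a},{int(r.start_a)},{int(r.end_a)}"
                     for r in sub.itertuples(index=False)],
        "anchor_b": [f"{r.chrom_b},{int(r.start_b)},{int(r.end_b)}"
                     for r in sub.itertuples(index=False)],
        "score": sub["pet_count"].to_numpy() if len(sub) else [],
    })
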