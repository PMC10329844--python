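"""ChIA-PET interaction calling from aligned PETs and peak intervals.

Pipeline: deduplicate -> classify (drop self-ligation/interchromosomal) ->
assign ends to peaks -> per-pair hypergeometric upper-tail p -> BH q ->
shuffled-null empirical-FDR cutoff -> high-confidence calls (>= 3 PETs).

A pair is significant only if it clears the shuffle cutoff, has BH q <= fdr,
and carries at least ``min_pets`` PETs; all three steps come from the
published procedure, read conjunctively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .stats import bh_adjust, hypergeom_upper_tail
from .synthetic import normalize_pet_frame

logger = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "deduplicate_pets",
    "classify_pets",
    "assign_pets_to_peaks",
    "pair_counts",
    "shuffle_null",
    "call_interactions",
    "classify_anchors",
    "bound_genes",
    "compare_interaction_sets",
    "loops_vs_rbm",
]

PET_KEY = ["chrom1", "start1", "end1", "strand1",
           "chrom2", "start2", "end2", "strand2"]


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the interaction caller.

    ``fdr`` defaults to 0.01 (the Ronin-type setting; Pol II-type runs use
    0.05). ``min_span`` = 4 kb self-ligation cutoff, ``min_overlap`` = 1 bp
    end/peak overlap, ``min_pets`` = 3 for high confidence, promoter window
    +-2500 bp, bound-gene window +-1000 bp.
    """

    min_span: int = 4_000
    min_overlap: int = 1
    fdr: float = 0.01
    min_pets: int = 3
    n_shuffles: int = 100
    seed: int = 0
    promoter_window: int = 2_500
    bound_window: int = 1_000
    span_mode: str = "midpoint"        # or "inner"
    population: str = "genome"         # or "per_chromosome"
    cutoff_mode: str = "empirical_fdr"  # or "null_quantile"

    def validate(self) -> "CallerConfig":
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        for name in ("min_span", "min_overlap", "min_pets", "n_shuffles",
                     "promoter_window", "bound_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        return self

    def with_(self, **kw) -> "CallerConfig":
        return replace(self, **kw)


def deduplicate_pets(pets: pd.DataFrame):
    """Collapse PETs identical in coordinates and strands at both ends.

    Order-stable and idempotent; returns (deduplicated frame, n_removed).
    """
    pets = normalize_pet_frame(pets)
    out = pets.drop_duplicates(subset=PET_KEY, keep="first").reset_index(drop=True)
    return out, len(pets) - len(out)


def pet_spans(pets: pd.DataFrame, mode: str = "midpoint") -> np.ndarray:
    """Span of each PET on its own chromosome (NaN for interchromosomal)."""
    if mode == "midpoint":
        m1 = (pets["start1"] + pets["end1"]).to_numpy() / 2.0
        m2 = (pets["start2"] + pets["end2"]).to_numpy() / 2.0
        span = np.abs(m2 - m1)
    elif mode == "inner":
        span = (pets["start2"] - pets["end1"]).to_numpy(dtype=float)
        span = np.maximum(span, 0.0)
    else:
        raise ValueError(f"unknown span mode {mode!r}")
    span = span.astype(float)
    span[(pets["chrom1"] != pets["chrom2"]).to_numpy()] = np.nan
    return span


def classify_pets(pets: pd.DataFrame, min_span: int = 4_000,
                  span_mode: str = "midpoint") -> pd.DataFrame:
    """Categorize PETs: inter, self_ligation (intra, span < min_span), intra.

    An intrachromosomal PET of span exactly ``min_span`` is retained as
    intra (the filter removes spans strictly below the cutoff). Output is
    independent of input row order (sorted by coordinates, stable).
    """
    out = normalize_pet_frame(pets).copy()
    span = pet_spans(out, span_mode)
    out["span"] = span
    inter = out["chrom1"] != out["chrom2"]
    out["category"] = np.where(
        inter, "inter", np.where(span < min_span, "self_ligation", "intra"))
    out = out.sort_values(PET_KEY, kind="stable").reset_index(drop=True)
    return out


def _assign_ends(chrom, start, end, peaks_by_chrom, min_overlap):
    """Peak row index per end (-1 = unassigned): max overlap, ties leftmost."""
    n = chrom.size
    out = np.full(n, -1, dtype=np.int64)
    for c, (pstart, pend, rows) in peaks_by_chrom.items():
        mask = chrom == c
        if not mask.any():
            continue
        s = start[mask]
        e = end[mask]
        # candidate peaks overlap [s, e): peaks with pstart < e and pend > s
        lo = np.searchsorted(pend, s, side="right")
        hi = np.searchsorted(pstart, e, side="left")
        res = np.full(s.size, -1, dtype=np.int64)
        multi = hi - lo
        for j in np.flatnonzero(multi > 0):
            cand = np.arange(lo[j], hi[j])
            ov = np.minimum(pend[cand], e[j]) - np.maximum(pstart[cand], s[j])
            ok = ov >= min_overlap
            if ok.any():
                cand, ov = cand[ok], ov[ok]
                res[j] = rows[cand[int(np.argmax(ov))]]  # argmax → leftmost tie
        out[np.flatnonzero(mask)] = res
    return out


def assign_pets_to_peaks(pets: pd.DataFrame, peaks: pd.DataFrame,
                         min_overlap: int = 1):
    """Assign both ends of each PET to peaks (>= min_overlap bp overlap).

    An end overlapping several peaks goes to the one with maximal overlap,
    ties broken toward the leftmost peak. Returns (assigned frame with
    ``peak_a``/``peak_b`` positional peak indices ordered a <= b, counts
    dict). PETs with both ends in the same peak are reported separately and
    excluded from pair statistics.
    """
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    by_chrom = {}
    for c, grp in peaks.groupby("chrom", sort=False):
        by_chrom[c] = (grp["start"].to_numpy(), grp["end"].to_numpy(),
                       grp.index.to_numpy())
    a = _assign_ends(pets["chrom1"].to_numpy(), pets["start1"].to_numpy(),
                     pets["end1"].to_numpy(), by_chrom, min_overlap)
    b = _assign_ends(pets["chrom2"].to_numpy(), pets["start2"].to_numpy(),
                     pets["end2"].to_numpy(), by_chrom, min_overlap)
    both = (a >= 0) & (b >= 0)
    same = both & (a == b)
    keep = both & ~same
    assigned = pets.loc[keep].copy()
    pa = np.minimum(a[keep], b[keep])
    pb = np.maximum(a[keep], b[keep])
    assigned["peak_a"] = pa
    assigned["peak_b"] = pb
    counts = {
        "n_unassigned": int((~both).sum()),
        "n_same_peak": int(same.sum()),
        "n_assigned": int(keep.sum()),
    }
    return assigned.reset_index(drop=True), counts, peaks


def pair_counts(peak_a: np.ndarray, peak_b: np.ndarray,
                chrom_of_peak: np.ndarray | None = None,
                population: str = "genome") -> pd.DataFrame:
    """Hypergeometric counts per unordered anchor pair.

    N = qualifying PETs (genome-wide by default, per-chromosome optional),
    n_a / n_b = PETs with an end in each anchor, k = PETs linking the pair.
    """
    if peak_a.size == 0:
        return pd.DataFrame(columns=["peak_a", "peak_b", "k", "n_a", "n_b", "N"])
    key = peak_a.astype(np.int64) << 32 | peak_b.astype(np.int64)
    uniq, k = np.unique(key, return_counts=True)
    pa = (uniq >> 32).astype(np.int64)
    pb = (uniq & 0xFFFFFFFF).astype(np.int64)
    ends = np.concatenate([peak_a, peak_b])
    peak_ids, end_counts = np.unique(ends, return_counts=True)
    lut = dict(zip(peak_ids.tolist(), end_counts.tolist()))
    n_a = np.array([lut[p] for p in pa], dtype=np.int64)
    n_b = np.array([lut[p] for p in pb], dtype=np.int64)
    if population == "per_chromosome":
        if chrom_of_peak is None:
            raise ValueError("per-chromosome population needs peak chromosomes")
        chrom = chrom_of_peak[peak_a]
        n_per = pd.Series(chrom).value_counts()
        N = n_per.reindex(chrom_of_peak[pa]).to_numpy(dtype=np.int64)
    else:
        N = np.full(pa.size, peak_a.size, dtype=np.int64)
    df = pd.DataFrame({"peak_a": pa, "peak_b": pb, "k": k,
                       "n_a": n_a, "n_b": n_b, "N": N})
    # guard: an anchor's end count can exceed N only through same-peak PETs,
    # which were dropped upstream, so the invariant k <= min(n_a, n_b) <= N holds
    return df


def _pair_pvalues(pairs: pd.DataFrame) -> np.ndarray:
    nab = np.minimum(pairs["n_a"].to_numpy(), pairs["N"].to_numpy())
    nbb = np.minimum(pairs["n_b"].to_numpy(), pairs["N"].to_numpy())
    return hypergeom_upper_tail(pairs["k"].to_numpy(), pairs["N"].to_numpy(),
                                nab, nbb)


def shuffle_null(assigned: pd.DataFrame, n_shuffles: int, seed: int,
                 fdr: float, chrom_of_peak=None, population="genome",
                 cutoff_mode: str = "empirical_fdr"):
    """Null p-value multiset by permuting end-2 anchor labels, plus cutoff.

    Each shuffle permutes the second-end peak labels uniformly among the
    assigned PETs (first ends fixed, so N is preserved exactly and the
    anchor marginals in expectation), recomputes pair counts and p-values.
    The cutoff at target ``fdr`` is the largest observed p-value c with
    mean_shuffles #{null p' <= c} / #{observed p <= c} <= fdr
    (``empirical_fdr``), or the fdr-quantile of the pooled null p-values
    (``null_quantile``). Returns (null p-values array, cutoff).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if len(assigned) < 2:
        raise ValueError("need at least two assigned PETs")
    rng = np.random.default_rng(seed)
    a = assigned["peak_a"].to_numpy()
    b = assigned["peak_b"].to_numpy()
    obs = pair_counts(a, b, chrom_of_peak, population)
    obs_p = np.sort(_pair_pvalues(obs))

    null_ps = []
    for _ in range(n_shuffles):
        perm = rng.permutation(b.size)
        b2 = b[perm]
        pa = np.minimum(a, b2)
        pb = np.maximum(a, b2)
        distinct = pa != pb
        pairs = pair_counts(pa[distinct], pb[distinct], chrom_of_peak, population)
        if len(pairs):
            null_ps.append(_pair_pvalues(pairs))
    null_p = np.sort(np.concatenate(null_ps)) if null_ps else np.array([])

    if cutoff_mode == "null_quantile":
        cutoff = float(np.quantile(null_p, fdr)) if null_p.size else -np.inf
        return null_p, cutoff

    cutoff = -np.inf
    if null_p.size and obs_p.size:
        # V(c): mean null pairs at or below c; R(c): observed pairs at or below c
        v = np.searchsorted(null_p, obs_p, side="right") / n_shuffles
        r = np.arange(1, obs_p.size + 1)
        ok = v / r <= fdr
        if ok.any():
            cutoff = float(obs_p[np.flatnonzero(ok).max()])
    return null_p, cutoff


INTERACTION_COLUMNS = [
    "chrom_a", "start_a", "end_a", "anchor_a",
    "chrom_b", "start_b", "end_b", "anchor_b",
    "pet_count", "p_value", "q_value", "significant", "category", "span",
]


def call_interactions(pets: pd.DataFrame, peaks: pd.DataFrame,
                      config: CallerConfig = CallerConfig()):
    """Full interaction-calling pipeline; returns (calls, log).

    Every candidate anchor pair is reported with its statistics; the
    ``significant`` flag marks high-confidence interactions (shuffle cutoff,
    BH q <= fdr, and >= min_pets PETs). The log carries the conservation
    identity: input = duplicates + self + inter + unassigned + same-peak +
    assigned.
    """
    config.validate()
    log = {"n_input": len(pets)}
    if len(peaks) == 0:
        logger.warning("empty peak set: no interactions can be called")
        log.update(n_duplicates_removed=0, n_self_ligation=0, n_inter=0,
                   n_unassigned=0, n_same_peak=0, n_assigned=0, cutoff=np.nan)
        return pd.DataFrame(columns=INTERACTION_COLUMNS), log

    deduped, n_dup = deduplicate_pets(pets)
    log["n_duplicates_removed"] = n_dup
    classified = classify_pets(deduped, config.min_span, config.span_mode)
    log["n_self_ligation"] = int((classified["category"] == "self_ligation").sum())
    log["n_inter"] = int((classified["category"] == "inter").sum())
    intra = classified[classified["category"] == "intra"]

    assigned, counts, peaks_sorted = assign_pets_to_peaks(
        intra, peaks, config.min_overlap)
    log.update(counts)
    if len(assigned) < 2:
        log["cutoff"] = np.nan
        return pd.DataFrame(columns=INTERACTION_COLUMNS), log

    chrom_codes = peaks_sorted["chrom"].to_numpy()
    pairs = pair_counts(assigned["peak_a"].to_numpy(),
                        assigned["peak_b"].to_numpy(),
                        chrom_codes, config.population)
    p = _pair_pvalues(pairs)
    q = bh_adjust(p)
    _, cutoff = shuffle_null(assigned, config.n_shuffles, config.seed,
                             config.fdr, chrom_codes, config.population,
                             config.cutoff_mode)
    log["cutoff"] = cutoff
    sig = (p <= cutoff) & (q <= config.fdr) & (pairs["k"].to_numpy() >= config.min_pets)

    pa = pairs["peak_a"].to_numpy()
    pb = pairs["peak_b"].to_numpy()
    mid_a = (peaks_sorted["start"].to_numpy()[pa] + peaks_sorted["end"].to_numpy()[pa]) / 2
    mid_b = (peaks_sorted["start"].to_numpy()[pb] + peaks_sorted["end"].to_numpy()[pb]) / 2
    same_chrom = peaks_sorted["chrom"].to_numpy()[pa] == peaks_sorted["chrom"].to_numpy()[pb]
    span = np.where(same_chrom, np.abs(mid_b - mid_a), np.nan)

    calls = pd.DataFrame({
        "chrom_a": peaks_sorted["chrom"].to_numpy()[pa],
        "start_a": peaks_sorted["start"].to_numpy()[pa],
        "end_a": peaks_sorted["end"].to_numpy()[pa],
        "anchor_a": peaks_sorted["peak_id"].to_numpy()[pa],
        "chrom_b": peaks_sorted["chrom"].to_numpy()[pb],
        "start_b": peaks_sorted["start"].to_numpy()[pb],
        "end_b": peaks_sorted["end"].to_numpy()[pb],
        "anchor_b": peaks_sorted["peak_id"].to_numpy()[pb],
        "pet_count": pairs["k"].to_numpy(),
        "p_value": p,
        "q_value": q,
        "significant": sig,
        "category": "other",
        "span": span,
    })
    log["n_significant"] = int(sig.sum())
    return calls, log


def _label_anchor(chrom, start, end, promoters, enhancers):
    """promoter wins over enhancer; enhancer over other."""
    n = chrom.size
    label = np.full(n, "other", dtype=object)
    for name, intervals in (("enhancer", enhancers), ("promoter", promoters)):
        for c, (istart, iend) in intervals.items():
            mask = chrom == c
            if not mask.any():
                continue
            s, e = start[mask], end[mask]
            lo = np.searchsorted(iend, s, side="right")
            hi = np.searchsorted(istart, e, side="left")
            hit = hi > lo
            idx = np.flatnonzero(mask)[hit]
            label[idx] = name
    return label


def _interval_index(df, start_col="start", end_col="end"):
    out = {}
    for c, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values(start_col)
        out[c] = (grp[start_col].to_numpy(), grp[end_col].to_numpy())
    return out


def classify_anchors(calls: pd.DataFrame, genes: pd.DataFrame,
                     enhancers: pd.DataFrame | None = None,
                     promoter_window: int = 2_500) -> pd.DataFrame:
    """Label anchors promoter/enhancer/other; category = unordered pair.

    Promoters are [TSS - w, TSS + w) half-open; an anchor overlapping both a
    promoter and an enhancer is a promoter. Pairs map to P-P / E-P / E-E;
    anything touching an unlabeled anchor is 'other'.
    """
    if calls.empty:
        out = calls.copy()
        out["category"] = pd.Series(dtype=object)
        return out
    prom = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": np.maximum(genes["tss"] - promoter_window, 0),
        "end": genes["tss"] + promoter_window,
    })
    promoters = _interval_index(prom)
    enh = _interval_index(enhancers) if enhancers is not None and len(enhancers) else {}
    la = _label_anchor(calls["chrom_a"].to_numpy(), calls["start_a"].to_numpy(),
                       calls["end_a"].to_numpy(), promoters, enh)
    lb = _label_anchor(calls["chrom_b"].to_numpy(), calls["start_b"].to_numpy(),
                       calls["end_b"].to_numpy(), promoters, enh)
    cat = np.full(la.size, "other", dtype=object)
    both = np.char.add(np.asarray(la, dtype=str), np.asarray(lb, dtype=str))
    cat[both == "promoterpromoter"] = "P-P"
    cat[(both == "promoterenhancer") | (both == "enhancerpromoter")] = "E-P"
    cat[both == "enhancerenhancer"] = "E-E"
    out = calls.copy()
    out["anchor_a_label"] = la
    out["anchor_b_label"] = lb
    out["category"] = cat
    return out


def bound_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                bound_window: int = 1_000) -> set:
    """Gene ids whose promoter window [TSS-w, TSS+w) overlaps any peak."""
    if genes.empty or peaks.empty:
        return set()
    idx = _interval_index(peaks)
    out = set()
    for g in genes.itertuples(index=False):
        if g.chrom not in idx:
            continue
        pstart, pend = idx[g.chrom]
        w0, w1 = g.tss - bound_window, g.tss + bound_window
        lo = np.searchsorted(pend, w0, side="right")
        hi = np.searchsorted(pstart, w1, side="left")
        if hi > lo:
            out.add(g.gene_id)
    return out


def _reciprocal_match(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> np.ndarray:
    """Boolean per row of calls_a: some call in calls_b overlaps both anchors."""
    matched = np.zeros(len(calls_a), dtype=bool)
    by_chrom = {}
    for i, r in calls_b.iterrows():
        by_chrom.setdefault((r.chrom_a, r.chrom_b), []).append(
            (r.start_a, r.end_a, r.start_b, r.end_b))
    for i, r in enumerate(calls_a.itertuples(index=False)):
        for sa, ea, sb, eb in by_chrom.get((r.chrom_a, r.chrom_b), ()):
            if (min(ea, r.end_a) > max(sa, r.start_a)
                    and min(eb, r.end_b) > max(sb, r.start_b)):
                matched[i] = True
                break
    return matched


def compare_interaction_sets(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Condition comparison (e.g. control vs knockout).

    Interactions match when both anchor intervals reciprocally overlap by at
    least 1 bp. Reports retained/lost/gained fractions, the fraction of
    ``calls_b`` anchors shared with ``calls_a``, and per-shared-anchor PET
    count differences.
    """
    chroms_a = set(calls_a["chrom_a"]) | set(calls_a["chrom_b"])
    chroms_b = set(calls_b["chrom_a"]) | set(calls_b["chrom_b"])
    if chroms_a and chroms_b and not (chroms_a & chroms_b):
        raise ValueError("interaction sets share no chromosome namespace")

    retained = _reciprocal_match(calls_a, calls_b)
    gained = ~_reciprocal_match(calls_b, calls_a)

    def anchor_pets(calls):
        rows = []
        for r in calls.itertuples(index=False):
            rows.append((r.chrom_a, r.start_a, r.end_a, r.pet_count))
            rows.append((r.chrom_b, r.start_b, r.end_b, r.pet_count))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "pet_count"])
        return df.groupby(["chrom", "start", "end"], as_index=False)["pet_count"].sum()

    aa, ab = anchor_pets(calls_a), anchor_pets(calls_b)
    deltas = []
    shared_anchors = 0
    if len(aa) and len(ab):
        idx = _interval_index(ab)
        for r in aa.itertuples(index=False):
            if r.chrom not in idx:
                continue
            istart, iend = idx[r.chrom]
            lo = np.searchsorted(iend, r.start, side="right")
            hi = np.searchsorted(istart, r.end, side="left")
            if hi > lo:
                shared_anchors += 1
                other = ab[(ab["chrom"] == r.chrom)
                           & (ab["start"] < r.end) & (ab["end"] > r.start)]
                deltas.append((r.chrom, r.start, r.end, r.pet_count,
                               float(other["pet_count"].sum())))
    delta_df = pd.DataFrame(
        deltas, columns=["chrom", "start", "end", "pets_a", "pets_b"])
    if len(delta_df):
        delta_df["delta"] = delta_df["pets_b"] - delta_df["pets_a"]
    return {
        "n_a": len(calls_a),
        "n_b": len(calls_b),
        "n_retained": int(retained.sum()),
        "n_gained": int(gained.sum()),
        "n_lost": int((~retained).sum()),
        "frac_retained": float(retained.mean()) if len(calls_a) else np.nan,
        "frac_gained": float(gained.mean()) if len(calls_b) else np.nan,
        "n_shared_anchors": shared_anchors,
        "frac_shared_anchors_of_b": shared_anchors / len(ab) if len(ab) else np.nan,
        "anchor_pet_deltas": delta_df,
    }


def loops_vs_rbm(calls: pd.DataFrame, motifs: pd.DataFrame,
                 genes: pd.DataFrame, promoter_window: int = 2_500) -> dict:
    """Per-promoter (RBM count, loop degree) pairs and their correlation.

    Loop degree counts significant interactions whose anchor overlaps the
    promoter window; RBM count deduplicates motif hits by interval. The
    correlation is over promoters with at least one loop and is flagged
    undefined for < 3 promoters or zero variance.
    """
    sig = calls[calls["significant"]] if "significant" in calls else calls
    anchors = []
    for r in sig.itertuples(index=False):
        anchors.append((r.chrom_a, r.start_a, r.end_a))
        anchors.append((r.chrom_b, r.start_b, r.end_b))
    dedup_motifs = motifs.drop_duplicates(subset=["chrom", "start", "end"])
    rows = []
    for g in genes.itertuples(index=False):
        w0, w1 = g.tss - promoter_window, g.tss + promoter_window
        n_rbm = int(((dedup_motifs["chrom"] == g.chrom)
                     & (dedup_motifs["start"] < w1)
                     & (dedup_motifs["end"] > w0)).sum())
        degree = sum(1 for c, s, e in anchors if c == g.chrom and s < w1 and e > w0)
        rows.append((g.gene_id, n_rbm, degree))
    table = pd.DataFrame(rows, columns=["gene_id", "rbm_count", "loop_degree"])
    looped = table[table["loop_degree"] >= 1]
    result = {"table": table, "n_looped_promoters": len(looped),
              "pearson_r": np.nan, "pearson_p": np.nan,
              "spearman_rho": np.nan, "spearman_p": np.nan,
              "defined": False}
    if len(looped) >= 3 and looped["rbm_count"].nunique() > 1 \
            and looped["loop_degree"].nunique() > 1:
        pr = pearsonr(looped["rbm_count"], looped["loop_degree"])
        sr = spearmanr(looped["rbm_count"], looped["loop_degree"])
        result.update(pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
                      spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
                      defined=True)
    return result
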