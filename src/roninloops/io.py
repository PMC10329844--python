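"""Readers and writers for the plain-text genomics formats the pipeline uses.

BED/BEDPE/bedGraph are 0-based half-open throughout; comment and ``track``
lines are skipped on input; writers can stamp a ``# seed=...`` header so
every file records its provenance. Malformed lines raise with their line
number.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "read_bed", "write_bed",
    "read_bedpe", "write_bedpe",
    "read_bedgraph", "write_bedgraph",
    "read_fasta", "read_chrom_sizes", "write_chrom_sizes",
    "read_genes", "write_genes",
    "write_interactions", "read_interactions", "write_washu",
]


class FormatError(ValueError):
    pass


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _check_interval(start, end, path, lineno):
    if start < 0 or end <= start:
        raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")


def _header(seed):
    return f"# seed={seed}\n" if seed is not None else ""


def read_bed(path) -> pd.DataFrame:
    """BED3/BED6 -> frame (chrom, start, end[, name, score, strand])."""
    rows = []
    n_fields = None
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates")
        _check_interval(start, end, path, lineno)
        n_fields = max(n_fields or 0, min(len(fields), 6))
        row = [fields[0], start, end]
        row += fields[3:4] or [""]
        row += [float(fields[4])] if len(fields) > 4 else [0.0]
        row += fields[5:6] or ["."]
        rows.append(row)
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.DataFrame(rows, columns=cols)
    if n_fields is not None and n_fields <= 3:
        df = df[["chrom", "start", "end"]]
    return df


def write_bed(df: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        for r in df.itertuples(index=False):
            fields = [r.chrom, int(r.start), int(r.end)]
            if hasattr(r, "name"):
                fields.append(r.name)
                fields.append(int(round(float(getattr(r, "score", 0.0)))))
                fields.append(getattr(r, "strand", "."))
            fh.write("\t".join(str(f) for f in fields) + "\n")


def write_peaks_bed(peaks: pd.DataFrame, path, seed=None) -> None:
    """Peaks as BED6; the score column is intensity x 1000, rounded."""
    df = pd.DataFrame({
        "chrom": peaks["chrom"], "start": peaks["start"], "end": peaks["end"],
        "name": peaks["peak_id"],
        "score": (peaks["intensity"] * 1000).round().astype(int),
        "strand": ".",
    })
    write_bed(df, path, seed=seed)


def read_peaks_bed(path) -> pd.DataFrame:
    df = read_bed(path)
    return pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "intensity": df["score"] / 1000.0, "peak_id": df["name"],
    })


BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
              "name", "score", "strand1", "strand2"]


def read_bedpe(path) -> pd.DataFrame:
    """10-column BEDPE -> PET frame."""
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 10:
            raise FormatError(f"{path}:{lineno}: fewer than 10 BEDPE fields")
        try:
            s1, e1 = int(fields[1]), int(fields[2])
            s2, e2 = int(fields[4]), int(fields[5])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates")
        _check_interval(s1, e1, path, lineno)
        _check_interval(s2, e2, path, lineno)
        rows.append([fields[0], s1, e1, fields[8],
                     fields[3], s2, e2, fields[9], fields[6]])
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "strand1",
                                       "chrom2", "start2", "end2", "strand2",
                                       "name"])


def write_bedpe(pets: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        for i, r in enumerate(pets.itertuples(index=False)):
            name = getattr(r, "name", f"PET{i:07d}")
            fh.write("\t".join(str(f) for f in [
                r.chrom1, int(r.start1), int(r.end1),
                r.chrom2, int(r.start2), int(r.end2),
                name, 1, r.strand1, r.strand2]) + "\n")


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph -> (chrom, start, end, value); overlapping intervals reject."""
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: fewer than 4 bedGraph fields")
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed bedGraph line")
        _check_interval(start, end, path, lineno)
        rows.append([fields[0], start, end, value])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values("start")
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise FormatError(f"{path}: overlapping bedGraph intervals on {chrom}")
    return df


def write_bedgraph(df: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        for r in df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{r.value:.10g}\n")


def read_fasta(path) -> dict:
    """FASTA -> {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_chrom_sizes(path) -> dict:
    sizes = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected name<TAB>length")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer length")
    return sizes


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


GENE_COLS = ["gene_id", "chrom", "strand", "tss", "tes", "flags"]


def write_genes(genes: pd.DataFrame, path, seed=None) -> None:
    """Gene table as 6-column TSV; flags pack housekeeping/metabolic/cluster."""
    with open(path, "w") as fh:
        fh.write(_header(seed))
        for g in genes.itertuples(index=False):
            flags = f"hk={int(g.housekeeping)};met={int(g.metabolic)};cluster={g.cluster_id}"
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{int(g.tss)}\t"
                     f"{int(g.tes)}\t{flags}\n")


def read_genes(path) -> pd.DataFrame:
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 gene fields")
        flags = dict(kv.split("=") for kv in fields[5].split(";"))
        rows.append([fields[0], fields[1], fields[2], int(fields[3]),
                     int(fields[4]), bool(int(flags.get("hk", 0))),
                     bool(int(flags.get("met", 0))),
                     int(flags.get("cluster", -1))])
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss",
                                       "tes", "housekeeping", "metabolic",
                                       "cluster_id"])


def write_interactions(calls: pd.DataFrame, path, seed=None) -> None:
    """Calls as extended BEDPE with statistics columns."""
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("#" + "\t".join([
            "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
            "anchor_a", "anchor_b", "pet_count", "p_value", "q_value",
            "significant", "category", "span"]) + "\n")
        for r in calls.itertuples(index=False):
            fh.write("\t".join(str(x) for x in [
                r.chrom_a, int(r.start_a), int(r.end_a),
                r.chrom_b, int(r.start_b), int(r.end_b),
                r.anchor_a, r.anchor_b, int(r.pet_count),
                f"{r.p_value:.6g}", f"{r.q_value:.6g}",
                int(bool(r.significant)), r.category,
                "NA" if pd.isna(r.span) else f"{r.span:g}"]) + "\n")


def read_interactions(path) -> pd.DataFrame:
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 14:
            raise FormatError(f"{path}:{lineno}: expected 14 interaction fields")
        rows.append([
            fields[0], int(fields[1]), int(fields[2]), fields[6],
            fields[3], int(fields[4]), int(fields[5]), fields[7],
            int(fields[8]), float(fields[9]), float(fields[10]),
            bool(int(fields[11])), fields[12],
            float("nan") if fields[13] == "NA" else float(fields[13])])
    return pd.DataFrame(rows, columns=[
        "chrom_a", "start_a", "end_a", "anchor_a",
        "chrom_b", "start_b", "end_b", "anchor_b",
        "pet_count", "p_value", "q_value", "significant", "category", "span"])


def write_washu(arcs: pd.DataFrame, path, seed=None) -> None:
    """WashU long-range text: chrA,startA,endA<TAB>chrB,startB,endB<TAB>score."""
    with open(path, "w") as fh:
        fh.write(_header(seed))
        for r in arcs.itertuples(index=False):
            fh.write(f"{r.anchor_a}\t{r.anchor_b}\t{r.score}\n")
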