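"""Readers and writers for the plain-text formats the pipeline touches.

FASTA (via pyfaidx), bedGraph mappability tracks, chrom.sizes, bin tables
(BED3+ with feature columns), interaction-record TSVs, BEDPE for significant
calls, and bedGraph hotspot tracks.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pyfaidx import Fasta

RECORD_FLOAT_FMT = "%.6g"


def read_fasta(path) -> dict:
    """Load a (multi-record) FASTA into {name: sequence} as plain strings."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True,
               rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path, sequences: dict, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k:k + width] + "\n")


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     comment="#")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_bedgraph_track(path, chrom_sizes: dict, default: float = 0.0) -> dict:
    """Expand a bedGraph into per-base arrays, one per chromosome."""
    tracks = {c: np.full(int(n), default, dtype=float)
              for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.chrom in tracks:
            tracks[row.chrom][int(row.start):int(row.end)] = float(row.value)
    return tracks


def write_bedgraph(path, intervals: pd.DataFrame) -> None:
    """Write chrom/start/end/value rows as bedGraph."""
    intervals.to_csv(path, sep="\t", header=False, index=False,
                     float_format=RECORD_FLOAT_FMT)


def array_to_bedgraph_intervals(chrom: str, values: np.ndarray) -> pd.DataFrame:
    """Run-length encode a per-base array into bedGraph intervals."""
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, len(values)]
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                         "value": values[starts]})


def write_bins_tsv(path, bins: pd.DataFrame) -> None:
    """BED3+ bin table with feature columns, tab-separated with a header."""
    bins.to_csv(path, sep="\t", index=False, float_format=RECORD_FLOAT_FMT)


def read_bins_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_records_tsv(path, records: pd.DataFrame,
                      bins: pd.DataFrame | None = None) -> None:
    """Interaction-record table; when ``bins`` is given, bin coordinates are
    joined in so each row carries chrom start_i end_i start_j end_j."""
    out = records
    if bins is not None:
        coords = bins.set_index(["chrom", "bin_id"])[["start", "end"]]
        left = coords.reindex(
            pd.MultiIndex.from_arrays([records["chrom"], records["i"]]))
        right = coords.reindex(
            pd.MultiIndex.from_arrays([records["chrom"], records["j"]]))
        out = records.copy()
        out.insert(1, "start_i", left["start"].to_numpy())
        out.insert(2, "end_i", left["end"].to_numpy())
        out.insert(3, "start_j", right["start"].to_numpy())
        out.insert(4, "end_j", right["end"].to_numpy())
    out.to_csv(path, sep="\t", index=False, float_format=RECORD_FLOAT_FMT)


def read_records_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedpe(path, records: pd.DataFrame, bins: pd.DataFrame,
                score_col: str = "q") -> None:
    """Significant interactions as BEDPE (chrom1 start1 end1 chrom2 ...)."""
    coords = bins.set_index(["chrom", "bin_id"])[["start", "end"]]
    rows = []
    for r in records.itertuples(index=False):
        ci = coords.loc[(r.chrom, r.i)]
        cj = coords.loc[(r.chrom, r.j)]
        rows.append((r.chrom, int(ci["start"]), int(ci["end"]),
                     r.chrom, int(cj["start"]), int(cj["end"]),
                     f"{r.chrom}:{r.i}-{r.j}", getattr(r, score_col)))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False,
                              float_format=RECORD_FLOAT_FMT)


def read_triplets_tsv(path) -> pd.DataFrame:
    """Pre-binned sparse contacts: chrom bin_i bin_j count (or bin_i bin_j
    count for a single unnamed chromosome)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] == 3:
        df.insert(0, "chrom", "chr")
    df.columns = ["chrom", "i", "j", "count"]
    return df
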