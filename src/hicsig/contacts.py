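"""Read-pair filtering, contact counting and interaction-bin enumeration.

A Hi-C experiment yields paired-end reads whose two ends map to (possibly
distant) genomic positions.  This module applies the standard validity
filters — both ends uniquely mapped, PCR duplicates collapsed, both ends
within a flank of a restriction site — counts the surviving intra-chromosomal
pairs into bin pairs, and enumerates the *zero-inclusive* list of interaction
records (every bin pair up to the distance cap, observed or not), which is
what the null model is fit to.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome_features import DEFAULT_FLANK

logger = logging.getLogger(__name__)

MAX_DISTANCE = 2_000_000  # focus on sub-TAD structure

PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


def read_pairs_tsv(path) -> pd.DataFrame:
    """Read a 6-column pairs TSV (chrom1 pos1 strand1 chrom2 pos2 strand2).

    ``#``-prefixed header lines are skipped; optional boolean columns
    ``unique1``/``unique2`` are honoured when present.  Malformed lines are
    skipped with a warning.
    """
    rows, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                skipped += 1
                continue
            try:
                row = [parts[0], int(parts[1]), parts[2],
                       parts[3], int(parts[4]), parts[5]]
            except ValueError:
                skipped += 1
                continue
            if len(parts) >= 8:
                row += [parts[6] not in ("0", "False", "false"),
                        parts[7] not in ("0", "False", "false")]
            else:
                row += [True, True]
            rows.append(row)
    if skipped:
        logger.warning("skipped %d malformed pair lines", skipped)
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS + ["unique1", "unique2"])
    df.attrs["malformed"] = skipped
    return df


def _nearest_site_distance(chrom: np.ndarray, pos: np.ndarray,
                           sites_by_chrom: dict) -> np.ndarray:
    """Distance from each position to the nearest RE site on its chromosome."""
    out = np.full(len(pos), np.inf)
    for c in np.unique(chrom):
        sites = np.asarray(sites_by_chrom.get(c, ()), dtype=np.int64)
        mask = chrom == c
        if sites.size == 0:
            continue
        p = pos[mask]
        idx = np.searchsorted(sites, p)
        left = np.where(idx > 0, np.abs(p - sites[np.maximum(idx - 1, 0)]),
                        np.inf)
        right = np.where(idx < sites.size,
                         np.abs(sites[np.minimum(idx, sites.size - 1)] - p),
                         np.inf)
        out[mask] = np.minimum(left, right)
    return out


def filter_pairs(pairs: pd.DataFrame, sites_by_chrom: dict,
                 flank: int = DEFAULT_FLANK):
    """Apply the validity filters in order unique -> duplicate -> RE-distance.

    Returns ``(valid_pairs, tally)`` where tally counts removals per rule.
    Duplicate collapse is exact coordinate+strand identity after canonical
    ordering of the two ends by (chrom, pos); RE-distance removal is strict
    (an end exactly ``flank`` bp from a site is kept, ``flank + 1`` is not).
    """
    tally = {"input": len(pairs), "nonunique": 0, "duplicate": 0,
             "re_distance": 0, "kept": 0}
    df = pairs.copy()
    if "unique1" not in df:
        df["unique1"] = True
        df["unique2"] = True

    keep = df["unique1"].to_numpy() & df["unique2"].to_numpy()
    tally["nonunique"] = int((~keep).sum())
    df = df[keep]

    # canonical end ordering so A-B and B-A duplicates collapse together
    swap = (df["chrom1"] > df["chrom2"]) | (
        (df["chrom1"] == df["chrom2"]) & (df["pos1"] > df["pos2"]))
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"),
                 ("strand1", "strand2")):
        va, vb = df[a].to_numpy().copy(), df[b].to_numpy().copy()
        df[a] = np.where(swap, vb, va)
        df[b] = np.where(swap, va, vb)
    before = len(df)
    df = df.drop_duplicates(subset=PAIR_COLUMNS, keep="first")
    tally["duplicate"] = before - len(df)

    d1 = _nearest_site_distance(df["chrom1"].to_numpy(),
                                df["pos1"].to_numpy(np.int64), sites_by_chrom)
    d2 = _nearest_site_distance(df["chrom2"].to_numpy(),
                                df["pos2"].to_numpy(np.int64), sites_by_chrom)
    near = (d1 <= flank) & (d2 <= flank)
    tally["re_distance"] = int((~near).sum())
    df = df[near].reset_index(drop=True)
    tally["kept"] = len(df)
    return df, tally


def assign_pairs_to_bins(pairs: pd.DataFrame, bins_by_chrom: dict):
    """Count valid intra-chromosomal pairs into sparse (chrom, i, j, count)
    triplets with i <= j; inter-chromosomal and unassignable pairs are tallied
    and dropped.
    """
    tally = {"inter_chromosomal": 0, "unassigned": 0, "assigned": 0}
    intra = pairs["chrom1"].to_numpy() == pairs["chrom2"].to_numpy()
    tally["inter_chromosomal"] = int((~intra).sum())
    df = pairs[intra]
    frames = []
    for chrom, grp in df.groupby("chrom1", sort=False):
        bins = bins_by_chrom.get(chrom)
        if bins is None:
            tally["unassigned"] += len(grp)
            continue
        starts = bins["start"].to_numpy()
        ends = bins["end"].to_numpy()
        ids = bins["bin_id"].to_numpy()
        b1 = np.searchsorted(starts, grp["pos1"].to_numpy(np.int64),
                             side="right") - 1
        b2 = np.searchsorted(starts, grp["pos2"].to_numpy(np.int64),
                             side="right") - 1
        ok = ((b1 >= 0) & (grp["pos1"].to_numpy() < ends[np.maximum(b1, 0)]) &
              (b2 >= 0) & (grp["pos2"].to_numpy() < ends[np.maximum(b2, 0)]))
        tally["unassigned"] += int((~ok).sum())
        b1, b2 = ids[b1[ok]], ids[b2[ok]]
        i = np.minimum(b1, b2)
        j = np.maximum(b1, b2)
        trip = (pd.DataFrame({"chrom": chrom, "i": i, "j": j})
                .groupby(["chrom", "i", "j"], as_index=False, sort=True)
                .size().rename(columns={"size": "count"}))
        frames.append(trip)
    tally["assigned"] = int(sum(f["count"].sum() for f in frames))
    if frames:
        triplets = pd.concat(frames, ignore_index=True)
    else:
        triplets = pd.DataFrame(columns=["chrom", "i", "j", "count"])
    return triplets, tally


def enumerate_interaction_bins(bins_by_chrom: dict, triplets: pd.DataFrame,
                               max_distance: float = MAX_DISTANCE,
                               include_diagonal: bool = True) -> pd.DataFrame:
    """Enumerate every intra-chromosomal bin pair within the distance cap.

    One record per pair (i, j), i <= j, with midpoint distance d <= cap
    (inclusive boundary) and i < j unless ``include_diagonal``; y is the
    triplet count or 0.  The output is sorted (chrom, i, j) and independent of
    triplet input order.
    """
    counts = {}
    for row in triplets.itertuples(index=False):
        counts[(row.chrom, int(row.i), int(row.j))] = \
            counts.get((row.chrom, int(row.i), int(row.j)), 0) + int(row.count)
    frames = []
    for chrom in sorted(bins_by_chrom):
        bins = bins_by_chrom[chrom]
        mids = bins["midpoint"].to_numpy()
        ids = bins["bin_id"].to_numpy()
        order = np.argsort(mids, kind="stable")
        mids, ids = mids[order], ids[order]
        ii, jj = [], []
        n = len(mids)
        hi = 0
        for a in range(n):
            lo = a if include_diagonal else a + 1
            if hi < lo:
                hi = lo
            while hi < n and mids[hi] - mids[a] <= max_distance:
                hi += 1
            ii.append(np.full(hi - lo, ids[a]))
            jj.append(ids[lo:hi])
        i = np.concatenate(ii) if ii else np.empty(0, np.int64)
        j = np.concatenate(jj) if jj else np.empty(0, np.int64)
        lo_id, hi_id = np.minimum(i, j), np.maximum(i, j)
        y = np.fromiter((counts.get((chrom, int(a), int(b)), 0)
                         for a, b in zip(lo_id, hi_id)),
                        dtype=np.int64, count=len(lo_id))
        mid_by_id = dict(zip(bins["bin_id"], bins["midpoint"]))
        d = np.abs(np.array([mid_by_id[b] for b in hi_id]) -
                   np.array([mid_by_id[a] for a in lo_id]))
        frames.append(pd.DataFrame({"chrom": chrom, "i": lo_id, "j": hi_id,
                                    "d": d, "y": y}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "i", "j", "d", "y"])
    out = pd.concat(frames, ignore_index=True)
    return (out.sort_values(["chrom", "i", "j"], kind="mergesort")
            .reset_index(drop=True))
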