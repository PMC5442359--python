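"""Analyses over called interactions.

Everything here consumes the scored record table (columns chrom/i/j/d/y plus
p/q from the null model) together with per-bin annotations:

* hotspot tracks — a 1D summary assigning each bin the maximum -log10 P over
  its significant long-range interactions;
* genomic / epigenomic bin labels and distance-stratified enrichment of
  labels among significant contacts (Fisher per 10 kb band, rank-sum pooling
  over longer windows);
* A/B compartment calls from the sign of the first principal component of the
  coarse-grained contact correlation matrix;
* downsampling of the contact matrix (without-replacement read resampling)
  and precision-recall evaluation of calls at reduced depth;
* extraction of the long-range promoter–promoter interaction network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

GENOMIC_LABELS = ("promoter", "gene_body", "distal_intergenic")


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

def hotspot_track(records: pd.DataFrame, fdr: float = 0.01,
                  min_distance: float = 50_000) -> pd.DataFrame:
    """Per-bin hotspot score: max -log10 p over incident records with
    q < fdr and d > min_distance; bins without any score 0."""
    sig = records[(records["q"] < fdr) & (records["d"] > min_distance)]
    scores: dict = {}
    for row in sig.itertuples(index=False):
        s = -np.log10(row.p)
        for b in (row.i, row.j):
            key = (row.chrom, b)
            if s > scores.get(key, -np.inf):
                scores[key] = s
    out = records.melt(id_vars=["chrom"], value_vars=["i", "j"],
                       value_name="bin_id")[["chrom", "bin_id"]]
    out = out.drop_duplicates().sort_values(["chrom", "bin_id"])
    out["score"] = [scores.get((c, b), 0.0)
                    for c, b in zip(out["chrom"], out["bin_id"])]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _overlaps_any(start, end, intervals) -> bool:
    return any(s < end and start < e for s, e in intervals)


def annotate_bins(bins: pd.DataFrame, peak_sets: dict | None = None,
                  tss=None, exons=None, introns=None,
                  promoter_flank: int = 2_000) -> pd.DataFrame:
    """Label each bin with epigenomic peak overlaps and one genomic class.

    Genomic precedence: promoter (within ``promoter_flank`` of a TSS) >
    exon > intron > distal intergenic, with exon/intron merged to gene_body.
    ``peak_sets`` maps name -> {chrom: [(start, end), ...]}; ``tss`` maps
    chrom -> positions; ``exons``/``introns`` map chrom -> interval lists.
    """
    peak_sets = peak_sets or {}
    out = bins[["chrom", "start", "end", "bin_id"]].copy()
    for name, by_chrom in peak_sets.items():
        out[name] = [
            _overlaps_any(s, e, by_chrom.get(c, ()))
            for c, s, e in zip(bins["chrom"], bins["start"], bins["end"])]
    labels = []
    for c, s, e in zip(bins["chrom"], bins["start"], bins["end"]):
        t = np.asarray((tss or {}).get(c, ()), dtype=float)
        # distance from interval [s, e) to a point: 0 if inside
        if t.size and np.min(np.maximum.reduce(
                [t - (e - 1), s - t, np.zeros_like(t)])) <= promoter_flank:
            labels.append("promoter")
        elif _overlaps_any(s, e, (exons or {}).get(c, ())):
            labels.append("gene_body")
        elif _overlaps_any(s, e, (introns or {}).get(c, ())):
            labels.append("gene_body")
        else:
            labels.append("distal_intergenic")
    out["genomic"] = labels
    return out


def contact_bears_pair(labels_i, labels_j, a: str, b: str) -> np.ndarray:
    """A contact bears the unordered label pair (a, b) if one endpoint bears
    a and the other bears b."""
    ai = np.asarray([a in s for s in labels_i])
    aj = np.asarray([a in s for s in labels_j])
    bi = np.asarray([b in s for s in labels_i])
    bj = np.asarray([b in s for s in labels_j])
    return (ai & bj) | (bi & aj)


# ---------------------------------------------------------------------------
# distance-band enrichment
# ---------------------------------------------------------------------------

def band_enrichment(records: pd.DataFrame, bin_labels: pd.DataFrame,
                    label_pairs, band: float = 10_000, fdr: float = 0.01,
                    max_d: float = 2_000_000, label_columns=None,
                    alternative: str = "greater") -> pd.DataFrame:
    """Per 10 kb distance band and label pair: the 2x2 significant-vs-label
    contingency table with its one-sided Fisher exact P and odds ratio.

    Self-ligating contacts (d = 0) are excluded.  ``bin_labels`` carries one
    row per bin; ``label_columns`` names its boolean columns (defaults to all
    bool columns) and the ``genomic`` column contributes its categories.
    """
    recs = records[(records["d"] > 0) & (records["d"] <= max_d)
                   & records["q"].notna()]
    if label_columns is None:
        label_columns = [c for c in bin_labels.columns
                         if bin_labels[c].dtype == bool]
    lab = bin_labels.set_index(["chrom", "bin_id"])
    sets_i, sets_j = [], []
    for row in recs.itertuples(index=False):
        li = lab.loc[(row.chrom, row.i)]
        lj = lab.loc[(row.chrom, row.j)]
        si = {c for c in label_columns if li[c]}
        sj = {c for c in label_columns if lj[c]}
        if "genomic" in lab.columns:
            si.add(li["genomic"])
            sj.add(lj["genomic"])
        sets_i.append(si or {"unannotated"})
        sets_j.append(sj or {"unannotated"})
    sig = (recs["q"] < fdr).to_numpy()
    d = recs["d"].to_numpy()
    edges = np.arange(0, max_d + band, band)
    band_idx = np.clip(np.searchsorted(edges, d, side="left") - 1, 0,
                       len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        in_band = band_idx == b
        for a, c in label_pairs:
            if not in_band.any():
                rows.append({"band_start": edges[b], "band_end": edges[b + 1],
                             "label_pair": f"{a}-{c}", "a": np.nan,
                             "b": np.nan, "c": np.nan, "d": np.nan,
                             "odds_ratio": np.nan, "fisher_p": np.nan})
                continue
            bears = contact_bears_pair(
                [s for s, m in zip(sets_i, in_band) if m],
                [s for s, m in zip(sets_j, in_band) if m], a, c)
            sb = sig[in_band]
            table = np.array([[int((sb & bears).sum()),
                               int((sb & ~bears).sum())],
                              [int((~sb & bears).sum()),
                               int((~sb & ~bears).sum())]])
            if table[0].sum() == 0 or table[1].sum() == 0 or \
                    table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
                orat, p = np.nan, np.nan
                if table.sum() > 0:   # degenerate margin: test undefined
                    p = 1.0
            else:
                orat, p = stats.fisher_exact(table, alternative=alternative)
            rows.append({"band_start": edges[b], "band_end": edges[b + 1],
                         "label_pair": f"{a}-{c}",
                         "a": table[0, 0], "b": table[0, 1],
                         "c": table[1, 0], "d": table[1, 1],
                         "odds_ratio": orat, "fisher_p": p})
    return pd.DataFrame(rows)


def pooled_enrichment(band_results: pd.DataFrame,
                      pool: float = 100_000) -> pd.DataFrame:
    """Pool band Fisher P values into contiguous windows and rank-sum test
    each label pair's P values against all other pairs' in the same pool
    (one-sided: smaller P = more enriched)."""
    res = band_results.dropna(subset=["fisher_p"]).copy()
    res["pool"] = (res["band_start"] // pool).astype(int)
    rows = []
    for (pl, pair), grp in res.groupby(["pool", "label_pair"]):
        others = res[(res["pool"] == pl) & (res["label_pair"] != pair)]
        if len(grp) < 2 or len(others) < 2:
            stat, p = np.nan, np.nan
        else:
            method = ("exact" if max(len(grp), len(others)) <= 10
                      else "asymptotic")
            r = stats.mannwhitneyu(grp["fisher_p"], others["fisher_p"],
                                   alternative="less", method=method)
            stat, p = float(r.statistic), float(r.pvalue)
        rows.append({"pool_start": pl * pool, "pool_end": (pl + 1) * pool,
                     "label_pair": pair, "statistic": stat, "ranksum_p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------

def call_compartments(records: pd.DataFrame, bins: pd.DataFrame,
                      metabin: float = 100_000,
                      openness: pd.Series | None = None) -> pd.DataFrame:
    """A/B compartment labels per 100 kb meta-bin from the sign of PC1 of the
    contact correlation matrix.

    Counts are aggregated into meta-bin pairs, the row-wise correlation matrix
    of the coarse matrix is formed (zero-variance rows labelled NA) and its
    leading eigenvector taken.  The sign group with the higher mean openness
    covariate (DNase peak density if given via ``openness``, else GC content)
    is labelled A (open).
    """
    frames = []
    for chrom, grp in records.groupby("chrom", sort=False):
        b = bins[bins["chrom"] == chrom]
        mb = dict(zip(b["bin_id"], (b["midpoint"] // metabin).astype(int)))
        mi = grp["i"].map(mb).to_numpy()
        mj = grp["j"].map(mb).to_numpy()
        n_meta = int(max(mi.max(), mj.max())) + 1
        if n_meta < 10:
            raise ValueError(f"chromosome {chrom}: fewer than 10 meta-bins")
        M = np.zeros((n_meta, n_meta))
        np.add.at(M, (mi, mj), grp["y"].to_numpy())
        np.add.at(M, (mj, mi), grp["y"].to_numpy())
        M[np.arange(n_meta), np.arange(n_meta)] /= 2  # diagonal added twice
        sd = M.std(axis=1)
        ok = sd > 0
        if ok.sum() < 2 or np.allclose(M[np.ix_(ok, ok)],
                                       M[np.ix_(ok, ok)].flat[0]):
            raise ValueError(f"chromosome {chrom}: constant contact matrix")
        C = np.corrcoef(M[np.ix_(ok, ok)])
        C = np.nan_to_num(C)
        w, v = np.linalg.eigh(C)
        pc1 = v[:, -1]
        labels = np.full(n_meta, "NA", dtype=object)
        pos = pc1 >= 0
        if openness is not None:
            open_cov = np.zeros(n_meta)
            cnt = np.zeros(n_meta)
            for bid, val in openness.items():
                if bid in mb and np.isfinite(val):
                    open_cov[mb[bid]] += val
                    cnt[mb[bid]] += 1
            open_cov = np.divide(open_cov, np.maximum(cnt, 1))
        else:
            open_cov = np.zeros(n_meta)
            cnt = np.zeros(n_meta)
            for bid, gc in zip(b["bin_id"], b.get("gc", pd.Series(0.5, index=b.index))):
                if np.isfinite(gc):
                    open_cov[mb[bid]] += gc
                    cnt[mb[bid]] += 1
            open_cov = np.divide(open_cov, np.maximum(cnt, 1))
        oc = open_cov[ok]
        mean_pos = oc[pos].mean() if pos.any() else -np.inf
        mean_neg = oc[~pos].mean() if (~pos).any() else -np.inf
        a_is_pos = mean_pos >= mean_neg
        lab_ok = np.where(pos == a_is_pos, "A", "B")
        labels[np.flatnonzero(ok)] = lab_ok
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "meta_start": np.arange(n_meta) * metabin,
            "meta_end": (np.arange(n_meta) + 1) * metabin,
            "compartment": labels,
            "pc1": [pc1[list(np.flatnonzero(ok)).index(k)] if ok[k] else np.nan
                    for k in range(n_meta)],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# downsampling + PR
# ---------------------------------------------------------------------------

def downsample_matrix(records: pd.DataFrame, fraction: float,
                      seed: int | None = None) -> pd.DataFrame:
    """Resample ``round(fraction * N)`` reads without replacement across all
    records (multivariate hypergeometric), preserving the total exactly.
    Equivalent to expanding counts to a read list and subsampling it."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    out = records.copy()
    y = out["y"].to_numpy(np.int64)
    total = int(y.sum())
    k = int(round(fraction * total))
    if fraction == 1.0 or total == 0:
        return out
    rng = np.random.default_rng(seed)
    out["y"] = rng.multivariate_hypergeometric(y, k, method="marginals")
    return out


def pr_evaluation(q_full, p_down, pos_thr: float = 0.05,
                  neg_thr: float = 0.1):
    """Precision-recall of downsampled calls against full-depth truth.

    Truth: positive where the full-depth adjusted P < ``pos_thr``, negative
    where > ``neg_thr``; the in-between stratum is excluded.  Score is
    -log10 of the downsampled P value; the curve sweeps all distinct scores
    and auPR is the trapezoid over the sorted sweep.

    Returns ``(curve: DataFrame[threshold, precision, recall], aupr)``.
    """
    q_full = np.asarray(q_full, float)
    p_down = np.asarray(p_down, float)
    keep = ((q_full < pos_thr) | (q_full > neg_thr)) \
        & np.isfinite(q_full) & np.isfinite(p_down)
    truth = q_full[keep] < pos_thr
    if truth.sum() == 0:
        raise ValueError("no positives in the truth set; auPR undefined")
    score = -np.log10(np.maximum(p_down[keep], np.finfo(float).tiny))
    order = np.argsort(-score, kind="mergesort")
    truth_sorted = truth[order]
    score_sorted = score[order]
    tp = np.cumsum(truth_sorted)
    npred = np.arange(1, len(truth_sorted) + 1)
    # evaluate at the last index of each distinct score
    last = np.flatnonzero(np.r_[np.diff(score_sorted) != 0, True])
    precision = tp[last] / npred[last]
    recall = tp[last] / truth.sum()
    curve = pd.DataFrame({"threshold": score_sorted[last],
                          "precision": precision, "recall": recall})
    rec = np.r_[0.0, recall]
    prec = np.r_[precision[0], precision]
    aupr = float(np.trapezoid(prec, rec))
    return curve, aupr


# ---------------------------------------------------------------------------
# long-range promoter network
# ---------------------------------------------------------------------------

def longrange_promoter_network(records: pd.DataFrame,
                               bin_labels: pd.DataFrame,
                               dmin: float = 1_500_000,
                               dmax: float = 2_000_000,
                               fdr: float = 0.01):
    """Significant long-range promoter–promoter interactions.

    Returns ``(per_chrom, edges, components)``: per-chromosome raw and
    per-Mb counts (length = covered extent of its bins), the bin–bin edge
    list, and connected components of the promoter interaction graph.
    """
    lab = bin_labels.set_index(["chrom", "bin_id"])["genomic"]
    sel = records[(records["q"] < fdr) & (records["d"] >= dmin)
                  & (records["d"] <= dmax)]
    keep = [lab.get((r.chrom, r.i)) == "promoter"
            and lab.get((r.chrom, r.j)) == "promoter"
            for r in sel.itertuples(index=False)]
    edges = sel[np.asarray(keep, bool)] if len(sel) else sel
    chrom_len = bin_labels.groupby("chrom")["end"].max() \
        if "end" in bin_labels.columns else None
    rows = []
    for chrom in records["chrom"].unique():
        n = int((edges["chrom"] == chrom).sum())
        length_mb = (chrom_len[chrom] / 1e6
                     if chrom_len is not None and chrom in chrom_len
                     else np.nan)
        rows.append({"chrom": chrom, "n_interactions": n,
                     "per_mb": n / length_mb if length_mb else np.nan})
    g = nx.Graph()
    g.add_edges_from(
        ((r.chrom, r.i), (r.chrom, r.j)) for r in edges.itertuples(index=False))
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=len, reverse=True)
    return pd.DataFrame(rows), edges.reset_index(drop=True), components
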