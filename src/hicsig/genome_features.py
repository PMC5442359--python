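"""Genome partitioning and per-bin bias covariates.

The genome is divided into interaction intervals ("bins") either by digesting
each chromosome at restriction-enzyme (RE) motif occurrences and merging runs
of contiguous fragments (default: ten fragments per bin, which for a 4-cutter
like MboI yields bins of a few kb), or by tiling with uniform fixed-width
windows.  For every bin we compute the covariates that enter the count
regression: GC content and mappability averaged over the *effective regions*
of the bin — the bases within a fixed flank (default 500 bp) of an RE site,
the only places a valid ligation-junction read can map — plus, for uniform
binning, the fraction of the bin that is effective ("effective sequence
space").

Coordinates are 0-based, half-open throughout (BED convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Built-in palindromic restriction motifs.
RESTRICTION_MOTIFS = {
    "MboI": "GATC",
    "DpnII": "GATC",
    "HindIII": "AAGCTT",
    "NcoI": "CCATGG",
}

DEFAULT_FLANK = 500

_VALID_BASES = set("ACGT")


def _is_palindromic(motif: str) -> bool:
    comp = str.maketrans("ACGT", "TGCA")
    return motif == motif.translate(comp)[::-1]


def resolve_motif(enzyme: str) -> str:
    """Translate an enzyme name or ``custom:MOTIF`` spec into a motif string."""
    if enzyme in RESTRICTION_MOTIFS:
        return RESTRICTION_MOTIFS[enzyme]
    if enzyme.startswith("custom:"):
        return enzyme.split(":", 1)[1].upper()
    raise ValueError(f"unknown enzyme {enzyme!r}; use one of "
                     f"{sorted(set(RESTRICTION_MOTIFS))} or custom:MOTIF")


def find_restriction_sites(sequence: str, motif: str) -> np.ndarray:
    """Return 0-based start positions of every exact forward-strand motif match.

    Only palindromic motifs are accepted: for a palindrome the forward-strand
    scan covers both strands, so a single pass suffices.  ``N`` bases in the
    sequence never match.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if not set(motif) <= _VALID_BASES:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if not _is_palindromic(motif):
        raise ValueError(f"motif {motif!r} is not palindromic; only "
                         "palindromic cutters are supported")
    seq = sequence.upper()
    out = []
    start = seq.find(motif)
    while start != -1:
        out.append(start)
        start = seq.find(motif, start + 1)  # overlapping matches allowed
    return np.asarray(out, dtype=np.int64)


def digest_to_fragments(chrom_length: int, sites) -> np.ndarray:
    """Cut ``[0, chrom_length)`` at each site, returning an (n, 2) array.

    Fragments are the consecutive disjoint intervals with RE sites as
    breakpoints; their concatenation tiles the chromosome exactly.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    sites = np.asarray(sites, dtype=np.int64)
    if sites.size and (np.any(np.diff(sites) < 0)
                       or sites[0] < 0 or sites[-1] >= chrom_length):
        raise ValueError("sites must be sorted and within [0, chrom_length)")
    breaks = np.concatenate(([0], sites[sites > 0], [chrom_length]))
    breaks = np.unique(breaks)
    return np.column_stack((breaks[:-1], breaks[1:]))


def merge_fragments(fragments: np.ndarray, n_per_bin: int = 10,
                    chrom: str = "chr") -> pd.DataFrame:
    """Merge runs of ``n_per_bin`` contiguous fragments into bins.

    The trailing remainder (< n_per_bin fragments) forms a final short bin.
    """
    if n_per_bin < 1:
        raise ValueError("n_per_bin must be >= 1")
    fragments = np.asarray(fragments)
    if fragments.ndim != 2 or fragments.shape[1] != 2:
        raise ValueError("fragments must be an (n, 2) array")
    if np.any(fragments[1:, 0] != fragments[:-1, 1]):
        raise ValueError("fragments must be contiguous and sorted")
    n = len(fragments)
    starts = fragments[::n_per_bin, 0]
    ends = np.append(fragments[n_per_bin - 1::n_per_bin, 1], fragments[-1, 1])
    ends = ends[: len(starts)]
    counts = np.full(len(starts), n_per_bin, dtype=np.int64)
    if n % n_per_bin:
        counts[-1] = n % n_per_bin
    return _bins_frame(chrom, starts, ends, counts)


def make_uniform_bins(chrom_length: int, width: int,
                      chrom: str = "chr") -> pd.DataFrame:
    """Tile ``[0, chrom_length)`` with fixed-width windows (last one truncated)."""
    if width < 1:
        raise ValueError("width must be >= 1")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    starts = np.arange(0, chrom_length, width, dtype=np.int64)
    ends = np.minimum(starts + width, chrom_length)
    return _bins_frame(chrom, starts, ends, np.zeros(len(starts), np.int64))


def _bins_frame(chrom, starts, ends, n_fragments) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": chrom,
        "start": np.asarray(starts, dtype=np.int64),
        "end": np.asarray(ends, dtype=np.int64),
        "bin_id": np.arange(len(starts), dtype=np.int64),
        "midpoint": (np.asarray(starts) + np.asarray(ends)) / 2.0,
        "n_fragments": n_fragments,
    })


def effective_regions(start: int, end: int, sites,
                      flank: int = DEFAULT_FLANK):
    """Union of ``[s - flank, s + flank)`` over RE sites inside ``[start, end)``,
    clipped to the bin.  Returns ``(intervals, fraction)``; fraction is the
    covered share of the bin length (0.0 when the bin has no site).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    sites = np.asarray(sites, dtype=np.int64)
    inside = sites[(sites >= start) & (sites < end)]
    if inside.size == 0:
        return [], 0.0
    lo = np.maximum(inside - flank, start)
    hi = np.minimum(inside + flank, end)
    merged = []
    cur_lo, cur_hi = int(lo[0]), int(hi[0])
    for a, b in zip(lo[1:], hi[1:]):
        if a <= cur_hi:
            cur_hi = max(cur_hi, int(b))
        else:
            merged.append((cur_lo, cur_hi))
            cur_lo, cur_hi = int(a), int(b)
    merged.append((cur_lo, cur_hi))
    covered = sum(b - a for a, b in merged)
    return merged, covered / (end - start)


def bin_features(bins: pd.DataFrame, sequence: str,
                 sites, mappability: np.ndarray | float = 1.0,
                 flank: int = DEFAULT_FLANK) -> pd.DataFrame:
    """Per-bin GC, mappability, effective fraction and has_site flags.

    GC is ``(#G + #C) / (#A + #C + #G + #T)`` over effective-region bases (N
    excluded from both numerator and denominator); mappability is the mean
    track value over the same bases.  Bins whose effective region is empty or
    entirely N get NaN features and are excluded from modelling downstream.

    ``mappability`` may be a scalar (constant track, default 1.0) or a
    per-base array covering the chromosome.
    """
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    is_g_or_c = (seq == b"G") | (seq == b"C")
    is_acgt = is_g_or_c | (seq == b"A") | (seq == b"T")
    if np.isscalar(mappability):
        map_track = None
        map_const = float(mappability)
    else:
        map_track = np.asarray(mappability, dtype=float)
        if map_track.size < len(seq):
            raise ValueError("mappability track shorter than sequence")
        if map_track.size and (map_track.min() < 0 or map_track.max() > 1):
            raise ValueError("mappability values must be in [0, 1]")
        map_const = None

    gc = np.full(len(bins), np.nan)
    mapp = np.full(len(bins), np.nan)
    eff = np.zeros(len(bins))
    has = np.zeros(len(bins), dtype=bool)
    for k, (s, e) in enumerate(zip(bins["start"], bins["end"])):
        regions, frac = effective_regions(int(s), int(e), sites, flank)
        eff[k] = frac
        if not regions:
            continue
        has[k] = True
        idx = np.concatenate([np.arange(a, b) for a, b in regions])
        n_real = int(is_acgt[idx].sum())
        if n_real == 0:
            continue  # effective region entirely N: undefined features
        gc[k] = is_g_or_c[idx].sum() / n_real
        if map_track is None:
            mapp[k] = map_const
        else:
            mapp[k] = map_track[idx].mean()
    out = bins.copy()
    out["gc"] = gc
    out["mappability"] = mapp
    out["effective_fraction"] = eff
    out["has_site"] = has
    return out


def pair_covariates(records: pd.DataFrame, features: pd.DataFrame,
                    uniform: bool = False) -> pd.DataFrame:
    """Attach standardized pair-level covariates to an interaction table.

    The raw pair feature is the product of the two bins' values (GC,
    mappability and — uniform mode — effective fraction), log-transformed and
    z-scored per chromosome over all non-excluded enumerated records, so the
    covariates do not depend on any later subsampling.  Records whose raw
    feature is zero or undefined are flagged ``excluded`` (log undefined) and
    receive no covariates.

    ``records`` needs columns chrom/i/j; ``features`` is indexed by bin_id per
    chromosome (output of :func:`bin_features`).
    """
    out = records.copy()
    n = len(out)
    for col in ("log_gc", "log_map") + (("log_eff",) if uniform else ()):
        out[col] = np.nan
    out["excluded"] = False
    stats: dict[str, dict[str, tuple[float, float]]] = {}
    for chrom, grp in out.groupby("chrom", sort=False):
        feat = features[features["chrom"] == chrom].set_index("bin_id")
        gi = feat["gc"].reindex(grp["i"]).to_numpy()
        gj = feat["gc"].reindex(grp["j"]).to_numpy()
        mi = feat["mappability"].reindex(grp["i"]).to_numpy()
        mj = feat["mappability"].reindex(grp["j"]).to_numpy()
        raw = {"log_gc": gi * gj, "log_map": mi * mj}
        if uniform:
            ei = feat["effective_fraction"].reindex(grp["i"]).to_numpy()
            ej = feat["effective_fraction"].reindex(grp["j"]).to_numpy()
            raw["log_eff"] = ei * ej
        bad = np.zeros(len(grp), dtype=bool)
        for v in raw.values():
            bad |= ~np.isfinite(v) | (v <= 0)
        chrom_stats = {}
        for col, v in raw.items():
            logv = np.where(bad, np.nan, np.log(np.where(bad, 1.0, v)))
            mean = float(np.nanmean(logv)) if (~bad).any() else 0.0
            sd = float(np.nanstd(logv)) if (~bad).any() else 1.0
            if sd == 0 or not np.isfinite(sd):
                sd = 1.0
            chrom_stats[col] = (mean, sd)
            out.loc[grp.index, col] = (logv - mean) / sd
        out.loc[grp.index, "excluded"] = bad
        stats[chrom] = chrom_stats
    rename = {"log_gc": "log_gc_z", "log_map": "log_map_z",
              "log_eff": "log_eff_z"}
    out = out.rename(columns=rename)
    out.attrs["standardization_stats"] = stats
    return out
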