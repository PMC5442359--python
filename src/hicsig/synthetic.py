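"""Synthetic Hi-C worlds with known ground truth.

The generator emulates what the null model assumes about real data: a toy
genome with restriction-site placement at a controllable density, a smoothly
varying GC landscape plus a blocky mappability track, and interaction-bin
counts drawn from the hurdle ZTNB law itself — zero with probability
``logistic(gamma . x)``, otherwise a zero-truncated NB draw with mean
``exp(beta . x)`` and dispersion ``alpha`` — on the same spline + bias
design the model fits.  A spike stage redraws a chosen subset of records at
``fold`` times their null mean to plant detectable true interactions.

Randomness: one scenario seed, with fixed substream offsets per stage
(0 genome, 1 counts, 2 spikes, 3 read-pair export), so each stage is
individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special, stats

from . import contacts, genome_features
from .hurdle_model import SplineSpec, design_matrix, _ALPHA_FLOOR

_STAGE_GENOME, _STAGE_COUNTS, _STAGE_SPIKES, _STAGE_PAIRS = 0, 1, 2, 3


def _stage_rng(seed, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2 ** 31), stage])


@dataclass
class SimulationScenario:
    """Stated world for the generator; defaults give ~50k interaction records
    on one 800 kb chromosome with MboI-density cutting and Hi-C-like decay."""

    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: {"chrS": 800_000})
    motif: str = "GATC"
    target_spacing: float = 256.0      # mean RE fragment length, bp (4-cutter)
    merge_n: int = 10                  # fragments per bin
    gc_base: float = 0.42
    gc_amplitude: float = 0.08
    gc_period: float = 50_000.0
    gc_noise_sd: float = 0.01          # per-kb block noise on the GC field
    map_base: float = 0.95
    map_n_dips: int = 4                # low-mappability blocks per 100 kb
    map_dip_len: int = 2_000
    map_dip_value: float = 0.4
    # truth: count part (6 spline + gc + map), log link
    beta: tuple = (3.4, 2.3, 1.4, 0.7, 0.1, -0.4, 0.25, 0.15)
    # truth: zero part (P(zero)), logit link — dropout grows with distance
    gamma: tuple = (-3.5, -2.5, -1.5, -0.5, 0.3, 0.8, -0.2, -0.1)
    alpha: float = 0.3
    spike_frac: float = 0.01
    spike_fold: float = 5.0
    spike_dmin: float = 50_000.0
    spike_dmax: float = 750_000.0
    max_distance: float = 750_000.0  # cap binds within the toy chromosome
    flank: int = 500

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("beta", "gamma"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

def _random_letters(rng, n, p_gc):
    """Draw n bases with per-base GC probability p_gc (array or scalar)."""
    u = rng.random(n)
    v = rng.random(n)
    gc = u < p_gc
    out = np.where(gc, np.where(v < 0.5, ord("G"), ord("C")),
                   np.where(v < 0.5, ord("A"), ord("T"))).astype(np.uint8)
    return out


def _scrub_motif(seq: np.ndarray, motif: str, intended: np.ndarray):
    """Mutate accidental motif occurrences so only intended sites remain."""
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    protected = np.zeros(len(seq), bool)
    for s in intended:
        protected[s:s + len(m)] = True
    repl = ord("C") if motif[1] != "C" else ord("A")
    for _ in range(20):
        s = seq.tobytes().decode("latin1")
        hits = []
        start = s.find(motif)
        while start != -1:
            hits.append(start)
            start = s.find(motif, start + 1)
        bad = [h for h in hits if h not in set(intended.tolist())]
        if not bad:
            break
        for h in bad:
            for off in range(len(m)):
                if not protected[h + off]:
                    seq[h + off] = repl
                    break
    return seq


def make_toy_genome(scenario: SimulationScenario):
    """Generate sequences and mappability tracks; deterministic per seed.

    Fragment lengths are exponential around ``target_spacing`` and the motif
    is implanted at each junction, with accidental occurrences scrubbed, so
    the realized RE density is controlled exactly by the spacing parameter.

    Returns ``{chrom: {"sequence": str, "mappability": np.ndarray,
    "sites": np.ndarray}}``.
    """
    rng = _stage_rng(scenario.seed, _STAGE_GENOME)
    mlen = len(scenario.motif)
    genome = {}
    for chrom, size in scenario.chrom_sizes.items():
        if size < 100_000:
            raise ValueError("chromosome sizes must be >= 100 kb")
        # GC field: sinusoid + per-kb noise
        x = np.arange(size)
        p_gc = (scenario.gc_base
                + scenario.gc_amplitude
                * np.sin(2 * np.pi * x / scenario.gc_period))
        n_blocks = size // 1000 + 1
        noise = np.repeat(rng.normal(0, scenario.gc_noise_sd, n_blocks),
                          1000)[:size]
        p_gc = np.clip(p_gc + noise, 0.05, 0.95)

        # restriction-site placement via exponential fragment lengths
        mean_body = max(scenario.target_spacing - mlen, 1.0)
        sites = []
        pos = 0
        while True:
            body = int(rng.exponential(mean_body)) + 1
            if pos + body + mlen >= size:
                break
            pos += body
            sites.append(pos)
            pos += mlen
        sites = np.asarray(sites, dtype=np.int64)

        seq = _random_letters(rng, size, p_gc)
        for s in sites:
            seq[s:s + mlen] = np.frombuffer(scenario.motif.encode(),
                                            dtype=np.uint8)
        seq = _scrub_motif(seq, scenario.motif, sites)

        # mappability: high baseline with low blocks
        mapp = np.full(size, scenario.map_base)
        n_dips = int(scenario.map_n_dips * size / 100_000)
        for start in rng.integers(0, max(size - scenario.map_dip_len, 1),
                                  n_dips):
            mapp[start:start + scenario.map_dip_len] = scenario.map_dip_value
        genome[chrom] = {"sequence": seq.tobytes().decode("latin1"),
                         "mappability": mapp, "sites": sites}
    return genome


# ---------------------------------------------------------------------------
# records with covariates, then counts
# ---------------------------------------------------------------------------

def build_scenario_records(scenario: SimulationScenario, genome=None):
    """Genome -> bins -> covariates -> zero-count enumerated records.

    Returns ``(records, bins_with_features, spec)`` where ``spec`` holds the
    truth spline knots (25/50/75% quantiles of the enumerated distances)."""
    if genome is None:
        genome = make_toy_genome(scenario)
    bins_by_chrom = {}
    feats = []
    for chrom, g in genome.items():
        frags = genome_features.digest_to_fragments(len(g["sequence"]),
                                                    g["sites"])
        bins = genome_features.merge_fragments(frags, scenario.merge_n,
                                               chrom=chrom)
        bf = genome_features.bin_features(bins, g["sequence"], g["sites"],
                                          mappability=g["mappability"],
                                          flank=scenario.flank)
        bins_by_chrom[chrom] = bf
        feats.append(bf)
    features = pd.concat(feats, ignore_index=True)
    empty = pd.DataFrame(columns=["chrom", "i", "j", "count"])
    records = contacts.enumerate_interaction_bins(
        bins_by_chrom, empty, max_distance=scenario.max_distance)
    records = genome_features.pair_covariates(records, features)
    spec = SplineSpec.from_distances(
        records.loc[~records["excluded"], "d"],
        boundary=(0.0, float(scenario.max_distance)))
    return records, features, spec


def _draw_ztnb(rng, mu, alpha):
    """Zero-truncated NB draws via inverse CDF on u ~ U(P(0), 1)."""
    mu = np.asarray(mu, float)
    u = rng.random(mu.shape)
    if alpha < _ALPHA_FLOOR:
        p0 = np.exp(-mu)
        y = stats.poisson.ppf(p0 + (1 - p0) * u, mu)
    else:
        r = 1.0 / alpha
        p = r / (r + mu)
        p0 = np.exp(r * np.log(p))
        y = stats.nbinom.ppf(p0 + (1 - p0) * u, r, p)
    return np.maximum(y, 1).astype(np.int64)


def simulate_null_counts(records: pd.DataFrame, scenario: SimulationScenario,
                         spec: SplineSpec, seed=None) -> pd.DataFrame:
    """Draw y for every non-excluded record from the truth hurdle law."""
    rng = _stage_rng(scenario.seed if seed is None else seed, _STAGE_COUNTS)
    out = records.copy()
    ok = ~out["excluded"].to_numpy()
    sub = out[ok]
    X, _ = design_matrix(sub, spec)
    with np.errstate(invalid="ignore"):
        eta = X @ np.asarray(scenario.beta)
        zeta = X @ np.asarray(scenario.gamma)
    if not (np.all(np.isfinite(eta)) and np.all(np.isfinite(zeta))):
        raise ValueError("non-finite linear predictor; check scenario truth")
    mu = np.exp(np.clip(eta, -30, 30))
    pi0 = special.expit(zeta)
    is_zero = rng.random(len(sub)) < pi0
    y = np.zeros(len(sub), dtype=np.int64)
    y[~is_zero] = _draw_ztnb(rng, mu[~is_zero], scenario.alpha)
    out.loc[ok, "y"] = y
    out["true_mu"] = np.nan
    out["true_pi0"] = np.nan
    out.loc[ok, "true_mu"] = mu
    out.loc[ok, "true_pi0"] = pi0
    return out


def spike_interactions(records: pd.DataFrame, scenario: SimulationScenario,
                       seed=None):
    """Redraw a seeded subset of eligible records from the hurdle law with
    count mean boosted to ``fold * mu`` (same dropout gate pi0, so fold = 1
    leaves the distribution unchanged).  Returns the spiked table and the
    truth labels."""
    if scenario.spike_fold < 1:
        raise ValueError("spike fold must be >= 1")
    rng = _stage_rng(scenario.seed if seed is None else seed, _STAGE_SPIKES)
    out = records.copy()
    eligible = np.flatnonzero(
        (~out["excluded"]).to_numpy()
        & (out["d"].to_numpy() >= scenario.spike_dmin)
        & (out["d"].to_numpy() <= scenario.spike_dmax))
    n_spikes = int(round(scenario.spike_frac * len(eligible)))
    if n_spikes > len(eligible):
        raise ValueError("more spikes requested than eligible records")
    chosen = rng.choice(eligible, size=n_spikes, replace=False)
    chosen.sort()
    mu = out["true_mu"].to_numpy()[chosen] * scenario.spike_fold
    pi0 = out["true_pi0"].to_numpy()[chosen]
    y = np.zeros(len(chosen), dtype=np.int64)
    pos = rng.random(len(chosen)) >= pi0
    y[pos] = _draw_ztnb(rng, mu[pos], scenario.alpha)
    out.loc[out.index[chosen], "y"] = y
    out["is_spike"] = False
    out.loc[out.index[chosen], "is_spike"] = True
    truth = out.iloc[chosen][["chrom", "i", "j", "d", "y"]].reset_index(
        drop=True)
    return out, truth


def simulate_scenario(scenario: SimulationScenario, spikes: bool = False):
    """End-to-end convenience: toy genome -> covariates -> counts (-> spikes).

    Returns a dict with genome, bins-with-features, records (y filled),
    truth spline spec and, when spiked, the truth label table."""
    genome = make_toy_genome(scenario)
    records, features, spec = build_scenario_records(scenario, genome)
    records = simulate_null_counts(records, scenario, spec)
    truth = None
    if spikes:
        records, truth = spike_interactions(records, scenario)
    return {"genome": genome, "features": features, "records": records,
            "spec": spec, "truth": truth, "scenario": scenario}


def records_to_pairs(records: pd.DataFrame, features: pd.DataFrame,
                     genome: dict, scenario: SimulationScenario,
                     seed=None) -> pd.DataFrame:
    """Expand counts into plausible read pairs (for exercising the counting
    pipeline): each read end lands within the flank of a random RE site
    inside its bin, so the standard filters keep it."""
    rng = _stage_rng(scenario.seed if seed is None else seed, _STAGE_PAIRS)
    coords = features.set_index(["chrom", "bin_id"])[["start", "end"]]
    rows = []
    for r in records[records["y"] > 0].itertuples(index=False):
        sites = genome[r.chrom]["sites"]
        size = len(genome[r.chrom]["sequence"])
        si = _bin_sites(sites, coords.loc[(r.chrom, r.i)])
        sj = _bin_sites(sites, coords.loc[(r.chrom, r.j)])
        if si.size == 0 or sj.size == 0:
            continue
        for _ in range(int(r.y)):
            p1 = int(rng.choice(si)) + int(rng.integers(-scenario.flank + 1,
                                                        scenario.flank))
            p2 = int(rng.choice(sj)) + int(rng.integers(-scenario.flank + 1,
                                                        scenario.flank))
            rows.append((r.chrom, int(np.clip(p1, 0, size - 1)),
                         "+" if rng.random() < 0.5 else "-",
                         r.chrom, int(np.clip(p2, 0, size - 1)),
                         "+" if rng.random() < 0.5 else "-"))
    return pd.DataFrame(rows, columns=contacts.PAIR_COLUMNS)


def _bin_sites(sites: np.ndarray, coord) -> np.ndarray:
    s, e = int(coord["start"]), int(coord["end"])
    return sites[(sites >= s) & (sites < e)]
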