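"""End-to-end orchestration: genome -> bins -> counts -> null model -> calls.

``run_call`` executes the whole calling pipeline from a :class:`RunConfig`
and writes the output bundle (bin table, record table, per-chromosome fit
JSONs, significant BEDPE, hotspot bedGraph and a machine-readable run
summary).  ``run_enrich`` drives the downstream annotation/enrichment/
compartment/network analyses over an already-called record table.  A failure
on one chromosome is logged and skipped; it does not abort the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import contacts, downstream, genome_features, hurdle_model, io

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or missing configuration / input paths (exit code 2)."""


class DataError(ValueError):
    """Inputs parsed but unusable (exit code 3)."""


class ConvergenceError(RuntimeError):
    """No chromosome produced a converged fit (exit code 4)."""


@dataclass
class RunConfig:
    fasta: str | None = None
    mappability: str | None = None
    pairs: str | None = None
    triplets: str | None = None
    enzyme: str = "MboI"
    uniform_width: int | None = None   # None -> merge-N fragment bins
    merge_n: int = 10
    flank: int = 500
    max_distance: float = 2_000_000.0
    sample_frac: float = 0.01
    outlier_q: float = 0.975
    fdr: float = 0.01
    seed: int = 0
    include_diagonal: bool = True
    per_chromosome_fdr: bool = False
    out_prefix: str = "hicsig"

    def validate(self) -> None:
        if self.fasta is None:
            raise ConfigError("a FASTA path is required")
        if self.pairs is None and self.triplets is None:
            raise ConfigError("either a pairs or a triplets file is required")
        for name in ("fasta", "mappability", "pairs", "triplets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input {name} not found: {p}")
        if not (0 < self.sample_frac <= 1):
            raise ConfigError("sample_frac must be in (0, 1]")
        if not (0.5 < self.outlier_q < 1):
            raise ConfigError("outlier_q must be in (0.5, 1)")
        if not (0 < self.fdr < 1):
            raise ConfigError("fdr must be in (0, 1)")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def prepare_bins(config: RunConfig):
    """FASTA (+ mappability) -> per-chromosome bins with features and sites."""
    sequences = io.read_fasta(config.fasta)
    chrom_sizes = {c: len(s) for c, s in sequences.items()}
    if config.mappability:
        tracks = io.read_bedgraph_track(config.mappability, chrom_sizes,
                                        default=1.0)
    else:
        tracks = {c: 1.0 for c in chrom_sizes}
    motif = genome_features.resolve_motif(config.enzyme)
    bins_by_chrom, sites_by_chrom = {}, {}
    for chrom, seq in sequences.items():
        sites = genome_features.find_restriction_sites(seq, motif)
        sites_by_chrom[chrom] = sites
        if config.uniform_width:
            bins = genome_features.make_uniform_bins(
                len(seq), config.uniform_width, chrom=chrom)
        else:
            frags = genome_features.digest_to_fragments(len(seq), sites)
            bins = genome_features.merge_fragments(frags, config.merge_n,
                                                   chrom=chrom)
        bins_by_chrom[chrom] = genome_features.bin_features(
            bins, seq, sites, mappability=tracks[chrom], flank=config.flank)
    return bins_by_chrom, sites_by_chrom


def run_call(config: RunConfig) -> dict:
    """Execute the calling pipeline; returns a summary dict (also written to
    ``<prefix>.summary.json``).  Deterministic for a fixed config + seed."""
    config.validate()
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    bins_by_chrom, sites_by_chrom = prepare_bins(config)
    features = pd.concat(bins_by_chrom.values(), ignore_index=True)

    tallies = {}
    if config.triplets:
        triplets = io.read_triplets_tsv(config.triplets)
    else:
        pairs = contacts.read_pairs_tsv(config.pairs)
        valid, filter_tally = contacts.filter_pairs(
            pairs, sites_by_chrom, flank=config.flank)
        triplets, assign_tally = contacts.assign_pairs_to_bins(
            valid, bins_by_chrom)
        tallies = {"filter": filter_tally, "assign": assign_tally}

    records = contacts.enumerate_interaction_bins(
        bins_by_chrom, triplets, max_distance=config.max_distance,
        include_diagonal=config.include_diagonal)
    records = genome_features.pair_covariates(
        records, features, uniform=bool(config.uniform_width))

    scored_frames, fits, failures = [], {}, {}
    for chrom, grp in records.groupby("chrom", sort=True):
        grp = grp.copy()
        grp.attrs = records.attrs
        try:
            fit = hurdle_model.estimate_null(
                grp, sample_frac=config.sample_frac,
                outlier_q=config.outlier_q, seed=config.seed,
                uniform=bool(config.uniform_width),
                max_distance=config.max_distance)
            fits[chrom] = fit
            scored_frames.append(hurdle_model.score_records(grp, fit))
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("chromosome %s skipped: %s", chrom, exc)
            failures[chrom] = str(exc)
    if not fits:
        raise ConvergenceError("no chromosome could be fit: "
                               + "; ".join(f"{c}: {m}"
                                           for c, m in failures.items()))
    scored = pd.concat(scored_frames, ignore_index=True)
    scored = hurdle_model.call_significant(
        scored, fdr=config.fdr, per_chromosome=config.per_chromosome_fdr)

    io.write_bins_tsv(f"{prefix}.bins.tsv", features)
    io.write_records_tsv(f"{prefix}.records.tsv", scored, bins=features)
    for chrom, fit in fits.items():
        fit.to_json(f"{prefix}.fit.{chrom}.json")
    sig = scored[scored["significant"].fillna(False)]
    io.write_bedpe(f"{prefix}.significant.bedpe", sig, features)
    track = downstream.hotspot_track(scored, fdr=config.fdr)
    coords = features.set_index(["chrom", "bin_id"])[["start", "end"]]
    hs = track.join(coords, on=["chrom", "bin_id"])
    io.write_bedgraph(f"{prefix}.hotspots.bedgraph",
                      hs[["chrom", "start", "end", "score"]])
    config.to_json(f"{prefix}.config.json")

    summary = {
        "config": asdict(config),
        "tallies": tallies,
        "n_records": int(len(scored)),
        "n_significant": int(sig.shape[0]),
        "chromosomes": {
            c: {"converged": bool(f.converged), "alpha": f.alpha,
                "n_outliers_removed": f.n_outliers_removed}
            for c, f in fits.items()},
        "failures": failures,
    }
    with open(f"{prefix}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def run_enrich(records: pd.DataFrame, features: pd.DataFrame,
               out_prefix: str, peak_sets: dict | None = None,
               tss: dict | None = None, exons: dict | None = None,
               introns: dict | None = None, fdr: float = 0.01,
               band: float = 10_000, pool: float = 100_000,
               metabin: float = 100_000) -> dict:
    """Downstream bundle: enrichment tables, compartment BED, network BEDPE.

    Analyses whose inputs are missing are skipped with a warning; genomic
    enrichment always runs (labels default to distal_intergenic)."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    produced = {}
    labels = downstream.annotate_bins(features, peak_sets=peak_sets,
                                      tss=tss, exons=exons, introns=introns)
    labels.to_csv(f"{prefix}.labels.tsv", sep="\t", index=False)

    genomic_pairs = [(a, b) for k, a in enumerate(downstream.GENOMIC_LABELS)
                     for b in downstream.GENOMIC_LABELS[k:]]
    bands = downstream.band_enrichment(records, labels, genomic_pairs,
                                       band=band, fdr=fdr)
    bands.to_csv(f"{prefix}.enrichment.genomic.tsv", sep="\t", index=False)
    pooled = downstream.pooled_enrichment(bands, pool=pool)
    pooled.to_csv(f"{prefix}.enrichment.genomic.pooled.tsv", sep="\t",
                  index=False)
    produced["genomic_enrichment"] = True

    if peak_sets:
        names = sorted(peak_sets)
        epi_pairs = [(a, b) for k, a in enumerate(names) for b in names[k:]]
        ebands = downstream.band_enrichment(records, labels, epi_pairs,
                                            band=band, fdr=fdr)
        ebands.to_csv(f"{prefix}.enrichment.epigenomic.tsv", sep="\t",
                      index=False)
        downstream.pooled_enrichment(ebands, pool=pool).to_csv(
            f"{prefix}.enrichment.epigenomic.pooled.tsv", sep="\t",
            index=False)
        produced["epigenomic_enrichment"] = True
    else:
        logger.warning("no peak files supplied; epigenomic enrichment skipped")
        produced["epigenomic_enrichment"] = False

    try:
        comp = downstream.call_compartments(records, features,
                                            metabin=metabin)
        comp.to_csv(f"{prefix}.compartments.bed", sep="\t", index=False,
                    header=False)
        produced["compartments"] = True
    except ValueError as exc:
        logger.warning("compartment analysis skipped: %s", exc)
        produced["compartments"] = False

    per_chrom, edges, comps = downstream.longrange_promoter_network(
        records, labels, fdr=fdr)
    per_chrom.to_csv(f"{prefix}.promoter_network.counts.tsv", sep="\t",
                     index=False)
    io.write_bedpe(f"{prefix}.promoter_network.bedpe", edges, features)
    produced["promoter_network"] = True
    return produced
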