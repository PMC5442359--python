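"""Hotspots, annotation, enrichment, compartments, downsampling, PR, network."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hicsig import downstream as ds
from hicsig import genome_features as gf


def make_records(rows):
    df = pd.DataFrame(rows, columns=["chrom", "i", "j", "d", "y", "p", "q"])
    return df


class TestHotspot:
    def test_single_significant_record(self):
        rec = make_records([
            ("c", 4, 9, 60_000.0, 10, 1e-6, 0.001),
            ("c", 1, 2, 60_000.0, 1, 0.5, 0.9),
        ])
        track = ds.hotspot_track(rec, fdr=0.01, min_distance=50_000)
        scores = dict(zip(track["bin_id"], track["score"]))
        assert scores[4] == pytest.approx(6.0)
        assert scores[9] == pytest.approx(6.0)
        assert scores[1] == 0.0 and scores[2] == 0.0

    def test_distance_filter(self):
        rec = make_records([("c", 4, 9, 40_000.0, 10, 1e-6, 0.001)])
        track = ds.hotspot_track(rec, fdr=0.01, min_distance=50_000)
        assert (track["score"] == 0).all()

    def test_matches_double_loop_oracle(self, rng):
        rows = []
        for _ in range(400):
            i, j = sorted(rng.integers(0, 40, 2))
            p = 10.0 ** -rng.uniform(0, 8)
            rows.append(("c", i, j, float(rng.integers(1, 200) * 1_000),
                         1, p, p * rng.uniform(1, 3)))
        rec = make_records(rows)
        track = ds.hotspot_track(rec, fdr=0.05, min_distance=50_000)
        got = dict(zip(track["bin_id"], track["score"]))
        for b in got:
            best = 0.0
            for r in rec.itertuples():
                if b in (r.i, r.j) and r.q < 0.05 and r.d > 50_000:
                    best = max(best, -math.log10(r.p))
            assert got[b] == pytest.approx(best)


class TestAnnotateBins:
    BINS = pd.DataFrame({
        "chrom": "c", "start": [0, 10_000, 20_000, 30_000],
        "end": [10_000, 15_000, 30_000, 40_000], "bin_id": [0, 1, 2, 3]})

    def test_promoter_within_2kb(self):
        lab = ds.annotate_bins(self.BINS, tss={"c": [16_500]})
        assert lab.loc[1, "genomic"] == "promoter"  # 1.5 kb downstream
        assert lab.loc[3, "genomic"] == "distal_intergenic"

    def test_exon_intron_merge_to_gene_body(self):
        lab = ds.annotate_bins(self.BINS,
                               exons={"c": [(21_000, 22_000)]},
                               introns={"c": [(33_000, 35_000)]})
        assert lab.loc[2, "genomic"] == "gene_body"
        assert lab.loc[3, "genomic"] == "gene_body"

    def test_promoter_precedence_over_exon(self):
        lab = ds.annotate_bins(self.BINS, tss={"c": [21_000]},
                               exons={"c": [(21_000, 22_000)]})
        assert lab.loc[2, "genomic"] == "promoter"

    def test_peak_overlap_flags(self):
        lab = ds.annotate_bins(self.BINS,
                               peak_sets={"CTCF": {"c": [(9_900, 10_050)]}})
        assert lab["CTCF"].tolist() == [True, True, False, False]

    def test_matches_nested_loop_oracle(self, rng):
        n = 500
        starts = np.sort(rng.integers(0, 1_000_000, n))
        bins = pd.DataFrame({"chrom": "c", "start": starts,
                             "end": starts + rng.integers(500, 5_000, n),
                             "bin_id": np.arange(n)})
        tss = np.sort(rng.integers(0, 1_000_000, 60))
        exons = [(s, s + 800) for s in rng.integers(0, 1_000_000, 80)]
        introns = [(s, s + 3_000) for s in rng.integers(0, 1_000_000, 80)]
        lab = ds.annotate_bins(bins, tss={"c": tss}, exons={"c": exons},
                               introns={"c": introns})
        for k in range(n):
            s, e = bins.loc[k, "start"], bins.loc[k, "end"]
            if min(abs(int(t) - (e - 1)) if t >= e
                   else (s - int(t) if t < s else 0) for t in tss) <= 2_000:
                want = "promoter"
            elif any(a < e and s < b for a, b in exons):
                want = "gene_body"
            elif any(a < e and s < b for a, b in introns):
                want = "gene_body"
            else:
                want = "distal_intergenic"
            assert lab.loc[k, "genomic"] == want


def fisher_greater_oracle(a, b, c, d):
    """One-sided (enrichment) Fisher P by direct hypergeometric summation."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        p += (math.comb(col1, k) * math.comb(n - col1, row1 - k)
              / math.comb(n, row1))
    return p


class TestBandEnrichment:
    def _world(self, rng, n=600):
        labels = pd.DataFrame({
            "chrom": "c", "bin_id": np.arange(50),
            "start": np.arange(50) * 10_000,
            "end": (np.arange(50) + 1) * 10_000,
            "CTCF": rng.random(50) < 0.3,
            "genomic": rng.choice(ds.GENOMIC_LABELS, 50)})
        rows = []
        for _ in range(n):
            i, j = sorted(rng.integers(0, 50, 2))
            q = rng.uniform(0, 1) ** 2
            rows.append(("c", i, j, float(abs(j - i)) * 10_000, 1,
                         q / 2, q))
        rec = make_records(rows)
        return rec[rec["d"] > 0].reset_index(drop=True), labels

    def test_fisher_matches_hypergeometric_oracle(self, rng):
        rec, labels = self._world(rng)
        res = ds.band_enrichment(rec, labels, [("CTCF", "CTCF")],
                                 band=100_000, fdr=0.2, max_d=500_000)
        checked = 0
        for r in res.dropna(subset=["fisher_p"]).itertuples():
            want = fisher_greater_oracle(int(r.a), int(r.b), int(r.c),
                                         int(r.d))
            assert r.fisher_p == pytest.approx(want, rel=1e-9)
            checked += 1
        assert checked >= 3

    def test_degenerate_margin(self):
        labels = pd.DataFrame({
            "chrom": "c", "bin_id": [0, 1], "start": [0, 10_000],
            "end": [10_000, 20_000], "CTCF": [True, True],
            "genomic": ["promoter", "promoter"]})
        rec = make_records([("c", 0, 1, 10_000.0, 3, 0.001, 0.005),
                            ("c", 0, 1, 10_000.0, 1, 0.5, 0.7)])
        res = ds.band_enrichment(rec, labels, [("CTCF", "CTCF")],
                                 band=20_000, fdr=0.01, max_d=20_000)
        row = res.dropna(subset=["fisher_p"]).iloc[0]
        assert np.isnan(row["odds_ratio"])  # label on every contact

    def test_shuffled_labels_calibrated(self, rng):
        # under label shuffling ~5% of bands reach p < 0.05
        hits, total = 0, 0
        for rep in range(30):
            rec, labels = self._world(rng, n=500)
            labels["CTCF"] = rng.permutation(labels["CTCF"].to_numpy())
            res = ds.band_enrichment(rec, labels, [("CTCF", "CTCF")],
                                     band=50_000, fdr=0.2, max_d=500_000)
            ok = res.dropna(subset=["fisher_p"])
            hits += (ok["fisher_p"] < 0.05).sum()
            total += len(ok)
        rate = hits / total
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / total) + 0.02


def ranksum_less_oracle(x, y):
    """Exact one-sided rank-sum by full enumeration.

    Alternative "x stochastically smaller than y" is supported by a LARGE
    number of (a, b) pairs with a < b, so the p-value is the fraction of
    equally likely group assignments at least that extreme."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a < b)
    u_obs = u_stat(x, y)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[k] for k in comb]
        ys = [pooled[k] for k in range(len(pooled)) if k not in comb]
        if u_stat(xs, ys) >= u_obs:
            count += 1
        total += 1
    return count / total


class TestPooledEnrichment:
    def _bands(self, focal, others):
        rows = []
        for k, p in enumerate(focal):
            rows.append({"band_start": k * 10_000, "band_end": (k + 1) * 10_000,
                         "label_pair": "A-A", "fisher_p": p})
        for k, p in enumerate(others):
            rows.append({"band_start": k * 10_000, "band_end": (k + 1) * 10_000,
                         "label_pair": "B-B", "fisher_p": p})
        return pd.DataFrame(rows)

    def test_extreme_ranking_minimal_p(self):
        focal = [0.001, 0.002, 0.003, 0.004, 0.005]
        others = [0.5, 0.6, 0.7, 0.8, 0.9]
        res = ds.pooled_enrichment(self._bands(focal, others), pool=100_000)
        p = res.loc[res["label_pair"] == "A-A", "ranksum_p"].iloc[0]
        assert p == pytest.approx(1 / math.comb(10, 5), rel=1e-9)

    def test_identical_groups_not_significant(self):
        res = ds.pooled_enrichment(self._bands([0.3] * 5, [0.3] * 5),
                                   pool=100_000)
        p = res.loc[res["label_pair"] == "A-A", "ranksum_p"].iloc[0]
        assert p >= 0.4

    def test_matches_exact_enumeration(self, rng):
        for _ in range(5):
            focal = rng.uniform(0, 1, 6).round(6).tolist()
            others = rng.uniform(0, 1, 7).round(6).tolist()
            res = ds.pooled_enrichment(self._bands(focal, others),
                                       pool=100_000)
            p = res.loc[res["label_pair"] == "A-A", "ranksum_p"].iloc[0]
            assert p == pytest.approx(ranksum_less_oracle(focal, others),
                                      rel=1e-9)

    def test_too_few_bands(self):
        res = ds.pooled_enrichment(self._bands([0.1], [0.5]), pool=100_000)
        assert res["ranksum_p"].isna().all()


class TestCompartments:
    def _planted(self, rng, n_meta=30, ratio=3.0, noise=True):
        width = 100_000
        bins = pd.DataFrame({
            "chrom": "c", "bin_id": np.arange(n_meta),
            "start": np.arange(n_meta) * width,
            "end": (np.arange(n_meta) + 1) * width,
            "midpoint": (np.arange(n_meta) + 0.5) * width,
            "gc": np.where(np.arange(n_meta) % 2 == 0, 0.6, 0.4)})
        block = np.arange(n_meta) % 2  # alternating planted blocks
        rows = []
        for i in range(n_meta):
            for j in range(i, n_meta):
                base = 60.0 if block[i] == block[j] else 60.0 / ratio
                y = rng.poisson(base) if noise else base
                rows.append(("c", i, j, float((j - i) * width), y))
        rec = pd.DataFrame(rows, columns=["chrom", "i", "j", "d", "y"])
        return rec, bins, block

    def test_recovers_planted_blocks(self, rng):
        rec, bins, block = self._planted(rng)
        comp = ds.call_compartments(rec, bins, metabin=100_000)
        want = np.where(block == 0, "A", "B")  # block 0 carries higher GC
        assert comp["compartment"].tolist() == want.tolist()

    def test_orientation_rule_fixes_pc1_sign(self, rng):
        # openness covariate decides which sign group is "A"
        rec, bins, block = self._planted(rng)
        openness = pd.Series(np.where(block == 1, 5.0, 0.0),
                             index=bins["bin_id"])
        comp = ds.call_compartments(rec, bins, metabin=100_000,
                                    openness=openness)
        want = np.where(block == 1, "A", "B")
        assert comp["compartment"].tolist() == want.tolist()

    def test_metabin_order_invariance(self, rng):
        rec, bins, block = self._planted(rng)
        perm = rng.permutation(len(rec))
        comp1 = ds.call_compartments(rec, bins, metabin=100_000)
        comp2 = ds.call_compartments(rec.iloc[perm].reset_index(drop=True),
                                     bins, metabin=100_000)
        assert comp1["compartment"].tolist() == comp2["compartment"].tolist()

    def test_constant_matrix_raises(self):
        n = 12
        bins = pd.DataFrame({
            "chrom": "c", "bin_id": np.arange(n),
            "start": np.arange(n) * 100_000,
            "end": (np.arange(n) + 1) * 100_000,
            "midpoint": (np.arange(n) + 0.5) * 100_000, "gc": 0.5})
        rows = [("c", i, j, float((j - i) * 100_000), 5)
                for i in range(n) for j in range(i, n)]
        rec = pd.DataFrame(rows, columns=["chrom", "i", "j", "d", "y"])
        with pytest.raises(ValueError):
            ds.call_compartments(rec, bins, metabin=100_000)


class TestDownsample:
    def _records(self, y):
        return pd.DataFrame({"chrom": "c", "i": np.arange(len(y)),
                             "j": np.arange(len(y)) + 1,
                             "d": 10_000.0, "y": y})

    def test_identity_at_full_fraction(self):
        rec = self._records([3, 0, 7])
        out = ds.downsample_matrix(rec, 1.0, seed=0)
        assert out["y"].tolist() == [3, 0, 7]

    def test_total_preserved_and_zeros_stay(self, rng):
        y = rng.poisson(4, 200)
        rec = self._records(y)
        for frac in (0.75, 0.5, 0.25):
            out = ds.downsample_matrix(rec, frac, seed=1)
            assert out["y"].sum() == round(frac * y.sum())
            assert (out["y"].to_numpy()[y == 0] == 0).all()
            assert (out["y"].to_numpy() <= y).all()

    def test_hypergeometric_mean(self):
        # a 10-read record among 100 total at fraction 0.5 -> mean 5
        rec = self._records([10, 90])
        draws = [ds.downsample_matrix(rec, 0.5, seed=s)["y"].iloc[0]
                 for s in range(10_000)]
        sd = np.sqrt(10 * 0.5 * 0.5 * 90 / 99)  # hypergeometric sd
        assert np.mean(draws) == pytest.approx(5.0, abs=3 * sd / 100)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            ds.downsample_matrix(self._records([1]), 0.0)
        with pytest.raises(ValueError):
            ds.downsample_matrix(self._records([1]), 1.5)


class TestPREvaluation:
    def test_perfect_ordering(self):
        q_full = np.array([0.001] * 10 + [0.5] * 30)
        p_down = np.r_[10.0 ** -np.arange(20, 10, -1), np.full(30, 0.6)]
        curve, aupr = ds.pr_evaluation(q_full, p_down)
        assert aupr == pytest.approx(1.0)

    def test_random_scores_near_prevalence(self, rng):
        n = 4_000
        q_full = np.where(rng.random(n) < 0.2, 0.001, 0.5)
        p_down = rng.uniform(0, 1, n)
        _, aupr = ds.pr_evaluation(q_full, p_down)
        assert aupr == pytest.approx(0.2, abs=0.05)

    def test_excluded_stratum_and_no_positives(self):
        q_full = np.array([0.07, 0.08])  # everything in (0.05, 0.1)
        with pytest.raises(ValueError):
            ds.pr_evaluation(q_full, np.array([0.1, 0.2]))

    def test_hand_enumeration_small(self):
        q_full = np.array([0.01, 0.01, 0.5, 0.5, 0.01, 0.9] + [0.5] * 14)
        rng_ = np.random.default_rng(5)
        p_down = rng_.uniform(0, 1, 20)
        curve, aupr = ds.pr_evaluation(q_full, p_down)
        truth = q_full < 0.05
        score = -np.log10(p_down)
        for row in curve.itertuples():
            pred = score >= row.threshold
            assert row.precision == pytest.approx(
                (pred & truth).sum() / pred.sum())
            assert row.recall == pytest.approx(
                (pred & truth).sum() / truth.sum())

    def test_monotone_transform_invariance(self, rng):
        q_full = np.where(rng.random(500) < 0.3, 0.001, 0.8)
        p_down = rng.uniform(0, 1, 500)
        _, a1 = ds.pr_evaluation(q_full, p_down)
        _, a2 = ds.pr_evaluation(q_full, p_down ** 3)  # monotone in p
        assert a1 == pytest.approx(a2)


class TestPromoterNetwork:
    def _labels(self, promoters, n=60):
        return pd.DataFrame({
            "chrom": "c", "bin_id": np.arange(n),
            "start": np.arange(n) * 100_000,
            "end": (np.arange(n) + 1) * 100_000,
            "genomic": ["promoter" if b in promoters else "distal_intergenic"
                        for b in range(n)]})

    def test_planted_clique(self):
        promoters = [0, 2, 4, 6, 8]
        rows = [("c", i, j, 1_600_000.0, 5, 1e-8, 1e-6)
                for k, i in enumerate(promoters) for j in promoters[k + 1:]]
        rec = make_records(rows)
        counts, edges, comps = ds.longrange_promoter_network(
            rec, self._labels(promoters))
        assert counts.loc[0, "n_interactions"] == 10
        assert len(comps) == 1 and len(comps[0]) == 5

    def test_no_promoters(self):
        rec = make_records([("c", 0, 16, 1_600_000.0, 5, 1e-8, 1e-6)])
        counts, edges, comps = ds.longrange_promoter_network(
            rec, self._labels([]))
        assert counts["n_interactions"].sum() == 0 and len(edges) == 0

    def test_matches_brute_force_filter(self, rng):
        promoters = set(rng.choice(60, 20, replace=False).tolist())
        rows = []
        for _ in range(300):
            i, j = sorted(rng.integers(0, 60, 2))
            q = 10.0 ** -rng.uniform(0, 4)
            rows.append(("c", i, j, float((j - i)) * 100_000, 1, q / 3, q))
        rec = make_records(rows)
        counts, edges, comps = ds.longrange_promoter_network(
            rec, self._labels(promoters))
        want = sum(1 for r in rec.itertuples()
                   if r.q < 0.01 and 1_500_000 <= r.d <= 2_000_000
                   and r.i in promoters and r.j in promoters)
        assert counts.loc[0, "n_interactions"] == want
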