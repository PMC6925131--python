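"""Breakome statistics: exact small-sample values, arithmetic examples,
and brute-force oracle agreement for every overlap/window operation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_breakset
from ssbmap import sim
from ssbmap.stats import (
    VariantSet,
    complexity_curve,
    conservation_profile,
    count_motif_sites,
    detection_sensitivity,
    element_enrichment,
    geneset_enrichment,
    hotspots,
    normalized_site_score,
    replication_ratio,
    select_break_genes,
    site_profile,
    strand_asymmetry,
    track_compare,
    variant_overlap,
)
from ssbmap.tracks import SignalTrack


class TestElementEnrichment:
    def test_odds_ratio_identity_when_rate_matches_coverage(self):
        # element covers 10% and k/n = 0.1 exactly -> OR = 1
        bs = make_breakset([("chrA", 5, "+")] +
                           [("chrA", 100 + 10 * i, "+") for i in range(9)])
        res = element_enrichment(bs, [("chrA", 0, 100)], [("chrA", 0, 1000)])
        assert res.k == 1 and res.n == 10
        assert res.odds_ratio == pytest.approx(1.0)

    def test_exact_two_sided_binomial_all_in_element(self):
        # n=10, k=10, p0=0.5 -> p = 2 * 0.5^10 = 0.001953125, OR = +inf
        bs = make_breakset([("chrA", i, "+") for i in range(10)])
        res = element_enrichment(bs, [("chrA", 0, 500)], [("chrA", 0, 1000)])
        assert res.k == 10
        assert res.odds_ratio == math.inf
        assert res.p_value == pytest.approx(0.001953125, abs=1e-12)

    def test_degenerate_element_raises(self):
        bs = make_breakset([("chrA", 5, "+")])
        with pytest.raises(ValueError, match="degenerate"):
            element_enrichment(bs, [("chrB", 0, 10)], [("chrA", 0, 100)])

    def test_planted_enrichment_ci_contains_truth(self):
        g = sim.make_genome(4, {"chrA": 1_000_000},
                            elements={"E": [("chrA", 200_000, 300_000)]})
        truth = sim.simulate_breaks(
            g, n=10_000, element_rates={"E": 3.0}, seed=12,
            edge_margin=0, non_a_terminal=False,
            avoid_priming_contexts=False, avoid_repeats=False)
        res = element_enrichment([(c, p) for c, p, _ in truth.breaks],
                                 g.element_annotations["E"],
                                 [("chrA", 0, 1_000_000)])
        assert res.ci95[0] <= 3.0 <= res.ci95[1]
        assert res.p_value < 0.01


class TestStrandAsymmetry:
    REGIONS = [("chrA", 0, 100, "+", "exon"), ("chrA", 200, 300, "+", "intron")]

    def test_constructed_ratio(self):
        # 6 template (break '-' in a '+' gene exon) / 3 non-template
        recs = [("chrA", 10 + i, "-") for i in range(6)] + \
               [("chrA", 50 + i, "+") for i in range(3)]
        out = strand_asymmetry(make_breakset(recs), self.REGIONS)
        assert out["exon"].template_count == 6
        assert out["exon"].nontemplate_count == 3
        assert out["exon"].ratio == pytest.approx(2.0)

    def test_both_strand_regions_excluded_by_default(self):
        regions = self.REGIONS + [("chrA", 0, 100, "-", "exon")]
        out = strand_asymmetry(make_breakset([("chrA", 10, "-")]), regions)
        assert out["exon"].template_count == 0
        assert out["exon"].nontemplate_count == 0

    def test_random_model_matches_brute_force(self, rng):
        regions = []
        for i in range(20):
            s = int(rng.integers(0, 5000))
            regions.append(("chrA", s, s + int(rng.integers(10, 200)),
                            "+" if rng.random() < 0.5 else "-",
                            "exon" if rng.random() < 0.5 else "intron"))
        breaks = [("chrA", int(rng.integers(0, 5200)),
                   "+" if rng.random() < 0.5 else "-") for _ in range(400)]
        bs = make_breakset(breaks)
        got = strand_asymmetry(bs, regions)
        for klass in ("exon", "intron"):
            t = nt = 0
            for c, p, s in bs.calls:
                gs = {r[3] for r in regions
                      if r[4] == klass and r[0] == c and r[1] <= p < r[2]}
                if len(gs) != 1:
                    continue
                if s != next(iter(gs)):
                    t += 1
                else:
                    nt += 1
            assert (got[klass].template_count, got[klass].nontemplate_count) == (t, nt)

    def test_zero_nontemplate_flags_undefined_ratio(self):
        out = strand_asymmetry(make_breakset([("chrA", 10, "-")]), self.REGIONS)
        with pytest.raises(ZeroDivisionError):
            _ = out["exon"].ratio


class TestSignalTracks:
    def test_uniform_track_ratio_one(self):
        track = SignalTrack.from_constant({"chrA": 1000}, 2.5)
        bs = make_breakset([("chrA", 10, "+"), ("chrA", 500, "-")])
        out = replication_ratio(bs, {"G1": track})
        assert out["G1"] == pytest.approx(1.0)

    def test_breaks_on_double_value_region(self):
        # background mean 1, breaks where value is 2 -> ratio 2
        track = SignalTrack.from_intervals(
            {"chrA": 1000}, [("chrA", 0, 500, 0.0), ("chrA", 500, 1000, 2.0)])
        bs = make_breakset([("chrA", 600, "+"), ("chrA", 700, "-")])
        out = replication_ratio(bs, {"S1": track})
        assert out["S1"] == pytest.approx(2.0)

    def test_random_track_matches_lookup_oracle(self, rng):
        vals = rng.random(2000)
        track = SignalTrack({"chrA": vals})
        pos = rng.integers(0, 2000, 100)
        bs = make_breakset([("chrA", int(p), "+") for p in pos])
        out = replication_ratio(bs, {"f": track})
        expected = np.mean([vals[p] for p, _ in
                            {(int(p), "+") for p in pos}]) / vals.mean()
        assert out["f"] == pytest.approx(expected)

    def test_identical_distributions_zero_median_difference(self):
        track = SignalTrack.from_constant({"chrA": 100}, 1.0)
        bs = make_breakset([("chrA", i, "+") for i in range(10)])
        out = track_compare(bs, track, n_background=50, seed=1)
        assert out["median_breaks"] == out["median_background"]

    def test_small_sample_p_matches_exhaustive_enumeration(self):
        """Rank-sum p at n <= 10 equals the exhaustive permutation oracle."""
        x = [0.1, 0.9, 1.3, 2.4, 3.3, 4.1]
        y = [0.5, 1.1, 1.8, 2.0, 5.2]
        vals = np.zeros(len(x) + len(y))
        vals[: len(x)] = x
        vals[len(x):] = y
        track = SignalTrack({"chrA": vals})
        bs = make_breakset([("chrA", i, "+") for i in range(len(x))])
        bg = [("chrA", len(x) + j) for j in range(len(y))]
        out = track_compare(bs, track, method="exact", background_positions=bg)

        # oracle: enumerate all assignments of the pooled values
        pooled = x + y
        n = len(x)
        u_obs = sum(1 for a in x for b in y if a > b) + \
            0.5 * sum(1 for a in x for b in y if a == b)
        m = len(y)
        mu = n * m / 2
        count = total = 0
        for comb in itertools.combinations(range(len(pooled)), n):
            xs = [pooled[i] for i in comb]
            ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
            u = sum(1 for a in xs for b in ys if a > b)
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        assert out["p_value"] == pytest.approx(count / total, abs=1e-12)

    def test_p_decreases_with_location_shift(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=200)
        ps = []
        for shift in (0.0, 0.5, 1.0):
            vals = np.concatenate([base + shift, rng.normal(size=2000)])
            track = SignalTrack({"chrA": vals})
            bs = make_breakset([("chrA", i, "+") for i in range(200)])
            bg = [("chrA", 200 + j) for j in range(2000)]
            ps.append(track_compare(bs, track,
                                    background_positions=bg)["p_value"])
        assert ps[2] < ps[1] < ps[0]


class TestVariantOverlap:
    def _vs(self, positions, vtype="SNP", af=0.2):
        return VariantSet([("chrA", p, vtype, af) for p in positions])

    def test_exact_overlap_counted_at_window_zero(self):
        bs = make_breakset([("chrA", 50, "+")])
        out = variant_overlap(bs, self._vs([50]), background_length=1000,
                              windows=(0,), types=("SNP",), classes=("common",))
        assert out[("SNP", "common", 0)].k == 1

    def test_window_boundary(self):
        bs = make_breakset([("chrA", 53, "+")])
        out = variant_overlap(bs, self._vs([50]), background_length=1000,
                              windows=(2, 5), types=("SNP",), classes=("common",))
        assert out[("SNP", "common", 2)].k == 0
        assert out[("SNP", "common", 5)].k == 1

    def test_af_classes(self):
        assert VariantSet.af_class(0.05) == "common"
        assert VariantSet.af_class(0.0499) == "low_frequency"
        assert VariantSet.af_class(0.004) == "rare"

    def test_random_instances_match_distance_oracle(self, rng):
        vpos = sorted(int(p) for p in rng.integers(0, 5000, 80))
        bpos = [int(p) for p in rng.integers(0, 5000, 300)]
        bs = make_breakset([("chrA", p, "+") for p in bpos])
        vs = self._vs(vpos)
        out = variant_overlap(bs, vs, background_length=5000,
                              windows=(0, 2, 5, 10),
                              types=("SNP",), classes=("common",))
        for w in (0, 2, 5, 10):
            expected = sum(
                1 for c, p, _ in bs.calls
                if any(abs(p - v) <= w for v in vpos)
            )
            assert out[("SNP", "common", w)].k == expected


class TestConservation:
    def test_all_positive_scores(self):
        track = SignalTrack.from_constant({"chrA": 100}, 1.0)
        bs = make_breakset([("chrA", 50, "+")])
        out = conservation_profile(bs, track, windows=(5,))[5]
        assert out["mean_positive"] == pytest.approx(1.0)
        assert out["mean_negative_abs"] == pytest.approx(0.0)

    def test_constructed_window_means(self):
        # window scores {+2, -1, 0, +1}: positive mean 1.5, |negative| mean 1
        vals = np.zeros(7)
        vals[1], vals[2], vals[3], vals[4] = 2.0, -1.0, 0.0, 1.0
        track = SignalTrack({"chrA": vals})
        bs = make_breakset([("chrA", 3, "+")])
        out = conservation_profile(bs, track, windows=(2,))[2]
        assert out["mean_positive"] == pytest.approx(1.5)
        assert out["mean_negative_abs"] == pytest.approx(1.0)

    def test_random_tracks_match_brute_force(self, rng):
        vals = rng.normal(size=3000)
        track = SignalTrack({"chrA": vals})
        pos = sorted({int(p) for p in rng.integers(30, 2970, 50)})
        bs = make_breakset([("chrA", p, "+") for p in pos])
        for w in (5, 10, 20):
            out = conservation_profile(bs, track, windows=(w,))[w]
            pms, nms = [], []
            for p in pos:
                win = vals[p - w : p + w + 1]
                pv, nv = win[win > 0], win[win < 0]
                pms.append(pv.mean() if len(pv) else 0.0)
                nms.append(np.abs(nv).mean() if len(nv) else 0.0)
            assert out["mean_positive"] == pytest.approx(np.mean(pms))
            assert out["mean_negative_abs"] == pytest.approx(np.mean(nms))


class TestSiteProfiles:
    def test_all_breaks_at_offset_zero_top(self):
        sites = [("chrA", 100, 107, "+"), ("chrA", 300, 307, "+")]
        bs = make_breakset([("chrA", 100, "+"), ("chrA", 300, "+")])
        prof = site_profile(bs, sites, flank=5)
        assert prof.fractions[(0, "top")] == pytest.approx(1.0)
        assert prof.total() == pytest.approx(1.0)

    def test_minus_strand_site_is_flipped(self):
        sites = [("chrA", 100, 107, "-")]
        # motif-relative offset 0 on a '-' site = genomic position 106,
        # top strand = '-'
        bs = make_breakset([("chrA", 106, "-")])
        prof = site_profile(bs, sites, flank=3)
        assert prof.fractions[(0, "top")] == pytest.approx(1.0)

    def test_profile_total_bounded_by_one(self, rng):
        sites = [("chrA", 100, 107, "+")]
        recs = [("chrA", int(p), "+") for p in rng.integers(0, 2000, 100)]
        prof = site_profile(make_breakset(recs), sites, flank=10)
        assert prof.total() <= 1.0 + 1e-12

    def test_planted_nickase_peak_at_cleavage_offset(self, genome_small):
        """Breaks planted at the nick base of CCTCAGC motifs dominate the
        profile at that offset on the top strand."""
        motif_sites = [(c, s, e, st) for c, s, e, st, _ in
                       genome_small.planted_motifs]
        nick_offset = 1
        recs = [(c, s + nick_offset, st) for c, s, e, st in motif_sites]
        prof = site_profile(make_breakset(recs), motif_sites, flank=10)
        assert prof.argmax() == (nick_offset, "top")


class TestNormalizedScore:
    def test_formula(self):
        bs = make_breakset([("chrA", 0, "+"), ("chrA", 1, "+"),
                            ("chrA", 2, "+"), ("chrA", 3, "+")])
        scores = normalized_site_score(bs, [("chrA", 0), ("chrA", 9)])
        assert scores[("chrA", 0)] == pytest.approx(1 * 1e9 / 4)
        assert scores[("chrA", 9)] == 0.0

    def test_conservation_over_full_genome(self, rng):
        recs = [("chrA", int(p), s)
                for p, s in zip(rng.integers(0, 200, 300),
                                rng.choice(["+", "-"], 300))]
        bs = make_breakset(recs)
        scores = normalized_site_score(bs, [("chrA", p) for p in range(200)])
        total = len(bs)
        assert sum(scores.values()) * total / 1e9 == pytest.approx(total)


class TestSubsamplingCurves:
    def test_full_depth_detects_every_hit_site(self):
        reads = [("chrA", 100, "+")] * 3 + [("chrA", 500, "-")] * 2
        out = detection_sensitivity(reads, [("chrA", 100), ("chrA", 500)],
                                    depths=[5], seed=0)
        assert out == [1.0]

    def test_detection_window(self):
        reads = [("chrA", 102, "+")]
        assert detection_sensitivity(reads, [("chrA", 100)], [1], window=1) == [0.0]
        assert detection_sensitivity(reads, [("chrA", 100)], [1], window=2) == [1.0]

    def test_depth_exceeding_reads_rejected(self):
        with pytest.raises(ValueError):
            detection_sensitivity([("chrA", 1, "+")], [("chrA", 1)], [2])

    def test_all_distinct_positions_complexity_one(self):
        reads = [("chrA", i, "+") for i in range(50)]
        assert complexity_curve(reads, [10, 50], seed=1) == [1.0, 1.0]

    def test_duplicated_positions_lower_ratio(self):
        reads = [("chrA", i % 10, "+") for i in range(100)]
        (r,) = complexity_curve(reads, [100], seed=1)
        assert r == pytest.approx(10 / 100)


class TestHotspots:
    def test_threshold_at_four_reads(self):
        bs = make_breakset([("chrA", 1, "+", 4), ("chrA", 2, "+", 3)])
        hot, rest = hotspots(bs)
        assert set(hot.calls) == {("chrA", 1, "+")}
        assert set(rest.calls) == {("chrA", 2, "+")}

    def test_partition_conserves_positions(self, rng):
        recs = [("chrA", int(i), "+", int(c))
                for i, c in enumerate(rng.integers(1, 10, 200))]
        bs = make_breakset(recs)
        hot, rest = hotspots(bs, min_reads=4)
        assert len(hot) + len(rest) == len(bs)
        for key, call in bs.calls.items():
            assert (key in hot.calls) == (call.read_count >= 4)


class TestGeneSelection:
    GENES = [("chrA", 1000, 2000, "+", "g1"), ("chrA", 9000, 10_000, "-", "g2")]

    def test_min_breaks_threshold(self):
        proms = [("chrA", 500, 700)]
        bs3 = make_breakset([("chrA", 500 + i, "+") for i in range(3)])
        bs2 = make_breakset([("chrA", 500 + i, "+") for i in range(2)])
        sel3, uni = select_break_genes(bs3, self.GENES, promoters=proms)
        sel2, _ = select_break_genes(bs2, self.GENES, promoters=proms)
        assert sel3 == ["g1"] and sel2 == []
        assert uni == ["g1"]

    def test_promoter_beyond_5kb_unassigned(self):
        # gene 5' end at 1000; promoter [6002, 6100): nearest edge 6002,
        # distance 5002 > 5000 -> unassigned
        proms = [("chrA", 6002, 6100)]
        bs = make_breakset([("chrA", 6010, "+")] * 1)
        _, uni = select_break_genes(bs, [self.GENES[0]], promoters=proms)
        assert uni == []

    def test_minus_strand_gene_uses_right_end_as_5prime(self):
        proms = [("chrA", 10_100, 10_200)]  # near g2 5' end (9999)
        bs = make_breakset([("chrA", 10_100 + i, "-") for i in range(3)])
        sel, uni = select_break_genes(bs, self.GENES, promoters=proms)
        assert uni == ["g2"] and sel == ["g2"]

    def test_random_assignment_matches_nearest_scan(self, rng):
        genes = []
        for i in range(15):
            s = int(rng.integers(0, 50_000))
            genes.append(("chrA", s, s + int(rng.integers(500, 3000)),
                          "+" if rng.random() < 0.5 else "-", f"g{i}"))
        proms = []
        for _ in range(30):
            s = int(rng.integers(0, 52_000))
            proms.append(("chrA", s, s + 200))
        bs = make_breakset([("chrA", int(p), "+")
                            for p in rng.integers(0, 52_000, 500)])
        _, uni = select_break_genes(bs, genes, promoters=proms)
        expected = set()
        for pc, ps, pe in proms:
            best = None
            for gc, gs, ge, gst, gn in genes:
                tss = gs if gst == "+" else ge - 1
                d = 0 if ps <= tss < pe else min(abs(tss - ps), abs(tss - pe + 1))
                if d <= 5000 and (best is None or (d, gn) < best):
                    best = (d, gn)
            if best:
                expected.add(best[1])
        assert set(uni) == expected


class TestGeneSets:
    def test_disjoint_set_p_one(self):
        rows = geneset_enrichment(["a"], ["a", "b", "c", "d"], {"S": ["b", "c"]})
        assert rows[0]["p_value"] == pytest.approx(1.0)

    def test_exact_hypergeometric(self):
        # universe 20, set 5, selected 5, overlap 5 -> p = 1/C(20,5)
        universe = [f"g{i}" for i in range(20)]
        rows = geneset_enrichment(universe[:5], universe, {"S": universe[:5]})
        assert rows[0]["p_value"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_bh_adjustment_monotone_in_rank(self, rng):
        universe = [f"g{i}" for i in range(50)]
        sets = {f"S{j}": list(rng.choice(universe, size=8, replace=False))
                for j in range(12)}
        selected = list(rng.choice(universe, size=10, replace=False))
        rows = geneset_enrichment(selected, universe, sets)
        rows.sort(key=lambda r: r["p_value"])
        adj = [r["p_adjusted"] for r in rows]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))


def test_count_motif_sites_finds_planted(genome_small):
    sites = count_motif_sites(genome_small.sequences, "CCTCAGC")
    starts = {s for _, s, _, _ in sites}
    assert {m[1] for m in genome_small.planted_motifs} <= starts
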