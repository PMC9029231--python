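"""Flexible-threshold statistics, the optimizer and flanking analysis."""

import math
from fractions import Fraction

import numpy as np
import pytest

import flexsite as fx
from flexsite.enrichment import (
    EnrichmentConfig,
    Fragment,
    additional_sites,
    binomial_p,
    candidate_thresholds,
    flanking_enrichment,
    flanking_regions,
    optimize,
    or_ratio,
    sample_control_fragments,
    scan_thresholds,
)
from flexsite.motifs import MotifHit, PromoterSet


def exact_binom_tail(A, n, p_frac, upper=True):
    """Arbitrary-precision binomial tail by direct Fraction summation."""
    p = Fraction(p_frac)
    total = Fraction(0)
    rng = range(A, n + 1) if upper else range(0, A + 1)
    for k in rng:
        total += Fraction(math.comb(n, k)) * p**k * (1 - p) ** (n - k)
    return float(total)


class TestFormulas:
    def test_or_ratio_printed_example(self):
        assert or_ratio(10, 100000, 20, 400000) == pytest.approx(2.0)

    def test_or_ratio_equal_rates(self):
        assert or_ratio(7, 1000, 28, 4000) == pytest.approx(1.0)

    def test_or_ratio_zero_control_is_infinite(self):
        assert or_ratio(5, 10000, 0, 10000) == math.inf

    def test_or_ratio_zero_length_rejected(self):
        with pytest.raises(ValueError):
            or_ratio(1, 0, 1, 100)

    def test_additional_sites_examples(self):
        assert additional_sites(10, 100000, 20, 400000) == pytest.approx(5.0)
        assert additional_sites(30, 50000, 100, 500000) == pytest.approx(20.0)
        assert additional_sites(4, 1000, 8, 2000) == pytest.approx(0.0)

    def test_binomial_upper_tail_at_zero(self):
        assert binomial_p(0, 5, 100, 100) == pytest.approx(1.0)

    def test_binomial_simple_half(self):
        # P(X >= 1 | n=2, p=1/2) = 3/4
        assert binomial_p(1, 1, 500, 500) == pytest.approx(0.75, rel=1e-12)

    def test_binomial_exact_tail(self):
        expected = exact_binom_tail(20, 25, Fraction(1, 2))
        assert binomial_p(20, 5, 777, 777) == pytest.approx(expected, rel=1e-12)

    def test_binomial_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_p(-1, 2, 100, 100)

    @pytest.mark.parametrize("model", ["conditional", "rate"])
    def test_binomial_random_tuples_match_fraction_oracle(self, model):
        rng = np.random.default_rng(12345)
        for _ in range(200):
            A = int(rng.integers(0, 60))
            B = int(rng.integers(0, 60))
            if A + B == 0:
                A = 1
            lenA = int(rng.integers(50, 400))
            lenB = int(rng.integers(50, 5000))
            side = "over" if rng.random() < 0.5 else "under"
            got = binomial_p(A, B, lenA, lenB, side, model=model)
            if model == "conditional":
                n, p = A + B, Fraction(lenA, lenA + lenB)
            else:
                n, p = lenA, min(Fraction(B, lenB), Fraction(1))
            if side == "over":
                exp = exact_binom_tail(min(A, n + 1), n, p, upper=True)
            else:
                exp = exact_binom_tail(min(A, n), n, p, upper=False)
            assert got == pytest.approx(exp, rel=1e-9, abs=1e-300)

    def test_binomial_monotone_in_A(self):
        ps = [binomial_p(a, 10, 1000, 1000) for a in range(0, 30)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))


class TestThresholdScan:
    def test_candidate_thresholds_union(self):
        got = candidate_thresholds([0.8, 0.9], [0.9, 0.95])
        np.testing.assert_allclose(got, [0.8, 0.9, 0.95])
        assert candidate_thresholds([], []).size == 0

    def test_candidates_match_sort_dedupe_oracle(self, fixture_bundle):
        rng = np.random.default_rng(3)
        a = list(rng.choice([0.7, 0.8, 0.9, 1.0], 30))
        b = list(rng.choice([0.7, 0.85, 0.9], 30))
        np.testing.assert_allclose(
            candidate_thresholds(a, b), sorted(set(a) | set(b))
        )

    def test_low_control_frequency_inadmissible(self):
        pts = scan_thresholds([0.9], [0.9], lenA=200000, lenB=200000)
        # one control site in 200 kb = 0.005/kb, below the 0.01 floor
        assert len(pts) == 1 and not pts[0].admissible

    def test_identical_scores_single_point(self):
        pts = scan_thresholds([0.9] * 5, [0.9] * 3, 10000, 30000)
        assert len(pts) == 1
        assert (pts[0].A, pts[0].B) == (5, 3)

    def test_counts_match_filter_and_count_oracle(self):
        rng = np.random.default_rng(11)
        ts = rng.uniform(0.7, 1.0, 30)
        cs = rng.uniform(0.7, 1.0, 25)
        cfg = EnrichmentConfig()
        pts = scan_thresholds(ts, cs, 50000, 60000, cfg)
        assert len(pts) == len(set(ts) | set(cs))
        for p in pts:
            A = int(np.sum(ts >= p.threshold))
            B = int(np.sum(cs >= p.threshold))
            assert (p.A, p.B) == (A, B)
            assert p.or_ratio == pytest.approx(or_ratio(A, 50000, B, 60000))
            assert p.additional_sites == pytest.approx(
                additional_sites(A, 50000, B, 60000)
            )
            assert p.p_value == pytest.approx(
                binomial_p(A, B, 50000, 60000, model=cfg.p_model)
            )
            assert p.admissible == (0.01 <= 1000 * B / 60000 <= 0.2)

    def test_counts_are_step_functions(self):
        rng = np.random.default_rng(7)
        pts = scan_thresholds(
            rng.uniform(0, 1, 100), rng.uniform(0, 1, 100), 1000, 1000
        )
        As = [p.A for p in pts]
        Bs = [p.B for p in pts]
        assert As == sorted(As, reverse=True)
        assert Bs == sorted(Bs, reverse=True)


def brute_force_optimum(points, objective, min_or):
    """Enumeration oracle for the optimizer, applying all constraints."""
    best = None
    for p in points:
        if not p.admissible:
            continue
        if objective == "AS" and p.or_ratio < min_or:
            continue
        val = p.or_ratio if objective == "OR" else p.additional_sites
        key = (val, -p.p_value, p.threshold)
        if best is None or key > best[0]:
            best = (key, p)
    return None if best is None else best[1]


class TestOptimize:
    def test_no_admissible_returns_none(self):
        pts = scan_thresholds([0.9], [0.9], 200000, 200000)
        assert optimize(pts) is None

    def test_single_admissible_returned(self):
        pts = scan_thresholds([0.9] * 8, [0.9] * 2, 10000, 20000,
                              EnrichmentConfig(objective="OR"))
        assert optimize(pts, EnrichmentConfig(objective="OR")) is pts[0]

    @pytest.mark.parametrize("objective", ["OR", "AS"])
    def test_matches_enumeration_oracle(self, objective):
        cfg = EnrichmentConfig(objective=objective)
        for seed in range(40):
            rng = np.random.default_rng(seed)
            nt, nc = rng.integers(5, 120, 2)
            ts = np.round(rng.uniform(0.6, 1.0, nt), 3)
            cs = np.round(rng.uniform(0.6, 1.0, nc), 3)
            lenA = int(rng.integers(5000, 300000))
            lenB = int(rng.integers(5000, 300000))
            pts = scan_thresholds(ts, cs, lenA, lenB, cfg)
            assert len(pts) <= 500
            got = optimize(pts, cfg)
            exp = brute_force_optimum(pts, objective, cfg.min_or)
            assert got is exp


class TestRunEnrichment:
    def test_identical_sets_give_unit_ratio(self, fixture_bundle):
        same = PromoterSet("control", fixture_bundle.test.entries)
        cfg = EnrichmentConfig(window_lengths=(500,), n_required=0, objective="OR")
        res = fx.run_enrichment(
            fixture_bundle.test, same, [fixture_bundle.pfms["AP1"]], (), cfg
        )
        best = res[0].best
        if best is not None:
            assert best.or_ratio == pytest.approx(1.0)
            assert best.additional_sites == pytest.approx(0.0)

    def test_planted_motif_detected(self, fixture_bundle):
        cfg = EnrichmentConfig(window_lengths=(500,), n_required=2, objective="OR")
        res = fx.run_enrichment(
            fixture_bundle.test,
            fixture_bundle.control,
            fixture_bundle.pfms.values(),
            fixture_bundle.bundles,
            cfg,
        )
        by_id = {r.motif_id: r for r in res}
        ap1 = by_id["AP1"].best
        assert ap1 is not None
        assert ap1.or_ratio > 1.0
        assert ap1.p_value < 0.05

    def test_conservation_improves_planted_ratio(self, pfms):
        from flexsite import simulate as sim

        spec = sim.SimulationSpec(
            seed=77, n_test=100, n_control=100, promoter_length=1000,
            plants=(sim.PlantSpec(pfms["AP1"], rate_test=0.3, rate_control=0.1),),
        )
        test, control, truth = sim.gen_promoters(spec)
        bundles = sim.gen_ortholog_bundles(test, control, truth, spec)
        r = {}
        for n in (0, 3):
            cfg = EnrichmentConfig(window_lengths=(1000,), n_required=n, objective="OR")
            res = fx.run_enrichment(test, control, [pfms["AP1"]], bundles, cfg)
            r[n] = res[0].best.or_ratio if res[0].best else 0.0
        assert r[3] > r[0]

    def test_degenerate_matrix_skipped_not_fatal(self, fixture_bundle):
        from flexsite.motifs import PositionFrequencyMatrix

        flat = PositionFrequencyMatrix("FLAT", "flat", "CUSTOM", np.full((4, 4), 1.0))
        cfg = EnrichmentConfig(window_lengths=(500,), n_required=0)
        res = fx.run_enrichment(
            fixture_bundle.test, fixture_bundle.control,
            [flat, fixture_bundle.pfms["AP1"]], (), cfg,
        )
        assert [r.motif_id for r in res] == ["AP1"]


class TestFlankingRegions:
    def _mk(self, promoters, anchors, m=10, flank=100):
        hits = [MotifHit(pid, off, "+", 1.0) for pid, off in anchors]
        return flanking_regions(hits, promoters, m, flank)

    def test_interior_anchor_two_flanks(self):
        ps = PromoterSet("test", [("p", "A" * 1000)])
        frags = self._mk(ps, [("p", 200)])
        assert {(f.start, f.end) for f in frags} == {(100, 200), (210, 310)}

    def test_edge_anchor_clipped(self):
        ps = PromoterSet("test", [("p", "A" * 1000)])
        frags = self._mk(ps, [("p", 30)])
        assert {(f.start, f.end) for f in frags} == {(0, 30), (40, 140)}

    def test_nearby_anchor_windows_masked_out(self):
        ps = PromoterSet("test", [("p", "A" * 1000)])
        frags = self._mk(ps, [("p", 200), ("p", 250)])
        intervals = {(f.start, f.end) for f in frags}
        # neither anchor window [200,210) nor [250,260) may appear inside any fragment
        for s, e in intervals:
            assert not (s < 210 and 200 < e)
            assert not (s < 260 and 250 < e)
        # left flank of the second anchor is split around the first anchor
        assert (210, 250) in intervals

    def test_fragment_sequences_carry_coordinates(self):
        seq = "".join("ACGT"[i % 4] for i in range(500))
        ps = PromoterSet("test", [("p", seq)])
        for f in self._mk(ps, [("p", 200)]):
            assert f.sequence == seq[f.start : f.end]


class TestFlankingEnrichment:
    def test_zero_fragments_rejected(self, fixture_bundle):
        with pytest.raises(ValueError):
            flanking_enrichment(
                [], fixture_bundle.control, [fixture_bundle.pfms["CRE"]],
            )

    def test_short_controls_rejected(self):
        ps = PromoterSet("control", [("p", "ACGT" * 10)])
        with pytest.raises(ValueError):
            sample_control_fragments(ps, 10, 200, np.random.default_rng(0))

    def test_identity_comparison_near_unit_ratio(self, fixture_bundle):
        # use the same fragments as test and control: OR == 1 wherever defined
        frags = [
            Fragment(pid, 0, 200, seq[:200])
            for pid, seq in fixture_bundle.test.entries[:10]
        ]
        test_set = PromoterSet("test", [(f.fragment_id, f.sequence) for f in frags])
        cfg = EnrichmentConfig(objective="OR")
        from flexsite.enrichment import build_hit_cache, evaluate_split

        pwm = fx.build_pwm(fixture_bundle.pfms["AP1"])
        pooled = [(g + "|t", s) for g, s in test_set.entries] + [
            (g + "|c", s) for g, s in test_set.entries
        ]
        cache = build_hit_cache(pwm, pooled, (), 0, cfg.low_rate_per_kb)
        best, _ = evaluate_split(
            cache,
            [g for g, _ in pooled[: len(frags)]],
            [g for g, _ in pooled[len(frags) :]],
            cfg,
        )
        if best is not None:
            assert best.or_ratio == pytest.approx(1.0)

    def test_seed_reproducibility(self, fixture_bundle):
        frags = [
            Fragment(pid, 100, 300, seq[100:300])
            for pid, seq in fixture_bundle.test.entries[:8]
        ]
        kw = dict(
            control_promoters=fixture_bundle.control,
            pwms=[fixture_bundle.pfms["CRE"]],
            n_fragments=50,
            rng_seed=9,
        )
        r1 = flanking_enrichment(frags, **kw)
        r2 = flanking_enrichment(frags, **kw)
        t1 = fx.results_table(r1)
        t2 = fx.results_table(r2)
        assert t1.equals(t2)
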