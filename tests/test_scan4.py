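"""Background-corrected k-scan test: enumeration, model fit, FDR, merging."""

import numpy as np
import pytest
from scipy.stats import norm

from uvhotspots.core import GenomicInterval, TrackSet
from uvhotspots.scan4 import (
    Hotspot,
    KScan,
    attach_background,
    enumerate_kscans,
    filter_scans,
    fit_width_model,
    local_background,
    merge_hotspots,
    merge_samples,
    restrict_promoter_hotspots,
    score_scans,
    summarize_hotspots,
)
from uvhotspots.stats import bh_qvalues

from conftest import make_cohort, random_cohort


def bh_oracle(p):
    """Definitional BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestMergeAndEnumerate:
    def test_cross_sample_duplicates_retained(self):
        c = make_cohort([("a", "1", 100), ("b", "1", 100)])
        pos, samples = merge_samples(c)["1"]
        assert pos.tolist() == [100, 100]
        assert samples.tolist() == ["a", "b"]

    def test_event_conservation(self, rng):
        c = random_cohort(rng, 500, 100_000, n_samples=20)
        events = merge_samples(c)
        assert sum(len(p) for p, _ in events.values()) == len(c)

    def test_consecutive_positions(self):
        c = make_cohort([("s", "1", i) for i in range(1, 11)])
        scans = enumerate_kscans(merge_samples(c), k=4)
        assert len(scans) == 7
        assert all(s.width == 4 for s in scans)

    def test_fewer_events_than_k(self):
        c = make_cohort([("s", "1", i) for i in (1, 5, 9)])
        assert enumerate_kscans(merge_samples(c), k=4) == []

    def test_recurrent_position_width_one(self):
        c = make_cohort([(f"s{i}", "1", 500) for i in range(4)])
        scans = enumerate_kscans(merge_samples(c), k=4)
        assert len(scans) == 1 and scans[0].width == 1

    def test_sample_relabelling_invariance(self, rng):
        c = random_cohort(rng, 300, 50_000, n_samples=10)
        relabel = {f"S{i}": f"T{(i + 3) % 10}" for i in range(10)}
        df = c.df.copy()
        df["sample_id"] = df["sample_id"].map(relabel)
        c2 = make_cohort(
            list(zip(df["sample_id"], df["chrom"], df["pos"])), genome_length=50_000
        )
        w1 = [s.width for s in enumerate_kscans(merge_samples(c), 4)]
        w2 = [s.width for s in enumerate_kscans(merge_samples(c2), 4)]
        assert w1 == w2


class TestLocalBackground:
    def test_uniform_counts(self):
        events = {"1": (np.arange(1, 4001) * 250, np.array(["s"] * 4000))}
        bg = local_background(events, n_samples=40, chrom_lengths={"1": 1_000_000})
        assert bg.c("1", 500_000) == pytest.approx(4000 / 40)

    def test_counting_matches_bruteforce(self, rng):
        pos = np.sort(rng.integers(1, 5_000_001, size=3000))
        events = {"1": (pos, np.array(["s"] * 3000))}
        bg = local_background(events, n_samples=10, chrom_lengths={"1": 5_000_000})
        for i, start in enumerate(range(0, 4_000_001, 100_000)):
            expected = np.sum((pos - 1 >= start) & (pos - 1 < start + 1_000_000))
            assert bg.window_count("1", i) == expected

    def test_empty_region_zero(self):
        events = {"1": (np.array([10]), np.array(["s"]))}
        bg = local_background(events, n_samples=5, chrom_lengths={"1": 10_000_000})
        assert bg.c("1", 9_000_000) == 0.0


class TestFilterScans:
    def _scan(self, first, last):
        return KScan("1", 4, first, last, tuple((p, "s") for p in (first, last)))

    def test_blacklist_and_mappability(self):
        tracks = TrackSet(
            {
                "blacklist": [GenomicInterval("1", 1000, 2000)],
                "mappable100": [
                    GenomicInterval("1", 0, 5000, score=1.0),
                    GenomicInterval("1", 5000, 6000, score=0.0),
                    GenomicInterval("1", 6000, 10_000, score=1.0),
                ],
            }
        )
        inside_blacklist = self._scan(1500, 1600)
        straddles_gap = self._scan(4990, 6010)
        clean = self._scan(3000, 3050)
        kept = filter_scans([inside_blacklist, straddles_gap, clean], tracks)
        assert kept == [clean]

    def test_missing_tracks_error(self):
        from uvhotspots.core import ConfigurationError

        with pytest.raises(ConfigurationError):
            filter_scans([self._scan(1, 5)], TrackSet())


class TestWidthModel:
    def _scans_from(self, widths, cs):
        return [
            KScan("1", 4, 1, int(w), ((1, "s"), (int(w), "s")), local_count=float(c))
            for w, c in zip(widths, cs)
        ]

    def test_known_quadratic_recovered(self, rng):
        beta = np.array([2.0, 0.8, 0.05])
        c = rng.lognormal(3.0, 1.0, size=5000)
        x = np.log(c + 0.5)
        y = beta[0] + beta[1] * x + beta[2] * x**2 + rng.normal(0, 0.3, size=5000)
        widths = np.maximum(1, np.round(np.exp(y) - 0.5)).astype(int)
        model = fit_width_model(self._scans_from(widths, c))
        # rounding to integer widths perturbs y slightly; recovery is approximate
        assert np.allclose(model.beta, beta, atol=0.15)
        assert model.sigma == pytest.approx(0.3, abs=0.05)

    def test_degenerate_design_errors(self):
        scans = self._scans_from([10] * 200, [5.0] * 200)
        with pytest.raises(ValueError, match="degenerate"):
            fit_width_model(scans)

    def test_too_few_scans_errors(self):
        scans = self._scans_from([10, 20], [1.0, 2.0])
        with pytest.raises(ValueError, match="need >="):
            fit_width_model(scans)

    def test_quadratic_term_null_coverage(self, rng):
        """With no true curvature the fitted beta2 CI covers 0 in >= 90% of reps."""
        import statsmodels.api as sm

        covered = 0
        for _ in range(100):
            c = rng.lognormal(3.0, 1.0, size=400)
            x = np.log(c + 0.5)
            y = 1.0 + 0.5 * x + rng.normal(0, 0.3, size=400)
            X = np.column_stack([np.ones(400), x, x**2])
            fit = sm.OLS(y, X).fit()
            lo, hi = fit.conf_int()[2]
            covered += lo <= 0 <= hi
        assert covered >= 90


class TestScoring:
    def _scored(self, widths, cs, model=None):
        scans = [
            KScan("1", 4, 1, int(w), ((1, "s"), (int(w), "s")), local_count=float(c))
            for w, c in zip(widths, cs)
        ]
        return scans, model

    def test_pvalues_follow_left_tail_normal(self):
        """p = Phi(residual / sigma): 0.5 at zero residual, Phi(-3) at -3 sigma."""
        from uvhotspots.scan4 import WidthModel

        sigma = 0.4
        # flat model: predicted log-width is exactly beta0 for any c
        model = WidthModel(beta=np.array([np.log(10.5), 0.0, 0.0]), sigma=sigma, n=100, r_squared=0.0)
        on_prediction = KScan("1", 4, 1, 10, ((1, "s"),), local_count=7.0)
        shifted = KScan(
            "1",
            4,
            1,
            int(round(np.exp(np.log(10.5) - 3 * sigma) - 0.5)),
            ((1, "s"),),
            local_count=7.0,
        )
        scored = score_scans([on_prediction, shifted], model)
        assert scored[0].p_value == pytest.approx(0.5)
        resid = np.log(scored[1].width + 0.5) - np.log(10.5)
        assert scored[1].p_value == pytest.approx(norm.cdf(resid / sigma))
        assert scored[1].p_value < 0.01  # about Phi(-3) ~ 1.35e-3 before rounding

    def test_bh_matches_definitional_oracle(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 1000)))
            assert np.allclose(bh_qvalues(p), bh_oracle(p), atol=1e-12)

    def test_smaller_width_smaller_p_at_equal_background(self, rng):
        from uvhotspots.scan4 import WidthModel

        model = WidthModel(beta=np.array([5.0, 0.3, 0.01]), sigma=0.5, n=1000, r_squared=0.1)
        widths = np.unique(np.maximum(1, rng.poisson(200, size=500)))
        scans = [KScan("1", 4, 1, int(w), ((1, "s"),), local_count=30.0) for w in widths]
        p = np.array([s.p_value for s in score_scans(scans, model)])
        assert np.all(np.diff(p) > 0)  # widths unique ascending -> p strictly increasing


class TestHotspotMerging:
    def _sig(self, first, last, q, members=None):
        members = members or tuple((p, f"s{p}") for p in (first, last))
        return KScan("1", 4, first, last, members, q_value=q, p_value=q)

    def test_no_significant_scans(self):
        assert merge_hotspots([self._sig(1, 10, 0.5)], 0.01) == []

    def test_two_overlapping_share_union(self):
        a = self._sig(100, 110, 1e-4, ((100, "x"), (104, "y"), (107, "z"), (110, "w")))
        b = self._sig(104, 115, 1e-3, ((104, "y"), (107, "z"), (110, "w"), (115, "v")))
        hs = merge_hotspots([a, b], 0.01)
        assert len(hs) == 1
        h = hs[0]
        assert (h.interval.start, h.interval.end) == (99, 115)
        assert h.n_variants == 5
        assert h.min_q == 1e-4

    def test_matches_connected_component_oracle(self, rng):
        import networkx as nx

        scans = []
        for _ in range(300):
            first = int(rng.integers(1, 10_000))
            last = first + int(rng.integers(0, 60))
            scans.append(self._sig(first, last, float(rng.choice([1e-5, 0.5]))))
        hs = merge_hotspots(scans, 0.01)
        sig = [s for s in scans if s.q_value < 0.01]
        g = nx.Graph()
        g.add_nodes_from(range(len(sig)))
        for i, a in enumerate(sig):
            for j in range(i + 1, len(sig)):
                b = sig[j]
                if a.first_pos <= b.last_pos and b.first_pos <= a.last_pos:
                    g.add_edge(i, j)
        comps = {
            frozenset((sig[i].first_pos, sig[i].last_pos) for i in comp)
            for comp in nx.connected_components(g)
        }
        got = {
            frozenset((s.first_pos, s.last_pos) for s in h.member_scans) for h in hs
        }
        assert got == comps
        # hotspots disjoint, each significant scan in exactly one
        assert sum(len(h.member_scans) for h in hs) == len(sig)
        hs_sorted = sorted(hs, key=lambda h: h.interval.start)
        for a, b in zip(hs_sorted, hs_sorted[1:]):
            assert a.interval.end <= b.interval.start

    def test_summaries(self):
        h = Hotspot(
            GenomicInterval("1", 100, 110),
            n_variants=4,
            n_samples=4,
            member_scans=[],
            min_q=1e-4,
        )
        s = summarize_hotspots([h])
        assert (s["mean_width"], s["mean_n_variants"], s["mean_n_samples"]) == (10, 4, 4)
        empty = summarize_hotspots([])
        assert empty["n_hotspots"] == 0


class TestRestrictPromoterHotspots:
    def test_three_filters(self):
        tracks = TrackSet(
            {
                "dhs": [GenomicInterval("1", 1000, 1200)],
                "chip": [GenomicInterval("1", 900, 1300, name=f"TF{i}") for i in range(3)],
                "mappable20": [GenomicInterval("1", 0, 10_000, score=1.0)],
            }
        )
        good = Hotspot(GenomicInterval("1", 1050, 1080), 4, 4, [], 1e-4)
        far = Hotspot(GenomicInterval("1", 5000, 5030), 4, 4, [], 1e-4)
        assert restrict_promoter_hotspots([good, far], tracks) == [good]

    def test_chip_count_failure_dropped(self):
        tracks = TrackSet(
            {
                "dhs": [GenomicInterval("1", 1000, 1200)],
                "chip": [GenomicInterval("1", 900, 1300, name="TF0")],
                "mappable20": [GenomicInterval("1", 0, 10_000, score=1.0)],
            }
        )
        h = Hotspot(GenomicInterval("1", 1050, 1080), 4, 4, [], 1e-4)
        assert restrict_promoter_hotspots([h], tracks) == []
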