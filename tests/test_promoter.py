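import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trisomethyl as tm
from trisomethyl.core_io import ValidationError


def make_track(values_by_sample: dict, chrom="chr1", spacing=100,
               promoter_map=None, mark="5mC") -> tm.ProbeTrack:
    n = len(next(iter(values_by_sample.values())))
    df = pd.DataFrame(
        {"probe_id": [f"p{i}" for i in range(n)], "chrom": chrom,
         "position": np.arange(n) * spacing}
    )
    for s, vals in values_by_sample.items():
        df[s] = np.asarray(vals, dtype=float)
    return tm.ProbeTrack(mark, df, list(values_by_sample), promoter_map or {})


class TestBiweight:
    def test_symmetric_data(self):
        assert tm.biweight_mean(np.array([1.0, 2.0, 3.0])) == pytest.approx(2.0)

    def test_outlier_downweighted(self):
        # one huge outlier among zeros: MAD 0 path returns the median
        assert abs(tm.biweight_mean(np.array([0, 0, 0, 0, 100.0]))) < 0.01

    def test_outlier_downweighted_with_spread(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 200), [1000.0]])
        assert abs(tm.biweight_mean(x)) < 0.2

    def test_scaling_idempotent(self):
        rng = np.random.default_rng(1)
        track = make_track({"s1": rng.normal(2.0, 1.0, 300)})
        once = tm.biweight_scale(track)
        frame2 = once.frame.copy()
        frame2["s1"] = once.scaled["s1"]
        twice = tm.biweight_scale(
            tm.ProbeTrack("5mC", frame2, ["s1"], dict(track.promoter_map))
        )
        np.testing.assert_allclose(
            twice.scaled["s1"], once.scaled["s1"], atol=1e-6
        )

    def test_constant_input_centers_to_zero(self):
        track = make_track({"s1": np.full(10, 3.5)})
        out = tm.biweight_scale(track)
        np.testing.assert_allclose(out.scaled["s1"], 0.0)


def brute_force_dplus(window, background):
    """sup_t [F_bg(t) - F_win(t)] over all evaluation points."""
    window = np.asarray(window, float)
    background = np.asarray(background, float)
    m, n = len(window), len(background)
    best = 0.0
    for t in np.concatenate([window, background]):
        for le in (True, False):
            if le:
                fw = (window <= t).sum() / m
                fb = (background <= t).sum() / n
            else:
                fw = (window < t).sum() / m
                fb = (background < t).sum() / n
            best = max(best, fb - fw)
    return best


class TestWindowedKs:
    def test_identical_window_and_background_scores_zero(self):
        d = tm.one_sided_ks_dplus(np.array([1.0, 1.0]), np.array([1.0] * 20))
        assert d == 0.0
        assert tm.ks_score_from_dplus(d, 2, 20) == 0.0

    def test_fully_separated_window_reaches_asymptotic_limit(self):
        # window {1,1,1} above a large zero background: D+=1 and the score
        # approaches 2*3*log10(e) ~ 2.606 as n grows
        w = np.array([1.0, 1.0, 1.0])
        bg = np.zeros(100_000)
        d = tm.one_sided_ks_dplus(w, bg)
        assert d == 1.0
        score = tm.ks_score_from_dplus(d, 3, len(bg))
        assert score == pytest.approx(2 * 3 * math.log10(math.e), abs=1e-3)

    def test_dplus_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            m = rng.integers(2, 10)
            n = rng.integers(2, 25)
            # mixed continuous and tied values
            w = np.round(rng.normal(size=m), 1)
            bg = np.round(rng.normal(size=n), 1)
            fast = tm.one_sided_ks_dplus(w, bg)
            slow = brute_force_dplus(w, bg)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_score_formula_matches_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            w = rng.normal(size=5)
            bg = rng.normal(size=30)
            d = tm.one_sided_ks_dplus(w, bg)
            p = math.exp(-2 * 5 * 30 * d**2 / 35)
            assert tm.ks_score_from_dplus(d, 5, 30) == pytest.approx(
                -math.log10(p), abs=1e-12
            )

    def test_track_scores_invariant_to_joint_shift(self, sheet):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(60, 8))
        t1 = make_track({s: vals[:, j] for j, s in enumerate(sheet.sample_ids)})
        t2 = make_track({s: vals[:, j] + 7.5 for j, s in enumerate(sheet.sample_ids)})
        s1 = tm.acme_ks_scores(tm.biweight_scale(t1), sheet, 750.0)
        s2 = tm.acme_ks_scores(tm.biweight_scale(t2), sheet, 750.0)
        for g in ("trisomy8", "disomy8", "reference"):
            np.testing.assert_allclose(s1.frame[g], s2.frame[g], atol=1e-9)

    def test_peak_probes_score_highest(self, sheet):
        track, truth = tm.simulate_promoter_track(
            n_probes=1500, peak_genes=1, peak_height=2.0, seed=5
        )
        scores = tm.acme_ks_scores(tm.biweight_scale(track), sheet, 750.0)
        [peak_gene] = list(truth.enriched_promoter_genes)
        top_probe = scores.frame.loc[scores.frame["trisomy8"].idxmax(), "probe_id"]
        assert scores.promoter_map[top_probe] == peak_gene

    def test_unscaled_track_is_error(self, sheet):
        track = make_track({"s1": np.zeros(5)})
        with pytest.raises(ValidationError, match="scaled"):
            tm.acme_ks_scores(track, sheet, 750.0, by="sample")


def brute_force_potts(x, gamma, min_segment):
    """Minimum penalized objective by enumerating all valid segmentations."""
    n = len(x)
    best = math.inf
    positions = list(range(1, n))
    for r in range(0, n):
        for cuts in itertools.combinations(positions, r):
            bounds = [0, *cuts, n]
            lengths = [b - a for a, b in zip(bounds, bounds[1:])]
            if min(lengths) < min_segment:
                continue
            cost = gamma * r
            for a, b in zip(bounds, bounds[1:]):
                seg = np.asarray(x[a:b], float)
                cost += ((seg - seg.mean()) ** 2).sum()
            best = min(best, cost)
    return best


class TestPottsSmooth:
    def test_constant_vector_single_segment(self):
        res = tm.potts_smooth([3.0] * 6, gamma=2.0, min_segment=2)
        assert res.n_segments == 1
        assert res.objective == 0.0
        assert res.segment_means == [3.0]

    def test_clear_step_detected(self):
        # jump penalty 2 beats the one-segment residual cost of 37.5
        res = tm.potts_smooth([0, 0, 0, 5, 5, 5], gamma=2.0, min_segment=2)
        assert res.segments == [(0, 3), (3, 6)]
        assert res.segment_means == [0.0, 5.0]
        assert res.objective == pytest.approx(2.0)

    def test_min_segment_blocks_single_point_spike(self):
        res = tm.potts_smooth([0, 0, 5, 0, 0], gamma=0.1, min_segment=2)
        assert all(b - a >= 2 for a, b in res.segments)

    def test_too_short_input_is_error(self):
        with pytest.raises(ValidationError):
            tm.potts_smooth([1.0], min_segment=2)

    def test_objective_identity(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        res = tm.potts_smooth(x, gamma=1.5, min_segment=2)
        recomputed = sum(
            ((x[a:b] - x[a:b].mean()) ** 2).sum() for a, b in res.segments
        ) + 1.5 * (res.n_segments - 1)
        assert res.objective == pytest.approx(recomputed, abs=1e-9)

    def test_all_binary_vectors_match_enumeration(self):
        for n in range(2, 11):
            for bits in itertools.product([0.0, 1.0], repeat=n):
                res = tm.potts_smooth(list(bits), gamma=2.0, min_segment=2)
                expected = brute_force_potts(list(bits), 2.0, 2)
                assert res.objective == pytest.approx(expected, abs=1e-9), bits

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=9),
           st.floats(0.1, 5.0))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_random_vectors_match_enumeration(self, xs, gamma):
        res = tm.potts_smooth(xs, gamma=gamma, min_segment=2)
        assert res.objective == pytest.approx(
            brute_force_potts(xs, gamma, 2), abs=1e-6
        )


class TestCallEnrichedGenes:
    def test_recovers_spiked_genes(self, sheet):
        track, truth = tm.simulate_promoter_track(
            n_probes=3000, peak_genes=10, seed=7
        )
        scores = tm.acme_ks_scores(tm.biweight_scale(track), sheet, 750.0)
        called = tm.call_enriched_genes(scores, "trisomy8", target_range=(8, 12))
        recovered = set(called.gene_ids) & set(truth.enriched_promoter_genes)
        assert len(recovered) >= 9
        assert called.threshold == pytest.approx(min(called.genes["score"]))

    def test_single_probe_spike_not_called(self, sheet):
        rng = np.random.default_rng(8)
        # gene "lonely" has one probe: below min_segment, cannot be called
        vals = rng.normal(0, 0.1, size=40)
        vals[0] = 50.0
        pm = {"p0": "lonely"}
        pm.update({f"p{i}": f"gene{i // 4}" for i in range(1, 40)})
        track = make_track({s: vals for s in sheet.sample_ids}, promoter_map=pm)
        scores = tm.acme_ks_scores(tm.biweight_scale(track), sheet, 750.0)
        called = tm.call_enriched_genes(scores, "trisomy8", target_range=(1, 3))
        assert "lonely" not in called.gene_ids

    def test_fixed_threshold_mode(self, sheet):
        track, _ = tm.simulate_promoter_track(n_probes=600, peak_genes=2, seed=9)
        scores = tm.acme_ks_scores(tm.biweight_scale(track), sheet, 750.0)
        called = tm.call_enriched_genes(scores, "trisomy8", score_threshold=1.3)
        assert (called.genes["score"] >= 1.3).all()

    def test_empty_promoter_map_warns_and_returns_empty(self, sheet, caplog):
        track = make_track({s: np.zeros(10) for s in sheet.sample_ids})
        scores = tm.acme_ks_scores(tm.biweight_scale(track), sheet, 750.0)
        with caplog.at_level("WARNING"):
            called = tm.call_enriched_genes(scores, "trisomy8")
        assert called.gene_ids == []


class TestChromosomeComparisons:
    def test_depleted_chromosome_detected_nulls_calibrated(self, sheet):
        # trisomy-only 5hmC depletion on chr8: chr8 must reject in every
        # seed; null chromosomes reject at roughly the nominal rate
        null_ps = []
        for seed in range(5):
            track, _ = tm.simulate_promoter_track(
                n_probes=2500, seed=seed, mark="5hmC",
                chrom_depletion={"chr8": {"trisomy8": -0.5}},
            )
            scaled = tm.biweight_scale(track)
            table, p8 = tm.chromosome_promoter_comparison(scaled, sheet, "chr8")
            assert p8 < 0.05
            assert table["difference"].mean() < -0.2
            for chrom in ("chr1", "chr7"):
                _, p = tm.chromosome_promoter_comparison(scaled, sheet, chrom)
                null_ps.append(p)
        assert np.mean(np.asarray(null_ps) < 0.05) <= 0.2

    def test_centering_invariance_under_arm_constant(self, sheet):
        track, _ = tm.simulate_promoter_track(n_probes=1200, seed=11)
        scaled = tm.biweight_scale(track)
        _, p1 = tm.chromosome_promoter_comparison(scaled, sheet, "chr7")
        shifted = scaled.scaled.copy()
        for s in sheet.samples_in_group("trisomy8"):
            shifted[s] = shifted[s] + 4.0
        scaled.scaled = shifted
        _, p2 = tm.chromosome_promoter_comparison(scaled, sheet, "chr7")
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_x_depletion_flagged_per_sample(self, sheet):
        track, _ = tm.simulate_promoter_track(
            n_probes=2500, seed=12, mark="5hmC", chrom_depletion={"chrX": -0.4},
        )
        out = tm.x_vs_autosome_comparison(tm.biweight_scale(track), sheet)
        assert (out["p"] < 0.05).all()
        assert (out["mean_X"] < out["mean_autosome"]).all()

    def test_rank_plot_is_permutation_of_levels(self, sheet):
        track, _ = tm.simulate_promoter_track(n_probes=1000, seed=13)
        scaled = tm.biweight_scale(track)
        ranked = tm.x_rank_plot_data(scaled, sheet)
        # values are sorted and conserve the underlying level multiset
        from trisomethyl.promoter import _promoter_levels

        levels = _promoter_levels(scaled, {s: [s] for s in scaled.sample_ids})
        sub = levels[levels["chrom"] == "chrX"]
        for s in scaled.sample_ids:
            expected = np.sort((sub[s] - levels[s].median()).to_numpy())
            np.testing.assert_allclose(ranked[s], expected)
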