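"""Fragment-size mixture EM, open-fragment selection, differential
accessibility with dependence labels, Fisher enrichment, and nucleosome
geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoclass.chromatin import (
    AccessibilityModel,
    FragmentSizeMixture,
    fisher_class_enrichment,
    motif_accessibility_scores,
    nucleosome_motif_overlap,
    occupancy_track,
    select_open_fragments,
)
from morphoclass.regions import GenomicInterval, Peak, Track
from _oracles import fisher_oracle
from morphoclass.synthetic import (
    SyntheticConfig,
    generate_world,
    simulate_atac_counts,
    simulate_fragments,
)


class TestFragmentMixture:
    def test_pure_exponential_recovers_degenerate_weight(self):
        cfg = SyntheticConfig(seed=3, frac_open=1.0, exp_rate=1 / 60)
        lengths, _ = simulate_fragments(cfg, 20_000)
        fit = FragmentSizeMixture(lengths).fit()
        assert fit.w >= 0.99

    def test_mixture_parameters_recovered_within_ten_percent(self):
        cfg = SyntheticConfig(
            seed=3, frac_open=0.6, exp_rate=1 / 60, nuc_mean=200, nuc_sd=30
        )
        lengths, _ = simulate_fragments(cfg, 100_000)
        fit = FragmentSizeMixture(lengths).fit()
        assert fit.converged
        for est, true in [(fit.w, 0.6), (fit.rate, 1 / 60),
                          (fit.mean, 200.0), (fit.sd, 30.0)]:
            assert abs(est - true) / true <= 0.10

    def test_loglik_nondecreasing_every_iteration(self):
        cfg = SyntheticConfig(seed=9, frac_open=0.5)
        lengths, _ = simulate_fragments(cfg, 5000)
        fit = FragmentSizeMixture(lengths).fit()
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-9).all()

    def test_model_implied_open_fraction_close_to_empirical(self):
        cfg = SyntheticConfig(seed=3)
        lengths, _ = simulate_fragments(cfg, 50_000)
        fit = FragmentSizeMixture(lengths).fit()
        implied = fit.open_fraction_below(100)
        empirical = float(np.mean(lengths <= 100))
        assert abs(implied - empirical) <= 0.05

    def test_too_few_lengths_rejected(self):
        with pytest.raises(ValueError):
            FragmentSizeMixture(np.full(50, 100.0))


class TestOpenFragments:
    def test_inclusive_cutoff(self):
        frags = [GenomicInterval("chr2L", 0, ln) for ln in (50, 100, 101)]
        kept = select_open_fragments(frags, cutoff=100)
        assert [len(f) for f in kept] == [50, 100]

    def test_all_longer_gives_empty(self):
        frags = [GenomicInterval("chr2L", 0, 200)]
        assert select_open_fragments(frags) == []

    def test_count_matches_brute_force(self, rng):
        lengths = rng.integers(1, 400, size=1000)
        frags = [GenomicInterval("chr2L", 0, int(ln)) for ln in lengths]
        assert len(select_open_fragments(frags)) == int((lengths <= 100).sum())


@pytest.fixture(scope="module")
def fitted(tiny_world):
    atac, is_bg = simulate_atac_counts(tiny_world)
    return tiny_world, AccessibilityModel(atac, "WT", "bcd-", is_bg).fit()


class TestDifferentialAccessibility:
    def test_dependence_sensitivity_and_specificity(self, fitted):
        world, res = fitted
        dep = res.dependent
        truth = world.bcd_dependent
        tp = (dep & truth).sum()
        tn = (~dep & ~truth).sum()
        assert tp / truth.sum() >= 0.9
        assert tn / (~truth).sum() >= 0.95

    def test_dependent_flag_invariant(self, fitted):
        _, res = fitted
        tab = res.table
        flagged = tab[tab.dependent]
        assert (flagged.q <= 0.05).all()
        assert (flagged.logfc > 0).all()

    def test_zero_mutant_counts_still_finite_logfc(self):
        from morphoclass.counts import CountMatrix, Sample

        regions = [GenomicInterval("chr2L", 0, 500)]
        samples = [Sample(f"WT_{r}", "WT", r) for r in (1, 2, 3)] + [
            Sample(f"mut_{r}", "bcd-", r) for r in (1, 2, 3)
        ]
        counts = np.array([[200, 210, 190, 0, 0, 0]])
        cm = CountMatrix(regions, samples, counts, np.full(6, 10_000))
        res = AccessibilityModel(cm, "WT", "bcd-").fit(dispersion=0.05)
        assert np.isfinite(res.table.logfc.iloc[0])
        assert bool(res.table.dependent.iloc[0])


class TestFisher:
    def _frame(self, a, b, c, d):
        labels = ["x"] * (a + b) + ["y"] * (c + d)
        flags = [True] * a + [False] * b + [True] * c + [False] * d
        return fisher_class_enrichment(labels, flags)

    def test_no_association(self):
        out = self._frame(5, 5, 5, 5)
        assert out.loc["x", "odds_ratio"] == pytest.approx(1.0)
        assert out.loc["x", "p"] == pytest.approx(1.0)

    def test_perfect_association_matches_oracle(self):
        out = self._frame(10, 0, 0, 10)
        assert out.loc["x", "p"] == pytest.approx(fisher_oracle(10, 0, 0, 10), rel=1e-9)
        # Haldane-corrected OR for the zero cells
        assert out.loc["x", "odds_ratio"] == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(40):
            a, b, c, d = rng.integers(0, 120, size=4)
            if a + b == 0 or c + d == 0 or a + b + c + d > 500:
                continue
            out = self._frame(int(a), int(b), int(c), int(d))
            assert out.loc["x", "p"] == pytest.approx(
                fisher_oracle(int(a), int(b), int(c), int(d)), rel=1e-7, abs=1e-12
            )

    def test_empty_class_impossible_by_construction(self):
        with pytest.raises(ValueError):
            fisher_class_enrichment([], [])


class TestMotifAccessibility:
    def test_bin_lookup_and_per_peak_mean(self):
        track = Track("chr2L", 10, np.array([0.0, 4.2, 0.0, 1.0, 3.0]))
        peaks = [Peak(GenomicInterval("chr2L", 0, 50), "p0")]
        motifs = pd.DataFrame(
            {"peak_id": ["p0", "p0"], "start": [12, 33], "end": [18, 39]}
        )
        out = motif_accessibility_scores({"chr2L": track}, motifs, peaks)
        # midpoints 15 and 36 fall in bins 1 (4.2) and 3 (1.0)
        assert out.loc["p0", "mean_score"] == pytest.approx((4.2 + 1.0) / 2)

    def test_motif_outside_track_excluded(self):
        track = Track("chr2L", 10, np.array([1.0]))
        peaks = [Peak(GenomicInterval("chr2L", 0, 5000), "p0")]
        motifs = pd.DataFrame({"peak_id": ["p0"], "start": [4000], "end": [4006]})
        out = motif_accessibility_scores({"chr2L": track}, motifs, peaks)
        assert len(out) == 0


class TestNucleosomeOverlap:
    def _run(self, dyads, motif_starts, width=6):
        peaks = [Peak(GenomicInterval("chr2L", 0, 10_000), "p0")]
        motifs = pd.DataFrame(
            {
                "peak_id": ["p0"] * len(motif_starts),
                "start": motif_starts,
                "end": [s + width for s in motif_starts],
            }
        )
        return nucleosome_motif_overlap(dyads, motifs, peaks, widen=160)

    def test_motif_on_dyad_is_associated(self):
        out = self._run([("chr2L", 1000)], [997])
        assert out.loc["p0", "open_fraction"] == 0.0

    def test_motif_100bp_away_is_open(self):
        # widened dyad spans +-80; a motif starting 100 bp away stays open
        out = self._run([("chr2L", 1000)], [1100])
        assert out.loc["p0", "open_fraction"] == 1.0

    def test_open_fraction_arithmetic(self):
        out = self._run([("chr2L", 1000)], [997, 3000, 4000, 5000])
        assert out.loc["p0", "open_fraction"] == pytest.approx(0.75)

    def test_peak_without_motifs_excluded(self):
        peaks = [Peak(GenomicInterval("chr2L", 0, 1000), "p0")]
        out = nucleosome_motif_overlap(
            [("chr2L", 100)], pd.DataFrame(columns=["peak_id", "start", "end"]), peaks
        )
        assert len(out) == 0


class TestOccupancyTrack:
    def test_single_dyad_bin_span(self):
        # 147 bp window on a dyad at 1000 spans [927, 1074): bins 92..107
        tracks = occupancy_track([("chr2L", 1000)], widen=147, bin_width=10)
        nonzero = np.nonzero(tracks["chr2L"].values)[0]
        assert nonzero.tolist() == list(range(92, 108))

    def test_no_dyads_gives_empty(self):
        assert occupancy_track([], chrom_lengths={"chr2L": 100})["chr2L"].values.sum() == 0

    def test_sum_aggregation_is_additive(self):
        d1 = [("chr2L", 500)]
        d2 = [("chr2L", 5000)]
        both = occupancy_track(d1 + d2, aggregate="sum", chrom_lengths={"chr2L": 10_000})
        t1 = occupancy_track(d1, aggregate="sum", chrom_lengths={"chr2L": 10_000})
        t2 = occupancy_track(d2, aggregate="sum", chrom_lengths={"chr2L": 10_000})
        np.testing.assert_allclose(
            both["chr2L"].values, t1["chr2L"].values + t2["chr2L"].values
        )

    def test_max_aggregation_caps_at_weight(self):
        tracks = occupancy_track(
            [("chr2L", 500), ("chr2L", 510)], weights=[0.6, 0.9], aggregate="max"
        )
        assert tracks["chr2L"].values.max() == pytest.approx(0.9)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            occupancy_track([("chr2L", 10)], weights=[1.5])
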