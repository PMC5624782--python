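"""Ground-truth generator: determinism, planted structure, and the
occupancy dose-response curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoclass.regions import overlaps
from morphoclass.synthetic import (
    CLASS_NAMES,
    SyntheticConfig,
    generate_world,
    occupancy,
    simulate_atac_counts,
    simulate_chip_counts,
    simulate_fragments,
    simulate_motifs_and_sequence,
    simulate_nucleosomes_and_annotations,
)


class TestOccupancy:
    def test_midpoint(self):
        assert occupancy(98.84, 98.84, 4) == pytest.approx(0.5)

    def test_saturation(self):
        assert occupancy(1e9, 98.84, 4) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_value(self):
        c, k, n = 242.61, 98.84, 4
        expected = c**n / (k**n + c**n)
        assert occupancy(c, k, n) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        k=st.floats(1.0, 500.0),
        n=st.floats(1.0, 6.0),
        c=st.floats(0.1, 1000.0),
        step=st.floats(1.01, 3.0),
    )
    def test_strictly_increasing_in_concentration(self, k, n, c, step):
        assert occupancy(c * step, k, n) > occupancy(c, k, n)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            occupancy(-1.0, 10.0, 2.0)
        with pytest.raises(ValueError):
            occupancy(1.0, 10.0, 0.5)


class TestWorldGeneration:
    def test_deterministic_given_seed(self, tiny_config):
        w1 = generate_world(tiny_config)
        w2 = generate_world(tiny_config)
        assert [(p.chrom, p.start, p.end, p.summit) for p in w1.peaks] == [
            (p.chrom, p.start, p.end, p.summit) for p in w2.peaks
        ]
        assert (w1.true_class == w2.true_class).all()
        assert (w1.bcd_dependent == w2.bcd_dependent).all()
        c1, _ = simulate_chip_counts(w1)
        c2, _ = simulate_chip_counts(w2)
        np.testing.assert_array_equal(c1.counts, c2.counts)

    def test_peak_counts_and_nonoverlap(self, tiny_world):
        assert tiny_world.n_peaks == 60
        assert overlaps(tiny_world.peaks, tiny_world.peaks) == [
            (i, i) for i in range(60)
        ]

    def test_background_and_noise_avoid_peaks(self, tiny_world):
        assert overlaps(tiny_world.noise_regions, tiny_world.peaks) == []
        assert overlaps(tiny_world.background_regions, tiny_world.peaks) == []

    def test_capacity_error_when_chromosome_too_small(self):
        cfg = SyntheticConfig(
            n_peaks={k: 100 for k in CLASS_NAMES},
            chrom_lengths={"chrS": 20_000},
            n_noise_regions=10,
            n_background_regions=10,
        )
        with pytest.raises(ValueError):
            generate_world(cfg)


class TestChipCounts:
    def test_poisson_limit_at_zero_dispersion(self, tiny_config):
        cfg = SyntheticConfig(**{**tiny_config.__dict__, "dispersion": 0.0, "seed": 8})
        world = generate_world(cfg)
        chip, is_noise = simulate_chip_counts(world, n_replicates=30)
        high = chip.counts[:, chip.columns("high")]
        m = high.mean(axis=1)
        v = high.var(axis=1, ddof=1)
        keep = m > 20
        # variance/mean ratio ~ 1 across many peaks under Poisson
        assert np.median(v[keep] / m[keep]) == pytest.approx(1.0, abs=0.15)

    def test_insensitive_class_is_saturated(self, tiny_world, tiny_chip):
        chip, _ = tiny_chip
        idx = tiny_world.class_indices("Insensitive")
        means = [
            chip.counts[idx][:, chip.columns(c)].mean() for c in ("low", "med", "high")
        ]
        assert max(means) / min(means) < 1.1

    def test_cs1_binding_drops_with_concentration(self, tiny_world, tiny_chip):
        chip, _ = tiny_chip
        idx = tiny_world.class_indices("CS-I")
        low = chip.counts[idx][:, chip.columns("low")].mean()
        high = chip.counts[idx][:, chip.columns("high")].mean()
        assert high > 5 * low

    def test_noise_regions_concentration_independent(self, tiny_chip):
        chip, is_noise = tiny_chip
        noise = chip.counts[is_noise]
        means = [noise[:, chip.columns(c)].mean() for c in ("low", "med", "high")]
        assert max(means) / min(means) < 1.15


class TestAtacCounts:
    def test_planted_dependence_effects(self, tiny_world):
        atac, is_bg = simulate_atac_counts(tiny_world)
        wt = atac.counts[: tiny_world.n_peaks][:, atac.columns("WT")].mean(axis=1)
        bcd = atac.counts[: tiny_world.n_peaks][:, atac.columns("bcd-")].mean(axis=1)
        dep = tiny_world.bcd_dependent
        assert (wt[dep] > bcd[dep]).all()
        # independent peaks keep comparable means
        ratio = wt[~dep] / np.maximum(bcd[~dep], 1)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.2)

    def test_unknown_genotype_rejected(self, tiny_world):
        with pytest.raises(ValueError):
            simulate_atac_counts(tiny_world, genotypes=("WT", "nonsense"))

    def test_uniform_lines_scale_with_occupancy(self, tiny_world):
        atac, _ = simulate_atac_counts(
            tiny_world, genotypes=("uBcd_low", "uBcd_high")
        )
        dep = tiny_world.bcd_dependent
        low = atac.counts[: tiny_world.n_peaks][:, atac.columns("uBcd_low")].mean(axis=1)
        high = atac.counts[: tiny_world.n_peaks][:, atac.columns("uBcd_high")].mean(axis=1)
        assert high[dep].sum() > low[dep].sum()


class TestFragments:
    def test_pure_exponential(self):
        cfg = SyntheticConfig(seed=3, frac_open=1.0, exp_rate=1 / 60)
        lengths, _ = simulate_fragments(cfg, 20_000)
        assert lengths.mean() == pytest.approx(60, rel=0.05)

    def test_pure_gaussian(self):
        cfg = SyntheticConfig(seed=3, frac_open=0.0, nuc_mean=200, nuc_sd=30)
        lengths, _ = simulate_fragments(cfg, 20_000)
        assert lengths.mean() == pytest.approx(200, rel=0.02)

    def test_lengths_at_least_one_and_match_intervals(self):
        cfg = SyntheticConfig(seed=3)
        lengths, intervals = simulate_fragments(cfg, 5000)
        assert lengths.min() >= 1
        assert [len(iv) for iv in intervals] == lengths.tolist()

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_fragments(SyntheticConfig(), 0)


class TestMotifsAndNucleosomes:
    def test_planted_motifs_lie_inside_their_peaks(self, tiny_world):
        motifs = simulate_motifs_and_sequence(tiny_world)
        by_id = {p.id: p for p in tiny_world.peaks}
        for row in motifs.itertuples():
            peak = by_id[row.peak_id]
            assert peak.start <= row.start < row.end <= peak.end

    def test_planted_sequence_contains_consensus(self, tiny_world):
        motifs = tiny_world.planted_motifs
        row = motifs[(motifs.motif == "bcd_strong") & (motifs.strand == "+")].iloc[0]
        seq = tiny_world.sequences[row.peak_id]
        assert seq[row.offset : row.offset + 6] == "TAATCC"

    def test_dyads_near_motifs_of_closed_peaks(self, tiny_world):
        dyads = simulate_nucleosomes_and_annotations(tiny_world, "bcd-")
        motifs = tiny_world.planted_motifs
        closed = {
            tiny_world.peaks[i].id
            for i in np.nonzero(tiny_world.bcd_dependent)[0]
        }
        bcd_motifs = motifs[(motifs.motif != "zld") & motifs.peak_id.isin(closed)]
        positions = {}
        for chrom, pos in dyads:
            positions.setdefault(chrom, []).append(pos)
        by_id = {p.id: p for p in tiny_world.peaks}
        for pid in bcd_motifs.peak_id.unique():
            peak = by_id[pid]
            rows = bcd_motifs[bcd_motifs.peak_id == pid]
            near = [
                pos
                for pos in positions.get(peak.chrom, [])
                if any(abs(pos - (r.start + r.end) // 2) <= 80 for r in rows.itertuples())
            ]
            assert near, f"no dyad within 80 bp of motifs in closed peak {pid}"

    def test_wild_type_open_peaks_have_no_planted_dyads(self, tiny_world):
        dyads = simulate_nucleosomes_and_annotations(tiny_world, "WT")
        # WT plants no closed-peak dyads; remaining background dyads avoid peaks
        positions = {}
        for chrom, pos in dyads:
            positions.setdefault(chrom, []).append(pos)
        for peak in tiny_world.peaks:
            for pos in positions.get(peak.chrom, []):
                assert not (peak.summit - 73 <= pos <= peak.summit + 73)
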