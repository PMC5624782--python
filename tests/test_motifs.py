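"""PWM construction/scanning against a naive oracle and permutation tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from morphoclass.motifs import (
    build_pwm,
    class_enrichment_permutation,
    group_difference_permutation,
    motif_counts_per_peak,
    read_jaspar,
    scan_pwm,
)
from morphoclass.regions import GenomicInterval, Peak

BASES = "ACGT"
RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq):
    return "".join(RC[b] for b in reversed(seq))


def naive_scan(seq, pwm, threshold_frac, both_strands=True):
    """Independent oracle: score every offset/strand with explicit loops."""
    lo = pwm.log_odds
    cutoff = pwm.min_score + threshold_frac * (pwm.max_score - pwm.min_score)
    hits = []
    targets = [("+", seq)]
    if both_strands:
        targets.append(("-", revcomp(seq)))
    for strand, s in targets:
        for off in range(len(s) - pwm.length + 1):
            score = 0.0
            for j in range(pwm.length):
                base = s[off + j]
                score += lo[BASES.index(base), j] if base in BASES else 0.0
            if score >= cutoff - 1e-12:
                fwd_off = off if strand == "+" else len(seq) - pwm.length - off
                hits.append((fwd_off, strand, round(score, 9)))
    return sorted(hits)


class TestBuildPwm:
    def test_consensus_column_probabilities(self):
        pwm = build_pwm("TAATCC", pseudo_weight=0.01)
        assert pwm.matrix[BASES.index("T"), 0] == pytest.approx(0.97)
        assert pwm.matrix[BASES.index("A"), 0] == pytest.approx(0.01)

    def test_degenerate_letter_splits_mass(self):
        pwm = build_pwm("NAAA", pseudo_weight=0.01)
        np.testing.assert_allclose(pwm.matrix[:, 0], 0.25)

    def test_max_score_is_sum_of_column_maxima(self):
        pwm = build_pwm("TAATCC")
        assert pwm.max_score == pytest.approx(pwm.log_odds.max(axis=0).sum())

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            build_pwm("TAAX")

    def test_jaspar_counts_round_trip(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">M1 test\n"
            "A [ 0 10  0  0 ]\n"
            "C [ 0  0 10  0 ]\n"
            "G [ 0  0  0 10 ]\n"
            "T [10  0  0  0 ]\n"
        )
        (pwm,) = read_jaspar(path, pseudo_weight=0.1)
        assert pwm.length == 4
        # consensus TACG dominates every column
        hits = scan_pwm("GGTACGGG", pwm, 0.9, both_strands=False)
        assert [h.offset for h in hits] == [2]


class TestScanPwm:
    def test_planted_consensus_found_with_full_score(self, rng):
        seq = "".join(rng.choice(list(BASES), size=200))
        seq = seq[:80] + "TAATCC" + seq[86:]
        pwm = build_pwm("TAATCC")
        hits = [h for h in scan_pwm(seq, pwm, 0.95) if h.strand == "+"]
        assert any(h.offset == 80 and h.score_fraction == pytest.approx(1.0)
                   for h in hits)

    def test_reverse_complement_hit_on_minus_strand(self):
        seq = "G" * 30 + revcomp("TAATCC") + "G" * 30
        pwm = build_pwm("TAATCC")
        hits = scan_pwm(seq, pwm, 0.95)
        assert len(hits) == 1
        assert hits[0].strand == "-" and hits[0].offset == 30

    def test_sequence_shorter_than_motif(self):
        assert scan_pwm("ACG", build_pwm("TAATCC")) == []

    def test_n_scores_as_background(self):
        pwm = build_pwm("TAAT")
        hits = scan_pwm("NNNN", pwm, threshold_frac=0.01)
        oracle = naive_scan("NNNN", pwm, 0.01, both_strands=False)
        assert len([h for h in hits if h.strand == "+"]) == len(oracle)

    @pytest.mark.parametrize("threshold", [0.6, 0.8, 0.95])
    def test_matches_naive_oracle_on_random_sequence(self, rng, threshold):
        seq = "".join(rng.choice(list(BASES), size=1000))
        pwm = build_pwm("TAATCCV", pseudo_weight=0.05)
        hits = scan_pwm(seq, pwm, threshold)
        got = sorted((h.offset, h.strand, round(h.score, 9)) for h in hits)
        assert got == naive_scan(seq, pwm, threshold)

    def test_raising_threshold_never_adds_hits(self, rng):
        seq = "".join(rng.choice(list(BASES), size=2000))
        pwm = build_pwm("TAATCC", pseudo_weight=0.05)
        counts = [len(scan_pwm(seq, pwm, t)) for t in (0.5, 0.7, 0.8, 0.9, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_hit_fraction_at_least_threshold(self, rng):
        seq = "".join(rng.choice(list(BASES), size=1000))
        pwm = build_pwm("TAATCC", pseudo_weight=0.05)
        for h in scan_pwm(seq, pwm, 0.8):
            assert h.score_fraction >= 0.8 - 1e-9


class TestCounts:
    def test_per_peak_counts_and_conservation(self):
        peaks = [
            Peak(GenomicInterval("chr2L", 0, 100), "p0"),
            Peak(GenomicInterval("chr2L", 200, 300), "p1"),
        ]
        hits = pd.DataFrame(
            {"peak_id": ["p0", "p0", "p0", "p1"], "motif": ["m"] * 4}
        )
        out = motif_counts_per_peak(peaks, hits)
        assert out.loc["p0", "m"] == 3
        assert out.loc["p1", "m"] == 1
        assert out["m"].sum() == len(hits)


class TestClassEnrichment:
    def test_whole_set_as_class_gives_fold_one(self, rng):
        counts = pd.DataFrame({"m": rng.poisson(2, size=50)})
        (res,) = class_enrichment_permutation(counts, ["all"] * 50, n_perm=200, seed=1)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_shuffled_labels_are_mostly_null(self, rng):
        counts = pd.DataFrame(
            {m: rng.poisson(2, size=200) for m in ("m1", "m2", "m3")}
        )
        labels = rng.permutation(["a"] * 50 + ["b"] * 50 + ["c"] * 100)
        results = class_enrichment_permutation(counts, labels, n_perm=500, seed=2)
        sig = [r for r in results if r.p <= 0.05]
        assert len(sig) <= max(1, int(0.15 * len(results)))

    def test_planted_enrichment_detected(self, rng):
        base = rng.poisson(1.0, size=200)
        base[:40] = rng.poisson(3.0, size=40)  # 3x enrichment in the first class
        counts = pd.DataFrame({"m": base})
        labels = ["hot"] * 40 + ["cold"] * 160
        results = class_enrichment_permutation(counts, labels, n_perm=2000, seed=11)
        hot = next(r for r in results if r.klass == "hot")
        assert hot.p <= 0.001
        assert hot.fold > 2.0

    def test_class_larger_than_peak_set_rejected(self):
        counts = pd.DataFrame({"m": [1, 2]})
        with pytest.raises(ValueError):
            class_enrichment_permutation(counts, ["a"], n_perm=100)


class TestGroupDifference:
    def test_no_effect_gives_large_p(self):
        p = group_difference_permutation([1, 2, 3], [1, 2, 3], n_perm=999, seed=3)
        assert p >= 0.5

    def test_complete_separation_hits_floor(self):
        p = group_difference_permutation(
            [10, 11, 12], [1, 2, 3], n_perm=999, seed=3
        )
        assert p <= 0.11  # best achievable with 3+3: 1/C(6,3) = 0.05 exact

    def test_exact_matches_independent_enumeration(self, rng):
        a = rng.normal(1, 1, size=3)
        b = rng.normal(0, 1, size=3)
        p = group_difference_permutation(a, b, exact=True)
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        diffs = [
            pooled[list(idx)].mean()
            - np.delete(pooled, list(idx)).mean()
            for idx in itertools.combinations(range(6), 3)
        ]
        expected = np.mean([d >= obs - 1e-12 for d in diffs])
        assert p == pytest.approx(expected)

    def test_sampled_p_consistent_with_exact(self, rng):
        a = rng.normal(1, 1, size=3)
        b = rng.normal(0, 1, size=3)
        exact = group_difference_permutation(a, b, exact=True)
        sampled = group_difference_permutation(a, b, n_perm=20_000, seed=5)
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            group_difference_permutation([], [1], n_perm=10)
        with pytest.raises(ValueError):
            group_difference_permutation([1], [1], n_perm=0)
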