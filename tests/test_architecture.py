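import numpy as np
import pytest

from promarch.architecture import (
    DEFAULT_GRID,
    compute_composition,
    count_metrics,
    estimate_boundary,
    pairwise_overlap_percent,
    stacking_test,
    summarize_distribution,
)
from promarch.intervals import GenomicInterval, PromoterWindow, TranscriptAnnotation


def _peaks(labels, chrom="chr1"):
    return [GenomicInterval(chrom, 10 * i, 10 * i + 5, ".", 500, lab) for i, lab in enumerate(labels)]


class TestCountMetrics:
    def test_four_variants(self):
        prof = count_metrics({"t": _peaks(["A", "A", "Pol2"])}, pol2_labels={"Pol2"})["t"]
        assert (prof.tfbs_total, prof.tfbs_unique, prof.tfbs_total_nopol2, prof.tfbs_unique_nopol2) == (3, 2, 2, 1)

    def test_no_peaks(self):
        prof = count_metrics({"t": []})["t"]
        assert (prof.tfbs_total, prof.tfbs_unique, prof.tfbs_total_nopol2, prof.tfbs_unique_nopol2) == (0, 0, 0, 0)

    def test_invariant_to_peak_order(self, rng):
        labels = list(rng.choice(["A", "B", "Pol2", "C"], size=30))
        peaks = _peaks(labels)
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        a = count_metrics({"t": peaks})["t"]
        b = count_metrics({"t": shuffled})["t"]
        assert a == b

    def test_total_and_unique_nearly_collinear_at_low_multiplicity(self, small_world):
        # Distinct-label counting barely changes the metric when few promoters
        # bind the same TF twice (the real-data analogue was r = 0.9929).
        from promarch.association import correlate
        from promarch.intervals import map_peaks_to_windows, promoter_window

        anns = small_world["annotations"]
        mapped = map_peaks_to_windows([promoter_window(t, 500) for t in anns], small_world["peaks"])
        profs = count_metrics(mapped)
        tot = [p.tfbs_total for p in profs.values()]
        uni = [p.tfbs_unique for p in profs.values()]
        assert correlate(tot, uni).r > 0.95


class TestSummarizeDistribution:
    def test_set_is_its_own_summary(self):
        s = summarize_distribution([0, 0, 4, 14, 58])
        assert s.tukey_five == (0, 0, 4, 14, 58)

    def test_hinges_for_even_n(self):
        s = summarize_distribution([1, 2, 3, 4])
        assert s.tukey_five == (1, 1.5, 2.5, 3.5, 4)

    def test_small_count_percentages(self):
        s = summarize_distribution([1, 2, 6, 7])
        assert s.pct_le5tf == 50.0
        assert s.pct_1tf == 25.0 and s.pct_2tf == 25.0

    def test_appending_new_max_raises_only_max_and_mean(self):
        x = [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
        a = summarize_distribution(x)
        b = summarize_distribution(x + [max(x) + 1])
        assert b.tukey_five[4] > a.tukey_five[4]
        assert b.mean > a.mean
        assert b.tukey_five[2] == pytest.approx(a.tukey_five[2], abs=0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_distribution([])


class TestComposition:
    @pytest.mark.parametrize(
        "seq,gc,cpg,oe",
        [("ATAT", 0.0, 0, 0.0), ("CGCG", 1.0, 2, 2.0), ("ACGT", 0.5, 1, 4.0)],
    )
    def test_hand_computed_profiles(self, seq, gc, cpg, oe):
        p = compute_composition(seq)
        assert (p.gc, p.cpg_count, p.cpg_oe) == (gc, cpg, oe)

    def test_n_bases_excluded_from_denominators(self):
        p = compute_composition("ACGTNN")
        assert p.gc == 0.5

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_composition("")


class TestBoundary:
    def test_recovers_planted_enrichment_scale(self, small_world):
        cfg = small_world["config"]
        est = estimate_boundary(small_world["annotations"], small_world["peaks"])
        gi = DEFAULT_GRID.index(3000)
        assert est.boundary in DEFAULT_GRID[gi - 1 : gi + 2]
        assert cfg.enrichment_scale == 3000

    def test_uniform_background_gives_first_grid_point(self):
        # evenly spaced peaks = an exactly uniform background: the derivative
        # is constant, so no transformation point exists
        anns = [TranscriptAnnotation(f"t{i}", "chr1", "+", 100_000 + 50_000 * i) for i in range(20)]
        peaks = [GenomicInterval("chr1", s, s + 100) for s in range(0, 1_200_000, 500)]
        est = estimate_boundary(anns, peaks)
        assert est.boundary == DEFAULT_GRID[0]

    def test_grid_validation(self, small_world):
        with pytest.raises(ValueError):
            estimate_boundary(small_world["annotations"], small_world["peaks"], grid=[100, 200, 300])
        with pytest.raises(ValueError):
            estimate_boundary(small_world["annotations"], small_world["peaks"], grid=[5, 4, 3, 2, 1])


class TestPairwiseOverlap:
    def test_identical_disjoint_and_partial(self):
        a = GenomicInterval("chr1", 0, 10)
        assert pairwise_overlap_percent([a, a]) == [100.0]
        b = GenomicInterval("chr1", 20, 30)
        assert pairwise_overlap_percent([a, b]) == [0.0]
        c = GenomicInterval("chr1", 5, 15)
        assert pairwise_overlap_percent([a, c]) == [pytest.approx(100 * 5 / 15)]

    def test_fewer_than_two_peaks(self):
        assert pairwise_overlap_percent([GenomicInterval("chr1", 0, 10)]) == []

    def test_pair_count(self):
        peaks = [GenomicInterval("chr1", i, i + 5) for i in range(0, 50, 10)]
        assert len(pairwise_overlap_percent(peaks)) == 5 * 4 // 2


def _two_peak_promoters(rng, n=300, stacked=False):
    out = []
    for i in range(n):
        base = i * 10_000
        w = PromoterWindow(f"t{i}", GenomicInterval("chr1", base, base + 1000), 500)
        peaks = []
        for _ in range(2):
            length = int(rng.integers(150, 350))
            if stacked:
                start = base + 400
            else:
                start = int(rng.integers(base, base + 1000 - length))
            peaks.append(GenomicInterval("chr1", start, start + length, ".", 500, "X"))
        out.append((w, peaks))
    return out


class TestStacking:
    def test_planted_stacking_detected(self, rng):
        data = _two_peak_promoters(rng, stacked=True)
        res = stacking_test(data, n_randomizations=1, seed=7)
        assert res.observed_mean_overlap_pct > 2 * res.null_mean_overlap_pct
        assert res.p_value < 0.01
        assert res.n_pairs >= 100

    def test_uniform_placement_rarely_significant(self):
        sig = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(900 + s)
            data = _two_peak_promoters(rng, stacked=False)
            res = stacking_test(data, n_randomizations=2, seed=3000 + s)
            sig += res.p_value < 0.01
        assert sig / n_seeds <= 0.05

    def test_deterministic_given_seed(self, rng):
        data = _two_peak_promoters(rng)
        a = stacking_test(data, seed=5)
        b = stacking_test(data, seed=5)
        assert a == b

    def test_requires_a_multi_peak_promoter(self):
        w = PromoterWindow("t", GenomicInterval("chr1", 0, 1000), 500)
        with pytest.raises(ValueError):
            stacking_test([(w, [GenomicInterval("chr1", 10, 20)])])
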