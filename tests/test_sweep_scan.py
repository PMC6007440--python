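"""Fst, d_i, windowing, empirical region calling, ΔCLR, region annotation."""

import numpy as np
import pytest

from popsweep import (
    CLRTrack,
    FstMatrix,
    GenomeLayout,
    RegionSet,
    ValidationError,
    annotate_regions_with_genes,
    delta_clr,
    di_statistic,
    empirical_top_regions,
    fst_matrix,
    hudson_fst,
    overlap_fraction,
    pairwise_fst,
    weir_cockerham_fst,
    window_mean,
)
from popsweep.allele_stats import FreqTable


def _freq_table(freqs, counts):
    freqs = np.asarray(freqs, dtype=float)
    counts = np.asarray(counts, dtype=np.int64)
    n = freqs.shape[1]
    return FreqTable(
        np.full(n, "1", dtype=object),
        np.arange(1, n + 1, dtype=np.int64) * 100,
        ("MS", "DU", "TB")[: freqs.shape[0]],
        freqs,
        counts,
    )


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        assert hudson_fst(1.0, 10, 0.0, 10) == pytest.approx(1.0)

    def test_equal_frequencies_nonpositive(self):
        for p in (0.1, 0.5, 0.9):
            v = hudson_fst(p, 20, p, 30)
            assert v <= 0
            expected_num = -p * (1 - p) * (1 / 19 + 1 / 29)
            den = 2 * p * (1 - p)
            assert v == pytest.approx(expected_num / den)

    def test_same_allele_monomorphic_undefined(self):
        assert np.isnan(hudson_fst(0.0, 10, 0.0, 10))
        assert np.isnan(hudson_fst(1.0, 10, 1.0, 10))

    def test_tiny_sample_undefined(self):
        assert np.isnan(hudson_fst(0.5, 1, 0.5, 10))

    def test_negative_values_retained(self):
        assert hudson_fst(0.5, 4, 0.5, 4) < 0

    def test_wc_estimator_agrees_on_fixed_difference(self):
        assert weir_cockerham_fst(1.0, 10, 0.0, 10) == pytest.approx(1.0)


class TestDiStatistic:
    def _fst_matrix(self, fst_md, fst_mt, mean=(0.1, 0.2), sd=(0.05, 0.1)):
        n = len(fst_md)
        return FstMatrix(
            np.full(n, "1", dtype=object),
            np.arange(1, n + 1, dtype=np.int64),
            {("MS", "DU"): np.asarray(fst_md, float),
             ("MS", "TB"): np.asarray(fst_mt, float)},
            {("MS", "DU"): mean[0], ("MS", "TB"): mean[1]},
            {("MS", "DU"): sd[0], ("MS", "TB"): sd[1]},
        )

    def test_at_means_is_zero(self):
        fm = self._fst_matrix([0.1], [0.2])
        assert di_statistic(fm, "MS")[0] == pytest.approx(0.0)

    def test_one_sd_above_gives_two(self):
        fm = self._fst_matrix([0.15], [0.3])
        assert di_statistic(fm, "MS")[0] == pytest.approx(2.0)

    def test_zero_sd_rejected(self):
        fm = self._fst_matrix([0.1], [0.2], sd=(0.0, 0.1))
        with pytest.raises(ValidationError, match="degenerate"):
            di_statistic(fm, "MS")

    def test_standardized_terms_have_zero_mean_unit_sd(self, rng):
        """Per-pair z-scored Fst has mean 0 and sd 1 by construction."""
        freqs = rng.random((3, 500))
        counts = np.full((3, 500), 40, dtype=np.int64)
        ft = _freq_table(freqs, counts)
        fm = fst_matrix(ft, [("MS", "DU"), ("MS", "TB")])
        for pair in fm.pairs:
            v = fm.pairs[pair]
            z = (v[~np.isnan(v)] - fm.mean[pair]) / fm.sd[pair]
            assert abs(z.mean()) < 1e-12
            assert abs(z.std() - 1) < 1e-12

    def test_location_shift_absorbed_by_standardization(self, rng):
        """Adding a constant to one pair's Fst leaves its z-scores unchanged
        after moment recomputation."""
        v = rng.random(200)
        z0 = (v - v.mean()) / v.std()
        w = v + 0.37
        z1 = (w - w.mean()) / w.std()
        assert np.allclose(z0, z1)

    def test_undefined_pair_propagates(self):
        fm = self._fst_matrix([0.1, np.nan], [0.2, 0.2])
        d = di_statistic(fm, "MS")
        assert np.isnan(d[1]) and not np.isnan(d[0])

    def test_moments_respect_layout(self, rng):
        """Sites off the layout's chromosomes are excluded from moments."""
        n = 100
        freqs = rng.random((2, n))
        ft = FreqTable(
            np.asarray(["1"] * 50 + ["X"] * 50, dtype=object),
            np.concatenate([np.arange(1, 51), np.arange(1, 51)]).astype(np.int64),
            ("MS", "DU"),
            freqs,
            np.full((2, n), 40, dtype=np.int64),
        )
        autosomes = GenomeLayout(("1",), (1000,))
        fm = fst_matrix(ft, [("MS", "DU")], layout=autosomes)
        v = fm.pairs[("MS", "DU")]
        keep = ~np.isnan(v[:50])
        assert fm.mean[("MS", "DU")] == pytest.approx(np.mean(v[:50][keep]))


class TestWindowMean:
    def test_simple_mean(self):
        gl = GenomeLayout(("1",), (200_000,))
        t = window_mean(
            np.asarray(["1", "1"], dtype=object),
            np.asarray([10_000, 90_000]),
            np.asarray([1.0, 3.0]),
            gl, size=100_000, min_snvs=1,
        )
        assert t.value[0] == pytest.approx(2.0)

    def test_half_open_boundary(self):
        gl = GenomeLayout(("1",), (300_000,))
        t = window_mean(
            np.asarray(["1"], dtype=object),
            np.asarray([100_000]),
            np.asarray([5.0]),
            gl, size=100_000, min_snvs=1,
        )
        assert np.isnan(t.value[0]) and t.value[1] == 5.0

    def test_min_snvs_masking(self):
        gl = GenomeLayout(("1",), (100_000,))
        t = window_mean(
            np.asarray(["1"], dtype=object),
            np.asarray([10]), np.asarray([1.0]),
            gl, size=100_000, min_snvs=2,
        )
        assert np.isnan(t.value[0]) and t.n_snvs[0] == 1

    def test_matches_groupby_oracle(self, rng):
        gl = GenomeLayout(("1", "2"), (1_000_000, 500_000))
        n = 5_000
        chrom = np.where(rng.random(n) < 0.7, "1", "2").astype(object)
        length = np.where(chrom == "1", 1_000_000, 500_000)
        pos0 = (rng.random(n) * length).astype(np.int64)
        vals = rng.normal(size=n)
        vals[rng.random(n) < 0.1] = np.nan
        t = window_mean(chrom, pos0, vals, gl, size=100_000, min_snvs=1)
        for w in range(len(t)):
            on = (
                (chrom == t.chrom[w])
                & (pos0 >= t.start[w])
                & (pos0 < t.start[w] + 100_000)
                & ~np.isnan(vals)
            )
            if on.sum() == 0:
                assert np.isnan(t.value[w])
            else:
                assert t.value[w] == pytest.approx(vals[on].mean())

    def test_tsv_roundtrip(self, tmp_path, rng):
        gl = GenomeLayout(("1",), (500_000,))
        pos0 = np.sort(rng.integers(0, 500_000, size=100))
        t = window_mean(np.full(100, "1", dtype=object), pos0,
                        rng.normal(size=100), gl, size=100_000, min_snvs=1)
        p = tmp_path / "track.tsv"
        t.to_tsv(p)
        from popsweep import WindowTrack

        back = WindowTrack.from_tsv(p)
        assert np.allclose(back.value, t.value, equal_nan=True)
        assert back.start.tolist() == t.start.tolist()


class TestEmpiricalTopRegions:
    def _track(self, values):
        n = len(values)
        gl = GenomeLayout(("1",), (n * 1000,))
        chrom, start, end = gl.windows(1000)
        from popsweep import WindowTrack

        return WindowTrack(chrom, start, end,
                           np.asarray(values, float), np.full(n, 10, dtype=np.int64))

    def test_order_statistics(self):
        t = self._track(np.arange(1, 201))
        regions, thr = empirical_top_regions(t, tail=0.01)
        # exactly the top 2 of 200 distinct values exceed the 99th percentile
        assert regions.total_length() == 2000
        assert thr < 199 and thr > 198

    def test_adjacent_windows_merge(self):
        vals = np.zeros(200)
        vals[50] = 10.0
        vals[51] = 9.0
        t = self._track(vals)
        regions, _ = empirical_top_regions(t, tail=0.01)
        assert len(regions) == 1
        assert (regions.start[0], regions.end[0]) == (50_000, 52_000)
        assert regions.score[0] == pytest.approx(10.0)

    def test_never_selects_more_than_tail_allows(self, rng):
        t = self._track(rng.normal(size=300))
        regions, thr = empirical_top_regions(t, tail=0.05)
        n_selected = int(np.sum(t.value > thr))
        assert n_selected <= int(np.ceil(0.05 * 300))

    def test_all_masked_rejected(self):
        t = self._track([np.nan, np.nan])
        with pytest.raises(ValidationError):
            empirical_top_regions(t)


class TestDeltaClr:
    def _clr(self, pop, values, spacing=1000):
        n = len(values)
        return CLRTrack(
            pop,
            np.full(n, "1", dtype=object),
            np.arange(n, dtype=np.int64) * spacing,
            np.asarray(values, float),
        )

    def test_stated_formula(self):
        gl = GenomeLayout(("1",), (1000,))
        t = delta_clr(self._clr("MS", [10.0]), (self._clr("DU", [4.0]),
                                                self._clr("TB", [2.0])), gl, size=1000)
        assert t.value[0] == pytest.approx(7.0)

    def test_identical_tracks_zero(self, rng):
        vals = rng.random(50) * 5
        gl = GenomeLayout(("1",), (50_000,))
        t = delta_clr(self._clr("MS", vals), (self._clr("DU", vals),
                                              self._clr("TB", vals)), gl, size=10_000)
        assert np.allclose(t.value[t.unmasked], 0.0)

    def test_matches_per_window_oracle(self, rng):
        gl = GenomeLayout(("1",), (100_000,))
        tracks = [self._clr(p, rng.random(100) * 10) for p in ("MS", "DU", "TB")]
        t = delta_clr(tracks[0], (tracks[1], tracks[2]), gl, size=10_000)
        for w in range(len(t)):
            sel = slice(w * 10, (w + 1) * 10)
            want = (tracks[0].clr[sel].mean()
                    - (tracks[1].clr[sel].mean() + tracks[2].clr[sel].mean()) / 2)
            assert t.value[w] == pytest.approx(want)

    def test_window_without_grid_masked(self):
        gl = GenomeLayout(("1",), (20_000,))
        t = delta_clr(self._clr("MS", [1.0]), (self._clr("DU", [1.0]),
                                               self._clr("TB", [1.0])), gl, size=10_000)
        assert np.isnan(t.value[1])


class TestOverlapAndAnnotation:
    def test_overlap_example(self):
        a = RegionSet(np.asarray(["1"], dtype=object), np.asarray([0]), np.asarray([100]))
        b = RegionSet(np.asarray(["1"], dtype=object), np.asarray([50]), np.asarray([150]))
        frac, inter = overlap_fraction(a, b)
        assert frac == 1.0
        assert (inter.start[0], inter.end[0]) == (50, 100)

    def test_disjoint_zero(self):
        a = RegionSet(np.asarray(["1"], dtype=object), np.asarray([0]), np.asarray([10]))
        b = RegionSet(np.asarray(["1"], dtype=object), np.asarray([20]), np.asarray([30]))
        frac, inter = overlap_fraction(a, b)
        assert frac == 0.0 and len(inter) == 0

    def test_empty_query_flagged_zero(self):
        b = RegionSet(np.asarray(["1"], dtype=object), np.asarray([0]), np.asarray([10]))
        frac, _ = overlap_fraction(RegionSet.empty(), b)
        assert frac == 0.0

    def test_fraction_matches_bruteforce(self, rng):
        def rand_regions(n):
            s = rng.integers(0, 9_000, size=n)
            return RegionSet(np.full(n, "1", dtype=object), s,
                             s + rng.integers(1, 800, size=n))

        a, b = rand_regions(100), rand_regions(100)
        frac, _ = overlap_fraction(a, b)
        brute = np.mean([
            any(bs < ae and be > as_ for bs, be in zip(b.start, b.end))
            for as_, ae in zip(a.start, a.end)
        ])
        assert frac == pytest.approx(brute)

    def test_gene_annotation(self):
        regions = RegionSet(np.asarray(["1", "1"], dtype=object),
                            np.asarray([0, 100_000]), np.asarray([100_000, 200_000]))
        genes = RegionSet(
            np.asarray(["1", "1"], dtype=object),
            np.asarray([50_000, 90_000]),
            np.asarray([60_000, 110_000]),
            np.asarray(["geneA", "geneB"], dtype=object),
        )
        per_region, n_unique = annotate_regions_with_genes(regions, genes)
        assert per_region == [["geneA", "geneB"], ["geneB"]]
        assert n_unique == 2  # spanning gene counted once globally

    def test_unnamed_gene_rejected(self):
        regions = RegionSet(np.asarray(["1"], dtype=object), np.asarray([0]), np.asarray([10]))
        genes = RegionSet(np.asarray(["1"], dtype=object), np.asarray([0]), np.asarray([10]))
        with pytest.raises(ValidationError):
            annotate_regions_with_genes(regions, genes)


def test_pairwise_fst_formula_oracle(rng):
    """Vectorized Hudson estimator equals an independently coded scalar
    evaluation of the formula."""
    for _ in range(50):
        p1, p2 = rng.random(2)
        n1, n2 = rng.integers(4, 200, size=2)
        got = hudson_fst(p1, n1, p2, n2)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert got == pytest.approx(num / den, abs=1e-14)
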