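"""Binned-coverage stages: binning, per-bin means, CPM, control
subtraction, denylist filtering, z-scoring, rolling smoothing."""

import numpy as np
import pandas as pd
import pytest

from chromdiff import binning
from chromdiff.binning import BinMatrix, StageError
from chromdiff.intervals import IntervalSet
from chromdiff.synthetic import GenomeLayout


def layout_of(*lengths, bin_size=1000):
    names = tuple(f"chr{i+1}" for i in range(len(lengths)))
    return GenomeLayout(names, tuple(lengths), bin_size)


def matrix(values, stage="raw", bin_size=1000, chrom=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n = values.shape[0]
    chroms = chrom if chrom is not None else ["chr1"] * n
    starts = []
    counter = {}
    for c in chroms:
        i = counter.get(c, 0)
        starts.append(i * bin_size)
        counter[c] = i + 1
    bins = IntervalSet(chroms, starts, [s + bin_size for s in starts])
    samples = [f"s{j}" for j in range(values.shape[1])]
    return BinMatrix(bins, values, samples, stage)


class TestMakeBins:
    def test_truncates_terminal_bin(self):
        bins = binning.make_bins(layout_of(2500))
        assert list(bins) == [
            ("chr1", 0, 1000, "."), ("chr1", 1000, 2000, "."),
            ("chr1", 2000, 2500, "."),
        ]

    def test_exact_fit_single_bin(self):
        assert list(binning.make_bins(layout_of(1000))) == [("chr1", 0, 1000, ".")]

    def test_orders_chromosomes(self):
        bins = binning.make_bins(layout_of(1500, 500))
        assert len(bins) == 3
        assert list(bins.chroms) == ["chr1", "chr1", "chr2"]

    def test_rejects_nonpositive_bin_size(self):
        with pytest.raises(ValueError):
            binning.make_bins(layout_of(1000), 0)


class TestReadCoverage:
    def write(self, tmp_path, rows):
        p = tmp_path / "t.bedgraph"
        p.write_text("".join(f"{c}\t{s}\t{e}\t{v}\n" for c, s, e, v in rows))
        return p

    def test_full_bin_record(self, tmp_path):
        bins = binning.make_bins(layout_of(1000))
        v = binning.read_coverage(self.write(tmp_path, [("chr1", 0, 1000, 4)]), bins)
        assert v.tolist() == [4.0]

    def test_half_covered_bin_averages_with_zeros(self, tmp_path):
        bins = binning.make_bins(layout_of(1000))
        v = binning.read_coverage(self.write(tmp_path, [("chr1", 0, 500, 4)]), bins)
        assert v.tolist() == [2.0]

    def test_weighted_mean_of_two_records(self, tmp_path):
        bins = binning.make_bins(layout_of(1000))
        v = binning.read_coverage(
            self.write(tmp_path, [("chr1", 0, 600, 1), ("chr1", 600, 1000, 6)]), bins
        )
        assert v.tolist() == [(600 * 1 + 400 * 6) / 1000]

    def test_record_spanning_bins_distributes_mass(self, tmp_path):
        bins = binning.make_bins(layout_of(3000))
        v = binning.read_coverage(
            self.write(tmp_path, [("chr1", 500, 2500, 3)]), bins
        )
        assert v.tolist() == [1.5, 3.0, 1.5]

    def test_unknown_chromosome_skipped_with_warning(self, tmp_path, caplog):
        bins = binning.make_bins(layout_of(1000))
        with caplog.at_level("WARNING"):
            v = binning.read_coverage(
                self.write(tmp_path, [("chrX", 0, 100, 9), ("chr1", 0, 1000, 2)]),
                bins,
            )
        assert v.tolist() == [2.0]
        assert "chrX" in caplog.text

    def test_malformed_record_raises(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1\t100\t50\t2\n")
        with pytest.raises(ValueError):
            binning.read_coverage(p, binning.make_bins(layout_of(1000)))

    @pytest.mark.parametrize("trial", range(10))
    def test_mass_conservation_over_whole_chromosome(self, tmp_path, trial):
        rng = np.random.default_rng(trial)
        # non-overlapping records tiling random stretches of a 10 kb chrom
        edges = np.sort(rng.choice(np.arange(1, 10_000), size=20, replace=False))
        edges = np.concatenate([[0], edges, [10_000]])
        rows, total = [], 0.0
        for s, e in zip(edges[:-1], edges[1:]):
            if rng.random() < 0.5:
                v = float(rng.integers(0, 10))
                rows.append(("chr1", int(s), int(e), v))
                total += v * (e - s)
        bins = binning.make_bins(layout_of(10_000))
        v = binning.read_coverage(self.write(tmp_path, rows), bins)
        assert np.isclose((v * bins.lengths).sum(), total)


class TestNormalization:
    def test_cpm_example(self):
        m = binning.cpm_normalize(matrix([10, 90]))
        assert m.values[:, 0].tolist() == [100000.0, 900000.0]
        assert m.stage == "cpm"

    def test_cpm_columns_sum_to_million(self, rng):
        m = binning.cpm_normalize(matrix(rng.poisson(5.0, size=(50, 3)) + 1.0))
        np.testing.assert_allclose(m.values.sum(axis=0), 1e6)

    def test_cpm_rejects_zero_total(self):
        with pytest.raises(ValueError, match="zero total"):
            binning.cpm_normalize(matrix([0, 0]))

    def test_subtract_control_example(self):
        t = matrix([5, 3], stage="cpm")
        c = matrix([1, 4], stage="cpm")
        out = binning.subtract_control(t, c)
        assert out.values[:, 0].tolist() == [4.0, -1.0]
        assert out.stage == "ctrl_subtracted"

    def test_subtract_zero_control_is_identity(self):
        t = matrix([5.0, 3.0], stage="cpm")
        out = binning.subtract_control(t, matrix([0, 0], stage="cpm"))
        assert out.values[:, 0].tolist() == [5.0, 3.0]

    def test_subtract_self_gives_zero(self):
        t = matrix([5.0, 3.0], stage="cpm")
        out = binning.subtract_control(t, matrix([5.0, 3.0], stage="cpm"))
        assert out.values[:, 0].tolist() == [0.0, 0.0]

    def test_subtract_rejects_bin_mismatch(self):
        t = matrix([5, 3], stage="cpm")
        c = matrix([1, 4, 2], stage="cpm")
        with pytest.raises(ValueError):
            binning.subtract_control(t, c)


class TestDenylist:
    def test_removes_any_overlap(self):
        m = matrix([1.0, 2.0, 3.0])
        deny = IntervalSet.from_records([("chr1", 1500, 1600)])
        out = binning.apply_denylist(m, deny)
        assert out.values[:, 0].tolist() == [1.0, 3.0]
        assert list(out.bins.starts) == [0, 2000]

    def test_empty_denylist_is_identity(self):
        m = matrix([1.0, 2.0])
        out = binning.apply_denylist(m, IntervalSet())
        assert out.values[:, 0].tolist() == [1.0, 2.0]

    def test_full_denylist_empties_matrix(self):
        m = matrix([1.0, 2.0])
        out = binning.apply_denylist(
            m, IntervalSet.from_records([("chr1", 0, 2000)])
        )
        assert len(out.bins) == 0


class TestZscore:
    def test_simple_column(self):
        m = binning.zscore(matrix([1.0, 2.0, 3.0], stage="ctrl_subtracted"))
        assert m.values[:, 0].tolist() == [-1.0, 0.0, 1.0]

    def test_columns_standardized(self, rng):
        m = binning.zscore(
            matrix(rng.normal(5, 2, size=(200, 3)), stage="ctrl_subtracted")
        )
        np.testing.assert_allclose(m.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(m.values.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_zero_variance_names_sample(self):
        with pytest.raises(ValueError, match="s0"):
            binning.zscore(matrix([5.0, 5.0, 5.0], stage="ctrl_subtracted"))


def naive_rolling_mean(col, window, left):
    """Per-position loop oracle for the clipped rolling mean."""
    n = len(col)
    out = np.empty(n)
    right = window - left - 1
    for i in range(n):
        lo, hi = max(i - left, 0), min(i + right + 1, n)
        out[i] = np.mean(col[lo:hi])
    return out


class TestSmooth:
    def test_constant_column_unchanged(self):
        m = binning.smooth(matrix([2.0] * 20, stage="zscore"))
        np.testing.assert_allclose(m.values[:, 0], 2.0)

    def test_single_bin_chromosome_unchanged(self):
        m = matrix([3.0, 1.0], stage="zscore", chrom=["chr1", "chr2"])
        out = binning.smooth(m, window=10)
        assert out.values[:, 0].tolist() == [3.0, 1.0]

    def test_never_crosses_chromosome_boundary(self):
        vals = [0.0] * 5 + [100.0] * 5
        m = matrix(vals, stage="zscore", chrom=["chr1"] * 5 + ["chr2"] * 5)
        out = binning.smooth(m, window=10)
        assert np.all(out.values[:5, 0] == 0.0)
        assert np.all(out.values[5:, 0] == 100.0)

    @pytest.mark.parametrize("window", [1, 2, 3, 10, 11])
    @pytest.mark.parametrize("centering", ["left", "right"])
    def test_matches_naive_loop_oracle(self, rng, window, centering):
        vals = rng.normal(size=47)
        m = matrix(vals, stage="zscore")
        out = binning.smooth(m, window=window, centering=centering)
        left = window // 2 if centering == "left" else window - window // 2 - 1
        np.testing.assert_allclose(
            out.values[:, 0], naive_rolling_mean(vals, window, left)
        )

    def test_impulse_window_10(self, ):
        vals = np.zeros(21)
        vals[10] = 10.0
        out = binning.smooth(matrix(vals, stage="zscore"), window=10)
        np.testing.assert_allclose(
            out.values[:, 0], naive_rolling_mean(vals, 10, 5)
        )
        # the impulse spreads over exactly 10 positions: i-4 .. i+5
        assert (out.values[:, 0] > 0).sum() == 10

    def test_rejects_window_below_one(self):
        with pytest.raises(ValueError):
            binning.smooth(matrix([1.0, 2.0], stage="zscore"), window=0)


class TestStageOrder:
    def test_each_stage_requires_its_predecessor(self):
        raw = matrix([1.0, 2.0, 4.0])
        with pytest.raises(StageError):
            binning.zscore(raw)
        with pytest.raises(StageError):
            binning.smooth(raw)
        with pytest.raises(StageError):
            binning.subtract_control(raw, raw)
        cpm = binning.cpm_normalize(raw)
        with pytest.raises(StageError):
            binning.cpm_normalize(cpm)
        with pytest.raises(StageError):
            binning.smooth(cpm)
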