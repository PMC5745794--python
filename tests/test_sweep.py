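import numpy as np
import pytest

from adaptkit.coalescent import HaplotypePanel, simulate_panel
from adaptkit.models import DemographicModel, Epoch
from adaptkit.sweep import (OmegaConfig, SweepScan, calibrate_cutoff, clr_scan,
                            folded_background, genes_in_regions,
                            intersect_methods, merge_regions, omega_scan,
                            sweep_spectrum)


def neutral_background(n):
    """Folded neutral spectrum proportional to 1/i + 1/(n-i)."""
    bg = np.zeros(n // 2 + 1)
    for i in range(1, n // 2 + 1):
        bg[i] = (1 / i + 1 / (n - i)) if i != n - i else 1 / i
    return bg * 1000


def distorted_panel(panel, focus, radius, rng):
    """Force a frequency excess of extreme classes around a focal site."""
    m = panel.matrix.copy()
    n = panel.n_haplotypes
    near = np.abs(panel.positions - focus) < radius
    for s in np.flatnonzero(near):
        col = np.zeros(n, dtype=np.int8)
        col[rng.integers(n)] = 1  # singleton: an extreme folded class
        m[:, s] = col
    return HaplotypePanel(m, panel.positions, panel.sequence_length,
                          panel.pop_labels)


class TestSweepSpectrum:
    def test_full_escape_recovers_background(self):
        n = 12
        bg = neutral_background(n)
        p_unf = np.zeros(n + 1)
        for i in range(1, n):
            c = min(i, n - i)
            p_unf[i] = bg[c] / (1 if c == n - c else 2)
        p_unf /= p_unf.sum()
        q = sweep_spectrum(p_unf, pe=1.0, n=n)
        assert np.allclose(q[1:n], p_unf[1:n] / p_unf[1:n].sum())

    def test_strong_sweep_loads_extreme_classes(self):
        n = 12
        p_unf = np.zeros(n + 1)
        p_unf[1:n] = [1 / i for i in range(1, n)]
        p_unf /= p_unf.sum()
        weak = sweep_spectrum(p_unf, pe=0.9, n=n)
        strong = sweep_spectrum(p_unf, pe=0.1, n=n)
        extreme = strong[1] + strong[n - 1]
        assert extreme > weak[1] + weak[n - 1]

    def test_normalized(self):
        n = 8
        p_unf = np.zeros(n + 1)
        p_unf[1:n] = 1.0 / np.arange(1, n)
        p_unf /= p_unf.sum()
        for pe in (0.2, 0.5, 0.95):
            assert sweep_spectrum(p_unf, pe, n).sum() == pytest.approx(1.0)


class TestClrScan:
    def test_nonnegative_everywhere(self, neutral_panel):
        scan = clr_scan(neutral_panel, folded_background(neutral_panel), n_grid=15)
        assert np.all(scan.values >= 0)

    def test_neutral_panel_values_small(self, neutral_panel):
        scan = clr_scan(neutral_panel, folded_background(neutral_panel), n_grid=15)
        assert np.median(scan.values) < 5.0

    def test_localizes_planted_distortion(self, constant_model):
        hits = 0
        n_seeds = 50
        for s in range(n_seeds):
            rng = np.random.default_rng(10_000 + s)
            panel = simulate_panel(constant_model, (30,), 100_000, seed=20_000 + s)
            if panel.n_sites < 30:
                continue
            focus = 50_000
            sweep_panel = distorted_panel(panel, focus, 12_000, rng)
            bg = folded_background(panel)  # background from the undistorted data
            grid = np.arange(5_000, 100_001, 5_000)
            scan = clr_scan(sweep_panel, bg, grid=grid)
            peak = grid[np.argmax(scan.values)]
            if abs(peak - focus) <= 10_000:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_empty_grid_rejected(self, neutral_panel):
        with pytest.raises(ValueError, match="grid"):
            clr_scan(neutral_panel, folded_background(neutral_panel),
                     grid=np.array([], dtype=np.int64))

    def test_zero_mass_background_rejected(self, neutral_panel):
        bg = folded_background(neutral_panel)
        bg[2] = 0.0
        with pytest.raises(ValueError, match="zero-mass"):
            clr_scan(neutral_panel, bg)


class TestOmegaScan:
    def _panel(self, cols, positions, length=2_000):
        m = np.column_stack(cols).astype(np.int8)
        return HaplotypePanel(m, np.asarray(positions), length, ["p"] * m.shape[0])

    def test_uniform_ld_gives_one(self):
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        panel = self._panel([a, a, a, a], [900, 950, 1050, 1100])
        scan = omega_scan(panel, OmegaConfig(1_000, 200, 500))
        assert scan.values[scan.grid_positions == 1_000][0] == pytest.approx(1.0)

    def test_hand_computed_toy_equals_four(self):
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        c = np.array([1, 1, 1, 0, 0, 0, 0, 1])  # r^2(a, c) = 0.25
        panel = self._panel([a, a, c, c], [900, 950, 1050, 1100])
        scan = omega_scan(panel, OmegaConfig(1_000, 200, 500))
        assert scan.values[scan.grid_positions == 1_000][0] == pytest.approx(4.0)

    def test_duplicating_haplotypes_leaves_omega_unchanged(self):
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        c = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        p1 = self._panel([a, a, c, c], [900, 950, 1050, 1100])
        m2 = np.vstack([p1.matrix, p1.matrix])
        p2 = HaplotypePanel(m2, p1.positions, p1.sequence_length, ["p"] * 16)
        s1 = omega_scan(p1, OmegaConfig(1_000, 200, 500))
        s2 = omega_scan(p2, OmegaConfig(1_000, 200, 500))
        assert np.allclose(s1.values, s2.values, equal_nan=True)

    def test_too_few_flanking_snps_gives_missing(self):
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        panel = self._panel([a, a, a], [900, 950, 1100])
        scan = omega_scan(panel, OmegaConfig(1_000, 200, 500))
        assert np.isnan(scan.values[scan.grid_positions == 1_000][0])

    def test_neutral_panels_bounded_with_no_positional_trend(self, constant_model):
        # the split maximization biases neutral omega above 1, but the
        # distribution stays bounded and shows no trend along the grid
        from scipy import stats as sps

        vals, positions = [], []
        for s in range(10):
            p = simulate_panel(constant_model, (30,), 100_000, seed=41_000 + s,
                               with_recombination=True)
            scan = omega_scan(p, OmegaConfig(10_000, 2_000, 20_000))
            # interior grid points: flanks not truncated by the sequence ends
            ok = (np.isfinite(scan.values)
                  & (scan.grid_positions >= 20_000)
                  & (scan.grid_positions <= 80_000))
            vals.extend(scan.values[ok])
            positions.extend(scan.grid_positions[ok])
        med = np.median(vals)
        assert 1.0 <= med < 12.0
        rho = sps.spearmanr(positions, vals).statistic
        assert abs(rho) < 0.3


class TestCalibration:
    def test_median_at_half_fpr(self):
        scan = SweepScan(np.arange(1, 12) * 10, np.arange(11.0), "CLR")
        assert calibrate_cutoff([scan], fpr=0.5) == pytest.approx(5.0)

    def test_monotone_in_fpr(self):
        rng = np.random.default_rng(0)
        scan = SweepScan(np.arange(1, 1_001) * 10, rng.exponential(size=1_000), "CLR")
        cuts = [calibrate_cutoff([scan], f) for f in (0.5, 0.1, 0.01)]
        assert cuts[0] <= cuts[1] <= cuts[2]

    def test_warns_when_null_set_is_small(self):
        scan = SweepScan(np.arange(1, 11) * 10, np.arange(10.0), "CLR")
        with pytest.warns(UserWarning, match="null values"):
            calibrate_cutoff([scan], fpr=1e-4)

    def test_empty_null_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate_cutoff([], fpr=0.1)


class TestRegions:
    def _scan(self, positions, values, cutoff):
        s = SweepScan(np.asarray(positions), np.asarray(values, float), "CLR",
                      cutoff=cutoff)
        return s

    def test_neighbours_merge(self):
        s = self._scan([10_000, 20_000, 50_000], [5.0, 6.0, 1.0], 2.0)
        assert merge_regions(s, max_gap=10_000) == [(10_000, 20_000)]

    def test_no_significant_points(self):
        s = self._scan([10_000, 20_000], [1.0, 1.5], 2.0)
        assert merge_regions(s, max_gap=10_000) == []

    def test_merge_idempotent_and_regions_contain_peaks(self):
        s = self._scan([10, 20, 40, 80], [9, 1, 9, 9], 5.0)
        r1 = merge_regions(s, max_gap=20)
        r2 = merge_regions(s, max_gap=20)
        assert r1 == r2
        for lo, hi in r1:
            assert np.any((s.grid_positions >= lo) & (s.grid_positions <= hi)
                          & (s.values > s.cutoff))

    def test_requires_cutoff(self):
        s = SweepScan(np.array([10]), np.array([1.0]), "CLR")
        with pytest.raises(ValueError):
            merge_regions(s)

    def test_intersection_arithmetic(self):
        assert intersect_methods([(100, 300)], [(200, 400)]) == [(200, 300)]
        assert intersect_methods([(100, 200)], [(300, 400)]) == []

    def test_intersection_idempotent_and_contained(self):
        a = [(100, 300), (500, 900)]
        b = [(250, 600)]
        assert intersect_methods(a, a) == a
        cons = intersect_methods(a, b)
        for lo, hi in cons:
            assert any(x0 <= lo and hi <= x1 for x0, x1 in a)
            assert any(x0 <= lo and hi <= x1 for x0, x1 in b)


class TestGenesInRegions:
    GFF = """##gff-version 3
chr1\tsrc\tgene\t150\t250\t.\t+\t.\tID=geneA
chr1\tsrc\tgene\t400\t500\t.\t-\t.\tID=geneB
chr1\tsrc\tgene\t600\t700\t.\t+\t.\tID=geneC
"""

    def test_overlap_and_boundary(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(self.GFF)
        genes, skipped = genes_in_regions([(200, 400)], gff)
        assert genes == ["geneA", "geneB"]  # geneB touches by exactly 1 bp
        assert skipped == 0

    def test_empty_regions(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(self.GFF)
        genes, _ = genes_in_regions([], gff)
        assert genes == []

    def test_malformed_rows_skipped(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(self.GFF + "chr1\tsrc\tgene\tnot_a_number\t900\t.\t+\t.\tID=bad\n")
        genes, skipped = genes_in_regions([(100, 1_000)], gff)
        assert skipped == 1
        assert genes == ["geneA", "geneB", "geneC"]
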