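import numpy as np
import pytest
from scipy import stats as sps

from adaptkit.qtl import (F2Cross, GeneticMap, QtlModel, arabidopsis_style_map,
                          candidate_filter, haldane_c, haplotype_association,
                          interval_mapping, permutation_threshold, simulate_f2,
                          variance_explained)


@pytest.fixture(scope="module")
def gmap():
    return arabidopsis_style_map()


@pytest.fixture(scope="module")
def null_truth():
    return QtlModel(qtls=(), residual_sd=1.0, grand_mean=0.0)


@pytest.fixture(scope="module")
def big_qtl_truth(gmap):
    pos = float(gmap.positions["chr3"][2])
    return QtlModel(qtls=(("chr3", pos, 2.0, 0.0),), residual_sd=1.0, grand_mean=10.0)


class TestHaldane:
    def test_limits(self):
        assert haldane_c(0.0) == 0.0
        assert haldane_c(1e9) == pytest.approx(0.5)

    def test_50_cm_is_quarter(self):
        assert haldane_c(50.0) == pytest.approx(0.5 * (1 - np.exp(-1)))


class TestSimulateF2:
    def test_study_design_dimensions(self, gmap, null_truth):
        cross = simulate_f2(86, gmap, null_truth, seed=1)
        assert cross.genotypes.shape == (86, 32)
        assert len(gmap.chromosomes) == 5

    def test_mendelian_segregation_1_2_1(self, gmap, null_truth):
        cross = simulate_f2(1_000, gmap, null_truth, seed=2)
        for col in range(0, 32, 7):
            counts = np.bincount(cross.genotypes[:, col], minlength=3)
            chi2 = np.sum((counts - np.array([250, 500, 250])) ** 2
                          / np.array([250, 500, 250]))
            assert chi2 < sps.chi2.ppf(0.99, df=2)

    def test_parental_mean_calibration(self, gmap):
        # homozygous-parent expectations hit the two parental flowering means
        a2, a5 = 7.978, 4.752
        truth = QtlModel(qtls=(("chr2", 45.0, a2, 0.0), ("chr5", 52.0, a5, 0.0)),
                         residual_sd=1e-6, grand_mean=(50.33 + 24.87) / 2)
        assert truth.grand_mean + a2 + a5 == pytest.approx(50.33, abs=0.01)
        assert truth.grand_mean - a2 - a5 == pytest.approx(24.87, abs=0.01)

    def test_deterministic(self, gmap, big_qtl_truth):
        a = simulate_f2(50, gmap, big_qtl_truth, seed=9)
        b = simulate_f2(50, gmap, big_qtl_truth, seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.phenotypes, b.phenotypes)

    def test_qtl_outside_map_rejected(self, gmap):
        truth = QtlModel(qtls=(("chr1", 999.0, 1.0, 0.0),), residual_sd=1.0,
                         grand_mean=0.0)
        with pytest.raises(ValueError, match="span"):
            simulate_f2(10, gmap, truth, seed=1)

    def test_csv_round_trip(self, tmp_path, gmap, big_qtl_truth):
        cross = simulate_f2(20, gmap, big_qtl_truth, seed=5)
        cross.to_csv(tmp_path / "g.csv", tmp_path / "p.csv", tmp_path / "m.csv")
        import pandas as pd
        g = pd.read_csv(tmp_path / "g.csv")
        assert g.shape == (20, 32)


class TestIntervalMapping:
    def test_null_phenotype_stays_below_threshold(self, gmap, null_truth):
        below = 0
        for s in range(6):
            cross = simulate_f2(86, gmap, null_truth, seed=50 + s)
            curve = interval_mapping(cross)
            thr = permutation_threshold(cross, n_perm=200, seed=60 + s)
            below += curve["lod"].max() < thr
        assert below >= 5

    def test_peak_on_correct_chromosome(self, gmap, big_qtl_truth):
        hits = 0
        n_seeds = 50
        for s in range(n_seeds):
            cross = simulate_f2(86, gmap, big_qtl_truth, seed=100 + s)
            curve = interval_mapping(cross)
            hits += curve.loc[curve["lod"].idxmax(), "chrom"] == "chr3"
        assert hits >= 0.9 * n_seeds

    def test_haley_knott_equals_anova_at_informative_marker(self, gmap, big_qtl_truth):
        cross = simulate_f2(120, gmap, big_qtl_truth, seed=7)
        curve = interval_mapping(cross, step=1_000.0)  # markers only
        y = cross.phenotypes
        col = gmap.marker_index().index(("chr3", 2))
        g = cross.genotypes[:, col]
        # single-marker ANOVA LOD with additive + dominance coding
        X = np.column_stack([np.ones_like(y), g - 1.0, (g == 1).astype(float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = np.sum((y - X @ beta) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        lod_anova = len(y) / 2 * np.log10(rss0 / rss1)
        at_marker = curve[(curve.chrom == "chr3")
                          & np.isclose(curve.cM, gmap.positions["chr3"][2])]
        assert at_marker["lod"].iloc[0] == pytest.approx(lod_anova, rel=1e-6)

    def test_lod_invariant_to_affine_phenotype_transform(self, gmap, big_qtl_truth):
        cross = simulate_f2(60, gmap, big_qtl_truth, seed=8)
        curve1 = interval_mapping(cross)
        scaled = F2Cross(cross.genotypes, 3.5 * cross.phenotypes - 11.0, gmap)
        curve2 = interval_mapping(scaled)
        assert np.allclose(curve1["lod"], curve2["lod"])

    def test_handles_missing_genotypes(self, gmap, big_qtl_truth):
        cross = simulate_f2(86, gmap, big_qtl_truth, seed=12, missing_rate=0.1)
        curve = interval_mapping(cross)
        assert np.isfinite(curve["lod"]).all()
        assert curve.loc[curve["lod"].idxmax(), "chrom"] == "chr3"

    def test_too_few_individuals_rejected(self, gmap, null_truth):
        cross = simulate_f2(5, gmap, null_truth, seed=1)
        with pytest.raises(ValueError):
            interval_mapping(cross)

    def test_constant_phenotype_rejected(self, gmap, null_truth):
        cross = simulate_f2(20, gmap, null_truth, seed=1)
        flat = F2Cross(cross.genotypes, np.ones(20), gmap)
        with pytest.raises(ValueError):
            interval_mapping(flat)


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self, gmap, null_truth):
        cross = simulate_f2(40, gmap, null_truth, seed=3)
        t_all = permutation_threshold(cross, n_perm=100, alpha=1.0, seed=4)
        t_05 = permutation_threshold(cross, n_perm=100, alpha=0.05, seed=4)
        assert t_all <= t_05

    def test_monotone_in_alpha(self, gmap, null_truth):
        cross = simulate_f2(40, gmap, null_truth, seed=5)
        ts = [permutation_threshold(cross, n_perm=100, alpha=a, seed=6)
              for a in (0.5, 0.2, 0.05)]
        assert ts[0] <= ts[1] <= ts[2]

    def test_requires_100_permutations(self, gmap, null_truth):
        cross = simulate_f2(40, gmap, null_truth, seed=5)
        with pytest.raises(ValueError):
            permutation_threshold(cross, n_perm=50)


class TestVarianceExplained:
    def test_zero_lod_zero_pve(self, gmap):
        # a phenotype orthogonal to the genotype scores gives LOD ~ 0, PVE ~ 0
        cross = simulate_f2(200, gmap, QtlModel(qtls=(), residual_sd=1.0,
                                                grand_mean=0.0), seed=13)
        out = variance_explained(cross, [("chr1", float(gmap.positions["chr1"][0]))])
        assert out["per_qtl_pve"][0] == pytest.approx(
            100 * (1 - 10 ** (-2 * out["lod"][0] / 200)))
        assert out["per_qtl_pve"][0] < 8.0

    def test_single_qtl_closed_form(self):
        # n = 100, LOD = 5 -> PVE = 1 - 10^(-0.1) = 0.206
        assert 1 - 10 ** (-2 * 5 / 100) == pytest.approx(0.2057, abs=1e-4)

    def test_unknown_chromosome_rejected(self, gmap, null_truth):
        cross = simulate_f2(20, gmap, null_truth, seed=1)
        with pytest.raises(ValueError):
            variance_explained(cross, [("chr9", 10.0)])

    def test_pve_unbiased_at_large_n(self, gmap):
        # drop-one PVE at n = 1000 recovers the generating fractions
        from adaptkit.experiments import study_qtl_truth
        _, truth, true_pve = study_qtl_truth()
        est2, est5 = [], []
        for s in range(10):
            cross = simulate_f2(1_000, gmap, truth, seed=700 + s)
            out = variance_explained(cross, [(q[0], q[1]) for q in truth.qtls])
            est2.append(out["per_qtl_pve"][0])
            est5.append(out["per_qtl_pve"][1])
        assert abs(np.mean(est2) - true_pve[0]) < 5.0
        assert abs(np.mean(est5) - true_pve[1]) < 5.0


class TestHaplotypeAssociation:
    def test_identical_groups_p_near_one(self):
        y = np.concatenate([np.arange(10.0), np.arange(10.0)])
        labels = ["h1"] * 10 + ["h2"] * 10
        out = haplotype_association(y, labels)
        assert out["p_value"] > 0.9

    def test_tiny_groups_exact_p(self):
        out = haplotype_association([1, 2, 3, 10, 11, 12],
                                    ["a", "a", "a", "b", "b", "b"])
        assert out["p_value"] == pytest.approx(0.1)
        assert out["means"] == (2.0, 11.0)

    def test_power_on_shifted_gaussians(self):
        # two haplotype classes of 49 accessions, means 2 sd apart
        rng = np.random.default_rng(0)
        sig = 0
        for _ in range(10):
            g1 = rng.normal(0.0, 1.0, 49)
            g2 = rng.normal(2.0, 1.0, 49)
            out = haplotype_association(np.concatenate([g1, g2]),
                                        ["a"] * 49 + ["b"] * 49)
            sig += out["p_value"] < 1e-3
        assert sig == 10

    def test_welch_alternative(self):
        out = haplotype_association([1, 2, 3, 4], ["a", "a", "b", "b"],
                                    test="welch")
        assert out["test"] == "welch" and 0 <= out["p_value"] <= 1

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValueError):
            haplotype_association([1.0, 2.0], ["a", "a"])


class TestCandidateFilter:
    VARIANTS = [
        {"pos": 10, "gene": "g1", "effect": "missense"},
        {"pos": 20, "gene": "g2", "effect": "synonymous"},
        {"pos": 30, "gene": "g3", "effect": "missense"},
        {"pos": 40, "gene": "g4", "effect": "intergenic"},
        {"pos": 50, "gene": "g5", "effect": "missense"},
        {"pos": 60, "gene": "g6", "effect": "missense"},
        {"pos": 999, "gene": "g7", "effect": "missense"},
    ]

    def test_four_missense_in_four_genes(self):
        out = candidate_filter(self.VARIANTS, interval=(1, 100))
        assert sorted(out) == ["g1", "g3", "g5", "g6"]

    def test_no_amino_acid_changes(self):
        out = candidate_filter([v for v in self.VARIANTS
                                if v["effect"] != "missense"], interval=(1, 100))
        assert out == {}

    def test_interval_bounds_applied(self):
        out = candidate_filter(self.VARIANTS, interval=(45, 70))
        assert sorted(out) == ["g5", "g6"]
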