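import numpy as np
import pytest
from scipy import stats as sps

from adaptkit.coalescent import simulate_null_set, simulate_panel
from adaptkit.models import DemographicModel, Epoch, MigrationWindow
from adaptkit.stats import harmonic_number, hudson_fst


def watterson_expected_s(n, N, mu, L):
    """Closed-form neutral expectation E[S] = 4*N*mu*L * a_{n-1}."""
    return 4 * N * mu * L * harmonic_number(n - 1)


class TestNeutralOracles:
    def test_zero_mutation_rate_gives_empty_panel(self, constant_model):
        model = constant_model.with_params(mutation_rate=0.0)
        panel = simulate_panel(model, (10,), 10_000, seed=1)
        assert panel.n_sites == 0

    def test_segregating_sites_match_watterson(self, constant_model):
        n, L, reps = 10, 100_000, 500
        s = np.array([simulate_panel(constant_model, (n,), L, seed=i).n_sites
                      for i in range(reps)])
        expected = watterson_expected_s(n, 10_000, 7e-9, L)
        se = s.std(ddof=1) / np.sqrt(reps)
        assert abs(s.mean() - expected) < 3 * se

    def test_pairwise_diversity_matches_theta(self, constant_model):
        # E[pi] = 4*N*mu*L under the neutral coalescent
        n, L, reps = 8, 100_000, 400
        pis = []
        for i in range(reps):
            p = simulate_panel(constant_model, (n,), L, seed=1_000 + i)
            freq = p.matrix.mean(axis=0)
            pis.append(np.sum(2 * freq * (1 - freq) * n / (n - 1)))
        pis = np.asarray(pis)
        expected = 4 * 10_000 * 7e-9 * L
        se = pis.std(ddof=1) / np.sqrt(reps)
        assert abs(pis.mean() - expected) < 3 * se

    def test_folded_sfs_matches_neutral_shape(self, constant_model):
        # folded class i expected proportional to 1/i + 1/(n-i) (halved at n/2);
        # sites within one panel share a genealogy, so uncertainty comes from
        # the spread of per-panel class proportions, not per-site counts
        n, reps = 10, 300
        props = []
        for i in range(reps):
            p = simulate_panel(constant_model, (n,), 50_000, seed=7_000 + i)
            if p.n_sites == 0:
                continue
            c = np.minimum(p.matrix.sum(axis=0), n - p.matrix.sum(axis=0))
            h = np.bincount(c, minlength=n // 2 + 1)[1:]
            props.append(h / h.sum())
        props = np.asarray(props)
        expected = np.array([
            (1 / i + 1 / (n - i)) if i != n - i else 1 / i for i in range(1, n // 2 + 1)
        ])
        expected = expected / expected.sum()
        z = (props.mean(axis=0) - expected) / (props.std(axis=0, ddof=1) / np.sqrt(len(props)))
        assert np.max(np.abs(z)) < 4.0


class TestStructure:
    def test_complete_lineage_sorting_limit(self):
        # huge divergence, no migration: every SNP is fixed-different or private
        model = DemographicModel(
            n_demes=2, epochs=(Epoch(0.0, (5_000.0, 5_000.0)),),
            divergence_time=5e6, ancestral_size=5_000.0,
        )
        panel = simulate_panel(model, (6, 6), 50_000, seed=11)
        assert panel.n_sites > 0
        a = panel.matrix[:6]
        b = panel.matrix[6:]
        for s in range(panel.n_sites):
            mono_a = a[:, s].min() == a[:, s].max()
            mono_b = b[:, s].min() == b[:, s].max()
            assert mono_a or mono_b

    def test_fst_increases_with_divergence_time(self):
        fsts = []
        for t_div in (2_000.0, 10_000.0, 50_000.0):
            model = DemographicModel(
                n_demes=2, epochs=(Epoch(0.0, (10_000.0, 10_000.0)),),
                divergence_time=t_div, ancestral_size=10_000.0,
            )
            vals = []
            for i in range(200):
                p = simulate_panel(model, (8, 8), 20_000, seed=3_000 + i,
                                   pop_labels=["A", "B"])
                if p.n_sites:
                    v = hudson_fst(p, ("A", "B"))
                    if np.isfinite(v):
                        vals.append(v)
            fsts.append(np.mean(vals))
        assert fsts[0] < fsts[1] < fsts[2]

    def test_migration_reduces_differentiation(self):
        base = dict(n_demes=2, epochs=(Epoch(0.0, (10_000.0, 10_000.0)),),
                    divergence_time=50_000.0, ancestral_size=10_000.0)
        iso = DemographicModel(**base)
        mig = DemographicModel(
            migration_windows=(MigrationWindow(0.0, 50_000.0, 2e-4, 2e-4),), **base)
        def mean_fst(model):
            vals = []
            for i in range(150):
                p = simulate_panel(model, (8, 8), 20_000, seed=9_000 + i,
                                   pop_labels=["A", "B"])
                if p.n_sites:
                    v = hudson_fst(p, ("A", "B"))
                    if np.isfinite(v):
                        vals.append(v)
            return np.mean(vals)
        assert mean_fst(mig) < mean_fst(iso)


class TestRecombination:
    def test_r2_decays_with_distance(self, constant_model):
        panel = simulate_panel(constant_model, (30,), 60_000, seed=21,
                               with_recombination=True)
        freq = panel.matrix.mean(axis=0)
        keep = (freq > 0.1) & (freq < 0.9)
        m = panel.matrix[:, keep].astype(float)
        pos = panel.positions[keep]
        assert m.shape[1] >= 10
        r2 = np.corrcoef(m.T) ** 2
        i, j = np.triu_indices(len(pos), 1)
        d = (pos[j] - pos[i]).astype(float)
        bins = np.digitize(d, [2_000, 10_000, 30_000])
        binned = [r2[i, j][bins == b].mean() for b in range(4)]
        rho = sps.spearmanr(np.arange(4), binned).statistic
        assert rho < 0

    def test_recombination_off_is_single_tree(self, constant_model):
        # without recombination all site patterns are nested or disjoint
        panel = simulate_panel(constant_model, (12,), 50_000, seed=22)
        cols = [frozenset(np.flatnonzero(panel.matrix[:, s]))
                for s in range(panel.n_sites)]
        for x in cols[:50]:
            for y in cols[:50]:
                assert x <= y or y <= x or not (x & y)


class TestDeterminismAndErrors:
    def test_same_seed_same_panel(self, m4):
        a = simulate_panel(m4, (10, 5), 30_000, seed=42)
        b = simulate_panel(m4, (10, 5), 30_000, seed=42)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.positions, b.positions)

    def test_null_set_reproducible_and_independent(self, m4):
        s1 = simulate_null_set(m4, 3, 20_000, (6, 4), seed=7)
        s2 = simulate_null_set(m4, 3, 20_000, (6, 4), seed=7)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.matrix, b.matrix)
            assert np.array_equal(a.positions, b.positions)
        assert not np.array_equal(s1[0].positions, s1[1].positions)

    def test_null_set_matches_watterson(self, constant_model):
        panels = simulate_null_set(constant_model, 200, 50_000, (10,), seed=3)
        s = np.array([p.n_sites for p in panels])
        expected = watterson_expected_s(10, 10_000, 7e-9, 50_000)
        se = s.std(ddof=1) / np.sqrt(len(s))
        assert abs(s.mean() - expected) < 3 * se

    def test_rejects_nonpositive_length(self, constant_model):
        with pytest.raises(ValueError):
            simulate_panel(constant_model, (5,), 0, seed=1)

    def test_rejects_two_deme_sample_on_one_deme_model(self, constant_model):
        with pytest.raises(ValueError):
            simulate_panel(constant_model, (5, 5), 1_000, seed=1)

    def test_rejects_zero_datasets(self, constant_model):
        with pytest.raises(ValueError):
            simulate_null_set(constant_model, 0, 1_000, (5,), seed=1)


class TestAgainstMsprime:
    """Independent cross-check of the home-grown simulator against msprime."""

    def test_two_deme_mean_segregating_sites(self):
        msprime = pytest.importorskip("msprime")
        t_div, n_anc, n0, n1 = 30_000.0, 20_000.0, 15_000.0, 8_000.0
        model = DemographicModel(
            n_demes=2, epochs=(Epoch(0.0, (n0, n1)),),
            divergence_time=t_div, ancestral_size=n_anc,
        )
        ours = np.array([
            simulate_panel(model, (8, 6), 50_000, seed=5_000 + i).n_sites
            for i in range(300)
        ])
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=n0)
        dem.add_population(name="B", initial_size=n1)
        dem.add_population(name="anc", initial_size=n_anc)
        dem.add_population_split(time=t_div, derived=["A", "B"], ancestral="anc")
        # haploid sample sets with diploid (1/(2N)) time scaling matches the
        # selfing-strain convention used by the simulator
        samples = [msprime.SampleSet(8, population="A", ploidy=1),
                   msprime.SampleSet(6, population="B", ploidy=1)]
        theirs = []
        for ts in msprime.sim_ancestry(
            samples=samples, demography=dem, sequence_length=50_000,
            ploidy=2, num_replicates=300, random_seed=99,
        ):
            mts = msprime.sim_mutations(ts, rate=7e-9, random_seed=ts.num_edges + 1)
            theirs.append(mts.num_sites)
        theirs = np.array(theirs)
        se = np.sqrt(ours.var(ddof=1) / ours.size + theirs.var(ddof=1) / theirs.size)
        assert abs(ours.mean() - theirs.mean()) < 3.5 * se
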