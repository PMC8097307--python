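"""Simulator checks against coalescent theory, closed forms and an
independent simulator (msprime) on small instances."""

import math

import numpy as np
import pytest
from scipy import stats

from ryupop import coalescent_sim as cs
from ryupop.popgen_stats import hudson_fst_from_panel, patterson_d_from_sfs

from conftest import single_deme, two_deme_split


class TestSiteSimulator:
    def test_pairwise_tmrca_matches_2n(self):
        # analytic E[T2] = 2N for a diploid deme of size N
        n = 1000
        panel = cs.simulate_sites(single_deme(n), {"A": 1}, 10_000, seed=11)
        t = panel.site_tmrca
        se = t.std() / math.sqrt(t.size)
        assert abs(t.mean() - 2 * n) < 3 * se

    def test_unfolded_sfs_proportional_to_one_over_i(self):
        # infinite-sites ensemble (Poisson mode): E[count at i] ~ 1/i
        panel = cs.simulate_sites(
            single_deme(5000), {"A": 5}, 50_000, seed=5, mutation_mode="poisson"
        )
        counts = panel.haplotypes.sum(axis=0)
        obs = np.bincount(counts, minlength=10)[1:10]
        harm = sum(1.0 / i for i in range(1, 10))
        exp = panel.n_sites * np.array([1.0 / i for i in range(1, 10)]) / harm
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=8) > 0.01

    def test_seed_determinism(self, fitted_model):
        ss = {"MYNE": 3, "IKM": 3}
        a = cs.simulate_sites(fitted_model, ss, 400, seed=9)
        b = cs.simulate_sites(fitted_model, ss, 400, seed=9)
        c = cs.simulate_sites(fitted_model, ss, 400, seed=10)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.pos_bp, b.pos_bp)
        assert not np.array_equal(a.haplotypes, c.haplotypes)

    def test_single_haplotype_errors(self):
        with pytest.raises(ValueError):
            cs.simulate_sites(single_deme(100), {"A": 0}, 100, seed=1)

    def test_invalid_model_rejected(self):
        from ryupop.demographic_model import DemographicModel, Epoch

        bad = DemographicModel(
            demes={
                "A": [Epoch(0, 10, 50), Epoch(12, math.inf, 50)],
            },
            splits=[],
            migrations=[],
        )
        with pytest.raises(ValueError, match="invalid demographic model"):
            cs.simulate_sites(bad, {"A": 2}, 10, seed=1)

    def test_two_deme_split_fst_matches_theory(self):
        # shallow split: Hudson F_ST ~ 1 - exp(-t/(2N)) for t << 2N
        t, n = 60, 1500
        panel = cs.simulate_sites(
            two_deme_split(t, n), {"A": 20, "B": 20}, 40_000, seed=21,
            mutation_mode="poisson",
        )
        r = hudson_fst_from_panel(panel, "A", "B")
        expected = 1 - math.exp(-t / (2 * n))
        assert abs(r.fst - expected) < 3 * r.se + 0.05 * expected

    def test_positions_strictly_increasing_and_mapped(self, fitted_model):
        panel = cs.simulate_sites(fitted_model, {"OKI": 3}, 1000, seed=2)
        assert np.all(np.diff(panel.pos_bp) > 0)
        assert np.allclose(panel.pos_cM, panel.pos_bp / 1e6)

    def test_maf_ascertainment_drops_rare_sites(self):
        panel = cs.simulate_sites(
            single_deme(2000), {"A": 10}, 4000, seed=3, ascertain_maf=0.1
        )
        freq = panel.haplotypes.mean(axis=0)
        assert np.all(np.minimum(freq, 1 - freq) > 0.1)
        assert panel.n_sites < 4000


class TestJointSFS:
    def test_total_equals_n_sites(self, fitted_model):
        sfs = cs.simulate_joint_sfs(fitted_model, {"OKI": 4, "IKM": 4}, 3000, seed=4)
        assert sfs.total() == 3000

    def test_symmetric_model_gives_symmetric_sfs(self):
        m = two_deme_split(200, 1000)
        sfs = cs.simulate_joint_sfs(m, {"A": 5, "B": 5}, 30_000, seed=6)
        arr = sfs.dense()
        asym = np.abs(arr - arr.T).sum() / arr.sum()
        # exchangeable demes: the joint spectrum is symmetric up to noise
        assert asym < 0.05

    def test_fitted_model_d_statistic_positive(self, fitted_model):
        # topology (((OKI,MYNE),MYSW),IKM) forces excess OKI-MYNE sharing
        sfs = cs.simulate_joint_sfs(
            fitted_model,
            {"CHB": 10, "OKI": 10, "MYNE": 10, "IKM": 10},
            100_000,
            seed=8,
        )
        d = patterson_d_from_sfs(sfs, ("CHB", "OKI", "IKM", "MYNE"))
        assert d > 0


class TestPairwiseIBD:
    def test_zero_length_chromosome(self, fitted_model):
        assert cs.simulate_pairwise_ibd(fitted_model, "IKM", 5, 0.0, seed=1) == []

    def test_unknown_deme_errors(self, fitted_model):
        with pytest.raises(ValueError):
            cs.simulate_pairwise_ibd(fitted_model, "XX", 5, 100.0, seed=1)

    def test_partition_tiles_chromosome(self):
        segs = cs.simulate_pairwise_ibd(single_deme(50), "A", 4, 10.0, seed=13)
        for pair in range(4):
            mine = sorted(
                (s for s in segs if s.sample1 == f"p{pair}a"),
                key=lambda s: s.start_cM,
            )
            assert mine[0].start_cM == 0.0
            assert mine[-1].end_cM == pytest.approx(10.0)
            for a, b in zip(mine, mine[1:]):
                assert b.start_cM == pytest.approx(a.end_cM)
            total = sum(s.length_cM for s in mine)
            assert total == pytest.approx(10.0)
            # maximal spans: adjacent segments have distinct TMRCA
            for a, b in zip(mine, mine[1:]):
                assert a.tmrca_gen != b.tmrca_gen

    def test_long_segment_count_matches_closed_form(self):
        # expected count >= 6 cM: sum_g P(g) L 2g exp(-2g*0.06)
        n, n_pairs, L_cM = 5000, 500, 3000.0
        model = single_deme(n)
        segs = cs.simulate_pairwise_ibd(
            model, "A", n_pairs, L_cM, seed=17, min_emit_cM=6.0
        )
        observed = len(segs)
        pmf = cs.pair_coalescence_pmf(model, "A")
        g = np.arange(1, pmf.size + 1)
        L = L_cM / 100.0
        expected = n_pairs * float(np.sum(pmf * L * 2 * g * np.exp(-2 * g * 0.06)))
        # segment counts are near-Poisson; allow 4 sigma
        assert abs(observed - expected) < 4 * math.sqrt(expected)

    def test_larger_population_yields_fewer_long_segments(self):
        counts = {}
        for n in (1000, 50_000):
            per_seed = []
            for seed in range(20):
                segs = cs.simulate_pairwise_ibd(
                    single_deme(n), "A", 20, 500.0, seed=100 + seed, min_emit_cM=6.0
                )
                per_seed.append(len(segs))
            counts[n] = np.mean(per_seed)
        assert counts[50_000] < counts[1000]

    def test_truth_seed_determinism(self, fitted_model):
        a = cs.simulate_pairwise_ibd(fitted_model, "IKM", 3, 200.0, seed=5, min_emit_cM=1.0)
        b = cs.simulate_pairwise_ibd(fitted_model, "IKM", 3, 200.0, seed=5, min_emit_cM=1.0)
        assert [(s.start_cM, s.end_cM, s.tmrca_gen) for s in a] == [
            (s.start_cM, s.end_cM, s.tmrca_gen) for s in b
        ]


class TestAgainstIndependentSimulator:
    """Small-instance cross-checks against msprime."""

    @pytest.fixture(scope="class")
    def designs(self):
        import msprime

        t, n_a, n_anc = 400, 800, 1500
        demog = msprime.Demography()
        demog.add_population(name="A", initial_size=n_a / 2)
        demog.add_population(name="B", initial_size=n_a / 2)
        demog.add_population(name="ANC", initial_size=n_anc / 2)
        demog.add_population_split(time=t, derived=["A", "B"], ancestral="ANC")
        # sizes above are haploid gene-copy counts halved: msprime sizes are
        # diploid, ours are set via gene-copies units below
        from ryupop.demographic_model import DemographicModel, Epoch, SplitEvent

        ours = DemographicModel(
            demes={
                "A": [Epoch(0, t, n_a)],
                "B": [Epoch(0, t, n_a)],
                "ANC": [Epoch(t, math.inf, n_anc)],
            },
            splits=[SplitEvent(t, "A", "ANC"), SplitEvent(t, "B", "ANC")],
            migrations=[],
            size_units="gene-copies",
        )
        return demog, ours

    def test_mean_tmrca_agrees(self, designs):
        import msprime

        demog, ours = designs
        reps = msprime.sim_ancestry(
            samples={"A": 2, "B": 2},
            demography=demog,
            num_replicates=4000,
            ploidy=2,
            random_seed=42,
        )
        ms_root = np.array([ts.first().time(ts.first().root) for ts in reps])
        panel = cs.simulate_sites(ours, {"A": 2, "B": 2}, 4000, seed=42)
        mine = panel.site_tmrca
        se = math.sqrt(ms_root.var() / ms_root.size + mine.var() / mine.size)
        assert abs(ms_root.mean() - mine.mean()) < 3.5 * se

    def test_marginal_sfs_agrees(self, designs):
        import msprime

        demog, ours = designs
        # branch-mode SFS from msprime vs our Poisson-mode site counts
        afs_total = np.zeros(11)
        for ts in msprime.sim_ancestry(
            samples={"A": 5},
            demography=demog,
            num_replicates=3000,
            ploidy=2,
            random_seed=7,
        ):
            afs_total += ts.allele_frequency_spectrum(
                mode="branch", polarised=True, span_normalise=False
            )
        ms_prop = afs_total[1:10] / afs_total[1:10].sum()
        panel = cs.simulate_sites(
            ours, {"A": 5}, 40_000, seed=3, mutation_mode="poisson"
        )
        counts = np.bincount(panel.haplotypes.sum(axis=0), minlength=11)[1:10]
        obs_prop = counts / counts.sum()
        assert np.all(np.abs(obs_prop - ms_prop) < 4 * np.sqrt(ms_prop * (1 - ms_prop) / counts.sum()) + 0.01)
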