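"""Hudson F_ST, Patterson's D, SFS utilities, ROH and PCA."""

import math

import numpy as np
import pytest

from ryupop import coalescent_sim as cs
from ryupop.popgen_stats import (
    SFS,
    assign_blocks,
    hudson_fst,
    hudson_fst_from_panel,
    joint_sfs_from_panel,
    patterson_d,
    patterson_d_from_panel,
    patterson_d_from_sfs,
    pca_projection,
    roh_detect,
    total_roh,
)

from conftest import make_panel, single_deme, two_deme_split


class TestHudsonFst:
    def test_fixed_opposite_alleles_give_one(self):
        S = 100
        d1 = np.zeros(S)
        d2 = np.full(S, 10.0)
        n = np.full(S, 10.0)
        r = hudson_fst(d1, n, d2, n)
        assert r.fst == pytest.approx(1.0)

    def test_hand_arithmetic_single_locus_terms(self):
        # p1=p2=0.5, n=10 haplotypes each: numerator -2*0.25/9, denominator 0.5
        d = np.array([5.0, 5.0])
        n = np.array([10.0, 10.0])
        r = hudson_fst(d, n, d, n, blocks=np.array([0, 1]))
        expected = (-2 * 0.25 / 9) / 0.5
        assert r.fst == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-0.111111, abs=1e-6)

    def test_too_few_usable_loci_errors(self):
        with pytest.raises(ValueError):
            hudson_fst([1.0], [10.0], [2.0], [10.0], blocks=np.array([0]))

    def test_skipped_locus_counting(self):
        d1 = np.array([5.0, 0.0, 3.0])
        n1 = np.array([10.0, 1.0, 10.0])  # middle locus unusable (n<2)
        d2 = np.array([2.0, 0.0, 7.0])
        n2 = np.array([10.0, 10.0, 10.0])
        r = hudson_fst(d1, n1, d2, n2, blocks=np.array([0, 0, 1]))
        assert r.n_skipped == 1
        assert r.n_loci == 2

    def test_split_model_matches_divergence_theory(self):
        t, n = 80, 1000
        panel = cs.simulate_sites(
            two_deme_split(t, n), {"A": 15, "B": 15}, 30_000, seed=31,
            mutation_mode="poisson",
        )
        r = hudson_fst_from_panel(panel, "A", "B")
        expected = 1 - math.exp(-t / (2 * n))
        assert abs(r.fst - expected) < 3 * r.se + 0.05 * expected

    def test_weir_cockerham_close_to_hudson_for_balanced_design(self):
        panel = cs.simulate_sites(
            two_deme_split(100, 1000), {"A": 15, "B": 15}, 20_000, seed=33
        )
        h = hudson_fst_from_panel(panel, "A", "B")
        w = hudson_fst_from_panel(panel, "A", "B", estimator="wc")
        assert w.fst == pytest.approx(h.fst, rel=0.25)


class TestPattersonD:
    def test_identical_p3_p4_gives_exact_zero(self):
        rng = np.random.default_rng(0)
        p1, p2, p3 = (rng.random(50) for _ in range(3))
        r = patterson_d(p1, p2, p3, p3.copy(), blocks=assign_blocks(50, n_blocks=5))
        assert r.d == 0.0

    def test_hand_arithmetic_abba_site(self):
        p = {
            "p1": np.array([0.0, 0.0]),
            "p2": np.array([1.0, 1.0]),
            "p3": np.array([0.0, 0.0]),
            "p4": np.array([1.0, 1.0]),
        }
        r = patterson_d(**p, blocks=np.array([0, 1]))
        assert r.d == pytest.approx(1.0)

    def test_swapping_p3_p4_flips_sign(self):
        rng = np.random.default_rng(3)
        p1, p2, p3, p4 = (rng.random(400) for _ in range(4))
        blocks = assign_blocks(400, n_blocks=20)
        a = patterson_d(p1, p2, p3, p4, blocks=blocks)
        b = patterson_d(p1, p2, p4, p3, blocks=blocks)
        assert b.d == pytest.approx(-a.d, rel=1e-12)
        assert abs(b.z) == pytest.approx(abs(a.z), rel=1e-9)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            patterson_d([0.5], [1.2], [0.1], [0.3])

    def test_null_model_z_is_approximately_standard_normal(self):
        # four labels drawn from one panmictic deme: E[D] = 0
        model = single_deme(2000)
        n_extreme = 0
        n_reps = 200
        for rep in range(n_reps):
            panel = cs.simulate_sites(model, {"A": 20}, 2000, seed=1000 + rep)
            hap = panel.haplotypes
            freqs = [hap[i * 10 : (i + 1) * 10].mean(axis=0) for i in range(4)]
            r = patterson_d(*freqs, blocks=assign_blocks(2000, n_blocks=50))
            if abs(r.z) >= 3:
                n_extreme += 1
        assert n_extreme <= n_reps * 0.01

    def test_sfs_and_sitewise_d_agree_exactly(self, fitted_model):
        panel = cs.simulate_sites(
            fitted_model,
            {"CHB": 5, "OKI": 5, "MYNE": 5, "IKM": 5},
            4000,
            seed=44,
        )
        sitewise = patterson_d_from_panel(panel, ("CHB", "OKI", "IKM", "MYNE"))
        sfs = joint_sfs_from_panel(panel, ["CHB", "OKI", "MYNE", "IKM"])
        from_sfs = patterson_d_from_sfs(sfs, ("CHB", "OKI", "IKM", "MYNE"))
        assert from_sfs == pytest.approx(sitewise.d, abs=1e-12)


class TestSFSContainer:
    def test_single_site_entry(self):
        sfs = SFS(pops=["A", "B"], n_hap=[4, 4])
        sfs.add((1, 0))
        assert sfs.counts[(1, 0)] == 1
        assert sfs.total() == 1

    def test_site_order_invariance(self, fitted_model):
        panel = cs.simulate_sites(fitted_model, {"OKI": 4, "IKM": 4}, 800, seed=9)
        sfs1 = joint_sfs_from_panel(panel)
        perm = np.random.default_rng(1).permutation(panel.n_sites)
        shuffled = make_panel(
            panel.haplotypes[:, perm], populations=list(panel.populations)
        )
        sfs2 = joint_sfs_from_panel(shuffled)
        assert sfs1.counts == sfs2.counts

    def test_folding_symmetry_under_label_flip(self, fitted_model):
        panel = cs.simulate_sites(fitted_model, {"OKI": 4, "IKM": 4}, 800, seed=10)
        sfs = joint_sfs_from_panel(panel)
        flipped = SFS(
            pops=sfs.pops,
            n_hap=sfs.n_hap,
            counts={
                tuple(n - c for c, n in zip(e, sfs.n_hap)): w
                for e, w in sfs.counts.items()
            },
        )
        assert sfs.folded().counts == flipped.folded().counts

    def test_marginal_preserves_total(self, fitted_model):
        panel = cs.simulate_sites(fitted_model, {"OKI": 4, "IKM": 4}, 500, seed=11)
        sfs = joint_sfs_from_panel(panel)
        assert sfs.marginal(["IKM"]).total() == sfs.total()

    def test_empty_population_errors(self, fitted_model):
        panel = cs.simulate_sites(fitted_model, {"OKI": 4}, 100, seed=12)
        with pytest.raises(ValueError):
            joint_sfs_from_panel(panel, ["OKI", "IKM"])

    def test_json_round_trip(self, tmp_path, fitted_model):
        panel = cs.simulate_sites(fitted_model, {"OKI": 3, "IKM": 3}, 300, seed=13)
        sfs = joint_sfs_from_panel(panel)
        sfs.to_json(tmp_path / "sfs.json")
        back = SFS.from_json(tmp_path / "sfs.json")
        assert back.counts == sfs.counts
        assert back.pops == sfs.pops


class TestROH:
    def test_fully_heterozygous_sample_has_none(self):
        g = np.ones(500, dtype=np.int8)
        pos = np.arange(500) * 1000 + 1
        assert roh_detect(g, pos) == []
        assert total_roh([]) == 0.0

    def test_planted_homozygous_tract_recovered(self):
        rng = np.random.default_rng(5)
        S = 10_000
        pos = np.arange(S) * 1000 + 1  # 1 kb spacing
        g = rng.choice([0, 1, 2], size=S, p=[0.3, 0.4, 0.3]).astype(np.int8)
        start, end = 4000, 9000  # 5 Mb tract
        g[start:end] = rng.choice([0, 2], size=end - start)
        segs = roh_detect(g, pos)
        assert len(segs) == 1
        seg = segs[0]
        window_bp = 50 * 1000
        assert abs(seg.start_bp - pos[start]) <= window_bp
        assert abs(seg.end_bp - pos[end - 1]) <= window_bp

    def test_bottleneck_cohort_has_more_roh(self):
        import math as _math

        from ryupop.demographic_model import DemographicModel, Epoch

        # without linkage, runs of homozygosity only emerge once the
        # bottleneck pushes genome-wide autozygosity near fixation, so the
        # contrast uses an extreme founder event
        const = single_deme(10_000)
        bott = DemographicModel(
            demes={
                "A": [
                    Epoch(0, 10, 10_000),
                    Epoch(10, 40, 5),
                    Epoch(40, _math.inf, 10_000),
                ]
            },
            splits=[],
            migrations=[],
        )
        means = {}
        for name, model in [("const", const), ("bott", bott)]:
            totals = []
            for seed in range(10):
                panel = cs.simulate_sites(model, {"A": 15}, 4000, seed=700 + seed)
                geno = panel.genotypes()
                tot = sum(
                    total_roh(roh_detect(geno[i], panel.pos_bp, min_length_bp=1e5))
                    for i in range(panel.n_samples)
                )
                totals.append(tot)
            means[name] = np.mean(totals)
        assert means["bott"] > means["const"]

    def test_additive_over_chromosome_halves(self):
        rng = np.random.default_rng(8)
        S = 4000
        pos = np.arange(S) * 1000 + 1
        g = rng.choice([0, 2], size=S).astype(np.int8)
        whole = total_roh(roh_detect(g, pos, min_length_bp=1e5))
        left = total_roh(roh_detect(g[: S // 2], pos[: S // 2], min_length_bp=1e5))
        right = total_roh(roh_detect(g[S // 2 :], pos[S // 2 :], min_length_bp=1e5))
        assert left + right == pytest.approx(whole, rel=0.05)


class TestPCA:
    def test_duplicated_sample_has_identical_scores(self):
        rng = np.random.default_rng(2)
        g = rng.choice([0, 1, 2], size=(20, 500)).astype(np.int8)
        g[5] = g[3]
        scores = pca_projection(g, k=2)
        assert np.allclose(scores[5], scores[3])

    def test_deep_split_separates_on_pc1(self):
        panel = cs.simulate_sites(
            two_deme_split(3000, 500), {"A": 15, "B": 15}, 3000, seed=14
        )
        scores = pca_projection(panel.genotypes(), k=1)
        a = scores[:15, 0]
        b = scores[15:, 0]
        # the two demes occupy disjoint PC1 ranges
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_site_permutation_changes_nothing_up_to_sign(self):
        rng = np.random.default_rng(4)
        g = rng.choice([0, 1, 2], size=(15, 300)).astype(np.int8)
        s1 = pca_projection(g, k=2)
        s2 = pca_projection(g[:, rng.permutation(300)], k=2)
        for comp in range(2):
            assert np.allclose(s1[:, comp], s2[:, comp], atol=1e-8) or np.allclose(
                s1[:, comp], -s2[:, comp], atol=1e-8
            )

    def test_k_beyond_rank_errors(self):
        g = np.tile(np.array([[0, 1, 2]], dtype=np.int8), (4, 1))
        with pytest.raises(ValueError):
            pca_projection(np.vstack([g, g]), k=7)
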