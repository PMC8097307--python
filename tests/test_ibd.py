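"""Genetic-map interpolation, IBD detection on planted and coalescent truth,
gap merging and the haplotype-sharing index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ryupop import coalescent_sim as cs
from ryupop.ibd import (
    GeneticMap,
    IBDSegment,
    bp_to_cM,
    detect_ibd,
    merge_segments,
    read_segments_tsv,
    sharing_index,
    write_segments_tsv,
)

from conftest import make_panel, single_deme


class TestGeneticMap:
    @pytest.fixture()
    def gmap(self):
        return GeneticMap({"1": (np.array([1e6, 2e6]), np.array([1.0, 3.0]))})

    def test_anchor_is_exact(self, gmap):
        assert bp_to_cM(gmap, "1", 1e6) == 1.0
        assert bp_to_cM(gmap, "1", 2e6) == 3.0

    def test_interior_interpolation(self, gmap):
        assert bp_to_cM(gmap, "1", 1.5e6) == pytest.approx(2.0)

    def test_terminal_extrapolation(self, gmap):
        assert bp_to_cM(gmap, "1", 2.5e6) == pytest.approx(4.0)
        assert bp_to_cM(gmap, "1", 0.5e6) == pytest.approx(0.0)

    def test_unknown_chromosome_errors(self, gmap):
        with pytest.raises(KeyError):
            bp_to_cM(gmap, "2", 1e6)

    def test_three_column_file_round_trip(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("chrom\tbp\tcM\n1\t1000000\t1.0\n1\t2000000\t3.0\n")
        gmap = GeneticMap.from_file(path)
        assert gmap.bp_to_cM("1", 1.5e6) == pytest.approx(2.0)

    def test_plink_map_file(self, tmp_path):
        path = tmp_path / "plink.map"
        path.write_text("1 snp1 1.0 1000000\n1 snp2 3.0 2000000\n")
        gmap = GeneticMap.from_plink_map(path)
        assert gmap.bp_to_cM("1", 2e6) == pytest.approx(3.0)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap({"1": (np.array([2e6, 1e6]), np.array([1.0, 2.0]))})

    @given(
        q1=st.floats(min_value=0, max_value=5e6),
        q2=st.floats(min_value=0, max_value=5e6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_interpolation_is_monotone(self, q1, q2):
        gmap = GeneticMap(
            {"1": (np.array([1e6, 2e6, 3e6]), np.array([1.0, 3.0, 3.5]))}
        )
        lo, hi = sorted((q1, q2))
        assert bp_to_cM(gmap, "1", lo) <= bp_to_cM(gmap, "1", hi) + 1e-12


def _random_haps(rng, n_hap, freqs):
    return (rng.random((n_hap, freqs.size)) < freqs[None, :]).astype(np.int8)


class TestDetectIBD:
    def test_identical_haplotypes_one_covering_segment(self):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0.2, 0.8, 5000)  # 50 cM at 0.01 cM spacing
        H = _random_haps(rng, 4, freqs)
        H[2] = H[0]  # sample 1 hap 0 copies sample 0 hap 0
        panel = make_panel(H, spacing_cM=0.01)
        segs = detect_ibd(panel, min_cM=6.0)
        covering = [
            s
            for s in segs
            if {s.sample1, s.sample2} == {"s0", "s1"} and (s.hap1, s.hap2) == (0, 0)
        ]
        assert len(covering) == 1
        assert covering[0].length_cM >= 0.99 * (panel.pos_cM[-1] - panel.pos_cM[0])

    def test_unsorted_positions_error(self):
        rng = np.random.default_rng(2)
        H = _random_haps(rng, 4, rng.uniform(0.3, 0.7, 200))
        panel = make_panel(H, spacing_cM=0.01)
        panel.pos_bp = panel.pos_bp[::-1].copy()
        with pytest.raises(ValueError):
            detect_ibd(panel)

    def test_planted_segments_recall_precision_and_endpoints(self):
        # 30 planted 8-12 cM tracts between otherwise unrelated haplotypes
        rng = np.random.default_rng(7)
        S = 3000  # 30 cM at 0.01 cM/site
        freqs = rng.uniform(0.2, 0.8, S)
        n_pairs = 30
        H = _random_haps(rng, 4 * n_pairs, freqs)
        truth = []
        for pair in range(n_pairs):
            a, b = 4 * pair, 4 * pair + 2  # hap0 of two adjacent samples
            length = rng.integers(800, 1200)
            start = rng.integers(0, S - length)
            H[b, start : start + length] = H[a, start : start + length]
            truth.append((2 * pair, 2 * pair + 1, start, start + length))
        panel = make_panel(H, spacing_cM=0.01)
        segs = detect_ibd(panel, min_cM=6.0)

        hits = 0
        used = []
        for si, sj, start, end in truth:
            t_start, t_end = panel.pos_cM[start], panel.pos_cM[end - 1]
            match = [
                s
                for s in segs
                if {s.sample1, s.sample2} == {f"s{si}", f"s{sj}"}
                and s.start_cM < t_end
                and s.end_cM > t_start
            ]
            if not match:
                continue
            best = max(match, key=lambda s: min(s.end_cM, t_end) - max(s.start_cM, t_start))
            if abs(best.start_cM - t_start) < 0.5 and abs(best.end_cM - t_end) < 0.5:
                hits += 1
            used.append(best)
        recall = hits / n_pairs
        assert recall >= 0.9
        precision = len(used) / max(len(segs), 1)
        assert precision >= 0.9

    def test_precision_against_coalescent_truth(self):
        # haplotype pairs built from a simulated TMRCA partition with
        # TMRCA-dependent mutation discordance
        model = single_deme(300)
        L_cM, spacing = 300.0, 0.02
        n_pairs = 40
        truth = cs.simulate_pairwise_ibd(model, "A", n_pairs, L_cM, seed=3)
        rng = np.random.default_rng(33)
        S = int(L_cM / spacing)
        pos_cM = np.arange(S) * spacing
        freqs = rng.uniform(0.2, 0.8, S)
        mu_site = 1.25e-8 * spacing * 1e6  # per generation per site span
        H = np.empty((4 * n_pairs, S), dtype=np.int8)
        truth_by_pair = {}
        for pair in range(n_pairs):
            mine = [t for t in truth if t.sample1 == f"p{pair}a"]
            g_site = np.empty(S)
            for t in mine:
                lo = np.searchsorted(pos_cM, t.start_cM)
                hi = np.searchsorted(pos_cM, t.end_cM)
                g_site[lo:hi] = t.tmrca_gen
            anc = (rng.random(S) < freqs).astype(np.int8)
            flip = -np.expm1(-g_site * mu_site)
            h1 = np.where(rng.random(S) < flip, 1 - anc, anc)
            h2 = np.where(rng.random(S) < flip, 1 - anc, anc)
            H[4 * pair] = h1
            H[4 * pair + 2] = h2
            # second haplotype of each sample: unrelated noise
            H[4 * pair + 1] = (rng.random(S) < freqs).astype(np.int8)
            H[4 * pair + 3] = (rng.random(S) < freqs).astype(np.int8)
            truth_by_pair[(f"s{2 * pair}", f"s{2 * pair + 1}")] = [
                (t.start_cM, t.end_cM) for t in mine if t.length_cM >= 5.0
            ]
        panel = make_panel(H, spacing_cM=spacing)
        segs = detect_ibd(panel, min_cM=6.0)
        assert segs, "expected some detected segments in this design"
        ok = 0
        for s in segs:
            key = tuple(sorted((s.sample1, s.sample2)))
            cands = truth_by_pair.get((key[0], key[1]), [])
            cover = max(
                (
                    min(s.end_cM, t_end) - max(s.start_cM, t_start)
                    for t_start, t_end in cands
                ),
                default=0.0,
            )
            if cover >= 0.7 * s.length_cM:
                ok += 1
        assert ok / len(segs) >= 0.9

    def test_distant_demes_share_almost_nothing(self):
        from conftest import two_deme_split

        model = two_deme_split(100_000, 10_000)
        panel = cs.simulate_sites(model, {"A": 5, "B": 5}, 4000, seed=12)
        # rescale positions to SNP-array-like density: 4000 sites over 40 cM
        panel.pos_cM = np.arange(panel.n_sites) * 0.01
        segs = detect_ibd(panel, min_cM=6.0)
        pop_of = dict(zip(panel.samples, panel.populations))
        cross = [s for s in segs if pop_of[s.sample1] != pop_of[s.sample2]]
        n_cross_pairs = 5 * 5 * 4
        assert len(cross) / n_cross_pairs < 0.05


class TestMergeSegments:
    def _seg(self, start, end, **kw):
        base = dict(
            sample1="x", sample2="y", hap1=0, hap2=0, chrom="1",
            start_bp=int(start * 1e6) + 1, end_bp=int(end * 1e6) + 1,
            start_cM=start, end_cM=end,
        )
        base.update(kw)
        return IBDSegment(**base)

    def test_single_segment_unchanged(self):
        segs = [self._seg(0.0, 4.0)]
        assert merge_segments(segs) == segs

    def test_short_clean_gap_merged(self):
        merged = merge_segments([self._seg(0.0, 4.0), self._seg(4.4, 8.4)])
        assert len(merged) == 1
        assert merged[0].length_cM == pytest.approx(8.4)

    def test_wide_gap_not_merged(self):
        merged = merge_segments([self._seg(0.0, 4.0), self._seg(6.0, 10.0)])
        assert len(merged) == 2

    def test_discordant_gap_blocks_merge(self):
        rng = np.random.default_rng(5)
        S = 1000
        H = _random_haps(rng, 4, rng.uniform(0.3, 0.7, S))
        H[2] = H[0]
        # make the gap 9.95-10.05 cM discordant at 3 sites
        gap = slice(995, 998)
        H[2, gap] = 1 - H[0, gap]
        panel = make_panel(H, spacing_cM=0.01)
        segs = [
            self._seg(0.0, 9.9, sample1="s0", sample2="s1"),
            self._seg(10.1, 20.0, sample1="s0", sample2="s1"),
        ]
        merged = merge_segments(segs, panel=panel)
        assert len(merged) == 2  # 3 discordant sites in the gap > allowance

    def test_merge_is_idempotent(self):
        segs = [self._seg(0.0, 4.0), self._seg(4.3, 9.0), self._seg(15.0, 22.0)]
        once = merge_segments(segs)
        twice = merge_segments(once)
        assert [(s.start_cM, s.end_cM) for s in once] == [
            (s.start_cM, s.end_cM) for s in twice
        ]

    def test_tsv_round_trip(self, tmp_path):
        segs = [self._seg(0.0, 4.0), self._seg(6.0, 14.5)]
        path = tmp_path / "segs.tsv"
        write_segments_tsv(segs, path, provenance="seed=1")
        back = read_segments_tsv(path)
        assert [(s.start_cM, s.end_cM) for s in back] == [
            (s.start_cM, s.end_cM) for s in segs
        ]


class TestSharingIndex:
    def _seg(self, s1, s2, length):
        return IBDSegment(
            sample1=s1, sample2=s2, hap1=0, hap2=0, chrom="1",
            start_bp=1, end_bp=int(length * 1e6) + 1,
            start_cM=0.0, end_cM=length,
        )

    def test_no_segments_gives_zero(self):
        r = sharing_index([], ["a", "b"], ["c", "d"])
        assert r.index == 0.0

    def test_worked_example_four_pairs_times_ten(self):
        # n=2, m=2, every cross pair shares 10 cM: (40/4) x 100 = 1000
        segs = [
            self._seg(a, b, 10.0) for a in ("a1", "a2") for b in ("b1", "b2")
        ]
        r = sharing_index(segs, ["a1", "a2"], ["b1", "b2"])
        assert r.index == pytest.approx(1000.0)

    def test_linearity_in_segment_length(self):
        segs = [self._seg("a1", "b1", 7.0)]
        double = [self._seg("a1", "b1", 14.0)]
        r1 = sharing_index(segs, ["a1"], ["b1"])
        r2 = sharing_index(double, ["a1"], ["b1"])
        assert r2.index == pytest.approx(2 * r1.index)

    def test_symmetry_and_sample_order_invariance(self):
        segs = [self._seg("a1", "b1", 5.0), self._seg("b2", "a2", 3.0)]
        r_ij = sharing_index(segs, ["a1", "a2"], ["b1", "b2"])
        r_ji = sharing_index(segs, ["b2", "b1"], ["a2", "a1"])
        assert r_ij.index == pytest.approx(r_ji.index)

    def test_within_population_uses_unordered_pairs(self):
        segs = [self._seg("a1", "a2", 6.0)]
        r = sharing_index(segs, ["a1", "a2", "a3"], ["a1", "a2", "a3"])
        assert r.n_pairs == 3
        assert r.index == pytest.approx(6.0 / 3 * 100)

    def test_empty_population_errors(self):
        with pytest.raises(ValueError):
            sharing_index([], [], ["a"])

    def test_partial_overlap_rejected(self):
        with pytest.raises(ValueError):
            sharing_index([], ["a", "b"], ["b", "c"])
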