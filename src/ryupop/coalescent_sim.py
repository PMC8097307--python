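"""Synthetic-data generation under a demographic model.

Two complementary engines:

* an independent-site structured coalescent (splits, size epochs, symmetric
  migration) producing SNP-array-like phased panels and joint site-frequency
  spectra, with exactly one mutation placed uniformly on each genealogy's
  total branch length (or an optional Poisson/segregating-site mode);
* a pairwise sequentially-Markov renewal process producing ground-truth IBD
  segments with their TMRCA for haplotype pairs sampled from one deme.

Simulating every site as an independent genealogy is deliberate: all the
statistics consumed downstream (F_ST, Patterson's D, SFS) are single-site
functionals, and the block jackknife used on real, linked data remains valid
(if conservative) on independent sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _engine
from .demographic_model import DemographicModel
from .popgen_stats import SFS

__all__ = [
    "HaplotypePanel",
    "IBDSegmentTruth",
    "simulate_sites",
    "simulate_joint_sfs",
    "simulate_pairwise_ibd",
    "pair_coalescence_pmf",
]


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with physical and genetic coordinates.

    Haplotypes are stored two rows per diploid sample (rows ``2i`` and
    ``2i+1`` belong to sample ``i``); alleles are 0 (ancestral/reference) or
    1 (derived/alternate).
    """

    samples: list[str]
    populations: list[str]
    haplotypes: np.ndarray  # (2 n_samples, n_sites) int8
    pos_bp: np.ndarray  # (n_sites,) int64, 1-based
    pos_cM: np.ndarray  # (n_sites,) float64, non-decreasing
    chrom: str = "1"
    site_tmrca: np.ndarray | None = None  # per-site root time (diagnostic)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cM = np.asarray(self.pos_cM, dtype=np.float64)
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("expected two haplotypes per diploid sample")
        if len(self.populations) != len(self.samples):
            raise ValueError("one population label per sample required")
        if self.haplotypes.shape[1] != self.pos_bp.size:
            raise ValueError("site count mismatch")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        if np.any(np.diff(self.pos_bp) <= 0):
            raise ValueError("physical positions must be strictly increasing")
        if np.any(np.diff(self.pos_cM) < 0):
            raise ValueError("genetic positions must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.haplotypes.shape[1])

    @property
    def hap_populations(self) -> np.ndarray:
        return np.repeat(np.asarray(self.populations), 2)

    def genotypes(self) -> np.ndarray:
        """Unphased diploid genotype codes {0,1,2} (samples x sites)."""
        return (self.haplotypes[0::2, :] + self.haplotypes[1::2, :]).astype(np.int8)

    def allele_freq(self, pop: str | None = None) -> np.ndarray:
        if pop is None:
            return self.haplotypes.mean(axis=0)
        sel = np.flatnonzero(self.hap_populations == pop)
        if sel.size == 0:
            raise ValueError(f"population {pop!r} has no samples")
        return self.haplotypes[sel, :].mean(axis=0)


@dataclass
class IBDSegmentTruth:
    """A ground-truth shared tract between two haplotypes, with its TMRCA."""

    sample1: str
    sample2: str
    hap1: int
    hap2: int
    chrom: str
    start_bp: int
    end_bp: int
    start_cM: float
    end_cM: float
    tmrca_gen: int

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


def _draw_positions(rng: np.random.Generator, n_sites: int, length_bp: int) -> np.ndarray:
    """Sorted unique 1-based positions, uniform over the chromosome."""
    if length_bp < n_sites:
        raise ValueError("chromosome shorter than the requested site count")
    pos = np.unique(rng.integers(1, length_bp + 1, size=int(n_sites * 1.05) + 16))
    while pos.size < n_sites:
        extra = rng.integers(1, length_bp + 1, size=n_sites)
        pos = np.unique(np.concatenate([pos, extra]))
    if pos.size > n_sites:
        pos = np.sort(rng.choice(pos, size=n_sites, replace=False))
    return pos.astype(np.int64)


def _sample_names(sample_sizes: dict[str, int]) -> tuple[list[str], list[str]]:
    samples, pops = [], []
    for pop, n in sample_sizes.items():
        for i in range(n):
            samples.append(f"{pop}_{i:04d}")
            pops.append(pop)
    return samples, pops


def simulate_sites(
    model: DemographicModel,
    sample_sizes: dict[str, int],
    n_sites: int,
    seed: int,
    chrom: str = "1",
    chrom_length_bp: int | None = None,
    cM_per_Mb: float = 1.0,
    genetic_map=None,
    mutation_mode: str = "one_per_tree",
    ascertain_maf: float | None = None,
) -> HaplotypePanel:
    """Simulate a phased panel of independent biallelic sites.

    Each site carries one structured-coalescent genealogy and exactly one
    mutation placed uniformly on its total branch length (array-like
    segregating sites).  ``mutation_mode="poisson"`` instead treats each
    site as a single base and keeps genealogies with probability
    proportional to the chance of carrying a mutation (the infinite-sites
    segregating-site ensemble), redropping monomorphic draws.  With
    ``ascertain_maf`` set, sites whose global minor
    allele frequency is at or below the threshold are dropped afterwards (the
    returned panel then has fewer than ``n_sites`` sites).
    """
    compiled = _engine.CompiledModel(model)
    lin0 = compiled.initial_demes(sample_sizes)
    if lin0.size < 2:
        raise ValueError("need at least 2 sampled haplotypes")
    if chrom_length_bp is None:
        chrom_length_bp = max(250_000_000, int(n_sites) * 2500)
    rng = np.random.default_rng([int(seed) % (2**31), 0x5EED])
    pos_bp = _draw_positions(rng, n_sites, chrom_length_bp)

    mut_mode = _engine.MUT_ONE_PER_TREE
    mu_span = 0.0
    if mutation_mode == "poisson":
        mut_mode = _engine.MUT_POISSON
        # a site is a single base: weights stay in the linear (~ mu T) regime,
        # reproducing the infinite-sites segregating-site ensemble
        mu_span = model.mutation_rate
    elif mutation_mode != "one_per_tree":
        raise ValueError(f"unknown mutation mode {mutation_mode!r}")

    derived, root_time = _engine.simulate_site_genealogies(
        compiled, lin0, n_sites, seed, mut_mode, mu_span
    )
    derived = derived.T.copy()  # haplotypes x sites

    if genetic_map is not None:
        pos_cM = np.array([genetic_map.bp_to_cM(chrom, int(b)) for b in pos_bp])
    else:
        pos_cM = pos_bp * (cM_per_Mb / 1e6)

    if ascertain_maf is not None:
        freq = derived.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        keep = maf > ascertain_maf
        derived = derived[:, keep]
        pos_bp = pos_bp[keep]
        pos_cM = pos_cM[keep]
        root_time = root_time[keep]

    samples, pops = _sample_names(sample_sizes)
    return HaplotypePanel(
        samples=samples,
        populations=pops,
        haplotypes=derived,
        pos_bp=pos_bp,
        pos_cM=pos_cM,
        chrom=chrom,
        site_tmrca=root_time,
    )


def simulate_joint_sfs(
    model: DemographicModel,
    sample_sizes: dict[str, int],
    n_sites: int,
    seed: int,
    mutation_mode: str = "one_per_tree",
) -> SFS:
    """Joint derived-allele-count spectrum of independent simulated sites."""
    compiled = _engine.CompiledModel(model)
    lin0 = compiled.initial_demes(sample_sizes)
    if lin0.size < 2:
        raise ValueError("need at least 2 sampled haplotypes")
    mut_mode = _engine.MUT_ONE_PER_TREE
    mu_span = 0.0
    if mutation_mode == "poisson":
        mut_mode = _engine.MUT_POISSON
        mu_span = model.mutation_rate
    derived, _ = _engine.simulate_site_genealogies(
        compiled, lin0, n_sites, seed, mut_mode, mu_span
    )
    pops = [p for p, n in sample_sizes.items() if n > 0]
    onehot = np.zeros((lin0.size, len(pops)), dtype=np.int64)
    col = 0
    row = 0
    for pop, n in sample_sizes.items():
        if n > 0:
            onehot[row : row + 2 * n, col] = 1
            col += 1
        row += 2 * n
    counts = derived.astype(np.int64) @ onehot  # n_sites x n_pops
    uniq, mult = np.unique(counts, axis=0, return_counts=True)
    sfs = SFS(pops=pops, n_hap=[2 * sample_sizes[p] for p in pops])
    for r, m in zip(uniq, mult):
        sfs.add(tuple(int(x) for x in r), float(m))
    return sfs


# ----------------------------------------------------------------- pairwise IBD

def pair_coalescence_pmf(
    model: DemographicModel, deme: str, tail_mass: float = 1e-9
) -> np.ndarray:
    """P(TMRCA = g) for a haplotype pair sampled from ``deme`` at present.

    The pair follows the deme's own size trajectory through its ancestors
    (migration is ignored); per generation g the coalescence probability is
    ``1/copies(g)`` and ``P(g) = h_g * prod_{k<g}(1 - h_k)``.  The array is
    truncated once the remaining mass drops below ``tail_mass`` and
    renormalised; index 0 corresponds to g = 1.
    """
    if deme not in model.demes:
        raise ValueError(f"unknown deme {deme!r}")
    # build the (start, end, copies) chain through ancestors
    chain = []
    cur = deme
    anc_of = {s.derived_deme: s.ancestral_deme for s in model.splits}
    while True:
        for ep in model.demes[cur]:
            chain.append((ep.start_gen, ep.end_gen, model.gene_copies(ep.size)))
        if math.isinf(model.demes[cur][-1].end_gen):
            break
        cur = anc_of[cur]
    chain.sort()
    lo0, _ = model.existence(deme)
    if lo0 != 0:
        raise ValueError(f"deme {deme!r} does not exist at present")

    hs = []
    surv = 1.0
    for start, end, copies in chain:
        h = 1.0 / copies
        if math.isinf(end):
            # run until the tail mass is exhausted
            n_more = int(math.ceil(math.log(tail_mass / max(surv, 1e-300)) / math.log(1 - h))) + 1
            n_more = max(n_more, 1)
            hs.append(np.full(n_more, h))
            break
        n = int(round(end - start))
        if n > 0:
            hs.append(np.full(n, h))
            surv *= (1 - h) ** n
            if surv < tail_mass:
                break
    h_arr = np.concatenate(hs)
    log_surv = np.concatenate([[0.0], np.cumsum(np.log1p(-h_arr))])[:-1]
    pmf = h_arr * np.exp(log_surv)
    return pmf / pmf.sum()


def simulate_pairwise_ibd(
    model: DemographicModel,
    deme: str,
    n_pairs: int,
    chrom_length_cM: float,
    seed: int,
    min_emit_cM: float = 0.0,
    bp_per_cM: float = 1e6,
    chrom: str = "1",
) -> list[IBDSegmentTruth]:
    """Ground-truth IBD partition for haplotype pairs from one deme.

    The TMRCA process along the chromosome is a stationary Markov renewal
    process: segment-level TMRCAs are drawn from the length-biased
    distribution ``Q(g) ~ P(g) * 2g`` and segment genetic lengths are
    exponential with rate ``2g`` per Morgan, so that the pointwise TMRCA
    marginal is ``P(g)`` and the expected number of segments from generation
    g with length in [a, b) Morgans is ``L * P(g) * 2g * (exp(-2ga) -
    exp(-2gb))``.  Segments tile the chromosome; adjacent segments that drew
    the same TMRCA are merged before emission.  Only segments of genetic
    length >= ``min_emit_cM`` are returned (the partition itself always
    tiles).
    """
    if chrom_length_cM < 0:
        raise ValueError("chromosome length must be non-negative")
    if chrom_length_cM == 0:
        return []
    pmf = pair_coalescence_pmf(model, deme)
    g = np.arange(1, pmf.size + 1, dtype=np.float64)
    q = pmf * 2.0 * g
    c = q.sum()  # expected segments per Morgan
    q_cum = np.cumsum(q / c)
    L = chrom_length_cM / 100.0  # Morgans

    rng = np.random.default_rng([int(seed) % (2**31), 0x1BD])
    out: list[IBDSegmentTruth] = []
    exp_n = L * c
    for pair in range(n_pairs):
        gs_parts = []
        len_parts = []
        tot = 0.0
        while tot < L:
            batch = int(max(64, 1.2 * (exp_n - tot * c) + 4 * math.sqrt(exp_n) + 16))
            gg = np.searchsorted(q_cum, rng.random(batch)) + 1
            ll = rng.exponential(1.0 / (2.0 * gg))
            gs_parts.append(gg)
            len_parts.append(ll)
            tot += ll.sum()
        gg = np.concatenate(gs_parts)
        ll = np.concatenate(len_parts)
        ends = np.cumsum(ll)
        last = int(np.searchsorted(ends, L))
        gg = gg[: last + 1]
        ends = ends[: last + 1]
        ends[-1] = L
        starts = np.concatenate([[0.0], ends[:-1]])
        # merge adjacent equal-TMRCA segments into maximal constant spans
        keep = np.concatenate([[True], gg[1:] != gg[:-1]])
        gseg = gg[keep]
        sseg = starts[keep]
        eseg = np.concatenate([sseg[1:], [L]])
        lengths_cM = (eseg - sseg) * 100.0
        sel = np.flatnonzero(lengths_cM >= min_emit_cM)
        s1 = f"p{pair}a"
        s2 = f"p{pair}b"
        for i in sel:
            scm = sseg[i] * 100.0
            ecm = eseg[i] * 100.0
            out.append(
                IBDSegmentTruth(
                    sample1=s1,
                    sample2=s2,
                    hap1=0,
                    hap2=0,
                    chrom=chrom,
                    start_bp=int(round(scm * bp_per_cM)) + 1,
                    end_bp=int(round(ecm * bp_per_cM)) + 1,
                    start_cM=float(scm),
                    end_cM=float(ecm),
                    tmrca_gen=int(gseg[i]),
                )
            )
    return out
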