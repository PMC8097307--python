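"""Core population-genetic statistics.

Hudson's F_ST (ratio of averages) with weighted block-jackknife standard
errors, Patterson's D (ABBA-BABA) with a block-jackknife Z score, joint
site-frequency spectra, runs-of-homozygosity detection and a plumbing PCA.

The weighted delete-one-block jackknife follows the usual unequal-block-size
construction (Busing's formula), with blocks weighted by the number of usable
sites they contain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SFS",
    "FstResult",
    "DStatResult",
    "ROHSegment",
    "assign_blocks",
    "block_jackknife",
    "hudson_fst",
    "hudson_fst_from_panel",
    "patterson_d",
    "patterson_d_from_sfs",
    "joint_sfs_from_panel",
    "roh_detect",
    "pca_projection",
]


# --------------------------------------------------------------------------- SFS

@dataclass
class SFS:
    """Joint derived-allele-count spectrum over labelled populations.

    ``counts`` maps a tuple of per-population derived-allele counts to the
    number of sites with that configuration.  Monomorphic configurations may
    be present; statistics that require segregating sites skip them.
    """

    pops: list[str]
    n_hap: list[int]
    counts: dict[tuple[int, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pops) != len(self.n_hap):
            raise ValueError("pops and n_hap must have equal length")
        for entry in self.counts:
            if len(entry) != len(self.pops):
                raise ValueError(f"entry {entry} does not match population count")
            for c, n in zip(entry, self.n_hap):
                if not 0 <= c <= n:
                    raise ValueError(f"entry {entry} out of range for n_hap {self.n_hap}")

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def add(self, entry: tuple[int, ...], weight: float = 1.0) -> None:
        self.counts[entry] = self.counts.get(entry, 0.0) + weight

    def marginal(self, pops: list[str]) -> "SFS":
        """Marginal spectrum over a subset of populations (order as given)."""
        sel = [self.pops.index(p) for p in pops]
        out = SFS(pops=list(pops), n_hap=[self.n_hap[i] for i in sel])
        for entry, w in self.counts.items():
            out.add(tuple(entry[i] for i in sel), w)
        return out

    def dense(self) -> np.ndarray:
        """Dense array representation (practical for up to ~3 populations)."""
        shape = tuple(n + 1 for n in self.n_hap)
        arr = np.zeros(shape, dtype=np.float64)
        for entry, w in self.counts.items():
            arr[entry] += w
        return arr

    def folded(self) -> "SFS":
        """Fold by global minor-allele count (derived/ancestral symmetrised)."""
        n_tot = sum(self.n_hap)
        out = SFS(pops=list(self.pops), n_hap=list(self.n_hap))
        for entry, w in self.counts.items():
            flipped = tuple(n - c for c, n in zip(entry, self.n_hap))
            s = 2 * sum(entry)
            if s > n_tot or (s == n_tot and flipped < entry):
                entry = flipped  # ties folded to the lexicographic minimum
            out.add(entry, w)
        return out

    def is_monomorphic_entry(self, entry: tuple[int, ...]) -> bool:
        s = sum(entry)
        return s == 0 or s == sum(self.n_hap)

    # serialization -----------------------------------------------------------
    def to_json(self, path) -> None:
        data = {
            "pops": self.pops,
            "n_hap": self.n_hap,
            "entries": [[list(k), v] for k, v in sorted(self.counts.items())],
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path) -> "SFS":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            pops=data["pops"],
            n_hap=data["n_hap"],
            counts={tuple(k): v for k, v in data["entries"]},
        )


def joint_sfs_from_panel(panel, demes: list[str] | None = None) -> SFS:
    """Joint SFS of a phased panel; derived allele = the non-reference allele."""
    pops = demes if demes is not None else sorted(set(panel.populations))
    hap_pops = np.repeat(np.asarray(panel.populations), 2)
    cols = []
    n_hap = []
    for p in pops:
        sel = np.flatnonzero(hap_pops == p)
        if sel.size == 0:
            raise ValueError(f"population {p!r} has no samples")
        cols.append(panel.haplotypes[sel, :].sum(axis=0))
        n_hap.append(int(sel.size))
    counts = np.stack(cols, axis=1)  # n_sites x n_pops
    uniq, mult = np.unique(counts, axis=0, return_counts=True)
    sfs = SFS(pops=list(pops), n_hap=n_hap)
    for row, m in zip(uniq, mult):
        sfs.add(tuple(int(x) for x in row), float(m))
    return sfs


# ------------------------------------------------------------------- jackknife

def assign_blocks(
    n_sites: int,
    pos_cM: np.ndarray | None = None,
    block_cM: float = 5.0,
    n_blocks: int = 200,
) -> np.ndarray:
    """Contiguous jackknife block ids per site.

    With a genetic map, blocks are contiguous ``block_cM`` windows; without
    one, sites are cut into ``n_blocks`` equal-count contiguous blocks.
    """
    if pos_cM is not None:
        pos = np.asarray(pos_cM, dtype=float)
        ids = np.floor((pos - pos[0]) / block_cM).astype(np.int64)
        # re-index to consecutive ids
        _, ids = np.unique(ids, return_inverse=True)
        return ids
    n_blocks = min(n_blocks, n_sites)
    return np.minimum(
        (np.arange(n_sites) * n_blocks) // n_sites, n_blocks - 1
    ).astype(np.int64)


def block_jackknife(num: np.ndarray, den: np.ndarray, blocks: np.ndarray):
    """Ratio estimator ``sum(num)/sum(den)`` with weighted jackknife SE.

    Blocks are weighted by their site counts; returns (theta, se, n_blocks).
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    blocks = np.asarray(blocks)
    uniq = np.unique(blocks)
    B = uniq.size
    if B < 2:
        raise ValueError("block jackknife requires at least 2 blocks")
    tot_num = num.sum()
    tot_den = den.sum()
    if tot_den == 0:
        raise ValueError("zero denominator over all loci")
    theta = tot_num / tot_den

    bn = np.zeros(B)
    bd = np.zeros(B)
    bm = np.zeros(B)
    inv = np.searchsorted(uniq, blocks)
    np.add.at(bn, inv, num)
    np.add.at(bd, inv, den)
    np.add.at(bm, inv, 1.0)
    n_tot = bm.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_j = (tot_num - bn) / (tot_den - bd)
    theta_j = np.where(np.isfinite(theta_j), theta_j, theta)
    h = n_tot / bm
    theta_dot = B * theta - np.sum((1.0 - bm / n_tot) * theta_j)
    var = np.mean((h * theta - (h - 1.0) * theta_j - theta_dot) ** 2 / (h - 1.0))
    return theta, float(np.sqrt(max(var, 0.0))), int(B)


# ------------------------------------------------------------------------ F_ST

@dataclass
class FstResult:
    fst: float
    se: float
    n_loci: int
    n_blocks: int = 0
    n_skipped: int = 0
    estimator: str = "hudson"


def _hudson_terms(d1, n1, d2, n2):
    p1 = d1 / n1
    p2 = d2 / n2
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _wc_terms(d1, n1, d2, n2):
    # Weir-Cockerham theta for two populations, haploid allele counts
    p1 = d1 / n1
    p2 = d2 / n2
    nbar = (n1 + n2) / 2.0
    r = 2.0
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2
    )
    return a, a + b


def hudson_fst(
    d1,
    n1,
    d2,
    n2,
    blocks: np.ndarray | None = None,
    estimator: str = "hudson",
) -> FstResult:
    """F_ST from per-locus derived-allele counts and haplotype sample sizes.

    Ratio-of-averages: per-locus numerators and denominators are averaged
    before the ratio is taken.  Loci with fewer than two haplotypes in either
    population or a zero denominator are skipped and counted.
    """
    d1, n1, d2, n2 = (np.asarray(x, dtype=float) for x in (d1, n1, d2, n2))
    usable = (n1 >= 2) & (n2 >= 2)
    if estimator == "hudson":
        num = np.zeros_like(d1)
        den = np.zeros_like(d1)
        num[usable], den[usable] = _hudson_terms(
            d1[usable], n1[usable], d2[usable], n2[usable]
        )
    elif estimator == "wc":
        num = np.zeros_like(d1)
        den = np.zeros_like(d1)
        num[usable], den[usable] = _wc_terms(
            d1[usable], n1[usable], d2[usable], n2[usable]
        )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    usable &= den != 0
    n_usable = int(usable.sum())
    if n_usable < 2:
        raise ValueError("fewer than 2 usable loci")
    if blocks is None:
        blocks = assign_blocks(len(d1))
    theta, se, n_blocks = block_jackknife(
        num[usable], den[usable], np.asarray(blocks)[usable]
    )
    return FstResult(
        fst=float(theta),
        se=se,
        n_loci=n_usable,
        n_blocks=n_blocks,
        n_skipped=int(len(d1) - n_usable),
        estimator=estimator,
    )


def hudson_fst_from_panel(panel, pop_a: str, pop_b: str, **kw) -> FstResult:
    hap_pops = np.repeat(np.asarray(panel.populations), 2)
    sa = np.flatnonzero(hap_pops == pop_a)
    sb = np.flatnonzero(hap_pops == pop_b)
    if sa.size < 2 or sb.size < 2:
        raise ValueError("need at least 2 haplotypes per population")
    d1 = panel.haplotypes[sa, :].sum(axis=0)
    d2 = panel.haplotypes[sb, :].sum(axis=0)
    n1 = np.full(panel.n_sites, sa.size)
    n2 = np.full(panel.n_sites, sb.size)
    if "blocks" not in kw:
        kw["blocks"] = assign_blocks(panel.n_sites, pos_cM=panel.pos_cM)
    return hudson_fst(d1, n1, d2, n2, **kw)


# ------------------------------------------------------------------ Patterson D

@dataclass
class DStatResult:
    d: float
    z: float
    se: float
    n_blocks: int
    abba_sum: float
    baba_sum: float
    n_loci: int


def patterson_d(p1, p2, p3, p4, blocks: np.ndarray | None = None) -> DStatResult:
    """Patterson's D from per-site derived-allele frequencies of P1..P4.

    ``D = sum (p1-p2)(p3-p4) / sum (p1+p2-2 p1 p2)(p3+p4-2 p3 p4)``; positive
    values indicate excess allele sharing between P2 and P4 (equivalently P1
    and P3).  Z is D over its weighted block-jackknife standard error.
    """
    p1, p2, p3, p4 = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p4))
    for p in (p1, p2, p3, p4):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
    num = (p1 - p2) * (p3 - p4)
    den = (p1 + p2 - 2 * p1 * p2) * (p3 + p4 - 2 * p3 * p4)
    if den.sum() == 0:
        raise ValueError("zero denominator: no informative sites")
    if blocks is None:
        blocks = assign_blocks(len(p1))
    d, se, n_blocks = block_jackknife(num, den, blocks)
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    # ABBA/BABA accumulators (biallelic frequency form)
    abba = float(np.sum((1 - p1) * p2 * p3 * (1 - p4) + p1 * (1 - p2) * (1 - p3) * p4))
    baba = float(np.sum(p1 * (1 - p2) * p3 * (1 - p4) + (1 - p1) * p2 * (1 - p3) * p4))
    z = d / se if se > 0 else np.inf * np.sign(d) if d != 0 else 0.0
    return DStatResult(
        d=float(d),
        z=float(z),
        se=float(se),
        n_blocks=n_blocks,
        abba_sum=abba,
        baba_sum=baba,
        n_loci=int(len(p1)),
    )


def patterson_d_from_panel(panel, pops: tuple[str, str, str, str], **kw) -> DStatResult:
    hap_pops = np.repeat(np.asarray(panel.populations), 2)
    freqs = []
    for p in pops:
        sel = np.flatnonzero(hap_pops == p)
        if sel.size == 0:
            raise ValueError(f"population {p!r} has no samples")
        freqs.append(panel.haplotypes[sel, :].mean(axis=0))
    if "blocks" not in kw:
        kw["blocks"] = assign_blocks(panel.n_sites, pos_cM=panel.pos_cM)
    return patterson_d(*freqs, **kw)


def patterson_d_from_sfs(sfs: SFS, pops: tuple[str, str, str, str]) -> float:
    """D statistic computed from a joint SFS (no Z; blocks are lost)."""
    marg = sfs.marginal(list(pops))
    n = np.asarray(marg.n_hap, dtype=float)
    num = 0.0
    den = 0.0
    for entry, w in marg.counts.items():
        p = np.asarray(entry, dtype=float) / n
        num += w * (p[0] - p[1]) * (p[2] - p[3])
        den += w * (p[0] + p[1] - 2 * p[0] * p[1]) * (p[2] + p[3] - 2 * p[2] * p[3])
    if den == 0:
        raise ValueError("zero denominator: no informative sites")
    return num / den


# ------------------------------------------------------------------------- ROH

@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    length_bp: int
    n_sites: int


def roh_detect(
    genotypes: np.ndarray,
    pos_bp: np.ndarray,
    sample: str = "",
    chrom: str = "1",
    window_sites: int = 50,
    max_het_per_window: int = 1,
    min_sites: int = 50,
    min_length_bp: float = 1e6,
) -> list[ROHSegment]:
    """Sliding-window runs-of-homozygosity scan on one sample's genotypes.

    Genotypes are diploid codes {0,1,2}, -1 for missing.  A window of
    ``window_sites`` consecutive sites passes when it contains at most
    ``max_het_per_window`` heterozygous calls; sites covered by any passing
    window form candidate runs, and maximal runs with at least ``min_sites``
    sites spanning at least ``min_length_bp`` are reported.
    """
    g = np.asarray(genotypes)
    pos = np.asarray(pos_bp)
    S = g.size
    if S < window_sites:
        return []
    het = (g == 1).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(het)])
    win_het = csum[window_sites:] - csum[:-window_sites]
    passing = win_het <= max_het_per_window  # window starting at i
    covered = np.zeros(S, dtype=bool)
    idx = np.flatnonzero(passing)
    for i in idx:
        covered[i : i + window_sites] = True

    out: list[ROHSegment] = []
    if not covered.any():
        return out
    d = np.diff(covered.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if covered[0]:
        starts.insert(0, 0)
    if covered[-1]:
        ends.append(S)
    for s, e in zip(starts, ends):
        n_sites = e - s
        length = int(pos[e - 1] - pos[s] + 1)
        if n_sites >= min_sites and length >= min_length_bp:
            out.append(
                ROHSegment(
                    sample=sample,
                    chrom=chrom,
                    start_bp=int(pos[s]),
                    end_bp=int(pos[e - 1] + 1),
                    length_bp=length,
                    n_sites=n_sites,
                )
            )
    return out


def total_roh(segments: list[ROHSegment]) -> float:
    return float(sum(s.length_bp for s in segments))


# ------------------------------------------------------------------------- PCA

def pca_projection(genotypes: np.ndarray, k: int) -> np.ndarray:
    """Sample scores from SVD of the frequency-standardised genotype matrix.

    ``genotypes`` is samples x sites with codes {0,1,2}, -1 for missing;
    missing entries are mean-imputed, columns are centred and scaled by
    ``sqrt(p(1-p))`` where p is the sample allele frequency.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    scale = np.sqrt(p * (1 - p))
    keep = scale > 0
    x = (g[:, keep] - col_mean[keep]) / scale[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    return u[:, :k] * s[:k]
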