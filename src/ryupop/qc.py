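"""Genotype and sample quality control for SNP-array-like panels.

Filters mirror common array QC practice: per-SNP and per-sample call rate
(default 98%), an exact Hardy-Weinberg test (sites with p <= 1e-6 removed),
a minor-allele-frequency floor (polymorphic in the focal cohort), and
relatedness pruning by the method-of-moments IBD-sharing estimate pi-hat
(one member of each pair with pi-hat above 0.25 is dropped).

Filter order is fixed for reproducibility: SNP call rate, sample call rate,
HWE, MAF, relatedness.  Re-running ``apply_qc`` on its own output is a no-op.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCConfig",
    "hwe_exact_test",
    "pi_hat",
    "apply_qc",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotype codes (0/1/2 alt-allele dosage, -1 missing)."""

    genotypes: np.ndarray  # (n_samples, n_sites) int8
    samples: list[str]
    populations: list[str]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    ref: list[str] | None = None
    alt: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a samples x sites matrix")
        if self.genotypes.shape[0] != len(self.samples):
            raise ValueError("sample metadata does not match matrix")
        if len(self.populations) != len(self.samples):
            raise ValueError("one population label per sample required")
        if not np.isin(self.genotypes, (-1, 0, 1, 2)).all():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        if self.pos is not None and len(self.pos) != self.genotypes.shape[1]:
            raise ValueError("site metadata does not match matrix")

    @classmethod
    def from_panel(cls, panel) -> "GenotypeMatrix":
        return cls(
            genotypes=panel.genotypes(),
            samples=list(panel.samples),
            populations=list(panel.populations),
            chrom=np.repeat(panel.chrom, panel.n_sites),
            pos=panel.pos_bp.copy(),
        )

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def take_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            genotypes=self.genotypes[:, keep],
            chrom=None if self.chrom is None else np.asarray(self.chrom)[keep],
            pos=None if self.pos is None else np.asarray(self.pos)[keep],
            ref=None if self.ref is None else [self.ref[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.ref[i] for i in keep],
            alt=None if self.alt is None else [self.alt[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.alt[i] for i in keep],
        )

    def take_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(keep) if keep.dtype == bool else np.asarray(keep)
        return replace(
            self,
            genotypes=self.genotypes[idx, :],
            samples=[self.samples[i] for i in idx],
            populations=[self.populations[i] for i in idx],
        )


@dataclass
class QCConfig:
    snp_call_rate_min: float = 0.98
    sample_call_rate_min: float = 0.98
    hwe_p_min: float = 1e-6
    maf_min_exclusive: float = 0.0
    pi_hat_max: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "snp_call_rate_min",
            "sample_call_rate_min",
            "hwe_p_min",
            "maf_min_exclusive",
            "pi_hat_max",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ----------------------------------------------------------------- HWE exact test

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test (conditional on allele counts).

    The p-value sums the Levene-Haldane conditional probabilities of all
    heterozygote counts compatible with the observed allele counts that are
    no more probable than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped samples at this site")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count; symmetry makes choice moot
    n_a = min(n_a, 2 * n - n_a)
    # log P(het = h | allele counts) up to a shared constant:
    #   C(n; nAA, h, naa) 2^h / C(2n, na)
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = np.empty(hets.size)
    for i, h in enumerate(hets):
        hom_rare = (n_a - h) // 2
        hom_common = n - h - hom_rare
        logp[i] = (
            h * math.log(2.0)
            - math.lgamma(h + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(hom_common + 1)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_Aa)
    if obs.size == 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(matrix: GenotypeMatrix) -> np.ndarray:
    g = matrix.genotypes
    out = np.empty(matrix.n_sites)
    for j in range(matrix.n_sites):
        col = g[:, j]
        n_aa = int(np.sum(col == 2))
        n_het = int(np.sum(col == 1))
        n_AA = int(np.sum(col == 0))
        if n_AA + n_het + n_aa == 0:
            out[j] = np.nan
        else:
            out[j] = hwe_exact_test(n_AA, n_het, n_aa)
    return out


# ------------------------------------------------------------------------ pi-hat

def pi_hat(
    g1: np.ndarray, g2: np.ndarray, freqs: np.ndarray, min_sites: int = 1000
) -> float:
    """Method-of-moments IBD-sharing estimate for one sample pair.

    Observed identity-by-state counts are compared with their expectations
    given allele frequencies under 0, 1 or 2 alleles shared identical by
    descent; ``pi_hat = P(IBD=1)/2 + P(IBD=2)``.  Estimates are clamped to
    [0, 1].
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    freqs = np.asarray(freqs, dtype=float)
    ok = (g1 >= 0) & (g2 >= 0) & (freqs > 0) & (freqs < 1)
    if not ok.any():
        raise ValueError("no overlapping informative sites")
    if ok.sum() < min_sites:
        warnings.warn(
            f"pi-hat from only {int(ok.sum())} sites; estimate may be noisy",
            stacklevel=2,
        )
    a = g1[ok].astype(np.int64)
    b = g2[ok].astype(np.int64)
    p = freqs[ok]
    q = 1 - p

    ibs0 = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
    ibs2 = a == b
    n0 = float(np.sum(ibs0))
    n2 = float(np.sum(ibs2))
    n1 = float(a.size - n0 - n2)

    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2 * p * q))
    e2_ibd1 = float(np.sum(p**2 + q**2))
    n_sites = float(a.size)

    p_ibd0 = n0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    p_ibd1 = (n1 - p_ibd0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p_ibd2 = (n2 - p_ibd0 * e2_ibd0 - p_ibd1 * e2_ibd1) / n_sites
    p_ibd0 = min(max(p_ibd0, 0.0), 1.0)
    p_ibd1 = min(max(p_ibd1, 0.0), 1.0)
    p_ibd2 = min(max(p_ibd2, 0.0), 1.0)
    return float(min(1.0, p_ibd1 / 2.0 + p_ibd2))


# ----------------------------------------------------------------------- apply_qc

def apply_qc(matrix: GenotypeMatrix, config: QCConfig | None = None):
    """Run all filters in order; returns (filtered matrix, report DataFrame).

    The report lists, per step, how many sites or samples were removed and
    how many remain.  An empty result is returned as an empty matrix, not an
    exception.
    """
    if config is None:
        config = QCConfig()
    steps: list[tuple[str, str, int, int]] = []
    m = matrix

    def note(step: str, axis: str, removed: int):
        remaining = m.n_sites if axis == "sites" else m.n_samples
        steps.append((step, axis, removed, remaining))

    # 1. SNP call rate
    if m.n_sites and m.n_samples:
        called = (m.genotypes >= 0).mean(axis=0)
        keep = called >= config.snp_call_rate_min
        removed = int((~keep).sum())
        m = m.take_sites(keep)
    else:
        removed = 0
    note("snp_call_rate", "sites", removed)

    # 2. sample call rate
    if m.n_sites and m.n_samples:
        called = (m.genotypes >= 0).mean(axis=1)
        keep = called >= config.sample_call_rate_min
        removed = int((~keep).sum())
        m = m.take_samples(keep)
    else:
        removed = 0
    note("sample_call_rate", "samples", removed)

    # 3. HWE
    if m.n_sites and m.n_samples:
        pvals = hwe_pvalues(m)
        keep = ~(pvals <= config.hwe_p_min)  # NaN (all-missing) kept here
        removed = int((~keep).sum())
        m = m.take_sites(keep)
    else:
        removed = 0
    note("hwe", "sites", removed)

    # 4. MAF
    if m.n_sites and m.n_samples:
        g = np.where(m.genotypes < 0, np.nan, m.genotypes.astype(float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(g, axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        keep = maf > config.maf_min_exclusive
        keep &= ~np.isnan(maf)
        removed = int((~keep).sum())
        m = m.take_sites(keep)
    else:
        removed = 0
    note("maf", "sites", removed)

    # 5. relatedness pruning (pi-hat), frequencies from the post-MAF panel
    removed = 0
    if m.n_sites and m.n_samples >= 2:
        g = np.where(m.genotypes < 0, np.nan, m.genotypes.astype(float))
        freqs = np.nanmean(g, axis=0) / 2.0
        call_rate = (m.genotypes >= 0).mean(axis=1)
        alive = np.ones(m.n_samples, dtype=bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for i in range(m.n_samples):
                if not alive[i]:
                    continue
                for j in range(i + 1, m.n_samples):
                    if not alive[j]:
                        continue
                    ph = pi_hat(m.genotypes[i], m.genotypes[j], freqs)
                    if ph > config.pi_hat_max:
                        # keep the better-called member; tie -> keep the
                        # lexicographically smaller id
                        if call_rate[i] > call_rate[j]:
                            drop = j
                        elif call_rate[i] < call_rate[j]:
                            drop = i
                        else:
                            drop = j if m.samples[i] <= m.samples[j] else i
                        alive[drop] = False
                        if drop == i:
                            break
        removed = int((~alive).sum())
        m = m.take_samples(alive)
    note("relatedness", "samples", removed)

    report = pd.DataFrame(steps, columns=["step", "axis", "removed", "remaining"])
    return m, report
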