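"""IBD segment detection from phased haplotypes and the haplotype-sharing index.

The detector is a hash seed-and-extend matcher: non-overlapping words of
consecutive sites are hashed per haplotype; haplotype pairs sharing an exact
word become candidates and their full diff profile is segmented under a
sliding mismatch budget (at most ``max_mismatch`` discordant sites within any
``window_sites`` consecutive sites).  Reported segments must contain at least
one exact seed word and span at least ``min_cM`` on the genetic map.

The haplotype-sharing index between populations I (size n) and J (size m) is

    IBD_IJ = (sum_i sum_j IBD_ij) / (n m) x 100

where IBD_ij is the total genetic length (cM) shared between individuals i
and j over all chromosomes and haplotype pairs.  Within one population the
mean is taken over the n(n-1)/2 unordered pairs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "IBDSegment",
    "SharingIndexResult",
    "bp_to_cM",
    "detect_ibd",
    "merge_segments",
    "sharing_index",
    "read_segments_tsv",
    "write_segments_tsv",
]


class GeneticMap:
    """Piecewise-linear physical-to-genetic map with terminal extrapolation."""

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            if bp.size < 2:
                raise ValueError(f"chrom {chrom!r}: need at least 2 anchors")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"chrom {chrom!r}: bp anchors must increase")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chrom {chrom!r}: cM anchors must be non-decreasing")
            self.anchors[chrom] = (bp, cm)

    @classmethod
    def from_file(cls, path) -> "GeneticMap":
        """Read a 3-column (chrom, bp, cM) map, optionally with a header line."""
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
        if df.shape[1] < 3:
            raise ValueError("genetic map needs 3 columns: chrom, bp, cM")
        try:
            float(df.iloc[0, 1])
        except ValueError:
            df = df.iloc[1:]
        anchors = {}
        for chrom, sub in df.groupby(0, sort=False):
            anchors[str(chrom)] = (
                sub[1].astype(float).to_numpy(),
                sub[2].astype(float).to_numpy(),
            )
        return cls(anchors)

    @classmethod
    def from_plink_map(cls, path) -> "GeneticMap":
        """Read a PLINK .map file (chrom, id, cM, bp)."""
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
        if df.shape[1] < 4:
            raise ValueError("PLINK .map needs 4 columns: chrom, id, cM, bp")
        anchors = {}
        for chrom, sub in df.groupby(0, sort=False):
            anchors[str(chrom)] = (
                sub[3].astype(float).to_numpy(),
                sub[2].astype(float).to_numpy(),
            )
        return cls(anchors)

    def bp_to_cM(self, chrom: str, pos_bp) -> float | np.ndarray:
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} not in map")
        bp, cm = self.anchors[chrom]
        pos = np.asarray(pos_bp, dtype=np.float64)
        out = np.interp(pos, bp, cm)
        # linear extrapolation beyond terminal anchors at the terminal rate
        lo_rate = (cm[1] - cm[0]) / (bp[1] - bp[0])
        hi_rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        below = pos < bp[0]
        above = pos > bp[-1]
        if np.ndim(pos_bp) == 0:
            if below:
                return float(cm[0] + (pos - bp[0]) * lo_rate)
            if above:
                return float(cm[-1] + (pos - bp[-1]) * hi_rate)
            return float(out)
        out[below] = cm[0] + (pos[below] - bp[0]) * lo_rate
        out[above] = cm[-1] + (pos[above] - bp[-1]) * hi_rate
        return out


def bp_to_cM(genetic_map: GeneticMap, chrom: str, pos_bp):
    """Genetic position of ``pos_bp`` by interpolation on ``genetic_map``."""
    return genetic_map.bp_to_cM(chrom, pos_bp)


# ----------------------------------------------------------------------- segments

@dataclass
class IBDSegment:
    sample1: str
    sample2: str
    hap1: int
    hap2: int
    chrom: str
    start_bp: int
    end_bp: int
    start_cM: float
    end_cM: float
    n_discordant: int = 0

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp or self.end_cM <= self.start_cM:
            raise ValueError("segment end must exceed start in bp and cM")

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM

    def pair_key(self):
        return (self.sample1, self.hap1, self.sample2, self.hap2, self.chrom)


def _segment_pair(
    diff: np.ndarray,
    seed_hits: np.ndarray,
    window_sites: int,
    max_mismatch: int,
) -> list[tuple[int, int, int]]:
    """Maximal (start, end, n_mismatch) site runs under the mismatch budget.

    A run breaks wherever ``max_mismatch + 1`` discordant sites fall within
    one ``window_sites`` window; the middle mismatch of the violating cluster
    is taken as the breakpoint.  Runs are trimmed to concordant end sites and
    must contain at least one seeded site.
    """
    S = diff.size
    mm = np.flatnonzero(diff)
    breaks = [-1]
    if mm.size > max_mismatch:
        viol = np.flatnonzero(mm[max_mismatch:] - mm[:-max_mismatch] < window_sites)
        for v in viol:
            b = int(mm[v + (max_mismatch + 1) // 2])
            if b > breaks[-1]:
                breaks.append(b)
    breaks.append(S)
    out = []
    for lo, hi in zip(breaks, breaks[1:]):
        s, e = lo + 1, hi  # half-open [s, e)
        # trim mismatching edge sites
        while s < e and diff[s]:
            s += 1
        while e > s and diff[e - 1]:
            e -= 1
        if e <= s:
            continue
        if not seed_hits[s:e].any():
            continue
        out.append((s, e, int(diff[s:e].sum())))
    return out


def detect_ibd(
    panel,
    min_cM: float = 6.0,
    seed_sites: int = 64,
    max_mismatch: int = 2,
    window_sites: int | None = None,
) -> list[IBDSegment]:
    """Detect IBD segments between all haplotype pairs of different samples."""
    if np.any(np.diff(panel.pos_bp) <= 0):
        raise ValueError("positions must be strictly increasing")
    if window_sites is None:
        window_sites = seed_sites
    H = np.ascontiguousarray(panel.haplotypes)
    n_hap, S = H.shape
    n_words = S // seed_sites
    if n_words == 0:
        return []

    # seed: exact word matches
    pair_words: dict[tuple[int, int], list[int]] = defaultdict(list)
    for w in range(n_words):
        sl = H[:, w * seed_sites : (w + 1) * seed_sites]
        buckets: dict[bytes, list[int]] = defaultdict(list)
        for h in range(n_hap):
            buckets[sl[h].tobytes()].append(h)
        for members in buckets.values():
            if len(members) < 2:
                continue
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    if a // 2 == b // 2:
                        continue  # same diploid sample
                    pair_words[(a, b)].append(w)

    out: list[IBDSegment] = []
    pos_cm = panel.pos_cM
    pos_bp = panel.pos_bp
    for (a, b), words in pair_words.items():
        diff = H[a] != H[b]
        seed_hits = np.zeros(S, dtype=bool)
        for w in words:
            seed_hits[w * seed_sites : (w + 1) * seed_sites] = True
        for s, e, n_mm in _segment_pair(diff, seed_hits, window_sites, max_mismatch):
            length = pos_cm[e - 1] - pos_cm[s]
            if length < min_cM:
                continue
            out.append(
                IBDSegment(
                    sample1=panel.samples[a // 2],
                    sample2=panel.samples[b // 2],
                    hap1=a % 2,
                    hap2=b % 2,
                    chrom=panel.chrom,
                    start_bp=int(pos_bp[s]),
                    end_bp=int(pos_bp[e - 1]) + 1,
                    start_cM=float(pos_cm[s]),
                    end_cM=float(pos_cm[e - 1]),
                    n_discordant=n_mm,
                )
            )
    out.sort(key=lambda seg: (seg.pair_key(), seg.start_cM))
    return out


def merge_segments(
    segments: list[IBDSegment],
    max_gap_cM: float = 0.6,
    max_gap_discordant: int = 1,
    panel=None,
) -> list[IBDSegment]:
    """Merge consecutive same-pair segments separated by short, clean gaps.

    A gap qualifies when its genetic length is at most ``max_gap_cM`` and, if
    a panel is supplied, the number of discordant sites inside the gap is at
    most ``max_gap_discordant`` (without a panel the gap is assumed clean).
    """
    by_pair: dict[tuple, list[IBDSegment]] = defaultdict(list)
    for seg in segments:
        by_pair[seg.pair_key()].append(seg)

    hap_index = None
    if panel is not None:
        hap_index = {s: i for i, s in enumerate(panel.samples)}

    out: list[IBDSegment] = []
    for key, segs in by_pair.items():
        segs = sorted(segs, key=lambda x: x.start_cM)
        cur = segs[0]
        for nxt in segs[1:]:
            gap = nxt.start_cM - cur.end_cM
            gap_mm = 0
            if panel is not None and gap > 0:
                a = 2 * hap_index[cur.sample1] + cur.hap1
                b = 2 * hap_index[cur.sample2] + cur.hap2
                in_gap = (panel.pos_cM > cur.end_cM) & (panel.pos_cM < nxt.start_cM)
                gap_mm = int(
                    np.sum(panel.haplotypes[a, in_gap] != panel.haplotypes[b, in_gap])
                )
            if gap <= max_gap_cM and gap_mm <= max_gap_discordant:
                cur = IBDSegment(
                    sample1=cur.sample1,
                    sample2=cur.sample2,
                    hap1=cur.hap1,
                    hap2=cur.hap2,
                    chrom=cur.chrom,
                    start_bp=cur.start_bp,
                    end_bp=max(cur.end_bp, nxt.end_bp),
                    start_cM=cur.start_cM,
                    end_cM=max(cur.end_cM, nxt.end_cM),
                    n_discordant=cur.n_discordant + nxt.n_discordant + gap_mm,
                )
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    out.sort(key=lambda seg: (seg.pair_key(), seg.start_cM))
    return out


# ------------------------------------------------------------------ sharing index

@dataclass
class SharingIndexResult:
    pop_i: str
    pop_j: str
    n: int
    m: int
    index: float
    total_cM: float
    n_pairs: int


def sharing_index(
    segments,
    pop_i_samples: list[str],
    pop_j_samples: list[str],
    pop_i: str = "I",
    pop_j: str = "J",
) -> SharingIndexResult:
    """Mean pairwise total IBD length (cM) between two populations, x100.

    For two disjoint populations the mean runs over all n*m cross pairs; when
    the same sample list is passed twice the mean runs over the n(n-1)/2
    unordered within-population pairs.
    """
    set_i = set(pop_i_samples)
    set_j = set(pop_j_samples)
    if not set_i or not set_j:
        raise ValueError("populations must be non-empty")
    same = set_i == set_j
    if not same and set_i & set_j:
        raise ValueError("populations must be disjoint (or identical)")

    totals: dict[tuple[str, str], float] = defaultdict(float)
    for seg in segments:
        s1, s2 = seg.sample1, seg.sample2
        if same:
            if s1 in set_i and s2 in set_i and s1 != s2:
                totals[tuple(sorted((s1, s2)))] += seg.length_cM
        else:
            if s1 in set_i and s2 in set_j:
                totals[(s1, s2)] += seg.length_cM
            elif s2 in set_i and s1 in set_j:
                totals[(s2, s1)] += seg.length_cM

    n, m = len(set_i), len(set_j)
    n_pairs = n * (n - 1) // 2 if same else n * m
    total = float(sum(totals.values()))
    return SharingIndexResult(
        pop_i=pop_i,
        pop_j=pop_j,
        n=n,
        m=m,
        index=total / n_pairs * 100.0,
        total_cM=total,
        n_pairs=n_pairs,
    )


# --------------------------------------------------------------------- TSV I/O

_SEG_COLS = [
    "sample1",
    "sample2",
    "hap1",
    "hap2",
    "chrom",
    "start_bp",
    "end_bp",
    "start_cM",
    "end_cM",
    "n_discordant",
]


def write_segments_tsv(segments, path, provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("\t".join(_SEG_COLS) + "\n")
        for seg in segments:
            nd = getattr(seg, "n_discordant", 0)
            fh.write(
                f"{seg.sample1}\t{seg.sample2}\t{seg.hap1}\t{seg.hap2}\t"
                f"{seg.chrom}\t{seg.start_bp}\t{seg.end_bp}\t"
                f"{seg.start_cM:.6f}\t{seg.end_cM:.6f}\t{nd}\n"
            )


def read_segments_tsv(path) -> list[IBDSegment]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_SEG_COLS[:9]) - set(df.columns)
    if missing:
        raise ValueError(f"segment TSV missing columns: {sorted(missing)}")
    return [
        IBDSegment(
            sample1=str(r.sample1),
            sample2=str(r.sample2),
            hap1=int(r.hap1),
            hap2=int(r.hap2),
            chrom=str(r.chrom),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            start_cM=float(r.start_cM),
            end_cM=float(r.end_cM),
            n_discordant=int(getattr(r, "n_discordant", 0)),
        )
        for r in df.itertuples()
    ]
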