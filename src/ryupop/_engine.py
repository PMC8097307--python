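"""Numba core of the independent-site structured-coalescent simulator.

One genealogy per site is simulated backwards in time under a piecewise
description of the demographic model (per-interval gene-copy counts,
per-interval migration matrices and a sorted list of backward merge events).

Time is discrete in generations.  Each generation, coalescence and migration
compete; three regimes keep this exact where it matters and fast elsewhere:

* total hazard < 0.25 per generation: geometric waiting time, single event;
* a deme holds at most 5% as many lineages as gene copies: the number of
  coalescing pairs that generation is drawn binomially and placed as pair
  mergers (triple mergers are negligible at this occupancy);
* otherwise: exact Wright-Fisher parent picking, with simultaneous and
  multiple mergers.

Each site gets its own RNG stream derived from (seed, site index), so runs
at nearby parameter values share their randomness until an event actually
depends on the changed parameter (common random numbers across likelihood
evaluations).

Two consumers share the tree builder: a site-pattern kernel that places one
mutation uniformly on the total branch length, and an expected-spectrum
kernel that instead adds every branch's subtended allele-count pattern with
weight proportional to its length (the per-tree conditional expectation of
the mutation placement — a Rao-Blackwellised estimate of SFS entry
probabilities with substantially lower Monte-Carlo noise).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .demographic_model import DemographicModel, validate_model

#: hazard per generation above which a generation is simulated explicitly
_EXPLICIT_HAZARD = 0.25

MUT_ONE_PER_TREE = 0
MUT_POISSON = 1


class CompiledModel:
    """Array form of a :class:`DemographicModel` consumed by the numba kernels."""

    def __init__(self, model: DemographicModel):
        rep = validate_model(model)
        if not rep.ok:
            raise ValueError("invalid demographic model: " + "; ".join(rep.violations))
        self.model = model
        self.deme_names = list(model.demes)
        idx = {d: i for i, d in enumerate(self.deme_names)}
        n_demes = len(self.deme_names)

        breaks = {0.0}
        for epochs in model.demes.values():
            for ep in epochs:
                breaks.add(float(ep.start_gen))
                if math.isfinite(ep.end_gen):
                    breaks.add(float(ep.end_gen))
        for s in model.splits:
            breaks.add(float(s.time_gen))
        self.t_break = np.array(sorted(breaks), dtype=np.float64)
        n_int = len(self.t_break)

        # gene copies per interval/deme; a huge sentinel where the deme does
        # not exist (no lineage should ever sit there)
        self.copies = np.full((n_int, n_demes), 1e18, dtype=np.float64)
        for name, epochs in model.demes.items():
            d = idx[name]
            for ep in epochs:
                for k, t0 in enumerate(self.t_break):
                    if ep.start_gen <= t0 < ep.end_gen:
                        self.copies[k, d] = model.gene_copies(ep.size)

        self.mig = np.zeros((n_int, n_demes, n_demes), dtype=np.float64)
        for m in model.migrations:
            a, b = idx[m.deme_a], idx[m.deme_b]
            alo, ahi = model.existence(m.deme_a)
            blo, bhi = model.existence(m.deme_b)
            lo, hi = max(alo, blo), min(ahi, bhi)
            for k, t0 in enumerate(self.t_break):
                if lo <= t0 < hi:
                    self.mig[k, a, b] += m.rate
                    self.mig[k, b, a] += m.rate
        self.mig_tot = self.mig.sum(axis=2)

        merges = sorted(model.splits, key=lambda s: (s.time_gen, s.derived_deme))
        self.merge_time = np.array([s.time_gen for s in merges], dtype=np.float64)
        self.merge_src = np.array([idx[s.derived_deme] for s in merges], dtype=np.int64)
        self.merge_dst = np.array(
            [idx[s.ancestral_deme] for s in merges], dtype=np.int64
        )
        self.deme_index = idx

    def initial_demes(self, sample_sizes: dict[str, int]) -> np.ndarray:
        """Per-haplotype initial deme indices (two per diploid, grouped by deme)."""
        out = []
        for name, n_dip in sample_sizes.items():
            if name not in self.deme_index:
                raise ValueError(f"unknown deme {name!r}")
            if n_dip < 0:
                raise ValueError("sample sizes must be non-negative")
            lo, _ = self.model.existence(name)
            if n_dip > 0 and lo != 0:
                raise ValueError(f"deme {name!r} does not exist at generation 0")
            out.extend([self.deme_index[name]] * (2 * n_dip))
        return np.array(out, dtype=np.int64)


@njit(cache=True)
def _one_tree(
    site_seed,
    lin_deme0,
    n_demes,
    t_break,
    copies,
    mig,
    mig_tot,
    merge_time,
    merge_src,
    merge_dst,
    parent,
    ntime,
    lin_node,
    lin_deme,
    cnt,
    hazc,
    hazm,
    dlin,
    ht_key,
    ht_lin,
    ht_node,
    touched,
    mask,
):
    """Build one genealogy in (parent, ntime); returns the node count."""
    np.random.seed(site_seed)
    n = lin_deme0.shape[0]
    n_intervals = t_break.shape[0]
    n_merge = merge_time.shape[0]
    for i in range(n):
        parent[i] = -1
        ntime[i] = 0.0
        lin_node[i] = i
        lin_deme[i] = lin_deme0[i]
    nxt = n
    n_act = n
    t = 0.0
    k = 0
    mp = 0
    for d in range(n_demes):
        cnt[d] = 0
    for i in range(n):
        cnt[lin_deme0[i]] += 1
    while n_act > 1:
        while mp < n_merge and merge_time[mp] <= t:
            src = merge_src[mp]
            dst = merge_dst[mp]
            if cnt[src] > 0:
                for i in range(n_act):
                    if lin_deme[i] == src:
                        lin_deme[i] = dst
                cnt[dst] += cnt[src]
                cnt[src] = 0
            mp += 1
        while k + 1 < n_intervals and t >= t_break[k + 1]:
            k += 1
        boundary = 1.0e18
        if k + 1 < n_intervals:
            boundary = t_break[k + 1]
        if mp < n_merge and merge_time[mp] < boundary:
            boundary = merge_time[mp]

        H = 0.0
        for d in range(n_demes):
            c = cnt[d]
            if c >= 2:
                hazc[d] = 0.5 * c * (c - 1) / copies[k, d]
            else:
                hazc[d] = 0.0
            hazm[d] = c * mig_tot[k, d]
            H += hazc[d] + hazm[d]

        if H <= 1e-300:
            if boundary >= 1.0e18:
                # no event possible and nothing ahead: should not happen for
                # a valid model; bail out rather than hang
                break
            t = boundary
            continue

        if H < _EXPLICIT_HAZARD:
            # geometric waiting time, single event
            p = 1.0 - np.exp(-H)
            u = np.random.random()
            g = 1.0 + np.floor(np.log(u) / np.log(1.0 - p))
            tev = t + g
            if tev >= boundary:
                t = boundary
                continue
            t = tev
            r = np.random.random() * H
            acc = 0.0
            ed = -1
            is_coal = False
            for d in range(n_demes):
                acc += hazc[d]
                if r < acc:
                    ed = d
                    is_coal = True
                    break
            if ed < 0:
                for d in range(n_demes):
                    acc += hazm[d]
                    if r < acc:
                        ed = d
                        break
                if ed < 0:
                    continue  # numeric edge; skip
            m = 0
            for i in range(n_act):
                if lin_deme[i] == ed:
                    dlin[m] = i
                    m += 1
            if is_coal:
                a = np.random.randint(0, m)
                b = np.random.randint(0, m - 1)
                if b >= a:
                    b += 1
                ia = dlin[a]
                ib = dlin[b]
                u_node = nxt
                nxt += 1
                parent[u_node] = -1
                ntime[u_node] = t
                parent[lin_node[ia]] = u_node
                parent[lin_node[ib]] = u_node
                lin_node[ia] = u_node
                lin_node[ib] = lin_node[n_act - 1]
                lin_deme[ib] = lin_deme[n_act - 1]
                n_act -= 1
                cnt[ed] -= 1
            else:
                a = dlin[np.random.randint(0, m)]
                r2 = np.random.random() * mig_tot[k, ed]
                acc2 = 0.0
                for e in range(n_demes):
                    acc2 += mig[k, ed, e]
                    if r2 < acc2:
                        lin_deme[a] = e
                        cnt[ed] -= 1
                        cnt[e] += 1
                        break
        else:
            # explicit generation
            if t + 1.0 > boundary:
                t = boundary
                continue
            t = t + 1.0
            # a generation landing exactly on a split time samples its
            # parents in the post-merge configuration
            while mp < n_merge and merge_time[mp] <= t:
                src = merge_src[mp]
                dst = merge_dst[mp]
                if cnt[src] > 0:
                    for i in range(n_act):
                        if lin_deme[i] == src:
                            lin_deme[i] = dst
                    cnt[dst] += cnt[src]
                    cnt[src] = 0
                mp += 1
            while k + 1 < n_intervals and t >= t_break[k + 1]:
                k += 1
            # migration phase: binomial migrant count per deme
            for d in range(n_demes):
                mt = mig_tot[k, d]
                c = cnt[d]
                if mt > 0.0 and c > 0:
                    n_mig = np.random.binomial(c, mt)
                    for _ in range(n_mig):
                        if cnt[d] == 0:
                            break
                        # rejection-pick a lineage still in deme d
                        for _try in range(256):
                            i = np.random.randint(0, n_act)
                            if lin_deme[i] == d:
                                r2 = np.random.random() * mt
                                acc2 = 0.0
                                for e in range(n_demes):
                                    acc2 += mig[k, d, e]
                                    if r2 < acc2:
                                        lin_deme[i] = e
                                        cnt[d] -= 1
                                        cnt[e] += 1
                                        break
                                break
            # coalescence per deme
            for d in range(n_demes):
                c = cnt[d]
                if c < 2:
                    continue
                cp_f = copies[k, d]
                if cp_f > 9.0e17:
                    continue
                if c <= 0.05 * cp_f:
                    # sparse regime: binomial pair-event count
                    n_ev = np.random.binomial(c * (c - 1) // 2, 1.0 / cp_f)
                    for _ in range(n_ev):
                        if cnt[d] < 2:
                            break
                        ia = -1
                        ib = -1
                        for _try in range(1024):
                            i = np.random.randint(0, n_act)
                            if lin_deme[i] == d:
                                if ia < 0:
                                    ia = i
                                elif i != ia:
                                    ib = i
                                    break
                        if ib < 0:
                            break
                        u_node = nxt
                        nxt += 1
                        parent[u_node] = -1
                        ntime[u_node] = t
                        parent[lin_node[ia]] = u_node
                        parent[lin_node[ib]] = u_node
                        lin_node[ia] = u_node
                        lin_node[ib] = lin_node[n_act - 1]
                        lin_deme[ib] = lin_deme[n_act - 1]
                        n_act -= 1
                        cnt[d] -= 1
                else:
                    # crowded regime: exact Wright-Fisher parent picking
                    cp = np.int64(cp_f)
                    if cp < 1:
                        cp = 1
                    m = 0
                    for i in range(n_act):
                        if lin_deme[i] == d:
                            dlin[m] = i
                            m += 1
                    ntouch = 0
                    any_dead = False
                    for jj in range(m):
                        i = dlin[jj]
                        pid = np.random.randint(0, cp)
                        h = (pid * 2654435761) & mask
                        while True:
                            if ht_key[h] == -1:
                                ht_key[h] = pid
                                ht_lin[h] = i
                                ht_node[h] = -1
                                touched[ntouch] = h
                                ntouch += 1
                                break
                            if ht_key[h] == pid:
                                j0 = ht_lin[h]
                                if ht_node[h] == -1:
                                    u_node = nxt
                                    nxt += 1
                                    parent[u_node] = -1
                                    ntime[u_node] = t
                                    parent[lin_node[j0]] = u_node
                                    lin_node[j0] = u_node
                                    ht_node[h] = u_node
                                parent[lin_node[i]] = ht_node[h]
                                lin_deme[i] = -9  # dead, compact below
                                cnt[d] -= 1
                                any_dead = True
                                break
                            h = (h + 1) & mask
                    for q in range(ntouch):
                        ht_key[touched[q]] = -1
                    if any_dead:
                        w = 0
                        for i in range(n_act):
                            if lin_deme[i] >= 0:
                                lin_node[w] = lin_node[i]
                                lin_deme[w] = lin_deme[i]
                                w += 1
                        n_act = w
    return nxt


@njit(cache=True)
def _site_seed(seed, s):
    return (seed + np.int64(2654435761) * (s + 1)) % 4294967291


@njit(cache=True)
def _sim_sites_kernel(
    seed,
    n_sites,
    lin_deme0,
    n_demes,
    t_break,
    copies,
    mig,
    mig_tot,
    merge_time,
    merge_src,
    merge_dst,
    out_derived,
    out_root_time,
    out_total_len,
):
    n = lin_deme0.shape[0]
    max_nodes = 2 * n
    parent = np.empty(max_nodes, np.int64)
    ntime = np.empty(max_nodes, np.float64)
    lin_node = np.empty(n, np.int64)
    lin_deme = np.empty(n, np.int64)
    cnt = np.empty(n_demes, np.int64)
    hazc = np.empty(n_demes, np.float64)
    hazm = np.empty(n_demes, np.float64)
    dlin = np.empty(n, np.int64)
    ht_size = 1
    while ht_size < 4 * n:
        ht_size *= 2
    mask = ht_size - 1
    ht_key = np.full(ht_size, np.int64(-1), np.int64)
    ht_lin = np.empty(ht_size, np.int64)
    ht_node = np.empty(ht_size, np.int64)
    touched = np.empty(n, np.int64)
    first_child = np.empty(max_nodes, np.int64)
    sibling = np.empty(max_nodes, np.int64)
    stack = np.empty(max_nodes, np.int64)

    for s in range(n_sites):
        nxt = _one_tree(
            _site_seed(seed, s),
            lin_deme0,
            n_demes,
            t_break,
            copies,
            mig,
            mig_tot,
            merge_time,
            merge_src,
            merge_dst,
            parent,
            ntime,
            lin_node,
            lin_deme,
            cnt,
            hazc,
            hazm,
            dlin,
            ht_key,
            ht_lin,
            ht_node,
            touched,
            mask,
        )
        root = lin_node[0]
        out_root_time[s] = ntime[root]

        total = 0.0
        for v in range(nxt):
            pv = parent[v]
            if pv >= 0:
                total += ntime[pv] - ntime[v]
        out_total_len[s] = total

        # one mutation, uniform on the total branch length
        x = np.random.random() * total
        chosen = -1
        acc3 = 0.0
        for v in range(nxt):
            pv = parent[v]
            if pv >= 0:
                acc3 += ntime[pv] - ntime[v]
                if x < acc3:
                    chosen = v
                    break
        if chosen < 0:
            chosen = root  # numeric guard

        for v in range(nxt):
            first_child[v] = -1
        for v in range(nxt):
            pv = parent[v]
            if pv >= 0:
                sibling[v] = first_child[pv]
                first_child[pv] = v
        for i in range(n):
            out_derived[s, i] = 0
        sp = 0
        stack[sp] = chosen
        sp += 1
        while sp > 0:
            sp -= 1
            v = stack[sp]
            if v < n:
                out_derived[s, v] = 1
            c = first_child[v]
            while c >= 0:
                stack[sp] = c
                sp += 1
                c = sibling[c]
    return


@njit(cache=True)
def _expected_tables_kernel(
    seed,
    n_sim,
    lin_deme0,
    n_demes,
    t_break,
    copies,
    mig,
    mig_tot,
    merge_time,
    merge_src,
    merge_dst,
    pop_of_leaf,
    n_pops,
    n_hap,
    pair_a,
    pair_b,
    pair_off,
    tables,
):
    """Accumulate branch-length-weighted joint allele-count tables.

    For every genealogy each node below the root contributes its subtended
    per-population leaf counts with weight (branch length / total length):
    the conditional expectation of the single-mutation placement.  ``tables``
    is a flat array holding one dense (n_hap[a]+1) x (n_hap[b]+1) table per
    population pair at offset ``pair_off[p]``.
    """
    n = lin_deme0.shape[0]
    max_nodes = 2 * n
    parent = np.empty(max_nodes, np.int64)
    ntime = np.empty(max_nodes, np.float64)
    lin_node = np.empty(n, np.int64)
    lin_deme = np.empty(n, np.int64)
    cnt = np.empty(n_demes, np.int64)
    hazc = np.empty(n_demes, np.float64)
    hazm = np.empty(n_demes, np.float64)
    dlin = np.empty(n, np.int64)
    ht_size = 1
    while ht_size < 4 * n:
        ht_size *= 2
    mask = ht_size - 1
    ht_key = np.full(ht_size, np.int64(-1), np.int64)
    ht_lin = np.empty(ht_size, np.int64)
    ht_node = np.empty(ht_size, np.int64)
    touched = np.empty(n, np.int64)
    counts = np.zeros((max_nodes, n_pops), np.int64)
    n_pairs = pair_a.shape[0]

    for s in range(n_sim):
        nxt = _one_tree(
            _site_seed(seed, s),
            lin_deme0,
            n_demes,
            t_break,
            copies,
            mig,
            mig_tot,
            merge_time,
            merge_src,
            merge_dst,
            parent,
            ntime,
            lin_node,
            lin_deme,
            cnt,
            hazc,
            hazm,
            dlin,
            ht_key,
            ht_lin,
            ht_node,
            touched,
            mask,
        )
        total = 0.0
        for v in range(nxt):
            pv = parent[v]
            if pv >= 0:
                total += ntime[pv] - ntime[v]
        if total <= 0.0:
            continue
        for v in range(nxt):
            for q in range(n_pops):
                counts[v, q] = 0
        for i in range(n):
            counts[i, pop_of_leaf[i]] = 1
        # children are created before parents, so a single ascending pass
        # accumulates subtree leaf counts
        for v in range(nxt):
            pv = parent[v]
            if pv >= 0:
                for q in range(n_pops):
                    counts[pv, q] += counts[v, q]
        for v in range(nxt):
            pv = parent[v]
            if pv < 0:
                continue
            w = (ntime[pv] - ntime[v]) / total
            for p in range(n_pairs):
                a = pair_a[p]
                b = pair_b[p]
                idx = pair_off[p] + counts[v, a] * (n_hap[b] + 1) + counts[v, b]
                tables[idx] += w
    return


def simulate_site_genealogies(
    compiled: CompiledModel,
    lin_deme0: np.ndarray,
    n_sites: int,
    seed: int,
    mut_mode: int = MUT_ONE_PER_TREE,
    mu_span: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one genealogy per site and place one mutation on each.

    Returns (derived indicator matrix, per-site root time).  In Poisson mode
    (``MUT_POISSON``) genealogies are kept by rejection with probability
    proportional to ``1 - exp(-mu_span * total_length)`` — the
    segregating-site ensemble of the infinite-sites model, with monomorphic
    draws redropped.
    """
    n = int(lin_deme0.shape[0])
    if n < 2:
        raise ValueError("at least two haplotypes are required for coalescence")
    if n_sites < 1:
        raise ValueError("n_sites must be positive")

    def run_chunk(n_chunk: int, chunk_seed: int):
        derived = np.empty((n_chunk, n), dtype=np.int8)
        root_time = np.empty(n_chunk, dtype=np.float64)
        total_len = np.empty(n_chunk, dtype=np.float64)
        _sim_sites_kernel(
            chunk_seed % (2**31),
            n_chunk,
            lin_deme0,
            len(compiled.deme_names),
            compiled.t_break,
            compiled.copies,
            compiled.mig,
            compiled.mig_tot,
            compiled.merge_time,
            compiled.merge_src,
            compiled.merge_dst,
            derived,
            root_time,
            total_len,
        )
        return derived, root_time, total_len

    if mut_mode == MUT_ONE_PER_TREE:
        derived, root_time, _ = run_chunk(int(n_sites), int(seed))
        return derived, root_time

    if mu_span <= 0:
        raise ValueError("Poisson mode requires a positive mutation span")
    rng = np.random.default_rng([int(seed) % (2**31), 0x90155])
    kept_d, kept_t = [], []
    n_kept = 0
    w_max = None
    offset = 0
    while n_kept < n_sites:
        chunk = max(int(n_sites) // 2, 4096)
        derived, root_time, total_len = run_chunk(chunk, int(seed) + 7919 * offset)
        offset += 1
        w = -np.expm1(-mu_span * total_len)
        if w_max is None:
            w_max = float(w.max()) * 1.5
        w_max = max(w_max, float(w.max()))
        accept = rng.random(chunk) < w / w_max
        kept_d.append(derived[accept])
        kept_t.append(root_time[accept])
        n_kept += int(accept.sum())
    derived = np.concatenate(kept_d)[:n_sites]
    root_time = np.concatenate(kept_t)[:n_sites]
    return derived, root_time


def expected_pairwise_tables(
    compiled: CompiledModel,
    sample_sizes: dict[str, int],
    n_sim: int,
    seed: int,
    pairs: list[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Monte-Carlo expected joint 2-D allele-count tables per population pair.

    Each table is the branch-weighted expectation of the joint derived-count
    spectrum under one-mutation-per-tree placement, on the scale of ``n_sim``
    sites (each simulated genealogy contributes total weight 1 per pair).
    """
    from itertools import combinations

    lin0 = compiled.initial_demes(sample_sizes)
    if lin0.size < 2:
        raise ValueError("need at least 2 sampled haplotypes")
    pops = [p for p, n_dip in sample_sizes.items() if n_dip > 0]
    pop_index = {p: i for i, p in enumerate(pops)}
    pop_of_leaf = np.empty(lin0.size, dtype=np.int64)
    row = 0
    for p, n_dip in sample_sizes.items():
        if n_dip > 0:
            pop_of_leaf[row : row + 2 * n_dip] = pop_index[p]
            row += 2 * n_dip
    n_hap = np.array([2 * sample_sizes[p] for p in pops], dtype=np.int64)
    if pairs is None:
        pairs = list(combinations(pops, 2))
    pair_a = np.array([pop_index[a] for a, _ in pairs], dtype=np.int64)
    pair_b = np.array([pop_index[b] for _, b in pairs], dtype=np.int64)
    sizes = [(n_hap[a] + 1) * (n_hap[b] + 1) for a, b in zip(pair_a, pair_b)]
    pair_off = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.int64)
    tables = np.zeros(int(np.sum(sizes)), dtype=np.float64)
    _expected_tables_kernel(
        int(seed) % (2**31),
        int(n_sim),
        lin0,
        len(compiled.deme_names),
        compiled.t_break,
        compiled.copies,
        compiled.mig,
        compiled.mig_tot,
        compiled.merge_time,
        compiled.merge_src,
        compiled.merge_dst,
        pop_of_leaf,
        len(pops),
        n_hap,
        pair_a,
        pair_b,
        pair_off,
        tables,
    )
    out = {}
    for i, (a, b) in enumerate(pairs):
        na, nb = n_hap[pair_a[i]] + 1, n_hap[pair_b[i]] + 1
        out[(a, b)] = tables[pair_off[i] : pair_off[i] + na * nb].reshape(na, nb)
    return out
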