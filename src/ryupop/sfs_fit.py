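"""Demographic parameter estimation from the joint SFS by simulated
composite likelihood.

The observable is a joint derived-allele-count spectrum of independent
segregating sites.  Entry probabilities under candidate parameters are
estimated by Monte-Carlo simulation of independent-site genealogies (the
expected SFS) and a multinomial composite log-likelihood
``CL = sum_e m_e log p_e`` is maximised over the free parameters.

Two design choices keep the Monte-Carlo noise manageable at desk scale:

* For more than two populations the composite likelihood multiplies dense
  pairwise two-dimensional marginal spectra rather than the full joint
  tensor (whose observed entries would almost never be seen among the
  simulated sites).  The expected tables are Rao-Blackwellised: every branch
  of every simulated genealogy contributes its allele-count pattern with
  weight proportional to its length, i.e. the per-tree conditional
  expectation of the mutation placement, which removes the placement noise
  entirely.  Pairs can further be restricted to those involving populations
  whose history the free parameters actually move (``focus_pops``) — the
  remaining tables are nearly ancillary and contribute mostly noise.
* Every evaluation reuses one fixed simulation seed, with a dedicated RNG
  stream per site (common random numbers): the objective is a deterministic
  function of the parameters, and genealogies at nearby parameter values
  share their randomness until an event depends on the changed parameter.

The grid maximum is refined by a local quadratic response-surface fit to the
profile (one free parameter): a least-squares parabola through the grid
neighbourhood pools the residual Monte-Carlo noise of many evaluations
instead of trusting the single noisiest one.  Multi-parameter refits fall
back to Nelder-Mead on the same cached objective.

Confidence intervals are parametric bootstrap: spectra are re-simulated under
the fitted model, refit, and percentile intervals reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from scipy.optimize import minimize

from . import _engine
from .coalescent_sim import simulate_joint_sfs
from .demographic_model import model_from_params
from .popgen_stats import SFS

__all__ = [
    "FitSpec",
    "FitResult",
    "SFSProbs",
    "expected_sfs_probs",
    "composite_log_likelihood",
    "fit_parameters",
    "parametric_bootstrap_ci",
]


class SFSProbs:
    """Monte-Carlo entry probabilities of a joint SFS.

    ``joint`` mode: probabilities on the full tensor — simulated counts over
    a normaliser that spreads a pseudo-count of ``0.5/n_sim`` across every
    never-simulated polymorphic cell, so the tensor sums to one.  ``pairwise``
    mode: one dense branch-weighted 2-D probability table per population
    pair.
    """

    def __init__(
        self,
        n_sim: int,
        pops: list[str],
        n_hap: list[int],
        sfs: SFS | None = None,
        tables: dict[tuple[str, str], np.ndarray] | None = None,
    ):
        self.pops = list(pops)
        self.n_hap = list(n_hap)
        self.n_sim = int(n_sim)
        self.pseudo = 0.5 / self.n_sim
        if tables is not None:
            self.marginal = "pairwise"
            self.tables = {}
            for key, arr in tables.items():
                arr = np.asarray(arr, dtype=np.float64).copy()
                arr[arr <= 0] = self.pseudo
                self.tables[key] = arr / arr.sum()
            return
        if sfs is None:
            raise ValueError("either a joint SFS or pairwise tables required")
        self.marginal = "joint"
        n_cells = 1
        for n in self.n_hap:
            n_cells *= n + 1
        n_cells -= 2  # globally monomorphic corners excluded
        poly = {
            e: w for e, w in sfs.counts.items() if not sfs.is_monomorphic_entry(e)
        }
        total = sum(poly.values())
        self.z = total + self.pseudo * (n_cells - len(poly))
        self.probs = {e: w / self.z for e, w in poly.items()}
        self.floor = self.pseudo / self.z

    def prob(self, entry: tuple[int, ...]) -> float:
        if self.marginal != "joint":
            raise ValueError("entry probabilities only available in joint mode")
        return self.probs.get(entry, self.floor)

    def total(self) -> float:
        """Sum of the probability tensor (1 by construction)."""
        if self.marginal == "joint":
            n_cells = 1
            for n in self.n_hap:
                n_cells *= n + 1
            n_unseen = n_cells - 2 - len(self.probs)
            return sum(self.probs.values()) + self.floor * n_unseen
        return float(np.mean([t.sum() for t in self.tables.values()]))


def expected_sfs_probs(
    model,
    sample_sizes: dict[str, int],
    n_sim_sites: int,
    seed: int,
    marginal: str = "pairwise",
    pairs: list[tuple[str, str]] | None = None,
) -> SFSProbs:
    """Estimate SFS entry probabilities from ``n_sim_sites`` simulated sites."""
    pops = [p for p, n in sample_sizes.items() if n > 0]
    n_hap = [2 * sample_sizes[p] for p in pops]
    if marginal == "pairwise" and len(pops) >= 2:
        compiled = _engine.CompiledModel(model)
        tables = _engine.expected_pairwise_tables(
            compiled, sample_sizes, n_sim_sites, seed, pairs=pairs
        )
        return SFSProbs(n_sim_sites, pops, n_hap, tables=tables)
    sfs = simulate_joint_sfs(model, sample_sizes, n_sim_sites, seed)
    return SFSProbs(n_sim_sites, pops, n_hap, sfs=sfs)


def composite_log_likelihood(observed, probs) -> float:
    """Multinomial composite log-likelihood ``sum_e m_e log p_e``.

    Accepts either plain count/probability arrays, or an :class:`SFS` with an
    :class:`SFSProbs` reference (joint or pairwise-marginal mode).  Globally
    monomorphic observed entries are excluded.
    """
    if isinstance(observed, (np.ndarray, list, tuple)):
        m = np.asarray(observed, dtype=float)
        p = np.asarray(probs, dtype=float)
        if m.shape != p.shape:
            raise ValueError("count and probability shapes differ")
        use = m > 0
        if np.any(p[use] <= 0):
            raise ValueError("nonzero count at zero-probability entry")
        return float(np.sum(m[use] * np.log(p[use])))

    sfs: SFS = observed
    if probs.marginal == "joint":
        cl = 0.0
        for entry, w in sfs.counts.items():
            if sfs.is_monomorphic_entry(entry):
                continue
            cl += w * math.log(probs.prob(entry))
        return cl
    cl = 0.0
    for (pa, pb), table in probs.tables.items():
        obs2 = sfs.marginal([pa, pb]).dense()
        use = obs2 > 0
        cl += float(np.sum(obs2[use] * np.log(table[use])))
    return cl


@dataclass
class FitSpec:
    """Free parameters, bounds/grids and evaluation settings for a refit."""

    sample_sizes: dict[str, int]
    free: dict[str, tuple[float, float]]  # name -> (lower, upper)
    base_params: dict[str, float] = field(default_factory=dict)
    grid_step: dict[str, float] | float = 1.0
    n_sim_sites: int = 50_000
    n_obs_sites: int = 200_000
    eval_seed: int = 20_201  # common-random-numbers seed for every evaluation
    marginal: str = "pairwise"
    #: restrict pairwise tables to pairs touching these populations (None = all)
    focus_pops: list[str] | None = None
    refine: bool = True
    #: half-width (in grid steps) of the quadratic response-surface window
    refine_window: int = 8
    builder: callable = model_from_params

    def step_for(self, name: str) -> float:
        if isinstance(self.grid_step, dict):
            return float(self.grid_step.get(name, 1.0))
        return float(self.grid_step)

    def pair_list(self) -> list[tuple[str, str]] | None:
        if self.focus_pops is None:
            return None
        pops = [p for p, n in self.sample_sizes.items() if n > 0]
        focus = set(self.focus_pops)
        return [
            (a, b) for a, b in combinations(pops, 2) if a in focus or b in focus
        ]


@dataclass
class FitResult:
    params: dict[str, float]
    cl: float
    ci: dict[str, tuple[float, float]] | None = None
    n_boot: int = 0
    n_dropped: int = 0
    flags: list[str] = field(default_factory=list)


def _evaluate(spec: FitSpec, observed: SFS, values: dict[str, float]) -> float:
    params = dict(spec.base_params)
    params.update(values)
    try:
        model = spec.builder(params)
        probs = expected_sfs_probs(
            model,
            spec.sample_sizes,
            spec.n_sim_sites,
            spec.eval_seed,
            marginal=spec.marginal,
            pairs=spec.pair_list(),
        )
    except (ValueError, KeyError):
        return -np.inf
    return composite_log_likelihood(observed, probs)


def _quadratic_vertex(xs: np.ndarray, ys: np.ndarray) -> float | None:
    """Vertex of the least-squares parabola through (xs, ys); None if convex."""
    if xs.size < 4:
        return None
    coeff = np.polyfit(xs, ys, 2)
    if coeff[0] >= 0:
        return None
    return float(-coeff[1] / (2 * coeff[0]))


def fit_parameters(spec: FitSpec, observed: SFS) -> FitResult:
    """Grid search with local response-surface (or Nelder-Mead) refinement."""
    if observed.total() < 10_000:
        warnings.warn(
            f"observed SFS has only {observed.total():.0f} sites; "
            "estimates may be unstable",
            stacklevel=2,
        )
    names = list(spec.free)
    if not names:
        cl = _evaluate(spec, observed, {})
        return FitResult(params=dict(spec.base_params), cl=cl)

    grids = []
    for name in names:
        lo, hi = spec.free[name]
        step = spec.step_for(name)
        grids.append(np.arange(lo, hi + step * 0.5, step))

    cache: dict[tuple, float] = {}

    def cl_at(vec) -> float:
        key = tuple(round(float(v), 10) for v in vec)
        if key not in cache:
            cache[key] = _evaluate(spec, observed, dict(zip(names, key)))
        return cache[key]

    best_vec, best_cl = None, -np.inf
    for vec in product(*grids):
        cl = cl_at(vec)
        if cl > best_cl:
            best_cl, best_vec = cl, np.array(vec, dtype=float)

    if best_vec is None or not np.isfinite(best_cl):
        raise RuntimeError("no valid parameter combination on the grid")

    flags = []
    if spec.refine and len(names) == 1:
        grid = grids[0]
        finite = np.array([np.isfinite(cl_at((g,))) for g in grid])
        xs = grid[finite]
        ys = np.array([cl_at((g,)) for g in xs])
        i_best = int(np.argmax(ys))
        lo_i = max(0, i_best - spec.refine_window)
        hi_i = min(xs.size, i_best + spec.refine_window + 1)
        vertex = _quadratic_vertex(xs[lo_i:hi_i], ys[lo_i:hi_i])
        if vertex is not None:
            # the grid maximum's CL is retained; the vertex pools the profile
            vertex = float(np.clip(vertex, xs[lo_i], xs[hi_i - 1]))
            best_vec = np.array([vertex])
    elif spec.refine and len(names) > 1:
        lo = np.array([spec.free[n][0] for n in names])
        hi = np.array([spec.free[n][1] for n in names])

        def neg_cl(x):
            if np.any(x < lo) or np.any(x > hi):
                return np.inf
            return -cl_at(x)

        steps = np.array([spec.step_for(n) for n in names])
        simplex = [best_vec]
        for i in range(len(names)):
            v = best_vec.copy()
            v[i] = v[i] + steps[i] if v[i] + steps[i] <= hi[i] else v[i] - steps[i]
            simplex.append(v)
        res = minimize(
            neg_cl,
            best_vec,
            method="Nelder-Mead",
            options={
                "initial_simplex": np.array(simplex),
                "xatol": min(steps) * 0.1,
                "fatol": 0.5,
                "maxiter": 25,
                "maxfev": 25,
            },
        )
        if -res.fun >= best_cl:
            best_vec, best_cl = np.asarray(res.x, dtype=float), -float(res.fun)

    for name, v, grid in zip(names, best_vec, grids):
        if v <= grid[0] + 1e-9 or v >= grid[-1] - 1e-9:
            flags.append(f"{name} at search bound")

    params = dict(spec.base_params)
    params.update(dict(zip(names, (float(v) for v in best_vec))))
    return FitResult(params=params, cl=float(best_cl), flags=flags)


def parametric_bootstrap_ci(
    spec: FitSpec,
    fitted_params: dict[str, float],
    n_boot: int = 50,
    level: float = 0.95,
    seed: int = 0,
) -> FitResult:
    """Percentile bootstrap CIs: re-simulate under the fit, refit each replicate."""
    if n_boot < 20:
        raise ValueError("parametric bootstrap requires n_boot >= 20")
    names = list(spec.free)
    model = spec.builder({**spec.base_params, **fitted_params})
    rng = np.random.SeedSequence(seed)
    estimates: list[dict[str, float]] = []
    n_dropped = 0
    for child in rng.spawn(n_boot):
        boot_seed = int(child.generate_state(1)[0] % (2**31))
        obs_b = simulate_joint_sfs(model, spec.sample_sizes, spec.n_obs_sites, boot_seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                fit_b = fit_parameters(spec, obs_b)
        except RuntimeError:
            n_dropped += 1
            continue
        if any("bound" in f for f in fit_b.flags):
            n_dropped += 1
            continue
        estimates.append({n: fit_b.params[n] for n in names})

    if not estimates:
        raise RuntimeError("all bootstrap replicates failed")
    alpha = (1.0 - level) / 2.0
    ci = {}
    point = {n: float(fitted_params[n]) for n in names}
    for n in names:
        vals = np.array([e[n] for e in estimates])
        ci[n] = (float(np.quantile(vals, alpha)), float(np.quantile(vals, 1 - alpha)))
    flags = []
    if len(estimates) >= 20:
        for n in names:
            if not (ci[n][0] <= point[n] <= ci[n][1]):
                flags.append(f"{n} point estimate outside bootstrap interval")
    return FitResult(
        params=point,
        cl=np.nan,
        ci=ci,
        n_boot=len(estimates),
        n_dropped=n_dropped,
        flags=flags,
    )
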