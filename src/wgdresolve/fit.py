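"""Maximum-likelihood fitting of the nested loss-model families.

Five families form a nesting lattice:

=========  ==================  ==========================================
family     free global params  meaning
=========  ==================  ==========================================
WGD-n      theta               balanced loss only (gamma=0, eps=1)
WGD-f      gamma, theta        + duplicate fixation
WGD-b      eps, theta          + biased fractionation
WGD-bf     gamma, eps, theta   both
WGD-btf    gamma, eps_early,   bias allowed to differ on the
           eps_late, theta     root-proximal ("early") branch class
=========  ==================  ==========================================

Branch lengths are always free.  Optimization is bound-constrained
quasi-Newton (L-BFGS-B) on the raw bounded parameters; keeping eps and gamma
on their natural scales lets the boundary values eps=1 and gamma=0 be reached
exactly, which matters for likelihood-ratio tests of the nested families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import (edge_transition_matrices, emission_matrix,
                         sequence_loglik)
from . import _hmmcore
from .model import LossParams
from .pillars import JunctionModel, PillarSet
from .trees import LossTree, enumerate_rooted_topologies

log = logging.getLogger(__name__)

#: family name -> (gamma free?, eps free?, eps split early/late?)
FAMILIES: dict[str, tuple[bool, bool, bool]] = {
    "n": (False, False, False),
    "f": (True, False, False),
    "b": (False, True, False),
    "bf": (True, True, False),
    "btf": (True, True, True),
}

_BOUNDS = {"b": (1e-4, 25.0), "gamma": (0.0, 50.0), "eps": (0.0, 1.0),
           "theta": (1e-5, 0.5)}


class OptimizationError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Fitted model: MLEs, maximized log-likelihood and diagnostics."""

    family: str
    loglik: float
    tree: LossTree
    gamma: float
    epsilon: float
    theta: float
    eps_early: float | None = None
    converged: bool = True
    message: str = ""
    n_evals: int = 0
    seed: int | None = None
    n_free: int = 0

    @property
    def eps_late(self) -> float | None:
        return self.epsilon if self.eps_early is not None else None

    def params(self) -> LossParams:
        return LossParams(gamma=self.gamma, epsilon=self.epsilon)

    def to_dict(self) -> dict:
        out = {
            "family": f"WGD-{self.family}",
            "loglik": self.loglik,
            "gamma": self.gamma,
            "epsilon": self.epsilon,
            "theta": self.theta,
            "converged": self.converged,
            "n_free_params": self.n_free,
            "branch_lengths": {self.tree.edge_label(i): float(self.tree.edge_lengths[i])
                               for i in range(self.tree.n_edges)},
        }
        if self.eps_early is not None:
            out["eps_early"] = self.eps_early
            out["eps_late"] = self.epsilon
        return out


def n_free_global(family: str) -> int:
    """Number of free global parameters (theta included, branches excluded)."""
    gamma_free, eps_free, split = FAMILIES[family]
    return 1 + gamma_free + eps_free + split


def _pack_template(family: str, n_edges: int):
    gamma_free, eps_free, split = FAMILIES[family]
    names = [f"b{e}" for e in range(n_edges)]
    bounds = [_BOUNDS["b"]] * n_edges
    if gamma_free:
        names.append("gamma"); bounds.append(_BOUNDS["gamma"])
    if eps_free:
        names.append("eps"); bounds.append(_BOUNDS["eps"])
    if split:
        names.append("eps_early"); bounds.append(_BOUNDS["eps"])
    names.append("theta"); bounds.append(_BOUNDS["theta"])
    return names, bounds


def fit_model(pillar_set: PillarSet, tree: LossTree | str, family: str = "bf",
              *, early: list[str] | None = None, seed: int = 0,
              restarts: int = 0, init: "FitResult | dict | None" = None,
              maxiter: int = 1000) -> FitResult:
    """Maximize the sequence log-likelihood over all free parameters.

    ``early`` names the branch class that gets its own fractionation bias
    under WGD-btf (default: branches incident to the WGD root).  ``restarts``
    adds that many randomized starting points (seeded); the best optimum is
    returned.  ``init`` warm-starts from a previous fit's parameters.
    Non-convergence is flagged on the result, not raised.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; choose from {list(FAMILIES)}")
    if isinstance(tree, str):
        tree = LossTree.from_newick(tree)
    tree = tree.with_lengths(tree.edge_lengths)  # private copy, mutated in place
    gamma_free, eps_free, split = FAMILIES[family]
    names, bounds = _pack_template(family, tree.n_edges)
    early_mask = tree.early_edge_mask(early) if split else None
    flips_template = pillar_set.double_breaks
    m = pillar_set.m
    n_evals = 0

    def unpack(x):
        E = tree.n_edges
        lengths = x[:E]
        i = E
        gamma = x[i] if gamma_free else 0.0
        i += gamma_free
        eps = x[i] if eps_free else 1.0
        i += eps_free
        eps_early = x[i] if split else None
        i += split
        theta = x[i]
        return lengths, gamma, eps, eps_early, theta

    def negloglik(x):
        nonlocal n_evals
        n_evals += 1
        lengths, gamma, eps, eps_early, theta = unpack(x)
        tree.edge_lengths[:] = lengths
        params = LossParams(gamma=gamma, epsilon=eps)
        edge_P = edge_transition_matrices(tree, params, eps_early=eps_early,
                                          early_mask=early_mask)
        E, log_scale = emission_matrix(pillar_set, tree, edge_P)
        flips = np.full(flips_template.shape, theta, dtype=float)
        flips[flips_template] = 0.5
        ll, _ = _hmmcore.forward(E, flips)
        total = ll + log_scale.sum()
        if not np.isfinite(total):
            return 1e12
        return -total

    def default_start():
        x0 = np.empty(len(names))
        x0[:tree.n_edges] = np.maximum(tree.edge_lengths, 0.05)
        i = tree.n_edges
        if gamma_free:
            x0[i] = 0.1; i += 1
        if eps_free:
            x0[i] = 0.8; i += 1
        if split:
            x0[i] = 0.8; i += 1
        x0[i] = 0.01
        return x0

    starts = []
    if init is not None:
        starts.append(_start_from(init, names, tree))
    starts.append(default_start())
    rng = np.random.default_rng(seed)
    base = starts[-1]
    for _ in range(restarts):
        x = base * np.exp(rng.uniform(-1.0, 1.0, size=base.shape))
        starts.append(np.clip(x, [lo for lo, _ in bounds], [hi for _, hi in bounds]))

    best = None
    for x0 in starts:
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                                         "ftol": 1e-11})
        if best is None or res.fun < best.fun:
            best = res
    lengths, gamma, eps, eps_early, theta = unpack(best.x)
    fitted = tree.with_lengths(lengths)
    if not best.success:
        log.warning("fit (WGD-%s) did not converge: %s", family, best.message)
    return FitResult(family=family, loglik=-float(best.fun), tree=fitted,
                     gamma=float(gamma), epsilon=float(eps), theta=float(theta),
                     eps_early=None if eps_early is None else float(eps_early),
                     converged=bool(best.success), message=str(best.message),
                     n_evals=n_evals, seed=seed,
                     n_free=len(names))


def _start_from(init, names, tree) -> np.ndarray:
    if isinstance(init, FitResult):
        init = {"branch_lengths": init.tree.edge_lengths.copy(),
                "gamma": init.gamma, "eps": init.epsilon,
                "eps_early": init.eps_early, "theta": init.theta}
    x0 = []
    bl = np.asarray(init.get("branch_lengths", np.full(tree.n_edges, 0.3)), dtype=float)
    x0.extend(bl[:tree.n_edges])
    for name in names[tree.n_edges:]:
        if name == "gamma":
            x0.append(init.get("gamma") or 0.1)
        elif name == "eps":
            x0.append(init.get("eps", 0.8) if init.get("eps") is not None else 0.8)
        elif name == "eps_early":
            v = init.get("eps_early")
            x0.append(v if v is not None else init.get("eps", 0.8))
        elif name == "theta":
            x0.append(init.get("theta") or 0.01)
    x0 = np.array(x0)
    # keep strictly inside trivially invalid values
    return np.clip(x0, 1e-4, None)


def lrt(nested: FitResult, fuller: FitResult, df: int | None = None
        ) -> tuple[float, float]:
    """Likelihood-ratio test of a nested family against a fuller one.

    Returns (statistic, p) with statistic = 2 (lnL_full - lnL_nested) and p
    from the upper tail of chi-square with ``df`` degrees of freedom
    (difference in free-parameter counts by default).  When the constrained
    parameter sits on its boundary under the null (eps = 1) the plain
    chi-square p-value is conservative.
    """
    if df is None:
        df = fuller.n_free - nested.n_free
    if df <= 0:
        raise ValueError("families are not nested (non-positive df)")
    statistic = 2.0 * (fuller.loglik - nested.loglik)
    if statistic < -1e-3:
        raise OptimizationError(
            f"fuller model has lower likelihood by {-statistic/2:.4g}; "
            "an optimization failed to converge")
    statistic = max(statistic, 0.0)
    return statistic, float(stats.chi2.sf(statistic, df))


def topology_sweep(pillar_set: PillarSet, taxa: list[str] | None = None,
                   family: str = "bf", *, seed: int = 0, max_taxa: int = 5,
                   **fit_kw) -> list[tuple[str, FitResult]]:
    """Fit every rooted binary topology and rank by log-likelihood.

    Ties are broken by free-parameter count, then lexicographic newick.
    """
    if taxa is None:
        taxa = list(pillar_set.genomes)
    if len(taxa) > max_taxa:
        raise ValueError(
            f"{len(taxa)} taxa would give too many rooted topologies; cap is {max_taxa}")
    results = []
    for newick in enumerate_rooted_topologies(taxa):
        fit = fit_model(pillar_set, newick, family, seed=seed, **fit_kw)
        results.append((fit.tree.to_newick(), fit))
    results.sort(key=lambda t: (-t[1].loglik, t[1].n_free, t[0]))
    return results


def fit_blocks(pillar_set: PillarSet, blocks: list[tuple[int, int]],
               tree: LossTree, global_fit: FitResult,
               min_pillars: int = 100) -> pd.DataFrame:
    """Per-block fractionation-bias estimates.

    Within each block of at least ``min_pillars`` pillars, eps is re-fit by
    profile likelihood with branch lengths, gamma and theta held at the
    global MLE.  Undersized blocks are skipped (logged).
    """
    rows = []
    for start, stop in blocks:
        size = stop - start
        if size < min_pillars:
            log.info("skipping block [%d, %d): only %d pillars", start, stop, size)
            continue
        sub = pillar_set.subset(start, stop)
        junc = JunctionModel.for_pillars(sub, global_fit.theta)

        def negll(eps):
            params = LossParams(gamma=global_fit.gamma, epsilon=float(eps))
            return -sequence_loglik(sub, tree, params, junc)

        res = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-5})
        rows.append({"start": start, "stop": stop, "n_pillars": size,
                     "midpoint": 0.5 * (start + stop),
                     "eps": float(res.x), "loglik": -float(res.fun)})
    return pd.DataFrame(rows, columns=["start", "stop", "n_pillars", "midpoint",
                                       "eps", "loglik"])
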