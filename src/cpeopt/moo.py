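"""Mixed-variable multi-objective maximization of the surrogate's responses.

An NSGA-II-style evolutionary loop searches the factor space for settings that
simultaneously maximize the three predicted responses (TPC, TC, AA):
tournament selection on (non-domination rank, crowding distance), uniform
crossover on categorical genes, blend crossover and Gaussian mutation on
continuous genes (clipped to bounds), and elitist survival from the combined
parent+offspring population.  The returned front is re-checked for
non-domination by brute force, and a single compromise setting is picked by an
equally weighted sum of front-normalized objectives.

Default run length (36 generations, population 100) matches the study's
reported optimization budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factor_space import FactorSpace
from .surrogate import SurrogateModel

__all__ = ["ParetoResult", "optimize", "pareto_filter", "compromise_index"]


def pareto_filter(points) -> np.ndarray:
    """Indices of the non-dominated subset of objective vectors (maximization).

    A point is dominated if some other point is >= in every objective and > in
    at least one.  Duplicated objective vectors are all retained.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if len(P) == 0:
        raise ValueError("need at least one point")
    keep = []
    for i in range(len(P)):
        dominated = np.any(
            np.all(P >= P[i], axis=1) & np.any(P > P[i], axis=1)
        )
        if not dominated:
            keep.append(i)
    return np.array(keep, dtype=int)


def _fast_nondominated_ranks(F: np.ndarray) -> np.ndarray:
    """Non-domination rank (0 = first front) for each row, maximization."""
    n = len(F)
    dominates = np.zeros((n, n), dtype=bool)
    for i in range(n):
        dominates[i] = np.all(F[i] >= F, axis=1) & np.any(F[i] > F, axis=1)
    n_dominators = dominates.sum(axis=0)
    ranks = np.full(n, -1, dtype=int)
    current, r = np.where(n_dominators == 0)[0], 0
    remaining = n_dominators.copy()
    while len(current):
        ranks[current] = r
        remaining[current] = -1
        for i in current:
            remaining[dominates[i]] -= 1
        current = np.where(remaining == 0)[0]
        r += 1
    return ranks


def _crowding(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        span = F[order[-1], j] - F[order[0], j]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0 and n > 2:
            d[order[1:-1]] += (F[order[2:], j] - F[order[:-2], j]) / span
    return d


@dataclass
class _Genome:
    """Internal mixed representation: continuous values + categorical indices."""
    cont: np.ndarray
    cat: np.ndarray


class _Problem:
    def __init__(self, model: SurrogateModel, space: FactorSpace):
        self.model = model
        self.space = space
        self.cont_factors = [f for f in space.factors if f.kind == "continuous"]
        self.cat_factors = [f for f in space.factors if f.kind == "categorical"]
        self.low = np.array([f.low for f in self.cont_factors])
        self.high = np.array([f.high for f in self.cont_factors])
        self.n_levels = np.array([len(f.levels) for f in self.cat_factors])
        self.n_genes = len(self.cont_factors) + len(self.cat_factors)
        # column layout of the encoded vector, for vectorized evaluation
        slices = space.feature_slices()
        self.cont_cols = np.array(
            [slices[f.name].start for f in self.cont_factors], dtype=int
        )
        self.cat_starts = np.array(
            [slices[f.name].start for f in self.cat_factors], dtype=int
        )

    def random_population(self, n, rng) -> _Genome:
        cont = rng.uniform(self.low, self.high, size=(n, len(self.low)))
        cat = rng.integers(0, self.n_levels, size=(n, len(self.n_levels)))
        return _Genome(cont, cat)

    def evaluate(self, g: _Genome) -> np.ndarray:
        n = len(g.cont)
        X = np.zeros((n, self.space.encoded_width))
        X[:, self.cont_cols] = np.clip(g.cont, self.low, self.high)
        for j, start in enumerate(self.cat_starts):
            X[np.arange(n), start + g.cat[:, j]] = 1.0
        return self.model.forward(X)

    def settings(self, g: _Genome, i: int) -> dict:
        s = {}
        for j, f in enumerate(self.cont_factors):
            s[f.name] = float(np.clip(g.cont[i, j], f.low, f.high))
        for j, f in enumerate(self.cat_factors):
            s[f.name] = f.levels[int(g.cat[i, j])]
        return s


@dataclass
class ParetoResult:
    """Non-dominated settings with predictions, plus the compromise optimum."""

    front: pd.DataFrame            # factor columns + predicted response columns
    compromise: pd.Series          # one row of `front`
    trace: list                    # per-generation best equal-weight statistic
    config: dict

    @property
    def n_front(self) -> int:
        return len(self.front)

    def write_tsv(self, path) -> None:
        self.front.to_csv(path, sep="\t", index=False)


def _normalize_objectives(F: np.ndarray) -> np.ndarray:
    lo, hi = F.min(axis=0), F.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    N = (F - lo) / span
    return np.where(hi > lo, N, 0.0)


def compromise_index(F: np.ndarray, weights=None) -> int:
    """Row index maximizing the weighted sum of min-max-normalized objectives.

    Objectives are normalized over the given set (the front); equal weights by
    default; ties resolve to the earliest row.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    m = F.shape[1]
    w = np.full(m, 1.0 / m) if weights is None else np.asarray(weights, float)
    scores = _normalize_objectives(F) @ w
    return int(np.argmax(scores))    # argmax returns the first maximizer


def optimize(model: SurrogateModel, space: FactorSpace | None = None,
             generations: int = 36, pop: int = 100, seed: int = 0,
             weights=None, crossover_prob: float = 0.9,
             mutation_sigma_frac: float = 0.05) -> ParetoResult:
    """Run the evolutionary multi-objective maximization.

    Continuous genes are bounded by each factor's [low, high]; categorical
    genes range over declared levels.  Mutation probability is 1/n_genes per
    gene; Gaussian mutation sigma is ``mutation_sigma_frac`` of each factor's
    range.  Fixed ``seed`` gives bit-reproducible results.
    """
    space = space or model.space
    if space is None:
        raise ValueError("no factor space given and none attached to the model")
    prob = _Problem(model, space)
    if prob.n_genes == 0:
        raise ValueError("empty feasible space: no factors to optimize")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A2E]))

    P = prob.random_population(pop, rng)
    F = prob.evaluate(P)
    sigma = mutation_sigma_frac * (prob.high - prob.low)
    p_mut = 1.0 / prob.n_genes
    trace = []

    for _ in range(generations):
        ranks = _fast_nondominated_ranks(F)
        crowd = np.zeros(pop)
        for r in np.unique(ranks):
            idx = np.where(ranks == r)[0]
            crowd[idx] = _crowding(F[idx])

        def tournament():
            a, b = rng.integers(0, pop, size=2)
            if ranks[a] != ranks[b]:
                return a if ranks[a] < ranks[b] else b
            return a if crowd[a] >= crowd[b] else b

        child_cont = np.empty_like(P.cont)
        child_cat = np.empty_like(P.cat)
        for i in range(0, pop, 2):
            pa, pb = tournament(), tournament()
            ca, cb = P.cont[pa].copy(), P.cont[pb].copy()
            ka, kb = P.cat[pa].copy(), P.cat[pb].copy()
            if rng.random() < crossover_prob:
                # blend (BLX-0.5) on continuous genes
                lo = np.minimum(ca, cb)
                hi = np.maximum(ca, cb)
                d = hi - lo
                ca = rng.uniform(lo - 0.5 * d, hi + 0.5 * d)
                cb = rng.uniform(lo - 0.5 * d, hi + 0.5 * d)
                # uniform crossover on categorical genes
                swap = rng.random(size=ka.shape) < 0.5
                ka, kb = np.where(swap, kb, ka), np.where(swap, ka, kb)
            for cont, cat in ((ca, ka), (cb, kb)):
                mask = rng.random(size=cont.shape) < p_mut
                cont += mask * rng.normal(0.0, sigma, size=cont.shape)
                cmask = rng.random(size=cat.shape) < p_mut
                resample = rng.integers(0, prob.n_levels, size=cat.shape)
                cat[cmask] = resample[cmask]
            np.clip(ca, prob.low, prob.high, out=ca)
            np.clip(cb, prob.low, prob.high, out=cb)
            child_cont[i], child_cat[i] = ca, ka
            if i + 1 < pop:
                child_cont[i + 1], child_cat[i + 1] = cb, kb

        Q = _Genome(child_cont, child_cat)
        FQ = prob.evaluate(Q)
        allF = np.vstack([F, FQ])
        allG = _Genome(np.vstack([P.cont, Q.cont]), np.vstack([P.cat, Q.cat]))
        ranks_all = _fast_nondominated_ranks(allF)
        order = []
        for r in np.unique(ranks_all):
            idx = np.where(ranks_all == r)[0]
            if len(order) + len(idx) <= pop:
                order.extend(idx.tolist())
            else:
                cd = _crowding(allF[idx])
                take = idx[np.argsort(-cd, kind="stable")][: pop - len(order)]
                order.extend(take.tolist())
            if len(order) >= pop:
                break
        sel = np.array(order[:pop])
        P = _Genome(allG.cont[sel], allG.cat[sel])
        F = allF[sel]
        trace.append(float(_normalize_objectives(F).mean(axis=1).max()))

    # final non-dominated set over unique settings
    keep = pareto_filter(F)
    # deduplicate identical genomes on the front
    seen, uniq = set(), []
    for i in keep:
        key = (tuple(np.round(P.cont[i], 12)), tuple(P.cat[i]))
        if key not in seen:
            seen.add(key)
            uniq.append(i)
    rows = []
    for i in uniq:
        row = prob.settings(P, i)
        for j, name in enumerate(space.response_names):
            row[f"pred_{name}"] = F[i, j]
        rows.append(row)
    front = pd.DataFrame(rows)
    Ffront = F[uniq]
    ci = compromise_index(Ffront, weights)
    config = {
        "generations": generations, "pop": pop, "seed": int(seed),
        "crossover_prob": crossover_prob,
        "mutation_sigma_frac": mutation_sigma_frac,
        "weights": None if weights is None else list(map(float, weights)),
    }
    return ParetoResult(front=front, compromise=front.iloc[ci],
                        trace=trace, config=config)
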