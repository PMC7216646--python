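"""Optimal cross selection by differential evolution.

Two formulations are provided.  ``ocs_select`` maximizes the expected mean
genetic value of the selected fractions V(nc) subject to the genome-wide
diversity floor D(nc) >= He(t) (constraint handled by feasibility-first
ranking: any feasible set beats any infeasible one, infeasible sets are
ranked by constraint violation).  ``bridging_select`` completes a fixed
breeding plan with bridging crosses maximizing the scalarized objective
alpha * V* + (1 - alpha) * D*, where V* and D* are min-max normalized by the
extreme sets nc*_V (max performance) and nc*_D (max diversity) found with
the same optimizer.

Candidate sets are encoded as integer index vectors over the enumerated
candidate crosses (duplicate pairs repaired after mutation); the search is a
standard DE/rand/1/bin scheme on the rounded integer space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DEParams", "CrossPlan", "ocs_select", "bridging_select", "top_uc_plan"]


@dataclass(frozen=True)
class DEParams:
    """Differential-evolution hyperparameters (budget and operators)."""

    pop_size: int = 60
    cr: float = 0.9
    f_min: float = 0.4
    f_max: float = 0.9
    max_gen: int = 2000
    stagnation: int = 200
    # probability that a trial is a fresh random subset (random immigrant);
    # integer-vector DE alone loses diversity quickly on set encodings
    immigrant_p: float = 0.05


@dataclass
class CrossPlan:
    """A selected cross set: candidate indices plus objective diagnostics."""

    indices: np.ndarray
    value: float                    # V of the set
    diversity: float                # D of the set
    feasible: bool = True
    info: dict = field(default_factory=dict)


def _random_subset(rng: np.random.Generator, n_cand: int, k: int) -> np.ndarray:
    return rng.choice(n_cand, size=k, replace=False)


def _repair_rows(mat: np.ndarray, n_cand: int, rng: np.random.Generator) -> None:
    """In-place: make every row a set of distinct candidate indices.

    Duplicates are replaced by fresh random candidates (rejection sampling;
    collisions are rare because the set size is much smaller than the
    candidate count in every use here).
    """
    for r in range(mat.shape[0]):
        row = mat[r]
        seen: set = set()
        for k in range(row.size):
            v = int(row[k])
            while v in seen:
                v = int(rng.integers(n_cand))
            seen.add(v)
            row[k] = v


def _de_maximize(n_cand: int, k: int, evaluate, rng: np.random.Generator,
                 params: DEParams, seeds: list[np.ndarray] | None = None):
    """Maximize a set function with feasibility-first lexicographic ranking.

    ``evaluate(idx_matrix)`` must return ``(feasible_bool, score)`` arrays;
    a member is better when it is feasible and the other is not, or when both
    have equal feasibility status and its score is higher.
    Returns (best_indices, best_feasible, best_score, n_generations).
    """
    p = max(params.pop_size, 4)
    pop = np.empty((p, k), dtype=np.int64)
    seeds = seeds or []
    for i in range(p):
        if i < len(seeds):
            pop[i] = seeds[i]
        else:
            pop[i] = _random_subset(rng, n_cand, k)
    feas, score = evaluate(pop)

    def best_of():
        order = np.lexsort((-score, ~feas))
        return order[0]

    b = best_of()
    best_key = (bool(feas[b]), float(score[b]))
    stagnant = 0
    gen = 0
    idx_all = np.arange(p)
    for gen in range(1, params.max_gen + 1):
        # mutation partners: three distinct rows, none equal to the target
        r = rng.integers(0, p, size=(p, 3))
        for _ in range(20):
            bad = ((r[:, 0] == idx_all) | (r[:, 1] == idx_all) | (r[:, 2] == idx_all)
                   | (r[:, 0] == r[:, 1]) | (r[:, 0] == r[:, 2]) | (r[:, 1] == r[:, 2]))
            if not bad.any():
                break
            r[bad] = rng.integers(0, p, size=(int(bad.sum()), 3))
        f = rng.uniform(params.f_min, params.f_max, size=(p, 1))
        mutant = np.rint(pop[r[:, 0]] + f * (pop[r[:, 1]] - pop[r[:, 2]]))
        mutant = np.clip(mutant, 0, n_cand - 1).astype(np.int64)
        cross = rng.random((p, k)) < params.cr
        cross[idx_all, rng.integers(0, k, size=p)] = True
        trial = np.where(cross, mutant, pop)
        for r in np.flatnonzero(rng.random(p) < params.immigrant_p):
            trial[r] = _random_subset(rng, n_cand, k)
        _repair_rows(trial, n_cand, rng)
        tfeas, tscore = evaluate(trial)
        better = (tfeas & ~feas) | ((tfeas == feas) & (tscore > score))
        pop[better] = trial[better]
        feas[better] = tfeas[better]
        score[better] = tscore[better]
        b = best_of()
        key = (bool(feas[b]), float(score[b]))
        if key > best_key:
            best_key = key
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= params.stagnation:
                break
    b = best_of()
    return pop[b].copy(), bool(feas[b]), float(score[b]), gen


def _set_stats(indices: np.ndarray, uc: np.ndarray, freqs: np.ndarray):
    v = float(uc[indices].mean())
    pooled = freqs[indices].mean(axis=0)
    d = float(np.mean(2.0 * pooled * (1.0 - pooled)))
    return v, d


def top_uc_plan(uc: np.ndarray, n_crosses: int) -> np.ndarray:
    """Exact unconstrained optimum: the n_crosses highest-UC candidates.

    V is additive over families, so when the diversity constraint is inactive
    the optimal set is the plain top-UC selection (ties broken by lowest
    candidate index).
    """
    order = np.lexsort((np.arange(uc.size), -uc))
    return np.sort(order[:n_crosses])


def ocs_select(uc: np.ndarray, selected_freqs: np.ndarray, n_crosses: int,
               he_min: float, rng: np.random.Generator,
               params: DEParams = DEParams()) -> CrossPlan:
    """Select n_crosses maximizing V subject to D >= he_min.

    ``uc`` (N,) and ``selected_freqs`` (N, L) are the per-candidate usefulness
    and expected selected-fraction allele frequencies.  If no feasible set is
    found, the maximal-diversity set is returned flagged infeasible (never
    raises).
    """
    n_cand = uc.size
    if n_crosses > n_cand:
        raise ValueError("more crosses requested than candidates")
    uc = np.asarray(uc, dtype=float)
    freqs = np.asarray(selected_freqs)

    def evaluate(mat):
        v = uc[mat].mean(axis=1)
        pooled = freqs[mat].mean(axis=1, dtype=np.float64)
        d = np.mean(2.0 * pooled * (1.0 - pooled), axis=1)
        feas = d >= he_min - 1e-12
        return feas, np.where(feas, v, d - he_min)

    seeds = [top_uc_plan(uc, n_crosses)]
    idx, feas, _, gen = _de_maximize(n_cand, n_crosses, evaluate, rng, params, seeds)
    idx = np.sort(idx)
    v, d = _set_stats(idx, uc, freqs)
    if not feas:
        warnings.warn("diversity constraint unmet for every evaluated cross set; "
                      "returning the maximal-diversity plan")
    return CrossPlan(idx, v, d, feas, {"generations": gen, "he_min": he_min})


def bridging_select(fixed_uc: np.ndarray, fixed_freqs: np.ndarray,
                    cand_uc: np.ndarray, cand_freqs: np.ndarray,
                    n_bridging: int, alpha: float, rng: np.random.Generator,
                    params: DEParams = DEParams()) -> CrossPlan:
    """Complete a fixed breeding plan with bridging crosses (weighted objective).

    Selects ``n_bridging`` crosses among the candidates maximizing
    alpha * V* + (1 - alpha) * D* evaluated on the full set (fixed plan plus
    bridging crosses), V* and D* min-max normalized by the max-V and max-D
    extreme sets.  A degenerate normalization range (max = min) sets the
    corresponding term to 0 with a warning.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    n_cand = cand_uc.size
    k = n_bridging
    n_total = fixed_uc.size + k
    fixed_uc_sum = float(np.sum(fixed_uc))
    fixed_freq_sum = np.asarray(fixed_freqs, np.float64).sum(axis=0)
    cand_uc = np.asarray(cand_uc, float)
    cand_freqs = np.asarray(cand_freqs)

    def full_stats(mat):
        v = (fixed_uc_sum + cand_uc[mat].sum(axis=1)) / n_total
        pooled = (fixed_freq_sum + cand_freqs[mat].sum(axis=1, dtype=np.float64)) / n_total
        d = np.mean(2.0 * pooled * (1.0 - pooled), axis=1)
        return v, d

    true_vec = np.ones(params.pop_size, dtype=bool)

    def eval_v(mat):
        v, _ = full_stats(mat)
        return true_vec[: len(v)].copy(), v

    def eval_d(mat):
        _, d = full_stats(mat)
        return true_vec[: len(d)].copy(), d

    greedy_v = top_uc_plan(cand_uc, k)
    nc_v, _, _, _ = _de_maximize(n_cand, k, eval_v, rng, params, [greedy_v])
    nc_d, _, _, _ = _de_maximize(n_cand, k, eval_d, rng, params)
    v_v, d_v = full_stats(nc_v[None, :])
    v_d, d_d = full_stats(nc_d[None, :])
    v_v, d_v, v_d, d_d = float(v_v[0]), float(d_v[0]), float(v_d[0]), float(d_d[0])

    v_range = v_v - v_d
    d_range = d_d - d_v
    if v_range <= 0:
        warnings.warn("degenerate V normalization range; V term set to 0")
    if d_range <= 0:
        warnings.warn("degenerate D normalization range; D term set to 0")

    def objective(v, d):
        vs = (v - v_d) / v_range if v_range > 0 else np.zeros_like(v)
        ds = (d - d_v) / d_range if d_range > 0 else np.zeros_like(d)
        return alpha * vs + (1.0 - alpha) * ds

    def eval_obj(mat):
        v, d = full_stats(mat)
        return true_vec[: len(v)].copy(), objective(v, d)

    idx, _, score, gen = _de_maximize(n_cand, k, eval_obj, rng, params,
                                      [nc_v.copy(), nc_d.copy()])
    idx = np.sort(idx)
    v, d = full_stats(idx[None, :])
    return CrossPlan(idx, float(v[0]), float(d[0]), True, {
        "generations": gen, "alpha": alpha, "objective": float(score),
        "nc_v": np.sort(nc_v), "nc_d": np.sort(nc_d),
        "v_extremes": (v_v, v_d), "d_extremes": (d_v, d_d),
        "objective_fn": objective,
    })
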