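"""Mixed-integer scatter search, local refinement and multistart baseline.

The simultaneous selection/estimation problem is a mixed-integer nonlinear
program: minimise a scalar objective over continuous variables p within box
bounds and integer variables q within integer bounds.  No convexity or
relaxability is assumed — the objective is only ever evaluated at integer
points of q.  The global driver is a scatter-search metaheuristic: a small
reference set of good and diverse solutions is evolved by path-relinking
style combinations, a rounding operator keeps integer coordinates integral,
and promising members are periodically polished by a local mixed-integer
refinement (bounded descent on the reals with integers fixed, followed by
greedy unit moves on the integers).

Objectives are plain callables ``f(xr, xi) -> float`` over a real vector and
an integer vector.  An objective may additionally expose
``residuals(xr, xi) -> array | None``; local refinement then uses bounded
nonlinear least squares on the reals, which converges far faster on
calibration problems than direct search.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .kdp_model import StructureVector

__all__ = [
    "DecisionVector",
    "SearchSettings",
    "RunResult",
    "MultistartResult",
    "enumerate_structures",
    "scatter_search",
    "local_refine",
    "multistart",
]


@dataclass
class DecisionVector:
    """A point of the mixed search space: continuous reals and exact integers."""

    reals: np.ndarray
    integers: np.ndarray

    def __post_init__(self) -> None:
        self.reals = np.asarray(self.reals, dtype=float)
        self.integers = np.asarray(self.integers, dtype=np.int64)

    def copy(self) -> "DecisionVector":
        return DecisionVector(self.reals.copy(), self.integers.copy())


@dataclass
class SearchSettings:
    """Tuning knobs of the scatter search; the seed is mandatory."""

    seed: int
    max_evaluations: int = 2000
    refset_size: int = 10
    n_diverse: int | None = None  # default 10 × dimension
    local_refine_every: int = 1
    local_budget: int = 400
    #: independent short refinements granted to each binary-switch stratum
    #: during the opening tournament (0 disables the tournament)
    tournament_restarts: int = 2
    stagnation_window: int = 20
    stagnation_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in ("max_evaluations", "refset_size", "local_refine_every", "local_budget"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RunResult:
    """Audit trail of one optimizer run."""

    best: DecisionVector
    best_value: float
    trace: list  # [(evaluation index, best-so-far value), ...]
    n_evaluations: int
    seed: int
    best_objective: object | None = None

    def to_dict(self) -> dict:
        return {
            "best_reals": self.best.reals.tolist(),
            "best_integers": self.best.integers.tolist(),
            "best_value": self.best_value,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "trace": [[int(i), float(v)] for i, v in self.trace],
        }


@dataclass
class MultistartResult:
    """Final values of independent local searches from random feasible starts."""

    values: np.ndarray
    finals: list
    seed: int

    def histogram(self, bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.values[np.isfinite(self.values)], bins=bins)


def enumerate_structures(exponent_values: Sequence[int] = (0, 1, 2, 3)) -> list[StructureVector]:
    """Every distinct nested structure of the superstructure.

    Structures differing only in inactive exponents share identical dynamics
    and are identified (represented with inactive exponents set to 0).  For
    exponents 0–3 this yields the full census of 1700 nested models.
    """
    exponent_values = sorted(set(int(v) for v in exponent_values))
    out = []
    seen = set()
    for bin1, bin2, bin3 in product((0, 1), repeat=3):
        n1s = exponent_values if bin1 else [0]
        n23s = list(product(exponent_values, repeat=2)) if bin2 else [(0, 0)]
        n4s = exponent_values
        n5s = exponent_values if bin3 else [0]
        for n1, (n2, n3), n4, n5 in product(n1s, n23s, n4s, n5s):
            s = StructureVector(bin1, bin2, bin3, n1, n2, n3, n4, n5)
            key = dataclasses.astuple(s)
            if key not in seen:
                seen.add(key)
                out.append(s)
    return out


# ---------------------------------------------------------------------------
# Budget-tracked evaluation


class _BudgetExhausted(Exception):
    pass


class _Evaluator:
    """Counts evaluations, tracks the incumbent and the best-so-far trace."""

    def __init__(self, objective: Callable, max_evaluations: int):
        self.objective = objective
        self.max_evaluations = max_evaluations
        self.count = 0
        self.best: DecisionVector | None = None
        self.best_value = np.inf
        self.trace: list[tuple[int, float]] = []

    def __call__(self, xr: np.ndarray, xi: np.ndarray) -> float:
        if self.count >= self.max_evaluations:
            raise _BudgetExhausted
        self.count += 1
        v = float(self.objective(xr, xi))
        if not np.isfinite(v):
            v = np.inf
        if v < self.best_value:
            self.best_value = v
            self.best = DecisionVector(np.array(xr, dtype=float), np.array(xi))
            self.trace.append((self.count, v))
        return v


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def _clip_int(xi: np.ndarray, int_bounds: np.ndarray) -> np.ndarray:
    if int_bounds.size == 0:
        return np.empty(0, dtype=np.int64)
    return np.clip(xi, int_bounds[:, 0], int_bounds[:, 1]).astype(np.int64)


def _lhs(rng: np.random.Generator, n: int, bounds: np.ndarray) -> np.ndarray:
    """Latin-hypercube sample of n points in the real box."""
    d = bounds.shape[0]
    if d == 0:
        return np.empty((n, 0))
    u = (rng.permuted(np.tile(np.arange(n), (d, 1)), axis=1).T + rng.random((n, d))) / n
    return bounds[:, 0] + u * (bounds[:, 1] - bounds[:, 0])


def _random_int(rng: np.random.Generator, n: int, int_bounds: np.ndarray) -> np.ndarray:
    if int_bounds.size == 0:
        return np.empty((n, 0), dtype=np.int64)
    return rng.integers(int_bounds[:, 0], int_bounds[:, 1] + 1, size=(n, int_bounds.shape[0]))


def _normalized(x: DecisionVector, real_bounds: np.ndarray, int_bounds: np.ndarray) -> np.ndarray:
    parts = []
    if real_bounds.size:
        parts.append((x.reals - real_bounds[:, 0]) / (real_bounds[:, 1] - real_bounds[:, 0]))
    if int_bounds.size:
        span = np.maximum(int_bounds[:, 1] - int_bounds[:, 0], 1)
        parts.append((x.integers - int_bounds[:, 0]) / span)
    return np.concatenate(parts) if parts else np.empty(0)


# ---------------------------------------------------------------------------
# Local mixed-integer refinement


def local_refine(
    objective: Callable,
    start: DecisionVector,
    real_bounds: np.ndarray,
    int_bounds: np.ndarray,
    budget: int = 400,
    rng: np.random.Generator | None = None,
    _evaluator: "_Evaluator | None" = None,
) -> tuple[DecisionVector, float]:
    """Descend from ``start``: reals first (integers fixed), then greedy unit
    integer moves, re-polishing the reals after each accepted move.

    Never returns a point worse than ``start``; the evaluation budget is a
    hard cap.  Uses bounded least squares when the objective exposes
    ``residuals``, otherwise bounded Powell search.
    """
    ev = _evaluator or _Evaluator(objective, budget)
    start_in_budget = min(budget, ev.max_evaluations - ev.count)
    if start_in_budget <= 0:
        return start.copy(), np.inf
    cap = ev.count + start_in_budget
    # local incumbent: the best point seen by THIS refinement, tracked at
    # every evaluation so budget interruptions lose nothing; the local
    # budget cap is enforced here, not through optimizer iteration limits
    local = {"x": None, "v": np.inf}

    def lev(xr, xi) -> float:
        if ev.count >= cap:
            raise _BudgetExhausted
        v = ev(xr, xi)
        if v < local["v"]:
            local["v"] = v
            local["x"] = DecisionVector(np.array(xr, dtype=float), np.array(xi))
        return v

    best = start.copy()
    try:
        best_val = lev(best.reals, best.integers)
    except _BudgetExhausted:
        return best, np.inf

    residual_fn = getattr(objective, "residuals", None)
    n_r = best.reals.size

    def refine_reals(x: DecisionVector, val: float, max_nfev: int) -> tuple[DecisionVector, float]:
        max_nfev = min(max_nfev, cap - ev.count - 1)
        if x.reals.size == 0 or max_nfev <= 2:
            return x, val
        if residual_fn is not None:
            def rfun(xr):
                lev(xr, x.integers)  # count + incumbent tracking
                r = residual_fn(xr, x.integers)
                if r is None or not np.all(np.isfinite(r)):
                    return np.full(1 if r is None else r.size, 1e8)
                return r
            try:
                # explicit FD step: the default square-root-eps step probes
                # log-space coordinates below the integration noise floor
                sol = least_squares(
                    rfun, x.reals, bounds=(real_bounds[:, 0], real_bounds[:, 1]),
                    x_scale="jac", diff_step=1e-5, max_nfev=max_nfev, method="trf",
                )
                cand = DecisionVector(sol.x, x.integers.copy())
                cand_val = lev(cand.reals, cand.integers)
            except _BudgetExhausted:
                raise
            except Exception:
                return x, val
        else:
            def f(xr):
                return lev(xr, x.integers)
            try:
                sol = minimize(
                    f, x.reals, method="Powell",
                    bounds=[tuple(b) for b in real_bounds],
                    options={"maxfev": max_nfev, "xtol": 1e-10, "ftol": 1e-12},
                )
                cand = DecisionVector(np.clip(sol.x, real_bounds[:, 0], real_bounds[:, 1]),
                                      x.integers.copy())
                cand_val = lev(cand.reals, cand.integers)
            except _BudgetExhausted:
                raise
        if cand_val < val:
            return cand, cand_val
        return x, val

    try:
        # initial descent on the reals, integers held fixed; reserve roughly
        # half the budget for the integer sweeps and the final polish
        initial = min(max(20 * n_r, 60), max((cap - ev.count) // 2, 30))
        best, best_val = refine_reals(best, best_val, initial)
        # integer sweeps: unit moves, or the objective's own model-aware
        # neighbourhood when it provides one (compound moves that switch a
        # mechanism on together with values for its activated exponents).
        # A move that activates dormant parameters may look worse before
        # its reals are re-polished, so the most promising neighbours earn
        # a short polish before the verdict.
        neighbour_fn = getattr(objective, "integer_neighbors", None)

        def neighbourhood(zi):
            if neighbour_fn is not None:
                return list(neighbour_fn(zi))
            out = []
            for i in range(int_bounds.shape[0]):
                for delta in (-1, 1):
                    z = zi.copy()
                    z[i] += delta
                    if int_bounds[i, 0] <= z[i] <= int_bounds[i, 1]:
                        out.append(z)
            return out

        improved = True
        while improved and int_bounds.size and ev.count < cap - 1:
            improved = False
            neighbours = []
            for idx, zi in enumerate(neighbourhood(best.integers)):
                neighbours.append((lev(best.reals, zi), idx,
                                   DecisionVector(best.reals.copy(), zi)))
            neighbours.sort(key=lambda t: (t[0], t[1]))
            for v, _, cand in neighbours[:3]:
                if v < best_val - 1e-12:
                    best, best_val, improved = cand, v, True
                elif cap - ev.count > 6 * n_r:
                    cand2, v2 = refine_reals(cand, v, 12 * n_r)
                    if v2 < best_val - 1e-12:
                        best, best_val, improved = cand2, v2, True
                if improved:
                    if cap - ev.count > 6 * n_r:
                        best, best_val = refine_reals(best, best_val, 20 * n_r)
                    break
        # perturbation restarts: jitter the reals around the incumbent and
        # re-descend while budget remains — escapes poor local minima of
        # the continuous subproblem that a single descent gets trapped in
        if rng is None:
            rng = np.random.default_rng(0)
        span = (real_bounds[:, 1] - real_bounds[:, 0]) if n_r else np.empty(0)
        while cap - ev.count > max(14 * n_r, 50):
            z = best.reals + 0.15 * span * rng.standard_normal(n_r)
            z = np.clip(z, real_bounds[:, 0], real_bounds[:, 1]) if n_r else z
            cand = DecisionVector(z, best.integers.copy())
            v = lev(cand.reals, cand.integers)
            cand, v = refine_reals(cand, v, 20 * n_r)
            if v < best_val - 1e-12:
                best, best_val = cand, v
    except _BudgetExhausted:
        pass
    if local["x"] is not None and local["v"] < best_val:
        # the local incumbent can beat the last accepted point when a
        # budget interruption cut a descent short
        best, best_val = local["x"].copy(), local["v"]
    return best, best_val


# ---------------------------------------------------------------------------
# Scatter search


def _refset_update(
    refset: list, candidate: tuple[DecisionVector, float], real_bounds, int_bounds,
) -> bool:
    """Quality replacement of the worst member, rejecting near-duplicates."""
    cand_n = _normalized(candidate[0], real_bounds, int_bounds)
    for x, _ in refset:
        if np.linalg.norm(_normalized(x, real_bounds, int_bounds) - cand_n) < 1e-6:
            return False
    worst = max(range(len(refset)), key=lambda i: refset[i][1])
    if candidate[1] < refset[worst][1]:
        refset[worst] = candidate
        return True
    return False


def scatter_search(
    objective: Callable,
    real_bounds: Sequence[Sequence[float]],
    int_bounds: Sequence[Sequence[int]],
    settings: SearchSettings,
) -> RunResult:
    """Minimise a mixed-integer objective within box bounds.

    Deterministic given ``settings.seed``; never evaluates outside the
    bounds; never exceeds ``settings.max_evaluations``; returns the best
    point found together with the non-increasing best-so-far trace.
    """
    real_bounds = np.atleast_2d(np.asarray(real_bounds, dtype=float)) if len(real_bounds) else np.empty((0, 2))
    int_bounds = np.atleast_2d(np.asarray(int_bounds, dtype=np.int64)) if len(int_bounds) else np.empty((0, 2), dtype=np.int64)
    n_r, n_i = real_bounds.shape[0], int_bounds.shape[0]
    rng = np.random.default_rng(settings.seed)
    ev = _Evaluator(objective, settings.max_evaluations)
    b = max(4, settings.refset_size)

    def evaluate_pool(Xr, Xi):
        pool = []
        for k in range(Xr.shape[0]):
            x = DecisionVector(Xr[k], _clip_int(Xi[k], int_bounds))
            pool.append((x, ev(x.reals, x.integers)))
        return pool

    try:
        # -- diversification: space-filling sample of the mixed box,
        # stratified over the binary integer dimensions so that every
        # on/off combination of switches enters the initial pool
        n_div = settings.n_diverse or max(10 * (n_r + n_i), 2 * b)
        Xi = _random_int(rng, n_div, int_bounds)
        binary_dims = [
            j for j in range(n_i) if int_bounds[j, 1] - int_bounds[j, 0] == 1
        ][:4]
        if binary_dims:
            strata = list(product(*[
                range(int_bounds[j, 0], int_bounds[j, 1] + 1) for j in binary_dims
            ]))
            for k in range(n_div):
                for j, v in zip(binary_dims, strata[k % len(strata)]):
                    Xi[k, j] = v
        pool = evaluate_pool(_lhs(rng, n_div, real_bounds), Xi)

        # -- initial reference set: half quality, half max-min diversity
        pool.sort(key=lambda t: t[1])
        refset = pool[: b // 2]
        rest = pool[b // 2:]
        while len(refset) < b and rest:
            chosen = [_normalized(x, real_bounds, int_bounds) for x, _ in refset]
            dists = [
                min(np.linalg.norm(_normalized(x, real_bounds, int_bounds) - c) for c in chosen)
                for x, _ in rest
            ]
            k = int(np.argmax(dists))
            refset.append(rest.pop(k))

        refined_structures: set[tuple] = set()
        refined_points: set[int] = set()

        # -- stratum tournament: every binary on/off combination gets short
        # refinements of its best diversification members, each from its own
        # fresh space-filling reals, so that no switch combination is
        # discarded on unpolished objective values alone and every stratum
        # is optimised with comparable effort before structures compete
        if binary_dims and settings.tournament_restarts > 0:
            short = max(settings.local_budget // 2, 40)
            by_stratum: dict[tuple, list[tuple[float, DecisionVector]]] = {}
            for x, v in pool:
                key = tuple(int(x.integers[j]) for j in binary_dims)
                by_stratum.setdefault(key, []).append((v, x))
            for key in sorted(by_stratum):
                members = sorted(by_stratum[key], key=lambda t: t[0])
                for v, x in members[: settings.tournament_restarts]:
                    xr_, vr = local_refine(
                        objective, x, real_bounds, int_bounds,
                        budget=short, rng=rng, _evaluator=ev,
                    )
                    refined_points.update({id(x), id(xr_)})
                    _refset_update(refset, (xr_, vr), real_bounds, int_bounds)

        iteration = 0
        stagnant = 0
        while ev.count < settings.max_evaluations:
            iteration += 1
            before = ev.best_value
            refset.sort(key=lambda t: t[1])
            # -- path-relinking combinations over all refset pairs
            new_members = False
            for a in range(len(refset)):
                for c in range(a + 1, len(refset)):
                    xa, xc = refset[a][0], refset[c][0]
                    d_r = (xc.reals - xa.reals) / 2.0
                    d_i = (xc.integers - xa.integers) / 2.0
                    for lo, hi in ((-1.0, 0.0), (0.0, 2.0), (2.0, 3.0)):
                        t_r = rng.uniform(lo, hi, size=n_r)
                        t_i = rng.uniform(lo, hi, size=n_i)
                        cr = np.clip(xa.reals + t_r * d_r, real_bounds[:, 0], real_bounds[:, 1]) if n_r else np.empty(0)
                        ci = _clip_int(_round_half_away(xa.integers + t_i * d_i), int_bounds)
                        cand = DecisionVector(cr, ci)
                        val = ev(cand.reals, cand.integers)
                        if _refset_update(refset, (cand, val), real_bounds, int_bounds):
                            new_members = True
            # -- periodic local refinement.  With binary switches present,
            # deep refinement rotates over the champions of the leading
            # binary patterns, so the final verdict compares structures that
            # received comparable optimisation effort; otherwise the best
            # not-yet-refined member is polished.
            if iteration % settings.local_refine_every == 0:
                refset.sort(key=lambda t: t[1])
                pick = None
                if binary_dims:
                    champions: dict[tuple, int] = {}
                    for k in range(len(refset)):
                        key = tuple(int(refset[k][0].integers[j]) for j in binary_dims)
                        if key not in champions:
                            champions[key] = k
                    leading = sorted(champions.values(),
                                     key=lambda k: refset[k][1])[:3]
                    pick = leading[(iteration // settings.local_refine_every - 1)
                                   % len(leading)]
                else:
                    for k in range(len(refset)):
                        if tuple(refset[k][0].integers) not in refined_structures:
                            pick = k
                            break
                    if pick is None:
                        for k in range(len(refset)):
                            if id(refset[k][0]) not in refined_points:
                                pick = k
                                break
                if pick is not None:
                    x, v = local_refine(
                        objective, refset[pick][0], real_bounds, int_bounds,
                        budget=settings.local_budget, rng=rng, _evaluator=ev,
                    )
                    refined_structures.add(tuple(refset[pick][0].integers))
                    refined_structures.add(tuple(x.integers))
                    refined_points.update({id(refset[pick][0]), id(x)})
                    if v < refset[pick][1]:
                        refset[pick] = (x, v)
            # -- stagnation control: refresh the diversity half
            if ev.best_value < before - settings.stagnation_tol or new_members:
                stagnant = 0
            else:
                stagnant += 1
            if stagnant >= settings.stagnation_window:
                refset.sort(key=lambda t: t[1])
                keep = max(b // 2, 1)
                n_new = len(refset) - keep
                if n_new > 0:
                    fresh = evaluate_pool(
                        _lhs(rng, n_new, real_bounds), _random_int(rng, n_new, int_bounds)
                    )
                    refset = refset[:keep] + fresh
                stagnant = 0
    except _BudgetExhausted:
        pass

    best = ev.best if ev.best is not None else DecisionVector(
        real_bounds[:, 0] if n_r else np.empty(0),
        int_bounds[:, 0] if n_i else np.empty(0, dtype=np.int64),
    )
    return RunResult(
        best=best.copy(), best_value=ev.best_value, trace=list(ev.trace),
        n_evaluations=ev.count, seed=settings.seed,
    )


def multistart(
    objective: Callable,
    n_starts: int,
    real_bounds: Sequence[Sequence[float]],
    int_bounds: Sequence[Sequence[int]],
    seed: int,
    local_budget: int = 150,
) -> MultistartResult:
    """Independent local refinements from uniform random feasible starts.

    The classical baseline protocol for probing multi-modality: the spread
    of the returned final values (histogram) reveals the local-optimum
    landscape the local solver alone gets trapped in.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    real_bounds = np.atleast_2d(np.asarray(real_bounds, dtype=float)) if len(real_bounds) else np.empty((0, 2))
    int_bounds = np.atleast_2d(np.asarray(int_bounds, dtype=np.int64)) if len(int_bounds) else np.empty((0, 2), dtype=np.int64)
    rng = np.random.default_rng(seed)
    values = np.empty(n_starts)
    finals = []
    for k in range(n_starts):
        xr = rng.uniform(real_bounds[:, 0], real_bounds[:, 1]) if real_bounds.size else np.empty(0)
        xi = _random_int(rng, 1, int_bounds)[0]
        x, v = local_refine(
            objective, DecisionVector(xr, xi), real_bounds, int_bounds,
            budget=local_budget, rng=rng,
        )
        values[k] = v
        finals.append(x)
    return MultistartResult(values=values, finals=finals, seed=seed)
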