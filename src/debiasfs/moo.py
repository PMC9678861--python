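"""Binary-encoded NSGA-III for three-objective feature selection.

The decision vector is a feature mask m in {0,1}^D. Variation is one-point
crossover plus independent per-bit mutation; environmental selection is
fast non-dominated sorting followed by reference-point niching on a
Das-Dennis simplex lattice. An external elitist archive accumulates every
evaluated individual and retains only the mutually non-dominated set.

All randomness flows from one seeded :class:`numpy.random.Generator`
created from ``MOOConfig.seed``, so a run is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Callable, Sequence

import numpy as np

from .io import FeatureTable
from .objectives import MOOConfig, ObjectiveVector, evaluate_individual


@dataclass
class Individual:
    """A feature mask with its objectives and selection bookkeeping."""

    mask: np.ndarray
    objectives: ObjectiveVector | None = None
    rank: int | None = None
    niche_id: int | None = None

    def obj_array(self) -> np.ndarray:
        if self.objectives is None:
            raise ValueError("individual not evaluated")
        return self.objectives.as_array()

    def copy_mask(self) -> np.ndarray:
        return self.mask.copy()


@dataclass
class Population:
    individuals: list[Individual]
    generation: int = 0
    fitness_calls: int = 0

    def __len__(self) -> int:
        return len(self.individuals)


# ---------------------------------------------------------------------------
# Dominance and sorting
# ---------------------------------------------------------------------------


def dominates(a, b) -> bool:
    """Pareto dominance, all-minimization: a <= b everywhere, < somewhere."""
    av = a.as_array() if isinstance(a, ObjectiveVector) else np.asarray(a, dtype=float)
    bv = b.as_array() if isinstance(b, ObjectiveVector) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("objective vectors differ in length")
    return bool(np.all(av <= bv) and np.any(av < bv))


def fast_nondominated_sort(objectives: np.ndarray) -> list[list[int]]:
    """Partition row indices of an N x M objective matrix into Pareto fronts.

    Front 0 holds the non-dominated rows; front r the rows non-dominated
    once fronts < r are removed. Deb's bookkeeping: O(N^2 M).
    """
    F = np.asarray(objectives, dtype=float)
    n = F.shape[0]
    if n == 0:
        return []
    # pairwise dominance: d[i, j] True iff i dominates j
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    fronts: list[list[int]] = []
    current = np.flatnonzero(n_dominators == 0)
    assigned = np.zeros(n, dtype=bool)
    while current.size:
        fronts.append(current.tolist())
        assigned[current] = True
        n_dominators = n_dominators - dom[current].sum(axis=0)
        current = np.flatnonzero((n_dominators == 0) & ~assigned)
    return fronts


# ---------------------------------------------------------------------------
# Reference points and niching
# ---------------------------------------------------------------------------


def generate_reference_points(M: int = 3, divisions: int = 12) -> np.ndarray:
    """Das-Dennis simplex lattice: all points with coordinates j/p summing to 1.

    Returns a C(p+M-1, M-1) x M matrix; rows sum to 1 exactly up to
    floating round-off.
    """
    if divisions < 1:
        raise ValueError("divisions must be >= 1")

    def rec(m_left: int, total_left: int) -> list[list[int]]:
        if m_left == 1:
            return [[total_left]]
        return [
            [j] + rest
            for j in range(total_left + 1)
            for rest in rec(m_left - 1, total_left - j)
        ]

    pts = np.array(rec(M, divisions), dtype=float) / divisions
    assert pts.shape[0] == comb(divisions + M - 1, M - 1)
    return pts


def normalize_objectives(vectors: np.ndarray, method: str = "range") -> np.ndarray:
    """Shift by the per-component ideal point and scale to [0, 1]-ish.

    ``range``: divide by the per-component range over the set (zero range
    -> divisor 1). ``hyperplane``: canonical NSGA-III intercepts from the
    achievement-scalarizing extreme points, falling back to the range
    divisor when the hyperplane is degenerate.
    """
    F = np.asarray(vectors, dtype=float)
    if F.ndim == 1:
        F = F[None, :]
    if F.shape[0] == 0:
        raise ValueError("need at least one vector")
    ideal = F.min(axis=0)
    shifted = F - ideal
    if method == "range":
        span = shifted.max(axis=0)
        span[span <= 0] = 1.0
        return shifted / span
    if method == "hyperplane":
        M = F.shape[1]
        # extreme point per axis: minimizer of the ASF with axis weights
        w = np.full((M, M), 1e-6)
        np.fill_diagonal(w, 1.0)
        extremes = np.array(
            [shifted[np.argmin(np.max(shifted / w[i], axis=1))] for i in range(M)]
        )
        try:
            intercepts = 1.0 / np.linalg.solve(extremes, np.ones(M))
            if np.any(intercepts <= 1e-12) or not np.all(np.isfinite(intercepts)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            intercepts = shifted.max(axis=0)
            intercepts[intercepts <= 0] = 1.0
        return shifted / intercepts
    raise ValueError(f"unknown normalization {method!r}")


def _perpendicular_distances(normed: np.ndarray, refpoints: np.ndarray) -> np.ndarray:
    """Distance of each normalized point to each reference line through 0."""
    w = refpoints / np.linalg.norm(refpoints, axis=1, keepdims=True)
    proj = normed @ w.T  # scalar projections, shape N x R
    # squared residual = |f|^2 - proj^2
    sq = np.maximum(np.sum(normed**2, axis=1)[:, None] - proj**2, 0.0)
    return np.sqrt(sq)


def associate_and_niche(
    individuals: Sequence[Individual],
    fronts: list[list[int]],
    refpoints: np.ndarray,
    target_size: int,
    rng: np.random.Generator,
    normalization: str = "range",
) -> list[Individual]:
    """NSGA-III environmental selection.

    Whole fronts are admitted in rank order until the next would overflow;
    the splitting front is filled by niching: each candidate associates to
    its nearest reference line (perpendicular distance in normalized
    space), then the emptiest niche picks next -- its closest candidate if
    the niche is empty, else a random associated candidate. Ties between
    equally empty niches break uniformly at random.
    """
    total = sum(len(f) for f in fronts)
    if total < target_size:
        raise ValueError("not enough candidates for environmental selection")
    for r, front in enumerate(fronts):
        for i in front:
            individuals[i].rank = r

    selected_idx: list[int] = []
    splitting: list[int] = []
    for front in fronts:
        if len(selected_idx) + len(front) <= target_size:
            selected_idx.extend(front)
            if len(selected_idx) == target_size:
                break
        else:
            splitting = front
            break
    if len(selected_idx) < target_size:
        considered = selected_idx + splitting
        objs = np.array([individuals[i].obj_array() for i in considered])
        normed = normalize_objectives(objs, method=normalization)
        dists = _perpendicular_distances(normed, refpoints)
        assoc = np.argmin(dists, axis=1)
        mindist = dists[np.arange(len(considered)), assoc]
        for pos, i in enumerate(considered):
            individuals[i].niche_id = int(assoc[pos])

        n_admitted = len(selected_idx)
        niche_counts = np.zeros(len(refpoints), dtype=int)
        for pos in range(n_admitted):
            niche_counts[assoc[pos]] += 1
        # remaining candidates per niche, as positions into `considered`
        remaining: dict[int, list[int]] = {}
        for pos in range(n_admitted, len(considered)):
            remaining.setdefault(int(assoc[pos]), []).append(pos)

        while len(selected_idx) < target_size:
            live = np.array(sorted(remaining.keys()))
            counts = niche_counts[live]
            candidates_j = live[counts == counts.min()]
            j = int(candidates_j[rng.integers(len(candidates_j))]) \
                if len(candidates_j) > 1 else int(candidates_j[0])
            members = remaining[j]
            if niche_counts[j] == 0:
                pick = min(members, key=lambda p: (mindist[p], p))
            else:
                pick = members[int(rng.integers(len(members)))]
            members.remove(pick)
            if not members:
                del remaining[j]
            niche_counts[j] += 1
            selected_idx.append(considered[pick])
    return [individuals[i] for i in selected_idx]


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------


def one_point_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap the tails of two masks after a uniform cut point in {1,..,D-1}."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("parent masks differ in length")
    D = a.size
    if D < 2:
        raise ValueError("crossover needs D >= 2")
    c = int(rng.integers(1, D))
    return (
        np.concatenate([a[:c], b[c:]]),
        np.concatenate([b[:c], a[c:]]),
    )


def bitwise_mutation(mask: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    mask = np.asarray(mask)
    flips = rng.random(mask.size) < rate
    return np.where(flips, 1 - mask, mask).astype(mask.dtype)


def repair_empty_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Set one uniformly random bit if the mask is all-zero; else unchanged."""
    mask = np.asarray(mask)
    if mask.any():
        return mask
    repaired = mask.copy()
    repaired[int(rng.integers(mask.size))] = 1
    return repaired


def initialize_population(
    config: MOOConfig, D: int, rng: np.random.Generator
) -> list[Individual]:
    """Random binary masks, each bit 1 with probability ``init_density``."""
    out = []
    for _ in range(config.population_size):
        mask = (rng.random(D) < config.init_density).astype(np.uint8)
        out.append(Individual(repair_empty_mask(mask, rng)))
    return out


# ---------------------------------------------------------------------------
# Archive and main loop
# ---------------------------------------------------------------------------


class ParetoArchive:
    """Elitist archive: the non-dominated set of everything evaluated."""

    def __init__(self) -> None:
        self.members: list[Individual] = []

    def add(self, ind: Individual) -> bool:
        v = ind.obj_array()
        keep: list[Individual] = []
        for m in self.members:
            mv = m.obj_array()
            if dominates(mv, v) or (
                np.array_equal(mv, v) and np.array_equal(m.mask, ind.mask)
            ):
                return False
            if not dominates(v, mv):
                keep.append(m)
        keep.append(Individual(ind.copy_mask(), ind.objectives))
        self.members = keep
        return True

    def __len__(self) -> int:
        return len(self.members)


def _binary_tournament(
    pop: list[Individual], rng: np.random.Generator
) -> Individual:
    i, j = rng.integers(len(pop)), rng.integers(len(pop))
    a, b = pop[int(i)], pop[int(j)]
    if a.rank is None or b.rank is None:
        raise ValueError("tournament requires ranked individuals")
    if a.rank < b.rank:
        return a
    if b.rank < a.rank:
        return b
    return a if rng.random() < 0.5 else b


def run_nsga3(
    table: FeatureTable,
    config: MOOConfig,
    callback: Callable[[int, list[Individual], ParetoArchive], None] | None = None,
) -> tuple[Population, ParetoArchive, list[dict]]:
    """Run the evolutionary feature selection until the fitness budget is spent.

    Returns the final population, the elitist archive (the non-dominated
    set over every evaluated mask) and a per-generation history log.
    Duplicate masks are served from an evaluation cache; cache hits still
    count against the budget, matching the fitness-call accounting.
    """
    if len(table.split_indices(config.reference_split)) == 0 or \
       len(table.split_indices(config.query_split)) == 0:
        raise ValueError("table must carry non-empty reference and query splits")
    D = table.n_features
    rng = np.random.default_rng(config.seed)
    mutation_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / D
    refpoints = generate_reference_points(3, config.reference_divisions)

    cache: dict[bytes, ObjectiveVector] = {}
    calls = 0

    def evaluate(ind: Individual) -> None:
        nonlocal calls
        calls += 1
        key = np.ascontiguousarray(ind.mask).tobytes()
        if key not in cache:
            cache[key] = evaluate_individual(ind.mask, table, config)
        ind.objectives = cache[key]

    pop = initialize_population(config, D, rng)
    for ind in pop:
        evaluate(ind)
    fronts = fast_nondominated_sort(np.array([i.obj_array() for i in pop]))
    for r, front in enumerate(fronts):
        for i in front:
            pop[i].rank = r
    archive = ParetoArchive()
    for ind in pop:
        archive.add(ind)

    history: list[dict] = []

    def log(gen: int) -> None:
        objs = np.array([i.obj_array() for i in pop])
        best = objs.min(axis=0)
        med = np.median(objs, axis=0)
        history.append(
            {
                "generation": gen,
                "fitness_calls": calls,
                "front_size": sum(1 for i in pop if i.rank == 0),
                "archive_size": len(archive),
                "best_f1_loss": float(best[0]),
                "best_f2_ratio": float(best[1]),
                "best_f3_site_acc": float(best[2]),
                "median_f1_loss": float(med[0]),
                "median_f2_ratio": float(med[1]),
                "median_f3_site_acc": float(med[2]),
            }
        )

    gen = 0
    log(gen)
    if callback is not None:
        callback(gen, pop, archive)

    while calls + config.population_size <= config.fitness_budget:
        gen += 1
        offspring: list[Individual] = []
        while len(offspring) < config.population_size:
            p1 = _binary_tournament(pop, rng)
            p2 = _binary_tournament(pop, rng)
            if rng.random() < config.crossover_probability:
                c1, c2 = one_point_crossover(p1.mask, p2.mask, rng)
            else:
                c1, c2 = p1.copy_mask(), p2.copy_mask()
            for child in (c1, c2):
                child = bitwise_mutation(child, mutation_rate, rng)
                child = repair_empty_mask(child, rng)
                offspring.append(Individual(child.astype(np.uint8)))
        offspring = offspring[: config.population_size]
        for ind in offspring:
            evaluate(ind)
            archive.add(ind)
        combined = list(pop) + offspring
        fronts = fast_nondominated_sort(np.array([i.obj_array() for i in combined]))
        pop = associate_and_niche(
            combined, fronts, refpoints, config.population_size, rng,
            normalization=config.normalization,
        )
        log(gen)
        if callback is not None:
            callback(gen, pop, archive)

    return Population(pop, generation=gen, fitness_calls=calls), archive, history
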