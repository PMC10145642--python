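"""Multiobjective particle-swarm engine for multilevel threshold search.

A swarm of particles explores the intensity range [0, 255]; each particle's
position is a (real-valued) threshold vector, evaluated on the image
histogram against up to three criteria (Otsu variance, Kapur entropy,
Renyi entropy).  Pareto non-dominated solutions accumulate in a bounded
external archive whose occupied objective-space bounding box is cut into an
adaptive hypercube grid; swarm leaders are drawn from the archive by a
roulette wheel biased toward sparsely populated hypercubes, which maintains
diversity along the front.  A non-uniform mutation operator with a
decreasing schedule keeps early iterations exploratory.

After the final iteration the single "best" compromise is extracted as the
archive member with the largest Euclidean distance of its fitness vector
from the objective-space origin, and its position — rounded, sorted — is
the threshold vector used to carve the image into segmentation maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DegenerateImageError, InvalidInputError
from .objectives import OBJECTIVE_NAMES, ObjectiveTables, histogram

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "ParetoArchive",
    "dominates",
    "initialize_swarm",
    "update_archive",
    "select_leader",
    "update_particle",
    "mutation_probability",
    "mutate",
    "best_particle",
    "run_mmpso",
    "apply_thresholds",
]


@dataclass
class SwarmConfig:
    """Swarm and archive parameters.

    Defaults are the tuned operating point: 150 particles, 150 iterations,
    k = 2 thresholds, inertia 1.3, acceleration c1 = c2 = 0.5, mutation
    rate 0.1, archive capacity 30, grid size 7 divisions per objective.
    """

    n_particles: int = 150
    n_iterations: int = 150
    n_thresholds: int = 2
    inertia: float = 1.3
    c1: float = 0.5
    c2: float = 0.5
    mutation_rate: float = 0.1
    archive_max: int = 30
    grid_size: int = 7
    grid_fitness_numerator: float = 10.0
    alpha: float = 2.0
    objectives: tuple[str, ...] = OBJECTIVE_NAMES
    x_bounds: tuple[float, float] = (0.0, 255.0)
    v_bounds: tuple[float, float] = (-5.0, 5.0)
    seed: int = 0

    def validate(self) -> "SwarmConfig":
        if self.n_particles < 1:
            raise ConfigError(f"n_particles must be >= 1, got {self.n_particles}")
        if self.n_iterations < 1:
            raise ConfigError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if self.n_thresholds < 1:
            raise ConfigError(f"n_thresholds must be >= 1, got {self.n_thresholds}")
        if self.archive_max < 1:
            raise ConfigError(f"archive_max must be >= 1, got {self.archive_max}")
        if self.grid_size < 2:
            raise ConfigError(f"grid_size must be >= 2, got {self.grid_size}")
        if self.grid_fitness_numerator <= 1:
            raise ConfigError(
                f"grid_fitness_numerator must be > 1, got {self.grid_fitness_numerator}"
            )
        if not 0 < self.mutation_rate <= 1:
            raise ConfigError(f"mutation_rate must be in (0, 1], got {self.mutation_rate}")
        bad = [o for o in self.objectives if o not in OBJECTIVE_NAMES]
        if bad or not self.objectives:
            raise ConfigError(f"objectives must be a non-empty subset of {OBJECTIVE_NAMES}")
        return self


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance in the maximization sense.

    ``a`` dominates ``b`` iff a >= b component-wise and a > b in at least
    one component.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return bool(np.all(a >= b) and np.any(a > b))


def _non_dominated_mask(F: np.ndarray) -> np.ndarray:
    """Boolean mask of the mutually non-dominated rows of ``F`` (N, m)."""
    ge = np.all(F[:, None, :] >= F[None, :, :], axis=2)
    gt = np.any(F[:, None, :] > F[None, :, :], axis=2)
    dominated = np.any(ge & gt, axis=0)  # dominated[j]: some i dominates j
    return ~dominated


class ParetoArchive:
    """Bounded archive of mutually non-dominated (position, fitness) pairs.

    An adaptive grid partitions the occupied fitness bounding box into
    ``grid_size`` divisions per objective.  Hypercube occupancy drives both
    leader selection (roulette with weight ``x / occupancy``) and eviction
    when the archive is full (a member of the most crowded cube is
    removed).  The grid is rebuilt whenever membership changes.
    """

    def __init__(self, capacity: int, grid_size: int, grid_fitness_numerator: float = 10.0):
        self.capacity = int(capacity)
        self.grid_size = int(grid_size)
        self.x = float(grid_fitness_numerator)
        self.positions: list[np.ndarray] = []
        self.fitnesses: list[np.ndarray] = []
        self._cubes: np.ndarray | None = None  # (n, m) integer cube coords

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def fitness_array(self) -> np.ndarray:
        return np.array(self.fitnesses) if self.fitnesses else np.empty((0, 0))

    def _rebuild_grid(self) -> None:
        if not self.fitnesses:
            self._cubes = None
            return
        F = np.array(self.fitnesses)
        lo, hi = F.min(axis=0), F.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        cubes = np.floor((F - lo) / span * self.grid_size).astype(np.int64)
        self._cubes = np.clip(cubes, 0, self.grid_size - 1)

    def _occupancy(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique occupied cubes and the member count of each."""
        assert self._cubes is not None
        cubes, inverse, counts = np.unique(
            self._cubes, axis=0, return_inverse=True, return_counts=True
        )
        return np.asarray(inverse).ravel(), counts

    def add(self, position: np.ndarray, fitness: np.ndarray) -> bool:
        """Offer a candidate to the archive; returns True if it entered.

        Rules: an empty archive accepts; a candidate dominated by any
        member is discarded; otherwise the candidate enters, evicting any
        members it dominates, and if the archive is full a member of the
        most crowded hypercube is removed first to make room.
        """
        position = np.array(position, dtype=np.float64)
        fitness = np.array(fitness, dtype=np.float64)
        if not self.positions:
            self.positions.append(position)
            self.fitnesses.append(fitness)
            self._rebuild_grid()
            return True
        F = np.array(self.fitnesses)
        if np.any(np.all(F >= fitness, axis=1) & np.any(F > fitness, axis=1)):
            return False
        # evict members the candidate dominates
        evict = np.all(fitness >= F, axis=1) & np.any(fitness > F, axis=1)
        if np.any(evict):
            keep = ~evict
            self.positions = [p for p, k in zip(self.positions, keep) if k]
            self.fitnesses = [f for f, k in zip(self.fitnesses, keep) if k]
            self._rebuild_grid()
        if len(self.positions) >= self.capacity:
            inverse, counts = self._occupancy()
            crowded = int(np.argmax(counts))
            victims = np.nonzero(inverse == crowded)[0]
            victim = int(victims[-1])  # deterministic: newest member of the cube
            del self.positions[victim]
            del self.fitnesses[victim]
        self.positions.append(position)
        self.fitnesses.append(fitness)
        self._rebuild_grid()
        return True

    def select_leader(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Roulette-wheel leader: cube weight ``x / occupancy``, then a
        uniformly random member of the drawn cube."""
        idx = self.select_leader_indices(1, rng)[0]
        return self.positions[idx], self.fitnesses[idx]

    def select_leader_indices(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if not self.positions:
            raise InvalidInputError("cannot select a leader from an empty archive")
        inverse, counts = self._occupancy()
        weights = self.x / counts
        probs = weights / weights.sum()
        cubes = rng.choice(len(counts), size=n, p=probs)
        members_per_cube = [np.nonzero(inverse == c)[0] for c in range(len(counts))]
        out = np.empty(n, dtype=np.int64)
        for i, c in enumerate(cubes):
            members = members_per_cube[c]
            out[i] = members[0] if len(members) == 1 else rng.choice(members)
        return out


def update_archive(archive: ParetoArchive, position, fitness) -> ParetoArchive:
    """Functional wrapper over :meth:`ParetoArchive.add` (mutates in place)."""
    archive.add(position, fitness)
    return archive


def select_leader(archive: ParetoArchive, rng: np.random.Generator):
    return archive.select_leader(rng)


@dataclass
class SwarmState:
    """Mutable swarm state: positions, velocities, fitnesses, personal bests."""

    X: np.ndarray  # (N, k) real positions, sorted ascending per row
    V: np.ndarray  # (N, k) velocities
    F: np.ndarray  # (N, m) fitnesses
    pbest_X: np.ndarray
    pbest_F: np.ndarray
    archive: ParetoArchive
    tables: ObjectiveTables = field(repr=False, default=None)


def _eval_positions(X: np.ndarray, tables: ObjectiveTables, which) -> np.ndarray:
    """Fitness of real-valued positions: round to integer thresholds in
    [1, 255], sort, evaluate.  Duplicate thresholds yield empty regions,
    which score 0 — the search space stays total."""
    tv = np.sort(np.clip(np.rint(X), 1, 255).astype(np.int64), axis=1)
    return tables.evaluate_batch(tv, which=which)


def initialize_swarm(
    cfg: SwarmConfig, counts: np.ndarray, rng: np.random.Generator | None = None
) -> SwarmState:
    """Random uniform positions in [Xmin, Xmax], zero velocities, personal
    bests at the initial positions, archive seeded with the swarm's
    non-dominated set."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    tables = ObjectiveTables(counts, alpha=cfg.alpha)
    lo, hi = cfg.x_bounds
    X = np.sort(rng.uniform(lo, hi, size=(cfg.n_particles, cfg.n_thresholds)), axis=1)
    V = np.zeros_like(X)
    F = _eval_positions(X, tables, cfg.objectives)
    archive = ParetoArchive(cfg.archive_max, cfg.grid_size, cfg.grid_fitness_numerator)
    for i in np.nonzero(_non_dominated_mask(F))[0]:
        archive.add(X[i], F[i])
    return SwarmState(X=X, V=V, F=F, pbest_X=X.copy(), pbest_F=F.copy(), archive=archive, tables=tables)


def update_particle(
    X: np.ndarray,
    V: np.ndarray,
    pbest: np.ndarray,
    leader: np.ndarray,
    cfg: SwarmConfig,
    r1: float,
    r2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One velocity/position step for a single particle.

    ``V' = w V + c1 r1 (pbest - X) + c2 r2 (leader - X)``, clamped to the
    velocity bounds; ``X' = X + V'`` clamped to the position bounds with
    components sorted ascending so the pair remains a valid threshold
    vector.
    """
    vlo, vhi = cfg.v_bounds
    xlo, xhi = cfg.x_bounds
    Vn = np.clip(
        cfg.inertia * V + cfg.c1 * r1 * (pbest - X) + cfg.c2 * r2 * (leader - X), vlo, vhi
    )
    Xn = np.sort(np.clip(X + Vn, xlo, xhi))
    return Xn, Vn


def mutation_probability(t: int, cfg: SwarmConfig) -> float:
    """Non-uniform mutation schedule ``pm(t) = (1 - (t-1)/(Nite-1))^(5/mu)``.

    Equals 1 at the first iteration (every particle eligible) and decays
    monotonically to 0 at the last.
    """
    if cfg.n_iterations == 1:
        return 0.0
    base = 1.0 - (t - 1) / (cfg.n_iterations - 1)
    return float(max(0.0, base) ** (5.0 / cfg.mutation_rate))


def mutate(state: SwarmState, t: int, cfg: SwarmConfig, rng: np.random.Generator) -> SwarmState:
    """Mutate each particle with probability ``pm(t)``: one randomly chosen
    position component is redrawn uniformly inside a window whose width
    shrinks with ``pm(t)``, then fitness and personal bests refresh."""
    pm = mutation_probability(t, cfg)
    n = state.X.shape[0]
    hit = rng.random(n) < pm
    if not np.any(hit):
        return state
    xlo, xhi = cfg.x_bounds
    half = pm * (xhi - xlo) / 2.0
    idx = np.nonzero(hit)[0]
    dims = rng.integers(0, state.X.shape[1], size=len(idx))
    for i, d in zip(idx, dims):
        lo = max(xlo, state.X[i, d] - half)
        hi = min(xhi, state.X[i, d] + half)
        state.X[i, d] = rng.uniform(lo, hi)
        state.X[i] = np.sort(state.X[i])
    newF = _eval_positions(state.X[idx], state.tables, cfg.objectives)
    state.F[idx] = newF
    _update_pbest(state, idx, rng)
    return state


def _update_pbest(state: SwarmState, rows: np.ndarray, rng: np.random.Generator) -> None:
    """Dominance-based personal-best update; mutual non-dominance breaks
    ties with a fair coin."""
    F, pF = state.F[rows], state.pbest_F[rows]
    new_dom = np.all(F >= pF, axis=1) & np.any(F > pF, axis=1)
    old_dom = np.all(pF >= F, axis=1) & np.any(pF > F, axis=1)
    tie = ~new_dom & ~old_dom
    coin = rng.random(len(rows)) < 0.5
    take = new_dom | (tie & coin)
    sel = rows[take]
    state.pbest_X[sel] = state.X[sel]
    state.pbest_F[sel] = state.F[sel]


def best_particle(archive: ParetoArchive) -> tuple[np.ndarray, np.ndarray]:
    """Archive member maximizing the Euclidean distance of its fitness
    vector from the objective-space origin, ``d(O, i) = ||f_i||``; ties
    broken by first index."""
    if not len(archive):
        raise InvalidInputError("archive is empty; cannot extract a best particle")
    d = np.linalg.norm(archive.fitness_array, axis=1)
    i = int(np.argmax(d))
    return archive.positions[i], archive.fitnesses[i]


def run_mmpso(
    ipre: np.ndarray,
    cfg: SwarmConfig | None = None,
    rng: np.random.Generator | None = None,
    history: list | None = None,
) -> tuple[int, ...]:
    """Full threshold search on a pre-processed grayscale image.

    Returns the k thresholds of the best archive member, rounded to
    integers and strictly increasing.  ``history``, if given, collects the
    archive fitness array after every iteration (for instrumented runs).

    Raises
    ------
    DegenerateImageError
        If the image holds a single intensity level.
    """
    cfg = (cfg or SwarmConfig()).validate()
    counts = histogram(ipre)
    if np.count_nonzero(counts) < 2:
        raise DegenerateImageError("image has a single intensity level; thresholding is undefined")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    state = initialize_swarm(cfg, counts, rng)
    n, k = state.X.shape
    vlo, vhi = cfg.v_bounds
    xlo, xhi = cfg.x_bounds
    t = 1
    while t < cfg.n_iterations:
        leaders = state.archive.select_leader_indices(n, rng)
        leader_X = np.array([state.archive.positions[i] for i in leaders])
        r1 = rng.random((n, 1))
        r2 = rng.random((n, 1))
        state.V = np.clip(
            cfg.inertia * state.V
            + cfg.c1 * r1 * (state.pbest_X - state.X)
            + cfg.c2 * r2 * (leader_X - state.X),
            vlo,
            vhi,
        )
        state.X = np.sort(np.clip(state.X + state.V, xlo, xhi), axis=1)
        state.F = _eval_positions(state.X, state.tables, cfg.objectives)
        _update_pbest(state, np.arange(n), rng)
        for i in np.nonzero(_non_dominated_mask(state.F))[0]:
            state.archive.add(state.X[i], state.F[i])
        mutate(state, t, cfg, rng)
        if history is not None:
            history.append(state.archive.fitness_array.copy())
        t += 1
    pos, _ = best_particle(state.archive)
    return _extract_thresholds(pos, counts)


def _canonicalize(tv: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Centre each threshold within its objective-equivalence plateau.

    Moving a threshold across a zero-count intensity level changes no
    region mass and hence no objective value, so every threshold inside a
    run of empty bins is equally optimal.  The classical tie-break —
    placing the threshold at the centre of the run (the histogram valley)
    — is applied here, which also makes the extracted thresholds
    well-defined instead of an arbitrary point of the plateau.
    """
    counts = np.asarray(counts)
    out = tv.copy()
    for i, t in enumerate(tv):
        lo = t
        while lo > 1 and counts[lo - 1] == 0:
            lo -= 1
        hi = t
        while hi < 255 and counts[hi] == 0:
            hi += 1
        out[i] = int(round((lo + hi) / 2))
    return out


def _extract_thresholds(position: np.ndarray, counts: np.ndarray | None = None) -> tuple[int, ...]:
    """Round a real position to a strictly increasing integer threshold
    vector in [1, 255], centring each threshold on its zero-mass plateau
    and nudging duplicates apart."""
    tv = np.sort(np.clip(np.rint(position), 1, 255).astype(int))
    if counts is not None:
        tv = np.sort(_canonicalize(tv, counts))
    for i in range(1, len(tv)):
        if tv[i] <= tv[i - 1]:
            tv[i] = tv[i - 1] + 1
    tv = np.minimum(tv, 255)
    for i in range(len(tv) - 2, -1, -1):
        if tv[i] >= tv[i + 1]:
            tv[i] = tv[i + 1] - 1
    return tuple(int(v) for v in tv)


def apply_thresholds(ipre: np.ndarray, t1: int, t2: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Carve the image into three binary maps: I1 = [0, t1-1],
    I2 = [t1, t2-1], I3 = [t2, 255].  The maps partition the pixels; I1
    holds the dark regions of interest."""
    ipre = np.asarray(ipre)
    if not 0 < t1 < t2 <= 255:
        raise InvalidInputError(f"thresholds must satisfy 0 < t1 < t2 <= 255, got ({t1}, {t2})")
    i1 = ipre < t1
    i2 = (ipre >= t1) & (ipre < t2)
    i3 = ipre >= t2
    return i1, i2, i3
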