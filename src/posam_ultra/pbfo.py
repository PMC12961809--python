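"""Polar-Bear Foraging Optimization over a mixed hyperparameter space.

A population of ``m`` candidate vectors evolves for up to ``T_max``
iterations.  Each candidate either takes an *exploitation* (hunting) step —
a contraction toward the best candidate by a factor ``gamma_t`` — or joins
the *exploration* (roaming) update

    H_i <- H_i + alpha_t * R1 . (H_best - H_i) + beta_t * R2 . (H_j - H_k)

with per-coordinate ``R1, R2 ~ U(0, 1)`` and distinct random partners
``j != k != i``.  The exploit/explore choice is Bernoulli with probability
``t / T_max``, and ``alpha/beta/gamma`` are linearly interpolated between
their schedule endpoints, so early iterations roam widely and later ones
contract onto the best solution.  Moves are accepted greedily — a candidate
keeps its previous position when the proposed move scores worse — which
preserves population diversity and prevents the contraction phase from
collapsing the swarm before it has localized the optimum.  Latent
coordinates are clamped to their bounds after every update; the best-ever
candidate and its fitness trace are returned.

Mixed dimensions live in a continuous latent space: log-scaled dimensions
are optimized in log10 units, discrete value sets snap to the nearest listed
value on decoding, and categorical dimensions round a [0, K) latent to an
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dimension",
    "SearchSpace",
    "Candidate",
    "PBFOConfig",
    "default_search_space",
    "sphere_space",
    "init_population",
    "decode_candidate",
    "evaluate_fitness",
    "exploration_step",
    "exploitation_step",
    "schedule",
    "check_termination",
    "run_pbfo",
]


@dataclass
class Dimension:
    name: str
    kind: str = "continuous"            # continuous | discrete | categorical
    bounds: tuple[float, float] | None = None
    values: tuple | None = None
    scale: str = "linear"               # linear | log

    def __post_init__(self):
        if self.kind == "continuous":
            lo, hi = self.bounds
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{self.name}: bounds must be finite with lo < hi")
            if self.scale == "log" and lo <= 0:
                raise ValueError(f"{self.name}: log scale requires positive bounds")
        elif self.kind in ("discrete", "categorical"):
            if not self.values:
                raise ValueError(f"{self.name}: value list must be nonempty")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def latent_bounds(self) -> tuple[float, float]:
        if self.kind == "continuous":
            lo, hi = self.bounds
            return (np.log10(lo), np.log10(hi)) if self.scale == "log" else (lo, hi)
        if self.kind == "discrete":
            return float(min(self.values)), float(max(self.values))
        return 0.0, float(len(self.values)) - 1e-9

    def decode(self, latent: float):
        lo, hi = self.latent_bounds()
        latent = float(np.clip(latent, lo, hi))
        if self.kind == "continuous":
            return 10.0**latent if self.scale == "log" else latent
        if self.kind == "discrete":
            arr = np.asarray(self.values, dtype=np.float64)
            val = arr[np.argmin(np.abs(arr - latent))]
            return type(self.values[0])(val)
        return self.values[int(np.clip(round(latent), 0, len(self.values) - 1))]


@dataclass
class SearchSpace:
    dims: list[Dimension]

    @property
    def n(self) -> int:
        return len(self.dims)

    def latent_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        pairs = [d.latent_bounds() for d in self.dims]
        return np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])

    def decode(self, latent: np.ndarray) -> dict:
        return {d.name: d.decode(v) for d, v in zip(self.dims, latent)}

    def clamp(self, latent: np.ndarray) -> np.ndarray:
        lo, hi = self.latent_bounds()
        return np.clip(latent, lo, hi)


@dataclass
class Candidate:
    latent: np.ndarray
    fitness: float | None = None


@dataclass
class PBFOConfig:
    m: int = 20
    t_max: int = 50
    eps: float = 0.0
    alpha: tuple[float, float] = (1.0, 0.2)
    beta: tuple[float, float] = (0.8, 0.1)
    gamma: tuple[float, float] = (0.1, 0.9)
    grace: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.m < 4:
            raise ValueError("population size m must be >= 4")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        for pair in (self.alpha, self.beta, self.gamma):
            if not all(0.0 <= v <= 2.0 for v in pair):
                raise ValueError("schedule endpoints must lie in [0, 2]")


def default_search_space() -> SearchSpace:
    """The full tuning domain: learning rate and weight decay on a log scale,
    discrete batch sizes / filter counts / decay steps, categorical optimizer,
    and continuous dropout, momentum and loss weights."""
    return SearchSpace([
        Dimension("learning_rate", "continuous", bounds=(1e-5, 1e-2), scale="log"),
        Dimension("batch_size", "discrete", values=(8, 16, 32, 64)),
        Dimension("weight_decay", "continuous", bounds=(1e-6, 1e-2), scale="log"),
        Dimension("dropout", "continuous", bounds=(0.1, 0.5)),
        Dimension("base_filters", "discrete", values=(32, 64, 128, 256)),
        Dimension("optimizer_name", "categorical", values=("adam", "sgd", "rmsprop")),
        Dimension("w_bce", "continuous", bounds=(0.1, 0.9)),
        Dimension("w_dice", "continuous", bounds=(0.1, 0.9)),
        Dimension("w_focal", "continuous", bounds=(0.1, 0.9)),
        Dimension("lr_decay_step", "discrete", values=(5, 10, 20)),
        Dimension("momentum", "continuous", bounds=(0.8, 0.99)),
    ])


def sphere_space(n_dims: int = 5, bound: float = 5.0) -> SearchSpace:
    """Continuous benchmark domain for the analytic surrogate objectives."""
    return SearchSpace([
        Dimension(f"x{i}", "continuous", bounds=(-bound, bound)) for i in range(n_dims)
    ])


# -- operators -------------------------------------------------------------

def init_population(space: SearchSpace, cfg: PBFOConfig) -> list[Candidate]:
    rng = np.random.default_rng(cfg.seed)
    lo, hi = space.latent_bounds()
    return [Candidate(rng.uniform(lo, hi)) for _ in range(cfg.m)]


def decode_candidate(latent: np.ndarray, space: SearchSpace) -> dict:
    return space.decode(np.asarray(latent, dtype=np.float64))


def evaluate_fitness(candidate: Candidate, fitness_fn, space: SearchSpace) -> float:
    """Decode and score a candidate; a non-finite objective records fitness 0
    (the "diverged training run" convention) instead of raising."""
    value = fitness_fn(space.decode(candidate.latent))
    value = float(value)
    if not np.isfinite(value):
        value = 0.0
    candidate.fitness = value
    return value


def exploration_step(latents: np.ndarray, best: np.ndarray, alpha: float,
                     beta: float, rng: np.random.Generator, space: SearchSpace,
                     r1: np.ndarray | None = None, r2: np.ndarray | None = None
                     ) -> np.ndarray:
    """Roaming update for every row of ``latents``; partners j != k != i."""
    m, n = latents.shape
    if m < 3:
        raise ValueError("exploration needs a population of at least 3")
    r1 = rng.uniform(size=(m, n)) if r1 is None else np.broadcast_to(r1, (m, n))
    r2 = rng.uniform(size=(m, n)) if r2 is None else np.broadcast_to(r2, (m, n))
    out = np.empty_like(latents)
    for i in range(m):
        j, k = _distinct_partners(i, m, rng)
        out[i] = (latents[i]
                  + alpha * r1[i] * (best - latents[i])
                  + beta * r2[i] * (latents[j] - latents[k]))
    return space.clamp(out)


def _distinct_partners(i: int, m: int, rng: np.random.Generator) -> tuple[int, int]:
    choices = [x for x in range(m) if x != i]
    j, k = rng.choice(choices, size=2, replace=False)
    return int(j), int(k)


def exploitation_step(latent: np.ndarray, best: np.ndarray, gamma: float,
                      space: SearchSpace) -> np.ndarray:
    """Hunting update: contract toward the best candidate."""
    return space.clamp(latent + gamma * (best - latent))


def schedule(t: int, t_max: int, cfg: PBFOConfig) -> tuple[float, float, float, float]:
    """Linear interpolation of (alpha, beta, gamma) plus the exploit
    probability ``t / t_max``."""
    if not 0 <= t <= t_max:
        raise ValueError("t must lie in [0, t_max]")
    frac = t / t_max
    lerp = lambda pair: pair[0] + frac * (pair[1] - pair[0])
    return lerp(cfg.alpha), lerp(cfg.beta), lerp(cfg.gamma), frac


def check_termination(fitness_history: list[float], t: int, cfg: PBFOConfig) -> bool:
    """Stop at ``t_max`` or once the best-fitness improvement drops below
    ``eps`` after a grace period."""
    if not fitness_history:
        raise ValueError("fitness history must be nonempty")
    if t >= cfg.t_max:
        return True
    if cfg.eps > 0 and t > cfg.grace and len(fitness_history) >= 2:
        return abs(fitness_history[-1] - fitness_history[-2]) < cfg.eps
    return False


def run_pbfo(space: SearchSpace, fitness_fn, cfg: PBFOConfig
             ) -> tuple[Candidate, dict]:
    """Run the optimizer; returns the best candidate ever evaluated and a
    history dict with per-iteration best and population-mean fitness."""
    rng = np.random.default_rng((cfg.seed + 1) % (2**31))
    population = init_population(space, cfg)
    for c in population:
        evaluate_fitness(c, fitness_fn, space)
    best = max(population, key=lambda c: c.fitness)
    best = Candidate(best.latent.copy(), best.fitness)
    history = {"iteration": [0], "best_fitness": [best.fitness],
               "mean_fitness": [float(np.mean([c.fitness for c in population]))]}

    for t in range(1, cfg.t_max + 1):
        alpha, beta, gamma, p_exploit = schedule(t, cfg.t_max, cfg)
        latents = np.array([c.latent for c in population])
        exploit_mask = rng.uniform(size=cfg.m) < p_exploit
        explored = exploration_step(latents, best.latent, alpha, beta, rng, space)
        for i, c in enumerate(population):
            proposal = exploitation_step(latents[i], best.latent, gamma, space) \
                if exploit_mask[i] else explored[i]
            previous_fitness = c.fitness
            c.latent = proposal
            new_fitness = evaluate_fitness(c, fitness_fn, space)
            if new_fitness < previous_fitness:    # greedy acceptance
                c.latent = latents[i]
                c.fitness = previous_fitness
            if c.fitness > best.fitness:
                best = Candidate(c.latent.copy(), c.fitness)
        history["iteration"].append(t)
        history["best_fitness"].append(best.fitness)
        history["mean_fitness"].append(float(np.mean([c.fitness for c in population])))
        if check_termination(history["best_fitness"], t, cfg):
            break
    return best, history
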