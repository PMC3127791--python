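"""ABC rejection and ABC SMC with vector tolerances.

Likelihood-free inference for the ten Psp rate constants: a candidate
parameter vector is simulated once, reduced to the five endpoint
summaries, and accepted when every component of the distance vector is
within the current tolerance row.  Populations of N weighted particles
are propagated through a fixed, component-wise decreasing tolerance
schedule; proposals for population t > 1 are drawn from the previous
population and perturbed with a component-wise uniform kernel whose
half-width adapts to half the parameter range spanned by the previous
population.  Importance weights use the standard prior-over-kernel-
mixture correction, so the final weighted population approximates the
posterior under the final tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Prior",
    "ToleranceSchedule",
    "Particle",
    "Population",
    "AcceptanceFloorError",
    "default_prior",
    "default_tolerances",
    "sample_prior",
    "kernel_scales",
    "perturb",
    "kernel_density",
    "particle_weight",
    "accept",
    "abc_rejection",
    "abc_smc",
    "write_populations_csv",
    "read_population_csv",
]

PARAM_NAMES = tuple(f"k{i}" for i in range(1, 11))
DISTANCE_NAMES = tuple(f"d{i}" for i in range(1, 6))


@dataclass(frozen=True)
class Prior:
    """Independent uniform priors, one (lower, upper) pair per parameter."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape:
            raise ValueError("lower/upper shape mismatch")
        if np.any(lo < 0) or np.any(hi <= lo):
            raise ValueError("need 0 <= lower < upper component-wise")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def density(self, theta: np.ndarray) -> float:
        if not self.contains(np.asarray(theta, dtype=float)):
            return 0.0
        return float(1.0 / np.prod(self.width))


def default_prior() -> Prior:
    """The uniform prior box used for the deterministic-framework fit:
    k1,k3,k4,k8,k9 ~ U(0,1); k2 ~ U(0,100); k5 ~ U(0,0.05);
    k6,k7 ~ U(0,0.01); k10 ~ U(0,5)."""
    upper = np.array([1.0, 100.0, 1.0, 1.0, 0.05, 0.01, 0.01, 1.0, 1.0, 5.0])
    return Prior(np.zeros(10), upper)


@dataclass(frozen=True)
class ToleranceSchedule:
    """T rows of five per-component tolerances, non-increasing down rows."""

    epsilons: np.ndarray

    def __post_init__(self) -> None:
        eps = np.atleast_2d(np.asarray(self.epsilons, dtype=float))
        if eps.shape[1] != 5:
            raise ValueError("tolerance rows must have 5 components")
        if np.any(eps <= 0):
            raise ValueError("tolerances must be positive")
        if np.any(np.diff(eps, axis=0) > 0):
            raise ValueError("tolerance rows must be component-wise non-increasing")
        object.__setattr__(self, "epsilons", eps)

    def __len__(self) -> int:
        return len(self.epsilons)


def default_tolerances() -> ToleranceSchedule:
    """The eight-population tolerance schedule of the a=60 fit."""
    return ToleranceSchedule(
        np.array(
            [
                [100.0, 13.0, 100.0, 100.0, 1.5],
                [80.0, 10.0, 100.0, 100.0, 1.3],
                [60.0, 8.0, 70.0, 70.0, 1.2],
                [50.0, 7.0, 60.0, 60.0, 1.1],
                [40.0, 6.0, 50.0, 50.0, 1.0],
                [30.0, 5.0, 40.0, 40.0, 0.9],
                [20.0, 4.0, 30.0, 30.0, 0.8],
                [10.0, 3.0, 20.0, 20.0, 0.7],
            ]
        )
    )


@dataclass(frozen=True)
class Particle:
    theta: np.ndarray
    weight: float
    distance: np.ndarray


@dataclass(frozen=True)
class Population:
    particles: tuple[Particle, ...]
    index: int  # 1-based population number
    epsilon: np.ndarray
    n_proposals: int = 0

    @property
    def thetas(self) -> np.ndarray:
        return np.array([p.theta for p in self.particles])

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.particles])

    @property
    def distances(self) -> np.ndarray:
        return np.array([p.distance for p in self.particles])

    @property
    def acceptance_rate(self) -> float:
        return len(self.particles) / self.n_proposals if self.n_proposals else float("nan")

    def weighted_quantile(self, q, axis_param: int) -> float | np.ndarray:
        """Weighted quantile(s) of one parameter's marginal."""
        x = self.thetas[:, axis_param]
        order = np.argsort(x)
        x = x[order]
        w = self.weights[order]
        cdf = np.cumsum(w) - 0.5 * w
        cdf /= w.sum()
        return np.interp(q, cdf, x)


class AcceptanceFloorError(RuntimeError):
    """Raised when a population's acceptance rate falls below the floor."""

    def __init__(self, population: int, rate: float, exceed_counts: np.ndarray):
        comps = ", ".join(
            f"{DISTANCE_NAMES[i]} ({int(c)}x)" for i, c in enumerate(exceed_counts) if c
        )
        super().__init__(
            f"population {population}: acceptance rate {rate:.2e} below floor; "
            f"components exceeding tolerance: {comps or 'none'}"
        )
        self.population = population
        self.rate = rate
        self.exceed_counts = exceed_counts


def sample_prior(prior: Prior, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(prior.lower, prior.upper)


def kernel_scales(population: Population, prior: Prior) -> np.ndarray:
    """Adaptive uniform-kernel half-widths for the next population.

    σ_i is half the range of parameter i over the previous population's
    accepted particles; degenerate (zero-range) components get a small
    floor of 1e-6 times the prior width so the kernel density stays
    proper.
    """
    if not population.particles:
        raise ValueError("empty population")
    thetas = population.thetas
    sigma = 0.5 * (thetas.max(axis=0) - thetas.min(axis=0))
    floor = 1e-6 * prior.width
    return np.maximum(sigma, floor)


def perturb(theta: np.ndarray, sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Component-wise uniform random-walk proposal on ±sigma."""
    return theta + rng.uniform(-sigma, sigma)


def kernel_density(theta: np.ndarray, center: np.ndarray, sigma: np.ndarray) -> float:
    """Density of the uniform box kernel K(theta | center)."""
    if np.any(np.abs(theta - center) > sigma):
        return 0.0
    return float(1.0 / np.prod(2.0 * sigma))


def particle_weight(
    theta: np.ndarray,
    previous: Population | None,
    sigma: np.ndarray | None,
    prior: Prior,
) -> float:
    """Importance weight: prior density over the kernel mixture.

    Population 1 gets unit weights (direct prior sampling).  Later
    populations use w = P(theta) / Σ_j w_j K(theta | theta_j) over the
    previous population.
    """
    if previous is None:
        return 1.0
    denom = sum(
        p.weight * kernel_density(theta, p.theta, sigma) for p in previous.particles
    )
    if denom <= 0.0:
        raise ValueError("proposal has zero kernel support under previous population")
    return prior.density(theta) / denom


def accept(d: np.ndarray, eps: np.ndarray) -> bool:
    """Vector acceptance: every distance component within its tolerance."""
    d = np.asarray(d, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if d.shape != eps.shape:
        raise ValueError("distance/tolerance length mismatch")
    return bool(np.all(d <= eps))


def _normalize(particles: list[Particle]) -> tuple[Particle, ...]:
    total = sum(p.weight for p in particles)
    return tuple(
        Particle(p.theta, p.weight / total, p.distance) for p in particles
    )


def abc_smc(
    distance_fn,
    prior: Prior,
    tolerances: ToleranceSchedule,
    n_particles: int = 100,
    seed: int = 0,
    acceptance_floor: float = 1e-5,
    min_attempts_before_floor: int = 2000,
) -> list[Population]:
    """Run ABC SMC and return one weighted Population per tolerance row.

    ``distance_fn(theta, rng) -> 5-vector`` must simulate one dataset at
    ``theta`` (using ``rng`` for any stochastic simulation) and return
    the distance vector; it is called exactly once per proposal.

    Reproducibility: the master seed spawns one stream per (population,
    particle slot), so results are independent of any parallel
    scheduling of slots.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    master = np.random.SeedSequence(seed)
    pop_seeds = master.spawn(len(tolerances))
    populations: list[Population] = []
    previous: Population | None = None
    sigma: np.ndarray | None = None
    for t, eps in enumerate(tolerances.epsilons, start=1):
        slot_seeds = pop_seeds[t - 1].spawn(n_particles)
        if previous is not None:
            sigma = kernel_scales(previous, prior)
            prev_thetas = previous.thetas
            prev_weights = previous.weights
            prev_cdf = np.cumsum(prev_weights)
            prev_cdf /= prev_cdf[-1]
        accepted: list[Particle] = []
        attempts = 0
        exceed_counts = np.zeros(5)
        for i in range(n_particles):
            rng = np.random.default_rng(slot_seeds[i])
            while True:
                attempts += 1
                if (
                    attempts >= min_attempts_before_floor
                    and (len(accepted) + 1) / attempts < acceptance_floor
                ):
                    raise AcceptanceFloorError(
                        t, (len(accepted) + 1) / attempts, exceed_counts
                    )
                if previous is None:
                    theta = sample_prior(prior, rng)
                else:
                    j = int(np.searchsorted(prev_cdf, rng.random()))
                    theta = perturb(prev_thetas[j], sigma, rng)
                    if prior.density(theta) == 0.0:
                        continue  # outside prior support: propose again
                d = np.asarray(distance_fn(theta, rng), dtype=float)
                if accept(d, eps):
                    break
                exceed_counts += d > eps
            w = particle_weight(theta, previous, sigma, prior)
            accepted.append(Particle(theta, w, d))
        population = Population(_normalize(accepted), t, np.asarray(eps), attempts)
        populations.append(population)
        previous = population
    return populations


def abc_rejection(
    distance_fn,
    prior: Prior,
    eps: np.ndarray,
    n_particles: int = 100,
    seed: int = 0,
    acceptance_floor: float = 1e-5,
    min_attempts_before_floor: int = 2000,
) -> Population:
    """ABC rejection sampling: a single population with uniform weights."""
    pops = abc_smc(
        distance_fn,
        prior,
        ToleranceSchedule(np.atleast_2d(eps)),
        n_particles=n_particles,
        seed=seed,
        acceptance_floor=acceptance_floor,
        min_attempts_before_floor=min_attempts_before_floor,
    )
    return pops[0]


def populations_frame(populations: list[Population]) -> pd.DataFrame:
    """All populations as one tidy table (one row per particle)."""
    rows = []
    for pop in populations:
        for p in pop.particles:
            rec = dict(zip(PARAM_NAMES, p.theta))
            rec["weight"] = p.weight
            rec.update(zip(DISTANCE_NAMES, p.distance))
            rec["population"] = pop.index
            rows.append(rec)
    return pd.DataFrame(rows)


def write_populations_csv(populations: list[Population], outdir) -> None:
    """One CSV per population plus a combined file, in ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = populations_frame(populations)
    for idx, sub in frame.groupby("population"):
        sub.to_csv(outdir / f"population_{idx}.csv", index=False)
    frame.to_csv(outdir / "populations_all.csv", index=False)


def read_population_csv(path) -> Population:
    df = pd.read_csv(path)
    particles = tuple(
        Particle(
            row[list(PARAM_NAMES)].to_numpy(dtype=float),
            float(row["weight"]),
            row[list(DISTANCE_NAMES)].to_numpy(dtype=float),
        )
        for _, row in df.iterrows()
    )
    return Population(particles, int(df["population"].iloc[0]), np.full(5, np.nan))
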