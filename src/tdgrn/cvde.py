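"""Complex-valued differential evolution (rand/1/bin).

Optimizes mixed parameter vectors whose components are either complex (the
TDCVSS rate constants alpha and beta, whose real and imaginary parts evolve
together) or real (kinetic orders). Mutation is the classic difference-
vector scheme donor = x_r1 + F * (x_r2 - x_r3) applied with complex
arithmetic on complex components; crossover is binomial per component with
complex components moving as indivisible units; selection is greedy
one-to-one, so the best fitness is non-increasing across generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "DEConfig",
    "ParameterVector",
    "ComponentSpec",
    "init_population",
    "de_mutate",
    "de_crossover",
    "cvde_optimize",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One component's kind and box: 'complex' uses (lo, hi) on re and im."""

    kind: str  # "complex" | "real"
    lo: float
    hi: float

    def __post_init__(self):
        if self.kind not in ("complex", "real"):
            raise ConfigError(f"unknown component kind {self.kind!r}")
        if self.lo > self.hi:
            raise ConfigError(f"degenerate bounds ({self.lo}, {self.hi})")


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution knobs (rand/1/bin variant).

    Defaults: population 40, F = 0.5, CR = 0.9, 150 generations, early
    stop after 30 generations with < 1e-10 improvement of the best SSE.
    """

    np_pop: int = 40
    f_weight: float = 0.5
    cr: float = 0.9
    generations: int = 150
    early_stop_tol: float = 1e-10
    early_stop_patience: int = 30

    def __post_init__(self):
        if self.np_pop < 4:
            raise ConfigError("np_pop must be >= 4")
        if not 0 < self.f_weight <= 2:
            raise ConfigError("f_weight must lie in (0, 2]")
        if not 0 <= self.cr <= 1:
            raise ConfigError("cr must lie in [0, 1]")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")


class ParameterVector:
    """Ordered components, each complex or real; immutable value object."""

    __slots__ = ("components", "kinds")

    def __init__(self, components, kinds):
        self.components = tuple(
            complex(c) if k == "complex" else float(c)
            for c, k in zip(components, kinds, strict=True)
        )
        self.kinds = tuple(kinds)

    def __len__(self):
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def __getitem__(self, i):
        return self.components[i]

    def __eq__(self, other):
        return (
            isinstance(other, ParameterVector)
            and self.kinds == other.kinds
            and self.components == other.components
        )

    def __repr__(self):
        return f"ParameterVector({list(self.components)!r})"


def _check_template(template, bounds):
    if len(template) != len(bounds):
        raise ConfigError("bounds must cover every component")
    for spec in bounds:
        if not isinstance(spec, ComponentSpec):
            raise ConfigError("bounds entries must be ComponentSpec")


def init_population(
    template,
    bounds,
    cfg: DEConfig,
    rng: np.random.Generator,
) -> list[ParameterVector]:
    """Uniform initial population inside the per-component boxes.

    ``template`` is the sequence of component kinds ("complex"/"real");
    ``bounds`` the matching :class:`ComponentSpec` list.
    """
    _check_template(template, bounds)
    pop = []
    for _ in range(cfg.np_pop):
        comps = []
        for kind, spec in zip(template, bounds):
            if kind != spec.kind:
                raise ConfigError("template kind disagrees with bounds kind")
            if kind == "complex":
                comps.append(
                    complex(rng.uniform(spec.lo, spec.hi), rng.uniform(spec.lo, spec.hi))
                )
            else:
                comps.append(float(rng.uniform(spec.lo, spec.hi)))
        pop.append(ParameterVector(comps, template))
    return pop


def de_mutate(
    population,
    target_idx: int,
    f_weight: float,
    rng: np.random.Generator,
) -> ParameterVector:
    """rand/1 donor: x_r1 + F * (x_r2 - x_r3), indices distinct from target."""
    n = len(population)
    if n < 4:
        raise ConfigError("rand/1 mutation needs at least 4 members")
    pool = [i for i in range(n) if i != target_idx]
    r1, r2, r3 = rng.choice(len(pool), size=3, replace=False)
    x1, x2, x3 = population[pool[r1]], population[pool[r2]], population[pool[r3]]
    comps = [
        a + f_weight * (b - c)
        for a, b, c in zip(x1.components, x2.components, x3.components)
    ]
    return ParameterVector(comps, x1.kinds)


def de_crossover(
    target: ParameterVector,
    donor: ParameterVector,
    cr: float,
    rng: np.random.Generator,
) -> ParameterVector:
    """Binomial crossover; component j_rand always comes from the donor.

    Complex components cross as units: their real and imaginary parts
    always travel together.
    """
    if target.kinds != donor.kinds:
        raise ConfigError("component kinds differ between target and donor")
    n = len(target)
    j_rand = int(rng.integers(n))
    comps = [
        donor[j] if (rng.random() < cr or j == j_rand) else target[j]
        for j in range(n)
    ]
    return ParameterVector(comps, target.kinds)


def _reflect(value: float, lo: float, hi: float) -> float:
    """Reflect an out-of-bounds coordinate back into [lo, hi]."""
    if lo == hi:
        return lo
    width = hi - lo
    # mirror repeatedly into the box
    v = (value - lo) % (2 * width)
    if v > width:
        v = 2 * width - v
    return lo + v


def _clip_vector(v: ParameterVector, bounds) -> ParameterVector:
    comps = []
    for c, kind, spec in zip(v.components, v.kinds, bounds):
        if kind == "complex":
            comps.append(
                complex(
                    _reflect(c.real, spec.lo, spec.hi),
                    _reflect(c.imag, spec.lo, spec.hi),
                )
            )
        else:
            comps.append(_reflect(c, spec.lo, spec.hi))
    return ParameterVector(comps, v.kinds)


def cvde_optimize(
    fitness,
    template,
    bounds,
    cfg: DEConfig,
    rng: np.random.Generator,
    initial: list[ParameterVector] | None = None,
):
    """Minimize ``fitness`` over parameter vectors; returns (best, f, history).

    ``initial`` optionally seeds the first members of the population (e.g.
    a chromosome's current parameters); the remainder is drawn uniformly in
    the bounds. ``history`` records the best fitness after every
    generation, starting with the initial population, and is monotone
    non-increasing by construction of the greedy selection.
    """
    _check_template(template, bounds)
    pop = init_population(template, bounds, cfg, rng)
    if initial:
        for i, v in enumerate(initial[: len(pop)]):
            pop[i] = _clip_vector(v, bounds)
    fits = np.array([float(fitness(v)) for v in pop])
    best_i = int(np.argmin(fits))
    history = [float(fits[best_i])]
    stall = 0
    for _ in range(cfg.generations):
        for i in range(cfg.np_pop):
            donor = de_mutate(pop, i, cfg.f_weight, rng)
            trial = de_crossover(pop[i], donor, cfg.cr, rng)
            trial = _clip_vector(trial, bounds)
            f_trial = float(fitness(trial))
            if f_trial <= fits[i]:
                pop[i] = trial
                fits[i] = f_trial
        new_best = float(fits.min())
        if history[-1] - new_best < cfg.early_stop_tol:
            stall += 1
        else:
            stall = 0
        history.append(new_best)
        if stall >= cfg.early_stop_patience:
            break
    best_i = int(np.argmin(fits))
    return pop[best_i], float(fits[best_i]), history
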