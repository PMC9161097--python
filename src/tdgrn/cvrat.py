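"""Restricted additive tree chromosomes for TDCVSS structure evolution.

The chromosome is a two-branch tree: a fixed subtraction root whose left
and right children are product nodes of arity 1..max_arity. Each leaf is a
variable node carrying (gene index, real kinetic order, integer lag); each
branch carries a complex rate constant (alpha on the left/production side,
beta on the right/degradation side). Leaf lags are pinned to the screening
stage's optimal lag for that (regulator, target) pair, so structure search
explores only regulator membership, arities, and kinetic orders.

Evolution uses tournament selection, a subtree/leaf swap crossover, and
pointwise mutations (gene replacement, order perturbation, branch
regeneration, constant perturbation). All operators are pure functions of
their inputs and the supplied numpy random generator, so runs are
reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import GeneModel, TermFactor

__all__ = [
    "AdditiveTreeChromosome",
    "random_chromosome",
    "chromosome_to_model",
    "model_to_chromosome",
    "crossover",
    "mutate",
    "tournament_select",
]

#: default range for freshly drawn kinetic orders
ORDER_INIT_RANGE = (-3.0, 3.0)
#: default box (re and im) for freshly drawn rate constants
CONST_INIT_BOX = 25.0
#: scale of Gaussian kinetic-order perturbations
ORDER_STEP_SD = 0.5
#: scale of Gaussian rate-constant perturbations (per component)
CONST_STEP_SD = 2.0


@dataclass(frozen=True)
class AdditiveTreeChromosome:
    """Two product terms plus their complex branch constants."""

    alpha: complex
    beta: complex
    production: tuple[TermFactor, ...]
    degradation: tuple[TermFactor, ...]

    def __post_init__(self):
        object.__setattr__(self, "production", tuple(self.production))
        object.__setattr__(self, "degradation", tuple(self.degradation))

    def validate(self, candidates=None, max_arity: int | None = None) -> None:
        """Raise ValueError on any grammar violation."""
        for side in (self.production, self.degradation):
            if not 1 <= len(side):
                raise ValueError("each product node needs arity >= 1")
            if max_arity is not None and len(side) > max_arity:
                raise ValueError("arity exceeds max_arity")
            genes = [f.regulator for f in side]
            if len(set(genes)) != len(genes):
                raise ValueError("duplicate gene within a product node")
            if candidates is not None:
                allowed = {g for g, _ in candidates}
                for f in side:
                    if f.regulator not in allowed:
                        raise ValueError(f"gene {f.regulator} not a candidate")

    def structure_key(self) -> tuple:
        """Hashable identity of regulator/lag membership per term (order-free)."""
        return (
            tuple(sorted((f.regulator, f.lag) for f in self.production)),
            tuple(sorted((f.regulator, f.lag) for f in self.degradation)),
        )


def _random_term(candidates, max_arity, rng: np.random.Generator, order_range):
    arity = int(rng.integers(1, min(max_arity, len(candidates)) + 1))
    picks = rng.choice(len(candidates), size=arity, replace=False)
    lo, hi = order_range
    return tuple(
        TermFactor(
            regulator=candidates[int(k)][0],
            order=float(rng.uniform(lo, hi)),
            lag=candidates[int(k)][1],
        )
        for k in picks
    )


def _random_constant(rng: np.random.Generator, box: float) -> complex:
    return complex(rng.uniform(-box, box), rng.uniform(-box, box))


def random_chromosome(
    candidates,
    max_arity: int,
    rng: np.random.Generator,
    order_range=ORDER_INIT_RANGE,
    const_box: float = CONST_INIT_BOX,
) -> AdditiveTreeChromosome:
    """Draw a grammatically valid chromosome uniformly at random.

    ``candidates`` is a non-empty list of (gene_index, lag) pairs — the
    target's initial-network regulators with their screened lags.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    return AdditiveTreeChromosome(
        alpha=_random_constant(rng, const_box),
        beta=_random_constant(rng, const_box),
        production=_random_term(candidates, max_arity, rng, order_range),
        degradation=_random_term(candidates, max_arity, rng, order_range),
    )


def chromosome_to_model(c: AdditiveTreeChromosome, target: int) -> GeneModel:
    """Left branch -> production with alpha; right branch -> degradation."""
    return GeneModel(
        target_index=target,
        alpha=c.alpha,
        beta=c.beta,
        production_term=c.production,
        degradation_term=c.degradation,
    )


def model_to_chromosome(m: GeneModel) -> AdditiveTreeChromosome:
    """Inverse of :func:`chromosome_to_model`."""
    return AdditiveTreeChromosome(
        alpha=m.alpha,
        beta=m.beta,
        production=m.production_term,
        degradation=m.degradation_term,
    )


def _term_valid(term) -> bool:
    genes = [f.regulator for f in term]
    return len(set(genes)) == len(genes) and len(genes) >= 1


def crossover(
    a: AdditiveTreeChromosome,
    b: AdditiveTreeChromosome,
    rng: np.random.Generator,
    max_retries: int = 8,
):
    """Swap one subtree between parents at a compatible grammar position.

    With probability 1/2 the whole product branch on one side (with its
    rate constant) is exchanged; otherwise a single leaf on that side is
    exchanged. Leaf swaps that would duplicate a gene within a term are
    retried; after ``max_retries`` failures the branch swap is used, which
    is always grammatical. The combined leaf multiset of the two children
    always equals that of the two parents.
    """
    side = "production" if rng.random() < 0.5 else "degradation"

    def branch_swap():
        if side == "production":
            c1 = replace(a, production=b.production, alpha=b.alpha)
            c2 = replace(b, production=a.production, alpha=a.alpha)
        else:
            c1 = replace(a, degradation=b.degradation, beta=b.beta)
            c2 = replace(b, degradation=a.degradation, beta=a.beta)
        return c1, c2

    if rng.random() < 0.5:
        return branch_swap()

    ta = list(getattr(a, side))
    tb = list(getattr(b, side))
    for _ in range(max_retries):
        i = int(rng.integers(len(ta)))
        j = int(rng.integers(len(tb)))
        na = ta.copy()
        nb = tb.copy()
        na[i], nb[j] = tb[j], ta[i]
        if _term_valid(na) and _term_valid(nb):
            c1 = replace(a, **{side: tuple(na)})
            c2 = replace(b, **{side: tuple(nb)})
            return c1, c2
    return branch_swap()


def mutate(
    a: AdditiveTreeChromosome,
    rate: float,
    candidates,
    rng: np.random.Generator,
    max_arity: int = 4,
    order_range=ORDER_INIT_RANGE,
    tau_max: int | None = None,
) -> AdditiveTreeChromosome:
    """Apply pointwise mutations, each site hit with probability ``rate``.

    Leaf sites: replace the leaf's gene with an unused candidate (lag
    follows the candidate's screened lag), perturb its kinetic order with
    a Gaussian step, or — when ``tau_max`` is given — move its lag
    uniformly within [0, tau_max] (the screened lag is only the starting
    point; level correlation peaks at the regulator's phase shift, which
    need not equal the dynamical delay). Branch sites: regenerate the
    product subtree with a fresh arity, or perturb the complex constant.
    rate = 0 returns the input unchanged.
    """
    candidates = list(candidates)
    lag_of = dict(candidates)
    alpha, beta = a.alpha, a.beta
    terms = {"production": list(a.production), "degradation": list(a.degradation)}

    for side in ("production", "degradation"):
        term = terms[side]
        for i in range(len(term)):
            if rng.random() >= rate:
                continue
            f = term[i]
            n_moves = 3 if tau_max is not None else 2
            move = int(rng.integers(n_moves))
            if move == 0:
                used = {g.regulator for g in term} - {f.regulator}
                free = [g for g, _ in candidates if g not in used]
                g_new = int(free[int(rng.integers(len(free)))])
                term[i] = TermFactor(g_new, f.order, lag_of[g_new])
            elif move == 1:
                term[i] = replace(
                    f, order=float(f.order + rng.normal(0.0, ORDER_STEP_SD))
                )
            else:
                term[i] = replace(f, lag=int(rng.integers(0, tau_max + 1)))
        if rng.random() < rate:
            if rng.random() < 0.5:
                terms[side] = list(
                    _random_term(candidates, max_arity, rng, order_range)
                )
            else:
                step = complex(
                    rng.normal(0.0, CONST_STEP_SD), rng.normal(0.0, CONST_STEP_SD)
                )
                if side == "production":
                    alpha += step
                else:
                    beta += step

    return AdditiveTreeChromosome(
        alpha=alpha,
        beta=beta,
        production=tuple(terms["production"]),
        degradation=tuple(terms["degradation"]),
    )


def tournament_select(population, fitnesses, k: int, rng: np.random.Generator):
    """Return the lowest-SSE member of k draws (with replacement)."""
    population = list(population)
    if not population:
        raise ValueError("empty population")
    if not 1 <= k <= len(population):
        raise ValueError("tournament size must be in [1, len(population)]")
    fitnesses = np.asarray(fitnesses, dtype=float)
    idx = rng.integers(len(population), size=k)
    best = min(idx, key=lambda i: fitnesses[i])
    return population[int(best)]
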