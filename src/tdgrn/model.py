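"""Time-delayed complex-valued S-system (TDCVSS) representation.

Each gene i obeys a power-law difference of a production and a degradation
term,

    dX_i/dt = alpha_i * prod_j X_j(t - tau_ij)^g_ij
            - beta_i  * prod_j X_j(t - tau_ij)^h_ij,

where the rate constants alpha, beta are complex, the kinetic orders g, h
are real, and each regulator enters with its own integer delay tau counted
in sampling steps. Observed expression data are real and are embedded as
complex values with zero imaginary part; only the rate constants carry
genuine imaginary components.

This module provides the model container, complex power-law evaluation,
slope estimation, the decoupled slope-matching fitness used throughout the
structure/parameter search, delayed forward-Euler simulation, and a
human-readable equation renderer with a round-tripping parser.
"""

from __future__ import annotations

import cmath
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import ExpressionTimeSeries
from .errors import DivergenceError, DomainError

__all__ = [
    "TermFactor",
    "GeneModel",
    "NetworkModel",
    "complex_power",
    "evaluate_rhs",
    "estimate_slopes",
    "decoupled_sse",
    "simulate_network",
    "render_equation",
    "parse_equation",
    "MODULUS_FLOOR",
    "DOMAIN_PENALTY",
]

#: positivity floor applied to moduli before exponentiation
MODULUS_FLOOR = 1e-6
#: finite penalty substituted for domain errors inside fitness evaluation
DOMAIN_PENALTY = 1e12
#: simulation overflow guard
OVERFLOW_GUARD = 1e6


@dataclass(frozen=True)
class TermFactor:
    """One regulator's contribution to a product term: X_reg(t-lag)^order."""

    regulator: int
    order: float
    lag: int = 0

    def __post_init__(self):
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if not np.isfinite(self.order):
            raise ValueError("kinetic order must be finite")


@dataclass(frozen=True)
class GeneModel:
    """One TDCVSS equation for a single target gene."""

    target_index: int
    alpha: complex
    beta: complex
    production_term: tuple[TermFactor, ...]
    degradation_term: tuple[TermFactor, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "production_term", tuple(self.production_term)
        )
        object.__setattr__(
            self, "degradation_term", tuple(self.degradation_term)
        )
        for term in (self.production_term, self.degradation_term):
            if len(term) < 1:
                raise ValueError("each term needs at least one factor")
            regs = [f.regulator for f in term]
            if len(set(regs)) != len(regs):
                raise ValueError("duplicate regulator within one term")

    @property
    def max_lag(self) -> int:
        return max(f.lag for f in self.production_term + self.degradation_term)

    def regulators(self) -> set[int]:
        """All regulator indices appearing in either term."""
        return {f.regulator for f in self.production_term + self.degradation_term}

    def to_dict(self) -> dict:
        return {
            "target": self.target_index,
            "alpha": [self.alpha.real, self.alpha.imag],
            "beta": [self.beta.real, self.beta.imag],
            "production": [[f.regulator, f.order, f.lag] for f in self.production_term],
            "degradation": [[f.regulator, f.order, f.lag] for f in self.degradation_term],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            target_index=int(d["target"]),
            alpha=complex(d["alpha"][0], d["alpha"][1]),
            beta=complex(d["beta"][0], d["beta"][1]),
            production_term=tuple(
                TermFactor(int(r), float(g), int(t)) for r, g, t in d["production"]
            ),
            degradation_term=tuple(
                TermFactor(int(r), float(h), int(t)) for r, h, t in d["degradation"]
            ),
        )


@dataclass(frozen=True)
class NetworkModel:
    """A full TDCVSS: one equation per gene, in target order."""

    gene_ids: tuple[str, ...]
    models: tuple[GeneModel, ...]

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "models", tuple(self.models))
        if len(self.models) != len(self.gene_ids):
            raise ValueError("need exactly one model per gene")
        for i, m in enumerate(self.models):
            if m.target_index != i:
                raise ValueError("models must be ordered by target index")

    @property
    def max_lag(self) -> int:
        return max(m.max_lag for m in self.models)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "gene_ids": list(self.gene_ids),
            "models": [m.to_dict() for m in self.models],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NetworkModel":
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(source)
        doc = json.loads(text)
        return cls(
            gene_ids=tuple(doc["gene_ids"]),
            models=tuple(GeneModel.from_dict(d) for d in doc["models"]),
        )

    def render(self, sep: str = "\n") -> str:
        return sep.join(render_equation(m, self.gene_ids) for m in self.models)


def complex_power(z: complex, g: float) -> complex:
    """Principal-branch complex power z**g = exp(g * Log z).

    0**g is 0 for positive g and a :class:`DomainError` otherwise.
    Satisfies |z**g| = |z|**g.
    """
    z = complex(z)
    if z == 0:
        if g > 0:
            return 0j
        raise DomainError(f"0 ** {g} is undefined")
    if g == 0:
        return 1 + 0j
    return cmath.exp(g * cmath.log(z))


def evaluate_rhs(model: GeneModel, lagged_values: dict) -> complex:
    """Evaluate the model right-hand side from a (regulator, lag) -> value map."""
    prod = model.alpha
    for f in model.production_term:
        prod *= complex_power(lagged_values[(f.regulator, f.lag)], f.order)
    deg = model.beta
    for f in model.degradation_term:
        deg *= complex_power(lagged_values[(f.regulator, f.lag)], f.order)
    return prod - deg


def estimate_slopes(data: ExpressionTimeSeries, gene: int) -> np.ndarray:
    """Numerical time derivative of one gene's series.

    Central differences at interior points, one-sided at the two boundary
    points, honoring the (possibly non-uniform) time grid.
    """
    return np.gradient(data.values[:, gene], data.times, edge_order=1)


def _floored(values: np.ndarray) -> np.ndarray:
    """Push moduli below MODULUS_FLOOR up to the floor, preserving phase."""
    values = np.asarray(values, dtype=complex)
    mod = np.abs(values)
    small = mod < MODULUS_FLOOR
    if not small.any():
        return values
    out = values.copy()
    zero = mod == 0.0
    out[zero] = MODULUS_FLOOR
    adj = small & ~zero
    out[adj] = values[adj] / mod[adj] * MODULUS_FLOOR
    return out


def decoupled_sse(
    model: GeneModel,
    data: ExpressionTimeSeries,
    slopes: np.ndarray,
) -> float:
    """Slope-matching fitness: sum of |RHS(t) - slope(t)|^2.

    The sum runs over the valid window t = max_lag .. T-1 (sample indices),
    where every factor reads the regulator's observed value at t - lag, so
    no history has to be fabricated. Domain errors (zero base, non-positive
    order) are avoided by flooring moduli; any residual non-finite value
    maps to the large finite penalty so evolutionary search stays total.
    """
    T = data.n_times
    start = model.max_lag
    if start > T - 1:
        return DOMAIN_PENALTY
    t_idx = np.arange(start, T)
    try:
        rhs = _rhs_over_window(model, data.values, t_idx)
    except (DomainError, OverflowError):
        return DOMAIN_PENALTY
    resid = rhs - np.asarray(slopes, dtype=float)[t_idx]
    sse = float(np.sum(np.abs(resid) ** 2))
    if not np.isfinite(sse):
        return DOMAIN_PENALTY
    return sse


def _rhs_over_window(
    model: GeneModel, values: np.ndarray, t_idx: np.ndarray
) -> np.ndarray:
    """Vectorized RHS across sample indices t_idx (factors read t - lag)."""
    prod = np.full(len(t_idx), model.alpha, dtype=complex)
    for f in model.production_term:
        z = _floored(values[t_idx - f.lag, f.regulator])
        prod *= np.exp(f.order * np.log(z))
    deg = np.full(len(t_idx), model.beta, dtype=complex)
    for f in model.degradation_term:
        z = _floored(values[t_idx - f.lag, f.regulator])
        deg *= np.exp(f.order * np.log(z))
    return prod - deg


def simulate_network(
    nm: NetworkModel,
    initial_history: np.ndarray,
    n_steps: int,
    dt: float,
    substeps: int = 10,
) -> np.ndarray:
    """Forward-Euler integration of the delayed system with a lag buffer.

    ``initial_history`` is a T0 x N real (or complex) matrix sampled at the
    output spacing ``dt``; T0 must cover the largest lag in the model. The
    history is linearly interpolated onto the Euler grid (spacing
    dt/substeps); each delayed factor reads the buffer ``substeps * lag``
    Euler steps back. Moduli are floored before exponentiation. Returns an
    ``(n_steps + 1) x N`` complex trajectory whose first row is the last
    history row, sampled every ``substeps`` Euler steps.

    Raises :class:`DivergenceError` when any state modulus exceeds the
    overflow guard, reporting the offending Euler step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    history = np.asarray(initial_history, dtype=complex)
    T0, N = history.shape
    max_lag = nm.max_lag
    # the last history row doubles as the initial state, so covering a
    # delayed read of max_lag samples needs max_lag + 1 rows
    if T0 < max_lag + 1:
        raise ValueError(
            f"history of {T0} rows cannot cover the maximum lag {max_lag}"
        )
    if N != len(nm.gene_ids):
        raise ValueError("history width does not match the gene count")

    # interpolate history onto the Euler grid: (T0-1)*substeps + 1 nodes
    if T0 == 1:
        buffer = [history[0].copy() for _ in range(max_lag * substeps + 1)]
    else:
        coarse = np.arange(T0, dtype=float)
        fine = np.arange((T0 - 1) * substeps + 1, dtype=float) / substeps
        fine_hist = np.stack(
            [
                np.interp(fine, coarse, history[:, g].real)
                + 1j * np.interp(fine, coarse, history[:, g].imag)
                for g in range(N)
            ],
            axis=1,
        )
        buffer = [fine_hist[k] for k in range(fine_hist.shape[0])]

    dt_sub = dt / substeps
    out = [buffer[-1].copy()]
    for step in range(n_steps * substeps):
        state = buffer[-1]
        deriv = np.empty(N, dtype=complex)
        for m in nm.models:
            vals = {}
            for f in m.production_term + m.degradation_term:
                key = (f.regulator, f.lag)
                if key not in vals:
                    back = f.lag * substeps
                    vals[key] = _floored(
                        np.array([buffer[-1 - back][f.regulator]])
                    )[0]
            deriv[m.target_index] = evaluate_rhs(m, vals)
        new = state + dt_sub * deriv
        if np.any(np.abs(new) > OVERFLOW_GUARD):
            bad = float(np.max(np.abs(new)))
            raise DivergenceError(step + 1, bad)
        buffer.append(new)
        # keep only what delayed reads can reach
        needed = max_lag * substeps + 1
        if len(buffer) > needed + substeps:
            del buffer[: len(buffer) - needed - substeps]
        if (step + 1) % substeps == 0:
            out.append(new.copy())
    return np.stack(out)


# ---------------------------------------------------------------------------
# rendering / parsing


def _fmt_complex(c: complex) -> str:
    sign = "+" if c.imag >= 0 else "-"
    return f"({c.real:.4f}{sign}{abs(c.imag):.4f}i)"


def _fmt_term(constant: complex, term, gene_ids) -> str:
    parts = [_fmt_complex(constant)]
    for f in term:
        name = gene_ids[f.regulator]
        lag = f"[t-{f.lag}]" if f.lag > 0 else ""
        parts.append(f"{name}{lag}^{f.order:.4f}")
    return "*".join(parts)


def render_equation(model: GeneModel, gene_ids) -> str:
    """Format one equation, e.g. ``dY/dt = (a+bi)*X[t-1]^g - (c+di)*Z^h``.

    Coefficients print with four decimals; the ``[t-k]`` lag suffix is
    omitted for lag 0. The output round-trips through
    :func:`parse_equation`.
    """
    target = gene_ids[model.target_index]
    lhs = f"d{target}/dt = "
    return (
        lhs
        + _fmt_term(model.alpha, model.production_term, gene_ids)
        + " - "
        + _fmt_term(model.beta, model.degradation_term, gene_ids)
    )


_COMPLEX_RE = re.compile(
    r"^\((-?\d+(?:\.\d+)?)([+-]\d+(?:\.\d+)?)i\)$"
)
_FACTOR_RE = re.compile(
    r"^(?P<name>\w+?)(?:\[t-(?P<lag>\d+)\])?\^(?P<order>-?\d+(?:\.\d+)?)$"
)


def _parse_term(text: str, gene_ids) -> tuple[complex, tuple[TermFactor, ...]]:
    parts = text.split("*")
    m = _COMPLEX_RE.match(parts[0].strip())
    if m is None:
        raise ValueError(f"cannot parse rate constant from {parts[0]!r}")
    constant = complex(float(m.group(1)), float(m.group(2)))
    factors = []
    for p in parts[1:]:
        fm = _FACTOR_RE.match(p.strip())
        if fm is None:
            raise ValueError(f"cannot parse factor {p!r}")
        factors.append(
            TermFactor(
                regulator=list(gene_ids).index(fm.group("name")),
                order=float(fm.group("order")),
                lag=int(fm.group("lag") or 0),
            )
        )
    return constant, tuple(factors)


def parse_equation(text: str, gene_ids) -> GeneModel:
    """Inverse of :func:`render_equation` (4-decimal precision)."""
    lhs, rhs = text.split("=", 1)
    target_name = lhs.strip()[1:].split("/")[0]
    target = list(gene_ids).index(target_name)
    # split the production/degradation terms on the top-level " - "
    prod_text, deg_text = rhs.split(" - ", 1)
    alpha, production = _parse_term(prod_text.strip(), gene_ids)
    beta, degradation = _parse_term(deg_text.strip(), gene_ids)
    return GeneModel(target, alpha, beta, production, degradation)
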