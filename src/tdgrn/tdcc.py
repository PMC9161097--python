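"""Time-delayed correlation coefficient (TDCC) screening.

The TDCC between a candidate regulator X and a target Y at lag tau is the
Pearson correlation of X(t) with Y(t + tau), computed over the overlap
window t = 1..T-tau with means and variances recomputed on that window.
Scanning tau = 0..tau_max and keeping the lag with the largest |r| yields a
best-lag correlation matrix and an integer lag matrix; thresholding |r|
gives the initial directed, weighted, lagged network that the S-system
pruning stage then refines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionTimeSeries
from .errors import LagTooLargeError
from .network import Edge, RegulatoryNetwork

__all__ = [
    "lagged_pearson",
    "tdcc_scan",
    "build_tdcc_matrix",
    "threshold_network",
    "TDCCResult",
]


def lagged_pearson(x, y, tau: int) -> float:
    """Pearson correlation between x(t) and y(t + tau).

    Requires ``tau <= T - 3`` so the overlap window keeps at least three
    points. Returns 0.0 when either windowed series has zero variance
    (degenerate); use :func:`lagged_pearson_flagged` to observe the flag.
    """
    r, _ = lagged_pearson_flagged(x, y, tau)
    return r


def lagged_pearson_flagged(x, y, tau: int) -> tuple[float, bool]:
    """As :func:`lagged_pearson`, returning (r, degenerate)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    T = len(x)
    if len(y) != T:
        raise ValueError("series lengths differ")
    if tau < 0:
        raise ValueError("lag must be non-negative")
    if tau > T - 3:
        raise LagTooLargeError(f"lag {tau} leaves fewer than 3 of {T} samples")
    xs = x[: T - tau] if tau else x
    ys = y[tau:]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = np.sqrt((xs @ xs) * (ys @ ys))
    if denom == 0.0:
        return 0.0, True
    r = float((xs @ ys) / denom)
    # guard rounding excursions outside [-1, 1]
    return max(-1.0, min(1.0, r)), False


def tdcc_scan(x, y, tau_max: int) -> tuple[float, int]:
    """Best signed correlation and lag over tau = 0..tau_max.

    The winning lag maximizes |r|; ties break toward the smallest tau.
    All-degenerate pairs give (0.0, 0).
    """
    cc, tau, _ = tdcc_scan_flagged(x, y, tau_max)
    return cc, tau


def tdcc_scan_flagged(x, y, tau_max: int) -> tuple[float, int, bool]:
    """As :func:`tdcc_scan`, returning (cc, tau, degenerate)."""
    best_cc, best_tau = 0.0, 0
    any_ok = False
    for tau in range(tau_max + 1):
        r, degenerate = lagged_pearson_flagged(x, y, tau)
        if degenerate:
            continue
        any_ok = True
        if abs(r) > abs(best_cc):
            best_cc, best_tau = r, tau
    return best_cc, best_tau, not any_ok


@dataclass(frozen=True)
class TDCCResult:
    """Best-lag correlations over all ordered gene pairs.

    ``cc[j, i]`` is the signed correlation of regulator j with target i at
    the best lag ``lag[j, i]``. Diagonals are cc = 1, lag = 0 by convention.
    ``degenerate[j, i]`` marks pairs where every scanned lag had zero
    variance.
    """

    gene_ids: tuple[str, ...]
    cc: np.ndarray
    lag: np.ndarray
    tau_max: int
    degenerate: np.ndarray
    # measured self-correlations at lag >= 1 (autocorrelation scan); the
    # matrix diagonal itself is the cc=1/lag=0 convention, not a measurement
    self_cc: np.ndarray | None = None
    self_lag: np.ndarray | None = None

    def cc_frame(self) -> pd.DataFrame:
        g = list(self.gene_ids)
        return pd.DataFrame(self.cc, index=g, columns=g)

    def lag_frame(self) -> pd.DataFrame:
        g = list(self.gene_ids)
        return pd.DataFrame(self.lag, index=g, columns=g)

    def write_tsv(self, prefix: str | Path) -> None:
        """Write ``<prefix>cc.tsv`` and ``<prefix>lag.tsv``."""
        prefix = str(prefix)
        self.cc_frame().to_csv(prefix + "cc.tsv", sep="\t")
        self.lag_frame().to_csv(prefix + "lag.tsv", sep="\t")


def build_tdcc_matrix(data: ExpressionTimeSeries, tau_max: int) -> TDCCResult:
    """Scan every ordered gene pair; regulator leads target by the lag."""
    if tau_max > data.n_times - 3:
        raise LagTooLargeError(
            f"tau_max {tau_max} too large for {data.n_times} samples"
        )
    data.check_uniform_for_lags()
    N = data.n_genes
    cc = np.eye(N)
    lag = np.zeros((N, N), dtype=int)
    degenerate = np.zeros((N, N), dtype=bool)
    self_cc = np.zeros(N)
    self_lag = np.zeros(N, dtype=int)
    for j in range(N):
        xj = data.values[:, j]
        for i in range(N):
            if i == j:
                continue
            cc[j, i], lag[j, i], degenerate[j, i] = tdcc_scan_flagged(
                xj, data.values[:, i], tau_max
            )
        # self-pair: lag 0 is trivially r=1, so scan delayed lags only
        best = (0.0, 0)
        for tau in range(1, tau_max + 1):
            r, deg = lagged_pearson_flagged(xj, xj, tau)
            if not deg and abs(r) > abs(best[0]):
                best = (r, tau)
        self_cc[j], self_lag[j] = best
    return TDCCResult(data.gene_ids, cc, lag, tau_max, degenerate, self_cc, self_lag)


def threshold_network(
    tdcc: TDCCResult,
    threshold: float,
    include_self_loops: bool = False,
) -> RegulatoryNetwork:
    """Keep edges with |cc| >= threshold; weight = |cc|, lag copied.

    The matrix diagonal is a cc = 1 convention, not a measurement, so
    self-loops never enter through it. With ``include_self_loops`` a self
    edge is screened like any other pair, using the measured delayed
    autocorrelation (lags >= 1) from the scan.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    N = len(tdcc.gene_ids)
    edges = []
    for j in range(N):
        for i in range(N):
            if i == j:
                continue
            if abs(tdcc.cc[j, i]) >= threshold:
                edges.append(
                    Edge(
                        tdcc.gene_ids[j],
                        tdcc.gene_ids[i],
                        weight=abs(float(tdcc.cc[j, i])),
                        lag=int(tdcc.lag[j, i]),
                    )
                )
    if include_self_loops and tdcc.self_cc is not None:
        for j in range(N):
            if abs(tdcc.self_cc[j]) >= threshold and tdcc.self_lag[j] > 0:
                edges.append(
                    Edge(
                        tdcc.gene_ids[j],
                        tdcc.gene_ids[j],
                        weight=abs(float(tdcc.self_cc[j])),
                        lag=int(tdcc.self_lag[j]),
                    )
                )
    return RegulatoryNetwork(tdcc.gene_ids, edges)
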