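"""Expression time-series container and tab-separated I/O.

The canonical on-disk format is a TSV with a ``time`` column followed by one
column per gene, one row per sampled time point — the layout short microarray
time courses are usually distributed in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExpressionTimeSeries:
    """A T x N matrix of expression levels sampled at increasing times.

    Parameters
    ----------
    gene_ids
        Unique gene names, one per column.
    times
        Strictly increasing sample times (arbitrary units), length T >= 3.
    values
        Real, finite expression levels, shape (T, N); non-negative by
        convention for abundance data, though negative values (e.g. log
        ratios) are accepted.
    """

    gene_ids: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        T, N = self.values.shape
        if T < 3:
            raise ValueError(f"need at least 3 time points, got {T}")
        if N < 2:
            raise ValueError(f"need at least 2 genes, got {N}")
        if len(self.times) != T:
            raise ValueError("times length does not match value rows")
        if len(self.gene_ids) != N:
            raise ValueError("gene_ids length does not match value columns")
        if len(set(self.gene_ids)) != N:
            raise ValueError("gene_ids must be pairwise distinct")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def is_uniform(self) -> bool:
        """True when the sampling grid is (numerically) equally spaced."""
        dts = np.diff(self.times)
        return bool(np.allclose(dts, dts[0]))

    def series(self, gene: int | str) -> np.ndarray:
        """Return one gene's expression series by index or name."""
        idx = gene if isinstance(gene, int) else self.gene_ids.index(gene)
        return self.values[:, idx]

    def check_uniform_for_lags(self) -> None:
        """Warn once if lags-in-samples are used on a non-uniform grid."""
        if not self.is_uniform:
            warnings.warn(
                "time grid is not uniform; lags are counted in samples, "
                "not time units",
                stacklevel=3,
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionTimeSeries":
        """Build from a DataFrame whose first column is the time stamp."""
        times = df.iloc[:, 0].to_numpy(dtype=float)
        genes = [str(c) for c in df.columns[1:]]
        return cls(gene_ids=genes, times=times, values=df.iloc[:, 1:].to_numpy(float))

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, columns=list(self.gene_ids))
        out.insert(0, "time", self.times)
        return out

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionTimeSeries":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)
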