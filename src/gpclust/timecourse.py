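"""Containers and I/O for replicate time-course expression data.

A :class:`TimeCourse` holds the observations of a single gene under a single
condition: strictly increasing observation times (days), a replicate matrix
(one row per time point), and the per-time-point observational noise
variances used as the diagonal noise matrix of the GP regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeCourse", "read_expression_table"]

#: Absolute floor on the observational noise variance.
NOISE_FLOOR_ABS = 1e-6
#: Relative floor, as a fraction of the median replicate variance.
NOISE_FLOOR_REL = 1e-3


@dataclass
class TimeCourse:
    """One gene x one condition of noisy time-course observations.

    Parameters
    ----------
    gene_id : str
        Gene identifier.
    condition : str
        Condition label (e.g. ``"case"`` / ``"control"``).
    times : ndarray, shape (n,)
        Observation times in days, strictly increasing.
    replicates : ndarray, shape (n, r)
        Observed values; one row per time point, NaN for missing replicates.
    noise_var : ndarray, shape (n,), optional
        Per-time-point observational variance.  When omitted it is set to
        the replicate sample variance at each time point, floored at
        ``max(NOISE_FLOOR_ABS, NOISE_FLOOR_REL * median variance)`` so the
        noise matrix stays invertible even with identical replicates.
    """

    gene_id: str
    condition: str
    times: np.ndarray
    replicates: np.ndarray
    noise_var: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.replicates = np.atleast_2d(np.asarray(self.replicates, dtype=float))
        if self.replicates.shape[0] != self.times.size:
            if self.replicates.shape[1] == self.times.size:
                self.replicates = self.replicates.T
            else:
                raise ValueError(
                    f"replicate matrix has {self.replicates.shape[0]} rows "
                    f"for {self.times.size} time points"
                )
        if self.times.size < 1 or not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite and non-empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            warnings.warn(
                f"{self.gene_id}/{self.condition}: negative observation times; "
                "data are assumed normalized so the perturbation occurs at t=0",
                stacklevel=2,
            )
        if self.noise_var is None:
            self.noise_var = self._replicate_noise()
        else:
            self.noise_var = np.asarray(self.noise_var, dtype=float)
            if self.noise_var.shape != self.times.shape:
                raise ValueError("noise_var must have one entry per time point")
            if np.any(self.noise_var <= 0):
                raise ValueError("noise_var must be positive")

    def _replicate_noise(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            var = np.nanvar(self.replicates, axis=1, ddof=1)
        var = np.where(np.isfinite(var), var, 0.0)
        med = np.median(var[var > 0]) if np.any(var > 0) else 0.0
        floor = max(NOISE_FLOOR_ABS, NOISE_FLOOR_REL * med)
        return np.maximum(var, floor)

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    @property
    def mean_values(self) -> np.ndarray:
        """Replicate-averaged observation at each time point."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.replicates, axis=1)


def read_expression_table(path_or_df, sep: str = "\t") -> list[TimeCourse]:
    """Read a long-format expression table into :class:`TimeCourse` objects.

    Expected columns: ``gene_id``, ``condition``, ``time_days``,
    ``replicate``, ``value``.  One :class:`TimeCourse` is produced per
    (gene, condition) pair; times are validated to be strictly increasing
    after the pivot.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep=sep)
    required = {"gene_id", "condition", "time_days", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    out: list[TimeCourse] = []
    for (gene, cond), grp in df.groupby(["gene_id", "condition"], sort=True):
        wide = grp.pivot_table(
            index="time_days", columns="replicate", values="value", aggfunc="mean"
        ).sort_index()
        out.append(
            TimeCourse(
                gene_id=str(gene),
                condition=str(cond),
                times=wide.index.to_numpy(dtype=float),
                replicates=wide.to_numpy(dtype=float),
            )
        )
    return out
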