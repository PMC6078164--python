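"""Core containers: circadian time grids and single-layer feature matrices.

Samples are columns named ``CT{hours}_r{replicate}`` (e.g. ``CT24_r1``);
circadian time (CT) is hours elapsed under constant conditions.  Phases are
reported modulo the period (24 h by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

_COLUMN_RE = re.compile(r"^CT(?P<time>\d+(?:\.\d+)?)_r(?P<rep>\d+)$")


@dataclass(frozen=True)
class TimeGrid:
    """Ordered circadian sampling design: one entry per sample column.

    Parameters
    ----------
    times
        CT hours of each sample, in column order.  Replicates repeat the
        same hour.
    replicates
        1-based replicate index of each sample.
    """

    times: tuple[float, ...]
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.replicates):
            raise ValueError("times and replicates must have equal length")
        if len(self.times) == 0:
            raise ValueError("empty time grid")

    @classmethod
    def regular(
        cls, start_h: float, end_h: float, step_h: float, n_replicates: int = 1
    ) -> "TimeGrid":
        """Evenly spaced grid from ``start_h`` to ``end_h`` inclusive."""
        if step_h <= 0:
            raise ValueError("step_h must be positive")
        pts = np.arange(start_h, end_h + 0.5 * step_h, step_h)
        times = tuple(float(t) for t in pts for _ in range(n_replicates))
        reps = tuple(r + 1 for _ in pts for r in range(n_replicates))
        return cls(times, reps)

    @classmethod
    def from_columns(cls, columns) -> "TimeGrid":
        """Parse a grid from ``CT{h}_r{rep}`` column names."""
        times, reps = [], []
        for c in columns:
            m = _COLUMN_RE.match(str(c))
            if m is None:
                raise ValueError(f"malformed sample column name: {c!r}")
            times.append(float(m.group("time")))
            reps.append(int(m.group("rep")))
        return cls(tuple(times), tuple(reps))

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def unique_times(self) -> np.ndarray:
        """Distinct CT hours in ascending order."""
        return np.unique(np.asarray(self.times))

    @property
    def n_timepoints(self) -> int:
        return len(self.unique_times)

    @property
    def step_h(self) -> float:
        """Sampling interval (smallest gap between distinct times)."""
        ut = self.unique_times
        if len(ut) < 2:
            raise ValueError("grid has a single time point")
        return float(np.min(np.diff(ut)))

    def column_names(self) -> list[str]:
        return [
            f"CT{int(t) if float(t).is_integer() else t}_r{r}"
            for t, r in zip(self.times, self.replicates)
        ]

    def time_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def timepoint_groups(self) -> list[np.ndarray]:
        """Column indices grouped by time point, ascending in time."""
        t = self.time_array()
        return [np.flatnonzero(t == u) for u in self.unique_times]

    def subset_window(self, start_h: float, end_h: float) -> np.ndarray:
        """Column indices with CT in the closed window [start_h, end_h]."""
        t = self.time_array()
        return np.flatnonzero((t >= start_h) & (t <= end_h))


@dataclass
class FeatureMatrix:
    """One omics layer: features x samples with grid and scale metadata.

    ``data`` is a pandas DataFrame indexed by feature id, columns named per
    the grid.  ``scale`` declares the analysis scale ('linear' for positive
    abundances such as FPKM, 'log' for log-ratio data); it is never
    inferred from the values.
    """

    data: pd.DataFrame
    grid: TimeGrid
    layer: str = "unknown"
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.data.shape[1] != self.grid.n_samples:
            raise ValueError(
                f"matrix has {self.data.shape[1]} sample columns but grid "
                f"defines {self.grid.n_samples}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dups[:5])}")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def timepoint_means(self) -> pd.DataFrame:
        """Average replicates: features x unique time points."""
        groups = self.grid.timepoint_groups()
        vals = self.values()
        out = np.column_stack(
            [np.nanmean(vals[:, g], axis=1) for g in groups]
        )
        return pd.DataFrame(out, index=self.data.index, columns=self.grid.unique_times)

    def subset_features(self, ids) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[ids], self.grid, self.layer, self.scale)


def circular_difference_h(a: np.ndarray, b: np.ndarray, period_h: float = 24.0) -> np.ndarray:
    """Signed circular difference a - b wrapped into [-period/2, period/2)."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period_h
    return np.where(d >= period_h / 2, d - period_h, d)
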