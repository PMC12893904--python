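"""Small assay summaries: TREC -dCt, trapezoid AUC, fold change from baseline.

Thymic output is quantified by qPCR of signal-joint T cell receptor excision
circles: dCt = Ct_TREC - Ct_TCRA over technical-duplicate means, reported as
-dCt so that higher values reflect greater relative TREC abundance.
Pharmacokinetic time courses are summarised by the trapezoid-rule AUC up to a
cutoff (default 48 h) and/or expressed as fold change from the t = 0 baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QpcrRecord",
    "TimeSeries",
    "trec_neg_delta_ct",
    "auc_trapezoid",
    "fold_change_series",
]


@dataclass
class QpcrRecord:
    sample_id: str
    ct_trec: Sequence[float]
    ct_tcra: Sequence[float]

    def validate(self) -> None:
        for name, vals in (("TREC", self.ct_trec), ("TCRA", self.ct_tcra)):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"missing Ct replicates for {name}")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"Ct values for {name} must be positive and finite")


@dataclass
class TimeSeries:
    """Time course with strictly increasing times (hours), values >= 0."""

    times: np.ndarray
    values: np.ndarray

    def __init__(self, times, values):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing (sorted, unique)")
        if np.any(self.values < 0):
            raise ValueError("values must be >= 0")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col="time_h", value_col="value"):
        return cls(df[time_col].to_numpy(), df[value_col].to_numpy())

    @property
    def baseline(self) -> float:
        if self.times[0] != 0:
            raise ValueError("series has no t = 0 baseline")
        return float(self.values[0])


def trec_neg_delta_ct(record: QpcrRecord) -> float:
    """-dCt = -(mean Ct_TREC - mean Ct_TCRA); higher = more TREC."""
    record.validate()
    return float(
        -(np.mean(np.asarray(record.ct_trec, dtype=float))
          - np.mean(np.asarray(record.ct_tcra, dtype=float)))
    )


def auc_trapezoid(series: TimeSeries, t_end: float = 48.0) -> float:
    """Trapezoid-rule area under the time course from t = 0 to ``t_end``.

    ``t_end`` must not exceed the last observed time; if it falls between
    observations, the value there is linearly interpolated before truncation.
    """
    if series.times[0] != 0:
        raise ValueError("AUC requires a t = 0 observation")
    if len(series.times) < 2:
        raise ValueError("need >= 2 timepoints")
    if t_end > series.times[-1]:
        raise ValueError("t_end exceeds the observed time range")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    keep = series.times <= t_end
    t = series.times[keep]
    v = series.values[keep]
    if t[-1] < t_end:
        v = np.append(v, np.interp(t_end, series.times, series.values))
        t = np.append(t, t_end)
    return float(np.trapezoid(v, t))


def fold_change_series(series: TimeSeries) -> TimeSeries:
    """Values divided by the t = 0 baseline (baseline maps to 1.0)."""
    base = series.baseline
    if base <= 0:
        raise ValueError("baseline must be > 0 for fold change")
    return TimeSeries(series.times, series.values / base)
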