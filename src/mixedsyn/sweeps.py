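"""Stack-of-sweeps container shared by the analysis and generator modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SweepSet"]


@dataclass
class SweepSet:
    """Aligned recording sweeps on a common time base.

    time : (T,) time base, ms
    data : (n_sweeps, T) values; mV for voltage sweeps, pA for current traces
    spike_time : presynaptic spike time (ms) for spike-triggered sweeps
    stim_onset / stim_duration / stim_amplitude : square-step metadata
        (ms, ms, pA) for step-response sweeps
    ground_truth : generator ground truth, when the sweeps are synthetic
    """

    time: np.ndarray
    data: np.ndarray
    units: str = "mV"
    spike_time: float | None = None
    stim_onset: float | None = None
    stim_duration: float | None = None
    stim_amplitude: float | None = None
    ground_truth: object | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != self.time.size:
            raise ValueError(
                f"data has {self.data.shape[1]} samples per sweep but the time "
                f"base has {self.time.size}"
            )

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return self.n_sweeps

    def sweep(self, i: int) -> np.ndarray:
        return self.data[i]

    def mean(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def subset(self, idx) -> "SweepSet":
        idx = np.asarray(idx)
        return SweepSet(
            time=self.time,
            data=self.data[idx],
            units=self.units,
            spike_time=self.spike_time,
            stim_onset=self.stim_onset,
            stim_duration=self.stim_duration,
            stim_amplitude=self.stim_amplitude,
            ground_truth=self.ground_truth,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: sweep, time_ms, value."""
        n, t = self.data.shape
        return pd.DataFrame(
            {
                "sweep": np.repeat(np.arange(n), t),
                "time_ms": np.tile(self.time, n),
                "value": self.data.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "SweepSet":
        required = {"sweep", "time_ms", "value"}
        if not required.issubset(df.columns):
            missing = required - set(df.columns)
            raise ValueError(f"sweep table is missing columns: {sorted(missing)}")
        sweeps = sorted(df["sweep"].unique())
        time = np.sort(df.loc[df["sweep"] == sweeps[0], "time_ms"].to_numpy())
        data = np.empty((len(sweeps), time.size))
        for k, s in enumerate(sweeps):
            sub = df[df["sweep"] == s].sort_values("time_ms")
            if sub.shape[0] != time.size:
                raise ValueError(f"sweep {s} has a different number of samples")
            data[k] = sub["value"].to_numpy()
        return cls(time=time, data=data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SweepSet":
        return cls.from_frame(pd.read_csv(Path(path)), **kwargs)
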