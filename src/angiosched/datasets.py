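"""Observed tumour-volume time series (one treatment arm each).

Delimited-text format: tab-separated with columns ``time_day``,
``volume_mm3`` and optionally ``sem_mm3``; the arm label and animal
count travel in the file name / constructor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ARMS = ("vehicle", "bvz", "folfox", "ts1", "ts2")


@dataclass(frozen=True)
class ArmDataset:
    """Mean tumour volume of one treatment arm at caliper-measurement
    times, with optional standard errors and animal count."""

    arm: str
    times: np.ndarray
    volumes: np.ndarray
    sem: np.ndarray | None = None
    n_animals: int | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        if self.sem is not None:
            object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        if times.ndim != 1 or times.shape != volumes.shape:
            raise ValueError("times and volumes must be 1-D and equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(volumes < 0):
            raise ValueError("volumes must be >= 0")
        if not np.any(volumes > 0):
            raise ValueError("arm has no non-zero volume to anchor a fit")

    @property
    def first_nonzero(self) -> int:
        """Index of the first non-zero volume — the fit anchor."""
        return int(np.argmax(self.volumes > 0))

    @property
    def fit_times(self) -> np.ndarray:
        return self.times[self.first_nonzero:]

    @property
    def fit_volumes(self) -> np.ndarray:
        return self.volumes[self.first_nonzero:]

    @property
    def v0(self) -> float:
        """Initial tumour volume for simulation: first non-zero value."""
        return float(self.volumes[self.first_nonzero])

    @property
    def k0(self) -> float:
        """Initial carrying capacity: five times the initial volume."""
        return 5.0 * self.v0

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_day": self.times, "volume_mm3": self.volumes})
        if self.sem is not None:
            df["sem_mm3"] = self.sem
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_arm(path, arm: str | None = None,
             n_animals: int | None = None) -> ArmDataset:
    path = Path(path)
    if arm is None:
        arm = path.stem.split("_")[0]
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    sem = df["sem_mm3"].to_numpy() if "sem_mm3" in df else None
    return ArmDataset(arm, df["time_day"].to_numpy(),
                      df["volume_mm3"].to_numpy(), sem, n_animals)
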