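"""Containers for fluorosequencing reads.

A read is a small matrix of fluorescence intensities, one row per imaging
timepoint and one column per color channel.  Datasets are stored densely as a
single ``(n_reads, n_timepoints, n_channels)`` array so that the simulator,
filters and fitters can operate vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReadMatrix", "ReadSet"]


@dataclass(frozen=True)
class ReadMatrix:
    """One read: ``(n_timepoints, n_channels)`` intensities plus an id."""

    intensities: np.ndarray
    read_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError("read intensities must be 2-D (timepoints x channels)")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"read {self.read_id!r} has non-finite intensities")
        object.__setattr__(self, "intensities", arr)


@dataclass
class ReadSet:
    """A dataset of reads with homogeneous shape.

    ``intensities`` has shape ``(n_reads, n_timepoints, n_channels)``;
    ``read_ids`` is aligned with the first axis.
    """

    intensities: np.ndarray
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("ReadSet intensities must be 3-D")
        if not self.read_ids:
            self.read_ids = [f"read{i}" for i in range(len(self.intensities))]
        if len(self.read_ids) != len(self.intensities):
            raise ValueError("read_ids length mismatch")

    def __len__(self) -> int:
        return len(self.intensities)

    @property
    def n_timepoints(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]

    def __getitem__(self, i: int) -> ReadMatrix:
        return ReadMatrix(self.intensities[i], self.read_ids[i])

    def subset(self, indices) -> "ReadSet":
        indices = np.asarray(indices)
        return ReadSet(
            self.intensities[indices],
            [self.read_ids[int(i)] for i in indices],
        )

    @classmethod
    def from_reads(cls, reads) -> "ReadSet":
        mats = [r.intensities if isinstance(r, ReadMatrix) else np.asarray(r) for r in reads]
        ids = [
            r.read_id if isinstance(r, ReadMatrix) else f"read{i}"
            for i, r in enumerate(reads)
        ]
        return cls(np.stack(mats), ids)
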