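"""Core domain types: peptide designs and the sequencing parameter vector.

A fluorosequencing run images a surface-attached peptide once before any
chemistry (timepoint 0) and once after each of ``n_cycles`` rounds of Edman
degradation, giving ``n_cycles + 1`` timepoints.  Each labeled residue carries
a fluorophore on one color channel; the observable at each timepoint is one
fluorescence intensity per channel.

The error model has six kinds of rate parameters:

* ``edman_failure_rate`` (e) -- per-cycle probability that Edman removal of the
  N-terminal residue fails;
* ``detach_rate`` (p) -- per-cycle probability the whole peptide leaves the
  surface;
* ``initial_block_rate`` (b) -- probability the N-terminus is chemically
  blocked before sequencing starts;
* ``cyclic_block_rate`` (c) -- per-cycle probability of acquiring a block;
* ``dye_loss_rate`` (l, per channel) -- per-cycle probability each individual
  fluorophore is destroyed (chemical destruction plus photobleaching);
* ``dud_rate`` (m, per channel) -- probability a fluorophore is dark or absent
  from the start.

The intensity model is a per-channel normal for a single fluorophore
(``mu``, ``sigma``) plus a background normal (``bg_mu``, ``bg_sigma``); a
state with k fluorophores on a channel emits
N(bg_mu + k*(mu - bg_mu), sqrt(bg_sigma^2 + k*sigma^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

__all__ = [
    "PeptideDesign",
    "SequencingParams",
    "RATE_NAMES",
    "rate_names_for",
    "identifiability_constraints",
]


@dataclass(frozen=True)
class PeptideDesign:
    """Dye-label layout of one peptide.

    Parameters
    ----------
    labels_by_channel
        For each color channel, the 1-based residue positions carrying that
        channel's dye.  Positions within a channel must be distinct.
    n_cycles
        Number of Edman cycles performed; reads have ``n_cycles + 1``
        timepoints (timepoint 0 is imaged before any chemistry).
    n_terminus
        Optional metadata recording the N-terminal chemistry from peptide
        notation ("NH2", "fmoc", "ac"); informational only, it does not change
        the model.
    """

    labels_by_channel: tuple[tuple[int, ...], ...]
    n_cycles: int
    n_terminus: str | None = None

    def __post_init__(self) -> None:
        labels = tuple(tuple(int(p) for p in ch) for ch in self.labels_by_channel)
        object.__setattr__(self, "labels_by_channel", labels)
        if not labels:
            raise ValueError("design needs at least one channel")
        if sum(len(ch) for ch in labels) == 0:
            raise ValueError("design needs at least one labeled position")
        for ch, positions in enumerate(labels):
            if any(p < 1 for p in positions):
                raise ValueError(f"channel {ch}: positions are 1-based (>= 1)")
            if len(set(positions)) != len(positions):
                raise ValueError(f"channel {ch}: duplicate label positions")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def n_channels(self) -> int:
        return len(self.labels_by_channel)

    @property
    def n_timepoints(self) -> int:
        return self.n_cycles + 1

    @property
    def label_counts(self) -> tuple[int, ...]:
        return tuple(len(ch) for ch in self.labels_by_channel)

    @property
    def total_labels(self) -> int:
        return sum(self.label_counts)

    def remaining_labels(self, n_edman: int) -> tuple[int, ...]:
        """Per-channel count of labels not yet removed after ``n_edman``
        successful Edman cycles (i.e. labels at positions > n_edman)."""
        return tuple(
            sum(1 for p in ch if p > n_edman) for ch in self.labels_by_channel
        )

    def labeled_channel_at(self, position: int) -> int | None:
        """Channel of the label at a 1-based residue position, or None."""
        for ch, positions in enumerate(self.labels_by_channel):
            if position in positions:
                return ch
        return None


# Scalar rate parameters, in canonical order; per-channel rates are appended
# as "dye_loss_rate[ch]" / "dud_rate[ch]" by rate_names_for().
RATE_NAMES = (
    "edman_failure_rate",
    "detach_rate",
    "initial_block_rate",
    "cyclic_block_rate",
)


def rate_names_for(design: PeptideDesign) -> tuple[str, ...]:
    """Canonical ordered names of all rate parameters for a design."""
    names = list(RATE_NAMES)
    names += [f"dye_loss_rate[{ch}]" for ch in range(design.n_channels)]
    names += [f"dud_rate[{ch}]" for ch in range(design.n_channels)]
    return tuple(names)


@dataclass(frozen=True)
class SequencingParams:
    """Full parameter vector for a sequencing experiment.

    Rates live in [0, 1); ``sigma`` and ``bg_sigma`` are positive; each
    channel's one-fluorophore mean must exceed the background mean.
    """

    edman_failure_rate: float
    detach_rate: float
    initial_block_rate: float
    cyclic_block_rate: float
    dye_loss_rate: tuple[float, ...]
    dud_rate: tuple[float, ...]
    mu: tuple[float, ...]
    sigma: tuple[float, ...]
    bg_sigma: float
    bg_mu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dye_loss_rate", "dud_rate", "mu", "sigma"):
            value = getattr(self, name)
            if isinstance(value, (int, float)):
                value = (float(value),)
            object.__setattr__(self, name, tuple(float(v) for v in value))
        n_ch = len(self.mu)
        for name in ("dye_loss_rate", "dud_rate", "sigma"):
            if len(getattr(self, name)) != n_ch:
                raise ValueError(f"{name} length does not match mu length {n_ch}")
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v} outside [0, 1)")
        for seq_name in ("dye_loss_rate", "dud_rate"):
            for v in getattr(self, seq_name):
                if not (0.0 <= v < 1.0):
                    raise ValueError(f"{seq_name} entry {v} outside [0, 1)")
        if any(s <= 0 for s in self.sigma) or self.bg_sigma <= 0:
            raise ValueError("sigma and bg_sigma must be > 0")
        if any(m <= self.bg_mu for m in self.mu):
            raise ValueError("each channel mu must exceed bg_mu")

    @property
    def n_channels(self) -> int:
        return len(self.mu)

    # -- name-based access used by the fitters -------------------------------

    def get_rate(self, name: str) -> float:
        base, ch = _split_rate_name(name)
        value = getattr(self, base)
        return value[ch] if ch is not None else value

    def with_rates(self, rates: Mapping[str, float]) -> "SequencingParams":
        """Return a copy with the named rates replaced."""
        updates: dict[str, object] = {}
        dye_loss = list(self.dye_loss_rate)
        dud = list(self.dud_rate)
        for name, value in rates.items():
            base, ch = _split_rate_name(name)
            if base == "dye_loss_rate":
                dye_loss[ch] = float(value)
            elif base == "dud_rate":
                dud[ch] = float(value)
            else:
                updates[base] = float(value)
        updates["dye_loss_rate"] = tuple(dye_loss)
        updates["dud_rate"] = tuple(dud)
        return replace(self, **updates)

    def rate_dict(self, design: PeptideDesign) -> dict[str, float]:
        return {name: self.get_rate(name) for name in rate_names_for(design)}


def _split_rate_name(name: str) -> tuple[str, int | None]:
    if name.endswith("]"):
        base, _, idx = name[:-1].partition("[")
        return base, int(idx)
    return name, None


def identifiability_constraints(design: PeptideDesign) -> dict[str, float]:
    """Parameters pinned during fitting for designs that cannot identify them.

    With a single fluorophore, dye loss and peptide detachment are visibly
    equivalent, all-dud peptides are never observed, and initial/cyclic
    blocking trade off freely against the Edman failure rate; so for one-label
    designs the detachment rate, all dud rates and the cyclic blocking rate
    are fixed to zero.  Designs with two or more labels leave all six rates
    free.
    """
    if design.total_labels != 1:
        return {}
    pins = {"detach_rate": 0.0, "cyclic_block_rate": 0.0}
    for ch in range(design.n_channels):
        pins[f"dud_rate[{ch}]"] = 0.0
    return pins
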