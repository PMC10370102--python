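"""Monte Carlo generative model of fluorosequencing reads.

Each simulated peptide carries its design's labels; duds are drawn per
fluorophore before sequencing, then each cycle applies the error mechanisms
in the same order as the model's transition factors (cyclic blocking,
detachment, per-fluorophore dye loss, Edman removal).  Intensities are
emitted at every timepoint from the per-count normal intensity model;
detached peptides keep emitting background noise (a detached spot looks like
background).

Peptides whose fluorophores are all dark at timepoint 0 never show up as
reads; by default they are re-drawn so the requested number of visible reads
is exact, with the invisible fraction available for censoring-bias tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .emission import emission_log_density, emission_mean_sd
from .params import PeptideDesign, SequencingParams
from .reads import ReadSet

__all__ = [
    "DyeTrack",
    "TrackHistogram",
    "simulate_reads",
    "reduce_to_dyetrack",
    "dyetrack_histogram",
    "histogram_rmse",
]


@dataclass(frozen=True)
class DyeTrack:
    """Integer fluorophore-count approximation of a read."""

    counts: np.ndarray  # (n_timepoints, n_channels) ints
    multiplicity: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 2 or np.any(arr < 0):
            raise ValueError("dye track counts must be a 2-D non-negative array")
        object.__setattr__(self, "counts", arr)


@dataclass(frozen=True)
class SimulationResult:
    reads: ReadSet
    truth_tracks: np.ndarray  # (n_reads, n_timepoints, n_channels) ints
    n_invisible_drawn: int  # all-dark peptides re-drawn (keep_invisible=False)


def _label_layout(design: PeptideDesign) -> tuple[np.ndarray, np.ndarray]:
    """Flattened label positions and their channels, sorted by position."""
    pos, chan = [], []
    for ch, positions in enumerate(design.labels_by_channel):
        for p in positions:
            pos.append(p)
            chan.append(ch)
    order = np.argsort(pos, kind="stable")
    return np.asarray(pos)[order], np.asarray(chan)[order]


def _stratified_fates(
    design: PeptideDesign,
    params: SequencingParams,
    n_reads: int,
    keep_invisible: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic largest-remainder allocation of reads over the joint
    (dud pattern x blocking time x detachment time) strata.

    Used by the RMSE fitter's internal simulations: the dud, blocking and
    detachment outcomes are allocated in exact proportion instead of
    sampled, which removes the dominant finite-simulation noise on the
    initial/cyclic block, detachment and dud rates -- the softest directions
    of the fit -- without changing the simulation's expectation.  Dye loss,
    Edman success and intensity noise are still sampled.

    Returns per-read arrays ``(alive0, block_time, detach_time)`` where
    ``block_time`` is 0 for an initial block, t >= 1 for a block acquired at
    cycle t, and n_cycles + 1 for never; ``detach_time`` is t >= 1 for
    detachment at cycle t and n_cycles + 1 for never.
    """
    positions, channels = _label_layout(design)
    n_labels = len(positions)
    t_cycles = design.n_cycles
    dud_per_label = np.array([params.dud_rate[ch] for ch in channels])
    b = params.initial_block_rate
    c = params.cyclic_block_rate
    p = params.detach_rate

    patterns: list[tuple[np.ndarray, float]] = []
    for pattern in itertools.product((True, False), repeat=n_labels):
        alive = np.array(pattern)
        if not keep_invisible and not alive.any():
            continue
        patterns.append(
            (alive, float(np.prod(np.where(alive, 1.0 - dud_per_label, dud_per_label))))
        )
    # block time: 0 (initial), 1..T (acquired at that cycle), T+1 (never)
    p_block = np.empty(t_cycles + 2)
    p_block[0] = b
    for t in range(1, t_cycles + 1):
        p_block[t] = (1.0 - b) * (1.0 - c) ** (t - 1) * c
    p_block[t_cycles + 1] = (1.0 - b) * (1.0 - c) ** t_cycles
    # detach time: 1..T (at that cycle), T+1 (never)
    p_det = np.empty(t_cycles + 1)
    for t in range(1, t_cycles + 1):
        p_det[t - 1] = (1.0 - p) ** (t - 1) * p
    p_det[t_cycles] = (1.0 - p) ** t_cycles

    strata_alive = []
    strata_block = []
    strata_det = []
    probs = []
    for alive, p_a in patterns:
        for bt in range(t_cycles + 2):
            for dt_i in range(t_cycles + 1):
                strata_alive.append(alive)
                strata_block.append(bt)
                strata_det.append(dt_i + 1)  # detach times are 1..T+1
                probs.append(p_a * p_block[bt] * p_det[dt_i])
    probs = np.asarray(probs)
    total = probs.sum()
    if total <= 0:
        raise ValueError("no visible stratum has positive probability")
    raw = probs / total * n_reads
    counts = np.floor(raw).astype(int)
    remainder = n_reads - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1

    alive0 = np.zeros((n_reads, n_labels), dtype=bool)
    block_time = np.zeros(n_reads, dtype=np.int64)
    detach_time = np.zeros(n_reads, dtype=np.int64)
    pos = 0
    for alive, bt, dt_i, cnt in zip(strata_alive, strata_block, strata_det, counts):
        alive0[pos : pos + cnt] = alive
        block_time[pos : pos + cnt] = bt
        detach_time[pos : pos + cnt] = dt_i
        pos += cnt
    return alive0, block_time, detach_time


def simulate_reads(
    design: PeptideDesign,
    params: SequencingParams,
    n_reads: int,
    seed=None,
    keep_invisible: bool = False,
    stratify_initial: bool = False,
) -> SimulationResult:
    """Draw ``n_reads`` fluorosequencing reads plus their pre-noise truth
    tracks.  Reproducible: the same seed gives byte-identical output.

    With ``stratify_initial`` the dud patterns and the blocking and
    detachment fates are allocated deterministically in exact proportion
    instead of sampled (a variance-reduction option used inside the
    dye-track RMSE objective); dye loss, Edman success and intensity noise
    are always sampled.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    positions, channels = _label_layout(design)
    n_labels = len(positions)
    t_points = design.n_timepoints
    n_ch = design.n_channels
    dud_per_label = np.array([params.dud_rate[ch] for ch in channels])
    loss_per_label = np.array([params.dye_loss_rate[ch] for ch in channels])

    n_invisible = 0
    block_time = detach_time = None
    if stratify_initial:
        alive, block_time, detach_time = _stratified_fates(
            design, params, n_reads, keep_invisible
        )
        blocked = block_time == 0
        detached = np.zeros(n_reads, dtype=bool)
    else:
        alive = rng.random((n_reads, n_labels)) >= dud_per_label
        if not keep_invisible:
            while True:
                dark = ~alive.any(axis=1)
                bad = int(dark.sum())
                if bad == 0:
                    break
                n_invisible += bad
                alive[dark] = rng.random((bad, n_labels)) >= dud_per_label
        blocked = rng.random(n_reads) < params.initial_block_rate
        detached = np.zeros(n_reads, dtype=bool)
    n_edman = np.zeros(n_reads, dtype=np.int64)

    truth = np.zeros((n_reads, t_points, n_ch), dtype=np.int64)

    def record(t: int) -> None:
        present = alive & (positions[None, :] > n_edman[:, None]) & ~detached[:, None]
        for ch in range(n_ch):
            truth[:, t, ch] = present[:, channels == ch].sum(axis=1)

    record(0)
    for t in range(1, t_points):
        if block_time is not None:
            blocked = block_time <= t
            detached = detach_time <= t
        else:
            active = ~detached
            blocked |= active & ~blocked & (
                rng.random(n_reads) < params.cyclic_block_rate
            )
            detached |= active & (rng.random(n_reads) < params.detach_rate)
        attached_dye = (
            alive & (positions[None, :] > n_edman[:, None]) & ~detached[:, None]
        )
        lost = attached_dye & (rng.random((n_reads, n_labels)) < loss_per_label)
        alive &= ~lost
        advance = (
            ~blocked
            & ~detached
            & (rng.random(n_reads) >= params.edman_failure_rate)
        )
        n_edman += advance
        record(t)

    intensities = np.empty((n_reads, t_points, n_ch))
    for ch in range(n_ch):
        mean, sd = emission_mean_sd(params, ch, truth[:, :, ch])
        intensities[:, :, ch] = rng.normal(mean, sd)

    reads = ReadSet(intensities)
    return SimulationResult(reads, truth, n_invisible)


def reduce_to_dyetrack(
    reads, params: SequencingParams, design: PeptideDesign
) -> np.ndarray:
    """Map each intensity independently to the fluorophore count maximizing
    the emission density (ties break toward the smaller count).

    Accepts a ReadSet or an (n_reads, n_timepoints, n_channels) array and
    returns integer counts of the same shape.
    """
    arr = reads.intensities if isinstance(reads, ReadSet) else np.asarray(reads, float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    counts = np.empty(arr.shape, dtype=np.int64)
    for ch in range(arr.shape[2]):
        k_max = design.label_counts[ch]
        k_values = np.arange(k_max + 1)
        logd = emission_log_density(
            arr[:, :, ch][:, :, None], k_values[None, None, :], params, ch
        )
        counts[:, :, ch] = np.argmax(logd, axis=2)  # first max -> smaller k
    return counts[0] if single else counts


@dataclass(frozen=True)
class TrackHistogram:
    """Counts of unique dye tracks; key equality is exact integer equality."""

    tracks: np.ndarray  # (n_unique, n_timepoints, n_channels)
    counts: np.ndarray  # (n_unique,)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict:
        return {
            tuple(map(tuple, track.tolist())): int(c)
            for track, c in zip(self.tracks, self.counts)
        }


def _as_track_array(tracks) -> np.ndarray:
    if isinstance(tracks, np.ndarray):
        arr = tracks
    else:
        mats = [t.counts if isinstance(t, DyeTrack) else np.asarray(t) for t in tracks]
        shapes = {m.shape for m in mats}
        if len(shapes) > 1:
            raise ValueError(f"heterogeneous track shapes: {sorted(shapes)}")
        arr = np.stack(mats) if mats else np.zeros((0, 0, 0), dtype=np.int64)
    if arr.ndim != 3:
        raise ValueError("tracks must be (n, timepoints, channels)")
    return arr.astype(np.int64)


def dyetrack_histogram(tracks) -> TrackHistogram:
    """Histogram of dye tracks.  ``tracks`` is a list of DyeTrack / 2-D
    arrays, or a single (n, timepoints, channels) integer array; counts sum
    to the number of input tracks."""
    arr = _as_track_array(tracks)
    if arr.shape[0] == 0:
        return TrackHistogram(arr, np.zeros(0, dtype=np.int64))
    multiplicity = None
    if not isinstance(tracks, np.ndarray):
        mult = [t.multiplicity if isinstance(t, DyeTrack) else 1 for t in tracks]
        multiplicity = np.asarray(mult, dtype=np.int64)
    flat = arr.reshape(arr.shape[0], -1)
    base = int(arr.max()) + 1
    width = flat.shape[1]
    if base > 1 and width * np.log2(base) < 62:
        powers = base ** np.arange(width, dtype=np.int64)
        codes = flat @ powers
        if multiplicity is None:
            uniq, counts = np.unique(codes, return_counts=True)
        else:
            uniq, inverse = np.unique(codes, return_inverse=True)
            counts = np.bincount(inverse, weights=multiplicity).astype(np.int64)
        # decode representative tracks
        rep = np.empty((len(uniq), width), dtype=np.int64)
        rest = uniq.copy()
        for j in range(width):
            rep[:, j] = rest % base
            rest //= base
        return TrackHistogram(rep.reshape((-1,) + arr.shape[1:]), counts)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    weights = multiplicity if multiplicity is not None else np.ones(len(flat), np.int64)
    counts = np.bincount(inverse, weights=weights).astype(np.int64)
    return TrackHistogram(uniq.reshape((-1,) + arr.shape[1:]), counts)


def histogram_rmse(
    data: TrackHistogram, simulated: TrackHistogram, scale: float = 1.0
) -> float:
    """Root-mean-square error between two dye-track count histograms.

    Simulated counts are multiplied by ``scale`` (typically
    n_data / n_simulated); the mean runs over the union of tracks present in
    either histogram.
    """
    if data.tracks.shape[0] == 0 and simulated.tracks.shape[0] == 0:
        return 0.0
    shapes = {
        h.tracks.shape[1:] for h in (data, simulated) if h.tracks.shape[0] > 0
    }
    if len(shapes) > 1:
        raise ValueError(f"histogram track shapes differ: {sorted(shapes)}")
    d_flat = data.tracks.reshape(data.tracks.shape[0], -1)
    s_flat = simulated.tracks.reshape(simulated.tracks.shape[0], -1)
    width = max(d_flat.shape[1], s_flat.shape[1])
    base = int(
        max(d_flat.max(initial=0), s_flat.max(initial=0))
    ) + 1
    if base < 2 or width * np.log2(base) >= 62:
        d = data.as_dict()
        s = {k: scale * v for k, v in simulated.as_dict().items()}
        keys = set(d) | set(s)
        sq = [(d.get(k, 0.0) - s.get(k, 0.0)) ** 2 for k in keys]
        return float(np.sqrt(np.mean(sq)))
    powers = base ** np.arange(width, dtype=np.int64)
    d_codes = d_flat @ powers if d_flat.shape[0] else np.zeros(0, np.int64)
    s_codes = s_flat @ powers if s_flat.shape[0] else np.zeros(0, np.int64)
    merged = np.unique(np.concatenate([d_codes, s_codes]))
    d_counts = np.zeros(len(merged))
    s_counts = np.zeros(len(merged))
    d_counts[np.searchsorted(merged, d_codes)] = data.counts
    s_counts[np.searchsorted(merged, s_codes)] = simulated.counts * scale
    return float(np.sqrt(np.mean((d_counts - s_counts) ** 2)))
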