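"""Fluorescence intensity model: per-count emission densities, per-channel
mu/sigma estimation from one-fluorophore intensity histograms, and
contaminant filtering of reads.

A state carrying k fluorophores on a channel emits the sum of k independent
one-dye signals plus background:

    intensity ~ Normal(bg_mu + k * (mu - bg_mu), sqrt(bg_sigma^2 + k * sigma^2))

Contaminants (dust, signal bleed-over from neighboring peaks) show up as
intensities outside the ranges plausible for any fluorophore count; reads
containing any such value are dropped before fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .params import SequencingParams
from .reads import ReadSet

__all__ = [
    "emission_mean_sd",
    "emission_density",
    "emission_log_density",
    "read_emission_table",
    "fit_channel_distribution",
    "IntensityFilter",
    "filter_reads",
]

_HWHM_TO_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))


def emission_mean_sd(
    params: SequencingParams, channel: int, count
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard deviation of the intensity for ``count`` fluorophores."""
    count = np.asarray(count)
    if np.any(count < 0):
        raise ValueError("fluorophore count must be >= 0")
    mean = params.bg_mu + count * (params.mu[channel] - params.bg_mu)
    sd = np.sqrt(params.bg_sigma**2 + count * params.sigma[channel] ** 2)
    return mean, sd


def emission_log_density(
    intensity, count, params: SequencingParams, channel: int
) -> np.ndarray:
    mean, sd = emission_mean_sd(params, channel, count)
    z = (np.asarray(intensity, dtype=float) - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * math.log(2.0 * math.pi)


def emission_density(intensity, count, params: SequencingParams, channel: int):
    """Normal density of one intensity value under the count-k model."""
    return np.exp(emission_log_density(intensity, count, params, channel))


def read_emission_table(
    intensities: np.ndarray, space, params: SequencingParams
) -> np.ndarray:
    """Log emission densities for a batch of reads against every state.

    ``intensities`` has shape (n_reads, n_timepoints, n_channels); the result
    has shape (n_reads, n_timepoints, n_states), summed over channels.  The
    detached state has zero counts and therefore emits background.
    """
    intensities = np.asarray(intensities, dtype=float)
    n, t, c = intensities.shape
    s = space.n_states
    out = np.zeros((n, t, s))
    for ch in range(c):
        counts = space.counts[:, ch]
        k_values = np.arange(counts.max() + 1)
        # (N, T, K): log density of each observed value under each count
        logd = emission_log_density(
            intensities[:, :, ch][:, :, None], k_values[None, None, :], params, ch
        )
        out += logd[:, :, counts]
    return out


def fit_channel_distribution(
    one_count_intensities, grid_size: int = 2048
) -> tuple[float, float]:
    """Estimate a channel's one-fluorophore (mu, sigma) from raw intensities.

    The histogram is smoothed with a Gaussian kernel density estimate; mu is
    the smoothed mode and sigma is the half-width at half-maximum of the peak
    divided by sqrt(2 ln 2).  Robust to moderate skew and to minority
    contaminant modes (the dominant mode wins).
    """
    values = np.asarray(one_count_intensities, dtype=float).ravel()
    if values.size < 100:
        raise ValueError(f"need >= 100 intensity values, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite intensity values")
    spread = values.max() - values.min()
    if spread == 0.0 or np.std(values) == 0.0:
        raise ValueError("degenerate (constant) intensity values")
    kde = gaussian_kde(values)
    pad = 0.1 * spread
    grid = np.linspace(values.min() - pad, values.max() + pad, grid_size)
    density = kde(grid)
    peak = int(np.argmax(density))
    mu = float(grid[peak])
    half = density[peak] / 2.0
    left = _half_crossing(grid, density, peak, half, direction=-1)
    right = _half_crossing(grid, density, peak, half, direction=+1)
    widths = [w for w in (left, right) if w is not None]
    if not widths:
        raise ValueError("flat histogram: no half-maximum crossing found")
    hwhm = float(np.mean(widths))
    return mu, hwhm * _HWHM_TO_SIGMA


def _half_crossing(grid, density, peak, half, direction):
    i = peak
    while 0 < i < len(grid) - 1:
        j = i + direction
        if density[j] <= half:
            # linear interpolation between grid[i] and grid[j]
            frac = (density[i] - half) / (density[i] - density[j])
            x = grid[i] + frac * (grid[j] - grid[i])
            return abs(x - grid[peak])
        i = j
    return None


@dataclass(frozen=True)
class IntensityFilter:
    """Per-channel closed allowed intensity intervals.

    ``allowed`` maps a channel index to a sorted list of non-overlapping
    ``(lo, hi)`` closed intervals.  Channels absent from the mapping (or
    mapped to an empty list) are unrestricted.
    """

    allowed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {}
        for ch, intervals in self.allowed.items():
            ivs = sorted((float(lo), float(hi)) for lo, hi in intervals)
            for lo, hi in ivs:
                if lo > hi:
                    raise ValueError(f"channel {ch}: interval ({lo}, {hi}) inverted")
            for (_, hi_a), (lo_b, _) in zip(ivs, ivs[1:]):
                if lo_b <= hi_a:
                    raise ValueError(f"channel {ch}: overlapping intervals")
            normalized[int(ch)] = ivs
        object.__setattr__(self, "allowed", normalized)

    def mask_allowed(self, channel: int, values: np.ndarray) -> np.ndarray:
        """Boolean mask: True where the value lies in some allowed interval."""
        intervals = self.allowed.get(channel, [])
        if not intervals:
            return np.ones_like(values, dtype=bool)
        ok = np.zeros_like(values, dtype=bool)
        for lo, hi in intervals:
            ok |= (values >= lo) & (values <= hi)
        return ok

    @classmethod
    def from_config(cls, spec: dict) -> "IntensityFilter":
        """Build from a config mapping ``{channel: [[lo, hi], ...]}``."""
        return cls({int(ch): [tuple(iv) for iv in ivs] for ch, ivs in spec.items()})


def filter_reads(reads: ReadSet, filt: IntensityFilter) -> tuple[ReadSet, int]:
    """Remove reads containing any out-of-range intensity.

    A read is removed iff any single intensity at any timepoint lies outside
    every allowed interval of its channel (interval bounds are inclusive).
    Order of the kept reads is preserved.
    """
    for ch in filt.allowed:
        if ch >= reads.n_channels:
            raise ValueError(f"filter channel {ch} not present in reads")
    keep = np.ones(len(reads), dtype=bool)
    for ch in range(reads.n_channels):
        ok = filt.mask_allowed(ch, reads.intensities[:, :, ch])
        keep &= ok.all(axis=1)
    kept = reads.subset(np.nonzero(keep)[0])
    return kept, int((~keep).sum())
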