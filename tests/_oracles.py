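"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's factored-matrix code paths: the
one-cycle transition matrix is built by explicit enumeration of joint
mechanism outcomes, and the likelihood oracle sums over every state path.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import binom, norm

from fluorofit.params import PeptideDesign, SequencingParams


def unfactored_cycle_matrix(design: PeptideDesign, params: SequencingParams, space):
    """One-cycle transition matrix from joint enumeration of (blocking,
    detachment, per-fluorophore loss, Edman) outcomes per starting state."""
    s = space.n_states
    det = space.detached_index
    m = np.zeros((s, s))
    m[det, det] = 1.0
    for i, (n, counts, blk) in enumerate(space.states):
        # blocking
        block_branches = [(1.0, True)] if blk else [
            (params.cyclic_block_rate, True),
            (1.0 - params.cyclic_block_rate, False),
        ]
        for p_blk, blocked in block_branches:
            # detachment
            for p_det, detached in (
                (params.detach_rate, True),
                (1.0 - params.detach_rate, False),
            ):
                if detached:
                    m[i, det] += p_blk * p_det
                    continue
                # dye loss, independently per channel
                loss_options = []
                for ch, k in enumerate(counts):
                    loss_options.append(
                        [
                            (binom.pmf(j, k, params.dye_loss_rate[ch]), k - j)
                            for j in range(k + 1)
                        ]
                    )
                for combo in itertools.product(*loss_options):
                    p_loss = math.prod(p for p, _ in combo)
                    k_after = tuple(k for _, k in combo)
                    # Edman
                    if blocked:
                        j = space.state_index(n, k_after, True)
                        m[i, j] += p_blk * p_det * p_loss
                        continue
                    e = params.edman_failure_rate
                    j = space.state_index(n, k_after, False)
                    m[i, j] += p_blk * p_det * p_loss * e
                    if n >= design.n_cycles:
                        m[i, j] += p_blk * p_det * p_loss * (1.0 - e)
                        continue
                    ch = design.labeled_channel_at(n + 1)
                    if ch is None:
                        j = space.state_index(n + 1, k_after, False)
                        m[i, j] += p_blk * p_det * p_loss * (1.0 - e)
                    else:
                        remaining = design.remaining_labels(n)[ch]
                        p_live = k_after[ch] / remaining
                        if p_live > 0:
                            down = list(k_after)
                            down[ch] -= 1
                            j = space.state_index(n + 1, tuple(down), False)
                            m[i, j] += p_blk * p_det * p_loss * (1.0 - e) * p_live
                        if p_live < 1:
                            j = space.state_index(n + 1, k_after, False)
                            m[i, j] += (
                                p_blk * p_det * p_loss * (1.0 - e) * (1.0 - p_live)
                            )
    return m


def state_emission_pdf(read_t, counts, params: SequencingParams) -> float:
    """Per-state emission density straight from scipy.stats.norm."""
    out = 1.0
    for ch, k in enumerate(counts):
        mean = params.bg_mu + k * (params.mu[ch] - params.bg_mu)
        sd = math.sqrt(params.bg_sigma**2 + k * params.sigma[ch] ** 2)
        out *= norm.pdf(read_t[ch], mean, sd)
    return out


def path_sum_log_likelihood(
    read: np.ndarray,
    design: PeptideDesign,
    params: SequencingParams,
    space,
    pi: np.ndarray,
) -> float:
    """Exhaustive sum over all state paths of the joint density."""
    m = unfactored_cycle_matrix(design, params, space)
    s = space.n_states
    t_points = design.n_timepoints
    counts_of = [
        space.counts[i] if i != space.detached_index else space.counts[i]
        for i in range(s)
    ]
    e = np.array(
        [
            [state_emission_pdf(read[t], counts_of[i], params) for i in range(s)]
            for t in range(t_points)
        ]
    )
    total = 0.0
    for path in itertools.product(range(s), repeat=t_points):
        pr = pi[path[0]] * e[0, path[0]]
        if pr == 0.0:
            continue
        for t in range(1, t_points):
            pr *= m[path[t - 1], path[t]] * e[t, path[t]]
            if pr == 0.0:
                break
        total += pr
    return math.log(total)
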