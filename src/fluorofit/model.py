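"""Merged-state hidden Markov model of fluorosequencing with a factored
transition matrix.

States track only what the observables can distinguish: the number of
successful Edman cycles so far, the count of live fluorophores on each color
channel, and whether the N-terminus is blocked; one extra absorbing state
represents a detached peptide.  Merging all label configurations with the
same counts keeps the state space polynomial in the number of labels.

Each sequencing cycle's transition matrix is factored into one sparse,
row-stochastic matrix per error mechanism (cyclic N-terminal blocking,
peptide detachment, per-channel dye loss, Edman removal).  The factorization
is exact -- the product of a cycle's factors equals the unfactored one-cycle
transition matrix -- and it isolates each error type on its own sub-transition,
which is what lets the EM fitter attribute posterior probability mass to
individual physical parameters.

The forward/backward pass runs factor by factor ("sub-steps"), scaled per
timepoint to avoid underflow, and returns state posteriors at every sub-step
plus sub-transition posteriors across every factor application.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.stats import binom

from .emission import read_emission_table
from .params import PeptideDesign, SequencingParams

__all__ = [
    "StateSpace",
    "TransitionFactor",
    "TransitionFactorSet",
    "KappaDistribution",
    "build_state_space",
    "initial_distribution",
    "transition_factors",
    "pre_sequencing_factor",
    "forward_backward",
    "kappa_distribution",
    "DEFAULT_FACTOR_ORDER",
]

# Order in which error mechanisms act within one cycle.  Blocking precedes
# Edman so an acquired block gates removal within the same cycle; dye loss
# precedes imaging because destruction happens during the chemistry
# incubations.  "dye_loss" expands to one factor per channel.
DEFAULT_FACTOR_ORDER: tuple[str, ...] = ("cyclic_block", "detach", "dye_loss", "edman")

# Rates exactly 0 or 1 are clamped inside likelihood evaluation so that log
# quantities stay finite; reported estimates are never clamped.
_CLAMP = 1e-9


@dataclass(frozen=True)
class StateSpace:
    """Merged HMM state space for one peptide design.

    States are ordered canonically: ascending number of successful Edman
    cycles, then per-channel counts (lexicographic), then blocked flag
    (unblocked first); the detached state is last.
    """

    design: PeptideDesign
    states: tuple[tuple[int, tuple[int, ...], bool], ...]
    detached_index: int
    n_edman: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    blocked: np.ndarray = field(repr=False)
    attached: np.ndarray = field(repr=False)
    blocked_twin: np.ndarray = field(repr=False)
    index: dict = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.states) + 1

    def state_index(self, n_edman: int, counts: tuple[int, ...], blocked: bool) -> int:
        return self.index[(n_edman, tuple(counts), blocked)]

    def to_jsonable(self) -> dict:
        return {
            "states": [
                {"n_edman": int(n), "counts": list(map(int, k)), "blocked": bool(b)}
                for (n, k, b) in self.states
            ],
            "detached_index": self.detached_index,
        }


def build_state_space(design: PeptideDesign) -> StateSpace:
    """Enumerate merged states (Edman count x per-channel fluorophore counts
    x blocked flag) plus the detached absorbing state.

    A channel's count after ``n`` successful Edman cycles can never exceed the
    number of that channel's labels still attached (positions > n).
    """
    states: list[tuple[int, tuple[int, ...], bool]] = []
    for n in range(design.n_cycles + 1):
        remaining = design.remaining_labels(n)
        for counts in itertools.product(*(range(r + 1) for r in remaining)):
            for blocked in (False, True):
                states.append((n, counts, blocked))
    detached_index = len(states)
    index = {s: i for i, s in enumerate(states)}
    s = len(states) + 1
    n_edman = np.zeros(s, dtype=np.int64)
    counts_arr = np.zeros((s, design.n_channels), dtype=np.int64)
    blocked = np.zeros(s, dtype=bool)
    attached = np.ones(s, dtype=bool)
    twin = np.arange(s)
    for i, (n, k, b) in enumerate(states):
        n_edman[i] = n
        counts_arr[i] = k
        blocked[i] = b
        twin[i] = index[(n, k, not b)]
    attached[detached_index] = False
    n_edman[detached_index] = -1
    return StateSpace(
        design=design,
        states=tuple(states),
        detached_index=detached_index,
        n_edman=n_edman,
        counts=counts_arr,
        blocked=blocked,
        attached=attached,
        blocked_twin=twin,
        index=index,
    )


@dataclass(frozen=True)
class TransitionFactor:
    """One sparse row-stochastic factor of a cycle's transition matrix."""

    name: str
    matrix: sparse.csr_array
    param_names: tuple[str, ...]

    def check_row_stochastic(self, tol: float = 1e-12) -> None:
        rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
        if not np.allclose(rowsum, 1.0, atol=tol, rtol=0.0):
            raise AssertionError(f"factor {self.name} rows do not sum to 1")


@dataclass(frozen=True)
class TransitionFactorSet:
    """Ordered factors applied within one cycle (or pre-sequencing)."""

    factors: tuple[TransitionFactor, ...]

    def __iter__(self):
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    def product(self) -> np.ndarray:
        """Dense product of the factors: the unfactored one-cycle matrix."""
        out = None
        for f in self.factors:
            m = f.matrix.toarray()
            out = m if out is None else out @ m
        return out

    def to_jsonable(self) -> dict:
        return {
            f.name: {
                "params": list(f.param_names),
                "rows": f.matrix.tocoo().row.tolist(),
                "cols": f.matrix.tocoo().col.tolist(),
                "values": f.matrix.tocoo().data.tolist(),
            }
            for f in self.factors
        }


def _clamp_rate(r: float) -> float:
    return min(max(r, _CLAMP), 1.0 - _CLAMP)


def _block_factor(space: StateSpace, rate: float, name: str) -> TransitionFactor:
    rows, cols, vals = [], [], []
    for i in range(space.n_states):
        if space.attached[i] and not space.blocked[i]:
            rows += [i, i]
            cols += [i, int(space.blocked_twin[i])]
            vals += [1.0 - rate, rate]
        else:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
    m = sparse.csr_array(
        (vals, (rows, cols)), shape=(space.n_states, space.n_states)
    )
    param = "initial_block_rate" if name == "initial_block" else "cyclic_block_rate"
    return TransitionFactor(name, m, (param,))


def _detach_factor(space: StateSpace, rate: float) -> TransitionFactor:
    d = space.detached_index
    rows, cols, vals = [], [], []
    for i in range(space.n_states):
        if space.attached[i]:
            rows += [i, i]
            cols += [i, d]
            vals += [1.0 - rate, rate]
        else:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
    m = sparse.csr_array((vals, (rows, cols)), shape=(space.n_states, space.n_states))
    return TransitionFactor("detach", m, ("detach_rate",))


def _dye_loss_factor(space: StateSpace, rate: float, channel: int) -> TransitionFactor:
    rows, cols, vals = [], [], []
    for i in range(space.n_states):
        if not space.attached[i]:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
            continue
        n = int(space.n_edman[i])
        k = int(space.counts[i, channel])
        base = space.counts[i].copy()
        for lost in range(k + 1):
            target = base.copy()
            target[channel] = k - lost
            j = space.state_index(n, tuple(target), bool(space.blocked[i]))
            rows.append(i)
            cols.append(j)
            vals.append(float(binom.pmf(lost, k, rate)))
    m = sparse.csr_array((vals, (rows, cols)), shape=(space.n_states, space.n_states))
    return TransitionFactor(f"dye_loss[{channel}]", m, (f"dye_loss_rate[{channel}]",))


def _edman_factor(
    space: StateSpace, rate: float, design: PeptideDesign
) -> TransitionFactor:
    """Edman removal: unblocked attached states advance with probability 1-e.

    When the removed residue (position n+1) carries a label on channel ch, the
    merged state cannot know whether that particular fluorophore is still
    alive; given k live fluorophores among the R labels of that channel still
    attached, the removed one is live with hypergeometric probability k/R, in
    which case the channel count decrements.
    """
    rows, cols, vals = [], [], []
    n_cycles = design.n_cycles
    for i in range(space.n_states):
        if (
            not space.attached[i]
            or space.blocked[i]
            or int(space.n_edman[i]) >= n_cycles
        ):
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
            continue
        n = int(space.n_edman[i])
        counts = space.counts[i]
        # failure: stay put
        rows.append(i)
        cols.append(i)
        vals.append(rate)
        ch = design.labeled_channel_at(n + 1)
        if ch is None:
            j = space.state_index(n + 1, tuple(counts), False)
            rows.append(i)
            cols.append(j)
            vals.append(1.0 - rate)
        else:
            r_remaining = design.remaining_labels(n)[ch]
            k = int(counts[ch])
            p_live = k / r_remaining
            if p_live > 0.0:
                down = counts.copy()
                down[ch] = k - 1
                j = space.state_index(n + 1, tuple(down), False)
                rows.append(i)
                cols.append(j)
                vals.append((1.0 - rate) * p_live)
            if p_live < 1.0:
                j = space.state_index(n + 1, tuple(counts), False)
                rows.append(i)
                cols.append(j)
                vals.append((1.0 - rate) * (1.0 - p_live))
    m = sparse.csr_array((vals, (rows, cols)), shape=(space.n_states, space.n_states))
    return TransitionFactor("edman", m, ("edman_failure_rate",))


def transition_factors(
    params: SequencingParams,
    space: StateSpace,
    cycle_index: int,
    order: tuple[str, ...] = DEFAULT_FACTOR_ORDER,
    clamp: bool = False,
) -> TransitionFactorSet:
    """Sparse factors of the transition matrix for one cycle, in mechanism
    order.  ``cycle_index`` runs from 1 to ``n_cycles``; the factors are the
    same for every cycle (the Edman count is part of the state), so the index
    only gates validity.
    """
    design = space.design
    if not (1 <= cycle_index <= design.n_cycles):
        raise ValueError(f"cycle_index {cycle_index} outside [1, {design.n_cycles}]")
    fix = _clamp_rate if clamp else (lambda r: r)
    factors: list[TransitionFactor] = []
    for name in order:
        if name == "cyclic_block":
            factors.append(
                _block_factor(space, fix(params.cyclic_block_rate), "cyclic_block")
            )
        elif name == "detach":
            factors.append(_detach_factor(space, fix(params.detach_rate)))
        elif name == "dye_loss":
            for ch in range(design.n_channels):
                factors.append(
                    _dye_loss_factor(space, fix(params.dye_loss_rate[ch]), ch)
                )
        elif name == "edman":
            factors.append(_edman_factor(space, fix(params.edman_failure_rate), design))
        else:
            raise ValueError(f"unknown factor name {name!r}")
    return TransitionFactorSet(tuple(factors))


def pre_sequencing_factor(
    params: SequencingParams, space: StateSpace, clamp: bool = False
) -> TransitionFactor:
    """The initial N-terminal blocking factor, applied once before timepoint 0."""
    rate = _clamp_rate(params.initial_block_rate) if clamp else params.initial_block_rate
    return _block_factor(space, rate, "initial_block")


def initial_dud_distribution(
    params: SequencingParams,
    space: StateSpace,
    condition_on_visible: bool,
    clamp: bool = False,
) -> np.ndarray:
    """Distribution over states at the first sub-step, before the initial
    blocking factor: Edman count 0, unblocked, per-channel counts independent
    Binomial(labels_ch, 1 - dud_rate_ch).

    With ``condition_on_visible`` the all-dark states (every channel count
    zero) receive zero mass and the vector is renormalized: a peptide whose
    fluorophores are all duds never appears as a read.
    """
    design = space.design
    pi = np.zeros(space.n_states)
    fix = _clamp_rate if clamp else (lambda r: r)
    duds = [fix(m) for m in params.dud_rate]
    for n, k, blocked in space.states:
        if n != 0 or blocked:
            continue
        prob = 1.0
        for ch, labels in enumerate(design.label_counts):
            prob *= binom.pmf(k[ch], labels, 1.0 - duds[ch])
        pi[space.state_index(0, k, False)] = prob
    if condition_on_visible:
        dark = (space.counts.sum(axis=1) == 0) & (np.arange(space.n_states) != space.detached_index)
        pi[dark] = 0.0
        total = pi.sum()
        if total <= 0:
            raise ValueError("no visible initial state has positive probability")
        pi /= total
    return pi


def initial_distribution(
    params: SequencingParams, space: StateSpace, condition_on_visible: bool = False
) -> np.ndarray:
    """State distribution at timepoint 0: dud realization followed by initial
    N-terminal blocking (probability b of landing on the blocked twin)."""
    pi = initial_dud_distribution(params, space, condition_on_visible)
    block = pre_sequencing_factor(params, space).matrix
    return pi @ block


# ---------------------------------------------------------------------------
# forward/backward over sub-steps


@dataclass
class FBResult:
    """Full forward/backward output for a single read.

    ``gammas[s]`` is the posterior state distribution at sub-step ``s`` (in
    timeline order, labels in ``sub_steps``); ``xis`` holds one
    ``(factor_label, cycle, xi)`` triple per factor application, where
    ``xi[i, j]`` is the posterior probability of the sub-transition i -> j.
    """

    log_likelihood: float
    sub_steps: list[str]
    gammas: list[np.ndarray]
    xis: list[tuple[str, int, np.ndarray]]


def forward_backward(
    read: np.ndarray,
    design: PeptideDesign,
    params: SequencingParams,
    condition_on_visible: bool = True,
    order: tuple[str, ...] = DEFAULT_FACTOR_ORDER,
    space: StateSpace | None = None,
) -> FBResult:
    """Scaled forward/backward pass for one read, factor by factor.

    The read is an ``(n_cycles + 1, n_channels)`` array of intensities.
    Emission densities are applied at each timepoint; scaling is per
    timepoint, so the log-likelihood is the sum of log scale factors.
    """
    read = np.asarray(read, dtype=float)
    if space is None:
        space = build_state_space(design)
    if read.shape != (design.n_timepoints, design.n_channels):
        raise ValueError(
            f"read shape {read.shape} does not match design "
            f"({design.n_timepoints}, {design.n_channels})"
        )
    # emission table: linear densities rescaled per timepoint by their max
    log_e = read_emission_table(read[None, :, :], space, params)[0]  # (T, S)
    log_e_max = log_e.max(axis=1)
    e_norm = np.exp(log_e - log_e_max[:, None])

    factors = [pre_sequencing_factor(params, space, clamp=True)]
    cycle_of_factor = [0]
    per_cycle = transition_factors(params, space, 1, order=order, clamp=True)
    for t in range(1, design.n_timepoints):
        for f in per_cycle:
            factors.append(f)
            cycle_of_factor.append(t)
    k = len(per_cycle)
    # emission t applies after flat factor index 1 + t*k (index 1 for t=0)

    pi = initial_dud_distribution(params, space, condition_on_visible, clamp=True)

    # forward over sub-steps; alphas[s] is the scaled forward vector at
    # sub-step s (s = 0 is the dud sub-step, then one per factor application)
    alphas: list[np.ndarray] = [pi.copy()]
    log_c: list[float] = []
    a = pi.copy()
    for f_idx, f in enumerate(factors, start=1):
        a = a @ f.matrix
        t = _emission_timepoint(f_idx, k, design.n_timepoints)
        if t is not None:
            w = a * e_norm[t]
            c = w.sum()
            c = max(c, 1e-300)
            a = w / c
            log_c.append(math.log(c) + log_e_max[t])
        alphas.append(a.copy())
    log_likelihood = float(sum(log_c))

    # backward; betas[s] aligned with alphas[s]
    s_total = len(alphas)
    betas: list[np.ndarray | None] = [None] * s_total
    b = np.ones(space.n_states)
    betas[s_total - 1] = b.copy()
    for f_idx in range(len(factors), 0, -1):
        t = _emission_timepoint(f_idx, k, design.n_timepoints)
        if t is not None:
            c = math.exp(log_c[t] - log_e_max[t])
            b = b * e_norm[t] / c
        b = factors[f_idx - 1].matrix @ b
        betas[f_idx - 1] = b.copy()

    sub_steps = ["dud"]
    gammas: list[np.ndarray] = []
    xis: list[tuple[str, int, np.ndarray]] = []
    for s in range(s_total):
        # alpha at sub-step s excludes emission at the pending timepoint only
        # when recorded pre-normalization; with per-timepoint scaling the
        # product alpha*beta is the posterior at every sub-step.
        g = alphas[s] * betas[s]
        gammas.append(g)
    for f_idx, f in enumerate(factors, start=1):
        t = _emission_timepoint(f_idx, k, design.n_timepoints)
        # beta at the post-factor sub-step *before* emission reweighting:
        if t is not None:
            c = math.exp(log_c[t] - log_e_max[t])
            b_post = betas[f_idx] * e_norm[t] / c
        else:
            b_post = betas[f_idx]
        xi = np.outer(alphas[f_idx - 1], b_post) * f.matrix.toarray()
        xis.append((f.name, cycle_of_factor[f_idx - 1], xi))
        sub_steps.append(f"{f.name}@{cycle_of_factor[f_idx - 1]}")
    return FBResult(log_likelihood, sub_steps, gammas, xis)


def _emission_timepoint(factor_idx: int, factors_per_cycle: int, n_timepoints: int):
    """Timepoint whose emission applies immediately after flat factor index
    ``factor_idx`` (1-based), or None."""
    if factor_idx == 1:
        return 0
    offset = factor_idx - 1
    if offset % factors_per_cycle == 0:
        t = offset // factors_per_cycle
        if t < n_timepoints:
            return t
    return None


# ---------------------------------------------------------------------------
# analytic single-fluorophore distribution


@dataclass(frozen=True)
class KappaDistribution:
    """Distribution of the last visible cycle of a single fluorophore.

    For a peptide with one fluorophore at 1-based position ``r`` and only the
    Edman failure rate e, initial block rate b, and cyclic block rate c
    non-zero, ``kappa[i]`` is the probability that the fluorophore's last
    cycle is cycle ``r + i``:

        kappa_i = (1 - b) * C(i + r - 1, i) * (1 - e)^r * e^i * (1 - c)^(r + i)

    Probability mass may remain on "never removed" outcomes (blocking), so
    the kappas need not sum to 1.
    """

    r: int
    kappa: np.ndarray
    i_max: int

    def ratios(self) -> np.ndarray:
        """kappa_{i+1} / kappa_i; equals e*(1-c)*(i+r)/(i+1)."""
        return self.kappa[1:] / self.kappa[:-1]


def kappa_distribution(
    r: int, e: float, b: float, c: float, i_max: int = 20
) -> KappaDistribution:
    if r < 1:
        raise ValueError("fluorophore position r must be >= 1")
    for name, v in (("e", e), ("b", b), ("c", c)):
        if not (0.0 <= v < 1.0):
            raise ValueError(f"rate {name}={v} outside [0, 1)")
    i = np.arange(i_max + 1)
    comb = np.array([math.comb(j + r - 1, j) for j in i], dtype=float)
    kappa = (1.0 - b) * comb * (1.0 - e) ** r * e**i * (1.0 - c) ** (r + i)
    return KappaDistribution(r=r, kappa=kappa, i_max=i_max)
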