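"""Modified Baum-Welch: EM over the factored HMM with tied-parameter
weighted maximum-likelihood updates.

Classical Baum-Welch re-estimates every transition probability independently;
here each sub-transition posterior is instead mapped to evidence about the
single physical rate that generated it.  For every rate parameter the E-step
accumulates a weighted trial count n and a weighted success count x (e.g. for
dye loss, n is the expected number of fluorophore-cycles exposed to loss and
x the expected number of fluorophores lost), and the M-step simply sets the
rate to x / n.  Because every tied Bernoulli/binomial likelihood is maximized
at x / n, the M-step maximizes the expected complete-data log-likelihood and
EM monotonicity holds.

Missing-fluorophore (dud) rates need an extra censoring correction: all-dud
peptides never appear as reads, so the naive estimator is biased low.  Each
iteration, the current dud estimates give the probability x that a peptide is
invisible; N * x / (1 - x) phantom all-dud reads are then added to the dud
trial/success counts (and only to those).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emission import read_emission_table
from .model import (
    DEFAULT_FACTOR_ORDER,
    FBResult,
    StateSpace,
    build_state_space,
    initial_dud_distribution,
    pre_sequencing_factor,
    transition_factors,
)
from .params import (
    PeptideDesign,
    SequencingParams,
    identifiability_constraints,
    rate_names_for,
)
from .reads import ReadSet
from .results import FitResult

__all__ = [
    "WeightedCount",
    "DudCorrectionState",
    "accumulate_sufficient_stats",
    "m_step",
    "dud_bias_correction",
    "fit_baum_welch",
]


@dataclass
class WeightedCount:
    """Expected number of Bernoulli trials (n) and successes (x)."""

    n: float = 0.0
    x: float = 0.0

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.x <= self.n + 1e-9):
            raise ValueError(f"invalid weighted count x={self.x}, n={self.n}")

    def __add__(self, other: "WeightedCount") -> "WeightedCount":
        return WeightedCount(self.n + other.n, self.x + other.x)

    @property
    def rate(self) -> float:
        if self.n <= 0:
            raise ZeroDivisionError("no trials accumulated")
        return min(max(self.x / self.n, 0.0), 1.0)


@dataclass(frozen=True)
class DudCorrectionState:
    """Censoring correction bookkeeping for one EM iteration."""

    n_observed_reads: int
    all_dud_prob: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.all_dud_prob < 1.0):
            raise ValueError("all-dud probability must be in [0, 1)")

    @property
    def missing_reads_estimate(self) -> float:
        x = self.all_dud_prob
        return self.n_observed_reads * x / (1.0 - x)


# rate parameter informed by each transition factor
_FACTOR_RATE = {
    "initial_block": "initial_block_rate",
    "cyclic_block": "cyclic_block_rate",
    "detach": "detach_rate",
    "edman": "edman_failure_rate",
}


def _factor_rate_name(factor_name: str) -> str:
    if factor_name.startswith("dye_loss["):
        return "dye_loss_rate[" + factor_name[len("dye_loss[") :]
    return _FACTOR_RATE[factor_name]


def stat_weight_matrices(
    factor_name: str, space: StateSpace, design: PeptideDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Dense (trial, success) weight matrices for one factor's sub-transition
    posteriors: n += sum_ij xi[i,j] * W_n[i,j], x += sum_ij xi[i,j] * W_x[i,j].

    For dye loss the weights count fluorophores (n: live fluorophores before
    the sub-transition; x: fluorophores lost across it); for the Bernoulli
    mechanisms they are indicators of eligible rows / event entries.
    """
    s = space.n_states
    rows = np.repeat(np.arange(s), s)
    cols = np.tile(np.arange(s), s)
    if factor_name.startswith("dye_loss["):
        ch = int(factor_name[len("dye_loss[") : -1])
        w_n = np.repeat(space.counts[:, ch].astype(float), s).reshape(s, s)
        w_x = (space.counts[rows, ch] - space.counts[cols, ch]).astype(float)
        return w_n, w_x.reshape(s, s)
    if factor_name in ("initial_block", "cyclic_block"):
        eligible = space.attached & ~space.blocked
        w_n = np.repeat(eligible.astype(float), s).reshape(s, s)
        w_x = (eligible[rows] & (cols == space.blocked_twin[rows])).astype(float)
        return w_n, w_x.reshape(s, s)
    if factor_name == "detach":
        eligible = space.attached
        w_n = np.repeat(eligible.astype(float), s).reshape(s, s)
        w_x = (eligible[rows] & (cols == space.detached_index)).astype(float)
        return w_n, w_x.reshape(s, s)
    if factor_name == "edman":
        eligible = (
            space.attached & ~space.blocked & (space.n_edman < design.n_cycles)
        )
        w_n = np.repeat(eligible.astype(float), s).reshape(s, s)
        # Edman *failure* is the success of the tied Bernoulli: staying put.
        w_x = (eligible[rows] & (space.n_edman[cols] == space.n_edman[rows])).astype(
            float
        )
        return w_n, w_x.reshape(s, s)
    raise ValueError(f"unknown factor {factor_name!r}")


def accumulate_sufficient_stats(
    fb: FBResult, space: StateSpace, design: PeptideDesign
) -> dict[str, WeightedCount]:
    """Map one read's sub-step/sub-transition posteriors to per-parameter
    weighted trial and success counts.  Counts are additive across reads."""
    stats = {name: WeightedCount() for name in rate_names_for(design)}
    for factor_name, _cycle, xi in fb.xis:
        rate = _factor_rate_name(factor_name)
        w_n, w_x = stat_weight_matrices(factor_name, space, design)
        stats[rate] = stats[rate] + WeightedCount(
            float((xi * w_n).sum()), float((xi * w_x).sum())
        )
    gamma_dud = fb.gammas[0]
    for ch in range(design.n_channels):
        labels = design.label_counts[ch]
        n = float(gamma_dud.sum() * labels)
        x = float((gamma_dud * (labels - space.counts[:, ch])).sum())
        name = f"dud_rate[{ch}]"
        stats[name] = stats[name] + WeightedCount(n, x)
    return stats


def m_step(
    stats: dict[str, WeightedCount],
    constraints: dict[str, float],
    template: SequencingParams,
) -> SequencingParams:
    """Weighted MLE update: each free rate becomes x / n; pinned parameters
    take their constraint value; intensity parameters are held fixed."""
    rates: dict[str, float] = {}
    for name, count in stats.items():
        if name in constraints:
            rates[name] = constraints[name]
            continue
        if count.n <= 0:
            raise ZeroDivisionError(
                f"parameter {name} has no expected trials; the design cannot "
                "identify it (consider pinning it)"
            )
        rates[name] = count.rate
    return template.with_rates(rates)


def dud_bias_correction(
    n_reads: int, params: SequencingParams, design: PeptideDesign
) -> tuple[DudCorrectionState, dict[str, WeightedCount]]:
    """Phantom all-dud pseudo-reads for the censoring correction.

    Under the current dud rates the probability a peptide is entirely dark is
    x = prod_ch m_ch^labels_ch; the estimated number of censored reads is
    N x / (1 - x), each contributing labels_ch all-dud fluorophores to
    channel ch's dud counts.
    """
    x = 1.0
    for ch in range(design.n_channels):
        x *= params.dud_rate[ch] ** design.label_counts[ch]
    if x >= 1.0:
        raise ValueError("all-dud probability >= 1; dud rates degenerate")
    state = DudCorrectionState(n_reads, x)
    missing = state.missing_reads_estimate
    extra = {
        f"dud_rate[{ch}]": WeightedCount(
            design.label_counts[ch] * missing, design.label_counts[ch] * missing
        )
        for ch in range(design.n_channels)
    }
    return state, extra


# ---------------------------------------------------------------------------
# vectorized E-step


class _EStepEngine:
    """Precomputed machinery for running the E-step over a whole dataset.

    Emission densities depend only on the (held-fixed) intensity model, so
    they are computed once; per EM iteration only the small dense factor
    matrices are rebuilt.  All passes are vectorized across reads (arrays of
    shape (n_reads, n_states)).

    Internally the states are permuted into [unblocked | blocked twins |
    detached] order so that every mask used by the sufficient statistics is a
    contiguous column slice (the blocked twin of unblocked column i is column
    i + U, and the unblocked states with Edman count below n_cycles form a
    prefix).  The permutation is invisible to callers: all outputs are
    per-parameter scalars and per-read log-likelihoods.
    """

    def __init__(
        self,
        intensities: np.ndarray,
        design: PeptideDesign,
        params: SequencingParams,
        space: StateSpace | None = None,
        order: tuple[str, ...] = DEFAULT_FACTOR_ORDER,
        condition_on_visible: bool = True,
        dtype=np.float64,
    ):
        self.dtype = np.dtype(dtype)
        self.design = design
        self.space = space if space is not None else build_state_space(design)
        self.order = order
        self.condition_on_visible = condition_on_visible
        space = self.space
        unb = np.nonzero(space.attached & ~space.blocked)[0]
        self._perm = np.concatenate(
            [unb, space.blocked_twin[unb], [space.detached_index]]
        )
        self._n_unb = len(unb)  # U; attached = [0, 2U), detached = 2U
        self._n_elig = int((space.n_edman[unb] < design.n_cycles).sum())
        if not np.all(np.diff(space.n_edman[unb]) >= 0):
            raise AssertionError("state ordering not sorted by Edman count")
        self._counts = space.counts[self._perm]  # (S, C) in engine order
        log_e = read_emission_table(intensities, space, params)[:, :, self._perm]
        log_e_max = log_e.max(axis=2)  # (N, T)
        self.log_e_max = np.ascontiguousarray(log_e_max.T)  # (T, N)
        self.e_norm = np.ascontiguousarray(
            np.exp(log_e - log_e_max[:, :, None]).transpose(1, 0, 2),
            dtype=self.dtype,
        )  # (T, N, S)
        self.n_reads = intensities.shape[0]
        self._bufs: dict | None = None

    def subset(self, indices) -> "_EStepEngine":
        """Engine for a resampled subset of the reads (bootstrap replicates):
        shares the design and state space, gathers the emission tables."""
        other = object.__new__(_EStepEngine)
        for name in ("design", "space", "order", "condition_on_visible",
                     "dtype", "_perm", "_n_unb", "_n_elig", "_counts"):
            setattr(other, name, getattr(self, name))
        other.log_e_max = np.ascontiguousarray(self.log_e_max[:, indices])
        other.e_norm = np.ascontiguousarray(self.e_norm[:, indices, :])
        other.n_reads = len(indices)
        other._bufs = None
        return other

    def _workspace(self, n_factors: int):
        n, s = self.n_reads, self.space.n_states
        t_points = self.design.n_timepoints
        if self._bufs is None or self._bufs["alphas"].shape[1] != n:
            dt = self.dtype
            self._bufs = {
                "alphas": np.empty((t_points, n, s), dtype=dt),
                "subs": np.empty((t_points - 1, n_factors, n, s), dtype=dt),
                "w": np.empty((n, s), dtype=dt),
                "bb": np.empty((n, s), dtype=dt),
                "beta": np.empty((n, s), dtype=dt),
            }
        return self._bufs

    def run(
        self, params: SequencingParams, want_stats: bool = True
    ) -> tuple[np.ndarray, dict[str, WeightedCount] | None]:
        """One E-step: per-read log-likelihoods and (optionally) aggregated
        sufficient statistics at the given parameters.

        Sufficient statistics come straight out of the pass itself: trial
        counts are (weighted) posterior mass at the pre-factor sub-step, and
        every factor's success count reduces to an elementwise contraction of
        quantities the forward/backward recursion already produces -- the
        expected fluorophore deficit across a dye-loss factor, or the factor
        rate times the forward/backward overlap on the event entries (the
        diagonal for Edman failure, the blocked twin / detached columns for
        blocking and detachment).  Agreement with the explicit per-read
        sub-transition posteriors is exercised in the test suite.
        """
        space, design = self.space, self.design
        n, t_points = self.n_reads, design.n_timepoints
        perm = self._perm
        factors = list(
            transition_factors(params, space, 1, order=self.order, clamp=True)
        )
        b0 = pre_sequencing_factor(params, space, clamp=True)
        pi = initial_dud_distribution(
            params, space, self.condition_on_visible, clamp=True
        )[perm].astype(self.dtype)
        f_dense = [
            f.matrix.toarray()[np.ix_(perm, perm)].astype(self.dtype)
            for f in factors
        ]
        f_dense_t = [np.ascontiguousarray(m.T) for m in f_dense]
        b0_dense = b0.matrix.toarray()[np.ix_(perm, perm)].astype(self.dtype)
        k_factors = len(f_dense)
        bufs = self._workspace(k_factors)
        alphas, subs = bufs["alphas"], bufs["subs"]

        # forward, storing every sub-step alpha (reused by the backward pass)
        log_c = np.empty((t_points, n))
        a0 = (pi @ b0_dense).astype(self.dtype)
        w = bufs["w"]
        np.multiply(a0[None, :], self.e_norm[0], out=w)
        c = np.maximum(w.sum(axis=1, dtype=np.float64), 1e-300)
        np.divide(w, c.astype(self.dtype)[:, None], out=alphas[0])
        log_c[0] = np.log(c) + self.log_e_max[0]
        for t in range(1, t_points):
            a = alphas[t - 1]
            for j, m in enumerate(f_dense):
                np.matmul(a, m, out=subs[t - 1, j])
                a = subs[t - 1, j]
            np.multiply(a, self.e_norm[t], out=w)
            c = np.maximum(w.sum(axis=1, dtype=np.float64), 1e-300)
            np.divide(w, c.astype(self.dtype)[:, None], out=alphas[t])
            log_c[t] = np.log(c) + self.log_e_max[t]
        loglik = log_c.sum(axis=0)
        if not want_stats:
            return loglik, None

        clamp = lambda r: min(max(r, 1e-9), 1.0 - 1e-9)  # noqa: E731
        u = self._n_unb
        u_e = self._n_elig
        det = 2 * u
        acc_n = np.zeros(len(factors))
        acc_x = np.zeros(len(factors))

        inv_c = np.exp(self.log_e_max - log_c).astype(self.dtype)  # (T, N)
        bb, beta = bufs["bb"], bufs["beta"]
        bb.fill(1.0)
        for t in range(t_points - 1, 0, -1):
            # fold emission t and its scale into the running beta
            np.multiply(bb, self.e_norm[t], out=bb)
            np.multiply(bb, inv_c[t][:, None], out=bb)
            for j in range(len(factors) - 1, -1, -1):
                a_pre = alphas[t - 1] if j == 0 else subs[t - 1, j - 1]
                np.matmul(bb, f_dense_t[j], out=beta)
                g_pre = np.einsum("ns,ns->s", a_pre, beta)
                name = factors[j].name
                if name == "cyclic_block":
                    acc_n[j] += g_pre[:u].sum()
                    acc_x[j] += clamp(params.cyclic_block_rate) * float(
                        np.einsum("ns,ns->", a_pre[:, :u], bb[:, u:det])
                    )
                elif name == "detach":
                    acc_n[j] += g_pre[:det].sum()
                    rowsum_att = a_pre.sum(axis=1) - a_pre[:, det]
                    acc_x[j] += clamp(params.detach_rate) * float(
                        rowsum_att @ bb[:, det]
                    )
                elif name.startswith("dye_loss["):
                    ch = int(name[len("dye_loss[") : -1])
                    k = self._counts[:, ch].astype(float)
                    g_post = np.einsum("ns,ns->s", subs[t - 1, j], bb)
                    acc_n[j] += float(g_pre @ k)
                    acc_x[j] += float((g_pre - g_post) @ k)
                elif name == "edman":
                    acc_n[j] += g_pre[:u_e].sum()
                    acc_x[j] += clamp(params.edman_failure_rate) * float(
                        np.einsum("ns,ns->", a_pre[:, :u_e], bb[:, :u_e])
                    )
                bb, beta = beta, bb
        # timepoint 0: initial block factor, then the dud sub-step
        np.multiply(bb, self.e_norm[0], out=bb)
        np.multiply(bb, inv_c[0][:, None], out=bb)
        gamma_dud = pi * (b0_dense @ bb.sum(axis=0))
        init_n = float(gamma_dud[:u].sum())
        init_x = clamp(params.initial_block_rate) * float(
            (pi[:u] * bb[:, u:det].sum(axis=0)).sum()
        )

        stats = {name: WeightedCount() for name in rate_names_for(design)}
        for j, f in enumerate(factors):
            rate = _factor_rate_name(f.name)
            stats[rate] = stats[rate] + WeightedCount(acc_n[j], max(acc_x[j], 0.0))
        stats["initial_block_rate"] = stats["initial_block_rate"] + WeightedCount(
            init_n, max(init_x, 0.0)
        )
        for ch in range(design.n_channels):
            labels = design.label_counts[ch]
            name = f"dud_rate[{ch}]"
            stats[name] = stats[name] + WeightedCount(
                float(gamma_dud.sum() * labels),
                max(float((gamma_dud * (labels - self._counts[:, ch])).sum()), 0.0),
            )
        return loglik, stats


# ---------------------------------------------------------------------------
# EM driver


def fit_baum_welch(
    reads: ReadSet,
    design: PeptideDesign,
    init: SequencingParams,
    *,
    tol: float = 1e-6,
    max_iter: int = 1000,
    condition_on_visible: bool = True,
    dud_correction: bool | None = None,
    constraints: dict[str, float] | None = None,
    n_starts: int = 3,
    seed: int = 0,
    accelerate: bool = True,
    order: tuple[str, ...] = DEFAULT_FACTOR_ORDER,
    space: StateSpace | None = None,
    dtype=np.float64,
) -> FitResult:
    """Fit the six sequencing error rates by tied-parameter Baum-Welch.

    ``init`` supplies the (held fixed) intensity model and the starting error
    rates.  ``n_starts`` EM runs are performed -- the given start plus
    jittered variants -- and the best final likelihood is kept.  Identifiability
    constraints for the design are applied automatically unless an explicit
    ``constraints`` mapping is given.  ``dud_correction`` defaults to the
    value of ``condition_on_visible``: real reads are visible by
    construction, and the censoring correction then supplies the missing
    all-dud mass.
    """
    if len(reads) < 1:
        raise ValueError("need at least one read")
    if dud_correction is None:
        dud_correction = condition_on_visible
    if constraints is None:
        constraints = identifiability_constraints(design)
    if space is None:
        space = build_state_space(design)
    if np.dtype(dtype) == np.float32:
        # single-precision sufficient statistics jitter the rates at the
        # ~1e-5 relative level; a tighter tolerance would never be met
        tol = max(tol, 2e-5)
    if reads.intensities.shape[1:] != (design.n_timepoints, design.n_channels):
        raise ValueError(
            f"reads shape {reads.intensities.shape[1:]} does not match design "
            f"({design.n_timepoints}, {design.n_channels})"
        )
    engine = _EStepEngine(
        reads.intensities,
        design,
        init,
        space=space,
        order=order,
        condition_on_visible=condition_on_visible,
        dtype=dtype,
    )
    rng = np.random.default_rng(seed)
    starts = [init.with_rates(constraints)]
    free = [n for n in rate_names_for(design) if n not in constraints]
    for _ in range(max(0, n_starts - 1)):
        jitter = {name: float(rng.uniform(0.01, 0.2)) for name in free}
        starts.append(starts[0].with_rates(jitter))

    best: FitResult | None = None
    for start in starts:
        result = _run_em(
            engine,
            reads,
            design,
            start,
            constraints,
            tol,
            max_iter,
            dud_correction,
            accelerate=accelerate,
        )
        if best is None or result.objective > best.objective:
            best = result
    return best


def _ll_slack(engine: "_EStepEngine") -> float:
    """Relative log-likelihood resolution of the engine's precision."""
    return 1e-10 if engine.dtype == np.float64 else 2e-7


def _rel_change(old: SequencingParams, new: SequencingParams, names) -> float:
    return max(
        abs(new.get_rate(n) - old.get_rate(n)) / max(abs(old.get_rate(n)), 1e-3)
        for n in names
    )


def _run_em(
    engine: _EStepEngine,
    reads: ReadSet,
    design: PeptideDesign,
    start: SequencingParams,
    constraints: dict[str, float],
    tol: float,
    max_iter: int,
    dud_correction: bool,
    accelerate: bool = True,
) -> FitResult:
    """EM loop with optional monotonicity-safeguarded extrapolation.

    In accelerated mode each round takes two EM steps, extrapolates the
    parameter vector along the squared step difference, and accepts the
    extrapolated point only if its observed-data log-likelihood does not fall
    below the best EM step's -- otherwise the plain double EM step is kept.
    The recorded log-likelihood trace is therefore non-decreasing whenever
    plain EM is (acceleration never accepts a likelihood decrease).
    """
    names = rate_names_for(design)
    free = [n for n in names if n not in constraints]

    def em_step(p: SequencingParams) -> tuple[float, SequencingParams]:
        loglik, stats = engine.run(p)
        if not np.all(np.isfinite(loglik)):
            bad = int(np.argmax(~np.isfinite(loglik)))
            raise FloatingPointError(
                f"non-finite log-likelihood for read {reads.read_ids[bad]!r}"
            )
        if dud_correction:
            _, extra = dud_bias_correction(len(reads), p, design)
            for name, count in extra.items():
                if name not in constraints:
                    stats[name] = stats[name] + count
        return float(loglik.sum()), m_step(stats, constraints, p)

    params = start
    trace: list[float] = []
    converged = False
    n_iter = 0
    while n_iter < max_iter:
        ll0, theta1 = em_step(params)
        n_iter += 1
        trace.append(ll0)
        ll_change = abs(trace[-1] - trace[-2]) if len(trace) > 1 else np.inf
        # the plateau test uses a double-precision threshold; with a
        # float32 engine the trace noise keeps it from firing and the
        # parameter-change criterion governs
        if (
            _rel_change(params, theta1, names) < tol
            or ll_change < 1e-10 * max(1.0, abs(ll0))
        ):
            params = theta1
            converged = True
            break
        if not accelerate or n_iter >= max_iter:
            params = theta1
            continue
        ll1, theta2 = em_step(theta1)
        n_iter += 1
        trace.append(ll1)
        if _rel_change(theta1, theta2, names) < tol:
            params = theta2
            converged = True
            break
        x0 = np.array([params.get_rate(n) for n in free])
        x1 = np.array([theta1.get_rate(n) for n in free])
        x2 = np.array([theta2.get_rate(n) for n in free])
        r = x1 - x0
        v = (x2 - x1) - r
        vnorm = float(np.linalg.norm(v))
        if vnorm == 0.0:
            params = theta2
            continue
        alpha = min(-float(np.linalg.norm(r)) / vnorm, -1.0)
        x_acc = np.clip(x0 - 2.0 * alpha * r + alpha**2 * v, 0.0, 1.0 - 1e-6)
        theta_acc = params.with_rates(dict(zip(free, x_acc)))
        ll_acc, _ = engine.run(theta_acc, want_stats=False)
        # accept within the accumulation noise of the engine's precision
        slack = _ll_slack(engine) * max(1.0, abs(ll1))
        round_start = params
        params = theta_acc if float(ll_acc.sum()) >= ll1 - slack else theta2
        # extrapolation rounds can oscillate (jump, EM pull-back) while the
        # net macro movement vanishes; converge on the round-level change too
        if _rel_change(round_start, params, names) < tol:
            converged = True
            break
    return FitResult(
        params_hat=params,
        objective=trace[-1],
        method="baum_welch",
        n_iterations=n_iter,
        converged=converged,
        constraints=dict(constraints),
        trace=trace,
        settings={
            "tol": tol,
            "max_iter": max_iter,
            "dud_correction": dud_correction,
            "condition_on_visible": engine.condition_on_visible,
        },
    )
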