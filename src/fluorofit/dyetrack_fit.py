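"""Dye-track RMSE fitting: global box trisection (DIRECT-style) followed by
coordinate-wise Powell minimization.

Every read is first reduced to a dye track -- the per-timepoint,
per-channel fluorophore counts maximizing the emission density.  Given
candidate error rates, the same reduction is applied to a freshly simulated
dataset and the objective is the root-mean-square error between the two
dye-track count histograms (simulated counts rescaled to the data size, the
mean taken over the union of observed tracks).

The objective is made deterministic by re-seeding the simulator identically
on every evaluation (common random numbers) and by allocating the simulated
peptides' dud/block/detach fates in exact proportion instead of sampling
them; a noisy surface would defeat Powell's line searches.  The fit chains a
global DIRECT search, trust-regioned Powell direction-set minimization, a
larger-simulation polish, and a profiled re-scan of the initial block rate
along its trade-off valley with the cyclic block and Edman failure rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import direct as _scipy_direct, minimize_scalar

from .params import (
    PeptideDesign,
    SequencingParams,
    identifiability_constraints,
    rate_names_for,
)
from .reads import ReadSet
from .results import FitResult
from .simulate import (
    TrackHistogram,
    dyetrack_histogram,
    histogram_rmse,
    reduce_to_dyetrack,
    simulate_reads,
)

__all__ = [
    "SearchBox",
    "DyetrackSettings",
    "rmse_objective",
    "direct_search",
    "powell_minimize",
    "fit_dyetrack",
]


@dataclass
class SearchBox:
    """Axis-aligned box in rate space with its evaluated center."""

    lower: np.ndarray
    upper: np.ndarray
    center: np.ndarray
    value: float

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if np.any(self.lower >= self.upper):
            raise ValueError("box bounds must satisfy lower < upper")

    @property
    def volume(self) -> float:
        return float(np.prod(self.upper - self.lower))


@dataclass
class DyetrackSettings:
    """Knobs for the DIRECT+Powell fitter.

    ``n_sim`` (simulated reads per objective evaluation during the global
    search and first Powell stage) defaults to max(10000, min(n_data,
    50000)); the final Powell polish re-simulates with ``polish_n_sim`` reads
    (default min(4 * n_data, 200000)) under a fresh stream, which shrinks the
    displacement of the fixed-seed optimum caused by finite simulation size.
    Default rate bounds are [0, 0.5] except the initial block rate, bounded
    by 0.99 so that heavily blocked peptides (e.g. acetylated N-termini,
    where block rates above 0.9 are expected) remain fittable.
    """

    n_sim: int | None = None
    direct_evals: int = 400
    direct_backend: str = "canonical"
    powell_tol: float = 1e-3
    max_sweeps: int = 8
    line_xatol: float = 2e-4
    polish_n_sim: int | None = None
    polish_sweeps: int = 1
    polish_tol: float = 5e-4
    search_max_step: float = 0.03
    polish_max_step: float = 0.01
    valley_scan: bool = True
    valley_halfwidth: float = 0.025
    valley_step: float = 0.005
    valley_fine_halfwidth: float = 0.005
    valley_fine_step: float = 0.0025
    valley_streams: int = 2
    bounds: dict | None = None
    seed: int = 0


_DEFAULT_UPPER = 0.5
_BLOCK_UPPER = 0.99


def default_bounds(free_names) -> list[tuple[float, float]]:
    return [
        (0.0, _BLOCK_UPPER if name == "initial_block_rate" else _DEFAULT_UPPER)
        for name in free_names
    ]


def rmse_objective(
    theta,
    target_hist: TrackHistogram,
    design: PeptideDesign,
    fixed_params: SequencingParams,
    free_names,
    n_sim: int,
    seed: int,
    stratify_initial: bool = True,
) -> float:
    """Deterministic simulation-vs-data dye-track histogram RMSE at ``theta``.

    ``theta`` holds the free rates (ordered as ``free_names``); all other
    parameters, including the intensity model, come from ``fixed_params``.
    The simulator is seeded identically on every call, and by default the
    simulated peptides' initial dud/block configurations are allocated in
    exact proportion rather than sampled: the objective's expectation is
    unchanged but the finite-simulation noise on the initial block and dud
    rates -- the softest directions of the fit -- drops sharply.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0.0) or np.any(theta >= 1.0):
        raise ValueError(f"rate vector {theta} outside [0, 1)")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    params = fixed_params.with_rates(dict(zip(free_names, theta)))
    sim = simulate_reads(
        design, params, n_sim, seed=seed, stratify_initial=stratify_initial
    )
    tracks = reduce_to_dyetrack(sim.reads, fixed_params, design)
    sim_hist = dyetrack_histogram(tracks)
    return histogram_rmse(target_hist, sim_hist, scale=target_hist.total / n_sim)


class _BudgetExhausted(Exception):
    pass


def direct_search(objective, bounds, max_evals: int = 400, backend: str = "canonical"):
    """Derivative-free global search over a bounding box.

    The default backend is the canonical DIRECT (DIviding RECTangles)
    algorithm; the "trisection" backend is a simplified variant that
    repeatedly picks a box -- alternating between the best-valued box
    (exploitation) and the largest-volume box (exploration) -- trisects it
    along its longest side and evaluates the centers of the two new outer
    thirds.  Both are deterministic for a deterministic objective and never
    exceed ``max_evals`` evaluations.

    Returns ``(best_x, best_value, n_evals, boxes)`` (``boxes`` is the final
    box decomposition for the trisection backend, empty for canonical).
    """
    if backend == "canonical":
        return _direct_canonical(objective, bounds, max_evals)
    if backend != "trisection":
        raise ValueError(f"unknown DIRECT backend {backend!r}")
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    lower = np.array([lo for lo, _ in bounds])
    upper = np.array([hi for _, hi in bounds])
    if not np.all(np.isfinite(lower)) or not np.all(np.isfinite(upper)):
        raise ValueError("bounds must be finite")

    def evaluate(x: np.ndarray) -> float:
        v = float(objective(x))
        if not np.isfinite(v):
            raise FloatingPointError(f"objective returned {v} at {x}")
        return v

    center = (lower + upper) / 2.0
    boxes = [SearchBox(lower, upper, center, evaluate(center))]
    n_evals = 1
    best = boxes[0]
    step = 0
    frozen: list[SearchBox] = []  # boxes too small to split further
    while n_evals < max_evals and boxes:
        if step % 2 == 0:
            idx = min(range(len(boxes)), key=lambda i: (boxes[i].value, i))
        else:
            idx = max(range(len(boxes)), key=lambda i: (boxes[i].volume, -i))
        box = boxes.pop(idx)
        d = int(np.argmax(box.upper - box.lower))
        if box.upper[d] - box.lower[d] < 1e-9:
            frozen.append(box)
            step += 1
            continue
        third = (box.upper[d] - box.lower[d]) / 3.0
        children = []
        cuts = [box.lower[d], box.lower[d] + third, box.lower[d] + 2 * third, box.upper[d]]
        for k in range(3):
            lo = box.lower.copy()
            hi = box.upper.copy()
            lo[d], hi[d] = cuts[k], cuts[k + 1]
            c = box.center.copy()
            c[d] = (lo[d] + hi[d]) / 2.0
            if k == 1:
                children.append(SearchBox(lo, hi, box.center.copy(), box.value))
                continue
            if n_evals >= max_evals:
                break
            child = SearchBox(lo, hi, c, evaluate(c))
            n_evals += 1
            children.append(child)
            if child.value < best.value:
                best = child
        boxes.extend(children if children else [box])
        step += 1
    return best.center.copy(), best.value, n_evals, boxes + frozen


def _direct_canonical(objective, bounds, max_evals: int):
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    lower = np.array([lo for lo, _ in bounds])
    upper = np.array([hi for _, hi in bounds])
    if not np.all(np.isfinite(lower)) or not np.all(np.isfinite(upper)):
        raise ValueError("bounds must be finite")
    state = {"n": 0, "best_x": None, "best_f": np.inf}

    def wrapped(x):
        if state["n"] >= max_evals:
            raise _BudgetExhausted
        state["n"] += 1
        v = float(objective(np.asarray(x, dtype=float)))
        if not np.isfinite(v):
            raise FloatingPointError(f"objective returned {v} at {x}")
        if v < state["best_f"]:
            state["best_f"] = v
            state["best_x"] = np.asarray(x, dtype=float).copy()
        return v

    try:
        _scipy_direct(wrapped, bounds, maxfun=max_evals, maxiter=10_000)
    except _BudgetExhausted:
        pass
    if state["best_x"] is None:  # max_evals == 0 guard
        state["best_x"] = (lower + upper) / 2.0
        state["best_f"] = float(objective(state["best_x"]))
        state["n"] = 1
    return state["best_x"], state["best_f"], state["n"], []


def powell_minimize(
    objective,
    start,
    bounds,
    tol: float = 1e-3,
    max_sweeps: int = 10,
    line_xatol: float = 2e-4,
    max_step: float | None = None,
):
    """Powell's method with bounded line searches.

    Each sweep minimizes the objective along one direction at a time with a
    bounded scalar search.  The direction set starts as the coordinate axes;
    after every sweep the sweep's net displacement is line-minimized too and
    replaces the direction that produced the largest single decrease
    (Powell's update).  The persistent direction set is what lets the search
    track ridges where parameters trade off against each other (here, e.g.,
    initial vs. cyclic blocking), which pure coordinate descent creeps
    along.  ``max_step`` caps each line search's displacement per parameter
    (a trust region): along near-flat ridge directions the objective's
    finite-simulation tilt would otherwise pull single line searches
    arbitrarily far.  Sweeps repeat until one improves the objective by less
    than ``tol`` (converged) or ``max_sweeps`` is reached; iterates never
    leave the bounds.

    Returns ``(x, value, n_sweeps, converged)``.
    """
    x = np.asarray(start, dtype=float).copy()
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    lo_arr = np.array([lo for lo, _ in bounds])
    hi_arr = np.array([hi for _, hi in bounds])
    n_dim = len(x)
    for d, (lo, hi) in enumerate(bounds):
        if not (lo <= x[d] <= hi):
            raise ValueError(f"start[{d}]={x[d]} outside [{lo}, {hi}]")
    f_x = float(objective(x))
    directions = [np.eye(n_dim)[d] for d in range(n_dim)]
    converged = False
    sweeps = 0

    def line_minimize(x0, f0, u):
        """Bounded line minimization of objective(x0 + t*u)."""
        scale = float(np.max(np.abs(u)))
        if scale == 0.0:
            return x0, f0
        with np.errstate(divide="ignore", invalid="ignore"):
            t_hi = np.where(
                u > 0, (hi_arr - x0) / u, np.where(u < 0, (lo_arr - x0) / u, np.inf)
            )
            t_lo = np.where(
                u > 0, (lo_arr - x0) / u, np.where(u < 0, (hi_arr - x0) / u, -np.inf)
            )
        t_max = float(np.min(t_hi))
        t_min = float(np.max(t_lo))
        if max_step is not None:
            t_cap = max_step / scale
            t_max = min(t_max, t_cap)
            t_min = max(t_min, -t_cap)
        if t_max - t_min <= 0.0:
            return x0, f0
        res = minimize_scalar(
            lambda t: float(objective(np.clip(x0 + t * u, lo_arr, hi_arr))),
            bounds=(t_min, t_max),
            method="bounded",
            options={"xatol": line_xatol / scale},
        )
        if res.fun < f0:
            return np.clip(x0 + float(res.x) * u, lo_arr, hi_arr), float(res.fun)
        return x0, f0

    for sweeps in range(1, max_sweeps + 1):
        f_before = f_x
        x_before = x.copy()
        decreases = np.zeros(len(directions))
        for i, u in enumerate(directions):
            f_prev = f_x
            x, f_x = line_minimize(x, f_x, u)
            decreases[i] = f_prev - f_x
        u_new = x - x_before
        norm = float(np.linalg.norm(u_new))
        if norm > 1e-12:
            x, f_x = line_minimize(x, f_x, u_new / norm)
            # Powell's update: the direction of largest decrease is the main
            # contributor to the net displacement; replace it to keep the
            # set linearly independent
            directions[int(np.argmax(decreases))] = u_new / norm
        if f_before - f_x < tol:
            converged = True
            break
    return x, f_x, sweeps, converged


def _scan_block_grid(
    x, objective, i_b, partners, lo_arr, hi_arr, halfwidth, step, trust, xatol
):
    """Outward grid scan of the block coordinate with partner re-minimization.

    At each grid value of the block rate the listed partner coordinates are
    line-minimized (bounded to ``trust`` around their current values),
    warm-started from the neighboring grid point; returns the best profiled
    point with the block coordinate parabolically refined.
    """

    def minimize_partner(x0, f0, d):
        lo_d = max(lo_arr[d], x0[d] - trust)
        hi_d = min(hi_arr[d], x0[d] + trust)
        if hi_d - lo_d <= 0:
            return x0, f0
        res = minimize_scalar(
            lambda v: float(objective(np.concatenate([x0[:d], [v], x0[d + 1 :]]))),
            bounds=(lo_d, hi_d),
            method="bounded",
            options={"xatol": xatol},
        )
        if res.fun < f0:
            x0 = x0.copy()
            x0[d] = float(res.x)
            return x0, float(res.fun)
        return x0, f0

    n_side = int(round(halfwidth / step))
    center_b = x[i_b]
    profile: dict[int, tuple[float, np.ndarray]] = {}

    def evaluate(k, warm):
        b_val = center_b + k * step
        if not (lo_arr[i_b] <= b_val <= hi_arr[i_b]):
            return None
        xx = warm.copy()
        xx[i_b] = b_val
        fx = float(objective(xx))
        for d in partners:
            xx, fx = minimize_partner(xx, fx, d)
        profile[k] = (fx, xx)
        return xx

    up = evaluate(0, x.copy())
    for k in range(1, n_side + 1):  # scan outward, warm-starting neighbors
        up = evaluate(k, up if up is not None else x.copy())
    down = profile[0][1] if 0 in profile else x.copy()
    for k in range(1, n_side + 1):
        down = evaluate(-k, down if down is not None else x.copy())

    best_k = min(profile, key=lambda k: profile[k][0])
    f_best, x_best = profile[best_k]
    if (best_k - 1) in profile and (best_k + 1) in profile:
        f_m = profile[best_k - 1][0]
        f_p = profile[best_k + 1][0]
        denom = f_m - 2.0 * f_best + f_p
        if denom > 0:
            shift = 0.5 * step * (f_m - f_p) / denom
            x_best = x_best.copy()
            x_best[i_b] = float(
                np.clip(x_best[i_b] + shift, lo_arr[i_b], hi_arr[i_b])
            )
    return x_best, f_best


def _profile_refine(x, coarse_objective, fine_objectives, free_names, bounds, settings):
    """Re-locate the initial block rate by profiled grid scans.

    Initial blocking, cyclic blocking and the Edman failure rate trade off
    along a nearly flat valley of the dye-track RMSE objective (for a single
    fluorophore the trade-off is exact), so descent methods settle wherever
    their simulation stream tilts the valley.  The block rate is therefore
    re-estimated directly, in two passes: a coarse scan re-minimizing the two
    main trade-off partners, then a fine scan around the coarse minimum
    re-minimizing *every* other free rate, its objective averaged over
    independent simulation streams to shrink the per-stream valley tilt.  The
    fine profile's parabolically-refined minimum gives the final estimate.
    Applies only when the initial block rate and at least one partner are
    free.
    """
    if "initial_block_rate" not in free_names:
        return x, None
    i_b = free_names.index("initial_block_rate")
    coarse_partners = [
        free_names.index(n)
        for n in ("cyclic_block_rate", "edman_failure_rate")
        if n in free_names
    ]
    all_partners = [i for i in range(len(free_names)) if i != i_b]
    if not all_partners:
        return x, None
    lo_arr = np.array([b[0] for b in bounds])
    hi_arr = np.array([b[1] for b in bounds])

    x1, _f1 = _scan_block_grid(
        x,
        coarse_objective,
        i_b,
        coarse_partners or all_partners,
        lo_arr,
        hi_arr,
        settings.valley_halfwidth,
        settings.valley_step,
        trust=0.02,
        xatol=3e-4,
    )

    def fine_objective(th):
        return float(np.mean([o(th) for o in fine_objectives]))

    return _scan_block_grid(
        x1,
        fine_objective,
        i_b,
        all_partners,
        lo_arr,
        hi_arr,
        settings.valley_fine_halfwidth,
        settings.valley_fine_step,
        trust=0.0075,
        xatol=6e-4,
    )


def fit_dyetrack(
    reads: ReadSet,
    design: PeptideDesign,
    fixed_params: SequencingParams,
    settings: DyetrackSettings | None = None,
    *,
    constraints: dict[str, float] | None = None,
    init: SequencingParams | None = None,
) -> FitResult:
    """Estimate error rates by DIRECT-style global search plus Powell
    refinement of the dye-track histogram RMSE.

    ``fixed_params`` supplies the intensity model (held fixed) and the values
    of pinned parameters.  If ``init`` is given the global search is skipped
    and Powell starts from ``init``'s rates (used for warm-started bootstrap
    replicates).
    """
    if len(reads) < 1:
        raise ValueError("need at least one read")
    settings = settings or DyetrackSettings()
    if constraints is None:
        constraints = identifiability_constraints(design)
    free_names = [n for n in rate_names_for(design) if n not in constraints]
    bounds = (
        [tuple(settings.bounds[n]) for n in free_names]
        if settings.bounds
        else default_bounds(free_names)
    )
    n_sim = (
        settings.n_sim
        if settings.n_sim is not None
        else max(10_000, min(len(reads), 50_000))
    )
    base = fixed_params.with_rates(constraints)
    tracks = reduce_to_dyetrack(reads, fixed_params, design)
    target_hist = dyetrack_histogram(tracks)
    seed_search, seed_polish = (
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(settings.seed).spawn(2)
    )

    def make_objective(size: int, sim_seed: int):
        def objective(theta):
            return rmse_objective(
                theta, target_hist, design, base, free_names, size, sim_seed
            )

        return objective

    trace: list[float] = []
    if init is None:
        # stage 1+2: global trisection then Powell sweeps, one shared stream
        objective = make_objective(n_sim, seed_search)
        x0, f0, _n_evals, _ = direct_search(
            objective, bounds, settings.direct_evals, backend=settings.direct_backend
        )
        trace.append(f0)
        x0, f1, _sweeps, _ = powell_minimize(
            objective,
            x0,
            bounds,
            tol=settings.powell_tol,
            max_sweeps=settings.max_sweeps,
            line_xatol=settings.line_xatol,
            max_step=settings.search_max_step,
        )
        trace.append(f1)
        # stage 3: polish with a larger simulation under a fresh stream --
        # the fixed-stream optimum is displaced from the noise-free optimum
        # by an O(1/sqrt(n_sim)) amount, so the polish both averages away
        # the search stream's displacement and tightens it
        polish_n = (
            settings.polish_n_sim
            if settings.polish_n_sim is not None
            else min(4 * len(reads), 200_000)
        )
        polish_n = max(polish_n, n_sim)
        objective = make_objective(polish_n, seed_polish)
        x, f, sweeps, converged = powell_minimize(
            objective,
            x0,
            bounds,
            tol=settings.polish_tol,
            max_sweeps=settings.polish_sweeps,
            line_xatol=settings.line_xatol,
            max_step=settings.polish_max_step,
        )
        trace.append(f)
        if settings.valley_scan:
            extra_streams = [
                int(s.generate_state(1)[0] % 2**31)
                for s in np.random.SeedSequence(seed_polish + 1).spawn(
                    max(0, settings.valley_streams - 1)
                )
            ]
            fine_objectives = [objective] + [
                make_objective(polish_n, s) for s in extra_streams
            ]
            x, f_profile = _profile_refine(
                x, objective, fine_objectives, free_names, bounds, settings
            )
            if f_profile is not None:
                f = f_profile
                trace.append(f)
    else:
        # warm start (bootstrap replicates): Powell only, replicate stream
        polish_n = n_sim
        x0 = np.array(
            [
                min(max(init.get_rate(n), lo), hi)
                for n, (lo, hi) in zip(free_names, bounds)
            ]
        )
        objective = make_objective(n_sim, seed_search)
        x, f, sweeps, converged = powell_minimize(
            objective,
            x0,
            bounds,
            tol=settings.powell_tol,
            max_sweeps=settings.max_sweeps,
            line_xatol=settings.line_xatol,
            max_step=settings.polish_max_step,
        )
        trace.append(f)
    params_hat = base.with_rates(dict(zip(free_names, x)))
    return FitResult(
        params_hat=params_hat,
        objective=f,
        method="dyetrack_rmse",
        n_iterations=sweeps,
        converged=converged,
        constraints=dict(constraints),
        trace=trace,
        settings={
            "n_sim": n_sim,
            "polish_n_sim": polish_n,
            "direct_evals": settings.direct_evals,
            "powell_tol": settings.powell_tol,
            "line_xatol": settings.line_xatol,
            "seed": settings.seed,
            "warm_start": init is not None,
        },
    )
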