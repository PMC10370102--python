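# Methods

## The generative model

A fluorosequencing experiment attaches dye-labeled peptides to a surface,
images them, and alternates imaging with Edman degradation, which removes one
N-terminal residue per cycle.  A read is the resulting time series of
fluorescence intensities: one value per color channel at timepoint 0 (before
any chemistry) and after each of the `n_cycles` cycles.

`fluorofit` models each read with a hidden Markov model whose states merge
everything the observations cannot distinguish: the number of successful
Edman cycles `n`, the count of live fluorophores per channel `k`, and a
blocked flag; one absorbing state represents a detached peptide.  Merging
makes the state count polynomial in the number of labels (a channel's count
can never exceed the number of its labels still attached), and the blocked
flag doubles the state space.

Six kinds of error rates parameterize the transitions:

| parameter | symbol | meaning | unit |
|---|---|---|---|
| `edman_failure_rate` | e | Edman removal fails this cycle | per cycle |
| `detach_rate` | p | whole peptide leaves the surface | per cycle |
| `initial_block_rate` | b | N-terminus blocked before sequencing | per peptide |
| `cyclic_block_rate` | c | N-terminus becomes blocked | per cycle |
| `dye_loss_rate[ch]` | l | an individual fluorophore is destroyed | per cycle |
| `dud_rate[ch]` | m | a fluorophore is dark from the start | per fluorophore |

Each cycle's transition matrix is factored into one sparse row-stochastic
matrix per mechanism, applied in the order **cyclic block → detach →
per-channel dye loss → Edman**; before timepoint 0 the order is **dud
realization (in the initial distribution) → initial block**.  Blocking must
precede Edman so that a block acquired this cycle gates removal, and dye loss
precedes imaging because destruction happens during the chemistry
incubations.  The order is exposed as a parameter of `transition_factors`
and `forward_backward` so alternatives can be tested; the factorization is
exact for any order (the product of a cycle's factors equals the one-cycle
transition matrix, verified against brute-force enumeration to 1e-12).

Within the Edman factor, removal of a labeled residue decrements that
channel's count by one with hypergeometric probability `k / R`, where `R` is
the number of that channel's labels still attached: the merged state cannot
know whether the removed position's fluorophore was still alive.  Because
duds and dye-loss events strike label positions independently and
identically, the live set is exchangeable over the remaining positions given
the counts, so this marginalization is exact — the merged HMM is precisely
the law of the per-position simulator.  Dud fluorophores still occupy their
positions (removal of a dud label position decrements nothing).

Emissions: a state with `k` fluorophores on a channel emits
`Normal(bg_mu + k*(mu - bg_mu), sqrt(bg_sigma^2 + k*sigma^2))` — the sum of
`k` independent one-dye signals plus background.  The detached state emits
background on every channel (a detached spot looks like background, and
reads keep their fixed shape).  The intensity model (`mu`, `sigma` per
channel, plus `bg_mu`, `bg_sigma`) is an input: it can be supplied, or `mu`
and `sigma` estimated from a one-fluorophore intensity histogram with
`fit_channel_distribution` (Gaussian-KDE smoothed mode, and half-width at
half-maximum divided by sqrt(2 ln 2)).  Background sigma comes from image
processing upstream and is always an input.  Both fitters hold the intensity
model fixed.

## Likelihood evaluation

`forward_backward` runs a scaled forward/backward pass factor by factor
("sub-steps"), applying emission densities at each timepoint and normalizing
per timepoint, so the log-likelihood is the sum of log scale factors and is
finite for any finite read (emission rows are additionally rescaled by their
per-timepoint maximum in log space to avoid underflow).  It returns state
posteriors at every sub-step and sub-transition posteriors across every
factor application.  Rates exactly 0 or 1 are clamped to [1e-9, 1 - 1e-9]
inside likelihood evaluation only, keeping logs finite; reported estimates
are never clamped.

The pass is validated three ways: against an exhaustive sum over all state
paths (1e-10), against a reference Gaussian-HMM implementation on the
unfactored model, and via posterior normalization invariants.

## The EM fitter (tied-parameter Baum-Welch)

Classical Baum-Welch re-estimates every transition probability
independently.  Here every sub-transition posterior is mapped instead to
evidence about the one physical rate that generated it: each parameter
accumulates a weighted trial count `n` and success count `x`, and the M-step
sets the rate to `x / n`.  The mappings:

* dye loss (per channel): `n` += posterior-weighted live-fluorophore count
  before the dye-loss factor; `x` += expected fluorophores lost across it;
* detachment: trials are posterior mass in attached states before the detach
  factor, successes the mass flowing to the detached state;
* Edman failure: trials are unblocked attached mass before the Edman factor,
  successes the mass staying at the same Edman count;
* cyclic block: trials are unblocked mass before each cycle's block factor,
  successes the mass crossing to the blocked twin; initial block uses the
  same mapping on the pre-sequencing factor;
* dud rate (per channel): from the posterior at the first sub-step, each
  state with counts `k` contributes `labels` trials and `labels - k`
  successes per unit mass.

Because every tied likelihood term is Bernoulli/binomial, `x / n` maximizes
the expected complete-data log-likelihood and EM monotonicity holds.  The
vectorized E-step computes these statistics directly from the
forward/backward recursion's own intermediates (no explicit sub-transition
matrices); its exact agreement with the per-read posterior accumulation is a
test.

**Censoring correction.**  Real reads are visible by construction — an
all-dud peptide never shows up — so the fitter conditions the initial
distribution on visibility and, each iteration, adds `N*x/(1-x)` phantom
all-dud pseudo-reads to the dud counts only, where
`x = prod_ch m_ch^labels_ch` under the current estimates and `N` is the
number of observed reads.  Channels are treated independently.  Without the
correction the dud estimate is biased low (demonstrated in the tests).  With
visibility conditioning the dud update is this approximate corrected
estimator rather than an exact M-step, so the textbook monotonicity
guarantee formally applies to the unconditioned configuration; in practice
the conditioned trace is monotone as well, and the monotonicity test runs in
the exact regime.

**Identifiability.**  For single-fluorophore designs, dye loss and
detachment are visibly equivalent, all-dud peptides are unobservable, and
cyclic blocking trades off freely against the Edman failure rate (the
closed-form removal-cycle distribution
`kappa_i = (1-b) C(i+r-1, i) (1-e)^r e^i (1-c)^(r+i)` depends on the tail
only through `e(1-c)`), so `detach_rate`, all `dud_rate`s and
`cyclic_block_rate` are pinned to zero.  Designs with two or more labels
leave all six rates free.

**Numerics.**  Defaults: all starting rates 0.05, three EM runs (the given
start plus jittered variants) keeping the best likelihood, convergence when
the maximum relative parameter change drops below `tol = 1e-6` (relative to
`max(rate, 1e-3)`) or the log-likelihood plateaus, `max_iter = 1000`
E-steps.  Each EM round optionally (default on) takes two EM steps and
extrapolates the parameter vector along the squared step difference,
accepting the extrapolated point only if its observed log-likelihood is not
below the second step's (within the accumulation noise of the working
precision) — this preserves monotonicity while cutting the iteration count
several-fold on the slowly converging block/Edman ridge.  The E-step can run
in single precision (`dtype=np.float32`); the resulting statistics differ in
the sixth decimal, far below sampling noise, and bootstrap replicates use it
by default.

## The dye-track RMSE fitter (DIRECT + Powell)

Each read is reduced to a dye track — per timepoint and channel, the
fluorophore count maximizing the emission density, ties toward the smaller
count — and the data are summarized by the histogram of dye-track counts.
The objective at candidate rates simulates `n_sim` reads, reduces them the
same way, rescales the simulated counts by `n_data / n_sim`, and returns the
root-mean-square difference over the union of observed tracks.  Two
variance-control devices make the surface optimizable:

* **Common random numbers:** the simulator is re-seeded identically on every
  evaluation, so the objective is deterministic and line searches are
  meaningful.
* **Fate stratification:** the simulated peptides' dud patterns, blocking
  times and detachment times are allocated deterministically in exact
  proportion (largest-remainder quotas over the joint strata) rather than
  sampled; only dye loss, Edman success and intensity noise remain random.
  This leaves the objective's expectation unchanged while removing the
  dominant finite-simulation noise on the initial/cyclic block, detachment
  and dud rates — the softest directions of the fit; without it the
  fixed-seed optimum is displaced from the noise-free optimum by an amount
  that can exceed the recovery tolerance.

The blocking rates deserve special care: initial blocking, cyclic blocking
and the Edman failure rate trade off along a nearly flat valley of the
objective (for one fluorophore the trade-off is exact — see the
identifiability discussion), and descent methods settle wherever their
particular stream tilts that valley.  The optimization therefore runs in
four stages: (1) canonical DIRECT over the rate box (default bounds
[0, 0.5] per rate, except [0, 0.99] for the initial block rate so that
acetylated peptides with block rates above 0.9 remain fittable) with a hard
evaluation budget; (2) Powell's method with persistent direction sets —
bounded line searches along one direction at a time, the sweep's net
displacement replacing the direction of largest decrease — with a
trust-region cap on each line search's step so near-flat directions cannot
pull single searches arbitrarily far; (3) a short Powell polish with a
larger simulation (default `min(4*n_data, 2e5)` reads) under a fresh
stream; (4) a profiled grid scan of the initial block rate in two passes —
a coarse scan re-minimizing its main trade-off partners (cyclic block and
Edman failure), then a fine scan around the coarse minimum re-minimizing
*every* other free rate, its objective averaged over independent streams —
whose parabolically-refined minimum gives the final position along the
valley.
A simplified best-box/largest-box trisection search is available as the
`"trisection"` DIRECT backend.  The same identifiability pins as the EM
fitter apply.

Even with all of this, the block rate carries the estimator's largest
residual: across independent 50,000-read datasets its point-estimate error
is typically one or two tenths of a percentage point but can approach a
full point on an unlucky dataset — an intrinsic property of the raw-count
RMSE statistic, echoed by this fitter's visibly wider bootstrap
distributions.  The likelihood-based fitter resolves the same parameter
about an order of magnitude more tightly.

## Bootstrap

Both fitters share a percentile bootstrap: each replicate resamples the
reads with replacement to the original size and refits, warm-started from
the original-data estimate (EM: a single capped run; RMSE: Powell sweeps
only, each replicate under its own simulation stream so finite-simulation
displacement averages out of the replicate median).  Confidence intervals
are empirical quantiles with linear interpolation.  Per-replicate randomness
comes from `SeedSequence(seed, spawn_key=(replicate,))` child streams, so
results are reproducible and independent of execution order.  Failed
replicate fits are warned about and skipped; the summary reports the
effective count.

## The simulator and what it does not emulate

`simulate_reads` draws duds and the initial block, then applies the error
mechanisms each cycle in the model's factor order, tracking per-position
fluorophores, and emits intensities from the per-count normal model;
detached peptides keep emitting background.  All-dud peptides are re-drawn
by default so the requested number of *visible* reads is exact (the re-drawn
count is reported for censoring tests).  Truth tracks record pre-noise
counts.

The simulator realizes exactly the process the HMM describes.  Passing the
recovery tests therefore shows correctness of the estimators under the
model, not robustness to real-data pathologies: contaminant fluorophores,
non-normal intensity distributions, cycle-to-cycle brightness drift, and
position-specific Edman chemistry (e.g. prolines) are not emulated.  The
contaminant filter (`filter_reads`: a read is dropped if any intensity falls
outside every allowed closed interval of its channel) and the histogram
mu/sigma estimator are provided for such data but are exercised only on
synthetic mixtures here.

## Reference experiment scales

The validation experiments fix these conditions (see
`fluorofit/scenarios.py`): a one-channel peptide with labels at positions 2
and 4 over 10 Edman cycles; ground truth e=0.06, p=0.05, b=0.10, c=0.02,
l=0.05, m=0.15 (all at or below 0.2, in the ranges reported for current
instruments); intensity model mu=6000, sigma=700 over background sigma=350.
Recovery uses 50,000 reads with 50 bootstrap replicates per method; the
dispersion-scaling experiment uses 1,000 / 10,000 / 100,000 reads with 25
replicates; the censoring experiment uses 15,000 reads at a dud rate of
0.2; the blocked-peptide experiment uses 10,000 reads of a single-label
acetylated design at b=0.95.  Bootstrap replicates run with capped
iteration budgets (EM: 8 accelerated E-steps; RMSE: 2 sweeps at
n_sim=15,000): warm-started replicates move by a few tenths of a percent at
most, well above the residual convergence error these caps leave.

## Known limitations

* Parameters are fit per peptide; no joint multi-peptide fitting.
* The intensity model is never re-estimated inside EM; a badly specified
  mu/sigma biases all rate estimates.
* For single-label designs the pinned parameters are a modeling convention,
  not an estimate: data generated with genuine detachment will fold that
  signal into the dye-loss rate.
* The RMSE fitter's objective weights common dye tracks heavily (raw counts,
  not frequencies); rare-track information is down-weighted relative to the
  likelihood-based fitter, which is one reason its estimates disperse more.
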