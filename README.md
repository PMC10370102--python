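# fluorofit

Error-rate estimation for single-molecule protein fluorosequencing.

Fluorosequencing reads out peptides one molecule at a time: peptides are
labeled with fluorescent dyes on specific residues, attached to a surface,
and imaged between rounds of Edman degradation, which removes one N-terminal
residue per cycle.  Each read is a time series of fluorescence intensities
per color channel.  Interpreting such data — and improving the chemistry —
requires knowing the experiment's error rates: the Edman failure rate e, the
peptide detachment rate p, the initial and cyclic N-terminal blocking rates
b and c, and per-channel dye loss and dud (dark-fluorophore) rates l and m.

`fluorofit` estimates these rates from a table of reads in two independent
ways:

* **Tied-parameter Baum-Welch.**  Each peptide's sequencing process is a
  hidden Markov model over merged states (Edman count × per-channel
  fluorophore counts × blocked flag, plus a detached state), with the cycle
  transition matrix factored into one sparse factor per error mechanism.
  Instead of re-estimating every transition probability, the EM M-step
  computes a weighted maximum-likelihood estimate of each *physical rate*
  directly from the sub-transition posteriors: each rate is updated to
  x/n, its expected successes over expected trials.  All-dud peptides never
  appear as reads, so the dud rates additionally receive an iterative
  censoring correction (N·x/(1−x) phantom all-dud reads per iteration).
* **DIRECT + Powell dye-track RMSE.**  Reads are reduced to integer
  fluorophore-count tracks; candidate rates are scored by the RMSE between
  the data's dye-track histogram and a seeded simulation's, and minimized by
  a global DIRECT search followed by Powell-style coordinate/ridge line
  minimization.

A Monte Carlo read simulator (also the package's synthetic-data generator),
percentile-bootstrap confidence intervals, intensity-model fitting and
contaminant filtering round out the toolkit.  For single-fluorophore
peptides the unidentifiable parameters (detachment, duds, cyclic blocking)
are pinned to zero automatically; the closed-form removal-cycle distribution
κᵢ = (1−b)·C(i+r−1, i)·(1−e)ʳ·eⁱ·(1−c)^(r+i) behind that choice is exposed
as `kappa_distribution`.

## A worked example

```python
import numpy as np
from fluorofit import fit_baum_welch, simulate_reads
from fluorofit.params import rate_names_for
from fluorofit.scenarios import two_label_design, two_label_truth

design = two_label_design()          # one channel, labels at residues 2 and 4
truth = two_label_truth()            # e=0.06 p=0.05 b=0.10 c=0.02 l=0.05 m=0.15
sim = simulate_reads(design, truth, 20_000, seed=2)

init = truth.with_rates({n: 0.05 for n in rate_names_for(design)})
em = fit_baum_welch(sim.reads, design, init, n_starts=1, dtype=np.float32)
for name in rate_names_for(design):
    print(f"{name:24s} truth={truth.get_rate(name):.3f} "
          f"est={em.params_hat.get_rate(name):.4f}")
```

prints (seed 2):

```
edman_failure_rate       truth=0.060 est=0.0616
detach_rate              truth=0.050 est=0.0493
initial_block_rate       truth=0.100 est=0.1029
cyclic_block_rate        truth=0.020 est=0.0191
dye_loss_rate[0]         truth=0.050 est=0.0501
dud_rate[0]              truth=0.150 est=0.1533
```

i.e. every rate is recovered to a few tenths of a percentage point from
20,000 reads; at 50,000 reads both estimators land within half a point (the
`examples/` scripts walk through the RMSE fitter, bootstrap intervals,
censoring and blocking).

The command-line surface mirrors the library:

```
fluorofit simulate --config config.yaml --n-reads 50000 --seed 1 --out reads.tsv
fluorofit filter   --config config.yaml --reads reads.tsv --out kept.tsv
fluorofit fit bw   --config config.yaml --reads kept.tsv --out fit.json
fluorofit fit rmse --config config.yaml --reads kept.tsv --out fit.json
fluorofit bootstrap --config config.yaml --reads kept.tsv --method bw --out boot.json
fluorofit kappa -r 2 -e 0.06 -b 0.1 -c 0.02
```

Reads travel as wide TSV (one row per read, `ch{c}_t{t}` columns); designs
can be given as peptide notation (`"NH2-G{azK}*AG{azK}*|"` — an asterisk
marks a labeled residue, the tag records the N-terminal chemistry).

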