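"""Reference study conditions used by the examples, tests and the
reproduction script.

These fix, once, the synthetic designs and ground-truth parameters of the
package's validation experiments: a two-fluorophore peptide for which all six
error rates are identifiable, a one-fluorophore peptide (detachment, dud and
cyclic blocking pinned to zero), and an N-terminally blocked variant.  Rates
sit in the ranges reported for current instruments (Edman failure a few
percent, dye loss ~5%/cycle, dud rates 10-20%); the intensity model uses a
well-separated one-dye peak (mu = 6000, sigma = 700) over background noise
(sigma = 350), similar to published intensity histograms.
"""

from __future__ import annotations

from .params import PeptideDesign, SequencingParams

__all__ = [
    "two_label_design",
    "two_label_truth",
    "one_label_design",
    "one_label_truth",
    "blocked_design",
    "blocked_truth",
]

_INTENSITY = dict(mu=(6000.0,), sigma=(700.0,), bg_mu=0.0, bg_sigma=350.0)


def two_label_design() -> PeptideDesign:
    """One channel, labels at positions 2 and 4, 10 Edman cycles."""
    return PeptideDesign(labels_by_channel=((2, 4),), n_cycles=10, n_terminus="NH2")


def two_label_truth() -> SequencingParams:
    """Ground truth for the two-label recovery experiment (all rates <= 0.2)."""
    return SequencingParams(
        edman_failure_rate=0.06,
        detach_rate=0.05,
        initial_block_rate=0.10,
        cyclic_block_rate=0.02,
        dye_loss_rate=(0.05,),
        dud_rate=(0.15,),
        **_INTENSITY,
    )


def one_label_design() -> PeptideDesign:
    """One channel, single label at position 3 (an fmoc-APK*-style peptide)."""
    return PeptideDesign(labels_by_channel=((3,),), n_cycles=8, n_terminus="fmoc")


def one_label_truth() -> SequencingParams:
    """Ground truth for the one-label scenario; unidentifiable rates are 0."""
    return SequencingParams(
        edman_failure_rate=0.07,
        detach_rate=0.0,
        initial_block_rate=0.10,
        cyclic_block_rate=0.0,
        dye_loss_rate=(0.04,),
        dud_rate=(0.0,),
        **_INTENSITY,
    )


def blocked_design() -> PeptideDesign:
    """Single label at position 2 on an acetylated (blocked) peptide."""
    return PeptideDesign(labels_by_channel=((2,),), n_cycles=8, n_terminus="ac")


def blocked_truth() -> SequencingParams:
    """Heavily blocked variant: 95% of peptides never sequence."""
    return SequencingParams(
        edman_failure_rate=0.02,
        detach_rate=0.0,
        initial_block_rate=0.95,
        cyclic_block_rate=0.0,
        dye_loss_rate=(0.04,),
        dud_rate=(0.0,),
        **_INTENSITY,
    )
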