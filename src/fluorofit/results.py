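"""Result containers shared by the two fitters."""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import SequencingParams

__all__ = ["FitResult"]


@dataclass
class FitResult:
    """Point estimate and convergence information from one fit.

    ``objective`` is the final observed-data log-likelihood for the EM fitter
    and the final dye-track histogram RMSE for the DIRECT+Powell fitter (the
    ``method`` field says which).  ``constraints`` lists the parameters held
    fixed during the fit, as name -> pinned value.
    """

    params_hat: SequencingParams
    objective: float
    method: str
    n_iterations: int
    converged: bool
    constraints: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    @property
    def log_likelihood(self) -> float:
        if self.method != "baum_welch":
            raise AttributeError("log_likelihood is only defined for the EM fitter")
        return self.objective

    @property
    def rmse(self) -> float:
        if self.method != "dyetrack_rmse":
            raise AttributeError("rmse is only defined for the dye-track fitter")
        return self.objective
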