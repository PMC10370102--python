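"""File formats and peptide-notation parsing.

Reads are stored wide: one TSV row per read (``read_id`` plus one
``ch{c}_t{t}`` column per channel/timepoint).  Fit results and bootstrap
summaries are schema-versioned JSON.  Peptide designs can be written in the
field's sequence notation: single-letter residues (or ``{...}`` groups such
as azido-lysine ``{azK}``), an asterisk after each labeled residue, an
optional N-terminal tag (``NH2-``, ``fmoc-``, ``ac-``) and an optional
trailing ``|`` marking truncation at the last labeled residue.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bootstrap import BootstrapSummary
from .emission import IntensityFilter
from .params import PeptideDesign, SequencingParams
from .reads import ReadSet
from .results import FitResult

__all__ = [
    "parse_peptide_notation",
    "read_reads_tsv",
    "write_reads_tsv",
    "write_fit_json",
    "read_fit_json",
    "load_config",
    "design_from_config",
    "params_from_config",
    "filter_from_config",
]

SCHEMA_VERSION = 1

_NTERM_TAGS = {"NH2": "NH2", "NH_2_": "NH2", "fmoc": "fmoc", "ac": "ac"}
# default labeling chemistry: lysine and azido-lysine dyes on channel 0
DEFAULT_LABEL_RULES = {"K": 0, "{azK}": 0}


def parse_peptide_notation(
    s: str,
    label_rules: dict | None = None,
    n_cycles: int = 10,
) -> PeptideDesign:
    """Parse sequence notation like ``"NH2-G{azK}*AG{azK}*|"`` into a design.

    ``label_rules`` maps residue tokens (e.g. ``"K"``, ``"{azK}"``) to the
    color channel of their dye.  A ``*`` marks the preceding residue as
    labeled; starred residues must appear in ``label_rules``.  The N-terminal
    tag is recorded as metadata only (an acetylated peptide is expected to
    *fit* with a high initial block rate; the tag does not change the model).
    """
    if label_rules is None:
        label_rules = DEFAULT_LABEL_RULES
    text = s.strip()
    n_terminus = None
    for tag, canonical in _NTERM_TAGS.items():
        if text.startswith(tag + "-"):
            n_terminus = canonical
            text = text[len(tag) + 1 :]
            break
    text = text.rstrip("|∣")
    tokens: list[str] = []
    starred: list[bool] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "{":
            j = text.find("}", i)
            if j < 0:
                raise ValueError(f"unclosed '{{' in peptide notation {s!r}")
            tokens.append(text[i : j + 1])
            starred.append(False)
            i = j + 1
        elif ch == "*":
            if not tokens or starred[-1]:
                raise ValueError(f"'*' must follow a residue token in {s!r}")
            starred[-1] = True
            i += 1
        elif ch.isalpha():
            tokens.append(ch)
            starred.append(False)
            i += 1
        else:
            raise ValueError(f"unknown character {ch!r} in peptide notation {s!r}")
    n_channels = max(label_rules.values()) + 1 if label_rules else 1
    labels: list[list[int]] = [[] for _ in range(n_channels)]
    for pos, (token, is_labeled) in enumerate(zip(tokens, starred), start=1):
        if not is_labeled:
            continue
        if token not in label_rules:
            raise ValueError(f"labeled token {token!r} has no channel assignment")
        labels[label_rules[token]].append(pos)
    return PeptideDesign(
        labels_by_channel=tuple(tuple(ch) for ch in labels),
        n_cycles=n_cycles,
        n_terminus=n_terminus,
    )


# ---------------------------------------------------------------------------
# reads TSV

_COLUMN_RE = re.compile(r"^ch(\d+)_t(\d+)$")


def write_reads_tsv(reads: ReadSet, path) -> None:
    """One row per read: ``read_id`` then ``ch{c}_t{t}`` columns (channel
    outer, timepoint inner).  Values round-trip losslessly."""
    n, t_points, n_ch = reads.intensities.shape
    data = {"read_id": reads.read_ids}
    for c in range(n_ch):
        for t in range(t_points):
            data[f"ch{c}_t{t}"] = reads.intensities[:, t, c]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> ReadSet:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    if "read_id" not in df.columns:
        raise ValueError(f"{path}: missing 'read_id' column")
    channels: set[int] = set()
    timepoints: set[int] = set()
    for col in df.columns:
        m = _COLUMN_RE.match(col)
        if m:
            channels.add(int(m.group(1)))
            timepoints.add(int(m.group(2)))
    if not channels:
        raise ValueError(f"{path}: no ch{{c}}_t{{t}} intensity columns found")
    n_ch = max(channels) + 1
    t_points = max(timepoints) + 1
    n = len(df)
    intensities = np.empty((n, t_points, n_ch))
    for c in range(n_ch):
        for t in range(t_points):
            col = f"ch{c}_t{t}"
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
            values = pd.to_numeric(df[col], errors="coerce").to_numpy()
            bad = np.nonzero(~np.isfinite(values))[0]
            if len(bad) and n > 0:
                raise ValueError(
                    f"{path}: non-numeric value in column {col!r}, row {bad[0] + 1}"
                )
            intensities[:, t, c] = values
    return ReadSet(intensities, [str(r) for r in df["read_id"]])


# ---------------------------------------------------------------------------
# fit results JSON


def _params_to_json(p: SequencingParams) -> dict:
    return {
        "edman_failure_rate": p.edman_failure_rate,
        "detach_rate": p.detach_rate,
        "initial_block_rate": p.initial_block_rate,
        "cyclic_block_rate": p.cyclic_block_rate,
        "dye_loss_rate": list(p.dye_loss_rate),
        "dud_rate": list(p.dud_rate),
        "mu": list(p.mu),
        "sigma": list(p.sigma),
        "bg_mu": p.bg_mu,
        "bg_sigma": p.bg_sigma,
    }


def params_from_json(d: dict) -> SequencingParams:
    return SequencingParams(**d)


def write_fit_json(result, path) -> None:
    """Serialize a FitResult or BootstrapSummary (schema-versioned)."""
    if isinstance(result, FitResult):
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "fit",
            "method": result.method,
            "params_hat": _params_to_json(result.params_hat),
            "objective": result.objective,
            "n_iterations": result.n_iterations,
            "converged": result.converged,
            "constraints": result.constraints,
            "trace": list(result.trace),
            "settings": result.settings,
        }
    elif isinstance(result, BootstrapSummary):
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "bootstrap",
            "point": result.point,
            "ci": {k: list(v) for k, v in result.ci.items()},
            "ci_level": result.ci_level,
            "n_boot": result.n_boot,
            "n_effective": result.n_effective,
            "seed": result.seed,
            "replicates": result.replicates.to_dict(orient="list"),
        }
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema version")
    return payload


# ---------------------------------------------------------------------------
# run configuration (YAML or JSON; equivalent schemas)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def design_from_config(cfg: dict) -> PeptideDesign:
    d = cfg["design"]
    n_cycles = int(d["n_cycles"])
    if "peptide" in d:
        rules = d.get("label_rules", DEFAULT_LABEL_RULES)
        rules = {k: int(v) for k, v in rules.items()}
        return parse_peptide_notation(d["peptide"], rules, n_cycles)
    return PeptideDesign(
        labels_by_channel=tuple(tuple(ch) for ch in d["labels_by_channel"]),
        n_cycles=n_cycles,
        n_terminus=d.get("n_terminus"),
    )


def params_from_config(cfg: dict) -> SequencingParams:
    p = dict(cfg["params"])
    rates = p.pop("rates", {})
    base = SequencingParams(
        edman_failure_rate=0.0,
        detach_rate=0.0,
        initial_block_rate=0.0,
        cyclic_block_rate=0.0,
        dye_loss_rate=tuple(0.0 for _ in p["mu"]),
        dud_rate=tuple(0.0 for _ in p["mu"]),
        mu=tuple(p["mu"]),
        sigma=tuple(p["sigma"]),
        bg_mu=float(p.get("bg_mu", 0.0)),
        bg_sigma=float(p["bg_sigma"]),
    )
    return base.with_rates({k: float(v) for k, v in rates.items()})


def filter_from_config(cfg: dict) -> IntensityFilter:
    return IntensityFilter.from_config(cfg.get("filter", {}))
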