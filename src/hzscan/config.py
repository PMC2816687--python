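"""Analysis thresholds, overridable from a key-value YAML config file."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Thresholds:
    """Pipeline-wide cutoffs.

    maf: informativeness filter — sites must have minor-allele frequency
         strictly above this to enter LD analysis (also the rare-minor
         condensation threshold).
    alpha: family-wise error rate for the Bonferroni cutoff.
    ld_min_n: minimum complete individuals for a pairwise LD estimate.
    efficiency: qPCR amplification efficiency (2 = perfect doubling).
    """

    maf: float = 0.05
    alpha: float = 0.05
    ld_min_n: int = 20
    efficiency: float = 2.0


def load_config(path: str | Path | None) -> Thresholds:
    """Thresholds from a flat YAML mapping; unknown keys are rejected."""
    base = Thresholds()
    if path is None:
        return base
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(Thresholds)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)} "
                         f"(expected subset of {sorted(known)})")
    return replace(base, **data)
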