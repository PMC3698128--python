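"""Result tables and run manifests.

ICER grids render as products x instruments tables (one per discounting
mode), each cell a whole-dollar ICER annotated with its WHO class, or a
dominance label where the ratio is undefined.  Internal arithmetic stays at
full precision; rounding happens only here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .parameters import ValidationError
from .scenarios import ScenarioResult

__all__ = ["render_icer_table", "icer_grid_frame", "RunManifest"]

_WHO_ABBREV = {
    "highly cost-effective": "highly CE",
    "cost-effective": "CE",
    "not cost-effective": "not CE",
}


def _cell_text(ce) -> str:
    if ce.dominance is not None:
        return ce.dominance
    if math.isnan(ce.icer):
        return "undefined"
    return f"{ce.icer:,.0f} ({_WHO_ABBREV.get(ce.who_class, ce.who_class)})"


def icer_grid_frame(result: ScenarioResult, mode: str = "discounted") -> pd.DataFrame:
    """Products-as-rows, instruments-as-columns ICER grid (numeric)."""
    discounted = _mode_flag(mode)
    f = result.frame
    sel = f[f["discounted"] == discounted]
    return sel.pivot(index="strategy", columns="instrument", values="icer")


def _mode_flag(mode: str) -> bool:
    if mode == "discounted":
        return True
    if mode == "undiscounted":
        return False
    raise ValidationError(f"mode must be 'discounted' or 'undiscounted', got {mode!r}")


def render_icer_table(result: ScenarioResult, mode: str = "discounted") -> str:
    """Aligned-text ICER table with WHO-class annotations."""
    discounted = _mode_flag(mode)
    result.check_complete()
    spec = result.spec
    strategies = list(dict.fromkeys(result.frame["strategy"]))
    rows = []
    for strategy in strategies:
        row = {"strategy": strategy}
        for inst in spec.instruments:
            row[inst] = _cell_text(result.cell(strategy, inst, discounted))
        rows.append(row)
    table = pd.DataFrame(rows).to_string(index=False)
    header = (
        f"ICER (USD per QALY) vs symptom management - {mode}\n"
        f"parameters: {result.fingerprint[:12]}\n"
    )
    return header + table + "\n"


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output set."""

    command: str
    params_fingerprint: str
    seed: int | None
    version: str
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        return path
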