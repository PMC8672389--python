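"""Total allowable error (TEa) utilities.

TEa is the maximum combined bias and imprecision considered clinically
acceptable for a test. CLIA publishes per-analyte values; where CLIA gives
an absolute concentration instead of a percentage (calcium, potassium,
sodium), a percentage defined at the medically most critical concentration
is used. A stricter, biological-variation-based minimum TEa can be derived
from the intra-individual (CVi) and inter-individual (CVg) coefficients of
variation:

    min TEa = 1.65 * (0.75 * CVi) + 0.375 * sqrt(CVi**2 + CVg**2)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

__all__ = ["TeaTable", "min_tea", "tea_lookup", "load_tea_table"]

VALID_SOURCES = {"CLIA", "Westgard-critical-concentration", "biological-variation"}


def min_tea(cvi: float, cvg: float) -> float:
    """Biological-variation minimum allowable error, in percent.

    ``1.65*(0.75*cvi) + 0.375*sqrt(cvi**2 + cvg**2)`` — an imprecision term
    at the 95th one-sided percentile plus a bias term against the combined
    biological variation. Linear under joint scaling of both CVs.
    """
    if cvi < 0 or cvg < 0:
        raise ValueError("CVi and CVg must be >= 0")
    return 1.65 * (0.75 * cvi) + 0.375 * math.sqrt(cvi**2 + cvg**2)


@dataclass
class TeaTable:
    """Mapping of analyte name to TEa percentage, with a source tag each."""

    values: dict = field(default_factory=dict)  # lowercase name -> (tea_pct, source)

    def add(self, analyte_name: str, tea_pct: float, source: str = "CLIA") -> None:
        if tea_pct <= 0:
            raise ValueError("TEa must be > 0")
        if source not in VALID_SOURCES:
            raise ValueError(f"unknown TEa source {source!r}; one of {sorted(VALID_SOURCES)}")
        self.values[analyte_name.lower()] = (float(tea_pct), source)

    def analytes(self) -> list[str]:
        return sorted(self.values)

    def __contains__(self, analyte_name: str) -> bool:
        return analyte_name.lower() in self.values


def tea_lookup(analyte_name: str, table: Optional[TeaTable] = None) -> float:
    """TEa percentage for an analyte (case-insensitive).

    Falls back to the packaged table when none is supplied. Unknown
    analytes raise a ``KeyError`` listing the known ones.
    """
    if table is None:
        table = load_tea_table()
    entry = table.values.get(analyte_name.lower())
    if entry is None:
        raise KeyError(
            f"no TEa configured for {analyte_name!r}; "
            f"known analytes: {', '.join(table.analytes())}"
        )
    return entry[0]


def load_tea_table(path: Optional[str] = None) -> TeaTable:
    """Load a TEa table from YAML (packaged default: ``data/tea.yaml``)."""
    if path is None:
        text = resources.files("pbrtqc.data").joinpath("tea.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    table = TeaTable()
    for name, entry in raw.items():
        if isinstance(entry, dict):
            table.add(name, entry["tea_pct"], entry.get("source", "CLIA"))
        else:
            table.add(name, float(entry))
    return table
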