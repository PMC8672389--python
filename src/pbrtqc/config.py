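"""Procedure/analyte configuration files.

A procedure config is a YAML or JSON mapping holding the union of the
:class:`~pbrtqc.types.MAProcedure` and :class:`~pbrtqc.types.AnalyteConfig`
fields for one analyte. The packaged ``data/procedures.yaml`` ships ready
configs for 10 clinical chemistry analytes; ``data/procedure.schema.json``
is the JSON Schema the fields validate against (generated from the pydantic
models, so validation errors come from the same source of truth).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from pbrtqc.types import AnalyteConfig, Formula, MAProcedure

__all__ = [
    "load_procedure_entry",
    "load_procedures",
    "load_procedure_file",
    "save_procedure",
    "procedure_json_schema",
]

_PROC_FIELDS = {
    "formula",
    "block_size",
    "weighting_factor",
    "truncation_lower",
    "truncation_upper",
    "control_lower",
    "control_upper",
    "ewma_seed",
}
_ANALYTE_FIELDS = {"units", "tea_pct", "min_tea_pct", "daily_volume", "cvi", "cvg"}


def load_procedure_entry(name: str, entry: dict) -> tuple[MAProcedure, AnalyteConfig]:
    """Build the typed pair from one raw config mapping."""
    unknown = set(entry) - _PROC_FIELDS - _ANALYTE_FIELDS
    if unknown:
        raise ValueError(f"{name}: unknown config fields {sorted(unknown)}")
    proc = MAProcedure(
        analyte_name=name,
        **{k: v for k, v in entry.items() if k in _PROC_FIELDS},
    )
    analyte = AnalyteConfig(
        analyte_name=name,
        **{k: v for k, v in entry.items() if k in _ANALYTE_FIELDS},
    )
    return proc, analyte


def load_procedures(path: Optional[str] = None) -> dict:
    """Load all procedure configs (packaged default: 10 analytes).

    Returns ``{analyte_name: (MAProcedure, AnalyteConfig)}``.
    """
    if path is None:
        text = resources.files("pbrtqc.data").joinpath("procedures.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {name: load_procedure_entry(name, entry) for name, entry in raw.items()}


def load_procedure_file(path: str) -> tuple[MAProcedure, AnalyteConfig]:
    """Load a single-analyte config file (YAML or JSON).

    The file either maps one analyte name to its fields, or carries an
    explicit ``analyte_name`` key at top level.
    """
    text = Path(path).read_text()
    raw = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"{path}: expected a non-empty mapping")
    if "analyte_name" in raw:
        name = raw.pop("analyte_name")
        return load_procedure_entry(name, raw)
    if len(raw) != 1:
        raise ValueError(
            f"{path}: a single-procedure config must hold exactly one analyte"
        )
    (name, entry), = raw.items()
    return load_procedure_entry(name, entry)


def save_procedure(proc: MAProcedure, analyte: AnalyteConfig, path: str) -> None:
    """Write a procedure + analyte config as JSON (or YAML by extension)."""
    entry = {}
    entry.update({k: v for k, v in proc.model_dump().items() if k != "analyte_name"})
    entry.update({k: v for k, v in analyte.model_dump().items() if k != "analyte_name"})
    entry["formula"] = Formula(entry["formula"]).value
    payload = {"analyte_name": proc.analyte_name, **{k: v for k, v in entry.items() if v is not None}}
    out = Path(path)
    if out.suffix in (".yaml", ".yml"):
        out.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        out.write_text(json.dumps(payload, indent=2) + "\n")


def procedure_json_schema() -> dict:
    """JSON Schema for a combined procedure + analyte config."""
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "MA procedure configuration",
        "type": "object",
        "allOf": [
            MAProcedure.model_json_schema(),
        ],
        "properties": {
            "analyte_config": AnalyteConfig.model_json_schema(),
        },
    }
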