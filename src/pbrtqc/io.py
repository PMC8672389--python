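"""Result-stream CSV interchange and MA chart rendering.

Stream files are locale-neutral CSV: UTF-8, comma-separated, ``.`` decimal
separator, ISO-8601 timestamps, one result per row, sorted by timestamp.
Columns: ``sample_id, patient_id, timestamp, analyte, value, unit,
hil_flags, is_control`` (``hil_flags`` a subset of ``"HIL"``, empty
allowed; ``is_control`` 0/1).
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from pbrtqc.types import MAPoint, MAProcedure, PatientResult

__all__ = ["STREAM_COLUMNS", "read_stream", "write_stream", "render_ma_chart"]

STREAM_COLUMNS = (
    "sample_id",
    "patient_id",
    "timestamp",
    "analyte",
    "value",
    "unit",
    "hil_flags",
    "is_control",
)


class StreamSchemaError(ValueError):
    """The stream file does not conform to the interchange schema."""


def write_stream(
    stream: Sequence[PatientResult], path: str, unit: str = ""
) -> None:
    """Write a result stream to interchange CSV."""
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in stream],
            "patient_id": [r.patient_id for r in stream],
            "timestamp": [r.timestamp.isoformat() for r in stream],
            "analyte": [r.analyte_name for r in stream],
            "value": [repr(r.value) for r in stream],
            "unit": unit,
            "hil_flags": ["".join(sorted(r.hil_flags)) for r in stream],
            "is_control": [int(r.is_control) for r in stream],
        }
    )
    frame.to_csv(path, index=False)


def read_stream(path: str, sort: bool = False) -> list[PatientResult]:
    """Read and validate a result stream from interchange CSV.

    Malformed rows (unparseable value/timestamp, bad flags) are rejected
    with their file line numbers. Non-monotone timestamps raise unless
    ``sort=True``, in which case the stream is stably sorted.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise StreamSchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in STREAM_COLUMNS if c not in frame.columns and c != "unit"]
    if missing:
        raise StreamSchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    results: list[PatientResult] = []
    errors: list[str] = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        lineno = pos + 2  # header is line 1
        try:
            value = float(row.value)
            timestamp = datetime.fromisoformat(row.timestamp)
            flags = frozenset(row.hil_flags)
            if not flags <= {"H", "I", "L"}:
                raise ValueError(f"invalid hil_flags {row.hil_flags!r}")
            if row.is_control not in ("0", "1"):
                raise ValueError(f"invalid is_control {row.is_control!r}")
            results.append(
                PatientResult(
                    sample_id=row.sample_id,
                    patient_id=row.patient_id,
                    timestamp=timestamp,
                    analyte_name=row.analyte,
                    value=value,
                    hil_flags=flags,
                    is_control=row.is_control == "1",
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        shown = "; ".join(errors[:10])
        more = f" (+{len(errors) - 10} more)" if len(errors) > 10 else ""
        raise StreamSchemaError(f"{path}: {len(errors)} malformed row(s): {shown}{more}")

    stamps = [r.timestamp for r in results]
    if any(b < a for a, b in zip(stamps, stamps[1:])):
        if not sort:
            raise StreamSchemaError(
                f"{path}: timestamps are not monotone non-decreasing "
                "(pass sort=True / --sort to sort)"
            )
        results.sort(key=lambda r: r.timestamp)
    return results


def render_ma_chart(
    ma_points: Sequence[MAPoint],
    proc: MAProcedure,
    out_png: Optional[str] = None,
    out_csv: Optional[str] = None,
) -> pd.DataFrame:
    """Dual-series MA chart: raw included results and their MA values.

    Control limits are drawn as horizontal lines and alarming points are
    marked. Returns (and optionally writes) the tidy table of plotted
    points — one row per MA point.
    """
    if not ma_points:
        raise ValueError("no MA points to plot")
    frame = pd.DataFrame(
        {
            "index": [p.index for p in ma_points],
            "timestamp": [p.source_result.timestamp for p in ma_points],
            "sample_id": [p.source_result.sample_id for p in ma_points],
            "result_value": [p.source_result.value for p in ma_points],
            "ma_value": [p.ma_value for p in ma_points],
            "warmup": [p.warmup for p in ma_points],
            "alarm": [p.alarm.value for p in ma_points],
        }
    )
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 5))
        ax.plot(
            frame["index"], frame["result_value"], ".", ms=3, alpha=0.4,
            color="grey", label="patient results",
        )
        ax.plot(frame["index"], frame["ma_value"], "-", lw=1.5, label="MA value")
        ax.axhline(proc.control_lower, color="tab:red", ls="--", lw=1, label="control limits")
        ax.axhline(proc.control_upper, color="tab:red", ls="--", lw=1)
        alarms = frame[frame["alarm"] != "none"]
        if not alarms.empty:
            ax.plot(
                alarms["index"], alarms["ma_value"], "o", color="tab:red",
                ms=6, label="MA alarm",
            )
        ax.set_xlabel("included result number")
        ax.set_ylabel(f"{proc.analyte_name} value")
        ax.set_title(f"Moving average control chart: {proc.analyte_name}")
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return frame
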