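"""Report serialization shared by all engines.

JSON is the canonical format and round-trips losslessly through the report
classes' ``to_dict``/``from_dict``; CSV is a flat projection with one row
per spot/cell plus a summary row.  A report that violates its own
invariants is refused at write time.  Nothing time- or host-dependent is
written, so a result file is reproducible bit-for-bit from (input, config,
seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .elispot import SpotReport
from .infiltrate import InfiltrationResult, PooledSummary

__all__ = ["write_report", "read_report"]


def _validate(report) -> dict:
    if isinstance(report, (SpotReport, InfiltrationResult)):
        report.validate()
        d = report.to_dict()
        d["report_type"] = type(report).__name__
        return d
    if isinstance(report, PooledSummary):
        d = report.to_dict()
        d["report_type"] = "PooledSummary"
        return d
    raise TypeError(f"cannot write report of type {type(report).__name__}")


def write_report(report, path, fmt: str = "json") -> Path:
    """Write a SpotReport / InfiltrationResult / PooledSummary to disk."""
    path = Path(path)
    d = _validate(report)
    if fmt == "json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        _write_csv(report, d, path)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def _write_csv(report, d: dict, path: Path) -> None:
    if isinstance(report, SpotReport):
        rows = pd.DataFrame(d["spots"])
        summary = {
            "spot_id": "SUMMARY",
            "area_um2": d["size_stats"]["mean"],
            "accepted": d["n_accepted"],
        }
    elif isinstance(report, InfiltrationResult):
        rows = pd.DataFrame(d["records"])
        summary = {
            "cell_id": "SUMMARY",
            "signed_distance_um": "",
            "classification": f"infiltrated={d['n_infiltrated']}/{d['n_cells_total']}",
        }
    else:  # PooledSummary
        rows = pd.DataFrame(
            {
                "chip": range(1, d["n_chips"] + 1),
                "n_infiltrated": d["n_infiltrated_per_chip"],
                "infiltrated_fraction": d["infiltrated_fraction_per_chip"],
            }
        )
        summary = {
            "chip": "SUMMARY",
            "n_infiltrated": f"{d['mean_n_infiltrated']}±{d['sem_n_infiltrated']}",
            "infiltrated_fraction": f"{d['mean_infiltrated_fraction']}±{d['sem_infiltrated_fraction']}",
        }
    if rows.empty:
        rows = pd.DataFrame(columns=list(summary))
    rows = pd.concat([rows, pd.DataFrame([summary])], ignore_index=True)
    rows.to_csv(path, index=False)


def read_report(path):
    """Read a JSON report back into its typed form."""
    d = json.loads(Path(path).read_text())
    kind = d.pop("report_type", None)
    if kind == "SpotReport":
        return SpotReport.from_dict(d)
    if kind == "InfiltrationResult":
        return InfiltrationResult.from_dict(d)
    if kind == "PooledSummary":
        return PooledSummary(**d)
    raise ValueError(f"{path}: unrecognized report_type {kind!r}")
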