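"""Signal file reading and analysis-record serialisation.

Signals are single-column numeric text files (one magnitude per line, an
optional header auto-detected, configurable delimiter for multi-column
files).  Analysis records are self-describing JSON (full float precision,
round-trip safe) with an optional per-pattern CSV table.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .ordinal_encoding import Signal
from .op_statistics import SummaryResult

__all__ = ["AnalysisRecord", "read_signal", "write_record", "read_record"]


@dataclass
class AnalysisRecord:
    """Self-describing analysis output: provenance plus numeric results."""

    provenance: dict
    results: dict

    def to_dict(self) -> dict:
        return {"provenance": self.provenance, "results": self.results}

    @classmethod
    def from_summary(cls, summary: SummaryResult, extra_provenance: Optional[dict] = None):
        prov = dict(summary.provenance)
        if extra_provenance:
            prov.update(extra_provenance)
        var = summary.variability
        results = {
            "H": summary.entropy.H,
            "H_inf": summary.entropy.H_inf,
            "H_max": summary.entropy.H_max,
            "avg_log2_sigma": var.avg,
            "mean_log2_sigma_per_j": [float(v) for v in var.mean_log_sigma],
            "dispersion_per_j": [float(v) for v in var.dispersion],
            "per_alpha": {
                "count": [int(c) for c in summary.distribution.counts],
                "P": [float(p) for p in summary.distribution.probabilities],
                "sigma": [
                    [None if not np.isfinite(s) else float(s) for s in row]
                    for row in var.sigma
                ],
                "included": [bool(b) for b in var.included_mask],
            },
        }
        return cls(provenance=prov, results=results)


def read_signal(
    path: Union[str, Path],
    delimiter: Optional[str] = None,
    column: int = 0,
    label: Optional[str] = None,
) -> Signal:
    """Read a single-column numeric signal from a text/CSV file.

    A non-numeric first row is treated as a header and skipped.  Any later
    non-numeric or blank line is an error that names the offending line
    number; trailing blank lines are tolerated.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    while raw and raw[-1].strip() == "":
        raw.pop()
    if not raw:
        raise ValueError(f"{path}: empty signal file")

    def parse(line: str) -> Optional[float]:
        fields = line.split(delimiter) if delimiter else line.split()
        if column >= len(fields):
            return None
        try:
            return float(fields[column])
        except ValueError:
            return None

    values = []
    start = 0
    if parse(raw[0]) is None and raw[0].strip() != "":
        start = 1  # header row
    for i, line in enumerate(raw[start:], start=start + 1):
        if line.strip() == "":
            raise ValueError(f"{path}: blank line at line {i}")
        v = parse(line)
        if v is None:
            raise ValueError(f"{path}: non-numeric value at line {i}: {line.strip()!r}")
        values.append(v)
    if not values:
        raise ValueError(f"{path}: no numeric rows found")
    return Signal(np.asarray(values), label=label or path.name)


def write_record(record: AnalysisRecord, path: Union[str, Path], fmt: str = "json") -> None:
    """Write an analysis record as JSON (full precision) or a per-pattern CSV."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(record.to_dict(), indent=2) + "\n")
    elif fmt == "csv":
        per_alpha = record.results.get("per_alpha")
        if per_alpha is None:
            raise ValueError("record has no per-pattern table; use fmt='json'")
        sigma = per_alpha["sigma"]
        D = len(sigma[0]) if sigma else 0
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["alpha", "count", "P"] + [f"sigma_{j + 1}" for j in range(D)])
            for a, (c, p, row) in enumerate(
                zip(per_alpha["count"], per_alpha["P"], sigma), start=1
            ):
                writer.writerow([a, c, repr(p)] + ["" if s is None else repr(s) for s in row])
    else:
        raise ValueError(f"unknown record format {fmt!r}")


def read_record(path: Union[str, Path]) -> AnalysisRecord:
    """Read back a JSON analysis record."""
    data = json.loads(Path(path).read_text())
    return AnalysisRecord(provenance=data["provenance"], results=data["results"])
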