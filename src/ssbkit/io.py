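"""Readers and writers for run tables, reference tables and reports.

All formats are plain delimited text.  Input delimiters are auto-detected
(tab if the header line contains a tab, else comma); output is always
tab-delimited.  Lines starting with '#' are ignored everywhere.  Reports
are written twice: a human-readable table rounded to two decimals and a
JSON document carrying full precision plus the MC runs and seed used.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .core import DeltaObservation, RatioMeasurement, Role, SSBError
from .uncertainty import ReportRow, UncertaintyReport

__all__ = [
    "ParseError",
    "ReferenceTable",
    "ReferenceValue",
    "read_run_table",
    "write_run_table",
    "read_reference_table",
    "write_delta_table",
    "write_report_table",
    "write_report_json",
    "read_report_json",
]

RUN_COLUMNS = ("label", "role", "mean_ratio", "std_error", "n_cycles")


class ParseError(SSBError):
    """A malformed input file; the message carries the file and line number."""


def _sniff_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a delimited file, returning header fields and (lineno, row) pairs."""
    path = Path(path)
    lines: list[tuple[int, str]] = []
    with path.open(newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.lstrip().startswith("#") or not raw.strip():
                continue
            lines.append((lineno, raw))
    if not lines:
        raise ParseError(f"{path}: file contains no data")
    delimiter = "\t" if "\t" in lines[0][1] else ","
    parsed = [
        (lineno, next(csv.reader([raw], delimiter=delimiter)))
        for lineno, raw in lines
    ]
    header = [h.strip().lower() for h in parsed[0][1]]
    return header, parsed[1:]


def read_run_table(path: str | Path) -> list[RatioMeasurement]:
    """Parse a measurement-run table into an ordered acquisition list.

    Required columns: label, role, mean_ratio, std_error, n_cycles (header
    mandatory, any order, case-insensitive).  Row order defines sequence
    order; seq_index is assigned 0, 1, ... in file order.  Role values are
    normalised case-insensitively ("Standard" == "standard" == "std").
    Malformed rows raise ParseError with the offending line number.
    """
    header, rows = _sniff_rows(path)
    missing = [c for c in RUN_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {', '.join(missing)}")
    col = {c: header.index(c) for c in RUN_COLUMNS}

    run: list[RatioMeasurement] = []
    for seq, (lineno, fields) in enumerate(rows):
        if len(fields) < len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
        try:
            run.append(
                RatioMeasurement(
                    label=fields[col["label"]].strip(),
                    role=Role.parse(fields[col["role"]]),
                    seq_index=seq,
                    mean_ratio=float(fields[col["mean_ratio"]]),
                    std_error=float(fields[col["std_error"]]),
                    n_cycles=int(float(fields[col["n_cycles"]])),
                )
            )
        except (ValueError, SSBError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return run


def write_run_table(path_or_file: str | Path | TextIO, run: Iterable[RatioMeasurement]) -> None:
    """Write an acquisition list as a tab-delimited run table."""
    def _emit(fh: TextIO) -> None:
        fh.write("\t".join(RUN_COLUMNS) + "\n")
        for m in run:
            fh.write(
                f"{m.label}\t{m.role.value}\t{float(m.mean_ratio)!r}"
                f"\t{float(m.std_error)!r}\t{m.n_cycles}\n"
            )

    if hasattr(path_or_file, "write"):
        _emit(path_or_file)  # type: ignore[arg-type]
    else:
        with Path(path_or_file).open("w") as fh:
            _emit(fh)


@dataclass(frozen=True)
class ReferenceValue:
    """Reference delta for one sample: the averaged value plus provenance."""

    delta_true: float
    values: tuple[float, ...]
    citations: tuple[str, ...]


@dataclass(frozen=True)
class ReferenceTable:
    """Mapping from sample label to its literature reference delta.

    Multiple literature values for one label are averaged (the convention
    used when several published determinations exist); the individual
    values and citations are retained for reporting.
    """

    entries: dict[str, ReferenceValue]

    def as_mapping(self) -> dict[str, float]:
        return {lab: rv.delta_true for lab, rv in self.entries.items()}

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_reference_table(path: str | Path) -> ReferenceTable:
    """Parse a reference-delta table (columns: label, delta_true[, citation]).

    An empty file (header only, or nothing at all) yields an empty table —
    every sample then falls back to mean substitution downstream.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return ReferenceTable(entries={})
    try:
        header, rows = _sniff_rows(path)
    except ParseError:
        return ReferenceTable(entries={})
    for c in ("label", "delta_true"):
        if c not in header:
            raise ParseError(f"{path}: missing required column {c}")
    li, di = header.index("label"), header.index("delta_true")
    ci = header.index("citation") if "citation" in header else None

    raw: dict[str, list[tuple[float, str]]] = {}
    for lineno, fields in rows:
        try:
            label = fields[li].strip()
            value = float(fields[di])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if not math.isfinite(value):
            raise ParseError(f"{path}:{lineno}: non-finite delta_true for {label!r}")
        citation = fields[ci].strip() if ci is not None and len(fields) > ci else ""
        raw.setdefault(label, []).append((value, citation))

    entries = {
        lab: ReferenceValue(
            delta_true=sum(v for v, _ in pairs) / len(pairs),
            values=tuple(v for v, _ in pairs),
            citations=tuple(c for _, c in pairs),
        )
        for lab, pairs in raw.items()
    }
    return ReferenceTable(entries=entries)


def write_delta_table(path_or_file: str | Path | TextIO, deltas: Sequence[DeltaObservation]) -> None:
    """Write per-bracket deltas as a tab-delimited table (full precision)."""
    def _emit(fh: TextIO) -> None:
        fh.write("label\tseq_index\tdelta_permil\tprop_se\n")
        for d in deltas:
            fh.write(
                f"{d.label}\t{d.seq_index}\t{float(d.delta_permil)!r}"
                f"\t{float(d.prop_se)!r}\n"
            )

    if hasattr(path_or_file, "write"):
        _emit(path_or_file)  # type: ignore[arg-type]
    else:
        with Path(path_or_file).open("w") as fh:
            _emit(fh)


_TABLE_COLUMNS = (
    "label",
    "delta_true",
    "delta_avg",
    "deviation_avg",
    "sd_delta",
    "sd_delta_mc",
    "u",
    "u_mc",
    "shapiro_p",
    "ttest_p",
    "n",
    "flag",
)


def _fmt(x: float | None, nd: int = 2) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "n.d."
    return f"{x:.{nd}f}"


def write_report_table(path_or_file: str | Path | TextIO, report: UncertaintyReport) -> None:
    """Write the report as a human-readable tab-delimited table.

    Deltas and uncertainties are rounded to two decimals, p-values to four;
    missing values print as "n.d.".  Full precision lives in the JSON form.
    """
    def _emit(fh: TextIO) -> None:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for r in report.rows:
            fh.write(
                "\t".join(
                    (
                        r.label,
                        _fmt(r.reference_delta),
                        _fmt(r.delta_avg),
                        _fmt(r.deviation_avg),
                        _fmt(r.sd_delta),
                        _fmt(r.sd_delta_mc),
                        _fmt(r.u),
                        _fmt(r.u_mc),
                        _fmt(r.shapiro_p, 4),
                        _fmt(r.ttest_p, 4),
                        str(r.n),
                        r.flag,
                    )
                )
                + "\n"
            )

    if hasattr(path_or_file, "write"):
        _emit(path_or_file)  # type: ignore[arg-type]
    else:
        with Path(path_or_file).open("w") as fh:
            _emit(fh)


def _row_to_json(r: ReportRow) -> dict:
    d = dict(vars(r))
    for k, v in d.items():
        if isinstance(v, float) and math.isnan(v):
            d[k] = None
    return d


def write_report_json(path_or_file: str | Path | TextIO, report: UncertaintyReport) -> None:
    """Write the full-precision machine-readable report (JSON)."""
    doc = {
        "mc_runs": report.mc_runs,
        "mc_seed": report.mc_seed,
        "coverage": report.coverage,
        "dominance_ratio": report.dominance_ratio,
        "rows": [_row_to_json(r) for r in report.rows],
    }
    if hasattr(path_or_file, "write"):
        json.dump(doc, path_or_file, indent=1)  # type: ignore[arg-type]
    else:
        with Path(path_or_file).open("w") as fh:
            json.dump(doc, fh, indent=1)


def read_report_json(path: str | Path) -> UncertaintyReport:
    """Parse a JSON report back; numerically identical to what was written."""
    with Path(path).open() as fh:
        doc = json.load(fh)
    rows = []
    for rd in doc["rows"]:
        rd = dict(rd)
        for k in ("deviation_avg", "sd_delta", "sd_delta_mc", "u", "u_mc", "shapiro_p", "ttest_p"):
            if rd[k] is None:
                rd[k] = float("nan")
        rows.append(ReportRow(**rd))
    return UncertaintyReport(
        rows=tuple(rows),
        mc_runs=doc["mc_runs"],
        mc_seed=doc["mc_seed"],
        coverage=doc["coverage"],
        dominance_ratio=doc["dominance_ratio"],
    )
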