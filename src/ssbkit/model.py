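"""Model/Results interface over the SSB pipeline.

`SSBModel` is constructed from an acquisition run (a list of
`RatioMeasurement`, a pandas DataFrame with the run-table columns, or a
file) plus optional literature reference deltas.  `fit()` runs the whole
pipeline — bracket pairing, delta computation, error propagation,
deviation statistics, validation tests, Monte Carlo uncertainty — and
returns an `SSBResults` carrying the report, with `summary()` for a
human-readable table.

    >>> model = SSBModel.from_files("run.tsv", "references.tsv")
    >>> res = model.fit(mc_runs=10_000, seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import io as _stdio
from typing import Mapping, Sequence

from .core import (
    BracketedObservation,
    DeltaObservation,
    RatioMeasurement,
    SSBError,
    compute_delta,
    pair_brackets,
)
from .uncertainty import (
    McConfig,
    SampleSeries,
    UncertaintyReport,
    build_report,
    group_series,
)

__all__ = ["SSBModel", "SSBResults"]


class SSBModel:
    """Standard-sample bracketing model for one measurement run.

    Parameters
    ----------
    run : sequence of RatioMeasurement
        Acquisitions in sequence order.
    references : mapping or ReferenceTable, optional
        Literature reference deltas (per mil) keyed by sample label.
        Samples without an entry use their own mean delta as reference.
    """

    def __init__(
        self,
        run: Sequence[RatioMeasurement],
        references: "Mapping[str, float] | None" = None,
    ) -> None:
        self.run = list(run)
        if references is not None and hasattr(references, "as_mapping"):
            references = references.as_mapping()
        self.references: dict[str, float] = dict(references or {})
        self.brackets: list[BracketedObservation] = pair_brackets(self.run)
        self.deltas: list[DeltaObservation] = [compute_delta(b) for b in self.brackets]
        self.series: list[SampleSeries] = group_series(self.deltas, self.references)

    @classmethod
    def from_dataframe(cls, df, references=None) -> "SSBModel":
        """Build from a DataFrame with the run-table columns.

        Required columns: label, role, mean_ratio, std_error; n_cycles is
        optional (defaults to 1).  Row order defines sequence order.
        """
        required = ("label", "role", "mean_ratio", "std_error")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SSBError(f"missing column(s): {', '.join(missing)}")
        run = [
            RatioMeasurement(
                label=str(row["label"]),
                role=row["role"],
                seq_index=i,
                mean_ratio=float(row["mean_ratio"]),
                std_error=float(row["std_error"]),
                n_cycles=int(row["n_cycles"]) if "n_cycles" in df.columns else 1,
            )
            for i, (_, row) in enumerate(df.iterrows())
        ]
        return cls(run, references)

    @classmethod
    def from_files(cls, run_path, reference_path=None) -> "SSBModel":
        """Build from a run-table file and an optional reference-table file."""
        from .io import read_reference_table, read_run_table

        refs = read_reference_table(reference_path) if reference_path else None
        return cls(read_run_table(run_path), refs)

    def fit(
        self,
        mc_runs: int = 10**6,
        seed: int | None = None,
        *,
        coverage: float = 0.95,
        dominance_ratio: float = 1.5,
    ) -> "SSBResults":
        """Run the uncertainty evaluation and return the results object."""
        cfg = McConfig(runs=mc_runs, seed=seed)
        report = build_report(
            self.series, cfg, coverage=coverage, dominance_ratio=dominance_ratio
        )
        return SSBResults(self, report)


class SSBResults:
    """Fitted results: the uncertainty report plus presentation helpers."""

    def __init__(self, model: SSBModel, report: UncertaintyReport) -> None:
        self.model = model
        self.report = report

    def to_frame(self):
        """Full-precision report rows as a pandas DataFrame."""
        return self.report.to_frame()

    def summary(self) -> str:
        """Human-readable report table (two decimals, Table-style layout)."""
        from .io import write_report_table

        buf = _stdio.StringIO()
        write_report_table(buf, self.report)
        lines = buf.getvalue().rstrip("\n").split("\n")
        cells = [l.split("\t") for l in lines]
        widths = [max(len(row[i]) for row in cells) for i in range(len(cells[0]))]
        body = "\n".join(
            "  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip() for row in cells
        )
        head = (
            "SSB uncertainty evaluation"
            f"  (MC runs={self.report.mc_runs}, seed={self.report.mc_seed}, "
            f"coverage={self.report.coverage:g})"
        )
        return head + "\n" + "=" * len(head) + "\n" + body

    def save(self, table_path=None, json_path=None) -> None:
        """Write the report (rounded table and/or full-precision JSON)."""
        from .io import write_report_json, write_report_table

        if table_path is not None:
            write_report_table(table_path, self.report)
        if json_path is not None:
            write_report_json(json_path, self.report)

    def plot_sequence(self, ax=None):
        """Plot delta vs acquisition index with propagated-error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in self.model.series:
            x = [d.seq_index for d in s.deltas]
            y = [d.delta_permil for d in s.deltas]
            e = [d.prop_se for d in s.deltas]
            ax.errorbar(x, y, yerr=e, fmt="o", capsize=3, label=s.label)
            ax.axhline(s.reference_delta, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("acquisition index")
        ax.set_ylabel("delta (permil)")
        ax.legend()
        return ax
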