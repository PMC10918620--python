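"""Deviation statistics and two-tier uncertainty evaluation for SSB deltas.

Given repeated delta measurements of each sample, the deviation of the
*i*-th measurement of sample *j* from its accepted value is

    Delta_ij = delta_ij - delta_true_j        [per mil]

For samples with no literature reference value the sample's own mean delta
is substituted, which forces the mean deviation to zero by construction.

Two uncertainty tiers are computed from the deviation population:

* the classical reproducibility tier: SD_Delta, the sample standard
  deviation (n-1 denominator) of the deviations, expanded to a 95 %
  bound U = z_0.975 * SD_Delta;
* the Monte Carlo tier: each delta carries its own propagated standard
  error SD_delta, and in every MC run each deviation is perturbed by
  independent zero-mean normal noise with that standard deviation before
  SD_Delta is recomputed; SD_Delta^MC is the arithmetic mean of the
  per-run standard deviations, expanded to U^MC = z_0.975 * SD_Delta^MC.

The gap between the two tiers is diagnostic: when SD_Delta^MC is close to
SD_Delta the single-acquisition ratios were measured precisely and the
uncertainty is reproducibility-dominated; a large gap means the individual
absolute ratios were measured with comparatively low precision.

Normality of the pooled deviations is checked with the Shapiro-Wilk test
and concentration around zero with a two-sided one-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import DeltaObservation, SSBError

__all__ = [
    "SampleSeries",
    "DeviationSet",
    "McConfig",
    "McResult",
    "ReportRow",
    "UncertaintyReport",
    "deviations",
    "test_normality",
    "test_zero_mean",
    "expanded_uncertainty",
    "monte_carlo_sd",
    "build_report",
    "group_series",
]

#: label used for the pooled (all samples) row, matching the report layout
JOINT_LABEL = "jointly"

#: flag values for the reproducibility vs measurement-precision diagnostic
FLAG_REPRODUCIBILITY = "reproducibility-dominated"
FLAG_PRECISION = "measurement-precision-dominated"


@dataclass(frozen=True)
class SampleSeries:
    """All delta observations of one sample plus its reference value.

    If ``reference_delta`` is None on construction, the arithmetic mean of
    the observed deltas is substituted and ``reference_source`` is set to
    ``"sample_mean"``; otherwise it is ``"literature"``.
    """

    label: str
    deltas: tuple[DeltaObservation, ...]
    reference_delta: float | None = None
    reference_source: str = field(init=False)

    def __post_init__(self) -> None:
        deltas = tuple(self.deltas)
        if not deltas:
            raise SSBError(f"sample {self.label!r}: empty delta series")
        object.__setattr__(self, "deltas", deltas)
        if self.reference_delta is None:
            mean = float(np.mean([d.delta_permil for d in deltas]))
            object.__setattr__(self, "reference_delta", mean)
            object.__setattr__(self, "reference_source", "sample_mean")
        else:
            if not math.isfinite(self.reference_delta):
                raise SSBError(f"sample {self.label!r}: non-finite reference delta")
            object.__setattr__(self, "reference_source", "literature")

    @property
    def delta_values(self) -> np.ndarray:
        return np.array([d.delta_permil for d in self.deltas], dtype=float)

    @property
    def prop_se_values(self) -> np.ndarray:
        return np.array([d.prop_se for d in self.deltas], dtype=float)

    @property
    def delta_avg(self) -> float:
        return float(np.mean(self.delta_values))


@dataclass(frozen=True)
class DeviationSet:
    """The deviation population Delta for one sample (or pooled)."""

    deviations: np.ndarray
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo settings: number of runs and RNG seed.

    ``runs`` defaults to 10**6; ``reduced_runs_hint`` is the smaller run
    count recommended for quick exploratory passes (result tolerances widen
    roughly as 1/sqrt(runs)).
    """

    runs: int = 10**6
    seed: int | None = None
    reduced_runs_hint: int = 10**4

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise SSBError(f"McConfig.runs must be >= 1, got {self.runs}")


@dataclass(frozen=True)
class McResult:
    """SD_Delta^MC per series and pooled, with the settings that produced it."""

    per_series: dict[str, float]
    pooled: float
    runs: int
    seed: int | None


def deviations(series: SampleSeries) -> DeviationSet:
    """Deviations Delta_i = delta_i - delta_true for one sample series.

    The mean is computed as mean(delta) - reference, so for a
    mean-substituted reference it is exactly zero.  The standard deviation
    uses the n-1 denominator (undefined, NaN, for a single observation).
    """
    values = series.delta_values
    devs = values - series.reference_delta
    mean = float(np.mean(values)) - float(series.reference_delta)
    sd = float(np.std(devs, ddof=1)) if devs.size > 1 else float("nan")
    return DeviationSet(deviations=devs, mean=mean, sd=sd, n=devs.size)


def _pooled_deviations(series_list: Sequence[SampleSeries]) -> np.ndarray:
    return np.concatenate([deviations(s).deviations for s in series_list])


def test_normality(devs: np.ndarray) -> float:
    """Shapiro-Wilk p-value for normality of a deviation population.

    Returns NaN (a not-applicable marker, never a silent default) outside
    the test's validity range 3 <= n <= 5000 or for zero-variance input.
    """
    devs = np.asarray(devs, dtype=float)
    if devs.size < 3 or devs.size > 5000 or np.ptp(devs) == 0.0:
        return float("nan")
    return float(stats.shapiro(devs).pvalue)


def test_zero_mean(devs: np.ndarray) -> float:
    """Two-sided one-sample t-test p-value for mean deviation equal to zero.

    Returns NaN for n < 2 or degenerate (zero) variance.
    """
    devs = np.asarray(devs, dtype=float)
    if devs.size < 2 or np.ptp(devs) == 0.0:
        return float("nan")
    return float(stats.ttest_1samp(devs, popmean=0.0).pvalue)


def expanded_uncertainty(sd: float, coverage: float = 0.95) -> float:
    """Expanded uncertainty U = z_{(1+coverage)/2} * sd.

    For the default 95 % coverage, z is the 0.975 standard normal quantile
    (1.959964...), so U is the half-width of the symmetric 95 % interval of
    a zero-mean normal with standard deviation ``sd``.
    """
    if not 0.0 < coverage < 1.0:
        raise SSBError(f"coverage must be in (0, 1), got {coverage}")
    if sd < 0:
        raise SSBError(f"sd must be >= 0, got {sd}")
    z = float(stats.norm.ppf(0.5 * (1.0 + coverage)))
    return z * sd


def monte_carlo_sd(
    series_list: Sequence[SampleSeries],
    cfg: McConfig,
    *,
    chunk_size: int | None = None,
) -> McResult:
    """Monte Carlo SD_Delta^MC per series and pooled.

    In every run each observation's deviation is perturbed by independent
    zero-mean normal noise with standard deviation equal to its own
    propagated standard error; the per-series and pooled sample standard
    deviations are recomputed on the disturbed set, and the returned values
    are arithmetic means of the per-run standard deviations.

    Noise is drawn observation-major within each run, with observations in
    a canonical (seq_index, label) order, so the result is independent of
    the ordering of ``series_list`` given the seed.  If every propagated
    standard error is zero, the per-run standard deviation is constant and
    SD_Delta^MC equals SD_Delta exactly at any run count.
    """
    if not series_list:
        raise SSBError("no sample series given")
    for s in series_list:
        for d in s.deltas:
            if not math.isfinite(d.prop_se):
                raise SSBError(
                    f"observation {d.label!r} at seq_index {d.seq_index} "
                    "has no finite propagated standard error"
                )

    # canonical observation order: independent of series_list ordering
    tagged = [
        (d.seq_index, s.label, i, j)
        for i, s in enumerate(series_list)
        for j, d in enumerate(s.deltas)
    ]
    order = sorted(range(len(tagged)), key=lambda k: tagged[k][:2])

    dev_arrays = [deviations(s).deviations for s in series_list]
    flat_devs = np.concatenate(dev_arrays)
    flat_se = np.concatenate([s.prop_se_values for s in series_list])
    flat_devs = flat_devs[order]
    flat_se = flat_se[order]
    n_total = flat_devs.size

    # column index groups per series, in canonical-column coordinates
    series_cols: dict[str, np.ndarray] = {}
    series_index_of = np.array([tagged[k][2] for k in order])
    for i, s in enumerate(series_list):
        if s.label in series_cols:
            raise SSBError(f"duplicate sample label {s.label!r}")
        series_cols[s.label] = np.flatnonzero(series_index_of == i)

    if np.all(flat_se == 0.0):
        per = {
            lab: (float(np.std(flat_devs[cols], ddof=1)) if cols.size > 1 else float("nan"))
            for lab, cols in series_cols.items()
        }
        pooled = float(np.std(flat_devs, ddof=1)) if n_total > 1 else float("nan")
        return McResult(per_series=per, pooled=pooled, runs=cfg.runs, seed=cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    if chunk_size is None:
        chunk_size = max(1, 4_000_000 // max(n_total, 1))

    sums = {lab: 0.0 for lab in series_cols}
    pooled_sum = 0.0
    done = 0
    while done < cfg.runs:
        m = min(chunk_size, cfg.runs - done)
        # standard normals scaled by prop_se: exact scale equivariance
        noise = rng.standard_normal((m, n_total)) * flat_se
        disturbed = flat_devs + noise
        for lab, cols in series_cols.items():
            if cols.size > 1:
                sums[lab] += float(np.sum(np.std(disturbed[:, cols], ddof=1, axis=1)))
            else:
                sums[lab] = float("nan")
        pooled_sum += float(np.sum(np.std(disturbed, ddof=1, axis=1)))
        done += m

    per = {lab: sums[lab] / cfg.runs for lab in series_cols}
    pooled = pooled_sum / cfg.runs if n_total > 1 else float("nan")
    return McResult(per_series=per, pooled=pooled, runs=cfg.runs, seed=cfg.seed)


@dataclass(frozen=True)
class ReportRow:
    """One row of the uncertainty report (one sample, or the pooled row)."""

    label: str
    reference_delta: float | None
    reference_source: str | None
    delta_avg: float | None
    deviation_avg: float
    sd_delta: float
    sd_delta_mc: float
    u: float
    u_mc: float
    shapiro_p: float
    ttest_p: float
    n: int
    flag: str


@dataclass(frozen=True)
class UncertaintyReport:
    """Per-sample rows plus a pooled row, with the MC settings used."""

    rows: tuple[ReportRow, ...]
    mc_runs: int
    mc_seed: int | None
    coverage: float
    dominance_ratio: float

    @property
    def per_sample(self) -> tuple[ReportRow, ...]:
        return tuple(r for r in self.rows if r.label != JOINT_LABEL)

    @property
    def joint(self) -> ReportRow:
        return next(r for r in self.rows if r.label == JOINT_LABEL)

    def to_frame(self):
        """Report as a pandas DataFrame (full precision)."""
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.rows])


def _dominance_flag(sd: float, sd_mc: float, ratio_threshold: float) -> str:
    if sd == 0.0:
        return FLAG_REPRODUCIBILITY if sd_mc == 0.0 else FLAG_PRECISION
    if not math.isfinite(sd) or not math.isfinite(sd_mc):
        return FLAG_REPRODUCIBILITY
    return FLAG_REPRODUCIBILITY if sd_mc / sd < ratio_threshold else FLAG_PRECISION


def build_report(
    series_list: Sequence[SampleSeries],
    cfg: McConfig | None = None,
    *,
    coverage: float = 0.95,
    dominance_ratio: float = 1.5,
) -> UncertaintyReport:
    """Assemble the full uncertainty report for a dataset of sample series.

    Per-sample rows carry the sample's own deviation statistics and tests;
    the pooled row concatenates all per-sample deviations (so its n is the
    sum of the per-sample n) and is the estimator intended for any newly
    measured sample with unknown reference value.  Each row is flagged
    reproducibility-dominated when SD_Delta^MC / SD_Delta is below
    ``dominance_ratio``, else measurement-precision-dominated.
    """
    if cfg is None:
        cfg = McConfig()
    labels = [s.label for s in series_list]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise SSBError(f"duplicate sample labels: {dup}")
    if not series_list:
        raise SSBError("empty dataset")

    mc = monte_carlo_sd(series_list, cfg)
    rows: list[ReportRow] = []
    for s in series_list:
        dev = deviations(s)
        sd_mc = mc.per_series[s.label]
        rows.append(
            ReportRow(
                label=s.label,
                reference_delta=(
                    float(s.reference_delta) if s.reference_source == "literature" else None
                ),
                reference_source=s.reference_source,
                delta_avg=s.delta_avg,
                deviation_avg=dev.mean,
                sd_delta=dev.sd,
                sd_delta_mc=sd_mc,
                u=expanded_uncertainty(dev.sd, coverage) if math.isfinite(dev.sd) else float("nan"),
                u_mc=expanded_uncertainty(sd_mc, coverage) if math.isfinite(sd_mc) else float("nan"),
                shapiro_p=test_normality(dev.deviations),
                ttest_p=test_zero_mean(dev.deviations),
                n=dev.n,
                flag=_dominance_flag(dev.sd, sd_mc, dominance_ratio),
            )
        )

    pooled_devs = _pooled_deviations(series_list)
    pooled_sd = float(np.std(pooled_devs, ddof=1)) if pooled_devs.size > 1 else float("nan")
    rows.append(
        ReportRow(
            label=JOINT_LABEL,
            reference_delta=None,
            reference_source=None,
            delta_avg=None,
            deviation_avg=float(np.mean(pooled_devs)),
            sd_delta=pooled_sd,
            sd_delta_mc=mc.pooled,
            u=expanded_uncertainty(pooled_sd, coverage) if math.isfinite(pooled_sd) else float("nan"),
            u_mc=expanded_uncertainty(mc.pooled, coverage) if math.isfinite(mc.pooled) else float("nan"),
            shapiro_p=test_normality(pooled_devs),
            ttest_p=test_zero_mean(pooled_devs),
            n=pooled_devs.size,
            flag=_dominance_flag(pooled_sd, mc.pooled, dominance_ratio),
        )
    )
    return UncertaintyReport(
        rows=tuple(rows),
        mc_runs=cfg.runs,
        mc_seed=cfg.seed,
        coverage=coverage,
        dominance_ratio=dominance_ratio,
    )


def group_series(
    deltas: Iterable[DeltaObservation],
    references: Mapping[str, float] | None = None,
) -> list[SampleSeries]:
    """Group delta observations by sample label into SampleSeries.

    Labels keep their order of first appearance in the run.  A label found
    in ``references`` gets that literature value; otherwise the sample mean
    is substituted.
    """
    references = references or {}
    by_label: dict[str, list[DeltaObservation]] = {}
    for d in deltas:
        by_label.setdefault(d.label, []).append(d)
    return [
        SampleSeries(
            label=lab,
            deltas=tuple(obs),
            reference_delta=references.get(lab),
        )
        for lab, obs in by_label.items()
    ]
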