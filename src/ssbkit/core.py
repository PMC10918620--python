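"""Standard-sample bracketing (SSB) primitives.

An SSB run is an ordered sequence of acquisitions alternating between a
bracketing standard and a sample.  Each sample acquisition, together with
the standard acquisition immediately before and immediately after it, forms
a bracketed observation from which a delta value is computed:

    delta = (mu_s / ((mu_b1 + mu_b2) / 2) - 1) * 1000   [per mil]

where mu_s, mu_b1, mu_b2 are the mean isotope ratios of the sample and the
two bracketing standards.  Because instrumental mass bias enters all three
ratios as a common multiplicative factor that varies slowly over the run,
it cancels (exactly, for linear drift with the sample midway between its
brackets) in the ratio of sample to bracket mean.

The standard error of a single delta follows from first-order (Taylor)
propagation of the three acquisition standard errors through the formula
above; see :func:`propagate_se`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Role",
    "RatioMeasurement",
    "BracketedObservation",
    "DeltaObservation",
    "SSBError",
    "pair_brackets",
    "compute_delta",
    "propagate_se",
    "reduce_run",
]


class SSBError(ValueError):
    """Raised for structurally invalid runs or inadmissible measurement values."""


class Role(str, Enum):
    """Role of an acquisition in a bracketing sequence."""

    STANDARD = "standard"
    SAMPLE = "sample"

    @classmethod
    def parse(cls, value: "str | Role") -> "Role":
        """Parse a role label, accepting case variants and common synonyms."""
        if isinstance(value, Role):
            return value
        key = str(value).strip().lower()
        aliases = {
            "standard": cls.STANDARD,
            "std": cls.STANDARD,
            "bracket": cls.STANDARD,
            "sample": cls.SAMPLE,
            "smp": cls.SAMPLE,
        }
        try:
            return aliases[key]
        except KeyError:
            raise SSBError(f"unrecognized role {value!r}") from None


@dataclass(frozen=True)
class RatioMeasurement:
    """One acquisition: a mean isotope ratio with its standard error.

    Parameters
    ----------
    label : str
        Sample or standard identifier.
    role : Role
        Whether the acquisition is a bracketing standard or a sample.
    seq_index : int
        Position in the run (0-based, strictly increasing in file order).
    mean_ratio : float
        Mean isotope ratio over the integration cycles; strictly positive.
    std_error : float
        Standard error of ``mean_ratio``; non-negative.
    n_cycles : int
        Number of integration cycles averaged into ``mean_ratio``.
    """

    label: str
    role: Role
    seq_index: int
    mean_ratio: float
    std_error: float
    n_cycles: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role.parse(self.role))
        if not math.isfinite(self.mean_ratio) or self.mean_ratio <= 0:
            raise SSBError(
                f"acquisition {self.seq_index} ({self.label!r}): "
                f"mean_ratio must be finite and > 0, got {self.mean_ratio!r}"
            )
        if not math.isfinite(self.std_error) or self.std_error < 0:
            raise SSBError(
                f"acquisition {self.seq_index} ({self.label!r}): "
                f"std_error must be finite and >= 0, got {self.std_error!r}"
            )
        if self.seq_index < 0:
            raise SSBError(f"seq_index must be >= 0, got {self.seq_index}")
        if self.n_cycles < 1:
            raise SSBError(f"n_cycles must be >= 1, got {self.n_cycles}")


@dataclass(frozen=True)
class BracketedObservation:
    """A sample acquisition with its two bracketing standard acquisitions."""

    b1: RatioMeasurement
    s: RatioMeasurement
    b2: RatioMeasurement

    def __post_init__(self) -> None:
        if self.b1.role is not Role.STANDARD or self.b2.role is not Role.STANDARD:
            raise SSBError("b1 and b2 must be standard acquisitions")
        if self.s.role is not Role.SAMPLE:
            raise SSBError("s must be a sample acquisition")
        if not (self.b1.seq_index < self.s.seq_index < self.b2.seq_index):
            raise SSBError(
                "bracket order violated: need seq_index(b1) < seq_index(s) < seq_index(b2), "
                f"got {self.b1.seq_index}, {self.s.seq_index}, {self.b2.seq_index}"
            )


@dataclass(frozen=True)
class DeltaObservation:
    """One SSB-derived delta (per mil) with its propagated standard error."""

    label: str
    delta_permil: float
    prop_se: float
    seq_index: int

    def __post_init__(self) -> None:
        if self.prop_se < 0:
            raise SSBError(f"prop_se must be >= 0, got {self.prop_se}")


def pair_brackets(run: Sequence[RatioMeasurement]) -> list[BracketedObservation]:
    """Group an ordered run into standard-sample-standard triplets.

    Adjacent samples share their middle standard (the standard closing one
    bracket opens the next).  Two consecutive standards with no sample in
    between are permitted: the later one simply starts the next bracket.
    Two consecutive samples, or a run starting or ending with a sample,
    are structural errors.

    Parameters
    ----------
    run : sequence of RatioMeasurement
        Acquisitions in sequence order.

    Returns
    -------
    list of BracketedObservation
        One triplet per sample acquisition, in run order.
    """
    if not run:
        raise SSBError("empty run")
    for prev, cur in zip(run, list(run)[1:]):
        if cur.seq_index <= prev.seq_index:
            raise SSBError(
                f"seq_index not strictly increasing at acquisition {cur.seq_index}"
            )

    triplets: list[BracketedObservation] = []
    last_standard: RatioMeasurement | None = None
    pending: RatioMeasurement | None = None
    for acq in run:
        if acq.role is Role.STANDARD:
            if pending is not None:
                assert last_standard is not None
                triplets.append(BracketedObservation(last_standard, pending, acq))
                pending = None
            last_standard = acq
        else:
            if last_standard is None:
                raise SSBError(
                    f"unbracketed sample at seq_index {acq.seq_index}: "
                    "no standard acquisition precedes it"
                )
            if pending is not None:
                raise SSBError(
                    f"consecutive sample acquisitions at seq_index "
                    f"{pending.seq_index} and {acq.seq_index}: the scheme is "
                    "strictly standard-sample-standard"
                )
            pending = acq
    if pending is not None:
        raise SSBError(
            f"unbracketed sample at seq_index {pending.seq_index}: "
            "no standard acquisition follows it"
        )
    return triplets


def _bracket_mean(obs: BracketedObservation) -> float:
    return 0.5 * (obs.b1.mean_ratio + obs.b2.mean_ratio)


def compute_delta(obs: BracketedObservation) -> DeltaObservation:
    """Evaluate the SSB delta (per mil) for one bracketed observation.

    delta = (mu_s / ((mu_b1 + mu_b2)/2) - 1) * 1000.  The result is exactly
    invariant under scaling all three ratios by a common positive factor,
    which is how the method cancels instrumental mass bias.
    """
    m = _bracket_mean(obs)
    delta = (obs.s.mean_ratio / m - 1.0) * 1000.0
    return DeltaObservation(
        label=obs.s.label,
        delta_permil=delta,
        prop_se=propagate_se(obs),
        seq_index=obs.s.seq_index,
    )


def propagate_se(obs: BracketedObservation) -> float:
    """First-order propagated standard error of the SSB delta, in per mil.

    Differentiating the delta formula with m = (mu_b1 + mu_b2)/2 gives

        d(delta)/d(mu_s)  =  1000 / m
        d(delta)/d(mu_b1) = d(delta)/d(mu_b2) = -1000 * mu_s / (2 m^2)

    and combining the three acquisition standard errors in quadrature,

        SD_delta = (1000/m) * sqrt(sigma_s^2
                                   + (mu_s/(2m))^2 * (sigma_b1^2 + sigma_b2^2)).

    The result is zero iff all three standard errors are zero, scales
    linearly with a common scaling of the sigmas, and is symmetric in the
    two brackets.
    """
    m = _bracket_mean(obs)
    bterm = obs.s.mean_ratio / (2.0 * m)
    return (1000.0 / m) * math.hypot(
        obs.s.std_error, bterm * math.hypot(obs.b1.std_error, obs.b2.std_error)
    )


def reduce_run(run: Iterable[RatioMeasurement]) -> list[DeltaObservation]:
    """Convenience: pair a run into brackets and compute every delta."""
    return [compute_delta(t) for t in pair_brackets(list(run))]
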