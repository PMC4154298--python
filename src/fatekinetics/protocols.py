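"""Culture conditions, protocols and pulse-chase designs.

A protocol is an ordered, contiguous list of (duration, condition)
segments starting at day 0. Conditions carry a single model-relevant
flag, ``ps_permissive``: whether primitive-streak-promoting signalling
(Activin/Wnt agonism) is present, which gates the effective PS
commitment rate. The built-in registry ships the two conditions the
model is parameterised for — neutral N2B27 medium (non-permissive) and
AC, Activin (100 ng/ml) + CHIR99021 (3 µM) (permissive) — and can be
extended with user-defined conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConditionLookupError, ValidationError
from .model import PopulationState, RateParameters, SignalLaw, simulate_protocol

__all__ = [
    "Condition",
    "Segment",
    "Protocol",
    "PulseChaseDesign",
    "PulseResponseTable",
    "condition_from_name",
    "register_condition",
    "known_conditions",
    "pulse_chase_protocols",
    "pulse_response",
    "fate_correlation",
]


@dataclass(frozen=True)
class Condition:
    """A culture condition with its PS-permissiveness flag and media notes."""

    name: str
    ps_permissive: bool
    media_meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("condition name must be non-empty")
        object.__setattr__(self, "media_meta", MappingProxyType(dict(self.media_meta)))


N2B27 = Condition("N2B27", ps_permissive=False, media_meta={"base": "N2B27"})
AC = Condition(
    "AC",
    ps_permissive=True,
    media_meta={"base": "N2B27", "Activin": "100 ng/ml", "CHIR99021": "3 uM"},
)

_REGISTRY: dict[str, Condition] = {c.name: c for c in (N2B27, AC)}


def known_conditions() -> tuple[str, ...]:
    """Names of all registered culture conditions."""
    return tuple(_REGISTRY)


def register_condition(condition: Condition, *, overwrite: bool = False) -> None:
    """Add a user-defined condition to the registry."""
    if condition.name in _REGISTRY and not overwrite:
        raise ValidationError(
            f"condition {condition.name!r} already registered (pass overwrite=True)"
        )
    _REGISTRY[condition.name] = condition


def condition_from_name(name: str) -> Condition:
    """Look up a registered condition by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConditionLookupError(name, known_conditions()) from None


@dataclass(frozen=True)
class Segment:
    """One protocol segment: a condition applied for a positive duration."""

    duration: float
    condition: Condition

    def __post_init__(self) -> None:
        duration = float(self.duration)
        if not math.isfinite(duration) or duration <= 0.0:
            raise ValidationError(f"segment duration must be > 0, got {duration!r}")
        object.__setattr__(self, "duration", duration)


@dataclass(frozen=True)
class Protocol:
    """Ordered contiguous culture segments, half-open [start, end) in days."""

    segments: tuple[Segment, ...]

    def __init__(self, segments: Sequence[Segment | tuple[float, Condition]]):
        parsed = tuple(
            seg if isinstance(seg, Segment) else Segment(*seg) for seg in segments
        )
        if not parsed:
            raise ValidationError("protocol must have at least one segment")
        object.__setattr__(self, "segments", parsed)

    @property
    def total_duration(self) -> float:
        return float(sum(seg.duration for seg in self.segments))

    @property
    def boundaries(self) -> tuple[float, ...]:
        """Segment edge times including 0 and the total duration."""
        edges = [0.0]
        for seg in self.segments:
            edges.append(edges[-1] + seg.duration)
        return tuple(edges)

    def condition_at(self, t: float) -> Condition:
        """Condition active at time ``t`` (half-open segments; t = end maps
        to the final segment)."""
        total = self.total_duration
        if not 0.0 <= t <= total:
            raise ValidationError(f"t={t!r} outside protocol span [0, {total}]")
        edges = self.boundaries
        for seg, start, end in zip(self.segments, edges[:-1], edges[1:]):
            if start <= t < end:
                return seg.condition
        return self.segments[-1].condition

    def describe(self) -> str:
        return " + ".join(f"{seg.duration:g}d {seg.condition.name}" for seg in self.segments)


@dataclass(frozen=True)
class PulseChaseDesign:
    """A family of protocols: single pulses of one condition on a base medium.

    Each member protocol spans ``total_duration`` days of
    ``base_condition`` with one ``pulse_duration``-day pulse of
    ``pulse_condition`` starting on one of ``pulse_start_days``. The
    default mirrors the classic design: 6 days of N2B27 with single
    1-day AC pulses starting on days 0–5.
    """

    total_duration: float = 6.0
    pulse_duration: float = 1.0
    pulse_start_days: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    pulse_condition: Condition = AC
    base_condition: Condition = N2B27

    def __post_init__(self) -> None:
        total = float(self.total_duration)
        width = float(self.pulse_duration)
        if total <= 0.0 or width <= 0.0:
            raise ValidationError("total_duration and pulse_duration must be > 0")
        starts = tuple(float(s) for s in self.pulse_start_days)
        if not starts:
            raise ValidationError("pulse_start_days must be non-empty")
        if sorted(set(starts)) != list(starts):
            raise ValidationError("pulse_start_days must be sorted and unique")
        for start in starts:
            if start < 0.0 or start + width > total + 1e-12:
                raise ValidationError(
                    f"pulse starting at day {start} with duration {width} does not fit "
                    f"inside total_duration={total}"
                )
        object.__setattr__(self, "total_duration", total)
        object.__setattr__(self, "pulse_duration", width)
        object.__setattr__(self, "pulse_start_days", starts)


@dataclass(frozen=True, eq=False)
class PulseResponseTable:
    """End-of-protocol fate fractions for each pulse start day."""

    frame: pd.DataFrame  # columns: pulse_start_day, n_final, m_final, uncommitted_final

    def __post_init__(self) -> None:
        required = {"pulse_start_day", "n_final", "m_final", "uncommitted_final"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"response table missing columns: {sorted(missing)}")
        fractions = self.frame[["n_final", "m_final", "uncommitted_final"]].to_numpy()
        if np.any(fractions < -1e-9) or np.any(fractions > 1.0 + 1e-9):
            raise ValidationError("response fractions must lie in [0, 1]")
        totals = fractions.sum(axis=1)
        if np.any(np.abs(totals - 1.0) > 1e-9):
            raise ValidationError("response rows must conserve mass (sum to 1)")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def pulse_chase_protocols(design: PulseChaseDesign) -> list[Protocol]:
    """One protocol per pulse start day: base, pulse, base remainder.

    Zero-length leading or trailing base segments are omitted, so a
    pulse starting on day 0 yields a two-segment protocol.
    """
    protocols = []
    for start in design.pulse_start_days:
        segments: list[tuple[float, Condition]] = []
        if start > 1e-12:
            segments.append((start, design.base_condition))
        segments.append((design.pulse_duration, design.pulse_condition))
        tail = design.total_duration - start - design.pulse_duration
        if tail > 1e-12:
            segments.append((tail, design.base_condition))
        protocols.append(Protocol(segments))
    return protocols


def pulse_response(
    design: PulseChaseDesign,
    params: RateParameters,
    *,
    init: PopulationState | None = None,
    signal_law: SignalLaw = "instantaneous",
) -> PulseResponseTable:
    """Simulate every pulse protocol and tabulate endpoint fate fractions.

    The model's M compartment corresponds to the PS reporter readout
    (T::GFP+), N to the NECT reporter (Sox1::GFP+) and p + d to
    reporter-negative uncommitted cells.
    """
    rows = []
    for start, protocol in zip(design.pulse_start_days, pulse_chase_protocols(design)):
        traj = simulate_protocol(
            protocol,
            params,
            init=init,
            output_grid=[design.total_duration],
            signal_law=signal_law,
        )
        p, d, n, m = traj.states[-1]
        rows.append(
            {
                "pulse_start_day": start,
                "n_final": n,
                "m_final": m,
                "uncommitted_final": p + d,
            }
        )
    return PulseResponseTable(pd.DataFrame(rows))


def fate_correlation(table: PulseResponseTable) -> float:
    """Pearson correlation between NECT and PS endpoint fractions across
    pulse days.

    A strongly negative value is the model analogue of the experimental
    anticorrelation between Sox1::GFP and T::GFP responses.
    """
    n_final = table.frame["n_final"].to_numpy(dtype=float)
    m_final = table.frame["m_final"].to_numpy(dtype=float)
    if len(n_final) < 3:
        raise ValidationError("correlation needs at least 3 pulse days")
    if np.std(n_final) == 0.0 or np.std(m_final) == 0.0:
        raise ValidationError("correlation undefined: zero variance in a fate readout")
    return float(np.corrcoef(n_final, m_final)[0, 1])
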