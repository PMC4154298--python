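"""Four-compartment kinetic model of ES-cell fate adoption.

States: pluripotent (P), differentiating/uncommitted (D), committed
neuroectoderm (N) and committed primitive streak (M). Cells exit
pluripotency at rate ``lambda_D`` and the uncommitted pool is drained by
two competing first-order channels, ``lambda_N`` (NECT) and an effective
PS rate ``lambda_M_eff``. A population-level signal s builds up as
pluripotency is lost; once s crosses the threshold ``theta`` the PS rate
switches from a negligible to a dominant value — but only while the
culture condition is PS-permissive (e.g. Activin + CHIR). Death and
division are not modelled, so p + d + n + m is conserved.

The system is linear with piecewise-constant rates, so trajectories are
built exactly by gluing closed-form constant-rate segment solutions at
the protocol boundaries and at the signal-crossing time. An adaptive
numerical integrator (:func:`numeric_oracle`) provides an independent
check of the analytic solver.

Time is measured in days; all rates are per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import IntegrationError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .protocols import Protocol

__all__ = [
    "RateParameters",
    "PopulationState",
    "SignalState",
    "RateRegime",
    "Trajectory",
    "SignalLaw",
    "rhs",
    "constant_rate_segment",
    "signal_level",
    "crossing_time",
    "simulate_protocol",
    "numeric_oracle",
]

SignalLaw = Literal["instantaneous", "cumulative"]

#: Relative tolerance below which |Λ - λ_D| is treated as degenerate and the
#: confluent (Λ = λ_D) closed-form branch is used.
DEGENERATE_RTOL = 1e-9

#: Mass-conservation tolerance for state validation.
CONSERVATION_ATOL = 1e-9


def _require_finite_nonneg(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class RateParameters:
    """Rate constants and signal threshold of the fate-adoption model.

    Parameters
    ----------
    lambda_D
        Exit rate from pluripotency (P -> D), per day.
    lambda_N
        NECT commitment rate (D -> N), per day.
    lambda_M_low
        PS commitment rate (D -> M) below the signal threshold, per day.
        Negligible by default (the PS channel is effectively closed
        before the signal crosses).
    lambda_M_high
        PS commitment rate at/above the threshold, per day. Must be
        >= ``lambda_M_low``.
    theta
        Dimensionless signal threshold in [0, 1].
    """

    lambda_D: float
    lambda_N: float
    lambda_M_low: float = 0.0
    lambda_M_high: float = 0.0
    theta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lambda_D", "lambda_N", "lambda_M_low", "lambda_M_high"):
            object.__setattr__(self, name, _require_finite_nonneg(getattr(self, name), name))
        theta = float(self.theta)
        if not math.isfinite(theta) or not 0.0 <= theta <= 1.0:
            raise ValidationError(f"theta must lie in [0, 1], got {theta!r}")
        object.__setattr__(self, "theta", theta)
        if self.lambda_M_low > self.lambda_M_high:
            raise ValidationError(
                "lambda_M_low must not exceed lambda_M_high "
                f"({self.lambda_M_low} > {self.lambda_M_high})"
            )

    def to_dict(self) -> dict[str, float]:
        return {
            "lambda_D": self.lambda_D,
            "lambda_N": self.lambda_N,
            "lambda_M_low": self.lambda_M_low,
            "lambda_M_high": self.lambda_M_high,
            "theta": self.theta,
        }


@dataclass(frozen=True)
class PopulationState:
    """Population fractions (p, d, n, m) at a time point; they sum to 1."""

    time: float
    p: float
    d: float
    n: float
    m: float

    def __post_init__(self) -> None:
        for name in ("time", "p", "d", "n", "m"):
            value = float(getattr(self, name))
            if not math.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
            object.__setattr__(self, name, value)
        for name in ("p", "d", "n", "m"):
            value = getattr(self, name)
            if not -CONSERVATION_ATOL <= value <= 1.0 + CONSERVATION_ATOL:
                raise ValidationError(f"fraction {name}={value!r} outside [0, 1]")
        total = self.p + self.d + self.n + self.m
        if abs(total - 1.0) > CONSERVATION_ATOL:
            raise ValidationError(f"fractions must sum to 1, got {total!r}")

    @classmethod
    def pluripotent(cls, time: float = 0.0) -> "PopulationState":
        """Fully pluripotent population, the model's default initial state."""
        return cls(time=time, p=1.0, d=0.0, n=0.0, m=0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.d, self.n, self.m], dtype=float)


@dataclass(frozen=True)
class SignalState:
    """Level of the pluripotency-loss signal and whether the threshold was hit."""

    s: float
    crossed: bool


@dataclass(frozen=True)
class RateRegime:
    """Effective rates governing one constant-rate piece of a protocol."""

    lambda_D_eff: float
    lambda_N_eff: float
    lambda_M_eff: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("lambda_D_eff", "lambda_N_eff", "lambda_M_eff"):
            object.__setattr__(self, name, _require_finite_nonneg(getattr(self, name), name))


@dataclass(eq=False)
class Trajectory:
    """Model solution sampled on a time grid.

    Attributes
    ----------
    times : array of days
    states : (len(times), 4) array of fractions in P, D, N, M order
    signal : signal level s at each grid time
    regime_labels : active regime label at each grid time
    """

    times: np.ndarray
    states: np.ndarray
    signal: np.ndarray
    regime_labels: list[str]
    params: RateParameters | None = None

    @property
    def p(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def d(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def n(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def m(self) -> np.ndarray:
        return self.states[:, 3]

    def state_at(self, index: int) -> PopulationState:
        p, d, n, m = self.states[index]
        return PopulationState(time=float(self.times[index]), p=p, d=d, n=n, m=m)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_day": self.times,
                "p": self.p,
                "d": self.d,
                "n": self.n,
                "m": self.m,
                "signal": self.signal,
                "regime_label": self.regime_labels,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rhs(state: PopulationState, regime: RateRegime) -> np.ndarray:
    """Right-hand side of the linear ODE system under a constant regime.

    Returns the derivative 4-vector
    (dp, dd, dn, dm) = (-λ_D p, λ_D p - (λ_N + λ_M) d, λ_N d, λ_M d),
    whose components sum to zero (mass conservation).
    """
    lam_d, lam_n, lam_m = regime.lambda_D_eff, regime.lambda_N_eff, regime.lambda_M_eff
    dp = -lam_d * state.p
    dd = lam_d * state.p - (lam_n + lam_m) * state.d
    dn = lam_n * state.d
    dm = lam_m * state.d
    return np.array([dp, dd, dn, dm], dtype=float)


def _propagate(
    p0: float, d0: float, lam_d: float, lam_n: float, lam_m: float, dt: float
) -> tuple[float, float, float, float]:
    """Exact constant-rate propagation over ``dt`` days.

    Returns (p, d, dn, dm) where dn/dm are the increments of the
    absorbing compartments, computed from the closed-form integral of d.
    """
    lam = lam_n + lam_m  # total drain Λ of the uncommitted pool
    ed = math.exp(-lam_d * dt)
    el = math.exp(-lam * dt)
    p = p0 * ed
    degenerate = abs(lam - lam_d) < DEGENERATE_RTOL * max(lam, lam_d, 1.0)
    if degenerate:
        # Confluent branch Λ -> λ_D: d(t) = (d0 + λ_D p0 t) e^{-Λ t}
        d = (d0 + lam_d * p0 * dt) * el
        if lam > 0.0:
            integral = d0 * (1.0 - el) / lam + lam_d * p0 * (
                1.0 - (1.0 + lam * dt) * el
            ) / lam**2
        else:
            # Λ ≈ λ_D ≈ 0: d is constant; the integral only feeds n/m,
            # whose rates are zero here, but keep it exact anyway.
            integral = d0 * dt
    elif lam > 0.0:
        d = d0 * el + lam_d * p0 / (lam - lam_d) * (ed - el)
        # ∫₀^dt d(u) du, with the λ_D factor absorbed so λ_D = 0 is regular
        integral = d0 * (1.0 - el) / lam + p0 / (lam - lam_d) * (
            (1.0 - ed) - lam_d * (1.0 - el) / lam
        )
    else:
        # Λ = 0 with λ_D clearly nonzero: d only accumulates influx.
        d = d0 + p0 * (1.0 - ed)
        integral = d0 * dt + p0 * (dt - (1.0 - ed) / lam_d)
    return p, d, lam_n * integral, lam_m * integral


def constant_rate_segment(
    state0: PopulationState, regime: RateRegime, dt: float
) -> PopulationState:
    """Exact closed-form solution of the linear system over [0, dt].

    p(dt) = p0 e^{-λ_D dt}; d(dt) follows the two-exponential solution
    (or its confluent limit when Λ = λ_N + λ_M ≈ λ_D); n and m grow by
    the closed-form integrals of λ_N d and λ_M d. Mass is conserved.
    """
    dt = float(dt)
    if not math.isfinite(dt) or dt < 0.0:
        raise ValidationError(f"dt must be finite and >= 0, got {dt!r}")
    if dt == 0.0:
        return state0
    p, d, dn, dm = _propagate(
        state0.p, state0.d, regime.lambda_D_eff, regime.lambda_N_eff, regime.lambda_M_eff, dt
    )
    return PopulationState(
        time=state0.time + dt, p=p, d=d, n=state0.n + dn, m=state0.m + dm
    )


def signal_level(
    params: RateParameters,
    t: float,
    *,
    p0: float = 1.0,
    law: SignalLaw = "instantaneous",
) -> SignalState:
    """Level of the population signal at time ``t``.

    The signal builds up as cells lose pluripotency. Under the default
    ``instantaneous`` law it equals the non-pluripotent fraction,
    s(t) = 1 - p0 e^{-λ_D t}; the ``cumulative`` law integrates that
    fraction over time, s(t) = ∫₀ᵗ (1 - p0 e^{-λ_D u}) du. Both are
    monotone nondecreasing; only the instantaneous law is bounded by 1.
    """
    t = float(t)
    if not math.isfinite(t) or t < 0.0:
        raise ValidationError(f"t must be finite and >= 0, got {t!r}")
    if not 0.0 <= p0 <= 1.0:
        raise ValidationError(f"p0 must lie in [0, 1], got {p0!r}")
    lam_d = params.lambda_D
    if law == "instantaneous":
        s = 1.0 - p0 * math.exp(-lam_d * t)
    elif law == "cumulative":
        if lam_d > 0.0:
            s = t - p0 * (1.0 - math.exp(-lam_d * t)) / lam_d
        else:
            s = t * (1.0 - p0)
    else:
        raise ValidationError(f"unknown signal law {law!r}")
    return SignalState(s=s, crossed=s >= params.theta)


def crossing_time(
    params: RateParameters,
    *,
    p0: float = 1.0,
    law: SignalLaw = "instantaneous",
) -> float:
    """Smallest t with s(t) >= theta, or +inf if the threshold is never hit.

    Under the default law with a fully pluripotent start,
    t* = ln(1 / (1 - theta)) / λ_D; theta = 0 gives t* = 0 and theta = 1
    or λ_D = 0 give +inf.
    """
    theta = params.theta
    if signal_level(params, 0.0, p0=p0, law=law).crossed:
        return 0.0
    lam_d = params.lambda_D
    if law == "instantaneous":
        # s(inf) = 1 for lam_d > 0; stuck at 1 - p0 for lam_d = 0
        if lam_d == 0.0 or theta >= 1.0:
            return math.inf
        # p0 e^{-λ_D t} = 1 - theta
        return math.log(p0 / (1.0 - theta)) / lam_d
    # Cumulative law: unbounded whenever some pluripotency is ever lost.
    if lam_d == 0.0 and p0 >= 1.0:
        return math.inf
    hi = 1.0
    while signal_level(params, hi, p0=p0, law=law).s < theta:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - defensive
            return math.inf
    return float(
        brentq(lambda t: signal_level(params, t, p0=p0, law=law).s - theta, 0.0, hi, xtol=1e-12)
    )


@dataclass(frozen=True)
class _Piece:
    """One maximal interval on which the rate regime is constant."""

    start: float
    end: float
    regime: RateRegime


def _regime_for(
    params: RateParameters, ps_permissive: bool, post_crossing: bool, condition_name: str
) -> RateRegime:
    if not ps_permissive:
        lam_m = 0.0
    elif post_crossing:
        lam_m = params.lambda_M_high
    else:
        lam_m = params.lambda_M_low
    phase = "post-threshold" if post_crossing else "pre-threshold"
    return RateRegime(
        lambda_D_eff=params.lambda_D,
        lambda_N_eff=params.lambda_N,
        lambda_M_eff=lam_m,
        label=f"{condition_name}/{phase}",
    )


def _build_pieces(
    protocol: "Protocol",
    params: RateParameters,
    init: PopulationState,
    law: SignalLaw,
    t_cross: float,
) -> list[_Piece]:
    total = protocol.total_duration
    breakpoints = set(protocol.boundaries)
    if 0.0 < t_cross < total:
        breakpoints.add(t_cross)
    edges = sorted(breakpoints)
    pieces: list[_Piece] = []
    for start, end in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (start + end)
        condition = protocol.condition_at(mid)
        post = mid >= t_cross
        pieces.append(
            _Piece(start, end, _regime_for(params, condition.ps_permissive, post, condition.name))
        )
    return pieces


def _prepare_grid(output_grid: Sequence[float], total: float) -> np.ndarray:
    grid = np.asarray(list(output_grid), dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValidationError("output grid must be a non-empty 1-D sequence of days")
    if not np.all(np.isfinite(grid)):
        raise ValidationError("output grid contains non-finite times")
    if grid.min() < -1e-12 or grid.max() > total + 1e-12:
        raise ValidationError(
            f"output grid must lie within the protocol span [0, {total}], "
            f"got range [{grid.min()}, {grid.max()}]"
        )
    if np.any(np.diff(grid) < 0):
        raise ValidationError("output grid must be sorted nondecreasing")
    return np.clip(grid, 0.0, total)


def simulate_protocol(
    protocol: "Protocol",
    params: RateParameters,
    init: PopulationState | None = None,
    output_grid: Sequence[float] | None = None,
    *,
    signal_law: SignalLaw = "instantaneous",
) -> Trajectory:
    """Exact piecewise-glued solution of the model over a culture protocol.

    The time axis is split at protocol segment boundaries and at the
    signal-crossing time; within each piece the rates are constant and
    the closed-form segment solution applies, with state continuity at
    the joints. The effective PS rate is 0 in non-PS-permissive media,
    ``lambda_M_low`` in permissive media before the crossing and
    ``lambda_M_high`` after.
    """
    if init is None:
        init = PopulationState.pluripotent()
    if init.time != 0.0:
        raise ValidationError("initial state must be at time 0 (protocols start at t=0)")
    total = protocol.total_duration
    if output_grid is None:
        output_grid = np.linspace(0.0, total, int(round(total * 10)) + 1)
    grid = _prepare_grid(output_grid, total)
    t_cross = crossing_time(params, p0=init.p, law=signal_law)
    pieces = _build_pieces(protocol, params, init, signal_law, t_cross)

    states = np.empty((grid.size, 4), dtype=float)
    labels: list[str] = [""] * grid.size
    state = init
    gi = 0
    # grid times exactly at a joint take the regime of the piece that starts
    # there (half-open convention); t = total falls to the last piece.
    for k, piece in enumerate(pieces):
        is_last = k == len(pieces) - 1
        while gi < grid.size and (
            grid[gi] < piece.end - 1e-15 or (is_last and grid[gi] <= piece.end + 1e-15)
        ):
            t = grid[gi]
            if t < piece.start - 1e-15:
                # grid time before this piece: only possible for t == 0
                out = state
                label = piece.regime.label
            else:
                out = constant_rate_segment(state, piece.regime, max(t - piece.start, 0.0))
                label = piece.regime.label
            states[gi] = out.as_array()
            labels[gi] = label
            gi += 1
        state = constant_rate_segment(state, piece.regime, piece.end - piece.start)
    signal = np.array(
        [signal_level(params, t, p0=init.p, law=signal_law).s for t in grid]
    )
    return Trajectory(times=grid, states=states, signal=signal, regime_labels=labels, params=params)


def numeric_oracle(
    protocol: "Protocol",
    params: RateParameters,
    init: PopulationState | None = None,
    output_grid: Sequence[float] | None = None,
    *,
    signal_law: SignalLaw = "instantaneous",
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Adaptive numerical integration of :func:`rhs`, for cross-validation.

    Integrates each constant-regime piece with a high-order adaptive
    scheme; the signal crossing is located by bisection on
    :func:`signal_level` to 1e-10 days rather than taken from the
    closed form used by the analytic solver.
    """
    if init is None:
        init = PopulationState.pluripotent()
    if init.time != 0.0:
        raise ValidationError("initial state must be at time 0 (protocols start at t=0)")
    total = protocol.total_duration
    if output_grid is None:
        output_grid = np.linspace(0.0, total, int(round(total * 10)) + 1)
    grid = _prepare_grid(output_grid, total)

    # Locate the crossing by bisection on the signal itself.
    theta = params.theta
    if signal_level(params, 0.0, p0=init.p, law=signal_law).crossed:
        t_cross = 0.0
    elif not signal_level(params, total, p0=init.p, law=signal_law).crossed:
        t_cross = math.inf
    else:
        lo, hi = 0.0, total
        while hi - lo > 1e-10:
            mid = 0.5 * (lo + hi)
            if signal_level(params, mid, p0=init.p, law=signal_law).s >= theta:
                hi = mid
            else:
                lo = mid
        t_cross = hi
    pieces = _build_pieces(protocol, params, init, signal_law, t_cross)

    states = np.empty((grid.size, 4), dtype=float)
    labels: list[str] = [""] * grid.size
    y = init.as_array()
    gi = 0
    for k, piece in enumerate(pieces):
        regime = piece.regime
        lam = np.array(
            [
                [-regime.lambda_D_eff, 0.0, 0.0, 0.0],
                [regime.lambda_D_eff, -(regime.lambda_N_eff + regime.lambda_M_eff), 0.0, 0.0],
                [0.0, regime.lambda_N_eff, 0.0, 0.0],
                [0.0, regime.lambda_M_eff, 0.0, 0.0],
            ]
        )
        is_last = k == len(pieces) - 1
        t_eval = []
        while gi + len(t_eval) < grid.size:
            t = grid[gi + len(t_eval)]
            if t < piece.end - 1e-15 or (is_last and t <= piece.end + 1e-15):
                t_eval.append(min(max(t, piece.start), piece.end))
            else:
                break
        sol = solve_ivp(
            lambda _t, _y: lam @ _y,
            (piece.start, piece.end),
            y,
            method="DOP853",
            t_eval=t_eval or None,
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"numerical integration failed on piece [{piece.start}, {piece.end}]: "
                f"{sol.message}"
            )
        for j in range(len(t_eval)):
            states[gi + j] = sol.y[:, j]
            labels[gi + j] = regime.label
        gi += len(t_eval)
        # advance to the piece end for the next piece's initial condition
        end_sol = solve_ivp(
            lambda _t, _y: lam @ _y,
            (piece.start, piece.end),
            y,
            method="DOP853",
            rtol=rtol,
            atol=atol,
        )
        if not end_sol.success:  # pragma: no cover - defensive
            raise IntegrationError(f"integration to piece end failed: {end_sol.message}")
        y = end_sol.y[:, -1]
    signal = np.array(
        [signal_level(params, t, p0=init.p, law=signal_law).s for t in grid]
    )
    return Trajectory(times=grid, states=states, signal=signal, regime_labels=labels, params=params)
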