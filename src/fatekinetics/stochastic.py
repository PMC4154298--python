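"""Per-cell stochastic counterpart of the deterministic fate model.

Each cell is an independent discrete-time Markov chain over the states
P -> D -> {N, M}, driven by the same rates as the mean-field model. The
population is advanced in fixed steps of at most 0.05 day; per step a
pluripotent cell exits with probability 1 - exp(-lambda_D dt) and an
uncommitted cell resolves a single categorical draw between staying,
committing to NECT and committing to PS, with the exact competing-risk
probabilities lambda_X / Lambda * (1 - exp(-Lambda dt)).

The threshold signal is computed from the *realized* pluripotent
fraction by default (population-coupled, self-consistent), with a
switch to the deterministic closed-form signal. Exit times are drawn
exactly from the truncated-exponential conditional law within the step
that the exit occurred, so the marginal exit-time distribution is
exactly exponential; commitment times are recorded at step resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model import RateParameters, SignalLaw, signal_level
from .protocols import Protocol

__all__ = ["CellRecord", "CountsTrajectory", "simulate_population", "MAX_DT"]

#: Largest allowed step, days. Keeps single-step transition probabilities
#: well below 1 at the supported rate bounds.
MAX_DT = 0.05

_STATE_P, _STATE_D, _STATE_N, _STATE_M = 0, 1, 2, 3
_FATE_NAMES = {_STATE_P: "uncommitted", _STATE_D: "uncommitted", _STATE_N: "NECT", _STATE_M: "PS"}


@dataclass(frozen=True)
class CellRecord:
    """Commitment history of one cell over a protocol."""

    cell_id: int
    t_exit: float | None      # P -> D transition time, days; None if never exited
    t_commit: float | None    # commitment time, days; None if uncommitted at end
    final_fate: str           # "NECT", "PS" or "uncommitted"

    def __post_init__(self) -> None:
        if self.final_fate not in ("NECT", "PS", "uncommitted"):
            raise ValidationError(f"unknown fate {self.final_fate!r}")
        if (self.t_commit is not None) == (self.final_fate == "uncommitted"):
            raise ValidationError("t_commit must be set exactly for committed cells")
        if self.t_commit is not None and self.t_exit is not None and self.t_exit > self.t_commit + 1e-9:
            raise ValidationError("t_exit must not exceed t_commit")


@dataclass(eq=False)
class CountsTrajectory:
    """Integer state counts (P, D, N, M) on a time grid; rows sum to n_cells."""

    times: np.ndarray
    counts: np.ndarray  # shape (len(times), 4), ints
    n_cells: int

    def fractions(self) -> np.ndarray:
        return self.counts / self.n_cells

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_day": self.times,
                "P": self.counts[:, 0],
                "D": self.counts[:, 1],
                "N": self.counts[:, 2],
                "M": self.counts[:, 3],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "t_exit_day": [r.t_exit for r in records],
            "t_commit_day": [r.t_commit for r in records],
            "final_fate": [r.final_fate for r in records],
        }
    )


def _step_edges(protocol: Protocol, dt: float) -> np.ndarray:
    """Step edges aligned to segment boundaries, each step <= dt."""
    edges = [0.0]
    for start, end in zip(protocol.boundaries[:-1], protocol.boundaries[1:]):
        n_steps = max(1, math.ceil((end - start) / dt - 1e-12))
        edges.extend(np.linspace(start, end, n_steps + 1)[1:])
    return np.asarray(edges)


def simulate_population(
    protocol: Protocol,
    params: RateParameters,
    n_cells: int,
    dt: float = 0.02,
    seed: int = 0,
    *,
    signal_coupling: Literal["population", "deterministic"] = "population",
    signal_law: SignalLaw = "instantaneous",
) -> tuple[CountsTrajectory, list[CellRecord]]:
    """Simulate ``n_cells`` independent cells through a culture protocol.

    Returns the per-step state counts and one :class:`CellRecord` per
    cell. Fully reproducible given ``seed``.
    """
    if n_cells < 1:
        raise ValidationError(f"n_cells must be >= 1, got {n_cells}")
    if not 0.0 < dt <= MAX_DT:
        raise ValidationError(
            f"dt must lie in (0, {MAX_DT}] day for transition-probability accuracy, got {dt}"
        )
    rng = np.random.default_rng(seed)
    edges = _step_edges(protocol, dt)
    lam_d, lam_n = params.lambda_D, params.lambda_N

    state = np.zeros(n_cells, dtype=np.int8)  # all pluripotent at t=0
    t_exit = np.full(n_cells, np.nan)
    t_commit = np.full(n_cells, np.nan)
    crossed = False

    counts = np.empty((edges.size, 4), dtype=np.int64)
    counts[0] = np.bincount(state, minlength=4)

    for k in range(edges.size - 1):
        t0, t1 = edges[k], edges[k + 1]
        h = t1 - t0
        condition = protocol.condition_at(0.5 * (t0 + t1))

        if not crossed:
            if signal_coupling == "population":
                s = 1.0 - counts[k, _STATE_P] / n_cells
            elif signal_coupling == "deterministic":
                s = signal_level(params, t0, law=signal_law).s
            else:
                raise ValidationError(f"unknown signal coupling {signal_coupling!r}")
            crossed = s >= params.theta  # irreversible switch

        if not condition.ps_permissive:
            lam_m = 0.0
        else:
            lam_m = params.lambda_M_high if crossed else params.lambda_M_low

        # P -> D exits, with the exit time drawn exactly from the
        # exponential law conditioned on exit within (t0, t1].
        is_p = state == _STATE_P
        n_p = int(is_p.sum())
        if n_p and lam_d > 0.0:
            u = rng.random(n_p)
            p_exit = -math.expm1(-lam_d * h)
            exits = u < p_exit
            if exits.any():
                # u | exit ~ U(0, p_exit), so -log(1-u)/lam_d is exactly
                # the exponential exit time truncated to (0, h]
                tau = -np.log1p(-u[exits]) / lam_d
                idx = np.flatnonzero(is_p)[exits]
                state[idx] = _STATE_D
                t_exit[idx] = t0 + tau

        # D -> {N, M}: one categorical draw per uncommitted cell. Cells
        # that exited this step first commit from the next step on.
        is_d = (state == _STATE_D) & (t_exit <= t0 + 1e-15)
        lam_total = lam_n + lam_m
        n_d = int(is_d.sum())
        if n_d and lam_total > 0.0:
            p_leave = -math.expm1(-lam_total * h)
            p_n = lam_n / lam_total * p_leave
            u = rng.random(n_d)
            to_n = u < p_n
            to_m = (u >= p_n) & (u < p_leave)
            idx = np.flatnonzero(is_d)
            if to_n.any():
                state[idx[to_n]] = _STATE_N
                t_commit[idx[to_n]] = t1
            if to_m.any():
                state[idx[to_m]] = _STATE_M
                t_commit[idx[to_m]] = t1

        counts[k + 1] = np.bincount(state, minlength=4)

    records = [
        CellRecord(
            cell_id=i,
            t_exit=None if math.isnan(t_exit[i]) else float(t_exit[i]),
            t_commit=None if math.isnan(t_commit[i]) else float(t_commit[i]),
            final_fate=_FATE_NAMES[int(state[i])],
        )
        for i in range(n_cells)
    ]
    return CountsTrajectory(times=edges, counts=counts, n_cells=n_cells), records
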