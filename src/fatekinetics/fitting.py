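"""Parameter estimation from reporter-positive fraction time courses.

The fit proceeds in the two stages the model's structure dictates:

1. :func:`fit_neutral` — estimate the pluripotency-exit rate ``lambda_D``
   and the NECT commitment rate ``lambda_N`` from neutral (N2B27)
   differentiation time courses, with the PS channel closed
   (``lambda_M = 0``), since no PS differentiation occurs there.
2. :func:`fit_switch` — with (``lambda_D``, ``lambda_N``) held fixed,
   estimate the post-threshold PS rate ``lambda_M_high`` and the signal
   threshold ``theta`` from pulse-chase endpoint fractions.

Both stages minimise a sum of squared errors on the fraction scale by
bounded multi-start nonlinear least squares (trust-region reflective),
with starts drawn log-uniformly from the parameter bounds. Binomial
variance weighting is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import (
    FitConvergenceError,
    IdentifiabilityError,
    ValidationError,
)
from .model import RateParameters, SignalLaw, simulate_protocol
from .protocols import Protocol

__all__ = [
    "TimeCourseDataset",
    "FitOptions",
    "FitResult",
    "sse_loss",
    "fit_neutral",
    "fit_switch",
    "REPORTER_TO_STATE",
]

#: Reporter labels and the model compartment each one reads out.
REPORTER_TO_STATE: Mapping[str, str] = {
    "NECT": "n",          # Sox1::GFP-like reporter
    "PS": "m",            # T::GFP-like reporter
    "pluripotency": "p",  # Nanog/Rex1-reporter-like readout
}

_COLUMNS = ["time_day", "protocol_id", "reporter", "positive_count", "total_count", "fraction"]


@dataclass(eq=False)
class TimeCourseDataset:
    """Observed reporter-positive fractions over days, per protocol.

    ``frame`` columns: time_day, protocol_id, reporter, positive_count,
    total_count, fraction. Counts are integers when the data come from
    (real or simulated) cell sampling and absent in noiseless synthetic
    mode; the ``fraction`` column is always present and is what the
    fitters consume. ``protocols`` maps each protocol_id to the
    :class:`~fatekinetics.protocols.Protocol` it was measured under.
    """

    frame: pd.DataFrame
    protocols: dict[str, Protocol]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        missing = [c for c in ("time_day", "protocol_id", "reporter") if c not in frame.columns]
        if missing:
            raise ValidationError(f"dataset missing columns: {missing}")
        if "fraction" not in frame.columns:
            if not {"positive_count", "total_count"} <= set(frame.columns):
                raise ValidationError("dataset needs either counts or a fraction column")
            frame["fraction"] = frame["positive_count"] / frame["total_count"]
        for col in ("positive_count", "total_count"):
            if col not in frame.columns:
                frame[col] = pd.array([pd.NA] * len(frame), dtype="Int64")
            else:
                frame[col] = frame[col].astype("Int64")
        frame = frame[_COLUMNS]
        self.frame = frame
        self.validate()

    def validate(self) -> None:
        frame = self.frame
        if len(frame) == 0:
            raise ValidationError("dataset is empty")
        if (frame["time_day"] < 0).any():
            raise ValidationError("times must be >= 0")
        bad = set(frame["reporter"]) - set(REPORTER_TO_STATE)
        if bad:
            raise ValidationError(
                f"unknown reporters {sorted(bad)}; expected {sorted(REPORTER_TO_STATE)}"
            )
        has_counts = frame["total_count"].notna()
        counts = frame.loc[has_counts]
        if (counts["total_count"] <= 0).any():
            raise ValidationError("total_count must be > 0")
        if (counts["positive_count"] < 0).any() or (
            counts["positive_count"] > counts["total_count"]
        ).any():
            raise ValidationError("positive_count must lie in [0, total_count]")
        if ((frame["fraction"] < 0) | (frame["fraction"] > 1)).any():
            raise ValidationError("fractions must lie in [0, 1]")
        unknown = set(frame["protocol_id"]) - set(self.protocols)
        if unknown:
            raise ValidationError(f"records reference unknown protocol ids: {sorted(unknown)}")
        for pid, protocol in self.protocols.items():
            times = frame.loc[frame["protocol_id"] == pid, "time_day"]
            if len(times) and times.max() > protocol.total_duration + 1e-9:
                raise ValidationError(
                    f"protocol {pid!r}: observation at day {times.max()} exceeds "
                    f"protocol span {protocol.total_duration}"
                )

    @property
    def n_timepoints(self) -> int:
        return self.frame["time_day"].nunique()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, protocols: dict[str, Protocol], metadata: dict | None = None):
        frame = pd.read_csv(path)
        return cls(frame=frame, protocols=protocols, metadata=metadata or {})


def _predict_fractions(
    params: RateParameters,
    dataset: TimeCourseDataset,
    signal_law: SignalLaw,
) -> np.ndarray:
    """Model-predicted fraction for each dataset record, in row order."""
    pred = np.empty(len(dataset.frame), dtype=float)
    state_cols = {"p": 0, "d": 1, "n": 2, "m": 3}
    for pid, group in dataset.frame.groupby("protocol_id", sort=False):
        protocol = dataset.protocols[pid]
        times = np.sort(group["time_day"].unique())
        traj = simulate_protocol(protocol, params, output_grid=times, signal_law=signal_law)
        lookup = {t: traj.states[i] for i, t in enumerate(times)}
        for idx, row in zip(group.index, group.itertuples(index=False)):
            col = state_cols[REPORTER_TO_STATE[row.reporter]]
            pred[dataset.frame.index.get_loc(idx)] = lookup[row.time_day][col]
    return pred


def _residuals(
    params: RateParameters,
    dataset: TimeCourseDataset,
    signal_law: SignalLaw,
    weighting: str,
) -> np.ndarray:
    observed = dataset.frame["fraction"].to_numpy(dtype=float)
    predicted = _predict_fractions(params, dataset, signal_law)
    res = observed - predicted
    if weighting == "binomial":
        totals = dataset.frame["total_count"].to_numpy(dtype=float)
        if np.any(~np.isfinite(totals)):
            raise ValidationError("binomial weighting requires counts in every record")
        q = np.clip(predicted, 1e-6, 1.0 - 1e-6)
        res = res / np.sqrt(q * (1.0 - q) / totals)
    elif weighting != "none":
        raise ValidationError(f"unknown weighting {weighting!r}")
    return res


def _build_params(candidate: Mapping[str, float], fixed: Mapping[str, float]) -> RateParameters:
    merged = dict(fixed)
    overlap = set(candidate) & set(fixed)
    if overlap:
        raise ValidationError(f"parameters specified both as candidate and fixed: {sorted(overlap)}")
    merged.update(candidate)
    return RateParameters(**merged)


def sse_loss(
    candidate: Mapping[str, float],
    dataset: TimeCourseDataset,
    fixed: Mapping[str, float] | None = None,
    *,
    signal_law: SignalLaw = "instantaneous",
    weighting: str = "none",
) -> float:
    """Sum of squared errors between observed and model-predicted fractions."""
    params = _build_params(candidate, fixed or {})
    res = _residuals(params, dataset, signal_law, weighting)
    return float(np.dot(res, res))


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for the multi-start bounded least-squares fits."""

    n_starts: int = 20
    seed: int = 0
    rate_bounds: tuple[float, float] = (1e-4, 10.0)
    theta_bounds: tuple[float, float] = (0.01, 0.99)
    weighting: str = "none"
    signal_law: SignalLaw = "instantaneous"
    ftol: float = 1e-10  # loss-change convergence tolerance
    xtol: float = 1e-8   # step convergence tolerance


@dataclass(frozen=True)
class FitResult:
    """Best-of-starts estimate with its loss and reproducibility metadata."""

    estimates: dict[str, float]
    loss: float
    n_starts: int
    converged: bool
    bounds: dict[str, tuple[float, float]]
    seed: int
    fixed: dict[str, float] = field(default_factory=dict)
    regime_consistent: bool | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": name,
                "estimate": value,
                "bound_low": self.bounds[name][0],
                "bound_high": self.bounds[name][1],
            }
            for name, value in self.estimates.items()
        ]
        return pd.DataFrame(rows)

    def report(self) -> str:
        lines = [
            "fit result",
            f"  loss (SSE on fractions): {self.loss:.6g}",
            f"  starts: {self.n_starts}, converged: {self.converged}, seed: {self.seed}",
        ]
        for name, value in self.estimates.items():
            lo, hi = self.bounds[name]
            lines.append(f"  {name} = {value:.6g}  (bounds [{lo:g}, {hi:g}])")
        for name, value in self.fixed.items():
            lines.append(f"  {name} = {value:.6g}  (fixed)")
        if self.regime_consistent is not None:
            lines.append(
                "  regime lambda_M_high > lambda_N: "
                + ("consistent" if self.regime_consistent else "NOT consistent")
            )
        return "\n".join(lines)


def _multistart(
    free_names: Sequence[str],
    bounds: dict[str, tuple[float, float]],
    fixed: Mapping[str, float],
    dataset: TimeCourseDataset,
    options: FitOptions,
) -> tuple[dict[str, float], float, bool]:
    lo = np.array([bounds[name][0] for name in free_names])
    hi = np.array([bounds[name][1] for name in free_names])
    rng = np.random.default_rng(options.seed)
    starts = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=(options.n_starts, len(free_names)))
    )

    def residual_fn(x: np.ndarray) -> np.ndarray:
        candidate = dict(zip(free_names, x))
        params = _build_params(candidate, fixed)
        return _residuals(params, dataset, options.signal_law, options.weighting)

    best_x = None
    best_loss = math.inf
    any_converged = False
    for x0 in starts:
        try:
            sol = least_squares(
                residual_fn,
                x0,
                bounds=(lo, hi),
                method="trf",
                ftol=options.ftol,
                xtol=options.xtol,
                gtol=1e-12,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        any_converged = True
        loss = float(2.0 * sol.cost)
        if loss < best_loss:  # strict: ties broken by first-found
            best_loss = loss
            best_x = sol.x
    if best_x is None:
        raise FitConvergenceError(
            f"none of the {options.n_starts} optimizer starts converged"
        )
    return dict(zip(free_names, (float(v) for v in best_x))), best_loss, any_converged


def fit_neutral(dataset: TimeCourseDataset, options: FitOptions | None = None) -> FitResult:
    """Estimate (lambda_D, lambda_N) from neutral-medium differentiation data.

    The PS channel is closed (lambda_M_low = lambda_M_high = 0),
    reflecting that no PS differentiation occurs in N2B27. The dataset
    must come from non-PS-permissive protocols, observe the NECT and/or
    pluripotency reporter, and contain at least two distinct time points.
    """
    options = options or FitOptions()
    for pid, protocol in dataset.protocols.items():
        if any(seg.condition.ps_permissive for seg in protocol.segments):
            raise ValidationError(
                f"neutral fit requires non-PS-permissive protocols; {pid!r} is not"
            )
    if "PS" in set(dataset.frame["reporter"]):
        raise ValidationError("neutral fit accepts NECT/pluripotency reporters only")
    if dataset.n_timepoints < 2:
        raise IdentifiabilityError(
            "neutral fit needs at least 2 distinct time points to separate "
            "lambda_D from lambda_N"
        )
    fixed = {"lambda_M_low": 0.0, "lambda_M_high": 0.0, "theta": 1.0}
    bounds = {"lambda_D": options.rate_bounds, "lambda_N": options.rate_bounds}
    estimates, loss, converged = _multistart(
        ("lambda_D", "lambda_N"), bounds, fixed, dataset, options
    )
    return FitResult(
        estimates=estimates,
        loss=loss,
        n_starts=options.n_starts,
        converged=converged,
        bounds=bounds,
        seed=options.seed,
        fixed={},
    )


def fit_switch(
    dataset: TimeCourseDataset,
    fixed: Mapping[str, float],
    options: FitOptions | None = None,
) -> FitResult:
    """Estimate (lambda_M_high, theta) from pulse-chase endpoint data.

    ``fixed`` must provide lambda_D and lambda_N (typically from
    :func:`fit_neutral`); lambda_M_low is held at 0. The result is
    flagged ``regime_consistent`` when the recovered lambda_M_high
    exceeds lambda_N, the switch regime the model assumes in
    PS-permissive media.
    """
    options = options or FitOptions()
    missing = {"lambda_D", "lambda_N"} - set(fixed)
    if missing:
        raise ValidationError(f"fit_switch requires fixed values for {sorted(missing)}")
    ps = dataset.frame[dataset.frame["reporter"] == "PS"]
    if len(ps) and (ps["fraction"] <= 1e-12).all():
        raise IdentifiabilityError(
            "all PS fractions are zero: theta and lambda_M_high are unidentifiable"
        )
    fixed_full = {
        "lambda_D": float(fixed["lambda_D"]),
        "lambda_N": float(fixed["lambda_N"]),
        "lambda_M_low": float(fixed.get("lambda_M_low", 0.0)),
    }
    bounds = {"lambda_M_high": options.rate_bounds, "theta": options.theta_bounds}
    estimates, loss, converged = _multistart(
        ("lambda_M_high", "theta"), bounds, fixed_full, dataset, options
    )
    return FitResult(
        estimates=estimates,
        loss=loss,
        n_starts=options.n_starts,
        converged=converged,
        bounds=bounds,
        seed=options.seed,
        fixed=dict(fixed_full),
        regime_consistent=estimates["lambda_M_high"] > fixed_full["lambda_N"],
    )
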