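"""Fixed-step explicit Runge-Kutta integration with trajectory recording.

Criticality Analysis depends on bit-reproducible dynamics: the same data
presented to the same network must settle onto the same orbit.  Adaptive
step-size control would make the trajectory depend on solver heuristics, so
only fixed-step steppers are provided: the classical RK4 scheme and the
fifth-order solution of the Runge-Kutta-Fehlberg 4(5) tableau, used here
without error adaptation.

Vector fields are callables ``deriv(t, y) -> dy/dt`` operating on 1-D (or
(n, d)-shaped) float arrays, matching the scipy convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BLOWUP_LIMIT",
    "ClampSchedule",
    "NumericalBlowUp",
    "Trajectory",
    "fehlberg_step",
    "integrate",
    "rk4_step",
]

#: Any state component whose magnitude exceeds this is treated as divergence.
BLOWUP_LIMIT = 1e12

VectorField = Callable[[float, np.ndarray], np.ndarray]


class NumericalBlowUp(RuntimeError):
    """Raised when a trajectory leaves the finite, bounded domain.

    Attributes carry the model time, global step index and (when the blow-up
    happens inside the clamping protocol) the index of the offending sample.
    """

    def __init__(self, message: str, t: float | None = None,
                 step: int | None = None, sample_index: int | None = None):
        super().__init__(message)
        self.t = t
        self.step = step
        self.sample_index = sample_index


@dataclass(frozen=True)
class ClampSchedule:
    """Timing of the clamping protocol.

    Each data sample is held constant at the network input for
    ``steps_per_sample`` integration steps of size ``step_size`` (model time
    units).  The leading ``transient_fraction`` of each clamp window is
    discarded before features are extracted, so that orbit summaries describe
    the settled response rather than the approach to it.  States are recorded
    every ``record_stride`` steps; features are computed on the recorded grid.
    """

    steps_per_sample: int = 50_000
    step_size: float = 0.1
    transient_fraction: float = 0.5
    record_stride: int = 10

    def __post_init__(self) -> None:
        if self.steps_per_sample < 1:
            raise ValueError("steps_per_sample must be >= 1")
        if not (self.step_size > 0):
            raise ValueError("step_size must be positive")
        if not (0 <= self.transient_fraction < 1):
            raise ValueError("transient_fraction must lie in [0, 1)")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.steps_per_sample % self.record_stride != 0:
            raise ValueError(
                "steps_per_sample must be divisible by record_stride "
                f"(got {self.steps_per_sample} / {self.record_stride})")

    @property
    def records_per_sample(self) -> int:
        return self.steps_per_sample // self.record_stride


@dataclass
class Trajectory:
    """A recorded trajectory, optionally segmented into clamp windows.

    ``states`` has one row per recorded time point and one column per state
    channel; ``channel_labels`` names the columns (e.g. ``"osc3:m"``).
    ``sample_boundaries`` holds ``(start, end)`` recorded-index pairs, one per
    presented sample, with ``end`` exclusive.
    """

    times: np.ndarray
    states: np.ndarray
    sample_boundaries: list[tuple[int, int]] = field(default_factory=list)
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states must be (n_times, n_channels)")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_boundaries)

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None
        return self.states[:, idx]

    def window(self, i: int) -> np.ndarray:
        start, end = self.sample_boundaries[i]
        return self.states[start:end]

    def window_times(self, i: int) -> np.ndarray:
        start, end = self.sample_boundaries[i]
        return self.times[start:end]


def _check_finite(y: np.ndarray, t: float, step: int) -> None:
    if not np.all(np.isfinite(y)) or np.any(np.abs(y) > BLOWUP_LIMIT):
        raise NumericalBlowUp(
            f"numerical blow-up at t={t:.6g} (step {step})", t=t, step=step)


def rk4_step(deriv: VectorField, state: np.ndarray, t: float, h: float) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step of size ``h``."""
    if not h > 0:
        raise ValueError("step size h must be positive")
    y = np.asarray(state, dtype=float)
    k1 = np.asarray(deriv(t, y))
    k2 = np.asarray(deriv(t + 0.5 * h, y + 0.5 * h * k1))
    k3 = np.asarray(deriv(t + 0.5 * h, y + 0.5 * h * k2))
    k4 = np.asarray(deriv(t + h, y + h * k3))
    out = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    _check_finite(out, t, 0)
    return out


# Runge-Kutta-Fehlberg 4(5) tableau; the 5th-order solution is used.
_RKF_C = (0.0, 1 / 4, 3 / 8, 12 / 13, 1.0, 1 / 2)
_RKF_A = (
    (),
    (1 / 4,),
    (3 / 32, 9 / 32),
    (1932 / 2197, -7200 / 2197, 7296 / 2197),
    (439 / 216, -8.0, 3680 / 513, -845 / 4104),
    (-8 / 27, 2.0, -3544 / 2565, 1859 / 4104, -11 / 40),
)
_RKF_B5 = (16 / 135, 0.0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55)


def fehlberg_step(deriv: VectorField, state: np.ndarray, t: float, h: float) -> np.ndarray:
    """One fixed-size Runge-Kutta-Fehlberg step (5th-order solution).

    The embedded 4th-order estimate is not evaluated: no step adaptation.
    """
    if not h > 0:
        raise ValueError("step size h must be positive")
    y = np.asarray(state, dtype=float)
    ks = []
    for i in range(6):
        yi = y.copy()
        for a, k in zip(_RKF_A[i], ks):
            yi += h * a * k
        ks.append(np.asarray(deriv(t + _RKF_C[i] * h, yi)))
    out = y + h * sum(b * k for b, k in zip(_RKF_B5, ks))
    _check_finite(out, t, 0)
    return out


STEPPERS = {"rk4": rk4_step, "fehlberg": fehlberg_step}


def integrate(
    deriv: VectorField,
    state0: Sequence[float] | np.ndarray,
    n_steps: int,
    schedule: ClampSchedule | None = None,
    *,
    h: float | None = None,
    t0: float = 0.0,
    stepper: VectorField | str = "rk4",
    record_stride: int | None = None,
    channel_labels: Sequence[str] | None = None,
) -> Trajectory:
    """Integrate ``deriv`` for ``n_steps`` fixed steps, recording states.

    Timing is taken from ``schedule`` (step size and recorder stride) unless
    overridden with ``h`` / ``record_stride``.  The initial state is always
    recorded; thereafter every ``record_stride``-th step.  With stride 1 the
    trajectory holds ``n_steps + 1`` points.
    """
    if schedule is None and h is None:
        raise ValueError("either a ClampSchedule or an explicit h is required")
    step_h = float(h if h is not None else schedule.step_size)
    stride = int(record_stride if record_stride is not None
                 else (schedule.record_stride if schedule is not None else 1))
    step_fn = STEPPERS[stepper] if isinstance(stepper, str) else stepper

    y = np.array(state0, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("initial state must be finite")

    rec_idx = [0]
    rec_states = [y.copy()]
    for step in range(1, n_steps + 1):
        t = t0 + (step - 1) * step_h
        try:
            y = step_fn(deriv, y, t, step_h)
        except NumericalBlowUp as exc:
            raise NumericalBlowUp(
                f"numerical blow-up at step {step} (t={t:.6g})",
                t=t, step=step) from exc
        if step % stride == 0 or step == n_steps:
            rec_idx.append(step)
            rec_states.append(y.copy())

    times = t0 + step_h * np.asarray(rec_idx, dtype=float)
    states = np.vstack(rec_states)
    labels = (list(channel_labels) if channel_labels is not None
              else [f"y{i}" for i in range(states.shape[1])])
    return Trajectory(times=times, states=states,
                      sample_boundaries=[(0, len(times))],
                      channel_labels=labels)
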