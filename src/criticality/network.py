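"""Networks of coupled RCC oscillators and the clamped-input protocol.

A Criticality Analysis network is a set of ``n`` identical RCC-controlled
oscillators.  Berry oscillators couple through their matrix variable: the
drive of oscillator ``i`` is

    rim_i = sum_{k != i} w[k, i] * m_k + eps_i,

with no self-connections, where ``eps_i`` is the clamped (scaled, possibly
dynamically normalised) data value routed to that oscillator.  Wu
oscillators couple diffusively through a shared weight vector, with the self
term included: ``D_v = sum_k w_k * v_k`` is added to every oscillator's
``v`` equation.

The protocol presents a dataset row by row: each row is held constant at the
input for a fixed number of integration steps while the network state is
carried continuously across samples — the system moves from orbit to orbit,
never being reset.  Because everything is deterministic, the same row always
selects the same orbit, and nearby rows select nearby orbits; that is the
representation this package extracts features from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .input_scaling import NormalisationSettings, dynamic_normalise
from .ode_engine import (BLOWUP_LIMIT, ClampSchedule, NumericalBlowUp,
                         Trajectory)
from .plasticity import HebbianSettings, ReadoutSettings, readout_inputs
from .rcc_models import (BerryParams, WuParams, berry_derivatives,
                         rcc_quotient, wu_derivatives)

__all__ = [
    "Network",
    "NetworkSpec",
    "RandomConnectivity",
    "berry_coupling_input",
    "build_network",
    "wu_diffusion",
]

BERRY_VARS = ("m", "f", "p", "g")
WU_VARS = ("x", "y", "z", "w")


@dataclass(frozen=True)
class RandomConnectivity:
    """Randomised uniform connectivity: weights drawn from N(mean, sd^2),
    clipped at zero, using the network seed."""

    mean: float
    sd: float


@dataclass(frozen=True)
class NetworkSpec:
    """Full description of a CA network.

    ``weights`` may be a scalar (uniform coupling), an explicit matrix
    (Berry) or vector (Wu), or a :class:`RandomConnectivity` draw resolved
    with ``seed``.  ``input_map`` assigns each data attribute to exactly one
    oscillator (an oscillator receives at most one attribute).  ``learning``
    enables the dynamic Hebbian rule on all reservoir connections;
    ``readout`` appends two readout units driven by the reservoir totals.
    """

    model: str = "berry"
    n_oscillators: int = 4
    weights: float | Sequence | np.ndarray | RandomConnectivity = 0.0005
    input_map: tuple[int, ...] = (0, 1, 2, 3)
    normalisation: str = "static"
    learning: HebbianSettings | None = None
    readout: ReadoutSettings | None = None
    seed: int = 0
    integrator: str = "rk4"
    reset_per_sample: bool = False
    params: BerryParams | WuParams | None = None
    initial_state: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.model not in ("berry", "wu"):
            raise ValueError("model must be 'berry' or 'wu'")
        if self.n_oscillators < 1:
            raise ValueError("n_oscillators must be >= 1")
        if self.integrator not in ("rk4", "fehlberg"):
            raise ValueError("integrator must be 'rk4' or 'fehlberg'")
        if self.normalisation not in ("static", "dynamic"):
            raise ValueError("normalisation must be 'static' or 'dynamic'")
        n_total = self.n_oscillators + (2 if self.readout is not None else 0)
        seen = set()
        for osc in self.input_map:
            if not (0 <= osc < self.n_oscillators):
                raise ValueError(
                    f"input_map entry {osc} outside reservoir 0..{self.n_oscillators - 1}")
            if osc in seen:
                raise ValueError(
                    f"oscillator {osc} assigned more than one attribute")
            seen.add(osc)
        if self.model == "wu":
            if self.normalisation == "dynamic":
                raise ValueError(
                    "dynamic normalisation is defined through the Berry "
                    "filament quotient; not available for Wu networks")
            if self.learning is not None or self.readout is not None:
                raise ValueError(
                    "Hebbian learning / readout units require Berry networks")
        del n_total

    @property
    def n_attributes(self) -> int:
        return len(self.input_map)

    @property
    def n_total(self) -> int:
        """Oscillator count including readout units."""
        return self.n_oscillators + (2 if self.readout is not None else 0)


def berry_coupling_input(m_values, weights, external: float, i: int) -> float:
    """Drive of Berry oscillator ``i``: incoming weighted matrix values of
    all other oscillators (column ``i`` of the weight matrix) plus the
    external input."""
    m = np.asarray(m_values, dtype=float)
    W = np.asarray(weights, dtype=float)
    s = float(np.dot(W[:, i], m) - W[i, i] * m[i])
    return s + float(external)


def wu_diffusion(states, weights) -> np.ndarray:
    """Diffusion terms for a Wu network: ``D_v = sum_k w_k v_k`` over all
    oscillators (self included), identical for every oscillator.  Returns an
    (n, 4) matrix of (Dx, Dy, Dz, Dw) rows."""
    S = np.atleast_2d(np.asarray(states, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != S.shape[0]:
        raise ValueError("weight vector length must equal oscillator count")
    D = w @ S
    return np.tile(D, (S.shape[0], 1))


def _resolve_weights(spec: NetworkSpec) -> np.ndarray:
    """Concrete coupling weights: an (n, n) zero-diagonal matrix for Berry,
    a length-n vector for Wu."""
    n = spec.n_oscillators
    w = spec.weights
    if spec.model == "berry":
        if isinstance(w, RandomConnectivity):
            rng = np.random.default_rng(spec.seed)
            W = rng.normal(w.mean, w.sd, size=(n, n)).clip(min=0.0)
        elif np.isscalar(w):
            W = np.full((n, n), float(w))
        else:
            W = np.array(w, dtype=float)
            if W.shape != (n, n):
                raise ValueError(f"weight matrix must be ({n}, {n})")
        W = W.copy()
        np.fill_diagonal(W, 0.0)
        return W
    if isinstance(w, RandomConnectivity):
        rng = np.random.default_rng(spec.seed)
        return rng.normal(w.mean, w.sd, size=n).clip(min=0.0)
    if np.isscalar(w):
        return np.full(n, float(w))
    v = np.array(w, dtype=float).ravel()
    if v.shape != (n,):
        raise ValueError(f"Wu weight vector must have length {n}")
    return v


def build_network(spec: NetworkSpec) -> "Network":
    """Resolve a :class:`NetworkSpec` into a runnable :class:`Network`."""
    return Network(spec)


class Network:
    """A concrete, stateful CA network (use :func:`build_network`)."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.params = spec.params if spec.params is not None else (
            BerryParams() if spec.model == "berry" else WuParams())
        if spec.model == "berry" and not isinstance(self.params, BerryParams):
            raise TypeError("berry network requires BerryParams")
        if spec.model == "wu" and not isinstance(self.params, WuParams):
            raise TypeError("wu network requires WuParams")
        self.weights = _resolve_weights(spec)
        if spec.readout is not None:
            # readout units occupy the last two indices of the padded state
            pad = spec.n_total
            W = np.zeros((pad, pad))
            W[:spec.n_oscillators, :spec.n_oscillators] = self.weights
            self.weights = W
        self.readout_w7 = np.zeros(spec.n_total)
        self.readout_w8 = np.zeros(spec.n_total)
        self.reset_state()

    # -- state ----------------------------------------------------------
    @property
    def n_total(self) -> int:
        return self.spec.n_total

    @property
    def readout_indices(self) -> tuple[int, int] | None:
        if self.spec.readout is None:
            return None
        return (self.spec.n_oscillators, self.spec.n_oscillators + 1)

    def reset_state(self) -> None:
        init = np.asarray(self.spec.initial_state, float)
        if init.ndim == 1:
            self.state = np.tile(init, (self.n_total, 1))
        else:
            if init.shape != (self.n_total, 4):
                raise ValueError(
                    f"initial_state must be a 4-vector or ({self.n_total}, 4)")
            self.state = init.copy()

    @property
    def channel_labels(self) -> list[str]:
        names = BERRY_VARS if self.spec.model == "berry" else WU_VARS
        return [f"osc{i}:{v}" for i in range(self.n_total) for v in names]

    # -- reference vector field (pure Python; cross-checked vs kernels) --
    def derivatives(self, t: float, flat_state: np.ndarray,
                    eps: np.ndarray) -> np.ndarray:
        """Vector field of the whole network at clamped inputs ``eps``
        (per-oscillator, already effective).  Reference implementation used
        by the generic integrator path and the test suite; the production
        path runs the compiled kernels."""
        S = np.asarray(flat_state, float).reshape(self.n_total, 4)
        out = np.empty_like(S)
        if self.spec.model == "berry":
            ro = self.readout_indices
            if ro is not None:
                res = [i for i in range(self.n_total) if i not in ro]
                F = float(S[res, 1].sum())
                M = float(S[res, 0].sum())
                rim7, rim8 = readout_inputs(
                    F, M, self.readout_w7, self.readout_w8,
                    m7=S[ro[0], 0], m8=S[ro[1], 0],
                    settings=self.spec.readout,
                    f_values=S[:, 1] * np.isin(np.arange(self.n_total), res),
                    m_values=S[:, 0] * np.isin(np.arange(self.n_total), res))
            for i in range(self.n_total):
                if ro is not None and i == ro[0]:
                    rim = rim7
                elif ro is not None and i == ro[1]:
                    rim = rim8
                else:
                    rim = berry_coupling_input(S[:, 0], self.weights,
                                               self.params.rim_base + eps[i], i)
                out[i] = berry_derivatives(S[i], self.params, rim)
        else:
            D = wu_diffusion(S, self.weights)
            for i in range(self.n_total):
                out[i] = wu_derivatives(S[i], self.params, eps[i], D[i])
        return out.ravel()

    # -- clamping protocol ----------------------------------------------
    def simulate_clamped(self, rows: np.ndarray, schedule: ClampSchedule,
                         normalisation: NormalisationSettings | None = None,
                         ) -> Trajectory:
        """Present ``rows`` (samples x attributes, already statically
        scaled) one after another, each clamped for
        ``schedule.steps_per_sample`` steps, and record the trajectory.

        The oscillator state carries over between samples unless the spec
        requests a per-sample reset.  Hebbian weight updates and dynamic
        normalisation are re-evaluated once per recorded point.
        """
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.size and rows.shape[1] != self.spec.n_attributes:
            raise ValueError(
                f"rows have {rows.shape[1]} attributes but input_map expects "
                f"{self.spec.n_attributes}")
        if self.spec.normalisation == "dynamic":
            if normalisation is None:
                raise ValueError(
                    "dynamic normalisation requested but no settings given")
            if normalisation.n_attributes != self.spec.n_attributes:
                raise ValueError("normalisation settings / input_map mismatch")

        n = self.n_total
        n_samples = rows.shape[0]
        n_rec = schedule.records_per_sample
        total_rec = 1 + n_samples * n_rec
        states = np.empty((total_rec, n, 4))
        states[0] = self.state
        boundaries = [(1 + s * n_rec, 1 + (s + 1) * n_rec)
                      for s in range(n_samples)]

        # route attributes to oscillators
        has_input = np.zeros(n, dtype=np.bool_)
        osc_of_attr = np.asarray(self.spec.input_map, dtype=np.int64)
        has_input[osc_of_attr] = True
        mu_eps_osc = np.ones(n)
        f_eps_osc = np.ones(n)
        th_eps_osc = np.zeros(n)
        dyn = self.spec.normalisation == "dynamic"
        if dyn:
            mu_eps_osc[osc_of_attr] = normalisation.mu_eps
            f_eps_osc[osc_of_attr] = normalisation.f_eps
            th_eps_osc[osc_of_attr] = normalisation.theta_eps

        integ = _kernels.RK4 if self.spec.integrator == "rk4" else _kernels.FEHLBERG
        ro = self.readout_indices
        ro7, ro8 = ro if ro is not None else (-1, -1)
        rd = self.spec.readout
        learn = self.spec.learning is not None
        hb = self.spec.learning or HebbianSettings()

        for s in range(n_samples):
            if self.spec.reset_per_sample:
                self.reset_state()
            eps_osc = np.zeros(n)
            eps_osc[osc_of_attr] = rows[s]
            if np.any(eps_osc < 0):
                raise ValueError(
                    f"negative input in sample {s}; shift attributes first")
            rec = states[boundaries[s][0]:boundaries[s][1]]
            if self.spec.model == "berry":
                pr = self.params
                status = _kernels.berry_window(
                    self.state, self.weights, eps_osc, has_input,
                    pr.rim_base, schedule.step_size, n_rec,
                    schedule.record_stride, integ,
                    pr.gamma, pr.beta, pr.KR ** pr.n, pr.KS ** pr.l, pr.KG,
                    pr.Kdeg, pr.kg, pr.kdeg, pr.ka, pr.l, pr.n,
                    pr.mu_f, pr.f_p, pr.f_g, pr.xi_p, pr.xi_g,
                    learn, hb.alpha, hb.theta,
                    ro7, ro8, self.readout_w7, self.readout_w8,
                    rd.phi7 if rd else 0.0, rd.phi8 if rd else 0.0,
                    (rd.sum_mode == "per_unit") if rd else False,
                    rd.alpha if rd else 0.0, rd.theta if rd else 0.0,
                    dyn, mu_eps_osc, f_eps_osc, th_eps_osc,
                    rec)
            else:
                pr = self.params
                status = _kernels.wu_window(
                    self.state, self.weights, eps_osc, schedule.step_size,
                    n_rec, schedule.record_stride, integ,
                    pr.a, pr.b, pr.c, pr.d, pr.e, pr.f_param, pr.k,
                    pr.mu_x, pr.mu_y, pr.mu_z, pr.mu_w,
                    pr.xi_x, pr.xi_y, pr.xi_z, pr.xi_w,
                    pr.omega, pr.rho_gain, rec)
            if status >= 0:
                step = (s * schedule.steps_per_sample
                        + (status + 1) * schedule.record_stride)
                raise NumericalBlowUp(
                    f"numerical blow-up while clamping sample {s} "
                    f"(global step {step})",
                    t=step * schedule.step_size, step=step, sample_index=s)

        stride_dt = schedule.step_size * schedule.record_stride
        times = np.arange(total_rec, dtype=float) * stride_dt
        return Trajectory(
            times=times,
            states=states.reshape(total_rec, n * 4),
            sample_boundaries=boundaries,
            channel_labels=self.channel_labels,
        )
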