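"""RCC-controlled oscillator models: the Berry bienzymatic model and the
Wu 4-D hyperchaotic extension of the Lorenz system.

Rate Control of Chaos (RCC) multiplies selected reaction-rate terms by
exponential control functions of saturating state quotients

    q(v) = v / (v + mu),        sigma(q) = f_scale * exp(xi * q),

which leaves equilibria untouched while reshaping local rates, so that a
system whose parameters sit in a chaotic domain settles into stable periodic
orbits (Berry) or steady states (Wu).  The controlled system remains weakly
chaotic in the sense that external perturbation moves it to a different --
but reproducible -- orbit, which is the mechanism Criticality Analysis uses
to represent data.

The Berry model describes two enzymes shuttling material between an
extracellular matrix ``m`` and soluble filaments ``f``: proteinase ``p``
degrades matrix into filaments, transglutaminase ``g`` reassembles filaments
into matrix, matrix is produced at rate ``rim`` (the bifurcation parameter,
through which both network coupling and external data enter), and the enzyme
pools follow Hill kinetics in ``f`` with RCC control on their production
terms.

The Wu model is a four-variable Lorenz extension with an extra feedback
loop ``w``; under RCC it converges to input-dependent steady states, with
external data entering through ``rho = rho_gain * eps`` in the ``w``
equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "BerryParams",
    "WuParams",
    "berry_derivatives",
    "berry_sigma",
    "rcc_quotient",
    "wu_control_terms",
    "wu_derivatives",
]


def rcc_quotient(value, mu):
    """Saturating RCC quotient ``value / (value + mu)``, in [0, 1).

    ``value`` is a nonnegative concentration-like quantity; negative values
    are a domain error here.  (Model code clamps small negative transients to
    zero *before* forming the quotient; see the derivative functions.)
    """
    value = np.asarray(value, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(value < 0):
        raise ValueError("rcc_quotient requires a nonnegative value")
    if np.any(mu <= 0):
        raise ValueError("rcc_quotient requires mu > 0")
    out = value / (value + mu)
    return float(out) if out.ndim == 0 else out


def berry_sigma(q, f_scale, xi):
    """RCC control function ``f_scale * exp(xi * q)``; strictly positive."""
    q = np.asarray(q, dtype=float)
    out = f_scale * np.exp(xi * q)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BerryParams:
    """Kinetic and RCC control constants of the Berry bienzymatic model.

    Defaults are the published operating point at which the uncontrolled
    model is chaotic for a range of the bifurcation parameter ``rim`` and
    the RCC-controlled model holds stable orbits.  ``ka`` is stored as the
    printed numeric value 0.0455 rather than derived from ``kdeg``/``Kdeg``.
    Hill exponents ``l`` and ``n`` are integers >= 1.
    """

    gamma: float = 0.026
    beta: float = 0.00075
    KR: float = 4.5
    KS: float = 1.0
    KG: float = 0.1
    Kdeg: float = 1.1
    kg: float = 0.05
    kdeg: float = 0.05
    ka: float = 0.0455
    l: int = 4
    n: int = 4
    rim_base: float = 0.0
    mu_f: float = 2.0
    f_p: float = 1.0
    f_g: float = 1.0
    xi_p: float = -3.0
    xi_g: float = -3.0

    def __post_init__(self) -> None:
        for name in ("gamma", "beta", "KR", "KS", "KG", "Kdeg",
                     "kg", "kdeg", "ka", "mu_f", "f_p", "f_g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"BerryParams.{name} must be positive")
        if self.l < 1 or self.n < 1:
            raise ValueError("Hill exponents must be >= 1")

    def without_control(self) -> "BerryParams":
        """Copy with the control exponents zeroed (sigma_p = sigma_g = 1)."""
        return replace(self, xi_p=0.0, xi_g=0.0)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "BerryParams":
        return cls(**d)


@dataclass(frozen=True)
class WuParams:
    """System and RCC constants of the Wu 4-D hyperchaotic Lorenz extension.

    ``r`` is the hyperchaos bifurcation parameter of the source system; it
    does not appear in the controlled vector field as used here and is kept
    as an inert configuration field.  External input enters as
    ``rho = rho_gain * eps``.
    """

    a: float = 56.0
    b: float = 16.0
    c: float = 49.0
    d: float = 9.0
    e: float = 30.0
    f_param: float = 40.0
    k: float = 8.0
    r: float = -600.0
    mu_x: float = 1000.0
    mu_y: float = 100.0
    mu_z: float = 100.0
    mu_w: float = 3000.0
    xi_x: float = -1.5
    xi_y: float = -1.0
    xi_z: float = -1.0
    xi_w: float = -1.5
    omega: float = 0.055
    rho_gain: float = -100.0

    def __post_init__(self) -> None:
        for name in ("mu_x", "mu_y", "mu_z", "mu_w"):
            if not getattr(self, name) > 0:
                raise ValueError(f"WuParams.{name} must be positive")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "WuParams":
        return cls(**d)


def berry_derivatives(state: Sequence[float], params: BerryParams,
                      rim_input: float) -> np.ndarray:
    """Time derivatives (dm, df, dp, dg) of one Berry oscillator.

    ``rim_input`` is the full matrix-production drive for this oscillator:
    coupling sum plus (possibly dynamically normalised) external input.
    The filament quotient uses ``max(f, 0)`` so a small negative transient
    cannot produce an out-of-range quotient; the mass-action terms use the
    raw state.
    """
    m, f, p, g = (float(v) for v in state)
    pr = params
    fq = f if f > 0.0 else 0.0
    qf = fq / (fq + pr.mu_f)
    sigma_p = pr.f_p * math.exp(pr.xi_p * qf)
    sigma_g = pr.f_g * math.exp(pr.xi_g * qf)

    exchange = pr.kg * f * g / (pr.KG + f)       # filament -> matrix (via g)
    degrade = m * p / (1.0 + m)                  # matrix -> filament (via p)
    fn = f ** pr.n
    fl = f ** pr.l

    dm = exchange - degrade + rim_input
    df = -exchange + degrade - f * p / (1.0 + f)
    dp = sigma_p * pr.gamma * fn / (pr.KR ** pr.n + fn) - pr.ka * p * p
    dg = sigma_g * pr.beta * fl / (pr.KS ** pr.l + fl) \
        - pr.kdeg * g * p / (pr.Kdeg + g)
    out = np.array([dm, df, dp, dg])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite Berry derivative")
    return out


def wu_control_terms(state: Sequence[float], params: WuParams):
    """RCC control factors (sigma_x, sigma_y, sigma_z, sigma_w) of the Wu model.

    Quotients are formed from the state clamped at zero (the RCC quotient is
    defined for nonnegative arguments).
    """
    x, y, z, w = (max(float(v), 0.0) for v in state)
    pr = params
    qx = x / (x + pr.mu_x)
    qy = y / (y + pr.mu_y)
    qz = z / (z + pr.mu_z)
    sigma_x = math.exp(pr.xi_x * qx * qz)
    sigma_y = math.exp(pr.xi_y * qx * qz)
    sigma_z = math.exp(pr.xi_z * qx * qy)
    sigma_w = math.exp(pr.xi_w * qy * qz) + pr.omega
    return sigma_x, sigma_y, sigma_z, sigma_w


def wu_derivatives(state: Sequence[float], params: WuParams,
                   eps_input: float = 0.0,
                   diffusion: Sequence[float] = (0.0, 0.0, 0.0, 0.0)) -> np.ndarray:
    """Time derivatives (dx, dy, dz, dw) of one Wu oscillator.

    ``eps_input`` is the clamped data value for this oscillator (entering as
    ``rho = rho_gain * eps``); ``diffusion`` the (Dx, Dy, Dz, Dw) coupling
    contribution from the network.
    """
    x, y, z, w = (float(v) for v in state)
    pr = params
    sx, sy, sz, sw = wu_control_terms(state, params)
    rho = pr.rho_gain * float(eps_input)
    Dx, Dy, Dz, Dw = (float(v) for v in diffusion)
    dx = pr.a * (y - x) + pr.e * sx * y * z + pr.k * w + Dx
    dy = pr.c * x - pr.d * y - sy * x * z + Dy
    dz = sz * x * y - pr.b * z + Dz
    dw = rho * y + pr.f_param * sw * y * z + Dw
    out = np.array([dx, dy, dz, dw])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite Wu derivative")
    return out
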