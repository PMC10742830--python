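"""Static scaling and RCC-based dynamic normalisation of data attributes.

Attributes are first multiplied by fixed per-attribute scalars chosen so the
resulting perturbations keep the network inside its controlled (critical)
regime.  Optionally, a *dynamic* normalisation is applied on top: the
effective input is attenuated through an RCC control function that couples
the input's own saturation quotient with the receiving oscillator's filament
quotient,

    q_eps = eps / (eps + mu_eps),
    effective = f_eps * exp(theta_eps * q_eps * q_i) * eps,

where ``mu_eps`` is the (predetermined, constant) maximum of the attribute
over the dataset.  Because ``q_i`` follows the oscillator's own orbit, a
constant attribute value becomes a dynamic drive, and attributes of very
different magnitudes are compressed onto comparable effective ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NormalisationSettings", "dynamic_normalise", "static_scale"]


@dataclass(frozen=True)
class NormalisationSettings:
    """Per-attribute constants of the dynamic normalisation.

    ``mu_eps`` is frozen at dataset-load time (the attribute maximum after
    static scaling) so representations are reproducible across runs.
    """

    mu_eps: np.ndarray
    f_eps: np.ndarray
    theta_eps: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_eps", np.atleast_1d(np.asarray(self.mu_eps, float)))
        object.__setattr__(self, "f_eps", np.broadcast_to(
            np.asarray(self.f_eps, float), self.mu_eps.shape).copy())
        object.__setattr__(self, "theta_eps", np.broadcast_to(
            np.asarray(self.theta_eps, float), self.mu_eps.shape).copy())
        if np.any(self.mu_eps <= 0):
            raise ValueError("mu_eps must be positive for every attribute")

    @classmethod
    def from_data(cls, scaled: np.ndarray, f_eps: float | np.ndarray = 1.0,
                  theta_eps: float | np.ndarray = -3.0) -> "NormalisationSettings":
        """Freeze ``mu_eps`` as the per-attribute maximum of ``scaled``."""
        scaled = np.atleast_2d(np.asarray(scaled, float))
        mu = scaled.max(axis=0)
        if np.any(mu <= 0):
            raise ValueError(
                "every attribute needs a positive maximum for normalisation")
        return cls(mu_eps=mu, f_eps=f_eps, theta_eps=theta_eps)

    @property
    def n_attributes(self) -> int:
        return self.mu_eps.shape[0]


def static_scale(row, scalars):
    """Elementwise product of an attribute row (or matrix) and its scalars."""
    row = np.asarray(row, dtype=float)
    scalars = np.asarray(scalars, dtype=float)
    if row.shape[-1] != scalars.shape[-1] and scalars.ndim > 0 and scalars.size > 1:
        raise ValueError(
            f"length mismatch: row has {row.shape[-1]} attributes, "
            f"{scalars.size} scalars given")
    return row * scalars


def dynamic_normalise(eps, q_i, *, mu_eps, f_eps=1.0, theta_eps=-3.0):
    """Effective input ``sigma_eps * eps`` for the current oscillator state.

    ``eps`` is the (statically scaled) attribute value, ``q_i`` the filament
    quotient of the receiving oscillator.  With ``theta_eps < 0`` the
    effective input never exceeds ``f_eps * eps`` and shrinks as the
    oscillator's filament pool fills.  Recomputed every control step because
    ``q_i`` evolves.
    """
    eps = np.asarray(eps, dtype=float)
    mu_eps = np.asarray(mu_eps, dtype=float)
    if np.any(mu_eps <= 0):
        raise ValueError("mu_eps must be positive")
    if np.any(eps < 0):
        raise ValueError("dynamic normalisation requires nonnegative eps")
    q_eps = eps / (eps + mu_eps)
    out = f_eps * np.exp(np.asarray(theta_eps, float) * q_eps * np.asarray(q_i, float)) * eps
    return float(out) if out.ndim == 0 else out


def shift_nonnegative(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shift each attribute by its minimum where negative values occur.

    The RCC quotient presumes nonnegative input, so attributes with negative
    entries are translated to start at zero.  Returns the shifted matrix and
    the per-attribute shifts that were subtracted (zero for attributes that
    were already nonnegative).
    """
    values = np.atleast_2d(np.asarray(values, float))
    mins = values.min(axis=0)
    shifts = np.where(mins < 0, mins, 0.0)
    return values - shifts, shifts
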