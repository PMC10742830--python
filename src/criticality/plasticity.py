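"""Dynamic Hebbian weight adaptation and deterministic-reservoir readouts.

The Hebbian rule used here is *dynamic*: the weight of a connection is a
closed-form function of the two oscillators' instantaneous filament
quotients, not an increment.  A connection from source ``i`` to target ``j``
is strengthened when the target's filament fraction exceeds the source's and
weakened (made negative) otherwise:

    w_ij = theta * exp(alpha * qf_i * qf_j) * sgn(qf_j - qf_i)

with ``sgn(0) = 0``, which makes the rule antisymmetric: ``w_ij = -w_ji``
at every instant.  Because the quotients evolve with the oscillators, the
weights track the changing behaviour of the network.

Readout units are ordinary Berry oscillators driven not by the coupling sum
but by the reservoir's summed activity: unit 7 receives the total filament
signal ``F`` through its learned weights (scaled by ``phi7``) plus the
matrix value of unit 8, and unit 8 symmetrically receives the total matrix
signal ``M`` plus ``m7``.  Each readout thus exhibits a dimensionally
reduced but characteristic version of the whole reservoir's response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HebbianSettings",
    "ReadoutSettings",
    "apply_learning",
    "hebbian_weight",
    "readout_inputs",
]


@dataclass(frozen=True)
class HebbianSettings:
    """Learning-rule constants: gain ``theta`` and exponent ``alpha``."""

    alpha: float = -1.0
    theta: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.theta)):
            raise ValueError("learning parameters must be finite")


@dataclass(frozen=True)
class ReadoutSettings:
    """Configuration of the two readout units of a 6+2 reservoir.

    ``phi7``/``phi8`` scale the summed-weight drive; the readout connections
    are maintained by the Hebbian rule with their own ``alpha``/``theta``.
    ``sum_mode`` selects how the learned weights multiply the reservoir
    signal: ``"total"`` applies the summed weight to the total F (or M) as
    printed; ``"per_unit"`` weights each unit's own f (or m) before summing.
    """

    phi7: float = 0.00015
    phi8: float = 0.00015
    alpha: float = -3.0
    theta: float = 3.0
    n_reservoir: int = 6
    sum_mode: str = "total"

    def __post_init__(self) -> None:
        if self.sum_mode not in ("total", "per_unit"):
            raise ValueError("sum_mode must be 'total' or 'per_unit'")
        if self.n_reservoir < 1:
            raise ValueError("n_reservoir must be >= 1")


def hebbian_weight(qf_i, qf_j, settings: HebbianSettings = HebbianSettings()):
    """Instantaneous Hebbian weight of the connection i -> j.

    Accepts scalars or arrays of quotients in [0, 1).
    """
    qi = np.asarray(qf_i, dtype=float)
    qj = np.asarray(qf_j, dtype=float)
    # the quotient product is grouped so w(i->j) == -w(j->i) bit-exactly
    out = settings.theta * np.exp(settings.alpha * (qi * qj)) * np.sign(qj - qi)
    return float(out) if out.ndim == 0 else out


def apply_learning(weights: np.ndarray, quotients: np.ndarray,
                   settings: HebbianSettings = HebbianSettings(),
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Return the weight matrix with every learned connection re-assigned.

    ``weights[i, j]`` feeds oscillator ``j`` from source ``i``.  Learned
    connections (all off-diagonal entries, or those selected by ``mask``)
    are *set* to the instantaneous Hebbian weight of the current quotients;
    non-learned entries and the diagonal are left untouched.
    """
    q = np.asarray(quotients, dtype=float)
    n = q.shape[0]
    W = np.array(weights, dtype=float, copy=True)
    if W.shape != (n, n):
        raise ValueError("weights must be (n, n) for n quotients")
    learned = np.ones((n, n), dtype=bool) if mask is None else np.asarray(mask, bool)
    learned = learned & ~np.eye(n, dtype=bool)
    H = hebbian_weight(q[:, None], q[None, :], settings)
    W[learned] = H[learned]
    return W


def readout_inputs(F_total: float, M_total: float,
                   weights7: np.ndarray, weights8: np.ndarray,
                   m7: float, m8: float,
                   settings: ReadoutSettings = ReadoutSettings(),
                   f_values: np.ndarray | None = None,
                   m_values: np.ndarray | None = None) -> tuple[float, float]:
    """Drive terms (rim7, rim8) of the two readout units.

    In ``"total"`` mode the summed learned weight multiplies the reservoir
    total; in ``"per_unit"`` mode the per-unit f and m vectors
    (``f_values``/``m_values``) are weighted individually.  The partner
    readout's matrix value (``m8`` for unit 7 and vice versa) enters the
    drive through the same input scalar: with the cross term taken bare,
    the two readouts obey d(m7 + m8)/dt >= m7 + m8 once the reservoir is
    active and diverge exponentially, so the scalar must scope the whole
    drive for the pair to remain a bounded oscillator.
    """
    w7 = np.asarray(weights7, dtype=float)
    w8 = np.asarray(weights8, dtype=float)
    if settings.sum_mode == "per_unit":
        if f_values is None or m_values is None:
            raise ValueError("per_unit mode requires f_values and m_values")
        rim7 = settings.phi7 * (float(np.dot(w7, f_values)) + float(m8))
        rim8 = settings.phi8 * (float(np.dot(w8, m_values)) + float(m7))
    else:
        rim7 = settings.phi7 * (float(w7.sum()) * float(F_total) + float(m8))
        rim8 = settings.phi8 * (float(w8.sum()) * float(M_total) + float(m7))
    return rim7, rim8
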