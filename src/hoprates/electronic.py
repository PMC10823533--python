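"""Electronic amplitudes / Bloch-vector propagation in the adiabatic basis.

The two-state wave function |ψ⟩ = c₊|+⟩ + c₋|−⟩ evolves along a nuclear
trajectory according to the adiabatic-representation TDSE

    iℏ ċ₊ = V₊ c₊ − iℏ Q̇ d c₋
    iℏ ċ₋ = V₋ c₋ + iℏ Q̇ d c₊

with d the (antisymmetric) derivative coupling.  In Bloch coordinates

    S_x = 2 Re(c₊* c₋),  S_y = 2 Im(c₊* c₋),  S_z = |c₊|² − |c₋|²

this is rigid precession of S about the field ω = (0, 2 Q̇ d, (V₊−V₋)/ℏ):
the electronic motion is literally a classical spin in a magnetic field.
The package-wide phase convention above is fixed once here; the engines
module relies on it (in particular S_x enters the fewest-switches flux).

Propagation uses the exact exponential of the traceless 2×2 generator over
each (sub)step, which conserves the norm to round-off by construction.  The
overall dynamical phase exp(−i V̄ dt/ℏ) is dropped: it is unobservable in
every quantity formed from populations or the coherence c₊*c₋.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElectronicState",
    "bloch_from_amplitudes",
    "amplitudes_from_bloch",
    "propagate_electronic",
]


@dataclass
class ElectronicState:
    """Complex adiabatic amplitudes (c₊, c₋); scalars or parallel arrays."""

    c_plus: complex | np.ndarray
    c_minus: complex | np.ndarray

    def norm(self):
        return np.abs(self.c_plus) ** 2 + np.abs(self.c_minus) ** 2

    @property
    def bloch(self):
        return bloch_from_amplitudes(self.c_plus, self.c_minus)

    @property
    def s_z(self):
        return np.abs(self.c_plus) ** 2 - np.abs(self.c_minus) ** 2


def bloch_from_amplitudes(c_plus, c_minus):
    """Bloch vector (S_x, S_y, S_z) of normalized amplitudes."""
    coh = np.conj(c_plus) * c_minus
    s_z = np.abs(c_plus) ** 2 - np.abs(c_minus) ** 2
    return 2.0 * coh.real, 2.0 * coh.imag, s_z


def amplitudes_from_bloch(s_x, s_y, s_z, phase=0.0):
    """Amplitudes realizing a unit Bloch vector, up to a global phase.

    The inverse of :func:`bloch_from_amplitudes` with the free overall
    phase applied to c₊.  Inputs must satisfy |S| = 1.
    """
    s_x = np.asarray(s_x, dtype=float)
    s_y = np.asarray(s_y, dtype=float)
    s_z = np.asarray(s_z, dtype=float)
    half_plus = np.sqrt(np.clip(0.5 * (1.0 + s_z), 0.0, 1.0))
    half_minus = np.sqrt(np.clip(0.5 * (1.0 - s_z), 0.0, 1.0))
    # relative phase of c₋ w.r.t. c₊ from the coherence S_x + iS_y = 2 c₊* c₋
    rel = np.angle(s_x + 1j * s_y)
    global_phase = np.exp(1j * np.asarray(phase))
    c_plus = half_plus * global_phase
    c_minus = half_minus * np.exp(1j * rel) * global_phase
    return c_plus, c_minus


def propagate_electronic(state: ElectronicState, gap, d, qdot, dt, hbar=1.0,
                         substeps=1) -> ElectronicState:
    """Advance the amplitudes by ``dt`` for a piecewise-constant field.

    Parameters
    ----------
    gap : adiabatic gap V₊ − V₋ at the (mid-)step configuration.
    d : nonadiabatic coupling there.
    qdot : nuclear velocity; only the product w = Q̇ d enters.
    substeps : number of equal sub-intervals; with the exact propagator this
        only matters when the caller supplies updated fields per substep,
        so the default is 1.

    The propagator is U = exp(−i θ n·σ) with θ = (dt/2)√((gap/ℏ)² + (2Q̇d)²)
    and axis n ∝ (0, 2Q̇d, gap/ℏ); the norm is conserved exactly.
    """
    c_plus, c_minus = state.c_plus, state.c_minus
    h = dt / substeps
    for _ in range(substeps):
        c_plus, c_minus = _step_amplitudes(c_plus, c_minus, gap, d, qdot, h, hbar)
    return ElectronicState(c_plus, c_minus)


def _step_amplitudes(c_plus, c_minus, gap, d, qdot, dt, hbar=1.0):
    """One exact-exponential step; array-broadcasting core used by engines."""
    w = np.asarray(qdot * d, dtype=float)
    bz = np.asarray(gap, dtype=float) / hbar
    mag = np.hypot(bz, 2.0 * w)
    theta = 0.5 * dt * mag
    cos_t = np.cos(theta)
    sinc = np.where(mag > 0.0, np.sin(theta) / np.where(mag > 0.0, mag, 1.0), 0.5 * dt)
    # U = cosθ·I − i sinθ (n_z σ_z + n_y σ_y); σ_y mixes with real coefficients
    az = sinc * bz      # sinθ · n_z
    ay = sinc * 2.0 * w  # sinθ · n_y
    new_plus = (cos_t - 1j * az) * c_plus - ay * c_minus
    new_minus = (cos_t + 1j * az) * c_minus + ay * c_plus
    return new_plus, new_minus
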