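"""Two-state Brownian-oscillator spin-boson model.

A single mass-weighted solvent polarization coordinate ``Q`` moves on two
diabatic Marcus parabolas of equal curvature Ω², separated by the
reorganization energy Λ and offset by the driving force ε, with a constant
diabatic coupling Δ.  The Ohmic environment (spectral density J(ω) = γω) is
folded into Langevin friction on ``Q`` by the engines module.

Reduced units are used throughout: β = ℏ = 1 and the nuclear mass is 1, so
energies are in units of k_BT, times in units of βℏ, and all model inputs
are the dimensionless groups βΛ, βε, βΔ, βℏΩ, βℏγ.

Conventions fixed package-wide:

* diabatic energy gap ``D(Q) = V_r(Q) − V_p(Q) = a (Q − Q‡)`` with the
  constant slope ``a = Ω² Q₀ = Ω √(2Λ) > 0``;
* the nonadiabatic coupling ``d(Q)`` is positive at the crossing,
  ``d(Q‡) = a / (4Δ)``;
* the active-state label is ``+1`` for the upper adiabat and ``−1`` for the
  lower adiabat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "diabatic_potentials",
    "crossing_point",
    "adiabatic_surfaces",
    "nonadiabatic_coupling",
    "adiabatic_force",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the two-state Brownian-oscillator model.

    Parameters
    ----------
    lam : float
        Reorganization energy Λ (units of k_BT).  Must be positive.
    eps : float
        Reaction driving force ε (k_BT).  ``eps == lam`` is the
        activationless point; ``eps > lam`` is the Marcus inverted regime.
    delta : float
        Constant diabatic coupling Δ (k_BT).  Must be positive.
    omega : float
        Characteristic frequency Ω of the parabolas (1/(βℏ)).
    gamma : float
        Langevin friction coefficient γ (1/(βℏ)).  ``gamma == 0`` gives
        microcanonical dynamics.
    beta, hbar : float
        Inverse temperature and ℏ; both 1 in the reduced-unit convention
        and exposed only so that formulas can be written dimensionally.
    """

    lam: float
    eps: float
    delta: float
    omega: float
    gamma: float
    beta: float = 1.0
    hbar: float = 1.0
    mass: float = field(default=1.0, repr=False)

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"reorganization energy lam must be > 0, got {self.lam}")
        if not self.delta > 0:
            raise ValueError(f"diabatic coupling delta must be > 0, got {self.delta}")
        if not self.omega > 0:
            raise ValueError(f"frequency omega must be > 0, got {self.omega}")
        if self.gamma < 0:
            raise ValueError(f"friction gamma must be >= 0, got {self.gamma}")
        if not self.beta > 0 or not self.hbar > 0 or not self.mass > 0:
            raise ValueError("beta, hbar and mass must all be > 0")

    @property
    def q_shift(self) -> float:
        """Separation Q₀ = √(2Λ)/Ω between the two diabatic minima."""
        return np.sqrt(2.0 * self.lam) / self.omega

    @property
    def diabatic_slope(self) -> float:
        """Constant slope a = Ω²Q₀ = Ω√(2Λ) of the diabatic gap V_r − V_p."""
        return self.omega * np.sqrt(2.0 * self.lam)


def diabatic_potentials(Q, params: ModelParams):
    """Marcus parabolas and their gradients.

    ``V_r(Q) = ½Ω²Q²`` (reactant) and ``V_p(Q) = ½Ω²(Q − Q₀)² − ε``
    (product), with Q₀ = √(2Λ)/Ω so the minima differ in energy by ε and
    the vertical excitation from either minimum to the other diabat is Λ.

    Returns
    -------
    (V_r, V_p, dV_r, dV_p) : arrays broadcast against ``Q``
    """
    Q = np.asarray(Q, dtype=float)
    w2 = params.omega**2
    q0 = params.q_shift
    v_r = 0.5 * w2 * Q**2
    v_p = 0.5 * w2 * (Q - q0) ** 2 - params.eps
    return v_r, v_p, w2 * Q, w2 * (Q - q0)


def crossing_point(params: ModelParams) -> float:
    """Position Q‡ of the diabatic crossing, V_r(Q‡) = V_p(Q‡).

    Closed form ``Q‡ = (Λ − ε) / (Ω √(2Λ))``; the symmetric model ε = 0 has
    the crossing half way between the minima, and ε = Λ (activationless)
    puts it at the reactant minimum.
    """
    return (params.lam - params.eps) / params.diabatic_slope


def diabatic_gap(Q, params: ModelParams):
    """Diabatic energy gap D(Q) = V_r(Q) − V_p(Q) = a (Q − Q‡)."""
    Q = np.asarray(Q, dtype=float)
    return params.diabatic_slope * Q - (params.lam - params.eps)


def adiabatic_surfaces(Q, params: ModelParams):
    """Adiabatic potentials V_∓ and the adiabatic gap.

    ``V_± = ½(V_r + V_p) ± ½√(D² + 4Δ²)`` with D = V_r − V_p.  The gap
    V₊ − V₋ = √(D² + 4Δ²) is bounded below by 2Δ, with equality exactly at
    the crossing point.

    Returns
    -------
    (V_minus, V_plus, gap)
    """
    v_r, v_p, _, _ = diabatic_potentials(Q, params)
    mean = 0.5 * (v_r + v_p)
    gap = np.hypot(v_r - v_p, 2.0 * params.delta)
    return mean - 0.5 * gap, mean + 0.5 * gap, gap


def nonadiabatic_coupling(Q, params: ModelParams):
    """First-derivative coupling d(Q) = ⟨+|∂/∂Q|−⟩.

    For constant Δ, ``d(Q) = Δ D′(Q) / (D(Q)² + 4Δ²)``.  Because the
    diabatic-gap slope D′ = a is constant here, d(Q) is a Lorentzian
    centred at Q‡ with height a/(4Δ) and unit area π/2 (the total mixing
    angle rotates by π/2 across the crossing).  Sign convention:
    d(Q‡) > 0.
    """
    d_gap = diabatic_gap(Q, params)
    return params.delta * params.diabatic_slope / (d_gap**2 + 4.0 * params.delta**2)


def adiabatic_force(Q, n, params: ModelParams):
    """Force −dV_n/dQ on the active adiabatic surface.

    ``n`` is +1 for the upper adiabat and −1 for the lower one (arrays
    broadcast).  Evaluated analytically via Hellmann–Feynman on the 2×2
    diabatic matrix:

        dV_±/dQ = ½(V_r′ + V_p′) ± D D′ / (2 √(D² + 4Δ²))
    """
    Q = np.asarray(Q, dtype=float)
    n = np.asarray(n, dtype=float)
    w2 = params.omega**2
    a = params.diabatic_slope
    d_gap = diabatic_gap(Q, params)
    root = np.hypot(d_gap, 2.0 * params.delta)
    mean_grad = w2 * (Q - 0.5 * params.q_shift)
    return -(mean_grad + n * 0.5 * a * d_gap / root)
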