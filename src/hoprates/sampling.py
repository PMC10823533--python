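"""Initial-condition sampling.

Trajectories start from the classical thermal ensemble restricted to a
region of state space: positions and active states are drawn jointly from
the Boltzmann weight exp(−βV_n(Q)) over the two adiabatic surfaces, momenta
from the Maxwell–Boltzmann distribution, and the sample is kept only if
(Q, n) lies in the requested region (reactant/product in the adiabatic
projector sense used by the observables module).  Wigner or other quantum
thermal distributions are deliberately not used — the dynamics treat the
nucleus classically and the benchmark (Marcus theory) assumes the same.

Electronic initialization differs between the engines:

* FSSH starts in the pure state of the active surface (Bloch vector at a
  pole);
* MASH draws S uniformly-in-azimuth from the hemisphere of the active
  surface with probability density ∝ |S_z| (so |S_z| = √u, u ~ U(0,1]),
  which is what replaces the stochasticity of the hops.

The overall wave-function phase is unobservable and is randomized uniformly
for MASH; FSSH keeps phase 0 (the conventional pure-state start).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .electronic import ElectronicState, amplitudes_from_bloch
from .model import ModelParams, adiabatic_surfaces, crossing_point, diabatic_potentials

__all__ = ["InitialConditionSpec", "sample_nuclear_and_state", "sample_electronic"]

Region = Literal["reactant", "product", "unconstrained"]

#: proposals per rejection-sampling round, per remaining sample
_BATCH_FACTOR = 4
_MIN_ACCEPT = 1e-6


@dataclass(frozen=True)
class InitialConditionSpec:
    """Which region to initialize in, for which engine, and the seed."""

    region: Region = "reactant"
    method: Literal["MASH", "FSSH"] = "MASH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region not in ("reactant", "product", "unconstrained"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.method not in ("MASH", "FSSH"):
            raise ValueError(f"unknown method {self.method!r}")


def _in_region(Q, n, region: Region, params: ModelParams):
    """Region membership in the adiabatic reactant/product partition.

    Products are the lower adiabat right of the diabatic crossing together
    with the upper adiabat left of it; reactants are the complement.  The
    boundary Q = Q‡ belongs to the reactant (measure-zero convention).
    """
    if region == "unconstrained":
        return np.ones(np.shape(Q), dtype=bool)
    qd = crossing_point(params)
    product = ((n < 0) & (Q > qd)) | ((n > 0) & (Q < qd))
    return product if region == "product" else ~product


def sample_nuclear_and_state(params: ModelParams, spec: InitialConditionSpec,
                             rng: np.random.Generator, size: int = 1):
    """Draw (Q, P, n) from the thermal ensemble restricted to a region.

    Positions and active states are sampled jointly ∝ exp(−βV_n(Q)) by
    rejection from diabatic-well Gaussians with exact acceptance weights
    (so no burn-in or correlation issues arise).  For the reactant
    (product) region the proposal is the reactant (product) diabat Gaussian
    and the envelope exp(−βV_n) ≤ exp(−βV_diab) e^{βΔ} follows from
    V₋ ≥ min(V_r, V_p) − Δ; unconstrained sampling proposes from the
    properly weighted two-Gaussian mixture e^{−βV_r} + e^{−βV_p} with a
    uniform surface label.  Momenta are independent Gaussians with
    ⟨P²⟩ = 1/β.

    Returns
    -------
    (Q, P, n) : float arrays and an int8 array of surface labels ±1.
    """
    beta = params.beta
    sigma_q = 1.0 / np.sqrt(beta * params.omega**2)
    qd = crossing_point(params)
    log_two_delta = beta * params.delta + np.log(2.0)

    out_q = np.empty(size)
    out_n = np.empty(size, dtype=np.int8)
    filled = 0
    proposed = accepted = 0
    while filled < size:
        m = _BATCH_FACTOR * max(size - filled, 256)
        if spec.region == "unconstrained":
            # mixture of the two diabat Gaussians, weighted by their
            # Boltzmann integrals (the product well sits ε lower)
            w_p = 1.0 / (1.0 + np.exp(-beta * params.eps))
            from_p = rng.random(m) < w_p
            q = rng.normal(np.where(from_p, params.q_shift, 0.0), sigma_q)
            n = np.where(rng.random(m) < 0.5, 1, -1).astype(np.int8)
        else:
            centre = 0.0 if spec.region == "reactant" else params.q_shift
            q = rng.normal(centre, sigma_q, size=m)
            # each in-region (Q, n) pair has a unique surface at a given Q
            lower_side = q <= qd if spec.region == "reactant" else q > qd
            n = np.where(lower_side, -1, 1).astype(np.int8)
        v_minus, v_plus, _ = adiabatic_surfaces(q, params)
        v_n = np.where(n > 0, v_plus, v_minus)
        v_r, v_p, _, _ = diabatic_potentials(q, params)
        if spec.region == "unconstrained":
            # exact ratio against the mixture envelope e^{βΔ}·2·g(Q)
            log_g = np.logaddexp(-beta * v_r, -beta * v_p)
            log_acc = -beta * v_n - log_g - log_two_delta
        else:
            v_prop = v_r if spec.region == "reactant" else v_p
            log_acc = -beta * (v_n - v_prop + params.delta)
        keep = np.log(rng.random(m)) < log_acc
        keep &= _in_region(q, n, spec.region, params)
        proposed += m
        accepted += int(keep.sum())
        if proposed >= 1e6 and accepted / proposed < _MIN_ACCEPT:
            raise RuntimeError(
                f"initial-condition acceptance rate {accepted/proposed:.2e} "
                f"below {_MIN_ACCEPT}; region {spec.region!r} is likely "
                "misconfigured for these parameters"
            )
        q_keep = q[keep][: size - filled]
        n_keep = n[keep][: size - filled]
        out_q[filled:filled + len(q_keep)] = q_keep
        out_n[filled:filled + len(n_keep)] = n_keep
        filled += len(q_keep)

    out_p = rng.normal(0.0, 1.0 / np.sqrt(beta / params.mass), size=size)
    return out_q, out_p, out_n


def sample_electronic(n, method: str, rng: np.random.Generator) -> ElectronicState:
    """Initial amplitudes consistent with active surface(s) ``n`` (±1 array).

    FSSH: the pure state of the active surface.  MASH: S drawn from the
    hemisphere of the active surface with density ∝ |S_z| and uniform
    azimuth, plus a uniform global phase.
    """
    n = np.atleast_1d(np.asarray(n))
    size = n.shape
    if method == "FSSH":
        c_plus = np.where(n > 0, 1.0 + 0.0j, 0.0j)
        c_minus = np.where(n > 0, 0.0j, 1.0 + 0.0j)
        return ElectronicState(c_plus, c_minus)
    if method != "MASH":
        raise ValueError(f"unknown method {method!r}")
    s_z = np.sign(n) * np.sqrt(rng.random(size))
    azim = rng.uniform(0.0, 2.0 * np.pi, size)
    s_perp = np.sqrt(np.clip(1.0 - s_z**2, 0.0, 1.0))
    phase = rng.uniform(0.0, 2.0 * np.pi, size)
    c_plus, c_minus = amplitudes_from_bloch(
        s_perp * np.cos(azim), s_perp * np.sin(azim), s_z, phase
    )
    return ElectronicState(c_plus, c_minus)
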