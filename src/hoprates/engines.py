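"""Trajectory engines: Langevin nuclei plus MASH or FSSH hopping.

Both engines share everything except the hopping rule:

* nuclear motion on the active adiabat integrates the Langevin equation
  with a BAOAB splitting (velocity Verlet in the γ = 0 limit), noise
  variance fixed by fluctuation–dissipation;
* the electronic amplitudes advance with the exact two-level propagator
  evaluated at the mid-step nuclear configuration and velocity;
* accepted hops rescale the momentum along the nonadiabatic coupling
  direction (in 1-D, along Q) to conserve V_n + P²/2 exactly; attempted
  hops with insufficient kinetic energy are "frustrated" and reflect the
  momentum component along the coupling (the prescription the MASH
  derivation yields, also applied to FSSH by default for comparability —
  set ``frustrated="ignore"`` to leave the momentum untouched instead).

MASH hops deterministically whenever sign(S_z) disagrees with the active
surface, so the wave function and active state can never become
inconsistent (outside frustrated-hop transients).  FSSH hops stochastically
with the fewest-switches probability built from the coherence; negative
raw probabilities mean no hop.

Optional decoherence corrections ("gap_triggered") are applied once per
sampling stride whenever the adiabatic gap exceeds a threshold (default
4 k_BT, i.e. only in the wells, far from the coupling region): MASH
resamples S from the |S_z|-weighted hemisphere of the active surface
(identical to its initial sampling); FSSH collapses the amplitudes to the
pure active state.

Seeding: a master seed spawns one child stream per fixed-size internal
chunk of trajectories, so results are reproducible bitwise and independent
of how the ensemble is batched over memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from .electronic import ElectronicState, _step_amplitudes, bloch_from_amplitudes
from .model import ModelParams, adiabatic_surfaces, crossing_point
from .observables import PopulationCurve, product_projector
from .sampling import InitialConditionSpec, sample_electronic, sample_nuclear_and_state

__all__ = [
    "TrajectoryState",
    "EnsembleSpec",
    "langevin_nuclear_step",
    "mash_update",
    "fssh_update",
    "fssh_hop_probability",
    "apply_decoherence",
    "run_trajectory",
    "run_ensemble",
    "validate_timestep",
]

logger = logging.getLogger(__name__)

try:  # compiled per-trajectory core; the numpy path is a full fallback
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    numba = None
    _HAVE_NUMBA = False

#: trajectories per internal chunk; fixed so that ensemble averages do not
#: depend on available memory or batching order, and small enough that the
#: per-chunk curves give an honest block estimate of statistical errors
CHUNK_SIZE = 2**15


@dataclass
class TrajectoryState:
    """One surface-hopping trajectory's full dynamical state."""

    Q: float
    P: float
    elec: ElectronicState
    n: int
    t: float = 0.0
    hops: int = 0

    def __post_init__(self) -> None:
        if self.n not in (-1, 1):
            raise ValueError("active state n must be +1 (upper) or -1 (lower)")
        if self.hops < 0:
            raise ValueError("hop counter must be nonnegative")


@dataclass(frozen=True)
class EnsembleSpec:
    """Everything that defines an ensemble run besides the Hamiltonian."""

    method: Literal["MASH", "FSSH"]
    n_traj: int
    dt: float = 0.01
    t_max: float = 20.0
    sample_stride: int = 10
    seed: int = 0
    decoherence: Literal["off", "gap_triggered"] = "off"
    decoherence_threshold: float = 4.0
    frustrated: Literal["reflect", "ignore"] = "reflect"

    def __post_init__(self) -> None:
        if self.method not in ("MASH", "FSSH"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")
        if self.decoherence not in ("off", "gap_triggered"):
            raise ValueError(f"unknown decoherence mode {self.decoherence!r}")
        if self.frustrated not in ("reflect", "ignore"):
            raise ValueError(f"unknown frustrated-hop mode {self.frustrated!r}")


def validate_timestep(params: ModelParams, dt: float, region: str = "reactant") -> None:
    """Error if dt cannot resolve the electronic phase where hops matter.

    The relevant gap scale is the adiabatic gap at the bottom of the
    initialization region's well (≈ |Λ − ε| for the reactant well); the
    much larger gap deep in the opposite well carries no coupling and the
    exact phase propagator handles it without instability.
    """
    q_min = params.q_shift if region == "product" else 0.0
    gap = adiabatic_surfaces(q_min, params)[2]
    if dt * float(gap) / params.hbar > 0.25:
        raise ValueError(
            f"dt={dt} is too large: dt*gap/hbar = {dt * float(gap):.3f} > 0.25 "
            f"for the well gap {float(gap):.3f}; reduce dt"
        )


# ---------------------------------------------------------------------------
# vectorized core


class _Consts:
    """Precomputed model constants for the inner loop."""

    def __init__(self, params: ModelParams, dt: float):
        self.w2 = params.omega**2
        self.a = params.diabatic_slope
        self.c0 = params.lam - params.eps  # D(Q) = a Q - c0
        self.q_half = 0.5 * params.q_shift
        self.two_delta = 2.0 * params.delta
        self.delta_a = params.delta * self.a
        self.hbar = params.hbar
        self.dt = dt
        self.half_dt = 0.5 * dt
        self.c1 = np.exp(-params.gamma * dt)
        self.c2 = np.sqrt((1.0 - self.c1**2) * params.mass / params.beta)
        self.mass = params.mass


class _Chunk:
    """Array-of-trajectories state advanced in lockstep."""

    __slots__ = ("Q", "P", "cp", "cm", "n", "hops", "force",
                 "frustrated_count", "hop_count", "prob_warn", "deco_count")

    def __init__(self, Q, P, cp, cm, n):
        self.Q = np.array(Q, dtype=float)
        self.P = np.array(P, dtype=float)
        self.cp = np.array(cp, dtype=complex)
        self.cm = np.array(cm, dtype=complex)
        self.n = np.array(n, dtype=float)
        self.hops = np.zeros_like(self.Q, dtype=np.int64)
        self.force = None
        self.frustrated_count = 0
        self.hop_count = 0
        self.prob_warn = 0
        self.deco_count = 0

    def compute_force(self, c: _Consts):
        d_gap = c.a * self.Q - c.c0
        root = np.hypot(d_gap, c.two_delta)
        self.force = -(c.w2 * (self.Q - c.q_half) + self.n * (0.5 * c.a) * d_gap / root)


def _step_chunk(ch: _Chunk, c: _Consts, method: str, frustrated_reflect: bool,
                rng: np.random.Generator) -> None:
    """Advance every trajectory in the chunk by one time step."""
    if ch.force is None:
        ch.compute_force(c)
    q_old = ch.Q
    p_old = ch.P

    # BAOAB nuclear step on the active surface
    p_half = p_old + c.half_dt * ch.force
    q_mid = q_old + c.half_dt * p_half
    if c.c1 != 1.0:
        p_half = c.c1 * p_half + c.c2 * rng.standard_normal(q_old.shape)
    q_new = q_mid + c.half_dt * p_half
    d_gap = c.a * q_new - c.c0
    root = np.hypot(d_gap, c.two_delta)
    force_new = -(c.w2 * (q_new - c.q_half) + ch.n * (0.5 * c.a) * d_gap / root)
    p_new = p_half + c.half_dt * force_new

    # electronic propagation with mid-step field; the active-state
    # population entering the fewest-switches denominator is taken *before*
    # the step (Tully's g = dt b/a_nn at time t), which converges much
    # faster in dt than post-step normalization
    dm = c.a * (0.5 * (q_old + q_new)) - c.c0
    rtm = np.hypot(dm, c.two_delta)
    coup = c.delta_a / (rtm * rtm)
    qdot = 0.5 * (p_old + p_new) / c.mass
    if method != "MASH":
        pop_n = np.where(ch.n > 0,
                         ch.cp.real**2 + ch.cp.imag**2,
                         ch.cm.real**2 + ch.cm.imag**2)
    ch.cp, ch.cm = _step_amplitudes(ch.cp, ch.cm, rtm, coup, qdot, c.dt, c.hbar)

    # hopping
    if method == "MASH":
        s_z = (ch.cp.real**2 + ch.cp.imag**2) - (ch.cm.real**2 + ch.cm.imag**2)
        attempt = (s_z * ch.n < 0.0)
    else:
        re_coh = ch.cp.real * ch.cm.real + ch.cp.imag * ch.cm.imag
        flux = 2.0 * qdot * coup * re_coh  # population flux out of the upper state
        prob = ch.n * flux * c.dt / np.maximum(pop_n, 1e-300)
        over = prob > 1.0
        if np.any(over):
            ch.prob_warn += int(over.sum())
        attempt = rng.random(q_new.shape) < prob

    if np.any(attempt):
        # hop from n to -n: ΔV = -n * gap; rescale P along the coupling
        # (all of P in 1-D) to conserve energy, else reflect
        p_sq_new = p_new**2 + 2.0 * c.mass * ch.n * root
        ok = attempt & (p_sq_new > 0.0)
        frustrated = attempt & ~ok
        if np.any(ok):
            p_new = np.where(ok, np.sign(p_new) * np.sqrt(np.abs(p_sq_new)), p_new)
            ch.n = np.where(ok, -ch.n, ch.n)
            ch.hops += ok
            ch.hop_count += int(ok.sum())
            # force depends on n: recompute for hopped trajectories
            force_new = -(c.w2 * (q_new - c.q_half)
                          + ch.n * (0.5 * c.a) * d_gap / root)
        if np.any(frustrated):
            ch.frustrated_count += int(frustrated.sum())
            if frustrated_reflect:
                p_new = np.where(frustrated, -p_new, p_new)

    ch.Q = q_new
    ch.P = p_new
    ch.force = force_new


def _apply_decoherence_chunk(ch: _Chunk, c: _Consts, method: str,
                             threshold: float, rng: np.random.Generator) -> None:
    """Gap-triggered decoherence on every chunk member whose gap exceeds it."""
    d_gap = c.a * ch.Q - c.c0
    root = np.hypot(d_gap, c.two_delta)
    mask = root > threshold
    if not np.any(mask):
        return
    ch.deco_count += int(mask.sum())
    if method == "FSSH":
        up = mask & (ch.n > 0)
        dn = mask & (ch.n < 0)
        ch.cp = np.where(up, 1.0 + 0.0j, np.where(dn, 0.0j, ch.cp))
        ch.cm = np.where(dn, 1.0 + 0.0j, np.where(up, 0.0j, ch.cm))
        return
    s_z = (ch.cp.real**2 + ch.cp.imag**2) - (ch.cm.real**2 + ch.cm.imag**2)
    if np.any(s_z[mask] * ch.n[mask] < 0.0):
        raise RuntimeError(
            "MASH decoherence resampling requested while sign(S_z) is "
            "inconsistent with the active state; this cannot happen under "
            "the large-gap trigger unless the trigger threshold is "
            "misconfigured"
        )
    k = int(mask.sum())
    elec = sample_electronic(ch.n[mask], "MASH", rng)
    cp = ch.cp.copy()
    cm = ch.cm.copy()
    cp[mask] = np.atleast_1d(elec.c_plus)[:k]
    cm[mask] = np.atleast_1d(elec.c_minus)[:k]
    ch.cp, ch.cm = cp, cm


# ---------------------------------------------------------------------------
# single-trajectory API (thin wrappers over the vectorized core)


def langevin_nuclear_step(Q, P, n, params: ModelParams, dt: float,
                          rng: np.random.Generator):
    """One BAOAB Langevin step on the active adiabat V_n.

    Reduces to velocity Verlet when γ = 0; the Ornstein–Uhlenbeck kick in
    the middle has the exact one-step variance (1 − e^{−2γdt})/β so the
    Boltzmann distribution is stationary up to O(dt²) sampling bias.
    Returns (Q', P') without any hopping.
    """
    c = _Consts(params, dt)
    ch = _Chunk(np.atleast_1d(Q), np.atleast_1d(P),
                np.zeros(np.shape(np.atleast_1d(Q)), complex),
                np.zeros(np.shape(np.atleast_1d(Q)), complex),
                np.broadcast_to(np.atleast_1d(n), np.atleast_1d(Q).shape))
    ch.compute_force(c)
    p_half = ch.P + c.half_dt * ch.force
    q_mid = ch.Q + c.half_dt * p_half
    if c.c1 != 1.0:
        p_half = c.c1 * p_half + c.c2 * rng.standard_normal(ch.Q.shape)
    q_new = q_mid + c.half_dt * p_half
    ch.Q = q_new
    ch.compute_force(c)
    p_new = p_half + c.half_dt * ch.force
    if np.isscalar(Q) or np.ndim(Q) == 0:
        return float(q_new[0]), float(p_new[0])
    return q_new, p_new


def _single_update(state: TrajectoryState, params: ModelParams, dt: float,
                   rng: np.random.Generator, method: str,
                   frustrated: str = "reflect") -> TrajectoryState:
    c = _Consts(params, dt)
    ch = _Chunk([state.Q], [state.P], [state.elec.c_plus], [state.elec.c_minus],
                [state.n])
    ch.hops[0] = state.hops
    _step_chunk(ch, c, method, frustrated == "reflect", rng)
    return TrajectoryState(
        Q=float(ch.Q[0]), P=float(ch.P[0]),
        elec=ElectronicState(complex(ch.cp[0]), complex(ch.cm[0])),
        n=int(ch.n[0]), t=state.t + dt, hops=int(ch.hops[0]),
    )


def mash_update(state: TrajectoryState, params: ModelParams, dt: float,
                rng: np.random.Generator, frustrated: str = "reflect") -> TrajectoryState:
    """One MASH step: deterministic hop whenever sign(S_z) leaves n."""
    return _single_update(state, params, dt, rng, "MASH", frustrated)


def fssh_update(state: TrajectoryState, params: ModelParams, dt: float,
                rng: np.random.Generator, frustrated: str = "reflect") -> TrajectoryState:
    """One FSSH step: stochastic fewest-switches hop attempt."""
    return _single_update(state, params, dt, rng, "FSSH", frustrated)


def fssh_hop_probability(elec: ElectronicState, qdot, d, n, dt: float):
    """Fewest-switches probability of hopping off the active surface.

    g = dt · (population flux out of the active state) / (active-state
    population); negative raw values mean the coherence is feeding the
    active state and are clamped to zero.
    """
    s_x, _, _ = bloch_from_amplitudes(elec.c_plus, elec.c_minus)
    flux_out_of_plus = qdot * d * s_x  # = 2 Q̇ d Re(c₊* c₋)
    n = np.asarray(n, dtype=float)
    pop = np.where(n > 0, np.abs(elec.c_plus) ** 2, np.abs(elec.c_minus) ** 2)
    raw = n * flux_out_of_plus * dt / np.maximum(pop, 1e-300)
    if np.any(raw > 1.0):
        logger.warning("FSSH hop probability exceeded 1 (max %.3f); reduce dt",
                       float(np.max(raw)))
    return np.clip(raw, 0.0, 1.0)


def apply_decoherence(state: TrajectoryState, method: str, params: ModelParams,
                      rng: np.random.Generator,
                      threshold: float = 4.0) -> TrajectoryState:
    """Decoherence correction for a single trajectory (see module docs).

    The caller is responsible for invoking this only while the adiabatic
    gap exceeds the trigger threshold; a ValueError is raised otherwise.
    """
    gap = float(adiabatic_surfaces(state.Q, params)[2])
    if gap <= threshold:
        raise ValueError(
            f"decoherence requested at gap {gap:.3f} <= threshold {threshold}"
        )
    if method == "FSSH":
        elec = sample_electronic(np.array([state.n]), "FSSH", rng)
    elif method == "MASH":
        if state.elec.s_z * state.n < 0:
            raise RuntimeError(
                "MASH decoherence with sign(S_z) inconsistent with the active "
                "state would change the active surface"
            )
        elec = sample_electronic(np.array([state.n]), "MASH", rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    new_elec = ElectronicState(complex(np.atleast_1d(elec.c_plus)[0]),
                               complex(np.atleast_1d(elec.c_minus)[0]))
    return replace(state, elec=new_elec)


# ---------------------------------------------------------------------------
# drivers


def run_trajectory(init: TrajectoryState, spec: EnsembleSpec,
                   params: ModelParams, rng: Optional[np.random.Generator] = None):
    """Propagate a single trajectory, recording every ``sample_stride`` steps.

    Returns a dict of arrays ``t, Q, P, S (3, n_samples), n, hops``.
    Deterministic given (init, spec.seed) when no generator is supplied.
    """
    validate_timestep(params, spec.dt)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    c = _Consts(params, spec.dt)
    ch = _Chunk([init.Q], [init.P], [init.elec.c_plus], [init.elec.c_minus], [init.n])
    ch.hops[0] = init.hops
    n_steps = int(round(spec.t_max / spec.dt))
    n_samples = n_steps // spec.sample_stride + 1
    out = {
        "t": np.empty(n_samples), "Q": np.empty(n_samples), "P": np.empty(n_samples),
        "S": np.empty((3, n_samples)), "n": np.empty(n_samples, dtype=np.int8),
        "hops": np.empty(n_samples, dtype=np.int64),
    }

    def record(idx, step):
        s_x, s_y, s_z = bloch_from_amplitudes(ch.cp[0], ch.cm[0])
        out["t"][idx] = init.t + step * spec.dt
        out["Q"][idx] = ch.Q[0]
        out["P"][idx] = ch.P[0]
        out["S"][:, idx] = (s_x.real if np.iscomplexobj(s_x) else s_x, s_y, s_z)
        out["n"][idx] = int(ch.n[0])
        out["hops"][idx] = int(ch.hops[0])

    record(0, 0)
    idx = 1
    for step in range(1, n_steps + 1):
        _step_chunk(ch, c, spec.method, spec.frustrated == "reflect", rng)
        if step % spec.sample_stride == 0:
            if spec.decoherence == "gap_triggered":
                _apply_decoherence_chunk(ch, c, spec.method,
                                         spec.decoherence_threshold, rng)
            record(idx, step)
            idx += 1
    return out


def run_ensemble(spec: EnsembleSpec, params: ModelParams,
                 init: Optional[InitialConditionSpec] = None,
                 strata: Optional[tuple] = None,
                 backend: str = "auto") -> PopulationCurve:
    """Run an ensemble and return the product-population curve.

    Trajectories are initialized from the thermal reactant distribution
    (or as directed by ``init``) and propagated in fixed-size chunks, each
    with its own child random stream of ``spec.seed``, so the result is
    bitwise reproducible and independent of memory batching.  When
    ``strata`` lists hop counts of interest, the returned curve carries
    the per-hop-count decomposition (plus a "rest" stratum so the pieces
    sum exactly to the total).

    ``backend`` selects the propagation core: "numba" (compiled
    per-trajectory loop, the default when numba is importable), "numpy"
    (vectorized reference implementation), or "auto".  Both cores
    implement identical dynamics; they consume the random stream in a
    different order, so individual trajectories differ while all ensemble
    statistics agree.
    """
    validate_timestep(params, spec.dt,
                      init.region if init is not None else "reactant")
    if init is None:
        init = InitialConditionSpec(region="reactant", method=spec.method,
                                    seed=spec.seed)
    if init.method != spec.method:
        raise ValueError("init.method must match spec.method")
    if backend == "auto":
        backend = "numba" if _HAVE_NUMBA else "numpy"
    if backend == "numba" and not _HAVE_NUMBA:
        raise RuntimeError("numba backend requested but numba is not importable")
    if backend not in ("numba", "numpy"):
        raise ValueError(f"unknown backend {backend!r}")

    c = _Consts(params, spec.dt)
    n_steps = int(round(spec.t_max / spec.dt))
    n_samples = n_steps // spec.sample_stride + 1
    times = np.arange(n_samples) * spec.sample_stride * spec.dt
    sum_pp = np.zeros(n_samples)
    strata = tuple(strata) if strata else ()
    sum_strata = np.zeros((len(strata) + 1, n_samples))  # last row = rest
    diag = {"hops": 0, "frustrated": 0, "prob_warnings": 0, "decoherence_events": 0}

    master = np.random.SeedSequence(spec.seed)
    n_chunks = (spec.n_traj + CHUNK_SIZE - 1) // CHUNK_SIZE
    children = master.spawn(n_chunks)
    block_means = []
    block_sizes = []
    for i_chunk in range(n_chunks):
        size = min(CHUNK_SIZE, spec.n_traj - i_chunk * CHUNK_SIZE)
        rng = np.random.default_rng(children[i_chunk])
        q0, p0, n0 = sample_nuclear_and_state(params, init, rng, size)
        elec = sample_electronic(n0, spec.method, rng)
        chunk_pp = np.zeros(n_samples)
        if backend == "numba":
            _run_chunk_numba(q0, p0, elec, n0, c, spec, params, rng,
                             strata, n_steps, chunk_pp, sum_strata, diag)
        else:
            _run_chunk_numpy(q0, p0, elec, n0, c, spec, params, rng,
                             strata, n_steps, chunk_pp, sum_strata, diag)
        sum_pp += chunk_pp
        block_means.append(chunk_pp / size)
        block_sizes.append(size)

    n_traj = spec.n_traj
    p_mean = sum_pp / n_traj
    p_stderr = np.sqrt(np.clip(p_mean * (1.0 - p_mean), 0.0, None) / n_traj)
    strata_out = None
    if strata:
        strata_out = {m: sum_strata[j] / n_traj for j, m in enumerate(strata)}
        strata_out["rest"] = sum_strata[-1] / n_traj
    if diag["prob_warnings"]:
        logger.warning("FSSH hop probability exceeded 1 in %d step-events; "
                       "consider a smaller dt", diag["prob_warnings"])
    logger.info("%s ensemble: %d trajectories, %d hops, %d frustrated, "
                "%d decoherence events", spec.method, n_traj, diag["hops"],
                diag["frustrated"], diag["decoherence_events"])
    return PopulationCurve(times=times, p_mean=p_mean, p_stderr=p_stderr,
                           n_traj=n_traj, strata=strata_out, diagnostics=diag,
                           block_means=np.asarray(block_means),
                           block_sizes=np.asarray(block_sizes))


def _run_chunk_numpy(q0, p0, elec, n0, c: _Consts, spec: EnsembleSpec,
                     params: ModelParams, rng, strata, n_steps,
                     sum_pp, sum_strata, diag) -> None:
    """Reference vectorized propagation of one chunk with accumulation."""
    ch = _Chunk(q0, p0, elec.c_plus, elec.c_minus, n0)

    def accumulate(idx):
        pp = product_projector(ch.Q, ch.n, params)
        sum_pp[idx] += pp.sum()
        for j, m in enumerate(strata):
            sum_strata[j, idx] += pp[ch.hops == m].sum()
        if strata:
            rest = ~np.isin(ch.hops, strata)
            sum_strata[-1, idx] += pp[rest].sum()

    accumulate(0)
    idx = 1
    for step in range(1, n_steps + 1):
        _step_chunk(ch, c, spec.method, spec.frustrated == "reflect", rng)
        if step % spec.sample_stride == 0:
            if spec.decoherence == "gap_triggered":
                _apply_decoherence_chunk(ch, c, spec.method,
                                         spec.decoherence_threshold, rng)
            accumulate(idx)
            idx += 1
    diag["hops"] += ch.hop_count
    diag["frustrated"] += ch.frustrated_count
    diag["prob_warnings"] += ch.prob_warn
    diag["decoherence_events"] += ch.deco_count


def _run_chunk_numba(q0, p0, elec, n0, c: _Consts, spec: EnsembleSpec,
                     params: ModelParams, rng, strata, n_steps,
                     sum_pp, sum_strata, diag) -> None:
    """Compiled propagation of one chunk (same dynamics as the numpy core)."""
    cp = np.atleast_1d(np.asarray(elec.c_plus, dtype=complex))
    cm = np.atleast_1d(np.asarray(elec.c_minus, dtype=complex))
    q = np.array(q0, dtype=float)
    p = np.array(p0, dtype=float)
    n = np.array(n0, dtype=float)
    hops = np.zeros_like(q, dtype=np.int64)
    strata_arr = np.asarray(strata, dtype=np.int64)
    qd = crossing_point(params)
    stats = _kernel(
        q, p,
        np.ascontiguousarray(cp.real), np.ascontiguousarray(cp.imag),
        np.ascontiguousarray(cm.real), np.ascontiguousarray(cm.imag),
        n, hops, strata_arr, sum_pp, sum_strata,
        c.w2, c.a, c.c0, c.q_half, c.two_delta, c.delta_a, c.hbar, c.mass,
        float(qd), c.dt, c.c1, c.c2, n_steps, spec.sample_stride,
        spec.method == "MASH", spec.frustrated == "reflect",
        spec.decoherence == "gap_triggered", spec.decoherence_threshold,
        bool(strata), rng,
    )
    tot_hops, tot_frust, tot_warn, tot_deco, inconsistent = stats
    if inconsistent:
        raise RuntimeError(
            "MASH decoherence resampling requested while sign(S_z) is "
            "inconsistent with the active state; this cannot happen under "
            "the large-gap trigger unless the trigger threshold is "
            "misconfigured"
        )
    diag["hops"] += int(tot_hops)
    diag["frustrated"] += int(tot_frust)
    diag["prob_warnings"] += int(tot_warn)
    diag["decoherence_events"] += int(tot_deco)


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _kernel(Q, P, cpr, cpi, cmr, cmi, n, hops, strata, sum_pp, sum_strata,
                w2, a, c0, q_half, two_delta, delta_a, hbar, mass, qd,
                dt, c1, c2, n_steps, stride, is_mash, reflect, deco, deco_thr,
                want_strata, rng):  # pragma: no cover - exercised via wrapper
        half_dt = 0.5 * dt
        n_traj = Q.shape[0]
        n_strata = strata.shape[0]
        two_pi = 2.0 * np.pi
        tot_hops = 0
        tot_frust = 0
        tot_warn = 0
        tot_deco = 0
        inconsistent = False
        for i in range(n_traj):
            if c2 > 0.0:
                noise = rng.standard_normal(n_steps)
            else:
                noise = np.empty(0)
            q = Q[i]
            p = P[i]
            ar = cpr[i]
            ai = cpi[i]
            br = cmr[i]
            bi = cmi[i]
            ni = n[i]
            hop_i = hops[i]
            dgap = a * q - c0
            root = np.sqrt(dgap * dgap + two_delta * two_delta)
            f = -(w2 * (q - q_half) + ni * 0.5 * a * dgap / root)
            # initial sample
            if (ni < 0.0 and q > qd) or (ni > 0.0 and q < qd):
                sum_pp[0] += 1.0
                if want_strata:
                    matched = False
                    for j in range(n_strata):
                        if hop_i == strata[j]:
                            sum_strata[j, 0] += 1.0
                            matched = True
                            break
                    if not matched:
                        sum_strata[n_strata, 0] += 1.0
            idx = 1
            for step in range(1, n_steps + 1):
                q_old = q
                p_old = p
                ph = p + half_dt * f
                q += half_dt * ph
                if c2 > 0.0:
                    ph = c1 * ph + c2 * noise[step - 1]
                q += half_dt * ph
                dgap = a * q - c0
                root = np.sqrt(dgap * dgap + two_delta * two_delta)
                f = -(w2 * (q - q_half) + ni * 0.5 * a * dgap / root)
                p = ph + half_dt * f
                # electronic step with mid-step field
                dm = a * 0.5 * (q_old + q) - c0
                rtm2 = dm * dm + two_delta * two_delta
                rtm = np.sqrt(rtm2)
                coup = delta_a / rtm2
                qdot = 0.5 * (p_old + p) / mass
                w = qdot * coup
                bz = rtm / hbar
                mag = np.sqrt(bz * bz + 4.0 * w * w)
                theta = 0.5 * dt * mag
                ct = np.cos(theta)
                st = np.sin(theta)
                az = st * bz / mag
                ay = st * 2.0 * w / mag
                if is_mash:
                    pop_before = 0.0
                elif ni > 0.0:
                    pop_before = ar * ar + ai * ai
                else:
                    pop_before = br * br + bi * bi
                nar = ct * ar + az * ai - ay * br
                nai = ct * ai - az * ar - ay * bi
                nbr = ct * br - az * bi + ay * ar
                nbi = ct * bi + az * br + ay * ai
                ar = nar
                ai = nai
                br = nbr
                bi = nbi
                # hop decision
                attempt = False
                if is_mash:
                    sz = ar * ar + ai * ai - (br * br + bi * bi)
                    attempt = sz * ni < 0.0
                else:
                    re_coh = ar * br + ai * bi
                    flux = 2.0 * qdot * coup * re_coh
                    popn = pop_before
                    if popn > 1e-300:
                        g = ni * flux * dt / popn
                    else:
                        g = 0.0
                    if g > 1.0:
                        tot_warn += 1
                    if g > 0.0 and rng.random() < g:
                        attempt = True
                if attempt:
                    p2 = p * p + 2.0 * mass * ni * root
                    if p2 > 0.0:
                        if p >= 0.0:
                            p = np.sqrt(p2)
                        else:
                            p = -np.sqrt(p2)
                        ni = -ni
                        hop_i += 1
                        tot_hops += 1
                        f = -(w2 * (q - q_half) + ni * 0.5 * a * dgap / root)
                    else:
                        tot_frust += 1
                        if reflect:
                            p = -p
                if step % stride == 0:
                    if deco and root > deco_thr:
                        tot_deco += 1
                        if is_mash:
                            sz = ar * ar + ai * ai - (br * br + bi * bi)
                            if sz * ni < 0.0:
                                inconsistent = True
                            else:
                                szn = ni * np.sqrt(rng.random())
                                azim = two_pi * rng.random()
                                phz = two_pi * rng.random()
                                hp = np.sqrt(0.5 * (1.0 + szn))
                                hm = np.sqrt(0.5 * (1.0 - szn))
                                ar = hp * np.cos(phz)
                                ai = hp * np.sin(phz)
                                br = hm * np.cos(phz + azim)
                                bi = hm * np.sin(phz + azim)
                        else:
                            if ni > 0.0:
                                ar = 1.0
                                ai = 0.0
                                br = 0.0
                                bi = 0.0
                            else:
                                ar = 0.0
                                ai = 0.0
                                br = 1.0
                                bi = 0.0
                    if (ni < 0.0 and q > qd) or (ni > 0.0 and q < qd):
                        sum_pp[idx] += 1.0
                        if want_strata:
                            matched = False
                            for j in range(n_strata):
                                if hop_i == strata[j]:
                                    sum_strata[j, idx] += 1.0
                                    matched = True
                                    break
                            if not matched:
                                sum_strata[n_strata, idx] += 1.0
                    idx += 1
            Q[i] = q
            P[i] = p
            cpr[i] = ar
            cpi[i] = ai
            cmr[i] = br
            cmi[i] = bi
            n[i] = ni
            hops[i] = hop_i
        return tot_hops, tot_frust, tot_warn, tot_deco, inconsistent
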