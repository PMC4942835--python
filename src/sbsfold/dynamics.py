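"""Energies, forces, and Langevin (BAOAB) time integration.

The integrator works in reduced units (kT = 1, sigma = 1, m = 1) on unwrapped
coordinates; periodicity enters only through minimum-image distances in the
pair interactions.  All randomness flows from a single integer seed, so a
trajectory is a pure function of (initial state, parameters, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .errors import (
    DomainError,
    InstabilityError,
    InvalidModelError,
    OverstretchError,
    SingularityError,
)
from .model import ForceField, System

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LangevinParams:
    """Integration parameters (reduced time units tau)."""

    dt: float = 0.012
    gamma: float = 0.5
    skin: float = 0.3


@dataclass
class Trajectory:
    """Sampled snapshots of a polymer-binder simulation.

    Coordinates are unwrapped; apply minimum image against ``box_edge`` when
    measuring contacts."""

    times: np.ndarray                 # (n_snap,)
    beads: np.ndarray                 # (n_snap, N, 3)
    binders: np.ndarray               # (n_snap, M, 3)
    kinetic_per_dof: np.ndarray       # (n_snap,)
    box_edge: float
    seed: int
    sample_interval: int
    params: LangevinParams
    ff: ForceField
    n_halved_steps: int = 0
    aborted: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_snapshots(self) -> int:
        return self.beads.shape[0]

    @property
    def n_beads(self) -> int:
        return self.beads.shape[1]


def attraction_depth_scale(r_cut_attr: float) -> float:
    """Prefactor making the truncated-shifted LJ well depth equal E_int."""
    src6 = (1.0 / r_cut_attr) ** 6
    return 1.0 / (1.0 + 4.0 * (src6 * src6 - src6))


def pair_energy(r: float, kind: str, ff: ForceField, color: int = 0) -> float:
    """Closed-form pair energy (kT) at separation ``r`` (sigma units)."""
    if r <= 0:
        raise DomainError("pair separation must be positive")
    s = ff.sigma
    if kind == "wca":
        if r >= K.WCA_CUT2**0.5 * s:
            return 0.0
        sr6 = (s / r) ** 6
        return 4.0 * ff.eps_rep * (sr6 * sr6 - sr6) + ff.eps_rep
    if kind == "fene":
        if r >= ff.fene_r0:
            raise OverstretchError(f"FENE bond at r={r} >= r0={ff.fene_r0}")
        return -0.5 * ff.fene_k * ff.fene_r0**2 * math.log(1 - (r / ff.fene_r0) ** 2)
    if kind == "attract":
        depth = ff.e_int[color] * attraction_depth_scale(ff.r_cut_attr)
        if r >= ff.r_cut_attr or depth == 0.0:
            return 0.0
        sr6 = (s / r) ** 6
        src6 = (s / ff.r_cut_attr) ** 6
        shift = 4.0 * depth * (src6 * src6 - src6)
        return 4.0 * depth * (sr6 * sr6 - sr6) - shift
    raise DomainError(f"unknown pair kind: {kind!r}")


def _packed(system: System):
    """Concatenate bead and binder coordinates and cache per-pair tables."""
    if system.chain.positions is None or system.binders.positions is None:
        raise InvalidModelError("system positions are not initialized")
    if system.ff.sigma != 1.0:
        raise InvalidModelError("dynamics requires reduced units (sigma = 1)")
    pos = np.vstack([system.chain.positions, system.binders.positions]).astype(float)
    bcolors = system.binders.colors.astype(np.int64)
    rc = system.ff.r_cut_attr
    # scale the LJ prefactor so the minimum of the truncated-shifted well is
    # exactly -E_int (truncation at rc otherwise shallows the well)
    attr = system.attraction_matrix() * attraction_depth_scale(rc)
    src6 = (1.0 / rc) ** 6
    attach_shifts = 4.0 * attr * (src6 * src6 - src6)
    return pos, bcolors, attr, attach_shifts


def total_forces(system: System, positions: np.ndarray | None = None) -> np.ndarray:
    """Deterministic forces -grad U on all particles (beads then binders)."""
    pos, bcolors, attr, shifts = _packed(system)
    if positions is not None:
        pos = np.asarray(positions, dtype=float)
    ff = system.ff
    L = system.box.edge
    n = pos.shape[0]
    forces = np.zeros_like(pos)
    wpos = np.empty_like(pos)
    K._wrap(pos, wpos, L)
    r_list = max(K.WCA_CUT2**0.5, ff.r_cut_attr) + 0.5
    pairs = np.empty((max(64, n * 200), 2), dtype=np.int64)
    npairs = K.build_pairs(wpos, L, r_list, pairs)
    if npairs < 0:
        pairs = np.empty((n * (n - 1) // 2 + 1, 2), dtype=np.int64)
        npairs = K.build_pairs(wpos, L, r_list, pairs)
    u, status = K.compute_forces(
        wpos, forces, pairs, npairs, system.chain.n_beads, bcolors, attr, L,
        ff.eps_rep, ff.r_cut_attr, ff.fene_k, ff.fene_r0, shifts,
    )
    if status == K.ERR_SINGULAR:
        raise SingularityError("overlapping particles (r < 1e-6 sigma)")
    if status == K.ERR_OVERSTRETCH:
        raise OverstretchError("FENE bond at or beyond maximum extension")
    return forces


def potential_energy(system: System, positions: np.ndarray | None = None) -> float:
    """Total potential energy (kT) of the current or supplied configuration."""
    pos, bcolors, attr, shifts = _packed(system)
    if positions is not None:
        pos = np.asarray(positions, dtype=float)
    ff = system.ff
    L = system.box.edge
    n = pos.shape[0]
    forces = np.zeros_like(pos)
    wpos = np.empty_like(pos)
    K._wrap(pos, wpos, L)
    pairs = np.empty((n * (n - 1) // 2 + 1, 2), dtype=np.int64)
    r_list = max(K.WCA_CUT2**0.5, ff.r_cut_attr) + 0.5
    npairs = K.build_pairs(wpos, L, r_list, pairs)
    u, status = K.compute_forces(
        wpos, forces, pairs, npairs, system.chain.n_beads, bcolors, attr, L,
        ff.eps_rep, ff.r_cut_attr, ff.fene_k, ff.fene_r0, shifts,
    )
    if status == K.ERR_SINGULAR:
        raise SingularityError("overlapping particles (r < 1e-6 sigma)")
    if status == K.ERR_OVERSTRETCH:
        raise OverstretchError("FENE bond at or beyond maximum extension")
    return float(u)


def langevin_step(
    system: System,
    velocities: np.ndarray,
    params: LangevinParams,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """One BAOAB update in place; returns the updated velocities.

    ``noise`` is a (n, 3) array of unit normals (zeros when omitted, which
    together with gamma=0 gives plain velocity-Verlet flight)."""
    pos, bcolors, attr, shifts = _packed(system)
    n = pos.shape[0]
    vel = np.asarray(velocities, dtype=float).copy()
    eta = np.zeros((1, n, 3)) if noise is None else noise.reshape(1, n, 3)
    ff = system.ff
    pairs = np.empty((max(64, n * 200), 2), dtype=np.int64)
    forces = np.zeros_like(pos)
    ref = np.zeros_like(pos)
    status, n_halved = K.run_chunk(
        pos, vel, forces, pairs, ref, 1, system.chain.n_beads, bcolors, attr,
        system.box.edge, ff.eps_rep, ff.r_cut_attr, ff.fene_k, ff.fene_r0,
        params.dt, params.gamma, ff.kT, params.skin, eta, shifts,
    )
    if status == K.ERR_OVERSTRETCH:
        raise OverstretchError("step rejected: bond overstretch persisted")
    if status == K.ERR_SINGULAR:
        raise SingularityError("overlapping particles")
    if status != K.OK:
        raise InstabilityError(f"integration failed with status {status}")
    system.chain.positions = pos[: system.chain.n_beads]
    system.binders.positions = pos[system.chain.n_beads :]
    return vel


def run_trajectory(
    system: System,
    n_steps: int,
    sample_interval: int,
    seed: int,
    params: LangevinParams = LangevinParams(),
) -> Trajectory:
    """Integrate ``n_steps`` Langevin steps, sampling every
    ``sample_interval`` steps (initial state is always the first snapshot).

    On numerical instability the run aborts and the trajectory holds all
    snapshots up to the last stable one (``aborted`` flag set).
    """
    if n_steps < 0 or sample_interval < 1:
        raise DomainError("n_steps >= 0 and sample_interval >= 1 required")
    pos, bcolors, attr, shifts = _packed(system)
    n = pos.shape[0]
    nb = system.chain.n_beads
    ff = system.ff
    rng = np.random.default_rng(seed)
    vel = rng.normal(scale=math.sqrt(ff.kT), size=(n, 3))
    vel -= vel.mean(axis=0)

    n_chunks = n_steps // sample_interval
    remainder = n_steps % sample_interval
    times = [0.0]
    bead_snaps = [pos[:nb].copy()]
    binder_snaps = [pos[nb:].copy()]
    ke = [0.5 * float(np.mean(vel**2))]  # kinetic energy per dof
    cap = max(64, n * 120)
    pairs = np.empty((cap, 2), dtype=np.int64)
    forces = np.zeros_like(pos)
    ref = np.zeros_like(pos)
    t = 0.0
    total_halved = 0
    aborted = False
    chunk_sizes = [sample_interval] * n_chunks + ([remainder] if remainder else [])
    for chunk in chunk_sizes:
        noise = rng.normal(size=(chunk, n, 3))
        x_save, v_save = pos.copy(), vel.copy()
        while True:
            status, n_halved = K.run_chunk(
                pos, vel, forces, pairs, ref, chunk, nb, bcolors, attr,
                system.box.edge, ff.eps_rep, ff.r_cut_attr, ff.fene_k,
                ff.fene_r0, params.dt, params.gamma, ff.kT, params.skin,
                noise, shifts,
            )
            if status == K.ERR_CAPACITY:
                cap *= 2
                pairs = np.empty((cap, 2), dtype=np.int64)
                pos[:], vel[:] = x_save, v_save
                continue
            break
        total_halved += n_halved
        if status != K.OK:
            log.warning("trajectory aborted with status %d at t=%.3f", status, t)
            aborted = True
            break
        t += chunk * params.dt
        if chunk == sample_interval:
            times.append(t)
            bead_snaps.append(pos[:nb].copy())
            binder_snaps.append(pos[nb:].copy())
            ke.append(0.5 * float(np.mean(vel**2)))
    if total_halved:
        log.warning("%d sub-steps required dt halving (overstretch guard)", total_halved)
    system.chain.positions = pos[:nb].copy()
    system.binders.positions = pos[nb:].copy()
    return Trajectory(
        times=np.asarray(times),
        beads=np.asarray(bead_snaps),
        binders=np.asarray(binder_snaps),
        kinetic_per_dof=np.asarray(ke),
        box_edge=system.box.edge,
        seed=seed,
        sample_interval=sample_interval,
        params=params,
        ff=ff,
        n_halved_steps=total_halved,
        aborted=aborted,
    )
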