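"""Reference ensembles and ground-truth fixtures.

Everything here is generated programmatically so the rest of the package can
be tested hermetically: pivot-sampled self-avoiding walks (coil reference),
Gaussian chains (ideal/theta reference), full simulator block-copolymer
fixtures with known binding-site truth, and slow brute-force re-implementations
of the contact observables for small inputs.

The brute-force oracles deliberately share no kernels with
:mod:`sbsfold.observables`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._kernels import OCTA_OPS, pivot_saw_ensemble
from .errors import DomainError, OracleScopeError
from .model import (
    BeadChain,
    ForceField,
    SimulationBox,
    assemble_system,
    build_block_copolymer,
)
from .observables import ContactMatrix, contact_map, gyration_radius


def sample_saw_pivot(
    n_beads: int,
    n_samples: int,
    seed: int,
    stride: int | None = None,
    warmup: int | None = None,
) -> np.ndarray:
    """Self-avoiding-walk ensemble on the cubic lattice via pivot Monte Carlo.

    Lattice spacing equals the bead diameter sigma, so no two beads are ever
    closer than sigma.  Samples are ``stride`` (default N) attempted pivots
    apart after ``warmup`` (default 20 N) attempts.  Returns float positions
    of shape (n_samples, n_beads, 3).
    """
    if n_beads < 8:
        raise DomainError("pivot sampler requires n_beads >= 8")
    stride = stride if stride is not None else n_beads
    warmup = warmup if warmup is not None else 20 * n_beads
    samples, _ = pivot_saw_ensemble(
        n_beads, n_samples, stride, warmup, seed, OCTA_OPS
    )
    return samples.astype(np.float64)


def sample_gaussian_chain(
    n_beads: int, bond_length: float, n_samples: int, seed: int
) -> np.ndarray:
    """Ideal-chain ensemble: cumulative sums of isotropic Gaussian steps with
    rms step length ``bond_length`` (so R^2(s) = b^2 s in expectation)."""
    if n_beads < 3:
        raise DomainError("need n_beads >= 3")
    rng = np.random.default_rng(seed)
    steps = rng.normal(
        scale=bond_length / np.sqrt(3.0), size=(n_samples, n_beads - 1, 3)
    )
    pos = np.zeros((n_samples, n_beads, 3))
    np.cumsum(steps, axis=1, out=pos[:, 1:])
    return pos


def saw_rg_reference(n_beads: int, seed: int = 7, n_samples: int = 300) -> tuple[float, float]:
    """(mean, sd) of the SAW gyration radius at this chain length."""
    ens = sample_saw_pivot(n_beads, n_samples, seed=seed)
    rgs = np.array([gyration_radius(frame) for frame in ens])
    return float(rgs.mean()), float(rgs.std(ddof=1))


@dataclass
class BlockFixture:
    """A ground-truth inference fixture: a block-copolymer chain simulated in
    a known phase, with the resulting ensemble contact matrix as target."""

    chain: BeadChain
    target: ContactMatrix
    clean_target: ContactMatrix
    e_int: float
    binder_counts: list[int]
    box_edge: float
    seed: int
    trajectories: list | None = None


def make_block_fixture(
    blocks,
    e_int: float = 4.1,
    binders_per_color: int = 90,
    box_edge: float = 18.0,
    n_traj: int = 6,
    n_steps: int = 120_000,
    sample_interval: int = 4000,
    equilibration_fraction: float = 0.5,
    threshold: float = 3.5,
    noise_cv: float = 0.0,
    seed: int = 0,
    keep_trajectories: bool = False,
) -> BlockFixture:
    """Run the full simulator on a known block profile and emit the ensemble
    contact matrix (optionally with entrywise log-normal noise of the given
    coefficient of variation).  The truth chain is stored for recovery
    scoring."""
    from .dynamics import run_trajectory  # local import avoids cycles

    chain_proto = build_block_copolymer(blocks)
    nc = chain_proto.n_colors
    ff = ForceField(e_int=tuple([e_int] * nc))
    acc = None
    kept = []
    for k in range(n_traj):
        chain = build_block_copolymer(blocks)
        box = SimulationBox(edge=box_edge)
        system = assemble_system(
            chain, ff, box, binder_counts=[binders_per_color] * nc,
            seed=seed * 1000 + k,
        )
        traj = run_trajectory(
            system, n_steps, sample_interval, seed=seed * 1000 + 500 + k
        )
        first = int(equilibration_fraction * traj.n_snapshots)
        cm = contact_map(traj.beads[first:], threshold=threshold,
                         box_edge=traj.box_edge)
        acc = cm.values if acc is None else acc + cm.values
        if keep_trajectories:
            kept.append(traj)
    mean_map = acc / n_traj
    clean = ContactMatrix(values=mean_map, meta={"threshold": threshold})
    target_values = mean_map
    if noise_cv > 0:
        rng = np.random.default_rng(seed + 99)
        sigma_ln = np.sqrt(np.log(1.0 + noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln,
                              size=mean_map.shape)
        noise = np.triu(noise)
        noise = noise + np.triu(noise, 1).T
        target_values = mean_map * noise
    target = ContactMatrix(values=target_values,
                           meta={"threshold": threshold, "noise_cv": noise_cv})
    return BlockFixture(
        chain=chain_proto, target=target, clean_target=clean, e_int=e_int,
        binder_counts=[binders_per_color] * nc, box_edge=box_edge, seed=seed,
        trajectories=kept if keep_trajectories else None,
    )


# Reference phase points for the N=250, box-edge-20, 120-binder system
# (validated empirically; concentrations in the tens of nmol/l at the default
# 87 nm bead size).
PHASE_POINTS = {
    "coil": {"e_int": 0.0, "binders": 120, "init": "saw"},
    "globule_disordered": {"e_int": 2.6, "binders": 120, "init": "saw"},
    # the deep quench is preceded by a short liquid-globule relaxation stage
    # that erases the compact initializer's fine-structure memory
    "globule_ordered": {"e_int": 4.1, "binders": 120, "init": "globule",
                        "relax_e_int": 3.0, "relax_steps": 50_000},
}


def phase_ensemble(
    state: str,
    n_beads: int = 250,
    n_traj: int = 4,
    n_steps: int = 150_000,
    sample_interval: int = 5000,
    box_edge: float = 20.0,
    equilibration_fraction: float = 0.4,
    seed: int = 0,
):
    """Equilibrium bead-frame ensemble at a named phase point.

    Collapsed states are initialized inside the phase (compact start) because
    collapse from a coil arrests on accessible time scales; coil states start
    from an open SAW.  Phase points may declare a relaxation stage (run at a
    softer affinity before the production quench).  Returns
    (frames, trajectories)."""
    from .dynamics import run_trajectory
    from .model import ForceField, SimulationBox, assemble_system, build_homopolymer

    if state not in PHASE_POINTS:
        raise DomainError(f"unknown phase point {state!r}")
    spec = PHASE_POINTS[state]
    frames = []
    trajs = []
    for k in range(n_traj):
        chain = build_homopolymer(n_beads)
        box = SimulationBox(edge=box_edge)
        ff = ForceField(e_int=(spec["e_int"],))
        system = assemble_system(
            chain, ff, box, binder_counts=[spec["binders"]],
            seed=seed * 100 + k, init=spec["init"],
        )
        if "relax_e_int" in spec:
            system.ff = ForceField(e_int=(spec["relax_e_int"],))
            run_trajectory(system, spec["relax_steps"], spec["relax_steps"],
                           seed=seed * 100 + 40 + k)
            system.ff = ForceField(e_int=(spec["e_int"],))
        traj = run_trajectory(system, n_steps, sample_interval,
                              seed=seed * 100 + 50 + k)
        first = int(equilibration_fraction * traj.n_snapshots)
        frames.append(traj.beads[first:])
        trajs.append(traj)
    return np.concatenate(frames, axis=0), trajs


# ---------------------------------------------------------------------------
# Brute-force oracles (independent, O(N^3), small inputs only)
# ---------------------------------------------------------------------------

_MAX_ORACLE_BEADS = 50
_MAX_ORACLE_SNAPSHOTS = 1000


def _oracle_guard(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1] > _MAX_ORACLE_BEADS:
        raise OracleScopeError(f"oracle limited to N <= {_MAX_ORACLE_BEADS}")
    if frames.shape[0] > _MAX_ORACLE_SNAPSHOTS:
        raise OracleScopeError(
            f"oracle limited to {_MAX_ORACLE_SNAPSHOTS} snapshots")
    return frames


def _oracle_adjacency(frame: np.ndarray, threshold: float,
                      box_edge: float | None) -> np.ndarray:
    n = frame.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        d = frame[i] - frame[j]
        if box_edge is not None and box_edge > 0:
            d = d - box_edge * np.round(d / box_edge)
        if float(np.dot(d, d)) <= threshold**2:
            adj[i, j] = adj[j, i] = True
    return adj


def brute_force_contact_probability(
    frames, threshold: float, box_edge: float | None = None
) -> np.ndarray:
    """P_c(s) for s = 1..N-1 by exhaustive enumeration."""
    frames = _oracle_guard(frames)
    n = frames.shape[1]
    hits = np.zeros(n)
    tots = np.zeros(n)
    for frame in frames:
        adj = _oracle_adjacency(frame, threshold, box_edge)
        for i, j in itertools.combinations(range(n), 2):
            tots[j - i] += 1
            if adj[i, j]:
                hits[j - i] += 1
    return hits[1:] / tots[1:]


def brute_force_triplet_grid(
    frames, threshold: float, max_s: int, box_edge: float | None = None
) -> np.ndarray:
    """P_c(s1, s2) by exhaustive enumeration over all (i, s1, s2)."""
    frames = _oracle_guard(frames)
    n = frames.shape[1]
    hits = np.zeros((max_s + 1, max_s + 1))
    tots = np.zeros((max_s + 1, max_s + 1))
    for frame in frames:
        adj = _oracle_adjacency(frame, threshold, box_edge)
        for s1 in range(1, max_s + 1):
            for s2 in range(1, max_s + 1):
                for i in range(n - s1 - s2):
                    j, k = i + s1, i + s1 + s2
                    tots[s1, s2] += 1
                    if adj[i, j] and adj[j, k] and adj[i, k]:
                        hits[s1, s2] += 1
    with np.errstate(invalid="ignore"):
        grid = np.where(tots > 0, hits / np.maximum(tots, 1), np.nan)
    return 0.5 * (grid + grid.T)


def brute_force_component_counts(
    frames, threshold: float, n_max: int, s_min: int = 2,
    box_edge: float | None = None,
) -> np.ndarray:
    """Mean per-snapshot counts of connected components of size exactly n,
    n = 2..n_max, via breadth-first search on the explicit contact graph."""
    frames = _oracle_guard(frames)
    n = frames.shape[1]
    counts = np.zeros(n_max + 1)
    for frame in frames:
        adj = _oracle_adjacency(frame, threshold, box_edge)
        for i in range(n):
            for j in range(n):
                if abs(i - j) < s_min:
                    adj[i, j] = False
        seen = np.zeros(n, dtype=bool)
        for i in range(n):
            if seen[i]:
                continue
            stack, comp = [i], []
            seen[i] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in np.flatnonzero(adj[u]):
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            if 2 <= len(comp) <= n_max:
                counts[len(comp)] += 1
    return counts[2:] / frames.shape[0]


def saw_many_body_baseline(
    n_beads: int, threshold: float, n_max: int, s_min: int = 2,
    n_samples: int = 2000, seed: int = 11,
) -> np.ndarray:
    """Mean cumulative component counts (size >= n, for n = 2..n_max) on a
    pivot-SAW ensemble: the open-state baseline for enrichment ratios."""
    from ._kernels import many_body_component_counts

    ens = sample_saw_pivot(n_beads, n_samples, seed=seed)
    counts = many_body_component_counts(
        np.ascontiguousarray(ens), -1.0, threshold, s_min
    ) / n_samples
    cumulative = np.cumsum(counts[::-1])[::-1]
    return cumulative[2:n_max + 1]
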