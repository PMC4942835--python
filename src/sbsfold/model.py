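"""Polymer-binder system definition and unit conversions.

All quantities are expressed in reduced units: bead diameter ``sigma`` is the
length unit, ``kT`` the energy unit, bead mass the mass unit.  Physical
quantities (nanometres, mol/litre, base pairs) enter only through the explicit
mapping helpers (:func:`binder_count_from_concentration`,
:func:`bp_per_bead`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import CongestionError, InvalidModelError, UnitMappingError

AVOGADRO = 6.02214076e23  # mol^-1

#: inert block label accepted by :func:`build_block_copolymer`
INERT = -1

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceField:
    """Pair-interaction parameters of the bead-binder system.

    ``e_int`` maps each color index to the bead-binder affinity (well depth,
    in kT) of that color.  Bead-bead and binder-binder interactions are purely
    repulsive (WCA); consecutive beads are additionally bonded by FENE
    springs.
    """

    sigma: float = 1.0
    eps_rep: float = 1.0
    e_int: tuple[float, ...] = (0.0,)
    r_cut_attr: float = 1.5
    fene_k: float = 30.0
    fene_r0: float = 1.5
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.fene_r0 <= self.sigma:
            raise InvalidModelError("fene_r0 must exceed sigma")
        if self.r_cut_attr <= WCA_CUTOFF * self.sigma:
            raise InvalidModelError(
                "attraction cutoff must exceed the WCA cutoff 2^(1/6) sigma"
            )
        if self.eps_rep < 0 or self.kT <= 0 or any(e < 0 for e in self.e_int):
            raise InvalidModelError("energies must be nonnegative, kT positive")

    @property
    def n_colors(self) -> int:
        return len(self.e_int)

    def with_affinity(self, e_int: Sequence[float]) -> "ForceField":
        return replace(self, e_int=tuple(float(e) for e in e_int))


@dataclass
class SimulationBox:
    """Cubic periodic box; ``physical_sigma`` (nm) enables unit mapping."""

    edge: float
    physical_sigma: float | None = 87.0

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise InvalidModelError("box edge must be positive")

    def volume_litres(self) -> float:
        if self.physical_sigma is None:
            raise UnitMappingError("physical_sigma is not set on this box")
        edge_nm = self.edge * self.physical_sigma
        return edge_nm**3 * 1e-24  # 1 nm^3 = 1e-24 l


@dataclass
class BeadChain:
    """Linear polymer of beads carrying per-color binding-site multiplicities.

    ``colors`` has shape (n_beads, n_colors); a row of zeros marks an inert
    bead.  Bond topology is the implicit linear one (i, i+1).
    """

    colors: np.ndarray
    positions: np.ndarray | None = None
    block_bounds: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.int64)
        if self.colors.ndim != 2:
            raise InvalidModelError("colors must be a (n_beads, n_colors) array")
        if self.colors.shape[0] < 2:
            raise InvalidModelError("a chain needs at least 2 beads")
        if (self.colors < 0).any():
            raise InvalidModelError("multiplicities must be nonnegative")

    @property
    def n_beads(self) -> int:
        return self.colors.shape[0]

    @property
    def n_colors(self) -> int:
        return self.colors.shape[1]

    def dominant_color(self) -> np.ndarray:
        """Per-bead argmax color; -1 for inert beads."""
        out = np.argmax(self.colors, axis=1)
        out[self.colors.sum(axis=1) == 0] = INERT
        return out


@dataclass
class BinderSet:
    """Diffusing binders; each carries a single color index."""

    colors: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.int64)
        if self.colors.ndim != 1:
            raise InvalidModelError("binder colors must be a 1-d index array")
        if (self.colors < 0).any():
            raise InvalidModelError("binder colors must be nonnegative indices")

    @property
    def m_binders(self) -> int:
        return self.colors.shape[0]

    def counts(self, n_colors: int) -> np.ndarray:
        return np.bincount(self.colors, minlength=n_colors)


def build_homopolymer(n_beads: int, color: int = 0, n_colors: int | None = None) -> BeadChain:
    """Chain of ``n_beads`` identical beads, multiplicity 1 in ``color``."""
    if n_beads < 2:
        raise InvalidModelError("homopolymer needs n_beads >= 2")
    if color < 0:
        raise InvalidModelError("color must be a nonnegative index")
    nc = n_colors if n_colors is not None else color + 1
    colors = np.zeros((n_beads, nc), dtype=np.int64)
    colors[:, color] = 1
    return BeadChain(colors=colors, block_bounds=(0, n_beads))


def build_block_copolymer(
    block_spec: Sequence[tuple[int, int]], n_colors: int | None = None
) -> BeadChain:
    """Chain built from ``(length, color)`` blocks; color ``INERT`` (-1) makes
    a non-interacting spacer.  Block boundaries are recorded on the chain."""
    if len(block_spec) == 0:
        raise InvalidModelError("need at least one block")
    lengths = [int(l) for l, _ in block_spec]
    if any(l <= 0 for l in lengths):
        raise InvalidModelError("zero-length block")
    total = sum(lengths)
    if total < 2:
        raise InvalidModelError("total chain length must be >= 2")
    colors_used = [c for _, c in block_spec if c != INERT]
    if any(c < 0 for c in colors_used):
        raise InvalidModelError("block colors must be nonnegative or INERT")
    nc = n_colors if n_colors is not None else (max(colors_used) + 1 if colors_used else 1)
    colors = np.zeros((total, nc), dtype=np.int64)
    bounds = [0]
    pos = 0
    for length, color in block_spec:
        if color != INERT:
            colors[pos : pos + length, color] = 1
        pos += length
        bounds.append(pos)
    return BeadChain(colors=colors, block_bounds=tuple(bounds))


def binder_count_from_concentration(c_molar_nmol_l: float, box: SimulationBox) -> int:
    """Number of binders corresponding to a molar concentration in nmol/l."""
    if c_molar_nmol_l < 0:
        raise InvalidModelError("concentration must be nonnegative")
    v = box.volume_litres()
    return int(round(c_molar_nmol_l * 1e-9 * AVOGADRO * v))


def count_to_concentration(count: int, box: SimulationBox) -> float:
    """Inverse of :func:`binder_count_from_concentration`, in nmol/l."""
    if count < 0:
        raise InvalidModelError("count must be nonnegative")
    v = box.volume_litres()
    return count / (AVOGADRO * v) * 1e9


def bp_per_bead(total_bp: float, n_beads: int) -> float:
    """Genomic span per bead under uniform coarse-graining."""
    if n_beads < 1:
        raise InvalidModelError("n_beads must be positive")
    if total_bp <= 0:
        raise InvalidModelError("total_bp must be positive")
    return total_bp / n_beads


def initialize_saw_configuration(
    chain: BeadChain,
    box: SimulationBox | None,
    seed: int,
    bond_length: float = 1.05,
    min_dist: float = 1.0,
    max_bead_retries: int = 60,
    max_restarts: int = 40,
) -> np.ndarray:
    """Grow a self-avoiding off-lattice conformation for ``chain``.

    Bond lengths are fixed at ``bond_length`` (within the FENE range) and no
    pair of beads ends closer than ``min_dist`` under the minimum-image
    convention of ``box`` (direct distances if ``box`` is None).  Coordinates
    are unwrapped.  Deterministic given ``seed``.
    """
    n = chain.n_beads
    rng = np.random.default_rng(seed)
    edge = box.edge if box is not None else None
    for _ in range(max_restarts):
        pos = np.empty((n, 3))
        pos[0] = rng.uniform(0.0, edge if edge else 10.0, size=3)
        i = 1
        failed = False
        while i < n:
            placed = False
            for _ in range(max_bead_retries):
                step = rng.normal(size=3)
                step *= bond_length / np.linalg.norm(step)
                cand = pos[i - 1] + step
                d = pos[:i] - cand
                if edge is not None:
                    d -= edge * np.round(d / edge)
                if (np.einsum("ij,ij->i", d, d) >= min_dist**2).all():
                    pos[i] = cand
                    placed = True
                    break
            if placed:
                i += 1
            else:
                # backtrack a few beads, then keep growing
                i = max(1, i - 8)
                if rng.random() < 0.02:
                    failed = True
                    break
        if not failed:
            chain.positions = pos
            return pos
    raise CongestionError(
        f"could not grow a self-avoiding configuration of {n} beads"
    )


def initialize_globule_configuration(
    chain: BeadChain,
    box: SimulationBox,
    seed: int,
    radius: float | None = None,
    extra_particles: int = 0,
    packing_fraction: float = 0.40,
    bond_length: float = 1.05,
    min_dist: float = 1.0,
    max_bead_retries: int = 300,
    max_restarts: int = 30,
) -> np.ndarray:
    """Grow a self-avoiding conformation confined to a sphere (compact
    initial state for sampling the globule phase).

    Collapse from an open conformation is kinetically arrested on accessible
    time scales, so equilibrium globule ensembles are initialized inside the
    phase and relaxed; ``radius`` defaults to packing the chain plus
    ``extra_particles`` binders at ``packing_fraction``.
    """
    n = chain.n_beads
    if radius is None:
        vol = (n + extra_particles) * (np.pi / 6.0) / packing_fraction
        radius = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    center = np.full(3, box.edge / 2.0)
    for _ in range(max_restarts):
        pos = np.empty((n, 3))
        pos[0] = 0.0
        i = 1
        stuck = 0
        while i < n and stuck < 20000:
            ok = False
            for _ in range(max_bead_retries):
                step = rng.normal(size=3)
                step *= bond_length / np.linalg.norm(step)
                cand = pos[i - 1] + step
                if np.linalg.norm(cand) > radius:
                    continue
                d = pos[:i] - cand
                if (np.einsum("ij,ij->i", d, d) >= min_dist**2).all():
                    pos[i] = cand
                    ok = True
                    break
            if ok:
                i += 1
            else:
                i = max(1, i - 10)
                stuck += 1
        if i == n:
            chain.positions = pos + center
            return chain.positions
    raise CongestionError(
        f"could not grow a confined configuration of {n} beads in R={radius:.2f}")


def place_binders_in_sphere(
    binders: BinderSet,
    box: SimulationBox,
    occupied: np.ndarray,
    seed: int,
    radius: float,
    min_dist: float = 0.9,
    max_retries: int = 2000,
) -> np.ndarray:
    """Place binders uniformly inside a sphere at the box center, avoiding
    overlaps (used together with the compact chain initializer)."""
    rng = np.random.default_rng(seed)
    center = np.full(3, box.edge / 2.0)
    placed: list[np.ndarray] = []
    for _ in range(binders.m_binders):
        ok = False
        for _ in range(max_retries):
            cand = rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(cand) > radius:
                continue
            cand = cand + center
            ref = np.vstack([occupied, *placed]) if placed else occupied
            d = ref - cand
            if (np.einsum("ij,ij->i", d, d) >= min_dist**2).all():
                placed.append(cand)
                ok = True
                break
        if not ok:
            raise CongestionError("sphere too crowded for binder placement")
    binders.positions = np.array(placed).reshape(binders.m_binders, 3)
    return binders.positions


def place_binders(
    binders: BinderSet,
    box: SimulationBox,
    occupied: np.ndarray | None,
    seed: int,
    min_dist: float = 1.0,
    max_retries: int = 200,
) -> np.ndarray:
    """Place binders uniformly in the box, avoiding overlaps below
    ``min_dist`` with ``occupied`` positions and previously placed binders."""
    m = binders.m_binders
    rng = np.random.default_rng(seed)
    edge = box.edge
    placed: list[np.ndarray] = []
    others = occupied if occupied is not None else np.empty((0, 3))
    for _ in range(m):
        ok = False
        for _ in range(max_retries):
            cand = rng.uniform(0.0, edge, size=3)
            ref = np.vstack([others, *placed]) if placed or len(others) else np.empty((0, 3))
            if len(ref):
                d = ref - cand
                d -= edge * np.round(d / edge)
                if (np.einsum("ij,ij->i", d, d) < min_dist**2).any():
                    continue
            placed.append(cand)
            ok = True
            break
        if not ok:
            raise CongestionError("binder placement failed: box too crowded")
    pos = np.array(placed).reshape(m, 3)
    binders.positions = pos
    return pos


@dataclass
class System:
    """A complete simulatable state: chain + binders + box + force field."""

    chain: BeadChain
    binders: BinderSet
    box: SimulationBox
    ff: ForceField

    def __post_init__(self) -> None:
        if self.chain.n_colors > self.ff.n_colors:
            raise InvalidModelError("force field declares fewer colors than chain")
        if self.binders.m_binders and self.binders.colors.max() >= self.ff.n_colors:
            raise InvalidModelError("binder color outside force-field palette")

    @property
    def n_particles(self) -> int:
        return self.chain.n_beads + self.binders.m_binders

    def attraction_matrix(self) -> np.ndarray:
        """(n_beads, n_colors) well depths: multiplicity times color affinity."""
        e = np.asarray(self.ff.e_int, dtype=float)[: self.chain.n_colors]
        return self.chain.colors.astype(float) * e[None, :]


def assemble_system(
    chain: BeadChain,
    ff: ForceField,
    box: SimulationBox,
    binder_counts: Sequence[int] | None = None,
    concentration_nmol_l: float | None = None,
    seed: int = 0,
    init: str = "saw",
) -> System:
    """Build an initialized :class:`System`.

    Binder numbers are given either directly per color (``binder_counts``) or
    as a total molar concentration split evenly across the chain's colors.
    ``init``: "saw" grows an open self-avoiding start; "globule" grows a
    compact confined start with binders inside (equilibrium sampling of the
    collapsed phases).
    """
    if binder_counts is None:
        if concentration_nmol_l is None:
            raise InvalidModelError("provide binder_counts or concentration_nmol_l")
        total = binder_count_from_concentration(concentration_nmol_l, box)
        ncol = chain.n_colors
        base = total // ncol
        counts = [base + (1 if i < total % ncol else 0) for i in range(ncol)]
    else:
        counts = [int(x) for x in binder_counts]
    colors = np.repeat(np.arange(len(counts)), counts)
    binders = BinderSet(colors=colors)
    if init == "globule":
        m = binders.m_binders
        vol = (chain.n_beads + m) * (np.pi / 6.0) / 0.40
        radius = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        if chain.positions is None:
            initialize_globule_configuration(
                chain, box, seed=seed, radius=radius)
        place_binders_in_sphere(
            binders, box, chain.positions, seed=seed + 1, radius=radius)
    else:
        if chain.positions is None:
            initialize_saw_configuration(chain, box, seed=seed)
        place_binders(binders, box, chain.positions, seed=seed + 1)
    return System(chain=chain, binders=binders, box=box, ff=ff)
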