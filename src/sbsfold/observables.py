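"""Structural observables of polymer-binder trajectories.

Implements the quantities used to characterize folding: gyration radius,
contact maps, contact probability vs contour separation with power-law
exponent fits, mean-square inter-site distances, the binder structure factor,
many-body contact statistics, triplet contact probabilities, and the
classification of the thermodynamic state (coil / disordered globule /
ordered globule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from . import _kernels as K
from .dynamics import Trajectory
from .errors import (
    DomainError,
    EmptyInputError,
    FitDomainError,
    NotConvergedError,
    WavevectorError,
)

DEFAULT_CONTACT_THRESHOLD = 3.5   # locus-style maps
EXPONENT_CONTACT_THRESHOLD = 2.0  # scaling-exponent estimation


@dataclass
class PowerLawFit:
    alpha: float
    ci_low: float
    ci_high: float
    window: tuple[float, float]
    n_bins: int


@dataclass
class PsCurve:
    """Contact probability vs contour (or genomic) separation."""

    s: np.ndarray
    p: np.ndarray
    counts: np.ndarray | None = None
    units: str = "beads"  # or "bp"
    fit: PowerLawFit | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.s.ndim != 1 or self.s.shape != self.p.shape:
            raise DomainError("s and p must be matching 1-d arrays")
        if (np.diff(self.s) <= 0).any():
            raise DomainError("separations must be strictly increasing")

    def positive(self) -> "PsCurve":
        m = self.p > 0
        return PsCurve(self.s[m], self.p[m],
                       None if self.counts is None else self.counts[m],
                       units=self.units)


@dataclass
class ContactMatrix:
    """Square symmetric nonnegative matrix of contact frequencies."""

    values: np.ndarray
    bin_size: float = 1.0
    units: str = "beads"
    normalization: str = "raw"  # or "observed_expected"
    labels: list[str] | None = None
    mask: np.ndarray | None = None  # True = masked-out bin (e.g., deletion)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DomainError("contact matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9 * max(1.0, np.abs(v).max())):
            raise DomainError("contact matrix must be symmetric")
        if np.nanmin(v) < 0:
            raise DomainError("contact matrix must be nonnegative")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class StructureFactorCurve:
    k: np.ndarray
    sk: np.ndarray
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    # (k*, height, prominence) per detected peak


def gyration_radius(positions: np.ndarray) -> float:
    """Rg = sqrt(mean |r_i - r_cm|^2) on unwrapped coordinates."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 1:
        raise DomainError("positions must be (n, 3) with n >= 1")
    d = pos - pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def gyration_radius_series(traj: Trajectory) -> np.ndarray:
    """Rg of the bead chain at every snapshot."""
    d = traj.beads - traj.beads.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(np.einsum("tij,tij->ti", d, d), axis=1))


def _bead_frames(traj) -> tuple[np.ndarray, float]:
    if isinstance(traj, Trajectory):
        if traj.n_snapshots == 0:
            raise EmptyInputError("trajectory has no snapshots")
        return np.ascontiguousarray(traj.beads, dtype=np.float64), traj.box_edge
    arr = np.ascontiguousarray(np.asarray(traj), dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise EmptyInputError("need a (T, N, 3) snapshot array")
    return arr, -1.0


def contact_map(
    traj, threshold: float = DEFAULT_CONTACT_THRESHOLD, box_edge: float | None = None
) -> ContactMatrix:
    """Fraction of snapshots in which each bead pair is within ``threshold``."""
    frames, L = _bead_frames(traj)
    if box_edge is not None:
        L = box_edge
    counts = K.contact_counts(frames, L, threshold)
    values = counts / frames.shape[0]
    return ContactMatrix(values=values, meta={"threshold": threshold, "n_snapshots": frames.shape[0]})


def contact_probability_vs_separation(
    source, threshold: float = EXPONENT_CONTACT_THRESHOLD, box_edge: float | None = None
) -> PsCurve:
    """Average contact probability over all pairs at each contour separation."""
    if isinstance(source, ContactMatrix):
        mat = source.values
        n_snap = source.meta.get("n_snapshots", 1)
    else:
        mat = contact_map(source, threshold=threshold, box_edge=box_edge).values
        n_snap = _bead_frames(source)[0].shape[0]
    n = mat.shape[0]
    s = np.arange(1, n)
    p = np.array([np.mean(np.diagonal(mat, offset=k)) for k in s])
    counts = (n - s) * n_snap
    return PsCurve(s=s.astype(float), p=p, counts=counts.astype(float))


def fit_power_law_exponent(
    curve: PsCurve,
    window: tuple[float, float],
    bins_per_decade: int = 8,
    n_boot: int = 200,
    seed: int = 0,
) -> PowerLawFit:
    """Least-squares slope of log10 P vs log10 s over log-spaced bins.

    The decay exponent alpha is minus the slope; the CI is a bootstrap over
    bins (percentile, 68%)."""
    lo, hi = window
    m = (curve.s >= lo) & (curve.s <= hi)
    if m.sum() < 5:
        raise FitDomainError("need at least 5 points inside the fit window")
    s, p = curve.s[m], curve.p[m]
    w = curve.counts[m] if curve.counts is not None else np.ones_like(s)
    if (p <= 0).any():
        raise FitDomainError("nonpositive probabilities in fit window")
    n_bins = max(3, int(np.ceil(np.log10(hi / lo) * bins_per_decade)))
    edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        # weighted geometric mean: exact for a pure power law
        xs.append(np.average(np.log10(s[sel]), weights=w[sel]))
        ys.append(np.average(np.log10(p[sel]), weights=w[sel]))
    if len(xs) < 3:
        raise FitDomainError("fewer than 3 populated bins in fit window")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope = np.polyfit(xs, ys, 1)[0]
    rng = np.random.default_rng(seed)
    boots = []
    nb = len(xs)
    for _ in range(n_boot):
        pick = rng.integers(0, nb, size=nb)
        if np.ptp(xs[pick]) < 1e-9:
            continue
        boots.append(-np.polyfit(xs[pick], ys[pick], 1)[0])
    if boots:
        lo_ci, hi_ci = np.percentile(boots, [16, 84])
    else:
        lo_ci = hi_ci = -slope
    return PowerLawFit(alpha=float(-slope), ci_low=float(lo_ci),
                       ci_high=float(hi_ci), window=(lo, hi), n_bins=nb)


def pre_plateau_window(
    curve: PsCurve, plateau_slope: float = -0.3, s_min: float = 4.0
) -> tuple[float, float]:
    """Fit window covering up to a decade before the P_c(s) plateau.

    The plateau start is the first separation where the local log-log slope
    (on smoothed log-binned data) stays above ``plateau_slope``."""
    cur = curve.positive()
    if len(cur.s) < 8:
        raise FitDomainError("curve too short for plateau detection")
    # log-binned slope
    edges = np.geomspace(max(s_min, cur.s[0]), cur.s[-1], 25)
    mids, vals = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (cur.s >= a) & (cur.s < b)
        if sel.any():
            mids.append(np.sqrt(a * b))
            vals.append(np.mean(np.log10(cur.p[sel])))
    mids, vals = np.asarray(mids), np.asarray(vals)
    lm = np.log10(mids)
    slopes = np.gradient(vals, lm)
    plateau_at = None
    for i in range(len(mids)):
        if mids[i] > 3 * s_min and slopes[i] > plateau_slope:
            plateau_at = mids[i]
            break
    s_hi = plateau_at if plateau_at is not None else cur.s[-1] / 2
    s_lo = max(s_min, s_hi / 10.0)
    return float(s_lo), float(s_hi)


def mean_square_distance_vs_separation(traj) -> tuple[np.ndarray, np.ndarray]:
    """R^2(s): mean square distance over all pairs and snapshots (unwrapped)."""
    frames, _ = _bead_frames(traj)
    sums, counts = K.r2_by_separation(frames)
    s = np.arange(1, frames.shape[1])
    return s, sums[1:] / counts[1:]


def structure_factor(
    binder_positions,
    box_edge: float,
    k_max: float = 9.0,
    max_vectors_per_shell: int = 80,
    k_grid: np.ndarray | None = None,
    seed: int = 0,
) -> StructureFactorCurve:
    """Spherically averaged S(k) of binder positions over box-commensurate
    wavevectors; snapshots along the first axis are averaged."""
    pos = np.asarray(binder_positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    if pos.shape[1] < 1:
        raise EmptyInputError("structure factor needs at least 1 binder")
    dk = 2 * np.pi / box_edge
    if k_grid is not None:
        ratios = np.asarray(k_grid) / dk
        if np.abs(ratios - np.round(ratios)).max() > 1e-6:
            raise WavevectorError("k values must be multiples of 2*pi/edge")
        n_max = int(np.round(ratios.max()))
    else:
        n_max = int(np.floor(k_max / dk))
    grid = np.arange(-n_max, n_max + 1)
    nx, ny, nz = np.meshgrid(grid, grid, grid, indexing="ij")
    vecs = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)
    n2 = np.einsum("ij,ij->i", vecs, vecs)
    keep = (n2 > 0) & (n2 <= n_max**2)
    # half-space to avoid double counting +-k
    first = np.argmax(vecs != 0, axis=1)
    sign = vecs[np.arange(len(vecs)), first]
    keep &= sign > 0
    vecs = vecs[keep]
    n2 = n2[keep]
    rng = np.random.default_rng(seed)
    order = np.lexsort((rng.random(len(vecs)), n2))
    vecs, n2 = vecs[order], n2[order]
    sel = []
    shell_count: dict[int, int] = {}
    for i, q in enumerate(n2):
        c = shell_count.get(q, 0)
        if c < max_vectors_per_shell:
            sel.append(i)
            shell_count[q] = c + 1
    vecs = vecs[sel]
    kmags = np.sqrt(n2[sel]) * dk
    kvecs = vecs * dk
    m = pos.shape[1]
    sk_acc = np.zeros(len(kvecs))
    for t in range(pos.shape[0]):
        phase = kvecs @ pos[t].T  # (n_k, M)
        amp2 = np.cos(phase).sum(axis=1) ** 2 + np.sin(phase).sum(axis=1) ** 2
        sk_acc += amp2 / m
    sk_acc /= pos.shape[0]
    # average within |k| shells
    uk = np.unique(np.round(kmags, 9))
    sk = np.array([sk_acc[np.isclose(kmags, q)].mean() for q in uk])
    if k_grid is not None:
        want = np.isin(np.round(uk / dk).astype(int),
                       np.round(np.asarray(k_grid) / dk).astype(int))
        uk, sk = uk[want], sk[want]
    pk, props = signal.find_peaks(sk, prominence=0.0)
    peaks = [(float(uk[i]), float(sk[i]), float(pr))
             for i, pr in sorted(zip(pk, props["prominences"]),
                                 key=lambda x: -x[1])]
    return StructureFactorCurve(k=uk, sk=sk, peaks=peaks)


def structure_factor_direct(positions: np.ndarray, kvecs: np.ndarray) -> np.ndarray:
    """S(k) = |sum_j exp(i k.r_j)|^2 / M at explicit wavevectors (no
    spherical averaging); snapshots on the first axis are averaged."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    if pos.shape[1] < 1:
        raise EmptyInputError("structure factor needs at least 1 particle")
    kv = np.atleast_2d(np.asarray(kvecs, dtype=float))
    out = np.zeros(len(kv))
    for t in range(pos.shape[0]):
        phase = kv @ pos[t].T
        out += (np.cos(phase).sum(axis=1) ** 2 +
                np.sin(phase).sum(axis=1) ** 2) / pos.shape[1]
    return out / pos.shape[0]


def has_sharp_peak(
    sk: StructureFactorCurve,
    ref_window: tuple[float, float] = (3.0, 9.0),
    factor: float = 0.85,
) -> bool:
    """Ordered/disordered criterion: a short-range-structure peak whose
    prominence exceeds ``factor`` times the median S(k) over the reference
    window (the particle-scale band k in [3, 9] / sigma; empirically the
    ordered aggregate gives prominence/median >= 1.1, the disordered lump
    <= 0.65)."""
    m = (sk.k >= ref_window[0]) & (sk.k <= ref_window[1])
    if not m.any():
        raise WavevectorError("reference window contains no wavevectors")
    ref = float(np.median(sk.sk[m]))
    return any(pr > factor * ref
               for kpos, _, pr in sk.peaks
               if ref_window[0] <= kpos <= ref_window[1])


def many_body_contact_frequency(
    traj,
    threshold: float = 1.5,
    n_max: int = 10,
    s_min: int = 2,
    box_edge: float | None = None,
    baseline: np.ndarray | None = None,
    pseudocount: float | None = None,
) -> dict:
    """Mean per-snapshot counts of contact-graph connected components of size
    exactly n (n = 2..n_max); edges require contour separation >= s_min.

    ``mean_counts`` holds exact-size counts; ``cumulative_counts`` holds
    counts of components of size >= n (the robust statistic for enrichment
    ratios: in a collapsed state the contact graph percolates, so exact
    sizes starve while >= n captures the giant cluster).  ``baseline``
    (cumulative mean counts from a SAW oracle at equal N) adds a ``ratio``
    entry; zero baseline entries are floored at ``pseudocount`` (default
    1/n_snapshots) so ratios stay finite.  Events are counted as connected
    components, not cliques (recorded in metadata)."""
    if n_max < 2:
        raise DomainError("n_max must be >= 2")
    frames, L = _bead_frames(traj)
    if box_edge is not None:
        L = box_edge
    counts = K.many_body_component_counts(frames, L, threshold, s_min)
    mean_all = counts / frames.shape[0]
    cumulative = np.cumsum(mean_all[::-1])[::-1]
    out = {
        "n": np.arange(2, n_max + 1),
        "mean_counts": mean_all[2:n_max + 1],
        "cumulative_counts": cumulative[2:n_max + 1],
        "threshold": threshold,
        "s_min": s_min,
        "definition": "connected_components",
        "n_snapshots": frames.shape[0],
    }
    if baseline is not None:
        eps = pseudocount if pseudocount is not None else 1.0 / frames.shape[0]
        base = np.maximum(np.asarray(baseline, dtype=float), eps)
        out["ratio"] = np.maximum(cumulative[2:n_max + 1], 0.0) / base
    return out


def triplet_contact_probability(
    traj, threshold: float = EXPONENT_CONTACT_THRESHOLD,
    max_s: int | None = None, box_edge: float | None = None,
) -> np.ndarray:
    """P_c(s1, s2): probability that beads (i, i+s1, i+s1+s2) are pairwise in
    contact, averaged over i and snapshots; grid indexed [s1, s2], symmetric."""
    frames, L = _bead_frames(traj)
    if box_edge is not None:
        L = box_edge
    n = frames.shape[1]
    if n < 3:
        raise DomainError("need at least 3 beads for triplets")
    ms = max_s if max_s is not None else (n - 1) // 2
    if ms < 1 or 2 * ms >= n + 1:
        raise DomainError("max_s out of range (s1+s2 must stay below N)")
    hits, totals = K.triplet_contact_grid(frames, L, threshold, ms)
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(totals > 0, hits / np.maximum(totals, 1), np.nan)
    sym = 0.5 * (grid + grid.T)
    return sym


@dataclass
class StateClassification:
    state: str  # coil | globule_disordered | globule_ordered
    theta_proximal: bool
    evidence: dict


def classify_state(
    e_int: float,
    c: float,
    diagnostics: dict,
    rel_tol: float = 0.15,
    drift_tol: float = 0.12,
    peak_factor: float = 0.85,
) -> StateClassification:
    """Classify the thermodynamic state from equilibrium diagnostics.

    ``diagnostics`` must provide ``rg_mean``, ``n_beads``, ``saw_rg_mean``
    (oracle value at equal N) and optionally ``saw_rg_sd``, ``rg_series``
    (equilibration check), ``sk`` (StructureFactorCurve for the
    ordered/disordered call), ``bond_length`` (default 0.97).
    """
    rg = float(diagnostics["rg_mean"])
    n = int(diagnostics["n_beads"])
    saw_rg = float(diagnostics["saw_rg_mean"])
    saw_sd = float(diagnostics.get("saw_rg_sd", 0.0))
    series = diagnostics.get("rg_series")
    if series is not None:
        series = np.asarray(series, dtype=float)
        half = len(series) // 2
        if half >= 2:
            a, b = series[:half].mean(), series[half:].mean()
            if abs(a - b) > max(drift_tol * b, 3 * series[half:].std(ddof=1) /
                                np.sqrt(half)):
                raise NotConvergedError(
                    f"gyration radius still drifting: {a:.3f} -> {b:.3f}")
    tol = max(3 * saw_sd, rel_tol * saw_rg)
    is_coil = (e_int == 0.0 or c == 0.0) or (abs(rg - saw_rg) <= tol)
    b = float(diagnostics.get("bond_length", 0.97))
    theta_rg = b * np.sqrt(n / 6.0)
    theta_proximal = (not is_coil) and abs(rg - theta_rg) <= rel_tol * theta_rg
    evidence = {
        "rg_mean": rg, "saw_rg_mean": saw_rg, "theta_rg": theta_rg,
        "tolerance": tol,
    }
    if is_coil:
        return StateClassification("coil", theta_proximal, evidence)
    sk = diagnostics.get("sk")
    ordered = False
    if sk is not None:
        ordered = has_sharp_peak(sk, factor=peak_factor)
        evidence["sk_peaks"] = sk.peaks[:3]
    state = "globule_ordered" if ordered else "globule_disordered"
    return StateClassification(state, theta_proximal, evidence)


@dataclass
class BoundaryPairResult:
    distances_symmetric: np.ndarray
    distances_asymmetric: np.ndarray
    median_difference: float
    u_statistic: float
    p_value: float


def boundary_pair_distance_test(
    traj, boundary: int, separation: int
) -> BoundaryPairResult:
    """Compare physical distances of two equal-contour-separation pairs:
    one straddling ``boundary`` symmetrically, one asymmetrically (1/4-3/4
    split).  Positive median difference means the symmetric pair is farther."""
    frames, _ = _bead_frames(traj)
    n = frames.shape[1]
    d1 = separation // 2
    d2 = 2 * separation - d1
    i_s, j_s = boundary - separation, boundary + separation
    i_a, j_a = boundary - d1, boundary + d2
    for idx in (i_s, j_s, i_a, j_a):
        if idx < 0 or idx >= n:
            raise DomainError("separation too large for this boundary")
    def dist(i, j):
        d = frames[:, i] - frames[:, j]
        return np.sqrt(np.einsum("tj,tj->t", d, d))
    ds, da = dist(i_s, j_s), dist(i_a, j_a)
    if (i_s, j_s) == (i_a, j_a):
        return BoundaryPairResult(ds, da, 0.0, float("nan"), 1.0)
    u, p = stats.mannwhitneyu(ds, da, alternative="two-sided")
    return BoundaryPairResult(
        ds, da, float(np.median(ds) - np.median(da)), float(u), float(p)
    )
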