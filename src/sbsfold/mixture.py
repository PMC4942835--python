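"""Mixture decomposition of contact-decay curves.

An observed P(s) is modelled as a convex combination of the pure-state
contact-probability curves (coil / theta / disordered globule / ordered
globule), plus a genomic scale factor g (bp per bead).  Curves are compared
in log10 space on log-spaced bins so every decade weighs equally, and both
model and data are anchored to 1 at the smallest shared separation (contact
data have arbitrary overall scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import FitDomainError, MislabeledStateError
from .observables import PsCurve, fit_power_law_exponent

STATES = ("coil", "theta", "globule_disordered", "globule_ordered")


@dataclass
class PureStateLibrary:
    """Per-state P_c(s) curves in bead units, with provenance."""

    curves: dict[str, PsCurve]
    provenance: dict[str, dict] = field(default_factory=dict)
    min_decades: float = 2.5

    def __post_init__(self) -> None:
        missing = [s for s in STATES if s not in self.curves]
        if missing:
            raise MislabeledStateError(f"library missing states: {missing}")
        lo, hi = self.support()
        if hi / lo < 10**self.min_decades:
            raise FitDomainError(
                f"library curves must share >= {self.min_decades} decades")

    def support(self) -> tuple[float, float]:
        los, his = [], []
        for st in STATES:
            cur = self.curves[st].positive()
            los.append(cur.s.min())
            his.append(cur.s.max())
        return max(los), min(his)


@dataclass
class MixtureFit:
    weights: dict[str, float]
    g: float
    chi2: float
    weight_sd: dict[str, float]
    n_bins: int


def _log_interp(curve: PsCurve, s: np.ndarray) -> np.ndarray:
    cur = curve.positive()
    return 10 ** np.interp(np.log10(s), np.log10(cur.s), np.log10(cur.p))


def _normalized_curves(library: PureStateLibrary):
    lo, hi = library.support()
    anchors = {st: _log_interp(library.curves[st], np.array([lo]))[0]
               for st in STATES}
    return lo, hi, anchors


def evaluate_mixture(
    weights, g: float, library: PureStateLibrary, s_grid_bp: np.ndarray
) -> PsCurve:
    """P(s) = sum_i w_i P_i(s/g), components normalized to 1 at the smallest
    common bead separation; log-log interpolation in between."""
    w = _as_weight_vector(weights)
    if g <= 0:
        raise FitDomainError("scale factor g must be positive")
    s_bp = np.asarray(s_grid_bp, dtype=float)
    s_beads = s_bp / g
    lo, hi, anchors = _normalized_curves(library)
    if s_beads.min() < lo * (1 - 1e-9) or s_beads.max() > hi * (1 + 1e-9):
        raise FitDomainError(
            f"separations {s_beads.min():.3g}-{s_beads.max():.3g} beads fall "
            f"outside library support [{lo:.3g}, {hi:.3g}]")
    mix = np.zeros_like(s_beads)
    for wi, st in zip(w, STATES):
        mix += wi * _log_interp(library.curves[st], s_beads) / anchors[st]
    return PsCurve(s=s_bp, p=mix, units="bp")


def _as_weight_vector(weights) -> np.ndarray:
    if isinstance(weights, dict):
        w = np.array([weights.get(st, 0.0) for st in STATES], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (4,) or (w < -1e-9).any():
        raise FitDomainError("weights must be 4 nonnegative numbers")
    if abs(w.sum() - 1.0) > 1e-6:
        raise FitDomainError("weights must sum to 1")
    return np.clip(w, 0.0, None)


def _binned_log_curve(curve: PsCurve, bins_per_decade: int = 8):
    cur = curve.positive()
    if len(cur.s) < 4:
        raise FitDomainError("observed curve too short")
    lo, hi = cur.s.min(), cur.s.max()
    if hi / lo < 10**2:
        raise FitDomainError("observed curve must span >= 2 decades")
    n_bins = int(np.ceil(np.log10(hi / lo) * bins_per_decade))
    edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(cur.s, edges) - 1, 0, n_bins - 1)
    s_out, p_out = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            s_out.append(10 ** np.mean(np.log10(cur.s[sel])))
            p_out.append(10 ** np.mean(np.log10(cur.p[sel])))
    return np.asarray(s_out), np.asarray(p_out)


def _chi2_at_g(log_obs, s_bins, g, library, anchors, lo, hi):
    s_beads = s_bins / g
    inside = (s_beads >= lo) & (s_beads <= hi)
    if inside.sum() < max(5, 0.6 * len(s_bins)):
        return None
    basis = np.stack([
        _log_interp(library.curves[st], s_beads[inside]) / anchors[st]
        for st in STATES
    ])  # (4, n_bins)
    y = log_obs[inside]

    def objective(w):
        mix = w @ basis
        lm = np.log10(np.maximum(mix, 1e-300))
        resid = lm - y
        resid = resid - resid.mean()  # overall scale is arbitrary in P(s)
        return float(np.mean(resid**2))

    best = None
    # warm start from a nonnegative linear least-squares solution
    target_lin = 10.0**(y - y.max())
    try:
        w_nnls, _ = optimize.nnls(
            (basis / basis.mean(axis=1, keepdims=True)).T, target_lin / target_lin.mean())
        if w_nnls.sum() > 0:
            w_nnls = w_nnls / w_nnls.sum()
        else:
            w_nnls = np.full(4, 0.25)
    except Exception:
        w_nnls = np.full(4, 0.25)
    starts = [np.full(4, 0.25), w_nnls * 0.96 + 0.01]
    starts += [np.eye(4)[i] * 0.97 + 0.01 for i in range(4)]
    cons = ({"type": "eq", "fun": lambda w: w.sum() - 1.0},)
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="SLSQP", bounds=[(0.0, 1.0)] * 4,
            constraints=cons, options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.fun is not None:
            if best is None or res.fun < best[0]:
                best = (float(res.fun), np.clip(res.x, 0, None))
    if best is None:
        return None
    w = best[1] / best[1].sum()
    return best[0], w, basis, y


def fit_mixture(
    observed: PsCurve,
    library: PureStateLibrary,
    g_grid: np.ndarray | None = None,
    bins_per_decade: int = 8,
    n_boot: int = 50,
    seed: int = 0,
) -> MixtureFit:
    """Global fit of mixture weights (on the simplex) and scale factor g.

    g is scanned on a log-spaced grid (20 points per decade by default);
    at each g the weight problem is solved by constrained least squares.
    chi^2 is the mean squared log10 residual over log-spaced bins; weight
    uncertainties come from a bootstrap over bins at the best g.
    """
    s_bins, p_bins = _binned_log_curve(observed, bins_per_decade)
    log_obs = np.log10(p_bins)
    lo, hi, anchors = _normalized_curves(library)
    if g_grid is None:
        # g must place the observed window inside the library support
        g_lo = s_bins.min() / lo
        g_hi = s_bins.max() / hi
        g_min = max(g_hi, g_lo / 10**2)
        n = max(2, int(np.ceil(np.log10(g_lo / g_min) * 20)))
        g_grid = np.geomspace(g_min, g_lo, n)
    g_grid = np.sort(np.asarray(g_grid, dtype=float))
    scan = []
    for gi, g in enumerate(g_grid):
        out = _chi2_at_g(log_obs, s_bins, g, library, anchors, lo, hi)
        if out is None:
            continue
        chi2, w, basis, y = out
        scan.append((chi2, gi, w, g, basis, y))
    if not scan:
        raise FitDomainError("no overlap between observed curve and library")
    scan.sort(key=lambda x: x[0])
    best = tuple(scan[0][i] for i in (0, 2, 3, 4, 5))
    # local refinement of g around the leading grid candidates (chi2(g) can
    # have several shallow basins on sampled curves)
    if len(g_grid) > 2:
        def g_objective(log_g):
            out = _chi2_at_g(log_obs, s_bins, 10**log_g, library, anchors, lo, hi)
            return out[0] if out is not None else np.inf

        for chi2_c, gi, *_ in scan[:3]:
            lo_i = max(0, gi - 1)
            hi_i = min(len(g_grid) - 1, gi + 1)
            if lo_i == hi_i:
                continue
            res = optimize.minimize_scalar(
                g_objective, bounds=(np.log10(g_grid[lo_i]),
                                     np.log10(g_grid[hi_i])),
                method="bounded", options={"xatol": 1e-4})
            if np.isfinite(res.fun) and res.fun < best[0]:
                out = _chi2_at_g(log_obs, s_bins, 10**res.x, library,
                                 anchors, lo, hi)
                best = (out[0], out[1], 10**res.x, out[2], out[3])
    chi2, w, g, basis, y = best
    rng = np.random.default_rng(seed)
    boots = []
    nb = len(y)
    for _ in range(n_boot):
        pick = rng.integers(0, nb, size=nb)

        def objective(wv):
            mix = wv @ basis[:, pick]
            lm = np.log10(np.maximum(mix, 1e-300))
            resid = lm - y[pick]
            return float(np.mean((resid - resid.mean()) ** 2))

        res = optimize.minimize(
            objective, w, method="SLSQP", bounds=[(0.0, 1.0)] * 4,
            constraints=({"type": "eq", "fun": lambda x: x.sum() - 1.0},),
            options={"maxiter": 100},
        )
        if res.success:
            boots.append(np.clip(res.x, 0, 1))
    sd = (np.std(np.asarray(boots), axis=0, ddof=1) if len(boots) > 2
          else np.zeros(4))
    return MixtureFit(
        weights={st: float(x) for st, x in zip(STATES, w)},
        g=float(g),
        chi2=float(chi2),
        weight_sd={st: float(x) for st, x in zip(STATES, sd)},
        n_bins=nb,
    )


def detect_plateau(curve: PsCurve, slope_threshold: float = -0.3) -> bool:
    """True when the last decade of the curve decays slower than the
    threshold slope (the disordered-globule signature)."""
    cur = curve.positive()
    hi = cur.s.max()
    m = cur.s >= hi / 10
    if m.sum() < 4:
        raise FitDomainError("curve too short for plateau detection")
    slope = np.polyfit(np.log10(cur.s[m]), np.log10(cur.p[m]), 1)[0]
    return slope > slope_threshold


def trim_by_expected_hits(curve: PsCurve, min_hits: float = 5.0) -> PsCurve:
    """Drop separations whose expected contact count (p * pair count) falls
    below ``min_hits``: the noisy tail of a sampled curve."""
    if curve.counts is None:
        return curve
    keep = curve.p * curve.counts >= min_hits
    if keep.sum() < 4:
        return curve
    last = np.max(np.flatnonzero(keep))
    sl = slice(0, last + 1)
    return PsCurve(curve.s[sl], curve.p[sl], curve.counts[sl],
                   units=curve.units)


def build_pure_state_library(
    coil: PsCurve,
    theta: PsCurve,
    globule_disordered: PsCurve,
    globule_ordered: PsCurve,
    provenance: dict | None = None,
    check: bool = True,
    min_decades: float = 2.5,
    min_hits: float = 5.0,
) -> PureStateLibrary:
    """Assemble a library from independently produced pure-state curves.

    With ``check`` on, the coil curve must show a SAW-like decay exponent
    (2.1 +- 0.4 over its central window) and the disordered-globule curve a
    long plateau; violations raise a mislabeled-state error.
    """
    curves = {
        "coil": trim_by_expected_hits(coil, min_hits),
        "theta": trim_by_expected_hits(theta, min_hits),
        "globule_disordered": trim_by_expected_hits(globule_disordered, min_hits),
        "globule_ordered": trim_by_expected_hits(globule_ordered, min_hits),
    }
    if check:
        c = coil.positive()
        fit = fit_power_law_exponent(c, (10, c.s.max() / 4))
        if not (1.7 <= fit.alpha <= 2.5):
            raise MislabeledStateError(
                f"coil curve exponent {fit.alpha:.2f} is not SAW-like")
        if not detect_plateau(globule_disordered):
            raise MislabeledStateError(
                "disordered-globule curve lacks a long plateau")
    return PureStateLibrary(curves=curves, provenance=provenance or {},
                            min_decades=min_decades)
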