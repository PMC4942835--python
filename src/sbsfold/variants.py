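"""Structural variants: apply deletions to an inferred model and predict the
mutant contact map with no refitting.

Binder numbers follow the fixed-molar-concentration convention: the box and
binder counts are unchanged by a deletion (binders are a reservoir), which is
recorded in the output metadata because predictions depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InvalidVariantError, SbsfoldError
from .inference import BindingProfile, SimulationConfig, simulate_profile_map
from .observables import ContactMatrix


@dataclass
class CoordinateMap:
    """Mapping between wild-type and mutant bead coordinates."""

    old_to_new: np.ndarray  # -1 where deleted
    new_to_old: np.ndarray
    deleted: tuple[int, int]


def apply_deletion(
    profile: BindingProfile, interval: tuple[int, int]
) -> tuple[BindingProfile, CoordinateMap]:
    """Remove beads in [start, end); the chain is re-joined across the gap.

    Binder counts/concentrations are left untouched."""
    start, end = int(interval[0]), int(interval[1])
    n = profile.n_beads
    if not (0 <= start <= end <= n):
        raise InvalidVariantError(f"bad interval [{start}, {end}) for N={n}")
    if n - (end - start) < 2:
        raise InvalidVariantError("deletion leaves fewer than 2 beads")
    keep = np.ones(n, dtype=bool)
    keep[start:end] = False
    old_to_new = np.full(n, -1, dtype=np.int64)
    old_to_new[keep] = np.arange(keep.sum())
    new_to_old = np.flatnonzero(keep)
    mutant = BindingProfile(
        multiplicities=profile.multiplicities[keep].copy(),
        affinities=None if profile.affinities is None else profile.affinities.copy(),
        binder_counts=None if profile.binder_counts is None else profile.binder_counts.copy(),
        box_edge=profile.box_edge,
        m_max=profile.m_max,
    )
    return mutant, CoordinateMap(old_to_new, new_to_old, (start, end))


def apply_inversion(profile, interval):
    raise NotImplementedError("only deletions are supported")


def apply_duplication(profile, interval):
    raise NotImplementedError("only deletions are supported")


def lift_to_wildtype(
    mutant_map: ContactMatrix, coord: CoordinateMap, n_wt: int
) -> ContactMatrix:
    """Insert masked rows/columns at the deletion so the mutant map lives in
    wild-type coordinates."""
    vals = np.full((n_wt, n_wt), np.nan)
    idx = coord.new_to_old
    vals[np.ix_(idx, idx)] = mutant_map.values
    mask = np.ones(n_wt, dtype=bool)
    mask[idx] = False
    filled = np.where(np.isnan(vals), 0.0, vals)
    out = ContactMatrix(values=filled, mask=mask,
                        meta=dict(mutant_map.meta, lifted=True,
                                  deleted=coord.deleted,
                                  binder_convention="fixed_concentration"))
    return out


def drop_masked(lifted: ContactMatrix) -> np.ndarray:
    """Inverse of lifting: remove masked rows/columns."""
    if lifted.mask is None:
        return lifted.values.copy()
    keep = ~lifted.mask
    return lifted.values[np.ix_(keep, keep)]


def predict_variant_map(
    wt_profile: BindingProfile,
    deletion: tuple[int, int],
    config: SimulationConfig | None = None,
) -> dict:
    """Simulate the deleted system with identical physics and no refitting.

    Returns the mutant-coordinate map, the same map lifted to WT coordinates
    (masked at the deletion), and the coordinate mapping."""
    cfg = config or SimulationConfig()
    mutant, coord = apply_deletion(wt_profile, deletion)
    if mutant.n_beads == wt_profile.n_beads:
        mut_map = simulate_profile_map(mutant, cfg)
        return {"mutant_map": mut_map,
                "lifted_map": ContactMatrix(values=mut_map.values.copy(),
                                            meta=dict(mut_map.meta)),
                "coordinates": coord}
    mut_map = simulate_profile_map(mutant, cfg)
    lifted = lift_to_wildtype(mut_map, coord, wt_profile.n_beads)
    return {"mutant_map": mut_map, "lifted_map": lifted, "coordinates": coord}


def observed_over_expected(matrix: ContactMatrix) -> ContactMatrix:
    """Divide each diagonal by its mean over unmasked bins."""
    v = matrix.values.copy().astype(float)
    n = v.shape[0]
    mask = matrix.mask if matrix.mask is not None else np.zeros(n, dtype=bool)
    keep = ~mask
    out = np.zeros_like(v)
    for k in range(n):
        ia = np.arange(n - k)
        sel = keep[ia] & keep[ia + k]
        if not sel.any():
            continue
        mean = v[ia[sel], ia[sel] + k].mean()
        if mean > 0:
            out[ia[sel], ia[sel] + k] = v[ia[sel], ia[sel] + k] / mean
    out = np.triu(out) + np.triu(out, 1).T
    return ContactMatrix(values=out, mask=None if matrix.mask is None else matrix.mask.copy(),
                         normalization="observed_expected",
                         meta=dict(matrix.meta))


def ectopic_interaction_map(
    wt: ContactMatrix, mut_lifted: ContactMatrix
) -> np.ndarray:
    """Signed difference of observed/expected maps in WT coordinates; masked
    bins are NaN.  Positive entries are ectopic gains in the mutant."""
    if wt.values.shape != mut_lifted.values.shape:
        raise AlignmentError("maps differ in shape")
    if mut_lifted.mask is not None and wt.mask is not None:
        if not np.array_equal(wt.mask, mut_lifted.mask):
            raise AlignmentError("masks differ between maps")
    wt_oe = observed_over_expected(wt)
    # the WT map must be normalized excluding the deletion bins so that the
    # expected reference matches the mutant's support
    if mut_lifted.mask is not None:
        wt_masked = ContactMatrix(values=wt.values, mask=mut_lifted.mask,
                                  meta=dict(wt.meta))
        wt_oe = observed_over_expected(wt_masked)
    mut_oe = observed_over_expected(mut_lifted)
    diff = mut_oe.values - wt_oe.values
    if mut_lifted.mask is not None:
        m = np.asarray(mut_lifted.mask, dtype=bool)
        diff[m, :] = np.nan
        diff[:, m] = np.nan
    return diff
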