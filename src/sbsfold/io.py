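"""File formats: dense-TSV / HDF5 contact matrices, BED binding profiles,
multi-frame XYZ trajectories, YAML configs, and provenance records."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .inference import BindingProfile
from .observables import ContactMatrix

SYMMETRY_TOL = 1e-6


def write_contact_matrix(matrix: ContactMatrix, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            g = fh.create_group("contact_matrix")
            g.create_dataset("values", data=matrix.values)
            g.attrs["bin_size"] = matrix.bin_size
            g.attrs["units"] = matrix.units
            g.attrs["normalization"] = matrix.normalization
            if matrix.labels is not None:
                g.create_dataset("labels", data=np.array(matrix.labels, dtype="S"))
            if matrix.mask is not None:
                g.create_dataset("mask", data=matrix.mask.astype(np.uint8))
        return
    labels = matrix.labels or [f"bin{i}" for i in range(matrix.n_bins)]
    df = pd.DataFrame(matrix.values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.9g")


def read_contact_matrix(path) -> ContactMatrix:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            g = fh["contact_matrix"]
            values = g["values"][...]
            labels = ([s.decode() for s in g["labels"][...]]
                      if "labels" in g else None)
            mask = g["mask"][...].astype(bool) if "mask" in g else None
            meta = {k: g.attrs[k] for k in g.attrs}
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        labels = [str(x) for x in df.index]
        mask = None
        meta = {}
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError("contact matrix file is not square")
    if np.isnan(values).any():
        raise FormatError("contact matrix contains NaN entries")
    asym = np.abs(values - values.T).max()
    if asym > SYMMETRY_TOL * max(1.0, np.abs(values).max()):
        raise FormatError(f"matrix asymmetry {asym:.3g} beyond tolerance")
    values = 0.5 * (values + values.T)
    return ContactMatrix(
        values=values, labels=labels, mask=mask,
        bin_size=float(meta.get("bin_size", 1.0)),
        units=str(meta.get("units", "beads")),
        normalization=str(meta.get("normalization", "raw")),
    )


def write_ps_curve(curve, path) -> None:
    df = pd.DataFrame({"s": curve.s, "p": curve.p})
    if curve.counts is not None:
        df["count"] = curve.counts
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_ps_curve(path):
    from .observables import PsCurve

    df = pd.read_csv(path, sep="\t")
    if "s" not in df or "p" not in df:
        raise FormatError("P(s) table needs 's' and 'p' columns")
    counts = df["count"].to_numpy(float) if "count" in df else None
    return PsCurve(s=df["s"].to_numpy(float), p=df["p"].to_numpy(float),
                   counts=counts)


def write_library(library, path) -> None:
    """Pure-state curve library as an HDF5 file (one group per state)."""
    with h5py.File(path, "w") as fh:
        for state, curve in library.curves.items():
            g = fh.create_group(state)
            g.create_dataset("s", data=curve.s)
            g.create_dataset("p", data=curve.p)
            if curve.counts is not None:
                g.create_dataset("counts", data=curve.counts)
            prov = library.provenance.get(state)
            if prov:
                g.attrs["provenance"] = json.dumps(prov, default=str)


def read_library(path):
    from .mixture import PureStateLibrary, STATES
    from .observables import PsCurve

    curves, prov = {}, {}
    with h5py.File(path, "r") as fh:
        for state in STATES:
            if state not in fh:
                raise FormatError(f"library file missing state {state!r}")
            g = fh[state]
            counts = g["counts"][...] if "counts" in g else None
            curves[state] = PsCurve(s=g["s"][...], p=g["p"][...], counts=counts)
            if "provenance" in g.attrs:
                prov[state] = json.loads(g.attrs["provenance"])
    return PureStateLibrary(curves=curves, provenance=prov)


def write_binding_profile_bed(
    profile: BindingProfile, path, bin_size_bp: int = 40_000,
    chrom: str = "chr1", origin_bp: int = 0,
) -> None:
    """One BED line per maximal run of constant (color, multiplicity);
    0-based half-open coordinates, color in the name field, multiplicity in
    the score field."""
    lines = []
    m = profile.multiplicities
    for c in range(profile.n_colors):
        col = m[:, c]
        i = 0
        while i < len(col):
            if col[i] == 0:
                i += 1
                continue
            j = i
            while j < len(col) and col[j] == col[i]:
                j += 1
            lines.append((origin_bp + i * bin_size_bp,
                          origin_bp + j * bin_size_bp,
                          f"color{c}", int(col[i])))
            i = j
    lines.sort()
    with open(path, "w") as fh:
        fh.write(f'track name="binding_profile" n_beads={profile.n_beads} '
                 f'n_colors={profile.n_colors} bin_size={bin_size_bp} '
                 f'chrom={chrom} origin={origin_bp}\n')
        for start, end, name, score in lines:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t.\n")


def read_binding_profile_bed(path) -> BindingProfile:
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("track"):
                for tok in line.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v.strip('"')
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError("BED line with fewer than 5 fields")
            rows.append(parts)
    try:
        n_beads = int(header["n_beads"])
        n_colors = int(header["n_colors"])
        bin_size = int(header["bin_size"])
        origin = int(header.get("origin", 0))
    except KeyError as exc:
        raise FormatError(f"BED track header missing {exc}") from exc
    mult = np.zeros((n_beads, n_colors), dtype=np.int64)
    for _, start, end, name, score, *_ in rows:
        c = int(name.removeprefix("color"))
        b0 = (int(start) - origin) // bin_size
        b1 = (int(end) - origin) // bin_size
        mult[b0:b1, c] = int(score)
    return BindingProfile(multiplicities=mult)


def write_trajectory_xyz(traj, path, include_binders: bool = True) -> None:
    """Multi-frame XYZ; element tag encodes particle class (bead colors as
    C0, C1, ..., binders as B#); the comment line carries time and box edge."""
    with open(path, "w") as fh:
        for t in range(traj.n_snapshots):
            beads = traj.beads[t]
            binders = traj.binders[t] if include_binders else np.empty((0, 3))
            fh.write(f"{len(beads) + len(binders)}\n")
            fh.write(f"time={traj.times[t]:.6f} box={traj.box_edge:.6f}\n")
            for i, r in enumerate(beads):
                fh.write(f"C0 {r[0]:.6f} {r[1]:.6f} {r[2]:.6f}\n")
            for r in binders:
                fh.write(f"B0 {r[0]:.6f} {r[1]:.6f} {r[2]:.6f}\n")


def read_trajectory_xyz(path):
    """Returns (times, frames) where frames is a list of (tag, xyz) arrays."""
    times, frames = [], []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            comment = fh.readline()
            t = 0.0
            for tok in comment.split():
                if tok.startswith("time="):
                    t = float(tok[5:])
            tags, xyz = [], np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                tags.append(parts[0])
                xyz[i] = [float(x) for x in parts[1:4]]
            times.append(t)
            frames.append((tags, xyz))
    return np.asarray(times), frames


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config must be a flat YAML mapping")
    return cfg


def provenance_record(config: dict, seed: int) -> dict:
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }


def write_provenance(config: dict, seed: int, path) -> None:
    with open(path, "w") as fh:
        json.dump(provenance_record(config, seed), fh, indent=2)
        fh.write("\n")
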