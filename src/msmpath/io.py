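"""Readers and writers for every format the pipeline touches.

The always-available trajectory path is a simple array interchange format:
a ``.npy`` payload next to a ``.json`` header recording shape, dtype, axis
semantics and units, so tests and pipelines need no binary MD-format
dependencies. PDB structures are read with biotite; DCD/XTC trajectories
are supported through an optional mdtraj adapter.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .structure import Trajectory

__all__ = [
    "write_array",
    "read_array",
    "write_trajectory",
    "read_trajectory",
    "read_structure",
    "write_dtrajs_csv",
    "read_dtrajs_csv",
]


# ---------------------------------------------------------------------------
# Array interchange format
# ---------------------------------------------------------------------------

def write_array(path, array: np.ndarray, axes: list[str] | None = None,
                units: list[str] | None = None, **metadata) -> Path:
    """Write a dense array as ``<path>.npy`` + ``<path>.json`` header."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npy", ".json") else path
    array = np.asarray(array)
    np.save(base.with_suffix(".npy"), array)
    header = {
        "shape": list(array.shape),
        "dtype": str(array.dtype),
        "axes": axes or [f"axis{i}" for i in range(array.ndim)],
        "units": units or ["unknown"] * array.ndim,
        **metadata,
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return base.with_suffix(".npy")


def read_array(path) -> tuple[np.ndarray, dict]:
    """Read an interchange array; validates the header against the payload."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npy", ".json") else path
    npy = base.with_suffix(".npy")
    hdr = base.with_suffix(".json")
    if not npy.exists():
        raise FileNotFoundError(npy)
    try:
        array = np.load(npy)
    except Exception as err:
        raise ValueError(f"truncated or corrupt array payload {npy}: {err}") from err
    header = json.loads(hdr.read_text()) if hdr.exists() else {}
    if header.get("shape") and list(array.shape) != header["shape"]:
        raise ValueError(
            f"header shape {header['shape']} does not match payload shape {list(array.shape)}"
        )
    return array, header


def write_trajectory(path, traj: Trajectory) -> Path:
    return write_array(
        path,
        traj.coordinates,
        axes=["frame", "particle", "xyz"],
        units=["frame", "index", "angstrom"],
        frame_interval_ns=traj.frame_interval,
        particle_labels=np.asarray(traj.particle_labels).tolist(),
    )


def read_trajectory(
    path,
    topology=None,
    frame_interval: float | None = None,
    stride: int = 1,
) -> Trajectory:
    """Read a trajectory from the interchange format or (via mdtraj) DCD/XTC.

    ``frame_interval`` (ns) overrides whatever the file claims — binary
    trajectory formats rarely carry it trustworthily. ``topology`` is the
    PDB path required for DCD/XTC.
    """
    path = Path(path)
    if path.suffix in (".npy", ".json") or path.with_suffix(".npy").exists():
        coords, header = read_array(path)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"trajectory payload must be (frames, particles, 3), got {coords.shape}")
        labels = header.get("particle_labels")
        fi = frame_interval or header.get("frame_interval_ns", 1.0)
        return Trajectory(
            coords[::stride],
            frame_interval=fi * stride,
            particle_labels=np.asarray(labels) if labels is not None else None,
        )
    if path.suffix in (".dcd", ".xtc", ".trr"):
        try:
            import mdtraj
        except ImportError as err:
            raise ImportError(
                "reading DCD/XTC requires the optional mdtraj adapter "
                "(install the 'md' extra)"
            ) from err
        if topology is None:
            raise ValueError("DCD/XTC reading requires a topology PDB")
        t = mdtraj.load(str(path), top=str(topology), stride=stride)
        coords = t.xyz * 10.0  # nm -> Angstrom
        labels = np.array([a.residue.resSeq for a in t.topology.atoms])
        return Trajectory(coords, frame_interval=(frame_interval or 1.0) * stride,
                          particle_labels=labels)
    raise ValueError(f"unrecognized trajectory format: {path}")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def read_structure(path, ca_only: bool = True, residue_range: tuple[int, int] | None = None):
    """Read a PDB reference structure.

    Returns ``(coordinates (n, 3) in Angstrom, residue_numbers (n,))`` for
    the Cα selection (or all atoms with ``ca_only=False``). Altloc policy:
    the first altloc is kept, with a warning when alternates exist.
    Missing Cα in a requested residue range is an error naming the
    residues.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    altlocs = pdb.get_structure(model=1, extra_fields=["occupancy"], altloc="all")
    structure = pdb.get_structure(model=1, altloc="first")
    if len(altlocs) != len(structure):
        warnings.warn("alternate locations present; keeping first altloc", stacklevel=2)
    if ca_only:
        structure = structure[structure.atom_name == "CA"]
        if len(structure) == 0:
            raise ValueError("no Cα atoms found in structure")
    coords = np.asarray(structure.coord, dtype=float)
    resnum = np.asarray(structure.res_id)
    if residue_range is not None:
        lo, hi = residue_range
        wanted = set(range(lo, hi + 1))
        have = set(int(r) for r in resnum)
        missing = sorted(wanted - have)
        if missing and ca_only:
            raise ValueError(f"residues missing Cα atoms in range {lo}-{hi}: {missing}")
        sel = (resnum >= lo) & (resnum <= hi)
        coords, resnum = coords[sel], resnum[sel]
    return coords, resnum


# ---------------------------------------------------------------------------
# Discrete trajectories / tabular outputs
# ---------------------------------------------------------------------------

def write_dtrajs_csv(path, dtrajs) -> Path:
    """Discrete trajectories as CSV (trajectory id, frame, label)."""
    import pandas as pd

    rows = []
    for i, d in enumerate(dtrajs):
        d = np.asarray(d)
        rows.append(pd.DataFrame({"trajectory": i, "frame": np.arange(len(d)), "label": d}))
    path = Path(path)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path


def read_dtrajs_csv(path) -> list[np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        g.sort_values("frame")["label"].to_numpy(dtype=np.int64)
        for _, g in df.groupby("trajectory")
    ]
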