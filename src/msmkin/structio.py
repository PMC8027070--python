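"""Structure, trajectory and table I/O.

This module owns every on-disk artifact of the pipeline: PDB structures and
multi-model PDB trajectories (via biotite), plain coordinate tables (one frame
per row, atom order fixed by the header), the CSV table schemas shared by the
analysis stages, YAML configuration and JSON run metadata.

Binary trajectory formats (DCD/XTC) are deliberately not handled; convert
upstream to multi-model PDB or a coordinate table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("msmkin")

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Average atomic masses in Da for the elements that occur in protein
#: backbones/sidechains; anything unknown falls back to carbon with a warning.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
}


def element_from_atom_name(name: str) -> str:
    """Guess the element of a PDB atom name (``CA`` -> C, ``OXT`` -> O)."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    return stripped[0].upper()


def mass_of_element(element: str) -> float:
    el = element.strip().upper()
    if el not in ATOMIC_MASSES:
        logger.warning("unknown element %r; using carbon mass", element)
        return ATOMIC_MASSES["C"]
    return ATOMIC_MASSES[el]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StructureFrame:
    """A single conformation: parallel per-atom arrays plus frame metadata.

    Residue indices are taken verbatim from the source file (1-based,
    per-chain); no renumbering is ever performed.
    """

    chain_id: np.ndarray        # (n,) str
    res_id: np.ndarray          # (n,) int
    res_name: np.ndarray        # (n,) str
    atom_name: np.ndarray       # (n,) str
    coord: np.ndarray           # (n, 3) float, Angstrom
    mass: np.ndarray            # (n,) float, Da
    frame_index: int = 0
    time_ns: float | None = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        for name in ("chain_id", "res_id", "res_name", "atom_name"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise ValueError("coord must be (n, 3)")
        n = len(self.coord)
        if not all(len(getattr(self, f)) == n
                   for f in ("chain_id", "res_id", "res_name", "atom_name", "mass")):
            raise ValueError("per-atom arrays have inconsistent lengths")
        if n == 0:
            raise ValueError("no atoms")
        if not np.isfinite(self.coord).all():
            raise ValueError("non-finite coordinates")
        # atom names must be unique within a residue
        key = list(zip(self.chain_id.tolist(), self.res_id.tolist(),
                       self.atom_name.tolist()))
        if len(set(key)) != n:
            raise ValueError("duplicate atom name within a residue")

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    def with_coord(self, coord: np.ndarray, frame_index: int | None = None,
                   time_ns: float | None = None) -> "StructureFrame":
        """A copy of this frame carrying new coordinates."""
        out = replace(self, coord=np.asarray(coord, dtype=float))
        if frame_index is not None:
            out.frame_index = frame_index
        if time_ns is not None:
            out.time_ns = time_ns
        return out

    def atom_indices(self, chain: str, res: int,
                     atom: str | None = None) -> np.ndarray:
        mask = (self.chain_id == chain) & (self.res_id == res)
        if atom is not None:
            mask &= self.atom_name == atom
        return np.flatnonzero(mask)

    def ca_indices(self) -> np.ndarray:
        return np.flatnonzero(self.atom_name == "CA")


@dataclass(frozen=True)
class ResidueGroup:
    """A named selection of residues with an atom-name filter.

    ``atom_filter`` is one of ``"backbone"`` (N, CA, C, O), ``"ca"``,
    ``"heavy"`` (no hydrogens) or ``"all"``.
    """

    name: str
    members: tuple  # of (chain_id, res_id)
    atom_filter: str = "backbone"

    def __post_init__(self):
        object.__setattr__(self, "members",
                           tuple((str(c), int(r)) for c, r in self.members))
        if not self.members:
            raise ValueError(f"residue group {self.name!r} is empty")
        if self.atom_filter not in ("backbone", "ca", "heavy", "all"):
            raise ValueError(f"unknown atom filter {self.atom_filter!r}")

    @classmethod
    def from_range(cls, name: str, chain: str, start: int, stop: int,
                   atom_filter: str = "backbone") -> "ResidueGroup":
        """Group spanning residues ``start``..``stop`` inclusive."""
        return cls(name, tuple((chain, r) for r in range(start, stop + 1)),
                   atom_filter)

    def resolve(self, frame: StructureFrame) -> np.ndarray:
        """Atom indices of this group in ``frame``; error if unresolvable."""
        member_set = set(self.members)
        in_group = np.fromiter(
            (pair in member_set
             for pair in zip(frame.chain_id.tolist(), frame.res_id.tolist())),
            dtype=bool, count=frame.n_atoms)
        found = {pair for pair, ok in
                 zip(zip(frame.chain_id.tolist(), frame.res_id.tolist()), in_group)
                 if ok}
        missing = member_set - found
        if missing:
            raise KeyError(
                f"group {self.name!r}: residues not in structure: "
                f"{sorted(missing)[:5]}")
        if self.atom_filter == "backbone":
            in_group &= np.isin(frame.atom_name, BACKBONE_ATOMS)
        elif self.atom_filter == "ca":
            in_group &= frame.atom_name == "CA"
        elif self.atom_filter == "heavy":
            elements = np.array([element_from_atom_name(a)
                                 for a in frame.atom_name])
            in_group &= elements != "H"
        idx = np.flatnonzero(in_group)
        if idx.size == 0:
            raise ValueError(f"group {self.name!r} resolves to zero atoms")
        return idx


@dataclass
class TrajectoryEnsemble:
    """Multi-replica trajectory: shared topology + per-replica coordinates.

    ``coords[replica]`` has shape (n_frames, n_atoms, 3); all replicas share
    the atom ordering of ``topology`` and a uniform frame spacing ``dt_ns``.
    """

    topology: StructureFrame
    coords: dict[str, np.ndarray]
    dt_ns: float

    def __post_init__(self) -> None:
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        if not self.coords:
            raise ValueError("ensemble needs at least one replica")
        n = self.topology.n_atoms
        for rep, xyz in self.coords.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.ndim != 3 or xyz.shape[1:] != (n, 3):
                raise ValueError(
                    f"replica {rep!r}: coordinate block shape {xyz.shape} "
                    f"inconsistent with topology ({n} atoms)")
            if xyz.shape[0] < 2:
                raise ValueError(f"replica {rep!r} has fewer than 2 frames")
            self.coords[rep] = xyz

    @property
    def replica_ids(self) -> list[str]:
        return list(self.coords)

    @property
    def n_replicas(self) -> int:
        return len(self.coords)

    def n_frames(self, replica: str) -> int:
        return self.coords[replica].shape[0]

    @property
    def total_frames(self) -> int:
        return sum(x.shape[0] for x in self.coords.values())

    def frame(self, replica: str, i: int) -> StructureFrame:
        return self.topology.with_coord(self.coords[replica][i],
                                        frame_index=i, time_ns=i * self.dt_ns)

    def stacked(self, atom_indices: np.ndarray | None = None
                ) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """All frames stacked into one (F, n, 3) array plus (replica, frame)
        provenance for each row."""
        blocks, refs = [], []
        for rep, xyz in self.coords.items():
            blocks.append(xyz if atom_indices is None else xyz[:, atom_indices])
            refs.extend((rep, i) for i in range(xyz.shape[0]))
        return np.concatenate(blocks, axis=0), refs


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _frame_from_atom_array(atoms, frame_index: int = 0,
                           time_ns: float | None = None) -> StructureFrame:
    elements = [e if e else element_from_atom_name(a)
                for e, a in zip(atoms.element, atoms.atom_name)]
    return StructureFrame(
        chain_id=np.asarray(atoms.chain_id),
        res_id=np.asarray(atoms.res_id, dtype=int),
        res_name=np.asarray(atoms.res_name),
        atom_name=np.asarray(atoms.atom_name),
        coord=np.asarray(atoms.coord, dtype=float),
        mass=np.array([mass_of_element(e) for e in elements]),
        frame_index=frame_index,
        time_ns=time_ns,
    )


def read_structure(path: str | Path, model_index: int = 1) -> StructureFrame:
    """Read one MODEL of a PDB file (1-based ``model_index``, default first).

    Only ATOM/HETATM/MODEL/ENDMDL/TER records are interpreted; alternate
    locations other than blank/'A' are dropped (biotite ``altloc="first"``).
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no atoms")
    if not 1 <= model_index <= n_models:
        raise IndexError(
            f"{path}: model_index {model_index} out of range 1..{n_models}")
    atoms = pdb.get_structure(model=model_index, altloc="first")
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no atoms")
    return _frame_from_atom_array(atoms, frame_index=model_index - 1)


def _read_models(path: Path) -> np.ndarray:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no atoms")
    stack = pdb.get_structure(altloc="first")  # AtomArrayStack
    return np.asarray(stack.coord, dtype=float)


def write_trajectory_pdb(path: str | Path, topology: StructureFrame,
                         coords: np.ndarray) -> None:
    """Write frames as a multi-model PDB (coordinates at PDB precision)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = topology.n_atoms
    atoms = struc.AtomArray(n)
    atoms.chain_id = topology.chain_id.astype("U4")
    atoms.res_id = topology.res_id.astype(int)
    atoms.res_name = topology.res_name.astype("U5")
    atoms.atom_name = topology.atom_name.astype("U6")
    atoms.element = np.array([element_from_atom_name(a)
                              for a in topology.atom_name], dtype="U2")
    atoms.coord = coords[0]
    stack = struc.stack([atoms] * coords.shape[0])
    stack.coord = coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory(paths: Sequence[str | Path], format: str = "multi-model-pdb",
                    dt_ns: float = 1.0) -> TrajectoryEnsemble:
    """Load one replica per file into a :class:`TrajectoryEnsemble`.

    All files must share the atom ordering of the first; frames keep their
    on-disk order and are spaced uniformly by ``dt_ns``.
    """
    if dt_ns <= 0:
        raise ValueError("dt_ns must be positive")
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no trajectory files given")
    coords: dict[str, np.ndarray] = {}
    topology: StructureFrame | None = None
    for i, path in enumerate(paths):
        if format == "multi-model-pdb":
            frame0 = read_structure(path, model_index=1)
            xyz = _read_models(path)
        elif format == "coord-table":
            frame0, xyz = read_coord_table(path)
        else:
            raise ValueError(f"unknown trajectory format {format!r}")
        if topology is None:
            topology = frame0
        elif frame0.n_atoms != topology.n_atoms:
            raise ValueError(
                f"{path}: atom count {frame0.n_atoms} inconsistent with "
                f"first replica ({topology.n_atoms})")
        rep = path.stem if path.stem not in coords else f"{path.stem}_{i}"
        coords[rep] = xyz
    logger.info("read_trajectory: %d replicas, %s frames, dt=%g ns",
                len(coords), [c.shape[0] for c in coords.values()], dt_ns)
    return TrajectoryEnsemble(topology=topology, coords=coords, dt_ns=dt_ns)


# ---------------------------------------------------------------------------
# Coordinate tables (one frame per row; atom order fixed by the header)
# ---------------------------------------------------------------------------

def write_coord_table(path: str | Path, topology: StructureFrame,
                      coords: np.ndarray) -> None:
    """CSV with header tokens ``chain:res_id:res_name:atom_name:{x,y,z}`` and
    one flattened-xyz frame per row. Self-contained: the topology is
    reconstructed from the header on read."""
    coords = np.asarray(coords, dtype=float)
    cols = []
    for c, r, rn, a in zip(topology.chain_id, topology.res_id,
                           topology.res_name, topology.atom_name):
        for ax in "xyz":
            cols.append(f"{c}:{r}:{rn}:{a}:{ax}")
    flat = coords.reshape(coords.shape[0], -1)
    pd.DataFrame(flat, columns=cols).to_csv(path, index=False,
                                            float_format="%.17g")


def read_coord_table(path: str | Path) -> tuple[StructureFrame, np.ndarray]:
    df = pd.read_csv(path)
    if df.shape[1] % 3 != 0:
        raise ValueError(f"{path}: column count not a multiple of 3")
    chains, res_ids, res_names, atom_names = [], [], [], []
    for col in df.columns[::3]:
        parts = col.rsplit(":", 4)
        if len(parts) != 5 or parts[4] != "x":
            raise ValueError(f"{path}: malformed coordinate header {col!r}")
        chains.append(parts[0])
        res_ids.append(int(parts[1]))
        res_names.append(parts[2])
        atom_names.append(parts[3])
    coords = df.to_numpy(dtype=float).reshape(len(df), -1, 3)
    topo = StructureFrame(
        chain_id=np.array(chains), res_id=np.array(res_ids, dtype=int),
        res_name=np.array(res_names), atom_name=np.array(atom_names),
        coord=coords[0],
        mass=np.array([mass_of_element(element_from_atom_name(a))
                       for a in atom_names]))
    return topo, coords


# ---------------------------------------------------------------------------
# Tabular schemas
# ---------------------------------------------------------------------------

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "order-params": ("frame", "time_ns", "theta_deg", "d_ecd_7tm",
                     "d_ecd_ecl1", "d_ecd_ecl3", "state"),
    "state-sequence": ("replica", "frame", "microstate"),
    "fes-grid": ("x_index", "y_index", "x_center", "y_center", "count",
                 "free_energy_kcal_mol"),
    "pathways": ("rank", "path", "bottleneck_flux", "transition_time_ns"),
    "decomposition": ("residue", "mean_kcal_mol"),
}


def write_table(records, path: str | Path, schema: str) -> None:
    """Write a rectangular record set under a named schema.

    ``schema="matrix"`` expects a square array (optionally with ids) and
    writes row/column microstate ids; other schemas expect a DataFrame (or
    convertible) containing at least the schema's columns. Every writer
    round-trips losslessly through :func:`read_table`.
    """
    path = Path(path)
    if schema == "matrix":
        if isinstance(records, tuple):
            ids, mat = records
        else:
            mat = np.asarray(records)
            ids = list(range(mat.shape[0]))
        mat = np.asarray(mat)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("matrix schema requires a square matrix")
        df = pd.DataFrame(mat, index=[str(i) for i in ids],
                          columns=[str(i) for i in ids])
        df.index.name = "id"
        df.to_csv(path, float_format="%.17g")
        return
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    df = pd.DataFrame(records)
    if len(df):
        missing = [c for c in TABLE_SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise ValueError(f"schema {schema!r}: missing columns {missing}")
    else:
        df = pd.DataFrame(columns=list(TABLE_SCHEMAS[schema]))
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path, schema: str):
    """Read back a table written by :func:`write_table`."""
    if schema == "matrix":
        df = pd.read_csv(path, index_col=0)
        ids = [_maybe_int(i) for i in df.index]
        return ids, df.to_numpy(dtype=float)
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    return pd.read_csv(path)


def _maybe_int(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return x


# ---------------------------------------------------------------------------
# Config, metadata, logging
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def write_run_metadata(path: str | Path, metadata: Mapping) -> None:
    """Record seeds, parameters and lag times of a pipeline run as JSON."""
    with open(path, "w") as fh:
        json.dump(dict(metadata), fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
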