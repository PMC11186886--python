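"""Structure/trajectory reading and writing, and the shared coordinate model.

PDB is the interchange format (single- and multi-model, CRYST1 boxes),
handled by biotite.  Strand identity survives round-trips through a
sidecar topology CSV (chain_id, layer, strand_index); when the sidecar is
absent, strands are reconstructed from chain-id change boundaries, which
is unambiguous because strands are written as contiguous atom blocks.
Scalar density grids are exported as OpenDX text files.

Internal units: Å and ps; orthorhombic boxes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .builder import FibrilModel, ScrewParameters

__all__ = [
    "Trajectory",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "write_topology_csv",
    "read_topology_csv",
    "write_density_dx",
    "minimum_image_displacement",
]


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``atoms`` carries the
    per-atom annotations (names, residue ids, chain ids, strand_id);
    ``times`` are ps; ``box`` is per-frame orthorhombic box lengths or None.
    """

    coords: np.ndarray
    atoms: struc.AtomArray
    times: np.ndarray | None = None
    box: np.ndarray | None = None  # (n_frames, 3) or None
    topology: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.atoms.array_length():
            raise ValueError("frame atom count does not match the topology")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        self.times = np.asarray(self.times, float)
        if len(self.times) != self.n_frames:
            raise ValueError("times length must equal the number of frames")
        if np.any(np.diff(self.times) <= 0) and self.n_frames > 1:
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> struc.AtomArray:
        """A copy of the topology with frame i's coordinates (and box)."""
        arr = self.atoms.copy()
        arr.coord = self.coords[i].copy()
        if self.box is not None:
            arr.box = np.diag(self.box[i])
        return arr

    def frame_box(self, i: int) -> np.ndarray | None:
        return None if self.box is None else self.box[i]

    @classmethod
    def from_frames(cls, frames: list[struc.AtomArray], **kwargs) -> "Trajectory":
        coords = np.stack([f.coord for f in frames])
        box = None
        if frames[0].box is not None:
            box = np.stack([np.diag(f.box) for f in frames])
        return cls(coords=coords, atoms=frames[0].copy(), box=box, **kwargs)


def _read_atom_array(path: str | Path) -> struc.AtomArray:
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # pragma: no cover - error path
        raise ValueError(f"failed to parse PDB file {path}: {exc}") from exc
    return atoms


def _annotate_strands(atoms: struc.AtomArray) -> struc.AtomArray:
    """Reconstruct strand_id from chain-id change boundaries (protein atoms)."""
    strand_id = np.full(atoms.array_length(), -1, dtype=int)
    current = -1
    prev_chain = None
    for i in range(atoms.array_length()):
        if atoms.hetero[i]:
            continue
        ch = atoms.chain_id[i]
        if ch != prev_chain:
            current += 1
            prev_chain = ch
        strand_id[i] = current
    atoms.set_annotation("strand_id", strand_id)
    return atoms


def read_structure(
    path: str | Path, topology_csv: str | Path | None = None
) -> FibrilModel:
    """Read a single-model PDB as a :class:`FibrilModel`.

    If a sidecar topology CSV is given it provides layer/strand_index;
    otherwise all strands are assigned to layer 1 in file order.
    """
    atoms = _annotate_strands(_read_atom_array(path))
    n_strands = int(atoms.get_annotation("strand_id").max()) + 1
    if topology_csv is not None:
        topology = read_topology_csv(topology_csv)
        if len(topology) != n_strands:
            raise ValueError(
                f"topology CSV lists {len(topology)} strands, file has {n_strands}"
            )
    else:
        chains = []
        sid = atoms.get_annotation("strand_id")
        for k in range(n_strands):
            chains.append(atoms.chain_id[sid == k][0])
        topology = pd.DataFrame(
            {
                "strand_id": np.arange(n_strands),
                "chain_id": chains,
                "layer": 1,
                "strand_index": np.arange(n_strands),
            }
        )
    box = None
    periodic = False
    if atoms.box is not None:
        box = np.diag(atoms.box).copy()
        periodic = bool(np.all(box > 0))
    return FibrilModel(
        atoms=atoms,
        topology=topology,
        screw=ScrewParameters(),
        periodic=periodic,
        box=box,
    )


def read_trajectory(
    path: str | Path, topology_csv: str | Path | None = None
) -> Trajectory:
    """Read a multi-model PDB as a :class:`Trajectory` (MODEL records → frames)."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    atoms = _annotate_strands(stack[0].copy())
    box = None
    if stack.box is not None:
        boxes = stack.box
        if boxes.ndim == 2:
            boxes = np.repeat(boxes[None], stack.stack_depth(), axis=0)
        box = np.stack([np.diag(b) for b in boxes])
        if not np.all(box > 0):
            box = None
    topology = read_topology_csv(topology_csv) if topology_csv else None
    return Trajectory(
        coords=stack.coord.copy(), atoms=atoms, box=box, topology=topology
    )


def write_pdb(obj: FibrilModel | Trajectory | struc.AtomArray, path: str | Path) -> None:
    """Write a model, frame or trajectory as (multi-model) PDB."""
    if isinstance(obj, FibrilModel):
        atoms = obj.atoms
        if obj.box is not None and atoms.box is None:
            atoms = atoms.copy()
            atoms.box = np.diag(obj.box)
        payload = atoms
    elif isinstance(obj, Trajectory):
        stack = struc.stack([obj.frame(i) for i in range(obj.n_frames)])
        payload = stack
    else:
        payload = obj
    pdb = PDBFile()
    pdb.set_structure(payload)
    pdb.write(str(path))


def write_topology_csv(topology: pd.DataFrame, path: str | Path) -> None:
    topology.to_csv(path, index=False)


def read_topology_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"strand_id", "chain_id", "layer", "strand_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"topology CSV missing columns: {sorted(missing)}")
    return df


def write_density_dx(grid, path: str | Path) -> None:
    """Write a scalar grid as an OpenDX text file (VMD/PyMOL readable).

    ``grid`` needs attributes ``origin`` (3,), ``voxel`` (float or (3,))
    and ``data`` (3-D array); values are written in C (z-fastest) order.
    """
    origin = np.asarray(grid.origin, float)
    voxel = np.asarray(grid.voxel, float)
    if voxel.ndim == 0:
        voxel = np.repeat(voxel, 3)
    data = np.asarray(grid.data, float)
    nx, ny, nz = data.shape
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {origin[0]:.6f} {origin[1]:.6f} {origin[2]:.6f}\n")
        fh.write(f"delta {voxel[0]:.6f} 0.0 0.0\n")
        fh.write(f"delta 0.0 {voxel[1]:.6f} 0.0\n")
        fh.write(f"delta 0.0 0.0 {voxel[2]:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {data.size} data follows\n"
        )
        flat = data.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.8g}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def minimum_image_displacement(
    delta: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``box`` is the 3 orthorhombic box lengths; None means no periodicity.
    """
    delta = np.asarray(delta, float)
    if box is None:
        return delta
    box = np.asarray(box, float)
    return delta - box * np.round(delta / box)
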