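"""Construction of finite and periodic two-layer cross-β protofibril models.

A protofibril model is assembled from a single template strand by a screw
operation (rise ~4.8 Å and a signed per-strand twist about the fibril
axis), duplicated into a second layer by a 180° rotation about the same
axis (C2 pseudosymmetry), and optionally closed into a periodic unit whose
per-layer strand count n satisfies n·twist ≈ 180° so that the rotated
continuation is seamless.  Solvent ions (Na⁺/Cl⁻/Zn²⁺) are counted from a
salt concentration, a per-monomer Zn²⁺ equivalent and a neutralization
constraint, and placed uniformly at random in the solvent region.

The build frame convention is: fibril axis = +z, origin at the layer-1
centroid.  Analysis modules never rely on this; they re-estimate the axis.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from scipy.constants import Avogadro
from scipy.spatial import cKDTree

from . import geometry
from .geometry import rotation_about_axis
from .sequences import AbetaSequence, variant_sequence

__all__ = [
    "StrandTemplate",
    "ScrewParameters",
    "FibrilModel",
    "IonRecipe",
    "IonCounts",
    "hairpin_template",
    "replicate_strand",
    "c2_assemble",
    "extend_n_terminus",
    "size_periodic_unit",
    "ion_counts",
    "place_ions",
    "build_fibril",
]

#: chain-id alphabet; cycled when a model has more chains than characters
CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits

ION_RES_NAMES = {"Na": "NA", "Cl": "CL", "Zn": "ZN"}
ION_CHARGES = {"Na": +1, "Cl": -1, "Zn": +2}


@dataclass(frozen=True)
class ScrewParameters:
    """Screw (helical) symmetry: rotate by ``twist`` and rise along ``axis``."""

    rise: float = 4.8  # Å per strand
    twist: float = 0.0  # degrees per strand, signed (right-handed positive)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if np.linalg.norm(self.axis) < 1e-12:
            raise ValueError("degenerate axis")
        object.__setattr__(
            self, "axis", tuple(np.asarray(self.axis, float) / np.linalg.norm(self.axis))
        )

    def transform(self, k: float) -> tuple[np.ndarray, np.ndarray]:
        """Rotation matrix and translation of the k-th power of the screw."""
        R = rotation_about_axis(self.axis, k * self.twist)
        o = np.asarray(self.origin, float)
        t = o - R @ o + k * self.rise * np.asarray(self.axis)
        return R, t

    def apply(self, coords: np.ndarray, k: float) -> np.ndarray:
        R, t = self.transform(k)
        return coords @ R.T + t


@dataclass
class StrandTemplate:
    """A single peptide strand used as the repeating unit of the fibril."""

    atoms: struc.AtomArray
    source: str = ""

    def __post_init__(self) -> None:
        res_ids = np.unique(self.atoms.res_id[~self.atoms.hetero])
        if res_ids.min() < 1 or res_ids.max() > 42:
            raise ValueError("template residue positions must map into 1..42")
        for r in res_ids:
            sel = (self.atoms.res_id == r) & (self.atoms.atom_name == "CA")
            if not sel.any():
                raise ValueError(f"template residue {r} lacks a CA atom")

    @classmethod
    def from_pdb(cls, path: str | Path, chain: str | None = None) -> "StrandTemplate":
        from .trajectory_io import _read_atom_array

        atoms = _read_atom_array(path)
        if chain is not None:
            atoms = atoms[atoms.chain_id == chain]
        if atoms.array_length() == 0:
            raise ValueError(f"no atoms read from {path} (chain={chain!r})")
        return cls(atoms=atoms, source=f"{path}:{chain or 'all'}")


@dataclass
class FibrilModel:
    """Atoms plus the chain → (layer, strand_index) topology of a built model."""

    atoms: struc.AtomArray
    topology: pd.DataFrame  # columns: strand_id, chain_id, layer, strand_index
    screw: ScrewParameters
    periodic: bool = False
    box: np.ndarray | None = None  # 3 orthorhombic box lengths, Å

    @property
    def n_strands(self) -> int:
        return len(self.topology)

    @property
    def protein(self) -> struc.AtomArray:
        return self.atoms[~self.atoms.hetero]

    @property
    def ions(self) -> struc.AtomArray:
        return self.atoms[self.atoms.hetero]

    def strand(self, strand_id: int) -> struc.AtomArray:
        return self.atoms[
            (~self.atoms.hetero) & (self.atoms.get_annotation("strand_id") == strand_id)
        ]

    def layer_strands(self, layer: int) -> list[int]:
        sub = self.topology[self.topology.layer == layer]
        return list(sub.sort_values("strand_index").strand_id)


@dataclass(frozen=True)
class IonRecipe:
    """Solvent ion prescription: salt concentration plus Zn²⁺ equivalents."""

    concentration: float = 0.0  # mol/L NaCl
    zn_equivalents: float = 0.0  # Zn²⁺ per peptide monomer
    neutralize: bool = True


@dataclass(frozen=True)
class IonCounts:
    n_na: int
    n_cl: int
    n_zn: int

    def total_charge(self) -> int:
        return self.n_na + 2 * self.n_zn - self.n_cl

    def as_dict(self) -> dict[str, int]:
        return {"Na": self.n_na, "Cl": self.n_cl, "Zn": self.n_zn}


def hairpin_template(
    sequence: AbetaSequence | str = "human",
    *,
    first_residue: int = 17,
    dihedrals: tuple[float, float] = geometry.PARALLEL_BETA,
) -> StrandTemplate:
    """Build a U-folded (β-arch-like) template strand for residues ``first_residue``..42.

    The strand runs extended from ``first_residue`` to 26, reverses through
    a four-residue turn (27–30) and comes back extended (31–42), so that
    the two halves form the intra-layer steric-zipper interface and the
    C-terminal carboxylate ends up near the N-terminal side of the strand
    — the fold feature that makes Ala42 reachable from the N-terminal
    domain.  The strand is centred and laid out in the xy plane (fibril
    axis = z).
    """
    if isinstance(sequence, str):
        sequence = variant_sequence(sequence)
    if not first_residue <= 26:
        raise ValueError("hairpin template must start at or before residue 26")
    seq_str = str(sequence)[first_residue - 1 :]
    n_lead = 27 - first_residue
    pp = (
        [dihedrals] * n_lead
        + list(geometry.HAIRPIN_TURN)
        + [dihedrals] * (42 - 31 + 1)
    )
    atoms = geometry.build_chain(seq_str, pp, start_res=first_residue)
    # centre, and put the dominant in-plane direction along x
    coords = atoms.coord - atoms.coord.mean(axis=0)
    ca = coords[atoms.atom_name == "CA"]
    u, s, vt = np.linalg.svd(ca - ca.mean(axis=0))
    R = vt  # rows: principal directions -> maps them to x, y, z
    if np.linalg.det(R) < 0:
        R = np.diag([1.0, 1.0, -1.0]) @ R
    atoms = atoms.copy()
    atoms.coord = coords @ R.T
    return StrandTemplate(atoms=atoms, source=f"hairpin:{sequence.variant_id}")


def replicate_strand(
    template: StrandTemplate | struc.AtomArray,
    n: int,
    screw: ScrewParameters,
) -> struc.AtomArray:
    """Stack ``n`` copies of the template under successive screw powers.

    Strand k is the template rotated by k·twist about the axis and
    translated by k·rise along it; copies carry ``strand_id`` annotations
    0..n−1 and chain ids cycling through the chain-id alphabet.
    """
    if n < 1:
        raise ValueError("need at least one strand")
    base = template.atoms if isinstance(template, StrandTemplate) else template
    copies = []
    for k in range(n):
        c = base.copy()
        c.coord = screw.apply(base.coord, k)
        c.chain_id = np.full(c.array_length(), CHAIN_IDS[k % len(CHAIN_IDS)])
        c.set_annotation("strand_id", np.full(c.array_length(), k, dtype=int))
        copies.append(c)
    out = copies[0]
    for c in copies[1:]:
        out += c
    return out


def c2_assemble(
    layer: struc.AtomArray,
    *,
    screw: ScrewParameters = ScrewParameters(),
    axial_shift: float | None = None,
    clash_distance: float = 1.5,
) -> FibrilModel:
    """Duplicate a layer by a 180° rotation about the fibril axis.

    The second layer is the C2 image of the first, offset along the axis
    by ``axial_shift`` (default: half the rise, the stagger that
    interdigitates the two layers).  Chain ids continue past layer 1's,
    and the topology table records (layer, strand_index) per strand.
    Heavy-atom clashes closer than ``clash_distance`` raise a warning.
    """
    if axial_shift is None:
        axial_shift = screw.rise / 2.0
    strand_ids = layer.get_annotation("strand_id")
    n_per_layer = int(strand_ids.max()) + 1
    R = rotation_about_axis(screw.axis, 180.0)
    o = np.asarray(screw.origin, float)
    second = layer.copy()
    second.coord = (layer.coord - o) @ R.T + o + axial_shift * np.asarray(screw.axis)
    second.set_annotation("strand_id", strand_ids + n_per_layer)
    second.chain_id = np.array(
        [CHAIN_IDS[(s + n_per_layer) % len(CHAIN_IDS)] for s in strand_ids]
    )
    atoms = layer + second

    heavy = atoms.element != "H"
    tree = cKDTree(layer.coord[layer.element != "H"])
    close = tree.query_ball_point(second.coord[second.element != "H"], clash_distance)
    n_clash = sum(1 for c in close if c)
    if n_clash:
        warnings.warn(
            f"{n_clash} heavy atoms of the C2 layer lie within "
            f"{clash_distance} Å of layer 1",
            stacklevel=2,
        )

    rows = []
    for layer_no, offset in ((1, 0), (2, n_per_layer)):
        for k in range(n_per_layer):
            sid = k + offset
            rows.append(
                {
                    "strand_id": sid,
                    "chain_id": CHAIN_IDS[sid % len(CHAIN_IDS)],
                    "layer": layer_no,
                    "strand_index": k,
                }
            )
    topology = pd.DataFrame(rows)
    return FibrilModel(atoms=atoms, topology=topology, screw=screw)


def extend_n_terminus(
    chain: struc.AtomArray,
    prefix: str,
    *,
    dihedrals: tuple[float, float] = geometry.EXTENDED_BETA,
    clash_distance: float = 1.0,
) -> struc.AtomArray:
    """Prepend ``prefix`` residues (ending at the chain's first residue − 1)
    in an extended conformation with ideal bond geometry.

    The prefix backbone is built together with a copy of the chain's first
    residue, superposed on that residue's N/CA/C atoms, and the prefix
    atoms are grafted on.  An empty prefix returns the chain unchanged.
    """
    if len(prefix) == 0:
        return chain
    first = int(chain.res_id[~chain.hetero].min())
    start = first - len(prefix)
    if start < 1:
        raise ValueError("prefix would extend below residue 1")
    # build prefix plus one anchor residue in the target conformation
    anchor_aa = "A"  # only backbone N/CA/C of the anchor is used
    built = geometry.build_chain(
        prefix + anchor_aa, dihedrals, start_res=start, with_oxt=False
    )
    anchor_res = start + len(prefix)

    def _bb(arr, res, names):
        return np.array(
            [arr.coord[(arr.res_id == res) & (arr.atom_name == nm)][0] for nm in names]
        )

    names = ("N", "CA", "C")
    _, R, _ = geometry.superpose(_bb(built, anchor_res, names), _bb(chain, first, names))
    # apply the same rigid map used for the anchor superposition
    prefix_atoms = built[built.res_id < anchor_res].copy()
    mob_centroid = _bb(built, anchor_res, names).mean(axis=0)
    ref_centroid = _bb(chain, first, names).mean(axis=0)
    prefix_atoms.coord = (prefix_atoms.coord - mob_centroid) @ R.T + ref_centroid
    prefix_atoms.chain_id = np.full(prefix_atoms.array_length(), chain.chain_id[0])
    for ann in chain.get_annotation_categories():
        if ann not in prefix_atoms.get_annotation_categories():
            fill = chain.get_annotation(ann)[0]
            prefix_atoms.set_annotation(
                ann, np.full(prefix_atoms.array_length(), fill)
            )

    tree = cKDTree(chain.coord)
    close = tree.query_ball_point(prefix_atoms.coord, clash_distance)
    n_clash = sum(1 for c in close if c)
    if n_clash:
        warnings.warn(
            f"{n_clash} prefix atoms clash with the existing chain within "
            f"{clash_distance} Å",
            stacklevel=2,
        )
    return prefix_atoms + chain


def size_periodic_unit(twist: float, *, tolerance: float | None = None) -> int:
    """Number of strands per layer for a seamless 180°-twist periodic unit.

    Returns the integer n minimizing |n·twist − 180°| (ties toward smaller
    n).  With C2 pseudosymmetry the 180°-rotated continuation of the unit
    is indistinguishable from the next period, so the box repeats along
    the axis every n·rise.
    """
    if not 0 < twist <= 180:
        raise ValueError("twist must lie in (0, 180] degrees per strand")
    n_float = 180.0 / twist
    candidates = {max(1, int(np.floor(n_float))), int(np.ceil(n_float))}
    return min(candidates, key=lambda n: (abs(n * twist - 180.0), n))


def ion_counts(
    protein_charge_per_chain: int,
    n_chains: int,
    recipe: IonRecipe = IonRecipe(),
    *,
    box_volume: float | None = None,
) -> IonCounts:
    """Ion counts neutralizing the system at a given salt concentration.

    ``n_zn`` = zn_equivalents × n_chains; ``n_cl`` from concentration ×
    box volume (Å³); ``n_na`` balances the total charge.  Counts round
    half away from zero; neutrality is restored after rounding via n_na.
    """
    def _round(x: float) -> int:
        return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))

    n_zn = _round(recipe.zn_equivalents * n_chains)
    if recipe.concentration > 0:
        if box_volume is None or box_volume <= 0:
            raise ValueError("positive box_volume required at non-zero concentration")
        n_cl = _round(recipe.concentration * Avogadro * box_volume * 1e-27)
    else:
        n_cl = 0
    protein_charge = protein_charge_per_chain * n_chains
    if recipe.neutralize:
        n_na = -(protein_charge + 2 * n_zn - n_cl)
    else:
        n_na = _round(recipe.concentration * Avogadro * (box_volume or 0.0) * 1e-27)
    if min(n_na, n_cl, n_zn) < 0:
        raise ValueError(
            f"cannot neutralize with non-negative counts: "
            f"Na={n_na}, Cl={n_cl}, Zn={n_zn} "
            f"(protein charge {protein_charge})"
        )
    return IonCounts(n_na=n_na, n_cl=n_cl, n_zn=n_zn)


def place_ions(
    model: FibrilModel,
    counts: IonCounts,
    seed: int | np.random.Generator,
    *,
    clearance: float = 2.5,
    max_attempts: int = 10000,
) -> FibrilModel:
    """Place ions uniformly at random in the box, away from protein and each other.

    Reproducible under a fixed seed.  Raises if the clearance cannot be
    satisfied for every ion within the attempt budget.
    """
    if model.box is None:
        raise ValueError("model needs a box before ions can be placed")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    species_list = [s for s, n in (("Na", counts.n_na), ("Cl", counts.n_cl), ("Zn", counts.n_zn)) for _ in range(n)]
    if not species_list:
        return model
    protein_tree = cKDTree(model.protein.coord)
    placed: list[np.ndarray] = []
    box = np.asarray(model.box, float)
    for _ in species_list:
        ok = False
        for _attempt in range(max_attempts):
            pos = rng.random(3) * box
            if protein_tree.query(pos)[0] < clearance:
                continue
            if placed and cKDTree(np.array(placed)).query(pos)[0] < clearance:
                continue
            placed.append(pos)
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place all {len(species_list)} ions at a "
                f"{clearance} Å clearance"
            )
    ions = struc.AtomArray(len(species_list))
    ions.coord = np.array(placed)
    ions.atom_name = np.array([ION_RES_NAMES[s] for s in species_list])
    ions.res_name = np.array([ION_RES_NAMES[s] for s in species_list])
    ions.element = np.array([s.upper() for s in species_list])
    ions.chain_id = np.full(len(species_list), "i")
    ions.res_id = np.arange(1, len(species_list) + 1)
    ions.hetero = np.ones(len(species_list), bool)
    ions.set_annotation("strand_id", np.full(len(species_list), -1, dtype=int))
    atoms = model.atoms + ions
    return replace(model, atoms=atoms)


def build_fibril(
    variant: str | AbetaSequence = "human",
    *,
    n_per_layer: int = 18,
    layers: int = 2,
    screw: ScrewParameters = ScrewParameters(),
    full_length: bool = True,
    periodic: bool = False,
    box_margin: float = 25.0,
    interlayer_gap: float = 10.0,
) -> FibrilModel:
    """Convenience constructor: template → layer → C2 model (→ periodic box).

    ``full_length=True`` prepends residues 1–16 in extended conformation
    to the 17–42 hairpin template before replication.  For a periodic
    model, ``n_per_layer`` should come from :func:`size_periodic_unit` and
    the box length along the axis is n·rise.
    """
    seq = variant if isinstance(variant, AbetaSequence) else variant_sequence(variant)
    template = hairpin_template(seq)
    chain = template.atoms
    if full_length:
        chain = extend_n_terminus(chain, str(seq)[:16])
        # re-centre so the fibril axis passes through the strand core
        core = chain.coord[(chain.res_id >= 17) & (chain.atom_name == "CA")]
        shifted = chain.copy()
        shifted.coord = chain.coord - core.mean(axis=0)
        chain = shifted
    if layers == 2:
        # lift the layer off the C2 axis so its 180° image faces it across
        # the inter-layer zipper gap instead of overlapping it
        lifted = chain.copy()
        lifted.coord = chain.coord + np.array(
            [0.0, interlayer_gap / 2.0 - chain.coord[:, 1].min(), 0.0]
        )
        chain = lifted
    layer = replicate_strand(StrandTemplate(chain, source=template.source), n_per_layer, screw)
    if layers == 2:
        model = c2_assemble(layer, screw=screw)
    elif layers == 1:
        strand_ids = layer.get_annotation("strand_id")
        topology = pd.DataFrame(
            {
                "strand_id": np.arange(n_per_layer),
                "chain_id": [CHAIN_IDS[k % len(CHAIN_IDS)] for k in range(n_per_layer)],
                "layer": 1,
                "strand_index": np.arange(n_per_layer),
            }
        )
        model = FibrilModel(atoms=layer, topology=topology, screw=screw)
    else:
        raise ValueError("layers must be 1 or 2")
    xy_extent = np.ptp(model.atoms.coord[:, :2], axis=0).max()
    if periodic:
        mismatch = abs(n_per_layer * screw.twist - 180.0)
        if mismatch > 0.5 * abs(screw.twist or 1.0):
            warnings.warn(
                f"n·twist deviates from 180° by {mismatch:.2f}°; the periodic "
                "seam will be strained",
                stacklevel=2,
            )
        lz = n_per_layer * screw.rise
        lxy = xy_extent + 2 * box_margin
        box = np.array([lxy, lxy, lz])
    else:
        extent = np.ptp(model.atoms.coord, axis=0)
        box = extent + 2 * box_margin
    # shift coordinates into the box (positive octant)
    shifted = model.atoms.copy()
    offset = box / 2.0 - model.atoms.coord.mean(axis=0)
    shifted.coord = model.atoms.coord + offset
    shifted.box = np.diag(box)
    model = replace(model, atoms=shifted, periodic=periodic, box=box)
    # keep the screw origin consistent with the shifted frame
    new_origin = tuple(np.asarray(model.screw.origin, float) + offset)
    model.screw = replace(model.screw, origin=new_origin)
    return model
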