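"""Aβ42 sequence variants, residue classification and formal-charge bookkeeping.

The amyloid-β(1–42) peptide carries a hydrophilic N-terminal domain
(residues 1–16) and a hydrophobic, β-sheet-forming core (17–42).  Several
disease-modifying variants differ only at N-terminal positions: the
AD-promoting Tottori substitution D7N and the protective rodent sequence
(R5G, Y10F, H13R).  At neutral pH, with histidines modelled as the neutral
Nδ tautomer, every Asp/Glu side chain contributes −1, every Arg/Lys +1,
the free N-terminal amine +1 and the C-terminal carboxylate −1.  This
module encodes those conventions so that per-strand and per-domain formal
charges can be tallied exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "AbetaSequence",
    "ProtonationModel",
    "DomainDefinition",
    "HUMAN_AB42",
    "BUILTIN_VARIANTS",
    "N_TERMINAL",
    "N_TAIL",
    "HYDROPHOBIC_CORE",
    "ACIDIC_DOMAIN",
    "FULL_LENGTH",
    "variant_sequence",
    "classify_residues",
    "net_formal_charge",
    "domain_charge",
    "acidic_face_positions",
    "write_fasta",
    "read_fasta",
    "write_substitutions_csv",
]

#: Human Aβ42, one-letter codes, positions 1..42 (standard Aβ numbering).
HUMAN_AB42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

#: Substitutions of the built-in variants relative to the human sequence,
#: as (1-based position, from, to).
BUILTIN_VARIANTS: dict[str, tuple[tuple[int, str, str], ...]] = {
    "human": (),
    "tottori": ((7, "D", "N"),),
    "rodent": ((5, "R", "G"), (10, "Y", "F"), (13, "H", "R")),
}

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Side-chain formal charges at neutral pH (His neutral, Nδ tautomer).
SIDECHAIN_CHARGE = {"D": -1, "E": -1, "R": +1, "K": +1}

_ACIDIC = set("DE")
_BASIC = set("RKH")
_POLAR = set("STNQYC")  # glycine handled via the ``glycine_polar`` switch


@dataclass(frozen=True)
class AbetaSequence:
    """A 42-residue Aβ variant with its substitution record."""

    variant_id: str
    residues: tuple[str, ...]
    substitutions: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        bad = [r for r in self.residues if r not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"non-amino-acid one-letter codes: {sorted(set(bad))}")
        if len(self.residues) != 42:
            raise ValueError(
                f"Aβ numbering requires exactly 42 residues, got {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        """Residue at a 1-based Aβ position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]

    def __str__(self) -> str:
        return "".join(self.residues)


@dataclass(frozen=True)
class ProtonationModel:
    """Protonation conventions; only the neutral-pH regime is modelled."""

    ph_regime: str = "neutral"
    his_state: str = "ND1"  # neutral imidazole, proton on Nδ
    n_terminal_amine: bool = True  # free amine, +1
    c_terminal_carboxylate: bool = True  # free carboxylate, −1

    def __post_init__(self) -> None:
        if self.ph_regime != "neutral":
            raise ValueError("only the neutral pH regime is supported")


@dataclass(frozen=True)
class DomainDefinition:
    """A named set of 1-based Aβ positions."""

    name: str
    positions: frozenset[int]

    def __post_init__(self) -> None:
        if any(not 1 <= p <= 42 for p in self.positions):
            raise ValueError(f"domain {self.name!r} has positions outside 1..42")


N_TERMINAL = DomainDefinition("n_terminal", frozenset(range(1, 17)))
N_TAIL = DomainDefinition("n_tail", frozenset(range(1, 10)))
HYDROPHOBIC_CORE = DomainDefinition("hydrophobic_core", frozenset(range(17, 43)))
#: Positions forming the N-terminal acidic β-sheet domain: the acidic
#: residues Asp1/Glu3/Asp7/Glu11 plus Arg5 and His13 on the same face, and
#: Ala42 whose C-terminal carboxylate reaches the N-terminal region.
ACIDIC_DOMAIN = DomainDefinition("acidic_domain", frozenset({1, 3, 5, 7, 11, 13, 42}))
FULL_LENGTH = DomainDefinition("full_length", frozenset(range(1, 43)))


def variant_sequence(variant_id: str) -> AbetaSequence:
    """Return a built-in Aβ42 variant or validate a custom 42-mer.

    Parameters
    ----------
    variant_id : str
        One of ``"human"``, ``"tottori"``, ``"rodent"``, or a custom
        42-character one-letter sequence.  Custom sequences keep standard
        Aβ numbering; any other length is rejected rather than renumbered.
    """
    key = variant_id.lower()
    if key in BUILTIN_VARIANTS:
        residues = list(HUMAN_AB42)
        subs = BUILTIN_VARIANTS[key]
        for pos, old, new in subs:
            if residues[pos - 1] != old:
                raise AssertionError("built-in substitution table inconsistent")
            residues[pos - 1] = new
        return AbetaSequence(key, tuple(residues), subs)
    candidate = variant_id.upper()
    if len(candidate) != 42:
        raise ValueError(
            f"unknown variant {variant_id!r}: custom sequences must be "
            f"42 one-letter codes (got length {len(variant_id)})"
        )
    subs = tuple(
        (i + 1, h, c) for i, (h, c) in enumerate(zip(HUMAN_AB42, candidate)) if h != c
    )
    return AbetaSequence("custom", tuple(candidate), subs)


def classify_residues(
    seq: AbetaSequence, *, glycine_polar: bool = True
) -> dict[int, str]:
    """Map each 1-based position to acidic | basic | polar | nonpolar.

    Glycine is classed polar by default (four-way colouring convention);
    set ``glycine_polar=False`` to count it nonpolar.
    """
    out: dict[int, str] = {}
    for pos in range(1, len(seq) + 1):
        aa = seq[pos]
        if aa in _ACIDIC:
            out[pos] = "acidic"
        elif aa in _BASIC:
            out[pos] = "basic"
        elif aa in _POLAR or (aa == "G" and glycine_polar):
            out[pos] = "polar"
        else:
            out[pos] = "nonpolar"
    return out


def net_formal_charge(
    seq: AbetaSequence, prot: ProtonationModel = ProtonationModel()
) -> int:
    """Net formal charge of one strand: side chains plus termini."""
    total = sum(SIDECHAIN_CHARGE.get(seq[p], 0) for p in range(1, len(seq) + 1))
    if prot.n_terminal_amine:
        total += 1
    if prot.c_terminal_carboxylate:
        total -= 1
    return total


def domain_charge(
    seq: AbetaSequence,
    dom: DomainDefinition,
    prot: ProtonationModel = ProtonationModel(),
) -> int:
    """Formal charge summed over a domain's positions.

    Convention: the C-terminal carboxylate (−1) is attributed to position
    42 when the domain includes it, but the N-terminal amine (+1) is NOT
    attributed to position 1 — it belongs to the backbone terminus, not to
    the Asp1 side chain.  Under this convention the acidic β-sheet domain
    {1,3,5,7,11,13,42} tallies −4 for human Aβ42, and domain charges are
    additive over disjoint domains with
    ``net = Σ domain_charge(partition) + 1``.
    """
    for p in dom.positions:
        if not 1 <= p <= len(seq):
            raise ValueError(f"domain position {p} outside 1..{len(seq)}")
    total = sum(SIDECHAIN_CHARGE.get(seq[p], 0) for p in dom.positions)
    if prot.c_terminal_carboxylate and len(seq) in dom.positions:
        total -= 1
    return total


def acidic_face_positions(
    seq: AbetaSequence, region: DomainDefinition = N_TERMINAL
) -> frozenset[int]:
    """Positions in ``region`` whose side chains are acidic (Asp/Glu).

    For human Aβ42 and the N-terminal domain this is {1, 3, 7, 11} — all
    odd, i.e. on a single face of an in-register β-strand, the geometric
    basis of the acidic β-sheet domain.
    """
    return frozenset(p for p in region.positions if seq[p] in _ACIDIC)


# -- external interfaces -----------------------------------------------------


def write_fasta(seq: AbetaSequence, path: str | Path) -> None:
    """Write a variant as a single-record FASTA file."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(str(seq)), id=f"abeta42_{seq.variant_id}", description="")
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path: str | Path) -> AbetaSequence:
    """Read a single-record FASTA file as a (custom) Aβ42 sequence."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    return variant_sequence(str(records[0].seq))


def write_substitutions_csv(seq: AbetaSequence, path: str | Path) -> None:
    """Write the variant's substitution table as CSV (position, from, to)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["position", "from", "to"])
        for pos, old, new in seq.substitutions:
            writer.writerow([pos, old, new])
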