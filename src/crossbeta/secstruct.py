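"""Secondary-structure assignment from backbone hydrogen bonds, and
per-residue / per-domain incidence statistics.

The assigner implements the Kabsch–Sander electrostatic hydrogen-bond
model: a bond from the N–H of one residue to the C=O of another is
recorded when

    E = 0.42 · 0.20 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  <  −0.5 kcal/mol.

Parallel and antiparallel bridges follow the standard patterns; ladders of
two or more consecutive bridges are labelled E (β-sheet), isolated
bridges B, α-helical i→i+4 bond runs H, other turns T, and the remainder
coil C.  Amide hydrogens are reconstructed geometrically when absent
(N–H along the bisector of C(i−1)–N and CA–N, 1.01 Å).

Absolute β percentages from this scheme can differ by a few points from
dihedral-augmented assigners (e.g. STRIDE); incidence comparisons should
stay within one method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sequences import DomainDefinition
from .trajectory_io import Trajectory

__all__ = [
    "SSAssignment",
    "backbone_hbonds",
    "assign_ss",
    "incidence",
]

KS_COUPLING = 0.42 * 0.20 * 332.0  # kcal·Å/mol
HBOND_CUTOFF = -0.5  # kcal/mol
CA_PREFILTER = 9.0  # Å; pairs with more distant CA cannot H-bond
N_H_LENGTH = 1.01  # Å

MOTIFS = ("E", "B", "H", "T", "C")


@dataclass
class SSAssignment:
    """Per-residue labels for one frame.

    ``labels[k]`` is the motif of residue ``residues[k]``, where
    ``residues`` lists (strand_id, res_id) in atom order.
    """

    residues: list[tuple[int, int]]
    labels: np.ndarray

    def as_dict(self) -> dict[tuple[int, int], str]:
        return {key: str(lab) for key, lab in zip(self.residues, self.labels)}

    def fraction(self, motif: str) -> float:
        return float(np.mean(self.labels == motif))


def _collect_backbone(frame):
    """Group backbone atoms per residue; returns residue keys and coordinate dict."""
    protein = frame[~frame.hetero]
    sid = protein.get_annotation("strand_id")
    keys: list[tuple[int, int]] = []
    coords: dict[str, list[np.ndarray | None]] = {n: [] for n in ("N", "CA", "C", "O", "H")}
    seen = set()
    order = []
    for i in range(protein.array_length()):
        key = (int(sid[i]), int(protein.res_id[i]))
        if key not in seen:
            seen.add(key)
            order.append(key)
    index = {key: k for k, key in enumerate(order)}
    for name in coords:
        coords[name] = [None] * len(order)
    for i in range(protein.array_length()):
        key = (int(sid[i]), int(protein.res_id[i]))
        name = protein.atom_name[i]
        if name in coords and coords[name][index[key]] is None:
            coords[name][index[key]] = protein.coord[i]
    return order, coords


def backbone_hbonds(frame, *, cutoff: float = HBOND_CUTOFF):
    """Kabsch–Sander backbone hydrogen bonds of one frame.

    Returns ``(residues, bonds)`` where ``residues`` lists (strand_id,
    res_id) keys and ``bonds`` is a set of index pairs ``(acceptor,
    donor)`` meaning "the C=O of residue ``acceptor`` accepts from the
    N–H of residue ``donor``", plus a dict of bond energies.  Residues
    missing backbone atoms are skipped.
    """
    order, coords = _collect_backbone(frame)
    n = len(order)
    chain_prev = [None] * n
    for k in range(1, n):
        s_prev, r_prev = order[k - 1]
        s, r = order[k]
        if s == s_prev and r == r_prev + 1:
            chain_prev[k] = k - 1

    # reconstruct missing amide hydrogens from the bisector convention
    H = list(coords["H"])
    for k in range(n):
        if H[k] is not None:
            continue
        p = chain_prev[k]
        if p is None or coords["C"][p] is None:
            continue
        N_k, CA_k = coords["N"][k], coords["CA"][k]
        if N_k is None or CA_k is None:
            continue
        u = N_k - coords["C"][p]
        v = N_k - CA_k
        u = u / np.linalg.norm(u)
        v = v / np.linalg.norm(v)
        b = u + v
        H[k] = N_k + N_H_LENGTH * b / np.linalg.norm(b)

    donors = [
        k
        for k in range(n)
        if H[k] is not None and coords["N"][k] is not None
    ]
    acceptors = [
        k
        for k in range(n)
        if coords["C"][k] is not None and coords["O"][k] is not None
    ]
    ca_ok = [k for k in range(n) if coords["CA"][k] is not None]
    ca_coords = {k: coords["CA"][k] for k in ca_ok}

    acc_with_ca = [k for k in acceptors if k in ca_coords]
    tree = cKDTree(np.array([ca_coords[k] for k in acc_with_ca]))
    bonds: set[tuple[int, int]] = set()
    energies: dict[tuple[int, int], float] = {}
    for d in donors:
        if d not in ca_coords:
            continue
        near = tree.query_ball_point(ca_coords[d], CA_PREFILTER)
        for idx in near:
            a = acc_with_ca[idx]
            if a == d:
                continue
            sd, rd = order[d]
            sa, ra = order[a]
            if sd == sa and abs(rd - ra) < 2:
                continue
            r_on = np.linalg.norm(coords["O"][a] - coords["N"][d])
            r_ch = np.linalg.norm(coords["C"][a] - H[d])
            r_oh = np.linalg.norm(coords["O"][a] - H[d])
            r_cn = np.linalg.norm(coords["C"][a] - coords["N"][d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, no meaningful energy
            e = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < cutoff:
                bonds.add((a, d))
                energies[(a, d)] = float(e)
    return order, bonds, energies


def assign_ss(frame) -> SSAssignment:
    """DSSP-style motif labels (E, B, H, T, C) for every residue of a frame."""
    order, bonds, _ = backbone_hbonds(frame)
    n = len(order)

    def hb(i: int, j: int) -> bool:
        """C=O of residue i accepts from N–H of residue j."""
        return (i, j) in bonds

    chain_next = [None] * n
    chain_prev = [None] * n
    for k in range(1, n):
        s_prev, r_prev = order[k - 1]
        s, r = order[k]
        if s == s_prev and r == r_prev + 1:
            chain_next[k - 1] = k
            chain_prev[k] = k - 1

    def seq_ok(i, steps):
        """Follow the chain ``steps`` residues forward; None off the end."""
        k = i
        for _ in range(steps):
            if k is None:
                return None
            k = chain_next[k]
        return k

    # n-turns: CO(i) -> NH(i+k), k in 3..5
    turn = np.zeros(n, dtype=bool)
    helix4 = np.zeros(n, dtype=bool)
    for i in range(n):
        for k in (3, 4, 5):
            j = seq_ok(i, k)
            if j is not None and hb(i, j):
                # residues strictly between i and j take part in the turn
                t = chain_next[i]
                while t is not None and t != j:
                    turn[t] = True
                    t = chain_next[t]
                turn[i] = True
                if k == 4:
                    helix4[i] = True

    # bridges
    bridge_partners: dict[int, list[tuple[int, str]]] = {k: [] for k in range(n)}
    for i in range(n):
        im1, ip1 = chain_prev[i], chain_next[i]
        for j in range(n):
            if j == i:
                continue
            si, ri = order[i]
            sj, rj = order[j]
            if si == sj and abs(ri - rj) < 3:
                continue
            jm1, jp1 = chain_prev[j], chain_next[j]
            par = False
            anti = False
            if im1 is not None and ip1 is not None:
                if hb(im1, j) and jp1 is not None and hb(j, ip1):
                    par = True
            if jm1 is not None and jp1 is not None and im1 is not None and ip1 is not None:
                if hb(jm1, i) and hb(i, jp1):
                    par = True
            if hb(i, j) and hb(j, i):
                anti = True
            if (
                im1 is not None
                and jp1 is not None
                and jm1 is not None
                and ip1 is not None
                and hb(im1, jp1)
                and hb(jm1, ip1)
            ):
                anti = True
            if par:
                bridge_partners[i].append((j, "P"))
            if anti:
                bridge_partners[i].append((j, "A"))

    in_ladder = np.zeros(n, dtype=bool)
    has_bridge = np.array([bool(bridge_partners[k]) for k in range(n)])
    for i in range(n):
        ip1 = chain_next[i]
        if ip1 is None:
            continue
        for j, kind in bridge_partners[i]:
            jp1, jm1 = chain_next[j], chain_prev[j]
            if kind == "P" and jp1 is not None and (jp1, "P") in bridge_partners[ip1]:
                in_ladder[[i, ip1, j, jp1]] = True
            if kind == "A" and jm1 is not None and (jm1, "A") in bridge_partners[ip1]:
                in_ladder[[i, ip1, j, jm1]] = True

    # minimal helix: 4-turn at i-1 and i -> residues i..i+3 helical
    helical = np.zeros(n, dtype=bool)
    for i in range(n):
        ip1 = chain_next[i]
        if ip1 is not None and helix4[i] and (
            chain_prev[i] is not None and helix4[chain_prev[i]]
        ):
            t = i
            for _ in range(4):
                if t is None:
                    break
                helical[t] = True
                t = chain_next[t]

    labels = np.full(n, "C", dtype="<U1")
    labels[turn] = "T"
    labels[has_bridge & ~in_ladder] = "B"
    labels[in_ladder] = "E"
    labels[helical] = "H"
    return SSAssignment(residues=order, labels=labels)


def incidence(
    traj: Trajectory | SSAssignment | list[SSAssignment],
    domain: DomainDefinition,
    motif: str = "E",
) -> tuple[float, pd.DataFrame]:
    """Percentage of (frame, strand, residue ∈ domain) triples with ``motif``.

    Accepts a trajectory (assigned frame by frame), a single assignment or
    a list of assignments.  Returns ``(percentage, per_position_profile)``
    where the profile has one row per position in the domain with the
    per-position percentage of each motif.
    """
    if not domain.positions:
        raise ValueError("empty domain")
    if isinstance(traj, Trajectory):
        assignments = [assign_ss(traj.frame(i)) for i in range(traj.n_frames)]
    elif isinstance(traj, SSAssignment):
        assignments = [traj]
    else:
        assignments = list(traj)

    positions = sorted(domain.positions)
    counts = {p: {m: 0 for m in MOTIFS} for p in positions}
    n_hit = 0
    n_total = 0
    for asg in assignments:
        for (sid, res), lab in zip(asg.residues, asg.labels):
            if res in domain.positions:
                counts[res][str(lab)] += 1
                n_total += 1
                if lab == motif:
                    n_hit += 1
    if n_total == 0:
        raise ValueError("no residues of the domain present in the assignments")
    rows = []
    for p in positions:
        tot = sum(counts[p].values())
        row = {"position": p}
        for m in MOTIFS:
            row[f"pct_{m}"] = 100.0 * counts[p][m] / tot if tot else np.nan
        rows.append(row)
    return 100.0 * n_hit / n_total, pd.DataFrame(rows)
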