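"""Alpha-helix assignment from backbone hydrogen bonds (DSSP criterion).

A backbone hydrogen bond exists between the C=O of residue i (acceptor)
and the N-H of residue j (donor) when the Kabsch-Sander electrostatic
energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

is below -0.5 kcal/mol. A residue is alpha-helical when it lies inside a
helix started by two consecutive (i, i+4) hydrogen bonds. Amide
hydrogens are rebuilt from N, Calpha and the preceding carbonyl carbon
when absent, so the assignment works on heavy-atom-only models.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import AMINO_ACIDS, StructureModel, TrajectoryHandle

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
HB_FACTOR = 0.084 * 332.0
NH_BOND = 1.01  # Angstrom
CHAIN_BREAK = 2.5  # Angstrom, C(i)-N(i+1) beyond this is a break


@dataclass
class HelixRegion:
    """Named helix segment (inclusive residue range, topology numbering)."""

    name: str
    first: int
    last: int

    def __post_init__(self):
        if self.first > self.last:
            raise ValueError("region first must be <= last")


# Approximate boundaries for the FOXP1 forkhead domain helices; the
# H2-H3 region spans residues 489-517 and the short H4 helix sits
# between H2 and H3. These are config defaults, not fixed truths.
DEFAULT_REGIONS = {
    "H2": HelixRegion("H2", 489, 502),
    "H4": HelixRegion("H4", 505, 510),
    "H3": HelixRegion("H3", 511, 524),
}


@dataclass
class SSAssignment:
    """Per-frame, per-residue alpha-helix flags."""

    helical: np.ndarray  # (n_frames, n_residues) bool
    residue_index: np.ndarray

    def __post_init__(self):
        self.helical = np.asarray(self.helical, dtype=bool)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.helical.shape[1] != self.residue_index.shape[0]:
            raise ValueError("helical/residue_index shape mismatch")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_index\t" + "\t".join(map(str, self.residue_index)) + "\n")
            for f in range(self.helical.shape[0]):
                fh.write(str(f) + "\t" +
                         "\t".join("H" if h else "-" for h in self.helical[f]) + "\n")


def _backbone_layout(topology: StructureModel):
    """Per-residue indices of backbone N, CA, C, O atoms (protein only)."""
    groups: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    for i, a in enumerate(topology.atoms):
        if a.residue_name not in AMINO_ACIDS:
            continue
        key = (a.chain_id, a.residue_index)
        if key not in groups:
            groups[key] = {}
            order.append(key)
        if a.name in ("N", "CA", "C", "O"):
            groups[key][a.name] = i
    order.sort()
    idx = {name: np.full(len(order), -1, dtype=int) for name in "N CA C O".split()}
    resids = np.empty(len(order), dtype=int)
    chains = []
    for r, key in enumerate(order):
        resids[r] = key[1]
        chains.append(key[0])
        for name in ("N", "CA", "C", "O"):
            if name in groups[key]:
                idx[name][r] = groups[key][name]
    return idx, resids, np.array(chains)


def _frame_energies(coords: np.ndarray, idx, chains) -> np.ndarray:
    """(i, i+4) hydrogen-bond energies per frame; NaN where unassignable.

    coords: (n_frames, n_atoms, 3). Returns (n_frames, n_res-4) energies
    for acceptor residue i, donor residue i+4.
    """
    R = len(idx["N"])
    F = coords.shape[0]
    ok = {n: idx[n] >= 0 for n in idx}
    pos = {n: coords[:, np.maximum(idx[n], 0), :] for n in idx}

    # amide H on residue r from N, CA and previous C (no H on first residue)
    H = np.full((F, R, 3), np.nan)
    donor_ok = np.zeros(R, dtype=bool)
    for r in range(1, R):
        if not (ok["N"][r] and ok["CA"][r] and ok["C"][r - 1]):
            continue
        if chains[r] != chains[r - 1]:
            continue
        cn = np.linalg.norm(pos["N"][:, r] - pos["C"][:, r - 1], axis=1)
        if np.any(cn > CHAIN_BREAK):
            continue
        u1 = pos["N"][:, r] - pos["C"][:, r - 1]
        u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
        u2 = pos["N"][:, r] - pos["CA"][:, r]
        u2 /= np.linalg.norm(u2, axis=1, keepdims=True)
        d = u1 + u2
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        H[:, r] = pos["N"][:, r] + NH_BOND * d
        donor_ok[r] = True

    E = np.full((F, R - 4), np.nan)
    for i in range(R - 4):
        j = i + 4
        if not (ok["C"][i] and ok["O"][i] and ok["N"][j] and donor_ok[j]):
            continue
        if chains[i] != chains[j]:
            continue
        # contiguity between acceptor and donor (no chain break inside)
        contiguous = True
        for rr in range(i, j):
            if (not ok["C"][rr]) or (not ok["N"][rr + 1]) or \
               chains[rr] != chains[rr + 1]:
                contiguous = False
                break
            gap = np.linalg.norm(coords[:, idx["C"][rr], :] -
                                 coords[:, idx["N"][rr + 1], :], axis=1)
            if np.any(gap > CHAIN_BREAK):
                contiguous = False
                break
        if not contiguous:
            continue
        rON = np.linalg.norm(pos["O"][:, i] - pos["N"][:, j], axis=1)
        rCH = np.linalg.norm(pos["C"][:, i] - H[:, j], axis=1)
        rOH = np.linalg.norm(pos["O"][:, i] - H[:, j], axis=1)
        rCN = np.linalg.norm(pos["C"][:, i] - pos["N"][:, j], axis=1)
        E[:, i] = HB_FACTOR * (1.0 / rON + 1.0 / rCH - 1.0 / rOH - 1.0 / rCN)
    return E


def hbond_energy(model: StructureModel, acceptor_residue: int,
                 donor_residue: int) -> float:
    """Kabsch-Sander energy (kcal/mol) for one CO(acceptor)...HN(donor) pair."""
    if acceptor_residue == donor_residue:
        raise ValueError("donor and acceptor must differ")
    idx, resids, chains = _backbone_layout(model)
    coords = model.coords()[None, :, :]
    ra = np.where(resids == acceptor_residue)[0]
    rd = np.where(resids == donor_residue)[0]
    if len(ra) == 0 or len(rd) == 0:
        raise ValueError("residue not found")
    i, j = int(ra[0]), int(rd[0])
    if j != i + 4:
        # generic pair: evaluate directly without the i+4 table
        ok = idx
        if min(ok["C"][i], ok["O"][i], ok["N"][j]) < 0 or j == 0 or \
           ok["CA"][j] < 0 or ok["C"][j - 1] < 0:
            raise ValueError("missing backbone atoms; residue unassignable")
        C = coords[0, ok["C"][i]]
        O = coords[0, ok["O"][i]]
        N = coords[0, ok["N"][j]]
        u1 = N - coords[0, ok["C"][j - 1]]
        u1 /= np.linalg.norm(u1)
        u2 = N - coords[0, ok["CA"][j]]
        u2 /= np.linalg.norm(u2)
        d = (u1 + u2)
        d /= np.linalg.norm(d)
        Hp = N + NH_BOND * d
        return float(HB_FACTOR * (1 / np.linalg.norm(O - N) +
                                  1 / np.linalg.norm(C - Hp) -
                                  1 / np.linalg.norm(O - Hp) -
                                  1 / np.linalg.norm(C - N)))
    E = _frame_energies(coords, idx, chains)
    val = E[0, i]
    if np.isnan(val):
        raise ValueError("missing backbone atoms; residue unassignable")
    return float(val)


def assign_alpha(traj: TrajectoryHandle | StructureModel) -> SSAssignment:
    """Alpha-helix flags per residue per frame (DSSP H rule).

    Residue r is helical when two consecutive 4-turns start at i and i+1
    with i+1 <= r <= i+4, where a 4-turn at i means an (i, i+4) backbone
    hydrogen bond.
    """
    if isinstance(traj, StructureModel):
        topology, coords = traj, traj.coords()[None, :, :]
    else:
        topology, coords = traj.topology, traj.coords
    idx, resids, chains = _backbone_layout(topology)
    R = len(resids)
    F = coords.shape[0]
    helical = np.zeros((F, R), dtype=bool)
    if R >= 6:
        E = _frame_energies(coords, idx, chains)
        turn = np.where(np.isnan(E), False, E < HB_ENERGY_CUTOFF)
        starts = turn[:, :-1] & turn[:, 1:]  # helix start at i (0..R-6)
        for i in range(starts.shape[1]):
            frames = starts[:, i]
            helical[frames, i + 1:i + 5] = True
    return SSAssignment(helical=helical, residue_index=resids)


def helical_count(ss: SSAssignment, region: HelixRegion) -> np.ndarray:
    """Number of helical residues inside the region, per frame."""
    lo, hi = int(ss.residue_index.min()), int(ss.residue_index.max())
    if region.last < lo or region.first > hi:
        raise ValueError(f"region {region.name} [{region.first}, {region.last}] "
                         f"outside topology range [{lo}, {hi}]")
    mask = (ss.residue_index >= region.first) & (ss.residue_index <= region.last)
    return ss.helical[:, mask].sum(axis=1)
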