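"""CAPRI metrics (Fnat, i-RMSD, l-RMSD, DockQ) for protein-DNA poses.

A pose is scored against a reference complex with the DNA as receptor
and the protein as ligand. Fnat uses 5.0 Angstrom heavy-atom residue-
nucleotide contacts; i-RMSD uses backbone atoms of interface residues
(any residue with a heavy atom within 10 Angstrom of the other component
in the reference); l-RMSD is the protein backbone RMSD after superposing
the DNA backbones; DockQ combines the three:

    DockQ = (Fnat + 1/(1+(iRMSD/1.5)^2) + 1/(1+(lRMSD/8.5)^2)) / 3
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._geom import kabsch, rmsd as _plain_rmsd
from .structure_io import (DNA_BACKBONE_NAMES, NUCLEOTIDES, AtomRecord,
                           StructureModel, TrajectoryHandle)

PROTEIN_BACKBONE = ("N", "CA", "C", "O")

# reference dsDNA duplex and DNA-contacting residues used in reproduction
# runs of the forkhead-domain docking protocol
REFERENCE_DNA_SEQUENCE = ("AACTATGAAACAAATTTTCCT", "TTAGGAAAATTTGTTTCATAG")
ACTIVE_RESIDUES_PROTEIN = ("N511", "R514", "H515", "S518", "L519", "W534")
ACTIVE_RESIDUES_DNA = ("A12", "A13", "A14", "T15", "A30", "T31", "T32", "T33")


@dataclass
class CapriParams:
    """Metric constants (published DockQ definition)."""

    fnat_cutoff: float = 5.0
    interface_cutoff: float = 10.0
    dockq_d1: float = 1.5
    dockq_d2: float = 8.5
    lrmsd_superpose_on: str = "receptor"  # CAPRI convention

    def __post_init__(self):
        for v in (self.fnat_cutoff, self.interface_cutoff,
                  self.dockq_d1, self.dockq_d2):
            if v <= 0:
                raise ValueError("all CAPRI constants must be positive")


@dataclass
class CapriScores:
    fnat: float
    irmsd: float
    lrmsd: float
    dockq: float


@dataclass
class ComplexStructure:
    """Protein-DNA complex with explicit chain roles."""

    model: StructureModel
    protein_chains: tuple[str, ...]
    dna_chains: tuple[str, ...]

    def __post_init__(self):
        self.protein_chains = tuple(self.protein_chains)
        self.dna_chains = tuple(self.dna_chains)
        if not self._atoms(self.protein_chains) or not self._atoms(self.dna_chains):
            raise ValueError("both complex components must be non-empty")

    def _atoms(self, chains) -> list[AtomRecord]:
        return [a for a in self.model.atoms if a.chain_id in chains]

    def protein_heavy(self) -> list[AtomRecord]:
        return [a for a in self._atoms(self.protein_chains) if not a.is_hydrogen]

    def dna_heavy(self) -> list[AtomRecord]:
        return [a for a in self._atoms(self.dna_chains) if not a.is_hydrogen]

    def with_coords(self, coords: np.ndarray) -> "ComplexStructure":
        return ComplexStructure(self.model.with_coords(coords),
                                self.protein_chains, self.dna_chains)


def dockq_from_components(fnat: float, irmsd: float, lrmsd: float,
                          params: CapriParams | None = None) -> float:
    p = params or CapriParams()
    return (fnat + 1.0 / (1.0 + (irmsd / p.dockq_d1) ** 2)
            + 1.0 / (1.0 + (lrmsd / p.dockq_d2) ** 2)) / 3.0


def _contact_pairs(prot: list[AtomRecord], dna: list[AtomRecord],
                   cutoff: float) -> set[tuple]:
    """(protein residue, nucleotide) pairs with any heavy-atom contact."""
    if not prot or not dna:
        return set()
    tp = cKDTree(np.array([a.coords for a in prot]))
    td = cKDTree(np.array([a.coords for a in dna]))
    pairs = tp.query_ball_tree(td, cutoff)
    out = set()
    for pi, hits in enumerate(pairs):
        for di in hits:
            out.add(((prot[pi].chain_id, prot[pi].residue_index),
                     (dna[di].chain_id, dna[di].residue_index)))
    return out


def native_contact_pairs_interface(ref: ComplexStructure,
                                   cutoff: float = 5.0) -> set[tuple]:
    """Residue-nucleotide pairs in contact (heavy atoms) in the reference."""
    pairs = _contact_pairs(ref.protein_heavy(), ref.dna_heavy(), cutoff)
    if not pairs:
        warnings.warn("empty reference interface; Fnat will be undefined")
    return pairs


def _keyed_coords(cplx: ComplexStructure, chains, names) -> dict[tuple, np.ndarray]:
    out = {}
    for a in cplx._atoms(chains):
        if a.name in names:
            out[(a.chain_id, a.residue_index, a.name)] = a.coords
    return out


def _matched(model: ComplexStructure, ref: ComplexStructure, chains, names):
    mk = _keyed_coords(model, chains, names)
    rk = _keyed_coords(ref, chains, names)
    keys = [k for k in rk if k in mk]
    if not keys:
        raise ValueError("no correspondence between model and reference atoms")
    return (np.array([mk[k] for k in keys]), np.array([rk[k] for k in keys]), keys)


def _interface_residues(ref: ComplexStructure, cutoff: float) -> set[tuple]:
    """Residues (chain, index) of both components near the interface."""
    pairs = _contact_pairs(ref.protein_heavy(), ref.dna_heavy(), cutoff)
    out = set()
    for p, d in pairs:
        out.add(p)
        out.add(d)
    return out


def score_pose(model: ComplexStructure, ref: ComplexStructure,
               params: CapriParams | None = None) -> CapriScores:
    """CAPRI metrics of a pose against the reference complex.

    Residue/nucleotide correspondence is by chain id + residue index.
    """
    p = params or CapriParams()
    nat = native_contact_pairs_interface(ref, p.fnat_cutoff)
    if not nat:
        raise ValueError("empty reference interface")
    mod = _contact_pairs(model.protein_heavy(), model.dna_heavy(), p.fnat_cutoff)
    fnat = len(nat & mod) / len(nat)

    # l-RMSD: superpose receptor (DNA) backbones, measure ligand backbone
    if p.lrmsd_superpose_on == "receptor":
        fit_chains, fit_names = ref.dna_chains, DNA_BACKBONE_NAMES
        meas_chains, meas_names = ref.protein_chains, PROTEIN_BACKBONE
    else:
        fit_chains, fit_names = ref.protein_chains, PROTEIN_BACKBONE
        meas_chains, meas_names = ref.dna_chains, DNA_BACKBONE_NAMES
    mfit, rfit, _ = _matched(model, ref, fit_chains, fit_names)
    R, t = kabsch(mfit, rfit)
    mmeas, rmeas, _ = _matched(model, ref, meas_chains, meas_names)
    lrmsd = _plain_rmsd(mmeas @ R.T + t, rmeas)

    # i-RMSD: backbone atoms of reference-interface residues, fitted RMSD
    iface = _interface_residues(ref, p.interface_cutoff)
    mk = {**_keyed_coords(model, ref.protein_chains, PROTEIN_BACKBONE),
          **_keyed_coords(model, ref.dna_chains, DNA_BACKBONE_NAMES)}
    rk = {**_keyed_coords(ref, ref.protein_chains, PROTEIN_BACKBONE),
          **_keyed_coords(ref, ref.dna_chains, DNA_BACKBONE_NAMES)}
    keys = [k for k in rk if (k[0], k[1]) in iface and k in mk]
    if not keys:
        raise ValueError("no interface backbone correspondence")
    mi = np.array([mk[k] for k in keys])
    ri = np.array([rk[k] for k in keys])
    Ri, ti = kabsch(mi, ri)
    irmsd = _plain_rmsd(mi @ Ri.T + ti, ri)

    return CapriScores(fnat=fnat, irmsd=irmsd, lrmsd=lrmsd,
                       dockq=dockq_from_components(fnat, irmsd, lrmsd, p))


def interface_persistence_series(traj: TrajectoryHandle, ref: ComplexStructure,
                                 cutoff: float = 4.0) -> np.ndarray:
    """Per-frame fraction of reference interface contacts still present.

    Contacts are residue-nucleotide pairs with heavy atoms within
    `cutoff` (4.0 Angstrom as in the docking validation analyses).
    """
    nat = _contact_pairs(ref.protein_heavy(), ref.dna_heavy(), cutoff)
    if not nat:
        raise ValueError("empty reference interface")
    top = traj.topology
    cplx0 = ComplexStructure(top, ref.protein_chains, ref.dna_chains)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = cplx0.with_coords(traj.coords[f])
        pairs = _contact_pairs(frame.protein_heavy(), frame.dna_heavy(), cutoff)
        out[f] = len(nat & pairs) / len(nat)
    return out


def protein_rmsd_dna_aligned(traj: TrajectoryHandle, ref: ComplexStructure) -> np.ndarray:
    """Protein backbone RMSD per frame after alignment on DNA phosphorus atoms."""
    top_cplx = ComplexStructure(traj.topology, ref.protein_chains, ref.dna_chains)
    ridx = {}
    for a in ref.model.atoms:
        if a.chain_id in ref.dna_chains and a.name == "P":
            ridx[(a.chain_id, a.residue_index)] = a.coords
    tidx, tkeys = [], []
    for i, a in enumerate(traj.topology.atoms):
        if a.chain_id in ref.dna_chains and a.name == "P":
            key = (a.chain_id, a.residue_index)
            if key in ridx:
                tidx.append(i)
                tkeys.append(key)
    if not tidx:
        raise ValueError("no matched DNA phosphorus atoms")
    ref_p = np.array([ridx[k] for k in tkeys])

    rbk = _keyed_coords(ref, ref.protein_chains, PROTEIN_BACKBONE)
    bidx, bkeys = [], []
    for i, a in enumerate(traj.topology.atoms):
        key = (a.chain_id, a.residue_index, a.name)
        if a.chain_id in ref.protein_chains and a.name in PROTEIN_BACKBONE \
                and key in rbk:
            bidx.append(i)
            bkeys.append(key)
    ref_b = np.array([rbk[k] for k in bkeys])

    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t = kabsch(traj.coords[f][tidx], ref_p)
        out[f] = _plain_rmsd(traj.coords[f][bidx] @ R.T + t, ref_b)
    return out
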