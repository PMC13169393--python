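"""Ground-truthed synthetic inputs for the pipeline.

Two generators emulate the statistical structure of the study data:

* multi-system conformational ensembles drawn i.i.d. from a small set of
  template conformations (macrostates, built as poly-alanine helices with
  localized unwinding) plus isotropic Gaussian coordinate noise, with
  planted per-system occupancy vectors;
* protein-DNA pose ladders obtained by rigid-body perturbation of a
  reference complex with known translation/rotation magnitudes.

Both are pure functions of their spec + seed. No kinetics is modelled:
the downstream pipeline treats frames as exchangeable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geom import place_atom, rotation_about_axis
from .capri_scoring import ComplexStructure
from .structure_io import AtomRecord, StructureModel, TrajectoryHandle

# ideal backbone internal coordinates (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = 180.0, 180.0


def build_helix_peptide(n_res: int, unwound_range: tuple[int, int] | None = None,
                        chain_id: str = "A") -> StructureModel:
    """Poly-alanine backbone with ideal alpha-helix dihedrals.

    Residues inside `unwound_range` (1-based, inclusive) are set to the
    extended conformation (phi = psi = 180 degrees), emulating localized
    helix unwinding. Atoms per residue: N, CA, C, O, CB.
    """
    if n_res < 6:
        raise ValueError("need at least 6 residues")
    if unwound_range is not None:
        lo, hi = unwound_range
        if lo < 1 or hi > n_res or lo > hi:
            raise ValueError("unwound_range outside chain")
        unwound = set(range(lo, hi + 1))
    else:
        unwound = set()

    def phi(r):  # 1-based residue
        return np.deg2rad(EXTENDED_PHI if r in unwound else HELIX_PHI)

    def psi(r):
        return np.deg2rad(EXTENDED_PSI if r in unwound else HELIX_PSI)

    rad = np.deg2rad
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([B_N_CA, 0.0, 0.0])]
    C = [place_atom(np.array([0.0, 1.0, 0.0]), N[0], CA[0],
                    B_CA_C, rad(A_N_CA_C), 0.0)]
    for r in range(2, n_res + 1):
        # psi(r-1): N-CA-C-N(next); omega fixed trans; phi(r): C-N-CA-C
        N.append(place_atom(N[-1], CA[-1], C[-1], B_C_N, rad(A_CA_C_N), psi(r - 1)))
        CA.append(place_atom(CA[-1], C[-1], N[-1], B_N_CA, rad(A_C_N_CA), np.pi))
        C.append(place_atom(C[-1], N[-1], CA[-1], B_CA_C, rad(A_N_CA_C), phi(r)))
    # carbonyl oxygens (sp2, opposite the bisector of CA and next N)
    O = []
    for r in range(n_res):
        if r + 1 < n_res:
            nxt = N[r + 1]
        else:  # virtual next N continuing the chain
            nxt = place_atom(N[r], CA[r], C[r], B_C_N, rad(A_CA_C_N), psi(n_res))
        u1 = CA[r] - C[r]
        u1 /= np.linalg.norm(u1)
        u2 = nxt - C[r]
        u2 /= np.linalg.norm(u2)
        d = -(u1 + u2)
        d /= np.linalg.norm(d)
        O.append(C[r] + B_C_O * d)
    # C-beta via the standard tetrahedral construction
    CB = []
    for r in range(n_res):
        b = CA[r] - N[r]
        c = C[r] - CA[r]
        a = np.cross(b, c)
        CB.append(-0.58273431 * a + 0.56802827 * b - 0.54067466 * c + CA[r])

    atoms = []
    serial = 1
    for r in range(n_res):
        for name, el, pos in (("N", "N", N[r]), ("CA", "C", CA[r]),
                              ("C", "C", C[r]), ("O", "O", O[r]),
                              ("CB", "C", CB[r])):
            atoms.append(AtomRecord(serial=serial, name=name, element=el,
                                    residue_index=r + 1, residue_name="ALA",
                                    chain_id=chain_id, coords=pos))
            serial += 1
    tag = f"helix{n_res}" + (f"_unwound{min(unwound)}-{max(unwound)}" if unwound else "")
    return StructureModel(atoms, model_id=1, source=f"synthetic:{tag}")


# ---------------------------------------------------------------------------
# conformational ensembles

@dataclass
class SyntheticEnsembleSpec:
    """Planted-macrostate ensemble: templates + occupancies + noise + seed.

    occupancy maps system label -> probability vector over templates;
    n_frames maps system label -> frames per replica.
    """

    templates: list[StructureModel]
    occupancy: dict[str, tuple[float, ...]]
    n_frames: dict[str, int]
    n_replicas: int = 10
    noise_sigma: float = 0.3  # Angstrom, isotropic per atom
    stride_ps: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        n_atoms = {t.n_atoms for t in self.templates}
        if len(n_atoms) != 1:
            raise ValueError("templates must share topology")
        for sys, occ in self.occupancy.items():
            if abs(sum(occ) - 1.0) > 1e-9:
                raise ValueError(f"occupancy for {sys} must sum to 1")
            if len(occ) != len(self.templates):
                raise ValueError(f"occupancy length mismatch for {sys}")


@dataclass
class SyntheticEnsemble:
    """Generated trajectories plus frame-level ground-truth labels."""

    trajectories: list[TrajectoryHandle]
    labels: pd.DataFrame  # columns: system, replica, time_ps, template
    spec: SyntheticEnsembleSpec


def generate_ensemble(spec: SyntheticEnsembleSpec) -> SyntheticEnsemble:
    """Draw frames i.i.d. from per-system occupancies (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    T = np.stack([t.coords() for t in spec.templates])
    topology = spec.templates[0]
    trajs, label_rows = [], []
    for system in spec.occupancy:
        occ = np.asarray(spec.occupancy[system], dtype=float)
        nf = spec.n_frames[system]
        for rep in range(1, spec.n_replicas + 1):
            ids = rng.choice(len(spec.templates), size=nf, p=occ)
            noise = rng.normal(0.0, spec.noise_sigma,
                               size=(nf,) + T.shape[1:]) if spec.noise_sigma > 0 \
                else np.zeros((nf,) + T.shape[1:])
            coords = T[ids] + noise
            times = (np.arange(nf) + 1) * spec.stride_ps
            trajs.append(TrajectoryHandle(topology=topology, coords=coords,
                                          frame_times=times,
                                          system_label=system, replica_id=rep))
            label_rows.append(pd.DataFrame({
                "system": system, "replica": rep, "time_ps": times,
                "template": ids}))
    return SyntheticEnsemble(trajectories=trajs,
                             labels=pd.concat(label_rows, ignore_index=True),
                             spec=spec)


def default_templates(n_res: int = 24) -> list[StructureModel]:
    """Four macrostate templates: intact helix and three unwinding variants
    (N-side unwound, C-side unwound, both) scaled to the chain length."""
    if n_res < 16:
        raise ValueError("need at least 16 residues for distinct macrostates")
    # interior windows: terminal residues fray anyway, so unwinding there
    # would barely distinguish the macrostates
    n_lo = (n_res // 4, n_res // 4 + 5)
    c_hi = (n_res - 10, n_res - 5)
    return [
        build_helix_peptide(n_res),
        build_helix_peptide(n_res, n_lo),
        build_helix_peptide(n_res, c_hi),
        build_helix_peptide(n_res, (n_lo[0], c_hi[1])),
    ]


def study_conditions(seed: int = 0, n_res: int = 24) -> SyntheticEnsembleSpec:
    """Default study-like conditions: a WT-like single-macrostate system and
    a mobile mutant-like system visiting four macrostates at 30/40/20/10%,
    each over 10 replicas (20,000 frames for the mobile system)."""
    return SyntheticEnsembleSpec(
        templates=default_templates(n_res),
        occupancy={"WT": (1.0, 0.0, 0.0, 0.0),
                   "MUT": (0.3, 0.4, 0.2, 0.1)},
        n_frames={"WT": 200, "MUT": 2000},
        n_replicas=10,
        noise_sigma=0.3,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# protein-DNA complexes and pose ladders

def build_synthetic_complex(n_bp: int = 10, n_res: int = 12,
                            target_gap: float = 3.2) -> ComplexStructure:
    """Synthetic protein-DNA complex for scoring tests.

    A stand-in reference complex: an idealized double-helical arrangement
    of DNA backbone atoms (two antiparallel strands, 5' nucleotides
    without phosphate) with a poly-alanine helix placed against one
    strand so that the closest heavy-atom gap is `target_gap` Angstrom.
    Geometry is schematic, not chemically refined; it exists to exercise
    interface detection, superposition and CAPRI scoring.
    """
    rise, twist = 3.38, np.deg2rad(36.0)
    atoms: list[AtomRecord] = []
    serial = 1

    def add_nt(chain, resid, resname, theta, z, with_p):
        nonlocal serial
        layout = [("P", "P", 9.0, 0.0, 0.0), ("O5'", "O", 8.2, 8.0, 0.4),
                  ("C5'", "C", 7.8, 14.0, 0.8), ("C4'", "C", 7.4, 20.0, 1.2),
                  ("C3'", "C", 7.6, 28.0, 1.6), ("O3'", "O", 8.0, 34.0, 2.0),
                  ("C1'", "C", 5.8, 18.0, 1.0), ("N1", "N", 4.0, 16.0, 1.0)]
        for name, el, radius, dphi, dz in layout:
            if name == "P" and not with_p:
                continue
            ang = theta + np.deg2rad(dphi)
            pos = [radius * np.cos(ang), radius * np.sin(ang), z + dz]
            atoms.append(AtomRecord(serial=serial, name=name, element=el,
                                    residue_index=resid, residue_name=resname,
                                    chain_id=chain, coords=pos))
            serial += 1

    names = ["DA", "DT"]
    for k in range(n_bp):
        add_nt("B", k + 1, names[k % 2], k * twist, k * rise, with_p=k > 0)
    for k in range(n_bp):
        add_nt("C", k + 1, names[(k + 1) % 2], -k * twist + np.deg2rad(200.0),
               (n_bp - 1 - k) * rise, with_p=k > 0)

    dna = StructureModel(atoms, source="synthetic:dsDNA")
    protein = build_helix_peptide(n_res, chain_id="A")

    # place the protein helix alongside strand B at the target gap
    dxyz = dna.coords()
    pxyz = protein.coords()
    pxyz = pxyz - pxyz.mean(axis=0)
    # orient the helix axis along z (it is roughly along the first
    # principal component of the backbone)
    _, _, Vt = np.linalg.svd(pxyz - pxyz.mean(axis=0))
    axis = Vt[0]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        Rot = np.eye(3)
    else:
        c = np.dot(axis, z)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        Rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    pxyz = pxyz @ Rot.T
    center = np.array([14.0, 0.0, (n_bp - 1) * rise / 2.0])
    pxyz = pxyz + center
    # slide along +x until the minimal heavy-atom gap equals target_gap
    from scipy.spatial.distance import cdist as _cdist
    for _ in range(60):
        gap = _cdist(pxyz, dxyz).min()
        if abs(gap - target_gap) < 1e-6:
            break
        pxyz[:, 0] -= gap - target_gap
    protein = protein.with_coords(pxyz)

    merged = StructureModel(protein.atoms + dna.atoms,
                            source="synthetic:protein-DNA complex")
    return ComplexStructure(model=merged, protein_chains=("A",),
                            dna_chains=("B", "C"))


@dataclass
class PoseLadderSpec:
    """Rigid-body perturbation ladder around a reference complex."""

    reference: ComplexStructure
    translation_mags: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 20.0)
    rotation_mags_deg: tuple[float, ...] = (0.0,)
    n_per_rung: int = 5
    seed: int = 0

    def __post_init__(self):
        if any(m < 0 for m in self.translation_mags) or \
           any(m < 0 for m in self.rotation_mags_deg):
            raise ValueError("magnitudes must be >= 0")


@dataclass
class GeneratedPose:
    pose: ComplexStructure
    translation: float
    rotation_deg: float
    direction: np.ndarray
    axis: np.ndarray


def _interface_centroid(ref: ComplexStructure, cutoff: float = 10.0) -> np.ndarray:
    from scipy.spatial.distance import cdist as _cdist
    p = np.array([a.coords for a in ref.protein_heavy()])
    d = np.array([a.coords for a in ref.dna_heavy()])
    near = (_cdist(p, d) < cutoff).any(axis=1)
    return p[near].mean(axis=0) if near.any() else p.mean(axis=0)


def generate_pose_ladder(spec: PoseLadderSpec) -> list[GeneratedPose]:
    """Perturbed poses (protein moved rigidly, DNA fixed) with ground truth.

    For each (translation, rotation) rung, `n_per_rung` poses are built by
    rotating the protein about the interface centroid around a random axis
    and translating it along a random direction (seeded).
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference
    centroid = _interface_centroid(ref)
    prot_idx = [i for i, a in enumerate(ref.model.atoms)
                if a.chain_id in ref.protein_chains]
    base = ref.model.coords()
    poses = []
    for tmag in spec.translation_mags:
        for rmag in spec.rotation_mags_deg:
            for _ in range(spec.n_per_rung):
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                coords = base.copy()
                P = coords[prot_idx]
                if rmag > 0:
                    R = rotation_about_axis(axis, np.deg2rad(rmag))
                    P = (P - centroid) @ R.T + centroid
                P = P + tmag * direction
                coords[prot_idx] = P
                poses.append(GeneratedPose(pose=ref.with_coords(coords),
                                           translation=tmag, rotation_deg=rmag,
                                           direction=direction, axis=axis))
    return poses
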