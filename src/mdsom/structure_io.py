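"""Structure and trajectory I/O plus deterministic atom selections.

PDB reading/writing goes through gemmi; GRO and XTC/DCD trajectories go
through MDAnalysis. Internally everything is stored in Angstrom with
1-based residue numbering as in the source files.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
}
NUCLEOTIDES = {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "T", "I"}

BACKBONE_NAMES = ("N", "CA", "C", "O")
DNA_BACKBONE_NAMES = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")


@dataclass(eq=False)
class AtomRecord:
    """One atom as read from a coordinate file (coords in Angstrom)."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.name:
            raise ValueError(f"atom {self.serial}: empty atom name")
        if self.residue_index < 1:
            raise ValueError(f"atom {self.serial}: residue_index must be >= 1")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class StructureModel:
    """A single coordinate model: an ordered list of atoms."""

    atoms: list[AtomRecord]
    model_id: int = 1
    source: str = ""

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in model {self.model_id}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates (same atoms)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [AtomRecord(a.serial, a.name, a.element, a.residue_index,
                            a.residue_name, a.chain_id, c)
                 for a, c in zip(self.atoms, coords)]
        return StructureModel(atoms, model_id=self.model_id, source=self.source)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_index, residue_name)."""
        out, seen = [], set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.residue_name)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out


@dataclass
class SelectionSpec:
    """Declarative atom selection resolved to a deterministic atom list.

    kind: cbeta_or_ca_gly | backbone | heavy | dna_phosphorus | custom
    """

    kind: str = "heavy"
    chains: frozenset[str] | None = None
    residue_range: tuple[int, int] | None = None
    names: tuple[str, ...] | None = None  # for kind == "custom"

    KINDS = ("cbeta_or_ca_gly", "backbone", "heavy", "dna_phosphorus", "custom")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown selection kind {self.kind!r}")


@dataclass
class TrajectoryHandle:
    """In-memory trajectory: topology + coordinates (Angstrom) + times (ps)."""

    topology: StructureModel
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray  # ps
    system_label: str = ""
    replica_id: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("trajectory/topology atom-count mismatch: "
                             f"{self.coords.shape[1]} vs {self.topology.n_atoms}")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must have at least one frame")
        if len(self.frame_times) != self.coords.shape[0]:
            raise ValueError("frame_times length mismatch")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])


# ---------------------------------------------------------------------------
# reading

def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            # two-letter elements are rare in protein/DNA files; first alpha works
            return ch.upper()
    return "X"


def read_structure(path, model_index: int = 1) -> StructureModel:
    """Read one model from a PDB or GRO file.

    For multi-model PDB files `model_index` (1-based) selects the model.
    Alternate locations keep the highest-occupancy copy (ties: altloc 'A').
    Insertion codes are not supported and raise.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() == ".gro":
        if model_index != 1:
            raise IndexError("GRO files hold a single model")
        return _read_gro(path)

    st = gemmi.read_structure(str(path))
    if not 1 <= model_index <= len(st):
        raise IndexError(
            f"model_index {model_index} out of range (file has {len(st)} models)")
    model = st[model_index - 1]
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if res.seqid.icode not in (" ", ""):
                raise ValueError(
                    f"insertion codes unsupported: {chain.name} {res.seqid.num}{res.seqid.icode}")
            by_name: dict[str, list] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                best = min(group, key=lambda a: (-a.occ, a.altloc or "A"))
                el = best.element.name if best.element.name else _element_from_name(name)
                atoms.append(AtomRecord(
                    serial=best.serial, name=name, element=el,
                    residue_index=res.seqid.num, residue_name=res.name,
                    chain_id=chain.name, coords=[best.pos.x, best.pos.y, best.pos.z]))
    return StructureModel(atoms, model_id=model_index, source=f"{path}#pdb")


def _read_gro(path: Path) -> StructureModel:
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    atoms = []
    for i, a in enumerate(u.atoms, start=1):
        atoms.append(AtomRecord(
            serial=i, name=a.name, element=_element_from_name(a.name),
            residue_index=int(a.resid), residue_name=str(a.resname),
            chain_id="A", coords=a.position))
    return StructureModel(atoms, model_id=1, source=f"{path}#gro")


def n_models(path) -> int:
    """Number of models in a PDB file."""
    import gemmi

    return len(gemmi.read_structure(str(path)))


# ---------------------------------------------------------------------------
# writing

def write_pdb(models: StructureModel | Sequence[StructureModel], path) -> None:
    """Write one model or a multi-model PDB (trajectory-like) file."""
    import gemmi

    if isinstance(models, StructureModel):
        models = [models]
    st = gemmi.Structure()
    for mi, model in enumerate(models, start=1):
        gm = gemmi.Model(mi)
        chains: dict[str, "gemmi.Chain"] = {}
        cur_res = {}
        for a in model.atoms:
            if a.chain_id not in chains:
                chains[a.chain_id] = gemmi.Chain(a.chain_id)
                cur_res[a.chain_id] = None
            ch = chains[a.chain_id]
            key = (a.residue_index, a.residue_name)
            if cur_res[a.chain_id] != key:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_index, " ")
                ch.add_residue(res)
                cur_res[a.chain_id] = key
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coords)
            atom.occ = 1.0
            atom.serial = a.serial
            ch[len(ch) - 1].add_atom(atom)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# selections

def _grouped_residues(model: StructureModel):
    groups: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in model.atoms:
        groups.setdefault((a.chain_id, a.residue_index), []).append(a)
    return dict(sorted(groups.items()))


def select_atoms(model: StructureModel, spec: SelectionSpec) -> list[AtomRecord]:
    """Resolve a SelectionSpec to an ordered (chain, residue_index) atom list."""
    if model.n_atoms == 0:
        raise ValueError("empty model")
    out: list[AtomRecord] = []
    for (chain, resid), atoms in _grouped_residues(model).items():
        if spec.chains is not None and chain not in spec.chains:
            continue
        if spec.residue_range is not None:
            lo, hi = spec.residue_range
            if not lo <= resid <= hi:
                continue
        resname = atoms[0].residue_name
        if spec.kind == "cbeta_or_ca_gly":
            if resname not in AMINO_ACIDS:
                continue
            by_name = {a.name: a for a in atoms}
            if "CB" in by_name:
                out.append(by_name["CB"])
            elif "CA" in by_name:
                out.append(by_name["CA"])
            else:
                raise ValueError(
                    f"residue {chain}:{resid} {resname} lacks both CB and CA")
        elif spec.kind == "backbone":
            if resname not in AMINO_ACIDS:
                continue
            by_name = {a.name: a for a in atoms}
            out.extend(by_name[n] for n in BACKBONE_NAMES if n in by_name)
        elif spec.kind == "heavy":
            out.extend(a for a in atoms if not a.is_hydrogen)
        elif spec.kind == "dna_phosphorus":
            if resname not in NUCLEOTIDES:
                continue
            out.extend(a for a in atoms if a.name == "P")
        elif spec.kind == "custom":
            names = set(spec.names or ())
            out.extend(a for a in atoms if a.name in names)
    return out


def atom_indices(model: StructureModel, spec: SelectionSpec) -> list[int]:
    """Indices into model.atoms for the atoms a SelectionSpec resolves to."""
    pos = {id(a): i for i, a in enumerate(model.atoms)}
    return [pos[id(a)] for a in select_atoms(model, spec)]


# ---------------------------------------------------------------------------
# trajectories

def read_trajectory(topology_path, traj_path=None, system_label: str = "",
                    replica_id: int = 0, frame_times=None,
                    dt_ps: float | None = None) -> TrajectoryHandle:
    """Read an XTC/DCD trajectory or a multi-model PDB as a trajectory.

    Coordinates come back in Angstrom (MDAnalysis converts from nm for
    XTC). `frame_times` (explicit array) or `dt_ps` (uniform spacing,
    times dt, 2*dt, ...) override the times stored in the file, which is
    needed for formats that carry no time information (multi-model PDB).
    """
    import MDAnalysis as mda

    topology = read_structure(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if traj_path is None:
            u = mda.Universe(str(topology_path))
        else:
            try:
                u = mda.Universe(str(topology_path), str(traj_path))
            except ValueError as e:
                raise ValueError(f"topology/trajectory mismatch: {e}") from e
        if u.atoms.n_atoms != topology.n_atoms:
            raise ValueError("topology/trajectory atom-count mismatch: "
                             f"{topology.n_atoms} vs {u.atoms.n_atoms}")
        coords, times = [], []
        for ts in u.trajectory:
            coords.append(u.atoms.positions.copy())
            times.append(float(ts.time))
    coords = np.asarray(coords, dtype=float)
    if frame_times is None and dt_ps is not None:
        frame_times = (np.arange(len(coords)) + 1.0) * dt_ps
    if frame_times is None:
        frame_times = np.asarray(times, dtype=float)
        if len(frame_times) > 1 and np.any(np.diff(frame_times) <= 0):
            frame_times = np.arange(1.0, len(coords) + 1.0)
    return TrajectoryHandle(topology=topology, coords=coords,
                            frame_times=np.asarray(frame_times, dtype=float),
                            system_label=system_label, replica_id=replica_id)


def write_xtc(traj: TrajectoryHandle, path) -> None:
    """Write a trajectory to XTC (times preserved)."""
    import MDAnalysis as mda

    n = traj.topology.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coords[i]
                u.trajectory.ts.time = traj.frame_times[i]
                u.trajectory.ts.frame = i
                w.write(u.atoms)
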