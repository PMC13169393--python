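"""Native-contact distance featurization and standard trajectory analyses.

A conformational snapshot is encoded as the vector of distances between
residue-representative atoms (Cbeta, or Calpha for glycine) over the set
of residue pairs that form a contact (distance below 11 Angstrom, i.e.
1.1 nm) in a reference structure. Frames are sampled on a fixed time
stride (100 ps by default).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from ._geom import kabsch, rmsd as _plain_rmsd
from .structure_io import (SelectionSpec, StructureModel, TrajectoryHandle,
                           atom_indices, select_atoms)


@dataclass
class FeatureSpec:
    """Featurization parameters (distances in Angstrom, stride in ps)."""

    contact_cutoff: float = 11.0
    min_sequence_separation: int = 0
    stride: float = 100.0

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.stride <= 0:
            raise ValueError("stride must be positive")


@dataclass
class ContactPairSet:
    """Ordered residue pairs (i < j) in contact in the reference structure."""

    pairs: list[tuple[int, int]]
    reference_distances: np.ndarray
    reference_source: str = ""

    def __post_init__(self):
        self.reference_distances = np.asarray(self.reference_distances, dtype=float)
        if len(self.pairs) != len(self.reference_distances):
            raise ValueError("pairs/reference_distances length mismatch")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate contact pairs")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.pairs, columns=["res_i", "res_j"])
        df["ref_dist_A"] = self.reference_distances
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, reference_source: str = "") -> "ContactPairSet":
        df = pd.read_csv(path, sep="\t")
        pairs = list(zip(df["res_i"].astype(int), df["res_j"].astype(int)))
        return cls(pairs, df["ref_dist_A"].to_numpy(), reference_source or str(path))


@dataclass
class FeatureMatrix:
    """Frames x contact-distances matrix with per-frame metadata."""

    values: np.ndarray  # (n_frames, n_pairs), Angstrom
    frame_meta: pd.DataFrame  # columns: system, replica, time_ps
    pair_index: ContactPairSet

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != self.pair_index.n_pairs:
            raise ValueError("column count must equal pair count")
        if len(self.frame_meta) != self.values.shape[0]:
            raise ValueError("frame_meta length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing values in feature matrix")

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    def to_csv(self, path) -> None:
        cols = [f"{i}-{j}" for i, j in self.pair_index.pairs]
        df = pd.concat([self.frame_meta.reset_index(drop=True),
                        pd.DataFrame(self.values, columns=cols)], axis=1)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta_cols = ["system", "replica", "time_ps"]
        pair_cols = [c for c in df.columns if c not in meta_cols]
        pairs = [tuple(int(x) for x in c.split("-")) for c in pair_cols]
        values = df[pair_cols].to_numpy(dtype=float)
        # reference distances are not stored in the CSV; use column minima as
        # a placeholder reference when reloading without the pair TSV
        ps = ContactPairSet(pairs, values.min(axis=0), reference_source=str(path))
        return cls(values, df[meta_cols].copy(), ps)


def concat_features(mats: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate feature matrices sharing the same pair set."""
    if not mats:
        raise ValueError("nothing to concatenate")
    first = mats[0].pair_index
    for m in mats[1:]:
        if m.pair_index.pairs != first.pairs:
            raise ValueError("pair sets differ between feature matrices")
    values = np.vstack([m.values for m in mats])
    meta = pd.concat([m.frame_meta for m in mats], ignore_index=True)
    return FeatureMatrix(values, meta, first)


# ---------------------------------------------------------------------------
# contact definition and featurization

def find_native_contact_pairs(reference: StructureModel,
                              spec: FeatureSpec | None = None) -> ContactPairSet:
    """All residue pairs whose representative atoms are in contact.

    Representative atoms follow the Cbeta rule (Calpha for glycine); a pair
    (i < j) is a native contact when its distance is strictly below
    ``spec.contact_cutoff`` and the sequence separation is at least
    ``spec.min_sequence_separation``.
    """
    spec = spec or FeatureSpec()
    sel = select_atoms(reference, SelectionSpec(kind="cbeta_or_ca_gly"))
    if not sel:
        raise ValueError("empty cbeta_or_ca_gly selection on reference")
    coords = np.array([a.coords for a in sel])
    resids = [a.residue_index for a in sel]
    D = squareform(pdist(coords))
    pairs, dists = [], []
    for ii in range(len(sel)):
        for jj in range(ii + 1, len(sel)):
            if abs(resids[jj] - resids[ii]) < spec.min_sequence_separation:
                continue
            if D[ii, jj] < spec.contact_cutoff:
                pairs.append((resids[ii], resids[jj]))
                dists.append(D[ii, jj])
    return ContactPairSet(pairs, np.array(dists),
                          reference_source=reference.source)


def _strided_frames(times: np.ndarray, stride: float) -> np.ndarray:
    """Indices of frames whose timestamps are multiples of the stride."""
    k = np.round(times / stride)
    return np.where(np.abs(k * stride - times) < 1e-6 * max(stride, 1.0))[0]


def compute_features(traj: TrajectoryHandle, pairs: ContactPairSet,
                     spec: FeatureSpec | None = None) -> FeatureMatrix:
    """Distance vectors for frames sampled at the stride (Angstrom)."""
    spec = spec or FeatureSpec()
    sel_spec = SelectionSpec(kind="cbeta_or_ca_gly")
    sel = select_atoms(traj.topology, sel_spec)
    idx = atom_indices(traj.topology, sel_spec)
    sel_idx = {a.residue_index: i for a, i in zip(sel, idx)}
    try:
        ii = np.array([sel_idx[i] for i, _ in pairs.pairs])
        jj = np.array([sel_idx[j] for _, j in pairs.pairs])
    except KeyError as e:
        raise ValueError(f"pair member residue {e} missing from topology") from e
    keep = _strided_frames(traj.frame_times, spec.stride)
    X = traj.coords[keep]
    values = np.linalg.norm(X[:, ii, :] - X[:, jj, :], axis=2)
    meta = pd.DataFrame({
        "system": traj.system_label,
        "replica": traj.replica_id,
        "time_ps": traj.frame_times[keep],
    })
    return FeatureMatrix(values, meta, pairs)


# ---------------------------------------------------------------------------
# standard trajectory analyses

def _matched_coords(traj: TrajectoryHandle, reference: StructureModel,
                    kind: str) -> tuple[np.ndarray, np.ndarray, list[int]]:
    ref_sel = select_atoms(reference, SelectionSpec(kind=kind))
    top_sel = select_atoms(traj.topology, SelectionSpec(kind=kind))
    ref_keys = [(a.chain_id, a.residue_index, a.name) for a in ref_sel]
    top_keys = [(a.chain_id, a.residue_index, a.name) for a in top_sel]
    if ref_keys != top_keys:
        raise ValueError("selection mismatch between trajectory and reference")
    idx = atom_indices(traj.topology, SelectionSpec(kind=kind))
    ref_xyz = np.array([a.coords for a in ref_sel])
    return traj.coords[:, idx, :], ref_xyz, idx


def backbone_rmsd_series(traj: TrajectoryHandle, reference: StructureModel,
                         selection: str = "backbone",
                         superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD to a reference (optimal superposition by default)."""
    X, ref, _ = _matched_coords(traj, reference, selection)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        if superpose:
            R, t = kabsch(X[f], ref)
            out[f] = _plain_rmsd(X[f] @ R.T + t, ref)
        else:
            out[f] = _plain_rmsd(X[f], ref)
    return out


def rmsf_per_residue(replicas: list[TrajectoryHandle]) -> pd.DataFrame:
    """Per-residue Calpha RMSF: mean and SEM across replicas.

    Each replica is superposed onto its own mean structure (two-pass) and
    the fluctuation about that mean is computed per residue. SEM is
    sd / sqrt(n_replicas).
    """
    if not replicas:
        raise ValueError("at least one replica required")
    per_replica = []
    resids = None
    for traj in replicas:
        if traj.n_frames < 2:
            raise ValueError("replica with a single frame has undefined RMSF")
        ca_spec = SelectionSpec(kind="custom", names=("CA",))
        sel = select_atoms(traj.topology, ca_spec)
        idx = atom_indices(traj.topology, ca_spec)
        ids = [a.residue_index for a in sel]
        if resids is None:
            resids = ids
        elif ids != resids:
            raise ValueError("replicas have differing residue sets")
        X = traj.coords[:, idx, :].copy()
        # two-pass alignment to the mean structure
        for _ in range(2):
            mean = X.mean(axis=0)
            for f in range(X.shape[0]):
                R, t = kabsch(X[f], mean)
                X[f] = X[f] @ R.T + t
        mean = X.mean(axis=0)
        per_replica.append(np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0)))
    arr = np.array(per_replica)  # (n_replicas, n_residues)
    n = arr.shape[0]
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1])
    return pd.DataFrame({"residue_index": resids,
                         "rmsf_mean_A": arr.mean(axis=0),
                         "rmsf_sem_A": sem})


def contact_count_series(traj: TrajectoryHandle, cutoff: float = 4.5,
                         min_sequence_separation: int = 3) -> np.ndarray:
    """Per-frame count of intra-domain residue-residue heavy-atom contacts.

    Two residues are in contact when any pair of their heavy atoms is
    closer than `cutoff` (4.5 Angstrom by default); trivially bonded
    neighbours are excluded via the sequence-separation floor.
    """
    heavy = SelectionSpec(kind="heavy")
    sel = select_atoms(traj.topology, heavy)
    if not sel:
        raise ValueError("empty heavy-atom selection")
    idx = atom_indices(traj.topology, heavy)
    resid = np.array([a.residue_index for a in sel])
    counts = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        X = traj.coords[f, idx, :]
        tree = cKDTree(X)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            counts[f] = 0
            continue
        ri, rj = resid[pairs[:, 0]], resid[pairs[:, 1]]
        ok = np.abs(ri - rj) >= min_sequence_separation
        respairs = {(min(a, b), max(a, b)) for a, b in zip(ri[ok], rj[ok])}
        counts[f] = len(respairs)
    return counts
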