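"""Projection of per-frame and per-pose quantities onto the SOM.

Covers per-system cluster occupancies, neuron population maps, per-neuron
scalar means (e.g. helical content), top-N docking-score aggregation and
per-neuron representative frame extraction. Neurons without contributing
items carry NaN, never zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .featurization import FeatureMatrix
from .neuron_clustering import NeuronClustering
from .som_core import BMUAssignment, SOMModel

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class NeuronPropertyMap:
    """Per-neuron scalar values with the count of contributing items."""

    values: np.ndarray  # NaN marks neurons with no contributing items
    counts: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.values.shape != self.counts.shape:
            raise ValueError("values/counts shape mismatch")

    @property
    def n_neurons(self) -> int:
        return int(self.values.shape[0])

    def to_csv(self, path, nx: int) -> None:
        rows, cols = np.divmod(np.arange(self.n_neurons), nx)
        pd.DataFrame({"neuron": np.arange(self.n_neurons), "row": rows,
                      "col": cols, "value": self.values,
                      "n": self.counts}).to_csv(path, index=False)


@dataclass
class DockAggregation:
    """Top-N aggregation of docking scores per neuron."""

    poses_per_neuron: int = 200
    top_n: int = 5

    def __post_init__(self):
        if not 1 <= self.top_n <= self.poses_per_neuron:
            raise ValueError("require 1 <= top_n <= poses_per_neuron")


def cluster_letters(clustering: NeuronClustering,
                    assignment: BMUAssignment) -> dict[int, str]:
    """Display letters A, B, ... for clusters by decreasing frame population."""
    pop = np.bincount(assignment.neuron, minlength=len(clustering.labels))
    totals = {lab: int(pop[clustering.labels == lab].sum())
              for lab in range(1, clustering.k + 1)}
    ranked = sorted(totals, key=lambda lab: (-totals[lab], lab))
    return {lab: _LETTERS[i] for i, lab in enumerate(ranked)}


def _systems(assignment: BMUAssignment) -> pd.Series:
    if assignment.frame_meta is None or "system" not in assignment.frame_meta:
        return pd.Series([""] * assignment.n_frames, name="system")
    return assignment.frame_meta["system"].reset_index(drop=True)


def occupancy_table(assignment: BMUAssignment,
                    clustering: NeuronClustering) -> pd.DataFrame:
    """Per-system percentage of frames falling within each cluster.

    Rows are systems, columns are cluster letters (by decreasing total
    population); each row sums to 100. The per-system frame counts are in
    ``df.attrs['n_frames']``.
    """
    letters = cluster_letters(clustering, assignment)
    frame_cluster = clustering.labels[assignment.neuron]
    df = pd.DataFrame({"system": _systems(assignment),
                       "cluster": [letters[c] for c in frame_cluster]})
    counts = df.groupby(["system", "cluster"], sort=True).size().unstack(fill_value=0)
    counts = counts.reindex(columns=sorted(set(letters.values())), fill_value=0)
    n_frames = counts.sum(axis=1)
    pct = counts.div(n_frames, axis=0) * 100.0
    pct.attrs["n_frames"] = n_frames.to_dict()
    return pct


def neuron_population_map(assignment: BMUAssignment, n_neurons: int,
                          system: str | None = None) -> NeuronPropertyMap:
    """Frame counts per neuron, optionally restricted to one system."""
    neuron = assignment.neuron
    if system is not None:
        systems = _systems(assignment)
        if system not in set(systems):
            raise ValueError(f"unknown system label {system!r}")
        neuron = neuron[(systems == system).to_numpy()]
    counts = np.bincount(neuron, minlength=n_neurons)
    values = counts.astype(float)
    values[counts == 0] = np.nan
    return NeuronPropertyMap(values=values, counts=counts,
                             name="population", units="frames")


def map_scalar(assignment: BMUAssignment, per_frame_values: np.ndarray,
               n_neurons: int, name: str = "", units: str = "") -> NeuronPropertyMap:
    """Arithmetic mean of a per-frame scalar over frames assigned to each neuron."""
    vals = np.asarray(per_frame_values, dtype=float)
    if vals.shape[0] != assignment.n_frames:
        raise ValueError("one value per frame required")
    counts = np.bincount(assignment.neuron, minlength=n_neurons)
    sums = np.bincount(assignment.neuron, weights=vals, minlength=n_neurons)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return NeuronPropertyMap(values=means, counts=counts, name=name, units=units)


def aggregate_dockq(per_neuron_scores: list[list[float]],
                    agg: DockAggregation | None = None) -> NeuronPropertyMap:
    """Mean of the top_n largest scores per neuron (top five of 200 by default).

    Neurons with fewer than top_n scores average all of them (with a
    warning); neurons with no scores are marked missing.
    """
    agg = agg or DockAggregation()
    values, counts = [], []
    for i, scores in enumerate(per_neuron_scores):
        if len(scores) > agg.poses_per_neuron:
            raise ValueError(f"neuron {i}: more scores than poses_per_neuron")
        counts.append(len(scores))
        if len(scores) == 0:
            values.append(np.nan)
            continue
        ranked = sorted(scores, reverse=True)
        if len(ranked) < agg.top_n:
            warnings.warn(f"neuron {i}: only {len(ranked)} scores; averaging all")
            values.append(float(np.mean(ranked)))
        else:
            values.append(float(np.mean(ranked[:agg.top_n])))
    return NeuronPropertyMap(values=np.array(values), counts=np.array(counts),
                             name="dockq_top{}".format(agg.top_n), units="")


def representative_frame(neuron: int, features: FeatureMatrix,
                         assignment: BMUAssignment,
                         codebook: np.ndarray | None = None) -> int | None:
    """Frame (row index) closest to the geometric centre of a neuron.

    The centre is the mean feature vector of the frames assigned to the
    neuron; passing `codebook` uses that neuron's codebook vector
    instead (the two agree closely on converged maps). Ties go to the
    earliest frame; empty neurons return None.
    """
    idx = np.where(assignment.neuron == neuron)[0]
    if len(idx) == 0:
        return None
    X = features.values[idx]
    center = codebook[neuron] if codebook is not None else X.mean(axis=0)
    d = np.linalg.norm(X - center, axis=1)
    return int(idx[np.argmin(d)])


def representative_frames(features: FeatureMatrix, assignment: BMUAssignment,
                          n_neurons: int,
                          codebook: np.ndarray | None = None) -> list[int | None]:
    """Representative frame per neuron (None for unpopulated neurons)."""
    return [representative_frame(v, features, assignment, codebook=codebook)
            for v in range(n_neurons)]
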