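"""Toroidal hexagonal self-organizing map.

The map is a Kohonen network on an nx-by-ny hexagonal lattice with
periodic (toroidal) boundaries, so every neuron has exactly six nearest
neighbours and the map has no edge artifacts. Training is online: input
rows are visited in a seeded shuffled order, the best-matching unit (BMU)
is found by Euclidean distance, and the BMU neighbourhood is pulled
toward the input with linearly decaying learning rate and radius.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass
class GridSpec:
    """Hexagonal lattice geometry (nx columns, ny rows)."""

    nx: int = 8
    ny: int = 8
    toroidal: bool = True

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must be at least 2x2")
        if self.toroidal and self.ny % 2 != 0:
            raise ValueError("toroidal hex grids require an even number of rows")

    @property
    def n_neurons(self) -> int:
        return self.nx * self.ny


@dataclass
class SOMTrainParams:
    """Online-training schedule.

    Learning rate decays linearly alpha_start -> alpha_end over all update
    steps; the gaussian neighbourhood radius decays linearly from
    radius_start (default: the 2/3 quantile of all inter-neuron lattice
    distances) to zero.
    """

    epochs: int = 100
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_start: float | None = None
    neighborhood: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.alpha_start >= self.alpha_end > 0):
            raise ValueError("require alpha_start >= alpha_end > 0")
        if self.neighborhood not in ("gaussian", "bubble"):
            raise ValueError("neighborhood must be 'gaussian' or 'bubble'")


@dataclass
class SOMModel:
    """Trained map: grid geometry + per-neuron codebook vectors (Angstrom)."""

    grid: GridSpec
    codebook: np.ndarray  # (n_neurons, dim)
    training_qerror: np.ndarray  # per-epoch mean quantization error
    params: SOMTrainParams
    feature_ref: str = ""
    # set when trained with standardize=True; BMU assignment re-applies it
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def __post_init__(self):
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.grid.n_neurons:
            raise ValueError("codebook size must equal nx*ny")
        if not np.all(np.isfinite(self.codebook)):
            raise ValueError("non-finite codebook vectors")

    def to_json(self, path) -> None:
        blob = {
            "grid": asdict(self.grid),
            "params": asdict(self.params),
            "training_qerror": np.asarray(self.training_qerror).tolist(),
            "codebook": self.codebook.tolist(),
            "feature_ref": self.feature_ref,
            "feature_mean": None if self.feature_mean is None
                            else np.asarray(self.feature_mean).tolist(),
            "feature_scale": None if self.feature_scale is None
                             else np.asarray(self.feature_scale).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def from_json(cls, path) -> "SOMModel":
        with open(path) as fh:
            blob = json.load(fh)
        fm = blob.get("feature_mean")
        fs = blob.get("feature_scale")
        return cls(grid=GridSpec(**blob["grid"]),
                   codebook=np.array(blob["codebook"]),
                   training_qerror=np.array(blob["training_qerror"]),
                   params=SOMTrainParams(**blob["params"]),
                   feature_ref=blob.get("feature_ref", ""),
                   feature_mean=None if fm is None else np.array(fm),
                   feature_scale=None if fs is None else np.array(fs))


@dataclass
class BMUAssignment:
    """Per-frame best-matching unit and quantization error."""

    neuron: np.ndarray  # int, 0..n_neurons-1
    qerror: np.ndarray  # Euclidean distance to the BMU, Angstrom
    frame_meta: "object" = None  # optional pandas DataFrame

    def __post_init__(self):
        self.neuron = np.asarray(self.neuron, dtype=int)
        self.qerror = np.asarray(self.qerror, dtype=float)
        if self.neuron.shape != self.qerror.shape:
            raise ValueError("neuron/qerror shape mismatch")
        if np.any(self.qerror < 0):
            raise ValueError("negative quantization error")

    @property
    def n_frames(self) -> int:
        return int(self.neuron.shape[0])


# ---------------------------------------------------------------------------
# lattice geometry

def neuron_positions(grid: GridSpec) -> np.ndarray:
    """2-D embedding of the hex lattice; neuron index = row*nx + col.

    Row i, column j sits at x = j + 0.5*(i mod 2), y = i*sqrt(3)/2, so all
    adjacent units are at embedding distance 1.
    """
    rows, cols = np.divmod(np.arange(grid.n_neurons), grid.nx)
    x = cols + 0.5 * (rows % 2)
    y = rows * SQRT3_2
    return np.column_stack([x, y]).astype(float)


def pairwise_lattice_distances(grid: GridSpec) -> np.ndarray:
    """All-pairs lattice distance; toroidal maps minimize over 9 images."""
    pos = neuron_positions(grid)
    if not grid.toroidal:
        return cdist(pos, pos)
    shifts = [(sx * grid.nx, sy * grid.ny * SQRT3_2)
              for sx in (-1, 0, 1) for sy in (-1, 0, 1)]
    best = np.full((grid.n_neurons, grid.n_neurons), np.inf)
    for sx, sy in shifts:
        d = cdist(pos, pos + np.array([sx, sy]))
        np.minimum(best, d, out=best)
    return best


def lattice_distance(u: int, v: int, grid: GridSpec) -> float:
    """Lattice distance between two neurons (toroidal-aware)."""
    pos = neuron_positions(grid)
    if not grid.toroidal:
        return float(np.linalg.norm(pos[u] - pos[v]))
    best = np.inf
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            img = pos[v] + np.array([sx * grid.nx, sy * grid.ny * SQRT3_2])
            best = min(best, np.linalg.norm(pos[u] - img))
    return float(best)


# ---------------------------------------------------------------------------
# training

@njit(cache=False)
def _train_online(X, codebook, order, D2, alphas, sigmas, gaussian, qerr_sum,
                  epoch_len):  # pragma: no cover - exercised via train_som
    n_steps = order.shape[0]
    n_neurons, dim = codebook.shape
    for t in range(n_steps):
        row = order[t]
        best = 0
        best_d = 1.0e300
        for v in range(n_neurons):
            s = 0.0
            for j in range(dim):
                diff = X[row, j] - codebook[v, j]
                s += diff * diff
            if s < best_d:
                best_d = s
                best = v
        qerr_sum[t // epoch_len] += np.sqrt(best_d)
        a = alphas[t]
        sig = sigmas[t]
        if gaussian:
            denom = 2.0 * sig * sig
            for v in range(n_neurons):
                if denom > 0.0:
                    h = np.exp(-D2[best, v] / denom)
                else:
                    h = 1.0 if v == best else 0.0
                if h > 1.0e-12:
                    for j in range(dim):
                        codebook[v, j] += a * h * (X[row, j] - codebook[v, j])
        else:
            sig2 = sig * sig
            for v in range(n_neurons):
                if D2[best, v] <= sig2 or v == best:
                    for j in range(dim):
                        codebook[v, j] += a * (X[row, j] - codebook[v, j])


def _as_array(features) -> np.ndarray:
    X = getattr(features, "values", features)
    return np.ascontiguousarray(np.asarray(X, dtype=np.float64))


def train_som(features, grid: GridSpec | None = None,
              params: SOMTrainParams | None = None,
              feature_ref: str = "", standardize: bool = False) -> SOMModel:
    """Train the toroidal hex SOM on a FeatureMatrix (or plain array).

    The codebook is initialized by sampling distinct input rows (seeded);
    training is bit-reproducible for a given seed. `standardize` z-scores
    the feature columns before training (off by default: contact
    distances share units); the scaling is stored on the model and
    re-applied by assign_bmu.
    """
    grid = grid or GridSpec()
    params = params or SOMTrainParams()
    X = _as_array(features)
    if X.shape[0] == 0:
        raise ValueError("empty training input")
    feature_mean = feature_scale = None
    if standardize:
        feature_mean = X.mean(axis=0)
        feature_scale = X.std(axis=0)
        feature_scale[feature_scale == 0] = 1.0
        X = np.ascontiguousarray((X - feature_mean) / feature_scale)
    if X.shape[0] < grid.n_neurons:
        warnings.warn("fewer input rows than neurons; codebook init will repeat rows")
    if np.any(X.std(axis=0) == 0):
        warnings.warn("zero-variance feature column(s) present")

    rng = np.random.default_rng(params.seed)
    n = X.shape[0]
    init_idx = rng.choice(n, size=grid.n_neurons, replace=n < grid.n_neurons)
    codebook = X[init_idx].copy()

    D = pairwise_lattice_distances(grid)
    D2 = np.ascontiguousarray(D ** 2)
    radius0 = params.radius_start
    if radius0 is None:
        radius0 = float(np.quantile(D[np.triu_indices_from(D, k=1)], 2.0 / 3.0))

    n_steps = params.epochs * n
    order = np.concatenate([rng.permutation(n) for _ in range(params.epochs)])
    order = np.ascontiguousarray(order.astype(np.int64))
    frac = np.arange(n_steps, dtype=np.float64) / max(n_steps - 1, 1)
    alphas = params.alpha_start + (params.alpha_end - params.alpha_start) * frac
    sigmas = np.maximum(radius0 * (1.0 - frac), 1.0e-9)
    qerr_sum = np.zeros(params.epochs)
    _train_online(X, codebook, order, D2, alphas, sigmas,
                  params.neighborhood == "gaussian", qerr_sum, n)
    return SOMModel(grid=grid, codebook=codebook,
                    training_qerror=qerr_sum / n, params=params,
                    feature_ref=feature_ref, feature_mean=feature_mean,
                    feature_scale=feature_scale)


def assign_bmu(features, model: SOMModel) -> BMUAssignment:
    """Best-matching unit per frame (ties resolved to the lowest index)."""
    X = _as_array(features)
    if X.shape[1] != model.codebook.shape[1]:
        raise ValueError("feature dimension does not match codebook")
    if model.feature_mean is not None:
        X = (X - model.feature_mean) / model.feature_scale
    D = cdist(X, model.codebook)
    neuron = np.argmin(D, axis=1)  # argmin returns the first (lowest) index
    qerror = D[np.arange(X.shape[0]), neuron]
    meta = getattr(features, "frame_meta", None)
    return BMUAssignment(neuron=neuron, qerror=qerror, frame_meta=meta)


# ---------------------------------------------------------------------------
# display re-centering

def _display_adjacency(grid: GridSpec) -> np.ndarray:
    """Non-periodic hex adjacency of the display grid (pairs of indices)."""
    pos = neuron_positions(grid)
    D = cdist(pos, pos)
    ii, jj = np.where(np.abs(D - 1.0) < 1e-9)
    keep = ii < jj
    return np.column_stack([ii[keep], jj[keep]])


def _n_components(labels: np.ndarray, edges: np.ndarray, n: int) -> int:
    total = 0
    for lab in np.unique(labels):
        nodes = np.where(labels == lab)[0]
        remap = -np.ones(n, dtype=int)
        remap[nodes] = np.arange(len(nodes))
        sub = edges[(labels[edges[:, 0]] == lab) & (labels[edges[:, 1]] == lab)]
        m = coo_matrix((np.ones(len(sub)), (remap[sub[:, 0]], remap[sub[:, 1]])),
                       shape=(len(nodes), len(nodes)))
        ncomp, _ = connected_components(m, directed=False)
        total += ncomp
    return total


def recenter_map(model: SOMModel, labels: np.ndarray) -> tuple[int, int]:
    """Display shift (dx, dy) that makes clusters maximally contiguous.

    Scans all nx*ny cyclic shifts of the toroidal map and returns the one
    minimizing the total number of connected components over clusters when
    the shifted map is drawn without wraparound. Ties prefer smaller
    |dx|+|dy|, then smaller dx, then dy. Display-only: neuron indices are
    unchanged. Non-toroidal maps return (0, 0).
    """
    grid = model.grid
    labels = np.asarray(labels)
    if labels.shape[0] != grid.n_neurons:
        raise ValueError("labels length must equal the number of neurons")
    if not grid.toroidal:
        return (0, 0)
    edges = _display_adjacency(grid)
    rows, cols = np.divmod(np.arange(grid.n_neurons), grid.nx)
    best = None
    for dy in range(grid.ny):
        for dx in range(grid.nx):
            src = ((rows + dy) % grid.ny) * grid.nx + (cols + dx) % grid.nx
            score = _n_components(labels[src], edges, grid.n_neurons)
            key = (score, abs(dx) + abs(dy), dx, dy)
            if best is None or key < best[0]:
                best = (key, (dx, dy))
    return best[1]


def shifted_labels(grid: GridSpec, values: np.ndarray,
                   shift: tuple[int, int]) -> np.ndarray:
    """Apply a display shift to any per-neuron array (for rendering)."""
    dx, dy = shift
    rows, cols = np.divmod(np.arange(grid.n_neurons), grid.nx)
    src = ((rows + dy) % grid.ny) * grid.nx + (cols + dx) % grid.nx
    return np.asarray(values)[src]
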