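"""Pipeline configuration: a single validated YAML file.

Unknown keys are rejected so typos fail fast. A complete annotated
example ships with the package (see `example_config`).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .featurization import FeatureSpec
from .property_mapping import DockAggregation
from .som_core import GridSpec, SOMTrainParams

STAGE_OFFSETS = {
    "simulate": 1, "featurize": 2, "train": 3, "cluster": 4,
    "map": 5, "represent": 6, "score": 7, "render": 8,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the global seed."""
    return (int(global_seed) * 10007 + STAGE_OFFSETS[stage]) % (2 ** 31)


@dataclass
class SyntheticConfig:
    """Synthetic-ensemble declaration for the simulate stage."""

    n_res: int = 18
    occupancy: dict = field(default_factory=lambda: {
        "WT": [1.0, 0.0, 0.0, 0.0], "MUT": [0.3, 0.4, 0.2, 0.1]})
    n_frames: dict = field(default_factory=lambda: {"WT": 50, "MUT": 100})
    n_replicas: int = 2
    noise_sigma: float = 0.3


@dataclass
class PipelineConfig:
    systems: dict = field(default_factory=dict)  # label -> list of {topology, trajectory, replica}
    reference: str | None = None  # structure defining native contacts
    synthetic: SyntheticConfig | None = None
    feature: FeatureSpec = field(default_factory=FeatureSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    training: SOMTrainParams = field(default_factory=SOMTrainParams)
    k_min: int = 2
    k_max: int = 10
    helix_regions: dict = field(default_factory=dict)  # name -> [first, last]
    dock_aggregation: DockAggregation = field(default_factory=DockAggregation)
    outdir: str = "mdsom_out"
    seed: int = 0

    _SECTIONS = {"systems", "reference", "synthetic", "feature", "grid",
                 "training", "k_min", "k_max", "helix_regions",
                 "dock_aggregation", "outdir", "seed"}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - cls._SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(klass, section):
            data = raw.get(section) or {}
            valid = {f for f in klass.__dataclass_fields__}
            bad = set(data) - valid
            if bad:
                raise ValueError(f"unknown keys in '{section}': {sorted(bad)}")
            return klass(**data)

        return cls(
            systems=raw.get("systems") or {},
            reference=raw.get("reference"),
            synthetic=build(SyntheticConfig, "synthetic")
                      if "synthetic" in raw else None,
            feature=build(FeatureSpec, "feature"),
            grid=build(GridSpec, "grid"),
            training=build(SOMTrainParams, "training"),
            k_min=int(raw.get("k_min", 2)),
            k_max=int(raw.get("k_max", 10)),
            helix_regions=raw.get("helix_regions") or {},
            dock_aggregation=build(DockAggregation, "dock_aggregation"),
            outdir=str(raw.get("outdir", "mdsom_out")),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        d = {
            "systems": self.systems,
            "reference": self.reference,
            "feature": asdict(self.feature),
            "grid": asdict(self.grid),
            "training": asdict(self.training),
            "k_min": self.k_min, "k_max": self.k_max,
            "helix_regions": self.helix_regions,
            "dock_aggregation": asdict(self.dock_aggregation),
            "outdir": self.outdir, "seed": self.seed,
        }
        if self.synthetic is not None:
            d["synthetic"] = asdict(self.synthetic)
        return d


EXAMPLE_CONFIG = """\
# mdsom pipeline configuration
# Either declare real trajectories under `systems`, or a `synthetic`
# section for a ground-truthed demo ensemble built by `mdsom simulate`.

seed: 1
outdir: mdsom_out

synthetic:
  n_res: 18             # residues in the synthetic helix peptide
  n_replicas: 2
  noise_sigma: 0.3      # Angstrom, isotropic per-atom Gaussian noise
  occupancy:            # per-system probabilities over the 4 macrostates
    WT:  [1.0, 0.0, 0.0, 0.0]
    MUT: [0.3, 0.4, 0.2, 0.1]
  n_frames:             # frames per replica
    WT: 50
    MUT: 100

# systems:              # for real data instead of `synthetic`
#   WT:
#     - {topology: wt.pdb, trajectory: wt_r1.xtc, replica: 1}
# reference: wt.pdb     # structure defining the native-contact pairs

feature:
  contact_cutoff: 11.0  # Angstrom (1.1 nm native-contact threshold)
  min_sequence_separation: 0
  stride: 100.0         # ps between retained frames

grid:
  nx: 8
  ny: 8
  toroidal: true

training:
  epochs: 100
  alpha_start: 0.05
  alpha_end: 0.01
  neighborhood: gaussian

k_min: 2
k_max: 10

helix_regions:          # inclusive residue ranges, topology numbering
  H3: [7, 14]

dock_aggregation:
  poses_per_neuron: 200
  top_n: 5
"""
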