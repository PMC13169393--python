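# Methods

This note documents the models, numerical choices and limitations behind
`mdsom`. Units are Angstrom for lengths, picoseconds for times and
kcal/mol for hydrogen-bond energies throughout.

## Native-contact featurization

A conformational snapshot is encoded as the vector of interatomic
distances between residue-representative atoms — Cβ, with Cα
substituted for glycine — over the pair set of *native contacts*: all
residue pairs (i < j) whose representative atoms lie strictly below the
contact cutoff in a reference structure. The default cutoff is 11.0 Å
(1.1 nm), a literature-standard threshold for reproducing protein
contact maps; it is stored internally in Å because PDB coordinates are
native Å. Distances are strictly compared (`d < cutoff`); at 11 Å the
choice of strict versus non-strict inequality is numerically immaterial
for real coordinates.

Two knobs matter in practice:

* `min_sequence_separation` (default 0) — no pairs are excluded by
  sequence distance by default; the parameter exists for sensitivity
  analyses because short-range pairs carry little conformational signal.
* `stride` (default 100 ps) — frames whose timestamps are not multiples
  of the stride are skipped, never interpolated, matching
  fixed-interval sampling of production trajectories. Formats that carry
  no time information (multi-model PDB) accept an explicit `dt_ps`.

Features are raw distances, unscaled: all columns share units and
comparable dynamic range, so standardization would only reweight noise.
A standardization switch exists but defaults off.

## Toroidal hexagonal SOM

Neurons sit on an nx×ny hexagonal lattice embedded at
x = col + 0.5·(row mod 2), y = row·√3/2, so adjacent units are at
embedding distance 1. With toroidal boundaries the lattice distance is
the minimum over the 9 periodic images (x shifts ±nx, y shifts
±ny·√3/2); consistent wrapping of the row-offset hex geometry requires
an even number of rows, which the default 8×8 grid satisfies. On the
torus every neuron has exactly six nearest neighbours, eliminating edge
effects — appropriate for sampling *around* equilibrium states rather
than along a path with endpoints.

Training is online Kohonen learning: input rows are visited in a seeded
shuffled order each epoch; the best-matching unit u (Euclidean argmin,
ties to the lowest neuron index) and its neighbourhood are updated as
w_v ← w_v + α(t)·h(u,v,t)·(x − w_v), with a Gaussian neighbourhood
h = exp(−d²(u,v)/2σ(t)²) measured in lattice distance. Schedules follow
common Kohonen-map practice: α decays linearly 0.05 → 0.01; σ decays
linearly from the 2/3 quantile of all inter-neuron lattice distances to
zero; 100 epochs. The codebook is initialized by sampling distinct input
rows (seeded), and the per-epoch mean quantization error is recorded.
All schedules are configurable and logged in the run manifest; training
is bit-reproducible given a seed. The inner update loop is JIT-compiled
(numba), which keeps a 100-epoch pass over ~2×10⁴ frames × ~10² features
in the tens of seconds on one CPU.

## Macrostate clustering and k selection

Neuron codebook vectors are clustered by complete-linkage agglomeration
with Euclidean distances (scipy linkage). The number of clusters is
selected by maximizing the mean silhouette over k = 2..10, ties going to
the smaller k.

Where the silhouette is evaluated matters more than expected. Evaluating
it on codebook vectors alone is confounded by *interpolating dead
units*: a topology-preserving map trained on well-separated discrete
macrostates necessarily leaves some neurons stranded between the states
(they are never anyone's BMU once the neighbourhood radius has shrunk),
and those stranded vectors form spurious, well-separated "clusters" that
inflate the silhouette at large k. `select_k` therefore evaluates the
silhouette at the frame level whenever the training features are
supplied: each candidate clustering's labels are carried to the frames
through their BMUs, so clusters without frames contribute nothing, and
candidate k values whose *effective* frame partitions coincide score
identically and resolve to the smallest k. Frame-level evaluation
deterministically subsamples at most 2048 frames (silhouette cost is
quadratic). The codebook-level silhouette remains available (and is the
fallback when no features are passed); on smooth, densely sampled
ensembles the two agree.

Cluster display labels A, B, … are assigned by decreasing total
assigned-frame population — a stable, meaningful naming; they are
display conventions, not identities.

## Property mapping

* Occupancy tables report, per system, the percentage of frames in each
  cluster (rows sum to 100).
* Per-neuron scalar maps are arithmetic means over the frames assigned
  to the neuron; neurons with no contributing items are explicitly
  missing (NaN, rendered hatched), never zero-filled — zero is a valid
  data value.
* Docking-quality mapping takes the mean of the top-5 largest scores of
  the (nominally 200) poses per neuron; fewer than five scores are
  averaged in full with a warning; truncation at rank 5 is stable, ties
  at the boundary are not expanded.
* The representative frame of a neuron minimizes the Euclidean distance
  to the *mean feature vector of the frames assigned to that neuron*
  (its geometric centre), with ties to the earliest frame. Using the
  codebook vector instead is available via a flag; on converged maps the
  two choices agree closely.

## α-helix assignment

The assigner re-implements the DSSP hydrogen-bond criterion natively so
the pipeline needs no external binary. A backbone H-bond between the
C=O of residue i and the N–H of residue j exists when the electrostatic
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) falls below
−0.5 kcal/mol. Amide hydrogens absent from the model are rebuilt 1.01 Å
from N along the bisector opposing C(prev) and Cα. A residue is
α-helical when it lies inside a helix started by two consecutive
(i, i+4) turns. Chain breaks (C–N distance > 2.5 Å) invalidate spanning
bonds. 3₁₀ and π helices are not separated out — the mapped quantity is
α-helical content. Helix regions (e.g. H2/H3/H4 of a forkhead domain)
are configuration inputs; the shipped defaults are approximations
consistent with partially specified boundaries and should be overridden
when exact ranges are known.

## CAPRI / DockQ scoring

Constants follow the published DockQ definition: Fnat contacts at 5.0 Å
between heavy atoms of protein residues and nucleotides; interface
residues for i-RMSD at 10.0 Å; DockQ scaling d1 = 1.5 Å (i-RMSD) and
d2 = 8.5 Å (l-RMSD). The DNA is the receptor: l-RMSD superposes the DNA
backbone (P, O5′, C5′, C4′, C3′, O3′) and measures the protein backbone
(N, Cα, C, O); this receptor-superposition convention is configurable.
Correspondence between a pose and the reference is by chain role +
residue index — docking inputs share numbering by construction, so no
sequence alignment is attempted. The docking-validation analyses use a
4.0 Å heavy-atom cutoff for interface-contact persistence and align
trajectory frames on the DNA *phosphorus atoms only* before measuring
protein backbone RMSD. The reference dsDNA duplex sequence and the
active-residue lists used in reproduction runs ship as constants in the
scoring module.

## Synthetic data: what it emulates and what it does not

The ensemble generator draws frames i.i.d. from per-system occupancy
vectors over a small set of template conformations and adds isotropic
per-atom Gaussian noise (default σ = 0.3 Å, a thermal-magnitude jitter).
Templates are poly-alanine helices (ideal backbone geometry, φ = −57°,
ψ = −47°) with localized unwinding windows (φ = ψ = 180°) placed in the
chain interior — terminal residues fray under the helix rule anyway, so
interior windows are what make the macrostates distinguishable both in
contact-distance space and in helicity. The default study-like
conditions use four macrostates, a WT-like system pinned to the folded
template, and a mobile system at 30/40/20/10 % over 10 replicas of
2,000 frames (20,000 frames).

This emulates the *statistical* structure of multi-replica MD — planted
occupancies, localized secondary-structure differences, exchangeable
frames — but deliberately not its physics: there is no kinetics or
autocorrelation (the pipeline treats frames exchangeably), no
force-field energetics, and the discrete templates make macrostates
more separable than real ensembles, where states blur into each other.
Passing tests on synthetic data therefore demonstrates the correctness
of the machinery (featurization, training, selection, mapping, scoring)
and its recovery guarantees under known ground truth — not that any
particular real ensemble will cluster cleanly.

The pose generator perturbs the protein rigidly (rotation about the
interface centroid around a seeded random axis, translation along a
seeded random direction) with recorded magnitudes, giving closed-form
expectations (pure translation t ⇒ l-RMSD = |t|). The synthetic
protein–DNA reference complex is schematic — idealized double-helical
backbone geometry with a poly-alanine helix placed at a 3.2 Å closest
heavy-atom gap — built to exercise interface detection, superposition
and scoring, not chemistry.

## Numerical and degenerate-input choices

* BMU ties resolve to the lowest neuron index; representative-frame ties
  to the earliest frame; silhouette ties in k selection to the smaller k.
* Toroidal display re-centering scans all nx·ny cyclic shifts and
  minimizes the summed number of connected components over clusters when
  the shifted map is drawn without wraparound (ties: smaller |dx|+|dy|,
  then dx, then dy). It affects rendering only; neuron indices never
  change.
* Altloc records keep the highest-occupancy copy, ties to altloc "A";
  insertion codes are rejected explicitly (absent from the intended
  inputs). Multi-model files default to model 1.
* Zero-variance feature columns and under-populated codebook
  initializations warn rather than fail; empty inputs fail.
* RMSF uses a two-pass superposition onto each replica's mean structure;
  the reported uncertainty is the SEM across replicas (sd/√n).
* Problem sizes in the shipped tests and the acceptance script (22,000
  frames, ~120 features, 100 epochs, 5-pose rungs) were chosen as the
  smallest sizes at which the statistical claims (±2-point occupancy
  recovery, ARI ≥ 0.9) are comfortably resolved.

## Known limitations

* PDB/GRO/XTC/DCD only; no mmCIF, no structure repair or mutagenesis.
* The SOM is online-mode only (no batch training, no growing maps) and
  the analysis is thermodynamic, not kinetic: no transition-path or
  network analysis on the map.
* Occupancy differences between systems are reported, not tested for
  statistical significance.
* The α-helix assigner reproduces the DSSP α criterion but not the full
  8-state assignment; β topology (strands, wings) is not mapped.
* Nucleotide pairing in scoring assumes shared numbering; scoring poses
  from heterogeneous sources would require an alignment step that is out
  of scope.
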