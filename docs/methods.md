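# Methods

## Problem and model

`voxdelta` predicts *relative* binding potency, ΔpIC50 = pIC50(a) − pIC50(b),
between pairs of congeneric ligands posed in the same protein pocket. In lead
optimization the absolute affinity scale matters less than ranking close
analogues, and relative prediction avoids concatenating the errors of two
absolute predictions.

Each protein–ligand complex is voxelized onto a cubic, pocket-centred box
(24 Å edge, 1 Å³ voxels). An atom at distance *r* from a voxel centre
contributes an occupancy

    n(r) = 1 − exp(−(r_vdw / r)^12),

with n(0) defined as 1; r_vdw is the element's van der Waals radius (Bondi
values, shipped as an editable table). Overlapping contributions to the same
channel are combined with a per-voxel **maximum**, so occupancies stay in
[0, 1] regardless of atom count (summing was the plausible alternative; max
was chosen because it preserves the [0, 1] occupancy semantics). Atoms more
than 5 Å from a voxel centre are skipped: their contribution is below 1e-4
for typical radii, under the resolution of the downstream float32 math.

Channels: 8 protein pharmacophore channels (hydrophobic, aromatic, H-bond
acceptor, H-bond donor, positive ionizable, negative ionizable, metallic,
total excluded volume) assigned from a residue/atom-name lookup table
(`data/protein_channels.tsv`, editable), plus element-level rules (C →
hydrophobic, metals → metallic, every heavy atom → excluded volume; protein
hydrogens carry nothing); and 10 ligand element channels, one-hot over
{C, N, O, F, P, S, Cl, Br, I, H} — 18 stacked channels total. The typing
table is a pragmatic convention, not a protonation-state calculation: ASP/GLU
carboxylates are always negative-ionizable, LYS/ARG always positive, the PRO
backbone nitrogen is excluded from donors, and SER/THR/TYR hydroxyls are both
donor and acceptor.

### The twin network

Both inputs pass through one shared-weight convolutional encoder:
conv(18→32, k3, pad 1) → ReLU → conv(32→64, k3, pad 1) → ReLU →
max-pool(2) → conv(64→192, k3, pad 1) → ReLU → global spatial max-pool,
flattening each leg to a 192-dimensional latent. The prediction is a
bias-free linear map of the latent difference,

    f(a, b) = w · (enc(a) − enc(b)),

so f(a, b) = −f(b, a) and f(a, a) = 0 hold *exactly*, by construction, for
any weights (IEEE negation and sign-symmetric addition make this bit-exact,
which the test suite asserts). Filter counts beyond the 192-d latent are
configuration parameters; the defaults above reproduce the printed latent
size with a conventional doubling schedule.

Training minimizes MSE of predicted vs. labelled ΔpIC50 with Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-4), batch size 32 pairs, 50 epochs, Xavier
initialization, dropout on each leg's latent (rate 0.5 by default,
independent masks per leg), and rotation augmentation: each epoch every pair
is re-voxelized under a fresh uniform SO(3) rotation applied identically to
both grids. The learning rate defaults to 1e-4 (the ε above is the Adam
epsilon, not a learning rate). Training pairs use one canonical order only:
exact antisymmetry makes the mirrored pair's gradient identical, so
including both orders would be redundant. From *n* assayed ligands the
trainer builds all n(n−1)/2 unordered pairs; at test time every (test,
train) ordered pair is predicted (n·m predictions, computed by encoding
each grid once and differencing head projections).

The network is implemented directly on NumPy (convolution as 27
shifted-slice matrix products with explicit backward passes, verified
against finite differences and `scipy.ndimage.correlate`); it needs no
GPU at the problem sizes this package targets.

### Absolute estimates and uncertainty

Given references with known pIC50, each predicted delta yields one absolute
estimate ref + Δ; their mean is the MAP absolute affinity μ and their
population standard deviation σ its uncertainty. With a single reference
σ = 0 — the UCB criterion below then degenerates to greedy, which is why
campaigns are normally started from several assayed compounds.

## Evaluation protocols

Affinities are converted to pIC50 = −log₁₀ IC50 [M]; Gibbs energies via
pIC50 = −ΔG/(ln 10·R·T) at T = 298.15 K, R = 1.9872e-3 kcal mol⁻¹ K⁻¹
(assuming IC50 ≈ Kd, i.e. non-competitive binding). The series reference is
the crystal-structure ligand when flagged, else the ligand with lowest mean
MCS distance d(a,b) = 1 − |MCS(a,b)| / max(heavy(a), heavy(b)) (bounded,
symmetric; ties go to series order). Duplicate ligands across series in one
target group (whose MCS covers all heavy atoms of both) are dropped, first
occurrence kept.

Three split schemes: **random** (seeded shuffle), **temporal** (first *n* by
assay timestamp — the realistic regime), and **similarity** (greedy growth
from the reference by highest ECFP4 Tanimoto similarity — radius 2, 2048
bits — to any train member). The continuous-learning loop retrains at each
schedule step on all pairs among the known ligands, predicts test-vs-train
deltas, and reports RMSE, Pearson R and Spearman ρ per step, aggregated as
mean ± sd over independent seeds. Correlations of constant vectors are
reported as NaN, never silently as zero. Test deltas are scored against
*all* train ligands by default; a `pair_mode="reference"` switch restricts to
the first train ligand only.

## Campaign simulation

A campaign starts from an initial pool of assayed ligands (by convention one
batch of the earliest-tested compounds). Each synthesis epoch: fine-tune the
model (3 epochs, Adam state carried over; full retrain available via
config) on all revealed pairs, score every candidate with
UCB = μ + β·σ (β = 1.64), reveal the top-`batch_size` candidates (ties by
ligand id), and repeat until the highest-affinity ligand is revealed.
Total sampled ligands count the initial pool plus every synthesis batch
including the final one: total = |initial| + epochs × batch. Advantages are
experimental-order − total and n/2 − total (n/2 being the expected rank
under a uniformly random ordering, which the simulator's `policy="random"`
baseline reproduces empirically). An oracle mode (μ = true pIC50, σ = 0)
isolates the acquisition loop from model quality.

## Synthetic benchmark series

The toy generator stands in for proprietary congeneric series. A pocket of
30–60 typed pseudo-atoms (templates drawn from standard residue atoms:
ALA CB, PHE CZ, SER OG, ASN ND2, ASP OD1, LYS NZ) sits on a hemispherical
shell of radius ~8 Å above a linear carbon scaffold threaded through the
pocket centre. Ligands decorate up to 4 fixed attachment sites with
substituents from {C, N, O, F, Cl}; sites alternate between pointing at the
pocket and sideways, so their distances to polar pocket atoms differ. The
affinity oracle is

    pIC50 = 5.0 + Σ_substituents w(element) · exp(−(d/6 Å)²) + N(0, σ),

with w = {C: 0.1, N: 0.8, O: 0.6, F: 0.3, Cl: −0.4} and d the distance to
the nearest H-bond donor/acceptor pocket atom. Defaults: 50 ligands,
σ = 0.3 pIC50 (a noise level comparable to inter-assay variability),
timestamps = generation order, ligand 0 = bare scaffold flagged as the
crystal reference. Affinity deliberately depends on pocket-proximal polar
substituents so the joint pocket+ligand voxel descriptor carries signal a
composition-only model lacks.

What the toy series does *not* emulate: conformational flexibility, real
chemistry (no force field, no protonation, bond-length-true geometry only),
activity cliffs, assay heterogeneity, or scaffold hops. Passing tests on it
therefore demonstrate that the pipeline can extract a geometric
structure–activity signal from voxel grids under noise — not that it matches
the accuracy reported on real pharmaceutical series.

## Problem sizes and numerical choices

Tests and benchmarks that must actually train a network use a desk-scale
configuration: 2 Å voxels (12³ grids), filter counts (8, 16), 48-d latent,
dropout 0, learning rate 3e-3, 8 epochs, no augmentation. This keeps a full
training run at a few seconds on one CPU while leaving the learning problem
intact; architecture-constant checks always use the full default
configuration (18×24³ grids, 192-d latent). Learning-signal checks keep the
stated series conditions (50 ligands at σ = 0.3 for the learning curve, 40/50
ligands for ranking/learnability properties, 5–10 seeds) and shrink only the
model and epoch count. Campaign benchmarks use a 40-ligand series, batch 5,
an initial pool of the 5 earliest compounds, and subsample revealed pairs to
at most 150 per epoch.

Other numerical choices: voxelization is float64 (verified against a brute
force to 1e-12) and cast to float32 for the network; max-pool gradient ties
route to the argmax (first occurrence); dropout is inverted (masks scaled by
1/(1−rate)); every stochastic choice (splits, init, shuffling, dropout,
rotations, campaign batching) flows from one integer seed through
`numpy.random.Generator`/`SeedSequence`, so runs are exactly reproducible;
training aborts with a diagnostic on non-finite loss.

## Known limitations

- The protein typing table is residue/atom-name based; non-standard residues
  fall back to excluded-volume-only with a warning.
- Pre-posed inputs are assumed: no docking, protonation or preparation.
- Dropout is applied to each leg's latent before the difference; applying it
  after the difference would be the other defensible reading.
- The grid featurization is not rotation-equivariant; augmentation mitigates
  but does not remove this.
- `fine_tune` continues the stored Adam state; a fresh optimizer per
  fine-tuning round would also be defensible and gives slightly different
  trajectories.
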