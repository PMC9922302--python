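# Methods

## The problem

Intrinsically disordered peptides (IDPs) do not fold into a single
structure; their biophysical identity is a broad conformational ensemble.
Molecular dynamics can sample such ensembles but pays for every conformation
with sequential integration. `disgen` implements the alternative studied in
this package: learn the Boltzmann ensemble of a residue-level coarse-grained
(CG) model with a sequence-conditional generative adversarial network (GAN)
that emits C-alpha conformations directly, then validate the generated
ensembles against simulation with a dedicated metric suite.

## The coarse-grained model

Each residue is one bead at its C-alpha position.  The potential is

U = Σ ½ k_bond (l − l0)² + Σ ½ k_angle (θ − θ0)²
  + Σ 4(ε + ε_cπ) [(σij/r)¹⁰ − (σij/r)⁵]
  + Σ (A_i A_j + A0_i A0_j) / r · exp(−r/κ)

with k_bond = 4184 kJ mol⁻¹ nm⁻², l0 = 0.38 nm, k_angle = 4.184
kJ mol⁻¹ rad⁻², θ0 = 180°; ε = 0.40 / 0.41 kJ mol⁻¹ for polar / non-polar
residues, ε_cπ = 0.3 kJ mol⁻¹ added for (Arg,Lys)×(Phe,Tyr,Trp) pairs;
σij = σi + σj with σi the radius of a sphere of the residue's mean volume
(Zamyatnin table, shipped as `data/forcefield.yaml`); A_i = sign(q_i)√(0.75|q_i|)
with q = +1 (R,K), −1 (D,E); A0_i = 0.05 for polar residues.  Non-bonded
pairs are |i−j| ≥ 2, truncated at 3 nm, minimum-image in a 300 nm box.
Choices the potential leaves open, fixed here:

* **ε for mixed pairs**: the polar value applies if either partner is polar.
* **Polarity classes**: polar = {R,K,D,E,N,Q,H,S,T,Y,C,W}, the rest
  non-polar; overridable in the config.
* **κ (Debye length)**: 1.0 nm, a physiological default; configurable, and
  any electrostatics-sensitive comparison should pin it explicitly.
* **Exclusions**: only directly bonded neighbours (|i−j| = 1) are excluded;
  angle partners i, i+2 interact non-bonded.

Units are kJ/mol, nm, ps; the consistent mass unit is then g/mol.  All
beads carry 110 g/mol (average residue mass); equilibrium ensembles are
mass-independent.

## Dynamics

Langevin dynamics with a BAOAB splitting, friction 0.01 ps⁻¹, 298 K,
production timestep 0.02 ps (the stiffest mode, bond vibration, has
ω·dt ≈ 0.17, comfortably stable).  A run starts from a seeded self-avoiding
random walk (bond 0.38 nm, all pairs ≥ 0.38 nm, rejection sampling with
≤ 1,000 retries per bead), 5,000 steepest-descent minimization steps, and
20,000 equilibration steps at 0.01 ps.  Frames are saved every 200 ps.  The
reference protocol runs five independent trajectories and concatenates
them; at full scale that is 5 × 1,000 ns → 25,000 frames per sequence.  The
inner loop is a numba kernel; tests assert it agrees with the plain numpy
energy/force path, which is in turn checked against an independent scalar
double-loop oracle and central finite differences.

Statistical notes that shaped the equilibrium tests:

* At friction 0.01 ps⁻¹ the oscillator energy decorrelates over
  ~1/γ = 100 ps, so a 5×10⁵-step dimer run carries only ~50 independent
  energy samples; variance and kinetic-energy estimators in the tests pool
  16 independent replicas to keep their sampling error a factor of
  several below the asserted bands.
* The trimer bond-angle test compares against the sin(θ)-weighted Boltzmann
  quadrature CDF with a Kolmogorov–Smirnov threshold of 0.12, registered
  from a calibration: correct runs give KS 0.04–0.08 (time-correlated
  frames), while omitting the sin(θ) Jacobian gives ≈ 0.25.

## The generative model

**Generator.** Per-residue latent noise z ∈ R^{L×8..16} is concatenated with
the one-hot sequence, embedded, summed with fixed sinusoidal residue-index
encodings, and passed through transformer blocks (multi-head self-attention
+ position-wise feed-forward); a position-wise two-layer head maps final
embeddings to 3D coordinates in nm.  The latent/sequence pair is re-injected
additively before every block — without this the normalization layers wash
out the noise path and training collapses onto a near-deterministic output.
The tiny preset (used by all tests) is n_z = 8, 2 blocks, d_model = 32,
4 heads, pre-norm blocks; pre-norm keeps amplitude modes in the residual
stream, which the small width needs to express the large long-range
distance variance of disordered chains.

**Discriminators.** One MLP per crop length scores the flattened upper
triangle of the C-alpha distance matrix — standardized per sequence
separation by training-set mean/SD (SD floored at 1e-4 nm) — concatenated
with the flattened one-hot sequence: three spectral-normalized linear
layers, leaky rectifiers (slope 0.2), sigmoid output in probability mode.
Distance features make the game invariant to rigid motions and reflections
by construction.  Optional variants: L−3 pseudo-torsion inputs (breaking
mirror symmetry for chiral targets) and a zero-padded 2D convolutional
discriminator that accepts any length.

**Objectives.** Non-saturated GAN loss (default), hinge loss with top-k
fake-sample selection (ν = 0.5 decayed by γ = 0.99 per epoch, floor one
sample) plus annealed coordinate noise (σ0 = 0.025 nm decaying linearly
over the first quarter of training), and Wasserstein critic loss with
gradient penalty (λ = 10, five critic iterations); the generator loss adds
the stereochemical clash term w_C·E_C with w_C = 0.3 and E_C the sum of
max(x_t − d, 0) over pairs three or more residues apart.  x_t defaults to
the 0.1 percentile of training-set non-bonded distances.  For the MLP
discriminators the gradient penalty uses the closed-form input-gradient of
the piecewise-linear network (activation slopes held fixed at the
evaluation point), which avoids second-order automatic differentiation.
Adam with β1 = 0, β2 = 0.9; learning rates 2.5e-4 (G) and 4e-4 (D); batch
192 of same-length crops; D and G alternate 1:1 except in Wasserstein mode.
Optionally the learning rates halve at fixed epoch fractions.

**Crop balancing.** Sequences map to the nearest crop length (ties to the
smaller value); random re-sampling tops every length up to c_max
assignments; each assignment contributes n_frames randomly cropped frames
per epoch with fresh offsets.

**Warm start.** GAN training from a random generator proved unreliable at
this scale: the early adversarial gradients contract the output
distribution faster than the latent pathway can learn, and once
∂output/∂z ≈ 0 the collapse is self-sustaining (the latent-weight gradients
average to zero over the batch).  Training therefore begins with a
distribution-matching warm start of the generator alone: per single-sequence
batch, the standardized distance features must match the real batch's
per-feature mean and SD, the radius-of-gyration distribution must match the
real batch's quantiles (sorted-value regression — this is what teaches the
global compaction modes), and the clash term is included.  The warm-start
landscape is itself init-sensitive, so a few candidate initializations are
probed briefly and the best continues (selection by warm-start training
loss only).  This phase uses momentum Adam (0.9/0.999) — it is an ordinary
regression, not an adversarial game.  The adversarial phase then sharpens
the joint distribution; it measurably improves all divergence metrics over
the warm start alone.

**Neural-network stack.** All networks, their gradients and optimizers are
implemented in this package on numpy: a small tape-based reverse-mode
autodiff engine with fused layer-norm, attention and affine nodes, plus a
pairwise-distance node so generator gradients flow from discriminator
scores back into coordinates.  Training runs in float32; gradient checks
run in float64 against central finite differences.

## Metrics

Given a reference and a generated ensemble of the same sequence: MSE_c
(mean squared difference of log contact frequencies, 0.8 nm threshold, 0.01
pseudo-count for zeros), MSE_d (mean squared difference of mean pair
distances, nm²), aKLD_d (mean over pairs of a 50-bin histogram KLD on the
pooled min–max range with 0.001 pseudo-count, natural log, no
renormalization after substitution), EMD-dRMSD (Hungarian assignment on the
all-pairs dRMSD matrix after seeded subsampling to ≤ 1,000 frames each;
exact assignment well beyond that size), KLD_r (the same histogram KLD on
radius-of-gyration samples), and MED (median generated potential energy
minus median reference, under the CG force field).  PCA potentials of mean
force are computed on reference distance features only (query ensembles are
projected onto the reference basis; free energy −k_B T ln p at 298 K; empty
cells are missing, not infinite), and the memorization search reports each
generated conformation's nearest-neighbour dRMSD over a training pool.

## Chirality

The CG potential is mirror-symmetric, so the generator cannot and need not
pick a handedness.  For chiral targets the package provides pseudo-torsion
profiles (IUPAC sign convention: the quadruplet (0,0,0),(1,0,0),(1,1,0),(1,1,1)
gives +π/2; collinear quadruplets report NaN), reflection (z → −z, all
distances preserved exactly), and a selector network (the generator trunk
over (sin φ, cos φ) tokens with a mean-pooled sigmoid head) trained on
chiral ensembles versus their mirror images.  A conformation scoring below
0.5 is replaced by its reflection only if the reflection scores strictly
higher, which makes the post-processing idempotent even for ambiguous
inputs.  Training data with no torsion-sign asymmetry yields chance-level
validation accuracy and the selector refuses to certify.  Synthetic chiral
fixtures are built from internal coordinates with a chosen torsion-sign
bias; they stand in for chiral all-atom trace data and match no simulation
protocol.

## Benchmarking

Sampling efficiency compares KLD_r convergence of generator samples and
simulation-trajectory prefixes against a long reference ensemble.  The
generator trace plateaus at KLD_r_top when no later point within a window
of additional samples improves the running minimum by more than 1e-3
(absolute); t_MD is the simulated time at the first prefix strictly below
KLD_r_top.  Timing values are recorded, never asserted — plateau and
crossing logic is tested on scripted traces only.

## Problem sizes used by the test suite

The full-scale study (thousands of sequences, 25,000 frames each, tens of
GPU-days of adversarial training) is far outside a desk-scale budget.  All
desk-scale runs use two length-20 fixture peptides (poly-alanine, a
featureless reference polymer, and an E/K charge-block peptide whose
screened electrostatics produce sequence-specific structure), with
reference ensembles built from five independent shortened runs at the
preserved 200 ps frame spacing, and tiny-preset networks evaluated with
1,000 generated conformations per peptide:

* **Package-default recipe** (`TrainingConfiguration.tiny()`): 60-epoch
  warm start (four probed inits) plus 400 adversarial epochs at batch 192,
  with within-run checkpoint selection by validation aKLD_d on a 10%
  held-back slice of the training frames.  At this depth, with
  2,000–5,000 reference frames per peptide, both fixture ensembles are
  typically recovered to roughly 0.1 nats in KLD_r and 0.1–0.3 nats in
  aKLD_d (the best observed runs reach ≈0.11 in both) with sub-threshold
  contact fractions well below 1%; run-to-run spread remains appreciable.
  `scripts/acceptance.py` runs this recipe end to end (1,500 training +
  750 held-out frames per peptide, 300 adversarial epochs) and reports the
  measured numbers.
* **In-suite pipeline test**: the same pipeline with 2,000 training +
  1,000 held-out frames per peptide and a shortened 60-epoch adversarial
  phase, for three fixed seeds plus a clash-term ablation.  At that depth
  the adversarial refinement is still far from its asymptote — per-pair
  divergences remain at roughly 0.2–0.4 nats — so the distribution-recovery
  test documents the full contract while the shortened depth leaves its
  strictest clause unmet; the converged behaviour is the acceptance
  script's job.

What a passing desk-scale run shows — and what it does not: the pipeline
recovers sequence-conditional CG ensembles at small L from modest data; it
does not demonstrate transfer to unseen sequences, lengths beyond the
training crops, or all-atom force fields.

## Known limitations

* The generator's local geometry is slightly too soft: generated bond-length
  SD remains ~1.5–2× the reference value, which dominates the residual
  per-pair divergence at small separations.
* With the distribution-matched warm start, the explicit clash term changes
  the sub-threshold contact fraction only modestly at this scale (the warm
  start already teaches realistic excluded volume); the dramatic
  no-penalty blow-up seen in full-scale adversarial-only training is not
  reproduced in this regime.
* Metric values carry finite-sample bias (≈ 0.03 nats for the histogram
  KLDs at the suite's sample sizes); comparisons between ensembles of very
  different sizes should subtract a same-size baseline.
* The Wasserstein gradient penalty is exact only for the MLP discriminator
  family (closed-form input gradients); the convolutional discriminator
  supports the probability and hinge objectives.
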