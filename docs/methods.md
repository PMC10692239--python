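# Methods

`domassembly` assembles full-length multi-domain (or multi-chain) protein
models from rigid single-domain structures. The inputs are (a) one backbone
structure per domain, (b) a domain layout naming which residues belong to
which rigid unit, and (c) an inter-domain interaction map — per-pair targets
for the relative geometry of residue pairs in different domains. The engine
turns the map into an energy, and searches linker-torsion space for the
conformation that satisfies it.

## Inter-residue interaction representation

Every residue carries a local orthonormal frame built from its backbone by
Gram-Schmidt: origin at Cα, x along Cα→C, y the component of Cα→N orthogonal
to x, z = x × y. Frames are stored as local→ground affine transforms
A = (R, t). The interaction between residues i and j is the relative
transform A_i⁻¹ ∘ A_j — where residue j's frame sits, seen from residue i.
It is encoded as a 6D vector (α, β, γ, r, θ, φ):

* (α, β, γ): intrinsic Z-Y-X Euler angles of the rotation,
  R = Rz(γ)·Ry(β)·Rx(α). Gimbal lock (β = ±π/2) is resolved by setting
  α = 0 and absorbing the remainder into γ; the reconstruction is exact
  even though the decomposition is not unique there.
* (r, θ, φ): spherical coordinates of the translation,
  t = (r sinθ cosφ, r sinθ sinφ, r cosθ). Because frame origins are Cα
  atoms, r is exactly the Cα–Cα distance.

The exact atom order inside the Gram-Schmidt construction is a convention;
the engine is self-consistent under any fixed choice, and the choice is
isolated in `frames.build_frame` so it can be swapped.

## The atomic coordinate deviation (ACD) potential

Given target transforms A_(i,j) for a set S of ordered inter-domain residue
pairs, a conformation is scored by

    F_ACD = (1 / N_tot) Σ_{(i,j) ∈ S} Σ_{k ∈ S_atoms}
            ‖ A_i⁻¹∘x_{j,k} − A_(i,j)∘A_j⁻¹∘x_{j,k} ‖₂

with S_atoms = {N, Cα, C, Cβ} and N_tot = 4·|S|. The first term is atom k of
residue j as residue i actually sees it; the second is where that atom would
sit in i's frame if the pair satisfied its target. F_ACD is a mean Euclidean
deviation in Angstrom: ≥ 0, zero iff every targeted relative transform is
met, and invariant under any global rigid motion of the conformation (all
terms live in local frames). Both (i, j) and (j, i) are separate terms.
Glycine has no Cβ, so every residue receives a virtual Cβ placed 1.522 Å
from Cα at equal 110.4° angles to the Cα→N and Cα→C bonds, on the L-chirality
side; the atom set is therefore uniform across residues.

Two named variants share this kernel: pACD scores a conformation against a
*predicted* (decoded) map, tACD against the transforms read directly off a
reference structure. No per-term clamp or weighting is applied by default;
a clamp and a soft steric CA-CA repulsion (weight 0 by default) exist as
options and are excluded from all default behavior.

## Interaction maps, binning and the structure oracle

Predictors emit categorical distributions, so the map supports two dialects:
`mode` (one 6D point target per pair) and `dist` (six per-pair histograms
over a bin scheme). The default scheme: r over [2, 40] Å in 1 Å bins plus
one overflow "no interaction" bin; α, γ, φ over [−180°, 180°) and β over
[−90°, 90°], θ over [0°, 180°], all at 15°. Published descriptions of such
predictors leave the discretization unspecified, so these are package
choices; the scheme is written into every interaction file header, which
makes energies reproducible from the file alone. Decoding takes the arg-max
bin per element (ties to the lowest index) and returns its midpoint; pairs
whose distance arg-max is the overflow bin are dropped.

The *oracle* replaces the neural network for offline work: given a reference
structure and layout it emits the exact 6D transform of every ordered
inter-domain pair with Cα–Cα distance ≤ r_max (default 40 Å). A
`discretize_targets` step turns oracle targets into delta or
Gaussian-blurred histograms (wrapped Gaussians for periodic elements), which
emulates a soft predictor with controllable error. The default blur is half
a bin width per element. For a decoded zero-blur map the energy assigned to
the reference itself is bounded by the quantization bound implemented in
`acd_quantization_bound` (rotation: unitary-factor telescoping; translation:
radial-then-angular path), which the tests use instead of ad-hoc tolerances.

## Kinematics

Domains are rigid; the decision variables are φ/ψ *offsets* of the linker
residues around each domain junction — by default eight residues per
boundary, four on each side — plus one rigid 6-DoF slot (three rotations
about the chain centroid, three translations) per non-anchor chain. A φ
offset rotates everything C-terminal of the residue's Cα about its N–Cα
axis, carrying the residue's own C, O and Cβ so the residue stays internally
rigid; a ψ offset rotates everything past C about the Cα–C axis, carrying
the carbonyl O. Offsets form a group action (apply v then w ≡ apply v + w)
and the zero vector is an exact identity.

Because the movable windows straddle the junctions, they lie *inside* the
flanking domains: a window torsion necessarily moves the tail of its own
domain. "Rigid domain" therefore means, precisely, the residues outside the
movable windows; all tests and reported rigidity numbers use these cores.

Full-length construction concatenates domains N→C per chain with ideal
peptide junctions (C–N 1.329 Å, ω = 180°, standard bond angles), placing
each next domain by superposing its first-residue frame onto the
NeRF-placed position. The deterministic base conformation fixes junction
torsions at φ = −120°, ψ = +140°, re-idealizes the junction carbonyl O to
the base ψ, and lays extra chains side by side; all randomness (initial
models: linker torsions uniform in [−π, π), chain poses uniform rotation
plus a translation inside the anchor's bounding sphere + 30 Å) enters as
offsets from this base, which is what makes runs exactly reproducible.

## Population-based assembly

The optimizer maintains a pool of decision vectors. Defaults follow the
published protocol: pool 1000, 500 iterations, top-10 output, 8 movable
linker residues per boundary. Each generation, every slot produces one
offspring by uniform crossover with a uniformly chosen distinct mate
(per-gene take-probability 0.5) followed by per-gene Gaussian mutation
(probability 0.1; sd 30° for angles, wrapped, and 2 Å for translations),
and the slot keeps the lower-energy of parent and offspring, ties to the
parent. This pairwise elitism makes the best pool energy non-increasing by
construction.

The optimizer is *memetic*: every 50 generations (`refine_every`) the
current best slot is polished by a bounded L-BFGS-B local search with
numerical gradients (`refine_maxfun` = 1500 evaluations) on the same
objective, accepted only on improvement. The rationale is structural:
linker torsions act through long lever arms, so F_ACD forms a narrow,
strongly anisotropic curved valley in torsion space. Fixed-width random
per-gene moves stall there — in our experiments plain crossover/mutation,
annealed-width variants and canonical differential evolution all plateaued
at several Å of residual energy at desk-scale budgets, while a quasi-Newton
step that follows the valley converges in a few thousand evaluations. The
population supplies basin diversity and global moves; the local step
supplies precision. Refinement is deterministic, preserves slot elitism and
the monotone trace, and can be disabled (`refine_every = 0`), which leaves
exactly the plain evolutionary scheme.

Randomness is a single seeded stream: a root `SeedSequence(rng_seed)` is
split into an initialization branch (spawned per individual, so pools are
reproducible at any pool size) and one evolution generator consumed in a
documented order (mate choice, crossover mask, mutation mask, noise — per
slot, per generation). Identical inputs, config and seed give bit-identical
ranked energies and gene vectors.

Energies are computed on the backbone + Cβ representation throughout; the
coarse-grained "centroid" side-chain reduction is realized here as the Cβ
(virtual where absent). No full-atom or side-chain refinement stage exists
in this package, so final ranking is by F_ACD alone.

## Evaluation metrics

* **Kabsch RMSD**: SVD-based least-squares rigid superposition with proper
  rotation enforced (no reflections); cross-checked against Horn's
  quaternion method in the tests.
* **TM-score**: (1/L_ref) Σ 1/(1 + (d_i/d0)²) maximized over superpositions,
  d0 = 1.24 (L_ref − 15)^{1/3} − 1.8 clamped below at 0.5; the search seeds
  superpositions from fragments of length L, L/2, L/4 and 4 and refines
  each iteratively with a d0-based inclusion cutoff until the included set
  is stable. The search is a heuristic maximization and may marginally
  under-attain the true optimum; identity (score 1) and rigid-motion
  invariance are exact.
* **Inter-domain distance error**: mean |r_pred − d(Cαᵢ, Cαⱼ)| over all
  ordered pairs present in a decoded map (median also exposed); pairs
  decoded to the no-interaction bin are excluded by construction.

## Synthetic fixtures

The generator grows ideal-geometry backbones (N–Cα 1.458, Cα–C 1.525,
C–N 1.329, C=O 1.231 Å; N–Cα–C 111.0°, Cα–C–N 116.2°, C–N–Cα 121.7°;
ω = 180°) from φ/ψ profiles: canonical helix (−57°, −47°) or strand
(−120°, +120°) torsions with a ±6° seeded jitter inside domains, and seeded
coil torsions (φ ∈ [−160°, −50°], ψ ∈ [90°, 180°]) in linkers. Targets are
regenerated until clash-free (inter-domain Cα–Cα ≥ 3.5 Å, ≤ 100 retries);
extra chains get a random contacting pose. The standard catalogue holds a
two-domain helix pair (64 residues), a three-domain helix/strand/helix
target (74 residues) and a two-chain pseudo-complex (52 residues), each
with layout JSON and oracle interaction files in both dialects.

These toys emulate the geometric structure of the problem — rigid compact
units, flexible linkers, exactly known ground truth — not real data: there
is no sequence signal, no side-chain packing, no prediction error beyond
the controlled blur, and no domain-boundary uncertainty (the layout is an
input by design). Recovery results on fixtures therefore demonstrate that
the representation, potential and optimizer are correct and can invert
their own forward model at desk scale; they say nothing about the accuracy
of any learned predictor on real proteins.

## Problem sizes and numerical choices

Tests and the acceptance script run the recovery experiment at pool 128 and
300 iterations on the ≤ 74-residue catalogue targets — a deliberately
scaled-down configuration of the default protocol chosen so the whole suite
runs on one CPU in minutes. Tolerances: rotation validity and codec round
trips at 1e-9; PDB coordinate round trips at 1e-3 Å (fixed 8.3 fields);
quantization checks use the analytic bound above. Degenerate inputs
(collinear frame atoms, r = 0 translations, empty pair sets, overflow-bin
decodes) are either given explicit conventions (θ = φ = 0 at r = 0; ties to
the lowest bin) or rejected with typed errors. Known limitations: no mmCIF,
no insertion codes, no side chains beyond Cβ, no full-atom refinement, and
a TM-score search that is heuristic rather than exhaustive.
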