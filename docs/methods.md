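# Methods

This note records the model, the synthetic-data design, the numerical
choices, and the open design decisions, in enough detail to re-derive the
implementation.

## Geometric encoding

A conformation is a set of atomic numbers and 3D coordinates in Å. The
molecular graph is a radius graph (default cutoff 5 Å) whose edge set is
symmetric and ordered by (i, j); any node with fewer than `min_neighbors`
(default 3) neighbors is connected to its nearest atoms until the quota is
met. On molecules with ≥ 4 atoms this construction keeps every node's
neighbor directions spanning 3D, which the sphere-fit update requires
(the 3×3 Gram matrix of each node's neighbor directions has rank 3; tested).
Graph topology is fixed at the input geometry; only directions and lengths
are recomputed as positions are refined.

Per directed edge (i, j), with unit direction d_ij pointing from atom j to
atom i, the chirality vectors are c_ij = Σ_{k∈N_i∖{j}} d_ij × d_ik and the
symmetric c_ji. Because d_ij × d_ij = 0 the excluded term vanishes
automatically, so the implementation computes c_ij = d_ij × Σ_{k∈N_i} d_ik
(bilinearity), which is also trivially invariant to neighbor enumeration
order. The torsion ψ_ij = asin(⟨(c_ij × c_ji)/(|c_ij||c_ji|), d_ij⟩) is
evaluated literally, with the asin argument clamped to [−1, 1]; since
c_ij × c_ji is parallel to d_ij the inner product is already the full
magnitude, and clamping only absorbs roundoff. ψ_ij = ψ_ji holds bitwise
(both cross-product negations are exact in floating point). Edges where
either chirality vector has norm < 1e−8 (collinear or isolated
neighborhoods) are flagged degenerate and get ψ = 0 with `valid = False`
rather than NaN — planar molecules are common and must encode cleanly; note
a *planar* molecule yields valid edges with ψ exactly 0 (both chirality
vectors are normal to the plane), while a *collinear* one is degenerate.

Circular harmonics keep the printed channel set: ω ∈ {−Ω, …, Ω} for both
the sine (l = 1) and cosine (l = −1) blocks, Ω default 4. The ω = 0 sine
channel is identically zero and negative-ω channels are sign/copy redundant;
they are retained for fidelity to the definition — the redundancy is
harmless to the learned affine map that consumes them. Radial features are
a Gaussian basis with `n_basis` (default 32) centers evenly spaced on
[0, r_max], width equal to the spacing.

Initial node features are a learned atomic-number embedding plus sum-pooled
incoming edge embeddings; edge features are the concatenated
[harmonics ‖ radial] vector through a learned affine map. The
`use_torsion=False` switch zeroes the harmonic block, which makes the whole
encoder a function of interatomic distances only and hence exactly
reflection-invariant (mirrored coordinates give bit-identical features:
squaring kills the sign flip before any rounding can differ).

## Geometry update and its supervision

Supervision decomposition: u_ij = d_ij·Δp*_i per directed edge, evaluated
in the geometry of the state the supervision is defined at. Each u involves
only that edge's direction and the target node's displacement, so it is
independent of neighborhood size and bitwise invariant to adding or
removing other edges.

Reconstruction: b_i and A_i are *means* over N_i as printed (the optimum is
unchanged versus sums; conditioning is better), c_i = (2A_i + εI)⁻¹b_i,
Δp_i = 2c_i, ε default 1e−6. With ε = 0 and a singular A_i the solver
raises naming the offending node. For consistent projections
(m_ij = d_ij·Δp) the identity ‖v_ij‖² = v_ij·Δp makes recovery exact; this
is verified on 1,000 random instances to < 1e−8, and the closed form is
checked against a black-box Nelder–Mead minimization of the printed
objective on noisy instances to < 1e−6 relative.

m is predicted per directed edge by a two-layer GeLU feed-forward map on
[node_i ‖ node_j ‖ edge_ij] and is **not** symmetrized; each node's update
uses only its incoming projections. Because m is an SE(3)-invariant scalar
composed with the equivariant directions, the position update is
SE(3)-equivariant (rotations rotate Δp; translations leave it unchanged).

Gradient routing: the reconstruction is applied to detached magnitudes, and
geometry recomputation between recycles is likewise detached — gradients
reach the geometry pathway through the edge-level loss mean|m_ij − u_ij|,
which is exactly the decomposed supervision the architecture is built
around. The position-space L1 loss ‖(P^S − P^{S−1}) − (P* − P^{S−1})‖₁ is
implemented verbatim and reported as a metric; its algebraic reduction to
mean|P^S − P*| (the reference cancels) is tested for all inputs. By default
only the final state is supervised; an optional flag supervises every
block's magnitudes against the remaining displacement at that block's own
input geometry ("on-policy" per-block supervision). The relaxation
benchmark enables it: without it, later recycles act on model-updated
geometries they were never supervised on, and their updates were observed
to raise energy on a seed-dependent minority of held-out molecules.

Whether recycled blocks share weights is not architecturally forced; shared
weights are the default (`share_recycle_weights=True`), which also makes
final-state supervision train all recycles.

## Task conditioning and readout

Task meta encoding: [one-hot group (7) ‖ one-hot type (2) ‖ learned
id-embedding (16) ‖ (η, μ, σ) zero-filled] through a two-layer MLP to a
d_emb = 64 embedding (defaults; all configurable). The router is a linear
map + softmax producing α on the N_M-simplex (N_M default 8); the MoE is
the dense convex combination over expert FFNs — no top-k sparsification,
load-balancing loss, or capacity factors. The router consumes the task
*embedding* (one learned encoder feeds both the MoE routing and the
readout); the alternative reading — routing the raw meta vector directly —
is representationally equivalent up to the encoder MLP and was not taken,
to keep all meta processing behind one component.

Each transformer layer is multi-head self-attention over nodes with an
additive per-edge bias (a learned linear functional of the edge feature per
head; non-bonded pairs share a learned "no-edge" scalar, the diagonal a
learned self scalar; attention stays dense), residual + LayerNorm, then the
MoE with residual + LayerNorm. The readout scores each node from
[node feature ‖ task embedding], softmax-normalizes over the molecule
(node-level attention, exposed per molecule for inspection), pools node
features by those weights, and applies a task-type head: linear for
regression (on the z-scored scale), linear + logistic for classification.
Both heads share the pooled embedding; the alternative of fully separate
embeddings per task type is noted as an open reading.

## Losses, sampler, training

* Regression: mean absolute error on z-scored targets; z-scoring uses the
  task's training-set mean/std carried in its meta-information.
* Classification: −[y/(2t₊)·log p + (1−y)/(2(1−t₊))·log(1−p)], p clamped
  to [1e−7, 1−1e−7]; the expected weight mass of each class is ½, and at
  t₊ = ½ the loss is exactly standard BCE.
* Total: L_reg + γ·L_cls (γ default 1.0) plus λ_geo (default 1.0) times the
  geometry loss — the geometry term carries its own coefficient because it
  must be optimized jointly with the property losses.
* Sampler: S̃_i = (1−θ)S_i + θS̄, θ default 0.5; Σ S̃ = Σ S identically.
  Each optimizer step draws one task (probability ∝ S̃) and then a batch
  from that task — the simplest scheme honoring the adjusted frequencies.

Optimization is Adam (lr default 1e−3) over the numpy autodiff engine in
float64; per-molecule forward/backward with gradient averaging over the
batch. Training is bit-reproducible from its seed, and checkpoints carry
model weights, optimizer moments, and the sampler RNG state so a resumed
run continues identically.

## Synthetic data

**Chiral molecules.** One carbon stereocenter bonded to four substituents
with fixed distinct elements (F > O > N > C by atomic number); the label is
R when the signed volume det[s_F−c, s_O−c, s_N−c] is positive, S otherwise
— a simplified priority rule (no isotopes, no duplicated-atom trees) with
the same mirror-flip semantics as CIP. Geometry is a *fixed, strongly
chiral* direction template with small jitter (σ = 0.04 on directions, bond
lengths U(1.42, 1.48) Å), randomly rotated; molecules are mirrored as
needed to balance classes, and each molecule's exact enantiomer is
available on demand. The template choice is load-bearing: a near-regular
tetrahedral center is an achiral *shape*, every pseudoscalar (including ψ)
vanishes on it, and jitter noise would dominate the torsion signal. The
chosen template maximizes the minimal center-edge |ψ|; substituent
distances are constrained to (1.95, 2.65) Å and chain atoms kept > 2.8 Å
from the core so that, at the dataset's recommended graph cutoff of 2.75 Å,
the stereocenter's neighbor sets are identical across molecules. Samples
whose center–F torsion falls within 0.05 rad of zero are rejected
(analogous to rejecting near-planar centers, |signed volume| ≤ 0.05 Å³).
Under this design the sign of ψ at the center–F edge separates the classes
exactly (tested on every generated dataset), so the classification task is
well-posed by construction. Size diversity (5–12 heavy atoms) comes from a
carbon chain random-walked off the lowest-priority substituent.

**Spring-network molecules.** A random connected bond graph (spanning tree
plus chords) with harmonic springs and soft-core pair repulsion:
E = Σ_bonds k/2 (r − r₀)² + Σ_{i<j} c_rep (r_c − r)²·[r < r_c], k = 10,
c_rep = 5, r_c = 1.0 Å. Rest lengths are a deterministic function of the
bonded element pair (a covalent-radius-like table over C/N/O), for the same
reason real force fields type their bonds: with random per-bond rest
lengths the edge supervision is largely unobservable from geometry plus
composition (an oracle-feature regression reached R² ≈ 0.16, and models
plateaued at the predict-zero baseline). Equilibria are minimized with
L-BFGS-B using the analytic gradient to ‖∇E‖∞ < 1e−4; high-energy states
add i.i.d. Gaussian coordinate noise (default σ = 0.3 Å). The potential is
exported so relaxation quality can be scored in energy.

**Multi-task suite.** Tasks are deterministic functions of geometry and
composition (radius-of-gyration and heteroatom-fraction latents):
classifications threshold a latent at its median, regressions read a latent
with noise; one designated pair shares a latent (|correlation| ≥ 0.8 on the
labeled overlap). Each task labels a uniform random subset at the requested
coverage, giving the hypergraph structure of partially annotated label
sets; TaskMeta statistics (η, μ, σ) are computed from the realized labels.

**What the generators do not emulate.** No real chemistry: no bond-order or
valence constraints, no hydrogens, no conformational ensembles, no
quantum-derived targets, and label functions far simpler than ADMET
endpoints. Passing tests demonstrate the architecture's symmetry properties,
the exactness of the reconstruction, and that the training loop can exploit
a chirality signal and a typed force field at desk scale — not performance
on real molecular data.

## Benchmarks

* *Reflection ceiling*: with the distance-only encoder, enantiomer pairs
  receive bit-identical embeddings, so balanced pair accuracy is exactly ½
  regardless of weights — asserted exactly, not approximately.
* *R/S classification*: 2,000 molecules, 80/20 split, compact model
  (hidden 32, 2 layers, 1 recycle, 2 experts, Ω = 4, cutoff 2.75 Å), Adam
  lr 2e−3, up to 40 epochs with early stopping once training accuracy holds
  at 100% for two epochs. Runs in a few CPU minutes.
* *Relaxation*: 190 spring molecules (40 held out), S = 3 recycles,
  2 layers/block, on-policy per-block supervision, fresh perturbations each
  draw, 25 epochs; scored by the fraction of held-out relaxations ending at
  lower toy energy and the mean displacement-to-equilibrium ratio.

Problem sizes are chosen so the full suite runs in minutes on one core;
the experiments are deterministic functions of their seed.

## Numerical choices and degenerate inputs

float64 throughout. Degeneracy threshold for chirality vectors 1e−8;
sphere-fit regularization ε = 1e−6; probability clamp 1e−7; LayerNorm
ε = 1e−5. Single-atom molecules are rejected at graph construction
(coincident atoms likewise, by name); molecules with no valid torsion edges
still encode (the harmonic block is zero there). Exact ties in nearest-
neighbor augmentation follow stable argsort order, making graph
construction deterministic.

## Known limitations

* Per-molecule (unbatched) forward/backward: fine at desk scale, not for
  large-scale training.
* Graph topology is frozen at P⁰; a large geometry update could in
  principle invalidate the radius graph.
* The m-head's edge-local view bounds how much of the perturbation noise is
  recoverable (the denoising limit seen in the relaxation benchmark).
* The chiral generator's separability-by-construction makes the R/S task
  easier than PubChem-scale chirality prediction; it validates the
  mechanism, not real-world accuracy.
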