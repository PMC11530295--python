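# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open.

## Model

### Geometric features

Each protein chain is a directed graph over residues.  Node features:

- **Vector channels (3 per residue):** unit Cα(i−1)−Cα(i), unit
  Cα(i+1)−Cα(i), and unit Cβ(i)−Cα(i).  Where the file stores no Cβ
  (glycine, backbone-only models) an idealized Cβ is constructed from
  tetrahedral backbone geometry with the standard fixed coefficients on
  b = Cα−N, c = C−Cα, a = b×c.  Undefined channels (chain termini,
  coincident atoms) use the zero vector: rotations map zero to zero, so
  equivariance survives the sentinel.
- **Scalar channels:** secondary-structure one-hot, sin/cos of φ and ψ,
  relative solvent accessibility, and a per-residue sequence embedding.
  With an external DSSP executable configured the one-hot is 8-state;
  otherwise a deterministic 3-state fallback assigns helix/strand/coil
  from Ramachandran boxes (helix: φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°];
  strand: φ ∈ [−180°, −90°], ψ ≥ 90° or ≤ −150°).  The feature manifest
  records which layout was used; column order is fixed and serialized.

Edge features for j→i: a 16-center Gaussian RBF of the Cα distance on
[0, 20] Å with σ equal to the center spacing, a 16-dimensional sinusoidal
encoding of the signed sequence offset j−i, and the unit Cα(i)−Cα(j)
direction.  Edges connect each residue to its k = 30 nearest Cα neighbors
(k-NN rather than a radius cutoff, for degree regularity; ties break
toward the smaller residue index so graphs are deterministic).  The
sinusoidal block encodes the *sequence* offset because the spatial
distance is already covered by the RBF block; a `posenc_mode` switch
selects the spatial-distance reading instead.

### Solvent accessibility

SASA is computed by an in-package Shrake–Rupley routine in float64 with
240 golden-spiral sphere points per atom, over the atoms actually present
(N, Cα, C, plus O/Cβ when stored), normalized by per-residue-type maximum
accessibility (Tien et al. 2013 theoretical values) and clipped to [0, 1].
Test-sphere directions are fixed in a canonical principal-axis frame of
the molecule (axis signs fixed by the largest-magnitude projection,
handedness enforced), which makes the value exactly invariant under rigid
motion of the input — library SASA routines with globally fixed sphere
directions and float32 coordinates are not, and full-pipeline invariance
is one of this package's guarantees.  The cost is that near-degenerate
principal axes (highly symmetric point sets) could in principle flip the
frame; for real and synthetic protein coordinates this does not occur.

### Network

The GVP uses ReLU for the scalar nonlinearity and a sigmoid gate on the
vector norms (the bounded nonnegative gate rescales but never flips vector
directions).  No vector-channel linear map carries a bias — a bias vector
would break equivariance.  LayerNorm splits by type: scalars are
standardized per node with a learned affine; vector channels are jointly
rescaled by the RMS of their norms, with no recentering.

Message passing follows

    h_m^{j→i} = g([h_v^{j}; h_e^{j→i}]),
    h_v^{i} ← LayerNorm(h_v^{i} + (1/k′) Σ h_m^{j→i})

with g a 3-GVP stack (the last without scalar activation) and k′ the
number of incoming messages (mean aggregation).  Two readings existed for
both symbols: the message could use the destination node's own features
(a literal reading) and k′ could be a feature width; source-node messages
and neighbor-count normalization are standard practice and are the
defaults, with both alternatives available behind `GnnConfig`
(`message_source`, `aggregation`).

Default widths are 64 scalar / 8 vector node channels, 32/1 edge channels,
3 message-passing layers, dropout 0.1, and a 64-wide scalar collapse.  No
width is externally prescribed; these defaults were chosen so that the
full synthetic training study runs in minutes on a single CPU core with
the NumPy engine, and every one of them is configurable.

The pooling head uses n = 64 supernodes and H = 4 heads (head width d/H);
supernode queries are initialized from a seeded normal with std 1/√d.
Stage-1 softmax runs over residues, stage-2 over supernodes; the
concatenated heads pass through a per-supernode one-hidden-layer MLP, so
the important-node matrix stays n × d.  Graph-convolution encoders use
symmetric normalization with self-loops, degrees counted on incoming
edges.  Batches are block-diagonal for message passing and padded with
masked softmax for attention, so pooling never crosses protein
boundaries.

### Training

Loss = BCE + InfoNCE (unweighted sum by default; weights configurable).
The contrastive view perturbs the *lifted* node features (after the input
GVP embedding, scalar and vector channels alike) with
h′ = h + |ε|·sign(h), ε ~ U(0, 0.1) componentwise: bounded, sign- and
sparsity-preserving (sign(0)=0 keeps the zero sentinels intact).
Perturbing raw coordinates instead would invalidate cached features and is
deliberately not done.  The two passes draw independent dropout masks.
Cosine similarities divided by τ = 0.5 enter the InfoNCE softmax over the
batch.  Optimization is Adam with global-norm gradient clipping at 1.0;
validation monitoring uses the total loss (the contrastive part is
evaluated with a fixed per-run seed so the monitored quantity is
deterministic), and early stopping restores the best-validation snapshot
after `patience` non-improving epochs.

Defaults mirror large-corpus settings (lr 1e-4, batch 64, 100 epochs,
patience 5).  The desk-scale synthetic tasks use a preset fixed after
piloting — lr 2e-3, batch 12, ≤30 epochs, patience 10 — because a
150-protein training split converges in a few hundred Adam steps, and the
InfoNCE term has an intrinsic floor that grows like log(batch), which
small batches keep low.  `TrainReport.initial_train_loss` is measured at
initialization (before any update), which is the natural baseline for
loss-reduction statements; per-epoch entries are averages over the epoch's
batches.

### Attribution

Grad-CAM differentiates the *pre-sigmoid* logit of one term with respect
to the collapsed feature map F (L × D): the logit avoids vanishing
gradients at saturated outputs.  Weights are per-element, with no spatial
averaging: CAM_i = ReLU(Σ_j W_ij F_ij / D).  Scores inherit the trunk's
exact rotation invariance.  Min–max normalization is applied only at
export (B-factor column); a constant map exports as all zeros.

### Metrics

Labels are closed under the GO true-path rule before anything else.
IC(t) = −log₂(n_t/N) in bits over the closed training labels; unseen terms
get +∞ and are excluded from Smin.  Fmax and Smin sweep thresholds
0.01…1.00 in steps of 0.01 (CAFA convention); precision at a threshold
averages only over proteins with ≥1 prediction, recall over proteins with
≥1 true term.  AUPR is micro-averaged over all protein–term pairs with
step-wise interpolation and tied scores grouped.  Metrics are reported per
namespace (MF/BP/CC).

## Synthetic data

The generator emulates what the method needs from real structures — ideal
secondary-structure geometry, multi-segment topologies, 3-D neighborhoods
— without pretending to be physical: backbones are grown atom-by-atom with
ideal bond lengths/angles (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å;
ω = 180°) and per-segment (φ, ψ) targets (−57°, −47° helix; −135°, 135°
strand; a coil band inside neither Ramachandran box).  Segment joins get
random hinge torsions and all coordinates receive Gaussian jitter of
0.2 Å — enough to exercise numerical robustness without flipping the
fallback secondary-structure assignment.  There is no side-chain packing,
no excluded-volume check between distant segments, and no real residue
composition, so passing tests demonstrate that the architecture learns
geometric motifs, not that it reaches any particular accuracy on real
proteomes.

Labels are motif predicates evaluated on the generative segment
composition — "contains a helix segment ≥ 12 residues", "has ≥ 2 strand
segments" — never re-detected from coordinates, so the ground truth is
noise-free.  Compositions are sampled with a margin around the rule
boundaries (helix lengths 5–8 or 14–18; strands 5–7 residues long): the
learnability guarantee is about a geometrically separable task, and
one-residue boundary cases would make the labels unidentifiable from
jittered geometry.  Rejection sampling keeps each term's prevalence within
[0.3, 0.7].  The standard study uses 200 proteins (150/25/25
train/val/test), chosen so the complete training run takes a few minutes
on one CPU core.

## Numerical choices

- float64 throughout; the L2-norm forward pass is exact (so zero vectors
  give exactly zero) with an ε-guarded backward at the origin.
- Softmax subtracts a detached rowwise max; InfoNCE uses a detached-shift
  log-sum-exp.  BCE clips predictions away from {0, 1} by 1e-12.
- Degenerate geometry: collinear N/Cα/C raises for the Cβ construction;
  degenerate dihedral quadruples are flagged undefined (their sin/cos
  encodings are zero) with a warning; coincident Cα pairs yield a zero
  edge direction with a warning.
- Reproducibility: every RNG is an explicit `numpy` Generator seeded from
  the run seed; identical config + seed reproduces training reports and
  prediction tables byte-for-byte in single-threaded execution.

## Known limitations

- Single chains only; multi-chain complexes must be split upstream.
- The offline embedder is a seeded random projection of residue identity;
  it provides no evolutionary signal.  Real ESM2/ProtTrans matrices plug
  in as precomputed inputs but are never downloaded or bundled.
- The NumPy engine is CPU-only and eager; it is sized for
  hundreds-of-residues proteins and desk-scale studies, not proteome-wide
  training.
- DSSP integration is exercised only through its fallback path in the
  test environment; the 8-state path requires a user-supplied executable.
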