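# Methods

## Scope and model

The package estimates per-model quality scores for multimeric protein
structures. Two score types are supported, each with its own trained
model: an overall-fold score (TM-score-like) and an interface score
(QS-score-like), both in (0, 1). Two inference routes exist over a shared
graph representation: direct graph-network regression, and an energy-based
regressor that reads the graph network's global embedding.

## Graph construction

A structure is reduced to backbone + CB coordinates. The representative
position of a residue is its CB atom; glycine uses CA. Residue pairs whose
representative atoms are within the cutoff (default 8.0 Å, ties included)
are connected; residues with at least one cross-chain edge are interface
residues, using the same cutoff. Node order is chain order then sequence
order, so graphs are reproducible.

Parsing (via gemmi) takes the first model of a PDB file, prefers blank or
'A' altlocs, maps common non-standard residues to their parents (MSE→MET
etc.), drops waters, unmappable residues and residues missing any of
N/CA/C with a warning. Missing CB atoms (and glycine, where edge geometry
needs a CB-like point) are reconstructed from ideal internal coordinates:
bond 1.522 Å, angle N–CA–CB 1.927 rad, dihedral C–N–CA–CB −2.143 rad.
These handling rules are this package's own choices; assessment-grade
inputs rarely exercise them but real PDB files do.

## Features

Node features (83 per residue, six blocks): one-hot amino acid (20, fixed
alphabetical three-letter order), PSSM (20), per-residue energy terms (20),
secondary-structure/solvent-accessibility scores (5), sinusoidal positional
encodings (12, 0-based over the concatenated multi-chain sequence), and
statistical potentials (6). Only the total width and the six block types
are externally fixed; the individual widths are this package's published
layout constants (`features.NODE_BLOCKS`) chosen to honor the total of 83
with the standard 20-wide one-hot and PSSM blocks.

Edge features (10): CB–CB distance; the angle between the two CA→CB
vectors; the ω dihedral (CA–CB–CB–CA); θ dihedrals (N–CA–CB–CB) and φ
planar angles (CA–CB–CB), each in both directions; and contact-dependent
plus two relative-solvent-accessibility potentials, populated only on
cross-chain edges and zero elsewhere. Angles are radians; dihedrals are
signed by the right-hand rule in (−π, π], planar angles in [0, π];
degenerate frames yield 0 with a warning.

PSSM, energy, SS/SA, statistical-potential and language-model-embedding
features normally come from external sequence/structure tools. They enter
through a provider contract (`FeatureProvider`: deterministic per-residue
matrix of fixed width). The shipped default is a hash-seeded synthetic
provider: reproducible, coordinate-independent values that stand in for
tool output so the full pipeline runs with no external binaries. The
optional language-model block (per-residue embedding plus mean / median /
std / variance summaries) is excluded from the 83-feature count.

## Backbones

Both variants end in global attention pooling (softmax over a learned
per-node gate, weighted sum of transformed features) producing the graph
embedding X, followed by a fully connected head and a logistic squash to
(0, 1).

* **Transformer** — per layer: multi-head attention over graph
  neighbourhoods with edge features added to keys and values, a root
  transform for the node's own contribution (so isolated nodes are
  well-defined), ReLU, optional LayerNorm, then TopK pooling (keep
  ceil(ratio·n) nodes under a learned projection, tanh-gated, stable
  tie-break toward lower node index, never fewer than one node).
* **MetaLayer** — per layer: edge update from (src, dst, edge, global),
  node update from (node, mean incident edge, global), global update from
  (mean node, mean edge, global), each a small MLP with ReLU; empty edge
  sets aggregate to zeros.

Training: weighted L1 loss, Σwᵢ|ŷᵢ−yᵢ|/Σwᵢ, with weights from inverse
label frequency over 10 equal bins (normalized to mean 1) — a standard
skew correction, since decoy sets concentrate near high quality. Optimizer
is Adam (lr 1e-3) with AutoClip: the gradient norm history (unbounded)
is tracked and gradients are rescaled to its 10th percentile when
exceeded; the percentile uses linear interpolation and the first step is
never clipped. One integer seed controls initialization, dropout and data
order. Defaults (2 layers, hidden 32, 4 heads, TopK ratio 0.8) are small
on purpose: the package targets desk-scale CPU training, and the
recovery tests pass at these sizes.

## Energy-based regressor

Scores are mapped to logits with a clamp at ε = 1e-6; sigmoid∘logit is an
identity to 1e-9 inside the clamp range. All proposal densities live in
logit space — the governing convention for the whole module.

For a true score μ the proposal standard deviation is

σ(μ, γ) = (logit(μ+γ) − logit(μ)) / 0.675 if μ+γ < 1, else
(logit(μ) − logit(μ−γ)) / 0.675,

with 0.675 the standard-normal third-quartile z-value (norm.ppf(0.75) =
0.67449; the conventional 3-digit constant is used). This places the
proposal's quartiles approximately ±γ from μ after mapping back to (0, 1),
counteracting the logit's asymptotes. σ is computed after clamping μ±γ.

Each training example contributes M samples in logit space: the noisy-true
sample y₀ = logit(μ) + N(0, β·σ²) and M−1 adversarial draws from
N(logit(μ), σ²); every sample carries its log-density under the
adversarial proposal (single normal; K = 1 mixture components, fixed).
The loss is the mean negative log-probability of identifying column 0
under the softmax of (f − log P), computed with log-sum-exp. The network
output is an *energy* E (low = compatible): f = −E is passed to the loss,
so training drives the true pair's energy down, and inference returns the
argmin of E over the grid logit((k−0.5)/grid_n), k = 1..grid_n (ties to
the smallest score, which the evaluation metrics penalize anyway via the
uniqueness rule).

Defaults: M−1 = 64 adversarial samples (32 in the recovery benchmark,
which trains faster at equal accuracy), β = 0.05, γ = 0.1, grid_n = 1000,
skip depth 2, hidden (64, 64). These follow the energy-based-regression
literature's typical ranges and are config-overridable; they were fixed
once as study conditions.

## Ranking metrics

Ranking loss per target and predictor: true score of the genuinely best
model minus true score of the predictor's top pick. The pick is accepted
only if the top predicted score is unique among the predictor's
predictions for that target; otherwise the loss records the 0.1 sentinel
and a flag. NDCG@3 uses relevance rᵢ = 1 − (best − trueᵢ)², zeroed when
the score that placed model i in its ranking is not unique, discounted by
1/log₂(i+1) over the top 3, and normalized by the true ranking's DCG@3.

Interpretation choices, made once and applied consistently: the reference
model in the relevance formula is the *true* best (the only reading under
which the true ranking's NDCG@3 is identically 1 for unique scores);
uniqueness refers to the scores that produced the ranking being evaluated
(predicted for predictors, true for the ideal); true-score ties rank by
model id, deterministically; targets with <3 models sum over available
positions with unchanged normalization. Leaderboards report mean loss
(sentinels included), the count of targets with loss < 0.1, and summed
NDCG@3, since different communities aggregate differently; predictors
absent on a target are charged the sentinel and zero NDCG.

## Synthetic data

The generator emulates the shape of an EMA training corpus without any
downloads. Natives are ideal-geometry α-helical chains (NeRF-built
backbones, φ/ψ = −57°/−47°, trans peptide) packed in parallel 8.5 Å
apart, which guarantees cross-chain contacts at the 8 Å cutoff. Decoys
apply per-chain rigid rotations (≤ rotation max, uniform axis) and
translations (≤ translation max) about the chain centroid plus i.i.d.
Gaussian atomic jitter; graded magnitudes span a quality range. Defaults
(10° / 2 Å / 0.3 Å over graded scales) were chosen once to produce labels
covering roughly 0.4–1.0 in fold score on 16–20-residue chains.

Labels are documented stand-ins, not the official scorers: the fold label
superposes CA atoms by Kabsch least squares under the fixed native
correspondence and applies the TM-style kernel with d₀ = 1.24(L−15)^⅓ −
1.8, floored at 0.5 Å for short chains (no alignment search); the
interface label is the Jaccard overlap of cross-chain contact sets at
8 Å. Both preserve the (0, 1) scale and quality orderings. What passing
tests show, therefore, is that the architecture and objectives can learn
and rank graded structural degradation under realistic feature layouts —
not that the defaults reach assessment-grade accuracy on real complexes
with real external-tool features.

Two auxiliary benchmarks with known ground truth: an embedding dataset
(standard-normal embeddings, score = sigmoid(w·x + b) + bounded noise,
mapping recorded) for energy-model recovery, and a graph dataset labelled
by each graph's cross-chain edge fraction — a topology statistic a graph
network must use message passing to read — for backbone recovery. The
recovery runs use n = 2000 embeddings and 120 graphs, sizes chosen so the
whole suite trains in well under a minute of CPU.

## Numerical core

All trainable components run on an in-package reverse-mode autodiff engine
over float64 numpy arrays (elementwise ops, matmul, reductions,
gather/scatter segment ops, concat/reshape), with gradients validated
against central finite differences in the test suite. Segment softmax
subtracts the per-segment max as a constant; the contrastive loss uses
log-sum-exp; attention scales by 1/√d per head. Checkpoints are JSON
(config + named weights), portable and diffable.

## Known limitations

* Synthetic feature providers carry no evolutionary or physical signal;
  with them, models can only learn from geometry, topology and encodings.
* Stand-in labels are not TM-score/QS-best; absolute values are not
  comparable to published assessment numbers.
* No mmCIF input, nucleic-acid chains, multi-model ensembles, consensus
  scoring, gradient-based (Langevin) inference, or K > 1 proposals.
* Training is single-CPU scale by design; layer counts and widths are far
  smaller than production EMA models.
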