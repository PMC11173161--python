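# graphema

Estimation of model accuracy (EMA) for **multimeric** protein models:
given a predicted complex structure — and no native — estimate how good it
is, both as an overall fold score (TM-score-like, in (0, 1]) and as an
interface score (QS-score-like, in [0, 1]). Ranking predicted complexes by
estimated quality is the practical core of structure-prediction pipelines
and of CASP-style EMA assessments.

The package is aimed at structural bioinformaticians who want a fully
self-contained, CPU-scale implementation of a graph + energy-based EMA
method: residue contact graphs, graph-neural regression backbones, an
energy-based regressor trained by noise-contrastive estimation, and the
ranking metrics used to compare predictors.

## Method

**Graphs.** Each residue is a node; its representative position is the CB
atom (CA for glycine). An edge joins any residue pair with representative
distance ≤ 8 Å; interface residues are those with a cross-chain edge. Nodes
carry 83 features in six blocks (amino-acid one-hot, PSSM, energy terms,
secondary-structure/SA scores, sinusoidal positional encodings, statistical
potentials); edges carry 10 features (distance d, inter-CB-vector angle α,
orientation dihedrals ω, θ<sub>ij</sub>, θ<sub>ji</sub> and planar angles
φ<sub>ij</sub>, φ<sub>ji</sub>, plus contact and solvent-accessibility
potentials on interface edges only). External-tool features enter through a
provider contract; a deterministic synthetic provider ships as the default.

**Backbones.** Either graph-transformer layers (multi-head attention with
edge features in keys/values, followed by TopK pooling) or MetaLayer blocks
(separate edge/node/global update networks). Global attention pooling
produces the graph embedding X; a fully connected head squashes X to a
score in (0, 1). Training minimizes a weighted L1 loss under Adam with
AutoClip percentile gradient clipping.

**Energy-based regressor.** Scores y ∈ (0, 1) are mapped to logits
y′ = logit(y). A fully connected energy net f(X, y′) (with y′ re-appended
through skip connections) is trained with the noise-contrastive objective

J(θ) = −E<sub>i</sub> log [ exp(f₀ − log P<sub>N</sub>(y₀))
/ Σ<sub>m=0..M−1</sub> exp(f<sub>m</sub> − log P<sub>N</sub>(y<sub>m</sub>)) ],

where y₀ is the true logit plus noise of intensity β and the M−1
adversarial logits are drawn from N(logit(y), σ²) with a *sliding*
σ = (logit(μ+γ) − logit(μ)) / 0.675 (mirrored near 1), which keeps the
proposal's quartiles roughly ±γ from μ back in score space. Inference is
brute force: evaluate the energy on a uniform grid of candidate scores and
return the argmin.

**Evaluation.** Per target, the modified ranking loss (true best minus the
true score of the predictor's top pick; 0.1 sentinel when the top predicted
score is not unique) and NDCG@3 with relevance rᵢ = 1 − (best − trueᵢ)²,
normalized so the true ranking scores 1.

## Worked example

```sh
graphema synth --out-dir demo --chains 2 --length 14 --decoys 12 --seed 3
graphema train-backbone demo --checkpoint demo/backbone.json \
    --epochs 10 --hidden 16 --layers 1 --seed 3
graphema train-ebm demo/backbone.json demo --checkpoint demo/ebm.json \
    --epochs 10 --m-total 17 --seed 3
graphema score demo/toy_c2_l14_s3_d000.pdb demo/toy_c2_l14_s3_d006.pdb \
    demo/toy_c2_l14_s3_d011.pdb --checkpoint demo/backbone.json \
    --ebm-checkpoint demo/ebm.json --mode ebm --out demo/scores.tsv
```

which prints (stderr) `wrote 12 decoys to demo`, `final val L1 0.4420`,
`final train loss 3.4190`, `scored 3 models -> demo/scores.tsv`, and writes

```
model_id                score_type  regression_score     ebm_score
toy_c2_l14_s3_d000      fold        0.3692445339340377   0.9095
toy_c2_l14_s3_d006      fold        0.35561084988627273  0.9085
toy_c2_l14_s3_d011      fold        0.3726939411357849   0.9125
```

Each row is one input structure; `regression_score` is the backbone's
direct prediction of the overall-fold label and `ebm_score` the energy
model's grid-inference estimate. A 12-decoy, 10-epoch demo is deliberately
tiny — the models are underfit and the absolute numbers mostly show the
pipeline's plumbing; the test suite trains at the sizes where the models
demonstrably recover their targets (see `tests/test_acceptance.py`).

Ranking evaluation works from plain tables:

```sh
graphema eval predictions.csv truth.csv --metric loss --out leaderboard.csv
```

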