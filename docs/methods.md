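# Methods

`mdtips` predicts whether a drug interacts with a protein target by fusing
three independently informative data channels and asking a single classifier
for the interaction probability. This note documents the model, its
parameters, the synthetic study conditions, and the numerical and design
choices a maintainer would want to know.

## The prediction model

A drug–target pair (d, t) is described by up to three channels:

**K — knowledge graph.** Entities (drugs, targets, diseases, side effects,
pathways) and multi-relational triples (h, r, t) are embedded with ConvE.
The head and relation embeddings e_h, r_r ∈ R^k are reshaped to k_w × k_h
matrices, stacked, convolved with a bank of 3×3 filters, passed through a
ReLU, flattened, projected back to R^k, passed through a second ReLU and
scored against the tail embedding by inner product (plus a learned
per-entity output bias). Training is 1-N: every (h, r) query is scored
against all entities simultaneously and optimized with multi-label binary
cross-entropy over the observed tails; inverse relations are added so that
head-side queries become tail predictions. The trained entity table supplies
d^k and t^k for the fusion model and supports link-prediction queries
(indications, side effects) directly.

**S — structure.** Drugs are heavy-atom molecular graphs with 39-dimensional
atom features (element, degree, formal charge, radical electrons,
hybridization, aromaticity, total hydrogens, chirality; the charge and
radical counts are signed integers, everything else one-hot or flags) and
11-dimensional bond features (type, conjugation, ring membership, stereo).
The graph encoder is Attentive FP: each message-passing layer lets an atom
attend over its neighbors (additive attention with leaky-ReLU scoring,
softmax-normalized per neighborhood; bond features concatenated to the
neighbor state before the attention MLP) and updates its state through a GRU
cell; an attentive super-node readout attends over all atoms for a fixed
number of GRU timesteps and its final state is the drug embedding. Protein
sequences are decomposed into moderate-sized substrings by a frequency-
derived byte-pair subword vocabulary, embedded as token + learned positional
embeddings (E = E_seq + E_pos), passed through one post-norm Transformer
encoder block (masked multi-head self-attention, then a position-wise
feed-forward network, each followed by dropout, a residual connection and
layer normalization) and mean-pooled over real tokens.

**E — expression.** Drugs and targets are represented by consensus
perturbation signatures over a fixed gene panel (978 landmark genes in real
data; configurable here): the compound-perturbation row for the drug, and
the gene-overexpression or gene-knockdown row for the target according to
whether the interaction activates or inhibits it. Lookups are exact rows;
a missing row marks the channel unavailable for that entity.

**Fusion.** Per channel, the drug and target vectors are concatenated and
mapped into a latent space: affine → dropout → ReLU → layer normalization
(width `proj_dim`). The latents are concatenated and passed through a
four-layer perceptron (hidden widths 1024/1024/512 by default, ReLU,
dropout 0.1) with a sigmoid output. All parameters — including the
structural encoders and (optionally) the ConvE entity table — are trained
end to end with binary cross-entropy, early-stopping on validation AUPR.

## Dataset assembly and evaluation

Negatives are drawn uniformly without replacement from the complement of the
positive (drug, target) set over the full pair grid, at a configurable
negatives-per-positive ratio (default 1:2), once per dataset build and
before splitting. Negative pairs carry direction `unknown`; the expression
channel then uses the knockdown matrix by default, because inhibition is by
far the majority direction among labeled interactions (the policy is
config-exposed: `xpr`, `oe`, or `both-averaged`). Evaluation uses repeated
random 8:1:1 train/validation/test partitions (10 by default, seeds
`base_seed..base_seed+9`) rather than rotating folds; within one repeat all
model variants see identical splits, so per-repeat metrics are paired.
AUROC is the Mann–Whitney statistic with ties at half credit; AUPR is
average precision (step interpolation, the conservative choice); AUPR is
the primary metric because the datasets are negative-heavy. Across-repeat
differences use a two-sided Wilcoxon signed-rank test on paired per-repeat
metrics; with 10 repeats its exact two-sided floor is 2/2^10 ≈ 0.002.

The leakage guard is structural: ConvE training inputs are assembled only by
`build_k_channel`, which receives the held-out pairs explicitly and raises
before training if any of them appears among the training positives or as a
head–tail pair anywhere in the support graph (any relation).

## The router and reverse screening

The deployed system keeps a family of trained models (KSE, KS, S, and the
bare K model). For an input compound, structure is always available (the
SMILES is the input); K requires KG membership; E requires a compound
signature row. Dispatch picks the richest available model with fixed
priority KSE > KS > S; an S+E-only compound routes to S (there is no
deployed SE model, mirroring the deployed family). Reverse screening scores
a drug against the target universe with the dispatched model, marks scores
above 0.7 credible, and keeps the top 10 credible candidates per drug.
Drug-related relations (indications, side effects, pharmacologic classes —
any KG relation) are ranked by ConvE link prediction, optionally after
re-training the K model with credible predicted interactions injected as
new triples.

## Numerical substrate

No GPU deep-learning framework is used: all models run on a small
reverse-mode automatic-differentiation engine over NumPy arrays written for
this package (`mdtips.nn`), with gradient-checked primitives (broadcasted
arithmetic, batched matmul, gather/scatter and segment sums, the usual
nonlinearities), layers (Linear, Embedding, LayerNorm, GRU cell, masked
multi-head attention, dropout) and Adam. Convolution in ConvE is expressed
as patch-gather + matmul, so its gradient comes from the same primitives.
Everything is float64 and single-threaded, hence bit-reproducible from the
seeds; dropout draws from per-layer generators seeded by the model config.

## Default parameters

| Parameter | Default | Notes |
| --- | --- | --- |
| ConvE k (k_w × k_h) | 200 (20 × 10) | standard ConvE dimensioning |
| ConvE filters | 32 of 3×3 | |
| Attentive FP layers / timesteps / width | 2 / 2 / 64 | matches target-encoder width |
| Transformer d / m / heads / FFN | 64 / 545 / 8 / 256 | m is the subword-length cap |
| Gene panel G | 978 (real data), 50 (fixtures) | |
| proj_dim | 256 | per-modality latent width |
| Classifier hidden | 1024, 1024, 512 | "four-layer perceptron" read as three hidden + output |
| Dropout | 0.1 | throughout the fusion path |
| Optimizer | Adam, lr 1e-3 (ConvE) / 1e-4 (fusion), patience 10 on val AUPR | |
| Sampling ratio | 1:2 | grid {1:1, 1:2, 1:5, 1:10} supported |
| Credibility threshold / top-k | 0.7 / 10 | reverse screening |

The **desk-scale profile** (`workflows.desk_fusion_config`,
`desk_kge_config`) is what the tests, examples and the acceptance script
use: ConvE k=32 (8×4, 8 filters, 200 epochs, lr 5e-3), Attentive FP width
32, Transformer d=32/m=64/2 heads, proj_dim 32, classifier 64/64/32, lr
3e-3, up to 100 epochs with patience 25 and no stopping before epoch 50
(small validation splits make the early AUPR trajectory noisy; the floor
prevents locking onto a lucky early epoch). The desk profile freezes the
pretrained ConvE table during fusion: at fixture scale entity embeddings are
nearly unique per entity, and fine-tuning them lets the classifier memorize
training pairs through the K channel; the library default for full-size runs
remains fine-tuning, with `freeze_kge` exposed either way.

## The synthetic world

The generator emulates the joint data space the method consumes, with a
planted cross-modality signal. Each drug and target carries three mutually
independent latents: a 2-D structure trait with ±1 entries, a community id
(4 communities), and a 2-D Gaussian expression factor. Interaction
propensity is

    z = w_K · [same community] + w_S · (s_d·s_t)/2 + w_E · (e_d·e_t)/2 + ε,

ε ~ N(0, noise_sd²), defaults w = (1.5, 1, 1) and noise_sd = 0.5; the top
`positive_rate` (default 10%) of all pairs become labeled positives, and a
positive's direction (activate/inhibit) follows the sign of the target's
first expression-factor coordinate. The K weight is set above the others so
the knowledge channel is the strong one, matching how knowledge-graph-driven
variants dominate in real DTI data. Observable data are tied to the latents:

- SMILES are composed from a closed, valence-safe fragment grammar; the
  aromatic/aliphatic and nitrogen/oxygen fragment mix follows the structure
  trait, so the trait is recoverable from graph features. Every generated
  string is validated with RDKit at generation time.
- Sequences (50–400 residues) are sampled with trait-dependent
  hydrophobic/polar and basic/acidic residue composition.
- The KG links every drug and target to its community's pathway hub, to two
  same-community peers, and to community-assigned diseases, plus random
  side-effect edges. The hub-and-peer structure is what makes the community
  recoverable by ConvE.
- Signature rows are noisy linear images (rank-2 loadings) of the expression
  factors. The overexpression and knockdown rows share the same loading sign
  with independent noise. Real OE/knockdown pairs are anti-correlated; the
  fixture deliberately forgoes that, because with direction-unaware
  featurization of unlabeled pairs an anti-correlated pair of matrices makes
  the planted expression signal unidentifiable at this scale.

What passing tests on this world show — and what they do not: the pipeline
can recover a planted multi-channel signal, fused models do not lose the
information of their parts, the under-sampling and null-control patterns
behave as the method claims, and every guard fires. They do not show
anything about real chemistry, real transcriptomics, production-scale
biomedical knowledge graphs, or
absolute performance numbers on public DTI benchmarks, which require the
original large-scale data and multi-hour training.

## Problem sizes used by tests and the acceptance script

Fixture worlds are 60 drugs × 80 targets (the ablation ordering and null
control use 60×80 and 40×50; the ratio grid uses positive rate 0.08 so that
a 1:10 complement exists; the acceptance script uses 40×50 with 3 repeats).
The ratio-grid check uses the K-only cell: it is the cheapest stable cell,
and — unlike the most flexible fused cells, whose AUROC still creeps up with
the extra negatives at fixture scale — it saturates at every ratio, which is
the regime the published pattern describes. These sizes are the package's
desk-scale defaults; all of them are ordinary config fields.

## Known limitations

- Pooling the Transformer output by masked mean is one of several defensible
  readouts (first-token or flattened m×d are alternatives); it is
  config-adjacent but only the mean is implemented.
- The ConvE inner nonlinearity is fixed to ReLU (as is the outer one).
- Scores are not calibrated; the 0.7 credibility threshold is a convention,
  not a probability statement.
- K-only entities without a parseable SMILES are outside the DTI routing
  path (the router starts from a SMILES); KG link prediction still covers
  them.
- The autodiff engine is single-threaded float64 NumPy: exactly reproducible
  and fine at desk scale, but not a substrate for full-size training runs.
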