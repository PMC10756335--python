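# Methods

## Model

The classifier predicts binary drug response (sensitive / resistant) for
(cell line, drug) pairs. A pair is sensitive when its IC50 does not exceed
the drug's maximum screening concentration; the comparison is inclusive and
monotone, so it can equivalently be carried out on the raw µM scale or on
log concentrations (both are supported; raw is the default and the choice
never changes a label as long as both columns share a scale).

**Cell lines.** Expression values are log2(TPM + 1)-transformed, missing
omics entries zero-filled, and every gene column standardized to zero mean
and unit population standard deviation (constant genes map to zero rather
than raising). Two bias-free linear encoders map the standardized
expression and CNV matrices to f-dimensional views `z_g`, `z_c`. A
per-cell-line gate scores each view with `w = tanh(W z + b)` (one scalar per
cell line per branch, each branch with its own bias) and fuses them with a
two-way softmax: `h_omics = α_g z_g + α_c z_c`, `α_g + α_c = 1`. The
morphology image (bilinearly resized to 224×224 RGB in [0, 1]) passes a
fixed 8×8 average-pooling front end (224 → 28), two conv(3×3, stride 1,
same padding) → ReLU → average-pool(2×2) blocks with 16 and 32 channels,
global average pooling, and a linear head to f dimensions. The cell
representation is `Z_cell = [h_omics ; h_image] ∈ R^{2f}`.

**Drugs.** SMILES strings are parsed into heavy-atom graphs (hydrogens
implicit; multi-fragment inputs reduced to the largest fragment, logged).
Each atom carries the standard 75-length feature vector (44-symbol one-hot
with an "other" slot, degree 0–10, implicit valence 0–6, formal charge,
radical electrons, hybridization SP/SP2/SP3/SP3D/SP3D2, aromaticity,
total hydrogens 0–4; one-hot overflows map to the last bucket). Two GCN
layers over the symmetric-normalized adjacency with self-loops,
`H' = ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} H W)` with widths 75 → 2f → 2f, are
followed by global max pooling over atoms (pooling acts on the activated
features), giving `Z_drug ∈ R^{2f}` invariant to atom relabeling.

**Objective.** A symmetric InfoNCE loss with temperature γ aligns the omics
and image views of the same cell line; rows are L2-normalized before the
similarity so that γ = 0.01 yields bounded logits (`normalize_contrastive`
can disable this). The prediction head is an MLP 4f → 2f → 1 with ReLU and
sigmoid output on the concatenated pair `[Z_cell ; Z_drug]`; its
cross-entropy uses mean reduction (sum available) with probabilities
clamped at 1e-7. The total loss is `L = α L_c + β L_cl`, `α + β = 1`
enforced at configuration time. Training is full batch with Adam; the
contrastive batch is the set of cell lines appearing in the training pairs.
Features are transductive (all cell lines and drugs are encoded at every
step) while labels are inductive: the cross-validation split is over
labeled pairs, matching the screening protocol.

## Defaults

| parameter | default | meaning |
|---|---|---|
| f | 18 | embedding half-dimension; cell and drug representations have width 2f = 36 |
| γ | 0.01 | contrastive temperature (on cosine similarities) |
| α, β | 0.6, 0.4 | classification / contrastive loss weights |
| lr | 0.008 | Adam step size |
| weight decay | 1e-5 | classic L2 added to the raw gradient |
| epochs | 2000 | full-batch steps (scaled-down experiments in this repo use 300) |
| folds | 10 | stratified pair-level cross-validation (scaled-down runs use 3) |

Ablation switches: `no_image`, `no_rnaseq`, `no_cnv` zero out the
corresponding branch (the pair representation keeps its 4f layout so all
variants share one head shape; a removed branch contributes a zero block),
`no_attention` replaces the gate by the unweighted mean, `no_cl` sets
α = 1, β = 0 (the contrastive value is still logged, never backpropagated).
Removing the image or both omics branches also disables the contrastive
term, which needs two views.

## Numerical and optimization choices

* **Autodiff.** The package trains through a small reverse-mode engine over
  float64 NumPy arrays (`cdrlearn.autodiff`); every operator's gradient is
  checked against central finite differences in the test suite. Max
  reductions split gradients equally over ties.
* **Bit-exact graph invariance.** Plain matmul aggregates neighbor
  contributions in atom-label order, so two relabelings of one molecule can
  differ in the last float bit. The GCN aggregation instead sums each
  node's neighbor contributions in value-sorted order, making the drug
  encoding exactly invariant to atom relabeling.
* **Attention gate initialization.** The score functionals start at zero:
  the gate begins at the unweighted mean (α = 1/2) and learns to deviate.
  Glorot-scale scores would saturate the tanh and freeze arbitrary
  per-cell-line gates for the duration of a short run.
* **Image head gain.** Globally pooled convolution features vary little
  across inputs at initialization, so the linear image head is initialized
  with an 8× gain. This puts `h_image` on the same cross-cell-line
  variability scale as `h_omics`; otherwise the symmetric contrastive
  objective spends the early epochs collapsing the informative omics view
  onto a nearly constant image view instead of adapting both.
* **Head output layer.** Zero-initialized: predictions start at 1/2 and the
  hidden layer receives gradient only as the readout grows.
* **Adam β₂ = 0.99.** The contrastive alignment phase produces a large early
  gradient transient; with the conventional 0.999 the inflated
  second-moment estimates throttle the shared encoders for roughly a
  thousand steps, which is the entire length of a scaled-down run. A
  shorter second-moment memory lets the encoders recover their effective
  step size. (Only the learning rate and weight decay are part of the
  reference configuration; the moment constants are this package's choice.)
* **Cross-validation.** Folds are stratified by label so every test fold
  contains both classes; a single-class fold raises with a remediation
  hint. Each fold's model uses a distinct initialization seed
  (`seed + fold`), so the fold mean averages over independent draws rather
  than reusing one; the whole protocol is bit-reproducible for a fixed
  seed. Degenerate inputs (empty graphs, non-finite losses, γ ≤ 0,
  α + β ≠ 1) raise typed errors naming the offending quantity.

## Synthetic data generator

The generator produces the five raw inputs — expression CSV, CNV CSV, one
PNG per cell line, a drug table drawn from a packaged library of 84 valid
drug-like SMILES, and a response CSV — in exactly the layout the readers
consume. It plants the structure the model assumes:

* Each cell line has k = 4 latent factors; factor 0 is visible only in
  expression, factor 1 only in CNV, factor 2 only in the images, factor 3
  in all three modalities. The images additionally carry a weak echo
  (amplitude 0.3) of the omics-private factors: morphology reflects overall
  molecular state, and this shared structure is what lets the cross-modal
  contrastive objective identify cell lines across views. Under
  `signal_modality="omics"` the images are pure noise; under `"image"` the
  omics are.
* The omics matrices are exact low-rank read-outs of their visible factors
  (expression on the log2(TPM+1) scale, mapped back to raw TPM; CNV around
  2 copies). Keeping them noise-free makes modality information cleanly
  attributable: an encoder cannot smuggle an invisible factor through
  per-cell noise fingerprints, so an ablation's loss is genuinely tied to
  the dropped modality. Missing values are planted as whole dropped genes
  (1% of columns) for the same reason.
* Images are procedural: per-channel intensity plus low-frequency cosine /
  blob textures encode the visible factors (intensity dominates because it
  survives any pooling), then sigmoid squashing, pixel noise (sd 0.05) and
  8-bit quantization.
* Each drug loads with unit magnitude and random sign on a single factor
  ("one target pathway per drug"); the image-private factor receives 3× the
  allocation weight (about half the drugs), with deterministic
  largest-remainder counts so every seed plants the same signal share per
  modality. Labels are Bernoulli(sigmoid(15·(u·v + ε) + b0_j)) with
  pair-level noise ε of sd `noise_sd` (default 0.3) and per-drug intercepts
  b0_j calibrated by root finding so every drug's expected sensitive
  fraction equals the target (default 0.35, the sensitive share of a
  GDSC-scale screen); drug-level base rates therefore carry no ranking
  information. The sharpness 15 makes the clean-latent oracle ranking
  essentially perfect at zero noise. 5% of pairs are left unmeasured.
  Labels are finally converted to (IC50, threshold) pairs — sensitive draws
  at or below the drug's screening maximum, resistant strictly above — that
  binarize back to exactly the planted labels.

What the generator does **not** emulate: gene–gene covariance and pathway
structure, cancer-type clusters, dose–response curve shapes, realistic cell
morphology (the images are textures, not cells), assay noise in the omics,
and any relationship between a drug's actual chemical structure and its
planted latent vector (the GCN can only memorize which graph maps to which
behavior, which is all a 40-drug screen identifies anyway). Passing the
end-to-end tests therefore shows that the architecture, objectives and
protocol can recover a planted multimodal signal at desk scale — not that
the model attains any particular accuracy on real screening data.

## Scaled-down experiment

The repository's end-to-end experiment (acceptance script and test suite)
uses 60 cell lines × 40 drugs × 200 genes with signal in both omics and
images, 3-fold stratified cross-validation and 300 epochs — sizes chosen so
the whole experiment runs in minutes on one CPU while leaving a clear
margin between the full model, the planted-signal ceiling, and the
single-modality ablations. The qualitative ablation ordering at these
conditions matches the reference analysis: the full model ranks first and
removing the morphology images costs by far the most.

## Known limitations

* Full-batch training only (the contrastive batch definition is then
  unambiguous); minibatching is out of scope.
* The transductive feature setting means every cell line and drug must be
  present at fit time; predicting for unseen cell lines requires refitting.
* The attention gate is a scalar per branch and cell line, not per
  dimension.
* AUC/AUPR are the only metrics; no calibration assessment.
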