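# cdrlearn

Multimodal cancer drug response prediction for cell-line screening data.

Large screens such as GDSC label each (cell line, drug) pair *sensitive* or
*resistant* by comparing the pair's IC50 with the drug's maximum screening
concentration. `cdrlearn` predicts these binary responses by combining three
views of a cell line — gene expression, copy-number variation (CNV) and a
morphology image — with a graph representation of each drug:

* **Cell lines.** Standardized expression and CNV matrices pass through
  independent bias-free linear encoders to f-dimensional views `z_g`, `z_c`.
  A per-cell-line attention gate scores each view with `w = tanh(W z + b)`
  and fuses them with a two-way softmax, `h_omics = α_g z_g + α_c z_c`
  (`α_g + α_c = 1`). A small CNN (two conv → ReLU → average-pool blocks,
  global average pooling, linear head) embeds the 224×224 RGB image to
  `h_image`. The cell representation is the concatenation
  `Z_cell = [h_omics ; h_image] ∈ R^{2f}`.
* **Drugs.** SMILES strings become heavy-atom molecular graphs with
  75-dimensional atom features. Two GCN layers over the
  symmetric-normalized adjacency with self-loops,
  `H' = ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} H W)`, followed by global max pooling,
  give `Z_drug ∈ R^{2f}`.
* **Objective.** A symmetric InfoNCE contrastive loss with temperature γ
  aligns the omics and image views of the same cell line; an MLP on the
  concatenated pair `[Z_cell ; Z_drug]` predicts the sensitivity
  probability with cross-entropy loss `L_c`. The total loss is
  `L = α L_c + β L_cl` with `α + β = 1`
  (defaults α = 0.6, β = 0.4, γ = 0.01, f = 18, Adam, lr 0.008,
  weight decay 1e-5, 2000 epochs, 10-fold stratified cross-validation).

Performance is reported as AUROC and AUPR over held-out pairs; ablation
switches (`no_image`, `no_rnaseq`, `no_cnv`, `no_attention`, `no_cl`)
reproduce the usual modality/module knock-out analysis.

Everything runs on CPU; the training engine is a compact reverse-mode
autodiff over NumPy arrays included in the package (`cdrlearn.autodiff`).

## Worked example

No downloads are required: the package ships a synthetic data generator
that plants a cross-modal latent structure and a response signal
(see `docs/methods.md` for what it emulates).

```python
from cdrlearn import SyntheticSpec, generate_dataset, cross_validate

spec = SyntheticSpec(m=60, n_drugs=40, d_genes=200, seed=1)
dataset = generate_dataset(spec).to_dataset()

report = cross_validate(dataset, n_splits=3, seed=1, epochs=300)
print(f"mean AUC  {report.mean_auc:.4f}")
print(f"mean AUPR {report.mean_aupr:.4f}")
```

```
mean AUC  0.8571
mean AUPR 0.7816
```

(Your exact numbers depend on the seed; training is bit-reproducible for a
fixed seed.) A mean AUC near 0.86 against a planted-signal ceiling of about
0.96 — the best any ranking can do given the generator's label noise — means
the model recovered most of the planted structure from 300 epochs of
training. Dropping the morphology image branch

```python
from cdrlearn import run_ablation
reports = run_ablation(dataset, variants=("no_image",), n_splits=3, seed=1, epochs=300)
```

costs about ten points of AUC (0.7519 at the same seed) because roughly
half of the synthetic drugs respond to a latent factor that only the
images carry.

The same pipeline is available from the shell:

```bash
cdrlearn synth --out data/ --m 60 --n-drugs 40 --seed 1
cdrlearn preprocess --expr data/expression.csv --cnv data/cnv.csv \
    --images-dir data/images --drugs data/drugs.csv \
    --response data/response.csv --out cache/
cdrlearn train-cv --cache cache/ --out run/ --folds 3 --epochs 300 --seed 1
cdrlearn sweep-alpha --cache cache/ --out sweep/ --alphas 1.0,0.8,0.6,0.4
```

`train-cv` writes a summary JSON, per-fold and per-pair CSVs, and cell/drug
embedding exports (m × 2f and n × 2f) for downstream visualization. Real
data in the documented CSV/PNG layout (omics: first column cell line ID,
header gene IDs; responses: `cell_line,drug,ic50,max_screening_conc`;
one image per cell line named by its ID) drops into the same commands.

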