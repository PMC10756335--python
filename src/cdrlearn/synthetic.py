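"""Synthetic multimodal drug-response datasets with a planted signal.

The generator emulates the statistical structure the classifier assumes,
without any download:

* every cell line i has a latent factor vector u_i (k factors, standard
  normal); every drug j has a latent vector v_j;
* the omics matrices are exact low-rank linear read-outs of (subsets of)
  the latent factors: expression = U G_e on the log2(TPM+1) scale, mapped
  back to raw TPM so the real preprocessing chain applies; CNV is a direct
  linear read-out around 2 copies.  Keeping these read-outs noise-free makes
  the information each modality carries cleanly attributable: an encoder can
  only represent the factors its input actually contains;
* each morphology image is a 224 x 224 x 3 procedural texture whose
  low-frequency components encode (subsets of) the same latent factors, plus
  pixel noise — a shared latent makes the omics <-> image alignment
  learnable, which is exactly what the contrastive objective needs;
* the response label of pair (i, j) is Bernoulli(sigmoid(s * (u_i . v_j +
  noise) + b0_j)) with per-drug intercepts b0_j calibrated so every drug's
  expected sensitive fraction matches the requested target (drug-level base
  rates carry no ranking information); labels are then converted to
  (IC50, max screening concentration) pairs that binarize back to exactly
  the same labels.  Drug latents v_j are sparse: each drug loads with unit
  magnitude and random sign on a single factor ("one target pathway per
  drug"), with image-only factors receiving a larger deterministic share of
  drugs — so removing a modality makes the pairs of the drugs targeting its
  private factor genuinely unpredictable.

Factor visibility plants complementary information per modality so ablations
are meaningful.  With ``signal_modality="both"`` (default, k = 4): factor 0
is expression-only, factor 1 CNV-only, factor 2 image-only, factor 3
shared by all three modalities.  The morphology image additionally carries a
weak echo of the omics-private factors: morphology reflects the overall
molecular state, which gives the cross-modal contrastive objective enough
shared structure to identify cell lines across views without making the
image a substitute for the omics read-outs.  ``"omics"`` routes everything through the
two omics matrices (images are pure noise) and ``"image"`` the reverse.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data import DrugResponseDataset, assemble_dataset
from .exceptions import ValidationError
from .graphs import featurize_smiles
from .preprocess import IMAGE_SIZE, OmicsMatrix

# label sharpness: with clean latents the oracle ranking is near-perfect
LABEL_SHARPNESS = 15.0
# pixel-level observation noise of the image read-out.  The omics matrices
# are exact low-rank read-outs of their visible factors: a linear encoder
# then cannot smuggle invisible factors through per-cell noise fingerprints,
# so whatever an ablated model loses is genuinely tied to the dropped
# modality.  The spec-level noise_sd governs the pair-level response noise.
IMAGE_NOISE_SD = 0.05
MISSING_PAIR_FRACTION = 0.05
# weight of each image-only factor in the drug-target allocation: the
# morphology branch carries the largest single share of the response signal
IMAGE_FACTOR_WEIGHT = 3.0
# amplitude of the weak echo of omics-private factors in the images,
# relative to the image's own factors
WEAK_IMAGE_LOADING = 0.3
# weight of each multi-modality (shared) factor in the drug-target allocation
SHARED_FACTOR_WEIGHT = 0.5
THRESHOLD_MENU = (0.1, 1.0, 4.0, 10.0, 32.0)  # µM max screening concentrations


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    m: int = 60
    n_drugs: int = 40
    d_genes: int = 200
    k: int = 4
    noise_sd: float = 0.3
    signal_modality: str = "both"  # both | omics | image
    sensitive_fraction: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if min(self.m, self.n_drugs, self.d_genes, self.k) < 1:
            raise ValidationError("all sizes must be >= 1")
        if self.k > min(self.m, self.d_genes):
            raise ValidationError(f"k={self.k} exceeds min(m, d_genes)")
        if self.signal_modality not in ("both", "omics", "image"):
            raise ValidationError(f"unknown signal_modality {self.signal_modality!r}")
        if not 0.0 < self.sensitive_fraction < 1.0:
            raise ValidationError("sensitive_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """Raw synthetic inputs plus ground truth for oracle checks."""

    spec: SyntheticSpec
    expr_df: pd.DataFrame  # raw TPM scale, may contain NaN
    cnv_df: pd.DataFrame  # copy-number scale, may contain NaN
    images: np.ndarray  # (m, 224, 224, 3) uint8
    drugs_df: pd.DataFrame  # drug_id, smiles
    response_df: pd.DataFrame  # cell_line, drug, ic50, max_screening_conc
    latents: dict = field(default_factory=dict)  # U, V, clean/noisy logits, oracle scores

    def to_dataset(self) -> DrugResponseDataset:
        """Run the real preprocessing chain on the synthetic raw inputs."""
        graphs = [
            featurize_smiles(r.smiles, drug_id=r.drug_id)
            for r in self.drugs_df.itertuples(index=False)
        ]
        return assemble_dataset(
            OmicsMatrix.from_dataframe(self.expr_df, state="raw"),
            OmicsMatrix.from_dataframe(self.cnv_df, state="raw"),
            self.images.astype(np.float64) / 255.0,
            graphs,
            self.response_df,
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the five inputs in the standard on-disk layout (CSV + PNG)."""
        from PIL import Image

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        paths = {
            "expr": out / "expression.csv",
            "cnv": out / "cnv.csv",
            "drugs": out / "drugs.csv",
            "response": out / "response.csv",
            "images_dir": out / "images",
        }
        self.expr_df.to_csv(paths["expr"], float_format="%.6f")
        self.cnv_df.to_csv(paths["cnv"], float_format="%.6f")
        self.drugs_df.to_csv(paths["drugs"], index=False)
        self.response_df.to_csv(paths["response"], index=False, float_format="%.6g")
        for i, cid in enumerate(self.expr_df.index):
            Image.fromarray(self.images[i], mode="RGB").save(paths["images_dir"] / f"{cid}.png")
        return paths


def load_smiles_library() -> pd.DataFrame:
    """The packaged library of drug-like molecules (drug_id, smiles)."""
    text = (
        importlib.resources.files("cdrlearn").joinpath("assets/smiles_library.txt").read_text()
    )
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return pd.DataFrame(rows, columns=["drug_id", "smiles"])


def _factor_visibility(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean masks (expr, cnv, image) over the k factors."""
    k = spec.k
    expr = np.zeros(k, bool)
    cnv = np.zeros(k, bool)
    img = np.zeros(k, bool)
    if spec.signal_modality == "both":
        # complementary split: one private factor per modality, rest shared
        expr[0 % k] = True
        cnv[1 % k] = True
        img[2 % k] = True
        if k > 3:
            expr[3:] = cnv[3:] = img[3:] = True
    elif spec.signal_modality == "omics":
        expr[: (k + 1) // 2] = True
        cnv[(k + 1) // 2 :] = True
        # keep one factor shared across the two omics so attention has overlap
        expr[-1] = cnv[-1] = True
    else:  # image
        img[:] = True
    return expr, cnv, img


def _draw_drug_latents(
    rng: np.random.Generator,
    n_drugs: int,
    see_expr: np.ndarray,
    see_cnv: np.ndarray,
    see_img: np.ndarray,
) -> np.ndarray:
    """Sparse drug latents: one factor per drug, unit loading, random sign.

    Factors visible in no modality get zero weight; factors visible only in
    the image get IMAGE_FACTOR_WEIGHT times the weight so the morphology
    branch carries a substantial share of the response signal.  Counts per
    factor are allocated deterministically (largest-remainder rounding) and
    only the assignment order is randomized, so every seed plants the same
    amount of signal per modality.
    """
    visible = see_expr | see_cnv | see_img
    image_only = see_img & ~see_expr & ~see_cnv
    n_visible_in = see_expr.astype(int) + see_cnv.astype(int) + see_img.astype(int)
    shared = n_visible_in >= 2
    weights = np.where(
        visible,
        np.where(image_only, IMAGE_FACTOR_WEIGHT, np.where(shared, SHARED_FACTOR_WEIGHT, 1.0)),
        0.0,
    )
    if weights.sum() == 0:
        raise ValidationError("no factor is visible in any modality")
    k = len(weights)
    ideal = weights / weights.sum() * n_drugs
    counts = np.floor(ideal).astype(int)
    while counts.sum() < n_drugs:
        counts[np.argmax(ideal - counts)] += 1
    fac = np.repeat(np.arange(k), counts)
    rng.shuffle(fac)
    sign = rng.choice([-1.0, 1.0], size=n_drugs)
    V = np.zeros((n_drugs, k))
    V[np.arange(n_drugs), fac] = sign
    return V


def _image_basis() -> np.ndarray:
    """Four standardized low-frequency 224x224 patterns (stack k x H x W)."""
    coords = np.arange(IMAGE_SIZE) / IMAGE_SIZE
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    patterns = [
        np.cos(2 * np.pi * xx),
        np.cos(2 * np.pi * yy),
        np.cos(2 * np.pi * (xx + yy)),
        np.exp(-((xx - 0.5) ** 2 + (yy - 0.5) ** 2) / 0.08),
    ]
    out = []
    for p in patterns:
        out.append((p - p.mean()) / p.std())
    return np.stack(out)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the five raw inputs with a planted cross-modal/response signal."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m, n, k = spec.m, spec.n_drugs, spec.k

    cell_ids = [f"CL{i:04d}" for i in range(m)]
    library = load_smiles_library()
    if n > len(library):
        raise ValidationError(
            f"n_drugs={n} exceeds the packaged SMILES library size {len(library)}"
        )
    drugs_df = library.iloc[
        np.sort(rng.choice(len(library), size=n, replace=False))
    ].reset_index(drop=True)

    U = rng.standard_normal((m, k))
    see_expr, see_cnv, see_img = _factor_visibility(spec)
    V = _draw_drug_latents(rng, n, see_expr, see_cnv, see_img)

    # --- omics ------------------------------------------------------------
    def omics_signal(mask: np.ndarray) -> np.ndarray:
        n_obs = max(int(mask.sum()), 1)
        G = rng.standard_normal((k, spec.d_genes)) * mask[:, None]
        return (U @ G) / np.sqrt(n_obs)

    expr_log = 6.0 + 1.5 * omics_signal(see_expr)
    expr_raw = np.maximum(np.exp2(expr_log) - 1.0, 0.0)
    cnv_vals = 2.0 + 0.5 * omics_signal(see_cnv)

    # plant missing values as whole dropped genes (failed probes), so the
    # zero-fill path is exercised without per-cell missingness fingerprints
    for mat in (expr_raw, cnv_vals):
        dropped = rng.random(spec.d_genes) < 0.01
        mat[:, dropped] = np.nan

    gene_ids = [f"G{j:05d}" for j in range(spec.d_genes)]
    expr_df = pd.DataFrame(expr_raw, index=pd.Index(cell_ids, name="cell_line"), columns=gene_ids)
    cnv_df = pd.DataFrame(cnv_vals, index=pd.Index(cell_ids, name="cell_line"), columns=gene_ids)

    # --- images -----------------------------------------------------------
    basis = _image_basis()  # (4, 224, 224)
    # strong loadings for the image's own factors, a weak echo of the
    # omics-private ones (morphology reflects overall molecular state)
    img_factors = list(np.flatnonzero(see_img))
    amplitudes = [1.0] * len(img_factors)
    if spec.signal_modality == "both":
        for fac in np.flatnonzero((see_expr | see_cnv) & ~see_img):
            img_factors.append(int(fac))
            amplitudes.append(WEAK_IMAGE_LOADING)
    mixing = rng.uniform(0.5, 1.5, size=(3, len(img_factors))) * rng.choice(
        [-1.0, 1.0], size=(3, len(img_factors))
    )
    images = np.empty((m, IMAGE_SIZE, IMAGE_SIZE, 3), dtype=np.uint8)
    for i in range(m):
        noise = IMAGE_NOISE_SD * rng.standard_normal((IMAGE_SIZE, IMAGE_SIZE, 3))
        signal = np.zeros((IMAGE_SIZE, IMAGE_SIZE, 3))
        for c in range(3):
            for t, fac in enumerate(img_factors):
                # mostly per-channel intensity (stain/confluence level) plus
                # low-frequency texture — intensity survives any pooling
                signal[:, :, c] += (
                    amplitudes[t]
                    * mixing[c, t]
                    * U[i, fac]
                    * (0.8 + 0.2 * basis[fac % len(basis)])
                )
        pixels = expit(0.9 * (signal + noise))
        images[i] = np.clip(np.round(pixels * 255.0), 0, 255).astype(np.uint8)

    # --- responses ----------------------------------------------------------
    clean = U @ V.T  # one unit-loading factor per drug: already unit scale
    noisy = clean + spec.noise_sd * rng.standard_normal((m, n))

    target = spec.sensitive_fraction

    # per-drug intercepts: every drug's expected sensitive fraction equals
    # the target, so drug-level base rates are uninformative and ranking
    # quality must come from cell-level information
    b0 = np.empty(n)
    for j in range(n):
        def frac(b: float, col=noisy[:, j]) -> float:
            return float(expit(LABEL_SHARPNESS * col + b).mean()) - target

        try:
            b0[j] = brentq(frac, -80.0, 80.0, xtol=1e-10)
        except ValueError as exc:  # pragma: no cover - degenerate latents
            raise ValidationError(
                f"cannot calibrate sensitive_fraction={target} for drug {j}: {exc}"
            ) from exc
    probs = expit(LABEL_SHARPNESS * noisy + b0)
    labels = (rng.random((m, n)) < probs).astype(np.int64)

    measured = rng.random((m, n)) >= MISSING_PAIR_FRACTION
    thresholds = rng.choice(THRESHOLD_MENU, size=n)
    rows = []
    for i in range(m):
        for j in range(n):
            if not measured[i, j]:
                continue
            thr = thresholds[j]
            if labels[i, j] == 1:
                ic50 = thr * rng.uniform(0.05, 1.0)  # <= threshold: sensitive
            else:
                ic50 = thr * rng.uniform(1.05, 30.0)  # strictly above: resistant
            rows.append((cell_ids[i], drugs_df["drug_id"].iloc[j], ic50, thr))
    response_df = pd.DataFrame(rows, columns=["cell_line", "drug", "ic50", "max_screening_conc"])

    oracle = expit(LABEL_SHARPNESS * clean + b0)  # b0 broadcasts per drug
    latents = {
        "U": U,
        "V": V,
        "clean_logits": LABEL_SHARPNESS * clean + b0,
        "noisy_logits": LABEL_SHARPNESS * noisy + b0,
        "oracle_scores": oracle,
        "labels": labels,
        "measured": measured,
        "factor_visibility": {
            "expr": see_expr,
            "cnv": see_cnv,
            "image": see_img,
        },
    }
    return SyntheticDataset(
        spec=spec,
        expr_df=expr_df,
        cnv_df=cnv_df,
        images=images,
        drugs_df=drugs_df,
        response_df=response_df,
        latents=latents,
    )


def make_worked_example(report_path: str | Path | None = None):
    """A hand-sized fixture (4 cell lines x 3 drugs) with printed intermediates.

    Returns a dict with the raw pieces, the assembled dataset, and the
    intermediate quantities (standardized omics, normalized adjacency per
    drug, attention weights under fixed score functionals).  If
    ``report_path`` is given, a plain-text reference report is written there.
    """
    from . import cell_encoder as ce
    from .graphs import normalize_adjacency
    from .preprocess import build_response_table

    cell_ids = ["CL-A", "CL-B", "CL-C", "CL-D"]
    gene_ids = ["G1", "G2", "G3", "G4", "G5"]
    expr_raw = np.array(
        [
            [0.0, 1.0, 7.0, 3.0, 15.0],
            [1.0, 3.0, 1.0, 3.0, 0.0],
            [3.0, 7.0, 0.0, 3.0, 1.0],
            [7.0, 15.0, 3.0, 3.0, 7.0],
        ]
    )
    cnv = np.array(
        [
            [2.0, 2.0, 1.0, 3.0, 2.0],
            [2.0, 4.0, 2.0, 2.0, 1.0],
            [2.0, 1.0, 3.0, 2.0, 2.0],
            [2.0, 2.0, 2.0, 1.0, 3.0],
        ]
    )
    drugs = pd.DataFrame(
        {
            "drug_id": ["ethanol-probe", "benzene-probe", "acetic-probe"],
            "smiles": ["CCO", "c1ccccc1", "CC(=O)O"],
        }
    )
    # IC50s straddle the shared 32 µM threshold to produce a chosen A matrix
    planted_A = np.array([[1, 0, 1], [0, 0, 1], [1, 1, 0], [0, 1, 1]])
    rows = []
    for i, cid in enumerate(cell_ids):
        for j, did in enumerate(drugs["drug_id"]):
            ic50 = 16.0 if planted_A[i, j] == 1 else 64.0
            rows.append((cid, did, ic50, 32.0))
    response_df = pd.DataFrame(rows, columns=["cell_line", "drug", "ic50", "max_screening_conc"])

    expr = OmicsMatrix(expr_raw, gene_ids, cell_ids, "raw").log_tpm().fill_missing().standardize()
    cnv_std = OmicsMatrix(cnv, gene_ids, cell_ids, "raw").fill_missing().standardize()
    table = build_response_table(response_df, cell_ids=cell_ids, drug_ids=list(drugs["drug_id"]))

    graphs = [featurize_smiles(s, drug_id=d) for d, s in zip(drugs["drug_id"], drugs["smiles"])]
    a_hats = {g.drug_id: normalize_adjacency(g.adjacency) for g in graphs}

    f = 3
    rng = np.random.default_rng(12345)
    W = rng.standard_normal((len(gene_ids), f))
    z_g = ce.encode_omics(expr.values, W)
    z_c = ce.encode_omics(cnv_std.values, W)
    Wg = rng.standard_normal((1, f))
    Wc = rng.standard_normal((1, f))
    h_omics, att = ce.attention_fuse(z_g, z_c, Wg, Wc, b_g=0.1, b_c=-0.1)

    images = np.tile(
        np.linspace(0.2, 0.8, 4)[:, None, None, None], (1, IMAGE_SIZE, IMAGE_SIZE, 3)
    )
    dataset = assemble_dataset(
        OmicsMatrix(expr_raw, gene_ids, cell_ids, "raw"),
        OmicsMatrix(cnv, gene_ids, cell_ids, "raw"),
        images,
        graphs,
        response_df,
    )
    example = {
        "cell_ids": cell_ids,
        "drug_ids": list(drugs["drug_id"]),
        "expr_standardized": expr.values,
        "cnv_standardized": cnv_std.values,
        "planted_A": planted_A,
        "response_table": table,
        "normalized_adjacency": a_hats,
        "attention": att,
        "h_omics": h_omics,
        "dataset": dataset,
    }
    if report_path is not None:
        with open(report_path, "w") as fh:
            fh.write("worked example: 4 cell lines x 3 drugs\n\n")
            fh.write("standardized expression:\n")
            fh.write(np.array2string(expr.values, precision=6) + "\n\n")
            fh.write("standardized CNV:\n")
            fh.write(np.array2string(cnv_std.values, precision=6) + "\n\n")
            fh.write("label matrix A:\n")
            fh.write(np.array2string(table.label_matrix) + "\n\n")
            for did, a_hat in a_hats.items():
                fh.write(f"normalized adjacency ({did}):\n")
                fh.write(np.array2string(a_hat, precision=6) + "\n\n")
            fh.write("attention alpha_g:\n")
            fh.write(np.array2string(att.alpha_g, precision=6) + "\n")
            fh.write("attention alpha_c:\n")
            fh.write(np.array2string(att.alpha_c, precision=6) + "\n")
    return example
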