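"""Input readers, IC50 binarization, omics normalization and image resizing.

The classifier consumes five raw inputs: a drug table (id + SMILES), a gene
expression matrix and a copy-number matrix (cell lines x genes), one RGB
morphology image per cell line, and a response table of
(cell line, drug, IC50, per-drug maximum screening concentration) rows.
This module validates them and brings them onto the scales the encoders
expect:

* responses are binarized — a pair is *sensitive* (label 1) when its IC50 is
  at or below the drug's screening-concentration threshold, *resistant* (0)
  otherwise;
* expression values are log2(TPM + 1)-transformed, missing entries in both
  omics matrices are zero-filled, and every gene column is standardized to
  zero mean / unit population standard deviation (constant genes map to the
  zero column);
* images are bilinearly resized to 224 x 224 RGB with pixel values in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .exceptions import ValidationError

IMAGE_SIZE = 224

RESPONSE_COLUMNS = ("cell_line", "drug", "ic50", "max_screening_conc")


# ---------------------------------------------------------------------------
# response table
# ---------------------------------------------------------------------------

def binarize_response(ic50: float, threshold: float) -> int:
    """Label a (cell line, drug) pair: 1 = sensitive (IC50 <= threshold), 0 = resistant.

    Both values must be on the same concentration scale (the comparison is
    monotone, so any shared monotone rescaling — e.g. natural log — yields
    the same labels).
    """
    if not math.isfinite(ic50) or ic50 < 0:
        raise ValidationError(f"ic50 must be finite and >= 0, got {ic50!r}")
    if not math.isfinite(threshold) or threshold <= 0:
        raise ValidationError(f"threshold must be finite and > 0, got {threshold!r}")
    return 1 if ic50 <= threshold else 0


@dataclass
class ResponseTable:
    """Measured (cell line, drug) pairs with binarized sensitivity labels.

    ``records`` has columns cell_line, drug, ic50, threshold, label.  The
    label matrix has one row per cell line and one column per drug; entries
    for unmeasured pairs are NaN and are excluded from training/evaluation.
    """

    records: pd.DataFrame
    cell_ids: list[str] = field(default_factory=list)
    drug_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.cell_ids:
            self.cell_ids = sorted(self.records["cell_line"].unique())
        if not self.drug_ids:
            self.drug_ids = sorted(self.records["drug"].unique())

    @property
    def label_matrix(self) -> np.ndarray:
        mat = np.full((len(self.cell_ids), len(self.drug_ids)), np.nan)
        ci = {c: i for i, c in enumerate(self.cell_ids)}
        di = {d: j for j, d in enumerate(self.drug_ids)}
        for row in self.records.itertuples(index=False):
            mat[ci[row.cell_line], di[row.drug]] = row.label
        return mat

    def pairs(self, ic50_col_present: bool = False):
        """Index pairs X (n, 2) of (cell index, drug index) and labels y."""
        ci = {c: i for i, c in enumerate(self.cell_ids)}
        di = {d: j for j, d in enumerate(self.drug_ids)}
        X = np.array(
            [[ci[r.cell_line], di[r.drug]] for r in self.records.itertuples(index=False)],
            dtype=np.int64,
        ).reshape(-1, 2)
        y = self.records["label"].to_numpy(dtype=np.int64)
        return X, y


def build_response_table(
    df: pd.DataFrame,
    ic50_scale: str = "raw",
    cell_ids: list[str] | None = None,
    drug_ids: list[str] | None = None,
) -> ResponseTable:
    """Validate a raw response frame and binarize it.

    ``ic50_scale`` selects the scale on which the threshold comparison runs:
    ``"raw"`` compares concentrations in µM directly, ``"ln"`` compares their
    natural logarithms.  Labels are identical either way (the map is
    monotone); the switch only affects the stored ic50/threshold columns.
    """
    missing_cols = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"response table missing columns {missing_cols}")
    if ic50_scale not in ("raw", "ln"):
        raise ValidationError(f"ic50_scale must be 'raw' or 'ln', got {ic50_scale!r}")
    dup = df.duplicated(subset=["cell_line", "drug"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate (cell line, drug) pair: ({first['cell_line']}, {first['drug']})"
        )
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        ic50 = float(row.ic50)
        thr = float(row.max_screening_conc)
        if not math.isfinite(ic50) or ic50 < 0:
            raise ValidationError(
                f"record {idx} ({row.cell_line}, {row.drug}): bad ic50 {row.ic50!r}"
            )
        if not math.isfinite(thr) or thr <= 0:
            raise ValidationError(
                f"record {idx} ({row.cell_line}, {row.drug}): bad threshold {row.max_screening_conc!r}"
            )
        label = binarize_response(ic50, thr)
        if ic50_scale == "ln":
            # log of 0 µM is -inf; keep it, the comparison below is still valid
            ic50 = math.log(ic50) if ic50 > 0 else -math.inf
            thr = math.log(thr)
        records.append((row.cell_line, row.drug, ic50, thr, label))
    rec_df = pd.DataFrame(records, columns=["cell_line", "drug", "ic50", "threshold", "label"])
    return ResponseTable(rec_df, cell_ids or [], drug_ids or [])


# ---------------------------------------------------------------------------
# omics matrices
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """Cell lines x genes matrix plus its normalization state."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    state: str = "raw"  # raw | log_tpm | standardized

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError(f"omics matrix must be 2-D, got shape {self.values.shape}")
        m, d = self.values.shape
        if len(self.cell_ids) != m or len(self.gene_ids) != d:
            raise ValidationError(
                f"omics ids do not match matrix shape {self.values.shape}: "
                f"{len(self.cell_ids)} cells, {len(self.gene_ids)} genes"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, state: str = "raw") -> "OmicsMatrix":
        return cls(df.to_numpy(dtype=np.float64), list(df.columns), list(df.index), state)

    def log_tpm(self) -> "OmicsMatrix":
        return replace(self, values=log_tpm_transform(self.values), state="log_tpm")

    def fill_missing(self) -> "OmicsMatrix":
        return replace(self, values=fill_missing(self.values))

    def standardize(self) -> "OmicsMatrix":
        return replace(self, values=gaussian_normalize(self.values), state="standardized")


def log_tpm_transform(values: np.ndarray) -> np.ndarray:
    """Elementwise log2(x + 1) on TPM-scale expression values."""
    values = np.asarray(values, dtype=np.float64)
    if values.size and np.nanmin(values) < 0:
        raise ValidationError("log-TPM transform requires non-negative values")
    return np.log2(values + 1.0)


def fill_missing(values: np.ndarray) -> np.ndarray:
    """Replace NaN entries with zero; observed entries are untouched."""
    values = np.asarray(values, dtype=np.float64)
    return np.where(np.isnan(values), 0.0, values)


def gaussian_normalize(values: np.ndarray) -> np.ndarray:
    """Per-gene standardization (x - mu) / sigma with population sigma.

    Zero-variance genes are mapped to the all-zero column instead of raising.
    Missing values must be filled first.
    """
    values = np.asarray(values, dtype=np.float64)
    if np.isnan(values).any():
        raise ValidationError("standardization requires no missing values; call fill_missing first")
    mu = values.mean(axis=0)
    sigma = values.std(axis=0)  # population (divide by m)
    safe = np.where(sigma == 0.0, 1.0, sigma)
    out = (values - mu) / safe
    out[:, sigma == 0.0] = 0.0
    return out


def load_omics_csv(path: str | Path) -> OmicsMatrix:
    """Read a CSV/TSV omics matrix: first column cell line IDs, header genes."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return OmicsMatrix.from_dataframe(df)


def load_response_csv(path: str | Path, ic50_scale: str = "raw") -> ResponseTable:
    df = pd.read_csv(path, dtype={"cell_line": str, "drug": str})
    return build_response_table(df, ic50_scale=ic50_scale)


# ---------------------------------------------------------------------------
# morphology images
# ---------------------------------------------------------------------------

def preprocess_image(image: "np.ndarray | Image.Image | str | Path") -> np.ndarray:
    """Standardize a morphology image to (224, 224, 3) float64 in [0, 1].

    Accepts a file path, a PIL image, or an array (HxW or HxWx3, uint8 or
    float).  Resizing is bilinear; grayscale inputs are replicated across the
    three channels.
    """
    if isinstance(image, (str, Path)):
        path = Path(image)
        try:
            with Image.open(path) as img:
                img.load()
                pil = img
                return _standardize_pil(pil)
        except (UnidentifiedImageError, OSError) as exc:
            raise ValidationError(f"cannot decode image file {path}: {exc}") from exc
    if isinstance(image, Image.Image):
        return _standardize_pil(image)
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise ValidationError(f"image array must be HxW or HxWx3, got shape {arr.shape}")
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.dtype == np.uint8:
        pil = Image.fromarray(arr, mode="RGB")
        return _standardize_pil(pil)
    # float arrays: assume already in [0, 1]
    arr = arr.astype(np.float64)
    if arr.shape[:2] != (IMAGE_SIZE, IMAGE_SIZE):
        pil = Image.fromarray(np.clip(arr * 255.0, 0, 255).astype(np.uint8), mode="RGB")
        return _standardize_pil(pil)
    return arr


def _standardize_pil(pil: Image.Image) -> np.ndarray:
    if pil.width < 1 or pil.height < 1:
        raise ValidationError("image has no pixels")
    pil = pil.convert("RGB")
    if pil.size != (IMAGE_SIZE, IMAGE_SIZE):
        pil = pil.resize((IMAGE_SIZE, IMAGE_SIZE), Image.BILINEAR)
    return np.asarray(pil, dtype=np.float64) / 255.0


def load_images(directory: str | Path, cell_ids: list[str]) -> np.ndarray:
    """Load one image per cell line (filename stem = cell line ID) into (m, 224, 224, 3)."""
    directory = Path(directory)
    by_stem: dict[str, Path] = {}
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in (".png", ".jpg", ".jpeg"):
            by_stem[p.stem] = p
    out = np.empty((len(cell_ids), IMAGE_SIZE, IMAGE_SIZE, 3))
    for i, cid in enumerate(cell_ids):
        if cid not in by_stem:
            raise ValidationError(f"no image found for cell line {cid!r} in {directory}")
        out[i] = preprocess_image(by_stem[cid])
    return out
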