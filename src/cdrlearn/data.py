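"""Assembled, model-ready dataset containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .graphs import MolecularGraph, load_drug_library
from .preprocess import (
    OmicsMatrix,
    ResponseTable,
    build_response_table,
    load_images,
    load_omics_csv,
    load_response_csv,
)


@dataclass
class DrugResponseDataset:
    """Everything the classifier needs, aligned by index.

    expr / cnv are standardized (cell lines x genes) matrices sharing the
    row order of ``cell_ids``; ``images`` is (m, 224, 224, 3) in [0, 1];
    ``drug_graphs`` follows ``drug_ids`` order; ``responses`` holds the
    measured pairs with labels.
    """

    cell_ids: list[str]
    drug_ids: list[str]
    expr: np.ndarray
    cnv: np.ndarray
    images: np.ndarray
    drug_graphs: list[MolecularGraph]
    responses: ResponseTable

    def __post_init__(self):
        m = len(self.cell_ids)
        if self.expr.shape[0] != m or self.cnv.shape[0] != m or self.images.shape[0] != m:
            raise ValidationError("expression/CNV/image row counts must all match cell_ids")
        if len(self.drug_graphs) != len(self.drug_ids):
            raise ValidationError("drug_graphs must match drug_ids")
        if self.images.shape[1:] != (224, 224, 3):
            raise ValidationError(f"images must be (m, 224, 224, 3), got {self.images.shape}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Labeled (cell index, drug index) pairs X (S, 2) and labels y (S,)."""
        return self.responses.pairs()


def assemble_dataset(
    expr: OmicsMatrix,
    cnv: OmicsMatrix,
    images: np.ndarray,
    drug_graphs: list[MolecularGraph],
    response_df: pd.DataFrame,
    ic50_scale: str = "raw",
) -> DrugResponseDataset:
    """Run the preprocessing chain and align all five inputs.

    Expression goes through log2(TPM + 1) (if still raw), zero-fill and
    per-gene standardization; CNV through zero-fill and standardization.
    Cell lines are restricted to those present in both omics matrices, and
    response records referring to unknown cell lines or drugs are rejected.
    """
    cell_ids = [c for c in expr.cell_ids if c in set(cnv.cell_ids)]
    if not cell_ids:
        raise ValidationError("expression and CNV matrices share no cell lines")
    expr_idx = [expr.cell_ids.index(c) for c in cell_ids]
    cnv_idx = [cnv.cell_ids.index(c) for c in cell_ids]

    # subset rows first so standardization statistics match the final matrix
    e = OmicsMatrix(expr.values[expr_idx], expr.gene_ids, cell_ids, expr.state)
    c = OmicsMatrix(cnv.values[cnv_idx], cnv.gene_ids, cell_ids, cnv.state)
    if e.state == "raw":
        e = e.log_tpm()
    e = e.fill_missing().standardize()
    c = c.fill_missing().standardize()

    drug_ids = [g.drug_id for g in drug_graphs]
    known_cells, known_drugs = set(cell_ids), set(drug_ids)
    bad = response_df[
        ~response_df["cell_line"].isin(known_cells) | ~response_df["drug"].isin(known_drugs)
    ]
    if len(bad):
        first = bad.iloc[0]
        raise ValidationError(
            f"response record refers to unknown entity: ({first['cell_line']}, {first['drug']})"
        )
    responses = build_response_table(
        response_df, ic50_scale=ic50_scale, cell_ids=cell_ids, drug_ids=drug_ids
    )
    return DrugResponseDataset(
        cell_ids=cell_ids,
        drug_ids=drug_ids,
        expr=e.values,
        cnv=c.values,
        images=np.asarray(images, dtype=np.float64),
        drug_graphs=drug_graphs,
        responses=responses,
    )


def load_dataset(
    expr_path,
    cnv_path,
    images_dir,
    drugs_path,
    response_path,
    ic50_scale: str = "raw",
) -> DrugResponseDataset:
    """Load the five raw inputs from disk and assemble a model-ready dataset."""
    expr = load_omics_csv(expr_path)
    cnv = load_omics_csv(cnv_path)
    graphs = load_drug_library(drugs_path)
    responses = pd.read_csv(response_path, dtype={"cell_line": str, "drug": str})
    cell_ids = [c for c in expr.cell_ids if c in set(cnv.cell_ids)]
    images = load_images(images_dir, cell_ids)
    return assemble_dataset(expr, cnv, images, graphs, responses, ic50_scale=ic50_scale)
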