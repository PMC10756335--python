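"""The multimodal drug-response classifier and its evaluation protocol.

:class:`DrugResponseClassifier` is a scikit-learn style estimator.  Its
feature matrix ``X`` is an ``(n_pairs, 2)`` integer array of
(cell line index, drug index) into the :class:`~cdrlearn.data.DrugResponseDataset`
passed as the ``dataset`` parameter, and ``y`` holds the binary
sensitive/resistant labels.  This keeps the multimodal inputs (omics
matrices, morphology images, molecular graphs) in one place while the
train/test split — like the underlying screening protocol — operates on
(cell line, drug) pairs, so the estimator composes with scikit-learn model
selection out of the box.

Training is transductive in the features and inductive in the labels: all
cell lines and drugs are encoded at every step, the cross-entropy is computed
only on training pairs, and the contrastive term runs over the cell lines
that appear in the training pairs.  Optimization is full batch with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .autodiff import Adam, Tensor, concatenate, glorot_uniform
from .cell_encoder import CellLineEncoder, front_pool_images
from .data import DrugResponseDataset
from .drug_encoder import GcnDrugEncoder
from .exceptions import ConfigError, TrainingError, ValidationError
from .losses import PROB_CLAMP, check_loss_weights, contrastive_loss_t
from .metrics import compute_metrics

ABLATION_VARIANTS = ("no_image", "no_rnaseq", "no_cnv", "no_attention", "no_cl")


class _MlpHead:
    """4f -> 2f -> 1 prediction head with ReLU hidden and sigmoid output."""

    def __init__(self, f: int, rng: np.random.Generator):
        self.W1 = glorot_uniform(rng, (4 * f, 2 * f), fan_in=4 * f, fan_out=2 * f)
        self.b1 = Tensor(np.zeros(2 * f), requires_grad=True)
        # zero-init output layer: predictions start at 1/2 and the hidden
        # layer receives gradient only as the readout grows
        self.W2 = Tensor(np.zeros((2 * f, 1)), requires_grad=True)
        self.b2 = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, z_pairs: Tensor) -> Tensor:
        h = (z_pairs @ self.W1 + self.b1).relu()
        logits = h @ self.W2 + self.b2
        return logits.sigmoid().reshape(z_pairs.shape[0])


def predict_pair(z_cell: np.ndarray, z_drug: np.ndarray, head: _MlpHead) -> float:
    """Sensitivity probability for one (cell, drug) representation pair."""
    z_cell = np.asarray(z_cell, dtype=np.float64).reshape(1, -1)
    z_drug = np.asarray(z_drug, dtype=np.float64).reshape(1, -1)
    z = Tensor(np.concatenate([z_cell, z_drug], axis=1))
    if z.shape[1] != head.W1.shape[0]:
        raise ValidationError(
            f"pair representation width {z.shape[1]} does not match head input {head.W1.shape[0]}"
        )
    return float(head.forward(z).data[0])


class DrugResponseClassifier(BaseEstimator, ClassifierMixin):
    """Multimodal cancer drug response classifier.

    Parameters
    ----------
    dataset : DrugResponseDataset
        The aligned multimodal data the pair indices in ``X`` refer to.
    f : int, default 18
        Embedding half-dimension; cell and drug representations have width
        2f (36 at the default, matching the reference configuration).
    gamma : float, default 0.01
        Contrastive temperature.
    alpha, beta : float, defaults 0.6 / 0.4
        Weights of the classification and contrastive terms; must sum to 1.
    lr, weight_decay, epochs
        Adam settings; defaults 0.008 / 1e-5 / 2000.
    ablation : tuple of str
        Any of 'no_image', 'no_rnaseq', 'no_cnv', 'no_attention', 'no_cl'.
    normalize_contrastive : bool, default True
        L2-normalize rows before the contrastive similarity.
    seed : int
        Seeds parameter initialization; training itself is deterministic.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray [0, 1]
    history_ : DataFrame with per-epoch loss, loss_c, loss_cl
    cell_embedding_ : ndarray (m, 2f)
    drug_embedding_ : ndarray (n_drugs, 2f)
    """

    def __init__(
        self,
        dataset: DrugResponseDataset | None = None,
        f: int = 18,
        gamma: float = 0.01,
        alpha: float = 0.6,
        beta: float = 0.4,
        lr: float = 0.008,
        weight_decay: float = 1e-5,
        epochs: int = 2000,
        ablation: tuple[str, ...] = (),
        normalize_contrastive: bool = True,
        seed: int = 0,
    ):
        self.dataset = dataset
        self.f = f
        self.gamma = gamma
        self.alpha = alpha
        self.beta = beta
        self.lr = lr
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.ablation = ablation
        self.normalize_contrastive = normalize_contrastive
        self.seed = seed

    # -- internals -------------------------------------------------------
    def _validate(self, X, y):
        if self.dataset is None:
            raise ConfigError("dataset parameter is required before fitting")
        unknown = set(self.ablation) - set(ABLATION_VARIANTS)
        if unknown:
            raise ConfigError(
                f"unknown ablation variant(s) {sorted(unknown)}; valid: {list(ABLATION_VARIANTS)}"
            )
        if self.f < 1:
            raise ConfigError(f"f must be >= 1, got {self.f}")
        if self.gamma <= 0:
            raise ConfigError(f"gamma must be > 0, got {self.gamma}")
        check_loss_weights(self.alpha, self.beta)
        X = np.asarray(X, dtype=np.int64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError(f"X must be (n_pairs, 2) index pairs, got {X.shape}")
        if len(X) != len(y):
            raise ValidationError("X and y length mismatch")
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("labels must be binary 0/1")
        ds = self.dataset
        if X[:, 0].min() < 0 or X[:, 0].max() >= ds.n_cells:
            raise ValidationError("cell index out of range")
        if X[:, 1].min() < 0 or X[:, 1].max() >= ds.n_drugs:
            raise ValidationError("drug index out of range")
        return X, y.astype(np.float64)

    def _branches(self) -> dict[str, bool]:
        ab = set(self.ablation)
        return {
            "use_expr": "no_rnaseq" not in ab,
            "use_cnv": "no_cnv" not in ab,
            "use_image": "no_image" not in ab,
            "use_attention": "no_attention" not in ab,
        }

    def _forward(self, train_idx_cell, train_idx_drug):
        """One full forward pass; returns (p_train, l_cl tensor or None)."""
        br = self._branches()
        z_cell, h_omics, h_image = self._cell_enc.forward(
            self.dataset.expr, self.dataset.cnv, self._pooled_images, **br
        )
        z_drug = self._drug_enc.encode_library_t(self._pre_graphs)
        z_pairs = concatenate(
            [z_cell[train_idx_cell], z_drug[train_idx_drug]], axis=1
        )
        p = self._head.forward(z_pairs)
        l_cl = None
        if br["use_image"] and (br["use_expr"] or br["use_cnv"]):
            cells = self._contrastive_cells
            _, _, l_cl = contrastive_loss_t(
                h_omics[cells], h_image[cells], self.gamma, self.normalize_contrastive
            )
        return p, l_cl, z_cell, z_drug

    def _initialize(self, X):
        rng = np.random.default_rng(self.seed)
        ds = self.dataset
        self._cell_enc = CellLineEncoder(ds.expr.shape[1], ds.cnv.shape[1], self.f, rng)
        self._drug_enc = GcnDrugEncoder(self.f, rng)
        self._head = _MlpHead(self.f, rng)
        self._pooled_images = front_pool_images(ds.images)
        self._pre_graphs = [GcnDrugEncoder.precompute(g) for g in ds.drug_graphs]
        self._contrastive_cells = np.unique(X[:, 0])

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        X, y = self._validate(X, y)
        alpha, beta = self.alpha, self.beta
        if "no_cl" in self.ablation:
            alpha, beta = 1.0, 0.0
        self._initialize(X)

        params = (
            self._cell_enc.parameters() + self._drug_enc.parameters() + self._head.parameters()
        )
        # beta2 = 0.99: the contrastive alignment phase produces a large
        # early gradient transient; a shorter second-moment memory lets the
        # shared encoders recover their effective step size within a short
        # training schedule
        opt = Adam(params, lr=self.lr, betas=(0.9, 0.99), weight_decay=self.weight_decay)
        y_t = y
        idx_cell, idx_drug = X[:, 0], X[:, 1]
        history = []
        for epoch in range(self.epochs):
            opt.zero_grad()
            p, l_cl_t, z_cell, z_drug = self._forward(idx_cell, idx_drug)
            p_c = p.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
            l_c_t = -(
                Tensor(y_t) * p_c.log() + Tensor(1.0 - y_t) * (1.0 - p_c).log()
            ).mean()
            l_cl_val = float(l_cl_t.data) if l_cl_t is not None else 0.0
            loss = alpha * l_c_t
            if l_cl_t is not None and beta > 0.0:
                loss = loss + beta * l_cl_t
            total = float(loss.data)
            if not np.isfinite(total):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: "
                    f"L={total}, L_c={float(l_c_t.data)}, L_cl={l_cl_val}"
                )
            history.append((epoch, total, float(l_c_t.data), l_cl_val))
            loss.backward()
            opt.step()

        self.classes_ = np.array([0, 1])
        self.history_ = pd.DataFrame(history, columns=["epoch", "loss", "loss_c", "loss_cl"])
        # final embeddings for prediction / export
        p, _, z_cell, z_drug = self._forward(idx_cell, idx_drug)
        self.cell_embedding_ = z_cell.data
        self.drug_embedding_ = z_drug.data
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=np.int64)
        z = np.concatenate(
            [self.cell_embedding_[X[:, 0]], self.drug_embedding_[X[:, 1]]], axis=1
        )
        p1 = self._head.forward(Tensor(z)).data
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def _check_fitted(self):
        if not hasattr(self, "cell_embedding_"):
            raise TrainingError("classifier is not fitted")

    # -- checkpointing -----------------------------------------------------
    def _named_parameters(self) -> dict[str, Tensor]:
        named = {}
        for prefix, obj in (
            ("cell", self._cell_enc),
            ("image", self._cell_enc.image_encoder),
            ("drug", self._drug_enc),
            ("head", self._head),
        ):
            for attr, value in vars(obj).items():
                if isinstance(value, Tensor) and value.requires_grad:
                    named[f"{prefix}.{attr}"] = value
        return named

    def save(self, path) -> None:
        """Write fitted parameters and the hyperparameter config to one file."""
        import json

        self._check_fitted()
        config = json.dumps(
            {k: v for k, v in self.get_params().items() if k != "dataset"}, sort_keys=True
        )
        arrays = {name: t.data for name, t in self._named_parameters().items()}
        np.savez(path, __config__=np.array(config), **arrays)

    def load(self, path):
        """Restore parameters saved by :meth:`save` (same dataset and config)."""
        import json

        with np.load(path, allow_pickle=False) as archive:
            config = json.loads(str(archive["__config__"]))
            mine = {k: v for k, v in self.get_params().items() if k != "dataset"}
            if json.dumps(mine, sort_keys=True) != json.dumps(config, sort_keys=True):
                raise ConfigError("checkpoint config does not match this estimator's parameters")
            Xall, _ = self.dataset.pairs()
            self._initialize(Xall)
            for name, tensor in self._named_parameters().items():
                tensor.data = archive[name]
        # embeddings under the restored weights
        _, _, z_cell, z_drug = self._forward(Xall[:, 0], Xall[:, 1])
        self.cell_embedding_ = z_cell.data
        self.drug_embedding_ = z_drug.data
        self.classes_ = np.array([0, 1])
        return self


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Cross-validation outcome: per-fold and mean AUC/AUPR plus predictions."""

    fold_auc: list[float]
    fold_aupr: list[float]
    predictions: pd.DataFrame  # cell_line, drug, score, label, fold
    variant: str = "full"
    config: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    def summary(self) -> dict:
        return {
            "variant": self.variant,
            "folds": len(self.fold_auc),
            "fold_auc": [round(v, 6) for v in self.fold_auc],
            "fold_aupr": [round(v, 6) for v in self.fold_aupr],
            "mean_auc": round(self.mean_auc, 6),
            "mean_aupr": round(self.mean_aupr, 6),
            "config": self.config,
        }


def cross_validate(
    dataset: DrugResponseDataset,
    n_splits: int = 10,
    seed: int = 0,
    variant_name: str = "full",
    **model_params,
) -> EvalReport:
    """Stratified pair-level k-fold cross-validation of the classifier.

    Folds are a random partition of the labeled pairs, stratified by label so
    every test fold contains both classes; with a fixed ``seed`` the partition
    is identical across calls (the same seed also initializes each fold's
    model, so two invocations produce identical reports).
    """
    X, y = dataset.pairs()
    if len(X) < n_splits:
        raise ValidationError(f"need at least {n_splits} labeled pairs, got {len(X)}")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_auc, fold_aupr, frames = [], [], []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        if y[test].min() == y[test].max():
            raise TrainingError(
                f"fold {fold} contains a single class; increase data or change seed"
            )
        # distinct initialization per fold: fold means then average over
        # independent inits instead of reusing one draw three times
        model = DrugResponseClassifier(dataset=dataset, seed=seed + fold, **model_params)
        model.fit(X[train], y[train])
        scores = model.predict_proba(X[test])[:, 1]
        auc, aupr = compute_metrics(scores, y[test])
        fold_auc.append(auc)
        fold_aupr.append(aupr)
        frames.append(
            pd.DataFrame(
                {
                    "cell_line": [dataset.cell_ids[i] for i in X[test, 0]],
                    "drug": [dataset.drug_ids[j] for j in X[test, 1]],
                    "score": scores,
                    "label": y[test],
                    "fold": fold,
                }
            )
        )
    config = dict(model_params)
    config.update({"n_splits": n_splits, "seed": seed})
    return EvalReport(
        fold_auc=fold_auc,
        fold_aupr=fold_aupr,
        predictions=pd.concat(frames, ignore_index=True),
        variant=variant_name,
        config=config,
    )


def run_ablation(
    dataset: DrugResponseDataset,
    variants: tuple[str, ...] = ABLATION_VARIANTS,
    n_splits: int = 10,
    seed: int = 0,
    **model_params,
) -> dict[str, EvalReport]:
    """Evaluate the full model and each requested ablation under shared folds.

    A variant name may be a single switch ('no_image') or a comma-joined
    combination ('no_cnv,no_image').
    """
    reports: dict[str, EvalReport] = {}
    reports["full"] = cross_validate(
        dataset, n_splits=n_splits, seed=seed, variant_name="full", **model_params
    )
    for name in variants:
        switches = tuple(s.strip() for s in name.split(","))
        unknown = set(switches) - set(ABLATION_VARIANTS)
        if unknown:
            raise ConfigError(
                f"unknown ablation variant(s) {sorted(unknown)}; valid: {list(ABLATION_VARIANTS)}"
            )
        reports[name] = cross_validate(
            dataset,
            n_splits=n_splits,
            seed=seed,
            variant_name=name,
            ablation=switches,
            **model_params,
        )
    return reports


def sweep_alpha(
    dataset: DrugResponseDataset,
    alphas: list[float],
    n_splits: int = 10,
    seed: int = 0,
    **model_params,
) -> pd.DataFrame:
    """Cross-validate over a grid of alpha values with beta = 1 - alpha."""
    if not alphas:
        raise ConfigError("alpha grid must not be empty")
    rows = []
    for a in alphas:
        report = cross_validate(
            dataset,
            n_splits=n_splits,
            seed=seed,
            variant_name=f"alpha={a}",
            alpha=a,
            beta=1.0 - a,
            **model_params,
        )
        rows.append({"alpha": a, "beta": 1.0 - a, "auc": report.mean_auc, "aupr": report.mean_aupr})
    return pd.DataFrame(rows)
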