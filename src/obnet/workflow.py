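"""Training loops, grouped cross-validation, grid search, and evaluation.

Training optimises the three-part loss with Adam and keeps the checkpoint
of the epoch with the highest validation accuracy (early-stopping model
selection over a fixed epoch budget).  Validation is a group-disjoint 10%
split of the training data, so no patient straddles train and validation.
Hyperparameters are tuned by grid search over the penalty weight
λ ∈ {0.1, 0.01, 1e-3} and the learning rate ∈ {1e-5, 1e-4, 1e-3}
(overridable), selected on validation accuracy with ties broken toward the
smaller λ, then the smaller learning rate.

The final prediction of the model is the perception-branch output; the
attention-branch logits only contribute their loss term during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import explain
from .nn import Adam
from .nn.functional import softmax
from .obn_core import (ObnConfig, ObnModel, inverse_frequency_weights,
                       total_loss)
from .preprocess import AugmentSpec, augment

__all__ = [
    "Dataset", "CvPlan", "TrainRun", "EvalReport",
    "dataset_from_samples", "make_cv_plan", "train", "grid_search",
    "predict_proba", "evaluate", "guidance_experiment",
]


@dataclass
class Dataset:
    """In-memory classification dataset with optional paired weight maps."""

    images: np.ndarray                      # (N, H, W) in [0, 1]
    labels: np.ndarray                      # (N,) int or (N, K) binary
    weight_maps: np.ndarray | None = None   # (N, H, W) binary, 1 = penalised
    groups: np.ndarray | None = None        # patient identifiers
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        n = len(self.images)
        if self.groups is None:
            self.groups = np.arange(n)
        if self.ids is None:
            self.ids = np.array([f"sample-{i}" for i in range(n)])
        if self.weight_maps is not None:
            self.weight_maps = np.asarray(self.weight_maps, dtype=np.float32)

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "Dataset":
        return Dataset(
            images=self.images[idx], labels=self.labels[idx],
            weight_maps=None if self.weight_maps is None else self.weight_maps[idx],
            groups=self.groups[idx], ids=self.ids[idx],
        )


def dataset_from_samples(samples) -> Dataset:
    """Pack a list of synthetic samples into a Dataset."""
    return Dataset(
        images=np.stack([s.image for s in samples]),
        labels=np.array([s.label for s in samples]),
        weight_maps=np.stack([s.weight_map.values for s in samples]),
    )


@dataclass
class CvPlan:
    """Group-disjoint fold assignment: fold[i] is sample i's test fold."""

    folds: int
    assignments: np.ndarray
    group_key: np.ndarray

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_cv_plan(sample_ids, group_ids, folds: int, seed: int = 0) -> CvPlan:
    """Assign samples to group-disjoint folds with balanced sizes.

    Groups are shuffled, then greedily assigned (largest first) to the
    currently smallest fold, so fold sizes are balanced to within one
    group.  Deterministic under ``seed``.
    """
    sample_ids = np.asarray(sample_ids)
    group_ids = np.asarray(group_ids)
    uniq = np.unique(group_ids)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > len(uniq):
        raise ValueError("more folds than groups")
    rng = np.random.default_rng(seed)
    uniq = uniq[rng.permutation(len(uniq))]
    counts = {g: int((group_ids == g).sum()) for g in uniq}
    order = sorted(uniq, key=lambda g: -counts[g])
    fold_sizes = np.zeros(folds, dtype=int)
    fold_of_group: dict = {}
    for g in order:
        f = int(np.argmin(fold_sizes))
        fold_of_group[g] = f
        fold_sizes[f] += counts[g]
    assignments = np.array([fold_of_group[g] for g in group_ids])
    return CvPlan(folds=folds, assignments=assignments, group_key=group_ids)


@dataclass
class TrainRun:
    cfg: ObnConfig
    lr: float
    epochs: int
    batch_size: int
    history: pd.DataFrame
    best_epoch: int
    best_val_accuracy: float
    model: ObnModel | None = None


def _accuracy(model: ObnModel, data: Dataset, batch_size: int = 64) -> float:
    probs = predict_proba(model, data.images, batch_size=batch_size)
    if model.cfg.multilabel:
        pred = (probs >= 0.5).astype(int)
        return float((pred == data.labels).mean())
    return float((probs.argmax(axis=1) == data.labels).mean())


def _split_validation(data: Dataset, val_fraction: float, seed: int):
    """Group-disjoint validation split (ceil(fraction × groups) groups)."""
    uniq = np.unique(data.groups)
    rng = np.random.default_rng(seed)
    uniq = uniq[rng.permutation(len(uniq))]
    n_val = max(1, int(np.ceil(val_fraction * len(uniq))))
    val_groups = set(uniq[:n_val].tolist())
    val_mask = np.array([g in val_groups for g in data.groups])
    return data.subset(~val_mask), data.subset(val_mask)


def train(model: ObnModel, data: Dataset, cfg: ObnConfig, lr: float = 1e-3,
          epochs: int = 20, batch_size: int = 32,
          val_data: Dataset | None = None, val_fraction: float = 0.1,
          augment_spec: AugmentSpec | None = None, seed: int | None = None) -> TrainRun:
    """Optimise the three-part loss with Adam and early-stopping selection.

    The history records the attention, perception, and operation loss
    components and the validation accuracy per epoch; the model is left at
    the weights of the best-validation-accuracy epoch.  With
    ``cfg.lambda_ > 0`` every training image must have a weight map.
    """
    if cfg.lambda_ > 0 and data.weight_maps is None:
        raise ValueError("weight maps are required to train with lambda_ > 0")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1)
    if val_data is None:
        train_data, val_data = _split_validation(data, val_fraction, seed + 2)
    else:
        train_data = data
    if cfg.multilabel:
        class_weights = None
    else:
        class_weights = inverse_frequency_weights(train_data.labels, cfg.num_classes)
    opt = Adam(model.parameters(), lr=lr, betas=(0.9, 0.999))
    n = len(train_data)
    history_rows = []
    best_epoch, best_acc, best_state = -1, -np.inf, None
    aug_rng = np.random.default_rng(seed + 3) if augment_spec is not None else None
    for epoch in range(epochs):
        order = rng.permutation(n)
        sums = {"l_att": 0.0, "l_per": 0.0, "l_ope": 0.0, "total": 0.0}
        n_batches = 0
        model.train()
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            imgs = train_data.images[idx]
            wmaps = None if train_data.weight_maps is None else train_data.weight_maps[idx]
            if augment_spec is not None:
                aug_imgs = np.empty_like(imgs)
                aug_maps = None if wmaps is None else np.empty_like(wmaps)
                for j in range(len(idx)):
                    ai, am = augment(imgs[j], None if wmaps is None else wmaps[j],
                                     augment_spec, rng=aug_rng)
                    aug_imgs[j] = ai
                    if aug_maps is not None:
                        aug_maps[j] = am
                imgs, wmaps = aug_imgs, aug_maps
            outs = model.forward(imgs)
            breakdown = total_loss(outs, train_data.labels[idx], wmaps, cfg,
                                   class_weights)
            opt.zero_grad()
            breakdown.total.backward()
            opt.step()
            for key, val in breakdown.as_floats().items():
                sums[key] += val
            n_batches += 1
        val_acc = _accuracy(model, val_data)
        row = {k: v / n_batches for k, v in sums.items()}
        row.update(epoch=epoch, val_accuracy=val_acc)
        history_rows.append(row)
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    history = pd.DataFrame(history_rows)
    return TrainRun(cfg=cfg, lr=lr, epochs=epochs, batch_size=batch_size,
                    history=history, best_epoch=best_epoch,
                    best_val_accuracy=float(best_acc), model=model)


def grid_search(data: Dataset, lambdas, lrs, cfg: ObnConfig,
                epochs: int = 20, batch_size: int = 32,
                train_fn=None) -> tuple[TrainRun, pd.DataFrame]:
    """Train every (λ, lr) pair and keep the best validation accuracy.

    Ties are broken toward the smaller λ, then the smaller learning rate.
    ``train_fn(lambda_, lr) -> TrainRun`` may be injected (e.g. for tests);
    the default builds a fresh model per grid point with the shared seed.
    """
    lambdas, lrs = list(lambdas), list(lrs)
    if not lambdas or not lrs:
        raise ValueError("grids must be non-empty")

    if train_fn is None:
        def train_fn(lambda_, lr):
            point_cfg = replace(cfg, lambda_=lambda_)
            model = ObnModel(point_cfg)
            return train(model, data, point_cfg, lr=lr, epochs=epochs,
                         batch_size=batch_size)

    rows, runs = [], {}
    for lam in lambdas:
        for lr in lrs:
            run = train_fn(lam, lr)
            runs[(lam, lr)] = run
            rows.append({"lambda": lam, "lr": lr,
                         "val_accuracy": run.best_val_accuracy,
                         "best_epoch": run.best_epoch})
    table = pd.DataFrame(rows)
    best_key = max(runs, key=lambda k: (runs[k].best_val_accuracy, -k[0], -k[1]))
    return runs[best_key], table


def predict_proba(model: ObnModel, images: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    """Perception-branch probabilities (softmax; sigmoid in multi-label mode)."""
    model.eval()
    images = np.asarray(images, dtype=np.float32)
    outs = []
    for start in range(0, len(images), batch_size):
        logits = model.forward(images[start:start + batch_size]).per_logits.data
        if model.cfg.multilabel:
            outs.append(1.0 / (1.0 + np.exp(-logits)))
        else:
            outs.append(softmax(logits))
    model.train()
    return np.concatenate(outs, axis=0)


@dataclass
class EvalReport:
    """Binary classification metrics at a fixed threshold plus ranking AUC."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: dict = field(default_factory=dict)
    per_label_auc: dict | None = None


def evaluate(model: ObnModel, data: Dataset, threshold: float = 0.5) -> EvalReport:
    """Accuracy / sensitivity / specificity at ``threshold`` and ranking AUC.

    Metrics are computed from the perception-branch probability of the
    positive class.  In multi-label mode only per-label AUCs (and their
    mean) are reported.  A single-class test set makes the AUC undefined
    and is an error.
    """
    probs = predict_proba(model, data.images)
    if model.cfg.multilabel:
        y = np.asarray(data.labels)
        per_label = {}
        for j in range(y.shape[1]):
            if len(np.unique(y[:, j])) < 2:
                raise ValueError(f"label column {j} has a single class; AUC undefined")
            per_label[j] = float(roc_auc_score(y[:, j], probs[:, j]))
        mean_auc = float(np.mean(list(per_label.values())))
        acc = float(((probs >= threshold).astype(int) == y).mean())
        return EvalReport(accuracy=acc, sensitivity=np.nan, specificity=np.nan,
                          auc=mean_auc, per_label_auc=per_label)
    y = np.asarray(data.labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class test set; AUC undefined")
    p1 = probs[:, 1]
    pred = (p1 >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return EvalReport(
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=float(roc_auc_score(y, p1)),
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    )


def guidance_experiment(n: int = 400, image_size: int = 64,
                        signal_strength: float = 0.4,
                        confound_strength: float = 0.8,
                        lambda_: float = 0.1, epochs: int = 20,
                        batch_size: int = 32, lr: float = 1e-3,
                        seeds=(0, 1, 2, 3, 4), test_fraction: float = 0.2,
                        backbone: str = "tiny") -> dict:
    """Paired ABN-vs-OBN comparison on the synthetic confounded dataset.

    For each seed: generate a dataset with a corner confounder stronger
    than the in-anatomy signal, train an ABN (λ = 0) and an OBN (λ as
    given) from identical initialisation, then on a group-disjoint test
    split compute the Grad-CAM Attention Index of every positive test image
    for both models, the strict improvement ratio OBN-vs-ABN, and both test
    AUCs.  Returns pooled summary statistics.
    """
    from .synthetic import SynthSpec, generate_classification_set

    all_pairs: list[explain.IndexPair] = []
    ai_obn, ai_abn, auc_obn, auc_abn = [], [], [], []
    for seed in seeds:
        spec = SynthSpec(n=n, image_size=image_size,
                         signal_strength=signal_strength,
                         confound_strength=confound_strength, seed=seed)
        data = dataset_from_samples(generate_classification_set(spec))
        fit_data, test_data = _split_validation(data, test_fraction, seed + 10)
        runs = {}
        for name, lam in (("abn", 0.0), ("obn", lambda_)):
            cfg = ObnConfig(backbone=backbone, lambda_=lam, num_classes=2,
                            input_size=image_size, seed=seed)
            model = ObnModel(cfg)
            runs[name] = train(model, fit_data, cfg, lr=lr, epochs=epochs,
                               batch_size=batch_size, seed=seed)
        rep = {name: evaluate(run.model, test_data) for name, run in runs.items()}
        auc_abn.append(rep["abn"].auc)
        auc_obn.append(rep["obn"].auc)
        pos = np.flatnonzero(np.asarray(test_data.labels) == 1)
        for i in pos:
            roi = explain.RoiSet.from_weight_map(test_data.weight_maps[i])
            s_abn = explain.grad_cam(runs["abn"].model, test_data.images[i], 1)
            s_obn = explain.grad_cam(runs["obn"].model, test_data.images[i], 1)
            try:
                base = explain.attention_index(s_abn, roi)
                prop = explain.attention_index(s_obn, roi)
            except ValueError:  # all-zero saliency: index undefined, skip pair
                continue
            ai_abn.append(base)
            ai_obn.append(prop)
            all_pairs.append(explain.IndexPair(
                sample_id=f"seed{seed}-{test_data.ids[i]}",
                baseline_index=base, proposed_index=prop))
    return {
        "pairs": all_pairs,
        "n_pairs": len(all_pairs),
        "mean_attention_index_obn": float(np.mean(ai_obn)),
        "mean_attention_index_abn": float(np.mean(ai_abn)),
        "improvement_ratio": explain.improvement_ratio(all_pairs),
        "auc_obn": float(np.mean(auc_obn)),
        "auc_abn": float(np.mean(auc_abn)),
    }
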