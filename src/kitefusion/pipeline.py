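"""Patient-level cross-validation and the training loops.

Fold construction is patient-level: every image of a patient lands in exactly
one fold, which is what prevents leakage between training and held-out data.
Stratified plans additionally keep the per-fold patient count of each class
within one of proportionality, assigning shuffled patients of each class to
the currently least-loaded fold (by image count) among the folds with the
fewest patients of that class.

Training follows the published recipe: AdamW, learning rate 1e-4, batch size
16, 40 epochs with a x0.1 learning-rate decay every 10 epochs; segmentation
optimizes the compound Dice-CE loss on per-pixel softmax probabilities, and
classification a soft-label cross entropy (which is what Mixup requires).
Augmentation ("M + kM" CarveMix or Mixup expansion plus flips/rotation) is
applied to training folds only and can be regenerated each epoch (fresh) or
frozen once per run.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import augmentation as aug
from . import metrics_stats as ms
from .imaging_io import SlicePair, clip_ct_hu, normalize_pet
from .losses import LossConfig, dice_ce
from .networks import FusionConfig, FusionModel, build_fusion_model
from .nn import AdamW, ConvBNReLU, Linear, Module, StepLR, Tensor
from .phantoms import SyntheticCohort

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "TrainResult",
    "ClassifierBackboneContract",
    "SmallConvClassifier",
    "build_classifier",
    "patient_kfold",
    "assert_no_leakage",
    "prepare_slice",
    "cohort_slices",
    "train_segmentation",
    "train_classification",
    "run_crossval",
    "run_scaling_experiment",
]


# --- fold construction --------------------------------------------------------


@dataclass
class FoldPlan:
    k: int
    assignments: dict  # patient_id -> fold index
    fold_counts: list  # per fold: {"patients": {label: n}, "images": {label: n}}

    def patients_in_fold(self, fold: int) -> list:
        return [p for p, f in self.assignments.items() if f == fold]


def patient_kfold(
    cohort: SyntheticCohort, k: int = 5, seed: int = 0, stratify: bool = True
) -> FoldPlan:
    """Assign whole patients to k folds, optionally stratified by class."""
    rng = np.random.default_rng(seed)
    info = [(pid, label, len(slices)) for pid, label, slices in cohort.patients]
    labels = sorted({label for _, label, _ in info})
    groups = (
        {lab: [p for p in info if p[1] == lab] for lab in labels}
        if stratify
        else {"all": list(info)}
    )
    if stratify:
        for lab, members in groups.items():
            if len(members) < k:
                raise ValueError(
                    f"stratified {k}-fold plan needs >= {k} patients per class; "
                    f"class {lab!r} has {len(members)}"
                )
    elif len(info) < k:
        raise ValueError(f"{k}-fold plan needs >= {k} patients, got {len(info)}")

    assignments = {}
    fold_counts = [
        {"patients": dict.fromkeys(labels, 0), "images": dict.fromkeys(labels, 0)}
        for _ in range(k)
    ]
    for members in groups.values():
        members = list(members)
        rng.shuffle(members)
        members.sort(key=lambda t: -t[2])  # big patients first, stable shuffle ties
        for pid, label, n_img in members:
            placed = [fold_counts[f]["patients"][label] for f in range(k)]
            candidates = [f for f in range(k) if placed[f] == min(placed)]
            f = min(candidates, key=lambda f: sum(fold_counts[f]["images"].values()))
            assignments[pid] = f
            fold_counts[f]["patients"][label] += 1
            fold_counts[f]["images"][label] += n_img
    return FoldPlan(k=k, assignments=assignments, fold_counts=fold_counts)


def assert_no_leakage(plan: FoldPlan, cohort: SyntheticCohort):
    """Every patient in exactly one fold; every slice follows its patient."""
    for pid, _, slices in cohort.patients:
        if pid not in plan.assignments:
            raise AssertionError(f"patient {pid} missing from the fold plan")
        for s in slices:
            if s.patient_id != pid:
                raise AssertionError(f"slice of {pid} carries id {s.patient_id}")
    folds = list(plan.assignments.values())
    if any(not 0 <= f < plan.k for f in folds):
        raise AssertionError("fold index out of range")


# --- data preparation ---------------------------------------------------------


def prepare_slice(pair: SlicePair) -> SlicePair:
    """Model-ready intensities: PET min-max to [0,1]; CT clipped to the
    [-150, 250] HU window then rescaled to [0,1]."""
    if pair.modality == "PET":
        img = normalize_pet(pair.image, "minmax")
    else:
        img = (clip_ct_hu(pair.image) + 150.0) / 400.0
    return pair.with_(image=img.astype(np.float32))


def cohort_slices(
    cohort: SyntheticCohort, modality: str = "PET", patients=None, preprocess=True
) -> list:
    """Flatten a cohort into single-modality SlicePairs, optionally restricted
    to a patient subset."""
    keep = None if patients is None else set(patients)
    out = []
    for pid, _, slices in cohort.patients:
        if keep is not None and pid not in keep:
            continue
        for s in slices:
            pet, ct = s.as_slice_pairs()
            pair = pet if modality == "PET" else ct
            out.append(prepare_slice(pair) if preprocess else pair)
    return out


# --- configuration ------------------------------------------------------------


@dataclass
class TrainConfig:
    """Published defaults; desk-scale runs shrink epochs/batch, not the recipe."""

    batch_size: int = 16
    lr: float = 1e-4
    epochs: int = 40
    lr_step: int = 10
    lr_gamma: float = 0.1
    weight_decay: float = 1e-2
    seed: int = 0
    task: str = "segmentation"
    loss: LossConfig = dc_field(default_factory=LossConfig)
    augment: dict = dc_field(default_factory=dict)
    # augment keys: carvemix_k / mixup_k (float), mixup_alpha, basic (bool),
    # rotation_deg, mode ('fresh' per epoch | 'frozen' once per run)

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.lr_step) <= 0 or self.lr <= 0:
            raise ValueError("batch_size, epochs, lr_step and lr must be positive")
        if self.epochs % self.lr_step:
            raise ValueError("lr schedule period must divide the epoch budget")
        if self.task not in ("segmentation", "classification"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class TrainResult:
    model: object
    history: dict
    best_epoch: int
    best_val: float
    best_state: dict


def _epoch_seed(seed: int, epoch: int) -> int:
    return int(np.random.SeedSequence([seed, epoch]).generate_state(1)[0] % (2**31))


# --- segmentation training ----------------------------------------------------


def _seg_batch(pairs):
    x = np.stack([p.image for p in pairs]).astype(np.float32)[:, None]
    m = np.stack([p.mask for p in pairs]).astype(np.float32)
    r = np.stack([1.0 - m, m], axis=1)
    return x, r


def _augmented_train_set(base, cfg: TrainConfig, epoch: int, task: str):
    a = cfg.augment
    k = a.get("carvemix_k" if task == "segmentation" else "mixup_k", 0.0)
    mode = a.get("mode", "fresh")
    seed = _epoch_seed(cfg.seed, 0 if mode == "frozen" else epoch)
    if k > 0:
        method = "carvemix" if task == "segmentation" else "mixup"
        expanded = aug.expand_dataset(
            base, k, method=method, seed=seed, mixup_alpha=a.get("mixup_alpha", 0.2)
        )
        samples = expanded.samples
    else:
        samples = list(base)
    if task == "segmentation" and a.get("basic", False):
        rng = np.random.default_rng(seed + 1)
        samples = [
            aug.basic_augment(s, rng, rotation_deg=a.get("rotation_deg", 15.0))
            for s in samples
        ]
    return samples


def evaluate_segmentation(model: FusionModel, val_pairs, threshold=0.5) -> dict:
    """Mean Dice/IoU/AHD of thresholded predictions over held-out slices."""
    probs = model.predict_proba(np.stack([p.image for p in val_pairs]))
    dices, ious, ahds = [], [], []
    for p, prob in zip(val_pairs, probs):
        pred = ms.binarize_probabilities(prob, threshold)
        pair = ms.BinaryMaskPair(pred, p.mask)
        dices.append(ms.dice_coefficient(pair))
        ious.append(ms.iou(pair))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ahds.append(ms.average_hausdorff(pair))
    return {
        "dice": float(np.mean(dices)),
        "iou": float(np.mean(ious)),
        "ahd_px": float(np.mean(ahds)),
    }


def train_segmentation(
    train_pairs: list,
    val_pairs: list,
    model: FusionModel | FusionConfig,
    cfg: TrainConfig,
) -> TrainResult:
    """Train the fusion (or single-branch) model; returns history and the
    best-validation-Dice checkpoint."""
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be nonempty")
    if isinstance(model, FusionConfig):
        model = build_fusion_model(model)
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = StepLR(opt, step_size=cfg.lr_step, gamma=cfg.lr_gamma)
    history = {"train_loss": [], "val_dice": [], "lr": []}
    best = (-1.0, -1, None)
    for epoch in range(cfg.epochs):
        history["lr"].append(opt.lr)
        samples = _augmented_train_set(train_pairs, cfg, epoch, "segmentation")
        order = rng.permutation(len(samples))
        losses = []
        model.train()
        for i in range(0, len(order), cfg.batch_size):
            batch = [samples[j] for j in order[i : i + cfg.batch_size]]
            x, r = _seg_batch(batch)
            out = model(Tensor(x))
            loss = dice_ce(out.probabilities, r, cfg.loss)
            loss.backward()
            opt.step()
            opt.zero_grad()
            losses.append(loss.item())
        sched.step()
        history["train_loss"].append(float(np.mean(losses)))
        val_dice = evaluate_segmentation(model, val_pairs)["dice"]
        history["val_dice"].append(val_dice)
        if val_dice > best[0]:
            best = (val_dice, epoch, copy.deepcopy(model.state_dict()))
    model.load_state_dict(best[2])
    model.eval()
    return TrainResult(
        model=model,
        history=history,
        best_epoch=best[1],
        best_val=best[0],
        best_state=best[2],
    )


# --- classification -----------------------------------------------------------


class SmallConvClassifier(Module):
    """Strided conv stages + global average pooling + linear head (2 logits)."""

    def __init__(self, channels=(8, 16, 32), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        c_in = 1
        self.stages = []
        for c in channels:
            self.stages.append(ConvBNReLU(c_in, c, stride=2, rng=rng))
            c_in = c
        self.fc = Linear(c_in, 2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        for stage in self.stages:
            x = stage(x)
        return self.fc(x.mean(axis=(2, 3)))


@dataclass
class ClassifierBackboneContract:
    """Pluggable image classifier mapping one grayscale image to 2 logits."""

    name: str
    model: Module

    def logits(self, x) -> Tensor:
        out = self.model(Tensor.as_tensor(x))
        if out.shape[-1] != 2:
            raise ValueError("backbone must output 2 logits")
        return out


def build_classifier(channels=(8, 16, 32), seed: int = 0) -> ClassifierBackboneContract:
    return ClassifierBackboneContract(
        name="small-conv-gap", model=SmallConvClassifier(channels, seed=seed)
    )


def classification_samples(slice_pairs: list) -> list:
    """(image, one-hot label, patient_id) triples; malignant is class index 1."""
    out = []
    for p in slice_pairs:
        if p.label is None:
            raise ValueError(f"slice of patient {p.patient_id} has no class label")
        y = np.array([0.0, 1.0]) if p.label == "malignant" else np.array([1.0, 0.0])
        out.append((p.image.astype(np.float32), y, p.patient_id))
    return out


def _soft_ce(logits: Tensor, y: np.ndarray) -> Tensor:
    probs = logits.softmax(axis=1)
    return -(Tensor(y) * probs.clamp_min(1e-12).log()).sum() * (1.0 / len(y))


def evaluate_classification(backbone: ClassifierBackboneContract, samples) -> dict:
    for m in backbone.model.modules():
        m.training = False
    x = np.stack([s[0] for s in samples])[:, None]
    logits = backbone.logits(x).data
    scores = logits[:, 1] - logits[:, 0]
    true = np.array(["malignant" if s[1][1] else "benign" for s in samples])
    pred = np.where(logits.argmax(axis=1) == 1, "malignant", "benign")
    out = {"acc": ms.accuracy(pred, true)}
    sens, spec = ms.sensitivity_specificity(pred, true)
    out["sensitivity"], out["specificity"] = sens, spec
    try:
        out["auc"] = ms.auc(scores, true)
    except ValueError:
        out["auc"] = float("nan")
    return out


def train_classification(
    train_samples: list,
    val_samples: list,
    backbone: ClassifierBackboneContract,
    cfg: TrainConfig,
) -> TrainResult:
    """Train a classifier on (image, one-hot, patient_id) samples with
    optional Mixup expansion; best-validation-accuracy checkpoint retained."""
    if not train_samples or not val_samples:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(backbone.model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = StepLR(opt, step_size=cfg.lr_step, gamma=cfg.lr_gamma)
    base = [(x, y) for x, y, _ in train_samples]
    history = {"train_loss": [], "val_acc": [], "lr": []}
    best = (-1.0, -1, None)
    for epoch in range(cfg.epochs):
        history["lr"].append(opt.lr)
        samples = _augmented_train_set(base, cfg, epoch, "classification")
        xy = [
            (s.image, s.soft_label) if isinstance(s, aug.MixupSample) else s
            for s in samples
        ]
        order = rng.permutation(len(xy))
        losses = []
        for m in backbone.model.modules():
            m.training = True
        for i in range(0, len(order), cfg.batch_size):
            batch = [xy[j] for j in order[i : i + cfg.batch_size]]
            x = np.stack([b[0] for b in batch]).astype(np.float32)[:, None]
            y = np.stack([b[1] for b in batch])
            loss = _soft_ce(backbone.logits(x), y)
            loss.backward()
            opt.step()
            opt.zero_grad()
            losses.append(loss.item())
        sched.step()
        history["train_loss"].append(float(np.mean(losses)))
        val_acc = evaluate_classification(backbone, val_samples)["acc"]
        history["val_acc"].append(val_acc)
        if val_acc > best[0]:
            best = (val_acc, epoch, copy.deepcopy(backbone.model.state_dict()))
    backbone.model.load_state_dict(best[2])
    return TrainResult(
        model=backbone,
        history=history,
        best_epoch=best[1],
        best_val=best[0],
        best_state=best[2],
    )


# --- cross-validation orchestration ------------------------------------------


def run_crossval(
    cohort: SyntheticCohort,
    plan: FoldPlan,
    cfg: TrainConfig,
    model_config: FusionConfig | None = None,
    classifier_channels=(8, 16, 32),
    modality: str = "PET",
    label: str = "model",
) -> ms.FoldResults:
    """One metric row per fold; training folds only ever see their own
    patients (asserted)."""
    assert_no_leakage(plan, cohort)
    metrics: dict = {}
    for fold in range(plan.k):
        val_patients = set(plan.patients_in_fold(fold))
        train_patients = [p for p in plan.assignments if p not in val_patients]
        train_slices = cohort_slices(cohort, modality, train_patients)
        val_slices = cohort_slices(cohort, modality, val_patients)
        if cfg.task == "segmentation":
            result = train_segmentation(train_slices, val_slices, model_config, cfg)
            fold_metrics = evaluate_segmentation(result.model, val_slices)
        else:
            backbone = build_classifier(classifier_channels, seed=cfg.seed + fold)
            result = train_classification(
                classification_samples(train_slices),
                classification_samples(val_slices),
                backbone,
                cfg,
            )
            fold_metrics = evaluate_classification(result.model,
                classification_samples(val_slices))
        for k, v in fold_metrics.items():
            metrics.setdefault(k, []).append(v)
    return ms.FoldResults(model=label, metrics=metrics)


def run_scaling_experiment(
    cohort: SyntheticCohort,
    plan: FoldPlan,
    cfg: TrainConfig,
    k_values=(1.0, 1.5, 2.0),
    method: str = "carvemix",
    model_config: FusionConfig | None = None,
) -> dict:
    """Baseline plus one aggregate column per expansion ratio k ("M + kM")."""
    key = "carvemix_k" if method == "carvemix" else "mixup_k"
    columns = {}
    for k in (0.0, *k_values):
        cfg_k = copy.deepcopy(cfg)
        cfg_k.augment = dict(cfg.augment, **{key: k})
        name = "baseline" if k == 0 else f"M+{k:g}M"
        results = run_crossval(
            cohort, plan, cfg_k, model_config=model_config, label=name
        )
        columns[name] = ms.fold_aggregate(results)
    return columns
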