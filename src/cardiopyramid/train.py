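"""Training loop, learning-rate schedule, evaluation and cross-validation.

Training uses Adam with a step-decay schedule: the learning rate starts at
``lr0`` and is multiplied by ``decay_factor`` every ``decay_every`` epochs
(the ECG configuration decays every 50 of 150 epochs, the PCG configuration
every 80 of 160; desk-scale defaults are much shorter).  The objective is
cross-entropy plus ``lambda_rec`` times the decoder's reconstruction loss.

Cross-validation is stratified at the *subject* level: all segments of one
recording stay in one fold, preventing window leakage between train and
test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .metrics import MetricReport, counts_from_predictions, evaluate_metrics
from .model import ModelConfig, MultiModalNet
from .preprocess import (
    FalsePeakConfig,
    NormalizationConfig,
    SegmentationConfig,
    WienerConfig,
    preprocess_record,
)
from .records import SegmentArchive, SignalRecord, is_positive
from .sstpnet import StftConfig, build_volume

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "VolumeDataset",
    "lr_at_epoch",
    "archives_from_pairs",
    "dataset_from_archives",
    "train_model",
    "evaluate_model",
    "subject_holdout_split",
    "stratified_subject_folds",
    "cross_validate",
]


@dataclass
class TrainConfig:
    lr0: float = 0.001
    decay_factor: float = 0.1
    decay_every: int = 50
    total_epochs: int = 20  # desk default; 150 (ECG) / 160 (PCG) at full scale
    batch_size: int = 16
    folds: int = 5
    repetitions: int = 10
    val_fraction: float = 0.25
    pretrain_epochs: int = 0  # optional reconstruction-only warm-up
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not 0 < self.decay_factor <= 1:
            raise ValueError("decay_factor must be in (0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @staticmethod
    def ecg_paper() -> "TrainConfig":
        return TrainConfig(lr0=0.001, decay_factor=0.1, decay_every=50, total_epochs=150)

    @staticmethod
    def pcg_paper() -> "TrainConfig":
        return TrainConfig(lr0=0.001, decay_factor=0.1, decay_every=80, total_epochs=160)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Piecewise-constant step decay: ``lr0 * decay_factor**floor(epoch/decay_every)``."""
    if not 0 <= epoch < cfg.total_epochs:
        raise ValueError(f"epoch {epoch} out of range [0, {cfg.total_epochs})")
    return cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_every)


# --------------------------------------------------------------------------- #
# dataset preparation                                                         #
# --------------------------------------------------------------------------- #

@dataclass
class VolumeDataset:
    """Aligned per-modality volume batches with integer labels and subjects."""

    volumes: dict[str, np.ndarray]  # modality -> (N, 1, H, W, B) float32
    labels: np.ndarray  # (N,) int
    label_names: list[str]
    subjects: np.ndarray  # (N,) record ids

    def __post_init__(self) -> None:
        n = self.labels.size
        for mod, v in self.volumes.items():
            if v.shape[0] != n:
                raise ValueError(f"{mod}: {v.shape[0]} volumes for {n} labels")

    @property
    def n(self) -> int:
        return int(self.labels.size)

    def subset(self, idx: np.ndarray) -> "VolumeDataset":
        return VolumeDataset(
            volumes={m: v[idx] for m, v in self.volumes.items()},
            labels=self.labels[idx],
            label_names=list(self.label_names),
            subjects=self.subjects[idx],
        )

    def batches(self, mods: tuple[str, ...]) -> dict[str, np.ndarray]:
        return {m: self.volumes[m] for m in mods}


def archives_from_pairs(
    pairs: list[tuple[SignalRecord, SignalRecord]],
    wiener: WienerConfig | None = None,
    fpe: FalsePeakConfig | None = None,
    seg: SegmentationConfig | None = None,
    norm: NormalizationConfig | None = None,
    apply_wiener: bool = True,
    apply_fpe: bool = True,
) -> dict[str, SegmentArchive]:
    """Preprocess paired (ECG, PCG) records into aligned per-modality archives."""
    per_mod: dict[str, list[SegmentArchive]] = {"ECG": [], "PCG": []}
    for ecg, pcg in pairs:
        for rec in (ecg, pcg):
            arc = preprocess_record(
                rec, wiener=wiener, fpe=fpe, seg=seg, norm=norm,
                apply_wiener=apply_wiener, apply_fpe=apply_fpe,
            )
            per_mod[rec.modality].append(arc)
    out = {m: SegmentArchive.concatenate(v) for m, v in per_mod.items() if v}
    if "ECG" in out and "PCG" in out and len(out["ECG"]) != len(out["PCG"]):
        raise ValueError("ECG and PCG archives are not aligned")
    return out


def dataset_from_archives(
    archives: dict[str, SegmentArchive],
    stft: StftConfig | None = None,
    binary: bool = True,
) -> VolumeDataset:
    """Build feature volumes and integer labels from aligned archives."""
    mods = list(archives)
    ref = archives[mods[0]]
    for m in mods[1:]:
        if [p[0] for p in archives[m].provenance] != [p[0] for p in ref.provenance]:
            raise ValueError("archives disagree on segment provenance")
    if binary:
        label_names = ["negative", "positive"]
        labels = np.array([1 if is_positive(l) else 0 for l in ref.labels], int)
    else:
        label_names = sorted(set(ref.labels), key=lambda l: (is_positive(l), l))
        lut = {l: i for i, l in enumerate(label_names)}
        labels = np.array([lut[l] for l in ref.labels], int)
    volumes = {}
    for m in mods:
        arc = archives[m]
        vols = [build_volume(s, arc.fs, stft, arc.window_s).values for s in arc.segments]
        volumes[m] = np.stack(vols).astype(np.float32)[:, None]
    return VolumeDataset(
        volumes=volumes,
        labels=labels,
        label_names=label_names,
        subjects=np.array([p[0] for p in ref.provenance]),
    )


# --------------------------------------------------------------------------- #
# training                                                                    #
# --------------------------------------------------------------------------- #

@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    best_val_accuracy: float | None = None
    best_epoch: int | None = None

    @property
    def losses(self) -> list[float]:
        return [e["loss"] for e in self.epochs]


def _predict_labels(model: MultiModalNet, ds: VolumeDataset, batch_size: int = 64) -> np.ndarray:
    preds = []
    for a in range(0, ds.n, batch_size):
        batch = {m: v[a : a + batch_size] for m, v in ds.volumes.items()}
        preds.append(np.argmax(model.predict_proba(batch), axis=1))
    return np.concatenate(preds) if preds else np.zeros(0, int)


def subject_holdout_split(
    subjects: np.ndarray, labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified subject-level holdout; returns (train_idx, holdout_idx).

    All segments of a subject land on one side of the split; per class,
    ``round(fraction * n_subjects)`` subjects (at least one when a class has
    more than one subject) go to the holdout side.
    """
    subj_label = {}
    for s, l in zip(subjects, labels):
        subj_label.setdefault(s, l)
    val_subjects = set()
    for cls in sorted(set(subj_label.values())):
        cls_subj = sorted(s for s, l in subj_label.items() if l == cls)
        k = max(int(round(fraction * len(cls_subj))), 1) if len(cls_subj) > 1 else 0
        val_subjects.update(rng.permutation(cls_subj)[:k])
    val_mask = np.isin(subjects, sorted(val_subjects))
    return np.where(~val_mask)[0], np.where(val_mask)[0]


def train_model(
    dataset: VolumeDataset,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    checkpoint_dir: str | Path | None = None,
) -> tuple[MultiModalNet, TrainHistory]:
    """Train the full pipeline network on a volume dataset.

    A stratified subject-level validation split (``val_fraction``) tracks the
    best validation accuracy; the best parameters are kept and written to
    ``checkpoint_dir`` when given.  Raises on an empty or single-class
    dataset and aborts with diagnostics on a non-finite loss.
    """
    model_cfg = model_cfg or ModelConfig.desk_scale()
    cfg = train_cfg or TrainConfig()
    if dataset.n == 0:
        raise ValueError("empty dataset")
    if len(set(dataset.labels.tolist())) < 2:
        raise ValueError("training requires at least 2 classes")

    rng = np.random.default_rng(cfg.seed)
    if cfg.val_fraction > 0:
        train_idx, val_idx = subject_holdout_split(dataset.subjects, dataset.labels, cfg.val_fraction, rng)
    else:
        train_idx, val_idx = np.arange(dataset.n), np.zeros(0, int)
    train_ds = dataset.subset(train_idx)
    val_ds = dataset.subset(val_idx) if val_idx.size else None

    model = MultiModalNet(model_cfg)
    opt = nn.Adam(model.parameters(), lr=cfg.lr0)
    history = TrainHistory()
    best_state: dict[str, np.ndarray] | None = None
    mods = model.cfg.modalities

    n_epochs = cfg.pretrain_epochs + cfg.total_epochs
    for epoch_all in range(n_epochs):
        pretraining = epoch_all < cfg.pretrain_epochs
        epoch = 0 if pretraining else epoch_all - cfg.pretrain_epochs
        opt.lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(train_ds.n)
        model.train()
        tot_loss = tot_ce = tot_rec = 0.0
        n_batches = 0
        for a in range(0, train_ds.n, cfg.batch_size):
            idx = order[a : a + cfg.batch_size]
            batch = {m: train_ds.volumes[m][idx] for m in mods}
            labels = train_ds.labels[idx]
            logits, recon, fused = model.forward(batch)
            loss, ce, rec = model.loss(logits, recon, fused, labels)
            if pretraining and rec is not None:
                loss = rec
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch_all}, batch {n_batches} "
                    f"(lr={opt.lr:g})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot_loss += float(loss.data)
            tot_ce += float(ce.data)
            tot_rec += float(rec.data) if rec is not None else 0.0
            n_batches += 1
            del logits, recon, fused, loss, ce, rec  # release the tape promptly

        entry = {
            "epoch": epoch_all,
            "pretrain": pretraining,
            "lr": opt.lr,
            "loss": tot_loss / n_batches,
            "ce": tot_ce / n_batches,
            "rec": tot_rec / n_batches,
        }
        if val_ds is not None:
            pred = _predict_labels(model, val_ds)
            acc = float(np.mean(pred == val_ds.labels))
            entry["val_accuracy"] = acc
            if history.best_val_accuracy is None or acc > history.best_val_accuracy:
                history.best_val_accuracy = acc
                history.best_epoch = epoch_all
                best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        history.epochs.append(entry)
        log.info(
            "epoch %d/%d loss=%.4f%s", epoch_all + 1, n_epochs, entry["loss"],
            f" val_acc={entry.get('val_accuracy', float('nan')):.3f}" if val_ds is not None else "",
        )

    if best_state is not None:
        model.load_state_arrays(best_state)
    if checkpoint_dir is not None:
        out = Path(checkpoint_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "model.npz", **model.state_arrays())
        (out / "history.json").write_text(json.dumps(
            {"epochs": history.epochs, "best_val_accuracy": history.best_val_accuracy,
             "best_epoch": history.best_epoch, "train_config": asdict(cfg)}, indent=2))
    return model, history


def evaluate_model(model: MultiModalNet, dataset: VolumeDataset) -> MetricReport:
    """Binary metric report on a dataset (class 1 = positive)."""
    pred = _predict_labels(model, dataset)
    if len(dataset.label_names) > 2:
        pos_idx = [i for i, l in enumerate(dataset.label_names) if l != "negative"]
        y_true = np.isin(dataset.labels, pos_idx).astype(int)
        y_pred = np.isin(pred, pos_idx).astype(int)
    else:
        y_true, y_pred = dataset.labels, pred
    return evaluate_metrics(counts_from_predictions(y_true, y_pred))


# --------------------------------------------------------------------------- #
# cross-validation                                                            #
# --------------------------------------------------------------------------- #

def stratified_subject_folds(
    subjects: np.ndarray,
    labels: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Partition segment indices into k subject-level, class-stratified folds.

    All segments of one subject land in exactly one fold; per class the
    subject counts across folds differ by at most 1.
    """
    subj_label: dict[str, int] = {}
    for s, l in zip(subjects, labels):
        subj_label.setdefault(str(s), int(l))
    classes = sorted(set(subj_label.values()))
    min_count = min(sum(1 for v in subj_label.values() if v == c) for c in classes)
    if k > min_count:
        raise ValueError(f"folds={k} exceeds the smallest class subject count {min_count}")
    fold_subjects: list[set] = [set() for _ in range(k)]
    for cls in classes:
        cls_subj = rng.permutation(sorted(s for s, l in subj_label.items() if l == cls))
        for i, s in enumerate(cls_subj):
            fold_subjects[i % k].add(s)
    return [np.where(np.isin(subjects, sorted(fs)))[0] for fs in fold_subjects]


def cross_validate(
    dataset: VolumeDataset,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    repetitions: int | None = None,
) -> tuple[list[MetricReport], dict]:
    """Repeated stratified subject-level k-fold cross-validation.

    Returns per-fold reports and an aggregate (mean, sd over folds x reps)
    for each defined metric.
    """
    cfg = train_cfg or TrainConfig()
    reps = cfg.repetitions if repetitions is None else repetitions
    reports: list[MetricReport] = []
    for r in range(reps):
        rng = np.random.default_rng([cfg.seed, r])
        folds = stratified_subject_folds(dataset.subjects, dataset.labels, cfg.folds, rng)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(dataset.n), test_idx)
            fold_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed + 1000 * r + f,
                                      "val_fraction": 0.0})
            model, _ = train_model(dataset.subset(train_idx), model_cfg, fold_cfg)
            reports.append(evaluate_model(model, dataset.subset(test_idx)))
    agg = {}
    for key in ("standard_accuracy", "precision", "recall", "f1", "standard_specificity"):
        vals = [getattr(rep, key) for rep in reports if getattr(rep, key) is not None]
        if vals:
            agg[key] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
    return reports, agg
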