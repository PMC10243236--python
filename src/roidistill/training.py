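"""Three-stage training orchestration.

Stage 1 trains a *teacher* on ROI-annotated images with plain
cross-entropy; its weights are then frozen.  Stage 2 trains a *student* on
raw images under the combined loss: each batch pairs the raw image (fed to
the student) with its ROI counterpart (fed to the frozen teacher) under
shared augmentation draws, and the consistency weight decays linearly per
epoch.  Stage 3 is the tail of the same student run with the weight at 0 —
plain fine-tuning on raw images, during which the teacher is never
evaluated.  A *baseline* is the identical pipeline trained end-to-end on
raw images only.

Model selection follows the lowest validation loss (for students: the CE
component only, computed on raw validation images — the consistency term
depends on the epoch weight and would make epochs incomparable).

Also provided: the four dropout/augmentation configurations, seeded
repeats with mean ± std summaries, the reduced-annotation experiment and
the raw-teacher ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data import AugmentationSpec, build_augmentation, preprocess_batch
from .distill import DistillationSchedule, alpha_weight, combined_loss_grads
from .evaluation import EvaluationReport, evaluate
from .models import FeatureClassifier, ModelConfig, build_model, feature_shape, freeze
from .synthetic import GeneratorConfig, generate_dataset

#: the four dropout/augmentation configurations for baseline and student
#: models; teachers always keep dropout on.
CONFIGURATIONS = {
    1: {"dropout": True, "augmentation": "strong"},
    2: {"dropout": False, "augmentation": "strong"},
    3: {"dropout": True, "augmentation": "weak"},
    4: {"dropout": False, "augmentation": "weak"},
}


@dataclass(frozen=True)
class TrainConfig:
    stage: str = "baseline"              # baseline | teacher | student
    model: ModelConfig = field(default_factory=ModelConfig)
    schedule: DistillationSchedule | None = None
    epochs: int = 60
    batch_size: int = 8
    base_lr: float = 1e-4
    augmentation: str = "strong"
    seed: int = 0
    configuration_id: int | None = None
    target_size: int | None = None       # None: native image size

    def __post_init__(self):
        if self.stage not in ("baseline", "teacher", "student"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "teacher" and not self.model.dropout:
            raise ValueError("teacher models always train with dropout on")
        if self.configuration_id is not None and self.configuration_id not in CONFIGURATIONS:
            raise ValueError("configuration_id must be 1..4")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_accuracy: float
    alpha: float | None = None
    train_mse: float | None = None
    train_ce: float | None = None


@dataclass
class RunResult:
    history: list
    selected_epoch: int
    validation_metrics: EvaluationReport
    seed: int
    model: FeatureClassifier = field(repr=False, default=None)

    @property
    def alphas(self) -> list:
        return [r.alpha for r in self.history]


@dataclass
class ArrayDataset:
    """In-memory paired dataset used by the trainers."""

    raw: np.ndarray                       # (N, H, W, 3) uint8
    roi: np.ndarray | None
    labels: np.ndarray                    # (N,) int
    patient_ids: list
    lesion_masks: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_samples(cls, samples) -> "ArrayDataset":
        return cls(
            raw=np.stack([s.raw_image for s in samples]),
            roi=np.stack([s.roi_image for s in samples]),
            labels=np.array([s.label for s in samples], dtype=np.int64),
            patient_ids=[s.patient_id for s in samples],
            lesion_masks=np.stack([s.lesion_mask for s in samples]),
        )

    @classmethod
    def from_records(cls, records) -> "ArrayDataset":
        from .data import load_image

        return cls(
            raw=np.stack([load_image(r.raw_path) for r in records]),
            roi=np.stack([load_image(r.roi_path) for r in records]),
            labels=np.array([r.label for r in records], dtype=np.int64),
            patient_ids=[r.patient_id for r in records],
        )

    def subset(self, idx) -> "ArrayDataset":
        idx = np.asarray(idx)
        return ArrayDataset(
            raw=self.raw[idx],
            roi=None if self.roi is None else self.roi[idx],
            labels=self.labels[idx],
            patient_ids=[self.patient_ids[i] for i in idx],
            lesion_masks=None if self.lesion_masks is None else self.lesion_masks[idx],
        )


def split_dataset(samples, val_fraction: float = 0.2, seed: int = 0):
    """Patient-level split of generator samples into two ArrayDatasets."""
    from .data import patient_level_split

    split = patient_level_split(samples, val_fraction=val_fraction, seed=seed)
    ids = {id(s): i for i, s in enumerate(samples)}
    tr = [ids[id(s)] for s in split.train]
    va = [ids[id(s)] for s in split.validation]
    ds = ArrayDataset.from_samples(samples)
    return ds.subset(tr), ds.subset(va)


def select_best_epoch(run) -> int:
    """Index of the epoch with the lowest validation loss (earliest tie)."""
    history = run.history if isinstance(run, RunResult) else list(run)
    if not history:
        raise ValueError("empty epoch history")
    losses = [r.val_loss if isinstance(r, EpochRecord) else float(r) for r in history]
    return int(np.argmin(losses))


def _validation_pass(model: FeatureClassifier, val_x: np.ndarray,
                     val_y: np.ndarray, batch_size: int = 64):
    """CE loss and accuracy on the validation tensor, inference mode."""
    losses, correct = [], 0
    for i in range(0, len(val_x), batch_size):
        xb, yb = val_x[i:i + batch_size], val_y[i:i + batch_size]
        logits, _ = model.forward(xb, train=False)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(val_x)), 100.0 * correct / len(val_x)


def _fit(model: FeatureClassifier, train_ds: ArrayDataset, val_ds: ArrayDataset,
         *, epochs: int, batch_size: int, base_lr: float,
         transform, student_input: str, seed: int,
         teacher: FeatureClassifier | None = None,
         schedule: DistillationSchedule | None = None,
         teacher_input: str = "roi",
         consistency_available: np.ndarray | None = None) -> RunResult:
    """Shared training loop for all three stages.

    ``student_input`` selects which image variant feeds the trained model;
    when ``teacher`` and ``schedule`` are given, epochs below the
    schedule's distillation horizon add the feature-consistency term, with
    the teacher fed ``teacher_input`` images augmented with the *same*
    sampled parameters as the trained model's input.
    """
    n = len(train_ds)
    rng = np.random.default_rng(seed)
    shuffle_rng = np.random.default_rng(rng.integers(2**31))
    aug_rng = np.random.default_rng(rng.integers(2**31))

    train_imgs = train_ds.raw if student_input == "raw" else train_ds.roi
    val_imgs = val_ds.raw if student_input == "raw" else val_ds.roi
    if train_imgs is None or val_imgs is None:
        raise ValueError(f"dataset provides no {student_input!r} images")
    teacher_imgs = None
    if teacher is not None and schedule is not None:
        if not teacher.frozen:
            raise ValueError("the teacher must be frozen before student training")
        teacher_imgs = train_ds.raw if teacher_input == "raw" else train_ds.roi
        if teacher_imgs is None:
            raise ValueError(f"dataset provides no {teacher_input!r} teacher images")
        size = transform.spec.target_size
        if feature_shape(teacher, size) != feature_shape(model, size):
            raise ValueError(
                f"teacher feature map {feature_shape(teacher, size)} does not "
                f"match student feature map {feature_shape(model, size)}"
            )

    val_x = preprocess_batch(val_imgs, transform.spec.target_size)
    val_y = val_ds.labels

    optimizer = nn.Adam(model.params(), model.grads(), lr=base_lr)
    history: list[EpochRecord] = []
    best_loss, best_state, best_epoch = np.inf, None, 0

    for e in range(epochs):
        optimizer.lr = nn.cosine_lr(base_lr, e, epochs)
        alpha = (alpha_weight(e, schedule)
                 if teacher is not None and schedule is not None else None)
        perm = shuffle_rng.permutation(n)
        tot_loss = tot_mse = tot_ce = 0.0
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            xb = np.empty((len(idx), 3, transform.spec.target_size,
                           transform.spec.target_size), dtype=np.float32)
            tb = np.empty_like(xb) if alpha is not None and alpha > 0 else None
            for j, i in enumerate(idx):
                params = transform.sample_params(aug_rng)
                xb[j] = transform.apply(train_imgs[i], params)
                if tb is not None:
                    tb[j] = transform.apply(teacher_imgs[i], params)
            yb = train_ds.labels[idx]

            logits, fmap = model.forward(xb, train=True)
            if tb is not None:
                _, t_fmap = teacher.forward(tb, train=False)
                mask = (consistency_available[idx]
                        if consistency_available is not None else None)
                breakdown, dlogits, dmap = combined_loss_grads(
                    t_fmap, logits, fmap, yb, alpha, consistency_mask=mask)
                tot_mse += breakdown.consistency_mse * len(idx)
                tot_ce += breakdown.classification_ce * len(idx)
                loss = breakdown.total
            else:
                loss, dlogits = nn.softmax_cross_entropy(logits, yb)
                dmap = None
                tot_ce += loss * len(idx)
            tot_loss += loss * len(idx)
            model.backward(dlogits, dmap)
            optimizer.step()
            optimizer.zero_grad()

        val_loss, val_acc = _validation_pass(model, val_x, val_y)
        history.append(EpochRecord(
            epoch=e, train_loss=tot_loss / n, val_loss=val_loss,
            val_accuracy=val_acc, alpha=alpha,
            train_mse=(tot_mse / n) if alpha is not None else None,
            train_ce=tot_ce / n,
        ))
        if val_loss < best_loss:
            best_loss, best_state, best_epoch = val_loss, model.state(), e

    model.load_state(best_state)
    metrics = evaluate(model, val_x, val_y)
    return RunResult(history=history, selected_epoch=best_epoch,
                     validation_metrics=metrics, seed=seed, model=model)


def _make_transform(config: TrainConfig, dataset: ArrayDataset):
    size = config.target_size if config.target_size is not None else dataset.raw.shape[1]
    spec = (AugmentationSpec.strong(size) if config.augmentation == "strong"
            else AugmentationSpec.weak(size))
    return build_augmentation(spec)


def train_teacher(config: TrainConfig, train_ds: ArrayDataset,
                  val_ds: ArrayDataset, input_variant: str = "roi") -> RunResult:
    """Stage 1: CE training on the annotated (ROI) image variant.

    The returned model is frozen.  ``input_variant="raw"`` runs the
    raw-teacher ablation arm instead.
    """
    if input_variant == "roi" and train_ds.roi is None:
        raise ValueError("teacher training requires ROI images")
    model = build_model(config.model, seed=config.seed)
    result = _fit(model, train_ds, val_ds, epochs=config.epochs,
                  batch_size=config.batch_size, base_lr=config.base_lr,
                  transform=_make_transform(config, train_ds),
                  student_input=input_variant, seed=config.seed)
    freeze(result.model)
    return result


def train_baseline(config: TrainConfig, train_ds: ArrayDataset,
                   val_ds: ArrayDataset) -> RunResult:
    """Reference arm: CE-only end-to-end training on raw images."""
    model = build_model(config.model, seed=config.seed)
    return _fit(model, train_ds, val_ds, epochs=config.epochs,
                batch_size=config.batch_size, base_lr=config.base_lr,
                transform=_make_transform(config, train_ds),
                student_input="raw", seed=config.seed)


def train_student(config: TrainConfig, train_ds: ArrayDataset,
                  val_ds: ArrayDataset, teacher: FeatureClassifier | None,
                  teacher_input: str = "roi",
                  consistency_available: np.ndarray | None = None) -> RunResult:
    """Stages 2 + 3: raw-image training guided by a frozen teacher.

    With ``teacher=None`` (and no schedule) the run degenerates to the
    baseline path — the documented escape hatch for a zero-length
    distillation phase.  ``consistency_available`` marks which training
    samples have ROI variants when annotations are partial.
    """
    if teacher is None and config.schedule is not None:
        raise ValueError("a schedule was given but no teacher")
    if teacher is not None and config.schedule is None:
        raise ValueError("student training with a teacher requires a schedule")
    model = build_model(config.model, seed=config.seed)
    return _fit(model, train_ds, val_ds, epochs=config.epochs,
                batch_size=config.batch_size, base_lr=config.base_lr,
                transform=_make_transform(config, train_ds),
                student_input="raw", seed=config.seed, teacher=teacher,
                schedule=config.schedule, teacher_input=teacher_input,
                consistency_available=consistency_available)


# ---------------------------------------------------------------------------
# experiment harnesses
# ---------------------------------------------------------------------------

#: desk-scale study conditions for the synthetic benchmark: ~1880 images
#: from 940 patients (some contributing several images), 64x64 pixels
BENCHMARK_GENERATOR = GeneratorConfig(n_patients=940, images_per_patient=2)

#: epoch budgets scaled for single-CPU runs (teacher converges fastest,
#: mirroring the 20/60/60 ratio of the full-scale protocol)
BENCHMARK_EPOCHS = {"teacher": 8, "total": 20, "distill": 12}

#: Adam base LR for the from-scratch tiny nets of the benchmark
BENCHMARK_LR = 2e-3


@dataclass
class ExperimentSummary:
    """Mean ± std accuracy per arm over seeded repeats, plus the
    student-minus-baseline improvement in percentage points."""

    arm_accuracies: dict                 # arm name -> list of accuracies (%)
    n_repeats: int
    configuration_id: int | None = None

    def mean(self, arm: str) -> float:
        return float(np.mean(self.arm_accuracies[arm]))

    def std(self, arm: str) -> float:
        vals = self.arm_accuracies[arm]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def improvement_pp(self) -> float:
        return self.mean("student") - self.mean("baseline")

    def table(self) -> str:
        lines = ["arm\tmean_accuracy\tstd"]
        for arm in self.arm_accuracies:
            lines.append(f"{arm}\t{self.mean(arm):.2f}\t{self.std(arm):.2f}")
        if "student" in self.arm_accuracies and "baseline" in self.arm_accuracies:
            lines.append(f"improvement_pp\t{self.improvement_pp:+.2f}\t")
        return "\n".join(lines)


def _benchmark_configs(configuration_id: int, seed: int,
                       teacher_epochs: int, total_epochs: int, e_distill: int,
                       base_lr: float):
    conf = CONFIGURATIONS[configuration_id]
    schedule = DistillationSchedule(e_distill=e_distill, e_total=total_epochs)
    teacher_cfg = TrainConfig(
        stage="teacher", model=ModelConfig(dropout=True),
        epochs=teacher_epochs, base_lr=base_lr,
        augmentation=conf["augmentation"], seed=seed,
        configuration_id=configuration_id)
    train_cfg = TrainConfig(
        stage="baseline", model=ModelConfig(dropout=conf["dropout"]),
        epochs=total_epochs, base_lr=base_lr,
        augmentation=conf["augmentation"], seed=seed,
        configuration_id=configuration_id)
    student_cfg = TrainConfig(
        stage="student", model=ModelConfig(dropout=conf["dropout"]),
        schedule=schedule, epochs=total_epochs, base_lr=base_lr,
        augmentation=conf["augmentation"], seed=seed,
        configuration_id=configuration_id)
    return teacher_cfg, train_cfg, student_cfg


def run_single_seed(seed: int, configuration_id: int = 3,
                    generator: GeneratorConfig | None = None,
                    arms=("teacher", "baseline", "student"),
                    teacher_epochs: int | None = None,
                    total_epochs: int | None = None,
                    e_distill: int | None = None,
                    base_lr: float = BENCHMARK_LR,
                    val_fraction: float = 0.2) -> dict:
    """Generate one seeded benchmark dataset and train the requested arms.

    Supported arms: ``teacher`` (ROI), ``teacher_raw``, ``baseline``,
    ``student`` (ROI teacher), ``student_raw_teacher``.  Returns a dict of
    arm name -> RunResult, plus the datasets under ``_train``/``_val``.
    """
    from dataclasses import replace

    generator = generator or replace(BENCHMARK_GENERATOR, seed=seed)
    teacher_epochs = teacher_epochs or BENCHMARK_EPOCHS["teacher"]
    total_epochs = total_epochs or BENCHMARK_EPOCHS["total"]
    e_distill = e_distill or BENCHMARK_EPOCHS["distill"]

    samples, _ = generate_dataset(generator)
    train_ds, val_ds = split_dataset(samples, val_fraction=val_fraction, seed=seed)
    t_cfg, b_cfg, s_cfg = _benchmark_configs(
        configuration_id, seed, teacher_epochs, total_epochs, e_distill, base_lr)

    out: dict = {"_train": train_ds, "_val": val_ds}
    if "teacher" in arms or "student" in arms:
        out["teacher"] = train_teacher(t_cfg, train_ds, val_ds, input_variant="roi")
    if "teacher_raw" in arms or "student_raw_teacher" in arms:
        out["teacher_raw"] = train_teacher(t_cfg, train_ds, val_ds, input_variant="raw")
    if "baseline" in arms:
        out["baseline"] = train_baseline(b_cfg, train_ds, val_ds)
    if "student" in arms:
        out["student"] = train_student(s_cfg, train_ds, val_ds, out["teacher"].model)
    if "student_raw_teacher" in arms:
        out["student_raw_teacher"] = train_student(
            s_cfg, train_ds, val_ds, out["teacher_raw"].model, teacher_input="raw")
    return out


def run_experiment(configuration_id: int = 3,
                   architectures=("tiny_reference",),
                   n_repeats: int = 5, seeds=None,
                   arms=("teacher", "baseline", "student"),
                   **kwargs) -> dict:
    """Seeded repeats of the benchmark for each architecture.

    Returns architecture -> :class:`ExperimentSummary`.
    """
    if configuration_id not in CONFIGURATIONS:
        raise ValueError("configuration_id must be 1..4")
    seeds = list(seeds) if seeds is not None else list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("len(seeds) must equal n_repeats")
    summaries = {}
    for arch in architectures:
        if arch != "tiny_reference":
            # surfaces the pretrained-weights error early
            build_model(ModelConfig(architecture=arch))
        accs: dict = {arm: [] for arm in arms}
        for seed in seeds:
            results = run_single_seed(seed, configuration_id, arms=arms, **kwargs)
            for arm in arms:
                accs[arm].append(results[arm].validation_metrics.overall_accuracy)
        summaries[arch] = ExperimentSummary(
            arm_accuracies=accs, n_repeats=n_repeats,
            configuration_id=configuration_id)
    return summaries


def roi_fraction_experiment(fractions=(0.1, 0.3, 0.5, 1.0), seeds=(0,),
                            configuration_id: int = 3, **kwargs):
    """Teacher/student accuracy when only a fraction of images carry ROIs.

    The ROI subset is sampled at random (seeded).  Batches mix annotated
    and unannotated samples; the consistency term is restricted to the
    annotated members, so every image still contributes to training.
    Returns fraction -> {"teacher": [...], "student": [...]} accuracies.
    """
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
    results: dict = {}
    for frac in fractions:
        accs = {"teacher": [], "student": []}
        for seed in seeds:
            from dataclasses import replace as _replace

            generator = kwargs.get("generator") or _replace(
                BENCHMARK_GENERATOR, seed=seed)
            samples, _ = generate_dataset(generator)
            train_ds, val_ds = split_dataset(samples, seed=seed)
            rng = np.random.default_rng(seed)
            n_annot = int(round(frac * len(train_ds)))
            annotated = np.zeros(len(train_ds), dtype=bool)
            annotated[rng.choice(len(train_ds), size=n_annot, replace=False)] = True
            for c in range(1, 5):
                if (train_ds.labels[annotated] == c).sum() < 1 and (train_ds.labels == c).any():
                    raise ValueError(
                        f"fraction {frac} leaves no annotated image for class {c}")
            t_cfg, _, s_cfg = _benchmark_configs(
                configuration_id, seed,
                kwargs.get("teacher_epochs") or BENCHMARK_EPOCHS["teacher"],
                kwargs.get("total_epochs") or BENCHMARK_EPOCHS["total"],
                kwargs.get("e_distill") or BENCHMARK_EPOCHS["distill"],
                kwargs.get("base_lr", BENCHMARK_LR))
            teacher_run = train_teacher(t_cfg, train_ds.subset(np.where(annotated)[0]),
                                        val_ds, input_variant="roi")
            student_run = train_student(s_cfg, train_ds, val_ds, teacher_run.model,
                                        consistency_available=annotated)
            accs["teacher"].append(teacher_run.validation_metrics.overall_accuracy)
            accs["student"].append(student_run.validation_metrics.overall_accuracy)
        results[frac] = accs
    return results


def raw_teacher_ablation(seeds=(0,), configuration_id: int = 3, **kwargs) -> dict:
    """Baseline vs student(ROI teacher) vs student(raw teacher).

    The raw-teacher arm runs the identical pipeline with the teacher fed
    raw images in both its own training and the consistency stage; returns
    per-arm accuracy lists plus the change in percentage points between
    the two student variants.
    """
    arms = ("teacher", "teacher_raw", "baseline", "student", "student_raw_teacher")
    accs: dict = {arm: [] for arm in arms}
    for seed in seeds:
        results = run_single_seed(seed, configuration_id, arms=arms, **kwargs)
        for arm in arms:
            accs[arm].append(results[arm].validation_metrics.overall_accuracy)
    accs["change_pp"] = float(np.mean(accs["student"]) -
                              np.mean(accs["student_raw_teacher"]))
    return accs
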