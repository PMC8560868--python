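"""The 20 benchmark method configurations, subject-level CV, and rank aggregation.

A *method* is one cell of the study grid: task (which normal-control cohort) x
input domain (spatial vs DCT) x augmentation mode x fold count.  Sixteen
methods cover the AD/NC(SPECT)/PD task across domains and augmentations; four
un-augmented methods cover AD/NC(PET)/PD.  Each method is scored by five
confusion-matrix metrics; methods are compared by dense-ranking each metric
column, summing the five ranks into an overall score, and dense-ranking the
scores (lower = better).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import cnn
from .augmentation import AugmentationConfig, AugmentationMode, build_training_set
from .cohort import ClassLabel, Split, SubjectRecord
from .metrics import ConfusionMatrix, metric_row
from .preprocessing import Domain, to_model_input

__all__ = [
    "Task",
    "MethodConfig",
    "SplitPlan",
    "RunResult",
    "enumerate_methods",
    "make_split",
    "run_method",
    "dense_rank",
    "aggregate_ranking",
    "DEFAULT_TEST_COUNTS",
    "SplitError",
    "AggregationError",
]


class Task(str, Enum):
    AD_NCSPECT_PD = "AD_NCSPECT_PD"
    AD_NCPET_PD = "AD_NCPET_PD"

    @property
    def classes(self) -> tuple[ClassLabel, ClassLabel, ClassLabel]:
        nc = ClassLabel.NC_SPECT if self is Task.AD_NCSPECT_PD else ClassLabel.NC_PET
        return (ClassLabel.AD, nc, ClassLabel.PD)


class SplitError(ValueError):
    """Cohort cannot satisfy the requested split."""


class AggregationError(ValueError):
    """Metric table incomplete or invalid for rank aggregation."""


@dataclass(frozen=True)
class MethodConfig:
    method_id: int
    task: Task
    domain: Domain
    augmentation: AugmentationMode
    folds: int

    def __post_init__(self) -> None:
        if self.folds not in (5, 10):
            raise ValueError(f"folds must be 5 or 10, got {self.folds}")


# the benchmark grid, in serial order
_METHOD_TABLE: tuple[tuple[Task, Domain, AugmentationMode, int], ...] = (
    (Task.AD_NCSPECT_PD, Domain.SPATIAL, AugmentationMode.BLUR, 5),
    (Task.AD_NCSPECT_PD, Domain.SPATIAL, AugmentationMode.BLUR, 10),
    (Task.AD_NCSPECT_PD, Domain.SPATIAL, AugmentationMode.COMBINED, 10),
    (Task.AD_NCSPECT_PD, Domain.FREQUENCY, AugmentationMode.ZOOM, 5),
    (Task.AD_NCSPECT_PD, Domain.FREQUENCY, AugmentationMode.COMBINED, 10),
    (Task.AD_NCSPECT_PD, Domain.SPATIAL, AugmentationMode.ZOOM, 5),
    (Task.AD_NCSPECT_PD, Domain.FREQUENCY, AugmentationMode.BLUR, 5),
    (Task.AD_NCSPECT_PD, Domain.SPATIAL, AugmentationMode.COMBINED, 5),
    (Task.AD_NCSPECT_PD, Domain.SPATIAL, AugmentationMode.ZOOM, 10),
    (Task.AD_NCSPECT_PD, Domain.FREQUENCY, AugmentationMode.COMBINED, 5),
    (Task.AD_NCSPECT_PD, Domain.FREQUENCY, AugmentationMode.NONE, 5),
    (Task.AD_NCSPECT_PD, Domain.FREQUENCY, AugmentationMode.NONE, 10),
    (Task.AD_NCSPECT_PD, Domain.SPATIAL, AugmentationMode.NONE, 5),
    (Task.AD_NCSPECT_PD, Domain.FREQUENCY, AugmentationMode.BLUR, 10),
    (Task.AD_NCSPECT_PD, Domain.FREQUENCY, AugmentationMode.ZOOM, 10),
    (Task.AD_NCSPECT_PD, Domain.SPATIAL, AugmentationMode.NONE, 10),
    (Task.AD_NCPET_PD, Domain.SPATIAL, AugmentationMode.NONE, 5),
    (Task.AD_NCPET_PD, Domain.SPATIAL, AugmentationMode.NONE, 10),
    (Task.AD_NCPET_PD, Domain.FREQUENCY, AugmentationMode.NONE, 5),
    (Task.AD_NCPET_PD, Domain.FREQUENCY, AugmentationMode.NONE, 10),
)


def enumerate_methods() -> list[MethodConfig]:
    """The 20 benchmark configurations in serial order."""
    return [
        MethodConfig(i, task, domain, aug, folds)
        for i, (task, domain, aug, folds) in enumerate(_METHOD_TABLE, start=1)
    ]


# ---------------------------------------------------------------------------
# subject-level splitting
# ---------------------------------------------------------------------------

#: held-out test-subset composition of the study
DEFAULT_TEST_COUNTS: dict[ClassLabel, int] = {
    ClassLabel.NC_SPECT: 4,
    ClassLabel.PD: 9,
    ClassLabel.AD: 4,
    ClassLabel.NC_PET: 12,
}


@dataclass(frozen=True)
class SplitPlan:
    """Subject-level partition: a fixed held-out test set plus k CV folds.

    Every selected subject is in exactly one fold or the test set; subjects
    dropped by class balancing appear in neither.
    """

    fold_assignment: dict[str, int]
    test_ids: frozenset[str]
    folds: int
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(sid for sid, f in self.fold_assignment.items() if f == fold)


def make_split(
    records: list[SubjectRecord],
    folds: int,
    test_counts: dict[ClassLabel, int] | None = None,
    seed: int = 0,
) -> SplitPlan:
    """Draw the held-out test subjects first, balance the remainder by random
    undersampling to the smallest class, then partition into subject-level
    folds with per-fold class counts differing by at most 1."""
    if test_counts is None:
        test_counts = DEFAULT_TEST_COUNTS
    rng = np.random.default_rng(seed)
    by_label: dict[ClassLabel, list[str]] = {}
    for rec in records:
        by_label.setdefault(rec.label, []).append(rec.subject_id)
    test_ids: set[str] = set()
    remaining: dict[ClassLabel, list[str]] = {}
    for label, ids in sorted(by_label.items(), key=lambda kv: kv[0].value):
        ids = sorted(ids)
        want = test_counts.get(label, 0)
        if len(ids) <= want:
            raise SplitError(
                f"class {label.value} has {len(ids)} subjects; "
                f"needs more than {want} for the test draw"
            )
        chosen = rng.choice(len(ids), size=want, replace=False) if want else []
        chosen = set(int(i) for i in np.atleast_1d(chosen))
        test_ids |= {ids[i] for i in chosen}
        remaining[label] = [s for i, s in enumerate(ids) if i not in chosen]
    smallest = min(len(v) for v in remaining.values())
    if smallest < folds:
        raise SplitError(
            f"smallest class has {smallest} non-test subjects; cannot form {folds} folds"
        )
    fold_assignment: dict[str, int] = {}
    for label, ids in sorted(remaining.items(), key=lambda kv: kv[0].value):
        keep = rng.choice(len(ids), size=smallest, replace=False)
        kept = [ids[int(i)] for i in keep]
        rng.shuffle(kept)
        for pos, sid in enumerate(kept):  # round-robin keeps folds balanced
            fold_assignment[sid] = pos % folds
    return SplitPlan(fold_assignment, frozenset(test_ids), folds, seed)


# ---------------------------------------------------------------------------
# one full cross-validated experiment
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: MethodConfig
    confusion: ConfusionMatrix
    metrics: pd.Series
    split: SplitPlan
    fold_logs: list[list[dict]] = field(default_factory=list)


def run_method(
    cfg: MethodConfig,
    cohort: list[SubjectRecord],
    train_cfg: cnn.TrainConfig | None = None,
    test_counts: dict[ClassLabel, int] | None = None,
    iba_alpha: float = 0.1,
) -> RunResult:
    """Run one method end to end: subject-level split, per-fold augmentation
    and training, held-out prediction pooled across folds into one confusion
    matrix, scored by all five metrics."""
    train_cfg = train_cfg or cnn.TrainConfig()
    classes = cfg.task.classes
    records = [r for r in cohort if r.label in classes]
    if {r.label for r in records} != set(classes):
        raise SplitError(f"cohort does not cover all classes of task {cfg.task.value}")
    plan = make_split(records, cfg.folds, test_counts=test_counts, seed=train_cfg.seed)
    by_id = {r.subject_id: r for r in records}
    shape = records[0].volume.shape
    arch = cnn.ArchitectureSpec(input_shape=shape)
    pooled = np.zeros((3, 3), dtype=np.int64)
    fold_logs = []
    for fold in range(cfg.folds):
        train_ids = [s for s, f in plan.fold_assignment.items() if f != fold]
        eval_ids = plan.fold_ids(fold)
        train_recs = [by_id[s].with_split(Split.TRAIN) for s in sorted(train_ids)]
        aug_cfg = AugmentationConfig(
            mode=cfg.augmentation, seed=train_cfg.seed * 1000 + fold
        )
        augmented = build_training_set(train_recs, aug_cfg)
        train_in = [
            r.with_volume(to_model_input(r.volume, cfg.domain)) for r in augmented
        ]
        eval_in = [
            by_id[s]
            .with_split(Split.VALIDATION)
            .with_volume(to_model_input(by_id[s].volume, cfg.domain))
            for s in eval_ids
        ]
        model = cnn.build_model(
            arch, seed=(train_cfg.seed * 10000 + cfg.method_id * 100 + fold) % (2**31)
        )
        fold_cfg = cnn.TrainConfig(
            learning_rate=train_cfg.learning_rate,
            batch_size=train_cfg.batch_size,
            max_epochs=train_cfg.max_epochs,
            l2_lambda=train_cfg.l2_lambda,
            seed=(train_cfg.seed * 7919 + fold) % (2**31),
        )
        fold_logs.append(cnn.train(model, train_in, eval_in, fold_cfg, classes))
        # inference-time BN statistics from the clean (un-augmented) training
        # volumes, matching the domain of the evaluation inputs
        clean_train = [
            r.with_volume(to_model_input(r.volume, cfg.domain)) for r in train_recs
        ]
        cnn.finalize_batchnorm(model, clean_train)
        pooled += cnn.predict(model, eval_in, classes).counts
    names = tuple(lab.value for lab in classes)
    cm = ConfusionMatrix(pooled, names)
    return RunResult(cfg, cm, metric_row(cm, cfg.method_id, iba_alpha), plan, fold_logs)


# ---------------------------------------------------------------------------
# rank aggregation
# ---------------------------------------------------------------------------

def dense_rank(values, direction: str = "higher_better") -> np.ndarray:
    """Dense ranks (best = 1, ties share, no gaps)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValueError("values must be non-empty and finite")
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction {direction!r}")
    keyed = -values if direction == "higher_better" else values
    return rankdata(keyed, method="dense").astype(np.int64)


_RANK_SPEC = (
    ("rci", "higher_better"),
    ("avg_cen", "lower_better"),
    ("avg_iba", "higher_better"),
    ("avg_gm", "higher_better"),
    ("avg_mcc", "higher_better"),
)


def aggregate_ranking(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-method metric table into the overall ranking.

    ``metric_table`` needs columns ``method_id, rci, avg_cen, avg_iba, avg_gm,
    avg_mcc`` (one row per method).  RCI is ranked higher-better on its raw
    value, averaged CEN lower-better, averaged IBA/GM/MCC higher-better; the
    overall score is the sum of the five ranks and the overall ranking its
    dense rank ascending.  Row order of the input does not matter.
    """
    required = ["method_id"] + [c for c, _ in _RANK_SPEC]
    missing_cols = [c for c in required if c not in metric_table.columns]
    if missing_cols:
        raise AggregationError(f"metric table missing columns {missing_cols}")
    for col, _ in _RANK_SPEC:
        bad = metric_table.loc[metric_table[col].isna(), "method_id"].tolist()
        if bad:
            raise AggregationError(f"missing {col} for methods {bad}")
    out = pd.DataFrame({"method_id": metric_table["method_id"].astype(int).values})
    score = np.zeros(len(out), dtype=np.int64)
    for col, direction in _RANK_SPEC:
        ranks = dense_rank(metric_table[col].values, direction)
        out[f"rank_{col.removeprefix('avg_')}"] = ranks
        score += ranks
    out["overall_score"] = score
    out["overall_ranking"] = dense_rank(score, "lower_better")
    return out
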