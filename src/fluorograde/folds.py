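"""Patient-level, class-balanced 5-fold cross-validation by random
permutation search.

Patients (and hence all their cores and crops) move between folds as
atomic units so no patient ever appears on both sides of a split.  A
permutation draw shuffles the patients and deals them round-robin into
equal-sized fold groups, appending any leftover patients to the last fold.
Each candidate split is scored by the mean squared error between the five
per-fold class-count ratios (class 0 over class 1) and a vector of ones;
the best of ``n_perm`` seeded draws wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import EXCLUDED, CropRecord, map_to_task
from .errors import ConfigurationError
from .metrics import TaskSpec

DEFAULT_N_FOLDS = 5
DEFAULT_N_PERM = 1000


@dataclass
class FoldAssignment:
    core_to_fold: dict[str, int]
    mse: float
    seed: int
    n_perm: int
    n_folds: int = DEFAULT_N_FOLDS
    core_to_patient: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "core_id": list(self.core_to_fold),
                "patient_id": [self.core_to_patient.get(c, "") for c in self.core_to_fold],
                "fold": list(self.core_to_fold.values()),
            }
        )


def _patient_class_counts(
    records: list[CropRecord], task: TaskSpec
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Aggregate class-0/class-1 crop counts per patient; also core->patient."""
    counts: dict[str, np.ndarray] = {}
    core_to_patient: dict[str, str] = {}
    for rec in records:
        core_to_patient[rec.core_id] = rec.patient_id
        if rec.removed:
            continue
        label = rec.task_labels.get(task)
        if label is None:
            label = map_to_task(rec.raw_label, task)
        if label == EXCLUDED:
            continue
        counts.setdefault(rec.patient_id, np.zeros(2, dtype=np.int64))
        counts[rec.patient_id][int(label)] += 1
    return counts, core_to_patient


def deal_round_robin(patients: list[str], n_folds: int) -> list[list[str]]:
    """Deal shuffled patients into folds; position i goes to fold i mod
    n_folds across the first ``n_folds * (n // n_folds)`` positions, and
    leftover patients join the last fold."""
    n_even = (len(patients) // n_folds) * n_folds
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for i, p in enumerate(patients[:n_even]):
        folds[i % n_folds].append(p)
    for p in patients[n_even:]:
        folds[-1].append(p)
    return folds


def balance_mse(fold_counts: np.ndarray) -> float:
    """MSE of per-fold (class0/class1) ratios against 1; a fold with zero
    class-1 crops scores +inf so that permutation is never selected."""
    c0 = fold_counts[:, 0].astype(float)
    c1 = fold_counts[:, 1].astype(float)
    if (c1 == 0).any():
        return float("inf")
    ratios = c0 / c1
    return float(np.mean((ratios - 1.0) ** 2))


def build_balanced_folds(
    records: list[CropRecord],
    task: TaskSpec,
    n_folds: int = DEFAULT_N_FOLDS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> FoldAssignment:
    """Best patient-atomic split over ``n_perm`` seeded permutation draws."""
    counts, core_to_patient = _patient_class_counts(records, task)
    if not counts:
        raise ConfigurationError(f"no labeled crops for task {task}")
    total = np.sum(list(counts.values()), axis=0)
    if total[0] == 0 or total[1] == 0:
        raise ConfigurationError(
            f"task {task} needs both classes present (counts {total.tolist()})"
        )
    patients = sorted(set(core_to_patient.values()))
    if len(patients) < n_folds:
        raise ConfigurationError(
            f"need at least {n_folds} patients, got {len(patients)}"
        )
    patient_counts = {p: counts.get(p, np.zeros(2, dtype=np.int64)) for p in patients}

    rng = np.random.default_rng(seed)
    best_mse = float("inf")
    best_folds: list[list[str]] | None = None
    for _ in range(n_perm):
        perm = [patients[i] for i in rng.permutation(len(patients))]
        folds = deal_round_robin(perm, n_folds)
        fc = np.stack([sum((patient_counts[p] for p in f), np.zeros(2)) for f in folds])
        mse = balance_mse(fc)
        if mse < best_mse:
            best_mse, best_folds = mse, folds
    if best_folds is None:  # every draw scored +inf; keep the last one anyway
        best_folds = folds
        best_mse = float("inf")

    patient_to_fold = {p: i for i, f in enumerate(best_folds) for p in f}
    core_to_fold = {c: patient_to_fold[p] for c, p in core_to_patient.items()}
    return FoldAssignment(
        core_to_fold=core_to_fold,
        mse=best_mse,
        seed=seed,
        n_perm=n_perm,
        n_folds=n_folds,
        core_to_patient=core_to_patient,
    )


def fold_split(assignment: FoldAssignment, val_fold: int) -> tuple[set[str], set[str]]:
    """(train cores, val cores) for one held-out fold; asserts no patient
    leaks across the split."""
    if not 0 <= val_fold < assignment.n_folds:
        raise ValueError(f"val_fold must be in [0, {assignment.n_folds})")
    val = {c for c, f in assignment.core_to_fold.items() if f == val_fold}
    train = set(assignment.core_to_fold) - val
    p = assignment.core_to_patient
    if p:
        shared = {p[c] for c in train} & {p[c] for c in val}
        assert not shared, f"patient leakage across folds: {shared}"
    return train, val
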