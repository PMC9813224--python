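"""Patient-level data splits and class balancing.

All spectra of a patient travel together into exactly one of train /
validation / test, so evaluation measures generalization to unseen patients
rather than to unseen spots on already-seen tissue. The binary task holds out
whole patient pairs for testing (default 20 pairs) and divides the remainder
8:2 into train and validation; the subgroup tasks (subtype, stage,
differentiation) hold out 20% of samples per class and divide the remainder
9:1.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import SpectralDataset

__all__ = [
    "SplitPlan",
    "Split",
    "split_by_patient",
    "class_weights",
    "task_labels",
    "binary_plan",
    "subgroup_plan",
]

TASKS = ("binary", "subtype", "stage", "differentiation")


@dataclass(frozen=True)
class SplitPlan:
    """How to partition patients.

    ``test_pairs`` is an absolute patient count (int) or a fraction (float).
    ``stratify_by`` draws the test fraction separately within each value of a
    patient-level metadata column.
    """

    test_pairs: int | float = 20
    train_val_ratio: tuple[float, float] = (0.8, 0.2)
    stratify_by: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.train_val_ratio
        if not np.isclose(a + b, 1.0) or min(a, b) < 0:
            raise ValueError("train/val ratio must be non-negative and sum to 1")


def binary_plan(seed: int = 0) -> SplitPlan:
    return SplitPlan(test_pairs=20, train_val_ratio=(0.8, 0.2), seed=seed)


def subgroup_plan(stratify_by: str, seed: int = 0) -> SplitPlan:
    return SplitPlan(
        test_pairs=0.2, train_val_ratio=(0.9, 0.1), stratify_by=stratify_by, seed=seed
    )


@dataclass
class Split:
    """Disjoint patient-level partitions of a dataset."""

    train: SpectralDataset
    val: SpectralDataset
    test: SpectralDataset
    patients: dict[str, list[str]] = field(default_factory=dict)

    def partition_hash(self) -> str:
        """Stable digest of the patient partition (protocol-equality checks)."""
        payload = "|".join(
            f"{part}:{','.join(sorted(self.patients[part]))}"
            for part in ("train", "val", "test")
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def _n_test(n_patients: int, test_pairs: int | float) -> int:
    if isinstance(test_pairs, float):
        if not 0 < test_pairs < 1:
            raise ValueError("fractional test size must be in (0, 1)")
        return max(int(round(test_pairs * n_patients)), 1)
    return int(test_pairs)


def split_by_patient(dataset: SpectralDataset, plan: SplitPlan) -> Split:
    """Partition spectra into train/val/test with patients as the unit."""
    if "patient_id" not in dataset.meta.columns:
        raise ValueError("dataset metadata lacks patient ids")
    rng = np.random.default_rng(plan.seed)
    patients = dataset.meta.drop_duplicates("patient_id")

    if plan.stratify_by is not None:
        groups = [g for _, g in patients.groupby(plan.stratify_by, sort=True)]
    else:
        groups = [patients]

    test_ids: list[str] = []
    rest_ids: list[str] = []
    for g in groups:
        ids = g["patient_id"].tolist()
        order = rng.permutation(len(ids))
        n_test = _n_test(len(ids), plan.test_pairs)
        if n_test >= len(ids):
            raise ValueError(
                f"test size {n_test} leaves no training patients (group of {len(ids)})"
            )
        test_ids += [ids[i] for i in order[:n_test]]
        rest_ids += [ids[i] for i in order[n_test:]]

    order = rng.permutation(len(rest_ids))
    n_val = int(round(plan.train_val_ratio[1] * len(rest_ids)))
    if len(rest_ids) - n_val < 1:
        raise ValueError("too few patients for the requested train/val ratio")
    val_ids = [rest_ids[i] for i in order[:n_val]]
    train_ids = [rest_ids[i] for i in order[n_val:]]

    pid = dataset.meta["patient_id"]
    parts = {
        "train": dataset.subset(pid.isin(train_ids).to_numpy()),
        "val": dataset.subset(pid.isin(val_ids).to_numpy()),
        "test": dataset.subset(pid.isin(test_ids).to_numpy()),
    }
    return Split(
        parts["train"], parts["val"], parts["test"],
        patients={"train": train_ids, "val": val_ids, "test": test_ids},
    )


def class_weights(labels: np.ndarray) -> dict:
    """Inverse-frequency loss weights: w_c = N / (K * n_c).

    Normalized so that every class contributes equally to the loss and
    sum_c w_c * n_c = N; balanced data gets unit weights.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0) or len(classes) == 0:
        raise ValueError("every class needs at least one example")
    n, k = labels.size, len(classes)
    return {c: n / (k * cnt) for c, cnt in zip(classes, counts)}


def task_labels(
    dataset: SpectralDataset, task: str
) -> tuple[SpectralDataset, np.ndarray, list[str]]:
    """Select the spectra and integer labels for one classification task.

    binary: all spectra, paracancer=0 / cancer=1. subtype: carcinoma spectra,
    HCC vs ICC. stage / differentiation: HCC carcinoma spectra with the
    corresponding grade labels.
    """
    meta = dataset.meta
    if task == "binary":
        classes = ["paracancer", "cancer"]
        y = (meta["tissue"] == "cancer").to_numpy().astype(int)
        return dataset, y, classes
    if task == "subtype":
        sub = dataset.subset((meta["tissue"] == "cancer").to_numpy())
        classes = ["HCC", "ICC"]
    elif task in ("stage", "differentiation"):
        sub = dataset.subset(
            ((meta["tissue"] == "cancer") & (meta["subtype"] == "HCC")).to_numpy()
        )
        classes = sorted(sub.meta[task].unique())
    else:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    col = {"subtype": "subtype", "stage": "stage", "differentiation": "differentiation"}[task]
    mapping = {c: i for i, c in enumerate(classes)}
    y = sub.meta[col].map(mapping).to_numpy().astype(int)
    return sub, y, classes
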