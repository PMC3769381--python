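"""Expression tables, sample annotations, and treatment-group fold-change profiles.

The unit of analysis throughout the pipeline is the *treatment group*: all
replicate animals that share compound, dose, sex, and dosing duration.  Each
group is represented by a vector of mean log2 fold-changes of every probeset
versus the time-matched vehicle-control samples (same vehicle, same dosing
duration).  Downstream signature selection and classification operate on these
group profiles, never on individual animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Compound-class vocabulary.  GC = genotoxic carcinogen, NGC = nongenotoxic
#: carcinogen, NC = non-carcinogen, UNDEF = ambiguous genotoxicity (excluded
#: from training), CONTROL = vehicle-treated control animals.
CLASS_LABELS = ("GC", "NGC", "NC", "UNDEF", "CONTROL")

VALID_DURATIONS = (3, 14)

#: Binary discrimination tasks: task -> (positive classes, negative classes).
#: "C" denotes the pooled carcinogen class GC + NGC.
TASKS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "C_vs_NC": (("GC", "NGC"), ("NC",)),
    "GC_vs_NGC": (("GC",), ("NGC",)),
    "GC_vs_NC": (("GC",), ("NC",)),
    "NGC_vs_NC": (("NGC",), ("NC",)),
}


@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata for one array/animal."""

    sample_id: str
    group_id: str
    compound: str
    vehicle: str
    dose: float
    sex: str
    duration_days: int
    class_label: str

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown class {self.class_label!r}; "
                f"expected one of {CLASS_LABELS}"
            )
        if self.duration_days not in VALID_DURATIONS:
            raise ValueError(
                f"sample {self.sample_id!r}: duration_days must be one of "
                f"{VALID_DURATIONS}, got {self.duration_days}"
            )
        if self.class_label == "CONTROL" and self.compound != self.vehicle:
            raise ValueError(
                f"control sample {self.sample_id!r} must have compound equal to "
                f"its vehicle ({self.vehicle!r}), got {self.compound!r}"
            )


@dataclass
class ExpressionDataset:
    """Probesets x samples log2 expression with per-sample annotations.

    ``values`` holds already normalized log2 intensities; normalization is
    upstream of this package.  ``annotations`` may be empty for a matrix that
    has been read but not yet joined with its annotation table.
    """

    values: np.ndarray
    probeset_ids: list[str]
    sample_ids: list[str]
    annotations: list[SampleAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probeset_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probeset_ids)} probesets x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probeset", self.probeset_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {name} IDs: {dupes}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at probeset "
                f"{self.probeset_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        if self.annotations:
            self._validate_annotations()

    # -- helpers -----------------------------------------------------------
    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def annotation_by_sample(self) -> dict[str, SampleAnnotation]:
        return {a.sample_id: a for a in self.annotations}

    def _validate_annotations(self) -> None:
        by_sample = self.annotation_by_sample()
        missing = [s for s in self.sample_ids if s not in by_sample]
        if missing:
            raise ValueError(f"samples without annotation: {missing}")
        anns = [by_sample[s] for s in self.sample_ids]
        controls = {(a.vehicle, a.duration_days) for a in anns if a.class_label == "CONTROL"}
        for a in anns:
            if a.class_label == "CONTROL":
                continue
            if (a.vehicle, a.duration_days) not in controls:
                raise ValueError(
                    f"sample {a.sample_id!r} (vehicle {a.vehicle!r}, "
                    f"{a.duration_days} d) has no time-matched vehicle control"
                )


@dataclass
class GroupProfile:
    """One treatment group as a fold-change vector over all probesets."""

    group_id: str
    class_label: str
    sex: str
    duration_days: int
    compound: str
    fold_changes: np.ndarray

    def __post_init__(self) -> None:
        self.fold_changes = np.asarray(self.fold_changes, dtype=float)


def read_expression_table(path) -> ExpressionDataset:
    """Read a tab-delimited probesets-x-samples log2 expression table.

    First column holds probeset IDs, the header row holds sample IDs.
    Duplicate IDs and non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    probesets = df.index.astype(str).tolist()
    samples = df.columns.astype(str).tolist()
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j in range(df.shape[1]):
        col = pd.to_numeric(raw[:, j], errors="coerce")
        bad = np.flatnonzero(np.isnan(col))
        if bad.size:
            raise ValueError(
                f"non-numeric value {raw[bad[0], j]!r} at probeset "
                f"{probesets[bad[0]]!r}, sample {samples[j]!r} in {path}"
            )
        values[:, j] = col
    ds = ExpressionDataset(values=values, probeset_ids=probesets, sample_ids=samples)
    logger.info("read expression table %s: %d probesets x %d samples",
                path, ds.n_probesets, ds.n_samples)
    return ds


#: expected annotation columns (after the leading sample_id column)
_ANNOTATION_COLUMNS = ("group_id", "compound", "vehicle", "dose", "sex", "duration", "class")


def read_annotation_table(path) -> list[SampleAnnotation]:
    """Read the tab-delimited sample annotation table.

    Columns: ``sample_id`` (join key to the expression header), then
    ``group_id, compound, vehicle, dose, sex, duration, class``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    required = ("sample_id",) + _ANNOTATION_COLUMNS
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"annotation table {path} lacks columns {missing}")
    anns = []
    for _, row in df.iterrows():
        anns.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                group_id=str(row["group_id"]),
                compound=str(row["compound"]),
                vehicle=str(row["vehicle"]),
                dose=float(row["dose"]),
                sex=str(row["sex"]),
                duration_days=int(row["duration"]),
                class_label=str(row["class"]),
            )
        )
    return anns


def load_dataset(expression_path, annotation_path) -> ExpressionDataset:
    """Read expression and annotations and join them (errors on orphans)."""
    ds = read_expression_table(expression_path)
    anns = read_annotation_table(annotation_path)
    return attach_annotations(ds, anns)


def attach_annotations(ds: ExpressionDataset, annotations: list[SampleAnnotation]) -> ExpressionDataset:
    by_sample = {a.sample_id: a for a in annotations}
    orphans = [s for s in ds.sample_ids if s not in by_sample]
    if orphans:
        raise ValueError(f"expression samples without annotation: {orphans}")
    return ExpressionDataset(
        values=ds.values,
        probeset_ids=ds.probeset_ids,
        sample_ids=ds.sample_ids,
        annotations=[by_sample[s] for s in ds.sample_ids],
    )


def compute_group_profiles(ds: ExpressionDataset, duration: int) -> list[GroupProfile]:
    """Collapse per-animal expression into per-treatment-group fold changes.

    For every non-control treatment group at ``duration``, the profile is the
    mean log2 expression of its replicates minus the mean log2 expression of
    the control samples sharing its vehicle and duration.  Male and female
    groups stay separate (the group ID encodes sex).
    """
    if duration not in VALID_DURATIONS:
        raise ValueError(f"duration must be one of {VALID_DURATIONS}")
    if not ds.annotations:
        raise ValueError("dataset has no annotations; join an annotation table first")
    by_sample = ds.annotation_by_sample()
    col = {s: j for j, s in enumerate(ds.sample_ids)}
    anns = [by_sample[s] for s in ds.sample_ids]

    control_cols: dict[str, list[int]] = {}
    for a in anns:
        if a.class_label == "CONTROL" and a.duration_days == duration:
            control_cols.setdefault(a.vehicle, []).append(col[a.sample_id])

    groups: dict[str, list[SampleAnnotation]] = {}
    for a in anns:
        if a.class_label != "CONTROL" and a.duration_days == duration:
            groups.setdefault(a.group_id, []).append(a)

    profiles = []
    for gid in sorted(groups):
        members = groups[gid]
        vehicle = members[0].vehicle
        if vehicle not in control_cols:
            raise ValueError(
                f"treatment group {gid!r} has no control samples for vehicle "
                f"{vehicle!r} at {duration} d"
            )
        treated = ds.values[:, [col[a.sample_id] for a in members]].mean(axis=1)
        control = ds.values[:, control_cols[vehicle]].mean(axis=1)
        profiles.append(
            GroupProfile(
                group_id=gid,
                class_label=members[0].class_label,
                sex=members[0].sex,
                duration_days=duration,
                compound=members[0].compound,
                fold_changes=treated - control,
            )
        )
    logger.info("computed %d group profiles at %d d", len(profiles), duration)
    return profiles


def profiles_to_matrix(profiles: list[GroupProfile]) -> np.ndarray:
    """Stack profiles into a groups x probesets matrix."""
    if not profiles:
        raise ValueError("no profiles given")
    return np.vstack([p.fold_changes for p in profiles])


def task_labels(profiles: list[GroupProfile], task: str):
    """Select the profiles involved in a binary task and code labels 0/1.

    Returns ``(selected_profiles, y)`` where ``y[i] = 1`` marks the task's
    positive class (e.g. carcinogen for C_vs_NC).  UNDEF and CONTROL profiles
    are never part of any task.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    pos, neg = TASKS[task]
    selected = [p for p in profiles if p.class_label in pos + neg]
    y = np.array([1 if p.class_label in pos else 0 for p in selected], dtype=int)
    return selected, y


def zscore_fit_apply(train: np.ndarray, test: np.ndarray | None = None):
    """Standardize features by z-scores fitted on the training rows only.

    Uses the sample (n-1) standard deviation.  Features with zero variance on
    the training set get SD := 1 (the feature becomes constant 0) with a
    logged warning, so applying a signature never aborts on a flat gene.

    Returns ``(train_std, test_std)``; ``test_std`` is None when no test
    matrix was given.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("need a 2-D training matrix with >= 2 profiles")
    if train.shape[1] == 0:
        raise ValueError("feature set is empty")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    flat = sd == 0.0
    if flat.any():
        logger.warning("%d zero-variance feature(s) on the training set; SD set to 1",
                       int(flat.sum()))
        sd = np.where(flat, 1.0, sd)
    train_std = (train - mean) / sd
    test_std = None
    if test is not None:
        test = np.asarray(test, dtype=float)
        if test.shape[1] != train.shape[1]:
            raise ValueError("train/test feature counts differ")
        test_std = (test - mean) / sd
    return train_std, test_std
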