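"""Grade schemes, label remapping and deterministic dataset splitting.

Diabetic-retinopathy screening programs rarely use the raw five-step
clinical grading (none / mild / moderate / severe / proliferative).
Triage-oriented programs collapse those grades into coarser schemes such
as {Healthy, Non-referable DR, Referable DR} or simply {Healthy,
Diseased}.  This module defines ordered grade schemes, severity-preserving
label maps between them (shipped with the two screening presets), per-class
dataset summaries, and reproducible stratified train/validation/test
splitting.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GradeScheme",
    "LabelMap",
    "SplitSpec",
    "Split",
    "DatasetSummary",
    "KAGGLE5",
    "THREE_CLASS",
    "TWO_CLASS",
    "KAGGLE_NUMERIC_ALIASES",
    "PRESET_MAPS",
    "remap_labels",
    "summarize",
    "make_split",
    "read_label_table",
    "write_label_table",
]


@dataclass(frozen=True)
class GradeScheme:
    """An ordered set of disease classes, least severe first.

    Parameters
    ----------
    classes
        Class names ordered from least to most severe.
    fallback_class
        The class assigned when no decision rule fires (the "~" class of
        a cascading-threshold policy).  Defaults to the least severe
        class, which is the conventional screening fallback.
    """

    classes: tuple[str, ...]
    fallback_class: str = ""

    def __post_init__(self) -> None:
        classes = tuple(self.classes)
        object.__setattr__(self, "classes", classes)
        if len(classes) < 2:
            raise ValueError("a grade scheme needs at least 2 classes")
        if len(set(classes)) != len(classes):
            raise ValueError(f"duplicate class names in {classes}")
        if not self.fallback_class:
            object.__setattr__(self, "fallback_class", classes[0])
        if self.fallback_class not in classes:
            raise ValueError(
                f"fallback class {self.fallback_class!r} not in {classes}"
            )

    def __len__(self) -> int:
        return len(self.classes)

    def index(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}; scheme has {self.classes}")

    def severity_descending(self) -> tuple[str, ...]:
        return tuple(reversed(self.classes))


#: The original Kaggle EyePACS five-grade scheme.
KAGGLE5 = GradeScheme(
    ("No DR", "Mild DR", "Moderate DR", "Severe DR", "Proliferative DR")
)

#: Triage scheme used by referral-based screening programs.
THREE_CLASS = GradeScheme(("Healthy", "Non-referable DR", "Referable DR"))

#: Broad disease-detection scheme.
TWO_CLASS = GradeScheme(("Healthy", "Diseased"))

#: Kaggle encodes the five grades as integers 0-4; accepted as aliases.
KAGGLE_NUMERIC_ALIASES: dict[str, str] = {
    str(i): name for i, name in enumerate(KAGGLE5.classes)
}


@dataclass(frozen=True)
class LabelMap:
    """A severity-preserving map from a source grade scheme to a target one.

    Every source grade maps to exactly one target class, every target class
    is hit at least once, and a more severe source grade never maps to a
    less severe target class.
    """

    entries: Mapping[str, str]
    source_scheme: tuple[str, ...]
    target_scheme: GradeScheme

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "source_scheme", tuple(self.source_scheme))
        missing = [g for g in self.source_scheme if g not in self.entries]
        if missing:
            raise ValueError(f"source grades without a target: {missing}")
        extra = [g for g in self.entries if g not in self.source_scheme]
        if extra:
            raise ValueError(f"map entries outside the source scheme: {extra}")
        targets_hit = set(self.entries.values())
        unhit = [c for c in self.target_scheme.classes if c not in targets_hit]
        if unhit:
            raise ValueError(f"target classes never mapped to: {unhit}")
        # severity monotonicity: target index non-decreasing along source order
        idx = [self.target_scheme.index(self.entries[g]) for g in self.source_scheme]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("map is not severity-preserving")

    def __getitem__(self, source_grade: str) -> str:
        return self.entries[source_grade]


#: Five grades -> {Healthy, Non-referable DR, Referable DR}.
KAGGLE5_TO_3 = LabelMap(
    entries={
        "No DR": "Healthy",
        "Mild DR": "Non-referable DR",
        "Moderate DR": "Non-referable DR",
        "Severe DR": "Referable DR",
        "Proliferative DR": "Referable DR",
    },
    source_scheme=KAGGLE5.classes,
    target_scheme=THREE_CLASS,
)

#: Five grades -> {Healthy, Diseased}.
KAGGLE5_TO_2 = LabelMap(
    entries={
        "No DR": "Healthy",
        "Mild DR": "Diseased",
        "Moderate DR": "Diseased",
        "Severe DR": "Diseased",
        "Proliferative DR": "Diseased",
    },
    source_scheme=KAGGLE5.classes,
    target_scheme=TWO_CLASS,
)

PRESET_MAPS: dict[str, LabelMap] = {
    "kaggle5to3": KAGGLE5_TO_3,
    "kaggle5to2": KAGGLE5_TO_2,
}


@dataclass(frozen=True)
class SplitSpec:
    """Reproducible three-way split specification.

    ``ratios`` are the (train, validation, test) fractions and must sum to
    one.  The same spec applied to the same inputs always yields the same
    partition.
    """

    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", tuple(float(r) for r in self.ratios))
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be three non-negative fractions")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(self.ratios)}")


@dataclass(frozen=True)
class Split:
    """The result of :func:`make_split`: three disjoint id tuples."""

    train: tuple
    validation: tuple
    test: tuple

    def __iter__(self):
        return iter((self.train, self.validation, self.test))

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


@dataclass(frozen=True)
class DatasetSummary:
    """Per-class sample counts plus their total."""

    counts: Mapping[str, int]
    total: int = field(default=-1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        total = sum(self.counts.values())
        if self.total == -1:
            object.__setattr__(self, "total", total)
        elif self.total != total:
            raise ValueError(
                f"total {self.total} != sum of counts {total}"
            )

    def __getitem__(self, cls: str) -> int:
        return self.counts[cls]

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, name="count")


def _canonical(label: str) -> str:
    """Resolve the Kaggle numeric alias 0-4 to its grade name."""
    s = str(label).strip()
    return KAGGLE_NUMERIC_ALIASES.get(s, s)


def remap_labels(labels: Sequence[str], label_map: LabelMap) -> list[str]:
    """Map a sequence of source grade names onto their target classes.

    Numeric Kaggle aliases ("0".."4") are resolved before lookup.  An
    unknown source grade raises ``KeyError`` naming the offending label.
    """
    out = []
    for lab in labels:
        name = _canonical(lab)
        if name not in label_map.entries:
            raise KeyError(
                f"unknown source grade {lab!r}; expected one of "
                f"{list(label_map.source_scheme)}"
            )
        out.append(label_map.entries[name])
    return out


def summarize(labels: Sequence[str], scheme: GradeScheme) -> DatasetSummary:
    """Tally labels into per-class counts; absent classes report zero."""
    tally = Counter(labels)
    unknown = set(tally) - set(scheme.classes)
    if unknown:
        raise KeyError(f"labels outside scheme {scheme.classes}: {sorted(unknown)}")
    return DatasetSummary({c: tally.get(c, 0) for c in scheme.classes})


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Allocate ``n`` items to bins by largest-remainder rounding.

    Ties in the fractional remainder are broken toward the earlier bin.
    """
    quotas = [n * r for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    short = n - sum(sizes)
    order = sorted(
        range(len(ratios)), key=lambda i: (-(quotas[i] - sizes[i]), i)
    )
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def make_split(
    ids: Sequence,
    labels: Sequence[str] | None,
    spec: SplitSpec,
) -> Split:
    """Partition sample ids into train/validation/test sets.

    With ``spec.stratified`` (the default) the split is performed per
    class so that each class's proportions match the ratios up to
    largest-remainder rounding; ``labels`` is then required.  The
    partition is a pure function of ``(ids, labels, spec)``.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    if spec.stratified:
        if labels is None:
            raise ValueError("stratified split requires labels")
        if len(labels) != len(ids):
            raise ValueError("labels must align with ids")
    rng = np.random.default_rng(spec.seed)
    parts: tuple[list, list, list] = ([], [], [])
    if spec.stratified:
        by_class: dict[str, list] = {}
        for i, lab in zip(ids, labels):
            by_class.setdefault(lab, []).append(i)
        groups = by_class.values()
    else:
        groups = [ids]
    for members in groups:
        perm = rng.permutation(len(members))
        shuffled = [members[j] for j in perm]
        n_tr, n_va, n_te = _largest_remainder(len(members), spec.ratios)
        parts[0].extend(shuffled[:n_tr])
        parts[1].extend(shuffled[n_tr : n_tr + n_va])
        parts[2].extend(shuffled[n_tr + n_va :])
    return Split(tuple(parts[0]), tuple(parts[1]), tuple(parts[2]))


def read_label_table(path) -> pd.DataFrame:
    """Read an (id, grade[, split]) CSV/TSV table.

    The grade column accepts grade names or the Kaggle 0-4 integers;
    integers are resolved to names on load.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"id", "grade"}
    if not required <= set(df.columns):
        raise ValueError(f"label table needs columns {sorted(required)}")
    df["grade"] = df["grade"].map(_canonical)
    return df


def write_label_table(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


def split_to_frame(ids: Sequence, labels: Sequence[str], split: Split) -> pd.DataFrame:
    """Tabulate a split as an (id, grade, split) frame for writing."""
    part_of = {}
    for name, members in zip(("train", "validation", "test"), split):
        for i in members:
            part_of[i] = name
    missing = [i for i in ids if i not in part_of]
    if missing:
        warnings.warn(f"{len(missing)} ids missing from split", stacklevel=2)
    return pd.DataFrame(
        {"id": list(ids), "grade": list(labels), "split": [part_of.get(i) for i in ids]}
    )
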