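"""CSV and image I/O for probability tables, predictions and quality scores.

Probability tables are CSV/TSV with columns ``id, p_<class>..., true_label``
(the ``true_label`` column optional); class columns must match the grade
scheme in order.  Images are 8-bit RGB PNG/JPEG.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .grading import GradeScheme
from .policies import ProbRecord
from .quality import QualityScore

__all__ = [
    "prob_columns",
    "read_prob_table",
    "write_prob_table",
    "write_predictions",
    "read_quality_scores",
    "write_quality_scores",
    "load_image",
    "save_image",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def prob_columns(scheme: GradeScheme) -> list[str]:
    return [f"p_{c}" for c in scheme.classes]


def read_prob_table(path, scheme: GradeScheme) -> list[ProbRecord]:
    df = pd.read_csv(path, sep=_sep(path))
    cols = prob_columns(scheme)
    missing = [c for c in ["id", *cols] if c not in df.columns]
    if missing:
        raise ValueError(f"probability table missing columns {missing}")
    has_truth = "true_label" in df.columns
    ids = df["id"].tolist()
    probs = df[cols].to_numpy(dtype=float)
    truths = df["true_label"].tolist() if has_truth else [None] * len(df)
    return [
        ProbRecord(
            id=i,
            probs=tuple(p),
            scheme=scheme,
            true_label=t if (t is not None and pd.notna(t)) else None,
        )
        for i, p, t in zip(ids, probs, truths)
    ]


def write_prob_table(records: Sequence[ProbRecord], path) -> None:
    if not records:
        raise ValueError("no records to write")
    scheme = records[0].scheme
    rows = []
    for r in records:
        row = {"id": r.id}
        row.update(dict(zip(prob_columns(scheme), r.probs)))
        row["true_label"] = r.true_label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def write_predictions(pairs: Iterable[tuple[object, str]], path) -> None:
    pd.DataFrame(pairs, columns=["id", "predicted"]).to_csv(
        path, sep=_sep(path), index=False
    )


def read_quality_scores(path, threshold: float = 0.5) -> list[QualityScore]:
    df = pd.read_csv(path, sep=_sep(path))
    if "label" in df.columns:
        return [
            QualityScore(id=r.id, score=float(r.score), label=r.label)
            for r in df.itertuples(index=False)
        ]
    return [
        QualityScore(
            id=r.id,
            score=float(r.score),
            label="adequate" if float(r.score) >= threshold else "inadequate",
        )
        for r in df.itertuples(index=False)
    ]


def write_quality_scores(scores: Sequence[QualityScore], path) -> None:
    pd.DataFrame(
        [(s.id, s.score, s.label) for s in scores],
        columns=["id", "score", "label"],
    ).to_csv(path, sep=_sep(path), index=False)


def load_image(path) -> np.ndarray:
    with PILImage.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(img: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    PILImage.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path)
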