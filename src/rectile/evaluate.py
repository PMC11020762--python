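"""Error-matrix accuracy assessment.

The error (confusion) matrix is oriented rows = classification result,
columns = reference, the usual layout in land-cover accuracy tables: user
accuracy reads along rows, producer accuracy along columns.  All metrics are
computed from exact integer counts and rounded only for display, so printed
2-d.p. percentages are reproduced from the underlying cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import LabelRaster
from .errors import ExtentError, ParameterError
from .raster import CLASSES, SamplePoint


@dataclass
class ErrorMatrix:
    """K x K contingency table: counts[i, j] = reference class j predicted i."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ParameterError(
                f"counts must be {k}x{k} for {k} classes"
            )
        if (self.counts < 0).any():
            raise ParameterError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _class_index(self, cls: str) -> int:
        try:
            return self.class_order.index(cls)
        except ValueError:
            raise ParameterError(f"unknown class {cls!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.class_order, name="predicted"),
            columns=pd.Index(self.class_order, name="reference"),
        )


@dataclass
class AccuracyReport:
    """Overall and per-class accuracy metrics (percent, kappa unitless)."""

    oa: float
    kappa: float
    pa: dict[str, float]
    ua: dict[str, float]
    f1: dict[str, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "oa": self.oa,
            "kappa": self.kappa,
            "pa": self.pa,
            "ua": self.ua,
            "f1": self.f1,
            "n": self.n,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        lines = [f"OA = {self.oa:.2f}%   kappa = {self.kappa:.4f}   n = {self.n}"]
        for cls in self.pa:
            lines.append(
                f"  {cls:<11} PA {self.pa[cls]:6.2f}%  "
                f"UA {self.ua[cls]:6.2f}%  F1 {self.f1[cls]:6.2f}%"
            )
        return "\n".join(lines)


def confusion(
    pred: LabelRaster,
    validation: Sequence[SamplePoint],
    split: str | None = "validation",
) -> ErrorMatrix:
    """Error matrix of a class map against labelled reference points.

    Points on nodata pixels or outside the extent are excluded (their count
    is retrievable as ``len(points) - matrix.total``).
    """
    order = pred.legend
    k = len(order)
    counts = np.zeros((k, k), dtype=np.int64)
    for p in validation:
        if split is not None and p.split != split:
            continue
        try:
            r, c = pred.rowcol(p.x, p.y)
        except ExtentError:
            continue
        v = int(pred.labels[r, c])
        if v < 0:
            continue
        counts[v, order.index(p.label)] += 1
    return ErrorMatrix(counts, tuple(order))


def oa(mat: ErrorMatrix) -> float:
    """Overall accuracy in percent: 100 * trace / total."""
    if mat.total == 0:
        raise ParameterError("empty error matrix")
    return 100.0 * float(np.trace(mat.counts)) / mat.total


def kappa(mat: ErrorMatrix) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e).

    p_o is observed agreement (trace / N) and p_e the chance agreement from
    the row/column marginals.  Returns NaN when p_e == 1 (degenerate
    single-cell margins).
    """
    n = mat.total
    if n == 0:
        raise ParameterError("empty error matrix")
    p_o = float(np.trace(mat.counts)) / n
    rows = mat.counts.sum(axis=1).astype(float)
    cols = mat.counts.sum(axis=0).astype(float)
    p_e = float((rows * cols).sum()) / (n * n)
    if p_e == 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def pa(mat: ErrorMatrix, cls: str) -> float:
    """Producer accuracy (percent): diagonal over reference-column sum."""
    i = mat._class_index(cls)
    col = mat.counts[:, i].sum()
    return 100.0 * float(mat.counts[i, i]) / col if col else 0.0


def ua(mat: ErrorMatrix, cls: str) -> float:
    """User accuracy (percent): diagonal over predicted-row sum."""
    i = mat._class_index(cls)
    row = mat.counts[i, :].sum()
    return 100.0 * float(mat.counts[i, i]) / row if row else 0.0


def f1(mat: ErrorMatrix, cls: str) -> float:
    """F1 (percent): harmonic mean of producer and user accuracy."""
    p, u = pa(mat, cls), ua(mat, cls)
    return 2.0 * p * u / (p + u) if (p + u) else 0.0


def accuracy_report(mat: ErrorMatrix) -> AccuracyReport:
    return AccuracyReport(
        oa=oa(mat),
        kappa=kappa(mat),
        pa={c: pa(mat, c) for c in mat.class_order},
        ua={c: ua(mat, c) for c in mat.class_order},
        f1={c: f1(mat, c) for c in mat.class_order},
        n=mat.total,
    )


def stratified_split(
    points: Sequence[SamplePoint], train_fraction: float = 0.7, seed: int = 0
) -> list[SamplePoint]:
    """Reassign train/validation tags with a seeded, class-stratified split.

    Within each class, ``round(train_fraction * n)`` points are drawn for
    training; order of the returned list matches the input.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    split_of = ["validation"] * len(points)
    for cls in {p.label for p in points}:
        idx = [i for i, p in enumerate(points) if p.label == cls]
        n_train = int(round(train_fraction * len(idx)))
        chosen = rng.choice(len(idx), size=n_train, replace=False)
        for j in chosen:
            split_of[idx[j]] = "train"
    return [
        SamplePoint(p.x, p.y, p.label, split_of[i])
        for i, p in enumerate(points)
    ]
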