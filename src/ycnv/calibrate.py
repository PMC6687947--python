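"""Ordinary-least-squares calibration of copy-number estimates.

Depth-derived values are calibrated against gold-standard copy counts
(single-molecule fibre measurements) with a plain OLS line, and
independent quantification methods are compared with the same machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_cn

GOLD_STANDARD_RESOURCE = "fibre_fish_gold_standard.tsv"


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted ``y = slope * x + intercept`` calibration line."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residuals: tuple[float, ...] = field(default_factory=tuple, repr=False)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("calibration needs n >= 2")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "r2": self.r_squared,
                "n": self.n,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            slope=d["slope"], intercept=d["intercept"],
            r_squared=d["r2"], n=d["n"],
        )


def fit_ols(x: Sequence[float], y: Sequence[float]) -> CalibrationModel:
    """Least-squares line of *y* on *x* via the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("zero variance predictor")
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        n=len(x),
        residuals=tuple(float(r) for r in resid),
    )


def predict_cn(model: CalibrationModel, x: float) -> tuple[float, int]:
    """Calibrated copy number for *x*: (real value, rounded integer >= 0)."""
    real = model.slope * x + model.intercept
    return real, round_cn(real)


@dataclass(frozen=True)
class ValidationReport:
    """Train/test concordance of integer calibrated calls vs truth."""

    model: CalibrationModel
    predictions: pd.DataFrame  # sample_id, x, truth, predicted_real, predicted_int, abs_error
    exact: int
    off_by_one: int
    worse: int

    @property
    def n_test(self) -> int:
        return self.exact + self.off_by_one + self.worse


def split_validation(
    table: pd.DataFrame,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    x_col: str = "x",
    y_col: str = "y",
    id_col: str = "sample_id",
) -> ValidationReport:
    """Fit on the training samples, score integer predictions on the rest.

    The table must carry one row per sample. Train and test sets must be
    disjoint subsets of the table's ids.
    """
    train_ids, test_ids = list(train_ids), list(test_ids)
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test sets overlap")
    known = set(table[id_col])
    missing = (set(train_ids) | set(test_ids)) - known
    if missing:
        raise ValueError(f"unknown sample ids: {sorted(missing)}")

    indexed = table.set_index(id_col)
    train = indexed.loc[train_ids]
    test = indexed.loc[test_ids]
    model = fit_ols(train[x_col].to_numpy(), train[y_col].to_numpy())

    rows = []
    for sid, row in test.iterrows():
        real, integer = predict_cn(model, float(row[x_col]))
        truth = float(row[y_col])
        rows.append(
            {
                "sample_id": sid,
                "x": float(row[x_col]),
                "truth": truth,
                "predicted_real": real,
                "predicted_int": integer,
                "abs_error": abs(integer - round_cn(truth)),
            }
        )
    pred = pd.DataFrame(rows)
    err = pred["abs_error"]
    return ValidationReport(
        model=model,
        predictions=pred,
        exact=int((err == 0).sum()),
        off_by_one=int((err == 1).sum()),
        worse=int((err >= 2).sum()),
    )


def load_gold_standard() -> pd.DataFrame:
    """The packaged 14-sample gold-standard copy-number table.

    Columns: per-region single-molecule counts (regions 1-4; a split
    cluster is stored as its summed count), the fibre total, and the
    read-depth and droplet-PCR estimates for the same samples.
    """
    ref = resources.files("ycnv.data").joinpath(GOLD_STANDARD_RESOURCE)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    region_cols = ["region_1", "region_2", "region_3", "region_4"]
    if not (df[region_cols].sum(axis=1) == df["total_fibre_fish"]).all():
        raise ValueError("gold-standard totals inconsistent with region counts")
    return df
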