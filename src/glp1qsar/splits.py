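"""Potency-based train/test constructions and external-prediction metrics.

Three deterministic test-set constructions over a potency-sorted dataset:

* ``alternating`` - sort ascending by pEC50 and alternate members between
  a reduced training set (odd positions, plus any odd remainder) and a
  potency-matched test set (even positions); for 31 records this gives
  16 train / 15 test.
* ``every_fifth`` - sort ascending, form consecutive groups of five,
  send the fifth member of each full group to the test set (31 records
  -> 25 / 6); a trailing partial group stays in training.
* ``potency_ranked`` - the least potent fraction trains, the most potent
  remainder tests (extrapolation stress test).

All sorts are stable with ties broken by id, so splits are independent
of input order. External predictions are summarized by R²_pred about
the training mean (which may be negative), RMSE_pred, the best-fit and
through-origin slopes of predicted vs observed, and the mean shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Split",
    "PredictionReport",
    "alternating_potency_split",
    "every_fifth_split",
    "potency_ranked_split",
    "assess_predictions",
]


@dataclass(frozen=True)
class Split:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    method: str
    train_fraction: float | None = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets must be disjoint")

    def summary(self, pec50_by_id: dict[str, float]) -> dict[str, float]:
        tr = np.array([pec50_by_id[i] for i in self.train_ids])
        te = np.array([pec50_by_id[i] for i in self.test_ids])
        return {
            "train_mean": float(tr.mean()),
            "train_sd": float(tr.std(ddof=1)) if len(tr) > 1 else 0.0,
            "test_mean": float(te.mean()),
            "test_sd": float(te.std(ddof=1)) if len(te) > 1 else 0.0,
        }


def _sorted_ids(records: Sequence[tuple[str, float]]) -> list[str]:
    # ascending potency, ties broken lexicographically by id
    return [rid for rid, _ in sorted(records, key=lambda r: (r[1], r[0]))]


def alternating_potency_split(records: Sequence[tuple[str, float]]) -> Split:
    """Potency-matched alternating split (odd sorted positions train)."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    ids = _sorted_ids(records)
    return Split(
        train_ids=tuple(ids[0::2]),
        test_ids=tuple(ids[1::2]),
        method="alternating",
    )


def every_fifth_split(records: Sequence[tuple[str, float]]) -> Split:
    """Every fifth member (of full potency-sorted groups of five) tests."""
    if len(records) < 5:
        raise ValueError("need at least five records")
    ids = _sorted_ids(records)
    train, test = [], []
    for i, rid in enumerate(ids):
        if i % 5 == 4:
            test.append(rid)
        else:
            train.append(rid)
    return Split(tuple(train), tuple(test), method="every_fifth")


def potency_ranked_split(
    records: Sequence[tuple[str, float]], train_fraction: float
) -> Split:
    """Least potent ``train_fraction`` trains, most potent remainder tests.

    The training count is round-half-away-from-zero of
    ``train_fraction * n``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    ids = _sorted_ids(records)
    n_train = int(math.floor(train_fraction * len(ids) + 0.5))
    if n_train == 0 or n_train == len(ids):
        raise ValueError("split leaves one side empty")
    return Split(
        tuple(ids[:n_train]), tuple(ids[n_train:]),
        method="potency_ranked", train_fraction=train_fraction,
    )


@dataclass(frozen=True)
class PredictionReport:
    r2_pred: float
    rmse_pred: float
    fit_slope: float
    fit_intercept: float
    origin_slope: float
    mean_shift: float

    def __post_init__(self) -> None:
        if self.rmse_pred < 0:
            raise ValueError("RMSE cannot be negative")


def assess_predictions(
    observed: Sequence[float],
    predicted: Sequence[float],
    train_mean: float,
) -> PredictionReport:
    """External-prediction assessment of a re-trained model.

    ``r2_pred = 1 − Σ(obs−pred)² / Σ(obs−train_mean)²`` (negative when
    predictions are worse than the constant training-mean predictor).
    The best-fit line regresses predicted on observed; the through-origin
    slope is the zero-intercept least-squares fit.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed/predicted must be equal-length 1-D, n >= 2")
    denom = float(np.sum((obs - train_mean) ** 2))
    if denom == 0:
        raise ValueError("all observed values equal the training mean")
    sse = float(np.sum((obs - pred) ** 2))
    r2_pred = 1.0 - sse / denom
    rmse = math.sqrt(sse / obs.size)
    sxx = float(np.sum((obs - obs.mean()) ** 2))
    if sxx > 0:
        slope = float(np.sum((obs - obs.mean()) * (pred - pred.mean())) / sxx)
        intercept = float(pred.mean() - slope * obs.mean())
    else:
        slope, intercept = 0.0, float(pred.mean())
    origin_slope = float(np.sum(obs * pred) / np.sum(obs * obs))
    return PredictionReport(
        r2_pred=r2_pred,
        rmse_pred=rmse,
        fit_slope=slope,
        fit_intercept=intercept,
        origin_slope=origin_slope,
        mean_shift=float(pred.mean() - obs.mean()),
    )
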