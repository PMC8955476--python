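"""Internal and external model validation.

Internal: leave-one-out and leave-many-out cross-validation, and
Y-scrambling (response permutation) to estimate the chance-correlation
baseline. External: the Q2F1/Q2F2/Q2F3 family, squared Pearson correlation
and Lin's concordance on a held-out prediction set. Kxy summarises the
joint correlation structure of a descriptor block (optionally with the
response) through the eigenvalue spread of its correlation matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import DatasetError, QsarDataset
from .mlr import (
    ModelEquation,
    SingularDesignError,
    concordance_ccc,
    design_matrix,
    fit_ols,
    predict,
)

__all__ = [
    "CrossValReport",
    "ScrambleReport",
    "ExternalReport",
    "q2_loo",
    "q2_lmo",
    "y_scramble",
    "external_validation",
    "kxy_index",
]


@dataclass
class CrossValReport:
    """Cross-validated performance block (LOO or LMO)."""

    Q2: float
    PRESS: float
    RMSE_cv: float
    MAE_cv: float
    CCC_cv: float
    method: str = "loo"
    iterations: int = 0
    leave_out_fraction: float = 0.0
    seed: int | None = None
    per_iteration: list[float] = field(default_factory=list)

    # kept as properties so callers can use the field-style names too
    @property
    def Q2_LOO(self) -> float:
        return self.Q2 if self.method == "loo" else math.nan

    @property
    def Q2_LMO(self) -> float:
        return self.Q2 if self.method == "lmo" else math.nan

    def as_dict(self) -> dict:
        return {
            "method": self.method, "Q2": self.Q2, "PRESS": self.PRESS,
            "RMSE_cv": self.RMSE_cv, "MAE_cv": self.MAE_cv, "CCC_cv": self.CCC_cv,
            "iterations": self.iterations,
            "leave_out_fraction": self.leave_out_fraction, "seed": self.seed,
            "per_iteration": list(self.per_iteration),
        }


@dataclass
class ScrambleReport:
    """Y-scrambling (response permutation) null summary."""

    R2_Yscr: float
    Q2_Yscr: float
    iterations: int
    seed: int
    Kxy: float
    per_iteration_R2: list[float]
    per_iteration_Q2: list[float]

    def as_dict(self) -> dict:
        return {
            "R2_Yscr": self.R2_Yscr, "Q2_Yscr": self.Q2_Yscr,
            "iterations": self.iterations, "seed": self.seed, "Kxy": self.Kxy,
            "per_iteration_R2": list(self.per_iteration_R2),
            "per_iteration_Q2": list(self.per_iteration_Q2),
        }


@dataclass
class ExternalReport:
    """Prediction-set validation block."""

    Q2_F1: float
    Q2_F2: float
    Q2_F3: float
    R2_ext: float
    CCC_ext: float
    PRESS_ext: float
    RMSE_ext: float
    MAE_ext: float
    n_test: int

    def as_dict(self) -> dict:
        return {
            "Q2_F1": self.Q2_F1, "Q2_F2": self.Q2_F2, "Q2_F3": self.Q2_F3,
            "R2_ext": self.R2_ext, "CCC_ext": self.CCC_ext,
            "PRESS_ext": self.PRESS_ext, "RMSE_ext": self.RMSE_ext,
            "MAE_ext": self.MAE_ext, "n_test": self.n_test,
        }


def _loo_predictions_shortcut(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deleted predictions via the hat-matrix identity e_i/(1 - h_ii)."""
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    # hat diagonal from the thin QR of A
    Q, _ = np.linalg.qr(A)
    h = np.sum(Q * Q, axis=1)
    if np.any(h >= 1.0 - 1e-12):
        bad = int(np.argmax(h))
        raise SingularDesignError(
            f"leave-one-out design rank deficient when removing row {bad} (h = {h[bad]:.6f})"
        )
    deleted = resid / (1.0 - h)
    return y - deleted


def _loo_predictions_refit(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force deleted predictions: refit without each row in turn."""
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta, *_ = np.linalg.lstsq(A[mask], y[mask], rcond=None)
        out[i] = A[i] @ beta
    return out


def q2_loo(
    train: QsarDataset,
    descriptor_subset: Sequence[str] | None = None,
    method: str = "shortcut",
) -> CrossValReport:
    """Leave-one-out cross-validation: Q2 = 1 - PRESS/TSS.

    ``method='shortcut'`` uses the deleted-residual identity e/(1-h);
    ``method='refit'`` performs the n explicit refits (identical result,
    kept as an internal cross-check).
    """
    names = train._check_subset(descriptor_subset)
    y = train.activity_vector()
    A = design_matrix(train, names)
    n, k = A.shape
    if n < k + 2:
        raise DatasetError(f"need at least p + 3 = {k + 2} compounds for LOO, have {n}")
    TSS = float(np.sum((y - y.mean()) ** 2))
    if TSS == 0.0:
        raise DatasetError("constant observed vector: Q2 undefined (TSS = 0)")
    if method == "shortcut":
        yhat = _loo_predictions_shortcut(A, y)
    elif method == "refit":
        yhat = _loo_predictions_refit(A, y)
    else:
        raise ValueError(f"unknown LOO method {method!r}")
    deleted = y - yhat
    PRESS = float(deleted @ deleted)
    return CrossValReport(
        Q2=1.0 - PRESS / TSS,
        PRESS=PRESS,
        RMSE_cv=math.sqrt(PRESS / n),
        MAE_cv=float(np.mean(np.abs(deleted))),
        CCC_cv=concordance_ccc(y, yhat),
        method="loo",
        iterations=n,
    )


def q2_lmo(
    train: QsarDataset,
    descriptor_subset: Sequence[str] | None = None,
    leave_out_fraction: float = 0.30,
    iterations: int = 2000,
    seed: int = 0,
) -> CrossValReport:
    """Leave-many-out cross-validation.

    Each iteration removes ``round(fraction * n)`` randomly chosen compounds,
    refits, and scores the left-out block with
    Q2 = 1 - sum((y - yhat)^2) / sum((y - ybar_retained)^2). The report's Q2
    is the mean over iterations; per-iteration values are retained for
    scatter plots.
    """
    names = train._check_subset(descriptor_subset)
    y = train.activity_vector()
    A = design_matrix(train, names)
    n, k = A.shape
    n_out = int(round(leave_out_fraction * n))
    if n_out < 1:
        raise DatasetError(
            f"leave_out_fraction {leave_out_fraction} removes 0 of {n} compounds"
        )
    if n - n_out < k + 1:
        raise DatasetError(
            f"leaving out {n_out} of {n} compounds leaves too few to fit p = {k - 1}"
        )
    rng = np.random.default_rng(seed)
    q2s = np.empty(iterations)
    press_total = 0.0
    abs_total = 0.0
    count = 0
    for it in range(iterations):
        out_idx = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out_idx] = False
        beta, *_ = np.linalg.lstsq(A[mask], y[mask], rcond=None)
        e_out = y[out_idx] - A[out_idx] @ beta
        denom = np.sum((y[out_idx] - y[mask].mean()) ** 2)
        q2s[it] = 1.0 - float(e_out @ e_out) / denom if denom > 0 else math.nan
        press_total += float(e_out @ e_out)
        abs_total += float(np.sum(np.abs(e_out)))
        count += n_out
    PRESS = press_total / iterations  # mean left-out SSE per iteration
    return CrossValReport(
        Q2=float(np.nanmean(q2s)),
        PRESS=PRESS,
        RMSE_cv=math.sqrt(press_total / count),
        MAE_cv=abs_total / count,
        CCC_cv=math.nan,
        method="lmo",
        iterations=iterations,
        leave_out_fraction=leave_out_fraction,
        seed=seed,
        per_iteration=q2s.tolist(),
    )


def y_scramble(
    train: QsarDataset,
    descriptor_subset: Sequence[str] | None = None,
    iterations: int = 2000,
    seed: int = 0,
) -> ScrambleReport:
    """Response permutation null: refit after each of ``iterations`` shuffles.

    Records per-iteration R2 and Q2(LOO); their means estimate the
    chance-correlation baseline (analytically E[R2] = p/(n-1) for an
    exchangeable response). Permutations are drawn uniformly and
    independently per iteration from the seed.
    """
    names = train._check_subset(descriptor_subset)
    y = train.activity_vector()
    A = design_matrix(train, names)
    n, k = A.shape
    p = k - 1
    if n < k + 2:
        raise DatasetError("too few compounds for scrambled LOO refits")
    TSS = float(np.sum((y - y.mean()) ** 2))
    if TSS == 0.0:
        raise DatasetError("constant observed vector")
    # hat diagonal is permutation-invariant: compute once
    Q, _ = np.linalg.qr(A)
    h = np.sum(Q * Q, axis=1)
    one_minus_h = 1.0 - h
    if np.any(one_minus_h <= 1e-12):
        raise SingularDesignError("a leave-one-out design is rank deficient")
    rng = np.random.default_rng(seed)
    r2s = np.empty(iterations)
    q2s = np.empty(iterations)
    proj = Q @ Q.T  # n x n hat matrix; n is small in QSAR training sets
    for it in range(iterations):
        ys = y[rng.permutation(n)] if p > 0 else y.copy()
        if p == 0:
            r2s[it] = 0.0
            q2s[it] = 1.0 - float(np.sum(((ys - ys.mean()) / one_minus_h) ** 2)) / TSS
            continue
        resid = ys - proj @ ys
        RSS = float(resid @ resid)
        r2s[it] = 1.0 - RSS / TSS  # TSS invariant under permutation
        deleted = resid / one_minus_h
        q2s[it] = 1.0 - float(deleted @ deleted) / TSS
    kxy = kxy_index(train, names, include_response=True) if names else math.nan
    return ScrambleReport(
        R2_Yscr=float(r2s.mean()),
        Q2_Yscr=float(q2s.mean()),
        iterations=iterations,
        seed=seed,
        Kxy=kxy,
        per_iteration_R2=r2s.tolist(),
        per_iteration_Q2=q2s.tolist(),
    )


def external_validation(
    model: ModelEquation,
    train: QsarDataset,
    test: QsarDataset,
) -> ExternalReport:
    """Prediction-set metrics for a fixed equation.

    Q2F1 references the training mean on the test set, Q2F2 the test mean,
    and Q2F3 compares per-compound error variance against the training
    response variance. With a single test compound Q2F2 is undefined (test
    TSS = 0) and reported as NaN; the others are still computed.
    """
    if len(test) == 0:
        raise DatasetError("empty prediction set")
    y_test = test.activity_vector()
    y_train = train.activity_vector()
    yhat = predict(model, test)
    e = y_test - yhat
    press = float(e @ e)
    n_test = len(y_test)
    n_train = len(y_train)
    ss_train_mean = float(np.sum((y_test - y_train.mean()) ** 2))
    ss_test_mean = float(np.sum((y_test - y_test.mean()) ** 2))
    ss_train = float(np.sum((y_train - y_train.mean()) ** 2))
    q2f1 = 1.0 - press / ss_train_mean if ss_train_mean > 0 else math.nan
    q2f2 = 1.0 - press / ss_test_mean if ss_test_mean > 0 else math.nan
    q2f3 = 1.0 - (press / n_test) / (ss_train / n_train) if ss_train > 0 else math.nan
    if ss_test_mean > 0 and np.std(yhat) > 0:
        r = float(np.corrcoef(y_test, yhat)[0, 1])
        r2_ext = r * r
    else:
        r2_ext = math.nan
    return ExternalReport(
        Q2_F1=q2f1,
        Q2_F2=q2f2,
        Q2_F3=q2f3,
        R2_ext=r2_ext,
        CCC_ext=concordance_ccc(y_test, yhat),
        PRESS_ext=press,
        RMSE_ext=math.sqrt(press / n_test),
        MAE_ext=float(np.mean(np.abs(e))),
        n_test=n_test,
    )


def kxy_index(
    dataset: QsarDataset,
    descriptor_subset: Sequence[str] | None = None,
    include_response: bool = False,
) -> float:
    """Multivariate correlation index K in [0, 1].

    K = sum_i |lambda_i / sum(lambda) - 1/m| / (2(m-1)/m), with lambda the
    eigenvalues of the Pearson correlation matrix of the m variables
    (response appended when ``include_response``). K = 0 for mutually
    uncorrelated variables, 1 for a perfectly collinear block.
    """
    names = dataset._check_subset(descriptor_subset)
    cols = [dataset.descriptor_matrix([nm])[:, 0] for nm in names]
    labels = list(names)
    if include_response:
        cols.append(dataset.activity_vector())
        labels.append("<response>")
    m = len(cols)
    if m < 2:
        raise DatasetError("Kxy needs at least two variables")
    for lab, c in zip(labels, cols):
        if np.std(c) == 0:
            raise DatasetError(f"variable {lab!r} has zero variance")
    M = np.column_stack(cols)
    C = np.corrcoef(M, rowvar=False)
    lam = np.linalg.eigvalsh(C)
    lam = np.clip(lam, 0.0, None)
    frac = lam / lam.sum()
    K = float(np.sum(np.abs(frac - 1.0 / m)) / (2.0 * (m - 1) / m))
    return K


def save_report(report, path: str | Path) -> None:
    """Serialize any validation report to structured text (JSON)."""
    Path(path).write_text(json.dumps(report.as_dict(), indent=1), encoding="utf-8")
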