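"""Ordinary-least-squares regression core and the training statistics block.

Conventions follow the chemometrics (QSARINS-style) reporting practice:
RMSE uses denominator n, the standard error s uses n - p - 1, Lin's
concordance correlation coefficient uses population (1/n) moments, and
Friedman's lack-of-fit penalises RSS for model size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dataset import DatasetError, QsarDataset

__all__ = [
    "ModelEquation",
    "FitStatistics",
    "SingularDesignError",
    "fit_ols",
    "predict",
    "compute_fit_statistics",
    "concordance_ccc",
    "design_matrix",
]


class SingularDesignError(ValueError):
    """Raised when the intercept-augmented design matrix is rank deficient."""


@dataclass
class ModelEquation:
    """A fixed linear QSAR equation: activity = intercept + sum(coef * descriptor)."""

    intercept: float
    coefficients: dict[str, float]
    name: str = "model"
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(set(self.coefficients)):
            raise ValueError("coefficient names must be unique")
        if any(not k for k in self.coefficients):
            raise ValueError("coefficient names must be non-empty")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    # -- serialization: lossless at 15 significant digits ------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "provenance": self.provenance,
                "intercept": float(repr(float(f"{self.intercept:.15g}"))),
                "coefficients": [
                    {"name": k, "value": float(f"{v:.15g}")}
                    for k, v in self.coefficients.items()
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelEquation":
        obj = json.loads(text)
        coeffs = obj["coefficients"]
        if isinstance(coeffs, list):
            coeffs = {c["name"]: c["value"] for c in coeffs}
        return cls(
            intercept=obj["intercept"],
            coefficients={k: float(v) for k, v in coeffs.items()},
            name=obj.get("name", "model"),
            provenance=obj.get("provenance", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ModelEquation":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


@dataclass
class FitStatistics:
    """Training-set goodness-of-fit block."""

    n: int
    p: int
    R2: float
    R2_adj: float
    RMSE: float
    MAE: float
    RSS: float
    TSS: float
    s: float
    F: float
    LOF: float
    CCC: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n, "p": self.p, "R2": self.R2, "R2_adj": self.R2_adj,
            "RMSE": self.RMSE, "MAE": self.MAE, "RSS": self.RSS, "TSS": self.TSS,
            "s": self.s, "F": self.F, "LOF": self.LOF, "CCC": self.CCC,
        }


def design_matrix(dataset: QsarDataset, subset: Sequence[str] | None = None) -> np.ndarray:
    """Intercept-augmented design matrix [1 | X] for the selected descriptors."""
    X = dataset.descriptor_matrix(subset)
    if not np.isfinite(X).all():
        raise DatasetError("design matrix contains non-finite descriptor values")
    return np.column_stack([np.ones(len(X)), X])


def _check_rank(A: np.ndarray, names: Sequence[str]) -> None:
    # SVD-based rank check; on deficiency, name the dependent columns via
    # pivoted QR so the error is actionable.
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        from scipy.linalg import qr

        _, R, piv = qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        bad = [piv[k] for k in range(len(diag)) if diag[k] <= tol]
        labels = ["intercept"] + list(names)
        collinear = [labels[j] for j in sorted(bad)]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
            f"collinear columns: {collinear}"
        )


def fit_ols(
    train: QsarDataset,
    descriptor_subset: Sequence[str] | None = None,
    lof_smoothness: float = 1.0,
    name: str = "ols_fit",
) -> tuple[ModelEquation, FitStatistics]:
    """Least-squares fit of activity on the selected descriptors plus intercept.

    Solved by SVD (numpy ``lstsq``), which is stable on near-collinear
    designs; an exactly rank-deficient design raises
    :class:`SingularDesignError` naming the collinear columns.
    """
    names = train._check_subset(descriptor_subset)
    y = train.activity_vector()
    A = design_matrix(train, names)
    n, k = A.shape
    p = k - 1
    if n < p + 2:
        raise DatasetError(f"need at least p + 2 = {p + 2} training compounds, have {n}")
    _check_rank(A, names)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    model = ModelEquation(
        intercept=float(beta[0]),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        name=name,
        provenance=f"OLS fit on {n} training compounds",
    )
    yhat = A @ beta
    stats = compute_fit_statistics(y, yhat, p, lof_smoothness=lof_smoothness)
    return model, stats


def predict(model: ModelEquation, data: QsarDataset) -> np.ndarray:
    """Apply a fixed equation; output order matches the dataset order."""
    missing = [nm for nm in model.descriptor_names if nm not in data.descriptor_names]
    if missing:
        raise DatasetError(f"dataset lacks model descriptors {missing}")
    X = data.descriptor_matrix(model.descriptor_names)
    coef = np.array([model.coefficients[nm] for nm in model.descriptor_names])
    return model.intercept + X @ coef


def concordance_ccc(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with population moments.

    CCC = 2*Sxy / (Sxx + Syy + n*(xbar - ybar)^2) where S are centred sums of
    squares/products; penalises both scatter and location/scale bias.
    """
    o = np.asarray(observed, dtype=float)
    pr = np.asarray(predicted, dtype=float)
    n = o.size
    do, dp = o - o.mean(), pr - pr.mean()
    denom = do @ do + dp @ dp + n * (o.mean() - pr.mean()) ** 2
    if denom == 0:
        return 1.0  # both vectors constant and equal
    return float(2.0 * (do @ dp) / denom)


def compute_fit_statistics(
    observed: np.ndarray,
    predicted: np.ndarray,
    p: int,
    lof_smoothness: float = 1.0,
    lof_basis_terms: int | None = None,
) -> FitStatistics:
    """Goodness-of-fit block for an OLS model with p descriptors.

    R2 = 1 - RSS/TSS, R2_adj = 1 - (1-R2)(n-1)/(n-p-1), RMSE = sqrt(RSS/n),
    s = sqrt(RSS/(n-p-1)), F = (R2/p)/((1-R2)/(n-p-1)), and Friedman's
    LOF = (RSS/n) / (1 - (c + d*p)/n)^2 with smoothness d and basis-term
    count c (default c = p).
    """
    o = np.asarray(observed, dtype=float)
    pr = np.asarray(predicted, dtype=float)
    if o.shape != pr.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-D vectors of equal length")
    n = o.size
    if n < 2:
        raise ValueError("need at least two observations")
    resid = o - pr
    RSS = float(resid @ resid)
    TSS = float(np.sum((o - o.mean()) ** 2))
    if TSS == 0.0:
        raise DatasetError("constant observed vector: R2 undefined (TSS = 0)")
    R2 = 1.0 - RSS / TSS
    RMSE = math.sqrt(RSS / n)
    MAE = float(np.mean(np.abs(resid)))
    dof = n - p - 1
    if p >= 1 and dof > 0:
        R2_adj = 1.0 - (1.0 - R2) * (n - 1) / dof
        s = math.sqrt(RSS / dof)
        F = (R2 / p) / ((1.0 - R2) / dof) if R2 < 1.0 else math.inf
    else:
        R2_adj, s, F = R2, math.nan, math.nan
    c = p if lof_basis_terms is None else lof_basis_terms
    shrink = 1.0 - (c + lof_smoothness * p) / n
    LOF = (RSS / n) / shrink**2 if shrink > 0 else math.inf
    CCC = concordance_ccc(o, pr)
    return FitStatistics(
        n=n, p=p, R2=R2, R2_adj=R2_adj, RMSE=RMSE, MAE=MAE,
        RSS=RSS, TSS=TSS, s=s, F=F, LOF=LOF, CCC=CCC,
    )
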