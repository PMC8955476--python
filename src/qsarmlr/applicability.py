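"""Leverage-based applicability domain (Williams plot data) and outlier handling.

A query compound's leverage h = x (X'X)^-1 x' against the intercept-augmented
training design X measures how far it sits from the training descriptor
cloud; h above the warning value h* = 3(p+1)/n marks a structural (X)
outlier. Standardized residuals beyond 3 sigma mark response (Y) outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .dataset import DatasetError, QsarDataset
from .mlr import ModelEquation, SingularDesignError, design_matrix, fit_ols, predict

__all__ = [
    "ADReport",
    "leverage_values",
    "warning_leverage",
    "williams_report",
    "detect_and_remove_outliers",
]


@dataclass
class ADReport:
    """Per-compound Williams-plot data plus the scalar thresholds."""

    ids: list[str]
    set_labels: list[str]
    leverage: np.ndarray
    std_residual: np.ndarray
    h_star: float
    rmse_train: float
    rmse_ext: float

    @property
    def x_outlier(self) -> np.ndarray:
        return self.leverage > self.h_star

    @property
    def y_outlier(self) -> np.ndarray:
        return np.abs(self.std_residual) > 3.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "set": self.set_labels,
                "leverage": self.leverage,
                "std_residual": self.std_residual,
                "x_outlier": self.x_outlier,
                "y_outlier": self.y_outlier,
            }
        )

    def save(self, path: str | Path) -> None:
        """Delimited table with a scalar header block — Williams-plot input."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# h_star\t{self.h_star:.10g}\n")
            fh.write(f"# rmse_train\t{self.rmse_train:.10g}\n")
            fh.write(f"# rmse_ext\t{self.rmse_ext:.10g}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def warning_leverage(p: int, n_train: int) -> float:
    """Warning leverage h* = 3(p + 1)/n."""
    if n_train <= 0:
        raise DatasetError("n_train must be positive")
    return 3.0 * (p + 1) / n_train


def leverage_values(
    train: QsarDataset,
    query: QsarDataset,
    descriptor_subset: Sequence[str] | None = None,
) -> np.ndarray:
    """h_i = x_i (X'X)^-1 x_i' for each query row against the training design.

    Querying the training compounds against their own design reproduces the
    hat-matrix diagonal.
    """
    names = train._check_subset(descriptor_subset)
    X = design_matrix(train, names)
    Xq = design_matrix(query.with_descriptors(names) if query is not train else query, names)
    # h = row-wise quadratic form via Cholesky of X'X
    G = X.T @ X
    try:
        cho = linalg.cho_factor(G)
    except linalg.LinAlgError as exc:
        raise SingularDesignError(f"X'X is singular: {exc}") from exc
    sol = linalg.cho_solve(cho, Xq.T)
    return np.einsum("ij,ji->i", Xq, sol)


def williams_report(
    model: ModelEquation,
    train: QsarDataset,
    test: QsarDataset | None = None,
) -> ADReport:
    """Williams-plot data: leverage and standardized residual per compound.

    Training residuals are standardized by the training RMSE of the given
    equation; test prediction errors by the external RMSE. Flags: X outlier
    when h > h* = 3(p+1)/n_train, Y outlier when |standardized residual| > 3.
    """
    names = model.descriptor_names
    if not train.has_activity:
        raise DatasetError("training set lacks activities")
    y_tr = train.activity_vector()
    e_tr = y_tr - predict(model, train)
    n_tr = len(train)
    rmse_tr = math.sqrt(float(e_tr @ e_tr) / n_tr)
    h_tr = leverage_values(train, train, names)
    h_star = warning_leverage(len(names), n_tr)

    ids = list(train.ids)
    labels = ["train"] * n_tr
    if rmse_tr == 0.0:
        sr_tr = np.zeros(n_tr)
    else:
        sr_tr = e_tr / rmse_tr
    lev = [h_tr]
    srs = [sr_tr]
    rmse_ext = math.nan
    if test is not None and len(test) > 0:
        h_te = leverage_values(train, test, names)
        if test.has_activity:
            e_te = test.activity_vector() - predict(model, test)
            rmse_ext = math.sqrt(float(e_te @ e_te) / len(test))
            scale = rmse_ext if rmse_ext > 0 else rmse_tr
            if scale == 0.0:
                if np.any(e_te != 0):
                    raise DatasetError(
                        "zero training and external RMSE with nonzero test errors: "
                        "cannot standardize residuals"
                    )
                sr_te = np.zeros(len(test))
            else:
                sr_te = e_te / scale
        else:
            sr_te = np.full(len(test), math.nan)
        ids += list(test.ids)
        labels += ["test"] * len(test)
        lev.append(h_te)
        srs.append(sr_te)
    return ADReport(
        ids=ids,
        set_labels=labels,
        leverage=np.concatenate(lev),
        std_residual=np.concatenate(srs),
        h_star=h_star,
        rmse_train=rmse_tr,
        rmse_ext=rmse_ext,
    )


def detect_and_remove_outliers(
    dataset: QsarDataset,
    descriptor_subset: Sequence[str] | None = None,
    max_rounds: int = 5,
) -> tuple[QsarDataset, list[dict]]:
    """Iterative outlier pruning on a training set.

    Each round refits OLS on the remaining compounds, flags Y outliers
    (|standardized residual| > 3, processed first, largest first) then X
    outliers (h > h*, largest leverage first), removes all flagged compounds,
    and repeats until no flags or ``max_rounds``. Removal stops with a
    ``warning`` log entry rather than leaving fewer than p + 3 compounds.
    """
    names = dataset._check_subset(descriptor_subset)
    current = dataset
    log: list[dict] = []
    p = len(names)
    for round_no in range(1, max_rounds + 1):
        model, _ = fit_ols(current, names)
        report = williams_report(model, current)
        sr = report.std_residual
        h = report.leverage
        flagged: list[tuple[str, str, float]] = []
        y_idx = np.where(np.abs(sr) > 3.0)[0]
        for i in sorted(y_idx, key=lambda i: -abs(sr[i])):
            flagged.append((report.ids[i], "y_outlier", float(sr[i])))
        x_idx = np.where((h > report.h_star) & (np.abs(sr) <= 3.0))[0]
        for i in sorted(x_idx, key=lambda i: -h[i]):
            flagged.append((report.ids[i], "x_outlier", float(h[i])))
        if not flagged:
            break
        remove_ids = []
        for cid, flag, value in flagged:
            if len(current) - len(remove_ids) - 1 < p + 3:
                log.append(
                    {"round": round_no, "id": cid, "flag": "warning",
                     "value": value,
                     "note": "removal stopped: too few compounds would remain"}
                )
                break
            remove_ids.append(cid)
            log.append({"round": round_no, "id": cid, "flag": flag, "value": value})
        if not remove_ids:
            break
        keep = [cid for cid in current.ids if cid not in set(remove_ids)]
        current = current.subset_by_ids(keep)
    return current, log
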