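"""Packaged reference fixtures.

- ``table3_dataset``: the published 26-compound uracil–coumarin MCF7 series
  (four 2D descriptors, observed pIC50, and the reference model's printed
  predictions/residuals). The source table prints every row twice; the CSV
  keeps all 52 printed rows and the loader collapses the reprint by default.
- ``table5_designed``: 12 designed pyrimidine–coumarin–triazole compounds
  with the same descriptors and the printed reference predictions (no
  observed activity).
- ``equations``: the four published model equations (intercept + named
  coefficients), of which model 2 is the reference "best" model.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from ..dataset import QsarDataset, load_dataset
from ..mlr import ModelEquation

__all__ = [
    "DESCRIPTORS",
    "load_table3",
    "load_table5",
    "table3_frame",
    "table5_frame",
    "model_equation",
]

DESCRIPTORS = ["AATS7s", "MATS2c", "SpMin3_Bhi", "MDEC-33"]


def _path(name: str):
    return resources.files(__package__) / name


def table3_frame() -> pd.DataFrame:
    """The dataset table as printed (52 rows incl. the reprint block)."""
    with resources.as_file(_path("table3_dataset.csv")) as p:
        return pd.read_csv(p)


def table5_frame() -> pd.DataFrame:
    """The designed-compound table with the printed reference predictions."""
    with resources.as_file(_path("table5_designed.csv")) as p:
        return pd.read_csv(p)


def load_table3(dedupe: bool = True) -> QsarDataset:
    """The reference dataset (26 unique compounds with ``dedupe=True``)."""
    with resources.as_file(_path("table3_dataset.csv")) as p:
        return load_dataset(
            p,
            id_column="compound_id",
            activity_column="observed_pIC50",
            dedupe=dedupe,
            descriptor_columns=DESCRIPTORS,
        )


def load_table5() -> QsarDataset:
    """The 12 designed compounds (descriptors only, no activity)."""
    with resources.as_file(_path("table5_designed.csv")) as p:
        return load_dataset(
            p,
            id_column="compound_id",
            descriptor_columns=DESCRIPTORS,
        )


def model_equation(number: int = 2) -> ModelEquation:
    """One of the four published equations (1-4); 2 is the best model."""
    if number not in (1, 2, 3, 4):
        raise ValueError("equation number must be 1, 2, 3 or 4")
    text = _path("equations.json").read_text(encoding="utf-8")
    obj = json.loads(text)[f"model{number}"]
    return ModelEquation(
        intercept=obj["intercept"],
        coefficients=dict(obj["coefficients"]),
        name=obj["name"],
        provenance=obj["provenance"],
    )
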