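"""Dataset model, delimited-table I/O, unit conversion, descriptor filtering, splitting.

A :class:`QsarDataset` is an ordered collection of compounds, each carrying a
text id, a fixed set of named molecular-descriptor values, an optional
activity (pIC50, i.e. -log10 of the molar IC50) and a train/test label.
Descriptors are consumed as given — this package never computes them from
structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "QsarDataset",
    "FilterPolicy",
    "SplitAssignment",
    "DatasetError",
    "load_dataset",
    "save_dataset",
    "convert_ic50_to_pic50",
    "filter_descriptors",
    "split_train_test",
]

SET_LABELS = ("train", "test", "unassigned")

# multiplier taking a concentration in the given unit to mol/L
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


class DatasetError(ValueError):
    """Raised for malformed input tables or invalid dataset operations."""


@dataclass
class CompoundRecord:
    """One compound: id, named descriptor values, optional activity, set label."""

    id: str
    descriptors: dict[str, float]
    activity: float | None = None
    set_label: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.id:
            raise DatasetError("compound id must be non-empty")
        if self.set_label not in SET_LABELS:
            raise DatasetError(f"invalid set_label {self.set_label!r}")


class QsarDataset:
    """Ordered compounds sharing one descriptor schema.

    Parameters
    ----------
    records
        Compound records; every record must carry exactly ``descriptor_names``.
    descriptor_names
        Column order of the descriptors. Defaults to the key order of the
        first record.
    """

    def __init__(
        self,
        records: Sequence[CompoundRecord],
        descriptor_names: Sequence[str] | None = None,
    ) -> None:
        records = list(records)
        if descriptor_names is None:
            if not records:
                raise DatasetError("cannot infer descriptor names from an empty dataset")
            descriptor_names = list(records[0].descriptors)
        self.descriptor_names: list[str] = list(descriptor_names)
        name_set = set(self.descriptor_names)
        if len(name_set) != len(self.descriptor_names):
            raise DatasetError("duplicate descriptor names")
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise DatasetError(f"duplicate compound id {rec.id!r}")
            seen.add(rec.id)
            if set(rec.descriptors) != name_set:
                raise DatasetError(
                    f"compound {rec.id!r} does not carry the dataset descriptor schema"
                )
        self.records: list[CompoundRecord] = records

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def has_activity(self) -> bool:
        return all(r.activity is not None for r in self.records)

    # -- array views -------------------------------------------------------
    def descriptor_matrix(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """n x p array of descriptor values in ``subset`` (default: all) order."""
        names = self._check_subset(subset)
        if not self.records:
            return np.empty((0, len(names)))
        return np.array(
            [[r.descriptors[name] for name in names] for r in self.records], dtype=float
        )

    def activity_vector(self) -> np.ndarray:
        if not self.has_activity:
            missing = [r.id for r in self.records if r.activity is None][:5]
            raise DatasetError(f"dataset lacks activities (e.g. compounds {missing})")
        return np.array([r.activity for r in self.records], dtype=float)

    def _check_subset(self, subset: Sequence[str] | None) -> list[str]:
        if subset is None:
            return list(self.descriptor_names)
        unknown = [s for s in subset if s not in self.descriptor_names]
        if unknown:
            raise DatasetError(f"unknown descriptors {unknown}")
        return list(subset)

    # -- subsetting --------------------------------------------------------
    def subset_by_ids(self, ids: Iterable[str]) -> "QsarDataset":
        wanted = set(ids)
        unknown = wanted - set(self.ids)
        if unknown:
            raise DatasetError(f"ids not in dataset: {sorted(unknown)}")
        recs = [replace(r, descriptors=dict(r.descriptors)) for r in self.records if r.id in wanted]
        return QsarDataset(recs, self.descriptor_names)

    def training_set(self) -> "QsarDataset":
        return QsarDataset(
            [replace(r, descriptors=dict(r.descriptors)) for r in self.records if r.set_label == "train"],
            self.descriptor_names,
        )

    def test_set(self) -> "QsarDataset":
        return QsarDataset(
            [replace(r, descriptors=dict(r.descriptors)) for r in self.records if r.set_label == "test"],
            self.descriptor_names,
        )

    def with_descriptors(self, names: Sequence[str]) -> "QsarDataset":
        names = self._check_subset(names)
        recs = [
            replace(r, descriptors={k: r.descriptors[k] for k in names})
            for r in self.records
        ]
        return QsarDataset(recs, names)

    # -- frame conversion --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {name: [r.descriptors[name] for r in self.records] for name in self.descriptor_names}
        )
        df.insert(0, "compound_id", self.ids)
        if any(r.activity is not None for r in self.records):
            df["activity"] = [r.activity for r in self.records]
        if any(r.set_label != "unassigned" for r in self.records):
            df["set"] = [r.set_label for r in self.records]
        return df


@dataclass(frozen=True)
class FilterPolicy:
    """Descriptor pre-filtering rules.

    ``constant_fraction_cutoff``: drop a descriptor whose modal value occurs in
    more than this fraction of compounds. ``pairwise_corr_cutoff``: absolute
    Pearson r above which one member of a descriptor pair is dropped.
    """

    constant_fraction_cutoff: float = 0.5
    pairwise_corr_cutoff: float = 0.85
    drop_missing: bool = True

    def __post_init__(self) -> None:
        for name in ("constant_fraction_cutoff", "pairwise_corr_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise DatasetError(f"{name} must lie in (0, 1], got {v}")


@dataclass(frozen=True)
class SplitAssignment:
    """Train/test split request.

    ``ratio`` is the train:test proportion (5 means 5:1). ``method`` is
    ``random`` (seeded) or ``activity_ranked`` (every (ratio+1)-th compound of
    the activity-sorted order goes to the test set). Explicit ``train_ids`` /
    ``test_ids`` override both, which is how externally published memberships
    are honoured.
    """

    ratio: float = 5.0
    method: str = "random"
    seed: int = 0
    train_ids: tuple[str, ...] | None = None
    test_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("random", "activity_ranked"):
            raise DatasetError(f"unknown split method {self.method!r}")
        if self.ratio <= 0:
            raise DatasetError("ratio must be positive")
        if self.train_ids is not None and self.test_ids is not None:
            if set(self.train_ids) & set(self.test_ids):
                raise DatasetError("train_ids and test_ids overlap")


# ---------------------------------------------------------------------------
# I/O


def _parse_cell(value, row_label, column) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    s = str(value).strip()
    if s in ("", "NA", "NaN", "nan"):
        return math.nan
    # tolerate the unicode minus that typeset tables use
    s = s.replace("−", "-")
    try:
        return float(s)
    except ValueError:
        raise DatasetError(
            f"non-numeric value {value!r} at row {row_label}, column {column!r}"
        ) from None


def load_dataset(
    path: str | Path,
    id_column: str | None = None,
    activity_column: str | None = None,
    dedupe: bool = False,
    sep: str | None = None,
    descriptor_columns: Sequence[str] | None = None,
) -> QsarDataset:
    """Read a delimited descriptor table (comma default, tab accepted).

    Every non-id, non-activity column is treated as a descriptor unless
    ``descriptor_columns`` restricts the choice. Empty cells and ``NA`` parse
    as missing (NaN); any other non-numeric cell is an error naming row and
    column. With ``dedupe=True`` rows identical in all descriptors and the
    activity collapse to the first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise DatasetError(f"empty input file: {path}")
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    if df.shape[1] == 0:
        raise DatasetError(f"no columns in {path}")
    if id_column is None:
        id_column = df.columns[0]
    if id_column not in df.columns:
        raise DatasetError(f"id column {id_column!r} not found in {path}")
    if activity_column is not None and activity_column not in df.columns:
        raise DatasetError(f"activity column {activity_column!r} not found in {path}")

    if descriptor_columns is None:
        descriptor_columns = [
            c for c in df.columns if c != id_column and c != activity_column
        ]
    records: list[CompoundRecord] = []
    seen_payload: set[tuple] = set()
    seen_ids: set[str] = set()
    for i, row in df.iterrows():
        cid = str(row[id_column]).strip()
        if not cid:
            raise DatasetError(f"empty compound id at row {i + 2}")
        desc = {c: _parse_cell(row[c], i + 2, c) for c in descriptor_columns}
        act = (
            _parse_cell(row[activity_column], i + 2, activity_column)
            if activity_column is not None
            else None
        )
        if act is not None and math.isnan(act):
            act = None
        payload = (tuple(desc[c] for c in descriptor_columns), act)
        if dedupe:
            if payload in seen_payload:
                continue
            seen_payload.add(payload)
        if cid in seen_ids:
            raise DatasetError(f"duplicate compound id {cid!r} (row {i + 2})")
        seen_ids.add(cid)
        records.append(CompoundRecord(cid, desc, act))
    return QsarDataset(records, descriptor_columns)


def save_dataset(dataset: QsarDataset, path: str | Path, sep: str = ",") -> None:
    """Write the dataset back to a delimited table (full float precision)."""
    df = dataset.to_frame()
    df.to_csv(path, sep=sep, index=False, float_format="%.17g", encoding="utf-8")


# ---------------------------------------------------------------------------
# Activity units


def convert_ic50_to_pic50(ic50: float, unit: str = "uM") -> float:
    """pIC50 = -log10(IC50 in mol/L). E.g. 1.55 µM -> 5.8097."""
    if unit not in _UNIT_TO_MOLAR:
        raise DatasetError(f"unknown unit {unit!r}; expected one of {sorted(set(_UNIT_TO_MOLAR))}")
    if not (ic50 > 0):
        raise DatasetError(f"IC50 must be positive, got {ic50}")
    return -math.log10(ic50 * _UNIT_TO_MOLAR[unit])


# ---------------------------------------------------------------------------
# Descriptor pre-filtering


def filter_descriptors(
    dataset: QsarDataset,
    policy: FilterPolicy | None = None,
    activity_required: bool = False,
) -> tuple[QsarDataset, list[dict]]:
    """Apply the standard QSAR descriptor pre-filter.

    Order of rules: (1) all-zero columns, (2) columns with any missing value
    (when ``drop_missing``), (3) near-constant columns whose modal value
    frequency exceeds ``constant_fraction_cutoff``, then (4) greedy pairwise
    decorrelation: while any pair exceeds ``pairwise_corr_cutoff`` in |Pearson
    r|, the most correlated pair loses one member — the one less correlated
    with the activity, or the later column when no activity is available.

    Returns the reduced dataset and a removal log with one entry per dropped
    descriptor (``name``, ``reason``, ``detail``).
    """
    if policy is None:
        policy = FilterPolicy()
    if len(dataset) == 0:
        raise DatasetError("cannot filter an empty dataset")
    if activity_required and not dataset.has_activity:
        raise DatasetError("activity required but dataset has none")

    X = dataset.descriptor_matrix()
    names = list(dataset.descriptor_names)
    log: list[dict] = []
    keep = []
    n = X.shape[0]
    for j, name in enumerate(names):
        col = X[:, j]
        finite = col[np.isfinite(col)]
        if finite.size and np.all(finite == 0.0):
            log.append({"name": name, "reason": "zero", "detail": "all values zero"})
            continue
        if policy.drop_missing and np.isnan(col).any():
            k = int(np.isnan(col).sum())
            log.append({"name": name, "reason": "missing", "detail": f"{k} missing values"})
            continue
        _, counts = np.unique(finite, return_counts=True)
        modal_frac = counts.max() / n if counts.size else 1.0
        if modal_frac > policy.constant_fraction_cutoff:
            log.append(
                {"name": name, "reason": "constant",
                 "detail": f"modal value frequency {modal_frac:.3f}"}
            )
            continue
        keep.append(name)

    y = dataset.activity_vector() if dataset.has_activity else None
    keep = _decorrelate(dataset, keep, y, policy.pairwise_corr_cutoff, log)
    if not keep:
        raise DatasetError("all descriptors removed by filtering")
    return dataset.with_descriptors(keep), log


def _decorrelate(dataset, names, y, cutoff, log):
    names = list(names)
    while len(names) >= 2:
        M = dataset.descriptor_matrix(names)
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(M, rowvar=False)
        np.fill_diagonal(C, 0.0)
        C = np.nan_to_num(np.abs(C))
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] <= cutoff:
            break
        if i > j:
            i, j = j, i
        if y is not None:
            ri = abs(_safe_corr(M[:, i], y))
            rj = abs(_safe_corr(M[:, j], y))
            drop = i if ri < rj else j  # tie keeps the earlier column
        else:
            drop = j
        log.append(
            {"name": names[drop], "reason": "correlated",
             "detail": f"|r|={C[i, j]:.4f} with {names[i if drop == j else j]!r}"}
        )
        del names[drop]
    return names


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Train/test splitting


def split_train_test(dataset: QsarDataset, spec: SplitAssignment) -> QsarDataset:
    """Label each compound train/test per the split request.

    Random splits draw ``round(n / (ratio + 1))`` test compounds with the
    given seed; activity-ranked splits send every (ratio+1)-th compound of the
    activity-sorted order to the test set. Explicit id lists override both.
    """
    ids = dataset.ids
    if spec.train_ids is not None or spec.test_ids is not None:
        train_ids = set(spec.train_ids or ())
        test_ids = set(spec.test_ids or ())
        if spec.train_ids is None:
            train_ids = set(ids) - test_ids
        if spec.test_ids is None:
            test_ids = set(ids) - train_ids
        unknown = (train_ids | test_ids) - set(ids)
        if unknown:
            raise DatasetError(f"split ids not in dataset: {sorted(unknown)}")
    else:
        if not dataset.has_activity:
            raise DatasetError("splitting requires activities")
        n = len(dataset)
        n_test = int(math.floor(n / (spec.ratio + 1.0) + 0.5))
        if n_test < 1:
            raise DatasetError(
                f"n={n} too small for a {spec.ratio:g}:1 split (would give 0 test compounds)"
            )
        if n - n_test < 2:
            raise DatasetError("split leaves too few training compounds")
        if spec.method == "random":
            rng = np.random.default_rng(spec.seed)
            test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
        else:  # activity_ranked
            order = np.argsort(dataset.activity_vector(), kind="stable")
            step = int(spec.ratio) + 1
            test_idx = set(order[step - 1 :: step][:n_test].tolist())
        test_ids = {ids[i] for i in test_idx}
        train_ids = set(ids) - test_ids

    records = [
        replace(
            r,
            descriptors=dict(r.descriptors),
            set_label="test" if r.id in test_ids else "train",
        )
        for r in dataset.records
    ]
    return QsarDataset(records, dataset.descriptor_names)
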