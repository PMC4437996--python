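"""Typed tabular inputs for rule discovery.

A :class:`Dataset` is a named table whose rows are identified samples and
whose columns are typed attributes.  Three attribute kinds are supported:

``quantitative``
    real-valued measurements (expression levels, metabolite assays, ...);
``binary``
    0/1 flags (e.g. a treatment or knockout indicator);
``categorical``
    a finite label set (e.g. a developmental phase or time point).

Files are plain UTF-8 TSV with a header row of attribute names and a first
column of sample identifiers; empty cells are missing values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateAttributeError, FormatError

KINDS = ("quantitative", "binary", "categorical")


@dataclass(frozen=True)
class AttributeSpec:
    """One typed column of a :class:`Dataset`."""

    name: str
    kind: str
    dataset: str

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r}")


class Dataset:
    """A named table of typed attributes over identified samples.

    Parameters
    ----------
    name:
        Table name, as referenced by SCOPE clauses.
    frame:
        Sample × attribute values; the index holds the sample identifiers.
        Missing values are NaN/None.
    kinds:
        Attribute name → kind. Attributes absent from the mapping are
        inferred (see :func:`infer_kind`).
    """

    def __init__(self, name: str, frame: pd.DataFrame,
                 kinds: Mapping[str, str] | None = None):
        kinds = dict(kinds or {})
        if frame.columns.has_duplicates:
            dupes = frame.columns[frame.columns.duplicated()].tolist()
            raise FormatError(f"duplicate attribute names in {name!r}: {dupes}")
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids in {name!r}: {dupes}")
        self.name = name
        self.attributes: list[AttributeSpec] = []
        columns = {}
        for col in frame.columns:
            kind = kinds.get(col) or infer_kind(frame[col])
            columns[col] = _coerce(frame[col], kind, col)
            self.attributes.append(AttributeSpec(str(col), kind, name))
        self.frame = pd.DataFrame(columns, index=frame.index.astype(str))
        self._row_of = {sid: i for i, sid in enumerate(self.frame.index)}

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_samples(self) -> int:
        return len(self.frame.index)

    @property
    def attr_names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def kind(self, attr: str) -> str:
        for spec in self.attributes:
            if spec.name == attr:
                return spec.kind
        raise KeyError(f"no attribute {attr!r} in dataset {self.name!r}")

    def has_attr(self, attr: str) -> bool:
        return attr in self.frame.columns

    def row_index(self, sample_id: str) -> int:
        return self._row_of[sample_id]

    def value(self, row: int, attr: str):
        """Cell value at integer row position; NaN/None marks missing."""
        return self.frame[attr].iat[row]

    def __repr__(self):
        return (f"Dataset({self.name!r}, {self.n_samples} samples × "
                f"{len(self.attributes)} attributes)")

    # -- preprocessing ---------------------------------------------------
    def scale_center(self, attrs: Sequence[str] | None = None) -> "Dataset":
        """Return a copy with the named quantitative attributes z-scored.

        Each value becomes (value − mean)/sd over the attribute's
        non-missing entries (sd with one delta degree of freedom, the
        convention of R's ``scale()``).  A constant attribute raises
        :class:`DegenerateAttributeError`.
        """
        if attrs is None:
            attrs = [a.name for a in self.attributes
                     if a.kind == "quantitative"]
        frame = self.frame.copy()
        for attr in attrs:
            if self.kind(attr) != "quantitative":
                raise FormatError(
                    f"scale_center requires quantitative attributes; "
                    f"{attr!r} is {self.kind(attr)}")
            col = frame[attr].astype(float)
            sd = col.std(ddof=1, skipna=True)
            if not np.isfinite(sd) or sd == 0:
                raise DegenerateAttributeError(attr)
            frame[attr] = (col - col.mean(skipna=True)) / sd
        return Dataset(self.name, frame,
                       {a.name: a.kind for a in self.attributes})

    # -- i/o -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write in the input dialect (tab separator, empty cell = missing)."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sample"] + self.attr_names)
            for sid in self.sample_ids:
                row = [sid]
                for attr in self.attr_names:
                    v = self.frame[attr].loc[sid]
                    row.append(_format_cell(v, self.kind(attr)))
                writer.writerow(row)


def infer_kind(values: pd.Series) -> str:
    """Infer an attribute kind: binary → categorical → quantitative.

    All non-missing values in {0, 1} → binary; any non-numeric value →
    categorical; otherwise quantitative.
    """
    non_missing = values.dropna()
    numeric = pd.to_numeric(non_missing, errors="coerce")
    if numeric.notna().all():
        if numeric.isin([0, 1]).all() and len(numeric) > 0:
            return "binary"
        return "quantitative"
    return "categorical"


def _float_or_nan(x):
    # exact round-trip parsing (pd.to_numeric's fast path loses ulps)
    try:
        return float(x)
    except (TypeError, ValueError):
        return float("nan")


def _coerce(values: pd.Series, kind: str, attr: str) -> pd.Series:
    if kind in ("quantitative", "binary"):
        coerced = values.map(_float_or_nan, na_action="ignore").astype(float)
        bad = values.notna() & coerced.isna()
        if bad.any():
            raise FormatError(
                f"attribute {attr!r} declared {kind} but holds "
                f"non-numeric values {values[bad].unique().tolist()}")
        if kind == "binary":
            obs = coerced.dropna()
            if not obs.isin([0, 1]).all():
                raise FormatError(
                    f"binary attribute {attr!r} holds values outside {{0,1}}")
        return coerced.astype(float)
    return values.astype(object).where(values.notna(), None)


def _format_cell(v, kind: str) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    if kind == "binary":
        return str(int(v))
    if kind == "quantitative":
        return repr(float(v))
    return str(v)


def load_table(path, type_hints: Mapping[str, str] | None = None,
               name: str | None = None) -> Dataset:
    """Read a TSV file into a typed :class:`Dataset`.

    The first column holds sample identifiers (a headerless pure matrix is
    rejected), the header row holds attribute names.  ``type_hints`` wins
    over kind inference.
    """
    path = str(path)
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or len(rows[0]) < 2:
        raise FormatError(f"{path}: need a sample-id column plus attributes")
    header = rows[0]
    attrs = header[1:]
    if len(set(attrs)) != len(attrs):
        dupes = sorted({a for i, a in enumerate(attrs) if a in attrs[:i]})
        raise FormatError(f"{path}: duplicate attribute names {dupes}")
    width = len(header)
    body = rows[1:]
    for i, row in enumerate(body, start=2):
        if len(row) != width:
            raise FormatError(f"{path}: row {i} has {len(row)} fields, "
                              f"expected {width}")
    sample_ids = [r[0] for r in body]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for i, s in enumerate(sample_ids)
                        if s in sample_ids[:i]})
        raise FormatError(f"{path}: duplicate sample ids {dupes}")
    data = {attr: [r[j + 1] if r[j + 1] != "" else None for r in body]
            for j, attr in enumerate(attrs)}
    frame = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample"))
    if name is None:
        name = _stem(path)
    return Dataset(name, frame, type_hints)


def load_catalog(paths: Iterable[str]) -> dict[str, Dataset]:
    """Load several tables, keyed by their file stem (the SCOPE name)."""
    catalog = {}
    for p in paths:
        ds = load_table(p)
        if ds.name in catalog:
            raise FormatError(f"two tables named {ds.name!r}")
        catalog[ds.name] = ds
    return catalog


def _stem(path: str) -> str:
    base = path.replace("\\", "/").rsplit("/", 1)[-1]
    return base.rsplit(".", 1)[0] if "." in base else base
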