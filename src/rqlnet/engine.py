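"""Query execution: evaluation units and the boolean satisfaction matrix.

Rule counting (support, confidence, ...) never touches the raw tables:
the engine first enumerates *evaluation units* — assignments of one sample
row to every tuple variable that satisfy the WHERE clause — then evaluates
every (predicate, attribute) pair on every unit.  The result is the
:class:`SatisfactionMatrix`, a units × labeled-attributes boolean grid
(with missing cells where an input value was missing) from which all
interest measures are computed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import rql
from .errors import BindingError, EvaluationError
from .tables import Dataset

MISSING = -1  # cell encoding: 1 true, 0 false, -1 missing


@dataclass(frozen=True)
class EvaluationUnit:
    """One assignment of sample rows to the query's tuple variables."""
    rows: tuple[int, ...]        # row index per scope binding, scope order
    sample_ids: tuple[str, ...]  # matching sample identifiers

    def assignment(self, tvars: Sequence[str]) -> dict[str, int]:
        return dict(zip(tvars, self.rows))


@dataclass(frozen=True)
class LabeledColumn:
    """One satisfaction-matrix column: an attribute under a predicate label."""
    dataset: str
    attribute: str
    label: str

    @property
    def name(self) -> str:
        # an empty label (hand-built matrices) leaves the attribute bare
        return f"{self.attribute}_{self.label}" if self.label \
            else self.attribute


class SatisfactionMatrix:
    """Boolean units × labeled-attributes matrix.

    ``data`` holds int8 cells (1 true, 0 false, -1 missing). Columns that
    share an underlying attribute (e.g. ``A1_1`` and ``A1_0``) are
    *siblings*; rule discovery never pairs siblings.
    """

    def __init__(self, units: list[EvaluationUnit],
                 columns: list[LabeledColumn], data: np.ndarray):
        if data.shape != (len(units), len(columns)):
            raise ValueError("data shape does not match units × columns")
        names = [c.name for c in columns]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate column names: {names}")
        self.units = units
        self.columns = columns
        self.data = data.astype(np.int8)
        self._index = {c.name: j for j, c in enumerate(columns)}

    @property
    def N(self) -> int:
        return len(self.units)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def column_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"no column {name!r} in satisfaction matrix")

    def underlying(self, name: str) -> str:
        """Underlying attribute of a column name."""
        return self.columns[self.column_index(name)].attribute

    def siblings(self, name: str) -> frozenset[str]:
        """All column names sharing this column's underlying attribute."""
        col = self.columns[self.column_index(name)]
        return frozenset(c.name for c in self.columns
                         if (c.dataset, c.attribute) == (col.dataset,
                                                         col.attribute))

    def to_frame(self) -> pd.DataFrame:
        """Units × columns frame with NA for missing cells (debug export)."""
        idx = ["|".join(u.sample_ids) for u in self.units]
        frame = pd.DataFrame(self.data, index=idx, columns=self.column_names,
                             dtype=float)
        return frame.mask(frame < 0)

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        out = frame.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        out.to_csv(path, sep="\t", index_label="unit")

    @classmethod
    def from_columns(cls, columns: "Mapping[str, Sequence]",
                     dataset: str = "m") -> "SatisfactionMatrix":
        """Hand-build a matrix from name → 0/1 sequences (None = missing).

        A name of the form ``attr_label`` keeps ``attr`` as the underlying
        attribute (so sibling exclusion applies); a bare name is its own
        attribute.
        """
        cols, arrays = [], []
        for name, values in columns.items():
            attr, _, label = name.rpartition("_") if "_" in name \
                else (name, "", "")
            cols.append(LabeledColumn(dataset, attr or name, label))
            arrays.append([MISSING if v is None else int(v) for v in values])
        data = np.array(arrays, dtype=np.int8).T
        units = [EvaluationUnit((i,), (f"u{i + 1}",))
                 for i in range(data.shape[0])]
        return cls(units, cols, data)


# ---------------------------------------------------------------------------
# Value lookup and expression evaluation
# ---------------------------------------------------------------------------

class _Context:
    """Value resolution for one query against a catalog.

    A tuple variable's row can serve attributes of *other* datasets through
    the sample identifier (row-wise join), which is how a one-variable
    scope over an annotation table can reference expression or metabolite
    attributes of the same sample.
    """

    def __init__(self, query: rql.Query, catalog: Mapping[str, Dataset]):
        self.query = query
        self.catalog = catalog
        self.tvar_dataset = dict(query.scope)
        self.tvar_pos = {t: i for i, (t, _) in enumerate(query.scope)}

    def lookup(self, tvar: str, dataset: str, attr: str,
               unit: EvaluationUnit):
        """Value of ``attr`` (owned by ``dataset``) for the sample bound to
        ``tvar`` in ``unit``."""
        home = self.tvar_dataset[tvar]
        pos = self.tvar_pos[tvar]
        if dataset == home:
            return self.catalog[home].value(unit.rows[pos], attr)
        other = self.catalog[dataset]
        sid = unit.sample_ids[pos]
        try:
            row = other.row_index(sid)
        except KeyError:
            raise BindingError(
                f"sample {sid!r} of dataset {home!r} has no matching row "
                f"in dataset {dataset!r}")
        return other.value(row, attr)

    def resolve_plain(self, tvar: str, attr: str) -> str:
        """Owning dataset for a bare ``tvar.attr`` reference."""
        home = self.tvar_dataset[tvar]
        if self.catalog[home].has_attr(attr):
            return home
        owners = sorted(d for d, ds in self.catalog.items()
                        if ds.has_attr(attr))
        if len(owners) == 1:
            return owners[0]
        if not owners:
            raise BindingError(f"unknown attribute {attr!r}")
        raise BindingError(f"attribute {attr!r} is ambiguous across "
                           f"datasets {owners}")


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _as_number(v):
    if isinstance(v, (int, float)) and not isinstance(v, bool):
        return float(v)
    if isinstance(v, str):
        try:
            return float(v)
        except ValueError:
            return None
    return None


def _eval_expr(expr, ctx: _Context, unit: EvaluationUnit,
               placeholder: rql.BoundAttr | None):
    """Three-valued evaluation: returns True/False, a value, or None
    (missing). Type mismatches raise :class:`EvaluationError`."""
    if isinstance(expr, rql.Num):
        return expr.value
    if isinstance(expr, rql.Str):
        return expr.value
    if isinstance(expr, rql.Placeholder):
        if placeholder is None:
            raise EvaluationError("placeholder $a outside a HAVING clause")
        v = ctx.lookup(expr.tvar, placeholder.dataset, placeholder.name, unit)
        return None if _is_missing(v) else v
    if isinstance(expr, rql.AttrRef):
        ds = ctx.resolve_plain(expr.tvar, expr.attr)
        v = ctx.lookup(expr.tvar, ds, expr.attr, unit)
        return None if _is_missing(v) else v
    if isinstance(expr, rql.Func):
        v = _eval_expr(expr.arg, ctx, unit, placeholder)
        if v is None:
            return None
        n = _as_number(v)
        if n is None:
            raise EvaluationError(f"abs() of non-numeric value {v!r}")
        return abs(n)
    if isinstance(expr, rql.BinOp):
        lv = _eval_expr(expr.left, ctx, unit, placeholder)
        rv = _eval_expr(expr.right, ctx, unit, placeholder)
        if lv is None or rv is None:
            return None
        ln, rn = _as_number(lv), _as_number(rv)
        if ln is None or rn is None:
            raise EvaluationError(
                f"arithmetic {expr.op!r} on non-numeric value "
                f"{lv if ln is None else rv!r}")
        if expr.op == "+":
            return ln + rn
        if expr.op == "-":
            return ln - rn
        if expr.op == "*":
            return ln * rn
        if rn == 0:
            raise EvaluationError("division by zero in predicate")
        return ln / rn
    if isinstance(expr, rql.Cmp):
        lv = _eval_expr(expr.left, ctx, unit, placeholder)
        rv = _eval_expr(expr.right, ctx, unit, placeholder)
        if lv is None or rv is None:
            return None
        ln, rn = _as_number(lv), _as_number(rv)
        if ln is not None and rn is not None:
            a, b = ln, rn
        elif expr.op in ("=", "!="):
            a, b = str(lv), str(rv)
        else:
            raise EvaluationError(
                f"ordering comparison {expr.op!r} on non-numeric values "
                f"{lv!r}, {rv!r}")
        return {"=": a == b, "!=": a != b, "<": a < b, "<=": a <= b,
                ">": a > b, ">=": a >= b}[expr.op]
    if isinstance(expr, rql.BoolOp):
        lv = _eval_expr(expr.left, ctx, unit, placeholder)
        rv = _eval_expr(expr.right, ctx, unit, placeholder)
        if lv is None or rv is None:
            return None
        return bool(lv) and bool(rv) if expr.op == "and" else bool(lv) or bool(rv)
    if isinstance(expr, rql.Not):
        v = _eval_expr(expr.operand, ctx, unit, placeholder)
        return None if v is None else not bool(v)
    raise TypeError(f"not an expression node: {expr!r}")


# ---------------------------------------------------------------------------
# Scope binding
# ---------------------------------------------------------------------------

def _pairs_unordered(query: rql.Query) -> bool:
    """Unordered pair enumeration applies when both variables range over
    one dataset, there is no WHERE, and every predicate is symmetric under
    exchanging the two variables."""
    if query.arity != 2 or query.where is not None:
        return False
    (t1, d1), (t2, d2) = query.scope
    if d1 != d2:
        return False
    return all(rql.is_symmetric(c.predicate.expr, t1, t2)
               for c in query.clauses)


def bind_scope(query: rql.Query,
               catalog: Mapping[str, Dataset]) -> list[EvaluationUnit]:
    """Enumerate the evaluation units of a query.

    Arity 1: one unit per sample row (restricted by WHERE if present).
    Arity ≥ 2: combinations of one row per variable; two variables bound to
    the same dataset never share a row, and for a symmetric two-variable
    query without WHERE each unordered pair is enumerated once.
    A unit whose WHERE value is missing is excluded.
    """
    for tvar, ds in query.scope:
        if ds not in catalog:
            raise BindingError(f"unknown dataset {ds!r} bound to {tvar!r}")
    ctx = _Context(query, catalog)
    datasets = [catalog[ds] for _, ds in query.scope]

    def make(rows: tuple[int, ...]) -> EvaluationUnit:
        ids = tuple(d.sample_ids[r] for d, r in zip(datasets, rows))
        return EvaluationUnit(rows, ids)

    if query.arity == 1:
        candidates = [make((r,)) for r in range(datasets[0].n_samples)]
    elif _pairs_unordered(query):
        n = datasets[0].n_samples
        candidates = [make((i, j)) for i, j in itertools.combinations(range(n), 2)]
    else:
        ranges = [range(d.n_samples) for d in datasets]
        candidates = []
        for rows in itertools.product(*ranges):
            clash = any(rows[i] == rows[j]
                        for i in range(len(rows)) for j in range(i + 1, len(rows))
                        if datasets[i].name == datasets[j].name)
            if not clash:
                candidates.append(make(rows))

    if query.where is None:
        return candidates
    kept = []
    for unit in candidates:
        v = _eval_expr(query.where, ctx, unit, None)
        if v is not None and bool(v):
            kept.append(unit)
    return kept


# ---------------------------------------------------------------------------
# Predicate evaluation
# ---------------------------------------------------------------------------

def evaluate(query: rql.Query, units: Sequence[EvaluationUnit],
             catalog: Mapping[str, Dataset]) -> SatisfactionMatrix:
    """Evaluate every (predicate, OVER attribute) pair on every unit."""
    ctx = _Context(query, catalog)
    columns: list[LabeledColumn] = []
    specs: list[tuple[rql.Predicate, rql.BoundAttr]] = []
    for clause in query.clauses:
        for battr in clause.attrs:
            columns.append(LabeledColumn(battr.dataset, battr.name,
                                         clause.predicate.label))
            specs.append((clause.predicate, battr))
    data = np.empty((len(units), len(columns)), dtype=np.int8)
    for j, (pred, battr) in enumerate(specs):
        col = columns[j]
        for i, unit in enumerate(units):
            try:
                v = _eval_expr(pred.expr, ctx, unit, battr)
            except EvaluationError as exc:
                raise EvaluationError(
                    f"unit {'|'.join(unit.sample_ids)}, column "
                    f"{col.name}: {exc}") from exc
            data[i, j] = MISSING if v is None else int(bool(v))
    return SatisfactionMatrix(list(units), columns, data)


def run_query(query: rql.Query,
              catalog: Mapping[str, Dataset]) -> SatisfactionMatrix:
    """bind_scope + evaluate in one call."""
    return evaluate(query, bind_scope(query, catalog), catalog)
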