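"""FINDRULES statements: grammar, parser, renderer and builtin templates.

The rule-query language is SQL-like.  One statement declares which rules to
mine::

    FINDRULES
      SCOPE t1 IN (gen), t2 IN (gen)
      WHERE t2.time = t1.time + 1
      HAVING high: t1.$a >= 0 OVER G1, G2, G3
      AND    low:  t1.$a <= 0 OVER *;

``SCOPE`` binds tuple variables to datasets; the optional ``WHERE``
restricts which tuple combinations are evaluation units; each
``HAVING``/``AND`` clause names a predicate and lists the attributes it is
instantiated over.  ``tvar.$a`` is the attribute placeholder: the predicate
is evaluated once per attribute in its OVER list, the placeholder bound to
that attribute.  ``*`` expands to every attribute of the clause's dataset
not referenced by the WHERE clause.

Grammar (tokens are case-insensitive keywords, identifiers, numbers,
quoted strings)::

    statement := "FINDRULES" scope [where] having+ ";"
    scope     := "SCOPE" binding ("," binding)*
    binding   := ident "IN" "(" ident ")"
    where     := "WHERE" boolexpr
    having    := ("HAVING"|"AND") ident ":" boolexpr "OVER" attrlist
    attrlist  := "*" | attr ("," attr)*
    attr      := ident ["." ident]          -- optionally dataset-qualified
    boolexpr  := orexpr (with AND/OR/NOT, comparisons =,!=,<,<=,>,>=,
                 arithmetic +,-,*,/, abs(...), literals, tvar.attr, tvar.$a)

``#`` starts a comment line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .errors import BindingError, ParseError
from .tables import Dataset

KEYWORDS = {"FINDRULES", "SCOPE", "IN", "WHERE", "HAVING", "AND", "OR",
            "NOT", "OVER"}


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Str:
    value: str


@dataclass(frozen=True)
class AttrRef:
    """``tvar.attr`` — a concrete attribute of the tuple bound to ``tvar``."""
    tvar: str
    attr: str


@dataclass(frozen=True)
class Placeholder:
    """``tvar.$a`` — stands for the clause's current OVER attribute."""
    tvar: str


@dataclass(frozen=True)
class BinOp:
    op: str  # + - * /
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Cmp:
    op: str  # = != < <= > >=
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class BoolOp:
    op: str  # and | or
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Not:
    operand: "Expr"


@dataclass(frozen=True)
class Func:
    name: str  # only "abs" for now
    arg: "Expr"


Expr = object  # union of the node classes above


def expr_tvars(expr) -> frozenset[str]:
    """Tuple variables referenced anywhere in an expression."""
    if isinstance(expr, (AttrRef, Placeholder)):
        return frozenset([expr.tvar])
    if isinstance(expr, (BinOp, Cmp, BoolOp)):
        return expr_tvars(expr.left) | expr_tvars(expr.right)
    if isinstance(expr, Not):
        return expr_tvars(expr.operand)
    if isinstance(expr, Func):
        return expr_tvars(expr.arg)
    return frozenset()


def expr_attrs(expr) -> frozenset[str]:
    """Concrete attribute names referenced in an expression."""
    if isinstance(expr, AttrRef):
        return frozenset([expr.attr])
    if isinstance(expr, (BinOp, Cmp, BoolOp)):
        return expr_attrs(expr.left) | expr_attrs(expr.right)
    if isinstance(expr, Not):
        return expr_attrs(expr.operand)
    if isinstance(expr, Func):
        return expr_attrs(expr.arg)
    return frozenset()


def swap_tvars(expr, a: str, b: str):
    """Expression with tuple variables ``a`` and ``b`` exchanged."""
    sub = {a: b, b: a}
    if isinstance(expr, AttrRef):
        return AttrRef(sub.get(expr.tvar, expr.tvar), expr.attr)
    if isinstance(expr, Placeholder):
        return Placeholder(sub.get(expr.tvar, expr.tvar))
    if isinstance(expr, BinOp):
        return BinOp(expr.op, swap_tvars(expr.left, a, b),
                     swap_tvars(expr.right, a, b))
    if isinstance(expr, Cmp):
        return Cmp(expr.op, swap_tvars(expr.left, a, b),
                   swap_tvars(expr.right, a, b))
    if isinstance(expr, BoolOp):
        return BoolOp(expr.op, swap_tvars(expr.left, a, b),
                      swap_tvars(expr.right, a, b))
    if isinstance(expr, Not):
        return Not(swap_tvars(expr.operand, a, b))
    if isinstance(expr, Func):
        return Func(expr.name, swap_tvars(expr.arg, a, b))
    return expr


_COMMUTATIVE_CMP = {"=": "=", "!=": "!="}
_FLIP_CMP = {"<": ">", ">": "<", "<=": ">=", ">=": "<="}


def _canon_key(expr) -> tuple:
    """Structural key invariant under commutative reordering.

    ``+``, ``*``, ``=``, ``!=``, AND and OR sort their operands;
    ``abs(x − y)`` is canonicalised on the sorted pair (it is symmetric in
    x and y); strict comparisons are oriented so the smaller key is left.
    """
    if isinstance(expr, Num):
        return ("num", expr.value)
    if isinstance(expr, Str):
        return ("str", expr.value)
    if isinstance(expr, AttrRef):
        return ("attr", expr.tvar, expr.attr)
    if isinstance(expr, Placeholder):
        return ("ph", expr.tvar)
    if isinstance(expr, Func):
        inner = expr.arg
        if expr.name == "abs" and isinstance(inner, BinOp) and inner.op == "-":
            pair = sorted((_canon_key(inner.left), _canon_key(inner.right)))
            return ("absdiff", tuple(pair))
        return ("func", expr.name, _canon_key(expr.arg))
    if isinstance(expr, BinOp):
        lk, rk = _canon_key(expr.left), _canon_key(expr.right)
        if expr.op in "+*":
            lk, rk = sorted((lk, rk))
        return ("bin", expr.op, lk, rk)
    if isinstance(expr, Cmp):
        lk, rk = _canon_key(expr.left), _canon_key(expr.right)
        if expr.op in _COMMUTATIVE_CMP:
            lk, rk = sorted((lk, rk))
            return ("cmp", expr.op, lk, rk)
        if rk < lk:
            return ("cmp", _FLIP_CMP[expr.op], rk, lk)
        return ("cmp", expr.op, lk, rk)
    if isinstance(expr, BoolOp):
        lk, rk = sorted((_canon_key(expr.left), _canon_key(expr.right)))
        return ("bool", expr.op, lk, rk)
    if isinstance(expr, Not):
        return ("not", _canon_key(expr.operand))
    raise TypeError(f"not an expression node: {expr!r}")


def is_symmetric(expr, t1: str, t2: str) -> bool:
    """True if the expression is invariant under exchanging ``t1``/``t2``
    (up to commutative reordering). Used to decide unordered vs ordered
    pair enumeration."""
    return _canon_key(expr) == _canon_key(swap_tvars(expr, t1, t2))


# ---------------------------------------------------------------------------
# Query objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Predicate:
    """A labeled boolean expression applied per OVER attribute."""
    label: str
    expr: object

    @property
    def arity(self) -> int:
        return len(expr_tvars(self.expr))


@dataclass(frozen=True)
class BoundAttr:
    """An OVER attribute resolved to its owning dataset."""
    dataset: str
    name: str


@dataclass(frozen=True)
class Clause:
    predicate: Predicate
    attrs: tuple[BoundAttr, ...]


@dataclass(frozen=True)
class Query:
    """Parsed, bound representation of one FINDRULES statement."""
    scope: tuple[tuple[str, str], ...]      # (tuple variable, dataset name)
    where: Optional[object]
    clauses: tuple[Clause, ...]
    central: Optional[frozenset[str]] = None

    @property
    def arity(self) -> int:
        return len(self.scope)

    @property
    def tvars(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.scope)


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"""
      (?P<ws>[ \t\r]+)
    | (?P<comment>\#[^\n]*)
    | (?P<nl>\n)
    | (?P<number>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
    | (?P<ident>[A-Za-z_][A-Za-z0-9_-]*)
    | (?P<placeholder>\$[A-Za-z_][A-Za-z0-9_]*)
    | (?P<string>'[^']*'|"[^"]*")
    | (?P<op><=|>=|!=|[=<>+\-*/(),:;.])
""", re.VERBOSE)


@dataclass(frozen=True)
class Token:
    kind: str   # NUMBER IDENT PLACEHOLDER STRING OP KEYWORD EOF
    text: str
    line: int
    col: int


def tokenize(text: str) -> list[Token]:
    tokens, line, col, pos = [], 1, 1, 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        tok = m.group()
        if kind == "nl":
            line += 1
            col = 1
        elif kind in ("ws", "comment"):
            col += len(tok)
        else:
            if kind == "ident" and tok.upper() in KEYWORDS:
                tokens.append(Token("KEYWORD", tok.upper(), line, col))
            elif kind == "ident":
                tokens.append(Token("IDENT", tok, line, col))
            elif kind == "number":
                tokens.append(Token("NUMBER", tok, line, col))
            elif kind == "placeholder":
                tokens.append(Token("PLACEHOLDER", tok, line, col))
            elif kind == "string":
                tokens.append(Token("STRING", tok[1:-1], line, col))
            else:
                tokens.append(Token("OP", tok, line, col))
            col += len(tok)
        pos = m.end()
    tokens.append(Token("EOF", "", line, col))
    return tokens


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> Token:
        return self.tokens[self.i]

    def error(self, msg: str):
        t = self.cur
        shown = t.text or "end of input"
        raise ParseError(f"{msg}, got {shown!r}", t.line, t.col)

    def advance(self) -> Token:
        t = self.cur
        self.i += 1
        return t

    def accept(self, kind: str, text: str | None = None) -> Token | None:
        t = self.cur
        if t.kind == kind and (text is None or t.text == text):
            return self.advance()
        return None

    def expect(self, kind: str, text: str | None = None) -> Token:
        t = self.accept(kind, text)
        if t is None:
            self.error(f"expected {text or kind}")
        return t

    # statement := FINDRULES scope [where] having+ ";"
    def statement(self):
        self.expect("KEYWORD", "FINDRULES")
        scope = self.scope()
        where = None
        if self.accept("KEYWORD", "WHERE"):
            where = self.boolexpr()
        clauses = [self.having("HAVING")]
        while self.cur.kind == "KEYWORD" and self.cur.text == "AND":
            clauses.append(self.having("AND"))
        self.expect("OP", ";")
        if self.cur.kind != "EOF":
            self.error("expected end of statement")
        return scope, where, clauses

    def scope(self):
        self.expect("KEYWORD", "SCOPE")
        bindings = [self.binding()]
        while self.accept("OP", ","):
            bindings.append(self.binding())
        return bindings

    def binding(self):
        tvar = self.expect("IDENT").text
        self.expect("KEYWORD", "IN")
        self.expect("OP", "(")
        ds = self.expect("IDENT").text
        self.expect("OP", ")")
        return tvar, ds

    def having(self, opener: str):
        self.expect("KEYWORD", opener)
        label = self.expect("IDENT").text
        self.expect("OP", ":")
        expr = self.boolexpr()
        self.expect("KEYWORD", "OVER")
        attrs = self.attrlist()
        return label, expr, attrs

    def attrlist(self):
        if self.accept("OP", "*"):
            return ["*"]
        attrs = [self.attrname()]
        while self.accept("OP", ","):
            attrs.append(self.attrname())
        return attrs

    def attrname(self):
        first = self.expect("IDENT").text
        if self.accept("OP", "."):
            second = self.expect("IDENT").text
            return f"{first}.{second}"
        return first

    # expression precedence: OR < AND < NOT < cmp < add < mul < unary
    def boolexpr(self):
        left = self.andexpr()
        while self.cur.kind == "KEYWORD" and self.cur.text == "OR":
            self.advance()
            left = BoolOp("or", left, self.andexpr())
        return left

    def andexpr(self):
        left = self.notexpr()
        # clause-level AND is "AND label :" — look ahead for the colon
        while (self.cur.kind == "KEYWORD" and self.cur.text == "AND"
               and not self._and_opens_clause()):
            self.advance()
            left = BoolOp("and", left, self.notexpr())
        return left

    def _and_opens_clause(self) -> bool:
        nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else None
        nxt2 = self.tokens[self.i + 2] if self.i + 2 < len(self.tokens) else None
        return (nxt is not None and nxt.kind == "IDENT"
                and nxt2 is not None and nxt2.kind == "OP" and nxt2.text == ":")

    def notexpr(self):
        if self.accept("KEYWORD", "NOT"):
            return Not(self.notexpr())
        return self.cmpexpr()

    def cmpexpr(self):
        left = self.addexpr()
        t = self.cur
        if t.kind == "OP" and t.text in ("=", "!=", "<", "<=", ">", ">="):
            self.advance()
            right = self.addexpr()
            return Cmp(t.text, left, right)
        return left

    def addexpr(self):
        left = self.mulexpr()
        while self.cur.kind == "OP" and self.cur.text in "+-":
            op = self.advance().text
            left = BinOp(op, left, self.mulexpr())
        return left

    def mulexpr(self):
        left = self.unary()
        while self.cur.kind == "OP" and self.cur.text in "*/":
            op = self.advance().text
            left = BinOp(op, left, self.unary())
        return left

    def unary(self):
        if self.accept("OP", "-"):
            operand = self.unary()
            if isinstance(operand, Num):
                return Num(-operand.value)
            return BinOp("-", Num(0.0), operand)
        return self.primary()

    def primary(self):
        t = self.cur
        if t.kind == "NUMBER":
            self.advance()
            return Num(float(t.text))
        if t.kind == "STRING":
            self.advance()
            return Str(t.text)
        if t.kind == "IDENT":
            name = self.advance().text
            if self.accept("OP", "("):   # function call, only abs()
                if name.lower() != "abs":
                    raise ParseError(f"unknown function {name!r}", t.line, t.col)
                arg = self.boolexpr()
                self.expect("OP", ")")
                return Func("abs", arg)
            self.expect("OP", ".")
            nt = self.cur
            if nt.kind == "PLACEHOLDER":
                self.advance()
                return Placeholder(name)
            if nt.kind == "IDENT":
                self.advance()
                return AttrRef(name, nt.text)
            self.error("expected attribute name or placeholder after '.'")
        if self.accept("OP", "("):
            e = self.boolexpr()
            self.expect("OP", ")")
            return e
        self.error("expected expression")


# ---------------------------------------------------------------------------
# Binding against a catalog
# ---------------------------------------------------------------------------

def _resolve_attr(name: str, scope_datasets: Sequence[str],
                  catalog: Mapping[str, Dataset]) -> BoundAttr:
    if "." in name:
        ds, attr = name.split(".", 1)
        if ds not in catalog:
            raise BindingError(f"unknown dataset {ds!r} in attribute {name!r}")
        if not catalog[ds].has_attr(attr):
            raise BindingError(f"dataset {ds!r} has no attribute {attr!r}")
        return BoundAttr(ds, attr)
    in_scope = [d for d in dict.fromkeys(scope_datasets)
                if catalog[d].has_attr(name)]
    if len(in_scope) == 1:
        return BoundAttr(in_scope[0], name)
    if len(in_scope) > 1:
        raise BindingError(
            f"attribute {name!r} is ambiguous across scope datasets "
            f"{in_scope}; qualify it as dataset.attribute")
    elsewhere = sorted(d for d, ds in catalog.items()
                       if d not in scope_datasets and ds.has_attr(name))
    if len(elsewhere) == 1:
        return BoundAttr(elsewhere[0], name)
    if len(elsewhere) > 1:
        raise BindingError(
            f"attribute {name!r} is ambiguous across datasets {elsewhere}")
    raise BindingError(f"unknown attribute {name!r}")


def parse_query(text: str, catalog: Mapping[str, Dataset]) -> Query:
    """Parse and bind one FINDRULES statement.

    Raises :class:`ParseError` (with line/column) on bad syntax and
    :class:`BindingError` when a dataset, attribute or tuple variable does
    not resolve against ``catalog``.
    """
    scope, where, raw_clauses = _Parser(tokenize(text)).statement()

    tvars = [t for t, _ in scope]
    if len(set(tvars)) != len(tvars):
        raise BindingError(f"duplicate tuple variable in SCOPE: {tvars}")
    for tvar, ds in scope:
        if ds not in catalog:
            raise BindingError(f"unknown dataset {ds!r} bound to {tvar!r}")
    bound = dict(scope)
    scope_datasets = [ds for _, ds in scope]

    def check_tvars(expr, where_ctx: bool):
        for tv in expr_tvars(expr):
            if tv not in bound:
                kind = "WHERE clause" if where_ctx else "predicate"
                raise BindingError(f"{kind} references unbound tuple "
                                   f"variable {tv!r}")

    where_attrs: frozenset[str] = frozenset()
    if where is not None:
        check_tvars(where, where_ctx=True)
        where_attrs = expr_attrs(where)
        _check_attr_refs(where, bound, catalog)

    clauses = []
    for label, expr, attrs in raw_clauses:
        check_tvars(expr, where_ctx=False)
        _check_attr_refs(expr, bound, catalog)
        pred = Predicate(label, expr)
        if expr_tvars(expr) and expr_tvars(expr) != frozenset(tvars):
            raise BindingError(
                f"predicate {label!r} must reference exactly the scope's "
                f"tuple variables {sorted(tvars)}")
        if attrs == ["*"]:
            ds = catalog[scope_datasets[0]]
            names = [a for a in ds.attr_names if a not in where_attrs]
            resolved = tuple(BoundAttr(ds.name, a) for a in names)
        else:
            resolved = tuple(_resolve_attr(a, scope_datasets, catalog)
                             for a in attrs)
        if not resolved:
            raise BindingError(f"clause {label!r} has an empty attribute list")
        clauses.append(Clause(pred, resolved))

    labels = [c.predicate.label for c in clauses]
    if len(set(labels)) != len(labels):
        raise BindingError(f"duplicate predicate labels: {labels}")
    return Query(tuple(scope), where, tuple(clauses))


def _check_attr_refs(expr, bound: Mapping[str, str],
                     catalog: Mapping[str, Dataset]) -> None:
    if isinstance(expr, AttrRef):
        ds = bound.get(expr.tvar)
        if ds is not None and not catalog[ds].has_attr(expr.attr):
            # cross-table reference: legal when exactly one other dataset
            # owns the attribute (rows joined by sample id at evaluation)
            owners = [d for d, dset in catalog.items()
                      if dset.has_attr(expr.attr)]
            if len(owners) != 1:
                raise BindingError(
                    f"attribute {expr.attr!r} (via tuple variable "
                    f"{expr.tvar!r}) resolves to {len(owners)} datasets")
    elif isinstance(expr, (BinOp, Cmp, BoolOp)):
        _check_attr_refs(expr.left, bound, catalog)
        _check_attr_refs(expr.right, bound, catalog)
    elif isinstance(expr, Not):
        _check_attr_refs(expr.operand, bound, catalog)
    elif isinstance(expr, Func):
        _check_attr_refs(expr.arg, bound, catalog)


def parse_query_file(path, catalog: Mapping[str, Dataset]) -> Query:
    """Read a query file (one statement; ``#`` comment lines) and parse it."""
    with open(path, encoding="utf-8") as fh:
        return parse_query(fh.read(), catalog)


# ---------------------------------------------------------------------------
# Canonical renderer (inverse of parse_query up to whitespace)
# ---------------------------------------------------------------------------

_PREC = {"or": 1, "and": 2, "not": 3, "cmp": 4, "+": 5, "-": 5, "*": 6,
         "/": 6}


def _render_expr(expr, parent_prec: int = 0, right: bool = False) -> str:
    if isinstance(expr, Num):
        v = expr.value
        return repr(int(v)) if float(v).is_integer() else repr(v)
    if isinstance(expr, Str):
        return f"'{expr.value}'"
    if isinstance(expr, AttrRef):
        return f"{expr.tvar}.{expr.attr}"
    if isinstance(expr, Placeholder):
        return f"{expr.tvar}.$a"
    if isinstance(expr, Func):
        return f"abs({_render_expr(expr.arg)})"
    if isinstance(expr, Not):
        inner = _render_expr(expr.operand, _PREC["not"])
        s = f"NOT {inner}"
        return f"({s})" if parent_prec > _PREC["not"] else s
    if isinstance(expr, BoolOp):
        p = _PREC[expr.op]
        s = (f"{_render_expr(expr.left, p)} {expr.op.upper()} "
             f"{_render_expr(expr.right, p + 1)}")
        return f"({s})" if parent_prec > p or (parent_prec == p and right) else s
    if isinstance(expr, Cmp):
        p = _PREC["cmp"]
        s = (f"{_render_expr(expr.left, p + 1)} {expr.op} "
             f"{_render_expr(expr.right, p + 1)}")
        return f"({s})" if parent_prec >= p else s
    if isinstance(expr, BinOp):
        p = _PREC[expr.op]
        s = (f"{_render_expr(expr.left, p)} {expr.op} "
             f"{_render_expr(expr.right, p + 1, right=True)}")
        return f"({s})" if parent_prec > p or (parent_prec == p and right) else s
    raise TypeError(f"not an expression node: {expr!r}")


def render(query: Query) -> str:
    """Canonical text for a query; ``parse_query(render(q)) == q``."""
    parts = ["FINDRULES"]
    parts.append("  SCOPE " + ", ".join(f"{t} IN ({d})" for t, d in query.scope))
    if query.where is not None:
        parts.append("  WHERE " + _render_expr(query.where))
    for k, clause in enumerate(query.clauses):
        opener = "HAVING" if k == 0 else "AND"
        attrs = ", ".join(f"{a.dataset}.{a.name}" for a in clause.attrs)
        parts.append(f"  {opener} {clause.predicate.label}: "
                     f"{_render_expr(clause.predicate.expr)} OVER {attrs}")
    return "\n".join(parts) + ";"


# ---------------------------------------------------------------------------
# Builtin templates
# ---------------------------------------------------------------------------

def builtin_query(which: str, dataset: Dataset,
                  attrs: Sequence[str] | None = None, *,
                  delta: float = 0.0, epsilon: float = 0.25) -> Query:
    """Instantiate one of the two predefined templates.

    ``Q1`` mines association-style rules between attributes that are
    simultaneously high (value ≥ ``delta``) or low (value ≤ −``delta``) in
    the same samples; it expects scaled/centered data, so with the default
    ``delta=0`` high/low means above/below the attribute's mean.

    ``Q2`` mines similar-profile rules over all unordered sample pairs: two
    attributes are linked when they agree (|t1.a − t2.a| ≤ ``epsilon``, in
    standard-deviation units) on the same pairs of samples.
    """
    if attrs is None:
        attrs = [a.name for a in dataset.attributes
                 if a.kind == "quantitative"]
    for a in attrs:
        if dataset.kind(a) != "quantitative":
            raise BindingError(
                f"builtin templates need quantitative attributes; "
                f"{a!r} is {dataset.kind(a)}")
    catalog = {dataset.name: dataset}
    over = ", ".join(attrs)
    if which.upper() == "Q1":
        text = (f"FINDRULES SCOPE t1 IN ({dataset.name}) "
                f"HAVING high: t1.$a >= {delta!r} OVER {over} "
                f"AND low: t1.$a <= {-delta!r} OVER {over};")
    elif which.upper() == "Q2":
        text = (f"FINDRULES SCOPE t1 IN ({dataset.name}), "
                f"t2 IN ({dataset.name}) "
                f"HAVING agree: abs(t1.$a - t2.$a) <= {epsilon!r} "
                f"OVER {over};")
    else:
        raise ValueError(f"unknown builtin template {which!r} "
                         f"(expected 'Q1' or 'Q2')")
    return parse_query(text, catalog)
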