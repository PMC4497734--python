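"""Expression syntax for selecting entities from the metadata store.

Every listing command accepts expressions such as::

    individual.common_name = patient1
    flow_cell_id='ABC123' and lane in [1,2]

Grammar: comparisons ``path op literal`` with ops ``= != < > like in``,
joined by ``and`` (binds tighter) and ``or``; parentheses allowed.
Literals are bare words, single-quoted strings, numbers, or bracketed
lists for ``in``.  ``like`` uses ``%`` wildcards.  An empty expression
matches everything.  Evaluation is total: a dotted path that does not
resolve on a row simply fails to match.
"""
from __future__ import annotations

import re
from dataclasses import dataclass


class FilterSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Comparison:
    path: tuple[str, ...]
    op: str
    value: object            # str | float | tuple of those

    def unparse(self) -> str:
        return f"{'.'.join(self.path)} {self.op} {_format_literal(self.value)}"


@dataclass(frozen=True)
class And:
    items: tuple

    def unparse(self) -> str:
        return " and ".join(i.unparse() if isinstance(i, Comparison) else f"({i.unparse()})"
                            for i in self.items)


@dataclass(frozen=True)
class Or:
    items: tuple

    def unparse(self) -> str:
        return " or ".join(i.unparse() for i in self.items)


@dataclass(frozen=True)
class MatchAll:
    def unparse(self) -> str:
        return ""


FilterNode = Comparison | And | Or | MatchAll


@dataclass(frozen=True)
class FilterExpression:
    ast: FilterNode
    OPS = ("=", "!=", "<", ">", "like", "in")

    def unparse(self) -> str:
        return self.ast.unparse()

    def matches(self, resolver) -> bool:
        """Evaluate against ``resolver(path) -> value or None``."""
        return _eval(self.ast, resolver)


def _format_literal(v) -> str:
    if isinstance(v, tuple):
        return "[" + ",".join(_format_literal(x) for x in v) + "]"
    if isinstance(v, (int, float)):
        return repr(v)
    return "'" + str(v) + "'"


_TOKEN_RE = re.compile(r"""
    \s*(?:
      (?P<quoted>'[^']*')
    | (?P<symbol>!=|=|<|>|\[|\]|\(|\)|,)
    | (?P<word>[^\s'=!<>\[\],()]+)
    )""", re.VERBOSE)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise FilterSyntaxError(f"cannot tokenize {text[pos:pos+10]!r}", pos)
            break
        if m.lastgroup == "quoted":
            tokens.append(("quoted", m.group("quoted")[1:-1], m.start("quoted")))
        elif m.lastgroup == "symbol":
            sym = m.group("symbol")
            tokens.append(("symbol", sym, m.start("symbol")))
        elif m.lastgroup == "word":
            tokens.append(("word", m.group("word"), m.start("word")))
        pos = m.end()
    if text.count("'") % 2:
        raise FilterSyntaxError("unbalanced quote", text.rfind("'"))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect_symbol(self, sym: str):
        kind, val, pos = self.next()
        if kind != "symbol" or val != sym:
            raise FilterSyntaxError(f"expected {sym!r}, got {val!r}", pos)

    def parse(self) -> FilterNode:
        if not self.tokens:
            return MatchAll()
        node = self.parse_or()
        kind, val, pos = self.peek()
        if kind is not None:
            raise FilterSyntaxError(f"unexpected trailing token {val!r}", pos)
        return node

    def parse_or(self) -> FilterNode:
        items = [self.parse_and()]
        while self.peek()[:2] == ("word", "or"):
            self.next()
            items.append(self.parse_and())
        return items[0] if len(items) == 1 else Or(tuple(items))

    def parse_and(self) -> FilterNode:
        items = [self.parse_atom()]
        while self.peek()[:2] == ("word", "and"):
            self.next()
            items.append(self.parse_atom())
        return items[0] if len(items) == 1 else And(tuple(items))

    def parse_atom(self) -> FilterNode:
        kind, val, pos = self.peek()
        if kind == "symbol" and val == "(":
            self.next()
            node = self.parse_or()
            self.expect_symbol(")")
            return node
        return self.parse_comparison()

    def parse_comparison(self) -> Comparison:
        kind, val, pos = self.next()
        if kind != "word":
            raise FilterSyntaxError(f"expected a property path, got {val!r}", pos)
        path = tuple(val.split("."))
        kind, op, pos = self.next()
        if kind == "word" and op in ("like", "in"):
            pass
        elif kind == "symbol" and op in ("=", "!=", "<", ">"):
            pass
        else:
            raise FilterSyntaxError(f"unknown operator {op!r}", pos)
        value = self.parse_list() if op == "in" else self.parse_literal()
        return Comparison(path, op, value)

    def parse_literal(self):
        kind, val, pos = self.next()
        if kind == "quoted":
            return val
        if kind == "word":
            return _coerce(val)
        raise FilterSyntaxError(f"expected a literal, got {val!r}", pos)

    def parse_list(self) -> tuple:
        self.expect_symbol("[")
        items = []
        while True:
            kind, val, pos = self.peek()
            if kind == "symbol" and val == "]":
                self.next()
                break
            if kind is None:
                raise FilterSyntaxError("unclosed '['", pos)
            if kind == "symbol" and val == ",":
                self.next()
                continue
            items.append(self.parse_literal())
        return tuple(items)


def _coerce(word: str):
    try:
        return int(word)
    except ValueError:
        pass
    try:
        return float(word)
    except ValueError:
        return word


def parse_filter(text: str) -> FilterExpression:
    """Parse an expression string; an empty string selects everything."""
    return FilterExpression(_Parser(text or "").parse())


def _as_number(v):
    if isinstance(v, (int, float)):
        return float(v)
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def _compare(op: str, actual, literal) -> bool:
    if actual is None:
        return False
    if op == "in":
        return any(_compare("=", actual, item) for item in literal)
    if op == "like":
        pattern = re.escape(str(literal)).replace("%", ".*").replace(r"\%", ".*")
        return re.fullmatch(pattern, str(actual)) is not None
    an, ln = _as_number(actual), _as_number(literal)
    if an is not None and ln is not None:
        a, b = an, ln
    else:
        a, b = str(actual), str(literal)
    if op == "=":
        return a == b
    if op == "!=":
        return a != b
    if op == "<":
        return a < b
    if op == ">":
        return a > b
    raise ValueError(f"unknown operator {op!r}")


def _eval(node: FilterNode, resolver) -> bool:
    if isinstance(node, MatchAll):
        return True
    if isinstance(node, And):
        return all(_eval(i, resolver) for i in node.items)
    if isinstance(node, Or):
        return any(_eval(i, resolver) for i in node.items)
    return _compare(node.op, resolver(node.path), node.value)
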