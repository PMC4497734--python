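"""The variant-detection strategy language.

Processing profiles for variant-calling pipelines carry up to four
strategy expressions (``snv_detection_strategy``,
``indel_detection_strategy``, ``sv_detection_strategy``,
``cnv_detection_strategy``).  Each is a declarative description of
detectors, filters and combination logic, e.g.::

    naive-snv 1.0 [min_vaf=0.15] filtered by depth-filter 1.0 [min_depth=8]
    breakdancer 1.2 [--per-chrom] filtered by sv-assembly-validate 1.0
        union breakdancer 1.2 [--transchrom]

Grammar (whitespace-insensitive, parentheses honored)::

    strategy   := term ('union' term)*
    term       := factor ('intersect' factor)*
    factor     := atom ('filtered by' filterlist)?
    atom       := NAME VERSION PARAMS? | '(' strategy ')'
    filterlist := filter (',' filter)*
    filter     := NAME VERSION PARAMS?
    PARAMS     := '[' ... ']'

``filtered by`` binds tighter than ``intersect``, which binds tighter
than ``union``.  Expressions expand into sub-workflow plans: detectors
marked chunkable in the tool registry scatter by chromosome and gather;
filters chain; combinations merge callsets under the matching policy.
"""
from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field

from .plan import InputRef, PlanGraph, PlanStep, StepOutput


class StrategySyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class FilterSpec:
    name: str
    version: str
    params: str = ""


@dataclass(frozen=True)
class Detector:
    name: str
    version: str
    params: str = ""

    def __post_init__(self):
        if not self.name or not self.version:
            raise ValueError("detector name and version must be non-empty")


@dataclass(frozen=True)
class Filtered:
    child: "StrategyNode"
    filters: tuple[FilterSpec, ...]


@dataclass(frozen=True)
class Combine:
    op: str                      # union | intersect
    left: "StrategyNode"
    right: "StrategyNode"

    def __post_init__(self):
        if self.op not in ("union", "intersect"):
            raise ValueError(f"unknown combinator {self.op!r}")


StrategyNode = Detector | Filtered | Combine

KEYWORDS = {"union", "intersect", "filtered", "by"}

_STRAT_TOKEN_RE = re.compile(r"\s*(?:(?P<params>\[[^\]]*\])|(?P<paren>[(),])|(?P<word>[^\s()\[\],]+))")


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _STRAT_TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise StrategySyntaxError(f"cannot tokenize {text[pos:pos+10]!r}", pos)
            break
        for group in ("params", "paren", "word"):
            if m.group(group):
                tokens.append((group, m.group(group), m.start(group)))
        pos = m.end()
    if text.count("[") != text.count("]"):
        raise StrategySyntaxError("unbalanced brackets", text.rfind("["))
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

    def parse(self) -> StrategyNode:
        if not self.tokens:
            raise StrategySyntaxError("empty strategy expression", 0)
        node = self.parse_strategy()
        kind, val, pos = self.peek()
        if kind is not None:
            raise StrategySyntaxError(f"unexpected trailing token {val!r}", pos)
        return node

    def parse_strategy(self) -> StrategyNode:
        node = self.parse_term()
        while self.peek()[:2] == ("word", "union"):
            self.next()
            node = Combine("union", node, self.parse_term())
        return node

    def parse_term(self) -> StrategyNode:
        node = self.parse_factor()
        while self.peek()[:2] == ("word", "intersect"):
            self.next()
            node = Combine("intersect", node, self.parse_factor())
        return node

    def parse_factor(self) -> StrategyNode:
        node = self.parse_atom()
        if self.peek()[:2] == ("word", "filtered"):
            self.next()
            kind, val, pos = self.next()
            if (kind, val) != ("word", "by"):
                raise StrategySyntaxError(f"expected 'by' after 'filtered', got {val!r}", pos)
            filters = [self.parse_filter()]
            while self.peek()[:2] == ("paren", ","):
                self.next()
                filters.append(self.parse_filter())
            node = Filtered(node, tuple(filters))
        return node

    def parse_atom(self) -> StrategyNode:
        kind, val, pos = self.peek()
        if (kind, val) == ("paren", "("):
            self.next()
            node = self.parse_strategy()
            kind, val, pos = self.next()
            if (kind, val) != ("paren", ")"):
                raise StrategySyntaxError("expected ')'", pos)
            return node
        name, version, params = self._name_version_params()
        return Detector(name, version, params)

    def parse_filter(self) -> FilterSpec:
        name, version, params = self._name_version_params()
        return FilterSpec(name, version, params)

    def _name_version_params(self) -> tuple[str, str, str]:
        kind, name, pos = self.next()
        if kind != "word" or name in KEYWORDS:
            raise StrategySyntaxError(f"expected a tool name, got {name!r}", pos)
        kind, version, pos = self.next()
        if kind != "word" or version in KEYWORDS:
            raise StrategySyntaxError(f"expected a version after {name!r}, got {version!r}", pos)
        params = ""
        if self.peek()[0] == "params":
            params = self.next()[1][1:-1].strip()
        return name, version, params


def parse_strategy(text: str) -> StrategyNode:
    if not text or not text.strip():
        raise StrategySyntaxError("empty strategy expression", 0)
    return _Parser(text).parse()


def parse_params(params: str) -> dict[str, str]:
    """``k=v`` pairs separated by commas/whitespace; bare tokens become
    flag-style keys with empty values."""
    out: dict[str, str] = {}
    for item in re.split(r"[,\s]+", params.strip()):
        if not item:
            continue
        k, _, v = item.partition("=")
        out[k] = v
    return out


def unparse_strategy(node: StrategyNode, _parent: str = "") -> str:
    if isinstance(node, Detector):
        s = f"{node.name} {node.version}"
        return s + (f" [{node.params}]" if node.params else "")
    if isinstance(node, Filtered):
        child = unparse_strategy(node.child, "filtered")
        if isinstance(node.child, (Combine, Filtered)):
            child = f"({child})"
        filters = ", ".join(f"{f.name} {f.version}" + (f" [{f.params}]" if f.params else "")
                            for f in node.filters)
        return f"{child} filtered by {filters}"
    # Combine: parenthesize children whose operator binds looser
    left = unparse_strategy(node.left)
    right = unparse_strategy(node.right)
    if node.op == "intersect":
        if isinstance(node.left, Combine) and node.left.op == "union":
            left = f"({left})"
        if isinstance(node.right, Combine):
            right = f"({right})"
    elif isinstance(node.right, Combine) and node.right.op == "union":
        right = f"({right})"
    return f"{left} {node.op} {right}"


def _canonical(node: StrategyNode):
    if isinstance(node, Detector):
        return ["detector", node.name, node.version, sorted(parse_params(node.params).items())]
    if isinstance(node, Filtered):
        return ["filtered", _canonical(node.child),
                [[f.name, f.version, sorted(parse_params(f.params).items())]
                 for f in node.filters]]
    children = sorted((_canonical(node.left), _canonical(node.right)),
                      key=lambda c: json.dumps(c, sort_keys=True))
    return [node.op] + children


def canonical_strategy_id(node: StrategyNode) -> str:
    """Digest invariant under whitespace, redundant parentheses and
    union/intersect child order (both combinators are commutative)."""
    blob = json.dumps(_canonical(node), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class ExpansionContext:
    """What a strategy needs to become concrete steps."""
    registry: object                      # ToolRegistry
    input_refs: dict[str, InputRef]       # roles tools may consume
    chromosomes: list[str] = field(default_factory=list)
    prefix: str = ""
    depth: int = 1


def _callset_file(registry, node: StrategyNode) -> str:
    """Output filename of the sink step ('calls.vcf' or 'calls.bed')."""
    if isinstance(node, Detector):
        return registry.resolve(node.name, node.version).callset_file
    if isinstance(node, Filtered):
        return _callset_file(registry, node.child)
    return _callset_file(registry, node.left)


def expand_strategy(node: StrategyNode, context: ExpansionContext,
                    graph: PlanGraph | None = None) -> tuple[PlanGraph, StepOutput]:
    """Expand a strategy tree into plan steps.

    Returns the (possibly shared) graph and a reference to the sink
    step's callset file.
    """
    graph = graph if graph is not None else PlanGraph()
    sink = _expand(node, context, graph, context.prefix)
    graph.validate()
    return graph, sink


def _tool_inputs(tool, context: ExpansionContext, step_name: str) -> dict[str, InputRef]:
    refs = {}
    for role in tool.input_roles:
        if role not in context.input_refs:
            raise ValueError(f"step {step_name!r}: context provides no input role {role!r}")
        refs[role] = context.input_refs[role]
    return refs


def _unique_label(graph: PlanGraph, base: str) -> str:
    """Disambiguate repeated tool labels (a scatter detector reserves its
    gather name too, since the bare label never becomes a step itself)."""
    def taken(label: str) -> bool:
        return label in graph.steps or f"{label} (gather)" in graph.steps
    if not taken(base):
        return base
    i = 2
    while taken(f"{base} #{i}"):
        i += 1
    return f"{base} #{i}"


def _expand(node: StrategyNode, ctx: ExpansionContext, graph: PlanGraph,
            prefix: str) -> StepOutput:
    registry = ctx.registry
    if isinstance(node, Detector):
        tool = registry.resolve(node.name, node.version)
        params = parse_params(node.params)
        label = _unique_label(graph, f"{prefix}{node.name} {node.version}")
        if tool.chunkable and ctx.chromosomes:
            parts = []
            for chrom in ctx.chromosomes:
                sname = f"{label} ({chrom})"
                sparams = dict(params, chromosome=chrom)
                graph.add_step(PlanStep(sname, tool.name, tool.version, sparams,
                                        _tool_inputs(tool, ctx, sname),
                                        outputs=(tool.callset_file,),
                                        depth=ctx.depth + 1, scatter_key=chrom))
                parts.append(StepOutput(sname, tool.callset_file))
            gname = _unique_label(graph, f"{label} (gather)")
            graph.add_step(PlanStep(
                gname, "gather-variants", "1.0", {"format": tool.callset_format},
                {f"part_{i}": p for i, p in enumerate(parts)},
                outputs=(tool.callset_file,), depth=ctx.depth))
            return StepOutput(gname, tool.callset_file)
        graph.add_step(PlanStep(label, tool.name, tool.version, params,
                                _tool_inputs(tool, ctx, label),
                                outputs=(tool.callset_file,), depth=ctx.depth))
        return StepOutput(label, tool.callset_file)

    if isinstance(node, Filtered):
        upstream = _expand(node.child, ctx, graph, prefix)
        for f in node.filters:
            tool = registry.resolve(f.name, f.version)
            label = _unique_label(graph, f"{prefix}{f.name} {f.version}")
            inputs = dict(_tool_inputs(tool, ctx, label))
            inputs["calls"] = upstream
            graph.add_step(PlanStep(label, tool.name, tool.version,
                                    parse_params(f.params), inputs,
                                    outputs=(upstream.filename,), depth=ctx.depth))
            upstream = StepOutput(label, upstream.filename)
        return upstream

    # Combine
    left = _expand(node.left, ctx, graph, prefix)
    right = _expand(node.right, ctx, graph, prefix)
    fmt = "bed" if left.filename.endswith(".bed") else "vcf"
    matching = "interval" if fmt == "bed" else "allele"
    label = f"{prefix}{node.op} #{len(graph.steps)}"
    out_file = left.filename
    graph.add_step(PlanStep(label, "combine-variants", "1.0",
                            {"op": node.op, "matching": matching, "format": fmt},
                            {"left": left, "right": right},
                            outputs=(out_file,), depth=ctx.depth))
    return StepOutput(label, out_file)
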