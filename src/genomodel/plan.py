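"""Executable workflow plans.

A :class:`PlanGraph` is the expanded, concrete form of a pipeline: a
DAG of tool invocations with bound parameters, explicit data edges and
per-chromosome scatter/gather groups.  The build engine executes plans
step by step; the strategy DSL and the pipeline definitions produce
them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass(frozen=True)
class FileInput:
    """A workflow-level input file, referenced by role name."""
    role: str


@dataclass(frozen=True)
class StepOutput:
    """An output file of an upstream step."""
    step: str
    filename: str


InputRef = FileInput | StepOutput


@dataclass
class PlanStep:
    name: str
    tool: str
    version: str
    params: dict[str, str] = field(default_factory=dict)
    inputs: dict[str, InputRef] = field(default_factory=dict)
    outputs: tuple[str, ...] = ("calls.vcf",)
    depth: int = 0                  # display nesting level
    scatter_key: str | None = None  # chromosome, for scatter steps


class PlanError(ValueError):
    pass


class PlanGraph:
    """Steps + dependency edges + the mapping from build-relative output
    paths to the producing (step, filename)."""

    def __init__(self):
        self.steps: dict[str, PlanStep] = {}
        self.graph = nx.DiGraph()
        self.input_files: dict[str, str] = {}          # role -> path
        self.final_outputs: dict[str, StepOutput] = {}  # rel path -> producer

    def declare_input(self, role: str, path: str) -> FileInput:
        self.input_files[role] = str(path)
        return FileInput(role)

    def add_step(self, step: PlanStep) -> PlanStep:
        if step.name in self.steps:
            raise PlanError(f"duplicate step name {step.name!r}")
        self.steps[step.name] = step
        self.graph.add_node(step.name)
        for ref in step.inputs.values():
            if isinstance(ref, StepOutput):
                if ref.step not in self.steps:
                    raise PlanError(f"step {step.name!r} consumes unknown step {ref.step!r}")
                if ref.filename not in self.steps[ref.step].outputs:
                    raise PlanError(f"step {ref.step!r} does not produce {ref.filename!r}")
                self.graph.add_edge(ref.step, step.name)
            elif ref.role not in self.input_files:
                raise PlanError(f"step {step.name!r} consumes undeclared input {ref.role!r}")
        return step

    def expose(self, rel_path: str, step: str, filename: str) -> None:
        self.final_outputs[rel_path] = StepOutput(step, filename)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise PlanError("plan graph contains a cycle")
        for rel, ref in self.final_outputs.items():
            if ref.step not in self.steps:
                raise PlanError(f"final output {rel!r} references unknown step {ref.step!r}")

    def topological_order(self) -> list[str]:
        """Deterministic topological order (lexicographic tie-break)."""
        return list(nx.lexicographical_topological_sort(self.graph))

    def dependencies(self, step_name: str) -> list[str]:
        return sorted(self.graph.predecessors(step_name))

    def descendants(self, step_name: str) -> set[str]:
        return nx.descendants(self.graph, step_name)
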