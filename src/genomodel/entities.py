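"""Persistent entity types of the metadata model.

The hierarchy mirrors how sequencing cores track material: an
individual owns samples, a sample owns instrument-data units (one per
flow cell / lane / index barcode), and analysis products hang off
models (subject + processing profile + inputs) whose executions are
immutable builds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class Individual:
    id: str = ""
    common_name: str = ""
    species: str = "human"
    kind = "individual"


@dataclass
class Sample:
    id: str = ""
    common_name: str = ""
    individual_id: str = ""
    extraction_type: str = "dna"     # dna | rna
    kind = "sample"

    def __post_init__(self):
        if self.extraction_type not in ("dna", "rna"):
            raise ValueError(f"extraction_type must be dna or rna, got {self.extraction_type!r}")


@dataclass
class InstrumentData:
    id: str = ""
    sample_id: str = ""
    flow_cell_id: str = ""
    lane: int = 1
    index_sequence: str | None = None
    read_path: str = ""
    read_count: int = 0
    kind = "instrument_data"

    def __post_init__(self):
        if self.lane < 1:
            raise ValueError("lane must be a positive integer")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")


@dataclass
class ProcessingProfile:
    id: str = ""
    name: str = ""
    type_name: str = ""              # e.g. "reference alignment", "somatic variation"
    params: dict[str, str] = field(default_factory=dict)
    kind = "processing_profile"

    def canonical_params(self) -> list[tuple[str, str]]:
        return sorted((k, str(v)) for k, v in self.params.items())


@dataclass
class InputSpec:
    name: str = ""                   # role label: instrument_data, reference, ...
    value_id: str = ""


@dataclass
class Model:
    id: str = ""
    name: str = ""
    subject_id: str = ""             # Individual or Sample id
    processing_profile_id: str = ""
    inputs: list[InputSpec] = field(default_factory=list)
    kind = "model"

    def input_ids(self, role: str) -> list[str]:
        return [i.value_id for i in self.inputs if i.name == role]


BUILD_STATUSES = ("new", "scheduled", "running", "succeeded", "failed")


@dataclass
class Build:
    id: str = ""
    model_id: str = ""
    status: str = "new"
    data_directory: str = ""
    resolved_inputs: dict[str, list[str]] = field(default_factory=dict)
    software_version: str = ""
    created_at: str = ""
    completed_at: str = ""
    kind = "build"

    def __post_init__(self):
        if self.status not in BUILD_STATUSES:
            raise ValueError(f"bad build status {self.status!r}")


@dataclass
class ReferenceSequence:
    id: str = ""
    name: str = ""
    fasta_path: str = ""
    kind = "reference_sequence"


@dataclass
class Annotation:
    id: str = ""
    name: str = ""
    bed_path: str = ""
    kind = "annotation"


STEP_STATUSES = ("new", "scheduled", "running", "succeeded", "failed", "shortcut")
# forward-only transitions; "shortcut" is reached directly from "new"
STEP_TRANSITIONS = {
    "new": {"scheduled", "shortcut"},
    "scheduled": {"running"},
    "running": {"succeeded", "failed"},
    "succeeded": set(), "failed": set(), "shortcut": set(),
}


@dataclass
class StepRecord:
    id: str = ""
    build_id: str = ""
    name: str = ""
    status: str = "new"
    depth: int = 0
    job_id: str = ""
    log_path: str = ""
    result_id: str = ""
    started_at: str = ""
    stopped_at: str = ""
    kind = "step"

    def transition(self, new_status: str) -> None:
        if new_status not in STEP_TRANSITIONS.get(self.status, set()):
            raise ValueError(f"illegal step transition {self.status} -> {new_status}")
        self.status = new_status


ENTITY_CLASSES = {
    cls.kind: cls
    for cls in (Individual, Sample, InstrumentData, ProcessingProfile,
                Model, Build, ReferenceSequence, Annotation, StepRecord)
}

ID_PREFIXES = {
    "individual": "IND", "sample": "S", "instrument_data": "I",
    "processing_profile": "P", "model": "M", "build": "B",
    "reference_sequence": "R", "annotation": "A", "step": "ST",
}

# dotted-path reference hops: kind -> {hop name: (target kind, id field)}
REFERENCES = {
    "sample": {"individual": ("individual", "individual_id")},
    "instrument_data": {"sample": ("sample", "sample_id")},
    "model": {"processing_profile": ("processing_profile", "processing_profile_id")},
    "build": {"model": ("model", "model_id")},
    "step": {"build": ("build", "build_id")},
}


def to_payload(entity) -> dict:
    d = asdict(entity)
    d["kind"] = entity.kind
    return d


def from_payload(d: dict):
    d = dict(d)
    kind = d.pop("kind")
    cls = ENTITY_CLASSES[kind]
    if kind == "model":
        d["inputs"] = [InputSpec(**i) for i in d.get("inputs", [])]
    return cls(**d)
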