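"""Pipeline types: what inputs a model needs and how its build plan is
composed.

Two pipelines ship with the system:

* **reference alignment** — aligns each instrument-data unit against a
  reference sequence, merges, and (optionally) runs the profile's SNV
  and indel detection strategies to produce a germline callset.
* **somatic variation** — takes two reference-alignment *models* as
  inputs (tumor and normal; resolved to their last complete builds),
  runs the detection strategies on each sample's alignments, subtracts
  normal from tumor, performs LOH analysis, annotates effects and runs
  the CNV/SV strategies on the tumor/normal alignment pair.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .entities import Model, ProcessingProfile
from .plan import PlanGraph, PlanStep, StepOutput
from .strategy import ExpansionContext, expand_strategy, parse_strategy

STRATEGY_FIELDS = ("snv_detection_strategy", "indel_detection_strategy",
                   "sv_detection_strategy", "cnv_detection_strategy")

ROLE_KINDS = {
    "instrument_data": "instrument_data",
    "reference": "reference_sequence",
    "annotation": "annotation",
    "tumor_model": "model",
    "normal_model": "model",
}


@dataclass
class PipelineType:
    type_name: str
    required_roles: tuple[str, ...]
    optional_roles: tuple[str, ...] = ()

    @property
    def allowed(self) -> set[str]:
        return set(self.required_roles) | set(self.optional_roles)


PIPELINES = {
    "reference alignment": PipelineType(
        "reference alignment", ("instrument_data", "reference")),
    "somatic variation": PipelineType(
        "somatic variation", ("tumor_model", "normal_model", "reference"),
        ("annotation",)),
}


class PipelineError(ValueError):
    pass


def get_pipeline(type_name: str) -> PipelineType:
    canon = type_name.replace("-", " ")
    if canon not in PIPELINES:
        raise PipelineError(f"unknown pipeline type {type_name!r}")
    return PIPELINES[canon]


def allowed_roles(type_name: str) -> set[str]:
    return get_pipeline(type_name).allowed


def role_kind(role: str) -> str:
    if role not in ROLE_KINDS:
        raise PipelineError(f"unknown input role {role!r}")
    return ROLE_KINDS[role]


def validate_profile(profile: ProcessingProfile) -> None:
    """Strategy fields of a variant-calling profile must parse."""
    for field in STRATEGY_FIELDS:
        if field in profile.params:
            parse_strategy(profile.params[field])


def missing_required_roles(pipeline: PipelineType, model: Model) -> list[str]:
    return [r for r in pipeline.required_roles if not model.input_ids(r)]


# --------------------------------------------------------------------------
# plan composition
# --------------------------------------------------------------------------

def _reference_context(store, resolved: dict[str, list[str]]):
    ref = store.get("reference_sequence", resolved["reference"][0])
    from .formats import read_fasta
    chroms = sorted(read_fasta(ref.fasta_path))
    return ref, chroms


def compose_reference_alignment(model: Model, profile: ProcessingProfile,
                                resolved: dict[str, list[str]], store,
                                registry) -> PlanGraph:
    graph = PlanGraph()
    ref, chroms = _reference_context(store, resolved)
    ref_in = graph.declare_input("reference", ref.fasta_path)

    merge_inputs = {}
    for i, inst_id in enumerate(resolved["instrument_data"]):
        inst = store.get("instrument_data", inst_id)
        reads_in = graph.declare_input(f"reads_{inst_id}", inst.read_path)
        step = PlanStep(f"align {inst_id}", "naive-align", "1.0",
                        {k: profile.params[k] for k in ("seed_length", "max_mismatches")
                         if k in profile.params},
                        {"reads": reads_in, "reference": ref_in},
                        outputs=("alignments.tsv",))
        graph.add_step(step)
        merge_inputs[f"aln_{i:03d}"] = StepOutput(step.name, "alignments.tsv")
    graph.add_step(PlanStep("merge alignments", "merge-alignments", "1.0", {},
                            merge_inputs, outputs=("alignments.tsv",)))
    aln_ref = StepOutput("merge alignments", "alignments.tsv")
    graph.expose("alignments/alignments.tsv", "merge alignments", "alignments.tsv")

    ctx_refs = {"alignments": aln_ref, "reference": ref_in}
    for field, out_name in (("snv_detection_strategy", "variants/snvs.vcf"),
                            ("indel_detection_strategy", "variants/indels.vcf")):
        if field in profile.params:
            node = parse_strategy(profile.params[field])
            label = field.split("_")[0]
            ctx = ExpansionContext(registry, ctx_refs, chromosomes=chroms,
                                   prefix=f"{label}: ")
            _, sink = expand_strategy(node, ctx, graph)
            graph.expose(out_name, sink.step, sink.filename)
    graph.validate()
    return graph


def compose_somatic_variation(model: Model, profile: ProcessingProfile,
                              resolved: dict[str, list[str]], store,
                              registry) -> PlanGraph:
    graph = PlanGraph()
    ref, chroms = _reference_context(store, resolved)
    ref_in = graph.declare_input("reference", ref.fasta_path)

    builds = {role: store.get("build", resolved[role][0])
              for role in ("tumor_model", "normal_model")}
    aln = {}
    for role, b in builds.items():
        label = role.split("_")[0]           # tumor / normal
        path = str(Path(b.data_directory) / "alignments" / "alignments.tsv")
        aln[label] = graph.declare_input(f"{label}_alignments", path)

    ann_in = None
    if resolved.get("annotation"):
        ann = store.get("annotation", resolved["annotation"][0])
        ann_in = graph.declare_input("annotation", ann.bed_path)

    sinks = {}
    for field, kind in (("snv_detection_strategy", "snv"),
                        ("indel_detection_strategy", "indel")):
        if field not in profile.params:
            continue
        node = parse_strategy(profile.params[field])
        per_sample = {}
        for label in ("tumor", "normal"):
            ctx = ExpansionContext(
                registry,
                {"alignments": aln[label], "reference": ref_in,
                 "tumor_alignments": aln["tumor"], "normal_alignments": aln["normal"]},
                chromosomes=chroms, prefix=f"{label} {kind}s: ")
            _, per_sample[label] = expand_strategy(node, ctx, graph)
        sub_name = f"{kind} somatic subtraction"
        graph.add_step(PlanStep(
            sub_name, "somatic-subtract", "1.0",
            {k: profile.params[k] for k in ("max_normal_vaf",) if k in profile.params},
            {"tumor_calls": per_sample["tumor"], "normal_calls": per_sample["normal"],
             "normal_alignments": aln["normal"], "reference": ref_in},
            outputs=("calls.vcf",)))
        sinks[kind] = (sub_name, per_sample)
        graph.expose(f"variants/{kind}s.somatic.vcf", sub_name, "calls.vcf")

    if "snv" in sinks:
        sub_name, per_sample = sinks["snv"]
        graph.add_step(PlanStep(
            "loh analysis", "loh-flag", "1.0",
            {k: profile.params[k] for k in ("hom_vaf_threshold",) if k in profile.params},
            {"tumor_calls": per_sample["tumor"], "normal_calls": per_sample["normal"]},
            outputs=("calls.vcf",)))
        graph.expose("variants/loh.vcf", "loh analysis", "calls.vcf")
        if ann_in is not None:
            graph.add_step(PlanStep(
                "annotate somatic snvs", "annotate-effects", "1.0", {},
                {"calls": StepOutput(sub_name, "calls.vcf"), "annotation": ann_in},
                outputs=("calls.vcf",)))
            graph.expose("variants/snvs.annotated.vcf", "annotate somatic snvs", "calls.vcf")

    for field, out_name, label in (("cnv_detection_strategy", "variants/cnvs.bed", "cnv"),
                                   ("sv_detection_strategy", "variants/svs.bed", "sv")):
        if field not in profile.params:
            continue
        node = parse_strategy(profile.params[field])
        ctx = ExpansionContext(
            registry,
            {"tumor_alignments": aln["tumor"], "normal_alignments": aln["normal"],
             "reference": ref_in},
            chromosomes=chroms, prefix=f"{label}s: ")
        _, sink = expand_strategy(node, ctx, graph)
        graph.expose(out_name, sink.step, sink.filename)

    graph.validate()
    return graph


COMPOSERS = {
    "reference alignment": compose_reference_alignment,
    "somatic variation": compose_somatic_variation,
}


def compose_plan(model: Model, profile: ProcessingProfile,
                 resolved: dict[str, list[str]], store, registry) -> PlanGraph:
    composer = COMPOSERS.get(profile.type_name)
    if composer is None:
        raise PipelineError(f"no plan composer for pipeline {profile.type_name!r}")
    return composer(model, profile, resolved, store, registry)
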