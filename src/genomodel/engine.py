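"""The build engine: turning models into immutable builds.

A build resolves its model's inputs (model-valued inputs become that
model's last complete build), composes the pipeline's plan graph, and
executes steps in dependency order.  Every step's output is recorded
as a content-keyed :class:`ResultRecord`; when a later build computes
the same key — same tool, version, implementation fingerprint,
parameters and input digests — the step *shortcuts*: the recorded
result is reused and no tool runs.

Outputs of cached and uncached runs are byte-identical because every
tool is deterministic and every output file is hashed into the build
manifest, which is itself part of the determinism contract.
"""
from __future__ import annotations

import datetime
import hashlib
import json
import os
import shutil
import uuid
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import __version__
from .entities import Build, Model, StepRecord
from .pipelines import get_pipeline, missing_required_roles, compose_plan, validate_profile
from .plan import FileInput, PlanGraph, StepOutput
from .store import MetadataStore, StoreError, ImmutableError
from .tools import ToolRegistry, default_registry


class BuildError(ValueError):
    pass


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


@dataclass
class StepContext:
    """Runtime surface a tool implementation sees."""
    inputs: dict[str, Path]
    params: dict[str, str]
    out_dir: Path
    log_lines: list[str] = field(default_factory=list)

    def input(self, role: str) -> Path:
        if role not in self.inputs:
            raise BuildError(f"step has no input role {role!r}")
        return self.inputs[role]

    def out(self, filename: str) -> Path:
        return self.out_dir / filename

    def log(self, msg: str) -> None:
        self.log_lines.append(str(msg))


class BuildEngine:
    """Executes builds against a metadata store rooted at ``root``.

    ``use_cache=False`` disables shortcutting (every tool runs).
    ``strict_version_key=True`` additionally keys results on the
    package version, so results never survive a software upgrade.
    """

    def __init__(self, store: MetadataStore, root: str | Path,
                 registry: ToolRegistry | None = None, use_cache: bool = True,
                 strict_version_key: bool = False,
                 software_version: str = __version__):
        self.store = store
        self.root = Path(root)
        self.registry = registry or default_registry()
        self.use_cache = use_cache
        self.strict_version_key = strict_version_key
        self.software_version = software_version
        sandbox = self.root / "sandbox"
        if sandbox.is_dir():
            self.registry.load_sandbox(sandbox)
        self.results_dir = self.root / "fs" / "results"
        self.last_stats: dict[str, int] = {}

    # -- input resolution ------------------------------------------------
    def resolve_inputs(self, model: Model) -> dict[str, list[str]]:
        """Freeze the model's inputs; model-valued roles resolve to the
        input model's most recently completed (succeeded) build."""
        resolved: dict[str, list[str]] = {}
        for inp in model.inputs:
            entity = self.store.find(inp.value_id)
            if entity.kind == "model":
                builds = [b for b in self.store.all("build")
                          if b.model_id == entity.id and b.status == "succeeded"]
                if not builds:
                    raise BuildError(
                        f"input model {entity.id} has no complete build")
                best = max(builds, key=lambda b: (b.completed_at, b.id))
                resolved.setdefault(inp.name, []).append(best.id)
            else:
                resolved.setdefault(inp.name, []).append(inp.value_id)
        return resolved

    # -- build lifecycle -------------------------------------------------
    def start_build(self, model_id: str, order: str = "topo", rng=None) -> Build:
        model = self.store.get("model", model_id)
        profile = self.store.get("processing_profile", model.processing_profile_id)
        validate_profile(profile)
        pipeline = get_pipeline(profile.type_name)
        missing = missing_required_roles(pipeline, model)
        if missing:
            raise BuildError(
                f"model {model_id} is missing required input role(s): {', '.join(missing)}")
        resolved = self.resolve_inputs(model)

        build = Build(model_id=model_id, status="running",
                      resolved_inputs=resolved,
                      software_version=self.software_version, created_at=_now())
        self.store.insert(build)
        build.data_directory = str(self.root / "fs" / "model_data" / model_id
                                   / f"build{build.id}")
        self.store.update(build)
        Path(build.data_directory, "logs").mkdir(parents=True, exist_ok=True)

        plan = compose_plan(model, profile, resolved, self.store, self.registry)
        self._register_raw_inputs(plan, resolved)
        self._execute_plan(build, plan, order=order, rng=rng)
        return self.store.get("build", build.id)

    def _register_raw_inputs(self, plan: PlanGraph, resolved: dict[str, list[str]]) -> None:
        for role, path in plan.input_files.items():
            if not Path(path).exists():
                raise BuildError(f"workflow input {role!r} missing on disk: {path}")
            digest = sha256_file(path)
            if role.startswith("reads_"):
                self.store.index_file(digest, "instrument_data", role[len("reads_"):])
            elif role == "reference" and resolved.get("reference"):
                self.store.index_file(digest, "reference_sequence", resolved["reference"][0])
            elif role == "annotation" and resolved.get("annotation"):
                self.store.index_file(digest, "annotation", resolved["annotation"][0])

    # -- step execution --------------------------------------------------
    def _result_key(self, tool, params: dict[str, str], input_digests: list[str]) -> str:
        payload = {
            "tool_name": tool.name, "tool_version": tool.version,
            "fingerprint": tool.fingerprint,
            "params": sorted((k, str(v)) for k, v in params.items()),
            "input_digests": input_digests,
        }
        if self.strict_version_key:
            payload["software_version"] = self.software_version
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()

    def _output_digest(self, out_dir: Path, filenames) -> str:
        pairs = [(f, sha256_file(out_dir / f)) for f in sorted(filenames)]
        return hashlib.sha256(json.dumps(pairs).encode()).hexdigest()

    def _execute_plan(self, build: Build, plan: PlanGraph, order: str = "topo",
                      rng=None) -> None:
        stats = {"executed": 0, "shortcut": 0, "failed": 0, "skipped": 0}
        # step name -> (result_id, result dir) once finished
        finished: dict[str, tuple[str, Path]] = {}
        failed_steps: set[str] = set()
        job_counter = 0

        if order == "random" and rng is not None:
            step_order = self._random_topological(plan, rng)
        else:
            step_order = plan.topological_order()

        records: dict[str, StepRecord] = {}
        for name in plan.steps:
            rec = StepRecord(build_id=build.id, name=name,
                             depth=plan.steps[name].depth)
            self.store.insert(rec)
            records[name] = rec

        for name in step_order:
            step = plan.steps[name]
            rec = records[name]
            deps = plan.dependencies(name)
            if any(d not in finished for d in deps):
                # an upstream failure (direct or transitive): leave the
                # step untouched in status "new" and keep going elsewhere
                stats["skipped"] += 1
                continue

            tool = self.registry.resolve(step.tool, step.version)
            input_paths, input_digests = self._bind_inputs(plan, step, finished)
            result_id = self._result_key(tool, step.params, input_digests)
            log_path = Path(build.data_directory) / "logs" / (_safe(name) + ".log")
            rec.log_path = str(log_path)
            job_counter += 1
            rec.job_id = f"job-{job_counter}"

            cached = self.store.get_result(result_id) if self.use_cache else None
            if cached is not None and self._verify_result(cached):
                rec.result_id = result_id
                rec.started_at = rec.stopped_at = _now()
                rec.transition("shortcut")
                self.store.update(rec)
                log_path.write_text(
                    f"shortcut: reusing result {result_id[:16]} "
                    f"created by build {cached['creating_build_id']}\n")
                finished[name] = (result_id, Path(cached["output_dir"]))
                stats["shortcut"] += 1
                continue

            rec.transition("scheduled")
            rec.started_at = _now()
            rec.transition("running")
            self.store.update(rec)
            tmp_dir = self.root / "fs" / "tmp" / f"run-{uuid.uuid4().hex}"
            tmp_dir.mkdir(parents=True, exist_ok=True)
            ctx = StepContext(inputs=input_paths, params=dict(step.params), out_dir=tmp_dir)
            try:
                tool.func(ctx)
                for f in step.outputs:
                    if not (tmp_dir / f).exists():
                        raise BuildError(f"tool {tool.name} did not produce {f!r}")
            except Exception as exc:  # noqa: BLE001 - failure is a recorded outcome
                rec.stopped_at = _now()
                rec.transition("failed")
                self.store.update(rec)
                log_path.write_text("\n".join(ctx.log_lines + [f"ERROR: {exc}"]) + "\n")
                failed_steps.add(name)
                stats["failed"] += 1
                shutil.rmtree(tmp_dir, ignore_errors=True)
                continue

            out_dir = self._store_result_dir(result_id, tmp_dir)
            output_digest = self._output_digest(out_dir, step.outputs)
            record = {
                "result_id": result_id, "tool_name": tool.name,
                "tool_version": tool.version, "fingerprint": tool.fingerprint,
                "params": sorted((k, str(v)) for k, v in step.params.items()),
                "input_digests": input_digests,
                "output_paths": sorted(step.outputs),
                "output_digest": output_digest,
                "output_dir": str(out_dir),
                "creating_build_id": build.id,
            }
            self.store.put_result(record)
            for f in step.outputs:
                self.store.index_file(sha256_file(out_dir / f), "result", result_id)
            rec.result_id = result_id
            rec.stopped_at = _now()
            rec.transition("succeeded")
            self.store.update(rec)
            log_path.write_text("\n".join(ctx.log_lines) + ("\n" if ctx.log_lines else ""))
            finished[name] = (result_id, out_dir)
            stats["executed"] += 1

        self.last_stats = stats
        if stats["failed"] or stats["skipped"]:
            build.status = "failed"
            build.completed_at = _now()
            self.store.update(build)
        else:
            self._finalize(build, plan, finished)

    def _random_topological(self, plan: PlanGraph, rng) -> list[str]:
        g = plan.graph.copy()
        order = []
        ready = sorted(n for n in g if g.in_degree(n) == 0)
        while ready:
            pick = ready.pop(int(rng.integers(len(ready))) if hasattr(rng, "integers")
                             else rng.randrange(len(ready)))
            order.append(pick)
            succ = sorted(g.successors(pick))
            g.remove_node(pick)
            ready = sorted(set(ready) | {n for n in succ if g.in_degree(n) == 0})
        return order

    def _bind_inputs(self, plan: PlanGraph, step, finished):
        input_paths: dict[str, Path] = {}
        digests: list[str] = []
        for role in sorted(step.inputs):
            ref = step.inputs[role]
            if isinstance(ref, FileInput):
                path = Path(plan.input_files[ref.role])
                input_paths[role] = path
                digests.append(f"raw:{sha256_file(path)}")
            else:
                rid, out_dir = finished[ref.step]
                input_paths[role] = out_dir / ref.filename
                digests.append(f"res:{rid}:{ref.filename}")
        return input_paths, digests

    def _store_result_dir(self, result_id: str, tmp_dir: Path) -> Path:
        out_dir = self.results_dir / result_id[:24]
        if out_dir.exists():
            # same key recomputed (cache disabled); keep the existing copy
            shutil.rmtree(tmp_dir, ignore_errors=True)
            return out_dir
        out_dir.parent.mkdir(parents=True, exist_ok=True)
        os.replace(tmp_dir, out_dir)
        return out_dir

    def _verify_result(self, record: dict) -> bool:
        """Shortcut only when the recorded outputs still hash correctly
        (self-healing: a corrupted cache entry is recomputed)."""
        out_dir = Path(record["output_dir"])
        try:
            return self._output_digest(out_dir, record["output_paths"]) == \
                record["output_digest"]
        except OSError:
            return False

    def _finalize(self, build: Build, plan: PlanGraph, finished) -> None:
        build_dir = Path(build.data_directory)
        manifest_rows = []
        for rel_path in sorted(plan.final_outputs):
            ref = plan.final_outputs[rel_path]
            rid, out_dir = finished[ref.step]
            dest = build_dir / rel_path
            dest.parent.mkdir(parents=True, exist_ok=True)
            shutil.copyfile(out_dir / ref.filename, dest)
            digest = sha256_file(dest)
            self.store.index_file(digest, "result", rid)
            manifest_rows.append(f"{rel_path}\t{digest}\t{ref.step}\t{rid}\n")
        (build_dir / "manifest").write_text("".join(manifest_rows), encoding="ascii")
        build.status = "succeeded"
        build.completed_at = _now()
        self.store.update(build)

    # -- inspection ------------------------------------------------------
    def build_status(self, build_id: str) -> dict:
        build = self.store.get("build", build_id)
        model = self.store.get("model", build.model_id)
        steps = sorted((s for s in self.store.all("step") if s.build_id == build_id),
                       key=lambda s: int(s.id[2:]))
        return {
            "build": build,
            "model_name": model.name,
            "processing_profile_id": model.processing_profile_id,
            "user": os.environ.get("USER", "analyst"),
            "steps": steps,
        }

    def read_manifest(self, build_id: str) -> list[tuple[str, str, str, str]]:
        build = self.store.get("build", build_id)
        rows = []
        manifest = Path(build.data_directory) / "manifest"
        if manifest.exists():
            for line in manifest.read_text().splitlines():
                rel, digest, step, rid = line.split("\t")
                rows.append((rel, digest, step, rid))
        return rows

    def verify_build(self, build_id: str) -> None:
        """Re-hash every manifest file; raise on tampering."""
        build = self.store.get("build", build_id)
        for rel, digest, step, _rid in self.read_manifest(build_id):
            actual = sha256_file(Path(build.data_directory) / rel)
            if actual != digest:
                raise ImmutableError(
                    f"build {build_id} output {rel} was modified (step {step})")

    def open_build_file(self, build_id: str, rel_path: str, mode: str = "r"):
        """Access a build output; write modes on a succeeded build raise."""
        build = self.store.get("build", build_id)
        if build.status == "succeeded" and any(c in mode for c in "wa+"):
            raise ImmutableError(f"build {build_id} is immutable; cannot open "
                                 f"{rel_path!r} for writing")
        return open(Path(build.data_directory) / rel_path, mode)

    # -- provenance ------------------------------------------------------
    def trace_provenance(self, target: str) -> nx.DiGraph:
        """Full derived-from ancestry of a build, result, entity or file
        digest.  Edges point from product to source; leaves are
        instrument data and declared reference/annotation inputs."""
        g = nx.DiGraph()
        start = self._target_node(target)
        self._walk(start, g, set())
        return g

    def _target_node(self, target: str) -> tuple[str, str]:
        if self.store.get_result(target) is not None:
            return ("result", target)
        try:
            entity = self.store.find(target)
            return (entity.kind, entity.id)
        except StoreError:
            pass
        looked = self.store.lookup_file(target)
        if looked:
            return looked
        raise BuildError(f"unknown provenance target {target!r}")

    def _walk(self, node: tuple[str, str], g: nx.DiGraph, seen: set) -> None:
        if node in seen:
            return
        seen.add(node)
        g.add_node(node)
        ntype, nid = node
        if ntype == "build":
            for _rel, _digest, _step, rid in self.read_manifest(nid):
                g.add_edge(node, ("result", rid))
                self._walk(("result", rid), g, seen)
        elif ntype == "result":
            record = self.store.get_result(nid)
            if record is None:
                return
            for dig in record["input_digests"]:
                if dig.startswith("res:"):
                    rid = dig.split(":")[1]
                    g.add_edge(node, ("result", rid))
                    self._walk(("result", rid), g, seen)
                else:
                    raw = dig[len("raw:"):]
                    looked = self.store.lookup_file(raw)
                    child = looked if looked else ("file", raw)
                    g.add_edge(node, child)
                    self._walk(child, g, seen)
        # instrument_data / reference_sequence / annotation / file are leaves


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)[:120]
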