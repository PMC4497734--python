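"""Build engine: input resolution, shortcutting, failure policy, order
independence, immutability and provenance."""
import hashlib
from pathlib import Path

import numpy as np
import pytest

from genomodel import entities as E
from genomodel.engine import BuildEngine, BuildError, sha256_file
from genomodel.store import ImmutableError, MetadataStore
from genomodel.tools import ToolImpl


def primary_digests(build) -> dict[str, str]:
    """Hashes of every non-log file in a build directory."""
    base = Path(build.data_directory)
    return {str(p.relative_to(base)): sha256_file(p)
            for p in sorted(base.rglob("*"))
            if p.is_file() and "logs" not in p.parts}


class TestResolveInputs:
    def test_model_input_resolves_to_latest_succeeded_build(self, tiny_pipeline):
        tp = tiny_pipeline
        m = tp.store.get("model", tp.somatic_model)
        resolved = tp.engine.resolve_inputs(m)
        assert resolved["tumor_model"] == [tp.tumor_build]
        assert resolved["normal_model"] == [tp.normal_build]
        # failed builds never win: insert one newer failed build
        tp.store.insert(E.Build(model_id=tp.tumor_model, status="failed",
                                data_directory="/nope", completed_at="2999-01-01"))
        assert tp.engine.resolve_inputs(m)["tumor_model"] == [tp.tumor_build]

    def test_raw_inputs_pass_through(self, tiny_pipeline):
        tp = tiny_pipeline
        m = tp.store.get("model", tp.tumor_model)
        resolved = tp.engine.resolve_inputs(m)
        assert resolved["reference"] == ["R1"]
        assert set(resolved["instrument_data"]) == {"I1", "I2", "I3"}

    def test_input_model_without_builds_is_an_error(self, tiny_pipeline):
        tp = tiny_pipeline
        m2 = tp.store.define_model("reference-alignment", "S3", "P2", "relapse")
        ms = tp.store.define_model("somatic-variation", "IND1", "P3", "r vs n")
        tp.store.add_model_input(ms.id, "tumor_model", m2.id)
        tp.store.add_model_input(ms.id, "normal_model", tp.normal_model)
        tp.store.add_model_input(ms.id, "reference", "R1")
        with pytest.raises(BuildError, match="no complete build"):
            tp.engine.resolve_inputs(tp.store.get("model", ms.id))


class TestStartBuild:
    def test_build_directory_layout(self, tiny_pipeline):
        tp = tiny_pipeline
        b = tp.store.get("build", tp.tumor_build)
        expected = tp.root / "fs" / "model_data" / tp.tumor_model / f"build{b.id}"
        assert Path(b.data_directory) == expected
        assert (expected / "alignments" / "alignments.tsv").exists()
        assert (expected / "manifest").exists()

    def test_missing_required_role_reported_before_running(self, tiny_pipeline):
        tp = tiny_pipeline
        ms = tp.store.define_model("somatic-variation", "IND1", "P3", "incomplete")
        tp.store.add_model_input(ms.id, "tumor_model", tp.tumor_model)
        tp.store.add_model_input(ms.id, "reference", "R1")
        with pytest.raises(BuildError, match="normal_model"):
            tp.engine.start_build(ms.id)

    def test_model_may_be_built_multiple_times(self, tiny_pipeline):
        tp = tiny_pipeline
        again = tp.engine.start_build(tp.somatic_model)
        builds = [b for b in tp.store.all("build") if b.model_id == tp.somatic_model]
        assert len(builds) >= 2 and again.id != tp.somatic_build


class TestShortcutting:
    def test_identical_rebuild_shortcuts_every_step(self, tiny_pipeline):
        tp = tiny_pipeline
        b2 = tp.engine.start_build(tp.somatic_model)
        assert b2.status == "succeeded"
        assert tp.engine.last_stats["executed"] == 0
        assert tp.engine.last_stats["shortcut"] > 0
        steps = [s for s in tp.store.all("step") if s.build_id == b2.id]
        assert all(s.status == "shortcut" for s in steps)

    def test_shortcut_outputs_byte_identical_to_uncached_run(self, tiny_pipeline):
        tp = tiny_pipeline
        cached = tp.engine.start_build(tp.somatic_model)
        nc = BuildEngine(tp.store, tp.root, use_cache=False)
        uncached = nc.start_build(tp.somatic_model)
        assert nc.last_stats["shortcut"] == 0
        assert primary_digests(cached) == primary_digests(uncached)

    def test_corrupted_cache_entry_self_heals(self, tiny_pipeline):
        tp = tiny_pipeline
        rec = next(r for r in tp.store.all_results()
                   if r["tool_name"] == "somatic-subtract")
        out_file = Path(rec["output_dir"]) / rec["output_paths"][0]
        original = out_file.read_bytes()
        out_file.write_bytes(b"corrupted\n")
        try:
            b = tp.engine.start_build(tp.somatic_model)
            assert b.status == "succeeded"
            assert tp.engine.last_stats["executed"] >= 1   # recomputed, not reused
        finally:
            out_file.write_bytes(original)

    def test_order_independence(self, tiny_pipeline):
        """Executing ready steps in random topological orders yields
        byte-identical outputs."""
        tp = tiny_pipeline
        nc = BuildEngine(tp.store, tp.root, use_cache=False)
        ref = primary_digests(nc.start_build(tp.somatic_model))
        for seed in (3, 4):
            b = nc.start_build(tp.somatic_model, order="random",
                               rng=np.random.default_rng(seed))
            assert primary_digests(b) == ref


class TestFailurePolicy:
    def test_failing_leaf_fails_build_but_siblings_complete(self, tmp_path):
        from conftest import run_somatic_pipeline
        root = tmp_path / "gms"
        tp = run_somatic_pipeline(root, seed=11, chrom_length=1500, n_germline=8,
                                  n_somatic=4, n_loh=2, tumor_depth=12,
                                  normal_depth=10)

        def boom(ctx):
            raise RuntimeError("injected tool failure")

        eng = BuildEngine(tp.store, root, use_cache=False)
        eng.registry.register(
            ToolImpl("naive-sv", "1.0", boom,
                     ("tumor_alignments", "normal_alignments"),
                     callset_format="bed"), layer=0)
        b = eng.start_build(tp.somatic_model)
        assert b.status == "failed"
        steps = {s.name: s for s in tp.store.all("step") if s.build_id == b.id}
        sv = steps["svs: naive-sv 1.0"]
        validate = steps["svs: sv-assembly-validate 1.0"]
        assert sv.status == "failed"
        assert validate.status == "new"          # dependent never started
        assert "injected tool failure" in Path(sv.log_path).read_text()
        # unrelated branches still ran to completion
        assert steps["snv somatic subtraction"].status == "succeeded"


class TestImmutability:
    def test_resolved_inputs_frozen_after_success(self, tiny_pipeline):
        tp = tiny_pipeline
        b = tp.store.get("build", tp.somatic_build)
        b.resolved_inputs["reference"] = ["R999"]
        with pytest.raises(ImmutableError):
            tp.store.update(b)

    def test_output_write_refused_via_api(self, tiny_pipeline):
        tp = tiny_pipeline
        with pytest.raises(ImmutableError):
            tp.engine.open_build_file(tp.somatic_build,
                                      "variants/snvs.somatic.vcf", "w")
        with tp.engine.open_build_file(tp.somatic_build, "manifest") as fh:
            assert fh.read()

    def test_manifest_verification_detects_tampering(self, tiny_pipeline):
        tp = tiny_pipeline
        tp.engine.verify_build(tp.somatic_build)
        target = Path(tp.store.get("build", tp.somatic_build).data_directory) \
            / "variants" / "loh.vcf"
        original = target.read_bytes()
        target.write_bytes(original + b"tampered\n")
        try:
            with pytest.raises(ImmutableError, match="modified"):
                tp.engine.verify_build(tp.somatic_build)
        finally:
            target.write_bytes(original)


class TestProvenance:
    def test_somatic_build_traces_to_raw_leaves_only(self, tiny_pipeline):
        tp = tiny_pipeline
        g = tp.engine.trace_provenance(tp.somatic_build)
        leaves = {n for n in g if g.out_degree(n) == 0}
        kinds = {k for k, _ in leaves}
        assert kinds == {"instrument_data", "reference_sequence", "annotation"}
        inst = {i for k, i in leaves if k == "instrument_data"}
        assert inst == {"I1", "I2", "I3", "I4", "I5"}

    def test_instrument_data_is_a_single_node_graph(self, tiny_pipeline):
        g = tiny_pipeline.engine.trace_provenance("I1")
        assert list(g.nodes) == [("instrument_data", "I1")]

    def test_shortcut_output_lineage_passes_through_original_result(self, tiny_pipeline):
        tp = tiny_pipeline
        b2 = tp.engine.start_build(tp.somatic_model)   # fully shortcut
        rows = tp.engine.read_manifest(b2.id)
        rid = dict((r[0], r[3]) for r in rows)["variants/snvs.somatic.vcf"]
        record = tp.store.get_result(rid)
        assert record["creating_build_id"] == tp.somatic_build
        g = tp.engine.trace_provenance(b2.id)
        assert ("result", rid) in g

    def test_every_manifest_file_is_reachable(self, tiny_pipeline):
        tp = tiny_pipeline
        g = tp.engine.trace_provenance(tp.somatic_build)
        for rel, digest, step, rid in tp.engine.read_manifest(tp.somatic_build):
            assert ("result", rid) in g


class TestSandboxOverride:
    def test_user_tool_shadows_shipped_and_changes_result_keys(self, tmp_path):
        from conftest import run_somatic_pipeline
        root = tmp_path / "gms"
        tp = run_somatic_pipeline(root, seed=23, chrom_length=1200, n_germline=6,
                                  n_somatic=3, n_loh=1, tumor_depth=12,
                                  normal_depth=10)
        ra_steps = lambda b: {s.name: s.status for s in tp.store.all("step")
                              if s.build_id == b}

        sandbox = root / "sandbox"
        sandbox.mkdir()
        (sandbox / "my_sv.py").write_text(
            "def my_sv(ctx):\n"
            "    ctx.log('sandbox sv: emitting nothing')\n"
            "    open(ctx.out('calls.bed'), 'w').close()\n"
            "register('naive-sv', '1.0', my_sv,\n"
            "         input_roles=('tumor_alignments', 'normal_alignments'),\n"
            "         callset_format='bed')\n")
        eng = BuildEngine(tp.store, root)   # picks up the sandbox
        assert eng.registry.resolve("naive-sv", "1.0").fingerprint != \
            tp.engine.registry.resolve("naive-sv", "1.0").fingerprint
        b = eng.start_build(tp.somatic_model)
        statuses = ra_steps(b.id)
        assert statuses["svs: naive-sv 1.0"] == "succeeded"   # ran, not shortcut
        assert statuses["snv somatic subtraction"] == "shortcut"

        # override removed: shipped tool dispatches again and its original
        # cached result is reused (no stale reuse of the sandbox result)
        (sandbox / "my_sv.py").unlink()
        eng2 = BuildEngine(tp.store, root)
        b2 = eng2.start_build(tp.somatic_model)
        assert ra_steps(b2.id)["svs: naive-sv 1.0"] == "shortcut"
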