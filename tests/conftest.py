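"""Shared fixtures: a full-scale synthetic tumor/normal bundle plus an
executed end-to-end pipeline (session-scoped so the expensive alignment
runs once), and a tiny bundle for fast engine-level tests."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest
from hypothesis import settings, HealthCheck

from genomodel.engine import BuildEngine
from genomodel.fixture import make_bundle, install_bundle
from genomodel.store import MetadataStore

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@dataclass
class PipelineRun:
    root: Path
    store: MetadataStore
    engine: BuildEngine
    truth: object
    tumor_model: str
    normal_model: str
    somatic_model: str
    tumor_build: str
    normal_build: str
    somatic_build: str


def run_somatic_pipeline(root: Path, seed: int = 1, **bundle_kw) -> PipelineRun:
    """Generate a bundle, import it, and run both reference-alignment
    builds plus the somatic-variation build."""
    truth = make_bundle(root / "fixture", seed=seed, **bundle_kw)
    store = MetadataStore(root / "db" / "metadata.db")
    install_bundle(store, root / "fixture")

    mt = store.define_model("reference-alignment", "S1", "P2", "TST1 tumor")
    store.add_model_input(mt.id, "instrument_data", "flow_cell_id='ABC123' and lane in [1,2]")
    store.add_model_input(mt.id, "reference", "R1")
    mn = store.define_model("reference-alignment", "S2", "P2", "TST1 normal")
    store.add_model_input(mn.id, "instrument_data", "flow_cell_id='DEF456'")
    store.add_model_input(mn.id, "reference", "R1")

    engine = BuildEngine(store, root)
    bt = engine.start_build(mt.id)
    bn = engine.start_build(mn.id)

    ms = store.define_model("somatic-variation", "IND1", "P3", "TST1 somatic")
    for role, val in [("tumor_model", mt.id), ("normal_model", mn.id),
                      ("reference", "R1"), ("annotation", "A1")]:
        store.add_model_input(ms.id, role, val)
    bs = engine.start_build(ms.id)
    assert bs.status == "succeeded", "somatic pipeline build failed"
    return PipelineRun(root, store, engine, truth, mt.id, mn.id, ms.id,
                       bt.id, bn.id, bs.id)


@pytest.fixture(scope="session")
def pipeline(tmp_path_factory) -> PipelineRun:
    """Full study-condition run: 2x15 kb reference, 100 germline + 50
    somatic SNVs, 10 LOH events, tumor 40x / normal 30x, 0.5% error."""
    root = tmp_path_factory.mktemp("gms_full")
    return run_somatic_pipeline(root, seed=1)


@pytest.fixture(scope="session")
def tiny_pipeline(tmp_path_factory) -> PipelineRun:
    """Down-scaled run for fast engine-level checks."""
    root = tmp_path_factory.mktemp("gms_tiny")
    return run_somatic_pipeline(
        root, seed=7, chrom_length=2000, n_germline=12, n_somatic=6, n_loh=3,
        tumor_depth=20, normal_depth=15,
        cnv_segments=[("chr1", 501, 1000, 2.0)])


@pytest.fixture()
def store(tmp_path) -> MetadataStore:
    return MetadataStore(tmp_path / "db" / "metadata.db")


def box2_store(store: MetadataStore) -> MetadataStore:
    """The minimal patient1 fixture used by the listing examples."""
    from genomodel import entities as E
    store.insert(E.Individual(id="IND1", common_name="patient1"))
    for sid, name in [("S1", "tumor"), ("S2", "normal"), ("S3", "relapse")]:
        store.insert(E.Sample(id=sid, common_name=name, individual_id="IND1"))
    for iid, fc, lane, idx in [("I1", "ABC123", 1, None), ("I2", "ABC123", 2, "AGCT"),
                               ("I3", "ABC123", 2, "TCAG")]:
        store.insert(E.InstrumentData(id=iid, sample_id="S1", flow_cell_id=fc,
                                      lane=lane, index_sequence=idx))
    return store


@pytest.fixture()
def patient1(store) -> MetadataStore:
    return box2_store(store)
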