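"""Single-file embedded metadata store.

All persistent entities live in one SQLite database as JSON payloads
keyed by (kind, id), together with the content-keyed result records
and the file-digest index the build engine uses for provenance.  A
plain-text JSON-lines snapshot (one file per entity kind) supports full
export/import, so any analysis can be reconstructed from metadata
alone.

Queries are expression-driven: :meth:`MetadataStore.list_entities`
applies a parsed :class:`~genomodel.filters.FilterExpression` row by
row over dotted paths resolved across entity references.
"""
from __future__ import annotations

import json
import os
import re
import sqlite3
from pathlib import Path

from . import entities as E
from .filters import FilterExpression, parse_filter


class StoreError(ValueError):
    pass


class ImmutableError(StoreError):
    pass


def _id_sort_key(entity_id: str):
    m = re.match(r"([A-Za-z]*)(\d+)$", entity_id)
    return (m.group(1), int(m.group(2))) if m else (entity_id, 0)


class MetadataStore:
    def __init__(self, path: str | Path | None = None):
        self.path = str(path) if path else ":memory:"
        if path:
            os.makedirs(os.path.dirname(os.path.abspath(self.path)) or ".", exist_ok=True)
        self._db = sqlite3.connect(self.path)
        self._db.executescript("""
            CREATE TABLE IF NOT EXISTS entities (
                kind TEXT NOT NULL, id TEXT NOT NULL, payload TEXT NOT NULL,
                PRIMARY KEY (kind, id));
            CREATE TABLE IF NOT EXISTS counters (prefix TEXT PRIMARY KEY, n INTEGER);
            CREATE TABLE IF NOT EXISTS results (result_id TEXT PRIMARY KEY, payload TEXT);
            CREATE TABLE IF NOT EXISTS file_index (
                digest TEXT PRIMARY KEY, node_type TEXT, node_id TEXT);
        """)
        self._db.commit()

    def close(self):
        self._db.close()

    # -- id allocation -------------------------------------------------
    def new_id(self, kind: str) -> str:
        prefix = E.ID_PREFIXES[kind]
        cur = self._db.execute("SELECT n FROM counters WHERE prefix=?", (prefix,))
        row = cur.fetchone()
        n = (row[0] if row else 0) + 1
        self._db.execute("INSERT OR REPLACE INTO counters (prefix, n) VALUES (?,?)", (prefix, n))
        self._db.commit()
        return f"{prefix}{n}"

    def _bump_counter_past(self, entity_id: str) -> None:
        m = re.match(r"([A-Za-z]+)(\d+)$", entity_id)
        if not m:
            return
        prefix, n = m.group(1), int(m.group(2))
        cur = self._db.execute("SELECT n FROM counters WHERE prefix=?", (prefix,))
        row = cur.fetchone()
        if row is None or row[0] < n:
            self._db.execute("INSERT OR REPLACE INTO counters (prefix, n) VALUES (?,?)",
                             (prefix, n))

    # -- CRUD ----------------------------------------------------------
    def exists(self, kind: str, entity_id: str) -> bool:
        cur = self._db.execute("SELECT 1 FROM entities WHERE kind=? AND id=?", (kind, entity_id))
        return cur.fetchone() is not None

    def get(self, kind: str, entity_id: str):
        cur = self._db.execute("SELECT payload FROM entities WHERE kind=? AND id=?",
                               (kind, entity_id))
        row = cur.fetchone()
        if row is None:
            raise StoreError(f"no {kind} with id {entity_id!r}")
        return E.from_payload(json.loads(row[0]))

    def find(self, entity_id: str):
        """Locate an entity of any kind by id."""
        cur = self._db.execute("SELECT payload FROM entities WHERE id=?", (entity_id,))
        row = cur.fetchone()
        if row is None:
            raise StoreError(f"no entity with id {entity_id!r}")
        return E.from_payload(json.loads(row[0]))

    def all(self, kind: str) -> list:
        cur = self._db.execute("SELECT id, payload FROM entities WHERE kind=?", (kind,))
        rows = sorted(cur.fetchall(), key=lambda r: _id_sort_key(r[0]))
        return [E.from_payload(json.loads(p)) for _, p in rows]

    def insert(self, entity) -> str:
        """Persist a new entity; allocates an id if empty.  Referential
        and uniqueness invariants are checked before anything is written."""
        if not entity.id:
            entity.id = self.new_id(entity.kind)
        if self.exists(entity.kind, entity.id):
            raise StoreError(f"duplicate {entity.kind} id {entity.id!r}")
        self._check_references(entity)
        self._check_unique(entity)
        self._db.execute("INSERT INTO entities (kind, id, payload) VALUES (?,?,?)",
                         (entity.kind, entity.id, json.dumps(E.to_payload(entity), sort_keys=True)))
        self._bump_counter_past(entity.id)
        self._db.commit()
        return entity.id

    def update(self, entity) -> None:
        old = self.get(entity.kind, entity.id)
        self._check_mutation_allowed(old, entity)
        self._check_references(entity)
        self._db.execute("UPDATE entities SET payload=? WHERE kind=? AND id=?",
                         (json.dumps(E.to_payload(entity), sort_keys=True),
                          entity.kind, entity.id))
        self._db.commit()

    def _check_references(self, entity) -> None:
        def need(kind, ref_id, label):
            if ref_id and not self.exists(kind, ref_id):
                raise StoreError(f"{entity.kind} {entity.id}: {label} {ref_id!r} does not resolve")
        k = entity.kind
        if k == "sample":
            need("individual", entity.individual_id, "individual_id")
        elif k == "instrument_data":
            need("sample", entity.sample_id, "sample_id")
        elif k == "model":
            need("processing_profile", entity.processing_profile_id, "processing_profile_id")
            if entity.subject_id and not (self.exists("individual", entity.subject_id)
                                          or self.exists("sample", entity.subject_id)):
                raise StoreError(f"model subject {entity.subject_id!r} does not resolve")
            for inp in entity.inputs:
                try:
                    self.find(inp.value_id)
                except StoreError:
                    raise StoreError(f"model input {inp.name}={inp.value_id!r} does not resolve")
        elif k in ("build", "step"):
            ref_kind = "model" if k == "build" else "build"
            need(ref_kind, getattr(entity, f"{ref_kind}_id"), f"{ref_kind}_id")

    def _check_unique(self, entity) -> None:
        if entity.kind == "instrument_data":
            for other in self.all("instrument_data"):
                if (other.flow_cell_id, other.lane, other.index_sequence) == \
                        (entity.flow_cell_id, entity.lane, entity.index_sequence):
                    raise StoreError(
                        f"instrument data with flow cell {entity.flow_cell_id!r} lane "
                        f"{entity.lane} index {entity.index_sequence!r} already exists ({other.id})")

    def _check_mutation_allowed(self, old, new) -> None:
        if old.kind == "build" and old.status == "succeeded":
            # status is frozen along with everything else once succeeded
            raise ImmutableError(f"build {old.id} has succeeded and is immutable")
        if old.kind == "processing_profile" and self.profile_in_use(old.id):
            raise ImmutableError(
                f"processing profile {old.id} is referenced by builds and is immutable")

    def profile_in_use(self, profile_id: str) -> bool:
        models = {m.id for m in self.all("model") if m.processing_profile_id == profile_id}
        return any(b.model_id in models for b in self.all("build"))

    # -- dotted-path resolution & listing ------------------------------
    def resolve_path(self, entity, path) -> object | None:
        """Follow reference hops then read a field; None when any hop or
        the final field is missing (never raises)."""
        cur = entity
        for i, hop in enumerate(path):
            refs = E.REFERENCES.get(cur.kind, {})
            if hop in refs and i < len(path) - 1:
                target_kind, id_field = refs[hop]
                ref_id = getattr(cur, id_field, None)
                if not ref_id or not self.exists(target_kind, ref_id):
                    return None
                cur = self.get(target_kind, ref_id)
            elif hop == "subject" and cur.kind == "model" and i < len(path) - 1:
                try:
                    cur = self.find(cur.subject_id)
                except StoreError:
                    return None
            elif i == len(path) - 1:
                return getattr(cur, hop, None)
            else:
                return None
        return cur.id if hasattr(cur, "id") else None

    def list_entities(self, kind: str, filt: FilterExpression | str = "") -> list:
        if kind not in E.ENTITY_CLASSES:
            raise StoreError(f"unknown entity kind {kind!r}")
        if isinstance(filt, str):
            filt = parse_filter(filt)
        return [e for e in self.all(kind)
                if filt.matches(lambda path, e=e: self.resolve_path(e, path))]

    # -- model operations ----------------------------------------------
    def define_model(self, pipeline_type: str, subject_id: str, profile_id: str,
                     name: str) -> E.Model:
        """Create a model binding subject + profile; profile type must
        match the requested pipeline."""
        profile = self.get("processing_profile", profile_id)
        canon = pipeline_type.replace("-", " ")
        if profile.type_name != canon:
            raise StoreError(
                f"profile {profile_id} has type {profile.type_name!r}, not {canon!r}")
        self.find(subject_id)   # must resolve to an individual or sample
        model = E.Model(name=name, subject_id=subject_id, processing_profile_id=profile_id)
        self.insert(model)
        return model

    def _subject_samples(self, subject_id: str) -> set[str]:
        subject = self.find(subject_id)
        if subject.kind == "sample":
            return {subject.id}
        if subject.kind == "individual":
            return {s.id for s in self.all("sample") if s.individual_id == subject.id}
        return set()

    def check_instrument_data_subject(self, model: E.Model, inst: E.InstrumentData) -> None:
        if inst.sample_id not in self._subject_samples(model.subject_id):
            raise StoreError(
                f"instrument data {inst.id} (sample {inst.sample_id}) is not from "
                f"model {model.id}'s subject {model.subject_id}")

    def add_model_input(self, model_id: str, role: str,
                        selector: str | FilterExpression) -> list[str]:
        """Attach entities selected by id or filter expression as inputs.

        Instrument data must belong to the model's subject.  Returns the
        ids newly attached (repeat calls are idempotent)."""
        from .pipelines import allowed_roles, role_kind   # local: avoid import cycle
        model = self.get("model", model_id)
        profile = self.get("processing_profile", model.processing_profile_id)
        allowed = allowed_roles(profile.type_name)
        if role not in allowed:
            raise StoreError(f"role {role!r} not permitted for {profile.type_name!r} "
                             f"(allowed: {sorted(allowed)})")
        kind = role_kind(role)
        if isinstance(selector, FilterExpression):
            selected = self.list_entities(kind, selector)
        else:
            text = str(selector)
            if self.exists(kind, text):
                selected = [self.get(kind, text)]
            else:
                selected = self.list_entities(kind, parse_filter(text))
        if not selected:
            raise StoreError(f"selector matched no {kind} entities")
        if role == "instrument_data":
            for inst in selected:
                self.check_instrument_data_subject(model, inst)
        have = set(model.input_ids(role))
        attached = []
        for ent in selected:
            if ent.id not in have:
                model.inputs.append(E.InputSpec(name=role, value_id=ent.id))
                attached.append(ent.id)
        if attached:
            self.update(model)
        return attached

    # -- result records / file index ------------------------------------
    def put_result(self, record: dict) -> None:
        self._db.execute("INSERT OR IGNORE INTO results (result_id, payload) VALUES (?,?)",
                         (record["result_id"], json.dumps(record, sort_keys=True)))
        self._db.commit()

    def get_result(self, result_id: str) -> dict | None:
        cur = self._db.execute("SELECT payload FROM results WHERE result_id=?", (result_id,))
        row = cur.fetchone()
        return json.loads(row[0]) if row else None

    def all_results(self) -> list[dict]:
        cur = self._db.execute("SELECT payload FROM results ORDER BY result_id")
        return [json.loads(r[0]) for r in cur.fetchall()]

    def index_file(self, digest: str, node_type: str, node_id: str) -> None:
        self._db.execute(
            "INSERT OR IGNORE INTO file_index (digest, node_type, node_id) VALUES (?,?,?)",
            (digest, node_type, node_id))
        self._db.commit()

    def lookup_file(self, digest: str) -> tuple[str, str] | None:
        cur = self._db.execute("SELECT node_type, node_id FROM file_index WHERE digest=?",
                               (digest,))
        row = cur.fetchone()
        return (row[0], row[1]) if row else None

    # -- snapshot export/import -----------------------------------------
    def export_snapshot(self, directory: str | Path) -> None:
        """One JSON-lines file per entity kind, plus results and counters."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for kind in sorted(E.ENTITY_CLASSES):
            rows = [json.dumps(E.to_payload(e), sort_keys=True) for e in self.all(kind)]
            (directory / f"{kind}.jsonl").write_text(
                "".join(r + "\n" for r in rows), encoding="ascii")
        results = [json.dumps(r, sort_keys=True) for r in self.all_results()]
        (directory / "results.jsonl").write_text(
            "".join(r + "\n" for r in results), encoding="ascii")

    def import_snapshot(self, directory: str | Path) -> int:
        """Load a snapshot (or a fixture bundle's metadata.jsonl)."""
        directory = Path(directory)
        n = 0
        combined = directory / "metadata.jsonl"
        files = [combined] if combined.exists() else sorted(directory.glob("*.jsonl"))
        # insertion order must respect references
        order = {k: i for i, k in enumerate(
            ("individual", "sample", "instrument_data", "processing_profile",
             "reference_sequence", "annotation", "model", "build", "step"))}
        payloads = []
        for f in files:
            if f.name == "results.jsonl":
                for line in f.read_text().splitlines():
                    if line.strip():
                        self.put_result(json.loads(line))
                continue
            for line in f.read_text().splitlines():
                if line.strip():
                    payloads.append(json.loads(line))
        payloads.sort(key=lambda p: order.get(p.get("kind"), 99))
        for p in payloads:
            entity = E.from_payload(p)
            if not self.exists(entity.kind, entity.id):
                self.insert(entity)
                n += 1
        return n
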