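"""The entity-selection expression language: grammar, semantics and the
brute-force query oracle."""
import pytest
from hypothesis import given, strategies as st

from genomodel import entities as E
from genomodel.filters import (And, Comparison, FilterSyntaxError, MatchAll, Or,
                               parse_filter)
from genomodel.store import MetadataStore, StoreError


class TestParsing:
    def test_simple_comparison_over_reference_path(self):
        f = parse_filter("individual.common_name = patient1")
        assert f.ast == Comparison(("individual", "common_name"), "=", "patient1")

    def test_empty_expression_matches_everything(self):
        f = parse_filter("")
        assert f.ast == MatchAll()
        assert f.matches(lambda path: None)

    def test_quoted_literal_and_bracketed_list(self):
        f = parse_filter("flow_cell_id='ABC123' and lane in [1,2]")
        assert f.ast == And((Comparison(("flow_cell_id",), "=", "ABC123"),
                             Comparison(("lane",), "in", (1, 2))))

    def test_and_binds_tighter_than_or(self):
        f = parse_filter("a = 1 or b = 2 and c = 3")
        assert isinstance(f.ast, Or)
        assert isinstance(f.ast.items[1], And)

    @pytest.mark.parametrize("bad", [
        "lane in [1,2", "name = 'oops", "a ~ b", "a =", "= 3", "a = 1 b = 2",
    ])
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(FilterSyntaxError) as err:
            parse_filter(bad)
        assert err.value.position >= 0

    def test_like_uses_percent_wildcards(self):
        f = parse_filter("common_name like 'pat%1'")
        assert f.matches(lambda p: "patient1")
        assert not f.matches(lambda p: "patient2")

    def test_numeric_comparison_when_both_sides_numeric(self):
        assert parse_filter("lane > 1").matches(lambda p: 2)
        assert not parse_filter("lane > 1").matches(lambda p: "1")
        # lexicographic fallback when either side is non-numeric
        assert parse_filter("name > abc").matches(lambda p: "abd")

    def test_missing_path_never_matches_even_negated(self):
        assert not parse_filter("ghost = 1").matches(lambda p: None)
        assert not parse_filter("ghost != 1").matches(lambda p: None)


_words = st.text(alphabet="abcdefXYZ_", min_size=1, max_size=6)
_literals = st.one_of(_words, st.integers(-100, 100),
                      st.floats(-10, 10, allow_nan=False).map(lambda f: round(f, 3)))
_comparisons = st.builds(
    Comparison,
    st.lists(_words, min_size=1, max_size=3).map(tuple),
    st.sampled_from(["=", "!=", "<", ">", "like"]),
    _literals,
) | st.builds(Comparison, st.lists(_words, min_size=1, max_size=2).map(tuple),
              st.just("in"), st.lists(_literals, min_size=1, max_size=3).map(tuple))
_asts = st.recursive(
    _comparisons,
    lambda children: st.builds(And, st.lists(children, min_size=2, max_size=3).map(tuple))
    | st.builds(Or, st.lists(children, min_size=2, max_size=3).map(tuple)),
    max_leaves=6)


@given(_asts)
def test_filter_round_trip(ast):
    """parse -> unparse -> parse is the identity on parsed expressions
    (and/or chains are flat in parsed form, so random trees are first
    pushed through the parser once)."""
    from genomodel.filters import FilterExpression
    parsed = parse_filter(FilterExpression(ast).unparse())
    assert parse_filter(parsed.unparse()).ast == parsed.ast


# ---------------------------------------------------------------------------
# query oracle: list_entities == brute-force row-by-row evaluation
# ---------------------------------------------------------------------------

def build_random_store(rng, tmp_path=None) -> tuple[MetadataStore, dict]:
    """A random store of <=200 entities plus flat row dicts resolving every
    dotted path independently of store.resolve_path."""
    store = MetadataStore()
    rows = {"individual": [], "sample": [], "instrument_data": []}
    individuals = {}
    for i in range(int(rng.integers(1, 6))):
        ind = E.Individual(common_name=f"patient{int(rng.integers(1, 4))}",
                           species=str(rng.choice(["human", "mouse"])))
        store.insert(ind)
        individuals[ind.id] = ind
        rows["individual"].append({"id": ind.id, "common_name": ind.common_name,
                                   "species": ind.species})
    samples = {}
    for i in range(int(rng.integers(1, 30))):
        ind = individuals[str(rng.choice(sorted(individuals)))]
        s = E.Sample(common_name=str(rng.choice(["tumor", "normal", "relapse"])),
                     individual_id=ind.id,
                     extraction_type=str(rng.choice(["dna", "rna"])))
        store.insert(s)
        samples[s.id] = (s, ind)
        rows["sample"].append({"id": s.id, "common_name": s.common_name,
                               "extraction_type": s.extraction_type,
                               "individual.id": ind.id,
                               "individual.common_name": ind.common_name,
                               "individual.species": ind.species})
    used = set()
    for i in range(int(rng.integers(0, 60))):
        s, ind = samples[str(rng.choice(sorted(samples)))]
        key = (f"FC{int(rng.integers(1, 5))}", int(rng.integers(1, 9)),
               str(rng.choice(["AGCT", "TCAG", ""])) or None)
        if key in used:
            continue
        used.add(key)
        inst = E.InstrumentData(sample_id=s.id, flow_cell_id=key[0], lane=key[1],
                                index_sequence=key[2])
        store.insert(inst)
        rows["instrument_data"].append({
            "id": inst.id, "flow_cell_id": inst.flow_cell_id, "lane": inst.lane,
            "index_sequence": inst.index_sequence, "sample.id": s.id,
            "sample.common_name": s.common_name,
            "sample.individual.common_name": ind.common_name})
    return store, rows


def random_filter_text(rng) -> str:
    paths = {
        "individual": ["id", "common_name", "species"],
        "sample": ["id", "common_name", "individual.common_name", "extraction_type"],
        "instrument_data": ["id", "flow_cell_id", "lane", "index_sequence",
                            "sample.id", "sample.individual.common_name"],
    }
    kind = str(rng.choice(sorted(paths)))
    clauses = []
    for _ in range(int(rng.integers(1, 4))):
        path = str(rng.choice(paths[kind]))
        op = str(rng.choice(["=", "!=", "<", ">", "like", "in"]))
        vals = ["patient1", "patient2", "tumor", "normal", "FC1", "FC2",
                "AGCT", "dna", "S1", "I2", "1", "3", "pat%", "%1"]
        if op == "in":
            picks = rng.choice(vals, size=int(rng.integers(1, 3)))
            lit = "[" + ",".join(f"'{v}'" for v in picks) + "]"
        else:
            lit = f"'{rng.choice(vals)}'"
        clauses.append(f"{path} {op} {lit}")
    joiners = [str(rng.choice(["and", "or"])) for _ in clauses[1:]]
    text = clauses[0]
    for j, c in zip(joiners, clauses[1:]):
        text += f" {j} {c}"
    return kind, text


def brute_force_rows(rows, ast):
    """Independent predicate evaluation over flat row dicts."""
    import re as _re

    def cmp(op, actual, literal):
        if actual is None:
            return False
        if op == "in":
            return any(cmp("=", actual, x) for x in literal)
        if op == "like":
            return _re.fullmatch(_re.escape(str(literal)).replace("%", ".*"),
                                 str(actual)) is not None
        def num(v):
            try:
                return float(v)
            except (TypeError, ValueError):
                return None
        a, b = num(actual), num(literal)
        if a is None or b is None:
            a, b = str(actual), str(literal)
        return {"=": a == b, "!=": a != b, "<": a < b, ">": a > b}[op]

    def ev(node, row):
        if isinstance(node, MatchAll):
            return True
        if isinstance(node, And):
            return all(ev(i, row) for i in node.items)
        if isinstance(node, Or):
            return any(ev(i, row) for i in node.items)
        return cmp(node.op, row.get(".".join(node.path)), node.value)

    return [r["id"] for r in rows if ev(ast, r)]


def test_query_oracle_random_stores():
    """list_entities agrees with a brute-force scan over independently
    flattened rows, for 30 random stores x random expressions."""
    import numpy as np
    rng = np.random.default_rng(20240)
    for _ in range(30):
        store, rows = build_random_store(rng)
        for _ in range(5):
            kind, text = random_filter_text(rng)
            f = parse_filter(text)
            got = [e.id for e in store.list_entities(kind, f)]
            expected = brute_force_rows(rows[kind], f.ast)
            assert got == expected, f"{kind}: {text}"
        store.close()


def test_list_entities_unknown_kind_raises(store):
    with pytest.raises(StoreError):
        store.list_entities("nonsense", parse_filter(""))


def test_match_all_on_empty_store(store):
    assert store.list_entities("sample", parse_filter("")) == []
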