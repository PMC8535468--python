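"""Knowledge-backend contract: lookups, approximate matching, schema checks."""

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinconcept.backend import (BackendError, FixtureBackend, RemoteBackend,
                                 load_fixture_kb, trigram_jaccard)
from clinconcept.fixtures import build_paper_fixture_kb
from clinconcept.types import Concept, EntityType, SemanticType, UNKNOWN_ENTITY_TYPE


def _trigram_oracle(a, b):
    """Independent trigram-Jaccard computed with raw set arithmetic."""
    def grams(s):
        s = f"  {s.lower().strip()}  "
        return {s[i:i + 3] for i in range(len(s) - 2)}
    ga, gb = grams(a), grams(b)
    return len(ga & gb) / len(ga | gb)


class TestConceptLookup:
    def test_coronary_artery_disease_concept_record(self, backend):
        concepts = backend.search_concepts("coronary artery disease")
        assert concepts[0] == Concept(cui="C0010054",
                                      name="Coronary Arteriosclerosis",
                                      root_source="MTH")

    def test_unknown_term_is_empty_not_error(self, backend):
        assert backend.search_concepts("zzzz-nonterm") == []

    def test_stress_has_four_concepts(self, backend):
        assert len(backend.search_concepts("stress")) == 4

    def test_limit_is_a_prefix(self, backend):
        for term in ("stress", "heart rate", "increased heart rate"):
            for k in range(1, 9):
                assert (backend.search_concepts(term, k)
                        == backend.search_concepts(term, k + 1)[:k])

    def test_lookup_is_case_insensitive(self, backend):
        assert backend.search_concepts("Stress") == backend.search_concepts("stress")

    def test_invalid_arguments(self, backend):
        with pytest.raises(ValueError):
            backend.search_concepts("")
        with pytest.raises(ValueError):
            backend.search_concepts("stress", limit=0)


class TestSemanticAndEntityTypes:
    def test_trout_semantic_type_record(self, backend):
        assert backend.search_concepts("trout")[0].name == "Salmo trutta"
        assert backend.search_semantic_types("C0041200") == [
            SemanticType(tui="T013", name="Fish")]

    def test_fish_entity_type_record(self, backend):
        assert backend.search_entity_type("T013") == EntityType(
            abbreviation="LIVB", expanded_form="Living Beings")

    def test_bismuth_concept_carries_two_types(self, backend):
        stys = backend.search_semantic_types("C0117361")
        assert [st.name.lower() for st in stys] == [
            "organic chemical", "pharmacological substance"]

    def test_unknown_cui_empty_and_unknown_tui_sentinel(self, backend):
        assert backend.search_semantic_types("C9999999") == []
        assert backend.search_entity_type("T999") is UNKNOWN_ENTITY_TYPE

    def test_every_fixture_tui_resolves(self, backend):
        kb = build_paper_fixture_kb()
        tuis = {st["tui"] for entry in kb["terms"] for c in entry["concepts"]
                for st in c["semantic_types"]}
        for tui in tuis:
            assert backend.search_entity_type(tui) is not UNKNOWN_ENTITY_TYPE

    def test_concepts_carry_one_to_five_types(self, backend):
        for term in backend.iter_terms():
            for concept in backend.search_concepts(term):
                assert 1 <= len(backend.search_semantic_types(concept.cui)) <= 5


class TestApproximateMatching:
    def test_exact_string_scores_one_and_ranks_first(self, backend):
        hits = backend.approximate_candidates("aspirin", 0.7)
        assert hits[0] == ("aspirin", 1.0)

    def test_threshold_one_keeps_only_exact_equals(self, backend):
        assert backend.approximate_candidates("aspirin", 1.0) == [("aspirin", 1.0)]
        assert backend.approximate_candidates("aspirinn", 1.0) == []

    def test_typo_recovered_with_hand_oracle_score(self, backend):
        hits = dict(backend.approximate_candidates("coronry artery disease", 0.7))
        assert "coronary artery disease" in hits
        assert hits["coronary artery disease"] == pytest.approx(
            _trigram_oracle("coronry artery disease", "coronary artery disease"))

    def test_threshold_out_of_range(self, backend):
        for bad in (0.5, 1.01, -0.1):
            with pytest.raises(ValueError):
                backend.approximate_candidates("aspirin", bad)

    @settings(max_examples=40, derandomize=True)
    @given(st.floats(min_value=0.6, max_value=0.99),
           st.floats(min_value=0.0, max_value=0.4))
    def test_monotone_in_threshold(self, backend, lo, delta):
        hi = min(1.0, lo + delta)
        lo_hits = {e for e, _ in backend.approximate_candidates("beta blocker", lo)}
        hi_hits = {e for e, _ in backend.approximate_candidates("beta blocker", hi)}
        assert hi_hits <= lo_hits

    def test_similarity_symmetric_and_bounded(self):
        pairs = [("stress", "stresses"), ("heart rate", "heart rte"), ("a", "b")]
        for a, b in pairs:
            assert trigram_jaccard(a, b) == trigram_jaccard(b, a)
            assert 0.0 <= trigram_jaccard(a, b) <= 1.0
        assert trigram_jaccard("aspirin", "aspirin") == 1.0


class TestHybridMatch:
    def test_exact_hit_regardless_of_threshold(self, backend):
        for thr in (0.6, 1.0):
            m = backend.hybrid_match(["heart rate"], thr)["heart rate"]
            assert m.mode == "exact" and m.score == 1.0

    def test_misspelling_goes_to_nearest_entry(self, backend):
        m = backend.hybrid_match(["coronry artery disease"], 0.7)
        assert m["coronry artery disease"].matched_term == "coronary artery disease"
        assert m["coronry artery disease"].mode == "approximate"

    def test_gibberish_absent(self, backend):
        assert backend.hybrid_match(["qqqq xxxx"], 0.7) == {}

    def test_union_of_exact_and_approximate(self, backend):
        result = backend.hybrid_match(
            ["aspirin", "atrial fibrilation", "qqqq xxxx"], 0.7)
        assert result["aspirin"].mode == "exact"
        assert result["atrial fibrilation"].mode == "approximate"
        assert result["atrial fibrilation"].matched_term == "atrial fibrillation"
        assert "qqqq xxxx" not in result


class TestFixtureLoading:
    def test_round_trip_through_file(self, tmp_path, backend):
        path = tmp_path / "kb.json"
        build_paper_fixture_kb(str(path))
        loaded = load_fixture_kb(str(path))
        for term in backend.iter_terms():
            assert loaded.search_concepts(term) == backend.search_concepts(term)

    def test_empty_kb_answers_empty(self):
        be = FixtureBackend({"terms": [], "entity_types": []})
        assert be.search_concepts("anything") == []
        assert be.search_semantic_types("C1") == []
        assert be.search_entity_type("T1") is UNKNOWN_ENTITY_TYPE

    def test_duplicate_cui_is_schema_error(self, tmp_path):
        kb = {"terms": [{"term": "x", "concepts": [
            {"cui": "C1", "name": "a", "semantic_types": [{"tui": "T1", "name": "t"}]},
            {"cui": "C1", "name": "b", "semantic_types": [{"tui": "T1", "name": "t"}]},
        ]}], "entity_types": []}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(kb))
        with pytest.raises(ValueError, match="C1"):
            load_fixture_kb(str(path))

    def test_concept_without_types_is_schema_error(self):
        kb = {"terms": [{"term": "x", "concepts": [
            {"cui": "C1", "name": "a", "semantic_types": []}]}]}
        with pytest.raises(ValueError, match="semantic types"):
            FixtureBackend(kb)

    def test_determinism_of_serialized_answers(self, backend):
        def snapshot():
            return json.dumps({
                term: [c.cui for c in backend.search_concepts(term)]
                for term in sorted(backend.iter_terms())})
        assert snapshot() == snapshot()

    def test_cache_transparency(self):
        cold = FixtureBackend(build_paper_fixture_kb())
        warm = FixtureBackend(build_paper_fixture_kb())
        warm.search_concepts("stress")  # prime the cache
        assert warm.search_concepts("stress") == cold.search_concepts("stress")


class _UTSHandler(BaseHTTPRequestHandler):
    """Minimal UTS-shaped JSON server over the paper fixture KB."""

    kb = build_paper_fixture_kb()

    def log_message(self, *args):  # quiet
        pass

    def _send(self, payload):
        body = json.dumps(payload).encode()
        self.send_response(200)
        self.send_header("Content-Type", "application/json")
        self.end_headers()
        self.wfile.write(body)

    def do_GET(self):
        from urllib.parse import parse_qs, unquote, urlparse
        parsed = urlparse(self.path)
        parts = [unquote(p) for p in parsed.path.strip("/").split("/")]
        if parts[0] == "search":
            term = parse_qs(parsed.query)["string"][0].lower()
            entry = next((e for e in self.kb["terms"] if e["term"] == term), None)
            results = [] if entry is None else [
                {"ui": c["cui"], "name": c["name"], "rootSource": c["root_source"]}
                for c in entry["concepts"]]
            self._send({"result": {"results": results}})
        elif parts[0] == "content":
            cui = parts[3]
            stys = []
            for e in self.kb["terms"]:
                for c in e["concepts"]:
                    if c["cui"] == cui:
                        stys = [{"name": st["name"],
                                 "uri": f"https://x/TUI/{st['tui']}"}
                                for st in c["semantic_types"]]
            self._send({"result": {"semanticTypes": stys}})
        else:  # semantic-network TUI
            tui = parts[3]
            group = next((e for e in self.kb["entity_types"] if e["tui"] == tui), None)
            payload = {} if group is None else {
                "semanticTypeGroup": {"abbreviation": group["abbreviation"],
                                      "expandedForm": group["expanded_form"]}}
            self._send({"result": payload})


@pytest.fixture(scope="module")
def uts_server():
    server = ThreadingHTTPServer(("127.0.0.1", 0), _UTSHandler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    yield f"http://127.0.0.1:{server.server_address[1]}"
    server.shutdown()


class TestRemoteBackend:
    def test_contract_matches_fixture_backend(self, uts_server, backend):
        remote = RemoteBackend(base_url=uts_server)
        for term in ("coronary artery disease", "trout", "stress"):
            assert remote.search_concepts(term) == backend.search_concepts(term)
        assert remote.search_semantic_types("C0041200") == \
            backend.search_semantic_types("C0041200")
        assert remote.search_entity_type("T013") == backend.search_entity_type("T013")

    def test_unreachable_service_raises_backend_error(self):
        remote = RemoteBackend(base_url="http://127.0.0.1:9", timeout=0.2)
        with pytest.raises(BackendError):
            remote.search_concepts("stress")
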