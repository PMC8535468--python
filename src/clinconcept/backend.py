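"""Metathesaurus-style knowledge backends.

A :class:`KnowledgeBackend` answers three lookups — term -> concepts,
CUI -> semantic types, TUI -> entity type (semantic group) — plus approximate
term retrieval. Two implementations share the contract:

* :class:`FixtureBackend`: an in-memory knowledge base loaded from a JSON
  file (the default; fully offline and deterministic).
* :class:`RemoteBackend`: a thin client for a UTS-style terminology REST
  service, for users with access to a full Metathesaurus deployment.

Approximate matching uses Jaccard similarity over character trigrams of the
lowercased strings — deterministic, symmetric and order-free, the standard
choice for dictionary matching. Thresholds are confined to [0.6, 1.0], the
range in which approximate concept retrieval is commonly operated.

Hybrid matching tries an exact lookup for every phrase first, then runs
approximate retrieval over the remainder, and returns the union.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.parse
import urllib.request
from abc import ABC, abstractmethod
from typing import Iterable, Optional

from .types import Concept, EntityType, SemanticType, TermMatch, UNKNOWN_ENTITY_TYPE

MAX_SEMANTIC_TYPES_PER_CONCEPT = 5
DEFAULT_CONCEPT_LIMIT = 8
DEFAULT_APPROX_THRESHOLD = 0.7
MIN_THRESHOLD, MAX_THRESHOLD = 0.6, 1.0


class BackendError(RuntimeError):
    """Retryable I/O failure talking to a remote backend (not 'no match')."""


class KnowledgeBaseSchemaError(ValueError):
    """The fixture knowledge-base file violates its schema."""


def character_trigrams(text: str) -> frozenset[str]:
    """Character trigrams of the lowercased string (padded with spaces)."""
    padded = f"  {text.lower().strip()}  "
    return frozenset(padded[i:i + 3] for i in range(len(padded) - 2))


def trigram_jaccard(a: str, b: str) -> float:
    """Jaccard similarity of the two strings' character-trigram sets."""
    ta, tb = character_trigrams(a), character_trigrams(b)
    if not ta and not tb:
        return 1.0
    union = ta | tb
    if not union:
        return 0.0
    return len(ta & tb) / len(union)


def _check_threshold(threshold: float) -> None:
    if not MIN_THRESHOLD <= threshold <= MAX_THRESHOLD:
        raise ValueError(
            f"approximate-match threshold must lie in "
            f"[{MIN_THRESHOLD}, {MAX_THRESHOLD}], got {threshold}")


class KnowledgeBackend(ABC):
    """Uniform contract for Metathesaurus-style lookups.

    Results are deterministic for a fixed knowledge-base snapshot and ordered
    by the backend's native preference order. A per-instance cache keyed by
    (operation, query) makes repeated lookups free; cached and uncached
    answers are identical.
    """

    def __init__(self) -> None:
        self._cache: dict[tuple[str, str], object] = {}

    def _cached(self, op: str, key: str, compute):
        cache_key = (op, key)
        if cache_key not in self._cache:
            self._cache[cache_key] = compute()
        return self._cache[cache_key]

    # -- contract ----------------------------------------------------------
    def search_concepts(self, term: str, limit: int = DEFAULT_CONCEPT_LIMIT) -> list[Concept]:
        """At most ``limit`` concepts for the term, in KB preference order."""
        if not term:
            raise ValueError("term must be nonempty")
        if limit < 1:
            raise ValueError(f"limit must be >= 1, got {limit}")
        concepts = self._cached("concepts", term.lower(),
                                lambda: self._search_concepts_impl(term.lower()))
        return list(concepts)[:limit]

    def search_semantic_types(self, cui: str) -> list[SemanticType]:
        """Semantic types of a concept (1..5); [] for an unknown CUI."""
        return list(self._cached("semtypes", cui,
                                 lambda: self._search_semantic_types_impl(cui)))

    def search_entity_type(self, tui: str) -> EntityType:
        """The semantic group of a TUI; a sentinel record when unseen."""
        return self._cached("entity", tui, lambda: self._search_entity_type_impl(tui))

    def approximate_candidates(self, term: str,
                               threshold: float = DEFAULT_APPROX_THRESHOLD,
                               ) -> list[tuple[str, float]]:
        """KB entry strings with trigram-Jaccard similarity >= threshold.

        Sorted by score descending, ties broken lexicographically.
        """
        _check_threshold(threshold)
        if not term:
            raise ValueError("term must be nonempty")
        scored = self._cached("approx", term.lower(),
                              lambda: self._score_all_terms(term.lower()))
        return [(entry, score) for entry, score in scored if score >= threshold]

    def _score_all_terms(self, term: str) -> list[tuple[str, float]]:
        scored = [(entry, trigram_jaccard(term, entry)) for entry in self.iter_terms()]
        scored.sort(key=lambda pair: (-pair[1], pair[0]))
        return scored

    @abstractmethod
    def iter_terms(self) -> Iterable[str]:
        """All entry strings of the knowledge base (lowercased)."""

    @abstractmethod
    def _search_concepts_impl(self, term: str) -> list[Concept]: ...

    @abstractmethod
    def _search_semantic_types_impl(self, cui: str) -> list[SemanticType]: ...

    @abstractmethod
    def _search_entity_type_impl(self, tui: str) -> EntityType: ...

    # -- derived operations ------------------------------------------------
    def exact_match(self, term: str) -> Optional[TermMatch]:
        normalized = term.lower()
        if self.search_concepts_exists(normalized):
            return TermMatch(query=normalized, matched_term=normalized,
                             mode="exact", score=1.0)
        return None

    def search_concepts_exists(self, term: str) -> bool:
        return bool(self._cached("concepts", term.lower(),
                                 lambda: self._search_concepts_impl(term.lower())))

    def hybrid_match(self, terms: Iterable[str],
                     threshold: float = DEFAULT_APPROX_THRESHOLD,
                     ) -> dict[str, TermMatch]:
        """Exact matches first; approximate retrieval for the rest; union.

        Phrases with neither kind of hit are absent from the returned map.
        """
        _check_threshold(threshold)
        result: dict[str, TermMatch] = {}
        unmatched: list[str] = []
        for phrase in terms:
            if not phrase:
                continue
            exact = self.exact_match(phrase)
            if exact is not None:
                result[phrase] = exact
            else:
                unmatched.append(phrase)
        for phrase in unmatched:
            candidates = [(entry, score)
                          for entry, score in self.approximate_candidates(phrase, threshold)
                          if score < 1.0]
            if candidates:
                entry, score = candidates[0]
                result[phrase] = TermMatch(query=phrase.lower(), matched_term=entry,
                                           mode="approximate", score=score)
        return result


class FixtureBackend(KnowledgeBackend):
    """In-memory knowledge base backed by a JSON fixture file.

    Schema::

        {"terms": [{"term": str,
                    "concepts": [{"cui": str, "name": str, "root_source": str,
                                  "semantic_types": [{"tui": str, "name": str}]}]}],
         "entity_types": [{"tui": str, "abbreviation": str, "expanded_form": str}]}

    Concept order within a term is the KB preference order.
    """

    def __init__(self, data: dict) -> None:
        super().__init__()
        self._terms: dict[str, list[Concept]] = {}
        self._semantic_types: dict[str, list[SemanticType]] = {}
        self._entity_types: dict[str, EntityType] = {}
        self._load(data)

    @classmethod
    def from_file(cls, path: str) -> "FixtureBackend":
        with open(path, encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise KnowledgeBaseSchemaError(f"{path}: not valid JSON: {exc}") from exc
        return cls(data)

    def _load(self, data: dict) -> None:
        if not isinstance(data, dict):
            raise KnowledgeBaseSchemaError("knowledge base must be a JSON object")
        for entry in data.get("terms", []):
            term = entry.get("term", "").strip().lower()
            if not term:
                raise KnowledgeBaseSchemaError(f"term entry without a term: {entry!r}")
            if term in self._terms:
                raise KnowledgeBaseSchemaError(f"duplicate term entry: {term!r}")
            concepts: list[Concept] = []
            seen_cuis: set[str] = set()
            for raw in entry.get("concepts", []):
                cui = raw.get("cui", "")
                if not cui:
                    raise KnowledgeBaseSchemaError(
                        f"term {term!r}: concept without a cui: {raw!r}")
                if cui in seen_cuis:
                    raise KnowledgeBaseSchemaError(
                        f"term {term!r}: duplicate cui {cui!r}")
                seen_cuis.add(cui)
                stys = [SemanticType(tui=st["tui"], name=st["name"])
                        for st in raw.get("semantic_types", [])]
                if not 1 <= len(stys) <= MAX_SEMANTIC_TYPES_PER_CONCEPT:
                    raise KnowledgeBaseSchemaError(
                        f"concept {cui!r} must carry 1..{MAX_SEMANTIC_TYPES_PER_CONCEPT}"
                        f" semantic types, has {len(stys)}")
                concepts.append(Concept(cui=cui, name=raw.get("name", cui),
                                        root_source=raw.get("root_source", "MTH")))
                existing = self._semantic_types.get(cui)
                if existing is not None and existing != stys:
                    raise KnowledgeBaseSchemaError(
                        f"cui {cui!r} listed with conflicting semantic types")
                self._semantic_types[cui] = stys
            if not concepts:
                raise KnowledgeBaseSchemaError(f"term {term!r} has no concepts")
            self._terms[term] = concepts
        for raw in data.get("entity_types", []):
            tui = raw.get("tui", "")
            if not tui:
                raise KnowledgeBaseSchemaError(f"entity type without a tui: {raw!r}")
            if tui in self._entity_types:
                raise KnowledgeBaseSchemaError(f"duplicate entity type for {tui!r}")
            self._entity_types[tui] = EntityType(
                abbreviation=raw.get("abbreviation", "UNKN"),
                expanded_form=raw.get("expanded_form", "Unknown"))

    def iter_terms(self) -> Iterable[str]:
        return self._terms.keys()

    def _search_concepts_impl(self, term: str) -> list[Concept]:
        return self._terms.get(term, [])

    def _search_semantic_types_impl(self, cui: str) -> list[SemanticType]:
        return self._semantic_types.get(cui, [])

    def _search_entity_type_impl(self, tui: str) -> EntityType:
        return self._entity_types.get(tui, UNKNOWN_ENTITY_TYPE)


def load_fixture_kb(path: str) -> FixtureBackend:
    """Load a JSON fixture knowledge base into an in-memory backend."""
    return FixtureBackend.from_file(path)


class RemoteBackend(KnowledgeBackend):
    """Client for a UTS-style terminology REST service.

    Expects endpoints shaped like the UMLS Terminology Services API:
    ``/search/{release}?string=...``, ``/content/{release}/CUI/{cui}`` and
    ``/semantic-network/{release}/TUI/{tui}``, answering JSON. Authentication
    is via an API key query parameter. Network failures raise
    :class:`BackendError` so callers can distinguish outage from 'no match'.

    Approximate retrieval requires enumerating entry strings, which a remote
    service does not expose; ``iter_terms`` therefore raises, and hybrid
    matching degrades to exact-only against this backend.
    """

    def __init__(self, base_url: str, api_key: str = "", release: str = "current",
                 timeout: float = 10.0) -> None:
        super().__init__()
        self.base_url = base_url.rstrip("/")
        self.api_key = api_key
        self.release = release
        self.timeout = timeout

    def _get(self, path: str, params: dict[str, str]) -> dict:
        if self.api_key:
            params = {**params, "apiKey": self.api_key}
        url = f"{self.base_url}{path}"
        if params:
            url += "?" + urllib.parse.urlencode(params)
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, json.JSONDecodeError) as exc:
            raise BackendError(f"terminology service request failed: {url}: {exc}") from exc

    def iter_terms(self) -> Iterable[str]:
        raise NotImplementedError(
            "a remote terminology service does not enumerate its entries; "
            "approximate matching requires the fixture backend")

    def approximate_candidates(self, term: str,
                               threshold: float = DEFAULT_APPROX_THRESHOLD,
                               ) -> list[tuple[str, float]]:
        _check_threshold(threshold)
        return []

    def _search_concepts_impl(self, term: str) -> list[Concept]:
        data = self._get(f"/search/{self.release}", {"string": term})
        results = data.get("result", {}).get("results", [])
        out = []
        for item in results:
            ui = item.get("ui", "")
            if not ui or ui == "NONE":
                continue
            out.append(Concept(cui=ui, name=item.get("name", ui),
                               root_source=item.get("rootSource", "MTH")))
        return out

    def _search_semantic_types_impl(self, cui: str) -> list[SemanticType]:
        data = self._get(f"/content/{self.release}/CUI/{cui}", {})
        stys = data.get("result", {}).get("semanticTypes", [])
        out = []
        for st in stys:
            uri = st.get("uri", "")
            tui = uri.rstrip("/").rsplit("/", 1)[-1] if uri else st.get("tui", "")
            if tui:
                out.append(SemanticType(tui=tui, name=st.get("name", tui)))
        return out[:MAX_SEMANTIC_TYPES_PER_CONCEPT]

    def _search_entity_type_impl(self, tui: str) -> EntityType:
        data = self._get(f"/semantic-network/{self.release}/TUI/{tui}", {})
        group = data.get("result", {}).get("semanticTypeGroup", {})
        if not group:
            return UNKNOWN_ENTITY_TYPE
        return EntityType(abbreviation=group.get("abbreviation", "UNKN"),
                          expanded_form=group.get("expandedForm", "Unknown"))
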