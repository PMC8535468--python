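"""Term finding and semantic resolution against a knowledge backend.

Boundary-validated candidate phrases are resolved in four ordered steps:

1. ``find_terms``      — keep only phrases with at least one knowledge-base
                         hit (exact first, approximate for the remainder);
2. ``identify_concepts``       — attach up to ``concept_limit`` concepts in
                                 KB preference order;
3. ``identify_semantic_types`` — attach 1..5 semantic types per concept;
4. ``identify_entity_types``   — attach the semantic group of every type.

Records are only ever dropped, never created or duplicated, after step 1;
drops are logged with their reason. The flattened semantic-type sequence of
a record (concept order, then within-concept order) feeds the positional
tie-breaking of the vote stage and must not be reordered.
"""

from __future__ import annotations

import json
import logging
from typing import Iterable, Optional, Sequence, Union

from .backend import DEFAULT_APPROX_THRESHOLD, DEFAULT_CONCEPT_LIMIT, KnowledgeBackend
from .types import CandidatePhrase, TermMatch, TermRecord

logger = logging.getLogger(__name__)


def find_terms(phrases: Sequence[Union[str, CandidatePhrase]],
               backend: KnowledgeBackend,
               threshold: float = DEFAULT_APPROX_THRESHOLD,
               use_approximate: bool = True,
               use_exact: bool = True) -> list[TermRecord]:
    """Match candidate phrases to knowledge-base terms; drop the unmatched.

    Each phrase is looked up by its surface form first and, failing that, by
    its lemmatised form. Exact lookups run before approximate retrieval over
    the remainder (hybrid matching); input order is preserved.
    """
    records: list[TermRecord] = []
    for phrase in phrases:
        if isinstance(phrase, CandidatePhrase):
            surface, lemma, source = phrase.normalized, phrase.normalized_lemma, phrase
        else:
            surface, lemma, source = phrase.lower().strip(), phrase.lower().strip(), None
        if not surface:
            continue
        record = _match_one(surface, lemma, backend, threshold,
                            use_exact=use_exact, use_approximate=use_approximate)
        if record is None:
            logger.debug("term finding: no KB hit for %r, omitted", surface)
            continue
        record.source = source
        records.append(record)
    return records


def _match_one(surface: str, lemma: str, backend: KnowledgeBackend,
               threshold: float, use_exact: bool, use_approximate: bool,
               ) -> Optional[TermRecord]:
    if use_exact:
        exact = backend.exact_match(surface)
        if exact is not None:
            return TermRecord(term=surface, match=exact, lookup_form="surface")
        if lemma != surface:
            exact = backend.exact_match(lemma)
            if exact is not None:
                return TermRecord(term=surface, match=exact, lookup_form="lemma")
    if use_approximate:
        candidates = [(entry, score)
                      for entry, score in backend.approximate_candidates(surface, threshold)
                      if score < 1.0]
        if candidates:
            entry, score = candidates[0]
            match = TermMatch(query=surface, matched_term=entry,
                              mode="approximate", score=score)
            return TermRecord(term=surface, match=match, lookup_form="surface")
    return None


def identify_concepts(term_records: Iterable[TermRecord],
                      backend: KnowledgeBackend,
                      concept_limit: int = DEFAULT_CONCEPT_LIMIT) -> list[TermRecord]:
    """Attach up to ``concept_limit`` concepts (KB order) to each record."""
    out: list[TermRecord] = []
    for rec in term_records:
        concepts = backend.search_concepts(rec.match.matched_term, limit=concept_limit)
        if not concepts:
            logger.warning("concept lookup returned nothing for %r; record dropped",
                           rec.match.matched_term)
            continue
        rec.concepts = concepts
        out.append(rec)
    return out


def identify_semantic_types(term_records: Iterable[TermRecord],
                            backend: KnowledgeBackend) -> list[TermRecord]:
    """Attach each concept's semantic types; concepts with none are dropped."""
    out: list[TermRecord] = []
    for rec in term_records:
        kept_concepts = []
        kept_types = []
        for concept in rec.concepts:
            stys = backend.search_semantic_types(concept.cui)
            if not stys:
                logger.warning("concept %s (%s) has no semantic types; dropped",
                               concept.cui, concept.name)
                continue
            kept_concepts.append(concept)
            kept_types.append(stys)
        if not kept_concepts:
            logger.warning("term %r lost all concepts at semantic-type stage; dropped",
                           rec.term)
            continue
        rec.concepts = kept_concepts
        rec.semantic_types = kept_types
        out.append(rec)
    return out


def identify_entity_types(term_records: Iterable[TermRecord],
                          backend: KnowledgeBackend) -> list[TermRecord]:
    """Map every semantic type to its semantic group (sentinel when unknown)."""
    out: list[TermRecord] = []
    for rec in term_records:
        rec.entity_types = {st.tui: backend.search_entity_type(st.tui)
                            for st in rec.flat_semantic_types()}
        out.append(rec)
    return out


def extract_terms(phrases: Sequence[Union[str, CandidatePhrase]],
                  backend: KnowledgeBackend,
                  concept_limit: int = DEFAULT_CONCEPT_LIMIT,
                  threshold: float = DEFAULT_APPROX_THRESHOLD,
                  use_approximate: bool = True,
                  use_exact: bool = True) -> list[TermRecord]:
    """Fused convenience call: the four resolution steps in sequence."""
    records = find_terms(phrases, backend, threshold=threshold,
                         use_approximate=use_approximate, use_exact=use_exact)
    records = identify_concepts(records, backend, concept_limit=concept_limit)
    records = identify_semantic_types(records, backend)
    records = identify_entity_types(records, backend)
    return records


def term_record_to_json(rec: TermRecord) -> str:
    """One TermRecord as a JSON line (for --dump-terms inspection)."""
    payload = {
        "term": rec.term,
        "match": {"query": rec.match.query, "matched_term": rec.match.matched_term,
                  "mode": rec.match.mode, "score": rec.match.score},
        "lookup_form": rec.lookup_form,
        "concepts": [{"cui": c.cui, "name": c.name, "root_source": c.root_source}
                     for c in rec.concepts],
        "semantic_types": [[{"tui": st.tui, "name": st.name} for st in group]
                           for group in rec.semantic_types],
        "entity_types": {tui: {"abbreviation": et.abbreviation,
                               "expanded_form": et.expanded_form}
                         for tui, et in rec.entity_types.items()},
    }
    return json.dumps(payload, sort_keys=True)
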