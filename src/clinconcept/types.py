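"""Core datatypes shared across the extraction pipeline.

The pipeline turns a raw clinical note into :class:`ConceptAnnotation` spans in
four stages: tokenisation into a :class:`Document`, candidate-phrase generation
(:class:`CandidatePhrase`), knowledge-base resolution (:class:`TermRecord`,
holding :class:`Concept` / :class:`SemanticType` / :class:`EntityType` chains)
and majority-vote classification (:class:`VoteResult`).

Span conventions follow the i2b2-2010 annotation format: lines are 1-based,
token offsets within a line are 0-based, and a span is inclusive on both ends.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class Token:
    """A single token with its position in the source document."""

    surface: str
    lemma: str
    pos_tag: str
    line_index: int  # 1-based line in the note
    token_index: int  # 0-based offset within the line

    def __post_init__(self) -> None:
        if self.line_index < 1:
            raise ValueError(f"line_index must be >= 1, got {self.line_index}")
        if self.token_index < 0:
            raise ValueError(f"token_index must be >= 0, got {self.token_index}")


@dataclass
class Sentence:
    """An ordered token sequence; never spans a line break."""

    tokens: list[Token]


@dataclass
class Document:
    """A clinical note split into sentences of position-annotated tokens."""

    doc_id: str
    text: str
    sentences: list[Sentence]


def _is_punctuation(tok: str) -> bool:
    return bool(tok) and all(ch in string.punctuation for ch in tok)


@dataclass
class CandidatePhrase:
    """A contiguous n-gram span (n <= n_max) that may denote a clinical concept.

    ``normalized`` is the lowercased, whitespace-collapsed join of the tokens
    with punctuation-only edge tokens stripped; it is the key used for
    deduplication and knowledge-base lookup.
    """

    tokens: list[str]
    lemmas: list[str]
    pos_tags: list[str]
    location: tuple[int, int, int]  # (line_index, first token_index, last token_index)
    normalized: str = field(init=False)
    normalized_lemma: str = field(init=False)

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.lemmas) == len(self.pos_tags)):
            raise ValueError("tokens, lemmas and pos_tags must be parallel")
        if not 1 <= len(self.tokens):
            raise ValueError("a candidate phrase needs at least one token")
        self.normalized = normalize_phrase(self.tokens)
        self.normalized_lemma = normalize_phrase(self.lemmas)

    @property
    def n(self) -> int:
        return len(self.tokens)


def normalize_phrase(tokens: list[str]) -> str:
    """Lowercase, strip punctuation-only edge tokens, collapse whitespace."""
    toks = list(tokens)
    while toks and _is_punctuation(toks[0]):
        toks.pop(0)
    while toks and _is_punctuation(toks[-1]):
        toks.pop()
    return " ".join(t.lower() for t in " ".join(toks).split())


@dataclass(frozen=True)
class Concept:
    """A Metathesaurus concept record."""

    cui: str  # concept unique identifier, C + digits
    name: str  # preferred concept name
    root_source: str = "MTH"

    def __post_init__(self) -> None:
        if not self.cui:
            raise ValueError("cui must be nonempty")


@dataclass(frozen=True)
class SemanticType:
    """A semantic type attached to a concept (1-5 per concept)."""

    tui: str  # type unique identifier, T + digits
    name: str

    def __post_init__(self) -> None:
        if not self.tui:
            raise ValueError("tui must be nonempty")


@dataclass(frozen=True)
class EntityType:
    """The single semantic group a semantic type belongs to."""

    abbreviation: str
    expanded_form: str


#: Sentinel returned for TUIs absent from the knowledge base.
UNKNOWN_ENTITY_TYPE = EntityType(abbreviation="UNKN", expanded_form="Unknown")


@dataclass(frozen=True)
class TermMatch:
    """How a candidate phrase was matched against the knowledge base."""

    query: str
    matched_term: str
    mode: str  # "exact" | "approximate"
    score: float  # similarity in [0, 1]; 1.0 for exact

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "approximate"):
            raise ValueError(f"unknown match mode {self.mode!r}")
        if self.mode == "exact" and self.score != 1.0:
            raise ValueError("exact matches must score 1.0")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class TermRecord:
    """A matched term with its resolved concept/semantic-type/entity-type chain.

    ``semantic_types`` is parallel to ``concepts`` (one list per concept);
    ``entity_types`` is parallel to the flattened semantic-type sequence.
    The flattened order — concepts in KB preference order, then within-concept
    order — is significant: vote tie-breaking is positional.
    """

    term: str
    match: TermMatch
    source: Optional[CandidatePhrase] = None
    lookup_form: str = "surface"  # "surface" | "lemma"
    concepts: list[Concept] = field(default_factory=list)
    semantic_types: list[list[SemanticType]] = field(default_factory=list)
    entity_types: dict[str, EntityType] = field(default_factory=dict)  # keyed by TUI

    def flat_semantic_types(self) -> list[SemanticType]:
        return [st for group in self.semantic_types for st in group]

    def flat_semantic_type_names(self) -> list[str]:
        return [st.name for st in self.flat_semantic_types()]


PROBLEM = "Problem"
TREATMENT = "Treatment"
TEST = "Test"
NONE_LABEL = "NONE"
CLASSES = (PROBLEM, TREATMENT, TEST)


@dataclass
class VoteResult:
    """Outcome of majority voting over dictionary-mapped semantic types."""

    labels: list[str]  # non-NONE labels, in flattened sequence order
    counts: dict[str, int]
    winner: Optional[str]
    rule_applied: str  # "rule1" | "rule2" | "rule3" | "unclassified"


@dataclass
class ConceptAnnotation:
    """A classified concept span in a document."""

    text: str
    location: tuple[int, int, int]  # (line, first token, last token), i2b2 convention
    category: str  # "problem" | "treatment" | "test"
    doc_id: str = ""
    vote: Optional[VoteResult] = None
    concepts: list[Concept] = field(default_factory=list)
    match: Optional[TermMatch] = None

    def __post_init__(self) -> None:
        if self.category not in ("problem", "treatment", "test"):
            raise ValueError(f"invalid category {self.category!r}")
        if self.vote is not None and self.vote.winner is not None:
            if self.category != self.vote.winner.lower():
                raise ValueError("category must equal the vote winner (lowercased)")


@dataclass(frozen=True)
class GoldAnnotation:
    """A reference concept span (same shape as ConceptAnnotation, no vote)."""

    text: str
    location: tuple[int, int, int]
    category: str
    doc_id: str = ""

    def __post_init__(self) -> None:
        if self.category not in ("problem", "treatment", "test"):
            raise ValueError(f"invalid category {self.category!r}")
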