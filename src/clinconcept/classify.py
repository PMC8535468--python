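"""Problem/Treatment/Test classification by dictionary vote.

Every semantic type attached to a term is looked up, case-insensitively, in
three disjoint semantic-type dictionaries (problem PRB, treatment TRT, test
TST). Types found in no dictionary label as NONE and are stripped before
counting. The term's category is the argmax of the per-class vote counts,

    T = argmax_c sum_i [label_i = c]

with three tie-break rules over the ordered label sequence:

* Rule 1 — a unique maximum wins outright.
* Rule 2 — a three-way tie is resolved to the class occurring earliest in
  the label sequence.
* Rule 3 — a two-way tie above the third class ignores that third class and
  is resolved to the earlier-occurring of the two tied classes.

Tie-breaking is positional (first occurrence in the flattened semantic-type
sequence), which is why the extraction stage must preserve concept order.

``run_pipeline`` glues preprocessing, extraction and voting into the
end-to-end document annotator, resolving overlapping classified spans in
favour of the longest (then leftmost) match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .backend import (DEFAULT_APPROX_THRESHOLD, DEFAULT_CONCEPT_LIMIT,
                      KnowledgeBackend)
from .extraction import extract_terms
from .preprocess import DEFAULT_STOPWORDS, candidate_phrases, document_from_text
from .types import (CLASSES, ConceptAnnotation, Document, NONE_LABEL, PROBLEM,
                    TermRecord, TEST, TREATMENT, VoteResult)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SemanticDictionary:
    """The three disjoint semantic-type dictionaries (PRB / TRT / TST)."""

    problem: frozenset[str]
    treatment: frozenset[str]
    test: frozenset[str]

    def __post_init__(self) -> None:
        if (self.problem & self.treatment or self.problem & self.test
                or self.treatment & self.test):
            raise ValueError("the three dictionaries must be pairwise disjoint")

    @classmethod
    def from_names(cls, problem: Iterable[str], treatment: Iterable[str],
                   test: Iterable[str]) -> "SemanticDictionary":
        norm = lambda names: frozenset(n.strip().lower() for n in names)
        return cls(problem=norm(problem), treatment=norm(treatment), test=norm(test))

    def label(self, semantic_type_name: str) -> str:
        name = semantic_type_name.strip().lower()
        if name in self.problem:
            return PROBLEM
        if name in self.treatment:
            return TREATMENT
        if name in self.test:
            return TEST
        return NONE_LABEL


#: Default dictionaries: 12 problem, 9 treatment and 7 test semantic types.
DEFAULT_DICTIONARIES = SemanticDictionary.from_names(
    problem=[
        "Disease or Syndrome", "Sign or Symptom", "Finding",
        "Pathologic Function", "Mental or Behavioral Dysfunction",
        "Injury or Poisoning", "Cell or Molecular Dysfunction",
        "Congenital Abnormality", "Acquired Abnormality", "Neoplastic Process",
        "Anatomic Abnormality", "virus/bacterium",
    ],
    treatment=[
        "Therapeutic or Preventive Procedure", "Organic Chemical",
        "Pharmacologic Substance", "Biomedical and Dental material",
        "Antibiotic", "Clinical Drug", "Steroid", "Drug Delivery Device",
        "Medical Device",
    ],
    test=[
        "Tissue", "Cell", "Laboratory or Test Result", "Laboratory Procedure",
        "diagnostic procedure", "Clinical Attribute", "Body Substance",
    ],
)


def label_semantic_types(semantic_type_names: Sequence[str],
                         dicts: SemanticDictionary = DEFAULT_DICTIONARIES,
                         ) -> list[str]:
    """Map each semantic-type name to Problem/Treatment/Test or NONE."""
    return [dicts.label(name) for name in semantic_type_names]


def majority_vote(labels: Sequence[str]) -> VoteResult:
    """Argmax vote over an ordered label sequence with positional tie-breaks."""
    for lab in labels:
        if lab not in CLASSES and lab != NONE_LABEL:
            raise ValueError(f"unknown label {lab!r}")
    kept = [lab for lab in labels if lab != NONE_LABEL]
    counts = {cls: kept.count(cls) for cls in CLASSES}
    if not kept:
        return VoteResult(labels=[], counts=counts, winner=None,
                          rule_applied="unclassified")
    top = max(counts.values())
    tied = [cls for cls in CLASSES if counts[cls] == top]
    if len(tied) == 1:
        return VoteResult(labels=kept, counts=counts, winner=tied[0],
                          rule_applied="rule1")
    winner = next(lab for lab in kept if lab in tied)
    rule = "rule2" if len(tied) == 3 else "rule3"
    return VoteResult(labels=kept, counts=counts, winner=winner, rule_applied=rule)


def classify_term(term_record: TermRecord,
                  dicts: SemanticDictionary = DEFAULT_DICTIONARIES,
                  ) -> Optional[ConceptAnnotation]:
    """Vote a fully resolved term into a category; None when unclassifiable."""
    labels = label_semantic_types(term_record.flat_semantic_type_names(), dicts)
    vote = majority_vote(labels)
    if vote.winner is None:
        return None
    if term_record.source is not None:
        text = " ".join(term_record.source.tokens)
        location = term_record.source.location
    else:
        text = term_record.term
        location = (1, 0, max(0, len(term_record.term.split()) - 1))
    return ConceptAnnotation(text=text, location=location,
                             category=vote.winner.lower(), vote=vote,
                             concepts=list(term_record.concepts),
                             match=term_record.match)


@dataclass
class PipelineConfig:
    """Tunable knobs of the end-to-end annotator."""

    ngram_max: int = 4
    concept_limit: int = DEFAULT_CONCEPT_LIMIT
    approx_threshold: float = DEFAULT_APPROX_THRESHOLD
    use_exact: bool = True
    use_approximate: bool = True
    stopwords: frozenset[str] = field(default_factory=lambda: DEFAULT_STOPWORDS)


def _spans_overlap(a: tuple[int, int, int], b: tuple[int, int, int]) -> bool:
    return a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]


def resolve_overlaps(annotations: Sequence[ConceptAnnotation]) -> list[ConceptAnnotation]:
    """Resolve overlapping spans: best match quality, then longest, leftmost.

    Exact dictionary hits outrank approximate ones (an approximate hit on a
    superstring must not swallow an exact hit nested inside it); among
    approximate hits the higher similarity wins; remaining ties go to the
    longer, then leftmost, span.
    """
    def quality(ann: ConceptAnnotation) -> tuple[int, float]:
        if ann.match is None or ann.match.mode == "exact":
            return (0, 1.0)
        return (1, -ann.match.score)

    ranked = sorted(
        annotations,
        key=lambda ann: (*quality(ann),
                         -(ann.location[2] - ann.location[1]),
                         ann.location[0], ann.location[1]))
    kept: list[ConceptAnnotation] = []
    for ann in ranked:
        if not any(_spans_overlap(ann.location, other.location) for other in kept):
            kept.append(ann)
    kept.sort(key=lambda ann: ann.location)
    return kept


def run_pipeline(document: Document | str,
                 backend: KnowledgeBackend,
                 dicts: SemanticDictionary = DEFAULT_DICTIONARIES,
                 config: Optional[PipelineConfig] = None,
                 doc_id: str = "") -> list[ConceptAnnotation]:
    """Annotate one clinical note end to end.

    Deterministic for fixed inputs and config. Accepts either a prepared
    :class:`Document` or raw text.
    """
    cfg = config or PipelineConfig()
    if isinstance(document, str):
        document = document_from_text(doc_id, document)
    candidates = candidate_phrases(document, n_max=cfg.ngram_max,
                                   stopwords=cfg.stopwords)
    logger.info("doc %s: %d boundary-validated candidates", document.doc_id,
                len(candidates))
    records = extract_terms(candidates, backend,
                            concept_limit=cfg.concept_limit,
                            threshold=cfg.approx_threshold,
                            use_approximate=cfg.use_approximate,
                            use_exact=cfg.use_exact)
    logger.info("doc %s: %d terms resolved in knowledge base", document.doc_id,
                len(records))
    annotations: list[ConceptAnnotation] = []
    for rec in records:
        ann = classify_term(rec, dicts)
        if ann is not None:
            ann.doc_id = document.doc_id
            annotations.append(ann)
    resolved = resolve_overlaps(annotations)
    logger.info("doc %s: %d annotations after overlap resolution",
                document.doc_id, len(resolved))
    return resolved
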