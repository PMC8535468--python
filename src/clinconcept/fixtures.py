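"""Offline test world: a miniature Metathesaurus and synthetic annotated notes.

The full UMLS Metathesaurus and the i2b2-2010 corpora are license-restricted,
so everything here is generated: :func:`build_paper_fixture_kb` emits a small
knowledge base whose entries reproduce the published worked examples of the
method (the "beta blockers" / "heart rate" / "increased heart rate" semantic
breakdowns, the "stress" four-concept case study, the coronary-artery-disease
and trout/fish/Living-Beings lookups) plus a handful of ordinary clinical
vocabulary, and :func:`generate_synthetic_corpus` plants that vocabulary
inside stopword/verb-heavy distractor sentences to produce notes with exact
gold annotations.

By construction a planted corpus is fully recoverable: distractor tokens are
all stopwords or verb/adjective/adverb forms (so boundary filtering removes
them), no distractor n-gram resembles a knowledge-base entry, and no planted
phrase nests inside another in the same document. Running the pipeline on a
generated corpus against its own knowledge base must therefore reach
precision and recall 1.0 under exact span matching — the end-to-end smoke
test. An optional typo injector perturbs one character of a long planted
token to exercise approximate matching with a known answer.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field
from typing import Optional

from .backend import FixtureBackend, trigram_jaccard
from .classify import DEFAULT_DICTIONARIES, SemanticDictionary, label_semantic_types, majority_vote
from .preprocess import DEFAULT_STOPWORDS, is_content_token
from .postag import pos_tag_token
from .types import GoldAnnotation

# ---------------------------------------------------------------------------
# The paper-derived fixture knowledge base
# ---------------------------------------------------------------------------


def _concept(cui: str, name: str, *types: tuple[str, str],
             root_source: str = "MTH") -> dict:
    return {"cui": cui, "name": name, "root_source": root_source,
            "semantic_types": [{"tui": t, "name": n} for t, n in types]}


PAPER_FIXTURE_KB: dict = {
    "terms": [
        {
            "term": "coronary artery disease",
            "concepts": [
                _concept("C0010054", "Coronary Arteriosclerosis",
                         ("T047", "Disease or Syndrome")),
                _concept("C1956346", "Coronary Artery Disease",
                         ("T047", "Disease or Syndrome")),
                _concept("C0010068", "Coronary heart disease",
                         ("T047", "Disease or Syndrome")),
            ],
        },
        {
            "term": "trout",
            "concepts": [_concept("C0041200", "Salmo trutta", ("T013", "Fish"))],
        },
        {
            "term": "stress",
            "concepts": [
                _concept("C0038435", "Stress", ("T046", "Pathologic Function")),
                _concept("C0038443", "Stress, Psychological",
                         ("T048", "Mental or Behavioral Dysfunction")),
                _concept("C0015260", "Exercise stress test",
                         ("T060", "Diagnostic Procedure")),
                _concept("C0117361", "Stress bismuth subsalicylate",
                         ("T109", "Organic Chemical"),
                         ("T121", "Pharmacological Substance")),
            ],
        },
        {
            "term": "beta blockers",
            "concepts": [
                _concept("C0001645", "beta-Adrenergic Blocking Agents",
                         ("T121", "Pharmacologic Substance"),
                         ("T109", "Organic Chemical")),
                _concept("C0596076", "Beta-adrenergic blockade",
                         ("T046", "Pathologic Function")),
                _concept("C0304516", "Beta-blocker preparation",
                         ("T109", "Organic Chemical"),
                         ("T201", "Clinical Attribute")),
                _concept("C0274281", "Beta-blocker overdose",
                         ("T037", "Injury or Poisoning")),
                _concept("C0304517", "Beta blocking agents",
                         ("T121", "Pharmacologic Substance")),
            ],
        },
        {
            "term": "heart rate",
            "concepts": [
                _concept("C0018810", "Heart rate", ("T201", "Clinical Attribute")),
                _concept("C0232117", "Pulse Rate", ("T201", "Clinical Attribute")),
                _concept("C0577821", "Heart rate finding", ("T033", "Finding")),
                _concept("C0428886", "Normal heart rate", ("T033", "Finding")),
                _concept("C0182537", "Heart rate monitor", ("T074", "Medical Device")),
                _concept("C0179805", "Cardiac monitor", ("T074", "Medical Device")),
            ],
        },
        {
            "term": "increased heart rate",
            "concepts": [
                _concept("C0039231", "Tachycardia", ("T033", "Finding")),
                _concept("C0437616", "Increased heart rate", ("T033", "Finding")),
                _concept("C0018810", "Heart rate", ("T201", "Clinical Attribute")),
                _concept("C0232117", "Pulse Rate", ("T201", "Clinical Attribute")),
                _concept("C0852911", "Heart rate increased",
                         ("T033", "Finding"), ("T201", "Clinical Attribute")),
                _concept("C0034642", "Rapid pulse",
                         ("T033", "Finding"), ("T201", "Clinical Attribute")),
                _concept("C0205217", "Increased", ("T000", "NONE")),
                _concept("C0871420", "Rate", ("T000", "NONE")),
            ],
        },
        {
            "term": "pelvic fracture",
            "concepts": [_concept("C0747328", "Pelvic Fracture",
                                  ("T037", "Injury or Poisoning"))],
        },
        {
            "term": "chest pain",
            "concepts": [_concept("C0008031", "Chest Pain",
                                  ("T184", "Sign or Symptom"))],
        },
        {
            "term": "aspirin",
            "concepts": [_concept("C0004057", "Aspirin",
                                  ("T109", "Organic Chemical"),
                                  ("T121", "Pharmacologic Substance"))],
        },
        {
            "term": "atrial fibrillation",
            "concepts": [_concept("C0004238", "Atrial Fibrillation",
                                  ("T047", "Disease or Syndrome"))],
        },
        {
            "term": "blood pressure",
            "concepts": [
                _concept("C0005823", "Blood Pressure", ("T201", "Clinical Attribute")),
                _concept("C0005824", "Blood pressure determination",
                         ("T060", "Diagnostic Procedure")),
            ],
        },
        {
            "term": "echocardiogram",
            "concepts": [_concept("C0013516", "Echocardiography",
                                  ("T060", "Diagnostic Procedure"))],
        },
        {
            "term": "serum creatinine",
            "concepts": [_concept("C0201976", "Serum creatinine measurement",
                                  ("T059", "Laboratory Procedure"))],
        },
        {
            "term": "lisinopril",
            "concepts": [_concept("C0065374", "Lisinopril",
                                  ("T121", "Pharmacologic Substance"))],
        },
    ],
    "entity_types": [
        {"tui": "T013", "abbreviation": "LIVB", "expanded_form": "Living Beings"},
        {"tui": "T033", "abbreviation": "DISO", "expanded_form": "Disorders"},
        {"tui": "T037", "abbreviation": "DISO", "expanded_form": "Disorders"},
        {"tui": "T046", "abbreviation": "DISO", "expanded_form": "Disorders"},
        {"tui": "T047", "abbreviation": "DISO", "expanded_form": "Disorders"},
        {"tui": "T048", "abbreviation": "DISO", "expanded_form": "Disorders"},
        {"tui": "T059", "abbreviation": "PROC", "expanded_form": "Procedures"},
        {"tui": "T060", "abbreviation": "PROC", "expanded_form": "Procedures"},
        {"tui": "T074", "abbreviation": "DEVI", "expanded_form": "Devices"},
        {"tui": "T109", "abbreviation": "CHEM", "expanded_form": "Chemicals & Drugs"},
        {"tui": "T121", "abbreviation": "CHEM", "expanded_form": "Chemicals & Drugs"},
        {"tui": "T184", "abbreviation": "DISO", "expanded_form": "Disorders"},
        {"tui": "T201", "abbreviation": "PHYS", "expanded_form": "Physiology"},
        {"tui": "T000", "abbreviation": "UNKN", "expanded_form": "Unknown"},
    ],
}

#: KB entries suitable for planting in synthetic notes (clinical vocabulary).
DEFAULT_VOCABULARY_TERMS = [
    "coronary artery disease", "stress", "beta blockers", "heart rate",
    "increased heart rate", "pelvic fracture", "chest pain", "aspirin",
    "atrial fibrillation", "blood pressure", "echocardiogram",
    "serum creatinine", "lisinopril",
]


def build_paper_fixture_kb(out_path: Optional[str] = None) -> dict:
    """The fixture knowledge base; optionally written to ``out_path`` as JSON."""
    kb = json.loads(json.dumps(PAPER_FIXTURE_KB))  # deep copy
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as fh:
            json.dump(kb, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return kb


def paper_fixture_backend() -> FixtureBackend:
    return FixtureBackend(build_paper_fixture_kb())


# ---------------------------------------------------------------------------
# Synthetic corpus generation
# ---------------------------------------------------------------------------

# Every template token is a stopword or tagged verb/adjective/adverb, so
# boundary filtering removes pure-distractor material entirely.
_PREFIX_POOL = [
    "she was feeling", "he had been", "they were", "it was", "she had",
    "he was having", "there was", "we did have", "he is", "she is being",
]
_SUFFIX_POOL = [
    "again", "now", "too", "then", "as well", "very often", "once more", "",
]
_FILLER_POOL = [
    "she was doing well .", "he had been very tired .", "they were fine .",
    "it was getting better .", "he was not feeling well .",
    "she had been well again .",
]


class FixtureSpecError(ValueError):
    """Invalid synthetic-corpus specification."""


@dataclass
class FixtureSpec:
    """Recipe for a reproducible synthetic annotated corpus."""

    seed: int = 1
    n_documents: int = 3
    concepts_per_doc: int = 5
    vocabulary: Optional[list[tuple[str, list[str], str]]] = None
    dictionaries: SemanticDictionary = field(default_factory=lambda: DEFAULT_DICTIONARIES)
    category_weights: Optional[dict[str, float]] = None
    typo_rate: float = 0.0  # fraction of planted phrases receiving a 1-char edit

    def __post_init__(self) -> None:
        if self.n_documents < 0 or self.concepts_per_doc < 0:
            raise FixtureSpecError("document and concept counts must be >= 0")
        if not 0.0 <= self.typo_rate <= 1.0:
            raise FixtureSpecError("typo_rate must lie in [0, 1]")


@dataclass
class SyntheticCorpus:
    """Generated notes, gold annotations, and the knowledge base they match."""

    notes: dict[str, str]  # doc_id -> note text
    gold: list[GoldAnnotation]
    kb: dict


def _vocabulary_from_kb(kb: dict, dicts: SemanticDictionary,
                        ) -> list[tuple[str, list[str], str]]:
    """(phrase, breakdown labels, voted category) triples for plantable terms."""
    by_term = {entry["term"]: entry for entry in kb["terms"]}
    vocab = []
    for term in DEFAULT_VOCABULARY_TERMS:
        entry = by_term[term]
        names = [st["name"] for concept in entry["concepts"]
                 for st in concept["semantic_types"]]
        labels = label_semantic_types(names, dicts)
        vote = majority_vote(labels)
        assert vote.winner is not None, f"vocabulary term {term!r} is unclassifiable"
        vocab.append((term, labels, vote.winner.lower()))
    return vocab


def _nested(a: str, b: str) -> bool:
    """True when one phrase's token sequence is contiguous inside the other's."""
    ta, tb = a.split(), b.split()
    if len(ta) > len(tb):
        ta, tb = tb, ta
    return any(tb[i:i + len(ta)] == ta for i in range(len(tb) - len(ta) + 1))


def _validate_distractors(kb_terms: list[str]) -> None:
    for template in _PREFIX_POOL + _SUFFIX_POOL + _FILLER_POOL:
        for tok in template.split():
            if tok == ".":
                continue
            if is_content_token(tok, pos_tag_token(tok), DEFAULT_STOPWORDS):
                raise FixtureSpecError(
                    f"distractor token {tok!r} would survive boundary filtering")
            for term in kb_terms:
                if trigram_jaccard(tok, term) >= 0.6:
                    raise FixtureSpecError(
                        f"distractor token {tok!r} resembles KB term {term!r}")


def _inject_typo(phrase: str, rng: random.Random) -> str:
    """Substitute one character inside the longest token (length >= 6)."""
    tokens = phrase.split()
    idx = max(range(len(tokens)), key=lambda i: len(tokens[i]))
    tok = tokens[idx]
    if len(tok) < 6:
        return phrase
    pos = rng.randrange(1, len(tok) - 1)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    repl = rng.choice([c for c in alphabet if c != tok[pos]])
    tokens[idx] = tok[:pos] + repl + tok[pos + 1:]
    return " ".join(tokens)


def generate_synthetic_corpus(spec: FixtureSpec) -> SyntheticCorpus:
    """Build notes with planted vocabulary phrases and exact gold spans."""
    rng = random.Random(spec.seed)
    kb = build_paper_fixture_kb()
    vocab = spec.vocabulary if spec.vocabulary is not None \
        else _vocabulary_from_kb(kb, spec.dictionaries)
    for phrase, labels, category in vocab:
        vote = majority_vote(labels)
        if vote.winner is None or vote.winner.lower() != category:
            raise FixtureSpecError(
                f"vocabulary entry {phrase!r}: gold category {category!r} does not "
                f"equal the majority vote of its breakdown labels")
    _validate_distractors([e["term"] for e in kb["terms"]])

    notes: dict[str, str] = {}
    gold: list[GoldAnnotation] = []
    for d in range(spec.n_documents):
        doc_id = f"doc_{d + 1:03d}"
        chosen: list[tuple[str, list[str], str]] = []
        pool = list(vocab)
        weights = None
        if spec.category_weights is not None:
            weights = [spec.category_weights.get(cat, 1.0) for _, _, cat in pool]
        while pool and len(chosen) < spec.concepts_per_doc:
            if weights is not None:
                pick = rng.choices(range(len(pool)), weights=weights, k=1)[0]
            else:
                pick = rng.randrange(len(pool))
            cand = pool.pop(pick)
            if weights is not None:
                weights.pop(pick)
            # no planted phrase may nest inside another in the same document
            if any(_nested(cand[0], prev[0]) for prev in chosen):
                continue
            chosen.append(cand)

        kb_terms = [e["term"] for e in kb["terms"]]
        lines: list[str] = []
        for phrase, _labels, category in chosen:
            surface = phrase
            # Typos are only injected into long phrases with no other KB term
            # nested inside: an exact sub-term hit would otherwise outrank the
            # approximate full-phrase hit during overlap resolution.
            typo_safe = (len(phrase) >= 12
                         and not any(_nested(other, phrase)
                                     for other in kb_terms if other != phrase))
            if spec.typo_rate > 0 and typo_safe and rng.random() < spec.typo_rate:
                surface = _inject_typo(phrase, rng)
            prefix = rng.choice(_PREFIX_POOL)
            suffix = rng.choice(_SUFFIX_POOL)
            pieces = [prefix, surface] + ([suffix] if suffix else []) + ["."]
            line_tokens = " ".join(pieces).split()
            start = len(prefix.split())
            end = start + len(surface.split()) - 1
            lines.append(" ".join(line_tokens))
            gold.append(GoldAnnotation(text=surface,
                                       location=(len(lines), start, end),
                                       category=category, doc_id=doc_id))
            if rng.random() < 0.5:
                lines.append(rng.choice(_FILLER_POOL))
        notes[doc_id] = "\n".join(lines) + ("\n" if lines else "")
    return SyntheticCorpus(notes=notes, gold=gold, kb=kb)


def write_corpus(corpus: SyntheticCorpus, out_dir: str) -> None:
    """Write notes (.txt), gold (.con) and fixture_kb.json into a directory."""
    from .conio import write_i2b2_con

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "fixture_kb.json"), "w", encoding="utf-8") as fh:
        json.dump(corpus.kb, fh, indent=1, sort_keys=True)
        fh.write("\n")
    by_doc: dict[str, list[GoldAnnotation]] = {doc_id: [] for doc_id in corpus.notes}
    for ann in corpus.gold:
        by_doc[ann.doc_id].append(ann)
    for doc_id, text in corpus.notes.items():
        with open(os.path.join(out_dir, f"{doc_id}.txt"), "w", encoding="utf-8") as fh:
            fh.write(text)
        write_i2b2_con(by_doc[doc_id], os.path.join(out_dir, f"{doc_id}.con"))
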