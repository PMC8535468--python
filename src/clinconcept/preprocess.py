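"""Document preprocessing: tokenisation, n-gram candidates, boundary filtering.

A raw clinical note is turned into boundary-validated candidate phrases in
five steps:

1. tokenise line by line (clinical notes are line-oriented; a newline or a
   sentence-final punctuation token ends a sentence),
2. POS-tag and lemmatise every token,
3. enumerate contiguous n-grams (n = 1..4 by default) within each sentence,
4. deduplicate on the normalised phrase text (first occurrence wins),
5. keep a candidate only if it contains at least one *content* token — a
   token that is neither a stopword nor tagged verb/adjective/adverb.

Step 5 is what separates concept-bearing spans such as "a pelvic fracture"
(kept: "pelvic", "fracture") from function-word debris such as "is the" or
"did have of" (every token disqualified). Candidates containing standalone
punctuation tokens are discarded outright so that span offsets always cover
exactly the matched words.
"""

from __future__ import annotations

import re
import string
from importlib import resources
from typing import Iterable, Optional, Sequence, Union

from .postag import is_verb_adj_adv, lemmatize_token, pos_tag_token
from .types import CandidatePhrase, Document, Sentence, Token

# Words with internal ./-/' (q.d., mg/dL, 3.5) stay single tokens; any other
# punctuation becomes its own token.
_TOKEN_RE = re.compile(
    r"[A-Za-z0-9]+(?:[./\-'][A-Za-z0-9]+)+\.?"
    r"|[A-Za-z0-9]+"
    r"|[^\sA-Za-z0-9]"
)

_SENT_FINAL = {".", "!", "?"}


def load_stopwords(path: Optional[str] = None) -> frozenset[str]:
    """Load the stopword list (the frozen English list shipped as package data)."""
    if path is None:
        text = (resources.files("clinconcept") / "data" / "stopwords.txt").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


DEFAULT_STOPWORDS = load_stopwords()


def tokenize(text: str) -> list[list[str]]:
    """Split raw text into sentences of surface tokens.

    Line numbering starts at 1; sentences never cross lines. Empty text (or
    text with no word characters) yields an empty list.
    """
    return [[tok.surface for tok in sent.tokens] for sent in tokenize_with_positions(text)]


def tokenize_with_positions(text: str) -> list[Sentence]:
    """Tokenise, tag and lemmatise; tokens carry (line_index, token_index)."""
    sentences: list[Sentence] = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        current: list[Token] = []
        for tok_no, match in enumerate(_TOKEN_RE.finditer(line)):
            surface = match.group(0)
            tag = pos_tag_token(surface)
            token = Token(
                surface=surface,
                lemma=lemmatize_token(surface, tag),
                pos_tag=tag,
                line_index=line_no,
                token_index=tok_no,
            )
            current.append(token)
            if surface in _SENT_FINAL:
                sentences.append(Sentence(tokens=current))
                current = []
        if current:
            sentences.append(Sentence(tokens=current))
    return sentences


def document_from_text(doc_id: str, text: str) -> Document:
    return Document(doc_id=doc_id, text=text, sentences=tokenize_with_positions(text))


def _as_tokens(sentence_tokens: Sequence[Union[str, Token]]) -> list[Token]:
    toks: list[Token] = []
    for i, t in enumerate(sentence_tokens):
        if isinstance(t, Token):
            toks.append(t)
        else:
            tag = pos_tag_token(t)
            toks.append(Token(surface=t, lemma=lemmatize_token(t, tag),
                              pos_tag=tag, line_index=1, token_index=i))
    return toks


def generate_ngrams(sentence_tokens: Sequence[Union[str, Token]],
                    n_max: int = 4) -> list[CandidatePhrase]:
    """All contiguous windows of length 1..n_max within one sentence.

    Enumeration order is n-major: every unigram left to right, then every
    bigram, and so on. Windows never cross the sentence.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    toks = _as_tokens(sentence_tokens)
    out: list[CandidatePhrase] = []
    for n in range(1, n_max + 1):
        for start in range(0, len(toks) - n + 1):
            window = toks[start:start + n]
            out.append(CandidatePhrase(
                tokens=[t.surface for t in window],
                lemmas=[t.lemma for t in window],
                pos_tags=[t.pos_tag for t in window],
                location=(window[0].line_index, window[0].token_index,
                          window[-1].token_index),
            ))
    return out


def document_ngrams(document: Document, n_max: int = 4) -> list[CandidatePhrase]:
    """Candidate phrases for every sentence of a document, in order."""
    out: list[CandidatePhrase] = []
    for sent in document.sentences:
        out.extend(generate_ngrams(sent.tokens, n_max=n_max))
    return out


def deduplicate(phrases: Iterable[CandidatePhrase]) -> list[CandidatePhrase]:
    """Keep the first occurrence of each normalised phrase, order preserved."""
    seen: set[str] = set()
    out: list[CandidatePhrase] = []
    for ph in phrases:
        if ph.normalized not in seen:
            seen.add(ph.normalized)
            out.append(ph)
    return out


def pos_filter_bag(tagged_tokens: Iterable[tuple[str, str]]) -> list[str]:
    """Retain tokens tagged NN*, JJ* or RB* — the single-word bag of words."""
    return [tok for tok, tag in tagged_tokens
            if tag.startswith(("NN", "JJ", "RB"))]


def _is_punct_token(tok: str) -> bool:
    return bool(tok) and all(ch in string.punctuation for ch in tok)


def is_content_token(surface: str, pos_tag: str,
                     stopwords: frozenset[str] = DEFAULT_STOPWORDS) -> bool:
    """True when the token is neither a stopword nor tagged verb/adj/adverb."""
    return surface.lower() not in stopwords and not is_verb_adj_adv(pos_tag)


def identify_word_boundaries(
    candidates: Iterable[CandidatePhrase],
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> list[CandidatePhrase]:
    """Filter candidates down to those with at least one content token.

    A token is disqualified when it is a stopword or tagged verb, adjective
    or adverb; a candidate whose tokens are all disqualified is dropped.
    Candidates containing standalone punctuation tokens are dropped as well.
    """
    out: list[CandidatePhrase] = []
    for cand in candidates:
        if any(_is_punct_token(t) for t in cand.tokens):
            continue
        if not cand.normalized:
            continue
        if any(is_content_token(surf, tag, stopwords)
               for surf, tag in zip(cand.tokens, cand.pos_tags)):
            out.append(cand)
    return out


def candidate_phrases(document: Document, n_max: int = 4,
                      stopwords: frozenset[str] = DEFAULT_STOPWORDS,
                      ) -> list[CandidatePhrase]:
    """The full preprocessing chain: n-grams, dedup, boundary filtering."""
    return identify_word_boundaries(
        deduplicate(document_ngrams(document, n_max=n_max)), stopwords)
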