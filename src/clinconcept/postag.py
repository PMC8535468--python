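"""Deterministic rule-based POS tagging and lemmatisation.

The pipeline only needs a coarse part-of-speech signal: word-boundary
filtering disqualifies tokens tagged as verbs, adjectives or adverbs, and the
unigram bag keeps nouns/adjectives/adverbs. A small closed-class lexicon plus
suffix heuristics is sufficient for that purpose and keeps results bit-stable
across environments. Tags are Penn Treebank. Unknown words default to ``NN``,
which errs on the side of keeping candidates — the knowledge-base lookup then
acts as the precision filter.

The lemmatiser is a suffix-rule English lemmatiser with a small irregular
table: plural nouns are singularised (``arteries -> artery``) and inflected
verbs reduced to their base (``caring -> care``). Out-of-vocabulary tokens
come back as their lowercased selves.
"""

from __future__ import annotations

import string
from typing import Optional, Sequence

VOWELS = "aeiou"

#: Closed-class and high-frequency lexicon (lowercased surface -> Penn tag).
_LEXICON: dict[str, str] = {}


def _extend(tag: str, words: str) -> None:
    for w in words.split():
        _LEXICON[w] = tag


_extend("DT", "the a an this that these those each every some any no all both another such")
_extend("IN", "of in on at by for with from about against between into through during "
              "before after above below under over as until while because if than")
_extend("TO", "to")
_extend("CC", "and or but nor yet")
_extend("PRP", "i you he she it we they him them me us her")
_extend("PRP$", "my your his its our their hers")
_extend("MD", "can could will would shall should may might must")
_extend("VBP", "am are have do")
_extend("VBZ", "is has does")
_extend("VBD", "was were had did went said made got took gave saw felt")
_extend("VB", "be take give get go see feel make say show deny present "
              "report state complain reveal start continue receive prescribe")
_extend("VBN", "been done gone taken given seen made shown denied")
_extend("VBG", "being having doing going")
_extend("RB", "very really quite too also never always often sometimes again still "
              "just now then here there not well soon slowly n't")
_extend("JJ", "good bad severe acute chronic mild moderate normal abnormal high low "
              "old new large small stable unstable better worse fine tired intact alert")
_extend("EX", "there's")
_extend("WDT", "which what")
_extend("WP", "who whom")
_extend("WRB", "when where why how")

_PENN_PUNCT = {".": ".", ",": ",", ":": ":", ";": ":", "(": "(", ")": ")",
               "?": ".", "!": ".", "``": "``", "''": "''", '"': "''", "'": "''"}

_JJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "ic", "ical", "al", "ar", "ary")


def _is_number(tok: str) -> bool:
    stripped = tok.replace(",", "").replace(".", "").replace("-", "").replace("/", "")
    return bool(stripped) and stripped.isdigit()


def pos_tag_token(token: str) -> str:
    """Tag a single token with a Penn Treebank tag."""
    low = token.lower()
    if all(ch in string.punctuation for ch in token) and token:
        return _PENN_PUNCT.get(token, "SYM")
    if _is_number(low):
        return "CD"
    if low in _LEXICON:
        return _LEXICON[low]
    if low.endswith("ly") and len(low) > 3:
        return "RB"
    if low.endswith("ing") and len(low) > 4:
        return "VBG"
    if low.endswith("ed") and len(low) > 3:
        return "VBD"
    for suf in _JJ_SUFFIXES:
        if low.endswith(suf) and len(low) > len(suf) + 2:
            return "JJ"
    if low.endswith("s") and not low.endswith(("ss", "us", "is")) and len(low) > 3:
        return "NNS"
    return "NN"


def pos_tag_tokens(tokens: Sequence[str]) -> list[str]:
    return [pos_tag_token(t) for t in tokens]


def is_verb_adj_adv(tag: str) -> bool:
    """Coarse map: VB*/MD -> Verb, JJ* -> Adjective, RB* -> Adverb."""
    return tag.startswith(("VB", "JJ", "RB")) or tag == "MD"


# ---------------------------------------------------------------------------
# Lemmatisation
# ---------------------------------------------------------------------------

_IRREGULAR = {
    "is": "be", "are": "be", "am": "be", "was": "be", "were": "be",
    "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "doing": "do", "done": "do",
    "goes": "go", "going": "go", "went": "go", "gone": "go",
    "took": "take", "taken": "take", "gave": "give", "given": "give",
    "felt": "feel", "saw": "see", "seen": "see", "got": "get",
    "made": "make", "said": "say", "showed": "show", "shown": "show",
    "denied": "deny", "revealed": "reveal", "complained": "complain",
    "presented": "present", "admitted": "admit", "started": "start",
    "reported": "report",
    "men": "man", "women": "woman", "children": "child", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "diagnoses": "diagnosis",
    "analyses": "analysis",
}


def _strip_double_consonant(base: str) -> str:
    if (len(base) >= 2 and base[-1] == base[-2]
            and base[-1] not in VOWELS
            and base[-2:] not in ("ll", "ss", "ff", "zz")):
        return base[:-1]
    return base


def _ends_cvc(base: str) -> bool:
    """consonant-vowel-consonant ending (final consonant not w/x/y)."""
    if len(base) < 3:
        return False
    c2, v, c1 = base[-3], base[-2], base[-1]
    return (c1 not in VOWELS and c1 not in "wxy"
            and v in VOWELS and c2 not in VOWELS)


def _lemma_noun(low: str) -> str:
    if low.endswith("ies") and len(low) > 4:
        return low[:-3] + "y"
    if low.endswith("ves") and len(low) > 4:
        return low[:-3] + "f"
    if low.endswith(("ches", "shes", "xes", "zes", "sses")):
        return low[:-2]
    if low.endswith("s") and not low.endswith(("ss", "us", "is")) and len(low) > 3:
        return low[:-1]
    return low


def _lemma_verb(low: str) -> str:
    if low.endswith("ies") and len(low) > 4:
        return low[:-3] + "y"
    if low.endswith("ing") and len(low) > 5:
        base = low[:-3]
        base = _strip_double_consonant(base)
        if base == low[:-3] and _ends_cvc(base):
            base += "e"
        return base
    if low.endswith("ed") and len(low) > 3:
        base = low[:-2]
        stripped = _strip_double_consonant(base)
        if stripped != base:
            return stripped
        if _ends_cvc(base):
            return base + "e"
        return base
    if low.endswith(("ches", "shes", "xes", "zes", "sses", "oes")):
        return low[:-2]
    if low.endswith("s") and not low.endswith(("ss", "us", "is")) and len(low) > 3:
        return low[:-1]
    return low


def lemmatize_token(token: str, pos_tag: Optional[str] = None) -> str:
    """Lemma of ``token``; the lowercased token itself when no rule applies."""
    low = token.lower()
    if low in _IRREGULAR:
        return _IRREGULAR[low]
    if pos_tag is None:
        if low.endswith(("ing", "ed")):
            return _lemma_verb(low)
        return _lemma_noun(low)
    if pos_tag.startswith("V") or pos_tag == "MD":
        return _lemma_verb(low)
    if pos_tag.startswith("N"):
        return _lemma_noun(low)
    return low


def lemmatize_tokens(tokens: Sequence[str],
                     pos_tags: Optional[Sequence[str]] = None) -> list[str]:
    """Lemmatise a parallel token/tag sequence (tags optional)."""
    if pos_tags is not None and len(pos_tags) != len(tokens):
        raise ValueError("tokens and pos_tags must have the same length")
    if pos_tags is None:
        return [lemmatize_token(t) for t in tokens]
    return [lemmatize_token(t, p) for t, p in zip(tokens, pos_tags)]
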