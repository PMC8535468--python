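# Methods

## Scope and model

`clinconcept` annotates unstructured clinical narratives with concept spans
of three categories — problem, treatment, test — using only rules and a
terminology knowledge base; nothing is trained. The pipeline has three
stages: candidate-phrase generation with word-boundary filtering, semantic
resolution against a Metathesaurus-style backend, and dictionary-based
majority voting. Its core assumptions are:

* clinical notes are line-oriented; a newline or sentence-final punctuation
  ends a sentence, and concept spans never cross lines;
* clinical concepts are contiguous token spans of at most four tokens;
* a span denotes a concept only if it contains a content token (not a
  stopword, not a verb/adjective/adverb), though it may contain interior
  stopwords ("a pelvic fracture");
* the knowledge base's concept order is meaningful (preference order), and
  the semantic types of a term's top-ranked concepts are a usable proxy for
  its clinical category.

## Preprocessing decisions

**Tokenisation.** A deterministic regex tokeniser: words with internal
`./-/'` stay whole (`q.d.`, `mg/dL`, `3.5`), all other punctuation becomes
its own token. Behaviour on clinical abbreviations is underdetermined in
general; keeping them whole was chosen because dose/frequency tokens should
neither split concepts nor end sentences mid-line.

**POS tagging and lemmatisation.** Both are deterministic rule systems: a
closed-class lexicon plus suffix heuristics for tagging (Penn Treebank tags;
unknown words default to `NN`), and a suffix-rule lemmatiser with a small
irregular table. The noun default deliberately over-retains candidates —
the knowledge-base lookup is the precision filter — while the suffix rules
(`-ing`, `-ed`, `-ly`, adjectival endings) supply the verb/adjective/adverb
signal that boundary filtering needs. The lemmatiser is heuristic
(`caring → care`, `arteries → artery`); lookups try the surface form first
and the lemma second, so an imperfect lemma can only add, never lose, a
match. Tokens are lemmatised once, before n-gramming, and candidates carry
both forms.

**Boundary filtering.** Implemented exactly as the disqualified-token count:
a candidate survives iff some token is neither a stopword nor tagged
verb/adjective/adverb. Note one corner this implies: "good effect" survives
(noun head "effect") even though a prose reading of the procedure would
discard it; the algorithmic formulation is taken as normative. Candidates
containing standalone punctuation tokens are dropped outright — an own
design choice that keeps every emitted span aligned with exactly the words
that matched (otherwise "aspirin ." would carry a span one token wider than
its match). The stopword list is a frozen copy of a standard English list,
shipped as package data so results cannot drift with toolkit versions.

**Duplicate removal** keys on the normalised phrase (lowercased,
whitespace-collapsed, punctuation-edge-stripped) and keeps the first
occurrence. Because n-grams are enumerated shortest-first, the survivor of
a tie is the tightest span.

## Knowledge backends

The backend contract is three lookups (term → concepts, CUI → semantic
types, TUI → semantic group) plus approximate retrieval. The default
implementation is an in-memory JSON fixture; a UTS-style REST client is
provided for users with a full Metathesaurus deployment (it cannot
enumerate entries, so approximate retrieval degrades to exact-only there).

**Approximate similarity** is Jaccard over character trigrams of the
lowercased, space-padded strings. It is symmetric, bounded in [0, 1],
order-free and needs no indexing at fixture scale. The threshold is
confined to [0.6, 1.0] — the range in which approximate dictionary
retrieval of medical concepts is commonly operated — with default 0.7. At
0.7 a single-character typo is recoverable only for strings of roughly 15+
characters (a substitution perturbs up to three trigrams); this is the
expected precision/recall dial, not a defect.

**Hybrid matching** tries exact lookup for every phrase, then approximate
retrieval over the remainder, and returns the union; each candidate phrase
is matched independently. `concept_limit` (default 8) caps how many
concepts per term enter the vote.

## Voting and tie-breaks

Semantic-type names are matched case-insensitively against three disjoint
dictionaries (12 problem, 9 treatment, 7 test entries by default,
user-overridable); unlisted names label NONE and are stripped before
counting. The winner is the count argmax. The tie-break rules are
positional: the tied class whose label occurs earliest in the flattened
semantic-type sequence wins (both a three-way and a two-way tie reduce to
this). An alternative reading — a fixed class precedence problem >
treatment > test — exists, but both published walk-throughs (a 2-2-2 tie
resolving to Test because "Clinical Attribute" leads the sequence, and a
4-4-0 tie resolving to Problem because "Finding" leads) are consistent only
with the positional reading, so that is what is implemented. The flattened
sequence order (concept preference order, then within-concept order) is
therefore part of the contract and is never sorted.

**Overlap resolution.** Nested and overlapping classified spans are
resolved by (1) match quality — exact dictionary hits outrank approximate
ones, and higher similarity outranks lower among approximate hits — then
(2) span length, then (3) left position. Pure length-first ranking was
tried and rejected: an approximate hit on a superstring (e.g. "coronary
artery disease now", which clears the 0.7 threshold against the dictionary
term) would swallow the exact hit nested inside it and shift the emitted
span. Preferring composite concepts is retained among matches of equal
quality.

## Evaluation conventions

Matching between predicted and gold spans is one-to-one and greedy
left-to-right, either exact (identical span and category) or overlap (same
line, intersecting ranges, same category); exact is the default because it
is the stricter protocol. Zero denominators follow the usual conventions
(precision/recall 0, F1 0); sensitivity with no relevant spans raises
instead, since silently reporting 0 would be misleading. Report
percentages are rounded half-up to two decimals. Published figures in this
area are not always rounded consistently (e.g. a truncated 97.14 where
817/841 rounds to 97.15); the package standardises on half-up rounding and
reports computed values. Spans use the i2b2-2010 convention: 1-based lines,
0-based inclusive token offsets.

Boundary sensitivity counts gold concept spans exactly covered by some
retained candidate phrase, i.e. it measures the boundary stage alone,
before any knowledge-base lookup.

## Synthetic data

The fixture knowledge base reproduces the published worked-example records
verbatim — the seven-type "beta blockers" breakdown, the six-type "heart
rate" breakdown, the ten-entry "increased heart rate" breakdown with its
two out-of-dictionary NONE entries (stored literally under the reserved
TUI T000), the four-concept "stress" case study including the two-type
bismuth concept, and the coronary-artery-disease / trout / Living-Beings
lookups — plus nine ordinary clinical vocabulary terms for corpus
generation. One deliberate faithfulness wrinkle: the bismuth concept's
second type is stored as "Pharmacological Substance" (as the case study
prints it), which is not the dictionary entry "Pharmacologic Substance"
and therefore votes NONE; "stress" still classifies as a problem (2-1-1).

The corpus generator plants vocabulary phrases inside distractor sentences
built exclusively from stopwords and verb/adjective/adverb forms, validated
at generation time (every distractor token must be non-content and
dissimilar from every KB term at the 0.6 level). Gold categories are
derived by running the vote on each phrase's breakdown, never hand-set. No
planted phrase may nest inside another in the same document. Under these
conditions the pipeline must recover exactly the planted annotations
(precision = recall = 1.0 under exact matching), which is the end-to-end
smoke test. Default scale is 3 documents × 5 concepts, regenerable
byte-identically from a seed; class imbalance and single-character typo
injection (to exercise approximate matching against a similarity oracle)
are options. Typos are only injected into phrases ≥ 12 characters with no
other KB term nested inside, because an exact sub-term hit would otherwise
legitimately outrank the approximate full-phrase hit.

What the generator does **not** emulate: real clinical language
(abbreviations, negation, misspellings beyond injected typos, section
headers), ambiguous phrase boundaries, knowledge-base noise (near-duplicate
terms, inconsistent naming across vocabularies) and corpus-scale class
distributions. Passing the self-consistency suite therefore demonstrates
the pipeline's internal correctness — boundary logic, resolution chain,
vote arithmetic, span bookkeeping — not expected performance on real
notes, which is dominated by knowledge-base coverage.

## Numerical and degenerate-input choices

* Thresholds outside [0.6, 1.0], non-positive n-gram sizes, negative
  counts, overlapping dictionaries and malformed knowledge bases or `.con`
  lines raise immediately with the offending value in the message.
* Unknown terms/CUIs return empty results (not errors); unknown TUIs return
  a sentinel Unknown group; remote I/O failures raise a distinct
  `BackendError` so outage is never mistaken for "no match".
* Approximate-candidate ordering is score-descending with lexicographic
  tie-break, making every result list fully deterministic.
* All randomness (corpus generation, tests) flows from explicit seeds.

## Known limitations

* The POS tagger and lemmatiser are heuristic; unusual inflections can
  mis-tag, which may admit junk candidates (harmless — they fail KB lookup)
  or, rarely, suppress a candidate whose every token looks like a
  verb/adjective/adverb.
* Approximate matching is phrase-local; it cannot recover typos in short
  words at the default threshold (see above).
* One annotation per normalised phrase per document: repeated mentions
  collapse to the first occurrence, which suits annotation bootstrapping
  but not mention-level frequency analysis.
* No negation/assertion handling, no abbreviation expansion, no
  relation extraction; multi-line spans are not supported in `.con` I/O.
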