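# clinconcept

Rule-based extraction and classification of clinical concepts — **problems**,
**treatments** and **tests** — from unstructured narrative notes such as
discharge summaries, using a Metathesaurus-style terminology backend.

Annotating clinical text by hand is the bottleneck for training supervised
concept extractors. `clinconcept` implements a transparent, fully rule-based
pipeline that produces such annotations automatically: it proposes candidate
phrases, resolves them to standard concepts and semantic types in a
UMLS-Metathesaurus-style knowledge base, and classifies each phrase by
majority voting over semantic-type dictionaries. It is aimed at clinical NLP
practitioners who need reproducible silver-standard annotations in the
i2b2-2010 `.con` format, or a reference implementation of dictionary-vote
concept classification to compare against.

## Method

For a document with words `W = {w_1, …, w_n}`:

1. **Preprocessing.** Tokenise line by line, lemmatise, POS-tag, and
   enumerate contiguous n-grams (n = 1..4), since clinical concepts are often
   compound ("overall left ventricular systolic function"). Duplicate
   phrases are removed; the unigram bag is restricted to the POS pattern
   `<NN*> <JJ*> <RB*>`.
2. **Word-boundary identification.** A candidate phrase survives iff at
   least one of its tokens is neither a stopword nor tagged verb/adjective/
   adverb. "a pelvic fracture" survives (noun head), "is the" and
   "did have of" do not.
3. **Semantic breakdown.** Each surviving phrase is matched to the knowledge
   base — exact lookup first, then approximate matching (character-trigram
   Jaccard similarity, threshold in [0.6, 1.0], default 0.7) for the
   remainder; the union of both result lists is kept. For each matched term
   the first `k = 8` concepts are retrieved, each carrying 1–5 semantic
   types (TUIs) and, per semantic type, one semantic group ("entity type").
4. **Majority voting.** Every semantic-type name is looked up in three
   disjoint dictionaries (PRB, TRT, TST); unlisted types label as NONE and
   are stripped. The category is

   `T = argmax_c Σ_i [label_i = c]`

   with three tie-break rules: a unique maximum wins (Rule 1); a three-way
   tie goes to the class occurring first in the label sequence (Rule 2); a
   two-way tie ignores the third class and goes to the earlier-occurring of
   the tied pair (Rule 3). Overlapping classified spans are resolved in
   favour of exact (over approximate) matches, then longer, then leftmost
   spans.
5. **Evaluation.** Span-level precision, recall and F1 (exact or overlap
   matching), macro averages `fP = (1/N) Σ TP_i/TI_i`,
   `fR = (1/N) Σ TP_i/TT_i`, and boundary sensitivity `TP/(TP+FN)`.

The full UMLS and the i2b2-2010 corpora are license-restricted, so the
package ships a generator for a miniature fixture knowledge base and
synthetic annotated notes (see `clinconcept.fixtures`); a client for a
UTS-style terminology REST service is included for users with Metathesaurus
access.

## Worked example

```python
import clinconcept as cc

be = cc.paper_fixture_backend()
rec = cc.extract_terms(["beta blockers"], be)[0]
ann = cc.classify_term(rec)
print(rec.flat_semantic_type_names())
print(ann.vote.counts, ann.vote.rule_applied, ann.category)
```

prints

```
['Pharmacologic Substance', 'Organic Chemical', 'Pathologic Function', 'Organic Chemical', 'Clinical Attribute', 'Injury or Poisoning', 'Pharmacologic Substance']
{'Problem': 2, 'Treatment': 4, 'Test': 1} rule1 treatment
```

The seven semantic types attached to the term's concepts map to 4 Treatment,
2 Problem and 1 Test votes; the unique maximum (Rule 1) classifies
"beta blockers" as a treatment.

The same flow from the shell, on a generated corpus:

```sh
clinconcept fixtures --seed 1 --out corpus/
clinconcept classify --input corpus/doc_001.txt --kb corpus/fixture_kb.json --out pred.con
clinconcept evaluate --pred pred.con --gold corpus/doc_001.con
# precision=100.0% recall=100.0% f1=100.0%  (exact matching)
```

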