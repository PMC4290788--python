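# Methods

## Scoring model

A document is a title plus an ordered list of abstract sentences. The
classifier is a weighted keyword-co-occurrence model with no learned
parameters; machine-learned classification was deliberately avoided
because per-subtype labelled data is scarce.

**Keyword decomposition.** Each subtype name dissociates into a subtype
keyword (SK), an anatomy keyword (AK) and a malignancy keyword (MK),
held in three lists with surface variants mapped to canonical forms
(`anaplastic`, `undifferentiated`, `un-differentiated` → ATC). The
builtin lexicon carries the variants of the four subtype adjectives,
two anatomy words and the common malignancy nouns including plural
forms. Matching is exact, case-insensitive, on word boundaries, with
hyphens treated as boundaries; multi-word variants match contiguous
token sequences. There is no stemming, fuzzy matching or abbreviation
expansion: anything not in the lexicon does not match, and users can
supply their own lexicon file (`[SK]`/`[AK]`/`[MK]` sections).

**Sentence relevance.** Per sentence and per subtype whose SK matched:
1 with both AK and MK present, 0.5 with exactly one, 0.25 with neither.
One score per subtype per sentence, regardless of how many times the SK
occurs — the rules are phrased per sentence, and accumulating repeats
would double-count rhetorical repetition. Sentence-level values are
therefore always in {0, 0.25, 0.5, 1}.

**Positional weights.** Title 4, first/last sentence 2,
second/penultimate 1, others 0.5. In short abstracts the categories
overlap (a single sentence is both first and last); the maximum
applicable weight is taken, which preserves "important positions weigh
more" without double counting. The title is not counted among the
sentence ordinals; it has its own weight. Titles are never
sentence-split.

**Thresholding.** Subtype *j* is labelled when its component is ≥ an
absolute threshold (default 1.0 for all subtypes) **and** its share of
the vector total is ≥ a share threshold (default 0.30 for PTC, 0.20 for
the others; PTC is held to a higher share because it dominates the
subtype literature and would otherwise piggy-back on mixed-signal
documents). With the default constants, absolute 1.0 means roughly "at
least a full-name mention in a prominent sentence, or a partial mention
in the title". Documents with no label fall back to `TC` if they showed
any thyroid-cancer signal — an SK hit anywhere, or AK and MK
co-occurring in one sentence ("thyroid cancer" with no subtype) — and
to `NON` otherwise. All thresholds and weights are configurable
(`ScoringConfig`, `key=value` config files); classification output
records the configuration and the sentence-splitter identity, since
sentence positions affect scores.

Scores are exact sums of dyadic/quarter constants; nothing is rounded
until serialization (4 decimal places in classification TSVs, 3 in
evaluation reports).

**Baseline.** The comparison classifier labels a document only when a
full subtype name — every SK × AK × MK combination in the orders
"SK AK MK", "AK SK MK" and "SK MK of the AK" — occurs verbatim in the
title or abstract. It has no scores and no `TC` refinement; it exists
to quantify what the decomposition buys on abbreviated mentions.

## Association

For entity *E*, *S_E* is the component-wise sum of the score vectors of
the distinct documents mentioning *E*: a document contributes once per
entity however many times it mentions it, because the aggregation is
defined over documents, not mentions. The ranked list *L_j* keeps
entities with ≥ 1 document labelled *j*, sorted by *S_Ej* descending;
ties break by document count descending, then entity id ascending —
the tie-break is a package choice made purely for determinism. No
document-frequency filter is applied: singly-mentioned entities can be
biologically relevant. Gene and pathway entities run through the same
machinery, distinguished by `entity_kind`; merging of overlapping NER
outputs is expected to have happened upstream of the mention table.

## Evaluation

One-vs-rest per subtype over the gold pmids (documents predicted but
absent from gold are ignored; gold documents without predictions count
as all-negative; `TC`/`NON` count as negative for every subtype).
Multi-label documents contribute to each of their subtypes separately.
P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R), with 0/0 defined as 0
(the convention only matters for degenerate fixtures). Micro-averaging
pools counts before the ratios. The optional FTC-reassignment mode adds
FTC to the gold labels of a caller-supplied pmid list before scoring;
this reproduces the adjusted analysis for differentiated-thyroid-cancer
articles that gold standards tend to annotate as PTC only. DTC-ness is
not inferred automatically — it is not decidable from the data the
package sees.

## Sentence splitting

A rule-based splitter: break after `.`/`!`/`?` + whitespace when the
next character is an uppercase letter or digit, unless the preceding
token is a known abbreviation ("et al.", "e.g.", "Fig.") or an
uppercase single-letter initial ("B. Smith"). Identified as
`thyroscore-rule-splitter/1` in output metadata. It is intentionally
conservative; mis-merged sentences shift positional weights slightly
but never lose text (splitting preserves every non-whitespace
character).

## Synthetic data

The generator emulates the structure of a subtype-annotated abstract
corpus: each document draws a category from a mixture over
{PTC, ATC, FTC, MTC, TC-only, NON}, defaulting to the published
corpus-level proportions (0.29 / 0.05 / 0.17 / 0.12 / 0.14 / 0.23).
Subtype documents get one planted mention: full name
("papillary thyroid carcinoma") or, with probability
`abbreviation_rate` (default 0.3, reflecting how often the literature
abbreviates), a partial form ("papillary cancer" or bare "papillary"),
placed per `position_profile` (default 0.50 title / 0.20 first /
0.15 last / 0.15 middle — articles usually name their topic up front).
Filler sentences use vocabulary disjoint from the lexicon, so planted
relevance is exactly computable. Gene mentions are planted per-entity
Bernoulli with probability `mention_rate × affinity(subtype)`; the
default catalogue has one subtype-exclusive marker gene per subtype
(BRAF/PTC, TP53/ATC, PAX8/FTC, CALCA/MTC) plus two shared genes (TG,
RET), so association recovery has a known right answer. One global seed
drives everything, with per-document substreams, making output
byte-identical across runs.

What the generator does **not** emulate: real linguistic variation,
subtype-name variants beyond the lexicon ("follicular variant of PTC"
— which the real method is known to misclassify as FTC), NER errors
other than omission, multi-subtype documents, and correlated topic
drift. Passing tests on synthetic corpora therefore demonstrate the
scoring/association machinery is implemented correctly, not that the
published corpus-level performance transfers.

`oracle_score` re-derives the document score by naive enumeration, in
code kept independent of the production scorer; the suite checks
equivalence on 1000 generated documents, which is the core correctness
argument for the scorer.

## Problem sizes in the test suite

Deterministic worked examples run on single documents. Stochastic
properties use fixed seeds with 200 documents (label recovery),
400 (scorer-vs-baseline recall, sized so per-subtype recall comparisons
are not dominated by small-count noise in the rarest subtype),
300 (association recovery) and 1000 (oracle equivalence). These sizes
were chosen once, from the variance considerations above.

## Known limitations

- The builtin lexicon covers the variants named in the method's
  description but is likely narrower than the original additional-file
  lists; recall on real text depends on lexicon completeness.
- Thresholds are package defaults; the original threshold values were
  never published, only that PTC's share threshold was slightly higher.
- Abstracts only; mentions whose subtype context lives in the full text
  score low by construction.
- "Follicular variant of papillary carcinoma" scores FTC — a known,
  accepted failure mode of keyword decomposition.
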