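"""Sentence relevance, positional weighting, document scoring and labelling.

The classifier assigns each abstract a four-component score vector
``S_i = <S_iP, S_iA, S_iF, S_iM>`` (PTC, ATC, FTC, MTC) and derives
subtype labels by thresholding.  Three rules drive the score:

1. *Sentence relevance.*  Within one sentence, a subtype keyword (SK)
   scores 1 for its subtype when it co-occurs with both an anatomy
   keyword (AK) and a malignancy keyword (MK); 0.5 when it co-occurs
   with exactly one of them; 0.25 when it appears alone.  This lets
   partial names like "papillary cancer" or a bare "medullary" still
   contribute, at reduced strength.

2. *Positional weighting.*  The title carries weight 4; the first and
   last abstract sentences weight 2; the second and penultimate weight
   1; all other sentences weight 0.5, which damps passing mentions of
   subtypes that are not the article's topic.

3. *Accumulation and thresholding.*  The document vector is the
   weight-by-relevance sum over the title and all sentences.  A subtype
   label is assigned when its component clears both an absolute minimum
   and a minimum share of the vector total; documents clearing neither
   are labelled ``TC`` (on-topic, no subtype focus) or ``NON``
   (unrelated to thyroid cancer).

A full-name-only baseline classifier is included for comparison: it
labels a document only when an assembled full subtype name occurs
verbatim, and is blind to abbreviated mentions by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from .errors import ValidationError
from .lexicon import SUBTYPES, KeywordMatches, SubtypeLexicon, _variant_pattern, match_sentence

if TYPE_CHECKING:  # pragma: no cover
    from .corpus import Document

logger = logging.getLogger(__name__)

#: Sentinel accepted by :func:`positional_weight` for the title position.
TITLE = "TITLE"

_COMPONENT = {"PTC": "s_p", "ATC": "s_a", "FTC": "s_f", "MTC": "s_m"}


@dataclass(frozen=True)
class ScoreVector:
    """Four non-negative subtype scores ``<S_P, S_A, S_F, S_M>``."""

    s_p: float = 0.0
    s_a: float = 0.0
    s_f: float = 0.0
    s_m: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_tuple()):
            raise ValidationError(f"negative score component in {self}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.s_p, self.s_a, self.s_f, self.s_m)

    def get(self, subtype: str) -> float:
        try:
            return getattr(self, _COMPONENT[subtype])
        except KeyError:
            raise ValidationError(f"unknown subtype code {subtype!r}") from None

    def total(self) -> float:
        return sum(self.as_tuple())

    def __add__(self, other: "ScoreVector") -> "ScoreVector":
        return ScoreVector(*(a + b for a, b in zip(self.as_tuple(), other.as_tuple())))

    def scaled(self, w: float) -> "ScoreVector":
        return ScoreVector(*(w * v for v in self.as_tuple()))


ZERO = ScoreVector()


def _default_min_score() -> dict[str, float]:
    return {s: 1.0 for s in SUBTYPES}


def _default_min_share() -> dict[str, float]:
    # PTC dominates the literature (over half of subtype articles), so its
    # share threshold sits slightly above the others.
    return {"PTC": 0.30, "ATC": 0.20, "FTC": 0.20, "MTC": 0.20}


@dataclass(frozen=True)
class ScoringConfig:
    """All tunable constants of the scorer and classifier.

    Relevance values and positional weights default to the canonical
    scheme (1/0.5/0.25 and 4/2/1/0.5).  Thresholds: a subtype label
    requires component ``>= min_score[j]`` and component share of the
    vector total ``>= min_share[j]``.
    """

    weight_title: float = 4.0
    weight_first_last: float = 2.0
    weight_second_penult: float = 1.0
    weight_other: float = 0.5
    relevance_full: float = 1.0
    relevance_partial: float = 0.5
    relevance_alone: float = 0.25
    min_score: Mapping[str, float] = field(default_factory=_default_min_score)
    min_share: Mapping[str, float] = field(default_factory=_default_min_share)

    def __post_init__(self) -> None:
        numeric = (
            self.weight_title, self.weight_first_last, self.weight_second_penult,
            self.weight_other, self.relevance_full, self.relevance_partial,
            self.relevance_alone,
        )
        if any(v < 0 for v in numeric):
            raise ValidationError("weights and relevance values must be >= 0")
        for j in SUBTYPES:
            if self.min_score.get(j, 0) < 0:
                raise ValidationError(f"min_score[{j}] must be >= 0")
            if not 0 <= self.min_share.get(j, 0) <= 1:
                raise ValidationError(f"min_share[{j}] must be in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoringConfig":
        """Read a ``key=value`` config file.

        Scalar keys match the field names; thresholds use dotted keys,
        e.g. ``min_share.PTC=0.35``.  Unknown keys raise
        :class:`ValidationError`.
        """
        cfg = cls()
        scalars: dict[str, float] = {}
        min_score = dict(cfg.min_score)
        min_share = dict(cfg.min_share)
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key=value")
            key, value = (part.strip() for part in line.split("=", 1))
            try:
                num = float(value)
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-numeric value {value!r}")
            if key.startswith("min_score."):
                min_score[key.split(".", 1)[1]] = num
            elif key.startswith("min_share."):
                min_share[key.split(".", 1)[1]] = num
            elif hasattr(cfg, key) and not key.startswith("min_"):
                scalars[key] = num
            else:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
        return replace(cfg, min_score=min_score, min_share=min_share, **scalars)


DEFAULT_CONFIG = ScoringConfig()


@dataclass(frozen=True)
class ClassifiedDocument:
    """A document together with its score vector and assigned labels."""

    document: "Document"
    scores: ScoreVector
    labels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("labels must be non-empty")
        special = self.labels & {"TC", "NON"}
        if special and len(self.labels) > 1:
            raise ValidationError(f"{sorted(special)} cannot co-occur with other labels")


def sentence_relevance(matches: KeywordMatches,
                       config: ScoringConfig = DEFAULT_CONFIG) -> ScoreVector:
    """Relevance vector of one sentence from its keyword matches.

    Each subtype whose SK matched scores ``relevance_full`` if both AK
    and MK are present, ``relevance_partial`` if exactly one is, and
    ``relevance_alone`` if neither — once per subtype regardless of how
    often the SK occurs.  Subtypes without an SK hit score 0.
    """
    if matches.ak_present and matches.mk_present:
        value = config.relevance_full
    elif matches.ak_present or matches.mk_present:
        value = config.relevance_partial
    else:
        value = config.relevance_alone
    return ScoreVector(**{
        _COMPONENT[j]: (value if j in matches.sk_present else 0.0)
        for j in SUBTYPES
    })


def positional_weight(index: int | str, n_sentences: int,
                      config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Weight of the sentence at ``index`` (0-based) in an ``n_sentences``
    abstract, or of the title when ``index`` is :data:`TITLE`.

    Short abstracts make position categories overlap (in a one-sentence
    abstract the sentence is both first and last); the maximum applicable
    weight is used.
    """
    if index == TITLE:
        return config.weight_title
    if not isinstance(index, int) or not 0 <= index < n_sentences:
        raise ValidationError(
            f"sentence index {index!r} out of range for {n_sentences} sentences"
        )
    weights = [config.weight_other]
    if index in (0, n_sentences - 1):
        weights.append(config.weight_first_last)
    if index in (1, n_sentences - 2):
        weights.append(config.weight_second_penult)
    return max(weights)


def _match_profile(document: "Document", lexicon: SubtypeLexicon):
    """Per-position keyword matches: [(position, matches), ...]."""
    profile = [(TITLE, match_sentence(document.title, lexicon))]
    for i, sentence in enumerate(document.sentences):
        profile.append((i, match_sentence(sentence, lexicon)))
    return profile


def score_document(document: "Document", lexicon: SubtypeLexicon,
                   config: ScoringConfig = DEFAULT_CONFIG) -> ScoreVector:
    """Weighted accumulation of sentence relevance over title + abstract.

    ``S_i = w_title * rel(title) + sum_k w(k) * rel(sentence_k)``.
    Title-only documents use only the title term.
    """
    n = len(document.sentences)
    total = ZERO
    for position, matches in _match_profile(document, lexicon):
        rel = sentence_relevance(matches, config)
        total = total + rel.scaled(positional_weight(position, n, config))
    return total


def classify(scores: ScoreVector, config: ScoringConfig = DEFAULT_CONFIG,
             any_tc_relevance: bool = False) -> frozenset[str]:
    """Threshold a document score vector into labels.

    Subtype ``j`` is assigned when ``scores[j] >= min_score[j]`` and
    ``scores[j] / total >= min_share[j]``.  An empty label set falls back
    to ``{"TC"}`` when the document showed any thyroid-cancer relevance
    (``any_tc_relevance``) and to ``{"NON"}`` otherwise.
    """
    total = scores.total()
    labels = frozenset(
        j for j in SUBTYPES
        if scores.get(j) >= config.min_score.get(j, 0.0)
        and total > 0
        and scores.get(j) / total >= config.min_share.get(j, 0.0)
    )
    if labels:
        return labels
    return frozenset({"TC"}) if any_tc_relevance else frozenset({"NON"})


def classify_document(document: "Document", lexicon: SubtypeLexicon,
                      config: ScoringConfig = DEFAULT_CONFIG) -> ClassifiedDocument:
    """Score one document and assign labels.

    A document counts as thyroid-cancer-relevant (for the TC/NON
    fallback) when any sentence or the title has an SK hit, or has AK
    and MK co-occurring without any SK ("thyroid cancer" alone).
    """
    n = len(document.sentences)
    total = ZERO
    any_tc = False
    for position, matches in _match_profile(document, lexicon):
        rel = sentence_relevance(matches, config)
        total = total + rel.scaled(positional_weight(position, n, config))
        if matches.sk_present or (matches.ak_present and matches.mk_present):
            any_tc = True
    return ClassifiedDocument(document, total, classify(total, config, any_tc))


def classify_corpus(documents: Iterable["Document"], lexicon: SubtypeLexicon,
                    config: ScoringConfig = DEFAULT_CONFIG,
                    log_every: int = 1000) -> list[ClassifiedDocument]:
    """Classify a whole corpus, logging progress every ``log_every`` docs."""
    results = []
    for i, doc in enumerate(documents, start=1):
        results.append(classify_document(doc, lexicon, config))
        if log_every and i % log_every == 0:
            logger.info("classified %d documents", i)
    return results


# ---------------------------------------------------------------------------
# Full-name baseline
# ---------------------------------------------------------------------------

_FULLNAME_TEMPLATES = (
    "{sk} {ak} {mk}",          # papillary thyroid cancer
    "{ak} {sk} {mk}",          # thyroid papillary carcinoma
    "{sk} {mk} of the {ak}",   # papillary carcinoma of the thyroid
)


def _fullname_patterns(lexicon: SubtypeLexicon):
    patterns = {}
    for j in lexicon.subtypes:
        pats = []
        for sk in sorted(lexicon.subtype_keywords.get(j, ())):
            for ak in sorted(lexicon.anatomy_keywords):
                for mk in sorted(lexicon.malignancy_keywords):
                    for tmpl in _FULLNAME_TEMPLATES:
                        phrase = tmpl.format(sk=sk, ak=ak, mk=mk)
                        pats.append(_variant_pattern(phrase))
        patterns[j] = pats
    return patterns


def baseline_classify(document: "Document",
                      lexicon: SubtypeLexicon) -> frozenset[str]:
    """Label a document only on verbatim full subtype names.

    Full names are assembled from every SK x AK x MK variant combination
    in the standard orders ("papillary thyroid cancer", "thyroid
    papillary carcinoma", "papillary carcinoma of the thyroid") and
    matched in the title and abstract.  Documents with no full-name hit
    are labelled ``NON``; there is no score and no ``TC`` refinement.
    """
    text = document.title + " " + " ".join(document.sentences)
    labels = frozenset(
        j for j, pats in _fullname_patterns(lexicon).items()
        if any(p.search(text) for p in pats)
    )
    return labels if labels else frozenset({"NON"})
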