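"""Synthetic corpora with planted subtype mentions and entity co-mentions.

Every pipeline stage can be exercised without downloading anything:
the generator assembles abstracts from neutral filler sentences whose
vocabulary is disjoint from the subtype lexicon, plants full or
abbreviated subtype names at controlled positions, records the planted
subtypes as gold labels, and plants gene mentions according to
per-subtype affinity weights.  Expected document score vectors are
computed by :func:`oracle_score`, a deliberately naive re-derivation of
the scoring rules kept separate from the production scorer so the two
can check each other.

Defaults mirror the make-up of the real thyroid-cancer literature: the
subtype mixture follows the published corpus proportions (papillary
dominant, anaplastic rare), about 30% of planted mentions are
abbreviated, and planted names usually sit in the title or the opening
sentence, where an article states its topic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import Document, EntityMention
from .errors import ValidationError
from .lexicon import SUBTYPES, SubtypeLexicon
from .scoring import ScoreVector, ScoringConfig, DEFAULT_CONFIG

_CATEGORIES = ("PTC", "ATC", "FTC", "MTC", "TC", "NON")
_POSITIONS = ("title", "first", "last", "middle")

#: Adjective used to plant each subtype (the canonical SK surface form).
_SK_SURFACE = {"PTC": "papillary", "ATC": "anaplastic",
               "FTC": "follicular", "MTC": "medullary"}

# Filler sentences: vocabulary strictly disjoint from the builtin lexicon
# (no subtype/anatomy/malignancy words), so they contribute exactly zero.
_FILLERS = (
    "The cohort included ninety consecutive patients.",
    "Samples were processed following standard protocols.",
    "Clinical records were reviewed retrospectively.",
    "Sequencing libraries were prepared in duplicate.",
    "Statistical analyses used mixed-effects models.",
    "Follow-up visits occurred every six months.",
    "Imaging was performed at baseline and at one year.",
    "Ethical approval was obtained from the review board.",
    "Demographic characteristics were balanced across groups.",
    "Results were validated in an independent series.",
)

_FILLER_TITLES = (
    "A multicentre observational cohort study.",
    "Molecular correlates of treatment response.",
    "Longitudinal outcomes in a regional registry.",
    "Genomic landscape of an endocrine case series.",
)


@dataclass(frozen=True)
class EntitySpec:
    """A catalogue entry: identifier, surface form and subtype affinities.

    ``affinity`` weights lie in [0, 1]; an entity is planted in a
    document of subtype j with probability ``mention_rate * affinity[j]``.
    """

    entity_id: str
    surface: str
    affinity: Mapping[str, float]
    entity_kind: str = "gene"


#: Default catalogue: one subtype-exclusive gene per subtype plus two
#: shared genes, echoing well-known thyroid-cancer markers.
DEFAULT_ENTITIES: tuple[EntitySpec, ...] = (
    EntitySpec("673", "BRAF", {"PTC": 1.0}),
    EntitySpec("7157", "TP53", {"ATC": 1.0}),
    EntitySpec("7849", "PAX8", {"FTC": 1.0}),
    EntitySpec("796", "CALCA", {"MTC": 1.0}),
    EntitySpec("7038", "TG", {"PTC": 0.5, "ATC": 0.5, "FTC": 0.5, "MTC": 0.5}),
    EntitySpec("5979", "RET", {"PTC": 0.6, "MTC": 0.6}),
)


def _default_mixture() -> dict[str, float]:
    # Proportions follow the published corpus-level subtype distribution:
    # papillary ~29%, anaplastic ~5%, follicular ~17%, medullary ~12%,
    # plus on-topic-unfocused and unrelated remainders.
    return {"PTC": 0.29, "ATC": 0.05, "FTC": 0.17, "MTC": 0.12,
            "TC": 0.14, "NON": 0.23}


def _default_positions() -> dict[str, float]:
    return {"title": 0.50, "first": 0.20, "last": 0.15, "middle": 0.15}


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; all probability vectors must sum to 1."""

    n_docs: int = 200
    subtype_mixture: Mapping[str, float] = field(default_factory=_default_mixture)
    abbreviation_rate: float = 0.3
    position_profile: Mapping[str, float] = field(default_factory=_default_positions)
    entities: tuple[EntitySpec, ...] = DEFAULT_ENTITIES
    mention_rate: float = 0.7
    min_fillers: int = 4
    max_fillers: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise ValidationError("n_docs must be >= 0")
        for name, probs, keys in (
            ("subtype_mixture", self.subtype_mixture, _CATEGORIES),
            ("position_profile", self.position_profile, _POSITIONS),
        ):
            unknown = set(probs) - set(keys)
            if unknown:
                raise ValidationError(f"{name}: unknown keys {sorted(unknown)}")
            if any(p < 0 for p in probs.values()):
                raise ValidationError(f"{name}: negative probability")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1")
        if not 0 <= self.abbreviation_rate <= 1:
            raise ValidationError("abbreviation_rate must be in [0, 1]")
        if not 0 <= self.mention_rate <= 1:
            raise ValidationError("mention_rate must be in [0, 1]")
        if not 2 <= self.min_fillers <= self.max_fillers:
            raise ValidationError("need min_fillers >= 2 and <= max_fillers")


@dataclass(frozen=True)
class SynthCorpus:
    """Generator output bundle."""

    documents: tuple[Document, ...]
    gold: Mapping[str, frozenset[str]]          # subtype docs only
    expected_scores: Mapping[str, ScoreVector]  # every doc, via oracle_score
    mentions: tuple[EntityMention, ...]


def _choice(rng: np.random.Generator, probs: Mapping[str, float],
            keys: Sequence[str]) -> str:
    ordered = [k for k in keys if probs.get(k, 0) > 0]
    p = np.array([probs[k] for k in ordered], dtype=float)
    return ordered[rng.choice(len(ordered), p=p / p.sum())]


def _planted_phrase(subtype: str, abbreviated: bool,
                    rng: np.random.Generator) -> str:
    sk = _SK_SURFACE[subtype]
    if not abbreviated:
        return f"{sk} thyroid carcinoma"
    # Partial forms: "papillary cancer" (SK+MK) or bare "papillary".
    return f"{sk} cancer" if rng.random() < 0.5 else sk


def _build_document(pmid: str, category: str, rng: np.random.Generator,
                    config: SynthConfig) -> tuple[Document, list[tuple[EntitySpec, int]]]:
    """Assemble one document; returns it plus (entity, sentence-index) plants."""
    n_fill = int(rng.integers(config.min_fillers, config.max_fillers + 1))
    sentences = [str(rng.choice(_FILLERS)) for _ in range(n_fill)]
    title = str(rng.choice(_FILLER_TITLES))

    if category in SUBTYPES:
        position = _choice(rng, config.position_profile, _POSITIONS)
        abbreviated = bool(rng.random() < config.abbreviation_rate)
        phrase = _planted_phrase(category, abbreviated, rng)
        if position == "title":
            title = f"{phrase.capitalize()} in a regional cohort."
        elif position == "first":
            sentences[0] = f"{phrase.capitalize()} accounts for a large share of cases."
        elif position == "last":
            sentences[-1] = f"The findings clarify management of {phrase}."
        else:  # middle: strictly interior so first/last stay neutral
            mid = int(rng.integers(1, len(sentences) - 1))
            sentences[mid] = f"A subset of cases involved {phrase}."
    elif category == "TC":
        # Anatomy + malignancy without any subtype keyword.
        title = "Thyroid carcinoma outcomes in a national registry."

    # Entity mentions, planted as extra interior sentences.
    plants: list[tuple[EntitySpec, int]] = []
    if category in SUBTYPES:
        for spec in config.entities:
            p = config.mention_rate * spec.affinity.get(category, 0.0)
            if p > 0 and rng.random() < p:
                idx = int(rng.integers(1, len(sentences)))
                sentences.insert(idx, f"Expression of {spec.surface} was measured in the series.")
                plants.append((spec, idx))
                # keep earlier plants' indices valid
                plants = [(s, i if i < idx or s is spec else i + 1) for s, i in plants]
    return Document(pmid=pmid, title=title, sentences=tuple(sentences)), plants


def generate_corpus(config: SynthConfig = SynthConfig()) -> SynthCorpus:
    """Generate documents, gold labels, expected scores and mentions.

    Fully deterministic in ``config.seed``: every document draws from
    its own substream derived from the global seed and its index.
    """
    documents: list[Document] = []
    gold: dict[str, frozenset[str]] = {}
    expected: dict[str, ScoreVector] = {}
    mentions: list[EntityMention] = []
    from .lexicon import load_lexicon
    lexicon = load_lexicon()

    category_rng = np.random.default_rng([config.seed, 0])
    for i in range(config.n_docs):
        pmid = str(9_000_000 + i)
        rng = np.random.default_rng([config.seed, 1, i])
        category = _choice(category_rng, config.subtype_mixture, _CATEGORIES)
        doc, plants = _build_document(pmid, category, rng, config)
        documents.append(doc)
        if category in SUBTYPES:
            gold[pmid] = frozenset({category})
        expected[pmid] = oracle_score(doc, lexicon, DEFAULT_CONFIG)
        # Mention offsets in the "title + ' ' + abstract" frame.
        for spec, idx in plants:
            prefix = len(doc.title) + 1 + sum(len(s) + 1 for s in doc.sentences[:idx])
            start = prefix + doc.sentences[idx].index(spec.surface)
            mentions.append(EntityMention(
                pmid=pmid, entity_kind=spec.entity_kind, entity_id=spec.entity_id,
                start=start, end=start + len(spec.surface),
                surface=spec.surface, source="synthetic",
            ))
    return SynthCorpus(tuple(documents), gold, expected, tuple(mentions))


# ---------------------------------------------------------------------------
# Independent scoring oracle
# ---------------------------------------------------------------------------

def _oracle_hits(text: str, variants: Sequence[str]) -> bool:
    low = text.lower()
    for v in variants:
        # naive boundary check, re-derived from scratch: variant must not
        # be flanked by letters/digits; internal whitespace is flexible
        pat = r"(?<![a-z0-9])" + r"\s+".join(map(re.escape, v.split())) + r"(?![a-z0-9])"
        if re.search(pat, low):
            return True
    return False


def oracle_score(document: Document, lexicon: SubtypeLexicon,
                 config: ScoringConfig = DEFAULT_CONFIG) -> ScoreVector:
    """Naive re-computation of the document score vector.

    Enumerates title + sentences, re-derives per-sentence relevance from
    the three co-occurrence rules and per-position weights from first
    principles.  Intentionally simple and independent of
    :func:`thyroscore.scoring.score_document`; used as the test oracle.
    """
    n = len(document.sentences)
    units: list[tuple[str, float]] = [(document.title, config.weight_title)]
    for i, s in enumerate(document.sentences):
        applicable = [config.weight_other]
        if i == 0:
            applicable.append(config.weight_first_last)
        if i == n - 1:
            applicable.append(config.weight_first_last)
        if i == 1:
            applicable.append(config.weight_second_penult)
        if i == n - 2:
            applicable.append(config.weight_second_penult)
        units.append((s, max(applicable)))

    totals = dict.fromkeys(SUBTYPES, 0.0)
    ak_vars = sorted(lexicon.anatomy_keywords)
    mk_vars = sorted(lexicon.malignancy_keywords)
    for text, weight in units:
        ak = _oracle_hits(text, ak_vars)
        mk = _oracle_hits(text, mk_vars)
        for j in SUBTYPES:
            if not _oracle_hits(text, sorted(lexicon.subtype_keywords.get(j, ()))):
                continue
            if ak and mk:
                rel = config.relevance_full
            elif ak or mk:
                rel = config.relevance_partial
            else:
                rel = config.relevance_alone
            totals[j] += weight * rel
    return ScoreVector(totals["PTC"], totals["ATC"], totals["FTC"], totals["MTC"])
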