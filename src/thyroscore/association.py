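"""Entity–subtype association: relevancy vectors and ranked lists.

For each text-mined entity E (gene or pathway) the association step
collects the set of documents ``D_E`` that mention it, sums their
subtype score vectors into the relevancy vector
``S_E = sum_i S_i = <S_EP, S_EA, S_EF, S_EM>``, and, per subtype j,
ranks entities by ``S_Ej`` descending.  An entity enters the list
``L_j`` only if at least one of its documents was labelled j in the
classification stage.  No document-frequency filter is applied: even
singly-mentioned entities can be biologically relevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .lexicon import SUBTYPES
from .scoring import ZERO, ScoreVector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntityAssociation:
    """One entity with its document set D_E and relevancy vector S_E."""

    entity_id: str
    entity_kind: str
    doc_pmids: frozenset[str]
    relevancy: ScoreVector

    @property
    def n_docs(self) -> int:
        return len(self.doc_pmids)


@dataclass(frozen=True)
class RankEntry:
    rank: int
    entity_id: str
    score: float
    n_docs: int


@dataclass(frozen=True)
class RankedList:
    """Entities ranked for one subtype by S_Ej descending."""

    subtype: str
    entries: tuple[RankEntry, ...]

    def entity_ids(self) -> list[str]:
        return [e.entity_id for e in self.entries]


def build_associations(
    mentions: Iterable,
    scores: Mapping[str, ScoreVector],
) -> list[EntityAssociation]:
    """Aggregate mentions into one association per (entity_kind, entity_id).

    A document contributes its full score vector once per entity no
    matter how many times the entity is mentioned in it.  Mentions whose
    pmid has no score vector are skipped with a logged warning.  Output
    order is deterministic (sorted by kind, then id) and independent of
    mention order.
    """
    docs: dict[tuple[str, str], set[str]] = {}
    skipped: set[str] = set()
    for m in mentions:
        if m.pmid not in scores:
            if m.pmid not in skipped:
                logger.warning("mention pmid %s has no score vector; skipped", m.pmid)
                skipped.add(m.pmid)
            continue
        docs.setdefault((m.entity_kind, m.entity_id), set()).add(m.pmid)
    out = []
    for (kind, entity_id), pmids in sorted(docs.items()):
        vec = ZERO
        for pmid in sorted(pmids):  # fixed order => reproducible float sums
            vec = vec + scores[pmid]
        out.append(EntityAssociation(entity_id, kind, frozenset(pmids), vec))
    return out


def ranked_list(
    subtype: str,
    associations: Sequence[EntityAssociation],
    classifications: Mapping[str, frozenset[str]],
) -> RankedList:
    """Build ``L_j``: entities with >= 1 document labelled ``subtype``,
    sorted by ``S_Ej`` descending (ties: n_docs descending, then
    entity_id ascending)."""
    if subtype not in SUBTYPES:
        raise ValidationError(f"unknown subtype code {subtype!r}")
    eligible = [
        a for a in associations
        if any(subtype in classifications.get(pmid, frozenset())
               for pmid in a.doc_pmids)
    ]
    eligible.sort(key=lambda a: (-a.relevancy.get(subtype), -a.n_docs, a.entity_id))
    entries = tuple(
        RankEntry(rank, a.entity_id, a.relevancy.get(subtype), a.n_docs)
        for rank, a in enumerate(eligible, start=1)
    )
    return RankedList(subtype, entries)


@dataclass(frozen=True)
class OverlapTable:
    """Exclusive-region counts of the four subtype lists (Venn regions).

    ``region_counts`` maps each non-empty subtype combination (a
    frozenset of codes) to the number of entities belonging to exactly
    that combination; ``unique_fraction`` is, per subtype, the share of
    its list found in no other subtype's list.
    """

    region_counts: Mapping[frozenset[str], int]
    unique_fraction: Mapping[str, float]

    def rows(self) -> list[tuple[str, int]]:
        """Regions as ('PTC|FTC', count) rows in canonical order."""
        def key(combo: frozenset[str]):
            return (len(combo), [SUBTYPES.index(c) for c in SUBTYPES if c in combo])
        return [
            ("|".join(c for c in SUBTYPES if c in combo), n)
            for combo, n in sorted(self.region_counts.items(), key=lambda kv: key(kv[0]))
        ]


def overlap_stats(lists: Mapping[str, RankedList]) -> OverlapTable:
    """Overlap structure of the per-subtype entity lists.

    Expects one ranked list per subtype.  Returns counts for every
    subtype combination actually populated, plus per-subtype unique
    fractions (0.0 for an empty list).
    """
    missing = set(SUBTYPES) - set(lists)
    if missing:
        raise ValidationError(f"missing ranked lists for {sorted(missing)}")
    membership: dict[str, set[str]] = {}
    for j in SUBTYPES:
        for entity_id in lists[j].entity_ids():
            membership.setdefault(entity_id, set()).add(j)
    regions: dict[frozenset[str], int] = {}
    for combo in map(frozenset, membership.values()):
        regions[combo] = regions.get(combo, 0) + 1
    unique = {}
    for j in SUBTYPES:
        size = len(lists[j].entries)
        unique[j] = (regions.get(frozenset({j}), 0) / size) if size else 0.0
    return OverlapTable(regions, unique)
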