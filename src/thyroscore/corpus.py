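"""Corpus, gold-standard, entity-mention and classification-file I/O.

Corpora are sequences of abstract records (pmid, title, abstract) in
either MEDLINE flat-file format (``PMID-``/``TI  -``/``AB  -`` fields,
parsed with Bio.Medline) or JSON-lines.  Abstracts are split into
sentences with a small rule-based splitter; sentence positions matter
to the scorer, so the splitter identity is recorded in output metadata.

Entity-mention tables (the output of upstream gene/pathway NER) and
gold subtype labels are tab-separated text.  Mention offsets are
0-based half-open over the concatenation ``title + " " + abstract``.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Medline

from .errors import InputError, OutputError, ValidationError
from .lexicon import SUBTYPES
from .scoring import ClassifiedDocument, ScoreVector

logger = logging.getLogger(__name__)

#: Identity of the sentence splitter, recorded in classification output.
SPLITTER_ID = "thyroscore-rule-splitter/1"

#: Label vocabulary allowed in classification files.
LABEL_VOCAB = frozenset(SUBTYPES) | {"TC", "NON"}

GoldLabels = Mapping[str, frozenset[str]]


@dataclass(frozen=True)
class Document:
    """One abstract record: pmid, title and ordered abstract sentences."""

    pmid: str
    title: str
    sentences: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValidationError("Document pmid must be non-empty")

    @property
    def abstract_text(self) -> str:
        """The abstract reassembled with single spaces between sentences."""
        return " ".join(self.sentences)


@dataclass(frozen=True)
class EntityMention:
    """A normalized gene or pathway mention located in one document."""

    pmid: str
    entity_kind: str
    entity_id: str
    start: int
    end: int
    surface: str
    source: str

    def __post_init__(self) -> None:
        if self.entity_kind not in ("gene", "pathway"):
            raise ValidationError(f"unknown entity_kind {self.entity_kind!r}")
        if self.end <= self.start:
            raise ValidationError(
                f"bad offsets for {self.entity_id}: end {self.end} <= start {self.start}"
            )


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

# Tokens before a period that never end a sentence.
_ABBREVIATIONS = {
    "al", "e.g", "i.e", "cf", "vs", "etc", "fig", "figs", "ref", "refs",
    "dr", "prof", "mr", "mrs", "ms", "st", "no", "ca", "approx", "resp",
    "spp", "subsp", "var", "inc", "ltd",
}

_CANDIDATE = re.compile(r"([.!?]+)(\s+)")


def split_sentences(abstract: str) -> tuple[str, ...]:
    """Split an abstract into sentences.

    Splits after ``.``/``!``/``?`` followed by whitespace and an
    upper-case letter or digit, unless the preceding token is a known
    abbreviation or a single-letter initial.  The concatenation of the
    returned sentences preserves every non-whitespace character of the
    input; no empty sentences are returned.
    """
    if not abstract.strip():
        return ()
    breaks = []
    for m in _CANDIDATE.finditer(abstract):
        nxt = abstract[m.end():m.end() + 1]
        if not (nxt.isupper() or nxt.isdigit()):
            continue
        before = abstract[:m.start(1)]
        prev = before.rsplit(None, 1)[-1] if before.split() else ""
        prev = prev.strip("([{\"'")
        is_initial = len(prev) == 1 and prev.isalpha() and prev.isupper()
        if prev.lower() in _ABBREVIATIONS or is_initial:
            continue
        breaks.append(m.end())
    pieces, start = [], 0
    for b in breaks:
        pieces.append(abstract[start:b])
        start = b
    pieces.append(abstract[start:])
    return tuple(p.strip() for p in pieces if p.strip())


# ---------------------------------------------------------------------------
# Corpus reading / writing
# ---------------------------------------------------------------------------

def _iter_jsonl(path: Path) -> Iterable[Document]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise InputError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            pmid = str(rec.get("pmid", "") or "")
            if not pmid:
                logger.warning("%s:%d: record without pmid skipped", path, lineno)
                continue
            yield Document(
                pmid=pmid,
                title=str(rec.get("title", "") or ""),
                sentences=split_sentences(str(rec.get("abstract", "") or "")),
            )


def _iter_medline(path: Path) -> Iterable[Document]:
    with path.open(encoding="utf-8") as fh:
        for rec in Medline.parse(fh):
            pmid = rec.get("PMID", "")
            if not pmid:
                logger.warning("%s: MEDLINE record without PMID skipped", path)
                continue
            yield Document(
                pmid=pmid,
                title=rec.get("TI", ""),
                sentences=split_sentences(rec.get("AB", "")),
            )


def read_corpus(path: str | Path, format: str = "jsonl") -> list[Document]:
    """Read a corpus file in the given dialect (``medline`` or ``jsonl``).

    Records missing a PMID are skipped with a logged warning; abstracts
    are sentence-split on load.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"corpus file not found: {path}")
    if format == "jsonl":
        return list(_iter_jsonl(path))
    if format == "medline":
        return list(_iter_medline(path))
    raise ValidationError(f"unknown corpus format {format!r}")


def write_corpus(documents: Sequence[Document], path: str | Path,
                 format: str = "jsonl") -> None:
    """Write documents in the given dialect (abstract = joined sentences)."""
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8") as fh:
            if format == "jsonl":
                for d in documents:
                    fh.write(json.dumps(
                        {"pmid": d.pmid, "title": d.title,
                         "abstract": d.abstract_text}) + "\n")
            elif format == "medline":
                for d in documents:
                    fh.write(f"PMID- {d.pmid}\n")
                    fh.write(f"TI  - {d.title}\n")
                    if d.sentences:
                        fh.write(f"AB  - {d.abstract_text}\n")
                    fh.write("\n")
            else:
                raise ValidationError(f"unknown corpus format {format!r}")
    except OSError as exc:
        raise OutputError(f"cannot write corpus to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Gold labels
# ---------------------------------------------------------------------------

_SC_ADJECTIVES = {
    "papillary": "PTC",
    "anaplastic": "ATC",
    "undifferentiated": "ATC",
    "follicular": "FTC",
    "medullary": "MTC",
}


def normalize_subtype_label(label: str) -> str:
    """Normalize a gold label to a canonical code.

    Accepts the codes themselves and MeSH-Supplementary-Concept-style
    names such as "Thyroid cancer, papillary".  Raises
    :class:`ValidationError` for anything unrecognized.
    """
    text = label.strip()
    if text.upper() in SUBTYPES:
        return text.upper()
    low = text.lower()
    if "thyroid" in low:
        hits = {code for adj, code in _SC_ADJECTIVES.items() if adj in low}
        if len(hits) == 1:
            return hits.pop()
    raise ValidationError(f"unrecognized subtype label {label!r}")


def read_gold(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a gold-standard TSV of ``pmid<TAB>subtype`` lines.

    Repeated pmids accumulate labels (multi-label documents).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"gold file not found: {path}")
    acc: dict[str, set[str]] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 'pmid<TAB>label'")
        pmid, label = fields
        try:
            code = normalize_subtype_label(label)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
        acc.setdefault(pmid.strip(), set()).add(code)
    return {pmid: frozenset(codes) for pmid, codes in acc.items()}


# ---------------------------------------------------------------------------
# Entity mentions
# ---------------------------------------------------------------------------

_MENTION_FIELDS = ("pmid", "entity_kind", "entity_id", "start", "end",
                   "surface", "source")


def read_mentions(path: str | Path) -> list[EntityMention]:
    """Read a headered TSV of entity mentions, validated, in file order."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"mentions file not found: {path}")
    mentions = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_MENTION_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                mentions.append(EntityMention(
                    pmid=row["pmid"], entity_kind=row["entity_kind"],
                    entity_id=row["entity_id"], start=int(row["start"]),
                    end=int(row["end"]), surface=row["surface"],
                    source=row["source"],
                ))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return mentions


def write_mentions(mentions: Sequence[EntityMention], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MENTION_FIELDS)
        for m in mentions:
            writer.writerow([m.pmid, m.entity_kind, m.entity_id,
                             m.start, m.end, m.surface, m.source])


# ---------------------------------------------------------------------------
# Classification results
# ---------------------------------------------------------------------------

def format_labels(labels: frozenset[str]) -> str:
    """Render a label set as its output cell: subtype codes '|'-joined in
    canonical order, or the special singleton ``TC``/``NON``."""
    if labels == {"NON"}:
        return "NON"
    if labels == {"TC"}:
        return "TC"
    return "|".join(j for j in SUBTYPES if j in labels)


def parse_labels(cell: str) -> frozenset[str]:
    labels = frozenset(cell.split("|")) if cell else frozenset()
    unknown = labels - LABEL_VOCAB
    if unknown:
        raise ValidationError(f"unknown labels {sorted(unknown)} in cell {cell!r}")
    return labels


def write_classification(results: Sequence[ClassifiedDocument],
                         path: str | Path, *, metadata: str = "") -> None:
    """Write classification results as a TSV.

    Columns: pmid, S_P, S_A, S_F, S_M, labels; scores serialized to four
    decimal places.  A comment header records the splitter identity and
    any caller-supplied metadata (e.g. the config used).
    """
    try:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            fh.write(f"# splitter={SPLITTER_ID}\n")
            if metadata:
                fh.write(f"# {metadata}\n")
            fh.write("pmid\tS_P\tS_A\tS_F\tS_M\tlabels\n")
            for r in results:
                cells = [r.document.pmid]
                cells += [f"{v:.4f}" for v in r.scores.as_tuple()]
                cells.append(format_labels(r.labels))
                fh.write("\t".join(cells) + "\n")
    except OSError as exc:
        raise OutputError(f"cannot write classification to {path}: {exc}") from exc


def read_classification(path: str | Path) -> dict[str, tuple[ScoreVector, frozenset[str]]]:
    """Read a classification TSV back as ``pmid -> (scores, labels)``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"classification file not found: {path}")
    out: dict[str, tuple[ScoreVector, frozenset[str]]] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.startswith("#") or raw.startswith("pmid\t"):
            continue
        fields = raw.split("\t")
        if len(fields) != 6:
            raise ValidationError(f"{path}:{lineno}: expected 6 columns")
        pmid, *scores, cell = fields
        out[pmid] = (ScoreVector(*map(float, scores)), parse_labels(cell))
    return out
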