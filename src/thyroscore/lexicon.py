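"""Decomposed subtype vocabulary and sentence-level keyword matching.

Thyroid-cancer subtype names are frequently written partially or in
abbreviated form ("papillary cancer", bare "medullary"), so a full-name
dictionary misses many mentions.  Each subtype name is therefore
dissociated into three independently matched parts:

* **SK** — the subtype keyword proper ("papillary", "anaplastic", ...),
  each variant mapped to a canonical subtype code (PTC, ATC, FTC, MTC);
* **AK** — the anatomy keyword ("thyroid", "thyroidal");
* **MK** — the malignancy keyword ("cancer", "carcinoma", "tumour", ...).

In "papillary thyroid cancer" the SK is "papillary", the AK "thyroid" and
the MK "cancer".  Synonymous subtype adjectives normalize to one code:
"anaplastic", "undifferentiated" and "un-differentiated" all map to ATC.

Matching is exact, case-insensitive and on word boundaries, with hyphens
treated as boundaries so hyphenated variants listed in the lexicon match
their surface form.  No stemming or fuzzy matching is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputError, ValidationError

#: Canonical subtype codes, in the order used everywhere in the package.
SUBTYPES: tuple[str, ...] = ("PTC", "ATC", "FTC", "MTC")

# A "word" for boundary purposes is a run of letters/digits; hyphens,
# punctuation and whitespace all act as boundaries.
_BOUND_L = r"(?<![A-Za-z0-9])"
_BOUND_R = r"(?![A-Za-z0-9])"


def _variant_pattern(variant: str) -> re.Pattern[str]:
    """Compile a case-insensitive word-boundary pattern for one variant.

    Multi-word variants match as contiguous token sequences (any run of
    whitespace between the words); hyphens inside a variant are literal.
    """
    parts = [re.escape(p) for p in variant.split()]
    return re.compile(_BOUND_L + r"\s+".join(parts) + _BOUND_R, re.IGNORECASE)


@dataclass(frozen=True)
class SubtypeLexicon:
    """The three keyword lists plus the variant→canonical-subtype mapping.

    Parameters
    ----------
    subtype_keywords
        Mapping canonical subtype code → set of SK surface variants.
    anatomy_keywords, malignancy_keywords
        AK and MK surface variants.
    subtypes
        Ordered canonical codes; defaults to ``("PTC", "ATC", "FTC", "MTC")``.
    """

    subtype_keywords: Mapping[str, frozenset[str]]
    anatomy_keywords: frozenset[str]
    malignancy_keywords: frozenset[str]
    subtypes: tuple[str, ...] = SUBTYPES
    _compiled: list = field(default=None, repr=False, compare=False, init=False)  # lazy cache

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for code, variants in self.subtype_keywords.items():
            if code not in self.subtypes:
                raise ValidationError(f"unknown subtype code {code!r}")
            for v in variants:
                if not v:
                    raise ValidationError("empty SK variant")
                if v in seen and seen[v] != code:
                    raise ValidationError(
                        f"SK variant {v!r} assigned to both {seen[v]} and {code}"
                    )
                seen[v] = code
        for name, pool in (("AK", self.anatomy_keywords),
                           ("MK", self.malignancy_keywords)):
            for v in pool:
                if not v:
                    raise ValidationError(f"empty {name} variant")
                if v in seen:
                    raise ValidationError(
                        f"variant {v!r} appears in both SK and {name} lists"
                    )
        overlap = self.anatomy_keywords & self.malignancy_keywords
        if overlap:
            raise ValidationError(
                f"variants in both AK and MK lists: {sorted(overlap)}"
            )

    @property
    def variant_to_subtype(self) -> dict[str, str]:
        """Flat mapping of SK variant → canonical subtype code."""
        return {
            v: code
            for code, variants in self.subtype_keywords.items()
            for v in variants
        }

    def _patterns(self) -> list[tuple[re.Pattern[str], str, str, str]]:
        # (pattern, keyword class, canonical form, variant); built once.
        if self._compiled is None:
            compiled = []
            for code in self.subtypes:
                for v in sorted(self.subtype_keywords.get(code, ())):
                    compiled.append((_variant_pattern(v), "SK", code, v))
            for v in sorted(self.anatomy_keywords):
                compiled.append((_variant_pattern(v), "AK", v, v))
            for v in sorted(self.malignancy_keywords):
                compiled.append((_variant_pattern(v), "MK", v, v))
            object.__setattr__(self, "_compiled", compiled)
        return self._compiled


@dataclass(frozen=True)
class KeywordMatches:
    """All SK/AK/MK hits found in a single sentence.

    ``spans`` are 0-based half-open character offsets into the sentence,
    one tuple ``(start, end, keyword_class, canonical_form)`` per hit.
    """

    sk_present: frozenset[str]
    ak_present: bool
    mk_present: bool
    spans: tuple[tuple[int, int, str, str], ...]


def match_sentence(sentence: str, lexicon: SubtypeLexicon) -> KeywordMatches:
    """Find every lexicon keyword in one sentence.

    The sentence is not split further; matching is case-insensitive on
    word boundaries (hyphen counts as a boundary).  An empty sentence
    yields empty matches.
    """
    spans: list[tuple[int, int, str, str]] = []
    for pattern, klass, canonical, _variant in lexicon._patterns():
        for m in pattern.finditer(sentence):
            spans.append((m.start(), m.end(), klass, canonical))
    spans.sort()
    sk = frozenset(c for _, _, k, c in spans if k == "SK")
    return KeywordMatches(
        sk_present=sk,
        ak_present=any(k == "AK" for _, _, k, _ in spans),
        mk_present=any(k == "MK" for _, _, k, _ in spans),
        spans=tuple(spans),
    )


# ---------------------------------------------------------------------------
# Lexicon file loading
# ---------------------------------------------------------------------------

_SECTIONS = ("SK", "AK", "MK")


def _parse_lexicon_lines(lines: Iterable[str], origin: str) -> SubtypeLexicon:
    section = None
    sk: dict[str, set[str]] = {}
    ak: set[str] = set()
    mk: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().upper()
            if section not in _SECTIONS:
                raise ValidationError(
                    f"{origin}:{lineno}: unknown section [{section}]"
                )
            continue
        if section is None:
            raise ValidationError(f"{origin}:{lineno}: content before any section")
        if section == "SK":
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(
                    f"{origin}:{lineno}: SK lines need 'variant<TAB>code'"
                )
            variant, code = fields[0].strip().lower(), fields[1].strip().upper()
            sk.setdefault(code, set()).add(variant)
        elif section == "AK":
            ak.add(line.lower())
        else:
            mk.add(line.lower())
    missing = [s for s, pool in (("SK", sk), ("AK", ak), ("MK", mk)) if not pool]
    if missing:
        raise ValidationError(
            f"{origin}: lexicon is missing section(s) {', '.join(missing)}"
        )
    return SubtypeLexicon(
        subtype_keywords={c: frozenset(v) for c, v in sk.items()},
        anatomy_keywords=frozenset(ak),
        malignancy_keywords=frozenset(mk),
    )


def load_lexicon(source: str | Path = "builtin") -> SubtypeLexicon:
    """Load a lexicon from the builtin default or a three-section text file.

    The file format has ``[SK]``/``[AK]``/``[MK]`` section headers, one
    ``variant<TAB>canonical`` (SK) or bare ``variant`` (AK/MK) per line,
    and ``#`` comments.  Raises :class:`InputError` for unreadable files
    and :class:`ValidationError` for malformed or inconsistent content.
    """
    if source == "builtin":
        text = (
            resources.files("thyroscore").joinpath("data/default_lexicon.txt")
            .read_text(encoding="utf-8")
        )
        return _parse_lexicon_lines(text.splitlines(), "builtin")
    path = Path(source)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read lexicon file {path}: {exc}") from exc
    return _parse_lexicon_lines(text.splitlines(), str(path))
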