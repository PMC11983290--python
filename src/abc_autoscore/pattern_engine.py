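"""Compile checklist-item patterns and run the four-stage match pipeline.

Each of the 20 checklist items is represented by one or more case-insensitive
regular expressions capturing how clinicians phrase the behavior in free text.
A raw expression hit only survives a chain of filters, applied in order within
the containing sentence:

1. core expression — the item's trigger phrase matches;
2. opioid context  — if the item requires it, an opioid/analgesic lexicon term
   must occur in the same sentence (optionally *after* the trigger, matching
   the "followed by" construction used for the hoarding item);
3. negation        — a negating term ("denies", "no", ...) strictly before the
   trigger in the sentence vetoes the hit;
4. false-positive prefix — a hit preceded anywhere earlier in the note by a
   phrase such as "discharge instructions" is discarded, because medication
   lists in discharge boilerplate mention opioids without implying behavior.

Every surviving hit is returned as an auditable :class:`Match` carrying its
character span, sentence, and a filter trail, so a reviewer can always see
exactly why a patient scored.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from functools import lru_cache
from typing import Iterable, Sequence

from .corpus_io import Note

logger = logging.getLogger(__name__)

ORDER_CONSTRAINTS = ("none", "trigger_before_term")
N_ITEMS = 20


class PatternCompileError(ValueError):
    """A configured expression does not compile; names the item and index."""


@dataclasses.dataclass(frozen=True)
class Lexicon:
    """Named list of case-insensitive term stems or expression fragments."""

    name: str
    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        cleaned: list[str] = []
        seen: set[str] = set()
        for e in self.entries:
            e = e.strip()
            if not e:
                continue
            key = e.casefold()
            if key in seen:
                logger.warning("lexicon %s: duplicate entry %r dropped", self.name, e)
                continue
            seen.add(key)
            cleaned.append(e)
        if not cleaned:
            raise ValueError(f"lexicon {self.name!r} has no entries")
        object.__setattr__(self, "entries", tuple(cleaned))

    def merged_with(self, other: "Lexicon", name: str | None = None) -> "Lexicon":
        return Lexicon(name or self.name, self.entries + other.entries)


@dataclasses.dataclass(frozen=True)
class ItemPattern:
    """One checklist item's executable definition: expressions plus filters."""

    item_id: int
    label: str
    core_expressions: tuple[str, ...]
    require_opioid_context: bool = False
    opioid_order_constraint: str = "none"
    negation_enabled: bool = True
    exclusion_prefixes: tuple[str, ...] = ("discharge instructions",)
    scope: str = "sentence"

    def __post_init__(self) -> None:
        if not 1 <= self.item_id <= N_ITEMS:
            raise ValueError(f"item_id must be in [1, {N_ITEMS}], got {self.item_id}")
        if not self.core_expressions:
            raise ValueError(f"item {self.item_id}: needs >= 1 core expression")
        if self.opioid_order_constraint not in ORDER_CONSTRAINTS:
            raise ValueError(
                f"item {self.item_id}: opioid_order_constraint must be one of "
                f"{ORDER_CONSTRAINTS}"
            )
        if self.opioid_order_constraint != "none" and not self.require_opioid_context:
            raise ValueError(
                f"item {self.item_id}: an opioid order constraint requires "
                "require_opioid_context=true"
            )
        if self.scope != "sentence":
            raise ValueError(f"item {self.item_id}: only sentence scope is supported")
        for idx, expr in enumerate(self.core_expressions):
            try:
                re.compile(expr, re.IGNORECASE)
            except re.error as exc:
                raise PatternCompileError(
                    f"item {self.item_id}, expression {idx}: {expr!r} does not "
                    f"compile ({exc})"
                ) from exc


@dataclasses.dataclass(frozen=True)
class SentenceSpan:
    """Half-open character offsets of one sentence within a note's text."""

    start: int
    end: int


@dataclasses.dataclass(frozen=True)
class Match:
    """An audited pattern hit that survived the full filter chain."""

    patient_id: str
    note_id: str
    item_id: int
    start: int
    end: int
    matched_text: str
    sentence_text: str
    filter_trail: tuple[tuple[str, str], ...]


# Tokens before a period that do not end a sentence.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st",
    "mg", "mcg", "ml", "tab", "tabs", "cap",
    "vs", "approx", "appt", "hx", "pt",
}


def segment_sentences(text: str) -> list[SentenceSpan]:
    """Split text into sentence spans on ., !, ? and newlines.

    Spans partition the non-whitespace characters: concatenating the slices
    reproduces all content except inter-sentence whitespace.  Periods inside
    decimals (``2.5``) and after a short abbreviation stop-list (``Dr.``,
    ``mg.``) do not break sentences.
    """
    n = len(text)
    raw: list[tuple[int, int]] = []
    seg_start = 0
    i = 0
    while i < n:
        ch = text[i]
        if ch == "\n":
            raw.append((seg_start, i))
            i += 1
            seg_start = i
        elif ch in ".!?":
            j = i
            while j + 1 < n and text[j + 1] in ".!?":
                j += 1
            if (
                ch == "."
                and i > 0
                and text[i - 1].isdigit()
                and j + 1 < n
                and text[j + 1].isdigit()
            ):
                i = j + 1
                continue
            if ch == "." and i == j:
                k = i - 1
                while k >= 0 and text[k].isalpha():
                    k -= 1
                word = text[k + 1 : i].lower()
                if word in _ABBREVIATIONS or len(word) == 1:
                    i = j + 1
                    continue
            if j + 1 >= n or text[j + 1].isspace():
                raw.append((seg_start, j + 1))
                i = j + 1
                seg_start = i
            else:
                i = j + 1
        else:
            i += 1
    if seg_start < n:
        raw.append((seg_start, n))
    spans: list[SentenceSpan] = []
    for s, e in raw:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if e > s:
            spans.append(SentenceSpan(s, e))
    return spans


def _entry_pattern(entry: str, whole_word: bool) -> str:
    # spaces in multi-word entries tolerate any whitespace run
    body = re.escape(entry).replace(r"\ ", r"\s+")
    return r"\b" + body + (r"\b" if whole_word else "")


@lru_cache(maxsize=256)
def _lexicon_regex(entries: tuple[str, ...], whole_word: bool) -> re.Pattern:
    parts = sorted(entries, key=len, reverse=True)
    return re.compile(
        "|".join(_entry_pattern(p, whole_word) for p in parts), re.IGNORECASE
    )


def has_opioid_context(
    sentence: str,
    trigger_span: tuple[int, int],
    lexicon: Lexicon,
    order: str = "none",
) -> bool:
    """True iff an opioid-lexicon term occurs in the sentence.

    With ``order="trigger_before_term"`` the term must start at or after the
    trigger's end (the "followed by" rule); lexicon entries are matched as
    case-insensitive word-initial stems, so ``narc`` covers ``narcotics``.
    """
    rx = _lexicon_regex(lexicon.entries, whole_word=False)
    if order == "none":
        return rx.search(sentence) is not None
    if order != "trigger_before_term":
        raise ValueError(f"unknown order constraint {order!r}")
    return any(m.start() >= trigger_span[1] for m in rx.finditer(sentence))


def is_negated(
    sentence: str, trigger_span: tuple[int, int], negation_lexicon: Lexicon | None
) -> bool:
    """True iff a negating term occurs strictly before the trigger's start.

    With no negation lexicon nothing is ever negated.
    """
    if negation_lexicon is None:
        return False
    rx = _lexicon_regex(negation_lexicon.entries, whole_word=True)
    return any(m.start() < trigger_span[0] for m in rx.finditer(sentence))


def is_excluded_by_prefix(
    note_text: str, trigger_offset: int, prefixes: Sequence[str]
) -> bool:
    """True iff any prefix phrase occurs in the note before ``trigger_offset``.

    The scan covers the whole note up to the trigger (not just the sentence)
    because phrases like "discharge instructions" act as section headers.
    """
    if not prefixes:
        return False
    head = note_text[:trigger_offset]
    rx = _lexicon_regex(tuple(prefixes), whole_word=True)
    return rx.search(head) is not None


class CompiledItemMatcher:
    """A deterministic, case-insensitive matcher for one checklist item."""

    def __init__(
        self,
        item: ItemPattern,
        opioid_lexicon: Lexicon,
        negation_lexicon: Lexicon,
    ):
        self.item = item
        self.opioid_lexicon = opioid_lexicon
        self.negation_lexicon = negation_lexicon
        unique: list[str] = []
        for idx, expr in enumerate(item.core_expressions):
            if expr in unique:
                logger.warning(
                    "item %d: duplicate core expression %d deduplicated",
                    item.item_id,
                    idx,
                )
                continue
            unique.append(expr)
        self.core_patterns = tuple(re.compile(e, re.IGNORECASE) for e in unique)

    @property
    def n_filter_stages(self) -> int:
        return 4

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CompiledItemMatcher item={self.item.item_id} " f"exprs={len(self.core_patterns)}>"


def compile_item_pattern(
    item: ItemPattern, opioid_lexicon: Lexicon, negation_lexicon: Lexicon
) -> CompiledItemMatcher:
    """Validate and compile one item's pattern into a reusable matcher."""
    return CompiledItemMatcher(item, opioid_lexicon, negation_lexicon)


def match_note(matcher: CompiledItemMatcher, note: Note) -> list[Match]:
    """Run one item's full filter chain over a note and return surviving hits.

    The chain order is fixed: core expression, opioid context, negation,
    prefix exclusion.  Matches are reported with note-level 0-based half-open
    offsets, sorted by position; identical spans arising from several core
    expressions of the same item are deduplicated.
    """
    item = matcher.item
    out: list[Match] = []
    seen: set[tuple[int, int]] = set()
    for span in segment_sentences(note.text):
        sentence = note.text[span.start : span.end]
        for rx in matcher.core_patterns:
            for m in rx.finditer(sentence):
                local = (m.start(), m.end())
                trail: list[tuple[str, str]] = [("core", "pass")]
                if item.require_opioid_context:
                    if not has_opioid_context(
                        sentence,
                        local,
                        matcher.opioid_lexicon,
                        item.opioid_order_constraint,
                    ):
                        continue
                    trail.append(("opioid_context", "pass"))
                else:
                    trail.append(("opioid_context", "skip"))
                if item.negation_enabled:
                    if is_negated(sentence, local, matcher.negation_lexicon):
                        continue
                    trail.append(("negation", "pass"))
                else:
                    trail.append(("negation", "skip"))
                abs_start = span.start + local[0]
                abs_end = span.start + local[1]
                if item.exclusion_prefixes:
                    if is_excluded_by_prefix(
                        note.text, abs_start, item.exclusion_prefixes
                    ):
                        continue
                    trail.append(("exclusion", "pass"))
                else:
                    trail.append(("exclusion", "skip"))
                if (abs_start, abs_end) in seen:
                    continue
                seen.add((abs_start, abs_end))
                out.append(
                    Match(
                        patient_id=note.patient_id,
                        note_id=note.note_id,
                        item_id=item.item_id,
                        start=abs_start,
                        end=abs_end,
                        matched_text=note.text[abs_start:abs_end],
                        sentence_text=sentence,
                        filter_trail=tuple(trail),
                    )
                )
    out.sort(key=lambda m: (m.start, m.end))
    return out


def match_corpus(
    matchers: Iterable[CompiledItemMatcher], notes: Iterable[Note]
) -> list[Match]:
    """Apply every item matcher to every note; hits sorted per note."""
    all_matches: list[Match] = []
    for note in notes:
        per_note: list[Match] = []
        for matcher in matchers:
            per_note.extend(match_note(matcher, note))
        per_note.sort(key=lambda m: (m.start, m.end, m.item_id))
        all_matches.extend(per_note)
    return all_matches
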