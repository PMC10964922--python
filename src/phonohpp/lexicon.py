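"""Phonemic lexicons: reading, derivation from transcribed utterances, synthesis.

A lexicon is a collection of *word types* — unique phonemic transcriptions —
each carrying an orthographic form and a token frequency. Word-type identity
is the transcription sequence, not the spelling: two rows with the same
transcription are the same type and their token frequencies are summed.
All phonotactic measures downstream are type-based, i.e. they ignore
``token_freq`` entirely.

Dialects describe CELEX-/LEXIQUE-like tabular files: which columns hold the
wordform, transcription and frequency, the column separator, how phonemes are
delimited inside the transcription (whitespace for multi-character codes,
per-character for DISC-like single-symbol codes), and an optional comment
prefix. Dialects can be loaded from YAML.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import EmptyLexiconError, LexiconFormatError, LexiconValidationError
from .inventory import PhonemeInventory

Transcription = tuple[str, ...]


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class LexEntry:
    """One word type: spelling, phonemic transcription, token frequency."""

    wordform: str
    transcription: Transcription
    token_freq: int = 1

    def __post_init__(self) -> None:
        if len(self.transcription) == 0:
            raise LexiconValidationError(f"empty transcription for wordform {self.wordform!r}")
        if self.token_freq < 0:
            raise LexiconValidationError(f"negative token_freq for wordform {self.wordform!r}")
        object.__setattr__(
            self, "transcription", tuple(_nfc(p) for p in self.transcription)
        )


@dataclass
class Lexicon:
    """Word types keyed by transcription, validated against an inventory."""

    entries: dict[Transcription, LexEntry]
    inventory: PhonemeInventory
    meta: dict = field(default_factory=dict)

    @property
    def n_types(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[LexEntry],
        inventory: PhonemeInventory,
        meta: Mapping | None = None,
    ) -> "Lexicon":
        """Build a lexicon, merging duplicate transcriptions by summing frequency."""
        merged: dict[Transcription, LexEntry] = {}
        bad: dict[str, None] = {}
        for e in entries:
            for sym in inventory.validate_transcription(e.transcription):
                bad.setdefault(sym)
            key = e.transcription
            if key in merged:
                old = merged[key]
                merged[key] = replace(old, token_freq=old.token_freq + e.token_freq)
            else:
                merged[key] = e
        if bad:
            raise LexiconValidationError(
                "phonemes outside inventory: " + ", ".join(repr(s) for s in bad)
            )
        if not merged:
            raise EmptyLexiconError("lexicon has no entries")
        m = dict(meta or {})
        m["n_types"] = len(merged)
        return cls(entries=merged, inventory=inventory, meta=m)


@dataclass(frozen=True)
class LexiconDialect:
    """Column roles and delimiters of a tabular lexicon file.

    ``phoneme_delimiter`` is ``"whitespace"`` (split transcription on runs of
    whitespace), ``"char"`` (one phoneme per character), or a literal
    delimiter string such as ``"."``.
    """

    wordform_col: str | int = "wordform"
    transcription_col: str | int = "transcription"
    frequency_col: str | int | None = "frequency"
    sep: str = "\t"
    phoneme_delimiter: str = "whitespace"
    comment_prefix: str | None = "#"
    has_header: bool = True
    encoding: str = "utf-8"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LexiconDialect":
        with open(path, encoding="utf-8") as fh:
            spec = yaml.safe_load(fh) or {}
        return cls(**spec)

    def split_phonemes(self, raw: str) -> Transcription:
        raw = raw.strip()
        if self.phoneme_delimiter == "whitespace":
            return tuple(raw.split())
        if self.phoneme_delimiter == "char":
            return tuple(raw)
        return tuple(p for p in raw.split(self.phoneme_delimiter) if p)


DEFAULT_DIALECT = LexiconDialect()


def _column(row: Sequence[str], header: list[str] | None, col: str | int, path, lineno):
    if isinstance(col, int):
        idx = col
    else:
        if header is None or col not in header:
            raise LexiconFormatError(f"{path}: missing column {col!r}")
        idx = header.index(col)
    if idx >= len(row):
        raise LexiconFormatError(f"{path}:{lineno}: row has no column {col!r}")
    return row[idx]


def read_lexicon(
    path: str | Path,
    inventory: PhonemeInventory,
    dialect: LexiconDialect = DEFAULT_DIALECT,
    meta: Mapping | None = None,
) -> Lexicon:
    """Read a tabular lexicon file and validate it against ``inventory``.

    Duplicate transcriptions are merged with summed token frequencies.
    Raises :class:`LexiconFormatError` for structural problems,
    :class:`LexiconValidationError` listing any out-of-inventory phonemes,
    and :class:`EmptyLexiconError` for a file with no data rows.
    """
    path = Path(path)
    entries: list[LexEntry] = []
    header: list[str] | None = None
    with open(path, encoding=dialect.encoding) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if dialect.comment_prefix and line.lstrip().startswith(dialect.comment_prefix):
                continue
            row = line.split(dialect.sep)
            if dialect.has_header and header is None:
                header = [c.strip() for c in row]
                for col in (dialect.wordform_col, dialect.transcription_col, dialect.frequency_col):
                    if isinstance(col, str) and col not in header:
                        raise LexiconFormatError(f"{path}: missing column {col!r}")
                continue
            wf = _column(row, header, dialect.wordform_col, path, lineno)
            tr = dialect.split_phonemes(
                _column(row, header, dialect.transcription_col, path, lineno)
            )
            if dialect.frequency_col is None:
                freq = 1
            else:
                raw = _column(row, header, dialect.frequency_col, path, lineno).strip()
                try:
                    freq = int(float(raw)) if raw else 0
                except ValueError as exc:
                    raise LexiconFormatError(
                        f"{path}:{lineno}: non-numeric frequency {raw!r}"
                    ) from exc
            entries.append(LexEntry(wordform=wf.strip(), transcription=tr, token_freq=freq))
    if not entries:
        raise EmptyLexiconError(f"{path}: no lexical entries")
    m = dict(meta or {})
    m.setdefault("source", str(path))
    return Lexicon.from_entries(entries, inventory, m)


def write_lexicon(lex: Lexicon, path: str | Path, phoneme_sep: str = " ") -> None:
    """Write a lexicon as UTF-8 TSV (wordform, transcription, frequency)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("wordform\ttranscription\tfrequency\n")
        for e in lex.entries.values():
            fh.write(f"{e.wordform}\t{phoneme_sep.join(e.transcription)}\t{e.token_freq}\n")


def derive_lexicon_from_utterances(
    utterance_lines: Iterable[str],
    inventory: PhonemeInventory,
    phoneme_delimiter: str = "char",
    meta: Mapping | None = None,
) -> Lexicon:
    """Derive an infant-directed-speech lexicon from transcribed utterances.

    Each line is a space-delimited sequence of phonemically transcribed words
    (one utterance per line, CHILDES-like). Unique word transcriptions become
    the word types; token frequency counts corpus occurrences. Phonemes within
    a word are split per ``phoneme_delimiter`` (default: one phoneme per
    character, the common convention for one-symbol phonemic codes).
    """
    dialect = LexiconDialect(phoneme_delimiter=phoneme_delimiter)
    counts: dict[Transcription, int] = {}
    for line in utterance_lines:
        for word in line.split():
            tr = dialect.split_phonemes(word)
            if tr:
                counts[tr] = counts.get(tr, 0) + 1
    if not counts:
        raise EmptyLexiconError("utterance corpus contains no words")
    m = dict(meta or {})
    m.setdefault("register", "IDS")
    entries = [
        LexEntry(wordform="".join(tr), transcription=tr, token_freq=c)
        for tr, c in counts.items()
    ]
    return Lexicon.from_entries(entries, inventory, m)


# ---------------------------------------------------------------------------
# Synthetic lexicons


def _encode_body(index: int, vowels: Sequence[str], min_len: int = 2) -> Transcription:
    """Injective index → vowel-sequence encoding (used to guarantee uniqueness)."""
    base = len(vowels)
    digits = []
    i = index
    while True:
        digits.append(i % base)
        i //= base
        if i == 0:
            break
    while len(digits) < min_len:
        digits.append(0)
    return tuple(vowels[d] for d in reversed(digits))


def synthetic_lexicon(
    n_types: int,
    inventory: PhonemeInventory,
    initial_biphones: Mapping[tuple[str, str], int] | None = None,
    initial_uniphones: Mapping[str, int] | None = None,
    overall_extra: Mapping[str, int] | None = None,
    filler_onsets: Sequence[str] = ("k", "m", "l", "t", "b", "d", "n", "r", "f", "v"),
    language: str = "synthetic",
    register: str = "ADS",
) -> Lexicon:
    """Construct a synthetic lexicon with prescribed word-initial counts.

    The generator is deterministic. It builds exactly ``n_types`` unique word
    types such that, for each requested initial biphone (e.g. ``("ʃ", "t")``),
    exactly that many types begin with the pair, and for each requested
    initial uniphone the *total* number of types beginning with that phoneme
    (biphone words included) matches the request. ``overall_extra`` appends
    additional non-initial occurrences of a phoneme across filler words so
    that whole-lexicon (non-positional) counts can also be prescribed.

    This is a synthetic stand-in shaped like the proprietary lexical
    databases (CELEX, LEXIQUE, CHILDES-derived IDS lexicons) that cannot be
    redistributed; only the prescribed counts are meaningful, the filler
    material is arbitrary.
    """
    initial_biphones = dict(initial_biphones or {})
    initial_uniphones = dict(initial_uniphones or {})
    overall_extra = dict(overall_extra or {})
    vowels = sorted(inventory.vowels())
    if not vowels:
        raise LexiconValidationError("synthetic lexicon needs at least one vowel")

    by_first: dict[str, int] = {}
    for (a, _b), cnt in initial_biphones.items():
        by_first[a] = by_first.get(a, 0) + cnt
    for a, total in initial_uniphones.items():
        if total < by_first.get(a, 0):
            raise LexiconValidationError(
                f"uniphone target for {a!r} ({total}) is below its biphone targets"
            )

    entries: list[LexEntry] = []
    counter = 0
    for (a, b), cnt in initial_biphones.items():
        for _ in range(cnt):
            entries.append(LexEntry("".join((a, b)) + str(counter), (a, b) + _encode_body(counter, vowels)))
            counter += 1
    for a, total in initial_uniphones.items():
        for _ in range(total - by_first.get(a, 0)):
            # follow the onset with a vowel so no extra initial biphone target is hit
            entries.append(LexEntry(a + str(counter), (a,) + _encode_body(counter, vowels)))
            counter += 1
    targeted = set(initial_uniphones) | {a for a, _ in initial_biphones}
    onsets = [c for c in filler_onsets if c in inventory and c not in targeted]
    if len(entries) > n_types:
        raise LexiconValidationError("initial-count targets exceed n_types")
    n_fillers = n_types - len(entries)
    if n_fillers > 0 and not onsets:
        raise LexiconValidationError("no filler onsets available outside the targeted phonemes")
    fillers: list[LexEntry] = []
    for i in range(n_fillers):
        onset = onsets[i % len(onsets)]
        fillers.append(LexEntry(onset + str(counter), (onset,) + _encode_body(counter, vowels)))
        counter += 1
    # distribute prescribed extra (non-initial) phoneme occurrences over fillers
    for phoneme, extra in overall_extra.items():
        if extra < 0:
            raise LexiconValidationError(f"negative overall_extra for {phoneme!r}")
        if extra == 0:
            continue
        if not fillers:
            raise LexiconValidationError("overall_extra requires filler words")
        q, r = divmod(extra, len(fillers))
        for i, e in enumerate(fillers):
            k = q + (1 if i < r else 0)
            if k:
                fillers[i] = replace(e, transcription=e.transcription + (phoneme,) * k)
    entries.extend(fillers)
    return Lexicon.from_entries(
        entries, inventory, {"language": language, "register": register, "source": "synthetic"}
    )
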