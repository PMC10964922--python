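"""Type-based phonotactic probability measures.

Three measures over a phonemic lexicon, all computed by *type frequency*
(each word type counts once; corpus token frequencies are ignored):

- positional uniphone probability: the share of word types whose phoneme at
  a given position (word-initial or word-final) is the target phoneme;
- positional biphone probability: the share of word types whose first (or
  last) two phonemes equal the target ordered pair;
- overall phoneme probability: a consonant's share of all consonant
  occurrences across all word types, irrespective of position.

Positional measures use the number of word types as the denominator, which
is the convention under which, e.g., 165 /s/-initial types in a 51,322-type
lexicon yield a probability of 0.0032 at four decimals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .errors import EmptyLexiconError, LexiconValidationError
from .lexicon import Lexicon

WORD_INITIAL = "word-initial"
WORD_FINAL = "word-final"
ANY_POSITION = "any"

S_CONDITION = "s-initial"
SH_CONDITION = "ʃ-initial"

DEFAULT_CLUSTERS: tuple[tuple[str, str], ...] = (("s", "t"), ("s", "p"), ("ʃ", "t"), ("ʃ", "p"))


@dataclass(frozen=True)
class PhonotacticRow:
    """One phonotactic count/probability cell."""

    language: str
    register: str
    unit: str  # "uniphone" | "biphone" | "overall"
    sequence: tuple[str, ...]
    position: str
    count: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise LexiconValidationError("denominator must be positive")
        if not 0 <= self.count <= self.denominator:
            raise LexiconValidationError("count must lie in [0, denominator]")

    @property
    def probability(self) -> float:
        return self.count / self.denominator

    @property
    def key(self) -> tuple:
        return (self.language, self.register, self.unit, self.sequence, self.position)


def format_probability(p: float, places: int = 4) -> str:
    """Round half-away-from-zero; nonzero values that round to 0 print as "<0.0001"."""
    q = Decimal(repr(p)).quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP)
    if p > 0 and q == 0:
        return "<" + str(Decimal(1).scaleb(-places))
    return f"{q:.{places}f}"


@dataclass
class PhonotacticTable:
    """A keyed collection of phonotactic rows with display rounding."""

    rows: list[PhonotacticRow] = field(default_factory=list)
    rounding: int = 4
    verdicts: dict[str, str] = field(default_factory=dict)  # language → frequent condition

    def add(self, row: PhonotacticRow) -> None:
        if any(r.key == row.key for r in self.rows):
            raise LexiconValidationError(f"duplicate phonotactic row key {row.key}")
        self.rows.append(row)

    def to_tsv(self) -> str:
        lines = ["language\tregister\tunit\tsequence\tposition\tcount\tdenominator\tprobability"]
        for r in self.rows:
            lines.append(
                "\t".join(
                    [
                        r.language,
                        r.register,
                        r.unit,
                        "".join(r.sequence),
                        r.position,
                        str(r.count),
                        str(r.denominator),
                        format_probability(r.probability, self.rounding),
                    ]
                )
            )
        return "\n".join(lines) + "\n"

    def to_markdown(self) -> str:
        """Frequency counts (and probability) per sequence × language."""
        langs = sorted({r.language for r in self.rows})
        seqs: list[tuple[str, tuple[str, ...]]] = []
        for r in self.rows:
            if (r.unit, r.sequence) not in seqs:
                seqs.append((r.unit, r.sequence))
        header = "| sequence | " + " | ".join(langs) + " |"
        rule = "|" + "---|" * (len(langs) + 1)
        lines = [header, rule]
        for unit, seq in seqs:
            cells = []
            for lang in langs:
                match = [r for r in self.rows if r.language == lang and r.unit == unit and r.sequence == seq]
                if match:
                    r = match[0]
                    cells.append(f"{r.count:,} ({format_probability(r.probability, self.rounding)})")
                else:
                    cells.append("")
            lines.append("| /" + "".join(seq) + "/ | " + " | ".join(cells) + " |")
        if self.verdicts:
            lines.append("")
            for lang in sorted(self.verdicts):
                lines.append(f"- {lang}: frequent condition = {self.verdicts[lang]}")
        return "\n".join(lines) + "\n"


def _require_nonempty(lex: Lexicon) -> None:
    if lex.n_types == 0:
        raise EmptyLexiconError("phonotactic measures need a non-empty lexicon")


def _meta(lex: Lexicon) -> tuple[str, str]:
    return str(lex.meta.get("language", "?")), str(lex.meta.get("register", "?"))


def positional_uniphone_probability(
    lex: Lexicon, phoneme: str, position: str = WORD_INITIAL
) -> PhonotacticRow:
    """How often a phoneme occupies a word position, over word types."""
    _require_nonempty(lex)
    if phoneme not in lex.inventory:
        raise LexiconValidationError(f"phoneme {phoneme!r} not in inventory")
    if position not in (WORD_INITIAL, WORD_FINAL):
        raise LexiconValidationError(f"unsupported position {position!r}")
    idx = 0 if position == WORD_INITIAL else -1
    count = sum(1 for e in lex if e.transcription[idx] == phoneme)
    lang, reg = _meta(lex)
    return PhonotacticRow(lang, reg, "uniphone", (phoneme,), position, count, lex.n_types)


def positional_biphone_probability(
    lex: Lexicon, biphone: Sequence[str], position: str = WORD_INITIAL
) -> PhonotacticRow:
    """How often an ordered phoneme pair occupies a word edge, over word types."""
    _require_nonempty(lex)
    pair = tuple(biphone)
    if len(pair) != 2:
        raise LexiconValidationError("biphone must have exactly two phonemes")
    for p in pair:
        if p not in lex.inventory:
            raise LexiconValidationError(f"phoneme {p!r} not in inventory")
    if position not in (WORD_INITIAL, WORD_FINAL):
        raise LexiconValidationError(f"unsupported position {position!r}")
    if position == WORD_INITIAL:
        count = sum(1 for e in lex if e.transcription[:2] == pair)
    else:
        count = sum(1 for e in lex if e.transcription[-2:] == pair and len(e.transcription) >= 2)
    lang, reg = _meta(lex)
    return PhonotacticRow(lang, reg, "biphone", pair, position, count, lex.n_types)


def overall_phoneme_probability(lex: Lexicon, phoneme: str) -> PhonotacticRow:
    """A consonant's share of all consonant occurrences across word types.

    Each word type contributes every one of its consonant slots once
    (type frequency: the word itself is counted once regardless of its
    corpus frequency).
    """
    _require_nonempty(lex)
    if not lex.inventory.is_consonant(phoneme):
        raise LexiconValidationError(f"{phoneme!r} is not a consonant in the inventory")
    count = 0
    denom = 0
    for e in lex:
        for p in e.transcription:
            if lex.inventory.is_consonant(p):
                denom += 1
                if p == phoneme:
                    count += 1
    if denom == 0:
        raise LexiconValidationError("lexicon contains no consonants")
    lang, reg = _meta(lex)
    return PhonotacticRow(lang, reg, "overall", (phoneme,), ANY_POSITION, count, denom)


def contrast_report(
    lexicons: Mapping[str, Lexicon],
    clusters: Sequence[tuple[str, str]] = DEFAULT_CLUSTERS,
    rounding: int = 4,
) -> PhonotacticTable:
    """Cross-language table of the fricative/cluster cells plus a verdict.

    For each language: word-initial uniphone rows for /s/ and /ʃ/ and biphone
    rows for the requested clusters. The per-language verdict names the
    condition (s-initial vs ʃ-initial) whose clusters have the greater summed
    word-initial biphone probability — the "frequent" condition in that
    language.
    """
    if not lexicons:
        raise EmptyLexiconError("contrast_report needs at least one lexicon")
    table = PhonotacticTable(rounding=rounding)
    for lang, lex in lexicons.items():
        for phoneme in ("s", "ʃ"):
            row = positional_uniphone_probability(lex, phoneme)
            table.add(dataclasses.replace(row, language=lang))
        sums = {S_CONDITION: 0.0, SH_CONDITION: 0.0}
        for cluster in clusters:
            row = positional_biphone_probability(lex, cluster)
            table.add(dataclasses.replace(row, language=lang))
            cond = S_CONDITION if cluster[0] == "s" else SH_CONDITION
            sums[cond] += row.probability
        table.verdicts[lang] = max(sums, key=lambda c: (sums[c], c))
    return table
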