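"""Phoneme inventories.

An inventory is the closed set of phoneme symbols a lexicon may use, each
classified as consonant or vowel (optionally with place/manner features).
Symbols are Unicode strings normalised to NFC; comparison is case-sensitive,
so SAMPA-like codes that distinguish /s/ from /S/ survive round trips.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

from .errors import LexiconValidationError

CONSONANT = "consonant"
VOWEL = "vowel"


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class PhonemeInventory:
    """A closed phoneme set with consonant/vowel classification.

    Parameters
    ----------
    class_map
        Mapping from phoneme symbol to ``"consonant"`` or ``"vowel"``.
        Every symbol of the inventory must appear here.
    feature_map
        Optional mapping from phoneme symbol to feature labels such as
        ``{"place": "coronal", "manner": "plosive"}``.
    """

    class_map: dict[str, str]
    feature_map: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_map:
            raise LexiconValidationError("phoneme inventory must be non-empty")
        norm = {}
        for sym, cls in self.class_map.items():
            if sym == "":
                raise LexiconValidationError("empty string is not a valid phoneme symbol")
            if cls not in (CONSONANT, VOWEL):
                raise LexiconValidationError(
                    f"phoneme {sym!r} has class {cls!r}; expected consonant or vowel"
                )
            norm[_nfc(sym)] = cls
        object.__setattr__(self, "class_map", norm)
        object.__setattr__(
            self, "feature_map", {_nfc(k): dict(v) for k, v in self.feature_map.items()}
        )

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.class_map)

    def __contains__(self, phoneme: str) -> bool:
        return _nfc(phoneme) in self.class_map

    def is_consonant(self, phoneme: str) -> bool:
        return self.class_map.get(_nfc(phoneme)) == CONSONANT

    def is_vowel(self, phoneme: str) -> bool:
        return self.class_map.get(_nfc(phoneme)) == VOWEL

    def consonants(self) -> frozenset[str]:
        return frozenset(p for p, c in self.class_map.items() if c == CONSONANT)

    def vowels(self) -> frozenset[str]:
        return frozenset(p for p, c in self.class_map.items() if c == VOWEL)

    def validate_transcription(self, transcription: tuple[str, ...]) -> list[str]:
        """Return the (deduplicated, ordered) symbols not in the inventory."""
        bad, seen = [], set()
        for p in transcription:
            q = _nfc(p)
            if q not in self.class_map and q not in seen:
                bad.append(p)
                seen.add(q)
        return bad


def study_inventory(extra_consonants: tuple[str, ...] = ()) -> PhonemeInventory:
    """Inventory covering the cross-linguistic fricative-cluster study material.

    Contains the contrast fricatives /s, ʃ/, the cluster plosives /t, p/, the
    medial consonants /k, g, d, b, m, n, r/, the six shared vowels
    /a, i, o, u, e, y/, and a handful of common filler consonants so that
    synthetic lexicons can populate non-target word onsets.
    """
    consonants = {
        "s": {"place": "coronal", "manner": "fricative"},
        "ʃ": {"place": "postalveolar", "manner": "fricative"},
        "t": {"place": "coronal", "manner": "plosive"},
        "p": {"place": "labial", "manner": "plosive"},
        "k": {"place": "dorsal", "manner": "plosive"},
        "g": {"place": "dorsal", "manner": "plosive"},
        "d": {"place": "coronal", "manner": "plosive"},
        "b": {"place": "labial", "manner": "plosive"},
        "m": {"place": "labial", "manner": "nasal"},
        "n": {"place": "coronal", "manner": "nasal"},
        "r": {"place": "coronal", "manner": "liquid"},
        "l": {"place": "coronal", "manner": "liquid"},
        "f": {"place": "labial", "manner": "fricative"},
        "v": {"place": "labial", "manner": "fricative"},
        "z": {"place": "coronal", "manner": "fricative"},
        "h": {"place": "glottal", "manner": "fricative"},
        "w": {"place": "labial", "manner": "glide"},
        "j": {"place": "palatal", "manner": "glide"},
    }
    vowels = ("a", "i", "o", "u", "e", "y")
    class_map = {c: CONSONANT for c in consonants}
    class_map.update({c: CONSONANT for c in extra_consonants})
    class_map.update({v: VOWEL for v in vowels})
    return PhonemeInventory(class_map=class_map, feature_map=consonants)
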