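"""Sum (effect) contrast codebook shared by the simulator and the analysis.

All four design factors are two-level and coded −1/+1. The sign convention
is chosen so that the published direction of each effect carries the
published sign: with s-initial = −1, "longer looking times to /s/-initial
lists" appears as a *negative* phonotactics coefficient, and with
block 1 = −1 a *negative* block coefficient encodes the attentional decline
from block 1 to block 2. The codebook is explicit and overridable; flipping
any factor's signs flips the corresponding estimates and nothing else.
"""

from __future__ import annotations

from typing import Mapping

Codebook = Mapping[str, Mapping[object, float]]

DEFAULT_CODEBOOK: dict[str, dict[object, float]] = {
    "language": {"French": 1.0, "German": -1.0},
    "phonotactics": {"s-initial": -1.0, "ʃ-initial": 1.0},
    "pronunciation": {"French": 1.0, "German": -1.0},
    "block": {1: -1.0, 2: 1.0},
}


def code(codebook: Codebook, factor: str, level) -> float:
    try:
        return float(codebook[factor][level])
    except KeyError as exc:
        raise KeyError(f"no contrast code for {factor}={level!r}") from exc


def flipped(codebook: Codebook, factor: str) -> dict[str, dict[object, float]]:
    """A copy of the codebook with one factor's signs reversed."""
    out = {f: dict(m) for f, m in codebook.items()}
    out[factor] = {lvl: -c for lvl, c in out[factor].items()}
    return out
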