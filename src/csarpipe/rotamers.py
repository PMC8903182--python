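"""Discrete rotamer state space of a hexitol.

A hexitol such as D-mannitol has five O-C-C-O backbone torsions (labelled
alpha..epsilon).  Each torsion sits near one of three staggered wells --
trans (T, 180 deg), gauche+ (P, +60 deg) or gauche- (N, -60 deg) -- so a
conformer is a 5-letter word over {T, P, N} and there are 3**5 = 243 rotamer
states.  This module owns the word <-> index encoding and the angle -> letter
classification used throughout the package.

Encoding: ``index = 1 + sum_i d_i * 3**(4-i)`` with digit map T->0, P->1,
N->2 and the alpha torsion most significant; indices run 1..243 and
"TTTTT" is state 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_TORSIONS = 5
N_STATES = 3**N_TORSIONS  # 243

LETTERS = "TPN"
LETTER_TO_DIGIT = {"T": 0, "P": 1, "N": 2}

#: Canonical well centers in degrees.
STATE_CENTERS = {"T": 180.0, "P": 60.0, "N": -60.0}

#: The crystal-forming rotamer of beta-D-mannitol.
CFR_WORD = "NTPTN"
#: The dominant rotamer in bulk solution.
BR_WORD = "TTPTT"
#: The two surface-favoured "release" rotamers.
RELEASE_WORDS = ("NNNPN", "NPTNP")

TORSION_LABELS = ("alpha", "beta", "gamma", "delta", "epsilon")


def word_to_index(word: str) -> int:
    """Map a 5-letter rotamer word to its 1-based index."""
    _check_word(word)
    idx = 0
    for letter in word:
        idx = idx * 3 + LETTER_TO_DIGIT[letter]
    return idx + 1


def index_to_word(index: int) -> str:
    """Inverse of :func:`word_to_index`."""
    if not 1 <= index <= N_STATES:
        raise ValueError(f"rotamer index {index} outside 1..{N_STATES}")
    digits = []
    k = index - 1
    for _ in range(N_TORSIONS):
        digits.append(k % 3)
        k //= 3
    return "".join(LETTERS[d] for d in reversed(digits))


def _check_word(word: str) -> None:
    if len(word) != N_TORSIONS or any(c not in LETTER_TO_DIGIT for c in word):
        raise ValueError(
            f"invalid rotamer word {word!r}: need 5 letters over {{T,P,N}}"
        )


@dataclass(frozen=True)
class RotamerState:
    """One of the 243 conformer states, addressable by word or index."""

    word: str

    def __post_init__(self) -> None:
        _check_word(self.word)

    @property
    def index(self) -> int:
        return word_to_index(self.word)

    @classmethod
    def from_index(cls, index: int) -> "RotamerState":
        return cls(index_to_word(index))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.word} (#{self.index})"


def enumerate_rotamers() -> list[RotamerState]:
    """All 243 states sorted by index ("TTTTT" first)."""
    return [RotamerState.from_index(i) for i in range(1, N_STATES + 1)]


def wrap_angle(angle):
    """Wrap angles (degrees) to the canonical range [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def classify_torsion(angle: float) -> str:
    """Classify a single torsion angle (degrees) into T/P/N.

    Boundaries sit at +-120 deg, midway between the canonical wells
    (a symmetric Voronoi partition of {180, +60, -60}); an exact 0 deg
    (cis) has no well of its own and ties to P.
    """
    a = float(wrap_angle(angle))
    if abs(a) >= 120.0:
        return "T"
    return "P" if a >= 0.0 else "N"


def classify_digits(angles) -> np.ndarray:
    """Vectorized torsion classification to digits (T=0, P=1, N=2)."""
    a = wrap_angle(angles)
    return np.where(np.abs(a) >= 120.0, 0, np.where(a >= 0.0, 1, 2))


def classify_words_to_indices(angles) -> np.ndarray:
    """Classify an (n, 5) array of torsions into 1-based state indices."""
    a = np.atleast_2d(np.asarray(angles, dtype=float))
    if a.shape[1] != N_TORSIONS:
        raise ValueError(f"expected {N_TORSIONS} torsions per frame, got {a.shape[1]}")
    digits = classify_digits(a)
    weights = 3 ** np.arange(N_TORSIONS - 1, -1, -1)
    return digits @ weights + 1


def centers_for_indices(indices) -> np.ndarray:
    """Canonical (n, 5) torsion centers in degrees for 1-based state indices."""
    table = np.empty((N_STATES, N_TORSIONS))
    for i in range(N_STATES):
        word = index_to_word(i + 1)
        table[i] = [STATE_CENTERS[c] for c in word]
    return table[np.asarray(indices, dtype=int) - 1]
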