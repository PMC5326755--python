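"""Letter-string encoding into positional visual-feature vectors.

A word is presented to the network as a position x feature binary array:
row ``p`` is the 14-segment feature code of the letter in position ``p``.
The feature level operates in parallel across positions, so the code of a
letter does not depend on where it appears.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

N_FEATURES = 14


class EncodingError(ValueError):
    """Raised when a letter string cannot be encoded with the given font."""


class FontError(ValueError):
    """Raised when a font table violates its invariants."""


class FeatureFont:
    """A fixed segment font: one binary 14-feature code per letter.

    Codes must be unique (so decoding by nearest code is well defined) and
    non-empty (a letter with no features would be invisible to the network).
    """

    def __init__(self, codes: Mapping[str, Iterable[int]]):
        self._codes: dict[str, np.ndarray] = {}
        for letter, bits in codes.items():
            arr = np.asarray(list(bits), dtype=np.float64)
            if arr.shape != (N_FEATURES,) or not np.isin(arr, (0.0, 1.0)).all():
                raise FontError(f"letter {letter!r}: code must be 14 binary flags")
            if arr.sum() < 1:
                raise FontError(f"letter {letter!r} uses no features")
            self._codes[letter] = arr
        seen: dict[tuple, str] = {}
        for letter, arr in self._codes.items():
            key = tuple(arr.astype(int))
            if key in seen:
                raise FontError(f"letters {seen[key]!r} and {letter!r} share a code")
            seen[key] = letter

    @property
    def alphabet(self) -> tuple[str, ...]:
        return tuple(sorted(self._codes))

    def __contains__(self, letter: str) -> bool:
        return letter in self._codes

    def __getitem__(self, letter: str) -> np.ndarray:
        return self._codes[letter].copy()

    def code_matrix(self, alphabet: Iterable[str] | None = None) -> np.ndarray:
        """Stack letter codes into an (n_letters, 14) array (sorted alphabet)."""
        letters = list(alphabet) if alphabet is not None else list(self.alphabet)
        return np.stack([self._codes[c] for c in letters])

    def decode(self, row: np.ndarray) -> str:
        """Nearest-code letter for one feature row (Hamming distance)."""
        row = np.asarray(row, dtype=np.float64)
        letters = self.alphabet
        dists = [int(np.abs(self._codes[c] - row).sum()) for c in letters]
        return letters[int(np.argmin(dists))]


def load_font(path: str | Path) -> FeatureFont:
    """Read a plain-text font table: letter + 14 binary flags per line."""
    codes: dict[str, list[int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 1 + N_FEATURES:
            raise FontError(f"{path}:{lineno}: expected letter + 14 flags")
        codes[parts[0]] = [int(x) for x in parts[1:]]
    return FeatureFont(codes)


def default_font() -> FeatureFont:
    """The shipped 14-segment uppercase font."""
    with resources.as_file(
        resources.files("iaread.data").joinpath("font14.tsv")
    ) as path:
        return load_font(path)


def encode_word(orthography: str, font: FeatureFont) -> np.ndarray:
    """Encode a letter string as a (length, 14) binary feature array.

    Raises :class:`EncodingError` naming the first letter missing from the
    font.
    """
    rows = []
    for letter in orthography:
        if letter not in font:
            raise EncodingError(f"letter {letter!r} not in font")
        rows.append(font[letter])
    if not rows:
        raise EncodingError("empty orthography")
    return np.stack(rows)
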