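"""Synthetic lexicons with the statistical structure the analysis assumes.

The generator emulates a naming corpus of fixed-length monosyllabic items:
two target frequency bands (high and low) embedded in a larger background
vocabulary, so that orthographic neighbours exist and lexical competition
is non-trivial.  Word frequency enters the model through the resting
activation of lexical units: a word's resting level is a normalised log
frequency mapped into ``[-frequency_scaling, 0]``, the conventional
localist mechanism for frequency effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .params import ModelParameters
from .routes import GPCRule, one_to_one_rules, translate_prefix

BANDS = ("high", "low", "background")

DEFAULT_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class LexiconError(ValueError):
    """Raised for infeasible specs or invalid lexicon inputs."""


@dataclass(frozen=True)
class LexiconEntry:
    """One word: spelling, pronunciation, frequency and derived resting level."""

    orthography: str
    phonology: str
    frequency: float  # occurrences per million, > 0
    frequency_band: str = "background"
    resting_level: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise LexiconError(f"{self.orthography}: frequency must be > 0")
        if self.frequency_band not in BANDS:
            raise LexiconError(f"unknown frequency band {self.frequency_band!r}")


@dataclass(frozen=True)
class LexiconSpec:
    """Parameters of the synthetic corpus.

    Frequency distributions are log10-normal per band (location/scale on
    the log10 per-million scale); high-band words are drawn well above
    low-band words.  ``p_exception`` is the proportion of words whose
    lexical pronunciation deviates from the rule translation of their
    spelling.  ``yoked_pairs`` makes each low-band word a one-letter
    mutation of a high-band word so the two bands have closely matched
    orthographic neighbourhoods.  ``neighbor_fraction`` of background words
    are one-letter mutations of target words, guaranteeing orthographic
    neighbours for the targets.
    """

    alphabet: str = DEFAULT_ALPHABET
    word_length: int = 4
    n_high: int = 70
    n_low: int = 68
    n_background: int = 500
    freq_log10_loc: dict = field(
        default_factory=lambda: {"high": 2.2, "low": 0.7, "background": 1.2}
    )
    freq_log10_scale: dict = field(
        default_factory=lambda: {"high": 0.30, "low": 0.30, "background": 0.50}
    )
    p_exception: float = 0.10
    yoked_pairs: bool = True
    neighbor_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 1 or self.n_low < 1:
            raise LexiconError("n_high and n_low must be positive")
        if not (0.0 <= self.p_exception <= 1.0):
            raise LexiconError("p_exception must lie in [0, 1]")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise LexiconError("alphabet letters must be unique")
        if self.freq_log10_loc["high"] <= self.freq_log10_loc["low"]:
            raise LexiconError("high band must sit above low band in frequency")

    @property
    def n_total(self) -> int:
        return self.n_high + self.n_low + self.n_background


def frequency_to_resting(
    frequency: float, f_max: float, params: ModelParameters
) -> float:
    """Map a per-million frequency to a lexical resting level.

    ``resting = s * (log10(f + 1) / log10(f_max + 1) - 1)`` with
    ``s = frequency_scaling``: zero for the most frequent word, approaching
    ``-s`` as frequency goes to zero, strictly increasing in between.
    """
    if frequency <= 0:
        raise LexiconError(f"frequency must be > 0, got {frequency}")
    if f_max < frequency:
        raise LexiconError("f_max must be >= frequency")
    s = params.frequency_scaling
    return s * (math.log10(frequency + 1.0) / math.log10(f_max + 1.0) - 1.0)


def assign_resting_levels(
    entries: Sequence[LexiconEntry], params: ModelParameters
) -> list[LexiconEntry]:
    """Recompute every resting level from the lexicon's frequency maximum."""
    f_max = max(e.frequency for e in entries)
    return [
        replace(e, resting_level=frequency_to_resting(e.frequency, f_max, params))
        for e in entries
    ]


def _rule_phonology(orth: str, rules: Sequence[GPCRule]) -> str:
    assignments, untranslatable = translate_prefix(orth, rules, len(orth))
    if untranslatable:
        raise LexiconError(f"no rule translation for {orth!r}")
    return "".join(a.phoneme for a in assignments)


def _mutate(word: str, alphabet: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(word)))
    choices = [c for c in alphabet if c != word[pos]]
    letter = choices[int(rng.integers(len(choices)))]
    return word[:pos] + letter + word[pos + 1 :]


def generate_lexicon(
    spec: LexiconSpec,
    params: ModelParameters | None = None,
    rules: Sequence[GPCRule] | None = None,
) -> list[LexiconEntry]:
    """Generate a reproducible synthetic lexicon from a spec.

    Orthographies are unique; pronunciations follow the GPC rule
    translation except for the exception words, whose pronunciation is
    perturbed at one position.  Raises :class:`LexiconError` when the spec
    asks for more unique words than the alphabet affords.
    """
    params = params or ModelParameters()
    rules = list(rules) if rules is not None else one_to_one_rules(spec.alphabet)
    capacity = len(spec.alphabet) ** spec.word_length
    if spec.n_total > capacity // 2:
        raise LexiconError(
            f"spec asks for {spec.n_total} unique words; alphabet supports "
            f"only {capacity} strings of length {spec.word_length}"
        )
    rng = np.random.default_rng(spec.seed)
    used: set[str] = set()

    def fresh_random() -> str:
        while True:
            word = "".join(
                spec.alphabet[i]
                for i in rng.integers(len(spec.alphabet), size=spec.word_length)
            )
            if word not in used:
                used.add(word)
                return word

    def fresh_neighbor(base: str) -> str:
        for _ in range(200):
            word = _mutate(base, spec.alphabet, rng)
            if word not in used:
                used.add(word)
                return word
        return fresh_random()

    high = [fresh_random() for _ in range(spec.n_high)]
    if spec.yoked_pairs:
        low = [fresh_neighbor(high[i % len(high)]) for i in range(spec.n_low)]
    else:
        low = [fresh_random() for _ in range(spec.n_low)]

    targets = high + low
    n_neighbor_bg = min(spec.n_background, int(round(spec.neighbor_fraction * len(targets))))
    background = [
        fresh_neighbor(targets[int(rng.integers(len(targets)))])
        for _ in range(n_neighbor_bg)
    ]
    background += [fresh_random() for _ in range(spec.n_background - n_neighbor_bg)]

    phoneme_inventory = sorted({r.phoneme for r in rules})
    entries: list[LexiconEntry] = []
    for band, words in (("high", high), ("low", low), ("background", background)):
        freqs = 10.0 ** rng.normal(
            spec.freq_log10_loc[band], spec.freq_log10_scale[band], size=len(words)
        )
        for word, freq in zip(words, freqs):
            phon = _rule_phonology(word, rules)
            if rng.random() < spec.p_exception:
                pos = int(rng.integers(len(phon)))
                others = [p for p in phoneme_inventory if p != phon[pos]]
                phon = phon[:pos] + others[int(rng.integers(len(others)))] + phon[pos + 1 :]
            entries.append(
                LexiconEntry(
                    orthography=word,
                    phonology=phon,
                    frequency=float(freq),
                    frequency_band=band,
                )
            )
    return assign_resting_levels(entries, params)


def with_frequency(
    lexicon: Sequence[LexiconEntry],
    orthography: str,
    frequency: float,
    params: ModelParameters | None = None,
) -> list[LexiconEntry]:
    """Counterfactual lexicon: one word's frequency changed, all else equal.

    This is the cleanest frequency control available: the word keeps its
    spelling, pronunciation and orthographic neighbourhood, so any change
    in naming cycles is attributable to frequency (via the resting level)
    alone.
    """
    params = params or ModelParameters()
    if all(e.orthography != orthography for e in lexicon):
        raise LexiconError(f"{orthography!r} not in lexicon")
    entries = [
        replace(e, frequency=frequency) if e.orthography == orthography else e
        for e in lexicon
    ]
    return assign_resting_levels(entries, params)


def target_entries(lexicon: Sequence[LexiconEntry]) -> list[LexiconEntry]:
    """The high- and low-band words (the items submitted to the experiment)."""
    return [e for e in lexicon if e.frequency_band in ("high", "low")]


def write_lexicon(path: str | Path, lexicon: Sequence[LexiconEntry]) -> None:
    """Write a plain-text lexicon table (orthography, phonology, frequency, band)."""
    lines = ["orthography\tphonology\tfrequency\tband"]
    for e in lexicon:
        lines.append(f"{e.orthography}\t{e.phonology}\t{e.frequency:.6g}\t{e.frequency_band}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lexicon(
    path: str | Path, params: ModelParameters | None = None
) -> list[LexiconEntry]:
    """Read a lexicon table and recompute resting levels."""
    params = params or ModelParameters()
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:4] != ["orthography", "phonology", "frequency", "band"]:
        raise LexiconError(f"{path}: missing lexicon header")
    entries = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise LexiconError(f"{path}:{lineno}: expected 4 tab-separated fields")
        orth, phon, freq, band = parts
        if orth in seen:
            raise LexiconError(f"{path}:{lineno}: duplicate orthography {orth!r}")
        seen.add(orth)
        entries.append(
            LexiconEntry(
                orthography=orth,
                phonology=phon,
                frequency=float(freq),
                frequency_band=band,
            )
        )
    return assign_resting_levels(entries, params)
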