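"""The two pathways: lexical-route manipulations and the non-lexical route.

The lexical route (feature -> letter -> orthographic lexicon -> phonological
lexicon -> phoneme) is interactive by default; :func:`disable_feedback`
surgically zeroes its three backward weight groups, converting it to a pure
feed-forward cascade while leaving every forward weight untouched.

Stimulus quality is a multiplicative reduction applied at one of two loci:
the external input to the feature level, or the feature-to-letter
connection weights.  :func:`apply_stimulus_quality` implements both.

The non-lexical route translates the letter string into phonemes with
grapheme-phoneme correspondence (GPC) rules, applied longest-match-first
over a left-to-right prefix that grows as cycles pass (semi-serial
processing).  It is purely feed-forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .params import FEATURE_LETTER_WEIGHT_FIELDS, FEEDBACK_WEIGHT_FIELDS, ModelParameters

SQ_LOCI = ("feature-input", "feature-letter-weights")
POSITION_CLASSES = ("any", "initial", "final")


class GPCRuleError(ValueError):
    """Raised for malformed rules or rule files."""


class StimulusQualityError(ValueError):
    """Raised for an out-of-range stimulus-quality factor or unknown locus."""


@dataclass(frozen=True)
class GPCRule:
    """One grapheme-phoneme correspondence.

    ``position_class`` restricts where the rule may apply: ``initial`` only
    at the first letter, ``final`` only when the grapheme ends at the last
    letter, ``any`` elsewhere.  At a given letter position, rules with
    longer graphemes take precedence.
    """

    grapheme: str
    phoneme: str
    position_class: str = "any"

    def __post_init__(self) -> None:
        if not self.grapheme:
            raise GPCRuleError("grapheme must be non-empty")
        if not self.phoneme:
            raise GPCRuleError("phoneme must be non-empty")
        if self.position_class not in POSITION_CLASSES:
            raise GPCRuleError(f"unknown position class {self.position_class!r}")


@dataclass(frozen=True)
class GPCAssignment:
    """One applied rule: which phoneme it drives, from which letter span."""

    phoneme_position: int
    phoneme: str
    letter_start: int
    letter_length: int


@dataclass(frozen=True)
class RouteConfig:
    """Which dynamics are in play for one simulation condition.

    ``sq_factor`` is the fraction of the default input strength (1.0 =
    clear); the factorial design uses {0.20, 0.40, 0.60, 0.80, 1.00}, but
    any fraction in (0, 1] is allowed for exploration.
    """

    feedback_enabled: bool = True
    nonlexical_enabled: bool = True
    sq_locus: str = "feature-input"
    sq_factor: float = 1.0
    staged_feature_mode: bool = False

    def __post_init__(self) -> None:
        if self.sq_locus not in SQ_LOCI:
            raise StimulusQualityError(f"unknown stimulus-quality locus {self.sq_locus!r}")
        if not (0.0 < self.sq_factor <= 1.0):
            raise StimulusQualityError(
                f"sq_factor must lie in (0, 1], got {self.sq_factor}"
            )


def disable_feedback(params: ModelParameters) -> ModelParameters:
    """Zero all between-level feedback weights along the lexical route.

    Only the three backward weight groups change; the operation is
    idempotent.
    """
    return params.replace(**{name: 0.0 for name in FEEDBACK_WEIGHT_FIELDS})


def apply_stimulus_quality(
    params: ModelParameters, locus: str, factor: float
) -> ModelParameters:
    """Scale the input strength at the chosen locus by ``factor``.

    ``feature-input`` scales the external drive to the feature level;
    ``feature-letter-weights`` scales the feature-to-letter excitatory and
    inhibitory weights.  ``factor`` must lie in (0, 1]; 1.0 is the identity.
    """
    if not (0.0 < factor <= 1.0):
        raise StimulusQualityError(f"factor must lie in (0, 1], got {factor}")
    if locus == "feature-input":
        return params.replace(
            feature_external_input=params.feature_external_input * factor
        )
    if locus == "feature-letter-weights":
        return params.replace(
            **{
                name: getattr(params, name) * factor
                for name in FEATURE_LETTER_WEIGHT_FIELDS
            }
        )
    raise StimulusQualityError(f"unknown stimulus-quality locus {locus!r}")


def parse_gpc_rules(path: str | Path) -> list[GPCRule]:
    """Read a rule table: ``grapheme<TAB>phoneme<TAB>position-class`` lines."""
    rules = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GPCRuleError(f"{path}:{lineno}: expected 3 tab-separated fields")
        rules.append(GPCRule(parts[0], parts[1], parts[2]))
    return rules


def default_gpc_rules() -> list[GPCRule]:
    """The shipped rule table (one-to-one letters plus multi-letter rules)."""
    from importlib import resources

    with resources.as_file(
        resources.files("iaread.data").joinpath("gpc_default.tsv")
    ) as path:
        return parse_gpc_rules(path)


def one_to_one_rules(alphabet: Iterable[str]) -> list[GPCRule]:
    """Letter -> lowercase-phoneme rules for a synthetic alphabet."""
    return [GPCRule(letter, letter.lower(), "any") for letter in alphabet]


def exposed_letter_count(cycle: int, word_length: int, params: ModelParameters) -> int:
    """Letters available to the GPC route at the given cycle.

    Zero before ``gpc_onset_cycle``; afterwards one letter plus one more per
    ``gpc_letter_interval`` cycles, capped at the word length (left-to-right
    semi-serial exposure).
    """
    if cycle < params.gpc_onset_cycle:
        return 0
    k = 1 + (cycle - params.gpc_onset_cycle) // params.gpc_letter_interval
    return min(word_length, k)


def translate_prefix(
    letters: str, rules: Sequence[GPCRule], exposed: int, word_length: int | None = None
) -> tuple[list[GPCAssignment], bool]:
    """Apply rules longest-match-first over the exposed prefix.

    Returns ``(assignments, untranslatable)``.  A grapheme matches only if
    fully inside the exposed prefix and its position class allows it.  If a
    letter has no applicable rule, translation stops there and the flag is
    set; a trial can still complete through the lexical route.
    """
    if word_length is None:
        word_length = len(letters)
    by_len = sorted(rules, key=lambda r: len(r.grapheme), reverse=True)
    out: list[GPCAssignment] = []
    pos = 0
    phon_pos = 0
    exposed = min(exposed, len(letters))
    while pos < exposed:
        matched = None
        for rule in by_len:
            g = rule.grapheme
            if pos + len(g) > exposed:
                continue
            if letters[pos : pos + len(g)] != g:
                continue
            if rule.position_class == "initial" and pos != 0:
                continue
            if rule.position_class == "final" and pos + len(g) != word_length:
                continue
            matched = rule
            break
        if matched is None:
            return out, True
        out.append(
            GPCAssignment(
                phoneme_position=phon_pos,
                phoneme=matched.phoneme,
                letter_start=pos,
                letter_length=len(matched.grapheme),
            )
        )
        pos += len(matched.grapheme)
        phon_pos += 1
    return out, False


def gpc_translate(
    letters: str,
    rules: Sequence[GPCRule],
    cycle: int,
    params: ModelParameters,
) -> tuple[list[GPCAssignment], bool]:
    """Phoneme assignments driven by the non-lexical route at one cycle.

    Combines the semi-serial exposure schedule with longest-match rule
    application.  Purely feed-forward: the result depends only on the letter
    string, the rules and the cycle, never on any lexical-route state.
    """
    exposed = exposed_letter_count(cycle, len(letters), params)
    if exposed == 0:
        return [], False
    return translate_prefix(letters, rules, exposed, word_length=len(letters))
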