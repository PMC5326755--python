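"""The factorial simulation design and the accuracy-screening procedure.

The full design orthogonally crosses the presence/absence of interactive
activation (feedback), the locus of the stimulus-quality manipulation, and
its strength.  The clear condition (100%) is identical at both loci, so it
is simulated once per feedback setting and reused in every pairing.

Before the experiment proper, an accuracy screen runs the target items at a
sweep of stimulus-quality levels (feedback on) and reports every naming
error; words that err at or above the analysis floor are excluded listwise
from all cells so every analysed condition uses the same item set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .ia_core import Network
from .params import ModelParameters
from .routes import SQ_LOCI, GPCRule, RouteConfig
from .stimuli import FeatureFont
from .synthetic_lexicon import LexiconEntry, target_entries

IA_LEVELS = ("on", "off")
DEFAULT_SQ_PERCENTS = (20, 40, 60, 80, 100)

TRIAL_COLUMNS = (
    "word",
    "band",
    "ia",
    "locus",
    "sq_percent",
    "cycles",
    "correct",
    "named_within_limit",
    "produced",
    "tie",
)


class DesignError(ValueError):
    """Raised for malformed condition descriptors or designs."""


@dataclass(frozen=True)
class ConditionDescriptor:
    """One cell of the factorial design.

    ``sq_percent`` is the percentage of the default input strength; 100 is
    the high-stimulus-quality condition in every pairing.
    """

    ia: str
    locus: str
    sq_percent: int
    word_set: str = "targets"

    def __post_init__(self) -> None:
        if self.ia not in IA_LEVELS:
            raise DesignError(f"ia must be one of {IA_LEVELS}, got {self.ia!r}")
        if self.locus not in SQ_LOCI:
            raise DesignError(f"unknown locus {self.locus!r}")
        if not (0 < self.sq_percent <= 100):
            raise DesignError(f"sq_percent must lie in (0, 100], got {self.sq_percent}")


def full_design(
    sq_percents: Sequence[int] = DEFAULT_SQ_PERCENTS,
    loci: Sequence[str] = SQ_LOCI,
    ia_levels: Sequence[str] = IA_LEVELS,
) -> list[ConditionDescriptor]:
    """The complete ia x locus x stimulus-quality crossing."""
    return [
        ConditionDescriptor(ia=ia, locus=locus, sq_percent=int(pct))
        for ia in ia_levels
        for locus in loci
        for pct in sq_percents
    ]


@dataclass
class ScreeningReport:
    """Accuracy-screen outcome over a stimulus-quality sweep."""

    locus: str
    floor: int
    errors_by_percent: pd.DataFrame  # columns: percent, n_errors, words
    exclusions: list[str] = field(default_factory=list)

    @property
    def highest_error_percent(self) -> int | None:
        """The highest quality level at which any error appears."""
        errs = self.errors_by_percent
        bad = errs.loc[errs["n_errors"] > 0, "percent"]
        return int(bad.max()) if len(bad) else None


def _run_condition(
    lexicon: Sequence[LexiconEntry],
    entries: Sequence[LexiconEntry],
    params: ModelParameters,
    ia: str,
    locus: str,
    sq_percent: int,
    font: FeatureFont | None,
    rules: Sequence[GPCRule] | None,
    nonlexical: bool,
) -> list:
    config = RouteConfig(
        feedback_enabled=(ia == "on"),
        nonlexical_enabled=nonlexical,
        sq_locus=locus,
        sq_factor=sq_percent / 100.0,
    )
    net = Network(lexicon, params=params, config=config, font=font, rules=rules)
    return net.run_trials(entries)


def run_grid(
    lexicon: Sequence[LexiconEntry],
    design: Sequence[ConditionDescriptor],
    params: ModelParameters | None = None,
    font: FeatureFont | None = None,
    rules: Sequence[GPCRule] | None = None,
    nonlexical: bool = True,
) -> pd.DataFrame:
    """One naming trial per target word x condition; deterministic.

    At 100% stimulus quality the two loci are the same simulation, so each
    feedback setting's clear condition is computed once and reused.  Trials
    that fail to name within ``max_cycles`` are retained with
    ``named_within_limit=False`` (downstream analysis excludes those words
    listwise).
    """
    params = params or ModelParameters()
    if not design:
        raise DesignError("empty design")
    word_sets = {d.word_set for d in design}
    if word_sets != {"targets"}:
        raise DesignError(f"all conditions must reference the same word set, got {word_sets}")
    entries = target_entries(lexicon)
    if not entries:
        raise DesignError("lexicon has no target (high/low band) words")
    band = {e.orthography: e.frequency_band for e in entries}

    cache: dict[tuple, list] = {}
    rows = []
    for cond in design:
        # locus is irrelevant at 100%: factor 1.0 is the identity at either
        key = (cond.ia, None if cond.sq_percent == 100 else cond.locus, cond.sq_percent)
        if key not in cache:
            cache[key] = _run_condition(
                lexicon, entries, params, cond.ia, cond.locus, cond.sq_percent,
                font, rules, nonlexical,
            )
        for res in cache[key]:
            rows.append(
                {
                    "word": res.orthography,
                    "band": band[res.orthography],
                    "ia": cond.ia,
                    "locus": cond.locus,
                    "sq_percent": cond.sq_percent,
                    "cycles": res.cycles_to_name,
                    "correct": res.correct,
                    "named_within_limit": res.named_within_limit,
                    "produced": res.produced_phonology,
                    "tie": res.tie,
                }
            )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def accuracy_screen(
    lexicon: Sequence[LexiconEntry],
    locus: str,
    params: ModelParameters | None = None,
    percents: Sequence[int] = DEFAULT_SQ_PERCENTS,
    floor: int = 20,
    font: FeatureFont | None = None,
    rules: Sequence[GPCRule] | None = None,
    nonlexical: bool = True,
) -> ScreeningReport:
    """Run the default (feedback-on) model over a stimulus-quality sweep.

    Reports the error count and erred words per level, and the exclusion
    list: every word that errs (wrong pronunciation or failure to name) at
    any level at or above ``floor``.
    """
    params = params or ModelParameters()
    entries = target_entries(lexicon)
    records = []
    excluded: set[str] = set()
    for pct in sorted(int(p) for p in percents):
        results = _run_condition(
            lexicon, entries, params, "on", locus, pct, font, rules, nonlexical
        )
        bad = [r.orthography for r in results if not r.correct]
        records.append({"percent": pct, "n_errors": len(bad), "words": bad})
        if pct >= floor:
            excluded.update(bad)
    return ScreeningReport(
        locus=locus,
        floor=floor,
        errors_by_percent=pd.DataFrame(records),
        exclusions=sorted(excluded),
    )


def nonnaming_words(trials: pd.DataFrame) -> list[str]:
    """Words that failed to reach threshold in any condition (excluded listwise)."""
    mask = ~trials["named_within_limit"].astype(bool)
    return sorted(trials.loc[mask, "word"].unique())


def apply_exclusions(trials: pd.DataFrame, exclusions: Sequence[str]) -> pd.DataFrame:
    """Drop all rows of the excluded words from every condition.

    Keeps the item set identical across cells; raises if an exclusion is
    not a word in the table.
    """
    words = set(trials["word"].unique())
    unknown = [w for w in exclusions if w not in words]
    if unknown:
        raise DesignError(f"exclusions not in trial table: {unknown}")
    return trials[~trials["word"].isin(set(exclusions))].reset_index(drop=True)
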