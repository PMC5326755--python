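"""Shared fixtures: toy networks, small lexicons, and the full-grid run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from iaread import (
    FeatureFont,
    LexiconEntry,
    LexiconSpec,
    ModelParameters,
    generate_lexicon,
    one_to_one_rules,
)
from iaread.experiment import (
    accuracy_screen,
    apply_exclusions,
    full_design,
    nonnaming_words,
    run_grid,
)
from iaread.routes import SQ_LOCI
from iaread.synthetic_lexicon import assign_resting_levels


def make_toy_font(alphabet: str, rng: np.random.Generator) -> FeatureFont:
    """Random unique non-empty 14-feature codes for a small alphabet."""
    codes = {}
    seen = set()
    for letter in alphabet:
        while True:
            bits = tuple(int(b) for b in rng.integers(0, 2, size=14))
            if sum(bits) >= 1 and bits not in seen:
                seen.add(bits)
                codes[letter] = bits
                break
    return FeatureFont(codes)


def make_toy_lexicon(
    alphabet: str,
    length: int,
    n_words: int,
    rng: np.random.Generator,
    params: ModelParameters,
) -> list[LexiconEntry]:
    from itertools import product

    universe = ["".join(p) for p in product(alphabet, repeat=length)]
    n_words = min(n_words, len(universe))
    idx = rng.permutation(len(universe))[:n_words]
    words = [universe[i] for i in idx]
    entries = [
        LexiconEntry(
            orthography=w,
            phonology=w.lower(),
            frequency=float(10 ** rng.uniform(0, 3)),
            frequency_band="background",
        )
        for w in sorted(words)
    ]
    return assign_resting_levels(entries, params)


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def small_lexicon(default_params):
    """A compact but complete synthetic corpus (fast tests)."""
    spec = LexiconSpec(seed=7, n_high=12, n_low=12, n_background=60)
    return spec, generate_lexicon(spec, default_params)


@pytest.fixture(scope="session")
def study_lexicon(default_params):
    """The study-sized corpus: 70 high, 68 low, 500 background words."""
    spec = LexiconSpec(seed=11)
    return spec, generate_lexicon(spec, default_params)


@pytest.fixture(scope="session")
def study_trials(study_lexicon, default_params):
    """Screen, run and clean the full 2 x 2 x 5 grid on the study corpus."""
    spec, lexicon = study_lexicon
    rules = one_to_one_rules(spec.alphabet)
    exclusions: set[str] = set()
    screens = {}
    for locus in SQ_LOCI:
        report = accuracy_screen(lexicon, locus, default_params, rules=rules)
        screens[locus] = report
        exclusions.update(report.exclusions)
    trials = run_grid(lexicon, full_design(), default_params, rules=rules)
    exclusions.update(nonnaming_words(trials))
    clean = apply_exclusions(trials, sorted(exclusions))
    return {
        "lexicon": lexicon,
        "spec": spec,
        "trials": trials,
        "clean": clean,
        "screens": screens,
        "exclusions": sorted(exclusions),
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
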