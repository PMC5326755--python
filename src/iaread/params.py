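"""Model parameters for the interactive-activation dual-route network.

All connection weights are stored as non-negative magnitudes; whether a
weight excites or inhibits is carried by its role (the field name), not by
its sign.  Feedback weights are the three backward connection groups along
the lexical route (word-to-letter, phonological-word-to-orthographic-word,
phoneme-to-phonological-word); zeroing them turns the lexical route into a
purely feed-forward cascade.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


#: Fields that carry backward (feedback) activation along the lexical route.
FEEDBACK_WEIGHT_FIELDS = (
    "orth_letter_feedback_excitation",
    "orth_letter_feedback_inhibition",
    "phon_orth_feedback_excitation",
    "phoneme_phon_feedback_excitation",
)

#: Fields scaled by a stimulus-quality manipulation at the feature-letter locus.
FEATURE_LETTER_WEIGHT_FIELDS = (
    "feature_letter_excitation",
    "feature_letter_inhibition",
)


@dataclass(frozen=True)
class ModelParameters:
    """Every weight, decay, clamp, threshold and schedule constant.

    Defaults are conventional for this family of localist reading models and
    are deliberately surfaced here (and in config files) rather than
    hard-coded anywhere: the published literature does not pin down a single
    canonical set, and every value below can be overridden.

    Units: activations are dimensionless in ``[activation_min,
    activation_max]``; weights are net-input units per unit of sender
    activation per cycle; schedule constants are in cycles.
    """

    activation_min: float = -1.0
    activation_max: float = 1.0
    decay_rate: float = 0.15

    # External drive to the feature level, per present feature per cycle.
    # 1.0 represents a clear (undegraded) stimulus.
    feature_external_input: float = 1.0

    # feature -> letter
    feature_letter_excitation: float = 0.035
    feature_letter_inhibition: float = 0.30

    # letter -> orthographic lexicon
    letter_orth_excitation: float = 0.08
    letter_orth_inhibition: float = 0.30

    # orthographic lexicon -> letter (feedback)
    orth_letter_feedback_excitation: float = 0.15
    orth_letter_feedback_inhibition: float = 0.0

    # orthographic lexicon -> phonological lexicon (forward)
    orth_phon_excitation: float = 0.60

    # phonological lexicon -> orthographic lexicon (feedback)
    phon_orth_feedback_excitation: float = 0.15

    # phonological lexicon -> phoneme
    phon_phoneme_excitation: float = 0.50
    phon_phoneme_inhibition: float = 0.0

    # phoneme -> phonological lexicon (feedback)
    phoneme_phon_feedback_excitation: float = 0.05

    # grapheme-phoneme route -> phoneme
    gpc_phoneme_excitation: float = 0.25

    # lateral (within-layer) inhibition
    feature_lateral_inhibition: float = 0.0
    letter_lateral_inhibition: float = 0.02
    orth_lateral_inhibition: float = 0.03
    phon_lateral_inhibition: float = 0.03
    phoneme_lateral_inhibition: float = 0.06

    # frequency -> resting level scaling (magnitude of the largest deficit)
    frequency_scaling: float = 0.30

    # response read-out and non-lexical route schedule
    phoneme_naming_threshold: float = 0.43
    gpc_onset_cycle: int = 10
    gpc_letter_interval: int = 17
    max_cycles: int = 500

    def __post_init__(self) -> None:
        m, big_m = self.activation_min, self.activation_max
        if not (m < 0 <= big_m):
            raise ParameterError(
                f"require activation_min < 0 <= activation_max, got [{m}, {big_m}]"
            )
        if not (0.0 < self.decay_rate < 1.0):
            raise ParameterError(f"decay_rate must lie in (0, 1), got {self.decay_rate}")
        if self.feature_external_input < 0:
            raise ParameterError("feature_external_input must be >= 0")
        if not (0.0 < self.phoneme_naming_threshold <= big_m):
            raise ParameterError(
                f"phoneme_naming_threshold must lie in (0, {big_m}], "
                f"got {self.phoneme_naming_threshold}"
            )
        for field in dataclasses.fields(self):
            if field.name.endswith(("excitation", "inhibition")):
                value = getattr(self, field.name)
                if value < 0:
                    raise ParameterError(
                        f"{field.name} must be non-negative (sign is carried "
                        f"by the role, not the value), got {value}"
                    )
        if self.gpc_onset_cycle < 0 or self.gpc_letter_interval < 1:
            raise ParameterError("gpc schedule constants out of range")
        if self.max_cycles < 1:
            raise ParameterError("max_cycles must be >= 1")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields changed (invariants re-checked)."""
        return dataclasses.replace(self, **changes)
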