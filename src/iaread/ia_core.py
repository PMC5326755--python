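"""Cycle-by-cycle interactive-activation dynamics.

The network has five layers: visual features (position x 14), letters
(position x alphabet), an orthographic lexicon and a phonological lexicon
(one localist unit per word each), and phonemes (position x inventory).
Every cycle, net inputs for all layers are computed synchronously from the
pre-step state -- only units with positive activation transmit -- and every
activation is then updated once with the standard interactive-activation
rule

    eps = net * (M - a)   if net > 0
          net * (a - m)   otherwise
    a'  = clamp(a + eps - theta * (a - rest), m, M)

so activations stay in ``[m, M]`` and decay toward their resting level.
External input is a per-cycle drive term added to the net input of each
present feature (value ``feature_external_input * sq_factor``), which makes
feature activation build up gradually rather than being clamped; the
optional staged feature mode instead holds features at their binary code
from the first cycle onward, reproducing the older discrete feature stage.

Naming: a trial is read out at the first cycle on which every response
position's most active phoneme exceeds ``phoneme_naming_threshold``; the
cycle count is the model's reaction-time proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import ModelParameters
from .routes import (
    GPCRule,
    RouteConfig,
    apply_stimulus_quality,
    exposed_letter_count,
    translate_prefix,
)
from .stimuli import N_FEATURES, FeatureFont, default_font, encode_word
from .synthetic_lexicon import LexiconEntry

LAYERS = ("feature", "letter", "orth", "phon", "phoneme")


class ConfigurationError(ValueError):
    """Raised for unknown layers, empty lexicons or mismatched geometry."""


class InputError(ValueError):
    """Raised when a stimulus does not fit the network's positional channels."""


@dataclass
class NetworkState:
    """Per-layer activations (batch-first) plus the cycle counter."""

    feature: np.ndarray  # (batch, positions * 14)
    letter: np.ndarray  # (batch, positions * alphabet)
    orth: np.ndarray  # (batch, n_words)
    phon: np.ndarray  # (batch, n_words)
    phoneme: np.ndarray  # (batch, positions * phoneme inventory)
    cycle: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.feature.copy(),
            self.letter.copy(),
            self.orth.copy(),
            self.phon.copy(),
            self.phoneme.copy(),
            self.cycle,
        )


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one word x condition naming trial."""

    orthography: str
    cycles_to_name: int
    produced_phonology: str
    correct: bool
    named_within_limit: bool
    tie: bool = False


@dataclass(frozen=True)
class Stimulus:
    """Precomputed drive terms for a batch of words.

    The non-lexical route is cascaded: its phoneme drive at a cycle is the
    rule-table gain times the current activation of the exposed grapheme's
    letters, so ``gpc_gain_by_exposure[b, k]`` is a (phoneme-units x
    letter-units) gain matrix for exposure ``k``.
    """

    words: tuple[str, ...]
    feature_drive: np.ndarray  # (batch, positions * 14)
    gpc_gain_by_exposure: np.ndarray  # (batch, L + 1, L * phonemes, L * alphabet)
    response_length: np.ndarray  # (batch,)


def update_activation(
    a: np.ndarray | float,
    net: np.ndarray | float,
    rest: np.ndarray | float,
    params: ModelParameters,
) -> np.ndarray | float:
    """One application of the interactive-activation update rule."""
    a = np.asarray(a, dtype=np.float64)
    net = np.asarray(net, dtype=np.float64)
    m, big_m, theta = params.activation_min, params.activation_max, params.decay_rate
    eps = np.where(net > 0, net * (big_m - a), net * (a - m))
    return np.clip(a + eps - theta * (a - rest), m, big_m)


class Network:
    """An interactive-activation dual-route network over a fixed lexicon.

    ``params`` are *base* parameters: the stimulus-quality scaling described
    by ``config`` is applied here, once, at construction.  With
    ``config.feedback_enabled`` false the three backward weight groups are
    structurally absent, which is equivalent to zeroing them in ``params``.
    """

    def __init__(
        self,
        lexicon: Sequence[LexiconEntry],
        params: ModelParameters | None = None,
        config: RouteConfig | None = None,
        font: FeatureFont | None = None,
        rules: Sequence[GPCRule] | None = None,
    ):
        if not lexicon:
            raise ConfigurationError("empty lexicon")
        self.base_params = params or ModelParameters()
        self.config = config or RouteConfig()
        self.params = apply_stimulus_quality(
            self.base_params, self.config.sq_locus, self.config.sq_factor
        )
        self.font = font or default_font()
        self.rules = list(rules) if rules is not None else None
        self.lexicon = list(lexicon)

        lengths = {len(e.orthography) for e in self.lexicon}
        if len(lengths) != 1:
            raise ConfigurationError("lexicon words must share one length")
        self.length = lengths.pop()
        if any(len(e.phonology) > self.length for e in self.lexicon):
            raise ConfigurationError("phonology longer than positional channels")

        self.alphabet = list(self.font.alphabet)
        self.letter_index = {c: i for i, c in enumerate(self.alphabet)}
        inventory = {p for e in self.lexicon for p in e.phonology}
        if self.rules is not None:
            inventory |= {r.phoneme for r in self.rules}
        self.phonemes = sorted(inventory)
        self.phoneme_index = {p: i for i, p in enumerate(self.phonemes)}

        self.n_words = len(self.lexicon)
        self.n_letters = len(self.alphabet)
        self.n_phonemes = len(self.phonemes)
        self._build_weights()

    # ----------------------------------------------------------------- build

    def _build_weights(self) -> None:
        p = self.params
        L, A, N, P = self.length, self.n_letters, self.n_words, self.n_phonemes
        fb = self.config.feedback_enabled

        codes = self.font.code_matrix(self.alphabet)  # (A, 14)
        # feature -> letter, block diagonal over positions
        w_fl_block = np.where(
            codes.T > 0, p.feature_letter_excitation, -p.feature_letter_inhibition
        )  # (14, A)
        self.w_feature_letter = np.zeros((L * N_FEATURES, L * A))
        for pos in range(L):
            self.w_feature_letter[
                pos * N_FEATURES : (pos + 1) * N_FEATURES, pos * A : (pos + 1) * A
            ] = w_fl_block

        # letter <-> orthographic lexicon
        match = np.zeros((L * A, N))
        for w, entry in enumerate(self.lexicon):
            for pos, letter in enumerate(entry.orthography):
                match[pos * A + self.letter_index[letter], w] = 1.0
        self.w_letter_orth = np.where(
            match > 0, p.letter_orth_excitation, -p.letter_orth_inhibition
        )
        self.w_orth_letter = (
            np.where(
                match.T > 0,
                p.orth_letter_feedback_excitation,
                -p.orth_letter_feedback_inhibition,
            )
            if fb
            else np.zeros((N, L * A))
        )

        # phonological lexicon <-> phonemes
        pmatch = np.zeros((N, L * P))
        for w, entry in enumerate(self.lexicon):
            for pos, phon in enumerate(entry.phonology):
                pmatch[w, pos * P + self.phoneme_index[phon]] = 1.0
        self.w_phon_phoneme = np.where(
            pmatch > 0, p.phon_phoneme_excitation, -p.phon_phoneme_inhibition
        )
        self.w_phoneme_phon = (
            np.where(pmatch.T > 0, p.phoneme_phon_feedback_excitation, 0.0)
            if fb
            else np.zeros((L * P, N))
        )

        self.orth_phon_gain = p.orth_phon_excitation
        self.phon_orth_gain = p.phon_orth_feedback_excitation if fb else 0.0
        self.resting = np.array([e.resting_level for e in self.lexicon])

    # ------------------------------------------------------------- stimulus

    def encode_stimulus(self, entries: Sequence[LexiconEntry]) -> Stimulus:
        """Precompute feature and non-lexical drive terms for a word batch."""
        p = self.params
        L, A, P = self.length, self.n_letters, self.n_phonemes
        words, drives, gpc, resp = [], [], [], []
        for entry in entries:
            if len(entry.orthography) != L:
                raise InputError(
                    f"{entry.orthography!r}: length {len(entry.orthography)} does "
                    f"not match the network's {L} positional channels"
                )
            code = encode_word(entry.orthography, self.font).ravel()
            drives.append(code * p.feature_external_input)
            words.append(entry.orthography)
            resp.append(len(entry.phonology))
            by_exposure = np.zeros((L + 1, L * P, L * A))
            if self.config.nonlexical_enabled and self.rules is not None:
                for k in range(1, L + 1):
                    assignments, _ = translate_prefix(
                        entry.orthography, self.rules, k, word_length=L
                    )
                    for a in assignments:
                        idx = self.phoneme_index.get(a.phoneme)
                        if idx is None or a.phoneme_position >= L:
                            continue
                        gain = p.gpc_phoneme_excitation / a.letter_length
                        for off in range(a.letter_length):
                            pos = a.letter_start + off
                            letter = entry.orthography[pos]
                            by_exposure[
                                k,
                                a.phoneme_position * P + idx,
                                pos * A + self.letter_index[letter],
                            ] = gain
            gpc.append(by_exposure)
        return Stimulus(
            words=tuple(words),
            feature_drive=np.stack(drives),
            gpc_gain_by_exposure=np.stack(gpc),
            response_length=np.array(resp),
        )

    def initial_state(self, batch: int = 1) -> NetworkState:
        """All units at rest: zero everywhere except the lexical resting levels."""
        L, A, N, P = self.length, self.n_letters, self.n_words, self.n_phonemes
        rest = np.tile(self.resting, (batch, 1))
        return NetworkState(
            feature=np.zeros((batch, L * N_FEATURES)),
            letter=np.zeros((batch, L * A)),
            orth=rest.copy(),
            phon=rest.copy(),
            phoneme=np.zeros((batch, L * P)),
            cycle=0,
        )

    # ------------------------------------------------------------- dynamics

    @staticmethod
    def _lateral(pos_act: np.ndarray, weight: float, pools: int) -> np.ndarray:
        """Within-pool lateral inhibition, excluding self-inhibition."""
        if weight == 0.0:
            return np.zeros_like(pos_act)
        batch = pos_act.shape[0]
        pooled = pos_act.reshape(batch, pools, -1)
        total = pooled.sum(axis=2, keepdims=True)
        return -weight * (total - pooled).reshape(batch, -1)

    def compute_net_input(
        self,
        state: NetworkState,
        node_set: str,
        stimulus: Stimulus | None = None,
    ) -> np.ndarray:
        """Net input for one layer from the current state.

        Excitatory minus inhibitory weighted sums over senders with positive
        activation; feedback terms are structurally zero when the route
        config disables them.  ``stimulus`` supplies the external feature
        drive and the non-lexical phoneme drive; without it those terms are
        zero (free-running network).
        """
        p = self.params
        feat = np.maximum(state.feature, 0.0)
        lett = np.maximum(state.letter, 0.0)
        orth = np.maximum(state.orth, 0.0)
        phon = np.maximum(state.phon, 0.0)
        phoneme = np.maximum(state.phoneme, 0.0)
        if node_set == "feature":
            net = self._lateral(feat, p.feature_lateral_inhibition, self.length)
            if stimulus is not None:
                # feature_drive already carries the stimulus-quality scaling
                # when the locus is feature-input (applied to params at build)
                net = net + stimulus.feature_drive
            return net
        if node_set == "letter":
            return (
                feat @ self.w_feature_letter
                + orth @ self.w_orth_letter
                + self._lateral(lett, p.letter_lateral_inhibition, self.length)
            )
        if node_set == "orth":
            return (
                lett @ self.w_letter_orth
                + self.phon_orth_gain * phon
                + self._lateral(orth, p.orth_lateral_inhibition, 1)
            )
        if node_set == "phon":
            return (
                self.orth_phon_gain * orth
                + phoneme @ self.w_phoneme_phon
                + self._lateral(phon, p.phon_lateral_inhibition, 1)
            )
        if node_set == "phoneme":
            net = phon @ self.w_phon_phoneme + self._lateral(
                phoneme, p.phoneme_lateral_inhibition, self.length
            )
            if stimulus is not None and self.config.nonlexical_enabled:
                k = exposed_letter_count(state.cycle, self.length, p)
                if k > 0:
                    net = net + np.einsum(
                        "bpa,ba->bp", stimulus.gpc_gain_by_exposure[:, k], lett
                    )
            return net
        raise ConfigurationError(f"unknown layer {node_set!r}")

    def step(self, state: NetworkState, stimulus: Stimulus) -> NetworkState:
        """One synchronous cycle: all nets from the pre-step state, then update."""
        if stimulus.feature_drive.shape != state.feature.shape:
            raise InputError("stimulus batch/geometry does not match state")
        p = self.params
        nets = {
            layer: self.compute_net_input(state, layer, stimulus) for layer in LAYERS
        }
        new = NetworkState(
            feature=update_activation(state.feature, nets["feature"], 0.0, p),
            letter=update_activation(state.letter, nets["letter"], 0.0, p),
            orth=update_activation(state.orth, nets["orth"], self.resting, p),
            phon=update_activation(state.phon, nets["phon"], self.resting, p),
            phoneme=update_activation(state.phoneme, nets["phoneme"], 0.0, p),
            cycle=state.cycle + 1,
        )
        if self.config.staged_feature_mode:
            # discrete feature stage: binary code from cycle 1 onward
            new.feature = (stimulus.feature_drive > 0).astype(np.float64)
        return new

    # --------------------------------------------------------------- trials

    def run_trials(self, entries: Sequence[LexiconEntry]) -> list[TrialResult]:
        """Run a batch of naming trials to threshold or ``max_cycles``."""
        p = self.params
        L, P = self.length, self.n_phonemes
        stim = self.encode_stimulus(entries)
        batch = len(entries)
        state = self.initial_state(batch)
        pending = np.ones(batch, dtype=bool)
        cycles = np.full(batch, p.max_cycles, dtype=int)
        named = np.zeros(batch, dtype=bool)
        produced: list[str] = [""] * batch
        ties = np.zeros(batch, dtype=bool)
        pos_idx = np.arange(L)
        resp_mask = pos_idx[None, :] < stim.response_length[:, None]

        while pending.any() and state.cycle < p.max_cycles:
            state = self.step(state, stim)
            acts = state.phoneme.reshape(batch, L, P)
            top = acts.max(axis=2)
            done = ((top > p.phoneme_naming_threshold) | ~resp_mask).all(axis=1)
            for b in np.flatnonzero(pending & done):
                named[b] = True
                cycles[b] = state.cycle
                n_resp = int(stim.response_length[b])
                out = []
                for pos in range(n_resp):
                    row = acts[b, pos]
                    best = row.max()
                    winners = np.flatnonzero(row == best)
                    if len(winners) > 1:
                        ties[b] = True
                    out.append(self.phonemes[int(winners[0])])
                produced[b] = "".join(out)
            pending &= ~done

        results = []
        for b, entry in enumerate(entries):
            correct = (
                named[b] and not ties[b] and produced[b] == entry.phonology
            )
            results.append(
                TrialResult(
                    orthography=entry.orthography,
                    cycles_to_name=int(cycles[b]),
                    produced_phonology=produced[b],
                    correct=bool(correct),
                    named_within_limit=bool(named[b]),
                    tie=bool(ties[b]),
                )
            )
        return results


def run_trial(
    word: LexiconEntry,
    lexicon: Sequence[LexiconEntry],
    params: ModelParameters | None = None,
    condition: RouteConfig | None = None,
    font: FeatureFont | None = None,
    rules: Sequence[GPCRule] | None = None,
) -> TrialResult:
    """Convenience wrapper: build the network for one condition, run one word.

    For whole-corpus runs build the :class:`Network` once and call
    :meth:`Network.run_trials`.
    """
    net = Network(lexicon, params=params, config=condition, font=font, rules=rules)
    return net.run_trials([word])[0]
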