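# Methods

## Model

The simulator is a localist interactive-activation network in the
dual-route tradition. Five layers are connected in a fixed architecture:

```
features (position × 14) → letters (position × 26) → orthographic lexicon (N words)
                                   ↘ (GPC rules) ↘        ↕
                                     phonemes  ←  phonological lexicon (N words)
                                  (position × inventory)
```

Forward connections run feature→letter, letter→orthographic lexicon,
orthographic→phonological lexicon and phonological lexicon→phoneme.
Backward (feedback) connections — orthographic lexicon→letter,
phonological→orthographic lexicon and phoneme→phonological lexicon — are
what make the dynamics *interactive*; zeroing them (the feedback ablation)
leaves a pure feed-forward cascade. All weights are stored as non-negative
magnitudes with the sign carried by the excitatory/inhibitory role. Each
layer also has lateral inhibition within its competition pool (per
position for letters and phonemes, global for the two lexicons).

Every cycle is fully synchronous: all net inputs are computed from the
pre-step state (only units with activation > 0 transmit), then every unit
is updated once with

    ε  = net·(M − a)  if net > 0,  else  net·(a − m)
    a′ = clamp(a + ε − θ·(a − rest), m, M)

with m = −1, M = 1, decay θ = 0.15. This is the standard
interactive-activation update; clamping makes the dynamics total for any
weight setting, and determinism is exact (pure float64, no noise terms).

**Word frequency** enters through resting levels. A word with frequency f
(per million) in a lexicon whose maximum is f_max rests at

    rest = s · (log10(f+1)/log10(f_max+1) − 1)   ∈ [−s, 0],  s = 0.3.

The most frequent word rests at 0; rarer words start deeper and therefore
cross any activation landmark later — the classic localist frequency
mechanism.

**Graded visual input.** Each feature present in the stimulus receives an
external drive added to its net input every cycle (`feature_external_input`,
default 1.0 for a clear stimulus). At the default the feature level
saturates within a cycle or two; as the drive is reduced the build-up
stretches over many cycles, which is exactly how degradation slows the
whole system. A *staged* feature mode is available that instead holds
features at their binary code from the first cycle, reproducing the older
discrete feature stage.

**Stimulus quality** is a multiplicative factor in (0, 1] applied at one
of two loci: the external feature drive (`feature-input`) or the
feature→letter excitatory and inhibitory weights
(`feature-letter-weights`). The feature-input manipulation is passed
through the saturating feature dynamics (equilibrium d/(d+θ) in the drive
d), so a nominal 20% reduction reaches the letter level much attenuated;
the weights manipulation scales letter input linearly. This is why the
simulated quality effect at the early locus is roughly half that of the
late locus — an attenuation that emerges from the dynamics, not from an
extra assumption.

**Naming.** A trial is read out at the first cycle on which, at every
response position, the most active phoneme exceeds the naming threshold
(0.43). The cycle count is the latency proxy; the produced string is the
arg-max phoneme per position. If two phonemes tie exactly at read-out the
trial is flagged and scored incorrect rather than silently resolved; with
deterministic dynamics ties essentially never occur. Trials that fail to
reach threshold within `max_cycles` (500) are retained with a flag and
excluded listwise downstream.

## Non-lexical route

Grapheme–phoneme rules are data (`grapheme<TAB>phoneme<TAB>position-class`);
the shipped default covers the synthetic alphabet one-to-one plus a few
multi-letter rules. Translation is longest-match-first with
initial/final/any position classes, over a left-to-right prefix that grows
with time: no letters before `gpc_onset_cycle` (10), then one more letter
every `gpc_letter_interval` cycles (17). The route is purely feed-forward;
its phoneme drive is the rule gain scaled by the current activation of the
exposed grapheme's letters. That scaling is a deliberate design choice:
the route reads the shared letter level (cascaded), so degraded input slows
sub-lexical translation too. A constant-strength drive would make
rule-paced trials completely insensitive to stimulus quality, which is not
a property of this model family. Untranslatable letters stop translation
with a flag; the lexical route can still name the item.

## Letter font

Letters are encoded as 14-segment binary feature codes shipped as data.
The codes are *constant-weight*: every letter uses exactly 7 of the 14
segments. The original letter-perception font pairs each present-feature
detector with an absent-feature detector, so a letter missing one of the
stimulus's segments is actively inhibited. This architecture has
present-feature channels only, and with arbitrary codes a letter whose
code is a superset of the stimulus letter's would receive identical
excitation and no inhibition — indistinguishable in principle. Constant
weight makes the code set an antichain (no letter's segments contain
another's), restoring discriminability: every non-target letter misses at
least one active feature and is inhibited through it. Which particular
segments form each letter is immaterial to every reported contrast; only
distinctness and constant weight matter.

## Parameters

All constants live in `ModelParameters` and every one can be overridden in
config; none is hard-coded elsewhere. The published literature does not
fix a canonical parameter set for this exact architecture, so the defaults
were chosen (once) to satisfy the behavioural sanity conditions the
experiment needs: the default (feedback-on) model names the whole target
set correctly at 100% quality, still names at 20% at both loci, and
produces graded latencies in between.

| parameter | default | role |
| --- | --- | --- |
| activation_min / max | −1 / 1 | clamp bounds |
| decay_rate | 0.15 | leak toward rest, per cycle |
| feature_external_input | 1.0 | clear-stimulus drive per present feature |
| feature_letter exc / inh | 0.035 / 0.30 | letter selectivity; inhibition ≫ excitation so one missing feature vetoes a letter |
| letter_orth exc / inh | 0.08 / 0.30 | lexical evidence; mismatch inhibition suppresses one-letter-off neighbours enough to prevent frequency-driven capture errors at full quality |
| orth_letter feedback exc / inh | 0.15 / 0 | interactive activation (ablatable) |
| orth_phon excitation | 0.60 | forward lexical cascade |
| phon_orth feedback | 0.15 | interactive activation (ablatable) |
| phon_phoneme exc / inh | 0.50 / 0 | pronunciation drive |
| phoneme_phon feedback | 0.05 | interactive activation (ablatable) |
| gpc_phoneme_excitation | 0.25 | rule-route drive (× letter activation); strong enough to name regular words alone, weak enough that the lexical route wins for exception words |
| lateral inhibition (letter/orth/phon/phoneme) | 0.02/0.03/0.03/0.06 | within-pool competition |
| frequency_scaling | 0.30 | depth of the resting-level range |
| phoneme_naming_threshold | 0.43 | read-out criterion |
| gpc_onset_cycle / letter_interval | 10 / 17 | semi-serial exposure schedule |
| max_cycles | 500 | trial cutoff |

## Synthetic lexicon

The generator emulates the structure a naming corpus needs for this
design: ~70 high-frequency and ~68 low-frequency fixed-length target words
embedded in a 500-word background vocabulary, with log10-normal
frequencies per band (high ≈ 160/million, low ≈ 5/million, background
≈ 16/million, σ ≈ 0.3–0.5 log10 units — ordinary magnitudes for printed-word
counts). Low-band words are generated as one-letter mutations of
high-band words (yoked pairs) and ~30% of background words are one-letter
mutations of targets, so orthographic neighbourhoods are populated and
matched across bands. About 10% of words are exceptions: their
pronunciation deviates from the rule translation at one position, which
makes them diagnostic of lexical-route dominance. For the cleanest
frequency control the package also provides a counterfactual helper
(`with_frequency`) that changes a single word's frequency while keeping
its spelling, pronunciation and neighbourhood identical.

What the generator does *not* emulate: English orthographic and
phonotactic structure, word-length variation, realistic neighbourhood
density distributions, syllable structure, or any semantic variable.
Passing tests therefore show that the *mechanisms* behave as the model
family predicts on a corpus with the right statistical skeleton — not that
the simulator reproduces any particular English corpus's latencies.

## Experiment and screening

The factorial design crosses feedback (on/off) × quality locus (2) ×
quality level (20/40/60/80/100%). The 100% condition is the identity at
either locus, so it is simulated once per feedback setting and reused in
every pairing. Before analysis, an accuracy screen runs the default
(feedback-on) model over the quality sweep at each locus; every word that
errs at or above the 20% floor is excluded from *all* cells, as are words
that ever fail to name, keeping the item set identical across conditions.
The screen's sweep defaults to the analysed levels (20–100% in steps of
20); a finer sweep is a config option. With the default corpus this
excludes 0–2 items per seed.

## Statistical analysis

Latencies are analysed with random-intercept-per-word mixed models fitted
by REML (statsmodels `MixedLM`) in a saturated cell-means parameterisation
— quality is a categorical factor with all five levels in one model.
Planned contrasts are explicit linear combinations of cell means, so
coding conventions cannot silently change an estimate. For each pairing
of 100% with a degraded level the three reported contrasts are the word
frequency main effect (low − high band, averaged over the two levels), the
simple quality effect for high-frequency words (degraded − clear), and the
interaction (difference of the two bands' quality effects; positive =
over-additive). Pooling feedback settings within a locus, the three-way
model yields one feedback-difference-of-interactions contrast per pairing.

Contrast standard errors are computed from the REML variance components as
c′(X′V⁻¹X)⁻¹c with V = σ²ₑI + σ²_b ZZ′; denominator degrees of freedom use
the Satterthwaite approximation df = 2g²/(∇g′ A ∇g), where g is the
contrast variance, ∇g its gradient in (σ²ₑ, σ²_b), and A the inverse REML
expected information — all computed group-by-group so nothing larger than
one word's block is materialised. The implementation agrees with R's
`lmerTest` (Satterthwaite `contest1D`) to ≤ 1e-3 relative on estimate, SE,
df and t, which the test suite verifies by running `Rscript` on shared
data. If the random-intercept variance collapses to zero the fit falls
back to ordinary least squares with residual df (logged). p-values are
two-sided t probabilities; no multiple-testing correction is applied, and
each contrast is reported individually.

The 2 × 2 factorial decomposition (cell means → simple effects →
interaction) is exact arithmetic and is exercised on the published human
naming means as a worked example.

## Problem sizes and numerical checks

- Engine equivalence: 100 random configurations of toy networks (≤ 3
  positions, ≤ 5 words, random weights, random route flags) match an
  independently coded loop-based reference at every cycle to 1e-12.
- Qualitative replication: seeded corpus of 138 targets + 500 background
  words, full 2 × 2 × 5 grid (~2,760 trials), minutes of CPU in total.
- Calibration: the interaction contrast's type-I error under a true null
  is estimated at 1,000 simulated datasets (48 words each) and must land
  in [0.03, 0.07] at α = 0.05; a three-way effect injected at the study
  size (138 words) must be recovered within 2 SE.
- Exact recovery: on noiseless balanced data all contrasts equal the
  built-in effects to 1e-8.

## Known limitations

- Latencies are integer cycle counts; at weak manipulations the quality
  effect is a fraction of a cycle per step, so single-trial differences
  are coarse even though cell means are graded.
- Absolute cycle counts are not comparable to any published simulation:
  they depend on the unpublished parameter set and lexicon of the original
  implementation. All claims are therefore about signs, orderings and
  ratios, never about matching cycle values.
- The additive human pattern (words mixed with non-words) has no mechanism
  in this model family; the package computes the human-table decomposition
  that exhibits it but does not attempt to simulate the context switch.
- No noise, no learning, no semantic system, no articulatory stage;
  lowercase input and variable word length are unsupported by design.
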