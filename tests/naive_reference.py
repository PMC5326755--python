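"""Independently coded brute-force reference for the network dynamics.

Deliberately naive: explicit Python loops over nodes and connections,
dictionaries instead of matrices, no vectorisation, no code shared with
the package's engine.  Used to verify the engine cycle by cycle.
"""

from __future__ import annotations


def naive_trajectory(
    lexicon,          # list of (orthography, phonology, resting_level)
    font,             # dict letter -> list of 14 ints
    params,           # iaread ModelParameters (read-only attribute access)
    word,             # stimulus orthography
    n_cycles,
    feedback=True,
    nonlexical=True,
    sq_locus="feature-input",
    sq_factor=1.0,
    rules=None,       # list of (grapheme, phoneme, position_class)
):
    """Return a list of per-cycle state dicts for one stimulus."""
    letters = sorted(font)
    length = len(word)
    phon_inventory = sorted(
        {p for _, phon, _ in lexicon for p in phon}
        | ({r[1] for r in rules} if rules else set())
    )

    fei = params.feature_external_input * (sq_factor if sq_locus == "feature-input" else 1.0)
    wscale = sq_factor if sq_locus == "feature-letter-weights" else 1.0
    fl_exc = params.feature_letter_excitation * wscale
    fl_inh = params.feature_letter_inhibition * wscale

    # state dictionaries
    feat = {(p, f): 0.0 for p in range(length) for f in range(14)}
    lett = {(p, c): 0.0 for p in range(length) for c in letters}
    orth = {w: lexicon[w][2] for w in range(len(lexicon))}
    plex = {w: lexicon[w][2] for w in range(len(lexicon))}
    phon = {(p, s): 0.0 for p in range(length) for s in phon_inventory}

    def pos_part(x):
        return x if x > 0.0 else 0.0

    def clamp(x):
        return min(max(x, params.activation_min), params.activation_max)

    def update(a, net, rest):
        if net > 0:
            eps = net * (params.activation_max - a)
        else:
            eps = net * (a - params.activation_min)
        return clamp(a + eps - params.decay_rate * (a - rest))

    def translate(exposed):
        # longest-match-first over the exposed prefix
        out = []
        pos, ppos = 0, 0
        ordered = sorted(rules or [], key=lambda r: len(r[0]), reverse=True)
        while pos < min(exposed, length):
            hit = None
            for g, ph, pc in ordered:
                if pos + len(g) > exposed or word[pos : pos + len(g)] != g:
                    continue
                if pc == "initial" and pos != 0:
                    continue
                if pc == "final" and pos + len(g) != length:
                    continue
                hit = (g, ph)
                break
            if hit is None:
                break
            out.append((ppos, hit[1], pos, len(hit[0])))
            pos += len(hit[0])
            ppos += 1
        return out

    history = []
    for cycle in range(n_cycles):
        # --- net inputs from the pre-step state ---
        net_feat = {}
        for p in range(length):
            for f in range(14):
                drive = fei if font[word[p]][f] else 0.0
                lat = 0.0
                if params.feature_lateral_inhibition:
                    others = sum(
                        pos_part(feat[(p, f2)]) for f2 in range(14) if f2 != f
                    )
                    lat = -params.feature_lateral_inhibition * others
                net_feat[(p, f)] = drive + lat

        net_lett = {}
        for p in range(length):
            for c in letters:
                total = 0.0
                for f in range(14):
                    a = pos_part(feat[(p, f)])
                    total += (fl_exc if font[c][f] else -fl_inh) * a
                if feedback:
                    for w in range(len(lexicon)):
                        a = pos_part(orth[w])
                        if lexicon[w][0][p] == c:
                            total += params.orth_letter_feedback_excitation * a
                        else:
                            total -= params.orth_letter_feedback_inhibition * a
                others = sum(pos_part(lett[(p, c2)]) for c2 in letters if c2 != c)
                total -= params.letter_lateral_inhibition * others
                net_lett[(p, c)] = total

        net_orth = {}
        for w in range(len(lexicon)):
            total = 0.0
            for p in range(length):
                for c in letters:
                    a = pos_part(lett[(p, c)])
                    if lexicon[w][0][p] == c:
                        total += params.letter_orth_excitation * a
                    else:
                        total -= params.letter_orth_inhibition * a
            if feedback:
                total += params.phon_orth_feedback_excitation * pos_part(plex[w])
            others = sum(pos_part(orth[w2]) for w2 in range(len(lexicon)) if w2 != w)
            total -= params.orth_lateral_inhibition * others
            net_orth[w] = total

        net_plex = {}
        for w in range(len(lexicon)):
            total = params.orth_phon_excitation * pos_part(orth[w])
            if feedback:
                for p, ph in enumerate(lexicon[w][1]):
                    total += params.phoneme_phon_feedback_excitation * pos_part(
                        phon[(p, ph)]
                    )
            others = sum(pos_part(plex[w2]) for w2 in range(len(lexicon)) if w2 != w)
            total -= params.phon_lateral_inhibition * others
            net_plex[w] = total

        gpc_now = []
        if nonlexical and rules:
            if cycle >= params.gpc_onset_cycle:
                k = 1 + (cycle - params.gpc_onset_cycle) // params.gpc_letter_interval
                gpc_now = translate(min(k, length))
        net_phon = {}
        for p in range(length):
            for s in phon_inventory:
                total = 0.0
                for w in range(len(lexicon)):
                    a = pos_part(plex[w])
                    if p < len(lexicon[w][1]) and lexicon[w][1][p] == s:
                        total += params.phon_phoneme_excitation * a
                    else:
                        total -= params.phon_phoneme_inhibition * a
                for ppos, ph, lstart, llen in gpc_now:
                    if ppos == p and ph == s:
                        for off in range(llen):
                            total += (
                                params.gpc_phoneme_excitation / llen
                            ) * pos_part(lett[(lstart + off, word[lstart + off])])
                others = sum(
                    pos_part(phon[(p, s2)]) for s2 in phon_inventory if s2 != s
                )
                total -= params.phoneme_lateral_inhibition * others
                net_phon[(p, s)] = total

        # --- synchronous update ---
        feat = {k: update(feat[k], net_feat[k], 0.0) for k in feat}
        lett = {k: update(lett[k], net_lett[k], 0.0) for k in lett}
        orth = {w: update(orth[w], net_orth[w], lexicon[w][2]) for w in orth}
        plex = {w: update(plex[w], net_plex[w], lexicon[w][2]) for w in plex}
        phon = {k: update(phon[k], net_phon[k], 0.0) for k in phon}
        history.append(
            {
                "feature": dict(feat),
                "letter": dict(lett),
                "orth": dict(orth),
                "phon": dict(plex),
                "phoneme": dict(phon),
            }
        )
    return history, letters, phon_inventory
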