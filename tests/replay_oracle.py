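"""Naive per-bout likelihood replay, independent of the compiled kernel.

Used as the oracle in likelihood-equivalence tests: it composes only the
public single-bout operations (window tally, soft-max, social probabilities,
mixture, attraction update), recomputing the window from the full history at
every bout, with none of the precomputation or compiled code of
:mod:`ewalearn.inference`.
"""

import numpy as np

import ewalearn as ew


def naive_log_likelihood(bouts, roster, techniques, learner,
                         window_days=14, initial_attractions=None):
    info = ew.RosterInfo(roster)
    state = ew.AttractionState.naive(info.ids, techniques, initial_attractions)
    history = []
    pointwise = []
    for b in bouts:
        summary = ew.tally_window(
            history, b.actor, b.day, window_days,
            techniques=techniques, roster=info, now_seq=b.seq,
        )
        r = info.position[b.actor]
        p_ind = ew.individual_choice_probs(state, b.actor, learner.lam)
        p_soc = ew.social_choice_probs(summary, learner.f[r], learner.beta[r])
        p = ew.combine_probs(p_ind, p_soc, learner.gam[r])
        pointwise.append(np.log(p[techniques.index[b.technique]]))
        state = ew.update_attractions(state, b.actor, b.technique,
                                      b.payoff, learner.phi[r])
        history.append(b)
    return float(np.sum(pointwise)), np.array(pointwise)
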