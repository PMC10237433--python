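"""Independent reference implementation of the go/no-go likelihood.

Deliberately written in a different style from the package (dict-keyed
state, explicit two-exponential softmax, per-variant parameter dicts) so it
can serve as a trial-by-trial oracle for ``gngbias.models.subject_loglik``.
"""

import math


def _reward_domain(cue):
    return cue in (1, 3)


def reference_loglik(params, cues, actions, feedback, variant):
    """Total log-likelihood of one session.

    ``params`` is a dict with the variant's own names (single ``pi``/``rho``
    for M1, split ones where the variant splits them).
    """
    xi = params["xi"]
    eps = params["eps"]
    b = params["b"]

    def pi_for(cue):
        if variant == "M3":
            return params["pi_rew"] if _reward_domain(cue) else params["pi_pun"]
        return params["pi"]

    def rho_for(cue):
        if variant in ("M2", "M3"):
            return params["rho_rew"] if _reward_domain(cue) else params["rho_pun"]
        return params["rho"]

    Q = {(a, s): 0.0 for a in (0, 1) for s in (1, 2, 3, 4)}
    V = {s: 0.0 for s in (1, 2, 3, 4)}
    total = 0.0
    for cue, action, r in zip(cues, actions, feedback):
        w_go = Q[(1, cue)] + b + pi_for(cue) * V[cue]
        w_nogo = Q[(0, cue)]
        m = max(w_go, w_nogo)
        e_go = math.exp(w_go - m)
        e_nogo = math.exp(w_nogo - m)
        p_go = e_go / (e_go + e_nogo) * (1.0 - xi) + xi / 2.0
        total += math.log(p_go if action == 1 else 1.0 - p_go)
        rho = rho_for(cue)
        Q[(action, cue)] = Q[(action, cue)] + eps * (rho * r - Q[(action, cue)])
        V[cue] = V[cue] + eps * (rho * r - V[cue])
    return total


def random_session(rng, n_trials=40):
    """A random (not necessarily balanced) valid session for oracle tests."""
    cues = rng.integers(1, 5, n_trials)
    actions = rng.integers(0, 2, n_trials)
    feedback = [
        int(rng.choice([0, 1] if _reward_domain(c) else [-1, 0]))
        for c in cues
    ]
    return cues.tolist(), actions.tolist(), feedback
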