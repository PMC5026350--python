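"""Randomized tiny model/sequence instances for exhaustive-oracle checks."""

from __future__ import annotations

import numpy as np

from crmseg.model import (
    BG_GLOBAL,
    BG_LOCAL,
    CRM_END,
    CRM_START,
    END,
    START,
    DurationParams,
    HsmmModel,
)
from crmseg.pwm import Pwm


def random_toy(seed: int, max_len: int = 8):
    """A random 1-2 motif model (width 2) and a short random sequence."""
    rng = np.random.default_rng(seed)
    K = int(rng.integers(1, 3))
    pwms = []
    for k in range(K):
        mat = rng.dirichlet(np.full(4, 0.8), size=2)
        pwms.append(Pwm(f"m{k}", mat, pseudocount=0.0))
    names = [p.name for p in pwms]
    motifs = [*names, *(n + "_rc" for n in names)]

    def drow(targets):
        probs = rng.dirichlet(np.ones(len(targets)))
        return dict(zip(targets, probs.tolist()))

    transitions = {
        START: {BG_GLOBAL: 1.0},
        BG_GLOBAL: drow([CRM_START, END]),
        CRM_START: drow(motifs),
        CRM_END: {BG_GLOBAL: 1.0},
        BG_LOCAL: drow(motifs),
    }
    for m in motifs:
        transitions[m] = drow([*motifs, BG_LOCAL, CRM_END])

    durations = DurationParams(
        p_g=float(rng.uniform(0.2, 0.8)),
        r=int(rng.integers(1, 3)),
        pi=float(rng.uniform(0.1, 0.6)),
        max_duration=6,
    )
    model = HsmmModel(
        pwms={p.name: p for p in pwms},
        durations=durations,
        transitions=transitions,
        bg_order_global=0,
        bg_order_local=0,
        window_halfwidth=16,
    )
    T = int(rng.integers(4, max_len + 1))
    seq = "".join(rng.choice(list("ACGT"), size=T))
    return model, seq
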