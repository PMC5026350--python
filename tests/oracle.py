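"""Independent brute-force reference for tiny instances.

Enumerates every legal (state path, duration) parse by direct recursion over
the full transition graph, computing each parse's probability from first
principles (transition products, truncated duration pmfs, per-segment
emissions). Used to check the dynamic-programming engine on instances small
enough for exhaustive enumeration.
"""

from __future__ import annotations

import numpy as np

from crmseg.background import fit_local_markov
from crmseg.model import BG_GLOBAL, CRM_END, CRM_START, END, START, HsmmModel
from crmseg.pwm import motif_emission_logprob


def logsumexp(vals):
    vals = np.asarray(vals, dtype=float)
    m = vals.max() if vals.size else -np.inf
    if m == -np.inf:
        return -np.inf
    return float(m + np.log(np.exp(vals - m).sum()))


class BruteForce:
    """All legal parses of a sequence under a model, with probabilities."""

    def __init__(self, model: HsmmModel, sequence: str, lattice=None):
        self.model = model
        self.seq = sequence
        self.T = len(sequence)
        self.lattice = lattice
        self.table_g = fit_local_markov(
            sequence, model.bg_order_global, model.window_halfwidth, model.bg_pseudocount
        )
        self.table_c = fit_local_markov(
            sequence, model.bg_order_local, model.window_halfwidth, model.bg_pseudocount
        )
        d = model.durations
        self.logd_g = d.bg_global_log_pmf(self.T)
        self.logd_c = d.bg_local_log_pmf(self.T)
        self.parses: list[tuple[tuple, float]] = []
        self._walk(START, 0, 0.0, ())
        self.loglik = logsumexp([lp for _, lp in self.parses])

    def _seg_emission(self, state, pos, u):
        if self.model.states.is_motif(state):
            return motif_emission_logprob(
                self.model.pwm_for(state), self.seq[pos : pos + u]
            )
        table = self.table_g if state == BG_GLOBAL else self.table_c
        return table.segment_logprob(pos, u)

    def _walk(self, state, pos, logp, segs):
        for nxt, p in self.model.transitions[state].items():
            if p <= 0:
                continue
            lp = logp + np.log(p)
            if nxt == END:
                if pos == self.T:
                    self.parses.append((segs, lp))
            elif nxt in (CRM_START, CRM_END):
                self._walk(nxt, pos, lp, segs + ((nxt, pos, 0),))
            elif self.model.states.is_motif(nxt):
                w = self.model.motif_width(nxt)
                if pos + w > self.T:
                    continue
                if self.lattice is not None and not self.lattice.admits(nxt, pos):
                    continue
                e = self._seg_emission(nxt, pos, w)
                if e == -np.inf:
                    continue
                self._walk(nxt, pos + w, lp + e, segs + ((nxt, pos, w),))
            else:
                logd = self.logd_g if nxt == BG_GLOBAL else self.logd_c
                for u in range(1, min(logd.shape[0], self.T - pos) + 1):
                    if logd[u - 1] == -np.inf:
                        continue
                    e = self._seg_emission(nxt, pos, u)
                    self._walk(
                        nxt,
                        pos + u,
                        lp + logd[u - 1] + e,
                        segs + ((nxt, pos, u),),
                    )

    # -- reference quantities ------------------------------------------------
    def emitting(self, segs):
        return tuple(s for s in segs if s[0] not in (CRM_START, CRM_END))

    def all_segments(self):
        out = set()
        for segs, _ in self.parses:
            out.update(self.emitting(segs))
        return out

    def segment_logposterior(self, state, start, duration):
        target = (state, start, duration)
        vals = [lp for segs, lp in self.parses if target in self.emitting(segs)]
        if not vals:
            return -np.inf
        return logsumexp(vals) - self.loglik

    def posterior_viterbi(self):
        """Best parse by product of segment posteriors; returns
        (emitting segments, score, runner-up score)."""
        scored = []
        for segs, _ in self.parses:
            emit = self.emitting(segs)
            score = sum(self.segment_logposterior(*s) for s in emit)
            scored.append((score, emit))
        scored.sort(key=lambda x: -x[0])
        best_score, best = scored[0]
        runner = scored[1][0] if len(scored) > 1 else -np.inf
        return best, best_score, runner
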