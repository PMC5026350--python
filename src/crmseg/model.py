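"""The segmentation model: state space, topology, and parameters.

A regulatory sequence is parsed as an alternation of global background and
cis-regulatory modules (CRMs); inside a CRM, motif occurrences alternate with
local background spacers. The state space is

    H = {S, E} ∪ {c_s, c_e} ∪ M ∪ M' ∪ {b_g} ∪ {b_c}

where M holds one state per motif, M' their reverse complements, b_g / b_c
the global / local backgrounds, c_s / c_e silent CRM delimiters, and S / E
silent sequence endpoints. Permitted transitions:

    S -> b_g;  b_g -> {c_s, E};  c_s -> any motif;
    motif -> {any motif, b_c, c_e};  b_c -> any motif;  c_e -> b_g.

A CRM therefore contains at least one motif, local background only separates
motifs, and every sequence begins and ends with global background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .background import LocalMarkovTable
from .durations import (
    geometric_duration_pmf,
    geometric_quantile,
    motif_duration_pmf,
    negbin_duration_pmf,
    negbin_quantile,
    truncated_geometric_log_pmf,
    truncated_negbin_log_pmf,
)
from .pwm import Pwm, motif_emission_logprob, reverse_complement_pwm

START, END, CRM_START, CRM_END = "S", "E", "c_s", "c_e"
BG_GLOBAL, BG_LOCAL = "b_g", "b_c"
SILENT_STATES = (START, END, CRM_START, CRM_END)
RC_SUFFIX = "_rc"

TRUNCATION_MASS = 1.0 - 1e-6

__all__ = [
    "StateSpace",
    "DurationParams",
    "HsmmModel",
    "segment_logprob",
    "START",
    "END",
    "CRM_START",
    "CRM_END",
    "BG_GLOBAL",
    "BG_LOCAL",
    "RC_SUFFIX",
]


@dataclass(frozen=True)
class StateSpace:
    """Names of all states, derived from the motif identifiers."""

    motif_states: tuple[str, ...]

    def __post_init__(self) -> None:
        names = self.motif_states
        object.__setattr__(self, "motif_states", tuple(names))
        all_ids = list(self.motif_states) + list(self.rc_motif_states) + [
            START,
            END,
            CRM_START,
            CRM_END,
            BG_GLOBAL,
            BG_LOCAL,
        ]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("state identifiers must be unique")

    @property
    def rc_motif_states(self) -> tuple[str, ...]:
        return tuple(m + RC_SUFFIX for m in self.motif_states)

    @property
    def all_motif_states(self) -> tuple[str, ...]:
        return self.motif_states + self.rc_motif_states

    @property
    def emitting_states(self) -> tuple[str, ...]:
        """All 2K + 2 emitting states, motifs first."""
        return self.all_motif_states + (BG_LOCAL, BG_GLOBAL)

    @property
    def silent_states(self) -> tuple[str, ...]:
        return SILENT_STATES

    def is_motif(self, state: str) -> bool:
        return state in self.motif_states or state in self.rc_motif_states

    def strand(self, state: str) -> str:
        return "-" if state.endswith(RC_SUFFIX) else "+"

    def base_motif(self, state: str) -> str:
        return state[: -len(RC_SUFFIX)] if state.endswith(RC_SUFFIX) else state


@dataclass(frozen=True)
class DurationParams:
    """Duration parameters: geometric p_g for b_g, negative binomial (r, pi)
    for b_c, and an optional explicit truncation bound for the DP."""

    p_g: float
    r: int
    pi: float
    max_duration: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_g <= 1.0:
            raise ValueError(f"p_g must be in (0, 1], got {self.p_g}")
        if self.r < 1 or int(self.r) != self.r:
            raise ValueError(f"r must be a positive integer, got {self.r}")
        if not 0.0 <= self.pi < 1.0:
            raise ValueError(f"pi must be in [0, 1), got {self.pi}")
        if self.max_duration is not None and self.max_duration < 1:
            raise ValueError("max_duration must be positive")

    def bg_global_bound(self, seq_length: int | None = None) -> int:
        """Truncation bound for b_g: explicit bound if set, else the 1-1e-6
        quantile, capped at the sequence length when one is given."""
        u = self.max_duration or geometric_quantile(self.p_g, TRUNCATION_MASS)
        if seq_length is not None:
            u = min(u, seq_length)
        return max(u, 1)

    def bg_local_bound(self, seq_length: int | None = None) -> int:
        u = self.max_duration or negbin_quantile(self.r, self.pi, TRUNCATION_MASS)
        if seq_length is not None:
            u = min(u, seq_length)
        return max(u, self.r)

    def bg_global_log_pmf(self, seq_length: int | None = None) -> np.ndarray:
        return truncated_geometric_log_pmf(self.p_g, self.bg_global_bound(seq_length))

    def bg_local_log_pmf(self, seq_length: int | None = None) -> np.ndarray:
        return truncated_negbin_log_pmf(
            self.r, self.pi, self.bg_local_bound(seq_length)
        )


def permitted_edges(space: StateSpace) -> set[tuple[str, str]]:
    """The full transition topology over the state space."""
    motifs = space.all_motif_states
    edges: set[tuple[str, str]] = {(START, BG_GLOBAL), (BG_GLOBAL, CRM_START),
                                   (BG_GLOBAL, END), (CRM_END, BG_GLOBAL)}
    for m in motifs:
        edges.add((CRM_START, m))
        edges.add((BG_LOCAL, m))
        edges.add((m, BG_LOCAL))
        edges.add((m, CRM_END))
        for m2 in motifs:
            edges.add((m, m2))
    return edges


@dataclass
class HsmmModel:
    """Full model: PWMs, durations, transitions, and background settings.

    ``transitions[state]`` maps successor states to probabilities; rows must
    sum to one and only edges of the permitted topology may carry mass.
    Reverse-complement motif states share the column-reversed complement of
    the forward matrix and are materialized in ``pwm_for``.
    """

    pwms: dict[str, Pwm]
    durations: DurationParams
    transitions: dict[str, dict[str, float]]
    bg_order_global: int = 3
    bg_order_local: int = 2
    window_halfwidth: int = 500
    bg_pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.states = StateSpace(tuple(sorted(self.pwms)))
        self.validate()

    def validate(self) -> None:
        allowed = permitted_edges(self.states)
        for src, row in self.transitions.items():
            total = 0.0
            for dst, p in row.items():
                if p < 0:
                    raise ValueError(f"negative transition {src}->{dst}")
                if p > 0 and (src, dst) not in allowed:
                    raise ValueError(f"transition {src}->{dst} not permitted")
                total += p
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"outgoing probabilities from {src} sum to {total}, not 1"
                )
        for src in [START, BG_GLOBAL, CRM_START, CRM_END, BG_LOCAL, *self.states.all_motif_states]:
            if src not in self.transitions:
                raise ValueError(f"missing transition row for state {src}")
        if self.bg_order_global < 0 or self.bg_order_local < 0:
            raise ValueError("background orders must be >= 0")
        if self.window_halfwidth <= 0:
            raise ValueError("window_halfwidth must be positive")

    def pwm_for(self, state: str) -> Pwm:
        """The (possibly reverse-complemented) PWM of a motif state."""
        base = self.states.base_motif(state)
        pwm = self.pwms[base]
        if state.endswith(RC_SUFFIX):
            return reverse_complement_pwm(pwm)
        return pwm

    def motif_width(self, state: str) -> int:
        return self.pwms[self.states.base_motif(state)].width

    def trans(self, src: str, dst: str) -> float:
        return self.transitions.get(src, {}).get(dst, 0.0)

    def duration_pmf(self, state: str, u: int) -> float:
        """Untruncated duration pmf of any emitting state at duration u."""
        if self.states.is_motif(state):
            return motif_duration_pmf(self.motif_width(state), u)
        if state == BG_GLOBAL:
            return geometric_duration_pmf(self.durations.p_g, u)
        if state == BG_LOCAL:
            return negbin_duration_pmf(self.durations.r, self.durations.pi, u)
        raise ValueError(f"state {state} has no duration model")

    def replace_params(self, **kwargs) -> "HsmmModel":
        """A copy with updated durations/transitions (used by EM)."""
        new = HsmmModel(
            pwms=self.pwms,
            durations=kwargs.get("durations", self.durations),
            transitions=kwargs.get("transitions", self.transitions),
            bg_order_global=self.bg_order_global,
            bg_order_local=self.bg_order_local,
            window_halfwidth=self.window_halfwidth,
            bg_pseudocount=self.bg_pseudocount,
        )
        return new

    @classmethod
    def default(
        cls,
        pwms: list[Pwm] | dict[str, Pwm],
        durations: DurationParams | None = None,
        p_crm: float = 0.5,
        p_motif_again: float = 0.2,
        p_spacer: float = 0.5,
        **kwargs,
    ) -> "HsmmModel":
        """A model with uniform motif choice and documented defaults.

        ``p_crm`` is b_g's probability of opening a CRM (vs ending the
        sequence); from a motif, ``p_motif_again`` continues directly to
        another motif, ``p_spacer`` inserts local background, and the rest
        closes the CRM.
        """
        if isinstance(pwms, list):
            pwms = {p.name: p for p in pwms}
        if durations is None:
            durations = DurationParams(p_g=1.0 / 1000.0, r=2, pi=1.0 - 2.0 / 50.0)
        names = sorted(pwms)
        motifs = [*names, *(n + RC_SUFFIX for n in names)]
        k2 = len(motifs)
        uniform = {m: 1.0 / k2 for m in motifs}
        p_close = 1.0 - p_motif_again - p_spacer
        if p_close <= 0:
            raise ValueError("p_motif_again + p_spacer must be < 1")
        transitions: dict[str, dict[str, float]] = {
            START: {BG_GLOBAL: 1.0},
            BG_GLOBAL: {CRM_START: p_crm, END: 1.0 - p_crm},
            CRM_START: dict(uniform),
            CRM_END: {BG_GLOBAL: 1.0},
            BG_LOCAL: dict(uniform),
        }
        for m in motifs:
            row = {m2: p_motif_again / k2 for m2 in motifs}
            row[BG_LOCAL] = p_spacer
            row[CRM_END] = p_close
            transitions[m] = row
        return cls(pwms=pwms, durations=durations, transitions=transitions, **kwargs)


def segment_logprob(
    model: HsmmModel,
    state: str,
    segment: str,
    context: LocalMarkovTable | None = None,
    start: int = 0,
) -> float:
    """log [ d_s(t) * e_s(segment) ] for an emitting state.

    Motif states use the product-multinomial PWM emission with a point-mass
    duration; background states need a fitted ``context`` table and the
    segment's ``start`` position within it.
    """
    if state in SILENT_STATES:
        raise ValueError(f"silent state {state} emits nothing")
    t = len(segment)
    if model.states.is_motif(state):
        if t != model.motif_width(state):
            return -np.inf
        return motif_emission_logprob(model.pwm_for(state), segment)
    if context is None:
        raise ValueError("background states need a fitted context table")
    d = model.duration_pmf(state, t)
    if d == 0.0:
        return -np.inf
    return float(np.log(d)) + context.segment_logprob(start, t)
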