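"""Explicit-duration dynamic programming over segmentations.

The sequence likelihood sums over all legal (state path, duration) parses;
a parse is a chain S -> b_g -> [c_s -> motifs/spacers -> c_e -> b_g]* -> E
whose segment durations tile the sequence. The forward/backward recursions
run over segment boundaries with the duration dimension bounded by each
state's truncated pmf; motif segments are restricted to candidate-lattice
placements when a lattice is supplied.

Decoding uses the posterior Viterbi rule: among legal paths, maximize the
product of the individual segment posteriors P(s_i, u_i | o_1:T) rather than
the joint path probability. Learning is EM: expected transition counts and
expected duration histograms from the segment posteriors drive closed-form
(transitions, p_g, pi) and integer-search (r) updates; PWMs and background
tables are held fixed.

All arithmetic is in log space with -inf as the impossible-event sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._alphabet import N_CODE, encode
from .background import LocalMarkovTable, fit_local_markov
from .durations import truncated_geometric_log_pmf, truncated_negbin_log_pmf
from .model import (
    BG_GLOBAL,
    BG_LOCAL,
    CRM_END,
    CRM_START,
    END,
    START,
    HsmmModel,
    permitted_edges,
)
from .scan import CandidateLattice

NEG_INF = -np.inf

__all__ = [
    "Segment",
    "SegmentPath",
    "PosteriorTables",
    "FitResult",
    "EmConfig",
    "forward",
    "backward",
    "segment_posteriors",
    "posterior_viterbi",
    "em_fit",
    "decode_to_annotations",
    "CrmInterval",
    "MotifInstance",
]


# ---------------------------------------------------------------------------
# paths

@dataclass(frozen=True)
class Segment:
    """One decoded segment: silent markers carry duration 0."""

    state: str
    start: int
    duration: int

    @property
    def end(self) -> int:
        return self.start + self.duration


@dataclass(frozen=True)
class SegmentPath:
    """An ordered parse of a sequence into state segments."""

    segments: tuple[Segment, ...]

    def __iter__(self):
        return iter(self.segments)

    def emitting(self) -> list[Segment]:
        return [
            s
            for s in self.segments
            if s.state not in (START, END, CRM_START, CRM_END)
        ]

    def total_length(self) -> int:
        return sum(s.duration for s in self.segments)

    def validate(self, model: HsmmModel, length: int) -> None:
        """Check tiling, motif widths, permitted edges and CRM bracketing."""
        if self.total_length() != length:
            raise ValueError("segment durations do not sum to the sequence length")
        pos = 0
        prev = START
        allowed = permitted_edges(model.states)
        depth = 0
        motifs_in_crm = 0
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError(f"segment {seg} does not abut at position {pos}")
            if (prev, seg.state) not in allowed:
                raise ValueError(f"transition {prev}->{seg.state} not permitted")
            if model.states.is_motif(seg.state):
                if seg.duration != model.motif_width(seg.state):
                    raise ValueError(f"motif segment {seg} has wrong duration")
                motifs_in_crm += 1
            if seg.state == CRM_START:
                if depth:
                    raise ValueError("nested CRM start")
                depth, motifs_in_crm = 1, 0
            elif seg.state == CRM_END:
                if not depth or motifs_in_crm == 0:
                    raise ValueError("CRM end without start or without motifs")
                depth = 0
            pos += seg.duration
            prev = seg.state
        if depth:
            raise ValueError("unterminated CRM")
        if (prev, END) not in allowed:
            raise ValueError(f"path may not end in state {prev}")


@dataclass(frozen=True)
class CrmInterval:
    start: int
    end: int


@dataclass(frozen=True)
class MotifInstance:
    motif: str
    state: str
    start: int
    end: int
    strand: str


def decode_to_annotations(
    path: SegmentPath,
) -> tuple[list[CrmInterval], list[MotifInstance]]:
    """CRM intervals (first motif start to last motif end per c_s..c_e
    stretch) and motif instance records with strand."""
    crms: list[CrmInterval] = []
    motifs: list[MotifInstance] = []
    in_crm = False
    first = last = None
    for seg in path:
        if seg.state == CRM_START:
            if in_crm:
                raise ValueError("malformed CRM bracketing: nested c_s")
            in_crm, first, last = True, None, None
        elif seg.state == CRM_END:
            if not in_crm or first is None:
                raise ValueError("malformed CRM bracketing: empty or stray c_e")
            crms.append(CrmInterval(first, last))
            in_crm = False
        elif seg.state not in (START, END, BG_GLOBAL, BG_LOCAL):
            # motif segment
            if not in_crm:
                raise ValueError("motif segment outside CRM bracketing")
            strand = "-" if seg.state.endswith("_rc") else "+"
            base = seg.state[:-3] if strand == "-" else seg.state
            motifs.append(MotifInstance(base, seg.state, seg.start, seg.end, strand))
            if first is None:
                first = seg.start
            last = seg.end
    if in_crm:
        raise ValueError("malformed CRM bracketing: unterminated c_s")
    return crms, motifs


# ---------------------------------------------------------------------------
# compilation and per-sequence precomputation

@dataclass
class CompiledModel:
    """Effective transition structure over emitting states only.

    Silent states are composed through: an edge carries the product of the
    underlying edge probabilities, and ``silent_via`` remembers the silent
    chain so decoded paths can restore the CRM boundary markers.
    """

    states: tuple[str, ...]
    idx: dict[str, int]
    logA: np.ndarray
    logA_start: np.ndarray
    logA_end: np.ndarray
    silent_via: dict[tuple[int, int], tuple[str, ...]]
    widths: dict[str, int]
    logd_g: np.ndarray
    logd_c: np.ndarray
    i_bc: int
    i_bg: int


def compile_model(
    model: HsmmModel, bound_g: int | None = None, bound_c: int | None = None
) -> CompiledModel:
    states = model.states.emitting_states
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    A = np.zeros((n, n))
    A_start = np.zeros(n)
    A_end = np.zeros(n)
    via: dict[tuple[int, int], tuple[str, ...]] = {}
    silents = (CRM_START, CRM_END)
    for i, si in enumerate(states):
        A_end[i] = model.trans(si, END)
        for j, sj in enumerate(states):
            p = model.trans(si, sj)
            for z in silents:
                pz = model.trans(si, z) * model.trans(z, sj)
                if pz > 0:
                    via[(i, j)] = (z,)
                p += pz
            A[i, j] = p
    for j, sj in enumerate(states):
        p = model.trans(START, sj)
        for z in silents:
            p += model.trans(START, z) * model.trans(z, sj)
        A_start[j] = p
    with np.errstate(divide="ignore"):
        logA, logA_start, logA_end = np.log(A), np.log(A_start), np.log(A_end)
    d = model.durations
    U_g = bound_g if bound_g is not None else d.bg_global_bound()
    U_c = bound_c if bound_c is not None else d.bg_local_bound()
    return CompiledModel(
        states=states,
        idx=idx,
        logA=logA,
        logA_start=logA_start,
        logA_end=logA_end,
        silent_via=via,
        widths={m: model.motif_width(m) for m in model.states.all_motif_states},
        logd_g=truncated_geometric_log_pmf(d.p_g, U_g),
        logd_c=truncated_negbin_log_pmf(d.r, d.pi, max(U_c, d.r)),
        i_bc=idx[BG_LOCAL],
        i_bg=idx[BG_GLOBAL],
    )


@dataclass
class SeqData:
    """Fixed per-sequence quantities: background tables and motif emission
    scores (lattice-masked). Independent of the learnable parameters, so EM
    computes them once."""

    codes: np.ndarray
    T: int
    table_g: LocalMarkovTable
    table_c: LocalMarkovTable
    mscore: dict[str, np.ndarray]
    lattice: CandidateLattice | None


def prepare_sequence(
    model: HsmmModel,
    sequence: str | np.ndarray,
    lattice: CandidateLattice | None = None,
) -> SeqData:
    codes = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    T = codes.shape[0]
    table_g = fit_local_markov(
        codes, model.bg_order_global, model.window_halfwidth, model.bg_pseudocount
    )
    table_c = fit_local_markov(
        codes, model.bg_order_local, model.window_halfwidth, model.bg_pseudocount
    )
    mscore: dict[str, np.ndarray] = {}
    for state in model.states.all_motif_states:
        pwm = model.pwm_for(state)
        w = pwm.width
        n_pos = max(T - w + 1, 0)
        logm = pwm.log_matrix
        sc = np.zeros(n_pos)
        for off in range(w):
            col = codes[off : off + n_pos]
            safe = np.minimum(col, 3)
            sc += np.where(col == N_CODE, np.log(0.25), logm[off, safe])
        if lattice is not None:
            adm = lattice.admissible[state]
            sc = np.where(adm[:n_pos], sc, NEG_INF)
        mscore[state] = sc
    return SeqData(codes, T, table_g, table_c, mscore, lattice)


def _lse(vals: np.ndarray) -> float:
    m = vals.max() if vals.size else NEG_INF
    if m == NEG_INF:
        return NEG_INF
    return float(m + np.log(np.exp(vals - m).sum()))


def _lse_axis(mat: np.ndarray, axis: int) -> np.ndarray:
    m = mat.max(axis=axis)
    safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = safe + np.log(np.exp(mat - np.expand_dims(safe, axis)).sum(axis=axis))
    return np.where(m == NEG_INF, NEG_INF, out)


# ---------------------------------------------------------------------------
# forward / backward

@dataclass
class PosteriorTables:
    """Forward/backward segment quantities and derived posteriors.

    ``fa[j, t]``: log P(o_1:t, a j-segment ends at t);
    ``ia[j, t]``: log P(o_1:t, a j-segment starts at t+1);
    ``fb[j, t]``: log P(o_t+1:T | a j-segment ended at t);
    ``ib[j, t]``: log P(o_t+1:T | a j-segment starts at t+1).
    """

    compiled: CompiledModel
    sd: SeqData
    loglik: float
    fa: np.ndarray | None = None
    ia: np.ndarray | None = None
    fb: np.ndarray | None = None
    ib: np.ndarray | None = None

    # -- posterior accessors -------------------------------------------------
    def segment_logposterior(self, state: str, start: int, duration: int) -> float:
        """log P(a segment of ``state`` covers [start, start+duration) | o)."""
        if self.fa is None or self.fb is None:
            raise ValueError("requires both forward and backward tables")
        c, sd = self.compiled, self.sd
        j = c.idx[state]
        p, t = start, start + duration
        if p < 0 or t > sd.T or duration < 1:
            return NEG_INF
        if state in c.widths:
            w = c.widths[state]
            if duration != w or p >= sd.mscore[state].shape[0]:
                return NEG_INF
            core = self.ia[j, p] + sd.mscore[state][p]
        elif state == BG_GLOBAL:
            if duration > c.logd_g.shape[0]:
                return NEG_INF
            core = (
                self.ia[j, p]
                + c.logd_g[duration - 1]
                + sd.table_g.prefix[t]
                - sd.table_g.prefix[p]
            )
        elif state == BG_LOCAL:
            if duration > c.logd_c.shape[0]:
                return NEG_INF
            core = (
                self.ia[j, p]
                + c.logd_c[duration - 1]
                + sd.table_c.prefix[t]
                - sd.table_c.prefix[p]
            )
        else:
            raise ValueError(f"unknown state {state}")
        return float(core + self.fb[j, t] - self.loglik)

    def covering_mass(self) -> np.ndarray:
        """Total posterior mass of segments covering each position; equals 1
        everywhere by the law of total probability."""
        c, sd = self.compiled, self.sd
        T = sd.T
        diff = np.zeros(T + 1)
        for state in c.states:
            j = c.idx[state]
            if state in c.widths:
                w = c.widths[state]
                n_pos = sd.mscore[state].shape[0]
                if n_pos <= 0:
                    continue
                ps = np.arange(n_pos)
                vals = (
                    self.ia[j, ps]
                    + sd.mscore[state]
                    + self.fb[j, ps + w]
                    - self.loglik
                )
                wts = np.exp(vals)
                np.add.at(diff, ps, wts)
                np.add.at(diff, ps + w, -wts)
            else:
                logd, pref = self._bg_parts(state)
                for u in range(1, min(logd.shape[0], T) + 1):
                    ps = np.arange(0, T - u + 1)
                    vals = (
                        self.ia[j, ps]
                        + logd[u - 1]
                        + pref[ps + u]
                        - pref[ps]
                        + self.fb[j, ps + u]
                        - self.loglik
                    )
                    wts = np.exp(vals)
                    np.add.at(diff, ps, wts)
                    np.add.at(diff, ps + u, -wts)
        return np.cumsum(diff[:-1])

    def state_occupancy(self, state: str) -> np.ndarray:
        """Posterior probability that each position lies in a ``state``
        segment."""
        c, sd = self.compiled, self.sd
        T = sd.T
        j = c.idx[state]
        diff = np.zeros(T + 1)
        if state in c.widths:
            w = c.widths[state]
            n_pos = sd.mscore[state].shape[0]
            if n_pos > 0:
                ps = np.arange(n_pos)
                wts = np.exp(
                    self.ia[j, ps] + sd.mscore[state] + self.fb[j, ps + w] - self.loglik
                )
                np.add.at(diff, ps, wts)
                np.add.at(diff, ps + w, -wts)
        else:
            logd, pref = self._bg_parts(state)
            for u in range(1, min(logd.shape[0], T) + 1):
                ps = np.arange(0, T - u + 1)
                wts = np.exp(
                    self.ia[j, ps]
                    + logd[u - 1]
                    + pref[ps + u]
                    - pref[ps]
                    + self.fb[j, ps + u]
                    - self.loglik
                )
                np.add.at(diff, ps, wts)
                np.add.at(diff, ps + u, -wts)
        return np.cumsum(diff[:-1])

    def crm_base_posterior(self) -> np.ndarray:
        """Per-position posterior of lying inside a CRM (= 1 minus global
        background occupancy)."""
        return 1.0 - self.state_occupancy(BG_GLOBAL)

    def _bg_parts(self, state):
        if state == BG_GLOBAL:
            return self.compiled.logd_g, self.sd.table_g.prefix
        return self.compiled.logd_c, self.sd.table_c.prefix


def _run_forward(c: CompiledModel, sd: SeqData) -> tuple[np.ndarray, np.ndarray, float]:
    T = sd.T
    n = len(c.states)
    fa = np.full((n, T + 1), NEG_INF)
    ia = np.full((n, T + 1), NEG_INF)
    ia[:, 0] = c.logA_start
    pref_g, pref_c = sd.table_g.prefix, sd.table_c.prefix
    xg = np.full(T + 1, NEG_INF)
    xc = np.full(T + 1, NEG_INF)
    xg[0] = ia[c.i_bg, 0]
    xc[0] = ia[c.i_bc, 0]
    U_g, U_c = c.logd_g.shape[0], c.logd_c.shape[0]
    motif_items = [(c.idx[s], c.widths[s], sd.mscore[s]) for s in c.states if s in c.widths]
    for t in range(1, T + 1):
        for j, w, msc in motif_items:
            p = t - w
            if p >= 0 and p < msc.shape[0]:
                fa[j, t] = ia[j, p] + msc[p]
        a = max(0, t - U_c)
        fa[c.i_bc, t] = pref_c[t] + _lse(xc[a:t] + c.logd_c[t - a - 1 :: -1])
        a = max(0, t - U_g)
        fa[c.i_bg, t] = pref_g[t] + _lse(xg[a:t] + c.logd_g[t - a - 1 :: -1])
        if t < T:
            ia[:, t] = _lse_axis(fa[:, t][:, None] + c.logA, axis=0)
            xg[t] = ia[c.i_bg, t] - pref_g[t]
            xc[t] = ia[c.i_bc, t] - pref_c[t]
    loglik = _lse(fa[:, T] + c.logA_end)
    return fa, ia, loglik


def _run_backward(c: CompiledModel, sd: SeqData) -> tuple[np.ndarray, np.ndarray, float]:
    T = sd.T
    n = len(c.states)
    fb = np.full((n, T + 1), NEG_INF)
    ib = np.full((n, T + 1), NEG_INF)
    fb[:, T] = c.logA_end
    pref_g, pref_c = sd.table_g.prefix, sd.table_c.prefix
    yg = np.full(T + 1, NEG_INF)
    yc = np.full(T + 1, NEG_INF)
    yg[T] = fb[c.i_bg, T] + pref_g[T]
    yc[T] = fb[c.i_bc, T] + pref_c[T]
    U_g, U_c = c.logd_g.shape[0], c.logd_c.shape[0]
    motif_items = [(c.idx[s], c.widths[s], sd.mscore[s]) for s in c.states if s in c.widths]
    for t in range(T - 1, -1, -1):
        for j, w, msc in motif_items:
            if t + w <= T and t < msc.shape[0]:
                ib[j, t] = msc[t] + fb[j, t + w]
        b = min(T, t + U_c)
        ib[c.i_bc, t] = _lse(yc[t + 1 : b + 1] + c.logd_c[: b - t]) - pref_c[t]
        b = min(T, t + U_g)
        ib[c.i_bg, t] = _lse(yg[t + 1 : b + 1] + c.logd_g[: b - t]) - pref_g[t]
        if t >= 1:
            fb[:, t] = _lse_axis(c.logA + ib[:, t][None, :], axis=1)
            yg[t] = fb[c.i_bg, t] + pref_g[t]
            yc[t] = fb[c.i_bc, t] + pref_c[t]
    loglik = _lse(c.logA_start + ib[:, 0])
    return fb, ib, loglik


def _tables(
    model: HsmmModel,
    sequence,
    lattice,
    need_backward: bool = True,
    sd: SeqData | None = None,
    compiled: CompiledModel | None = None,
) -> PosteriorTables:
    if sd is None:
        sd = prepare_sequence(model, sequence, lattice)
    if compiled is None:
        d = model.durations
        compiled = compile_model(
            model, d.bg_global_bound(sd.T), d.bg_local_bound(sd.T)
        )
    if sd.T < 1:
        warnings.warn("sequence shorter than the smallest legal parse", stacklevel=2)
        return PosteriorTables(compiled, sd, NEG_INF)
    fa, ia, ll = _run_forward(compiled, sd)
    out = PosteriorTables(compiled, sd, ll, fa=fa, ia=ia)
    if np.isneginf(ll):
        warnings.warn("no admissible parse; log-likelihood is -inf", stacklevel=2)
    if need_backward:
        fb, ib, _ = _run_backward(compiled, sd)
        out.fb, out.ib = fb, ib
    return out


def forward(
    model: HsmmModel,
    sequence: str | np.ndarray,
    lattice: CandidateLattice | None = None,
) -> PosteriorTables:
    """Forward pass only: alpha tables and the sequence log-likelihood."""
    return _tables(model, sequence, lattice, need_backward=False)


def backward(
    model: HsmmModel,
    sequence: str | np.ndarray,
    lattice: CandidateLattice | None = None,
) -> PosteriorTables:
    """Backward pass; ``loglik`` is recomputed from the beta recursion and
    agrees with the forward value to numerical precision."""
    sd = prepare_sequence(model, sequence, lattice)
    d = model.durations
    compiled = compile_model(model, d.bg_global_bound(sd.T), d.bg_local_bound(sd.T))
    fb, ib, ll = _run_backward(compiled, sd)
    return PosteriorTables(compiled, sd, ll, fb=fb, ib=ib)


def segment_posteriors(
    model: HsmmModel,
    sequence: str | np.ndarray,
    lattice: CandidateLattice | None = None,
) -> PosteriorTables:
    """Both passes; exposes segment posteriors and occupancy."""
    return _tables(model, sequence, lattice, need_backward=True)


# ---------------------------------------------------------------------------
# posterior Viterbi

def posterior_viterbi(
    model: HsmmModel,
    sequence: str | np.ndarray,
    lattice: CandidateLattice | None = None,
    tables: PosteriorTables | None = None,
) -> SegmentPath:
    """The legal path maximizing the product of segment posteriors.

    Ties are broken deterministically: at each cell the scan prefers the
    earliest segment start, then the smallest state index.
    """
    if tables is None:
        tables = _tables(model, sequence, lattice, need_backward=True)
    c, sd = tables.compiled, tables.sd
    T, n = sd.T, len(c.states)
    L = tables.loglik
    if np.isneginf(L):
        raise ValueError("sequence has no admissible parse")
    ia, fb = tables.ia, tables.fb
    pref_g, pref_c = sd.table_g.prefix, sd.table_c.prefix
    legal = np.where(np.isfinite(c.logA), 0.0, NEG_INF)
    V = np.full((n, T + 1), NEG_INF)
    Vin = np.full((n, T + 1), NEG_INF)
    Vin[np.isfinite(c.logA_start), 0] = 0.0
    bp_i = np.zeros((n, T + 1), dtype=np.int64)
    bp_u = {c.i_bg: np.zeros(T + 1, dtype=np.int64), c.i_bc: np.zeros(T + 1, dtype=np.int64)}
    wg = np.full(T + 1, NEG_INF)
    wc = np.full(T + 1, NEG_INF)
    wg[0] = ia[c.i_bg, 0] + Vin[c.i_bg, 0]
    wc[0] = ia[c.i_bc, 0] + Vin[c.i_bc, 0]
    U_g, U_c = c.logd_g.shape[0], c.logd_c.shape[0]
    motif_items = [(c.idx[s], c.widths[s], sd.mscore[s]) for s in c.states if s in c.widths]
    for t in range(1, T + 1):
        for j, w, msc in motif_items:
            p = t - w
            if p >= 0 and p < msc.shape[0]:
                V[j, t] = ia[j, p] + msc[p] + fb[j, t] - L + Vin[j, p]
        for j, wvec, logd, pref, U in (
            (c.i_bc, wc, c.logd_c, pref_c, U_c),
            (c.i_bg, wg, c.logd_g, pref_g, U_g),
        ):
            a = max(0, t - U)
            vals = wvec[a:t] + logd[t - a - 1 :: -1]
            k = int(np.argmax(vals))  # first max = earliest start
            best = vals[k]
            if np.isfinite(best):
                V[j, t] = best + pref[t] + fb[j, t] - L
                bp_u[j][t] = t - (a + k)
        if t <= T:
            scores = V[:, t][:, None] + legal
            Vin[:, t] = scores.max(axis=0)
            bp_i[:, t] = scores.argmax(axis=0)
            wg[t] = ia[c.i_bg, t] - pref_g[t] + Vin[c.i_bg, t]
            wc[t] = ia[c.i_bc, t] - pref_c[t] + Vin[c.i_bc, t]
    final = np.where(np.isfinite(c.logA_end), V[:, T], NEG_INF)
    j = int(np.argmax(final))
    if np.isneginf(final[j]):
        raise ValueError("no legal path reaches the end state")
    segs: list[tuple[int, int, int]] = []  # (state idx, start, duration)
    t = T
    while t > 0:
        state = c.states[j]
        u = c.widths[state] if state in c.widths else int(bp_u[j][t])
        p = t - u
        segs.append((j, p, u))
        if p == 0:
            break
        j = int(bp_i[j, p])
        t = p
    segs.reverse()
    return _expand_path(c, segs)


def _expand_path(c: CompiledModel, segs: list[tuple[int, int, int]]) -> SegmentPath:
    """Insert silent CRM boundary markers along effective edges."""
    out: list[Segment] = []
    prev: int | None = None
    for j, p, u in segs:
        if prev is not None:
            for z in c.silent_via.get((prev, j), ()):
                out.append(Segment(z, p, 0))
        out.append(Segment(c.states[j], p, u))
        prev = j
    # closing silent chain before END (motif -> c_e -> ... not possible at end
    # since only b_g may end the sequence, but keep symmetric for safety)
    return SegmentPath(tuple(out))


# ---------------------------------------------------------------------------
# EM

@dataclass
class EmConfig:
    tol: float = 1e-6
    max_iter: int = 100
    r_max: int = 20
    n_restarts: int = 0  # extra fits from jittered starts; best loglik wins
    restart_seed: int = 0
    restart_scale: float = 0.35  # sd of the multiplicative log-jitter
    verbose: bool = False


@dataclass
class FitResult:
    model: HsmmModel
    loglik_trace: list[float]
    n_iterations: int
    converged: bool


def _expected_counts(c: CompiledModel, sd: SeqData, tab: PosteriorTables):
    """Expected effective-edge counts, end counts, and background duration
    histograms for one sequence."""
    T = sd.T
    n = len(c.states)
    L = tab.loglik
    fa, ia, fb, ib = tab.fa, tab.ia, tab.fb, tab.ib
    edge = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if not np.isfinite(c.logA[i, j]):
                continue
            vals = fa[i, 1:T] + c.logA[i, j] + ib[j, 1:T] - L
            edge[i, j] = np.exp(vals).sum()
    end = np.exp(fa[:, T] + c.logA_end - L)
    hists = {}
    for j, logd, pref in (
        (c.i_bg, c.logd_g, sd.table_g.prefix),
        (c.i_bc, c.logd_c, sd.table_c.prefix),
    ):
        U = min(logd.shape[0], T)
        x = ia[j, :T] - pref[:T]
        y = fb[j, 1 : T + 1] + pref[1 : T + 1]
        mx = x.max()
        my = y.max()
        h = np.zeros(logd.shape[0])
        if np.isfinite(mx) and np.isfinite(my):
            X = np.exp(x - mx)
            Y = np.exp(y - my)
            corr = np.convolve(Y, X[::-1])  # corr[T-1+l] = sum_p X[p] Y[p+l]
            lags = np.maximum(corr[T - 1 : T - 1 + U], 0.0)
            # combine in log space: the offset mx+my-L alone may overflow
            # even though the true expected count (<= T) cannot
            with np.errstate(divide="ignore"):
                logh = (mx + my - L) + logd[:U] + np.log(lags)
            h[:U] = np.exp(np.minimum(logh, 700.0))
        hists[j] = h
    return edge, end, hists


def _fit_negbin(hist: np.ndarray, r_max: int, max_duration: int) -> tuple[int, float]:
    """Integer search on r; pi matches the conditional mean given r; the
    winner maximizes the expected truncated log-likelihood."""
    total = hist.sum()
    u = np.arange(1, hist.shape[0] + 1)
    mean = float((u * hist).sum() / total)
    best = (1, 0.0)
    best_obj = NEG_INF
    for r in range(1, min(r_max, max_duration) + 1):
        if hist[: r - 1].sum() > 0:
            continue  # observed durations below r are impossible under this r
        pi = min(max(1.0 - r / mean, 0.0), 1.0 - 1e-12)
        logd = truncated_negbin_log_pmf(r, pi, max_duration)
        with np.errstate(invalid="ignore"):
            obj = float(np.where(hist > 0, hist * logd, 0.0).sum())
        if obj > best_obj:
            best_obj = obj
            best = (r, pi)
    return best


def _jitter_model(model: HsmmModel, rng: np.random.Generator, scale: float) -> HsmmModel:
    """A randomly perturbed copy: transition rows multiplied by lognormal
    noise and renormalized, duration parameters nudged on their natural
    scales (r may step down by one; the integer search cannot raise it past
    durations the current support forbids)."""
    from .model import DurationParams

    trans = {}
    for src, row in model.transitions.items():
        keys = list(row)
        vals = np.array([row[k] for k in keys])
        if len(keys) > 1 and vals.sum() > 0:
            vals = vals * np.exp(rng.normal(0.0, scale, size=len(keys)))
            vals = vals / vals.sum()
        trans[src] = dict(zip(keys, vals.tolist()))
    d = model.durations
    p_g = float(np.clip(d.p_g * np.exp(rng.normal(0.0, scale)), 1e-6, 1.0))
    logit = np.log(d.pi / (1 - d.pi)) if 0 < d.pi < 1 else 0.0
    pi = float(1 / (1 + np.exp(-(logit + rng.normal(0.0, scale)))))
    r = max(1, d.r - int(rng.integers(0, 2)))
    return model.replace_params(
        durations=DurationParams(p_g, r, min(pi, 1 - 1e-9), d.max_duration),
        transitions=trans,
    )


def em_fit(
    model: HsmmModel,
    sequences: list[str],
    lattices: list[CandidateLattice] | None = None,
    config: EmConfig | None = None,
) -> FitResult:
    """Modified Baum-Welch: learn transitions and duration parameters.

    PWMs and the per-sequence background tables are held fixed. Expected
    counts are summed across sequences (independent-sequence likelihood).
    The duration truncation bounds are frozen at fit start (quantile bound
    capped at the longest training sequence) so the objective is constant
    across iterations and the log-likelihood trace is non-decreasing.

    With ``n_restarts`` > 0, additional fits run from seeded random jitters
    of the initial model and the fit with the best final log-likelihood is
    returned (EM converges to local optima).
    """
    if not sequences:
        raise ValueError("need at least one training sequence")
    cfg = config or EmConfig()
    if cfg.n_restarts > 0:
        rng = np.random.default_rng(cfg.restart_seed)
        base = EmConfig(tol=cfg.tol, max_iter=cfg.max_iter, r_max=cfg.r_max,
                        verbose=cfg.verbose)
        fits = [em_fit(model, sequences, lattices, base)]
        for _ in range(cfg.n_restarts):
            start = _jitter_model(model, rng, cfg.restart_scale)
            fits.append(em_fit(start, sequences, lattices, base))
        return max(fits, key=lambda f: f.loglik_trace[-1])
    if lattices is None:
        lattices = [None] * len(sequences)
    sds = [
        prepare_sequence(model, seq, lat) for seq, lat in zip(sequences, lattices)
    ]
    T_max = max(sd.T for sd in sds)
    d0 = model.durations
    bound_g = d0.bg_global_bound(T_max)
    bound_c = d0.bg_local_bound(T_max)

    cur = model
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        c = compile_model(cur, bound_g, bound_c)
        n = len(c.states)
        edge_sum = np.zeros((n, n))
        end_sum = np.zeros(n)
        hist_g = np.zeros(bound_g)
        hist_c = np.zeros(c.logd_c.shape[0])
        total_ll = 0.0
        n_used = 0
        for sd in sds:
            fa, ia, ll = _run_forward(c, sd)
            if np.isneginf(ll):
                warnings.warn("skipping sequence with no admissible parse", stacklevel=2)
                continue
            fb, ib, _ = _run_backward(c, sd)
            tab = PosteriorTables(c, sd, ll, fa=fa, ia=ia, fb=fb, ib=ib)
            edge, end, hists = _expected_counts(c, sd, tab)
            edge_sum += edge
            end_sum += end
            hist_g += hists[c.i_bg]
            hist_c += hists[c.i_bc]
            total_ll += ll
            n_used += 1
        if n_used == 0:
            raise ValueError("no training sequence admits a parse")
        trace.append(total_ll)
        if cfg.verbose:
            print(f"EM iteration {it}: loglik {total_ll:.4f}")
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(total_ll - prev) <= cfg.tol * (abs(prev) + 1e-12):
                converged = True
                break
        cur = _m_step(cur, c, edge_sum, end_sum, hist_g, hist_c, cfg, bound_c)
    return FitResult(cur, trace, it, converged)


def _m_step(
    model: HsmmModel,
    c: CompiledModel,
    edge: np.ndarray,
    end: np.ndarray,
    hist_g: np.ndarray,
    hist_c: np.ndarray,
    cfg: EmConfig,
    bound_c: int,
) -> HsmmModel:
    from .model import DurationParams

    motifs = model.states.all_motif_states
    midx = [c.idx[m] for m in motifs]
    new_trans = {s: dict(row) for s, row in model.transitions.items()}

    # b_g row: open a CRM vs end the sequence
    open_crm = edge[c.i_bg, midx].sum()
    end_seq = end[c.i_bg]
    tot = open_crm + end_seq
    if tot > 0:
        new_trans[BG_GLOBAL] = {CRM_START: open_crm / tot, END: end_seq / tot}
    # c_s row: which motif opens a CRM
    cs = edge[c.i_bg, midx]
    if cs.sum() > 0:
        new_trans[CRM_START] = {m: v / cs.sum() for m, v in zip(motifs, cs)}
    # b_c row
    bc = edge[c.i_bc, midx]
    if bc.sum() > 0:
        new_trans[BG_LOCAL] = {m: v / bc.sum() for m, v in zip(motifs, bc)}
    # motif rows: to motifs, to b_c, to c_e (observed as motif -> b_g)
    for m in motifs:
        i = c.idx[m]
        to_motifs = edge[i, midx]
        to_bc = edge[i, c.i_bc]
        to_ce = edge[i, c.i_bg]
        tot = to_motifs.sum() + to_bc + to_ce
        if tot > 0:
            row = {m2: v / tot for m2, v in zip(motifs, to_motifs)}
            row[BG_LOCAL] = to_bc / tot
            row[CRM_END] = to_ce / tot
            new_trans[m] = row

    # durations
    d = model.durations
    p_g = d.p_g
    if hist_g.sum() > 0:
        u = np.arange(1, hist_g.shape[0] + 1)
        mean = float((u * hist_g).sum() / hist_g.sum())
        p_g = min(max(1.0 / mean, 1e-12), 1.0)
    r, pi = d.r, d.pi
    if hist_c.sum() > 0:
        r, pi = _fit_negbin(hist_c, cfg.r_max, bound_c)
    durations = DurationParams(p_g=p_g, r=r, pi=pi, max_duration=d.max_duration)
    return model.replace_params(durations=durations, transitions=new_trans)
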