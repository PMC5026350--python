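"""Generative sampling of annotated synthetic regulatory sequences.

The segmentation model is generative: a Markov walk over states, an explicit
duration draw at each emitting state, and column-wise (motif) or Markov-chain
(background) base emission. Sampling from a model instance yields sequences
together with their true parse, which is the ground truth for recovery and
benchmarking experiments.

Background emission uses a stationary Markov chain with configurable order
and composition; the windowed position-dependent estimator is a fitting-time
device, not a generative one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._alphabet import decode
from .engine import (
    CrmInterval,
    MotifInstance,
    Segment,
    SegmentPath,
    decode_to_annotations,
)
from .model import BG_GLOBAL, BG_LOCAL, CRM_END, CRM_START, END, START, HsmmModel

__all__ = ["BackgroundChain", "SimulatedTrs", "sample_path", "emit_sequence", "generate_dataset"]


@dataclass(frozen=True)
class BackgroundChain:
    """Stationary background used for emission during simulation.

    ``composition`` is the base distribution; for order >= 1 a conditional
    table (4^order, 4) may be supplied, otherwise bases are iid.
    """

    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    order: int = 0
    conditional: np.ndarray | None = None

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("composition must be 4 nonnegative values summing to 1")
        if self.order > 0 and self.conditional is not None:
            cond = np.asarray(self.conditional, dtype=float)
            if cond.shape != (4**self.order, 4):
                raise ValueError("conditional table must have shape (4^order, 4)")

    def draw(self, rng: np.random.Generator, length: int, history: list[int]) -> list[int]:
        comp = np.asarray(self.composition)
        out: list[int] = []
        if self.order == 0 or self.conditional is None:
            return list(rng.choice(4, size=length, p=comp))
        for _ in range(length):
            ctx = (history + out)[-self.order :]
            if len(ctx) < self.order:
                probs = comp
            else:
                idx = 0
                for c in ctx:
                    idx = idx * 4 + c
                probs = self.conditional[idx]
            out.append(int(rng.choice(4, p=probs)))
        return out


@dataclass
class SimulatedTrs:
    """One simulated sequence with its generating parse and true CRMs."""

    name: str
    sequence: str
    truth_path: SegmentPath
    truth_crms: list[CrmInterval]
    truth_motifs: list[MotifInstance]
    seed: int
    truncated: bool = False


def sample_path(
    model: HsmmModel,
    seed: int | np.random.Generator,
    max_length: int = 100_000,
) -> tuple[SegmentPath, bool]:
    """Sample a state/duration path S -> ... -> E.

    Each emitting state draws its duration from the model's truncated,
    renormalized pmf. If the walk exceeds ``max_length`` the path is trimmed
    back to global background, whose final duration is clipped so the total
    is exactly ``max_length``; the flag in the returned pair marks this.
    """
    rng = np.random.default_rng(seed)
    dur = model.durations
    pmf_g = np.exp(dur.bg_global_log_pmf())
    pmf_c = np.exp(dur.bg_local_log_pmf())

    segs: list[tuple[str, int]] = []  # (state, duration)
    state = START
    total = 0
    truncated = False
    while True:
        row = model.transitions[state]
        nxt = rng.choice(list(row), p=np.asarray(list(row.values())))
        if nxt == END:
            break
        if nxt == BG_GLOBAL:
            u = 1 + int(rng.choice(pmf_g.shape[0], p=pmf_g))
        elif nxt == BG_LOCAL:
            u = 1 + int(rng.choice(pmf_c.shape[0], p=pmf_c))
        elif nxt in (CRM_START, CRM_END):
            u = 0
        else:
            u = model.motif_width(nxt)
        segs.append((nxt, u))
        total += u
        state = nxt
        if total >= max_length:
            truncated = True
            # trim back so the path ends in a clipped b_g of duration >= 1
            while True:
                while segs and segs[-1][0] != BG_GLOBAL:
                    total -= segs.pop()[1]
                if not segs:
                    raise ValueError("max_length too small for any legal path")
                total -= segs.pop()[1]
                if max_length - total >= 1:
                    break
            segs.append((BG_GLOBAL, max_length - total))
            total = max_length
            break

    out: list[Segment] = []
    pos = 0
    for s, u in segs:
        out.append(Segment(s, pos, u))
        pos += u
    return SegmentPath(tuple(out)), truncated


def emit_sequence(
    model: HsmmModel,
    path: SegmentPath,
    seed: int | np.random.Generator,
    background: BackgroundChain | None = None,
) -> str:
    """Emit nucleotides along a path: motif segments column-wise from their
    (strand-resolved) PWM, background segments from the stationary chain."""
    rng = np.random.default_rng(seed)
    bg = background or BackgroundChain()
    codes: list[int] = []
    for seg in path:
        if seg.duration == 0:
            continue
        if seg.state in (BG_GLOBAL, BG_LOCAL):
            codes.extend(bg.draw(rng, seg.duration, codes))
        else:
            mat = model.pwm_for(seg.state).matrix
            for i in range(seg.duration):
                codes.append(int(rng.choice(4, p=mat[i])))
    return decode(np.asarray(codes, dtype=np.int8))


def generate_dataset(
    model: HsmmModel,
    n: int,
    seed: int,
    max_length: int = 100_000,
    background: BackgroundChain | None = None,
    name_prefix: str = "sim",
) -> list[SimulatedTrs]:
    """n independent draws with per-sequence seeds derived from one master
    seed; each record carries sequence, true parse, and true intervals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(master.spawn(n)):
        sub = child.generate_state(1)[0] % (2**31)
        rng = np.random.default_rng(child)
        path, truncated = sample_path(model, rng, max_length)
        seq = emit_sequence(model, path, rng, background)
        crms, motifs = decode_to_annotations(path)
        out.append(
            SimulatedTrs(
                name=f"{name_prefix}{i}",
                sequence=seq,
                truth_path=path,
                truth_crms=crms,
                truth_motifs=motifs,
                seed=int(sub),
                truncated=truncated,
            )
        )
    return out
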