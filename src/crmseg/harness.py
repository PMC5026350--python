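"""Reference study conditions for recovery and benchmark experiments.

Two fixed synthetic settings exercise the full pipeline:

* a parameter-recovery setting — two strong motifs, negative-binomial
  spacers, several CRMs per ~2 kb sequence — for refitting a perturbed model
  by EM and comparing against the generating parameters;
* a plant-and-recover setting — 1 kb sequences carrying exactly one CRM —
  for scoring scan+decode predictions against the planted truth at
  nucleotide level.

The constructors are deterministic; all sampling is driven by caller seeds.
"""

from __future__ import annotations

import numpy as np

from .engine import Segment, SegmentPath, decode_to_annotations
from .model import (
    BG_GLOBAL,
    BG_LOCAL,
    CRM_END,
    CRM_START,
    DurationParams,
    HsmmModel,
)
from .pwm import Pwm
from .simulate import BackgroundChain, SimulatedTrs, emit_sequence

__all__ = [
    "strong_pwm",
    "recovery_model",
    "perturbed_recovery_start",
    "plant_model",
    "plant_dataset",
]


def strong_pwm(name: str, consensus_codes, dominant: float = 0.97) -> Pwm:
    """A near-consensus PWM: one base per position at ``dominant``, the rest
    sharing the remainder."""
    w = len(consensus_codes)
    mat = np.full((w, 4), (1.0 - dominant) / 3.0)
    mat[np.arange(w), consensus_codes] = dominant
    return Pwm(name, mat, pseudocount=0.0)


def _two_motifs(width: int) -> list[Pwm]:
    rng = np.random.default_rng(20160916)  # fixed: part of the setting
    return [
        strong_pwm("tfA", rng.integers(0, 4, size=width)),
        strong_pwm("tfB", rng.integers(0, 4, size=width)),
    ]


def recovery_model() -> HsmmModel:
    """Generating model of the parameter-recovery setting.

    The two background roles are identifiable from durations and topology
    alone: inter-module gaps are geometric with mean 100 bp while spacers
    are NB(r=3, pi=0.8) with mean 15 bp, and both backgrounds use the same
    Markov order so emission cannot blur the roles. CRMs are compact (~5
    motifs each, ~11 per sequence) so every learnable transition row —
    including the CRM-opening row, which sees one event per CRM —
    accumulates hundreds of expected events across 50 sequences."""
    return HsmmModel.default(
        _two_motifs(8),
        durations=DurationParams(p_g=1 / 100, r=3, pi=0.8),
        p_crm=0.92,
        p_motif_again=0.3,
        p_spacer=0.5,
        bg_order_global=1,
        bg_order_local=1,
        window_halfwidth=400,
    )


def perturbed_recovery_start() -> HsmmModel:
    """A deliberately misparameterized starting point for EM: slower CRM
    opening, different motif-row balance, r started above the truth (the
    integer search can widen the support downward but never upward)."""
    model = HsmmModel.default(
        _two_motifs(8),
        durations=DurationParams(p_g=1 / 150, r=5, pi=0.75),
        p_crm=0.7,
        p_motif_again=0.15,
        p_spacer=0.45,
        bg_order_global=1,
        bg_order_local=1,
        window_halfwidth=400,
    )
    return model


def fit_with_r_profile(
    start: HsmmModel,
    sequences: list[str],
    lattices,
    config=None,
    profile_iter: int = 10,
):
    """EM fit followed by a likelihood profile over the integer stopping
    count r.

    The M-step's integer search can only shrink the negative-binomial
    support (durations below the current r carry posterior mass once r is
    small, which rules larger r out forever), so EM can stall in a
    neighbouring-r basin. After the main fit, the fitted model is refit with
    r forced one step down and one step up (pi rescaled to keep the mean
    spacer length) and the solution with the best final log-likelihood wins.
    """
    from .engine import EmConfig, em_fit

    cfg = config or EmConfig()
    best = em_fit(start, sequences, lattices, cfg)
    short = EmConfig(tol=cfg.tol, max_iter=profile_iter, r_max=cfg.r_max)
    d = best.model.durations
    mean = d.r / (1.0 - d.pi)
    for r_alt in (d.r - 1, d.r + 1):
        if not 1 <= r_alt <= cfg.r_max:
            continue
        pi_alt = min(max(1.0 - r_alt / mean, 0.0), 1.0 - 1e-9)
        alt_start = best.model.replace_params(
            durations=DurationParams(d.p_g, r_alt, pi_alt, d.max_duration)
        )
        alt = em_fit(alt_start, sequences, lattices, short)
        if alt.loglik_trace[-1] > best.loglik_trace[-1]:
            best = alt
    return best


def plant_model() -> HsmmModel:
    """Model of the plant-and-recover setting: width-10 strong motifs,
    ~4 motifs per CRM, NB spacers of mean 30 bp."""
    rng = np.random.default_rng(7)
    pwms = [
        strong_pwm("tfC", rng.integers(0, 4, size=10)),
        strong_pwm("tfD", rng.integers(0, 4, size=10)),
    ]
    return HsmmModel.default(
        pwms,
        durations=DurationParams(p_g=1 / 300, r=3, pi=0.9),
        p_crm=0.5,
        p_motif_again=0.25,
        p_spacer=0.5,
        bg_order_global=1,
        bg_order_local=0,
        window_halfwidth=300,
    )


def _sample_crm_segments(model: HsmmModel, rng: np.random.Generator):
    """One CRM's internal (state, duration) run: c_s .. motifs/spacers .. c_e."""
    pmf_c = np.exp(model.durations.bg_local_log_pmf())
    segs = [(CRM_START, 0)]
    row = model.transitions[CRM_START]
    state = rng.choice(list(row), p=np.asarray(list(row.values())))
    while True:
        if state == CRM_END:
            segs.append((CRM_END, 0))
            return segs
        if state == BG_LOCAL:
            u = 1 + int(rng.choice(pmf_c.shape[0], p=pmf_c))
        else:
            u = model.motif_width(state)
        segs.append((state, u))
        row = model.transitions[state]
        state = rng.choice(list(row), p=np.asarray(list(row.values())))


def plant_dataset(
    model: HsmmModel,
    n: int,
    seed: int,
    length: int = 1000,
    background: BackgroundChain | None = None,
) -> list[SimulatedTrs]:
    """n sequences of exactly ``length`` bp, each carrying one CRM sampled
    from the model's CRM sub-process and placed uniformly at random inside
    global background."""
    master = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(master.spawn(n)):
        rng = np.random.default_rng(child)
        while True:
            crm = _sample_crm_segments(model, rng)
            crm_len = sum(u for _, u in crm)
            if crm_len <= length - 2:  # leave >= 1 bp background each side
                break
        u1 = int(rng.integers(1, length - crm_len))
        segs = [(BG_GLOBAL, u1), *crm, (BG_GLOBAL, length - crm_len - u1)]
        path_segs, pos = [], 0
        for s, u in segs:
            path_segs.append(Segment(s, pos, u))
            pos += u
        path = SegmentPath(tuple(path_segs))
        seq = emit_sequence(model, path, rng, background)
        crms, motifs = decode_to_annotations(path)
        out.append(
            SimulatedTrs(
                name=f"plant{i}",
                sequence=seq,
                truth_path=path,
                truth_crms=crms,
                truth_motifs=motifs,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
    return out
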