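"""Position-dependent local Markov background model.

Non-motif sequence is modelled by order-k Markov chains whose conditional
probabilities vary along the sequence: at position i they are estimated from
(k+1)-mer and k-mer frequencies inside a window of length 2D centred on i.
A single left-to-right pass maintains the window counts incrementally (each
unit shift removes one (k+1)-mer and adds one), so the per-position estimate
costs O(1) amortized.

Two tables are built per sequence: order m for the global (inter-module)
background and order m' for the local (intra-module) background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._alphabet import N_CODE, encode

DEFAULT_PSEUDOCOUNT = 0.25

__all__ = ["LocalMarkovTable", "fit_local_markov", "background_segment_logprob"]


@dataclass
class LocalMarkovTable:
    """Per-position conditional base probabilities.

    ``cond_logprob[i, b]`` is log P(base b at i | the k observed bases
    preceding i), estimated from the window around i. Positions i < k use a
    truncated, order-i context so the product over a segment is defined from
    the first base. ``logp_obs`` caches the log probability of the base that
    is actually observed at each position, and ``prefix`` its cumulative sum
    for O(1) segment scores.
    """

    order: int
    window_halfwidth: int
    pseudocount: float
    cond_logprob: np.ndarray  # (T, 4)
    logp_obs: np.ndarray  # (T,)
    prefix: np.ndarray  # (T+1,)

    @property
    def length(self) -> int:
        return self.logp_obs.shape[0]

    def segment_logprob(self, start: int, length: int) -> float:
        """log probability of ``length`` observed bases from ``start``."""
        if start < 0 or length < 0 or start + length > self.length:
            raise IndexError(
                f"segment [{start}, {start + length}) out of bounds "
                f"for length {self.length}"
            )
        return float(self.prefix[start + length] - self.prefix[start])

    def to_tsv(self, path) -> None:
        """Dump (position, base, log-probability) rows for diagnostics."""
        with open(path, "w") as fh:
            fh.write("position\tbase\tlog_prob\n")
            for i in range(self.length):
                for b, base in enumerate("ACGT"):
                    fh.write(f"{i}\t{base}\t{self.cond_logprob[i, b]:.10g}\n")


def _kmer_counts(codes: np.ndarray, k1: int, lo: int, hi: int) -> np.ndarray:
    """Counts of all k1-mers fully inside window [lo, hi); k1-mers containing
    N are skipped."""
    counts = np.zeros(4**k1, dtype=np.int64)
    for p in range(lo, hi - k1 + 1):
        window = codes[p : p + k1]
        if (window == N_CODE).any():
            continue
        idx = 0
        for c in window:
            idx = idx * 4 + int(c)
        counts[idx] += 1
    return counts


def fit_local_markov(
    sequence: str | np.ndarray,
    order: int,
    window_halfwidth: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> LocalMarkovTable:
    """Estimate the position-dependent order-k background table.

    Windows are clipped (not wrapped) at the sequence ends. The conditional
    for position i uses the k observed bases before i; when fewer than k are
    available the context is truncated to what exists.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if window_halfwidth <= 0:
        raise ValueError("window_halfwidth must be positive")
    codes = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    T = codes.shape[0]
    k = order
    D = window_halfwidth
    if 2 * D < 4 ** (k + 1):
        warnings.warn(
            f"window 2D={2 * D} is smaller than the 4^(k+1)={4 ** (k + 1)} "
            "context table; estimates will be sparse",
            stacklevel=2,
        )
    if T < 2 * D:
        warnings.warn(
            f"sequence length {T} < window 2D={2 * D}; windows clip to the "
            "whole sequence",
            stacklevel=2,
        )

    cond = np.empty((T, 4), dtype=float)
    counts = None
    lo_prev = hi_prev = 0
    pc = pseudocount
    for i in range(T):
        lo, hi = max(0, i - D), min(T, i + D)
        if counts is None:
            counts = _kmer_counts(codes, k + 1, lo, hi)
        else:
            # incremental update: windows move by at most one on either side
            while lo_prev < lo:
                counts -= _kmer_counts(codes, k + 1, lo_prev, min(lo_prev + k + 1, hi_prev))
                lo_prev += 1
            while hi_prev < hi:
                counts += _kmer_counts(codes, k + 1, max(hi_prev - k, lo), hi_prev + 1)
                hi_prev += 1
        lo_prev, hi_prev = lo, hi

        ki = min(k, i)  # truncated context near the sequence start
        ctx = codes[i - ki : i]
        if (ctx == N_CODE).any() if ki else False:
            cond[i] = 0.25
            continue
        if ki == k:
            idx = 0
            for c in ctx:
                idx = idx * 4 + int(c)
            row = counts[idx * 4 : idx * 4 + 4].astype(float)
        else:
            # lower-order conditional from scratch for the few edge positions
            sub = _kmer_counts(codes, ki + 1, lo, hi)
            idx = 0
            for c in ctx:
                idx = idx * 4 + int(c)
            row = sub[idx * 4 : idx * 4 + 4].astype(float)
        row += pc
        total = row.sum()
        cond[i] = row / total if total > 0 else 0.25

    with np.errstate(divide="ignore"):
        cond_log = np.log(cond)
    logp_obs = np.where(
        codes == N_CODE,
        np.log(0.25),
        cond_log[np.arange(T), np.minimum(codes, 3)],
    )
    prefix = np.concatenate([[0.0], np.cumsum(logp_obs)])
    return LocalMarkovTable(k, D, pc, cond_log, logp_obs, prefix)


def background_segment_logprob(
    table: LocalMarkovTable, sequence: str | np.ndarray, start: int, length: int
) -> float:
    """log probability of the observed segment [start, start+length).

    The sequence argument is accepted for interface symmetry and checked
    against the fitted length; the table already caches the observed-base
    probabilities.
    """
    codes = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    if codes.shape[0] != table.length:
        raise ValueError("sequence length does not match the fitted table")
    return table.segment_logprob(start, length)
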