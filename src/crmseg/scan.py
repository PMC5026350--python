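"""PWM pre-scanning and the candidate lattice.

Explicit-duration dynamic programming over every possible motif placement is
wasteful: almost all windows are obvious non-matches. Before parsing, each
PWM is scored against both strands and placements whose match p-value (under
the sequence's global base composition) passes a threshold are retained. The
parser then only considers state paths whose motif segments start at retained
placements; background segments are unrestricted, and overlapping candidate
sites are all kept — path legality during decoding resolves conflicts.

Scores are log-odds in bits; p-values are exact, computed by dynamic
programming over the discretized column-score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._alphabet import N_CODE, encode
from .background import LocalMarkovTable
from .model import HsmmModel, RC_SUFFIX
from .pwm import Pwm, reverse_complement_pwm

DEFAULT_PVALUE_THRESHOLD = 1e-4
DEFAULT_GRANULARITY_BITS = 1e-3

__all__ = [
    "MotifSite",
    "CandidateLattice",
    "score_site",
    "exact_score_pvalue",
    "scan_sequence",
    "sites_to_bed",
]


@dataclass(frozen=True)
class MotifSite:
    """One candidate motif placement (0-based start, half-open end)."""

    motif: str
    start: int
    strand: str
    score: float  # log-odds, bits
    pvalue: float

    @property
    def state(self) -> str:
        """The motif state this placement instantiates."""
        return self.motif if self.strand == "+" else self.motif + RC_SUFFIX


@dataclass
class CandidateLattice:
    """Admissible motif segment placements for one sequence.

    ``admissible[state]`` is a boolean vector over start positions
    (length T - w + 1); a trivial lattice admits every placement.
    """

    length: int
    sites: list[MotifSite]
    admissible: dict[str, np.ndarray]

    @classmethod
    def trivial(cls, model: HsmmModel, length: int) -> "CandidateLattice":
        adm = {}
        for state in model.states.all_motif_states:
            w = model.motif_width(state)
            adm[state] = np.ones(max(length - w + 1, 0), dtype=bool)
        return cls(length, [], adm)

    def admits(self, state: str, start: int) -> bool:
        vec = self.admissible[state]
        return 0 <= start < vec.shape[0] and bool(vec[start])

    def n_sites(self) -> int:
        return len(self.sites)


def score_site(
    pwm: Pwm,
    bg: LocalMarkovTable,
    sequence: str | np.ndarray,
    start: int,
    strand: str = "+",
) -> float:
    """log-odds (bits) of a single placement: PWM emission minus the
    background probability of the same window. The minus strand scores the
    reverse-complement PWM on the forward sequence."""
    codes = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    w = pwm.width
    if start < 0 or start + w > codes.shape[0]:
        raise IndexError(f"window [{start}, {start + w}) out of bounds")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    mat = pwm if strand == "+" else reverse_complement_pwm(pwm)
    from .pwm import motif_emission_logprob

    lm = motif_emission_logprob(mat, codes[start : start + w])
    lb = bg.segment_logprob(start, w)
    return (lm - lb) / np.log(2.0)


def _logodds_bits(pwm: Pwm, bg_composition: np.ndarray) -> np.ndarray:
    comp = np.asarray(bg_composition, dtype=float)
    if comp.shape != (4,) or (comp <= 0).any():
        raise ValueError("bg_composition must be 4 positive frequencies")
    comp = comp / comp.sum()
    return (pwm.log_matrix - np.log(comp)) / np.log(2.0)


def exact_score_pvalue(
    pwm: Pwm,
    bg_composition: np.ndarray,
    score: float,
    granularity: float = DEFAULT_GRANULARITY_BITS,
) -> float:
    """P(score' >= score) for a random window drawn iid from the
    composition, by exact DP over the discretized column scores.

    The threshold is slackened by half a quantum per column so that the
    column-wise discretization never drops a genuine tie: outcome classes
    separated by more than ~w*granularity bits are resolved exactly.
    """
    grid, dist = _score_distribution(pwm, bg_composition, granularity)
    q = _discretize_threshold(score, pwm.width, granularity)
    return float(dist[grid >= q].sum())


def _discretize_threshold(score: float, width: int, granularity: float) -> int:
    tol = granularity * (width / 2.0 + 1.0)
    return int(np.ceil((score - tol) / granularity))


def _score_distribution(
    pwm: Pwm, bg_composition: np.ndarray, granularity: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the discretized total log-odds score under the
    iid composition null. Returns (integer score grid, probabilities)."""
    comp = np.asarray(bg_composition, dtype=float)
    comp = comp / comp.sum()
    lo = _logodds_bits(pwm, comp)
    q = np.round(lo / granularity).astype(np.int64)  # (w, 4)
    offset = 0
    dist = np.array([1.0])
    for i in range(pwm.width):
        col = q[i]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(dist.shape[0] + (cmax - cmin), dtype=float)
        for b in range(4):
            new[col[b] - cmin : col[b] - cmin + dist.shape[0]] += comp[b] * dist
        dist = new
        offset += cmin
    grid = offset + np.arange(dist.shape[0])
    return grid, dist


def scan_sequence(
    model: HsmmModel,
    sequence: str | np.ndarray,
    pvalue_threshold: float = DEFAULT_PVALUE_THRESHOLD,
    granularity: float = DEFAULT_GRANULARITY_BITS,
) -> CandidateLattice:
    """Scan both strands with every PWM and build the candidate lattice.

    Site p-values are exact under the sequence's global base composition
    (ambiguous positions excluded from the composition, scored as 1/4).
    """
    if not model.pwms:
        raise ValueError("model has no PWMs to scan with")
    codes = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    T = codes.shape[0]
    known = codes != N_CODE
    counts = np.bincount(codes[known], minlength=4)[:4].astype(float)
    comp = (counts + 1.0) / (counts.sum() + 4.0)  # add-one: composition > 0

    sites: list[MotifSite] = []
    admissible: dict[str, np.ndarray] = {}
    for name in model.states.motif_states:
        pwm = model.pwms[name]
        w = pwm.width
        n_pos = max(T - w + 1, 0)
        grid, dist = _score_distribution(pwm, comp, granularity)
        # survival function over the integer grid
        sf = np.cumsum(dist[::-1])[::-1]
        for strand, state in (("+", name), ("-", name + RC_SUFFIX)):
            mat = pwm if strand == "+" else reverse_complement_pwm(pwm)
            lo = _logodds_bits(mat, comp)
            scores = np.zeros(n_pos)
            for off in range(w):
                col = codes[off : off + n_pos]
                safe = np.minimum(col, 3)
                # ambiguous bases contribute 0 bits (neutral)
                scores += np.where(col == N_CODE, 0.0, lo[off, safe])
            tol = granularity * (w / 2.0 + 1.0)
            q = np.ceil((scores - tol) / granularity).astype(np.int64)
            idx = np.clip(np.searchsorted(grid, q), 0, grid.shape[0])
            pvals = np.where(idx < grid.shape[0], sf[np.minimum(idx, grid.shape[0] - 1)], 0.0)
            keep = pvals <= pvalue_threshold
            admissible[state] = keep
            for p in np.nonzero(keep)[0]:
                sites.append(
                    MotifSite(name, int(p), strand, float(scores[p]), float(pvals[p]))
                )
    sites.sort(key=lambda s: (s.start, s.motif, s.strand))
    return CandidateLattice(T, sites, admissible)


def sites_to_bed(sites: list[MotifSite], model: HsmmModel, chrom: str) -> str:
    """Candidate sites as BED6 text (score = round(1000 * (1 - pvalue)))."""
    lines = []
    for s in sites:
        w = model.pwms[s.motif].width
        lines.append(
            f"{chrom}\t{s.start}\t{s.start + w}\t{s.motif}\t"
            f"{round(1000 * (1 - s.pvalue))}\t{s.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
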