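"""Position weight matrices and the product-multinomial motif emission model.

A motif state emits a fixed-width segment whose per-position base
probabilities are given by a PWM; positions are independent (the standard
product multinomial). Reverse-strand occurrences are handled by dedicated
states carrying the reverse-complement matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._alphabet import N_CODE, encode

DEFAULT_PSEUDOCOUNT = 0.01

__all__ = ["Pwm", "motif_emission_logprob", "reverse_complement_pwm"]


@dataclass(frozen=True)
class Pwm:
    """A motif model: per-position probabilities over A, C, G, T.

    ``matrix`` has shape (width, 4) with rows summing to one; ``pseudocount``
    records the per-cell value added before normalization (database count
    matrices contain zeros that would otherwise forbid any mismatch).
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must have shape (width>=1, 4)")
        if (m < 0).any():
            raise ValueError("PWM entries must be nonnegative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        object.__setattr__(self, "matrix", m)
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        m.setflags(write=False)

    @classmethod
    def from_counts(
        cls, name: str, counts: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT
    ) -> "Pwm":
        """Build from a (width, 4) count/frequency matrix, adding the
        pseudocount to every cell and normalizing each position."""
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError("count matrix must have shape (width, 4)")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        c = c + pseudocount
        return cls(name, c / c.sum(axis=1, keepdims=True), pseudocount)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_matrix(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.matrix)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


def motif_emission_logprob(pwm: Pwm, segment: str | np.ndarray) -> float:
    """log probability of ``segment`` under the product multinomial.

    ``segment`` must have exactly the PWM width; the ambiguity code N
    contributes a factor 1/4 at its position.
    """
    codes = encode(segment) if isinstance(segment, str) else np.asarray(segment)
    if codes.shape[0] != pwm.width:
        raise ValueError(
            f"segment length {codes.shape[0]} != motif width {pwm.width}"
        )
    logm = pwm.log_matrix
    pos = np.arange(pwm.width)
    known = codes != N_CODE
    total = float(logm[pos[known], codes[known]].sum())
    total += float(np.log(0.25) * (~known).sum())
    return total


def reverse_complement_pwm(pwm: Pwm) -> Pwm:
    """Reverse column order and swap A<->T, C<->G within each position.

    With the ACGT base order this is a double flip of the matrix; the
    transform is an involution.
    """
    return Pwm(pwm.name, pwm.matrix[::-1, ::-1].copy(), pwm.pseudocount)
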