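"""End-to-end conveniences tying scanning, decoding and evaluation together."""

from __future__ import annotations

import numpy as np

from .engine import decode_to_annotations, posterior_viterbi, segment_posteriors
from .evaluate import ConfusionCounts, confusion_counts
from .io import Prediction
from .model import HsmmModel
from .scan import DEFAULT_PVALUE_THRESHOLD, CandidateLattice, scan_sequence

__all__ = ["predict_sequence", "predict_set", "score_against_truth"]


def predict_sequence(
    model: HsmmModel,
    name: str,
    sequence: str,
    pvalue_threshold: float = DEFAULT_PVALUE_THRESHOLD,
    lattice: CandidateLattice | None = None,
) -> Prediction:
    """Scan, decode with posterior Viterbi, and attach posterior scores."""
    if lattice is None:
        lattice = scan_sequence(model, sequence, pvalue_threshold)
    tables = segment_posteriors(model, sequence, lattice)
    path = posterior_viterbi(model, sequence, lattice, tables=tables)
    crms, motifs = decode_to_annotations(path)
    base_post = tables.crm_base_posterior()
    crm_scores = [float(np.mean(base_post[c.start : c.end])) for c in crms]
    motif_scores = [
        float(np.exp(tables.segment_logposterior(m.state, m.start, m.end - m.start)))
        for m in motifs
    ]
    return Prediction(name, crms, motifs, crm_scores, motif_scores)


def predict_set(
    model: HsmmModel,
    sequences: dict[str, str],
    pvalue_threshold: float = DEFAULT_PVALUE_THRESHOLD,
) -> list[Prediction]:
    return [
        predict_sequence(model, name, seq, pvalue_threshold)
        for name, seq in sequences.items()
    ]


def score_against_truth(
    predictions: list[Prediction],
    truth: dict[str, list[tuple[int, int]]],
    lengths: dict[str, int],
) -> list[ConfusionCounts]:
    """Per-sequence nucleotide confusion counts of predicted vs true CRMs."""
    out = []
    for p in predictions:
        pred_iv = [(c.start, c.end) for c in p.crms]
        out.append(
            confusion_counts(pred_iv, truth.get(p.name, []), lengths[p.name])
        )
    return out
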