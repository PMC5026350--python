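"""File formats: FASTA, JASPAR/TRANSFAC matrices, BED6, GFF3, model and run
configuration documents.

Coordinates are 0-based half-open internally and in BED; GFF3 output is
1-based inclusive per the format standard. The model document is a flat,
human-readable YAML file that round-trips bit-exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs as bio_motifs

from ._alphabet import encode
from .engine import CrmInterval, MotifInstance
from .model import DurationParams, HsmmModel
from .pwm import DEFAULT_PSEUDOCOUNT, Pwm

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pwms",
    "write_pwms",
    "read_bed",
    "write_bed",
    "Prediction",
    "write_predictions",
    "save_model",
    "load_model",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Named sequences in input order, uppercased; duplicate ids and
    non-IUPAC characters are errors."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        try:
            encode(seq)
        except ValueError as e:
            raise ValueError(f"record {rec.id!r}: {e}") from None
        out[rec.id] = seq
    return out


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PWMs

def _counts_matrix(motif) -> np.ndarray:
    return np.array([[motif.counts[b][i] for b in "ACGT"] for i in range(motif.length)])


def read_pwms(
    path, fmt: str = "jaspar", pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> list[Pwm]:
    """Parse JASPAR PFM or TRANSFAC matrices; counts are pseudocounted and
    normalized to frequencies per position."""
    if fmt not in ("jaspar", "transfac"):
        raise ValueError(f"unknown matrix format {fmt!r}")
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, fmt)
    out = []
    for m in parsed:
        name = getattr(m, "matrix_id", None) or m.name or f"motif{len(out)}"
        counts = _counts_matrix(m)
        if (counts < 0).any():
            raise ValueError(f"negative counts in motif {name}")
        out.append(Pwm.from_counts(str(name), counts, pseudocount))
    if not out:
        raise ValueError(f"no matrices found in {path}")
    return out


def write_pwms(pwms: list[Pwm], path, fmt: str = "jaspar") -> None:
    """Write frequency matrices in JASPAR PFM or TRANSFAC layout."""
    with open(path, "w") as fh:
        for pwm in pwms:
            if fmt == "jaspar":
                fh.write(f">{pwm.name} {pwm.name}\n")
                for b, base in enumerate("ACGT"):
                    row = " ".join(f"{v:.10g}" for v in pwm.matrix[:, b])
                    fh.write(f"{base} [ {row} ]\n")
            elif fmt == "transfac":
                # TRANSFAC uses two spaces between key and value columns
                fh.write(f"ID  {pwm.name}\nBF  unknown\nP0      A      C      G      T\n")
                for i in range(pwm.width):
                    row = "  ".join(f"{v:.10g}" for v in pwm.matrix[i])
                    fh.write(f"{i + 1:02d}  {row}  {pwm.consensus()[i]}\n")
                fh.write("XX\n//\n")
            else:
                raise ValueError(f"unknown matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# BED / GFF3

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """BED6 (or fewer columns) as a DataFrame with half-open coordinates."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS)
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df:
            df[col] = default
    if (df["start"] < 0).any() or (df["end"] < df["start"]).any():
        raise ValueError(f"malformed intervals in {path}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED_COLUMNS)


def intervals_by_chrom(df: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["chrom"], []).append((int(row["start"]), int(row["end"])))
    return out


@dataclass
class Prediction:
    """Decoded annotations for one sequence, with posterior scores."""

    name: str
    crms: list[CrmInterval]
    motifs: list[MotifInstance]
    crm_scores: list[float] = field(default_factory=list)  # mean per-base posterior
    motif_scores: list[float] = field(default_factory=list)  # site posterior


def write_predictions(predictions: list[Prediction], bed_path, gff_path=None) -> None:
    """CRMs as BED6 (score = round(1000 * mean per-base posterior)), motif
    instances as GFF3 child features of their CRM."""
    rows = []
    for p in predictions:
        scores = p.crm_scores or [0.0] * len(p.crms)
        for crm, sc in zip(p.crms, scores):
            rows.append(
                {
                    "chrom": p.name,
                    "start": crm.start,
                    "end": crm.end,
                    "name": "CRM",
                    "score": round(1000 * sc),
                    "strand": ".",
                }
            )
    write_bed(pd.DataFrame(rows, columns=BED_COLUMNS), bed_path)
    if gff_path is None:
        return
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in predictions:
            scores = p.crm_scores or [0.0] * len(p.crms)
            site_scores = p.motif_scores or [0.0] * len(p.motifs)
            for k, (crm, sc) in enumerate(zip(p.crms, scores)):
                cid = f"{p.name}_crm{k}"
                fh.write(
                    f"{p.name}\tcrmseg\tCRM\t{crm.start + 1}\t{crm.end}\t"
                    f"{sc:.4f}\t.\t.\tID={cid}\n"
                )
                for mi, ms in zip(p.motifs, site_scores):
                    if crm.start <= mi.start and mi.end <= crm.end:
                        fh.write(
                            f"{p.name}\tcrmseg\tTF_binding_site\t{mi.start + 1}\t"
                            f"{mi.end}\t{ms:.4f}\t{mi.strand}\t.\t"
                            f"Parent={cid};motif={mi.motif}\n"
                        )


# ---------------------------------------------------------------------------
# model document

def model_to_dict(model: HsmmModel) -> dict:
    return {
        "pwms": {
            name: {
                "matrix": [[float(v) for v in row] for row in p.matrix],
                "pseudocount": float(p.pseudocount),
            }
            for name, p in model.pwms.items()
        },
        "durations": {
            "p_g": float(model.durations.p_g),
            "r": int(model.durations.r),
            "pi": float(model.durations.pi),
            "max_duration": model.durations.max_duration,
        },
        "transitions": {
            src: {dst: float(p) for dst, p in row.items()}
            for src, row in model.transitions.items()
        },
        "bg_order_global": model.bg_order_global,
        "bg_order_local": model.bg_order_local,
        "window_halfwidth": model.window_halfwidth,
        "bg_pseudocount": float(model.bg_pseudocount),
    }


def model_from_dict(doc: dict) -> HsmmModel:
    pwms = {
        name: Pwm(name, np.array(spec["matrix"]), spec.get("pseudocount", 0.0))
        for name, spec in doc["pwms"].items()
    }
    dur = doc["durations"]
    return HsmmModel(
        pwms=pwms,
        durations=DurationParams(
            p_g=dur["p_g"],
            r=dur["r"],
            pi=dur["pi"],
            max_duration=dur.get("max_duration"),
        ),
        transitions={s: dict(r) for s, r in doc["transitions"].items()},
        bg_order_global=doc.get("bg_order_global", 3),
        bg_order_local=doc.get("bg_order_local", 2),
        window_halfwidth=doc.get("window_halfwidth", 500),
        bg_pseudocount=doc.get("bg_pseudocount", 0.25),
    )


def save_model(model: HsmmModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=True)


def load_model(path) -> HsmmModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Flat key-value run configuration with explicit validation."""

    pwm_path: str = ""
    pwm_format: str = "jaspar"
    bg_order_global: int = 3
    bg_order_local: int = 2
    window_halfwidth: int = 500
    bg_pseudocount: float = 0.25
    pwm_pseudocount: float = DEFAULT_PSEUDOCOUNT
    pvalue_threshold: float = 1e-4
    em_tol: float = 1e-6
    em_max_iter: int = 100
    em_seed: int = 0
    em_restarts: int = 0
    p_g: float = 1e-3
    r: int = 2
    pi: float = 0.96
    r_max: int = 20

    def validate(self) -> None:
        if self.pwm_format not in ("jaspar", "transfac"):
            raise ValueError(f"pwm_format must be jaspar or transfac, got {self.pwm_format!r}")
        if self.pwm_path and not Path(self.pwm_path).exists():
            raise ValueError(f"pwm_path {self.pwm_path!r} does not exist")
        checks = [
            (self.bg_order_global >= 0, "bg_order_global must be >= 0"),
            (self.bg_order_local >= 0, "bg_order_local must be >= 0"),
            (self.window_halfwidth > 0, "window_halfwidth must be > 0"),
            (self.bg_pseudocount >= 0, "bg_pseudocount must be >= 0"),
            (0 < self.pvalue_threshold <= 1, "pvalue_threshold must be in (0, 1]"),
            (self.em_tol > 0, "em_tol must be > 0"),
            (self.em_max_iter >= 1, "em_max_iter must be >= 1"),
            (0 < self.p_g <= 1, "p_g must be in (0, 1]"),
            (self.r >= 1, "r must be >= 1"),
            (0 <= self.pi < 1, "pi must be in [0, 1)"),
            (self.r_max >= 1, "r_max must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
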