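"""Transcript quantification: representative selection, RPKM, expression filter.

Contigs from a de novo assembly are aligned to a protein database; when
several contigs share one subject protein, the most significant hit (the
lowest e-value) is kept as that subject's representative. Counts on the
representatives are normalized to RPKM, reads per kilobase of transcript
per million mapped reads::

    RPKM[i, j] = 1e9 * counts[i, j] / (length_bp[i] * library_size[j])

and transcripts are retained when their RPKM exceeds a threshold
(default 5) in at least one sample ("any" mode; a strict all-samples
mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import BLAST_COLUMNS


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with quantification metadata."""

    values: pd.DataFrame
    unit: str  # "counts" | "RPKM"
    lengths: pd.Series
    library_sizes: pd.Series

    def __post_init__(self):
        if self.unit not in ("counts", "RPKM"):
            raise ValueError(f"unit must be 'counts' or 'RPKM', got {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        self.lengths = self.lengths.reindex(self.values.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every feature needs a positive length")
        self.library_sizes = self.library_sizes.reindex(self.values.columns)
        if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
            raise ValueError("every sample needs a positive library size")


def select_representatives(hits: pd.DataFrame) -> dict[str, str]:
    """Pick one representative contig per subject from a tabular hit table.

    The winner is the most significant hit: lowest e-value, ties broken by
    highest bit score, then longest alignment, then lexicographically
    smallest contig id. Idempotent and independent of row order.
    """
    if len(hits) == 0:
        return {}
    missing = {"qseqid", "sseqid", "evalue", "bitscore", "length"} - set(hits.columns)
    if missing:
        raise ValueError(f"hit table is missing columns: {sorted(missing)}")
    if (hits["evalue"] < 0).any():
        raise ValueError("e-values must be non-negative")
    if (hits["bitscore"] <= 0).any():
        raise ValueError("bit scores must be positive")
    reps: dict[str, str] = {}
    key = hits.assign(
        _neg_bits=-hits["bitscore"].astype(float),
        _neg_len=-hits["length"].astype(float),
    )
    ordered = key.sort_values(
        ["sseqid", "evalue", "_neg_bits", "_neg_len", "qseqid"], kind="stable"
    )
    firsts = ordered.drop_duplicates("sseqid", keep="first")
    for _, row in firsts.iterrows():
        reps[str(row["sseqid"])] = str(row["qseqid"])
    return reps


def compute_rpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a count matrix to RPKM using per-sample total mapped reads."""
    if counts.unit != "counts":
        raise ValueError("compute_rpkm expects a matrix in counts")
    lengths = counts.lengths.astype(float)
    libs = counts.library_sizes.astype(float)
    rpkm = (
        1e9
        * counts.values.astype(float)
        / np.outer(lengths.values, libs.values)
    )
    return ExpressionMatrix(
        values=pd.DataFrame(rpkm, index=counts.values.index, columns=counts.values.columns),
        unit="RPKM",
        lengths=counts.lengths,
        library_sizes=counts.library_sizes,
    )


def rpkm_formula(count: float, length_bp: float, library_size: float) -> float:
    """Scalar RPKM, the closed form behind :func:`compute_rpkm`."""
    if length_bp <= 0 or library_size <= 0:
        raise ValueError("length and library size must be positive")
    return 1e9 * count / (length_bp * library_size)


def filter_expressed(
    rpkm: ExpressionMatrix, threshold: float = 5.0, mode: str = "any"
) -> ExpressionMatrix:
    """Keep transcripts whose RPKM exceeds ``threshold``.

    ``mode="any"`` (default) keeps a transcript expressed above the
    threshold in at least one sample; ``mode="all"`` demands it in every
    sample. Sample order is unchanged; idempotent.
    """
    if rpkm.unit != "RPKM":
        raise ValueError("filter_expressed expects a matrix in RPKM")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    above = rpkm.values.values > threshold
    keep = above.any(axis=1) if mode == "any" else above.all(axis=1)
    return ExpressionMatrix(
        values=rpkm.values.loc[keep],
        unit="RPKM",
        lengths=rpkm.lengths.loc[keep],
        library_sizes=rpkm.library_sizes,
    )


# ---------------------------------------------------------------------------
# Tabular I/O


def read_blast_tab(path) -> pd.DataFrame:
    """Read a 12-column tabular alignment file (outfmt-6 dialect)."""
    df = pd.read_csv(path, sep="\t", header=None, names=list(BLAST_COLUMNS))
    return df


def read_count_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_series(path, name: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0]
    s.name = name
    return s


def write_matrix(df: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
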