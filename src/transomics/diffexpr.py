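"""Per-time-point fasting vs feeding differential expression.

The test is a classical two-proportion Z test on pooled within-group
counts (the proportions-test family behind "DGE test" tools): per
feature, counts are summed within each group, and with x1 reads of N1
total in group 1 and x2 of N2 in group 2,

    z = (p1 - p2) / sqrt(p0 (1 - p0) (1/N1 + 1/N2)),   p0 = (x1+x2)/(N1+N2)

with a two-sided normal p-value. A Welch t test on log2 RPKM is
available as an alternative backend. The gate replicating the study's
criterion is p < 0.05 (strict) and fold-change >= 2.0; Benjamini-
Hochberg q-values are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import StudyDesign


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    mean_a: float
    mean_b: float
    fold_change: float  # ratio >= 1
    direction: str  # "first" | "second" | "tie"
    p_value: float
    q_value: float
    verdict: str  # "up" | "down" | "ns"


def dge_test(counts_a, counts_b, library_sizes_a, library_sizes_b) -> np.ndarray:
    """Two-proportion Z test per feature on pooled within-group counts.

    ``counts_a``/``counts_b`` are features x replicates arrays;
    library sizes are per-replicate totals. Features with zero counts in
    both groups get p = 1.
    """
    a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    Na = float(np.sum(library_sizes_a))
    Nb = float(np.sum(library_sizes_b))
    if Na <= 0 or Nb <= 0:
        raise ValueError("library sizes must be positive")
    x1 = a.sum(axis=1)
    x2 = b.sum(axis=1)
    p1 = x1 / Na
    p2 = x2 / Nb
    p0 = (x1 + x2) / (Na + Nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(p0 * (1 - p0) * (1 / Na + 1 / Nb))
        z = np.where(se > 0, (p1 - p2) / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    p[(x1 == 0) & (x2 == 0)] = 1.0
    return p


def dge_z(x1: float, x2: float, n1: float, n2: float) -> tuple[float, float]:
    """Scalar (z, p) for pooled totals — the closed form behind dge_test."""
    p = dge_test(np.array([[x1]]), np.array([[x2]]), [n1], [n2])[0]
    p0 = (x1 + x2) / (n1 + n2)
    se = np.sqrt(p0 * (1 - p0) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else (x1 / n1 - x2 / n2) / se
    return float(z), float(p)


def welch_test(log_a, log_b) -> np.ndarray:
    """Welch t test per feature on log2-expression replicate values."""
    a = np.atleast_2d(np.asarray(log_a, dtype=float))
    b = np.atleast_2d(np.asarray(log_b, dtype=float))
    return stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue


def fold_change(mean_a: float, mean_b: float, pseudocount: float = 0.1) -> tuple[float, str]:
    """Symmetric fold-change ratio (>= 1) and the direction of the larger group."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    a = mean_a + pseudocount
    b = mean_b + pseudocount
    if a == b:
        return 1.0, "tie"
    return (a / b, "first") if a > b else (b / a, "second")


def classify_de(
    feature_ids,
    means_a,
    means_b,
    p_values,
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
    pseudocount: float = 0.1,
) -> tuple[list[DEResult], int, int]:
    """Apply the significance + fold-change gate and tally directions.

    Verdict is "up" when group B (e.g. feeding) is the larger side of a
    gated feature, "down" when group A is, "ns" otherwise. The p gate is
    strict (<); the fold-change gate is inclusive (>=).
    """
    if not 0 < p_thresh <= 1:
        raise ValueError("p_thresh must be in (0, 1]")
    if fc_thresh < 1:
        raise ValueError("fc_thresh must be >= 1")
    p = np.asarray(p_values, dtype=float)
    q = multipletests(p, method="fdr_bh")[1]
    out = []
    n_up = n_down = 0
    for fid, ma, mb, pv, qv in zip(feature_ids, means_a, means_b, p, q):
        fc, direction = fold_change(float(ma), float(mb), pseudocount)
        verdict = "ns"
        if pv < p_thresh and fc >= fc_thresh and direction != "tie":
            verdict = "up" if direction == "second" else "down"
        n_up += verdict == "up"
        n_down += verdict == "down"
        out.append(
            DEResult(str(fid), float(ma), float(mb), float(fc), direction, float(pv), float(qv), verdict)
        )
    return out, n_up, n_down


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "fold_change": r.fold_change,
                "direction": r.direction,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "verdict": r.verdict,
            }
            for r in results
        ]
    )


def de_per_timepoint(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    design: StudyDesign,
    day_a: str = "NF2",
    day_b: str = "F4",
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
) -> dict[int, pd.DataFrame]:
    """Fasting-vs-feeding comparison at each shared ZT (default NF2 vs F4).

    Returns one gated DE table per ZT; means are library-size-scaled
    (counts per million) so the fold change is depth-corrected.
    """
    meta = design.to_frame().set_index("sample_id")
    tables: dict[int, pd.DataFrame] = {}
    for zt in design.zt_grid:
        cols_a = meta.index[(meta["day"] == day_a) & (meta["zt"] == zt)]
        cols_b = meta.index[(meta["day"] == day_b) & (meta["zt"] == zt)]
        if len(cols_a) == 0 or len(cols_b) == 0:
            continue
        ca = counts[cols_a].values
        cb = counts[cols_b].values
        la = library_sizes[cols_a].values
        lb = library_sizes[cols_b].values
        p = dge_test(ca, cb, la, lb)
        cpm_a = (ca / la * 1e6).mean(axis=1)
        cpm_b = (cb / lb * 1e6).mean(axis=1)
        results, _, _ = classify_de(
            counts.index, cpm_a, cpm_b, p, p_thresh=p_thresh, fc_thresh=fc_thresh
        )
        tables[zt] = results_to_frame(results)
    return tables
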