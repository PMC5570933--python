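"""Teacher-pattern correlation screening and omics integration.

The screening method classifies feature time courses (genes or
metabolites) by Pearson correlation against four reference ("teacher")
templates laid over the study timeline:

* **P1 diurnal** — high while lights are on, low in the dark (and its
  negative correlates: the nocturnal features);
* **P2 fasting-low** — low during the two fasting days, high during the
  two feeding days;
* **P3 gradual** — monotone decline across fasting, then recovery across
  feeding;
* **P4 feeding-acute** — elevated at and immediately after each feeding
  event, baseline elsewhere.

Features whose replicate-averaged time course correlates with a template
beyond a threshold (default |r| >= 0.8) are reported as positive or
negative hits; circadian (P1) hits additionally receive a peak-time
phase bin (morning ZT2 / day ZT6 / afternoon ZT10 / night ZT14-22).
Gene and metabolite hits sharing a template and sign are then paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import LIGHTS_ON_H, StudyDesign

logger = logging.getLogger(__name__)

PATTERN_IDS = ("P1_diurnal", "P2_fasting_low", "P3_gradual", "P4_feeding_acute")

#: Peak-time bins over the sampled ZT grid.
PHASE_BINS = {
    2: "morning ZT2",
    6: "day ZT6",
    10: "afternoon ZT10",
    14: "night ZT14-22",
    18: "night ZT14-22",
    22: "night ZT14-22",
}


@dataclass(frozen=True)
class TeacherPattern:
    """A reference time course over the design's sample-point order."""

    pattern_id: str
    values: np.ndarray  # one value per design point, centered

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or np.allclose(v, v[0]):
            raise ValueError(f"teacher pattern {self.pattern_id} must be a non-constant vector")


@dataclass(frozen=True)
class PatternHit:
    feature_id: str
    layer: str  # "gene" | "metabolite"
    pattern_id: str
    r: float
    sign: str  # "positive" | "negative"
    primary: bool = False
    phase_bin: str | None = None


def pattern_shapes(design: StudyDesign) -> dict[str, np.ndarray]:
    """Uncentered canonical template shapes, one value per design point.

    These are the raw encodings; :func:`build_teacher_patterns` centers
    them. The synthetic generator reuses them as planted class shapes.
    """
    n = design.n_points
    zts = np.array([p.zt for p in design.samples])
    fasting = np.array([p.state == "fasting" for p in design.samples])

    p1 = np.where(zts < LIGHTS_ON_H, 1.0, -1.0)
    p2 = np.where(fasting, -1.0, 1.0)

    p3 = np.empty(n)
    idx_fast = np.flatnonzero(fasting)
    idx_feed = np.flatnonzero(~fasting)
    p3[idx_fast] = np.linspace(0.0, -1.0, len(idx_fast))
    p3[idx_feed] = np.linspace(-1.0, 1.0, len(idx_feed))

    # Feeding at ZT2 and ZT10; with 4-h sampling the acute window covers
    # the feeding sample and the next one (ZT2-6 and ZT10-14).
    acute = {zt for (_, fzt) in design.feeding_events for zt in (fzt, fzt + 4)}
    feed_days = {d for (d, _) in design.feeding_events}
    p4 = np.array(
        [1.0 if (p.day in feed_days and p.zt in acute) else -1.0 for p in design.samples]
    )
    return {
        "P1_diurnal": p1,
        "P2_fasting_low": p2,
        "P3_gradual": p3,
        "P4_feeding_acute": p4,
    }


def build_teacher_patterns(design: StudyDesign) -> list[TeacherPattern]:
    """The four centered teacher templates for a design."""
    return [
        TeacherPattern(pid, v - v.mean()) for pid, v in pattern_shapes(design).items()
    ]


def average_replicates(matrix: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Collapse a replicate-level matrix (features x samples) to design-point means.

    Columns must follow the design's flat chronological sample order.
    """
    if list(matrix.columns) != design.sample_ids:
        raise ValueError("matrix columns do not match the design's sample order")
    point_idx = np.array(design.point_of_sample())
    out = {}
    for i, lab in enumerate(design.point_labels):
        out[lab] = matrix.values[:, point_idx == i].mean(axis=1)
    return pd.DataFrame(out, index=matrix.index)


def _pearson_matrix(profiles: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of ``profiles`` against one template (vectorized)."""
    x = profiles - profiles.mean(axis=1, keepdims=True)
    t = template - template.mean()
    xn = np.linalg.norm(x, axis=1)
    tn = np.linalg.norm(t)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ t) / (xn * tn)
    return r


def correlation_screen(
    matrix: pd.DataFrame,
    patterns: list[TeacherPattern],
    design: StudyDesign,
    r_threshold: float = 0.8,
    layer: str = "gene",
    assign_phases: bool = True,
) -> list[PatternHit]:
    """Screen feature time courses against the teacher templates.

    Replicate columns are averaged per design point first; each feature is
    then correlated (Pearson) with every template. Features reaching
    ``|r| >= r_threshold`` for a template are reported as hits; the hit
    with the largest |r| per feature is flagged primary. Zero-variance
    features are excluded and logged. Circadian (P1) hits get a phase bin.
    """
    if not 0 < r_threshold <= 1:
        raise ValueError(f"r_threshold must be in (0, 1], got {r_threshold}")
    if matrix.shape[1] == design.n_points and list(matrix.columns) == design.point_labels:
        points = matrix
    else:
        points = average_replicates(matrix, design)
    prof = points.values.astype(float)
    variances = prof.var(axis=1)
    keep = variances > 0
    if not keep.all():
        for fid in points.index[~keep]:
            logger.warning("excluding zero-variance feature %s from screen", fid)
    ids = points.index[keep]
    prof = prof[keep]

    r_by_pattern = {p.pattern_id: _pearson_matrix(prof, p.values) for p in patterns}
    hits: list[PatternHit] = []
    for i, fid in enumerate(ids):
        feat_hits = []
        for pid in (p.pattern_id for p in patterns):
            r = float(r_by_pattern[pid][i])
            if r >= r_threshold or r <= -r_threshold:
                feat_hits.append((pid, r))
        if not feat_hits:
            continue
        best = max(range(len(feat_hits)), key=lambda k: abs(feat_hits[k][1]))
        for k, (pid, r) in enumerate(feat_hits):
            phase = None
            if assign_phases and pid == "P1_diurnal":
                phase = assign_phase(points.loc[fid].values, design)
            hits.append(
                PatternHit(
                    feature_id=str(fid),
                    layer=layer,
                    pattern_id=pid,
                    r=r,
                    sign="positive" if r > 0 else "negative",
                    primary=(k == best),
                    phase_bin=phase,
                )
            )
    return hits


def assign_phase(timecourse, design: StudyDesign) -> str:
    """Peak-time phase bin of a point-level circadian time course.

    Averages the profile across days at each sampled ZT and bins the
    argmax ZT; ties go to the earliest ZT.
    """
    tc = np.asarray(timecourse, dtype=float)
    if tc.shape[0] != design.n_points:
        raise ValueError("timecourse length must equal the number of design points")
    zts = np.array([p.zt for p in design.samples])
    means = {zt: tc[zts == zt].mean() for zt in design.zt_grid}
    best_zt = max(sorted(means), key=lambda zt: (means[zt], -zt))
    return PHASE_BINS[best_zt]


def hits_to_frame(hits: list[PatternHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": h.feature_id,
                "layer": h.layer,
                "pattern_id": h.pattern_id,
                "r": h.r,
                "sign": h.sign,
                "primary": h.primary,
                "phase_bin": h.phase_bin if h.phase_bin is not None else "",
            }
            for h in hits
        ],
        columns=["feature_id", "layer", "pattern_id", "r", "sign", "primary", "phase_bin"],
    )


def integrate_omics(
    gene_hits: list[PatternHit],
    metabolite_hits: list[PatternHit],
    gene_points: pd.DataFrame,
    metabolite_points: pd.DataFrame,
) -> pd.DataFrame:
    """Pair gene and metabolite hits sharing (template, sign).

    Emits every gene-metabolite pair within a (pattern_id, sign) group
    with the Pearson r of their point-averaged time courses, sorted by
    |r| descending.
    """
    rows = []
    groups: dict[tuple[str, str], tuple[list[PatternHit], list[PatternHit]]] = {}
    for h in gene_hits:
        groups.setdefault((h.pattern_id, h.sign), ([], []))[0].append(h)
    for h in metabolite_hits:
        groups.setdefault((h.pattern_id, h.sign), ([], []))[1].append(h)
    for (pid, sign), (genes, metabs) in sorted(groups.items()):
        for g in genes:
            gv = gene_points.loc[g.feature_id].values.astype(float)
            for m in metabs:
                mv = metabolite_points.loc[m.feature_id].values.astype(float)
                r = float(np.corrcoef(gv, mv)[0, 1])
                rows.append(
                    {
                        "pattern_id": pid,
                        "sign": sign,
                        "gene_id": g.feature_id,
                        "metabolite_id": m.feature_id,
                        "r": r,
                    }
                )
    out = pd.DataFrame(rows, columns=["pattern_id", "sign", "gene_id", "metabolite_id", "r"])
    if len(out):
        out = out.reindex(out["r"].abs().sort_values(ascending=False, kind="stable").index)
        out = out.reset_index(drop=True)
    return out
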