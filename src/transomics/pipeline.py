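"""End-to-end orchestration: simulate -> quantify -> NMR -> MVA -> DE -> screen -> integrate.

Every run is driven by a :class:`RunConfig` (serialized verbatim into the
output directory), produces only deterministic text artifacts, and ends
with a manifest listing each artifact with its SHA-256 checksum:
identical config + seed gives byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, jres, multivariate, quant, rhythm, simulate
from .design import StudyDesign, build_design

logger = logging.getLogger(__name__)

CLASS_OF_PATTERN = {
    "P1_diurnal": "circadian",
    "P2_fasting_low": "fasting_low",
    "P3_gradual": "gradual",
    "P4_feeding_acute": "feeding_acute",
}
PATTERN_OF_CLASS = {v: k for k, v in CLASS_OF_PATTERN.items()}


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults mirror the study's thresholds."""

    seed: int = 0
    replicates_per_point: int = 3
    n_genes: int = 2000
    n_rois: int = 407
    dispersion: float = 0.1
    noise_cv: float = 0.2
    amplitude: float = 1.0
    class_fractions: dict = field(default_factory=lambda: dict(simulate.DEFAULT_CLASS_FRACTIONS))
    rpkm_threshold: float = 5.0
    rpkm_filter_mode: str = "any"  # "any" | "all"
    p_thresh: float = 0.05
    fc_thresh: float = 2.0
    r_threshold: float = 0.8
    normalization: str = "total"  # "total" | "pqn"
    norm_constant: float = 100.0
    gene_scaling: str = "log2_autoscale"
    metab_scaling: str = "autoscale"
    hca_k: int = 3

    def validate(self) -> "RunConfig":
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0 < self.r_threshold <= 1:
            raise ValueError(f"r_threshold must be in (0, 1], got {self.r_threshold}")
        if not 0 < self.p_thresh <= 1:
            raise ValueError("p_thresh must be in (0, 1]")
        if self.fc_thresh < 1:
            raise ValueError("fc_thresh must be >= 1")
        if self.rpkm_threshold < 0:
            raise ValueError("rpkm_threshold must be non-negative")
        if self.rpkm_filter_mode not in ("any", "all"):
            raise ValueError("rpkm_filter_mode must be 'any' or 'all'")
        if self.normalization not in ("total", "pqn"):
            raise ValueError("normalization must be 'total' or 'pqn'")
        return self

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text)).validate()


def _write(df: pd.DataFrame, path: Path, index_label="feature_id") -> Path:
    quant.write_matrix(df, path, index_label=index_label)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    design = build_design(cfg.replicates_per_point)
    sim_c = simulate.simulate_counts(
        design,
        n_features=cfg.n_genes,
        class_fractions=cfg.class_fractions,
        dispersion=cfg.dispersion,
        amplitude=cfg.amplitude,
        seed=cfg.seed,
    )
    sim_m = simulate.simulate_metabolites(
        design,
        n_rois=cfg.n_rois,
        class_fractions=cfg.class_fractions,
        noise_cv=cfg.noise_cv,
        amplitude=cfg.amplitude,
        seed=cfg.seed + 1,
    )
    hits, _ = simulate.simulate_blast_hits(
        contig_ids=list(sim_c.counts.index), bijective=True, seed=cfg.seed + 2
    )
    _write(design.to_frame(), out / "design.tsv", index_label="row")
    _write(sim_c.counts, out / "counts.tsv")
    _write(sim_c.lengths.to_frame(), out / "lengths.tsv")
    _write(sim_c.library_sizes.to_frame(), out / "library_sizes.tsv")
    _write(sim_c.truth_frame, out / "truth_genes.tsv", index_label="row")
    _write(sim_m.intensities, out / "metabolites.tsv", index_label="roi_id")
    _write(sim_m.rois, out / "rois.tsv", index_label="row")
    _write(sim_m.truth_frame, out / "truth_metabolites.tsv", index_label="row")
    hits.to_csv(out / "blast_hits.tsv", sep="\t", header=False, index=False)
    return {"design": design, "counts": sim_c, "metabolites": sim_m, "hits": hits}


def stage_quantify(cfg: RunConfig, out: Path, sim: dict) -> quant.ExpressionMatrix:
    reps = quant.select_representatives(sim["hits"])
    rep_contigs = sorted(set(reps.values()) & set(sim["counts"].counts.index))
    pd.Series(reps).sort_index().to_frame("contig_id").to_csv(
        out / "representatives.tsv", sep="\t", index_label="subject_id"
    )
    counts = quant.ExpressionMatrix(
        values=sim["counts"].counts.loc[rep_contigs],
        unit="counts",
        lengths=sim["counts"].lengths,
        library_sizes=sim["counts"].library_sizes,
    )
    rpkm = quant.compute_rpkm(counts)
    filtered = quant.filter_expressed(rpkm, cfg.rpkm_threshold, cfg.rpkm_filter_mode)
    _write(filtered.values, out / "rpkm_filtered.tsv")
    return filtered


def stage_nmr(cfg: RunConfig, out: Path, sim: dict) -> jres.MetaboliteMatrix:
    # demonstration spectrum: the six reference peaks, lactate as a doublet
    peaks = [
        (1.34, 7.0, 120.0, 3.0),  # lactate CH3 doublet
        (3.02, 0.0, 80.0, 3.0),
        (3.25, 0.0, 90.0, 3.0),
        (3.41, 0.0, 70.0, 3.0),
        (3.53, 0.0, 60.0, 3.0),
        (3.92, 0.0, 50.0, 3.0),
    ]
    spec = simulate.simulate_jres(peaks, seed=cfg.seed + 3)
    processed = jres.symmetrize(jres.tilt_correct(spec))
    proj = jres.project(processed)
    rois = jres.default_roi_table()
    vec = jres.quantify_rois(proj, rois)
    table = rois.assign(intensity=vec)
    table.to_csv(out / "jres_quantified.tsv", sep="\t", index=False, float_format="%.10g")
    ann = jres.annotate_peaks([p[0] for p in peaks])
    pd.DataFrame(ann, columns=["ppm", "metabolite"]).to_csv(
        out / "jres_annotation.tsv", sep="\t", index=False, float_format="%.10g"
    )
    raw = jres.MetaboliteMatrix(
        values=sim["metabolites"].intensities, normalization="raw", rois=sim["metabolites"].rois
    )
    norm = jres.normalize_spectrum(raw, method=cfg.normalization, constant=cfg.norm_constant)
    _write(norm.values, out / "metabolites_normalized.tsv", index_label="roi_id")
    return norm


def _gene_features(cfg: RunConfig, filtered: quant.ExpressionMatrix) -> pd.DataFrame:
    """Per-feature gene matrix on the scale used for screening/MVA (log2 RPKM)."""
    return np.log2(filtered.values + 1.0)


def stage_mva(
    cfg: RunConfig,
    out: Path,
    design: StudyDesign,
    filtered: quant.ExpressionMatrix,
    metab: jres.MetaboliteMatrix,
) -> dict:
    meta = design.to_frame().set_index("sample_id")
    genes_log = _gene_features(cfg, filtered)

    # transcripts: PCA of autoscaled log2 RPKM (samples x features)
    gene_pca = multivariate.pca(multivariate.autoscale(genes_log.T.values))
    scores = pd.DataFrame(
        gene_pca.scores_[:, :4],
        index=genes_log.columns,
        columns=[f"PC{i + 1}" for i in range(min(4, gene_pca.scores_.shape[1]))],
    )
    _write(scores, out / "pca_gene_scores.tsv", index_label="sample_id")
    pd.DataFrame(
        {"variance_fraction": gene_pca.explained_variance_ratio_[:10]},
        index=[f"PC{i + 1}" for i in range(min(10, len(gene_pca.explained_variance_ratio_)))],
    ).to_csv(out / "pca_gene_variance.tsv", sep="\t", index_label="component")

    # transcripts: HCA of z-scored features (heat-map row clustering)
    z = multivariate.zscore_features(genes_log)
    clus = multivariate.hca(z.values)
    labels = clus.cut(cfg.hca_k)
    pd.DataFrame({"cluster": labels}, index=z.index).to_csv(
        out / "hca_gene_clusters.tsv", sep="\t", index_label="feature_id"
    )
    (out / "hca_genes.newick").write_text(clus.to_newick(list(z.index)) + "\n")

    # metabolites: OPLS-DA fasting vs feeding; PLS-DA on time-of-day groups
    M = multivariate.autoscale(metab.values.T.values)
    states = meta.loc[metab.values.columns, "state"].values
    op = multivariate.oplsda(M, states, n_ortho=1)
    _write(
        pd.DataFrame(
            {"T": op.t_scores_, "T_ortho1": op.ortho_scores_[:, 0], "state": states},
            index=metab.values.columns,
        ),
        out / "oplsda_scores.tsv",
        index_label="sample_id",
    )
    zt = meta.loc[metab.values.columns, "zt"].values
    tod = np.where(zt >= 14, "night ZT14-22", [f"ZT{z}" for z in zt])
    pls = multivariate.plsda(M, tod, n_components=3)
    _write(
        pd.DataFrame(
            pls.x_scores_,
            index=metab.values.columns,
            columns=[f"PLS{i + 1}" for i in range(pls.x_scores_.shape[1])],
        ).assign(group=tod),
        out / "plsda_scores.tsv",
        index_label="sample_id",
    )
    return {"gene_pca": gene_pca, "clusters": labels, "oplsda": op, "plsda": pls}


def stage_de(
    cfg: RunConfig, out: Path, design: StudyDesign, sim: dict
) -> dict[int, pd.DataFrame]:
    tables = diffexpr.de_per_timepoint(
        sim["counts"].counts,
        sim["counts"].library_sizes,
        design,
        p_thresh=cfg.p_thresh,
        fc_thresh=cfg.fc_thresh,
    )
    for zt, df in tables.items():
        df.to_csv(out / f"de_ZT{zt:02d}.tsv", sep="\t", index=False, float_format="%.10g")
    return tables


def stage_screen(
    cfg: RunConfig,
    out: Path,
    design: StudyDesign,
    filtered: quant.ExpressionMatrix,
    metab: jres.MetaboliteMatrix,
) -> dict:
    patterns = rhythm.build_teacher_patterns(design)
    genes_log = _gene_features(cfg, filtered)
    metab_log = np.log(metab.values + 1e-12)
    gene_hits = rhythm.correlation_screen(
        genes_log, patterns, design, cfg.r_threshold, layer="gene"
    )
    metab_hits = rhythm.correlation_screen(
        metab_log, patterns, design, cfg.r_threshold, layer="metabolite"
    )
    rhythm.hits_to_frame(gene_hits).to_csv(
        out / "hits_genes.tsv", sep="\t", index=False, float_format="%.10g"
    )
    rhythm.hits_to_frame(metab_hits).to_csv(
        out / "hits_metabolites.tsv", sep="\t", index=False, float_format="%.10g"
    )
    gene_points = rhythm.average_replicates(genes_log, design)
    metab_points = rhythm.average_replicates(metab_log, design)
    lines = []
    for p in patterns:
        ng = sum(h.pattern_id == p.pattern_id for h in gene_hits)
        nm = sum(h.pattern_id == p.pattern_id for h in metab_hits)
        lines.append(f"{p.pattern_id}: {ng} gene hits, {nm} metabolite hits")
    (out / "screen_summary.txt").write_text("\n".join(lines) + "\n")
    return {
        "patterns": patterns,
        "gene_hits": gene_hits,
        "metab_hits": metab_hits,
        "gene_points": gene_points,
        "metab_points": metab_points,
    }


def stage_integrate(cfg: RunConfig, out: Path, screen: dict) -> pd.DataFrame:
    pairs = rhythm.integrate_omics(
        screen["gene_hits"],
        screen["metab_hits"],
        screen["gene_points"],
        screen["metab_points"],
    )
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False, float_format="%.10g")
    return pairs


# ---------------------------------------------------------------------------
# Evaluation against ground truth


def true_phase_bin(phase_zt: float, design: StudyDesign) -> str:
    """Bin of the sampled ZT closest (circularly) to a true peak phase."""
    grid = sorted(design.zt_grid)
    best = min(grid, key=lambda z: (min(abs(z - phase_zt), 24 - abs(z - phase_zt)), z))
    return rhythm.PHASE_BINS[best]


def evaluate_screen(
    hits: list[rhythm.PatternHit], truth: pd.DataFrame, design: StudyDesign
) -> dict:
    """Primary-hit recall/precision per class and circadian phase accuracy."""
    truth = truth.set_index("feature_id")
    primary = {h.feature_id: h for h in hits if h.primary}
    metrics: dict[str, float] = {}
    for klass, pattern in PATTERN_OF_CLASS.items():
        members = truth.index[truth["class"] == klass]
        members = [f for f in members]
        called = [f for f, h in primary.items() if h.pattern_id == pattern]
        tp = [f for f in called if f in set(members)]
        metrics[f"recall_{klass}"] = len(tp) / len(members) if members else float("nan")
        metrics[f"precision_{klass}"] = len(tp) / len(called) if called else float("nan")
    circ = [
        f
        for f in truth.index[truth["class"] == "circadian"]
        if f in primary and primary[f].pattern_id == "P1_diurnal"
    ]
    if circ:
        correct = sum(
            primary[f].phase_bin == true_phase_bin(float(truth.loc[f, "phase_zt"]), design)
            for f in circ
        )
        metrics["phase_bin_accuracy"] = correct / len(circ)
    else:
        metrics["phase_bin_accuracy"] = float("nan")
    return metrics


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(cfg: RunConfig, outdir="run_out") -> dict:
    """Run every stage in order and return the artifact manifest."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json() + "\n")

    stages = []
    t0 = time.perf_counter()

    def tick(name):
        logger.info("stage %-10s done at %.2fs", name, time.perf_counter() - t0)
        stages.append(name)

    try:
        sim = stage_simulate(cfg, out)
        tick("simulate")
        design = sim["design"]
        filtered = stage_quantify(cfg, out, sim)
        tick("quantify")
        metab = stage_nmr(cfg, out, sim)
        tick("nmr")
        stage_mva(cfg, out, design, filtered, metab)
        tick("mva")
        stage_de(cfg, out, design, sim)
        tick("de")
        screen = stage_screen(cfg, out, design, filtered, metab)
        tick("screen")
        stage_integrate(cfg, out, screen)
        tick("integrate")
        gene_metrics = evaluate_screen(screen["gene_hits"], sim["counts"].truth_frame, design)
        metab_metrics = evaluate_screen(
            screen["metab_hits"], sim["metabolites"].truth_frame, design
        )
        metrics = {"genes": gene_metrics, "metabolites": metab_metrics}
        (out / "screen_metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
        tick("evaluate")
    except Exception as err:
        stage = ["simulate", "quantify", "nmr", "mva", "de", "screen", "integrate", "evaluate"][
            len(stages)
        ]
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "artifacts": [{"path": p.name, "sha256": _sha256(p)} for p in artifacts],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def render_report(outdir) -> str:
    """Plain-text run summary from a completed run directory."""
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"no manifest found in {out}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    if not manifest.get("artifacts"):
        raise ValueError("manifest lists no artifacts")
    lines = ["# Pipeline run summary", ""]

    rpkm = pd.read_csv(out / "rpkm_filtered.tsv", sep="\t", index_col=0)
    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col=0)
    lines.append(
        f"Expression filter: {rpkm.shape[0]} of {counts.shape[0]} transcripts retained"
    )
    lines.append("")
    lines.append("Differential expression (feeding vs fasting) per ZT:")
    for de_path in sorted(out.glob("de_ZT*.tsv")):
        df = pd.read_csv(de_path, sep="\t")
        up = int((df["verdict"] == "up").sum())
        down = int((df["verdict"] == "down").sum())
        lines.append(f"  {de_path.stem[3:]}: {up} up, {down} down")
    lines.append("")
    for layer, path in (("gene", "hits_genes.tsv"), ("metabolite", "hits_metabolites.tsv")):
        hits = pd.read_csv(out / path, sep="\t")
        lines.append(f"Teacher-pattern hits ({layer}s):")
        for pid in rhythm.PATTERN_IDS:
            sub = hits[hits["pattern_id"] == pid]
            lines.append(
                f"  {pid}: {len(sub)} hits ({int((sub['sign'] == 'positive').sum())} positive)"
            )
        if layer == "gene" and "phase_bin" in hits.columns:
            circ = hits[(hits["pattern_id"] == "P1_diurnal") & hits["primary"]]
            bins = circ["phase_bin"].value_counts()
            for b, n in bins.items():
                lines.append(f"    phase {b}: {n}")
        lines.append("")
    metrics_path = out / "screen_metrics.json"
    if metrics_path.exists():
        metrics = json.loads(metrics_path.read_text())
        lines.append("Screen performance vs planted ground truth:")
        for layer, m in metrics.items():
            parts = ", ".join(f"{k}={v:.3f}" for k, v in sorted(m.items()) if v == v)
            lines.append(f"  {layer}: {parts}")
    report = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(report)
    return report
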