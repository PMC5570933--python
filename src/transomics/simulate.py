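"""Synthetic study data with planted, labelled temporal structure.

The study's raw reads and spectra are not deposited, so every input the
pipeline consumes is generated here with known ground truth: a
negative-binomial count matrix (transcriptome), a log-normal ROI
intensity matrix (metabolome), 2-D J-resolved spectra for the NMR
processing chain, and a tabular BLAST-like hit table for representative
selection.

Non-null features follow one of the four temporal classes the screening
templates describe (see :mod:`transomics.rhythm`):

* ``circadian`` — log-mean modulated by ``amplitude * cos(2*pi*(zt - phase)/24)``;
  default phases sit mid-photophase or mid-scotophase (ZT6 or ZT18 +/- 0.75 h),
  i.e. the day-high / night-high features the diurnal template targets.
* ``fasting_low`` / ``gradual`` / ``feeding_acute`` — log-mean offset by
  ``amplitude * sign * shape``, where the shape is the corresponding
  uncentered template over the design points.
* ``null`` — flat log-mean.

All randomness flows through explicit integer seeds; identical seeds and
parameters give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StudyDesign
from .rhythm import pattern_shapes

CLASSES = ("circadian", "fasting_low", "gradual", "feeding_acute", "null")

DEFAULT_CLASS_FRACTIONS = {
    "circadian": 0.05,
    "fasting_low": 0.05,
    "gradual": 0.05,
    "feeding_acute": 0.05,
    "null": 0.80,
}


@dataclass(frozen=True)
class GroundTruth:
    feature_id: str
    klass: str
    phase_zt: float  # NaN unless circadian
    amplitude: float
    sign: int


@dataclass
class SimulatedCounts:
    counts: pd.DataFrame  # features x replicate-level samples
    lengths: pd.Series  # bp per feature
    library_sizes: pd.Series  # total mapped reads per sample
    truth: list[GroundTruth]
    log_means: pd.DataFrame  # noiseless natural-log mean per design point

    @property
    def truth_frame(self) -> pd.DataFrame:
        return truth_to_frame(self.truth)


@dataclass
class SimulatedMetabolites:
    intensities: pd.DataFrame  # ROIs x replicate-level samples
    rois: pd.DataFrame  # roi_id, ppm_low, ppm_high
    truth: list[GroundTruth]
    log_means: pd.DataFrame

    @property
    def truth_frame(self) -> pd.DataFrame:
        return truth_to_frame(self.truth)


def truth_to_frame(truth: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": t.feature_id,
                "class": t.klass,
                "phase_zt": t.phase_zt,
                "amplitude": t.amplitude,
                "sign": t.sign,
            }
            for t in truth
        ]
    )


def _validate_fractions(class_fractions: dict[str, float]) -> dict[str, float]:
    fr = {k: 0.0 for k in CLASSES}
    for k, v in class_fractions.items():
        if k not in CLASSES:
            raise ValueError(f"unknown class {k!r}; expected one of {CLASSES}")
        if v < 0:
            raise ValueError(f"class fraction for {k!r} is negative")
        fr[k] = float(v)
    total = sum(fr.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1, got {total}")
    return fr


def _class_counts(n_features: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of features to classes."""
    raw = {k: fractions[k] * n_features for k in CLASSES}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n_features - sum(base.values())
    order = sorted(CLASSES, key=lambda k: raw[k] - base[k], reverse=True)
    for k in order[:short]:
        base[k] += 1
    return base


def _plant_truth(
    n_features: int,
    prefix: str,
    fractions: dict[str, float],
    amplitude: float,
    rng: np.random.Generator,
    circadian_phase_choices: tuple[float, ...],
    phase_jitter: float,
) -> list[GroundTruth]:
    counts = _class_counts(n_features, fractions)
    labels = [k for k in CLASSES for _ in range(counts[k])]
    rng.shuffle(labels)
    width = max(4, len(str(n_features)))
    truth = []
    for i, klass in enumerate(labels):
        fid = f"{prefix}{i + 1:0{width}d}"
        phase = float("nan")
        sign = 1
        amp = 0.0 if klass == "null" else amplitude
        if klass == "circadian":
            phase = float(rng.choice(circadian_phase_choices)) + float(
                rng.uniform(-phase_jitter, phase_jitter)
            )
            phase %= 24.0
        elif klass != "null":
            sign = int(rng.choice([-1, 1]))
        truth.append(GroundTruth(fid, klass, phase, amp, sign))
    return truth


def _effect_matrix(truth: list[GroundTruth], design: StudyDesign) -> np.ndarray:
    """Per-feature x per-point log-scale effect (amplitude and sign applied)."""
    shapes = pattern_shapes(design)
    zts = np.array([p.zt for p in design.samples], dtype=float)
    shape_of = {
        "fasting_low": shapes["P2_fasting_low"],
        "gradual": shapes["P3_gradual"],
        "feeding_acute": shapes["P4_feeding_acute"],
    }
    eff = np.zeros((len(truth), design.n_points))
    for i, t in enumerate(truth):
        if t.klass == "circadian":
            eff[i] = t.amplitude * np.cos(2 * np.pi * (zts - t.phase_zt) / 24.0)
        elif t.klass in shape_of:
            eff[i] = t.amplitude * t.sign * shape_of[t.klass]
    return eff


def simulate_counts(
    design: StudyDesign,
    n_features: int = 2000,
    class_fractions: dict[str, float] | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
    amplitude: float = 1.0,
    mean_range: tuple[float, float] = (50.0, 500.0),
    length_range: tuple[int, int] = (300, 3000),
    depth_variation: float = 0.2,
    circadian_phase_choices: tuple[float, ...] = (6.0, 18.0),
    phase_jitter: float = 0.75,
) -> SimulatedCounts:
    """Simulate a transcript count matrix over the study design.

    Per-feature means follow the planted temporal class on the natural-log
    scale; counts are negative-binomial with ``var = mu + dispersion*mu**2``.
    Sequencing-depth variation multiplies each sample's means by a uniform
    factor in ``1 +/- depth_variation``. Library sizes are the realized
    per-sample count totals.
    """
    if n_features < 10:
        raise ValueError("n_features must be at least 10")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    fractions = _validate_fractions(class_fractions or DEFAULT_CLASS_FRACTIONS)
    rng = np.random.default_rng(seed)

    truth = _plant_truth(
        n_features, "gene_", fractions, amplitude, rng, circadian_phase_choices, phase_jitter
    )
    base = rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_features)
    eff = _effect_matrix(truth, design)
    log_mu_points = base[:, None] + eff  # features x points

    point_idx = np.array(design.point_of_sample())
    depth = rng.uniform(1 - depth_variation, 1 + depth_variation, size=len(point_idx))
    mu = np.exp(log_mu_points)[:, point_idx] * depth[None, :]

    n_nb = 1.0 / dispersion
    p_nb = n_nb / (n_nb + mu)
    counts = rng.negative_binomial(n_nb, p_nb)

    ids = [t.feature_id for t in truth]
    counts_df = pd.DataFrame(counts, index=ids, columns=design.sample_ids)
    lengths = pd.Series(
        rng.integers(length_range[0], length_range[1] + 1, size=n_features),
        index=ids,
        name="length_bp",
    )
    lib = counts_df.sum(axis=0).astype(float)
    lib.name = "library_size"
    log_means = pd.DataFrame(log_mu_points, index=ids, columns=design.point_labels)
    return SimulatedCounts(counts_df, lengths, lib, truth, log_means)


def simulate_metabolites(
    design: StudyDesign,
    n_rois: int = 407,
    class_fractions: dict[str, float] | None = None,
    noise_cv: float = 0.2,
    seed: int = 0,
    amplitude: float = 1.0,
    intensity_range: tuple[float, float] = (10.0, 1000.0),
    ppm_span: tuple[float, float] = (0.5, 9.5),
    circadian_phase_choices: tuple[float, ...] = (6.0, 18.0),
    phase_jitter: float = 0.75,
) -> SimulatedMetabolites:
    """Simulate an ROI intensity matrix with log-normal noise.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    noise; the log-scale noise standard deviation is
    ``sqrt(log(1 + noise_cv**2))``.
    """
    if n_rois < 10:
        raise ValueError("n_rois must be at least 10")
    if noise_cv <= 0:
        raise ValueError("noise_cv must be positive")
    fractions = _validate_fractions(class_fractions or DEFAULT_CLASS_FRACTIONS)
    rng = np.random.default_rng(seed)

    truth = _plant_truth(
        n_rois, "roi_", fractions, amplitude, rng, circadian_phase_choices, phase_jitter
    )
    base = rng.uniform(
        np.log(intensity_range[0]), np.log(intensity_range[1]), size=n_rois
    )
    eff = _effect_matrix(truth, design)
    log_mu_points = base[:, None] + eff

    point_idx = np.array(design.point_of_sample())
    sigma = np.sqrt(np.log1p(noise_cv**2))
    noise = rng.normal(0.0, sigma, size=(n_rois, len(point_idx)))
    intensities = np.exp(log_mu_points[:, point_idx] + noise)

    ids = [t.feature_id for t in truth]
    edges = np.linspace(ppm_span[0], ppm_span[1], n_rois + 1)
    rois = pd.DataFrame(
        {"roi_id": ids, "ppm_low": edges[:-1], "ppm_high": edges[1:]}
    )
    intens_df = pd.DataFrame(intensities, index=ids, columns=design.sample_ids)
    log_means = pd.DataFrame(log_mu_points, index=ids, columns=design.point_labels)
    return SimulatedMetabolites(intens_df, rois, truth, log_means)


def simulate_jres(
    peaks: list[tuple[float, float, float, float]],
    f1_points: int = 65,
    f1_max_hz: float = 25.0,
    f2_points: int = 4096,
    f2_range_ppm: tuple[float, float] = (0.0, 10.0),
    sf_mhz: float = 600.0,
    noise_level: float = 0.0,
    seed: int = 0,
):
    """Simulate a 2-D J-resolved spectrum before tilt correction.

    ``peaks`` is a list of ``(ppm_center, j_hz, amplitude, width_hz)``.
    A coupling of ``j_hz = 0`` gives a singlet on the F1 = 0 row; otherwise
    a doublet with components at F1 = +/- J/2 Hz, displaced along F2 by the
    same +/- J/2 Hz (the 45-degree diagonal that tilt correction shears
    away). Each component is a 2-D Lorentzian whose discrete mass is
    normalized to its share of the peak amplitude, so ROI sums of the
    processed projection recover amplitudes regardless of window
    truncation of the heavy Lorentzian tails.
    """
    from .jres import Spectrum2D

    if f1_points < 3 or f2_points < 8:
        raise ValueError("spectrum grid is degenerate")
    if f2_range_ppm[1] <= f2_range_ppm[0] or f1_max_hz <= 0:
        raise ValueError("spectrum axis ranges must be non-degenerate")
    if f1_points % 2 == 0:
        raise ValueError("f1_points must be odd so the F1 axis is symmetric about 0 Hz")

    f1_hz = np.linspace(-f1_max_hz, f1_max_hz, f1_points)
    # descending-ppm storage convention for F2
    f2_ppm = np.linspace(f2_range_ppm[1], f2_range_ppm[0], f2_points)
    data = np.zeros((f1_points, f2_points))

    def lorentz(axis: np.ndarray, center: float, gamma: float) -> np.ndarray:
        return gamma / (np.pi * ((axis - center) ** 2 + gamma**2))

    for ppm_center, j_hz, amplitude, width_hz in peaks:
        if width_hz <= 0:
            raise ValueError("peak width must be positive")
        gamma_ppm = (width_hz / 2.0) / sf_mhz
        gamma_hz = width_hz / 2.0
        comps = [0.0] if j_hz == 0 else [j_hz / 2.0, -j_hz / 2.0]
        for f1_c in comps:
            # the peak ridge lies on the 45-degree diagonal: a point at F1
            # row f1 has its F2 center displaced by f1 (in Hz) from the
            # parent chemical shift, which is exactly what tilt undoes
            prof = np.empty_like(data)
            wf1 = lorentz(f1_hz, f1_c, gamma_hz)
            for i, f1 in enumerate(f1_hz):
                prof[i] = wf1[i] * lorentz(f2_ppm, ppm_center + f1 / sf_mhz, gamma_ppm)
            total = prof.sum()
            if total <= 0:
                continue
            data += prof * (amplitude / len(comps) / total)

    if noise_level > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_level, size=data.shape)
    return Spectrum2D(data=data, f1_hz=f1_hz, f2_ppm=f2_ppm, sf_mhz=sf_mhz)


BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def simulate_blast_hits(
    n_contigs: int | None = None,
    n_subjects: int | None = None,
    seed: int = 0,
    max_extra_hits: int = 4,
    contig_ids: list[str] | None = None,
    bijective: bool = False,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate a 12-column tabular hit table with a known best contig per subject.

    The designated truth contig of every subject carries a strictly
    smaller e-value (and larger bit score) than any competing hit for
    that subject. Pass ``contig_ids`` to draw hits over an existing contig
    set; with ``bijective=True`` each contig is the truth hit of its own
    subject (one subject per contig).
    """
    if contig_ids is not None:
        contigs = list(contig_ids)
        n_contigs = len(contigs)
    else:
        if n_contigs is None or n_contigs < 1:
            raise ValueError("n_contigs must be positive")
        contigs = [f"contig_{i + 1:05d}" for i in range(n_contigs)]
    if bijective:
        n_subjects = n_contigs
    if n_subjects is None or n_subjects < 1 or n_contigs < 1:
        raise ValueError("n_contigs and n_subjects must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, str] = {}

    def make_row(contig: str, subject: str, exponent: float) -> dict:
        aln = int(rng.integers(80, 500))
        return {
            "qseqid": contig,
            "sseqid": subject,
            "pident": round(float(rng.uniform(60, 100)), 2),
            "length": aln,
            "mismatch": int(rng.integers(0, 30)),
            "gapopen": int(rng.integers(0, 5)),
            "qstart": 1,
            "qend": aln,
            "sstart": 1,
            "send": aln,
            "evalue": 10.0 ** (-exponent),
            "bitscore": round(exponent * 2.0 + float(rng.uniform(0, 10)), 1),
        }

    for j in range(n_subjects):
        subject = f"ENSDARP{j + 1:08d}"
        best = contigs[j] if bijective else contigs[int(rng.integers(0, n_contigs))]
        truth[subject] = best
        rows.append(make_row(best, subject, float(rng.uniform(60, 150))))
        n_extra = int(rng.integers(0, max_extra_hits + 1))
        others = [c for c in contigs if c != best]
        for _ in range(min(n_extra, len(others))):
            other = others[int(rng.integers(0, len(others)))]
            rows.append(make_row(other, subject, float(rng.uniform(1, 40))))

    hits = pd.DataFrame(rows, columns=list(BLAST_COLUMNS))
    hits = hits.sample(frac=1.0, random_state=int(rng.integers(0, 2**31 - 1)))
    return hits.reset_index(drop=True), truth
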