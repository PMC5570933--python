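# Methods

## Study design model

The timeline is fixed by the experiment the package targets: four
consecutive days — two fasting (NF1, NF2) then two feeding (F3, F4, meals
at ZT2 and ZT10) — sampled every 4 h at ZT ∈ {2, 6, 10, 14, 18, 22} with
the ZT18 and ZT22 points absent on NF1 and F3. The source experiment
states only that "the evenings" of those days were skipped; we interpret
that as ZT18/ZT22 because lights-off falls at ZT11 (11L:13D photoperiod),
making ZT14 early night and ZT18/22 late evening, and because ZT14 data
appear on all days in the reported clusterings. With r replicates per
point a design has 20·r samples in fixed chronological order; every
matrix the pipeline handles keeps that column order.

## Synthetic data generator

The generator is the package's stand-in for raw data that the study type
rarely deposits. Each feature (transcript or metabolite ROI) gets a
temporal class with fractions (default 5% per non-null class, 80% null),
and a log-scale mean profile over the 20 design points:

* **circadian** — `log μ(t) = b + a·cos(2π(ZT − φ)/24)`. Default phases
  are drawn as ZT6 or ZT18 ± 0.75 h (uniform): the diurnal-template class
  is, by definition, the day-high/night-high features, and the ±0.75 h
  bound keeps every noiseless profile correlated with the day/night
  square-wave template at |r| ≥ 0.9 on this ZT grid (the correlation of a
  cosine with the template peaks at 0.943 for φ = 6 and falls below 0.9
  beyond roughly ±1 h). Tests that need other phases (e.g. phase-binning
  accuracy across all bins) pass `circadian_phase_choices` explicitly.
* **fasting_low / gradual / feeding_acute** — `log μ(t) = b + a·s·e(t)`
  with sign s = ±1 and e(t) the corresponding uncentred screening template
  (see below). Planting the template shapes themselves makes class
  membership an unambiguous ground truth. For the feeding-acute class
  this means the response covers the feeding sample and the next sampled
  point (the 4-h-wide acute window) rather than decaying geometrically;
  a decay tail would make the class an intermediate between the acute and
  fasting-low templates and ground truth ill-defined.

Counts are negative-binomial with `var = μ + α·μ²` (default dispersion
α = 0.1, typical for bulk RNA-seq replicates), baseline means uniform on
log [50, 500] counts, transcript lengths uniform on [300, 3000] bp, and a
per-sample depth factor uniform on 1 ± 0.2; library sizes are the realized
column totals. Metabolite intensities are log-normal with coefficient of
variation 0.2 (default; log-sd √log(1+cv²) ≈ 0.198), baselines uniform on
log [10, 1000]. The default effect size is a = 1.0 on the natural-log
scale (≈ e-fold). All randomness flows through explicit
`numpy.random.default_rng(seed)` generators; no global state.

What the generator does **not** emulate: read-level artifacts (GC bias,
multimapping, length-dependent counting), correlated features or pathway
structure, batch effects, inter-individual variation beyond iid noise,
and NMR baseline/phase distortions or peak overlap between ROIs. Passing
tests therefore demonstrate correctness of the algorithms under their
stated statistical assumptions, not robustness to those real-data
pathologies.

Simulated J-res spectra place each peak's intensity on the 45° diagonal:
a point at F1 row f₁ (Hz) has its F2 Lorentzian centred at δ + f₁/SF ppm,
with the F1 profile Lorentzian around ±J/2 (doublet) or 0 (singlet). Each
component's discrete mass is normalised to its share of the peak
amplitude, so ROI sums recover amplitudes exactly despite the heavy
Lorentzian tails a finite window truncates.

## Processing and statistics

**Representative selection.** "Best hit" is the lowest e-value; ties break
by higher bit score, then longer alignment, then lexicographic contig id.
(The convention that a *better* BLAST hit has a *smaller* e-value is
applied even where sources describe representatives as "highest e-value".)

**RPKM.** `10⁹·C/(L·N)` with N the per-sample total mapped reads, not the
column sum of a filtered matrix. The expression filter keeps features with
RPKM above the threshold (default 5) in at least one sample: the strict
all-samples reading would discard exactly the fasting-suppressed genes the
screen is designed to find; a config switch (`mode="all"`) provides it.
No between-sample normalisation is applied by default; the ROI
normalisers can be repurposed as a hook if needed.

**J-res chain.** Tilt correction resamples each F1 row at `ppm + f1/SF`
with linear interpolation (intensity-conserving away from the F2 edges;
conservation is asserted at 0.1%). Symmetrisation uses the elementwise
minimum of the +J/−J rows (standard artifact suppression; `mean`
available). Projection defaults to the F1 sum because it preserves
integrals, which ROI quantification relies on; skyline (max) is an
option. ROIs are half-open `[low, high)` ppm intervals — a boundary point
belongs to the lower-ppm ROI — evaluated on the descending-ppm axis. The
packaged 407-interval ROI table is a synthetic stand-in (real boundaries
for such studies are unpublished) covering 0.5–9.5 ppm with deterministic
variable widths and the six annotated reference peaks isolated at
± 0.02 ppm. Numerical caveat: the min rule needs the lineshape sampled by
at least ~2 points per half-width at half-maximum; coarser F2 grids clip
intensity because mirrored rows sample a sub-pixel line differently.
Total-intensity normalisation (each sample scaled to sum to 100) is the
default; PQN divides each total-scaled sample by the median of its
ROI-wise quotients against the median spectrum.

**PCA / PLS-DA / OPLS-DA.** PCA is the SVD of the column-centred matrix;
variance fractions are σᵢ²/Σσⱼ². PLS-DA runs NIPALS on centred X and a
centred class-indicator Y (two classes: one centred ±1 column),
deflating both blocks per component; convergence at weight change < 1e-10
or 500 iterations. OPLS-DA (two classes) strips `n_ortho` Y-orthogonal
components by orthogonal signal correction, then extracts one predictive
T score; with `n_ortho = 0` it reproduces PLS component 1 exactly, and
orthogonal scores are uncorrelated with the class vector by construction.
Sign convention everywhere: each weight/loading vector is flipped so its
largest-|entry| is positive. Scaling is the caller's choice; the pipeline
uses log2(RPKM+1) for transcripts and unit-variance autoscaling for
metabolites (the conventional choices; both are config). HCA is Euclidean
distance with complete linkage via scipy's agglomerative linkage, with
`cut(k)` labels and Newick export.

**Differential expression.** The "DGE test" family used by assembler GUIs
is a proportions test; we implement the classical two-proportion Z on
within-group pooled counts with a two-sided normal p (features at 0/0 get
p = 1), plus a Welch-t-on-log2 alternative backend. The gate is strict
p < 0.05 and inclusive fold-change ≥ 2.0 on depth-corrected (CPM) group
means with pseudocount 0.1; BH q-values are always reported even though
the gate uses raw p, replicating the original criterion. Note the pooled
Z test assumes counts at their nominal (binomial/Poisson) variance;
overdispersed replicates inflate its false-positive rate — the reason
q-values and the Welch backend are provided.

**Teacher-pattern screen.** Template encodings (the shapes are named by
the method, the numbers are ours): P1 = +1 where ZT < 11, −1 otherwise;
P2 = −1 on fasting days, +1 on feeding days; P3 = linear 0→−1 over the
fasting samples then −1→+1 over the feeding samples; P4 = +1 at F3/F4
samples with ZT ∈ {2, 6, 10, 14} (at or immediately after a meal), −1
elsewhere; all centred. Replicates are averaged per design point before
correlating. The default threshold |r| ≥ 0.8 is a package convention
(none is stated for the method); it is a flag everywhere. Features are
screened on the log scale (z-scoring would change nothing — Pearson r is
affine-invariant). A feature may pass several templates (P2 and P4
correlate at 0.82 on this design by construction); all passing hits are
reported and the best-|r| one is flagged primary, and recall/precision
against planted truth are computed on primary hits. Phase bins take the
argmax of the day-averaged profile over the ZT grid (ties to the earliest
ZT). Integration pairs gene and metabolite hits within each
(template, sign) group and reports the Pearson r of their point-averaged
profiles, sorted by |r|.

## Pipeline and problem sizes

`run_pipeline` executes simulate → quantify → NMR → multivariate → DE →
screen → integrate → evaluate, writes only text artifacts, and records a
SHA-256 manifest; identical config + seed gives byte-identical manifests
(the output directory is not part of the config). Default run sizes —
2,000 transcripts, 407 ROIs, 3 replicates/point — keep a full run under a
few seconds. Tests and the acceptance script use 100–500 features per
scenario and a 65 × 2001–8192 spectral grid; these sizes already give the
oracle checks machine-precision agreement and the stochastic checks
comfortable margins, so larger simulations would add nothing but runtime.

## Known limitations

* OPLS-DA supports exactly two classes (its use case here); multi-class
  discrimination falls back to PLS-DA.
* The two-proportion DGE test ignores biological overdispersion (see
  above); a negative-binomial GLM is deliberately out of scope.
* The screen's fixed templates only find features resembling them;
  circadian features in quadrature with the light/dark split (phases near
  ZT0 or ZT12) are invisible to P1 by design of the method. Formal
  rhythmicity statistics (cosinor, JTK-style tests) are out of scope.
* Vendor NMR formats are not read; spectra enter as calibrated CSV
  matrices (a documented extension point).
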