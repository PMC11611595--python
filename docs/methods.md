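# Methods

This note documents the models and procedures behind `nexudate`, the
assumptions they make, and the choices taken where the design was open.

## The experiment being modeled

Cotton plants grown aeroponically in two treatments (well-watered control
and progressive drought) are sampled non-destructively on days 0, 2, 4, 7,
9, 11, 14, 16 and 18 after treatment start. Day 0 is the baseline phase,
days 2–11 the drought treatment phase, days 14–18 the recovery phase (full
irrigation restored). Each treatment has ten pots of three plants; on each
sampling day five pots per treatment are rinsed with a CaCl₂ sampling
solution, yielding 90 rinseate samples. Two measurement layers follow:
quantitative chemistry (total organic C, total N, NO₃-N, NH₄-N, free amino
acids) on the end-of-phase days, and untargeted negative-mode FT-ICR-MS on
every sample.

## Quantitative N balance

TON is total N minus inorganic N (NO₃-N + NH₄-N). NH₄-N is zero throughout
(none was detected; NO₃-N is an artifact of the nutrient solution rinsed
off the roots). A negative balance is recorded as missing with a flag
rather than clamped, so group means are not silently biased. Exuded mass
(mg) is concentration (mg/L) × rinseate volume (mL, default 128.8) / 1000;
specific exudation divides by root dry weight (g). Whole-pot masses are
the default; division by the three plants per pot is available via
`per_plant=True` because the two conventions coexist in practice and the
mass-balance tables we emulate use the whole-pot form.

C:N of exudates defaults to *per-replicate ratios then mean* rather than
ratio of means: the two differ whenever replicates vary, and the reported
table behavior matches the former (its printed C:N of 4.2 is not the ratio
of its printed means, 79.0/20.4 = 3.9).

Amino-acid N converts each amino acid's mass concentration to N using
N_count × 14.007 / average molar mass from a built-in table of the 20
proteinogenic amino acids (average atomic masses; e.g. glycine 75.07 g/mol
contributes 18.7% of its mass as N).

## Synthetic data generator

The generator is the study-conditions oracle for every recovery test. It
draws a catalog of CHNOSP formulas inside the detected compositional space
(C 5–56, N 0–3, S 0–3, P 0–2, [M−H]⁻ m/z in 200–900, golden-rule
plausibility), with ~40% of molecules N-containing, matching the observed
share (1,616 of 3,985 ≈ 41%). The default catalog size is 4,000 molecules
and the default noise level 330 peaks per sample, so a simulated
experiment produces on the order of 30k distinct raw peaks across the 90
samples — the scale of the real dataset. Tests and the acceptance runs use
smaller catalogs (stated per test, typically 150–1,000) to keep runtimes
in seconds; statements verified at reduced scale are noted as such below.

Each molecule receives a base presence probability uniform on [0.2, 0.9].
Twelve CH₂ homologous series (CHO-only, the lignin-like backbone of
dissolved organic matter) are seeded explicitly and given near-ubiquitous
presence (0.92–1.0) — these are what internal calibration locks onto, and
in real spectra they are the abundant, always-detected ion families.
Drought enrichment is injected as a +0.25 presence-probability boost for
N-containing molecules whose ion mass falls in the 275–390 or 450–550 amu
windows, applied only to drought samples on days 2–11. The boost value is
the generator's effect-size knob; 0.25 over a ~0.55 average base rate
produces day-level response ratios of roughly +5 to +10%, a clearly
positive treatment-phase signal of the kind the study reports, while
leaving baseline and recovery centered on zero.

Peaks are emitted at theoretical [M−H]⁻ m/z (neutral monoisotopic mass −
1.0072765; the electron mass is neglected, < 0.5 ppm at these masses)
scaled by a configurable instrument miscalibration in ppm. With
probability 0.3 a ¹³C isotopologue follows at +1.003355 with relative
intensity 1.1% per carbon. Intensities are log-normal and S/N is intensity
over a fixed noise floor — downstream analysis is presence/absence, so the
intensity model only needs to produce a realistic S/N spread. Noise peaks
are uniform over 150–950 m/z with mostly sub-threshold S/N; 30 blank
contaminants appear in the blank spectra and ride along in 90% of samples.

Quantitative tables are drawn around the control-phase means (treatment
phase: TOC 79.0 ± 4.2, TON 20.4 ± 6.8 mg/L; recovery: 77.5 ± 0.8,
23.4 ± 5.2), with drought samples scaled by per-analyte multipliers
derived from the reported end-of-phase means (TON ×1.69 in the treatment
phase, ×1.53 in recovery; TOC ×1.07/×1.01). NO₃-N is generated as ~25% of
TON so inorganic N is ~20% of total N; NH₄-N is 0. Root dry weights are
back-solved from the reported mass and specific-exudation columns (e.g.
4.4 mg / 1.4 mg g⁻¹ → 3.14 g). Amino acids are a small TON subfraction
with drought multipliers concentrated on the drought-responsive residues
(serine, aspartate, asparagine strongest).

What the generator does *not* emulate: chromatography and ion suppression,
adducts other than [M−H]⁻, charge states beyond 1, mass-dependent
calibration drift beyond a linear ppm model, correlated presence between
molecules, and day-to-day instrument variation. Passing recovery tests
therefore demonstrate that the pipeline inverts the generator's forward
model faithfully, not that it is robust to every artifact of real spectra.

## Peak-list quality control

Stages run per sample in the order: internal calibration → S/N filter →
m/z window → isotopologue removal; then blank subtraction and cross-sample
alignment. Every stage returns a subset of its input peaks, so the
per-stage counts form a non-increasing funnel that the pipeline logs and
verifies.

**Internal calibration.** A uniform ppm miscalibration scales the spacing
of a homologous series away from the exact CH₂ mass (14.015650), so each
detected chain (greedy ascending matching within 2 ppm, minimum length 5)
yields one offset estimate localized at its mean m/z: (fitted spacing /
14.015650 − 1) × 10⁶. Chains that bridge unrelated peaks produce wild
estimates, so chains farther than 0.5 ppm from the weighted median are
discarded before a linear ppm-vs-m/z model (constant if only one chain
survives) is fit and divided out. With no qualifying series the spectrum
passes through unchanged with a warning flag. Blanks carry no homologous
series of their own but share the instrument session, so they are
corrected with the median of the per-sample models — without this, blank
contaminants fail to match their (calibrated) counterparts in samples and
survive subtraction.

**Filters.** S/N is strictly greater-than (threshold 7); the m/z window is
closed at both ends ([200, 900]). A peak is an isotopologue when a
retained peak sits 1.003355 below it within 1 ppm and its intensity is
below `ratio_max` times that parent's. `ratio_max` defaults to 0.65: the
¹³C/¹²C intensity ratio reaches 1.1% × 56 ≈ 0.62 for the largest allowed
carbon number, so the ceiling must sit above that to catch the partners of
C55–C56 molecules while still rejecting co-eluting unrelated peaks of
comparable intensity.

**Alignment.** Peaks pooled over samples are sorted and chained into bins
wherever consecutive m/z values are within 1 ppm (single-linkage); each
raw peak lands in exactly one bin; within a bin one peak per sample is
kept (most intense, ties toward lower m/z). Bins seen in fewer than two
samples are dropped. On default-condition synthetic data ≥ 99% of retained
bins correspond to true catalog molecules.

## Formula assignment

The neutral mass of an ion is m/z + 1.0072765. Candidates are enumerated
exhaustively inside the element bounds by looping a precomputed
(C, N, O, S, P) partial-mass grid and solving the hydrogen count from the
residual mass (at ≤ 1 ppm tolerance only the nearest integer H can
qualify); correctness is guarded in the tests by a no-pruning nested-loop
oracle. Bounds beyond the observed C 5–56 / N 0–3 are H 4–120, O 0–40,
S 0–3, P 0–2 — wide enough to cover every reported drought-important
formula — and screening uses DBE = C − H/2 + N/2 + P/2 + 1 ∈ [0, 40],
0.3 ≤ H/C ≤ 2.5, O/C ≤ 1.2, applied as flags on the candidate list and as
an eligibility requirement for assignment. The best candidate minimizes
|ppm error| with a deterministic tie-break: fewer S+P, then fewer N, then
lexicographic (C, H, N, O, S, P). Assignment uses a 1 ppm window and a
post-assignment 0.5 ppm error filter, mirroring the two-stage tolerance of
the original processing chain; both are configurable. Elemental classes
partition assigned formulas: nonN (N = 0), else CHON / CHON-S / CHON-P /
CHON-SP by S and P content.

## N-metabolome descriptors

All descriptors operate on the binary molecules × samples matrix.
Per-sample relative abundance is 100 × N-containing present / all present.
The response ratio first averages RA by day and treatment, then computes
100 × (RA_drought − RA_control)/RA_drought; it is undefined (missing) when
RA_drought = 0 because the definition normalizes by the drought RA. Note
the estimator carries a small negative Jensen bias at low molecule counts
(it divides by a noisy quantity); at catalog sizes ≥ ~500 the bias is
well below the sampling noise and the null-symmetry test passes.

Element totals are occurrence-weighted — a molecule counts once per sample
in which it appears — which is what makes group totals (tens of thousands)
far exceed distinct-molecule counts (thousands). Mass C:N is
(ΣC × 12.011)/(ΣN × 14.007) on average atomic masses, reported to 1 dp.

Molecular-weight bins overlap at 600 amu in the prose convention
(LMW 200–600, HMW 600–900); the half-open split [200, 600) / [600, 900] is
adopted so the bins partition. Mass densities are Gaussian KDEs with
Silverman bandwidth, occurrence-weighted, and integrate to 1 over the real
line — over a narrow evaluation grid the integral can fall short when few
masses force a broad bandwidth.

Venn partitions use the phase-restricted presence matrix of N-containing
molecules; drought-important molecules are those in the drought-unique set
present on ≥ 3 distinct treatment-phase days and detected in ≥ 5 samples
("detections" counts samples, which under presence/absence equals peak
observations). Pathway-database mapping is a stub returning no matches —
consistent with the finding that none of the N-containing molecules map —
with a hook for an external annotator.

## Statistics

**Bootstrap t.** The observed statistic is Welch's t. The null reference
recenters each group to the pooled mean, resamples within groups with
replacement, and uses the add-one permutation p-value
(1 + #{|t*| ≥ |t_obs|})/(n_boot + 1), two-sided, deterministic given the
seed. Type-I error at α = 0.05 is calibrated to 0.05 ± 0.02 over 500 null
simulations in the acceptance suite. An alternative percentile-CI
formulation was considered and not adopted; the recenter-then-resample
null is the direct bootstrap analog of the two-sample t test.

**BH adjustment** is the standard step-up, cross-checked against
statsmodels. The family for quantitative tests is all analytes within a
timepoint.

**KS test.** D is the exact sup-difference of the two ECDFs. The p-value
is the asymptotic Kolmogorov series with the small-sample continuity
correction, or an exact lattice-path count (paths whose ECDF difference
stays below D, assuming no ties) when min(n, m) ≤ 10; both are
cross-checked against an independent implementation.

**Bray–Curtis / PERMANOVA.** On binary data d = (A + B − 2J)/(A + B).
PERMANOVA Gower-centers −D²/2 and takes sequential (Type I) sums of
squares by projecting onto the growing design — intercept, treatment, day,
treatment × day, in that order — with SS_term = tr((H_k − H_{k−1})G),
pseudo-F per term against the residual mean square, and free permutation
of sample rows (999 by default, add-one smoothing). Day is categorical.
Restricted permutation schemes are out of scope; the per-phase analyses
use simple free permutation. On Euclidean distances of a single variable
the pseudo-F reduces algebraically to the classical one-way ANOVA F, which
the tests verify, along with agreement with an independent single-factor
implementation. A distance matrix with zero total sum of squares (all
samples identical) is rejected with an informative error and skipped at
the pipeline level.

**PCA.** Elemental-class proportions are standardized and decomposed by
SVD. The squared cosine of a variable on a component is its squared
correlation with the component scores, normalized per variable so the
cosines of every variable sum to exactly 1 across components. For
full-rank main variables the normalization is a no-op (the PCs span the
variable space, so raw squared correlations already sum to 1); for
supplementary variables — one-hot coded categorical metadata projected
without influencing the decomposition — the raw sum is their R² on the
component space, and the normalization makes the "quality of
representation" reading (shares of a variable's representation across
components) hold uniformly. Zero-variance variables are dropped with a
warning.

## Numerical and reproducibility choices

Monoisotopic masses: C 12, H 1.0078250319, N 14.0030740052,
O 15.9949146221, S 31.97207069, P 30.97376151; proton 1.0072765; average
masses 12.011/1.008/14.007/15.999/32.06/30.974. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical seed
and configuration give byte-identical outputs, which the tests assert at
the file level. Permutation and bootstrap p-values use add-one smoothing
and can never be 0.

Problem sizes in the test and acceptance suites are scaled down from the
default study conditions: catalogs of 150–1,000 molecules, 49–999
permutations/bootstrap draws per test, 500 null simulations for the
calibration checks, and 100 seeded end-to-end runs (catalog 1,000, 150
noise peaks, 1 ppm miscalibration) for the drought-recovery rate. These
sizes are the package's choice of a fast, statistically adequate test
bench; the generator's defaults remain at the full experimental scale.

## Known limitations

- The calibration model is linear in ppm over m/z; strongly nonlinear mass
  drift is not corrected.
- Candidate ranking is minimum-|error| with the documented tie-break; on
  genuinely ambiguous masses a different ranking (e.g. isotope-pattern
  informed) could pick differently. Isotope patterns are used only to
  remove ¹³C partners, not to validate formulas.
- The KS exact p assumes no ties; on heavily tied data it falls back to a
  conservative count.
- Free permutation ignores the repeated-measures structure of sampling the
  same pots over time; a restricted scheme would be more faithful but is
  deliberately out of scope.
- The response-ratio estimator is biased at very small molecule counts
  (see above); interpret it at realistic metabolome sizes.
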