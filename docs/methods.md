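# Methods

## The measurement being emulated

An exhaled-aerosol test has a subject inhale a tracer aerosol at a
prescribed flow rate; during exhalation the particles deposit on a mouth
filter. The deposition pattern integrates the whole transit history through
the airway tree, so a constriction of two segmental bronchioles (grades
D0 = 0 %, D1 = 25 %, D2 = 50 %, D3 = 75 % diameter reduction) starves a
coherent region of the filter of particles. The package's synthetic
generator reproduces the *statistical structure* of such patterns — not any
particular image — so that the downstream feature-extraction and
classification machinery can be exercised and validated end to end.

## The fingerprint generator

A fingerprint is a set of landing positions on the unit disc, truncated to
a deposition radius r_dep = 0.92. Positions are drawn from a five-component
mixture (weights 0.28 / 0.26 / 0.22 / 0.12 / 0.12):

* **uniform background** over the deposition disc;
* **two vortex spirals** centred at (−0.38, −0.42) and (0.33, −0.35) in the
  lower half-disc — deliberately asymmetric about the vertical centreline,
  mirroring right–left lung asymmetry — with Archimedean arms (2.5 and
  −2.0 turns, arm radii 0.50 and 0.42) and Gaussian scatter 0.035;
* **two hot spots**: σ = 0.10 at (−0.30, −0.05), above the left vortex, and
  σ = 0.08 at (0.52, 0.55), upper right, bordering the depletion region and
  fed by the diseased branch.

The disease signature has two parts, both keyed to the constriction grade:

* a **crescent depletion sector** at the top of the disc (radial extent
  0.40–0.92) whose full angular width is 0 / 1.2 / 1.8 / 2.4 rad and whose
  removal probability is 0 / 0.70 / 0.88 / 0.97 for D0–D3 — the growing
  particle-free crescent;
* **branch starvation**: the diseased-branch hot spot retains a fraction
  1.0 / 0.75 / 0.50 / 0.25 of its particles, the gradual loss of aerosol
  exhaled through the constricted bronchioles.

Flow rate Q (L/min) acts strongly: the whole pattern rotates by
0.05·(Q − 30) rad, spiral arms lengthen by 12 % per 10 L/min, scatter grows
by 15 % per 10 L/min, and the background mixture weight shifts by −0.04 per
10 L/min. Particle diameter d_p acts weakly by design (sub-micron to 5 µm
aerosols are near-inert at the filter scale): a downward drift of
0.0015·(d_p − 1) and jitter of 0.0005·d_p, bounded so the per-cell occupancy
shift across the whole size band stays below an L1 budget of 0.05 — an
order of magnitude below the flow-rate-induced shift. Upper-airway variants
apply fixed affine distortions: a 1.05 isotropic scale (oral expansion,
with a vortex-centre shift of magnitude 0.054) and a 0.92 vertical
compression (tracheal contraction, shift 0.022); the oral perturbation is
the larger of the two in feature space.

Deposition/measurement scatter — the generator's single *noise dial* — adds
isotropic Gaussian displacement (default σ = 0.02 on the unit disc) to every
surviving particle **after** the depletion step, so raising it genuinely
blurs the crescent edge and degrades disease-label recovery; at σ = 0.02
the 324-sample design classifies at ≥ 0.95, and accuracy falls monotonically
through σ = 0.6 and 1.2.

Each sample releases 10 000 particles. This density was chosen once so that
per-cell binary rasters are well resolved: at this density the
fractal-dimension estimates are stable enough that the 108-sample ideal
design clusters into exactly 12 pure (D, Q) subgroups, while the corner
cells remain empty by geometry. All randomness flows from a single
`numpy` Generator per sample; every random draw is taken unconditionally at
full length, so two configurations differing only in disease level or
particle size share common random numbers under the same seed (this is what
makes the size-invariance and depletion Monte-Carlo checks sharp).
Dataset-level seeds derive per-cell seeds via `SeedSequence([seed, index])`,
so any cell regenerates in isolation.

**What the generator does not emulate**: pixel-level appearance of real
deposition images, turbulent dispersion, wall films, hygroscopic growth,
intra-subject breath-to-breath variability, or inter-subject anatomy beyond
the two affine variants. Passing tests therefore demonstrate that the
feature-extraction and classification machinery recovers structure *of the
kind* the physical system produces, at the separability the study design
posits — not clinical performance.

## The Lagrangian integrator

The optional physics route integrates
dv/dt = (f/(τ_p C_c))(u − v) + g(1 − α) + f_Brownian in an analytic flow
field (two desingularised point vortices plus a flow-rate-proportional
wash). Parameters: τ_p = ρ_p d_p² C_c/(18 µ) with air viscosity
µ = 1.89·10⁻⁵ Pa·s at body temperature and unit-density particles; Stokes
drag factor f = 1 (adequate for d_p ≤ 5 µm); Cunningham slip
C_c = 1 + Kn(1.257 + 0.400 e^(−1.100/Kn)) with Kn = 2λ/d_p and
λ = 0.066 µm; α is the fluid-to-particle density ratio (≈ 1.2·10⁻³), making
g(1 − α) buoyancy-corrected gravity; the Brownian term is a velocity kick
scaled by √dt.

The drag relaxation is linear in v, so each step applies the exact
exponential (integrating-factor) update with the fluid velocity frozen over
the step, with a series-safe evaluation of (1 − e^(−βdt))/β. This is exact
for locally constant u, unconditionally stable as τ_p → 0, and reduces to
the streamline map in the zero-Stokes limit; the closed-form relaxation and
streamline-limit checks in the tests hold at 10⁻³ relative tolerance with
large margin. Particles crossing r_dep are projected radially onto the
boundary and frozen (their crossing point is the deposition location).

## Feature extraction

Rasterisation maps the disc's bounding square onto a 512×512 binary image
(a pixel is set when ≥ 1 particle lands in it; row 0 at top). For the 6×6
analysis the image is padded with empty pixels at the bottom/right to
516 px, giving 86-px cells. Per cell, box counts N_ε use a fixed-origin
grid anchored at the cell's top-left corner with a power-of-two ladder
ε = 2 … cell/2 (here {2, 4, 8, 16, 32}); partial boxes at the far edges
count. D_B is the equally-weighted OLS slope of ln N_ε against ln(1/ε).
Conventions: an empty cell reports D_B = 0 with an undefined fit flag —
which is exactly why the four corner cells (entirely outside r_dep; the
nearest corner-cell pixel sits at radius 0.94 > 0.92) are constant across
any dataset and are removed by the exact zero-variance prune (max = min,
tolerance 0). Single-origin counting (no multi-origin averaging) keeps the
computation deterministic and directly checkable against a brute-force
double-loop scanner; the tests verify exact agreement, the canonical
dimensions (filled square 2, line 1, point 0 on dyadic regions), and the
depth-5 Sierpiński carpet at ln 8/ln 3 within 0.02 (the ladder {3, 9, 27,
81} reproduces the self-similar counts 8^k exactly).

Cell indexing is row-major from the top-left, 1-based in file headers
(f01…f36). The region of interest for ANOVA is the fourth cell (row 1,
column 4), which overlies the depletion crescent.

## Classification

One binary soft-margin SVM per unordered class pair, trained on a
precomputed Gram matrix from the package's own RBF kernel; the quadratic
program is solved by scikit-learn's SVC, treated as a black-box optimiser.
Defaults C = 100 and γ = 1/32 (= one over the retained feature count);
features are not rescaled by default since fractal dimensions already share
the [0, 2] scale (a standardisation flag exists). Prediction tallies
max-wins votes over all pairs; ties break by the largest summed absolute
decision value among the tied classes, then by the lowest class index —
both choices exist purely to make prediction deterministic, and a
hand-built cyclic-tie case exercises them.

Cross-validation partitions the samples into k = 10 near-equal folds by a
seeded uniform permutation (unstratified by default; a stratified flag
exists). Per run it records training- and test-error counts, pooling test
predictions into a confusion matrix; accuracy = 1 − misclassified/n holds
as an identity against that matrix to 10⁻¹². Sensitivity/specificity
collapse the matrix by a positive-class grouping (e.g. D1–D3 vs D0);
repeated CV across seeds intersects the misclassified-id sets to flag
persistent outliers.

## Data quality and forensics

PCA is performed on the covariance matrix of the retained features
(mean-centred, not variance-scaled), via a symmetric eigendecomposition
with a deterministic sign convention (largest-magnitude loading positive);
rank-deficient inputs return fewer components with a flag. The one-way
ANOVA uses `scipy.stats.f_oneway` with Tukey HSD comparisons at α = 0.05
from statsmodels; its type-I error is verified at 0.05 ± 0.03 over 200
seeded null replicates. The distance matrix is pairwise Euclidean distance
divided by the maximum off-diagonal entry, so values span [0, 1] exactly
(the normalisation constant is retained for round-tripping); identical-only
datasets are rejected as degenerate. Agglomerative clustering uses complete
linkage by default (average/Ward/single selectable). The flat cut is either
a fixed subgroup count or, given per-sample label combinations, the
smallest k that maximises sample-weighted mean subgroup purity; on the
ideal design this cut lands at 12 subgroups, one per (D, Q) combination.
The forensics dossier lists, for each cross-validation misclassification,
its subgroup, that subgroup's label composition, and its nearest
neighbours by normalised distance — checked against a brute-force scan.

## Problem sizes and determinism

Default study sizes are the two factorial designs (108 and 324 samples,
10 000 particles each) with 512-px rasters; the full synthesis-to-CV chain
runs in seconds per design on one CPU, and the acceptance script uses the
ideal design. All stochastic steps (generation, fold assignment, repeated
CV) are driven by explicit integer seeds; two runs with equal
configurations produce byte-identical feature tables and reports, which the
pipeline manifest certifies with SHA-256 checksums.

## Known limitations

* The published per-sample feature tables ship as RAR archives; the
  ingestion path accepts extracted CSV/TSV/XLSX exports rather than reading
  RAR directly, and id-level reproduction of specific published outlier
  samples is not attempted (their ids are only meaningful relative to an
  unavailable sample ordering).
* Binary occupancy rasters discard concentration information; concentration
  rasters are supported for visualisation only.
* The purity-maximising cut assumes label combinations are available; on
  unlabelled data only fixed-count cuts apply.
* Lift forces default to zero in the analytic flow field (no wall shear),
  and the integrator's filter-plane geometry is two-dimensional.
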