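# Methods

This note records the models, parameter choices and numerical decisions
behind kinflow, and what the synthetic-data tests do and do not establish.

## Kinetic model

The reaction scheme is the minimal polymerase cycle: reversible enzyme/DNA
binding (k₁, k₋₁), one-step reversible nucleotide binding (k₂, k₋₂ with
K_d,app = k₋₂/k₂; ground-state binding and the induced-fit conformational
change are collapsed), committed chemistry (k_pol), and dissociation of the
post-chemistry complex at the DNA off-rate (post-chemistry steps —
translocation, PPi release — are treated as kinetically fast).  The flowed
nucleotide is always in large excess over enzyme and templates and is held
constant, so the only nonlinearity is the E·D association term.

Species are integrated with SciPy's BDF (stiff) solver, analytic Jacobian,
rtol 1e-8 / atol 1e-12.  Units: µM, s, µM⁻¹s⁻¹.  Three modes:

- **single_turnover** — only unextended DNA binds enzyme; used for
  quench-flow emulation (with `preincubated=True` starting from the
  preformed E·D complex).
- **flow** — partially extended templates rebind and continue; fully
  extended templates rebind as a chemistry-dead binary complex.  This is a
  cluster during one flow: the correct-nucleotide trace rises to its
  transient maximum, decays as templates complete, and returns to the same
  binding equilibrium a mismatch sits at from the start.
- **clamped** — free unextended DNA held constant (pseudo-first-order
  regime); the system is then linear, the matrix exponential is an exact
  oracle, and the steady state has the closed form
  SC/E = a(1 + r + k_pol·r/k₋₁)/(k₋₁ + k_pol·r) with a = k₁[D] and
  r = k₂[N]/(k₋₂ + k_pol).

Homopolymers chain n incorporation stages (binary/ternary pairs) before the
final complex dissociates; runs longer than 5 are simulated as 5, since the
signal is window-limited and dwell growth is already sub-linear there.

### Theory-regime calibration

The published regime states k₋₁ = 500 s⁻¹, k_pol = 9 s⁻¹, K_d,app = 30 µM
and a mismatch %SC plateau of 0.2, but not k₁ or the species
concentrations.  The plateau fixes the pseudo-first-order association flux:
0.2/0.8 × 500 = 125 s⁻¹ (package-wide constant; internally k₁ = 10 µM⁻¹s⁻¹
with 12.5 µM DNA and 10 nM enzyme).  Nucleotide on-rate defaults to
100 µM⁻¹s⁻¹ so binding relaxation is much faster than chemistry.  The
mismatch parameter set uses a non-saturable K_d,app of 10⁴ µM with
k_pol chosen to give the measured mismatch specificity 4.6×10⁻⁶ µM⁻¹s⁻¹.
Under this calibration the correct-nucleotide maximum at 500 µM is 0.775
(reported value ≈ 0.8); the 5 µM point computes to ≈ 0.23 rather than the
reported 0.4 — with k₁ and concentrations unpublished, the calibration
cannot pin both ends, and the mismatch plateau plus the 500 µM maximum were
chosen as the constraints.

## Pre-steady-state fitting

Product formation is fit to the rising exponential A(1 − e^(−kt)) + C (a
decaying form is available); rates vs concentration to
k_max[S]/(K_d,app + [S]); mismatch rates to a line whose slope is the
specificity constant.  Nonlinear fits are unweighted least squares with
positivity bounds and multi-started initial values on log grids; constant
curves are rejected as unidentifiable rather than returning a meaningless
rate.  The discrimination value is the ratio of correct to mismatch
specificity constants.

## Run simulator

The generator's defaults are the study conditions: 10 frames/s for 40 s per
flow; a monotemplate run of 44 flows (order G,C,A,T) over 357 clusters with
the 75 bp insert; a phiX-like run of 64 flows (order G,T,A,C), 5,000
clusters by default, reads clipped at 20 bp.  Per-flow traces are
`photon_scale × copy_number × %SC(t)` plus background, linear drift,
Gaussian read noise and optional shot noise, with 40 dead frames before
reagent arrival (the DC-bias window of the caller averages exactly this
pre-flow baseline).  Copy numbers are lognormal with CV 0.3 (mean 1) —
amplitude variation between clusters is attributed to template density, and
a lognormal is the standard choice absent a stated distribution.

The flow-regime kinetics use the same 125 s⁻¹ association flux with a
1.5 µM template pool and 150 nM enzyme, sizing one incorporation stage at
~3 s so that 0/1/2/3-mers produce clearly graded integrals inside the
150-frame G/A integration window and a 5-mer fits the 350-frame T window.

Phasing is tracked as a per-cluster probability distribution over template
positions (exact in expectation; a per-molecule sampling mode exists for
validation): on a matching flow, mass advances by the full homopolymer with
probability 1 − p_lag; on a non-matching flow it advances one base with
probability p_lead.  A cluster's trace is the mixture of the n-mer basis
time courses weighted by the current position distribution — a linear
superposition that treats template subpopulations as kinetically
independent.  Truth flowgrams are recorded from the phasing-free walk.

Movies render each cluster as a Gaussian PSF (default σ 1.2 px) scaled by
its trace, on the run's background, with per-flow noise substreams so
stacks can be rendered and processed one flow at a time (memory stays flat
for full-size runs).

What the generator does **not** emulate: optics beyond the PSF, fluidic
mixing gradients across the field of view, enzyme batch variability, DNA
secondary structure, cluster shape.  Passing tests therefore establish the
correctness of the processing chain, not the field performance of the
chemistry on real flow cells.

## Image processing

Average image = mean of the first 100 frames.  Spot detection filters the
average with a difference of Gaussians (centre σ 0.7 px, surround σ 2 px)
and takes 4-connected regional maxima, plateau ties broken top-left, with
reflection padding at borders; spots whose 5×5 neighbourhood leaves the
image are dropped.  A maximum is accepted when it exceeds the global Otsu
threshold of the DoG response *and* its matched-filter score — the image
correlated with a zero-mean, unit-norm Gaussian spot template (σ 1.2 px) —
exceeds 5× the pixel noise, robustly estimated from adjacent-pixel
differences.  The Otsu term governs clean, strongly bimodal data; the
5-sigma matched-filter term is required because Otsu alone admits noise
maxima on blank or sparse images (it splits inside the noise mode).  The
operating point was calibrated on blank-noise and planted-spot ensembles:
zero false positives across 2,800 blank realizations with full recall at
peak-SNR 5.

Background pixels for each spot are the 5×5 outer-ring pixels (Chebyshev
distance 2 — the reading of "more than two pixels away" consistent with a
square neighbourhood; a Euclidean option exists) whose DoG response is
below the global Otsu threshold; if none qualifies, the three dimmest ring
pixels serve as a fallback.  Traces: each frame is smoothed with a Gaussian
(σ 1 px); foreground = smoothed centre pixel, background = mean of the
spot's background pixels on the same frame, corrected = difference.

## Base calling

DC bias is removed by subtracting the mean of the first 40 frames.
Integration windows are per-base (G/A 150, C 200, T 350 frames) — tied to
incorporation speed.  Counts are normalized per cluster by the summed
counts of calibration flows (defaults 7, 12, 20, 23, 32 in 1-based
counting, homopolymer-rich flows of the monotemplate); clusters with
non-positive calibration sums are excluded.  For heterogeneous libraries a
known 8-base calibration sequence (GTACGTAC under the G,T,A,C order) is
prepended to every template; flows 1–7 then carry exactly seven bases per
cluster and act as the normalizer (flow 8 can absorb a leading C-run of the
fragment and is excluded), and decoding strips the known prefix.

MaxAmp is taken on a 5-frame moving average, SSAmp is the mean of the last
50 frames, and their ratio uses an epsilon floor of 1e-6 of the run's
intensity scale.  Classification is pooled per base across flows:

- **kmeans2d** — k-means++ (50 restarts, fixed seed) on z-scored
  (ratio, normalized counts); groups map to homopolymer counts by ascending
  mean normalized counts.  Class values may be non-contiguous (e.g. a
  template whose T flows carry 0/1/2/5-mers).
- **gmm1d** — hand-written univariate EM (shared variance by default,
  variance floor at 1e-8 of the data variance, deterministic k-means
  initialisation — quantile initialisation collapses components when 0-mers
  dominate).  The per-iteration log-likelihood trajectory is exposed and is
  non-decreasing by construction.  With unknown class count, BIC selects
  the number of components; in calibration mode (truth known) the component
  count is fixed and truth values are clipped at the max-mer class, since
  longer runs saturate the chained-stage signal.

Qualities: Phred = −10·log₁₀(1 − posterior) capped at 40 from GMM
posteriors; fixed Q20 in k-means mode.  Reads decode as base^count per
flow, clipped (default 20 bp), written as standard FASTQ.

## Evaluation

The cyclic-speed model is exact rational arithmetic: homopolymers are
collapsed, the next-base distribution is p(b)/(1 − p(c)), matched-base
frequencies come from the exact stationary distribution of the collapsed
chain, and homopolymers of length ≥ 3 contribute exactly 3 bases.  For
G,T,A,C with uniform bases and the 75/24.5/0.5% n-mer mix this gives
1.255 bases per match, 2 flows per match, 0.6275 bases per flow.

Alignment is semi-global (whole read vs best reference infix) by edit
distance via edlib, both strands, ties to the forward strand and leftmost
location; "aligned" requires read length ≥ min_overlap and edit distance /
read length ≤ max_error_rate (default 10%, chosen to make "aligned"
well-defined).  Coordinates are 0-based half-open.  A full O(nm) dynamic
programming oracle backs the aligner in tests.  The error breakdown tallies
called vs true homopolymer classes; undercalls are deletions, overcalls
insertions.

## Known limitations

- The ensemble trace is a linear mixture over template subpopulations;
  enzyme competition between subpopulations within a cluster is ignored.
- The caller does not correct phasing; the simulator models it so that
  future correction layers can be tested against truth.
- Blind (truth-free) class assignment assumes the observed classes are the
  contiguous counts 0..k−1; templates whose flows skip intermediate counts
  need calibration mode or explicit class values.
- The theory-regime calibration reproduces the 500 µM maximum and the
  mismatch plateau, not the low-concentration (5 µM) maximum (see above).
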