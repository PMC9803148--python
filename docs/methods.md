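# Methods

`ramangrade` implements an analysis chain for grading radiation-induced
lung toxicity (fibrosis, and preliminarily pneumonitis) from dispersive
Raman microspectroscopy maps of cryopreserved murine lung sections. The
chain has three analysis stages — spectral preprocessing, fixed-basis
non-negative unmixing for air-pocket removal, and multinomial LASSO
classification of pathology grades — plus a synthetic spectral-map
generator that encodes the statistical structure the analysis assumes and
supplies ground truth for every stage.

## Spectral model and preprocessing

A measured point spectrum is modelled as a non-negative mixture of
chemical signatures sitting on a smooth instrument/fluorescence baseline
with additive detector noise:

    s(ν) = Σ_k w_k · h_k(ν) + b(ν) + ε(ν),   w_k ≥ 0.

Preprocessing turns raw spectra into unit-area, baseline-free,
axis-aligned vectors, in this order:

1. **Window crop** to [461, 1606] cm⁻¹ (both ends inclusive).
2. **Savitzky–Golay smoothing**, window 3, order 1 (a centred 3-point
   moving average on interior points). Reflect padding is used for all SG
   filters so short windows do not collapse at the endpoints.
3. **Baseline estimation** by iterative peak stripping: starting from the
   spectrum itself, repeatedly replace the current estimate by the
   pointwise minimum of itself and its first-order SG smooth, with a
   window of 7% of the channel count (rounded to the nearest odd integer,
   clamped to ≥ 3 with a logged warning), for 20 iterations. The estimate
   is pointwise non-increasing in the iteration count. The estimated
   baseline is subtracted and negative residuals are clamped to zero,
   since the downstream factorization requires a non-negative data
   matrix.
4. **Area normalization**: each spectrum is scaled to unit trapezoidal
   area over its axis.
5. **Phenylalanine alignment**: a Gaussian-plus-offset is fitted in a
   ±15 cm⁻¹ window around the ~1005 cm⁻¹ Phe ring-breathing band; the
   window is first re-centred on the in-window argmax so that bias from
   neighbouring bands (1031 cm⁻¹) is identical across spectra and cancels
   when shifts are differenced. Every spectrum is shifted by (reference
   centre − own centre) through a shape-preserving PCHIP interpolant with
   edge-value fill, using the first spectrum as the reference, and the
   whole pass is repeated twice. Degenerate windows (flat, or failed
   fits) fall back to the argmax channel with a logged warning.

Axis merging between gratings uses the same PCHIP interpolant
(`interpolate_to_axis`), which cannot overshoot beyond neighbouring knot
values; extrapolation is refused.

Ordering note: the text protocol lists normalization before alignment, and
that order is kept; alignment perturbs the unit area by well under 1% so no
re-normalization is applied afterwards.

Alignment precision is physics-limited: the Cramér–Rao bound for the
centre of a single Gaussian band of width σ≈4 cm⁻¹ sampled at 1.69 cm⁻¹
with peak SNR 20 is ≈0.1–0.15 cm⁻¹ per spectrum. Recovery of injected
shifts is therefore assessed as the mean absolute error over a batch of
shifted copies against a clean reference, which is 0.08–0.15 cm⁻¹ at SNR
20 (the per-spectrum maximum at that SNR necessarily exceeds 0.2 cm⁻¹ now
and then, for any estimator that uses only the Phe band).

## Fixed-basis unmixing and air-pocket filtering

The lungs are inflated with OCT:PBS medium before cryosectioning, so map
points that land on air pockets record the medium, not tissue. The
preprocessed data matrix X (n spectra × p channels, X ≥ 0) is factorized
as X ≈ W H with the q = 3 rows of H *fixed* to known signatures — lung
tissue, contaminated ("mixed") tissue, and OCT:PBS medium — and W ≥ 0
fitted. With every basis fixed the problem separates by row into
non-negative least squares, solved exactly by the active-set method; this
is deterministic and optimal, with no initialization sensitivity. An
alternating solver is retained for optional additional free
(unconstrained, learned) basis rows.

Scores are column-normalized to unit mean, so a threshold of 1 means "the
mean score of that basis". A spectrum is kept iff its normalized tissue
score is ≥ 1 **and** its normalized media score is ≤ 1, both comparisons
inclusive; the mixed-basis score is not thresholded. The filter is applied
exactly once — re-running it on the kept subset would recompute the column
means and could change the mask.

Degeneracy note: the synthetic mixed basis is by convention the 50/50
average of the tissue and media bases, which makes the default basis
matrix rank 2 and the weight vector of an individual spectrum non-unique.
The active-set solver resolves ties sparsely (a pure α-mixture of tissue
and media gets weights (1−α, 0, α)); weight-recovery tests use a linearly
independent basis, for which the solution is unique.

## Grade classification

Pathology grades are fractions of a region scored as diseased (fibrosis:
{0, 0.05, 0.1, 0.3, 0.5, 0.6, 0.9, 1}; pneumonitis: {0, 0.05, 0.1, 0.15,
0.2, 0.3, 0.5, 0.8}). They are treated as nominal classes — not
thresholded to a binary label, and not as an ordinal response — and
fitted with an L1-penalized multinomial logistic model in the symmetric
softmax parameterization:

    min_{B,b} (1/n) Σ_i −log softmax(x_i B + b)_{y_i} + λ‖B‖₁.

No reference class is singled out; the L1 penalty resolves the shift
ambiguity of the coefficient block. Channels are not standardized before
fitting (the spectra are already unit-area); a switch exposes
standardization if wanted.

**Solver.** Monotone FISTA (accelerated proximal gradient with a
non-increase acceptance rule): soft-thresholding yields exact zeros, the
gradient step size is 1/L with L = σ_max(X)²/(2n), and the objective
history is non-increasing by construction. For λ ≥ λ_max =
max |Xᵀ(Y − p̄)|/n the exact null model (zero coefficients,
log-class-frequency intercepts) satisfies the stationarity conditions and
is returned in closed form. Path fits over a decreasing λ grid are
warm-started. Convergence is a relative objective change below `tol`
(default 1e−7 for single fits; 1e−6 with a 400-iteration cap inside
cross-validation, where the held-out deviance is insensitive to the last
digits). A fit that exhausts its iteration cap raises a convergence error
with diagnostics unless explicitly downgraded to a warning (as in path
fits).

**Penalty selection.** 100 λ values log-spaced from λ_max down to
1e−4·λ_max; stratified, seeded 10-fold cross-validation; per-λ score =
across-fold mean of each fold's per-observation held-out multinomial
deviance (−2 Σ log p̂, probabilities floored at 1e−10); λ_1se = the
largest λ whose mean deviance is within one standard error (across folds)
of the minimum. Stratification keeps rare grades present in every fold;
a class rarer than the fold count raises an error advising binning.

**Evaluation.** 70/30 uniform random train/test split (train size =
round(0.7·n)); argmax-probability prediction with ties broken toward the
lower (less diseased) grade; K×K confusion matrices (rows = truth) and
the classification rate CR = trace/n. Experiments without a split are
evaluated by self-prediction on the training data and labelled as such.
Binning schemes map grades onto ordered coarse levels: scheme "lmh" =
Low (0–0.1) / Medium (0.3–0.6) / High (0.9–1); scheme "zlmh" = Zero (0) /
Low (0.05–0.3) / Medium (0.5–0.6) / High (0.9–1). The Low bin of "zlmh"
starts at 0.05 so that every fibrosis grade is covered. λ is re-selected
by CV within each experiment (binned, strain-restricted, …) rather than
reused across experiments.

**Path behaviour.** The L1 norm of the fitted coefficient block is
non-increasing in λ (a property of the penalized objective, asserted in
the tests). The *support size* is not: as λ decreases, channels can leave
the active set again — the classic LASSO variable-dropping phenomenon —
and this persists at solver tolerances down to 1e−10, so it is a property
of the exact path, not of the solver. Support-size counts along a path
should therefore be read as a trend, not a monotone sequence.

The per-channel coefficient table (`coefficient_map`) records, for every
(channel, class), the coefficient and its display category: green
(positive — intensity increase raises that class's likelihood), red
(negative), white (exactly zero).

## Synthetic data: what it emulates, and what it does not

Each simulated campaign draws, per (strain, grade, map), 30–80 point
spectra. A point is an air pocket with probability `air_pocket_rate`
(default 0.4, giving ≈60% retention through the score filter, the regime
the pipeline targets); air pockets are media-dominated (media proportion
0.55–0.9). Ordinary tissue points carry a media fraction drawn from
`media_mix_fraction_range` (default 0–0.2) and a small mixed-basis
fraction (0–0.1), with an overall intensity scale of 0.9–1.1. Fibrosis
enters as three collagen bands (855, 938, 1245 cm⁻¹ — proline,
hydroxyproline, amide III) whose amplitude scales linearly with
grade × tissue weight. Baselines are positive random cubics (or decaying
exponentials for stress tests) of scale 5e−3; noise is white Gaussian
with σ = 2e−4; each spectrum receives a wavenumber jitter of σ = 0.3 cm⁻¹
applied analytically to all band positions. Default band libraries: 11
tissue bands (prominent, narrow Phe at 1005, σ = 4 cm⁻¹ ≈ 9.4 cm⁻¹ FWHM),
5 media bands, 3 collagen bands, all Gaussian.

The defaults are the study conditions of the test-bed. With unit-area
spectra the Phe peak height is ≈0.010, so σ_noise = 2e−4 is a peak SNR of
≈50 — a good 30-second dispersive map point. At that level adjacent grade
increments of 0.05 produce an aggregate ≈3σ separation over the collagen
channels, which is the regime in which grade-resolved classification is
meaningful; at several-fold higher noise the 0.05-spaced grades become
information-theoretically indistinguishable (confusions concentrate on
adjacent grades and coarse binning still classifies essentially
perfectly — a useful stress behaviour, but not the default).

Not emulated: cosmic-ray spikes (removed by instrument software upstream),
instrument response functions, pseudo-Voigt/Lorentzian line shapes,
photobleaching drifts, spatial correlation of points within a map, and any
strain-specific spectral difference (strain only restricts which grades
occur, as in the C3H/HeJ fibrosis subset {0, 0.1, 0.3, 0.5}). Passing
tests on this generator therefore demonstrate the correctness and
statistical behaviour of the pipeline under its own model assumptions, not
performance on real tissue spectra; the published confusion matrices enter
only as fixed worked examples of the evaluation arithmetic.

## Numerical choices and edge cases

- Baseline SG window: 7% of the channel count, nearest odd integer,
  clamped to ≥ 3 (warning logged).
- Negative residuals after baseline subtraction, and −1e−20-scale float
  dust after PCHIP shifting, are clamped to zero.
- Gaussian reference fits fall back to the windowed argmax on flat
  windows, failed convergence, or a fitted centre outside the window.
- NNLS ties under collinear bases resolve to the active-set vertex
  solution (sparse); documented above.
- `predict_classes` breaks exact probability ties toward the lower grade
  (classes are stored ascending and argmax takes the first maximum).
- One global pipeline seed expands into independent per-stage seeds via
  `numpy.random.SeedSequence(seed).spawn(...)`, reduced mod 2³¹.
- Identical configs and seeds give byte-identical artifacts (reports
  contain no timestamps).

## Known limitations

- The 59.4% retention and the 91.6% test-set accuracy of the originating
  murine study are properties of its unreleased data; on synthetic data
  retention tracks the configured contamination rate and accuracy tracks
  the configured SNR.
- The exact Schulze-style stopping rule internals are not reproduced; the
  estimator implements the stated parameters (first-order SG at 7% window,
  20 iterations, min-update).
- The free-rank alternating NMF updates are a basic block-coordinate
  scheme intended for small free ranks; no sparsity or graph
  regularization.
- Multinomial deviance uses the standard −2·log-likelihood definition.
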