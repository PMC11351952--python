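# Methods

This note documents the models, algorithms and numerical choices behind
`nmropls`, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind before pointing the pipeline at
real spectra.

## Synthetic cohort model

Each sample's spectrum is a sum of metabolite multiplets on a dense ppm grid
(default 0.2–9.8 ppm, 9601 points, i.e. 1 mppm spacing):

* **Lineshape.** Lorentzian by default — the natural NMR lineshape —
  parameterized by full width at half maximum (FWHM); a Gaussian of matching
  FWHM is available via `CohortConfig(lineshape="gaussian")` for situations
  where the Lorentzian's long tails are undesirable (e.g. constructing
  contamination-free test fixtures). Multiplet lines sit at
  `center + J·(k − (L−1)/2)` with relative heights summing to 1.
* **Noise model.** Three independent components per sample: a multiplicative
  amplitude factor `1 + cv·ε` drawn once per metabolite (default cv = 0.12,
  mimicking between-animal concentration variability), a per-multiplet
  chemical-shift jitter (sd 0.0015 ppm, mimicking pH/temperature drift), and
  additive Gaussian baseline noise (sd 0.4 intensity units against peak
  heights of ~6–135). Traces are clipped at zero. Each sample draws from its
  own `SeedSequence` substream, so cohorts are reproducible bit for bit and
  invariant to generation order.
* **Effect structure.** The default metabolite table encodes the canonical
  genotype × Western-diet signature: lipid CH₃/CH₂, VLDL and unsaturated
  lipid rise (KO/WD reaching +40–50%), lactate, alanine, valine, isoleucine
  and glucose fall (KO/WD reaching −35–40%), with mostly additive
  genotype+diet structure and a KO/WD-specific interaction for unsaturated
  lipid and glucose. Creatine and formate carry no effect and serve as null
  controls. All multipliers are per-group config values; effect sizes in the
  ±30–50% band for the combined group were chosen as typical of strong
  dietary-intervention metabolomics and are deliberately large enough that a
  14-sample two-class comparison is well powered.
* **Ground truth.** `GroundTruth` records every injected amplitude and maps
  each metabolite to the spectral bins it occupies. A bin "overlaps" a
  multiplet when it intersects the line span padded by one FWHM — within
  ±1 FWHM a Lorentzian is above 20% of its peak height, so these bins carry
  the bulk of the signal; wider pads would label tail-dominated bins as
  effect bins and dilute recovery metrics.

**What the generator does not emulate:** phasing and baseline-distortion
artifacts (spectra arrive phased and baseline-flat), macromolecule
background underneath the CPMG-filtered trace, peak-position dependence on
metabolite concentration, ridge-like correlated noise, and the full ~50
metabolite complement of real plasma. Passing tests therefore demonstrate
that the *analysis machinery* is correct and calibrated under realistic
amplitude/shift/noise structure — not that any particular biological claim
about real plasma would replicate.

## Preprocessing

* **Referencing.** The spectrum is shifted so the lactate doublet midpoint
  sits at δ = 1.33 ppm. Detection is deliberately robust to the lipid
  envelope that dominates the 1.2–1.45 ppm window in high-fat phenotypes:
  the window is detrended with a ~0.03-ppm running median (removing broad
  background while narrow lines pass through), candidate maxima need
  prominence ≥ 5× the detrended window's median absolute value, and the
  doublet is the candidate *pair* separated by a J-doublet spacing
  (0.006–0.018 ppm; lactate ³J ≈ 7 Hz ≈ 0.01 ppm at 700 MHz) with the
  largest combined height. Naive "two tallest maxima" rules mis-reference
  lipid-rich spectra by ~0.02 ppm — exactly one bin width. The shift is an
  integer grid translation with zero padding; sub-gridpoint residuals
  (≤ 0.5 mppm) are far below the bin width.
* **Binning.** Half-open 0.02-ppm bins anchored at the range minimum
  (default 0.5–9.0 ppm), trailing partial bin dropped, bins overlapping the
  residual-water window 4.5–5.0 ppm removed — 400 bins with the defaults.
  The integral assigns each inter-gridpoint trapezoid to the bin containing
  its midpoint, which makes binning exactly linear and exactly
  conservative: bin sums equal the whole-range trapezoidal integral.
* **Normalization and scaling.** Total-sum normalization divides each row by
  its sum (removing dilution/receiver-gain factors); Pareto scaling centers
  each column and divides by √sd (sample sd, n−1), a standard compromise
  between unit-variance and no scaling for NMR bins. Constant columns are
  centered and left unscaled. The `BinMatrix` carries an explicit
  `raw → normalized → pareto` state and operations refuse out-of-state
  input rather than silently re-applying themselves.

## OPLS-DA, PCA, VIP

PCA is a plain SVD of the centered matrix with a deterministic sign
convention (largest-magnitude loading element positive); explained fractions
are σᵢ²/Σσ².

OPLS-DA codes the two classes ±1 (centered). Per orthogonal component:
`w = Xᵀy/(yᵀy)` normalized, `t = Xw`, `p = Xᵀt/(tᵀt)`,
`w_o = p − (wᵀp)w` normalized, `t_o = Xw_o`, `p_o = Xᵀt_o/(t_oᵀt_o)`,
`X ← X − t_o p_oᵀ`; after deflation a single predictive PLS component is
fitted on the residual. One predictive component is the OPLS-DA standard for
binary discrimination. With zero orthogonal components the model reduces
exactly to one-component PLS1, and on noiseless rank-(1+k) inputs its
predictions match a (1+k)-component PLS oracle — both identities are
asserted in the tests against scikit-learn. The decision threshold is the
midpoint of the class-mean predicted training scores (robust to the
unbalanced folds cross-validation produces); score ties resolve to the
first-listed class. Prediction removes the stored orthogonal components
from new rows before projecting.

VIP is computed on the predictive component only,
`VIP_j = √J·|w_j|/‖w‖`, which fixes Σ VIP² = J. A variant including
orthogonal variation ("VIP_total") was considered and rejected: orthogonal
components are by construction class-uncorrelated, and mixing their loadings
into a discrimination-importance score blurs the question the threshold
answers.

## Validation scheme

* **External folds.** Per repetition, each class's members are shuffled and
  dealt round-robin into 8 folds with a random per-class offset, so fold
  class counts differ by at most one and every training split contains both
  classes; partitions that leave a fold empty are redrawn (≤10 attempts).
  With 7+7 samples, folds hold 1–2 samples.
* **No leakage.** Pareto statistics are computed on each external training
  split and stored in the fitted model; the held-out fold is projected with
  them. Internal cross-validation (7-fold, same stratified construction)
  likewise rescales within each internal training split. The internal CV
  selects the orthogonal-component count over {0, 1, 2} by pooled internal
  accuracy, ties to the smaller count. Note the standalone `pareto_scale`
  operation (for whole-cohort PCA) is *not* used inside CV for exactly this
  reason.
* **Counting and metrics.** 8 folds × 100 repetitions = 800 models per arm.
  Per-model accuracy/sensitivity/specificity are computed on the held-out
  fold (undefined rates on single-class folds are recorded as NaN and
  excluded from aggregation); the positive class is the first group of the
  comparison label. Aggregation is the unweighted mean over models.
* **Permutation arm.** Identical scheme with labels shuffled once per
  repetition before fold assignment. Its mean accuracy sits slightly *below*
  50% (typically 47–49% here): small-sample cross-validation is
  pessimistically biased, a well-documented effect that makes the
  significance test conservative, never optimistic. The same pessimism
  explains why a *true* arm run on effect-free data can average noticeably
  below 0.5 for a given dataset — with fixed labels the bias does not
  average out over repetitions, only over independent datasets.
* **Significance.** One-sided two-sample KS between the 800 true and 800
  permuted accuracies, `D = sup(F_perm − F_true)`, asymptotic Smirnov
  p-value (an exact variant exists for small inputs and is cross-checked
  against a label-permutation oracle in the tests), significant at
  p < 0.001. The four comparisons of the two-factor design are diet within
  each genotype and genotype within each diet; each comparison and arm draws
  from its own deterministic substream of one seed.

## Profiling

Bin selection takes the union over comparisons of bins whose mean VIP
(across that comparison's 800 true models) exceeds 1.5. Region integration
sums normalized bin integrals whose bin midpoint falls inside a region
interval (midpoint membership avoids double counting at interval edges);
the default region table is derived from the simulator's metabolite table
with the same ±1 FWHM padding, closing the recovery loop. Percent-of-control
divides by the control-group mean, making the control row average exactly
100.

Two compositional caveats are inherent to the method, visible in the
examples, and worth remembering with real data: (i) total-sum normalization
couples all regions — when lipids rise, every other metabolite's *relative*
level falls even at constant concentration (the flat null metabolites read
~75–85% in lipid-rich groups); (ii) regions overlapping the lipid envelope
(notably lactate at 1.33 ppm on the lipid CH₂ shoulder, isoleucine/valine
near lipid CH₃) mix the lipid effect into their integral. The simulator
reproduces both effects faithfully rather than hiding them.

## Univariate layer and assays

Two-way ANOVA uses Type II sums of squares (statsmodels OLS), which
coincides with classical balanced ANOVA and remains sensible for the mildly
unbalanced cells (6–8 animals) such studies produce; the design-matrix
least-squares oracle in the tests pins the implementation to 1e−8. Tukey
comparisons use the studentized-range distribution with Tukey–Kramer
standard errors. The two-sample t-test is pooled-variance Student's by
default (Welch behind a flag); one-sample t against 100% serves
diet-normalized readouts (WD values as percent of the same genotype's CD
mean).

OGTT area under the curve is the trapezoid over 0–30 min divided by the
basal (0-min) glucose — "normalized to basal" read as a ratio, making the
statistic scale-free with units of minutes (a flat curve gives exactly 30).
The alternative reading, incremental area *above* baseline, is available via
`incremental=True`. Comparative-Ct folds use ΔCt against the arithmetic mean
of the reference-gene Cts (equivalent to a geometric mean of expression),
ΔΔCt against the control-group mean ΔCt, fold = 2^−ΔΔCt; the control
group's folds then have geometric mean 1, and a global cycle shift cancels
exactly.

## Problem sizes and determinism

Default analysis scale: 28 samples × 400 bins; 800 models per validation
arm (≈17,600 small OPLS fits including internal CV), a few seconds per arm
on one core. The test suite runs the full four-comparison protocol once and
the VIP-recovery analysis on ten independent cohorts; the ANOVA type-I
calibration uses 3000 null replicates (rejection-rate bands at 1000
replicates are dominated by binomial noise). Every stochastic stage —
simulation, fold draws, permutations — derives from explicit
`numpy.random.SeedSequence` fan-out, so a single seed reproduces any result
byte for byte.

## Known limitations

* The simulator's spectra are cleaner than real plasma (no baseline roll,
  no macromolecule background, fixed line positions); real-data use requires
  instrument-side phasing/baseline correction upstream.
* OPLS-DA is limited to two classes; multi-group questions go through the
  four pairwise comparisons, as in the underlying protocol.
* The KS p-value treats the 800 model accuracies as independent draws; they
  share training data, so the nominal p is optimistic in absolute terms.
  The permutation arm is subject to the same dependence, which is why the
  decision compares the two distributions rather than testing either against
  a parametric null.
* Region integrals are not deconvolved; overlap with the lipid envelope is
  reported as-is (see Profiling).
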