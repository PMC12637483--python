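# Methods

This note documents the models, conventions and numerical choices behind
loopquant, in the order data flows through the package.

## Synthetic data model

The generator emulates the statistical structure of single-allele
DNA/RNA-FISH tables from an optogenetic looping experiment, not the optics:
there is no point-spread function, no camera noise model, and spot placement
is 2D (matching analyses done on maximum projections). What it *does*
reproduce, with controllable parameters:

- **Looping.** Each of a cell's `ploidy` alleles is looped with a cell-level
  probability. The cross-channel separation of an allele's two labeled loci
  is drawn from a half-normal law (location 0.10 μm, scale 0.05 μm by
  default) when looped and a Rayleigh law (scale 0.6 μm) when free. The
  Rayleigh is the natural 2D-projected distance of an isotropic
  displacement; the defaults place ~9.6% of free pairs below the 0.27 μm
  contact threshold, in the range of dark-condition baselines, and nearly
  all looped pairs below it. Published work using this threshold does not
  report the underlying distance densities, so these laws are plausibility
  choices surfaced in `SimulationConfig`, not fixed truths.
- **Allele coupling.** Within-cell correlation of loop states uses a
  beta-binomial hierarchy: the cell-level loop probability is drawn from a
  Beta distribution with mean `p_loop` and intra-class correlation
  `allele_coupling` (degenerate at `p_loop` when the coupling is 0, making
  alleles exchangeable and independent). This is the minimal exchangeable
  model for "alleles of a cell respond more similarly than alleles of
  different cells".
- **Expression dependence.** `expression_effect` shifts the loop log-odds
  linearly in centered log expression; 0 disables it.
- **Detection.** True spots drop out independently with probability
  `1 − spot_detection_prob`; spurious spots arrive per nucleus and channel
  as Poisson counts with mean `false_spot_rate`, placed uniformly in the
  nucleus.
- **Transcription.** An allele shows an active transcription site with
  probability `rna_p_on · (1 − repression_effect · contact)`, where contact
  means the true pair distance is below the contact threshold. TS
  intensities are log-normal.

All randomness flows from a single seed through spawned child streams of a
`numpy` generator; identical configs produce byte-identical tables.
Because the generator shares none of the analysis code paths (distances are
never computed by matching; contacts come from the true displacement
magnitude), recovery tests are genuine round-trips. Passing them shows the
analysis is correct *under this generative model*; it does not certify
behavior under real-microscope artifacts (chromatic offsets, segmentation
errors, intensity-dependent localization bias) that the generator does not
emulate.

The synthetic kinetic trace is
CV(t) = cv0 + (cv_max − cv0)(1 − e^(−r·t))·e^(−d·max(0, t − t_peak)) with
rise rate r and decay rate d in 1/min. The peak time is not a free
parameter: it is set to t_peak = ln(1 + r/d)/r, the unique time where the
one-sided decay continues the rising curve with zero slope, giving a smooth
interior maximum; combinations with d ≥ r are rejected. Ground-truth
half-times are computed by Brent root-finding on the noiseless curve and
stored with the trace.

## Clustering metrics

The CV uses the population (divide-by-N) standard deviation; the sample
convention would scale every value by √(N/(N−1)), so comparisons are
internally consistent either way, but the choice is fixed and documented.
CV is computed on raw masked intensities without background subtraction.

Half-time estimation interpolates the raw series piecewise-linearly, with
an optional moving-average window (default off — no smoothing). Ties at the
maximum resolve to the first frame. t_d is referenced to the time of the
(first) CV maximum by default — the start of reversion — with a
`from_activation` flag for the t = 0 reference. A measurement-theory caveat
follows from this choice: the sampled argmax carries a uniform ±Δ/2
discretization error relative to the true peak (Δ = frame interval), so the
from-max t_d inherits that jitter and cannot be recovered to better than
±Δ/2 in general, whereas the absolute declustering crossing (from-activation
reference) is recovered well within ±Δ/2 on noiseless traces. The validation
suite asserts t_c and the absolute crossing to ±Δ/2 and the from-max t_d to
±Δ over 100 random parameter draws in realistic ranges (rise 1–3/min, decay
0.08–0.25/min, i.e. declustering half-times of roughly 3–9 min, 30 s
frames).

The CV-vs-expression logistic is fitted per variant by least squares
(`scipy.optimize.curve_fit`), initialized at the empirical maximum and
median log intensity; non-convergence is reported per variant without
aborting the others, and near-constant data are flagged as
slope-unconstrained.

## Registration

Phase correlation is computed directly: normalized cross-power spectrum
F(a)·conj(F(b)) / |·| (with a 1e−12 magnitude floor), inverse FFT, argmax
mapped to a signed shift in (−N/2, N/2]. Only integer-pixel translation is
estimated — fields drift by a few pixels between sequential rounds, never
rotate or approach half a frame — and one vector is applied per field.
Optional Hann windowing (default off) is available for non-cyclic content.
Constant images have an undefined phase spectrum and are rejected.

## Quantification conventions

- Processing order is fixed: QC filter → ploidy filter → matching → contact
  calling → per-cell summaries.
- **Matching** is greedy one-to-one in ascending distance order. With the
  ploidy filter guaranteeing equal channel counts, one-to-one assignment
  prevents a single spot from representing two alleles; a per-spot-minimum
  mode is exposed for sensitivity analysis. Assigned pairs are retained only
  below the 2 μm cap (strict `<`). A vectorized batch path handles the
  uniform-count case and is verified against the per-nucleus path.
- **Contacts** use strict `<` at the 0.27 μm threshold, following the usual
  "less than" phrasing of imaging contact definitions. The threshold is an
  imaging-resolution convention; the suite checks that between-condition
  differences keep their sign at 0.2/0.27/0.35 μm.
- Cells with zero retained pairs get `fraction_close = NaN` and are excluded
  from contact analyses (no measurement is not the same as no contact) while
  keeping their RNA metrics.
- **Binning** is by quantiles to hold per-bin counts equal up to ties; when
  binning by contact fraction, the zero-contact cells form their own bin
  "0" and the remaining cells are quantile-split. Constant binning variables
  produce a single bin with a warning.
- Normalization "relative to control" divides by the mean of the declared
  control condition.

## Statistics

`binomial_expected` evaluates the independence null f(c) = C(n,c) p_c^c
(1−p_c)^(n−c) with p_c pooled from the same cells (total contacts / (N·n)).
The Pearson statistic is computed over the n+1 categories; categories with
expected count below a configurable floor (default 1) are merged with their
smaller neighbor, reducing the degrees of freedom.

Degrees of freedom: the default is categories − 1 (the plain chi-square
reading). Because p_c is estimated from the data being tested, the
statistic is asymptotically chi-square with categories − 2 degrees of
freedom under the null; `fitted_params=1` selects that calibrated choice,
and it is what the pipeline and the validation suite use. The difference
matters: for diploid data the uncorrected test has asymptotic size ~1.4%
at nominal 5%, while the corrected test is calibrated (measured 5.25%
rejection over 400 independent-allele replicate datasets of 5000 cells;
100% power at allele coupling 0.3). Degenerate distributions (p_c equal to
0 or 1) make the test undefined and are flagged rather than raised.

The Marascuilo procedure compares all k(k−1)/2 proportion pairs against
critical ranges sqrt(χ²_{1−α, k−1}) · sqrt(p_i(1−p_i)/n_i + p_j(1−p_j)/n_j).
Report rendering uses the asterisk convention * p<0.05, ** p<0.01,
*** p<0.001. Two-factor ANOVA/Tukey and t-tests, where needed, are standard
library calls and not re-implemented here.

## Problem sizes in the validation suite

Replicate counts and cell numbers were chosen to give stable Monte-Carlo
estimates at desk scale: 400 replicates × 5000 diploid cells for type-I
calibration (binomial standard error ~1.1% at a 5% rate), 50 replicates for
power and repression recovery, 50 seeds × 2000 cells for contact-fraction
recovery, 100 parameter draws for kinetics, and exhaustive integer shifts
on a 64×64 grid for registration. The acceptance script uses the same
designs at 200/50/25 replicates and reseeds everything from its `--seed`
argument.

## Known limitations

- The generator places channel-A spots exactly at allele anchors (no
  localization noise parameter); matching fidelity under localization error
  is exercised only through the distance laws themselves.
- 2D distances only; axial (z) separation is not modeled, consistent with
  maximum-projection analysis, and will underestimate true 3D distances.
- The chi-square df correction assumes the pooled p_c is the only fitted
  parameter; conditions with additional selection (e.g. post-hoc binning)
  are not corrected further.
- Registration is translation-only and integer-pixel; subpixel drift,
  rotation and chromatic aberration are out of scope.
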