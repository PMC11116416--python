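# Methods

## Colorimetry

Input colors are assumed to be 8-bit sRGB without ICC profile handling,
which matches consumer-camera JPEG/PNG pellet photographs. Channels are
linearized with the IEC 61966-2-1 transfer function and mapped to CIE
XYZ (0–100 scale) through the matrix derived from the sRGB primary
chromaticities and the white point of the chosen illuminant/observer
pair, so RGB white maps exactly onto the reference white. Four pairs are
supported — D65/2°, D65/10°, C/2°, C/10° — each carrying the ASTM E313
yellowness coefficients $C_X, C_Z$; the constructor enforces
$|C_X X_w - C_Z Z_w| / Y_w < 10^{-3}$ so that neutral grays score ~0.
D65/2° is the default: daylight illuminant, standard observer, the
conventional choice for photography-based colorimetry. The yellowness
index $YI = 100 (C_X X - C_Z Z)/Y$ is homogeneous of degree zero, hence
invariant to exposure/luminance scaling; it is undefined at $Y = 0$
(pure black), which is treated as an error at the single-color level and
as a zero-contribution cluster inside image aggregation.

## Dominant-color decomposition

Foreground pixels (alpha > 0, or away from a uniform reference
background color) are deduplicated into (color, count) pairs and
clustered with k-means (k-means++ init, 10 restarts, tolerance 1e-4,
fixed seed) in raw 8-bit RGB — the most literal "color values of each
pixel" space; counts enter as sample weights, which is exactly
equivalent to clustering the full pixel list but much faster. With fewer
distinct colors than requested clusters the distinct colors themselves
are the clusters, so a solid-color image reproduces its closed-form YI
exactly — this is the oracle the image tests lean on. Per-cluster YI is
computed from the *unrounded* centroid; the sample %YI is the
pixel-fraction-weighted mean over clusters (a single dominant-color
variant is exposed for auditing, since the aggregation rule is a
genuinely open choice). Cluster order is by descending weight with RGB
tie-breaks, making outputs fully deterministic for a given seed. Images
are not resized by default (resizing changes cluster weights); an
optional pixel cap subsamples deterministically by seed.

## Weathering scores

Score = 1 + yellowing + cracking with the flags as 0/1. Sample summaries
keep exact percentages; rounding to integer percent happens only in
display columns. Two derived metrics feed the regression: `pct_ge2`, the
percentage of pellets scoring ≥ 2, and `weathering_pct` =
100·mean_score/2, a scale on which a uniform score of 2 is 100% (values
above 100% are possible when score-3 pellets dominate — both metrics are
emitted precisely because the conversion is an interpretation).
Between-sample "increase in weathering" is reported as the ratio
100·test/reference of the weathered fractions — the only reading under
which a (5/35 → 32/35) change is 640% — with the percent-change
convention also computed and labelled.

## Bioassay endpoint chain

Per-larva size increase is length − mean egg size; negative values are
retained with a warning. Acceptability uses strict inequalities
(fertilization > 95%, control mean increase > 253 µm); failing assays
are withheld with reasons rather than silently dropped. Responses are
normalized per vial by the mean of control vial means, so control vials
average to exactly 1; values above 1 are kept (inhibition may be
negative at low doses).

The probit fit uses per-vial mean normalized responses — respecting the
replicate structure rather than pooling larvae — weighted by larvae
count, with inhibition $I = 1 - r$ modelled as
$\Phi(b_0 + b_1 \log_{10} d)$. Log10 dilution is the standard probit
dose metameter. Initialization comes from a linear regression of
$\Phi^{-1}(I)$ (clipped to [1e-4, 1−1e-4]) on $\log_{10} d$, refined by
nonlinear least squares. The parameter covariance is the Gauss–Newton
form $s^2 (J^T W J)^{-1}$ with the analytic Jacobian, well defined even
at an exact zero-residual fit; a singular $J^T W J$, a flat response
profile (peak-to-peak inhibition < 1e-9) or a failed optimization are
reported as `converged=False`, which propagates to "n.c." endpoints.

Because every response is divided by the same estimated control mean,
the control mean's sampling error is a *common* disturbance across all
fitted points that per-vial residual scatter cannot register; ignoring
it makes nominally 95% intervals undercover. The covariance therefore
adds a rank-1 term propagating the relative variance of the control mean
through the weighted-least-squares sensitivity of $(b_0, b_1)$ to a
common shift $(1-I)\varepsilon$. With this term, simulated coverage sits
at ~95%; the term vanishes for noiseless data, preserving exact
round-trips.

ECx solves $\log_{10} EC_x = (\Phi^{-1}(x/100) - b_0)/b_1$; the CI is
the delta method on the log10 scale with t critical values at
df = n_vials − 2, back-transformed. An estimate above the undiluted
leachate (fraction > 1) is flagged not-calculable — reported as the
literal string "n.c." — and suppresses TU = 1/EC20.

NOEC/LOEC run on raw per-vial mean size increases (the ANOVA framing),
α = 0.05: Shapiro–Wilk on ANOVA residuals is reported but non-blocking
(no nonparametric branch is defined), Levene's test (mean-centered)
gates the post hoc: heteroscedastic ⇒ Dunnett's T3, otherwise Dunnett's
test. A `gating="literal"` switch inverts the assignment for
compatibility with analyses that used the opposite rule. Dunnett
p-values come from the multivariate t of the simultaneous comparisons
(scipy's implementation, seeded); the test suite checks it against an
independent Monte Carlo of the max-|T| null. Dunnett's T3 is Welch
statistics with Satterthwaite df, adjusted by the studentized maximum
modulus $p = 1 - (2F_\nu(|t|) - 1)^k$ — conservative-to-nominal under
unequal variances. LOEC is the least concentrated treatment with
adjusted p < α (a significance gap above it raises a non-monotonicity
warning); NOEC is the greatest tested concentration below the LOEC,
"highest tested" when nothing is significant, and "< lowest tested" when
everything is.

## Regression

Ordinary least squares of mean larval growth in the undiluted leachate
(% of control, higher = less toxic) on one weathering metric at a time,
with the two-sided t test on the slope and significance bands at 0.1,
0.05 and 0.01. n ≥ 3 and a non-constant predictor are required; field
studies legitimately sit near that floor, so small-n fits are allowed
but should be interpreted cautiously.

## Synthetic data

The generators define the conditions the tests certify.

* **Pellet images**: an unantialiased ellipse of one blend color (gray
  tinted toward pure sRGB yellow) with an optional fraction of
  foreground pixels painted near-black as cracks. Ground-truth YI is the
  exact pixel-fraction-weighted closed-form YI of the constituent solid
  colors, so pipeline error is measurable without confounding from edge
  anti-aliasing. These images lack real-pellet texture, gloss, shadows
  and chromatic noise: passing tests certify the clustering/colorimetry
  arithmetic, not robustness to photographic artifacts.
* **Score tables** realize requested (n1, n2, n3) counts exactly;
  summarization inverts them, seed only shuffles row order.
* **Bioassays** draw larval lengths as egg size + Normal(expected
  increase, σ) with expected increase
  $\mu_c (1 - \Phi(b_1(\log_{10} d - \log_{10} EC_{50})))$. Defaults:
  dilutions 1, 1/3, 1/10, 1/30; 4 vials per group; 35 measured larvae
  per vial; fertilization 98%; control mean increase 304 µm (≈1.2× the
  acceptability floor); egg size 95 µm (typical *P. lividus*); σ = 40 µm;
  slope $b_1 = 1.5$ per log10 unit, a realistic leachate steepness
  spanning ~7%→77% inhibition across the tested range. Gaussian,
  homoscedastic, vial-independent noise is an idealization — real assays
  show vial effects and occasional developmental failure.

## Problem sizes and determinism

Simulation-based checks use 500 assay replicates for EC50
recovery/coverage and 2000 null replicates for the Dunnett familywise
error (the acceptance script uses 300/1000, which bounds its Monte Carlo
error at roughly ±1.3 percentage points on coverage while staying fast).
Every stochastic component takes an explicit seed; pipeline outputs are
byte-identical across reruns of the same configuration, and the run
manifest records seeds, config, package version and input checksums.

## Known limitations

No automatic pellet segmentation (backgrounds must be pre-removed), no
camera calibration or chromatic adaptation, no hormesis or Bayesian
dose–response modelling, no linkage of individual pellet photos to
individual score rows. The station-level regressions in real use rest on
few points; the module refuses n < 3 but cannot make n = 5 informative.
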