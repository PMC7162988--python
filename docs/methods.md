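# Methods

## Signal model and inversion

A pixel is treated as an ensemble: real-valued donor and acceptor counts
n_D, n_A (not integers — a widefield pixel averages many molecules) with a
single FRET probability E. The three detected intensities are linear in
the counts:

    I_AA = n_A * L_A * sigma_Aex_A * phi_A * eta_Adet_Aem
    I_DD = n_D * L_D * sigma_Dex_D * (1 - E) * phi_D * eta_Ddet_Dem
    I_DA = FRET term + donor bleedthrough term + direct-excitation term

The acceptor-excited donor image carries no signal and is not modelled.
Four dimensionless ratios of the instrument parameters (alpha_BT,
delta_DE, gamma_M, beta_X) close the system; with the crosstalk-corrected
sensitized emission I_DA_corr the master equations for E and S are exact
algebraic inversions of the model. On noise-free synthetic data the
pipeline therefore recovers E_true and n_D/(n_D+n_A) to floating-point
precision; the suite asserts 1e-10 on the unit scale of E and S rather
than purely relative error, because the crosstalk subtraction cancels
catastrophically as E -> 0 and relative error on a vanishing quantity is
not numerically meaningful.

## Calibration

Crosstalks are pooled pixelwise medians of I_DA/I_DD (donor-only cells)
and I_DA/I_AA (acceptor-only cells). Pixels whose denominator falls below
a noise floor (5x the read-noise sd by default) are excluded so dark-pixel
ratios cannot blow up. The quoted uncertainty is the standard deviation
of the pooled median under bootstrap resampling of whole cells (1000
replicates by default): cells, not pixels, are the exchangeable unit of
this experiment. Fewer than 5 cells triggers a warning.

gamma_M and beta_X come from unweighted ordinary least squares without
intercept on all in-mask pixels pooled over the known-stoichiometry
dataset, solving [I_DD, I_DA_corr] @ [gamma*beta, beta] = S0/(1-S0)*I_AA.
Pixel pooling (rather than per-cell weighting) follows the convention of
gathering the whole dataset into one cloud. R^2 is the standard
1 - SS_res/SS_tot about the response mean. A dataset with a single FRET
level is a line, not a plane: the fit refuses clouds whose
column-normalised design matrix has a singular-value ratio below 1e-3,
which operationalises "the FRET values must be sufficiently spread". An
optional robust (IRLS) variant was considered and deliberately omitted:
the plain fit is the documented method and is already exact in the
noise-free limit.

## Synthetic data

The generator emulates the calibration experiment the analysis expects:

- **Cells** are random ellipses (radii 14–28 px by default) on a jittered
  grid (guaranteeing non-overlap and seed determinism), with a smooth
  radial brightness profile (0.35–1.0) and log-normal pixel texture
  (sd 0.25 in log space).
- **Expression** spans two decades: per-cell total-fluorophore amplitudes
  are stratified log-uniform over [2e4, 2e6] within each dataset, so
  every sample type covers the same concentration range — as matched
  transfected populations do. Without stratification the pooled
  concentration-independence diagnostic is dominated by the random
  construct-vs-brightness draw at ~26 cells per construct.
- **FRET**: per-cell construct means drawn N(E0, 0.015) — the few-percent
  cell-to-cell spread seen for FRET standards — plus N(0, 0.02) pixel
  spread, clipped to [0, 1]. Default constructs C5V/C17V/C32V at
  E0 = 0.503/0.417/0.351 with 26/25/27 cells, 1:1 stoichiometry;
  donor-only (10 cells) and acceptor-only (12 cells) samples for the
  crosstalks.
- **Stoichiometry** parametrizes counts as n_D = S*n_tot,
  n_A = (1-S)*n_tot, which is the donor-fraction definition itself and
  remains well-defined for the pure-donor (S=1) and pure-acceptor (S=0)
  samples.
- **Camera**: Poisson shot noise on expected photons, then gain,
  multiplicative flat field, additive dark offset (100 counts) and
  Gaussian read noise (sd 2) — the standard sCMOS/EMCCD forward model,
  and exactly what the preprocessing removes. With the default instrument
  the dimmest in-cell pixels carry a few hundred photons (SNR >= ~15),
  the brightest ~1e6.

What the generator does **not** emulate: optical blur (no PSF), spatial
organelle structure, photobleaching or other kinetics, chromatic
aberrations beyond a global affine, pH/environment-dependent fluorophore
photophysics, and constructs that genuinely violate the single-plane model
(a deliberately off-plane population can be injected by rendering with a
second instrument, but no physical cause is modelled). Passing tests
therefore validate the estimator chain — crosstalk medians, plane fit,
map inversion, diagnostics — under realistic photon statistics and
expression heterogeneity, not the full complexity of live-cell imaging.

## Preprocessing

Camera correction is (raw - dark) / (flat / mean(flat)); negatives from
read noise are preserved (clipping would bias medians and the plane fit).
Channel registration estimates local displacements by upsampled
phase cross-correlation in a block grid and fits a 2x3 affine by least
squares; because rotation and scale blur a block's correlation peak, the
estimate is refined iteratively (warp, re-estimate the residual
transform, compose; up to 3 passes, stopping when the residual stops
improving). Recovery accuracy on synthetic bead fields is ~0.01–0.05 px
mean displacement for |translation| <= 10 px, |rotation| <= 2 deg, scale
within 2%. Warped-out pixels become NaN and are excluded from masks
rather than zero-filled. Resampling is bilinear by default,
nearest-neighbour for exactness tests.

Segmentation (the mask only gates which pixels enter statistics) smooths
I_DD + I_AA and applies Otsu's threshold **in the log1p domain**: with
expression spanning orders of magnitude a linear-domain Otsu threshold
places itself between dim and bright cells instead of between background
and cells, discarding the dim half of the population. Components under
100 px are removed and holes filled; all parameters are exposed in
`SegmentationConfig`, including an absolute-threshold override.

## Diagnostics

Concentration independence is quantified by the Spearman rank correlation
between the pixelwise E map and I_AA (the only channel unaffected by
FRET); calibration quality by Spearman(E, S), which is near zero only
when gamma_M and beta_X are right — with gamma = beta = 1 the E–S cloud
tilts strongly (rho ~ 0.96 on the default study). Both statistics are
stochastic at the cell level: with ~26 cells per construct their
seed-to-seed spread is a few hundredths even for a perfectly calibrated
instrument, which is the natural scale against which single measured
values of a few hundredths should be read. Dataset summaries use the
mean of per-cell medians with the SEM over cells, since cell-to-cell
variability, not pixel statistics, dominates.

## Confidence filter

W = exp(-(S-S0)^2 / (2 sigma_S^2)) with sigma_S acting as the sd-like
sensitivity parameter (default 0.1, i.e. pixels with S outside roughly
[0.4, 0.6] for a 1:1 construct lose most of their weight). The weighted
filter is normalized convolution with a unit-sum Gaussian kernel (sd 1.5,
7x7); borders renormalize over in-image support, equivalent to
zero-padding W. The W_th = 0.5 threshold is applied to the pixel's own
raw weight, not the smoothed weight, so a single anomalous pixel is
removed even when surrounded by good neighbours. Outputs are NaN where
no weight is available — the filter never invents values.

## Mixture model

Free donor shifts both observables: E_app = E0/(1+r), S_app =
(1+r)/(1/S0+r) with r the free-donor to construct ratio; eliminating r
gives the trajectory S_app = (E0/E_app)/(1/S0 + E0/E_app - 1), fitted to
(E_app, S_app) samples by least squares in the single parameter E0 using
vertical (S) residuals. Free acceptor leaves E untouched and dilutes S:
from the count definition, S_app = S0/(1 + r*S0); this expression is
validated against the rendered two-population forward model rather than
transcribed. A horizontal free-acceptor series fed to the free-donor fit
is flagged by the RMS-residual diagnostic (threshold 0.05 in S units).
Simultaneous free donor *and* free acceptor is out of scope: the
per-pixel ensemble makes that deconvolution ill-posed.

## Method benchmark

The two rival calibrations are implemented from their defining
constraints, not transcribed formulas, and both are gated by a noise-free
equivalence oracle (they must reproduce the generating gamma_M/beta_X
exactly): the 1/S-vs-E line fit inverts intercept = 1 + beta*gamma,
slope = beta*(1-gamma); the two-step G/k route solves the per-pixel
ratio-mean constraint that (G*I_DD + I_DA_corr)/I_AA is identical across
same-stoichiometry populations, then reads k off a known-stoichiometry
standard. Pixels with S_raw < 0.05 are excluded from the line fit (1/S
diverges). Under matched noisy bootstraps the line fit's factor
dispersion exceeds the plane fit's by an order of magnitude at 1e3–1e5
pixels (errors-in-variables noise in the E_raw abscissa also biases it
low on dim-pixel-heavy data), and the two-step route's factors swing by
tens of percent across two-construct subsets while the plane fit moves
by <1% — the quantitative case for the single-step 3D fit.

## Problem sizes and determinism

The default study renders ~19 fields of 320x320 px (~1.1e5 in-cell
pixels), which the full pipeline processes in a few seconds; bootstrap
tables use 200 replicates. All randomness flows through one
`numpy.random.Generator`, so identical seeds give bit-identical images,
calibrations and reports.
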