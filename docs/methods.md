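# Methods

## Statistical model

A droplet of volume *V* (pL) is formed from a phage-side stream (volume
fraction *α*, titer *c_p* in PFU/mL) and a bacteria-side stream (fraction
1−*α*, density *c_b* in cells/mL). Encapsulation of each particle is
independent, so the phage and bacterium counts per droplet are Poisson with
means λ_p = α·c_p·V and λ_b = (1−α)·c_b·V (the single pL→mL conversion,
1 pL = 10⁻⁹ mL, lives in `core.PL_TO_ML`). A droplet exhibits a lysis event
iff it contains ≥1 bacterium and ≥1 phage that adsorbed, giving

P_L = (1 − e^{−λ_p})(1 − e^{−λ_b}).

For λ_b ≥ 10 the bacterial factor is within 5×10⁻⁵ of 1 (`core.LARGE_LAMBDA_B`),
and P_L ≈ 1 − e^{−λ_p} no longer depends on the bacterial density; this is the
regime in which observed positive fractions are inverted to digital titers,
c_p = −ln(1 − P_L/(1 − e^{−λ_b})) / (αV). The inversion **raises**
`InfeasiblePositiveFraction` when P_L reaches the bacterial-occupancy ceiling
1 − e^{−λ_b} instead of clamping, so upstream misclassification surfaces
rather than being absorbed into a silently infinite titer.

Kinetics: phage adsorption follows mass action with second-order constant
*k* (mL/min) against the *effective* bacterial density, after a maturation
lag τ (min) covering adsorption-to-lysis delay and emulsification dead time:

P_L(t) = 1 − e^{−α c_p V·A(t)},  A(t) = (1 − e^{−(1−α)·k c_b·(t−τ)})⁺.

The fit identifies the product k·c_b (an effective first-order rate, 1/min);
*k* itself is back-calculated by dividing by the effective density
(`adsorption_rate_from_effective`). The form assumes λ_b large; both the
forward evaluation and the fit warn when the configured λ_b < 10. A
per-droplet variant with rate k·(b/V) exists only in the simulator and
converges to the mean-field form as λ_b grows.

### Effective vs nominal bacterial density

Bulk OD measurements count dead, dormant and resistant cells along with
infectable ones, so the density that actually drives droplet lysis is a
fraction of nominal. The continuous-α design identifies this fraction from
the assay itself: P_L(α) rises with α through the phage factor and falls near
α→1 through the bacterial factor, so a weighted nonlinear fit of the product
form recovers (c_p, effective c_b) jointly. OD conversion uses a configurable
ρ = 8×10⁸ cells/mL per OD600 unit (strain- and instrument-dependent; all
reported densities scale linearly with it).

## Digitization

Droplet fluorescence modes are approximately log-normal, so a Gaussian
mixture is fitted to natural-log green peaks (base only rescales means).
K = 1..4 is selected by BIC. Two deterministic EM starts are tried per K —
k-means and quantile-placed means — and the better log-likelihood wins:
one-sided initialization alone leaves EM in poor local optima when the
negative mode is either rare or dominant, which is exactly where a biased
P_L is most damaging. Components supported by fewer than 5 droplets are
discarded as EM artifacts (an outlier can otherwise claim its own component
below the true negative mode and flip the polarity of every real mode).

The negative set is the lowest-mean component, extended by any neighbour
closer than 2×min(SD) (fragments of an over-split mode); P_L is the summed
weight of all remaining (higher) components, which automatically absorbs the
multi-lytic-cycle tiers seen at high titers. Hard-label and mean-posterior
estimates are available as cross-checks and agree within 0.01 whenever modes
are ≥4σ apart. The confidence interval on P_L is a Wilson interval at the
droplet count, propagated through the monotone inversion for titer CIs.

A single-component fit is ambiguous (all-negative vs all-positive) and
`positive_fraction` refuses to guess; `classify_with_control` polarizes it
against a phage-free control, and for time courses
`timecourse_positive_fractions` uses the most clearly multimodal aliquot as
the negative-mode reference for pre-lag aliquots.

Silhouette scores are computed on hard labels with a 10⁴ subsample cap
(O(n²) metric); at the simulator's 4σ mode separation scores fall in the
0.5–0.8 band.

## Population splitting

The red reference dye travels with the phage-side stream, so the red peak
encodes α (linearly, by default gain 1.0 and offset 0.1 in arbitrary units)
and the red pulse width encodes droplet diameter (∝ (6V/π)^{1/3}).

* Discrete α groups and size modes: 1-D Gaussian mixtures on red peak /
  width, groups ordered by mean; an optional posterior floor discards
  droplets between groups.
* Continuous α: equal-width bins over the calibrated red range (endpoints
  measured externally, e.g. by microscopy; the simulator supplies exact
  endpoints), each bin assigned the α of its mean red peak; out-of-range
  droplets are discarded and counted, bins below a minimum occupancy are
  dropped. The default 300 bins at 7.2×10⁵ droplets give ≈2400 droplets per
  bin. A `red_encodes="bacteria"` flag handles the swapped dye convention.
* Coalescence: widths beyond 4 SD above the largest legitimate size mode are
  flagged and excluded from positive-fraction statistics.

## Fits

Both nonlinear fits are weighted least squares with binomial weights
w = n/(P(1−P)+ε), ε = 10⁻⁶ guarding degenerate bins, solved by
`scipy.optimize.least_squares` from a fixed multistart grid (occupancy
parameters on log scale: c_p·V ∈ {0.01, 0.1, 1, 10}, c_b·V ∈ {1, 10, 100};
τ over 5 equispaced values in [0, first positive time]; rate r ∈
{10⁻⁴..10⁻¹}). Best final SSE wins, ties broken toward lower c_p, so fits
are deterministic given the data. Internal parameterization uses
droplet-scale occupancies (c_p·V, c_b·V) to decouple the unit system from
the optimizer. R² is 1 − SS_res/SS_tot on weighted residuals. Hard bin
counts (not posterior-weighted) enter the weighting; the digitized P_L per
bin is the mixture-weight estimate.

Lysis completion f = P_L^exp/P_L^th uses the plate-count titer and the
*nominal* density for P_L^th, so f < 1 exposes incomplete lysis and/or
reduced effective density; an OLS line of f against λ_b summarizes the trend.
Time-course titers are computed per aliquot independently (destructive
readout, no serial correlation), and the two size modes of a bimodal
emulsion are fitted independently by default.

## Simulator

`simulate_emulsion` draws, per droplet: α (fixed, discrete set, or uniform
range), volume (weighted modes; coalesced droplets get doubled volume with
probability 0.5% and are flagged), Poisson counts b and p at the *effective*
density, and a binomial number of adsorbed phages with per-phage adsorption
probability A(t) (mean-field default, per-droplet option). The droplet is
truth-positive iff b ≥ 1 and ≥1 phage adsorbed.

Green signal: log-normal with mean μ_neg + shift·tier, σ = 0.15 in natural
log space and shift 1.0 (≈6.7σ mode separation), tier = lysed bacteria
capped at 2; an extra shift marks droplets whose first adsorption preceded
the observation by more than a 30-min burst period with hosts to spare
(phenomenological secondary, progeny-driven lysis — the mechanism is not
modeled). Unadsorbed bacteria lyse spontaneously with probability 10⁻⁵
each, producing the faint false-positive tail real bacteria-only emulsions
show. Red signals get mean-one multiplicative log-normal noise with 2% CV.
Time courses draw an independent emulsion per observation time, mirroring
scanning of separate aliquots.

What the simulator does **not** emulate: hydrodynamic droplet formation,
detector shot noise and electronic baselines, dye partitioning and
photobleaching, phage aggregation, and any correlation between α and droplet
size. Passing recovery tests therefore demonstrate correctness of the
statistical machinery under the model's own assumptions, not instrument
robustness. Red↔α calibration and droplet volumes are free simulator
parameters and are not claims about any particular instrument.

## Study conditions used in tests and the reproduction script

* Continuous-α sweep: 7.2×10⁵ droplets, α uniform on (0.02, 0.98), V = 15 pL,
  c_p = 1.205×10⁸ PFU/mL, effective density 28.6% of the nominal
  OD-derived value (effective OD 0.773), 300 bins. V is chosen so λ_p ≤ ~1.8
  across the α range, keeping every bin inside the assay's informative band —
  the same dynamic-range argument that motivates α screening in the first
  place; at several-fold larger volumes the high-α bins saturate and
  threshold-free digitization of a vanishing negative mode becomes fragile.
* Kinetic time course: α = 0.5, V = 40 pL (λ_b ≈ 10.5 at the effective
  density), c_p = 8.30×10⁷ PFU/mL, τ = 24.6 min, k·c_b = 0.0061/min; 8
  aliquots at 10–600 min, 10⁵ droplets each — the upper end of realistic
  per-aliquot scan counts, keeping Monte-Carlo spread of the rate estimate
  small relative to its tolerance.
* Property suites run at reduced replication (e.g. 6 seeds for
  model-selection stability, 80 replicates for CI coverage) — sizes chosen
  as the package's own test design for single-CPU runs.

## Numerical choices and edge cases

* `expm1`/`log1p` throughout the closed forms; exact 0 returned at t ≤ τ.
* GMM: `reg_covar = 10⁻⁶`, 500 EM iterations, diagonal covariances;
  deterministic given the seed.
* Degenerate inputs raise: identical red signals (clustering), <50 droplets
  (digitization), <10 bins or α span <0.2 (α fit), <4 time points or
  all-plateau courses (kinetic fit), P_th = 0 (completion).
* JSON reports serialize floats at 12 significant digits with sorted keys;
  identical config + seed reproduces reports byte for byte.

## Known limitations

* The digitizer trusts mode structure; fluorescence distributions with heavy
  non-log-normal tails would need the control-based path.
* The α fit treats bin α as exact; red-noise-induced smearing of bin
  composition is negligible at 2% CV but would bias strongly curved regions
  at much higher noise.
* Secondary-lysis modeling is phenomenological (a fluorescence tier, not a
  progeny dynamics model); burst size and multi-round infection are out of
  scope.
* Identical seeds reproduce results on a fixed software stack; bitwise
  reproducibility across BLAS/library versions is not guaranteed.
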