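# Methods

This note documents the models implemented in `lipodimer`, the defaults
they ship with, the numerical choices made where the design was open,
and what the synthetic-data tests do and do not demonstrate.

## Density scales

Membrane density enters on four scales. From the reconstitution mass
density ρ (µg protein per mg lipid):

    chi_recon = ρ · 1e-3 · MW_lipid / MW_protein        (subunit/lipid)
    chi_obs   = recovery_factor · chi_recon
    chi*      = orientation_factor · chi_obs
    rho_area  = 2 · chi* / SA_lipid                     (subunit/nm²)

`recovery_factor = 0.50` is the measured observed/reconstituted ratio
after freeze/thaw and extrusion; `orientation_factor = 0.5` reflects
random insertion orientation with only like-oriented subunits able to
react. `SA_lipid = 0.6 nm²` is the per-leaflet area per lipid; the
factor 2 counts both leaflets' lipids against the bilayer area.
`box_nm = sqrt(1/rho_area)` is the side of the square bilayer patch
holding one subunit.

Defaults `MW_protein = 50,000 g/mol` and `MW_lipid = 750 g/mol` were
chosen as the round-number pair that reproduces the published
density-conversion lookup table at printed precision in every row
(column 2 of that table is exactly 1.5e-5·ρ). The construct-specific
subunit masses (51,997–52,177 g/mol) and the 2:1 POPE:POPG sodium-salt
molar mean (735.66 g/mol) are available as named constants; conversions
are exact in the inputs, with rounding applied only at presentation.

## Two-site labeling model

Each subunit has a specific engineered-cysteine site (probability
`p_site = p_cy5 − p_ns`) and one lumped non-specific site (`p_ns`),
labeled independently. Marginalizing the four site states gives the
monomer fluorophore-count law on {0, 1, 2}; a dimer is two independent
subunits, so its law on {0,...,4} is the discrete self-convolution. No
cooperativity between sites or subunits is modeled, and at most two
fluorophores per subunit are allowed. Defaults `p_cy5 = 0.72`,
`p_ns = 0.14` are the pooled spectrophotometric means. Photophysics
(blinking, dark states) is out of scope; the experiment this models
avoids blinking by omitting oxygen scavengers.

## Liposome population and capture

The extruded population is a discrete radius distribution over 2.5 nm
bins on [10, 100] nm. The measured cryo-EM histogram for 0.4 µm
extruded membranes is published only as a figure, so the package ships
a **synthetic stand-in**: a truncated lognormal (σ_log = 0.35)
calibrated by bisection of the median so that 40% of liposomes fall
below r = 27.5 nm, matching the reported small-liposome mass. Users
with a measured table substitute it via a two-column text file.

Capture follows three rules:

1. Liposome counts per bin are proportional to the bin probability.
2. Dimers (~10 nm across) cannot enter liposomes below
   `r_min = 25 nm`; the excluded bins keep their liposomes, which stay
   empty and contribute to the unoccupied fraction F0. Monomers see the
   whole population.
3. Protein partitions between accessible bins in proportion to
   membrane surface area, i.e. weights ∝ r²P(r) (renormalized over
   accessible bins); within a bin each particle lands on a uniformly
   random liposome. One liposome of radius r holds 8πr²/SA_lipid
   lipids (two leaflets), which fixes the mole fraction of a counted
   system as chi = N_sub·SA_lipid / (N_lip·8π·E[r²]).

Two engines evaluate the per-liposome visible-fluorophore law P*:

* **Analytic.** Within a bin the particle count per liposome is
  Binomial(N_particles(bin), 1/N_liposomes(bin)); the fluorophore count
  compounds that with the label-count law. Per-bin laws are mixed with
  the bins' liposome shares. Fractional expected bin counts use the
  mean-preserving mixture of the two bracketing integer binomials; bins
  with at least 1e4 liposomes use the Poisson limit (error
  O(λ²/N_lip) < 1e-4). The occupancy support is truncated at
  N_Cy5 = 12 with a tail bucket (traces up to nine steps are countable
  in practice, so 12 is beyond the usable range).
* **Monte Carlo.** Liposomes are never materialized: particles draw a
  bin (multinomial on the allocation weights) and an integer index
  within the bin, and collisions are accumulated by sorting the sparse
  (bin, index) keys. Populations up to 1e12 liposomes run in memory.
  Bin allocation is stochastic (multinomial), agreeing with the
  surface-area expectations. Streams are seeded per bin from a spawned
  seed sequence, so per-bin draws are order-independent.

The analytic engine is the default for ideal monomer/dimer reference
distributions (deterministic, no simulation noise); the Monte Carlo
engine validates it (total-variation agreement tested at 1e5 occupied
liposomes) and powers the joint-capture generator. Conditioning the
occupancy on visibility gives the step-count probabilities
P_n = P*(n)/(1−F0) with the top category absorbing the tail; the
default category scheme for fitting is 1–4 plus 5+.

Above chi = 3.8e-4 subunit/lipid the monomer and dimer references
merge and the package warns; multilamellarity and size-dependent
detection efficiency are not modeled.

## Dimer-fraction estimation

At each density the observed distribution is matched to
(1−F)·P^M + F·P^D by least squares over the step categories. The
minimizer is the closed-form projection
F = Σ(P_e−P^M)(P^D−P^M)/Σ(P^D−P^M)², clamped to [0, 1]; a grid scan at
1e-3 resolution is retained for verification and for plotting R²(F)
curves. The per-point weight for the isotherm fit is 1/R²_min with
R²_min floored at 1e-6, since the inverse is undefined at an exact fit.
Replicates at one density are averaged (mean F, mean R²) before
fitting, matching the experimental practice of fitting mean values
across samples and counters; unaveraged estimation is available.

Two-sample comparisons of count vectors use the Pearson chi-squared
statistic on the 2×k contingency table, pooling categories whose
expected counts fall below 5 in both samples into the top bucket.
Counting uncertainty on a proportion is sqrt(p(1−p)/N).

**Known bias of the literal mixture model.** The estimator weights
per-spot distributions by the per-subunit dimer fraction F, but a dimer
spot carries two subunits and is more often visible. Physically
generated data (joint mode, below) therefore recover the visible-spot
dimer fraction s = (F/2)v_D/((1−F)v_M + (F/2)v_D), where v is each
species' probability of carrying at least one fluorophore — about 0.09
below F at mid-transition with the default yields. The package follows
the literal convention throughout (so fitted constants are comparable
with the published ones) and quantifies the discrepancy in the test
suite rather than silently correcting it.

## Isotherm and thermodynamics

For M + M ⇌ D on the mole-fraction scale with K = chi*_D/(chi*_M)² and
chi* = chi*_M + 2chi*_D, the subunit dimer fraction is

    F(chi*) = (1 + 4chi*K − sqrt(1 + 8chi*K)) / (4chi*K),

evaluated in the cancellation-free form x/(1 + x + sqrt(1+2x)) with
x = 4chi*K. Titrations carry a baseline offset Y0:
F = (1−Y0)F + Y0, with Y0 either fitted or fixed (fixing is needed when
the all-monomer plateau is experimentally unreachable).

The fit is weighted nonlinear least squares in log10 K (positivity and
conditioning; the original analysis does not state its
parameterization), weights 1/R²_min, via a trust-region solver.
Standard errors come from the linearized covariance scaled by the
reduced chi-squared. The 95% CI half-width on log10 K uses a delete-1
jackknife SE with a t quantile: the 1/R² weights are noisy surrogates
for inverse variances, and calibration on synthetic titrations (100
replicates at true log10 K = 6.57) gave 90% coverage for the linearized
CI versus 96% for the jackknife at nominal 95%. For fewer than four
points the linearized CI is used.

Free energies: ΔG° = −RT ln(chi°·K) with R = 1.9872036 cal/(mol·K),
T = 298 K and chi° = 1 subunit/lipid. On the area scale
K_ρ = K·SA_lipid/2 (nm²/subunit), ρ° = 1 subunit/nm², and
`eq_box = sqrt(K_ρ)` is the patch size at which half the subunits are
dimeric. Reproducing the last printed digit of published derived
quantities from rounded printed constants is not always possible; tests
compare only digits stable under printed-precision inputs. No
subunit/lipid volume corrections are applied to either scale.

## FRET saturation model

The macroscopic FRET readout is the summed-intensity ratio
acceptor/(donor+acceptor), after subtracting 0.12× the acceptor-only
reference for direct acceptor excitation. For an n-mer with random
donor/acceptor assignment at acceptor/donor ratio R, normalized FRET
follows ((R+1)ⁿ − Rⁿ − 1)/((R+1)ⁿ − Rⁿ − 1 + n). Order selection fits
candidates n ∈ {2, 3, 4} with a free amplitude and compares residuals
on the log scale (fluorescence-ratio noise is multiplicative; the
amplitude becomes a fitted offset, and donor-excess points — where the
orders differ most in relative terms — carry full weight). A one-site
hyperbola fit supplies the reported saturation amplitude and R50. Note
the n = 2 curve is exactly R/(R+1), so normalizing by a
hyperbola-fitted maximum before selection is unbiased only for dimers;
that is why the amplitude is re-fit per candidate. Linear residuals are
used as a fallback when any FRET value is zero.

## Synthetic titrations

`generate_titration` plays the experiment: evaluate F(chi*) from a true
K and Y0 at each density, then draw per-sample step counts.

* `mixture` mode draws multinomial counts from (1−F)P^M + F·P^D — the
  estimator's own model, so recovery tests isolate estimation and
  fitting error.
* `joint` mode runs one Monte Carlo capture with monomers and dimers in
  the same liposome population (co-capture allowed) and subsamples the
  requested number of spots — the stricter realism test; see the
  spot-weighting bias above.

Default conditions mirror the study: 13 densities spanning
chi* = 3.8e-10 to 1.9e-4, 200–500 spots per sample, 2–3 replicates.
Ground truth is embedded in a commented JSON header of the dataset file
so recovery tests need no side channel; identical seed and
configuration produce byte-identical files.

What passing tests show: the estimator and fit recover a known constant
without bias (mean log10 K within ±0.3 at 300 spots, 8 densities, 3
replicates) and with calibrated uncertainty under the mixture noise
model. What they do not show: robustness to an inaccurate radius
distribution (the stand-in is not the measured histogram),
multilamellarity, counting errors by human scorers, or the
spot-weighting bias of the literal mixture convention — the latter is
measured (~0.09 in F at mid-transition) but deliberately not corrected.

## Problem sizes in the test suite

Monte Carlo cross-checks run at ~1.2e5 occupied liposomes per
condition; end-to-end recovery uses 20 seeded replicates of a
24-sample titration; FRET order recovery uses 20 replicates of a
10-point saturation curve. The full suite completes in well under a
minute on one core.
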