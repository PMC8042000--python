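# Methods

## Optimality core

The package predicts V<sub>cmax25</sub> from growing-season climate by
combining the least-cost hypothesis (optimal χ = C<sub>i</sub>/C<sub>a</sub>)
with the coordination hypothesis (carboxylation co-limiting with
electron transport), followed by Arrhenius standardization to 25 °C.
Assumptions inherited from that framework: stomatal behaviour has
equilibrated to the *growth* environment (all kinetics inside the χ
equation are evaluated at T<sub>g</sub>, not instantaneous leaf
temperature); mesophyll conductance is non-limiting, so predicted and
observed values are "apparent" capacities; soil moisture is not
represented.

Parameter defaults, all overridable through `KineticParams`:

| parameter | default | units | note |
|---|---|---|---|
| Γ*₂₅ | 42.75 μmol/mol → 4.332 Pa | Pa | tobacco in-vivo (Bernacchi) set |
| K<sub>C25</sub> | 404.9 μmol/mol → 41.03 Pa | Pa | |
| K<sub>O25</sub> | 278.4 mmol/mol → 28.21 kPa | Pa | |
| ΔH<sub>a</sub> (Γ*, K<sub>C</sub>, K<sub>O</sub>, V<sub>cmax</sub>, J<sub>max</sub>) | 37.83, 79.43, 36.38, 65.33, 43.9 | kJ mol⁻¹ | |
| β | 146 | – | carboxylation:transpiration unit-cost ratio |
| φ0 coefficients | (0.352, 0.021, −3.4·10⁻⁴)/8 | – | quantum-yield polynomial in T<sub>g</sub> |
| R<sub>d</sub> fraction | 0.015 | – | day respiration as share of V<sub>cmax</sub> |
| energy-to-flux | 2.04 | μmol J⁻¹ | shortwave → PPFD |
| C<sub>a</sub> | 400 μmol/mol | – | converted to Pa via site pressure |
| O₂ | 0.20946 | mole fraction | converted to Pa via site pressure |

The mole-fraction constants are converted to partial pressures at the
barometric pressure of each site's elevation, so Γ\*, C<sub>a</sub> and
O scale in direct proportion to atmospheric pressure.

**Water viscosity.** η\* uses the Vogel (Vogel–Fulcher–Tammann)
equation η = 0.02414·10^(247.8/(T−140)) mPa s (T in K), normalised to
25 °C. It matches tabulated viscosities to <1 % over 0–40 °C and is a
single swappable expression behind `eta_star`; replacing it with the
full IAPWS formulation changes the temperature elasticity below by
under 10⁻⁴ K⁻¹.

**Units.** D is Pa inside the theory module (ξ has units Pa^0.5) and
kPa at every I/O boundary; conversion happens in
`EnvConditions.from_climate` and the CSV schemas.

## Climate elasticities

`elasticities` returns (∂lnV<sub>cmax25</sub>/∂lnPPFD,
∂lnV<sub>cmax25</sub>/∂T<sub>g</sub>, ∂lnV<sub>cmax25</sub>/∂lnD) by
central finite differences (relative step 10⁻⁵ on the log axes,
0.005 K on T<sub>g</sub>, halved near domain edges); the test suite
checks them against a symbolic-differentiation oracle to 10⁻⁶.

At the median climate (PPFD 400 μmol m⁻² s⁻¹, T<sub>g</sub> 25 °C,
D 0.6 kPa, sea level) the defaults give **(1, −0.0454 K⁻¹, 0.047)**.

Two deliberate choices here:

* **φ0 is held fixed while differentiating with respect to
  T<sub>g</sub>** (default). Differentiating through the quantum-yield
  polynomial as well gives −0.0394 K⁻¹; treating φ0 as a calibrated
  constant gives −0.0454 K⁻¹, the variant consistent with the commonly
  quoted −0.05 K⁻¹ for this model class. The flag
  `include_phi0_response=True` selects the full-chain derivative (and
  is what the synthetic-data generator's own local gradient matches,
  since the generator evaluates the full theory).
* **The lnD elasticity computes to ≈0.047, not the ≈0.07 sometimes
  quoted for this model class.** The value is insensitive to
  C<sub>a</sub> ∈ [38, 42] Pa (0.0468–0.0471) and to the viscosity
  correlation; reproducing 0.07 would require χ ≈ 0.70 at this climate,
  i.e. an effective β near 50 rather than 146. We report what the
  stated equations and constants give.

## Climate drivers

Monthly → growing-season aggregation follows fixed conventions: mean
daily temperature (T<sub>max</sub>+T<sub>min</sub>)/2 > 0 °C defines
the thermal growing season; daytime temperature uses the sinusoidal
diurnal-cycle weights with x = −tan λ tan δ; solar declination is the
standard annual harmonic −23.45°·cos(360°(d+10)/365) at mid-month;
polar day takes the continuous limit (daytime mean = diurnal mean) and
polar-night months are excluded; the barometric formula is the
standard-atmosphere lapse form (101 325 Pa at sea level). VPD is
computed per month and then averaged (not ea/es averaged first), is
clamped at zero when coarse humidity data imply supersaturation, and
the aggregate is floored at 0.01 kPa so ln D stays finite.

## Trait standardization

One-point V<sub>cmax</sub> estimates use leaf temperature and site
pressure in the kinetics. Records lacking measured C<sub>i</sub> are
dropped and counted, never imputed from χ. Site means are taken in two
stages (individuals → species-at-site → site) on the natural scale;
log-transformation happens only at regression time, because
mean-of-logs ≠ log-of-means. Single-stage pooling is available by flag.

## Statistical layer

The site-mean analysis is OLS of ln V<sub>cmax25</sub> on ln PPFD,
T<sub>g</sub>, ln D. The all-species analysis is a linear mixed model
with the same fixed effects and crossed random intercepts for site and
species (variance-components formulation, REML; crossed because
species recur across sites). Variance fractions are each random
component's share of site + species + residual variance, i.e. of the
variation unexplained by the climate fixed effects. Both marginal and
conditional R² are reported (fixed-effects variance over total, and
fixed+random over total); the marginal value is the one comparable to
an OLS R². Fixed-effect p-values use the large-sample normal
approximation. A singular or non-convergent random-effects fit falls
back to OLS with an explicit flag. Cook's-distance diagnostics and a
refit-without-top-k utility are provided; nothing is dropped
automatically.

Partial residuals are median-anchored: each response is adjusted to
hold all other predictors at their medians, which preserves the exact
identity between the partial-residual slope and the fitted coefficient.

## Smooth-minimum co-limitation

The co-limitation model fits ln V<sub>cmax25</sub> =
smooth-min(a<sub>N</sub> + b<sub>N</sub> ln N<sub>area</sub>,
a<sub>P</sub> + b<sub>P</sub> ln P<sub>area</sub>; k) by nonlinear
least squares at fixed sharpness k (default 20). Choices:

* *Limb form.* Linear in ln nutrient with log response by default
  (magnitude variables belong on the log scale); linear-in-nutrient
  limbs and natural-scale response are selectable. Published boundary
  curves for this model class imply other parameterizations are in
  use; the boundary extraction (`boundary_curve`) is generic in the
  limb form rather than tied to any one of them.
* *k fixed, not estimated.* k and the limb parameters are poorly
  jointly identified; `k_sensitivity` refits over a grid instead. With
  data generated from a (near-)hard minimum, RSS is non-increasing in
  k and plateaus beyond k ≈ 10.
* *Initialisation.* Min-regression is multi-modal, so each limb starts
  from its single-nutrient OLS line shifted to the upper residual
  quartile (an envelope, since the minimum lies below both limbs),
  plus 10 seeded jittered restarts; the best solution is kept.
  Convergence: least-squares with ftol = xtol = 10⁻¹², ≤ 2000 residual
  evaluations per start.
* *Identifiability.* A limb that is the argmin for under 5 % of
  records is flagged unidentifiable; its parameters and SEs
  (Gauss–Newton, pseudo-inverse guarded) should not be interpreted.

## Synthetic data

The generator emulates the structure of a global leaf-trait
compilation at a scaled size (default 200 sites, 4–12 species per site
from a 250-species pool, 1–3 individuals per species-at-site, ~6 % of
records by the one-point method). Per-site climate: PPFD log-uniform
100–800 μmol m⁻² s⁻¹, T<sub>g</sub> uniform 0–30 °C, VPD log-uniform
0.1–3 kPa but capped below 95 % of saturation at the site's diurnal
mean temperature (cold air cannot carry a 3 kPa deficit), elevation
uniform 0–4500 m. ln V<sub>cmax25</sub> = theory + site + species +
residual Gaussian effects with default standard deviations
(1.12, 0.74, 0.84), which place 50 % / 22 % / 28 % of the
climate-unexplained variance on site, species and residual and leave
climate explaining a realistically small share (~0.2 marginal R²
all-species, ~0.3 site-mean) of the total. Leaf P derives from total
soil P (log-log slope 0.4 plus noise), leaf N from capacity
(metabolic slope 0.02 g m⁻² per μmol m⁻² s⁻¹ over a 0.6 g m⁻²
structural intercept), with an optional pH coupling and an optional
P-limitation cap applied through the same smooth minimum the fitting
code uses.

Monthly climate tables are produced by inverting the aggregation:
twelve identical above-freezing months at latitude 0 whose daytime
temperature, PPFD and VPD reproduce the generating aggregates to
rounding error. The round trip through `aggregate_sites` is exact by
construction; the tables are *not* realistic weather (no seasonality,
no spatial correlation, no phylogenetic structure among species
effects), so passing tests demonstrate correctness of the aggregation
and inference machinery, not robustness to real-world seasonality or
sampling designs. All draws come from per-field substreams spawned
from one seed, so outputs are bit-reproducible and adding a field
never shifts existing draws.

Because the generating theory is nonlinear over these wide climate
ranges, the noise-free "exact recovery" check collapses the ranges to
a neighbourhood of the median climate, where the site-mean OLS
recovers the model's local elasticities to 10⁻³; over the full ranges
the best linear projection of the theory is (≈1.00, ≈−0.045, ≈0.049)
and the noisy fits are compared against it via their standard errors.

## Known limitations

* No J<sub>max</sub> optimality prediction (J<sub>max25</sub> is only
  standardized, not modelled); no mesophyll conductance; no
  soil-moisture modifier on χ.
* The lnD elasticity discrepancy described above.
* The mixed model reports normal-approximation p-values, not
  Satterthwaite/Kenward–Roger degrees of freedom.
* The generator's monthly climate is a structural inversion, not a
  weather simulation; GWR-style interpolation of gridded climate is
  out of scope — the package consumes per-site monthly climate
  directly.
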