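# leafopt

Optimality-based prediction and analysis of leaf photosynthetic capacity
for C3 plants.

Earth-system and ecosystem models need the maximum rate of Rubisco
carboxylation standardized to 25 °C (V<sub>cmax25</sub>, μmol m⁻² s⁻¹)
for every vegetated grid cell, yet it varies enormously within and
between species. `leafopt` implements the eco-evolutionary optimality
route to predicting it from climate alone, together with the
statistical machinery needed to confront that prediction with
multi-site, multi-species leaf-trait data and with leaf/soil nutrients.
It is aimed at plant ecophysiologists and land-surface modellers
working with site-level trait compilations.

## The model

Stomata are assumed to regulate the ratio χ = C<sub>i</sub>/C<sub>a</sub>
of intercellular to ambient CO₂ partial pressure so as to minimise the
combined unit costs of transpiration and carboxylation capacity
(the *least-cost hypothesis*):

```
χ_opt = Γ*/Ca + (1 − Γ*/Ca) · ξ/(ξ + √D),   ξ = √[β (K + Γ*) / (1.6 η*)]
```

where Γ\* is the photorespiratory compensation point (Pa), K the
effective Michaelis–Menten coefficient of Rubisco
(K = K<sub>C</sub>(1 + O/K<sub>O</sub>), Pa), D the vapour pressure
deficit (Pa), η\* the viscosity of water relative to 25 °C and β = 146
the carboxylation:transpiration unit-cost ratio. The *coordination
hypothesis* (carboxylation and electron transport co-limiting under
typical daytime conditions) then gives the optimal capacity

```
Vcmax,opt = φ0 · Iabs · (Ci + K)/(Ci + 2 Γ*)
```

with φ0 the intrinsic quantum efficiency
(φ0 = (0.352 + 0.021 T<sub>g</sub> − 3.4·10⁻⁴ T<sub>g</sub>²)/8) and
I<sub>abs</sub> the absorbed PPFD. Enzyme kinetics follow in-vivo
tobacco (Bernacchi) constants; Γ\*, C<sub>a</sub> and O scale with
atmospheric pressure; Arrhenius scaling converts to 25 °C.

Around this core the package provides:

* `leafopt.climate` — growing-season drivers (daytime T<sub>g</sub>
  from a sinusoidal diurnal cycle, PPFD from shortwave radiation,
  Magnus–Tetens VPD from specific humidity, barometric pressure);
* `leafopt.traits` — one-point V<sub>cmax</sub> estimation from
  light-saturated assimilation, 25 °C standardization, two-stage
  (individual → species-at-site → site) trait aggregation;
* `leafopt.inference` — site-mean OLS and crossed (site × species)
  mixed-model regressions of ln V<sub>cmax25</sub> on ln PPFD,
  T<sub>g</sub> and ln D; model-bias statistics; partial residual
  plots; leaf-nutrient/soil regressions;
* `leafopt.minfunc` — the smooth-minimum (log-sum-exp) model of
  nutrient co-limitation, Z = −(1/k) ln(e<sup>−kx</sup> + e<sup>−ky</sup>),
  with k-sensitivity scans and N/P limitation classification;
* `leafopt.synth` — a seeded generator of synthetic leaf-trait datasets
  with the statistical structure above, used throughout the test suite.

## Worked example

Predict the optimal capacity at the median climate of a global trait
compilation (PPFD = 400 μmol m⁻² s⁻¹, T<sub>g</sub> = 25 °C,
D = 0.6 kPa, sea level):

```sh
$ leafopt predict env.csv
site_id,tg_c,d_kpa,ppfd,elevation_m,chi,ci_pa,phi0,vcmax,vcmax25,elast_ln_ppfd,elast_tg,elast_ln_d
median,25.0,0.6,400.0,0.0,0.7972,32.312,0.0830625,84.496,84.496,1.0000,-0.0454,0.0470
```

χ ≈ 0.80 sits in the 0.5–0.9 range typical of C3 plants; the predicted
V<sub>cmax25</sub> of ≈ 84 μmol m⁻² s⁻¹ is a realistic mid-range value.
The last three columns are the climate elasticities of
ln V<sub>cmax25</sub>: exact proportionality to PPFD (elasticity 1), a
4.5 % *decline* per °C of growth temperature (the enzyme-kinetic saving
at warmth outweighs the photorespiratory cost), and a weak increase
with vapour pressure deficit (drier air → lower χ → more carboxylation
capacity needed per unit assimilation).

Fitting the nutrient co-limitation model to a demo dataset generated
from two known limbs:

```sh
$ leafopt minfunc demo.csv --k 50
k=50.0 limb_N=(3.0000, 0.8000) limb_P=(4.6000, 0.7000) R2=1.000 AIC=-2821.2
limited fraction: N=0.28 P=0.72
```

The two generating limbs are recovered exactly and each record is
labelled by its limiting nutrient (the argmin of the limb predictions).

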