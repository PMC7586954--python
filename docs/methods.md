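# Methods

This note documents the model as implemented: its equations, assumptions,
default parameters, numerical choices, what the synthetic world does and does
not emulate, and known limitations.

## 1. Xylem vulnerability curves (`vcurves`)

Conductivity loss with xylem pressure ψ (MPa, ≤ 0) is a two-parameter
Weibull, PLC(ψ) = 100(1 − exp(−(−ψ/b)^c)).  `b` is stored as a positive
magnitude; `c` < 1 gives the R-shaped curves typical of cotton.  P50 has the
closed form −b(ln 2)^(1/c).

Fitting is nonlinear least squares on either the PLC or the conductivity
scale.  Because R-shaped data admit poor local minima under single starts,
every fit runs a 3×3 multistart grid (b₀ ∈ {0.2, 1, 3} MPa, c₀ ∈
{0.5, 1, 2}) under box bounds b ∈ (0.01, 20], c ∈ (0.05, 20], keeping the
lowest-cost solution.  PLC fits supply the (b, c) used by the simulator; the
conductivity-scale fit is provided but secondary.  Data with fewer than two
distinct pressures or zero response variance raise a non-identifiability
error rather than returning a flat curve.

Genotype comparisons use a one-way fixed-effects ANOVA computed from the
textbook sums of squares with Tukey HSD post-hoc pairs (studentized-range
p-values), α = 0.05.  Both are implemented from the formulas (with scipy
distributions for tail probabilities) so the comparison has no hidden
degrees-of-freedom conventions; tests cross-check against independent
implementations.

## 2. Soil texture interpolation (`soilgrid`)

Ordinary block kriging with an exponential (default) or spherical variogram.
The empirical semivariogram is binned (12 bins to half the maximum lag) and
fitted by least squares weighted by √(pair count).  The kriging system
carries a Lagrange multiplier so weights sum to one (unbiasedness); block
support is a 4×4 cell-centered discretization whose point predictions are
averaged.  Duplicate sample locations are averaged before solving (they make
the zero-nugget system singular).  Clay and sand are kriged independently per
depth layer; silt = 1 − clay − sand, clipped — a deliberate simplification
that preserves closure without compositional (log-ratio) machinery.
Contrasting cells are those at or beyond the 10th/90th clay percentiles
(linear interpolation between order statistics, boundary ties included).

## 3. Pedotransfer and soil water (`soilphys`)

The Rawls–Brakensiek regression family maps (clay %, sand %, porosity) to
Brooks–Corey parameters: air-entry potential ψ_e, pore-size index λ,
saturated conductivity K_s, and residual water content θ_r; θ_s is porosity.
Coefficients are stored as data tables keyed by monomial exponents so an
alternative regression can be swapped without code changes.  Inputs outside
the calibration envelope (clay > 0.60, sand > 0.95, or below 0.05) are
clamped with a warning.  One caveat found during implementation: the
regression's air-entry head is *non-monotone* in clay at fixed sand and
porosity over the agronomic range, so "more clay ⇒ more negative ψ_e" only
holds under the realistic covariation where sand falls as clay rises (it does
hold between the packaged low-clay and high-clay sets).

Retention is Brooks–Corey, ψ = ψ_e·S_e^(−1/λ) with
S_e = (θ−θ_r)/(θ_s−θ_r), exactly invertible; potentials wetter than air entry
map to saturation.  Unsaturated conductivity is the Campbell power law
K = K_s·S_e^(3+2/λ).  Field capacity and wilting point are θ at −0.033 and
−1.5 MPa.  All potentials are MPa to match the plant side.

## 4. The hydraulic network (`hydraulics`)

**Topology.** One Weibull shoot element in series with a root crown node;
below the crown, one branch per soil layer consisting of a linear rhizosphere
conductance in series with a Weibull root element.  Saturated whole-plant
conductance k_max = E_sat/(ψ_pd − ψ_md) (7.125 mmol m⁻² s⁻¹ MPa⁻¹ for the
packaged species set) is split 50/50 in resistance between shoot and root
(configurable); per-layer root conductances scale with root-area fractions.
Rhizosphere conductance is K(θ) over a characteristic length (50 × the
geometric mean particle diameter, configurable) scaled by absorbing root area
(LAI × root:leaf ratio × layer fraction); it is effectively infinite in wet
soil and collapses steeply as the soil dries, which is the mechanism that
shuts off uptake from dry layers.

**Fluxes.** The Kirchhoff transform of the Weibull conductivity has the
closed form Φ(x) = b·Γ(1+1/c)·P(1/c, (x/b)^c) (x = −ψ, P the regularized
lower incomplete gamma), so element fluxes are Φ-differences and only node
potentials require iteration.  The per-layer rhizosphere–root balance is
solved by bracketed root finding *in flux space*: solving for the interface
tension instead would amplify the absolute tolerance by the (possibly
enormous) rhizosphere conductance.  The supply function saturates at
E_crit, found as the crossing of the increasing crown inflow and the
decreasing residual shoot capacity k_sh(Φ_max − Φ(x_crown)); for a single
element on saturated soil this reduces to the closed form k·b·Γ(1+1/c),
which the tests verify by quadrature.

**Regulation.** Demand above 90 % of the instantaneous E_crit (configurable)
is capped and the step flagged — a simple stand-in for stomatal closure
preventing runaway cavitation.  Element conductivities are computed from
current-step potentials (within-step refilling, no cavitation memory):
appropriate for a single-season crop whose measured curves were constructed
after flushing.

**A structural caveat.** With the packaged species parameters the network's
saturated-soil E_crit is ≈ 5.6 mmol m⁻² s⁻¹, below the measured saturated
transpiration E_sat = 11.4.  This is a theorem, not a bug: the root curve
(b = 0.29, c = 0.59) bounds the root element's Kirchhoff capacity at
k_root·b·Γ(1+1/c), and no resistance split consistent with k_max both passes
11.4 and keeps leaf potentials near ψ_md.  Eq-4-style k_max is a definition
of the saturated conductance, not an operating point of the cavitating supply
curve; consequently well-watered middays can be supply-capped, and solving
for E_sat does not return ψ_md.  The model's comparative statements
(genotype orderings, soil contrasts, scenario responses) are unaffected.

**Demand and canopy temperature.** G_s(D) = max(0, G_sref(1 − 0.6 ln D))
(Oren form, slope 0.6 fixed as the literature default, configurable), times a
saturating light factor PAR/(PAR+250) normalized to 1 at the 2000 µmol m⁻²
s⁻¹ cuvette reference; E_demand = G_s·(D/P_atm)·LAI.  Canopy temperature is a
big-leaf energy balance T_c = T_air + (R_n − λE)/(ρc_p·g_H) with absorbed net
radiation proportional to PAR (0.283 W m⁻² per µmol m⁻² s⁻¹ ≈ 65 % of the
implied shortwave) and forced-convection boundary-layer conductance
1.4·0.135·√(u/d) per unit leaf area (d = 0.1 m).  In high advective demand a
transpiring canopy is cooler than the air.

## 5. Season loop (`simulate`)

Five 30 cm layers (0–150 cm, matching the sampling scheme); half-hourly steps
over DOY 160–240 (3840 records).  Step order: (1) infiltrate water input
top-down, filling each layer to field capacity before passing excess (bottom
excess leaves as deep drainage); (2) stomatal demand; (3) network solve;
(4) remove per-layer uptake; (5) layers above field capacity drain toward it
at 0.5 day⁻¹ (configurable).  The water balance closes to < 1e-6 mm per step
by construction and is hard-checked; θ leaving [θ_r, θ_s] is a hard error.
Initial θ is field capacity (configurable) — the profile is fully charged at
simulation start, consistent with pre-season irrigation.  There is no
bare-soil evaporation term: the focus is plant hydraulics, and irrigation
depths in the synthetic world are netted accordingly (a config hook exists).

Validation uses RMSE = √(mean(Y_f − Y_o)²) on nearest-step matched pairs
(1-hour tolerance).  The root:leaf-area ratio is calibrated by grid search
minimizing the across-layer mean RMSE; only windows containing a dry-down
carry signal for this ratio (under full irrigation θ sits at field capacity
regardless of root area), so the packaged calibration check runs DOY 175–205
under the severe scenario.

## 6. Metrics (`metrics`)

Daily predawn (03:00–05:00) and midday (12:00–14:00) means use half-open
windows in local standard time — four half-hour steps each.  PLK uses the
midday-mean k_plant; numerical supersaturation (k_plant marginally above
k_max) clamps to zero loss with a warning.  ρ divides daily margins by the
seasonal maximum (the windowed-mean convention; a 12:30-instant variant can
be had by aggregating that single step).  δ is the normalized difference of
midday transpiration between two runs with explicit role arguments; zero-mean
days are NaN-flagged, never dropped.  A divergence day has strictly opposite
δ signs on the two soils (zero counts as non-divergent — conservative flip
detection); windows are maximal runs of ≥ 2 consecutive same-orientation
flip days.  Scenarios E2/E3 multiply every water-input step from DOY 188
onward by 0.5/0.25, leaving all other forcing untouched.

## 7. The synthetic world (`synthetic`)

The generators emulate an arid-summer irrigated cotton season at 33° N:
solar-elevation PAR peaking near 2000 µmol m⁻² s⁻¹; air temperature
31 ± 7 °C with a 15:00 peak; VPD from Tetens saturation pressure against an
18 °C dewpoint (midday ≈ 4–4.5 kPa, below the 5.3 kPa closure point of the
stomatal model so middays remain transpiring); wind ≥ 0.3 m s⁻¹; no rain.
Irrigation: 20 mm every 2 days before drought initiation (≈ demand-matching),
10.6 mm every 2 days after DOY 188 — sized so the severe scenario (25 %)
receives 68.9 mm over the drought period, matching the reported severe-
scenario total of ≈ 69 mm.  Soil fields are Gaussian random fields with
exponential covariance; VC measurements add Gaussian PLC noise (σ = 5 PLC
units by default, 3 segments × 6 pressures).  Moisture observations subsample
19 time-points with σ = 0.01–0.02 m³ m⁻³ noise.

What the synthetic world does *not* emulate: real weather autocorrelation and
frontal events, soil heterogeneity with depth beyond a mild clay trend,
instrument drift, or the actual 2012 field records (not deposited).  A green
end-to-end test therefore establishes internal consistency and the
qualitative genotype × soil × scenario mechanisms, not numerical agreement
with the original field season.

Genotype stem-VC presets are synthetic stand-ins: only genotype P50s were
published, so preset `b` values are back-computed from P50 (−0.49 for the
landrace-like, −1.52 for the PD3-like, −1.15/−1.05 interpolated for the
remaining two) with the species shape c = 0.75.

## 8. Experiments (`experiments`)

`validation`: species parameter set × {high, low clay} × {well-watered,
water-limited} with staged LAI (1.5 → 4.0 in four stages).  `sensitivity`:
five stem VCs × E1–E3 on the mean soil (24–58–18 clay-sand-silt), LAI fixed
at 3.5.  `gxe`: the steep landrace-like and modern-cultivar-like curves ×
{HC, LC} × E1–E3 (12 runs) plus per-scenario divergence reports.  A manifest
records the seed and config hashes; identical specs reproduce bitwise.

## 9. Known limitations

* No carbon assimilation, allocation, growth, or yield; LAI is prescribed.
* No soil evaporation or energy-budget closure at the land surface.
* The rhizosphere geometry factor and the 50/50 resistance split are
  conventions, not measurements; both are exposed as configuration.
* Kriging is isotropic and non-compositional.
* The supply-function capacity caveat of §4: absolute transpiration under
  saturation is bounded below the measured E_sat by the published root curve;
  comparative results are robust to this, absolute fluxes are not.
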