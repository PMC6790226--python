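# Methods

This note documents the models, conventions and design choices of the
chamberflux pipeline: what each stage assumes, which parameters matter,
what the synthetic generators do and do not emulate, and the numerical
details a user reproducing or extending the analysis should know.

## Closure-curve fitting

Each chamber closure is a ~60-s, 1-Hz record of the wet CO₂ mole fraction.
The first `dead_band` seconds (default 20 s) are discarded while the
headspace mixes; the following `fit_window` seconds (default 40 s) are
used. The fit window is the half-open interval
[t₀+dead_band, t₀+dead_band+fit_window), which contains exactly 40 samples
at 1 Hz for a 61-sample record — matching the convention of a 20-s dead
band with 40 s of usable data.

Before fitting, the wet mole fraction is water-corrected,
C′ = C_wet/(1 − W/1000) with W in mmol mol⁻¹ (toggleable via
`co2_dilution_correction`). The saturating exponential
C′(t) = C′ₓ + (C′₀ − C′ₓ)e^(−κ(t−t₀)) is fitted by Levenberg–Marquardt-type
bounded least squares with initial values C′₀ = first window sample,
C′ₓ = last, and κ from a log-linearised two-point estimate, with
κ ∈ [10⁻⁶, 1] s⁻¹. t₀ is the first sample *after* the dead band: the
closure's earliest usable instant, so the reported slope is the least
asymptote-attenuated estimate available. When the optimiser fails, the
record is flat, or κ pins at the lower bound (an effectively linear
closure, where κ and C′ₓ are jointly unidentifiable), the fit falls back to
an ordinary linear slope and is flagged `fallback_linear`. Records with
fewer than 10 usable points or non-finite values are rejected outright.

The flux conversion NEE = (dC′/dt)·n/S uses the ideal-gas mole content
n = PV/(R·T) of the chamber system (default V = 4 L including collar
headspace — configurable because collar insertion depth varies — and
P = 76 kPa, the barometric default for ~2,400 m elevation, used when no
pressure column is present). CO₂ drawdown therefore always yields
negative NEE (uptake-negative convention throughout).

## Light response, temperature response, indices

The sigmoid light response is fitted per plot × campaign group under the
sign constraints α ≥ 0, F∞ ≤ 0 (bounded away from the F∞ = 0 singularity
by 10⁻⁹), R_d ≥ 0, with structural identities NEE(0) = R_d,
NEE(∞) = F∞ + R_d and dNEE/dPPFD|₀ = −α. Groups need ≥ 5 points on ≥ 3
distinct PPFD levels; all-dark groups return a flagged respiration-only
fit. The repeated zero-filter closure that ends each sequence stays a
separate observation and feeds a drift diagnostic (it is never averaged
into the opening closure).

The temperature response Reco = R_ref·exp[E₀(k_ref − 1/(T+46.02))] stores
k_ref as the exact quotient 1/(10+46.02) (printed 0.0178507 °C⁻¹) so
Reco(10 °C) = R_ref holds to machine precision. Fitting is direct
non-linear least squares started from the log-linear OLS solution (the
log-linear path is kept as a cross-check); R_ref > 0 and E₀ ≥ 0 are
enforced. Respiration observations are the per-fit R_d values paired with
mean campaign air temperature — 15 points per transect in the default
design — requiring ≥ 5 points spanning ≥ 3 °C.

GEE2000 is defined as NEE2000 − R_d (the light-response model's own
daytime respiration), not NEE2000 − Reco(T): the sigmoid is the only
model entering the 2000-level indices. R10 equals R_ref by construction.

Daily budgets evaluate reco(t) = Reco(T(t)), gee(t) = NEE(PPFD(t)) − R_d
and nee(t) = gee(t) + reco(t) on a uniform diurnal grid (default 48
steps/day; drivers must cover 24 h at ≤ 1-h steps with no gaps) and
convert mean fluxes by M_C·86400·10⁻⁶ to g C m⁻² day⁻¹. The partition
identity NEE = GEE + Reco is exact at every step and in the aggregates;
on an all-dark day GEE is identically zero and NEE equals Reco. Measured
driver series can be supplied; the default is an idealised half-sine PPFD
(sunrise 06:00, sunset 20:00) with sinusoidal air temperature, which is a
deliberate idealisation — the daily numbers are only as realistic as
these drivers.

## Stock accounting

Soil cores come in three half-open 5-cm layers [0,5), [5,10), [10,15) cm
(midpoints −2.5/−7.5/−12.5 cm for profile plots). Sample volume is
ball-backfill mass divided by a calibration density (default
0.57 g cm⁻³, a config constant). Bulk density is (fine + stone dry
mass)/volume, numerically identical in kg dm⁻³ and g cm⁻³. A component's
stock is dry mass × mass fraction / collar area, additive across
components and layers; soil C/N covers fine earth + stones (toggleable),
roots are accounted separately as below-ground vegetation. Transect
summaries use across-plot means with n−1 sample SDs; the topsoil share is
the [0,5)-cm fraction of the 0–15 cm stock. The chronosequence
accumulation rate divides the difference of a configurable component sum
(default soil + below-ground C) between a young and an old site by the age
gap, default 154 yr (1860 Little-Ice-Age maximum to a 2014 sampling
season). The component set is exposed rather than fixed because the rate
is sensitive to whether above-ground carbon is included (soil+BG gives
≈ 8 g C m⁻² yr⁻¹ on the default scenario; adding AG raises it by half).

## Statistical layer

One-way ANOVA uses the classical SSB/SSW decomposition; pairwise Tukey
HSD comparisons use the studentized-range distribution on the
within-group mean square with the harmonic mean of the two group sizes
(the standard unbalanced extension). Letters come from an insert-and-
absorb compact letter display: two groups share a letter iff no
significant pair separates them within a letter set. scipy's
studentized-range distribution supplies the quantiles; tests cross-check
it against a Monte-Carlo simulation and against `scipy.stats.tukey_hsd`.

OLS fits report AIC = n·ln(RSS/n) + 2(p+2) — the Gaussian form with p
slopes, an intercept and the error variance. It differs from R's `AIC()`
by the additive constant n + n·ln 2π, which cancels in every comparison,
so backward deletion is unaffected. Backward deletion removes the
predictor whose removal lowers AIC most, ties broken by predictor name,
stopping when no removal lowers AIC (no re-entry of dropped predictors);
the result never has higher AIC than the full model. VIFⱼ = 1/(1−R²ⱼ)
with perfect collinearity reported as ∞ rather than raised. The LMG
relative-importance decomposition is computed through the subset-weighted
form (2^p submodel R² values) which equals the average over all p!
orderings exactly; p > 10 is refused. Mixed-effects models are not
re-implemented; `export_mixed_model_design` writes the long-format design
for external fitting.

## Synthetic generators

The scenario emulates the study design: 3 transects × 5 plots × 3
campaigns, each plot measured through the shading sequence
0,1,2,3,4,5,6,7,9,11 filters and a repeated zero — 11 closures, with
filter transmission geometric (PPFD_in = PPFD_out·τᵏ, default τ = 0.7 per
filter; both sensors are written out so no transmission assumption leaks
into fitting). Per closure the generator evaluates the plot's true
sigmoid at the transmitted PPFD — with R_d tied to the plot's temperature
response at the campaign temperature, so the two models are mutually
consistent — inverts the flux through the chamber mass balance to a
concentration slope, and bends it into an exponential closure whose time
origin sits at the start of the fit window (hence the pipeline's
initial-slope estimate equals the true flux exactly when noise is zero).
Water vapour is constant within a closure, so the dilution correction
inverts exactly.

Default parameter magnitudes are centred on values typical of an alpine
forefield gradient: a sparsely vegetated young site (F∞ ≈ −2…−5,
R10 ≈ 0.9), a productive intermediate grassland (F∞ ≈ −11…−12,
R10 ≈ 3.6) and a dwarf-shrub old site (F∞ ≈ −10, R10 ≈ 3.5); soil C
stocks of 40/557/384 g m⁻² with topsoil shares of 70/45/61 % and bulk
density increasing with depth. Noise levels: closure sample noise
σ_c = 0.3 µmol mol⁻¹, flux noise σ_f = 0.5 µmol m⁻² s⁻¹, assay CV 10 %,
between-plot lognormal CV 15 %. The closure curvature is drawn from
κ ∈ [0.005, 0.02] s⁻¹, the regime where a 60-s closure shows visible
bending; below that the curve is indistinguishable from a line within a
40-s window and κ is not meaningfully estimable (the flux still is — the
linear fallback covers that regime in real data).

What the generators do *not* emulate: within-closure driver drift,
chamber leaks or pressure transients, spatial autocorrelation between
plots, weather beyond the sinusoidal diurnal cycle, and any soil-forming
process (layer properties are drawn, not evolved). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every field artefact.

## Recovery studies and problem sizes

The standing verification studies use: 1,000 synthetic closures for the
curvature/flux recovery (median κ error ≈ 4 %, flux bias ≈ 0.01 %), 500
replicates of the 11-closure filter design at σ_f = 0.5 for the
light-response triple (median errors 3–8 %), and 500 replicates of a
15-point, 5–17 °C respiration series for (R_ref, E₀) (3 and 7 %). These
sizes give stable medians while keeping the full suite fast; they are the
same computations `scripts/acceptance.py` reports.

## Known limitations

- The chamber mass balance assumes ideal gas, a known constant system
  volume and no venting; collar insertion depth must be folded into the
  configured volume.
- κ is reported per closure but is only weakly identified for
  near-linear closures; treat it as a diagnostic, not a measurement.
- The daily budgets inherit the idealised drivers unless measured series
  are supplied.
- "Tukey b" style grouping is implemented as Tukey HSD with
  harmonic-mean group sizes; for strongly unbalanced designs the letters
  are approximate.
- The LMG decomposition assigns non-negative shares for ordinary designs
  but can be slow near p = 10 (2¹⁰ submodels per response).
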