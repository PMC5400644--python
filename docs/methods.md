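# Methods

This note records the models behind `ritdose`, the defaults and why they
were chosen, and what the synthetic generators do and do not emulate.

## Radionuclide data and β spectra

The built-in registry ships In-111 (electron capture, γ 171/245 keV,
T½ = 2.80 d — counting/imaging only, no β branches), Lu-177 (β⁻,
E_max 490 keV, 6.73 d), Y-90 (β⁻, 2290 keV, 2.67 d) and I-131 (β⁻,
606 keV, 8.03 d). Each β emitter carries its single dominant endpoint at
branch fraction 1.0; this is a deliberate simplification — full decay
schemes have several branches and the compiled per-decay mean energies
differ at the few-percent level — and user registries (YAML mapping
name → half_life_h, daughter_z, branches) can supply multi-branch
entries. With the single-endpoint default the allowed-shape means come
out at ≈153 keV (Lu-177) and ≈952 keV (Y-90), consistent with the usual
~149/~930 keV summary values.

Spectra use the allowed shape N(E) ∝ p·W·(W₀−W)²·F(Z,W) with the
nonrelativistic Fermi function F = 2πη/(1−e^(−2πη)), η = αZ·W/p of the
daughter nucleus; `coulomb=False` switches F off for analytic tests.
The grid default is 2048 bins; spectrum construction, the analytic Δ/m
self-dose and Monte Carlo source sampling all use the same grid so that
discretization cancels in their comparisons. Sampling is inverse-CDF on
the discretized grid, seeded explicitly; there is no hidden global RNG
state anywhere in the package.

## Biodistribution kinetics

γ-counting records convert to %IA = 100·(counts/efficiency)/injected and
%IA/g = %IA/mass. An optional correction undoes physical decay between
sacrifice and counting (`count_offset_h`); by default counters are
assumed to apply it themselves. Whether curve values retain physical
decay is tracked by a `decay_corrected` flag: the package supports both
conventions, defaulting to non-corrected values (λ_eff = λ_bio + λ_phys)
because that is what raw per-sacrifice-time counting yields.

Per-organ curves are the mean ± SEM (n−1 denominator) over mice at each
time point. Clearance organs are fitted with A₀e^(−λ_eff t); tumor and
spleen, which accumulate antibody over the first days, use a hybrid
model: a polynomial (degree 2 by default, 1–3 allowed) on [0, t_peak]
constrained to meet a mono-exponential tail continuously at t_peak,
where t_peak is the earliest time of the maximum observed value.
Monotone-decreasing data degenerate gracefully to the mono-exponential.
Predictions are clipped at zero so integrals never go negative.

Fits are nonlinear least squares on the original scale (never
log-linearized) with λ bounded positive. The default objective weights
residuals by 1/y (a proportional-error model): γ-counting noise is
multiplicative at the ~10% level while organ activities span two orders
of magnitude, so unweighted least squares lets the first time point
dominate and loses most of the information in the tail — in simulation
it misses the 10%-accuracy mark on fast-clearing organs a quarter of the
time, while the weighted fit essentially always recovers the rate.
`weighting="none"` restores the unweighted objective.

Cumulated activity Ã integrates the fitted curve by adaptive quadrature
(QUADPACK via `scipy.integrate.quad`, relative tolerance 1e-8 or better)
up to the last observed time, then adds the exponential tail
A(t_last)/λ_eff in closed form. Default bounds are [0, ∞). Because the
first sacrifice is at 4 h, the unobserved early uptake of clearance
organs can be handled two ways (both exposed): extrapolating the fitted
exponential back to t = 0 (default for the closed-form contract), or the
flat-back convention A(t < 4 h) := A(4 h) used by the pipeline. Hybrid
organs model the uptake phase explicitly, so no flat-back is applied to
them. Ã is stored in "fraction-seconds" (Bq·s per Bq injected).

Surrogate-nuclide extrapolation removes the source nuclide's physical
decay from λ_eff (λ_bio = λ_eff − λ_phys when the fit is on
non-corrected data) and installs the target's. For hybrid fits the whole
biological curve is transferred pointwise:
A_target(t) = A_fit(t)·e^((λ_phys,src − λ_phys,tgt)·t). The result is
always expressed in the non-corrected convention of the target nuclide,
because dose integration needs physical activity. A fitted λ_eff below
λ_phys of the source implies negative biological clearance (possible
under noise for retaining organs); λ_bio is then clamped to zero with a
logged warning.

## Phantom and Monte Carlo S-values

The phantom is parametric: named sphere/box organs inside a background
box (the trunk, "rest of body"). Materials are restricted to the
three-density table {soft tissue 1.04, lung 0.296, bone 1.4 g/cm³}.
Named organs must be mutually disjoint and inside the background (checked
exactly for sphere/sphere, sphere/box and box/box); region lookup
priority is listing order, and the background mass is its volume minus
the organs carved out of it, times density. The default mouse phantom
holds the study organs at typical masses for a ~25 g animal (tumor
0.30 g, spleen 0.10 g, kidneys 0.30 g, liver 1.30 g, heart 0.15 g, lungs
0.15 g at lung density, brain 0.40 g, trunk ≈22 g).

Transport is deliberately reduced to the physics that sets organ-scale
dose partitioning: electrons travel in straight lines and deposit energy
uniformly per unit mass path length (geometric length × local density)
until their CSDA range is exhausted. The range–energy relation is a
water electron CSDA table (10 keV–3 MeV, log-log interpolated), scaled
by 1/density per region. Particles below a 20 keV production threshold
(range < 0.01 mm in soft tissue) deposit at the emission point. Ignored
by construction: multiple scattering (real tracks are shorter-reaching
than straight CSDA paths), δ-ray transport, and bremsstrahlung (a few
percent of the ⁹⁰Y energy budget escapes as photons in reality). A
dose-point-kernel integrator can replace the engine behind the same
`svalue_matrix` interface if higher fidelity is needed.

Uncertainty uses the batch method: 10 independent seed sub-streams
(spawned from one `SeedSequence`, so every run is bit-reproducible from
its seed); the quoted relative uncertainty is the standard error of the
batch means and scales as 1/√n. The default 10⁶ particles gives ≲0.1%
self-dose statistics on the default phantom — runs take seconds, not the
hours a condensed-history code needs, which is the point of the
simplification. Two limits anchor validation: S·m → Δ (mean emitted
energy per decay) for a region much larger than the β range, and exact
per-particle energy conservation (deposited ≤ sampled, with equality
when the phantom encloses every track).

## MIRD dose assembly

D(target) = Σ_sources Ã(source)·S(source→target), evaluated for a stated
injected activity (3.7 MBq default). Tumor-to-organ ratios are computed
from unrounded doses and displayed at two decimals; a zero organ dose
yields an undefined marker, never infinity. Dose uncertainty for a
product is propagated as relative errors in quadrature — a choice, since
published dose tables rarely state their error model. Blood appears in
biodistribution data but has no phantom region; the pipeline folds its
cumulated activity into the rest-of-body source (configurable), which
slightly overweights the trunk as a source rather than dropping the
blood pool entirely.

## Binding assays

The Lindmo estimate is unweighted OLS of T/B on 1/(cells per tube), with
IRF = 1/intercept and a delta-method 95% CI
(Var(1/b) ≈ Var(b)/b⁴). A weighted variant (1/x weights; low-cell-count
tubes are noisiest) is available behind a flag. Estimates above 1 are
reported with a nonphysical flag, never clamped, and a nonpositive
intercept raises rather than returning a meaningless negative fraction.
Because the titration runs at a single tracer concentration, the
infinite-antigen-excess extrapolation is approximate; no correction is
attempted. Competition curves normalize to the mean zero-competitor
binding; monotonicity is diagnosed, not enforced, and the 4-parameter
logistic IC50 fit is diagnostic only.

## Efficacy statistics

Caliper volume uses the standard xenograft ellipsoid approximation
V = L·W²/2 (swapped axes are corrected with a warning). Each animal is
summarized by the trapezoidal AUC of its volume curve from the first
measurement day, with no extrapolation past the last measurement and an
optional baseline-volume subtraction. Groups are compared by one-way
ANOVA at α = 0.05 (two groups reduce exactly to the pooled-variance
t-test, F = t²); all-identical data produce a degenerate exact-equality
report instead of a test. No multiple-testing correction is applied — a
single planned comparison.

## Synthetic generators

All generators are pure functions of (parameters, seed).

* **Biodistribution** — 5 sacrifice times (4, 24, 72, 120, 168 h), 3
  mice per time, 9 tissues, injected activity Normal(3.5, 0.4) MBq
  truncated positive. Organ truth is A₀e^(−λ_bio t), with an
  (1−e^(−k·t)) uptake factor for tumor (peak near 72 h on the
  biology-only curve) and spleen (plateau). Defaults are calibrated so
  the noise-free pipeline shows the qualitative pattern of an
  antibody study — slow blood pool clearance, tumor/blood > 1 by 72 h,
  spleen retention, negligible brain uptake — and so whole-body %IA
  never exceeds 100. Noise: lognormal CV 10% on organ masses and kinetic
  amplitudes, Poisson counting at ~10⁴–10⁶ expected counts
  (efficiency 2×10⁶ cpm/MBq). Not emulated: inter-compartment mass
  balance (organs fluctuate independently), imaging-based
  quantification, and dissection/weighing artifacts — so passing
  recovery tests demonstrate estimator correctness under the stated
  noise model, not robustness to systematic experimental error.
* **Lindmo** — four cell counts (1, 2, 5, 10 ×10⁶), expected bound
  fraction IRF·c/(c+c₅₀) with c₅₀ = 2×10⁶ cells, Poisson totals
  (5×10³ default) split binomially into bound and supernatant. True IRF
  defaults to 0.83; at the default counting statistics the estimator
  spread (SD ≈ 0.02) sits well inside the ±0.08 window a 4-replicate
  experimental estimate reports.
* **Growth** — three arms (cold antibody, non-specific RIT, specific
  RIT), 6 mice each, twice-weekly calipers from day 9 (treatment day) to
  day 26, exponential volumes from 100 mm³ at 0.08/day with lognormal
  CV 25% between mice; treatment multiplies the post-treatment rate
  (0.85 non-specific, 0.50 specific by default). Tumor regressions,
  measurement error and dropout are not modelled.

Noise-free limits invert exactly through the matching analysis
operations; these round trips are tested for every stage.

## Numerical choices and degenerate inputs

* Quadrature: `epsrel = 1e-10`, with the hybrid junction passed as an
  interior break point.
* Mono-exponential seeds come from a log-linear regression of the
  positive values; data whose log-linear slope is nonnegative raise a
  fit failure pointing at the hybrid model.
* A hybrid peak at the last time point cannot anchor a tail and raises,
  advising the mono-exponential; a two-point tail is solved exactly.
* Ties for the peak resolve to the earliest time.
* MC regions with zero volume, phantoms without regions, unknown
  materials, and overlapping named organs are validation errors.
* Seeds: every stochastic entry point takes one explicit seed;
  sub-streams are spawned via `numpy.random.SeedSequence`.

## Problem sizes

Default analyses use 10⁵–10⁶ Monte Carlo particles per source (batch
uncertainty ≲0.1–0.3% for self-dose), 500 replicate studies for
parameter-recovery simulations and 1000 for ANOVA calibration. These
sizes put every quoted statistical property at least ~3σ away from its
acceptance boundary while keeping a full run in seconds on one CPU.
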