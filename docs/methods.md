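# Methods

## Scope and model

`bsrkit` treats a continuously fed sulfate-reducing bioreactor at steady
state as a combination of three idealisations:

1. **Reaction thermodynamics.** Catabolism is described by a small registry
   of net reactions over anionic species (acetate⁻, propionate⁻, lactate⁻,
   citrate³⁻, HCO₃⁻, SO₄²⁻, HS⁻, H₂O, H⁺, H₂). ΔG°′ of a reaction is the
   coefficient-weighted sum of standard transformed formation energies at
   pH 7 and 25 °C in the Thauer convention (the proton's value, −39.87
   kJ/mol, carries the pH-7 correction; dissolved H₂ is the zero
   reference). No activity, ionic-strength, temperature or pH corrections
   are applied, and no H₂S/HS⁻ speciation: the numbers are standard-state
   references, not in-situ driving forces.

2. **Hydrodynamics and kinetics.** Packed-bed columns are ideal plug-flow
   reactors: a parcel's sulfate concentration evolves with cumulative
   residence time τ = V/F under the empirical rate law r = k·Cⁿ. Stirred
   tanks are ideal CSTRs with the steady-state balance k·Cⁿ = D·(C₀ − C),
   D = 1/HRT. The order n lumps everything the rate law does not resolve —
   biomass gradients, donor switching, transport — into a single
   concentration sensitivity; k has units mg^(1−n)·L^(n−1)·h⁻¹, so values
   at different n are not directly comparable. Axial dispersion, biofilm
   diffusion, Monod/inhibition kinetics and sulfide toxicity are out of
   scope.

3. **Route accounting.** Observed steady-state deltas are explained as
   non-negative molar extents of the registry routes. Extents are expressed
   per mole of the route's organic substrate (per lactate for incomplete
   oxidation and fermentation, per propionate, per acetate; per sulfate for
   H₂). The partitioning rule is: in an acetate-fed reactor all sulfate
   reduction is acetate-coupled; in a lactate-fed reactor net propionate
   *production* fixes the fermentation extent (3 lactate → 2 propionate),
   net *consumption* fixes the propionate-oxidation extent (0.75 sulfate
   each), and the remaining sulfate is assigned to incomplete lactate
   oxidation (0.5 sulfate per lactate), optionally spilling to acetate
   oxidation when a finite lactate supply is declared. Propionate turnover
   in a single well-mixed volume cannot distinguish simultaneous production
   and consumption; the net-sign rule is a stated modelling decision.
   Every partition satisfies Σ extentᵢ·|sulfate coefficientᵢ| = Δsulfate
   exactly. The H₂ route is representable (for scenario studies of
   syntrophic hydrogen transfer) but never inferred from measurements,
   since no measured species constrains it.

## The reaction registry

The bundled table stores the six standard equations both **as printed** in
the literature and in **canonical balanced form**; computation always uses
the canonical forms, and the balance audit is the place where discrepancies
surface rather than being silently repaired. Two known data issues are kept
deliberately visible:

* The printed incomplete-lactate-oxidation equation omits 0.5 H⁺ on the
  product side; `validate_balance` reports H and charge residuals of −0.5,
  and ΔG°′ is refused for it. The canonical form adds the half proton.
* The printed ΔG°′ values for complete lactate oxidation (−225.3) and
  lactate fermentation (−70.0) disagree with both direct formation-energy
  computation and Hess combination of the other equations (≈ −255.4 and
  ≈ −165 kJ respectively, the former consistent with a digit
  transposition). They are stored as `dG_printed` data and excluded from
  any computed result; the suite instead asserts the exact Hess identity
  ΔG(complete) = 2·ΔG(incomplete) + 2·ΔG(acetate-coupled).

Coefficients are exact `fractions.Fraction` values, so 0.75/0.5/0.25
couplings carry no float drift and balance residuals of well-formed
reactions are exactly zero (tolerance 1e−9 is applied only as a guard).
Molar masses are anion masses from standard atomic weights (sulfate 96.06,
acetate 59.04, lactate 89.07, propionate 73.07, HCO₃⁻ 61.02, HS⁻ 33.07
g/mol), checked against each species' formula to 0.05 g/mol at load. Feed
salts are converted to anion concentrations at load time (0.92 g/L sodium
acetate → 662 mg/L acetate⁻; 1.2 g/L sodium lactate → 954 mg/L lactate⁻).
Sulfide mass is reported on an explicit basis — `as_S` (32.06 mg/mmol,
the default, matching colorimetric assays), `as_HS` (33.07) or `as_H2S`
(34.08).

## Plug-flow evaluation and fitting

The closed-form effluent is evaluated in a log1p form that is smooth
through n = 1 at machine precision:

    ln C = ln C₀ − k·τ·C₀^(n−1)·φ(g),   g = (n−1)·k·τ·C₀^(n−1),
    φ(g) = log1p(g)/g  (series 1 − g/2 for |g| < 1e−8),

with C = 0 once g ≤ −1 (substrate exhaustion, reachable for n < 1). This
avoids the catastrophic cancellation of forming C₀^(1−n) − (1−n)kτ near
n = 1 and is verified against an independent fixed-step RK4 integration of
dC/dτ = −k·Cⁿ to 1e−6 relative across n ∈ {0.5, 1, 1.5, 2, 2.9, 3.5}.

`fit_order_and_rate` minimises Σ(C_obs − C_model(τᵢ))² over all
zone-boundary and effluent observations of one reactor across its HRT
series, in the parameters (n, log₁₀ k) with bounds n ∈ [0.1, 5],
log₁₀ k ∈ [−12, 3]. The default objective is in **concentration space**:
the measurements are concentrations, and rates are derived quantities; a
rate-space objective (`objective="rate"`) is available for comparison, and
all observations and HRTs are weighted equally. The optimiser is SciPy's
bounded trust-region least squares restarted from a fixed grid of trial
orders (0.5 … 4.0 in steps of 0.5), each paired with a closed-form rate
constant guess from the median observation — the objective is smooth and
two-dimensional, so this deterministic multi-start reliably finds the
global minimum (extra log-spaced k starts are available via
`extra_k_starts`). SSE ties within 1e−9 that disagree in (n, k) are
resolved toward the smaller order and flagged. Observations exceeding the
feed concentration (assay noise) are retained in the objective and listed
in `clipped_observations` rather than dropped. Fitting requires ≥ 3
observations spanning ≥ 2 distinct residence times; anything less is
refused as underdetermined.

## Synthetic data generator

The generator emulates the structure of a zone-resolved HRT study: a 1 L
column sampled at cumulative volumes 0.33/0.66/1.0 L, feed sulfate
1000 mg/L, HRTs of 4, 3, 2.66, 2.33, 2, 1.5, 1.3 and 1.0 days (96 … 24 h),
and 5 % relative measurement noise — multiplicative Gaussian truncated at
zero, reflecting the roughly constant relative error of the sulfate and
VFA assays (an additive model is available). Companion metabolite columns
(VFAs, bicarbonate, sulfide) are filled by applying a declared route mix to
each sample's sulfate drop, so the stoichiometric round trip
generate → partition → predict closes exactly at zero noise. All
randomness flows from a single integer seed; noiseless output is
seed-independent, and equal seeds give byte-identical CSVs.

What it does **not** emulate: temporal approach to steady state, biomass
growth and washout dynamics, zone-to-zone donor switching (the route mix is
uniform along the column), yeast-extract/citrate side metabolism beyond a
single constant acetate credit (`ye_acetate`, default 0 — any non-zero
value must come from an independent quantification), and correlated or
heteroscedastic assay error. Passing tests on these data therefore
demonstrate the estimators' correctness and stability under the stated
noise model, not the field accuracy of the plug-flow idealisation.

## Numerical and design choices

* Fit determinism: fixed start grid, fixed optimiser tolerances
  (xtol = ftol = gtol = 1e−15); re-running a fit or any CLI subcommand on
  the same inputs reproduces outputs byte-for-byte.
* The problem sizes used throughout the suite mirror the default design
  (3 zones × 8 HRTs = 24 points per fit; 100 seeded replicates for the
  noisy-recovery check), chosen so the whole suite runs in well under a
  minute on one CPU.
* Units: mg/L and hours at every I/O boundary (HRTs may be configured in
  days); moles appear only internally. Concentrations are never negative;
  a stoichiometric prediction that goes negative is flagged as a model
  violation instead of being clipped.
* Config files are strictly validated (unknown keys rejected with their
  location); schema errors exit with code 2, model inconsistencies with 3.

## Known limitations

* One global (n, k) per reactor assumes a constant rate constant along the
  column; real columns with strong axial biomass gradients can violate
  this, and the fitted n then absorbs the gradient.
* The lactate-route partition is identifiable only because fermentation is
  tied to propionate; systems where propionate is simultaneously produced
  and consumed are reported as the net route only.
* ΔG°′ values are standard-state; no conclusion about in-situ
  favourability should be drawn without activity corrections.
* The citrate and yeast-extract catabolic routes are not modelled; their
  products surface only through the explicit `ye_acetate` credit.
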