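# bsrkit

Analysis toolkit for **biological sulfate reduction (BSR) bioreactors** —
the continuous systems in which sulfate-reducing microorganisms (SRM)
convert sulfate to sulfide at the expense of an organic electron donor
(lactate, acetate, propionate, H₂), e.g. for treating acid rock drainage.
It is written for bioprocess engineers and environmental microbiologists
who run packed-bed, stirred-tank or channel reactors across a hydraulic
retention time (HRT) series and want the reactor-side bookkeeping done
reproducibly:

* **Thermodynamics & stoichiometry** (`bsrkit.thermostoich`) — a registry of
  the common sulfidogenic and fermentative reactions with exact rational
  coefficients, an elemental/charge balance audit, and standard transformed
  Gibbs free energies ΔG°′ (pH 7, 25 °C) computed from bundled formation
  energies (Thauer convention: the proton carries the pH-7 correction,
  dissolved H₂ is the zero reference).
* **Plug-flow kinetics** (`bsrkit.kinetics`) — the nth-order ideal plug-flow
  model of sulfate removal,

      r = k·Cⁿ,   dC/dτ = −k·Cⁿ,   τ = V/F,

  with closed-form effluent concentrations
  C(τ) = C₀·e^(−kτ) for n = 1 and C(τ) = [C₀^(1−n) − (1−n)kτ]^(1/(1−n))
  otherwise; volumetric sulfate reduction rate r_A = X·F·C₀/V with
  conversion X = (C_in − C_out)/C_in; and nonlinear least-squares fitting of
  one global (n, k) per reactor to zone-resolved, multi-HRT concentration
  profiles (deterministic multi-start, bounded).
* **Stoichiometric prediction** (`bsrkit.predictions`) — partitions observed
  sulfate reduction and propionate turnover into non-negative molar extents
  over the reaction routes (acetate oxidation, propionate oxidation,
  incomplete lactate oxidation, lactate fermentation, H₂ oxidation) and
  forward-predicts effluent acetate, bicarbonate and sulfide for comparison
  with measurements.
* **Synthetic data** (`bsrkit.synthetic`) — seeded generators for
  zone-resolved plug-flow profiles across an 8-point HRT series (4 → 1 days)
  and stirred-tank (CSTR) steady states from the mass balance
  k·Cⁿ = D·(C₀ − C), with companion metabolite columns filled consistently
  with a chosen route mix — so every analysis here is testable without any
  measured dataset.
* **I/O and CLI** (`bsrkit.io`, `bsrkit.cli`) — a documented long-format
  observation CSV schema, a strict YAML run configuration, deterministic
  reports, and the `bsrkit` command with `thermo`, `simulate`,
  `fit-plugflow`, `predict` and `report` subcommands.

## Worked example

```python
import bsrkit as b

reg = b.load_registry()
dg = b.delta_g_prime(reg.reaction("eq1"), reg)
print(f"acetate + sulfate -> 2 bicarbonate + sulfide:  dG'0 = {dg:.1f} kJ/reaction")

column = b.ReactorGeometry("upbr_acetate", "plug_flow", 1.0, (0.33, 0.66, 1.0))
scenario = b.SyntheticScenario(
    geometry=column, true_n=2.9, true_k=2.2e-7,
    route_mix=b.RouteMix({"eq1": 1.0}),           # all sulfate via acetate oxidation
    feed={"sulfate": 1000.0, "acetate": 662.0},   # mg/L
    noise_rel=0.05, seed=17,
)
obs = b.simulate_plugflow_dataset(scenario)       # 3 zones × 8 HRTs
fit = b.fit_order_and_rate(obs, column)
print(f"fitted order n = {fit.n:.2f}, rate constant k = {fit.k:.2e} "
      f"(sse = {fit.sse:.1f} (mg/L)^2 over {fit.n_obs} points)")

effluent = next(o for o in obs if o.hrt == 96.0 and o.position == 1.0)
ds = (effluent.feed["sulfate"] - effluent.concentrations["sulfate"]) / 96.06
part = b.partition_routes(ds, 0.0, "acetate")
pred = b.predict_acetate(part, 662.0, 0.0, observed=effluent.concentrations["acetate"])
print(f"4-day HRT effluent: {ds:.2f} mmol/L sulfate reduced; "
      f"acetate predicted {pred.predicted:.0f} vs observed {pred.observed:.0f} mg/L "
      f"({pred.percent_diff:.1f}% difference)")
print(f"sulfide at full reduction of the feed: "
      f"{b.predict_sulfide(1000.0).predicted / 1000:.2f} g/L as S")
```

prints

```
acetate + sulfate -> 2 bicarbonate + sulfide:  dG'0 = -47.6 kJ/reaction
fitted order n = 2.89, rate constant k = 2.35e-07 (sse = 4336.9 (mg/L)^2 over 24 points)
4-day HRT effluent: 8.53 mmol/L sulfate reduced; acetate predicted 158 vs observed 167 mg/L (5.1% difference)
sulfide at full reduction of the feed: 0.33 g/L as S
```

Reading: the free energy of acetate-coupled sulfate reduction is recomputed
from formation energies, not looked up; a noisy synthetic column generated
at (n = 2.9, k = 2.2 × 10⁻⁷) is fitted back to within the assay noise; the
effluent acetate predicted purely from the observed sulfate drop (1 acetate
per sulfate) lands within ~5 % of the "measured" value; and complete
reduction of a 1000 mg/L sulfate feed corresponds to 0.33 g/L of sulfide
reported as S.

The same pipeline runs from the shell:

```sh
bsrkit simulate --config reactor.yaml --true-n 2.9 --true-k 2.2e-7 --out obs.csv
bsrkit fit-plugflow --input obs.csv --config reactor.yaml --out fit.json
bsrkit predict --input obs.csv --config reactor.yaml --out pred.csv
```

## Layout

```
src/bsrkit/            thermostoich, kinetics, predictions, synthetic, io, cli
src/bsrkit/data/       species/reaction registry (YAML, user-extensible)
tests/                 pytest suite (unit, property and end-to-end tests)
docs/methods.md        model assumptions, parameter choices, limitations
```
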