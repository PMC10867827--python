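"""Synthetic reactor datasets with the structure the analysis assumes.

Two generators:

* :func:`simulate_plugflow_dataset` — zone-resolved sulfate profiles across
  an HRT series for a packed-bed (plug-flow) column, produced by the
  nth-order plug-flow law plus multiplicative measurement noise, with
  companion VFA / bicarbonate / sulfide columns filled consistently with a
  chosen reaction-route mix.
* :func:`simulate_cstr_series` — stirred-tank steady states per HRT from the
  CSTR mass balance k·Cⁿ = D·(C0 − C), with the same route accounting.

Defaults mirror the study design these data stand in for: 1 L columns
sampled at cumulative volumes 0.33 / 0.66 / 1.0 L, feed sulfate 1000 mg/L,
HRTs of 4, 3, 2.66, 2.33, 2, 1.5, 1.3 and 1 days, and 5 % relative assay
noise. All randomness flows from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import ReactorGeometry, SteadyStateObservation, cstr_effluent, plugflow_effluent
from .predictions import ROUTE_BASIS, ROUTE_IDS, RoutePartition, predict_species_delta
from .thermostoich import Registry, load_registry

__all__ = [
    "DEFAULT_HRT_SERIES_H",
    "RouteMix",
    "SyntheticScenario",
    "simulate_plugflow_dataset",
    "simulate_cstr_series",
]

#: Applied HRT series, hours (4, 3, 2.66, 2.33, 2, 1.5, 1.3, 1 days).
DEFAULT_HRT_SERIES_H = (96.0, 72.0, 63.8, 55.9, 48.0, 36.0, 31.2, 24.0)

#: Species given companion columns in generated datasets.
TRACKED_SPECIES = ("sulfate", "sulfide", "lactate", "acetate", "propionate", "bicarbonate")


@dataclass(frozen=True)
class RouteMix:
    """How reduced sulfate (and co-occurring fermentation) is apportioned.

    ``sulfate_fractions`` splits each mmol of sulfate reduced among the
    sulfate-consuming routes eq1/eq2/eq3/eq6 (must sum to 1);
    ``fermented_lactate_per_sulfate`` sets the eq5 extent (mmol lactate
    fermented) per mmol sulfate reduced — fermentation has no sulfate
    coupling of its own, so it rides along at a fixed ratio.
    """

    sulfate_fractions: dict[str, float]
    fermented_lactate_per_sulfate: float = 0.0

    def __post_init__(self) -> None:
        allowed = {"eq1", "eq2", "eq3", "eq6"}
        unknown = set(self.sulfate_fractions) - allowed
        if unknown:
            raise ValueError(f"unknown sulfate routes {sorted(unknown)}")
        fr = {k: float(v) for k, v in self.sulfate_fractions.items()}
        if any(v < 0 for v in fr.values()) or self.fermented_lactate_per_sulfate < 0:
            raise ValueError("route fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("sulfate_fractions must sum to 1")
        object.__setattr__(self, "sulfate_fractions", fr)

    def partition(self, delta_sulfate_mmol: float, registry: Registry | None = None) -> RoutePartition:
        """Route extents implied by ``delta_sulfate_mmol`` of sulfate reduced."""
        registry = registry or load_registry()
        extents = dict.fromkeys(ROUTE_IDS, 0.0)
        for rid, frac in self.sulfate_fractions.items():
            rxn = registry.reaction(rid).normalized(ROUTE_BASIS[rid])
            s_per_unit = abs(float(rxn.coefficient("sulfate")))
            extents[rid] = frac * delta_sulfate_mmol / s_per_unit
        extents["eq5"] = self.fermented_lactate_per_sulfate * delta_sulfate_mmol
        return RoutePartition(extents)


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete description of a simulated reactor experiment."""

    geometry: ReactorGeometry
    true_n: float
    true_k: float
    route_mix: RouteMix
    feed: dict[str, float] = field(default_factory=lambda: {"sulfate": 1000.0})
    hrt_series: tuple[float, ...] = DEFAULT_HRT_SERIES_H
    ye_acetate: float = 0.0
    noise_rel: float = 0.05
    noise_model: str = "multiplicative"  # or "additive" (noise_rel × feed as s.d.)
    sulfide_basis: str = "as_S"  # reporting basis of the generated sulfide column
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")
        if self.noise_model not in ("multiplicative", "additive"):
            raise ValueError("noise_model must be 'multiplicative' or 'additive'")
        if self.sulfide_basis not in ("as_S", "as_HS", "as_H2S"):
            raise ValueError("sulfide_basis must be as_S, as_HS or as_H2S")
        if self.true_k < 0 or self.true_n < 0:
            raise ValueError("true_k and true_n must be >= 0")
        if "sulfate" not in self.feed or self.feed["sulfate"] <= 0:
            raise ValueError("feed must contain positive sulfate")


def _apply_noise(
    value: float, feed_value: float, scenario: SyntheticScenario, rng: np.random.Generator
) -> float:
    if scenario.noise_rel == 0:
        return value
    z = rng.standard_normal()
    if scenario.noise_model == "multiplicative":
        return value * max(0.0, 1.0 + scenario.noise_rel * z)
    return max(0.0, value + scenario.noise_rel * feed_value * z)


def _companion_concentrations(
    scenario: SyntheticScenario, sulfate_true: float, registry: Registry
) -> dict[str, float]:
    """Noise-free concentrations of all tracked species at one sample point.

    The sulfide column is reported on the scenario's mass basis (default
    "as S", matching sulfide assays); all other species use anion masses.
    """
    from .predictions import SULFIDE_BASIS_MASS

    mw = {s: registry.species_or_raise(s).molar_mass for s in TRACKED_SPECIES}
    mw["sulfide"] = SULFIDE_BASIS_MASS[scenario.sulfide_basis]
    feed = {s: scenario.feed.get(s, 0.0) for s in TRACKED_SPECIES}
    delta_s_mmol = (feed["sulfate"] - sulfate_true) / mw["sulfate"]
    part = scenario.route_mix.partition(delta_s_mmol, registry)
    conc = {"sulfate": sulfate_true}
    for sp in TRACKED_SPECIES:
        if sp == "sulfate":
            continue
        delta_mmol, _ = predict_species_delta(part, sp, registry)
        c = feed[sp] + delta_mmol * mw[sp]
        if sp == "acetate":
            c += scenario.ye_acetate
        conc[sp] = max(c, 0.0)
    return conc


def simulate_plugflow_dataset(
    scenario: SyntheticScenario, registry: Registry | None = None
) -> list[SteadyStateObservation]:
    """Zone-resolved steady states of a plug-flow column across the HRT series.

    For each HRT and each zone boundary, sulfate follows the closed-form
    nth-order plug-flow profile at the boundary's cumulative residence time;
    companion species are filled from the route mix applied to the zone's
    sulfate drop, then measurement noise is applied per concentration.
    Deterministic given the seed; exactly the model curve when noise_rel = 0.
    """
    if scenario.geometry.kind == "cstr":
        raise ValueError("plug-flow simulation requires a plug_flow or channel geometry")
    registry = registry or load_registry()
    rng = np.random.default_rng(scenario.seed)
    c0 = scenario.feed["sulfate"]
    out: list[SteadyStateObservation] = []
    for hrt in scenario.hrt_series:
        flow = scenario.geometry.total_volume / hrt
        for boundary in scenario.geometry.zone_boundaries:
            tau = boundary / flow
            sulfate_true = plugflow_effluent(c0, scenario.true_n, scenario.true_k, tau)
            conc_true = _companion_concentrations(scenario, sulfate_true, registry)
            conc = {
                sp: _apply_noise(c, scenario.feed.get(sp, c0), scenario, rng)
                for sp, c in conc_true.items()
            }
            out.append(
                SteadyStateObservation(
                    reactor_id=scenario.geometry.reactor_id,
                    hrt=hrt,
                    flow_rate=flow,
                    position=boundary,
                    concentrations=conc,
                    feed=dict(scenario.feed),
                )
            )
    return out


def simulate_cstr_series(
    scenario: SyntheticScenario,
    registry: Registry | None = None,
    conversion_curve=None,
) -> list[SteadyStateObservation]:
    """One stirred-tank effluent observation per HRT.

    Sulfate conversion comes either from the (n, k) CSTR mass balance
    k·Cⁿ = D·(C0 − C) or, if ``conversion_curve`` (a callable HRT h → X) is
    given, from that curve. Companion species follow the route mix exactly
    as in the plug-flow generator.
    """
    if scenario.geometry.kind != "cstr":
        raise ValueError("CSTR simulation requires a cstr geometry")
    registry = registry or load_registry()
    rng = np.random.default_rng(scenario.seed)
    c0 = scenario.feed["sulfate"]
    out: list[SteadyStateObservation] = []
    for hrt in scenario.hrt_series:
        flow = scenario.geometry.total_volume / hrt
        if conversion_curve is not None:
            x = float(conversion_curve(hrt))
            if not 0 <= x <= 1:
                raise ValueError(f"conversion curve returned {x} outside [0, 1]")
            sulfate_true = c0 * (1.0 - x)
        else:
            sulfate_true = cstr_effluent(c0, scenario.true_n, scenario.true_k, hrt)
        conc_true = _companion_concentrations(scenario, sulfate_true, registry)
        conc = {
            sp: _apply_noise(c, scenario.feed.get(sp, c0), scenario, rng)
            for sp, c in conc_true.items()
        }
        out.append(
            SteadyStateObservation(
                reactor_id=scenario.geometry.reactor_id,
                hrt=hrt,
                flow_rate=flow,
                position=scenario.geometry.total_volume,
                concentrations=conc,
                feed=dict(scenario.feed),
            )
        )
    return out
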