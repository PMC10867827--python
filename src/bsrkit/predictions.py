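"""Route partitioning of sulfate reduction and stoichiometric forward prediction.

Observed sulfate and propionate turnover is reconciled into non-negative
molar extents over the catabolic routes of the registry:

* ``eq1`` — complete acetate oxidation (1 sulfate per acetate)
* ``eq2`` — propionate oxidation to acetate (0.75 sulfate per propionate)
* ``eq3`` — incomplete lactate oxidation to acetate (0.5 sulfate per lactate)
* ``eq5`` — fermentative lactate disproportionation (no sulfate)
* ``eq6`` — hydrogenotrophic sulfate reduction (scenario-only; never inferred)

Extents are expressed per mole of the route's organic substrate (per lactate
for eq3/eq5, per propionate for eq2, per acetate for eq1, per sulfate for
eq6), in mmol per litre of throughput. Effluent acetate, bicarbonate and
sulfide then follow linearly from the canonical stoichiometry, which is what
lets a measured profile be compared with an independent prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .thermostoich import Registry, load_registry

__all__ = [
    "ROUTE_IDS",
    "ROUTE_BASIS",
    "SULFIDE_BASIS_MASS",
    "RoutePartition",
    "PredictionResult",
    "partition_routes",
    "predict_species_delta",
    "predict_acetate",
    "predict_bicarbonate",
    "predict_sulfide",
    "percent_difference",
    "lactate_utilization_ratio",
]

ROUTE_IDS = ("eq1", "eq2", "eq3", "eq5", "eq6")

#: Species each route's extent is normalised to (|coefficient| 1).
ROUTE_BASIS = {
    "eq1": "acetate",
    "eq2": "propionate",
    "eq3": "lactate",
    "eq5": "lactate",
    "eq6": "sulfate",
}

#: Mass per mmol of sulfide at each reporting basis, mg/mmol.
SULFIDE_BASIS_MASS = {"as_S": 32.06, "as_HS": 33.07, "as_H2S": 34.08}

#: Sulfate-conservation tolerance for partitions, mmol/L.
PARTITION_TOL = 1e-9


class RouteInconsistencyError(ValueError):
    """Observed deltas cannot be reconciled into non-negative route extents."""


@dataclass(frozen=True)
class RoutePartition:
    """Non-negative molar extents (mmol per L of throughput) per route."""

    extents: dict[str, float]
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ext = {rid: float(self.extents.get(rid, 0.0)) for rid in ROUTE_IDS}
        unknown = set(self.extents) - set(ROUTE_IDS)
        if unknown:
            raise ValueError(f"unknown routes {sorted(unknown)}; allowed: {ROUTE_IDS}")
        if any(v < 0 for v in ext.values()):
            raise ValueError("route extents must be non-negative")
        object.__setattr__(self, "extents", ext)

    def sulfate_consumed(self, registry: Registry | None = None) -> float:
        """Σ extent × |sulfate coefficient per basis unit|, mmol/L."""
        registry = registry or load_registry()
        total = 0.0
        for rid, ext in self.extents.items():
            rxn = registry.reaction(rid).normalized(ROUTE_BASIS[rid])
            total += ext * abs(float(rxn.coefficient("sulfate")))
        return total

    def scaled(self, factor: float) -> "RoutePartition":
        return RoutePartition({rid: v * factor for rid, v in self.extents.items()})


@dataclass(frozen=True)
class PredictionResult:
    """A stoichiometric prediction for one species, mg/L, with provenance."""

    species: str
    predicted: float
    observed: float | None = None
    percent_diff: float | None = None
    components: dict[str, float] = field(default_factory=dict)  # per-route mg/L
    basis: str | None = None
    model_violation: bool = False


def partition_routes(
    delta_sulfate: float,
    delta_propionate: float,
    donor_regime: str,
    *,
    lactate_supply: float | None = None,
    registry: Registry | None = None,
    tol: float = PARTITION_TOL,
) -> RoutePartition:
    """Assign observed sulfate reduction to reaction routes.

    Parameters
    ----------
    delta_sulfate:
        Sulfate reduced, mmol/L (feed − effluent, ≥ 0).
    delta_propionate:
        Net propionate change, mmol/L; positive = produced (fermentation,
        eq5), negative = consumed (propionate oxidation, eq2).
    donor_regime:
        ``"acetate"`` — all sulfate reduction assigned to eq1.
        ``"lactate"`` — fermentation inferred from produced propionate
        (eq5, 3 lactate per 2 propionate) or propionate oxidation from
        consumed propionate (eq2); the remaining sulfate is assigned to
        incomplete lactate oxidation (eq3, 0.5 sulfate per lactate).
    lactate_supply:
        Optional lactate available (mmol/L). If eq3's lactate demand exceeds
        it, the overflow sulfate spills to acetate oxidation (eq1).

    The returned extents always satisfy sulfate conservation:
    Σ extent × |sulfate coefficient| = ``delta_sulfate``.
    """
    if donor_regime not in ("acetate", "lactate"):
        raise ValueError("donor_regime must be 'acetate' or 'lactate'")
    if delta_sulfate < -tol:
        raise RouteInconsistencyError("delta_sulfate must be >= 0 (feed minus effluent)")
    delta_sulfate = max(delta_sulfate, 0.0)
    notes: dict[str, str] = {}
    if donor_regime == "acetate":
        return RoutePartition(
            {"eq1": delta_sulfate}, notes={"eq1": "all sulfate assigned to acetate oxidation"}
        )

    extents = dict.fromkeys(ROUTE_IDS, 0.0)
    sulfate_left = delta_sulfate
    if delta_propionate > 0:
        extents["eq5"] = 1.5 * delta_propionate  # 3 lactate -> 2 propionate
        notes["eq5"] = "fermentation inferred from net propionate production"
    elif delta_propionate < 0:
        consumed = -delta_propionate
        extents["eq2"] = consumed
        sulfate_eq2 = 0.75 * consumed
        if sulfate_eq2 > sulfate_left + tol:
            raise RouteInconsistencyError(
                f"propionate oxidation alone needs {sulfate_eq2:g} mmol/L sulfate "
                f"but only {sulfate_left:g} was reduced"
            )
        sulfate_left = max(sulfate_left - sulfate_eq2, 0.0)
        notes["eq2"] = "propionate oxidation inferred from net propionate consumption"

    eq3_lactate = 2.0 * sulfate_left  # 0.5 sulfate per lactate
    if lactate_supply is not None and eq3_lactate > lactate_supply:
        taken = max(lactate_supply, 0.0)
        extents["eq3"] = taken
        overflow_sulfate = sulfate_left - 0.5 * taken
        extents["eq1"] = overflow_sulfate
        notes["eq1"] = "lactate supply exhausted; residual sulfate spilled to acetate oxidation"
    else:
        extents["eq3"] = eq3_lactate
    notes.setdefault("eq3", "sulfate-linked incomplete lactate oxidation")

    part = RoutePartition(extents, notes=notes)
    assigned = part.sulfate_consumed(registry)
    if abs(assigned - delta_sulfate) > max(tol, 1e-12 * max(delta_sulfate, 1.0)):
        raise RouteInconsistencyError(
            f"assigned sulfate {assigned:g} mmol/L != observed {delta_sulfate:g} mmol/L"
        )
    return part


def predict_species_delta(
    partition: RoutePartition, species: str, registry: Registry | None = None
) -> tuple[float, dict[str, float]]:
    """Net production of ``species`` implied by a partition, mmol/L.

    Returns the total and the per-route breakdown (signed; consumption is
    negative). Linear in the extents.
    """
    registry = registry or load_registry()
    components: dict[str, float] = {}
    for rid, ext in partition.extents.items():
        if ext == 0:
            continue
        rxn = registry.reaction(rid).normalized(ROUTE_BASIS[rid])
        coeff = float(rxn.coefficient(species))
        if coeff:
            components[rid] = ext * coeff
    return sum(components.values()), components


def _finalize(
    species: str,
    predicted: float,
    observed: float | None,
    components_mg: dict[str, float],
    basis: str | None = None,
) -> PredictionResult:
    violation = predicted < 0
    pct = None
    if observed is not None and observed > 0:
        pct = percent_difference(observed, predicted)
    return PredictionResult(
        species=species,
        predicted=predicted,
        observed=observed,
        percent_diff=pct,
        components=components_mg,
        basis=basis,
        model_violation=violation,
    )


def predict_acetate(
    partition: RoutePartition,
    acetate_in: float,
    ye_acetate: float = 0.0,
    observed: float | None = None,
    registry: Registry | None = None,
) -> PredictionResult:
    """Effluent acetate (mg/L) from feed acetate, route stoichiometry and the
    yeast-extract acetate correction.

    Acetate is consumed by eq1 and produced by eq2, eq3 and eq5; ``ye_acetate``
    is the separately quantified acetate released by yeast-extract oxidation.
    A negative prediction is flagged as a model violation, not clipped.
    """
    if acetate_in < 0 or ye_acetate < 0:
        raise ValueError("acetate_in and ye_acetate must be >= 0")
    registry = registry or load_registry()
    mw = registry.species_or_raise("acetate").molar_mass
    delta_mmol, comps = predict_species_delta(partition, "acetate", registry)
    comps_mg = {rid: v * mw for rid, v in comps.items()}
    if ye_acetate:
        comps_mg["yeast_extract"] = ye_acetate
    predicted = acetate_in + delta_mmol * mw + ye_acetate
    return _finalize("acetate", predicted, observed, comps_mg)


def predict_bicarbonate(
    partition: RoutePartition,
    hco3_in: float = 0.0,
    observed: float | None = None,
    registry: Registry | None = None,
) -> PredictionResult:
    """Effluent bicarbonate (mg/L): 2 per acetate oxidised (eq1), 1 per
    propionate (eq2), 1 per lactate (eq3), 1/3 per lactate fermented (eq5)."""
    if hco3_in < 0:
        raise ValueError("hco3_in must be >= 0")
    registry = registry or load_registry()
    mw = registry.species_or_raise("bicarbonate").molar_mass
    delta_mmol, comps = predict_species_delta(partition, "bicarbonate", registry)
    comps_mg = {rid: v * mw for rid, v in comps.items()}
    return _finalize("bicarbonate", hco3_in + delta_mmol * mw, observed, comps_mg)


def predict_sulfide(
    delta_sulfate: float, basis: str = "as_S", observed: float | None = None
) -> PredictionResult:
    """Sulfide produced by complete reduction of ``delta_sulfate`` mg/L sulfate.

    One mole of sulfide per mole of sulfate; the mass basis is explicit
    (``as_S`` 32.06, ``as_HS`` 33.07, ``as_H2S`` 34.08 mg/mmol; assays here
    report "as S" by default). Returns mg/L.
    """
    if delta_sulfate < 0:
        raise ValueError("delta_sulfate must be >= 0")
    if basis not in SULFIDE_BASIS_MASS:
        raise ValueError(f"basis must be one of {sorted(SULFIDE_BASIS_MASS)}")
    mmol = delta_sulfate / 96.06
    predicted = mmol * SULFIDE_BASIS_MASS[basis]
    return _finalize("sulfide", predicted, observed, {"sulfate_reduction": predicted}, basis=basis)


def percent_difference(observed: float, predicted: float) -> float:
    """100·|observed − predicted| / observed."""
    if observed <= 0:
        raise ValueError("undefined denominator: observed must be > 0")
    return 100.0 * abs(observed - predicted) / observed


def lactate_utilization_ratio(delta_lactate: float, delta_sulfate: float) -> float:
    """Moles of lactate utilised per mole of sulfate reduced.

    2.0 matches pure incomplete oxidation to acetate; 2/3 matches complete
    oxidation to bicarbonate.
    """
    if delta_sulfate <= 0:
        raise ValueError("delta_sulfate must be > 0")
    return delta_lactate / delta_sulfate
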