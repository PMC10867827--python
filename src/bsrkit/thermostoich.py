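"""Species/reaction registry, balance validation and Gibbs free energies.

The registry bundles the species occurring in sulfidogenic and fermentative
reactor chemistry with standard transformed Gibbs free energies of formation
(ΔGf°′, pH 7, 25 °C, Thauer convention: the proton carries the pH-7
correction and dissolved H₂ is the zero reference) and anion molar masses.
Reactions are signed rational stoichiometries over those species; ΔG°′ of a
reaction is the coefficient-weighted sum of formation energies.

All stoichiometric coefficients are exact :class:`fractions.Fraction` values,
so quarter- and three-quarter couplings never accumulate float error and
balance residuals of well-formed reactions are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ATOMIC_WEIGHTS",
    "Species",
    "Reaction",
    "BalanceReport",
    "Registry",
    "load_registry",
    "validate_balance",
    "delta_g_prime",
    "hess_combine",
    "molar_ratio",
    "mass_to_moles",
    "moles_to_mass",
]

#: Standard atomic weights (g/mol) for the elements the registry uses.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Fe": 55.845,
}

#: Molar-mass self-consistency tolerance for registry species, g/mol.
MASS_TOLERANCE = 0.05

#: Residual magnitude below which a rational balance counts as exact.
BALANCE_TOLERANCE = 1e-9


class UnknownSpeciesError(KeyError):
    """A reaction references a species id absent from the registry."""


class UnbalancedReactionError(ValueError):
    """A thermodynamic quantity was requested for an unbalanced reaction."""


@dataclass(frozen=True)
class Species:
    """A chemical species with formula, charge and formation energy.

    Parameters
    ----------
    id:
        Short name, e.g. ``"sulfate"``.
    formula:
        Element symbol → atom count (non-negative integers).
    charge:
        Net charge in elementary units.
    dGf_prime:
        Standard transformed Gibbs free energy of formation at pH 7, 25 °C,
        kJ/mol. ``None`` if unknown (ΔG computation will refuse).
    molar_mass:
        Anion molar mass in g/mol (no counter-ion).
    """

    id: str
    formula: Mapping[str, int]
    charge: int
    molar_mass: float
    dGf_prime: float | None = None

    def __post_init__(self) -> None:
        if not self.formula:
            raise ValueError(f"species {self.id!r}: empty formula")
        if any(n < 0 for n in self.formula.values()):
            raise ValueError(f"species {self.id!r}: negative atom count")
        unknown = set(self.formula) - set(ATOMIC_WEIGHTS)
        if unknown:
            raise ValueError(f"species {self.id!r}: no atomic weight for {sorted(unknown)}")
        computed = self.formula_mass()
        if abs(computed - self.molar_mass) > MASS_TOLERANCE:
            raise ValueError(
                f"species {self.id!r}: molar_mass {self.molar_mass} g/mol disagrees "
                f"with formula mass {computed:.3f} g/mol by more than {MASS_TOLERANCE}"
            )

    def formula_mass(self) -> float:
        """Molar mass computed from the formula and standard atomic weights."""
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in self.formula.items())


def _as_fraction(value: object) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, float):
        # Accept exact dyadic/decimal user input (0.75, 0.5) without binary drift.
        return Fraction(str(value))
    raise TypeError(f"cannot interpret coefficient {value!r} as an exact rational")


@dataclass(frozen=True)
class Reaction:
    """A signed rational stoichiometry over registry species.

    Reactants carry negative coefficients, products positive. ``dG_printed``
    stores a literature ΔG°′ value (kJ/reaction) as data; it is never used
    in computation.
    """

    id: str
    coefficients: Mapping[str, Fraction]
    dG_printed: float | None = None
    canonical_of: str | None = None

    def __post_init__(self) -> None:
        coeffs = {sp: _as_fraction(c) for sp, c in self.coefficients.items() if c != 0}
        object.__setattr__(self, "coefficients", coeffs)
        if coeffs:
            has_reactant = any(c < 0 for c in coeffs.values())
            has_product = any(c > 0 for c in coeffs.values())
            if not (has_reactant and has_product):
                raise ValueError(
                    f"reaction {self.id!r}: needs at least one reactant and one product"
                )

    @property
    def reactants(self) -> dict[str, Fraction]:
        return {sp: -c for sp, c in self.coefficients.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {sp: c for sp, c in self.coefficients.items() if c > 0}

    def coefficient(self, species_id: str) -> Fraction:
        return self.coefficients.get(species_id, Fraction(0))

    def scaled(self, factor: Fraction | int | str, new_id: str | None = None) -> "Reaction":
        """Return the reaction with every coefficient multiplied by ``factor``."""
        f = _as_fraction(factor)
        if f == 0:
            raise ValueError("scale factor must be nonzero")
        return Reaction(
            id=new_id or f"{self.id}*{f}",
            coefficients={sp: c * f for sp, c in self.coefficients.items()},
            dG_printed=None,
        )

    def normalized(self, species_id: str, new_id: str | None = None) -> "Reaction":
        """Scale so ``species_id`` has |coefficient| 1 (sign preserved)."""
        c = self.coefficient(species_id)
        if c == 0:
            raise ValueError(f"reaction {self.id!r}: species {species_id!r} absent")
        return self.scaled(Fraction(1, 1) / abs(c), new_id=new_id or f"{self.id}_per_{species_id}")


@dataclass(frozen=True)
class BalanceReport:
    """Per-element and charge residuals (products − reactants) of a reaction."""

    reaction_id: str
    element_residuals: Mapping[str, Fraction]
    charge_residual: Fraction
    balanced: bool

    def nonzero_residuals(self) -> dict[str, Fraction]:
        out = {el: r for el, r in self.element_residuals.items() if r != 0}
        if self.charge_residual != 0:
            out["charge"] = self.charge_residual
        return out


class Registry:
    """Lookup table of :class:`Species` and :class:`Reaction` objects."""

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction] = ()):
        self.species: dict[str, Species] = {s.id: s for s in species}
        self.reactions: dict[str, Reaction] = {r.id: r for r in reactions}

    def species_or_raise(self, species_id: str) -> Species:
        try:
            return self.species[species_id]
        except KeyError:
            raise UnknownSpeciesError(f"unknown species id {species_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[reaction_id]

    def add_reaction(self, reaction: Reaction) -> None:
        for sp in reaction.coefficients:
            self.species_or_raise(sp)
        self.reactions[reaction.id] = reaction

    def canonical_reactions(self) -> dict[str, Reaction]:
        """Reactions used in computation: every entry that is not shadowed by
        a canonical variant (``*_printed`` forms with a ``canonical_of``
        pointer at them are excluded)."""
        shadowed = {r.canonical_of for r in self.reactions.values() if r.canonical_of}
        return {rid: r for rid, r in self.reactions.items() if rid not in shadowed}


def load_registry(path: str | Path | None = None) -> Registry:
    """Load the bundled registry, or a user-supplied YAML with the same schema."""
    if path is None:
        source = resources.files("bsrkit.data").joinpath("registry.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    species = [
        Species(
            id=sid,
            formula=entry["formula"],
            charge=entry["charge"],
            molar_mass=entry["molar_mass"],
            dGf_prime=entry.get("dGf_prime"),
        )
        for sid, entry in raw["species"].items()
    ]
    reactions = [
        Reaction(
            id=rid,
            coefficients={sp: _as_fraction(c) for sp, c in entry["coefficients"].items()},
            dG_printed=entry.get("dG_printed"),
            canonical_of=entry.get("canonical_of"),
        )
        for rid, entry in raw.get("reactions", {}).items()
    ]
    return Registry(species, reactions)


def validate_balance(reaction: Reaction, registry: Registry) -> BalanceReport:
    """Audit elemental and charge balance of ``reaction``.

    Imbalance is a finding, not an error: the report flags it. Only an
    unknown species id raises.
    """
    element_residuals: dict[str, Fraction] = {}
    charge = Fraction(0)
    for sid, coeff in reaction.coefficients.items():
        sp = registry.species_or_raise(sid)
        for el, count in sp.formula.items():
            element_residuals[el] = element_residuals.get(el, Fraction(0)) + coeff * count
        charge += coeff * sp.charge
    balanced = all(abs(r) <= BALANCE_TOLERANCE for r in element_residuals.values())
    balanced = balanced and abs(charge) <= BALANCE_TOLERANCE
    return BalanceReport(
        reaction_id=reaction.id,
        element_residuals=element_residuals,
        charge_residual=charge,
        balanced=balanced,
    )


def delta_g_prime(reaction: Reaction, registry: Registry) -> float:
    """ΔG°′ of a balanced reaction, kJ/reaction.

    Coefficient-weighted sum of ΔGf°′ (products minus reactants). Refuses
    unbalanced reactions — a free energy of a non-conserving equation is
    meaningless — and species without a formation energy.
    """
    report = validate_balance(reaction, registry)
    if not report.balanced:
        raise UnbalancedReactionError(
            f"reaction {reaction.id!r} is unbalanced "
            f"(residuals {report.nonzero_residuals()}); cannot compute ΔG°′"
        )
    total = 0.0
    for sid, coeff in reaction.coefficients.items():
        sp = registry.species_or_raise(sid)
        if sp.dGf_prime is None:
            raise ValueError(f"species {sid!r} has no dGf_prime; cannot compute ΔG°′")
        total += float(coeff) * sp.dGf_prime
    return total


def hess_combine(
    reactions: Sequence[Reaction],
    multipliers: Sequence[Fraction | int | str],
    new_id: str = "combined",
) -> Reaction:
    """Coefficient-wise weighted sum of reactions; exact cancellation drops species.

    The result may be empty (all species cancel); such a degenerate reaction
    has zero coefficients and ΔG°′ 0 by construction.
    """
    if len(reactions) != len(multipliers):
        raise ValueError("reactions and multipliers must have the same length")
    fracs = [_as_fraction(m) for m in multipliers]
    if any(m == 0 for m in fracs):
        raise ValueError("multipliers must be nonzero")
    combined: dict[str, Fraction] = {}
    for rxn, m in zip(reactions, fracs):
        for sp, c in rxn.coefficients.items():
            combined[sp] = combined.get(sp, Fraction(0)) + m * c
    combined = {sp: c for sp, c in combined.items() if c != 0}
    if not combined:
        # empty net reaction: bypass the reactant/product requirement
        rxn = object.__new__(Reaction)
        object.__setattr__(rxn, "id", new_id)
        object.__setattr__(rxn, "coefficients", {})
        object.__setattr__(rxn, "dG_printed", None)
        object.__setattr__(rxn, "canonical_of", None)
        return rxn
    return Reaction(id=new_id, coefficients=combined)


def molar_ratio(reaction: Reaction, species_a: str, species_b: str) -> float:
    """|coeff(A)| / |coeff(B)| — the molar coupling of two species in a reaction.

    E.g. lactate:sulfate is 2.0 for incomplete lactate oxidation and
    2/3 for complete oxidation.
    """
    ca, cb = reaction.coefficient(species_a), reaction.coefficient(species_b)
    if ca == 0 or cb == 0:
        missing = [s for s, c in ((species_a, ca), (species_b, cb)) if c == 0]
        raise ValueError(f"reaction {reaction.id!r}: species {missing} not in reaction")
    return float(abs(ca) / abs(cb))


def mass_to_moles(concentration_mg_per_L: float, species: Species) -> float:
    """Convert mg/L to mmol/L via the species' anion molar mass."""
    if concentration_mg_per_L < 0:
        raise ValueError("concentration must be >= 0")
    return concentration_mg_per_L / species.molar_mass


def moles_to_mass(concentration_mmol_per_L: float, species: Species) -> float:
    """Convert mmol/L to mg/L via the species' anion molar mass."""
    if concentration_mmol_per_L < 0:
        raise ValueError("concentration must be >= 0")
    return concentration_mmol_per_L * species.molar_mass
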