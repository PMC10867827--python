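# Species and reaction registry for sulfidogenic / fermentative bioreactor accounting.
#
# Formation energies (dGf_prime, kJ/mol) are standard transformed values at
# pH 7, 25 degC in the Thauer convention: the proton carries the pH-7
# correction (-39.87 kJ/mol) and dissolved H2 is the zero reference.
# Molar masses are anion masses (no counter-ion), g/mol.
#
# Reaction coefficients are exact rationals written as strings; reactants
# negative, products positive. dG_printed is the literature value stored as
# data — computation always goes through the formation energies.
#
# Users may extend this file; schema: species{formula,charge,dGf_prime,
# molar_mass}, reactions{coefficients,dG_printed?,canonical_of?}.

species:
  sulfate:
    formula: {S: 1, O: 4}
    charge: -2
    dGf_prime: -744.63
    molar_mass: 96.06
  sulfide:            # hydrosulfide anion HS-; reporting basis handled downstream
    formula: {H: 1, S: 1}
    charge: -1
    dGf_prime: 12.05
    molar_mass: 33.07
  acetate:
    formula: {C: 2, H: 3, O: 2}
    charge: -1
    dGf_prime: -369.41
    molar_mass: 59.04
  propionate:
    formula: {C: 3, H: 5, O: 2}
    charge: -1
    dGf_prime: -361.08
    molar_mass: 73.07
  lactate:
    formula: {C: 3, H: 5, O: 3}
    charge: -1
    dGf_prime: -517.81
    molar_mass: 89.07
  citrate:
    formula: {C: 6, H: 5, O: 7}
    charge: -3
    dGf_prime: -1168.34
    molar_mass: 189.10
  bicarbonate:
    formula: {H: 1, C: 1, O: 3}
    charge: -1
    dGf_prime: -586.85
    molar_mass: 61.02
  water:
    formula: {H: 2, O: 1}
    charge: 0
    dGf_prime: -237.17
    molar_mass: 18.02
  proton:
    formula: {H: 1}
    charge: 1
    dGf_prime: -39.87
    molar_mass: 1.01
  hydrogen:
    formula: {H: 2}
    charge: 0
    dGf_prime: 0.0
    molar_mass: 2.02

reactions:
  # Complete acetate oxidation coupled to sulfate reduction.
  eq1:
    coefficients: {acetate: "-1", sulfate: "-1", bicarbonate: "2", sulfide: "1"}
    dG_printed: -47.6
  # Propionate oxidation to acetate coupled to sulfate reduction.
  eq2:
    coefficients: {propionate: "-1", sulfate: "-3/4", acetate: "1",
                   bicarbonate: "1", sulfide: "3/4", proton: "1/4"}
    dG_printed: -37.7
  # Incomplete lactate oxidation to acetate, as printed in the source table:
  # fails H and charge balance by 0.5 (missing 0.5 H+ product).
  eq3_printed:
    coefficients: {lactate: "-1", sulfate: "-1/2", acetate: "1",
                   bicarbonate: "1", sulfide: "1/2"}
    dG_printed: -80.2
  # Canonical balanced form used in all computation.
  eq3:
    canonical_of: eq3_printed
    coefficients: {lactate: "-1", sulfate: "-1/2", acetate: "1",
                   bicarbonate: "1", sulfide: "1/2", proton: "1/2"}
    dG_printed: -80.2
  # Complete lactate oxidation coupled to sulfate reduction.
  # The printed -225.3 conflicts with Hess additivity (2*eq3 + 2*eq1 gives
  # about -255.4); stored as data only.
  eq4:
    coefficients: {lactate: "-2", sulfate: "-3", bicarbonate: "6",
                   sulfide: "3", proton: "1"}
    dG_printed: -225.3
  # Fermentative lactate disproportionation to acetate + propionate.
  # Printed -70.0 conflicts with formation-energy computation (about -165);
  # stored as data only.
  eq5:
    coefficients: {lactate: "-3", acetate: "1", propionate: "2",
                   bicarbonate: "1", proton: "1"}
    dG_printed: -70.0
  # Hydrogenotrophic sulfate reduction.
  eq6:
    coefficients: {hydrogen: "-4", sulfate: "-1", proton: "-1",
                   sulfide: "1", water: "4"}
    dG_printed: -151.9
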