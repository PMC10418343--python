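"""Physical constants and unit conventions.

Canonical internal units: kcal/mol (energy), e (charge), Debye (dipole),
Angstrom (length), degrees (angles), K (temperature).
"""

#: Hartree -> kcal/mol conversion factor.
HARTREE_TO_KCAL = 627.5095

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987204e-3

#: log(10) factor used throughout linear free-energy relationships.
LOG10_FACTOR = 2.303

#: Default analysis temperature, K (110.3 degrees C).
DEFAULT_TEMPERATURE_K = 383.45
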