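"""Unit conversion constants.

All internal arithmetic is done in Hartree atomic units (bohr, hartree,
electron charge).  Conversions to the I/O units (angstrom, kcal/mol)
happen only at the boundaries.
"""

BOHR_PER_ANGSTROM = 1.0 / 0.52917721
ANGSTROM_PER_BOHR = 0.52917721
KCAL_PER_HARTREE = 627.509
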