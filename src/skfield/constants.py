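"""Physical constants used throughout the package.

All electrostatics run in the Å / elementary-charge / volt unit chain.  The
Coulomb constant is pinned to a fixed literal (not recomputed from CODATA at
import time) so that every test value is bit-stable across platforms.
"""

#: e/(4*pi*eps0) expressed in V·Å per elementary charge.  Equivalently,
#: e**2/(4*pi*eps0) = 14.399645 eV·Å.
COULOMB_K_V_ANG = 14.399645

#: 1 V/Å = 100 MV/cm; probe-bond fields are reported in MV/cm.
V_PER_ANG_TO_MV_PER_CM = 100.0

#: Planck constant, J·s (SI exact).
PLANCK_H = 6.62607015e-34

#: Boltzmann constant, J/K (SI exact).
BOLTZMANN_KB = 1.380649e-23

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987204e-3

#: 1 hartree / e in volts, for converting QM-engine potentials.
HARTREE_TO_VOLT = 27.211386245988

#: 1 bohr in Å.
BOHR_TO_ANG = 0.529177210903
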