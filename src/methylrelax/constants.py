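"""Physical constants used throughout the package.

All values are CODATA-2018 so that every derived number (dipolar couplings,
transition rates, the deuteration factor) is reproducible bit-for-bit.
Gyromagnetic ratios are in rad s^-1 T^-1.
"""

#: Reduced Planck constant (J s).
HBAR = 1.054571817e-34

#: mu_0 / 4 pi (T^2 m^3 J^-1); converts the CGS-style gamma*gamma*hbar/r^3
#: dipolar coupling to SI.
MU0_OVER_4PI = 1e-7

#: 1H gyromagnetic ratio (rad s^-1 T^-1).
GAMMA_H = 2.6752218744e8

#: 13C gyromagnetic ratio (rad s^-1 T^-1).
GAMMA_C = 6.728284e7

#: 2H gyromagnetic ratio (rad s^-1 T^-1).
GAMMA_D = 4.10662791e7

#: Spin quantum numbers of 1H and 2H.
SPIN_H = 0.5
SPIN_D = 1.0

#: Gas constant in kcal mol^-1 K^-1, matching activation energies in kcal/mol.
R_GAS_KCAL = 1.9872e-3

#: Angstrom in metres.
ANGSTROM = 1e-10
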