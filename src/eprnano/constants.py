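"""Physical constants and package-wide defaults.

Field/frequency conversion uses CODATA-2018 values. Magnetic-tensor
defaults are standard doxyl-nitroxide literature values for a fatty-acid
spin probe in a lipid bilayer; they are configurable inputs everywhere,
not fitted quantities.
"""

PLANCK_H = 6.62607015e-34  # J s
BOHR_MAGNETON = 9.2740100783e-24  # J / T

#: h * 1e9 / mu_B * 1e3 — resonance field in mT for frequency in GHz: B = C * nu / g
FIELD_PER_GHZ = PLANCK_H * 1.0e9 / BOHR_MAGNETON * 1.0e3  # mT GHz^-1 (times 1/g)

#: electron gyromagnetic ratio expressed per nanosecond per millitesla;
#: scales the motional-narrowing linewidth term  kappa * tau_c * Var[B_res]
GAMMA_E_NS_MT = 1.76085963023e11 * 1e-9 * 1e-3  # 1/(ns mT) ~= 0.17609

#: default motional-broadening scale (see docs/methods.md)
DEFAULT_KAPPA = GAMMA_E_NS_MT

# doxyl nitroxide hyperfine principal values [mT] and g principal values
DEFAULT_A_TENSOR = (0.63, 0.58, 3.36)
DEFAULT_G_TENSOR = (2.0088, 2.0061, 2.0027)

DEFAULT_MICROWAVE_FREQUENCY_GHZ = 9.59
DEFAULT_CENTER_FIELD_MT = 341.5
DEFAULT_SWEEP_WIDTH_MT = 10.0
DEFAULT_N_POINTS = 1024
DEFAULT_MODULATION_AMPLITUDE_MT = 0.2
DEFAULT_TEMPERATURE_C = 20.0

DEFAULT_N_THETA = 64  # powder-average Gauss-Legendre nodes
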