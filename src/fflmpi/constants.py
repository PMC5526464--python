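"""Physical constants used throughout the simulator (SI units)."""

MU0 = 1.25663706212e-6  # vacuum permeability [T·m/A]
KB = 1.380649e-23  # Boltzmann constant [J/K]

# Magnetite (Fe3O4) properties for the default SPION parameterization.
MAGNETITE_DENSITY = 5170.0  # [kg/m^3]
MAGNETITE_MS_BULK = 4.8e5  # bulk saturation magnetization [A/m]
MAGNETITE_FE_MASS_FRACTION = 0.724  # 3*55.845 / (3*55.845 + 4*15.999)
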