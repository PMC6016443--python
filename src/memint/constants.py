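"""Physical constants and analysis defaults, defined once.

Units follow CHARMM conventions: lengths in Å, energies in kcal/mol,
charges in elementary charge units, temperatures in K.
"""

#: Coulomb prefactor, kcal·Å/(mol·e²) (CHARMM value).
COULOMB_CONSTANT = 332.0636

#: Gas constant in cal/(mol·K), the value conventionally used when
#: converting ITC association constants to free energies.
R_GAS_CAL = 1.986

#: Molar concentration of water (M); rescales Ka to a mole-fraction
#: standard state in dG = -RT ln(55.5 Ka).
WATER_MOLARITY = 55.5

#: Physiological temperature (37 °C) in K, the default for thermodynamics.
T_PHYSIOLOGICAL = 310.15

#: Geometric hydrogen-bond criteria: donor-acceptor distance cutoff (Å)
#: and maximum deviation of the D-H···A angle from linearity (degrees).
HBOND_DMAX = 4.0
HBOND_AMAX = 60.0

#: Nonbonded truncation: interactions switched off smoothly between
#: SWITCH_ON and CUTOFF (Å), zero beyond CUTOFF.
NONBONDED_CUTOFF = 12.0
NONBONDED_SWITCH_ON = 10.0

#: Laurdan emission wavelengths (nm) entering generalized polarization.
LAURDAN_BLUE_NM = 440.0
LAURDAN_RED_NM = 490.0
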