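"""Fixed physical constants used throughout the package.

Natural-abundance isotope ratios follow the VPDB / air-N2 reference values
commonly used for SIMS work. Fractions are derived from the ratios as
f = R / (1 + R).
"""

#: Natural-abundance atomic ratio 13C/12C.
NATURAL_13C_RATIO: float = 0.011237

#: Natural-abundance atom fraction of 13C, R/(1+R).
NATURAL_13C_FRACTION: float = NATURAL_13C_RATIO / (1.0 + NATURAL_13C_RATIO)

#: Natural-abundance atomic ratio 15N/14N.
NATURAL_15N_RATIO: float = 0.003676

#: Natural-abundance atom fraction of 15N, R/(1+R).
NATURAL_15N_FRACTION: float = NATURAL_15N_RATIO / (1.0 + NATURAL_15N_RATIO)

#: Default electron-multiplier dead time in nanoseconds (configurable).
DEFAULT_DEAD_TIME_NS: float = 44.0

#: The four secondary-ion species collected per experiment.
ION_SPECIES: tuple[str, ...] = ("12C2", "13C12C", "12C14N", "12C15N")

#: Major (denominator) species per element.
MAJOR_SPECIES: dict[str, str] = {"C": "12C2", "N": "12C14N"}

#: Minor (numerator) species per element.
MINOR_SPECIES: dict[str, str] = {"C": "13C12C", "N": "12C15N"}
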