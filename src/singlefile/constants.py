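"""Physical constants for liquid water at 25 °C, CGS units.

These enter only the dimensional predictions (prefactor B, per-pore pf);
the dimensionless theory needs no constants. All values are standard
bulk-water numbers and can be overridden through any function that
accepts :class:`~singlefile.theory.TransportParams`.
"""

#: Self-diffusion coefficient of bulk water at 25 °C, cm^2/s
#: (Mills, J. Phys. Chem. 77, 685 (1973): 2.30e-5).
D0_WATER_CM2_S: float = 2.30e-5

#: Effective hard-sphere diameter of a water molecule, cm (2.8 Å).
A_WATER_CM: float = 2.8e-8

#: Volume per molecule of pure water, cm^3
#: (molar volume 18.07 cm^3/mol / Avogadro's number).
VW0_WATER_CM3: float = 2.99e-23

#: Length of the gramicidin A pore, cm (2.5 nm).
L_GRAMICIDIN_CM: float = 2.5e-7

CM_PER_NM: float = 1e-7
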