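"""Physical constants shared across the pipeline.

Two mass regimes coexist: native MS of 0.4-0.55 MDa complexes uses average
masses and an average proton/adduct mass, while peptide-level cross-linking
MS resolves isotopes and uses monoisotopic masses.
"""

# Proton (charge carrier) masses, Da.
PROTON_AVG = 1.00728       # native-MS regime (average, includes adducting H)
PROTON_MONO = 1.00727646   # peptide regime

WATER_MONO = 18.0105646863

#: FWHM of a Gaussian in units of sigma, 2*sqrt(2*ln 2).
GAUSSIAN_FWHM = 2.3548200450309493

#: Mass difference between deuterium and protium, Da (monoisotopic).
D_MINUS_H = 2.0141017778 - 1.0078250319

#: BS3 cross-link mass additions (both NHS esters reacted), Da, monoisotopic.
#: d0 corresponds to the suberate bridge C8H10O2.
BS3_D0_MASS = 138.06808
BS3_D4_MASS = BS3_D0_MASS + 4 * D_MINUS_H   # 142.09319
BS3_ISOTOPE_SHIFT = 4 * D_MINUS_H           # 4.02511
BS3_SPACER_A = 11.4                          # N-N spacer length, Angstrom
LYSINE_SIDE_CHAIN_A = 6.5                    # Calpha-to-Nzeta reach, Angstrom

# Average masses of nucleotides as bound (Da).
ATP_AVG = 507.2
ATP_GAMMA_S_AVG = 523.3
ADP_AVG = 427.2

#: Common PTM mass shifts on intact proteins (name, delta Da, default max count).
PTM_DELTAS = (
    ("Met-loss", -131.040, 1),
    ("N-acetylation", +42.011, 1),
    ("oxidation", +15.995, 4),
    ("phosphorylation", +79.966, 3),
)

# Variable peptide modifications (residue, name, monoisotopic delta Da).
CARBAMIDOMETHYL_C = ("C", "carbamidomethyl", 57.02146)
OXIDATION_M = ("M", "oxidation", 15.9949)
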