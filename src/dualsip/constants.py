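"""Physical constants of the qSIP density/molecular-weight model.

All density-to-GC and GC-to-molecular-weight coefficients follow the
single-isotope qSIP framework of Hungate et al. (2015, AEM 81:7570),
as implemented in the HTSSIP R package.  The dual-isotope maximum-heavy
coefficients are the nitrogen-corrected modification of that framework's
equation for the fully 13C-labelled molecular weight.  They are kept in
one place so that every module (analysis and simulator) shares exactly
the same numbers.
"""

# Buoyant density (g ml^-1) of unlabelled DNA as a linear function of GC
# proportion: rho = DENSITY_GC_INTERCEPT + DENSITY_GC_SLOPE * G
# (Hungate et al. 2015, after Schildkraut et al. 1962).
DENSITY_GC_INTERCEPT = 1.646057
DENSITY_GC_SLOPE = 0.083506

# Mean molecular weight (g mol^-1) per nucleotide of unlabelled DNA:
# M_light = LIGHT_MW_SLOPE * G + LIGHT_MW_INTERCEPT  (Hungate et al. 2015).
LIGHT_MW_SLOPE = 0.496
LIGHT_MW_INTERCEPT = 307.691

# Maximum per-nucleotide mass gain under full 13C substitution:
# CARBON_MAX_SLOPE * G + CARBON_MAX_INTERCEPT  (Hungate et al. 2015, the
# carbon-only term; A/T pairs have 10 C per average nucleotide, G/C 9.5
# after averaging complementary strands).
CARBON_MAX_SLOPE = -0.4987282
CARBON_MAX_INTERCEPT = 9.974564

# Maximum per-base mass gain (g mol^-1) under full 15N substitution,
# from nitrogen atom counts: A and G have 5 N, T has 2, C has 3.
NITROGEN_MAX_PER_BASE = {"A": 4.985, "G": 4.985, "T": 1.994, "C": 2.991}

# Combined 13C + 15N maximum mass gain, as the dual-isotope modification
# prints it: M_heavymax - M_light = DUAL_MAX_SLOPE * G + DUAL_MAX_INTERCEPT.
# NOTE: this printed combined form does not equal the sum of the carbon
# term above and the per-base nitrogen masses (that sum is
# -0.0002282*G + 13.464064); the analysis uses the printed form verbatim
# and the per-element reconstruction is available as a separate mode.
DUAL_MAX_SLOPE = 0.0025
DUAL_MAX_INTERCEPT = 13.416

# Plausible CsCl buoyant-density window for DNA (g ml^-1); densities
# outside it are treated as input errors.
MIN_PLAUSIBLE_DENSITY = 1.55
MAX_PLAUSIBLE_DENSITY = 1.85

# Molecular-weight-excess cutoff for calling an OTU active; matches the
# labelled fraction of the added substrate.
DEFAULT_MWE_THRESHOLD = 0.14

# Micrograms of DNA loaded onto each CsCl gradient.
DEFAULT_DNA_LOADED_UG = 4.0
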