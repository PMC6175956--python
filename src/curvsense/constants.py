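"""Registry of numeric defaults used across the package.

Every physically meaningful default lives here so that the provenance of a
number is always one import away.
"""

#: Physical length of one chain bond (nm) — the Calpha-Calpha spacing.
STEP_LENGTH_NM = 0.38

#: Scan-length base per remaining bond of the future segment (entropy runs).
N_BAR = 1000
#: Equilibration base per remaining bond of the future segment.
N_BAR_PRIME = 100
#: Default number of chain reconstructions per entropy estimate.
N_RECONSTRUCTIONS = 96

#: Defaults for structural (radius-of-gyration) Monte Carlo runs.
MC_TRAJECTORIES = 64
MC_STEPS = 10_000_000
MC_BLOCKS = 10

#: Vesicle-diameter binning of puncta tables (nm).
BIN_STEP_NM = 5.0
BIN_HALF_WIDTH_NM = 2.5
BIN_MIN_NM = 20.0
BIN_MAX_NM = 250.0

#: Reference vesicle diameter and averaging window for normalization (nm).
REFERENCE_DIAMETER_NM = 200.0
REFERENCE_WINDOW_NM = (190.0, 210.0)

#: Fixed triplet-state parameters of the autocorrelation model.
TRIPLET_AMPLITUDE = 0.05
TRIPLET_TIME_S = 5e-6
#: Allowed range of the anomalous-diffusion exponent.
ALPHA_BOUNDS = (0.9, 1.0)

#: Bound-protein radius used in the geometric binding-capacity correction (nm).
PROTEIN_RADIUS_NM = 6.0
#: Membrane footprint of the 569-residue reference disordered domain (nm^2).
REFERENCE_FOOTPRINT_NM2 = 115.0
REFERENCE_FOOTPRINT_RESIDUES = 569

#: Mean diameters of the three vesicle preparations (nm): sonicated,
#: 30 nm-extruded, and 200 nm-extruded.
PREP_MEAN_DIAMETERS_NM = (49.0, 67.0, 147.0)

#: Default solvent conditions for hydrodynamic conversions.
TEMPERATURE_K = 295.0
WATER_VISCOSITY_PA_S = 9.544e-4  # water at 295 K

BOLTZMANN_J_PER_K = 1.380649e-23
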