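"""Physical constants and default model geometry for 90Y radioembolization
microdosimetry.

All spatial quantities are micrometres unless stated otherwise; doses are Gy,
activities Bq, energies J.
"""

# 90Y decay physics
MEAN_BETA_ENERGY_J = 1.485e-13   # mean energy emitted per decay [J]
DECAY_CONSTANT_PER_S = 3.006e-6  # lambda [1/s]
MEAN_LIFETIME_S = 1.0 / DECAY_CONSTANT_PER_S  # tau [s], ~332,668 s
S_90Y_J_PER_GBQ = 49.38          # total emitted energy per GBq administered
BETA_ENDPOINT_MEV = 2.2801       # 90Y -> 90Zr beta endpoint energy
DAUGHTER_Z = 40                  # Zr, used in the Fermi function

# Medium (soft tissue)
DENSITY_G_PER_ML = 1.03

# Default model geometry
VOXEL_PITCH_UM = 30.0
SIDE_LENGTH_MM = 22.0
GRID_DIM = 735                   # replicated per axis -> 735^3 voxels
CONTRACTION_VOXELS = 80          # 2.4 mm beta range, charged-particle equilibrium margin

# Published cluster-parameter medians (histology)
MEDIAN_C_DIA_UM = 337.0
MEDIAN_C_DIST_UM = 470.0
MEDIAN_C_POP = 5

# Default kernel extent
KERNEL_HALF_WIDTH = 80           # near-field dose-voxel kernel, in voxels


def voxel_mass_kg(pitch_um: float = VOXEL_PITCH_UM,
                  density_g_per_ml: float = DENSITY_G_PER_ML) -> float:
    """Mass of one voxel in kg (pitch in um, density in g/ml)."""
    volume_ml = (pitch_um * 1e-4) ** 3  # cm^3 == ml
    return volume_ml * density_g_per_ml * 1e-3
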