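"""Physical constants and default parameters of the nuclear replication model.

All defaults reproduce the reference parameterization of the model: a
self-avoiding semi-flexible chain on an fcc lattice (bead = 1 kb = 20 nm),
confined in a 2 um nucleus with Rabl tethering, replicated by stochastic
origin firing under a limiting pool of firing factors.
"""

import math

# --- lattice geometry -------------------------------------------------------
#: bead diameter = fcc nearest-neighbour spacing (nm); the internal length unit
SIGMA_NM = 20.0
#: physical length of one integer coordinate step (nm): fcc sites are integer
#: triples of even sum, nearest neighbours differ by e.g. (1, 1, 0)
STEP_NM = SIGMA_NM / math.sqrt(2.0)
#: edge of one cubic lattice cell (nm) — one "lattice unit" of the box
CELL_EDGE_NM = SIGMA_NM * math.sqrt(2.0)
#: cubic cells per box side for the full nucleus
BOX_EDGE = 70

# --- chain mechanics --------------------------------------------------------
#: bending modulus (kT) mapping to a 100 nm Kuhn length at 20 nm beads
KAPPA = 3.217
#: tether spring constant, kT per squared bead diameter
K_TETHER = 100.0
#: physical time of one Monte Carlo sweep (ms), from MSD calibration
TIME_PER_MCS_MS = 0.075

# --- nuclear geometry (nm) --------------------------------------------------
NUCLEAR_RADIUS_NM = 1000.0
CEN_SHELL_NM = (250.0, 325.0)     # centromere shell around the SPB
TELO_SHELL_NM = 950.0             # telomeres free beyond this radius
NUCLEOLUS_WALL_NM = 800.0         # wall plane distance from center, -z pole

# --- replication kinetics ---------------------------------------------------
N_FACTORS = 120                   # total firing factors N_f
ORIGIN_RATE = 1e-9                # per-MCS firing rate constant (MC^-1)
RAMP_AMPLITUDE = 0.13             # factor ramp N_f (1 - 0.13 exp(-t/tau))
RAMP_TAU_S = 90.0                 # ramp time constant (1 min 30 s)
FORK_SPEED_KB_MIN = 2.2           # replication fork speed
PORI_PER_KB = 1.0 / 5.0           # N_origins = floor(L_chromosome / 5)

# --- S-phase interactions ---------------------------------------------------
J_SISTER = 100.0                  # sister-fork pairing energy depth (kT)
TH_SISTER_NM = 50.0               # pairing saturation distance
J_FORKS = 0.0                     # non-specific fork-fork contact energy (kT)
J_FORKS_EXPLORED = 1.7            # value explored for aggregated-fork runs
FORK_SHELL_NM = 40.0              # non-specific interaction range

# --- analysis ---------------------------------------------------------------
R_CONTACT_NM = 80.0               # Hi-C contact radius r_c
RFI_THETA_NM = (60.0, 125.0, 160.0, 200.0)   # RFi detection resolutions
RFI_THETA_DEFAULT_NM = 125.0
SANER_REFERENCE_FORKS = 229       # reference fork total for even-casting
SD_LAG_S = 15.0                   # lag of the replication-aligned SD
MSD_EXP_PREFACTOR_UM2 = 0.01      # experimental law MSD(tau) ~ 0.01 tau^0.5 (um^2)

# origin classification thresholds on the IPLS
EARLY_TOP_FRACTION = 0.15
EARLY_MIN_SIGNAL = 5.0
LATE_MIN_SIGNAL = 1.0


def mcs_per_minute(time_per_mcs_ms: float = TIME_PER_MCS_MS) -> float:
    """Number of Monte Carlo sweeps per minute of physical time."""
    return 60_000.0 / time_per_mcs_ms


def fork_step_probability(v_kb_min: float = FORK_SPEED_KB_MIN,
                          time_per_mcs_ms: float = TIME_PER_MCS_MS) -> float:
    """Per-MCS probability for a fork to replicate one 1 kb monomer.

    A fork moving at ``v`` kb/min covers ``v * dt`` monomers per sweep of
    duration ``dt``; at the defaults this is 2.75e-6 (~3e-6).
    """
    return v_kb_min * time_per_mcs_ms / 60_000.0
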