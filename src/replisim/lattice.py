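"""fcc lattice geometry, chain energetics and the Metropolis criterion.

Sites are integer triples ``(x, y, z)`` with even coordinate sum.  One integer
step corresponds to :data:`replisim.constants.STEP_NM` (= sigma / sqrt(2) nm);
the 12 nearest neighbours differ by permutations of ``(+-1, +-1, 0)`` and lie
at the bead diameter sigma = 20 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as C

#: the 12 fcc nearest-neighbour displacement vectors (integer coordinates)
NN_VECTORS = np.array(
    [
        [1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0],
        [1, 0, 1], [1, 0, -1], [-1, 0, 1], [-1, 0, -1],
        [0, 1, 1], [0, 1, -1], [0, -1, 1], [0, -1, -1],
    ],
    dtype=np.int64,
)


def is_valid_site(site) -> bool:
    """True if ``site`` satisfies the fcc parity convention (even sum)."""
    x, y, z = (int(v) for v in site)
    return (x + y + z) % 2 == 0


def neighbor_sites(site) -> np.ndarray:
    """The 12 nearest-neighbour sites of ``site`` (each 20 nm away).

    Raises ``ValueError`` on a parity-violating site.
    """
    if not is_valid_site(site):
        raise ValueError(f"site {tuple(site)} violates the fcc parity convention")
    return np.asarray(site, dtype=np.int64)[None, :] + NN_VECTORS


@dataclass(frozen=True)
class LatticeGeometry:
    """Geometry of the simulation lattice.

    Parameters
    ----------
    box_edge:
        Cubic lattice cells per box side (70 for the full nucleus).
    nn_spacing:
        Physical nearest-neighbour distance in nm (equals the bead
        diameter sigma).
    """

    box_edge: int = C.BOX_EDGE
    nn_spacing: float = C.SIGMA_NM
    nn_vectors: np.ndarray = field(default_factory=lambda: NN_VECTORS.copy(),
                                   repr=False, compare=False)

    @property
    def cell_edge(self) -> float:
        """One lattice unit of the box, nn_spacing * sqrt(2) nm."""
        return self.nn_spacing * math.sqrt(2.0)

    @property
    def step_nm(self) -> float:
        """Physical length of one integer coordinate step."""
        return self.nn_spacing / math.sqrt(2.0)

    @property
    def grid_size(self) -> int:
        """Number of integer coordinate values per axis (0 .. 2 * box_edge)."""
        return 2 * self.box_edge + 1

    def to_nm(self, coords) -> np.ndarray:
        return np.asarray(coords, dtype=float) * self.step_nm


@dataclass
class SimulationParameters:
    """Physical parameters of the kinetic Monte Carlo engine."""

    kappa: float = C.KAPPA                       # bending modulus, kT
    k_tether: float = C.K_TETHER                 # kT per squared bead diameter
    time_per_mcs_ms: float = C.TIME_PER_MCS_MS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.k_tether <= 0:
            raise ValueError("k_tether must be > 0")
        if self.time_per_mcs_ms <= 0:
            raise ValueError("time_per_MCS must be > 0")


def bending_energy(coords, kappa: float = C.KAPPA) -> float:
    """Bending energy ``kappa * sum_i (1 - cos theta_i)`` of one chain, in kT.

    ``theta_i`` is the angle at each interior monomer.  Chains of fewer than
    three monomers are straight by convention and cost nothing.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or (len(coords) >= 2 and coords.shape[1] != 3):
        raise ValueError("coords must be an (N, 3) array")
    if len(coords) < 3:
        return 0.0
    bonds = np.diff(coords, axis=0)
    norms = np.linalg.norm(bonds, axis=1)
    cos = np.einsum("ij,ij->i", bonds[:-1], bonds[1:]) / (norms[:-1] * norms[1:])
    return float(kappa * np.sum(1.0 - np.clip(cos, -1.0, 1.0)))


def metropolis_accept(delta_h: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability ``min(1, exp(-dH))``."""
    if delta_h <= 0.0:
        return True
    if not np.isfinite(delta_h):
        return False
    return rng.random() < math.exp(-delta_h)


def calibrate_box_edge(diameter_nm: float, nn_spacing_nm: float = C.SIGMA_NM) -> int:
    """Lattice cells per side needed to span a nucleus of given diameter.

    One cell edge is ``nn_spacing * sqrt(2)`` nm; 2000 nm / 20 nm beads
    gives 70.
    """
    if diameter_nm < 0 or nn_spacing_nm <= 0:
        raise ValueError("diameter must be >= 0 and nn_spacing > 0")
    return int(diameter_nm // (nn_spacing_nm * math.sqrt(2.0)))
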