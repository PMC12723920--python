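"""Explicit 3D chain duplication: the coupled S-phase driver.

Origin firing inserts a newborn monomer at its template's lattice site
(transiently exempt from excluded volume), bonded to the two maternal
neighbours of the origin; the two flanking monomers acquire triple
connectivity and become the replication forks.  Forks advance by inserting
further newborn monomers and moving the junction outward; convergent
adjacent forks always replicate as a pair (bubble merge, releasing one
firing factor), and a fork reaching a chain end opens the bubble by
replicating both the fork and the end monomer.

Two sister-fork scenarios are supported: *non-interacting* (forks diffuse
independently) and *interacting*, where the two forks born from one origin
are coupled by a flat-bottomed elastic well (depth ``J_sister`` = 100 kT,
saturation distance ``th`` = 50 nm) until either partner dies.  Optional
non-specific contact attraction ``J_f`` acts between all forks within
40 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels as K
from . import constants as C
from .kinetics import IPLSTrack, sample_p_oris
from .world import EngineParameters, Trajectory, World


def sister_fork_energy(d_nm, j_sister: float = C.J_SISTER,
                       th_nm: float = C.TH_SISTER_NM):
    """Pairing energy (kT) of one intact sister-fork pair at distance d.

    A flat well of depth ``-j_sister`` for d <= th, rising quadratically
    with stiffness ``j_sister/th^2`` beyond (zero crossing at sqrt(2) th).
    """
    d = np.asarray(d_nm, dtype=float)
    out = np.where(d <= th_nm, -j_sister,
                   j_sister * ((d / th_nm) ** 2 - 2.0))
    return float(out) if out.ndim == 0 else out


def nonspecific_fork_energy(fork_positions_nm,
                            j_f: float = C.J_FORKS_EXPLORED,
                            shell_nm: float = C.FORK_SHELL_NM) -> float:
    """Total contact energy -J_f x (fork pairs within the 40 nm shell)."""
    pts = np.atleast_2d(np.asarray(fork_positions_nm, dtype=float))
    if len(pts) < 2:
        return 0.0
    tree = cKDTree(pts)
    n_pairs = len(tree.query_pairs(shell_nm + 1e-9))
    return -j_f * n_pairs


@dataclass
class SPhaseResult:
    """One coupled S-phase trajectory and its replication bookkeeping."""

    trajectory: Trajectory
    rep_time_mcs: np.ndarray          # per-locus replication time (MCS from S entry)
    events: np.ndarray                # (time, type, bin) rows
    fork_count: np.ndarray            # per-frame live fork counts
    completed: bool
    params: EngineParameters
    sc1_ids: np.ndarray = field(default=None, repr=False)

    @property
    def rep_time_min(self) -> np.ndarray:
        return self.rep_time_mcs * self.params.time_per_mcs_ms / 60_000.0


def run_s_phase(world: World, track: IPLSTrack,
                frame_every_mcs: int = 2000,
                max_minutes: float = 90.0,
                p_oris: np.ndarray | None = None) -> SPhaseResult:
    """Drive one S-phase on an equilibrated (G1) world until the genome is
    fully duplicated or the time budget runs out.

    The p-ori multiset is drawn once at S-phase entry (unless provided);
    the simulation clock restarts at 0 so the firing-factor ramp and all
    recorded replication times are measured from S-phase onset.  Frames
    (positions + live fork monomers) are emitted every ``frame_every_mcs``.
    """
    params = world.params
    if p_oris is None:
        p_oris = sample_p_oris(track, world.rng)
    world.set_p_oris(p_oris)
    world.cnt[K.C_TMCS] = 0
    world.cnt[K.C_NEV] = 0
    max_mcs = int(max_minutes * 60.0 * params.mcs_per_s)
    traj = Trajectory(time_per_mcs_ms=params.time_per_mcs_ms,
                      gbin=world.gbin, sc=world.sc, n_bins=world.n_bins)
    fork_count = []
    pos, forks = world.snapshot()
    traj.add(0.0, pos, forks)
    fork_count.append(world.n_forks)
    done = 0
    while done < max_mcs:
        block = min(frame_every_mcs, max_mcs - done)
        ran = world.run_s_phase(block)
        done += ran
        pos, forks = world.snapshot()
        traj.add(world.t_mcs, pos, forks)
        fork_count.append(world.n_forks)
        if world.cnt[K.C_NREP] >= world.n_bins:
            break
        if ran < block:
            break
    completed = bool(world.cnt[K.C_NREP] >= world.n_bins)
    return SPhaseResult(
        trajectory=traj,
        rep_time_mcs=world.rep_time.copy(),
        events=world.ev[:int(world.cnt[K.C_NEV])].copy(),
        fork_count=np.asarray(fork_count),
        completed=completed,
        params=params,
        sc1_ids=np.arange(world.n_bins),
    )
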