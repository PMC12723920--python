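"""Simulation state container tying the numba kernels together.

A :class:`World` owns the flat arrays the kernels mutate: monomer positions
and bonds, lattice occupancy, tether roles, the replication-fork registry and
the per-locus replication times.  Monomer ids ``0..G-1`` are the maternal
(Sister Chromatid 1) copies, in genomic order; newborn SC2 copies get ids
``G..2G-1`` as they are created.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from . import constants as C
from .genome import GenomeSpec


@dataclass
class EngineParameters:
    """All tunable physics of the engine, at the reference defaults."""

    kappa: float = C.KAPPA
    k_tether: float = C.K_TETHER
    time_per_mcs_ms: float = C.TIME_PER_MCS_MS
    n_factors: float = C.N_FACTORS
    origin_rate: float = C.ORIGIN_RATE
    ramp_amplitude: float = C.RAMP_AMPLITUDE
    ramp_tau_s: float = C.RAMP_TAU_S
    fork_speed_kb_min: float = C.FORK_SPEED_KB_MIN
    j_sister: float = C.J_SISTER
    th_sister_nm: float = C.TH_SISTER_NM
    j_forks: float = C.J_FORKS
    interacting: bool = True

    @property
    def mcs_per_s(self) -> float:
        return 1000.0 / self.time_per_mcs_ms

    @property
    def ramp_tau_mcs(self) -> float:
        return self.ramp_tau_s * self.mcs_per_s

    @property
    def fork_step_probability(self) -> float:
        return self.fork_speed_kb_min * self.time_per_mcs_ms / 60_000.0

    def rescaled(self, factor: float) -> "EngineParameters":
        """Speed replication up by ``factor`` (OriginRate, fork stepping and
        the factor ramp scale together, so the fork-budget dynamics on the
        rescaled time axis match the reference dynamics)."""
        out = EngineParameters(**{k: getattr(self, k) for k in
                                  self.__dataclass_fields__})
        out.origin_rate = self.origin_rate * factor
        out.fork_speed_kb_min = self.fork_speed_kb_min * factor
        out.ramp_tau_s = self.ramp_tau_s / factor
        return out


@dataclass
class Trajectory:
    """Frames emitted by a run: times (MCS), positions, fork monomer ids."""

    times: list = field(default_factory=list)
    positions: list = field(default_factory=list)      # (n_mon, 3) int16
    fork_monomers: list = field(default_factory=list)  # alive junction ids
    step_nm: float = C.STEP_NM
    time_per_mcs_ms: float = C.TIME_PER_MCS_MS
    gbin: np.ndarray | None = None                     # monomer id -> bin
    sc: np.ndarray | None = None                       # monomer id -> SC label
    n_bins: int = 0

    def add(self, t: float, pos: np.ndarray, forks: np.ndarray) -> None:
        self.times.append(float(t))
        self.positions.append(pos)
        self.fork_monomers.append(forks)

    def __len__(self) -> int:
        return len(self.times)

    def times_min(self) -> np.ndarray:
        return np.asarray(self.times) * self.time_per_mcs_ms / 60_000.0


class World:
    """Mutable lattice state of one trajectory."""

    def __init__(self, spec: GenomeSpec, params: EngineParameters,
                 box_cells: int, periodic: bool = False,
                 geometry=None, seed: int = 0):
        self.spec = spec
        self.params = params
        self.box_cells = int(box_cells)
        self.periodic = bool(periodic)
        self.geometry = geometry
        self.rng = np.random.default_rng(seed)
        G = spec.n_monomers
        self.n_bins = G
        cap = 2 * G
        self.smod = 2 * self.box_cells if periodic else 2 * self.box_cells + 1
        S = self.smod

        self.pos = np.zeros((cap, 3), dtype=np.int64)
        self.nb = np.full((cap, 3), -1, dtype=np.int64)
        self.nnb = np.zeros(cap, dtype=np.uint8)
        self.ang = np.full((cap, 2, 2), -1, dtype=np.int64)
        self.nang = np.zeros(cap, dtype=np.uint8)
        self.role = np.zeros(cap, dtype=np.uint8)
        self.sc = np.zeros(cap, dtype=np.uint8)
        self.gbin = np.full(cap, -1, dtype=np.int64)
        self.fork_of_mon = np.full(cap, -1, dtype=np.int64)
        self.occ = np.zeros((S, S, S), dtype=np.uint8)
        self.blocked = np.zeros((S, S, S), dtype=np.uint8)
        self.fld = np.zeros((S, S, S), dtype=np.uint16)

        self.mat_id = np.arange(G, dtype=np.int64)
        self.copy_id = np.full(G, -1, dtype=np.int64)
        self.rep_time = np.full(G, -1.0, dtype=np.float64)
        self.junction_of_bin = np.full(G, -1, dtype=np.int64)
        self.bin_chain = spec.bin_chain.astype(np.int64)
        self.chain_first = spec.chain_first.astype(np.int64)
        self.chain_last = spec.chain_last.astype(np.int64)

        cap_f = 2 * max(G // 3, 64)
        self.f_bin = np.full(cap_f, -1, dtype=np.int64)
        self.f_dir = np.zeros(cap_f, dtype=np.int64)
        self.f_mon = np.full(cap_f, -1, dtype=np.int64)
        self.f_partner = np.full(cap_f, -1, dtype=np.int64)
        self.f_pair = np.zeros(cap_f, dtype=np.uint8)
        self.f_alive = np.zeros(cap_f, dtype=np.uint8)
        self.falive_list = np.full(cap_f, -1, dtype=np.int64)
        self.f_pos_in_list = np.full(cap_f, -1, dtype=np.int64)

        self.pori_list = np.zeros(0, dtype=np.int64)
        self.ev = np.zeros((3 * max(G // 3, 64), 3), dtype=np.float64)
        self.cnt = np.zeros(K.NCNT, dtype=np.int64)
        self.par = np.zeros(K.NPAR, dtype=np.float64)
        self.ipar = np.zeros(K.NIPAR, dtype=np.int64)
        self._pack_parameters()

    # ------------------------------------------------------------------
    def _pack_parameters(self) -> None:
        p = self.params
        par = self.par
        par[K.P_KAPPA] = p.kappa
        par[K.P_KTETHER] = p.k_tether
        par[K.P_JSISTER] = p.j_sister
        par[K.P_TH2U] = (p.th_sister_nm / C.SIGMA_NM) ** 2
        par[K.P_JF] = p.j_forks
        par[K.P_PSTEP] = p.fork_step_probability
        par[K.P_ORATE] = p.origin_rate
        par[K.P_NF] = p.n_factors
        par[K.P_RAMPA] = p.ramp_amplitude
        par[K.P_RAMPTAU] = p.ramp_tau_mcs
        L = self.box_cells
        par[K.P_SPBX], par[K.P_SPBY], par[K.P_SPBZ] = L, L, 2 * L
        par[K.P_CENX], par[K.P_CENY], par[K.P_CENZ] = L, L, L
        g = self.geometry
        if g is not None:
            to_i = 1.0 / C.STEP_NM      # nm -> integer coordinate units
            par[K.P_CENLO2] = (g.cen_shell_nm[0] * to_i) ** 2
            par[K.P_CENHI2] = (g.cen_shell_nm[1] * to_i) ** 2
            par[K.P_TELO2] = (g.telo_shell_nm * to_i) ** 2
            par[K.P_WALLZ] = L - g.nucleolus_wall_nm * to_i
        else:
            par[K.P_CENLO2] = 0.0
            par[K.P_CENHI2] = np.inf
            par[K.P_TELO2] = 0.0
            par[K.P_WALLZ] = -1e9
        self.ipar[K.I_PERIODIC] = 1 if self.periodic else 0
        self.ipar[K.I_SMOD] = self.smod
        self.ipar[K.I_INTERACT] = 1 if p.interacting else 0
        self.ipar[K.I_JFON] = 1 if p.j_forks != 0.0 else 0

    # ------------------------------------------------------------------
    @property
    def n_monomers(self) -> int:
        return int(self.cnt[K.C_NMON])

    @property
    def n_forks(self) -> int:
        return int(self.cnt[K.C_NFORKS])

    @property
    def t_mcs(self) -> float:
        return float(self.cnt[K.C_TMCS])

    @property
    def replicated_fraction(self) -> float:
        return float(self.cnt[K.C_NREP]) / self.n_bins

    def free_factors(self, t_mcs: float | None = None) -> float:
        """Available firing factors max(0, N_f(t) - N_forks/2)."""
        p = self.params
        t = self.t_mcs if t_mcs is None else t_mcs
        nf_t = p.n_factors * (1.0 - p.ramp_amplitude
                              * math.exp(-t / p.ramp_tau_mcs))
        return max(0.0, nf_t - self.n_forks / 2.0)

    def alive_forks(self) -> np.ndarray:
        return self.falive_list[:self.n_forks].copy()

    def fork_positions_nm(self) -> np.ndarray:
        ids = self.f_mon[self.alive_forks()]
        return self.pos[ids].astype(float) * C.STEP_NM

    def monomer_positions_nm(self) -> np.ndarray:
        return self.pos[:self.n_monomers].astype(float) * C.STEP_NM

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    def place_chain(self, chain_index: int, path: np.ndarray) -> None:
        """Install a grown self-avoiding path as the maternal chain
        ``chain_index`` (ids equal global bins; occupancy must already
        include the path sites)."""
        b0 = int(self.chain_first[chain_index])
        b1 = int(self.chain_last[chain_index])
        n = b1 - b0 + 1
        assert path.shape[0] == n
        self.pos[b0:b1 + 1] = path
        self.sc[b0:b1 + 1] = 1
        self.gbin[b0:b1 + 1] = np.arange(b0, b1 + 1)
        for b in range(b0, b1 + 1):
            if b > b0:
                K._add_nb(self.nb, self.nnb, b, b - 1)
            if b < b1:
                K._add_nb(self.nb, self.nnb, b, b + 1)
        for b in range(b0 + 1, b1):
            self.ang[b, 0, 0] = b - 1
            self.ang[b, 0, 1] = b + 1
            self.nang[b] = 1

    def finalize_chains(self) -> None:
        self.cnt[K.C_NMON] = self.n_bins
        self.role[:self.n_bins] = self.spec.roles
        got = self.recompute_occupancy()
        if not np.array_equal(got, self.occ):
            raise RuntimeError("occupancy inconsistent after construction")

    # ------------------------------------------------------------------
    # dynamics
    # ------------------------------------------------------------------
    def _block_seed(self) -> int:
        return int(self.rng.integers(0, 2**31 - 1))

    def run(self, n_mcs: int, reptation_fraction: float = 0.0) -> None:
        """Plain kinetic Monte Carlo (no replication trials).

        ``reptation_fraction`` mixes in slithering-snake trials, valid only
        while the chains are linear and unreplicated (equilibration)."""
        if reptation_fraction > 0.0 and self.n_monomers != self.n_bins:
            raise RuntimeError("reptation requires unreplicated chains")
        K.run_sweeps(int(n_mcs), self._block_seed(), self.pos, self.nb,
                     self.nnb, self.ang, self.nang, self.role, self.occ,
                     self.blocked, self.fork_of_mon, self.f_mon,
                     self.f_partner, self.f_pair, self.f_alive, self.fld,
                     self.par, self.ipar, self.cnt, self.chain_first,
                     self.chain_last, float(reptation_fraction))

    def record(self, n_mcs: int, frame_every: int) -> Trajectory:
        """Run plain dynamics, collecting a frame every ``frame_every`` MCS
        (the state at t=start is frame 0)."""
        traj = Trajectory(time_per_mcs_ms=self.params.time_per_mcs_ms,
                          gbin=self.gbin, sc=self.sc, n_bins=self.n_bins)
        pos, forks = self.snapshot()
        traj.add(self.t_mcs, pos, forks)
        done = 0
        while done < n_mcs:
            step = min(frame_every, n_mcs - done)
            self.run(step)
            done += step
            pos, forks = self.snapshot()
            traj.add(self.t_mcs, pos, forks)
        return traj

    def set_p_oris(self, bins: np.ndarray) -> None:
        """Install the sampled p-ori multiset (global bins, with
        multiplicity) for the coupled S-phase driver."""
        self.pori_list = np.ascontiguousarray(bins, dtype=np.int64).copy()
        self.cnt[K.C_NPORI] = len(self.pori_list)

    def run_s_phase(self, n_mcs: int) -> int:
        """Coupled S-phase dynamics for up to ``n_mcs`` sweeps; returns the
        number executed (stops early at full replication)."""
        if len(self.pori_list) == 0:
            raise RuntimeError("no p-oris sampled; call set_p_oris first")
        return int(K.run_s_phase_block(
            int(n_mcs), self._block_seed(), self.pos, self.nb, self.nnb,
            self.ang, self.nang, self.role, self.sc, self.gbin, self.occ,
            self.blocked, self.fork_of_mon, self.f_bin, self.f_dir,
            self.f_mon, self.f_partner, self.f_pair, self.f_alive,
            self.falive_list, self.f_pos_in_list, self.junction_of_bin,
            self.mat_id, self.copy_id, self.rep_time, self.bin_chain,
            self.chain_first, self.chain_last, self.pori_list, self.fld,
            self.ev, self.par, self.ipar, self.cnt, self.n_bins))

    # manual event wrappers (unit tests / custom drivers)
    def fire_origin(self, b: int, t: float | None = None) -> bool:
        t = self.t_mcs if t is None else t
        return bool(K._fire_origin(
            int(b), float(t), self.pos, self.nb, self.nnb, self.ang,
            self.nang, self.role, self.sc, self.gbin, self.occ,
            self.fork_of_mon, self.f_bin, self.f_dir, self.f_mon,
            self.f_partner, self.f_pair, self.f_alive, self.falive_list,
            self.f_pos_in_list, self.junction_of_bin, self.mat_id,
            self.copy_id, self.rep_time, self.bin_chain, self.chain_first,
            self.chain_last, self.fld, self.ev, self.par, self.ipar,
            self.cnt))

    def advance_fork(self, fi: int, t: float | None = None) -> None:
        if self.f_alive[fi] == 0:
            raise ValueError(f"fork {fi} is not alive")
        t = self.t_mcs if t is None else t
        K._advance_fork(
            int(fi), float(t), self.pos, self.nb, self.nnb, self.ang,
            self.nang, self.role, self.sc, self.gbin, self.occ,
            self.fork_of_mon, self.f_bin, self.f_dir, self.f_mon,
            self.f_partner, self.f_pair, self.f_alive, self.falive_list,
            self.f_pos_in_list, self.junction_of_bin, self.mat_id,
            self.copy_id, self.rep_time, self.bin_chain, self.chain_first,
            self.chain_last, self.fld, self.ev, self.par, self.ipar,
            self.cnt)

    # ------------------------------------------------------------------
    # bookkeeping checks
    # ------------------------------------------------------------------
    def recompute_occupancy(self) -> np.ndarray:
        occ = np.zeros_like(self.occ)
        n = self.n_monomers
        for m in range(n):
            x, y, z = self.pos[m]
            if self.periodic:
                x, y, z = x % self.smod, y % self.smod, z % self.smod
            occ[x, y, z] += 1
        return occ

    def total_energy(self) -> float:
        return float(K._total_energy(
            self.pos, self.nb, self.nnb, self.ang, self.nang, self.role,
            self.fork_of_mon, self.f_mon, self.f_partner, self.f_pair,
            self.f_alive, self.falive_list, self.n_forks, self.par,
            self.n_monomers, self.ipar[K.I_JFON]))

    def check_invariants(self) -> None:
        """Raise on any violated topology/occupancy invariant."""
        n = self.n_monomers
        occ = self.recompute_occupancy()
        if not np.array_equal(occ, self.occ):
            raise AssertionError("occupancy index out of sync")
        if occ.max() > 2:
            raise AssertionError("more than two monomers on one site")
        for m in range(n):
            for k in range(self.nnb[m]):
                w = self.nb[m, k]
                d = self.pos[m] - self.pos[w]
                if int(d @ d) != 2:
                    raise AssertionError("bond is not a nearest-neighbour vector")
                if m not in self.nb[w, :self.nnb[w]]:
                    raise AssertionError("bond table asymmetric")
        deg = self.nnb[:n]
        junctions = np.flatnonzero(self.fork_of_mon[:n] >= 0)
        if not np.all(deg[junctions] == 3):
            raise AssertionError("fork junction without triple connectivity")
        non_j = np.setdiff1d(np.arange(n), junctions)
        if deg[non_j].max(initial=0) > 2:
            raise AssertionError("degree-3 monomer that is not a junction")
        for fi in self.alive_forks():
            pj = self.f_partner[fi]
            if pj >= 0 and self.f_alive[pj] == 0:
                raise AssertionError("paired fork with dead partner")

    def snapshot(self) -> tuple[np.ndarray, np.ndarray]:
        """(positions int16 copy, alive fork monomer ids) for a frame."""
        return (self.pos[:self.n_monomers].astype(np.int16),
                self.f_mon[self.alive_forks()].copy())
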