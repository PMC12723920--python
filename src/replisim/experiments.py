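"""Scaled-down study drivers: reusable in-silico experiments.

Each function runs a self-contained, time-rescaled version of one of the
model's headline measurements at desk scale.  Rescaling multiplies
OriginRate and fork speed and divides the factor-ramp time constant by the
same factor, so the replication program is unchanged on the compressed
time axis; problem sizes are chosen so each driver runs in seconds to a
few minutes on one core.
"""

from __future__ import annotations

import numpy as np

from . import constants as C
from . import contacts as ct
from . import dynamics as dyn
from .engine import SPhaseResult, run_s_phase
from .genome import GenomeSpec
from .kinetics import IPLSTrack
from .nucleus import free_chains, initialize_rabl, relax_to_g1
from .spatial import detect_rfi
from .world import EngineParameters, Trajectory, World


def subset_frames(tr: Trajectory, keep) -> Trajectory:
    """A trajectory view restricted to the given frame indices."""
    t2 = Trajectory(step_nm=tr.step_nm, time_per_mcs_ms=tr.time_per_mcs_ms,
                    gbin=tr.gbin, sc=tr.sc, n_bins=tr.n_bins)
    for k in keep:
        t2.add(tr.times[k], tr.positions[k], tr.fork_monomers[k])
    return t2


def replicated_fraction_per_frame(res: SPhaseResult) -> np.ndarray:
    rt = res.rep_time_mcs
    return np.array([((rt >= 0) & (rt <= t)).mean()
                     for t in res.trajectory.times])


# ---------------------------------------------------------------------------
# time-mapping calibration (reference single-chromosome run)
# ---------------------------------------------------------------------------

def calibration_experiment(seed: int = 0, sweeps: int = 27000,
                           chain_length: int = 1531,
                           box_cells: int = 20) -> float:
    """MSD time calibration on the chromosome-4-sized reference system
    (1531 monomers, ~5% volumic fraction, periodic box); returns ms/MCS."""
    w = free_chains([chain_length], box_cells, EngineParameters(),
                    periodic=True, seed=seed)
    w.run(2000)
    cadence = max(sweeps // 300, 1)
    traj = w.record((sweeps // cadence) * cadence, cadence)
    lags = np.unique(np.round(np.logspace(
        0, np.log10(len(traj) - 2), 24)).astype(int))
    curve = dyn.msd(traj, lags)
    return dyn.calibrate_time_mapping(curve)


# ---------------------------------------------------------------------------
# fountain contrast (single chromosome, three early origins)
# ---------------------------------------------------------------------------

_FOUNTAIN_ORIGINS = np.array([60, 150, 240])


def _fountain_setup(interacting: bool, rescale: float = 400.0):
    spec = GenomeSpec.toy([300])
    vals = np.full(300, 0.02)
    vals[_FOUNTAIN_ORIGINS] = 8.0
    track = IPLSTrack(spec, vals)
    p = EngineParameters(interacting=interacting,
                         n_factors=6).rescaled(rescale)
    p.origin_rate *= 50         # near-synchronous firing of the toy origins
    return spec, track, p


def fountain_runs(interacting: bool, n_traj: int = 5, seed: int = 0,
                  box_cells: int = 24) -> list[SPhaseResult]:
    """S-phase ensemble for one sister-fork scenario on the fountain toy."""
    spec, track, p = _fountain_setup(interacting)
    out = []
    for i in range(n_traj):
        w = free_chains([300], box_cells, p, spec=spec,
                        seed=seed + 10 * i + interacting)
        w.run(2000)
        out.append(run_s_phase(w, track, frame_every_mcs=400,
                               max_minutes=1e9))
    return out


def fountain_strength(runs, window=(0.15, 0.5),
                      r_c_nm: float = C.R_CONTACT_NM) -> tuple[float, int]:
    """Contact enrichment at the expected fork-pair coordinates.

    For every early-window frame and every origin with an intact bubble,
    the observed fork-pair contact (3D junction distance < r_c) is
    compared with the raw contact frequency at the matched genomic
    separation; returns (mean observed / mean expected, sample count).
    """
    spec = GenomeSpec.toy([300])
    cmap = None
    nfr = 0
    for res in runs:
        fr = replicated_fraction_per_frame(res)
        keep = np.flatnonzero((fr >= window[0]) & (fr < window[1]))
        nfr += len(keep)
        sub = ct.contacts_from_frames(subset_frames(res.trajectory, keep),
                                      spec, r_c_nm=r_c_nm)
        cmap = sub if cmap is None else ct.ContactMap(
            sub.bins, (cmap.mat + sub.mat).tocsr(), 1)
    raw = cmap.dense() / max(nfr, 1)
    obs, exp = [], []
    for res in runs:
        tr = res.trajectory
        fr = replicated_fraction_per_frame(res)
        for k in np.flatnonzero((fr >= window[0]) & (fr < window[1])):
            forks = tr.fork_monomers[k]
            bins = tr.gbin[forks]
            pos = tr.positions[k]
            for o in _FOUNTAIN_ORIGINS:
                left = [f for f, b in zip(forks, bins)
                        if b < o and o - b < 45]
                right = [f for f, b in zip(forks, bins)
                         if b > o and b - o < 45]
                if len(left) == 1 and len(right) == 1:
                    s = int(tr.gbin[right[0]] - tr.gbin[left[0]])
                    d = ((pos[left[0]].astype(float) - pos[right[0]])
                         * C.STEP_NM)
                    obs.append(float(np.linalg.norm(d) < r_c_nm))
                    exp.append(float(np.mean(np.diag(raw, s))))
    return float(np.mean(obs) / np.mean(exp)), len(obs)


def fountain_g1_control(seed: int = 999, n_mcs: int = 20000,
                        box_cells: int = 24) -> float:
    """The same statistic on unreplicated (G1) frames, at pseudo-fork
    pixels symmetric about each origin: ~1, no fountain."""
    spec, track, p = _fountain_setup(True)
    w = free_chains([300], box_cells, p, spec=spec, seed=seed)
    w.run(2000)
    g1 = w.record(n_mcs, 400)
    raw = ct.contacts_from_frames(g1, spec).dense() / len(g1)
    rng = np.random.default_rng(seed)
    obs, exp = [], []
    for k in range(len(g1)):
        pos = g1.positions[k]
        for o in _FOUNTAIN_ORIGINS:
            half = int(rng.integers(10, 40))
            a, b = o - half, o + half
            d = (pos[a].astype(float) - pos[b]) * C.STEP_NM
            obs.append(float(np.linalg.norm(d) < C.R_CONTACT_NM))
            exp.append(float(np.mean(np.diag(raw, b - a))))
    return float(np.mean(obs) / np.mean(exp))


# ---------------------------------------------------------------------------
# replication-aligned mobility dip (single origin, gentle rescale)
# ---------------------------------------------------------------------------

def dip_runs(interacting: bool, n_traj: int = 5,
             seed: int = 5000) -> list[SPhaseResult]:
    """Early-S ensemble in the regime where the 15 s-scale lag stays below
    the per-monomer fork residence time (rescale x40)."""
    spec = GenomeSpec.toy([160])
    vals = np.full(160, 0.01)
    vals[80] = 8.0
    track = IPLSTrack(spec, vals)
    p = EngineParameters(interacting=interacting, n_factors=2).rescaled(40)
    p.origin_rate *= 400
    max_min = 250000 * C.TIME_PER_MCS_MS / 60000.0
    out = []
    for i in range(n_traj):
        w = free_chains([160], 15, p, spec=spec,
                        seed=seed + 13 * i + interacting)
        w.run(2000)
        out.append(run_s_phase(w, track, frame_every_mcs=500,
                               max_minutes=max_min))
    return out


def dip_ratio(runs, tau_mcs: float = 4000.0) -> float:
    """SD(t=0) / SD(pre-replication baseline) for the dip ensemble."""
    cad_min = 500 * C.TIME_PER_MCS_MS / 60000.0
    ids = np.arange(40, 121)
    s = dyn.aligned_sd(runs, tau_s=tau_mcs * C.TIME_PER_MCS_MS / 1000.0,
                       ids=ids, bin_min=cad_min * 6)
    t, v = s.t_rel_min, s.sd_nm2
    at0 = np.nanmean(v[np.abs(t) < cad_min * 6])
    base = np.nanmean(v[(t > -0.45) & (t < -0.12)])
    return float(at0 / base)


# ---------------------------------------------------------------------------
# full-genome G1 nucleus and its contact signature
# ---------------------------------------------------------------------------

def g1_nucleus(seed: int = 0, relax_sweeps: int = 15000,
               params: EngineParameters | None = None,
               spec: GenomeSpec | None = None) -> World:
    """Equilibrated Rabl nucleus (centromere-seeded build + relaxation)."""
    spec = spec or GenomeSpec.builtin()
    w = initialize_rabl(spec, params or EngineParameters(), seed=seed)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        relax_to_g1(w, relax_sweeps, monitor_every=relax_sweeps)
    return w


def centromere_contact_percentage(world: World, record_mcs: int = 8000,
                                  frame_every: int = 200) -> float:
    """Mean centromere-centromere trans contact frequency as a percentage
    of P_intra(10 kb), from frames of the equilibrated G1 nucleus."""
    spec = world.spec
    traj = world.record(record_mcs, frame_every)
    bal = ct.ice_balance(ct.contacts_from_frames(traj, spec))
    ps = ct.expected_cis(bal)
    cen = spec.centromere_bins()
    chrom = spec.bin_chrom[cen]
    vals = bal.balanced_values()
    pairs = []
    for i in range(len(cen)):
        for j in range(i + 1, len(cen)):
            if chrom[i] != chrom[j]:
                pairs.append(vals[cen[i], cen[j]])
    return float(np.mean(pairs) / ps.at(10.0) * 100.0)


def early_s_rfi(world: World, track: IPLSTrack, rescale: float = 300.0,
                theta_nm: float = C.RFI_THETA_DEFAULT_NM,
                fork_window=(200, 240), max_mcs: int = 40000,
                frame_every: int = 400):
    """Run early S-phase on a G1 nucleus (time-rescaled) and count
    replication foci in frames whose live fork count falls inside
    ``fork_window`` (matching the microscopy comparison window).

    Returns (mean focus count, fork counts used, clusterings)."""
    world.params = world.params.rescaled(rescale)
    world._pack_parameters()
    res = run_s_phase(world, track, frame_every_mcs=frame_every,
                      max_minutes=max_mcs * C.TIME_PER_MCS_MS / 60000.0)
    tr = res.trajectory
    counts, clusterings, forks_used = [], [], []
    for k in range(len(tr)):
        forks = tr.fork_monomers[k]
        if not (fork_window[0] <= len(forks) <= fork_window[1]):
            continue
        pos = tr.positions[k][forks].astype(float) * tr.step_nm
        cl = detect_rfi(pos, theta_nm)
        clusterings.append(cl)
        counts.append(cl.n_clusters)
        forks_used.append(len(forks))
    mean = float(np.mean(counts)) if counts else float("nan")
    return mean, np.asarray(forks_used), clusterings
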