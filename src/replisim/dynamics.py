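"""Chromatin mobility statistics: MSD, time calibration, aligned SD.

All dynamics observables are computed on the Sister Chromatid 1 copy of
each locus (for replicated loci the maternal monomer, which exists at all
times).  The physical time axis comes from matching the simulated monomer
MSD to the experimentally observed law ``MSD(tau) ~ 0.01 tau^1/2 um^2``
(tau in seconds), which fixes 1 MCS = 0.075 ms at the reference move set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as C


@dataclass
class MSDCurve:
    """Ensemble/time-averaged mean squared displacement."""

    lag_mcs: np.ndarray
    msd_nm2: np.ndarray
    time_per_mcs_ms: float = C.TIME_PER_MCS_MS

    @property
    def lag_s(self) -> np.ndarray:
        return self.lag_mcs * self.time_per_mcs_ms / 1000.0

    @property
    def msd_um2(self) -> np.ndarray:
        return self.msd_nm2 / 1e6

    def fit_exponent(self, window=None) -> tuple[float, float]:
        """Power-law fit MSD = A * lag^b over a lag window (in MCS);
        returns (A, b) with lag in MCS and MSD in nm^2."""
        lag = self.lag_mcs
        m = self.msd_nm2
        keep = (lag > 0) & (m > 0)
        if window is not None:
            keep &= (lag >= window[0]) & (lag <= window[1])
        if keep.sum() < 2:
            raise ValueError("not enough points to fit")
        b, loga = np.polyfit(np.log(lag[keep]), np.log(m[keep]), 1)
        return float(np.exp(loga)), float(b)


def _trim(traj, n_keep):
    from .world import Trajectory
    t2 = Trajectory(step_nm=traj.step_nm,
                    time_per_mcs_ms=traj.time_per_mcs_ms, gbin=traj.gbin,
                    sc=traj.sc, n_bins=traj.n_bins)
    for k in range(min(n_keep, len(traj.times))):
        t2.add(traj.times[k], traj.positions[k], traj.fork_monomers[k])
    return t2


def _stack_positions(traj, ids):
    pos = np.stack([p[ids].astype(float) for p in traj.positions])
    return pos * traj.step_nm


def msd(trajs, lag_frames, ids=None, time_per_mcs_ms=None) -> MSDCurve:
    """MSD over frame lags, averaged over start frames, monomers and
    trajectories.

    ``ids`` selects the monomer scope (default: all SC1 loci, present at
    every frame).  Frames must be at uniform cadence; lags exceeding a
    trajectory are dropped with a warning.
    """
    if not isinstance(trajs, (list, tuple)):
        trajs = [trajs]
    t0 = trajs[0]
    if time_per_mcs_ms is None:
        time_per_mcs_ms = t0.time_per_mcs_ms
    times = np.asarray(t0.times)
    if len(times) < 2:
        raise ValueError("need at least two frames")
    cadence = times[1] - times[0]
    gaps = np.diff(times)
    if not np.allclose(gaps, cadence):
        # a final frame may land off-cadence (e.g. at completion of
        # replication); use the longest uniform prefix
        bad = np.flatnonzero(~np.isclose(gaps, cadence))
        n_keep = int(bad[0]) + 1
        if n_keep < 3:
            raise ValueError("frames are not at uniform cadence")
        warnings.warn(f"trimming {len(times) - n_keep} off-cadence trailing "
                      "frames", stacklevel=2)
        trajs = [_trim(t, n_keep) for t in trajs]
        t0 = trajs[0]
        times = np.asarray(t0.times)
    lag_frames = np.asarray(lag_frames, dtype=int)
    usable = lag_frames[lag_frames < len(times)]
    if len(usable) < len(lag_frames):
        warnings.warn(f"dropped {len(lag_frames) - len(usable)} lags longer "
                      "than the trajectory", stacklevel=2)
    out = np.zeros(len(usable))
    norm = np.zeros(len(usable))
    for traj in trajs:
        if ids is None:
            sel = np.arange(traj.n_bins)
        else:
            sel = np.asarray(ids, dtype=int)
        pos = _stack_positions(traj, sel)        # (F, n, 3) nm
        for k, lf in enumerate(usable):
            if lf == 0:
                norm[k] += 1
                continue
            d = pos[lf:] - pos[:-lf]
            out[k] += np.mean(np.sum(d * d, axis=2))
            norm[k] += 1
    msd_vals = out / np.maximum(norm, 1)
    return MSDCurve(usable * cadence, msd_vals, time_per_mcs_ms)


def calibrate_time_mapping(curve: MSDCurve,
                           prefactor_um2: float = C.MSD_EXP_PREFACTOR_UM2,
                           tau_window_s=(0.1, 1.0),
                           max_iter: int = 60) -> float:
    """Physical time per MCS (ms) from matching the simulated MSD to the
    experimentally observed law ``prefactor * tau^1/2`` um^2 (tau in s).

    With ``MSD_sim = A tau_MCS^1/2`` um^2 the mapping is
    ``dt = (A / prefactor)^2`` seconds per MCS.  The fixed-exponent fit is
    taken over the lag range corresponding to the physical timescales
    where the experimental law was measured (``tau_window_s``); since that
    window is set in physical units, the fit is iterated to a fixed point
    of the window <-> dt relation.  Warns if the free-exponent fit on the
    final window falls outside [0.4, 0.6].
    """
    lag = curve.lag_mcs.astype(float)
    m = curve.msd_um2
    keep = (lag > 0) & (m > 0)
    lag, m = lag[keep], m[keep]
    if len(lag) < 3:
        raise ValueError("curve too short to calibrate")
    ll, lm = np.log(lag), np.log(m)
    # initial estimate: fixed-exponent fit over all lags
    dt_s = (np.exp(np.mean(lm - 0.5 * ll)) / prefactor_um2) ** 2
    win = np.ones(len(lag), bool)
    for _ in range(max_iter):
        lo = tau_window_s[0] / dt_s
        hi = tau_window_s[1] / dt_s
        win = (lag >= lo) & (lag <= hi)
        if win.sum() < 3:
            # curve does not reach the physical window; use the closest
            # decade of available lags
            warnings.warn("MSD curve barely covers the calibration window;"
                          " using the longest available lags", stacklevel=2)
            win = lag >= lag.max() / 10.0
        a = np.exp(np.mean(lm[win] - 0.5 * ll[win]))
        dt_new = (a / prefactor_um2) ** 2
        if abs(dt_new - dt_s) <= 1e-12 + 1e-6 * dt_s:
            dt_s = dt_new
            break
        dt_s = dt_new
    bfit = np.polyfit(ll[win], lm[win], 1)[0]
    if not (0.4 <= bfit <= 0.6):
        warnings.warn(f"fitted exponent {bfit:.2f} outside [0.4, 0.6] on "
                      "the calibration window", stacklevel=2)
    return float(dt_s * 1000.0)


# ---------------------------------------------------------------------------
# replication-aligned squared displacement
# ---------------------------------------------------------------------------

@dataclass
class AlignedSDSeries:
    """SD(t, tau) averaged per time bin relative to each locus's
    replication instant (t = 0)."""

    t_rel_min: np.ndarray
    sd_nm2: np.ndarray
    counts: np.ndarray
    tau_s: float
    n_excluded_loci: int = 0


def aligned_sd(results, tau_s: float = C.SD_LAG_S, ids=None,
               bin_min: float | None = None) -> AlignedSDSeries:
    """Replication-time-aligned squared displacement at lag tau.

    ``results`` are S-phase results (trajectory + per-locus replication
    times).  For every SC1 locus, SD(t) = |r(t + tau) - r(t)|^2 is shifted
    so that the locus's replication instant sits at t = 0, then averaged
    over loci and trajectories in time bins (default: the frame cadence).
    Loci never replicated in a trajectory are excluded and counted.
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    first = results[0].trajectory
    dt_ms = first.time_per_mcs_ms
    times = np.asarray(first.times)
    cadence_mcs = times[1] - times[0]
    lag_frames = int(round(tau_s * 1000.0 / dt_ms / cadence_mcs))
    if lag_frames < 1:
        raise ValueError("tau shorter than the frame cadence")
    cadence_min = cadence_mcs * dt_ms / 60_000.0
    if bin_min is None:
        bin_min = cadence_min
    rel_all, sd_all = [], []
    excluded = 0
    for res in results:
        traj = res.trajectory
        gaps = np.diff(traj.times)
        if len(gaps) and not np.allclose(gaps, gaps[0]):
            bad = np.flatnonzero(~np.isclose(gaps, gaps[0]))
            traj = _trim(traj, int(bad[0]) + 1)
        if ids is None:
            sel = np.arange(traj.n_bins)
        else:
            sel = np.asarray(ids, dtype=int)
        rep = res.rep_time_mcs[sel]
        good = rep >= 0
        excluded += int((~good).sum())
        sel = sel[good]
        rep = rep[good]
        pos = _stack_positions(traj, sel)
        t = np.asarray(traj.times)
        d = pos[lag_frames:] - pos[:-lag_frames]
        sd = np.sum(d * d, axis=2)               # (F - lag, n)
        trel = (t[:-lag_frames, None] - rep[None, :]) * dt_ms / 60_000.0
        rel_all.append(trel.ravel())
        sd_all.append(sd.ravel())
    rel = np.concatenate(rel_all)
    sd = np.concatenate(sd_all)
    lo = np.floor(rel.min() / bin_min) * bin_min
    hi = np.ceil(rel.max() / bin_min) * bin_min + bin_min
    edges = np.arange(lo, hi, bin_min)
    which = np.digitize(rel, edges) - 1
    nb = len(edges) - 1
    sums = np.bincount(which, weights=sd, minlength=nb)[:nb]
    counts = np.bincount(which, minlength=nb)[:nb]
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = edges[:-1] + bin_min / 2.0
    return AlignedSDSeries(centers, mean, counts, tau_s, excluded)
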