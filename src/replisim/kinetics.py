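"""1D replication kinetics: IPLS tracks, origin sampling and firing dynamics.

Replication initiation is a bimolecular reaction between a limiting pool of
``N_f`` firing factors and a multiset of potential origins (p-oris) drawn,
with replacement, proportionally to the Initiation Probability Landscape
Signal (IPLS, 1 kb bins).  Each unreplicated p-ori entry undergoes one
firing trial per MCS with probability
``(N_f(t) - N_forks/2) * OriginRate``; forks then progress at constant
average speed.  These dynamics have no feedback from 3D, so a 1D-only
ensemble reproduces the coupled engine's replication timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from . import _kernels as K
from . import constants as C
from .genome import GenomeSpec
from .world import EngineParameters


class IPLSTrack:
    """Non-negative initiation-propensity signal, one value per 1 kb bin."""

    def __init__(self, spec: GenomeSpec, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (spec.n_monomers,):
            raise ValueError(
                f"track length {values.shape} does not match the genome "
                f"({spec.n_monomers} bins)")
        if (values < 0).any() or not np.isfinite(values).all():
            raise ValueError("IPLS values must be finite and non-negative")
        self.spec = spec
        self.values = values

    def chromosome(self, chrom: str) -> np.ndarray:
        idx = self.spec.chroms.index(chrom)
        return self.values[self.spec.bin_chrom == idx]

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class OriginClassification:
    """Peak positions of an IPLS split into early and late origin classes."""

    peaks: np.ndarray            # global bins of all detected peaks
    heights: np.ndarray
    early: np.ndarray            # top 15% by height, signal > 5
    late: np.ndarray             # remaining peaks with signal > 1

    @property
    def n_origins(self) -> int:
        return int(len(self.early) + len(self.late))


def available_factors(t_mcs: float, n_forks: int,
                      params: EngineParameters) -> float:
    """Free firing factors max(0, N_f(t) - N_forks/2); the total pool ramps
    in as N_f (1 - 0.13 exp(-t/tau)) with tau = 90 s."""
    if t_mcs < 0:
        raise ValueError("time must be >= 0")
    nf_t = params.n_factors * (1.0 - params.ramp_amplitude
                               * np.exp(-t_mcs / params.ramp_tau_mcs))
    return max(0.0, nf_t - n_forks / 2.0)


def firing_probability(t_mcs: float, n_forks: int,
                       params: EngineParameters) -> float:
    """Per-trial firing probability (N_f - N_forks/2) * OriginRate, in [0, 1]."""
    p = available_factors(t_mcs, n_forks, params) * params.origin_rate
    return float(min(max(p, 0.0), 1.0))


def fork_step_probability(v_kb_min: float = C.FORK_SPEED_KB_MIN,
                          time_per_mcs_ms: float = C.TIME_PER_MCS_MS) -> float:
    """Per-MCS probability for a fork to replicate one monomer (~3e-6)."""
    return C.fork_step_probability(v_kb_min, time_per_mcs_ms)


# ---------------------------------------------------------------------------
# origin sampling and classification
# ---------------------------------------------------------------------------

def sample_p_oris(track: IPLSTrack, rng,
                  per_kb: float = C.PORI_PER_KB) -> np.ndarray:
    """Draw the p-ori multiset: floor(L/5) draws with replacement per
    chromosome, with per-monomer probability proportional to the IPLS.

    Returns global bins, with multiplicity (a bin drawn m times carries
    m independent firing trials)."""
    spec = track.spec
    out = []
    for idx, name in enumerate(spec.chroms):
        mask = spec.bin_chrom == idx
        w = track.values[mask]
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"IPLS is all-zero on {name}")
        n_draw = int(mask.sum() * per_kb)
        bins = np.flatnonzero(mask)
        out.append(rng.choice(bins, size=n_draw, replace=True, p=w / tot))
    return np.concatenate(out)


def classify_origins(track: IPLSTrack,
                     top_fraction: float = C.EARLY_TOP_FRACTION,
                     early_min: float = C.EARLY_MIN_SIGNAL,
                     late_min: float = C.LATE_MIN_SIGNAL) -> OriginClassification:
    """Detect IPLS peaks and split them into early and late origins.

    A peak is a strict local maximum (plateaus count once, at their leftmost
    bin).  Early origins are the top ``top_fraction`` of peaks by height
    that also exceed ``early_min``; the remaining peaks above ``late_min``
    are late origins.
    """
    spec = track.spec
    peaks = []
    heights = []
    for idx in range(len(spec.chroms)):
        mask = spec.bin_chrom == idx
        sig = track.values[mask]
        offset = np.flatnonzero(mask)[0]
        loc, props = find_peaks(sig, plateau_size=1)
        left = props["left_edges"]
        peaks.append(left + offset)
        heights.append(sig[left])
    peaks = np.concatenate(peaks) if peaks else np.zeros(0, int)
    heights = np.concatenate(heights) if heights else np.zeros(0)
    if len(peaks) == 0:
        z = np.zeros(0, dtype=int)
        return OriginClassification(peaks, heights, z, z)
    k = int(round(top_fraction * len(peaks)))
    if k > 0:
        cut = np.sort(heights)[::-1][min(k, len(peaks)) - 1]
        early_mask = (heights >= cut) & (heights > early_min)
    else:
        early_mask = np.zeros(len(peaks), bool)
    late_mask = ~early_mask & (heights > late_min)
    order = np.argsort(peaks)
    peaks, heights = peaks[order], heights[order]
    early_mask, late_mask = early_mask[order], late_mask[order]
    return OriginClassification(peaks, heights, peaks[early_mask],
                                peaks[late_mask])


def synthetic_ipls(spec: GenomeSpec, n_early: int = 111, n_late: int = 615,
                   early_heights: tuple = (6.0, 15.0),
                   late_heights: tuple = (1.2, 4.8),
                   background: float = 0.05,
                   early_near_cen_frac: float = 0.5,
                   early_cen_window_kb: int = 100,
                   min_separation: int = 5, edge_margin: int = 3,
                   seed: int = 0):
    """Generate a sparse, peaky IPLS emulating the inferred yeast landscape.

    Plants ``n_early`` single-bin peaks with signal > 5 (a fraction of them
    centromere-proximal, as observed for early origins) and ``n_late``
    peaks with signal in (1, 5], over a weak non-negative background.
    Defaults mirror the published landscape summary (726 origins: 111
    early, 615 late over ~12 Mb).

    Returns ``(track, ground_truth)`` with the planted early/late bins.
    """
    rng = np.random.default_rng(seed)
    G = spec.n_monomers
    n_total = n_early + n_late
    # candidate bins keep away from chain ends and from each other
    allowed = np.ones(G, bool)
    for ci in range(spec.n_chains):
        b0, b1 = spec.chain_first[ci], spec.chain_last[ci]
        allowed[b0:b0 + edge_margin] = False
        allowed[b1 - edge_margin + 1:b1 + 1] = False
    if n_total * min_separation > allowed.sum():
        raise ValueError("too many peaks requested for this genome")

    cen = spec.centromere_bins()
    weights = np.ones(G)
    near_cen = np.zeros(G, bool)
    for cb in cen:
        lo = max(0, cb - early_cen_window_kb)
        hi = min(G, cb + early_cen_window_kb + 1)
        near_cen[lo:hi] = True

    taken = np.zeros(G, bool)

    def _draw(n, prefer_near_cen):
        if n <= 0:
            return np.zeros(0, dtype=int)
        chosen = []
        pool_mask = allowed & ~taken
        if prefer_near_cen:
            pool = np.flatnonzero(pool_mask & near_cen)
        else:
            pool = np.flatnonzero(pool_mask)
        rng.shuffle(pool)
        for b in pool:
            if taken[max(0, b - min_separation):b + min_separation + 1].any():
                continue
            if not allowed[b]:
                continue
            chosen.append(b)
            taken[b] = True
            if len(chosen) == n:
                break
        if len(chosen) < n:
            raise ValueError("could not place all requested peaks")
        return np.array(sorted(chosen), dtype=int)

    n_cen = int(round(early_near_cen_frac * n_early))
    early_bins = np.sort(np.concatenate([
        _draw(n_cen, True), _draw(n_early - n_cen, False)]))
    late_bins = _draw(n_late, False)

    values = rng.uniform(0.0, background, size=G)
    values[early_bins] = rng.uniform(*early_heights, size=n_early)
    values[late_bins] = rng.uniform(*late_heights, size=n_late)
    # keep planted peaks strict local maxima over the background
    for b in np.concatenate([early_bins, late_bins]):
        for d in (-1, 1):
            if 0 <= b + d < G and values[b + d] >= values[b]:
                values[b + d] = values[b] * 0.5
    track = IPLSTrack(spec, values)
    truth = {"early": early_bins, "late": late_bins}
    return track, truth


# ---------------------------------------------------------------------------
# 1D ensemble runner
# ---------------------------------------------------------------------------

@dataclass
class Ensemble1D:
    """Result of a 1D-only replication ensemble."""

    spec: GenomeSpec
    params: EngineParameters
    rep_times: np.ndarray        # (n_traj, G) in MCS, NaN where unreplicated
    fork_logs: list = field(repr=False, default_factory=list)
    events: list = field(repr=False, default_factory=list)

    @property
    def mrt_min(self) -> np.ndarray:
        """Mean replication time per locus, minutes."""
        return (np.nanmean(self.rep_times, axis=0)
                * self.params.time_per_mcs_ms / 60_000.0)

    @property
    def durations_min(self) -> np.ndarray:
        """S-phase duration per trajectory (time of last replicated locus),
        minutes; NaN for trajectories that did not finish."""
        full = ~np.isnan(self.rep_times).any(axis=1)
        out = np.full(len(self.rep_times), np.nan)
        out[full] = (self.rep_times[full].max(axis=1)
                     * self.params.time_per_mcs_ms / 60_000.0)
        return out

    @property
    def replicated_fraction(self) -> float:
        return float(1.0 - np.isnan(self.rep_times).mean())

    @property
    def rfd(self) -> np.ndarray:
        """Replication fork directionality per locus in [-1, 1]: the mean
        sign of the replication-time gradient (+1 where rightward forks
        always replicate the locus, -1 for leftward)."""
        spec = self.spec
        out = np.zeros(spec.n_monomers)
        for ci in range(spec.n_chains):
            b0 = int(spec.chain_first[ci])
            b1 = int(spec.chain_last[ci])
            seg = self.rep_times[:, b0:b1 + 1]
            grad = np.gradient(seg, axis=1)
            with np.errstate(invalid="ignore"):
                out[b0:b1 + 1] = np.nanmean(np.sign(grad), axis=0)
        return out


def run_1d_ensemble(track: IPLSTrack, params: EngineParameters | None = None,
                    n_traj: int = 10, seed: int = 0,
                    max_minutes: float = 120.0) -> Ensemble1D:
    """Simulate ``n_traj`` independent 1D S-phases on one IPLS.

    Each trajectory draws a fresh p-ori multiset at S-phase entry, then runs
    the firing/progression/merging dynamics until full replication (or the
    time budget)."""
    params = params or EngineParameters()
    spec = track.spec
    rng = np.random.default_rng(seed)
    G = spec.n_monomers
    n_mcs_max = max_minutes * 60.0 * params.mcs_per_s
    rep = np.full((n_traj, G), np.nan)
    fork_logs = []
    events = []
    for it in range(n_traj):
        pori = sample_p_oris(track, rng)
        rep_time = np.full(G, -1.0)
        junction = np.full(G, -1, dtype=np.int64)
        cap = 4 * len(pori) + 64
        log_t = np.zeros(cap)
        log_n = np.zeros(cap, dtype=np.int64)
        ev = np.zeros((cap, 3))
        t_end, nrep, nev, nlog = K.run_1d(
            int(rng.integers(2**31 - 1)), float(n_mcs_max), rep_time,
            junction, spec.bin_chain.astype(np.int64),
            spec.chain_first.astype(np.int64),
            spec.chain_last.astype(np.int64),
            pori.astype(np.int64).copy(), len(pori),
            float(params.n_factors), float(params.ramp_amplitude),
            float(params.ramp_tau_mcs), float(params.origin_rate),
            float(params.fork_step_probability),
            log_t, log_n, ev)
        rep[it] = np.where(rep_time >= 0, rep_time, np.nan)
        fork_logs.append((log_t[:nlog].copy(), log_n[:nlog].copy()))
        events.append(ev[:nev].copy())
    return Ensemble1D(spec, params, rep, fork_logs, events)
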