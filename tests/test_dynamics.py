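"""Mobility statistics: MSD, time-mapping calibration, aligned SD."""

import numpy as np
import pytest

from replisim import EngineParameters
from replisim import constants as C
from replisim import dynamics as dyn
from replisim.engine import SPhaseResult
from replisim.genome import GenomeSpec
from replisim.nucleus import free_chains
from replisim.world import Trajectory
from replisim import _kernels as K


def synthetic_traj(positions, cadence_mcs=100.0, n_bins=None):
    n_bins = n_bins if n_bins is not None else positions[0].shape[0]
    tr = Trajectory(gbin=np.arange(n_bins), sc=None, n_bins=n_bins)
    for i, p in enumerate(positions):
        tr.add(i * cadence_mcs, np.asarray(p, dtype=np.int16),
               np.zeros(0, dtype=int))
    return tr


class TestMSD:
    def test_frozen_trajectory_is_zero(self):
        pos = [np.zeros((5, 3))] * 20
        curve = dyn.msd(synthetic_traj(pos), [1, 3, 7])
        assert (curve.msd_nm2 == 0).all()

    def test_single_free_monomer_is_diffusive(self):
        """A free monomer random-walks: MSD linear in lag with slope equal
        to acceptance rate x step variance (analytic random-walk oracle on
        the same move set)."""
        w = free_chains([1], 8, EngineParameters(), periodic=True, seed=3)
        traj = w.record(20000, 10)
        acc = w.cnt[K.C_ACC] / w.cnt[K.C_TRIALS]
        lags = np.array([1, 2, 4, 8, 16, 32])
        curve = dyn.msd(traj, lags)
        _, b = curve.fit_exponent()
        assert b == pytest.approx(1.0, abs=0.05)
        slope = curve.msd_nm2[0] / curve.lag_mcs[0]
        assert slope == pytest.approx(acc * C.SIGMA_NM ** 2, rel=0.1)

    def test_chain_interior_is_subdiffusive(self):
        """Interior monomers of a long chain show the Rouse-like regime
        (exponent near 0.5) between the stiffness crossover and terminal
        relaxation."""
        w = free_chains([400], 14, EngineParameters(), periodic=True, seed=5)
        w.run(2000)
        traj = w.record(40000, 200)
        lags = np.unique(np.round(np.logspace(0, np.log10(190),
                                              16)).astype(int))
        curve = dyn.msd(traj, lags, ids=np.arange(100, 300))
        _, b = curve.fit_exponent(window=(12000, 40000))
        assert 0.4 <= b <= 0.6

    def test_overlong_lags_dropped_with_warning(self):
        pos = [np.zeros((3, 3))] * 5
        with pytest.warns(UserWarning):
            curve = dyn.msd(synthetic_traj(pos), [1, 2, 50])
        assert len(curve.lag_mcs) == 2


class TestTimeCalibration:
    def test_inverse_construction_recovers_reference(self):
        """A curve built as 0.01 sqrt(7.5e-5) tau_MCS^1/2 um^2 calibrates
        to exactly 0.075 ms per MCS."""
        lag = np.unique(np.round(np.logspace(0.5, 4, 30)).astype(int))
        a = 0.01 * np.sqrt(7.5e-5)
        msd_um2 = a * np.sqrt(lag)
        curve = dyn.MSDCurve(lag, msd_um2 * 1e6)
        assert dyn.calibrate_time_mapping(curve) == pytest.approx(0.075,
                                                                  rel=1e-6)

    def test_doubling_prefactor_quadruples_dt(self):
        lag = np.unique(np.round(np.logspace(0.5, 4, 30)).astype(int))
        a = 0.01 * np.sqrt(7.5e-5)
        c1 = dyn.MSDCurve(lag, a * np.sqrt(lag) * 1e6)
        c2 = dyn.MSDCurve(lag, 2 * a * np.sqrt(lag) * 1e6)
        assert (dyn.calibrate_time_mapping(c2)
                == pytest.approx(4 * dyn.calibrate_time_mapping(c1),
                                 rel=1e-6))


class TestAlignedSD:
    def _random_walk(self, rng, n_frames, n_loci, step):
        steps = rng.normal(0, step, (n_frames, n_loci, 3))
        return np.cumsum(steps, axis=0)

    def test_constant_mobility_is_flat(self):
        rng = np.random.default_rng(0)
        pos = self._random_walk(rng, 300, 40, 1.0)
        tr = synthetic_traj(list(pos))
        rep = np.linspace(5000, 25000, 40)
        res = SPhaseResult(tr, rep, np.zeros((0, 3)), np.zeros(0), True,
                           None)
        series = dyn.aligned_sd([res], tau_s=100 * 0.075 / 1000.0,
                                bin_min=0.01)
        good = series.counts > 200
        vals = series.sd_nm2[good]
        assert vals.std() / vals.mean() < 0.25

    def test_planted_dip_recovered_at_alignment(self):
        """Mobility dips injected at known per-locus times appear at t=0
        after alignment and are invisible without alignment."""
        rng = np.random.default_rng(1)
        n_frames, n_loci = 400, 60
        rep = rng.uniform(8000, 30000, n_loci)
        steps = rng.normal(0, 1.0, (n_frames, n_loci, 3))
        t = np.arange(n_frames)[:, None] * 100.0
        dip = np.abs(t - rep[None, :]) < 1000.0       # +-10 frames
        steps[dip[:, :, None].repeat(3, axis=2)] *= 0.3
        pos = np.cumsum(steps, axis=0)
        tr = synthetic_traj(list(pos))
        res = SPhaseResult(tr, rep, np.zeros((0, 3)), np.zeros(0), True,
                           None)
        series = dyn.aligned_sd([res], tau_s=200 * 0.075 / 1000.0,
                                bin_min=100 * 0.075 / 60000.0)
        t0 = np.nanargmin(np.abs(series.t_rel_min))
        good = series.counts > 20
        base = np.nanmean(series.sd_nm2[good & (series.t_rel_min < -0.003)])
        assert series.sd_nm2[t0] < 0.4 * base
        # without alignment the per-frame average shows no comparable dip
        sd_all = np.sum((pos[2:] - pos[:-2]) ** 2, axis=2).mean(axis=1)
        assert sd_all.min() > 0.4 * np.median(sd_all)

    def test_never_replicated_loci_excluded(self):
        rng = np.random.default_rng(2)
        pos = self._random_walk(rng, 100, 10, 1.0)
        rep = np.full(10, -1.0)
        rep[:4] = 2000.0
        res = SPhaseResult(synthetic_traj(list(pos)), rep, np.zeros((0, 3)),
                           np.zeros(0), True, None)
        series = dyn.aligned_sd([res], tau_s=100 * 0.075 / 1000.0)
        assert series.n_excluded_loci == 6


class TestReplicationSlowsChromatin:
    def test_post_replication_msd_below_g1(self, dyn_data):
        lags = [5, 10, 15]
        g1 = np.mean([dyn.msd(t, lags).msd_nm2
                      for t in dyn_data[True]["g1"] + dyn_data[False]["g1"]],
                     axis=0)
        post = np.mean([dyn.msd(t, lags).msd_nm2
                        for t in dyn_data[True]["post"]
                        + dyn_data[False]["post"]], axis=0)
        assert (post < g1).all()

    def test_aligned_dip_at_replication(self, dyn_data):
        """Fork passage transiently reduces mobility: SD(t) dips at t=0."""
        cad_min = 250 * 0.075 / 60000.0
        tau = 2000 * 0.075 / 1000.0
        ids = np.concatenate([np.arange(8, 60), np.arange(140, 192)])
        for interacting in (True, False):
            s = dyn.aligned_sd(dyn_data[interacting]["s"], tau_s=tau,
                               ids=ids, bin_min=cad_min * 4)
            t, v = s.t_rel_min, s.sd_nm2
            at0 = np.nanmean(v[np.abs(t) < cad_min * 4])
            base = np.nanmean(v[(t > -0.2) & (t < -0.06)])
            assert at0 < 0.8 * base

    def test_dip_deeper_for_interacting_forks(self, dip_data):
        """With the lag below the fork residence time, the pairing spring
        visibly deepens the mobility dip at replication."""
        cad_min = 500 * 0.075 / 60000.0
        tau = 4000 * 0.075 / 1000.0
        ratios = {}
        for interacting in (True, False):
            s = dyn.aligned_sd(dip_data[interacting], tau_s=tau,
                               ids=dip_data["ids"], bin_min=cad_min * 6)
            t, v = s.t_rel_min, s.sd_nm2
            at0 = np.nanmean(v[np.abs(t) < cad_min * 6])
            base = np.nanmean(v[(t > -0.45) & (t < -0.12)])
            ratios[interacting] = at0 / base
        assert ratios[True] < 0.5          # a strong dip is present
        assert ratios[True] < 0.9 * ratios[False]
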