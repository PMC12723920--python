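"""1D replication kinetics: firing law, p-ori sampling, origin classes."""

import numpy as np
import pytest

from replisim import (EngineParameters, IPLSTrack, available_factors,
                      classify_origins, firing_probability,
                      fork_step_probability, run_1d_ensemble, sample_p_oris,
                      synthetic_ipls)
from replisim.genome import GenomeSpec


class TestFiringLaw:
    def test_factor_pool_limits(self):
        p = EngineParameters()
        assert available_factors(1e12, 0, p) == pytest.approx(120.0)
        assert available_factors(0.0, 0, p) == pytest.approx(104.4)
        assert available_factors(1e12, 2 * 120, p) == 0.0

    def test_firing_probability_values(self):
        p = EngineParameters()
        assert firing_probability(1e12, 0, p) == pytest.approx(1.2e-7)
        assert firing_probability(1e12, 240, p) == 0.0
        p2 = EngineParameters(origin_rate=2e-9)
        assert firing_probability(1e12, 0, p2) == pytest.approx(2.4e-7)

    def test_fork_step_probability(self):
        # 2.2 kb/min at 0.075 ms/MCS is 2.75e-6 per MCS (~3e-6)
        assert fork_step_probability() == pytest.approx(2.75e-6)
        assert fork_step_probability(0.0) == 0.0
        assert fork_step_probability(2.2, 0.15) == pytest.approx(5.5e-6)


class TestPOriSampling:
    def test_draw_count_rule(self):
        spec = GenomeSpec.toy([1000])
        track = IPLSTrack(spec, np.ones(1000))
        rng = np.random.default_rng(0)
        assert len(sample_p_oris(track, rng)) == 200

    def test_single_nonzero_bin(self):
        spec = GenomeSpec.toy([100])
        vals = np.zeros(100)
        vals[37] = 2.0
        track = IPLSTrack(spec, vals)
        draws = sample_p_oris(track, np.random.default_rng(0))
        assert (draws == 37).all()

    def test_uniform_track_uniform_draws(self):
        spec = GenomeSpec.toy([200])
        track = IPLSTrack(spec, np.ones(200))
        rng = np.random.default_rng(1)
        draws = np.concatenate([sample_p_oris(track, rng)
                                for _ in range(200)])
        freq = np.bincount(draws, minlength=200) / len(draws)
        # multinomial sampling error around 1/200
        assert freq.std() < 3.0 / 200

    def test_zero_track_rejected(self):
        spec = GenomeSpec.toy([50])
        track = IPLSTrack(spec, np.zeros(50))
        with pytest.raises(ValueError):
            sample_p_oris(track, np.random.default_rng(0))


class TestOriginClassification:
    def test_flat_track_has_no_peaks(self):
        spec = GenomeSpec.toy([100])
        cls = classify_origins(IPLSTrack(spec, np.ones(100)))
        assert cls.n_origins == 0

    def test_threshold_rules_on_toy_peaks(self):
        # 22 isolated peaks: 20 of height 1.5, one of 6 and one of 2;
        # the height-6 peak is within the top 15% and above 5 (early),
        # the height-2 peak is late, as are the 1.5s
        spec = GenomeSpec.toy([300])
        vals = np.zeros(300)
        pos = np.arange(10, 10 + 22 * 10, 10)
        heights = np.full(22, 1.5)
        heights[3] = 6.0
        heights[11] = 2.0
        vals[pos] = heights
        cls = classify_origins(IPLSTrack(spec, vals))
        assert list(cls.early) == [pos[3]]
        assert len(cls.late) == 21
        assert pos[11] in cls.late

    def test_plateaus_resolve_leftmost(self):
        spec = GenomeSpec.toy([60])
        vals = np.zeros(60)
        vals[20:23] = 7.0       # 3-bin plateau
        cls = classify_origins(IPLSTrack(spec, vals))
        assert list(cls.peaks) == [20]


class TestSyntheticIPLS:
    def test_planted_counts_recovered_exactly(self):
        spec = GenomeSpec.builtin()
        track, truth = synthetic_ipls(spec, seed=3)
        cls = classify_origins(track)
        assert np.array_equal(cls.early, np.sort(truth["early"]))
        assert np.array_equal(cls.late, np.sort(truth["late"]))
        assert (track.values >= 0).all()

    def test_overcrowded_request_rejected(self):
        spec = GenomeSpec.toy([100])
        with pytest.raises(ValueError):
            synthetic_ipls(spec, n_early=30, n_late=30, seed=0)


class TestEnsemble1D:
    def test_single_origin_v_shaped_mrt(self):
        """One deterministic early-firing origin: MRT is a V with slope 1/v
        around the origin."""
        spec = GenomeSpec.toy([240])
        vals = np.full(240, 1e-6)
        vals[120] = 5.0
        track = IPLSTrack(spec, vals)
        p = EngineParameters(n_factors=2, origin_rate=1.0,
                             fork_speed_kb_min=2.2 * 500)
        ens = run_1d_ensemble(track, p, n_traj=20, seed=4, max_minutes=1e5)
        assert ens.replicated_fraction == 1.0
        # every locus replicated exactly once per trajectory
        assert np.isfinite(ens.rep_times).all()
        mrt = ens.mrt_min
        x = np.arange(240)
        interior = (np.abs(x - 120) > 5) & (x > 5) & (x < 234)
        slope_exp = 1.0 / p.fork_speed_kb_min       # min per kb
        fit = np.polyfit(np.abs(x - 120)[interior], mrt[interior], 1)
        assert fit[0] == pytest.approx(slope_exp, rel=0.1)
        assert mrt[120] == mrt.min()

    def test_rfd_sign_around_single_origin(self):
        """A lone origin replicates leftward on its left and rightward on
        its right: RFD is -1/+1 on the two sides."""
        spec = GenomeSpec.toy([240])
        vals = np.full(240, 1e-6)
        vals[120] = 5.0
        p = EngineParameters(n_factors=2, origin_rate=1.0,
                             fork_speed_kb_min=2.2 * 500)
        ens = run_1d_ensemble(IPLSTrack(spec, vals), p, n_traj=5, seed=3,
                              max_minutes=1e5)
        rfd = ens.rfd
        assert np.all(rfd[10:110] < -0.9)
        assert np.all(rfd[130:230] > 0.9)

    def test_duration_monotone_in_factor_count(self):
        spec = GenomeSpec.toy([400, 300])
        track, _ = synthetic_ipls(spec, n_early=4, n_late=10, seed=5,
                                  early_near_cen_frac=0.0)
        durations = []
        for nf in (2, 8):
            p = EngineParameters(n_factors=nf).rescaled(500)
            ens = run_1d_ensemble(track, p, n_traj=10, seed=6,
                                  max_minutes=1e5)
            durations.append(np.nanmean(ens.durations_min))
        assert durations[1] < durations[0]

    def test_factor_conservation_and_merge_release(self):
        """free + N_forks/2 tracks N_f(t); each merge frees one factor."""
        spec = GenomeSpec.toy([300])
        track, _ = synthetic_ipls(spec, n_early=3, n_late=3, seed=7,
                                  early_near_cen_frac=0.0)
        p = EngineParameters(n_factors=5).rescaled(500)
        ens = run_1d_ensemble(track, p, n_traj=3, seed=8, max_minutes=1e5)
        for (t, n), ev in zip(ens.fork_logs, ens.events):
            assert (n >= 0).all() and (n <= 2 * p.n_factors).all()
            merges = ev[ev[:, 1] == 1]
            fires = ev[ev[:, 1] == 0]
            opens = ev[ev[:, 1] == 2]
            # fork count bookkeeping: 2 per firing, -2 per merge, -1 per end
            assert 2 * len(fires) - 2 * len(merges) - len(opens) == 0
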