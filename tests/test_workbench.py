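"""File formats, configuration, trajectory store and the CLI."""

import json

import numpy as np
import pytest
import scipy.sparse as sp
from click.testing import CliRunner

from replisim import EngineParameters, IPLSTrack, contacts as ct
from replisim.cli import main
from replisim.config import RunConfig
from replisim.engine import run_s_phase
from replisim.genome import GenomeSpec
from replisim.kinetics import synthetic_ipls
from replisim.nucleus import free_chains
from replisim import trackio as tio


@pytest.fixture
def toy_spec():
    return GenomeSpec.toy([40, 25])


class TestSignalTracks:
    def test_bedgraph_round_trip(self, toy_spec, tmp_path):
        track, _ = synthetic_ipls(toy_spec, n_early=2, n_late=3,
                                  min_separation=3, seed=1)
        p = tmp_path / "t.bedgraph"
        tio.write_track(track, p)
        back = tio.read_track(p, toy_spec)
        assert np.allclose(back.values, track.values, atol=1e-12)

    def test_wiggle_matches_bedgraph(self, toy_spec, tmp_path):
        track, _ = synthetic_ipls(toy_spec, n_early=2, n_late=3,
                                  min_separation=3, seed=2)
        pb = tmp_path / "t.bedgraph"
        pw = tmp_path / "t.wig"
        tio.write_track(track, pb)
        tio.write_track(track, pw, fmt="wiggle")
        assert np.allclose(tio.read_signal(pb, toy_spec),
                           tio.read_signal(pw, toy_spec), atol=1e-12)

    def test_overlapping_intervals_rejected(self, toy_spec, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("toy1\t0\t2000\t1.0\ntoy1\t1000\t3000\t2.0\n")
        with pytest.raises(ValueError, match="overlap"):
            tio.read_signal(p, toy_spec)

    def test_binning_mismatch_rejected(self, toy_spec, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("toy1\t0\t1500\t1.0\n")
        with pytest.raises(ValueError):
            tio.read_signal(p, toy_spec)
        p.write_text("chrZZ\t0\t1000\t1.0\n")
        with pytest.raises(ValueError):
            tio.read_signal(p, toy_spec)

    def test_bed_round_trip(self, toy_spec, tmp_path):
        bins = np.array([3, 17, 50])
        p = tmp_path / "o.bed"
        tio.write_bed(toy_spec, bins, p)
        assert np.array_equal(tio.read_bed_bins(p, toy_spec), bins)


class TestContactContainer:
    def test_mcool_round_trip_and_coarsening(self, toy_spec, tmp_path):
        rng = np.random.default_rng(3)
        n = toy_spec.n_monomers
        a = rng.poisson(3, (n, n)).astype(float)
        a = a + a.T
        cmap = ct.ContactMap(ct.bins_from_spec(toy_spec), sp.csr_matrix(a))
        p = tmp_path / "m.mcool"
        tio.export_contacts(cmap, p)
        back = tio.read_contacts(p, 1)
        assert np.allclose(back.dense(), a)
        c16 = tio.read_contacts(p, 16)
        assert c16.mat.sum() == pytest.approx(a.sum())

    def test_weights_propagate(self, toy_spec, tmp_path):
        rng = np.random.default_rng(4)
        n = toy_spec.n_monomers
        a = rng.poisson(5, (n, n)).astype(float)
        a = a + a.T
        a[7, :] = 0
        a[:, 7] = 0
        cmap = ct.ice_balance(
            ct.ContactMap(ct.bins_from_spec(toy_spec), sp.csr_matrix(a)))
        p = tmp_path / "m.mcool"
        tio.export_contacts(cmap, p, resolutions=(1,))
        back = tio.read_contacts(p, 1)
        assert np.isnan(back.weights[7])
        assert back.masked_bins()[7]


class TestTrajectoryStore:
    def test_round_trip(self, toy_spec, tmp_path):
        track, _ = synthetic_ipls(toy_spec, n_early=2, n_late=2,
                                  min_separation=3, seed=5)
        p = EngineParameters(n_factors=3).rescaled(2000)
        w = free_chains([40, 25], 10, p, spec=toy_spec, seed=6)
        res = run_s_phase(w, track, frame_every_mcs=500, max_minutes=1e9)
        path = tmp_path / "traj.npz"
        tio.save_trajectory(res.trajectory, path, rep_time=res.rep_time_mcs,
                            events=res.events, meta={"scenario": "test"})
        traj, rep, ev, meta = tio.load_trajectory(path)
        assert len(traj) == len(res.trajectory)
        assert np.array_equal(traj.positions[-1],
                              res.trajectory.positions[-1])
        assert np.allclose(rep, res.rep_time_mcs)
        assert meta["scenario"] == "test"
        assert "config_hash" in meta


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=7, scenario="non-interacting", j_forks=1.7)
        p = tmp_path / "c.yaml"
        cfg.dump_yaml(p)
        back = RunConfig.from_yaml(p)
        assert back.to_dict() == cfg.to_dict()

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("seed: 3\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            RunConfig.from_yaml(p)

    def test_engine_parameters_defaults(self):
        p = RunConfig().engine_parameters()
        assert p.n_factors == 120
        assert p.origin_rate == 1e-9
        assert p.fork_step_probability == pytest.approx(2.75e-6)
        assert p.interacting

    def test_rescale_preserves_fork_budget(self):
        cfg = RunConfig(time_rescale=100.0)
        p = cfg.engine_parameters()
        assert p.origin_rate == pytest.approx(1e-7)
        assert p.ramp_tau_s == pytest.approx(0.9)


class TestDeterminism:
    def test_identical_seeds_identical_event_logs(self, toy_spec):
        track, _ = synthetic_ipls(toy_spec, n_early=2, n_late=2,
                                  min_separation=3, seed=9)
        logs = []
        for _ in range(2):
            p = EngineParameters(n_factors=3).rescaled(2000)
            w = free_chains([40, 25], 10, p, spec=toy_spec, seed=11)
            res = run_s_phase(w, track, frame_every_mcs=500,
                              max_minutes=1e9)
            logs.append((res.events.copy(), res.rep_time_mcs.copy()))
        assert np.array_equal(logs[0][0], logs[1][0])
        assert np.array_equal(logs[0][1], logs[1][1])


class TestCLI:
    def test_synth_ipls_classify_round_trip(self, tmp_path):
        runner = CliRunner()
        genome = tmp_path / "g.tsv"
        genome.write_text("# c\nchrA\t300\t150\nchrB\t200\t100\n")
        track = tmp_path / "ipls.bedgraph"
        r = runner.invoke(main, ["synth-ipls", "--genome", str(genome),
                                 "--n-early", "4", "--n-late", "8",
                                 "--seed", "3", "--out", str(track)])
        assert r.exit_code == 0, r.output
        r2 = runner.invoke(main, ["classify-origins", "--track", str(track),
                                  "--genome", str(genome),
                                  "--out-prefix", str(tmp_path / "ori")])
        assert r2.exit_code == 0, r2.output
        assert "early 4" in r2.output and "late 8" in r2.output
        early = (tmp_path / "ori_early.bed").read_text().strip().splitlines()
        assert len(early) == 4

    def test_dry_run_validates_without_simulating(self):
        runner = CliRunner()
        r = runner.invoke(main, ["simulate-s", "--dry-run"])
        assert r.exit_code == 0
        assert "OK" in r.output

    def test_missing_track_is_explicit_error(self):
        runner = CliRunner()
        r = runner.invoke(main, ["simulate-s", "--out", "x.npz"])
        assert r.exit_code != 0
        assert "IPLS" in r.output

    def test_unknown_option_fails(self):
        runner = CliRunner()
        r = runner.invoke(main, ["simulate-s", "--no-such-flag"])
        assert r.exit_code != 0
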