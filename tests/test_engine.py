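"""3D replication topology: bubbles, forks, merges, interaction energies."""

import numpy as np
import pytest

from replisim import (EngineParameters, IPLSTrack, nonspecific_fork_energy,
                      run_1d_ensemble, sister_fork_energy)
from replisim.engine import run_s_phase
from replisim.genome import GenomeSpec
from replisim.nucleus import free_chains
from replisim import _kernels as K


def toy_world(lengths=(60,), interacting=True, seed=1, j_forks=0.0,
              box=12, **kw):
    spec = GenomeSpec.toy(list(lengths))
    p = EngineParameters(interacting=interacting, j_forks=j_forks, **kw)
    return free_chains(list(lengths), box, p, spec=spec, seed=seed)


class TestFireOrigin:
    def test_bubble_creation(self):
        w = toy_world()
        n0 = w.n_monomers
        assert w.fire_origin(30)
        assert w.n_monomers == n0 + 1       # one newborn monomer
        assert w.n_forks == 2               # two diverging forks
        # newborn co-located with its template
        newborn = n0
        assert (w.pos[newborn] == w.pos[30]).all()
        assert w.sc[newborn] == 2 and w.sc[30] == 1
        # junctions flank the one-monomer bubble with triple connectivity
        assert w.nnb[29] == 3 and w.nnb[31] == 3
        w.check_invariants()

    def test_refire_rejected(self):
        w = toy_world()
        assert w.fire_origin(30)
        state = (w.n_monomers, w.n_forks)
        assert not w.fire_origin(30)        # already replicated
        assert not w.fire_origin(29)        # junction
        assert not w.fire_origin(28)        # adjacent to a junction
        assert not w.fire_origin(0)         # chain end
        assert (w.n_monomers, w.n_forks) == state

    def test_sister_pairing_flag(self):
        w = toy_world(interacting=True)
        w.fire_origin(30)
        fl, fr = w.alive_forks()
        assert w.f_partner[fl] == fr and w.f_pair[fl] == 1
        w2 = toy_world(interacting=False)
        w2.fire_origin(30)
        assert (w2.f_partner[w2.alive_forks()] == -1).all()

    def test_newborn_separates_under_dynamics(self):
        w = toy_world()
        w.fire_origin(30)
        w.run(500)
        assert w.occ.max() == 1             # excluded volume reinstated
        w.check_invariants()


class TestAdvanceFork:
    def test_replicon_growth(self):
        w = toy_world()
        w.fire_origin(30)
        right = [f for f in w.alive_forks() if w.f_dir[f] == 1][0]
        before = int(w.cnt[K.C_NREP])
        w.advance_fork(right)
        assert int(w.cnt[K.C_NREP]) == before + 1
        assert w.junction_of_bin[32] == right
        assert w.rep_time[31] >= 0
        w.check_invariants()

    def test_merge_releases_factor_and_pairings(self):
        w = toy_world(lengths=(80,), interacting=True)
        w.fire_origin(20)
        w.fire_origin(26)
        # advance the converging forks until the bubbles merge
        for _ in range(10):
            conv = [f for f in w.alive_forks()
                    if (w.f_dir[f] == 1 and w.f_bin[f] < 26)
                    or (w.f_dir[f] == -1 and w.f_bin[f] > 20)]
            if not conv:
                break
            w.advance_fork(conv[0])
        assert w.n_forks == 2               # two outer forks survive
        free_before = w.free_factors()
        # merging released one factor: free = N_f(t) - n_forks/2
        assert free_before == pytest.approx(
            w.params.n_factors * (1 - w.params.ramp_amplitude
                                  * np.exp(-w.t_mcs
                                           / w.params.ramp_tau_mcs)) - 1.0)
        # survivors diffuse freely: no pairing energy remains
        for f in w.alive_forks():
            assert w.f_partner[f] == -1 and w.f_pair[f] == 0
        w.check_invariants()

    def test_telomere_opening(self):
        w = toy_world(lengths=(40,))
        w.fire_origin(37)
        right = [f for f in w.alive_forks() if w.f_dir[f] == 1][0]
        w.advance_fork(right)       # junction at 38, adjacent to end 39
        assert w.rep_time[38] >= 0 and w.rep_time[39] >= 0
        assert w.n_forks == 1       # right fork died opening the bubble
        w.check_invariants()

    def test_dead_fork_rejected(self):
        w = toy_world(lengths=(40,))
        w.fire_origin(37)
        right = [f for f in w.alive_forks() if w.f_dir[f] == 1][0]
        w.advance_fork(right)
        with pytest.raises(ValueError):
            w.advance_fork(right)


class TestInteractionEnergies:
    def test_sister_well_shape(self):
        assert sister_fork_energy(0.0) == -100.0
        assert sister_fork_energy(50.0) == -100.0
        assert sister_fork_energy(np.sqrt(2) * 50.0) == pytest.approx(0.0)
        assert sister_fork_energy(100.0) == pytest.approx(200.0)

    def test_nonspecific_pair_counting(self):
        assert nonspecific_fork_energy([[0, 0, 0]], j_f=1.7) == 0.0
        two = [[0, 0, 0], [20, 0, 0]]
        assert nonspecific_fork_energy(two, j_f=1.7) == pytest.approx(-1.7)
        three = [[0, 0, 0], [20, 0, 0], [0, 20, 0]]
        assert nonspecific_fork_energy(three, j_f=1.7) == pytest.approx(-5.1)
        far = [[0, 0, 0], [100, 0, 0]]
        assert nonspecific_fork_energy(far, j_f=1.7) == 0.0

    def test_fork_field_matches_direct_count(self):
        """The incremental 40 nm fork-proximity field agrees with a direct
        recount from fork positions (dual-route check)."""
        w = toy_world(lengths=(80,), j_forks=1.7, box=14)
        w.fire_origin(20)
        w.fire_origin(50)
        w.run(200)
        field = np.zeros_like(w.fld)
        for f in w.alive_forks():
            p = w.pos[w.f_mon[f]]
            for off in K.BALL:
                s = p + off
                if (0 <= s[0] < w.smod and 0 <= s[1] < w.smod
                        and 0 <= s[2] < w.smod):
                    field[s[0], s[1], s[2]] += 1
        assert np.array_equal(field, w.fld)
        # total pair energy from the engine equals the direct pair count
        pos_nm = w.fork_positions_nm()
        direct = nonspecific_fork_energy(pos_nm, j_f=1.7)
        pair_terms = 0.0
        forks = w.alive_forks()
        for i in range(len(forks)):
            for j in range(i + 1, len(forks)):
                d = w.pos[w.f_mon[forks[i]]] - w.pos[w.f_mon[forks[j]]]
                if d @ d <= 8:
                    pair_terms += -1.7
        assert pair_terms == pytest.approx(direct)


class TestSPhase:
    def test_full_duplication_and_fork_series(self, fountain_data):
        res = fountain_data["runs"][True][0]
        spec = fountain_data["spec"]
        assert res.completed
        assert (res.rep_time_mcs >= 0).all()
        fc = res.fork_count
        assert fc[0] == 0 and fc[-1] == 0 and fc.max() >= 4
        # rises then falls: after the global maximum the series never
        # exceeds it again
        imax = fc.argmax()
        assert fc[imax:].max() == fc[imax]

    def test_monomer_doubling(self, fountain_data):
        res = fountain_data["runs"][True][0]
        spec = fountain_data["spec"]
        assert len(res.trajectory.positions[-1]) == 2 * spec.n_monomers

    def test_paired_fork_distance_constraint(self):
        """Intact sister pairs stay within ~th + one bead of each other on
        average (J_sister = 100 kT acts as a hard constraint).  Uses a
        gentle time rescale so the polymer relaxes between fork steps."""
        w = toy_world(lengths=(80,), interacting=True, box=14, seed=31,
                      n_factors=2)
        w.params = w.params.rescaled(50)
        w._pack_parameters()
        w.run(1000)
        w.fire_origin(40)
        # open the bubble to ~30 kb so the forks are contour-distant and
        # only the pairing potential holds them together
        for _ in range(15):
            for f in list(w.alive_forks()):
                w.advance_fork(f)
            w.run(100)
        dists = []
        for _ in range(40):
            w.run(400)
            forks = w.alive_forks()
            if len(forks) < 2:
                break
            f = forks[0]
            pj = w.f_partner[f]
            if pj >= 0 and w.f_alive[pj]:
                d = (w.pos[w.f_mon[f]] - w.pos[w.f_mon[pj]]) * 14.1421356
                dists.append(np.linalg.norm(d))
        assert len(dists) > 20
        assert np.mean(dists) <= 50.0 + 20.0

    def test_mrt_matches_1d_ensemble(self, fountain_data):
        """No 3D feedback exists: the coupled engine's replication timing
        agrees with the 1D-only runner on the same track/parameters."""
        spec = fountain_data["spec"]
        track = fountain_data["track"]
        runs = fountain_data["runs"][True] + fountain_data["runs"][False]
        mrt3d = np.mean([r.rep_time_mcs for r in runs], axis=0)
        ens = run_1d_ensemble(track, fountain_data["params"](True),
                              n_traj=12, seed=77, max_minutes=1e5)
        mrt1d = np.nanmean(ens.rep_times, axis=0)
        # same V-structure: strong correlation and matching scale
        r = np.corrcoef(mrt3d, mrt1d)[0, 1]
        assert r > 0.9
        assert np.mean(mrt3d) == pytest.approx(np.mean(mrt1d), rel=0.2)
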