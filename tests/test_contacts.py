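"""Contact maps: counting, balancing, expected/O-E, pileups, comparisons."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from replisim import constants as C
from replisim import contacts as ct
from replisim.genome import GenomeSpec
from replisim.world import Trajectory


def frame_traj(spec, positions_list, gbin):
    """Trajectory from explicit integer positions (one array per frame)."""
    tr = Trajectory(gbin=np.asarray(gbin), sc=None, n_bins=spec.n_monomers)
    for i, pos in enumerate(positions_list):
        tr.add(float(i), np.asarray(pos, dtype=np.int16),
               np.zeros(0, dtype=int))
    return tr


def toy_map(mat, chroms=None):
    n = len(mat)
    chroms = chroms or ["c1"] * n
    bins = pd.DataFrame({"chrom": chroms,
                         "start": [i * 1000 for i in range(n)],
                         "end": [(i + 1) * 1000 for i in range(n)]})
    # rebuild per-chromosome starts
    starts = []
    seen = {}
    for c in chroms:
        starts.append(seen.get(c, 0))
        seen[c] = starts[-1] + 1
    bins["start"] = [s * 1000 for s in starts]
    bins["end"] = [(s + 1) * 1000 for s in starts]
    return ct.ContactMap(bins, sp.csr_matrix(np.asarray(mat, dtype=float)))


class TestContactCounting:
    def test_bonded_and_distant_pairs(self):
        spec = GenomeSpec.toy([4])
        pos = np.array([[0, 0, 0], [1, 1, 0], [2, 2, 0], [30, 30, 0]])
        tr = frame_traj(spec, [pos], [0, 1, 2, 3])
        cmap = ct.contacts_from_frames(tr, spec)
        m = cmap.dense()
        assert m[0, 1] == 1          # 20 nm apart, bonded neighbours
        assert m[0, 2] == 1          # 40 nm
        assert m[0, 3] == 0          # ~800 nm
        assert (m == m.T).all()

    def test_contact_radius_is_strict(self):
        spec = GenomeSpec.toy([2])
        # (4,4,0) has length exactly 80 nm: excluded by d < r_c
        pos = np.array([[0, 0, 0], [4, 4, 0]])
        tr = frame_traj(spec, [pos], [0, 1])
        assert ct.contacts_from_frames(tr, spec).mat.nnz == 0

    def test_sister_copies_pool_to_four_pairs(self):
        """Both copies of two replicated bins within r_c: 4 copy pairs."""
        spec = GenomeSpec.toy([4])
        pos = np.array([[0, 0, 0], [1, 1, 0], [0, 2, 0], [1, 1, 2]])
        tr = frame_traj(spec, [pos], [0, 1, 0, 1])   # bins 0,1 duplicated
        m = ct.contacts_from_frames(tr, spec).dense()
        assert m[0, 1] == 4
        assert m[0, 0] == 1 and m[1, 1] == 1         # copy-copy self pairs

    def test_time_window_selection(self):
        spec = GenomeSpec.toy([2])
        pos = np.array([[0, 0, 0], [1, 1, 0]])
        far = np.array([[0, 0, 0], [30, 30, 0]])
        tr = frame_traj(spec, [pos, far], [0, 1])
        tr.times = [0.0, 60_000.0 / tr.time_per_mcs_ms * 10]  # 0 and 10 min
        full = ct.contacts_from_frames(tr, spec).dense()[0, 1]
        early = ct.contacts_from_frames(
            tr, spec, time_window_min=(0, 5)).dense()[0, 1]
        assert full == 1 and early == 1
        with pytest.raises(ValueError):
            ct.contacts_from_frames(tr, spec, time_window_min=(20, 30))


class TestIceBalance:
    def test_row_sums_equalized(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(20, (12, 12)).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        cmap = ct.ice_balance(toy_map(a), tol=1e-6)
        bal = np.asarray(cmap.balanced_values().todense())
        sums = bal.sum(axis=1)
        assert sums.std() / sums.mean() < 1e-5

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(10, (10, 10)).astype(float)
        a = a + a.T
        b1 = ct.ice_balance(toy_map(a)).balanced_values().todense()
        b2 = ct.ice_balance(toy_map(7.0 * a)).balanced_values().todense()
        assert np.allclose(b1, b2, rtol=1e-4)

    def test_zero_rows_masked_not_failed(self):
        a = np.ones((6, 6))
        a[3, :] = 0
        a[:, 3] = 0
        cmap = ct.ice_balance(toy_map(a))
        assert np.isnan(cmap.weights[3])
        assert cmap.masked_bins()[3]
        assert np.isfinite(cmap.weights[[0, 1, 2, 4, 5]]).all()


class TestExpectedAndOE:
    def test_ps_matches_hand_enumeration(self):
        a = np.array([[0, 4, 2, 0, 0],
                      [4, 0, 6, 2, 0],
                      [2, 6, 0, 8, 2],
                      [0, 2, 8, 0, 10],
                      [0, 0, 2, 10, 0]], dtype=float)
        cmap = toy_map(a)
        ps = ct.expected_cis(cmap)
        # hand enumeration of diagonal means over the 5x5 matrix
        for s in range(1, 5):
            vals = [a[i, i + s] for i in range(5 - s)]
            assert ps.p[s] == pytest.approx(np.mean(vals))

    def test_oe_diagonal_means_are_one(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(30, (15, 15)).astype(float)
        a = a + a.T
        cmap = ct.ice_balance(toy_map(a))
        ps, oe = ct.expected_and_oe(cmap)
        d = np.asarray(oe.mat.todense())
        for s in range(1, 10):
            assert np.nanmean(np.diag(d, s)) == pytest.approx(1.0, rel=1e-6)

    def test_distance_only_map_gives_flat_oe(self):
        n = 20
        a = np.fromfunction(lambda i, j: 100.0 / (1 + np.abs(i - j)), (n, n))
        ps, oe = ct.expected_and_oe(toy_map(a))
        d = np.asarray(oe.mat.todense())
        off = d[np.triu_indices(n, 1)]
        assert np.allclose(off[off > 0], 1.0)


class TestPileup:
    def test_single_anchor_recovers_window(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(30, (21, 21)).astype(float)
        a = a + a.T
        cmap = ct.ice_balance(toy_map(a))
        ps, oe = ct.expected_and_oe(cmap)
        mat, used = ct.pileup(oe, [10], 3)
        assert used == 1
        d = np.asarray(oe.mat.todense())
        assert np.allclose(mat, d[7:14, 7:14], equal_nan=True)

    def test_edge_anchors_skipped(self):
        a = np.ones((10, 10))
        cmap = ct.ice_balance(toy_map(a))
        ps, oe = ct.expected_and_oe(cmap)
        mat, used = ct.pileup(oe, [0, 5, 9], 3)
        assert used == 1

    def test_off_diagonal_normalized_by_short_range_ps(self):
        n = 40
        rng = np.random.default_rng(4)
        a = rng.poisson(20, (n, n)).astype(float)
        a = a + a.T
        chroms = ["c1"] * 20 + ["c2"] * 20
        cmap = ct.ice_balance(toy_map(a, chroms))
        ps, oe = ct.expected_and_oe(cmap)
        mat, used = ct.pileup(cmap, [10], 2, mode="off-diagonal",
                              anchors2=[30], ps=ps, norm_s_kb=10.0)
        assert used == 1
        bal = np.asarray(cmap.balanced_values().todense())
        expect = bal[8:13, 28:33] / ps.at(10.0)
        assert np.allclose(mat, expect)


class TestComparisons:
    def test_gamma_identity_and_linearity(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(25, (30, 30)).astype(float)
        a = a + a.T
        m1 = toy_map(a)
        m2 = toy_map(2.0 * a)
        assert ct.gamma_rescale(m1, m1) == pytest.approx(1.0)
        assert ct.gamma_rescale(m2, m1) == pytest.approx(0.5)

    def test_alpha_closed_form_matches_grid_search(self):
        rng = np.random.default_rng(6)
        s = np.arange(50)
        p_sim = ct.PsCurve(s, rng.uniform(0.1, 1.0, 50))
        p_exp = ct.PsCurve(s, rng.uniform(0.1, 1.0, 50))
        alpha = ct.alpha_fit(p_sim, p_exp, 10, 40)
        # brute-force grid oracle
        grid = np.linspace(0.01, 5.0, 200001)
        win = (s >= 10) & (s <= 40)
        mse = [(np.sum((p_exp.p[win] - g * p_sim.p[win]) ** 2)) for g in grid]
        assert alpha == pytest.approx(grid[int(np.argmin(mse))], abs=1e-4)
        assert ct.alpha_fit(p_sim, p_sim, 10, 40) == pytest.approx(1.0)
        p3 = ct.PsCurve(s, 3.0 * p_sim.p)
        assert ct.alpha_fit(p_sim, p3, 10, 40) == pytest.approx(3.0)

    def test_mix_maps(self):
        a = toy_map(np.full((4, 4), 2.0))
        b = toy_map(np.full((4, 4), 10.0))
        assert np.allclose(ct.mix_maps([a, b], [1, 0]).dense(), 2.0)
        mixed = ct.mix_maps([a, b], [0.2, 0.8])
        assert np.allclose(mixed.dense(), 0.2 * 2 + 0.8 * 10)
        with pytest.raises(ValueError):
            ct.mix_maps([a, b], [0.5, 0.2])

    def test_pearson_similarity(self):
        rng = np.random.default_rng(7)
        a = rng.poisson(10, (8, 8)).astype(float)
        a = a + a.T
        m = toy_map(a)
        assert ct.pearson_map_similarity(m, m) == pytest.approx(1.0)
        b = rng.poisson(10, (8, 8)).astype(float)
        b = b + b.T
        m2 = toy_map(b)
        iu = np.triu_indices(8)
        expect = np.corrcoef(a[iu], b[iu])[0, 1]
        assert ct.pearson_map_similarity(m, m2) == pytest.approx(expect)


class TestCoarsen:
    def test_counts_conserved(self):
        spec = GenomeSpec.toy([10, 6])
        rng = np.random.default_rng(8)
        a = rng.poisson(5, (16, 16)).astype(float)
        a = a + a.T
        bins = ct.bins_from_spec(spec)
        cmap = ct.ContactMap(bins, sp.csr_matrix(a))
        c4 = cmap.coarsen(4)
        assert c4.mat.sum() == pytest.approx(cmap.mat.sum())
        assert list(c4.bins["chrom"]).count("toy1") == 3
        # spot-check one aggregated pixel
        assert c4.dense()[0, 1] == pytest.approx(a[0:4, 4:8].sum())
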