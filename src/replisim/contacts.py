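"""In-silico Hi-C: contact maps from trajectory frames and map statistics.

Two monomers are in contact when their 3D Euclidean distance is below the
contact radius ``r_c`` (80 nm by default).  Sister chromatids are pooled
onto genomic coordinates, so a bin pair of a replicated region can collect
up to four copy-pair contacts per frame.  Maps are balanced with iterative
correction (ICE), which also flattens the copy-number step at replication
bubbles, and normalized to observed-over-expected via the distance-decay
P(s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from . import constants as C
from .genome import GenomeSpec
from .world import Trajectory


@dataclass
class ContactMap:
    """Symmetric binned contact matrix with balancing weights."""

    bins: pd.DataFrame            # chrom, start, end (bp)
    mat: sp.csr_matrix            # symmetric counts/values
    resolution_kb: int = 1
    weights: np.ndarray | None = None
    state: str = "raw"            # raw | balanced | oe

    def __post_init__(self):
        n = len(self.bins)
        if self.mat.shape != (n, n):
            raise ValueError("matrix shape does not match bin table")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chrom_ids(self) -> np.ndarray:
        return pd.factorize(self.bins["chrom"])[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.mat.todense())

    def masked_bins(self) -> np.ndarray:
        if self.weights is None:
            marg = np.asarray(self.mat.sum(axis=1)).ravel()
            return marg == 0
        return ~np.isfinite(self.weights)

    def balanced_values(self) -> sp.csr_matrix:
        """Counts scaled by the balancing weights (identity if raw)."""
        if self.weights is None:
            return self.mat
        w = np.where(np.isfinite(self.weights), self.weights, 0.0)
        d = sp.diags(w)
        return (d @ self.mat @ d).tocsr()

    def coarsen(self, factor: int) -> "ContactMap":
        """Aggregate to a coarser resolution (counts are summed)."""
        if factor == 1:
            return self
        res = self.resolution_kb * factor
        new_index = np.zeros(self.n_bins, dtype=np.int64)
        rows = []
        off = 0
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            sub = starts // (res * 1000)
            new_index[grp.index.to_numpy()] = off + sub
            n_new = sub.max() + 1
            ns = np.arange(n_new) * res * 1000
            ne = np.minimum(ns + res * 1000, ends.max())
            rows.append(pd.DataFrame({"chrom": chrom, "start": ns, "end": ne}))
            off += n_new
        bins = pd.concat(rows, ignore_index=True)
        coo = self.mat.tocoo()
        mat = sp.coo_matrix(
            (coo.data, (new_index[coo.row], new_index[coo.col])),
            shape=(off, off)).tocsr()
        mat.sum_duplicates()
        return ContactMap(bins, mat, resolution_kb=res)


def bins_from_spec(spec: GenomeSpec, resolution_kb: int = 1) -> pd.DataFrame:
    return spec.bin_table(resolution_kb)


def contacts_from_frames(traj: Trajectory, spec: GenomeSpec,
                         r_c_nm: float = C.R_CONTACT_NM,
                         time_window_min: tuple | None = None) -> ContactMap:
    """Count contacts (d < r_c) over frames, pooled onto genomic bins.

    ``time_window_min`` restricts aggregation to frames whose time (minutes
    from the trajectory origin) falls in [t0, t1).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if traj.gbin is None:
        raise ValueError("trajectory carries no genomic bin mapping")
    times = traj.times_min()
    if time_window_min is None:
        keep = np.arange(len(traj))
    else:
        t0, t1 = time_window_min
        keep = np.flatnonzero((times >= t0) & (times < t1))
        if len(keep) == 0:
            raise ValueError("no frames in the requested time window")
    G = spec.n_monomers
    rows, cols = [], []
    for fi in keep:
        pos = traj.positions[fi].astype(float) * traj.step_nm
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r_c_nm - 1e-9, output_type="ndarray")
        if len(pairs) == 0:
            continue
        bi = traj.gbin[pairs[:, 0]]
        bj = traj.gbin[pairs[:, 1]]
        lo = np.minimum(bi, bj)
        hi = np.maximum(bi, bj)
        rows.append(lo)
        cols.append(hi)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.ones(len(rows))
        upper = sp.coo_matrix((data, (rows, cols)), shape=(G, G)).tocsr()
        upper.sum_duplicates()
        diag = sp.diags(upper.diagonal())
        mat = upper + upper.T - diag
    else:
        mat = sp.csr_matrix((G, G))
    return ContactMap(bins_from_spec(spec, 1), mat.tocsr())


# ---------------------------------------------------------------------------
# balancing and expected
# ---------------------------------------------------------------------------

def ice_balance(cmap: ContactMap, tol: float = 1e-5,
                max_iter: int = 200) -> ContactMap:
    """Iterative correction: scale rows/columns until all non-masked
    marginals agree (coefficient of variation < tol).  All-zero bins are
    masked (weight NaN), not failed."""
    m = cmap.mat.tocsr().astype(float)
    marg0 = np.asarray(m.sum(axis=1)).ravel()
    mask = marg0 == 0
    w = np.ones(cmap.n_bins)
    w[mask] = 0.0
    for _ in range(max_iter):
        d = sp.diags(w)
        marg = np.asarray((d @ m @ d).sum(axis=1)).ravel()
        live = marg[~mask]
        mean = live.mean()
        if mean == 0:
            break
        cv = live.std() / mean
        s = np.ones_like(w)
        nz = marg > 0
        s[nz] = marg[nz] / mean
        w = w / np.sqrt(s)
        if cv < tol:
            break
    # normalize so balanced non-masked marginals average to 1
    d = sp.diags(w)
    marg = np.asarray((d @ m @ d).sum(axis=1)).ravel()
    scale = marg[~mask].mean()
    if scale > 0:
        w = w / np.sqrt(scale)
    w_out = w.copy()
    w_out[mask] = np.nan
    return replace(cmap, weights=w_out, state="balanced")


@dataclass
class PsCurve:
    """Mean contact frequency vs genomic separation (cis)."""

    s_kb: np.ndarray
    p: np.ndarray
    resolution_kb: int = 1

    def at(self, s_kb: float) -> float:
        i = int(round(s_kb / self.resolution_kb))
        if not (0 <= i < len(self.p)):
            raise ValueError(f"s = {s_kb} kb outside the curve")
        return float(self.p[i])


def expected_cis(cmap: ContactMap) -> PsCurve:
    """Genome-average P(s): mean balanced contact frequency per diagonal,
    averaged over valid (non-masked) intra-chromosomal pixel pairs."""
    vals = cmap.balanced_values().tocoo()
    chrom = cmap.chrom_ids
    masked = cmap.masked_bins()
    n_max = int(np.max(np.bincount(chrom)))
    sums = np.zeros(n_max)
    intra = chrom[vals.row] == chrom[vals.col]
    s = np.abs(vals.col[intra] - vals.row[intra])
    np.add.at(sums, s, vals.data[intra])
    counts = np.zeros(n_max)
    for ci in np.unique(chrom):
        u = (~masked[chrom == ci]).astype(float)
        corr = np.correlate(u, u, mode="full")[len(u) - 1:]
        counts[:len(corr)] += corr
    # the symmetric matrix stores each off-diagonal pair twice
    sums[1:] /= 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(counts > 0, sums / counts, np.nan)
    return PsCurve(np.arange(n_max) * cmap.resolution_kb, p,
                   cmap.resolution_kb)


def expected_trans(cmap: ContactMap) -> float:
    """Mean balanced contact frequency over valid trans pixel pairs."""
    vals = cmap.balanced_values().tocoo()
    chrom = cmap.chrom_ids
    masked = cmap.masked_bins()
    trans = chrom[vals.row] != chrom[vals.col]
    total = vals.data[trans].sum() / 2.0
    live = (~masked).astype(float)
    per_chrom = np.bincount(chrom, weights=live)
    n_live = live.sum()
    n_pairs = (n_live ** 2 - np.sum(per_chrom ** 2)) / 2.0
    return float(total / n_pairs) if n_pairs > 0 else np.nan


def expected_and_oe(cmap: ContactMap) -> tuple[PsCurve, ContactMap]:
    """P(s) plus the observed-over-expected map (cis by P(|i-j|), trans by
    the mean trans frequency)."""
    ps = expected_cis(cmap)
    t_exp = expected_trans(cmap)
    vals = cmap.balanced_values().tocoo()
    chrom = cmap.chrom_ids
    intra = chrom[vals.row] == chrom[vals.col]
    s = np.abs(vals.col - vals.row)
    denom = np.where(intra, ps.p[np.minimum(s, len(ps.p) - 1)], t_exp)
    with np.errstate(invalid="ignore", divide="ignore"):
        data = np.where(denom > 0, vals.data / denom, np.nan)
    oe = sp.coo_matrix((data, (vals.row, vals.col)), shape=vals.shape).tocsr()
    return ps, ContactMap(cmap.bins, oe, cmap.resolution_kb,
                          weights=cmap.weights, state="oe")


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def pileup(cmap: ContactMap, anchors, flank_bins: int,
           mode: str = "on-diagonal",
           anchors2=None, ps: PsCurve | None = None,
           norm_s_kb: float = 10.0, log2: bool = False):
    """Anchor-centered aggregate maps.

    on-diagonal: mean O/E submatrix around each anchor (``cmap`` must be an
    O/E map).  off-diagonal: mean cross submatrix at anchor-pair crossings
    of a balanced map, divided by P_intra(``norm_s_kb``).  Anchors too close
    to a chromosome edge are skipped; the count of used anchors is returned.
    """
    f = int(flank_bins)
    n = cmap.n_bins
    chrom = cmap.chrom_ids
    dense_needed = cmap.mat.tocsr()
    masked = cmap.masked_bins()

    def window_ok(a):
        return (a - f >= 0 and a + f < n
                and chrom[a - f] == chrom[a + f] == chrom[a])

    acc = np.zeros((2 * f + 1, 2 * f + 1))
    cnt = np.zeros_like(acc)
    used = 0
    if mode == "on-diagonal":
        if cmap.state != "oe":
            raise ValueError("on-diagonal pileup expects an O/E map")
        for a in np.asarray(anchors, dtype=int):
            if not window_ok(a) or masked[a]:
                continue
            sub = np.asarray(
                dense_needed[a - f:a + f + 1, a - f:a + f + 1].todense())
            bad = masked[a - f:a + f + 1]
            sub[bad, :] = np.nan
            sub[:, bad] = np.nan
            # implicit zeros are genuine observations in sparse maps
            good = np.isfinite(sub)
            acc[good] += sub[good]
            cnt += good
            used += 1
    elif mode == "off-diagonal":
        if ps is None:
            raise ValueError("off-diagonal pileup needs the P(s) curve")
        norm = ps.at(norm_s_kb)
        a1 = np.asarray(anchors, dtype=int)
        a2 = np.asarray(anchors if anchors2 is None else anchors2, dtype=int)
        bal = cmap.balanced_values()
        for a in a1:
            if not window_ok(a) or masked[a]:
                continue
            for b in a2:
                if b == a or chrom[a] == chrom[b]:
                    continue
                if not window_ok(b) or masked[b]:
                    continue
                sub = np.asarray(
                    bal[a - f:a + f + 1, b - f:b + f + 1].todense()) / norm
                good = np.isfinite(sub)
                acc[good] += sub[good]
                cnt += good
                used += 1
    else:
        raise ValueError(f"unknown pileup mode {mode!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnt > 0, acc / cnt, np.nan)
    if log2:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.log2(out)
    return out, used


# ---------------------------------------------------------------------------
# cross-dataset comparison
# ---------------------------------------------------------------------------

def gamma_rescale(sim: ContactMap, exp: ContactMap,
                  s_kb: float = 16.0) -> float:
    """Scale factor gamma = P_exp(s) / P_sim(s) at s = 16 kb."""
    p_sim = expected_cis(sim).at(s_kb)
    p_exp = expected_cis(exp).at(s_kb)
    if p_sim == 0 or not np.isfinite(p_sim):
        raise ValueError("simulated P(s) vanishes at the matching distance")
    return float(p_exp / p_sim)


def alpha_fit(p_sim: PsCurve, p_exp: PsCurve,
              s_min_kb: float = 10.0, s_max_kb: float = 1000.0) -> float:
    """MSE-optimal scale alpha between P(s) curves on [s_min, s_max]:
    alpha = sum(P_exp P_sim) / sum(P_sim^2)."""
    if p_sim.resolution_kb != p_exp.resolution_kb:
        raise ValueError("curves must share a resolution")
    n = min(len(p_sim.p), len(p_exp.p))
    s = p_sim.s_kb[:n]
    win = (s >= s_min_kb) & (s <= s_max_kb)
    a = p_sim.p[:n][win]
    b = p_exp.p[:n][win]
    good = np.isfinite(a) & np.isfinite(b)
    a, b = a[good], b[good]
    denom = np.sum(a * a)
    if denom == 0 or len(a) == 0:
        raise ValueError("simulated P(s) is degenerate on the fit window")
    return float(np.sum(a * b) / denom)


def mix_maps(maps, weights) -> ContactMap:
    """Convex combination of raw maps (before balancing / O-E)."""
    weights = np.asarray(weights, dtype=float)
    if len(maps) != len(weights):
        raise ValueError("one weight per map required")
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be >= 0 and sum to 1")
    first = maps[0]
    out = first.mat * weights[0]
    for m, w in zip(maps[1:], weights[1:]):
        if m.mat.shape != first.mat.shape:
            raise ValueError("maps must share binning")
        out = out + m.mat * w
    return ContactMap(first.bins, out.tocsr(), first.resolution_kb)


def pearson_map_similarity(a: ContactMap, b: ContactMap) -> float:
    """Pearson correlation over shared non-masked pixels."""
    if a.mat.shape != b.mat.shape:
        raise ValueError("maps must share binning")
    da = np.asarray(a.balanced_values().todense())
    db = np.asarray(b.balanced_values().todense())
    bad = a.masked_bins() | b.masked_bins()
    keep = ~bad
    iu = np.triu_indices(a.n_bins)
    sel = keep[iu[0]] & keep[iu[1]]
    x = da[iu][sel]
    y = db[iu][sel]
    if len(x) < 2:
        raise ValueError("no overlapping unmasked pixels")
    return float(pearsonr(x, y)[0])
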