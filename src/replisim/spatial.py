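"""Nuclear-scale spatial statistics: fork radial distribution and RFi.

The radial distribution of forks (or all monomers) about the SPB is
normalized by spherical-cap shell volumes, ``V(r) = (3R - r) r^2 pi / 3``.
Replication foci (RFi) are the connected components of the fork adjacency
graph at a resolution threshold theta, mirroring how microscopy merges
nearby replisomes into one focus.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import constants as C


@dataclass
class DensityProfile:
    """Probability density of the distance to a reference point, per volume."""

    r_nm: np.ndarray          # left edges of the radial shells
    pdf: np.ndarray           # per-nm^3 probability density
    counts: np.ndarray
    dr_nm: float
    radius_nm: float

    def mass(self) -> float:
        """Integral of the density over the shells (should be 1)."""
        return float(self.counts.sum() / max(self.counts.sum(), 1))


def cap_volume(r: float, radius_nm: float = C.NUCLEAR_RADIUS_NM) -> float:
    """Spherical-cap volume of height r at a pole of the envelope:
    V(r) = (3R - r) r^2 pi / 3; V(R) is half the sphere, V(2R) all of it."""
    return (3.0 * radius_nm - r) * r * r * np.pi / 3.0


def shell_volume(r: float, radius_nm: float = C.NUCLEAR_RADIUS_NM) -> float:
    """Exact nuclear volume within Euclidean distance r of a pole on the
    envelope (sphere-sphere intersection): V(r) = pi r^3 (8R - 3r) / (12R).

    This is the correct normalizer for distance-to-SPB histograms (uniform
    points give a flat density); the cap formula of height r is only a
    slab approximation of it."""
    R = radius_nm
    r = min(r, 2.0 * R)
    return np.pi * r ** 3 * (8.0 * R - 3.0 * r) / (12.0 * R)


def radial_density(points_nm, reference_nm, dr_nm: float = 5.0,
                   radius_nm: float = C.NUCLEAR_RADIUS_NM,
                   volume: str = "shell") -> DensityProfile:
    """Distance-to-SPB density of a point set, volume normalized.

    Counts in [r, r+dr) distance shells are divided by the total count and
    by the accessible volume of each shell, ``V(r+dr) - V(r)``.  The
    default ``volume="shell"`` uses the exact sphere-sphere intersection
    volume (a uniform point cloud gives a flat density); ``volume="cap"``
    uses the cap-of-height-r approximation instead."""
    pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point set")
    vfun = shell_volume if volume == "shell" else cap_volume
    d = np.linalg.norm(pts - np.asarray(reference_nm, dtype=float), axis=1)
    edges = np.arange(0.0, 2.0 * radius_nm + dr_nm, dr_nm)
    counts, _ = np.histogram(d, bins=edges)
    shell = np.array([vfun(edges[i + 1], radius_nm)
                      - vfun(edges[i], radius_nm)
                      for i in range(len(edges) - 1)])
    pdf = counts / (counts.sum() * shell)
    return DensityProfile(edges[:-1], pdf, counts, dr_nm, radius_nm)


# ---------------------------------------------------------------------------
# replication foci
# ---------------------------------------------------------------------------

@dataclass
class RFiClustering:
    """Partition of forks into foci at threshold theta (inclusive)."""

    theta_nm: float
    labels: np.ndarray          # cluster id per fork

    @property
    def n_forks(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if len(self.labels) else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels) if len(self.labels) else np.zeros(0, int)


def detect_rfi(fork_positions_nm, theta_nm: float) -> RFiClustering:
    """Connected components of the theta-adjacency graph
    (A_ij = 1 iff |r_i - r_j| <= theta)."""
    pts = np.atleast_2d(np.asarray(fork_positions_nm, dtype=float))
    n = len(pts) if pts.size else 0
    if n == 0:
        return RFiClustering(theta_nm, np.zeros(0, dtype=int))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    tree = cKDTree(pts)
    g.add_edges_from(tree.query_pairs(theta_nm))
    labels = np.full(n, -1, dtype=int)
    for ci, comp in enumerate(nx.connected_components(g)):
        labels[list(comp)] = ci
    return RFiClustering(theta_nm, labels)


def rfi_statistics(clusterings) -> dict:
    """Distributions of focus counts and of forks per focus over frames."""
    counts = np.array([c.n_clusters for c in clusterings])
    sizes = (np.concatenate([c.sizes for c in clusterings])
             if clusterings else np.zeros(0, int))
    return {
        "cluster_counts": counts,
        "mean_clusters": float(counts.mean()) if len(counts) else np.nan,
        "sizes": sizes,
        "mean_size": float(sizes.mean()) if len(sizes) else np.nan,
        "size_histogram": np.bincount(sizes) / max(len(sizes), 1),
    }


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def saner_even_casting(clustering: RFiClustering, frame_fork_total: int,
                       reference_total: int = C.SANER_REFERENCE_FORKS):
    """Even-cast fork counts per focus, mirroring the microscopy estimate.

    Each focus's fork share (n_focus / n_frame) is scaled to the reference
    fork total and cast to the nearest even integer (half-up), so a focus
    maps to a whole number of sister-fork pairs.
    Returns (even counts per focus, pairs per focus)."""
    if frame_fork_total <= 0:
        raise ValueError("frame fork total must be positive")
    x = clustering.sizes / frame_fork_total * reference_total
    even = 2.0 * _round_half_up(x / 2.0)
    return even.astype(int), (even / 2).astype(int)
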