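"""Nuclear geometry, genome initialization and Rabl tethering.

The nucleus is a sphere of radius 1000 nm carved out of the lattice box
(70 cells for a 2 um nucleus).  The spindle pole body (SPB) sits on the +z
pole; centromeres diffuse freely in a 250-325 nm shell around it and are
harmonically pulled back otherwise.  Telomeres feel an outward harmonic
drive saturating within 50 nm of the envelope.  Opposite the SPB an
impermeable wall 800 nm from the center delimits the nucleolus; the two
rDNA-boundary monomers of chromosome 12 are pulled onto it by a spring in z.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from . import constants as C
from .genome import GenomeSpec
from .lattice import LatticeGeometry
from .world import EngineParameters, Trajectory, World


@dataclass(frozen=True)
class NuclearGeometry:
    radius_nm: float = C.NUCLEAR_RADIUS_NM
    cen_shell_nm: tuple = C.CEN_SHELL_NM
    telo_shell_nm: float = C.TELO_SHELL_NM
    nucleolus_wall_nm: float = C.NUCLEOLUS_WALL_NM

    @classmethod
    def scaled(cls, radius_nm: float) -> "NuclearGeometry":
        """Geometry proportional to the reference nucleus (centromere
        shell at 25-32.5% of R, telomere shell at 95% R, wall at 80% R) —
        for reduced boxes in toy runs."""
        f = radius_nm / C.NUCLEAR_RADIUS_NM
        return cls(radius_nm=radius_nm,
                   cen_shell_nm=(C.CEN_SHELL_NM[0] * f,
                                 C.CEN_SHELL_NM[1] * f),
                   telo_shell_nm=C.TELO_SHELL_NM * f,
                   nucleolus_wall_nm=C.NUCLEOLUS_WALL_NM * f)

    def anchors_nm(self, box_cells: int = C.BOX_EDGE):
        """(SPB, center) positions in nm for a given box."""
        L = box_cells * C.STEP_NM
        spb = np.array([L, L, 2 * L])
        center = np.array([L, L, L])
        return spb, center

    def cap_volume(self, r: float) -> float:
        """Spherical-cap volume V(r) = (3R - r) r^2 pi / 3 within distance r
        of a surface pole; V(R) is half the sphere, V(2R) the whole."""
        R = self.radius_nm
        return (3.0 * R - r) * r * r * math.pi / 3.0


def build_confinement(geometry: NuclearGeometry,
                      lattice: LatticeGeometry) -> np.ndarray:
    """Blocked-site mask for the spherical envelope plus nucleolus wall.

    Sites outside the sphere or beyond the wall (the cap on the -z pole,
    height 200 nm at the defaults) are permanently blocked.  The 70-cell box
    underfits a 1000 nm radius by under one lattice unit; a larger deficit
    raises.
    """
    L = lattice.box_edge
    S = 2 * L + 1
    if L * lattice.cell_edge < 2 * geometry.radius_nm - lattice.cell_edge:
        raise ValueError("box too small for the requested nuclear diameter")
    step = lattice.step_nm
    idx = np.arange(S, dtype=float)
    dx2 = ((idx - L) * step) ** 2
    d2 = dx2[:, None, None] + dx2[None, :, None] + dx2[None, None, :]
    blocked = d2 >= geometry.radius_nm ** 2
    wall_z = L - geometry.nucleolus_wall_nm / step
    blocked |= (idx < wall_z)[None, None, :]
    return blocked.astype(np.uint8)


def accessible_fraction(blocked: np.ndarray) -> float:
    """Fraction of in-box fcc sites that are accessible."""
    S = blocked.shape[0]
    ix = np.indices((S, S, S)).sum(axis=0)
    parity = (ix % 2) == 0
    return float((~blocked.astype(bool) & parity).sum() / parity.sum())


def volumic_fraction(world: World) -> float:
    """Diagnostic Phi: occupied fraction of accessible fcc sites."""
    S = world.blocked.shape[0]
    ix = np.indices((S, S, S)).sum(axis=0)
    parity = (ix % 2) == 0
    acc = (~world.blocked.astype(bool) & parity).sum()
    return world.n_monomers / float(acc)


# ---------------------------------------------------------------------------
# tether energies (pure reference implementation; the kernels mirror this)
# ---------------------------------------------------------------------------

def tether_energy(cen_nm=None, telo_nm=None, rdna_nm=None,
                  geometry: NuclearGeometry | None = None,
                  k_tether: float = C.K_TETHER,
                  box_cells: int = C.BOX_EDGE) -> float:
    """Total Rabl tethering energy (kT) for explicit anchor positions (nm).

    Centromeres cost ``k d^2`` outside the 250-325 nm SPB shell (d to the
    SPB, in bead diameters); telomeres feel the outward harmonic drive
    ``k (950^2 - d^2)``, zero once within 50 nm of the envelope (d to the
    nuclear center); rDNA boundaries cost ``k z^2`` with z the height
    above the nucleolus wall plane.
    """
    geometry = geometry or NuclearGeometry()
    spb, center = geometry.anchors_nm(box_cells)
    sig2 = C.SIGMA_NM ** 2
    e = 0.0
    if cen_nm is not None and len(cen_nm):
        d2 = np.sum((np.atleast_2d(cen_nm) - spb) ** 2, axis=1)
        lo, hi = geometry.cen_shell_nm
        outside = ~((lo ** 2 < d2) & (d2 < hi ** 2))
        e += k_tether * np.sum(d2[outside]) / sig2
    if telo_nm is not None and len(telo_nm):
        # outward harmonic drive, zero within 50 nm of the envelope
        d2 = np.sum((np.atleast_2d(telo_nm) - center) ** 2, axis=1)
        gap = np.maximum(geometry.telo_shell_nm ** 2 - d2, 0.0)
        e += k_tether * np.sum(gap) / sig2
    if rdna_nm is not None and len(rdna_nm):
        wall_z = center[2] - geometry.nucleolus_wall_nm
        z = np.atleast_2d(rdna_nm)[:, 2] - wall_z
        e += k_tether * np.sum(z ** 2) / sig2
    return float(e)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def sunflower_points(n: int, radius: float) -> np.ndarray:
    """n points packed in a disc of given radius (golden-angle spiral)."""
    k = np.arange(1, n + 1)
    r = radius * np.sqrt((k - 0.5) / n)
    th = k * math.pi * (3.0 - math.sqrt(5.0))
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


def _start_sites(n: int, box_cells: int, blocked: np.ndarray,
                 disc_frac: float = 0.55) -> np.ndarray:
    L = box_cells
    pts = sunflower_points(n, disc_frac * L)
    sites = np.zeros((n, 3), dtype=np.int64)
    used = set()
    for i, (x, y) in enumerate(pts):
        xi = int(round(L + x))
        yi = int(round(L + y))
        if (xi + yi + L) % 2 == 1:
            xi += 1
        site = (xi, yi, L)
        shift = 0
        while site in used or blocked[site]:
            shift += 2
            site = (xi + shift, yi, L)
        used.add(site)
        sites[i] = site
    return sites


def _place_backbone(world: World, start: np.ndarray, target: int,
                    arm: int, rng) -> np.ndarray | None:
    """Try to lay a V-shaped backbone of two straight branches starting at
    ``start`` (the chain's first monomer); returns the occupied path
    (contour order) or None."""
    arm = min(arm, max((target - 1) // 2, 0))
    for _ in range(300):
        i1, i2 = rng.choice(12, size=2, replace=False)
        v1, v2 = K.NNV[i1], K.NNV[i2]
        elbow = start + v1 * arm
        sites = ([start + v1 * i for i in range(arm + 1)]
                 + [elbow + v2 * (i + 1) for i in range(arm)])
        ok = True
        seen = set()
        for s in sites:
            t = tuple(int(v) for v in s)
            ti = tuple(v % world.smod for v in t) if world.periodic else t
            if (not world.periodic
                    and not all(0 <= v < world.smod for v in t)):
                ok = False
                break
            if world.blocked[ti] or world.occ[ti] or t in seen:
                ok = False
                break
            seen.add(t)
        if ok:
            path = np.array(sites, dtype=np.int64)
            for s in sites:
                ti = (tuple(v % world.smod for v in s) if world.periodic
                      else tuple(int(v) for v in s))
                world.occ[ti] += 1
            return path
    return None


def _grow_one(world: World, start: np.ndarray, target: int, arm: int,
              rng, retries: int = 25) -> np.ndarray:
    for _ in range(retries):
        backbone = _place_backbone(world, start, target, arm, rng)
        if backbone is None:
            continue
        path = np.zeros((target, 3), dtype=np.int64)
        path[:len(backbone)] = backbone
        got = K.grow_chain(path, len(backbone), target, world.occ,
                           world.blocked, world.smod,
                           1 if world.periodic else 0,
                           int(rng.integers(2**31 - 1)))
        if got == target:
            return path
        # jammed: roll back this chain's occupancy and retry
        for s in path[:got]:
            ti = (tuple(int(v) % world.smod for v in s) if world.periodic
                  else tuple(int(v) for v in s))
            world.occ[ti] -= 1
    raise RuntimeError(
        f"chain growth failed after {retries} retries (target {target}); "
        "retry with another seed")


def initialize_genome(spec: GenomeSpec, params: EngineParameters | None = None,
                      geometry: NuclearGeometry | None = None,
                      box_cells: int = C.BOX_EDGE, seed: int = 0) -> World:
    """Build 17 mutually avoiding chains inside the confined nucleus.

    Each chain starts at a sunflower-packed point of the equatorial plane,
    gets a V-shaped backbone of two straight L/8 arms in random directions,
    and is grown to its full length by random bond subdivision; chains are
    built in random order.
    """
    params = params or EngineParameters()
    geometry = geometry or NuclearGeometry()
    lattice = LatticeGeometry(box_edge=box_cells)
    world = World(spec, params, box_cells, periodic=False,
                  geometry=geometry, seed=seed)
    world.blocked[:] = build_confinement(geometry, lattice)
    rng = world.rng
    starts = _start_sites(spec.n_chains, box_cells, world.blocked)
    arm = max(1, box_cells // 8)
    order = rng.permutation(spec.n_chains)
    paths: dict[int, np.ndarray] = {}
    for ci in order:
        ch = spec.chains[ci]
        paths[ci] = _grow_one(world, starts[ci], ch.length, arm, rng)
    for ci, path in paths.items():
        world.place_chain(ci, path)
    world.finalize_chains()
    return world


#: parity-preserving search offsets (even coordinate sum, downward-biased)
_PARITY_OFFSETS = sorted(
    ((dx, dy, dz) for dx in range(-8, 9) for dy in range(-8, 9)
     for dz in (0, -2, -4, -6) if (dx + dy + dz) % 2 == 0),
    key=lambda o: (o[0] ** 2 + o[1] ** 2 + o[2] ** 2))


def initialize_rabl(spec: GenomeSpec, params: EngineParameters | None = None,
                    geometry: NuclearGeometry | None = None,
                    box_cells: int = C.BOX_EDGE, seed: int = 0) -> World:
    """Build the 17 chains with centromeres pre-seeded on the SPB shell.

    The equilibrium ensemble is fixed by the Hamiltonian, not the starting
    configuration; anchoring each chain at its centromere (chromosome-12
    chain B at its rDNA boundary near the nucleolus wall) and growing both
    arms along straight backbones pointing away from the pole reaches the
    Rabl steady state with a short relaxation, instead of dragging
    mid-chain monomers across the nucleus.  :func:`initialize_genome` is
    the reference equatorial construction.
    """
    params = params or EngineParameters()
    geometry = geometry or NuclearGeometry()
    lattice = LatticeGeometry(box_edge=box_cells)
    world = World(spec, params, box_cells, periodic=False,
                  geometry=geometry, seed=seed)
    world.blocked[:] = build_confinement(geometry, lattice)
    rng = world.rng
    L = box_cells
    step = C.STEP_NM
    shell_r = 0.5 * sum(geometry.cen_shell_nm) / step
    pts = sunflower_points(spec.n_chains, 0.85 * shell_r)
    wall_zi = int(math.ceil(L - geometry.nucleolus_wall_nm / step)) + 1
    anchors = np.zeros((spec.n_chains, 3), dtype=np.int64)
    used = set()
    for ci, ch in enumerate(spec.chains):
        x, y = pts[ci]
        if ch.centromere is None:
            xi, yi, zi = int(round(L + 1.5 * x)), int(round(L + 1.5 * y)), wall_zi
        else:
            dz2 = max(shell_r ** 2 - x * x - y * y, 4.0)
            xi, yi = int(round(L + x)), int(round(L + y))
            zi = int(round(2 * L - math.sqrt(dz2)))
        if (xi + yi + zi) % 2 == 1:
            xi += 1
        site = None
        for dx, dy, dz in _PARITY_OFFSETS:
            cand = (xi + dx, yi + dy, zi + dz)
            if (cand not in used
                    and all(0 <= v < world.smod for v in cand)
                    and not world.blocked[cand]):
                site = cand
                break
        if site is None:
            raise RuntimeError("could not place a shell anchor")
        used.add(site)
        anchors[ci] = site
    # phase 1: straight descending backbones for every arm
    arms = {}       # (chain, side) -> [path, current_len, target]
    for ci in rng.permutation(spec.n_chains):
        ch = spec.chains[ci]
        pivot = ch.centromere if ch.centromere is not None else 0
        away = -1 if ch.centromere is not None else 1
        arms[(ci, 0)] = _seed_arm(world, anchors[ci], pivot + 1, away, rng,
                                  occupy_start=True)
        # an arm ending at an rDNA boundary gets a deep backbone so the
        # boundary bead starts close to the nucleolus wall
        deep = 110 if ch.rdna_last else 60
        arms[(ci, 1)] = _seed_arm(world, anchors[ci], ch.length - pivot,
                                  away, rng, occupy_start=False,
                                  seed_len=deep)
    # phase 2: round-robin bond-subdivision growth so space fills evenly
    chunk = 64
    stalled = 0
    while True:
        pending = [k for k, a in arms.items() if a[1] < a[2]]
        if not pending:
            break
        progressed = False
        for k in rng.permutation(len(pending)):
            path, ln, target = arms[pending[k]]
            want = min(target, ln + chunk)
            got = K.grow_chain(path, ln, want, world.occ, world.blocked,
                               world.smod, 0, int(rng.integers(2**31 - 1)))
            if got > ln:
                progressed = True
            arms[pending[k]][1] = got
        stalled = 0 if progressed else stalled + 1
        if stalled > 50:
            raise RuntimeError("chain growth jammed; retry with another seed")
    for ci in range(spec.n_chains):
        left = arms[(ci, 0)][0]
        right = arms[(ci, 1)][0]
        path = np.concatenate([left[::-1], right[1:]], axis=0)
        world.place_chain(ci, path)
    world.finalize_chains()
    return world


def _seed_arm(world: World, start: np.ndarray, target: int, zdir: int,
              rng, occupy_start: bool, seed_len: int = 60) -> list:
    """Lay a straight-ish backbone (alternating two z-stepping vectors) for
    an arm of ``target`` monomers; returns [path, current_len, target]."""
    st = tuple(int(v) for v in start)
    if occupy_start:
        world.occ[st] += 1
    path = np.zeros((max(target, 1), 3), dtype=np.int64)
    path[0] = start
    if target <= 1:
        return [path, max(target, 1), max(target, 1)]
    vecs = K.NNV[K.NNV[:, 2] == zdir]
    n_seed = min(target, seed_len)
    for attempt in range(400):
        i1, i2 = rng.choice(len(vecs), size=2, replace=False)
        v1, v2 = vecs[i1], vecs[i2]
        sites = [np.asarray(start)]
        ok = True
        for i in range(1, n_seed):
            s = sites[-1] + (v1 if i % 2 else v2)
            t = tuple(int(v) for v in s)
            if (not all(0 <= v < world.smod for v in t)
                    or world.blocked[t] or world.occ[t]):
                ok = False
                break
            sites.append(s)
        if not ok:
            if attempt % 24 == 23 and n_seed > 3:
                n_seed = max(3, n_seed * 2 // 3)
            continue
        for s in sites[1:]:
            world.occ[tuple(int(v) for v in s)] += 1
        path[:n_seed] = sites
        return [path, n_seed, target]
    raise RuntimeError("backbone placement failed; retry with another seed")


def free_chains(lengths, box_cells: int, params: EngineParameters | None = None,
                periodic: bool = False, seed: int = 0,
                spec: GenomeSpec | None = None) -> World:
    """Chains in an empty box (no confinement, no tethers): toy systems and
    the periodic single-chromosome calibration run."""
    params = params or EngineParameters()
    spec = spec or GenomeSpec.toy(lengths)
    world = World(spec, params, box_cells, periodic=periodic, seed=seed)
    world.role[:] = 0
    rng = world.rng
    n = spec.n_chains
    L = box_cells
    if n == 1:
        x0 = L if (3 * L) % 2 == 0 else L + 1
        starts = np.array([[x0, L, L]], dtype=np.int64)
    else:
        starts = _start_sites(n, L, world.blocked, disc_frac=0.6)
    arm = max(1, box_cells // 8)
    paths = {}
    for ci in range(n):
        paths[ci] = _grow_one(world, starts[ci], spec.chains[ci].length,
                              arm, rng)
    for ci, path in paths.items():
        world.place_chain(ci, path)
    world.finalize_chains()
    world.role[:] = 0      # toy systems carry no tethers
    return world


# ---------------------------------------------------------------------------
# G1 relaxation
# ---------------------------------------------------------------------------

def relax_to_g1(world: World, n_sweeps: int, frame_every: int | None = None,
                monitor_every: int = 1000,
                reptation_fraction: float = 0.1) -> tuple[Trajectory, dict]:
    """Equilibrate toward the Rabl configuration, monitoring the energy and
    the anchor distances; warns if the energy has not plateaued.

    A fraction of slithering-snake trials is mixed in (same equilibrium
    ensemble, much faster chain translation); set it to 0 for pure local
    dynamics."""
    traj = Trajectory(time_per_mcs_ms=world.params.time_per_mcs_ms,
                      gbin=world.gbin, sc=world.sc, n_bins=world.n_bins)
    spb, center = (world.geometry or NuclearGeometry()).anchors_nm(
        world.box_cells)
    cen_bins = world.spec.centromere_bins()
    telo_bins = world.spec.telomere_bins()
    monitor = {"t_mcs": [], "energy": [], "cen_spb_nm": [], "telo_center_nm": []}
    done = 0
    block = min(monitor_every, n_sweeps) if n_sweeps else 0
    while done < n_sweeps:
        step = min(block, n_sweeps - done)
        world.run(step, reptation_fraction=reptation_fraction)
        done += step
        pos_nm = world.pos[:world.n_bins] * C.STEP_NM
        monitor["t_mcs"].append(world.t_mcs)
        monitor["energy"].append(world.total_energy())
        monitor["cen_spb_nm"].append(float(np.mean(np.linalg.norm(
            pos_nm[cen_bins] - spb, axis=1))))
        monitor["telo_center_nm"].append(float(np.mean(np.linalg.norm(
            pos_nm[telo_bins] - center, axis=1))))
        if frame_every and (done % frame_every == 0):
            p, f = world.snapshot()
            traj.add(world.t_mcs, p, f)
    e = monitor["energy"]
    if len(e) >= 4:
        tail = e[-len(e) // 4:]
        if abs(tail[-1] - tail[0]) > 0.05 * (abs(np.mean(tail)) + 1.0):
            warnings.warn("G1 relaxation may not have plateaued; "
                          "consider more sweeps", stacklevel=2)
    return traj, monitor
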