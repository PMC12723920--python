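"""Numba kernels of the kinetic Monte Carlo engine.

State lives in flat numpy arrays owned by :class:`replisim.world.World`; the
kernels mutate them in place.  Conventions:

* sites are integer triples of even coordinate sum; one integer step is
  sigma/sqrt(2) nm, so squared integer distances convert to squared
  bead-diameter units by a factor 1/2;
* ``nb``/``nnb`` hold the bonded neighbours of each monomer (up to 3: a
  replication-fork junction has triple connectivity);
* ``ang``/``nang`` hold the angle triplets (pairs of neighbour ids) through
  each monomer, one per strand passing through it;
* energies are in kT.

Parameter packing (``par`` float64 vector) -- see index constants below.
"""

import numpy as np
from numba import njit

# --- par indices ------------------------------------------------------------
P_KAPPA = 0
P_KTETHER = 1
P_JSISTER = 2
P_TH2U = 3          # sister saturation distance^2, bead-diameter units
P_JF = 4
P_WALLZ = 5         # nucleolus wall plane, integer z coordinate (float)
P_CENLO2 = 6        # centromere shell bounds, squared integer distance
P_CENHI2 = 7
P_TELO2 = 8         # telomere shell bound, squared integer distance
P_SPBX, P_SPBY, P_SPBZ = 9, 10, 11
P_CENX, P_CENY, P_CENZ = 12, 13, 14
P_PSTEP = 15        # fork step probability per MCS
P_ORATE = 16        # OriginRate per MCS
P_NF = 17           # total firing factors
P_RAMPA = 18        # factor ramp amplitude
P_RAMPTAU = 19      # factor ramp time constant, MCS
NPAR = 20

# --- ipar indices -----------------------------------------------------------
I_PERIODIC = 0
I_SMOD = 1          # coordinate modulus (periodic) / grid size (bounded)
I_INTERACT = 2      # sister-fork pairing scenario flag
I_JFON = 3          # non-specific fork interactions flag
NIPAR = 4

# --- cnt indices ------------------------------------------------------------
C_NMON = 0
C_NFORKS = 1
C_FREGSZ = 2
C_NPORI = 3
C_NEV = 4
C_ACC = 5
C_NREP = 6
C_TRIALS = 7
C_TMCS = 8
NCNT = 9

# role bits
ROLE_CEN = 1
ROLE_TELO = 2
ROLE_RDNA = 4

# event types
EV_FIRE = 0
EV_MERGE = 1
EV_OPEN = 2

NNV = np.array(
    [[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0],
     [1, 0, 1], [1, 0, -1], [-1, 0, 1], [-1, 0, -1],
     [0, 1, 1], [0, 1, -1], [0, -1, 1], [0, -1, -1]], dtype=np.int64)


def _ball_offsets(max_sq: int = 8) -> np.ndarray:
    """All even-parity integer offsets with squared norm <= max_sq (40 nm)."""
    out = []
    for x in range(-3, 4):
        for y in range(-3, 4):
            for z in range(-3, 4):
                if (x + y + z) % 2 == 0 and 0 < x * x + y * y + z * z <= max_sq:
                    out.append((x, y, z))
    out.append((0, 0, 0))
    return np.array(sorted(out), dtype=np.int64)


BALL = _ball_offsets()


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _widx(v, smod, periodic):
    if periodic == 1:
        return v % smod
    return v


@njit(cache=True, inline="always")
def _angle_term(ux, uy, uz, cx, cy, cz, wx, wy, wz, kappa):
    # bonds are nearest-neighbour vectors of squared length 2
    b1x = cx - ux
    b1y = cy - uy
    b1z = cz - uz
    b2x = wx - cx
    b2y = wy - cy
    b2z = wz - cz
    cos = (b1x * b2x + b1y * b2y + b1z * b2z) * 0.5
    return kappa * (1.0 - cos)


@njit(cache=True)
def _bend_local(m, x, y, z, pos, nb, nnb, ang, nang, kappa):
    """Bending energy of all angle triplets involving monomer m, with m at
    trial position (x, y, z) and everything else at its current position."""
    e = 0.0
    for t in range(nang[m]):
        u = ang[m, t, 0]
        w = ang[m, t, 1]
        e += _angle_term(pos[u, 0], pos[u, 1], pos[u, 2], x, y, z,
                         pos[w, 0], pos[w, 1], pos[w, 2], kappa)
    for k in range(nnb[m]):
        c = nb[m, k]
        for t in range(nang[c]):
            u = ang[c, t, 0]
            w = ang[c, t, 1]
            if u == m:
                e += _angle_term(x, y, z,
                                 pos[c, 0], pos[c, 1], pos[c, 2],
                                 pos[w, 0], pos[w, 1], pos[w, 2], kappa)
            elif w == m:
                e += _angle_term(pos[u, 0], pos[u, 1], pos[u, 2],
                                 pos[c, 0], pos[c, 1], pos[c, 2],
                                 x, y, z, kappa)
    return e


@njit(cache=True, inline="always")
def _tether_local(r, x, y, z, par):
    """Tethering energy of a monomer with role bits r at (x, y, z), kT."""
    e = 0.0
    k = par[P_KTETHER]
    if r & ROLE_CEN:
        dx = x - par[P_SPBX]
        dy = y - par[P_SPBY]
        dz = z - par[P_SPBZ]
        d2 = dx * dx + dy * dy + dz * dz
        if not (par[P_CENLO2] < d2 < par[P_CENHI2]):
            e += k * d2 * 0.5
    if r & ROLE_TELO:
        # outward drive -k d^2 inside the 950 nm shell, shifted to be
        # continuous (and zero) at the free-diffusion shell boundary
        dx = x - par[P_CENX]
        dy = y - par[P_CENY]
        dz = z - par[P_CENZ]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < par[P_TELO2]:
            e += k * (par[P_TELO2] - d2) * 0.5
    if r & ROLE_RDNA:
        h = z - par[P_WALLZ]
        e += k * h * h * 0.5
    return e


@njit(cache=True, inline="always")
def _sister_local(m, x, y, z, pos, fork_of_mon, f_mon, f_partner, f_pair,
                  f_alive, par):
    fi = fork_of_mon[m]
    if fi < 0 or f_pair[fi] == 0:
        return 0.0
    pj = f_partner[fi]
    if pj < 0 or f_alive[pj] == 0:
        return 0.0
    q = f_mon[pj]
    dx = x - pos[q, 0]
    dy = y - pos[q, 1]
    dz = z - pos[q, 2]
    d2u = (dx * dx + dy * dy + dz * dz) * 0.5
    th2 = par[P_TH2U]
    j = par[P_JSISTER]
    if d2u <= th2:
        return -j
    return j * (d2u / th2 - 2.0)


@njit(cache=True)
def _fork_field_add(p, fld, smod, periodic, delta):
    for b in range(BALL.shape[0]):
        x = _widx(p[0] + BALL[b, 0], smod, periodic)
        y = _widx(p[1] + BALL[b, 1], smod, periodic)
        z = _widx(p[2] + BALL[b, 2], smod, periodic)
        if 0 <= x < fld.shape[0] and 0 <= y < fld.shape[1] and 0 <= z < fld.shape[2]:
            fld[x, y, z] += delta


@njit(cache=True)
def _total_energy(pos, nb, nnb, ang, nang, role, fork_of_mon,
                  f_mon, f_partner, f_pair, f_alive, n_forks_list, nf_alive,
                  par, n_mon, jf_on):
    """Full Hamiltonian recomputation (bookkeeping checks; O(N))."""
    e = 0.0
    for m in range(n_mon):
        for t in range(nang[m]):
            u = ang[m, t, 0]
            w = ang[m, t, 1]
            e += _angle_term(pos[u, 0], pos[u, 1], pos[u, 2],
                             pos[m, 0], pos[m, 1], pos[m, 2],
                             pos[w, 0], pos[w, 1], pos[w, 2], par[P_KAPPA])
        if role[m]:
            e += _tether_local(role[m], pos[m, 0], pos[m, 1], pos[m, 2], par)
    # sister springs, one term per intact pair
    for li in range(nf_alive):
        fi = n_forks_list[li]
        pj = f_partner[fi]
        if f_pair[fi] == 1 and pj >= 0 and fi < pj and f_alive[pj] == 1:
            m = f_mon[fi]
            e += _sister_local(m, pos[m, 0], pos[m, 1], pos[m, 2], pos,
                               fork_of_mon, f_mon, f_partner, f_pair,
                               f_alive, par)
    if jf_on == 1:
        jf = par[P_JF]
        for li in range(nf_alive):
            fi = n_forks_list[li]
            mi = f_mon[fi]
            for lj in range(li + 1, nf_alive):
                fj = n_forks_list[lj]
                mj = f_mon[fj]
                dx = pos[mi, 0] - pos[mj, 0]
                dy = pos[mi, 1] - pos[mj, 1]
                dz = pos[mi, 2] - pos[mj, 2]
                if dx * dx + dy * dy + dz * dz <= 8:
                    e += -jf
    return e


# ---------------------------------------------------------------------------
# Monte Carlo sweep
# ---------------------------------------------------------------------------

@njit(cache=True)
def _attempt_move(pos, nb, nnb, ang, nang, role, occ, blocked, fork_of_mon,
                  f_mon, f_partner, f_pair, f_alive, fld, par, ipar, cnt):
    n_mon = cnt[C_NMON]
    m = np.random.randint(0, n_mon)
    periodic = ipar[I_PERIODIC]
    smod = ipar[I_SMOD]
    # geometric candidate set: sites bonded-adjacent to every neighbour of m.
    # It depends only on the neighbours' positions, so proposing uniformly
    # from it is symmetric and preserves detailed balance.
    if nnb[m] == 0:
        ax, ay, az = pos[m, 0], pos[m, 1], pos[m, 2]
    else:
        u = nb[m, 0]
        ax, ay, az = pos[u, 0], pos[u, 1], pos[u, 2]
    mx, my, mz = pos[m, 0], pos[m, 1], pos[m, 2]
    ncand = 0
    for vi in range(12):
        x = ax + NNV[vi, 0]
        y = ay + NNV[vi, 1]
        z = az + NNV[vi, 2]
        if x == mx and y == my and z == mz:
            continue        # the current site is excluded in both states
        ok = True
        for k in range(1, nnb[m]):
            w = nb[m, k]
            dx = x - pos[w, 0]
            dy = y - pos[w, 1]
            dz = z - pos[w, 2]
            if dx * dx + dy * dy + dz * dz != 2:
                ok = False
                break
        if ok:
            ncand += 1
    if ncand == 0:
        return 0
    ci = np.random.randint(0, ncand)
    x = mx
    y = my
    z = mz
    hit = -1
    for vi in range(12):
        xx = ax + NNV[vi, 0]
        yy = ay + NNV[vi, 1]
        zz = az + NNV[vi, 2]
        if xx == mx and yy == my and zz == mz:
            continue
        ok = True
        for k in range(1, nnb[m]):
            w = nb[m, k]
            dx = xx - pos[w, 0]
            dy = yy - pos[w, 1]
            dz = zz - pos[w, 2]
            if dx * dx + dy * dy + dz * dz != 2:
                ok = False
                break
        if ok:
            hit += 1
            if hit == ci:
                x, y, z = xx, yy, zz
                break
    xi = _widx(x, smod, periodic)
    yi = _widx(y, smod, periodic)
    zi = _widx(z, smod, periodic)
    if periodic == 0:
        if xi < 0 or yi < 0 or zi < 0 or xi >= smod or yi >= smod or zi >= smod:
            return 0
    if blocked[xi, yi, zi] == 1 or occ[xi, yi, zi] > 0:
        return 0

    ox, oy, oz = pos[m, 0], pos[m, 1], pos[m, 2]
    kappa = par[P_KAPPA]
    dh = (_bend_local(m, x, y, z, pos, nb, nnb, ang, nang, kappa)
          - _bend_local(m, ox, oy, oz, pos, nb, nnb, ang, nang, kappa))
    if role[m]:
        dh += (_tether_local(role[m], x, y, z, par)
               - _tether_local(role[m], ox, oy, oz, par))
    is_fork = fork_of_mon[m] >= 0
    if is_fork:
        dh += (_sister_local(m, x, y, z, pos, fork_of_mon, f_mon, f_partner,
                             f_pair, f_alive, par)
               - _sister_local(m, ox, oy, oz, pos, fork_of_mon, f_mon,
                               f_partner, f_pair, f_alive, par))
        if ipar[I_JFON] == 1:
            # counts exclude this fork's own contribution to the field
            dx = x - ox
            dy = y - oy
            dz = z - oz
            own_new = 1 if dx * dx + dy * dy + dz * dz <= 8 else 0
            c_old = fld[_widx(ox, smod, periodic), _widx(oy, smod, periodic),
                        _widx(oz, smod, periodic)] - 1
            c_new = fld[xi, yi, zi] - own_new
            dh += -par[P_JF] * (float(c_new) - float(c_old))

    if dh > 0.0:
        if np.random.random() >= np.exp(-dh):
            return 0
    # accept
    oxi = _widx(ox, smod, periodic)
    oyi = _widx(oy, smod, periodic)
    ozi = _widx(oz, smod, periodic)
    occ[oxi, oyi, ozi] -= 1
    occ[xi, yi, zi] += 1
    pos[m, 0] = x
    pos[m, 1] = y
    pos[m, 2] = z
    if is_fork and ipar[I_JFON] == 1:
        old = np.empty(3, dtype=np.int64)
        old[0], old[1], old[2] = ox, oy, oz
        new = np.empty(3, dtype=np.int64)
        new[0], new[1], new[2] = x, y, z
        _fork_field_add(old, fld, smod, periodic, -1)
        _fork_field_add(new, fld, smod, periodic, 1)
    cnt[C_ACC] += 1
    return 1


@njit(cache=True)
def _attempt_reptation(pos, role, occ, blocked, chain_first, chain_last,
                       par, ipar):
    """Slithering-snake trial: the chain slides one site along its contour.

    Used only for equilibration of unreplicated chains (linear topology):
    it samples the same Boltzmann ensemble as the local moves but
    translates tethered chains orders of magnitude faster.  Proposal:
    uniform chain, uniform end, uniform direction — symmetric.
    """
    nchain = chain_first.shape[0]
    c = np.random.randint(0, nchain)
    b0 = chain_first[c]
    b1 = chain_last[c]
    n = b1 - b0 + 1
    if n < 3:
        return 0
    periodic = ipar[I_PERIODIC]
    smod = ipar[I_SMOD]
    if np.random.randint(0, 2) == 0:
        head, tail, step = b1, b0, 1
    else:
        head, tail, step = b0, b1, -1
    v = NNV[np.random.randint(0, 12)]
    hx = pos[head, 0] + v[0]
    hy = pos[head, 1] + v[1]
    hz = pos[head, 2] + v[2]
    xi = _widx(hx, smod, periodic)
    yi = _widx(hy, smod, periodic)
    zi = _widx(hz, smod, periodic)
    if periodic == 0:
        if xi < 0 or yi < 0 or zi < 0 or xi >= smod or yi >= smod or zi >= smod:
            return 0
    if blocked[xi, yi, zi] == 1 or occ[xi, yi, zi] > 0:
        return 0
    kappa = par[P_KAPPA]
    # bending: one joint appears at the old head, one disappears at the tail
    p1 = head - step
    dh = _angle_term(pos[p1, 0], pos[p1, 1], pos[p1, 2],
                     pos[head, 0], pos[head, 1], pos[head, 2],
                     hx, hy, hz, kappa)
    t1 = tail + step
    t2 = tail + 2 * step
    dh -= _angle_term(pos[tail, 0], pos[tail, 1], pos[tail, 2],
                      pos[t1, 0], pos[t1, 1], pos[t1, 2],
                      pos[t2, 0], pos[t2, 1], pos[t2, 2], kappa)
    # tethers: every role-carrying monomer of the chain shifts by one site
    for r in range(b0, b1 + 1):
        if role[r] == 0:
            continue
        rn = r + step
        if b0 <= rn <= b1:
            nx, ny, nz = pos[rn, 0], pos[rn, 1], pos[rn, 2]
        else:
            nx, ny, nz = hx, hy, hz
        dh += (_tether_local(role[r], nx, ny, nz, par)
               - _tether_local(role[r], pos[r, 0], pos[r, 1], pos[r, 2], par))
    if dh > 0.0:
        if np.random.random() >= np.exp(-dh):
            return 0
    # accept: slide positions along the contour
    txi = _widx(pos[tail, 0], smod, periodic)
    tyi = _widx(pos[tail, 1], smod, periodic)
    tzi = _widx(pos[tail, 2], smod, periodic)
    occ[txi, tyi, tzi] -= 1
    occ[xi, yi, zi] += 1
    if step == 1:
        for b in range(b0, b1):
            pos[b, 0] = pos[b + 1, 0]
            pos[b, 1] = pos[b + 1, 1]
            pos[b, 2] = pos[b + 1, 2]
    else:
        for b in range(b1, b0, -1):
            pos[b, 0] = pos[b - 1, 0]
            pos[b, 1] = pos[b - 1, 1]
            pos[b, 2] = pos[b - 1, 2]
    pos[head, 0] = hx
    pos[head, 1] = hy
    pos[head, 2] = hz
    return 1


@njit(cache=True)
def _attempt_chain_translate(pos, role, occ, blocked, chain_first,
                             chain_last, par, ipar):
    """Rigid translation of one chain by a nearest-neighbour vector.

    Equilibration-only companion to reptation: bending is untouched, only
    tether energies change, so tethered chains drift bodily toward their
    anchors.  Proposal (uniform chain, uniform vector) is symmetric.
    """
    nchain = chain_first.shape[0]
    c = np.random.randint(0, nchain)
    b0 = chain_first[c]
    b1 = chain_last[c]
    periodic = ipar[I_PERIODIC]
    smod = ipar[I_SMOD]
    v = NNV[np.random.randint(0, 12)]
    # remove own occupancy, then test the shifted footprint
    for b in range(b0, b1 + 1):
        occ[_widx(pos[b, 0], smod, periodic), _widx(pos[b, 1], smod, periodic),
            _widx(pos[b, 2], smod, periodic)] -= 1
    ok = True
    for b in range(b0, b1 + 1):
        x = pos[b, 0] + v[0]
        y = pos[b, 1] + v[1]
        z = pos[b, 2] + v[2]
        xi = _widx(x, smod, periodic)
        yi = _widx(y, smod, periodic)
        zi = _widx(z, smod, periodic)
        if periodic == 0:
            if xi < 0 or yi < 0 or zi < 0 or xi >= smod or yi >= smod or zi >= smod:
                ok = False
                break
        if blocked[xi, yi, zi] == 1 or occ[xi, yi, zi] > 0:
            ok = False
            break
    if ok:
        dh = 0.0
        for b in range(b0, b1 + 1):
            if role[b]:
                dh += (_tether_local(role[b], pos[b, 0] + v[0],
                                     pos[b, 1] + v[1], pos[b, 2] + v[2], par)
                       - _tether_local(role[b], pos[b, 0], pos[b, 1],
                                       pos[b, 2], par))
        if dh > 0.0 and np.random.random() >= np.exp(-dh):
            ok = False
    if not ok:
        for b in range(b0, b1 + 1):
            occ[_widx(pos[b, 0], smod, periodic),
                _widx(pos[b, 1], smod, periodic),
                _widx(pos[b, 2], smod, periodic)] += 1
        return 0
    for b in range(b0, b1 + 1):
        pos[b, 0] += v[0]
        pos[b, 1] += v[1]
        pos[b, 2] += v[2]
        occ[_widx(pos[b, 0], smod, periodic),
            _widx(pos[b, 1], smod, periodic),
            _widx(pos[b, 2], smod, periodic)] += 1
    return 1


@njit(cache=True)
def _sweep(pos, nb, nnb, ang, nang, role, occ, blocked, fork_of_mon,
           f_mon, f_partner, f_pair, f_alive, fld, par, ipar, cnt):
    """One MCS: one trial move per currently existing monomer."""
    n = cnt[C_NMON]
    for _ in range(n):
        _attempt_move(pos, nb, nnb, ang, nang, role, occ, blocked,
                      fork_of_mon, f_mon, f_partner, f_pair, f_alive,
                      fld, par, ipar, cnt)
    cnt[C_TRIALS] += n


@njit(cache=True)
def run_sweeps(n_mcs, seed, pos, nb, nnb, ang, nang, role, occ, blocked,
               fork_of_mon, f_mon, f_partner, f_pair, f_alive, fld,
               par, ipar, cnt, chain_first, chain_last, rept_frac):
    """Plain (non-replicating) kinetic Monte Carlo for n_mcs sweeps.

    ``rept_frac`` > 0 mixes in that fraction of reptation trials per sweep
    (equilibration only; requires linear, unreplicated chains)."""
    np.random.seed(seed)
    for _ in range(n_mcs):
        _sweep(pos, nb, nnb, ang, nang, role, occ, blocked, fork_of_mon,
               f_mon, f_partner, f_pair, f_alive, fld, par, ipar, cnt)
        if rept_frac > 0.0:
            n_rep = int(rept_frac * cnt[C_NMON])
            for _ in range(n_rep):
                cnt[C_ACC] += _attempt_reptation(pos, role, occ, blocked,
                                                 chain_first, chain_last,
                                                 par, ipar)
            nchain = chain_first.shape[0]
            for _ in range(nchain):
                cnt[C_ACC] += _attempt_chain_translate(pos, role, occ,
                                                       blocked, chain_first,
                                                       chain_last, par, ipar)
            cnt[C_TRIALS] += n_rep + nchain
        cnt[C_TMCS] += 1


# ---------------------------------------------------------------------------
# replication topology events
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _add_nb(nb, nnb, i, j):
    nb[i, nnb[i]] = j
    nnb[i] += 1


@njit(cache=True)
def _remove_nb(nb, nnb, i, j):
    for k in range(nnb[i]):
        if nb[i, k] == j:
            nnb[i] -= 1
            nb[i, k] = nb[i, nnb[i]]
            nb[i, nnb[i]] = -1
            return
    # bond bookkeeping is an invariant; a miss is a fatal inconsistency
    raise RuntimeError("bond table inconsistent")


@njit(cache=True)
def _recompute_angles(i, nb, nnb, ang, nang, fork_of_mon, f_bin, f_dir,
                      mat_id, copy_id):
    d = nnb[i]
    if d < 2:
        nang[i] = 0
    elif d == 2:
        ang[i, 0, 0] = nb[i, 0]
        ang[i, 0, 1] = nb[i, 1]
        nang[i] = 1
    else:
        fi = fork_of_mon[i]
        j = f_bin[fi]
        dirn = f_dir[fi]
        ang[i, 0, 0] = mat_id[j - 1]
        ang[i, 0, 1] = mat_id[j + 1]
        ang[i, 1, 0] = copy_id[j - dirn]
        ang[i, 1, 1] = mat_id[j + dirn]
        nang[i] = 2


@njit(cache=True)
def _new_monomer(template, b, pos, nb, nnb, nang, role, sc, gbin, occ,
                 fork_of_mon, ipar, cnt):
    n = cnt[C_NMON]
    cnt[C_NMON] = n + 1
    pos[n, 0] = pos[template, 0]
    pos[n, 1] = pos[template, 1]
    pos[n, 2] = pos[template, 2]
    nnb[n] = 0
    nang[n] = 0
    role[n] = role[template]
    sc[n] = 2
    gbin[n] = b
    fork_of_mon[n] = -1
    xi = _widx(pos[n, 0], ipar[I_SMOD], ipar[I_PERIODIC])
    yi = _widx(pos[n, 1], ipar[I_SMOD], ipar[I_PERIODIC])
    zi = _widx(pos[n, 2], ipar[I_SMOD], ipar[I_PERIODIC])
    occ[xi, yi, zi] += 1
    return n


@njit(cache=True)
def _new_fork(b, dirn, mon, f_bin, f_dir, f_mon, f_partner, f_pair, f_alive,
              falive_list, f_pos_in_list, junction_of_bin, fork_of_mon,
              pos, fld, ipar, cnt):
    fi = cnt[C_FREGSZ]
    cnt[C_FREGSZ] = fi + 1
    f_bin[fi] = b
    f_dir[fi] = dirn
    f_mon[fi] = mon
    f_partner[fi] = -1
    f_pair[fi] = 0
    f_alive[fi] = 1
    li = cnt[C_NFORKS]
    falive_list[li] = fi
    f_pos_in_list[fi] = li
    cnt[C_NFORKS] = li + 1
    junction_of_bin[b] = fi
    fork_of_mon[mon] = fi
    if ipar[I_JFON] == 1:
        _fork_field_add(pos[mon], fld, ipar[I_SMOD], ipar[I_PERIODIC], 1)
    return fi


@njit(cache=True)
def _kill_fork(fi, f_bin, f_mon, f_partner, f_pair, f_alive, falive_list,
               f_pos_in_list, junction_of_bin, fork_of_mon, pos, fld,
               ipar, cnt):
    f_alive[fi] = 0
    junction_of_bin[f_bin[fi]] = -1
    fork_of_mon[f_mon[fi]] = -1
    if ipar[I_JFON] == 1:
        _fork_field_add(pos[f_mon[fi]], fld, ipar[I_SMOD], ipar[I_PERIODIC], -1)
    # pairing dissolves when one partner is lost; survivors diffuse freely
    pj = f_partner[fi]
    if pj >= 0:
        f_partner[pj] = -1
        f_pair[pj] = 0
    f_partner[fi] = -1
    f_pair[fi] = 0
    li = f_pos_in_list[fi]
    last = cnt[C_NFORKS] - 1
    moved = falive_list[last]
    falive_list[li] = moved
    f_pos_in_list[moved] = li
    cnt[C_NFORKS] = last


@njit(cache=True)
def _log_event(t, kind, b, ev, cnt):
    i = cnt[C_NEV]
    if i < ev.shape[0]:
        ev[i, 0] = t
        ev[i, 1] = kind
        ev[i, 2] = b
        cnt[C_NEV] = i + 1


@njit(cache=True)
def _fire_origin(b, t, pos, nb, nnb, ang, nang, role, sc, gbin, occ,
                 fork_of_mon, f_bin, f_dir, f_mon, f_partner, f_pair,
                 f_alive, falive_list, f_pos_in_list, junction_of_bin,
                 mat_id, copy_id, rep_time, bin_chain, chain_first,
                 chain_last, fld, ev, par, ipar, cnt):
    """Open a one-monomer replication bubble at global bin b.

    Returns 1 on success, 0 on a skipped trial (no factor consumed)."""
    if rep_time[b] >= 0.0 or junction_of_bin[b] >= 0:
        return 0
    c = bin_chain[b]
    if b - 1 <= chain_first[c] or b + 1 >= chain_last[c]:
        return 0
    if junction_of_bin[b - 1] >= 0 or junction_of_bin[b + 1] >= 0:
        return 0
    nf_t = par[P_NF] * (1.0 - par[P_RAMPA] * np.exp(-t / par[P_RAMPTAU]))
    if nf_t - cnt[C_NFORKS] * 0.5 < 1.0:
        return 0
    m = mat_id[b]
    u = mat_id[b - 1]
    w = mat_id[b + 1]
    n = _new_monomer(m, b, pos, nb, nnb, nang, role, sc, gbin, occ,
                     fork_of_mon, ipar, cnt)
    _add_nb(nb, nnb, n, u)
    _add_nb(nb, nnb, n, w)
    _add_nb(nb, nnb, u, n)
    _add_nb(nb, nnb, w, n)
    rep_time[b] = t
    copy_id[b] = n
    cnt[C_NREP] += 1
    fl = _new_fork(b - 1, -1, u, f_bin, f_dir, f_mon, f_partner, f_pair,
                   f_alive, falive_list, f_pos_in_list, junction_of_bin,
                   fork_of_mon, pos, fld, ipar, cnt)
    fr = _new_fork(b + 1, 1, w, f_bin, f_dir, f_mon, f_partner, f_pair,
                   f_alive, falive_list, f_pos_in_list, junction_of_bin,
                   fork_of_mon, pos, fld, ipar, cnt)
    if ipar[I_INTERACT] == 1:
        f_partner[fl] = fr
        f_partner[fr] = fl
        f_pair[fl] = 1
        f_pair[fr] = 1
    _recompute_angles(u, nb, nnb, ang, nang, fork_of_mon, f_bin, f_dir,
                      mat_id, copy_id)
    _recompute_angles(w, nb, nnb, ang, nang, fork_of_mon, f_bin, f_dir,
                      mat_id, copy_id)
    _recompute_angles(n, nb, nnb, ang, nang, fork_of_mon, f_bin, f_dir,
                      mat_id, copy_id)
    _log_event(t, EV_FIRE, b, ev, cnt)
    return 1


@njit(cache=True)
def _advance_fork(fi, t, pos, nb, nnb, ang, nang, role, sc, gbin, occ,
                  fork_of_mon, f_bin, f_dir, f_mon, f_partner, f_pair,
                  f_alive, falive_list, f_pos_in_list, junction_of_bin,
                  mat_id, copy_id, rep_time, bin_chain, chain_first,
                  chain_last, fld, ev, par, ipar, cnt):
    """Replicate one monomer at fork fi, moving/merging/opening the bubble."""
    j = f_bin[fi]
    d = f_dir[fi]
    jn = j + d
    c = bin_chain[j]
    mj = f_mon[fi]
    s = copy_id[j - d]
    n1 = _new_monomer(mj, j, pos, nb, nnb, nang, role, sc, gbin, occ,
                      fork_of_mon, ipar, cnt)
    _remove_nb(nb, nnb, mj, s)
    _remove_nb(nb, nnb, s, mj)
    _add_nb(nb, nnb, n1, s)
    _add_nb(nb, nnb, s, n1)
    rep_time[j] = t
    copy_id[j] = n1
    cnt[C_NREP] += 1

    fj = junction_of_bin[jn]
    if fj >= 0:
        # convergent forks adjacent along the chain: replicate as a pair,
        # merging the two bubbles and releasing one firing factor
        mjn = f_mon[fj]
        s2 = copy_id[jn + d]
        n2 = _new_monomer(mjn, jn, pos, nb, nnb, nang, role, sc, gbin, occ,
                          fork_of_mon, ipar, cnt)
        _remove_nb(nb, nnb, mjn, s2)
        _remove_nb(nb, nnb, s2, mjn)
        _add_nb(nb, nnb, n2, s2)
        _add_nb(nb, nnb, s2, n2)
        _add_nb(nb, nnb, n1, n2)
        _add_nb(nb, nnb, n2, n1)
        rep_time[jn] = t
        copy_id[jn] = n2
        cnt[C_NREP] += 1
        _kill_fork(fi, f_bin, f_mon, f_partner, f_pair, f_alive, falive_list,
                   f_pos_in_list, junction_of_bin, fork_of_mon, pos, fld,
                   ipar, cnt)
        _kill_fork(fj, f_bin, f_mon, f_partner, f_pair, f_alive, falive_list,
                   f_pos_in_list, junction_of_bin, fork_of_mon, pos, fld,
                   ipar, cnt)
        for i in (mj, mjn, n1, n2, s, s2):
            _recompute_angles(i, nb, nnb, ang, nang, fork_of_mon, f_bin,
                              f_dir, mat_id, copy_id)
        _log_event(t, EV_MERGE, j, ev, cnt)
    elif jn == chain_first[c] or jn == chain_last[c]:
        # fork adjacent to a chain end: open the bubble by replicating both
        # the fork and the chain-end monomer
        mjn = mat_id[jn]
        n2 = _new_monomer(mjn, jn, pos, nb, nnb, nang, role, sc, gbin, occ,
                          fork_of_mon, ipar, cnt)
        _add_nb(nb, nnb, n1, n2)
        _add_nb(nb, nnb, n2, n1)
        rep_time[jn] = t
        copy_id[jn] = n2
        cnt[C_NREP] += 1
        _kill_fork(fi, f_bin, f_mon, f_partner, f_pair, f_alive, falive_list,
                   f_pos_in_list, junction_of_bin, fork_of_mon, pos, fld,
                   ipar, cnt)
        for i in (mj, n1, n2, s):
            _recompute_angles(i, nb, nnb, ang, nang, fork_of_mon, f_bin,
                              f_dir, mat_id, copy_id)
        _log_event(t, EV_OPEN, j, ev, cnt)
    else:
        # plain progression: the triple connectivity moves one bin outward
        mjn = mat_id[jn]
        _add_nb(nb, nnb, n1, mjn)
        _add_nb(nb, nnb, mjn, n1)
        junction_of_bin[j] = -1
        fork_of_mon[mj] = -1
        if ipar[I_JFON] == 1:
            _fork_field_add(pos[mj], fld, ipar[I_SMOD], ipar[I_PERIODIC], -1)
            _fork_field_add(pos[mjn], fld, ipar[I_SMOD], ipar[I_PERIODIC], 1)
        f_bin[fi] = jn
        f_mon[fi] = mjn
        junction_of_bin[jn] = fi
        fork_of_mon[mjn] = fi
        for i in (mj, n1, mjn, s):
            _recompute_angles(i, nb, nnb, ang, nang, fork_of_mon, f_bin,
                              f_dir, mat_id, copy_id)


@njit(cache=True)
def run_s_phase_block(n_mcs, seed, pos, nb, nnb, ang, nang, role, sc, gbin,
                      occ, blocked, fork_of_mon, f_bin, f_dir, f_mon,
                      f_partner, f_pair, f_alive, falive_list, f_pos_in_list,
                      junction_of_bin, mat_id, copy_id, rep_time, bin_chain,
                      chain_first, chain_last, pori_list, fld, ev,
                      par, ipar, cnt, n_bins_total):
    """Coupled 3D S-phase driver: per MCS one sweep, then firing trials for
    the active p-ori entries and one Bernoulli advance trial per live fork.

    Stops early once the genome is fully replicated; returns MCS executed."""
    np.random.seed(seed)
    done = 0
    for step in range(n_mcs):
        _sweep(pos, nb, nnb, ang, nang, role, occ, blocked, fork_of_mon,
               f_mon, f_partner, f_pair, f_alive, fld, par, ipar, cnt)
        t = float(cnt[C_TMCS])
        # firing trials
        npori = cnt[C_NPORI]
        if npori > 0:
            nf_t = par[P_NF] * (1.0 - par[P_RAMPA] * np.exp(-t / par[P_RAMPTAU]))
            free = nf_t - cnt[C_NFORKS] * 0.5
            p = free * par[P_ORATE]
            if p > 1.0:
                p = 1.0
            if p > 0.0:
                k = np.random.binomial(npori, p)
                for _ in range(k):
                    if cnt[C_NPORI] <= 0:
                        break
                    idx = np.random.randint(0, cnt[C_NPORI])
                    b = pori_list[idx]
                    if rep_time[b] >= 0.0:
                        cnt[C_NPORI] -= 1
                        pori_list[idx] = pori_list[cnt[C_NPORI]]
                        continue
                    ok = _fire_origin(b, t, pos, nb, nnb, ang, nang, role, sc,
                                      gbin, occ, fork_of_mon, f_bin, f_dir,
                                      f_mon, f_partner, f_pair, f_alive,
                                      falive_list, f_pos_in_list,
                                      junction_of_bin, mat_id, copy_id,
                                      rep_time, bin_chain, chain_first,
                                      chain_last, fld, ev, par, ipar, cnt)
                    if ok == 1:
                        cnt[C_NPORI] -= 1
                        pori_list[idx] = pori_list[cnt[C_NPORI]]
        # fork progression trials
        nfk = cnt[C_NFORKS]
        if nfk > 0:
            k2 = np.random.binomial(nfk, par[P_PSTEP])
            for _ in range(k2):
                if cnt[C_NFORKS] <= 0:
                    break
                li = np.random.randint(0, cnt[C_NFORKS])
                fi = falive_list[li]
                _advance_fork(fi, t, pos, nb, nnb, ang, nang, role, sc, gbin,
                              occ, fork_of_mon, f_bin, f_dir, f_mon,
                              f_partner, f_pair, f_alive, falive_list,
                              f_pos_in_list, junction_of_bin, mat_id,
                              copy_id, rep_time, bin_chain, chain_first,
                              chain_last, fld, ev, par, ipar, cnt)
        cnt[C_TMCS] += 1
        done = step + 1
        if cnt[C_NREP] >= n_bins_total:
            break
        if (step & 4095) == 4095:
            # drop p-ori entries whose locus has been replicated meanwhile
            i = 0
            while i < cnt[C_NPORI]:
                if rep_time[pori_list[i]] >= 0.0:
                    cnt[C_NPORI] -= 1
                    pori_list[i] = pori_list[cnt[C_NPORI]]
                else:
                    i += 1
    return done


# ---------------------------------------------------------------------------
# 1D-only replication kinetics (no 3D state)
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_1d(seed, n_mcs_max, rep_time, junction_of_bin, bin_chain,
           chain_first, chain_last, pori_list, n_pori,
           nf_total, ramp_amp, ramp_tau, orate, pstep,
           fork_log_t, fork_log_n, ev):
    """Event-driven 1D replication: identical firing/advance/merge rules as
    the 3D engine, on genomic bins only.

    Inter-event gaps are sampled geometrically from the combined per-MCS
    event probability, refreshed after every event and capped at 4096 MCS so
    the factor ramp is tracked to <0.1%.  Returns (t_end, n_replicated,
    n_events_logged, n_fork_log).
    """
    np.random.seed(seed)
    G = rep_time.shape[0]
    nchain = chain_first.shape[0]
    cap_f = 2 * n_pori + 4
    f_bin = np.full(cap_f, -1, dtype=np.int64)
    f_dir = np.zeros(cap_f, dtype=np.int64)
    f_alive = np.zeros(cap_f, dtype=np.uint8)
    falive = np.full(cap_f, -1, dtype=np.int64)
    fpos = np.full(cap_f, -1, dtype=np.int64)
    nreg = 0
    nforks = 0
    npori = n_pori
    nrep = 0
    nev = 0
    nlog = 0
    t = 0.0
    while t < n_mcs_max and nrep < G:
        nf_t = nf_total * (1.0 - ramp_amp * np.exp(-t / ramp_tau))
        free = nf_t - nforks * 0.5
        pf = free * orate
        if pf < 0.0:
            pf = 0.0
        elif pf > 1.0:
            pf = 1.0
        q = 1.0 - (1.0 - pf) ** npori * (1.0 - pstep) ** nforks
        if q <= 1e-300:
            t += 4096.0
            continue
        if q < 0.01:
            # skip geometrically to the next MCS with a successful trial;
            # at such small q two successes in one MCS are O(q^2) and the
            # single trial is typed by its share of the total rate
            u = np.random.random()
            gap = int(np.log(u) / np.log(1.0 - q)) + 1
            if gap > 4096:
                t += 4096.0
                continue
            t += gap
            rate_f = npori * pf
            rate_s = nforks * pstep
            if np.random.random() < rate_f / (rate_f + rate_s):
                k_fire = 1
                k_step = 0
            else:
                k_fire = 0
                k_step = 1
        else:
            # event-dense regime: plain per-MCS binomial trials
            t += 1.0
            k_fire = np.random.binomial(npori, pf) if npori > 0 and pf > 0.0 else 0
            k_step = np.random.binomial(nforks, pstep) if nforks > 0 else 0
        for _ in range(k_fire):
            if npori <= 0:
                break
            idx = np.random.randint(0, npori)
            b = pori_list[idx]
            if rep_time[b] >= 0.0:
                npori -= 1
                pori_list[idx] = pori_list[npori]
                continue
            if junction_of_bin[b] >= 0:
                continue
            c = bin_chain[b]
            if b - 1 <= chain_first[c] or b + 1 >= chain_last[c]:
                continue
            if junction_of_bin[b - 1] >= 0 or junction_of_bin[b + 1] >= 0:
                continue
            nf_now = nf_total * (1.0 - ramp_amp * np.exp(-t / ramp_tau))
            if nf_now - nforks * 0.5 < 1.0:
                continue
            # fire
            rep_time[b] = t
            nrep += 1
            for dd in (-1, 1):
                fi = nreg
                nreg += 1
                f_bin[fi] = b + dd
                f_dir[fi] = dd
                f_alive[fi] = 1
                falive[nforks] = fi
                fpos[fi] = nforks
                nforks += 1
                junction_of_bin[b + dd] = fi
            npori -= 1
            pori_list[idx] = pori_list[npori]
            if nev < ev.shape[0]:
                ev[nev, 0] = t
                ev[nev, 1] = EV_FIRE
                ev[nev, 2] = b
                nev += 1
            if nlog < fork_log_t.shape[0]:
                fork_log_t[nlog] = t
                fork_log_n[nlog] = nforks
                nlog += 1
        for _ in range(k_step):
            if nforks <= 0:
                break
            li = np.random.randint(0, nforks)
            fi = falive[li]
            j = f_bin[fi]
            d = f_dir[fi]
            jn = j + d
            c = bin_chain[j]
            rep_time[j] = t
            nrep += 1
            fj = junction_of_bin[jn]
            kill2 = -1
            if fj >= 0:
                rep_time[jn] = t
                nrep += 1
                kill2 = fj
                if nev < ev.shape[0]:
                    ev[nev, 0] = t
                    ev[nev, 1] = EV_MERGE
                    ev[nev, 2] = j
                    nev += 1
            elif jn == chain_first[c] or jn == chain_last[c]:
                rep_time[jn] = t
                nrep += 1
                if nev < ev.shape[0]:
                    ev[nev, 0] = t
                    ev[nev, 1] = EV_OPEN
                    ev[nev, 2] = j
                    nev += 1
            else:
                junction_of_bin[j] = -1
                f_bin[fi] = jn
                junction_of_bin[jn] = fi
                continue
            # fork deaths (merge or bubble opening)
            junction_of_bin[j] = -1
            f_alive[fi] = 0
            li2 = fpos[fi]
            nforks -= 1
            moved = falive[nforks]
            falive[li2] = moved
            fpos[moved] = li2
            if kill2 >= 0:
                junction_of_bin[f_bin[kill2]] = -1
                f_alive[kill2] = 0
                li3 = fpos[kill2]
                nforks -= 1
                moved = falive[nforks]
                falive[li3] = moved
                fpos[moved] = li3
            if nlog < fork_log_t.shape[0]:
                fork_log_t[nlog] = t
                fork_log_n[nlog] = nforks
                nlog += 1
    return t, nrep, nev, nlog


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------

@njit(cache=True)
def grow_chain(path, length0, target, occ, blocked, smod, periodic, seed):
    """Grow a chain in place by random bond subdivision.

    ``path[:length0]`` holds an existing self-avoiding backbone (occupancy
    already set).  New monomers are inserted at a free site adjacent to both
    ends of a randomly chosen bond until ``target`` monomers exist.  Returns
    the final length (== target on success; caller retries otherwise).
    """
    np.random.seed(seed)
    ln = length0
    max_tries = 200 * target + 2000
    tries = 0
    while ln < target and tries < max_tries:
        tries += 1
        i = np.random.randint(0, ln - 1)
        ax, ay, az = path[i, 0], path[i, 1], path[i, 2]
        bx, by, bz = path[i + 1, 0], path[i + 1, 1], path[i + 1, 2]
        v = NNV[np.random.randint(0, 12)]
        x = ax + v[0]
        y = ay + v[1]
        z = az + v[2]
        dx = x - bx
        dy = y - by
        dz = z - bz
        if dx * dx + dy * dy + dz * dz != 2:
            continue
        xi = _widx(x, smod, periodic)
        yi = _widx(y, smod, periodic)
        zi = _widx(z, smod, periodic)
        if periodic == 0:
            if xi < 0 or yi < 0 or zi < 0 or xi >= smod or yi >= smod or zi >= smod:
                continue
        if blocked[xi, yi, zi] == 1 or occ[xi, yi, zi] > 0:
            continue
        # shift tail up by one and insert
        for k in range(ln, i + 1, -1):
            path[k, 0] = path[k - 1, 0]
            path[k, 1] = path[k - 1, 1]
            path[k, 2] = path[k - 1, 2]
        path[i + 1, 0] = x
        path[i + 1, 1] = y
        path[i + 1, 2] = z
        occ[xi, yi, zi] += 1
        ln += 1
    return ln
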