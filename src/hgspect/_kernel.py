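"""Numba transport kernels.

The scene is handed to the kernels as a flat float64 parameter array
(``geo``, indices below) plus resampled linear-attenuation tables on a
log-energy grid.  Photon histories are tracked analytically through the
layered head geometry; the hexagonal collimator is traversed by exact
hole/septum chord segmentation rather than by stepping.

Everything here is an implementation detail; the public surface lives
in :mod:`hgspect.engine`.
"""

import math

import numpy as np
from numba import njit

# geo[] layout -------------------------------------------------------------
G_KIND = 0          # 0 planar, 1 tomographic
G_COL_LEN = 1
G_PITCH = 2
G_F2F = 3
G_FHX = 4
G_FHY = 5
G_ZCOV = 6          # cumulative layer ends (mm from collimator entrance)
G_ZCRY = 7
G_ZCOUP = 8
G_ZBSC = 9
G_ZBACK = 10
G_SIDE_T = 11
G_MASK = 12
G_P0 = 13           # bar periods, quadrants (x<0,y>=0),(x>=0,y>=0),(x<0,y<0),(x>=0,y<0)
G_MHX = 17
G_MHY = 18
G_SHX = 19          # planar source box
G_SHY = 20
G_SZLO = 21
G_SZHI = 22
G_HDIST = 23
G_SLHX = 24         # phantom slab half-widths (phantom frame)
G_SLHY = 25
G_SLHZ = 26
G_TZLO = 27         # table slab (phantom frame)
G_TZHI = 28
G_THX = 29
G_THY = 30
G_CROT = 31         # lab->phantom rotation about x
G_SROT = 32
G_NCYL = 33
G_CONE_CMIN = 34    # emission cone: cos(theta) sampled in [cmin, 1]
G_DOUBLE = 35       # 1 -> double cone (both +z and -z)
G_CUTOFF = 36
G_PB_EDGE = 37
G_PB_YIELD = 38
G_CYL0 = 40         # per cylinder: y, z, r, half_len, cumulative activity
CYL_STRIDE = 5

# material ids
M_AIR = 0
M_LEAD = 1
M_NAI = 2
M_WATER = 3
M_PMMA = 4
M_ALUM = 5
M_BSC = 6

# region ids
R_AIR = 0
R_SOURCE = 1
R_SLAB = 2
R_TABLE = 3
R_COLL = 4
R_COVER = 5
R_CRYSTAL = 6
R_COUPL = 7
R_BSC = 8
R_BACK = 9
R_SIDE = 10

# origin classes
O_DIRECT = 0
O_PHANTOM = 1
O_UPSTREAM = 2
O_DOWNSTREAM = 3

# tally slots
T_EMITTED = 0
T_MASKED = 1
T_ABSORBED = 2
T_ESCAPED = 3
T_CUTOFF = 4

SQRT3 = math.sqrt(3.0)
COS30 = SQRT3 / 2.0
M_E_C2 = 511.0
EPS = 1e-6
WORLD = 700.0


@njit(cache=True, inline="always")
def _mu(mat, E, mu_pe, mu_inc, lne0, dln):
    ng = mu_pe.shape[1]
    f = (math.log(E) - lne0) / dln
    if f < 0.0:
        f = 0.0
    if f > ng - 1.001:
        f = ng - 1.001
    i = int(f)
    w = f - i
    pe = mu_pe[mat, i] * (1.0 - w) + mu_pe[mat, i + 1] * w
    inc = mu_inc[mat, i] * (1.0 - w) + mu_inc[mat, i + 1] * w
    return pe, inc


@njit(cache=True, inline="always")
def _in_hex(x, y, f2f):
    h = 0.5 * f2f
    if abs(y) > h:
        return False
    if abs(SQRT3 * x + y) > 2.0 * h:
        return False
    if abs(SQRT3 * x - y) > 2.0 * h:
        return False
    return True


@njit(cache=True, inline="always")
def _hex_interval(px, py, dx, dy, h):
    """Clip 2-D ray (p + t d) against hexagon |n.p| <= h, three normals.
    Returns (t_lo, t_hi); miss when t_lo >= t_hi."""
    t_lo = -1e30
    t_hi = 1e30
    for k in range(3):
        if k == 0:
            nx = 0.0
            ny = 1.0
        elif k == 1:
            nx = COS30
            ny = 0.5
        else:
            nx = -COS30
            ny = 0.5
        num = nx * px + ny * py
        den = nx * dx + ny * dy
        if abs(den) < 1e-15:
            if abs(num) > h:
                return 1.0, 0.0
        else:
            ta = (-h - num) / den
            tb = (h - num) / den
            if ta > tb:
                tmp = ta
                ta = tb
                tb = tmp
            if ta > t_lo:
                t_lo = ta
            if tb < t_hi:
                t_hi = tb
            if t_lo >= t_hi:
                return 1.0, 0.0
    return t_lo, t_hi


@njit(cache=True)
def _collimator_transport(lx, ly, lz, dx, dy, dz, mu_pb, geo):
    """Advance a photon through the collimator slab in head-local
    coordinates.  Returns (code, t_end, septa) with code 0 when the
    photon reaches the slab boundary without interacting and 1 when an
    interaction occurs in lead at parameter t_end along the (unit)
    direction.  ``mu_pb`` is the lead linear attenuation at the current
    energy (1/mm)."""
    L = geo[G_COL_LEN]
    pitch = geo[G_PITCH]
    f2f = geo[G_F2F]
    h = 0.5 * f2f
    fhx = geo[G_FHX]
    fhy = geo[G_FHY]
    big = 1e30

    # slab exit in z
    if dz > 1e-12:
        T = (L - lz) / dz
    elif dz < -1e-12:
        T = lz / (-dz)
    else:
        T = big
    # lateral exit into the side shield
    if dx > 1e-12:
        t = (fhx - lx) / dx
        if t < T:
            T = t
    elif dx < -1e-12:
        t = (-fhx - lx) / dx
        if t < T:
            T = t
    if dy > 1e-12:
        t = (fhy - ly) / dy
        if t < T:
            T = t
    elif dy < -1e-12:
        t = (-fhy - ly) / dy
        if t < T:
            T = t
    if T < 0.0:
        T = 0.0

    tau_target = -math.log(np.random.random())
    tau = 0.0
    septa = 0
    t = 0.0
    ax = pitch * COS30   # lattice: a1 = (ax, pitch/2), a2 = (0, pitch)
    while t < T - 1e-9:
        x = lx + dx * (t + 1e-7)
        y = ly + dy * (t + 1e-7)
        # nearest-hole search (3x3 in lattice coords)
        fi = x / ax
        fj = y / pitch - 0.5 * fi
        i0 = int(round(fi))
        j0 = int(round(fj))
        in_hole = False
        hx = 0.0
        hy = 0.0
        for di in range(-1, 2):
            for dj in range(-1, 2):
                cx = ax * (i0 + di)
                cy = pitch * (0.5 * (i0 + di) + (j0 + dj))
                if _in_hex(x - cx, y - cy, f2f):
                    in_hole = True
                    hx = cx
                    hy = cy
                    break
            if in_hole:
                break
        if in_hole:
            # air segment to hex exit
            t0, t1 = _hex_interval(lx - hx, ly - hy, dx, dy, h)
            t_next = t1
            if t_next > T:
                t_next = T
            if t_next <= t + 1e-9:
                t_next = t + 1e-9
            t = t_next
        else:
            # in lead: find next hole entry among nearby candidates
            t_entry = big
            for s in range(2):
                if s == 0:
                    qx = x
                    qy = y
                else:
                    # look ahead half a pitch (2-D)
                    d2 = math.hypot(dx, dy)
                    if d2 < 1e-12:
                        break
                    adv = 0.5 * pitch / d2
                    qx = x + dx * adv
                    qy = y + dy * adv
                fi = qx / ax
                fj = qy / pitch - 0.5 * fi
                i0 = int(round(fi))
                j0 = int(round(fj))
                for di in range(-1, 2):
                    for dj in range(-1, 2):
                        cx = ax * (i0 + di)
                        cy = pitch * (0.5 * (i0 + di) + (j0 + dj))
                        t0, t1 = _hex_interval(lx - cx, ly - cy, dx, dy, h)
                        if t0 < t1 and t1 > t + 1e-9 and t0 > t - 1e-9:
                            if t0 < t_entry:
                                t_entry = t0
            if t_entry < t + 1e-9:
                t_entry = t + 1e-9
            seg_end = t_entry
            if seg_end > T:
                seg_end = T
            d2 = math.hypot(dx, dy)
            if t_entry >= big * 0.5 and d2 > 1e-12:
                # no hole found nearby: advance half a pitch and rescan
                adv = t + 0.5 * pitch / d2
                if adv < seg_end:
                    seg_end = adv
                    seg_len = seg_end - t
                    dtau = mu_pb * seg_len
                    if tau + dtau >= tau_target:
                        t_int = t + (tau_target - tau) / mu_pb
                        return 1, t_int, septa + 1
                    tau += dtau
                    t = seg_end
                    continue
            seg_len = seg_end - t
            if seg_len > 1e-9:
                septa += 1
                dtau = mu_pb * seg_len
                if tau + dtau >= tau_target:
                    t_int = t + (tau_target - tau) / mu_pb
                    return 1, t_int, septa
                tau += dtau
            t = seg_end + 1e-9
    return 0, T, septa


@njit(cache=True, inline="always")
def _slab_exit(p, d, lo, hi, t_exit):
    """Distance to leaving the slab lo <= p <= hi along d (1-D)."""
    if d > 1e-12:
        t = (hi - p) / d
    elif d < -1e-12:
        t = (lo - p) / d
    else:
        t = 1e30
    if t < t_exit:
        return t
    return t_exit


@njit(cache=True, inline="always")
def _box_entry(px, py, pz, dx, dy, dz, hx, hy, hz, cx, cy, cz):
    """Entry parameter into an axis-aligned box (centre c, half-widths
    h); 1e30 when missed or behind."""
    t_lo = -1e30
    t_hi = 1e30
    for k in range(3):
        if k == 0:
            p = px - cx
            d = dx
            hh = hx
        elif k == 1:
            p = py - cy
            d = dy
            hh = hy
        else:
            p = pz - cz
            d = dz
            hh = hz
        if abs(d) < 1e-12:
            if abs(p) > hh:
                return 1e30
        else:
            ta = (-hh - p) / d
            tb = (hh - p) / d
            if ta > tb:
                tmp = ta
                ta = tb
                tb = tmp
            if ta > t_lo:
                t_lo = ta
            if tb < t_hi:
                t_hi = tb
    if t_lo >= t_hi or t_hi < 0.0:
        return 1e30
    if t_lo < 0.0:
        return 0.0
    return t_lo


@njit(cache=True, inline="always")
def _cyl_entry(px, py, pz, dx, dy, dz, cy, cz, r, hl):
    """Entry parameter into an x-axis cylinder (phantom frame)."""
    # radial quadratic in (y, z)
    oy = py - cy
    oz = pz - cz
    a = dy * dy + dz * dz
    t_lo = -1e30
    t_hi = 1e30
    if a < 1e-15:
        if oy * oy + oz * oz > r * r:
            return 1e30
    else:
        b = oy * dy + oz * dz
        c = oy * oy + oz * oz - r * r
        disc = b * b - a * c
        if disc <= 0.0:
            return 1e30
        sq = math.sqrt(disc)
        t_lo = (-b - sq) / a
        t_hi = (-b + sq) / a
    # axial slab
    if abs(dx) < 1e-12:
        if abs(px) > hl:
            return 1e30
    else:
        ta = (-hl - px) / dx
        tb = (hl - px) / dx
        if ta > tb:
            tmp = ta
            ta = tb
            tb = tmp
        if ta > t_lo:
            t_lo = ta
        if tb < t_hi:
            t_hi = tb
    if t_lo >= t_hi or t_hi < 0.0:
        return 1e30
    if t_lo < 0.0:
        return 0.0
    return t_lo


@njit(cache=True, inline="always")
def _cyl_exit(px, py, pz, dx, dy, dz, cy, cz, r, hl):
    """Exit parameter from inside an x-axis cylinder."""
    oy = py - cy
    oz = pz - cz
    a = dy * dy + dz * dz
    t_hi = 1e30
    if a > 1e-15:
        b = oy * dy + oz * dz
        c = oy * oy + oz * oz - r * r
        disc = b * b - a * c
        if disc > 0.0:
            t_hi = (-b + math.sqrt(disc)) / a
    t_hi = _slab_exit(px, dx, -hl, hl, t_hi)
    return t_hi


@njit(cache=True, inline="always")
def _head_local(x, y, z, geo, head):
    """Map a lab point into head-local coordinates for head 0/1."""
    if geo[G_KIND] < 0.5:
        return x, y, z
    hd = geo[G_HDIST]
    if head == 0:
        return x, y, z - hd
    return x, -y, -z - hd


@njit(cache=True, inline="always")
def _head_local_dir(dx, dy, dz, geo, head):
    if geo[G_KIND] < 0.5 or head == 0:
        return dx, dy, dz
    return dx, -dy, -dz


@njit(cache=True, inline="always")
def _locate(x, y, z, geo):
    """Region id, material id and head index at a lab point."""
    kind = geo[G_KIND]
    if kind < 0.5:
        # planar: source box below the collimator face
        if (geo[G_SZLO] <= z < geo[G_SZHI] and abs(x) <= geo[G_SHX]
                and abs(y) <= geo[G_SHY]):
            return R_SOURCE, M_WATER, 0
        heads = 1
    else:
        # phantom frame
        c = geo[G_CROT]
        s = geo[G_SROT]
        py = c * y - s * z
        pz = s * y + c * z
        ncyl = int(geo[G_NCYL])
        for k in range(ncyl):
            base = G_CYL0 + CYL_STRIDE * k
            cy = geo[base]
            cz = geo[base + 1]
            r = geo[base + 2]
            hl = geo[base + 3]
            if (abs(x) <= hl
                    and (py - cy) ** 2 + (pz - cz) ** 2 <= r * r):
                return R_SOURCE, M_WATER, k
        if (abs(x) <= geo[G_SLHX] and abs(py) <= geo[G_SLHY]
                and abs(pz) <= geo[G_SLHZ]):
            return R_SLAB, M_PMMA, 0
        if (geo[G_TZLO] <= pz <= geo[G_TZHI] and abs(x) <= geo[G_THX]
                and abs(py) <= geo[G_THY]):
            return R_TABLE, M_PMMA, 0
        heads = 2
    side = geo[G_SIDE_T]
    for head in range(heads):
        lx, ly, lz = _head_local(x, y, z, geo, head)
        if lz < 0.0 or lz > geo[G_ZBACK]:
            continue
        if abs(lx) > geo[G_FHX] + side or abs(ly) > geo[G_FHY] + side:
            continue
        if abs(lx) > geo[G_FHX] or abs(ly) > geo[G_FHY]:
            return R_SIDE, M_LEAD, head
        if lz < geo[G_COL_LEN]:
            return R_COLL, M_LEAD, head
        if lz < geo[G_ZCOV]:
            return R_COVER, M_ALUM, head
        if lz < geo[G_ZCRY]:
            return R_CRYSTAL, M_NAI, head
        if lz < geo[G_ZCOUP]:
            return R_COUPL, M_PMMA, head
        if lz < geo[G_ZBSC]:
            return R_BSC, M_BSC, head
        return R_BACK, M_LEAD, head
    return R_AIR, M_AIR, 0


@njit(cache=True, inline="always")
def _region_exit(region, head, x, y, z, dx, dy, dz, geo):
    """Distance to leaving the current homogeneous region."""
    t = 1e30
    if region == R_SOURCE and geo[G_KIND] < 0.5:
        t = _slab_exit(x, dx, -geo[G_SHX], geo[G_SHX], t)
        t = _slab_exit(y, dy, -geo[G_SHY], geo[G_SHY], t)
        t = _slab_exit(z, dz, geo[G_SZLO], geo[G_SZHI], t)
        return t
    if region == R_SOURCE or region == R_SLAB or region == R_TABLE:
        c = geo[G_CROT]
        s = geo[G_SROT]
        py = c * y - s * z
        pz = s * y + c * z
        qy = c * dy - s * dz
        qz = s * dy + c * dz
        if region == R_SOURCE:
            base = G_CYL0 + CYL_STRIDE * head
            return _cyl_exit(x, py, pz, dx, qy, qz, geo[base],
                             geo[base + 1], geo[base + 2], geo[base + 3])
        if region == R_SLAB:
            t = _slab_exit(x, dx, -geo[G_SLHX], geo[G_SLHX], t)
            t = _slab_exit(py, qy, -geo[G_SLHY], geo[G_SLHY], t)
            t = _slab_exit(pz, qz, -geo[G_SLHZ], geo[G_SLHZ], t)
            ncyl = int(geo[G_NCYL])
            for k in range(ncyl):
                base = G_CYL0 + CYL_STRIDE * k
                te = _cyl_entry(x, py, pz, dx, qy, qz, geo[base],
                                geo[base + 1], geo[base + 2], geo[base + 3])
                if te < t:
                    t = te
            return t
        t = _slab_exit(x, dx, -geo[G_THX], geo[G_THX], t)
        t = _slab_exit(py, qy, -geo[G_THY], geo[G_THY], t)
        t = _slab_exit(pz, qz, geo[G_TZLO], geo[G_TZHI], t)
        return t
    # head layers, in local coordinates
    lx, ly, lz = _head_local(x, y, z, geo, head)
    ldx, ldy, ldz = _head_local_dir(dx, dy, dz, geo, head)
    side = geo[G_SIDE_T]
    if region == R_SIDE:
        t = _slab_exit(lz, ldz, 0.0, geo[G_ZBACK], t)
        t = _slab_exit(lx, ldx, -geo[G_FHX] - side, geo[G_FHX] + side, t)
        t = _slab_exit(ly, ldy, -geo[G_FHY] - side, geo[G_FHY] + side, t)
        te = _box_entry(lx, ly, lz, ldx, ldy, ldz, geo[G_FHX], geo[G_FHY],
                        0.5 * geo[G_ZBACK], 0.0, 0.0, 0.5 * geo[G_ZBACK])
        if te < t:
            t = te
        return t
    if region == R_COVER:
        z0 = geo[G_COL_LEN]
        z1 = geo[G_ZCOV]
    elif region == R_CRYSTAL:
        z0 = geo[G_ZCOV]
        z1 = geo[G_ZCRY]
    elif region == R_COUPL:
        z0 = geo[G_ZCRY]
        z1 = geo[G_ZCOUP]
    elif region == R_BSC:
        z0 = geo[G_ZCOUP]
        z1 = geo[G_ZBSC]
    else:
        z0 = geo[G_ZBSC]
        z1 = geo[G_ZBACK]
    t = _slab_exit(lz, ldz, z0, z1, t)
    t = _slab_exit(lx, ldx, -geo[G_FHX], geo[G_FHX], t)
    t = _slab_exit(ly, ldy, -geo[G_FHY], geo[G_FHY], t)
    return t


@njit(cache=True, inline="always")
def _air_advance(x, y, z, dx, dy, dz, geo):
    """Distance from an air point to the next object, 1e30 = escape."""
    t = 1e30
    side = geo[G_SIDE_T]
    kind = geo[G_KIND]
    dzb = 0.5 * geo[G_ZBACK]
    if kind < 0.5:
        te = _box_entry(x, y, z, dx, dy, dz, geo[G_SHX], geo[G_SHY],
                        0.5 * (geo[G_SZHI] - geo[G_SZLO]), 0.0, 0.0,
                        0.5 * (geo[G_SZHI] + geo[G_SZLO]))
        if te < t:
            t = te
        te = _box_entry(x, y, z, dx, dy, dz, geo[G_FHX] + side,
                        geo[G_FHY] + side, dzb, 0.0, 0.0, dzb)
        if te < t:
            t = te
        return t
    c = geo[G_CROT]
    s = geo[G_SROT]
    py = c * y - s * z
    pz = s * y + c * z
    qy = c * dy - s * dz
    qz = s * dy + c * dz
    te = _box_entry(x, py, pz, dx, qy, qz, geo[G_SLHX], geo[G_SLHY],
                    geo[G_SLHZ], 0.0, 0.0, 0.0)
    if te < t:
        t = te
    te = _box_entry(x, py, pz, dx, qy, qz, geo[G_THX], geo[G_THY],
                    0.5 * (geo[G_TZHI] - geo[G_TZLO]), 0.0, 0.0,
                    0.5 * (geo[G_TZHI] + geo[G_TZLO]))
    if te < t:
        t = te
    hd = geo[G_HDIST]
    te = _box_entry(x, y, z, dx, dy, dz, geo[G_FHX] + side,
                    geo[G_FHY] + side, dzb, 0.0, 0.0, hd + dzb)
    if te < t:
        t = te
    te = _box_entry(x, y, z, dx, dy, dz, geo[G_FHX] + side,
                    geo[G_FHY] + side, dzb, 0.0, 0.0, -hd - dzb)
    if te < t:
        t = te
    return t


@njit(cache=True, inline="always")
def _mask_blocks(x, y, geo):
    if abs(x) > geo[G_MHX] or abs(y) > geo[G_MHY]:
        return False
    if y >= 0.0:
        p = geo[G_P0] if x < 0.0 else geo[G_P0 + 1]
    else:
        p = geo[G_P0 + 2] if x < 0.0 else geo[G_P0 + 3]
    frac = (abs(x) % p) / p
    return frac >= 0.5


@njit(cache=True, inline="always")
def _kn_sample(E):
    """Klein-Nishina polar angle via rejection on uniform cos(theta)."""
    k = E / M_E_C2
    fmax = 1.0  # value at theta=0: 0.5*(1+1-0)=1
    while True:
        c = 2.0 * np.random.random() - 1.0
        r = 1.0 / (1.0 + k * (1.0 - c))
        val = 0.5 * r * r * (r + 1.0 / r - (1.0 - c * c))
        if np.random.random() * fmax <= val:
            return c


@njit(cache=True, inline="always")
def _rotate_dir(dx, dy, dz, cth, phi):
    sth = math.sqrt(max(0.0, 1.0 - cth * cth))
    # orthonormal frame around d
    if abs(dz) < 0.999:
        ux = dy
        uy = -dx
        uz = 0.0
    else:
        ux = 0.0
        uy = dz
        uz = -dy
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= un
    uy /= un
    uz /= un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    cp = math.cos(phi)
    sp = math.sin(phi)
    nx = cth * dx + sth * (cp * ux + sp * vx)
    ny = cth * dy + sth * (cp * uy + sp * vy)
    nz = cth * dz + sth * (cp * uz + sp * vz)
    n = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / n, ny / n, nz / n


@njit(cache=True)
def run_histories(n, seed, E0, geo, mu_pe, mu_inc, lne0, dln,
                  fl_e, fl_cum,
                  ev_x, ev_y, ev_e, ev_w, ev_origin, ev_septa, ev_head,
                  tallies):
    """Trace ``n`` photon histories of initial energy ``E0``.

    Returns (n_done, n_events).  Detected events fill the ``ev_*``
    arrays (head-local centroid position, pooled crystal deposit,
    statistical weight, scatter-origin class, septa crossed before the
    first crystal deposit, head index).  ``tallies`` accumulates
    emitted/masked/absorbed/escaped/cutoff weight.
    """
    np.random.seed(seed)
    cap = ev_x.shape[0]
    nev = 0
    kind = geo[G_KIND]
    cmin = geo[G_CONE_CMIN]
    double = geo[G_DOUBLE] > 0.5
    if double:
        w0 = 1.0 - cmin
    else:
        w0 = 0.5 * (1.0 - cmin)
    cutoff = geo[G_CUTOFF]
    mask_on = geo[G_MASK] > 0.5 and kind < 0.5

    for ih in range(n):
        if nev >= cap:
            return ih, nev
        # --- emission point (lab frame)
        if kind < 0.5:
            x = (2.0 * np.random.random() - 1.0) * geo[G_SHX]
            y = (2.0 * np.random.random() - 1.0) * geo[G_SHY]
            z = geo[G_SZLO] + np.random.random() * (geo[G_SZHI] - geo[G_SZLO])
        else:
            u = np.random.random()
            ncyl = int(geo[G_NCYL])
            k = ncyl - 1
            for kk in range(ncyl):
                if u <= geo[G_CYL0 + CYL_STRIDE * kk + 4]:
                    k = kk
                    break
            base = G_CYL0 + CYL_STRIDE * k
            r = geo[base + 2]
            while True:
                a = 2.0 * np.random.random() - 1.0
                b = 2.0 * np.random.random() - 1.0
                if a * a + b * b <= 1.0:
                    break
            px = (2.0 * np.random.random() - 1.0) * geo[base + 3]
            py = geo[base] + a * r
            pz = geo[base + 1] + b * r
            c = geo[G_CROT]
            s = geo[G_SROT]
            x = px
            y = c * py + s * pz
            z = -s * py + c * pz
        # --- emission direction (cone importance sampling about +-z)
        cth = cmin + np.random.random() * (1.0 - cmin)
        if double and np.random.random() < 0.5:
            cth = -cth
        phi = 2.0 * math.pi * np.random.random()
        sth = math.sqrt(max(0.0, 1.0 - cth * cth))
        dx = sth * math.cos(phi)
        dy = sth * math.sin(phi)
        dz = cth
        w = w0
        tallies[T_EMITTED] += w

        E = E0
        septa = 0
        last_class = O_DIRECT
        origin = -1
        septa_frozen = -1
        head_id = -1
        edep = 0.0
        exs = 0.0
        eys = 0.0
        fate = -1   # T_ slot of the terminal fate

        for _step in range(400):
            region, mat, head = _locate(x, y, z, geo)
            if region == R_COLL:
                lx, ly, lz = _head_local(x, y, z, geo, head)
                ldx, ldy, ldz = _head_local_dir(dx, dy, dz, geo, head)
                pe_pb, inc_pb = _mu(M_LEAD, E, mu_pe, mu_inc, lne0, dln)
                code, t_end, dsepta = _collimator_transport(
                    lx, ly, lz, ldx, ldy, ldz, pe_pb + inc_pb, geo)
                septa += dsepta
                x += dx * (t_end + EPS)
                y += dy * (t_end + EPS)
                z += dz * (t_end + EPS)
                if code == 0:
                    continue
                mu_tot = pe_pb + inc_pb
                mu_pe_here = pe_pb
            else:
                pe_m, inc_m = _mu(mat, E, mu_pe, mu_inc, lne0, dln)
                mu_tot = pe_m + inc_m
                mu_pe_here = pe_m
                if region == R_AIR:
                    d_next = _air_advance(x, y, z, dx, dy, dz, geo)
                else:
                    d_next = _region_exit(region, head, x, y, z,
                                          dx, dy, dz, geo)
                if mu_tot > 1e-12:
                    s_free = -math.log(np.random.random()) / mu_tot
                else:
                    s_free = 1e30
                step = s_free if s_free < d_next else d_next + EPS
                # bar-mask check on any crossing of the z=0 plane
                if mask_on and abs(dz) > 1e-15:
                    tc = -z / dz
                    if 0.0 < tc <= step:
                        mx = x + dx * tc
                        my = y + dy * tc
                        if _mask_blocks(mx, my, geo):
                            tallies[T_MASKED] += w
                            fate = T_MASKED
                            break
                x += dx * step
                y += dy * step
                z += dz * step
                if abs(x) > WORLD or abs(y) > WORLD or abs(z) > WORLD:
                    tallies[T_ESCAPED] += w
                    fate = T_ESCAPED
                    break
                if s_free >= d_next:
                    continue

            # --- interaction at current position
            if np.random.random() * mu_tot < mu_pe_here:
                # photoelectric (with lead K fluorescence)
                if mat == M_LEAD and E > geo[G_PB_EDGE] and \
                        np.random.random() < geo[G_PB_YIELD]:
                    u = np.random.random()
                    kl = 0
                    for kk in range(fl_e.shape[0]):
                        if u <= fl_cum[kk]:
                            kl = kk
                            break
                    e_line = fl_e[kl]
                    E = e_line
                    cth = 2.0 * np.random.random() - 1.0
                    phi = 2.0 * math.pi * np.random.random()
                    sth = math.sqrt(max(0.0, 1.0 - cth * cth))
                    dx = sth * math.cos(phi)
                    dy = sth * math.sin(phi)
                    dz = cth
                    if region == R_COLL or region == R_COVER:
                        last_class = O_UPSTREAM
                    elif region == R_SIDE or region == R_BACK:
                        last_class = O_DOWNSTREAM
                    if E < cutoff:
                        tallies[T_CUTOFF] += w
                        fate = T_CUTOFF
                        break
                    continue
                if region == R_CRYSTAL:
                    lx, ly, lz = _head_local(x, y, z, geo, head)
                    edep += E
                    exs += E * lx
                    eys += E * ly
                    if origin < 0:
                        origin = last_class
                        septa_frozen = septa
                        head_id = head
                tallies[T_ABSORBED] += w
                fate = T_ABSORBED
                break
            # Compton
            cth = _kn_sample(E)
            e_new = E / (1.0 + (E / M_E_C2) * (1.0 - cth))
            deposit = E - e_new
            if region == R_CRYSTAL:
                lx, ly, lz = _head_local(x, y, z, geo, head)
                edep += deposit
                exs += deposit * lx
                eys += deposit * ly
                if origin < 0:
                    origin = last_class
                    septa_frozen = septa
                    head_id = head
            else:
                if region == R_SOURCE or region == R_SLAB or region == R_TABLE:
                    last_class = O_PHANTOM
                elif region == R_COLL or region == R_COVER:
                    last_class = O_UPSTREAM
                elif region != R_AIR:
                    last_class = O_DOWNSTREAM
            phi = 2.0 * math.pi * np.random.random()
            dx, dy, dz = _rotate_dir(dx, dy, dz, cth, phi)
            E = e_new
            if E < cutoff:
                tallies[T_CUTOFF] += w
                fate = T_CUTOFF
                break

        if fate < 0:
            # step budget exhausted (pathological history)
            tallies[T_ESCAPED] += w
        if edep > 0.0:
            ev_x[nev] = exs / edep
            ev_y[nev] = eys / edep
            ev_e[nev] = edep
            ev_w[nev] = w
            ev_origin[nev] = origin
            ev_septa[nev] = septa_frozen
            ev_head[nev] = head_id
            nev += 1
    return n, nev


@njit(cache=True)
def septal_survey(n, seed, E, geo, mu_pe, mu_inc, lne0, dln, hist):
    """Deterministic ray-trace tally of septal penetration.

    Photons start uniformly in the planar source box with isotropic
    upward directions, cross the bar mask (if enabled), are traced
    straight through the collimator, and contribute their survival
    weight  exp(-mu_Pb * lead path) * exp(-mu_Al * cover) *
    P(interaction in crystal)  to the histogram bin of the number of
    septa crossed.  Returns the summed tallied weight.
    """
    np.random.seed(seed)
    pe_pb, inc_pb = _mu(M_LEAD, E, mu_pe, mu_inc, lne0, dln)
    mu_pb = pe_pb + inc_pb
    pe_al, inc_al = _mu(M_ALUM, E, mu_pe, mu_inc, lne0, dln)
    mu_al = pe_al + inc_al
    pe_na, inc_na = _mu(M_NAI, E, mu_pe, mu_inc, lne0, dln)
    mu_na = pe_na + inc_na
    t_cov = geo[G_ZCOV] - geo[G_COL_LEN]
    t_cry = geo[G_ZCRY] - geo[G_ZCOV]
    mask_on = geo[G_MASK] > 0.5
    nbins = hist.shape[0]
    total = 0.0
    for ih in range(n):
        x = (2.0 * np.random.random() - 1.0) * geo[G_SHX]
        y = (2.0 * np.random.random() - 1.0) * geo[G_SHY]
        z = geo[G_SZLO] + np.random.random() * (geo[G_SZHI] - geo[G_SZLO])
        cth = np.random.random()
        if cth < 1e-6:
            continue
        phi = 2.0 * math.pi * np.random.random()
        sth = math.sqrt(max(0.0, 1.0 - cth * cth))
        dx = sth * math.cos(phi)
        dy = sth * math.sin(phi)
        dz = cth
        # to the collimator face
        tc = -z / dz
        mx = x + dx * tc
        my = y + dy * tc
        if mask_on and _mask_blocks(mx, my, geo):
            continue
        if abs(mx) > geo[G_FHX] or abs(my) > geo[G_FHY]:
            continue
        # lead path through the collimator (no interaction sampling):
        # walk hole/septum segments accumulating lead length
        lead_len = 0.0
        septa = 0
        L = geo[G_COL_LEN]
        pitch = geo[G_PITCH]
        f2f = geo[G_F2F]
        h = 0.5 * f2f
        ax = pitch * COS30
        T = L / dz
        t = 0.0
        while t < T - 1e-9:
            qx = mx + dx * (t + 1e-7)
            qy = my + dy * (t + 1e-7)
            fi = qx / ax
            fj = qy / pitch - 0.5 * fi
            i0 = int(round(fi))
            j0 = int(round(fj))
            in_hole = False
            hx = 0.0
            hy = 0.0
            for di in range(-1, 2):
                for dj in range(-1, 2):
                    cx = ax * (i0 + di)
                    cy = pitch * (0.5 * (i0 + di) + (j0 + dj))
                    if _in_hex(qx - cx, qy - cy, f2f):
                        in_hole = True
                        hx = cx
                        hy = cy
                        break
                if in_hole:
                    break
            if in_hole:
                t0, t1 = _hex_interval(mx - hx, my - hy, dx, dy, h)
                tn = t1 if t1 < T else T
                if tn <= t + 1e-9:
                    tn = t + 1e-9
                t = tn
            else:
                t_entry = 1e30
                for sstep in range(2):
                    if sstep == 0:
                        wx = qx
                        wy = qy
                    else:
                        d2 = math.hypot(dx, dy)
                        if d2 < 1e-12:
                            break
                        adv = 0.5 * pitch / d2
                        wx = qx + dx * adv
                        wy = qy + dy * adv
                    fi = wx / ax
                    fj = wy / pitch - 0.5 * fi
                    i0 = int(round(fi))
                    j0 = int(round(fj))
                    for di in range(-1, 2):
                        for dj in range(-1, 2):
                            cx = ax * (i0 + di)
                            cy = pitch * (0.5 * (i0 + di) + (j0 + dj))
                            t0, t1 = _hex_interval(mx - cx, my - cy,
                                                   dx, dy, h)
                            if t0 < t1 and t1 > t + 1e-9 and t0 > t - 1e-9:
                                if t0 < t_entry:
                                    t_entry = t0
                if t_entry < t + 1e-9:
                    t_entry = t + 1e-9
                seg_end = t_entry if t_entry < T else T
                d2 = math.hypot(dx, dy)
                if t_entry >= 1e29 and d2 > 1e-12:
                    adv = t + 0.5 * pitch / d2
                    if adv < seg_end:
                        lead_len += adv - t
                        t = adv
                        continue
                if seg_end - t > 1e-9:
                    septa += 1
                    lead_len += seg_end - t
                t = seg_end + 1e-9
        wgt = math.exp(-mu_pb * lead_len) * math.exp(-mu_al * t_cov / cth) \
            * (1.0 - math.exp(-mu_na * t_cry / cth))
        b = septa if septa < nbins else nbins - 1
        hist[b] += wgt
        total += wgt
    return total
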