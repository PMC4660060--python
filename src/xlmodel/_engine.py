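"""Numba-accelerated scoring and Monte Carlo inner loop.

The engine packs an assembly, its restraints and (optionally) a rigid
tubulin lattice with ambiguous complex-to-tubulin restraints into flat
arrays, and runs segments of single-bead Metropolis moves (plus rigid-body
lattice moves during docking) inside one jitted kernel.  Random numbers come
from a ``numpy.random.Generator`` shared with the Python layer, so runs are
bit-for-bit reproducible given a seed.

Move energetics are evaluated locally: a bead displacement touches only the
terms involving the moved bead (and its symmetric image while the symmetry
constraint is active), so the cost per step is O(n_beads).  The full energy
is recomputed from scratch at every segment boundary, which keeps the
accumulated energy exact regardless of floating-point drift inside a
segment.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .representation import Assembly
from .restraints import RestraintSet

__all__ = ["ScoringEngine", "SegmentResult"]


# ---------------------------------------------------------------------------
# jitted primitives


@njit(cache=True, inline="always")
def _surf(coords, radii, i, j):
    dx = coords[i, 0] - coords[j, 0]
    dy = coords[i, 1] - coords[j, 1]
    dz = coords[i, 2] - coords[j, 2]
    return np.sqrt(dx * dx + dy * dy + dz * dz) - radii[i] - radii[j]


@njit(cache=True)
def _conn_local(coords, radii, chain, rigid_start, i, k):
    """Connectivity terms of the (at most two) bonds touching bead i."""
    if i >= rigid_start:
        return 0.0
    e = 0.0
    n = rigid_start
    if i > 0 and chain[i - 1] == chain[i]:
        s = _surf(coords, radii, i - 1, i)
        if s > 0.0:
            e += k * s * s
    if i + 1 < n and chain[i + 1] == chain[i]:
        s = _surf(coords, radii, i, i + 1)
        if s > 0.0:
            e += k * s * s
    return e


@njit(cache=True)
def _ev_bead(coords, radii, chain, cpos, rigid_start, i, skip, k):
    """Excluded-volume terms between bead i and all other beads.

    ``skip`` (or -1) is excluded so a two-bead moved set is not counted
    twice; the (i, skip) pair is added separately by the caller.
    Pairs fully inside the rigid lattice are never scored.
    """
    n = coords.shape[0]
    e = 0.0
    for j in range(n):
        if j == i or j == skip:
            continue
        if i >= rigid_start and j >= rigid_start:
            continue
        if chain[j] == chain[i]:
            d = cpos[i] - cpos[j]
            if d == 1 or d == -1:
                continue
        s = _surf(coords, radii, i, j)
        if s < 0.0:
            e += k * s * s
    return e


@njit(cache=True)
def _xl_energy(coords, radii, xa, xb, n_per_copy, n_copies, bound, k, rec):
    """Upper-bound harmonic on the minimum ambiguous copy assignment."""
    a = xa[rec]
    b = xb[rec]
    best = 1.0e30
    for ca in range(n_copies):
        ia = a + ca * n_per_copy
        for cb in range(n_copies):
            ib = b + cb * n_per_copy
            s = _surf(coords, radii, ia, ib)
            if s < best:
                best = s
    if best <= bound:
        return 0.0
    d = best - bound
    return k * d * d


@njit(cache=True)
def _txl_energy(
    coords, radii, txa, tx_off, tx_cand, n_per_copy, n_copies, bound, k, rec
):
    """Complex-to-lattice restraint: min over copies x candidate subunits."""
    a = txa[rec]
    best = 1.0e30
    for ca in range(n_copies):
        ia = a + ca * n_per_copy
        for p in range(tx_off[rec], tx_off[rec + 1]):
            ib = tx_cand[p]
            s = _surf(coords, radii, ia, ib)
            if s < best:
                best = s
    if best <= bound:
        return 0.0
    d = best - bound
    return k * d * d


@njit(cache=True)
def _box_energy(coords, blo, bhi, has_box, i, k):
    if not has_box[i]:
        return 0.0
    d2 = 0.0
    for ax in range(3):
        x = coords[i, ax]
        if x < blo[i, ax]:
            d = blo[i, ax] - x
            d2 += d * d
        elif x > bhi[i, ax]:
            d = x - bhi[i, ax]
            d2 += d * d
    return k * d2


@njit(cache=True)
def _group_energy(coords, radii, grp_off, grp_mstart, grp_mend, g, k):
    """Subcomplex connectivity of group instance g."""
    e = 0.0
    for m in range(grp_off[g], grp_off[g + 1]):
        gmin = 1.0e30
        for m2 in range(grp_off[g], grp_off[g + 1]):
            if m2 == m:
                continue
            for a in range(grp_mstart[m], grp_mend[m]):
                for b in range(grp_mstart[m2], grp_mend[m2]):
                    s = _surf(coords, radii, a, b)
                    if s < gmin:
                        gmin = s
        if gmin > 0.0 and gmin < 1.0e29:
            e += k * gmin * gmin
    return e


@njit(cache=True)
def _wte_bias(E, centers, heights, sigma):
    v = 0.0
    for i in range(centers.shape[0]):
        d = (E - centers[i]) / sigma
        v += heights[i] * np.exp(-0.5 * d * d)
    return v


@njit(cache=True)
def _full_energy(
    coords,
    radii,
    chain,
    cpos,
    rigid_start,
    n_per_copy,
    n_copies,
    has_box,
    blo,
    bhi,
    xa,
    xb,
    grp_off,
    grp_mstart,
    grp_mend,
    txa,
    tx_off,
    tx_cand,
    conn_k,
    ev_k,
    xl_bound,
    xl_k,
    box_k,
    sub_k,
    txl_bound,
    txl_k,
):
    n = coords.shape[0]
    e = 0.0
    # connectivity (complex chains only; the lattice is rigid)
    for i in range(rigid_start - 1):
        if chain[i + 1] == chain[i]:
            s = _surf(coords, radii, i, i + 1)
            if s > 0.0:
                e += conn_k * s * s
    # excluded volume
    for i in range(n):
        for j in range(i + 1, n):
            if i >= rigid_start and j >= rigid_start:
                continue
            if chain[i] == chain[j] and cpos[j] - cpos[i] == 1:
                continue
            s = _surf(coords, radii, i, j)
            if s < 0.0:
                e += ev_k * s * s
    # cross-links
    for rec in range(xa.shape[0]):
        e += _xl_energy(coords, radii, xa, xb, n_per_copy, n_copies, xl_bound, xl_k, rec)
    # localization boxes
    for i in range(rigid_start):
        e += _box_energy(coords, blo, bhi, has_box, i, box_k)
    # subcomplex connectivity
    for g in range(grp_off.shape[0] - 1):
        e += _group_energy(coords, radii, grp_off, grp_mstart, grp_mend, g, sub_k)
    # complex-to-lattice restraints
    for rec in range(txa.shape[0]):
        e += _txl_energy(
            coords, radii, txa, tx_off, tx_cand, n_per_copy, n_copies, txl_bound, txl_k, rec
        )
    return e


@njit(cache=True)
def _local_energy(
    coords,
    radii,
    chain,
    cpos,
    rigid_start,
    n_per_copy,
    n_copies,
    has_box,
    blo,
    bhi,
    xa,
    xb,
    xl_off,
    xl_ids,
    grp_off,
    grp_mstart,
    grp_mend,
    bgrp,
    txa,
    tx_off,
    tx_cand,
    txl_off,
    txl_ids,
    conn_k,
    ev_k,
    xl_bound,
    xl_k,
    box_k,
    sub_k,
    txl_bound,
    txl_k,
    i,
    j,
):
    """Energy of every term touching bead i (and its image j, or -1)."""
    e = _conn_local(coords, radii, chain, rigid_start, i, conn_k)
    e += _ev_bead(coords, radii, chain, cpos, rigid_start, i, j, ev_k)
    e += _box_energy(coords, blo, bhi, has_box, i, box_k)
    if j >= 0:
        e += _conn_local(coords, radii, chain, rigid_start, j, conn_k)
        e += _ev_bead(coords, radii, chain, cpos, rigid_start, j, i, ev_k)
        e += _box_energy(coords, blo, bhi, has_box, j, box_k)
        s = _surf(coords, radii, i, j)  # the (i, image) pair itself, once
        if s < 0.0:
            e += ev_k * s * s
    base = i % n_per_copy
    for p in range(xl_off[base], xl_off[base + 1]):
        e += _xl_energy(
            coords, radii, xa, xb, n_per_copy, n_copies, xl_bound, xl_k, xl_ids[p]
        )
    for p in range(txl_off[base], txl_off[base + 1]):
        e += _txl_energy(
            coords, radii, txa, tx_off, tx_cand, n_per_copy, n_copies,
            txl_bound, txl_k, txl_ids[p],
        )
    g = bgrp[i]
    if g >= 0:
        e += _group_energy(coords, radii, grp_off, grp_mstart, grp_mend, g, sub_k)
    if j >= 0:
        g2 = bgrp[j]
        if g2 >= 0 and g2 != g:
            e += _group_energy(coords, radii, grp_off, grp_mstart, grp_mend, g2, sub_k)
    return e


@njit(cache=True)
def _rigid_cross_energy(
    coords, radii, chain, cpos, rigid_start,
    n_per_copy, n_copies,
    txa, tx_off, tx_cand, txl_bound, txl_k, ev_k,
):
    """Every term whose value changes under a rigid lattice move."""
    n = coords.shape[0]
    e = 0.0
    for c in range(rigid_start):
        for l in range(rigid_start, n):
            s = _surf(coords, radii, c, l)
            if s < 0.0:
                e += ev_k * s * s
    for rec in range(txa.shape[0]):
        e += _txl_energy(
            coords, radii, txa, tx_off, tx_cand, n_per_copy, n_copies,
            txl_bound, txl_k, rec,
        )
    return e


@njit(cache=True)
def _random_in_ball(rng, radius):
    while True:
        x = 2.0 * rng.random() - 1.0
        y = 2.0 * rng.random() - 1.0
        z = 2.0 * rng.random() - 1.0
        if x * x + y * y + z * z <= 1.0:
            return x * radius, y * radius, z * radius


@njit(cache=True)
def _run_segment(
    coords,
    radii,
    chain,
    cpos,
    rigid_start,
    sym_on,
    sym_R,
    sym_t,
    n_per_copy,
    n_copies,
    mobile,
    has_box,
    blo,
    bhi,
    xa,
    xb,
    xl_off,
    xl_ids,
    grp_off,
    grp_mstart,
    grp_mend,
    bgrp,
    txa,
    tx_off,
    tx_cand,
    txl_off,
    txl_ids,
    conn_k,
    ev_k,
    xl_bound,
    xl_k,
    box_k,
    sub_k,
    txl_bound,
    txl_k,
    max_move,
    p_rigid,
    rigid_max_trans,
    rigid_max_rot,
    p_registry,
    reg_lat_a,
    reg_lat_b,
    reg_ax_a,
    reg_ax_b,
    wte_on,
    wte_centers,
    wte_heights,
    wte_sigma,
    temperature,
    n_steps,
    e_in,
    rng,
    best_coords,
):
    n = coords.shape[0]
    e = e_in
    best_e = e_in
    best_coords[:, :] = coords
    n_accept = 0
    n_lat = n - rigid_start
    lat_buf = np.empty((n_lat, 3))
    n_mobile = mobile.shape[0]

    for _step in range(n_steps):
        do_rigid = n_lat > 0 and rng.random() < p_rigid
        if do_rigid:
            e_old = _rigid_cross_energy(
                coords, radii, chain, cpos, rigid_start,
                n_per_copy, n_copies, txa, tx_off, tx_cand, txl_bound, txl_k, ev_k,
            )
            for a in range(n_lat):
                for ax in range(3):
                    lat_buf[a, ax] = coords[rigid_start + a, ax]
            # centroid
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for a in range(n_lat):
                cx += coords[rigid_start + a, 0]
                cy += coords[rigid_start + a, 1]
                cz += coords[rigid_start + a, 2]
            cx /= n_lat
            cy /= n_lat
            cz /= n_lat
            if p_registry > 0.0 and rng.random() < p_registry:
                # registry jump: translate by one lattice vector or rotate
                # 90/180 degrees about the lattice normal -- proposals map
                # the lattice onto (near-)equivalent registries, letting
                # the chain hop between subunit-assignment basins that
                # small moves cannot connect.  The proposal set is closed
                # under inversion, so detailed balance holds.
                lvx = coords[reg_lat_b, 0] - coords[reg_lat_a, 0]
                lvy = coords[reg_lat_b, 1] - coords[reg_lat_a, 1]
                lvz = coords[reg_lat_b, 2] - coords[reg_lat_a, 2]
                avx = coords[reg_ax_b, 0] - coords[reg_ax_a, 0]
                avy = coords[reg_ax_b, 1] - coords[reg_ax_a, 1]
                avz = coords[reg_ax_b, 2] - coords[reg_ax_a, 2]
                choice = rng.integers(0, 7)
                tx = 0.0
                ty = 0.0
                tz = 0.0
                theta = 0.0
                ux = 0.0
                uy = 1.0
                uz = 0.0
                if choice == 0:
                    tx, ty, tz = lvx, lvy, lvz
                elif choice == 1:
                    tx, ty, tz = -lvx, -lvy, -lvz
                elif choice == 2:
                    tx, ty, tz = avx, avy, avz
                elif choice == 3:
                    tx, ty, tz = -avx, -avy, -avz
                else:
                    # rotation about the lattice normal
                    ux = lvy * avz - lvz * avy
                    uy = lvz * avx - lvx * avz
                    uz = lvx * avy - lvy * avx
                    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                    if choice == 4:
                        theta = 0.5 * np.pi
                    elif choice == 5:
                        theta = -0.5 * np.pi
                    else:
                        theta = np.pi
            else:
                # small random pose move (Rodrigues rotation + translation)
                while True:
                    ux = rng.standard_normal()
                    uy = rng.standard_normal()
                    uz = rng.standard_normal()
                    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                    if norm > 1e-12:
                        break
                ux /= norm
                uy /= norm
                uz /= norm
                theta = (2.0 * rng.random() - 1.0) * rigid_max_rot
                tx, ty, tz = _random_in_ball(rng, rigid_max_trans)
            ct = np.cos(theta)
            st = np.sin(theta)
            omc = 1.0 - ct
            for a in range(n_lat):
                px = coords[rigid_start + a, 0] - cx
                py = coords[rigid_start + a, 1] - cy
                pz = coords[rigid_start + a, 2] - cz
                qx = (
                    (ct + ux * ux * omc) * px
                    + (ux * uy * omc - uz * st) * py
                    + (ux * uz * omc + uy * st) * pz
                )
                qy = (
                    (uy * ux * omc + uz * st) * px
                    + (ct + uy * uy * omc) * py
                    + (uy * uz * omc - ux * st) * pz
                )
                qz = (
                    (uz * ux * omc - uy * st) * px
                    + (uz * uy * omc + ux * st) * py
                    + (ct + uz * uz * omc) * pz
                )
                coords[rigid_start + a, 0] = qx + cx + tx
                coords[rigid_start + a, 1] = qy + cy + ty
                coords[rigid_start + a, 2] = qz + cz + tz
            e_new = _rigid_cross_energy(
                coords, radii, chain, cpos, rigid_start,
                n_per_copy, n_copies, txa, tx_off, tx_cand, txl_bound, txl_k, ev_k,
            )
            de = e_new - e_old
            de_eff = de
            if wte_on:
                de_eff = de + _wte_bias(e + de, wte_centers, wte_heights, wte_sigma) - _wte_bias(
                    e, wte_centers, wte_heights, wte_sigma
                )
            accept = de_eff <= 0.0 or rng.random() < np.exp(-de_eff / temperature)
            if accept:
                e += de
                n_accept += 1
                if e < best_e:
                    best_e = e
                    best_coords[:, :] = coords
            else:
                for a in range(n_lat):
                    for ax in range(3):
                        coords[rigid_start + a, ax] = lat_buf[a, ax]
        else:
            i = mobile[rng.integers(0, n_mobile)]
            j = -1
            if sym_on:
                j = i + n_per_copy if i < n_per_copy else i - n_per_copy
            e_old = _local_energy(
                coords, radii, chain, cpos, rigid_start, n_per_copy, n_copies,
                has_box, blo, bhi, xa, xb, xl_off, xl_ids,
                grp_off, grp_mstart, grp_mend, bgrp,
                txa, tx_off, tx_cand, txl_off, txl_ids,
                conn_k, ev_k, xl_bound, xl_k, box_k, sub_k, txl_bound, txl_k,
                i, j,
            )
            ox = coords[i, 0]
            oy = coords[i, 1]
            oz = coords[i, 2]
            if j >= 0:
                ojx = coords[j, 0]
                ojy = coords[j, 1]
                ojz = coords[j, 2]
            else:
                ojx = 0.0
                ojy = 0.0
                ojz = 0.0
            dx, dy, dz = _random_in_ball(rng, max_move)
            coords[i, 0] = ox + dx
            coords[i, 1] = oy + dy
            coords[i, 2] = oz + dz
            if j >= 0:
                # symmetric image: j = R @ i + t (copy-0 bead drives copy 1)
                if i < n_per_copy:
                    src = i
                    dst = j
                else:
                    src = j
                    dst = i
                px = coords[src, 0]
                py = coords[src, 1]
                pz = coords[src, 2]
                coords[dst, 0] = sym_R[0, 0] * px + sym_R[0, 1] * py + sym_R[0, 2] * pz + sym_t[0]
                coords[dst, 1] = sym_R[1, 0] * px + sym_R[1, 1] * py + sym_R[1, 2] * pz + sym_t[1]
                coords[dst, 2] = sym_R[2, 0] * px + sym_R[2, 1] * py + sym_R[2, 2] * pz + sym_t[2]
            e_new = _local_energy(
                coords, radii, chain, cpos, rigid_start, n_per_copy, n_copies,
                has_box, blo, bhi, xa, xb, xl_off, xl_ids,
                grp_off, grp_mstart, grp_mend, bgrp,
                txa, tx_off, tx_cand, txl_off, txl_ids,
                conn_k, ev_k, xl_bound, xl_k, box_k, sub_k, txl_bound, txl_k,
                i, j,
            )
            de = e_new - e_old
            de_eff = de
            if wte_on:
                de_eff = de + _wte_bias(e + de, wte_centers, wte_heights, wte_sigma) - _wte_bias(
                    e, wte_centers, wte_heights, wte_sigma
                )
            accept = de_eff <= 0.0 or rng.random() < np.exp(-de_eff / temperature)
            if accept:
                e += de
                n_accept += 1
                if e < best_e:
                    best_e = e
                    best_coords[:, :] = coords
            else:
                coords[i, 0] = ox
                coords[i, 1] = oy
                coords[i, 2] = oz
                if j >= 0:
                    coords[j, 0] = ojx
                    coords[j, 1] = ojy
                    coords[j, 2] = ojz
    return e, best_e, n_accept


# ---------------------------------------------------------------------------
# python-side packing


class SegmentResult:
    __slots__ = ("energy", "best_energy", "best_coords", "n_accepted", "n_steps")

    def __init__(self, energy, best_energy, best_coords, n_accepted, n_steps):
        self.energy = energy
        self.best_energy = best_energy
        self.best_coords = best_coords
        self.n_accepted = n_accepted
        self.n_steps = n_steps

    @property
    def acceptance_rate(self):
        return self.n_accepted / self.n_steps if self.n_steps else 0.0


_EMPTY_I = np.zeros(0, dtype=np.int64)
_EMPTY_F = np.zeros(0, dtype=np.float64)


class ScoringEngine:
    """Flat-array view of an assembly + restraints for fast MC sampling.

    Optionally extends the system with a rigid lattice (appended beads) and
    ambiguous complex-to-lattice distance restraints, used for docking.
    """

    def __init__(
        self,
        assembly: Assembly,
        restraints: RestraintSet,
        symmetry_on: bool | None = None,
        lattice=None,
        tubulin_xls=None,
        txl_bound: float | None = None,
        txl_k: float = 1.0,
        isoform_restricted: bool = True,
    ):
        self.assembly = assembly
        self.restraints = restraints
        top = assembly.topology
        n_complex = assembly.n_beads
        self.rigid_start = n_complex
        self.n_per_copy = assembly.n_per_copy
        self.n_copies = top.copy_count

        if symmetry_on is None:
            symmetry_on = top.copy_count == 2
        if symmetry_on and top.copy_count != 2:
            raise ValueError("symmetry requires a 2-copy topology")

        radii = [assembly.radii]
        chain = [assembly.chain_of]
        cpos = [assembly.pos_in_chain]
        self.lattice = lattice
        if lattice is not None:
            radii.append(lattice.radii)
            chain.append(lattice.chain_of + len(assembly.chains))
            cpos.append(lattice.pos_in_chain)
        self.radii = np.concatenate(radii)
        self.chain = np.concatenate(chain).astype(np.int64)
        self.cpos = np.concatenate(cpos).astype(np.int64)
        self.n_beads = len(self.radii)

        # localization boxes -> per-bead bounds (copy 0 only; copy 1 is
        # localized implicitly through the symmetry transform)
        self.has_box = np.zeros(self.n_beads, dtype=np.bool_)
        self.blo = np.zeros((self.n_beads, 3))
        self.bhi = np.zeros((self.n_beads, 3))
        for name, box in top.bounding_boxes.items():
            sl = assembly.chain_slice(name, 0)
            self.has_box[sl] = True
            self.blo[sl] = box.lo
            self.bhi[sl] = box.hi

        # cross-links -> copy-0 bead pairs
        xa, xb = [], []
        for rec in restraints.crosslinks:
            xa.append(assembly.bead_index(rec.protein_a, rec.position_a, 0))
            xb.append(assembly.bead_index(rec.protein_b, rec.position_b, 0))
        self.xa = np.array(xa, dtype=np.int64) if xa else _EMPTY_I
        self.xb = np.array(xb, dtype=np.int64) if xb else _EMPTY_I
        self.xl_off, self.xl_ids = _build_csr(
            self.n_per_copy, [(a % self.n_per_copy, b % self.n_per_copy) for a, b in zip(self.xa, self.xb)]
        )

        # subcomplex groups -> per-copy instances of member bead ranges
        grp_off = [0]
        mstart, mend = [], []
        self.bgrp = np.full(self.n_beads, -1, dtype=np.int64)
        gid = 0
        for group in top.subcomplex_groups:
            for copy in range(top.copy_count):
                for name in group:
                    sl = assembly.chain_slice(name, copy)
                    mstart.append(sl.start)
                    mend.append(sl.stop)
                    if np.any(self.bgrp[sl] >= 0):
                        raise ValueError(
                            f"component {name!r} belongs to more than one subcomplex group"
                        )
                    self.bgrp[sl] = gid
                grp_off.append(len(mstart))
                gid += 1
        self.grp_off = np.array(grp_off, dtype=np.int64)
        self.grp_mstart = np.array(mstart, dtype=np.int64) if mstart else _EMPTY_I
        self.grp_mend = np.array(mend, dtype=np.int64) if mend else _EMPTY_I

        # complex-to-lattice restraints
        txa, tx_off, tx_cand = [], [0], []
        if tubulin_xls:
            if lattice is None:
                raise ValueError("tubulin cross-links require a lattice")
            for rec in tubulin_xls:
                txa.append(
                    assembly.bead_index(rec.protein, rec.position, 0)
                )
                cands = lattice.candidate_beads(
                    rec.tubulin_chain,
                    rec.tubulin_position,
                    isoform_restricted=isoform_restricted,
                )
                tx_cand.extend(int(c) + n_complex for c in cands)
                tx_off.append(len(tx_cand))
        self.txa = np.array(txa, dtype=np.int64) if txa else _EMPTY_I
        self.tx_off = np.array(tx_off, dtype=np.int64)
        self.tx_cand = np.array(tx_cand, dtype=np.int64) if tx_cand else _EMPTY_I
        self.txl_off, self.txl_ids = _build_csr(
            self.n_per_copy, [(a % self.n_per_copy,) for a in self.txa]
        )
        self.txl_bound = float(
            restraints.xl_upper_bound if txl_bound is None else txl_bound
        )
        self.txl_k = float(txl_k)

        self.sym_R = (
            top.symmetry.rotation if top.symmetry is not None else np.eye(3)
        )
        self.sym_t = (
            top.symmetry.translation if top.symmetry is not None else np.zeros(3)
        )
        self.set_symmetry(symmetry_on)

        # move parameters (overridable by the sampler)
        self.max_move = 1.0
        self.p_rigid = 0.1 if lattice is not None else 0.0
        self.rigid_max_trans = 2.0
        self.rigid_max_rot = np.deg2rad(2.0)
        self.p_registry = 0.0
        self.reg_lat = (0, 0)
        self.reg_ax = (0, 0)
        if lattice is not None:
            by_grid = {
                (sub["pf"], sub["row"]): sub["bead_start"]
                for sub in lattice.subunits
            }
            origin = by_grid[(0, 0)]
            self.reg_lat = (n_complex + origin, n_complex + by_grid[(1, 0)])
            self.reg_ax = (n_complex + origin, n_complex + by_grid[(0, 2)])

    def set_symmetry(self, on: bool) -> None:
        """Toggle the symmetry constraint and rebuild the mobile-bead list."""
        self.symmetry_on = bool(on) and self.n_copies == 2
        if self.symmetry_on:
            self.mobile = np.arange(self.n_per_copy, dtype=np.int64)
        else:
            self.mobile = np.arange(self.rigid_start, dtype=np.int64)

    def full_energy(self, coords: np.ndarray) -> float:
        r = self.restraints
        return float(
            _full_energy(
                coords, self.radii, self.chain, self.cpos, self.rigid_start,
                self.n_per_copy, self.n_copies,
                self.has_box, self.blo, self.bhi,
                self.xa, self.xb,
                self.grp_off, self.grp_mstart, self.grp_mend,
                self.txa, self.tx_off, self.tx_cand,
                r.connectivity_k, r.excluded_volume_k, r.xl_upper_bound, r.xl_k,
                r.box_k, r.subcomplex_k, self.txl_bound, self.txl_k,
            )
        )

    def run(
        self,
        coords: np.ndarray,
        temperature: float,
        n_steps: int,
        rng: np.random.Generator,
        energy: float | None = None,
        wte_centers: np.ndarray | None = None,
        wte_heights: np.ndarray | None = None,
        wte_sigma: float = 2.0,
    ) -> SegmentResult:
        """Run a segment of MC steps in place; returns exact final energy."""
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        if energy is None:
            energy = self.full_energy(coords)
        wte_on = wte_centers is not None and len(wte_centers) > 0
        r = self.restraints
        best_coords = np.empty_like(coords)
        e, best_e, n_acc = _run_segment(
            coords, self.radii, self.chain, self.cpos, self.rigid_start,
            self.symmetry_on, self.sym_R, self.sym_t,
            self.n_per_copy, self.n_copies, self.mobile,
            self.has_box, self.blo, self.bhi,
            self.xa, self.xb, self.xl_off, self.xl_ids,
            self.grp_off, self.grp_mstart, self.grp_mend, self.bgrp,
            self.txa, self.tx_off, self.tx_cand, self.txl_off, self.txl_ids,
            r.connectivity_k, r.excluded_volume_k, r.xl_upper_bound, r.xl_k,
            r.box_k, r.subcomplex_k, self.txl_bound, self.txl_k,
            self.max_move, self.p_rigid, self.rigid_max_trans, self.rigid_max_rot,
            self.p_registry,
            self.reg_lat[0], self.reg_lat[1], self.reg_ax[0], self.reg_ax[1],
            wte_on,
            wte_centers if wte_on else _EMPTY_F,
            wte_heights if wte_on else _EMPTY_F,
            wte_sigma,
            float(temperature), int(n_steps), float(energy),
            rng, best_coords,
        )
        # re-anchor to the exact energy so drift cannot accumulate
        e = self.full_energy(coords)
        return SegmentResult(e, best_e, best_coords, int(n_acc), int(n_steps))


def _build_csr(n_slots: int, touched: list[tuple]) -> tuple[np.ndarray, np.ndarray]:
    """CSR map slot -> record ids, given per-record touched slots."""
    lists: list[list[int]] = [[] for _ in range(n_slots)]
    for rec_id, slots in enumerate(touched):
        for s in set(slots):
            lists[int(s)].append(rec_id)
    off = np.zeros(n_slots + 1, dtype=np.int64)
    ids = []
    for s in range(n_slots):
        ids.extend(lists[s])
        off[s + 1] = len(ids)
    return off, (np.array(ids, dtype=np.int64) if ids else _EMPTY_I)
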