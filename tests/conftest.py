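"""Shared fixtures: tiny assemblies and an independent brute-force scorer.

The brute-force scorer re-derives every restraint term with plain loops,
straight from the definitions, and is kept free of any code from the
package's scoring path so it can serve as an oracle.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from xlmodel.io import CrossLinkRecord
from xlmodel.representation import (
    AssemblyTopology,
    Box,
    RigidTransform,
    build_assembly,
)


def c2_transform(separation: float = 60.0) -> RigidTransform:
    """Two-fold rotation about z with copies separated along x."""
    return RigidTransform(
        np.diag([-1.0, -1.0, 1.0]), np.array([separation, 0.0, 0.0])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_topology():
    """Two short components, dimeric, one bounding box."""
    return AssemblyTopology(
        sequences={"A": "ACDEFGHIKLMNPQRSTVWYACDEF", "B": "ACDEFGHIKL"},
        copy_count=2,
        granularity=10,
        symmetry=c2_transform(60.0),
        bounding_boxes={"A": Box([-30, -30, -30], [30, 30, 30])},
    )


@pytest.fixture
def small_assembly(small_topology, rng):
    assembly = build_assembly(small_topology)
    coords = rng.normal(scale=10.0, size=(assembly.n_beads, 3))
    assembly.set_coords(assembly.apply_symmetry(coords))
    return assembly


def random_assembly(n_per_chain, seed, copy_count=2, boxes=(), groups=(),
                    scale=15.0):
    """Random positioned assembly with given chain sizes (beads per chain)."""
    rng = np.random.default_rng(seed)
    sequences = {
        f"C{i}": "A" * (10 * n) for i, n in enumerate(n_per_chain)
    }
    topology = AssemblyTopology(
        sequences=sequences,
        copy_count=copy_count,
        granularity=10,
        symmetry=c2_transform(4.0 * scale) if copy_count == 2 else None,
        bounding_boxes={
            name: Box(np.array(lo), np.array(hi)) for name, lo, hi in boxes
        },
        subcomplex_groups=[list(g) for g in groups],
    )
    assembly = build_assembly(topology)
    coords = rng.normal(scale=scale, size=(assembly.n_beads, 3))
    assembly.set_coords(assembly.apply_symmetry(coords))
    return assembly


# ---------------------------------------------------------------------------
# independent brute-force scoring oracle


def brute_force_score(assembly, restraints, coords=None):
    """All restraint terms by direct looping over the definitions."""
    if coords is None:
        coords = assembly.coords
    top = assembly.topology
    radii = assembly.radii

    def surf(i, j):
        return (
            math.dist(coords[i], coords[j]) - radii[i] - radii[j]
        )

    terms = dict.fromkeys(
        ["connectivity", "excluded_volume", "crosslink", "box", "subcomplex"], 0.0
    )
    n = assembly.n_beads
    adjacent = set()
    for i in range(n - 1):
        if assembly.chain_of[i] == assembly.chain_of[i + 1]:
            adjacent.add((i, i + 1))
            s = surf(i, i + 1)
            if s > 0:
                terms["connectivity"] += restraints.connectivity_k * s * s
    for i, j in itertools.combinations(range(n), 2):
        if (i, j) in adjacent:
            continue
        s = surf(i, j)
        if s < 0:
            terms["excluded_volume"] += restraints.excluded_volume_k * s * s
    for rec in restraints.crosslinks:
        best = math.inf
        for ca in range(top.copy_count):
            for cb in range(top.copy_count):
                ia = assembly.bead_index(rec.protein_a, rec.position_a, ca)
                ib = assembly.bead_index(rec.protein_b, rec.position_b, cb)
                best = min(best, surf(ia, ib) if ia != ib else -2 * radii[ia])
        if best > restraints.xl_upper_bound:
            terms["crosslink"] += (
                restraints.xl_k * (best - restraints.xl_upper_bound) ** 2
            )
    for name, box in top.bounding_boxes.items():
        sl = assembly.chain_slice(name, 0)
        for i in range(sl.start, sl.stop):
            d2 = 0.0
            for ax in range(3):
                if coords[i][ax] < box.lo[ax]:
                    d2 += (box.lo[ax] - coords[i][ax]) ** 2
                elif coords[i][ax] > box.hi[ax]:
                    d2 += (coords[i][ax] - box.hi[ax]) ** 2
            terms["box"] += restraints.box_k * d2
    for group in top.subcomplex_groups:
        for copy in range(top.copy_count):
            for name in group:
                sl = assembly.chain_slice(name, copy)
                g = math.inf
                for other in group:
                    if other == name:
                        continue
                    so = assembly.chain_slice(other, copy)
                    for i in range(sl.start, sl.stop):
                        for j in range(so.start, so.stop):
                            g = min(g, surf(i, j))
                if g > 0:
                    terms["subcomplex"] += restraints.subcomplex_k * g * g
    terms["total"] = sum(terms.values())
    return terms


def random_crosslinks(assembly, n, seed):
    """Random residue-pair records on an assembly's components."""
    rng = np.random.default_rng(seed)
    names = assembly.topology.components
    recs = []
    for _ in range(n):
        pa, pb = rng.choice(names), rng.choice(names)
        ra = int(rng.integers(1, len(assembly.topology.sequences[pa]) + 1))
        rb = int(rng.integers(1, len(assembly.topology.sequences[pb]) + 1))
        recs.append(CrossLinkRecord(pa, ra, pb, rb, 0.001).normalized())
    return recs
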