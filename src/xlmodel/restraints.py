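"""The scoring function for cross-link-driven coarse-grained modelling.

All terms act on the *surface distance* between beads,

    s(i, j) = ||c_i - c_j|| - r_i - r_j,

which is negative when beads overlap.  Terms:

* connectivity  — sequence-adjacent beads: ``k s²`` for ``s > 0`` (gap only;
  overlap of neighbours is already penalized by excluded volume);
* excluded volume — all non-adjacent pairs: ``k s²`` for ``s < 0``;
* cross-link    — upper-bound harmonic ``k (s* - bound)²`` for ``s* > bound``
  where ``s*`` is the minimum surface distance over the ambiguous
  intra-/inter-copy endpoint assignments;
* localization  — ``k d²`` with ``d`` the distance from a bead centre to its
  component's bounding box (0 inside);
* subcomplex connectivity — for each member of a group, ``k g²`` where ``g``
  is its smallest surface distance to any bead of any other member
  (0 when already in contact).

Copy 1 of a dimer is a constraint (the symmetric image of copy 0), not a
restraint: ``apply_symmetry`` maps coordinates exactly.

All energies are dimensionless (units of kT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CrossLinkRecord
from .representation import Assembly, Box, RigidTransform

__all__ = [
    "RestraintSet",
    "ScoreBreakdown",
    "surface_distance",
    "connectivity_score",
    "excluded_volume_score",
    "crosslink_score",
    "min_crosslink_surface_distance",
    "localization_score",
    "subcomplex_score",
    "apply_symmetry",
    "total_score",
]


@dataclass
class RestraintSet:
    """All restraint parameters plus the cross-link list."""

    crosslinks: list[CrossLinkRecord] = field(default_factory=list)
    connectivity_k: float = 1.0
    excluded_volume_k: float = 1.0
    xl_upper_bound: float = 5.0
    xl_k: float = 1.0
    box_k: float = 1.0
    subcomplex_k: float = 1.0

    def __post_init__(self):
        for name in (
            "connectivity_k",
            "excluded_volume_k",
            "xl_k",
            "box_k",
            "subcomplex_k",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.xl_upper_bound <= 0:
            raise ValueError("xl_upper_bound must be > 0")


@dataclass
class ScoreBreakdown:
    connectivity: float = 0.0
    excluded_volume: float = 0.0
    crosslink: float = 0.0
    box: float = 0.0
    subcomplex: float = 0.0
    tubulin_xl: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.connectivity
            + self.excluded_volume
            + self.crosslink
            + self.box
            + self.subcomplex
            + self.tubulin_xl
        )

    def as_dict(self) -> dict[str, float]:
        d = {
            "connectivity": self.connectivity,
            "excluded_volume": self.excluded_volume,
            "crosslink": self.crosslink,
            "box": self.box,
            "subcomplex": self.subcomplex,
        }
        if self.tubulin_xl:
            d["tubulin_xl"] = self.tubulin_xl
        d["total"] = self.total
        return d


def surface_distance(c1, r1, c2, r2) -> float:
    return float(np.linalg.norm(np.asarray(c1) - np.asarray(c2))) - r1 - r2


def connectivity_score(coords: np.ndarray, radii: np.ndarray, k: float = 1.0) -> float:
    """Gap-harmonic over consecutive beads of one chain."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        return 0.0
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    s = d - radii[:-1] - radii[1:]
    gaps = np.maximum(s, 0.0)
    return float(k * np.sum(gaps**2))


def excluded_volume_score(
    coords: np.ndarray,
    radii: np.ndarray,
    k: float = 1.0,
    chain_of: np.ndarray | None = None,
    pos_in_chain: np.ndarray | None = None,
) -> float:
    """Soft quadratic overlap penalty over all non-sequence-adjacent pairs."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return 0.0
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    s = dist - radii[:, None] - radii[None, :]
    overlap = np.minimum(s, 0.0)
    pair = np.triu(np.ones((n, n), dtype=bool), 1)
    if chain_of is not None:
        adjacent = (chain_of[:, None] == chain_of[None, :]) & (
            np.abs(pos_in_chain[:, None] - pos_in_chain[None, :]) == 1
        )
        pair &= ~adjacent
    return float(k * np.sum(overlap[pair] ** 2))


def min_crosslink_surface_distance(
    record: CrossLinkRecord, assembly: Assembly, coords: np.ndarray | None = None
) -> float:
    """Minimum surface distance over the ambiguous copy assignments.

    For a dimer each endpoint may live in either copy, so the restraint is
    applied to the smallest of the intra-copy and inter-copy bead-pair
    distances (the same-copy pairings are equivalent by symmetry when the
    constraint holds, but all pairings are evaluated so the ambiguity is
    exact also after the symmetry constraint is released).
    """
    if coords is None:
        coords = assembly.coords
    ncopies = assembly.topology.copy_count
    best = np.inf
    for ca in range(ncopies):
        ia = assembly.bead_index(record.protein_a, record.position_a, ca)
        for cb in range(ncopies):
            ib = assembly.bead_index(record.protein_b, record.position_b, cb)
            # a same-bead pairing (both residues in one bead) has centre
            # distance 0, i.e. s = -2r: trivially satisfied
            s = surface_distance(
                coords[ia], assembly.radii[ia], coords[ib], assembly.radii[ib]
            )
            best = min(best, s)
    return best


def crosslink_score(
    record: CrossLinkRecord,
    assembly: Assembly,
    bound: float = 5.0,
    k: float = 1.0,
    coords: np.ndarray | None = None,
) -> float:
    """Upper-bound harmonic on the minimum ambiguous surface distance."""
    s_star = min_crosslink_surface_distance(record, assembly, coords)
    if s_star <= bound:
        return 0.0
    return float(k * (s_star - bound) ** 2)


def localization_score(centre: np.ndarray, box: Box, k: float = 1.0) -> float:
    """Harmonic pull back into a bounding box, active only outside it."""
    d = box.distance(np.asarray(centre, dtype=float))
    return float(k * d * d)


def subcomplex_score(
    group: list[str],
    assembly: Assembly,
    k: float = 1.0,
    copy: int = 0,
    coords: np.ndarray | None = None,
) -> float:
    """Connectivity among a group: each member near at least one other.

    For each member protein the gap ``g`` is the minimum bead-pair surface
    distance to any other member; a positive gap contributes ``k g²``.
    """
    if len(group) < 2:
        raise ValueError("subcomplex group needs >= 2 members")
    if coords is None:
        coords = assembly.coords
    total = 0.0
    slices = {name: assembly.chain_slice(name, copy) for name in group}
    for name in group:
        sl = slices[name]
        ca, ra = coords[sl], assembly.radii[sl]
        g = np.inf
        for other in group:
            if other == name:
                continue
            so = slices[other]
            cb, rb = coords[so], assembly.radii[so]
            d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
            s = d - ra[:, None] - rb[None, :]
            g = min(g, float(s.min()))
        if g > 0:
            total += k * g * g
    return float(total)


def apply_symmetry(coords0: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Image of copy-0 centres under the dimer symmetry (exact constraint)."""
    return transform.apply(coords0)


def total_score(
    assembly: Assembly,
    restraints: RestraintSet,
    coords: np.ndarray | None = None,
) -> ScoreBreakdown:
    """Full scoring-function breakdown; a pure function of the coordinates."""
    if coords is None:
        coords = assembly.coords
    coords = np.asarray(coords, dtype=float)
    top = assembly.topology
    bd = ScoreBreakdown()

    for name, copy in assembly.chains:
        sl = assembly.chain_slice(name, copy)
        bd.connectivity += connectivity_score(
            coords[sl], assembly.radii[sl], restraints.connectivity_k
        )

    bd.excluded_volume = excluded_volume_score(
        coords,
        assembly.radii,
        restraints.excluded_volume_k,
        assembly.chain_of,
        assembly.pos_in_chain,
    )

    for rec in restraints.crosslinks:
        bd.crosslink += crosslink_score(
            rec, assembly, restraints.xl_upper_bound, restraints.xl_k, coords
        )

    # boxes confine copy 0 only; copy 1 is determined by the symmetry
    # transform (and inherits the localization through it)
    for name, box in top.bounding_boxes.items():
        sl = assembly.chain_slice(name, 0)
        for centre in coords[sl]:
            bd.box += localization_score(centre, box, restraints.box_k)

    for group in top.subcomplex_groups:
        for copy in range(top.copy_count):
            bd.subcomplex += subcomplex_score(
                group, assembly, restraints.subcomplex_k, copy, coords
            )

    return bd
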