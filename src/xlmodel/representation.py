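"""Coarse-grained bead representation of a protein assembly.

Each protein chain is represented as a string of spherical beads, one bead
per ``granularity`` consecutive residues (default 10).  Bead volumes follow
the standard protein partial specific volume so that a 10-residue bead has a
radius of about 7 Å.  A dimeric assembly carries two copies of every chain;
copy 1 is the image of copy 0 under a fixed proper rigid transform
(the symmetry constraint), so only copy 0 carries degrees of freedom while
the constraint is active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Bead",
    "Box",
    "RigidTransform",
    "AssemblyTopology",
    "Assembly",
    "bead_radius",
    "build_beads",
    "residue_to_bead",
    "build_assembly",
]

#: Protein volume per dalton (Å³/Da), the conventional partial specific
#: volume of globular proteins.
C_VOL = 1.21
#: Mean residue mass in daltons.
M_RES = 110.0


def bead_radius(n_res: int, c_vol: float = C_VOL, m_res: float = M_RES) -> float:
    """Radius (Å) of a sphere holding the average volume of ``n_res`` residues.

    The volume is ``c_vol * m_res`` per residue; the radius is that of the
    equivalent sphere, ``(3V / 4π)^(1/3)``.
    """
    if n_res < 1:
        raise ValueError(f"n_res must be >= 1, got {n_res}")
    volume = c_vol * m_res * n_res
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass
class Bead:
    """One coarse-grained sphere covering an inclusive 1-based residue range."""

    component: str
    copy: int
    first_res: int
    last_res: int
    radius: float
    centre: np.ndarray | None = None

    @property
    def n_res(self) -> int:
        return self.last_res - self.first_res + 1


def build_beads(
    sequence: str,
    granularity: int = 10,
    component: str = "",
    copy: int = 0,
    c_vol: float = C_VOL,
    m_res: float = M_RES,
) -> list[Bead]:
    """Partition a sequence into consecutive beads of ``granularity`` residues.

    Ranges are contiguous and non-overlapping; the final bead holds the
    remainder (and is smaller) so that residue-to-bead addressing stays a
    pure function of the residue index.  Centres are left unset.
    """
    if not sequence:
        raise ValueError("cannot build beads for an empty sequence")
    if granularity < 1:
        raise ValueError(f"granularity must be >= 1, got {granularity}")
    n = len(sequence)
    beads = []
    for first in range(1, n + 1, granularity):
        last = min(first + granularity - 1, n)
        beads.append(
            Bead(
                component=component,
                copy=copy,
                first_res=first,
                last_res=last,
                radius=bead_radius(last - first + 1, c_vol, m_res),
            )
        )
    return beads


def residue_to_bead(residue: int, granularity: int = 10, n_res: int | None = None,
                    component: str = "") -> int:
    """Bead index (0-based) covering a 1-based residue position."""
    if residue < 1 or (n_res is not None and residue > n_res):
        raise ValueError(
            f"residue {residue} out of range for component {component!r}"
            + (f" (length {n_res})" if n_res is not None else "")
        )
    return (residue - 1) // granularity


@dataclass
class Box:
    """Axis-aligned bounding box in Å."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.lo.shape != (3,) or self.hi.shape != (3,):
            raise ValueError("box corners must be 3-vectors")
        if np.any(self.hi < self.lo):
            raise ValueError("box has hi < lo on some axis")

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.all((points >= self.lo) & (points <= self.hi), axis=1)

    def distance(self, point: np.ndarray) -> float:
        """Euclidean distance from a point to the box (0 inside)."""
        d = np.maximum(self.lo - point, 0.0) + np.maximum(point - self.hi, 0.0)
        return float(np.linalg.norm(d))

    @property
    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("need a 3x3 rotation and a 3-vector translation")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation matrix must have determinant +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class AssemblyTopology:
    """Everything needed to lay out the bead representation of an assembly.

    ``sequences`` maps component name to one-letter amino-acid sequence.
    ``copy_count`` is 2 for a symmetric dimer.  ``subcomplex_groups`` lists
    sets of components that must stay mutually connected (each member in
    contact with at least one other member of its group).  ``bounding_boxes``
    confine the named components, emulating localization data.
    """

    sequences: dict[str, str]
    copy_count: int = 2
    granularity: int = 10
    symmetry: RigidTransform | None = None
    subcomplex_groups: list[list[str]] = field(default_factory=list)
    bounding_boxes: dict[str, Box] = field(default_factory=dict)
    c_vol: float = C_VOL
    m_res: float = M_RES

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("topology needs at least one component")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"component {name!r} has an empty sequence")
        if self.copy_count not in (1, 2):
            raise ValueError("copy_count must be 1 or 2")
        if self.copy_count == 2 and self.symmetry is None:
            raise ValueError("a 2-copy topology requires a symmetry transform")
        for group in self.subcomplex_groups:
            if len(group) < 2:
                raise ValueError("subcomplex groups need at least 2 members")
            for name in group:
                if name not in self.sequences:
                    raise KeyError(f"unknown component {name!r} in subcomplex group")
        for name in self.bounding_boxes:
            if name not in self.sequences:
                raise KeyError(f"bounding box for unknown component {name!r}")

    @property
    def components(self) -> list[str]:
        return list(self.sequences)

    def n_beads(self, component: str) -> int:
        return -(-len(self.sequences[component]) // self.granularity)

    def residue_bead(self, component: str, residue: int) -> int:
        return residue_to_bead(
            residue, self.granularity, len(self.sequences[component]), component
        )


class Assembly:
    """Positioned bead representation of the full assembly, flat-array form.

    Beads are stored copy-major: all beads of copy 0 (components in topology
    order), then the same layout for copy 1.  This makes the symmetric image
    of bead ``i`` simply ``i ± n_per_copy``.
    """

    def __init__(self, topology: AssemblyTopology):
        self.topology = topology
        chains: list[tuple[str, int]] = []
        beads: list[Bead] = []
        chain_of: list[int] = []
        pos_in_chain: list[int] = []
        self._chain_start: dict[tuple[str, int], int] = {}
        for copy in range(topology.copy_count):
            for name in topology.components:
                chain_idx = len(chains)
                chains.append((name, copy))
                self._chain_start[(name, copy)] = len(beads)
                for pos, bead in enumerate(
                    build_beads(
                        topology.sequences[name],
                        topology.granularity,
                        component=name,
                        copy=copy,
                        c_vol=topology.c_vol,
                        m_res=topology.m_res,
                    )
                ):
                    beads.append(bead)
                    chain_of.append(chain_idx)
                    pos_in_chain.append(pos)
        self.beads = beads
        self.chains = chains
        self.chain_of = np.array(chain_of, dtype=np.int64)
        self.pos_in_chain = np.array(pos_in_chain, dtype=np.int64)
        self.radii = np.array([b.radius for b in beads], dtype=float)
        self.copy_of = np.array([b.copy for b in beads], dtype=np.int64)
        self.n_beads = len(beads)
        self.n_per_copy = self.n_beads // topology.copy_count
        self.coords = np.full((self.n_beads, 3), np.nan)

    def bead_index(self, component: str, residue: int, copy: int = 0) -> int:
        """Global bead index for a residue of a component copy."""
        return self._chain_start[(component, copy)] + self.topology.residue_bead(
            component, residue
        )

    def chain_slice(self, component: str, copy: int = 0) -> slice:
        start = self._chain_start[(component, copy)]
        return slice(start, start + self.topology.n_beads(component))

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_beads, 3):
            raise ValueError(
                f"coords shape {coords.shape} != ({self.n_beads}, 3)"
            )
        self.coords = coords.copy()
        for bead, c in zip(self.beads, self.coords):
            bead.centre = c

    def apply_symmetry(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Overwrite copy-1 centres with the symmetric image of copy 0."""
        from .restraints import apply_symmetry  # local import, avoids cycle

        if coords is None:
            coords = self.coords
        if self.topology.copy_count == 2:
            n0 = self.n_per_copy
            coords[n0:] = apply_symmetry(coords[:n0], self.topology.symmetry)
        return coords


def build_assembly(topology: AssemblyTopology) -> Assembly:
    """Construct the (unpositioned) bead representation of a topology."""
    return Assembly(topology)
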