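"""Restraint-guided flexible docking onto a coarse-grained tubulin lattice.

A flat 6x6 patch of alpha/beta-tubulin monomers (alternating along each
protofilament) is built at ten residues per bead.  Complex-to-tubulin
cross-links are ambiguous restraints: each acts on the minimum surface
distance over both complex copies and over every *interior* lattice subunit
of the matching isoform (edge subunits are excluded so boundary artefacts
of the finite patch cannot attract restraints).

Docking runs in two stages of parallel-tempering MC on the combined score
(all free-complex restraints plus the tubulin restraints plus complex-to-
lattice excluded volume): stage 1 moves the lattice as one rigid body from
a random pose far away while every complex bead stays individually mobile
under the symmetry constraint; stage 2 continues with the symmetry
constraint released so the two monomers can reorient independently.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import ScoringEngine
from .representation import Assembly, AssemblyTopology, build_beads
from .restraints import RestraintSet
from .sampler import Ensemble, ModelState, SamplerConfig, run_sampling

__all__ = [
    "TubulinLattice",
    "TubulinXLRecord",
    "DockingConfig",
    "DockingResult",
    "build_lattice",
    "read_tubulin_xl_table",
    "write_tubulin_xl_table",
    "tubulin_xl_score",
    "tubulin_xl_satisfaction",
    "dock_flexible",
    "classify_orientation",
]

TXL_COLUMNS = ["protein", "position", "tubulin_chain", "tubulin_position"]


@dataclass(frozen=True, order=True)
class TubulinXLRecord:
    """A cross-link between a complex residue and a tubulin residue."""

    protein: str
    position: int
    tubulin_chain: str  # "alpha" or "beta"
    tubulin_position: int

    def __post_init__(self):
        if self.tubulin_chain not in ("alpha", "beta"):
            raise ValueError(
                f"tubulin_chain must be 'alpha' or 'beta', got {self.tubulin_chain!r}"
            )


class TubulinLattice:
    """Rigid coarse-grained patch of tubulin monomers on a flat lattice.

    Protofilaments run along +z (the plus-end direction); neighbouring
    protofilaments are offset along +x.  Subunit (p, k) sits at
    ``(p * lateral_spacing, 0, k * axial_spacing)`` and is alpha for even
    ``k``, beta for odd.  Each monomer is a bead chain whose beads are
    packed deterministically on a compact cubic grid around the subunit
    centre.  Subunits on the patch boundary are flagged as edge and never
    serve as restraint candidates.
    """

    def __init__(
        self,
        alpha_seq: str,
        beta_seq: str,
        granularity: int = 10,
        n_protofilaments: int = 6,
        n_monomers: int = 6,
        lateral_spacing: float = 52.0,
        axial_spacing: float = 40.0,
    ):
        if lateral_spacing <= 0 or axial_spacing <= 0:
            raise ValueError("lattice spacings must be > 0")
        self.sequences = {"alpha": alpha_seq, "beta": beta_seq}
        self.granularity = granularity
        self.n_protofilaments = n_protofilaments
        self.n_monomers = n_monomers
        self.lateral_spacing = lateral_spacing
        self.axial_spacing = axial_spacing
        self.axis = np.array([0.0, 0.0, 1.0])  # plus-end direction (template)

        radii, chain_of, pos_in_chain, coords = [], [], [], []
        self.subunits: list[dict] = []
        self._chain_beads: dict[str, list] = {
            iso: build_beads(seq, granularity, component=iso)
            for iso, seq in self.sequences.items()
        }
        bead_cursor = 0
        for p in range(n_protofilaments):
            for k in range(n_monomers):
                iso = "alpha" if k % 2 == 0 else "beta"
                beads = self._chain_beads[iso]
                nb = len(beads)
                centre = np.array([p * lateral_spacing, 0.0, k * axial_spacing])
                layout = _cubic_layout(nb, 2.0 * max(b.radius for b in beads))
                sub_id = len(self.subunits)
                interior = (
                    1 <= p <= n_protofilaments - 2 and 1 <= k <= n_monomers - 2
                )
                self.subunits.append(
                    {
                        "pf": p,
                        "row": k,
                        "isoform": iso,
                        "interior": interior,
                        "bead_start": bead_cursor,
                        "n_beads": nb,
                        "centre": centre,
                    }
                )
                for b_i, bead in enumerate(beads):
                    radii.append(bead.radius)
                    chain_of.append(sub_id)
                    pos_in_chain.append(b_i)
                    coords.append(centre + layout[b_i])
                bead_cursor += nb
        self.radii = np.array(radii)
        self.chain_of = np.array(chain_of, dtype=np.int64)
        self.pos_in_chain = np.array(pos_in_chain, dtype=np.int64)
        self.coords_template = np.array(coords)
        self.n_beads = len(radii)

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    @property
    def n_interior(self) -> int:
        return sum(s["interior"] for s in self.subunits)

    @property
    def n_edge(self) -> int:
        return self.n_subunits - self.n_interior

    def residue_bead_offset(self, isoform: str, residue: int) -> int:
        seq = self.sequences[isoform]
        if residue < 1 or residue > len(seq):
            raise ValueError(
                f"tubulin residue {residue} out of range for {isoform} "
                f"(length {len(seq)})"
            )
        return (residue - 1) // self.granularity

    def candidate_beads(
        self, isoform: str, residue: int, isoform_restricted: bool = True
    ) -> np.ndarray:
        """Template bead indices for a tubulin residue in every interior
        subunit eligible under the ambiguity rule."""
        out = []
        for sub in self.subunits:
            if not sub["interior"]:
                continue
            if isoform_restricted and sub["isoform"] != isoform:
                continue
            seq = self.sequences[sub["isoform"]]
            if residue > len(seq):
                continue
            out.append(sub["bead_start"] + (residue - 1) // self.granularity)
        if not out:
            raise ValueError(
                f"no interior subunit can host a {isoform} residue {residue}"
            )
        return np.array(out, dtype=np.int64)

    def pose_from_coords(self, lattice_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Recover the rigid pose (R, t) mapping the template onto coords."""
        a = self.coords_template - self.coords_template.mean(axis=0)
        b = lattice_coords - lattice_coords.mean(axis=0)
        H = a.T @ b
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        t = lattice_coords.mean(axis=0) - R @ self.coords_template.mean(axis=0)
        return R, t

    def protofilament_axis(self, lattice_coords: np.ndarray | None = None) -> np.ndarray:
        """Plus-end direction, in the docked frame when coords are given."""
        if lattice_coords is None:
            return self.axis.copy()
        R, _ = self.pose_from_coords(lattice_coords)
        return R @ self.axis


def _cubic_layout(n: int, spacing: float) -> np.ndarray:
    """Deterministic compact cubic packing of n points around the origin."""
    side = max(1, math.ceil(n ** (1.0 / 3.0)))
    pts = []
    for idx in range(n):
        ix = idx % side
        iy = (idx // side) % side
        iz = idx // (side * side)
        pts.append([ix, iy, iz])
    pts = np.array(pts, dtype=float) * spacing
    return pts - pts.mean(axis=0)


def build_lattice(
    alpha_seq: str,
    beta_seq: str,
    granularity: int = 10,
    n_protofilaments: int = 6,
    n_monomers: int = 6,
    lateral_spacing: float = 52.0,
    axial_spacing: float = 40.0,
) -> TubulinLattice:
    """Construct the coarse-grained tubulin patch (deterministic)."""
    return TubulinLattice(
        alpha_seq,
        beta_seq,
        granularity=granularity,
        n_protofilaments=n_protofilaments,
        n_monomers=n_monomers,
        lateral_spacing=lateral_spacing,
        axial_spacing=axial_spacing,
    )


def read_tubulin_xl_table(path) -> list[TubulinXLRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TXL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    recs = set()
    for row in df.itertuples(index=False):
        recs.add(
            TubulinXLRecord(
                str(row.protein), int(row.position),
                str(row.tubulin_chain), int(row.tubulin_position),
            )
        )
    return sorted(recs)


def write_tubulin_xl_table(records, path) -> None:
    rows = [
        {
            "protein": r.protein,
            "position": r.position,
            "tubulin_chain": r.tubulin_chain,
            "tubulin_position": r.tubulin_position,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TXL_COLUMNS).to_csv(path, sep="\t", index=False)


def _min_txl_surface_distance(
    record: TubulinXLRecord,
    assembly: Assembly,
    complex_coords: np.ndarray,
    lattice: TubulinLattice,
    lattice_coords: np.ndarray,
    isoform_restricted: bool = True,
) -> float:
    cands = lattice.candidate_beads(
        record.tubulin_chain, record.tubulin_position, isoform_restricted
    )
    best = np.inf
    for copy in range(assembly.topology.copy_count):
        ia = assembly.bead_index(record.protein, record.position, copy)
        ca = complex_coords[ia]
        ra = assembly.radii[ia]
        d = np.linalg.norm(lattice_coords[cands] - ca, axis=1)
        s = d - lattice.radii[cands] - ra
        best = min(best, float(s.min()))
    return best


def tubulin_xl_score(
    record: TubulinXLRecord,
    assembly: Assembly,
    complex_coords: np.ndarray,
    lattice: TubulinLattice,
    lattice_coords: np.ndarray,
    bound: float = 5.0,
    k: float = 1.0,
    isoform_restricted: bool = True,
) -> float:
    """Upper-bound harmonic on the minimum ambiguous complex-lattice pair."""
    s = _min_txl_surface_distance(
        record, assembly, complex_coords, lattice, lattice_coords, isoform_restricted
    )
    if s <= bound:
        return 0.0
    return float(k * (s - bound) ** 2)


def tubulin_xl_satisfaction(
    records,
    assembly: Assembly,
    complex_coords: np.ndarray,
    lattice: TubulinLattice,
    lattice_coords: np.ndarray,
    cutoff: float = 10.0,
    isoform_restricted: bool = True,
) -> float:
    """Fraction of tubulin cross-links fit within ``cutoff`` Å (surfaces)."""
    if not records:
        raise ValueError("no tubulin cross-links given")
    n_ok = sum(
        _min_txl_surface_distance(
            r, assembly, complex_coords, lattice, lattice_coords, isoform_restricted
        )
        <= cutoff
        for r in records
    )
    return n_ok / len(records)


@dataclass
class DockingConfig:
    """Two-stage docking protocol parameters."""

    stage1_steps: int = 200_000
    stage2_steps: int = 100_000
    n_replicas: int = 8
    t_min: float = 1.0
    t_max: float = 3.0
    max_move: float = 1.0
    exchange_interval: int = 500
    seed: int = 0
    init_distance: float = 1000.0  # 100 nm, lattice start pose
    p_rigid: float = 0.2
    rigid_max_trans: float = 2.0
    rigid_max_rot_deg: float = 2.0
    p_registry: float = 0.1  # fraction of rigid moves that are lattice-symmetry jumps
    top_n_keep: int = 200
    stage2: bool = True
    quench_steps: int = 30_000  # per quench stage; 0 disables polishing
    isoform_restricted: bool = True
    txl_k: float = 1.0
    txl_bound: float | None = None
    fit_cutoff: float = 10.0


@dataclass
class DockingResult:
    coords: np.ndarray              # complex + lattice beads, docked
    n_complex: int
    stage1_best_score: float
    stage2_best_score: float | None
    txl_satisfaction: float
    orientation: dict
    ensemble: Ensemble = field(repr=False)

    @property
    def complex_coords(self) -> np.ndarray:
        return self.coords[: self.n_complex]

    @property
    def lattice_coords(self) -> np.ndarray:
        return self.coords[self.n_complex :]


def _random_pose(template: np.ndarray, centre_target: np.ndarray, distance: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Template at a uniformly random orientation, centred at a random point
    ``distance`` away from ``centre_target``."""
    # uniform random rotation from a random quaternion
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    centred = template - template.mean(axis=0)
    return centred @ R.T + centre_target + distance * direction


def dock_flexible(
    topology: AssemblyTopology,
    restraints: RestraintSet,
    model_coords: np.ndarray,
    lattice: TubulinLattice,
    tubulin_xls: list[TubulinXLRecord],
    config: DockingConfig | None = None,
    labelled_termini: dict[str, tuple[str, str]] | None = None,
) -> DockingResult:
    """Flexibly dock a modelled complex onto the tubulin lattice.

    ``model_coords`` is a positioned model from free-complex sampling (its
    cluster-centre, typically).  Stage 1 samples per-bead complex moves with
    the symmetry constraint on, plus rigid-body lattice moves, starting the
    lattice at a random pose ``init_distance`` away.  Stage 2 continues from
    the stage-1 optimum with the symmetry constraint released.
    """
    if config is None:
        config = DockingConfig()
    if tubulin_xls is not None and len(tubulin_xls) == 0:
        tubulin_xls = None
    from .representation import build_assembly

    assembly = build_assembly(topology)
    engine = ScoringEngine(
        assembly,
        restraints,
        symmetry_on=topology.copy_count == 2,
        lattice=lattice,
        tubulin_xls=tubulin_xls,
        txl_bound=config.txl_bound,
        txl_k=config.txl_k,
        isoform_restricted=config.isoform_restricted,
    )
    engine.p_rigid = config.p_rigid
    engine.rigid_max_trans = config.rigid_max_trans
    engine.rigid_max_rot = np.deg2rad(config.rigid_max_rot_deg)
    engine.p_registry = config.p_registry

    ss = np.random.SeedSequence(config.seed)
    pose_seed, s1_seed, s2_seed, q_seed = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]
    pose_rng = np.random.default_rng(pose_seed)
    n_complex = assembly.n_beads
    centre = model_coords.mean(axis=0)

    initial_states = []
    for _ in range(config.n_replicas):
        coords = np.vstack(
            [
                model_coords,
                _random_pose(
                    lattice.coords_template, centre, config.init_distance, pose_rng
                ),
            ]
        )
        initial_states.append(ModelState(coords=coords))

    s1_config = SamplerConfig(
        n_replicas=config.n_replicas,
        t_min=config.t_min,
        t_max=config.t_max,
        max_move=config.max_move,
        n_steps=config.stage1_steps,
        exchange_interval=config.exchange_interval,
        seed=s1_seed,
        top_n_keep=config.top_n_keep,
    )
    stage1 = run_sampling(
        topology, restraints, s1_config, engine=engine, initial_states=initial_states
    )
    best = stage1.best
    stage2_best_score = None
    final_ensemble = stage1
    if config.stage2:
        engine.set_symmetry(False)
        s2_states = [
            ModelState(coords=best.coords.copy()) for _ in range(config.n_replicas)
        ]
        s2_config = dataclasses.replace(
            s1_config, n_steps=config.stage2_steps, seed=s2_seed
        )
        stage2 = run_sampling(
            topology, restraints, s2_config, engine=engine, initial_states=s2_states
        )
        stage2_best_score = float(stage2.best.score)
        final_ensemble = stage2
        best = stage2.best

    docked = best.coords.copy()
    if config.quench_steps > 0:
        # polish: anneal the best state down to near-zero temperature so
        # small residual restraint violations are worked out
        quench_rng = np.random.default_rng(q_seed)
        energy = engine.full_energy(docked)
        for temperature, max_move in ((0.3, 1.0), (0.05, 0.5), (0.01, 0.25)):
            engine.max_move = max_move
            seg = engine.run(
                docked, temperature, config.quench_steps, quench_rng, energy=energy
            )
            energy = seg.energy
        engine.max_move = config.max_move
        if config.stage2:
            stage2_best_score = float(energy)
    engine.set_symmetry(topology.copy_count == 2)
    sat = tubulin_xl_satisfaction(
        tubulin_xls or [],
        assembly,
        docked[:n_complex],
        lattice,
        docked[n_complex:],
        cutoff=config.fit_cutoff,
        isoform_restricted=config.isoform_restricted,
    ) if tubulin_xls else float("nan")
    orientation = classify_orientation(
        docked[:n_complex],
        lattice.protofilament_axis(docked[n_complex:]),
        assembly=assembly,
        labelled_termini=labelled_termini,
    )
    return DockingResult(
        coords=docked,
        n_complex=n_complex,
        stage1_best_score=float(stage1.best.score),
        stage2_best_score=stage2_best_score,
        txl_satisfaction=float(sat),
        orientation=orientation,
        ensemble=final_ensemble,
    )


def classify_orientation(
    complex_coords: np.ndarray,
    protofilament_axis: np.ndarray,
    assembly: Assembly | None = None,
    labelled_termini: dict[str, tuple[str, str]] | None = None,
    degeneracy_ratio: float = 1.02,
) -> dict:
    """Orientation of the complex relative to microtubule polarity.

    The complex long axis is the largest-variance principal axis of its
    bead centres; the reported angle to the protofilament (plus-end) axis is
    folded into [0°, 90°].  ``labelled_termini`` maps a label to a
    (component, "N"/"C") terminus; each is classified plus- or minus-facing
    by the sign of its axial coordinate relative to the complex centroid.
    An isotropic bead cloud has no defined long axis; the angle is then
    reported as None.
    """
    axis = np.asarray(protofilament_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pts = np.asarray(complex_coords, dtype=float)
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    principal = evecs[:, -1]
    degenerate = evals[-1] <= degeneracy_ratio * evals[-2]
    if degenerate:
        angle = None
        orient_class = "undefined"
    else:
        cosang = abs(float(principal @ axis))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        orient_class = "perpendicular" if angle > 45.0 else "parallel"
    report = {
        "angle_deg": angle,
        "class": orient_class,
        "termini": {},
    }
    if labelled_termini and assembly is not None:
        centroid_ax = float(pts.mean(axis=0) @ axis)
        for label, (component, end) in labelled_termini.items():
            residue = 1 if end == "N" else len(assembly.topology.sequences[component])
            entries = {}
            for copy in range(assembly.topology.copy_count):
                idx = assembly.bead_index(component, residue, copy)
                ax_pos = float(pts[idx] @ axis) - centroid_ax
                entries[f"copy{copy}"] = {
                    "axial_offset": ax_pos,
                    "facing": "plus" if ax_pos > 0 else "minus",
                }
            report["termini"][label] = entries
    return report
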