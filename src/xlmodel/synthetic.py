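"""Synthetic ground-truth assemblies and simulated cross-link observations.

This module generates toy complexes with known bead-level structure and
simulates the cross-linking experiment on them: site pairs whose true
ambiguous surface distance is within the observable span are detected with
a stated probability, and a small fraction of uniformly random decoy pairs
is appended, mimicking the residual false positives of a 1%-FDR dataset.
Every pipeline stage can therefore be exercised end to end, with parameter
recovery measured against the known truth.

Sequences are synthetic: lysine-like reactive sites are placed every 8th
residue (about the natural lysine frequency), written as 'K' in otherwise
poly-alanine sequences so that coverage accounting works unchanged.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .analysis import contact_map, daura_cluster, satisfaction_fraction
from .io import CrossLinkRecord, MonoLinkRecord
from .representation import (
    Assembly,
    AssemblyTopology,
    Box,
    RigidTransform,
    build_assembly,
    build_beads,
)
from .restraints import RestraintSet, min_crosslink_surface_distance
from .sampler import SamplerConfig, run_sampling

__all__ = [
    "ToyAssemblySpec",
    "elongated_rod_dimer",
    "ToyAssembly",
    "SimulatedDataset",
    "lysine_sites",
    "make_site_sequence",
    "generate_toy_assembly",
    "simulate_crosslinks",
    "simulate_monolinks",
    "derive_bounding_boxes",
    "simulate_tubulin_xls",
    "default_study_spec",
    "recovery_study",
    "docking_recovery_study",
]

SITE_PERIOD = 8  # one lysine-like site every 8 residues


def make_site_sequence(length: int, period: int = SITE_PERIOD) -> str:
    """Poly-alanine with 'K' at positions period/2, period/2+period, ..."""
    start = max(1, period // 2)
    seq = ["A"] * length
    for pos in range(start, length + 1, period):
        seq[pos - 1] = "K"
    return "".join(seq)


def lysine_sites(sequence: str) -> list[int]:
    """1-based positions of lysines (the cross-linkable sites)."""
    return [i + 1 for i, aa in enumerate(sequence) if aa == "K"]


@dataclass
class ToyAssemblySpec:
    """Recipe for a synthetic ground-truth assembly."""

    lengths: dict[str, int]
    granularity: int = 10
    copy_count: int = 2
    rg_target: float | None = None  # per-copy radius of gyration target, Å
    growth_bias: float = 0.0  # directional bias (+x) during growth: elongates
    subcomplex_groups: list[list[str]] = field(default_factory=list)
    site_period: int = SITE_PERIOD
    seed: int = 0

    def __post_init__(self):
        if not self.lengths:
            raise ValueError("need at least one component")
        if not any(n >= self.granularity for n in self.lengths.values()):
            raise ValueError("at least one component must span a full bead")


@dataclass
class ToyAssembly:
    """Ground truth: topology plus true bead coordinates."""

    spec: ToyAssemblySpec
    topology: AssemblyTopology
    assembly: Assembly
    coords: np.ndarray  # (n_beads, 3) ground-truth centres

    @property
    def sequences(self) -> dict[str, str]:
        return self.topology.sequences


@dataclass
class SimulatedDataset:
    """Simulated cross-link observations from a known structure.

    ``decoy_keys`` flags the appended false-positive UDRs; it is meta
    information for validation and is never an input to the modelling.
    """

    crosslinks: list[CrossLinkRecord]
    decoy_keys: set[tuple]
    params: dict = field(default_factory=dict)

    @property
    def true_records(self) -> list[CrossLinkRecord]:
        return [r for r in self.crosslinks if r.udr_key not in self.decoy_keys]

    @property
    def decoy_records(self) -> list[CrossLinkRecord]:
        return [r for r in self.crosslinks if r.udr_key in self.decoy_keys]


# ---------------------------------------------------------------------------
# ground-truth generation


def _repair(
    coords: np.ndarray,
    radii: np.ndarray,
    adjacent: np.ndarray,
    tol: float = 5e-4,
    max_sweeps: int = 500,
) -> bool:
    """Project out overlaps (non-adjacent pairs) and gaps (adjacent pairs).

    Jacobi-style simultaneous projection; returns True on convergence.
    """
    n = len(coords)
    eye = np.eye(n, dtype=bool)
    for _ in range(max_sweeps):
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, 1.0)
        s = dist - radii[:, None] - radii[None, :]
        overlap = (s < -tol) & ~adjacent & ~eye
        gap = (s > tol) & adjacent
        worst = 0.0
        if overlap.any():
            worst = max(worst, float(-s[overlap].min()))
        if gap.any():
            worst = max(worst, float(s[gap].max()))
        if worst <= tol:
            return True
        corr = np.zeros_like(coords)
        unit = diff / dist[..., None]
        # each member of a violating pair moves half the violation
        push = np.where(overlap, -s, 0.0) * 0.5
        pull = np.where(gap, s, 0.0) * 0.5
        move = (push - pull)[..., None] * unit
        corr += 0.6 * move.sum(axis=1)  # under-relaxation for stability
        coords += corr
    return False


def generate_toy_assembly(spec: ToyAssemblySpec) -> ToyAssembly:
    """Grow a self-avoiding compact bead assembly with known coordinates.

    Chains are grown bead by bead (each new bead touching its predecessor,
    avoiding overlap), new components attach to already-placed ones (group
    members attach within their subcomplex group so the group connectivity
    holds in the truth), and the structure is compacted to the
    radius-of-gyration target by shrink-and-repair relaxation under the
    connectivity and excluded-volume constraints.  For a dimer, copy 1 is
    the image under a two-fold rotation placed so the copies just touch.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sequences = {
        name: make_site_sequence(n, spec.site_period)
        for name, n in spec.lengths.items()
    }
    names = list(sequences)

    # per-copy chain layout
    chains = {
        name: build_beads(sequences[name], spec.granularity, component=name)
        for name in names
    }
    radii = np.concatenate([[b.radius for b in chains[n]] for n in names])
    chain_id = np.concatenate(
        [[i] * len(chains[n]) for i, n in enumerate(names)]
    )
    pos_id = np.concatenate([np.arange(len(chains[n])) for n in names])
    adjacent = (chain_id[:, None] == chain_id[None, :]) & (
        np.abs(pos_id[:, None] - pos_id[None, :]) == 1
    )
    n_beads = len(radii)

    group_of = {}
    for g, group in enumerate(spec.subcomplex_groups):
        for name in group:
            group_of[name] = g

    coords = np.zeros((n_beads, 3))
    placed: list[int] = []
    placed_by_comp: dict[str, list[int]] = {}
    cursor = 0
    for name in names:
        nb = len(chains[name])
        idx = list(range(cursor, cursor + nb))
        # anchor bead
        if not placed:
            coords[idx[0]] = 0.0
        else:
            anchor_pool = placed
            g = group_of.get(name)
            if g is not None:
                mates = [
                    i
                    for other, lst in placed_by_comp.items()
                    if group_of.get(other) == g
                    for i in lst
                ]
                if mates:
                    anchor_pool = mates
            anchor = anchor_pool[rng.integers(0, len(anchor_pool))]
            coords[idx[0]] = _grow_position(
                coords, radii, placed, anchor, idx[0], rng, bias=spec.growth_bias
            )
        placed.append(idx[0])
        for k in range(1, nb):
            coords[idx[k]] = _grow_position(
                coords, radii, placed, idx[k - 1], idx[k], rng,
                adjacent_ok=idx[k - 1], bias=spec.growth_bias,
            )
            placed.append(idx[k])
        placed_by_comp[name] = idx
        cursor += nb

    # compaction
    r_mean = float(radii.mean())
    target = spec.rg_target
    if target is None:
        target = 0.95 * r_mean * (n_beads / 0.6) ** (1.0 / 3.0)
    converged = False
    for _ in range(400):
        centroid = coords.mean(axis=0)
        rg = float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))
        if rg <= target:
            converged = _repair(coords, radii, adjacent)
            if converged:
                break
        coords = centroid + (coords - centroid) * 0.97
        if not _repair(coords, radii, adjacent, max_sweeps=200):
            continue
    if not converged:
        centroid = coords.mean(axis=0)
        rg = float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))
        raise RuntimeError(
            f"compactness target Rg <= {target:.1f} Å infeasible "
            f"(reached {rg:.1f} Å)"
        )
    coords -= coords.mean(axis=0)

    symmetry = None
    if spec.copy_count == 2:
        # C2 about z, copies separated along x so they just touch
        rot = np.diag([-1.0, -1.0, 1.0])
        copy1 = coords @ rot.T
        for dx in np.arange(0.0, 1000.0, 0.5):
            trial = copy1 + np.array([dx, 0.0, 0.0])
            d = np.linalg.norm(coords[:, None, :] - trial[None, :, :], axis=-1)
            s = d - radii[:, None] - radii[None, :]
            if s.min() >= 0.2:
                break
        else:
            raise RuntimeError("could not place the symmetric copy")
        symmetry = RigidTransform(rot, np.array([dx, 0.0, 0.0]))

    topology = AssemblyTopology(
        sequences=sequences,
        copy_count=spec.copy_count,
        granularity=spec.granularity,
        symmetry=symmetry,
        subcomplex_groups=[list(g) for g in spec.subcomplex_groups],
    )
    assembly = build_assembly(topology)
    full = np.vstack([coords] + ([topology.symmetry.apply(coords)] if spec.copy_count == 2 else []))
    assembly.set_coords(full)
    return ToyAssembly(spec=spec, topology=topology, assembly=assembly, coords=full)


def _grow_position(
    coords, radii, placed, anchor, new, rng, adjacent_ok=None, n_tries=300,
    bias=0.0,
):
    """Random position touching the anchor bead, avoiding overlaps.

    A positive ``bias`` skews growth directions toward +x, producing an
    elongated rather than globular chain.
    """
    bond = radii[anchor] + radii[new]
    best = None
    best_clearance = -np.inf
    others = [i for i in placed if i != anchor and i != adjacent_ok]
    other_idx = np.array(others, dtype=int) if others else None
    for _ in range(n_tries):
        v = rng.standard_normal(3)
        v[0] += bias
        v /= np.linalg.norm(v)
        cand = coords[anchor] + bond * v
        if other_idx is None:
            return cand
        d = np.linalg.norm(coords[other_idx] - cand, axis=1)
        clearance = float((d - radii[other_idx] - radii[new]).min())
        if clearance >= -0.2:
            return cand
        if clearance > best_clearance:
            best_clearance = clearance
            best = cand
    return best


# ---------------------------------------------------------------------------
# simulated observations


def all_sites(toy: ToyAssembly) -> list[tuple[str, int]]:
    return [
        (name, pos)
        for name, seq in toy.sequences.items()
        for pos in lysine_sites(seq)
    ]


def simulate_crosslinks(
    toy: ToyAssembly,
    d_true: float = 5.0,
    p_det: float = 0.7,
    f_decoy: float = 0.01,
    seed: int = 0,
    q_value: float = 0.001,
) -> SimulatedDataset:
    """Simulate cross-link detection from the ground truth.

    Every site pair whose true minimum ambiguous surface distance is within
    ``d_true`` Å is observed with probability ``p_det``; afterwards
    ``ceil(f_decoy * n_true)`` uniformly random site pairs are appended as
    decoys (worst-case contamination: not distance weighted).  All records
    get the same q-value and are order-normalized and deduplicated.
    """
    if not (0.0 <= p_det <= 1.0 and 0.0 <= f_decoy <= 1.0 and d_true > 0):
        raise ValueError("invalid simulation parameters")
    rng = np.random.default_rng(seed)
    sites = all_sites(toy)
    if len(sites) < 2:
        raise ValueError("no eligible site pairs")
    observed: dict[tuple, CrossLinkRecord] = {}
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            (pa, ra), (pb, rb) = sites[i], sites[j]
            rec = CrossLinkRecord(pa, ra, pb, rb, q_value).normalized()
            s = min_crosslink_surface_distance(rec, toy.assembly, toy.coords)
            if s <= d_true and rng.random() < p_det:
                observed[rec.udr_key] = rec
    n_true = len(observed)
    if n_true == 0:
        raise ValueError("no site pair is observable at the given span")
    n_decoy = math.ceil(f_decoy * n_true)
    decoy_keys: set[tuple] = set()
    guard = 0
    while len(decoy_keys) < n_decoy:
        guard += 1
        if guard > 100 * n_decoy + 1000:
            raise RuntimeError("could not draw enough distinct decoy pairs")
        i, j = rng.integers(0, len(sites), size=2)
        if i == j:
            continue
        (pa, ra), (pb, rb) = sites[i], sites[j]
        rec = CrossLinkRecord(pa, ra, pb, rb, q_value).normalized()
        if rec.udr_key in observed or rec.udr_key in decoy_keys:
            continue
        decoy_keys.add(rec.udr_key)
        observed[rec.udr_key] = rec
    records = sorted(observed.values())
    return SimulatedDataset(
        crosslinks=records,
        decoy_keys=decoy_keys,
        params={
            "d_true": d_true,
            "p_det": p_det,
            "f_decoy": f_decoy,
            "seed": seed,
            "n_true": n_true,
            "n_decoy": n_decoy,
        },
    )


def simulate_monolinks(
    toy: ToyAssembly, p_det: float = 0.8, seed: int = 0, q_value: float = 0.001
) -> list[MonoLinkRecord]:
    """Each reactive site is seen as a mono-link with probability p_det."""
    rng = np.random.default_rng(seed)
    return [
        MonoLinkRecord(name, pos, q_value)
        for (name, pos) in all_sites(toy)
        if rng.random() < p_det
    ]


def derive_bounding_boxes(
    toy: ToyAssembly, pad: float = 20.0, subset: list[str] | None = None
) -> dict[str, Box]:
    """Axis-aligned boxes around each component's true centres, padded.

    The box of a component spans its copy-0 true bead centres (boxes act on
    copy 0; the symmetric copy is localized through the transform),
    expanded by ``pad`` Å on every face — deliberately loose, emulating
    localization data that is coarser than the structure itself.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    names = subset if subset is not None else list(toy.sequences)
    boxes = {}
    for name in names:
        sl = toy.assembly.chain_slice(name, 0)
        pts = toy.coords[sl]
        boxes[name] = Box(pts.min(axis=0) - pad, pts.max(axis=0) + pad)
    return boxes


# ---------------------------------------------------------------------------
# planted docking pose


def simulate_tubulin_xls(
    toy: ToyAssembly,
    lattice,
    d_true: float = 5.0,
    gap: float = 0.5,
    align: bool = True,
    p_det: float = 1.0,
    seed: int = 0,
):
    """Plant the complex on the lattice surface and read off the contacts.

    The complex (in its true conformation) is planted lying flat over the
    interior of the lattice patch: its longest principal axis along the
    lateral (x) direction, its shortest along the surface normal (y), so
    the whole elongated face contacts the surface — the canonical
    perpendicular arrangement.  It is lowered onto the +y surface until the
    closest surfaces are ``gap`` Å apart; every (complex site, tubulin
    site) pair within ``d_true`` Å then yields a tubulin cross-link record.
    Each eligible pair is observed with probability ``p_det``.  Returns
    the records, the planted complex coordinates and the rigid transform
    mapping the truth frame to the planted frame (the lattice stays in its
    template pose).
    """
    from .docking import TubulinXLRecord

    rng = np.random.default_rng(seed)
    interior_centres = np.array(
        [s["centre"] for s in lattice.subunits if s["interior"]]
    )
    target = interior_centres.mean(axis=0)
    centroid = toy.coords.mean(axis=0)
    if align:
        centred = toy.coords - centroid
        cov = centred.T @ centred / len(centred)
        evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
        # rows: new x <- largest axis, new y <- smallest, new z <- middle
        M = np.vstack([evecs[:, 2], evecs[:, 0], evecs[:, 1]])
        if np.linalg.det(M) < 0:
            M[2] = -M[2]
    else:
        M = np.eye(3)
    pts = (toy.coords - centroid) @ M.T
    lat = lattice.coords_template
    lat_top = float((lat[:, 1] + lattice.radii).max())
    comp_bottom = float((pts[:, 1] - toy.assembly.radii).min())
    shift = np.array(
        [target[0], lat_top + gap - comp_bottom, target[2]]
    )
    planted = pts + shift
    plant_transform = RigidTransform(M, shift - M @ centroid)

    records = set()
    tub_sites = {
        iso: lysine_sites(seq) for iso, seq in lattice.sequences.items()
    }
    for sub in lattice.subunits:
        if not sub["interior"]:
            continue
        iso = sub["isoform"]
        for tpos in tub_sites[iso]:
            tb = sub["bead_start"] + lattice.residue_bead_offset(iso, tpos)
            for name, seq in toy.sequences.items():
                for cpos in lysine_sites(seq):
                    for copy in range(toy.topology.copy_count):
                        cb = toy.assembly.bead_index(name, cpos, copy)
                        s = (
                            float(np.linalg.norm(planted[cb] - lat[tb]))
                            - toy.assembly.radii[cb]
                            - lattice.radii[tb]
                        )
                        if s <= d_true:
                            records.add(TubulinXLRecord(name, cpos, iso, tpos))
    records = sorted(records)
    if p_det < 1.0:
        records = [r for r in records if rng.random() < p_det]
    return records, planted, plant_transform


# ---------------------------------------------------------------------------
# end-to-end studies


def default_study_spec(seed: int = 0) -> ToyAssemblySpec:
    """The reference synthetic study: four components, ~40 beads per copy."""
    return ToyAssemblySpec(
        lengths={"P1": 140, "P2": 120, "P3": 80, "P4": 60},
        granularity=10,
        copy_count=2,
        seed=seed,
    )


def recovery_study(
    seed: int = 0,
    n_steps: int = 2_000_000,
    n_replicas: int = 8,
    d_true: float = 5.0,
    p_det: float = 0.7,
    f_decoy: float = 0.01,
    box_pad: float = 20.0,
    boxed_components: tuple[str, ...] = ("P1", "P2"),
    top_n_keep: int = 1000,
    cluster_cutoff: float = 17.0,
    satisfaction_cutoff: float = 10.0,
    contact_cutoff: float = 5.0,
    spec: ToyAssemblySpec | None = None,
) -> dict:
    """Full parameter-recovery study against a synthetic ground truth.

    Generates a toy dimer, simulates cross-links (detection probability,
    observable span, decoy contamination), boxes half the components, runs
    parallel-tempering sampling, clusters the top models, and measures how
    well the cluster-centre model recovers the truth: satisfaction of the
    true (non-decoy) UDRs at the fit cutoff, satisfaction of the decoys,
    and the recovered fraction of true protein-pair contacts.
    """
    ss = np.random.SeedSequence(seed)
    toy_seed, xl_seed, run_seed = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
    ]
    if spec is None:
        spec = default_study_spec(toy_seed)
    toy = generate_toy_assembly(spec)
    ds = simulate_crosslinks(
        toy, d_true=d_true, p_det=p_det, f_decoy=f_decoy, seed=xl_seed
    )
    boxes = derive_bounding_boxes(
        toy, pad=box_pad, subset=[c for c in boxed_components if c in toy.sequences]
    )
    topology = dataclasses.replace(toy.topology, bounding_boxes=boxes)
    restraints = RestraintSet(crosslinks=ds.crosslinks)
    config = SamplerConfig(
        n_replicas=n_replicas,
        n_steps=n_steps,
        seed=run_seed,
        top_n_keep=top_n_keep,
    )
    ensemble = run_sampling(topology, restraints, config)
    clusters = daura_cluster(ensemble, cluster_cutoff)
    centre = ensemble[clusters.centers[0]].coords
    model = build_assembly(topology)
    model.set_coords(centre)

    sat_true = satisfaction_fraction(
        model, ds.true_records, satisfaction_cutoff
    ).fraction
    sat_decoy = (
        satisfaction_fraction(model, ds.decoy_records, satisfaction_cutoff).fraction
        if ds.decoy_records
        else float("nan")
    )
    cm_truth = contact_map(toy.assembly, contact_cutoff, coords=toy.coords)
    cm_model = contact_map(model, contact_cutoff, coords=centre)
    # recovery is scored on protein pairs irrespective of the monomer
    # assignment: for components without localization boxes the intra- vs
    # inter-monomer placement of an interface is exactly degenerate under
    # the ambiguous restraints and the two-fold symmetry
    truth_pairs = {(a, b) for (a, b, _kind) in cm_truth.protein_pairs}
    model_pairs = {(a, b) for (a, b, _kind) in cm_model.protein_pairs}
    contact_recovery = (
        len(truth_pairs & model_pairs) / len(truth_pairs) if truth_pairs else float("nan")
    )
    return {
        "seed": seed,
        "n_udrs": len(ds.crosslinks),
        "n_true_udrs": len(ds.true_records),
        "n_decoys": len(ds.decoy_records),
        "best_score": float(ensemble.best.score),
        "n_clusters": clusters.n_clusters,
        "true_satisfaction": float(sat_true),
        "decoy_satisfaction": float(sat_decoy),
        "contact_recovery": float(contact_recovery),
        "ensemble": ensemble,
        "toy": toy,
        "dataset": ds,
        "topology": topology,
        "centre_coords": centre,
    }



def elongated_rod_dimer(granularity: int = 10) -> ToyAssembly:
    """Deterministic flat-bottomed rod dimer for docking studies.

    Two hairpin-folded chains stacked into a flat rod (all beads in one
    plane, so the whole face can contact a lattice), dimerized by a
    two-fold rotation into a ~220 Å long particle — elongated relative to
    the lattice patch, like the real dimer against its binding site.  No
    randomness: the docking studies draw their variability from the
    simulated observations and the sampling, not from the ground truth.
    """
    from .representation import bead_radius

    r = bead_radius(granularity)
    d = 2.0 * r
    lengths = {"D1": 16 * granularity, "D2": 8 * granularity}
    sequences = {
        name: make_site_sequence(n) for name, n in lengths.items()
    }
    pos = []
    # D1: hairpin, two rows of 8 along x
    for i in range(8):
        pos.append([i * d, 0.0, 0.0])
    for i in range(8):
        pos.append([(7 - i) * d, 0.0, d])
    # D2: hairpin, two rows of 4, stacked on D1 in z
    for i in range(4):
        pos.append([(i + 2) * d, 0.0, 2 * d])
    for i in range(4):
        pos.append([(5 - i) * d, 0.0, 3 * d])
    coords0 = np.array(pos)

    rot = np.diag([-1.0, -1.0, 1.0])
    tx = 14 * d + 2 * r + 0.5
    symmetry = RigidTransform(rot, np.array([tx, 0.0, 0.0]))
    topology = AssemblyTopology(
        sequences=sequences,
        copy_count=2,
        granularity=granularity,
        symmetry=symmetry,
    )
    assembly = build_assembly(topology)
    full = np.vstack([coords0, symmetry.apply(coords0)])
    assembly.set_coords(full)
    spec = ToyAssemblySpec(lengths=lengths, granularity=granularity)
    return ToyAssembly(spec=spec, topology=topology, assembly=assembly, coords=full)


def docking_recovery_study(
    seed: int = 0,
    stage1_steps: int = 240_000,
    stage2_steps: int = 60_000,
    n_replicas: int = 8,
    tubulin_length: int = 150,
    d_true: float = 5.0,
    tubulin_span: float = 10.0,
    fit_cutoff: float = 10.0,
) -> dict:
    """Planted-pose docking recovery on a small synthetic system.

    A two-component toy dimer is planted on a toy tubulin lattice; the
    resulting tubulin cross-links (no decoys) are handed to the two-stage
    flexible docking, and success means every planted restraint is fit and
    the recovered orientation class matches the planted (perpendicular)
    arrangement.  Tubulin cross-links are simulated at the 10 Å fit span
    (the modelling restraint bound of 5 Å is deliberately tighter, as in
    the free-complex protocol), which yields a planted dataset of roughly
    ten restraints — about the density of a real complex-to-tubulin
    dataset on this reduced system size.
    """
    from .docking import DockingConfig, build_lattice, dock_flexible

    ss = np.random.SeedSequence(seed)
    xl_seed, dock_seed = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)
    ]
    # a deterministic elongated dimer: long against the finite lattice
    # patch, flat-bottomed so planted contacts spread over its full length
    toy = elongated_rod_dimer()
    ds = simulate_crosslinks(toy, d_true=d_true, p_det=0.9, f_decoy=0.0, seed=xl_seed)

    # distinct isoforms whose different lengths (hence bead layouts and
    # site patterns) carry the lattice polarity signal, as in real tubulin.
    # Subunit size matters: orientation is identifiable only when the
    # lattice features (subunit extent, same-isoform repeat) are large
    # against the ~20 Å ambiguity reach of a single restraint, as they are
    # for real tubulin monomers
    alpha = make_site_sequence(tubulin_length, period=4)
    beta = make_site_sequence(max(tubulin_length - 10, 10), period=4)
    sub_beads = build_beads(alpha, 10)
    extent = 2.0 * max(b.radius for b in sub_beads) * math.ceil(
        len(sub_beads) ** (1 / 3)
    )
    lattice = build_lattice(
        alpha,
        beta,
        # anisotropic spacings, mimicking the microtubule lattice where the
        # same-isoform repeat differs along and across protofilaments
        lateral_spacing=extent + 11.0,
        axial_spacing=extent + 2.0,
    )
    txls, planted, plant = simulate_tubulin_xls(
        toy, lattice, d_true=tubulin_span, p_det=0.15, seed=xl_seed
    )

    # express the localization boxes and the symmetry transform in the
    # planted frame: for the frame map A(x) = Mx + b the dimer symmetry T
    # becomes A T A^-1
    boxes = {}
    for name in toy.sequences:
        sl = toy.assembly.chain_slice(name, 0)
        pts = planted[sl]
        boxes[name] = Box(pts.min(axis=0) - 5.0, pts.max(axis=0) + 5.0)
    sym = toy.topology.symmetry
    M, b = plant.rotation, plant.translation
    rot_p = M @ sym.rotation @ M.T
    sym_planted = RigidTransform(rot_p, M @ sym.translation + b - rot_p @ b)
    topology = dataclasses.replace(
        toy.topology, bounding_boxes=boxes, symmetry=sym_planted
    )
    restraints = RestraintSet(crosslinks=ds.crosslinks)
    config = DockingConfig(
        stage1_steps=stage1_steps,
        stage2_steps=stage2_steps,
        n_replicas=n_replicas,
        seed=dock_seed,
        fit_cutoff=fit_cutoff,
        # restrain the synthetic tubulin links at the span they were
        # generated with, so the planted pose is a true optimum
        txl_bound=tubulin_span,
    )
    result = dock_flexible(
        topology, restraints, planted, lattice, txls, config=config
    )
    from .docking import classify_orientation

    planted_orientation = classify_orientation(
        planted, lattice.protofilament_axis()
    )
    return {
        "seed": seed,
        "n_tubulin_xls": len(txls),
        "result": result,
        "txl_satisfaction": result.txl_satisfaction,
        "orientation_class": result.orientation["class"],
        "planted_class": planted_orientation["class"],
        "recovered": (
            result.txl_satisfaction == 1.0
            and result.orientation["class"] == planted_orientation["class"]
        ),
    }
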