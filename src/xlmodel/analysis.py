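"""Post-sampling analysis of model ensembles.

Clustering (greedy neighbour-count algorithm with an RMSD cutoff),
per-bead localization densities and their half-maximum variability,
cross-link satisfaction, bead/protein/macro-region contact maps, and
jackknife validation by restraint subsampling.

The pairwise distance between models is the bead-centre RMSD after optimal
least-squares rigid superposition over all beads (no chain relabelling:
the symmetric copy is a constraint, not a free permutation).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist

from .io import CrossLinkRecord
from .representation import Assembly, AssemblyTopology
from .restraints import RestraintSet, min_crosslink_surface_distance
from .sampler import Ensemble, SamplerConfig, run_sampling

__all__ = [
    "ClusterResult",
    "DensityMap",
    "SatisfactionReport",
    "ContactMap",
    "JackknifeReport",
    "kabsch_superpose",
    "pairwise_rmsd",
    "daura_cluster",
    "compute_density",
    "bead_variability",
    "satisfaction_fraction",
    "macro_regions",
    "contact_map",
    "macro_region_compare",
    "jackknife_validate",
]


# ---------------------------------------------------------------------------
# superposition / RMSD


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    H = mob_c.T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return mob_c @ R.T + reference.mean(axis=0)


def pairwise_rmsd(stack: np.ndarray) -> np.ndarray:
    """All-pairs minimal RMSD matrix over a stack of (M, N, 3) models.

    Uses the closed form rmsd² = (tr(A) + tr(B) - 2(σ1 + σ2 ± σ3)) / N from
    the singular values of the pairwise cross-covariance, evaluated with
    batched SVDs.
    """
    stack = np.asarray(stack, dtype=float)
    m, n, _ = stack.shape
    centred = stack - stack.mean(axis=1, keepdims=True)
    sq = np.einsum("mij,mij->m", centred, centred)
    cross = np.einsum("aik,bil->abkl", centred, centred)
    s = np.linalg.svd(cross, compute_uv=False)
    det = np.linalg.det(cross)
    sign = np.where(det < 0, -1.0, 1.0)
    trace = s[..., 0] + s[..., 1] + sign * s[..., 2]
    rmsd2 = (sq[:, None] + sq[None, :] - 2.0 * trace) / n
    rmsd2 = np.maximum(rmsd2, 0.0)
    out = np.sqrt(rmsd2)
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    labels: np.ndarray          # cluster id per ensemble member
    centers: list[int]          # ensemble index of each cluster centre
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def daura_cluster(
    ensemble: Ensemble | np.ndarray,
    cutoff: float,
    scores: np.ndarray | None = None,
    rmsd: np.ndarray | None = None,
) -> ClusterResult:
    """Greedy neighbour-count clustering with an RMSD cutoff.

    Iteratively pick the structure with the most neighbours within
    ``cutoff``, form a cluster from it and its neighbours, remove them, and
    repeat.  Ties go to the lowest-score, then lowest-index structure.
    """
    if isinstance(ensemble, Ensemble):
        if len(ensemble) == 0:
            raise ValueError("cannot cluster an empty ensemble")
        stack = ensemble.coords_stack()
        if scores is None:
            scores = ensemble.scores
    else:
        stack = np.asarray(ensemble)
        if stack.ndim != 3 or len(stack) == 0:
            raise ValueError("need a non-empty (M, N, 3) coordinate stack")
    m = len(stack)
    if scores is None:
        scores = np.zeros(m)
    if rmsd is None:
        rmsd = pairwise_rmsd(stack)
    neighbours = rmsd <= cutoff
    np.fill_diagonal(neighbours, True)

    labels = np.full(m, -1, dtype=int)
    centers: list[int] = []
    remaining = np.ones(m, dtype=bool)
    order = np.lexsort((np.arange(m), scores))  # tie-break: score, then index
    while remaining.any():
        counts = (neighbours & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        best_count = counts.max()
        centre = next(i for i in order if counts[i] == best_count)
        cluster_members = neighbours[centre] & remaining
        cid = len(centers)
        labels[cluster_members] = cid
        centers.append(int(centre))
        remaining &= ~cluster_members
    return ClusterResult(labels=labels, centers=centers, cutoff=cutoff)


# ---------------------------------------------------------------------------
# densities


@dataclass
class DensityMap:
    """Per-bead occupancy histograms of an aligned ensemble on a common grid.

    Each bead's histogram is normalized to 1.  Voxels are stored sparsely:
    ``indices[b]`` is a (k, 3) integer array and ``values[b]`` the matching
    probabilities.
    """

    origin: np.ndarray
    bin_size: float
    shape: tuple[int, int, int]
    indices: list[np.ndarray]
    values: list[np.ndarray]

    @property
    def n_beads(self) -> int:
        return len(self.indices)

    def voxel_centres(self, bead: int) -> np.ndarray:
        return self.origin + (self.indices[bead] + 0.5) * self.bin_size

    def bead_grid(self, bead: int) -> np.ndarray:
        grid = np.zeros(self.shape)
        idx = self.indices[bead]
        grid[idx[:, 0], idx[:, 1], idx[:, 2]] = self.values[bead]
        return grid

    def combined(self) -> np.ndarray:
        """Sum of the per-bead probability maps (expected centres per voxel)."""
        grid = np.zeros(self.shape)
        for idx, val in zip(self.indices, self.values):
            np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), val)
        return grid


def compute_density(
    ensemble: Ensemble | np.ndarray,
    reference: np.ndarray | None = None,
    bin_size: float = 2.0,
    align: bool = True,
) -> DensityMap:
    """Per-bead 3D occupancy histograms over an ensemble.

    Models are superposed onto ``reference`` (default: the first model)
    before binning; each bead's histogram is normalized to 1.
    """
    stack = ensemble.coords_stack() if isinstance(ensemble, Ensemble) else np.asarray(ensemble, dtype=float)
    if stack.ndim != 3 or len(stack) == 0:
        raise ValueError("need a non-empty (M, N, 3) coordinate stack")
    if bin_size <= 0:
        raise ValueError("bin size must be > 0")
    if reference is None:
        reference = stack[0]
    if align:
        stack = np.stack([kabsch_superpose(m, reference) for m in stack])
    lo = stack.reshape(-1, 3).min(axis=0)
    hi = stack.reshape(-1, 3).max(axis=0)
    origin = np.floor(lo / bin_size) * bin_size - bin_size
    shape = tuple((np.ceil((hi - origin) / bin_size).astype(int) + 1).tolist())
    n_models, n_beads, _ = stack.shape
    indices, values = [], []
    vox = np.floor((stack - origin) / bin_size).astype(int)  # (M, N, 3)
    for b in range(n_beads):
        uniq, counts = np.unique(vox[:, b, :], axis=0, return_counts=True)
        indices.append(uniq)
        values.append(counts / n_models)
    return DensityMap(
        origin=origin, bin_size=bin_size, shape=shape, indices=indices, values=values
    )


def bead_variability(
    density: DensityMap, threshold: float = 3.0
) -> tuple[np.ndarray, float]:
    """Per-bead spatial extent at half-maximum density.

    The extent of a bead is the maximum pairwise distance between centres of
    voxels whose probability is at least half that bead's maximum (0 for a
    single voxel).  Returns the per-bead extents and the fraction of beads
    with extent <= ``threshold`` Å.
    """
    extents = np.zeros(density.n_beads)
    for b in range(density.n_beads):
        vals = density.values[b]
        sel = vals >= 0.5 * vals.max()
        pts = density.voxel_centres(b)[sel]
        if len(pts) > 1:
            extents[b] = float(pdist(pts).max())
    fraction = float(np.mean(extents <= threshold))
    return extents, fraction


# ---------------------------------------------------------------------------
# satisfaction


@dataclass
class SatisfactionReport:
    satisfied: dict[tuple, bool]
    fraction: float
    cutoff: float
    distances: dict[tuple, float] = field(default_factory=dict)


def satisfaction_fraction(
    assembly: Assembly,
    udrs: list[CrossLinkRecord],
    cutoff: float = 10.0,
    coords: np.ndarray | None = None,
) -> SatisfactionReport:
    """Fraction of UDRs whose minimum ambiguous surface distance <= cutoff.

    A restraint is a fit when the surfaces of the two beads holding the
    cross-linked residues are within ``cutoff`` Å in the best ambiguous
    (intra- or inter-copy) assignment.
    """
    if not udrs:
        raise ValueError("satisfaction fraction is undefined for an empty UDR set")
    satisfied: dict[tuple, bool] = {}
    distances: dict[tuple, float] = {}
    for rec in udrs:
        try:
            s = min_crosslink_surface_distance(rec, assembly, coords)
        except KeyError as exc:
            raise KeyError(f"UDR {rec} cannot be mapped onto the assembly") from exc
        key = rec.udr_key
        distances[key] = float(s)
        satisfied[key] = bool(s <= cutoff)
    fraction = sum(satisfied.values()) / len(satisfied)
    return SatisfactionReport(
        satisfied=satisfied, fraction=float(fraction), cutoff=cutoff, distances=distances
    )


# ---------------------------------------------------------------------------
# contacts / macro-regions


def macro_regions(length: int, target: int = 100) -> list[tuple[str, int, int]]:
    """Partition a sequence into ~``target``-residue macro-regions.

    Returns (label, first_res, last_res) per region (1-based, inclusive).
    A protein under 1.5x the target is a single region; three regions are
    labelled N/M/C, two N/C, more N/M1../C.  Remainder residues go to the
    C-terminal regions.
    """
    n_regions = max(1, round(length / target))
    base = length // n_regions
    rem = length - base * n_regions
    sizes = [base] * n_regions
    for i in range(rem):
        sizes[n_regions - 1 - i] += 1
    if n_regions == 1:
        labels = [""]
    elif n_regions == 2:
        labels = ["N", "C"]
    elif n_regions == 3:
        labels = ["N", "M", "C"]
    else:
        labels = ["N"] + [f"M{i}" for i in range(1, n_regions - 1)] + ["C"]
    regions = []
    first = 1
    for label, size in zip(labels, sizes):
        regions.append((label, first, first + size - 1))
        first += size
    return regions


@dataclass
class ContactMap:
    """Bead-level contacts of a positioned model, aggregated upward.

    A bead pair is in contact when its surface distance <= ``cutoff``;
    sequence-adjacent pairs are excluded (they touch by construction).
    ``bead_pairs`` holds canonical global bead-index pairs (for a dimer,
    the copy-swapped image of a pair maps to the same canonical key, so
    contact sets are invariant to relabelling the two copies).
    ``protein_pairs`` and ``region_pairs`` count contacts per protein pair
    and per macro-region pair, split intra-/inter-monomer.
    """

    cutoff: float
    bead_pairs: set[tuple[int, int]]
    protein_pairs: Counter
    region_pairs: Counter
    topology_tag: tuple = ()

    @property
    def n_contacts(self) -> int:
        return len(self.bead_pairs)


def _canonical_pair(i: int, j: int, n_per_copy: int, n_copies: int) -> tuple[int, int]:
    a = tuple(sorted((i, j)))
    if n_copies != 2:
        return a
    total = 2 * n_per_copy
    b = tuple(sorted(((i + n_per_copy) % total, (j + n_per_copy) % total)))
    return min(a, b)


def contact_map(
    assembly: Assembly,
    cutoff: float = 5.0,
    coords: np.ndarray | None = None,
    region_target: int = 100,
) -> ContactMap:
    """All bead-pair contacts of a model (surface distance <= cutoff)."""
    if coords is None:
        coords = assembly.coords
    coords = np.asarray(coords, dtype=float)
    top = assembly.topology
    n = assembly.n_beads
    diff = coords[:, None, :] - coords[None, :, :]
    s = np.linalg.norm(diff, axis=-1) - assembly.radii[:, None] - assembly.radii[None, :]
    in_contact = s <= cutoff
    adjacent = (assembly.chain_of[:, None] == assembly.chain_of[None, :]) & (
        np.abs(assembly.pos_in_chain[:, None] - assembly.pos_in_chain[None, :]) == 1
    )
    in_contact &= ~adjacent
    iu, ju = np.triu_indices(n, 1)
    mask = in_contact[iu, ju]
    region_of = {
        name: macro_regions(len(seq), region_target)
        for name, seq in top.sequences.items()
    }

    def region_label(name: str, residue: int) -> str:
        for label, first, last in region_of[name]:
            if first <= residue <= last:
                return label
        raise AssertionError("residue outside its own sequence")

    bead_pairs: set[tuple[int, int]] = set()
    protein_pairs: Counter = Counter()
    region_pairs: Counter = Counter()
    for i, j in zip(iu[mask], ju[mask]):
        bead_pairs.add(
            _canonical_pair(int(i), int(j), assembly.n_per_copy, top.copy_count)
        )
        bi, bj = assembly.beads[i], assembly.beads[j]
        kind = "intra" if bi.copy == bj.copy else "inter"
        pa = (bi.component, region_label(bi.component, bi.first_res))
        pb = (bj.component, region_label(bj.component, bj.first_res))
        if (pb[0], pb[1]) < (pa[0], pa[1]):
            pa, pb = pb, pa
        prot_key = tuple(sorted((bi.component, bj.component))) + (kind,)
        protein_pairs[prot_key] += 1
        region_pairs[(pa, pb, kind)] += 1
    tag = (
        tuple(sorted(top.sequences)),
        top.copy_count,
        top.granularity,
        region_target,
    )
    return ContactMap(
        cutoff=cutoff,
        bead_pairs=bead_pairs,
        protein_pairs=protein_pairs,
        region_pairs=region_pairs,
        topology_tag=tag,
    )


def macro_region_compare(map_a: ContactMap, map_b: ContactMap) -> dict:
    """Differential macro-region interaction table between two conditions.

    Per macro-region pair: contact counts in A and B and a classification
    (shared / lost in B / gained in B).
    """
    if map_a.topology_tag != map_b.topology_tag:
        raise ValueError("contact maps were built on different topologies")
    keys = sorted(set(map_a.region_pairs) | set(map_b.region_pairs))
    table = {}
    n_shared = n_gained = n_lost = 0
    for key in keys:
        ca = map_a.region_pairs.get(key, 0)
        cb = map_b.region_pairs.get(key, 0)
        if ca and cb:
            status = "shared"
            n_shared += 1
        elif ca:
            status = "lost"
            n_lost += 1
        else:
            status = "gained"
            n_gained += 1
        (pa, pb, kind) = key
        table[key] = {
            "region_a": f"{pa[0]}{pa[1]}",
            "region_b": f"{pb[0]}{pb[1]}",
            "kind": kind,
            "count_a": int(ca),
            "count_b": int(cb),
            "status": status,
        }
    return {
        "pairs": table,
        "n_shared": n_shared,
        "n_gained": n_gained,
        "n_lost": n_lost,
    }


# ---------------------------------------------------------------------------
# jackknife


@dataclass
class JackknifeReport:
    conserved_fractions: list[float]
    subset_fraction: float
    n_subsets: int
    seed: int
    subset_sizes: list[int]


def cluster_centre_model(
    topology: AssemblyTopology,
    restraints: RestraintSet,
    config: SamplerConfig,
    cluster_cutoff: float = 17.0,
) -> tuple[Assembly, np.ndarray, Ensemble]:
    """Sample, cluster, and return the top cluster's centre model."""
    from .representation import build_assembly

    ensemble = run_sampling(topology, restraints, config)
    clusters = daura_cluster(ensemble, cluster_cutoff)
    centre = ensemble[clusters.centers[0]].coords
    assembly = build_assembly(topology)
    assembly.set_coords(centre)
    return assembly, centre, ensemble


def jackknife_validate(
    topology: AssemblyTopology,
    restraints: RestraintSet,
    udrs: list[CrossLinkRecord],
    fraction: float = 0.95,
    n_subsets: int = 3,
    seed: int = 0,
    config: SamplerConfig | None = None,
    contact_cutoff: float = 5.0,
    cluster_cutoff: float = 17.0,
) -> JackknifeReport:
    """Remodel with random restraint subsets; measure contact conservation.

    For each subset a ``fraction`` of the UDRs is drawn without replacement,
    the modelling is rerun, and the conserved-interaction fraction is the
    share of the full-data cluster-centre model's bead contacts recovered by
    the subset model's cluster centre.  ``fraction = 1.0`` reruns the
    identical problem (same seed) and conserves everything exactly.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if config is None:
        config = SamplerConfig()
    full_restraints = replace(restraints, crosslinks=list(udrs))
    full_assembly, _, _ = cluster_centre_model(
        topology, full_restraints, config, cluster_cutoff
    )
    full_contacts = contact_map(full_assembly, contact_cutoff).bead_pairs
    if not full_contacts:
        raise ValueError("full-data model has no contacts to conserve")

    ss = np.random.SeedSequence(seed)
    subset_rngs = [np.random.default_rng(c) for c in ss.spawn(n_subsets)]
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_subsets)[n_subsets:]]

    conserved: list[float] = []
    sizes: list[int] = []
    for k in range(n_subsets):
        size = int(round(fraction * len(udrs)))
        if size == len(udrs):
            subset = list(udrs)
            sub_config = config
        else:
            pick = subset_rngs[k].choice(len(udrs), size=size, replace=False)
            subset = [udrs[i] for i in sorted(pick)]
            sub_config = dataclasses.replace(config, seed=run_seeds[k])
        sizes.append(size)
        sub_restraints = replace(restraints, crosslinks=subset)
        sub_assembly, _, _ = cluster_centre_model(
            topology, sub_restraints, sub_config, cluster_cutoff
        )
        sub_contacts = contact_map(sub_assembly, contact_cutoff).bead_pairs
        conserved.append(len(sub_contacts & full_contacts) / len(full_contacts))
    return JackknifeReport(
        conserved_fractions=conserved,
        subset_fraction=fraction,
        n_subsets=n_subsets,
        seed=seed,
        subset_sizes=sizes,
    )
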