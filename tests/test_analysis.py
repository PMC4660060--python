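"""Ensemble analysis: clustering, densities, satisfaction, contacts."""

import dataclasses

import numpy as np
import pytest

from conftest import c2_transform
from xlmodel.analysis import (
    bead_variability,
    compute_density,
    contact_map,
    daura_cluster,
    jackknife_validate,
    kabsch_superpose,
    macro_region_compare,
    macro_regions,
    pairwise_rmsd,
    satisfaction_fraction,
)
from xlmodel.io import CrossLinkRecord
from xlmodel.representation import (
    AssemblyTopology,
    bead_radius,
    build_assembly,
)
from xlmodel.restraints import RestraintSet
from xlmodel.sampler import SamplerConfig
from xlmodel.synthetic import (
    ToyAssemblySpec,
    derive_bounding_boxes,
    generate_toy_assembly,
    simulate_crosslinks,
)

R10 = bead_radius(10)


def daura_oracle(rmsd, cutoff, scores):
    """Greedy neighbour-count clustering, written independently with sets."""
    m = len(rmsd)
    remaining = set(range(m))
    labels = {}
    centers = []
    while remaining:
        best = None
        for i in sorted(remaining, key=lambda i: (scores[i], i)):
            neigh = {j for j in remaining if rmsd[i][j] <= cutoff}
            if best is None or len(neigh) > len(best[1]):
                best = (i, neigh)
        centre, members = best
        for j in members:
            labels[j] = len(centers)
        centers.append(centre)
        remaining -= members
    return labels, centers


class TestRmsd:
    def test_zero_for_identical_and_rigidly_moved(self, rng):
        base = rng.normal(size=(10, 3))
        theta = 0.6
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = base @ rot.T + [4.0, 5.0, -6.0]
        rmsd = pairwise_rmsd(np.stack([base, base, moved]))
        assert np.allclose(rmsd, 0.0, atol=1e-7)

    def test_matches_direct_superposition(self, rng):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        direct = np.sqrt(np.mean(np.sum((kabsch_superpose(a, b) - b) ** 2, axis=1)))
        assert pairwise_rmsd(np.stack([a, b]))[0, 1] == pytest.approx(direct, rel=1e-8)


class TestDauraCluster:
    def test_three_structure_example(self):
        rmsd = np.array(
            [[0.0, 1.0, 30.0], [1.0, 0.0, 30.0], [30.0, 30.0, 0.0]]
        )
        coords = np.zeros((3, 2, 3))
        res = daura_cluster(coords, 17.0, scores=np.zeros(3), rmsd=rmsd)
        assert res.labels.tolist() == [0, 0, 1]
        assert res.centers[0] in (0, 1)

    def test_identical_structures_single_cluster(self, rng):
        coords = np.repeat(rng.normal(size=(1, 5, 3)), 6, axis=0)
        res = daura_cluster(coords, 1.0, scores=np.zeros(6))
        assert res.n_clusters == 1
        assert (res.labels == 0).all()

    def test_zero_cutoff_singletons(self, rng):
        coords = rng.normal(size=(5, 4, 3)) * 50
        res = daura_cluster(coords, 0.0, scores=np.zeros(5))
        assert res.n_clusters == 5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_oracle_on_small_ensembles(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 9))
        d = rng.uniform(0, 30, size=(m, m))
        rmsd = (d + d.T) / 2
        np.fill_diagonal(rmsd, 0.0)
        scores = rng.uniform(size=m)
        cutoff = float(rng.uniform(5, 25))
        res = daura_cluster(np.zeros((m, 2, 3)), cutoff, scores=scores, rmsd=rmsd)
        labels, centers = daura_oracle(rmsd.tolist(), cutoff, scores.tolist())
        assert res.centers == centers
        assert [labels[i] for i in range(m)] == res.labels.tolist()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            daura_cluster(np.zeros((0, 2, 3)), 1.0)


class TestDensity:
    def test_identical_models_single_voxel(self, rng):
        model = rng.normal(size=(6, 3))
        stack = np.repeat(model[None], 100, axis=0)
        dm = compute_density(stack, bin_size=2.0, align=False)
        for b in range(6):
            assert len(dm.values[b]) == 1
            assert dm.values[b][0] == pytest.approx(1.0)

    def test_per_bead_mass_normalized(self, rng):
        stack = rng.normal(scale=5.0, size=(50, 4, 3))
        dm = compute_density(stack, bin_size=2.0, align=False)
        for b in range(4):
            assert dm.values[b].sum() == pytest.approx(1.0)

    def test_variability_single_voxel_zero(self, rng):
        stack = np.repeat(rng.normal(size=(1, 3, 3)), 10, axis=0)
        dm = compute_density(stack, align=False)
        extents, fraction = bead_variability(dm)
        assert extents.tolist() == [0.0, 0.0, 0.0]
        assert fraction == 1.0

    def test_variability_two_equal_voxels(self):
        from xlmodel.analysis import DensityMap

        dm = DensityMap(
            origin=np.zeros(3),
            bin_size=2.0,
            shape=(3, 3, 3),
            indices=[np.array([[0, 0, 0], [1, 0, 0]])],
            values=[np.array([0.5, 0.5])],
        )
        extents, fraction = bead_variability(dm)
        assert extents[0] == pytest.approx(2.0)


class TestSatisfaction:
    @pytest.fixture
    def dimer(self):
        topology = AssemblyTopology(
            sequences={"A": "A" * 20},
            copy_count=2,
            symmetry=c2_transform(200.0),
        )
        return build_assembly(topology)

    def _with_gap(self, dimer, gap):
        coords = np.zeros((4, 3))
        coords[1, 0] = 2 * R10 + gap
        dimer.set_coords(dimer.apply_symmetry(coords))
        return dimer

    @pytest.mark.parametrize("gap,expected", [(9.9, 1.0), (10.1, 0.0)])
    def test_fit_cutoff_boundary(self, dimer, gap, expected):
        dimer = self._with_gap(dimer, gap)
        rec = CrossLinkRecord("A", 5, "A", 15)
        report = satisfaction_fraction(dimer, [rec], cutoff=10.0)
        assert report.fraction == expected

    def test_empty_udr_set_rejected(self, dimer):
        with pytest.raises(ValueError):
            satisfaction_fraction(dimer, [], 10.0)

    def test_self_generated_links_all_fit(self, dimer):
        dimer = self._with_gap(dimer, 2.0)
        recs = [CrossLinkRecord("A", 5, "A", 15)]
        assert satisfaction_fraction(dimer, recs, 10.0).fraction == 1.0

    def test_monotone_in_cutoff(self, dimer, rng):
        coords = rng.normal(scale=25.0, size=(4, 3))
        dimer.set_coords(dimer.apply_symmetry(coords))
        recs = [
            CrossLinkRecord("A", 1, "A", 11),
            CrossLinkRecord("A", 5, "A", 20),
            CrossLinkRecord("A", 11, "A", 20),
        ]
        fractions = [
            satisfaction_fraction(dimer, recs, c).fraction
            for c in (0.0, 5.0, 10.0, 30.0, 100.0)
        ]
        assert fractions == sorted(fractions)


class TestMacroRegions:
    def test_ask1_like_split(self):
        regions = macro_regions(292)
        assert [(lab, last - first + 1) for lab, first, last in regions] == [
            ("N", 97),
            ("M", 97),
            ("C", 98),
        ]

    def test_short_protein_single_region(self):
        assert macro_regions(96) == [("", 1, 96)]

    @pytest.mark.parametrize("length", [50, 100, 151, 292, 343, 1000])
    def test_partition_property(self, length):
        regions = macro_regions(length)
        covered = []
        for _, first, last in regions:
            covered.extend(range(first, last + 1))
        assert covered == list(range(1, length + 1))


class TestContactMap:
    def _two_protein_assembly(self, gap):
        topology = AssemblyTopology(
            sequences={"X": "A" * 10, "Y": "A" * 10}, copy_count=1
        )
        assembly = build_assembly(topology)
        coords = np.zeros((2, 3))
        coords[1, 0] = 2 * R10 + gap
        assembly.set_coords(coords)
        return assembly

    def test_touching_proteins_one_contact(self):
        cm = contact_map(self._two_protein_assembly(0.0), 5.0)
        assert cm.n_contacts == 1
        assert cm.protein_pairs == {("X", "Y", "intra"): 1}

    def test_dispersed_model_empty(self):
        cm = contact_map(self._two_protein_assembly(50.0), 5.0)
        assert cm.n_contacts == 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_counts_match_bruteforce(self, seed):
        from conftest import random_assembly

        assembly = random_assembly((3, 2), seed, copy_count=2, scale=12.0)
        cutoff = 5.0
        cm = contact_map(assembly, cutoff)
        expected = 0
        n = assembly.n_beads
        for i in range(n):
            for j in range(i + 1, n):
                same_chain = assembly.chain_of[i] == assembly.chain_of[j]
                adjacent = same_chain and abs(
                    assembly.pos_in_chain[i] - assembly.pos_in_chain[j]
                ) == 1
                if adjacent:
                    continue
                s = (
                    np.linalg.norm(assembly.coords[i] - assembly.coords[j])
                    - assembly.radii[i]
                    - assembly.radii[j]
                )
                if s <= cutoff:
                    expected += 1
        assert sum(cm.protein_pairs.values()) == expected


class TestMacroRegionCompare:
    def _assembly(self, gap):
        topology = AssemblyTopology(
            sequences={"X": "A" * 10, "Y": "A" * 10}, copy_count=1
        )
        assembly = build_assembly(topology)
        coords = np.zeros((2, 3))
        coords[1, 0] = 2 * R10 + gap
        assembly.set_coords(coords)
        return assembly

    def test_identical_maps_no_changes(self):
        a = contact_map(self._assembly(0.0), 5.0)
        table = macro_region_compare(a, a)
        assert table["n_gained"] == 0 and table["n_lost"] == 0
        assert table["n_shared"] == 1

    def test_pair_only_in_a_is_lost(self):
        a = contact_map(self._assembly(0.0), 5.0)
        b = contact_map(self._assembly(50.0), 5.0)
        table = macro_region_compare(a, b)
        assert table["n_lost"] == 1 and table["n_gained"] == 0

    def test_counts_partition_the_union(self):
        a = contact_map(self._assembly(0.0), 5.0)
        b = contact_map(self._assembly(50.0), 5.0)
        table = macro_region_compare(a, b)
        union = set(a.region_pairs) | set(b.region_pairs)
        assert table["n_shared"] + table["n_gained"] + table["n_lost"] == len(union)

    def test_mismatched_topologies_rejected(self):
        a = contact_map(self._assembly(0.0), 5.0)
        other_top = AssemblyTopology(sequences={"Z": "A" * 10}, copy_count=1)
        other = build_assembly(other_top)
        other.set_coords(np.zeros((1, 3)))
        b = contact_map(other, 5.0)
        with pytest.raises(ValueError):
            macro_region_compare(a, b)


class TestJackknife:
    def test_full_fraction_conserves_everything_exactly(self):
        toy = generate_toy_assembly(
            ToyAssemblySpec(lengths={"A": 80, "B": 60}, seed=4)
        )
        ds = simulate_crosslinks(toy, seed=5, p_det=0.9, f_decoy=0.0)
        topology = dataclasses.replace(
            toy.topology,
            bounding_boxes=derive_bounding_boxes(toy, 20.0, ["A"]),
        )
        config = SamplerConfig(n_replicas=2, n_steps=20_000, seed=6, top_n_keep=50)
        report = jackknife_validate(
            topology,
            RestraintSet(),
            ds.crosslinks,
            fraction=1.0,
            n_subsets=2,
            seed=7,
            config=config,
        )
        assert report.conserved_fractions == [1.0, 1.0]
        assert report.subset_sizes == [len(ds.crosslinks)] * 2

    def test_subset_size_arithmetic(self):
        toy = generate_toy_assembly(
            ToyAssemblySpec(lengths={"A": 80, "B": 60}, seed=4)
        )
        ds = simulate_crosslinks(toy, seed=5, p_det=0.9, f_decoy=0.0)
        topology = dataclasses.replace(
            toy.topology,
            bounding_boxes=derive_bounding_boxes(toy, 20.0, ["A"]),
        )
        config = SamplerConfig(n_replicas=2, n_steps=5_000, seed=6, top_n_keep=20)
        report = jackknife_validate(
            topology, RestraintSet(), ds.crosslinks,
            fraction=0.95, n_subsets=2, seed=8, config=config,
        )
        assert report.subset_sizes == [round(0.95 * len(ds.crosslinks))] * 2
        assert all(0.0 <= f <= 1.0 for f in report.conserved_fractions)
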