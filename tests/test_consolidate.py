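"""Unit and property tests for 2.5D nucleus consolidation."""

import numpy as np
import networkx as nx
import pytest

from axialquant import (
    ConsolidationParams,
    PlaneMask,
    build_link_graph,
    compute_overlap,
    connected_components,
    consolidate,
    extract_features,
    prune_component,
)

from conftest import mask_from_array, params_for, rect_mask, recovered_labels, scene_ari
from oracle_prune import oracle_prune, random_component


def chain_graph(distances, t_typical=3, t_max=6):
    nodes = [(z, 1) for z in range(len(distances) + 1)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, d in enumerate(distances):
        g.add_edge(nodes[i], nodes[i + 1], jaccard_distance=d, overlap_fraction=1.0, intersection_px=1)
    return g, ConsolidationParams(t_typical=t_typical, t_max=t_max)


class TestOverlap:
    def test_identical_masks(self):
        a = rect_mask(0, 1, 0, 0, 5, 5)
        b = rect_mask(1, 1, 0, 0, 5, 5)
        s = compute_overlap(a, b)
        assert s.overlap_fraction == 1.0 and s.jaccard_distance == 0.0

    def test_disjoint_masks(self):
        s = compute_overlap(rect_mask(0, 1, 0, 0, 3, 3), rect_mask(1, 1, 10, 10, 3, 3))
        assert s.overlap_fraction == 0.0 and s.jaccard_distance == 1.0

    def test_partial_overlap_min_denominator(self):
        # areas 100 and 50 intersecting in 25 pixels
        a = rect_mask(0, 1, 0, 0, 10, 10)
        b = rect_mask(1, 1, 5, 5, 5, 10)
        inter = compute_overlap(a, b)
        assert inter.intersection_px == 25
        assert inter.overlap_fraction == pytest.approx(25 / 50)
        assert inter.jaccard_distance == pytest.approx(1 - 25 / 125)

    def test_symmetry(self):
        a = rect_mask(0, 1, 0, 0, 6, 4)
        b = rect_mask(1, 2, 2, 1, 6, 4)
        sa, sb = compute_overlap(a, b), compute_overlap(b, a)
        assert sa == sb

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            PlaneMask(0, 1, np.empty((0, 2), dtype=int))


class TestLinkGraph:
    def test_overlap_threshold_inclusive(self):
        # 100-px masks; lateral shift controls the overlap fraction
        a = rect_mask(0, 1, 0, 0, 10, 10)
        params = ConsolidationParams(t_typical=4, t_max=8, overlap_min=0.30)
        b = rect_mask(1, 1, 0, 7, 10, 10)  # overlap 30/100
        assert compute_overlap(a, b).overlap_fraction == pytest.approx(0.30)
        assert build_link_graph([a, b], params).number_of_edges() == 1  # inclusive
        b_low = rect_mask(1, 1, 0, 8, 10, 10)  # overlap 20/100
        assert build_link_graph([a, b_low], params).number_of_edges() == 0

    def test_no_same_plane_edges(self):
        a = rect_mask(0, 1, 0, 0, 5, 5)
        b = rect_mask(0, 2, 0, 0, 5, 5)  # same plane, full overlap
        g = build_link_graph([a, b], ConsolidationParams(t_typical=4, t_max=8))
        assert g.number_of_edges() == 0

    def test_single_plane_stack(self):
        masks = [rect_mask(0, i, 0, 6 * i, 4, 4) for i in range(1, 4)]
        g = build_link_graph(masks, ConsolidationParams(t_typical=4, t_max=8))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 0

    def test_duplicate_key_rejected(self):
        a = rect_mask(0, 1, 0, 0, 3, 3)
        b = rect_mask(0, 1, 5, 5, 3, 3)
        with pytest.raises(ValueError, match="duplicate"):
            build_link_graph([a, b], ConsolidationParams(t_typical=4, t_max=8))

    def test_plane_gap_option_bridges_missing_plane(self):
        a = rect_mask(0, 1, 0, 0, 6, 6)
        c = rect_mask(2, 1, 0, 0, 6, 6)
        p1 = ConsolidationParams(t_typical=4, t_max=8, max_plane_gap=1)
        p2 = ConsolidationParams(t_typical=4, t_max=8, max_plane_gap=2)
        assert build_link_graph([a, c], p1).number_of_edges() == 0
        assert build_link_graph([a, c], p2).number_of_edges() == 1


class TestComponentsAndPruning:
    def test_connected_components_partition(self):
        g = nx.Graph()
        g.add_edges_from([((0, 1), (1, 1)), ((0, 2), (1, 2))])
        comps = connected_components(g)
        assert sorted(len(c) for c in comps) == [2, 2]
        assert connected_components(nx.Graph()) == []

    def test_chain_components(self):
        g, _ = chain_graph([0.1] * 4)
        assert len(connected_components(g)) == 1

    def test_purge_rule_splits_high_distance_edge(self):
        g, params = chain_graph([0.1, 0.8, 0.1, 0.1], t_typical=3, t_max=6)
        out = prune_component(g, params, np.random.default_rng(0))
        assert sorted(sorted(c.nodes) for c in out) == [
            [(0, 1), (1, 1)],
            [(2, 1), (3, 1), (4, 1)],
        ]

    def test_same_plane_conflict_resolution(self):
        a, b, c, d = (0, 1), (1, 1), (1, 2), (2, 1)
        g = nx.Graph()
        for (u, v), jd in [((a, b), 0.3), ((a, c), 0.5), ((b, d), 0.3), ((c, d), 0.4)]:
            g.add_edge(u, v, jaccard_distance=jd, overlap_fraction=1.0, intersection_px=1)
        out = prune_component(g, ConsolidationParams(t_typical=3, t_max=6), np.random.default_rng(0))
        assert sorted(sorted(cc.nodes) for cc in out) == [[a, b, d], [c]]

    def test_random_rule_is_seeded_and_bounded(self):
        g, params = chain_graph([0.1] * 7, t_typical=3, t_max=6)
        runs = [
            prune_component(g, params, np.random.default_rng(5)) for _ in range(2)
        ]
        parts = [sorted(sorted(c.nodes) for c in run) for run in runs]
        assert parts[0] == parts[1]
        assert all(len(c) <= params.t_max for c in runs[0])

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_literal_oracle(self, seed):
        """Production pruning equals a naive step-by-step re-implementation."""
        rng = np.random.default_rng(seed)
        comp = random_component(rng)
        t_typ = int(rng.integers(1, 7))
        params = ConsolidationParams(t_typical=t_typ, t_max=t_typ + int(rng.integers(0, 5)))
        got = prune_component(comp, params, np.random.default_rng(seed + 1))
        want = oracle_prune(comp, params, np.random.default_rng(seed + 1))
        assert sorted((frozenset(c.nodes) for c in got), key=min) == sorted(want, key=min)


class TestConsolidate:
    def test_single_mask_single_plane(self):
        m = rect_mask(0, 1, 0, 0, 4, 4)
        nuclei = consolidate([m], ConsolidationParams(t_typical=4, t_max=8))
        assert len(nuclei) == 1 and nuclei[0].n_planes == 1

    def test_empty_stack(self):
        assert consolidate([], ConsolidationParams(t_typical=4, t_max=8)) == []

    def test_min_planes_filter(self):
        m = rect_mask(0, 1, 0, 0, 4, 4)
        p = ConsolidationParams(t_typical=4, t_max=8, min_planes_keep=2)
        assert consolidate([m], p) == []

    def test_interface_merge_then_split(self):
        """Two stacked nuclei joined by one 40%-overlap interface edge are
        merged into one component and separated again by pruning."""
        lo = [rect_mask(z, 1, 0, 0, 10, 10) for z in range(4)]
        hi = [rect_mask(z, 1, 0, 6, 10, 10) for z in range(4, 8)]
        params = ConsolidationParams(t_typical=4, t_max=8)
        g = build_link_graph(lo + hi, params)
        assert len(connected_components(g)) == 1  # interface overlap 40% links them
        nuclei = consolidate(lo + hi, params)
        got = sorted(sorted(n.member_masks) for n in nuclei)
        assert got == [sorted(m.key for m in lo), sorted(m.key for m in hi)]

    def test_partition_and_size_invariants_on_scenes(self):
        for seed in (0, 1):
            _, truth, masks, nuclei = scene_ari(seed, n_nuclei=100)
            members = [k for n in nuclei for k in n.member_masks]
            assert sorted(members) == sorted(m.key for m in masks)  # no loss/duplication
            t_max = params_for(truth).t_max
            assert all(len(n.member_masks) <= t_max for n in nuclei)

    def test_threshold_soundness(self, small_scene):
        """No nucleus contains adjacent-plane members linked below overlap_min."""
        _, _, truth, masks = small_scene
        params = params_for(truth)
        nuclei = consolidate(masks, params)
        g = build_link_graph(masks, params)
        for n in nuclei:
            sub = g.subgraph(n.member_masks)
            assert all(
                sub.edges[e]["overlap_fraction"] >= params.overlap_min for e in sub.edges
            )

    def test_overlap_monotonicity(self, small_scene):
        """Raising overlap_min can only split components, never merge them."""
        _, _, truth, masks = small_scene
        base = params_for(truth)
        counts = []
        for omin in (0.2, 0.3, 0.5, 0.7):
            p = ConsolidationParams(
                t_typical=base.t_typical, t_max=base.t_max, overlap_min=omin
            )
            counts.append(len(consolidate(masks, p)))
        assert counts == sorted(counts)

    def test_determinism_byte_for_byte(self, small_scene):
        _, _, truth, masks = small_scene
        params = params_for(truth, rng_seed=3)
        runs = []
        for _ in range(2):
            nuclei = consolidate(masks, params)
            runs.append(
                [(n.nucleus_id, n.member_masks, n.voxel_mask.tobytes()) for n in nuclei]
            )
        assert runs[0] == runs[1]

    def test_noise_free_recovery_exact(self, small_scene):
        from sklearn.metrics import adjusted_rand_score
        from axialquant.synthetic import true_mask_labels

        _, _, truth, masks = small_scene
        nuclei = consolidate(masks, params_for(truth))
        assert len(nuclei) == len(truth.nuclei)
        ari = adjusted_rand_score(true_mask_labels(truth, masks), recovered_labels(nuclei, masks))
        assert ari == 1.0


class TestFeatures:
    def test_constant_channel(self):
        vox = np.array([[0, 1, 1], [1, 2, 2]])
        ch = np.full((1, 3, 4, 4), 7.0)
        assert extract_features(vox, ch, ["a"]) == {"a": 7.0}

    def test_two_voxel_mean(self):
        vox = np.array([[0, 0, 0], [0, 0, 1]])
        ch = np.zeros((1, 1, 1, 2))
        ch[0, 0, 0, 0], ch[0, 0, 0, 1] = 10.0, 20.0
        assert extract_features(vox, ch, ["a"])["a"] == 15.0

    def test_gaussian_profile_matches_bruteforce(self, small_scene):
        _, stack, truth, masks = small_scene
        nuclei = consolidate(masks, params_for(truth))
        n = nuclei[0]
        means = extract_features(n.voxel_mask, stack, truth.channel_names)
        # brute force: explicit python loop over voxels
        for ci, name in enumerate(truth.channel_names):
            total = sum(stack[ci, z, r, c] for z, r, c in n.voxel_mask)
            assert means[name] == pytest.approx(total / len(n.voxel_mask), rel=1e-6)

    def test_out_of_bounds_rejected(self):
        vox = np.array([[5, 0, 0]])
        with pytest.raises(ValueError, match="bounds"):
            extract_features(vox, np.zeros((1, 2, 2, 2)), ["a"])
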