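"""Tests for radial profiling, aggregate counting and expression scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from axialquant.colony import (
    bin_radial_cells,
    bin_radial_image,
    count_edge_aggregates,
    fit_circle,
    radial_profile,
    relative_expression,
)
from axialquant.synthetic import SceneSpec, Zone, generate_scene


def ring_image(size=200, r0=0.85, r1=0.95, level=100.0, background=10.0):
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx + 0.5 - size / 2, yy + 0.5 - size / 2) / (size / 2)
    img = np.full((size, size), background)
    img[(r >= r0) & (r <= r1)] = level
    return img


class TestRadialProfile:
    def test_uniform_image_constant_profile(self):
        img = np.full((100, 100), 3.5)
        bins = bin_radial_image(img, (50, 50), 50, n_bins=20)
        assert np.allclose(bins[np.isfinite(bins)], 3.5)

    def test_ring_argmax_in_ring(self):
        bins = bin_radial_image(ring_image(), (100, 100), 100, n_bins=50)
        prof = radial_profile([bins])
        peak = prof.bin_centers[int(np.nanargmax(prof.mean))]
        assert 0.85 <= peak <= 0.95

    def test_single_colony_sd_zero(self):
        prof = radial_profile([bin_radial_image(ring_image(), (100, 100), 100, 20)])
        assert prof.n_colonies == 1 and np.all(prof.sd == 0)

    def test_rotation_invariance(self):
        img = ring_image()
        # make it angularly asymmetric, then rotate about the center
        img[:100, :] *= 1.3
        rot = ndi.rotate(img, 37.0, reshape=False, order=1, mode="nearest")
        a = bin_radial_image(img, (100, 100), 100, 25)
        b = bin_radial_image(rot, (100, 100), 100, 25)
        inner = slice(1, 24)  # boundary bins suffer interpolation loss
        assert np.allclose(a[inner], b[inner], rtol=0.03)

    def test_pixels_beyond_radius_excluded(self):
        img = np.full((60, 60), 1.0)
        bins, counts = bin_radial_image(img, (30, 30), 20, 10, return_counts=True)
        inside = np.hypot(*(np.mgrid[0:60, 0:60] + 0.5 - 30)) <= 20
        assert counts.sum() == inside.sum()

    def test_generator_edge_ring_recovered_from_cells(self):
        layout = [Zone("ring", {"PERK": 150.0}, r_range=(0.85, 0.95))]
        spec = SceneSpec(
            geometry="disc", diameter=200, n_nuclei=200, class_layout=layout,
            background_markers={"PERK": 10.0}, rng_seed=3,
        )
        _, truth = generate_scene(spec, render=False)
        rec = pd.DataFrame(
            [
                {"x_um": n.center[0], "y_um": n.center[1],
                 "mean_PERK": n.channel_means.get("PERK", 10.0)}
                for n in truth.nuclei
            ]
        )
        prof = radial_profile([bin_radial_cells(rec, "mean_PERK", spec.center_um, spec.diameter / 2, 20)])
        peak = prof.bin_centers[int(np.nanargmax(prof.mean))]
        assert 0.85 - 0.05 <= peak <= 0.95 + 0.05

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError, match="center"):
            bin_radial_image(np.zeros((10, 10)), (50, 50), 5, 5)


def cells_at_angles(angles_deg, r_norm=0.9, radius=100.0):
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return pd.DataFrame(
        {
            "x_um": r_norm * radius * np.cos(a),
            "y_um": r_norm * radius * np.sin(a),
            "level_TBXT": "high",
        }
    )


class TestEdgeAggregates:
    def test_single_arc(self):
        rec = cells_at_angles(np.arange(0, 40, 5))
        agg = count_edge_aggregates(records=rec, center=(0, 0), radius=100, min_cells=3)
        assert agg.n_aggregates == 1

    def test_three_arcs(self):
        angles = list(range(0, 30, 5)) + list(range(120, 150, 5)) + list(range(240, 270, 5))
        agg = count_edge_aggregates(records=cells_at_angles(angles), center=(0, 0), radius=100, min_cells=3)
        assert agg.n_aggregates == 3

    def test_no_high_cells(self):
        rec = cells_at_angles([10, 50])
        rec["level_TBXT"] = "low"
        agg = count_edge_aggregates(records=rec, center=(0, 0), radius=100)
        assert agg.n_aggregates == 0

    def test_arc_wrapping_through_zero(self):
        rec = cells_at_angles([350, 355, 0, 5, 10])
        agg = count_edge_aggregates(records=rec, center=(0, 0), radius=100, min_cells=3)
        assert agg.n_aggregates == 1

    def test_rotation_invariance(self):
        angles = np.array(list(range(0, 30, 5)) + list(range(180, 225, 5)))
        base = count_edge_aggregates(records=cells_at_angles(angles), center=(0, 0), radius=100, min_cells=3)
        rot = count_edge_aggregates(records=cells_at_angles(angles + 77.0), center=(0, 0), radius=100, min_cells=3)
        assert base.n_aggregates == rot.n_aggregates == 2

    def test_interior_cells_ignored(self):
        rec = pd.concat([cells_at_angles(range(0, 40, 5)), cells_at_angles(range(100, 160, 5), r_norm=0.3)])
        agg = count_edge_aggregates(records=rec, center=(0, 0), radius=100, min_cells=3)
        assert agg.n_aggregates == 1


class TestRelativeExpression:
    def test_hand_computed_example(self):
        df = pd.DataFrame([[0, 9, 99]], index=["g"], columns=["t0", "t1", "t2"])
        out = relative_expression(df, pseudo_count=1.0)
        assert np.allclose(out.loc["g"], [0.0, 0.5, 1.0])

    def test_constant_positive_gene(self):
        df = pd.DataFrame([[7, 7, 7]], index=["g"])
        assert np.allclose(relative_expression(df).loc["g"], 1.0)

    def test_max_is_exactly_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(0, 100, size=(5, 8)))
        out = relative_expression(df)
        assert np.allclose(out.max(axis=1), 1.0)

    def test_all_zero_gene_flagged_nan(self):
        df = pd.DataFrame([[0, 0, 0], [1, 2, 3]], index=["dead", "ok"])
        out = relative_expression(df)
        assert out.loc["dead"].isna().all() and not out.loc["ok"].isna().any()


class TestFitCircle:
    def test_recovers_circle(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack((5 + 20 * np.cos(t), -3 + 20 * np.sin(t)))
        cx, cy, r = fit_circle(pts)
        assert (cx, cy, r) == pytest.approx((5, -3, 20), abs=1e-6)
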