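"""Scene geometry: hexagonal collimator tracing, phantoms, sampling."""

import math

import numpy as np
import pytest
from scipy import stats

from hgspect import geometry as geo
from hgspect.geometry import (BAR_PERIODS, HEGP, LEHR, CollimatorSpec,
                              abdominal_scene, bar_mask_blocked,
                              hole_center, locate, nearest_hole,
                              planar_bar_scene, point_in_hex,
                              sample_emission_point, trace_collimator)


class TestCollimatorSpec:
    def test_derived_dimensions(self):
        assert LEHR.flat_to_flat == pytest.approx(1.22 * math.cos(math.pi / 6))
        assert LEHR.pitch == pytest.approx(LEHR.flat_to_flat + 0.152)
        assert HEGP.pitch == pytest.approx(3.81 * math.cos(math.pi / 6) + 1.73)
        assert 0 < LEHR.open_fraction < 1

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            CollimatorSpec("bad", 0.0, 1.0, 0.1)


class TestTraceCollimator:
    def test_axial_ray_through_hole_center(self):
        segs, septa = trace_collimator((0, 0, 0), (0, 0, 1), LEHR)
        assert septa == 0
        assert segs == [("air_hole", pytest.approx(27.0))]

    def test_axial_ray_inside_septum(self):
        # (0.62, 0) lies beyond the central hexagon's vertex (0.61 mm)
        # and outside every neighbour
        assert nearest_hole(0.62, 0.0, LEHR) is None
        segs, septa = trace_collimator((0.62, 0, 0), (0, 0, 1), LEHR)
        assert septa == 1
        assert segs == [("lead", pytest.approx(27.0))]

    def test_parallel_direction_rejected(self):
        with pytest.raises(ValueError):
            trace_collimator((0, 0, 0), (1, 0, 0), LEHR)

    def test_segments_partition_the_chord(self, rng):
        for _ in range(50):
            x0, y0 = rng.uniform(-5, 5, 2)
            d = np.array([rng.uniform(-0.8, 0.8), rng.uniform(-0.8, 0.8),
                          1.0])
            d /= np.linalg.norm(d)
            segs, _ = trace_collimator((x0, y0, 0.0), d, LEHR)
            total = sum(length for _, length in segs)
            assert total == pytest.approx(27.0 / d[2], rel=1e-9)

    @pytest.mark.parametrize("spec", [LEHR, HEGP], ids=["lehr", "hegp"])
    def test_agrees_with_voxel_marching_oracle(self, spec, rng):
        """Lead path length and septa count match a brute-force ray
        marcher classifying micro-steps with the hexagon test."""
        step = 0.002
        for _ in range(12):
            x0, y0 = rng.uniform(-2 * spec.pitch, 2 * spec.pitch, 2)
            d = np.array([rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5),
                          1.0])
            d /= np.linalg.norm(d)
            segs, septa = trace_collimator((x0, y0, 0.0), d, spec)
            T = spec.hole_length / d[2]
            ts = np.arange(step / 2, T, step)
            xs = x0 + d[0] * ts
            ys = y0 + d[1] * ts
            in_hole = np.array([nearest_hole(x, y, spec) is not None
                                for x, y in zip(xs, ys)])
            lead_oracle = step * (~in_hole).sum()
            lead_traced = sum(length for m, length in segs if m == "lead")
            assert lead_traced == pytest.approx(lead_oracle, abs=5 * step)
            runs = np.diff(np.concatenate([[False], ~in_hole]).astype(int))
            septa_oracle = int((runs == 1).sum())
            assert abs(septa - septa_oracle) <= 1

    def test_lattice_translation_invariance(self):
        p = LEHR.pitch
        d = np.array([0.3, 0.2, 1.0])
        d /= np.linalg.norm(d)
        ref, septa_ref = trace_collimator((0.31, -0.22, 0.0), d, LEHR)
        for (i, j) in [(1, 0), (0, 2), (-1, 1), (3, -2)]:
            cx, cy = hole_center(i, j, p)
            segs, septa = trace_collimator((0.31 + cx, -0.22 + cy, 0.0),
                                           d, LEHR)
            assert septa == septa_ref
            assert [m for m, _ in segs] == [m for m, _ in ref]
            for (_, a), (_, b) in zip(segs, ref):
                assert a == pytest.approx(b, abs=1e-6)


class TestHexLattice:
    def test_hexagon_contains_center_and_excludes_vertex_overshoot(self):
        f = LEHR.flat_to_flat
        assert point_in_hex(0, 0, f)
        assert point_in_hex(0, f / 2 - 1e-9, f)
        assert not point_in_hex(0, f / 2 + 1e-9, f)
        r = f / math.sqrt(3)  # circumradius
        assert point_in_hex(r - 1e-9, 0, f)
        assert not point_in_hex(r + 1e-9, 0, f)

    def test_every_point_in_at_most_one_hole(self, rng):
        for _ in range(500):
            x, y = rng.uniform(-3, 3, 2)
            hole = nearest_hole(x, y, LEHR)
            if hole is not None:
                cx, cy = hole_center(*hole, LEHR.pitch)
                assert point_in_hex(x - cx, y - cy, LEHR.flat_to_flat)


class TestBarMask:
    def test_exact_periods_and_duty_cycle(self):
        # quadrant (x>0, y>0): 6 mm period, open first half-period
        x = np.linspace(0.01, 59.9, 12000)
        blocked = bar_mask_blocked(x, np.full_like(x, 10.0))
        frac = np.mod(x, 6.0) / 6.0
        assert np.array_equal(blocked, frac >= 0.5)

    def test_quadrant_period_assignment(self):
        for (qx, qy), period in zip([(-1, 1), (1, 1), (-1, -1), (1, -1)],
                                    BAR_PERIODS):
            x = qx * (period / 2 + 0.05)   # just inside the blocked stripe
            assert bar_mask_blocked(x, qy * 10.0)
            x = qx * (period / 4)          # centre of the open stripe
            assert not bar_mask_blocked(x, qy * 10.0)

    def test_open_outside_mask_extent(self):
        assert not bar_mask_blocked(70.0, 0.0)
        assert not bar_mask_blocked(3.0, 50.0)


class TestLocate:
    def test_points_in_named_volumes(self):
        scene = abdominal_scene()
        assert locate((0, 0, 0), scene)[0] == "V11"
        assert locate((0, -70, 0), scene)[0] == "V25"
        assert locate((0, 65, 0), scene)[0] == "SYR"
        assert locate((0, 120, 0), scene) == ("phantom", "pmma")
        assert locate((0, 0, -52), scene) == ("table", "pmma")
        assert locate((0, 0, 100), scene) == ("air", "air")
        assert locate((0, 0, 205), scene) == ("collimator", "lead")
        # posterior head: collimator entrance at z = -200, crystal at
        # local depth 28.5-38 mm
        assert locate((0, 0, -215), scene) == ("collimator", "lead")
        assert locate((0, 0, -232), scene)[0] == "crystal"

    def test_rotation_moves_the_phantom_not_the_heads(self):
        scene = abdominal_scene()
        scene.rotation_deg = 90.0
        # V25 sits at phantom (y=-70, z=0); at a 90 degree gantry angle
        # it appears on the lab +z side
        assert locate((0, 0, 70), scene)[0] == "V25"
        assert locate((0, 0, 205), scene)[0] == "collimator"

    def test_containment_oracle_agreement(self, rng):
        scene = abdominal_scene()
        cyls = [v for v in scene.volumes
                if isinstance(v, geo.CylinderVolume)]
        for _ in range(2000):
            p = rng.uniform(-160, 160, 3)
            label, _ = locate(p, scene)
            in_cyl = any(v.contains(*p) for v in cyls)
            assert (label in {"V11", "V25", "SYR"}) == in_cyl

    def test_planar_source_and_head(self):
        scene = planar_bar_scene("lehr")
        assert locate((0, 0, -1.0), scene) == ("flask", "water")
        assert locate((0, 0, 5.0), scene) == ("collimator", "lead")
        assert locate((0, 0, 40.0), scene)[0] in {"crystal", "coupling"}
        assert locate((0, 0, -300.0), scene)[0] == "air"


class TestEmissionSampling:
    def test_single_box_mean_at_center(self, rng):
        scene = planar_bar_scene("lehr")
        pos, labels = sample_emission_point(scene, rng, 20_000)
        se = pos.std(axis=0) / math.sqrt(len(pos))
        assert np.all(np.abs(pos.mean(axis=0) - [0, 0, -2.0]) < 3.5 * se)
        assert set(labels) == {"flask"}

    def test_zero_activity_volume_never_sampled(self, rng):
        scene = abdominal_scene(
            sources=(("V25", -70.0, 0.0, 13.5, 22.0, 0.0),
                     ("V11", 0.0, 0.0, 9.5, 20.0, 1.0)))
        _, labels = sample_emission_point(scene, rng, 2000)
        assert set(labels) == {"V11"}

    def test_no_active_volume_raises(self, rng):
        scene = planar_bar_scene("lehr", activity=0.0)
        with pytest.raises(ValueError):
            sample_emission_point(scene, rng, 10)

    def test_volume_shares_follow_activity_times_volume(self, rng):
        scene = abdominal_scene()
        n = 30_000
        _, labels = sample_emission_point(scene, rng, n)
        acts = {v.label: v.activity for v in scene.active_volumes}
        tot = sum(acts.values())
        for lbl, act in acts.items():
            p = act / tot
            k = labels.count(lbl)
            assert abs(k - n * p) < 4 * math.sqrt(n * p * (1 - p))

    def test_uniform_density_within_cylinder(self, rng):
        scene = abdominal_scene(
            sources=(("V25", 0.0, 0.0, 13.5, 22.0, 1.0),))
        pos, _ = sample_emission_point(scene, rng, 100_000)
        # chi-square over an 8^3 binning of the bounding box, masked to
        # fully-interior cells
        H, edges = np.histogramdd(pos, bins=8,
                                  range=[(-22, 22), (-13.5, 13.5),
                                         (-13.5, 13.5)])
        yc = 0.5 * (edges[1][:-1] + edges[1][1:])
        zc = 0.5 * (edges[2][:-1] + edges[2][1:])
        hw = (edges[1][1] - edges[1][0]) / 2, (edges[2][1] - edges[2][0]) / 2
        inner = np.zeros((8, 8), bool)
        for i, y in enumerate(yc):
            for j, z in enumerate(zc):
                corners = [(y + sy * hw[0], z + sz * hw[1])
                           for sy in (-1, 1) for sz in (-1, 1)]
                inner[i, j] = all(cy**2 + cz**2 <= 13.5**2
                                  for cy, cz in corners)
        counts = H[:, inner].ravel()
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, len(counts) - 1)
        assert p > 0.001
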