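"""Extracellular field kernels, boundary averaging and the transfer matrix.

The independent oracle throughout is quadrature: dense sums of point
sources along cylinder axes (and over spherical shells), which the
closed-form line-source kernel must reproduce.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ephapsim as ep
from ephapsim.errors import SingularityError, ValidationError
from ephapsim.field import (SamplingSpec, boundary_averaged_coefficient,
                            extracellular_pattern, probe_matrix,
                            quadrature_probe_matrix, segment_sample_points)


def line_quadrature(i_na, r, l, h, sigma, n=100000):
    """Oracle: midpoint sum of point sources along the axis."""
    L = l - h
    z = (np.arange(n) + 0.5) / n * L
    d = np.sqrt(r ** 2 + (l - z) ** 2)
    return i_na / (4 * np.pi * sigma * n) * np.sum(1.0 / d)


class TestLineSource:
    def test_zero_current_zero_potential(self, medium):
        g = ep.FieldGeometry(r=5.0, l=5.0, h=-5.0)
        assert ep.line_source_potential(0.0, g, medium) == 0.0

    def test_matches_quadrature_beside_midpoint(self, medium):
        # I = 1 nA, sigma = 0.3 S/m, L = 10 um, r = 5 um at the midpoint
        g = ep.FieldGeometry(r=5.0, l=5.0, h=-5.0)
        v = ep.line_source_potential(1.0, g, medium)
        vq = line_quadrature(1.0, 5.0, 5.0, -5.0, 0.3)
        assert v == pytest.approx(vq, rel=1e-6)

    @pytest.mark.parametrize("l,h", [(2.0, -8.0), (15.0, 5.0), (-3.0, -13.0)])
    def test_matches_quadrature_at_general_positions(self, medium, l, h):
        v = ep.line_source_potential(1.0, ep.FieldGeometry(r=4.0, l=l, h=h),
                                     medium)
        assert v == pytest.approx(line_quadrature(1.0, 4.0, l, h, 0.3),
                                  rel=1e-6)

    def test_mirror_symmetry_about_midpoint(self, medium):
        va = ep.line_source_potential(1.0, ep.FieldGeometry(r=3.0, l=7.0,
                                                            h=-3.0), medium)
        vb = ep.line_source_potential(1.0, ep.FieldGeometry(r=3.0, l=3.0,
                                                            h=-7.0), medium)
        assert va == pytest.approx(vb, rel=1e-12)

    def test_on_axis_inside_source_raises(self, medium):
        with pytest.raises(SingularityError):
            ep.line_source_potential(1.0, ep.FieldGeometry(r=0.0, l=5.0,
                                                           h=-5.0), medium)

    def test_on_axis_outside_source_finite(self, medium):
        v = ep.line_source_potential(1.0, ep.FieldGeometry(r=0.0, l=20.0,
                                                           h=10.0), medium)
        assert v == pytest.approx(line_quadrature(1.0, 1e-9, 20.0, 10.0, 0.3),
                                  rel=1e-5)

    def test_far_field_converges_to_point_source(self, medium):
        # |distance| = 20 L: agreement within 0.5%
        L, d = 10.0, 200.0
        v_line = ep.line_source_potential(
            1.0, ep.FieldGeometry(r=d, l=L / 2, h=-L / 2), medium)
        v_point = 1.0 / (4 * np.pi * 0.3 * d)
        assert abs(v_line - v_point) / v_point < 0.005


class TestPointSource:
    def test_inverse_distance_scaling(self, medium):
        v1 = ep.point_source_potential(1.0, 10.0, 1.0, medium)
        v2 = ep.point_source_potential(1.0, 20.0, 1.0, medium)
        assert v1 == pytest.approx(2 * v2, rel=1e-12)

    def test_interior_clamped_to_surface(self, medium):
        vs = ep.point_source_potential(1.0, 2.0, 2.0, medium)
        assert ep.point_source_potential(1.0, 0.0, 2.0, medium) == vs
        assert ep.point_source_potential(1.0, 1.0, 2.0, medium) == vs

    def test_absolute_value(self, medium):
        # 1 nA at 10 um in 0.3 S/m: 1e-9 A / (4 pi 0.3 S/m 1e-5 m) in mV
        v = ep.point_source_potential(1.0, 10.0, 1.0, medium)
        assert v == pytest.approx(1e-9 / (4 * np.pi * 0.3 * 1e-5) * 1e3,
                                  rel=1e-12)
        assert v == pytest.approx(0.0265, abs=2e-4)

    def test_matches_spherical_shell_quadrature(self, medium):
        # uniform shell source integrates to the exterior point-source form
        rs, R = 3.0, 11.0
        rng = np.random.default_rng(7)
        n = 200000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        d = np.linalg.norm(u * rs - np.array([R, 0, 0]), axis=1)
        v_shell = 1.0 / (4 * np.pi * 0.3 * n) * np.sum(1.0 / d)
        assert ep.point_source_potential(1.0, R, rs, medium) == pytest.approx(
            v_shell, rel=1e-3)


class TestBoundaryAveraging:
    def test_far_field_equals_point_source_within_1pct(self, medium):
        net = ep.fixture_network("axon", nseg=41)
        src = net.segments[0]
        tgt = net.segments[40]  # ~975 um away, segment size ~24 um
        c = boundary_averaged_coefficient(src, tgt, medium, network=net)
        d = np.linalg.norm(tgt.center - src.center)
        assert c == pytest.approx(1.0 / (4 * np.pi * 0.3 * d), rel=0.01)

    def test_rigid_motion_invariance(self, medium):
        def coef(net):
            return boundary_averaged_coefficient(
                net.segments[0], net.segments[3], medium, network=net)

        def bas():
            cell = ep.Cell("c")
            cell.add_section(ep.sphere("soma", 10.0))
            cell.add_section(ep.cylinder("axon", 1.0, 100.0,
                                         proximal_point=(10.0, 0, 0),
                                         nseg=4))
            ep.connect(cell, "axon", 0, "soma", 1)
            return cell

        ref = ep.discretize(ep.Network().add(bas()))
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        moved = ep.discretize(ep.Network().add(bas(), offset=(11, -7, 3),
                                               rotation=rot))
        assert coef(moved) == pytest.approx(coef(ref), rel=1e-12)

    def test_self_coefficient_matches_dense_quadrature(self, medium):
        # cylinder L=10, r=1: surface-average of the line kernel
        cell = ep.Cell("c").add_section(ep.cylinder("a", 1.0, 10.0))
        net = ep.discretize(ep.Network().add(cell))
        seg = net.segments[0]
        dense = boundary_averaged_coefficient(
            seg, seg, medium, SamplingSpec(n_axial=100, n_azimuth=100), net)
        denser = boundary_averaged_coefficient(
            seg, seg, medium, SamplingSpec(n_axial=200, n_azimuth=50), net)
        assert dense == pytest.approx(denser, rel=1e-4)

    def test_zero_point_sampling_rejected(self):
        with pytest.raises(ValidationError):
            SamplingSpec(n_axial=0)

    def test_sphere_ring_has_requested_points_at_radius(self, medium):
        net = ep.fixture_network("ball_and_stick", nseg=4)
        pts = segment_sample_points(net.segments[0], SamplingSpec(), net)
        assert pts.shape == (8, 3)
        assert np.allclose(np.linalg.norm(pts - net.segments[0].center,
                                          axis=1), 10.0)


class TestTransferMatrix:
    def test_single_segment_matrix_is_self_coefficient(self, medium):
        cell = ep.Cell("c").add_section(ep.cylinder("a", 1.0, 10.0))
        net = ep.discretize(ep.Network().add(cell))
        tm = ep.build_transfer_matrix(net, medium)
        c = boundary_averaged_coefficient(net.segments[0], net.segments[0],
                                          medium, tm.sampling, net)
        assert tm.entries.shape == (1, 1)
        assert tm.entries[0, 0] == pytest.approx(c, rel=1e-12)

    def test_inverse_sigma_scaling_exact(self):
        net = ep.fixture_network("axon", nseg=5)
        t1 = ep.build_transfer_matrix(net, ep.ExtracellularMedium(1.0))
        t2 = ep.build_transfer_matrix(net, ep.ExtracellularMedium(2.0))
        # doubling sigma halves every entry exactly (binary scaling)
        assert np.array_equal(t1.entries, 2.0 * t2.entries)

    def test_superposition_to_machine_precision(self, medium):
        net = ep.fixture_network("axon", nseg=3)
        tm = ep.build_transfer_matrix(net, medium)
        currents = np.array([1.0, -2.0, 1.0])
        combined = tm.entries @ currents
        separate = sum(tm.entries @ (currents * (np.arange(3) == k))
                       for k in range(3))
        assert np.allclose(combined, separate, rtol=0, atol=1e-15)

    def test_far_field_reciprocity(self, medium):
        net = ep.fixture_network("axon", nseg=41)
        tm = ep.build_transfer_matrix(net, medium)
        # segments 0 and 40 are separated by ~40x their size
        assert tm.entries[0, 40] == pytest.approx(tm.entries[40, 0],
                                                  rel=0.02)

    def test_potentials_vanish_at_infinity(self, medium, axon_net):
        # near field at the mid-axon surface; far field at 1e4 x the
        # 1000-um geometry scale
        near = ep.ProbeGrid(points=[[500.0, 1.0, 0.0]])
        far = ep.ProbeGrid(points=[[500.0, 1.0e4 * 1000.0, 0.0]])
        k_near = probe_matrix(axon_net, near, medium)
        k_far = probe_matrix(axon_net, far, medium)
        assert np.max(np.abs(k_far)) < 1e-6 * np.max(np.abs(k_near))


class TestProbes:
    def test_zero_currents_zero_potentials(self, medium):
        net = ep.fixture_network("axon", nseg=5)
        probes = ep.ProbeGrid(points=[[500.0, 5.0, 0.0]])
        v = ep.evaluate_probes(net, np.zeros((5, 4)), probes, medium)
        assert np.all(v == 0.0)

    def test_single_sphere_probe_reproduces_point_source(self, medium,
                                                         single_sphere_net):
        net = single_sphere_net("pas")
        probes = ep.ProbeGrid(points=[[25.0, 0.0, 0.0]])
        v = ep.evaluate_probes(net, np.array([2.0]), probes, medium)
        assert v[0] == pytest.approx(
            ep.point_source_potential(2.0, 25.0, 10.0, medium), rel=1e-12)

    def test_probe_on_axis_raises_with_probe_identified(self, medium):
        net = ep.fixture_network("axon", nseg=5)
        probes = ep.ProbeGrid(points=[[500.0, 0.0, 0.0]])
        with pytest.raises(SingularityError, match="segment"):
            probe_matrix(net, probes, medium)

    def test_closed_form_matches_quadrature_matrix(self, medium):
        net = ep.fixture_network("axon", nseg=7, length=100.0)
        probes = ep.ProbeGrid(points=[[30.0, 2.0, 0.0], [80.0, 7.0, 1.0]])
        kc = probe_matrix(net, probes, medium)
        kq = quadrature_probe_matrix(net, probes, medium, n_sub=20000)
        assert np.max(np.abs(kc - kq) / np.abs(kc)) < 1e-6

    def test_duplicate_probe_points_rejected(self):
        with pytest.raises(ValidationError):
            ep.ProbeGrid(points=[[0, 0, 1.0], [0, 0, 1.0]])


class TestExtracellularStimulus:
    def test_plate_field_linear_potential_difference(self, medium):
        spec = ep.StimulusSpec(side="extracellular", electrode="plates",
                               waveform="dc", amplitude=1.0,
                               field_direction=(0, 0, 2.0))
        pts = np.array([[0, 0, 0.0], [0, 0, 7.0]])
        v = extracellular_pattern(spec, pts, medium)
        assert v[1] - v[0] == pytest.approx(-7.0, rel=1e-12)

    def test_point_electrode_value(self, medium):
        spec = ep.StimulusSpec(side="extracellular", electrode="point",
                               waveform="dc", amplitude=1.0,
                               position=(0.0, 0.0, 0.0))
        v = extracellular_pattern(spec, np.array([[20.0, 0, 0]]), medium)
        assert v[0] == pytest.approx(0.0133, abs=1e-4)

    def test_evaluation_at_electrode_location_raises(self, medium):
        spec = ep.StimulusSpec(side="extracellular", electrode="point",
                               waveform="dc", amplitude=1.0,
                               position=(1.0, 2.0, 3.0))
        with pytest.raises(SingularityError):
            extracellular_pattern(spec, np.array([[1.0, 2.0, 3.0]]), medium)


@settings(max_examples=25, deadline=None)
@given(r=st.floats(0.5, 50.0), l=st.floats(-30.0, 60.0),
       L=st.floats(1.0, 30.0), sigma=st.floats(0.01, 10.0))
def test_line_kernel_matches_quadrature_property(r, l, L, sigma):
    med = ep.ExtracellularMedium(sigma)
    v = ep.line_source_potential(1.0, ep.FieldGeometry(r=r, l=l, h=l - L),
                                 med)
    vq = line_quadrature(1.0, r, l, l - L, sigma, n=20000)
    assert v == pytest.approx(vq, rel=1e-4)
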