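"""Orientation-dependent observables and PISA-wheel geometry.

The central check is oracle equivalence: the closed-form wheel
frequencies must agree, to 1e-9, with a brute-force path that builds the
full Ry(τ)·Rz(ρ₀) rotation matrices, rotates every tensor axis and N-H
vector into the lab frame, and projects onto the field axis.
"""

import numpy as np
import pytest

import pisawheel as pw
from pisawheel.oriented_nmr import CSATensor


def rotation_matrices(tilt_deg, rho_deg):
    t, r = np.radians(tilt_deg), np.radians(rho_deg)
    ry = np.array([[np.cos(t), 0, np.sin(t)],
                   [0, 1, 0],
                   [-np.sin(t), 0, np.cos(t)]])
    rz = np.array([[np.cos(r), -np.sin(r), 0],
                   [np.sin(r), np.cos(r), 0],
                   [0, 0, 1]])
    return ry @ rz


def brute_force_peaks(h, t15n, w, b, residues):
    """Explicit rotation-matrix route to the observed frequencies."""
    R = rotation_matrices(w.tilt_deg, w.rho0_deg)
    z = np.array([0.0, 0.0, 1.0])
    out = []
    for res in residues:
        i = res - 1
        frame_lab = h.csa_frames[i] @ R.T      # rows rotated into lab
        shift = pw.static_shift(t15n, frame_lab, z)
        nh_lab = R @ h.nh_vectors[i]
        theta = np.degrees(np.arccos(np.clip(nh_lab @ z, -1, 1)))
        coup = pw.static_coupling(w.nu_parallel_khz, theta)
        out.append((float(pw.observe(shift, t15n.iso, b)),
                    float(pw.observe_coupling(coup, b))))
    return out


class TestCSATensor:
    def test_canonical_ordering_and_iso(self):
        t = CSATensor(217.0, 64.0, 77.0)
        assert (t.sigma11, t.sigma22, t.sigma33) == (64.0, 77.0, 217.0)
        assert t.iso == (64.0 + 77.0 + 217.0) / 3.0


class TestStaticShift:
    def test_projection_along_principal_axes(self, n15):
        frame = np.eye(3)
        assert pw.static_shift(n15, frame, [1, 0, 0]) == n15.sigma11
        assert pw.static_shift(n15, frame, [0, 0, 1]) == n15.sigma33

    def test_powder_average_equals_iso(self, n15):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(20000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        shifts = [pw.static_shift(n15, np.eye(3), d) for d in v]
        assert np.mean(shifts) == pytest.approx(n15.iso, abs=0.5)

    def test_non_unit_direction_rejected(self, n15):
        with pytest.raises(ValueError):
            pw.static_shift(n15, np.eye(3), [1.0, 1.0, 0.0])


class TestStaticCoupling:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, 10.52), (90.0, -5.26), (180.0, 10.52),
    ])
    def test_limits(self, theta, expected):
        assert pw.static_coupling(10.52, theta) == pytest.approx(expected)

    def test_magic_angle_zero(self):
        assert pw.static_coupling(10.52, 54.7356) == pytest.approx(0.0,
                                                                   abs=1e-4)

    def test_sphere_average_zero(self):
        rng = np.random.default_rng(11)
        cos = rng.uniform(-1, 1, size=200000)
        theta = np.degrees(np.arccos(cos))
        assert np.mean(pw.static_coupling(10.52, theta)) == pytest.approx(
            0.0, abs=0.05)


class TestObserve:
    def test_identity_limit(self):
        b = pw.BicelleModel(order_parameter=1.0, flip="flipped")
        assert pw.observe(200.0, 119.3, b) == pytest.approx(200.0)
        assert pw.observe_coupling(5.0, b) == pytest.approx(5.0)

    def test_isotropic_limit(self):
        b = pw.BicelleModel(order_parameter=0.0, flip="unflipped")
        assert pw.observe(200.0, 119.3, b) == pytest.approx(119.3)
        assert pw.observe_coupling(5.0, b) == pytest.approx(0.0)

    def test_unflipped_scaling_hand_value(self, bicelle):
        # 119.3 - 0.425 * (217 - 119.3) = 77.7775
        assert pw.observe(217.0, 119.3, bicelle) == pytest.approx(77.7775)

    def test_invalid_bicelle_rejected(self):
        with pytest.raises(ValueError):
            pw.BicelleModel(order_parameter=1.2)
        with pytest.raises(ValueError):
            pw.BicelleModel(flip="sideways")


class TestPisaWheel:
    def test_zero_tilt_collapses_to_point(self, tm_helix, n15, bicelle):
        w = pw.WheelParams(0.0, 0.0, 10.52)
        peaks = pw.pisa_wheel(tm_helix, n15, w, bicelle)
        shifts = np.array([p.shift_ppm for p in peaks])
        coups = np.array([p.coupling_khz for p in peaks])
        assert np.ptp(shifts) < 1e-6
        assert np.ptp(coups) < 1e-6

    def test_empty_span_rejected(self, tm_helix, n15, bicelle):
        w = pw.WheelParams(10.0, 0.0, 10.52)
        with pytest.raises(ValueError):
            pw.pisa_wheel(tm_helix, n15, w, bicelle, residues=[])

    def test_residue_one_has_no_amide(self, tm_helix, n15, bicelle):
        w = pw.WheelParams(10.0, 0.0, 10.52)
        with pytest.raises(ValueError):
            pw.pisa_wheel(tm_helix, n15, w, bicelle, residues=[1, 2])

    @pytest.mark.parametrize("tilt", [6.0, 16.0])
    def test_tm_couplings_within_reported_band(self, tm_helix, n15, bicelle,
                                               tilt):
        """At the fitted tilts all TM couplings fall in 2-4.5 kHz."""
        for rho in np.arange(0.0, 360.0, 15.0):
            w = pw.WheelParams(tilt, float(rho), 10.52)
            peaks = pw.pisa_wheel(tm_helix, n15, w, bicelle)
            coups = np.array([p.coupling_khz for p in peaks])
            assert coups.min() >= 2.0
            assert coups.max() <= 4.5

    def test_matches_brute_force_rotation_oracle(self, tm_helix, n15):
        rng = np.random.default_rng(23)
        residues = list(range(2, tm_helix.n_residues + 1))
        for _ in range(100):
            w = pw.WheelParams(float(rng.uniform(0, 90)),
                               float(rng.uniform(0, 360)),
                               float(rng.uniform(5, 15)))
            b = pw.BicelleModel(float(rng.uniform(0, 1)),
                                str(rng.choice(["unflipped", "flipped"])))
            peaks = pw.pisa_wheel(tm_helix, n15, w, b, residues=residues)
            ref = brute_force_peaks(tm_helix, n15, w, b, residues)
            for p, (shift, coup) in zip(peaks, ref):
                assert p.shift_ppm == pytest.approx(shift, abs=1e-9)
                assert p.coupling_khz == pytest.approx(abs(coup), abs=1e-9)


class TestWheelLocus:
    def test_zero_tilt_all_points_coincide(self, tm_helix, n15, bicelle):
        w = pw.WheelParams(0.0, 0.0, 10.52)
        loc = pw.wheel_locus(tm_helix, n15, w, bicelle, 50)
        assert np.ptp(loc[:, 0]) < 1e-6
        assert np.ptp(loc[:, 1]) < 1e-6

    def test_periodicity(self, tm_helix, n15, bicelle):
        w = pw.WheelParams(12.0, 30.0, 10.52)
        loc = pw.wheel_locus(tm_helix, n15, w, bicelle, 8)
        loc2 = pw.wheel_locus(
            tm_helix, n15, pw.WheelParams(12.0, 30.0 + 360.0, 10.52),
            bicelle, 8)
        assert np.allclose(loc, loc2, atol=1e-9)

    def test_peaks_lie_on_locus_at_twist_spaced_azimuths(
            self, tm_helix, n15, bicelle):
        """Residue i+1 sits on the locus one helix twist from residue i."""
        w = pw.WheelParams(14.0, 25.0, 10.52)
        peaks = pw.pisa_wheel(tm_helix, n15, w, bicelle)
        rep = max(2, tm_helix.n_residues // 2 + 1)
        from pisawheel.oriented_nmr import _wheel_frequencies
        for p in peaks:
            delta = tm_helix.twist_deg * (p.residue - rep)
            sh, cp = _wheel_frequencies(
                tm_helix, n15, w, bicelle, np.array([rep - 1]),
                w.rho0_deg + delta)
            assert p.shift_ppm == pytest.approx(float(sh[0, 0]), abs=1e-6)
            assert p.coupling_khz == pytest.approx(abs(float(cp[0, 0])),
                                                   abs=1e-6)

    def test_continuity_in_azimuth(self, tm_helix, n15, bicelle):
        w = pw.WheelParams(16.0, 0.0, 10.52)
        jumps = []
        for n in (90, 360, 1440):
            loc = pw.wheel_locus(tm_helix, n15, w, bicelle, n)
            closed = np.vstack([loc, loc[:1]])
            jumps.append(np.abs(np.diff(closed, axis=0)).max())
        assert jumps[0] > jumps[1] > jumps[2]

    def test_coupling_radius_nondecreasing_in_tilt(self, tm_helix, n15,
                                                   bicelle):
        radii = []
        for tilt in np.arange(0.0, 20.5, 2.5):
            loc = pw.wheel_locus(tm_helix, n15,
                                 pw.WheelParams(float(tilt), 0.0, 10.52),
                                 bicelle, 360)
            radii.append((loc[:, 1].max() - loc[:, 1].min()) / 2.0)
        assert all(b >= a - 1e-9 for a, b in zip(radii, radii[1:]))


class TestClassify1D:
    def test_reported_convention(self):
        part = pw.classify_1d([70.0, 130.0])
        assert part["surface"] == [70.0]
        assert part["transmembrane"] == [130.0]

    def test_empty_input(self):
        part = pw.classify_1d([])
        assert part["surface"] == [] and part["transmembrane"] == []

    def test_threshold_tie_goes_transmembrane(self):
        part = pw.classify_1d([120.0])
        assert part["transmembrane"] == [120.0]

    def test_physics_convention_flips_assignment(self):
        part = pw.classify_1d([70.0, 130.0], surface_below=False)
        assert part["surface"] == [130.0]
        assert part["transmembrane"] == [70.0]
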