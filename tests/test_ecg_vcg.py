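"""Kors VCG construction, frame alignment, QRS loop and electrical axes."""

import numpy as np
import pytest

from cardaxes import (
    DegenerateGeometryError,
    FrameError,
    MedianBeatECG,
    QRSLoop,
    UsageError,
    Vectorcardiogram,
    electrical_axis,
    extract_qrs_loop,
    frank_to_lps,
    kors_matrix,
    kors_transform,
    load_ecg_table,
    qrs_amplitude,
    save_ecg_table,
)
from cardaxes.cohort_analysis import qrs_amplitude_qc
from cardaxes.ecg_vcg import LEADS
from cardaxes.synthetic_cohort import vcg_to_leads


def make_ecg(arrays, fs=500.0, onset=2, offset=8):
    return MedianBeatECG(samples=dict(zip(LEADS, arrays)), fs=fs, qrs_onset=onset, qrs_offset=offset)


def flat_ecg(n=10, value=0.0):
    return make_ecg([np.full(n, value) for _ in LEADS])


class TestKorsMatrix:
    def test_transcription_row_norms(self):
        """Checksum of the shipped regression coefficients (rows X, Y, Z)."""
        M = kors_matrix()
        assert M.shape == (3, 8)
        expected = [
            np.linalg.norm([0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54]),
            np.linalg.norm([-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13]),
            np.linalg.norm([0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31]),
        ]
        np.testing.assert_allclose(np.linalg.norm(M, axis=1), expected, atol=1e-12)
        assert np.linalg.matrix_rank(M) == 3


class TestQRSAmplitude:
    def test_constant_lead_has_zero_amplitude(self):
        ecg = flat_ecg(value=200.0)
        assert qrs_amplitude(ecg, "I") == 0.0

    def test_max_absolute_deflection(self):
        x = np.zeros(10)
        x[4], x[6] = 1500.0, -800.0
        ecg = make_ecg([x] + [np.zeros(10)] * 7)
        assert qrs_amplitude(ecg, "I") == 1500.0

    def test_absent_lead_rejected(self):
        with pytest.raises(UsageError):
            qrs_amplitude(flat_ecg(), "V9")

    def test_population_qc_flags_planted_outliers(self, rng):
        """Subjects whose amplitude z-score exceeds 3 in any lead are flagged."""
        import pandas as pd

        amp = pd.DataFrame(rng.normal(1500, 150, size=(500, 8)), columns=LEADS)
        amp.iloc[3, 0] = 4000.0   # lead I outlier
        amp.iloc[7, 5] = 100.0    # lead V4 outlier
        include = qrs_amplitude_qc(amp, k=3.0)
        # hand recomputation per lead
        expected = np.ones(500, bool)
        for lead in LEADS:
            v = amp[lead].to_numpy()
            expected &= np.abs(v - v.mean()) <= 3 * v.std(ddof=1)
        np.testing.assert_array_equal(include.to_numpy(), expected)
        assert not include.iloc[3] and not include.iloc[7]


class TestKorsTransform:
    def test_zero_in_zero_out(self):
        vcg = kors_transform(flat_ecg())
        assert vcg.frame == "FRANK"
        assert np.all(vcg.as_matrix() == 0.0)

    def test_linearity(self, rng):
        n = 50
        e1 = [rng.normal(size=n) for _ in LEADS]
        e2 = [rng.normal(size=n) for _ in LEADS]
        a, b = 2.5, -1.25
        combo = make_ecg([a * x + b * y for x, y in zip(e1, e2)], onset=5, offset=45)
        v1 = kors_transform(make_ecg(e1, onset=5, offset=45)).as_matrix()
        v2 = kors_transform(make_ecg(e2, onset=5, offset=45)).as_matrix()
        vc = kors_transform(combo).as_matrix()
        np.testing.assert_allclose(vc, a * v1 + b * v2, atol=1e-12)

    def test_pseudoinverse_round_trip(self, rng):
        """vcg_to_leads then kors_transform reproduces the VCG to 1e-9."""
        xyz = rng.normal(scale=800, size=(3, 120))
        vcg = Vectorcardiogram(
            vx=xyz[0], vy=xyz[1], vz=xyz[2], fs=500.0, qrs_onset=10, qrs_offset=60
        )
        back = kors_transform(vcg_to_leads(vcg)).as_matrix()
        rel = np.linalg.norm(back - vcg.as_matrix()) / np.linalg.norm(vcg.as_matrix())
        assert rel < 1e-9


class TestFrameAlignment:
    def test_left_axis_preserved(self):
        vcg = Vectorcardiogram(
            vx=np.ones(5), vy=np.zeros(5), vz=np.zeros(5), fs=500, qrs_onset=0, qrs_offset=5
        )
        out = frank_to_lps(vcg)
        assert out.frame == "LPS"
        np.testing.assert_allclose(out.as_matrix()[0], [1, 0, 0])

    def test_frank_inferior_maps_to_minus_z(self):
        vcg = Vectorcardiogram(
            vx=np.zeros(5), vy=np.ones(5), vz=np.zeros(5), fs=500, qrs_onset=0, qrs_offset=5
        )
        np.testing.assert_allclose(frank_to_lps(vcg).as_matrix()[0], [0, 0, -1])

    def test_double_application_rejected(self):
        vcg = Vectorcardiogram(
            vx=np.zeros(5), vy=np.zeros(5), vz=np.zeros(5), fs=500, qrs_onset=0, qrs_offset=5
        )
        with pytest.raises(FrameError):
            frank_to_lps(frank_to_lps(vcg))

    def test_mapping_is_orthogonal(self, rng):
        from cardaxes.ecg_vcg import FRANK_TO_LPS

        v = rng.normal(size=(10, 3))
        np.testing.assert_allclose(v @ FRANK_TO_LPS.T @ FRANK_TO_LPS, v, atol=1e-14)


class TestQRSLoopExtraction:
    def test_re_origin_rule(self, rng):
        xyz = rng.normal(size=(3, 50))
        vcg = frank_to_lps(
            Vectorcardiogram(vx=xyz[0], vy=xyz[1], vz=xyz[2], fs=500, qrs_onset=10, qrs_offset=40)
        )
        loop = extract_qrs_loop(vcg)
        full = vcg.as_matrix()
        np.testing.assert_allclose(loop.points, full[10:40] - full[10], atol=1e-12)
        assert np.all(loop.points[0] == 0.0)
        assert len(loop.points) == 30

    def test_window_too_short(self):
        vcg = Vectorcardiogram(
            vx=np.zeros(9), vy=np.zeros(9), vz=np.zeros(9),
            fs=500, qrs_onset=4, qrs_offset=6, frame="LPS",
        )
        with pytest.raises(DegenerateGeometryError):
            extract_qrs_loop(vcg)

    def test_constant_vcg_gives_degenerate_loop(self):
        vcg = Vectorcardiogram(
            vx=np.full(20, 7.0), vy=np.full(20, -3.0), vz=np.full(20, 1.0),
            fs=500, qrs_onset=0, qrs_offset=20, frame="LPS",
        )
        loop = extract_qrs_loop(vcg)
        assert np.all(loop.points == 0.0)
        with pytest.raises(DegenerateGeometryError):
            electrical_axis(loop, "maxQRS")


def ellipse_loop(A=1000.0, B=300.0, u=None, v=None, n=80):
    """Closed planar ellipse starting at the origin; semi-major along u."""
    u = np.array([1.0, 0.0, 0.0]) if u is None else u
    v = np.array([0.0, 1.0, 0.0]) if v is None else v
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = (A * np.cos(t)[:, None] * u) + (B * np.sin(t)[:, None] * v) - A * u
    pts[0] = 0.0
    return QRSLoop(points=pts, fs=500.0)


class TestElectricalAxis:
    def test_ellipse_max_and_principal_direction(self):
        """maxQRS = brute-force max-norm sample; eig1QRS = semi-major axis
        sign-resolved to the meanQRS side."""
        u = np.array([0.0, 0.6, 0.8])
        v = np.array([1.0, 0.0, 0.0])
        loop = ellipse_loop(u=u, v=v, n=80)
        d_max = electrical_axis(loop, "maxQRS").direction
        brute = loop.points[np.argmax(np.linalg.norm(loop.points, axis=1))]
        np.testing.assert_allclose(d_max, brute / np.linalg.norm(brute), atol=1e-12)
        np.testing.assert_allclose(d_max, -u, atol=1e-9)  # far point at -2A u
        d_eig = electrical_axis(loop, "eig1QRS").direction
        assert min(np.linalg.norm(d_eig - u), np.linalg.norm(d_eig + u)) < 1e-9
        d_mean = electrical_axis(loop, "meanQRS").direction
        assert float(d_eig @ d_mean) >= 0

    def test_single_dominant_sample(self):
        pts = np.zeros((10, 3))
        pts[1:] = np.random.default_rng(0).normal(scale=5, size=(9, 3))
        pts[4] = [0.0, 0.0, 2000.0]
        pts[0] = 0.0
        loop = QRSLoop(points=pts, fs=500.0)
        np.testing.assert_allclose(electrical_axis(loop, "maxQRS").direction, [0, 0, 1], atol=1e-12)

    def test_straight_line_loop_all_methods_agree(self):
        u = np.array([0.48, -0.6, 0.64])
        t = np.linspace(0, 1, 25)
        loop = QRSLoop(points=np.outer(t * 900.0, u), fs=500.0)
        for method in ("maxQRS", "meanQRS", "vavgQRS", "eig1QRS"):
            np.testing.assert_allclose(
                electrical_axis(loop, method).direction, u, atol=1e-9, err_msg=method
            )

    def test_vavg_invariant_to_nonuniform_resampling_mean_is_not(self):
        """Arc-length weighting compensates sampling density; the plain mean
        shifts toward the oversampled segment."""
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 0.0, 1.0])

        def loop_at(param):
            t = 2 * np.pi * param
            pts = 800 * (1 - np.cos(t))[:, None] * u + 500 * np.sin(t)[:, None] * v
            pts[0] = 0.0
            return QRSLoop(points=pts, fs=500.0)

        uniform = loop_at(np.linspace(0, 1, 200, endpoint=False))
        warped = loop_at((np.linspace(0, 1, 400, endpoint=False)) ** 2)  # dense near onset
        v_uni = electrical_axis(uniform, "vavgQRS").direction
        v_wrp = electrical_axis(warped, "vavgQRS").direction
        assert np.linalg.norm(v_uni - v_wrp) < 1e-3
        m_uni = electrical_axis(uniform, "meanQRS").direction
        m_wrp = electrical_axis(warped, "meanQRS").direction
        assert np.linalg.norm(m_uni - m_wrp) > 10 * np.linalg.norm(v_uni - v_wrp)

    def test_rotation_equivariance_and_scale_invariance(self, default_loop, rng):
        from scipy.spatial.transform import Rotation

        loop, _ = default_loop
        R = Rotation.random(random_state=rng).as_matrix()
        rotated = QRSLoop(points=loop.points @ R.T, fs=loop.fs)
        scaled = QRSLoop(points=loop.points * 3.7, fs=loop.fs)
        for method in ("maxQRS", "meanQRS", "vavgQRS", "eig1QRS"):
            d = electrical_axis(loop, method).direction
            np.testing.assert_allclose(
                electrical_axis(rotated, method).direction, R @ d, atol=1e-9
            )
            np.testing.assert_allclose(
                electrical_axis(scaled, method).direction, d, atol=1e-12
            )

    def test_eig1_sign_rule_is_deterministic(self, default_loop):
        loop, _ = default_loop
        d1 = electrical_axis(loop, "eig1QRS").direction
        d2 = electrical_axis(loop, "eig1QRS").direction
        assert (d1 == d2).all()


class TestECGTableIO:
    def test_round_trip(self, tmp_path, rng):
        ecg = make_ecg([rng.normal(size=30) for _ in LEADS], onset=5, offset=25)
        path = save_ecg_table(ecg, tmp_path / "beat.csv")
        back = load_ecg_table(path)
        assert back.fs == ecg.fs
        assert (back.qrs_onset, back.qrs_offset) == (5, 25)
        for lead in LEADS:
            np.testing.assert_allclose(back.samples[lead], ecg.samples[lead], atol=1e-9)
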