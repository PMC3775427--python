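"""Resting-state chain: screen, nuisance, band-pass, tau, Fisher averaging."""
import numpy as np
import pytest

import netshift as ns
from netshift.resting import BandSpec, build_nuisance, regress_nuisance


def _panel_from(cov, n_subjects=6, t=120, seed=0, **kw):
    return ns.gen_subject_panel(cov, n_subjects=n_subjects, t=t, seed=seed, **kw)


@pytest.fixture
def cov8():
    return ns.gen_modular_matrix(ns.ModularSpec(8, [4, 4], mu_in=0.6, mu_out=0.1,
                                                sigma=0.0, seed=0))


class TestMotionScreen:
    def test_all_small_traces_kept(self, cov8):
        panel = _panel_from(cov8)
        kept, excluded = ns.motion_screen(panel)
        assert kept == list(range(panel.n_subjects)) and excluded == []

    def test_one_violator_among_103_leaves_102(self, cov8):
        panel = _panel_from(
            cov8, n_subjects=103, t=12,
            motion_spec=ns.MotionSpec(violator_index=50, violator_peak_mm=3.5),
        )
        kept, excluded = ns.motion_screen(panel, threshold_mm=3.0)
        assert len(kept) == 102
        assert excluded == [(50, pytest.approx(3.5))]

    def test_exactly_3mm_is_kept(self, cov8):
        """Exclusion is strictly 'greater than 3 mm'."""
        panel = _panel_from(cov8, n_subjects=2, t=40)
        peak = np.abs(panel.motion[0][:, :3]).max()
        panel.motion[0][:, :3] *= 3.0 / peak
        kept, _ = ns.motion_screen(panel, threshold_mm=3.0)
        assert 0 in kept


class TestNuisance:
    def test_design_has_23_labeled_columns(self, rng):
        t = 50
        nuis = build_nuisance(rng.normal(size=(t, 6)), rng.normal(size=(t, 5)),
                              rng.normal(size=(t, 5)))
        assert nuis.k == 23
        assert nuis.column_roles[:2] == ["motion1", "motion2"]
        assert nuis.column_roles[6] == "dmotion1"
        assert nuis.column_roles[-1] == "intercept"

    def test_derivative_columns(self, rng):
        t = 30
        motion = np.column_stack([np.full(t, 2.0)] * 3 + [0.5 * np.arange(t)] * 3)
        nuis = build_nuisance(motion, rng.normal(size=(t, 5)), rng.normal(size=(t, 5)))
        d = nuis.columns[:, 6:12]
        np.testing.assert_array_equal(d[0], np.zeros(6))       # first row zero
        np.testing.assert_array_equal(d[1:, :3], np.zeros((t - 1, 3)))  # constant
        np.testing.assert_allclose(d[1:, 3:], 0.5)             # ramp slope

    def test_residuals_orthogonal_and_match_normal_equations(self, rng):
        t, n = 80, 4
        nuis = build_nuisance(rng.normal(size=(t, 6)), rng.normal(size=(t, 5)),
                              rng.normal(size=(t, 5)))
        y = rng.normal(size=(t, n))
        resid = regress_nuisance(y, nuis)
        x = nuis.columns
        assert np.abs(x.T @ resid).max() < 1e-8 * t
        hat = x @ np.linalg.solve(x.T @ x, x.T @ y)  # explicit normal equations
        np.testing.assert_allclose(resid, y - hat, atol=1e-8)

    def test_perfect_fit_and_untouched_orthogonal_series(self, rng):
        t = 60
        nuis = build_nuisance(rng.normal(size=(t, 6)), rng.normal(size=(t, 5)),
                              rng.normal(size=(t, 5)))
        as_col = nuis.columns[:, [2]]
        assert np.abs(regress_nuisance(as_col, nuis)).max() < 1e-10
        q, _ = np.linalg.qr(np.hstack([nuis.columns, rng.normal(size=(t, 1))]))
        ortho = q[:, [-1]]  # orthogonal to the design by construction
        np.testing.assert_allclose(regress_nuisance(ortho, nuis), ortho, atol=1e-10)

    def test_too_few_frames_rejected(self, rng):
        nuis = build_nuisance(rng.normal(size=(20, 6)), rng.normal(size=(20, 5)),
                              rng.normal(size=(20, 5)))
        with pytest.raises(ValueError):
            regress_nuisance(rng.normal(size=(20, 2)), nuis)


class TestBandpass:
    band = BandSpec(0.01, 0.1, 1.8)

    def test_constant_series_removed(self):
        out = ns.bandpass(np.full((240, 2), 5.0), self.band)
        assert np.abs(out).max() < 1e-10

    @pytest.mark.parametrize("freq,kept", [(0.05, True), (0.2, False)])
    def test_fft_amplitude_oracle(self, freq, kept):
        t = 240
        time = np.arange(t) * 1.8
        x = np.sin(2 * np.pi * freq * time)[:, None]
        out = ns.bandpass(x, self.band)
        amp_in = np.abs(np.fft.rfft(x[:, 0]))
        amp_out = np.abs(np.fft.rfft(out[:, 0]))
        peak = amp_in.argmax()
        if kept:
            assert amp_out[peak] == pytest.approx(amp_in[peak], rel=0.01)
        else:
            assert amp_out[peak] <= 0.01 * amp_in[peak]

    def test_butterworth_variant_attenuates_stopband(self):
        t = 240
        time = np.arange(t) * 1.8
        x = np.sin(2 * np.pi * 0.2 * time)[:, None]
        out = ns.bandpass(x, self.band, method="butterworth")
        amp_in = np.abs(np.fft.rfft(x[:, 0]))
        amp_out = np.abs(np.fft.rfft(out[:, 0]))
        # stop-band amplitude at the probe frequency bin (edge transients aside)
        assert amp_out[amp_in.argmax()] < 0.01 * amp_in.max()
        assert np.abs(out[20:-20]).max() < 0.05 * np.abs(x).max()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandSpec(0.01, 0.3, 1.8)  # above Nyquist = 0.278
        with pytest.raises(ValueError):
            ns.bandpass(np.zeros((10, 2)), self.band)  # too short


class TestKendall:
    def test_monotone_gives_unit_tau(self, rng):
        x = rng.normal(size=30)
        series = np.column_stack([x, np.exp(x), x])
        tau = ns.kendall_matrix(series)
        assert tau[0, 1] == pytest.approx(1.0)
        np.testing.assert_array_equal(tau, tau.T)
        assert np.all(np.diag(tau) == 1.0)

    def test_brute_force_pair_count(self):
        """tau of [1,2,3] vs [1,3,2] equals concordant-discordant counting."""
        x, y = np.array([1.0, 2.0, 3.0]), np.array([1.0, 3.0, 2.0])
        conc = disc = 0
        for i in range(3):
            for j in range(i + 1, 3):
                s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
                conc += s > 0
                disc += s < 0
        expected = (conc - disc) / 3  # 3 pairs, no ties
        tau = ns.kendall_matrix(np.column_stack([x, y]))
        assert tau[0, 1] == pytest.approx(expected) == pytest.approx(1 / 3)

    def test_constant_column_names_roi(self):
        series = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.raises(ValueError, match="flat_roi"):
            ns.kendall_matrix(series, labels=["ok", "flat_roi"])


class TestFisher:
    def test_closed_forms_and_roundtrip(self):
        assert ns.fisher_z(0.0) == 0.0
        assert ns.fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)
        r = np.linspace(-0.999, 0.999, 41)
        np.testing.assert_allclose(ns.fisher_inv(ns.fisher_z(r)), r, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ns.fisher_z(1.5)


class TestGroupAverage:
    def test_single_subject_passthrough_with_unit_diagonal(self, rng):
        m = np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-0.5, 0.5, (4, 4))), -1, 1)
        out = ns.group_average([m]).values
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(out[off], m[off], atol=1e-12)
        assert np.all(np.diag(out) == 1.0)

    def test_two_subject_closed_form(self):
        m1 = np.array([[1.0, 0.2], [0.2, 1.0]])
        m2 = np.array([[1.0, 0.6], [0.6, 1.0]])
        out = ns.group_average([m1, m2]).values
        expected = np.tanh((np.arctanh(0.2) + np.arctanh(0.6)) / 2)
        assert out[0, 1] == pytest.approx(expected)

    def test_mean_of_copies_is_identity(self, rng):
        m = (lambda a: np.clip((a + a.T) / 2, -0.9, 0.9))(rng.uniform(-1, 1, (5, 5)))
        np.fill_diagonal(m, 1.0)
        out = ns.group_average([m] * 4).values
        np.testing.assert_allclose(out, m, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ns.group_average([np.eye(3), np.eye(4)])


class TestFullChain:
    def test_deterministic(self, cov8):
        panel = _panel_from(cov8, n_subjects=4, t=60)
        g1, _ = ns.build_resting_matrix(panel)
        g2, _ = ns.build_resting_matrix(panel)
        np.testing.assert_array_equal(g1.values, g2.values)

    def test_block_structure_recovered(self):
        """Within-module tau exceeds between-module tau by a clear margin."""
        cov = ns.gen_modular_matrix(ns.ModularSpec(16, [8, 8], mu_in=0.6,
                                                   mu_out=0.1, sigma=0.0, seed=0))
        panel = _panel_from(cov, n_subjects=8, t=120, seed=2, noise_sd=0.5)
        group, report = ns.build_resting_matrix(panel)
        assert report["n_subjects_kept"] == 8
        mem = np.repeat([0, 1], 8)
        iu = np.triu_indices(16, k=1)
        vals = group.values[iu]
        within = vals[mem[iu[0]] == mem[iu[1]]]
        between = vals[mem[iu[0]] != mem[iu[1]]]
        se = np.sqrt(within.var(ddof=1) / within.size + between.var(ddof=1) / between.size)
        assert within.mean() - between.mean() > 3 * se
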